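"""Directional Borda aggregation of per-dataset PC1 rankings and the
binned cross-validation used to choose the core gene set.

Each dataset's adjusted-PCA fit yields a PC1 loading per gene; genes are
ranked per dataset and the rankings are aggregated by the Borda *median*
rule (a gene's consensus score is the median of its ranks).  To keep
directional information, the aggregation is run twice — once with
gregarious-biased (positive-loading) genes at the top, once with
solitary-biased genes at the top — and the two consensus lists are merged
by alternately taking the next unseen gene from each.  The core gene set is
the top fraction of that merged list.

Validation refits the model per gene bin and measures phase-prediction
accuracy either leave-one-sample-out within a dataset (LOO-CV) or by
training on one dataset and predicting the others (cross-dataset, CDV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acpca import (ACPCAModel, build_confounder_design, fit_acpca,
                    predict_phase, tune_lambda)
from .preprocess import counts_to_rpkm, log_quantile_center


@dataclass
class RankedGeneList:
    """Genes in rank order with their scores; ``direction`` states which
    phase the top of the list is biased toward ("G", "S" or "merged")."""

    gene_ids: pd.Index
    scores: np.ndarray
    direction: str = "G"

    def __post_init__(self) -> None:
        self.gene_ids = pd.Index(self.gene_ids)
        self.scores = np.asarray(self.scores, float)
        if self.gene_ids.duplicated().any():
            raise ValueError("gene ids must be unique")
        if len(self.gene_ids) != len(self.scores):
            raise ValueError("scores must align with gene_ids")

    def __len__(self) -> int:
        return len(self.gene_ids)


def rank_by_loading(pc1: pd.Series, direction: str = "G") -> RankedGeneList:
    """Order genes by PC1 loading; ``direction='G'`` puts the most positive
    (gregarious-biased) loadings first, ``'S'`` the most negative."""
    if direction not in ("G", "S"):
        raise ValueError("direction must be 'G' or 'S'")
    asc = direction == "S"
    s = pc1.sort_values(ascending=asc, kind="mergesort")
    return RankedGeneList(s.index, s.to_numpy(), direction)


@dataclass
class BordaResult:
    """Median-rank consensus over several rankings of a shared universe."""

    order: pd.Index
    median_rank: pd.Series
    mean_rank: pd.Series
    direction: str = "G"

    def as_list(self) -> RankedGeneList:
        return RankedGeneList(self.order, self.median_rank.loc[self.order].to_numpy(),
                              self.direction)


def borda_median(lists: list[RankedGeneList]) -> BordaResult:
    """Borda aggregation with the median rule.

    Lists are first restricted to their common gene universe; each gene's
    consensus score is the median of its (1-based) ranks across lists.
    Ties are broken by mean rank, then lexicographic gene id.
    """
    if len(lists) < 2:
        raise ValueError("need at least 2 lists")
    universe = lists[0].gene_ids
    for l in lists[1:]:
        universe = universe.intersection(l.gene_ids)
    if len(universe) == 0:
        raise ValueError("gene universes are disjoint")
    ranks = np.empty((len(universe), len(lists)))
    for j, l in enumerate(lists):
        kept = l.gene_ids[l.gene_ids.isin(universe)]
        r = pd.Series(np.arange(1, len(kept) + 1), index=kept)
        ranks[:, j] = r.loc[universe].to_numpy()
    med = pd.Series(np.median(ranks, axis=1), index=universe)
    mean = pd.Series(ranks.mean(axis=1), index=universe)
    key = pd.DataFrame({"med": med, "mean": mean, "gid": universe.astype(str)},
                       index=universe)
    order = key.sort_values(["med", "mean", "gid"], kind="mergesort").index
    direction = lists[0].direction
    return BordaResult(order, med, mean, direction)


def directional_merge(borda_g: BordaResult, borda_s: BordaResult) -> RankedGeneList:
    """Merge the gregarious-top and solitary-top consensus lists by
    alternately selecting the next not-yet-emitted gene from each.

    Every gene appears once and is tagged with the phase direction of the
    pass that contributed it (exposed via :func:`merge_directions`).
    """
    if set(borda_g.order) != set(borda_s.order):
        raise ValueError("the two passes must cover the same universe")
    merged, dirs = _alternate(list(borda_g.order), list(borda_s.order))
    scores = np.arange(1, len(merged) + 1, dtype=float)
    out = RankedGeneList(pd.Index(merged), scores, "merged")
    out.gene_direction = pd.Series(dirs, index=out.gene_ids, name="direction")
    return out


def _alternate(g_list: list, s_list: list) -> tuple[list, list]:
    emitted: set = set()
    merged: list = []
    dirs: list = []
    it_g, it_s = iter(g_list), iter(s_list)
    iters = [(it_g, "G"), (it_s, "S")]
    turn = 0
    n = len(g_list)
    while len(merged) < n:
        it, tag = iters[turn % 2]
        for gene in it:
            if gene not in emitted:
                emitted.add(gene)
                merged.append(gene)
                dirs.append(tag)
                break
        turn += 1
    return merged, dirs


def select_core(ranked: RankedGeneList, fraction: float = 0.10,
                universe_size: int | None = None) -> pd.Index:
    """Top ``floor(fraction * universe_size)`` genes of the ranked list."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if universe_size is None:
        universe_size = len(ranked)
    n = math.floor(fraction * universe_size)
    return ranked.gene_ids[:n]


def dataset_ranking(dataset, dataset_kind: str, lam: float | None = None,
                    tol: float = 0.05) -> tuple[ACPCAModel, pd.Series]:
    """Fit adjusted PCA on one dataset (counts or RPKM) and return the
    model plus its PC1 loadings, with lambda tuned unless given."""
    ds = counts_to_rpkm(dataset) if dataset.kind == "counts" else dataset
    x = log_quantile_center(ds)
    design, kept = build_confounder_design(ds.meta, dataset_kind)
    x = x.loc[kept]
    if lam is None:
        lam = tune_lambda(x, design, tol=tol).lam
    model = fit_acpca(x, design, lam, n_components=2,
                      phases=ds.meta.loc[kept, "phase"])
    return model, model.pc1


def directional_borda(pc1_lists: list[pd.Series]) -> RankedGeneList:
    """Two-pass directional Borda over per-dataset PC1 loading vectors."""
    g_pass = borda_median([rank_by_loading(p, "G") for p in pc1_lists])
    s_lists = [rank_by_loading(p, "S") for p in pc1_lists]
    s_pass = borda_median(s_lists)
    s_pass.direction = "S"
    return directional_merge(g_pass, s_pass)


def make_bins(ranked: RankedGeneList, bin_size: int, n_top: int) -> list[pd.Index]:
    """Split the top ``n_top`` genes of a ranked list into consecutive bins
    of ``bin_size`` genes each."""
    if len(ranked) < n_top:
        raise ValueError("ranked list shorter than n_top")
    if n_top % bin_size:
        raise ValueError("n_top must be divisible by bin_size")
    genes = ranked.gene_ids[:n_top]
    return [genes[i:i + bin_size] for i in range(0, n_top, bin_size)]


def binned_validation(datasets: dict[str, "ExpressionDataset"],
                      ranked: RankedGeneList, bin_size: int, n_top: int,
                      mode: str = "loo",
                      dataset_kinds: dict[str, str] | None = None,
                      lambdas: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-bin phase-prediction accuracy.

    ``mode='loo'``: within each dataset, refit on all-but-one sample for the
    bin's genes and predict the left-out sample; accuracy is the fraction of
    samples called correctly.  ``mode='cdv'``: train on one dataset (the
    row label) and predict the samples of the other datasets.  The penalty
    weight is tuned once per dataset on the full gene set and held fixed
    across bins and refits.
    """
    if mode not in ("loo", "cdv"):
        raise ValueError("mode must be 'loo' or 'cdv'")
    if dataset_kinds is None:
        dataset_kinds = {name: name for name in datasets}
    bins = make_bins(ranked, bin_size, n_top)
    for b in bins:
        if len(b) < 2:
            raise ValueError("bins must contain at least 2 genes")

    prep: dict[str, tuple[pd.DataFrame, "ConfounderDesign", pd.Series, float]] = {}
    for name, ds in datasets.items():
        dsr = counts_to_rpkm(ds) if ds.kind == "counts" else ds
        x = log_quantile_center(dsr)
        design, kept = build_confounder_design(dsr.meta, dataset_kinds[name])
        x = x.loc[kept]
        phases = dsr.meta.loc[kept, "phase"]
        if lambdas is not None and name in lambdas:
            lam = lambdas[name]
        else:
            lam = tune_lambda(x, design, tol=0.05).lam
        prep[name] = (x, design, phases, lam)

    rows = []
    for bi, bin_genes in enumerate(bins):
        for name, (x, design, phases, lam) in prep.items():
            genes = bin_genes.intersection(x.columns)
            if len(genes) < 2:
                raise ValueError("bin has < 2 genes present in the dataset")
            xb = x[genes]
            if mode == "loo":
                correct = 0
                for sid in xb.index:
                    train = xb.drop(index=sid)
                    tr_design, _ = _subset_design(design, train.index)
                    model = fit_acpca(train, tr_design, lam,
                                      n_components=1,
                                      phases=phases.drop(index=sid))
                    pred = predict_phase(model, xb.loc[[sid]],
                                         labels=phases.loc[[sid]])
                    correct += int(pred["correct"].iloc[0])
                rows.append((bi, name, correct / len(xb)))
            else:
                model = fit_acpca(xb, design, lam, n_components=1, phases=phases)
                hits = total = 0
                for other, (xo, _, ph_o, _) in prep.items():
                    if other == name:
                        continue
                    genes_o = genes.intersection(xo.columns)
                    pred = predict_phase(model, xo[genes_o], labels=ph_o)
                    hits += int(pred["correct"].sum())
                    total += len(pred)
                rows.append((bi, name, hits / total))
    out = pd.DataFrame(rows, columns=["bin", "train_dataset", "accuracy"])
    out["mode"] = mode
    return out


def _subset_design(design, sample_ids):
    """Restrict a confounder design to a subset of its samples."""
    from .acpca import ConfounderDesign
    old_ids = design.sample_ids
    keep = pd.Index(sample_ids)
    pos_of = {sid: i for i, sid in enumerate(keep)}
    groups = []
    for g in design.groups:
        members = [pos_of[old_ids[i]] for i in g if old_ids[i] in pos_of]
        if members:
            groups.append(np.asarray(members))
    return ConfounderDesign(keep, groups), keep
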