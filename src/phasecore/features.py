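"""Per-gene attribute measurements and their rank-bin trend summaries.

Covers the specificity index tau, the CpG observed/expected dinucleotide
ratio, gene-body methylation summarization, topological-overlap (TOM)
network connectivity, the Audic-Claverie no-replicate differential test and
the derived phase-related gene (PRG) calls, and the binning of features
along a ranked gene list.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import spearmanr

from .enrich import bh_adjust


# ---------------------------------------------------------------- tau ----

def tau(expression_row) -> float:
    """Specificity index tau over n samples of one gene.

    ``tau = sum_j (1 - log2(S_j + 1) / log2(S_max + 1)) / (n - 1)``;
    0 for uniform expression, 1 for expression confined to one sample.
    Returns NaN for an all-zero row (undefined).
    """
    s = np.asarray(expression_row, float)
    if s.ndim != 1 or s.size < 2:
        raise ValueError("tau needs a 1-D row with n >= 2 samples")
    if (s < 0).any():
        raise ValueError("expression must be non-negative")
    smax = s.max()
    if smax == 0 or np.log2(smax + 1.0) == 0.0:  # all-zero (or underflow)
        return float("nan")
    terms = 1.0 - np.log2(s + 1.0) / np.log2(smax + 1.0)
    return float(terms.sum() / (s.size - 1))


def tau_table(rpkm: pd.DataFrame) -> pd.Series:
    """tau per gene of a genes x samples RPKM matrix."""
    return rpkm.apply(lambda row: tau(row.to_numpy()), axis=1).rename("tau")


# ------------------------------------------------------------ CpG o/e ----

def cpg_oe(sequence: str) -> float:
    """CpG observed/expected ratio of a nucleotide sequence.

    ``%CG / (%C * %G)`` with ``%CG = #CG / (L - 1)``; case-insensitive,
    non-ACGT characters are excluded from both the dinucleotide count and
    the base fractions.  Returns NaN when the sequence has no C or no G.
    """
    seq = "".join(c for c in sequence.upper() if c in "ACGT")
    L = len(seq)
    if L < 2:
        raise ValueError("sequence must contain >= 2 ACGT characters")
    n_cg = seq.count("CG")
    f_c = seq.count("C") / L
    f_g = seq.count("G") / L
    if f_c == 0 or f_g == 0:
        return float("nan")
    return (n_cg / (L - 1)) / (f_c * f_g)


def cpg_oe_table(sequences: dict[str, str]) -> pd.Series:
    return pd.Series({g: cpg_oe(s) for g, s in sequences.items()},
                     name="cpg_oe")


# -------------------------------------------------------- methylation ----

def methylation_gene_level(table: pd.DataFrame, min_sites: int = 19) -> pd.Series:
    """Mean CG-site methylation per gene body.

    ``table`` has columns ``gene_id`` and ``beta`` (one row per CG site,
    levels in [0, 1]); genes with fewer than ``min_sites`` sites are dropped
    for reliability.
    """
    if len(table) == 0:
        return pd.Series(dtype=float, name="methylation_mean")
    if ((table["beta"] < 0) | (table["beta"] > 1)).any():
        raise ValueError("methylation levels must be in [0, 1]")
    grouped = table.groupby("gene_id")["beta"]
    counts = grouped.size()
    means = grouped.mean()
    return means[counts >= min_sites].rename("methylation_mean")


# ------------------------------------------------ TOM connectivity ----

def tom_matrix(expr: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Topological overlap matrix from a signed soft-threshold adjacency.

    ``expr`` is samples x genes.  Adjacency ``a_ij = ((1 + cor_ij)/2)^beta``
    (diagonal zero); ``TOM_ij = (sum_u a_iu a_uj + a_ij) /
    (min(k_i, k_j) + 1 - a_ij)`` with ``k`` the adjacency row sums.
    Zero-variance genes get zero correlation to everything.
    """
    if expr.shape[0] < 3:
        raise ValueError("need >= 3 samples")
    if beta < 1:
        raise ValueError("beta must be >= 1")
    x = expr.to_numpy(float)
    sd = x.std(axis=0)
    flat = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x, rowvar=False)
    c = np.nan_to_num(c, nan=0.0)
    c[flat, :] = 0.0
    c[:, flat] = 0.0
    np.fill_diagonal(c, 1.0)
    a = ((1.0 + c) / 2.0) ** beta
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 0.0)
    return pd.DataFrame(tom, index=expr.columns, columns=expr.columns)


def tom_connectivity(expr: pd.DataFrame, beta: float) -> pd.Series:
    """Per-gene network connectivity: sum of topological overlap with all
    other genes."""
    tom = tom_matrix(expr, beta)
    return tom.sum(axis=1).rename("connectivity")


# -------------------------------------------------- Audic-Claverie ----

def _ac_log_pmf(ts: np.ndarray, x: int, log_r: float) -> np.ndarray:
    """log p(t | x) for the no-replicate count model with rate ratio
    r = N2/N1:  p(y|x) = r^y (x+y)! / (x! y! (1+r)^(x+y+1))."""
    return (ts * log_r + gammaln(x + ts + 1) - gammaln(x + 1)
            - gammaln(ts + 1) - (x + ts + 1) * np.log1p(np.exp(log_r)))


def audic_claverie_p(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided Audic-Claverie p-value for counts without replicates.

    The conditional distribution of the second-library count given the
    first is ``p(y|x) = (N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^(x+y+1))``.
    The two tails ``P(Y <= y | x)`` and ``P(X <= x | y)`` (with the library
    ratio inverted) are exact complements; the two-sided p is twice the
    smaller of them, capped at 1 and computed in log space, which makes the
    test exchangeable: ``p(x, y, N1, N2) = p(y, x, N2, N1)``.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    x, y = int(x), int(y)
    log_r = float(np.log(n2) - np.log(n1))
    log_lower = logsumexp(_ac_log_pmf(np.arange(0, y + 1), x, log_r))
    log_lower_swapped = logsumexp(_ac_log_pmf(np.arange(0, x + 1), y, -log_r))
    p = 2.0 * np.exp(min(log_lower, log_lower_swapped))
    return float(min(p, 1.0))


# ------------------------------------------------------------- PRGs ----

def detect_prgs(dataset, alpha: float = 0.05, min_fold: float = 2.0,
                rule: str = "any") -> pd.Index:
    """Phase-related genes of one dataset (no-replicate design).

    Samples are paired G vs S within each confounder level; per comparison
    a gene is significant when its BH-adjusted Audic-Claverie p is below
    ``alpha`` and the depth-normalized fold change is at least
    ``min_fold``.  ``rule`` decides how comparisons combine: a gene is a
    PRG when significant in ``any`` / a ``majority`` of / ``all``
    comparisons.
    """
    if rule not in ("any", "majority", "all"):
        raise ValueError("rule must be 'any', 'majority' or 'all'")
    if dataset.kind != "counts":
        raise ValueError("PRG detection needs raw counts")
    meta = dataset.meta
    counts = dataset.values
    sig = []
    for level, sub in meta.groupby("confounder_level", sort=False):
        g = sub.index[sub["phase"] == "G"]
        s = sub.index[sub["phase"] == "S"]
        if len(g) != 1 or len(s) != 1:
            raise ValueError(f"confounder level {level!r} is not a matched "
                             "G/S pair")
        xg = counts[g[0]].to_numpy()
        xs = counts[s[0]].to_numpy()
        n1, n2 = float(xg.sum()), float(xs.sum())
        pvals = np.array([audic_claverie_p(a, b, n1, n2)
                          for a, b in zip(xg, xs)])
        q = bh_adjust(pvals)
        cpm_g = (xg + 0.5) / n1
        cpm_s = (xs + 0.5) / n2
        fold = np.maximum(cpm_g / cpm_s, cpm_s / cpm_g)
        sig.append((q < alpha) & (fold >= min_fold))
    sig = np.column_stack(sig)
    if rule == "any":
        mask = sig.any(axis=1)
    elif rule == "all":
        mask = sig.all(axis=1)
    else:
        mask = sig.sum(axis=1) > sig.shape[1] / 2
    return counts.index[mask]


def feature_table(rpkm: pd.DataFrame | None = None,
                  sequences: dict[str, str] | None = None,
                  methylation: pd.DataFrame | None = None,
                  connectivity: pd.Series | None = None,
                  prgs=None, known_function=None,
                  gene_ids=None) -> pd.DataFrame:
    """Assemble the per-gene feature table from whichever inputs are given.

    Columns: tau, cpg_oe, methylation_mean, connectivity (numeric, missing
    where not computable) and the is_prg / is_known_function flags.
    Missing values stay missing; they are never silently zero.
    """
    pieces = {}
    if rpkm is not None:
        pieces["tau"] = tau_table(rpkm)
    if sequences is not None:
        pieces["cpg_oe"] = cpg_oe_table(sequences)
    if methylation is not None:
        pieces["methylation_mean"] = methylation_gene_level(methylation)
    if connectivity is not None:
        pieces["connectivity"] = connectivity
    if not pieces and gene_ids is None:
        raise ValueError("no inputs given")
    table = pd.DataFrame(pieces)
    if gene_ids is not None:
        table = table.reindex(pd.Index(gene_ids))
    if prgs is not None:
        table["is_prg"] = table.index.isin(pd.Index(prgs))
    if known_function is not None:
        table["is_known_function"] = table.index.isin(pd.Index(known_function))
    table.index.name = "gene_id"
    return table


# ------------------------------------------------------- bin trends ----

def bin_feature_trends(ranked_genes, feature_table: pd.DataFrame,
                       bin_size: int = 1700, n_top: int = 15300) -> pd.DataFrame:
    """Summarize gene features along a ranked list in equal bins.

    The top ``n_top`` genes are split sequentially into ``n_top/bin_size``
    bins (the first bin being the core set); numeric features are
    summarized by bin mean and median, boolean flags by their fraction.
    A ``spearman_rho`` attribute on the result records the trend of each
    feature's bin means against bin index.
    """
    genes = pd.Index(ranked_genes)
    if n_top % bin_size:
        raise ValueError("n_top must be divisible by bin_size")
    if len(genes) < n_top:
        raise ValueError("ranked list shorter than n_top")
    genes = genes[:n_top]
    n_bins = n_top // bin_size
    bin_idx = np.repeat(np.arange(1, n_bins + 1), bin_size)
    ft = feature_table.reindex(genes)
    ft = ft.assign(_bin=bin_idx)
    agg = {}
    trends = {}
    for col in feature_table.columns:
        series = ft[col]
        if series.dtype == bool:
            summary = ft.groupby("_bin")[col].mean().rename(f"{col}_fraction")
        else:
            summary = ft.groupby("_bin")[col].agg(["mean", "median"])
            summary.columns = [f"{col}_mean", f"{col}_median"]
        agg[col] = summary
        means = summary.iloc[:, 0]
        if means.notna().sum() >= 3 and means.nunique() > 1:
            rho = spearmanr(means.index[means.notna()], means.dropna())[0]
        else:
            rho = 0.0
        trends[col] = float(rho)
    out = pd.concat(agg.values(), axis=1)
    out.index.name = "bin"
    out.attrs["spearman_rho"] = trends
    return out
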