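"""High-level pipeline helpers tying the modules together.

These wrap the per-module operations into the study-level workflow: per-
dataset adjusted-PCA ranking, directional Borda aggregation and core
selection, pooled network inference, and edge-recovery evaluation against
a known network.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import counts_to_rpkm, log_quantile_center
from .rank import (RankedGeneList, dataset_ranking, directional_borda,
                   select_core)
from .synth import SyntheticStudy
from . import trn


def study_rankings(study: SyntheticStudy, lam: float | None = None
                   ) -> tuple[dict, list[pd.Series]]:
    """Fit adjusted PCA per dataset; returns models and PC1 loading lists."""
    models, pc1s = {}, []
    for name, ds in study.datasets.items():
        model, pc1 = dataset_ranking(ds, name, lam=lam)
        models[name] = model
        pc1s.append(pc1)
    return models, pc1s


def study_core_genes(study: SyntheticStudy, fraction: float = 0.10
                     ) -> tuple[RankedGeneList, pd.Index]:
    """Directional Borda list over the three datasets and its top fraction."""
    _, pc1s = study_rankings(study)
    merged = directional_borda(pc1s)
    return merged, select_core(merged, fraction, len(merged))


def pooled_normalized_matrix(study: SyntheticStudy) -> pd.DataFrame:
    """All samples of all datasets as one log/quantile/centered matrix
    (samples x genes), the input to network inference."""
    rpkms = [counts_to_rpkm(d).values for d in study.datasets.values()]
    return log_quantile_center(pd.concat(rpkms, axis=1))


def score_all_methods(X: pd.DataFrame, tf_list, seed: int = 0,
                      n_trees: int = 30, tom_beta: float = 6.0,
                      module_k_range=(3, 12)) -> list[trn.ScoreMatrix]:
    """Run the six network scorers on one matrix."""
    return [
        trn.score_mi_clr(X, tf_list),
        trn.score_aracne(X, tf_list),
        trn.score_tom(X, tf_list, beta=tom_beta),
        trn.score_tree_importance(X, tf_list, n_trees=n_trees, seed=seed),
        trn.score_partial_correlation(X, tf_list),
        trn.score_modules_multi([X], tf_list, k_range=module_k_range,
                                iters=3, seed=seed),
    ]


def edge_auroc(scores_or_ranks, truth_edges: pd.DataFrame, tfs, genes) -> float:
    """AUROC of an edge scoring against the planted TF->target network.

    ``scores_or_ranks`` is either a ScoreMatrix (higher = stronger) or a
    Series of aggregate ranks indexed by (tf, target) (lower = stronger);
    pairs absent from a rank list get a worst rank.
    """
    from sklearn.metrics import roc_auc_score
    idx = pd.MultiIndex.from_product([pd.Index(tfs), pd.Index(genes)])
    idx = idx[idx.get_level_values(0) != idx.get_level_values(1)]
    truth = set(zip(truth_edges["tf"], truth_edges["target"]))
    y = np.fromiter(((a, b) in truth for a, b in idx), dtype=bool,
                    count=len(idx))
    if isinstance(scores_or_ranks, trn.ScoreMatrix):
        s = scores_or_ranks.scores.stack(future_stack=True).reindex(idx)
        v = s.to_numpy(float)
        finite = np.isfinite(v)
        v[~finite] = v[finite].min() - 1.0
    else:
        ranks = scores_or_ranks.reindex(idx)
        worst = float(np.nanmax(ranks)) + 1.0
        v = -ranks.fillna(worst).to_numpy(float)
    return float(roc_auc_score(y.astype(int), v))
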