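"""Ensemble transcriptional-regulatory-network inference.

Several independent scorers each produce a TF x gene matrix of regulatory
strengths from the same preprocessed expression matrix:

* ``score_mi_clr`` — mutual information with the CLR background correction,
* ``score_aracne`` — mutual information pruned by the data-processing
  inequality (the weakest edge of every triangle is removed),
* ``score_tom`` — signed soft-threshold co-expression topological overlap,
* ``score_tree_importance`` — tree-ensemble regression importance of each
  TF for each target (GENIE3-style),
* ``score_partial_correlation`` — shrinkage-regularized Gaussian graphical
  model partial correlations,
* ``score_modules`` — a module-based surrogate: genes are clustered by
  K-means (K chosen by BIC) and every member of a cluster inherits the
  |correlation| of the TF with the cluster centroid.

Each scorer's TF-target pairs are ranked, truncated, and aggregated by
Borda with the median rule into the ensemble network; target genes
regulated by (essentially) every TF are filtered as promiscuous and the
network refilled once from the aggregate list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import ExtraTreesRegressor

from .features import tom_matrix

MI_CAP = 1e6  # cap for the Gaussian MI of perfectly correlated pairs


@dataclass
class ScoreMatrix:
    """TF x gene regulatory-strength scores for one inference method."""

    scores: pd.DataFrame  # index = TFs, columns = genes
    method: str

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy(float)
        if not np.isfinite(vals).all():
            raise ValueError("scores must be finite")
        # self-regulation is masked
        for tf in self.scores.index:
            if tf in self.scores.columns:
                self.scores.loc[tf, tf] = -np.inf

    def pair_ranking(self) -> pd.DataFrame:
        """All TF->gene pairs sorted by decreasing score (self-edges last)."""
        stacked = self.scores.rename_axis(index="tf", columns="target")
        long = stacked.stack(future_stack=True).rename("score").reset_index()
        long = long[long["tf"] != long["target"]]
        long = long.sort_values(["score", "tf", "target"],
                                ascending=[False, True, True],
                                kind="mergesort").reset_index(drop=True)
        long["rank"] = np.arange(1, len(long) + 1)
        return long


def _validate_matrix(matrix: pd.DataFrame, tf_list, min_samples: int) -> list:
    if matrix.shape[0] < min_samples:
        raise ValueError(f"need >= {min_samples} samples")
    tfs = [t for t in tf_list if t in matrix.columns]
    if not tfs:
        raise ValueError("no TF found in the expression matrix")
    return tfs


def _gaussian_mi(matrix: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Gaussian MI = -0.5 log(1 - rho^2), capped for |rho| = 1."""
    x = matrix.to_numpy(float)
    sd = x.std(axis=0)
    flat = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x, rowvar=False)
    c = np.nan_to_num(c, nan=0.0)
    c[flat, :] = 0.0
    c[:, flat] = 0.0
    np.fill_diagonal(c, 0.0)
    r2 = np.clip(c ** 2, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        mi = -0.5 * np.log1p(-r2)
    mi = np.minimum(np.nan_to_num(mi, posinf=MI_CAP), MI_CAP)
    return mi, flat


def _binned_mi(matrix: pd.DataFrame, n_bins: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise MI from fixed equal-width binning (plug-in estimator)."""
    x = matrix.to_numpy(float)
    n, p = x.shape
    lo, hi = x.min(axis=0), x.max(axis=0)
    flat = hi == lo
    width = np.where(flat, 1.0, hi - lo)
    b = np.clip(((x - lo) / width * n_bins).astype(int), 0, n_bins - 1)
    mi = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            joint = np.bincount(b[:, i] * n_bins + b[:, j],
                                minlength=n_bins * n_bins).reshape(n_bins, n_bins)
            pj = joint / n
            pi_ = pj.sum(axis=1, keepdims=True)
            pj_ = pj.sum(axis=0, keepdims=True)
            nzm = pj > 0
            mi[i, j] = mi[j, i] = float(
                (pj[nzm] * np.log(pj[nzm] / (pi_ @ pj_)[nzm])).sum())
    mi[flat, :] = 0.0
    mi[:, flat] = 0.0
    return mi, flat


def _mi_matrix(matrix: pd.DataFrame, estimator: str) -> np.ndarray:
    if estimator == "gaussian":
        mi, _ = _gaussian_mi(matrix)
    elif estimator == "binned":
        mi, _ = _binned_mi(matrix)
    else:
        raise ValueError("estimator must be 'gaussian' or 'binned'")
    return mi


def score_mi_clr(matrix: pd.DataFrame, tf_list,
                 estimator: str = "gaussian") -> ScoreMatrix:
    """Context-likelihood-of-relatedness scores.

    The MI of each pair is standardized against the MI background of both
    of its genes; ``z_ij = sqrt(max(0, z_i(j))^2 + max(0, z_j(i))^2)``.
    """
    tfs = _validate_matrix(matrix, tf_list, 8)
    mi = _mi_matrix(matrix, estimator)
    mu = mi.mean(axis=1)
    sd = mi.std(axis=1)
    sd[sd == 0] = 1.0
    z_rows = np.maximum((mi - mu[:, None]) / sd[:, None], 0.0)
    z = np.sqrt(z_rows ** 2 + z_rows.T ** 2)
    genes = matrix.columns
    tf_pos = genes.get_indexer(tfs)
    return ScoreMatrix(pd.DataFrame(z[tf_pos], index=pd.Index(tfs),
                                    columns=genes), "clr")


def dpi_prune(mi: np.ndarray, rows: np.ndarray, dpi_eps: float = 0.0
              ) -> np.ndarray:
    """Data-processing-inequality mask for the given rows of an MI matrix.

    Entry [r, j] is True when edge (rows[r], j) is the strict minimum of some
    triangle: ``MI_ij < min(MI_ik, MI_jk) - dpi_eps`` for some k.  The
    strongest edge of a triangle can never satisfy this.
    """
    removed = np.zeros((len(rows), mi.shape[1]), dtype=bool)
    for r, i in enumerate(rows):
        maxmin = np.minimum(mi[i][None, :], mi).max(axis=1)
        removed[r] = mi[i] < maxmin - dpi_eps
    return removed


def score_aracne(matrix: pd.DataFrame, tf_list, dpi_eps: float = 0.0,
                 estimator: str = "gaussian") -> ScoreMatrix:
    """ARACNE: raw MI with data-processing-inequality pruning.

    An edge (i, j) is removed when some third gene k satisfies
    ``MI_ij < min(MI_ik, MI_jk) - dpi_eps``; the surviving edges keep their
    MI as score (pruned edges score 0).  Pruning is evaluated for the TF
    rows, against triangles through every gene.
    """
    tfs = _validate_matrix(matrix, tf_list, 8)
    mi = _mi_matrix(matrix, estimator)
    genes = matrix.columns
    tf_pos = genes.get_indexer(tfs)
    kept = mi[tf_pos].copy()
    kept[dpi_prune(mi, tf_pos, dpi_eps)] = 0.0
    return ScoreMatrix(pd.DataFrame(kept, index=pd.Index(tfs), columns=genes),
                       "aracne")


def score_tom(matrix: pd.DataFrame | list[pd.DataFrame], tf_list,
              beta: float = 6.0) -> ScoreMatrix:
    """Topological-overlap co-expression scores (TF rows of the TOM).

    When several per-dataset matrices are supplied, each dataset's pair
    ranking is computed separately and the rankings are merged by Borda
    (median rank; negated so larger = stronger).
    """
    if isinstance(matrix, list):
        mats = matrix
        per = [score_tom(m, tf_list, beta).pair_ranking() for m in mats]
        merged = _borda_pair_ranks(per, limit=None)
        tfs = sorted({t for p in per for t in p["tf"].unique()})
        genes = mats[0].columns
        score = pd.DataFrame(0.0, index=pd.Index(tfs), columns=genes)
        for _, row in merged.iterrows():
            score.loc[row["tf"], row["target"]] = -row["agg_rank"]
        return ScoreMatrix(score, "tom")
    tfs = _validate_matrix(matrix, tf_list, 3)
    tom = tom_matrix(matrix, beta)
    return ScoreMatrix(tom.loc[tfs], "tom")


def score_tree_importance(matrix: pd.DataFrame, tf_list, n_trees: int = 50,
                          seed: int = 0, max_features: str | float = "sqrt"
                          ) -> ScoreMatrix:
    """Tree-ensemble importance of every TF for every target gene.

    For each target, an extremely-randomized-trees regression of the target
    profile on all TF profiles (the target itself excluded when it is a TF)
    is fitted; the score is the impurity-reduction importance.
    """
    tfs = _validate_matrix(matrix, tf_list, 10)
    genes = matrix.columns
    x_tf = matrix[tfs].to_numpy(float)
    out = pd.DataFrame(0.0, index=pd.Index(tfs), columns=genes)
    rng = np.random.RandomState(seed)
    for g in genes:
        y = matrix[g].to_numpy(float)
        if y.std() == 0:
            continue
        cols = [i for i, t in enumerate(tfs) if t != g]
        if not cols:
            continue
        model = ExtraTreesRegressor(n_estimators=n_trees,
                                    max_features=max_features,
                                    random_state=rng.randint(2 ** 31 - 1),
                                    n_jobs=1)
        model.fit(x_tf[:, cols], y)
        out.loc[[tfs[i] for i in cols], g] = model.feature_importances_
    return ScoreMatrix(out, "trees")


def score_partial_correlation(matrix: pd.DataFrame, tf_list,
                              shrinkage: float | None = None) -> ScoreMatrix:
    """Shrinkage-regularized partial correlations (Gaussian graphical model).

    The correlation matrix is shrunk toward the identity — by the
    Schaefer-Strimmer analytic intensity unless ``shrinkage`` is given —
    inverted, and scaled to partial correlations; the score is their
    absolute value.
    """
    tfs = _validate_matrix(matrix, tf_list, 4)
    x = matrix.to_numpy(float)
    n, p = x.shape
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    r = (z.T @ z) / (n - 1)
    np.fill_diagonal(r, 1.0)
    if shrinkage is None:
        # Schaefer-Strimmer: lambda* = sum Var(r_ij) / sum r_ij^2 (off-diag),
        # with Var(r_ij) = n/(n-1)^3 * sum_k (w_kij - wbar_ij)^2 computed via
        # sum w^2 = (Z*Z)'(Z*Z) to avoid materializing the n x p x p tensor
        z2 = z ** 2
        sum_w2 = z2.T @ z2
        wbar = (n - 1) / n * r
        ss = sum_w2 - n * wbar ** 2
        var_r = n / (n - 1) ** 3 * ss
        off = ~np.eye(p, dtype=bool)
        denom = (r[off] ** 2).sum()
        shrinkage = 1.0 if denom == 0 else float(np.clip(
            var_r[off].sum() / denom, 0.0, 1.0))
    r_shrunk = (1 - shrinkage) * r + shrinkage * np.eye(p)
    omega = np.linalg.inv(r_shrunk)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    genes = matrix.columns
    tf_pos = genes.get_indexer(tfs)
    sm = ScoreMatrix(pd.DataFrame(np.abs(pcor[tf_pos]), index=pd.Index(tfs),
                                  columns=genes), "ggm")
    sm.pcor = pd.DataFrame(pcor, index=genes, columns=genes)
    sm.shrinkage = shrinkage
    return sm


@dataclass
class ModuleClustering:
    """K-means clustering of gene profiles with the K chosen by BIC."""

    k: int
    assignments: pd.Series        # gene -> cluster id
    centroids: np.ndarray         # k x samples
    sigma_eps: float              # residual s.d. evaluated at K = 3
    bic_curve: pd.Series          # K -> BIC


def kmeans_bic(matrix: pd.DataFrame, k_range: tuple[int, int] = (3, 100),
               iters: int = 10, seed: int = 0) -> ModuleClustering:
    """Cluster genes (rows = genes, coordinates = samples) by K-means and
    choose K minimizing

    ``BIC(K) = sum_l sum_j ((x_lj - c_{k_l, j}) / sigma_eps)^2
    + log(N) * M * K``

    with ``sigma_eps^2`` the mean intra-cluster variance evaluated at
    K = 3, N the number of genes and M the number of samples.
    """
    genes_by_samples = matrix.T if matrix.shape[0] < matrix.shape[1] else matrix
    x = genes_by_samples.to_numpy(float)
    n, m = x.shape
    k_lo, k_hi = int(k_range[0]), int(k_range[1])
    if k_lo < 2 or k_hi > n - 1 or k_lo > k_hi:
        raise ValueError("k_range must lie within [2, N-1]")

    def _fit(k: int):
        km = KMeans(n_clusters=k, n_init=iters, random_state=seed)
        labels = km.fit_predict(x)
        resid = x - km.cluster_centers_[labels]
        return km, labels, resid

    _, labels3, resid3 = _fit(3)
    sigma2 = float((resid3 ** 2).sum() / resid3.size)
    if sigma2 == 0:
        sigma2 = 1e-12
    bic = {}
    fits = {}
    for k in range(k_lo, k_hi + 1):
        km, labels, resid = _fit(k)
        rss = float((resid ** 2).sum())
        bic[k] = rss / sigma2 + np.log(n) * m * k
        fits[k] = (km, labels)
    curve = pd.Series(bic).sort_index()
    k_star = int(curve.idxmin())
    km, labels = fits[k_star]
    return ModuleClustering(k=k_star,
                            assignments=pd.Series(labels,
                                                  index=genes_by_samples.index),
                            centroids=km.cluster_centers_,
                            sigma_eps=float(np.sqrt(sigma2)),
                            bic_curve=curve)


def score_modules(clustering: ModuleClustering, matrix: pd.DataFrame,
                  tf_list) -> ScoreMatrix:
    """Module-based surrogate scores: every member of a cluster inherits
    |cor(TF profile, cluster centroid profile)|."""
    tfs = _validate_matrix(matrix, tf_list, 3)
    genes = matrix.columns
    cent = clustering.centroids  # k x samples
    out = pd.DataFrame(0.0, index=pd.Index(tfs), columns=genes)
    assign = clustering.assignments.reindex(genes)
    for tf in tfs:
        prof = matrix[tf].to_numpy(float)
        if prof.std() == 0:
            continue
        cors = np.zeros(cent.shape[0])
        for k in range(cent.shape[0]):
            c = cent[k]
            if c.std() == 0:
                continue
            cors[k] = abs(np.corrcoef(prof, c)[0, 1])
        out.loc[tf] = cors[assign.to_numpy(int)]
    return ScoreMatrix(out, "modules")


def score_modules_multi(matrices: list[pd.DataFrame], tf_list,
                        k_range=(3, 15), iters: int = 5, seed: int = 0
                        ) -> ScoreMatrix:
    """Per-dataset module scores merged by Borda (median pair rank)."""
    per = []
    for i, m in enumerate(matrices):
        clustering = kmeans_bic(m.T, k_range=k_range, iters=iters,
                                seed=seed + i)
        per.append(score_modules(clustering, m, tf_list).pair_ranking())
    merged = _borda_pair_ranks(per, limit=None)
    tfs = sorted({t for p in per for t in p["tf"].unique()})
    genes = matrices[0].columns
    score = pd.DataFrame(0.0, index=pd.Index(tfs), columns=genes)
    for _, row in merged.iterrows():
        score.loc[row["tf"], row["target"]] = -row["agg_rank"]
    return ScoreMatrix(score, "modules")


# --------------------------------------------------------- ensembling ----

def _borda_pair_ranks(rankings: list[pd.DataFrame],
                      limit: int | None) -> pd.DataFrame:
    """Median-rank Borda over per-method pair rankings.

    Each ranking has columns tf, target, rank.  With ``limit`` set, each
    ranking is truncated to its top ``limit`` pairs and pairs absent from a
    truncated list are assigned rank ``limit + 1``.
    """
    trunc = []
    for rk in rankings:
        rk = rk[["tf", "target", "rank"]]
        if limit is not None:
            rk = rk[rk["rank"] <= limit]
        trunc.append(rk.set_index(["tf", "target"])["rank"])
    index = trunc[0].index
    for t in trunc[1:]:
        index = index.union(t.index)
    fill = (limit + 1) if limit is not None else max(len(t) for t in trunc) + 1
    mat = np.column_stack([t.reindex(index, fill_value=fill).to_numpy()
                           for t in trunc])
    med = np.median(mat, axis=1)
    mean = mat.mean(axis=1)
    out = pd.DataFrame({"tf": index.get_level_values(0),
                        "target": index.get_level_values(1),
                        "agg_rank": med, "mean_rank": mean})
    for j, rk in enumerate(trunc):
        out[f"rank_{j}"] = mat[:, j]
    out = out.sort_values(["agg_rank", "mean_rank", "tf", "target"],
                          kind="mergesort").reset_index(drop=True)
    return out


@dataclass
class EnsembleNetwork:
    """Directed TF->target edge list with per-method and aggregate ranks."""

    edges: pd.DataFrame           # tf, target, agg_rank, rank_<method>...
    tfs: list[str]
    methods: list[str]
    aggregate: pd.DataFrame | None = None  # full aggregate list pre-truncation
    filtered_targets: list[str] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def nodes(self) -> pd.Index:
        return pd.Index(self.edges["tf"]).union(pd.Index(self.edges["target"]))

    def targets_of(self, tf: str) -> pd.Index:
        return pd.Index(self.edges.loc[self.edges["tf"] == tf, "target"])

    def mean_targets_per_tf(self) -> float:
        n_tf = self.edges["tf"].nunique()
        return self.n_edges / n_tf if n_tf else float("nan")


def ensemble_network(score_matrices: list[ScoreMatrix],
                     top_k_per_method: int = 100_000,
                     top_k_final: int = 100_000,
                     promiscuity_fraction: float = 1.0) -> EnsembleNetwork:
    """Aggregate per-method TF-target rankings into one network.

    Per method the pairs are ranked by decreasing score and truncated to
    ``top_k_per_method``; pairs missing from a truncated list get rank
    ``top_k_per_method + 1``.  The Borda-median aggregate is truncated to
    ``top_k_final``; target genes regulated by at least
    ``promiscuity_fraction`` of the network's TFs are then dropped as
    promiscuous and the network refilled once from the aggregate list.
    """
    if len(score_matrices) < 2:
        raise ValueError("need >= 2 score matrices")
    genes = score_matrices[0].scores.columns
    for sm in score_matrices[1:]:
        if not genes.equals(sm.scores.columns):
            raise ValueError("score matrices cover different gene universes")
    rankings = [sm.pair_ranking() for sm in score_matrices]
    agg = _borda_pair_ranks(rankings, limit=top_k_per_method)
    methods = [sm.method for sm in score_matrices]
    agg = agg.rename(columns={f"rank_{j}": f"rank_{m}"
                              for j, m in enumerate(methods)})
    edges = agg.head(top_k_final).copy()

    n_tfs = edges["tf"].nunique()
    degree = edges.groupby("target")["tf"].nunique()
    promiscuous = list(degree.index[degree >= promiscuity_fraction * n_tfs])
    if promiscuous:
        clean = agg[~agg["target"].isin(promiscuous)]
        edges = clean.head(top_k_final).copy()
    tfs = sorted(set(score_matrices[0].scores.index))
    return EnsembleNetwork(edges=edges.reset_index(drop=True), tfs=tfs,
                           methods=methods, aggregate=agg,
                           filtered_targets=promiscuous)


def per_tf_network(score_matrices: list[ScoreMatrix],
                   top_m: int = 1700) -> EnsembleNetwork:
    """Borda-aggregate each TF's pair ranks separately and keep its top
    ``top_m`` targets, so every TF gets a comparably sized target set."""
    if len(score_matrices) < 1:
        raise ValueError("need >= 1 score matrix")
    genes = score_matrices[0].scores.columns
    tfs = list(score_matrices[0].scores.index)
    methods = [sm.method for sm in score_matrices]
    pieces = []
    for tf in tfs:
        per = []
        for sm in score_matrices:
            s = sm.scores.loc[tf].drop(labels=[tf], errors="ignore")
            order = s.sort_values(ascending=False, kind="mergesort")
            per.append(pd.DataFrame({"tf": tf, "target": order.index,
                                     "rank": np.arange(1, len(order) + 1)}))
        agg = _borda_pair_ranks(per, limit=None)
        pieces.append(agg.head(min(top_m, len(agg))))
    edges = pd.concat(pieces, ignore_index=True)
    edges = edges.rename(columns={f"rank_{j}": f"rank_{m}"
                                  for j, m in enumerate(methods)})
    return EnsembleNetwork(edges=edges, tfs=tfs, methods=methods)


def write_edges_tsv(network: EnsembleNetwork, path) -> None:
    network.edges.to_csv(path, sep="\t", index=False)
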