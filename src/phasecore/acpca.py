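"""Confounder-adjusted PCA.

Ordinary PCA of a heterogeneous expression study is dominated by the
between-stage / between-tissue / between-time variation rather than the
phase difference of interest.  Adjusted PCA maximizes, over unit loading
vectors ``v``,

    v' X' X v  -  lambda * penalty(v),
    penalty(v) = sum_groups sum_{i in g} ((x_i - xbar_g) . v)^2,

i.e. captured variance minus a penalty on projection scatter *within*
declared replicate groups.  The replicate groups encode the confounder
design: for the development and tissue datasets all samples of the same
phase are biological replicates (so stage/tissue variation is confounding);
for the time-course datasets, samples of the two tissues at the same time
point under the same treatment are replicates, and the final converged time
point is dropped before fitting.

With the penalty written through the within-group centering operator ``H``
(idempotent, symmetric), the objective is the quadratic form of
``X'(I - lambda*H)X`` and the loadings are its leading eigenvectors; they
are computed in sample space (via the thin SVD of ``X``), which is exact
because every eigenvector with nonzero eigenvalue lies in the row space of
``X``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DATASET_KINDS = ("development", "tissue", "timecourse")


@dataclass
class ConfounderDesign:
    """Partition of samples into replicate groups.

    Variation *within* a group is considered confounding and penalized.
    Groups with a single sample contribute zero penalty.
    """

    sample_ids: pd.Index
    groups: list[np.ndarray]  # integer positions into sample_ids

    def __post_init__(self) -> None:
        seen = np.concatenate(self.groups) if self.groups else np.array([], int)
        if len(seen) != len(self.sample_ids) or len(np.unique(seen)) != len(seen):
            raise ValueError("groups must partition the samples")

    def centering_operator(self) -> np.ndarray:
        """The within-group centering matrix H (n x n)."""
        n = len(self.sample_ids)
        h = np.zeros((n, n))
        for g in self.groups:
            h[np.ix_(g, g)] = -1.0 / len(g)
            h[g, g] += 1.0
        return h

    def penalty(self, scores: np.ndarray) -> float:
        """Within-group scatter of per-sample scores."""
        total = 0.0
        for g in self.groups:
            s = scores[g]
            total += float(np.sum((s - s.mean(axis=0)) ** 2))
        return total


def build_confounder_design(meta: pd.DataFrame, dataset_kind: str
                            ) -> tuple[ConfounderDesign, pd.Index]:
    """Replicate-group partition for a dataset kind.

    Returns the design plus the sample ids retained (the final time point of
    a time-course is excluded before grouping).
    """
    if dataset_kind not in DATASET_KINDS:
        raise ValueError(f"unknown dataset_kind {dataset_kind!r}; "
                         f"expected one of {DATASET_KINDS}")
    if dataset_kind in ("development", "tissue"):
        kept = meta.index
        key = meta["phase"]
    else:
        tp = meta["timepoint"].astype(float)
        kept = meta.index[tp < tp.max()]
        sub = meta.loc[kept]
        key = sub["treatment"].astype(str) + "|" + sub["timepoint"].astype(str)
    codes = pd.Series(key, index=kept)
    positions = pd.Series(np.arange(len(kept)), index=kept)
    groups = [positions[codes == lev].to_numpy() for lev in codes.unique()]
    return ConfounderDesign(pd.Index(kept), groups), pd.Index(kept)


@dataclass
class ACPCAModel:
    """Fitted adjusted-PCA model: unit loadings over genes, per-sample
    scores, the penalty weight and the score-sign -> phase convention."""

    gene_ids: pd.Index
    loadings: np.ndarray          # genes x n_components, columns unit norm
    scores: pd.DataFrame          # samples x components
    lam: float
    sign_map: dict[str, str] = field(default_factory=lambda: {"+": "G", "-": "S"})
    variance_explained: np.ndarray | None = None

    @property
    def pc1(self) -> pd.Series:
        """PC1 loading per gene (positive = gregarious-biased)."""
        return pd.Series(self.loadings[:, 0], index=self.gene_ids, name="pc1")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_ids": list(map(str, self.gene_ids)),
            "loadings": self.loadings.tolist(),
            "lambda": self.lam,
            "sign_map": self.sign_map,
            "variance_explained": (None if self.variance_explained is None
                                   else list(map(float, self.variance_explained))),
            "scores": {"index": list(map(str, self.scores.index)),
                       "values": self.scores.to_numpy().tolist()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ACPCAModel":
        d = json.loads(Path(path).read_text())
        scores = pd.DataFrame(d["scores"]["values"], index=d["scores"]["index"])
        ve = d["variance_explained"]
        return cls(gene_ids=pd.Index(d["gene_ids"]),
                   loadings=np.asarray(d["loadings"]),
                   scores=scores, lam=d["lambda"], sign_map=d["sign_map"],
                   variance_explained=None if ve is None else np.asarray(ve))


def fit_acpca(X: pd.DataFrame, design: ConfounderDesign, lam: float,
              n_components: int = 2,
              phases: pd.Series | None = None) -> ACPCAModel:
    """Fit adjusted PCA on a preprocessed samples x genes matrix.

    ``X`` must be log2(x+1)-transformed, quantile-normalized and
    gene-centered (see :func:`phasecore.preprocess.log_quantile_center`) and
    restricted to the design's samples.  ``phases`` (per-sample G/S labels)
    fixes the sign convention: the gregarious mean score on each component
    is made non-negative, so positive PC1 loadings mark gregarious-biased
    genes.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if list(X.index) != list(design.sample_ids):
        X = X.loc[design.sample_ids]
    x = X.to_numpy(float)
    n = x.shape[0]
    h = design.centering_operator()
    m = np.eye(n) - lam * h

    # sample-space eigen-solve of X'(I - lam H)X
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    nz = s > s.max() * 1e-12 if s.size and s.max() > 0 else np.zeros_like(s, bool)
    u, s, vt = u[:, nz], s[nz], vt[nz]
    b = (s[:, None] * (u.T @ m @ u)) * s[None, :]
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:n_components]
    w = evecs[:, order]
    loadings = vt.T @ w                       # genes x k, orthonormal
    scores = x @ loadings

    if phases is not None:
        gmask = (pd.Series(phases).loc[X.index] == "G").to_numpy()
        for k in range(loadings.shape[1]):
            if gmask.any() and scores[gmask, k].mean() < 0:
                loadings[:, k] *= -1
                scores[:, k] *= -1

    total_var = float(np.sum(x ** 2))
    ve = (np.sum(scores ** 2, axis=0) / total_var) if total_var > 0 else None
    score_df = pd.DataFrame(scores, index=X.index,
                            columns=[f"PC{k + 1}" for k in range(scores.shape[1])])
    return ACPCAModel(gene_ids=X.columns, loadings=loadings, scores=score_df,
                      lam=lam, variance_explained=ve)


def acpca_objective(x: np.ndarray, design: ConfounderDesign, lam: float,
                    v: np.ndarray) -> float:
    """v'X'Xv - lambda * within-group scatter of Xv (for oracles/tuning)."""
    s = x @ v
    return float(np.sum(s ** 2)) - lam * design.penalty(s[:, None])


@dataclass
class LambdaTuning:
    lam: float
    grid: np.ndarray
    ratios: np.ndarray
    converged: bool


def tune_lambda(X: pd.DataFrame, design: ConfounderDesign,
                grid=None, tol: float = 0.05) -> LambdaTuning:
    """Pick the smallest penalty weight that suppresses the confounder.

    Returns the smallest grid lambda whose fitted leading component has
    ``penalty(v(lambda)) / penalty(v(0)) <= tol``.  If no grid value
    qualifies, the grid maximum is returned with ``converged=False`` and a
    warning.
    """
    if grid is None:
        grid = np.logspace(-1, 2, 20)
    grid = np.asarray(list(grid), float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    grid = np.sort(grid)
    x = X.to_numpy(float)
    base = fit_acpca(X, design, 0.0, n_components=1)
    p0 = design.penalty(x @ base.loadings)
    ratios = np.empty(grid.size)
    for i, lam in enumerate(grid):
        mod = fit_acpca(X, design, float(lam), n_components=1)
        p = design.penalty(x @ mod.loadings)
        ratios[i] = 1.0 if p0 == 0 else p / p0
    if p0 == 0:
        return LambdaTuning(float(grid[0]), grid, ratios, True)
    ok = np.nonzero(ratios <= tol)[0]
    if ok.size:
        return LambdaTuning(float(grid[ok[0]]), grid, ratios, True)
    warnings.warn("no lambda on the grid reached the penalty tolerance; "
                  "returning the grid maximum")
    return LambdaTuning(float(grid[-1]), grid, ratios, False)


def predict_phase(model: ACPCAModel, X_new: pd.DataFrame,
                  labels: pd.Series | None = None) -> pd.DataFrame:
    """Project new (identically preprocessed) samples on PC1 and call phase
    by score sign; zero scores are flagged unassigned."""
    common = X_new.columns.intersection(model.gene_ids)
    if len(common) == 0:
        raise ValueError("no overlap between model genes and new matrix")
    v = pd.Series(model.loadings[:, 0], index=model.gene_ids).loc[common]
    scores = X_new[common].to_numpy(float) @ v.to_numpy()
    pos, neg = model.sign_map["+"], model.sign_map["-"]
    calls = np.where(scores > 0, pos, np.where(scores < 0, neg, "unassigned"))
    out = pd.DataFrame({"score": scores, "call": calls}, index=X_new.index)
    if labels is not None:
        truth = pd.Series(labels).loc[X_new.index]
        out["correct"] = (out["call"] == truth.to_numpy())
    return out


def prediction_accuracy(pred: pd.DataFrame) -> float:
    return float(pred["correct"].mean())
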