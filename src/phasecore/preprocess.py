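"""Normalization of count/RPKM matrices ahead of ranking and network inference.

The pipeline starts from a gene x sample count (or RPKM) matrix: RPKM
conversion, trimmed-mean-of-M-values (TMM) scaling factors to correct for
differences in RNA output size between libraries, and the
log2(x+1) -> quantile-normalize -> gene-center transform whose output feeds
confounder-adjusted PCA and network inference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset


def rpkm(counts: pd.DataFrame, gene_lengths: pd.Series,
         library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads.

    ``rpkm = count / (length/1e3) / (library_size/1e6)``.  Library sizes
    default to the column sums of ``counts``.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("gene_lengths missing for some genes")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    else:
        library_sizes = pd.Series(library_sizes, index=counts.columns)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.div(lengths / 1e3, axis=0).div(library_sizes / 1e6, axis=1)


def counts_to_rpkm(dataset: ExpressionDataset) -> ExpressionDataset:
    if dataset.kind != "counts":
        raise ValueError("dataset is not a count matrix")
    if dataset.gene_lengths is None:
        raise ValueError("gene lengths required for RPKM")
    values = rpkm(dataset.values, dataset.gene_lengths)
    return ExpressionDataset(values, dataset.meta, kind="rpkm",
                             gene_lengths=dataset.gene_lengths)


def _choose_reference(counts: pd.DataFrame) -> str:
    """Sample whose upper-quartile (of positive counts, depth-scaled) is
    closest to the mean upper-quartile."""
    scaled = counts / counts.sum(axis=0)
    uq = scaled.apply(lambda c: np.quantile(c[c > 0], 0.75), axis=0)
    return (uq - uq.mean()).abs().idxmin()


def tmm_factors(counts: pd.DataFrame, ref_column: str | None = None,
                trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Trimmed mean of M-values scaling factors (one per sample).

    For each sample vs the reference, genes expressed in both are scored by
    log-ratio M and average abundance A; the extreme ``trim_m`` fraction of
    M values and ``trim_a`` fraction of A values (each side) are discarded
    and the factor is 2 to the precision-weighted mean of the remaining M
    values.  Factors are renormalized to geometric mean 1.
    """
    zero = counts.sum(axis=0) == 0
    if zero.any():
        raise ValueError(f"sample(s) with all-zero counts: "
                         f"{list(counts.columns[zero])}")
    if ref_column is None:
        ref_column = _choose_reference(counts)
    ref = counts[ref_column].to_numpy(float)
    n_ref = ref.sum()
    factors = {}
    for col in counts.columns:
        obs = counts[col].to_numpy(float)
        n_obs = obs.sum()
        keep = (obs > 0) & (ref > 0)
        o, r = obs[keep], ref[keep]
        m = np.log2((o / n_obs) / (r / n_ref))
        a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
        w = 1.0 / o - 1.0 / n_obs + 1.0 / r - 1.0 / n_ref  # delta-method var
        finite = np.isfinite(m) & np.isfinite(a)
        m, a, w = m[finite], a[finite], w[finite]
        if m.size == 0:
            factors[col] = 1.0
            continue
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        kept = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not kept.any():
            factors[col] = 1.0
            continue
        wm = np.sum(m[kept] / w[kept]) / np.sum(1.0 / w[kept])
        factors[col] = 2.0 ** wm
    out = pd.Series(factors)[counts.columns]
    out /= np.exp(np.log(out).mean())  # geometric mean 1
    out.name = "tmm_factor"
    return out


def quantile_normalize(samples_by_genes: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize rows (samples) against the mean-of-sorted reference.

    Ties within a sample receive the mean of the reference values at their
    tied ranks.
    """
    x = samples_by_genes.to_numpy(float)
    n_samples, n_genes = x.shape
    if n_samples < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    reference = np.sort(x, axis=1).mean(axis=0)
    out = np.empty_like(x)
    for i in range(n_samples):
        order = np.argsort(x[i], kind="mergesort")
        assigned = np.empty(n_genes)
        assigned[order] = reference
        # average reference values over tied groups
        row = pd.Series(assigned).groupby(pd.Series(x[i])).transform("mean")
        out[i] = row.to_numpy()
    return pd.DataFrame(out, index=samples_by_genes.index,
                        columns=samples_by_genes.columns)


def log_quantile_center(dataset: ExpressionDataset | pd.DataFrame) -> pd.DataFrame:
    """log2(x+1), quantile-normalize across samples, mean-center each gene.

    Returns a samples x genes matrix (samples as rows), the orientation the
    adjusted-PCA fit expects.
    """
    if isinstance(dataset, ExpressionDataset):
        if dataset.kind != "rpkm":
            raise ValueError("log_quantile_center expects an RPKM dataset; "
                             "convert counts with counts_to_rpkm first")
        values = dataset.values
    else:
        values = dataset
    x = np.log2(values.to_numpy(float).T + 1.0)  # samples x genes
    df = pd.DataFrame(x, index=values.columns, columns=values.index)
    df = quantile_normalize(df)
    return df - df.mean(axis=0)
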