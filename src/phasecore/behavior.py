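"""Behavioral phase probability from arena-tracking parameters.

A published binary logistic model scores how gregarious an individual's
arena behavior is:

    P_greg = exp(eta) / (1 + exp(eta)),
    eta = -2.11 + 0.005 * AI + 0.012 * TDM + 0.015 * TDMV,

where AI (attraction index) is the time spent near the stimulus group
minus the time spent in the opposite area, TDM the total distance moved
and TDMV the total duration of movement over a 300 s trial.  The
coefficients are constants of the published model; nothing is refit here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

ETA_INTERCEPT = -2.11
ETA_AI = 0.005
ETA_TDM = 0.012
ETA_TDMV = 0.015
TRIAL_SECONDS = 300.0


def attraction_index(dur_stimulus, dur_opposite):
    """AI = time in the stimulus area minus time in the opposite area (s)."""
    ds = np.asarray(dur_stimulus, float)
    do = np.asarray(dur_opposite, float)
    if (ds < 0).any() or (do < 0).any():
        raise ValueError("durations must be non-negative")
    if (ds + do > TRIAL_SECONDS + 1e-9).any():
        raise ValueError(f"durations exceed the {TRIAL_SECONDS:.0f} s trial")
    out = ds - do
    return float(out) if out.ndim == 0 else out


def pgreg(ai, tdm, tdmv):
    """Gregariousness probability of one or more behavior records."""
    ai = np.asarray(ai, float)
    tdm = np.asarray(tdm, float)
    tdmv = np.asarray(tdmv, float)
    if not (np.isfinite(ai).all() and np.isfinite(tdm).all()
            and np.isfinite(tdmv).all()):
        raise ValueError("behavior parameters must be finite")
    eta = ETA_INTERCEPT + ETA_AI * ai + ETA_TDM * tdm + ETA_TDMV * tdmv
    out = expit(eta)
    return float(out) if out.ndim == 0 else out


def score_records(records: pd.DataFrame) -> pd.DataFrame:
    """Add AI and P_greg columns to a table of behavior records."""
    out = records.copy()
    out["ai"] = attraction_index(out["dur_stimulus"], out["dur_opposite"])
    out["p_greg"] = pgreg(out["ai"], out["tdm"], out["tdmv"])
    return out


def compare_groups(pgreg_a, pgreg_b) -> dict:
    """Median P_greg per group and the two-sided Mann-Whitney p-value
    (exact when sample sizes permit, normal approximation otherwise)."""
    a = np.asarray(pgreg_a, float)
    b = np.asarray(pgreg_b, float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least one record")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return {"median_a": float(np.median(a)), "median_b": float(np.median(b)),
            "u_statistic": float(res.statistic), "p_value": float(res.pvalue)}
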