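"""Per-neuron stimulus-response scoring.

Pip-locked CS responses (mean z over ~1 s after each 1-Hz tone pip,
baseline-normalized to the 30-s pre-trial window, averaged over 3-trial
phase blocks with the last pip of every trial excluded), shock (US)
responses (mean z over 1.5 s from each of the 7 shock onsets), and the
membership-ratio bookkeeping used to relate responsive cells to extracted
ensembles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synth import TrialTimeline
from .traces import TraceMatrix

__all__ = [
    "score_cs_responses",
    "score_us_responses",
    "membership_ratio",
    "pip_samples",
]

ALPHA = 0.05


def _trial_block(timeline: TrialTimeline, phase: str, cs_type: str) -> pd.DataFrame:
    day = 3 if phase.startswith("D3") else 4
    block = timeline.select(day=day, cs_type=cs_type, phase=phase)
    if len(block) < 3:
        raise ValueError(f"phase {phase}/{cs_type} has {len(block)} trials; need >= 3")
    return block


def pip_samples(z: TraceMatrix, timeline: TrialTimeline, phase: str, cs_type: str,
                *, baseline_s: float | None = 30.0, window_s: float = 1.0) -> np.ndarray:
    """Per-pip response samples [neurons x samples] for a 3-trial phase block.

    For each trial, traces are re-expressed as z-scores against the
    ``baseline_s`` pre-trial window (``None`` keeps the whole-day z scale;
    see the methods note on the type-I cost of per-trial baselines), then
    each retained pip contributes the mean over the ~``window_s``
    post-onset frames (truncated before the next pip onset).  The last pip
    of every trial is excluded — during conditioning it coincides with the
    shock — leaving 29 pips/trial and 87 samples per 3-trial block.
    """
    day = 3 if phase.startswith("D3") else 4
    block = _trial_block(timeline, phase, cs_type)
    fr = z.frame_rate_hz
    vals = z.day_slice(day)
    nf = vals.shape[1]
    pip_spacing = 1.0  # pips are presented at 1 Hz
    win_frames = max(1, int(np.floor(min(window_s, pip_spacing) * fr)))
    samples = []
    for row in block.itertuples():
        if baseline_s is None:
            mu = np.zeros((vals.shape[0], 1))
            sd = np.ones((vals.shape[0], 1))
        else:
            b0 = max(0, int(round((row.onset_s - baseline_s) * fr)))
            b1 = int(round(row.onset_s * fr))
            base = vals[:, b0:b1]
            mu = base.mean(axis=1, keepdims=True)
            sd = base.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
        onsets = timeline.pip_onsets(row)[:-1]  # drop the last pip
        for t0 in onsets:
            i0 = int(round(t0 * fr))
            i1 = min(i0 + win_frames, int(round((t0 + pip_spacing) * fr)), nf)
            seg = (vals[:, i0:i1] - mu) / sd
            samples.append(seg.mean(axis=1))
    return np.column_stack(samples)


def score_cs_responses(z: TraceMatrix, timeline: TrialTimeline, phase: str,
                       cs_type: str, *, baseline_s: float = 30.0,
                       alpha: float = ALPHA) -> pd.DataFrame:
    """Classify each neuron's CS response within a phase block.

    Returns a tidy frame (neuron_id, phase, cs_type, mean_z, p, class) where
    class is 'activated' / 'inactivated' / 'none' by a two-tailed Wilcoxon
    signed-rank test of the 87 per-pip samples against zero at p < alpha,
    signed by the block mean.
    """
    S = pip_samples(z, timeline, phase, cs_type, baseline_s=baseline_s)
    n = S.shape[0]
    mean_z = S.mean(axis=1)
    p = np.ones(n)
    for i in range(n):
        if np.allclose(S[i], 0):
            continue
        p[i] = sps.wilcoxon(S[i], zero_method="wilcox", alternative="two-sided").pvalue
    cls = np.where(p < alpha, np.where(mean_z > 0, "activated", "inactivated"), "none")
    return pd.DataFrame(
        dict(neuron_id=np.arange(n), phase=phase, cs_type=cs_type,
             mean_z=mean_z, p=p, n_samples=S.shape[1], **{"class": cls})
    )


def score_us_responses(z: TraceMatrix, timeline: TrialTimeline, *,
                       window_s: float = 1.5, threshold: float = 1.0) -> pd.DataFrame:
    """Mean z over ``window_s`` from each US onset, averaged over the 7 shocks.

    A neuron is flagged US-responsive (``usr``) when that mean is at or
    above ``threshold`` (z >= 1).  Uses the whole-day z-normalized trace.
    """
    us = timeline.us_onsets(day=3)
    if us.size == 0:
        raise ValueError("timeline contains no US events")
    fr = z.frame_rate_hz
    vals = z.day_slice(3)
    win = max(1, int(round(window_s * fr)))
    means = []
    for t0 in us:
        i0 = int(round(t0 * fr))
        means.append(vals[:, i0:i0 + win].mean(axis=1))
    mean_z = np.mean(means, axis=0)
    return pd.DataFrame(
        dict(neuron_id=np.arange(vals.shape[0]), mean_z=mean_z, usr=mean_z >= threshold)
    )


def membership_ratio(n_in_ensemble: int, n_category: int) -> float:
    """Percentage of a response category captured by an ensemble, 2 decimals."""
    if n_category <= 0:
        raise ValueError("category count must be positive")
    if not (0 <= n_in_ensemble <= n_category):
        raise ValueError("need 0 <= n_in_ensemble <= n_category")
    return round(100.0 * n_in_ensemble / n_category, 2)
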