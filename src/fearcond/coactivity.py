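"""Pairwise coactivity during tone periods and shuffle-based null controls.

Pearson correlations between z-scored traces over concatenated CS+ frames,
per-group summaries (within the conditioned-response ensemble, within the
non-ensemble cells, across), and a null built by independently permuting
each neuron's frame order — which preserves every marginal exactly and
destroys only the coincidence structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from ._util import as_rng

__all__ = [
    "CorrelationResult",
    "pairwise_correlations",
    "shuffle_null",
    "summarize_groups",
]


@dataclass
class CorrelationResult:
    """Symmetric r and p matrices over the masked frames.

    Pairs involving a constant trace are undefined: r and p are NaN there
    and ``defined`` is False; summaries skip them.
    """

    r: np.ndarray
    p: np.ndarray
    defined: np.ndarray
    n_frames: int
    group_labels: np.ndarray | None = None


def _corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-tailed p for Pearson r via the t transform with n-2 df."""
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        t = rr * np.sqrt((n - 2) / (1 - rr**2))
        p = 2 * sps.t.sf(np.abs(t), df=n - 2)
    return p


def pairwise_correlations(values: np.ndarray, frame_mask: np.ndarray | None = None,
                          group_labels: np.ndarray | None = None) -> CorrelationResult:
    """Pearson r and two-tailed p for every neuron pair over masked frames.

    ``values`` is [neurons x frames]; ``frame_mask`` selects the frames to
    concatenate (all frames if None).
    """
    V = np.asarray(values, dtype=float)
    if frame_mask is not None:
        V = V[:, np.asarray(frame_mask, dtype=bool)]
    n_neurons, n = V.shape
    if n < 3:
        raise ValueError("need at least 3 masked frames")
    sd = V.std(axis=1)
    const = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            r = np.corrcoef(V)
    r[const, :] = np.nan
    r[:, const] = np.nan
    np.fill_diagonal(r, 1.0)
    p = _corr_pvalues(r, n)
    np.fill_diagonal(p, 0.0)
    defined = ~np.isnan(r)
    np.fill_diagonal(defined, True)
    return CorrelationResult(r=r, p=p, defined=defined, n_frames=n,
                             group_labels=group_labels)


def shuffle_null(values: np.ndarray, frame_mask: np.ndarray | None, n_shuffles: int,
                 rng=None) -> np.ndarray:
    """Null correlation matrices from per-neuron frame permutation.

    Each neuron's masked time series is permuted independently (its total
    activity and marginal distribution are untouched); correlations are
    recomputed per shuffle.  Returns [n_shuffles x neurons x neurons].
    """
    if n_shuffles < 100:
        raise ValueError("use at least 100 shuffles for a stable null")
    rng = as_rng(rng)
    V = np.asarray(values, dtype=float)
    if frame_mask is not None:
        V = V[:, np.asarray(frame_mask, dtype=bool)]
    n_neurons, n = V.shape
    out = np.empty((n_shuffles, n_neurons, n_neurons))
    for s in range(n_shuffles):
        shuf = np.empty_like(V)
        for i in range(n_neurons):
            shuf[i] = V[i, rng.permutation(n)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[s] = np.corrcoef(shuf)
    return out


def _pair_indices(labels: np.ndarray, a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    ia = np.flatnonzero(labels == a)
    ib = np.flatnonzero(labels == b)
    if a == b:
        iu, ju = np.triu_indices(ia.size, k=1)
        return ia[iu], ia[ju]
    return np.repeat(ia, ib.size), np.tile(ib, ia.size)


def summarize_groups(corr: CorrelationResult, corr_before: CorrelationResult | None = None,
                     *, alpha: float = 0.05) -> dict:
    """Per-group coactivity summaries (and paired change vs a 'before' day).

    Groups come from ``corr.group_labels`` (e.g. 'CRE' / 'nonCRE').  For
    every within-group and across-group pair set the summary holds the mean
    positive r, the fraction of significantly positive pairs (p < alpha,
    r > 0), and — when ``corr_before`` is given (same neurons) — the mean
    paired per-pair change after minus before.  Pair sets with no defined
    pairs are omitted.
    """
    labels = corr.group_labels
    if labels is None:
        raise ValueError("group labels are required for group summaries")
    labels = np.asarray(labels)
    groups = sorted(set(labels))
    sets = {f"within-{g}": (g, g) for g in groups}
    if len(groups) > 1:
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                sets[f"across-{groups[gi]}-{groups[gj]}"] = (groups[gi], groups[gj])
    out = {}
    for name, (a, b) in sets.items():
        ii, jj = _pair_indices(labels, a, b)
        if ii.size == 0:
            continue
        ok = corr.defined[ii, jj]
        if corr_before is not None:
            ok &= corr_before.defined[ii, jj]
        if not ok.any():
            warnings.warn(f"group pair set {name} has no defined pairs; omitted")
            continue
        r = corr.r[ii, jj][ok]
        p = corr.p[ii, jj][ok]
        pos = r > 0
        entry = dict(
            n_pairs=int(ok.sum()),
            mean_r=float(r.mean()),
            mean_positive_r=float(r[pos].mean()) if pos.any() else 0.0,
            frac_significant_positive=float(np.mean((p < alpha) & pos)),
        )
        if corr_before is not None:
            r0 = corr_before.r[ii, jj][ok]
            entry["mean_paired_change"] = float((r - r0).mean())
        out[name] = entry
    return out
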