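"""Resampling statistics for nested neural data.

A paired permutation (sign-flip) test on the difference of means, a
hierarchical bootstrap that resamples units (neurons or pairs) within each
animal before summarizing across animals, an exact 2x2 association test,
and a Pearson correlation test.  The permutation and bootstrap routines are
bespoke; the exact 2x2 test, correlation test and the rank-based tests
delegate to vetted library routines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._util import as_rng

__all__ = [
    "PairedSamples",
    "paired_permutation_test",
    "hierarchical_bootstrap",
    "exact_2x2_test",
    "correlation_test",
    "wilcoxon_signed_rank",
    "rank_sum",
    "friedman",
]

EXHAUSTIVE_LIMIT = 2**20


@dataclass
class PairedSamples:
    """Two equal-length vectors paired by unit (animal, neuron, ...)."""

    a: np.ndarray
    b: np.ndarray
    unit_ids: np.ndarray | None = None

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("a and b must be equal-length 1-D vectors")
        if self.a.size < 2:
            raise ValueError("need at least 2 pairs")
        if np.isnan(self.a).any() or np.isnan(self.b).any():
            raise ValueError("missing pairs are not allowed")


@dataclass
class TestResult:
    statistic: float
    p: float
    n: int
    method: str
    distribution: np.ndarray | None = None

    def to_record(self, seed=None) -> dict:
        return dict(statistic=self.statistic, p=self.p, n=self.n,
                    method=self.method, seed=seed)


def paired_permutation_test(samples: PairedSamples | tuple, *, n_perm: int = 10**5,
                            tail: str = "two", rng=None) -> TestResult:
    """Sign-flip permutation test on the mean paired difference.

    The null distribution flips the sign of each pair's difference; all 2^n
    assignments are enumerated when feasible (n <= 20), otherwise ``n_perm``
    Monte-Carlo draws that always include the identity flip (so p >= 1/(n_perm+1)).
    Two-tailed p = Pr(|T*| >= |T_obs|).  With four pairs the one-sided
    exhaustive floor is 1/16.
    """
    if not isinstance(samples, PairedSamples):
        samples = PairedSamples(*samples)
    d = samples.a - samples.b
    n = d.size
    t_obs = float(d.mean())
    if np.all(d == 0):
        return TestResult(statistic=0.0, p=1.0, n=n, method="paired-permutation")
    if 2**n <= EXHAUSTIVE_LIMIT:
        null = np.empty(2**n)
        chunk = 1 << 16
        for start in range(0, 2**n, chunk):
            codes = np.arange(start, min(start + chunk, 2**n))[:, None]
            signs = ((codes >> np.arange(n)[None, :]) & 1) * 2.0 - 1.0
            null[start:start + signs.shape[0]] = signs @ d / n
        method = "paired-permutation-exhaustive"
    else:
        rng = as_rng(rng)
        signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
        signs[0] = 1  # identity flip included
        null = signs @ d / n
        method = "paired-permutation-montecarlo"
    eps = 1e-12 * max(1.0, abs(t_obs))
    if tail == "two":
        p = float(np.mean(np.abs(null) >= abs(t_obs) - eps))
    elif tail == "greater":
        p = float(np.mean(null >= t_obs - eps))
    elif tail == "less":
        p = float(np.mean(null <= t_obs + eps))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return TestResult(statistic=t_obs, p=p, n=n, method=method, distribution=null)


def _per_mouse_arrays(data) -> dict:
    """Normalize input to {mouse: (a,) or (a, b)} of float arrays."""
    if isinstance(data, pd.DataFrame):
        out = {}
        conds = sorted(data["condition"].unique()) if "condition" in data else [None]
        for mouse, g in data.groupby("mouse_id"):
            if len(conds) == 2:
                g = g.sort_values("unit_id")
                a = g[g.condition == conds[0]]["value"].to_numpy()
                b = g[g.condition == conds[1]]["value"].to_numpy()
                if a.size != b.size:
                    raise ValueError(f"mouse {mouse}: unpaired unit sets across conditions")
                out[mouse] = (a, b)
            else:
                out[mouse] = (g["value"].to_numpy(),)
        return out
    out = {}
    for mouse, v in data.items():
        if isinstance(v, tuple):
            out[mouse] = tuple(np.asarray(x, dtype=float) for x in v)
        else:
            out[mouse] = (np.asarray(v, dtype=float),)
    return out


def hierarchical_bootstrap(data, *, n_boot: int = 2000, group_summary: str = "mean",
                           rng=None) -> TestResult:
    """Mouse-level bootstrap of unit-level values, 2000 replicates by default.

    ``data`` maps mouse -> vector of unit values, or mouse -> (a, b) paired
    vectors over identical unit sets (then the statistic is the paired
    difference a - b), or a tidy DataFrame (mouse_id, unit_id, condition,
    value).  Per replicate, units are resampled with replacement within
    each mouse at the original size — using identical draws across paired
    conditions — the mouse-level mean is taken, then the group-level mean
    or median across mice.  Two-tailed p = 2 * min(Pr(stat <= 0),
    Pr(stat >= 0)), clipped to [0, 1]; for a single-condition summary the
    distribution itself is the product and p is relative to zero as well.
    """
    if group_summary not in ("mean", "median"):
        raise ValueError("group_summary must be 'mean' or 'median'")
    rng = as_rng(rng)
    arrays = _per_mouse_arrays(data)
    if len(arrays) < 2:
        raise ValueError("need >= 2 mice for a group summary")
    mouse_stats = np.empty((n_boot, len(arrays)))
    for k, (mouse, vecs) in enumerate(sorted(arrays.items(), key=lambda kv: str(kv[0]))):
        n_units = vecs[0].size
        if n_units == 0:
            raise ValueError(f"mouse {mouse} has no units")
        if any(v.size != n_units for v in vecs):
            raise ValueError(f"mouse {mouse}: paired conditions differ in unit count")
        idx = rng.integers(0, n_units, size=(n_boot, n_units))
        if len(vecs) == 2:
            diff = vecs[0] - vecs[1]
            mouse_stats[:, k] = diff[idx].mean(axis=1)
        else:
            mouse_stats[:, k] = vecs[0][idx].mean(axis=1)
    dist = mouse_stats.mean(axis=1) if group_summary == "mean" else np.median(mouse_stats, axis=1)
    # +1/(B+1) finite-resample correction keeps the doubled tail honest
    lo = (np.sum(dist <= 0) + 1.0) / (n_boot + 1.0)
    hi = (np.sum(dist >= 0) + 1.0) / (n_boot + 1.0)
    p = min(1.0, 2.0 * min(lo, hi))
    return TestResult(statistic=float(np.mean(dist)), p=p, n=len(arrays),
                      method=f"hierarchical-bootstrap-{group_summary}", distribution=dist)


def exact_2x2_test(table) -> TestResult:
    """Two-tailed exact association test on a 2x2 count table.

    Sums hypergeometric probabilities of all tables (at fixed margins) no
    more likely than the observed one.  A zero margin gives p = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t = np.asarray(table, dtype=float)
        if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
            raise ValueError("table must be 2x2 non-negative integer counts")
        t = t.astype(int)
    if t.sum() == 0:
        raise ValueError("all-zero table")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(statistic=float(odds), p=float(p), n=int(t.sum()),
                      method="fisher-exact")


def correlation_test(x, y) -> TestResult:
    """Pearson r with two-tailed p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D vectors of size >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    res = sps.pearsonr(x, y)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue), n=x.size,
                      method="pearson-correlation")


# Rank-based tests of the standard family: delegated, exposed for pipeline use.

def wilcoxon_signed_rank(a, b=None, **kwargs) -> TestResult:
    res = sps.wilcoxon(a, b, alternative="two-sided", **kwargs)
    n = len(a)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue), n=n,
                      method="wilcoxon-signed-rank")


def rank_sum(a, b) -> TestResult:
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue),
                      n=len(a) + len(b), method="wilcoxon-rank-sum")


def friedman(*groups) -> TestResult:
    res = sps.friedmanchisquare(*groups)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue),
                      n=len(groups[0]), method="friedman")
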