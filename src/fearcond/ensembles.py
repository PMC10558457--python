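"""Elastic-net extraction of behavior-state-coding neuronal ensembles.

The extraction problem is a penalized logistic regression of a binary
behavior state y (1 = freezing-like / stationary, 0 = locomotive) on the
z-scored population activity x at each frame:

    min_{b0, b}  (1/N) sum_i [ -y_i log yh_i - (1-y_i) log(1-yh_i) ]
                 + gamma * P_alpha(b),
    yh_i = 1 / (1 + exp(-(b0 + x_i' b))),
    P_alpha(b) = sum_j [ (1-alpha)/2 b_j^2 + alpha |b_j| ].

gamma is selected per dataset by 7-fold cross-validated binomial deviance
over 7 log-spaced values in [1e-3.3, 1e-2.5].  To stabilize the selected
neuron set, the fit is repeated (default 100x) on class-balanced resamples
(900 activity vectors per state, drawn with replacement); a Gaussian is fit
to each neuron's coefficient sample and a neuron is an ensemble member iff
the 95% CI excludes zero, with the centroid as its final coefficient.

The sparsity / grouping trade-off alpha is optimized by comparing how much
decodable information remains after removing the extracted ensemble versus
removing an equally sized random set of non-members (the removal-AUC
difference), with a rank-sum tie rule favoring the largest alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted, validate_data

from ._util import as_rng
from .synth import BehaviorTrack, TrialTimeline
from .traces import TraceMatrix

__all__ = [
    "LabeledDataset",
    "ElasticNetEnsemble",
    "AlphaScanResult",
    "build_dataset",
    "fit_penalized_logistic",
    "select_gamma",
    "extract_ensemble",
    "evaluate_model",
    "removal_auc_difference",
    "optimize_alpha",
    "default_gamma_grid",
    "DEFAULT_ALPHA_GRID",
]

DEFAULT_ALPHA_GRID = (0.9, 0.75, 0.5, 0.25, 0.1, 0.05, 0.01)
RS_ALPHA = 0.75


def default_gamma_grid() -> np.ndarray:
    """7 values evenly log-spaced between 1e-3.3 and 1e-2.5."""
    return np.logspace(-3.3, -2.5, 7)


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

@dataclass
class LabeledDataset:
    """Frames x neurons design matrix with binary state labels.

    y = 1 marks the freezing-like / stationary state, y = 0 locomotion.
    ``condition`` records what the frames are ("cr@D4E", "rs@d4", ...).
    """

    X: np.ndarray
    y: np.ndarray
    condition: str
    day: int
    frame_idx: np.ndarray = field(default=None)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on sample count")

    @property
    def n_neurons(self) -> int:
        return self.X.shape[1]

    def subset_neurons(self, cols: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(X=self.X[:, cols], y=self.y, condition=self.condition,
                              day=self.day, frame_idx=self.frame_idx)


def _post_trial_mask(timeline: TrialTimeline, day: int, pad_s: float = 30.0) -> np.ndarray:
    times = timeline.frame_times(day)
    mask = np.zeros(times.size, dtype=bool)
    for row in timeline.select(day=day).itertuples():
        end = row.onset_s + row.duration_s
        mask |= (times >= end) & (times < end + pad_s)
    return mask


def build_dataset(z: TraceMatrix, behavior: BehaviorTrack, timeline: TrialTimeline,
                  condition: str, *, phase: str | None = None, day: int | None = None,
                  lag_frames: int = 0, min_label_frac: float = 0.10,
                  check_balance: bool = True) -> LabeledDataset:
    """Assemble the labeled frames for one extraction condition.

    condition='cr': frames inside CS+ trials of ``phase`` (e.g. 'D4E');
    label 1 = freezing-like (>=1 s immobile).  condition='rs': frames of
    ``day`` outside every tone trial, excluding the 30 s after each trial;
    label 1 = stationary.  ``lag_frames`` averages activity over a symmetric
    window of that many frames on each side before labeling.

    CR datasets with less than ``min_label_frac`` of either label raise
    (the extraction precondition on label balance).
    """
    cond = condition.lower()
    if cond == "cr":
        if phase is None:
            raise ValueError("CR condition requires a phase (e.g. 'D4E')")
        day = 3 if phase.startswith("D3") else 4
        trials = timeline.select(day=day, cs_type="CS+", phase=phase)
        mask = timeline.in_trial_mask(day, trials)
        tag = f"cr@{phase}"
    elif cond == "rs":
        if day is None:
            raise ValueError("RS condition requires a day")
        mask = ~timeline.in_trial_mask(day) & ~_post_trial_mask(timeline, day)
        tag = f"rs@d{day}"
    else:
        raise ValueError(f"unknown condition {condition!r}")

    vals = z.day_slice(day)
    nf = min(vals.shape[1], mask.size)
    mask = mask[:nf]
    X = vals[:, :nf].T
    if lag_frames > 0:
        kernel = np.ones(2 * lag_frames + 1)
        sm = np.apply_along_axis(lambda v: np.convolve(v, kernel, "same")
                                 / np.convolve(np.ones_like(v), kernel, "same"), 0, X)
        X = sm
    y = behavior.still_mask(day)[:nf].astype(int)
    idx = np.flatnonzero(mask)
    ds = LabeledDataset(X=X[idx], y=y[idx], condition=tag, day=day, frame_idx=idx)
    frac1 = ds.y.mean() if ds.y.size else 0.0
    if check_balance and min(frac1, 1 - frac1) < min_label_frac:
        raise ValueError(
            f"insufficient label balance for {tag}: minority label fraction "
            f"{min(frac1, 1 - frac1):.3f} < {min_label_frac}"
        )
    return ds


# ---------------------------------------------------------------------------
# Penalized logistic fit (objective of the extraction problem)
# ---------------------------------------------------------------------------

def _make_solver(alpha: float, gamma: float, n: int, tol: float, max_iter: int):
    # The library solver minimizes  sum_i loss_i + (1/C) * P'_alpha(b)  with
    # P'_alpha = alpha |b|_1 + (1-alpha)/2 |b|_2^2; multiplying the mean-loss
    # objective by N gives C = 1 / (N * gamma).
    return LogisticRegression(
        solver="saga", l1_ratio=float(alpha), C=1.0 / (n * gamma),
        tol=tol, max_iter=max_iter, warm_start=True, random_state=0,
    )


def fit_penalized_logistic(X: np.ndarray, y: np.ndarray, alpha: float, gamma: float,
                           *, tol: float = 1e-5, max_iter: int = 5000):
    """Single elastic-net logistic fit; returns ``(beta0, beta)``.

    X columns are used as given (no internal standardization here); the
    estimator wrapper standardizes and maps back.  Raises on
    non-convergence.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    clf = _make_solver(alpha, gamma, len(y), tol, max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(X, y)
        except ConvergenceWarning as exc:  # pragma: no cover - defensive
            raise RuntimeError(
                f"elastic-net fit did not converge (alpha={alpha}, gamma={gamma}, "
                f"max_iter={max_iter}): {exc}"
            ) from None
    return float(clf.intercept_[0]), clf.coef_.ravel().copy()


def _binomial_deviance(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def select_gamma(X: np.ndarray, y: np.ndarray, alpha: float, *,
                 gamma_grid: np.ndarray | None = None, n_folds: int = 7,
                 rng=None, tol: float = 1e-3, max_iter: int = 3000) -> float:
    """Pick gamma by minimum expected (cross-validated) binomial deviance.

    7 folds, stratified; on ties the larger gamma (stronger shrinkage) wins.
    """
    grid = default_gamma_grid() if gamma_grid is None else np.asarray(gamma_grid, float)
    y = np.asarray(y)
    if min((y == 0).sum(), (y == 1).sum()) < n_folds:
        raise ValueError("each label needs at least one sample per fold")
    rng = as_rng(rng)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=int(rng.integers(2**31 - 1)))
    folds = list(skf.split(X, y))
    dev = np.zeros(grid.size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for g, gamma in enumerate(grid):
            clf = _make_solver(alpha, gamma, len(y), tol, max_iter)
            d = 0.0
            for tr, te in folds:
                clf.C = 1.0 / (len(tr) * gamma)
                clf.fit(X[tr], y[tr])
                d += _binomial_deviance(clf.predict_proba(X[te])[:, 1], y[te])
            dev[g] = d / len(folds)
    # argmin, ties toward the largest gamma
    order = np.argsort(grid)[::-1]
    return float(grid[order[np.argmin(dev[order])]])


# ---------------------------------------------------------------------------
# The estimator
# ---------------------------------------------------------------------------

class ElasticNetEnsemble(ClassifierMixin, BaseEstimator):
    """Ensemble extraction by repeated balanced elastic-net logistic fits.

    Parameters
    ----------
    alpha : float, default 0.75
        Elastic-net mixing (1 = lasso).  0.75 is the fixed value used for
        regular-stationary ensembles; the conditioned-response ensemble
        normally gets its alpha from :func:`optimize_alpha`.
    gamma : float or None
        Penalty strength; None selects it by 7-fold CV deviance on the
        balanced template resample.
    n_repeats : int, default 100
        Balanced-resample refits used to build coefficient distributions.
    n_per_state : int, default 900
        Samples drawn with replacement per label in each resample.
    standardize : bool, default True
        Standardize columns inside the fit; coefficients are reported on
        the original scale.
    random_state : int or None
        Seed for resampling and fold assignment.

    Attributes
    ----------
    coef_ : (n_neurons,) final coefficients (centroid for members, else 0)
    intercept_ : float
    members_ : sorted array of selected neuron indices
    coef_samples_ : (n_repeats, n_neurons) per-repeat coefficients
    centroid_, ci_halfwidth_ : Gaussian fit per neuron (95% CI half-width)
    gamma_ : penalty actually used
    """

    def __init__(self, alpha: float = RS_ALPHA, gamma: float | None = None,
                 n_repeats: int = 100, n_per_state: int = 900,
                 standardize: bool = True, tol: float = 1e-3,
                 max_iter: int = 3000, cv_folds: int = 7,
                 random_state: int | None = None):
        self.alpha = alpha
        self.gamma = gamma
        self.n_repeats = n_repeats
        self.n_per_state = n_per_state
        self.standardize = standardize
        self.tol = tol
        self.max_iter = max_iter
        self.cv_folds = cv_folds
        self.random_state = random_state

    # -- internals ----------------------------------------------------------
    def _balanced_resample(self, X, y, rng):
        idx0 = np.flatnonzero(y == 0)
        idx1 = np.flatnonzero(y == 1)
        take0 = rng.choice(idx0, size=self.n_per_state, replace=True)
        take1 = rng.choice(idx1, size=self.n_per_state, replace=True)
        idx = np.concatenate([take0, take1])
        return X[idx], y[idx]

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        classes = np.unique(y)
        self.classes_ = classes
        if classes.size != 2:
            raise ValueError("ensemble extraction needs exactly two states")
        y = (y == classes[1]).astype(int)
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        rng = as_rng(self.random_state)
        p = X.shape[1]

        if self.standardize:
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
        else:
            mu = np.zeros(p)
            sd = np.ones(p)
        Xs = (X - mu) / sd

        # gamma is selected once per dataset by CV on the original frames;
        # CV on a with-replacement resample would leak duplicated samples
        # across folds and systematically under-penalize.
        gamma = self.gamma
        if gamma is None:
            gamma = select_gamma(Xs, y, self.alpha, rng=rng,
                                 n_folds=self.cv_folds, tol=self.tol,
                                 max_iter=self.max_iter)
        self.gamma_ = float(gamma)

        n_fit = 2 * self.n_per_state
        clf = _make_solver(self.alpha, self.gamma_, n_fit, self.tol, self.max_iter)
        coef = np.empty((self.n_repeats, p))
        icpt = np.empty(self.n_repeats)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for r in range(self.n_repeats):
                Xr, yr = self._balanced_resample(Xs, y, rng)
                clf.fit(Xr, yr)
                b = clf.coef_.ravel()
                coef[r] = b / sd
                icpt[r] = clf.intercept_[0] - float((b * mu / sd).sum())
        self.coef_samples_ = coef
        self.intercept_samples_ = icpt
        self.centroid_ = coef.mean(axis=0)
        sigma = coef.std(axis=0)  # ML normal fit
        self.ci_halfwidth_ = 1.96 * sigma
        excludes_zero = np.abs(self.centroid_) > self.ci_halfwidth_
        degenerate = (sigma == 0) & (self.centroid_ != 0)
        member_mask = excludes_zero | degenerate
        self.members_ = np.flatnonzero(member_mask)
        self.coef_ = np.where(member_mask, self.centroid_, 0.0)
        self.intercept_ = float(icpt.mean())
        self.n_features_in_ = p
        return self

    # -- prediction ---------------------------------------------------------
    def decision_function(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.intercept_ + X @ self.coef_

    def predict_proba(self, X):
        z = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        # strict > 0.5: a tie at exactly 0.5 goes to class 0
        p1 = self.predict_proba(X)[:, 1]
        return self.classes_[(p1 > 0.5).astype(int)]


def extract_ensemble(dataset: LabeledDataset, alpha: float, *, n_repeats: int = 100,
                     n_per_state: int = 900, gamma: float | None = None,
                     random_state=None, tol: float = 1e-3) -> ElasticNetEnsemble:
    """Fit an :class:`ElasticNetEnsemble` on a labeled dataset."""
    seed = random_state
    if isinstance(seed, np.random.Generator):
        seed = int(seed.integers(2**31 - 1))
    est = ElasticNetEnsemble(alpha=alpha, gamma=gamma, n_repeats=n_repeats,
                             n_per_state=n_per_state, random_state=seed, tol=tol)
    return est.fit(dataset.X, dataset.y)


def evaluate_model(model: ElasticNetEnsemble, dataset: LabeledDataset,
                   mode: str = "fitting") -> dict:
    """Accuracy and ROC AUC of a model on a dataset.

    ``mode`` is metadata: 'fitting' when the frames overlap the training
    condition, 'decoding' when they are disjoint from it.
    """
    if mode not in ("fitting", "decoding"):
        raise ValueError("mode must be 'fitting' or 'decoding'")
    y = dataset.y
    if np.unique(y).size < 2:
        raise ValueError("AUC undefined on a single-label dataset")
    p1 = model.predict_proba(dataset.X)[:, 1]
    acc = float(np.mean((p1 > 0.5).astype(int) == y))
    auc = float(roc_auc_score(y, p1))
    return dict(accuracy=acc, auc=auc, mode=mode, condition=dataset.condition)


# ---------------------------------------------------------------------------
# Alpha optimization by removal-AUC difference
# ---------------------------------------------------------------------------

@dataclass
class RemovalResult:
    alpha: float
    auc_cre_removed: np.ndarray
    auc_noncre_removed: np.ndarray

    @property
    def auc_difference(self) -> float:
        return float(self.auc_noncre_removed.mean() - self.auc_cre_removed.mean())


def removal_auc_difference(dataset: LabeledDataset, members: np.ndarray, alpha: float,
                           *, n_outer: int = 10, inner_repeats: int = 20,
                           n_per_state: int = 900, rng=None,
                           tol: float = 1e-3) -> RemovalResult:
    """Information remaining after removing the ensemble vs a random set.

    For each of ``n_outer`` estimates, re-extracts an ensemble (with
    ``inner_repeats`` resampling repeats) on (a) all neurons minus the
    members and (b) all neurons minus an equally sized random non-member
    subset, then records the fitting AUC of each reduced model.  Returns
    the 10+10 AUCs; the headline statistic is
    mean(non-ensemble-removed) - mean(ensemble-removed).
    """
    rng = as_rng(rng)
    members = np.asarray(sorted(members))
    p = dataset.n_neurons
    if members.size >= p - 1:
        raise ValueError("cannot remove the ensemble: too few neurons would remain")
    non_members = np.setdiff1d(np.arange(p), members)
    keep_cre_removed = non_members  # fixed across outer repeats
    ds_cre_rem = dataset.subset_neurons(keep_cre_removed)
    gamma_cre = None
    auc_cre, auc_non = np.empty(n_outer), np.empty(n_outer)
    for k in range(n_outer):
        seed = int(rng.integers(2**31 - 1))
        m = extract_ensemble(ds_cre_rem, alpha, n_repeats=inner_repeats,
                             n_per_state=n_per_state, gamma=gamma_cre,
                             random_state=seed, tol=tol)
        gamma_cre = m.gamma_  # columns are fixed; reuse the selected penalty
        auc_cre[k] = evaluate_model(m, ds_cre_rem)["auc"]

        drop = rng.choice(non_members, size=members.size, replace=False)
        keep = np.setdiff1d(np.arange(p), drop)
        ds_non = dataset.subset_neurons(keep)
        m2 = extract_ensemble(ds_non, alpha, n_repeats=inner_repeats,
                              n_per_state=n_per_state,
                              random_state=int(rng.integers(2**31 - 1)), tol=tol)
        auc_non[k] = evaluate_model(m2, ds_non)["auc"]
    return RemovalResult(alpha=alpha, auc_cre_removed=auc_cre, auc_noncre_removed=auc_non)


@dataclass
class AlphaScanResult:
    alphas: list[float]
    ensemble_sizes: list[int]
    auc_original: list[float]
    removals: list[RemovalResult]
    best_alpha: float
    models: dict[float, ElasticNetEnsemble]

    @property
    def auc_differences(self) -> list[float]:
        return [r.auc_difference for r in self.removals]


def optimize_alpha(dataset: LabeledDataset, alpha_grid=DEFAULT_ALPHA_GRID, *,
                   extract_repeats: int = 100, n_outer: int = 10,
                   inner_repeats: int = 20, n_per_state: int = 900,
                   rng=None, tol: float = 1e-3) -> AlphaScanResult:
    """Scan alphas and pick the sparsest one that keeps the removal gap.

    The alpha with the maximum removal-AUC difference is the anchor; any
    alpha whose 10 difference estimates are statistically indistinguishable
    from the anchor's (two-sided rank-sum, p >= 0.05) joins the candidate
    set, and the largest candidate alpha wins (smallest ensemble among
    equivalently informative ones).
    """
    rng = as_rng(rng)
    alphas = sorted(set(float(a) for a in alpha_grid))
    sizes, auc_orig, removals, models = [], [], [], {}
    for a in alphas:
        model = extract_ensemble(dataset, a, n_repeats=extract_repeats,
                                 n_per_state=n_per_state,
                                 random_state=int(rng.integers(2**31 - 1)), tol=tol)
        models[a] = model
        sizes.append(int(model.members_.size))
        auc_orig.append(evaluate_model(model, dataset)["auc"])
        removals.append(removal_auc_difference(
            dataset, model.members_, a, n_outer=n_outer,
            inner_repeats=inner_repeats, n_per_state=n_per_state, rng=rng, tol=tol))
    if len(alphas) == 1:
        return AlphaScanResult(alphas, sizes, auc_orig, removals, alphas[0], models)
    diffs_per_alpha = [r.auc_noncre_removed - r.auc_cre_removed for r in removals]
    anchor = int(np.argmax([d.mean() for d in diffs_per_alpha]))
    candidates = {alphas[anchor]}
    for i, a in enumerate(alphas):
        if i == anchor:
            continue
        stat = sps.mannwhitneyu(diffs_per_alpha[i], diffs_per_alpha[anchor],
                                alternative="two-sided")
        if stat.pvalue >= 0.05:
            candidates.add(a)
    best = max(candidates)
    return AlphaScanResult(alphas, sizes, auc_orig, removals, best, models)
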