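"""Synthetic fear-conditioning experiments with planted ground truth.

Emulates a two-day discriminative auditory fear-conditioning protocol under a
head-fixed two-photon microscope: on day 3 (D3) a habituation session (4 CS-
and 4 CS+ tone trials, alternating, no shock) is immediately followed by the
conditioning session in which 7 CS+ trials each co-terminate with a 1-s foot
shock (US), alternating with CS- trials; on day 4 (D4) a post-conditioning
session presents 4 CS- and 12 CS+ trials without shock.  Every tone trial
lasts 30 s and consists of 30 50-ms pips at 1 Hz; inter-trial intervals are
drawn uniformly from 50-150 s.  Frames are acquired at ~9 Hz.

The generator plants ground truth that the downstream analyses are expected
to recover: a conditioned-response (CR) ensemble whose firing rate is
elevated while the animal shows CS+-evoked freezing-like immobility on D4, a
regular-stationary (RS) ensemble tied to spontaneous immobility outside tone
periods, shock-responsive (USR) neurons emitting large transients within
1.5 s of each US, a D4-only shared drive that raises within-CR-ensemble
correlations, and (for network-inference validation) explicit pairwise
couplings realized through a Gibbs-sampled binary raster.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import as_rng, check_fraction

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "TrialTimeline",
    "BehaviorTrack",
    "generate_timeline",
    "generate_behavior",
    "generate_activity",
    "generate_toy_movie",
    "generate_coupled_raster",
    "sample_ising_raster",
    "make_ground_truth",
    "generate_experiment",
    "default_session_plan",
]

# phase labels used throughout
D3_EARLY, D3_LATE, D4_EARLY, D4_LATE = "D3E", "D3L", "D4E", "D4L"


def default_session_plan() -> list[tuple[str, list[str]]]:
    """The standard protocol: D3 habituation, D3 conditioning, D4 post-FC.

    Trial codes: ``"CS-"``, ``"CS+"`` (tone only) and ``"CS+US"`` (tone whose
    last pip coincides with the 1-s shock).  The conditioning session carries
    exactly 7 CS+-US pairings alternating with CS- trials; the post-FC
    session has 4 CS- and 12 CS+ (4 alternating pairs, then 8 CS+).
    """
    hab = ["CS-", "CS+"] * 4
    cond = ["CS-", "CS+US"] * 7
    post = ["CS-", "CS+"] * 4 + ["CS+"] * 8
    return [("D3-hab", hab), ("D3-cond", cond), ("D4-post", post)]


@dataclass
class SyntheticConfig:
    """Parameters of the simulated experiment.

    Rates are per-neuron event rates in Hz; fractions are of ``n_neurons``.
    """

    n_neurons: int = 150
    frame_rate_hz: float = 9.0
    rng_seed: int = 0
    session_plan: list[tuple[str, list[str]]] = field(default_factory=default_session_plan)
    iti_range_s: tuple[float, float] = (50.0, 150.0)
    trial_duration_s: float = 30.0
    n_pips: int = 30
    us_duration_s: float = 1.0

    # ground-truth ensemble composition
    cr_ensemble_frac: float = 0.15
    rs_ensemble_frac: float = 0.15
    usr_count: int = 8
    usr_in_cre_frac: float = 0.75

    # behavior (first-order Markov move/stop process, per frame)
    p_move_to_stop: float = 0.05
    p_stop_to_move: float = 0.08
    cr_stop_hazard_gain: float = 5.0   # multiplier on move->stop during D4-early CS+
    cr_stop_release_gain: float = 1.0  # multiplier on stop->move during D4-early CS+
    mean_speed_cm_s: float = 8.0

    # activity
    baseline_rate_hz: float = 0.12
    cr_active_rate_hz: float = 2.0
    rs_active_rate_hz: float = 2.0
    us_event_prob: float = 0.85        # per-frame event prob for USR in US window
    us_amplitude: float = 3.0          # amplitude multiplier for US-locked events
    within_cre_corr_gain_d4: float = 0.35
    latent_rate_hz: float = 0.5        # rate of the shared within-CRE drive (D4 only)
    calcium_decay_s: float = 0.25
    noise_sd: float = 0.15

    def __post_init__(self) -> None:
        check_fraction("cr_ensemble_frac", self.cr_ensemble_frac)
        check_fraction("rs_ensemble_frac", self.rs_ensemble_frac)
        check_fraction("usr_in_cre_frac", self.usr_in_cre_frac)
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        if self.within_cre_corr_gain_d4 < 0:
            raise ValueError("within_cre_corr_gain_d4 must be >= 0")
        lo, hi = self.iti_range_s
        if not (0 < lo <= hi):
            raise ValueError(f"invalid iti_range_s {self.iti_range_s!r}")
        n_us = sum(t == "CS+US" for _, trials in self.session_plan for t in trials)
        if n_us and n_us != 7:
            raise ValueError(
                f"conditioning must contain exactly 7 CS+-US pairings, got {n_us}"
            )

    def replace(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Planted structure the analyses should recover."""

    cr_members: set[int]
    rs_members: set[int]
    usr_members: set[int]
    # day -> {(i, j): coupling strength}, i < j
    pairwise_coupling: dict[int, dict[tuple[int, int], float]] = field(default_factory=dict)

    def validate(self, n_neurons: int) -> None:
        for name, s in (("cr", self.cr_members), ("rs", self.rs_members), ("usr", self.usr_members)):
            if s and (min(s) < 0 or max(s) >= n_neurons):
                raise ValueError(f"{name}_members outside 0..{n_neurons - 1}")
        for day, cmap in self.pairwise_coupling.items():
            for (i, j) in cmap:
                if i == j:
                    raise ValueError(f"self-coupling ({i},{j}) on day {day}")
                if not i < j:
                    raise ValueError("coupling keys must have i < j")


@dataclass
class TrialTimeline:
    """Tidy trial table plus frame-level clock bookkeeping.

    ``trials`` columns: session, day (3/4), trial_index (within day),
    cs_type ("CS+"/"CS-"), onset_s (within-day clock), duration_s,
    us_onset_s (NaN if no shock), phase (D3E/D3L/D4E/D4L or "mid").
    """

    trials: pd.DataFrame
    day_duration_s: dict[int, float]
    frame_rate_hz: float
    n_pips: int = 30
    us_duration_s: float = 1.0

    def pip_onsets(self, trial_row) -> np.ndarray:
        return trial_row.onset_s + np.arange(self.n_pips, dtype=float)

    def us_onsets(self, day: int | None = None) -> np.ndarray:
        t = self.trials if day is None else self.trials[self.trials.day == day]
        return t.us_onset_s.dropna().to_numpy()

    def select(self, day=None, cs_type=None, phase=None) -> pd.DataFrame:
        t = self.trials
        if day is not None:
            t = t[t.day == day]
        if cs_type is not None:
            t = t[t.cs_type == cs_type]
        if phase is not None:
            t = t[t.phase == phase]
        return t

    # -- frame-level helpers -------------------------------------------------
    def n_frames(self, day: int) -> int:
        return int(round(self.day_duration_s[day] * self.frame_rate_hz))

    def frame_times(self, day: int) -> np.ndarray:
        return np.arange(self.n_frames(day)) / self.frame_rate_hz

    def in_trial_mask(self, day: int, trials: pd.DataFrame | None = None) -> np.ndarray:
        """Boolean per-frame mask covering the given trials (default: all of day)."""
        t = self.select(day=day) if trials is None else trials
        times = self.frame_times(day)
        mask = np.zeros(times.size, dtype=bool)
        for row in t.itertuples():
            mask |= (times >= row.onset_s) & (times < row.onset_s + row.duration_s)
        return mask

    def to_frame(self) -> pd.DataFrame:
        return self.trials.copy()


def _tag_phases(trials: pd.DataFrame) -> pd.Series:
    """Phase blocks: first/last 3 conditioning trials per CS type on D3;
    first 3 per CS type and last 3 CS+ on D4."""
    phase = pd.Series("mid", index=trials.index)
    cond = trials[trials.session.str.contains("cond")]
    for cs in ("CS+", "CS-"):
        sel = cond[cond.cs_type == cs]
        if len(sel) < 3:
            raise ValueError(f"conditioning session needs >=3 {cs} trials for phase blocks")
        phase.loc[sel.index[:3]] = D3_EARLY
        phase.loc[sel.index[-3:]] = D3_LATE
    post = trials[trials.day == 4]
    for cs in ("CS+", "CS-"):
        sel = post[post.cs_type == cs]
        if len(sel) < 3:
            raise ValueError(f"post-FC session needs >=3 {cs} trials for phase blocks")
        phase.loc[sel.index[:3]] = D4_EARLY
    csp = post[post.cs_type == "CS+"]
    phase.loc[csp.index[-3:]] = D4_LATE
    return phase


def generate_timeline(config: SyntheticConfig, rng=None) -> TrialTimeline:
    """Lay out trials on per-day clocks with uniform inter-trial intervals.

    Each 30-s tone trial carries 30 pip onsets at 1-s spacing; on CS+US
    trials a 1-s shock starts at the 30th pip onset and co-terminates with
    the trial.  Gaps before every trial are drawn uniformly from
    ``iti_range_s``.  D3 habituation and conditioning share one clock.
    """
    rng = as_rng(config.rng_seed if rng is None else rng)
    lo, hi = config.iti_range_s
    rows = []
    day_clock: dict[int, float] = {}
    trial_idx: dict[int, int] = {}
    for session, trial_codes in config.session_plan:
        day = 4 if session.startswith("D4") else 3
        t = day_clock.get(day, 0.0)
        for code in trial_codes:
            gap = float(rng.uniform(lo, hi))
            onset = t + gap
            cs = "CS+" if code.startswith("CS+") else "CS-"
            us = onset + config.trial_duration_s - config.us_duration_s if code == "CS+US" else np.nan
            rows.append(
                dict(session=session, day=day, trial_index=trial_idx.get(day, 0),
                     cs_type=cs, onset_s=onset, duration_s=config.trial_duration_s,
                     us_onset_s=us)
            )
            trial_idx[day] = trial_idx.get(day, 0) + 1
            t = onset + config.trial_duration_s
        day_clock[day] = t
    trials = pd.DataFrame(rows)
    trials["phase"] = _tag_phases(trials)
    day_duration = {d: day_clock[d] + hi for d in day_clock}  # tail padding
    return TrialTimeline(
        trials=trials,
        day_duration_s=day_duration,
        frame_rate_hz=config.frame_rate_hz,
        n_pips=config.n_pips,
        us_duration_s=config.us_duration_s,
    )


@dataclass
class BehaviorTrack:
    """Per-frame locomotion, per day.

    ``speed`` maps day -> array of disk speeds (cm/s); ``moving`` maps
    day -> boolean array (True while locomoting).  A freezing-like /
    stationary label is any no-movement bout lasting at least
    ``min_still_s`` (1 s by default), matching the behavioral scoring rule.
    """

    speed: dict[int, np.ndarray]
    moving: dict[int, np.ndarray]
    frame_rate_hz: float
    min_still_s: float = 1.0

    def still_mask(self, day: int) -> np.ndarray:
        """Frames inside a no-movement bout of >= min_still_s."""
        stop = ~self.moving[day]
        min_len = max(1, int(round(self.min_still_s * self.frame_rate_hz)))
        out = np.zeros_like(stop)
        i = 0
        n = stop.size
        while i < n:
            if stop[i]:
                j = i
                while j < n and stop[j]:
                    j += 1
                if j - i >= min_len:
                    out[i:j] = True
                i = j
            else:
                i += 1
        return out


def generate_behavior(timeline: TrialTimeline, config: SyntheticConfig, rng=None) -> BehaviorTrack:
    """Two-state (move/stop) first-order Markov locomotion process.

    During D4-early CS+ trials the move->stop hazard is multiplied by
    ``cr_stop_hazard_gain`` and the stop->move hazard by
    ``cr_stop_release_gain``, producing the conditioned suppression of
    locomotion; D4-late CS+ trials use baseline hazards (extinction).
    """
    rng = as_rng(config.rng_seed + 1 if rng is None else rng)
    days = sorted(timeline.day_duration_s)
    if set(days) != {3, 4}:
        raise ValueError("timeline must cover both days (3 and 4)")
    speed, moving = {}, {}
    for day in days:
        n = timeline.n_frames(day)
        cr_mask = np.zeros(n, dtype=bool)
        if day == 4:
            d4e = timeline.select(day=4, cs_type="CS+", phase=D4_EARLY)
            cr_mask = timeline.in_trial_mask(4, d4e)
        mov = np.zeros(n, dtype=bool)
        state = True  # sessions start with the animal locomoting
        u = rng.random(n)
        for i in range(n):
            p_ms = config.p_move_to_stop * (config.cr_stop_hazard_gain if cr_mask[i] else 1.0)
            p_sm = config.p_stop_to_move * (config.cr_stop_release_gain if cr_mask[i] else 1.0)
            if state:
                state = not (u[i] < min(p_ms, 1.0))
            else:
                state = u[i] < min(p_sm, 1.0)
            mov[i] = state
        spd = np.where(mov, rng.gamma(4.0, config.mean_speed_cm_s / 4.0, size=n), 0.0)
        speed[day], moving[day] = spd, mov
    return BehaviorTrack(speed=speed, moving=moving, frame_rate_hz=config.frame_rate_hz)


def make_ground_truth(config: SyntheticConfig, rng=None,
                      hub_fanout_frac: float = 0.6,
                      hub_coupling: float = 0.8,
                      background_coupling: float = 0.0) -> GroundTruth:
    """Draw member sets and per-day couplings.

    CR and RS ensembles are disjoint; ``usr_in_cre_frac`` of the USR neurons
    are placed inside the CR ensemble.  On day 4 each USR-in-CRE neuron
    (candidate network hub) is coupled to a random ``hub_fanout_frac`` of the
    other CR-ensemble members with strength ``hub_coupling``; day 3 carries
    no such couplings.
    """
    rng = as_rng(config.rng_seed + 2 if rng is None else rng)
    n = config.n_neurons
    n_cr = int(round(config.cr_ensemble_frac * n))
    n_rs = int(round(config.rs_ensemble_frac * n))
    perm = rng.permutation(n)
    cr = set(int(i) for i in perm[:n_cr])
    rs = set(int(i) for i in perm[n_cr:n_cr + n_rs])
    n_usr_in = min(int(round(config.usr_in_cre_frac * config.usr_count)), n_cr)
    usr = set(int(i) for i in rng.choice(sorted(cr), size=n_usr_in, replace=False))
    outside = [i for i in range(n) if i not in cr]
    usr |= set(int(i) for i in rng.choice(outside, size=config.usr_count - n_usr_in, replace=False))
    coupling: dict[int, dict[tuple[int, int], float]] = {3: {}, 4: {}}
    hubs = sorted(usr & cr)
    others = sorted(cr - usr)
    for h in hubs:
        k = int(round(hub_fanout_frac * len(others)))
        for t in rng.choice(others, size=k, replace=False):
            key = (min(h, int(t)), max(h, int(t)))
            coupling[4][key] = hub_coupling
    if background_coupling:
        for day in (3, 4):
            for _ in range(n // 10):
                i, j = rng.choice(n, size=2, replace=False)
                coupling[day][(min(i, j), max(i, j))] = background_coupling
    gt = GroundTruth(cr_members=cr, rs_members=rs, usr_members=usr, pairwise_coupling=coupling)
    gt.validate(n)
    return gt


def _no_cs_mask(timeline: TrialTimeline, day: int) -> np.ndarray:
    return ~timeline.in_trial_mask(day)


def generate_activity(timeline: TrialTimeline, behavior: BehaviorTrack,
                      truth: GroundTruth, config: SyntheticConfig, rng=None):
    """Per-neuron binary event trains convolved with a calcium kernel.

    Returns ``(traces, raster)`` where both map day -> array
    [neurons x frames]; ``traces`` are dF/F-scale (events convolved with a
    single-exponential kernel of decay ``calcium_decay_s`` plus Gaussian
    noise), ``raster`` is the underlying {0,1} event train.

    Rate rules (per frame, Bernoulli):
      * everyone fires at ``baseline_rate_hz``;
      * CR members fire at ``cr_active_rate_hz`` in freezing-like frames
        inside D4 CS+ trials;
      * RS members fire at ``rs_active_rate_hz`` in stationary (>=1 s still)
        frames except inside D4 CS+ trials, where the conditioned-response
        representation supersedes the regular-stationary one;
      * USR members emit events of amplitude ``us_amplitude`` with
        probability ``us_event_prob`` within 1.5 s of each US onset;
      * on D4 a shared latent Bernoulli drive (rate ``latent_rate_hz``)
        adds event probability ``within_cre_corr_gain_d4`` to every CR
        member while it is on.
    """
    rng = as_rng(config.rng_seed + 3 if rng is None else rng)
    truth.validate(config.n_neurons)
    fr = config.frame_rate_hz
    n = config.n_neurons
    cr = sorted(truth.cr_members)
    rs = sorted(truth.rs_members)
    usr = sorted(truth.usr_members)
    decay = np.exp(-1.0 / (config.calcium_decay_s * fr))
    kernel_len = max(1, int(round(5 * config.calcium_decay_s * fr)))
    kernel = decay ** np.arange(kernel_len)

    traces, rasters = {}, {}
    for day in sorted(timeline.day_duration_s):
        nf = timeline.n_frames(day)
        times = timeline.frame_times(day)
        p = np.full((n, nf), min(config.baseline_rate_hz / fr, 1.0))

        still = behavior.still_mask(day)
        d4_csp = np.zeros(nf, dtype=bool)
        if day == 4:
            d4_csp = timeline.in_trial_mask(4, timeline.select(day=4, cs_type="CS+"))
        if rs:
            rs_frames = still & ~d4_csp
            p[np.ix_(rs, np.flatnonzero(rs_frames))] = min(config.rs_active_rate_hz / fr, 1.0)
        if day == 4 and cr:
            freeze_cs = d4_csp & still
            p[np.ix_(cr, np.flatnonzero(freeze_cs))] = min(config.cr_active_rate_hz / fr, 1.0)

        amp = np.ones((n, nf))
        if usr:
            us_mask = np.zeros(nf, dtype=bool)
            for t0 in timeline.us_onsets(day):
                us_mask |= (times >= t0) & (times < t0 + 1.5)
            if us_mask.any():
                idx = np.flatnonzero(us_mask)
                p[np.ix_(usr, idx)] = config.us_event_prob
                amp[np.ix_(usr, idx)] = config.us_amplitude

        events = (rng.random((n, nf)) < p).astype(np.float64)
        if day == 4 and cr and config.within_cre_corr_gain_d4 > 0:
            latent = rng.random(nf) < min(config.latent_rate_hz / fr, 1.0)
            extra = rng.random((len(cr), nf)) < config.within_cre_corr_gain_d4
            events[cr] = np.maximum(events[cr], (extra & latent[None, :]).astype(np.float64))
        rasters[day] = (events > 0).astype(np.int8)

        amped = events * amp
        tr = np.empty_like(amped)
        for i in range(n):
            tr[i] = np.convolve(amped[i], kernel)[:nf]
        if config.noise_sd > 0:
            tr += rng.normal(0.0, config.noise_sd, size=tr.shape)
        traces[day] = tr
    return traces, rasters


# ---------------------------------------------------------------------------
# Ising-style raster generator (network-inference ground truth)
# ---------------------------------------------------------------------------

def sample_ising_raster(h: np.ndarray, J: np.ndarray, n_frames: int, rng,
                        burn_in: int = 200, thin: int = 2) -> np.ndarray:
    """Gibbs-sample frames from a pairwise binary model.

    The model is ``p(x) ∝ exp(sum_i h_i x_i + sum_{i<j} J_ij x_i x_j)`` with
    x in {0,1}.  Returns an array [n_frames x n] of iid-ish samples obtained
    by systematic-scan Gibbs with ``burn_in`` initial sweeps discarded and
    ``thin`` sweeps between retained frames.
    """
    rng = as_rng(rng)
    n = h.size
    J = np.asarray(J, dtype=float)
    if J.shape != (n, n) or not np.allclose(J, J.T):
        raise ValueError("J must be a symmetric n x n matrix")
    x = (rng.random(n) < 0.5).astype(np.float64)
    out = np.empty((n_frames, n), dtype=np.int8)
    total = burn_in + n_frames * thin
    u = rng.random((total, n))
    kept = 0
    for sweep in range(total):
        for i in range(n):
            field = h[i] + J[i] @ x - J[i, i] * x[i]
            x[i] = 1.0 if u[sweep, i] < 1.0 / (1.0 + np.exp(-field)) else 0.0
        if sweep >= burn_in and (sweep - burn_in) % thin == 0 and kept < n_frames:
            out[kept] = x.astype(np.int8)
            kept += 1
    return out


def generate_coupled_raster(truth: GroundTruth, day: int, config: SyntheticConfig,
                            n_frames: int, rng=None,
                            base_logit: float = -2.2) -> np.ndarray:
    """Binary raster [frames x neurons] realizing the planted couplings of a day.

    Node biases are uniform (``base_logit``); pairwise couplings come from
    ``truth.pairwise_coupling[day]``.  Used to validate graphical-model
    structure recovery and day-specific hub emergence.
    """
    rng = as_rng(config.rng_seed + 10 + day if rng is None else rng)
    n = config.n_neurons
    h = np.full(n, base_logit)
    J = np.zeros((n, n))
    for (i, j), w in truth.pairwise_coupling.get(day, {}).items():
        J[i, j] = J[j, i] = w
    return sample_ising_raster(h, J, n_frames, rng)


# ---------------------------------------------------------------------------
# Toy pixel movies (background-subtraction fixture)
# ---------------------------------------------------------------------------

def generate_toy_movie(traces: np.ndarray, config: SyntheticConfig, rng=None,
                       frame_shape: tuple[int, int] = (96, 96), roi_radius: int = 3,
                       background: np.ndarray | None = None,
                       pixel_noise_sd: float = 0.0, offset: float = 100.0):
    """Paint disk ROIs carrying the given traces onto a small movie.

    ``traces`` is [neurons x frames].  Each neuron becomes a disk of radius
    ``roi_radius`` at a random non-overlapping center; all pixels share an
    additive low-frequency ``background`` series (scalar per frame) plus the
    constant ``offset`` so raw intensities stay positive.  Returns
    ``(movie, masks)`` with movie [frames x h x w] and masks a list of
    boolean [h x w] arrays.
    """
    rng = as_rng(config.rng_seed + 20 if rng is None else rng)
    n, nf = traces.shape
    h, w = frame_shape
    if h > 128 or w > 128 or n > 50:
        raise ValueError("toy movies are limited to <=128x128 px and <=50 ROIs")
    margin = roi_radius + 2
    centers: list[tuple[int, int]] = []
    for _ in range(10000):
        if len(centers) == n:
            break
        cy, cx = rng.integers(margin, h - margin), rng.integers(margin, w - margin)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= (2 * roi_radius + 2) ** 2 for y, x in centers):
            centers.append((int(cy), int(cx)))
    if len(centers) < n:
        raise ValueError("could not place non-overlapping ROI centers (frame too small)")
    yy, xx = np.mgrid[0:h, 0:w]
    masks = [((yy - cy) ** 2 + (xx - cx) ** 2) <= roi_radius**2 for cy, cx in centers]
    if background is None:
        background = np.zeros(nf)
    background = np.asarray(background, dtype=float)
    if background.shape != (nf,):
        raise ValueError("background must be a per-frame series")
    movie = np.tile((offset + background)[:, None, None], (1, h, w)).astype(np.float64)
    for i, mask in enumerate(masks):
        movie[:, mask] += traces[i][:, None]
    if pixel_noise_sd > 0:
        movie += rng.normal(0.0, pixel_noise_sd, size=movie.shape)
    return movie, masks


# ---------------------------------------------------------------------------
# One-call experiment bundle
# ---------------------------------------------------------------------------

@dataclass
class Experiment:
    """A complete synthetic recording: timeline, behavior, traces, truth."""

    config: SyntheticConfig
    timeline: TrialTimeline
    behavior: BehaviorTrack
    traces: dict[int, np.ndarray]
    raster: dict[int, np.ndarray]
    truth: GroundTruth


def generate_experiment(config: SyntheticConfig | None = None, seed: int | None = None) -> Experiment:
    """Generate a full experiment; all randomness derives from one seed."""
    config = config or SyntheticConfig()
    if seed is not None:
        config = config.replace(rng_seed=int(seed))
    timeline = generate_timeline(config)
    behavior = generate_behavior(timeline, config)
    truth = make_ground_truth(config)
    traces, raster = generate_activity(timeline, behavior, truth, config)
    return Experiment(config=config, timeline=timeline, behavior=behavior,
                      traces=traces, raster=raster, truth=truth)
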