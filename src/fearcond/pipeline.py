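"""End-to-end orchestration of the analysis on synthetic or user data.

Stages run in dependency order: synthesis (or loading) -> preprocessing ->
per-neuron response scoring -> ensemble extraction -> coactivity -> network
model -> statistics.  Every stochastic stage receives a seed derived
deterministically from the root seed and the stage name, outputs are
written as CSV/JSON, and a manifest records versions, seeds and content
hashes so that two runs with the same configuration are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._util import as_rng, derive_seed
from . import coactivity as coact
from . import crf as crfmod
from . import ensembles as ens
from . import responses as resp
from . import stats as st
from .synth import SyntheticConfig, generate_coupled_raster, generate_experiment
from .traces import TraceMatrix, binarize_events

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``synth`` holds keyword overrides for :class:`SyntheticConfig`; when
    ``traces_csv``/``timeline_csv``/``behavior_csv`` are given, those files
    are used instead of synthesis.  Scale parameters for the heavier stages
    are exposed so that small smoke runs stay cheap.
    """

    seed: int = 0
    out_dir: str = "fearcond_run"
    synth: dict = field(default_factory=dict)
    traces_csv: str | None = None
    timeline_csv: str | None = None
    behavior_csv: str | None = None

    cr_phase: str = "D4E"
    alpha_grid: tuple = ens.DEFAULT_ALPHA_GRID
    optimize_cr_alpha: bool = False
    cr_alpha: float = 0.5
    rs_alpha: float = ens.RS_ALPHA
    extract_repeats: int = 100
    n_per_state: int = 900

    crf_frames: int = 1500
    crf_lambda_s_grid: tuple = tuple(np.linspace(1e-5, 0.5, 8))
    crf_lambda_p_grid: tuple = (1.0, 10.0, 100.0)

    n_boot: int = 2000
    coactivity_shuffles: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))


def validate_inputs(traces: TraceMatrix, timeline, behavior) -> dict:
    """Alignment and precondition checks; report-only (never raises)."""
    issues = []
    for day in sorted(timeline.day_duration_s):
        nf_tl = timeline.n_frames(day)
        nf_tr = traces.day_slice(day).shape[1]
        if nf_tr < nf_tl:
            issues.append(f"day {day}: traces have {nf_tr} frames but timeline "
                          f"implies {nf_tl}")
        tr = timeline.select(day=day)
        if not tr.onset_s.is_monotonic_increasing:
            issues.append(f"day {day}: trial onsets are not monotone")
        last = tr.onset_s.max() + 30.0
        if last * timeline.frame_rate_hz > nf_tr:
            issues.append(f"day {day}: timeline extends beyond the trace")
        if behavior is not None and behavior.moving.get(day) is not None:
            if behavior.moving[day].size != nf_tl:
                issues.append(f"day {day}: behavior frame count mismatch")
    try:
        ds = ens.build_dataset(traces, behavior, timeline, "cr", phase="D4E")
        frac = min(ds.y.mean(), 1 - ds.y.mean())
    except ValueError as exc:
        issues.append(str(exc))
        frac = None
    return dict(ok=not issues, issues=issues, cr_minority_label_frac=frac)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {stage: derive_seed(config.seed, stage)
             for stage in ("synth", "ensembles", "coactivity", "crf", "stats")}
    manifest = dict(package_version=__version__, python=platform.python_version(),
                    root_seed=config.seed, stage_seeds=seeds, stages={}, outputs={})

    def record(stage, path: Path):
        manifest["outputs"][str(path.relative_to(out))] = _sha256(path)

    stage = "synth"
    try:
        synth_cfg = SyntheticConfig(rng_seed=seeds["synth"], **config.synth)
        exp = generate_experiment(synth_cfg)
        timeline, behavior, truth = exp.timeline, exp.behavior, exp.truth
        z = TraceMatrix.from_days(exp.traces, "dff", synth_cfg.frame_rate_hz)
        from .traces import znormalize
        z = znormalize(z)
        timeline.to_frame().to_csv(out / "timeline.csv", index=False)
        record(stage, out / "timeline.csv")
        _write_json(out / "ground_truth.json", dict(
            cr_members=sorted(truth.cr_members), rs_members=sorted(truth.rs_members),
            usr_members=sorted(truth.usr_members)))
        record(stage, out / "ground_truth.json")
        manifest["stages"][stage] = "ok"

        stage = "responses"
        us_table = resp.score_us_responses(z, timeline)
        us_table.to_csv(out / "us_responses.csv", index=False)
        record(stage, out / "us_responses.csv")
        cs_table = pd.concat([
            resp.score_cs_responses(z, timeline, ph, cs)
            for ph in ("D3E", "D3L", "D4E") for cs in ("CS+", "CS-")
        ])
        cs_table.to_csv(out / "cs_responses.csv", index=False)
        record(stage, out / "cs_responses.csv")
        manifest["stages"][stage] = "ok"

        stage = "ensembles"
        rng_e = as_rng(seeds["ensembles"])
        ds_cr = ens.build_dataset(z, behavior, timeline, "cr", phase=config.cr_phase)
        if config.optimize_cr_alpha:
            scan = ens.optimize_alpha(ds_cr, config.alpha_grid,
                                      extract_repeats=config.extract_repeats,
                                      n_per_state=config.n_per_state, rng=rng_e)
            cr_model = scan.models[scan.best_alpha]
            cr_alpha = scan.best_alpha
        else:
            cr_alpha = config.cr_alpha
            cr_model = ens.extract_ensemble(
                ds_cr, cr_alpha, n_repeats=config.extract_repeats,
                n_per_state=config.n_per_state,
                random_state=int(rng_e.integers(2**31 - 1)))
        ds_rs = ens.build_dataset(z, behavior, timeline, "rs", day=4)
        rs_model = ens.extract_ensemble(
            ds_rs, config.rs_alpha, n_repeats=config.extract_repeats,
            n_per_state=config.n_per_state,
            random_state=int(rng_e.integers(2**31 - 1)))
        cre = set(cr_model.members_.tolist())
        rse = set(rs_model.members_.tolist())
        overlap = len(cre & rse) / max(len(cre | rse), 1) * 100
        # cross-decoding: each model applied to CS+ frames before/after conditioning
        cross = {}
        for ph in ("D3E", config.cr_phase):
            ds_ph = ens.build_dataset(z, behavior, timeline, "cr", phase=ph,
                                      check_balance=False)
            if np.unique(ds_ph.y).size == 2:
                cross[f"rs_to_{ph}"] = ens.evaluate_model(rs_model, ds_ph, "decoding")["auc"]
                mode = "fitting" if ph == config.cr_phase else "decoding"
                cross[f"cr_to_{ph}"] = ens.evaluate_model(cr_model, ds_ph, mode)["auc"]
        _write_json(out / "ensembles.json", dict(
            cr_alpha=cr_alpha, cr_gamma=cr_model.gamma_,
            cr_members=sorted(cre), rs_members=sorted(rse),
            cre_rse_overlap_pct=overlap, cross_decoding=cross,
            cr_fit=ens.evaluate_model(cr_model, ds_cr),
            rs_fit=ens.evaluate_model(rs_model, ds_rs)))
        record(stage, out / "ensembles.json")
        manifest["stages"][stage] = "ok"

        stage = "coactivity"
        rng_c = as_rng(seeds["coactivity"])
        labels = np.array(["CRE" if i in cre else "nonCRE" for i in range(z.n_neurons)])
        summaries = {}
        corr_by_day = {}
        for day, ph in ((3, "D3E"), (4, "D4E")):
            trials = timeline.select(day=day, cs_type="CS+", phase=ph)
            mask = timeline.in_trial_mask(day, trials)
            vals = z.day_slice(day)[:, : mask.size]
            corr_by_day[day] = coact.pairwise_correlations(vals, mask[: vals.shape[1]],
                                                           group_labels=labels)
        summaries = coact.summarize_groups(corr_by_day[4], corr_by_day[3])
        null = coact.shuffle_null(z.day_slice(4), None,
                                  max(config.coactivity_shuffles, 100), rng_c)
        summaries["shuffle_null_mean_r"] = float(np.nanmean(
            null[:, ~np.eye(z.n_neurons, dtype=bool)]))
        _write_json(out / "coactivity.json", summaries)
        record(stage, out / "coactivity.json")
        manifest["stages"][stage] = "ok"

        stage = "crf"
        rng_g = as_rng(seeds["crf"])
        crf_report = {}
        conn_by_day = {}
        for day in (3, 4):
            raster = generate_coupled_raster(truth, day, synth_cfg, config.crf_frames,
                                             rng=rng_g)
            sel = crfmod.select_model(raster, config.crf_lambda_s_grid,
                                      config.crf_lambda_p_grid, rng=rng_g)
            conn = sel.model.connectivity_scores()
            conn_by_day[day] = conn
            usr_in_cre = sorted(truth.usr_members & truth.cr_members)
            cre_others = sorted(truth.cr_members - truth.usr_members)
            crf_report[f"day{day}"] = dict(
                lambda_s=sel.lambda_s, lambda_p=sel.lambda_p,
                n_edges=sel.model.structure_.n_edges,
                heldout_loglik=sel.heldout_loglik,
                mean_conn_usr_in_cre=float(conn[usr_in_cre].mean()) if usr_in_cre else None,
                mean_conn_other_cre=float(conn[cre_others].mean()) if cre_others else None)
        _write_json(out / "crf.json", crf_report)
        record(stage, out / "crf.json")
        manifest["stages"][stage] = "ok"

        stage = "stats"
        rng_s = as_rng(seeds["stats"])
        usr_ids = us_table[us_table.usr].neuron_id.to_numpy()
        n_usr_in_cre = int(np.isin(usr_ids, sorted(cre)).sum())
        ratios = {}
        if usr_ids.size:
            ratios["usr_in_cre_pct"] = resp.membership_ratio(n_usr_in_cre, usr_ids.size)
        table = np.array([
            [n_usr_in_cre, usr_ids.size - n_usr_in_cre],
            [len(cre) - n_usr_in_cre,
             z.n_neurons - usr_ids.size - (len(cre) - n_usr_in_cre)],
        ])
        fisher = st.exact_2x2_test(table) if usr_ids.size else None
        report = dict(
            membership_ratios=ratios,
            usr_cre_fisher_p=(fisher.p if fisher else None),
            cre_rse_overlap_pct=overlap,
            cross_decoding=cross,
            hub_connectivity=crf_report,
        )
        _write_json(out / "report.json", report)
        record(stage, out / "report.json")
        manifest["stages"][stage] = "ok"
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        _write_json(out / "manifest.json", manifest)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _write_json(out / "manifest.json", manifest)
    return manifest
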