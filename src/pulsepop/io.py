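"""Session-bundle readers/writers, validation, and the pipeline orchestrator.

A session is stored as a directory of four comma-separated tables
(``trials.csv``, ``pulses.csv``, ``spikes.csv``, ``units.csv``) plus a
JSON sidecar ``config.json`` holding seeds and generator parameters. All
bundle invariants are checked on load and violations raise named
validation errors, so malformed inputs never propagate into analyses.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .stimgen import N_PULSES
from .synth import STIM_DUR_S, SessionBundle

TRIAL_COLUMNS = [
    "trial_id", "condition", "mu_index", "choice", "correct", "rt_s",
    "t_stim_on", "t_stim_off", "t_fix_off", "t_sacc", "t_reward",
    "t_targets_on", "frozen",
]
PULSE_COLUMNS = ["trial_id", "pulse_index", "value"]
SPIKE_COLUMNS = ["trial_id", "unit_id", "time_s"]
UNIT_COLUMNS = ["unit_id", "d_prime", "pref_sign"]

_TIME_TOL = 1e-6


class ValidationError(ValueError):
    """Base class for session-bundle validation failures."""


class MissingColumnError(ValidationError):
    pass


class OrphanReferenceError(ValidationError):
    pass


class PulseCountError(ValidationError):
    pass


class EventOrderError(ValidationError):
    pass


def validate_bundle(bundle: SessionBundle) -> None:
    """Check every SessionBundle invariant; raise a named error on failure."""
    for frame, cols, name in [
        (bundle.trials, TRIAL_COLUMNS, "trials"),
        (bundle.pulses, PULSE_COLUMNS, "pulses"),
        (bundle.spikes, SPIKE_COLUMNS, "spikes"),
        (bundle.units, UNIT_COLUMNS, "units"),
    ]:
        missing = set(cols) - set(frame.columns)
        if missing:
            raise MissingColumnError(f"{name} table missing columns {sorted(missing)}")
    trial_ids = set(bundle.trials["trial_id"])
    for name, frame in [("spikes", bundle.spikes), ("pulses", bundle.pulses)]:
        orphans = set(frame["trial_id"]) - trial_ids
        if orphans:
            raise OrphanReferenceError(
                f"{name} reference unknown trial_ids {sorted(orphans)[:5]}"
            )
    counts = bundle.pulses.groupby("trial_id").size()
    if set(counts.index) != trial_ids or (counts != N_PULSES).any():
        raise PulseCountError("every trial must have exactly 7 pulse rows")
    tr = bundle.trials
    dur = tr["t_stim_off"] - tr["t_stim_on"]
    if not np.allclose(dur, STIM_DUR_S, atol=_TIME_TOL):
        raise EventOrderError("stimulus duration must be 1.05 s on every trial")
    if not ((tr["t_fix_off"] >= tr["t_stim_off"] + 0.5 - _TIME_TOL).all()):
        raise EventOrderError("fixation offset must be >= 0.5 s after motion offset")
    if not ((tr["t_sacc"] > tr["t_fix_off"]).all()):
        raise EventOrderError("saccade must follow fixation offset")


def write_session(bundle: SessionBundle, dir_path: str | Path) -> Path:
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    bundle.trials.to_csv(dir_path / "trials.csv", index=False)
    bundle.pulses.to_csv(dir_path / "pulses.csv", index=False)
    bundle.spikes.to_csv(dir_path / "spikes.csv", index=False)
    bundle.units.to_csv(dir_path / "units.csv", index=False)
    with open(dir_path / "config.json", "w") as fh:
        json.dump(bundle.config, fh, indent=2, sort_keys=True)
    return dir_path


def read_session(dir_path: str | Path) -> SessionBundle:
    """Load and validate a session directory."""
    dir_path = Path(dir_path)
    for name in ("trials", "pulses", "spikes", "units"):
        if not (dir_path / f"{name}.csv").exists():
            raise FileNotFoundError(f"missing {name}.csv in {dir_path}")
    bundle = SessionBundle(
        trials=pd.read_csv(dir_path / "trials.csv"),
        pulses=pd.read_csv(dir_path / "pulses.csv"),
        spikes=pd.read_csv(dir_path / "spikes.csv"),
        units=pd.read_csv(dir_path / "units.csv"),
        config=json.loads((dir_path / "config.json").read_text())
        if (dir_path / "config.json").exists()
        else {},
    )
    validate_bundle(bundle)
    return bundle


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 0,
    "n_trials": 200,
    "n_units": 15,
    "condition": "flat",
    "choice_amplitude": 0.3,
    "stages": ["simulate", "behavior", "decode", "pta", "choice"],
    "out_dir": "pipeline_out",
}


def run_pipeline(config: dict) -> dict:
    """Execute simulate -> behavior -> decode -> pta -> choice on one session.

    Each stage writes its artifact under ``out_dir`` and is skipped (the
    cached artifact reloaded) when its output already exists, so toggling
    a downstream stage does not re-run upstream ones. All randomness
    derives from ``config['seed']``; rerunning with the same config
    reproduces the report exactly.
    """
    from . import behavior, choicemap, popdecode, pta, synth

    cfg = {**DEFAULT_CONFIG, **config}
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    report: dict = {"config": {k: v for k, v in cfg.items() if k != "stages"}}

    session_dir = out_dir / "session"
    if "simulate" in stages and not (session_dir / "trials.csv").exists():
        pop = synth.PopulationSpec(
            n_units=cfg["n_units"],
            choice_amplitude=cfg["choice_amplitude"],
            gain_profile=synth.decaying_gain,
        )
        bundle = synth.simulate_session(
            cfg["n_trials"], cfg["condition"], pop=pop, rng=cfg["seed"],
            spike_window="stimulus",
        )
        write_session(bundle, session_dir)
    bundle = read_session(session_dir)
    pulses = bundle.pulse_matrix()
    choices = bundle.trials["choice"].to_numpy()

    def cached(stage: str, compute):
        path = out_dir / f"{stage}.json"
        if stage not in stages and path.exists():
            return json.loads(path.read_text())
        if stage not in stages:
            return None
        if path.exists():
            return json.loads(path.read_text())
        result = compute()
        path.write_text(json.dumps(result, indent=2, sort_keys=True))
        return result

    def _behavior():
        x = pulses.sum(axis=1)
        x_z = (x - x.mean()) / (x.std() or 1.0)
        psy = behavior.fit_psychometric(x_z, choices)
        kern = behavior.fit_temporal_kernel(pulses, choices)
        return {
            "psychometric": {
                "alpha": psy.alpha, "beta": psy.beta, "gamma": psy.gamma,
                "se_alpha": psy.se_alpha, "se_beta": psy.se_beta,
                "se_gamma": psy.se_gamma, "loglik": psy.loglik,
            },
            "kernel": {
                "weights": kern.weights.tolist(),
                "normalized_weights": kern.normalized_weights.tolist(),
                "bias": kern.bias,
                "lambda_ridge": kern.lambda_ridge,
                "slope": kern.slope_linear_fit,
            },
        }

    def _decode():
        direction = popdecode.fit_direction_decoder(bundle)
        proj = popdecode.project_rates(direction, bundle)
        out = {
            "direction_weights": direction.weights.tolist(),
            "n_training_trials": int(len(direction.training_trials)),
        }
        frozen = bundle.trials["frozen"].to_numpy() == 1
        if frozen.sum() >= 10 and len(np.unique(choices[frozen])) == 2:
            choice_dec = popdecode.fit_choice_decoder_counts(bundle)
            cproj = popdecode.project_rates(choice_dec, bundle)
            cp = popdecode.cp_timecourse(
                popdecode.ProjectedRates(
                    values=cproj.values[frozen], times=cproj.times,
                    bin_s=cproj.bin_s, smoothing_s=cproj.smoothing_s,
                    alignment=cproj.alignment,
                ),
                choices[frozen],
            )
            out["choice_weights"] = choice_dec.weights.tolist()
            out["frozen_cp_mean"] = float(np.nanmean(cp.cp))
        np.save(out_dir / "projection.npy", proj.values)
        return out

    def _pta():
        proj_values = np.load(out_dir / "projection.npy")
        design = pta.build_design(pulses, trial_len_ms=1200, resolution_ms=10)
        response = pta.upsample_response(
            proj_values[:, :, None], bin_ms=10, trial_len_ms=1200, resolution_ms=10
        )
        result = pta.fit_pta(response, design)
        expfit = pta.fit_exponential(result.normalized_curves.max(axis=1)[:, 0])
        return {
            "lambda_prime": result.lambda_prime,
            "peaks": result.peaks[:, 0].tolist(),
            "normalized_peaks": result.normalized_curves.max(axis=1)[:, 0].tolist(),
            "exp_fit": {"a": expfit.a, "b": expfit.b, "r_squared": expfit.r_squared},
        }

    def _choice():
        weak = choicemap.select_weak_trials(
            pulses.sum(axis=1), bundle.trials["correct"].to_numpy(),
            min_trials=min(choicemap.MIN_WEAK_TRIALS, cfg["n_trials"] // 3),
        )
        rates, _ = popdecode.binned_rates(bundle, (0.0, 1.2), bin_s=0.1)
        factors = rates.transpose(0, 2, 1) * 0.1  # counts per 100 ms bin
        ids = weak.trial_ids
        resid = choicemap.residualize(factors[ids], pulses[ids])
        r_sum = resid.residuals.sum(axis=1)
        try:
            decoder, mapping = choicemap.fit_choice_decoder(r_sum, choices[ids])
            cp = choicemap.pooled_cp(mapping.c, choices[ids], mapping.fold_id)
        except ValueError as err:
            return {"excluded": True, "reason": str(err)}
        return {
            "n_weak_trials": int(len(ids)),
            "excluded": bool(weak.excluded),
            "lambda_hat": decoder.lambda_hat,
            "lambda_tilde": resid.lambda_tilde,
            "pooled_cp": cp,
        }

    report["behavior"] = cached("behavior", _behavior)
    report["decode"] = cached("decode", _decode)
    report["pta"] = cached("pta", _pta)
    report["choice"] = cached("choice", _choice)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
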