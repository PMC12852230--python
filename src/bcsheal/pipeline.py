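"""End-to-end analysis orchestration.

Stages: cohort generation (LHS) -> healing simulation per patient at each
fidelity -> outcome extraction (+ synthetic reviewer-consensus labels) ->
multi-fidelity surrogate training and repeated-split validation ->
2-D prediction maps.  Every artifact is a plain-text file (CSV/JSON) under
the output directory, written atomically (temp file + rename) and recorded
in ``manifest.json`` with the seeds and configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fem, gp, kinetics
from .cohort import (
    CohortDesign,
    PatientCharacteristics,
    cohort_table,
    sample_characteristics,
    synthetic_consensus_labels,
)
from .outcomes import SimulationOutcome, outcome_from_simulation, outcomes_table, summarize_cohort

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "simulate_cohort", "SCALES"]

#: named problem sizes: (n_low, n_high); the full-study scale is 273/163
SCALES = {"smoke": (5, 3), "desk": (16, 8), "paper": (273, 163)}


@dataclass
class PipelineConfig:
    n_low: int = 16
    n_high: int = 8
    seed: int = 0
    out_dir: str = "results/pipeline"
    dt: float = 0.5
    horizon: float = 28.0
    output_cadence: float = 2.0
    n_repeats: int = 20
    gp_restarts: int = 3
    n_mc: int = 100
    map_grid: int = 50
    params_path: str | None = None
    jobs: int = 1
    resume: bool = False
    write_fields: bool = False  # VTU/STL output per patient

    @classmethod
    def at_scale(cls, scale: str, **kw):
        n_low, n_high = SCALES[scale]
        return cls(n_low=n_low, n_high=n_high, **kw)

    def solver(self) -> fem.SolverConfig:
        return fem.SolverConfig(dt=self.dt, horizon=self.horizon,
                                output_cadence=self.output_cadence)

    def params(self) -> kinetics.KineticParams:
        if self.params_path:
            return kinetics.load_params(self.params_path)
        return kinetics.default_params()

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _atomic_write(path: Path, write_fn):
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        write_fn(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _simulate_one(chars: PatientCharacteristics, fidelity, params, solver_cfg, out_dir=None,
                  write_fields=False):
    sim = fem.simulate_patient(chars, fidelity, params=params, config=solver_cfg)
    out = outcome_from_simulation(sim)
    out.consensus_score = synthetic_consensus_labels(
        min(out.pbsd, 100.0), out.cavity_depth, seed=chars.seed + 17
    )
    if write_fields and out_dir is not None:
        from .mesh import write_stl, write_vtu

        mesh = sim["mesh"]
        st = sim["states"][-1]
        tag = f"{fidelity}_{chars.seed}"
        write_vtu(
            Path(out_dir) / f"patient_{tag}_week4.vtu", mesh,
            point_data={"displacement": st.u, "rho": st.rho, "c": st.c},
            cell_data={"phi": st.micro.phi, "kappa": st.micro.kappa,
                       "Jp": np.prod(st.micro.lam_p, axis=1)},
        )
        skin = mesh.boundary_faces[mesh.boundary_label == 0]
        write_stl(Path(out_dir) / f"patient_{tag}_skin_week4.stl",
                  mesh.points + st.u, skin)
    return out


def simulate_cohort(patients, fidelity, params, solver_cfg, jobs: int = 1,
                    out_dir=None, write_fields=False):
    """Run healing simulations for a list of patients; failed patients are
    logged and skipped (their ids recorded)."""
    results: list[SimulationOutcome] = []
    failed = []

    def one(ch):
        try:
            return _simulate_one(ch, fidelity, params, solver_cfg, out_dir, write_fields)
        except Exception as exc:  # noqa: BLE001 - per-patient isolation
            log.warning("patient seed=%d (%s) failed: %s", ch.seed, fidelity, exc)
            return exc

    if jobs > 1:
        from joblib import Parallel, delayed

        outs = Parallel(n_jobs=jobs)(delayed(one)(ch) for ch in patients)
    else:
        outs = [one(ch) for ch in patients]
    for ch, o in zip(patients, outs):
        if isinstance(o, SimulationOutcome):
            results.append(o)
        else:
            failed.append({"seed": ch.seed, "fidelity": fidelity, "error": str(o)})
    return results, failed


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.digest(),
        "artifacts": [],
        "failed_patients": [],
    }
    params = config.params()
    solver_cfg = config.solver()

    def record(name):
        manifest["artifacts"].append(str(name))

    # --- stage 1: cohorts ---------------------------------------------------
    low_design = CohortDesign(n_samples=config.n_low, seed=config.seed, fidelity="low")
    high_design = CohortDesign(n_samples=config.n_high, seed=config.seed + 1, fidelity="high")
    pats_low = sample_characteristics(low_design)
    pats_high = sample_characteristics(high_design)
    for name, pats in [("cohort_low.csv", pats_low), ("cohort_high.csv", pats_high)]:
        _atomic_write(out / name, lambda tmp, p=pats: cohort_table(p).to_csv(tmp, index=False))
        record(name)

    # --- stage 2/3: simulations + outcomes ---------------------------------
    outcomes = {}
    for fidelity, pats in [("low", pats_low), ("high", pats_high)]:
        ocs, failed = simulate_cohort(pats, fidelity, params, solver_cfg,
                                      jobs=config.jobs, out_dir=out,
                                      write_fields=config.write_fields)
        if len(ocs) < 2:
            raise RuntimeError(f"{fidelity}-fidelity cohort yielded fewer than 2 outcomes")
        outcomes[fidelity] = ocs
        manifest["failed_patients"].extend(failed)
        name = f"outcomes_{fidelity}.csv"
        _atomic_write(out / name, lambda tmp, o=ocs: outcomes_table(o).to_csv(tmp, index=False))
        record(name)
        traj = pd.DataFrame(
            {o.characteristics.seed: o.contraction for o in ocs},
            index=pd.Index(ocs[0].days, name="day"),
        )
        name = f"contraction_{fidelity}.csv"
        _atomic_write(out / name, lambda tmp, t=traj: t.to_csv(tmp))
        record(name)

    summary = summarize_cohort(outcomes["high"] if len(outcomes["high"]) > 1 else outcomes["low"])
    manifest["cohort_summary"] = {
        "mean_week4_contraction": float(summary.mean_contraction[-1]),
        "mean_min_contraction": float(summary.mean_contraction.min()),
        "min_day": float(summary.days[int(np.argmin(summary.mean_contraction))]),
        "pbsd_bins": summary.pbsd_bins,
    }

    # --- stage 4: surrogates ------------------------------------------------
    try:
        report = gp.validate(outcomes["low"], outcomes["high"],
                             n_repeats=config.n_repeats, seed=config.seed,
                             restarts=config.gp_restarts, n_mc=config.n_mc)
        manifest["validation"] = {
            "mae_bsd_pct": report.mean_mae,
            "rmse_contraction": report.mean_rmse,
            "n_test_predictions": report.n_predictions,
            "n_repeats": report.n_repeats,
            "n_test_per_repeat": report.n_test,
        }
    except ValueError as exc:  # cohort too small after failures
        log.warning("validation skipped: %s", exc)
        manifest["validation"] = {"skipped": str(exc)}
    _atomic_write(out / "validation.json",
                  lambda tmp: Path(tmp).write_text(json.dumps(manifest["validation"], indent=2)))
    record("validation.json")

    # final surrogates on all data
    sc4 = gp.InputScaler()
    Xb_lo, yb_lo = gp.bsd_dataset(outcomes["low"])
    Xb_hi, yb_hi = gp.bsd_dataset(outcomes["high"])
    mf_bsd = gp.MFGPModel().fit(sc4.transform(Xb_lo), yb_lo, sc4.transform(Xb_hi), yb_hi,
                                restarts=config.gp_restarts, seed=config.seed)
    all_out = outcomes["low"] + outcomes["high"]
    clf, clf_sc = gp.fit_visibility_classifier(
        np.vstack([o.characteristics.as_array() for o in all_out]),
        np.array([o.consensus_score for o in all_out]),
        restarts=config.gp_restarts, seed=config.seed,
    )
    # agreement between the quantitative surrogate call (>10 %BSD) and the
    # reviewer-consensus majority
    pred_b, _ = mf_bsd.predict(sc4.transform(Xb_hi), n_mc=config.n_mc, seed=config.seed)
    consensus = np.array([o.consensus_score for o in outcomes["high"]])
    agree = float(np.mean((pred_b > 10.0) == (consensus >= 0.5)) * 100.0)
    manifest["classifier_agreement_pct"] = agree

    # --- stage 5: prediction maps -------------------------------------------
    def bsd_predict(X_raw):
        return mf_bsd.predict(sc4.transform(X_raw), n_mc=config.n_mc, seed=config.seed)

    maps = {}
    for pair in [("cavity_volume", "breast_density"),
                 ("breast_volume", "cavity_volume"),
                 ("cavity_depth", "breast_density"),
                 ("cavity_depth", "cavity_volume")]:
        maps["-".join(pair)] = gp.prediction_maps(bsd_predict, pair, grid_n=config.map_grid)
    for key, m in maps.items():
        df = pd.DataFrame(m["mean"], index=m["axis_1"], columns=m["axis_2"])
        name = f"map_bsd_{key}.csv"
        _atomic_write(out / name, lambda tmp, d=df: d.to_csv(tmp))
        record(name)

    _atomic_write(out / "manifest.json",
                  lambda tmp: Path(tmp).write_text(json.dumps(manifest, indent=2)))
    return manifest
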