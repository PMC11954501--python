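"""Config-driven orchestration: validate inputs, fit every outcome, emit a bundle.

A run is described by a YAML config naming the input CSVs, the outcomes
with their effect scale and benefit direction, node merges, priors, the
MCMC schedule, sensitivity exclusions and a seed. ``run_pipeline`` builds
the per-outcome network, fits the designated models (efficacy: random-
effects primary plus fixed-effect secondary Bayesian NMA; safety:
fixed-effect penalized-likelihood cloglog NMA), derives rankings, league
tables and node-split consistency checks, re-runs sensitivity exclusions,
and writes everything as UTF-8 CSV/JSON plus DOT network diagrams and a
manifest that suffices to relaunch the identical run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import (McmcConfig, Priors, fit_binary_nma, fit_contrast_nma,
                    model_fit, relative_effects)
from .consistency import node_split_all
from .effects import ContrastRecord, loghr_from_hr_ci
from .km import KMCurve, cox_loghr, reconstruct_ipd
from .network import (EvidenceNetwork, TrialArm, build_network, merge_nodes,
                      restrict_to_component, to_dot)
from .plnma import AEArmRecord, fit_pl_cloglog, relative_discrete_hazards
from .ranking import league_table, rankings

logger = logging.getLogger("nmalab")

__all__ = [
    "OutcomeSpec", "RunConfig", "load_config", "validate_inputs", "run_pipeline",
    "read_contrasts", "read_arms", "read_ae_arms", "read_km_curves",
    "contrasts_from_km",
]

EXIT_OK, EXIT_VALIDATION, EXIT_DIAGNOSTICS = 0, 1, 2


@dataclass
class OutcomeSpec:
    """One outcome's analysis settings."""

    name: str
    scale: str            # "log_hr" | "log_or" | "ae"
    direction: str        # "lower_better" | "higher_better"
    data: str             # "contrasts" | "arms" | "ae_arms"
    note: str = ""        # free-text provenance (data cut, assessment method)


@dataclass
class RunConfig:
    inputs: dict[str, str]
    outcomes: list[OutcomeSpec]
    reference: str | None = None
    merges: list[dict] = field(default_factory=list)
    priors: Priors = field(default_factory=Priors)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    sensitivity_exclusions: list[str] = field(default_factory=list)
    output_dir: str = "nma_output"
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    outcomes = [OutcomeSpec(**o) for o in raw.get("outcomes", [])]
    pri = raw.get("priors", {})
    priors = Priors(
        d_sd=float(pri.get("d_sd", 100.0)),
        tau2_lognormal=tuple(pri.get("tau2_lognormal", (-3.95, 1.79))),
    )
    mc = raw.get("mcmc", {})
    mcmc = McmcConfig(
        n_burn=int(mc.get("burn", 60_000)),
        n_sample=int(mc.get("sample", 60_000)),
        n_chains=int(mc.get("chains", 4)),
        seed=int(mc.get("seed", raw.get("seed", 0))),
        thin=int(mc.get("thin", 1)),
    )
    return RunConfig(
        inputs=dict(raw.get("inputs", {})),
        outcomes=outcomes,
        reference=raw.get("reference"),
        merges=list(raw.get("merges", [])),
        priors=priors,
        mcmc=mcmc,
        sensitivity_exclusions=list(raw.get("sensitivity_exclusions", [])),
        output_dir=str(raw.get("output_dir", "nma_output")),
        seed=int(raw.get("seed", 0)),
    )


# ---------------------------------------------------------------------------
# CSV readers (fixed schemas, UTF-8)
# ---------------------------------------------------------------------------

def _has(row, col) -> bool:
    return col in row and pd.notna(row[col])


def read_contrasts(path: str | Path, outcome: str | None = None) -> list[ContrastRecord]:
    """`contrasts.csv`: trial_id, outcome, treatment, baseline_treatment and
    either (hr, ci_low, ci_high) or (log_hr, se) - mixing both groups in one
    row is rejected."""
    df = pd.read_csv(path)
    records = []
    for i, row in df.iterrows():
        if outcome is not None and row["outcome"] != outcome:
            continue
        has_ratio = any(_has(row, c) for c in ("hr", "ci_low", "ci_high"))
        has_log = any(_has(row, c) for c in ("log_hr", "se"))
        if has_ratio and has_log:
            raise ValueError(
                f"{path} row {i}: both hr and log_hr column groups filled (ambiguous)"
            )
        if has_ratio:
            log_effect, se = loghr_from_hr_ci(row["hr"], row["ci_low"], row["ci_high"])
        elif has_log:
            log_effect, se = float(row["log_hr"]), float(row["se"])
        else:
            raise ValueError(f"{path} row {i}: no effect columns filled")
        records.append(ContrastRecord(
            trial_id=str(row["trial_id"]), outcome=str(row["outcome"]),
            treatment=str(row["treatment"]),
            baseline_treatment=str(row["baseline_treatment"]),
            log_effect=log_effect, se=se,
            effect_scale=str(row.get("effect_scale", "log_hr")),
        ))
    return records


def read_arms(path: str | Path, outcome: str | None = None) -> list[TrialArm]:
    """`network.csv` arm-level schema: trial_id, outcome, treatment, n,
    events, follow_up_months."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        if outcome is not None and row["outcome"] != outcome:
            continue
        records.append(TrialArm(
            trial_id=str(row["trial_id"]), treatment=str(row["treatment"]),
            n=int(row["n"]),
            events=int(row["events"]) if _has(row, "events") else None,
            follow_up=float(row["follow_up_months"]) if _has(row, "follow_up_months") else None,
        ))
    return records


def read_ae_arms(path: str | Path, outcome: str | None = None) -> list[AEArmRecord]:
    """`ae_arms.csv`: trial_id, outcome, treatment, events, n, follow_up_months."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        if outcome is not None and row["outcome"] != outcome:
            continue
        records.append(AEArmRecord(
            trial_id=str(row["trial_id"]), treatment=str(row["treatment"]),
            events=int(row["events"]), n=int(row["n"]),
            follow_up=float(row["follow_up_months"]) if _has(row, "follow_up_months") else None,
            outcome=str(row["outcome"]),
        ))
    return records


def read_km_curves(points_path, risk_path, meta_path=None):
    """KM inputs -> {(trial_id, arm): KMCurve}, plus per-trial baseline arm.

    `km_points.csv`: trial_id, arm, time, survival. `km_risk.csv`:
    trial_id, arm, time, n_at_risk. Optional `km_meta.csv`: trial_id, arm,
    total_events, is_baseline.
    """
    pts = pd.read_csv(points_path)
    risk = pd.read_csv(risk_path)
    meta = pd.read_csv(meta_path) if meta_path else None
    curves: dict[tuple[str, str], KMCurve] = {}
    baselines: dict[str, str] = {}
    for (tid, arm), g in pts.groupby(["trial_id", "arm"]):
        g = g.sort_values("time")
        rg = risk[(risk.trial_id == tid) & (risk.arm == arm)].sort_values("time")
        total_events = None
        if meta is not None:
            mg = meta[(meta.trial_id == tid) & (meta.arm == arm)]
            if len(mg):
                if "total_events" in mg and pd.notna(mg.iloc[0].get("total_events")):
                    total_events = int(mg.iloc[0]["total_events"])
                if "is_baseline" in mg and bool(mg.iloc[0].get("is_baseline")):
                    baselines[str(tid)] = str(arm)
        curves[(str(tid), str(arm))] = KMCurve(
            points=list(zip(g.time.astype(float), g.survival.astype(float))),
            risk_table=list(zip(rg.time.astype(float), rg.n_at_risk.astype(int))),
            total_events=total_events,
        )
    return curves, baselines


def contrasts_from_km(curves, baselines, outcome: str = "os") -> list[ContrastRecord]:
    """Reconstruct pseudo-IPD per arm and emit one Cox contrast per trial."""
    by_trial: dict[str, list[str]] = {}
    for tid, arm in curves:
        by_trial.setdefault(tid, []).append(arm)
    out = []
    for tid, arms in sorted(by_trial.items()):
        if len(arms) != 2:
            raise ValueError(f"KM trial {tid!r} must have exactly two arms, got {arms}")
        base = baselines.get(tid, sorted(arms)[0])
        treat = next(a for a in arms if a != base)
        ipd_t = reconstruct_ipd(curves[(tid, treat)])
        ipd_b = reconstruct_ipd(curves[(tid, base)])
        loghr, se = cox_loghr(ipd_t, ipd_b)
        out.append(ContrastRecord(
            trial_id=tid, outcome=outcome, treatment=treat,
            baseline_treatment=base, log_effect=loghr, se=se,
            effect_scale="log_hr",
        ))
    return out


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_inputs(config: RunConfig) -> ValidationReport:
    """Schema and invariant checks across every configured input file.

    Every violation is reported with its file and row number; referential
    integrity (each configured outcome has rows) is checked across files.
    """
    rep = ValidationReport()
    frames: dict[str, pd.DataFrame] = {}
    for key, path in config.inputs.items():
        p = Path(path)
        if not p.exists():
            rep.violations.append(f"{key}: file {path} does not exist")
            continue
        frames[key] = pd.read_csv(p)
    for key in ("arms", "ae_arms"):
        if key not in frames:
            continue
        df = frames[key]
        for i, row in df.iterrows():
            if _has(row, "events") and _has(row, "n") and row["events"] > row["n"]:
                rep.violations.append(
                    f"{key} row {i} (trial {row.get('trial_id')}): events "
                    f"{row['events']} > n {row['n']}"
                )
            if _has(row, "n") and row["n"] < 1:
                rep.violations.append(f"{key} row {i}: n < 1")
            if _has(row, "follow_up_months") and row["follow_up_months"] <= 0:
                rep.violations.append(f"{key} row {i}: follow_up_months <= 0")
    if "contrasts" in frames:
        df = frames["contrasts"]
        for i, row in df.iterrows():
            has_ratio = any(_has(row, c) for c in ("hr", "ci_low", "ci_high"))
            has_log = any(_has(row, c) for c in ("log_hr", "se"))
            if has_ratio and has_log:
                rep.violations.append(
                    f"contrasts row {i} (trial {row.get('trial_id')}): both hr "
                    "and log_hr column groups filled (ambiguous)"
                )
            if not has_ratio and not has_log:
                rep.violations.append(f"contrasts row {i}: no effect columns filled")
            if _has(row, "se") and row["se"] <= 0:
                rep.violations.append(f"contrasts row {i}: se <= 0")
    for spec in config.outcomes:
        key = spec.data
        if key not in frames:
            rep.violations.append(f"outcome {spec.name}: input {key!r} not configured")
            continue
        if "outcome" in frames[key] and spec.name not in set(frames[key]["outcome"]):
            rep.violations.append(f"outcome {spec.name}: no rows in {key}")
        if spec.direction not in ("lower_better", "higher_better"):
            rep.violations.append(f"outcome {spec.name}: direction undeclared")
    for v in rep.violations:
        logger.warning("validation: %s", v)
    return rep


# ---------------------------------------------------------------------------
# Run
# ---------------------------------------------------------------------------

def _apply_merges(net: EvidenceNetwork, merges: list[dict]) -> EvidenceNetwork:
    merge_map = {}
    for block in merges:
        for src in block.get("from", []):
            merge_map[src] = block["to"]
    merge_map = {k: v for k, v in merge_map.items()
                 if k in net.treatments and k != v}
    return merge_nodes(net, merge_map) if merge_map else net


def _posterior_outputs(post, direction, outdir: Path, prefix: str, seed: int):
    post.summaries.join(post.diagnostics, how="left").to_csv(
        outdir / f"{prefix}_posterior_summary.csv")
    resdev, pd_, dic = model_fit(post)
    (outdir / f"{prefix}_fit.json").write_text(json.dumps({
        "resdev": resdev, "pd": pd_, "dic": dic,
        "n_datapoints": post.fit["n_datapoints"],
        "converged": post.converged,
    }, indent=2))
    rk = rankings(post, direction, seed=seed)
    rk.to_frame().to_csv(outdir / f"{prefix}_rankings.csv", index=False)
    table, sig = league_table(post, direction, seed=seed)
    table.to_csv(outdir / f"{prefix}_league.csv")
    sig.to_csv(outdir / f"{prefix}_league_significant.csv")
    relative_effects(post).to_csv(outdir / f"{prefix}_relative_effects.csv", index=False)
    return rk


def _analyse_outcome(spec: OutcomeSpec, records, config: RunConfig, outdir: Path,
                     tag: str = "") -> dict:
    """Fit one outcome (all designated models) and write its outputs."""
    prefix = spec.name + (f"_{tag}" if tag else "")
    reference = config.reference
    if reference is None:
        treatments = sorted({r.treatment for r in records} |
                            {getattr(r, "baseline_treatment", None) for r in records} - {None})
        reference = treatments[0]
    net = build_network(records, outcome=spec.name, reference=reference)
    net = _apply_merges(net, config.merges)
    net = restrict_to_component(net)
    recs = [r for r in records if r.trial_id in net.trials]
    (outdir / f"{prefix}_network.dot").write_text(to_dot(net))
    entry: dict = {"outcome": spec.name, "tag": tag, "n_trials": net.n_trials,
                   "n_treatments": net.n_treatments, "reference": net.reference,
                   "status": "ok"}
    if spec.scale == "ae":
        fit = fit_pl_cloglog(net, recs, penalty="firth")
        fit.summary().to_csv(outdir / f"{prefix}_pl_summary.csv", index=False)
        relative_discrete_hazards(fit).to_csv(
            outdir / f"{prefix}_league.csv", index=False)
        entry["converged"] = fit.converged
        entry["warnings"] = fit.warnings
        if not fit.converged:
            entry["status"] = "failed-diagnostics"
        return entry
    fitter = fit_contrast_nma if spec.data == "contrasts" else fit_binary_nma
    results = {}
    for model in ("random", "fixed"):
        post = fitter(net, recs, model=model, priors=config.priors, mcmc=config.mcmc)
        rk = _posterior_outputs(post, spec.direction, outdir,
                                f"{prefix}_{model}", config.seed)
        results[model] = post
        entry[f"{model}_converged"] = post.converged
        entry[f"{model}_dic"] = post.fit["dic"]
        if not post.converged:
            entry["status"] = "failed-diagnostics"
        if model == "random":
            order = np.argsort(-rk.sucra)
            entry["top_ranked"] = rk.treatments[int(order[0])]
    cons = node_split_all(net, recs, model="random", priors=config.priors,
                          mcmc=config.mcmc)
    cons.to_csv(outdir / f"{prefix}_consistency.csv", index=False)
    entry["n_splittable"] = int(cons["splittable"].sum()) if len(cons) else 0
    return entry


def _load_records(spec: OutcomeSpec, config: RunConfig):
    readers = {"contrasts": read_contrasts, "arms": read_arms, "ae_arms": read_ae_arms}
    path = config.inputs[spec.data]
    return readers[spec.data](path, outcome=spec.name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full configured analysis; returns the manifest.

    The manifest records inputs, settings, package version, seeds, per-
    outcome status (including "failed-diagnostics" when MCMC gates fail)
    and every warning surfaced during the run, and is written alongside
    the outputs as ``manifest.json``.
    """
    if not config.outcomes:
        raise ValueError("config lists no outcomes")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": config.inputs,
        "priors": asdict(config.priors),
        "mcmc": asdict(config.mcmc),
        "merges": config.merges,
        "sensitivity_exclusions": config.sensitivity_exclusions,
        "outcomes": [],
    }
    try:
        report = validate_inputs(config)
        if not report.ok:
            manifest["validation"] = report.violations
            manifest["status"] = "validation-failed"
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            return manifest
        status = "ok"
        for spec in config.outcomes:
            records = _load_records(spec, config)
            entry = _analyse_outcome(spec, records, config, outdir)
            manifest["outcomes"].append(entry)
            if entry["status"] != "ok":
                status = "failed-diagnostics"
            excl = [t for t in config.sensitivity_exclusions
                    if any(r.trial_id == t for r in records)]
            for trial in excl:
                sub = [r for r in records if r.trial_id != trial]
                sens = _analyse_outcome(spec, sub, config, outdir,
                                        tag=f"without_{trial}")
                sens["excluded_trial"] = trial
                manifest["outcomes"].append(sens)
                if sens["status"] != "ok":
                    status = "failed-diagnostics"
        manifest["status"] = status
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return manifest
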