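"""End-to-end pipeline orchestration from a single config.

``run_pipeline`` drives simulate -> ISC -> extremes -> mixed models ->
content units and writes every stage's output (tidy TSV tables, JSON
bundles) into one run directory, together with a manifest recording
parameters, seeds, and artifact hashes.  Deterministic stages reproduce
bit-for-bit under the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cu as cu_mod
from . import extremes as ex
from . import isc as isc_mod
from . import stats as st
from . import synthdata as sd

__all__ = ["RunConfig", "run_pipeline", "write_report"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run; every seed explicit."""

    out_dir: str = "results/run"
    template: str = "small"
    seed: int = 0
    fraction: float = 0.10
    z_threshold: float = 1.0
    null_iters: int = 10_000
    min_participants: int = 3
    onset_exclusion_s: float = 6.0
    models: tuple = ("condition", "per_condition", "per_froi", "interaction")
    cu_metric: str = "mean_cu"
    cu_scope: str = "all"  # "all" or "+M" (meaningful stimuli only)
    with_rest: bool = True
    with_cu: bool = True
    with_extremes: bool = True
    n_text_participants: int = 20
    n_subclips: int = 10

    def __post_init__(self):
        for name in ("fraction", "z_threshold", "null_iters", "min_participants"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.onset_exclusion_s < 0:
            raise ValueError("onset_exclusion_s must be non-negative")
        self.models = tuple(self.models)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["models"] = list(d["models"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_fit(fit: st.LMEFit, path: Path) -> None:
    fit.terms.to_csv(path.with_suffix(".tsv"), sep="\t", index=False)
    meta = {
        "formula_id": fit.formula_id,
        "formula": fit.formula,
        "reference_level": fit.reference_level,
        "loglik": fit.loglik,
        "aic": fit.aic,
        "n_params": fit.n_params,
        "nobs": fit.nobs,
        "fit_method": fit.fit_method,
        "converged": fit.converged,
        "singular": fit.singular,
        "vc_estimates": {k: float(v) for k, v in fit.vc_estimates.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": dataclasses.asdict(config) | {"models": list(config.models)}}

    # 1. simulate
    design = sd.make_design(config.template, seed=config.seed)
    design.to_json(out / "design.json")
    tcs = sd.simulate_timecourses(design)
    tcs.onset_exclusion_s = config.onset_exclusion_s
    tcs.to_tsv(out / "timecourses.tsv")

    # 2. ISC
    pre = isc_mod.preprocess(tcs)
    isc = isc_mod.compute_isc_table(pre)
    isc.to_csv(out / "isc.tsv", sep="\t", index=False)
    log["mean_isc_by_type"] = {
        k: float(v) for k, v in isc_mod.mean_isc_by_type(isc, "r").items()
    }

    if config.with_rest:
        rest = sd.simulate_rest(design=design, seed=config.seed)
        rest_isc = isc_mod.compute_isc_table(isc_mod.preprocess(rest))
        rest_isc.to_csv(out / "isc_rest.tsv", sep="\t", index=False)
        t, df, p = isc_mod.rest_baseline_test(rest_isc)
        log["rest_baseline"] = {"t": t, "df": df, "p": p}

    # 3. extremes (the meaningful-nonverbal conditions, as in the source design)
    if config.with_extremes:
        conds = [c.name for c in design.conditions if c.condition_type == "+M/-L"]
        ex_rows = []
        for c in conds:
            peaks = ex.detect_extremes(pre, c, "peak", config.z_threshold)
            m = len(peaks.indices)
            if m == 0 or pre.n_timepoints(c) - m < 4:
                continue
            null = ex.random_removal_null(
                pre, c, m, n_iter=config.null_iters, seed=config.seed
            )
            peak_mean = ex.removed_mean_isc(pre, c, peaks.indices)
            troughs = ex.matched_trough_indices(pre, c, m)
            trough_mean = ex.removed_mean_isc(pre, c, troughs)
            ex_rows.append(
                {
                    "condition": c,
                    "m_removed": m,
                    "peak_removed_mean_z": peak_mean,
                    "trough_removed_mean_z": trough_mean,
                    "null_p_peak": null.p_value(peak_mean),
                    "null_p_trough": null.p_value(trough_mean),
                    **{f"null_q{int(q*1000)}": v for q, v in null.quantiles().items()},
                }
            )
        pd.DataFrame(ex_rows).to_csv(out / "extremes.tsv", sep="\t", index=False)
        if conds:
            pvt = ex.peak_vs_trough_suite(pre, conds, config.z_threshold)
            pvt.to_csv(out / "peak_vs_trough.tsv", sep="\t", index=False)

    # 4. mixed models
    (out / "models").mkdir(exist_ok=True)
    if "condition" in config.models:
        _write_fit(st.fit_condition_model(isc), out / "models" / "condition")
    if "per_condition" in config.models:
        _, summary = st.per_condition_suite(isc)
        summary.to_csv(out / "models" / "per_condition.tsv", sep="\t", index=False)
    if "per_froi" in config.models:
        fits = st.fit_per_froi_model(isc)
        pd.concat([f.to_frame() for f in fits.values()], ignore_index=True).to_csv(
            out / "models" / "per_froi.tsv", sep="\t", index=False
        )
    if "interaction" in config.models:
        _write_fit(st.fit_interaction_model(isc), out / "models" / "interaction")

    # 5. content units
    if config.with_cu:
        corpus = sd.simulate_corpus(
            design,
            n_participants=config.n_text_participants,
            n_subclips=config.n_subclips,
            seed=config.seed,
        )
        corpus.to_json(out / "corpus.json")
        cu_table = cu_mod.score_corpus(corpus, min_participants=config.min_participants)
        cu_table.counts.to_csv(out / "cu_counts.tsv", sep="\t", index=False)
        cu_fit = cu_mod.cu_condition_model(cu_table, design.condition_types())
        _write_fit(cu_fit, out / "models" / "cu_condition")
        scope = (
            [c.name for c in design.conditions if c.condition_type.startswith("+M")]
            if config.cu_scope == "+M"
            else [c.name for c in design.conditions]
        )
        assoc = cu_mod.cu_isc_association(cu_table, isc, metric=config.cu_metric, scope=scope)
        assoc_out = {k: v for k, v in assoc.items() if k != "fits"}
        if assoc_out.get("cu_beta_in_joint_model") is not None:
            assoc_out["cu_beta_in_joint_model"] = list(assoc_out["cu_beta_in_joint_model"])
        (out / "cu_association.json").write_text(json.dumps(assoc_out, indent=1))
        log["cu_association"] = {
            "pearson_r": assoc["pearson_r"], "p": assoc["p"], "n_stimuli": assoc["n_stimuli"]
        }

    config.to_yaml(out / "config.yaml")
    log["artifacts"] = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(log, indent=1))
    write_report(out)
    return out


def write_report(run_dir) -> Path:
    """Assemble a human-readable summary of a finished (or partial) run."""
    run_dir = Path(run_dir)
    lines = ["# Pipeline report", ""]

    isc_path = run_dir / "isc.tsv"
    if isc_path.exists():
        isc = pd.read_csv(isc_path, sep="\t")
        lines.append("## Mean ISC by condition type")
        by_type = isc.groupby("condition_type")[["r", "z"]].mean()
        lines.append(by_type.to_string(float_format="%.4f"))
        lines.append("")
        lines.append("## Mean ISC by fROI")
        lines.append(isc.groupby("froi")[["r", "z"]].mean().to_string(float_format="%.4f"))
        lines.append("")
    else:
        lines.append("ISC table: ABSENT\n")

    rest = run_dir / "isc_rest.tsv"
    manifest = run_dir / "manifest.json"
    if manifest.exists():
        log = json.loads(manifest.read_text())
        if "rest_baseline" in log:
            rb = log["rest_baseline"]
            lines.append(
                f"Rest baseline (one-tailed vs 0): t({rb['df']}) = {rb['t']:.3f}, "
                f"p = {rb['p']:.3f}"
            )
            lines.append("")
    elif not rest.exists():
        lines.append("Rest baseline: ABSENT\n")

    for name, title in [
        ("extremes.tsv", "Peak/trough removal vs random-removal null"),
        ("peak_vs_trough.tsv", "Peak- vs trough-removed two-sample tests"),
    ]:
        p = run_dir / name
        lines.append(f"## {title}")
        if p.exists() and p.stat().st_size > 1:
            df = pd.read_csv(p, sep="\t")
            lines.append(df.to_string(index=False, float_format="%.4f") if len(df) else "(empty)")
        else:
            lines.append("ABSENT")
        lines.append("")

    models_dir = run_dir / "models"
    if models_dir.exists():
        for tsv in sorted(models_dir.glob("*.tsv")):
            lines.append(f"## Model: {tsv.stem}")
            lines.append(pd.read_csv(tsv, sep="\t").to_string(index=False, float_format="%.4f"))
            lines.append("")

    assoc = run_dir / "cu_association.json"
    if assoc.exists():
        a = json.loads(assoc.read_text())
        lines.append("## CU-ISC association")
        lrt = a.get("lrt_add_cu")
        lrt_txt = (
            f"LRT add-CU chi2 = {lrt['chi2']:.2f} (p = {lrt['p']:.3f})"
            if lrt
            else f"LRT add-CU: {a.get('joint_model_note', 'not available')}"
        )
        lines.append(
            f"metric = {a['metric']}, r = {a['pearson_r']:.3f} (p = {a['p']:.3f}, "
            f"n = {a['n_stimuli']} stimuli); {lrt_txt}; "
            f"delta-AIC CU-only = {a['delta_aic_cu_only']:.2f}"
        )
        lines.append("")

    report = run_dir / "report.md"
    report.write_text("\n".join(lines))
    return report
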