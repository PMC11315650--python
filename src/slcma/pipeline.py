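"""End-to-end orchestration: simulate -> encode -> impute -> select -> infer
-> report, with a provenance manifest.

Every run writes its outputs (cohort CSV, design matrix, selection path,
elbow plot, estimate tables, descriptive tables, age-crime curve) into one
output directory together with ``manifest.json`` recording configuration,
seeds, package versions and the participant counts at each filtering stage
(eligible alive-at-10 -> valid crime data -> complete case).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .descriptives import age_crime_curve, crosstab, derive_outcomes, offence_summary, poverty_continuity
from .encoding import COVARIATE_NAMES, PovertyDefinition
from .impute import ImputationSpec, completeness_report, mice_impute
from .inference import estimates_to_frame, stacked_bootstrap
from .model import SLCMA
from .simulate import (
    SimulationParams,
    apply_missingness,
    read_cohort,
    read_offences,
    simulate_cohort,
    simulate_offences,
    write_cohort,
    write_offences,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("slcma")

OUTCOMES = ("violent_any", "homicide_any", "fight_any", "violent_after22")


@dataclass
class PipelineConfig:
    """One pipeline run: exactly one input source (file or simulation)."""

    output_dir: str = "slcma_output"
    cohort_csv: str | None = None
    offences_csv: str | None = None
    simulation: SimulationParams | None = None
    poverty: PovertyDefinition = field(default_factory=PovertyDefinition)
    sensitivity_definitions: list = field(default_factory=list)
    outcome: str = "violent_any"
    adjusted: bool = True
    include_mobility: bool = True
    m: int = 20
    n_iterations: int = 10
    B: int = 1000
    tau: float = 0.05
    n_penalties: int = 100
    seed: int = 0
    run_imputation: bool = True

    def __post_init__(self) -> None:
        if (self.cohort_csv is None) == (self.simulation is None):
            raise ValueError("configure exactly one input source: cohort_csv or simulation")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            sim = raw["simulation"]
            if isinstance(sim, dict):
                for tup in ("income_log_mean", "income_log_sd", "beta_age"):
                    if tup in sim:
                        sim[tup] = tuple(sim[tup])
                if "latent_corr" in sim:
                    sim["latent_corr"] = tuple(tuple(r) for r in sim["latent_corr"])
                raw["simulation"] = SimulationParams(**sim)
        if "poverty" in raw and isinstance(raw["poverty"], dict):
            raw["poverty"] = PovertyDefinition(**raw["poverty"])
        raw["sensitivity_definitions"] = [
            PovertyDefinition(**d) if isinstance(d, dict) else d
            for d in raw.get("sensitivity_definitions", [])
        ]
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _write(df: pd.DataFrame, path: Path, created: list) -> None:
    df.to_csv(path, index=False)
    created.append(path)


def _fit_and_estimate(table, cfg: PipelineConfig, definition, outdir: Path, created: list, tag: str) -> dict:
    """Complete-case SLCMA fit + (optionally) MICE/stacked bootstrap for one
    poverty definition. Returns the manifest fragment."""
    info: dict = {"poverty": dataclasses.asdict(definition)}

    events = int(table[cfg.outcome].fillna(0).sum())
    info["events"] = events
    if events == 0:
        log.warning("no events for outcome %s under definition %s; skipping estimation", cfg.outcome, tag)
        info["status"] = "no_events"
        return info

    model = SLCMA.from_cohort(
        table, poverty=definition, outcome=cfg.outcome,
        adjusted=cfg.adjusted, include_mobility=cfg.include_mobility,
    )
    res = model.fit(tau=cfg.tau, n_penalties=cfg.n_penalties)
    info["entry_order"] = list(res.path.entry_order)
    info["k_selected"] = res.k_selected_
    info["selected"] = res.selected_
    info["hypothesis"] = res.hypothesis_

    _write(res.path.to_frame(), outdir / f"path_{tag}.csv", created)
    _write(res.elbow.plot_data(), outdir / f"elbow_{tag}.csv", created)
    ax = res.plot_elbow()
    fig = ax.get_figure()
    fig.savefig(outdir / f"elbow_{tag}.png", dpi=150, bbox_inches="tight")
    created.append(outdir / f"elbow_{tag}.png")
    import matplotlib.pyplot as plt

    plt.close(fig)

    frames = []
    if res.estimates:
        frames.append(res.estimates_.assign(inference="naive_wald"))
        frames.append(estimates_to_frame(res.bonferroni()).assign(inference="bonferroni"))
        try:
            frames.append(
                estimates_to_frame(res.selective_inference()).assign(inference="selective")
            )
        except Exception as exc:  # numerically empty truncation regions are reported, not fatal
            log.warning("selective inference failed: %s", exc)
            info["selective_error"] = str(exc)

    if cfg.run_imputation and res.selected_:
        spec = ImputationSpec(m=cfg.m, n_iterations=cfg.n_iterations, seed=cfg.seed + 1)
        imputed = mice_impute(table[table[cfg.outcome].notna()].reset_index(drop=True), spec)
        boot = stacked_bootstrap(
            stacked_design_tables(imputed, definition, cfg),
            outcome=cfg.outcome,
            variables=res.selected_,
            covariates=list(COVARIATE_NAMES) if cfg.adjusted else None,
            B=cfg.B,
            seed=cfg.seed + 2,
        )
        frames.append(estimates_to_frame(boot).assign(inference="stacked_bootstrap"))
        info["imputations"] = cfg.m

    if frames:
        est = pd.concat(frames).reset_index()
        _write(est, outdir / f"estimates_{tag}.csv", created)
    info["status"] = "ok"
    return info


def stacked_design_tables(imputed, definition, cfg: PipelineConfig) -> list:
    """Encode every imputed table so candidate columns exist for the stacked
    bootstrap (complete data after imputation: encoding is total)."""
    from .encoding import build_design

    out = []
    for t in imputed:
        d = build_design(t, definition, include_mobility=cfg.include_mobility)
        out.append(d.reset_index(drop=True))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and return the manifest dict (also written to
    ``manifest.json``). Partial outputs are removed if the run fails."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    try:
        return _run(config, outdir, created)
    except Exception:
        for p in created:
            try:
                p.unlink()
            except OSError:
                pass
        raise


def _run(config: PipelineConfig, outdir: Path, created: list) -> dict:
    manifest: dict = {
        "config": json.loads(json.dumps(config.to_dict(), default=str)),
        "versions": {
            "slcma": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
    }

    if config.simulation is not None:
        params = dataclasses.replace(config.simulation, seed=config.seed or config.simulation.seed)
        table = simulate_cohort(params)
        offences = simulate_offences(table, params)
        table = derive_outcomes(offences, table)
        table = apply_missingness(table, params)
        write_cohort(table, outdir / "cohort.csv", params)
        created += [outdir / "cohort.csv", outdir / "cohort.params.json"]
        write_offences(offences, outdir / "offences.csv")
        created.append(outdir / "offences.csv")
    else:
        table = read_cohort(config.cohort_csv)
        offences = read_offences(config.offences_csv) if config.offences_csv else pd.DataFrame()
        _validate_schema(table)

    # filtering stages (flow-diagram style)
    report = completeness_report(table)
    manifest["stages"] = {
        "total_n": report["n"],
        "eligible_alive_at_10": report["eligible_n"],
        "valid_crime_data": report["valid_crime_n"],
        "complete_case": report["complete_case_n"],
    }
    analysis = table[table["alive_at_10"].fillna(0).astype(bool)].reset_index(drop=True)

    # descriptives
    if len(offences):
        curve = age_crime_curve(offences)
        _write(curve.data.reset_index(), outdir / "age_crime_curve.csv", created)
        _write(offence_summary(offences, "homicide"), outdir / "offence_summary.csv", created)
    cont = poverty_continuity(analysis, config.poverty)
    _write(cont, outdir / "poverty_continuity.csv", created)

    from .encoding import build_design

    design = build_design(analysis, config.poverty, include_mobility=config.include_mobility)
    _write(design, outdir / "design.csv", created)

    definitions = [("main", config.poverty)] + [
        (f"sensitivity_{i}", d) for i, d in enumerate(config.sensitivity_definitions)
    ]
    manifest["analyses"] = {}
    for tag, definition in definitions:
        manifest["analyses"][tag] = _fit_and_estimate(analysis, config, definition, outdir, created, tag)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    created.append(outdir / "manifest.json")
    return manifest


def _validate_schema(table: pd.DataFrame) -> None:
    from .simulate import COHORT_COLUMNS

    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing required columns: {missing}")
    for col in ("sex", "maternal_educ_low", "maternal_age_young", "violent_any", "homicide_any"):
        bad = table.index[~table[col].isin([0, 1]) & table[col].notna()]
        if len(bad):
            raise ValueError(f"column {col} is not binary at rows {list(bad[:5])}")
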