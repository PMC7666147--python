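"""Configuration and end-to-end pipeline orchestration.

Two pipeline modes keep the deterministic reproduction surface separate
from the stochastic recovery surface:

* ``reported-rates`` plugs the study's measured vital rates straight into
  the scenario engine — no randomness, seed-independent output;
* ``estimate-from-synthetic`` generates a synthetic study bundle, estimates
  vital rates from the tables, rebuilds the scenario set from those
  estimates and then runs both the deterministic and stochastic engines.

A run produces a :class:`ReportBundle` (estimates, scenario table, bout
sweep, provenance metadata) written as CSV files plus a JSON summary whose
config hash ties every artifact to the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .matrix_model import VitalRates
from .scenarios import (
    Scenario,
    study_scenarios,
    scenarios_from_records,
    scenarios_to_records,
    run_scenarios,
    report_table,
    worst_case_discrepancy,
)
from .stochastic_env import bout_probability_sweep
from .synthetic_data import gen_study_bundle
from .assay_stats import estimates_table, estimate_fecundity, estimate_survival

log = logging.getLogger("midgepop")

__all__ = ["RunConfig", "ReportBundle", "load_config", "run_pipeline", "write_report"]

_KNOWN_KEYS = {
    "seed", "scenarios", "control", "multiplier", "outdir", "rounding", "stochastic",
}
_KNOWN_STOCHASTIC_KEYS = {
    "p_grid", "normal", "stressed", "steps", "burn_in", "autocorrelation",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration with defaults filled in."""

    seed: int = 0
    scenarios: tuple[Scenario, ...] = ()
    control: str = "control"
    multiplier: int = 1
    outdir: str = "results"
    rounding: bool = True
    stochastic: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1")

    def scenario_list(self) -> list[Scenario]:
        return list(self.scenarios) if self.scenarios else study_scenarios()

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "scenarios": scenarios_to_records(self.scenario_list()),
            "control": self.control,
            "multiplier": self.multiplier,
            "outdir": self.outdir,
            "rounding": self.rounding,
            "stochastic": dict(self.stochastic),
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass(frozen=True)
class ReportBundle:
    estimates: pd.DataFrame
    scenario_table: pd.DataFrame
    sweep: pd.DataFrame
    metadata: dict


def _config_from_mapping(raw: dict) -> RunConfig:
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    stoch = raw.get("stochastic") or {}
    bad = set(stoch) - _KNOWN_STOCHASTIC_KEYS
    if bad:
        raise ValueError(f"unknown stochastic config keys: {sorted(bad)}")
    scen = tuple(scenarios_from_records(raw["scenarios"])) if "scenarios" in raw else ()
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        scenarios=scen,
        control=str(raw.get("control", "control")),
        multiplier=int(raw.get("multiplier", 1)),
        outdir=str(raw.get("outdir", "results")),
        rounding=bool(raw.get("rounding", True)),
        stochastic=dict(stoch),
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration.

    Unknown keys are rejected by name; missing keys get defaults (an absent
    ``scenarios`` block loads the built-in study scenario set).
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return _config_from_mapping(raw)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def _estimated_scenarios(bundle) -> list[Scenario]:
    """Rebuild the seven study scenarios from synthetic-table estimates."""
    fec = {
        tr: estimate_fecundity(bundle.fecundity, tr).mean
        for tr in ("control", "male_dehydration", "female_dehydration", "both_dehydration")
    }
    surv = {
        tr: estimate_survival(bundle.survival, tr).pooled_p
        for tr in ("egg_control", "larva_control", "egg_thermal", "larva_no_gel")
    }
    s_e, s_l = surv["egg_control"], surv["larva_control"]
    mk = VitalRates
    return [
        Scenario("control", mk(fec["control"], s_e, s_l)),
        Scenario("male_dehydration", mk(fec["male_dehydration"], s_e, s_l)),
        Scenario("female_dehydration", mk(fec["female_dehydration"], s_e, s_l)),
        Scenario("both_dehydration", mk(fec["both_dehydration"], s_e, s_l)),
        Scenario("no_gel", mk(fec["control"], s_e, surv["larva_no_gel"])),
        Scenario("thermal_stress", mk(fec["control"], surv["egg_thermal"], s_l)),
        Scenario("worst_case",
                 mk(fec["both_dehydration"], surv["egg_thermal"], surv["larva_no_gel"])),
    ]


def _sweep_from_config(cfg: RunConfig, scenarios: list[Scenario]) -> pd.DataFrame:
    by_name = {s.name: s for s in scenarios}
    stoch = cfg.stochastic
    normal = by_name[stoch.get("normal", cfg.control)].vital_rates
    stressed_name = stoch.get("stressed", "both_dehydration")
    if stressed_name not in by_name:
        stressed_name = scenarios[-1].name
    stressed = by_name[stressed_name].vital_rates
    p_grid = stoch.get("p_grid", [i / 10 for i in range(11)])
    return bout_probability_sweep(normal, stressed, p_grid)


def run_pipeline(cfg: RunConfig, mode: str = "reported-rates") -> ReportBundle:
    """Run the full analysis pipeline in the given mode.

    Returns a ReportBundle; in ``reported-rates`` mode the output is fully
    deterministic and independent of the seed.
    """
    if mode not in ("reported-rates", "estimate-from-synthetic"):
        raise ValueError(f"unknown mode {mode!r}")

    log.info("pipeline mode=%s seed=%d", mode, cfg.seed)

    if mode == "reported-rates":
        scenarios = cfg.scenario_list()
        rows = []
        for s in scenarios:
            vr = s.vital_rates
            rows.append((s.name, "fecundity_mean", vr.fecundity, 0.0, 0))
            rows.append((s.name, "egg_survival", vr.egg_survival, 0.0, 0))
            rows.append((s.name, "larval_survival", vr.larval_survival, 0.0, 0))
        estimates = pd.DataFrame(
            rows, columns=["treatment", "quantity", "estimate", "se", "n"]
        )
    else:
        log.info("generating synthetic study bundle (multiplier=%d)", cfg.multiplier)
        bundle = gen_study_bundle(cfg.seed, multiplier=cfg.multiplier)
        estimates = estimates_table(bundle)
        try:
            scenarios = _estimated_scenarios(bundle)
        except ValueError as e:
            raise RuntimeError(f"vital-rate estimation failed: {e}") from e

    log.info("running %d deterministic scenarios", len(scenarios))
    results = run_scenarios(scenarios, control_name=cfg.control)
    scen_table, scen_meta = report_table(results, rounding=cfg.rounding)

    log.info("running bout-probability sweep")
    sweep = _sweep_from_config(cfg, scenarios)

    metadata = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "mode": mode,
        "package_version": __version__,
        "scenario_metadata": scen_meta,
        "worst_case_discrepancy": worst_case_discrepancy()
        if {s.name for s in scenarios} >= {"worst_case", "control"}
        else None,
    }
    return ReportBundle(
        estimates=estimates, scenario_table=scen_table, sweep=sweep, metadata=metadata
    )


def write_report(bundle: ReportBundle, outdir, force: bool = False) -> list[str]:
    """Write the bundle as estimates.csv, scenarios.csv, sweep.csv, summary.json.

    Refuses to overwrite an existing report unless ``force``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = ["estimates.csv", "scenarios.csv", "sweep.csv", "summary.json"]
    existing = [n for n in names if (outdir / n).exists()]
    if existing and not force:
        raise FileExistsError(
            f"report files already exist in {outdir}: {existing}; use force=True"
        )
    written = []
    for name, df in (
        ("estimates.csv", bundle.estimates),
        ("scenarios.csv", bundle.scenario_table),
        ("sweep.csv", bundle.sweep),
    ):
        p = outdir / name
        df.to_csv(p, index=False)
        log.info("wrote %s", p)
        written.append(str(p))
    p = outdir / "summary.json"
    p.write_text(json.dumps(bundle.metadata, indent=2, default=str))
    log.info("wrote %s", p)
    written.append(str(p))
    return written
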