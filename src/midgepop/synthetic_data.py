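"""Synthetic assay tables with the replicate structure of the midge study.

Three kinds of raw records feed the downstream vital-rate estimation:

* fecundity: per-mating-pair counts of eggs laid and viable eggs
  (6-8 pairs per treatment in the original assays);
* survival: per-replicate (alive, total) counts for eggs or larvae
  (e.g. four replicates of 25 larvae);
* thermal profiles: paired per-minute temperature series inside and
  outside the egg-mass gel over several days.

Egg counts are drawn from a negative binomial (clutch counts are
overdispersed relative to Poisson; a Poisson option exists), survival from
a binomial per replicate, and temperature from a diurnal sinusoid plus
Gaussian noise whose amplitude is damped inside the gel.  Every generator
is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "ThermalProfile",
    "StudyBundle",
    "gen_fecundity_counts",
    "gen_survival_replicates",
    "gen_thermal_profile",
    "gen_study_bundle",
    "FECUNDITY_TREATMENTS",
    "SURVIVAL_TREATMENTS",
]

FECUNDITY_COLUMNS = ["pair_id", "treatment", "eggs_laid", "viable_eggs"]
SURVIVAL_COLUMNS = ["replicate_id", "treatment", "n_start", "n_alive"]
THERMAL_COLUMNS = ["time_min", "temp_inside", "temp_outside"]

#: mean eggs laid per female by treatment, with pairs per treatment and the
#: egg viability applied to each clutch (control egg survival).
FECUNDITY_TREATMENTS: dict[str, dict] = {
    "control": {"mean": 42.9, "n_pairs": 8, "viability": 0.82},
    "male_dehydration": {"mean": 34.6, "n_pairs": 8, "viability": 0.82},
    "female_dehydration": {"mean": 35.6, "n_pairs": 8, "viability": 0.82},
    "both_dehydration": {"mean": 21.5, "n_pairs": 8, "viability": 0.82},
}

#: survival/viability proportions by treatment with replicate layout.
#: Larval assays: four replicates of 25 individuals; egg assays: three
#: replicate clutches of ~40 eggs (one egg mass holds 40-50 eggs).
SURVIVAL_TREATMENTS: dict[str, dict] = {
    "egg_control": {"p": 0.82, "n_replicates": 3, "unit_size": 40},
    "larva_control": {"p": 0.78, "n_replicates": 4, "unit_size": 25},
    "egg_thermal": {"p": 0.63, "n_replicates": 3, "unit_size": 40},
    "larva_no_gel": {"p": 0.5, "n_replicates": 4, "unit_size": 25},
    "egg_gel_dehydrated": {"p": 0.81, "n_replicates": 3, "unit_size": 40},
    "egg_no_gel_dehydrated": {"p": 0.0, "n_replicates": 3, "unit_size": 40},
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters for one synthetic treatment group.

    ``mean_or_p`` is a mean count for fecundity draws and a success
    probability for survival draws.  ``dispersion`` is the negative-binomial
    size parameter k (variance = m + m^2/k), so larger k is closer to
    Poisson; it is a modelling choice, not a measured quantity.
    """

    treatment_name: str
    n_units: int
    mean_or_p: float
    unit_size: int = 25
    dispersion: float = 10.0
    seed: int = 0
    count_family: str = "negative_binomial"  # or "poisson"

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.unit_size < 1:
            raise ValueError("unit_size must be >= 1")
        if self.mean_or_p < 0:
            raise ValueError("mean_or_p must be nonnegative")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.count_family not in ("negative_binomial", "poisson"):
            raise ValueError(f"unknown count_family {self.count_family!r}")


@dataclass(frozen=True)
class ThermalProfile:
    """Paired temperature series inside and outside the egg-mass gel.

    ``data`` holds columns ``time_min, temp_inside, temp_outside`` at a
    fixed sampling interval; ``damping`` is the fraction of the outside
    diurnal amplitude transmitted through the gel.
    """

    data: pd.DataFrame
    sampling_interval: float  # minutes
    duration_days: float
    label: str = "profile"

    def __post_init__(self) -> None:
        t = self.data["time_min"].to_numpy()
        if len(t) < 2:
            raise ValueError("thermal profile needs at least two samples")
        dt = np.diff(t)
        if not (dt > 0).all() or not np.allclose(dt, self.sampling_interval):
            raise ValueError("timestamps must be strictly increasing and evenly spaced")


@dataclass(frozen=True)
class StudyBundle:
    """All synthetic treatment tables from one seeded draw."""

    fecundity: pd.DataFrame
    survival: pd.DataFrame
    thermal: tuple[ThermalProfile, ...]
    seed: int
    multiplier: int = 1


def gen_fecundity_counts(cfg: SyntheticConfig, viability: float) -> pd.DataFrame:
    """Draw per-pair egg counts and viable-egg counts for one treatment.

    ``eggs_laid`` follows a negative binomial with the configured mean and
    dispersion (or Poisson when ``count_family == "poisson"``); each pair's
    ``viable_eggs`` is binomial(eggs_laid, viability).
    """
    if not 0 <= viability <= 1:
        raise ValueError(f"viability must lie in [0, 1], got {viability}")
    rng = np.random.default_rng(cfg.seed)
    m = cfg.mean_or_p
    if m == 0:
        eggs = np.zeros(cfg.n_units, dtype=int)
    elif cfg.count_family == "poisson":
        eggs = rng.poisson(m, size=cfg.n_units)
    else:
        k = cfg.dispersion
        eggs = rng.negative_binomial(n=k, p=k / (k + m), size=cfg.n_units)
    viable = rng.binomial(eggs, viability)
    return pd.DataFrame(
        {
            "pair_id": [f"{cfg.treatment_name}_pair{i + 1}" for i in range(cfg.n_units)],
            "treatment": cfg.treatment_name,
            "eggs_laid": eggs,
            "viable_eggs": viable,
        }
    )


def gen_survival_replicates(cfg: SyntheticConfig) -> pd.DataFrame:
    """Draw per-replicate survivor counts: n_alive ~ Binomial(unit_size, p)."""
    if not 0 <= cfg.mean_or_p <= 1:
        raise ValueError(f"survival probability must lie in [0, 1], got {cfg.mean_or_p}")
    rng = np.random.default_rng(cfg.seed)
    alive = rng.binomial(cfg.unit_size, cfg.mean_or_p, size=cfg.n_units)
    return pd.DataFrame(
        {
            "replicate_id": [f"{cfg.treatment_name}_rep{i + 1}" for i in range(cfg.n_units)],
            "treatment": cfg.treatment_name,
            "n_start": cfg.unit_size,
            "n_alive": alive,
        }
    )


def gen_thermal_profile(
    days: float,
    interval: float,
    mean_temp: float,
    amplitude: float,
    damping: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "profile",
) -> ThermalProfile:
    """Simulate paired in-gel / ambient temperature series.

    The ambient (outside) series is ``mean + amplitude * sin(2 pi t / 24 h)``
    plus Gaussian noise; the in-gel series has the same phase with the
    amplitude multiplied by ``damping`` in [0, 1] (gel thermal buffering)
    and independent noise of the same scale.
    """
    if interval <= 0:
        raise ValueError("sampling interval must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    if not 0 <= damping <= 1:
        raise ValueError("damping must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = int(round(days * 24 * 60 / interval))
    t = np.arange(n) * interval
    phase = np.sin(2 * np.pi * t / (24 * 60))
    outside = mean_temp + amplitude * phase
    inside = mean_temp + damping * amplitude * phase
    if noise_sd > 0:
        outside = outside + rng.normal(0, noise_sd, n)
        inside = inside + rng.normal(0, noise_sd, n)
    data = pd.DataFrame(
        {"time_min": t, "temp_inside": inside, "temp_outside": outside}
    )
    return ThermalProfile(
        data=data, sampling_interval=interval, duration_days=days, label=label
    )


def gen_study_bundle(seed: int, multiplier: int = 1) -> StudyBundle:
    """Generate every treatment table of the study design in one seeded call.

    Four fecundity treatments (8 pairs each) around means 42.9 / 34.6 /
    35.6 / 21.5 eggs, and six survival treatments around proportions
    0.82 / 0.78 / 0.63 / 0.5 / 0.81 / 0.0, plus six paired thermal
    profiles (3 days at 1-minute sampling, gel damping 0.5).

    ``multiplier`` scales every replicate count (pairs and survival
    replicates) for parameter-recovery experiments; the distributional
    parameters are untouched.
    """
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    ss = np.random.SeedSequence(seed)
    n_child = len(FECUNDITY_TREATMENTS) + len(SURVIVAL_TREATMENTS) + 6
    child_seeds = [int(s) % (2**31) for s in ss.generate_state(n_child)]
    seeds = iter(child_seeds)

    fec_frames = []
    for name, params in FECUNDITY_TREATMENTS.items():
        cfg = SyntheticConfig(
            treatment_name=name,
            n_units=params["n_pairs"] * multiplier,
            mean_or_p=params["mean"],
            seed=next(seeds),
        )
        fec_frames.append(gen_fecundity_counts(cfg, viability=params["viability"]))
    fecundity = pd.concat(fec_frames, ignore_index=True)

    surv_frames = []
    for name, params in SURVIVAL_TREATMENTS.items():
        cfg = SyntheticConfig(
            treatment_name=name,
            n_units=params["n_replicates"] * multiplier,
            unit_size=params["unit_size"],
            mean_or_p=params["p"],
            seed=next(seeds),
        )
        surv_frames.append(gen_survival_replicates(cfg))
    survival = pd.concat(surv_frames, ignore_index=True)

    # six thermocouple pairs in the field: austral-summer mean ~4 C with a
    # ~5 C diurnal swing; the gel transmits about half the amplitude
    thermal = tuple(
        gen_thermal_profile(
            days=3, interval=1.0, mean_temp=4.0, amplitude=5.0,
            damping=0.5, noise_sd=0.3, seed=next(seeds), label=f"gel{i + 1}",
        )
        for i in range(6)
    )
    return StudyBundle(
        fecundity=fecundity, survival=survival, thermal=thermal,
        seed=seed, multiplier=multiplier,
    )


def write_bundle_csv(bundle: StudyBundle, outdir) -> list[str]:
    """Write the bundle tables as UTF-8 CSV; returns the paths written."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    p = outdir / "fecundity.csv"
    bundle.fecundity.to_csv(p, index=False)
    paths.append(str(p))
    p = outdir / "survival.csv"
    bundle.survival.to_csv(p, index=False)
    paths.append(str(p))
    for prof in bundle.thermal:
        p = outdir / f"thermal_{prof.label}.csv"
        prof.data.to_csv(p, index=False)
        paths.append(str(p))
    return paths
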