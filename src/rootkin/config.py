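"""Scenario and threshold configuration.

A :class:`ScenarioConfig` carries the ground truth for one treatment
(well-watered ``WW`` or water-deficit ``WD``): the overall elongation rate,
the logistic displacement-velocity curve of the growth zone, the mature
cortical cell length, the diameter taper, and the effect sizes and noise
levels used by the synthetic generators.  :class:`AnalysisThresholds`
collects every statistical gate of the downstream analysis under one roof
so that a pipeline run is reproducible from a single YAML file.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from typing import Mapping

import pandas as pd
import yaml

REGIONS = ("R1", "R2", "R3")

#: Growth-zone regions in mm from the root-cap junction: R1 0-3 mm (plus the
#: root cap, which carries no kinematic grid), R2 3-6 mm, R3 6-9.5 mm.
REGION_BOUNDS: dict[str, tuple[float, float]] = {
    "R1": (0.0, 3.0),
    "R2": (3.0, 6.0),
    "R3": (6.0, 9.5),
}


class ConfigError(ValueError):
    """Raised when a scenario or threshold configuration is invalid."""


@dataclass(frozen=True)
class LogisticTruth:
    """Parameters of the logistic displacement-velocity curve.

    v(x) = a2 + (a1 - a2) / (1 + (x / x0)**p)

    with ``a1`` the velocity at the root-cap junction (mm/h), ``a2`` the
    mature-zone plateau velocity equal to the overall elongation rate
    (mm/h), ``x0`` the midpoint position (mm) and ``p`` the unitless
    steepness.
    """

    a1: float
    a2: float
    x0: float
    p: float

    def __post_init__(self) -> None:
        if not (self.a2 > self.a1 >= 0):
            raise ConfigError(f"require a2 > a1 >= 0, got a1={self.a1}, a2={self.a2}")
        if self.x0 <= 0 or self.p <= 0:
            raise ConfigError(f"require x0 > 0 and p > 0, got x0={self.x0}, p={self.p}")


@dataclass(frozen=True)
class DiameterTaper:
    """Monotone diameter taper from ``d_tip`` at x=0 to ``d_mature``.

    The approach to the mature diameter is exponential with the given decay
    length (mm).  ``d_tip > d_mature`` is permitted (inverted taper) but a
    zero or negative diameter is not.
    """

    d_tip_mm: float
    d_mature_mm: float
    decay_mm: float

    def __post_init__(self) -> None:
        if self.d_tip_mm <= 0 or self.d_mature_mm <= 0:
            raise ConfigError("diameters must be positive")
        if self.decay_mm < 0:
            raise ConfigError("decay length must be non-negative")


@dataclass(frozen=True)
class TierProportions:
    """Expected fractions of transcripts per |log2FC| tier in one region.

    ``up2``/``down2`` are the fractions at |log2FC| >= 2; ``up1``/``down1``
    the fractions at |log2FC| >= 1 (cumulative, so tier-1 >= tier-2).
    """

    up2: float
    down2: float
    up1: float
    down1: float

    def __post_init__(self) -> None:
        for v in (self.up2, self.down2, self.up1, self.down1):
            if v < 0:
                raise ConfigError("tier proportions must be non-negative")
        if self.up1 < self.up2 or self.down1 < self.down2:
            raise ConfigError("tier-1 (>=1) proportions must be >= tier-2 (>=2) proportions")
        if self.up1 + self.down1 > 1:
            raise ConfigError("tier proportions per region must sum to <= 1")


@dataclass
class ScenarioConfig:
    """Ground truth for one treatment scenario."""

    name: str
    elong_rate_cm_per_day: float
    final_cell_len_um: float
    logistic_truth: LogisticTruth
    plateau_start_mm: float
    diameter_taper: DiameterTaper
    n_plants: int = 9
    length_sd_cm: float = 1.0
    day15_mean_len_cm: float = 10.0
    met_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    met_cv: float = 0.10
    met_n_reps: int = 3
    met_n_null: int = 0
    missing_rate: float = 0.0
    dat_proportions: Mapping[str, TierProportions] = field(default_factory=dict)
    n_transcripts: int = 45_764
    seed: int = 0

    def __post_init__(self) -> None:
        if self.elong_rate_cm_per_day <= 0:
            raise ConfigError("elongation rate must be positive")
        if self.final_cell_len_um <= 0:
            raise ConfigError("final cell length must be positive")
        if self.n_plants <= 0:
            raise ConfigError("n_plants must be positive")
        if self.length_sd_cm < 0:
            raise ConfigError("length SD must be non-negative")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.met_n_reps < 2:
            raise ConfigError("met_n_reps must be >= 2")
        if self.met_cv < 0:
            raise ConfigError("met_cv must be non-negative")
        for met, by_region in self.met_effects.items():
            for region, fc in by_region.items():
                if fc <= 0:
                    raise ConfigError(f"fold change must be > 0 ({met}/{region}: {fc})")

    @property
    def elong_rate_mm_per_h(self) -> float:
        return self.elong_rate_cm_per_day * 10.0 / 24.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        d["logistic_truth"] = LogisticTruth(**d["logistic_truth"])
        d["diameter_taper"] = DiameterTaper(**d["diameter_taper"])
        d["dat_proportions"] = {
            r: TierProportions(**tp) if not isinstance(tp, TierProportions) else tp
            for r, tp in d.get("dat_proportions", {}).items()
        }
        return cls(**d)


@dataclass(frozen=True)
class AnalysisThresholds:
    """Statistical gates of the differential and pathway analyses.

    Defaults follow the study design this package emulates: metabolite
    significance requires p < 0.05, BH q < 0.10 and a two-sided fold change
    of at least 1.5; transcripts are tiered at |log2FC| >= 2 and >= 1;
    transcription factors at log2FC >= 1.2 with a mean count >= 5;
    dominant pathways need -log10 p > 2, impact > 0.1 and FDR < 0.1.
    """

    dam_p: float = 0.05
    dam_q: float = 0.10
    dam_fc: float = 1.5
    dat_tiers: tuple[float, ...] = (2.0, 1.0)
    tf_log2fc: float = 1.2
    tf_min_count: float = 5.0
    tf_two_sided: bool = True
    pathway_neglog10p: float = 2.0
    pathway_impact: float = 0.1
    pathway_fdr: float = 0.1
    concordance_log2fc: float = 1.0
    osmotic_adjustment_tol_mpa: float = 0.05


def _table2_effects() -> dict[str, dict[str, float]]:
    """Packaged per-region WD/WW fold-change ground truth for metabolites."""
    ref = importlib.resources.files("rootkin.data") / "metabolite_fold_changes.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", index_col=0)
    return {met: {r: float(df.loc[met, r]) for r in REGIONS} for met in df.index}


# Table-1-style expected tier counts per region out of 45,764 transcripts.
_DAT_COUNTS = {
    # region: (up at >=2, down at >=2, up at >=1, down at >=1)
    "R1": (63, 41, 104, 91),
    "R2": (168, 382, 384, 845),
    "R3": (182, 183, 396, 493),
}


def _dat_proportions(n: int = 45_764) -> dict[str, TierProportions]:
    return {
        r: TierProportions(up2=u2 / n, down2=d2 / n, up1=u1 / n, down1=d1 / n)
        for r, (u2, d2, u1, d1) in _DAT_COUNTS.items()
    }


def builtin_scenario(name: str, seed: int = 0) -> ScenarioConfig:
    """Packaged WW / WD scenarios calibrated to the published kinematics.

    WW: elongation 3.08 cm/day, cell flux 8.18 cells/h (so a final cell
    length of 156.9 um), REL peak at 2.5 mm and growth-zone extent 10 mm.
    WD: 3.13 cm/day, 7.68 cells/h (169.8 um), velocity curve shifted so the
    volumetric-expansion peak sits ~1.5 mm basal of WW, slightly wider root.
    """
    common = dict(
        met_effects=_table2_effects(),
        met_cv=0.10,
        met_n_reps=3,
        # pad the measured-compound universe to the study's scale (569
        # identified compounds) with unaffected background metabolites
        met_n_null=548,
        missing_rate=0.05,
        dat_proportions=_dat_proportions(),
        seed=seed,
    )
    if name == "WW":
        return ScenarioConfig(
            name="WW",
            elong_rate_cm_per_day=3.08,
            final_cell_len_um=156.9,
            logistic_truth=LogisticTruth(a1=0.05, a2=3.08 * 10 / 24, x0=3.24228, p=2.90058),
            plateau_start_mm=10.0,
            diameter_taper=DiameterTaper(d_tip_mm=0.90, d_mature_mm=1.10, decay_mm=4.0),
            n_plants=9,
            length_sd_cm=1.0,
            **common,
        )
    if name == "WD":
        return ScenarioConfig(
            name="WD",
            elong_rate_cm_per_day=3.13,
            final_cell_len_um=169.8,
            logistic_truth=LogisticTruth(a1=0.05, a2=3.13 * 10 / 24, x0=4.63656, p=3.77406),
            plateau_start_mm=11.5,
            diameter_taper=DiameterTaper(d_tip_mm=0.95, d_mature_mm=1.18, decay_mm=5.0),
            n_plants=9,
            length_sd_cm=1.0,
            **common,
        )
    raise ConfigError(f"unknown builtin scenario {name!r} (expected 'WW' or 'WD')")


def load_scenario(path) -> ScenarioConfig:
    with open(path) as fh:
        return ScenarioConfig.from_dict(yaml.safe_load(fh))


def dump_scenario(cfg: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
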