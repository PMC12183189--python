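"""Seeded synthetic-data generators for every pipeline input.

Each generator is a pure function of ``(cfg, seed)``: the scenario's
ground truth (elongation rate, logistic velocity curve, mature cell
length, diameter taper, metabolite fold changes, transcript tier
proportions) plus explicitly modelled noise.  Noise models: additive
Gaussian for axial lengths, multiplicative lognormal for strictly
positive measurements (cell lengths, diameters, metabolite abundances),
missing-at-random masking for metabolite cells.

The generators emulate a two-harvest cohort design (days 15 and 17),
cell-length and diameter profiles over the apical 12 mm, three-replicate
metabolite abundance matrices and region-structured transcript log2FC
tables.  They do not emulate images, raw spectra or sequencing reads.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import REGIONS, ScenarioConfig
from .kinematics import (
    AxialLengthCohort,
    CellLengthProfile,
    DiameterProfile,
    logistic_velocity,
)
from .omics import AbundanceMatrix

__all__ = [
    "make_cohort",
    "make_cell_profile",
    "make_diameter_profile",
    "make_metabolome",
    "make_transcript_log2fc",
    "make_solute_field",
    "select_roots",
]

# distinct stream tags keep the generators independent under one seed
_TAG_COHORT, _TAG_CELLS, _TAG_DIAM, _TAG_MET, _TAG_DAT, _TAG_FIELD = range(6)


def _rng(cfg: ScenarioConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, tag])


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit median and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return np.exp(rng.normal(0.0, sigma, size))


def make_cohort(cfg: ScenarioConfig) -> AxialLengthCohort:
    """Two-harvest axial-length cohort with Gaussian plant-to-plant noise.

    Day-17 lengths exceed day-15 lengths by two days of elongation in
    expectation; separate plants are harvested on each day.
    """
    rng = _rng(cfg, _TAG_COHORT)
    n = cfg.n_plants
    base = cfg.day15_mean_len_cm
    l15 = base + rng.normal(0.0, cfg.length_sd_cm, n)
    l17 = base + 2.0 * cfg.elong_rate_cm_per_day + rng.normal(0.0, cfg.length_sd_cm, n)
    lengths = np.concatenate([l15, l17])
    if np.any(lengths <= 0):
        raise ValueError("noise produced a non-positive root length; lower length_sd_cm")
    return AxialLengthCohort(
        plant=np.array([f"{cfg.name}_p{i:03d}" for i in range(2 * n)]),
        day=np.array([15] * n + [17] * n),
        treatment=np.array([cfg.name] * 2 * n),
        length_cm=lengths,
    )


def make_cell_profile(cfg: ScenarioConfig, grid_mm, noise_cv: float = 0.0) -> CellLengthProfile:
    """Cortical cell-length profile consistent with the velocity truth.

    Under flux constancy ``l(x) = l_final * v(x) / E``; beyond the plateau
    start the profile is clipped to the final cell length.  Optional
    multiplicative lognormal measurement noise with the given CV.
    """
    x = np.asarray(grid_mm, dtype=float)
    if x.size and (x.min() < 0 or x.max() > 12.0):
        raise ValueError("cell-length grid must lie within [0, 12] mm")
    t = cfg.logistic_truth
    v = logistic_velocity(x, t.a1, t.a2, t.x0, t.p)
    frac = np.where(x >= cfg.plateau_start_mm, 1.0, v / cfg.elong_rate_mm_per_h)
    cell_len = cfg.final_cell_len_um * frac
    cell_len = cell_len * _lognormal_noise(_rng(cfg, _TAG_CELLS), noise_cv, x.shape)
    return CellLengthProfile(x, cell_len, treatment=cfg.name)


def make_diameter_profile(cfg: ScenarioConfig, grid_mm, noise_cv: float = 0.0) -> DiameterProfile:
    """Smooth monotone diameter taper from d_tip to d_mature.

    Exponential approach over the configured decay length; a zero decay
    length degenerates to a step just basal of the root-cap junction.
    """
    x = np.asarray(grid_mm, dtype=float)
    taper = cfg.diameter_taper
    if taper.d_tip_mm > taper.d_mature_mm:
        warnings.warn("inverted taper: d_tip > d_mature", stacklevel=2)
    if taper.decay_mm == 0:
        d = np.where(x > 0, taper.d_mature_mm, taper.d_tip_mm).astype(float)
    else:
        d = taper.d_mature_mm - (taper.d_mature_mm - taper.d_tip_mm) * np.exp(-x / taper.decay_mm)
    d = d * _lognormal_noise(_rng(cfg, _TAG_DIAM), noise_cv, x.shape)
    return DiameterProfile(x, d, treatment=cfg.name)


def make_metabolome(cfg: ScenarioConfig, regions=REGIONS) -> AbundanceMatrix:
    """Replicated lognormal metabolite abundances with configured effects.

    For each metabolite and region the WW replicates are lognormal around
    a metabolite-specific baseline with CV ``met_cv``; WD replicates carry
    a geometric-mean WD/WW ratio equal to the configured fold change
    (fold change 1.0 where a metabolite has no configured effect).  Cells
    are masked missing-at-random at ``missing_rate``.  ``met_n_null``
    additional background metabolites with no treatment effect pad the
    measured-compound universe for enrichment analyses.
    """
    if not cfg.met_effects:
        raise ValueError("scenario has no metabolite effects configured")
    rng = _rng(cfg, _TAG_MET)
    mets = list(cfg.met_effects)
    mets += [f"compound_{i:04d}" for i in range(cfg.met_n_null)]
    n_rep = cfg.met_n_reps
    # metabolite-specific raw-area baselines, spanning a few decades
    baselines = 10.0 ** rng.uniform(4.0, 7.0, len(mets))
    cols, treats, regs, reps = [], [], [], []
    for treat in ("WW", "WD"):
        for region in regions:
            for rep in range(1, n_rep + 1):
                cols.append(f"{treat}_{region}_{rep}")
                treats.append(treat)
                regs.append(region)
                reps.append(rep)
    data = np.empty((len(mets), len(cols)))
    for i, met in enumerate(mets):
        j = 0
        effects = cfg.met_effects.get(met, {})
        for treat in ("WW", "WD"):
            for region in regions:
                fc = effects.get(region, 1.0) if treat == "WD" else 1.0
                if fc <= 0:
                    raise ValueError(f"fold change must be > 0 ({met}/{region})")
                vals = baselines[i] * fc * _lognormal_noise(rng, cfg.met_cv, n_rep)
                data[i, j:j + n_rep] = vals
                j += n_rep
    if cfg.missing_rate > 0:
        mask = rng.random(data.shape) < cfg.missing_rate
        data = np.where(mask, np.nan, data)
    values = pd.DataFrame(data, index=pd.Index(mets, name="metabolite"), columns=cols)
    samples = pd.DataFrame(
        {"treatment": treats, "region": regs, "replicate": reps},
        index=pd.Index(cols, name="sample"),
    )
    return AbundanceMatrix(values, samples)


def make_transcript_log2fc(cfg: ScenarioConfig, regions=REGIONS) -> pd.DataFrame:
    """Per-transcript, per-region log2FC table with configured tier structure.

    Each transcript is assigned to one of five categories per region --
    up/down at |log2FC| >= 2, up/down in [1, 2), or null (|log2FC| < 1) --
    with probabilities given by the scenario's tier proportions, so the
    expected threshold counts match the configured values.  A lognormal
    ``max_mean_count`` column is attached for count-floor filters.
    """
    if not cfg.dat_proportions:
        raise ValueError("scenario has no transcript tier proportions configured")
    rng = _rng(cfg, _TAG_DAT)
    n = cfg.n_transcripts
    features = np.array([f"t{i:06d}" for i in range(n)])
    frames = []
    for region in regions:
        tp = cfg.dat_proportions[region]
        probs = [tp.up2, tp.down2, tp.up1 - tp.up2, tp.down1 - tp.down2]
        probs.append(1.0 - sum(probs))
        cat = rng.choice(5, size=n, p=probs)
        lfc = rng.normal(0.0, 0.3, n).clip(-0.999, 0.999)  # null background
        lfc[cat == 0] = 2.0 + rng.exponential(0.7, (cat == 0).sum())
        lfc[cat == 1] = -(2.0 + rng.exponential(0.7, (cat == 1).sum()))
        lfc[cat == 2] = rng.uniform(1.0, 2.0, (cat == 2).sum())
        lfc[cat == 3] = -rng.uniform(1.0, 2.0, (cat == 3).sum())
        counts = np.exp(rng.normal(3.0, 1.5, n))
        frames.append(pd.DataFrame({
            "feature": features, "region": region,
            "log2fc": lfc, "max_mean_count": counts,
        }))
    return pd.concat(frames, ignore_index=True)


def make_solute_field(cfg: ScenarioConfig, grid_mm, c_tip: float = 0.3,
                      c_mature: float = 0.4, rise_mm: float = 4.0):
    """Synthetic osmolyte field (c, A, v) on a grid, for deposition analysis.

    Concentration rises smoothly from ``c_tip`` to ``c_mature`` (opaque
    consistent units); area comes from the scenario's diameter taper and
    velocity from its logistic truth.  Returns ``(c, area, v)`` arrays.
    """
    from .kinematics import area_profile

    x = np.asarray(grid_mm, dtype=float)
    c = c_mature - (c_mature - c_tip) * np.exp(-x / rise_mm)
    area = area_profile(make_diameter_profile(cfg, x))
    t = cfg.logistic_truth
    v = logistic_velocity(x, t.a1, t.a2, t.x0, t.p)
    return c, area, v


def select_roots(lengths) -> tuple[np.ndarray, np.ndarray]:
    """Keep roots whose length lies within 1 sample SD of the cohort mean.

    Returns ``(kept_lengths, mask)``.  With identical lengths the sample
    SD is zero and every root is kept (the boundary counts as within).
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size < 2:
        raise ValueError("need >= 2 roots to select on the 1-SD rule")
    mean = lengths.mean()
    sd = lengths.std(ddof=1)
    mask = np.abs(lengths - mean) <= sd
    return lengths[mask], mask
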