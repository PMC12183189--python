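"""End-to-end pipeline: simulate, analyse, integrate, report.

``run_pipeline`` executes the stages in order -- simulate, kinematics,
water, omics, pathways, concordance, report -- from a single YAML config,
writing every artifact as delimited text plus a manifest (inputs,
parameters, seed, checksums).  Runs with the same config and seed are
bit-identical.

The transcript-metabolite concordance classifier lives here: a
significant metabolite change is *transcriptionally coordinated* when at
least one mapped enzymatic step changed in a direction consistent with
the metabolite change (synthesis up or degradation/competing down for an
accumulating metabolite, mirrored for a depleting one), under *metabolic
control* when mapped transcripts exist but none passed the threshold,
*discordant* when the passing transcripts all point the opposite way,
and *unmapped* otherwise.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import shutil
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .config import REGIONS, AnalysisThresholds, ScenarioConfig, builtin_scenario, load_scenario
from .kinematics import (
    area_profile, cell_flux, elongation_rate, fit_logistic, growth_zone_extent,
    mature_cell_length, radtan_rate, region_summaries, rel_profile,
    velocity_profile, volumetric_profiles,
)
from .omics import count_dats, differential_analysis, impute_min, ln_transform, median_scale, pca_variance, tf_filter
from .pathways import enrich, load_pathways
from .synthetic import (
    make_cell_profile, make_cohort, make_diameter_profile, make_metabolome,
    make_solute_field, make_transcript_log2fc, select_roots,
)
from .water import SoluteField, TissueWaterStatus, deposition_rate, osmotic_adjustment

__all__ = ["ConcordanceCall", "PipelineError", "classify_concordance",
           "run_pipeline", "make_report", "builtin_enzyme_map",
           "builtin_enzyme_transcripts", "builtin_pathways"]

CLASSES = ("transcriptionally_coordinated", "metabolic_control", "discordant", "unmapped")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class ConcordanceCall:
    metabolite: str
    region: str
    klass: str
    supporting: tuple[str, ...]
    evidence: pd.DataFrame

    def __post_init__(self) -> None:
        if self.klass not in CLASSES:
            raise ValueError(f"unknown concordance class {self.klass!r}")


def classify_concordance(dam_row, dats: pd.DataFrame, enzyme_map: pd.DataFrame,
                         dat_threshold: float = 1.0) -> ConcordanceCall:
    """Classify one significant metabolite change against mapped transcripts.

    ``dam_row`` needs ``feature``, ``region`` and ``fc``; ``dats`` is a
    per-transcript log2FC table with ``feature``, ``region``, ``log2fc``
    columns; ``enzyme_map`` follows :func:`rootkin.io.read_enzyme_map`.
    """
    met = dam_row["feature"]
    region = dam_row["region"]
    accumulating = dam_row["fc"] >= 1.0
    steps = enzyme_map.loc[enzyme_map["metabolite"] == met]
    mapped: list[dict] = []
    for _, step in steps.iterrows():
        if not isinstance(step["transcripts"], tuple):
            raise ValueError("malformed enzyme map: transcripts must be parsed tuples")
        for t in step["transcripts"]:
            hit = dats.loc[(dats["feature"] == t) & (dats["region"] == region)]
            if hit.empty:
                continue
            mapped.append({"transcript": t, "step": step["step"], "role": step["role"],
                           "log2fc": float(hit["log2fc"].iloc[0])})
    if not mapped:
        return ConcordanceCall(met, region, "unmapped", (), pd.DataFrame())
    ev = pd.DataFrame(mapped)
    lfc = ev["log2fc"].to_numpy()
    makes = ev["role"].to_numpy() == "synthesis"  # degradation/competing consume
    up = lfc >= dat_threshold
    down = lfc <= -dat_threshold
    if accumulating:
        support = (makes & up) | (~makes & down)
        oppose = (makes & down) | (~makes & up)
    else:
        support = (makes & down) | (~makes & up)
        oppose = (makes & up) | (~makes & down)
    if support.any():
        klass = "transcriptionally_coordinated"
        supp = tuple(ev.loc[support, "transcript"])
    elif oppose.any():
        klass = "discordant"
        supp = ()
    else:
        klass = "metabolic_control"
        supp = ()
    return ConcordanceCall(met, region, klass, supp, ev)


# ---------------------------------------------------------------------------
# packaged resources


def _data_path(name: str):
    return importlib.resources.as_file(importlib.resources.files("rootkin.data") / name)


def builtin_enzyme_map() -> pd.DataFrame:
    with _data_path("enzyme_map.tsv") as p:
        return rio.read_enzyme_map(p)


def builtin_enzyme_transcripts() -> pd.DataFrame:
    """Synthetic per-region log2FC of the mapped enzyme transcripts.

    A constructed stand-in encoding the qualitative published pattern
    (proline-synthesis steps up, the competing pipecolate branch down,
    the saccharopine-forming step unchanged, taurine steps up in R1/R2).
    """
    with _data_path("synthetic_enzyme_transcript_log2fc.tsv") as p:
        wide = pd.read_csv(p, sep="\t")
    return wide.melt(id_vars="transcript", var_name="region", value_name="log2fc"
                     ).rename(columns={"transcript": "feature"})


def builtin_pathways():
    with _data_path("toy_pathways.gmt") as g, _data_path("toy_pathway_edges.tsv") as e:
        return load_pathways(g, e)


# ---------------------------------------------------------------------------
# pipeline


_DEFAULT_CONFIG = {
    "seed": 1,
    "scenarios": {"WW": "builtin", "WD": "builtin"},
    "kinematics": {"grid_step_mm": 0.1, "grid_max_mm": 12.0,
                   "mature_window_mm": [10.0, 12.0],
                   "cell_noise_cv": 0.02, "diam_noise_cv": 0.01},
    "water": {"status": {"WW": {"psi_w": -0.25, "psi_s": -0.85},
                         "WD": {"psi_w": -0.75, "psi_s": -1.35}},
              "wd_concentration_factor": 1.5},
    "thresholds": {},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config=None, out_dir="rootkin_out", seed: int | None = None) -> dict:
    """Run every stage and write a results bundle to ``out_dir``.

    ``config`` may be a YAML path, a dict, or None for the packaged demo
    configuration; ``seed`` overrides the config seed.  Returns the bundle
    (stage results keyed by stage name).  On stage failure, outputs
    written so far are moved under ``out_dir/failed`` and a
    :class:`PipelineError` naming the stage is raised.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = _merge(_DEFAULT_CONFIG, config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    thresholds = AnalysisThresholds(**cfg.get("thresholds", {}))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": cfg}
    outputs: list[Path] = []
    stage = "configure"
    try:
        scenarios: dict[str, ScenarioConfig] = {}
        for name, src in cfg["scenarios"].items():
            scenarios[name] = (builtin_scenario(name, seed=cfg["seed"])
                               if src == "builtin" else load_scenario(src))

        stage = "simulate"
        kin_cfg = cfg["kinematics"]
        grid = np.round(np.arange(0.0, kin_cfg["grid_max_mm"] + 1e-9,
                                  kin_cfg["grid_step_mm"]), 10)
        sim: dict[str, dict] = {}
        for name, scn in scenarios.items():
            cohort = make_cohort(scn)
            cells = make_cell_profile(scn, grid, noise_cv=kin_cfg["cell_noise_cv"])
            diam = make_diameter_profile(scn, grid, noise_cv=kin_cfg["diam_noise_cv"])
            rio.write_cohort(cohort, out / f"cohort_{name}.tsv")
            rio.write_profile(cells, out / f"cells_{name}.tsv", "cell_length_um")
            rio.write_profile(diam, out / f"diameter_{name}.tsv", "diameter_mm")
            outputs += [out / f"cohort_{name}.tsv", out / f"cells_{name}.tsv",
                        out / f"diameter_{name}.tsv"]
            sim[name] = {"cohort": cohort, "cells": cells, "diam": diam, "scenario": scn}
        met_scn = scenarios.get("WD", next(iter(scenarios.values())))
        metabolome = make_metabolome(met_scn)
        transcripts = make_transcript_log2fc(met_scn)
        rio.write_matrix(metabolome, out / "metabolome.tsv")
        transcripts.to_csv(out / "transcript_log2fc.tsv", sep="\t", index=False)
        outputs += [out / "metabolome.tsv", out / "transcript_log2fc.tsv"]
        bundle["simulate"] = sim

        stage = "kinematics"
        kin: dict[str, dict] = {}
        for name, parts in sim.items():
            rate_cm, rate_mm = elongation_rate(parts["cohort"])
            kept, mask = select_roots(parts["cohort"].lengths_on(17))
            vel = velocity_profile(parts["cells"], rate_mm,
                                   tuple(kin_cfg["mature_window_mm"]))
            fit = fit_logistic(vel)
            rel = rel_profile(fit, grid)
            extent, peak_x, peak_rel = growth_zone_extent(grid, rel)
            area = area_profile(parts["diam"])
            radtan = radtan_rate(vel, area)
            expansion = volumetric_profiles(grid, rel, radtan, area)
            regions = region_summaries(grid, {"rel": rel, "radtan": radtan,
                                              "volrate": expansion.volrate})
            l_final = mature_cell_length(parts["cells"], tuple(kin_cfg["mature_window_mm"]))
            flux = cell_flux(rate_mm, l_final)
            fit.to_json(out / f"logistic_{name}.json")
            prof = pd.DataFrame({"position_mm": grid, "rel": rel, "radtan": radtan,
                                 "relvol": expansion.relvol, "area_mm2": area,
                                 "volrate": expansion.volrate})
            prof.to_csv(out / f"expansion_{name}.tsv", sep="\t", index=False)
            outputs += [out / f"logistic_{name}.json", out / f"expansion_{name}.tsv"]
            kin[name] = {
                "rate_cm_day": rate_cm, "rate_mm_h": rate_mm, "l_final_um": l_final,
                "flux_cells_h": flux, "fit": fit, "rel": rel,
                "growth_zone_mm": extent, "rel_peak_mm": peak_x, "rel_peak": peak_rel,
                "vol_peak_mm": expansion.peak_position_mm, "expansion": expansion,
                "regions": regions, "n_roots_kept": int(mask.sum()),
                "n_roots": int(mask.size),
            }
        bundle["kinematics"] = kin

        stage = "water"
        wcfg = cfg["water"]
        status = {name: TissueWaterStatus("N2 root tip", name, **vals)
                  for name, vals in wcfg["status"].items()}
        delta, complete = osmotic_adjustment(
            status["WW"], status["WD"], thresholds.osmotic_adjustment_tol_mpa)
        depo = {}
        for name, scn in scenarios.items():
            c, area, v = make_solute_field(scn, grid)
            if name == "WD":
                c = c * wcfg["wd_concentration_factor"]
            field = SoluteField(grid, c, area, v)
            D, per_region = deposition_rate(field)
            depo[name] = {"per_region": per_region, "profile": D}
        water = {"status": status, "delta_psi_s": delta, "complete_adjustment": complete,
                 "turgor": {n: s.psi_p for n, s in status.items()}, "deposition": depo}
        pd.DataFrame([
            {"treatment": n, "psi_w": s.psi_w, "psi_s": s.psi_s, "psi_p": s.psi_p}
            for n, s in status.items()
        ]).to_csv(out / "water_status.tsv", sep="\t", index=False)
        outputs.append(out / "water_status.tsv")
        bundle["water"] = water

        stage = "omics"
        dams = differential_analysis(metabolome, thresholds)
        dat_counts = count_dats(transcripts, thresholds.dat_tiers)
        tfs = tf_filter(transcripts, thresholds.tf_log2fc, thresholds.tf_min_count,
                        thresholds.tf_two_sided)
        pca_input = ln_transform(median_scale(impute_min(metabolome)))
        pca_frac, pca_scores = pca_variance(pca_input)
        dams.to_csv(out / "dam_table.tsv", sep="\t", index=False)
        dat_counts.to_csv(out / "dat_counts.tsv", sep="\t")
        pca_scores.to_csv(out / "pca_scores.tsv", sep="\t")
        outputs += [out / "dam_table.tsv", out / "dat_counts.tsv", out / "pca_scores.tsv"]
        bundle["omics"] = {"dams": dams, "dat_counts": dat_counts, "tfs": tfs,
                           "pca_fractions": pca_frac}

        stage = "pathways"
        library = builtin_pathways()
        universe = list(metabolome.values.index)
        pw_results = {}
        for region in REGIONS:
            sig = dams[(dams["region"] == region) & dams["significant"]]
            for direction, subset in (("up", sig[sig["fc"] > 1]), ("down", sig[sig["fc"] < 1])):
                hits = list(subset["feature"])
                res = enrich(library, hits, universe, thresholds)
                pw_results[(region, direction)] = res
                res.to_csv(out / f"pathways_{region}_{direction}.tsv", sep="\t", index=False)
                outputs.append(out / f"pathways_{region}_{direction}.tsv")
        bundle["pathways"] = pw_results

        stage = "concordance"
        emap = builtin_enzyme_map()
        named_dats = builtin_enzyme_transcripts()
        calls = []
        for _, row in dams[dams["significant"]].iterrows():
            call = classify_concordance(row, named_dats, emap,
                                        thresholds.concordance_log2fc)
            calls.append(call)
        conc = pd.DataFrame([
            {"metabolite": c.metabolite, "region": c.region, "class": c.klass,
             "supporting": ",".join(c.supporting)} for c in calls])
        conc.to_csv(out / "concordance.tsv", sep="\t", index=False)
        outputs.append(out / "concordance.tsv")
        bundle["concordance"] = calls

        stage = "report"
        report = make_report(bundle)
        (out / "report.md").write_text(report)
        outputs.append(out / "report.md")

        stage = "manifest"
        manifest = {
            "seed": cfg["seed"],
            "config": {k: v for k, v in cfg.items() if k != "scenarios"},
            "scenarios": {n: s.name for n, s in scenarios.items()},
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        bundle["manifest"] = manifest
        return bundle
    except Exception as err:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for p in outputs:
            if p.exists():
                shutil.move(str(p), failed / p.name)
        if isinstance(err, PipelineError):
            raise
        raise PipelineError(stage, str(err)) from err


def _fmt(x: float, nd: int = 3) -> str:
    return f"{x:.{nd}f}"


def make_report(bundle: dict) -> str:
    """Render the results bundle as a Markdown report."""
    lines = ["# Nodal-root water-deficit analysis report", ""]

    kin = bundle.get("kinematics", {})
    lines += ["## Kinematic summary", ""]
    if kin:
        lines += ["| treatment | rate (cm/day) | rate (mm/h) | final cell (um) | "
                  "flux (cells/h) | growth zone (mm) | REL peak (mm) | vol peak (mm) | fit R |",
                  "|---|---|---|---|---|---|---|---|---|"]
        for name, k in kin.items():
            lines.append(
                f"| {name} | {_fmt(k['rate_cm_day'], 2)} | {_fmt(k['rate_mm_h'])} | "
                f"{_fmt(k['l_final_um'], 1)} | {_fmt(k['flux_cells_h'], 2)} | "
                f"{_fmt(k['growth_zone_mm'], 2)} | {_fmt(k['rel_peak_mm'], 2)} | "
                f"{_fmt(k['vol_peak_mm'], 2)} | {_fmt(k['fit'].r, 4)} |")
        if {"WW", "WD"} <= kin.keys():
            shift = kin["WD"]["vol_peak_mm"] - kin["WW"]["vol_peak_mm"]
            lines += ["", f"Volumetric-expansion peak shift (WD - WW): {_fmt(shift, 2)} mm"]
    lines.append("")

    water = bundle.get("water")
    lines += ["## Water relations", ""]
    if water:
        for name, s in water["status"].items():
            lines.append(f"- {name}: psi_w {s.psi_w} MPa, psi_s {s.psi_s} MPa, "
                         f"turgor {_fmt(s.psi_p, 2)} MPa")
        adj = "complete" if water["complete_adjustment"] else "incomplete"
        lines += [f"- Osmotic adjustment: delta psi_s = {_fmt(water['delta_psi_s'], 2)} MPa "
                  f"({adj} turgor maintenance)"]
        for name, d in water["deposition"].items():
            per = ", ".join(f"{r}: {_fmt(v, 4)}" for r, v in d["per_region"].items())
            lines.append(f"- Net solute deposition integrals ({name}): {per}")
    lines.append("")

    omics = bundle.get("omics")
    lines += ["## Differentially accumulated metabolites", ""]
    if omics is not None:
        dams = omics["dams"]
        sig = dams[dams["significant"]]
        if sig.empty:
            lines.append("none called")
        else:
            wide = sig.pivot_table(index="feature", columns="region", values="fc")
            lines += ["| metabolite | " + " | ".join(wide.columns) + " |",
                      "|---" * (len(wide.columns) + 1) + "|"]
            for feat, row in wide.iterrows():
                cells = [("" if pd.isna(v) else _fmt(v, 2)) for v in row]
                lines.append(f"| {feat} | " + " | ".join(cells) + " |")
        lines += ["", "## Transcript threshold counts", ""]
        dc = omics["dat_counts"].reset_index()
        lines += ["| region | tier | total | up | down |", "|---|---|---|---|---|"]
        for _, r in dc.iterrows():
            lines.append(f"| {r['region']} | {r['tier']:g} | {r['total']} | "
                         f"{r['up']} | {r['down']} |")
        lines += ["", f"Transcription factors passing the gate: "
                  f"{omics['tfs']['feature'].nunique() if len(omics['tfs']) else 0}",
                  "", "Metabolome PCA variance fractions: "
                  + ", ".join(_fmt(f, 3) for f in omics["pca_fractions"])]
    lines.append("")

    pws = bundle.get("pathways")
    lines += ["## Dominant pathways", ""]
    if pws:
        any_dom = False
        for (region, direction), res in pws.items():
            dom = res[res["dominant"]]
            for _, r in dom.iterrows():
                any_dom = True
                lines.append(f"- {region} ({direction}): {r['pathway']} "
                             f"(p={r['p']:.2e}, impact={_fmt(r['impact'], 2)}, "
                             f"FDR={r['fdr']:.2e})")
        if not any_dom:
            lines.append("none called")
    lines.append("")

    calls = bundle.get("concordance")
    lines += ["## Transcript-metabolite concordance", ""]
    if calls:
        counts: dict[str, int] = {}
        for c in calls:
            counts[c.klass] = counts.get(c.klass, 0) + 1
        lines.append("Class counts: " + ", ".join(f"{k}: {v}" for k, v in sorted(counts.items())))
        for c in calls:
            supp = f" via {', '.join(c.supporting)}" if c.supporting else ""
            lines.append(f"- {c.metabolite} / {c.region}: {c.klass}{supp}")
    elif calls is not None:
        lines.append("none called")
    lines.append("")
    return "\n".join(lines)
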