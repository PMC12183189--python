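"""Delimited-text readers and writers for the pipeline's tables.

Profiles travel as two-column TSV (``position_mm <TAB> value``), cohorts
as ``plant <TAB> day <TAB> treatment <TAB> length_cm``, and abundance
matrices as features-in-rows TSV whose header is followed by commented
metadata lines (``#treatment``, ``#region``, ``#replicate``) carrying the
sample descriptors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kinematics import AxialLengthCohort, CellLengthProfile, DiameterProfile, VelocityProfile
from .omics import AbundanceMatrix

__all__ = [
    "write_profile", "read_profile",
    "write_cohort", "read_cohort",
    "write_matrix", "read_matrix",
    "read_enzyme_map",
]

_PROFILE_TYPES = {
    "cell_length": CellLengthProfile,
    "diameter": DiameterProfile,
    "velocity": VelocityProfile,
}


def write_profile(profile, path, value_name: str = "value") -> None:
    pd.DataFrame({"position_mm": profile.position_mm, value_name: profile.value}).to_csv(
        path, sep="\t", index=False)


def read_profile(path, kind: str = "cell_length", treatment: str = "", day=None):
    df = pd.read_csv(path, sep="\t")
    cls = _PROFILE_TYPES[kind]
    return cls(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float),
               treatment=treatment, day=day)


def write_cohort(cohort: AxialLengthCohort, path) -> None:
    pd.DataFrame({"plant": cohort.plant, "day": cohort.day,
                  "treatment": cohort.treatment, "length_cm": cohort.length_cm}
                 ).to_csv(path, sep="\t", index=False)


def read_cohort(path) -> AxialLengthCohort:
    df = pd.read_csv(path, sep="\t")
    return AxialLengthCohort(df["plant"].to_numpy(), df["day"].to_numpy(),
                             df["treatment"].to_numpy(), df["length_cm"].to_numpy(float))


def write_matrix(m: AbundanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("feature\t" + "\t".join(m.values.columns) + "\n")
        for col in ("treatment", "region", "replicate"):
            fh.write(f"#{col}\t" + "\t".join(map(str, m.samples[col])) + "\n")
        for feat, row in m.values.iterrows():
            cells = ["" if np.isnan(v) else repr(float(v)) for v in row.to_numpy(float)]
            fh.write(str(feat) + "\t" + "\t".join(cells) + "\n")


def read_matrix(path) -> AbundanceMatrix:
    meta: dict[str, list[str]] = {}
    rows, index = [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = header[1:]
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                parts = line.split("\t")
                meta[parts[0][1:]] = parts[1:]
                continue
            parts = line.split("\t")
            index.append(parts[0])
            rows.append([float(v) if v else np.nan for v in parts[1:]])
    values = pd.DataFrame(rows, index=pd.Index(index, name="feature"), columns=cols)
    samples = pd.DataFrame(
        {"treatment": meta["treatment"], "region": meta["region"],
         "replicate": [int(r) for r in meta["replicate"]]},
        index=pd.Index(cols, name="sample"))
    return AbundanceMatrix(values, samples)


def read_enzyme_map(path) -> pd.DataFrame:
    """Metabolite -> enzymatic-step -> transcripts map.

    TSV columns: ``metabolite, step, role, transcripts`` with role in
    {synthesis, degradation, competing} and transcripts comma-separated.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("metabolite", "step", "role", "transcripts"):
        if col not in df.columns:
            raise ValueError(f"enzyme map lacks the {col!r} column")
    bad = ~df["role"].isin(["synthesis", "degradation", "competing"])
    if bad.any():
        raise ValueError(f"unknown enzyme roles: {sorted(df.loc[bad, 'role'].unique())}")
    df = df.copy()
    df["transcripts"] = df["transcripts"].fillna("").map(
        lambda s: tuple(t.strip() for t in str(s).split(",") if t.strip()))
    return df
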