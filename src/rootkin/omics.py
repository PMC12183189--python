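"""Differential-abundance statistics for metabolite and transcript tables.

Metabolite preprocessing follows the locked chain

    impute (per-feature observed minimum) -> median scale -> natural log

after which group differences are tested per feature and region with
Welch's unequal-variance t-test, corrected by Benjamini-Hochberg FDR
within each region.  A metabolite is differentially accumulated (DAM)
when p < 0.05, q < 0.10 and the WD/WW fold change is >= 1.5 in either
direction.  Transcript tables arrive as per-region log2 fold changes and
are tiered at |log2FC| >= 2 and >= 1 (DATs); transcription factors are
additionally gated on a mean-count floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .config import REGIONS, AnalysisThresholds

__all__ = [
    "AbundanceMatrix",
    "OmicsError",
    "median_scale",
    "impute_min",
    "ln_transform",
    "preprocess",
    "welch_test",
    "bh_fdr",
    "fold_change",
    "differential_analysis",
    "call_dams",
    "count_dats",
    "tf_filter",
    "pca_variance",
]

PREPROCESS_ORDER = ("impute", "scale", "ln")


class OmicsError(ValueError):
    pass


@dataclass
class AbundanceMatrix:
    """Feature-by-sample abundance table with sample metadata.

    ``values``: DataFrame, features in rows, samples in columns; missing
    entries are NaN and raw abundances are non-negative.  ``samples``:
    DataFrame indexed by sample id with columns ``treatment`` (WW/WD),
    ``region`` (R1/R2/R3) and ``replicate``.  ``history`` records the
    preprocessing steps already applied.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    history: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise OmicsError("sample metadata must be indexed by the value columns, in order")
        for col in ("treatment", "region", "replicate"):
            if col not in self.samples.columns:
                raise OmicsError(f"sample metadata lacks the {col!r} column")
        if "ln" not in self.history and np.any(self.values.to_numpy() < 0):
            raise OmicsError("raw abundances must be non-negative")

    def group(self, treatment: str, region: str) -> pd.DataFrame:
        mask = (self.samples["treatment"] == treatment) & (self.samples["region"] == region)
        return self.values.loc[:, mask.to_numpy()]

    def _replace(self, values: pd.DataFrame, step: str) -> "AbundanceMatrix":
        return AbundanceMatrix(values, self.samples, self.history + (step,))


def _check_observed(values: pd.DataFrame) -> None:
    all_missing = values.isna().all(axis=1)
    if all_missing.any():
        names = ", ".join(map(str, values.index[all_missing][:5]))
        raise OmicsError(f"feature(s) with no observed value: {names}")


def median_scale(m: AbundanceMatrix) -> AbundanceMatrix:
    """Divide each feature by its median over observed values."""
    _check_observed(m.values)
    med = m.values.median(axis=1, skipna=True)
    if np.any(med.to_numpy() <= 0):
        raise OmicsError("median scaling requires positive per-feature medians")
    return m._replace(m.values.div(med, axis=0), "scale")


def impute_min(m: AbundanceMatrix) -> AbundanceMatrix:
    """Replace missing cells of each feature by its observed minimum."""
    _check_observed(m.values)
    mins = m.values.min(axis=1, skipna=True)
    values = m.values.apply(lambda row: row.fillna(mins[row.name]), axis=1)
    return m._replace(values, "impute")


def ln_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    """Elementwise natural log (requires strictly positive values)."""
    arr = m.values.to_numpy()
    if np.any(~np.isnan(arr) & (arr <= 0)):
        raise OmicsError("ln transform requires positive values; impute and scale first")
    return m._replace(np.log(m.values), "ln")


def preprocess(m: AbundanceMatrix,
               order: tuple[str, ...] = PREPROCESS_ORDER) -> AbundanceMatrix:
    """Run the preprocessing chain; warns if the locked order is changed."""
    if tuple(order) != PREPROCESS_ORDER:
        warnings.warn(
            f"preprocessing order {order} deviates from the locked chain "
            f"{PREPROCESS_ORDER}; results will differ", stacklevel=2)
    steps = {"impute": impute_min, "scale": median_scale, "ln": ln_transform}
    for name in order:
        m = steps[name](m)
    return m


def welch_test(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of freedom
    and a two-sided p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise OmicsError("need >= 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise OmicsError("both group variances are zero")
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa ** 2 / (a.size - 1) + sb ** 2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise OmicsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(wd, ww, geometric: bool = False) -> float:
    """WD/WW fold change on the (pre-log) preprocessed scale.

    Defaults to the ratio of arithmetic means; ``geometric=True`` uses the
    ratio of geometric means instead.
    """
    wd = np.asarray(wd, dtype=float)
    ww = np.asarray(ww, dtype=float)
    if geometric:
        if np.any(wd <= 0) or np.any(ww <= 0):
            raise OmicsError("geometric fold change requires positive values")
        return float(np.exp(np.log(wd).mean() - np.log(ww).mean()))
    mww = ww.mean()
    if mww <= 0:
        raise OmicsError("WW mean must be positive")
    return float(wd.mean() / mww)


def differential_analysis(m: AbundanceMatrix,
                          thresholds: AnalysisThresholds = AnalysisThresholds(),
                          regions=REGIONS, geometric_fc: bool = False) -> pd.DataFrame:
    """Full DAM pipeline: preprocess, test, adjust and gate per region.

    Expects a raw matrix (no preprocessing applied).  Returns a tidy
    DataFrame with one row per feature x region and columns ``feature,
    region, fc, log2fc, t, df, p, q, significant``.  BH adjustment is
    applied within each region across features.
    """
    if m.history:
        raise OmicsError("differential_analysis expects a raw (unprocessed) matrix")
    scaled = median_scale(impute_min(m))
    logged = ln_transform(scaled)
    rows = []
    for region in regions:
        wd_ln = logged.group("WD", region)
        ww_ln = logged.group("WW", region)
        wd_sc = scaled.group("WD", region)
        ww_sc = scaled.group("WW", region)
        if wd_ln.shape[1] < 2 or ww_ln.shape[1] < 2:
            raise OmicsError(f"need >= 2 replicates per treatment in {region}")
        pvals = []
        for feat in m.values.index:
            a = wd_ln.loc[feat].to_numpy()
            b = ww_ln.loc[feat].to_numpy()
            try:
                t, df, p = welch_test(a, b)
            except OmicsError:  # zero variance in both groups, unequal means
                t, df, p = np.inf, float(a.size + b.size - 2), 0.0
            fc = fold_change(wd_sc.loc[feat].to_numpy(), ww_sc.loc[feat].to_numpy(),
                             geometric=geometric_fc)
            rows.append({"feature": feat, "region": region, "fc": fc,
                         "log2fc": np.log2(fc) if fc > 0 else -np.inf,
                         "t": t, "df": df, "p": p})
            pvals.append(p)
        qvals = bh_fdr(pvals)
        for row, q in zip(rows[-len(pvals):], qvals):
            row["q"] = q
    table = pd.DataFrame(rows)
    return call_dams(table, thresholds)


def call_dams(diff: pd.DataFrame,
              thresholds: AnalysisThresholds = AnalysisThresholds()) -> pd.DataFrame:
    """Gate a differential table: p < 0.05, q < 0.10 and two-sided FC >= 1.5."""
    for col in ("p", "q", "fc"):
        if col not in diff.columns:
            raise OmicsError(f"differential table lacks the {col!r} column")
    fc = diff["fc"].to_numpy()
    passed = (
        (diff["p"].to_numpy() < thresholds.dam_p)
        & (diff["q"].to_numpy() < thresholds.dam_q)
        & ((fc >= thresholds.dam_fc) | (fc <= 1.0 / thresholds.dam_fc))
    )
    out = diff.copy()
    out["significant"] = passed
    return out


def count_dats(diff: pd.DataFrame, tiers=(2.0, 1.0), regions=REGIONS) -> pd.DataFrame:
    """Tiered up/down counts of a per-region log2FC table.

    ``diff`` needs ``region`` and ``log2fc`` columns.  Returns a DataFrame
    indexed by (region, tier) with columns ``total, up, down``; tier-1
    counts are cumulative and therefore >= tier-2 counts.
    """
    if "log2fc" not in diff.columns or "region" not in diff.columns:
        raise OmicsError("table needs 'region' and 'log2fc' columns")
    rows = []
    for region in regions:
        lfc = diff.loc[diff["region"] == region, "log2fc"].to_numpy()
        for tier in tiers:
            up = int((lfc >= tier).sum())
            down = int((lfc <= -tier).sum())
            rows.append({"region": region, "tier": tier, "total": up + down,
                         "up": up, "down": down})
    return pd.DataFrame(rows).set_index(["region", "tier"])


def tf_filter(diff: pd.DataFrame, threshold: float = 1.2, min_count: float = 5.0,
              two_sided: bool = True) -> pd.DataFrame:
    """Transcription-factor gate: |log2FC| >= threshold and count floor.

    ``diff`` needs ``log2fc`` and ``max_mean_count`` (the largest mean
    transcript count over region-by-treatment combinations) columns.  The
    threshold is applied two-sided by default; ``two_sided=False``
    restricts to accumulating (positive log2FC) features.
    """
    for col in ("log2fc", "max_mean_count"):
        if col not in diff.columns:
            raise OmicsError(f"table needs the {col!r} column")
    lfc = diff["log2fc"].to_numpy()
    hit = (np.abs(lfc) >= threshold) if two_sided else (lfc >= threshold)
    hit &= diff["max_mean_count"].to_numpy() >= min_count
    return diff.loc[hit]


def pca_variance(m: AbundanceMatrix, n_pc: int = 2,
                 scale: bool = False) -> tuple[np.ndarray, pd.DataFrame]:
    """Centered PCA over samples; returns variance fractions and scores.

    Samples are observations and features variables.  Fractions are the
    per-PC shares of total variance (non-increasing, summing to <= 1);
    scores are returned per sample with the metadata attached.
    """
    X = m.values.to_numpy().T
    if np.isnan(X).any():
        raise OmicsError("PCA requires a complete matrix; impute first")
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise OmicsError("need >= 2 samples and >= 2 features")
    if np.allclose(X, X[0]):
        raise OmicsError("constant matrix has no principal components")
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    n_pc = min(n_pc, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_pc, svd_solver="full")  # exact and deterministic
    scores = pca.fit_transform(X)
    frac = pca.explained_variance_ratio_
    out = pd.DataFrame(scores, index=m.samples.index,
                       columns=[f"PC{i + 1}" for i in range(n_pc)])
    out = pd.concat([out, m.samples], axis=1)
    return frac, out
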