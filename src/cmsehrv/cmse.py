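"""Composite multiscale entropy: coarse-graining, curves, curve parameters.

The multiscale view of an RR series maps it, for each scale factor tau, to
tau offset coarse-grained series (non-overlapping windows of length tau,
averaged, starting at offset k = 1..tau).  The composite variant evaluates
the base entropy on every offset series and averages, which stabilises the
estimate at large scales where each offset series is short.

Five per-estimator curve parameters summarise the curve E(tau), tau=1..20:
the entropy at scale 1 and at scale 5, the least-squares slope over scales
1-5, and the areas under the curve over scales 1-5 (short-term complexity
index) and 6-20 (long-term complexity index).  With 15 base estimators this
yields the 75 multiscale HRV features; age, sex and hypertension-history
years complete the 78-column per-hour feature matrix.

Tolerance convention: for estimators whose ``r`` is a fraction of SD, ``r``
is resolved in absolute units from the scale-1 series and held fixed across
scales.  Coarse-graining contracts the variance of an uncorrelated series by
1/tau, so a fixed tolerance makes white-noise entropy fall with scale while
1/f-type series retain complexity at long scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import entropy as _ent

__all__ = [
    "CoarseGrainedSeries",
    "CMSECurve",
    "CMSEParameters",
    "FEATURE_SUFFIXES",
    "coarse_grain",
    "cmse_value",
    "cmse_curve",
    "cmse_parameters",
    "feature_names",
    "features_for_series",
    "build_feature_matrix",
]

FEATURE_SUFFIXES: tuple[str, ...] = ("sc1", "sc5", "s15", "a15", "a620")
COVARIATE_COLUMNS: tuple[str, ...] = ("age", "sex", "history_years")
RESPONSE_COLUMN = "lvef_pct"

DEFAULT_MAX_SCALE = 20
DEFAULT_MIN_COARSE_POINTS = 50


@dataclass(frozen=True)
class CoarseGrainedSeries:
    values: np.ndarray
    tau: int
    k: int
    parent_length: int


@dataclass(frozen=True)
class CMSECurve:
    estimator: str
    params: dict
    values: np.ndarray  # entropy per tau = 1..max_scale; NaN where undefined

    @property
    def max_scale(self) -> int:
        return self.values.size

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.values).sum())


@dataclass(frozen=True)
class CMSEParameters:
    """Curve parameters; fields are None when required scales are undefined."""

    scale1: float | None
    scale5: float | None
    slope_1_5: float | None
    area_1_5: float | None
    area_6_20: float | None

    def as_dict(self) -> dict:
        nan = float("nan")
        return {
            "sc1": self.scale1 if self.scale1 is not None else nan,
            "sc5": self.scale5 if self.scale5 is not None else nan,
            "s15": self.slope_1_5 if self.slope_1_5 is not None else nan,
            "a15": self.area_1_5 if self.area_1_5 is not None else nan,
            "a620": self.area_6_20 if self.area_6_20 is not None else nan,
        }


def coarse_grain(x, tau: int, k: int = 1) -> CoarseGrainedSeries:
    """Offset-k coarse-grained series at scale tau (both 1-based).

    y_j is the mean of x over indices (j-1)*tau + k .. j*tau + k - 1 (1-based)
    for every full window; the result has floor((N - k + 1)/tau) points.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if tau < 1:
        raise ValueError("scale factor tau must be >= 1")
    if k < 1 or k > tau:
        raise ValueError(f"offset k={k} must satisfy 1 <= k <= tau={tau}")
    if tau > n:
        raise ValueError(f"tau={tau} exceeds series length {n}")
    n_windows = (n - k + 1) // tau
    trimmed = x[k - 1 : k - 1 + n_windows * tau]
    values = trimmed.reshape(n_windows, tau).mean(axis=1)
    return CoarseGrainedSeries(values=values, tau=tau, k=k, parent_length=n)


def _resolved(x: np.ndarray, estimator: str, params: dict | None) -> dict:
    """Resolve defaults and freeze a fractional tolerance in absolute units
    from the parent (scale-1) series."""
    resolved = _ent.default_params(estimator)
    if params:
        resolved.update(params)
    if _ent.uses_tolerance(estimator) and not resolved.get("r_absolute", False):
        resolved["r"] = float(resolved["r"]) * float(np.std(x))
        resolved["r_absolute"] = True
    return resolved


def cmse_value(x, estimator: str, params: dict | None = None,
               tau: int = 1) -> float:
    """Composite entropy at one scale: mean of the base estimator over the
    tau offset coarse-grained series, averaging the defined offsets; NaN when
    every offset is undefined."""
    x = np.asarray(x, dtype=float)
    resolved = _resolved(x, estimator, params)
    func = _ent.estimator_function(estimator)
    vals = np.array([
        func(coarse_grain(x, tau, k).values, **resolved)
        for k in range(1, tau + 1)
    ])
    if np.all(np.isnan(vals)):
        return float("nan")
    return float(np.nanmean(vals))


def cmse_curve(x, estimator: str, params: dict | None = None,
               max_scale: int = DEFAULT_MAX_SCALE,
               min_len: int = DEFAULT_MIN_COARSE_POINTS) -> CMSECurve:
    """Composite multiscale curve up to ``max_scale``.

    A scale is declared undefined (NaN) when the coarse-grained series would
    have fewer than ``min_len`` points; an hour of RR data (~3600 beats)
    leaves ~180 points at scale 20, comfortably above the default of 50.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    resolved = _resolved(x, estimator, params)
    func = _ent.estimator_function(estimator)
    values = np.full(max_scale, np.nan)
    for tau in range(1, max_scale + 1):
        if tau > n or n // tau < min_len:
            continue
        vals = np.array([
            func(coarse_grain(x, tau, k).values, **resolved)
            for k in range(1, tau + 1)
        ])
        if not np.all(np.isnan(vals)):
            values[tau - 1] = np.nanmean(vals)
    return CMSECurve(estimator=estimator, params=resolved, values=values)


def cmse_parameters(curve: CMSECurve,
                    ci_convention: str = "trapezoid") -> CMSEParameters:
    """The five curve parameters.

    ``ci_convention`` selects the complexity-index quadrature: "trapezoid"
    (area under the piecewise-linear curve over integer scales, widths 4 and
    14) or "sum" (plain sum of entropies over the scale range).
    """
    if ci_convention not in ("trapezoid", "sum"):
        raise ValueError("ci_convention must be 'trapezoid' or 'sum'")
    e = curve.values
    if e.size < 20:
        raise ValueError("curve must cover at least 20 scales")
    taus = np.arange(1, e.size + 1)

    short_ok = np.all(np.isfinite(e[0:5]))
    long_ok = np.all(np.isfinite(e[5:20]))

    scale1 = float(e[0]) if np.isfinite(e[0]) else None
    scale5 = float(e[4]) if np.isfinite(e[4]) else None
    if short_ok:
        slope = float(np.polyfit(taus[0:5], e[0:5], 1)[0])
        if ci_convention == "trapezoid":
            area15 = float(np.trapezoid(e[0:5], taus[0:5]))
        else:
            area15 = float(e[0:5].sum())
    else:
        slope = None
        area15 = None
    if long_ok:
        if ci_convention == "trapezoid":
            area620 = float(np.trapezoid(e[5:20], taus[5:20]))
        else:
            area620 = float(e[5:20].sum())
    else:
        area620 = None
    return CMSEParameters(scale1=scale1, scale5=scale5, slope_1_5=slope,
                          area_1_5=area15, area_6_20=area620)


def feature_names(estimators: Sequence[str] | None = None) -> list[str]:
    """The multiscale HRV feature vocabulary: '{estimator}_{suffix}'."""
    estimators = tuple(estimators) if estimators else _ent.ESTIMATOR_NAMES
    return [f"{est}_{suf}" for est in estimators for suf in FEATURE_SUFFIXES]


def features_for_series(x, estimators: Sequence[str] | None = None,
                        max_scale: int = DEFAULT_MAX_SCALE,
                        min_len: int = DEFAULT_MIN_COARSE_POINTS,
                        ci_convention: str = "trapezoid") -> dict[str, float]:
    """All multiscale features for one series (NaN marks missing).

    Equivalent to :func:`cmse_curve` + :func:`cmse_parameters` per estimator,
    but the offset coarse-grained series are computed once and shared across
    estimators.
    """
    estimators = tuple(estimators) if estimators else _ent.ESTIMATOR_NAMES
    x = np.asarray(x, dtype=float)
    n = x.size
    offsets: dict[int, list[np.ndarray]] = {}
    for tau in range(1, max_scale + 1):
        if tau > n or n // tau < min_len:
            continue
        offs = []
        for k in range(1, tau + 1):
            n_windows = (n - k + 1) // tau
            offs.append(x[k - 1: k - 1 + n_windows * tau]
                        .reshape(n_windows, tau).mean(axis=1))
        offsets[tau] = offs
    out: dict[str, float] = {}
    for est in estimators:
        resolved = _resolved(x, est, None)
        func = _ent.estimator_function(est)
        values = np.full(max_scale, np.nan)
        for tau, offs in offsets.items():
            vals = np.array([func(o, **resolved) for o in offs])
            if not np.all(np.isnan(vals)):
                values[tau - 1] = np.nanmean(vals)
        params = cmse_parameters(
            CMSECurve(estimator=est, params=resolved, values=values),
            ci_convention=ci_convention)
        for suf, val in params.as_dict().items():
            out[f"{est}_{suf}"] = val
    return out


def curves_long_frame(rr: pd.DataFrame,
                      estimators: Sequence[str] | None = None,
                      max_scale: int = DEFAULT_MAX_SCALE,
                      min_len: int = DEFAULT_MIN_COARSE_POINTS,
                      ) -> pd.DataFrame:
    """Batch runner: multiscale curves for every subject-hour, long format.

    ``rr`` is long-format with columns (subject_id, hour, rr_s); the result
    has one row per (subject, hour, estimator, scale) with the composite
    entropy value (NaN where undefined).
    """
    estimators = tuple(estimators) if estimators else _ent.ESTIMATOR_NAMES
    rows = []
    for (subj, hour), grp in rr.groupby(["subject_id", "hour"], sort=True):
        x = grp["rr_s"].to_numpy()
        for est in estimators:
            curve = cmse_curve(x, est, max_scale=max_scale, min_len=min_len)
            for tau, value in enumerate(curve.values, start=1):
                rows.append((subj, int(hour), est, tau, value))
    return pd.DataFrame(rows, columns=["subject_id", "hour", "estimator",
                                       "scale", "value"])


def build_feature_matrix(rr: pd.DataFrame, covariates: pd.DataFrame,
                         hours: Iterable[int] | None = None,
                         estimators: Sequence[str] | None = None,
                         max_scale: int = DEFAULT_MAX_SCALE,
                         min_len: int = DEFAULT_MIN_COARSE_POINTS,
                         ci_convention: str = "trapezoid",
                         ) -> dict[int, pd.DataFrame]:
    """Per-hour feature matrices for a cohort.

    ``rr`` is long-format with columns (subject_id, hour, rr_s); ``covariates``
    has one row per subject with (subject_id, age, sex, history_years,
    lvef_pct).  Each returned frame is indexed by subject_id with the 75
    multiscale columns, the 3 covariates, and the LVEF response; a subject
    missing an hour gets an all-NaN multiscale row with covariates present.
    """
    estimators = tuple(estimators) if estimators else _ent.ESTIMATOR_NAMES
    ms_cols = feature_names(estimators)
    cov = covariates.set_index("subject_id")
    subjects = cov.index.tolist()
    if hours is None:
        hours = sorted(rr["hour"].unique())
    grouped = {key: grp["rr_s"].to_numpy()
               for key, grp in rr.groupby(["subject_id", "hour"], sort=False)}
    matrices: dict[int, pd.DataFrame] = {}
    for hour in hours:
        rows = []
        for subj in subjects:
            series = grouped.get((subj, hour))
            if series is None or series.size == 0:
                rows.append({c: float("nan") for c in ms_cols})
            else:
                rows.append(features_for_series(
                    series, estimators, max_scale=max_scale, min_len=min_len,
                    ci_convention=ci_convention))
        fm = pd.DataFrame(rows, index=pd.Index(subjects, name="subject_id"),
                          columns=ms_cols)
        for c in COVARIATE_COLUMNS:
            fm[c] = cov[c]
        fm[RESPONSE_COLUMN] = cov[RESPONSE_COLUMN]
        matrices[int(hour)] = fm
    return matrices
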