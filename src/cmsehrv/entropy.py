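"""Fifteen entropy estimators for RR-interval (and general numeric) series.

Each estimator is a pure function of a 1-D numeric series plus a few
hyperparameters, and doubles as the base measure for composite multiscale
entropy (:mod:`cmsehrv.cmse`).  The registry maps the field's short names
(PsdEn, Een, ApEn, SampEn, FuzzyEn, PEn, Aen, BubbEn, DispEn, DistEn, GdEn,
IncrEn, PhaseEn, SlopEn, SyDyEn) to implementations.

Conventions
-----------
* ApEn / SampEn / FuzzyEn are reported in nats (natural log of conditional
  match probabilities); all Shannon-form estimators use log2 and report bits.
* ``0 * log 0 := 0`` everywhere.  Degenerate (constant) inputs return 0
  wherever the pattern distribution is a point mass: coarse-graining at large
  scale can legitimately produce near-constant series and a hard failure
  there would poison whole feature columns.
* Results that are genuinely undefined (e.g. SampEn with zero similar-pair
  counts, or a series shorter than the estimator's minimum) are returned as
  NaN and propagate as missing feature values for downstream imputation.
* Tolerance ``r`` is interpreted as a fraction of the series SD unless
  ``r_absolute=True``; the multiscale driver freezes ``r`` in absolute units
  from the scale-1 series, which is what makes the white-noise multiscale
  curve decline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import _kernels

__all__ = [
    "ESTIMATOR_NAMES",
    "EntropyParams",
    "EntropyValue",
    "RegistryError",
    "entropy",
    "default_params",
    "estimator_function",
]


class RegistryError(KeyError):
    """Raised when an unknown estimator name is requested."""


@dataclass(frozen=True)
class EntropyParams:
    """Resolved hyperparameters for one estimator evaluation.

    ``m`` embedding dimension, ``r`` similarity tolerance (fraction of SD
    unless ``r_absolute``), ``delay`` embedding lag, ``c`` alphabet size,
    ``extra`` method-specific settings (fuzzy exponent, slope thresholds,
    histogram bins, grid size, segment count, ...).
    """

    m: int | None = None
    r: float | None = None
    delay: int | None = None
    c: int | None = None
    r_absolute: bool = False
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class EntropyValue:
    value: float
    estimator: str
    params: dict
    n_used: int

    @property
    def defined(self) -> bool:
        return math.isfinite(self.value)


def _shannon_bits(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _resolve_r(x: np.ndarray, r: float, r_absolute: bool) -> float:
    return float(r) if r_absolute else float(r) * float(np.std(x))


# ---------------------------------------------------------------------------
# spectral / energy


def psd_entropy(x: np.ndarray) -> float:
    """Shannon entropy (bits) of the normalised periodogram over positive
    frequencies, computed on the mean-removed series."""
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        return float("nan")
    xm = x - x.mean()
    power = np.abs(np.fft.rfft(xm)) ** 2
    power = power[1:]  # positive frequencies (DC removed with the mean)
    total = power.sum()
    if total <= 0:
        return 0.0
    return _shannon_bits(power)


def energy_entropy(x: np.ndarray, K: int = 10) -> float:
    """Entropy (bits) of the energy distribution over K equal-length
    segments; remainder samples beyond K*floor(n/K) are dropped."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < K:
        return float("nan")
    seg_len = n // K
    seg = x[: seg_len * K].reshape(K, seg_len)
    e = (seg ** 2).sum(axis=1)
    if e.sum() <= 0:
        return 0.0
    return _shannon_bits(e)


# ---------------------------------------------------------------------------
# template-matching family (nats)


def approximate_entropy(x: np.ndarray, m: int = 2, r: float = 0.2,
                        r_absolute: bool = False) -> float:
    x = np.ascontiguousarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        return float("nan")
    ra = _resolve_r(x, r, r_absolute)
    phi_m = _kernels.apen_phi(x, m, ra)
    phi_m1 = _kernels.apen_phi(x, m + 1, ra)
    return float(phi_m - phi_m1)


def sample_entropy(x: np.ndarray, m: int = 2, r: float = 0.2,
                   r_absolute: bool = False) -> float:
    x = np.ascontiguousarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        return float("nan")
    ra = _resolve_r(x, r, r_absolute)
    if ra == 0.0 and not np.all(x == x[0]):
        return float("nan")  # zero tolerance on a non-constant series
    A, B = _kernels.sampen_counts(x, m, ra)
    if A == 0 or B == 0:
        return float("nan")
    return float(-np.log(A / B))


def fuzzy_entropy(x: np.ndarray, m: int = 2, r: float = 0.2,
                  n_exp: float = 2.0, r_absolute: bool = False) -> float:
    x = np.ascontiguousarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        return float("nan")
    ra = _resolve_r(x, r, r_absolute)
    if ra <= 0.0:
        # constant series: all memberships 1 at both lengths
        return 0.0 if np.all(x == x[0]) else float("nan")
    # membership exp(-(d/r)^n): scale-invariant when r is a fraction of SD
    nt = n - m  # same template range for both lengths
    u_m = sliding_window_view(x, m)[:nt]
    u_m1 = sliding_window_view(x, m + 1)[:nt]
    u_m = np.ascontiguousarray(u_m - u_m.mean(axis=1, keepdims=True))
    u_m1 = np.ascontiguousarray(u_m1 - u_m1.mean(axis=1, keepdims=True))
    mu_m = _kernels.fuzzy_mean_membership(u_m, ra, float(n_exp))
    mu_m1 = _kernels.fuzzy_mean_membership(u_m1, ra, float(n_exp))
    if mu_m <= 0 or mu_m1 <= 0:
        return float("nan")
    return float(np.log(mu_m) - np.log(mu_m1))


# ---------------------------------------------------------------------------
# ordinal / symbolic family (bits)


def permutation_entropy(x: np.ndarray, m: int = 3, delay: int = 1) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < m * delay + 1:
        return float("nan")
    return float(_kernels.perm_entropy(np.ascontiguousarray(x), m, delay))


def attention_entropy(x: np.ndarray) -> float:
    """Mean Shannon entropy (bits) of the four key-point interval streams
    (max-max, min-min, max-next-min, min-next-max); strict local extrema."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 8:
        return float("nan")
    return float(_kernels.attention_entropy_core(np.ascontiguousarray(x)))


def bubble_entropy(x: np.ndarray, m: int = 10) -> float:
    """Renyi-2 entropy growth of bubble-sort swap counts from window size m
    to m+1, normalised by ln((m+1)/(m-1))."""
    x = np.asarray(x, dtype=float)
    if x.size < m + 2:
        return float("nan")

    xc = np.ascontiguousarray(x)
    h_m = _kernels.bubble_renyi2(xc, m)
    h_m1 = _kernels.bubble_renyi2(xc, m + 1)
    return float((h_m1 - h_m) / math.log((m + 1) / (m - 1)))


def dispersion_entropy(x: np.ndarray, m: int = 2, c: int = 6,
                       delay: int = 1) -> float:
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < (m - 1) * delay + 2:
        return float("nan")
    sd = x.std()
    if sd == 0 or np.all(x == x[0]):
        return 0.0
    return float(_kernels.dispersion_entropy_core(
        np.ascontiguousarray(x), m, c, delay, float(x.mean()), float(sd)))


def distribution_entropy(x: np.ndarray, m: int = 2, B: int = 64) -> float:
    """Entropy of the pairwise Chebyshev-distance histogram between
    m-embeddings, normalised by log2(B) to [0, 1]."""
    x = np.ascontiguousarray(x, dtype=float)
    if x.size < m + 2:
        return float("nan")
    counts, dmax = _kernels.disten_histogram(x, m, int(B))
    if dmax == 0.0:
        return 0.0
    return _shannon_bits(counts) / math.log2(B)


def gridded_distribution_entropy(x: np.ndarray, grid: int = 10) -> float:
    """Entropy (bits) of the occupancy of Poincare points (x_i, x_{i+1}) on a
    grid x grid lattice spanning [min, max]^2."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return float("nan")
    return float(_kernels.gridded_distribution_entropy_core(
        np.ascontiguousarray(x), grid))


def incremental_entropy(x: np.ndarray, m: int = 2, R: int = 4) -> float:
    """Entropy (bits) of words of m consecutive (sign, magnitude-quantile)
    increment symbols; magnitude quantised against SD of the increments."""
    x = np.asarray(x, dtype=float)
    if x.size - 1 < m:
        return float("nan")
    return float(_kernels.incremental_entropy_core(
        np.ascontiguousarray(x), m, R))


def phase_entropy(x: np.ndarray, sectors: int = 8) -> float:
    """Entropy (bits) of the angular distribution of second-order difference
    plot points, each sector weighted by its share of radial magnitude."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        return float("nan")
    return float(_kernels.phase_entropy_core(np.ascontiguousarray(x),
                                              sectors))


def slope_entropy(x: np.ndarray, m: int = 3, gamma: float = 1.0,
                  delta: float = 0.001) -> float:
    """Entropy (bits) of words of m-1 slope symbols; differences classified
    into 5 classes by thresholds +-delta and +-gamma."""
    x = np.asarray(x, dtype=float)
    if x.size < m + 1:
        return float("nan")
    return float(_kernels.slope_entropy_core(np.ascontiguousarray(x), m,
                                              float(gamma), float(delta)))


def symbolic_dynamic_entropy(x: np.ndarray, m: int = 2, c: int = 6) -> float:
    """Entropy (bits) of the joint (length-m state pattern, next symbol)
    distribution under a maximum-entropy (equal-frequency) partition."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        return float("nan")
    if np.all(x == x[0]):
        return 0.0
    return float(_kernels.symbolic_dynamic_entropy_core(
        np.ascontiguousarray(x), m, c))


# ---------------------------------------------------------------------------
# registry

_Estimator = Callable[..., float]

# name -> (function, default params, uses r-as-fraction-of-SD)
_REGISTRY: dict[str, tuple[_Estimator, dict, bool]] = {
    "PsdEn": (psd_entropy, {}, False),
    "Een": (energy_entropy, {"K": 10}, False),
    "ApEn": (approximate_entropy, {"m": 2, "r": 0.2}, True),
    "SampEn": (sample_entropy, {"m": 2, "r": 0.2}, True),
    "FuzzyEn": (fuzzy_entropy, {"m": 2, "r": 0.2, "n_exp": 2.0}, True),
    "PEn": (permutation_entropy, {"m": 3, "delay": 1}, False),
    "Aen": (attention_entropy, {}, False),
    "BubbEn": (bubble_entropy, {"m": 10}, False),
    "DispEn": (dispersion_entropy, {"m": 2, "c": 6, "delay": 1}, False),
    "DistEn": (distribution_entropy, {"m": 2, "B": 64}, False),
    "GdEn": (gridded_distribution_entropy, {"grid": 10}, False),
    "IncrEn": (incremental_entropy, {"m": 2, "R": 4}, False),
    "PhaseEn": (phase_entropy, {"sectors": 8}, False),
    "SlopEn": (slope_entropy, {"m": 3, "gamma": 1.0, "delta": 0.001}, False),
    "SyDyEn": (symbolic_dynamic_entropy, {"m": 2, "c": 6}, False),
}

ESTIMATOR_NAMES: tuple[str, ...] = tuple(_REGISTRY)


def estimator_function(name: str) -> _Estimator:
    try:
        return _REGISTRY[name][0]
    except KeyError:
        raise RegistryError(f"unknown entropy estimator {name!r}; "
                            f"known: {', '.join(ESTIMATOR_NAMES)}") from None


def default_params(name: str) -> dict:
    try:
        return dict(_REGISTRY[name][1])
    except KeyError:
        raise RegistryError(f"unknown entropy estimator {name!r}") from None


def uses_tolerance(name: str) -> bool:
    try:
        return _REGISTRY[name][2]
    except KeyError:
        raise RegistryError(f"unknown entropy estimator {name!r}") from None


def entropy(x, estimator: str, params: dict | None = None) -> EntropyValue:
    """Evaluate a registered estimator on a finite numeric series.

    Returns an :class:`EntropyValue` whose ``value`` is NaN when the result
    is undefined (series too short, zero similar-pair counts, ...).
    """
    func = estimator_function(estimator)
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    resolved = default_params(estimator)
    if params:
        unknown = set(params) - set(resolved) - {"r_absolute"}
        if unknown:
            raise ValueError(f"unknown parameters for {estimator}: {unknown}")
        resolved.update(params)
    value = func(x, **resolved)
    return EntropyValue(value=float(value), estimator=estimator,
                        params=resolved, n_used=x.size)
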