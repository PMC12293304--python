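"""Synthetic cohorts: circadian RR series, rendered ECG, covariates, and an
LVEF response planted as a known linear function of multiscale entropy
features.

The generator stands in for a 24 h Holter cohort so every downstream stage
is testable without patient data.  Each subject-hour RR series is a
circadian-modulated mean (cosine in clock hour) plus a noise mixture of a
1/f-type component (complexity retained at long scales, dominant at night)
and white noise, with optional planted ectopic short-long pairs.  An ECG can
be rendered from any RR series as a train of Gaussian QRS bumps plus
configurable baseline wander, powerline and broadband artifacts, with the
planted R-peak positions recorded as ground truth.

The LVEF response is planted on *cohort-standardised, actually computed*
multiscale features, so the regression harness's recovery tests measure the
harness, not an idealised shortcut: coefficients are in percent LVEF per
feature SD and independent of entropy units.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cmse
from .preprocess import ECGSignal, correct_rr_intervals, RRSeries, FLAG_CORRECTED

__all__ = [
    "CohortSpec",
    "ArtifactSpec",
    "TruthManifest",
    "CohortData",
    "generate_rr_hour",
    "render_ecg",
    "generate_cohort",
]


def _default_noise_mix() -> dict[int, float]:
    # 1/f weight peaks at night (complexity highest during sleep) and dips
    # in the afternoon; acrophase aligned with the RR acrophase default.
    return {h: round(0.6 + 0.3 * math.cos(2 * math.pi * (h - 4) / 24), 4)
            for h in range(1, 25)}


def _default_lvef_coeffs() -> dict[str, float]:
    # three designated evening-hour features from distinct estimators,
    # percent LVEF per cohort SD of the feature
    return {"SampEn_sc5": 4.0, "FuzzyEn_a15": 3.5, "PEn_sc1": 3.0}


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults emulate the target population: 200 hypertensive adults, 24
    hourly segments, mean RR 0.85 s with a 0.10 s circadian swing peaking at
    04:00, beat-to-beat noise SD 50 ms, and an LVEF of 65% +- a planted
    3-feature signal and 4% residual noise (covariates per the cohort table:
    age 59.4 +- 9.3 y, 51% male, history 7.5 +- 6.8 y).
    """

    n_subjects: int = 200
    seed: int = 0
    hours: tuple[int, ...] = tuple(range(1, 25))
    mean_rr_s: float = 0.85
    circadian_amplitude_s: float = 0.10
    acrophase_hour: float = 4.0
    noise_mix_by_hour: dict[int, float] = field(default_factory=_default_noise_mix)
    noise_sd_s: float = 0.05
    ectopic_rate: float = 0.0
    hour_duration_s: float = 3600.0
    lvef_intercept: float = 65.0
    lvef_coeffs: dict[str, float] = field(default_factory=_default_lvef_coeffs)
    lvef_noise_sd: float = 4.0
    lvef_feature_hour: int = 21

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("cohort needs at least 2 subjects")
        if self.mean_rr_s <= 0:
            raise ValueError("mean_rr_s must be positive")
        if self.lvef_noise_sd < 0:
            raise ValueError("lvef_noise_sd must be non-negative")
        if any(not (0.0 <= w <= 1.0) for w in self.noise_mix_by_hour.values()):
            raise ValueError("noise mixture weights must lie in [0, 1]")
        if any(h < 1 or h > 24 for h in self.hours):
            raise ValueError("hours must be clock-hour indices in 1..24")
        known = set(cmse.feature_names())
        unknown = set(self.lvef_coeffs) - known
        if unknown:
            raise ValueError(f"unknown LVEF feature names: {sorted(unknown)}")


@dataclass
class ArtifactSpec:
    """ECG rendering artifacts (amplitudes in mV)."""

    baseline_amp_mv: float = 0.3
    baseline_freq_hz: float = 0.1
    powerline_amp_mv: float = 0.05
    powerline_freq_hz: float = 50.0
    noise_sd_mv: float = 0.02
    qrs_width_ms: float = 20.0  # Gaussian sigma ~ width/2.355 (FWHM)
    qrs_amp_mv: float = 1.0

    @classmethod
    def none(cls) -> "ArtifactSpec":
        return cls(baseline_amp_mv=0.0, powerline_amp_mv=0.0, noise_sd_mv=0.0)


@dataclass
class TruthManifest:
    """Cohort ground truth: reproducible from the spec + seed."""

    seed: int
    lvef_intercept: float
    lvef_coeffs: dict[str, float]
    lvef_noise_sd: float
    lvef_feature_hour: int
    subjects: dict[int, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = asdict(self)
        payload["subjects"] = {str(k): v for k, v in self.subjects.items()}
        return json.dumps(payload, sort_keys=True, indent=1)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


@dataclass
class CohortData:
    rr: pd.DataFrame           # subject_id, hour, beat_clock, rr_s, flag
    covariates: pd.DataFrame   # subject_id, age, sex, history_years, lvef_pct
    manifest: TruthManifest


# ---------------------------------------------------------------------------
# noise synthesis


def one_over_f_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f noise by inverse-FFT spectral shaping: amplitude
    proportional to f^(-1/2) (power ~ 1/f) with random phases."""
    nf = n // 2 + 1
    freqs = np.fft.rfftfreq(n)
    spectrum = np.zeros(nf, dtype=complex)
    amp = np.zeros(nf)
    amp[1:] = freqs[1:] ** -0.5
    spectrum = amp * (rng.standard_normal(nf) + 1j * rng.standard_normal(nf))
    spectrum[0] = 0.0
    if n % 2 == 0:
        spectrum[-1] = spectrum[-1].real
    y = np.fft.irfft(spectrum, n)
    sd = y.std()
    return y / sd if sd > 0 else y


def _hour_rng(spec: CohortSpec, subject: int, hour: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed & 0x7FFFFFFF, subject, hour])


def generate_rr_hour(spec: CohortSpec, subject: int, hour: int,
                     rng: np.random.Generator | None = None) -> RRSeries:
    """One subject-hour RR series.

    RR_i = mean + amplitude * cos(2 pi (hour - acrophase)/24) + eps_i, where
    eps mixes unit-SD 1/f and white components with hour weight w and is
    scaled to total SD ``noise_sd_s`` (the components are independent, so the
    mixture is divided by sqrt(w^2 + (1-w)^2)).  Intervals <= 0.25 s are
    re-drawn; the cumulative series is truncated at the hour duration.
    """
    if hour < 1 or hour > 24:
        raise ValueError("hour must be in 1..24")
    if rng is None:
        rng = _hour_rng(spec, subject, hour)
    base = spec.mean_rr_s + spec.circadian_amplitude_s * math.cos(
        2 * math.pi * (hour - spec.acrophase_hour) / 24)
    if base <= 0.25:
        raise ValueError("circadian parameters yield non-physiological RR")
    n = int(spec.hour_duration_s / base * 1.25) + 16
    w = float(spec.noise_mix_by_hour.get(hour, 0.5))
    if spec.noise_sd_s > 0:
        white = rng.standard_normal(n)
        pink = one_over_f_noise(n, rng)
        eps = (w * pink + (1 - w) * white) / math.sqrt(w * w + (1 - w) ** 2)
        rr = base + spec.noise_sd_s * eps
    else:
        rr = np.full(n, base)
    bad = rr <= 0.25
    while np.any(bad):  # resample offending draws from the white component
        rr[bad] = base + spec.noise_sd_s * rng.standard_normal(int(bad.sum()))
        bad = rr <= 0.25
    flags = np.zeros(n, dtype=np.int8)
    if spec.ectopic_rate > 0:
        hit = np.where(rng.random(n - 1) < spec.ectopic_rate)[0]
        last = -2
        for i in hit:
            if i <= last + 1:
                continue  # no overlapping pairs
            rr_i = rr[i]
            rr[i] = 0.6 * rr_i
            rr[i + 1] = 1.4 * rr_i
            flags[i] = flags[i + 1] = FLAG_CORRECTED
            last = i
    cum = np.cumsum(rr)
    n_keep = int(np.searchsorted(cum, spec.hour_duration_s, side="right"))
    n_keep = max(n_keep, 1)
    clock = (hour - 1) * 3600.0 + cum[:n_keep]
    return RRSeries(rr_s=rr[:n_keep], beat_clock=clock, flags=flags[:n_keep])


# ---------------------------------------------------------------------------
# ECG rendering


def render_ecg(rr: RRSeries, fs: float = 250.0,
               artifacts: ArtifactSpec | None = None,
               rng: np.random.Generator | None = None,
               start_clock: float | None = None,
               lead_in_s: float = 0.5,
               ) -> tuple[ECGSignal, np.ndarray]:
    """Render an ECG from an RR series; returns (signal, planted R indices).

    Beats are Gaussian bumps (truncated at +-3 sigma, so an artifact-free
    render is exactly zero away from the peaks) at cumulative RR times, with
    the first R-peak ``lead_in_s`` after signal start (a short lead-in keeps
    the first beat away from filter edge transients).  Optional
    baseline-wander and powerline sinusoids and white noise are added on top.
    """
    if len(rr) == 0:
        raise ValueError("cannot render ECG from an empty RR series")
    if fs < 100:
        raise ValueError("sampling rate must be at least 100 Hz")
    art = artifacts if artifacts is not None else ArtifactSpec()
    if rng is None:
        rng = np.random.default_rng(0)
    peak_times = lead_in_s + np.concatenate([[0.0], np.cumsum(rr.rr_s)])
    duration = peak_times[-1] + 0.5
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    sigma = art.qrs_width_ms / 1000.0 / 2.355  # FWHM -> sigma
    half = int(round(3 * sigma * fs))
    tmpl_t = np.arange(-half, half + 1) / fs
    template = art.qrs_amp_mv * np.exp(-0.5 * (tmpl_t / sigma) ** 2)
    peak_idx = np.round(peak_times * fs).astype(np.int64)
    for idx in peak_idx:
        lo = max(0, idx - half)
        hi = min(n, idx + half + 1)
        x[lo:hi] += template[lo - (idx - half): hi - (idx - half)]
    if art.baseline_amp_mv:
        x += art.baseline_amp_mv * np.sin(2 * np.pi * art.baseline_freq_hz * t)
    if art.powerline_amp_mv:
        x += art.powerline_amp_mv * np.sin(2 * np.pi * art.powerline_freq_hz * t)
    if art.noise_sd_mv:
        x += art.noise_sd_mv * rng.standard_normal(n)
    if start_clock is None:
        # signal start precedes the first R-peak by the lead-in
        start_clock = float(rr.beat_clock[0] - rr.rr_s[0] - lead_in_s)
    sig = ECGSignal(samples=x, fs=fs, start_clock=start_clock)
    return sig, peak_idx


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(spec: CohortSpec) -> CohortData:
    """Full cohort: RR tables, covariates with planted LVEF, truth manifest.

    The planted LVEF uses multiscale features *computed by the same code
    path* the analysis pipeline uses, on the ectopic-corrected RR series of
    ``spec.lvef_feature_hour``, standardised across the cohort:

        LVEF_s = intercept + sum_f coeff_f * z(feature_f(s)) + N(0, sd^2),

    clipped to [20, 80]%.
    """
    needed_estimators = sorted({name.rsplit("_", 1)[0]
                                for name in spec.lvef_coeffs})
    rows = []
    manifest = TruthManifest(
        seed=spec.seed, lvef_intercept=spec.lvef_intercept,
        lvef_coeffs=dict(spec.lvef_coeffs), lvef_noise_sd=spec.lvef_noise_sd,
        lvef_feature_hour=spec.lvef_feature_hour)
    planted = np.zeros((spec.n_subjects, len(spec.lvef_coeffs)))
    coeff_names = list(spec.lvef_coeffs)

    for s in range(spec.n_subjects):
        subject_entry = {"hours": {}}
        for hour in spec.hours:
            rr = generate_rr_hour(spec, s, hour)
            rows.append(pd.DataFrame({
                "subject_id": s, "hour": hour,
                "beat_clock": rr.beat_clock, "rr_s": rr.rr_s,
                "flag": rr.flags,
            }))
            subject_entry["hours"][int(hour)] = {
                "w": float(spec.noise_mix_by_hour.get(hour, 0.5)),
                "n_beats": int(len(rr)),
                "ectopic_positions": np.where(rr.flags == FLAG_CORRECTED)[0].tolist(),
            }
            if hour == spec.lvef_feature_hour and coeff_names:
                corrected, _ = correct_rr_intervals(rr.rr_s)
                feats = cmse.features_for_series(corrected, needed_estimators)
                for j, name in enumerate(coeff_names):
                    planted[s, j] = feats[name]
        manifest.subjects[s] = subject_entry

    rr_table = pd.concat(rows, ignore_index=True)

    cov_rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 0xC0DA])
    age = np.round(cov_rng.normal(59.4, 9.3, spec.n_subjects)).astype(int)
    sex = (cov_rng.random(spec.n_subjects) < 0.51).astype(int)  # 1 = male
    history = np.maximum(0.0, cov_rng.normal(7.5, 6.8, spec.n_subjects))

    lvef = np.full(spec.n_subjects, spec.lvef_intercept)
    if coeff_names:
        mu = planted.mean(axis=0)
        sd = planted.std(axis=0)
        sd[sd == 0] = 1.0
        z = (planted - mu) / sd
        lvef = lvef + z @ np.array([spec.lvef_coeffs[n] for n in coeff_names])
    if spec.lvef_noise_sd > 0:
        lvef = lvef + cov_rng.normal(0.0, spec.lvef_noise_sd, spec.n_subjects)
    lvef = np.clip(lvef, 20.0, 80.0)

    covariates = pd.DataFrame({
        "subject_id": np.arange(spec.n_subjects),
        "age": age, "sex": sex, "history_years": history,
        "lvef_pct": lvef,
    })
    for s in range(spec.n_subjects):
        manifest.subjects[s].update({
            "lvef_true": float(lvef[s]), "age": int(age[s]),
            "sex": int(sex[s]), "history_years": float(history[s]),
            "planted_features": {name: float(planted[s, j])
                                 for j, name in enumerate(coeff_names)},
        })
    return CohortData(rr=rr_table, covariates=covariates, manifest=manifest)


def write_cohort(cohort: CohortData, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.rr.to_csv(out / "rr.csv", index=False)
    cohort.covariates.to_csv(out / "covariates.csv", index=False)
    cohort.manifest.write(out / "truth_manifest.json")
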