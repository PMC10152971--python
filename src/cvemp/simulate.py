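"""Synthetic c-VEMP cohorts and session waveforms.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without recorded data:

* a cohort of children (6 months to 16 years) and adults (16-62 years) with
  roughly balanced sexes, both ears tested in air (AC) and bone (BC)
  conduction;
* a latent per-ear amplitude ratio that follows a sex-scaled maturation
  curve -- rising to a peak at 4-6 years, then declining slowly -- with
  log-normal subject and ear effects whose split sets the right-left
  correlation (default 0.85, matching the printed ICC) and a partially
  shared subject effect giving an AC-BC correlation of ~0.6;
* a threshold negatively coupled to the amplitude ratio, snapped to the
  5-dB staircase ladder, with occasional absent BC responses from
  mid-adolescence onward;
* per-epoch waveforms: band-limited Gaussian tonic EMG (RMS equal to the
  subject's EMG level, within the 100-500 uV biofeedback target band) plus
  a biphasic Gaussian-bump response at the subject's P/N latencies, scaled
  so the noiseless peak-to-peak equals ratio * EMG * growth(level), where
  growth rises linearly in dB from zero at threshold-5 to one at the
  reference level.

All randomness flows from one seed through named per-subject streams, so a
cohort and every session in it are reproducible independently of ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import Conduction, StaircaseProtocol
from .features import AveragedTrace

__all__ = [
    "CohortConfig",
    "MaturationCurve",
    "WaveformConfig",
    "EarTruth",
    "TrueSubject",
    "DEFAULT_CURVES",
    "sample_cohort",
    "cohort_to_frame",
    "synth_epoch",
    "synth_average",
    "synth_session",
]

MODES = (Conduction.AC, Conduction.BC)
EARS = ("R", "L")


@dataclass(frozen=True)
class MaturationCurve:
    """Mean amplitude-ratio curve over age.

    ``m(age) = s * [b + g*(age/t)*exp(1 - age/t) - d*max(0, age - t)]`` peaks
    exactly at ``t`` years (the gamma-shaped rise is maximal there and the
    linear decline starts there).  ``sex_multiplier`` (> 1) scales the male
    curve, reproducing the higher male medians.
    """

    baseline: float
    gain: float
    peak_age: float
    decline: float
    sex_multiplier: float = 1.0

    def __post_init__(self):
        if self.baseline < 0 or self.peak_age <= 0:
            raise ValueError("baseline must be >= 0 and peak_age > 0")

    def mean(self, age, sex: str = "F"):
        age = np.asarray(age, dtype=float)
        rel = age / self.peak_age
        m = self.baseline + self.gain * rel * np.exp(1.0 - rel) \
            - self.decline * np.maximum(0.0, age - self.peak_age)
        if np.any(m <= 0):
            raise ValueError("maturation curve non-positive on the requested ages")
        s = self.sex_multiplier if sex == "M" else 1.0
        out = s * m
        return out if out.shape else float(out)


#: Default curves, matched to the child/adult band means of the measured
#: characteristics table (AC peaks higher and declines faster than BC).
DEFAULT_CURVES: dict[Conduction, MaturationCurve] = {
    Conduction.AC: MaturationCurve(baseline=0.75, gain=1.3, peak_age=5.0,
                                   decline=0.008, sex_multiplier=1.15),
    Conduction.BC: MaturationCurve(baseline=1.3, gain=0.8, peak_age=4.5,
                                   decline=0.020, sex_multiplier=1.10),
}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition and latent-effect parameters."""

    n_children: int = 118
    n_adults: int = 41
    age_range_children: tuple[float, float] = (0.5, 16.0)
    age_range_adults: tuple[float, float] = (16.0, 62.0)
    sex_ratio: float = 0.5  # fraction male
    tau_log: float = 0.4  # total log-scale SD of the amplitude ratio
    ear_corr: float = 0.85  # right-left correlation of log ratios (ICC target)
    mode_corr: float = 0.6  # AC-BC correlation of log ratios
    emg_range_uv: tuple[float, float] = (100.0, 500.0)
    threshold_intercept_dbnhl: Mapping[str, float] = field(
        default_factory=lambda: {"AC": 83.0, "BC": 81.0})
    threshold_slope_db_per_ratio: float = 4.0
    threshold_sd_db: float = 3.0
    latency_p_base_ms: float = 12.8
    latency_p_age_slope: float = 0.05
    latency_p_sd_ms: float = 0.4
    latency_pn_gap_ms: float = 6.3
    latency_pn_gap_sd_ms: float = 0.8
    response_width_ms: float = 2.0  # keep equal to WaveformConfig.response_width_ms
    absent_bc_age_years: float = 14.0
    absent_bc_prob_child: float = 0.05
    absent_bc_prob_adult: float = 0.15

    def __post_init__(self):
        if self.n_children < 0 or self.n_adults < 0:
            raise ValueError("cohort counts must be non-negative")
        for lo, hi in (self.age_range_children, self.age_range_adults):
            if hi <= lo:
                raise ValueError("age ranges must be non-degenerate")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if self.tau_log <= 0 or self.threshold_sd_db <= 0 \
                or self.latency_p_sd_ms <= 0 or self.latency_pn_gap_sd_ms <= 0:
            raise ValueError("variance parameters must be positive")
        if not 0.0 <= self.ear_corr <= 1.0 or not 0.0 <= self.mode_corr <= 1.0:
            raise ValueError("correlations must lie in [0, 1]")
        if self.mode_corr > self.ear_corr:
            raise ValueError("mode_corr cannot exceed ear_corr "
                             "(the shared subject effect is nested)")


@dataclass(frozen=True)
class WaveformConfig:
    """Sampling and epoch parameters of the synthetic recordings."""

    sampling_rate_hz: float = 10000.0
    epoch_ms: float = 150.0
    n_epochs_child: int = 25
    n_epochs_adult: int = 50
    n_epochs_threshold: int = 50  # sub-reference levels (threshold search)
    n_replicates_reference: int = 2  # validation averages at the reference level
    n_replicates_search: int = 4  # validation averages during threshold search
    noise_rms_uv: float | None = None  # None: use the subject's EMG level
    response_width_ms: float = 2.0
    noise_band_hz: tuple[float, float] = (20.0, 450.0)
    emg_window_ms: tuple[float, float] = (50.0, 150.0)

    def __post_init__(self):
        n = self.sampling_rate_hz * self.epoch_ms / 1000.0
        if abs(n - round(n)) > 1e-9:
            raise ValueError("sampling_rate * epoch_length must give an integer "
                             "sample count")
        if self.n_epochs_child < 2 or self.n_epochs_adult < 2:
            raise ValueError("need at least 2 epochs per average")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate_hz * self.epoch_ms / 1000.0))


@dataclass(frozen=True)
class EarTruth:
    """Latent per-ear, per-mode ground truth.

    ``t_p_ms``/``t_n_ms`` are the peak times of the noiseless waveform (what
    a latency measurement estimates); the Gaussian bump centres used to build
    the waveform are kept separately, since the overlapping opposite-polarity
    bump shifts each true peak slightly off its centre.
    """

    ratio: float
    threshold_dbnhl: float | None  # None: response absent up to the ceiling
    t_p_ms: float
    t_n_ms: float
    center_p_ms: float = float("nan")
    center_n_ms: float = float("nan")

    def __post_init__(self):
        if math.isnan(self.center_p_ms):
            object.__setattr__(self, "center_p_ms", self.t_p_ms)
        if math.isnan(self.center_n_ms):
            object.__setattr__(self, "center_n_ms", self.t_n_ms)


@dataclass(frozen=True)
class TrueSubject:
    id: str
    age_years: float
    sex: str
    group: str  # "child" | "adult"
    emg_uv: float
    subject_effect: float  # shared latent log-effect
    ears: Mapping[tuple[str, str], EarTruth]  # (ear, mode) -> truth
    seed: int  # per-subject stream seed for session synthesis

    def truth(self, ear: str, mode) -> EarTruth:
        return self.ears[(ear, str(Conduction(mode)))]


# ---------------------------------------------------------------------------
# Cohort sampling


def _biphasic_peak(cp: float, cn: float, w: float, which: str) -> float:
    """Peak time of ``exp(-(t-cp)^2/2w^2) - exp(-(t-cn)^2/2w^2)`` near one bump.

    Newton iterations from the bump centre; the opposite bump's tail shifts
    the true extremum slightly toward earlier (P) / later (N) times.
    """
    t = cp if which == "P" else cn
    w2 = w * w
    for _ in range(6):
        a = math.exp(-((t - cp) ** 2) / (2 * w2))
        b = math.exp(-((t - cn) ** 2) / (2 * w2))
        d1 = -(t - cp) / w2 * a + (t - cn) / w2 * b
        d2 = a * ((t - cp) ** 2 / w2**2 - 1.0 / w2) \
            - b * ((t - cn) ** 2 / w2**2 - 1.0 / w2)
        if d2 == 0:
            break
        step = d1 / d2
        t -= step
        if abs(step) < 1e-10:
            break
    return t


def sample_cohort(config: CohortConfig = CohortConfig(),
                  curves: Mapping = DEFAULT_CURVES,
                  seed: int = 0,
                  protocol: StaircaseProtocol = StaircaseProtocol()
                  ) -> list[TrueSubject]:
    """Draw a cohort of latent subjects; deterministic under a fixed seed."""
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    subjects: list[TrueSubject] = []
    tau = config.tau_log
    v_common = config.mode_corr * tau**2
    v_mode = (config.ear_corr - config.mode_corr) * tau**2
    v_ear = (1.0 - config.ear_corr) * tau**2

    specs = [("child", config.n_children, config.age_range_children),
             ("adult", config.n_adults, config.age_range_adults)]
    idx = 0
    for group, n, (lo, hi) in specs:
        for _ in range(n):
            idx += 1
            age = float(rng.uniform(lo, hi))
            sex = "M" if rng.random() < config.sex_ratio else "F"
            emg = float(rng.uniform(*config.emg_range_uv))
            u = float(rng.normal(0.0, math.sqrt(v_common))) if v_common > 0 else 0.0
            ears: dict[tuple[str, str], EarTruth] = {}
            for mode in MODES:
                curve = curves[mode]
                v = float(rng.normal(0.0, math.sqrt(v_mode))) if v_mode > 0 else 0.0
                absent = _absent_response(rng, config, mode, age)
                for ear in EARS:
                    w = float(rng.normal(0.0, math.sqrt(v_ear))) if v_ear > 0 else 0.0
                    ratio = curve.mean(age, sex) * math.exp(u + v + w)
                    thr = None
                    if not absent:
                        thr = _draw_threshold(rng, config, protocol, mode, ratio)
                    c_p = config.latency_p_base_ms + config.latency_p_age_slope * age \
                        + float(rng.normal(0.0, config.latency_p_sd_ms))
                    gap = max(float(rng.normal(config.latency_pn_gap_ms,
                                               config.latency_pn_gap_sd_ms)), 3.0)
                    c_n = c_p + gap
                    w = config.response_width_ms
                    ears[(ear, str(mode))] = EarTruth(
                        ratio, thr,
                        t_p_ms=_biphasic_peak(c_p, c_n, w, "P"),
                        t_n_ms=_biphasic_peak(c_p, c_n, w, "N"),
                        center_p_ms=c_p, center_n_ms=c_n)
            subjects.append(TrueSubject(
                id=f"S{idx:04d}", age_years=age, sex=sex, group=group,
                emg_uv=emg, subject_effect=u, ears=ears,
                seed=int(root.entropy % (2**31)) ^ (idx * 2654435761 % (2**31)),
            ))
    return subjects


def _absent_response(rng, config: CohortConfig, mode: Conduction, age: float) -> bool:
    if mode is not Conduction.BC or age < config.absent_bc_age_years:
        return False
    p = config.absent_bc_prob_adult if age >= 16.0 else config.absent_bc_prob_child
    return bool(rng.random() < p)


def _draw_threshold(rng, config: CohortConfig, protocol: StaircaseProtocol,
                    mode: Conduction, ratio: float) -> float | None:
    theta0 = config.threshold_intercept_dbnhl[str(mode)]
    raw = theta0 - config.threshold_slope_db_per_ratio * ratio \
        + float(rng.normal(0.0, config.threshold_sd_db))
    ceiling = protocol.ceiling_nhl(mode)
    if raw > ceiling + protocol.step_db / 2.0:
        return None  # no response even at the device ceiling
    return protocol.snap_nhl(mode, raw)


def cohort_to_frame(subjects: Iterable[TrueSubject]) -> pd.DataFrame:
    """Ground-truth table, one row per subject x ear x mode."""
    rows = []
    for s in subjects:
        for (ear, mode), t in s.ears.items():
            rows.append({
                "subject_id": s.id, "group": s.group, "age_years": s.age_years,
                "sex": s.sex, "ear": ear, "mode": mode, "emg_uv": s.emg_uv,
                "true_ratio": t.ratio, "true_threshold_dbnhl": t.threshold_dbnhl,
                "true_p_latency_ms": t.t_p_ms, "true_n_latency_ms": t.t_n_ms,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Waveform synthesis


def _band_noise(rng, shape, fs: float, band: tuple[float, float], rms: float):
    """Stationary Gaussian noise with a flat band spectrum and exact RMS.

    Synthesised in the frequency domain (independent complex Gaussian bins
    inside the band), which avoids the edge transients a causal filter would
    leave on epoch-length chunks.
    """
    if np.isscalar(shape):
        shape = (int(shape),)
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    m = int(mask.sum())
    if m == 0:
        raise ValueError("noise band contains no frequency bins")
    spec_shape = shape[:-1] + (freqs.size,)
    spec = (rng.standard_normal(spec_shape) + 1j * rng.standard_normal(spec_shape))
    spec *= mask
    x = np.fft.irfft(spec, n=n, axis=-1)
    # each in-band bin contributes 4/n^2 to the per-sample variance
    return x * (rms * n / (2.0 * math.sqrt(m)))


def response_growth(level_dbnhl: float, threshold_dbnhl: float | None,
                    reference_dbnhl: float, step_db: float = 5.0) -> float:
    """Amplitude growth factor in [0, 1]: zero below threshold, linear in dB
    from threshold - step up to the reference level."""
    if threshold_dbnhl is None or level_dbnhl < threshold_dbnhl:
        return 0.0
    span = max(reference_dbnhl - (threshold_dbnhl - step_db), step_db)
    return float(np.clip((level_dbnhl - (threshold_dbnhl - step_db)) / span, 0.0, 1.0))


def _bump_shape(t_ms: np.ndarray, t_p: float, t_n: float, w: float) -> np.ndarray:
    return np.exp(-((t_ms - t_p) ** 2) / (2 * w**2)) \
        - np.exp(-((t_ms - t_n) ** 2) / (2 * w**2))


def synth_epoch(subject: TrueSubject, ear: str, mode, level_dbnhl: float,
                wconfig: WaveformConfig = WaveformConfig(),
                rng=None, protocol: StaircaseProtocol = StaircaseProtocol()
                ) -> np.ndarray:
    """One raw epoch: band-limited EMG noise plus the scaled biphasic response."""
    mode = Conduction(mode)
    truth = subject.truth(ear, mode)
    if wconfig.epoch_ms < truth.t_n_ms + 3 * wconfig.response_width_ms:
        raise ValueError("epoch too short to contain the response")
    rng = np.random.default_rng(rng)
    t_ms = np.arange(wconfig.n_samples) * 1000.0 / wconfig.sampling_rate_hz
    rms = wconfig.noise_rms_uv if wconfig.noise_rms_uv is not None else subject.emg_uv
    noise = (_band_noise(rng, wconfig.n_samples, wconfig.sampling_rate_hz,
                         wconfig.noise_band_hz, rms) if rms > 0 else np.zeros_like(t_ms))
    g = response_growth(level_dbnhl, truth.threshold_dbnhl,
                        protocol.reference_nhl(mode), protocol.step_db)
    if g <= 0:
        return noise
    shape = _bump_shape(t_ms, truth.center_p_ms, truth.center_n_ms,
                            wconfig.response_width_ms)
    pp_unit = float(shape.max() - shape.min())
    amp = truth.ratio * subject.emg_uv * g / pp_unit
    return noise + amp * shape


def synth_average(subject: TrueSubject, ear: str, mode, level_dbnhl: float,
                  n_epochs: int, wconfig: WaveformConfig = WaveformConfig(),
                  rng=None, replicate: int = 0,
                  protocol: StaircaseProtocol = StaircaseProtocol()) -> AveragedTrace:
    """Average of ``n_epochs`` fresh epochs; per-epoch EMG kept as metadata."""
    mode = Conduction(mode)
    truth = subject.truth(ear, mode)
    if wconfig.epoch_ms < truth.t_n_ms + 3 * wconfig.response_width_ms:
        raise ValueError("epoch too short to contain the response")
    rng = np.random.default_rng(rng)
    fs = wconfig.sampling_rate_hz
    t_ms = np.arange(wconfig.n_samples) * 1000.0 / fs
    rms = wconfig.noise_rms_uv if wconfig.noise_rms_uv is not None else subject.emg_uv
    if rms > 0:
        epochs = _band_noise(rng, (n_epochs, wconfig.n_samples), fs,
                             wconfig.noise_band_hz, rms)
    else:
        epochs = np.zeros((n_epochs, wconfig.n_samples))
    g = response_growth(level_dbnhl, truth.threshold_dbnhl,
                        protocol.reference_nhl(mode), protocol.step_db)
    if g > 0:
        shape = _bump_shape(t_ms, truth.center_p_ms, truth.center_n_ms,
                                wconfig.response_width_ms)
        epochs = epochs + (truth.ratio * subject.emg_uv * g
                           / float(shape.max() - shape.min())) * shape
    lo, hi = wconfig.emg_window_ms
    i0, i1 = int(round(lo * fs / 1000.0)), int(round(hi * fs / 1000.0))
    emg = float(np.mean(np.abs(epochs[:, i0:i1])))
    return AveragedTrace(
        samples=epochs.mean(axis=0), sampling_rate_hz=fs, ear=ear,
        mode=str(mode), level_dbnhl=float(level_dbnhl), replicate=replicate,
        n_epochs=n_epochs, emg_uv=emg,
    )


def synth_session(subject: TrueSubject,
                  protocol: StaircaseProtocol = StaircaseProtocol(),
                  wconfig: WaveformConfig = WaveformConfig(),
                  seed: int | None = None,
                  modes: Sequence = MODES,
                  ears: Sequence[str] = EARS,
                  ) -> dict[tuple[str, str], dict[float, list[AveragedTrace]]]:
    """Full protocol for one subject: per (ear, mode), replicate averages at
    every staircase level.

    Two independent averages are produced at each level (the replicability
    validation).  The descent runs from the reference level to two steps
    below the subject's true threshold (the examiner stops soon after
    responses vanish); response-absent or above-reference-threshold ears get
    the ascending branch up to the device ceiling instead.  Children get 25
    epochs at the reference level and 50 during threshold search; adults get
    50 throughout.
    """
    seed = subject.seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    session: dict[tuple[str, str], dict[float, list[AveragedTrace]]] = {}
    streams = iter(root.spawn(len(list(modes)) * len(list(ears))))
    is_child = subject.group == "child"
    for mode in modes:
        mode = Conduction(mode)
        ladder = protocol.ladder_nhl(mode)
        ref = protocol.reference_nhl(mode)
        for ear in ears:
            rng = np.random.default_rng(next(streams))
            truth = subject.truth(ear, mode)
            thr = truth.threshold_dbnhl
            if thr is None or thr > ref:
                levels = [ref] + [l for l in ladder.ascending]
            else:
                stop = thr - 2 * protocol.step_db
                levels = [l for l in ladder.descending if l >= stop - 1e-9]
            recording: dict[float, list[AveragedTrace]] = {}
            for level in levels:
                if is_child:
                    n_ep = wconfig.n_epochs_child if level >= ref else \
                        wconfig.n_epochs_threshold
                else:
                    n_ep = wconfig.n_epochs_adult
                if level == ref:
                    # base validation pair; if the examiner is unsure the
                    # acquisition count is raised to the threshold-search value
                    n_eps = [n_ep] * wconfig.n_replicates_reference + \
                        [wconfig.n_epochs_threshold if is_child
                         else wconfig.n_epochs_adult] * 2
                else:
                    n_eps = [n_ep] * wconfig.n_replicates_search
                recording[level] = [
                    synth_average(subject, ear, mode, level, ne, wconfig,
                                  rng=rng, replicate=k, protocol=protocol)
                    for k, ne in enumerate(n_eps)
                ]
            session[(ear, str(mode))] = recording
    return session
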