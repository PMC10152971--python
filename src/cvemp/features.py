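"""Waveform measurements: EMG level, P/N peaks, replicability, threshold.

An averaged trace covers 150 ms from stimulus onset.  The biphasic response
(positive P peak near 13 ms, negative N peak near 19 ms) is read from the
first 50 ms; the tonic-EMG level is quantified as the rectified mean of the
50-150 ms segment so the evoked response itself is excluded.  The amplitude
ratio PN/EMG removes the dependence on muscle-contraction strength.

Peak picking operates on a zero-phase 200 Hz low-passed copy of the trace
(the biphasic complex lives below ~150 Hz, and the low-frequency tonic-EMG
rumble that survives averaging is what shifts a raw argmax); peak
amplitudes are read from the raw samples at the detected latencies.

A stimulation level counts as replicable when two successive averages both
show a detectable response, agree in P latency within 2 ms and correlate at
or above ``r_min``.  The correlation is evaluated where the response
actually discriminates: the 5-35 ms window, band-passed to 40-200 Hz -- the
P-N complex (two opposite 2-ms Gaussian flanks ~6 ms apart) is spectrally
an ~80 Hz wavelet, while the 20-40 Hz EMG rumble contributes only a couple
of effective degrees of freedom per window and would otherwise dominate the
Pearson statistic.  The threshold is the lowest replicable level of the
descending 5-dB staircase (or of the ascending branch when the starting
level gives no response); when a level carries more than two validation
averages, the walk retries with the next replicate pair before declaring
the level non-replicable, mirroring an examiner who keeps acquiring until
reproducibility is decided.  A subject never replicable up to the device
ceiling is flagged response-absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .calibration import StaircaseProtocol

__all__ = [
    "AveragedTrace",
    "VempFeatures",
    "ThresholdResult",
    "FeatureConfig",
    "emg_level",
    "detect_pn",
    "amplitude_ratio",
    "is_replicable",
    "find_threshold",
    "extract_ear_features",
]


@dataclass
class AveragedTrace:
    """Averaged voltage trace; sample 0 is at stimulus onset."""

    samples: np.ndarray  # microvolts
    sampling_rate_hz: float
    ear: str = "R"
    mode: str = "AC"
    level_dbnhl: float = float("nan")
    replicate: int = 0
    n_epochs: int = 1
    emg_uv: float | None = None  # per-epoch rectified-mean EMG, if known

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be 1-d")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if self.sampling_rate_hz <= 2000:
            raise ValueError("sampling rate must exceed 2 kHz")

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.samples.size / self.sampling_rate_hz

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) * 1000.0 / self.sampling_rate_hz

    def window(self, lo_ms: float, hi_ms: float) -> np.ndarray:
        i0 = int(math.ceil(lo_ms * self.sampling_rate_hz / 1000.0))
        i1 = int(math.floor(hi_ms * self.sampling_rate_hz / 1000.0))
        return self.samples[max(i0, 0):i1 + 1]


@dataclass(frozen=True)
class VempFeatures:
    p_latency_ms: float | None
    n_latency_ms: float | None
    pn_uv: float
    emg_uv: float | None
    amplitude_ratio: float | None
    response_present: bool


@dataclass(frozen=True)
class ThresholdResult:
    threshold_dbnhl: float | None  # None = response absent up to the ceiling
    levels_tested: tuple[float, ...]
    replicable_at: tuple[float, ...]

    @property
    def response_present(self) -> bool:
        return self.threshold_dbnhl is not None


@dataclass(frozen=True)
class FeatureConfig:
    """Windows and decision knobs of the feature extractor."""

    p_window_ms: tuple[float, float] = (8.0, 18.0)
    n_window_max_ms: float = 30.0
    n_gap_ms: float = 2.0
    emg_window_ms: tuple[float, float] = (50.0, 150.0)
    analysis_window_ms: float = 50.0
    detection_k: float = 3.0  # response present if PN >= k * robust noise scale
    r_min: float = 0.45
    latency_tol_ms: float = 2.0
    lowpass_hz: float | None = 200.0  # zero-phase low-pass for peak picking
    peak_refine_ms: float = 0.4  # snap to the raw local extremum within this radius
    corr_band_hz: tuple[float, float] = (40.0, 200.0)  # replicability band
    corr_window_ms: tuple[float, float] = (5.0, 35.0)  # replicability window


DEFAULT_CONFIG = FeatureConfig()


def _lowpass(x: np.ndarray, fs: float, cutoff: float | None) -> np.ndarray:
    if cutoff is None or cutoff <= 0 or cutoff >= fs / 2:
        return x
    sos = sps.butter(4, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def emg_level(trace: AveragedTrace, window_ms: tuple[float, float] = (50.0, 150.0)) -> float:
    """Rectified-mean voltage over the window (response-excluded by default)."""
    lo, hi = window_ms
    hi = min(hi, trace.duration_ms)
    if hi <= lo:
        raise ValueError("empty EMG window")
    seg = trace.window(lo, hi)
    if seg.size == 0:
        raise ValueError("empty EMG window")
    return float(np.mean(np.abs(seg)))


def detect_pn(trace: AveragedTrace, config: FeatureConfig = DEFAULT_CONFIG) -> VempFeatures:
    """Locate the P (max) and N (min) peaks and decide response presence.

    P is the maximum of the low-passed trace in the P search window, N the
    minimum between P + gap and the end of the N window; the peak-to-peak
    amplitude is read from the raw samples at those latencies.  A response is
    present when PN exceeds ``k`` times the robust noise scale of the
    post-response segment.
    """
    if trace.duration_ms < config.n_window_max_ms:
        raise ValueError(
            f"trace covers {trace.duration_ms:.1f} ms; "
            f"need at least {config.n_window_max_ms} ms"
        )
    fs = trace.sampling_rate_hz
    smooth = _lowpass(trace.samples, fs, config.lowpass_hz)
    dt_ms = 1000.0 / fs

    def idx(ms: float) -> int:
        return int(round(ms / dt_ms))

    def refine(i, lo, hi, sign):
        # the smoothed argmax locates the peak; the raw local extremum removes
        # the filter-induced shift from the overlapping opposite-polarity bump
        r = idx(config.peak_refine_ms)
        j0, j1 = max(i - r, lo), min(i + r, hi)
        seg = sign * trace.samples[j0:j1 + 1]
        return j0 + int(np.argmax(seg))

    p_lo, p_hi = config.p_window_ms
    i0, i1 = idx(p_lo), min(idx(p_hi), trace.samples.size - 1)
    p_idx = refine(i0 + int(np.argmax(smooth[i0:i1 + 1])), i0, i1, +1)
    n0 = min(p_idx + idx(config.n_gap_ms), trace.samples.size - 1)
    n1 = min(idx(config.n_window_max_ms), trace.samples.size - 1)
    if n1 <= n0:
        n0 = n1
    n_idx = refine(n0 + int(np.argmin(smooth[n0:n1 + 1])), n0, n1, -1)
    pn = float(trace.samples[p_idx] - trace.samples[n_idx])

    noise_seg = trace.window(config.emg_window_ms[0],
                             min(config.emg_window_ms[1], trace.duration_ms))
    if noise_seg.size < 8:  # short trace: fall back to the tail after N
        noise_seg = trace.samples[n1:]
    centred = noise_seg - np.median(noise_seg)
    scale = 1.4826 * float(np.median(np.abs(centred))) if noise_seg.size else 0.0
    # averaged-trace residual noise; per-epoch EMG is emg_uv * sqrt(n_epochs) larger
    present = pn > 0 and pn >= config.detection_k * scale
    return VempFeatures(
        p_latency_ms=p_idx * dt_ms,
        n_latency_ms=n_idx * dt_ms,
        pn_uv=pn,
        emg_uv=trace.emg_uv,
        amplitude_ratio=(pn / trace.emg_uv) if trace.emg_uv else None,
        response_present=bool(present),
    )


def amplitude_ratio(pn_uv: float, emg_uv: float) -> float:
    """Dimensionless PN/EMG normalised amplitude."""
    if emg_uv <= 0:
        raise ValueError("EMG level must be positive")
    return float(pn_uv) / float(emg_uv)


def is_replicable(trace_a: AveragedTrace, trace_b: AveragedTrace,
                  config: FeatureConfig = DEFAULT_CONFIG) -> bool:
    """Two successive averages show the same response (presence + latency + shape)."""
    if trace_a.sampling_rate_hz != trace_b.sampling_rate_hz:
        raise ValueError("traces have different sampling rates")
    la, lb = trace_a.level_dbnhl, trace_b.level_dbnhl
    if not (np.isnan(la) and np.isnan(lb)) and la != lb:
        raise ValueError("traces were recorded at different stimulation levels")
    fa = detect_pn(trace_a, config)
    fb = detect_pn(trace_b, config)
    if not (fa.response_present and fb.response_present):
        return False
    if abs(fa.p_latency_ms - fb.p_latency_ms) > config.latency_tol_ms:
        return False
    fs = trace_a.sampling_rate_hz
    lo, hi = config.corr_window_ms
    i0 = int(round(lo * fs / 1000.0))
    i1 = min(trace_a.samples.size, trace_b.samples.size,
             int(round(hi * fs / 1000.0)))
    sos = sps.butter(4, config.corr_band_hz, btype="bandpass", fs=fs, output="sos")
    xa = sps.sosfiltfilt(sos, trace_a.samples)[i0:i1]
    xb = sps.sosfiltfilt(sos, trace_b.samples)[i0:i1]
    xa = xa - xa.mean()
    xb = xb - xb.mean()
    denom = math.sqrt(float(xa @ xa) * float(xb @ xb))
    if denom == 0:
        return False
    return float(xa @ xb) / denom >= config.r_min


def find_threshold(recording: Mapping[float, Sequence[AveragedTrace]],
                   protocol: StaircaseProtocol | None = None,
                   mode: str | None = None,
                   config: FeatureConfig = DEFAULT_CONFIG) -> ThresholdResult:
    """Walk the staircase: threshold = lowest level replicable on two trials.

    ``recording`` maps stimulation level (dB nHL) to its replicate averages
    (>= 2 per level).  The walk starts at the protocol's reference level
    (or the highest level at/below it present in the recording), descends
    while replicable, and ascends toward the ceiling if the start is not
    replicable; a recording never replicable up to the ceiling is absent.
    """
    if not recording:
        raise ValueError("empty session recording")
    for lvl, traces in recording.items():
        if len(traces) < 2:
            raise ValueError(f"level {lvl} has fewer than 2 replicate averages")
    levels = sorted(recording)
    if mode is None:
        mode = next(iter(recording.values()))[0].mode
    ref = protocol.reference_nhl(mode) if protocol is not None else None
    at_or_below = [l for l in levels if ref is None or l <= ref + 1e-9]
    start = max(at_or_below) if at_or_below else min(levels)

    def replicable(level: float) -> bool:
        # adjacent replicate pairs: an examiner re-validates a doubtful level
        traces = recording[level]
        return any(is_replicable(traces[k], traces[k + 1], config)
                   for k in range(len(traces) - 1))

    tested, good = [], []
    if replicable(start):
        tested.append(start)
        good.append(start)
        for lvl in sorted((l for l in levels if l < start), reverse=True):
            tested.append(lvl)
            if replicable(lvl):
                good.append(lvl)
            else:
                break
        return ThresholdResult(min(good), tuple(tested), tuple(sorted(good)))
    tested.append(start)
    for lvl in sorted(l for l in levels if l > start):
        tested.append(lvl)
        if replicable(lvl):
            good.append(lvl)
            return ThresholdResult(lvl, tuple(tested), tuple(sorted(good)))
    return ThresholdResult(None, tuple(tested), ())


def extract_ear_features(recording: Mapping[float, Sequence[AveragedTrace]],
                         protocol: StaircaseProtocol | None = None,
                         config: FeatureConfig = DEFAULT_CONFIG
                         ) -> tuple[VempFeatures, ThresholdResult]:
    """Reference-level features plus the staircase threshold for one ear/mode.

    Reference-level features are averaged over the two validation replicates;
    the amplitude ratio divides the mean PN by the mean per-epoch EMG level.
    When the session is response-absent, amplitudes and latencies are
    reported as missing.
    """
    if not recording:
        raise ValueError("empty session recording")
    mode = next(iter(recording.values()))[0].mode
    thr = find_threshold(recording, protocol, mode=mode, config=config)
    ref = protocol.reference_nhl(mode) if protocol is not None else max(recording)
    ref_level = ref if ref in recording else max(recording)
    reps = recording[ref_level]
    emgs = [t.emg_uv if t.emg_uv is not None else emg_level(t, config.emg_window_ms)
            for t in reps[:2]]
    emg = float(np.mean(emgs))
    if thr.threshold_dbnhl is None:
        return (VempFeatures(None, None, 0.0, emg, None, False), thr)
    feats = [detect_pn(t, config) for t in reps[:2]]
    pn = float(np.mean([f.pn_uv for f in feats]))
    return (
        VempFeatures(
            p_latency_ms=float(np.mean([f.p_latency_ms for f in feats])),
            n_latency_ms=float(np.mean([f.n_latency_ms for f in feats])),
            pn_uv=pn,
            emg_uv=emg,
            amplitude_ratio=amplitude_ratio(pn, emg),
            response_present=True,
        ),
        thr,
    )
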