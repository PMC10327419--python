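"""Surface-EMG conditioning chain and MVC/MVV normalization.

The chain, in order: optional 20-450 Hz band-limit (emulating acquisition
hardware for synthetic signals), 6th-order elliptical notch at the mains
frequency applied forward-backward (zero phase), first-order detrend,
full-wave rectification, zero-phase 10 ms centered moving average, and
normalization to 100% of the per-muscle maximal voluntary contraction
(MVC).  All stages preserve signal length; the envelope is non-negative.

MVC is extracted per muscle from three isometric maximal-effort trials as
the rectified-EMG average over a 500 ms window centered at the activity
peak, averaged across trials.  MVV (maximal voluntary velocity) is the
mean peak endpoint speed across three maximal-effort reaches; it
normalizes perturbation timing rather than EMG amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "FilterParams",
    "ProcessedEmg",
    "MvcTable",
    "MvvValue",
    "EmgProcessingError",
    "condition_raw",
    "rectify",
    "smooth_envelope",
    "process_emg",
    "compute_mvc",
    "compute_mvv",
    "background_activity",
]


class EmgProcessingError(ValueError):
    pass


@dataclass(frozen=True)
class FilterParams:
    """Parameters of the conditioning chain.

    The elliptical notch is realized as an order-3 band-stop prototype
    (6th-order filter) with a 1 Hz half-bandwidth, 1 dB passband ripple
    and 40 dB stopband attenuation; applied with filtfilt it is zero
    phase.  ``apply_bandpass`` should be True for synthetic raw signals
    (hardware band-limits real recordings before digitization).
    """

    mains_hz: float = 60.0
    notch_half_bandwidth_hz: float = 1.0
    notch_order: int = 3  # prototype order; band-stop doubles it
    notch_ripple_db: float = 1.0
    notch_attenuation_db: float = 40.0
    bandpass_hz: tuple[float, float] = (20.0, 450.0)
    bandpass_order: int = 4
    apply_bandpass: bool = True
    smooth_window_s: float = 0.010

    def smooth_window_samples(self, fs: float) -> int:
        n = int(round(self.smooth_window_s * fs))
        return n + 1 if n % 2 == 0 else n  # odd length for exact zero phase


@dataclass
class ProcessedEmg:
    """Per-channel EMG envelopes in % MVC at the recording rate."""

    envelopes: dict[str, np.ndarray]
    sampling_rate: float
    params: FilterParams

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.envelopes[channel]

    @property
    def channels(self) -> list[str]:
        return list(self.envelopes)


@dataclass
class MvcTable:
    """Per-muscle MVC in raw envelope units, with per-trial intermediates."""

    values: dict[str, float]
    per_trial: dict[str, list[float]] = field(default_factory=dict)

    def __getitem__(self, muscle: str) -> float:
        return self.values[muscle]


@dataclass
class MvvValue:
    """MVV (m/s) and the per-trial peak speeds it averages."""

    mvv: float
    peaks: list[float]


def _sos_notch(params: FilterParams, fs: float) -> np.ndarray:
    lo = params.mains_hz - params.notch_half_bandwidth_hz
    hi = params.mains_hz + params.notch_half_bandwidth_hz
    return signal.ellip(
        params.notch_order,
        params.notch_ripple_db,
        params.notch_attenuation_db,
        [lo, hi],
        btype="bandstop",
        fs=fs,
        output="sos",
    )


def condition_raw(
    x: np.ndarray, fs: float, params: FilterParams | None = None
) -> np.ndarray:
    """Band-limit (optional), notch, and detrend a raw EMG channel."""
    params = params or FilterParams()
    x = np.asarray(x, float)
    if params.apply_bandpass:
        sos = signal.butter(
            params.bandpass_order, params.bandpass_hz, btype="bandpass", fs=fs, output="sos"
        )
        x = signal.sosfiltfilt(sos, x)
    x = signal.sosfiltfilt(_sos_notch(params, fs), x)
    return signal.detrend(x, type="linear")


def rectify(x: np.ndarray) -> np.ndarray:
    """Full-wave rectification; idempotent on non-negative input."""
    return np.abs(np.asarray(x, float))


def smooth_envelope(x: np.ndarray, fs: float, params: FilterParams | None = None) -> np.ndarray:
    """Zero-phase centered moving average with reflected edges."""
    params = params or FilterParams()
    n = params.smooth_window_samples(fs)
    half = n // 2
    padded = np.pad(np.asarray(x, float), half, mode="reflect")
    kernel = np.full(n, 1.0 / n)
    return np.convolve(padded, kernel, mode="valid")


def process_emg(
    raw: dict[str, np.ndarray],
    sampling_rate: float,
    mvc: MvcTable,
    params: FilterParams | None = None,
) -> ProcessedEmg:
    """Full conditioning chain ending in % MVC envelopes.

    Raises when a channel has no MVC entry or the MVC is not positive.
    """
    params = params or FilterParams()
    out: dict[str, np.ndarray] = {}
    for ch, x in raw.items():
        if ch not in mvc.values:
            raise EmgProcessingError(f"no MVC value for channel {ch!r}")
        if mvc[ch] <= 0:
            raise EmgProcessingError(f"MVC for channel {ch!r} must be positive")
        env = smooth_envelope(rectify(condition_raw(x, sampling_rate, params)), sampling_rate, params)
        out[ch] = env / mvc[ch] * 100.0
    return ProcessedEmg(out, sampling_rate, params)


def compute_mvc(
    trials_per_muscle: dict[str, list[np.ndarray]],
    sampling_rate: float,
    params: FilterParams | None = None,
    window_s: float = 0.500,
    condition: bool = True,
) -> MvcTable:
    """MVC per muscle from three maximal isometric trials.

    Per trial: condition and rectify; locate the peak on the smoothed
    envelope; average the *rectified* (unsmoothed) signal over the 500 ms
    window centered there, truncated symmetrically at trial edges; average
    across the three trials.  ``condition=False`` treats the inputs as
    already filtered (only rectification and windowing are applied).
    """
    params = params or FilterParams()
    half = int(round(window_s * sampling_rate / 2.0))
    values: dict[str, float] = {}
    per_trial: dict[str, list[float]] = {}
    for muscle, trials in trials_per_muscle.items():
        if len(trials) != 3:
            raise EmgProcessingError(
                f"expected exactly 3 MVC trials for {muscle!r}, got {len(trials)}"
            )
        vals = []
        for x in trials:
            x = np.asarray(x, float)
            if len(x) < 2 * half:
                raise EmgProcessingError(
                    f"MVC trial for {muscle!r} shorter than the {window_s*1e3:.0f} ms window"
                )
            rect = rectify(condition_raw(x, sampling_rate, params) if condition else x)
            smooth = smooth_envelope(rect, sampling_rate, params)
            peak = int(np.argmax(smooth))
            radius = min(half, peak, len(x) - 1 - peak)  # symmetric edge truncation
            vals.append(float(np.mean(rect[peak - radius : peak + radius + 1])))
        per_trial[muscle] = vals
        values[muscle] = float(np.mean(vals))
    return MvcTable(values, per_trial)


def compute_mvv(speed_trials: list[np.ndarray]) -> MvvValue:
    """Mean peak endpoint speed across the three maximal-velocity reaches."""
    if len(speed_trials) < 3:
        raise EmgProcessingError(f"need 3 MVV trials, got {len(speed_trials)}")
    peaks = [float(np.max(np.asarray(s, float))) for s in speed_trials]
    return MvvValue(float(np.mean(peaks)), peaks)


def background_activity(
    processed: ProcessedEmg,
    phase_start_time: float,
    trial_start_time: float = 0.0,
    window_s: float = 0.100,
) -> dict[str, float]:
    """Mean envelope (% MVC) per muscle over the 100 ms window starting at
    the pre-motion phase start — the quiescent baseline tone."""
    fs = processed.sampling_rate
    i0 = int(round((phase_start_time - trial_start_time) * fs))
    i1 = i0 + int(round(window_s * fs))
    n = len(next(iter(processed.envelopes.values())))
    if i0 < 0 or i1 > n:
        raise EmgProcessingError(
            f"background window [{i0}, {i1}) outside trial of {n} samples"
        )
    return {ch: float(np.mean(env[i0:i1])) for ch, env in processed.envelopes.items()}
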