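"""Per-trial scalar features of AVREC and layer traces.

Evoked responses are scored inside half-open windows anchored at the
stimulus event grid (200 ms windows for a 5 Hz train, 100 ms for 10 Hz;
1400 ms bins for spontaneous activity).  Per window we extract the RMS of
the trace, the most prominent peak (topographic prominence, with an
absolute floor below which the trial-window counts as "no response
detected"), the first/last response ratio across the train, and the vector
strength of peak latencies against the modulation period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .csd import compute_avrec, compute_csd, compute_layer_traces, smooth_lfp
from .types import LayerMap, LfpRecording

__all__ = [
    "WindowScheme",
    "PeakFeature",
    "window_rms",
    "detect_peak",
    "first_last_ratio",
    "vector_strength",
    "build_feature_table",
    "vector_strength_table",
    "DEFAULT_PROMINENCE_THRESHOLD",
    "FEATURE_COLUMNS",
]

#: absolute peak-prominence floor, in pipeline CSD units
DEFAULT_PROMINENCE_THRESHOLD = 0.00008

#: fixed column order of the feature table
FEATURE_COLUMNS = [
    "group",
    "animal_id",
    "measurement",
    "stimulus",
    "rate_hz",
    "trace",
    "trial",
    "window",
    "window_onset_ms",
    "rms",
    "peak_amplitude",
    "peak_latency_ms",
    "peak_prominence",
    "detected",
]

SPONTANEOUS_BIN_MS = 1400.0


@dataclass(frozen=True)
class WindowScheme:
    """Half-open analysis windows ``[onset, onset + width)`` in ms."""

    onsets: tuple[float, ...]
    width_ms: float
    mode: str = "evoked"

    def __post_init__(self):
        if self.width_ms <= 0:
            raise ValueError("width_ms must be > 0")
        if not self.onsets:
            raise ValueError("at least one window onset is required")

    @classmethod
    def evoked(cls, rate_hz: float, total_ms: float = 1000.0) -> "WindowScheme":
        """One window per stimulus event: 0-200, ..., 800-1000 ms at 5 Hz;
        100 ms windows at 10 Hz."""
        width = 1000.0 / rate_hz
        n = int(round(total_ms / width))
        return cls(tuple(i * width for i in range(n)), width, "evoked")

    @classmethod
    def spontaneous(cls, total_ms: float) -> "WindowScheme":
        """Contiguous 1400 ms bins covering the recording."""
        n = int(total_ms // SPONTANEOUS_BIN_MS)
        if n < 1:
            raise ValueError(
                f"recording of {total_ms} ms is shorter than one "
                f"{SPONTANEOUS_BIN_MS} ms bin"
            )
        return cls(tuple(i * SPONTANEOUS_BIN_MS for i in range(n)),
                   SPONTANEOUS_BIN_MS, "spontaneous")

    def sample_slices(self, fs_hz: float, n_samples: int) -> list[tuple[int, int]]:
        slices = []
        for onset in self.onsets:
            start = int(round(onset * fs_hz / 1000.0))
            stop = start + int(round(self.width_ms * fs_hz / 1000.0))
            if stop > n_samples or start < 0:
                raise ValueError(
                    f"window [{onset}, {onset + self.width_ms}) ms exceeds the "
                    f"trace of {n_samples} samples at {fs_hz} Hz"
                )
            slices.append((start, stop))
        return slices


@dataclass(frozen=True)
class PeakFeature:
    """Most prominent peak inside one window; ``detected`` is False when no
    local maximum reaches the prominence floor (the trial-window is then
    excluded from latency-based analyses downstream)."""

    amplitude: float
    latency_ms: float
    prominence: float
    detected: bool


def window_rms(trace: np.ndarray, scheme: WindowScheme, fs_hz: float) -> np.ndarray:
    """Root mean square per window, ``sqrt(mean(x**2))`` over the half-open
    window.  Sign-insensitive, so the non-negative AVREC and the
    non-positive layer traces are treated identically.  Works on a single
    trace or a trials x time stack; windows index the last axis."""
    trace = np.asarray(trace, dtype=float)
    slices = scheme.sample_slices(fs_hz, trace.shape[-1])
    out = [np.sqrt(np.mean(trace[..., a:b] ** 2, axis=-1)) for a, b in slices]
    return np.stack(out, axis=-1)


def detect_peak(
    trace: np.ndarray,
    window: tuple[int, int],
    threshold: float = DEFAULT_PROMINENCE_THRESHOLD,
    polarity: str = "positive",
    fs_hz: float = 1000.0,
) -> PeakFeature:
    """Most prominent local maximum of the windowed trace.

    ``window`` is a half-open sample range.  For ``polarity='negative'``
    (sink traces) the trace is negated before peak finding, so "peaks" are
    the deepest sinks; the returned amplitude is the original trace value.
    Topographic prominence is computed for every interior local maximum and
    the peak with the highest prominence is returned iff that prominence
    reaches ``threshold``; exact prominence ties break toward the earlier
    latency.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if polarity not in ("positive", "negative"):
        raise ValueError(f"unknown polarity {polarity!r}")
    start, stop = window
    seg = np.asarray(trace, dtype=float)[start:stop]
    if seg.size == 0:
        raise ValueError(f"window [{start}, {stop}) selects no samples")
    x = seg if polarity == "positive" else -seg
    peaks, props = find_peaks(x, prominence=(None, None))
    if peaks.size == 0:
        return PeakFeature(np.nan, np.nan, np.nan, False)
    best = int(np.argmax(props["prominences"]))  # argmax takes the first on ties
    prom = float(props["prominences"][best])
    idx = int(peaks[best])
    if prom < threshold:
        return PeakFeature(np.nan, np.nan, prom, False)
    return PeakFeature(
        amplitude=float(seg[idx]),
        latency_ms=idx * 1000.0 / fs_hz,
        prominence=prom,
        detected=True,
    )


def first_last_ratio(rms_by_window: np.ndarray) -> float:
    """RMS(first window) / RMS(last window); NaN flags an undefined ratio
    (zero last-window RMS)."""
    r = np.asarray(rms_by_window, dtype=float)
    if r.size < 2:
        raise ValueError("need at least two windows for a first/last ratio")
    if not np.all(np.isfinite(r[[0, -1]])):
        raise ValueError("first/last RMS must be finite")
    if r[-1] == 0:
        return float("nan")
    return float(r[0] / r[-1])


def vector_strength(peak_latencies_ms, mod_freq_hz: float) -> float:
    """Resultant length of unit phase vectors.

    Each latency ``t`` (ms) maps to the phase the amplitude modulation
    would have at that moment, ``theta = 2 pi f t / 1000``; the vector
    strength is ``|sum of unit vectors| / count``, 1 for perfect phase
    locking and 0 for uniformly spread phases.  Click-train latencies get
    the identical mapping (the supposed phase of an AM tone at those
    latencies).
    """
    t = np.asarray(peak_latencies_ms, dtype=float)
    if t.size == 0:
        raise ValueError("need at least one peak latency")
    if mod_freq_hz <= 0:
        raise ValueError("mod_freq_hz must be > 0")
    theta = 2.0 * np.pi * mod_freq_hz * (t / 1000.0)
    return float(np.abs(np.mean(np.exp(1j * theta))))


def _default_scheme(stimulus) -> WindowScheme:
    if stimulus.kind in ("click_train", "am_tone"):
        return WindowScheme.evoked(stimulus.rate_hz, stimulus.trial_duration_ms)
    if stimulus.kind == "tonotopy_tone":
        return WindowScheme((0.0,), 200.0, "evoked")
    return WindowScheme.spontaneous(stimulus.trial_duration_ms)


def build_feature_table(
    dataset,
    layer_map: LayerMap | None = None,
    scheme: WindowScheme | None = None,
    threshold: float = DEFAULT_PROMINENCE_THRESHOLD,
    smooth_window: int = 7,
    n: int = 1,
    pad: str = "replicate",
    traces: list[str] | None = None,
    detect_peaks: bool = True,
) -> pd.DataFrame:
    """Run the full transform chain and emit one row per (trial, window,
    trace).

    Stages per recording: Hamming depth smoothing -> CSD -> AVREC + layer
    traces -> windowed RMS and (for evoked stimuli) peak detection.  Peak
    polarity is positive for the AVREC and negative for sink traces.
    ``traces`` restricts the emitted traces (default: AVREC plus every
    mapped layer).  Row counts are exact functions of the design:
    trials x windows x traces per recording.
    """
    if layer_map is None:
        layer_map = LayerMap.default_32()
    rows: list[dict] = []
    recordings = dataset.recordings if hasattr(dataset, "recordings") else dataset
    for rec in recordings:
        if rec.stimulus is None:
            raise ValueError(f"recording {rec.animal_id!r} has no stimulus metadata")
        try:
            rec_scheme = scheme if scheme is not None else _default_scheme(rec.stimulus)
            smoothed = smooth_lfp(rec, smooth_window)
            profile = compute_csd(smoothed, n=n, pad=pad)
            trace_arrays: dict[str, np.ndarray] = {"AVREC": compute_avrec(profile)}
            trace_arrays.update(compute_layer_traces(profile, layer_map))
        except ValueError as err:
            raise ValueError(
                f"feature extraction failed for {rec.group}/{rec.animal_id}/"
                f"{rec.measurement}/{rec.stimulus.label}: {err}"
            ) from err
        if traces is not None:
            trace_arrays = {k: v for k, v in trace_arrays.items() if k in traces}
        slices = rec_scheme.sample_slices(rec.fs_hz, rec.n_samples)
        want_peaks = detect_peaks and rec_scheme.mode == "evoked"
        for trace_name, arr in trace_arrays.items():
            polarity = "positive" if trace_name == "AVREC" else "negative"
            rms = window_rms(arr, rec_scheme, rec.fs_hz)  # trials x windows
            for trial in range(arr.shape[0]):
                for w, (a, b) in enumerate(slices):
                    if want_peaks:
                        pk = detect_peak(arr[trial], (a, b), threshold, polarity, rec.fs_hz)
                    else:
                        pk = PeakFeature(np.nan, np.nan, np.nan, False)
                    rows.append(
                        {
                            "group": rec.group,
                            "animal_id": rec.animal_id,
                            "measurement": rec.measurement,
                            "stimulus": rec.stimulus.label,
                            "rate_hz": rec.stimulus.rate_hz,
                            "trace": trace_name,
                            "trial": trial,
                            "window": w,
                            "window_onset_ms": rec_scheme.onsets[w],
                            "rms": float(rms[trial, w]),
                            "peak_amplitude": pk.amplitude,
                            "peak_latency_ms": pk.latency_ms,
                            "peak_prominence": pk.prominence,
                            "detected": pk.detected,
                        }
                    )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def vector_strength_table(features: pd.DataFrame) -> pd.DataFrame:
    """Vector strength per (group, animal, measurement, stimulus) from the
    detected AVREC peak latencies, each mapped to absolute trial time
    (window onset + in-window latency) and scored against the stimulus
    modulation rate.  Windows without a detected peak contribute nothing."""
    df = features[
        (features["trace"] == "AVREC")
        & features["detected"].astype(bool)
        & features["rate_hz"].notna()
    ]
    rows = []
    for (group, animal, meas, stim, rate), sub in df.groupby(
        ["group", "animal_id", "measurement", "stimulus", "rate_hz"], sort=True
    ):
        latencies = sub["window_onset_ms"].to_numpy() + sub["peak_latency_ms"].to_numpy()
        rows.append(
            {
                "group": group,
                "animal_id": animal,
                "measurement": meas,
                "stimulus": stim,
                "rate_hz": rate,
                "n_peaks": len(latencies),
                "vector_strength": vector_strength(latencies, rate),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["group", "animal_id", "measurement", "stimulus", "rate_hz",
                 "n_peaks", "vector_strength"],
    )
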