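"""CSD, AVREC and layer-trace transforms.

The current source density is estimated as the second spatial difference of
the laminar LFP along cortical depth,

    CSD_z = (phi[z + n*dz] - 2 phi[z] + phi[z - n*dz]) / (n*dz)^2,

applied literally (no sign flip, no conductivity factor), so current sinks
— excitatory synaptic population activity — come out negative.  Before
differencing, the depth profile is smoothed with a Hamming-weighted running
average across channels (a 7-channel window at 50 um pitch is a ~300 um
spatial kernel).  The CSD is then collapsed into a per-trial AVREC trace
(mean absolute CSD over channels) and per-layer sink traces (mean of the
negative-only CSD over each layer's channels).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from scipy.signal.windows import hamming

from .types import CsdProfile, LayerMap, LfpRecording, TraceSet

__all__ = [
    "smooth_lfp",
    "compute_csd",
    "compute_avrec",
    "compute_layer_traces",
    "compute_traces",
    "find_best_frequency",
]


def smooth_lfp(rec: LfpRecording, window_channels: int = 7) -> LfpRecording:
    """Hamming-weighted running average across depth.

    Each channel is replaced by the weighted mean of itself and its
    neighbours; weights are a symmetric Hamming window normalized to unit
    sum.  At the probe edges the window is truncated and re-normalized so
    constants are preserved everywhere.  ``window_channels=1`` is the
    identity.  The time axis is untouched.
    """
    if window_channels % 2 == 0:
        raise ValueError("window_channels must be odd")
    if window_channels < 1:
        raise ValueError("window_channels must be >= 1")
    if window_channels > rec.n_channels:
        raise ValueError(
            f"window_channels={window_channels} exceeds {rec.n_channels} channels"
        )
    if window_channels == 1:
        return rec
    # banded weight matrix with rows truncated and re-normalized at the
    # edges; applying it is a single BLAS matmul over the channel axis
    w = hamming(window_channels, sym=True)
    half = window_channels // 2
    n_ch = rec.n_channels
    weights = np.zeros((n_ch, n_ch))
    for c in range(n_ch):
        lo = max(0, c - half)
        hi = min(n_ch, c + half + 1)
        row = w[lo - (c - half): window_channels - ((c + half + 1) - hi)]
        weights[c, lo:hi] = row / row.sum()
    smoothed = np.matmul(weights, rec.potentials)
    return LfpRecording(
        potentials=smoothed,
        fs_hz=rec.fs_hz,
        spacing_um=rec.spacing_um,
        group=rec.group,
        animal_id=rec.animal_id,
        measurement=rec.measurement,
        stimulus=rec.stimulus,
    )


def compute_csd(rec: LfpRecording, n: int = 1, pad: str = "none") -> CsdProfile:
    """Second spatial difference of the LFP, per trial and time sample.

    Parameters
    ----------
    n : differential grid; the difference spans ``n`` channels to each side.
    pad : ``'none'`` keeps only interior channels (the output loses ``n``
        channels at each edge); ``'replicate'`` duplicates the first/last
        channel ``n`` times so all contacts get a value, with the edge
        values flagged as ``boundary_channels`` in the provenance.
    """
    if n < 1:
        raise ValueError("differential grid n must be >= 1")
    if rec.n_channels < 2 * n + 1:
        raise ValueError(
            f"need at least {2 * n + 1} channels for differential grid n={n}, "
            f"got {rec.n_channels}"
        )
    if rec.spacing_um <= 0:
        raise ValueError("spacing_um must be > 0")
    if pad not in ("none", "replicate"):
        raise ValueError(f"unknown pad mode {pad!r}; expected 'none' or 'replicate'")

    phi = rec.potentials
    dz = n * rec.spacing_mm
    inv = 1.0 / (dz * dz)
    n_ch = rec.n_channels

    def second_diff(z):
        """(phi[z+n] - 2 phi[z] + phi[z-n]) / (n dz)^2 with replicate
        clamping of out-of-range neighbours."""
        lo = max(z - n, 0)
        hi = min(z + n, n_ch - 1)
        return (phi[:, hi, :] - 2.0 * phi[:, z, :] + phi[:, lo, :]) * inv

    # loop over the (short) channel axis: contiguous slices beat the big
    # strided three-term temporaries on wide trial x time blocks
    if pad == "replicate":
        csd = np.empty_like(phi)
        for z in range(n_ch):
            csd[:, z, :] = second_diff(z)
    else:
        csd = np.empty((phi.shape[0], n_ch - 2 * n, phi.shape[2]))
        for i, z in enumerate(range(n, n_ch - n)):
            csd[:, i, :] = second_diff(z)

    if pad == "replicate":
        channel_index = np.arange(rec.n_channels)
        boundary = list(range(n)) + list(range(rec.n_channels - n, rec.n_channels))
    else:
        channel_index = np.arange(n, rec.n_channels - n)
        boundary = []
    provenance = {
        "n": n,
        "pad": pad,
        "boundary_channels": boundary,
        "spacing_um": rec.spacing_um,
    }
    return CsdProfile(csd, channel_index, rec.fs_hz, provenance)


def compute_avrec(profile: CsdProfile) -> np.ndarray:
    """Average rectified CSD: mean over channels of |CSD| per trial and
    time sample.  A non-negative trials x time array measuring the overall
    local current flow of the column."""
    if profile.csd.shape[1] == 0:
        raise ValueError("CSD profile has no valid channels")
    return np.mean(np.abs(profile.csd), axis=1)


def compute_layer_traces(profile: CsdProfile, layers: LayerMap) -> dict[str, np.ndarray]:
    """Per-layer sink traces: positive (source) values are zeroed and the
    retained sink activity averaged over the layer's full channel count, so
    the traces are non-positive trials x time arrays."""
    out: dict[str, np.ndarray] = {}
    index = {ch: i for i, ch in enumerate(profile.channel_index)}
    for name, (start, stop) in layers.items():
        missing = [c for c in range(start, stop) if c not in index]
        if missing:
            raise ValueError(
                f"layer {name!r} channels {missing} are outside the valid CSD "
                f"channels {profile.channel_index[0]}..{profile.channel_index[-1]}"
            )
        pos = [index[c] for c in range(start, stop)]
        sinks = np.minimum(profile.csd[:, pos, :], 0.0)
        out[name] = sinks.sum(axis=1) / len(pos)
    return out


def compute_traces(profile: CsdProfile, layers: LayerMap) -> TraceSet:
    """AVREC plus layer traces bundled on the profile's clock."""
    return TraceSet(
        avrec=compute_avrec(profile),
        layer_traces=compute_layer_traces(profile, layers),
        fs_hz=profile.fs_hz,
    )


def _frequency_sort_key(label):
    try:
        return (0, float(label))
    except (TypeError, ValueError):
        return (1, str(label))


def find_best_frequency(
    tonotopy_profiles: Mapping[object, CsdProfile],
    layers: LayerMap,
    window_ms: tuple[float, float] = (0.0, 200.0),
):
    """Best frequency: the pure tone evoking the strongest granular response.

    For each frequency, the layer-IV sink trace is computed, averaged over
    trials, and its RMS taken over the post-onset window (0-200 ms by
    default); the frequency maximizing that RMS wins, ties going to the
    lowest frequency.
    """
    if not tonotopy_profiles:
        raise ValueError("at least one tonotopy frequency is required")
    if "IV" not in layers:
        raise ValueError("granular layer 'IV' missing from LayerMap")
    best_label, best_rms = None, -np.inf
    for label in sorted(tonotopy_profiles, key=_frequency_sort_key):
        profile = tonotopy_profiles[label]
        trace = compute_layer_traces(profile, layers)["IV"].mean(axis=0)
        i0 = int(round(window_ms[0] * profile.fs_hz / 1000.0))
        i1 = int(round(window_ms[1] * profile.fs_hz / 1000.0))
        seg = trace[i0:i1]
        if seg.size == 0:
            raise ValueError(f"window {window_ms} ms is empty for frequency {label!r}")
        rms = float(np.sqrt(np.mean(seg * seg)))
        if rms > best_rms:
            best_label, best_rms = label, rms
    return best_label
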