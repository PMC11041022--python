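"""Core data model for laminar LFP/CSD analysis.

The containers here mirror a standard laminar recording setup: a linear
multi-contact probe inserted perpendicular to the cortical surface records
local field potentials (LFP) on ``n_channels`` contacts at ``spacing_um``
pitch while auditory stimuli are presented.  Everything downstream (CSD,
AVREC, layer traces, features, statistics) consumes these types.

Conventions
-----------
* Arrays are ``trials x channels x time`` with channel 0 the most
  superficial contact.  Channel indices are 0-based in code; configuration
  files and documentation tables use the 1-based electrophysiology
  convention, converted on load.
* Time is stored in samples with an ``fs_hz`` attribute; user-facing
  quantities are in milliseconds.
* CSD sign convention: sinks (net inward current, excitatory synaptic
  activity) are negative, sources positive.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "StimulusSpec",
    "SinkEvent",
    "GroupSpec",
    "SimConfig",
    "CsdGroundTruth",
    "LfpRecording",
    "CsdProfile",
    "LayerMap",
    "TraceSet",
    "PRE_LASER",
    "POST_LASER",
    "MEASUREMENTS",
]

PRE_LASER = "pre_laser"
POST_LASER = "post_laser"
MEASUREMENTS = (PRE_LASER, POST_LASER)

#: stimulus kinds understood by the generator and the feature extractor
STIMULUS_KINDS = ("click_train", "am_tone", "tonotopy_tone", "spontaneous")

#: fixed stimulus duration for click trains and AM tones, ms
TRAIN_DURATION_MS = 999.0


@dataclass(frozen=True)
class StimulusSpec:
    """Description of one auditory stimulus condition.

    ``onset_times`` are the event onsets (clicks, or AM cycle starts) in ms
    relative to trial start.  For click trains and AM tones they sit on the
    1000/rate grid inside ``[0, duration_ms)``.  ``trial_duration_ms`` is the
    recorded trial length, which may outlast the stimulus (evoked trials are
    recorded for a full second around the 999 ms stimulus so the last
    response window is complete).
    """

    kind: str
    rate_hz: float | None = None
    duration_ms: float = TRAIN_DURATION_MS
    onset_times: tuple[float, ...] = ()
    carrier_label: str = ""
    trial_duration_ms: float | None = None

    def __post_init__(self):
        if self.kind not in STIMULUS_KINDS:
            raise ValueError(
                f"unknown stimulus kind {self.kind!r}; expected one of {STIMULUS_KINDS}"
            )
        if self.kind in ("click_train", "am_tone"):
            if self.rate_hz is None or self.rate_hz <= 0:
                raise ValueError(f"{self.kind} requires a positive rate_hz")
            if self.duration_ms != TRAIN_DURATION_MS:
                raise ValueError(
                    f"{self.kind} duration_ms must be {TRAIN_DURATION_MS}"
                )
            period = 1000.0 / self.rate_hz
            for t in self.onset_times:
                if not (0 <= t < self.duration_ms):
                    raise ValueError(f"onset {t} ms outside [0, {self.duration_ms})")
                if abs(t / period - round(t / period)) > 1e-9:
                    raise ValueError(
                        f"onset {t} ms is not a multiple of the {period} ms period"
                    )
        if self.trial_duration_ms is None:
            default = 1000.0 if self.kind in ("click_train", "am_tone") else self.duration_ms
            object.__setattr__(self, "trial_duration_ms", default)

    # -- constructors ------------------------------------------------------
    @classmethod
    def click_train(cls, rate_hz: float, carrier_label: str = "BF") -> "StimulusSpec":
        period = 1000.0 / rate_hz
        onsets = tuple(i * period for i in range(int(math.ceil(TRAIN_DURATION_MS / period))))
        return cls("click_train", rate_hz, TRAIN_DURATION_MS, onsets, carrier_label)

    @classmethod
    def am_tone(cls, rate_hz: float, carrier_label: str = "BF") -> "StimulusSpec":
        period = 1000.0 / rate_hz
        onsets = tuple(i * period for i in range(int(math.ceil(TRAIN_DURATION_MS / period))))
        return cls("am_tone", rate_hz, TRAIN_DURATION_MS, onsets, carrier_label)

    @classmethod
    def tonotopy_tone(cls, frequency_label: str, duration_ms: float = 200.0) -> "StimulusSpec":
        return cls("tonotopy_tone", None, duration_ms, (0.0,), frequency_label,
                   trial_duration_ms=max(400.0, duration_ms * 2))

    @classmethod
    def spontaneous(cls, duration_ms: float = 2800.0) -> "StimulusSpec":
        return cls("spontaneous", None, duration_ms, (), "")

    # -- helpers -----------------------------------------------------------
    def n_samples(self, fs_hz: float) -> int:
        return int(round(self.trial_duration_ms * fs_hz / 1000.0))

    @property
    def label(self) -> str:
        if self.rate_hz is not None:
            return f"{self.kind}_{self.rate_hz:g}hz"
        if self.kind == "tonotopy_tone":
            return f"{self.kind}_{self.carrier_label}"
        return self.kind

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "rate_hz": self.rate_hz,
                "duration_ms": self.duration_ms,
                "onset_times": list(self.onset_times),
                "carrier_label": self.carrier_label,
                "trial_duration_ms": self.trial_duration_ms,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "StimulusSpec":
        d = json.loads(s)
        d["onset_times"] = tuple(d["onset_times"])
        return cls(**d)


@dataclass(frozen=True)
class SinkEvent:
    """One laminar sink component of the evoked response template.

    A sink is modelled as a Gaussian in depth (center/width in channel
    units) with a difference-of-exponentials time course triggered at each
    stimulus onset (plus ``onset`` ms of lag).  ``amplitude`` is in CSD
    units; negative values are sinks, which is the physiological case.
    """

    layer_name: str
    depth_center: float
    depth_sigma: float
    onset: float = 0.0
    rise_tau: float = 5.0
    decay_tau: float = 30.0
    amplitude: float = -0.01

    def __post_init__(self):
        if self.depth_sigma <= 0:
            raise ValueError("depth_sigma must be > 0")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("rise_tau and decay_tau must be > 0")
        if self.rise_tau == self.decay_tau:
            raise ValueError("rise_tau must differ from decay_tau")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")


@dataclass(frozen=True)
class GroupSpec:
    """One subject group with its evoked-response gain before/after laser."""

    name: str
    n_animals: int
    evoked_gain_pre: float = 1.0
    evoked_gain_post: float = 1.0

    def __post_init__(self):
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.evoked_gain_pre <= 0 or self.evoked_gain_post <= 0:
            raise ValueError("evoked gains must be > 0")

    def gain(self, measurement: str) -> float:
        return self.evoked_gain_pre if measurement == PRE_LASER else self.evoked_gain_post


def default_groups() -> tuple[GroupSpec, ...]:
    """The three-group optogenetics design: a treated group whose evoked
    responses are multiplicatively suppressed after the light pulse
    (post/pre gain ratio exp(-0.13) on the evoked amplitude, i.e. a -0.13
    shift in log response strength) and two unaffected control groups."""
    return (
        GroupSpec("treated", 10, 1.0, float(np.exp(-0.13))),
        GroupSpec("naive_control", 10, 1.0, 1.0),
        GroupSpec("viral_control", 7, 1.0, 1.0),
    )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic laminar experiment.

    Noise model: each animal carries a lognormal baseline factor
    (``animal_baseline_sd`` log-units, drawn once per animal), each trial a
    lognormal evoked-amplitude factor (``trial_gain_sd`` log-units) and
    additive i.i.d. Gaussian noise in CSD space (``trial_noise_sd`` CSD
    units), injected before the forward model so it is spatially structured
    in the LFP.
    """

    n_channels: int = 32
    spacing_um: float = 50.0
    fs_hz: float = 1000.0
    groups: tuple[GroupSpec, ...] = field(default_factory=default_groups)
    n_trials_per_condition: int = 50
    animal_baseline_sd: float = 0.3
    trial_gain_sd: float = 0.25
    trial_noise_sd: float = 1e-4
    spont_amplitude: float = 0.001
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_channels < 5:
            raise ValueError("n_channels must be >= 5")
        if self.spacing_um <= 0 or self.fs_hz <= 0:
            raise ValueError("spacing_um and fs_hz must be > 0")
        if self.n_trials_per_condition < 1:
            raise ValueError("n_trials_per_condition must be >= 1")
        for sd in (self.animal_baseline_sd, self.trial_gain_sd, self.trial_noise_sd,
                   self.spont_amplitude):
            if sd < 0:
                raise ValueError("noise scales must be >= 0")

    @property
    def spacing_mm(self) -> float:
        return self.spacing_um / 1000.0

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, rng_seed=int(seed))


@dataclass
class CsdGroundTruth:
    """A noise-free CSD template (channels x time) with its provenance.

    By construction every time slice sums to zero across channels (charge
    balance): each Gaussian sink is compensated by two flanking source bands
    carrying half its integral each.
    """

    array: np.ndarray
    events: tuple[SinkEvent, ...]
    stimulus: StimulusSpec

    def __post_init__(self):
        self.array = np.asarray(self.array, dtype=float)
        if self.array.ndim != 2:
            raise ValueError("ground-truth array must be channels x time")
        if not np.all(np.isfinite(self.array)):
            raise ValueError("ground-truth array must be finite")


@dataclass
class LfpRecording:
    """Multi-trial laminar LFP block for one animal/measurement/stimulus."""

    potentials: np.ndarray  # trials x channels x time
    fs_hz: float = 1000.0
    spacing_um: float = 50.0
    group: str = ""
    animal_id: str = ""
    measurement: str = PRE_LASER
    stimulus: StimulusSpec | None = None

    def __post_init__(self):
        self.potentials = np.asarray(self.potentials, dtype=float)
        if self.potentials.ndim != 3:
            raise ValueError("potentials must be trials x channels x time")
        if not np.all(np.isfinite(self.potentials)):
            raise ValueError("potentials must be finite")
        if self.fs_hz <= 0 or self.spacing_um <= 0:
            raise ValueError("fs_hz and spacing_um must be > 0")

    @property
    def n_trials(self) -> int:
        return self.potentials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.potentials.shape[1]

    @property
    def n_samples(self) -> int:
        return self.potentials.shape[2]

    @property
    def spacing_mm(self) -> float:
        return self.spacing_um / 1000.0


@dataclass
class CsdProfile:
    """CSD estimate with bookkeeping of where the second difference was
    computable.  ``channel_index`` maps rows of ``csd`` back to contacts of
    the original probe; with ``pad='none'`` the edge contacts are absent,
    with ``pad='replicate'`` they are present but flagged as boundary
    values in ``provenance``."""

    csd: np.ndarray  # trials x kept-channels x time
    channel_index: np.ndarray
    fs_hz: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.csd = np.asarray(self.csd, dtype=float)
        self.channel_index = np.asarray(self.channel_index, dtype=int)
        if self.csd.ndim != 3:
            raise ValueError("csd must be trials x channels x time")
        if self.csd.shape[1] != self.channel_index.size:
            raise ValueError("channel_index length must match csd channel axis")

    @property
    def valid_channels(self) -> np.ndarray:
        return self.channel_index

    @property
    def n_trials(self) -> int:
        return self.csd.shape[0]


class LayerMap:
    """Ordered mapping of layer names to contiguous probe-channel ranges.

    Ranges are stored 0-based half-open; :meth:`from_dict` accepts the
    1-based inclusive convention used in configuration files and
    electrophysiology tables.
    """

    def __init__(self, ranges: Mapping[str, tuple[int, int]], n_channels: int | None = None):
        self.ranges: dict[str, tuple[int, int]] = {}
        occupied: list[tuple[int, int, str]] = []
        for name, (start, stop) in ranges.items():
            start, stop = int(start), int(stop)
            if stop <= start:
                raise ValueError(f"layer {name!r} range is empty")
            if start < 0:
                raise ValueError(f"layer {name!r} starts below channel 0")
            if n_channels is not None and stop > n_channels:
                raise ValueError(f"layer {name!r} exceeds {n_channels} channels")
            for s, e, other in occupied:
                if start < e and s < stop:
                    raise ValueError(f"layers {name!r} and {other!r} overlap")
            occupied.append((start, stop, name))
            self.ranges[name] = (start, stop)

    @classmethod
    def default_32(cls) -> "LayerMap":
        # 1-based inclusive: II=1-6, IV=7-12, V=13-20, VI=21-26; 27-32 unassigned
        return cls({"II": (0, 6), "IV": (6, 12), "V": (12, 20), "VI": (20, 26)}, 32)

    @classmethod
    def from_dict(cls, d: Mapping[str, tuple[int, int]], n_channels: int | None = None) -> "LayerMap":
        """Build from 1-based inclusive ranges, e.g. ``{"II": [1, 6]}``."""
        return cls({k: (int(v[0]) - 1, int(v[1])) for k, v in d.items()}, n_channels)

    def channels(self, name: str) -> np.ndarray:
        start, stop = self.ranges[name]
        return np.arange(start, stop)

    def __contains__(self, name: str) -> bool:
        return name in self.ranges

    def __iter__(self):
        return iter(self.ranges)

    def items(self):
        return self.ranges.items()

    def __repr__(self) -> str:
        inner = ", ".join(f"{k}={v[0] + 1}-{v[1]}" for k, v in self.ranges.items())
        return f"LayerMap({inner})"


@dataclass
class TraceSet:
    """AVREC trace (>= 0) and per-layer sink traces (<= 0) per trial."""

    avrec: np.ndarray  # trials x time
    layer_traces: dict[str, np.ndarray]
    fs_hz: float

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.avrec.shape[1]) * 1000.0 / self.fs_hz
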