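"""On-disk data model and run configuration.

Datasets are HDF5 containers: one group ``/recordings/<id>`` per LFP block
with a ``lfp`` dataset (trials x channels x time, float64) and attributes
``fs_hz``, ``spacing_um``, ``group``, ``animal_id``, ``measurement`` and
``stimulus`` (a JSON-encoded stimulus spec); root attributes carry
``format_version``, ``rng_seed`` and ``created_by``.  The provenance table
of a simulated dataset is stored column-wise under ``/provenance``.

Run configurations are YAML documents validated against a strict pydantic
schema (unknown keys rejected) before any computation.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .features import DEFAULT_PROMINENCE_THRESHOLD
from .stats import DEFAULT_N_TESTS
from .synth import SimulatedDataset
from .types import GroupSpec, LayerMap, LfpRecording, SimConfig, StimulusSpec

__all__ = [
    "FORMAT_VERSION",
    "write_dataset",
    "read_dataset",
    "write_recording_npz",
    "read_recording_npz",
    "RunConfig",
    "load_config",
]

FORMAT_VERSION = "1.0"

_REQUIRED_REC_ATTRS = ("fs_hz", "spacing_um", "group", "animal_id", "measurement", "stimulus")


# ---------------------------------------------------------------------------
# HDF5 dataset container
# ---------------------------------------------------------------------------

def write_dataset(dataset, path, rng_seed: int | None = None) -> None:
    """Write a dataset (anything iterating :class:`LfpRecording`, e.g. a
    :class:`SimulatedDataset`) to the HDF5 layout."""
    recordings = list(dataset.recordings if hasattr(dataset, "recordings") else dataset)
    if not recordings:
        raise ValueError("dataset has no recordings")
    n_channels = {r.n_channels for r in recordings}
    if len(n_channels) != 1:
        raise ValueError(f"all recordings in a file must share channel count, got {n_channels}")
    if rng_seed is None:
        cfg = getattr(dataset, "config", None)
        rng_seed = getattr(cfg, "rng_seed", -1) if cfg is not None else -1
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["rng_seed"] = int(rng_seed)
        f.attrs["created_by"] = "lamcsd"
        grp = f.create_group("recordings")
        for i, rec in enumerate(recordings):
            g = grp.create_group(f"rec_{i:04d}")
            g.create_dataset("lfp", data=rec.potentials)
            g.attrs["fs_hz"] = float(rec.fs_hz)
            g.attrs["spacing_um"] = float(rec.spacing_um)
            g.attrs["group"] = rec.group
            g.attrs["animal_id"] = rec.animal_id
            g.attrs["measurement"] = rec.measurement
            g.attrs["stimulus"] = rec.stimulus.to_json() if rec.stimulus else ""
        prov = getattr(dataset, "provenance", None)
        if prov is not None and len(prov):
            pg = f.create_group("provenance")
            for col in prov.columns:
                values = prov[col].to_numpy()
                if values.dtype.kind in ("O", "U"):
                    pg.create_dataset(col, data=np.asarray(values, dtype=object),
                                      dtype=h5py.string_dtype("utf-8"))
                else:
                    pg.create_dataset(col, data=values)
            pg.attrs["columns"] = json.dumps(list(prov.columns))


def read_dataset(path) -> SimulatedDataset:
    """Read a dataset file back; arrays round-trip bit-exactly and metadata
    field-for-field.  Missing attributes and unsupported versions raise."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version is None:
            raise ValueError(f"{path}: missing root attribute 'format_version'")
        if str(version) != FORMAT_VERSION:
            raise ValueError(
                f"{path}: unsupported format_version {version!r} "
                f"(supported: {FORMAT_VERSION})"
            )
        recordings = []
        for rec_id in sorted(f["recordings"]):
            g = f["recordings"][rec_id]
            for attr in _REQUIRED_REC_ATTRS:
                if attr not in g.attrs:
                    raise ValueError(f"{path}: recording {rec_id!r} lacks attribute {attr!r}")
            stim_json = g.attrs["stimulus"]
            recordings.append(
                LfpRecording(
                    potentials=g["lfp"][()],
                    fs_hz=float(g.attrs["fs_hz"]),
                    spacing_um=float(g.attrs["spacing_um"]),
                    group=str(g.attrs["group"]),
                    animal_id=str(g.attrs["animal_id"]),
                    measurement=str(g.attrs["measurement"]),
                    stimulus=StimulusSpec.from_json(stim_json) if stim_json else None,
                )
            )
        provenance = pd.DataFrame()
        if "provenance" in f:
            pg = f["provenance"]
            columns = json.loads(pg.attrs["columns"])
            data = {}
            for col in columns:
                values = pg[col][()]
                if values.dtype.kind in ("O", "S"):
                    values = np.array([v.decode() if isinstance(v, bytes) else v for v in values])
                data[col] = values
            provenance = pd.DataFrame(data, columns=columns)
    return SimulatedDataset(recordings, provenance, None)


# ---------------------------------------------------------------------------
# single-recording NPZ interchange
# ---------------------------------------------------------------------------

def write_recording_npz(rec: LfpRecording, path) -> None:
    np.savez(
        path,
        potentials=rec.potentials,
        fs_hz=rec.fs_hz,
        spacing_um=rec.spacing_um,
        group=rec.group,
        animal_id=rec.animal_id,
        measurement=rec.measurement,
        stimulus=rec.stimulus.to_json() if rec.stimulus else "",
    )


def read_recording_npz(path) -> LfpRecording:
    with np.load(path, allow_pickle=False) as z:
        stim = str(z["stimulus"])
        return LfpRecording(
            potentials=z["potentials"],
            fs_hz=float(z["fs_hz"]),
            spacing_um=float(z["spacing_um"]),
            group=str(z["group"]),
            animal_id=str(z["animal_id"]),
            measurement=str(z["measurement"]),
            stimulus=StimulusSpec.from_json(stim) if stim else None,
        )


# ---------------------------------------------------------------------------
# run configuration (YAML -> validated model)
# ---------------------------------------------------------------------------

class GroupCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    n_animals: int = Field(ge=1)
    evoked_gain_pre: float = Field(default=1.0, gt=0)
    evoked_gain_post: float = Field(default=1.0, gt=0)


class StimulusCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str
    rate_hz: float | None = None

    def to_spec(self) -> StimulusSpec:
        if self.kind == "click_train":
            return StimulusSpec.click_train(self.rate_hz)
        if self.kind == "am_tone":
            return StimulusSpec.am_tone(self.rate_hz)
        if self.kind == "spontaneous":
            return StimulusSpec.spontaneous()
        raise ValueError(f"unknown stimulus kind {self.kind!r} in config")


def _default_group_cfgs() -> list[GroupCfg]:
    return [
        GroupCfg(name="treated", n_animals=10, evoked_gain_pre=1.0,
                 evoked_gain_post=float(np.exp(-0.13))),
        GroupCfg(name="naive_control", n_animals=10),
        GroupCfg(name="viral_control", n_animals=7),
    ]


class SimulationCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_channels: int = Field(default=32, ge=5)
    spacing_um: float = Field(default=50.0, gt=0)
    fs_hz: float = Field(default=1000.0, gt=0)
    n_trials_per_condition: int = Field(default=50, ge=1)
    animal_baseline_sd: float = Field(default=0.3, ge=0)
    trial_gain_sd: float = Field(default=0.25, ge=0)
    trial_noise_sd: float = Field(default=1e-4, ge=0)
    spont_amplitude: float = Field(default=0.001, ge=0)
    rng_seed: int = 0
    groups: list[GroupCfg] = Field(default_factory=_default_group_cfgs)
    stimuli: list[StimulusCfg] = Field(
        default_factory=lambda: [StimulusCfg(kind="click_train", rate_hz=5.0)]
    )

    def to_sim_config(self, seed: int | None = None) -> SimConfig:
        return SimConfig(
            n_channels=self.n_channels,
            spacing_um=self.spacing_um,
            fs_hz=self.fs_hz,
            groups=tuple(
                GroupSpec(g.name, g.n_animals, g.evoked_gain_pre, g.evoked_gain_post)
                for g in self.groups
            ),
            n_trials_per_condition=self.n_trials_per_condition,
            animal_baseline_sd=self.animal_baseline_sd,
            trial_gain_sd=self.trial_gain_sd,
            trial_noise_sd=self.trial_noise_sd,
            spont_amplitude=self.spont_amplitude,
            rng_seed=self.rng_seed if seed is None else int(seed),
        )

    def to_stimuli(self) -> list[StimulusSpec]:
        return [s.to_spec() for s in self.stimuli]


class WindowCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    # per-rate window widths, ms; one window per stimulus event by default
    width_5hz_ms: float = Field(default=200.0, gt=0)
    width_10hz_ms: float = Field(default=100.0, gt=0)
    spontaneous_bin_ms: float = Field(default=1400.0, gt=0)


class PeakCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    threshold: float = Field(default=DEFAULT_PROMINENCE_THRESHOLD, ge=0)
    avrec_polarity: str = "positive"
    layer_polarity: str = "negative"


class StatsCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    reference_group: str = "treated"
    reference_measurement: str = "post_laser"
    n_tests: int = Field(default=DEFAULT_N_TESTS, ge=1)
    alpha: float = Field(default=0.05, gt=0, lt=1)


class OutputCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dir: str = "out"
    figures: bool = True
    write_dataset: bool = False


# 1-based inclusive channel ranges in config files
_DEFAULT_LAYER_MAP = {"II": (1, 6), "IV": (7, 12), "V": (13, 20), "VI": (21, 26)}


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    simulation: SimulationCfg = Field(default_factory=SimulationCfg)
    layer_map: dict[str, tuple[int, int]] = Field(
        default_factory=lambda: dict(_DEFAULT_LAYER_MAP)
    )
    window: WindowCfg = Field(default_factory=WindowCfg)
    peak: PeakCfg = Field(default_factory=PeakCfg)
    stats: StatsCfg = Field(default_factory=StatsCfg)
    output: OutputCfg = Field(default_factory=OutputCfg)
    smooth_window_channels: int = Field(default=7, ge=1)
    csd_grid_n: int = Field(default=1, ge=1)
    csd_pad: str = "replicate"

    @field_validator("smooth_window_channels")
    @classmethod
    def _odd_window(cls, v):
        if v % 2 == 0:
            raise ValueError("smooth_window_channels must be odd")
        return v

    @field_validator("csd_pad")
    @classmethod
    def _pad_mode(cls, v):
        if v not in ("none", "replicate"):
            raise ValueError("csd_pad must be 'none' or 'replicate'")
        return v

    @model_validator(mode="after")
    def _check_layers(self):
        # validates non-overlap / range before any computation
        LayerMap.from_dict(self.layer_map, self.simulation.n_channels)
        return self

    def to_layer_map(self) -> LayerMap:
        return LayerMap.from_dict(self.layer_map, self.simulation.n_channels)


def load_config(path) -> RunConfig:
    """Load and schema-validate a YAML run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return RunConfig.model_validate(data)
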