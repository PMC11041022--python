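"""End-to-end report generation.

Stage order mirrors the analysis chain: simulate (or load) -> depth
smoothing -> CSD -> AVREC/layer traces -> windowed RMS and peaks ->
mixed model, Bonferroni t-tests with Cohen's d, vector-strength ANOVA.
Every stage logs its parameters and row/trial counts; identical config and
seed yield byte-identical CSV reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import csd as csd_mod
from . import features as feat_mod
from . import stats as stats_mod
from .io import RunConfig, write_dataset
from .synth import SimulatedDataset, simulate_experiment
from .types import LayerMap

logger = logging.getLogger("lamcsd.pipeline")

__all__ = ["PipelineResult", "run_pipeline"]

#: float format used for every CSV so reports are byte-stable
CSV_FLOAT_FORMAT = "%.12g"


@dataclass
class PipelineResult:
    features: pd.DataFrame
    lmm: dict[str, pd.DataFrame]
    ttests: pd.DataFrame
    vector_strength: pd.DataFrame
    anova: pd.DataFrame | None
    summary: dict
    outdir: Path | None


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT, lineterminator="\n")


def _plot_figures(dataset: SimulatedDataset, config: RunConfig, layer_map: LayerMap,
                  outdir: Path) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    # group recordings by (group, measurement) for the first evoked stimulus
    evoked = [r for r in dataset.recordings if r.stimulus and r.stimulus.kind != "spontaneous"]
    if not evoked:
        return written
    stim_label = evoked[0].stimulus.label
    groups = list(dict.fromkeys(r.group for r in evoked))

    def mean_traces(group, measurement):
        """Grand-average CSD and AVREC over all animals of a cell."""
        profiles, avrecs = [], []
        for rec in evoked:
            if rec.group != group or rec.measurement != measurement:
                continue
            if rec.stimulus.label != stim_label:
                continue
            smoothed = csd_mod.smooth_lfp(rec, config.smooth_window_channels)
            profile = csd_mod.compute_csd(smoothed, n=config.csd_grid_n, pad=config.csd_pad)
            profiles.append(profile.csd.mean(axis=0))
            avrecs.append(csd_mod.compute_avrec(profile).mean(axis=0))
        return np.mean(profiles, axis=0), np.mean(avrecs, axis=0)

    for group in groups:
        fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        cell = {}
        for ax, meas in zip(axes, ("pre_laser", "post_laser")):
            csd_img, av = mean_traces(group, meas)
            cell[meas] = av
            vmax = np.max(np.abs(csd_img))
            im = ax.imshow(csd_img, aspect="auto", cmap="RdBu_r",
                           vmin=-vmax, vmax=vmax, origin="upper")
            ax.set_title(f"{group} {meas}")
            ax.set_xlabel("time (ms)")
            ax.set_ylabel("channel (depth)")
        fig.colorbar(im, ax=axes, label="CSD (a.u., sinks blue)")
        fig_path = outdir / f"csd_heatmap_{group}_{stim_label}.png"
        fig.savefig(fig_path, dpi=110)
        plt.close(fig)
        written.append(fig_path.name)

        fig, ax = plt.subplots(figsize=(7, 3.5))
        t = np.arange(cell["pre_laser"].size)
        ax.plot(t, cell["pre_laser"], color="#e8975a", label="pre-laser")
        ax.plot(t, cell["post_laser"], color="#5aa7e8", label="post-laser")
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("AVREC (a.u.)")
        ax.set_title(f"{group}: AVREC pre vs post, {stim_label}")
        ax.legend()
        fig.tight_layout()
        fig_path = outdir / f"avrec_overlay_{group}_{stim_label}.png"
        fig.savefig(fig_path, dpi=110)
        plt.close(fig)
        written.append(fig_path.name)
    return written


def run_pipeline(
    config: RunConfig,
    seed: int | None = None,
    outdir: str | Path | None = None,
    dataset: SimulatedDataset | None = None,
) -> PipelineResult:
    """Execute the full chain and (optionally) write the report to disk.

    ``dataset`` may be supplied to analyze pre-existing recordings;
    otherwise a synthetic experiment is simulated from the config.  ``seed``
    overrides the config's rng seed.
    """
    layer_map = config.to_layer_map()

    if dataset is None:
        sim_config = config.simulation.to_sim_config(seed)
        stimuli = config.simulation.to_stimuli()
        logger.info("simulating: %d groups, %d trials/condition, seed=%d",
                    len(sim_config.groups), sim_config.n_trials_per_condition,
                    sim_config.rng_seed)
        dataset = simulate_experiment(sim_config, stimuli)
    logger.info("dataset: %d recordings", len(dataset.recordings))

    features = feat_mod.build_feature_table(
        dataset,
        layer_map=layer_map,
        threshold=config.peak.threshold,
        smooth_window=config.smooth_window_channels,
        n=config.csd_grid_n,
        pad=config.csd_pad,
    )
    logger.info("feature table: %d rows", len(features))

    spec = stats_mod.LmmSpec(
        reference_group=config.stats.reference_group,
        reference_measurement=config.stats.reference_measurement,
    )
    lmm_tables: dict[str, pd.DataFrame] = {}
    first_window = features[features["window"] == 0]
    for (stim, trace), sub in first_window.groupby(["stimulus", "trace"], sort=True):
        if sub["measurement"].nunique() < 2 or sub["group"].nunique() < 2:
            continue
        lmm_tables[f"{stim}:{trace}"] = stats_mod.fit_lmm(sub, spec)
    logger.info("fitted %d mixed models", len(lmm_tables))

    ttest_frames = []
    for stim, sub in first_window.groupby("stimulus", sort=True):
        tab = stats_mod.run_ttest_family(sub)
        tab.insert(0, "stimulus", stim)
        ttest_frames.append(tab)
    ttests = pd.concat(ttest_frames, ignore_index=True) if ttest_frames else pd.DataFrame()

    vs = feat_mod.vector_strength_table(features)
    anova = None
    if len(vs) and vs["group"].nunique() >= 2 and vs["measurement"].nunique() >= 2:
        try:
            anova = stats_mod.vs_anova(vs)
        except ValueError as err:
            logger.warning("vector-strength ANOVA skipped: %s", err)

    summary = {
        "n_recordings": len(dataset.recordings),
        "n_feature_rows": int(len(features)),
        "lmm": {k: v[["term", "estimate", "se", "p"]].to_dict("records")
                for k, v in lmm_tables.items()},
        "anova": anova.to_dict("records") if anova is not None else None,
    }

    out_path = None
    if outdir is not None:
        out_path = Path(outdir)
        out_path.mkdir(parents=True, exist_ok=True)
        _write_csv(features, out_path / "features.csv")
        for key, tab in lmm_tables.items():
            safe = key.replace(":", "_")
            _write_csv(tab, out_path / f"lmm_{safe}.csv")
        _write_csv(ttests, out_path / "ttests.csv")
        _write_csv(vs, out_path / "vector_strength.csv")
        if anova is not None:
            _write_csv(anova, out_path / "anova_vector_strength.csv")
        (out_path / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        if config.output.write_dataset:
            write_dataset(dataset, out_path / "dataset.h5")
        if config.output.figures:
            figs = _plot_figures(dataset, config, layer_map, out_path)
            logger.info("wrote %d figures", len(figs))
        logger.info("report written to %s", out_path)

    return PipelineResult(features, lmm_tables, ttests, vs, anova, summary, out_path)
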