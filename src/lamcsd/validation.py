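"""Simulation studies validating the pipeline against known ground truth.

These are the package's own calibration experiments: forward/inverse
exactness of the CSD estimator, recovery of an injected multiplicative
evoked suppression by the log-RMS mixed model, and family-wise error
control of the Bonferroni t-test family under a null experiment.  They are
reused by the test suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .csd import compute_csd
from .features import build_feature_table
from .stats import LmmSpec, fit_lmm, run_ttest_family
from .synth import lfp_from_csd_array, simulate_experiment
from .types import GroupSpec, LfpRecording, SimConfig, StimulusSpec

__all__ = [
    "csd_roundtrip_max_error",
    "lmm_recovery_study",
    "fwer_null_study",
]

TRUE_LOG_SUPPRESSION = -0.13


def csd_roundtrip_max_error(
    n_arrays: int = 100,
    seed: int = 0,
    shape: tuple[int, int] = (32, 1000),
    spacing_mm: float = 0.05,
) -> float:
    """Worst normwise relative error of CSD-estimate(forward-model(x))
    against x on interior channels, ``max|back - x| / max|x|``, over
    ``n_arrays`` standard-normal CSD arrays."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_arrays):
        csd = rng.standard_normal((1, *shape))
        phi = lfp_from_csd_array(csd, spacing_mm)
        rec = LfpRecording(phi, 1000.0, spacing_mm * 1000.0)
        back = compute_csd(rec, n=1, pad="none").csd
        x = csd[:, 1:-1, :]
        rel = float(np.max(np.abs(back - x)) / np.max(np.abs(x)))
        worst = max(worst, rel)
    return worst


def recovery_config(seed: int, log_suppression: float = TRUE_LOG_SUPPRESSION) -> SimConfig:
    """The full-scale recovery design: 10/10/7 animals, 50 trials/condition,
    treated-only post-laser evoked suppression of exp(log_suppression)."""
    return SimConfig(
        groups=(
            GroupSpec("treated", 10, 1.0, float(np.exp(log_suppression))),
            GroupSpec("naive_control", 10, 1.0, 1.0),
            GroupSpec("viral_control", 7, 1.0, 1.0),
        ),
        rng_seed=int(seed),
    )


def _treated_post_vs_pre(lmm_table: pd.DataFrame) -> tuple[float, float]:
    """post - pre log-RMS contrast at the reference (treated) group: the
    negated pre_laser main-effect coefficient."""
    pre = lmm_table[
        lmm_table["term"].str.contains("pre_laser", regex=False)
        & ~lmm_table["term"].str.contains(":")
    ]
    if len(pre) != 1:
        raise ValueError("could not locate the pre_laser main-effect term")
    return -float(pre.iloc[0]["estimate"]), float(pre.iloc[0]["se"])


def lmm_recovery_single(seed: int, log_suppression: float = TRUE_LOG_SUPPRESSION) -> dict:
    """One replicate: simulate the full design, extract first-window AVREC
    RMS, fit the mixed model, return the treated post-vs-pre contrast."""
    config = recovery_config(seed, log_suppression)
    dataset = simulate_experiment(config, [StimulusSpec.click_train(5)])
    feats = build_feature_table(dataset, traces=["AVREC"], detect_peaks=False)
    table = fit_lmm(feats[feats["window"] == 0], LmmSpec())
    est, se = _treated_post_vs_pre(table)
    return {"estimate": est, "se": se,
            "covered": abs(est - log_suppression) <= 1.96 * se,
            "negative": est < 0}


def lmm_recovery_study(
    n_replicates: int = 100,
    seed: int = 0,
    log_suppression: float = TRUE_LOG_SUPPRESSION,
) -> pd.DataFrame:
    """Parameter-recovery experiment over seeded replicates."""
    rows = []
    base = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    for rep_seed in base:
        rows.append(lmm_recovery_single(int(rep_seed), log_suppression))
    return pd.DataFrame(rows)


def null_config(seed: int) -> SimConfig:
    """Null experiment for error-rate calibration: three groups with equal
    gains everywhere and no between-animal baseline variance, so trials are
    exchangeable across every compared cell (the t-test's own null)."""
    return SimConfig(
        groups=(
            GroupSpec("treated", 2, 1.0, 1.0),
            GroupSpec("naive_control", 2, 1.0, 1.0),
            GroupSpec("viral_control", 2, 1.0, 1.0),
        ),
        n_trials_per_condition=5,
        animal_baseline_sd=0.0,
        rng_seed=int(seed),
    )


def fwer_null_single(seed: int, alpha: float = 0.05) -> bool:
    """True if any Bonferroni-adjusted p in the 14-test family falls below
    alpha for one null replicate."""
    dataset = simulate_experiment(null_config(seed), [StimulusSpec.click_train(5)])
    feats = build_feature_table(dataset, traces=["AVREC", "IV", "V"], detect_peaks=False)
    table = run_ttest_family(feats[feats["window"] == 0])
    return bool((table["p_adjusted"] < alpha).any())


def fwer_null_study(n_replicates: int = 500, seed: int = 0, alpha: float = 0.05) -> dict:
    """Family-wise error rate of the Bonferroni-corrected family under the
    null experiment, with its Monte-Carlo standard error."""
    base = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    hits = sum(fwer_null_single(int(s), alpha) for s in base)
    rate = hits / n_replicates
    mc_se = float(np.sqrt(alpha * (1 - alpha) / n_replicates))
    return {"fwer": rate, "n_replicates": n_replicates, "mc_se": mc_se, "alpha": alpha}
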