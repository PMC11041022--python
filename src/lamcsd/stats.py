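"""Group-comparison statistics on the feature table.

Three complementary analyses:

* a linear mixed model on log RMS,
  ``log(RMS) ~ Group * Measurement + (1 | Animal / TrialNumber)``,
  with treatment coding referenced to the treated group and the post-laser
  measurement, fit by REML — the conservative, repeated-measures-aware
  summary of the design;
* Bonferroni-corrected (n = 14 by default) two-sample Student's t-tests at
  the raw single-trial level, each with a Cohen's d effect size;
* a two-way factorial ANOVA (group x measurement, with interaction) on
  vector strength.

The single-trial t-tests pool trials across animals, which pseudo-
replicates the animal effect; they are located effects to be read together
with the mixed model, not substitutes for it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger("lamcsd.stats")

__all__ = [
    "LmmSpec",
    "fit_lmm",
    "extract_contrast",
    "TTestResult",
    "ttest_bonferroni",
    "cohens_d",
    "default_family",
    "run_ttest_family",
    "vs_anova",
]

DEFAULT_N_TESTS = 14


@dataclass(frozen=True)
class LmmSpec:
    """Fixed/random structure of the log-RMS mixed model."""

    reference_group: str = "treated"
    reference_measurement: str = "post_laser"
    response: str = "rms"


def fit_lmm(table: pd.DataFrame, spec: LmmSpec = LmmSpec()) -> pd.DataFrame:
    """REML fit of ``log(RMS) ~ Group*Measurement + (1|Animal/TrialNumber)``.

    Rows with non-positive RMS are dropped (count logged).  Fixed-effect
    contrasts are each non-reference level against the reference cell
    (treated group, post-laser).  The nested random structure is a random
    intercept per animal plus a variance component for trial-number within
    animal; if that fit is singular or fails to converge, the model falls
    back to the animal-only random intercept and flags it.

    Returns a table with columns term, estimate, se, statistic, df, p,
    model.  Degrees of freedom are the residual count ``n_obs - n_fixed``
    (large-sample Wald-t inference); the estimates and SEs are the
    comparable surface across fitting engines.
    """
    required = {"group", "measurement", "animal_id", "trial", spec.response}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"feature table lacks columns {sorted(missing)}")
    df = table.copy()
    n_bad = int((df[spec.response] <= 0).sum())
    if n_bad:
        logger.warning("dropping %d rows with non-positive RMS before log transform", n_bad)
        df = df[df[spec.response] > 0]
    if spec.reference_group not in set(df["group"]):
        raise ValueError(f"reference group {spec.reference_group!r} not present in data")
    if spec.reference_measurement not in set(df["measurement"]):
        raise ValueError(
            f"reference measurement {spec.reference_measurement!r} not present in data"
        )
    for col in ("group", "measurement"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs >= 2 levels")
    df = df.assign(log_rms=np.log(df[spec.response].to_numpy(dtype=float)))
    df["trial"] = df["trial"].astype(str)

    formula = (
        f"log_rms ~ C(group, Treatment({spec.reference_group!r})) "
        f"* C(measurement, Treatment({spec.reference_measurement!r}))"
    )

    def _fit(vc):
        model = smf.mixedlm(
            formula,
            df,
            groups=df["animal_id"],
            re_formula="1",
            vc_formula=vc,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            return model.fit(reml=True)

    model_label = "animal/trial nested random intercepts"
    try:
        result = _fit({"trial": "0 + C(trial)"})
        if not np.all(np.isfinite(result.bse_fe)):
            raise ValueError("non-finite fixed-effect SEs")
    except (Exception,) as err:  # singular/non-converged nested fit
        # log the message only: captured log records must not pin the
        # exception's traceback (and the fit workspaces it references)
        logger.warning("nested random-effects fit failed (%s); falling back to "
                       "animal-only random intercept", str(err))
        model_label = "animal random intercept (fallback)"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            result = smf.mixedlm(
                formula, df, groups=df["animal_id"], re_formula="1"
            ).fit(reml=True)

    k_fe = len(result.fe_params)
    dof = max(int(len(df) - k_fe), 1)
    rows = []
    for term in result.fe_params.index:
        est = float(result.fe_params[term])
        se = float(result.bse_fe[term])
        stat = est / se if se > 0 else np.nan
        p = 2.0 * scipy.stats.t.sf(abs(stat), dof) if np.isfinite(stat) else np.nan
        rows.append(
            {
                "term": term,
                "estimate": est,
                "se": se,
                "statistic": stat,
                "df": dof,
                "p": p,
                "model": model_label,
            }
        )
    return pd.DataFrame(rows)


def extract_contrast(lmm_table: pd.DataFrame, level: str, factor: str = "measurement") -> dict:
    """Pull one treatment-coded contrast from a fitted LMM table.

    ``level`` is the non-reference level; the returned estimate is
    ``level - reference``.  For the within-group laser effect expressed as
    post-vs-pre, negate the ``pre_laser`` contrast (see callers).
    """
    mask = lmm_table["term"].str.contains(f"C({factor}", regex=False) & lmm_table[
        "term"
    ].str.contains(f"[T.{level}]", regex=False) & ~lmm_table["term"].str.contains(":")
    hits = lmm_table[mask]
    if len(hits) != 1:
        raise ValueError(
            f"expected exactly one main-effect term for {factor}={level}, "
            f"found {len(hits)}"
        )
    row = hits.iloc[0]
    return {
        "estimate": float(row["estimate"]),
        "se": float(row["se"]),
        "p": float(row["p"]),
        "df": int(row["df"]),
    }


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_raw: float
    p_adjusted: float
    n_tests: int
    flagged: bool = False


def ttest_bonferroni(a, b, n_tests: int = DEFAULT_N_TESTS) -> TTestResult:
    """Two-sided pooled-variance Student's t-test with Bonferroni-adjusted
    p = min(1, n_tests * p).  Degenerate zero-variance identical samples
    return p = 1, flagged."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        stat = np.nan if np.mean(a) == np.mean(b) else np.inf * np.sign(np.mean(a) - np.mean(b))
        p = 1.0 if np.mean(a) == np.mean(b) else 0.0
        return TTestResult(float(stat), p, min(1.0, n_tests * p), n_tests, True)
    stat, p = scipy.stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(stat), float(p), min(1.0, n_tests * float(p)), n_tests)


def cohens_d(a, b) -> float:
    """Cohen's d with the pooled standard deviation
    ``sqrt(((na-1) sa^2 + (nb-1) sb^2) / (na + nb - 2))``; sign preserved,
    NaN flags a zero pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        return float("nan")
    return float((np.mean(a) - np.mean(b)) / np.sqrt(pooled_var))


def default_family(
    groups: tuple[str, ...] = ("treated", "naive_control", "viral_control"),
) -> list[dict]:
    """The default Bonferroni family on single-trial RMS.

    For the canonical three-group design this is the 14-comparison family:
    between-group comparisons pre- and post-laser on the AVREC (6), the
    within-group pre-vs-post comparisons on the AVREC (3), the post-laser
    between-group comparisons on the granular layer IV trace (3), and the
    first (treated) group's pre-vs-post comparisons on layers IV and V (2).
    With other group counts the same construction is used and the
    correction adapts to the family size; the family is configurable
    wherever it is consumed.
    """
    from itertools import combinations

    pairs = list(combinations(groups, 2))
    fam: list[dict] = []
    for meas in ("pre_laser", "post_laser"):
        for g1, g2 in pairs:
            fam.append({"kind": "between", "trace": "AVREC", "measurement": meas,
                        "group_a": g1, "group_b": g2})
    for g in groups:
        fam.append({"kind": "within", "trace": "AVREC", "group": g})
    for g1, g2 in pairs:
        fam.append({"kind": "between", "trace": "IV", "measurement": "post_laser",
                    "group_a": g1, "group_b": g2})
    fam.append({"kind": "within", "trace": "IV", "group": groups[0]})
    fam.append({"kind": "within", "trace": "V", "group": groups[0]})
    if len(groups) == 3:
        assert len(fam) == DEFAULT_N_TESTS
    return fam


def _rms_sample(features: pd.DataFrame, trace: str, group: str, measurement: str,
                window: int | None) -> np.ndarray:
    df = features[(features["trace"] == trace) & (features["group"] == group)
                  & (features["measurement"] == measurement)]
    if window is not None:
        df = df[df["window"] == window]
    return df["rms"].to_numpy(dtype=float)


def run_ttest_family(
    features: pd.DataFrame,
    family: list[dict] | None = None,
    window: int | None = 0,
) -> pd.DataFrame:
    """Run every comparison of the Bonferroni family on single-trial RMS.

    By default only the first response window (index 0) enters, matching
    the focus of the downstream analyses on the first 200 ms.  Returns one
    row per comparison with t, raw p, adjusted p and Cohen's d.
    """
    if family is None:
        present = tuple(dict.fromkeys(features["group"]))
        family = default_family(present)
    n_tests = len(family)
    rows = []
    for comp in family:
        trace = comp["trace"]
        if comp["kind"] == "between":
            a = _rms_sample(features, trace, comp["group_a"], comp["measurement"], window)
            b = _rms_sample(features, trace, comp["group_b"], comp["measurement"], window)
            label = f"{comp['group_a']} vs {comp['group_b']}"
            meas = comp["measurement"]
        elif comp["kind"] == "within":
            a = _rms_sample(features, trace, comp["group"], "pre_laser", window)
            b = _rms_sample(features, trace, comp["group"], "post_laser", window)
            label = f"{comp['group']} pre vs post"
            meas = "pre_vs_post"
        else:
            raise ValueError(f"unknown comparison kind {comp['kind']!r}")
        res = ttest_bonferroni(a, b, n_tests=n_tests)
        rows.append(
            {
                "comparison": label,
                "trace": trace,
                "measurement": meas,
                "n_a": a.size,
                "n_b": b.size,
                "t": res.statistic,
                "p_raw": res.p_raw,
                "p_adjusted": res.p_adjusted,
                "cohens_d": cohens_d(a, b),
                "flagged": res.flagged,
            }
        )
    return pd.DataFrame(rows)


def vs_anova(vs_table: pd.DataFrame) -> pd.DataFrame:
    """Two-way factorial ANOVA (group x measurement, with interaction) on
    vector strength.  Requires >= 2 levels per factor and no empty cells."""
    required = {"group", "measurement", "vector_strength"}
    missing = required - set(vs_table.columns)
    if missing:
        raise ValueError(f"vector-strength table lacks columns {sorted(missing)}")
    for col in ("group", "measurement"):
        if vs_table[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs >= 2 levels")
    counts = vs_table.groupby(["group", "measurement"]).size()
    full = pd.MultiIndex.from_product(
        [vs_table["group"].unique(), vs_table["measurement"].unique()]
    )
    empty = [cell for cell in full if cell not in counts.index]
    if empty:
        raise ValueError(f"empty design cells: {empty}")
    fit = smf.ols("vector_strength ~ C(group) * C(measurement)", data=vs_table).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    out = table.reset_index().rename(
        columns={"index": "factor", "sum_sq": "sum_sq", "F": "F", "PR(>F)": "p"}
    )
    return out[["factor", "sum_sq", "df", "F", "p"]]
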