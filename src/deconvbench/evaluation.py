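"""Accuracy and robustness scoring of deconvolution outputs.

Accuracy is measured against RNA-fraction ground truth: per-sample RMSE over
cell types (averaged within a group) and signed estimate - truth differences
per cell type. Robustness is the unbiased sample variance of a method's
estimate for the same (sample, cell type) across a varied condition — bulk
protocol, or reference-profile size/subset — optionally accumulated stepwise
as smaller references are added. A factor-level fixed-effects ANOVA with
sequential (Type I) sums of squares attributes variation in the most
variable cell type's estimates to the experimental factors.

All operations consume tidy long-format DataFrames; `results_to_frame`
flattens :class:`~deconvbench.deconv.DeconvolutionResult` objects into one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .errors import AlignmentError, CoverageError

__all__ = [
    "EvaluationReport",
    "results_to_frame",
    "rmse",
    "proportion_differences",
    "robustness_variance",
    "stepwise_variance",
    "accuracy_robustness_summary",
    "anova_factors",
]

DEFAULT_ANOVA_FACTORS = ("method", "enrichment", "reference_size", "dissociated")


@dataclass
class EvaluationReport:
    """Container for the evaluation tables of one benchmark run."""

    rmse: pd.DataFrame | None = None
    differences: pd.DataFrame | None = None
    variance_bulk: pd.DataFrame | None = None
    variance_reference: pd.DataFrame | None = None
    summary: pd.DataFrame | None = None
    anova: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def results_to_frame(results, group: str | None = None) -> pd.DataFrame:
    """Flatten DeconvolutionResult objects into a tidy long DataFrame."""
    rows = []
    for r in results:
        for cell_type, frac in r.fractions.items():
            rows.append({
                "method": r.method,
                "sample": r.sample_id,
                "protocol": r.protocol,
                "reference_tag": r.reference_tag,
                "cell_type": cell_type,
                "fraction": float(frac),
                "group": group,
            })
    return pd.DataFrame(rows)


def _align(estimates: pd.DataFrame, truths: pd.DataFrame) -> pd.DataFrame:
    """Inner-join estimates and truths on (sample, cell_type); validate coverage."""
    need = {"sample", "cell_type", "fraction"}
    if not need <= set(estimates.columns) or not need <= set(truths.columns):
        raise AlignmentError("estimates/truths need sample, cell_type, fraction columns")
    merged = estimates.merge(
        truths.rename(columns={"fraction": "truth"})[["sample", "cell_type", "truth"]],
        on=["sample", "cell_type"],
        how="left",
    )
    if merged["truth"].isna().any():
        missing = merged.loc[merged["truth"].isna(), ["sample", "cell_type"]].iloc[0]
        raise AlignmentError(
            f"no truth for sample={missing['sample']!r}, cell_type={missing['cell_type']!r}"
        )
    return merged


def rmse(estimates: pd.DataFrame, truths: pd.DataFrame,
         group_cols: tuple[str, ...] = ("method",)) -> pd.DataFrame:
    """Per-sample RMSE over cell types, averaged within each group.

    RMSE_sample = sqrt(mean_k (estimate_k - truth_k)^2); the reported value
    is the mean of per-sample RMSEs over the samples of each group.
    """
    merged = _align(estimates, truths)
    merged["sq"] = (merged["fraction"] - merged["truth"]) ** 2
    keys = [c for c in group_cols if c in merged.columns]
    per_sample = (
        merged.groupby(keys + ["sample"], dropna=False)["sq"]
        .mean().pow(0.5).rename("rmse_sample").reset_index()
    )
    return (
        per_sample.groupby(keys, dropna=False)["rmse_sample"]
        .mean().rename("rmse").reset_index()
    )


def proportion_differences(estimates: pd.DataFrame, truths: pd.DataFrame,
                           group_cols: tuple[str, ...] = ("method",)) -> pd.DataFrame:
    """Signed estimate - truth per observation, with per-(group, type) means.

    Returns the observation-level table (column ``difference``) carrying a
    ``mean_difference`` column merged back per (group, cell_type); zero means
    perfect concordance, and within any sample the differences sum to zero by
    the simplex constraint.
    """
    merged = _align(estimates, truths)
    merged["difference"] = merged["fraction"] - merged["truth"]
    keys = [c for c in group_cols if c in merged.columns] + ["cell_type"]
    means = merged.groupby(keys, dropna=False)["difference"].mean().rename("mean_difference")
    return merged.merge(means.reset_index(), on=keys, how="left")


def robustness_variance(results: pd.DataFrame, vary: str) -> pd.DataFrame:
    """Unbiased variance of estimates across the ``vary`` condition.

    For every (method, sample, cell_type) key with >= 2 observations along
    ``vary``, the sample variance (n-1 denominator) of ``fraction``;
    singleton keys are excluded with a warning. Aggregate means per method
    and per (method, cell_type) can be taken directly from the output.
    """
    need = {"method", "sample", "cell_type", "fraction", vary}
    if not need <= set(results.columns):
        raise AlignmentError(f"results table needs columns {sorted(need)}")
    keys = ["method", "sample", "cell_type"]
    grouped = results.groupby(keys, dropna=False)["fraction"]
    sizes = grouped.size()
    singletons = sizes[sizes < 2]
    if len(singletons):
        warnings.warn(
            f"excluded {len(singletons)} singleton keys from variance over {vary!r}",
            stacklevel=2,
        )
    var = grouped.var(ddof=1).rename("variance").reset_index()
    var = var[var["variance"].notna()].reset_index(drop=True)
    var["vary"] = vary
    return var


def stepwise_variance(results: pd.DataFrame, axis: str, order: list) -> pd.DataFrame:
    """Variance recomputed cumulatively as each condition level is added.

    ``order`` lists the levels of ``axis`` from first to last (e.g. reference
    sizes large to small); step i uses levels order[: i + 1]. Mirrors the
    stepwise robustness view where each smaller reference profile joins the
    comparison in turn.
    """
    frames = []
    for i in range(1, len(order) + 1):
        included = order[:i]
        sub = results[results[axis].isin(included)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v = robustness_variance(sub, vary=axis)
        v["step"] = i
        v["levels"] = ",".join(str(x) for x in included)
        frames.append(v)
    return pd.concat(frames, ignore_index=True)


def accuracy_robustness_summary(rmse_table: pd.DataFrame,
                                variance_table: pd.DataFrame) -> pd.DataFrame:
    """Per-method (mean variance, mean RMSE) coordinate pairs.

    The variance coordinate averages the variance table over all its keys;
    the RMSE coordinate averages the RMSE table; which truth fed the RMSE
    (pseudo-bulk RNA fractions, or single-cell cell-count fractions for real
    bulk) is the caller's choice of input table.
    """
    m_r = set(rmse_table["method"])
    m_v = set(variance_table["method"])
    if m_r != m_v:
        raise CoverageError(
            f"method sets differ: only-in-rmse={sorted(m_r - m_v)}, "
            f"only-in-variance={sorted(m_v - m_r)}"
        )
    mean_var = variance_table.groupby("method")["variance"].mean().rename("mean_variance")
    mean_rmse = rmse_table.groupby("method")["rmse"].mean().rename("mean_rmse")
    return pd.concat([mean_var, mean_rmse], axis=1).reset_index()


def anova_factors(
    table: pd.DataFrame,
    response: str = "fraction",
    factors: tuple[str, ...] = DEFAULT_ANOVA_FACTORS,
) -> pd.DataFrame:
    """Fixed-effects ANOVA with sequential (Type I) sums of squares.

    Factors are entered in the given order; factors with a single observed
    level are dropped with a warning. A zero-variance response returns a
    degenerate table (all SS and F zero) rather than NaNs. Output columns:
    factor, df, sum_sq, F, p, degenerate.
    """
    usable = []
    for f in factors:
        if f not in table.columns:
            raise AlignmentError(f"factor {f!r} missing from table")
        if table[f].nunique() < 2:
            warnings.warn(f"factor {f!r} has a single level; excluded", stacklevel=2)
        else:
            usable.append(f)
    if not usable:
        raise AlignmentError("no factor has >= 2 levels")

    y = table[response].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        resid_df = len(y) - sum(table[f].nunique() - 1 for f in usable) - 1
        return pd.DataFrame({
            "factor": list(usable) + ["Residual"],
            "df": [float(table[f].nunique() - 1) for f in usable] + [float(resid_df)],
            "sum_sq": 0.0,
            "F": 0.0,
            "p": 1.0,
            "degenerate": True,
        })

    formula = f"Q('{response}') ~ " + " + ".join(f"C(Q('{f}'))" for f in usable)
    model = smf.ols(formula, data=table).fit()
    tab = anova_lm(model, typ=1)
    out = tab.rename(columns={"PR(>F)": "p"}).reset_index(names="factor")
    # map the patsy term names back to the plain factor names
    rename = {f"C(Q('{f}'))": f for f in usable}
    out["factor"] = out["factor"].map(lambda t: rename.get(t, t))
    out["degenerate"] = False
    out = out[["factor", "df", "sum_sq", "F", "p", "degenerate"]]
    return out
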