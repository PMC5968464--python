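"""Instrument-quality diagnostics for list experiments.

Four checks on whether a fielded (or simulated) list experiment behaved the
way the design assumes:

* :func:`floor_ceiling_profile` — the empirical distribution of direct-arm
  control sums.  Mass at 0 (floor) or J (ceiling) means a respondent's
  count would reveal the sensitive answer, undermining concealment.
* :func:`design_effects_test` — the nonnegativity test for design effects.
  Under the no-design-effects assumption, each joint respondent type
  (y affirmative controls, sensitive answer z) has a proportion identified
  by differences of the two arms' count CDFs; estimated proportions
  significantly below zero indicate respondents changing answers because
  of the list format.  One-sided z-tests on the negative cells with a
  Bonferroni correction over the number of negative cells.
* :func:`position_stratified_lr` — the difference-in-means estimate
  recomputed per randomized position of the sensitive item within the
  block, with a heterogeneity chi-square; a position-dependent estimate
  suggests the sensitive item standing out cognitively.
* :func:`balance_table` — arm-balance of covariates with Welch t-tests,
  the standard randomization check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import SurveyDesign
from .estimators import (
    EstimationError,
    PrevalenceEstimate,
    Z95,
    arm_a_counts,
    arm_b_control_sums,
    lr_difference_in_means,
    subpop_mask,
    _unavailable,
)
from .io import SchemaError

__all__ = [
    "DesignEffectsResult",
    "PositionEffectsResult",
    "floor_ceiling_profile",
    "design_effects_test",
    "position_stratified_lr",
    "balance_table",
]


def floor_ceiling_profile(
    records: pd.DataFrame, design: SurveyDesign, block_id: int, subpop=None
) -> pd.Series:
    """Empirical distribution of Arm B control sums for one block.

    Returns fractions over sums 0..J (summing to 1), indexed by the sum.
    The fraction at 0 is the floor exposure, at J the ceiling exposure.
    """
    sub = records.loc[subpop_mask(records, subpop)]
    sums = arm_b_control_sums(sub, block_id, design)
    if len(sums) == 0:
        raise EstimationError(f"no Arm B records for block {block_id}")
    J = design.n_controls
    frac = (
        sums.value_counts(normalize=True)
        .reindex(range(J + 1), fill_value=0.0)
        .sort_index()
    )
    frac.index.name = "control_sum"
    frac.name = "fraction"
    return frac


def _ecdf_at(values: np.ndarray, y: float) -> float:
    """F(y) = proportion of values <= y, no smoothing."""
    return float(np.mean(values <= y))


@dataclass
class DesignEffectsResult:
    """Estimated respondent-type proportions and the nonnegativity test.

    ``pi_hat`` has one row per control count y = 0..J and columns ``z1``
    (sensitive answer true) and ``z0``; the used cells sum to 1 exactly by
    the telescoping identity.  ``p_value`` is the Bonferroni-corrected
    one-sided p over the negative cells; 1.0 when no cell is negative.
    """

    pi_hat: pd.DataFrame
    ses: pd.DataFrame
    negative_cells: list
    p_value: float
    n_arm_a: int
    n_arm_b: int

    def summary(self) -> str:
        out = self.pi_hat.copy()
        out.columns = [f"pi({c})" for c in out.columns]
        neg = ", ".join(f"(y={y}, z={z})" for y, z in self.negative_cells) or "none"
        return (
            "Design-effects nonnegativity test\n"
            f"{out.to_string(float_format=lambda v: f'{v: .4f}')}\n"
            f"negative cells: {neg}\n"
            f"Bonferroni-corrected one-sided p = {self.p_value:.4f}"
        )


def design_effects_test(
    records: pd.DataFrame, design: SurveyDesign, block_id: int, subpop=None
) -> DesignEffectsResult:
    """Nonnegativity test for design effects in one block.

    With F_A, F_B the empirical CDFs of Arm A counts and Arm B control
    sums, the joint respondent-type proportions are estimated as::

        pi(y, 1) = F_B(y) - F_A(y)          y = 0..J
        pi(y, 0) = F_A(y) - F_B(y - 1)      with F_B(-1) = 0

    Standard errors treat the two arms' CDF values as independent binomial
    proportions.  Each negative cell gets a one-sided z-test against zero;
    the reported p-value is min(1, m * min_i p_i) over the m negative
    cells, and 1 when no cell is negative (no evidence of design effects).
    """
    sub = records.loc[subpop_mask(records, subpop)]
    a = arm_a_counts(sub, block_id).to_numpy()
    b = arm_b_control_sums(sub, block_id, design).to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise EstimationError(
            f"design-effects test needs both arms for block {block_id}"
        )
    J = design.n_controls
    n_a, n_b = len(a), len(b)
    rows = []
    se_rows = []
    for y in range(J + 1):
        fa_y = _ecdf_at(a, y)
        fb_y = _ecdf_at(b, y)
        fb_ym1 = _ecdf_at(b, y - 1) if y >= 1 else 0.0
        pi1 = fb_y - fa_y
        pi0 = fa_y - fb_ym1
        var1 = fb_y * (1 - fb_y) / n_b + fa_y * (1 - fa_y) / n_a
        var0 = fa_y * (1 - fa_y) / n_a + fb_ym1 * (1 - fb_ym1) / n_b
        rows.append({"z1": pi1, "z0": pi0})
        se_rows.append({"z1": np.sqrt(var1), "z0": np.sqrt(var0)})
    pi_hat = pd.DataFrame(rows, index=pd.Index(range(J + 1), name="y"))
    ses = pd.DataFrame(se_rows, index=pi_hat.index)

    negative = []
    pvals = []
    for y in range(J + 1):
        for z, col in ((1, "z1"), (0, "z0")):
            est = pi_hat.loc[y, col]
            if est < 0:
                se = ses.loc[y, col]
                p = float(stats.norm.cdf(est / se)) if se > 0 else 0.0
                negative.append((y, z))
                pvals.append(p)
    p_value = 1.0 if not pvals else min(1.0, len(pvals) * min(pvals))
    return DesignEffectsResult(
        pi_hat=pi_hat, ses=ses, negative_cells=negative,
        p_value=p_value, n_arm_a=n_a, n_arm_b=n_b,
    )


@dataclass
class PositionEffectsResult:
    """Per-position difference-in-means estimates plus heterogeneity test.

    ``estimates[p]`` is the LR estimate with Arm A restricted to
    respondents whose sensitive item sat at position p (Arm B is position-
    free and enters every estimate).  The heterogeneity statistic is a
    Cochran-style chi-square on the per-position Arm A mean counts
    weighted by the inverse variance of each mean — the shared Arm B term
    cancels in any between-position contrast, so it is excluded from the
    weights.
    """

    estimates: dict
    het_stat: float
    het_df: int
    het_p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.as_dict() | {"position": p}
                             for p, e in self.estimates.items()])


def position_stratified_lr(
    records: pd.DataFrame, design: SurveyDesign, block_id: int, subpop=None
) -> PositionEffectsResult:
    """Difference-in-means estimates stratified by sensitive-item position."""
    sub = records.loc[subpop_mask(records, subpop)]
    J = design.n_controls
    pos_col = f"pos_block{block_id}"
    if pos_col not in sub.columns:
        raise EstimationError(f"position column {pos_col!r} absent")
    item = design.block(block_id).sensitive_item_id
    estimates: dict[int, PrevalenceEstimate] = {}
    means, variances, ns = [], [], []
    for p in range(1, J + 2):
        at_p = (pd.to_numeric(sub[pos_col], errors="coerce") == p) | (sub["arm"] == "B")
        try:
            est = lr_difference_in_means(sub.loc[at_p], design, block_id)
        except EstimationError:
            est = _unavailable("lr", item, f"position_{p}", f"no Arm A records at position {p}")
        estimates[p] = est
        a = arm_a_counts(sub.loc[at_p], block_id)
        if len(a) >= 2:
            means.append(a.mean())
            variances.append(a.var(ddof=1) / len(a))
            ns.append(len(a))
    if len(means) >= 2 and all(v > 0 for v in variances):
        w = 1.0 / np.asarray(variances)
        m = np.asarray(means)
        mbar = np.sum(w * m) / np.sum(w)
        q = float(np.sum(w * (m - mbar) ** 2))
        df = len(means) - 1
        p_het = float(stats.chi2.sf(q, df))
    else:
        q, df, p_het = np.nan, 0, np.nan
    return PositionEffectsResult(estimates=estimates, het_stat=q, het_df=df, het_p=p_het)


def balance_table(records: pd.DataFrame, fields: list[str]) -> pd.DataFrame:
    """Arm-balance summary: mean (SD) by arm plus Welch t-test p-values.

    One row per field with columns ``mean_all, sd_all, mean_A, sd_A,
    mean_B, sd_B, diff, p_value`` (difference is Arm A minus Arm B).
    Degenerate zero-variance comparisons get p = 1 when the means agree
    and p = 0 when they differ.
    """
    rows = []
    for f in fields:
        if f not in records.columns:
            raise SchemaError(f"balance field {f!r} absent from records")
        try:
            col = records[f]
            if not pd.api.types.is_numeric_dtype(col):
                col = col.astype("string").replace("", pd.NA)
            vals = pd.to_numeric(col, errors="raise").astype("float64")
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"balance field {f!r} is not numeric: {exc}") from None
        a = vals[records["arm"] == "A"].dropna()
        b = vals[records["arm"] == "B"].dropna()
        if len(a) == 0 or len(b) == 0:
            raise EstimationError(f"balance field {f!r}: an arm has no data")
        diff = float(a.mean() - b.mean())
        tt = stats.ttest_ind(a, b, equal_var=False)
        p = float(tt.pvalue)
        if not np.isfinite(p):  # zero variance in both arms
            p = 1.0 if diff == 0 else 0.0
        rows.append({
            "field": f,
            "mean_all": float(vals.dropna().mean()), "sd_all": float(vals.dropna().std(ddof=1)),
            "mean_A": float(a.mean()), "sd_A": float(a.std(ddof=1)),
            "mean_B": float(b.mean()), "sd_B": float(b.std(ddof=1)),
            "diff": diff, "p_value": p,
        })
    return pd.DataFrame(rows).set_index("field")
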