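"""Prevalence estimators for list-experiment validation studies.

Four routes to the prevalence of a sensitive item are implemented and meant
to be compared side by side:

``lr``
    the list-randomization difference-in-means: mean count in the list arm
    (Arm A, J controls + sensitive item) minus mean sum of the same J
    control answers in the direct arm (Arm B).  Under arm exchangeability
    and no design effects this difference identifies the prevalence of the
    sensitive item.  The point estimate is a difference of means and may
    legitimately fall outside [0, 1]; it is reported unclipped.
``direct``
    the proportion answering the sensitive question affirmatively when
    asked directly (Arm B only).
``truth``
    the prevalence computed from researcher-known truth (surveillance
    serostatus / observed test refusal).  For HIV status, respondents who
    refused the surveillance test have no observable truth and are excluded.
``truth_adjusted``
    the full-sample truth prevalence with refusers imputed at an assumed
    population prevalence; its confidence interval conservatively reuses
    the half-width of the non-refused subsample's interval (the imputation
    is assumed to add no precision).

All intervals are Wald (normal-approximation) intervals, point +/- 1.96 se,
matching the symmetric intervals such studies print.  The difference in
means uses an unpooled (Welch-style) standard error since the two arms'
outcomes are constructed differently.

The module is organised statsmodels-style: :class:`ListExperiment` is the
model, its :meth:`~ListExperiment.fit` returns
:class:`ListExperimentResults` holding one :class:`PrevalenceEstimate` per
item/method, and :class:`ListRegression` fits the linear list-experiment
regression (treatment-interaction least squares with robust errors).
Functional wrappers (:func:`lr_difference_in_means`, ...) expose each
estimator individually.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import SurveyDesign, truth_column

__all__ = [
    "PrevalenceEstimate",
    "EstimationError",
    "ListExperiment",
    "ListExperimentResults",
    "ListRegression",
    "ListRegressionResults",
    "lr_difference_in_means",
    "direct_prevalence",
    "truth_prevalence",
    "truth_prevalence_adjusted",
    "lr_linear_regression",
    "subpop_mask",
    "SUBPOPULATIONS",
]

Z95 = 1.96  # normal 95% multiplier used for every Wald interval

#: Named subpopulations mirroring the validation study's report panels.
SUBPOPULATIONS = {
    "full": lambda df: pd.Series(True, index=df.index),
    # HIV status known to the researchers (took the surveillance test)
    "status_known": lambda df: df["stratum"] != "refused",
    # HIV+ status known to the individual (linked to care)
    "pos_linked": lambda df: df["stratum"] == "pos_linked",
    "pos_unlinked": lambda df: df["stratum"] == "pos_unlinked",
    "negative": lambda df: df["stratum"] == "negative",
    "refused": lambda df: df["stratum"] == "refused",
}


class EstimationError(ValueError):
    """Raised when an estimator's preconditions fail (e.g. an empty arm)."""


def subpop_mask(records: pd.DataFrame, subpop) -> pd.Series:
    """Resolve a subpopulation spec (name, boolean mask, or callable)."""
    if subpop is None:
        subpop = "full"
    if isinstance(subpop, str):
        try:
            return SUBPOPULATIONS[subpop](records).fillna(False)
        except KeyError:
            raise EstimationError(
                f"unknown subpopulation {subpop!r}; known: {sorted(SUBPOPULATIONS)}"
            ) from None
    if callable(subpop):
        return pd.Series(subpop(records), index=records.index).astype(bool)
    return pd.Series(subpop, index=records.index).astype(bool)


@dataclass(frozen=True)
class PrevalenceEstimate:
    """One prevalence estimate with its Wald uncertainty.

    ``n_treat``/``n_control`` are the list-arm and direct-arm sample sizes
    entering the estimate; single-arm estimators set ``n_treat`` to 0.
    An unavailable estimate (no observable truth, say) carries NaN values
    and ``available`` False.
    """

    method: str
    item_id: str
    subpop: str
    point: float
    se: float
    ci_low: float
    ci_high: float
    n_treat: int
    n_control: int
    note: str = ""

    @property
    def available(self) -> bool:
        return np.isfinite(self.point)

    def as_dict(self) -> dict:
        return {
            "method": self.method, "item_id": self.item_id, "subpop": self.subpop,
            "point": self.point, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "n_treat": self.n_treat, "n_control": self.n_control, "note": self.note,
        }


def _unavailable(method, item_id, subpop, note) -> PrevalenceEstimate:
    return PrevalenceEstimate(method, item_id, subpop, np.nan, np.nan, np.nan,
                              np.nan, 0, 0, note=note)


def _subpop_label(subpop) -> str:
    return subpop if isinstance(subpop, str) else "custom"


# ---------------------------------------------------------------------------
# column helpers
# ---------------------------------------------------------------------------

def arm_a_counts(records: pd.DataFrame, block_id: int) -> pd.Series:
    col = f"count_block{block_id}"
    if col not in records.columns:
        raise EstimationError(f"column {col!r} absent from records")
    return pd.to_numeric(records.loc[records["arm"] == "A", col], errors="coerce").dropna()


def arm_b_control_sums(records: pd.DataFrame, block_id: int, design: SurveyDesign) -> pd.Series:
    blk = design.block(block_id)
    cols = [f"ctrl_b{block_id}_i{k}" for k in range(1, blk.n_controls + 1)]
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise EstimationError(f"control columns absent from records: {missing}")
    sub = records.loc[records["arm"] == "B", cols].apply(pd.to_numeric, errors="coerce")
    return sub.dropna(how="any").sum(axis=1)


def arm_b_direct(records: pd.DataFrame, block_id: int) -> pd.Series:
    col = f"direct_b{block_id}"
    if col not in records.columns:
        raise EstimationError(f"column {col!r} absent from records")
    return pd.to_numeric(records.loc[records["arm"] == "B", col], errors="coerce").dropna()


# ---------------------------------------------------------------------------
# the four estimators
# ---------------------------------------------------------------------------

def lr_difference_in_means(
    records: pd.DataFrame,
    design: SurveyDesign,
    block_id: int,
    subpop=None,
) -> PrevalenceEstimate:
    """List-randomization difference-in-means estimate for one block.

    point = mean(Arm A count) - mean(Arm B control sum); unpooled-variance
    standard error; Wald 95% interval, reported unclipped.
    """
    mask = subpop_mask(records, subpop)
    sub = records.loc[mask]
    item = design.block(block_id).sensitive_item_id
    a = arm_a_counts(sub, block_id)
    b = arm_b_control_sums(sub, block_id, design)
    label = _subpop_label(subpop or "full")
    if len(a) == 0 or len(b) == 0:
        raise EstimationError(
            f"empty arm {'A' if len(a) == 0 else 'B'} for block {block_id} "
            f"under subpopulation {label!r}"
        )
    point = a.mean() - b.mean()
    var_a = a.var(ddof=1) if len(a) > 1 else 0.0
    var_b = b.var(ddof=1) if len(b) > 1 else 0.0
    se = float(np.sqrt(var_a / len(a) + var_b / len(b)))
    return PrevalenceEstimate(
        "lr", item, label, float(point), se,
        float(point - Z95 * se), float(point + Z95 * se), len(a), len(b),
    )


def direct_prevalence(
    records: pd.DataFrame,
    design: SurveyDesign,
    block_id: int,
    subpop=None,
) -> PrevalenceEstimate:
    """Directly-asked prevalence (Arm B): binomial proportion with Wald
    interval truncated to [0, 1]."""
    mask = subpop_mask(records, subpop)
    sub = records.loc[mask]
    item = design.block(block_id).sensitive_item_id
    y = arm_b_direct(sub, block_id)
    label = _subpop_label(subpop or "full")
    if len(y) == 0:
        raise EstimationError(
            f"no Arm B records for block {block_id} under subpopulation {label!r}"
        )
    p = float(y.mean())
    se = float(np.sqrt(p * (1 - p) / len(y)))
    return PrevalenceEstimate(
        "direct", item, label, p, se,
        max(0.0, p - Z95 * se), min(1.0, p + Z95 * se), 0, len(y),
    )


def truth_prevalence(
    records: pd.DataFrame,
    design: SurveyDesign,
    item_id: str,
    subpop=None,
) -> PrevalenceEstimate:
    """Known-truth prevalence of a sensitive item in a subpopulation.

    For ``hiv_negative`` the refused stratum carries no researcher-observable
    serostatus and is excluded; if no respondent in the subpopulation has
    observable truth the estimate is returned as unavailable (NaN), never 0.
    """
    mask = subpop_mask(records, subpop)
    sub = records.loc[mask]
    label = _subpop_label(subpop or "full")
    col = truth_column(item_id)
    if col not in sub.columns:
        return _unavailable("truth", item_id, label, f"no truth column {col!r}")
    if item_id == "hiv_negative":
        sub = sub.loc[sub["stratum"] != "refused"]
    vals = pd.to_numeric(sub[col], errors="coerce").dropna()
    if len(vals) == 0:
        return _unavailable("truth", item_id, label, "no observable truth in subpopulation")
    p = float(vals.mean())
    se = float(np.sqrt(p * (1 - p) / len(vals)))
    return PrevalenceEstimate(
        "truth", item_id, label, p, se,
        max(0.0, p - Z95 * se), min(1.0, p + Z95 * se), 0, len(vals),
    )


def truth_prevalence_adjusted(
    records: pd.DataFrame,
    design: SurveyDesign,
    pop_prev: float = 0.31,
    item_id: str = "hiv_negative",
    subpop=None,
) -> PrevalenceEstimate:
    """Full-sample truth prevalence with refusers imputed at ``pop_prev``.

    point = (n_true_among_tested + pop_prev * n_refused) / n_total.  The
    interval reuses the non-refused subsample's Wald half-width — a
    deliberately conservative (too wide) choice, treating the population
    imputation as adding no precision.  With no refusers this reduces
    exactly to :func:`truth_prevalence`.
    """
    if not 0.0 <= pop_prev <= 1.0:
        raise EstimationError(f"pop_prev = {pop_prev} outside [0, 1]")
    mask = subpop_mask(records, subpop)
    sub = records.loc[mask]
    label = _subpop_label(subpop or "full")
    col = truth_column(item_id)
    if col not in sub.columns:
        return _unavailable("truth_adjusted", item_id, label, f"no truth column {col!r}")
    n_total = len(sub)
    if n_total == 0:
        raise EstimationError(f"empty subpopulation {label!r}")
    refused = sub["stratum"] == "refused"
    tested = sub.loc[~refused]
    vals = pd.to_numeric(tested[col], errors="coerce").dropna()
    if len(vals) == 0:
        return _unavailable("truth_adjusted", item_id, label,
                            "no observable truth among non-refusers")
    n_true = float(vals.sum())
    n_refused = int(refused.sum())
    point = (n_true + pop_prev * n_refused) / n_total
    p_nr = float(vals.mean())
    se_nr = float(np.sqrt(p_nr * (1 - p_nr) / len(vals)))
    half = Z95 * se_nr
    return PrevalenceEstimate(
        "truth_adjusted", item_id, label, float(point), se_nr,
        max(0.0, point - half), min(1.0, point + half), 0, n_total,
        note=f"refusers imputed at population prevalence {pop_prev}",
    )


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class ListExperiment:
    """List-experiment model over a canonical respondent table.

    Parameters
    ----------
    records
        Canonical-schema respondent table (see :mod:`itemcount.io`).
    design
        The instrument the table was collected under.

    Examples
    --------
    >>> model = ListExperiment(records, design)
    >>> res = model.fit(subpop="full")
    >>> print(res.summary())
    """

    def __init__(self, records: pd.DataFrame, design: SurveyDesign):
        if "arm" not in records.columns or "stratum" not in records.columns:
            raise EstimationError("records lack 'arm'/'stratum' columns")
        self.records = records
        self.design = design

    def fit(
        self,
        items: Sequence[str] | None = None,
        subpop=None,
        methods: Sequence[str] = ("lr", "direct", "truth", "truth_adjusted"),
        pop_prev: float = 0.31,
    ) -> "ListExperimentResults":
        """Estimate every requested item by every requested method.

        ``truth_adjusted`` is only computed for ``hiv_negative`` (the item
        whose refuser truth the population-prevalence adjustment targets).
        """
        items = list(items) if items is not None else list(self.design.sensitive_items)
        out: list[PrevalenceEstimate] = []
        for item in items:
            blk = self.design.block_for_item(item)
            for method in methods:
                if method == "lr":
                    out.append(lr_difference_in_means(
                        self.records, self.design, blk.block_id, subpop))
                elif method == "direct":
                    out.append(direct_prevalence(
                        self.records, self.design, blk.block_id, subpop))
                elif method == "truth":
                    out.append(truth_prevalence(self.records, self.design, item, subpop))
                elif method == "truth_adjusted":
                    if item == "hiv_negative":
                        out.append(truth_prevalence_adjusted(
                            self.records, self.design, pop_prev, item, subpop))
                else:
                    raise EstimationError(f"unknown method {method!r}")
        return ListExperimentResults(self, out)


class ListExperimentResults:
    """Estimates produced by :meth:`ListExperiment.fit`."""

    def __init__(self, model: ListExperiment, estimates: list[PrevalenceEstimate]):
        self.model = model
        self.estimates = estimates

    def get(self, item_id: str, method: str) -> PrevalenceEstimate:
        for e in self.estimates:
            if e.item_id == item_id and e.method == method:
                return e
        raise KeyError(f"no estimate for ({item_id!r}, {method!r})")

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: method, item, subpopulation, point, se, CI, n."""
        df = pd.DataFrame([e.as_dict() for e in self.estimates])
        if self.model.design.training_block_id is not None:
            tut = self.model.design.block(
                self.model.design.training_block_id).sensitive_item_id
            df["tutorial"] = (df["item_id"] == tut).astype(int)
        return df

    def summary(self) -> str:
        df = self.to_frame().copy()
        for c in ("point", "se", "ci_low", "ci_high"):
            df[c] = df[c].map(lambda v: f"{v:.3f}" if np.isfinite(v) else "--")
        return "Prevalence estimates (95% Wald intervals)\n" + df.to_string(index=False)


class ListRegression:
    """Linear list-experiment regression (treatment-interaction OLS).

    The observed outcome is the Arm A block count or the Arm B control sum.
    Regressing it on covariates X plus interactions of X with the list-arm
    indicator T estimates, in the interaction coefficients, how the
    sensitive item's prevalence varies with X (the sensitive-item submodel,
    ``delta``); the main effects (``gamma``) describe the control-item sum.
    Standard errors are heteroskedasticity-robust (HC2) — the interaction
    model is intrinsically heteroskedastic — and the linear form is chosen
    for computational robustness over MLE alternatives.

    Parameters
    ----------
    records, design
        As for :class:`ListExperiment`.
    block_id
        Block whose sensitive item is modelled.
    covariates
        Names of numeric covariate columns; the intercept is always
        included (pass ``[]`` for intercept-only, which reproduces the
        difference-in-means point estimate exactly).
    subpop
        Optional subpopulation restriction.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        design: SurveyDesign,
        block_id: int,
        covariates: Sequence[str] = (),
        subpop=None,
    ):
        self.design = design
        self.block_id = block_id
        self.covariates = list(covariates)
        self.subpop = subpop
        mask = subpop_mask(records, subpop)
        self.records = records.loc[mask]

    def _build(self):
        df = self.records
        missing = [c for c in self.covariates if c not in df.columns]
        if missing:
            raise EstimationError(f"covariate column(s) absent: {missing}")
        a = arm_a_counts(df, self.block_id)
        b = arm_b_control_sums(df, self.block_id, self.design)
        if len(a) == 0 or len(b) == 0:
            raise EstimationError(
                f"both arms required for block {self.block_id}; "
                f"n_A={len(a)}, n_B={len(b)}"
            )
        y = pd.concat([a, b])
        t = pd.Series(np.r_[np.ones(len(a)), np.zeros(len(b))], index=y.index)
        X = pd.DataFrame({"const": 1.0}, index=y.index)
        for c in self.covariates:
            X[c] = pd.to_numeric(df.loc[y.index, c], errors="coerce")
        keep = X.notna().all(axis=1) & y.notna()
        y, t, X = y[keep], t[keep], X[keep]
        inter = X.mul(t, axis=0)
        inter.columns = [f"treat:{c}" for c in X.columns]
        full = pd.concat([X, inter], axis=1).astype("float64")
        rank = np.linalg.matrix_rank(full.to_numpy())
        if rank < full.shape[1]:
            # identify offending columns by greedy rank check
            bad = []
            cols: list[str] = []
            for c in full.columns:
                trial = full[cols + [c]].to_numpy()
                if np.linalg.matrix_rank(trial) == len(cols):
                    bad.append(c)
                else:
                    cols.append(c)
            raise EstimationError(f"design matrix rank-deficient; collinear columns: {bad}")
        return y, t, X, full

    def fit(self) -> "ListRegressionResults":
        y, t, X, full = self._build()
        ols = sm.OLS(y.to_numpy(dtype=float), full.to_numpy(dtype=float))
        res = ols.fit(cov_type="HC2")
        names = list(full.columns)
        params = pd.Series(res.params, index=names)
        ses = pd.Series(res.bse, index=names)
        gamma = params[[c for c in names if not c.startswith("treat:")]]
        delta = params[[c for c in names if c.startswith("treat:")]]
        delta.index = [c.split("treat:", 1)[1] for c in delta.index]
        se_gamma = ses[gamma.index]
        se_delta = ses[[f"treat:{c}" for c in delta.index]]
        se_delta.index = delta.index
        resid = y.to_numpy(dtype=float) - res.fittedvalues
        dof = max(len(y) - full.shape[1], 1)
        rmse = float(np.sqrt((resid ** 2).sum() / dof))
        sd_y = float(np.std(y.to_numpy(dtype=float), ddof=1))
        residual_se = rmse / sd_y if sd_y > 0 else np.nan
        return ListRegressionResults(
            model=self,
            delta=delta, gamma=gamma,
            delta_se=se_delta, gamma_se=se_gamma,
            residual_se=residual_se, rmse=rmse,
            n_arm_a=int(t.sum()), n_arm_b=int((1 - t).sum()),
        )


class ListRegressionResults:
    """Coefficients of the two submodels of a linear list regression.

    ``delta`` — sensitive-item submodel (treatment-interaction
    coefficients): how the sensitive item's prevalence shifts with each
    covariate, the intercept being the baseline prevalence.  ``gamma`` —
    control-items submodel (main effects).  ``residual_se`` is the
    root-mean-square residual scaled by the outcome's standard deviation,
    so 0 is a perfect fit and values near 1 indicate no explanatory power.
    """

    def __init__(self, model, delta, gamma, delta_se, gamma_se,
                 residual_se, rmse, n_arm_a, n_arm_b):
        self.model = model
        self.delta = delta
        self.gamma = gamma
        self.delta_se = delta_se
        self.gamma_se = gamma_se
        self.residual_se = residual_se
        self.rmse = rmse
        self.n_arm_a = n_arm_a
        self.n_arm_b = n_arm_b

    @property
    def n_total(self) -> int:
        return self.n_arm_a + self.n_arm_b

    def conf_int(self, which: str = "delta") -> pd.DataFrame:
        est = self.delta if which == "delta" else self.gamma
        se = self.delta_se if which == "delta" else self.gamma_se
        return pd.DataFrame(
            {"low": est - Z95 * se, "high": est + Z95 * se}, index=est.index
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for which, est, se in (("sensitive", self.delta, self.delta_se),
                               ("controls", self.gamma, self.gamma_se)):
            ci = est.index.map(lambda c: (est[c] - Z95 * se[c], est[c] + Z95 * se[c]))
            for c, (lo, hi) in zip(est.index, ci):
                rows.append({"submodel": which, "term": c, "coef": est[c],
                             "se": se[c], "ci_low": lo, "ci_high": hi})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        item = self.model.design.block(self.model.block_id).sensitive_item_id
        df = self.to_frame().copy()
        for c in ("coef", "se", "ci_low", "ci_high"):
            df[c] = df[c].map(lambda v: f"{v: .3f}")
        lines = [
            f"Linear list-experiment regression — item {item!r}",
            f"n = {self.n_total} (Arm A {self.n_arm_a}, Arm B {self.n_arm_b}); "
            f"residual SE (0-1 scale) = {self.residual_se:.2f}",
            df.to_string(index=False),
        ]
        return "\n".join(lines)


def lr_linear_regression(
    records: pd.DataFrame,
    design: SurveyDesign,
    block_id: int,
    covariates: Sequence[str] = (),
    subpop=None,
) -> ListRegressionResults:
    """Convenience wrapper: build and fit a :class:`ListRegression`."""
    return ListRegression(records, design, block_id, covariates, subpop).fit()
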