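"""Synthetic respondent cohorts with a social-desirability response model.

The generator emulates the validation study's population structure: four
truth strata sampled in configurable proportions (HIV-positive linked to
care, HIV-positive unlinked, HIV-negative, surveillance-test refusers),
stratified 60/40 randomization into a list-format arm (A) and a direct-
questioning arm (B), and five blocks of one sensitive plus four control
items.

Truthful answers are determined by stratum where the design ties them to it
("I am HIV negative" is true exactly for the negative stratum, with
refusers' unobserved status imputed at a configurable population prevalence;
"I refused the ... HIV test" is true exactly for refusers) and are Bernoulli
draws at configurable prevalences for the remaining sensitive items and all
control items.

Reporting noise has three dials, all probabilities:

``lambda_direct``
    chance that a truthfully *undesirable* answer to a sensitive item
    (true under a +1 desirability sign means desirable; under -1,
    undesirable) is flipped to the desirable answer when asked directly
    (Arm B).
``lambda_list``
    the same flip probability for the answer a respondent silently
    contributes to a finger count (Arm A).  Setting
    ``lambda_list < lambda_direct`` encodes the hypothesis that list
    randomization conceals answers and thereby reduces misreporting.
``epsilon_count``
    chance of a +/-1 miscount on an Arm A block count (finger-counting
    slip), clamped to the feasible range [0, J+1].

With all three at 0 the observed data are noiseless functions of truth, and
the downstream difference-in-means estimator recovers each item's truth
prevalence up to sampling error — the generator's core calibration property.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .design import SurveyDesign, truth_column

__all__ = ["ResponseModelConfig", "generate_cohort", "truth_summary", "ConfigError"]


class ConfigError(ValueError):
    """Raised before any sampling when a response-model config is invalid."""


#: default true prevalences for the sensitive items whose truth is not
#: determined by the sampling strata
_DEFAULT_ITEM_PREVS = {
    "brushed_teeth": 0.90,
    "used_condom": 0.45,
    "anal_sex": 0.05,
}

_STRATUM_ITEMS = ("hiv_negative", "refused_test")


@dataclass
class ResponseModelConfig:
    """Parameters of the respondent-behaviour model.

    Attributes
    ----------
    lambda_direct, lambda_list, epsilon_count
        Misreporting and miscount probabilities (see module docstring).
    pop_neg_prev
        HIV-negative prevalence imputed to surveillance-test refusers,
        default 0.31 (a general-population figure for the study region).
    item_prevs
        ``item_id -> prevalence`` for sensitive items whose truth is not
        stratum-determined.  A value may also be a pair
        ``(intercept, {covariate: slope})`` giving a linear-probability
        model in generated covariates (clipped to [0, 1]), used for
        regression-recovery experiments.
    stratum_props
        Proportions of the four truth strata, in the order of
        ``design.strata``; default 0.25 each (the study's target sample drew
        2000 per stratum).
    covariates
        ``name -> ("uniform", lo, hi)`` or an explicit array of length n;
        generated columns are carried on the cohort for regression tests.
    seed
        Root seed for the cohort.
    """

    lambda_direct: float = 0.0
    lambda_list: float = 0.0
    epsilon_count: float = 0.0
    pop_neg_prev: float = 0.31
    item_prevs: dict = field(default_factory=lambda: dict(_DEFAULT_ITEM_PREVS))
    stratum_props: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    covariates: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self, design: SurveyDesign) -> None:
        for name in ("lambda_direct", "lambda_list", "epsilon_count", "pop_neg_prev"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} = {v} outside [0, 1]")
        props = np.asarray(self.stratum_props, dtype=float)
        if props.shape != (len(design.strata),):
            raise ConfigError(
                f"stratum_props has {props.size} entries for {len(design.strata)} strata"
            )
        if (props < 0).any() or not np.isclose(props.sum(), 1.0):
            raise ConfigError(f"stratum_props must be nonnegative and sum to 1, got {props}")
        for item, prev in self.item_prevs.items():
            if np.isscalar(prev) and not 0.0 <= float(prev) <= 1.0:
                raise ConfigError(f"item_prevs[{item!r}] = {prev} outside [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "ResponseModelConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "stratum_props" in data:
            data["stratum_props"] = tuple(data["stratum_props"])
        return cls(**data)


def _item_truth_prob(prev, cov_values: dict[str, np.ndarray], n: int) -> np.ndarray:
    """Resolve a scalar or (intercept, slopes) prevalence spec to length n."""
    if np.isscalar(prev):
        return np.full(n, float(prev))
    intercept, slopes = prev
    p = np.full(n, float(intercept))
    for name, slope in slopes.items():
        if name not in cov_values:
            raise ConfigError(f"prevalence model refers to unknown covariate {name!r}")
        p = p + float(slope) * cov_values[name]
    return np.clip(p, 0.0, 1.0)


def generate_cohort(
    n: int,
    design: SurveyDesign,
    config: ResponseModelConfig | None = None,
    seed=None,
) -> pd.DataFrame:
    """Draw a synthetic cohort of ``n`` respondents in canonical schema.

    Deterministic given the seed (``seed`` overrides ``config.seed`` when
    given; it may be an int or a :class:`numpy.random.SeedSequence` so that
    replicate studies can spawn independent substreams).
    """
    config = config or ResponseModelConfig()
    config.validate(design)
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    root = seed if seed is not None else config.seed
    ss = root if isinstance(root, np.random.SeedSequence) else np.random.SeedSequence(root)
    rng = np.random.default_rng(ss)
    J = design.n_controls

    strata = np.asarray(design.strata)
    stratum = strata[rng.choice(len(strata), size=n, p=np.asarray(config.stratum_props))]
    arm = np.where(rng.random(n) < design.arm_allocation, "A", "B")

    cov_values: dict[str, np.ndarray] = {}
    for name, spec in config.covariates.items():
        if isinstance(spec, (tuple, list)) and len(spec) == 3 and spec[0] == "uniform":
            cov_values[name] = rng.uniform(float(spec[1]), float(spec[2]), size=n)
        else:
            arr = np.asarray(spec, dtype=float)
            if arr.shape != (n,):
                raise ConfigError(f"covariate {name!r} must have length {n}")
            cov_values[name] = arr

    # truthful sensitive answers -------------------------------------------
    truth: dict[str, np.ndarray] = {}
    for blk in design.blocks:
        item = blk.sensitive_item_id
        if item == "hiv_negative":
            t = (stratum == "negative").astype(int)
            refused = stratum == "refused"
            t[refused] = (rng.random(refused.sum()) < config.pop_neg_prev).astype(int)
        elif item == "refused_test":
            t = (stratum == "refused").astype(int)
        else:
            prev = config.item_prevs.get(item, blk.sensitive_prob)
            p = _item_truth_prob(prev, cov_values, n)
            t = (rng.random(n) < p).astype(int)
        truth[item] = t

    data: dict[str, object] = {
        "respondent_id": [f"r{i:06d}" for i in range(n)],
        "arm": arm,
        "stratum": stratum,
    }
    for blk in design.blocks:
        data[truth_column(blk.sensitive_item_id)] = truth[blk.sensitive_item_id].astype(float)

    is_a = arm == "A"
    a_cols: dict[str, np.ndarray] = {}
    b_cols: dict[str, np.ndarray] = {}
    for blk in design.blocks:
        b = blk.block_id
        # truthful control answers, both arms
        ctrl = (rng.random((n, J)) < np.asarray(blk.control_probs)).astype(int)
        t = truth[blk.sensitive_item_id]
        desirable = 1 if blk.desirability_sign == +1 else 0
        undesirable_truth = t != desirable
        flip_direct = undesirable_truth & (rng.random(n) < config.lambda_direct)
        flip_list = undesirable_truth & (rng.random(n) < config.lambda_list)
        reported_direct = np.where(flip_direct, desirable, t)
        reported_list = np.where(flip_list, desirable, t)

        count = ctrl.sum(axis=1) + reported_list
        slip = rng.random(n) < config.epsilon_count
        direction = np.where(rng.random(n) < 0.5, -1, 1)
        count = np.clip(count + slip * direction, 0, J + 1)
        position = rng.integers(1, J + 2, size=n)

        a_cols[f"count_block{b}"] = count
        a_cols[f"pos_block{b}"] = position
        for k in range(J):
            b_cols[f"ctrl_b{b}_i{k + 1}"] = ctrl[:, k]
        b_cols[f"direct_b{b}"] = reported_direct

    for name, vals in a_cols.items():
        data[name] = np.where(is_a, vals.astype(float), np.nan)
    for name, vals in b_cols.items():
        data[name] = np.where(~is_a, vals.astype(float), np.nan)
    for name, vals in cov_values.items():
        data[name] = vals

    return pd.DataFrame(data)


def truth_summary(records: pd.DataFrame, design: SurveyDesign) -> pd.DataFrame:
    """Exact true prevalence of each sensitive item, overall and by stratum.

    Returns a frame indexed by ``item_id`` with columns ``overall`` plus one
    per stratum.  Items whose truth column is absent, or subgroups where it
    is entirely missing, are reported as NaN (unavailable), never as zero.
    """
    rows = {}
    for blk in design.blocks:
        item = blk.sensitive_item_id
        col = truth_column(item)
        row: dict[str, float] = {}
        if col not in records.columns:
            row["overall"] = np.nan
            row.update({s: np.nan for s in design.strata})
        else:
            vals = pd.to_numeric(records[col], errors="coerce")
            row["overall"] = vals.mean() if vals.notna().any() else np.nan
            for s in design.strata:
                sub = vals[records["stratum"] == s]
                row[s] = sub.mean() if sub.notna().any() else np.nan
        rows[item] = row
    out = pd.DataFrame(rows).T
    out.index.name = "item_id"
    return out
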