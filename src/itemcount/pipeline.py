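"""End-to-end pipeline: design → simulate/ingest → estimate → diagnose → report.

:func:`run_replication` takes a :class:`RunConfig` pointing at either a
respondent table on disk or a simulation configuration, runs every
estimator and diagnostic the data supports, and writes a reproducible
report bundle of plain delimited tables plus a JSON manifest (seed, config
hash, row-count reconciliation).  Outputs carry no timestamps, so identical
config + seed yields byte-identical bundles.

:func:`run_power_grid` sweeps the response-model parameter grid (sample
size, direct/list misreporting rates, miscount rate) and summarises each
estimator's bias, RMSE and interval width over Monte-Carlo replicates —
the power/bias trade-off a randomized-response design confronts: hiding
answers costs statistical power.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import SurveyDesign, default_design, truth_column
from .diagnostics import (
    balance_table,
    design_effects_test,
    floor_ceiling_profile,
    position_stratified_lr,
)
from .estimators import (
    EstimationError,
    ListExperiment,
    lr_linear_regression,
)
from .io import ColumnMapping, read_respondents, write_respondents
from .simulate import ResponseModelConfig, generate_cohort, truth_summary

__all__ = ["RunConfig", "run_replication", "run_power_grid"]

#: report panels mirroring the validation study's figures: full sample,
#: status known to researchers (took the test), status known to the
#: individual (linked to care), and the individual truth strata
REPORT_SUBPOPS = ("full", "status_known", "pos_linked",
                  "pos_unlinked", "negative", "refused")


@dataclass
class RunConfig:
    """Configuration of one replication run.

    Exactly one of ``data`` (respondent table on disk) or ``simulate``
    (keyword dict: ``n`` plus :class:`ResponseModelConfig` fields) must be
    given.
    """

    out: str = "itemcount_report"
    data: str | None = None
    mapping: str | None = None
    simulate: dict | None = None
    design: str | None = None           # YAML path; None = default instrument
    seed: int = 0
    subpops: tuple = REPORT_SUBPOPS
    items: tuple | None = None          # None = all sensitive items
    covariates: tuple = ()              # regression covariate columns
    balance_fields: tuple = ()          # covariates for the balance table
    pop_prev: float = 0.31
    lenient: bool = False
    verbose: bool = False

    def __post_init__(self) -> None:
        if (self.data is None) == (self.simulate is None):
            raise ValueError("exactly one of 'data' and 'simulate' must be supplied")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        for k in ("subpops", "items", "covariates", "balance_fields"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    def to_jsonable(self) -> dict:
        """Analysis-relevant configuration; the output location is excluded
        so that identical analyses hash identically wherever they land."""
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items() if k != "out"}
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _load_design(config: RunConfig) -> SurveyDesign:
    return SurveyDesign.from_yaml(config.design) if config.design else default_design()


def _acquire_records(config: RunConfig, design: SurveyDesign):
    """Read or simulate the respondent table; returns (records, counts)."""
    if config.data is not None:
        mapping = ColumnMapping.from_file(config.mapping) if config.mapping else None
        records = read_respondents(config.data, design, mapping, lenient=config.lenient)
        counts = {
            "n_read": records.attrs["n_read"],
            "n_accepted": records.attrs["n_accepted"],
            "n_rejected": records.attrs["n_read"] - records.attrs["n_accepted"],
        }
    else:
        sim = dict(config.simulate)
        n = int(sim.pop("n"))
        model = ResponseModelConfig(**sim)
        records = generate_cohort(n, design, model, seed=config.seed)
        counts = {"n_read": n, "n_accepted": n, "n_rejected": 0}
    counts["n_arm_a"] = int((records["arm"] == "A").sum())
    counts["n_arm_b"] = int((records["arm"] == "B").sum())
    return records, counts


def run_replication(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Writes to ``config.out``:

    * ``cohort.csv`` (simulated runs only) — the generated respondent table
    * ``estimates.csv`` — every item x method x subpopulation prevalence
      estimate with CIs (the headline comparison table)
    * ``regression_<item>.csv`` — linear list-regression coefficient tables
      for the items with stratum-determined truth
    * ``floor_ceiling.csv`` — per-block control-sum distributions
    * ``design_effects.csv`` — per-block nonnegativity-test p-values
    * ``positions.csv`` — position-stratified estimates and heterogeneity
    * ``balance.csv`` — arm balance of configured fields
    * ``summary.txt`` — human-readable digest
    * ``manifest.json`` — seed, config hash, row-count reconciliation

    Returns the bundle as a dict of in-memory objects keyed like the files.
    Subpopulation/method combinations whose inputs are unavailable are
    recorded as unavailable and the run continues; a missing arm is a hard
    error.
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    design = _load_design(config)
    records, counts = _acquire_records(config, design)
    if config.simulate is not None:
        write_respondents(records, out / "cohort.csv", design)

    items = list(config.items) if config.items else list(design.sensitive_items)
    model = ListExperiment(records, design)
    bundle: dict = {"design": design, "records": records}
    log: list[str] = []

    # --- estimates over all requested subpopulations ----------------------
    frames = []
    for subpop in config.subpops:
        try:
            res = model.fit(items=items, subpop=subpop, pop_prev=config.pop_prev)
        except EstimationError as exc:
            log.append(f"subpopulation {subpop!r}: {exc}")
            continue
        frames.append(res.to_frame())
    estimates = pd.concat(frames, ignore_index=True)
    bundle["estimates"] = estimates
    estimates.to_csv(out / "estimates.csv", index=False)

    # --- truth bookkeeping (simulated cohorts carry full truth) -----------
    truth = truth_summary(records, design)
    bundle["truth_summary"] = truth
    truth.to_csv(out / "truth_summary.csv")

    # --- regressions for the stratum-determined-truth items ---------------
    regressions = {}
    for item, truth_cov in (("hiv_negative", "truth_hiv_negative"),
                            ("refused_test", "truth_refused")):
        if item not in design.sensitive_items:
            continue
        covs = [c for c in (truth_cov, *config.covariates) if c in records.columns]
        blk = design.block_for_item(item)
        try:
            reg = lr_linear_regression(records, design, blk.block_id, covs)
        except EstimationError as exc:
            log.append(f"regression for {item!r}: {exc}")
            continue
        regressions[item] = reg
        reg.to_frame().to_csv(out / f"regression_{item}.csv", index=False)
    bundle["regressions"] = regressions

    # --- diagnostics -------------------------------------------------------
    fc_rows, de_rows, pos_rows = [], [], []
    for blk in design.blocks:
        fc = floor_ceiling_profile(records, design, blk.block_id)
        for s, frac in fc.items():
            fc_rows.append({"block_id": blk.block_id, "item_id": blk.sensitive_item_id,
                            "control_sum": s, "fraction": frac})
        de = design_effects_test(records, design, blk.block_id)
        de_rows.append({"block_id": blk.block_id, "item_id": blk.sensitive_item_id,
                        "p_value": de.p_value,
                        "n_negative_cells": len(de.negative_cells)})
        pos = position_stratified_lr(records, design, blk.block_id)
        for p, est in pos.estimates.items():
            pos_rows.append({"block_id": blk.block_id, "position": p,
                             **est.as_dict(), "het_p": pos.het_p})
    bundle["floor_ceiling"] = pd.DataFrame(fc_rows)
    bundle["design_effects"] = pd.DataFrame(de_rows)
    bundle["positions"] = pd.DataFrame(pos_rows)
    bundle["floor_ceiling"].to_csv(out / "floor_ceiling.csv", index=False)
    bundle["design_effects"].to_csv(out / "design_effects.csv", index=False)
    bundle["positions"].to_csv(out / "positions.csv", index=False)

    # --- balance ------------------------------------------------------------
    bal_fields = [f for f in config.balance_fields if f in records.columns]
    for f in ("truth_hiv_negative", "truth_refused"):
        if f in records.columns and f not in bal_fields:
            bal_fields.append(f)
    if bal_fields:
        bal = balance_table(records, bal_fields)
        bundle["balance"] = bal
        bal.to_csv(out / "balance.csv")

    # --- manifest & summary -------------------------------------------------
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_jsonable(),
        "counts": counts,
        "n_excluded_by_filter": 0,
        "items": items,
        "log": log,
        "environment": {
            "python": platform.python_version(),
            "machine": platform.machine(),
        },
    }
    bundle["manifest"] = manifest
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    lines = ["item-count replication report",
             f"records: {counts}", ""]
    for subpop in config.subpops:
        part = estimates[estimates["subpop"] == subpop]
        if len(part):
            lines.append(f"--- subpopulation: {subpop}")
            lines.append(part.to_string(index=False))
            lines.append("")
    for item, reg in regressions.items():
        lines.append(reg.summary())
        lines.append("")
    lines.append("design-effects p-values by block:")
    lines.append(bundle["design_effects"].to_string(index=False))
    (out / "summary.txt").write_text("\n".join(lines))
    return bundle


# ---------------------------------------------------------------------------
# power / bias grid
# ---------------------------------------------------------------------------

def run_power_grid(
    grid: dict,
    replicates: int = 50,
    seed: int = 0,
    design: SurveyDesign | None = None,
    base_config: ResponseModelConfig | None = None,
    items: list | None = None,
) -> pd.DataFrame:
    """Monte-Carlo bias/RMSE/CI-width summary over a response-model grid.

    Parameters
    ----------
    grid
        Mapping of grid axes to value lists; recognised axes are ``n``,
        ``lambda_direct``, ``lambda_list`` and ``epsilon_count``.  Axes
        not supplied are held at the base config's value.
    replicates
        Cohorts generated per grid cell (>= 2).
    seed
        Root seed; each (cell, replicate) gets an independent substream.
    design, base_config, items
        Instrument, baseline response model, and sensitive items to track
        (default: all).

    Returns a tidy frame with one row per cell x item x estimator carrying
    mean bias (estimate minus the cohort's realised truth prevalence),
    RMSE, mean CI width and the replicate count.
    """
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    if not grid:
        raise ValueError("grid must be non-empty")
    allowed = {"n", "lambda_direct", "lambda_list", "epsilon_count"}
    unknown = set(grid) - allowed
    if unknown:
        raise ValueError(f"unknown grid axes: {sorted(unknown)}; allowed: {sorted(allowed)}")
    for axis, values in grid.items():
        vals = list(values)
        if not vals:
            raise ValueError(f"grid axis {axis!r} is empty")
        if axis == "n" and any(int(v) < 2 for v in vals):
            raise ValueError("grid axis 'n' needs values >= 2")
        if axis != "n" and any(not 0 <= float(v) <= 1 for v in vals):
            raise ValueError(f"grid axis {axis!r} values must lie in [0, 1]")

    design = design or default_design()
    base = base_config or ResponseModelConfig()
    items = list(items) if items else list(design.sensitive_items)
    axes = sorted(grid)
    cells = list(itertools.product(*(list(grid[a]) for a in axes)))
    root = np.random.SeedSequence(seed)
    streams = iter(root.spawn(len(cells) * replicates))

    rows = []
    for cell in cells:
        params = dict(zip(axes, cell))
        n = int(params.pop("n", 2000))
        cfg = ResponseModelConfig(**{**base.__dict__, **params})
        acc: dict[tuple, list] = {}
        for _ in range(replicates):
            cohort = generate_cohort(n, design, cfg, seed=next(streams))
            truth = truth_summary(cohort, design)
            ex = ListExperiment(cohort, design)
            for item in items:
                blk = design.block_for_item(item)
                tprev = truth.loc[item, "overall"]
                for method, est in (
                    ("lr", ex.fit(items=[item], methods=("lr",)).estimates[0]),
                    ("direct", ex.fit(items=[item], methods=("direct",)).estimates[0]),
                ):
                    acc.setdefault((item, method), []).append(
                        (est.point - tprev, est.ci_high - est.ci_low))
        for (item, method), pairs in acc.items():
            errs = np.array([p[0] for p in pairs])
            widths = np.array([p[1] for p in pairs])
            rows.append({
                "n": n, **{a: params.get(a, getattr(base, a, None)) for a in
                           ("lambda_direct", "lambda_list", "epsilon_count")},
                "item_id": item, "method": method, "replicates": replicates,
                "bias": float(errs.mean()),
                "rmse": float(np.sqrt((errs ** 2).mean())),
                "ci_width": float(widths.mean()),
                "seed": seed,
            })
    return pd.DataFrame(rows)
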