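"""Workflows that turn stratified permeability data into QSPR models.

Two workflows are provided:

* **Per-scenario modelling with selection** — fit one model per non-empty
  scenario, then pick the best-performing model among those with enough
  compounds (n >= 16 by default), maximising R-squared.

* **Pooled outlier-filtered modelling** — reduce every compound to a single
  preferred measurement using experimental preference criteria, fit one
  pooled model, drop rows whose residual exceeds +/- 1.5 log units in a
  single pass, refit, and validate the refit with a random 80/20
  train/test split.

All randomness is seed-controlled; identical inputs and seeds give
byte-identical outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io import Dataset, PermeabilityRecord
from .regression import (
    QsprModel,
    evaluate,
    fit_ols,
    models_to_frame,
    predict_rows,
)
from .stratification import ScenarioAssignment, ScenarioKey, enumerate_scenarios

logger = logging.getLogger(__name__)

ROW_COLUMNS = ("compound_id", "log_p", "tpsa", "mv", "log_kp")


@dataclass
class ScenarioModelTable:
    """One fitted model per non-empty scenario, in scenario-enumeration order."""

    rows: list[QsprModel] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return models_to_frame(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)


@dataclass
class SplitResult:
    """An 80/20 train/test partition with per-set metrics."""

    train_rows: pd.DataFrame
    test_rows: pd.DataFrame
    model: QsprModel
    train_metrics: dict
    test_metrics: dict
    seed: int
    n_resample_attempts: int


@dataclass
class PreferenceCriteria:
    """Experimental conditions preferred when reducing compounds to one row.

    Each criterion contributes one point to a record's score when satisfied;
    a missing field never satisfies its criterion.  Defaults follow the
    conditions most representative of in-vivo-like permeation work: abdomen
    skin, the combined epidermis+dermis layer, a concentrated donor phase,
    donor temperature 30-35 degC, and donor pH 7-7.5.
    """

    skin_source: str = "abdomen"
    skin_layer: str = "epidermis+dermis"
    donor_concentration: str = "concentrated"
    temperature_range: tuple[float, float] = (30.0, 35.0)
    ph_range: tuple[float, float] = (7.0, 7.5)

    def __post_init__(self) -> None:
        if self.temperature_range[0] > self.temperature_range[1]:
            raise ValueError("temperature_range is empty")
        if self.ph_range[0] > self.ph_range[1]:
            raise ValueError("ph_range is empty")

    def score(self, rec: PermeabilityRecord) -> int:
        s = 0
        s += rec.skin_source == self.skin_source
        s += rec.skin_layer == self.skin_layer
        s += rec.donor_concentration == self.donor_concentration
        s += (
            rec.donor_temperature_c is not None
            and self.temperature_range[0] <= rec.donor_temperature_c <= self.temperature_range[1]
        )
        s += (
            rec.donor_ph is not None
            and self.ph_range[0] <= rec.donor_ph <= self.ph_range[1]
        )
        return int(s)


@dataclass
class OutlierFilterResult:
    """Single-pass residual filter around an initial pooled fit."""

    kept_rows: pd.DataFrame
    removed_rows: pd.DataFrame
    threshold: float
    model_before: QsprModel
    model_after: QsprModel
    diagnostics_before: object = None
    diagnostics_after: object = None


@dataclass
class PooledWorkflowResult:
    """Everything the pooled workflow produced, with stage counts."""

    filter_result: OutlierFilterResult
    split_result: SplitResult
    counts: dict


def build_scenario_table(assignment: ScenarioAssignment) -> ScenarioModelTable:
    """Fit one QSPR model per non-empty scenario group.

    Every (record, descriptors) pair in a group becomes a regression row, so
    repeat measurements of a compound enter as separate rows.  Groups with a
    single row cannot be fitted and yield a flagged coefficient-free
    placeholder.  Output order follows :func:`enumerate_scenarios`.
    """
    table = ScenarioModelTable()
    for key in enumerate_scenarios():
        group = assignment.groups.get(key)
        if not group:
            continue
        rows = pd.DataFrame(
            [
                {
                    "compound_id": rec.compound_id,
                    "log_p": desc.log_p,
                    "tpsa": desc.tpsa,
                    "mv": desc.mv,
                    "log_kp": rec.log_kp,
                }
                for rec, desc in group
            ],
            columns=list(ROW_COLUMNS),
        )
        n_compounds = rows["compound_id"].nunique()
        if len(rows) < 2:
            table.rows.append(
                QsprModel(
                    intercept=math.nan,
                    coef_logp=math.nan,
                    coef_tpsa=math.nan,
                    coef_mv=math.nan,
                    n=len(rows),
                    r_squared=None,
                    rmse=None,
                    underdetermined=True,
                    scenario=key,
                    n_compounds=n_compounds,
                    label="placeholder: too few rows to fit",
                )
            )
            continue
        model, _ = fit_ols(rows, scenario=key, n_compounds=n_compounds)
        table.rows.append(model)
    logger.info("fitted %d scenario models", len(table))
    return table


def select_best(table: ScenarioModelTable, min_n: int = 16) -> QsprModel:
    """Pick the qualifying scenario model with the highest R-squared.

    Only models with at least ``min_n`` rows and a determined fit compete;
    ties break toward the earlier scenario in enumeration order.
    """
    candidates = [
        m
        for m in table.rows
        if m.n >= min_n and not m.underdetermined and m.r_squared is not None
    ]
    if not candidates:
        largest = max((m.n for m in table.rows), default=0)
        raise ValueError(
            f"no scenario model has n >= {min_n}; largest available n is {largest}"
        )
    order = {k: i for i, k in enumerate(enumerate_scenarios())}
    candidates.sort(key=lambda m: order.get(m.scenario, len(order)))
    best = candidates[0]
    for m in candidates[1:]:
        if m.r_squared > best.r_squared:
            best = m
    return best


def train_size(n_total: int, train_fraction: float = 0.8) -> int:
    """round(train_fraction * n) with ties rounded half up."""
    return int(math.floor(train_fraction * n_total + 0.5))


def split_train_test(
    rows: pd.DataFrame,
    seed: int,
    train_fraction: float = 0.8,
    max_attempts: int = 1000,
    min_spread_fraction: float = 0.25,
) -> SplitResult:
    """Random train/test split with a descriptor-coverage check.

    The test set must span a range of every descriptor: its spread
    (max - min) must reach ``min_spread_fraction`` of the full set's spread
    for logP, TPSA and MV.  Splits are redrawn (up to ``max_attempts``) until
    the check passes; the accepted attempt count is recorded.  The model is
    refitted on the training rows only and both sets are scored.
    """
    n = len(rows)
    if n < 5:
        raise ValueError(f"need at least 5 rows to split, got {n}")
    n_train = train_size(n, train_fraction)
    rng = np.random.default_rng(seed)
    spans = {
        c: rows[c].max() - rows[c].min() for c in ("log_p", "tpsa", "mv")
    }
    last_failed = None
    for attempt in range(1, max_attempts + 1):
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        test = rows.iloc[np.sort(test_idx)]
        ok = True
        for c, span in spans.items():
            test_span = test[c].max() - test[c].min()
            if span > 0 and test_span < min_spread_fraction * span:
                ok = False
                last_failed = c
                break
        if ok:
            train = rows.iloc[np.sort(train_idx)]
            model, _ = fit_ols(train, label="train")
            return SplitResult(
                train_rows=train,
                test_rows=test,
                model=model,
                train_metrics=evaluate(model, train),
                test_metrics=evaluate(model, test),
                seed=seed,
                n_resample_attempts=attempt,
            )
    raise ValueError(
        f"test-set coverage unachievable in {max_attempts} attempts; "
        f"descriptor {last_failed!r} failed the spread check"
    )


def select_one_per_compound(
    dataset: Dataset, criteria: Optional[PreferenceCriteria] = None
) -> pd.DataFrame:
    """Reduce each compound to its single most preferred measurement.

    Every record is scored by how many preference criteria it satisfies
    (0-5); the highest-scoring record per compound wins, with ties broken by
    input order (first record kept).  Compounds without descriptors are
    dropped with a warning.  Returns one labelled row per compound.
    """
    criteria = criteria or PreferenceCriteria()
    best: dict[str, tuple[int, PermeabilityRecord]] = {}
    order: list[str] = []
    for rec in dataset.records:
        s = criteria.score(rec)
        if rec.compound_id not in best:
            best[rec.compound_id] = (s, rec)
            order.append(rec.compound_id)
        elif s > best[rec.compound_id][0]:
            best[rec.compound_id] = (s, rec)
    rows = []
    n_dropped = 0
    for cid in order:
        desc = dataset.descriptors.get(cid)
        if desc is None:
            n_dropped += 1
            continue
        _, rec = best[cid]
        rows.append(
            {
                "compound_id": cid,
                "log_p": desc.log_p,
                "tpsa": desc.tpsa,
                "mv": desc.mv,
                "log_kp": rec.log_kp,
            }
        )
    if n_dropped:
        logger.warning(
            "dropped %d compound(s) without descriptor entries", n_dropped
        )
    return pd.DataFrame(rows, columns=list(ROW_COLUMNS))


def outlier_filter_refit(
    rows: pd.DataFrame, threshold: float = 1.5
) -> OutlierFilterResult:
    """Fit, drop gross outliers once, refit.

    ``model_before`` is fitted on all rows; rows whose absolute residual
    (observed - predicted) exceeds ``threshold`` log10 units are removed and
    ``model_after`` is fitted on the remainder.  One pass only — no
    iterative re-removal.
    """
    if len(rows) < 5:
        raise ValueError(f"need at least 5 rows, got {len(rows)}")
    model_before, diag_before = fit_ols(rows, label="pre-filter pooled fit")
    resid = rows["log_kp"].to_numpy() - predict_rows(model_before, rows)
    outlier = np.abs(resid) > threshold
    kept = rows.loc[~outlier]
    removed = rows.loc[outlier]
    if len(kept) == 0:
        raise ValueError("outlier filter removed every row")
    if len(removed) == 0:
        model_after, diag_after = model_before, diag_before
    else:
        model_after, diag_after = fit_ols(kept, label="post-filter pooled fit")
    logger.info(
        "outlier filter at +/-%.2f: kept %d, removed %d",
        threshold, len(kept), len(removed),
    )
    return OutlierFilterResult(
        kept_rows=kept,
        removed_rows=removed,
        threshold=threshold,
        model_before=model_before,
        model_after=model_after,
        diagnostics_before=diag_before,
        diagnostics_after=diag_after,
    )


def run_pooled_workflow(
    dataset: Dataset,
    criteria: Optional[PreferenceCriteria] = None,
    threshold: float = 1.5,
    seed: int = 0,
) -> PooledWorkflowResult:
    """One-per-compound selection -> outlier filter -> train/test validation.

    The split is drawn from the kept (post-filter) rows.  Two pooled models
    result: the full post-filter fit (``filter_result.model_after``) and the
    training-set fit (``split_result.model``); both are reported because
    either can serve as the final pooled equation.
    """
    pooled = select_one_per_compound(dataset, criteria)
    logger.info("pooled one row per compound: %d rows", len(pooled))
    filt = outlier_filter_refit(pooled, threshold=threshold)
    split = split_train_test(filt.kept_rows.reset_index(drop=True), seed=seed)
    counts = {
        "n_records_in": len(dataset.records),
        "n_compounds_pooled": len(pooled),
        "n_removed_outliers": len(filt.removed_rows),
        "n_kept": len(filt.kept_rows),
        "n_train": len(split.train_rows),
        "n_test": len(split.test_rows),
    }
    logger.info("pooled workflow counts: %s", counts)
    return PooledWorkflowResult(filter_result=filt, split_result=split, counts=counts)


def assignment_to_rows(assignment: ScenarioAssignment) -> dict[ScenarioKey, pd.DataFrame]:
    """Labelled regression rows per scenario, for inspection or plotting."""
    out = {}
    for key, group in assignment.groups.items():
        out[key] = pd.DataFrame(
            [
                {
                    "compound_id": rec.compound_id,
                    "log_p": desc.log_p,
                    "tpsa": desc.tpsa,
                    "mv": desc.mv,
                    "log_kp": rec.log_kp,
                }
                for rec, desc in group
            ],
            columns=list(ROW_COLUMNS),
        )
    return out
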