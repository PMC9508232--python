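"""Three-descriptor linear QSPR fitted by ordinary least squares.

The model is

    logKp = b0 + b1*logP + b2*TPSA + b3*MV

with logKp in log10(cm/s) units.  The fit minimises the residual sum of
squares; the solution comes from a rank-revealing least-squares solve (SVD),
which returns the unique OLS estimate for full-rank designs and the
deterministic minimum-norm solution otherwise.  RMSE uses divisor n (a
population-style root mean square of residuals), isolated here in one place.

Fits with n <= p = 4 rows are flagged ``underdetermined``: the coefficients
exist (minimum-norm) but interpolate the data, so R-squared is reported as
1.0 when the residuals vanish with n in (3, 4) and as missing (None) for
n = 2, where even an interpolating plane is ambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .stratification import ScenarioKey

logger = logging.getLogger(__name__)

#: Design columns after the intercept, in order.
DESCRIPTOR_NAMES = ("log_p", "tpsa", "mv")

_N_PARAMS = 4
_COND_LIMIT = 1e10


@dataclass
class QsprModel:
    """Intercept plus the three descriptor coefficients, with diagnostics.

    ``provenance`` distinguishes models fitted by this package from models
    transcribed from the literature; ``unit`` tags the scale of the
    prediction (log10 cm/s throughout this pipeline).
    """

    intercept: float
    coef_logp: float
    coef_tpsa: float
    coef_mv: float
    n: int = 0
    r_squared: Optional[float] = None
    rmse: Optional[float] = None
    underdetermined: bool = False
    provenance: str = "fitted"
    scenario: Optional[ScenarioKey] = None
    label: str = ""
    n_compounds: Optional[int] = None
    unit: str = "log10(cm/s)"

    @property
    def coefficients(self) -> np.ndarray:
        """(intercept, b_logp, b_tpsa, b_mv) as an array."""
        return np.array(
            [self.intercept, self.coef_logp, self.coef_tpsa, self.coef_mv]
        )

    def predict(self, log_p, tpsa, mv):
        return predict(self, log_p, tpsa, mv)


@dataclass
class FitDiagnostics:
    """Residual decomposition of one OLS fit."""

    residuals: np.ndarray
    ss_res: float
    ss_tot: float
    condition_warning: bool = False
    rank: int = _N_PARAMS
    extra: dict = field(default_factory=dict)


RowsLike = Union[pd.DataFrame, np.ndarray, Sequence[Sequence[float]]]


def _as_xy(rows: RowsLike) -> tuple[np.ndarray, np.ndarray]:
    """Coerce rows of (log_p, tpsa, mv, log_kp) to (X, y) arrays."""
    if isinstance(rows, pd.DataFrame):
        X = rows[list(DESCRIPTOR_NAMES)].to_numpy(dtype=float)
        y = rows["log_kp"].to_numpy(dtype=float)
    else:
        arr = np.asarray(rows, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError("rows must be (n, 4): log_p, tpsa, mv, log_kp")
        X, y = arr[:, :3], arr[:, 3]
    return X, y


def fit_ols(
    rows: RowsLike,
    scenario: Optional[ScenarioKey] = None,
    label: str = "",
    n_compounds: Optional[int] = None,
) -> tuple[QsprModel, FitDiagnostics]:
    """Fit logKp on [1, logP, TPSA, MV] by least squares.

    Requires at least 2 rows.  For full-rank designs this is the unique OLS
    estimate; rank-deficient designs get the minimum-norm solution and a
    ``condition_warning``.  R-squared is 1 - SS_res/SS_tot about the response
    mean (missing when SS_tot == 0); RMSE is sqrt(SS_res / n).
    """
    X, y = _as_xy(rows)
    n = len(y)
    if n < 2:
        raise ValueError(f"need at least 2 rows to fit, got {n}")
    A = np.column_stack([np.ones(n), X])
    beta, _, rank, sv = np.linalg.lstsq(A, y, rcond=None)
    cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
    condition_warning = rank < min(_N_PARAMS, n) or cond > _COND_LIMIT

    fitted = A @ beta
    resid = y - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    rmse = float(np.sqrt(ss_res / n))

    underdetermined = n <= _N_PARAMS
    r2: Optional[float]
    if ss_tot <= 0.0 or n == 2:
        r2 = None
    elif underdetermined and ss_res <= 1e-12 * max(ss_tot, 1.0):
        # n = 3 or 4: the fit interpolates; report the degenerate 1.0.
        r2 = 1.0
    else:
        r2 = 1.0 - ss_res / ss_tot

    if condition_warning:
        logger.warning(
            "near-singular design (rank %d, cond %.2e) for %s",
            rank, cond, scenario or label or "fit",
        )

    model = QsprModel(
        intercept=float(beta[0]),
        coef_logp=float(beta[1]),
        coef_tpsa=float(beta[2]),
        coef_mv=float(beta[3]),
        n=n,
        r_squared=r2,
        rmse=rmse,
        underdetermined=underdetermined,
        provenance="fitted",
        scenario=scenario,
        label=label,
        n_compounds=n_compounds,
    )
    diag = FitDiagnostics(
        residuals=resid,
        ss_res=ss_res,
        ss_tot=ss_tot,
        condition_warning=condition_warning,
        rank=int(rank),
    )
    return model, diag


def predict(model: QsprModel, log_p, tpsa, mv):
    """Evaluate the linear model; accepts scalars or aligned arrays."""
    return (
        model.intercept
        + model.coef_logp * np.asarray(log_p)
        + model.coef_tpsa * np.asarray(tpsa)
        + model.coef_mv * np.asarray(mv)
    )


def predict_rows(model: QsprModel, rows: RowsLike) -> np.ndarray:
    if isinstance(rows, pd.DataFrame):
        return np.asarray(
            predict(model, rows["log_p"], rows["tpsa"], rows["mv"]), dtype=float
        )
    X, _ = _as_xy(rows)
    return np.asarray(predict(model, X[:, 0], X[:, 1], X[:, 2]), dtype=float)


def evaluate(model: QsprModel, rows: RowsLike) -> dict:
    """Goodness-of-fit of a model on labelled rows.

    Two R-squared conventions are reported because they differ off the
    training data: ``r_squared_sse`` = 1 - SSE/SST about the evaluation
    rows' own mean, and ``r_squared_pearson`` = squared Pearson correlation
    of predicted with observed.  Both are None when the observed values have
    zero variance.  RMSE is sqrt(mean squared residual).
    """
    X, y = _as_xy(rows)
    if len(y) == 0:
        raise ValueError("cannot evaluate on empty rows")
    pred = np.asarray(predict(model, X[:, 0], X[:, 1], X[:, 2]), dtype=float)
    resid = y - pred
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst > 0:
        r2_sse: Optional[float] = 1.0 - sse / sst
        if np.var(pred) > 0:
            r = np.corrcoef(pred, y)[0, 1]
            r2_pearson: Optional[float] = float(r * r)
        else:
            r2_pearson = None
    else:
        r2_sse = None
        r2_pearson = None
    return {
        "r_squared_sse": r2_sse,
        "r_squared_pearson": r2_pearson,
        "rmse": float(np.sqrt(sse / len(y))),
        "n": len(y),
    }


MODELS_CSV_COLUMNS = (
    "skin_source",
    "skin_layer",
    "donor_concentration",
    "temperature_bin",
    "n_records",
    "n_compounds",
    "r_squared",
    "rmse",
    "intercept",
    "coef_logp",
    "coef_tpsa",
    "coef_mv",
    "underdetermined",
)


def models_to_frame(models: Sequence[QsprModel]) -> pd.DataFrame:
    """Serialize fitted models to the models-CSV schema (one row each)."""
    rows = []
    for m in models:
        key = m.scenario
        rows.append(
            {
                "skin_source": key.skin_source if key else "",
                "skin_layer": key.skin_layer if key else "",
                "donor_concentration": key.donor_concentration if key else "",
                "temperature_bin": key.temperature_bin if key else "",
                "n_records": m.n,
                "n_compounds": m.n_compounds if m.n_compounds is not None else "",
                "r_squared": "" if m.r_squared is None else f"{m.r_squared:.6f}",
                "rmse": "" if m.rmse is None else f"{m.rmse:.6f}",
                "intercept": f"{m.intercept:.6f}" if np.isfinite(m.intercept) else "",
                "coef_logp": f"{m.coef_logp:.6f}" if np.isfinite(m.coef_logp) else "",
                "coef_tpsa": f"{m.coef_tpsa:.6f}" if np.isfinite(m.coef_tpsa) else "",
                "coef_mv": f"{m.coef_mv:.6f}" if np.isfinite(m.coef_mv) else "",
                "underdetermined": m.underdetermined,
            }
        )
    return pd.DataFrame(rows, columns=list(MODELS_CSV_COLUMNS))
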