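"""Leave-one-state-out validation of the PCR system.

For each omitted state: refit the five-equation system on the remaining
states, predict the omitted state's hospital×payer PCRs (second-stage
coefficients with residual covariates at 0), and report in/out-of-sample
RMSE, MAE, predicted and actual means, and the relative RMSE
(out-of-sample RMSE as a percentage of the mean actual PCR).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PAYERS
from .telser import SystemSpec, TelserSystem, TelserSystemResults


def split_by_state(
    observations: pd.DataFrame, omitted_state: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test partition by state label."""
    states = set(observations["state_id"].astype(str))
    if str(omitted_state) not in states:
        raise KeyError(f"state {omitted_state!r} not present in observations")
    mask = observations["state_id"].astype(str) == str(omitted_state)
    return observations[~mask].copy(), observations[mask].copy()


def metrics(actual, predicted) -> dict[str, float]:
    """RMSE, MAE and the two means for one payer's predictions."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError("actual and predicted must have equal length")
    if a.size == 0:
        raise ValueError("need at least one observation")
    err = p - a
    return {
        "rmse": float(np.sqrt(np.mean(err**2))),
        "mae": float(np.mean(np.abs(err))),
        "mean_actual": float(np.mean(a)),
        "mean_pred": float(np.mean(p)),
    }


def relative_rmse(rmse: float, mean_actual: float) -> float:
    """Out-of-sample RMSE as a percentage of the mean actual PCR."""
    if mean_actual <= 0:
        raise ValueError("mean actual PCR must be positive")
    return 100.0 * rmse / mean_actual


def fit_predict_omitted(
    system_spec: SystemSpec,
    train: pd.DataFrame,
    test: pd.DataFrame,
    stage: int | None = None,
) -> tuple[TelserSystemResults, pd.DataFrame, pd.DataFrame]:
    """Fit on ``train``; predict ``test`` (and ``train``, for in-sample
    RMSE) with residual covariates at their null value 0.

    Returns (fitted system, out-of-sample predictions, in-sample
    predictions); prediction frames carry hospital_id, payer, actual,
    predicted.  ``stage=1`` predicts from the first-stage coefficients
    instead of the default final stage.
    """
    result = TelserSystem(train, system_spec).fit()
    out_pred = result.predict(test, stage=stage).merge(
        test[["hospital_id", "payer", "pcr"]], on=["hospital_id", "payer"])
    in_pred = result.predict(train, stage=stage).merge(
        train[["hospital_id", "payer", "pcr"]], on=["hospital_id", "payer"])
    for frame in (out_pred, in_pred):
        frame.rename(columns={"pcr": "actual"}, inplace=True)
    return result, out_pred, in_pred


def validation_report(
    observations: pd.DataFrame,
    system_spec: SystemSpec,
    omitted_states: list[str],
    stage: int | None = None,
) -> pd.DataFrame:
    """One row per (omitted state, payer).

    Columns: omitted_state, payer, n_train, n_test, rmse_in, rmse_out,
    mae_out, mean_pred, mean_actual, relative_rmse_pct,
    share_pred_above_1.  The relative RMSE uses the *all-state* mean
    actual PCR for the payer as denominator.
    """
    if not omitted_states:
        raise ValueError("need at least one omitted state")
    all_state_means = observations.groupby("payer", observed=True)["pcr"].mean()
    rows = []
    for state in omitted_states:
        train, test = split_by_state(observations, state)
        _, out_pred, in_pred = fit_predict_omitted(system_spec, train, test, stage=stage)
        for payer in PAYERS:
            o = out_pred[out_pred["payer"] == payer]
            i = in_pred[in_pred["payer"] == payer]
            if o.empty or i.empty:
                continue
            mo = metrics(o["actual"], o["predicted"])
            mi = metrics(i["actual"], i["predicted"])
            rows.append({
                "omitted_state": state, "payer": payer,
                "n_train": len(i), "n_test": len(o),
                "rmse_in": mi["rmse"], "rmse_out": mo["rmse"],
                "mae_out": mo["mae"], "mean_pred": mo["mean_pred"],
                "mean_actual": mo["mean_actual"],
                "relative_rmse_pct": relative_rmse(
                    mo["rmse"], float(all_state_means[payer])),
                "share_pred_above_1": float(np.mean(o["predicted"] > 1.0)),
            })
    return pd.DataFrame(rows)


def write_validation_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, index=False)
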