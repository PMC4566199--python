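"""Stay-level records -> the hospital×payer analysis table.

The unit of analysis is the hospital-payer combination.  A payer's
payment-to-charge ratio (PCR) at a hospital is the ratio of total
payments to total charges over all stays with that primary payer.
Person-level characteristics enter as hospital-level means (casemix
proportions), joined with hospital designations, market concentration
(HHI over a fixed-radius market) and state covariates.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import (
    AGE_BANDS, CASEMIX_COLS, HOSPITAL_COLS, PAYERS, RACE_BANDS, STATE_COLS,
    VOLUME_COLS,
)

#: Stay-table categorical codings (CSV-friendly labels).
AGE_LABELS = ("0_17", "18_35", "36_45", "46_55", "56_plus")
RACE_LABELS = ("white", "black", "hispanic", "other")


class RankDeficiencyError(ValueError):
    """Raised when a design matrix is not full column rank."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix rank-deficient; offending columns: {self.columns}")


# ---------------------------------------------------------------------------
# PCR construction and retention filter
# ---------------------------------------------------------------------------

def compute_pcr(stays: pd.DataFrame) -> pd.DataFrame:
    """Per hospital×payer: PCR = Σ payments / Σ charges, unfiltered.

    Values outside (0, 1] are retained here; :func:`filter_pcr_range`
    applies the retention rule.
    """
    if (stays["charge"] <= 0).any():
        raise ValueError("all stay charges must be strictly positive")
    g = stays.groupby(["hospital_id", "payer"], sort=True, observed=True)
    out = g.agg(
        n_stays=("charge", "size"),
        total_charge=("charge", "sum"),
        total_payment=("payment", "sum"),
    ).reset_index()
    if (out["total_charge"] <= 0).any():
        raise ValueError("zero total charge for a hospital-payer group")
    out["pcr"] = out["total_payment"] / out["total_charge"]
    return out[["hospital_id", "payer", "pcr", "n_stays", "total_charge", "total_payment"]]


def filter_pcr_range(
    pcr_table: pd.DataFrame, upper_inclusive: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the retention rule: keep PCRs greater than zero and no
    greater than 1.0 (``upper_inclusive=False`` excludes exactly 1.0,
    the stricter variant used by the correlation analysis).

    Returns ``(kept, excluded)``; ``excluded`` carries a ``reason``
    column (``nonpositive`` or ``above_one``).
    """
    pcr = pcr_table["pcr"]
    nonpos = pcr <= 0
    above = pcr > 1.0 if upper_inclusive else pcr >= 1.0
    kept = pcr_table[~(nonpos | above)].copy()
    excluded = pcr_table[nonpos | above].copy()
    excluded["reason"] = np.where(nonpos[nonpos | above], "nonpositive", "above_one")
    return kept, excluded


# ---------------------------------------------------------------------------
# Hospital-level covariates
# ---------------------------------------------------------------------------

def casemix_profile(stays: pd.DataFrame) -> pd.DataFrame:
    """Hospital×payer casemix shares (plus average DRG weight).

    Shares are computed over that group's stays only: female, the five
    age bands, four race/ethnicity bands, in-hospital death, and the
    five APR-DRG severity levels.  Shares within each block sum to 1.
    """
    if stays.empty:
        raise ValueError("empty stay table")
    g = stays.groupby(["hospital_id", "payer"], sort=True, observed=True)
    prof = g.agg(
        n_stays=("female", "size"),
        female=("female", "mean"),
        died=("died", "mean"),
        avg_drg_weight=("drg_weight", "mean"),
    )
    for band, label in zip(AGE_BANDS, AGE_LABELS):
        prof[band] = g["age_band"].agg(lambda s, lab=label: np.mean(s == lab))
    for band, label in zip(RACE_BANDS, RACE_LABELS):
        prof[band] = g["race"].agg(lambda s, lab=label: np.mean(s == lab))
    for lev in range(5):
        prof[f"sev_{lev}"] = g["severity"].agg(lambda s, k=lev: np.mean(s == k))
    return prof.reset_index()


def volume_features(stays: pd.DataFrame, payer: str) -> pd.DataFrame:
    """Scaled payer volume and efficiency terms (Medicare/Medicaid only).

    Per hospital: discharges/10,000 and its square; stay-weighted
    average length of stay (ALOS)/10 and its square.
    """
    if payer not in ("medicare", "medicaid"):
        raise ValueError("volume features are defined for medicare and medicaid only")
    sub = stays[stays["payer"] == payer]
    g = sub.groupby("hospital_id", sort=True)
    feat = g.agg(n_stays=("los_days", "size"), alos=("los_days", "mean")).reset_index()
    feat["disch_10k"] = feat["n_stays"] / 10_000.0
    feat["disch_10k_sq"] = feat["disch_10k"] ** 2
    feat["alos_10"] = feat["alos"] / 10.0
    feat["alos_10_sq"] = feat["alos_10"] ** 2
    return feat[["hospital_id", "disch_10k", "disch_10k_sq", "alos_10", "alos_10_sq"]]


def compute_hhi(hospitals: pd.DataFrame, radius_miles: float = 15.0) -> pd.DataFrame:
    """Herfindahl-Hirschman index of each hospital's market.

    The market of hospital *i* is every hospital (including *i*) within
    ``radius_miles`` of it (planar Euclidean distance on the synthetic
    coordinates); shares are measured by total discharges over all
    payers.  Returns HHI in (0, 1] plus the scaled HHI×10 and its square
    used in the regressions.
    """
    if radius_miles <= 0:
        raise ValueError("radius must be positive")
    pts = hospitals[["x_miles", "y_miles"]].to_numpy(dtype=float)
    vol = hospitals["total_discharges"].to_numpy(dtype=float)
    tree = cKDTree(pts)
    neighbours = tree.query_ball_point(pts, r=radius_miles)
    hhi = np.empty(len(hospitals))
    for i, idx in enumerate(neighbours):
        v = vol[idx]
        total = v.sum()
        if total <= 0:
            raise ValueError(
                f"market of hospital {hospitals['hospital_id'].iloc[i]} has zero total volume")
        shares = v / total
        hhi[i] = float(np.sum(shares**2))
    out = hospitals[["hospital_id"]].copy()
    out["hhi"] = hhi
    out["hhi10"] = hhi * 10.0
    out["hhi10_sq"] = out["hhi10"] ** 2
    return out


def state_design(states: pd.DataFrame) -> pd.DataFrame:
    """Scaled state covariates for the regression design.

    The budget deficit (stored in $millions) enters per $1,000M; income
    is already in $1,000s, uninsured counts in 100,000s, Medicaid
    eligibility thresholds as ratios to the federal poverty level, and
    Medicaid per-capita spending in dollars.
    """
    out = states[["state_id"]].copy()
    out["deficit_bil"] = states["deficit_millions"] / 1000.0
    for col in STATE_COLS:
        if col != "deficit_bil":
            out[col] = states[col]
    return out


# ---------------------------------------------------------------------------
# Final analysis table
# ---------------------------------------------------------------------------

def assemble_observations(
    pcr_table: pd.DataFrame,
    profiles: pd.DataFrame,
    features: dict[str, pd.DataFrame],
    hospitals: pd.DataFrame,
    states: pd.DataFrame,
    radius_miles: float = 15.0,
) -> pd.DataFrame:
    """Join the retained PCR table with all covariate blocks.

    One row per retained hospital-payer.  Reference categories (age 56+,
    white race, severity 0/1) are dropped; the scaling registry is
    applied via :func:`state_design` and :func:`compute_hhi`.  Volume
    columns are NaN for payers other than Medicare/Medicaid.
    """
    obs = pcr_table.merge(profiles, on=["hospital_id", "payer"], how="left",
                          suffixes=("", "_prof"))
    if obs[["female", "died"]].isna().any().any():
        missing = obs.loc[obs["female"].isna(), ["hospital_id", "payer"]]
        raise KeyError(f"no casemix profile for groups: {missing.to_dict('records')[:5]}")
    hosp_cols = ["hospital_id", "state_id", "critical_access", "rural_referral",
                 "sole_community", "teaching", "wage_index"]
    obs = obs.merge(hospitals[hosp_cols], on="hospital_id", how="left")
    if obs["state_id"].isna().any():
        bad = obs.loc[obs["state_id"].isna(), "hospital_id"].unique()
        raise KeyError(f"unmatched hospital ids: {list(bad)[:5]}")

    obs = obs.merge(compute_hhi(hospitals, radius_miles), on="hospital_id", how="left")
    obs = obs.merge(state_design(states), on="state_id", how="left")
    if obs[list(STATE_COLS)].isna().any().any():
        bad = obs.loc[obs["deficit_bil"].isna(), "state_id"].unique()
        raise KeyError(f"unmatched state ids: {list(bad)[:5]}")

    for col in VOLUME_COLS:
        obs[col] = np.nan
    for payer, feat in features.items():
        mask = obs["payer"] == payer
        merged = obs.loc[mask, ["hospital_id"]].merge(feat, on="hospital_id", how="left")
        for col in VOLUME_COLS:
            obs.loc[mask, col] = merged[col].to_numpy()

    keep = (["hospital_id", "state_id", "payer", "pcr", "n_stays"]
            + list(CASEMIX_COLS) + list(HOSPITAL_COLS)
            + list(VOLUME_COLS) + list(STATE_COLS))
    return obs[keep].sort_values(["payer", "hospital_id"]).reset_index(drop=True)


def build_observations(
    stays: pd.DataFrame,
    hospitals: pd.DataFrame,
    states: pd.DataFrame,
    radius_miles: float = 15.0,
    upper_inclusive: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full stay-level -> analysis-table pipeline.

    Returns ``(observations, excluded)`` where ``excluded`` logs the
    hospital-payer PCRs removed by the retention rule.
    """
    pcr_table = compute_pcr(stays)
    kept, excluded = filter_pcr_range(pcr_table, upper_inclusive=upper_inclusive)
    profiles = casemix_profile(stays)
    features = {p: volume_features(stays, p) for p in ("medicare", "medicaid")
                if (stays["payer"] == p).any()}
    obs = assemble_observations(kept, profiles, features, hospitals, states,
                                radius_miles=radius_miles)
    return obs, excluded


# ---------------------------------------------------------------------------
# Serialisation (UTF-8, comma-separated, RFC-4180 quoting, "." decimal)
# ---------------------------------------------------------------------------

def write_observations(obs: pd.DataFrame, path) -> None:
    # %.17g guarantees binary64 round-trip through the CSV dialect
    obs.to_csv(path, index=False, float_format="%.17g")


def read_observations(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_exclusions(excluded: pd.DataFrame, path) -> None:
    """Exclusion log as JSON lines (one record per excluded group)."""
    with open(path, "w") as fh:
        for rec in excluded.to_dict("records"):
            fh.write(json.dumps(rec, default=float) + "\n")
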