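"""Seeded synthetic states, hospitals, stays and cost-to-charge ratios.

The generator emulates the statistical structure the analysis assumes:

* hospital×payer PCRs are gamma-distributed around ``exp(eta)`` where
  ``eta`` is a log-linear predictor in casemix, hospital and state
  covariates (true coefficients live in the config);
* the five payer errors within a hospital are tied together by a
  Gaussian copula with correlation matrix ``R`` over the gamma
  marginals, so the cross-equation residual estimator has signal to
  find;
* stay-level charges are lognormal and payments equal
  charge × true PCR × multiplicative mean-one noise, so aggregated
  payment/charge converges to the true PCR;
* each hospital's cost-to-charge ratio (CCR) is a noisy weighted
  combination of its three major-payer PCRs and independent of the
  self-pay/other PCRs.

Latent PCR draws above 1.0 (or at 0) are kept and *flagged*, not
redrawn, so the downstream retention filter has realistic work to do.
A :class:`TruthRecord` carries the true coefficients, linear
predictors, latent errors and true PCRs for parameter-recovery tests.
All randomness flows from a single seed via spawned substreams.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import aggregate
from .config import (
    AGE_BANDS, CASEMIX_COLS, HOSPITAL_COLS, PAYERS, RACE_BANDS, STATE_COLS,
    VOLUME_COLS, SimConfig,
)
from .aggregate import AGE_LABELS, RACE_LABELS

_STREAMS = ("states", "hospitals", "truth", "stays", "ccrs")


def _rngs(config: SimConfig) -> dict[str, np.random.Generator]:
    """One independent substream per generation stage (single seed)."""
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _lognormal(rng, mean: float, sd: float, size) -> np.ndarray:
    """Lognormal draws matched to a target mean and sd."""
    if mean <= 0:
        raise ValueError("lognormal mean must be positive")
    if sd == 0:
        return np.full(size, mean)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _trunc_normal(rng, mean, sd, size, lower):
    x = rng.normal(mean, sd, size)
    return np.clip(x, lower, None)


def _quota_counts(n: int, probs: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n items to categories with target
    shares ``probs`` (realised shares equal targets up to rounding)."""
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()
    raw = n * probs
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:short]] += 1
    return counts


def _quota_codes(rng, n: int, probs) -> np.ndarray:
    counts = _quota_counts(n, np.asarray(probs))
    codes = np.repeat(np.arange(len(counts)), counts)
    rng.shuffle(codes)
    return codes


# ---------------------------------------------------------------------------
# States and hospitals
# ---------------------------------------------------------------------------

def generate_states(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One row per state with the eight state covariates.

    Distribution families and default moments follow the hospital-level
    descriptive statistics of the study population (deficit in
    $millions, income in $1,000s, uninsured nonelderly below poverty in
    100,000s, eligibility thresholds as FPL ratios, Medicaid per-capita
    spending in dollars, CHIP enrollment rate, FQHCs per 1,000
    nonelderly uninsured).
    """
    if config.n_states < 1:
        raise ValueError("n_states must be >= 1")
    rng = rng or _rngs(config)["states"]
    n = config.n_states
    out = {"state_id": [f"S{i:03d}" for i in range(n)]}
    for name, (mean, sd, family) in config.state_dists.items():
        if family == "lognormal":
            out[name] = _lognormal(rng, mean, sd, n)
        elif family == "normal":
            out[name] = rng.normal(mean, sd, n)
        elif family == "unit_normal":
            out[name] = np.clip(rng.normal(mean, sd, n), 0.0, 1.0)
        else:
            raise ValueError(f"unknown distribution family {family!r}")
    return pd.DataFrame(out)


def generate_hospitals(
    config: SimConfig,
    states: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Hospitals with state assignment, planar coordinates, designation
    flags, wage index and per-payer annual stay counts.

    Each state occupies its own square of side ``region_size_miles``,
    offset along x so markets never straddle states.  Total discharges
    are the sum of the per-payer stay counts (drawn lognormal around the
    configured means; a configurable probability of a zero-stay
    hospital-payer cell exercises missing-equation handling).
    """
    if states.empty:
        raise ValueError("states table is empty")
    rng = rng or _rngs(config)["hospitals"]
    m = config.hospitals_per_state
    size = len(states) * m
    state_ids = np.repeat(states["state_id"].to_numpy(), m)
    state_index = np.repeat(np.arange(len(states)), m)
    L = config.region_size_miles
    # offset keeps different states' hospitals out of each other's markets
    offset = state_index * (L + 10 * config.hhi_radius_miles)
    out = pd.DataFrame({
        "hospital_id": [f"H{i:05d}" for i in range(size)],
        "state_id": state_ids,
        "x_miles": rng.uniform(0, L, size) + offset,
        "y_miles": rng.uniform(0, L, size),
        "wage_index": _trunc_normal(rng, config.wage_index_mean,
                                    config.wage_index_sd, size, 0.5),
    })
    for flag, prev in config.designation_prevalence.items():
        out[flag] = (rng.random(size) < prev).astype(int)
    for payer in PAYERS:
        counts = np.rint(_lognormal(rng, config.stay_count_mean[payer],
                                    config.stay_count_mean[payer] * config.stay_count_cv,
                                    size)).astype(int)
        counts = np.maximum(counts, 1)
        pz = config.zero_stay_prob.get(payer, 0.0)
        if pz > 0:
            counts[rng.random(size) < pz] = 0
        out[f"n_stays_{payer}"] = counts
    out["total_discharges"] = sum(out[f"n_stays_{p}"] for p in PAYERS)
    q = out["total_discharges"].rank(pct=True)
    out["bed_size_cat"] = pd.cut(q, [0, 0.25, 0.5, 0.9, 1.0],
                                 labels=["<100", "100-199", "200-499", "500+"],
                                 include_lowest=True).astype(str)
    return out


# ---------------------------------------------------------------------------
# True PCRs
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    """True coefficients and latent state of the generated world.

    ``coefs``: payer × (intercept + covariates) true coefficient table.
    ``table``: one row per hospital×payer with every design covariate,
    the linear predictor ``eta``, the latent copula normal ``latent_z``,
    the true PCR and retention flags (``flag_above_one``,
    ``flag_nonpositive``).
    """

    coefs: pd.DataFrame
    table: pd.DataFrame


def _draw_casemix(config: SimConfig, payer: str, size: int, rng) -> pd.DataFrame:
    """Per-hospital casemix proportion parameters for one payer."""
    c = config.casemix_concentration

    def beta(mean):
        if mean <= 0 or mean >= 1:
            return np.full(size, float(mean))
        return rng.beta(c * mean, c * (1 - mean), size)

    def dirichlet(shares):
        alpha = np.maximum(np.asarray(shares, dtype=float), 1e-4)
        alpha = alpha / alpha.sum() * c
        return rng.dirichlet(alpha, size)

    out = pd.DataFrame({"female": beta(config.female_mean[payer]),
                        "died": beta(config.died_mean[payer])})
    age = dirichlet(config.age_shares[payer])
    for j, band in enumerate(AGE_BANDS):
        out[band] = age[:, j]
    race = dirichlet(config.race_shares[payer])
    for j, band in enumerate(RACE_BANDS):
        out[band] = race[:, j]
    sev = dirichlet(config.severity_shares[payer])
    for j in range(5):
        out[f"sev_{j}"] = sev[:, j]
    return out


def generate_true_pcrs(
    config: SimConfig,
    hospitals: pd.DataFrame,
    states: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> TruthRecord:
    """Draw the latent hospital×payer world: covariates, linear
    predictors, correlated gamma errors and true PCRs.

    For each hospital×payer, ``eta = alpha_j + slopes · x`` with the
    intercept ``alpha_j`` calibrated so that the population mean of
    ``exp(eta)`` equals the configured mean PCR.  Errors are drawn via a
    Gaussian copula: ``z ~ N(0, R)`` across payers within hospital,
    ``PCR = GammaPPF(Phi(z); shape nu, mean exp(eta))``.  Draws above
    1.0 are flagged, not redrawn.
    """
    rng = rng or _rngs(config)["truth"]
    R = np.asarray(config.error_corr, dtype=float)
    if np.linalg.eigvalsh(R).min() < -1e-8:
        raise ValueError("error_corr must be positive semi-definite")
    nu = config.gamma_shape
    if nu <= 0:
        raise ValueError("gamma_shape must be positive")

    n_h = len(hospitals)
    hhi = aggregate.compute_hhi(hospitals, config.hhi_radius_miles)
    sdesign = aggregate.state_design(states)
    hosp_block = hospitals[["hospital_id", "state_id", "critical_access",
                            "rural_referral", "sole_community", "teaching",
                            "wage_index"]].merge(hhi, on="hospital_id")
    hosp_block = hosp_block.merge(sdesign, on="state_id", how="left")

    # latent copula normals: one 5-vector per hospital, shared across payers
    chol = np.linalg.cholesky(R + 1e-12 * np.eye(len(PAYERS)))
    z = rng.standard_normal((n_h, len(PAYERS))) @ chol.T

    frames = []
    coef_rows = {}
    for j, payer in enumerate(PAYERS):
        block = hosp_block.copy()
        block["payer"] = payer
        cm = _draw_casemix(config, payer, n_h, rng)
        for col in cm.columns:
            block[col] = cm[col].to_numpy()
        mean_w, sd_w = config.drg_weight[payer]
        block["avg_drg_weight"] = _trunc_normal(rng, mean_w, sd_w, n_h, 0.1)
        block["n_stays"] = hospitals[f"n_stays_{payer}"].to_numpy()
        if payer in ("medicare", "medicaid"):
            block["disch_10k"] = block["n_stays"] / 10_000.0
            block["disch_10k_sq"] = block["disch_10k"] ** 2
            block["alos_days"] = _lognormal(
                rng, config.alos_mean[payer],
                config.alos_mean[payer] * config.alos_cv, n_h)
            block["alos_10"] = block["alos_days"] / 10.0
            block["alos_10_sq"] = block["alos_10"] ** 2
        else:
            block["alos_days"] = _lognormal(
                rng, config.alos_mean[payer],
                config.alos_mean[payer] * config.alos_cv, n_h)
            for col in VOLUME_COLS:
                block[col] = np.nan

        slopes = config.true_slopes.get(payer, {})
        contrib = np.zeros(n_h)
        for cov, b in slopes.items():
            contrib += b * block[cov].to_numpy(dtype=float)
        # calibrate the intercept so mean(exp(eta)) == configured mean PCR
        alpha = float(np.log(config.mean_pcr[payer]) - np.log(np.mean(np.exp(contrib))))
        eta = alpha + contrib
        mu = np.exp(eta)
        u = stats.norm.cdf(z[:, j])
        pcr = stats.gamma.ppf(u, a=nu, scale=mu / nu)

        block["eta"] = eta
        block["latent_z"] = z[:, j]
        block["pcr_true"] = pcr
        block["flag_above_one"] = (pcr > 1.0).astype(int)
        block["flag_nonpositive"] = (pcr <= 0.0).astype(int)
        frames.append(block)

        coef = {"intercept": alpha}
        coef.update(slopes)
        coef_rows[payer] = coef

    table = pd.concat(frames, ignore_index=True)
    all_covs = (["intercept"] + list(CASEMIX_COLS) + list(HOSPITAL_COLS)
                + list(VOLUME_COLS) + list(STATE_COLS))
    coefs = pd.DataFrame(
        {payer: {c: coef_rows[payer].get(c, 0.0) for c in all_covs} for payer in PAYERS}
    ).T.reindex(PAYERS)[all_covs]
    # volume terms have no defined truth for payers whose equations omit them
    for payer in ("private", "self_pay", "other"):
        coefs.loc[payer, list(VOLUME_COLS)] = np.nan
    return TruthRecord(coefs=coefs, table=table)


# ---------------------------------------------------------------------------
# Stays
# ---------------------------------------------------------------------------

def generate_stays(
    config: SimConfig,
    truth: TruthRecord,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Stay-level records consistent with the latent truth.

    Per hospital×payer the configured number of stays is generated with
    lognormal charges, ``payment = charge × true PCR × noise`` (mean-one
    lognormal, sd ``payment_noise_sd``), casemix attributes allocated by
    largest-remainder quota from the hospital's true proportions (so
    realised shares equal the truth up to rounding), gamma lengths of
    stay around the hospital's true ALOS, and per-stay DRG weights
    around the hospital's true average.  The aggregate payment/charge
    ratio converges to the true PCR as the stay count grows and equals
    it exactly at zero payment noise.
    """
    rng = rng or _rngs(config)["stays"]
    sd = config.payment_noise_sd
    if sd > 0:
        sig2 = np.log1p(sd**2)
        noise_mu, noise_sigma = -sig2 / 2.0, np.sqrt(sig2)

    rows = truth.table
    frames = []
    for rec in rows.itertuples(index=False):
        n = int(rec.n_stays)
        if n == 0:
            continue
        charge = rng.lognormal(config.charge_log_mean, config.charge_log_sd, n)
        noise = rng.lognormal(noise_mu, noise_sigma, n) if sd > 0 else 1.0
        payment = charge * rec.pcr_true * noise
        if config.los_cv > 0:
            shape = 1.0 / config.los_cv**2
            los = rng.gamma(shape, rec.alos_days / shape, n)
        else:
            los = np.full(n, rec.alos_days)
        if config.drg_weight_stay_sd > 0:
            drg = np.clip(rng.normal(rec.avg_drg_weight, config.drg_weight_stay_sd, n),
                          0.05, None)
        else:
            drg = np.full(n, rec.avg_drg_weight)
        age = np.array(AGE_LABELS)[_quota_codes(
            rng, n, [getattr(rec, b) for b in AGE_BANDS])]
        race = np.array(RACE_LABELS)[_quota_codes(
            rng, n, [getattr(rec, b) for b in RACE_BANDS])]
        sev = _quota_codes(rng, n, [getattr(rec, f"sev_{k}") for k in range(5)])
        female = _quota_codes(rng, n, [1 - rec.female, rec.female])
        died = _quota_codes(rng, n, [1 - rec.died, rec.died])
        frames.append(pd.DataFrame({
            "hospital_id": rec.hospital_id,
            "state_id": rec.state_id,
            "payer": rec.payer,
            "female": female,
            "age_band": age,
            "race": race,
            "died": died,
            "severity": sev,
            "los_days": los,
            "drg_weight": drg,
            "charge": charge,
            "payment": payment,
        }))
    if not frames:
        raise ValueError("no stays generated (all hospital-payer counts zero)")
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# CCRs
# ---------------------------------------------------------------------------

def generate_ccrs(
    config: SimConfig,
    truth: TruthRecord,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-hospital cost-to-charge ratio linked to the major payers.

    CCR = weighted combination of the hospital's Medicare/Medicaid/
    private *true* PCRs plus independent Gaussian noise; weights over
    missing payers are renormalised.  Defaults give a population
    correlation of roughly 0.75-0.79 with each major-payer PCR and ~0
    with self-pay/other.
    """
    rng = rng or _rngs(config)["ccrs"]
    weights = config.ccr_weights
    if all(w == 0 for w in weights.values()) and config.ccr_noise_sd == 0:
        raise ValueError("degenerate CCR: all link weights zero with zero noise")
    wide = truth.table.pivot(index="hospital_id", columns="payer", values="pcr_true")
    majors = [p for p in ("medicare", "medicaid", "private") if p in wide.columns]
    if not majors or wide[majors].isna().all(axis=1).any():
        raise ValueError("each hospital needs a true PCR for at least one major payer")
    w = np.array([weights.get(p, 0.0) for p in majors])
    vals = wide[majors].to_numpy()
    mask = ~np.isnan(vals)
    wmat = np.where(mask, w, 0.0)
    denom = wmat.sum(axis=1)
    denom[denom == 0] = np.nan
    combo = np.nansum(vals * wmat, axis=1) / denom
    ccr = combo + rng.normal(0.0, config.ccr_noise_sd, len(wide))
    return pd.DataFrame({"hospital_id": wide.index.to_numpy(), "ccr": ccr})


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

@dataclass
class SimData:
    """All artifacts of one simulated world."""

    config: SimConfig
    states: pd.DataFrame
    hospitals: pd.DataFrame
    truth: TruthRecord
    stays: pd.DataFrame | None
    ccrs: pd.DataFrame

    def write(self, out_dir) -> dict:
        """Write CSVs plus a manifest (config hash, seed, file digests)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = {"states.csv": self.states, "hospitals.csv": self.hospitals,
                 "truth.csv": self.truth.table, "truth_coefs.csv": self.truth.coefs,
                 "ccrs.csv": self.ccrs}
        if self.stays is not None:
            files["stays.csv"] = self.stays
        digests = {}
        for name, df in files.items():
            path = out / name
            df.to_csv(path, index=(name == "truth_coefs.csv"))
            digests[name] = hashlib.sha256(path.read_bytes()).hexdigest()
        cfg_yaml = json.dumps(self.config.to_dict(), sort_keys=True)
        manifest = {
            "seed": self.config.seed,
            "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
            "files": digests,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest


def simulate(config: SimConfig, with_stays: bool = True) -> SimData:
    """Run every generation stage from the single config seed."""
    rngs = _rngs(config)
    states = generate_states(config, rngs["states"])
    hospitals = generate_hospitals(config, states, rngs["hospitals"])
    truth = generate_true_pcrs(config, hospitals, states, rngs["truth"])
    stays = generate_stays(config, truth, rngs["stays"]) if with_stays else None
    ccrs = generate_ccrs(config, truth, rngs["ccrs"])
    return SimData(config=config, states=states, hospitals=hospitals,
                   truth=truth, stays=stays, ccrs=ccrs)


def observations_from_truth(
    truth: TruthRecord, apply_filter: bool = True, upper_inclusive: bool = True
) -> pd.DataFrame:
    """Hospital×payer analysis table taken directly from the truth
    record (no stay-level measurement noise).

    The covariates are exactly those entering ``eta`` and the response
    is the true PCR, which makes this the natural input for
    parameter-recovery and estimator-calibration experiments.
    """
    cols = (["hospital_id", "state_id", "payer", "n_stays"]
            + list(CASEMIX_COLS) + list(HOSPITAL_COLS) + list(VOLUME_COLS)
            + list(STATE_COLS))
    obs = truth.table[cols + ["pcr_true"]].rename(columns={"pcr_true": "pcr"}).copy()
    if apply_filter:
        obs, _ = aggregate.filter_pcr_range(obs, upper_inclusive=upper_inclusive)
    return obs.reset_index(drop=True)
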