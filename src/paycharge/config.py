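"""Configuration for the synthetic all-payer claims world.

Defaults encode the hospital population the models are meant for: ten
states of community hospitals, five payer categories, hospital-level
payment-to-charge ratios (PCRs) that follow a log-linear predictor with
gamma-distributed variation, and cross-payer error correlation within a
hospital.  Every default is overridable; the random seed fully
determines all output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import yaml

#: The five primary-payer categories, in canonical order.
PAYERS = ("medicare", "medicaid", "private", "self_pay", "other")

#: Age bands; the last (56+) is the regression reference category.
AGE_BANDS = ("age_0_17", "age_18_35", "age_36_45", "age_46_55", "age_56_plus")

#: Race/ethnicity bands; white is the reference category.
RACE_BANDS = ("race_white", "race_black", "race_hispanic", "race_other")

#: APR-DRG severity levels 0..4; levels 0 and 1 are pooled as reference.
SEVERITY_LEVELS = (0, 1, 2, 3, 4)

# Covariate blocks of the hospital×payer design (casemix C, hospital H,
# payer volume/efficiency V, state S).
CASEMIX_COLS = (
    "female",
    "age_0_17", "age_18_35", "age_36_45", "age_46_55",
    "race_black", "race_hispanic", "race_other",
    "died",
    "sev_2", "sev_3", "sev_4",
)
HOSPITAL_COLS = (
    "critical_access", "rural_referral", "sole_community", "teaching",
    "avg_drg_weight", "wage_index", "hhi10", "hhi10_sq",
)
VOLUME_COLS = ("disch_10k", "disch_10k_sq", "alos_10", "alos_10_sq")
STATE_COLS = (
    "deficit_bil", "income_1k", "uninsured_100k",
    "elig_child_fpl", "elig_adult_fpl",
    "medicaid_pc_spend", "chip_rate", "fqhc_per_1k",
)


def default_terms(payer: str, state_mode: str = "covariates") -> list[str]:
    """Default covariate list for one payer equation.

    Medicare and Medicaid equations additionally carry the payer's scaled
    discharge count and average length of stay, each with its square.
    With ``state_mode="fixed_effects"`` the eight state covariates are
    replaced by a state dummy block (encoded at design-build time).
    """
    terms = list(CASEMIX_COLS) + list(HOSPITAL_COLS)
    if payer in ("medicare", "medicaid"):
        terms += list(VOLUME_COLS)
    if state_mode == "covariates":
        terms += list(STATE_COLS)
    elif state_mode == "fixed_effects":
        terms += ["state_id"]
    else:
        raise ValueError(f"unknown state_mode: {state_mode!r}")
    return terms


# --- population defaults (hospital-level means / sds) -------------------

_DEFAULT_MEAN_PCR = {
    "medicare": 0.320, "medicaid": 0.367, "private": 0.487,
    "self_pay": 0.456, "other": 0.611,
}

_DEFAULT_FEMALE = {
    "medicare": 0.566, "medicaid": 0.640, "private": 0.585,
    "self_pay": 0.466, "other": 0.423,
}
_DEFAULT_AGE = {  # shares over AGE_BANDS
    "medicare": (0.005, 0.018, 0.030, 0.053, 0.894),
    "medicaid": (0.293, 0.305, 0.121, 0.130, 0.151),
    "private": (0.191, 0.211, 0.145, 0.180, 0.272),
    "self_pay": (0.134, 0.311, 0.200, 0.197, 0.159),
    "other": (0.113, 0.221, 0.173, 0.212, 0.281),
}
_DEFAULT_RACE = {  # shares over RACE_BANDS (white, black, hispanic, other)
    "medicare": (0.709, 0.087, 0.079, 0.125),
    "medicaid": (0.471, 0.156, 0.219, 0.154),
    "private": (0.655, 0.086, 0.107, 0.152),
    "self_pay": (0.552, 0.119, 0.186, 0.142),
    "other": (0.615, 0.109, 0.136, 0.141),
}
_DEFAULT_DIED = {
    "medicare": 0.042, "medicaid": 0.013, "private": 0.014,
    "self_pay": 0.015, "other": 0.023,
}
_DEFAULT_SEVERITY = {  # shares over severity levels 0..4
    "medicare": (0.000, 0.195, 0.453, 0.282, 0.070),
    "medicaid": (0.000, 0.505, 0.340, 0.124, 0.031),
    "private": (0.000, 0.539, 0.334, 0.100, 0.026),
    "self_pay": (0.001, 0.507, 0.361, 0.104, 0.027),
    "other": (0.000, 0.485, 0.357, 0.125, 0.033),
}
_DEFAULT_DRG_WEIGHT = {  # (mean, sd) of hospital-level average DRG weight
    "medicare": (1.32, 0.278), "medicaid": (0.878, 0.280),
    "private": (1.03, 0.310), "self_pay": (0.975, 0.234),
    "other": (1.22, 0.355),
}
_DEFAULT_STAY_MEAN = {  # mean stays per hospital and payer, per year
    "medicare": 4190.0, "medicaid": 2050.0, "private": 3000.0,
    "self_pay": 600.0, "other": 500.0,
}
_DEFAULT_ALOS_MEAN = {  # mean length of stay in days
    "medicare": 6.40, "medicaid": 6.01, "private": 4.60,
    "self_pay": 4.00, "other": 5.00,
}

# State covariates: name -> (mean, sd, family). Deficit is in millions of
# dollars; income in $1,000s; uninsured nonelderly below poverty in
# 100,000s; eligibility thresholds as ratios to the federal poverty
# level; Medicaid spending per capita in dollars.
_DEFAULT_STATE_DISTS: dict[str, tuple[float, float, str]] = {
    "deficit_millions": (5423.0, 6211.0, "lognormal"),
    "income_1k": (41.07, 4.75, "normal"),
    "uninsured_100k": (13.2, 11.1, "lognormal"),
    "elig_child_fpl": (1.03, 0.134, "normal"),
    "elig_adult_fpl": (1.11, 0.503, "lognormal"),
    "medicaid_pc_spend": (1137.0, 566.0, "lognormal"),
    "chip_rate": (0.851, 0.061, "unit_normal"),
    "fqhc_per_1k": (6.82, 3.20, "lognormal"),
}

_DEFAULT_DESIGNATIONS = {  # prevalence of the four Medicare designations
    "teaching": 0.294,
    "critical_access": 0.095,
    "sole_community": 0.086,
    "rural_referral": 0.033,
}

# Latent Gaussian-copula correlation of the five payer errors within a
# hospital (order = PAYERS).  The three major payers are strongly
# mutually correlated; self-pay and other only weakly, with the
# private/self-pay entry negative so a cost-to-charge ratio built from
# the major payers is uncorrelated with self-pay in the population.
_DEFAULT_R = (
    (1.00, 0.77, 0.69, 0.12, 0.00),
    (0.77, 1.00, 0.62, 0.21, 0.08),
    (0.69, 0.62, 1.00, -0.30, -0.06),
    (0.12, 0.21, -0.30, 1.00, 0.24),
    (0.00, 0.08, -0.06, 0.24, 1.00),
)

# Modest true slopes on a handful of covariates (same for every payer by
# default); all other covariates have true coefficient zero.  Intercepts
# are calibrated at generation time so the population mean PCR matches
# ``mean_pcr`` exactly (see simulate.generate_true_pcrs).
_DEFAULT_SLOPES = {
    payer: {
        "female": -0.15, "died": 0.5, "teaching": 0.10,
        "wage_index": -0.20, "hhi10": 0.02, "income_1k": 0.005,
    }
    for payer in PAYERS
}

# CCR = weighted mean of the hospital's major-payer true PCRs + Gaussian
# noise.  The noise sd was calibrated once so the default population
# correlation with each major-payer PCR is about 0.75-0.79 and about 0
# with self-pay/other.
_DEFAULT_CCR_WEIGHTS = {"medicare": 1 / 3, "medicaid": 1 / 3, "private": 1 / 3}
_DEFAULT_CCR_NOISE_SD = 0.07


def _asdict_payer(d: Mapping[str, Any]) -> dict[str, Any]:
    return {p: d[p] for p in PAYERS}


@dataclass
class SimConfig:
    """Full parameterisation of the synthetic claims world.

    Attributes
    ----------
    n_states, hospitals_per_state
        Geography.  Defaults give ~1,140 hospitals across 10 states.
    mean_pcr
        Target population mean PCR per payer (the intercept of each true
        equation is calibrated to hit it given the slopes).
    true_slopes
        Per payer, mapping covariate name -> true log-scale coefficient.
    error_corr
        5×5 latent Gaussian correlation matrix across payers (order =
        :data:`PAYERS`); must be symmetric, unit-diagonal, PSD.
    gamma_shape
        Shape ν of the gamma PCR distribution around exp(η); larger ν
        means less hospital-level noise (CV = 1/√ν).
    payment_noise_sd
        Stay-level multiplicative (mean-1 lognormal) noise linking
        payment to charge × PCR; 0 makes aggregation exact.
    """

    n_states: int = 10
    hospitals_per_state: int = 114
    seed: int = 0

    # true model
    mean_pcr: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MEAN_PCR))
    true_slopes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {p: dict(s) for p, s in _DEFAULT_SLOPES.items()})
    error_corr: Any = _DEFAULT_R
    gamma_shape: float = 8.0

    # casemix populations
    female_mean: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_FEMALE))
    age_shares: dict[str, tuple] = field(default_factory=lambda: dict(_DEFAULT_AGE))
    race_shares: dict[str, tuple] = field(default_factory=lambda: dict(_DEFAULT_RACE))
    died_mean: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_DIED))
    severity_shares: dict[str, tuple] = field(default_factory=lambda: dict(_DEFAULT_SEVERITY))
    casemix_concentration: float = 40.0

    # hospitals and markets
    designation_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DESIGNATIONS))
    wage_index_mean: float = 1.07
    wage_index_sd: float = 0.178
    drg_weight: dict[str, tuple] = field(default_factory=lambda: dict(_DEFAULT_DRG_WEIGHT))
    region_size_miles: float = 175.0
    hhi_radius_miles: float = 15.0

    # stays
    stay_count_mean: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_STAY_MEAN))
    stay_count_cv: float = 0.9   # between-hospital CV of stay counts
    zero_stay_prob: dict[str, float] = field(default_factory=lambda: {p: 0.0 for p in PAYERS})
    alos_mean: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_ALOS_MEAN))
    alos_cv: float = 0.30          # between-hospital spread of true ALOS
    los_cv: float = 0.50           # within-hospital stay-to-stay spread
    charge_log_mean: float = float(np.log(25_000.0))
    charge_log_sd: float = 1.0
    payment_noise_sd: float = 0.20
    drg_weight_stay_sd: float = 0.25

    # state covariates
    state_dists: dict[str, tuple] = field(default_factory=lambda: dict(_DEFAULT_STATE_DISTS))

    # CCR link
    ccr_weights: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_CCR_WEIGHTS))
    ccr_noise_sd: float = _DEFAULT_CCR_NOISE_SD

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.hospitals_per_state < 1:
            raise ValueError("hospitals_per_state must be >= 1")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        R = np.asarray(self.error_corr, dtype=float)
        if R.shape != (len(PAYERS), len(PAYERS)):
            raise ValueError("error_corr must be 5x5 in payer order")
        if not np.allclose(R, R.T):
            raise ValueError("error_corr must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("error_corr must have unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-8:
            raise ValueError("error_corr must be positive semi-definite")
        self.error_corr = R
        for name, probs in (("female_mean", self.female_mean),
                            ("died_mean", self.died_mean),
                            ("designation_prevalence", self.designation_prevalence),
                            ("zero_stay_prob", self.zero_stay_prob)):
            for key, v in probs.items():
                if not 0.0 <= float(v) <= 1.0:
                    raise ValueError(f"{name}[{key!r}] must lie in [0, 1]")
        for payer in PAYERS:
            for cov in self.true_slopes.get(payer, {}):
                allowed = set(default_terms(payer))
                if cov not in allowed:
                    raise ValueError(
                        f"true slope on unknown covariate {cov!r} for payer {payer!r}")

    # -- (de)serialisation ------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["error_corr"] = np.asarray(self.error_corr).tolist()
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
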