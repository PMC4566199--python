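"""Shared builders for simulation-based tests.

The "slim" world keeps the generative structure of the default
configuration (gamma PCRs around a log-linear predictor, copula-linked
payer errors) but puts true slopes on only three covariates so that
replicated estimator experiments stay cheap.
"""

import numpy as np

import paycharge as pc

SLIM_TERMS = ("female", "teaching", "wage_index")

SLIM_SLOPES = {
    p: {"female": -0.15, "teaching": 0.10, "wage_index": -0.20}
    for p in pc.PAYERS
}

# one equation-specific extra regressor per payer (exclusion
# restrictions, as in the full specification where only the
# Medicare/Medicaid equations carry volume terms)
EXTRA_TERM = {"medicare": "hhi10", "medicaid": "income_1k",
              "private": "avg_drg_weight", "self_pay": "chip_rate",
              "other": "fqhc_per_1k"}
EXTRA_SLOPE = {"hhi10": 0.03, "income_1k": 0.01, "avg_drg_weight": 0.15,
               "chip_rate": -0.8, "fqhc_per_1k": -0.02}


def slim_config(seed, n_states=4, hospitals_per_state=50, R=None, **kwargs):
    d = dict(n_states=n_states, hospitals_per_state=hospitals_per_state,
             seed=seed, true_slopes={p: dict(s) for p, s in SLIM_SLOPES.items()})
    if R is not None:
        d["error_corr"] = np.asarray(R)
    d.update(kwargs)
    return pc.SimConfig(**d)


def slim_system_spec(**kwargs):
    return pc.SystemSpec.default(
        terms={p: list(SLIM_TERMS) for p in pc.PAYERS}, **kwargs)


def distinct_config(seed, n_states=5, hospitals_per_state=60, **kwargs):
    slopes = {p: {**SLIM_SLOPES[p], EXTRA_TERM[p]: EXTRA_SLOPE[EXTRA_TERM[p]]}
              for p in pc.PAYERS}
    d = dict(n_states=n_states, hospitals_per_state=hospitals_per_state,
             seed=seed, true_slopes=slopes)
    d.update(kwargs)
    return pc.SimConfig(**d)


def distinct_system_spec(**kwargs):
    terms = {p: list(SLIM_TERMS) + [EXTRA_TERM[p]] for p in pc.PAYERS}
    return pc.SystemSpec.default(terms=terms, **kwargs)


def truth_obs(cfg, **kwargs):
    """Hospital×payer observations taken straight from the latent truth."""
    data = pc.simulate(cfg, with_stays=False)
    return pc.observations_from_truth(data.truth, **kwargs), data
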