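"""Two-stage cross-equation residual (Telser) system estimator.

The five payer equations are seemingly unrelated: each hospital
contributes up to five PCR observations whose errors are correlated
within the hospital.  The Telser procedure estimates each equation
individually, saves the errors, then re-estimates each equation with
the *other* four equations' first-stage errors appended as covariates.
The process may be iterated; convergence often occurs at the second
stage, which is the default.

Hospitals missing from some equations leave holes in the residual
table.  Two policies are provided: ``complete_case`` (an equation's
second-stage sample keeps only hospitals with residuals from all four
other equations — the default) and ``zero_impute`` (missing residuals
set to 0, logged).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PAYERS, default_terms
from .glm import GammaGLM, GammaGLMResults, ModelSpec

_RESIDUAL_KINDS = ("response", "pearson", "deviance")
_POLICIES = ("complete_case", "zero_impute")


def resid_col(payer: str) -> str:
    return f"resid_{payer}"


@dataclass
class SystemSpec:
    """Specification of the five-equation system."""

    specs: dict[str, ModelSpec]
    residual_kind: str = "response"
    stages: int = 2
    missing_policy: str = "complete_case"

    def __post_init__(self):
        if set(self.specs) != set(PAYERS):
            raise ValueError(f"need exactly one ModelSpec per payer {PAYERS}")
        if self.residual_kind not in _RESIDUAL_KINDS:
            raise ValueError(f"residual_kind must be one of {_RESIDUAL_KINDS}")
        if self.missing_policy not in _POLICIES:
            raise ValueError(f"missing_policy must be one of {_POLICIES}")
        if self.stages < 1:
            raise ValueError("stages must be >= 1")

    @classmethod
    def default(cls, state_mode: str = "covariates", terms: dict | None = None,
                **kwargs) -> "SystemSpec":
        """The full specification used in the main analysis (casemix +
        hospital + market + volume + state blocks per payer), or custom
        per-payer term lists via ``terms``."""
        specs = {
            p: ModelSpec(payer=p,
                         terms=list(terms[p]) if terms else default_terms(p, state_mode),
                         state_mode=state_mode)
            for p in PAYERS
        }
        return cls(specs=specs, **kwargs)


def stage_one(
    system_spec: SystemSpec, observations: pd.DataFrame
) -> tuple[dict[str, GammaGLMResults], pd.DataFrame]:
    """Fit the five equations individually and save the errors.

    Returns the fits and a hospital × payer residual table; hospitals
    absent from an equation's estimation sample have missing entries.
    """
    fits: dict[str, GammaGLMResults] = {}
    cols = {}
    for payer in PAYERS:
        model = GammaGLM.from_spec(system_spec.specs[payer], observations)
        fit = model.fit()
        fits[payer] = fit
        hosp = observations.loc[model.row_index, "hospital_id"].to_numpy()
        cols[payer] = pd.Series(fit.resid(system_spec.residual_kind), index=hosp)
    residual_table = pd.DataFrame(cols)
    residual_table.index.name = "hospital_id"
    return fits, residual_table


def align_residuals(
    residual_table: pd.DataFrame, policy: str = "complete_case"
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Per-equation second-stage residual covariates.

    For equation *j* the residual covariates are the other four payers'
    first-stage errors.  ``complete_case`` keeps hospitals in *j*'s
    sample that have all four; ``zero_impute`` keeps all of *j*'s sample,
    filling holes with 0.  Returns ``{payer: frame}`` (index hospital,
    columns resid_<other payer>) plus a log of dropped/imputed counts.
    """
    if policy not in _POLICIES:
        raise ValueError(f"unknown missing-residual policy {policy!r}")
    out: dict[str, pd.DataFrame] = {}
    log: dict = {"policy": policy, "per_equation": {}}
    for payer in residual_table.columns:
        others = [p for p in residual_table.columns if p != payer]
        in_sample = residual_table[payer].notna()
        block = residual_table.loc[in_sample, others]
        if policy == "complete_case":
            complete = block.notna().all(axis=1)
            dropped = int((~complete).sum())
            block = block[complete]
            log["per_equation"][payer] = {"n": len(block), "dropped": dropped}
        else:
            n_imputed = int(block.isna().sum().sum())
            block = block.fillna(0.0)
            log["per_equation"][payer] = {"n": len(block), "imputed": n_imputed}
        if block.empty:
            raise ValueError(f"empty second-stage sample for payer {payer!r}")
        out[payer] = block.rename(columns=resid_col)
    return out, log


def stage_two(
    system_spec: SystemSpec,
    observations: pd.DataFrame,
    stage1_fits: dict[str, GammaGLMResults],
    augmented: dict[str, pd.DataFrame],
) -> dict[str, GammaGLMResults]:
    """Refit each equation with the other payers' residuals appended."""
    fits: dict[str, GammaGLMResults] = {}
    for payer in PAYERS:
        spec = system_spec.specs[payer]
        block = augmented[payer]
        sub = observations[(observations["payer"] == payer)
                           & observations["hospital_id"].isin(block.index)].copy()
        aligned = block.reindex(sub["hospital_id"])
        for col in block.columns:
            sub[col] = aligned[col].to_numpy()
        spec2 = ModelSpec(payer=payer, terms=list(spec.terms) + list(block.columns),
                          response=spec.response, state_mode=spec.state_mode)
        fits[payer] = GammaGLM.from_spec(spec2, sub).fit()
    return fits


@dataclass
class TelserSystemResults:
    """The fitted system across Telser stages.

    ``stage_fits[s]`` maps payer -> fit for stage ``s+1`` (so
    ``stage_fits[0]`` is the individual-equation stage).  Residual and
    alignment bookkeeping is kept so every second-stage design can be
    reconstructed and audited.
    """

    spec: SystemSpec
    stage_fits: list[dict[str, GammaGLMResults]]
    residual_table: pd.DataFrame
    alignment_log: dict
    change_norms: list[float] = field(default_factory=list)
    diverged: bool = False

    @property
    def stage1(self) -> dict[str, GammaGLMResults]:
        return self.stage_fits[0]

    @property
    def stage2(self) -> dict[str, GammaGLMResults] | None:
        return self.stage_fits[1] if len(self.stage_fits) > 1 else None

    @property
    def final(self) -> dict[str, GammaGLMResults]:
        return self.stage_fits[-1]

    def nobs(self, stage: int | None = None) -> dict[str, int]:
        fits = self.stage_fits[(stage or len(self.stage_fits)) - 1]
        return {p: f.nobs for p, f in fits.items()}

    def predict(self, observations: pd.DataFrame, stage: int | None = None) -> pd.DataFrame:
        """Predicted PCRs for new hospital×payer rows.

        Prediction uses the requested stage's coefficients with the
        residual covariates at their null value 0 (new hospitals have no
        first-stage errors).  Returns hospital_id, payer, predicted pcr.
        """
        fits = self.stage_fits[(stage or len(self.stage_fits)) - 1]
        frames = []
        for payer, fit in fits.items():
            sub = observations[observations["payer"] == payer]
            if sub.empty:
                continue
            spec = self.spec.specs[payer]
            if spec.state_mode == "fixed_effects":
                fitted_states = {n.split("state_id_", 1)[1]
                                 for n in fit.params.index if n.startswith("state_id_")}
                new = set(sub["state_id"].astype(str)) - fitted_states
                if new:
                    raise ValueError(
                        f"states {sorted(new)} were not in the training sample; "
                        "state fixed-effects models cannot predict for unseen states "
                        "— use state_mode='covariates'")
            frame = sub.copy()
            for p in PAYERS:
                col = resid_col(p)
                if col in fit.params.index:
                    frame[col] = 0.0
            if spec.state_mode == "fixed_effects":
                for name in fit.params.index:
                    if name.startswith("state_id_"):
                        frame[name] = (frame["state_id"].astype(str)
                                       == name.split("state_id_", 1)[1]).astype(float)
            pred = fit.predict(frame)
            frames.append(pd.DataFrame({"hospital_id": sub["hospital_id"].to_numpy(),
                                        "payer": payer, "predicted": pred}))
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        lines = [f"Telser system — {len(self.stage_fits)} stage(s), "
                 f"residual kind = {self.spec.residual_kind}, "
                 f"missing policy = {self.spec.missing_policy}", ""]
        for payer, fit in self.final.items():
            lines.append(fit.summary())
            lines.append("")
        if self.change_norms:
            lines.append("coefficient change norms between stages: "
                         + ", ".join(f"{v:.4g}" for v in self.change_norms))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON layout mirroring a published coefficient table: one
        column per payer with a substantive block, a first-stage-errors
        block, the intercept and N."""
        out = {"residual_kind": self.spec.residual_kind,
               "missing_policy": self.spec.missing_policy,
               "stages": len(self.stage_fits), "equations": {}}
        for payer, fit in self.final.items():
            tab = fit.wald_table()
            eq = {"covariates": {}, "first_stage_errors": {}, "intercept": None,
                  "n": int(fit.nobs), "aicc": fit.aicc}
            for name, row in tab.iterrows():
                cell = {"coef": float(row["coef"]), "se": float(row["se"]),
                        "p": float(row["p"]), "stars": row["stars"]}
                if name == "intercept":
                    eq["intercept"] = cell
                elif name.startswith("resid_"):
                    eq["first_stage_errors"][name.split("resid_", 1)[1]] = cell
                else:
                    eq["covariates"][name] = cell
            out["equations"][payer] = eq
        return out

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


class TelserSystem:
    """Model object for the five-equation PCR system.

    Parameters
    ----------
    observations : hospital×payer analysis table (one row per retained
        hospital-payer with all covariates).
    spec : :class:`SystemSpec`; defaults to the full specification with
        state covariates, response-scale residual feedback, two stages
        and complete-case alignment.
    """

    def __init__(self, observations: pd.DataFrame, spec: SystemSpec | None = None):
        self.observations = observations
        self.spec = spec or SystemSpec.default()

    def fit(self, stages: int | None = None,
            divergence_bound: float = 1e3) -> TelserSystemResults:
        """Run the staged estimation.

        Stage 1 fits each equation alone; stage ``s >= 2`` refits each
        equation with stage ``s-1`` residuals of the other equations as
        covariates.  Coefficient change norms between consecutive stages
        are recorded; growth of the coefficient norm beyond
        ``divergence_bound`` sets the ``diverged`` flag and warns.
        """
        stages = stages if stages is not None else self.spec.stages
        if stages < 1:
            raise ValueError("stages must be >= 1")
        obs = self.observations
        fits1, residual_table = stage_one(self.spec, obs)
        stage_fits = [fits1]
        alignment_log: dict = {}
        change_norms: list[float] = []
        diverged = False
        prev_fits = fits1
        for s in range(2, stages + 1):
            if s == 2:
                resid = residual_table
            else:
                # carry forward refined estimates of the *structural*
                # errors: residuals around the substantive part of the
                # previous stage's fit, residual covariates zeroed (raw
                # stage-2 residuals have the cross-equation correlation
                # already absorbed, so feeding them on would oscillate)
                cols = {}
                for payer in PAYERS:
                    fit = prev_fits[payer]
                    hosp = obs.loc[fit.model.row_index, "hospital_id"].to_numpy()
                    cols[payer] = pd.Series(
                        _structural_residuals(fit, self.spec.residual_kind),
                        index=hosp)
                resid = pd.DataFrame(cols)
            augmented, alignment_log = align_residuals(resid, self.spec.missing_policy)
            fits_s = stage_two(self.spec, obs, prev_fits, augmented)
            norm = _change_norm(prev_fits, fits_s)
            change_norms.append(norm)
            coef_norm = float(np.sqrt(sum(
                np.sum(f.params.to_numpy() ** 2) for f in fits_s.values())))
            if coef_norm > divergence_bound:
                diverged = True
                warnings.warn(
                    f"coefficient norm {coef_norm:.3g} exceeded the divergence bound "
                    f"at stage {s}", RuntimeWarning)
            stage_fits.append(fits_s)
            prev_fits = fits_s
        return TelserSystemResults(
            spec=self.spec, stage_fits=stage_fits, residual_table=residual_table,
            alignment_log=alignment_log, change_norms=change_norms, diverged=diverged)


def _structural_residuals(fit: GammaGLMResults, kind: str) -> np.ndarray:
    """Residuals around the substantive part of a fit.

    The fitted mean is recomputed with every ``resid_*`` coefficient
    zeroed, i.e. ``mu = exp(X_sub beta_sub)``, so the returned values
    estimate the equation's structural error rather than the leftover
    noise after cross-equation absorption.  For a first-stage fit this
    coincides with ``fit.resid(kind)``.
    """
    names = list(fit.params.index)
    keep = [j for j, n in enumerate(names) if not n.startswith("resid_")]
    X = fit.model.exog[:, keep]
    beta = fit.params.to_numpy()[keep]
    mu = np.exp(np.clip(X @ beta, -30, 30))
    y = fit.model.endog
    if kind == "response":
        return y - mu
    if kind == "pearson":
        return (y - mu) / mu
    if kind == "deviance":
        d2 = 2.0 * ((y - mu) / mu - np.log(y / mu))
        return np.sign(y - mu) * np.sqrt(np.maximum(d2, 0.0))
    raise ValueError(f"unknown residual kind {kind!r}")


def _change_norm(prev: dict[str, GammaGLMResults], new: dict[str, GammaGLMResults]) -> float:
    """L2 norm of the change in the substantive coefficients.

    Residual-term coefficients are excluded: the residual covariates are
    redefined at every stage, so their coefficients are not comparable
    across stages and would swamp the convergence signal.
    """
    total = 0.0
    for payer, fit in new.items():
        shared = [n for n in fit.params.index
                  if n in prev[payer].params.index and not n.startswith("resid_")]
        diff = fit.params[shared] - prev[payer].params[shared]
        total += float(np.sum(diff.to_numpy() ** 2))
    return float(np.sqrt(total))
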