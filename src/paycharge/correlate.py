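"""Pearson correlation of the cost-to-charge ratio with the five PCRs.

The sample is limited to hospitals for which *all* five PCRs lie
strictly between 0 and 1 (a stricter joint filter than the regressions,
which constrain only their own dependent variable).  Significance uses
the t-transform of r with n-2 degrees of freedom; stars are printed at
p < .05 (*) and p < .01 (**).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PAYERS

#: Canonical column order of the wide table.
VARIABLES = ("ccr",) + tuple(f"pcr_{p}" for p in PAYERS)


def pcr_wide(pcr_table: pd.DataFrame, ccrs: pd.DataFrame,
             value_col: str = "pcr", source: str = "actual") -> pd.DataFrame:
    """Pivot a long hospital×payer PCR table to one row per hospital with
    the CCR and five PCR columns.

    ``value_col`` selects which PCR feeds the analysis (``pcr`` for
    actual values, e.g. ``predicted`` for model output); the choice is
    recorded in a ``source`` column.
    """
    wide = pcr_table.pivot(index="hospital_id", columns="payer", values=value_col)
    wide = wide.rename(columns={p: f"pcr_{p}" for p in PAYERS}).reset_index()
    wide = wide.merge(ccrs, on="hospital_id", how="inner")
    wide["source"] = source
    return wide[["hospital_id", "source"] + list(VARIABLES)]


def joint_filter(wide: pd.DataFrame) -> pd.DataFrame:
    """Keep hospitals whose five PCRs are all present and strictly
    inside (0, 1)."""
    cols = [f"pcr_{p}" for p in PAYERS]
    vals = wide[cols]
    ok = vals.notna().all(axis=1) & (vals > 0).all(axis=1) & (vals < 1).all(axis=1)
    return wide[ok].copy()


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations with t-transform p-values."""

    n: int
    corr: pd.DataFrame
    pvalues: pd.DataFrame
    stars: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        rows = []
        names = list(self.corr.columns)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                rows.append({"var1": a, "var2": b,
                             "r": float(self.corr.loc[a, b]),
                             "p": float(self.pvalues.loc[a, b]),
                             "stars": self.stars.loc[a, b], "n": self.n})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {"n": self.n, "variables": list(self.corr.columns),
                "corr": self.corr.to_numpy().tolist(),
                "pvalues": self.pvalues.to_numpy().tolist(),
                "stars": self.stars.to_numpy().tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "CorrelationReport":
        names = d["variables"]
        return cls(n=int(d["n"]),
                   corr=pd.DataFrame(d["corr"], index=names, columns=names),
                   pvalues=pd.DataFrame(d["pvalues"], index=names, columns=names),
                   stars=pd.DataFrame(d["stars"], index=names, columns=names))

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def _corr_star(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson_matrix(filtered: pd.DataFrame, columns=None) -> CorrelationReport:
    """Pairwise Pearson r over the common filtered sample.

    Two-sided p-values come from ``t = r sqrt((n-2)/(1-r^2))`` with
    ``n-2`` degrees of freedom.  Requires at least 3 rows and positive
    variance in every column.
    """
    cols = list(columns) if columns is not None else [
        c for c in VARIABLES if c in filtered.columns]
    X = filtered[cols].to_numpy(dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 hospitals for correlations")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [c for c, s in zip(cols, sd) if s == 0]
        raise ValueError(f"zero-variance columns: {bad}")
    r = np.corrcoef(X, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    corr = pd.DataFrame(r, index=cols, columns=cols)
    pv = pd.DataFrame(p, index=cols, columns=cols)
    stars = pv.map(_corr_star)
    for c in cols:
        stars.loc[c, c] = ""
    return CorrelationReport(n=n, corr=corr, pvalues=pv, stars=stars)


def render_table(report: CorrelationReport) -> str:
    """Upper-triangular text rendering with significance stars."""
    names = list(report.corr.columns)
    width = max(len(n) for n in names) + 2
    header = " " * width + "".join(f"{n:>12}" for n in names)
    lines = [f"Pearson correlations (N = {report.n})", header]
    for i, a in enumerate(names):
        cells = []
        for j, b in enumerate(names):
            if j < i:
                cells.append(" " * 12)
            else:
                val = f"{report.corr.loc[a, b]:.2f}{report.stars.loc[a, b]}"
                cells.append(f"{val:>12}")
        lines.append(f"{a:<{width}}" + "".join(cells))
    lines.append("*p < .05, **p < .01")
    return "\n".join(lines)


def write_correlations(report: CorrelationReport, path) -> None:
    """Long-form CSV: var1, var2, r, p, stars, n."""
    report.to_long().to_csv(path, index=False)
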