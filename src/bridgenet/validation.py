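"""Covariate-adjusted regression validation of focal bridge edges.

For each (symptom, metabolite) pair, the metabolite (continuous, post-log
scale) is regressed on the symptom score (entered numerically, 0-3) under
seven nested covariate sets; every set additionally contains sex, age and
shipment batch.  The same ladder run on a second data wave provides a
consistency check (sign agreement of both-significant fits).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .variables import (
    CovariateTable,
    MixedDataMatrix,
    SpecificationError,
)

__all__ = ["COVARIATE_SETS", "run_covariate_ladder", "compare_waves",
           "RegressionReport"]

#: the seven covariate sets (sex, age and batch are always included)
COVARIATE_SETS: dict[str, tuple[str, ...]] = {
    "sex_age": (),
    "statin": ("statin_use",),
    "ad": ("ad_use",),
    "bmi": ("bmi",),
    "bmi_smoking": ("bmi", "smoking"),
    "bmi_smoking_ad": ("bmi", "smoking", "ad_use"),
    "bmi_smoking_ad_statin": ("bmi", "smoking", "ad_use", "statin_use"),
}

_BASE = ("sex", "age", "batch")


@dataclass
class RegressionReport:
    """Ladder results: one row per (pair, covariate set, wave)."""

    table: pd.DataFrame

    def row(self, symptom: str, metabolite: str, covariate_set: str,
            wave: str = "baseline") -> pd.Series:
        t = self.table
        m = ((t["symptom"] == symptom) & (t["metabolite"] == metabolite)
             & (t["covariate_set"] == covariate_set) & (t["wave"] == wave))
        sub = t[m]
        if len(sub) != 1:
            raise SpecificationError(
                f"no unique row for ({symptom}, {metabolite}, {covariate_set}, {wave})"
            )
        return sub.iloc[0]


def run_covariate_ladder(
    data: MixedDataMatrix,
    covariates: CovariateTable,
    pairs: list[tuple[str, str]],
    wave: str = "baseline",
    alpha: float = 0.05,
) -> RegressionReport:
    """OLS of metabolite on symptom score under the seven covariate sets.

    Complete-case per model: rows missing the pair columns or any covariate
    in the active set are dropped for that fit.  Asserts the nesting
    property (adding covariates never increases the residual sum of
    squares on a common sample).
    """
    if covariates.n != data.n:
        raise SpecificationError("covariate table not aligned with data")
    rows = []
    for symptom, metabolite in pairs:
        y_all = data.column(metabolite)
        x_all = data.column(symptom)
        if data.spec(symptom).is_categorical is False:
            raise SpecificationError(f"{symptom!r} is not a categorical symptom item")
        # common complete-case sample across the ladder, so RSS nesting holds
        all_covs = list(_BASE) + ["bmi", "smoking", "ad_use", "statin_use"]
        cov_vals = covariates.frame[all_covs].to_numpy(dtype=float)
        keep = (~np.isnan(y_all)) & (~np.isnan(x_all)) & (~np.isnan(cov_vals).any(axis=1))
        if np.ptp(x_all[keep]) == 0:
            raise SpecificationError(f"symptom column {symptom!r} is constant")
        prev_rss = None
        nested_chain = True
        for set_name, extra in COVARIATE_SETS.items():
            names = list(_BASE) + list(extra)
            X = np.column_stack(
                [x_all[keep]]
                + [covariates.frame[c].to_numpy(dtype=float)[keep] for c in names]
            )
            X = sm.add_constant(X, prepend=True)
            fit = sm.OLS(y_all[keep], X).fit()
            rss = float(fit.ssr)
            if nested_chain and prev_rss is not None and set(extra) >= prev_extra:
                assert rss <= prev_rss + 1e-8, "nesting property violated"
            prev_rss, prev_extra = rss, set(extra)
            rows.append({
                "symptom": symptom,
                "metabolite": metabolite,
                "covariate_set": set_name,
                "wave": wave,
                "coef": float(fit.params[1]),
                "se": float(fit.bse[1]),
                "pvalue": float(fit.pvalues[1]),
                "n": int(fit.nobs),
                "significant": bool(fit.pvalues[1] < alpha),
            })
    return RegressionReport(pd.DataFrame(rows))


def compare_waves(
    report_w1: RegressionReport, report_w2: RegressionReport
) -> pd.DataFrame:
    """Side-by-side coefficients across waves with sign-agreement flags.

    The overall consistency (``.attrs['consistency']``) is the fraction of
    (pair, set) fits that are significant in both waves with agreeing
    signs.
    """
    t1, t2 = report_w1.table, report_w2.table
    keys = ["symptom", "metabolite", "covariate_set"]
    if set(map(tuple, t1[keys].drop_duplicates().values)) != set(
        map(tuple, t2[keys].drop_duplicates().values)
    ):
        raise SpecificationError("wave reports cover different pairs/sets")
    merged = t1.merge(t2, on=keys, suffixes=("_w1", "_w2"))
    merged["sign_agrees"] = np.sign(merged["coef_w1"]) == np.sign(merged["coef_w2"])
    merged["both_significant"] = merged["significant_w1"] & merged["significant_w2"]
    merged["consistent"] = merged["sign_agrees"] & merged["both_significant"]
    out = merged[keys + ["coef_w1", "coef_w2", "pvalue_w1", "pvalue_w2",
                         "sign_agrees", "both_significant", "consistent"]]
    out.attrs["consistency"] = float(out["consistent"].mean())
    return out
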