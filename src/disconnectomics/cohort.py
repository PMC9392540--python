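"""Cohort-level linear models and summaries.

Ordinary least squares throughout (statsmodels): phase-group effect on
MoCA, lesion-load effect, a lesion-size outlier sensitivity refit, the
brain-score vs lesion-size association, and the impairment rate under the
conventional MoCA cutoff (scores below 26 count as impaired).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)

__all__ = [
    "LinearFit",
    "fit_group_model",
    "fit_lesionload_model",
    "outlier_sensitivity",
    "OutlierSensitivity",
    "brainscore_lesion_assoc",
    "impairment_rate",
    "flag_volume_outliers",
]

GROUP_LEVELS = ("acute", "subacute", "chronic")

# zero-residual / zero-effect guard, relative to the centered total SS
_SS_TOL = 1e-12


@dataclasses.dataclass
class LinearFit:
    """Plain container for an OLS fit (coefficient table + overall F)."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    fvalue: float
    f_pvalue: float
    df_resid: float
    nobs: int
    rsquared: float
    degenerate: bool = False
    collinear: bool = False
    dropped: list = dataclasses.field(default_factory=list)

    @classmethod
    def from_results(cls, res, dropped: list | None = None) -> "LinearFit":
        tss = float(res.centered_tss) if np.isfinite(res.centered_tss) else 0.0
        ess, ssr = float(res.ess), float(res.ssr)
        degenerate = False
        rsquared = float(res.rsquared) if tss > _SS_TOL else 0.0
        if ess <= _SS_TOL * max(tss, 1.0):
            # no explained variance at all: report F = 0 rather than 0/0
            fvalue, f_pvalue = 0.0, 1.0
        else:
            fvalue, f_pvalue = float(res.fvalue), float(res.f_pvalue)
            if ssr <= _SS_TOL * max(tss, 1.0):
                # perfect fit: t and F diverge; flag instead of reporting noise
                degenerate = True
        cond = float(np.linalg.cond(res.model.exog))
        return cls(
            params=res.params,
            bse=res.bse,
            tvalues=res.tvalues,
            pvalues=res.pvalues,
            fvalue=fvalue,
            f_pvalue=f_pvalue,
            df_resid=float(res.df_resid),
            nobs=int(res.nobs),
            rsquared=rsquared,
            degenerate=degenerate,
            collinear=cond > 1e12,
            dropped=dropped or [],
        )


def fit_group_model(tab: pd.DataFrame, covariates: tuple[str, ...] = ()) -> LinearFit:
    """OLS of MoCA on stroke-phase group (reference level: acute).

    With no covariates the model F is exactly the one-way ANOVA F for the
    group factor. Optional covariates can be added; the reported F is then
    the overall model F.
    """
    present = [g for g in GROUP_LEVELS if (tab["group"] == g).any()]
    dropped = [g for g in GROUP_LEVELS if g not in present]
    if dropped:
        log.info("group levels with no subjects dropped: %s", dropped)
    if len(present) < 2:
        raise ValueError("need at least 2 phase groups with subjects")
    sub = tab[tab["group"].isin(present)]
    if len(sub) <= len(present) + len(covariates):
        raise ValueError("too few subjects for the group model")
    ref = "acute" if "acute" in present else present[0]
    formula = f"moca ~ C(group, Treatment('{ref}'))"
    for cov in covariates:
        formula += f" + {cov}"
    res = smf.ols(formula, data=sub).fit()
    return LinearFit.from_results(res, dropped=dropped)


def fit_lesionload_model(tab: pd.DataFrame) -> LinearFit:
    """OLS of MoCA on total lesion volume and number of lesions."""
    if len(tab) <= 3:
        raise ValueError("need more than 3 subjects")
    res = smf.ols("moca ~ lesion_volume + n_lesions", data=tab).fit()
    fit = LinearFit.from_results(res)
    if fit.collinear:
        log.warning("lesion-load design is ill-conditioned; t-values unreliable")
    return fit


def flag_volume_outliers(tab: pd.DataFrame, z_threshold: float = 4.0) -> list:
    """Subjects whose log lesion volume is more than ``z_threshold`` SDs out.

    The log scale matches the heavy right tail of lesion-size
    distributions; the threshold-based rule flags every qualifying
    subject, not just the single most extreme one.
    """
    logv = np.log(tab["lesion_volume"].to_numpy(dtype=float))
    sd = logv.std(ddof=1)
    if sd == 0:
        return []
    z = (logv - logv.mean()) / sd
    return list(tab.index[np.abs(z) > z_threshold])


@dataclasses.dataclass
class OutlierSensitivity:
    fit_full: LinearFit
    fit_trimmed: LinearFit
    flagged: list


def outlier_sensitivity(
    tab: pd.DataFrame, rule=None, model=fit_lesionload_model
) -> OutlierSensitivity:
    """Refit a model with and without extreme-lesion-volume subjects.

    ``rule`` maps the table to a list of flagged row labels (default:
    :func:`flag_volume_outliers`); flagging more than 10% of the cohort is
    an error, since the check targets isolated extreme cases.
    """
    rule = rule or flag_volume_outliers
    flagged = list(rule(tab))
    if len(flagged) > 0.10 * len(tab):
        raise ValueError(
            f"outlier rule flagged {len(flagged)}/{len(tab)} subjects (> 10%)"
        )
    fit_full = model(tab)
    fit_trimmed = model(tab.drop(index=flagged)) if flagged else fit_full
    return OutlierSensitivity(fit_full=fit_full, fit_trimmed=fit_trimmed,
                              flagged=flagged)


def brainscore_lesion_assoc(tab: pd.DataFrame, rule=None) -> OutlierSensitivity:
    """OLS of PLS brain score on lesion volume, with and without flagged
    extreme-volume subjects; rows missing a brain score are dropped."""
    if "brain_score" not in tab.columns:
        raise ValueError("cohort table has no 'brain_score' column (join PLS first)")
    sub = tab.dropna(subset=["brain_score"])
    n_drop = len(tab) - len(sub)
    if n_drop:
        log.info("dropped %d subjects without brain scores", n_drop)

    def _fit(t: pd.DataFrame) -> LinearFit:
        res = smf.ols("brain_score ~ lesion_volume", data=t).fit()
        return LinearFit.from_results(res)

    return outlier_sensitivity(sub, rule=rule, model=_fit)


def impairment_rate(tab: pd.DataFrame, cutoff: int = 26) -> dict:
    """Proportion of subjects below the MoCA cutoff (strictly below:
    a score of exactly ``cutoff`` is not impaired)."""
    moca = tab["moca"].dropna()
    n = len(moca)
    if n == 0:
        raise ValueError("no MoCA scores available")
    n_impaired = int((moca < cutoff).sum())
    return {"rate": n_impaired / n, "n_impaired": n_impaired, "n": n,
            "cutoff": cutoff}
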