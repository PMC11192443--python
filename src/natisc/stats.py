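"""Mixed-effects model suite for Fisher-transformed ISCs.

All models share one recipe: Fisher z as response, condition type (or a
recoding of it) as the fixed effect under dummy coding with +M/-L as
the default reference level, and crossed random intercepts for some
subset of {fROI, participant, condition}.  Crossed intercepts are
encoded with statsmodels ``MixedLM`` variance components over a single
all-encompassing group, the standard statsmodels formulation of a
crossed design.  Fixed-effect p values are two-tailed Wald tests with
the normal approximation.

Coefficients are reported from REML fits; likelihood-ratio tests and
AIC comparisons always refit under ML.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "LMEFit",
    "fit_lme",
    "fit_condition_model",
    "fit_per_condition_model",
    "per_condition_suite",
    "fit_per_froi_model",
    "fit_interaction_model",
    "fdr_bh",
    "compare_models",
    "REFERENCE_TYPE",
]

REFERENCE_TYPE = "+M/-L"

_TERM_RE = re.compile(r"C\([^\[\]]*\)\[(?:T\.)?([^\]]+)\]")


def _pretty_term(name: str) -> str:
    """Strip patsy contrast wrapping: C(x, Treatment(...))[T.level] -> level."""
    out = _TERM_RE.sub(lambda m: m.group(1), name)
    return out


@dataclass
class LMEFit:
    """A fitted mixed model: term table plus fit diagnostics."""

    formula_id: str
    formula: str
    terms: pd.DataFrame  # columns: term, beta, se, p
    reference_level: str | None
    loglik: float
    aic: float
    n_params: int
    nobs: int
    fit_method: str  # "ML" | "REML" | "OLS"
    converged: bool
    singular: bool
    vc_estimates: dict = field(default_factory=dict)
    response_hash: int = 0

    def coef(self, term: str) -> tuple[float, float, float]:
        row = self.terms[self.terms["term"] == term]
        if row.empty:
            raise KeyError(f"term {term!r} not in fit (have {self.terms['term'].tolist()})")
        r = row.iloc[0]
        return float(r["beta"]), float(r["se"]), float(r["p"])

    def to_frame(self) -> pd.DataFrame:
        return self.terms.assign(formula_id=self.formula_id)


def _response_hash(y: np.ndarray) -> int:
    return hash(np.round(np.asarray(y, dtype=float), 12).tobytes())


def fit_lme(
    data: pd.DataFrame,
    fixed: str,
    vc_factors,
    formula_id: str,
    reference_level: str | None = None,
    reml: bool = True,
    response: str = "z",
) -> LMEFit:
    """Fit ``response ~ fixed`` with crossed random intercepts.

    ``vc_factors`` lists the grouping columns that receive a random
    intercept; a factor with fewer than 2 levels in ``data`` is dropped
    with a warning (its variance is unidentifiable).  Non-convergence
    is flagged on the result, never silent.
    """
    import statsmodels.api as sm

    data = data.reset_index(drop=True)
    vc = {}
    for f in vc_factors:
        if data[f].nunique() >= 2:
            vc[f] = f"0 + C({f})"
        else:
            warnings.warn(
                f"random factor {f!r} has a single level; dropped from the model",
                stacklevel=2,
            )
    formula = f"{response} ~ {fixed}"
    y = data[response].to_numpy(dtype=float)

    if not vc:  # no random structure left: ordinary least squares
        import statsmodels.formula.api as smf

        res = smf.ols(formula, data=data).fit()
        k = len(res.params) + 1
        terms = pd.DataFrame(
            {
                "term": [_pretty_term(t) for t in res.params.index],
                "beta": res.params.to_numpy(),
                "se": res.bse.to_numpy(),
                "p": res.pvalues.to_numpy(),
            }
        )
        return LMEFit(
            formula_id=formula_id,
            formula=formula,
            terms=terms,
            reference_level=reference_level,
            loglik=float(res.llf),
            aic=float(2 * k - 2 * res.llf),
            n_params=k,
            nobs=int(res.nobs),
            fit_method="OLS",
            converged=True,
            singular=False,
            response_hash=_response_hash(y),
        )

    model = sm.MixedLM.from_formula(
        formula, data=data, groups=np.ones(len(data)), vc_formula=vc, re_formula="0"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=reml, method=["powell", "lbfgs"], maxiter=2000)
    fe = res.fe_params
    se = res.bse[: len(fe)]
    pvals = res.pvalues[: len(fe)]
    k = len(fe) + len(res.vcomp) + 1  # fixed effects + variance components + residual
    loglik = float(res.llf)
    vc_names = list(model.exog_vc.names) if hasattr(model.exog_vc, "names") else list(vc)
    terms = pd.DataFrame(
        {
            "term": [_pretty_term(t) for t in fe.index],
            "beta": fe.to_numpy(),
            "se": np.asarray(se),
            "p": np.asarray(pvals),
        }
    )
    return LMEFit(
        formula_id=formula_id,
        formula=formula,
        terms=terms,
        reference_level=reference_level,
        loglik=loglik,
        aic=float(2 * k - 2 * loglik),
        n_params=k,
        nobs=int(len(data)),
        fit_method="REML" if reml else "ML",
        converged=bool(res.converged),
        singular=bool(np.any(res.vcomp < 1e-6)),
        vc_estimates=dict(zip(vc_names, np.asarray(res.vcomp, dtype=float))),
        response_hash=_response_hash(y),
    )


def _drop_rest(isc: pd.DataFrame) -> pd.DataFrame:
    return isc[isc["condition_type"] != "rest"]


def _treatment(column: str, reference: str) -> str:
    return f'C({column}, Treatment("{reference}"))'


def fit_condition_model(
    isc: pd.DataFrame, reference: str = REFERENCE_TYPE, reml: bool = True
) -> LMEFit:
    """The headline model: z ~ condition type + (1|fROI) + (1|participant) + (1|condition).

    Condition type is dummy coded with +M/-L as the reference level, so
    the intercept is the +M/-L mean and each remaining coefficient is a
    condition-type contrast against it.  With a single condition type
    present the model reduces to an intercept-only test against zero.
    """
    data = _drop_rest(isc)
    types = data["condition_type"].unique()
    if len(types) < 2:
        fixed = "1"
        reference = None
    else:
        if reference not in types:
            raise ValueError(f"reference level {reference!r} absent from data")
        fixed = _treatment("condition_type", reference)
    return fit_lme(
        data,
        fixed,
        vc_factors=["froi", "participant", "condition"],
        formula_id="condition_type",
        reference_level=reference,
        reml=reml,
    )


def _six_level_recode(isc: pd.DataFrame) -> pd.DataFrame:
    """Treat each +M/-L stimulus as its own condition type (six levels)."""
    data = _drop_rest(isc).copy()
    data["condition_type6"] = np.where(
        data["condition_type"] == REFERENCE_TYPE, data["condition"], data["condition_type"]
    )
    return data


def fit_per_condition_model(isc: pd.DataFrame, reference: str = "zero", reml: bool = True) -> LMEFit:
    """Six-level model testing each +M/-L stimulus against a reference.

    Each +M/-L stimulus becomes its own condition-type level (six levels
    with the paper-template design).  ``reference="zero"`` fits cell
    means (no intercept), so every coefficient is a test against the
    zero baseline; otherwise the named level (``"+M/+L"`` or
    ``"-M/-L"``) is the dummy-coding reference.  Random intercepts:
    fROI and participant.
    """
    data = _six_level_recode(isc)
    if reference == "zero":
        fixed = "0 + C(condition_type6)"
        ref = None
    else:
        if reference not in set(data["condition_type6"]):
            raise ValueError(f"reference level {reference!r} absent from recoded data")
        fixed = _treatment("condition_type6", reference)
        ref = reference
    return fit_lme(
        data,
        fixed,
        vc_factors=["froi", "participant"],
        formula_id=f"per_condition[{reference}]",
        reference_level=ref,
        reml=reml,
    )


def per_condition_suite(isc: pd.DataFrame, reml: bool = True):
    """Per-stimulus contrasts against zero, +M/+L, and -M/-L, with FDR.

    Returns ``(fits, summary)``: the three LMEFits keyed by reference,
    and a tidy table of the +M/-L-stimulus coefficients with p values
    FDR-corrected across the three reference comparisons per stimulus.
    """
    data = _drop_rest(isc)
    stimuli = sorted(data.loc[data["condition_type"] == REFERENCE_TYPE, "condition"].unique())
    fits = {ref: fit_per_condition_model(isc, reference=ref, reml=reml)
            for ref in ("zero", "+M/+L", "-M/-L")}
    rows = []
    for stim in stimuli:
        for ref, fit in fits.items():
            beta, se, p = fit.coef(stim)
            rows.append(
                {"condition": stim, "contrast": f"vs {ref}", "beta": beta, "se": se, "p": p}
            )
    summary = pd.DataFrame(rows)
    summary["p_fdr"] = np.nan
    for stim in stimuli:
        mask = summary["condition"] == stim
        summary.loc[mask, "p_fdr"] = fdr_bh(summary.loc[mask, "p"].tolist())
    return fits, summary


def fit_per_froi_model(isc: pd.DataFrame, reference: str = REFERENCE_TYPE, reml: bool = True) -> dict:
    """One condition-type model per fROI; FDR across fROIs within term.

    Each fROI's data are modeled with condition type as the fixed effect
    and participant and condition as random intercepts.  After fitting,
    each term's p values are Benjamini-Hochberg corrected across the
    fROIs (added as a ``p_fdr`` column on every fit's term table).
    """
    data = _drop_rest(isc)
    frois = sorted(data["froi"].unique())
    fits = {}
    for f in frois:
        sub = data[data["froi"] == f]
        types = sub["condition_type"].unique()
        fixed = _treatment("condition_type", reference) if len(types) > 1 else "1"
        fits[f] = fit_lme(
            sub,
            fixed,
            vc_factors=["participant", "condition"],
            formula_id=f"per_froi[{f}]",
            reference_level=reference if len(types) > 1 else None,
            reml=reml,
        )
    # correct each term family across fROIs
    all_terms = fits[frois[0]].terms["term"].tolist()
    for term in all_terms:
        ps = [fits[f].coef(term)[2] for f in frois]
        adj = fdr_bh(ps)
        for f, q in zip(frois, adj):
            fit = fits[f]
            if "p_fdr" not in fit.terms.columns:
                fit.terms["p_fdr"] = np.nan
            fit.terms.loc[fit.terms["term"] == term, "p_fdr"] = q
    return fits


def fit_interaction_model(isc: pd.DataFrame, reference: str = REFERENCE_TYPE, reml: bool = True) -> LMEFit:
    """Region-by-condition-type interaction model.

    z ~ 0 + fROI + fROI:condition_type + (1|condition) + (1|participant):
    no global intercept, so each fROI gets its own intercept (its +M/-L
    mean) plus per-fROI condition-type contrasts.
    """
    data = _drop_rest(isc)
    fixed = f"0 + C(froi) + C(froi):{_treatment('condition_type', reference)}"
    return fit_lme(
        data,
        fixed,
        vc_factors=["condition", "participant"],
        formula_id="froi_x_condition_type",
        reference_level=reference,
        reml=reml,
    )


def fdr_bh(pvals, n: int | None = None) -> list:
    """Benjamini-Hochberg step-up adjusted p values.

    ``n`` defaults to ``len(pvals)`` but may be larger (correction
    against a wider family).  Adjusted values are monotone in the input
    order statistics and capped at 1.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p) if n is None else int(n)
    if m < len(p):
        raise ValueError("family size n cannot be smaller than the number of p values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, len(p) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out.tolist()


def compare_models(fit_a: LMEFit, fit_b: LMEFit, nested: bool) -> dict:
    """Likelihood-ratio test (nested) or AIC difference (non-nested).

    For a nested comparison, ``fit_b`` must extend ``fit_a``:
    chi2 = 2 (loglik_b - loglik_a) on df = Delta(params); both fits must
    be ML (REML log-likelihoods are not comparable across fixed-effect
    structures).  Both fits must be on identical rows.
    """
    if fit_a.nobs != fit_b.nobs or fit_a.response_hash != fit_b.response_hash:
        raise ValueError("model comparison requires fits on identical rows")
    if nested:
        for f in (fit_a, fit_b):
            if f.fit_method == "REML":
                raise ValueError("likelihood-ratio test requires ML fits; refit with reml=False")
        chi2 = 2.0 * (fit_b.loglik - fit_a.loglik)
        df = fit_b.n_params - fit_a.n_params
        if df < 0:
            raise ValueError("nested comparison requires fit_b to have at least as many parameters")
        p = 1.0 if df == 0 else float(sps.chi2.sf(max(chi2, 0.0), df))
        return {"chi2": float(chi2), "df": int(df), "p": p}
    return {"delta_aic": float(fit_b.aic - fit_a.aic)}
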