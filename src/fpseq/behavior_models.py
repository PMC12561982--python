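"""Mixed-effects reaction-time models over hazard regressors.

Reaction times following FP2 are regressed on the unconditional hazard HF_U,
the conditional hazard HF_C, and their product, with random intercepts for
participant and for the FP1 duration category (which absorbs the asymmetric
sequential effect); FP1 reaction times are regressed on HF_U with a
participant intercept only.  Fitting is delegated to statsmodels MixedLM
(REML for estimates; a maximum-likelihood refit supplies AIC/BIC for model
comparison).  Regressor construction, model comparison, conditional R^2 and
the sequential-effect summary are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from . import paradigm
from .hazard import HazardSeries

#: Fixed-term names and the regressor columns they map to.
TERM_COLUMNS = {"HF_U": "hf_u", "HF_C": "hf_c", "HF_U:HF_C": "hf_uc"}

#: The four FP2 model specifications, in increasing complexity.
FP2_MODELS: dict[str, tuple[str, ...]] = {
    "HF_U": ("HF_U",),
    "HF_C": ("HF_C",),
    "HF_U+HF_C": ("HF_U", "HF_C"),
    "HF_U+HF_C+HF_U:HF_C": ("HF_U", "HF_C", "HF_U:HF_C"),
}


def build_regressor_table(
    trials: pd.DataFrame,
    hz_u: HazardSeries,
    hz_c: dict[tuple[int, str], HazardSeries],
) -> pd.DataFrame:
    """Per-trial regressor rows for the mixed models.

    One row per non-false-alarm trial with a recorded reaction time.  FP2
    rows join the conditional hazard of their block given the FP1 category;
    the interaction column is the exact elementwise product.  Only false
    alarms are excluded — outliers are retained.
    """
    ok = (~trials["false_alarm"]) & trials["rt_s"].notna()
    t = trials[ok].copy()
    fp = t["foreperiod_s"].to_numpy()
    hf_u = np.asarray(hz_u.value_at(np.round(fp, 2)))
    is_fp2 = (t["position"] == "FP2").to_numpy()

    hf_c = np.full(len(t), np.nan)
    fp1_cat = np.array([""] * len(t), dtype=object)
    if is_fp2.any():
        blocks = t["block"].to_numpy()
        ctx_s = t["fp1_context_s"].to_numpy()
        fp1_cat[is_fp2] = [paradigm.duration_category(c) for c in ctx_s[is_fp2]]
        joined = np.zeros(len(t), dtype=bool)
        for (block, category), hz in hz_c.items():
            sel = is_fp2 & (blocks == block) & (fp1_cat == category)
            if sel.any():
                hf_c[sel] = hz.value_at(np.round(fp[sel], 2))
                joined[sel] = True
        missing = t.index[is_fp2 & ~joined]
        if len(missing):
            raise ValueError(f"unjoinable fp1_context for rows {missing[:10].tolist()}")

    out = pd.DataFrame({
        "participant": t["participant_id"].to_numpy(),
        "block": t["block"].to_numpy(),
        "position": t["position"].to_numpy(),
        "rt": t["rt_s"].to_numpy(),
        "log_rt": np.log(t["rt_s"].to_numpy()),
        "hf_u": hf_u,
        "hf_c": hf_c,
        "hf_uc": hf_u * hf_c,
        "fp1_category": fp1_cat,
    })
    return out


@dataclass(frozen=True)
class FitResult:
    """Summary of one mixed-model fit (estimates on the response scale)."""

    label: str
    terms: tuple[str, ...]
    estimates: dict[str, float]
    se: dict[str, float]
    std_beta: dict[str, float]
    tvalues: dict[str, float]
    pvalues: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    aic: float
    bic: float
    llf_ml: float
    n_obs: int
    df_fixed: int
    re_variances: dict[str, float]
    resid_variance: float
    conditional_r2: float
    converged: bool
    singular: bool
    response_scale: str = "raw"

    def to_dict(self) -> dict:
        return {
            "label": self.label, "terms": list(self.terms),
            "estimates": self.estimates, "se": self.se, "std_beta": self.std_beta,
            "t": self.tvalues, "p": self.pvalues,
            "conf_int": {k: list(v) for k, v in self.conf_int.items()},
            "aic": self.aic, "bic": self.bic, "llf_ml": self.llf_ml,
            "n_obs": self.n_obs, "re_variances": self.re_variances,
            "resid_variance": self.resid_variance,
            "conditional_r2": self.conditional_r2,
            "converged": self.converged, "singular": self.singular,
            "response_scale": self.response_scale,
        }


def conditional_r2_components(var_fixed: float, var_random: float, var_resid: float) -> float:
    """Conditional pseudo-R^2: (fixed + random) / (fixed + random + residual)."""
    total = var_fixed + var_random + var_resid
    if total <= 0 or not np.isfinite(total):
        raise ValueError("variance components must be finite and positive in total")
    return (var_fixed + var_random) / total


def conditional_r2(fit: FitResult) -> float:
    """Conditional R^2 of a fitted model from its stored variance components."""
    return conditional_r2_components(
        getattr(fit, "_var_fixed"),
        sum(fit.re_variances.values()),
        fit.resid_variance,
    )


def fit_mixed_model(
    table: pd.DataFrame,
    fixed_terms: Sequence[str] = ("HF_U", "HF_C", "HF_U:HF_C"),
    random_terms: Sequence[str] = ("participant", "fp1_category"),
    response_scale: str = "raw",
    information_criteria: bool = True,
    reml: bool = True,
    label: str | None = None,
    start_params=None,
) -> FitResult:
    """Fit one random-intercept mixed model via statsmodels MixedLM (REML).

    Crossed participant and FP1-category intercepts are fitted as independent
    variance components; a boundary (zero) variance for the 2-level category
    factor is tolerated and flagged as ``singular`` rather than failing.
    AIC/BIC come from a maximum-likelihood refit.  p values are large-sample
    Wald tests.
    """
    if len(table) == 0:
        raise ValueError("empty regressor table")
    fixed_terms = tuple(fixed_terms)
    for term in fixed_terms:
        if term not in TERM_COLUMNS:
            raise ValueError(f"unknown fixed term {term!r}")
    y = table["log_rt" if response_scale == "log" else "rt"].to_numpy()
    cols = [TERM_COLUMNS[t] for t in fixed_terms]
    x = table[cols].to_numpy()
    if np.isnan(x).any():
        raise ValueError("NaN regressor values for the requested terms")
    exog = sm.add_constant(x, has_constant="add")
    names = ["(Intercept)", *fixed_terms]

    random_terms = tuple(random_terms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if random_terms == ("participant",):
            model = sm.MixedLM(y, exog, groups=table["participant"].to_numpy())
        else:
            # crossed intercepts as variance components on a single group,
            # with indicator matrices built directly (no formula machinery)
            from statsmodels.regression.mixed_linear_model import VCSpec

            vc_names, vc_colnames, vc_mats = [], [], []
            for term in random_terms:
                if term not in ("participant", "fp1_category"):
                    raise ValueError(f"unknown random term {term!r}")
                levels, codes = np.unique(table[term].to_numpy(), return_inverse=True)
                mat = np.zeros((len(y), len(levels)))
                mat[np.arange(len(y)), codes] = 1.0
                vc_names.append(term)
                vc_colnames.append([[str(l) for l in levels]])
                vc_mats.append([mat])
            if not vc_names:
                raise ValueError("at least one random intercept is required")
            model = sm.MixedLM(
                y, exog, groups=np.ones(len(y)),
                exog_vc=VCSpec(vc_names, vc_colnames, vc_mats),
            )
        res = model.fit(reml=reml, method="lbfgs", start_params=start_params)
        singular = bool(np.any(np.asarray(res.vcomp if hasattr(res, "vcomp") else []) <= 1e-12))
        if random_terms == ("participant",):
            singular = bool(np.asarray(res.cov_re).min() <= 1e-12)
        aic = bic = llf_ml = np.nan
        if information_criteria:
            res_ml = res if not reml else model.fit(
                reml=False, method="lbfgs", start_params=res.params_object
            )
            k = res_ml.k_fe + res_ml.k_re2 + res_ml.k_vc + 1  # + residual variance
            llf_ml = float(res_ml.llf)
            aic = -2 * llf_ml + 2 * k
            bic = -2 * llf_ml + np.log(len(y)) * k

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params = np.asarray(res.fe_params)
        se = np.asarray(res.bse_fe)
    tvals = params / se
    pvals = 2 * stats.norm.sf(np.abs(tvals))
    ci = np.column_stack([params - 1.96 * se, params + 1.96 * se])

    ordered = list(zip(names, params, se, tvals, pvals, ci))
    if random_terms == ("participant",):
        re_var = {"participant": float(np.asarray(res.cov_re)[0, 0])}
    else:
        re_var = {
            name: float(v) for name, v in zip(model.exog_vc.names, res.vcomp)
        }
    fitted_fixed = exog @ params

    var_fixed = float(np.var(fitted_fixed))
    var_random = float(sum(re_var.values()))
    var_resid = float(res.scale)
    con_r2 = conditional_r2_components(var_fixed, var_random, var_resid)

    sd_y = y.std()
    estimates, ses, stds, ts, ps, cis = {}, {}, {}, {}, {}, {}
    data_cols = {"(Intercept)": np.ones(len(y))}
    for term, col in TERM_COLUMNS.items():
        if term in fixed_terms:
            data_cols[term] = table[col].to_numpy()
    for name, est, s, tv, pv, c in ordered:
        estimates[name] = float(est)
        ses[name] = float(s)
        ts[name] = float(tv)
        ps[name] = float(pv)
        cis[name] = (float(c[0]), float(c[1]))
        if name == "(Intercept)":
            stds[name] = np.nan
        else:
            stds[name] = float(est * data_cols[name].std() / sd_y)

    result = FitResult(
        label=label or "+".join(fixed_terms),
        terms=fixed_terms,
        estimates=estimates, se=ses, std_beta=stds, tvalues=ts, pvalues=ps,
        conf_int=cis, aic=float(aic), bic=float(bic), llf_ml=float(llf_ml),
        n_obs=len(y), df_fixed=len(fixed_terms) + 1,
        re_variances=re_var, resid_variance=var_resid,
        conditional_r2=con_r2,
        converged=bool(res.converged), singular=singular,
        response_scale=response_scale,
    )
    object.__setattr__(result, "_var_fixed", var_fixed)
    object.__setattr__(result, "_start_params", res.params_object)  # warm starts
    return result


@dataclass(frozen=True)
class ModelComparison:
    ranking_aic: tuple[str, ...]
    ranking_bic: tuple[str, ...]
    table: pd.DataFrame
    lr_tests: dict[str, dict]


def compare_models(fits: Sequence[FitResult]) -> ModelComparison:
    """Rank nested model fits by AIC/BIC and run likelihood-ratio tests.

    Each reduced model is tested against the richest model (most fixed
    terms) with a chi-square likelihood-ratio test on the ML likelihoods.
    """
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) != 1:
        raise ValueError(f"fits use different observation counts: {sorted(n_obs)}")
    full = max(fits, key=lambda f: len(f.terms))
    rows = []
    lr = {}
    for f in fits:
        rows.append({
            "model": f.label, "aic": f.aic, "bic": f.bic,
            "conditional_r2": f.conditional_r2, "n_obs": f.n_obs,
        })
        if f is not full:
            if not set(f.terms) <= set(full.terms):
                raise ValueError(f"model {f.label!r} is not nested in {full.label!r}")
            lr_stat = 2 * (full.llf_ml - f.llf_ml)
            df = len(full.terms) - len(f.terms)
            lr[f.label] = {
                "lr_stat": float(lr_stat), "df": df,
                "p": float(stats.chi2.sf(max(lr_stat, 0.0), df)),
            }
    table = pd.DataFrame(rows)
    by_aic = tuple(table.sort_values("aic")["model"])
    by_bic = tuple(table.sort_values("bic")["model"])
    return ModelComparison(by_aic, by_bic, table, lr)


def fit_fp2_model_set(
    table: pd.DataFrame,
    response_scale: str = "raw",
    models: dict[str, tuple[str, ...]] | None = None,
) -> dict[str, FitResult]:
    """Fit the four FP2 models on identical rows (FP2, complete regressors)."""
    fp2 = table[(table["position"] == "FP2") & table["hf_c"].notna()]
    fits = {}
    for lab, terms in (models or FP2_MODELS).items():
        fits[lab] = fit_mixed_model(
            fp2, terms, ("participant", "fp1_category"), response_scale, label=lab
        )
    return fits


def sequential_effect_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean FP2 reaction time by sequence type within each block.

    The asymmetric sequential effect shows as slower responses after a longer
    preceding foreperiod (LS slower than SS); cells absent from a block's
    design are omitted.
    """
    fp2 = trials[
        (trials["position"] == "FP2") & (~trials["false_alarm"]) & trials["rt_s"].notna()
    ].copy()
    seq_type = (
        fp2["fp1_context_s"].map(paradigm.duration_category)
        + fp2["foreperiod_s"].map(paradigm.duration_category)
    )
    fp2["seq_type"] = seq_type
    out = (
        fp2.groupby(["block", "seq_type"])["rt_s"]
        .agg(mean_rt="mean", sd_rt="std", n="count")
        .reset_index()
    )
    return out


def exclude_outliers(table: pd.DataFrame, threshold_sd: float = 2.5) -> pd.DataFrame:
    """Optionally drop reaction times beyond +/- threshold_sd of each
    participant's mean (outliers are retained by default everywhere else;
    this reproduces the sensitivity analysis that removes them)."""
    def keep(group: pd.DataFrame) -> pd.DataFrame:
        rt = group["rt"]
        z = (rt - rt.mean()) / (rt.std(ddof=1) or np.inf)
        return group[np.abs(z) <= threshold_sd]

    return (
        table.groupby("participant", group_keys=False)[table.columns]
        .apply(keep)
        .reset_index(drop=True)
    )
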