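"""Nested multilevel models of phase-prediction accuracy.

Predictions are nested — records within individuals within datasets — so
accuracy is modelled with linear mixed-effects models fitted by maximum
likelihood, and nested models are compared with likelihood-ratio tests.
Three presets mirror the analysis design:

* null:         accuracy ~ 1            + (1 | dataset) + (1 | dataset:individual)
* base:         accuracy ~ state        + (1 | dataset) + (1 | dataset:individual)
* intermediate: accuracy ~ state*power  + (power | dataset) + (power | dataset:individual)
* full:         accuracy ~ state*power*snr
                + (power*snr | dataset) + (power*snr | dataset:individual)

Accuracy is scaled to 0-100 before fitting so coefficients read in
percentage points of the 180-degree half cycle.  Covariates enter
unstandardized ("per unit increase" semantics).  Random effects use an
unstructured covariance at the dataset level; individual-within-dataset
effects are independent variance components.  On non-convergence the
dataset-level slopes fall back to independent (diagonal) components, and
the result records the fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

from .containers import ValidationError

_STATE_TERM = "C(state, Treatment('EC'))"

#: canonical report order of the full model's 12 terms
FULL_MODEL_TERMS = [
    "Intercept (state EC)", "Power", "StatusEO", "StatusTask", "SNR",
    "Power:StatusEO", "Power:StatusTask", "Power:SNR",
    "StatusEO:SNR", "StatusTask:SNR",
    "Power:StatusEO:SNR", "Power:StatusTask:SNR",
]


@dataclass(frozen=True)
class ModelSpec:
    name: str
    fixed: str                      # patsy RHS of the fixed part
    dataset_re: str = "1"           # dataset-level random-effects formula
    individual_terms: tuple = ("1",)  # individual-level variance components


def null_model() -> ModelSpec:
    return ModelSpec("null", "1")


def base_model() -> ModelSpec:
    return ModelSpec("base", _STATE_TERM)


def intermediate_model() -> ModelSpec:
    return ModelSpec("intermediate", f"{_STATE_TERM} * power",
                     dataset_re="1 + power", individual_terms=("1", "power"))


def full_model() -> ModelSpec:
    return ModelSpec("full", f"{_STATE_TERM} * power * snr",
                     dataset_re="1 + power + snr + power:snr",
                     individual_terms=("1", "power", "snr", "power:snr"))


@dataclass
class FitResult:
    spec: ModelSpec
    table: pd.DataFrame          # term, coef, se, t, p, ci_low, ci_high
    loglik: float
    n_obs: int
    df_params: int               # fixed + covariance + residual parameters
    converged: bool
    fallback_diagonal: bool = False
    _model: object = field(default=None, repr=False, compare=False)
    _result: object = field(default=None, repr=False, compare=False)


@dataclass
class LRTResult:
    chi2: float
    df: int
    p: float


def _prepare(records: pd.DataFrame) -> pd.DataFrame:
    req = {"accuracy", "state", "dataset_id", "individual_id"}
    missing = req - set(records.columns)
    if missing:
        raise ValidationError(f"records missing columns {sorted(missing)}")
    df = records.copy()
    df["accuracy_pct"] = df["accuracy"].astype(float) * 100.0
    if "inst_power" in df.columns:
        df["power"] = df["inst_power"].astype(float)
    if "snr_db" in df.columns:
        df["snr"] = df["snr_db"].astype(float)
    df["indiv_uid"] = df["dataset_id"].astype(str) + ":" + df["individual_id"].astype(str)
    if df["dataset_id"].nunique() < 2:
        raise ValidationError("need records from at least 2 datasets")
    return df


_TERM_PRIORITY = {"Power": 0, "StatusEO": 1, "StatusTask": 1, "SNR": 2}


def _clean_term(name: str) -> str:
    name = name.replace(f"{_STATE_TERM}[T.EO]", "StatusEO")
    name = name.replace(f"{_STATE_TERM}[T.task]", "StatusTask")
    name = name.replace("power", "Power").replace("snr", "SNR")
    if name == "Intercept":
        return "Intercept (state EC)"
    parts = name.split(":")
    if len(parts) > 1:  # canonical factor order inside interactions
        parts = sorted(parts, key=lambda p: _TERM_PRIORITY.get(p, 9))
        name = ":".join(parts)
    return name


def _vc_formula(terms) -> dict:
    vc = {}
    for t in terms:
        key = "indiv" if t == "1" else "indiv_" + t.replace(":", "_")
        rhs = "0 + C(indiv_uid)" if t == "1" else f"0 + C(indiv_uid):{t}"
        vc[key] = rhs
    return vc


def _do_fit(df, spec: ModelSpec, dataset_re: str, start_params=None):
    model = smf.mixedlm(f"accuracy_pct ~ {spec.fixed}", df,
                        groups=df["dataset_id"], re_formula=dataset_re,
                        vc_formula=_vc_formula(spec.individual_terms))
    import warnings
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kwargs = {} if start_params is None else {"start_params": start_params}
        res = model.fit(reml=False, maxiter=200, **kwargs)
    return model, res


def fit_model(records: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Maximum-likelihood mixed-model fit of the accuracy records.

    Coefficients are reported in accuracy percentage points with
    normal-approximation 95% confidence intervals (coef +/- 1.96 SE) and
    two-sided t tests on residual degrees of freedom.
    """
    df = _prepare(records)
    fallback = False
    model, res = _do_fit(df, spec, spec.dataset_re)
    if not res.converged and spec.dataset_re != "1":
        # diagonal fallback: dataset slopes become independent components
        slope_terms = [t.strip() for t in spec.dataset_re.split("+")
                       if t.strip() not in ("", "1")]
        diag_spec = ModelSpec(spec.name, spec.fixed, "1",
                              tuple(spec.individual_terms) +
                              tuple("ds_" + t for t in slope_terms))
        vc = _vc_formula(spec.individual_terms)
        for t in slope_terms:
            vc["dataset_" + t.replace(":", "_")] = f"0 + {t}"
        model = smf.mixedlm(f"accuracy_pct ~ {spec.fixed}", df,
                            groups=df["dataset_id"], re_formula="1",
                            vc_formula=vc)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=False, maxiter=200)
        fallback = True

    return _build_fit_result(model, res, spec, len(df), fallback)


def _build_fit_result(model, res, spec: ModelSpec, n: int,
                      fallback: bool) -> FitResult:
    fe = res.fe_params
    se = res.bse_fe
    k_fe = len(fe)
    df_resid = max(n - k_fe, 1)
    tvals = fe / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    table = pd.DataFrame({
        "term": [_clean_term(t) for t in fe.index],
        "coef": fe.to_numpy(),
        "se": se.to_numpy(),
        "t": tvals.to_numpy(),
        "p": pvals,
        "ci_low": fe.to_numpy() - 1.96 * se.to_numpy(),
        "ci_high": fe.to_numpy() + 1.96 * se.to_numpy(),
    })
    k_re = model.k_re
    df_params = k_fe + k_re * (k_re + 1) // 2 + model.k_vc + 1
    return FitResult(spec=spec, table=table, loglik=float(res.llf), n_obs=n,
                     df_params=df_params, converged=bool(res.converged),
                     fallback_diagonal=fallback, _model=model, _result=res)


def likelihood_ratio_test(fit_small: FitResult, fit_big: FitResult) -> LRTResult:
    """chi2 = 2 * (ll_big - ll_small), df = parameter-count difference.

    For nested models the larger model's maximum likelihood can never be
    below the smaller one's; when the optimizer nevertheless stalled there,
    the larger model is re-optimized starting from the smaller model's
    solution (possible whenever the two share their random-effects
    structure) and ``fit_big`` is updated in place.
    """
    df = fit_big.df_params - fit_small.df_params
    if df < 0:
        raise ValidationError("models are not nested (df difference negative)")
    if (fit_big.loglik < fit_small.loglik - 1e-8
            and fit_big._model is not None and fit_small._result is not None
            and fit_big._model.k_re == fit_small._model.k_re
            and fit_big._model.k_vc == fit_small._model.k_vc):
        import warnings
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_big._model.fit(reml=False, maxiter=200,
                                     start_params=fit_small._result.params_object)
        if np.isfinite(res.llf) and res.llf > fit_big.loglik:
            better = _build_fit_result(fit_big._model, res, fit_big.spec,
                                       fit_big.n_obs, fit_big.fallback_diagonal)
            fit_big.table = better.table
            fit_big.loglik = better.loglik
            fit_big.converged = better.converged
            fit_big._result = res
    chi2 = max(0.0, 2.0 * (fit_big.loglik - fit_small.loglik))
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return LRTResult(chi2=float(chi2), df=int(df), p=p)


def significance_report(fit: FitResult, order=None) -> pd.DataFrame:
    """Coefficient table with the p < 0.05 significance flag applied
    (strict inequality).  ``order`` optionally imposes a canonical row
    order such as :data:`FULL_MODEL_TERMS`."""
    table = fit.table.copy()
    table["significant"] = table["p"] < 0.05
    if order is not None:
        table["__o"] = table["term"].map({t: i for i, t in enumerate(order)})
        table = table.sort_values("__o").drop(columns="__o").reset_index(drop=True)
    return table


def render_report(fit: FitResult) -> str:
    """Plain-text coefficient report (significant rows marked with *)."""
    order = FULL_MODEL_TERMS if fit.spec.name == "full" else None
    tab = significance_report(fit, order)
    lines = [f"model: {fit.spec.name}   n={fit.n_obs}   logLik={fit.loglik:.1f}"
             f"   converged={fit.converged}"
             + ("   (diagonal RE fallback)" if fit.fallback_diagonal else "")]
    lines.append(f"{'term':<28}{'coef':>10}{'SE':>9}{'t':>9}{'p':>11}")
    for r in tab.itertuples():
        star = "*" if r.significant else " "
        lines.append(f"{r.term:<28}{r.coef:>9.2f}%{r.se:>8.2f}%{r.t:>9.2f}"
                     f"{r.p:>11.2g}{star}")
    return "\n".join(lines)


def simulate_accuracy_records(n_datasets: int = 15, n_individuals: int = 6,
                              n_records: int = 25, intercept_pct: float = 76.3,
                              eo_effect: float = -2.03, task_effect: float = -2.78,
                              power_slope: float = 0.0, sd_dataset: float = 0.8,
                              sd_individual: float = 1.2, sd_resid: float = 10.0,
                              rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Hierarchical accuracy data with known effects, for recovery checks.

    Datasets cycle through the EC / EO / task states (each dataset holds a
    single state, as in multi-dataset pooling); individuals are nested in
    datasets.  The instantaneous-power covariate is gamma-distributed with
    unit mean.  Accuracy is returned as a fraction.
    """
    rng = np.random.default_rng(rng)
    states = ["EC", "EO", "task"]
    effects = {"EC": 0.0, "EO": eo_effect, "task": task_effect}
    rows = []
    for d in range(n_datasets):
        state = states[d % 3]
        u_d = rng.normal(0.0, sd_dataset)
        for i in range(n_individuals):
            u_i = rng.normal(0.0, sd_individual)
            power = rng.gamma(2.0, 0.5, size=n_records)
            eps = rng.normal(0.0, sd_resid, size=n_records)
            pct = (intercept_pct + effects[state] + u_d + u_i
                   + power_slope * power + eps)
            for k in range(n_records):
                rows.append((f"ds{d:02d}", f"s{i:02d}", state,
                             pct[k] / 100.0, power[k], 0.0))
    return pd.DataFrame(rows, columns=["dataset_id", "individual_id", "state",
                                       "accuracy", "inst_power", "snr_db"])
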