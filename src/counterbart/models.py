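"""Variable preparation and trial-level models of emotion change.

The core model regresses standardized emotion-change ratings on
information seeking (effect coded, -1 = not sought / +1 = sought), pump
value (sample-standardized, then mean-centered within participants), and
missed opportunity (raw scale, mean-centered within participants), with a
participant random intercept and uncorrelated random slopes for every
trial-level predictor (REML).  Step 1 holds the main effects; Step 2 adds
the two interactions with information seeking.  Singular fits are refit
after dropping random slopes in a fixed order (interactions first), and
flagged.  Inference is Wald-z throughout, matching the z statistics the
per-experiment results feed into the meta-analytic layer.

Also here: simple slopes from a Step-2 fit, Welch's t test with Cohen's d
for the one-shot replication's group contrast, and the replication's OLS
interaction model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .task import Outcome

__all__ = [
    "CoefStats",
    "FitResult",
    "prepare_variables",
    "fit_emotion_model",
    "fixed_effects_at_zero_variance",
    "simple_slopes",
    "welch_test",
    "replication_interaction_model",
]

COEF_IS = "IS"
COEF_PV = "PV_c"
COEF_MO = "MO_c"
COEF_IS_PV = "IS:PV_c"
COEF_IS_MO = "IS:MO_c"

#: random slopes eligible for dropping on singular fits, interactions first,
#: then pump value, missed opportunity, information seeking; never the intercept
SLOPE_DROP_ORDER = [COEF_IS_PV, COEF_IS_MO, COEF_PV, COEF_MO, COEF_IS]

_SINGULAR_TOL = 1e-6


class CoefStats(NamedTuple):
    b: float
    se: float
    z: float
    p: float


@dataclass
class FitResult:
    """Named coefficients and random-effect variances from one model fit."""

    coefficients: dict[str, CoefStats]
    cov_fixed: pd.DataFrame
    re_var: dict[str, float]
    singular_fit: bool
    dropped_slopes: list[str]
    n_obs: int
    n_participants: int
    method: str
    experiment_id: str = ""

    def coef(self, name: str) -> CoefStats:
        if name not in self.coefficients:
            raise KeyError(f"no coefficient named {name!r}; have {list(self.coefficients)}")
        return self.coefficients[name]


def prepare_variables(
    trials: pd.DataFrame,
    trial_subset: Literal["bank", "bust"] = "bank",
) -> pd.DataFrame:
    """Filter and code a tidy trial table into a model frame.

    Keeps the requested outcome subset, drops practice and try-harder rows,
    then applies the coding used throughout: emotion change standardized at
    the sample level over included rows; IS effect coded (+1 sought / -1
    not); pump value sample-standardized then within-participant centered;
    missed opportunity kept on the raw pump scale and within-participant
    centered.
    """
    if trial_subset not in ("bank", "bust"):
        raise ValueError("trial_subset must be 'bank' or 'bust'")
    df = trials.loc[
        (~trials["is_practice"].astype(bool))
        & (~trials["try_harder"].astype(bool))
        & (trials["outcome"] == Outcome(trial_subset).value)
    ].copy()
    if df.empty:
        raise ValueError(f"no analyzable {trial_subset} trials after exclusions")
    y = df["emotion_change"].astype(float)
    sd = y.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("emotion-change ratings are constant; cannot standardize")
    df["outcome_z"] = (y - y.mean()) / sd
    df[COEF_IS] = np.where(df["info_sought"].astype(bool), 1.0, -1.0)
    pv = df["pump_value"].astype(float)
    pv_std = (pv - pv.mean()) / pv.std(ddof=1)
    df["PV_c"] = pv_std - pv_std.groupby(df["participant_id"]).transform("mean")
    mo = (df["limit"] - df["n_pumps"]).astype(float)
    df["MO"] = mo
    df["MO_c"] = mo - mo.groupby(df["participant_id"]).transform("mean")
    keep = [
        "participant_id",
        "experiment_id",
        "trial_index",
        "outcome_z",
        COEF_IS,
        "PV_c",
        "MO_c",
        "MO",
    ]
    return df[keep].reset_index(drop=True)


def _vc_formulas(step: int) -> dict[str, str]:
    vc = {COEF_IS: f"0 + {COEF_IS}", COEF_PV: "0 + PV_c", COEF_MO: "0 + MO_c"}
    if step == 2:
        vc[COEF_IS_PV] = "0 + IS:PV_c"
        vc[COEF_IS_MO] = "0 + IS:MO_c"
    return vc


def _fixed_formula(step: int) -> str:
    base = "outcome_z ~ IS + PV_c + MO_c"
    if step == 2:
        base += " + IS:PV_c + IS:MO_c"
    return base


def _wald_table(params: pd.Series, cov: pd.DataFrame) -> dict[str, CoefStats]:
    out = {}
    for name in params.index:
        b = float(params[name])
        se = float(np.sqrt(cov.loc[name, name]))
        z = b / se if se > 0 else np.nan
        p = 2.0 * st.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        out[name] = CoefStats(b, se, z, p)
    return out


def fit_emotion_model(
    frame: pd.DataFrame,
    step: Literal[1, 2] = 1,
    refit_on_singular: bool = True,
) -> FitResult:
    """Fit the Step-1 or Step-2 emotion-change mixed model on one experiment.

    Random effects: participant intercept plus an uncorrelated variance
    component per trial-level predictor.  A fit is singular when any
    variance component collapses to ~0; with ``refit_on_singular`` the
    model is refit after dropping slopes in ``SLOPE_DROP_ORDER`` until the
    fit is clean (the flag stays set to record the reduction).
    """
    if step not in (1, 2):
        raise ValueError("step must be 1 or 2")
    vc = _vc_formulas(step)
    dropped: list[str] = []
    last_exc: Exception | None = None
    while True:
        try:
            res = _fit_mixedlm(frame, _fixed_formula(step), vc)
        except Exception as exc:  # np.linalg.LinAlgError and friends
            last_exc = exc
            res = None
        # an unusable fit (failed, or broken fixed-effect covariance) always
        # walks the fallback chain; a merely boundary-singular fit does so
        # only when refit_on_singular is set
        usable = res is not None and _valid_fixed_cov(res)
        if usable and (not _is_singular(res) or not refit_on_singular):
            break
        remaining = [k for k in SLOPE_DROP_ORDER if k in vc]
        if not remaining:
            if not usable:
                raise RuntimeError(
                    f"mixed model failed even with intercept-only random effects: {last_exc}"
                )
            break
        drop = remaining[0]
        del vc[drop]
        dropped.append(drop)
    fe_names = list(res.fe_params.index)
    cov = pd.DataFrame(
        np.asarray(res.cov_params())[: len(fe_names), : len(fe_names)],
        index=fe_names,
        columns=fe_names,
    )
    re_var = {"intercept": float(np.asarray(res.cov_re)[0, 0])}
    for name, v in zip(res.model.exog_vc.names, np.atleast_1d(res.vcomp)):
        re_var[name] = float(v)
    return FitResult(
        coefficients=_wald_table(res.fe_params, cov),
        cov_fixed=cov,
        re_var=re_var,
        singular_fit=bool(_is_singular(res) or dropped),
        dropped_slopes=dropped,
        n_obs=int(res.nobs),
        n_participants=int(frame["participant_id"].nunique()),
        method="MixedLM-REML",
        experiment_id=str(frame["experiment_id"].iloc[0]) if len(frame) else "",
    )


def fixed_effects_at_zero_variance(
    frame: pd.DataFrame,
    step: Literal[1, 2] = 1,
    eps: float = 1e-12,
) -> pd.Series:
    """Fixed effects of the mixed model in the zero-variance limit.

    Profiles the model's GLS fixed effects at (numerically vanishing)
    random-effect variances, where generalized least squares collapses to
    ordinary least squares on the same design -- the closed-form anchor the
    estimation machinery must reproduce.
    """
    model = smf.mixedlm(
        _fixed_formula(step),
        data=frame,
        groups=frame["participant_id"],
        re_formula="1",
        vc_formula=_vc_formulas(step),
    )
    fe, _ = model.get_fe_params(
        eps * np.eye(1), eps * np.ones(len(model.exog_vc.names)), tol=eps * 1e-4
    )
    return pd.Series(np.asarray(fe), index=model.exog_names)


def _fit_mixedlm(frame: pd.DataFrame, fixed: str, vc: dict[str, str]):
    model = smf.mixedlm(
        fixed,
        data=frame,
        groups=frame["participant_id"],
        re_formula="1",
        vc_formula=vc or None,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True, method=["lbfgs", "bfgs"], maxiter=500)
    return res


def _valid_fixed_cov(res) -> bool:
    k = len(res.fe_params)
    diag = np.diag(np.asarray(res.cov_params()))[:k]
    return bool(np.all(np.isfinite(diag)) and np.all(diag > 0))


def _is_singular(res) -> bool:
    variances = [float(np.asarray(res.cov_re)[0, 0])]
    variances.extend(float(v) for v in np.atleast_1d(res.vcomp))
    return any(v < _SINGULAR_TOL for v in variances)


def simple_slopes(
    fit: FitResult,
    moderator_level: int,
    predictor: str = COEF_MO,
) -> CoefStats:
    """Conditional slope of a predictor at IS = -1 or +1 from a Step-2 fit.

    slope = b_main + level * b_interaction; its variance is the quadratic
    form var_main + level^2 var_int + 2 level cov from the fixed-effect
    covariance matrix.
    """
    if moderator_level not in (-1, 1):
        raise ValueError("moderator_level must be -1 or +1")
    interaction = f"{COEF_IS}:{predictor}"
    if interaction not in fit.coefficients:
        raise KeyError(f"fit has no interaction term {interaction!r}; fit Step 2 first")
    b_main = fit.coef(predictor).b
    b_int = fit.coef(interaction).b
    v = (
        fit.cov_fixed.loc[predictor, predictor]
        + moderator_level**2 * fit.cov_fixed.loc[interaction, interaction]
        + 2.0 * moderator_level * fit.cov_fixed.loc[predictor, interaction]
    )
    b = b_main + moderator_level * b_int
    se = float(np.sqrt(v))
    z = b / se
    return CoefStats(float(b), se, float(z), float(2.0 * st.norm.sf(abs(z))))


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float
    cohens_d: float


def welch_test(change_sought: np.ndarray, change_not: np.ndarray) -> WelchResult:
    """Welch's t test (Welch-Satterthwaite df) plus pooled-SD Cohen's d."""
    x = np.asarray(change_sought, dtype=float)
    y = np.asarray(change_not, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    n1, n2 = x.size, y.size
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        t = 0.0
        df = float(n1 + n2 - 2)
        p = 1.0
    else:
        t = float((x.mean() - y.mean()) / np.sqrt(se2))
        df = float(se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)))
        p = float(2.0 * st.t.sf(abs(t), df))
    pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    d = float((x.mean() - y.mean()) / pooled) if pooled > 0 else 0.0
    return WelchResult(t, df, p, d)


def replication_interaction_model(trials: pd.DataFrame) -> FitResult:
    """OLS for the one-shot replication: bankers' standardized emotion-rating
    change on effect-coded seeking, mean-centered missed opportunity, and
    their product.  Inference uses the t distribution with the residual df.
    """
    df = trials.loc[
        (~trials["is_practice"].astype(bool)) & (trials["outcome"] == Outcome.BANK.value)
    ].copy()
    if df["participant_id"].duplicated().any():
        raise ValueError("expected one critical trial per participant")
    y = df["emotion_change"].astype(float)
    df["outcome_z"] = (y - y.mean()) / y.std(ddof=1)
    df[COEF_IS] = np.where(df["info_sought"].astype(bool), 1.0, -1.0)
    mo = (df["limit"] - df["n_pumps"]).astype(float)
    df["MO_c"] = mo - mo.mean()
    design = df[[COEF_IS, "MO_c"]].copy()
    design[COEF_IS_MO.replace(":", "_")] = design[COEF_IS] * design["MO_c"]
    if design.drop_duplicates().shape[0] < 3:
        raise ValueError("need at least 3 distinct design rows")
    X = sm.add_constant(design.to_numpy())
    res = sm.OLS(df["outcome_z"].to_numpy(), X).fit()
    names = ["Intercept", COEF_IS, COEF_MO, COEF_IS_MO]
    params = pd.Series(res.params, index=names)
    cov = pd.DataFrame(res.cov_params(), index=names, columns=names)
    dfree = res.df_resid
    coefs = {}
    for name in names:
        b = float(params[name])
        se = float(np.sqrt(cov.loc[name, name]))
        t = b / se
        coefs[name] = CoefStats(b, se, float(t), float(2.0 * st.t.sf(abs(t), dfree)))
    return FitResult(
        coefficients=coefs,
        cov_fixed=cov,
        re_var={},
        singular_fit=False,
        dropped_slopes=[],
        n_obs=int(res.nobs),
        n_participants=int(df["participant_id"].nunique()),
        method=f"OLS (t, df={int(dfree)})",
        experiment_id=str(df["experiment_id"].iloc[0]),
    )
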