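"""Downstream path model: seeking -> emotion -> adjustment -> next trial.

Bank trials at t are paired with the participant's trial t+1 to form a
lagged frame with the behavior adjustment (pumps(t+1) - pumps(t); positive
means becoming riskier) and the next trial's outcome and points.  Three
estimating layers, each ordinary least squares with participant-clustered
sandwich standard errors, mirror the restricted path structure:

  (i)   emotion ~ IS + PV_c + MO_c + IS:PV_c + IS:MO_c
  (ii)  adjustment ~ emotion + PV_c + MO_c + IS:PV_c + IS:MO_c
  (iii) next_outcome ~ adjustment    and    next_points ~ adjustment

(the IS main effect is excluded from layer (ii), matching the omitted
direct path from seeking to adjustment).  The seeking -> next-trial
mediation is the three-path product a*b*c with a multivariate delta-method
SE under the independent-layer approximation,

  SE = sqrt(b^2 c^2 SEa^2 + a^2 c^2 SEb^2 + a^2 b^2 SEc^2).

next_outcome is modeled on the linear-probability scale by default; note
the task mechanics pin its relationship to next-trial pumps at -1/13.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .models import COEF_IS, COEF_IS_MO, COEF_IS_PV, COEF_MO, COEF_PV, CoefStats, prepare_variables
from .meta import MetaResult, random_effects_meta
from .task import Outcome

__all__ = [
    "PATH_NAMES",
    "PathResult",
    "build_lagged_frame",
    "fit_path_model",
    "mediation_effect",
    "integrate_paths",
]

PATH_IS_EMOTION = "is_to_emotion"
PATH_EMOTION_ADJUST = "emotion_to_adjustment"
PATH_ADJUST_OUTCOME = "adjustment_to_next_outcome"
PATH_ADJUST_POINTS = "adjustment_to_next_points"
PATH_NAMES = (PATH_IS_EMOTION, PATH_EMOTION_ADJUST, PATH_ADJUST_OUTCOME, PATH_ADJUST_POINTS)


@dataclass
class PathResult:
    """Per-path coefficients with cluster-robust SEs, plus controls."""

    paths: dict[str, CoefStats]
    controls: dict[str, dict[str, CoefStats]]
    n_obs: int
    n_clusters: int
    experiment_id: str = ""

    def path(self, name: str) -> CoefStats:
        if name not in self.paths:
            raise KeyError(f"no path named {name!r}; have {list(self.paths)}")
        return self.paths[name]


def build_lagged_frame(trials: pd.DataFrame) -> pd.DataFrame:
    """Pair each retained bank trial t with the same participant's trial t+1.

    Codes at t come from the bank-trial model frame (practice and
    try-harder rows already excluded); the successor trial may have either
    outcome.  Participants' final trials contribute no row.  An empty
    result is allowed (returned with the right columns).
    """
    frame = prepare_variables(trials, "bank")
    raw = trials.loc[~trials["is_practice"].astype(bool)].copy()
    nxt = raw[["participant_id", "trial_index", "n_pumps", "outcome", "points"]].copy()
    nxt["trial_index"] -= 1
    nxt = nxt.rename(
        columns={"n_pumps": "next_pumps", "outcome": "next_outcome_str", "points": "next_points"}
    )
    cur = raw[["participant_id", "trial_index", "n_pumps"]]
    merged = frame.merge(cur, on=["participant_id", "trial_index"], how="left").merge(
        nxt, on=["participant_id", "trial_index"], how="inner"
    )
    merged["adjustment"] = (merged["next_pumps"] - merged["n_pumps"]).astype(int)
    merged["next_outcome"] = (merged["next_outcome_str"] == Outcome.BANK.value).astype(int)
    merged["cluster"] = merged["participant_id"]
    cols = [
        "participant_id",
        "experiment_id",
        "trial_index",
        "outcome_z",
        COEF_IS,
        "PV_c",
        "MO_c",
        "n_pumps",
        "next_pumps",
        "adjustment",
        "next_outcome",
        "next_points",
        "cluster",
    ]
    return merged[cols].reset_index(drop=True)


def _cluster_ols(y: np.ndarray, X: pd.DataFrame, groups: np.ndarray) -> tuple[pd.Series, pd.DataFrame]:
    """OLS with the basic clustered sandwich covariance (no small-sample
    correction) and z-based inference."""
    Xc = sm.add_constant(X, has_constant="add")
    res = sm.OLS(np.asarray(y, dtype=float), Xc.to_numpy()).fit(
        cov_type="cluster",
        cov_kwds={"groups": np.asarray(groups), "use_correction": False},
        use_t=False,
    )
    names = ["Intercept"] + list(X.columns)
    return pd.Series(res.params, index=names), pd.DataFrame(
        res.cov_params(), index=names, columns=names
    )


def _stats(params: pd.Series, cov: pd.DataFrame, name: str) -> CoefStats:
    b = float(params[name])
    se = float(np.sqrt(cov.loc[name, name]))
    z = b / se if se > 0 else np.nan
    return CoefStats(b, se, float(z), float(2.0 * st.norm.sf(abs(z))))


def fit_path_model(frame: pd.DataFrame) -> PathResult:
    """Fit the three estimating layers on one experiment's lagged frame."""
    if frame.empty:
        raise ValueError("lagged frame is empty")
    groups = frame["cluster"].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("cluster-robust errors need at least 2 participants")
    frame = frame.copy()
    frame["IS_PV"] = frame[COEF_IS] * frame["PV_c"]
    frame["IS_MO"] = frame[COEF_IS] * frame["MO_c"]
    controls: dict[str, dict[str, CoefStats]] = {}

    # (i) emotion layer: the Step-2 fixed-effect structure
    X1 = frame[[COEF_IS, "PV_c", "MO_c", "IS_PV", "IS_MO"]]
    p1, c1 = _cluster_ols(frame["outcome_z"], X1, groups)
    controls["emotion"] = {n: _stats(p1, c1, n) for n in X1.columns if n != COEF_IS}

    # (ii) adjustment layer: emotion plus controls, no direct IS path
    X2 = frame[["outcome_z", "PV_c", "MO_c", "IS_PV", "IS_MO"]]
    p2, c2 = _cluster_ols(frame["adjustment"], X2, groups)
    controls["adjustment"] = {n: _stats(p2, c2, n) for n in X2.columns if n != "outcome_z"}

    # (iii) distal layers
    X3 = frame[["adjustment"]]
    p3a, c3a = _cluster_ols(frame["next_outcome"], X3, groups)
    p3b, c3b = _cluster_ols(frame["next_points"], X3, groups)

    paths = {
        PATH_IS_EMOTION: _stats(p1, c1, COEF_IS),
        PATH_EMOTION_ADJUST: _stats(p2, c2, "outcome_z"),
        PATH_ADJUST_OUTCOME: _stats(p3a, c3a, "adjustment"),
        PATH_ADJUST_POINTS: _stats(p3b, c3b, "adjustment"),
    }
    return PathResult(
        paths=paths,
        controls=controls,
        n_obs=int(len(frame)),
        n_clusters=int(len(np.unique(groups))),
        experiment_id=str(frame["experiment_id"].iloc[0]),
    )


def mediation_effect(
    path: PathResult,
    target: Literal["next_outcome", "next_points"] = "next_outcome",
) -> CoefStats:
    """Three-path mediation product seeking -> emotion -> adjustment -> target.

    The product a*b*c carries a delta-method SE under the independent-layer
    approximation; any zero path gives a zero product with finite SE.
    """
    if target == "next_outcome":
        c_path = path.path(PATH_ADJUST_OUTCOME)
    elif target == "next_points":
        c_path = path.path(PATH_ADJUST_POINTS)
    else:
        raise ValueError("target must be 'next_outcome' or 'next_points'")
    a = path.path(PATH_IS_EMOTION)
    b = path.path(PATH_EMOTION_ADJUST)
    prod = a.b * b.b * c_path.b
    var = (
        (b.b * c_path.b * a.se) ** 2
        + (a.b * c_path.b * b.se) ** 2
        + (a.b * b.b * c_path.se) ** 2
    )
    se = float(np.sqrt(var))
    z = prod / se if se > 0 else np.nan
    return CoefStats(float(prod), se, float(z), float(2.0 * st.norm.sf(abs(z))))


def integrate_paths(results: Iterable[PathResult], path_name: str) -> MetaResult:
    """Meta-integrate one path coefficient across experiments."""
    results = list(results)
    bs = [r.path(path_name).b for r in results]
    ses = [r.path(path_name).se for r in results]
    return random_effects_meta(bs, ses, label=path_name)
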