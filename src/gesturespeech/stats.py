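"""Statistical models: condition contrasts, beat-locked trajectory smooths,
and deceleration scaling of acoustic peaks.

Three analyses, all linear mixed models with participant-level random
effects (fitting delegates to statsmodels MixedLM; the contribution here
is the model specifications and contrasts):

1. condition contrasts -- per-trial mean acoustics ~ condition (reference
   passive), plus sex for F0;
2. trajectory smooths -- epoch samples ~ per-condition {linear trend +
   nonlinear spline} over relative time, a GAM-style smooth-by-factor
   model; the nonlinearity test is a Wald chi-square on the nonlinear
   basis block, and difference smooths contrast each movement condition
   with the reference;
3. deceleration effects -- trial-averaged acoustic maxima ~ max
   deceleration (envelope: slope model; F0: condition x deceleration
   interaction with wrist as reference).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats as spstats
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

log = logging.getLogger(__name__)


@dataclass
class EffectEstimate:
    term: str
    b: float
    se: float
    stat: float
    p: float

    def __post_init__(self):
        if np.isfinite(self.se) and self.se <= 0:
            raise ValueError("standard error must be positive")


@dataclass
class SmoothFitResult:
    response: str
    rel_t_ms: np.ndarray
    fitted: dict                      # level -> fitted trajectory over rel_t
    difference: dict                  # level -> (diff, se) vs reference
    nonlinearity_p: dict              # level -> p of the nonlinear block
    parametric: list = field(default_factory=list)  # EffectEstimate list
    random_structure: str = "intercept"

    def difference_peak_ms(self, level: str) -> float:
        """Location of the difference-smooth maximum, in ms."""
        diff, _ = self.difference[level]
        return float(self.rel_t_ms[int(np.argmax(diff))])


@dataclass
class FixedEffectsFit:
    """Uniform view of the fixed-effects part of a fitted model."""

    fe_params: np.ndarray
    bse_fe: np.ndarray
    cov_fe: np.ndarray
    structure: str
    #: degrees of freedom for t-based inference; participant-level effects
    #: are judged against between-cluster df (G - 1), the conservative
    #: standard in cluster-robust inference
    df_inference: float = np.inf


def _try_mixed(endog, exog, groups, exog_re):
    model = MixedLM(endog, exog, groups=groups, exog_re=exog_re)
    try:
        res = model.fit(reml=True, method="lbfgs", maxiter=200)
    except (np.linalg.LinAlgError, ValueError):
        res = model.fit(reml=True)  # statsmodels' own optimizer cascade
    if not getattr(res, "converged", True):
        raise np.linalg.LinAlgError("mixed model did not converge")
    if not np.all(np.isfinite(res.bse_fe)):
        raise np.linalg.LinAlgError("non-finite fixed-effect SEs")
    # at a variance-component boundary (cov_re -> 0) statsmodels can report
    # astronomically inflated SEs; treat that as a failed fit
    scale_y = float(np.std(np.asarray(endog))) + 1e-12
    if np.any(np.asarray(res.bse_fe) > 1e3 * scale_y):
        raise np.linalg.LinAlgError("degenerate SEs at variance boundary")
    k = len(res.fe_params)
    cov = np.asarray(res.cov_params())[:k, :k]
    df = max(len(np.unique(groups)) - 1, 1)
    return FixedEffectsFit(np.asarray(res.fe_params), np.asarray(res.bse_fe),
                           cov, "mixed", df_inference=df)


def _fit_mixedlm(endog, exog, groups, exog_re=None) -> tuple[FixedEffectsFit, str]:
    """Mixed-model fit: random-slope attempt, random-intercept fallback,
    and cluster-robust OLS as the boundary-case last resort.

    When the participant variance component sits on the boundary (zero) the
    mixed fit can fail outright; the model then reduces to OLS, for which
    participant-clustered standard errors give the matching inference.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if exog_re is not None:
            try:
                fit = _try_mixed(endog, exog, groups, exog_re)
                fit.structure = "intercept+slope"
                return fit, fit.structure
            except (np.linalg.LinAlgError, ValueError):
                log.info("random-slope fit failed; trying random intercept")
        try:
            fit = _try_mixed(endog, exog, groups, None)
            fit.structure = "intercept"
            return fit, fit.structure
        except (np.linalg.LinAlgError, ValueError):
            log.info("mixed fit failed; cluster-robust OLS fallback")
        try:
            res = sm.OLS(endog, exog).fit(cov_type="cluster",
                                          cov_kwds={"groups": groups})
            df = max(len(np.unique(groups)) - 1, 1)
            structure = "ols_cluster"
        except (ZeroDivisionError, np.linalg.LinAlgError, ValueError):
            # saturated or degenerate design: plain OLS as a last resort
            res = sm.OLS(endog, exog).fit()
            df = max(len(endog) - exog.shape[1], 1)
            structure = "ols"
        fit = FixedEffectsFit(np.asarray(res.params), np.asarray(res.bse),
                              np.asarray(res.cov_params()), structure,
                              df_inference=df)
        return fit, fit.structure


def _effects_from_fit(res: FixedEffectsFit,
                      names: Sequence[str]) -> list[EffectEstimate]:
    out = []
    df = res.df_inference
    for i, name in enumerate(names):
        b = float(res.fe_params[i])
        se = float(res.bse_fe[i])
        z = b / se if se > 0 else np.nan
        if np.isfinite(z):
            p = float(2.0 * (spstats.t.sf(abs(z), df) if np.isfinite(df)
                             else spstats.norm.sf(abs(z))))
        else:
            p = np.nan
        out.append(EffectEstimate(term=name, b=b, se=se, stat=z, p=p))
    return out


# ---------------------------------------------------------------------------
# 1. condition contrasts

def fit_condition_effects(summaries: pd.DataFrame,
                          reference: str = "passive") -> dict[str, list[EffectEstimate]]:
    """Mixed models for condition effects on per-trial mean acoustics.

    ``summaries`` needs columns participant_id, sex, condition, mean_env_z,
    mean_f0.  The envelope model is ``mean_env_z ~ condition``; the F0
    model additionally adjusts for sex.  Participant random intercepts.
    Returns contrasts labeled ``<level>_vs_<reference>``.
    """
    df = summaries.dropna(subset=["mean_env_z", "mean_f0"]).copy()
    levels = [c for c in df["condition"].unique()]
    if len(levels) < 2:
        raise ValueError("need at least two conditions")
    if df["participant_id"].nunique() < 2:
        raise ValueError("need at least two participants")

    results = {}
    for response, with_sex in (("mean_env_z", False), ("mean_f0", True)):
        rhs = f"C(condition, Treatment('{reference}'))"
        if with_sex and df["sex"].nunique() > 1:
            rhs += " + C(sex, Treatment('female'))"
        y, X = patsy.dmatrices(f"{response} ~ {rhs}", df, return_type="dataframe")
        names = [_clean_term(c, reference) for c in X.columns]
        res, _ = _fit_mixedlm(np.asarray(y).ravel(), np.asarray(X),
                              groups=df["participant_id"].to_numpy())
        results[response] = _effects_from_fit(res, names)
    return results


def _clean_term(patsy_name: str, reference: str) -> str:
    if patsy_name == "Intercept":
        return "intercept"
    if "[T." in patsy_name:
        level = patsy_name.split("[T.")[1].rstrip("]")
        ref = reference if "condition" in patsy_name else "female"
        return f"{level}_vs_{ref}"
    return patsy_name


# ---------------------------------------------------------------------------
# 2. trajectory smooths

def _nonlinear_basis(x_unique: np.ndarray, k: int) -> np.ndarray:
    """B-spline basis over x, orthogonalized against {1, x}.

    Returns an orthonormal column basis spanning the purely nonlinear part
    of the spline space (rank k - 2), so the Wald test on its coefficients
    is exactly a test for nonlinearity.
    """
    B = patsy.dmatrix(f"bs(x, df={k}, degree=3, include_intercept=True) - 1",
                      {"x": x_unique}, return_type="matrix")
    B = np.asarray(B)
    lin = np.column_stack([np.ones_like(x_unique), x_unique])
    proj = lin @ np.linalg.lstsq(lin, B, rcond=None)[0]
    R = B - proj
    U, s, _ = np.linalg.svd(R, full_matrices=False)
    keep = s > s[0] * 1e-8
    return U[:, keep]


def fit_trajectory_smooths(epochs_df: pd.DataFrame, response: str = "env",
                           reference: str = "passive", k: int = 10,
                           max_rows: int = 1_500_000,
                           subsample_seed: int = 0) -> SmoothFitResult:
    """GAM-style smooth-by-condition fit of beat-locked trajectories.

    Model: response ~ condition + rel_t:condition + spline(rel_t):condition.
    Because the responses are z-scaled within participant, the
    participant-level location variance is absorbed by construction;
    coefficients are estimated by least squares and all inference uses a
    participant-clustered sandwich covariance, which is consistent under
    the strong within-epoch autocorrelation of the samples.  The spline
    block is orthogonal to {1, rel_t} per condition, so its Wald
    chi-square is a per-condition nonlinearity test.  When the table
    exceeds ``max_rows`` rows, whole epochs are subsampled (seeded).
    """
    df = epochs_df.dropna(subset=[response]).copy()
    levels = list(pd.unique(df["condition"]))
    if reference in levels:
        levels = [reference] + [l for l in levels if l != reference]
    counts = df.groupby("condition", observed=True)["rel_t_ms"].count()
    if (counts < 10).any():
        raise ValueError("fewer than 10 samples in some condition")

    if len(df) > max_rows:
        rng = np.random.default_rng(subsample_seed)
        keys = df[["participant_id", "trial_id", "cycle_index"]].apply(tuple, axis=1)
        uniq = keys.unique()
        target = max(1, int(len(uniq) * max_rows / len(df)))
        chosen = set(rng.choice(len(uniq), size=target, replace=False))
        keep = keys.map({u: (i in chosen) for i, u in enumerate(uniq)})
        df = df[keep.to_numpy()]

    x_all = df["rel_t_ms"].to_numpy()
    x0, x1 = x_all.min(), x_all.max()
    xs = (x_all - x0) / (x1 - x0)
    x_unique = np.unique(xs)
    Q = _nonlinear_basis(x_unique, k)
    k_nl = Q.shape[1]
    # map each row to its grid index
    pos = np.searchsorted(x_unique, xs)
    Qrows = Q[pos]

    n = len(df)
    cols, names = [np.ones(n)], ["intercept"]
    cond = df["condition"].to_numpy()
    for lv in levels[1:]:
        cols.append((cond == lv).astype(float))
        names.append(f"{lv}_vs_{levels[0]}")
    for lv in levels:
        ind = (cond == lv).astype(float)
        cols.append(xs * ind)
        names.append(f"slope:{lv}")
        for j in range(k_nl):
            cols.append(Qrows[:, j] * ind)
            names.append(f"nl{j}:{lv}")
    X = np.column_stack(cols)
    y = df[response].to_numpy()
    groups = df["participant_id"].to_numpy()

    fe, *_ = np.linalg.lstsq(X, y, rcond=None)
    V = _cluster_sandwich(y, X, fe, groups)
    structure = "ols+cluster(participant)"
    res = FixedEffectsFit(fe, np.sqrt(np.clip(np.diag(V), 0, None)), V, structure,
                          df_inference=max(len(np.unique(groups)) - 1, 1))

    name_idx = {nm: i for i, nm in enumerate(names)}
    grid_ms = np.sort(df["rel_t_ms"].unique())
    xg = (grid_ms - x0) / (x1 - x0)
    posg = np.searchsorted(x_unique, xg)
    Qg = Q[posg]

    fitted, difference, nonlin_p = {}, {}, {}
    for lv in levels:
        contrib = np.full((len(grid_ms), len(fe)), 0.0)
        contrib[:, name_idx["intercept"]] = 1.0
        if lv != levels[0]:
            contrib[:, name_idx[f"{lv}_vs_{levels[0]}"]] = 1.0
        contrib[:, name_idx[f"slope:{lv}"]] = xg
        for j in range(k_nl):
            contrib[:, name_idx[f"nl{j}:{lv}"]] = Qg[:, j]
        fitted[lv] = contrib @ fe
        idx = [name_idx[f"nl{j}:{lv}"] for j in range(k_nl)]
        b = fe[idx]
        Vb = V[np.ix_(idx, idx)]
        q = max(np.linalg.matrix_rank(Vb), 1)
        t2 = float(b @ np.linalg.pinv(Vb) @ b)
        G = len(np.unique(groups))
        if G > q + 1:
            # Hotelling small-sample correction: with G cluster score
            # contributions the Wald statistic is F-distributed, not chi2
            fstat = (G - q) / (q * (G - 1)) * t2
            nonlin_p[lv] = float(spstats.f.sf(fstat, q, G - q))
        else:
            nonlin_p[lv] = float(spstats.chi2.sf(t2, df=q))
        if lv != levels[0]:
            D = np.zeros((len(grid_ms), len(fe)))
            D[:, name_idx[f"{lv}_vs_{levels[0]}"]] = 1.0
            D[:, name_idx[f"slope:{lv}"]] = xg
            D[:, name_idx[f"slope:{levels[0]}"]] = -xg
            for j in range(k_nl):
                D[:, name_idx[f"nl{j}:{lv}"]] = Qg[:, j]
                D[:, name_idx[f"nl{j}:{levels[0]}"]] = -Qg[:, j]
            diff = D @ fe
            se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", D, V, D), 0.0))
            difference[lv] = (diff, se)

    parametric = _effects_from_fit(res, names)[:len(levels)]
    return SmoothFitResult(response=response, rel_t_ms=grid_ms, fitted=fitted,
                           difference=difference, nonlinearity_p=nonlin_p,
                           parametric=parametric, random_structure=structure)


def _cluster_sandwich(y, X, beta, clusters) -> np.ndarray:
    """Cluster-robust covariance of ``beta`` (GEE-style sandwich).

    Consistent under arbitrary within-cluster correlation of the marginal
    residuals; clusters are participants.
    """
    r = y - X @ beta
    A = X.T @ X
    B = np.zeros_like(A)
    for g in np.unique(clusters):
        m = clusters == g
        s = X[m].T @ r[m]
        B += np.outer(s, s)
    Ainv = np.linalg.pinv(A)
    G = len(np.unique(clusters))
    corr = G / (G - 1) if G > 1 else 1.0
    return corr * Ainv @ B @ Ainv


# ---------------------------------------------------------------------------
# 3. deceleration effects

def fit_deceleration_effects(trial_means: pd.DataFrame,
                             reference: str = "wrist",
                             decel_scale: float = 100.0
                             ) -> dict[str, list[EffectEstimate]]:
    """Deceleration scaling of trial-averaged acoustic peaks.

    Envelope model: ``max_env ~ max_decel`` with participant random
    intercept and slope (intercept-only fallback).  F0 model:
    ``max_f0 ~ condition * max_decel`` with wrist as reference.  The
    deceleration predictor is scaled to units of ``decel_scale`` cm/s^2
    (default: per 100 cm/s^2) for numerical conditioning; coefficients are
    per scaled unit.
    """
    df = trial_means.dropna(subset=["max_decel", "max_env"]).copy()
    df["decel_s"] = df["max_decel"] / decel_scale
    groups = df["participant_id"].to_numpy()
    results = {}

    X = np.column_stack([np.ones(len(df)), df["decel_s"].to_numpy()])
    res, _ = _fit_mixedlm(df["max_env"].to_numpy(), X, groups, exog_re=X)
    results["max_env"] = _effects_from_fit(res, ["intercept", "max_decel"])

    conds = [c for c in df["condition"].unique()]
    if len(conds) < 2:
        raise ValueError("interaction model needs at least two conditions")
    dff = df.dropna(subset=["max_f0"])
    others = [c for c in conds if c != reference]
    cols = [np.ones(len(dff)), ]
    names = ["intercept"]
    cond = dff["condition"].to_numpy()
    d = dff["decel_s"].to_numpy()
    for c in others:
        cols.append((cond == c).astype(float))
        names.append(f"{c}_vs_{reference}")
    cols.append(d)
    names.append("max_decel")
    for c in others:
        cols.append(d * (cond == c))
        names.append(f"{c}_x_max_decel")
    X = np.column_stack(cols)
    Xre = np.column_stack([np.ones(len(dff)), d])
    res, _ = _fit_mixedlm(dff["max_f0"].to_numpy(), X,
                          dff["participant_id"].to_numpy(), exog_re=Xre)
    results["max_f0"] = _effects_from_fit(res, names)
    return results
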