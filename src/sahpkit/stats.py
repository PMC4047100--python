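"""Group-level mixed-effects inference for sweep-derived features.

The central model is a linear mixed-effects regression of a per-sweep
response (typically the slow-AHP amplitude, mV) on treatment group,
injected current step, and their interaction, with per-cell random
intercepts and random slopes in current:

    y_ij = β0 + β_T·T_i + β_S·s_ij + β_TS·T_i·s_ij + u0_i + u1_i·s_ij + ε_ij

where ``s`` is the current step centered at 300 pA and scaled to 100 pA
units.  Current is coded as a centered continuous covariate by default so
the treatment × current interaction is the 1-df trend test matching single
chi-square reporting; the 13-level factor coding is available behind a
flag.  Fixed-effect hypotheses are tested by likelihood-ratio tests of
nested maximum-likelihood fits (never REML).  Supporting machinery:
observation-level Cook's-distance influence screening with the 4/n cutoff,
multiple imputation of missing observations by an
expectation-maximization-with-bootstrapping scheme on a multivariate-normal
model of the per-cell response profile, pooling across imputations, and
simulation-based power for the interaction test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .io import DEPOL_STEP_GRID
from .synth import CohortGenParams, generate_cohort

STEP_CENTER = 300.0   # pA
STEP_SCALE = 100.0    # pA per unit of the fitting covariate


# ---------------------------------------------------------------------------
# Long-table assembly
# ---------------------------------------------------------------------------

def build_long_table(cells, response_name: str = "v_slow") -> pd.DataFrame:
    """Assemble a long-format cohort table from per-cell feature maps.

    Each :class:`~sahpkit.io.CellRecord` must carry the per-step feature
    dictionaries filled by the upstream stages in ``cell.features``
    (``"ahp"``: step → AHPFit, ``"trains"``: step → SpikeTrainStats).
    Missing observations (absent step, failed fit) are flagged, not
    dropped.
    """
    rows = []
    for cell in cells:
        for step in DEPOL_STEP_GRID:
            step = float(step)
            value = np.nan
            if response_name in ("v_slow", "v_med", "tau_slow", "tau_med",
                                 "peak_amp", "r2"):
                fit = cell.features.get("ahp", {}).get(step)
                if fit is not None and fit.ok:
                    value = getattr(fit, response_name)
            elif response_name in ("n_spikes", "accommodation_pct",
                                   "mean_isi"):
                ts = cell.features.get("trains", {}).get(step)
                if ts is not None:
                    value = getattr(ts, response_name)
            else:
                raise ValueError(f"unknown response_name {response_name!r}")
            rows.append({
                "cell_id": cell.cell_id, "group": cell.group_label,
                "step": step, "response": value,
                "response_name": response_name,
                "missing": bool(np.isnan(value)),
            })
    table = pd.DataFrame(rows)
    dup = table.duplicated(subset=["cell_id", "step"])
    if dup.any():
        raise ValueError("duplicate (cell, step) rows in cohort table")
    return table


def _prepare(table: pd.DataFrame) -> pd.DataFrame:
    df = table.loc[~table["missing"] & table["response"].notna()].copy()
    df["step_c"] = (df["step"] - STEP_CENTER) / STEP_SCALE
    levels = sorted(df["group"].unique())
    if "treated" in levels and len(levels) == 2:
        ref = [g for g in levels if g != "treated"][0]
        df["treated"] = (df["group"] == "treated").astype(float)
    elif len(levels) == 2:
        ref = levels[0]
        df["treated"] = (df["group"] == levels[1]).astype(float)
    else:
        raise ValueError("cohort table must contain exactly two groups")
    df.attrs["reference_group"] = ref
    return df


# ---------------------------------------------------------------------------
# Mixed-effects fitting and likelihood-ratio tests
# ---------------------------------------------------------------------------

@dataclass
class LMEResult:
    """A converged maximum-likelihood mixed-model fit."""

    params: pd.Series          # fixed effects
    bse: pd.Series
    cov_params: pd.DataFrame
    cov_re: np.ndarray         # 2×2 random intercept/slope covariance
    scale: float               # residual variance
    llf: float
    converged: bool
    diagonal_re: bool          # True when refit with independent effects
    formula: str
    n_obs: int
    n_groups: int
    # design pieces retained for influence diagnostics
    exog: np.ndarray = field(repr=False, default=None)
    endog: np.ndarray = field(repr=False, default=None)
    exog_names: list = field(default_factory=list)
    group_codes: np.ndarray = field(repr=False, default=None)
    row_index: pd.Index = field(repr=False, default=None)
    sm_params: object = field(repr=False, default=None)  # packed ML params

    @property
    def interaction_name(self) -> str | None:
        for name in self.params.index:
            if ":" in name:
                return name
        return None


@dataclass
class LRTResult:
    chi_square: float
    df: int
    p_value: float
    full_model_id: str
    reduced_model_id: str


def _fit_one(df: pd.DataFrame, fixed: str, diag_re: bool):
    kwargs = {"groups": df["cell_id"]}
    if diag_re:
        kwargs["re_formula"] = "~1"
        kwargs["vc_formula"] = {"stepslope": "0 + step_c"}
    else:
        kwargs["re_formula"] = "~step_c"
    model = smf.mixedlm(fixed, df, **kwargs)
    last = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                res = model.fit(reml=False, method=method, maxiter=200)
            except (np.linalg.LinAlgError, ValueError):
                continue
            last = res
            if res.converged:
                break
    if last is None:
        raise RuntimeError("mixed-model fit failed for all optimizers")
    return model, last


def fit_lme(table: pd.DataFrame, fixed: str = "response ~ treated * step_c",
            step_factor: bool = False, force_diag: bool = False) -> LMEResult:
    """Fit the mixed model by maximum likelihood.

    ``step_factor=True`` switches the fixed-effect current coding to a
    13-level factor (12-df interaction); the random slope stays continuous.
    A singular random-effects covariance triggers a refit with independent
    intercept and slope, flagged via ``diagonal_re`` (``force_diag`` makes
    that structure unconditional, e.g. to keep two LRT fits nested).
    """
    df = _prepare(table)
    if len(df["cell_id"].unique()) < 4:
        raise ValueError("need at least 2 cells per group")
    if step_factor:
        fixed = fixed.replace("step_c", "C(step)")
    if force_diag:
        model, res = _fit_one(df, fixed, diag_re=True)
        var_slope = float(res.vcomp[0]) if len(res.vcomp) else 0.0
        cov_re = np.diag([float(res.cov_re.iloc[0, 0]), var_slope])
        fe_names = list(model.exog_names)
        groups, codes = np.unique(df["cell_id"].to_numpy(),
                                  return_inverse=True)
        return LMEResult(
            params=res.params[fe_names], bse=res.bse[fe_names],
            cov_params=res.cov_params().loc[fe_names, fe_names],
            cov_re=cov_re, scale=float(res.scale), llf=float(res.llf),
            converged=bool(res.converged), diagonal_re=True, formula=fixed,
            n_obs=len(df), n_groups=len(groups),
            exog=np.asarray(model.exog), endog=np.asarray(model.endog),
            exog_names=fe_names, group_codes=codes, row_index=df.index,
            sm_params=getattr(res, "params_object", None),
        )
    model, res = _fit_one(df, fixed, diag_re=False)
    cov_re = np.asarray(res.cov_re)
    diag = False
    singular = (np.linalg.eigvalsh(cov_re).min() < 1e-8 * max(cov_re.max(), 1)
                if cov_re.size else False)
    if not res.converged or singular:
        model2, res2 = _fit_one(df, fixed, diag_re=True)
        if res2.converged:
            model, res, diag = model2, res2, True
    if diag:
        var_slope = float(res.vcomp[0]) if len(res.vcomp) else 0.0
        cov_re = np.diag([float(res.cov_re.iloc[0, 0]), var_slope])
    else:
        cov_re = np.asarray(res.cov_re)

    fe_names = list(model.exog_names)
    params = res.params[fe_names]
    groups, codes = np.unique(df["cell_id"].to_numpy(), return_inverse=True)
    return LMEResult(
        params=params, bse=res.bse[fe_names],
        cov_params=res.cov_params().loc[fe_names, fe_names],
        cov_re=cov_re, scale=float(res.scale), llf=float(res.llf),
        converged=bool(res.converged), diagonal_re=diag, formula=fixed,
        n_obs=len(df), n_groups=len(groups),
        exog=np.asarray(model.exog), endog=np.asarray(model.endog),
        exog_names=fe_names, group_codes=codes, row_index=df.index,
        sm_params=getattr(res, "params_object", None),
    )


def lrt(full: LMEResult, reduced: LMEResult) -> LRTResult:
    """Likelihood-ratio test of nested maximum-likelihood fits."""
    df_diff = len(full.params) - len(reduced.params)
    if df_diff <= 0 and full.formula != reduced.formula:
        raise ValueError("models are not nested (full has no extra parameters)")
    chi2 = 2.0 * (full.llf - reduced.llf)
    # the full model can always match the reduced fit, so a slightly
    # negative statistic is optimizer noise and clips to zero; a grossly
    # negative one signals genuine non-convergence
    if chi2 < -max(1e-6 * abs(full.llf), 0.05):
        raise RuntimeError(
            f"negative LRT statistic ({chi2:.3g}): reduced model out-fitted "
            "the full model, indicating non-convergence"
        )
    chi2 = max(chi2, 0.0)
    if df_diff == 0:
        return LRTResult(chi_square=chi2, df=0, p_value=1.0,
                         full_model_id=full.formula,
                         reduced_model_id=reduced.formula)
    p = float(sps.chi2.sf(chi2, df_diff))
    return LRTResult(chi_square=float(chi2), df=df_diff, p_value=p,
                     full_model_id=full.formula,
                     reduced_model_id=reduced.formula)


def _nested_lrt(table: pd.DataFrame, full_fixed: str, reduced_fixed: str,
                step_factor: bool = False,
                ) -> tuple[LRTResult, LMEResult, LMEResult]:
    full = fit_lme(table, full_fixed, step_factor)
    reduced = fit_lme(table, reduced_fixed, step_factor)
    if full.diagonal_re != reduced.diagonal_re:
        # keep the random-effects structure identical so the models nest
        full = fit_lme(table, full_fixed, step_factor, force_diag=True)
        reduced = fit_lme(table, reduced_fixed, step_factor, force_diag=True)
    return lrt(full, reduced), full, reduced


def interaction_lrt(table: pd.DataFrame, step_factor: bool = False,
                     ) -> tuple[LRTResult, LMEResult, LMEResult]:
    """LRT of the treatment × current-step interaction (1 df by default)."""
    return _nested_lrt(table, "response ~ treated * step_c",
                       "response ~ treated + step_c", step_factor)


def main_effect_lrt(table: pd.DataFrame) -> tuple[LRTResult, LMEResult, LMEResult]:
    """LRT of the treatment main effect (model without interaction)."""
    return _nested_lrt(table, "response ~ treated + step_c",
                       "response ~ step_c")


# ---------------------------------------------------------------------------
# Influence screening
# ---------------------------------------------------------------------------

@dataclass
class InfluenceReport:
    distances: pd.Series   # indexed like the rows used in the fit
    cutoff: float          # 4 / n
    flagged: pd.Index

    @property
    def n_flagged(self) -> int:
        return len(self.flagged)


def cooks_screen(table: pd.DataFrame, result: LMEResult,
                 method: str = "refit") -> InfluenceReport:
    """Observation-level Cook's distances from the mixed model.

    ``method="refit"`` (default) deletes each observation in turn, refits
    the mixed model (variance components included), and computes
    ``D_i = (β − β_(i))ᵀ Cov(β)⁻¹ (β − β_(i)) / p`` — full case-deletion
    influence.  ``method="gls"`` is a fast approximation: conditioning on
    the estimated variance components, each cell's block is whitened by the
    Cholesky factor of ``V_i = Z_i Ψ Z_iᵀ + σ²I`` and the standard
    hat-matrix Cook's distance of the whitened regression is used.
    Observations with ``D > 4/n`` are flagged.
    """
    if method == "refit":
        return _cooks_refit(table, result)
    if method != "gls":
        raise ValueError("method must be 'refit' or 'gls'")
    X, y = result.exog, result.endog
    n, p = X.shape
    if n <= p:
        raise ValueError("fewer observations than fixed-effect parameters")
    # random-effects design: intercept and centered step (same as the fit)
    try:
        j = result.exog_names.index("step_c")
        z_step = X[:, j]
    except ValueError:
        z_step = np.zeros(n)
    Z = np.column_stack([np.ones(n), z_step])
    Xw = np.empty_like(X)
    yw = np.empty_like(y)
    for g in np.unique(result.group_codes):
        m = result.group_codes == g
        Zg = Z[m]
        V = Zg @ result.cov_re @ Zg.T + result.scale * np.eye(m.sum())
        L = np.linalg.cholesky(V)
        Xw[m] = np.linalg.solve(L, X[m])
        yw[m] = np.linalg.solve(L, y[m])
    Q, R = np.linalg.qr(Xw)
    h = np.einsum("ij,ij->i", Q, Q)
    beta = np.linalg.solve(R, Q.T @ yw)
    e = yw - Xw @ beta
    s2 = float(e @ e) / (n - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (e ** 2) * h / (p * s2 * (1.0 - h) ** 2)
    distances = pd.Series(d, index=result.row_index, name="cooks_d")
    cutoff = 4.0 / n
    flagged = distances.index[distances > cutoff]
    return InfluenceReport(distances=distances, cutoff=cutoff, flagged=flagged)


def _cooks_refit(table: pd.DataFrame, result: LMEResult) -> InfluenceReport:
    p = len(result.params)
    beta = result.params.to_numpy()
    covinv = np.linalg.inv(result.cov_params.to_numpy())
    df = _prepare(table)
    used = result.row_index
    n = len(used)
    dist = np.full(n, np.nan)
    re_kw = ({"re_formula": "~1", "vc_formula": {"stepslope": "0 + step_c"}}
             if result.diagonal_re else {"re_formula": "~step_c"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, idx in enumerate(used):
            sub = df.drop(index=idx)
            try:
                model = smf.mixedlm(result.formula, sub,
                                    groups=sub["cell_id"], **re_kw)
                fit_i = model.fit(reml=False, method="lbfgs", maxiter=200,
                                  start_params=result.sm_params)
            except (np.linalg.LinAlgError, ValueError, RuntimeError):
                continue
            d = beta - fit_i.fe_params.to_numpy()
            dist[k] = float(d @ covinv @ d) / p
    distances = pd.Series(dist, index=used, name="cooks_d")
    cutoff = 4.0 / n
    flagged = distances.index[distances > cutoff]
    return InfluenceReport(distances=distances, cutoff=cutoff, flagged=flagged)


def screen_and_mask(table: pd.DataFrame, result: LMEResult) -> pd.DataFrame:
    """Set influential observations missing (to be re-imputed downstream)."""
    rep = cooks_screen(table, result)
    out = table.copy()
    out.loc[rep.flagged, "response"] = np.nan
    out.loc[rep.flagged, "missing"] = True
    return out


# ---------------------------------------------------------------------------
# Multiple imputation (EM with bootstrapping)
# ---------------------------------------------------------------------------

def _em_mvn(X: np.ndarray, max_iter: int = 200, tol: float = 1e-7,
            ridge: float = 2.0, shrink: float = 0.05,
            ) -> tuple[np.ndarray, np.ndarray]:
    """EM estimate of (μ, Σ) for a multivariate normal with missing values.

    A light ridge (``ridge`` pseudo-observations of the diagonal, plus
    ``shrink`` shrinkage of off-diagonal terms) stabilizes Σ when the cell
    count barely exceeds the dimension, in the spirit of ridge-prior EM
    imputation.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    obs = ~np.isnan(X)
    mu = np.nanmean(X, axis=0)
    var = np.nanvar(X, axis=0)
    var[~np.isfinite(var) | (var <= 0)] = 1.0
    Sigma = np.diag(var)
    for _ in range(max_iter):
        M = np.zeros(p)
        S = np.zeros((p, p))
        for i in range(n):
            o = obs[i]
            x = X[i].copy()
            C = np.zeros((p, p))
            if not o.all():
                mm = ~o
                Soo = Sigma[np.ix_(o, o)]
                Smo = Sigma[np.ix_(mm, o)]
                sol = np.linalg.solve(Soo, (x[o] - mu[o]))
                x[mm] = mu[mm] + Smo @ sol
                C[np.ix_(mm, mm)] = (Sigma[np.ix_(mm, mm)]
                                     - Smo @ np.linalg.solve(Soo, Smo.T))
            M += x
            S += np.outer(x, x) + C
        mu_new = M / n
        S_new = S / n - np.outer(mu_new, mu_new)
        d = np.sqrt(np.clip(np.diag(S_new), 1e-12, None))
        corr = S_new / np.outer(d, d)
        corr = (1.0 - shrink) * corr + shrink * np.eye(p)
        S_new = corr * np.outer(d, d)
        S_new = (n * S_new + ridge * np.diag(np.diag(S_new))) / (n + ridge)
        delta = max(np.abs(mu_new - mu).max(), np.abs(S_new - Sigma).max())
        mu, Sigma = mu_new, S_new
        if delta < tol:
            break
    return mu, Sigma


def impute(table: pd.DataFrame, m: int = 20, seed: int = 0,
           ) -> list[pd.DataFrame]:
    """Multiple imputation of flagged-missing observations.

    The per-cell response profile across the 13 current steps, augmented
    with the treated-group indicator, is modeled as multivariate normal.
    For each of *m* imputations the cells are bootstrap-resampled, (μ, Σ)
    re-estimated by EM on the resample, and the original table's missing
    entries drawn from the conditional normal given that cell's observed
    values.  Cells with all 13 values missing are dropped with a warning.
    Deterministic under *seed*.
    """
    if not table["missing"].any():
        return [table.copy() for _ in range(m)]
    wide = table.pivot(index="cell_id", columns="step", values="response")
    steps = sorted(wide.columns)
    group = table.drop_duplicates("cell_id").set_index("cell_id")["group"]
    group = group.loc[wide.index]
    treated = (group == group.sort_values().unique()[-1]).astype(float)
    all_missing = wide.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} cell(s) with all "
            "observations missing", stacklevel=2)
        wide = wide.loc[~all_missing]
        treated = treated.loc[wide.index]
    frac = float(wide.isna().to_numpy().mean())
    if frac >= 0.5:
        raise ValueError(f"missing fraction {frac:.0%} exceeds 50%")
    X = np.column_stack([treated.to_numpy(), wide.to_numpy()])
    n, p = X.shape
    miss = np.isnan(X)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(m):
        boot = rng.integers(0, n, size=n)
        mu, Sigma = _em_mvn(X[boot])
        filled = X.copy()
        for i in range(n):
            mm = miss[i]
            if not mm.any():
                continue
            o = ~mm
            Soo = Sigma[np.ix_(o, o)]
            Smo = Sigma[np.ix_(mm, o)]
            cmean = mu[mm] + Smo @ np.linalg.solve(Soo, X[i, o] - mu[o])
            ccov = (Sigma[np.ix_(mm, mm)]
                    - Smo @ np.linalg.solve(Soo, Smo.T))
            ccov = (ccov + ccov.T) / 2 + 1e-10 * np.eye(mm.sum())
            L = np.linalg.cholesky(ccov)
            filled[i, mm] = cmean + L @ rng.standard_normal(mm.sum())
        comp = table.copy()
        comp = comp[comp["cell_id"].isin(wide.index)].reset_index(drop=True)
        fill_map = {
            (cid, step): filled[i, 1 + j]
            for i, cid in enumerate(wide.index)
            for j, step in enumerate(steps)
        }
        was_missing = comp["missing"].to_numpy()
        comp["response"] = [
            fill_map[(r.cell_id, r.step)] if r.missing else r.response
            for r in comp.itertuples()
        ]
        comp["missing"] = False
        comp["imputed"] = was_missing
        out.append(comp)
    return out


# ---------------------------------------------------------------------------
# Pooling across imputations
# ---------------------------------------------------------------------------

@dataclass
class PooledEstimate:
    estimate: float
    se: float
    df: float
    p_value: float
    between_var: float
    within_var: float
    m: int


@dataclass
class PooledLRT:
    statistic: float   # F-scaled pooled statistic (D2)
    df: tuple
    p_value: float
    mean_chi_square: float
    m: int


def pool(results: list) -> PooledEstimate | PooledLRT | pd.DataFrame:
    """Combine fits or LRTs across imputed datasets.

    ``LMEResult`` list → DataFrame of Rubin-pooled fixed effects;
    ``LRTResult`` list → chi-square combination (D2 statistic of
    Li–Meng–Raghunathan–Rubin against an F reference).
    """
    if not results:
        raise ValueError("nothing to pool")
    if isinstance(results[0], LRTResult):
        return _pool_lrt(results)
    if isinstance(results[0], LMEResult):
        names = list(results[0].params.index)
        if any(list(r.params.index) != names for r in results):
            raise ValueError("heterogeneous model specifications")
        rows = {}
        for name in names:
            q = np.array([r.params[name] for r in results])
            u = np.array([r.bse[name] ** 2 for r in results])
            rows[name] = _rubin(q, u)
        return pd.DataFrame(
            {n: {"estimate": e.estimate, "se": e.se, "df": e.df,
                 "p_value": e.p_value} for n, e in rows.items()}
        ).T
    raise TypeError(f"cannot pool objects of type {type(results[0])}")


def pool_scalar(estimates: np.ndarray, variances: np.ndarray) -> PooledEstimate:
    return _rubin(np.asarray(estimates, float), np.asarray(variances, float))


def _rubin(q: np.ndarray, u: np.ndarray) -> PooledEstimate:
    m = len(q)
    qbar = q.mean()
    ubar = u.mean()
    b = q.var(ddof=1) if m > 1 else 0.0
    t = ubar + (1.0 + 1.0 / m) * b
    if b > 0 and m > 1:
        dof = (m - 1) * (1.0 + ubar / ((1.0 + 1.0 / m) * b)) ** 2
    else:
        dof = np.inf
    se = np.sqrt(t)
    stat = qbar / se if se > 0 else np.inf
    p = float(2.0 * sps.t.sf(abs(stat), dof)) if np.isfinite(dof) else \
        float(2.0 * sps.norm.sf(abs(stat)))
    return PooledEstimate(estimate=float(qbar), se=float(se), df=float(dof),
                          p_value=p, between_var=float(b),
                          within_var=float(ubar), m=m)


def _pool_lrt(results: list[LRTResult]) -> PooledLRT:
    m = len(results)
    k = results[0].df
    if any(r.df != k for r in results):
        raise ValueError("heterogeneous LRT degrees of freedom")
    d = np.array([r.chi_square for r in results], dtype=float)
    if m == 1:
        return PooledLRT(statistic=d[0] / k, df=(k, np.inf),
                         p_value=float(sps.chi2.sf(d[0], k)),
                         mean_chi_square=float(d[0]), m=1)
    sq = np.sqrt(d)
    r = (1.0 + 1.0 / m) * sq.var(ddof=1)
    r = max(r, 1e-10)
    d2 = (d.mean() / k - (m + 1.0) / (m - 1.0) * r) / (1.0 + r)
    nu = k ** (-3.0 / m) * (m - 1.0) * (1.0 + 1.0 / r) ** 2
    p = float(sps.f.sf(max(d2, 0.0), k, nu))
    return PooledLRT(statistic=float(d2), df=(k, float(nu)), p_value=p,
                     mean_chi_square=float(d.mean()), m=m)


# ---------------------------------------------------------------------------
# Correlation of sAHP with spike output
# ---------------------------------------------------------------------------

def correlate_sahp_spikes(sahp_table: pd.DataFrame, spikes_table: pd.DataFrame,
                          ) -> dict[str, tuple[float, float]]:
    """Per-group Pearson correlation of sAHP amplitude with spike count.

    Both inputs are long cohort tables (``cell_id, group, step, response``);
    responses are averaged per (group, step), giving 13 paired points per
    group, and the correlation of mean sAHP amplitude with mean spike count
    is computed with its two-sided p value.
    """
    out = {}
    a = sahp_table.groupby(["group", "step"])["response"].mean()
    b = spikes_table.groupby(["group", "step"])["response"].mean()
    for grp in sorted(sahp_table["group"].unique()):
        x = a.loc[grp]
        y = b.loc[grp]
        common = x.index.intersection(y.index)
        x, y = x.loc[common].dropna(), y.loc[common].dropna()
        common = x.index.intersection(y.index)
        if len(common) < 3:
            raise ValueError(f"fewer than 3 paired step means for {grp!r}")
        r, p = sps.pearsonr(x.loc[common], y.loc[common])
        out[grp] = (float(r), float(p))
    return out


# ---------------------------------------------------------------------------
# Simulation-based power
# ---------------------------------------------------------------------------

@dataclass
class PowerCurve:
    n_total: np.ndarray
    power: np.ndarray
    mc_se: np.ndarray
    alpha: float
    n_sim: int
    effect_spec: CohortGenParams


def effect_spec_from_lme(result: LMEResult,
                         base: CohortGenParams | None = None) -> CohortGenParams:
    """Translate a fitted mixed model into generative cohort parameters."""
    base = base or CohortGenParams()
    p = result.params
    inter = result.interaction_name
    gamma = -p[inter] / STEP_SCALE if inter else 0.0
    step_name = "step_c"
    return replace(
        base,
        sahp_base_amp=float(-p.get("Intercept", -base.sahp_base_amp)),
        sahp_step_slope=float(-p.get(step_name, 0.0) / STEP_SCALE),
        sahp_interaction_slope=float(gamma),
        random_intercept_sd=float(np.sqrt(max(result.cov_re[0, 0], 0.0))),
        random_slope_sd=float(np.sqrt(max(result.cov_re[1, 1], 0.0))
                              / STEP_SCALE),
        residual_sd=float(np.sqrt(result.scale)),
    )


def simulate_rejection(effect: CohortGenParams, alpha: float, n_sim: int,
                       seed: int) -> tuple[float, float]:
    """Fraction of simulated cohorts whose interaction LRT rejects at α."""
    rng = np.random.default_rng(seed)
    rej = 0
    done = 0
    for _ in range(n_sim):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        table, _, _ = generate_cohort(None, None, replace(effect, seed=sub_seed))
        try:
            res, _, _ = interaction_lrt(table)
        except RuntimeError:
            continue
        done += 1
        if res.p_value < alpha:
            rej += 1
    if done == 0:
        raise RuntimeError("all simulated fits failed")
    phat = rej / done
    return phat, float(np.sqrt(max(phat * (1 - phat), 1e-12) / done))


def power_curve(effect: CohortGenParams, n_grid, alpha: float = 0.05,
                n_sim: int = 1000, seed: int = 0) -> PowerCurve:
    """Monte-Carlo power of the interaction LRT over total sample sizes.

    For each total N the two groups keep the proportions of
    ``effect.n_cells_per_group``; cohorts are simulated at the table level
    from the generative model, the full fit + LRT pipeline runs on each,
    and the rejection fraction is recorded with its Monte-Carlo standard
    error.
    """
    if min(effect.random_intercept_sd, effect.random_slope_sd,
           effect.residual_sd) < 0 or effect.residual_sd == 0:
        raise ValueError("effect spec needs positive residual variance")
    n1_ref, n2_ref = effect.n_cells_per_group
    ratio = n1_ref / (n1_ref + n2_ref)
    rng = np.random.default_rng(seed)
    powers, ses = [], []
    for n_tot in n_grid:
        n1 = max(int(round(n_tot * ratio)), 2)
        n2 = max(int(n_tot) - n1, 2)
        eff = replace(effect, n_cells_per_group=(n1, n2))
        p, se = simulate_rejection(eff, alpha, n_sim,
                                   int(rng.integers(0, 2**31 - 1)))
        powers.append(p)
        ses.append(se)
    return PowerCurve(n_total=np.asarray(list(n_grid)),
                      power=np.asarray(powers), mc_se=np.asarray(ses),
                      alpha=alpha, n_sim=n_sim, effect_spec=effect)


def analytic_power(effect: CohortGenParams, n_total: int,
                   alpha: float = 0.05) -> float:
    """Closed-form power of the 1-df interaction trend test.

    With known variance components the interaction estimate is normal with
    variance ``(σ_u1² + σ²/Sxx)(1/n₁ + 1/n₂)`` (per-pA units, Sxx the
    per-cell centered sum of squares of current), so the LRT statistic is
    noncentral χ²₁ with λ = γ²/Var(γ̂).
    """
    n1_ref, n2_ref = effect.n_cells_per_group
    n1 = max(int(round(n_total * n1_ref / (n1_ref + n2_ref))), 2)
    n2 = max(int(n_total) - n1, 2)
    steps = np.array(DEPOL_STEP_GRID, dtype=float)
    sxx = float(((steps - STEP_CENTER) ** 2).sum())
    v_slope = effect.random_slope_sd ** 2 + effect.residual_sd ** 2 / sxx
    var_gamma = v_slope * (1.0 / n1 + 1.0 / n2)
    lam = effect.sahp_interaction_slope ** 2 / var_gamma
    crit = sps.chi2.isf(alpha, 1)
    return float(sps.ncx2.sf(crit, 1, lam))
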