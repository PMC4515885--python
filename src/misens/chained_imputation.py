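"""Multiple imputation by sequential regression (chained equations).

Missing cells of the wide one-row-per-subject table are filled by normal
linear regression with full parameter uncertainty ("proper" imputation): for
every target the residual variance is drawn from its scaled
inverse-chi-square posterior, the coefficients from their conditional
normal, and the imputed values from the resulting predictive normal.  Binary
covariates use a logistic sub-model with an asymptotic-normal coefficient
draw.

Two execution paths exist.  If the missingness pattern across target
variables is *monotone* (the missing sets can be nested by ordering the
variables), each dataset is completed in a single sequential pass, every
regression conditioning on previously completed variables.  Otherwise the
engine cycles chained equations for ``n_iterations`` rounds per dataset,
visiting targets in order of increasing missing fraction, and checks a
simple stationarity criterion on the trace of imputed-cell means.

Because both subject-level covariates and several summaries of the same
trajectories (trend coefficients, last two process values) enter the
predictor pool, the design matrices can be strongly collinear.  Before
fitting, predictors of each target are therefore reduced: while any variance
inflation factor exceeds ``vif_drop_threshold`` (default 10) the collinear
variable with the highest p-value in the target regression is dropped; if
the sampler then fails its stationarity check, reduction is repeated with
the stricter ``vif_fallback_threshold`` (default 5).

Rubin's rules for combining the m completed-data analyses are provided by
:func:`pool_estimates`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import (
    ConfigurationError,
    MisensError,
    NonConvergenceError,
    NonMonotoneError,
    PredictorReductionError,
    UnimputableVariableError,
)

_NON_MODEL_COLUMNS = ("subject_id", "M")


@dataclass
class ImputationSpec:
    """Settings of one multiple-imputation run.

    ``predictor_map`` optionally fixes the candidate predictor pool per
    target; by default every other numeric variable is a candidate.  With
    ``apply_vif_reduction=False`` a supplied map is used verbatim (useful
    when the reduction has already been performed on the same design).
    """

    m: int = 10
    n_iterations: int = 10
    predictor_map: Mapping[str, Sequence[str]] | None = None
    vif_drop_threshold: float = 10.0
    vif_fallback_threshold: float = 5.0
    apply_vif_reduction: bool = True
    clip_bounds: tuple[float, float] | None = None
    convergence_tol: float = 1e-2
    seed: int = 0

    def validate(self) -> None:
        if self.m < 2:
            raise ConfigurationError("m must be >= 2")
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if self.vif_drop_threshold <= 0 or self.vif_fallback_threshold <= 0:
            raise ConfigurationError("VIF thresholds must be positive")
        if self.vif_fallback_threshold >= self.vif_drop_threshold:
            raise ConfigurationError("vif_fallback_threshold must be < vif_drop_threshold")
        if self.convergence_tol <= 0:
            raise ConfigurationError("convergence_tol must be positive")


@dataclass
class ImputationResult:
    """m completed copies of the input table plus per-variable diagnostics."""

    datasets: list[pd.DataFrame]
    diagnostics: dict

    @property
    def m(self) -> int:
        return len(self.datasets)


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of m completed-data estimates."""

    estimate: float
    variance: float
    df: float
    within: float
    between: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))


# ---------------------------------------------------------------------------
# collinearity handling


def variance_inflation_factors(data: pd.DataFrame, predictors: Sequence[str]) -> pd.Series:
    """VIF_j = 1 / (1 - R^2_j) from regressing predictor j on the others.

    Computed on the rows complete for all listed predictors.  Constant
    columns and perfectly collinear predictors get VIF = inf.
    """
    preds = list(predictors)
    x = data[preds].dropna().to_numpy(dtype=float)
    vifs = {}
    for j, name in enumerate(preds):
        yj = x[:, j]
        if np.ptp(yj) == 0:
            vifs[name] = np.inf
            continue
        if len(preds) == 1:
            vifs[name] = 1.0
            continue
        others = np.column_stack([np.ones(x.shape[0]), np.delete(x, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        vifs[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(vifs)


def _ols_pvalues(data: pd.DataFrame, target: str, predictors: Sequence[str]) -> pd.Series:
    """Two-sided t-test p-values of each predictor in the complete-case OLS."""
    from scipy import stats as sps

    cc = data[[target, *predictors]].dropna()
    y = cc[target].to_numpy(dtype=float)
    x = np.column_stack([np.ones(len(cc)), cc[list(predictors)].to_numpy(dtype=float)])
    n, k = x.shape
    xtx_inv = np.linalg.pinv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    dof = max(n - k, 1)
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 1e-300))
    tvals = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(tvals), dof)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)  # degenerate columns: maximal p
    return pd.Series(pvals[1:], index=list(predictors))


def reduce_predictors(
    target: str,
    predictors: Sequence[str],
    data: pd.DataFrame,
    spec: ImputationSpec,
    enforce_fallback: bool = False,
) -> tuple[list[str], list[dict]]:
    """Drop collinear predictors until all VIFs fall below the threshold.

    While any VIF exceeds the threshold (``vif_drop_threshold``, or
    ``vif_fallback_threshold`` when ``enforce_fallback``), the member of the
    collinear set with the highest p-value in the complete-case regression of
    the target is removed first.  Returns the reduced list and the VIF
    history (one record per iteration).
    """
    threshold = spec.vif_fallback_threshold if enforce_fallback else spec.vif_drop_threshold
    current = list(predictors)
    history: list[dict] = []
    while True:
        if not current:
            raise PredictorReductionError(
                f"all predictors of '{target}' removed during collinearity reduction"
            )
        vifs = variance_inflation_factors(data, current)
        history.append({"predictors": list(current), "vif": vifs.to_dict()})
        vmax = vifs.max()
        if not (vmax > threshold):
            return current, history
        offenders = list(vifs.index[vifs > threshold])
        if len(offenders) == 1 and len(current) > 1:
            # a lone offender is collinear with *something*: include its
            # strongest partner so the p-value rule decides which one goes
            cc = data[current].dropna()
            corr = cc.corr().loc[offenders[0]].drop(offenders[0]).abs()
            offenders.append(corr.idxmax())
        pvals = _ols_pvalues(data, target, current)
        drop = pvals.loc[offenders].idxmax()
        current.remove(drop)


# ---------------------------------------------------------------------------
# elementary draws


def _draw_normal_linear(
    x_obs: np.ndarray, y_obs: np.ndarray, x_mis: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Bayesian normal-linear imputation draw.

    sigma^2 from its scaled inverse-chi-square posterior, beta from the
    conditional normal, imputed values from the predictive normal.
    """
    n, k = x_obs.shape
    xtx = x_obs.T @ x_obs
    xtx_inv = np.linalg.pinv(xtx)
    beta_hat = xtx_inv @ x_obs.T @ y_obs
    resid = y_obs - x_obs @ beta_hat
    dof = max(n - k, 1)
    sigma2 = float(resid @ resid) / dof * dof / max(rng.chisquare(dof), 1e-12)
    cov = xtx_inv * sigma2
    # symmetrize for the Cholesky of a pinv-based covariance
    cov = (cov + cov.T) / 2.0
    jitter = 1e-10 * max(np.trace(cov) / k, 1e-12)
    chol = np.linalg.cholesky(cov + jitter * np.eye(k))
    beta = beta_hat + chol @ rng.standard_normal(k)
    return x_mis @ beta + rng.normal(0.0, np.sqrt(sigma2), size=x_mis.shape[0])


def _draw_logistic(
    x_obs: np.ndarray, y_obs: np.ndarray, x_mis: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Logistic imputation draw for binary targets (asymptotic-normal beta)."""
    import statsmodels.api as sm

    try:
        fit = sm.Logit(y_obs, x_obs).fit(disp=0, maxiter=100)
        cov = np.asarray(fit.cov_params())
        cov = (cov + cov.T) / 2.0
        chol = np.linalg.cholesky(cov + 1e-10 * np.eye(cov.shape[0]))
        beta = np.asarray(fit.params) + chol @ rng.standard_normal(cov.shape[0])
        p = expit(x_mis @ beta)
    except Exception:
        # separation or non-convergence: fall back to the observed marginal
        p = np.full(x_mis.shape[0], y_obs.mean())
    return (rng.random(x_mis.shape[0]) < p).astype(float)


def _is_binary(values: np.ndarray) -> bool:
    u = np.unique(values[~np.isnan(values)])
    return u.size <= 2 and np.isin(u, (0.0, 1.0)).all()


def _design(data: pd.DataFrame, predictors: Sequence[str], rows: np.ndarray) -> np.ndarray:
    x = data.loc[rows, list(predictors)].to_numpy(dtype=float)
    return np.column_stack([np.ones(x.shape[0]), x])


def _impute_one_variable(
    data: pd.DataFrame,
    target: str,
    predictors: Sequence[str],
    miss_mask: pd.Series,
    rng: np.random.Generator,
    clip_bounds: tuple[float, float] | None,
) -> None:
    """Fill the missing cells of one target in place with a single draw."""
    obs_rows = data.index[~miss_mask]
    mis_rows = data.index[miss_mask]
    x_obs = _design(data, predictors, obs_rows)
    x_mis = _design(data, predictors, mis_rows)
    y_obs = data.loc[obs_rows, target].to_numpy(dtype=float)
    if _is_binary(y_obs):
        drawn = _draw_logistic(x_obs, y_obs, x_mis, rng)
    else:
        drawn = _draw_normal_linear(x_obs, y_obs, x_mis, rng)
        if clip_bounds is not None:
            drawn = np.clip(drawn, *clip_bounds)
    data.loc[mis_rows, target] = drawn


# ---------------------------------------------------------------------------
# monotone path


def missingness_is_monotone(block: pd.DataFrame, targets: Sequence[str]) -> bool:
    """True if the targets' missing sets are nested when ordered by count."""
    order = sorted(targets, key=lambda t: int(block[t].isna().sum()))
    prev = None
    for t in order:
        cur = set(block.index[block[t].isna()])
        if prev is not None and not prev.issubset(cur):
            return False
        prev = cur
    return True


def monotone_impute(
    block: pd.DataFrame,
    predictors: Mapping[str, Sequence[str]],
    spec: ImputationSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One completed copy of a monotone block (single sequential pass).

    Targets are imputed in order of increasing missing count; each regression
    conditions on the supplied predictors plus all previously completed
    targets.  Raises :class:`NonMonotoneError` for non-monotone blocks (use
    the chained path in :func:`impute` instead).
    """
    targets = [t for t in block.columns if block[t].isna().any()]
    if not missingness_is_monotone(block, targets):
        raise NonMonotoneError(
            "block missingness is not monotone; impute() with chained cycling is required"
        )
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    completed = block.copy()
    done: list[str] = []
    for t in sorted(targets, key=lambda c: int(block[c].isna().sum())):
        preds = list(predictors.get(t, [])) + done
        miss = block[t].isna()
        _impute_one_variable(completed, t, preds, miss, rng, spec.clip_bounds)
        done.append(t)
    return completed


# ---------------------------------------------------------------------------
# main engine


def _default_candidates(columns: Sequence[str], target: str) -> list[str]:
    return [c for c in columns if c != target]


def _model_columns(wide: pd.DataFrame) -> list[str]:
    num = wide.select_dtypes(include=[np.number]).columns
    return [c for c in num if c not in _NON_MODEL_COLUMNS]


def impute(wide: pd.DataFrame, spec: ImputationSpec) -> ImputationResult:
    """Generate m completed datasets from the wide table.

    Observed cells are preserved bit-exactly in every dataset.  With a
    monotone missingness pattern the single-pass monotone path is used;
    otherwise chained cycling with a stationarity check (falling back to the
    stricter VIF threshold once on declared non-convergence).
    """
    spec.validate()
    model_cols = _model_columns(wide)
    targets = [c for c in model_cols if wide[c].isna().any()]
    diagnostics: dict = {
        "targets": targets,
        "predictors": {},
        "vif_history": {},
        "monotone": None,
        "converged": True,
        "fallback_used": False,
        "trace": {},
    }
    if not targets:
        diagnostics["monotone"] = True
        return ImputationResult([wide.copy() for _ in range(spec.m)], diagnostics)

    for t in targets:
        if wide[t].notna().sum() == 0:
            raise UnimputableVariableError(f"target '{t}' has no observed cases")

    def _reduced_map(enforce_fallback: bool) -> dict[str, list[str]]:
        pmap: dict[str, list[str]] = {}
        for t in targets:
            if spec.predictor_map is not None and t in spec.predictor_map:
                cands = [c for c in spec.predictor_map[t] if c in wide.columns and c != t]
            else:
                cands = _default_candidates(model_cols, t)
            cands = [c for c in cands if wide[c].notna().any()]
            if spec.apply_vif_reduction:
                reduced, hist = reduce_predictors(t, cands, wide, spec, enforce_fallback)
            else:
                reduced, hist = list(cands), []
            if not reduced:
                raise PredictorReductionError(f"target '{t}' left without predictors")
            pmap[t] = reduced
            diagnostics["predictors"][t] = reduced
            diagnostics["vif_history"][t] = hist
        return pmap

    def _run(enforce_fallback: bool) -> tuple[list[pd.DataFrame], bool]:
        pmap = _reduced_map(enforce_fallback)
        master = np.random.SeedSequence(spec.seed)
        streams = [np.random.default_rng(s) for s in master.spawn(spec.m)]
        monotone = missingness_is_monotone(wide[targets], targets)
        diagnostics["monotone"] = monotone
        datasets: list[pd.DataFrame] = []
        converged = True
        if monotone:
            for rng in streams:
                completed = wide.copy()
                done: list[str] = []
                for t in sorted(targets, key=lambda c: int(wide[c].isna().sum())):
                    # fully observed predictors plus previously completed targets
                    avail = set(done) | {c for c in model_cols if not wide[c].isna().any()}
                    preds = list(dict.fromkeys([p for p in pmap[t] if p in avail] + done))
                    miss = wide[t].isna()
                    _impute_one_variable(completed, t, preds, miss, rng, spec.clip_bounds)
                    done.append(t)
                datasets.append(completed)
        else:
            visit = sorted(targets, key=lambda c: float(wide[c].isna().mean()))
            diagnostics["visit_order"] = visit
            for chain, rng in enumerate(streams):
                completed = wide.copy()
                # initialize by drawing from the observed marginals
                for t in targets:
                    miss = wide[t].isna()
                    pool = wide.loc[~miss, t].to_numpy(dtype=float)
                    completed.loc[miss, t] = rng.choice(pool, size=int(miss.sum()), replace=True)
                trace = {t: [] for t in targets}
                for _ in range(spec.n_iterations):
                    for t in visit:
                        miss = wide[t].isna()
                        preds = [p for p in pmap[t]]
                        _impute_one_variable(completed, t, preds, miss, rng, spec.clip_bounds)
                        trace[t].append(float(completed.loc[miss, t].mean()))
                diagnostics["trace"][f"chain_{chain}"] = trace
                if spec.n_iterations >= 4:
                    # stationarity: drift of the imputed-cell mean between the
                    # two halves of the trace must be explicable by draw noise
                    # (proper-MI traces fluctuate even at stationarity, so a
                    # raw per-cycle relative-change rule would always fire)
                    for t in targets:
                        tr = np.asarray(trace[t])
                        half = tr.size // 2
                        a, b = tr[:half], tr[half:]
                        noise = np.std(np.concatenate([a - a.mean(), b - b.mean()]))
                        se = noise * np.sqrt(1.0 / a.size + 1.0 / b.size)
                        scale = max(float(wide[t].std(skipna=True)), 1e-12)
                        drift = abs(b.mean() - a.mean())
                        if drift > spec.convergence_tol * scale + 4.0 * se:
                            converged = False
                datasets.append(completed)
        return datasets, converged

    datasets, converged = _run(enforce_fallback=False)
    if not converged:
        diagnostics["fallback_used"] = True
        datasets, converged = _run(enforce_fallback=True)
        if not converged:
            diagnostics["converged"] = False
            raise NonConvergenceError(
                f"chained imputation failed its stationarity check; diagnostics: "
                f"targets={targets}, predictors={diagnostics['predictors']}"
            )
    diagnostics["converged"] = converged
    return ImputationResult(datasets, diagnostics)


# ---------------------------------------------------------------------------
# Rubin's rules


def pool_estimates(
    per_dataset_estimates: Sequence[float], per_dataset_variances: Sequence[float]
) -> PooledEstimate:
    """Combine m completed-data estimates: total variance W + (1+1/m)B."""
    q = np.asarray(per_dataset_estimates, dtype=float)
    u = np.asarray(per_dataset_variances, dtype=float)
    if q.size < 2 or u.size != q.size:
        raise MisensError("pooling requires m >= 2 paired estimates and variances")
    m = q.size
    qbar = float(q.mean())
    within = float(u.mean())
    between = float(q.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    if between == 0.0:
        df = float(np.inf)
    else:
        r = (1.0 + 1.0 / m) * between
        df = float((m - 1) * (1.0 + within / r) ** 2)
    return PooledEstimate(estimate=qbar, variance=total, df=df, within=within, between=between)
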