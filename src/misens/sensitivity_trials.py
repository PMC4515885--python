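"""Simulation trials assessing robustness of the imputation to MNAR dropout.

The sensitivity analysis takes a complete, classified reference dataset
(every subject with pre, process history and outcome) and repeatedly
resamples it while deleting outcomes under a controlled mechanism:

MAR1
    Bootstrap the reference; delete the post-assessment outcome of d cases
    still not improved at the *last process measurement* (deletion depends
    only on observed data -> MAR).
MAR2
    Bootstrap the reference; delete the *last process measurement* of d
    cases not improved at the penultimate measurement; the outcome is then
    evaluated at the last process measurement (post values are ignored).
MNAR1
    Composition-preserving resampling: b improved and c not-improved cases
    keep their outcomes, d further not-improved cases lose them (deletion
    depends on the - hidden - outcome classification: worst-case MNAR).
MNAR2
    As MNAR1 but the d deleted cases are improved (opposite-direction MNAR).

Each replicate is analyzed with multiple imputation (optionally with the
delta-adjustment or selection-model MNAR corrections) and the two simple
comparators, complete-case and last-observation-carried-forward.  The mean
effect size over the pre-deletion replicates serves as the "true" value
gamma; estimators are judged by percentage bias (robust if |PB| <= 5%),
standardized bias, and percentile confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chained_imputation import ImputationSpec, impute, reduce_predictors
from .exceptions import ConfigurationError, MisensError, TrialError
from .mnar_adjustment import SelectionDrawSpec, delta_adjust, mnar_impute
from .outcome_metrics import (
    IMPROVED,
    NOT_IMPROVED,
    ROBUSTNESS_PB_LIMIT,
    ClinicalSignificanceConfig,
    cc_effect,
    classify_cases,
    effect_size,
    locf_effect,
    percentage_bias,
    standardized_bias,
)
from .synthetic_cohort import CohortConfig, generate_cohort
from .trajectory_features import assemble_wide

TRIALS = ("MAR1", "MAR2", "MNAR1", "MNAR2")
ESTIMATORS = ("MI", "CC", "LOCF", "MI_delta", "MI_selection")

#: covariates never used as imputation predictors (identifiers / leakage)
_NON_PREDICTORS = ("subject_id", "M", "category", "improved", "deleted")


@dataclass
class TrialComposition:
    """Resampling composition: b improved + c not-improved observed, d deleted."""

    b: int = 132
    c: int = 78
    d: int = 50
    d_category: str = NOT_IMPROVED

    def validate(self) -> None:
        if min(self.b, self.c, self.d) < 0:
            raise ConfigurationError("composition counts must be >= 0")
        if self.d_category not in (IMPROVED, NOT_IMPROVED):
            raise ConfigurationError("d_category must be 'improved' or 'not_improved'")

    @property
    def size(self) -> int:
        return self.b + self.c + self.d


@dataclass
class TrialConfig:
    trial: str = "MNAR1"
    composition: TrialComposition = field(default_factory=TrialComposition)
    reps: int = 1000
    imputation_spec: ImputationSpec = field(default_factory=lambda: ImputationSpec(m=5))
    estimators: Sequence[str] = ("MI", "CC", "LOCF")
    delta: float | None = None
    selection_spec: SelectionDrawSpec = field(default_factory=SelectionDrawSpec)
    ci_level: float = 0.95
    cs_config: ClinicalSignificanceConfig = field(default_factory=ClinicalSignificanceConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.trial not in TRIALS:
            raise ConfigurationError(f"trial must be one of {TRIALS}")
        if self.reps < 1:
            raise ConfigurationError("reps must be >= 1")
        unknown = set(self.estimators) - set(ESTIMATORS)
        if unknown:
            raise ConfigurationError(f"unknown estimators {sorted(unknown)}")
        if "MI_delta" in self.estimators and self.delta is None:
            raise ConfigurationError("MI_delta requires a delta value")
        if not 0.0 < self.ci_level < 1.0:
            raise ConfigurationError("ci_level must lie in (0, 1)")
        self.composition.validate()
        self.imputation_spec.validate()


@dataclass
class EstimatorSummary:
    estimates: np.ndarray
    mean: float
    ci: tuple[float, float]
    percentage_bias: float
    standardized_bias: float
    mc_se_pb: float


@dataclass
class TrialResult:
    trial: str
    gamma: float
    estimators: dict[str, EstimatorSummary]
    delta_overestimate: float | None
    reps: int
    config: TrialConfig


@dataclass
class RobustnessAssessment:
    robust: bool
    percentage_bias: float
    recommended_delta: float | None


# ---------------------------------------------------------------------------
# reference construction


def calibrated_reference(seed: int = 0, config: CohortConfig | None = None) -> pd.DataFrame:
    """Complete classified wide reference from the calibrated generator."""
    config = config or CohortConfig(seed=seed)
    cohort = generate_cohort(config)
    wide = assemble_wide(cohort).cases
    ref = classify_cases(wide)
    if ref["post_oq"].isna().any():
        raise MisensError("reference must be complete on the outcome")
    return ref


# ---------------------------------------------------------------------------
# resampling


def _relabel(sample: pd.DataFrame) -> pd.DataFrame:
    out = sample.reset_index(drop=True)
    out["subject_id"] = np.arange(len(out))
    return out


def sample_composition(
    reference: pd.DataFrame, composition: TrialComposition, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw a composition-preserving replicate; outcomes of the d cases deleted.

    Draws with replacement b improved and c not-improved cases (outcome
    observed) and d cases of ``d_category`` whose outcome values are marked
    deleted.  The returned frame keeps the true outcome in ``post_true`` and
    flags the deleted rows in ``deleted``.
    """
    composition.validate()
    improved_pool = reference.index[reference["category"] == IMPROVED].to_numpy()
    not_improved_pool = reference.index[
        (reference["category"].notna()) & (reference["category"] != IMPROVED)
    ].to_numpy()
    pools = {IMPROVED: improved_pool, NOT_IMPROVED: not_improved_pool}
    for cat, need in ((IMPROVED, composition.b), (NOT_IMPROVED, composition.c)):
        if need > 0 and pools[cat].size == 0:
            raise TrialError(f"reference contains no '{cat}' cases")
    if composition.d > 0 and pools[composition.d_category].size == 0:
        raise TrialError(f"reference contains no '{composition.d_category}' cases")

    picks = np.concatenate(
        [
            rng.choice(improved_pool, size=composition.b, replace=True),
            rng.choice(not_improved_pool, size=composition.c, replace=True),
            rng.choice(pools[composition.d_category], size=composition.d, replace=True),
        ]
    )
    rep = _relabel(reference.loc[picks])
    rep["post_true"] = rep["post_oq"]
    rep["deleted"] = False
    if composition.d > 0:
        rep.loc[rep.index[-composition.d :], "deleted"] = True
    return rep


def _bootstrap(reference: pd.DataFrame, n: int, rng: np.random.Generator) -> pd.DataFrame:
    picks = rng.integers(0, len(reference), size=n)
    return _relabel(reference.iloc[picks])


# ---------------------------------------------------------------------------
# per-trial wiring

#: outcome / carried-forward / eligibility columns per trial
_TRIAL_OUTCOME = {
    "MAR1": "post_oq",
    "MNAR1": "post_oq",
    "MNAR2": "post_oq",
    "MAR2": "oq_total_last",
}
_TRIAL_CARRY = {
    "MAR1": "oq_total_last",
    "MNAR1": "oq_total_last",
    "MNAR2": "oq_total_last",
    "MAR2": "oq_total_penult",
}


def _predictor_pool(replicate: pd.DataFrame, trial: str, outcome: str) -> list[str]:
    cols = [
        c
        for c in replicate.select_dtypes(include=[np.number]).columns
        if c not in _NON_PREDICTORS and c not in (outcome, "post_true")
    ]
    if trial == "MAR2":
        # the target is the last process measurement: anything measured on
        # that occasion or summarizing it (trends, last-two values, the
        # ignored post assessment) must not predict it
        cols = [
            c
            for c in cols
            if not c.endswith("_last") and not c.endswith("_int") and not c.endswith("_slope")
            and c != "post_oq"
        ]
    return cols


def _make_replicate(
    reference: pd.DataFrame, config: TrialConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """One replicate with ``deleted`` flag and true outcome stashed."""
    trial = config.trial
    comp = config.composition
    threshold = config.cs_config.reliable_change_threshold
    if trial in ("MNAR1", "MNAR2"):
        want = NOT_IMPROVED if trial == "MNAR1" else IMPROVED
        if comp.d_category != want:
            comp = replace(comp, d_category=want)
        rep = sample_composition(reference, comp, rng)
        rep["post_true"] = rep["post_oq"]
        return rep

    rep = _bootstrap(reference, comp.size, rng)
    if trial == "MAR1":
        eligible = (rep["pre_oq"] - rep["oq_total_last"]) < threshold
        outcome = "post_oq"
    else:  # MAR2
        eligible = (rep["pre_oq"] - rep["oq_total_penult"]) < threshold
        outcome = "oq_total_last"
    idx = rep.index[eligible].to_numpy()
    if idx.size < comp.d:
        raise TrialError(
            f"{trial}: only {idx.size} cases eligible for deletion, need {comp.d}"
        )
    chosen = rng.choice(idx, size=comp.d, replace=False)
    rep["post_true"] = rep[outcome]
    rep["deleted"] = False
    rep.loc[chosen, "deleted"] = True
    return rep


def percentile_ci(estimates, level: float = 0.95) -> tuple[float, float]:
    """Empirical percentile interval at (1-level)/2 and 1-(1-level)/2."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise MisensError("percentile CI needs at least two estimates")
    if not 0.0 < level < 1.0:
        raise MisensError("level must lie in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(est, [100.0 * alpha, 100.0 * (1.0 - alpha)])
    return float(lo), float(hi)


def run_trial(reference: pd.DataFrame, config: TrialConfig) -> TrialResult:
    """Run one simulation trial: R replicates, all configured estimators.

    The truth gamma is the mean effect size over the pre-deletion replicates.
    Per-replicate random streams are spawned from the master seed, so any
    replicate is reproducible in isolation.
    """
    config.validate()
    if reference["category"].isna().any():
        raise TrialError("reference contains unclassifiable cases")
    trial = config.trial
    outcome = _TRIAL_OUTCOME[trial]
    carry = _TRIAL_CARRY[trial]

    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(config.reps)
    estimates: dict[str, list[float]] = {e: [] for e in config.estimators}
    truths: list[float] = []
    delta_over: list[float] = []
    needs_mi = any(e.startswith("MI") for e in config.estimators)

    for seq in streams:
        rng = np.random.default_rng(seq)
        rep = _make_replicate(reference, config, rng)
        truths.append(effect_size(rep["pre_oq"], rep["post_true"]))

        analysis = rep.copy()
        analysis.loc[analysis["deleted"], outcome] = np.nan
        analysis["M"] = analysis["deleted"].astype(int)

        if "CC" in config.estimators:
            estimates["CC"].append(
                cc_effect(analysis, post_col=outcome).gamma_hat
            )
        if "LOCF" in config.estimators:
            estimates["LOCF"].append(
                locf_effect(analysis, post_col=outcome, carry_col=carry).gamma_hat
            )
        if not needs_mi:
            continue

        pool = _predictor_pool(rep, trial, outcome)
        model = analysis[["subject_id", "M", outcome, *pool]]
        ispec = config.imputation_spec
        if ispec.apply_vif_reduction:
            reduced, _ = reduce_predictors(outcome, pool, model, ispec)
        else:
            reduced = list(ispec.predictor_map.get(outcome, pool)) if ispec.predictor_map else pool
        rep_seed = int(seq.generate_state(2)[1] % (2**31))
        rep_spec = replace(
            ispec,
            predictor_map={outcome: reduced},
            apply_vif_reduction=False,
            seed=rep_seed,
        )
        deleted_mask = analysis["deleted"].to_numpy()
        true_out = rep.loc[deleted_mask, "post_true"].to_numpy(dtype=float)

        mar_result = None
        if "MI" in config.estimators or "MI_delta" in config.estimators:
            mar_result = impute(model, rep_spec)
        if "MI" in config.estimators:
            gammas = [
                effect_size(rep["pre_oq"], ds[outcome]) for ds in mar_result.datasets
            ]
            estimates["MI"].append(float(np.mean(gammas)))
            over = [
                float(np.mean(true_out - ds.loc[deleted_mask, outcome].to_numpy(dtype=float)))
                for ds in mar_result.datasets
            ]
            delta_over.append(float(np.mean(over)))
        if "MI_delta" in config.estimators:
            adj = delta_adjust(mar_result, config.delta, outcome=outcome)
            gammas = [effect_size(rep["pre_oq"], ds[outcome]) for ds in adj.datasets]
            estimates["MI_delta"].append(float(np.mean(gammas)))
        if "MI_selection" in config.estimators:
            sel = mnar_impute(
                model,
                replace(rep_spec, seed=int(seq.generate_state(3)[2] % (2**31))),
                mode="selection",
                draw_spec=config.selection_spec,
                outcome=outcome,
            )
            gammas = [effect_size(rep["pre_oq"], ds[outcome]) for ds in sel.datasets]
            estimates["MI_selection"].append(float(np.mean(gammas)))

    gamma = float(np.mean(truths))
    summaries: dict[str, EstimatorSummary] = {}
    for name, vals in estimates.items():
        arr = np.asarray(vals, dtype=float)
        mean = float(arr.mean())
        pb = percentage_bias(mean, gamma)
        sb = standardized_bias(arr, gamma) if arr.size >= 2 and arr.std(ddof=1) > 0 else float("nan")
        ci = percentile_ci(arr, config.ci_level) if arr.size >= 2 else (mean, mean)
        mc_se = float(100.0 * arr.std(ddof=1) / np.sqrt(arr.size) / abs(gamma)) if arr.size >= 2 else float("nan")
        summaries[name] = EstimatorSummary(
            estimates=arr,
            mean=mean,
            ci=ci,
            percentage_bias=pb,
            standardized_bias=sb,
            mc_se_pb=mc_se,
        )
    return TrialResult(
        trial=trial,
        gamma=gamma,
        estimators=summaries,
        delta_overestimate=float(np.mean(delta_over)) if delta_over else None,
        reps=config.reps,
        config=config,
    )


def assess_robustness(trial_result: TrialResult, estimator: str = "MI") -> RobustnessAssessment:
    """Robust iff |percentage bias| <= 5%; otherwise recommend a delta.

    The recommended delta is the mean over-estimation of the deleted cases'
    pre-post difference (true minus imputed outcome, averaged over imputed
    datasets and replicates); feeding it back through the delta mode shifts
    imputed outcomes so the residual bias is near zero.
    """
    if estimator not in trial_result.estimators:
        raise MisensError(f"estimator '{estimator}' not present in trial result")
    pb = trial_result.estimators[estimator].percentage_bias
    robust = abs(pb) <= ROBUSTNESS_PB_LIMIT
    delta = None
    if not robust:
        if trial_result.delta_overestimate is None:
            raise MisensError("trial was run without the MI estimator; no delta available")
        delta = trial_result.delta_overestimate
    return RobustnessAssessment(robust=robust, percentage_bias=pb, recommended_delta=delta)


def summary_table(results: Sequence[TrialResult]) -> pd.DataFrame:
    """Flat estimator x trial table: mean, CI bounds, PB, SB, truth."""
    rows = []
    for res in results:
        for name, s in res.estimators.items():
            rows.append(
                {
                    "trial": res.trial,
                    "estimator": name,
                    "gamma": res.gamma,
                    "mean": s.mean,
                    "ci_lo": s.ci[0],
                    "ci_hi": s.ci[1],
                    "percentage_bias": s.percentage_bias,
                    "standardized_bias": s.standardized_bias,
                    "mc_se_pb": s.mc_se_pb,
                }
            )
    return pd.DataFrame(rows)
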