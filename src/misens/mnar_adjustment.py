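"""MNAR imputation built on top of the MAR machinery.

Two corrections translate MAR imputations into missing-not-at-random
scenarios in which non-respondents are assumed more dysfunctional than
respondents with the same covariate values:

Pattern-mixture delta adjustment
    ``E(Y | X, M=1) = E(Y | X, M=0) + delta``: a constant is added to every
    imputed outcome value of cases with a missing outcome.  The size of delta
    can be supplied directly or taken from the sensitivity-trial bias
    assessment (the mean over-estimation of the deleted cases' pre-post
    difference).

Selection-model weighted draw
    For each missing cell, ``n_candidates`` MAR imputations are generated and
    sorted ascending into a vector v; ``n_candidates`` uniform random numbers
    on (lower, upper) are sorted ascending into a weight vector p (normalized
    to sum 1); the definitive imputation is drawn from v with probabilities
    p.  Because larger candidates receive stochastically larger weights, the
    selected values occupy higher percentiles than a plain MAR draw --
    encoding "the higher the dysfunction, the higher the dropout
    probability" (an MNAR-linear association; other mechanisms can be
    plugged in via ``weight_generator``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd

from .chained_imputation import ImputationResult, ImputationSpec, impute
from .exceptions import ConfigurationError

OUTCOME_COL = "post_oq"
MISSING_COL = "M"


@dataclass(frozen=True)
class DeltaAdjustment:
    """Constant (outcome points) added to imputed values of M=1 cases."""

    delta: float

    def validate(self) -> None:
        if not np.isfinite(self.delta):
            raise ConfigurationError("delta must be finite")


@dataclass
class SelectionDrawSpec:
    """Weighted-draw settings of the selection-model correction."""

    n_candidates: int = 10
    lower: float = 0.0
    upper: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_candidates < 2:
            raise ConfigurationError("n_candidates must be >= 2")
        if not 0.0 <= self.lower:
            raise ConfigurationError("lower must be >= 0")
        if self.upper <= self.lower:
            raise ConfigurationError("upper must be > lower")


def delta_adjust(
    result: ImputationResult,
    delta: DeltaAdjustment | float,
    outcome: str = OUTCOME_COL,
    missing_col: str = MISSING_COL,
) -> ImputationResult:
    """Shift every imputed outcome cell by delta in all m datasets.

    Observed cells (M=0) are untouched, bit-exactly.  Applied to the outcome
    variable only (the pattern-mixture equation is written for Y).
    """
    if not isinstance(delta, DeltaAdjustment):
        delta = DeltaAdjustment(float(delta))
    delta.validate()
    shifted = []
    for ds in result.datasets:
        out = ds.copy()
        mask = out[missing_col] == 1
        out.loc[mask, outcome] = out.loc[mask, outcome] + delta.delta
        shifted.append(out)
    diagnostics = dict(result.diagnostics)
    diagnostics["delta_adjustment"] = delta.delta
    return ImputationResult(shifted, diagnostics)


def selection_draw(
    candidates,
    spec: SelectionDrawSpec,
    rng: np.random.Generator | None = None,
    weight_generator: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> float:
    """Draw one definitive value from sorted candidate imputations.

    Candidates are sorted ascending; the weight vector is a sorted sample of
    ``n_candidates`` uniforms on (lower, upper), normalized to sum 1 per draw
    (the natural completion: a probability vector must sum to one, and ten
    U(0, 0.2) draws sum to one in expectation).  ``weight_generator`` may
    replace the uniform mechanism to encode other M-Y associations.
    """
    spec.validate()
    v = np.sort(np.asarray(candidates, dtype=float))
    if v.size != spec.n_candidates:
        raise ConfigurationError(
            f"expected {spec.n_candidates} candidates, got {v.size}"
        )
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if weight_generator is None:
        w = rng.uniform(spec.lower, spec.upper, size=spec.n_candidates)
    else:
        w = np.asarray(weight_generator(rng, spec.n_candidates), dtype=float)
    p = np.sort(w)
    p = p / p.sum()
    return float(rng.choice(v, p=p))


def mnar_impute(
    wide: pd.DataFrame,
    spec: ImputationSpec,
    mode: str,
    delta: DeltaAdjustment | float | None = None,
    draw_spec: SelectionDrawSpec | None = None,
    outcome: str = OUTCOME_COL,
    missing_col: str = MISSING_COL,
) -> ImputationResult:
    """Impute under an MNAR assumption.

    ``mode='delta'``: MAR imputation followed by :func:`delta_adjust`.
    ``mode='selection'``: each of the m final datasets consumes an
    independent set of ``n_candidates`` MAR imputations per missing cell and
    an independent weight draw, preserving between-imputation variability.
    """
    if mode == "delta":
        if delta is None:
            raise ConfigurationError("delta mode requires a delta value")
        return delta_adjust(impute(wide, spec), delta, outcome, missing_col)
    if mode != "selection":
        raise ConfigurationError("mode must be 'delta' or 'selection'")

    draw_spec = draw_spec or SelectionDrawSpec()
    draw_spec.validate()
    master = np.random.SeedSequence(spec.seed)
    final_datasets: list[pd.DataFrame] = []
    mask = wide[outcome].isna()
    mis_rows = wide.index[mask]
    diagnostics: dict = {}
    for l, seq in enumerate(master.spawn(spec.m)):
        child_seed = int(seq.generate_state(1)[0] % (2**31))
        cand_spec = replace(spec, m=draw_spec.n_candidates, seed=child_seed)
        cand_result = impute(wide, cand_spec)
        if l == 0:
            diagnostics = dict(cand_result.diagnostics)
        rng = np.random.default_rng(seq.spawn(1)[0])
        cand_matrix = np.column_stack(
            [ds.loc[mis_rows, outcome].to_numpy(dtype=float) for ds in cand_result.datasets]
        )
        completed = cand_result.datasets[0].copy()
        chosen = [
            selection_draw(cand_matrix[i], draw_spec, rng=rng) for i in range(len(mis_rows))
        ]
        completed.loc[mis_rows, outcome] = chosen
        final_datasets.append(completed)
    diagnostics["mnar_mode"] = "selection"
    diagnostics["selection_spec"] = {
        "n_candidates": draw_spec.n_candidates,
        "lower": draw_spec.lower,
        "upper": draw_spec.upper,
    }
    return ImputationResult(final_datasets, diagnostics)
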