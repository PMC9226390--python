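"""Staged multilevel model selection for the ordinal outcome scores.

The ladder grows a cumulative-link mixed model in six stages, mirroring a
level-1 (trial) / level-2 (person) decomposition:

* **X0** — random participant intercept plus trial Order.
* **X1** — + Sequence and Condition (the experimental variables).
* **X2** — + person-level main effects, kept only when a likelihood-ratio
  test shows improvement.
* **X3** — + Condition:covariate (optionally Sequence:covariate)
  interactions, same retention rule.
* **X4** — random Order slope per participant + Order:covariate terms;
  Order^2 and Order:Condition are tried and dropped when not improving.
* **X5** — backward simplification: a term is removed whenever the smaller
  model is not significantly worse by the LR test.

Every comparison p-value is recorded; a non-convergent stage is marked
failed and the ladder continues from the last converged stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .ordinal import ModelSpec, OrdinalFit, fit_model, lr_test

ORDER_SQ = "Order^2"


@dataclass
class LadderStage:
    name: str
    spec: ModelSpec
    fit: OrdinalFit | None
    p_vs_previous: float | None
    note: str = ""


@dataclass
class LadderResult:
    response: str
    stages: list[LadderStage]

    @property
    def final(self) -> LadderStage:
        fitted = [s for s in self.stages if s.fit is not None]
        return fitted[-1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.stages:
            rows.append(
                {
                    "name": s.name,
                    "formula": s.spec.formula(),
                    "aic": s.fit.aic if s.fit else None,
                    "loglik": s.fit.loglik if s.fit else None,
                    "n_params": s.fit.n_params if s.fit else None,
                    "p_vs_previous": s.p_vs_previous,
                    "note": s.note,
                }
            )
        return pd.DataFrame(rows)


def _safe_fit(spec: ModelSpec, data: pd.DataFrame, fit_kw: dict) -> OrdinalFit | None:
    try:
        fit = fit_model(spec, data, **fit_kw)
    except Exception as exc:  # pragma: no cover - defensive
        warnings.warn(f"stage fit failed for {spec.formula()}: {exc}")
        return None
    return fit


def _forward(
    current_spec: ModelSpec,
    current_fit: OrdinalFit,
    candidates: Sequence[tuple[str, ...]],
    data: pd.DataFrame,
    alpha: float,
    fit_kw: dict,
) -> tuple[ModelSpec, OrdinalFit, list[str]]:
    """Sequentially add each candidate term, keeping it when LR p < alpha."""
    kept = []
    for term in candidates:
        trial_spec = current_spec.add_term(term)
        trial_fit = _safe_fit(trial_spec, data, fit_kw)
        if trial_fit is None:
            continue
        if lr_test(current_fit, trial_fit) < alpha:
            current_spec, current_fit = trial_spec, trial_fit
            kept.append(":".join(term))
    return current_spec, current_fit, kept


def run_ladder(
    data: pd.DataFrame,
    response: str,
    person_covariates: Sequence[str],
    *,
    group: str = "Participant",
    order_var: str = "Order",
    condition_var: str = "Condition",
    sequence_var: str = "Sequence",
    alpha: float = 0.05,
    include_sequence: bool = True,
    test_sequence_interactions: bool = True,
    test_order_extras: bool = True,
    fit_kw: dict | None = None,
) -> LadderResult:
    """Execute the X0..X5 staged model build for one outcome score."""
    fit_kw = {"se": False, **(fit_kw or {})}
    data = data.copy()
    data[ORDER_SQ] = data[order_var].astype(float) ** 2
    stages: list[LadderStage] = []

    # X0: random intercept + Order
    spec = ModelSpec(response, ((order_var,),), ("1",), group)
    fit = _safe_fit(spec, data, fit_kw)
    stages.append(LadderStage("X0", spec, fit, None))
    if fit is None:
        return LadderResult(response, stages)
    prev_spec, prev_fit = spec, fit

    # X1: + Sequence + Condition
    spec = prev_spec
    if include_sequence:
        spec = spec.add_term((sequence_var,))
    spec = spec.add_term((condition_var,))
    fit = _safe_fit(spec, data, fit_kw)
    if fit is not None:
        stages.append(LadderStage("X1", spec, fit, lr_test(prev_fit, fit)))
        prev_spec, prev_fit = spec, fit
    else:
        stages.append(LadderStage("X1", spec, None, None, note="failed"))

    # X2: person-level main effects
    spec, fit, kept = _forward(
        prev_spec, prev_fit, [(z,) for z in person_covariates], data, alpha, fit_kw
    )
    stages.append(
        LadderStage("X2", spec, fit, lr_test(prev_fit, fit), note=f"kept: {kept}")
    )
    prev_spec, prev_fit = spec, fit

    # X3: Condition (and Sequence) interactions with person covariates
    candidates = [(condition_var, z) for z in person_covariates]
    if include_sequence and test_sequence_interactions:
        candidates += [(sequence_var, z) for z in person_covariates]
    spec, fit, kept = _forward(prev_spec, prev_fit, candidates, data, alpha, fit_kw)
    stages.append(
        LadderStage("X3", spec, fit, lr_test(prev_fit, fit), note=f"kept: {kept}")
    )
    prev_spec, prev_fit = spec, fit

    # X4: random Order slope + Order:covariate terms (+ Order^2, Order:Condition trials)
    spec = prev_spec.with_random(("1", order_var))
    fit = _safe_fit(spec, data, fit_kw)
    note4 = []
    if fit is None:
        stages.append(LadderStage("X4", spec, None, None, note="failed"))
        spec, fit = prev_spec, prev_fit
    else:
        spec, fit, kept = _forward(
            spec, fit, [(order_var, z) for z in person_covariates], data, alpha, fit_kw
        )
        note4.append(f"kept: {kept}")
        if test_order_extras:
            for extra in ((ORDER_SQ,), (order_var, condition_var)):
                trial_spec = spec.add_term(extra)
                trial_fit = _safe_fit(trial_spec, data, fit_kw)
                if trial_fit is not None and lr_test(fit, trial_fit) < alpha:
                    spec, fit = trial_spec, trial_fit
                    note4.append(f"retained {':'.join(extra)}")
                else:
                    note4.append(f"dropped {':'.join(extra)}")
        stages.append(
            LadderStage("X4", spec, fit, lr_test(prev_fit, fit), note="; ".join(note4))
        )
    prev_spec, prev_fit = spec, fit

    # X5: backward simplification
    spec, fit = prev_spec, prev_fit
    dropped = []
    while True:
        best_term, best_p, best = None, alpha, None
        for term in spec.terms:
            reduced_spec = spec.drop_term(term)
            if not reduced_spec.terms:
                continue
            reduced_fit = _safe_fit(reduced_spec, data, fit_kw)
            if reduced_fit is None:
                continue
            p = lr_test(reduced_fit, fit)
            if p >= best_p:
                best_term, best_p, best = term, p, (reduced_spec, reduced_fit)
        if best is None:
            break
        spec, fit = best
        dropped.append(":".join(best_term))
    stages.append(
        LadderStage(
            "X5", spec, fit, lr_test(fit, prev_fit), note=f"dropped: {dropped}"
        )
    )
    return LadderResult(response, stages)
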