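"""Sequential Bayes-factor design analysis (SBF + maxN).

Monte-Carlo estimation of the stopping behaviour of a sequential
sampling plan: start with ``n_min`` listeners per group, compute the
interaction Bayes factor, then add one listener per group (sequential
accrual -- earlier listeners are kept) and recompute until the BF
crosses an upper or lower evidence threshold or ``n_max`` per group is
reached.

Scores are generated from Gaussian cell distributions supplied by the
caller (the generating means/SDs of the original power analysis came
from an external publication and are therefore an *input* here, not a
built-in); an example configuration ships with the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import mixed_anova_bf

__all__ = [
    "EffectModel",
    "DesignSpec",
    "DesignOutcome",
    "example_effect_model",
    "sbf_maxn",
]


@dataclass(frozen=True)
class EffectModel:
    """Gaussian generating model: one (mean, sd) per group x within-cell.

    ``cells`` maps a within-cell label (e.g. ``("0.15", "stationary")``)
    to per-group (mean, sd) pairs in RAU.  ``factors`` names the
    within-subject factors, matching the tuple positions of the cell
    labels.  ``subject_sd`` adds a shared random intercept per listener.
    """

    factors: tuple[str, ...]
    cells: dict[tuple, dict[str, tuple[float, float]]]
    subject_sd: float = 0.0

    def __post_init__(self):
        for cell, groups in self.cells.items():
            if len(cell) != len(self.factors):
                raise ValueError(
                    f"cell {cell} does not match factors {self.factors}")
            for g, (mu, sd) in groups.items():
                if sd <= 0:
                    raise ValueError(
                        f"degenerate SD {sd} in cell {cell}, group {g}")


def example_effect_model(interaction_rau: float = 0.0,
                         sd: float = 13.0,
                         subject_sd: float = 10.0) -> EffectModel:
    """A documented 2 (RT) x 2 (group) example configuration.

    Baseline scores drop by 25 RAU from low to high reverberation in
    both groups; ``interaction_rau`` is added to the HI drop (so 0 is an
    exact null).  The SDs are in the range typical of intelligibility
    scores in RAU.
    """
    lo, drop = 70.0, 25.0
    return EffectModel(
        factors=("rt",),
        cells={
            ("0.15",): {"NH": (lo, sd), "HI": (lo - 5.0, sd)},
            ("1.5",): {"NH": (lo - drop, sd),
                       "HI": (lo - 5.0 - drop - interaction_rau, sd)},
        },
        subject_sd=subject_sd,
    )


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of the SBF+maxN plan."""

    effect_model: EffectModel
    n_min: int = 16
    n_max: int = 32
    step: int = 1
    bf_upper: float = 3.0
    bf_lower: float = 1.0 / 3.0
    n_reps: int = 200
    target_interaction: str = "rt:group"
    bf_method: str = "bic"          # "bic" (fast) or "laplace"
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_min > self.n_max:
            raise ValueError("n_min must be <= n_max")
        if not (self.bf_lower < 1.0 < self.bf_upper):
            raise ValueError("need bf_lower < 1 < bf_upper")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.step < 1:
            raise ValueError("step must be >= 1")


@dataclass(frozen=True)
class DesignOutcome:
    """Aggregated stopping behaviour over the Monte-Carlo replicates."""

    p_confirm_null: float
    p_confirm_alt: float
    p_inconclusive: float
    p_leaning_null_at_maxn: float
    mean_n: float                   # mean total listeners at stopping
    n_reps: int
    bf_method: str

    def __post_init__(self):
        total = (self.p_confirm_null + self.p_confirm_alt
                 + self.p_inconclusive)
        if abs(total - 1.0) > 1.0 / max(self.n_reps, 1):
            raise ValueError(f"stopping probabilities sum to {total}")


def _draw_listener(model: EffectModel, group: str,
                   rng: np.random.Generator) -> dict[tuple, float]:
    b = rng.normal(0.0, model.subject_sd) if model.subject_sd > 0 else 0.0
    return {
        cell: b + rng.normal(*groups[group])
        for cell, groups in model.cells.items()
    }


def _to_table(listeners: dict[str, list[dict]], model: EffectModel
              ) -> pd.DataFrame:
    rows = []
    for group, people in listeners.items():
        for i, scores in enumerate(people):
            sid = f"{group}{i}"
            for cell, value in scores.items():
                row = {"subject": sid, "group": group, "score": value}
                row.update(dict(zip(model.factors, cell)))
                rows.append(row)
    return pd.DataFrame(rows)


def sbf_maxn(spec: DesignSpec) -> DesignOutcome:
    """Run the sequential design analysis.

    Per replicate: draw ``n_min`` listeners per group, test, then accrue
    ``step`` listeners per group per look until the interaction BF
    crosses a threshold or ``n_max`` per group is reached.  Replicates
    reaching maxN without a crossing count as inconclusive;
    ``p_leaning_null_at_maxn`` is the probability, within those
    replicates, that the final BF still points toward the null (BF < 1).
    """
    model = spec.effect_model
    rng = np.random.default_rng(spec.rng_seed)
    results = []     # (outcome, total_n, final_bf)
    for _ in range(spec.n_reps):
        listeners = {
            g: [_draw_listener(model, g, rng) for _ in range(spec.n_min)]
            for g in ("NH", "HI")
        }
        n = spec.n_min
        outcome = "inconclusive"
        bf = None
        while True:
            table = _to_table(listeners, model)
            bf = mixed_anova_bf(
                table, spec.target_interaction,
                method=spec.bf_method if spec.bf_method != "laplace"
                else "laplace",
            ).bf10
            if bf >= spec.bf_upper:
                outcome = "confirm_alt"
                break
            if bf <= spec.bf_lower:
                outcome = "confirm_null"
                break
            if n >= spec.n_max:
                break
            for g in ("NH", "HI"):
                listeners[g].extend(
                    _draw_listener(model, g, rng)
                    for _ in range(spec.step))
            n += spec.step
        results.append((outcome, 2 * n, bf))

    outcomes = [r[0] for r in results]
    n_incon = outcomes.count("inconclusive")
    at_max = [bf for o, _, bf in results if o == "inconclusive"]
    return DesignOutcome(
        p_confirm_null=outcomes.count("confirm_null") / spec.n_reps,
        p_confirm_alt=outcomes.count("confirm_alt") / spec.n_reps,
        p_inconclusive=n_incon / spec.n_reps,
        p_leaning_null_at_maxn=(
            float(np.mean([bf < 1.0 for bf in at_max]))
            if at_max else float("nan")),
        mean_n=float(np.mean([r[1] for r in results])),
        n_reps=spec.n_reps,
        bf_method=spec.bf_method,
    )
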