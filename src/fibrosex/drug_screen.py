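"""In-silico drug screen on the fibrotic-stimulus state.

Each drug is applied as a static perturbation (default dose weight 0.85)
on top of a fibrotic baseline (all inputs at w=0.4 except E2, which carries
the sex condition's weight).  Mechanism semantics:

* non-competitive antagonist — the target's Ymax is scaled by (1 − w);
* competitive antagonist — the weight of every reaction producing the
  target is scaled by (1 − w);
* agonist (either mechanism) — a source reaction onto the target with
  weight w, OR-combined with existing producers.

Outcomes are summarized by mean activity changes of three output panels
(matrix proteins, proteases, protease inhibitors) and a composite Matrix
Content Score; by default MCS = matrix − protease + inhibitor (proteases
degrade matrix), with an all-plus convention selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import IntegrationError, ModelValidationError, ProtocolError
from .logic_ode_core import SimulationSettings, compile_model, simulate
from .network_io import DrugTarget, NetworkModel, ReactionSpec
from .sex_conditions import SexCondition, apply_condition, resolve_e2

__all__ = [
    "OutputCategories",
    "DrugScreenConfig",
    "DrugEffect",
    "apply_drug",
    "matrix_content_score",
    "run_drug_screen",
    "classify_drug_strategies",
    "DEFAULT_W_DRUG",
]

DEFAULT_W_DRUG = 0.85

#: Full-model output panels.
FULL_MATRIX = ("proCI", "proCIII", "fibronectin", "periostin", "osteopontin",
               "LOXL1")
FULL_PROTEASE = ("proMMP1", "proMMP2", "proMMP3", "proMMP8", "proMMP9",
                 "proMMP12", "proMMP14")
FULL_INHIBITOR = ("TIMP1", "TIMP2", "PAI1")


@dataclass(frozen=True)
class OutputCategories:
    """Disjoint output panels whose mean activities feed the MCS."""

    matrix: tuple[str, ...] = FULL_MATRIX
    protease: tuple[str, ...] = FULL_PROTEASE
    inhibitor: tuple[str, ...] = FULL_INHIBITOR

    def __post_init__(self) -> None:
        panels = (set(self.matrix), set(self.protease), set(self.inhibitor))
        if sum(map(len, panels)) != len(set().union(*panels)):
            raise ModelValidationError("output categories must be disjoint")
        if not all(panels):
            raise ModelValidationError("every output category must be non-empty")

    @property
    def all_outputs(self) -> tuple[str, ...]:
        return self.matrix + self.protease + self.inhibitor

    def validate_against(self, model: NetworkModel) -> None:
        missing = [s for s in self.all_outputs if s not in model.species_ids]
        if missing:
            raise ModelValidationError(
                "output category members absent from model: " + ", ".join(missing)
            )

    @classmethod
    def restricted_to(cls, model: NetworkModel) -> "OutputCategories":
        """Intersect the full-model panels with this model's species."""
        ids = set(model.species_ids)
        return cls(
            matrix=tuple(s for s in FULL_MATRIX if s in ids),
            protease=tuple(s for s in FULL_PROTEASE if s in ids),
            inhibitor=tuple(s for s in FULL_INHIBITOR if s in ids),
        )


@dataclass(frozen=True)
class DrugScreenConfig:
    """Protocol constants of the drug screen."""

    w_drug: float = DEFAULT_W_DRUG
    basal_input_w: float = 0.4
    t_baseline: float = 80.0
    t_drug: float = 240.0
    categories: OutputCategories = field(default_factory=OutputCategories)
    mcs_convention: str = "minus"  # "minus" | "plus"
    settings: SimulationSettings = field(default_factory=SimulationSettings)


@dataclass
class DrugEffect:
    """Per-drug outcome: output deltas, panel means, MCS change."""

    drug_id: str
    deltas: dict[str, float]  # per output-panel species
    matrix_mean: float
    protease_mean: float
    inhibitor_mean: float
    mcs_delta: float
    failed: bool = False
    message: str = ""


def matrix_content_score(matrix: float, protease: float, inhibitor: float,
                         convention: str = "minus") -> float:
    """Composite matrix-content readout from the three panel means.

    ``minus`` (default): matrix − protease + inhibitor, reflecting that
    proteases degrade matrix while their inhibitors preserve it; ``plus``:
    the all-additive variant.
    """
    if convention == "minus":
        return matrix - protease + inhibitor
    if convention == "plus":
        return matrix + protease + inhibitor
    raise ProtocolError(f"unknown MCS convention {convention!r}")


def apply_drug(model: NetworkModel, drug: DrugTarget,
               w_drug: float = DEFAULT_W_DRUG) -> NetworkModel:
    """Return a copy of the model with the drug's perturbation installed.

    Multi-target drugs apply the mechanism to each target.  A zero dose
    returns the model unchanged.
    """
    if not (0.0 <= w_drug <= 1.0):
        raise ProtocolError(f"w_drug={w_drug} outside [0, 1]")
    missing = [t for t in drug.targets if t not in model.species_ids]
    if missing:
        raise ModelValidationError(
            f"{drug.drug_id}: unknown target species " + ", ".join(missing)
        )
    if w_drug == 0.0:
        return model.copy()

    out = model.copy()
    for target in drug.targets:
        if drug.action == "agonist":
            out = out.with_added_reaction(
                ReactionSpec(rule=f"=> {target}", w=w_drug)
            )
        elif drug.mechanism == "noncompetitive":
            ymax = out.get_species(target).ymax * (1.0 - w_drug)
            out = out.with_species_ymax({target: ymax})
        else:  # competitive antagonist: scale producer weights
            for i, r in enumerate(out.reactions):
                if r.parsed().product == target:
                    out.reactions[i] = replace(r, w=r.w * (1.0 - w_drug))
    out.metadata = {**out.metadata, "drug": drug.drug_id}
    return out


def run_drug_screen(model: NetworkModel, drugs: Sequence[DrugTarget],
                    cond: SexCondition,
                    cfg: DrugScreenConfig | None = None) -> list[DrugEffect]:
    """Score every drug against the un-drugged fibrotic baseline.

    Fibrotic baseline: conditioned model, all inputs at 0.4 except E2 at
    the condition's weight, run for the baseline horizon; the un-drugged
    model is then continued through the drug horizon so drugged and
    baseline states are compared at the same simulated time.  Per-drug
    integration failures are recorded and the screen continues.
    """
    cfg = cfg or DrugScreenConfig()
    conditioned = apply_condition(model, cond)
    cats = cfg.categories
    cats.validate_against(conditioned)
    e2 = resolve_e2(conditioned)
    weights = {sid: cfg.basal_input_w for sid in conditioned.input_ids}
    weights[e2] = cond.e2_input_w

    base_cm = compile_model(conditioned)
    fib = simulate(base_cm, weights, replace(cfg.settings, t_end=cfg.t_baseline))
    control = simulate(base_cm, weights, replace(cfg.settings, t_end=cfg.t_drug),
                       y_start=fib)

    outputs = cats.all_outputs
    effects: list[DrugEffect] = []
    for drug in drugs:
        try:
            drugged = apply_drug(conditioned, drug, cfg.w_drug)
            # clamp the continuation start into the (possibly reduced) ymax box
            end = simulate(compile_model(drugged), weights,
                           replace(cfg.settings, t_end=cfg.t_drug),
                           y_start=fib.activities)
            deltas = {o: end[o] - control[o] for o in outputs}
            m = float(np.mean([deltas[o] for o in cats.matrix]))
            p = float(np.mean([deltas[o] for o in cats.protease]))
            i = float(np.mean([deltas[o] for o in cats.inhibitor]))
            effects.append(
                DrugEffect(
                    drug_id=drug.drug_id, deltas=deltas,
                    matrix_mean=m, protease_mean=p, inhibitor_mean=i,
                    mcs_delta=matrix_content_score(m, p, i, cfg.mcs_convention),
                )
            )
        except IntegrationError as err:  # pragma: no cover - defensive
            effects.append(
                DrugEffect(
                    drug_id=drug.drug_id, deltas={o: np.nan for o in outputs},
                    matrix_mean=np.nan, protease_mean=np.nan,
                    inhibitor_mean=np.nan, mcs_delta=np.nan,
                    failed=True, message=str(err),
                )
            )
    return effects


def classify_drug_strategies(effects_by_condition: Mapping[str, Sequence[DrugEffect]],
                             epsilon: float = 0.05) -> pd.DataFrame:
    """Label each drug per condition and tabulate cross-condition divergence.

    ``mcs_delta < −ε`` → antifibrotic, ``> +ε`` → profibrotic, else neutral
    (ε defaults to the 0.05 activity-change threshold).  The returned frame
    has one row per drug, one label column per condition, and a
    ``divergent`` flag for drugs whose labels differ across conditions.
    """
    conds = list(effects_by_condition)
    if not conds:
        raise ProtocolError("no conditions supplied")
    id_lists = [tuple(e.drug_id for e in effects_by_condition[c]) for c in conds]
    if len(set(map(frozenset, id_lists))) != 1:
        raise ProtocolError("conditions were screened with different drug lists")

    def label(delta: float) -> str:
        if np.isnan(delta):
            return "failed"
        if delta < -epsilon:
            return "antifibrotic"
        if delta > epsilon:
            return "profibrotic"
        return "neutral"

    by_cond = {
        c: {e.drug_id: e for e in effects_by_condition[c]} for c in conds
    }
    rows = []
    for drug_id in sorted(id_lists[0]):
        labels = {c: label(by_cond[c][drug_id].mcs_delta) for c in conds}
        deltas = {f"mcs_{c}": by_cond[c][drug_id].mcs_delta for c in conds}
        rows.append(
            {
                "drug_id": drug_id, **labels, **deltas,
                "divergent": len(set(labels.values())) > 1,
            }
        )
    return pd.DataFrame(rows).set_index("drug_id")
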