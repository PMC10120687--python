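"""Node-knockdown perturbation screen.

Under a given estrogen condition the network is first brought to a
fibrotic-tone baseline (all inputs at w=0.4, E2 at the condition's weight)
for 80 h.  Each node is then knocked down in turn by clamping its Ymax to
0.1 and the simulation continued for 240 h from the baseline state.  The
screen collects the knockdown matrix D[k, j] = Δ activity of node j under
knockdown of node k, from which *influential* nodes (row aggregates: whose
removal moves the network most) and *sensitive* nodes (column aggregates:
which move most across knockdowns) are ranked.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import IntegrationError
from .logic_ode_core import SimulationSettings, compile_model, simulate
from .network_io import NetworkModel
from .sex_conditions import SexCondition, apply_condition, resolve_e2

__all__ = [
    "PerturbationConfig",
    "KnockdownMatrix",
    "run_knockdown_screen",
    "influence_scores",
    "sensitivity_scores",
]


@dataclass(frozen=True)
class PerturbationConfig:
    """Protocol constants of the knockdown screen."""

    basal_input_w: float = 0.4
    knockdown_ymax: float = 0.1
    t_basal: float = 80.0
    t_knockdown: float = 240.0
    knockable: tuple[str, ...] | None = None  # None -> every species
    settings: SimulationSettings = field(default_factory=SimulationSettings)

    def __post_init__(self) -> None:
        if not (0.0 <= self.knockdown_ymax < 1.0):
            raise ValueError(
                f"knockdown_ymax={self.knockdown_ymax} outside [0, 1)"
            )
        if self.t_basal <= 0 or self.t_knockdown <= 0:
            raise ValueError("phase durations must be > 0")


@dataclass
class KnockdownMatrix:
    """Δ-activity matrix indexed (knocked node, observed node)."""

    D: pd.DataFrame
    basal: pd.Series
    condition: str
    failures: dict = field(default_factory=dict)  # knocked id -> message

    @property
    def knocked(self) -> list[str]:
        return list(self.D.index)

    @property
    def observed(self) -> list[str]:
        return list(self.D.columns)


def run_knockdown_screen(model: NetworkModel, cond: SexCondition,
                         cfg: PerturbationConfig | None = None
                         ) -> KnockdownMatrix:
    """Knock every (knockable) node down to Ymax=0.1 and record Δ activity.

    The basal run starts from y0 with all inputs at the basal weight and E2
    at the condition's weight; each knockdown continues from the basal
    endpoint.  Per-row integration failures are recorded (NaN row) and the
    screen continues.
    """
    cfg = cfg or PerturbationConfig()
    conditioned = apply_condition(model, cond)
    e2 = resolve_e2(conditioned)
    weights = {sid: cfg.basal_input_w for sid in conditioned.input_ids}
    weights[e2] = cond.e2_input_w

    cm = compile_model(conditioned)
    basal = simulate(cm, weights, replace(cfg.settings, t_end=cfg.t_basal))

    knockable = list(cfg.knockable) if cfg.knockable else conditioned.species_ids
    kd_settings = replace(cfg.settings, t_end=cfg.t_knockdown)
    rows: dict[str, np.ndarray] = {}
    failures: dict[str, str] = {}
    for k in knockable:
        kd_model = conditioned.with_species_ymax({k: cfg.knockdown_ymax})
        try:
            end = simulate(compile_model(kd_model), weights, kd_settings,
                           y_start=basal.activities)
            rows[k] = end.activities - basal.activities
        except IntegrationError as err:  # pragma: no cover - defensive
            failures[k] = str(err)
            rows[k] = np.full(len(cm.species), np.nan)

    D = pd.DataFrame.from_dict(rows, orient="index", columns=cm.species)
    D = D.loc[knockable]
    return KnockdownMatrix(
        D=D,
        basal=pd.Series(basal.activities, index=cm.species),
        condition=cond.name,
        failures=failures,
    )


def _aggregate(km_or_df, axis: int, signed: bool, include_self: bool) -> pd.Series:
    D = km_or_df.D if isinstance(km_or_df, KnockdownMatrix) else km_or_df
    vals = D.to_numpy(dtype=float).copy()
    if not include_self:
        common = [c for c in D.index if c in D.columns]
        for k in common:
            vals[D.index.get_loc(k), D.columns.get_loc(k)] = 0.0
    if not signed:
        vals = np.abs(vals)
    summed = np.nansum(vals, axis=axis)
    index = D.index if axis == 1 else D.columns
    scores = pd.Series(summed, index=index, name="score")
    # descending by score, alphabetical among ties
    order = sorted(scores.index, key=lambda sid: (-scores[sid], sid))
    return scores.loc[order]


def influence_scores(km, signed: bool = False,
                     include_self: bool = False) -> pd.Series:
    """Per-knocked-node influence: Σ_j |D[k, j]|, ranked descending.

    The knocked node's own change is excluded by default (self-change is
    mechanistic, not network influence); ``signed=True`` sums raw deltas
    instead of magnitudes.
    """
    return _aggregate(km, axis=1, signed=signed, include_self=include_self)


def sensitivity_scores(km, signed: bool = False,
                       include_self: bool = False) -> pd.Series:
    """Per-observed-node sensitivity: Σ_k |D[k, j]|, ranked descending."""
    return _aggregate(km, axis=0, signed=signed, include_self=include_self)
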