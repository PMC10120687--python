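"""Literature-validation protocols and scoring.

The single-stimulus protocol simulates basal conditions (tension at its
calibrated weight, other inputs at a low basal tone) for 40 h, then raises
one input to full stimulus (w=1) for 80 h, and reports the per-node change
in endpoint activity.  Changes of at least 5% of the normalized 0–1 scale
(|Δ| ≥ 0.05) are classified as up/down; smaller changes are "no change".
Predicted categories are scored against curated literature records routed
by cell sex: male records against the male model, female against the
female model, pooled against the mean of both.

The combined-treatment protocol reproduces the co-stimulation experiment
design: 80 h of basal input tone (w=0.25), then 240 h with the named
treatments (e.g. AngII, ET1, E2, or pairs) raised to w=1, reading out the
fibrosis markers fibronectin, proCI, proCIII and αSMA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ProtocolError
from .logic_ode_core import SimulationSettings, StateVector, compile_model, simulate
from .network_io import NetworkModel, ValidationRecord
from .sex_conditions import E2_ALIASES, pooled_prediction

__all__ = [
    "ValidationProtocol",
    "CombinedTreatmentProtocol",
    "DeltaActivityResult",
    "ValidationScore",
    "run_single_stimulus_protocol",
    "classify_delta",
    "score_validation",
    "run_combined_treatment_protocol",
    "DELTA_THRESHOLD",
]

#: Classification threshold: 5% of the normalized 0–1 activity scale.
DELTA_THRESHOLD = 0.05

#: Default readout panel of the combined-treatment protocol.
COMBINED_READOUTS = ("fibronectin", "proCI", "proCIII", "aSMA")


@dataclass(frozen=True)
class ValidationProtocol:
    """Constants of the single-stimulus validation protocol."""

    t_basal: float = 40.0
    t_stimulus: float = 80.0
    tension_w: float = 0.65
    stimulus_w: float = 1.0
    basal_input_w: float = 0.1
    tension_id: str = "tension"
    settings: SimulationSettings = field(default_factory=SimulationSettings)


@dataclass(frozen=True)
class CombinedTreatmentProtocol:
    """Constants of the combined-treatment (co-stimulation) protocol."""

    t_basal: float = 80.0
    t_treatment: float = 240.0
    tension_w: float = 0.65
    treatment_w: float = 1.0
    basal_input_w: float = 0.25
    tension_id: str = "tension"
    readouts: tuple[str, ...] = COMBINED_READOUTS
    settings: SimulationSettings = field(default_factory=SimulationSettings)


@dataclass
class DeltaActivityResult:
    """Per-node endpoint activity change between two protocol phases."""

    species: list[str]
    delta: np.ndarray
    basal: StateVector
    stimulated: StateVector
    stimulus: str

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.species, map(float, self.delta)))

    def __getitem__(self, species_id: str) -> float:
        return float(self.delta[self.species.index(species_id)])


def _basal_weights(model: NetworkModel, proto: ValidationProtocol,
                   ) -> dict[str, float]:
    """All inputs at the basal tone, tension at its calibrated weight.

    E2 is treated as an ordinary biochemical input here: it carries no
    sex-specific basal tone during validation and enters only as an
    explicit stimulus.
    """
    weights = {sid: proto.basal_input_w for sid in model.input_ids}
    if proto.tension_id in weights:
        weights[proto.tension_id] = proto.tension_w
    return weights


def run_single_stimulus_protocol(model: NetworkModel, stimulus: str,
                                 proto: ValidationProtocol | None = None
                                 ) -> DeltaActivityResult:
    """Δ activity of every node after raising one input to full stimulus."""
    proto = proto or ValidationProtocol()
    if stimulus not in model.input_ids:
        raise ProtocolError(
            f"unknown stimulus {stimulus!r}; declared inputs: "
            + ", ".join(model.input_ids)
        )
    cm = compile_model(model)
    basal_w = _basal_weights(model, proto)
    basal = simulate(cm, basal_w, replace(proto.settings, t_end=proto.t_basal))
    stim_w = {**basal_w, stimulus: proto.stimulus_w}
    stimulated = simulate(
        cm, stim_w, replace(proto.settings, t_end=proto.t_stimulus), y_start=basal
    )
    return DeltaActivityResult(
        species=cm.species,
        delta=stimulated.activities - basal.activities,
        basal=basal,
        stimulated=stimulated,
        stimulus=stimulus,
    )


def classify_delta(delta, threshold: float = DELTA_THRESHOLD):
    """Classify an activity change: ``up`` (Δ ≥ threshold), ``down``
    (Δ ≤ −threshold), else ``nochange``.  Boundaries inclusive."""
    arr = np.asarray(delta, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ProtocolError(f"non-finite delta: {delta}")
    cats = np.where(arr >= threshold, "up",
                    np.where(arr <= -threshold, "down", "nochange"))
    return str(cats) if np.isscalar(delta) or arr.ndim == 0 else cats


@dataclass
class ValidationScore:
    """Accuracy of model predictions against literature records."""

    n_total: int
    n_match: int
    by_group: dict  # cell_sex -> {"n": int, "n_match": int, "accuracy": float}
    per_record: pd.DataFrame
    n_excluded: int
    n_unevaluable: int
    estrogen_n: int
    estrogen_match: int

    @property
    def accuracy(self) -> float:
        return self.n_match / self.n_total

    @property
    def estrogen_accuracy(self) -> float | None:
        return self.estrogen_match / self.estrogen_n if self.estrogen_n else None


def score_validation(records: Iterable[ValidationRecord],
                     male_model: NetworkModel,
                     female_model: NetworkModel,
                     proto: ValidationProtocol | None = None,
                     include_unreported: bool = False,
                     threshold: float = DELTA_THRESHOLD) -> ValidationScore:
    """Score literature records against the per-sex models.

    Routing: male records → male model, female → female model, pooled →
    elementwise mean of both endpoints (equivalently of both deltas, the
    mean being linear); unreported-sex records are excluded unless
    ``include_unreported`` routes them to the pooled prediction.  Records
    whose stimulus or measured node is absent from the model are counted as
    unevaluable and reported, never silently dropped.
    """
    records = list(records)
    proto = proto or ValidationProtocol()
    if male_model.species_ids != female_model.species_ids:
        raise ProtocolError("male and female models must share species order")

    usable = []
    n_excluded = 0
    for r in records:
        if r.cell_sex == "unreported" and not include_unreported:
            n_excluded += 1
        else:
            usable.append(r)
    if not usable:
        raise ProtocolError("no scoreable records (empty or all excluded)")

    cache: dict[tuple[str, str], DeltaActivityResult] = {}

    def deltas_for(sex: str, stimulus: str) -> np.ndarray:
        if sex == "pooled":
            return pooled_prediction(
                deltas_for("male", stimulus), deltas_for("female", stimulus)
            )
        key = (sex, stimulus)
        if key not in cache:
            model = male_model if sex == "male" else female_model
            cache[key] = run_single_stimulus_protocol(model, stimulus, proto)
        return cache[key].delta

    ids = male_model.species_ids
    index = {sid: i for i, sid in enumerate(ids)}
    rows = []
    for r in usable:
        sex = "pooled" if r.cell_sex == "unreported" else r.cell_sex
        evaluable = r.stimulus in male_model.input_ids and r.measured in index
        predicted, match = None, None
        if evaluable:
            d = float(deltas_for(sex, r.stimulus)[index[r.measured]])
            predicted = classify_delta(d, threshold)
            match = predicted == r.expected
        rows.append(
            {
                "stimulus": r.stimulus, "measured": r.measured,
                "cell_sex": r.cell_sex, "routed_to": sex,
                "expected": r.expected, "predicted": predicted,
                "match": match, "evaluable": evaluable, "source": r.source,
            }
        )
    per_record = pd.DataFrame(rows)

    scored = per_record[per_record["evaluable"]]
    n_unevaluable = int((~per_record["evaluable"]).sum())
    if scored.empty:
        raise ProtocolError("no evaluable records against this model")

    by_group = {}
    for sex, grp in scored.groupby("cell_sex"):
        by_group[sex] = {
            "n": int(len(grp)),
            "n_match": int(grp["match"].sum()),
            "accuracy": float(grp["match"].mean()),
        }
    e2_names = set(E2_ALIASES)
    e2 = scored[scored["stimulus"].isin(e2_names)]
    return ValidationScore(
        n_total=int(len(scored)),
        n_match=int(scored["match"].sum()),
        by_group=by_group,
        per_record=per_record,
        n_excluded=n_excluded,
        n_unevaluable=n_unevaluable,
        estrogen_n=int(len(e2)),
        estrogen_match=int(e2["match"].sum()),
    )


def run_combined_treatment_protocol(model: NetworkModel,
                                    treatments: Iterable[str],
                                    proto: CombinedTreatmentProtocol | None = None
                                    ) -> dict:
    """Endpoint activities of the fibrosis readouts after co-stimulation.

    Basal phase: all inputs at w=0.25 (tension at 0.65) for 80 h; treatment
    phase: the named inputs raised to w=1 for a further 240 h.  An empty
    treatment set yields the extended basal run (negative control).
    """
    proto = proto or CombinedTreatmentProtocol()
    treatments = list(treatments)
    unknown = [t for t in treatments if t not in model.input_ids]
    if unknown:
        raise ProtocolError(
            "unknown treatment id(s): " + ", ".join(sorted(unknown))
        )
    cm = compile_model(model)
    basal_w = {sid: proto.basal_input_w for sid in model.input_ids}
    if proto.tension_id in basal_w:
        basal_w[proto.tension_id] = proto.tension_w
    basal = simulate(cm, basal_w, replace(proto.settings, t_end=proto.t_basal))
    treat_w = {**basal_w, **{t: proto.treatment_w for t in treatments}}
    end = simulate(cm, treat_w,
                   replace(proto.settings, t_end=proto.t_treatment), y_start=basal)
    readouts = {r: end[r] for r in proto.readouts if r in cm.species}
    return {"readouts": readouts, "state": end, "basal": basal,
            "treatments": treatments}
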