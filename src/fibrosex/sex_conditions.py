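"""Sex-specific model configuration.

Sex differences are encoded entirely through two knobs: the maximal
saturation (Ymax) of the three estrogen receptors (ERα, ERβ, GPR30) and the
weight of the estradiol (E2) source reaction.  The male condition halves
receptor saturation (Ymax 0.5) and uses a low circulating-E2 weight (0.25);
both female conditions use full receptor saturation (Ymax 1.0) with E2
weight 0.5 (post-menopausal) or 1.0 (pre-menopausal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ModelValidationError, ProtocolError
from .network_io import NetworkModel

__all__ = [
    "SexCondition",
    "CONDITION_NAMES",
    "RECEPTOR_ALIASES",
    "E2_ALIASES",
    "make_condition",
    "apply_condition",
    "resolve_receptors",
    "resolve_e2",
    "pooled_prediction",
]

CONDITION_NAMES = ("male", "female_post", "female_pre")

#: Canonical receptor keys -> accepted species spellings (case-sensitive;
#: covers the naming mix seen in published model tables).
RECEPTOR_ALIASES: dict[str, tuple[str, ...]] = {
    "ERA": ("ERA", "ERa", "ERalpha", "ERX"),
    "ERB": ("ERB", "ERb", "ERbeta"),
    "GPR30": ("GPR30", "GPER", "GPER1"),
}

E2_ALIASES: tuple[str, ...] = ("E2", "estrogen", "estradiol")


@dataclass(frozen=True)
class SexCondition:
    """Receptor saturations and E2 input weight defining one condition."""

    name: str
    receptor_ymax: dict[str, float] = field(
        default_factory=lambda: {"ERA": 1.0, "ERB": 1.0, "GPR30": 1.0}
    )
    e2_input_w: float = 1.0

    def __post_init__(self) -> None:
        for k, v in self.receptor_ymax.items():
            if not (0.0 <= v <= 1.0):
                raise ProtocolError(f"receptor_ymax[{k}]={v} outside [0, 1]")
        if not (0.0 <= self.e2_input_w <= 1.0):
            raise ProtocolError(f"e2_input_w={self.e2_input_w} outside [0, 1]")


_CONDITION_TABLE: dict[str, tuple[float, float]] = {
    # name -> (receptor ymax for all three receptors, E2 input weight)
    "male": (0.5, 0.25),
    "female_post": (1.0, 0.5),
    "female_pre": (1.0, 1.0),
}


def make_condition(name: str) -> SexCondition:
    """Build the standard condition for ``male``, ``female_post`` or
    ``female_pre``."""
    try:
        ymax, e2w = _CONDITION_TABLE[name]
    except KeyError:
        raise ProtocolError(
            f"unknown condition {name!r}; valid names: {', '.join(CONDITION_NAMES)}"
        ) from None
    return SexCondition(
        name=name,
        receptor_ymax={"ERA": ymax, "ERB": ymax, "GPR30": ymax},
        e2_input_w=e2w,
    )


def resolve_receptors(model: NetworkModel,
                      aliases: Mapping[str, Sequence[str]] | None = None
                      ) -> dict[str, str]:
    """Map canonical receptor keys to the species ids this model uses.

    Raises naming every receptor that cannot be found.
    """
    aliases = aliases or RECEPTOR_ALIASES
    ids = set(model.species_ids)
    found: dict[str, str] = {}
    missing: list[str] = []
    for key, names in aliases.items():
        hit = next((n for n in names if n in ids), None)
        if hit is None:
            missing.append(key)
        else:
            found[key] = hit
    if missing:
        raise ModelValidationError(
            "model lacks estrogen receptor species: " + ", ".join(sorted(missing))
        )
    return found


def resolve_e2(model: NetworkModel,
               aliases: Sequence[str] = E2_ALIASES) -> str:
    ids = set(model.species_ids)
    hit = next((n for n in aliases if n in ids), None)
    if hit is None:
        raise ModelValidationError(
            f"model lacks an E2 species (tried {', '.join(aliases)})"
        )
    return hit


def apply_condition(model: NetworkModel, cond: SexCondition,
                    aliases: Mapping[str, Sequence[str]] | None = None
                    ) -> NetworkModel:
    """Return a copy with receptor Ymax and the E2 source weight set.

    The original model is untouched; applying the same condition twice is
    idempotent.
    """
    receptors = resolve_receptors(model, aliases)
    e2 = resolve_e2(model)
    out = model.with_species_ymax(
        {receptors[k]: v for k, v in cond.receptor_ymax.items()}
    )
    out = out.with_source_weight(e2, cond.e2_input_w)
    out.metadata = {**out.metadata, "condition": cond.name}
    return out


def pooled_prediction(male_result, female_result):
    """Elementwise mean of aligned male and female per-node values.

    Accepts arrays (same length) or dicts (same key set); emulates pooled
    male+female cell preparations by averaging model predictions.
    """
    if isinstance(male_result, dict) or isinstance(female_result, dict):
        if set(male_result) != set(female_result):
            raise ProtocolError("pooled_prediction: species sets differ")
        return {k: 0.5 * (male_result[k] + female_result[k]) for k in male_result}
    a = np.asarray(male_result, dtype=float)
    b = np.asarray(female_result, dtype=float)
    if a.shape != b.shape:
        raise ProtocolError(
            f"pooled_prediction: misaligned shapes {a.shape} vs {b.shape}"
        )
    return 0.5 * (a + b)
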