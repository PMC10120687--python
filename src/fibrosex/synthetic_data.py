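"""Synthetic networks, validation records and drug tables.

Everything a pipeline stage needs can be generated here with no external
files: toy logic networks with known steady states (plus an independent
fixed-point oracle), synthetic literature-record sets with controllable
concordance, toy drug-target tables, a hand-built 12-node "mini
fibroblast" network exercising every mechanism (estrogen branch, three
receptors, a NOT gate, matrix/protease/inhibitor outputs), and a builder
that merges an estrogen extension into a base network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import ModelValidationError, ProtocolError
from .network_io import (
    DrugTarget,
    NetworkModel,
    ReactionSpec,
    SpeciesSpec,
    ValidationRecord,
    parse_rule,
)
from .validation_harness import (
    ValidationProtocol,
    classify_delta,
    run_single_stimulus_protocol,
)
from .sex_conditions import pooled_prediction

__all__ = [
    "ToySpec",
    "make_toy_network",
    "fixed_point_oracle",
    "make_synthetic_validation_set",
    "make_toy_drug_table",
    "mini_fibroblast",
    "mini_output_categories",
    "ExtensionTables",
    "build_estrogen_extension",
    "estrogen_extension_tables",
    "synthetic_base_network",
    "synthetic_estrogen_extension",
]

TOPOLOGIES = ("chain", "fan_in", "fan_out", "negative_feedback", "random_dag")


@dataclass(frozen=True)
class ToySpec:
    """Recipe for a deterministic toy network."""

    n_nodes: int = 5
    topology: str = "chain"
    gate_mix: dict = field(default_factory=lambda: {"and": 0.3, "not": 0.2})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ProtocolError("n_nodes must be >= 2")
        if self.topology not in TOPOLOGIES:
            raise ProtocolError(
                f"unknown topology {self.topology!r}; valid: {', '.join(TOPOLOGIES)}"
            )
        frac = sum(self.gate_mix.get(k, 0.0) for k in ("and", "not"))
        if not (0.0 <= frac <= 1.0):
            raise ProtocolError("gate_mix fractions must sum to <= 1")


def _node_ids(n: int) -> list[str]:
    return [f"X{i}" for i in range(n)]


def make_toy_network(spec: ToySpec) -> NetworkModel:
    """Build a toy network; deterministic for a fixed seed.

    ``chain``: source -> X0 -> X1 -> ...; ``fan_in``: all of X0..X_{n-2}
    (each with a source) feed X_{n-1}; ``fan_out``: X0 feeds every other
    node; ``negative_feedback``: a chain whose last node inhibits the
    first internal step; ``random_dag``: topological order by node index,
    each non-root wired to 1–3 earlier producers with AND/NOT usage drawn
    from ``gate_mix``.
    """
    rng = np.random.default_rng(spec.seed)
    ids = _node_ids(spec.n_nodes)
    species = [SpeciesSpec(id=s, role="intermediate") for s in ids]
    reactions: list[ReactionSpec] = []

    if spec.topology == "chain":
        reactions.append(ReactionSpec(rule=f"=> {ids[0]}", w=0.0))
        for a, b in zip(ids, ids[1:]):
            reactions.append(ReactionSpec(rule=f"{a} => {b}"))
    elif spec.topology == "fan_in":
        for s in ids[:-1]:
            reactions.append(ReactionSpec(rule=f"=> {s}", w=0.0))
        use_and = spec.gate_mix.get("and", 0.0) >= 0.5 and spec.n_nodes >= 3
        if use_and:
            reactions.append(
                ReactionSpec(rule=f"{' & '.join(ids[:-1])} => {ids[-1]}")
            )
        else:
            for s in ids[:-1]:
                reactions.append(ReactionSpec(rule=f"{s} => {ids[-1]}"))
    elif spec.topology == "fan_out":
        reactions.append(ReactionSpec(rule=f"=> {ids[0]}", w=0.0))
        for s in ids[1:]:
            reactions.append(ReactionSpec(rule=f"{ids[0]} => {s}"))
    elif spec.topology == "negative_feedback":
        reactions.append(ReactionSpec(rule=f"=> {ids[0]}", w=0.0))
        reactions.append(ReactionSpec(rule=f"{ids[0]} & !{ids[-1]} => {ids[1]}"))
        for a, b in zip(ids[1:], ids[2:]):
            reactions.append(ReactionSpec(rule=f"{a} => {b}"))
    else:  # random_dag
        n_roots = max(1, int(rng.integers(1, max(2, spec.n_nodes // 3 + 1))))
        for s in ids[:n_roots]:
            reactions.append(ReactionSpec(rule=f"=> {s}", w=0.0))
        p_and = spec.gate_mix.get("and", 0.0)
        p_not = spec.gate_mix.get("not", 0.0)
        for i in range(n_roots, spec.n_nodes):
            k = int(rng.integers(1, min(3, i) + 1))
            parents = list(rng.choice(ids[:i], size=k, replace=False))
            negs = [bool(rng.random() < p_not) for _ in parents]
            terms = [("!" if neg else "") + p for p, neg in zip(parents, negs)]
            if len(terms) > 1 and rng.random() < p_and:
                reactions.append(ReactionSpec(rule=f"{' & '.join(terms)} => {ids[i]}"))
            else:
                for t in terms:
                    reactions.append(ReactionSpec(rule=f"{t} => {ids[i]}"))

    return NetworkModel(
        species=species,
        reactions=reactions,
        metadata={"topology": spec.topology, "seed": spec.seed},
    )


def fixed_point_oracle(model: NetworkModel,
                       input_weights: Mapping[str, float] | None = None,
                       ymax_override: Mapping[str, float] | None = None,
                       damping: float = 0.5,
                       tol: float = 1e-12,
                       max_iter: int = 20000) -> dict[str, float]:
    """Steady state by damped fixed-point iteration, independent of the
    ODE integrator.

    Evaluates the rule tables directly: y_i <- (1-d) y_i + d F_i ymax_i,
    with the normalized-Hill term activations recomputed locally.  For
    acyclic networks this converges to the exact fixed point; for cyclic
    networks it is a relaxation oracle (d=0.5 by default).
    """
    input_weights = dict(input_weights or {})
    ids = model.species_ids
    ymax = {s.id: s.ymax for s in model.species}
    if ymax_override:
        ymax.update(ymax_override)

    parsed = []
    for r in model.reactions:
        p = r.parsed()
        w = r.w
        if p.is_source and p.product in input_weights:
            w = input_weights.pop(p.product)
        parsed.append((p, w, r.n, r.ec50))
    if input_weights:
        raise ProtocolError(
            "input ids without a source reaction: "
            + ", ".join(sorted(input_weights))
        )

    def f_hill(x: float, n: float, ec50: float) -> float:
        e = ec50 ** n
        b = (e - 1.0) / (2.0 * e - 1.0)
        return b * x ** n / ((b - 1.0) + x ** n)

    y = {s.id: s.y0 for s in model.species}
    for _ in range(max_iter):
        target: dict[str, float] = {sid: 0.0 for sid in ids}
        for p, w, n, ec50 in parsed:
            if p.is_source:
                c = w
            else:
                c = w
                for sid, neg in p.terms:
                    fx = f_hill(min(max(y[sid], 0.0), 1.0), n, ec50)
                    c *= (1.0 - fx) if neg else fx
            a = target[p.product]
            target[p.product] = a + c - a * c  # OR fold
        new = {sid: (1.0 - damping) * y[sid] + damping * target[sid] * ymax[sid]
               for sid in ids}
        err = max(abs(new[sid] - y[sid]) for sid in ids)
        y = new
        if err < tol * max(damping, 1e-3):
            break
    return y


def make_synthetic_validation_set(male_model: NetworkModel,
                                  female_model: NetworkModel,
                                  concordance: float,
                                  n_records: int,
                                  seed: int = 0,
                                  proto: ValidationProtocol | None = None
                                  ) -> list[ValidationRecord]:
    """Literature-record set whose agreement with the models is known.

    Exactly ``round(concordance * n_records)`` records carry the direction
    the routed model itself predicts under the single-stimulus protocol;
    the rest carry a deliberately different direction.  Cell sexes cycle
    male → female → pooled.
    """
    if not (0.0 <= concordance <= 1.0):
        raise ProtocolError(f"concordance={concordance} outside [0, 1]")
    proto = proto or ValidationProtocol()
    rng = np.random.default_rng(seed)

    stimuli = male_model.input_ids
    measurable = [s for s in male_model.species_ids if s not in stimuli]
    pairs = [(st, m) for st in stimuli for m in measurable]
    sexes = ("male", "female", "pooled")
    if n_records > len(pairs) * len(sexes):
        raise ProtocolError(
            f"n_records={n_records} exceeds available stimulus x node x sex "
            f"combinations ({len(pairs) * len(sexes)})"
        )

    cache: dict[tuple[str, str], dict[str, float]] = {}

    def predicted(sex: str, stimulus: str, measured: str) -> str:
        if sex == "pooled":
            d = pooled_prediction(
                {measured: _delta(male_model, "male", stimulus)[measured]},
                {measured: _delta(female_model, "female", stimulus)[measured]},
            )[measured]
        else:
            model = male_model if sex == "male" else female_model
            d = _delta(model, sex, stimulus)[measured]
        return str(classify_delta(d))

    def _delta(model, sex, stimulus):
        key = (sex, stimulus)
        if key not in cache:
            cache[key] = run_single_stimulus_protocol(model, stimulus, proto).as_dict()
        return cache[key]

    chosen = rng.permutation(len(pairs) * len(sexes))[:n_records]
    n_match = int(round(concordance * n_records))
    concordant = set(range(n_match))  # first n_match of the shuffled draw
    flip = {"up": "down", "down": "nochange", "nochange": "up"}

    records: list[ValidationRecord] = []
    for i, idx in enumerate(chosen):
        stimulus, measured = pairs[idx % len(pairs)]
        sex = sexes[idx // len(pairs)]
        pred = predicted(sex, stimulus, measured)
        expected = pred if i in concordant else flip[pred]
        records.append(
            ValidationRecord(
                stimulus=stimulus, measured=measured, expected=expected,
                cell_sex=sex, source=f"synthetic-{i}",
            )
        )
    return records


def make_toy_drug_table(model: NetworkModel, n_drugs: int = 6,
                        seed: int = 0) -> list[DrugTarget]:
    """Random drug-target table over the model's non-input species."""
    rng = np.random.default_rng(seed)
    candidates = [s for s in model.species_ids if s not in model.input_ids]
    if not candidates:
        raise ProtocolError("model has no non-input species to target")
    drugs = []
    for i in range(n_drugs):
        k = int(rng.integers(1, 3))
        targets = tuple(rng.choice(candidates, size=min(k, len(candidates)),
                                   replace=False))
        action = "agonist" if rng.random() < 0.4 else "antagonist"
        mechanism = "competitive" if rng.random() < 0.5 else "noncompetitive"
        drugs.append(
            DrugTarget(drug_id=f"drug{i}", targets=targets,
                       action=action, mechanism=mechanism)
        )
    return drugs


# ---------------------------------------------------------------------------
# Bundled 12-node mini-fibroblast fixture

def mini_fibroblast() -> NetworkModel:
    """Hand-built 12-node fibroblast network with an estrogen branch.

    Inputs: E2, AngII, tension.  E2 drives its three receptors; AngII
    signals through AT1R to NFKB, with ERβ providing the estrogen brake
    (NOT gate); tension and AT1R converge (OR) on smad3; collagen (proCI)
    integrates smad3 and NFKB; NFKB also drives the protease proMMP9, and
    ERα drives the protease inhibitor TIMP1 — so matrix, protease and
    inhibitor panels are all populated and every screen mechanism (sex
    conditions, knockdown, drug action, MCS) is exercisable at a size
    amenable to oracle verification.
    """
    species = [
        SpeciesSpec(id="E2", name="estradiol", role="input"),
        SpeciesSpec(id="AngII", name="angiotensin II", role="input"),
        SpeciesSpec(id="tension", name="mechanical tension", role="input"),
        SpeciesSpec(id="ERA", name="estrogen receptor alpha"),
        SpeciesSpec(id="ERB", name="estrogen receptor beta"),
        SpeciesSpec(id="GPR30", name="G-protein coupled estrogen receptor"),
        SpeciesSpec(id="AT1R", name="angiotensin receptor 1"),
        SpeciesSpec(id="smad3", name="SMAD3", reaction_class="signaling"),
        SpeciesSpec(id="NFKB", name="NF-kB"),
        SpeciesSpec(id="proCI", name="procollagen I", role="output",
                    reaction_class="translation"),
        SpeciesSpec(id="proMMP9", name="pro-MMP9", role="output",
                    reaction_class="translation"),
        SpeciesSpec(id="TIMP1", name="TIMP1", role="output",
                    reaction_class="translation"),
    ]
    reactions = [
        ReactionSpec(rule="=> E2", w=0.0),
        ReactionSpec(rule="=> AngII", w=0.0),
        ReactionSpec(rule="=> tension", w=0.0),
        ReactionSpec(rule="E2 => ERA"),
        ReactionSpec(rule="E2 => ERB"),
        ReactionSpec(rule="E2 => GPR30"),
        ReactionSpec(rule="AngII => AT1R"),
        ReactionSpec(rule="AT1R & !ERB => NFKB"),
        ReactionSpec(rule="tension => smad3"),
        ReactionSpec(rule="AT1R => smad3"),
        ReactionSpec(rule="smad3 => proCI"),
        ReactionSpec(rule="NFKB => proCI"),
        ReactionSpec(rule="NFKB => proMMP9"),
        ReactionSpec(rule="ERA => TIMP1"),
        ReactionSpec(rule="GPR30 => TIMP1"),
    ]
    return NetworkModel(species=species, reactions=reactions,
                        metadata={"fixture": "mini_fibroblast"})


def mini_output_categories():
    """Output panels matching the mini-fibroblast fixture."""
    from .drug_screen import OutputCategories

    return OutputCategories(matrix=("proCI",), protease=("proMMP9",),
                            inhibitor=("TIMP1",))


# ---------------------------------------------------------------------------
# Estrogen-extension builder

@dataclass(frozen=True)
class ExtensionTables:
    """Additions and rule alterations merged onto a base network."""

    new_species: tuple[SpeciesSpec, ...]
    new_reactions: tuple[ReactionSpec, ...]
    altered: tuple[tuple[str, str], ...] = ()  # (old rule, new rule)


def build_estrogen_extension(base: NetworkModel,
                             extension: ExtensionTables) -> NetworkModel:
    """Merge an extension into a base network.

    New species are appended, new reactions added, and each ``(old, new)``
    alteration replaces the (unique) base reaction whose rule matches
    ``old``; a missing old rule raises.  Species count of the result is
    base + added; the merge is logged in the metadata.
    """
    merged = base.copy()
    existing = set(merged.species_ids)
    for s in extension.new_species:
        if s.id in existing:
            raise ModelValidationError(
                f"extension species {s.id!r} already present in base"
            )
        merged.species.append(s)
        existing.add(s.id)
    rules = [r.rule for r in merged.reactions]
    for old, new in extension.altered:
        try:
            i = rules.index(old)
        except ValueError:
            raise ModelValidationError(
                f"alteration references a rule absent from base: {old!r}"
            ) from None
        parse_rule(new)
        merged.reactions[i] = ReactionSpec(
            rule=new, w=merged.reactions[i].w,
            n=merged.reactions[i].n, ec50=merged.reactions[i].ec50,
        )
        rules[i] = new
    for r in extension.new_reactions:
        merged.reactions.append(r.resolved(merged.default_n, merged.default_ec50))
    merged.validate()
    merged.metadata = {
        **merged.metadata,
        "extension": {
            "species_added": len(extension.new_species),
            "reactions_added": len(extension.new_reactions),
            "reactions_altered": len(extension.altered),
        },
    }
    return merged


def estrogen_extension_tables() -> ExtensionTables:
    """Estrogen-extension rows reconstructable from the published network
    description: E2 with its receptors ERα, ERβ and GPR30, plus CyclinB1
    and CDK1 downstream of GPR30.

    Partial by design — only six of the seven new nodes and their
    first-connection edges are named in the published text; the complete
    reaction enumeration lives in the model's supplementary table, which
    users who have it can merge via :func:`build_estrogen_extension`.
    """
    new_species = (
        SpeciesSpec(id="E2", name="estradiol", role="input"),
        SpeciesSpec(id="ERA", name="estrogen receptor alpha"),
        SpeciesSpec(id="ERB", name="estrogen receptor beta"),
        SpeciesSpec(id="GPR30", name="G-protein coupled estrogen receptor"),
        SpeciesSpec(id="CyclinB1", name="cyclin B1"),
        SpeciesSpec(id="CDK1", name="cyclin-dependent kinase 1"),
    )
    new_reactions = (
        ReactionSpec(rule="=> E2", w=0.0),
        ReactionSpec(rule="E2 => ERA"),
        ReactionSpec(rule="E2 => ERB"),
        ReactionSpec(rule="E2 => GPR30"),
        ReactionSpec(rule="GPR30 => CyclinB1"),
        ReactionSpec(rule="CyclinB1 => CDK1"),
    )
    return ExtensionTables(new_species=new_species, new_reactions=new_reactions)


def synthetic_base_network(n_nodes: int = 125, seed: int = 7) -> NetworkModel:
    """Synthetic random-DAG stand-in for a large published base network.

    Used to exercise extension arithmetic and large-model plumbing at
    realistic size; it shares nothing but scale with any real model.
    """
    return make_toy_network(
        ToySpec(n_nodes=n_nodes, topology="random_dag",
                gate_mix={"and": 0.3, "not": 0.15}, seed=seed)
    )


def synthetic_estrogen_extension(base: NetworkModel,
                                 n_new_reactions: int = 29,
                                 n_altered: int = 6,
                                 seed: int = 11) -> ExtensionTables:
    """Synthetic 7-node estrogen extension wired into ``base``.

    Adds E2, its three receptors, CyclinB1, CDK1 and one synthetic effector
    node, with ``n_new_reactions`` edges (receptor wiring plus random
    receptor→base links) and ``n_altered`` base rules rewritten to include
    direct ERβ inhibition.  A synthetic stand-in for the published
    supplementary extension, sized to match its arithmetic (7 nodes).
    """
    rng = np.random.default_rng(seed)
    ext = estrogen_extension_tables()
    new_species = ext.new_species + (
        SpeciesSpec(id="E2eff", name="synthetic estrogen effector"),
    )
    reactions = list(ext.new_reactions)
    reactions.append(ReactionSpec(rule="ERA => E2eff"))

    base_ids = [s for s in base.species_ids]
    receptors = ("ERA", "ERB", "GPR30", "E2eff")
    while len(reactions) < n_new_reactions:
        src = receptors[int(rng.integers(0, len(receptors)))]
        dst = base_ids[int(rng.integers(0, len(base_ids)))]
        rule = f"{src} => {dst}"
        if rule not in [r.rule for r in reactions]:
            reactions.append(ReactionSpec(rule=rule))

    non_source = [r.rule for r in base.reactions if not r.parsed().is_source]
    altered = []
    for rule in list(rng.permutation(non_source))[:n_altered]:
        p = parse_rule(str(rule))
        lhs = " & ".join(("!" if neg else "") + sid for sid, neg in p.terms)
        altered.append((str(rule), f"{lhs} & !ERB => {p.product}"))
    return ExtensionTables(
        new_species=new_species,
        new_reactions=tuple(reactions[:n_new_reactions]),
        altered=tuple(altered),
    )
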