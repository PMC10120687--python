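"""Read, validate and write logic-ODE network model definitions.

A network model is a pair of tables in the Netflux tradition: a *species*
table (one row per molecular node: id, display name, maximal activity Ymax,
initial activity y0, time constant tau, reaction class) and a *reactions*
table (one row per edge: a logic rule string such as ``"AngII & !E2 =>
proCI"``, a reaction weight w, a Hill coefficient n and an EC50).  Several
reactions may share a product; they are OR-combined when the ODE right-hand
side is assembled.  A rule with no reactants (``"=> E2"``) is a *source*
reaction and its weight acts as the input stimulus level.
"""

from __future__ import annotations

import copy
import functools
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import ModelValidationError, RuleParseError

__all__ = [
    "SpeciesSpec",
    "ReactionSpec",
    "ParsedRule",
    "NetworkModel",
    "ValidationRecord",
    "DrugTarget",
    "NetworkSummary",
    "parse_rule",
    "format_rule",
    "load_network",
    "write_network",
    "network_summary",
    "load_validation_records",
    "write_validation_records",
    "load_drug_targets",
    "write_drug_targets",
    "DEFAULT_HILL_N",
    "DEFAULT_EC50",
    "TAU_BY_CLASS",
]

#: Model-level defaults: Hill coefficient and EC50 shared by every reaction
#: unless a row overrides them.
DEFAULT_HILL_N = 1.05
DEFAULT_EC50 = 0.65

#: Default time constants (hours) by reaction class.
TAU_BY_CLASS = {"signaling": 1.0, "transcription": 0.1, "translation": 10.0}

REACTION_CLASSES = frozenset(TAU_BY_CLASS)
ROLES = frozenset({"input", "intermediate", "output"})
EXPECTED_DIRECTIONS = frozenset({"up", "down", "nochange"})
CELL_SEXES = frozenset({"male", "female", "pooled", "unreported"})
DRUG_ACTIONS = frozenset({"agonist", "antagonist"})
DRUG_MECHANISMS = frozenset({"competitive", "noncompetitive"})

_ID_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


@dataclass(frozen=True)
class SpeciesSpec:
    """One molecular node: activity bounded by ``[0, ymax]``, relaxing with
    time constant ``tau`` (hours)."""

    id: str
    name: str = ""
    ymax: float = 1.0
    y0: float = 0.0
    tau: float | None = None  # None -> default by reaction_class
    reaction_class: str = "signaling"
    role: str = "intermediate"

    def resolved_tau(self, tau_by_class: Mapping[str, float] | None = None) -> float:
        if self.tau is not None:
            return float(self.tau)
        table = TAU_BY_CLASS if tau_by_class is None else tau_by_class
        return float(table[self.reaction_class])

    def validate(self) -> None:
        if not _ID_RE.match(self.id):
            raise ModelValidationError(f"invalid species id {self.id!r}")
        if self.ymax < 0:
            raise ModelValidationError(f"{self.id}: ymax must be >= 0, got {self.ymax}")
        if not (0 <= self.y0 <= self.ymax or (self.ymax == 0 and self.y0 == 0)):
            raise ModelValidationError(
                f"{self.id}: y0={self.y0} outside [0, ymax={self.ymax}]"
            )
        if self.tau is not None and self.tau <= 0:
            raise ModelValidationError(f"{self.id}: tau must be > 0, got {self.tau}")
        if self.reaction_class not in REACTION_CLASSES:
            raise ModelValidationError(
                f"{self.id}: unknown reaction_class {self.reaction_class!r} "
                f"(expected one of {sorted(REACTION_CLASSES)})"
            )
        if self.role not in ROLES:
            raise ModelValidationError(
                f"{self.id}: unknown role {self.role!r} (expected one of {sorted(ROLES)})"
            )


@dataclass(frozen=True)
class ParsedRule:
    """Structured form of a logic rule: product id plus ``(reactant,
    negated)`` terms, AND-combined.  Empty terms mark a source reaction."""

    product: str
    terms: tuple[tuple[str, bool], ...]

    @property
    def is_source(self) -> bool:
        return not self.terms

    @property
    def reactants(self) -> tuple[str, ...]:
        return tuple(t[0] for t in self.terms)


@dataclass(frozen=True)
class ReactionSpec:
    """One reaction: AND over its (possibly negated) Hill-transformed
    reactants, scaled by weight ``w``; OR-combined with sibling reactions
    sharing the product."""

    rule: str
    w: float = 1.0
    n: float | None = None  # None -> model default
    ec50: float | None = None

    def parsed(self) -> ParsedRule:
        return parse_rule(self.rule)

    def resolved(self, default_n: float = DEFAULT_HILL_N,
                 default_ec50: float = DEFAULT_EC50) -> "ReactionSpec":
        return replace(
            self,
            n=self.n if self.n is not None else default_n,
            ec50=self.ec50 if self.ec50 is not None else default_ec50,
        )

    def validate(self) -> None:
        parse_rule(self.rule)
        if not (0 <= self.w <= 1):
            raise ModelValidationError(f"{self.rule!r}: w={self.w} outside [0, 1]")
        if self.n is not None and self.n <= 0:
            raise ModelValidationError(f"{self.rule!r}: n must be > 0, got {self.n}")
        if self.ec50 is not None and not (0 < self.ec50 < 1):
            raise ModelValidationError(
                f"{self.rule!r}: ec50={self.ec50} outside open interval (0, 1)"
            )


@functools.lru_cache(maxsize=None)
def parse_rule(rule: str) -> ParsedRule:
    """Parse ``"[!]A & [!]B => C"`` into a :class:`ParsedRule`.

    OR across reactions is expressed as separate rows sharing a product, so
    ``|`` inside a rule is rejected with a pointer to that convention.
    """
    if not isinstance(rule, str):
        raise RuleParseError(f"rule must be a string, got {type(rule).__name__}")
    if "|" in rule:
        raise RuleParseError(
            f"{rule!r}: OR is expressed as multiple reactions sharing a product, "
            "not with '|' inside one rule"
        )
    if "=>" not in rule:
        raise RuleParseError(f"{rule!r}: missing '=>'")
    lhs, _, rhs = rule.partition("=>")
    product = rhs.strip()
    if not _ID_RE.match(product):
        raise RuleParseError(f"{rule!r}: invalid product token {product!r}")
    terms: list[tuple[str, bool]] = []
    lhs = lhs.strip()
    if lhs:
        for raw in lhs.split("&"):
            tok = raw.strip()
            negated = tok.startswith("!")
            if negated:
                tok = tok[1:].strip()
            if not _ID_RE.match(tok):
                raise RuleParseError(f"{rule!r}: invalid reactant token {raw.strip()!r}")
            terms.append((tok, negated))
    return ParsedRule(product=product, terms=tuple(terms))


def format_rule(parsed: ParsedRule) -> str:
    """Inverse of :func:`parse_rule` (identity on canonical spacing)."""
    lhs = " & ".join(("!" if neg else "") + sid for sid, neg in parsed.terms)
    return f"{lhs} => {parsed.product}" if lhs else f"=> {parsed.product}"


@dataclass
class NetworkModel:
    """A fully resolved, validated logic-ODE network.

    Construction fills per-reaction ``n``/``ec50`` and per-species ``tau``
    from model-level defaults and cross-checks every rule reference.
    """

    species: list[SpeciesSpec]
    reactions: list[ReactionSpec]
    metadata: dict = field(default_factory=dict)
    default_n: float = DEFAULT_HILL_N
    default_ec50: float = DEFAULT_EC50
    tau_by_class: dict[str, float] = field(default_factory=lambda: dict(TAU_BY_CLASS))

    def __post_init__(self) -> None:
        self.species = [s for s in self.species]
        self.reactions = [r.resolved(self.default_n, self.default_ec50)
                          for r in self.reactions]
        self.validate()

    # -- structural queries -------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def index_of(self, species_id: str) -> int:
        try:
            return self.species_ids.index(species_id)
        except ValueError:
            raise ModelValidationError(f"unknown species {species_id!r}") from None

    def get_species(self, species_id: str) -> SpeciesSpec:
        return self.species[self.index_of(species_id)]

    def producers(self, species_id: str) -> list[ReactionSpec]:
        return [r for r in self.reactions if r.parsed().product == species_id]

    @property
    def input_ids(self) -> list[str]:
        """Species driven by at least one source reaction, in species order."""
        sourced = {r.parsed().product for r in self.reactions if r.parsed().is_source}
        return [sid for sid in self.species_ids if sid in sourced]

    def validate(self) -> None:
        seen: set[str] = set()
        for s in self.species:
            s.validate()
            if s.id in seen:
                raise ModelValidationError(f"duplicate species id {s.id!r}")
            seen.add(s.id)
        missing: list[str] = []
        for r in self.reactions:
            r.validate()
            p = r.parsed()
            for sid in (p.product, *p.reactants):
                if sid not in seen and sid not in missing:
                    missing.append(sid)
        if missing:
            raise ModelValidationError(
                "rules reference undeclared species: " + ", ".join(sorted(missing))
            )

    # -- functional updates (originals untouched) ---------------------------
    def copy(self) -> "NetworkModel":
        return copy.deepcopy(self)

    def with_species_ymax(self, updates: Mapping[str, float]) -> "NetworkModel":
        m = self.copy()
        for sid, ymax in updates.items():
            i = m.index_of(sid)
            s = m.species[i]
            m.species[i] = replace(s, ymax=float(ymax), y0=min(s.y0, float(ymax)))
        return m

    def with_source_weight(self, species_id: str, w: float) -> "NetworkModel":
        """Set the weight of every source reaction feeding ``species_id``."""
        m = self.copy()
        hit = False
        for i, r in enumerate(m.reactions):
            p = r.parsed()
            if p.is_source and p.product == species_id:
                m.reactions[i] = replace(r, w=float(w))
                hit = True
        if not hit:
            raise ModelValidationError(f"{species_id!r} has no source reaction")
        return m

    def with_added_reaction(self, reaction: ReactionSpec) -> "NetworkModel":
        m = self.copy()
        m.reactions.append(reaction.resolved(m.default_n, m.default_ec50))
        m.validate()
        return m


# ---------------------------------------------------------------------------
# Auxiliary record types

@dataclass(frozen=True)
class ValidationRecord:
    """One literature perturbation experiment: stimulus applied, node
    measured, reported direction, sex of the cells, citation."""

    stimulus: str
    measured: str
    expected: str
    cell_sex: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.expected not in EXPECTED_DIRECTIONS:
            raise ModelValidationError(
                f"expected={self.expected!r} not in {sorted(EXPECTED_DIRECTIONS)}"
            )
        if self.cell_sex not in CELL_SEXES:
            raise ModelValidationError(
                f"cell_sex={self.cell_sex!r} not in {sorted(CELL_SEXES)}"
            )


@dataclass(frozen=True)
class DrugTarget:
    """One drug-target interaction: agonist/antagonist,
    competitive/non-competitive, possibly multi-target."""

    drug_id: str
    targets: tuple[str, ...]
    action: str
    mechanism: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(self.targets))
        if not self.targets:
            raise ModelValidationError(f"{self.drug_id}: empty target list")
        if self.action not in DRUG_ACTIONS:
            raise ModelValidationError(
                f"{self.drug_id}: action {self.action!r} not in {sorted(DRUG_ACTIONS)}"
            )
        if self.mechanism not in DRUG_MECHANISMS:
            raise ModelValidationError(
                f"{self.drug_id}: mechanism {self.mechanism!r} "
                f"not in {sorted(DRUG_MECHANISMS)}"
            )


# ---------------------------------------------------------------------------
# Tabular IO

_SPECIES_COLUMNS = ["id", "name", "ymax", "y0", "tau", "reaction_class", "role"]
_REACTION_COLUMNS = ["rule", "w", "n", "ec50"]


def _species_from_row(row: pd.Series) -> SpeciesSpec:
    def _get(col, default):
        v = row.get(col)
        return default if v is None or (isinstance(v, float) and pd.isna(v)) or v == "" else v

    tau = _get("tau", None)
    return SpeciesSpec(
        id=str(row["id"]).strip(),
        name=str(_get("name", "")),
        ymax=float(_get("ymax", 1.0)),
        y0=float(_get("y0", 0.0)),
        tau=None if tau is None else float(tau),
        reaction_class=str(_get("reaction_class", "signaling")).strip(),
        role=str(_get("role", "intermediate")).strip(),
    )


def _reaction_from_row(row: pd.Series) -> ReactionSpec:
    def _opt(col):
        v = row.get(col)
        if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
            return None
        return float(v)

    w = _opt("w")
    return ReactionSpec(
        rule=str(row["rule"]).strip(),
        w=1.0 if w is None else w,
        n=_opt("n"),
        ec50=_opt("ec50"),
    )


def _frames_from_source(source) -> tuple[pd.DataFrame, pd.DataFrame]:
    if isinstance(source, tuple) and len(source) == 2:
        a, b = source
        if isinstance(a, pd.DataFrame) and isinstance(b, pd.DataFrame):
            return a, b
        return pd.read_csv(a), pd.read_csv(b)
    path = Path(source)
    if path.is_dir():
        return (pd.read_csv(path / "species.csv"), pd.read_csv(path / "reactions.csv"))
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        sheets = pd.read_excel(path, sheet_name=None)
        keys = {k.lower(): k for k in sheets}
        try:
            return sheets[keys["species"]], sheets[keys["reactions"]]
        except KeyError:
            raise ModelValidationError(
                f"{path}: expected sheets 'species' and 'reactions', "
                f"found {sorted(sheets)}"
            ) from None
    raise ModelValidationError(f"cannot interpret model source {source!r}")


def load_network(source, *, default_n: float = DEFAULT_HILL_N,
                 default_ec50: float = DEFAULT_EC50,
                 tau_by_class: Mapping[str, float] | None = None,
                 metadata: dict | None = None) -> NetworkModel:
    """Load a :class:`NetworkModel` from CSV pair, directory, spreadsheet,
    or an in-memory ``(species_df, reactions_df)`` tuple.

    Missing per-row ``n``/``ec50``/``tau`` are filled from the model-level
    defaults; cross-references are checked and all offending undeclared
    species reported at once.
    """
    sp_df, rx_df = _frames_from_source(source)
    if len(sp_df) and "id" not in sp_df.columns:
        raise ModelValidationError("species table lacks required column 'id'")
    if len(rx_df) and "rule" not in rx_df.columns:
        raise ModelValidationError("reactions table lacks required column 'rule'")
    species = [_species_from_row(row) for _, row in sp_df.iterrows()]
    reactions = [_reaction_from_row(row) for _, row in rx_df.iterrows()]
    return NetworkModel(
        species=species,
        reactions=reactions,
        metadata=dict(metadata or {}),
        default_n=default_n,
        default_ec50=default_ec50,
        tau_by_class=dict(tau_by_class or TAU_BY_CLASS),
    )


def network_to_frames(model: NetworkModel) -> tuple[pd.DataFrame, pd.DataFrame]:
    sp = pd.DataFrame(
        [
            {
                "id": s.id,
                "name": s.name,
                "ymax": s.ymax,
                "y0": s.y0,
                "tau": s.resolved_tau(model.tau_by_class),
                "reaction_class": s.reaction_class,
                "role": s.role,
            }
            for s in model.species
        ],
        columns=_SPECIES_COLUMNS,
    )
    rx = pd.DataFrame(
        [{"rule": r.rule, "w": r.w, "n": r.n, "ec50": r.ec50} for r in model.reactions],
        columns=_REACTION_COLUMNS,
    )
    return sp, rx


def write_network(model: NetworkModel, destination) -> None:
    """Serialize a model so :func:`load_network` reproduces it exactly.

    ``destination`` is a directory (``species.csv`` + ``reactions.csv``) or
    an ``.xlsx`` path.  Defaults are written out explicitly.
    """
    sp, rx = network_to_frames(model)
    path = Path(destination)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        # a leading "=" would be read back as a spreadsheet formula; pad
        # source rules with a space (the rule parser strips whitespace)
        rx = rx.assign(rule=rx["rule"].map(
            lambda r: " " + r if r.startswith("=") else r))
        with pd.ExcelWriter(path) as xw:
            sp.to_excel(xw, sheet_name="species", index=False)
            rx.to_excel(xw, sheet_name="reactions", index=False)
        return
    path.mkdir(parents=True, exist_ok=True)
    sp.to_csv(path / "species.csv", index=False)
    rx.to_csv(path / "reactions.csv", index=False)


@dataclass(frozen=True)
class NetworkSummary:
    n_species: int
    n_reactions: int
    by_role: dict
    by_reaction_class: dict

    def __iter__(self):  # allows tuple-unpacking (nodes, edges)
        return iter((self.n_species, self.n_reactions))


def network_summary(model: NetworkModel) -> NetworkSummary:
    """Node/edge counts (source reactions included) plus role/class tallies."""
    by_role: dict[str, int] = {}
    by_class: dict[str, int] = {}
    for s in model.species:
        by_role[s.role] = by_role.get(s.role, 0) + 1
        by_class[s.reaction_class] = by_class.get(s.reaction_class, 0) + 1
    return NetworkSummary(
        n_species=len(model.species),
        n_reactions=len(model.reactions),
        by_role=by_role,
        by_reaction_class=by_class,
    )


# ---------------------------------------------------------------------------
# Validation-record and drug tables

def load_validation_records(source) -> list[ValidationRecord]:
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    return [
        ValidationRecord(
            stimulus=str(r["stimulus"]).strip(),
            measured=str(r["measured"]).strip(),
            expected=str(r["expected"]).strip(),
            cell_sex=str(r["cell_sex"]).strip(),
            source=str(r.get("source", "") or ""),
        )
        for _, r in df.iterrows()
    ]


def write_validation_records(records: Iterable[ValidationRecord], destination) -> None:
    pd.DataFrame(
        [
            {
                "stimulus": r.stimulus,
                "measured": r.measured,
                "expected": r.expected,
                "cell_sex": r.cell_sex,
                "source": r.source,
            }
            for r in records
        ]
    ).to_csv(destination, index=False)


def load_drug_targets(source) -> list[DrugTarget]:
    """Drug table CSV: columns drug_id, targets (semicolon-separated),
    action, mechanism."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    return [
        DrugTarget(
            drug_id=str(r["drug_id"]).strip(),
            targets=tuple(t.strip() for t in str(r["targets"]).split(";") if t.strip()),
            action=str(r["action"]).strip(),
            mechanism=str(r["mechanism"]).strip(),
        )
        for _, r in df.iterrows()
    ]


def write_drug_targets(drugs: Iterable[DrugTarget], destination) -> None:
    pd.DataFrame(
        [
            {
                "drug_id": d.drug_id,
                "targets": ";".join(d.targets),
                "action": d.action,
                "mechanism": d.mechanism,
            }
            for d in drugs
        ]
    ).to_csv(destination, index=False)
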