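"""Executable dichotomous identification key.

A key is an ordered set of numbered couplets, each with two mutually
exclusive leads. A lead either forwards to another couplet or terminates in
a species. Lead texts are kept verbatim; the machine-readable layer is a
list of predicates per lead, over either coded matrix characters (in-set on
state codes) or quantitative/qualitative description fields (inclusive
numeric ranges, token sets).

Identification is deterministic: at each couplet exactly one lead must be
satisfied by the subject. A subject that satisfies both leads (or neither)
raises an ambiguity error naming the couplet; a subject lacking a value the
couplet needs raises an incomplete-subject error. The same machinery drives
the key-vs-matrix consistency check, which runs every species' own coded
data through the key and reports conflicts instead of resolving them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .morphology import CharacterMatrix, SpeciesDescription, StateSet

__all__ = [
    "Predicate",
    "Lead",
    "Couplet",
    "DichotomousKey",
    "KeyValidationReport",
    "KeySubject",
    "KeyParseError",
    "IdentificationError",
    "AmbiguityError",
    "IncompleteSubjectError",
    "load_key",
    "validate_key",
    "identify",
    "subject_for_species",
    "consistency_check",
]


class KeyParseError(ValueError):
    """Raised when a key file is structurally invalid."""


class IdentificationError(Exception):
    """Base class for traversal failures; carries the couplet id."""

    def __init__(self, couplet_id: int, message: str):
        super().__init__(f"couplet {couplet_id}: {message}")
        self.couplet_id = couplet_id


class AmbiguityError(IdentificationError):
    """Both leads (or neither lead) of a couplet are satisfied."""


class IncompleteSubjectError(IdentificationError):
    """The subject lacks a value needed to evaluate a couplet."""


@dataclass(frozen=True)
class KeySubject:
    """What the key sees of a specimen: coded character states plus
    description fields (numeric scalars/ranges or token sets)."""

    states: Mapping[str, StateSet] = field(default_factory=dict)
    fields: Mapping[str, object] = field(default_factory=dict)
    label: str = ""


@dataclass(frozen=True)
class Predicate:
    """One testable condition of a lead.

    Exactly one of ``states`` (in-set on matrix codes), ``value_range``
    (inclusive numeric interval, upper bound None = unbounded) or ``tokens``
    (in-set on description tokens) is set; ``key`` names the matrix character
    or description field it applies to.
    """

    key: str
    states: frozenset[int] | None = None
    value_range: tuple[float, float | None] | None = None
    tokens: frozenset[str] | None = None

    def __post_init__(self) -> None:
        set_kinds = sum(
            x is not None for x in (self.states, self.value_range, self.tokens)
        )
        if set_kinds != 1:
            raise KeyParseError(
                f"predicate on {self.key!r} must have exactly one of "
                "states/range/tokens"
            )
        if self.states is not None and not self.states:
            raise KeyParseError(f"predicate on {self.key!r}: empty state set")
        if self.value_range is not None:
            lo, hi = self.value_range
            if hi is not None and hi < lo:
                raise KeyParseError(f"predicate on {self.key!r}: empty range")

    @property
    def is_categorical(self) -> bool:
        return self.states is not None

    def evaluate(self, subject: KeySubject) -> bool | None:
        """True/False when decidable, None when the subject lacks the value."""
        if self.states is not None:
            s = subject.states.get(self.key)
            if s is None or s.unknown:
                return None
            return s.states <= self.states
        value = subject.fields.get(self.key)
        if value is None:
            return None
        if self.value_range is not None:
            lo, hi = self.value_range
            if isinstance(value, (int, float)):
                vlo = vhi = float(value)
            else:
                vlo, vhi = float(value[0]), float(value[1])
            return vlo >= lo and (hi is None or vhi <= hi)
        toks = {value} if isinstance(value, str) else set(value)
        if not toks:
            return None
        return toks <= self.tokens


@dataclass(frozen=True)
class Lead:
    """One half of a couplet: verbatim text, predicates, and a target."""

    text: str
    predicates: tuple[Predicate, ...]
    couplet: int | None = None
    species: str | None = None

    def __post_init__(self) -> None:
        if (self.couplet is None) == (self.species is None):
            raise KeyParseError(
                f"lead {self.text!r} must target exactly one of couplet/species"
            )

    def evaluate(self, subject: KeySubject) -> bool | None:
        """Conjunction over predicates; None dominates False-free results."""
        result: bool | None = True
        for p in self.predicates:
            r = p.evaluate(subject)
            if r is False:
                return False
            if r is None:
                result = None
        return result


@dataclass(frozen=True)
class Couplet:
    id: int
    lead_a: Lead
    lead_b: Lead

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise KeyParseError(f"couplet id must be positive, got {self.id}")
        # Where both leads constrain the same character categorically, the
        # state sets must be disjoint (otherwise the couplet cannot decide).
        a_cat = {p.key: p.states for p in self.lead_a.predicates if p.is_categorical}
        for p in self.lead_b.predicates:
            if p.is_categorical and p.key in a_cat:
                if a_cat[p.key] & p.states:
                    raise KeyParseError(
                        f"couplet {self.id}: leads overlap on character {p.key!r}"
                    )

    @property
    def leads(self) -> tuple[Lead, Lead]:
        return (self.lead_a, self.lead_b)


@dataclass(frozen=True)
class DichotomousKey:
    couplets: tuple[Couplet, ...]
    root: int

    def __post_init__(self) -> None:
        ids = [c.id for c in self.couplets]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise KeyParseError(f"duplicate couplet ids: {dupes}")
        by_id = {c.id: c for c in self.couplets}
        if self.root not in by_id:
            raise KeyParseError(f"root couplet {self.root} not present")
        for c in self.couplets:
            for lead in c.leads:
                if lead.couplet is not None and lead.couplet not in by_id:
                    raise KeyParseError(
                        f"couplet {c.id}: lead targets missing couplet {lead.couplet}"
                    )

    def couplet(self, cid: int) -> Couplet:
        for c in self.couplets:
            if c.id == cid:
                return c
        raise KeyError(f"no couplet {cid}")

    def terminal_species(self) -> list[str]:
        return [
            lead.species
            for c in self.couplets
            for lead in c.leads
            if lead.species is not None
        ]


@dataclass(frozen=True)
class KeyValidationReport:
    """Structural validation and (optionally) matrix-consistency findings."""

    reachable: Mapping[int, bool]
    terminal_species: tuple[str, ...]
    cycles: tuple[tuple[int, ...], ...]
    conflicts: tuple[tuple[str, int | None, str, str], ...] = ()
    # conflicts: (species, couplet id or None, character/field, detail)

    @property
    def duplicate_terminals(self) -> tuple[str, ...]:
        counts = Counter(self.terminal_species)
        return tuple(sorted(sp for sp, n in counts.items() if n > 1))

    @property
    def unreachable(self) -> tuple[int, ...]:
        return tuple(sorted(cid for cid, ok in self.reachable.items() if not ok))

    def ok(self, species: Sequence[str] | None = None) -> bool:
        if self.unreachable or self.cycles or self.duplicate_terminals:
            return False
        if self.conflicts:
            return False
        if species is not None and sorted(self.terminal_species) != sorted(species):
            return False
        return True


def _parse_predicate(raw: Mapping) -> Predicate:
    if "character" in raw:
        return Predicate(key=raw["character"], states=frozenset(raw["states"]))
    if "field" in raw and "range" in raw:
        lo, hi = raw["range"]
        return Predicate(
            key=raw["field"],
            value_range=(float(lo), None if hi is None else float(hi)),
        )
    if "field" in raw and "tokens" in raw:
        return Predicate(key=raw["field"], tokens=frozenset(raw["tokens"]))
    raise KeyParseError(f"unrecognised predicate {raw!r}")


def load_key(path: str | Path) -> DichotomousKey:
    """Load a structured key file (one record per couplet, two leads each)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    couplets = []
    for c in raw["couplets"]:
        leads = []
        for entry in c["leads"]:
            leads.append(
                Lead(
                    text=entry["text"],
                    predicates=tuple(
                        _parse_predicate(p) for p in entry.get("predicates", [])
                    ),
                    couplet=entry.get("couplet"),
                    species=entry.get("species"),
                )
            )
        if len(leads) != 2:
            raise KeyParseError(f"couplet {c['id']} must have exactly two leads")
        couplets.append(Couplet(id=int(c["id"]), lead_a=leads[0], lead_b=leads[1]))
    return DichotomousKey(couplets=tuple(couplets), root=int(raw.get("root", 1)))


def validate_key(
    key: DichotomousKey, species: Sequence[str] | None = None
) -> KeyValidationReport:
    """Check reachability from the root, acyclicity, and terminal coverage."""
    graph = {
        c.id: [lead.couplet for lead in c.leads if lead.couplet is not None]
        for c in key.couplets
    }
    # reachability
    reachable = {cid: False for cid in graph}
    stack = [key.root]
    while stack:
        cid = stack.pop()
        if reachable[cid]:
            continue
        reachable[cid] = True
        stack.extend(graph[cid])
    # cycle detection (iterative DFS with colouring)
    cycles: list[tuple[int, ...]] = []
    colour = {cid: 0 for cid in graph}  # 0 white, 1 grey, 2 black
    path: list[int] = []

    def visit(start: int) -> None:
        stack = [(start, iter(graph[start]))]
        colour[start] = 1
        path.append(start)
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if colour[nxt] == 1:
                    cycles.append(tuple(path[path.index(nxt):] + [nxt]))
                elif colour[nxt] == 0:
                    colour[nxt] = 1
                    path.append(nxt)
                    stack.append((nxt, iter(graph[nxt])))
                    advanced = True
                    break
            if not advanced:
                stack.pop()
                colour[node] = 2
                path.pop()

    for cid in graph:
        if colour[cid] == 0:
            visit(cid)

    terminals = tuple(key.terminal_species())
    conflicts: list[tuple[str, int | None, str, str]] = []
    if species is not None:
        missing = sorted(set(species) - set(terminals))
        extra = sorted(set(terminals) - set(species))
        for sp in missing:
            conflicts.append((sp, None, "terminal", "species absent from key"))
        for sp in extra:
            conflicts.append((sp, None, "terminal", "terminal not in species list"))
    return KeyValidationReport(
        reachable=reachable,
        terminal_species=terminals,
        cycles=tuple(cycles),
        conflicts=tuple(conflicts),
    )


def identify(key: DichotomousKey, subject: KeySubject) -> tuple[str, list[int]]:
    """Run a subject through the key; return (species, couplet path).

    Raises AmbiguityError when both or neither lead of a couplet is
    satisfied, IncompleteSubjectError when a needed value is missing.
    """
    path: list[int] = []
    cid = key.root
    for _ in range(len(key.couplets) + 1):
        couplet = key.couplet(cid)
        path.append(cid)
        results = [lead.evaluate(subject) for lead in couplet.leads]
        if results.count(True) == 1:
            chosen = couplet.leads[results.index(True)]
        elif None in results:
            missing = sorted(
                {
                    p.key
                    for lead in couplet.leads
                    for p in lead.predicates
                    if p.evaluate(subject) is None
                }
            )
            raise IncompleteSubjectError(
                cid, f"subject lacks value(s) for {missing}"
            )
        else:
            which = "both leads satisfied" if results.count(True) == 2 else "neither lead satisfied"
            raise AmbiguityError(cid, which)
        if chosen.species is not None:
            return chosen.species, path
        cid = chosen.couplet
    raise AmbiguityError(path[-1], "traversal exceeded couplet count (cycle?)")


def subject_for_species(
    species: str,
    matrix: CharacterMatrix,
    descriptions: Mapping[str, SpeciesDescription] | None = None,
) -> KeySubject:
    """Build a KeySubject from a species' own matrix row and description."""
    profile = matrix.profile_of(species)
    states = dict(zip(matrix.character_ids, profile.states))
    fields: dict[str, object] = {}
    if descriptions and species in descriptions:
        d = descriptions[species]
        fields["spire_height"] = d.spire_height
        fields["spire_width"] = d.spire_width
        fields["whorls"] = d.whorls
        fields["rib_density"] = d.rib_density
        if d.whorl_periphery:
            fields["whorl_periphery"] = d.whorl_periphery
        if d.tuba_length_ratio is not None:
            fields["tuba_length_ratio"] = d.tuba_length_ratio
        if d.tuba_attachment is not None:
            fields["tuba_attachment"] = d.tuba_attachment
        fields.update(d.extras)
    return KeySubject(states=states, fields=fields, label=species)


def consistency_check(
    key: DichotomousKey,
    matrix: CharacterMatrix,
    descriptions: Mapping[str, SpeciesDescription] | None = None,
) -> KeyValidationReport:
    """Run every matrix species through the key on its own coded data.

    Records a conflict when the traversal lands on a different species, is
    ambiguous, or needs a value the species' data does not provide. Conflicts
    are reported with provenance, never resolved.
    """
    base = validate_key(key, species=list(matrix.species))
    conflicts = list(base.conflicts)
    for sp in matrix.species:
        subject = subject_for_species(sp, matrix, descriptions)
        try:
            terminal, _path = identify(key, subject)
        except IncompleteSubjectError as e:
            conflicts.append((sp, e.couplet_id, "missing-data", str(e)))
            continue
        except AmbiguityError as e:
            conflicts.append((sp, e.couplet_id, "ambiguity", str(e)))
            continue
        if terminal != sp:
            conflicts.append(
                (sp, None, "terminal", f"identified as {terminal!r}")
            )
    return KeyValidationReport(
        reachable=base.reachable,
        terminal_species=base.terminal_species,
        cycles=base.cycles,
        conflicts=tuple(conflicts),
    )
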