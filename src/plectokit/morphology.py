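"""Shell-character matrix model and diagnosability analysis.

The taxonomic backbone of the toolkit is a species x character matrix of
11 general qualitative shell characters (apex form, apical/basal spire form,
constriction teeth, tuba form, aperture view, peristome type, spiral lines,
rib shape and rib thickness). Cells hold coded states, possibly polymorphic
("2 or 3") or unknown ("?"). Two species are *diagnosable* from each other
when at least one character has disjoint, known state sets; a species is
*unique* when no other species carries an identical state-set vector.

The default profile-equality semantics is exact: two cells are equal iff
their state sets are identical, with "?" equal only to "?". An alternative
"overlap" semantics (cells conflict only when their known state sets are
disjoint) can be selected where a more conservative grouping is wanted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "CharacterDefinition",
    "StateSet",
    "SpeciesProfile",
    "CharacterMatrix",
    "SpeciesDescription",
    "DiagnosisReport",
    "MatrixParseError",
    "parse_state_cell",
    "load_matrix",
    "collapse_forms",
    "find_unique_profiles",
    "diagnostic_characters",
]


class MatrixParseError(ValueError):
    """Raised when a character-matrix table cannot be parsed."""


@dataclass(frozen=True)
class CharacterDefinition:
    """One coded shell character and its legend of integer state codes."""

    character_id: str
    name: str
    state_codes: Mapping[int, str]
    figure_ref: str = ""

    def __post_init__(self) -> None:
        if not self.state_codes:
            raise ValueError(f"character {self.character_id!r} has no states")
        for code, label in self.state_codes.items():
            if not (isinstance(code, int) and code > 0):
                raise ValueError(
                    f"character {self.character_id!r}: state code {code!r} "
                    "must be a positive integer"
                )
            if not label:
                raise ValueError(
                    f"character {self.character_id!r}: empty label for code {code}"
                )

    def valid_codes(self) -> frozenset[int]:
        return frozenset(self.state_codes)


@dataclass(frozen=True)
class StateSet:
    """States observed for one species in one character.

    ``unknown`` encodes the "?" cell and holds exactly when ``states`` is
    empty. Polymorphic cells ("2 or 3") carry two or more codes.
    """

    states: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", frozenset(self.states))

    @property
    def unknown(self) -> bool:
        return not self.states

    @property
    def polymorphic(self) -> bool:
        return len(self.states) >= 2

    def disjoint_from(self, other: "StateSet") -> bool:
        """True when both sets are known and share no state."""
        if self.unknown or other.unknown:
            return False
        return self.states.isdisjoint(other.states)

    def __str__(self) -> str:
        if self.unknown:
            return "?"
        return " or ".join(str(c) for c in sorted(self.states))


@dataclass(frozen=True)
class SpeciesProfile:
    """Ordered state-set vector for one species (or one form of a species)."""

    species: str
    states: tuple[StateSet, ...]
    form_label: str | None = None

    @property
    def row_label(self) -> str:
        return f"{self.species} {self.form_label}" if self.form_label else self.species


@dataclass(frozen=True)
class CharacterMatrix:
    """Character definitions plus one profile row per species/form."""

    definitions: tuple[CharacterDefinition, ...]
    profiles: tuple[SpeciesProfile, ...]

    def __post_init__(self) -> None:
        labels = [p.row_label for p in self.profiles]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate species/form rows: {dupes}")
        n = len(self.definitions)
        for p in self.profiles:
            if len(p.states) != n:
                raise ValueError(
                    f"profile {p.row_label!r} has {len(p.states)} cells, "
                    f"expected {n}"
                )
            for d, s in zip(self.definitions, p.states):
                bad = s.states - d.valid_codes()
                if bad:
                    raise ValueError(
                        f"profile {p.row_label!r}, character "
                        f"{d.character_id!r}: invalid codes {sorted(bad)}"
                    )

    @property
    def character_ids(self) -> tuple[str, ...]:
        return tuple(d.character_id for d in self.definitions)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(p.species for p in self.profiles)

    def profile_of(self, species: str) -> SpeciesProfile:
        for p in self.profiles:
            if p.species == species:
                return p
        raise KeyError(f"species {species!r} not in matrix")

    def states_of(self, species: str, character_id: str) -> StateSet:
        idx = self.character_ids.index(character_id)
        return self.profile_of(species).states[idx]


@dataclass(frozen=True)
class SpeciesDescription:
    """Quantitative/qualitative description fields for one species.

    Ranges are inclusive ``(low, high)`` tuples: spire height and width in mm,
    whorl counts in whorls, rib density in ribs per mm on the whorl above the
    constriction, tuba length as a fraction of the spire's last whorl, tuba
    attachment as the attached fraction of the tuba. ``whorl_periphery`` holds
    convexity tokens (flat/slight/moderate/distinct); ``extras`` carries any
    further key-relevant fields (e.g. peristome projection ratio).
    """

    species: str
    spire_height: tuple[float, float]
    spire_width: tuple[float, float]
    whorls: tuple[float, float]
    rib_density: tuple[float, float]
    whorl_periphery: frozenset[str] = frozenset()
    tuba_length_ratio: tuple[float, float] | None = None
    tuba_attachment: tuple[float, float] | None = None
    type_locality: tuple[float, float] | None = None
    extras: Mapping[str, object] = field(default_factory=dict)

    # Genus-wide plausibility bounds for the revised fauna.
    HEIGHT_BOUNDS = (1.0, 3.8)
    WIDTH_BOUNDS = (0.85, 2.60)
    RIB_DENSITY_BOUNDS = (3.0, 32.0)

    def __post_init__(self) -> None:
        for name, rng, bounds in (
            ("spire_height", self.spire_height, self.HEIGHT_BOUNDS),
            ("spire_width", self.spire_width, self.WIDTH_BOUNDS),
            ("rib_density", self.rib_density, self.RIB_DENSITY_BOUNDS),
        ):
            lo, hi = rng
            if not (lo <= hi):
                raise ValueError(f"{self.species}: {name} range {rng} is empty")
            if lo < bounds[0] or hi > bounds[1]:
                raise ValueError(
                    f"{self.species}: {name} {rng} outside genus bounds {bounds}"
                )

    def field_value(self, name: str):
        """Look up a description field by name (dataclass field or extra)."""
        if hasattr(self, name):
            return getattr(self, name)
        return self.extras.get(name)


@dataclass(frozen=True)
class DiagnosisReport:
    """Outcome of the unique-profile analysis of a species-level matrix."""

    unique_species: tuple[str, ...]
    shared_groups: tuple[frozenset[str], ...]
    pairwise_diagnostics: Mapping[frozenset[str], tuple[str, ...]]

    @property
    def n_species(self) -> int:
        return len(self.unique_species) + sum(len(g) for g in self.shared_groups)


def parse_state_cell(cell: str) -> StateSet:
    """Parse a matrix cell: an integer code, ``a or b`` polymorphism, or ``?``."""
    text = str(cell).strip()
    if text == "?":
        return StateSet()
    parts = [p.strip() for p in text.lower().split("or")]
    try:
        codes = [int(p) for p in parts if p]
    except ValueError:
        raise MatrixParseError(f"unparseable state cell {cell!r}") from None
    if not codes:
        raise MatrixParseError(f"empty state cell {cell!r}")
    return StateSet(frozenset(codes))


def load_matrix(
    path: str | Path, definitions: Sequence[CharacterDefinition]
) -> CharacterMatrix:
    """Load a TSV character matrix against a character legend.

    The table needs ``species`` and ``form_label`` columns followed by one
    column per character (matched by ``character_id``). Cells are integer
    codes, ``a or b`` polymorphisms, or ``?`` for unknown.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = [d.character_id for d in definitions]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise MatrixParseError(f"matrix at {path} lacks character columns {missing}")
    if "species" not in df.columns:
        raise MatrixParseError(f"matrix at {path} lacks a 'species' column")

    profiles = []
    for row_i, row in df.iterrows():
        cells = []
        for d in definitions:
            raw = row[d.character_id]
            try:
                s = parse_state_cell(raw)
            except MatrixParseError as e:
                raise MatrixParseError(
                    f"row {row_i + 1} ({row['species']}), column "
                    f"{d.character_id!r}: {e}"
                ) from None
            bad = s.states - d.valid_codes()
            if bad:
                raise MatrixParseError(
                    f"row {row_i + 1} ({row['species']}), column "
                    f"{d.character_id!r}: code(s) {sorted(bad)} not in legend "
                    f"{sorted(d.valid_codes())}"
                )
            cells.append(s)
        form = row.get("form_label", "") or None
        profiles.append(
            SpeciesProfile(species=row["species"], form_label=form, states=tuple(cells))
        )
    return CharacterMatrix(definitions=tuple(definitions), profiles=tuple(profiles))


def collapse_forms(matrix: CharacterMatrix) -> CharacterMatrix:
    """Merge form rows of the same species by state-set union per character.

    A merged cell is unknown only when it is unknown in every form. The
    operation is idempotent and the identity on matrices without duplicate
    species names.
    """
    by_species: dict[str, list[SpeciesProfile]] = {}
    order: list[str] = []
    for p in matrix.profiles:
        if p.species not in by_species:
            order.append(p.species)
        by_species.setdefault(p.species, []).append(p)

    merged = []
    for sp in order:
        rows = by_species[sp]
        if len(rows) == 1:
            merged.append(replace(rows[0], form_label=None))
            continue
        cells = tuple(
            StateSet(frozenset().union(*(r.states[i].states for r in rows)))
            for i in range(len(matrix.definitions))
        )
        merged.append(SpeciesProfile(species=sp, states=cells, form_label=None))
    return CharacterMatrix(definitions=matrix.definitions, profiles=tuple(merged))


def _profiles_equivalent(
    a: SpeciesProfile, b: SpeciesProfile, semantics: str
) -> bool:
    if semantics == "exact":
        return a.states == b.states
    if semantics == "overlap":
        # Indistinguishable unless some character has disjoint known states.
        return not any(x.disjoint_from(y) for x, y in zip(a.states, b.states))
    raise ValueError(f"unknown semantics {semantics!r} (use 'exact' or 'overlap')")


def diagnostic_characters(
    matrix: CharacterMatrix, a: str, b: str
) -> list[str]:
    """Characters whose state sets are disjoint and known for both species.

    Unknown cells are never diagnostic; overlapping polymorphic cells are not
    diagnostic either.
    """
    pa, pb = matrix.profile_of(a), matrix.profile_of(b)
    return [
        d.character_id
        for d, x, y in zip(matrix.definitions, pa.states, pb.states)
        if x.disjoint_from(y)
    ]


def find_unique_profiles(
    matrix: CharacterMatrix, semantics: str = "exact"
) -> DiagnosisReport:
    """Partition species into unique profiles and shared-profile groups.

    With the default exact semantics two species share a group iff their
    state-set vectors are identical elementwise ("?" equal only to "?").
    With ``semantics="overlap"``, species are grouped by the transitive
    closure of "no character separates them".
    """
    profiles = list(matrix.profiles)
    n = len(profiles)
    # Union-find over rows; exact equality is an equivalence relation already,
    # overlap semantics needs the transitive closure.
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        if _profiles_equivalent(profiles[i], profiles[j], semantics):
            parent[find(i)] = find(j)

    groups: dict[int, list[str]] = {}
    for i, p in enumerate(profiles):
        groups.setdefault(find(i), []).append(p.species)

    unique = tuple(sorted(g[0] for g in groups.values() if len(g) == 1))
    shared = tuple(
        sorted(
            (frozenset(g) for g in groups.values() if len(g) > 1),
            key=lambda s: sorted(s),
        )
    )
    diagnostics = {
        frozenset((a, b)): tuple(diagnostic_characters(matrix, a, b))
        for a, b in itertools.combinations(matrix.species, 2)
    }
    return DiagnosisReport(
        unique_species=unique, shared_groups=shared, pairwise_diagnostics=diagnostics
    )
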