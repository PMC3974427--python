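"""Synthetic data with known ground truth for every pipeline stage.

The sequence generator emulates the structure the delimitation analysis
assumes for hill-restricted land snails: a star phylogeny in which each
species ancestor sits at depth d_b/2 below the root and each specimen at a
further d_w/2 below its ancestor, so the expected K2P distance is d_w
within species and d_b + d_w between species (net divergence d_b). Sites
evolve independently under the two-parameter (K80) substitution process
with uniform base composition; substitution probabilities are the model's
exact transition functions at the target depth, so expected distances are
analytic and no small-step discretisation is involved.

Character matrices are generated with controlled duplicate-profile pairs,
polymorphism and missing data; occurrence records with a planted sympatry
structure; and a greedy-balanced decision tree can be built from any fully
diagnosable matrix to round-trip the key engine.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .barcode import AlignedSequences
from .morphology import (
    CharacterDefinition,
    CharacterMatrix,
    SpeciesProfile,
    StateSet,
)
from .records_geo import CollectionRecord
from .taxo_key import Couplet, DichotomousKey, Lead, Predicate

__all__ = [
    "SimulationConfig",
    "k80_site_probabilities",
    "simulate_k2p_pair",
    "simulate_clade_panel",
    "simulate_matrix",
    "build_key_from_matrix",
    "simulate_records",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# transition partners by base index: A<->G, C<->T
_TS_PARTNER = np.array([2, 3, 0, 1])
# the two transversion targets by base index
_TV_TARGETS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for the synthetic panels.

    Defaults mirror the study conditions of the revised fauna: COI-length
    alignments, transition/transversion ratio kappa = 2, within-species
    depths of ~2% and between-species depths well above the 10% threshold.
    """

    seed: int
    kappa: float = 2.0
    L: int = 615
    n_species: int = 5
    specimens_per_species: int = 3
    d_w: float = 0.02
    d_b: float = 0.15
    n_characters: int = 11
    states_per_character: int = 3
    n_duplicate_pairs: int = 0
    polymorphism_rate: float = 0.05
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        if self.L < 1:
            raise ValueError(f"sequence length must be >= 1, got {self.L}")
        if not 0 <= self.d_w < self.d_b:
            raise ValueError(
                f"need 0 <= d_w < d_b, got d_w={self.d_w}, d_b={self.d_b}"
            )
        if self.n_species < 1 or self.specimens_per_species < 1:
            raise ValueError("need at least one species and one specimen each")
        for name in ("polymorphism_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.states_per_character < 2:
            raise ValueError("characters need at least two states")
        if 2 * self.n_duplicate_pairs > self.n_species:
            raise ValueError("too many duplicate pairs for the species count")


def k80_site_probabilities(d: float, kappa: float) -> tuple[float, float, float]:
    """Exact K80 site transition functions at total depth ``d``.

    Returns (p_identical, p_transition, p_each_transversion) for one site,
    with rates scaled so that the expected number of substitutions is ``d``
    and the instantaneous transition/transversion rate ratio is ``kappa``.
    """
    if d < 0:
        raise ValueError(f"depth must be non-negative, got {d}")
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    # with alpha = kappa * beta and d = (alpha + 2 beta) t:
    beta_t = d / (kappa + 2.0)
    alpha_t = kappa * beta_t
    e_tv = math.exp(-4.0 * beta_t)
    e_ts = math.exp(-2.0 * (alpha_t + beta_t))
    p_ts = 0.25 + 0.25 * e_tv - 0.5 * e_ts
    p_tv_each = 0.25 - 0.25 * e_tv
    p_same = 1.0 - p_ts - 2.0 * p_tv_each
    return p_same, p_ts, p_tv_each


def _evolve(indices: np.ndarray, d: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve base indices over depth d under K80; returns new indices."""
    if d == 0:
        return indices.copy()
    p_same, p_ts, p_tv_each = k80_site_probabilities(d, kappa)
    u = rng.random(indices.shape)
    out = indices.copy()
    ts = u < p_ts
    tv1 = (u >= p_ts) & (u < p_ts + p_tv_each)
    tv2 = (u >= p_ts + p_tv_each) & (u < p_ts + 2 * p_tv_each)
    out[ts] = _TS_PARTNER[indices[ts]]
    out[tv1] = _TV_TARGETS[indices[tv1], 0]
    out[tv2] = _TV_TARGETS[indices[tv2], 1]
    return out


def _to_seq(indices: np.ndarray) -> str:
    return _BASES[indices].tobytes().decode("ascii")


def simulate_k2p_pair(
    d_true: float,
    kappa: float = 2.0,
    L: int = 615,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[str, str]:
    """Two aligned sequences whose expected K2P distance is ``d_true``.

    The first sequence is uniform random; the second is derived site-wise
    through the exact K80 transition functions at depth ``d_true`` (the
    process is time-reversible, so this equals evolving both from a common
    ancestor at depth d_true/2 each).
    """
    if d_true < 0:
        raise ValueError(f"d_true must be non-negative, got {d_true}")
    if rng is None:
        rng = np.random.default_rng(seed)
    a = rng.integers(0, 4, size=L)
    b = _evolve(a, d_true, kappa, rng)
    return _to_seq(a), _to_seq(b)


def simulate_clade_panel(
    config: SimulationConfig,
) -> tuple[AlignedSequences, dict[str, tuple[str, ...]]]:
    """A labelled star-phylogeny panel plus its true species grouping.

    Species ancestors sit at depth d_b/2 from the root, specimens at a
    further d_w/2, so within-species pairs have expected distance d_w and
    cross-species pairs d_b + d_w (net between-group divergence d_b).
    """
    rng = np.random.default_rng(config.seed)
    root = rng.integers(0, 4, size=config.L)
    records = []
    truth: dict[str, tuple[str, ...]] = {}
    width = len(str(config.n_species))
    for i in range(config.n_species):
        sp = f"sp{i + 1:0{width}d}"
        ancestor = _evolve(root, config.d_b / 2.0, config.kappa, rng)
        ids = []
        for j in range(config.specimens_per_species):
            tip = _evolve(ancestor, config.d_w / 2.0, config.kappa, rng)
            rid = f"{sp}_{j + 1}"
            records.append((rid, sp, _to_seq(tip)))
            ids.append(rid)
        truth[sp] = tuple(ids)
    return AlignedSequences(records=tuple(records)), truth


def _default_definitions(n_characters: int, states: int) -> tuple[CharacterDefinition, ...]:
    return tuple(
        CharacterDefinition(
            character_id=f"c{i + 1:02d}",
            name=f"synthetic character {i + 1}",
            state_codes={s: f"state {s}" for s in range(1, states + 1)},
        )
        for i in range(n_characters)
    )


def simulate_matrix(
    config: SimulationConfig,
) -> tuple[CharacterMatrix, list[frozenset[str]]]:
    """A coded character matrix with planted shared-profile pairs.

    Exactly ``n_duplicate_pairs`` species pairs share identical profiles;
    all remaining profiles are pairwise distinct under exact state-set
    equality. Polymorphism ("a or b" cells) and missing states ("?") are
    injected at the configured rates identically within a planted pair so
    the planted structure survives. With ``missing_rate == 1`` the matrix
    degenerates to all-unknown profiles (every species in one shared group)
    and no structure is enforced.
    """
    n_distinct = config.n_species - config.n_duplicate_pairs
    n_base = n_distinct  # number of distinct base profiles needed
    space = config.states_per_character ** config.n_characters
    if space < n_base:
        raise ValueError(
            f"state space {space} too small for {n_base} distinct profiles"
        )
    definitions = _default_definitions(config.n_characters, config.states_per_character)
    width = len(str(config.n_species))
    names = [f"sp{i + 1:0{width}d}" for i in range(config.n_species)]

    rng = np.random.default_rng(config.seed)
    for _attempt in range(50):
        base: list[tuple[int, ...]] = []
        seen: set[tuple[int, ...]] = set()
        tries = 0
        while len(base) < n_base and tries < 10000:
            vec = tuple(
                int(x)
                for x in rng.integers(1, config.states_per_character + 1, config.n_characters)
            )
            tries += 1
            if vec not in seen:
                seen.add(vec)
                base.append(vec)
        if len(base) < n_base:
            raise ValueError("could not draw enough distinct profiles")

        # species i pairs with species i + 1 for the first n_duplicate_pairs pairs
        assignment: list[int] = []
        planted: list[frozenset[str]] = []
        for p in range(config.n_duplicate_pairs):
            assignment.extend([p, p])
            planted.append(frozenset((names[2 * p], names[2 * p + 1])))
        assignment.extend(range(config.n_duplicate_pairs, n_base))

        # inject polymorphism / missing per base profile (shared by duplicates)
        cells_by_base: list[list[StateSet]] = []
        for vec in base:
            cells = []
            for code in vec:
                u = rng.random()
                if u < config.missing_rate:
                    cells.append(StateSet())
                elif u < config.missing_rate + config.polymorphism_rate:
                    others = [
                        s
                        for s in range(1, config.states_per_character + 1)
                        if s != code
                    ]
                    extra = int(rng.choice(others))
                    cells.append(StateSet(frozenset((code, extra))))
                else:
                    cells.append(StateSet(frozenset((code,))))
            cells_by_base.append(cells)

        profiles = tuple(
            SpeciesProfile(species=names[i], states=tuple(cells_by_base[assignment[i]]))
            for i in range(config.n_species)
        )
        matrix = CharacterMatrix(definitions=definitions, profiles=profiles)

        if config.missing_rate >= 1.0:
            return matrix, planted
        # verify the planted structure survived the injection
        vectors = [p.states for p in profiles]
        groups: dict[tuple[StateSet, ...], list[str]] = {}
        for name, vec in zip(names, vectors):
            groups.setdefault(vec, []).append(name)
        realised = sorted(
            (frozenset(g) for g in groups.values() if len(g) > 1),
            key=sorted,
        )
        if realised == sorted(planted, key=sorted):
            return matrix, planted
    raise ValueError(
        "infeasible configuration: injected polymorphism/missing keeps "
        "collapsing the planted profile structure"
    )


def build_key_from_matrix(
    matrix: CharacterMatrix, strategy: str = "greedy-balanced"
) -> DichotomousKey:
    """Build a binary decision tree over state-subset splits.

    Greedy-balanced: at each node choose the (character, state subset) split
    minimising the larger partition; ties are broken by character order,
    then by the subset's sorted code tuple. Every terminal is one species.
    Raises a ValueError listing the clash set when some species cannot be
    separated on non-missing characters.
    """
    if strategy != "greedy-balanced":
        raise ValueError(f"unknown strategy {strategy!r}")
    profiles = {p.species: p for p in matrix.profiles}
    char_ids = matrix.character_ids

    couplets: dict[int, Couplet] = {}
    counter = itertools.count(1)

    def best_split(members: list[str]):
        best = None
        for ci, cid in enumerate(char_ids):
            cells = {sp: profiles[sp].states[ci] for sp in members}
            if any(c.unknown for c in cells.values()):
                continue
            observed = sorted(set().union(*(c.states for c in cells.values())))
            if len(observed) < 2:
                continue
            anchor = observed[0]
            for r in range(1, len(observed)):
                for combo in itertools.combinations(observed, r):
                    if anchor not in combo:
                        continue  # canonical side contains the smallest code
                    a_set = frozenset(combo)
                    b_set = frozenset(observed) - a_set
                    side_a = [sp for sp in members if cells[sp].states <= a_set]
                    side_b = [sp for sp in members if cells[sp].states <= b_set]
                    if not side_a or not side_b:
                        continue
                    if len(side_a) + len(side_b) != len(members):
                        continue  # some species straddles the split
                    score = (
                        max(len(side_a), len(side_b)),
                        ci,
                        tuple(sorted(a_set)),
                    )
                    if best is None or score < best[0]:
                        best = (score, cid, a_set, b_set, side_a, side_b)
        return best

    def build(members: list[str]) -> tuple[str, object]:
        if len(members) == 1:
            return "species", members[0]
        split = best_split(members)
        if split is None:
            raise ValueError(
                f"indistinguishable species (no valid split): {sorted(members)}"
            )
        _score, cid, a_set, b_set, side_a, side_b = split
        node_id = next(counter)

        def lead_for(states: frozenset[int], side: list[str]) -> Lead:
            kind, target = build(side)
            codes = ",".join(str(s) for s in sorted(states))
            text = f"{cid} in {{{codes}}}"
            if kind == "species":
                return Lead(
                    text=text,
                    predicates=(Predicate(key=cid, states=states),),
                    species=target,
                )
            return Lead(
                text=text,
                predicates=(Predicate(key=cid, states=states),),
                couplet=target,
            )

        lead_a = lead_for(a_set, side_a)
        lead_b = lead_for(b_set, side_b)
        couplets[node_id] = Couplet(id=node_id, lead_a=lead_a, lead_b=lead_b)
        return "couplet", node_id

    kind, target = build(sorted(profiles))
    if kind == "species":
        raise ValueError("matrix has a single species; no key to build")
    ordered = tuple(couplets[i] for i in sorted(couplets))
    return DichotomousKey(couplets=ordered, root=target)


def simulate_records(
    species: Sequence[str],
    n_sites: int,
    sympatry_map: Mapping[int, Sequence[str]],
    seed: int,
    bbox: tuple[float, float, float, float] = (3.4, 100.1, 6.7, 103.2),
) -> list[CollectionRecord]:
    """Occurrence records with a planted sympatry structure.

    ``sympatry_map`` assigns species to site indices 0..n_sites-1; a site
    with two or more species is a planted co-occurrence. Species not placed
    anywhere get a private extra site, so every species is georeferenced.
    Site coordinates are drawn in ``bbox`` (lat_min, lon_min, lat_max,
    lon_max) and are guaranteed distinct after rounding to three decimals.
    """
    unknown = sorted(
        {sp for members in sympatry_map.values() for sp in members} - set(species)
    )
    if unknown:
        raise ValueError(f"sympatry_map names unknown species: {unknown}")
    bad_sites = sorted(k for k in sympatry_map if not 0 <= k < n_sites)
    if bad_sites:
        raise ValueError(f"sympatry_map site indices out of range: {bad_sites}")

    rng = np.random.default_rng(seed)
    placed = {sp for members in sympatry_map.values() for sp in members}
    extra = [sp for sp in species if sp not in placed]
    total_sites = n_sites + len(extra)

    lat_min, lon_min, lat_max, lon_max = bbox
    coords: list[tuple[float, float]] = []
    seen: set[tuple[float, float]] = set()
    while len(coords) < total_sites:
        lat = round(float(rng.uniform(lat_min, lat_max)), 3)
        lon = round(float(rng.uniform(lon_min, lon_max)), 3)
        if (lat, lon) not in seen:
            seen.add((lat, lon))
            coords.append((lat, lon))

    records: list[CollectionRecord] = []
    voucher = itertools.count(1)
    for site_idx in range(n_sites):
        for sp in sympatry_map.get(site_idx, ()):
            lat, lon = coords[site_idx]
            records.append(
                CollectionRecord(
                    reference=f"SYN {next(voucher):04d}",
                    species=sp,
                    locality=f"synthetic hill {site_idx + 1}",
                    lat=lat,
                    lon=lon,
                )
            )
    for k, sp in enumerate(extra):
        lat, lon = coords[n_sites + k]
        records.append(
            CollectionRecord(
                reference=f"SYN {next(voucher):04d}",
                species=sp,
                locality=f"synthetic hill {n_sites + k + 1}",
                lat=lat,
                lon=lon,
            )
        )
    return records
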