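"""Kimura 2-parameter barcode divergence and the 10% delimitation screen.

The COI barcode analysis proceeds in four steps:

1. alignment columns with poor site coverage are removed (default: a column
   is kept only if >= 95% of sequences carry an unambiguous A/C/G/T there);
2. for every sequence pair, transitions (A<->G, C<->T) and transversions are
   counted over the sites where both residues are unambiguous (pairwise
   deletion), giving proportions P and Q over L compared sites;
3. the Kimura 2-parameter distance d = -1/2 ln[(1-2P-Q) sqrt(1-2Q)] is
   evaluated per pair, and aggregated per species into mean within-group
   divergence and *net* between-group divergence
   d_net(A,B) = mean cross-pair distance - (d_w(A) + d_w(B)) / 2;
4. divergences are screened against the delimitation threshold tau = 0.10:
   a species pair with net divergence below tau is a lump candidate, a
   species whose within-group divergence reaches tau is a split candidate.

Saturation (a non-positive argument to either logarithm) is an explicit
signal: the pair's distance is undefined and every aggregate it enters is
marked undetermined rather than silently NaN.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AlignedSequences",
    "PairwiseCounts",
    "DistanceMatrix",
    "GroupDivergenceTable",
    "DelimitationFlag",
    "SaturationError",
    "DEFAULT_THRESHOLD",
    "DEFAULT_COVERAGE",
    "read_fasta",
    "filter_site_coverage",
    "count_substitutions",
    "k2p",
    "k2p_distance_matrix",
    "group_divergences",
    "screen_threshold",
    "read_distance_table",
]

DEFAULT_THRESHOLD = 0.10
DEFAULT_COVERAGE = 0.95

_UNAMBIGUOUS = frozenset(b"ACGT")
_TRANSITIONS = frozenset({(65, 71), (71, 65), (67, 84), (84, 67)})  # A<->G, C<->T


class SaturationError(ValueError):
    """K2P distance undefined: substitution proportions past the model's range."""


@dataclass(frozen=True)
class AlignedSequences:
    """An equal-length nucleotide alignment with a species label per record."""

    records: tuple[tuple[str, str, str], ...]  # (id, species, residues)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty alignment")
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")
        lengths = {len(r[2]) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.records[0][2])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r[0] for r in self.records)

    def species_map(self) -> dict[str, str]:
        return {rid: sp for rid, sp, _ in self.records}

    def groups(self) -> dict[str, tuple[str, ...]]:
        """Sequence ids per species label, in record order."""
        out: dict[str, list[str]] = {}
        for rid, sp, _ in self.records:
            out.setdefault(sp, []).append(rid)
        return {sp: tuple(v) for sp, v in out.items()}

    def as_array(self) -> np.ndarray:
        """(n_records, length) uint8 array of residue byte codes."""
        return np.frombuffer(
            "".join(r[2] for r in self.records).upper().encode("ascii"),
            dtype=np.uint8,
        ).reshape(len(self.records), self.length)


@dataclass(frozen=True)
class PairwiseCounts:
    """Transition/transversion counts for one sequence pair.

    ``L`` counts the sites where both residues are unambiguous A/C/G/T
    (pairwise deletion); ``s`` and ``v`` the transition and transversion
    differences among them.
    """

    L: int
    s: int
    v: int

    def __post_init__(self) -> None:
        if self.L < 0 or self.s < 0 or self.v < 0 or self.s + self.v > self.L:
            raise ValueError(f"inconsistent counts L={self.L}, s={self.s}, v={self.v}")

    @property
    def P(self) -> float:
        return self.s / self.L if self.L else 0.0

    @property
    def Q(self) -> float:
        return self.v / self.L if self.L else 0.0

    @property
    def p_distance(self) -> float:
        return (self.s + self.v) / self.L if self.L else 0.0


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix; NaN marks undefined (saturated) pairs."""

    ids: tuple[str, ...]
    values: np.ndarray  # (n, n) float, NaN = undefined, diagonal 0

    def __post_init__(self) -> None:
        n = len(self.ids)
        v = self.values
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        both = ~np.isnan(v)
        if not np.array_equal(np.isnan(v), np.isnan(v.T)) or not np.allclose(
            v[both & both.T], v.T[both & both.T]
        ):
            raise ValueError("matrix must be symmetric")
        with np.errstate(invalid="ignore"):
            if np.any(v[~np.isnan(v)] < 0):
                raise ValueError("distances must be non-negative")

    def distance(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def undefined_pairs(self) -> list[frozenset[str]]:
        out = []
        for i, j in zip(*np.triu_indices(len(self.ids), k=1)):
            if math.isnan(self.values[i, j]):
                out.append(frozenset((self.ids[i], self.ids[j])))
        return out


@dataclass(frozen=True)
class GroupDivergenceTable:
    """Within-group and net between-group divergences per species (pair).

    ``within`` is None for singleton groups; pairs are keyed by
    ``frozenset({species_a, species_b})``. ``undetermined`` lists aggregates
    that could not be computed (saturated member pairs) with a reason.
    """

    groups: Mapping[str, tuple[str, ...]]
    within: Mapping[str, float | None]
    net: Mapping[frozenset[str], float]
    between_mean: Mapping[frozenset[str], float] = field(default_factory=dict)
    undetermined: Mapping[object, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp, members in self.groups.items():
            w = self.within.get(sp)
            if (len(members) >= 2) != (w is not None) and sp not in self.undetermined:
                raise ValueError(
                    f"within divergence defined iff group size >= 2 (group {sp!r})"
                )

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.groups)

    @property
    def n_pairs(self) -> int:
        return len(self.net) + sum(
            1 for k in self.undetermined if isinstance(k, frozenset)
        )

    def net_of(self, a: str, b: str) -> float:
        return self.net[frozenset((a, b))]


@dataclass(frozen=True)
class DelimitationFlag:
    """Screening outcome for one species (split check) or species pair (lump check)."""

    kind: str  # lump-candidate | split-candidate | distinct | undetermined
    subject: str | frozenset[str]
    value: float | None
    threshold: float = DEFAULT_THRESHOLD
    note: str = ""


def read_fasta(
    path: str | Path, species_map: Mapping[str, str] | None = None
) -> AlignedSequences:
    """Read an aligned FASTA; species labels come from ``>id|species`` headers
    or from an explicit id -> species mapping."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if species_map is not None:
            if rid not in species_map:
                raise KeyError(f"sequence {rid!r} missing from species map")
            sp = species_map[rid]
        elif "|" in rid:
            rid, sp = rid.split("|", 1)
        else:
            raise ValueError(
                f"sequence {rec.id!r}: no species label (use 'id|species' headers "
                "or pass species_map)"
            )
        records.append((rid, sp, str(rec.seq).upper()))
    return AlignedSequences(records=tuple(records))


def filter_site_coverage(
    aln: AlignedSequences, c: float = DEFAULT_COVERAGE
) -> AlignedSequences:
    """Keep only columns where the fraction of unambiguous A/C/G/T residues
    is at least ``c``. Row order is preserved; the filter is idempotent."""
    if not 0 < c <= 1:
        raise ValueError(f"coverage threshold must be in (0, 1], got {c}")
    arr = aln.as_array()
    good = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    keep = good.mean(axis=0) >= c
    if not keep.any():
        raise ValueError("no alignment column satisfies the coverage threshold")
    kept = arr[:, keep]
    records = tuple(
        (rid, sp, kept[i].tobytes().decode("ascii"))
        for i, (rid, sp, _) in enumerate(aln.records)
    )
    return AlignedSequences(records=records)


def count_substitutions(a: str, b: str) -> PairwiseCounts:
    """Count transitions and transversions between two aligned sequences.

    Sites where either residue is not an unambiguous A/C/G/T (gaps, Ns,
    IUPAC ambiguity codes) are excluded pairwise.
    """
    if len(a) != len(b):
        raise ValueError(f"sequence length mismatch: {len(a)} vs {len(b)}")
    L = s = v = 0
    for x, y in zip(a.upper().encode(), b.upper().encode()):
        if x not in _UNAMBIGUOUS or y not in _UNAMBIGUOUS:
            continue
        L += 1
        if x == y:
            continue
        if (x, y) in _TRANSITIONS:
            s += 1
        else:
            v += 1
    return PairwiseCounts(L=L, s=s, v=v)


def k2p(counts: PairwiseCounts) -> float:
    """Kimura 2-parameter distance d = -1/2 ln[(1-2P-Q) sqrt(1-2Q)].

    Raises SaturationError when either logarithm argument is non-positive,
    i.e. the observed proportions are outside the model's invertible range.
    """
    if counts.L <= 0:
        raise ValueError("no compared sites (L = 0)")
    P, Q = counts.P, counts.Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"saturated pair: P={P:.4f}, Q={Q:.4f} outside the K2P range"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def _pair_counts_array(arr: np.ndarray, i: int, j: int) -> PairwiseCounts:
    good = np.isin(arr[i], np.frombuffer(b"ACGT", dtype=np.uint8)) & np.isin(
        arr[j], np.frombuffer(b"ACGT", dtype=np.uint8)
    )
    x, y = arr[i][good], arr[j][good]
    diff = x != y
    # transitions: {A,G} or {C,T} pairs; A=65 G=71 C=67 T=84
    ts = diff & (
        ((x == 65) & (y == 71))
        | ((x == 71) & (y == 65))
        | ((x == 67) & (y == 84))
        | ((x == 84) & (y == 67))
    )
    s = int(ts.sum())
    v = int(diff.sum()) - s
    return PairwiseCounts(L=int(good.sum()), s=s, v=v)


def k2p_distance_matrix(aln: AlignedSequences) -> DistanceMatrix:
    """All-pairs K2P distances with pairwise deletion; saturated pairs are NaN."""
    arr = aln.as_array()
    n = len(aln.records)
    values = np.zeros((n, n), dtype=float)
    for i, j in itertools.combinations(range(n), 2):
        try:
            d = k2p(_pair_counts_array(arr, i, j))
        except SaturationError:
            d = math.nan
        values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=aln.ids, values=values)


def group_divergences(
    dm: DistanceMatrix, groups: Mapping[str, Sequence[str]]
) -> GroupDivergenceTable:
    """Aggregate a distance matrix into within/between/net group divergences.

    ``within`` is the arithmetic mean over all intra-group pairs (None for
    singletons); ``between_mean`` the mean over all cross-group pairs; and
    ``net`` subtracts the average of the two within means, treating a
    singleton's within as 0 so that pairs involving singletons stay defined.
    Aggregates touching a saturated (undefined) pair become undetermined.
    """
    index = {rid: k for k, rid in enumerate(dm.ids)}
    assigned = [rid for members in groups.values() for rid in members]
    if len(set(assigned)) != len(assigned):
        raise ValueError("a sequence id is assigned to more than one group")
    missing = sorted(set(assigned) - set(dm.ids))
    if missing:
        raise ValueError(f"group members absent from distance matrix: {missing}")

    def mean_over(pairs: Iterable[tuple[str, str]]) -> float | None:
        vals = [dm.values[index[a], index[b]] for a, b in pairs]
        if not vals:
            return None
        arr = np.asarray(vals)
        if np.isnan(arr).any():
            raise SaturationError("aggregate includes an undefined pair")
        return float(arr.mean())

    within: dict[str, float | None] = {}
    undetermined: dict[object, str] = {}
    for sp, members in groups.items():
        try:
            within[sp] = mean_over(itertools.combinations(members, 2))
        except SaturationError:
            within[sp] = None
            undetermined[sp] = "saturated pair within group"

    between_mean: dict[frozenset[str], float] = {}
    net: dict[frozenset[str], float] = {}
    for a, b in itertools.combinations(groups, 2):
        key = frozenset((a, b))
        if a in undetermined or b in undetermined:
            undetermined[key] = "within divergence undetermined"
            continue
        try:
            bm = mean_over(itertools.product(groups[a], groups[b]))
        except SaturationError:
            undetermined[key] = "saturated cross-group pair"
            continue
        wa = within[a] or 0.0
        wb = within[b] or 0.0
        between_mean[key] = bm
        net[key] = bm - (wa + wb) / 2.0

    return GroupDivergenceTable(
        groups={sp: tuple(m) for sp, m in groups.items()},
        within=within,
        net=net,
        between_mean=between_mean,
        undetermined=undetermined,
    )


def screen_threshold(
    table: GroupDivergenceTable, tau: float = DEFAULT_THRESHOLD
) -> list[DelimitationFlag]:
    """Flag lump candidates (net < tau), split candidates (within >= tau),
    and undetermined aggregates; everything else is distinct.

    The lump comparison is strict: a pair whose net divergence equals tau at
    full precision is distinct but annotated as borderline.
    """
    flags: list[DelimitationFlag] = []
    for sp in table.groups:
        if sp in table.undetermined:
            flags.append(
                DelimitationFlag(
                    "undetermined", sp, None, tau, table.undetermined[sp]
                )
            )
            continue
        w = table.within.get(sp)
        if w is not None and w >= tau:
            flags.append(DelimitationFlag("split-candidate", sp, w, tau))
    for key, value in table.net.items():
        if value < tau:
            flags.append(DelimitationFlag("lump-candidate", key, value, tau))
        else:
            note = "borderline: net equals threshold" if value == tau else ""
            flags.append(DelimitationFlag("distinct", key, value, tau, note))
    for key, reason in table.undetermined.items():
        if isinstance(key, frozenset):
            flags.append(DelimitationFlag("undetermined", key, None, tau, reason))
    return flags


def read_distance_table(path: str | Path) -> GroupDivergenceTable:
    """Ingest a published lower-triangular divergence table.

    Expected TSV layout: columns ``n_specimens``, ``within``, ``species``,
    then one column per species (short name = last word of the binomial)
    holding the net between-group divergences below the diagonal. Singleton
    groups carry ``n.a.`` within. Member ids are synthesised as
    ``<shortname>_<k>`` so that group sizes are preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"n_specimens", "within", "species"}
    if not required.issubset(df.columns):
        raise ValueError(f"divergence table lacks columns {sorted(required - set(df.columns))}")

    species = list(df["species"])
    short = [s.split()[-1] for s in species]
    col_order = [c for c in df.columns if c not in required]
    if col_order != short[: len(col_order)]:
        raise ValueError(
            "between-group columns must follow the row order of the table"
        )

    groups: dict[str, tuple[str, ...]] = {}
    within: dict[str, float | None] = {}
    for sp, sh, n_raw, w_raw in zip(species, short, df["n_specimens"], df["within"]):
        n = int(n_raw)
        if n < 1:
            raise ValueError(f"group {sp!r} has non-positive size {n}")
        groups[sp] = tuple(f"{sh}_{k + 1}" for k in range(n))
        if w_raw.strip().lower() in {"n.a.", "na", ""}:
            if n >= 2:
                raise ValueError(f"group {sp!r} of size {n} lacks a within divergence")
            within[sp] = None
        else:
            within[sp] = float(w_raw)

    net: dict[frozenset[str], float] = {}
    for i, row_sp in enumerate(species):
        for j in range(i):
            cell = df.iloc[i][short[j]].strip()
            if not cell:
                raise ValueError(
                    f"missing net divergence for pair ({row_sp}, {species[j]})"
                )
            key = frozenset((row_sp, species[j]))
            value = float(cell)
            if key in net and net[key] != value:
                raise ValueError(f"asymmetric duplicate entry for pair {sorted(key)}")
            net[key] = value
        for j in range(i + 1, len(col_order)):
            if df.iloc[i][short[j]].strip():
                raise ValueError(
                    f"unexpected upper-triangle entry at ({row_sp}, {species[j]})"
                )

    expected_pairs = len(species) * (len(species) - 1) // 2
    if len(net) != expected_pairs:
        raise ValueError(f"expected {expected_pairs} pairs, parsed {len(net)}")
    return GroupDivergenceTable(groups=groups, within=within, net=net)
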