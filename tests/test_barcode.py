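"""K2P distances, coverage filtering, divergence aggregation, threshold screen."""

import itertools
import math
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plectokit.barcode import (
    AlignedSequences,
    DistanceMatrix,
    GroupDivergenceTable,
    PairwiseCounts,
    SaturationError,
    count_substitutions,
    filter_site_coverage,
    group_divergences,
    k2p,
    k2p_distance_matrix,
    read_distance_table,
    screen_threshold,
)
from plectokit.synthetic_data import SimulationConfig, simulate_clade_panel


def _aln(*seqs):
    return AlignedSequences(
        records=tuple((f"s{i}", f"sp{i}", s) for i, s in enumerate(seqs))
    )


class TestCoverageFilter:
    def test_clean_alignment_unchanged(self):
        aln = _aln("ACGT", "ACGT", "TGCA")
        out = filter_site_coverage(aln)
        assert out.records == aln.records

    def test_half_covered_column_removed(self):
        # column 2 has 2 gaps out of 4 sequences: coverage 0.5 < 0.95
        aln = _aln("AC-T", "AC-T", "ACGT", "ACGT")
        out = filter_site_coverage(aln, 0.95)
        assert out.length == 3
        assert [r[2] for r in out.records] == ["ACT", "ACT", "ACT", "ACT"]

    def test_full_coverage_threshold_drops_single_n(self):
        aln = _aln("ANGT", "ACGT")
        out = filter_site_coverage(aln, 1.0)
        assert out.length == 3

    def test_idempotent(self):
        aln = _aln("AC-TNGGA", "ACGT-GGA", "ACGTAGGA")
        once = filter_site_coverage(aln, 0.9)
        twice = filter_site_coverage(once, 0.9)
        assert once.records == twice.records

    def test_ambiguity_codes_count_as_uncovered(self):
        aln = _aln("ARGT", "ACGT", "ACGT", "ACGT", "ACGT", "ACGT", "ACGT",
                   "ACGT", "ACGT", "ACGT", "ACGT", "ACGT", "ACGT", "ACGT",
                   "ACGT", "ACGT", "ACGT", "ACGT", "ACGT", "ACGT")
        # 19/20 = 0.95 coverage in column 2: kept at c=0.95, dropped at c=0.96
        assert filter_site_coverage(aln, 0.95).length == 4
        assert filter_site_coverage(aln, 0.96).length == 3

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            filter_site_coverage(_aln("ACGT"), 0.0)


class TestCounting:
    @pytest.mark.parametrize(
        "a,b,L,s,v",
        [
            ("ACGT", "ACGT", 4, 0, 0),
            ("AAAA", "GAAA", 4, 1, 0),  # A->G is a transition
            ("AC-T", "ACGT", 3, 0, 0),  # gap column excluded pairwise
            ("AAAA", "CAAA", 4, 0, 1),  # A->C is a transversion
            ("ACGT", "GTAC", 4, 4, 0),  # A-G, C-T, G-A, T-C: all transitions
            ("AANA", "AAAA", 3, 0, 0),  # N excluded pairwise
        ],
    )
    def test_counts(self, a, b, L, s, v):
        c = count_substitutions(a, b)
        assert (c.L, c.s, c.v) == (L, s, v)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            count_substitutions("ACG", "ACGT")

    def test_symmetry(self):
        a, b = "ACGTRN-ACGT", "TCGA-NAACGA"
        ca, cb = count_substitutions(a, b), count_substitutions(b, a)
        assert (ca.L, ca.s, ca.v) == (cb.L, cb.s, cb.v)


class TestK2P:
    def test_zero_distance(self):
        assert k2p(PairwiseCounts(L=100, s=0, v=0)) == 0.0

    def test_hand_evaluated_value(self):
        # P=0.10, Q=0.05: d = -1/2 ln(0.75 * sqrt(0.90)), frozen from an
        # exact symbolic evaluation.
        d = k2p(PairwiseCounts(L=100, s=10, v=5))
        assert d == pytest.approx(0.17018116514034704, abs=1e-12)

    def test_saturation_is_explicit(self):
        with pytest.raises(SaturationError):
            k2p(PairwiseCounts(L=100, s=50, v=0))  # 1 - 2P - Q = 0
        with pytest.raises(SaturationError):
            k2p(PairwiseCounts(L=100, s=0, v=60))

    def test_zero_sites_rejected(self):
        with pytest.raises(ValueError):
            k2p(PairwiseCounts(L=0, s=0, v=0))

    @settings(max_examples=200, deadline=None)
    @given(st.integers(100, 2000), st.integers(0, 30), st.integers(0, 30))
    def test_correction_dominates_p_distance(self, L, s, v):
        counts = PairwiseCounts(L=L, s=s, v=v)
        try:
            d = k2p(counts)
        except SaturationError:
            return
        assert d >= counts.p_distance - 1e-12

    def test_small_divergence_approaches_p_distance(self):
        # d -> P + Q as P, Q -> 0 (Jukes-Cantor-like limit)
        counts = PairwiseCounts(L=100000, s=20, v=10)
        assert k2p(counts) == pytest.approx(counts.p_distance, rel=1e-3)


class TestDistanceMatrix:
    def test_matrix_properties(self):
        cfg = SimulationConfig(seed=2, n_species=3, specimens_per_species=2, L=400)
        aln, _ = simulate_clade_panel(cfg)
        dm = k2p_distance_matrix(aln)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0)
        assert (dm.values[~np.isnan(dm.values)] >= 0).all()

    def test_saturated_pair_is_nan(self):
        # maximally divergent pair: all transitions at half the sites
        aln = _aln("A" * 100, "G" * 50 + "A" * 50)
        dm = k2p_distance_matrix(aln)
        assert math.isnan(dm.distance("s0", "s1"))
        assert dm.undefined_pairs() == [frozenset({"s0", "s1"})]

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="needs Rscript")
    def test_matches_ape_k80_oracle(self, tmp_path):
        """Cross-check the K2P matrix against ape::dist.dna (model K80,
        pairwise deletion) on a small simulated alignment."""
        cfg = SimulationConfig(
            seed=31, n_species=3, specimens_per_species=2, L=600, d_w=0.03, d_b=0.2
        )
        aln, _ = simulate_clade_panel(cfg)
        fasta = tmp_path / "aln.fasta"
        fasta.write_text(
            "".join(f">{rid}\n{seq}\n" for rid, _sp, seq in aln.records)
        )
        out = tmp_path / "dist.tsv"
        script = tmp_path / "oracle.R"
        script.write_text(
            'library(ape)\n'
            f'aln <- read.dna("{fasta}", format="fasta")\n'
            'd <- dist.dna(aln, model="K80", pairwise.deletion=TRUE, as.matrix=TRUE)\n'
            f'write.table(d, "{out}", sep="\\t")\n'
        )
        subprocess.run(
            ["Rscript", "--vanilla", str(script)], check=True, capture_output=True
        )
        import pandas as pd

        ref = pd.read_csv(out, sep="\t")
        dm = k2p_distance_matrix(aln)
        for i, a in enumerate(dm.ids):
            for j, b in enumerate(dm.ids):
                assert dm.values[i, j] == pytest.approx(ref.loc[a, b], abs=1e-9)


def _table_from_values(groups, values):
    """Independent brute-force aggregation oracle."""
    within = {}
    for sp, members in groups.items():
        pairs = list(itertools.combinations(members, 2))
        within[sp] = (
            sum(values[frozenset(p)] for p in pairs) / len(pairs) if pairs else None
        )
    net = {}
    for a, b in itertools.combinations(groups, 2):
        cross = [
            values[frozenset((x, y))] for x in groups[a] for y in groups[b]
        ]
        bm = sum(cross) / len(cross)
        net[frozenset((a, b))] = bm - ((within[a] or 0) + (within[b] or 0)) / 2
    return within, net


class TestGroupDivergences:
    def test_identical_singletons_net_zero(self):
        aln = _aln("ACGTACGT", "ACGTACGT")
        dm = k2p_distance_matrix(aln)
        table = group_divergences(dm, {"a": ["s0"], "b": ["s1"]})
        assert table.net_of("a", "b") == 0.0
        assert table.within["a"] is None

    def test_within_zero_for_identical_pair(self):
        aln = AlignedSequences(
            records=(("x1", "a", "ACGT"), ("x2", "a", "ACGT"))
        )
        dm = k2p_distance_matrix(aln)
        table = group_divergences(dm, {"a": ["x1", "x2"]})
        assert table.within["a"] == 0.0

    def test_net_formula_by_enumeration(self):
        ids = ("a1", "a2", "b1", "b2")
        vals = np.array(
            [
                [0.00, 0.02, 0.15, 0.17],
                [0.02, 0.00, 0.16, 0.18],
                [0.15, 0.16, 0.00, 0.04],
                [0.17, 0.18, 0.04, 0.00],
            ]
        )
        dm = DistanceMatrix(ids=ids, values=vals)
        table = group_divergences(dm, {"A": ["a1", "a2"], "B": ["b1", "b2"]})
        between = (0.15 + 0.17 + 0.16 + 0.18) / 4
        assert table.between_mean[frozenset(("A", "B"))] == pytest.approx(between)
        assert table.net_of("A", "B") == pytest.approx(between - (0.02 + 0.04) / 2)

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_agrees_with_bruteforce_oracle(self, data):
        n = data.draw(st.integers(2, 10))
        ids = tuple(f"q{i}" for i in range(n))
        vals = np.zeros((n, n))
        values = {}
        for i, j in itertools.combinations(range(n), 2):
            d = data.draw(
                st.floats(0, 0.5, allow_nan=False, allow_infinity=False)
            )
            vals[i, j] = vals[j, i] = d
            values[frozenset((ids[i], ids[j]))] = d
        n_groups = data.draw(st.integers(1, min(4, n)))
        assignment = [
            data.draw(st.integers(0, n_groups - 1)) for _ in range(n)
        ]
        groups = {}
        for idx, g in enumerate(assignment):
            groups.setdefault(f"g{g}", []).append(ids[idx])
        dm = DistanceMatrix(ids=ids, values=vals)
        table = group_divergences(dm, groups)
        exp_within, exp_net = _table_from_values(groups, values)
        for sp in groups:
            if exp_within[sp] is None:
                assert table.within[sp] is None
            else:
                assert table.within[sp] == pytest.approx(exp_within[sp])
        for key, v in exp_net.items():
            assert table.net[key] == pytest.approx(v)

    def test_saturation_propagates_as_undetermined(self):
        vals = np.array(
            [
                [0.0, np.nan, 0.2],
                [np.nan, 0.0, 0.2],
                [0.2, 0.2, 0.0],
            ]
        )
        dm = DistanceMatrix(ids=("x1", "x2", "y1"), values=vals)
        table = group_divergences(dm, {"X": ["x1", "x2"], "Y": ["y1"]})
        assert table.within["X"] is None
        assert "X" in table.undetermined
        assert frozenset(("X", "Y")) in table.undetermined
        flags = screen_threshold(table)
        assert {f.kind for f in flags if f.subject == "X"} == {"undetermined"}


class TestScreenThreshold:
    def test_published_lump_and_split_candidates(self, divergences):
        flags = screen_threshold(divergences)
        lump = {
            frozenset(f.subject) for f in flags if f.kind == "lump-candidate"
        }
        assert lump == {
            frozenset({"Plectostoma crassipupa", "Plectostoma christae"}),
            frozenset({"Plectostoma crassipupa", "Plectostoma laidlawi"}),
        }
        for f in flags:
            if f.kind == "lump-candidate":
                assert f.value == pytest.approx(0.09)
        split = [f for f in flags if f.kind == "split-candidate"]
        assert [f.subject for f in split] == ["Plectostoma crassipupa"]
        assert split[0].value == pytest.approx(0.13)

    def test_169_of_171_pairs_at_or_above_threshold(self, divergences):
        flags = screen_threshold(divergences)
        distinct = [f for f in flags if f.kind == "distinct"]
        assert len(distinct) == 169
        assert len(distinct) + 2 == divergences.n_pairs == 171

    def test_exact_tau_is_distinct_but_borderline(self):
        table = GroupDivergenceTable(
            groups={"a": ("a1",), "b": ("b1",)},
            within={"a": None, "b": None},
            net={frozenset(("a", "b")): 0.10},
        )
        flags = screen_threshold(table, 0.10)
        (flag,) = [f for f in flags if isinstance(f.subject, frozenset)]
        assert flag.kind == "distinct"
        assert "borderline" in flag.note

    def test_threshold_monotonicity(self, divergences):
        """Raising tau can only move pairs from distinct to lump-candidate."""
        lumps = {}
        for tau in (0.05, 0.10, 0.15, 0.20):
            flags = screen_threshold(divergences, tau)
            lumps[tau] = {
                f.subject for f in flags if f.kind == "lump-candidate"
            }
        assert lumps[0.05] <= lumps[0.10] <= lumps[0.15] <= lumps[0.20]


class TestReadDistanceTable:
    def test_shape_and_counts(self, divergences):
        assert len(divergences.groups) == 19
        assert divergences.n_pairs == 171
        assert sum(len(m) for m in divergences.groups.values()) == 51

    def test_published_entries(self, divergences):
        assert divergences.within["Plectostoma christae"] == pytest.approx(0.06)
        assert divergences.within["Plectostoma dindingensis"] is None
        assert divergences.net_of(
            "Plectostoma kubuensis", "Plectostoma kakiense"
        ) == pytest.approx(0.16)

    def test_within_defined_iff_multiple_specimens(self, divergences):
        for sp, members in divergences.groups.items():
            assert (divergences.within[sp] is not None) == (len(members) >= 2)

    def test_bad_table_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "n_specimens\twithin\tspecies\ta\tb\n"
            "2\t0.01\tg a\t\t0.3\n"  # upper-triangle entry
            "1\tn.a.\tg b\t0.2\t\n"
        )
        with pytest.raises(ValueError, match="upper-triangle"):
            read_distance_table(p)


class TestEstimatorRecovery:
    def test_bias_shrinks_with_length(self):
        """Mean K2P estimate recovers the generating depth; estimator
        variance scales roughly inversely with sequence length."""
        rng = np.random.default_rng(123)
        from plectokit.synthetic_data import simulate_k2p_pair

        def estimates(L, n=60, d=0.20):
            out = []
            for _ in range(n):
                a, b = simulate_k2p_pair(d, kappa=2.0, L=L, rng=rng)
                out.append(k2p(count_substitutions(a, b)))
            return np.array(out)

        short = estimates(200)
        long = estimates(2000)
        assert abs(long.mean() - 0.20) < 0.01
        ratio = short.var() / long.var()
        assert 3 < ratio < 30  # ~10 expected from the 1/L scaling
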