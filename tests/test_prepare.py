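"""Contig splitting, L90, quality ordering and the greedy distance filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pancore import prepare
from pancore.prepare import Assembly, split_contigs, compute_l90


def asm(genome_id, contig_lengths, **kw):
    return Assembly(
        genome_id=genome_id,
        contigs=[(str(i + 1), "A" * n) for i, n in enumerate(contig_lengths)],
        **kw,
    )


def asm_with_quality(genome_id, l90, nb):
    """Assembly with exact l90 and contig count (l90 <= 10, nb <= 100)."""
    a = asm(genome_id, [900] * l90 + [1] * (nb - l90))
    assert a.l90 == l90 and a.nb_contigs == nb
    return a


class TestSplitContigs:
    @pytest.mark.parametrize(
        "seq,cutn,expected",
        [
            ("AAAANNNNNTTTT", 5, ["AAAA", "TTTT"]),
            ("AAAANNNNNTTTT", 6, ["AAAANNNNNTTTT"]),  # run shorter than cutn
            ("NNNNNAAAA", 5, ["AAAA"]),  # leading empty fragment dropped
            ("AAAAnnnnnTTTT", 5, ["AAAA", "TTTT"]),  # case-insensitive
            ("ACGTRYSWKM", 5, ["ACGTRYSWKM"]),  # other IUPAC codes retained
        ],
    )
    def test_splitting_rule(self, seq, cutn, expected):
        a = split_contigs([("e1", seq)], cutn=cutn)
        assert [s for _, s in a.contigs] == expected

    def test_cutn_zero_disables_splitting(self):
        a = split_contigs([("e1", "AANNNNNNNNAA")], cutn=0)
        assert a.nb_contigs == 1

    def test_contigs_numbered_in_input_order(self):
        a = split_contigs([("e1", "AANNNNNCC"), ("e2", "GG")], cutn=5)
        assert [cid for cid, _ in a.contigs] == ["1", "2", "3"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            split_contigs("", cutn=5)

    def test_non_iupac_character_named(self):
        with pytest.raises(ValueError, match="'J'"):
            split_contigs([("e1", "ACGJ")], cutn=5)

    def test_rejoin_resplit_idempotent(self):
        a = split_contigs([("e1", "AAANNNNNCCCNNNNNGGG")], cutn=5)
        joined = ("N" * 5).join(s for _, s in a.contigs)
        b = split_contigs([("e1", joined)], cutn=5)
        assert [s for _, s in b.contigs] == [s for _, s in a.contigs]


class TestL90:
    @pytest.mark.parametrize(
        "lengths,expected",
        [([1000], 1), ([50, 30, 20], 3), ([900, 50, 30, 20], 1)],
    )
    def test_examples(self, lengths, expected):
        assert compute_l90(lengths) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_l90([])

    @given(st.lists(st.integers(min_value=1, max_value=10_000), min_size=1, max_size=40))
    @settings(derandomize=True, max_examples=200)
    def test_matches_brute_force_prefix_search(self, lengths):
        ordered = sorted(lengths, reverse=True)
        target = 0.9 * sum(lengths)
        oracle = next(
            m for m in range(1, len(lengths) + 1) if sum(ordered[:m]) >= target
        )
        assert compute_l90(lengths) == oracle


class TestQualityFilter:
    def test_boundary_values_pass(self):
        # l90 exactly 100 and nbcont exactly 999 with default thresholds
        a = asm("g", [10] * 99 + [1] * 111)
        assert a.l90 == 100
        assert prepare.quality_filter([a]).kept == ["g"]
        b = asm("h", [9000] + [1] * 998)
        assert b.nb_contigs == 999
        assert prepare.quality_filter([b]).kept == ["h"]

    def test_boundary_plus_one_discarded(self):
        a = asm_with_quality("g", l90=5, nb=10)
        rep = prepare.quality_filter([a], l90_max=4)
        assert rep.kept == [] and rep.discarded[0].reason == "l90_exceeded"
        rep = prepare.quality_filter([a], nbcont_max=9)
        assert rep.discarded[0].reason == "nbcont_exceeded"

    def test_empty_input(self):
        rep = prepare.quality_filter([])
        assert rep.kept == [] and rep.discarded == []

    def test_never_discards_compliant_genome(self):
        rng = np.random.default_rng(0)
        assemblies = [
            asm(f"g{i}", list(rng.integers(1, 500, size=rng.integers(1, 30))))
            for i in range(20)
        ]
        rep = prepare.quality_filter(assemblies, l90_max=10, nbcont_max=20)
        for a in assemblies:
            if a.l90 <= 10 and a.nb_contigs <= 20:
                assert a.genome_id in rep.kept


class TestSortByQuality:
    def test_l90_primary_nbcont_secondary(self):
        a = asm_with_quality("a", l90=3, nb=10)
        b = asm_with_quality("b", l90=1, nb=50)
        assert [x.genome_id for x in prepare.sort_by_quality([a, b])] == ["b", "a"]

    def test_genome_id_tiebreak(self):
        a = asm_with_quality("zz", l90=2, nb=5)
        b = asm_with_quality("aa", l90=2, nb=5)
        assert [x.genome_id for x in prepare.sort_by_quality([a, b])] == ["aa", "zz"]

    def test_single_genome(self):
        a = asm_with_quality("only", l90=1, nb=1)
        assert prepare.sort_by_quality([a]) == [a]


def _dists(pairs):
    return {frozenset(k): v for k, v in pairs.items()}


class TestGreedyDistanceFilter:
    def _ordered(self, n):
        return [asm_with_quality(f"g{i}", l90=1, nb=i + 1) for i in range(1, n + 1)]

    def test_too_close_hand_trace(self):
        genomes = self._ordered(3)
        d = _dists({("g1", "g2"): 5e-5, ("g1", "g3"): 0.03, ("g2", "g3"): 0.03})
        rep = prepare.greedy_distance_filter(genomes, d)
        assert rep.kept == ["g1", "g3"]
        (disc,) = rep.discarded
        assert (disc.genome_id, disc.reason, disc.partner) == ("g2", "too_close", "g1")

    def test_all_within_bounds_kept(self):
        genomes = self._ordered(3)
        d = _dists({("g1", "g2"): 0.01, ("g1", "g3"): 0.02, ("g2", "g3"): 0.03})
        rep = prepare.greedy_distance_filter(genomes, d)
        assert rep.kept == ["g1", "g2", "g3"] and rep.discarded == []

    def test_order_dependence_hand_trace(self):
        genomes = self._ordered(3)
        d = _dists({("g1", "g2"): 0.1, ("g1", "g3"): 0.03, ("g2", "g3"): 0.02})
        rep = prepare.greedy_distance_filter(genomes, d)
        assert rep.kept == ["g1", "g3"]
        (disc,) = rep.discarded
        assert (disc.genome_id, disc.reason, disc.partner) == ("g2", "too_distant", "g1")

    def test_boundary_equality_passes(self):
        genomes = self._ordered(2)
        d = _dists({("g1", "g2"): 0.06})
        assert prepare.greedy_distance_filter(genomes, d).kept == ["g1", "g2"]
        d = _dists({("g1", "g2"): 1e-4})
        assert prepare.greedy_distance_filter(genomes, d).kept == ["g1", "g2"]

    def test_missing_distance_is_internal_error(self):
        genomes = self._ordered(2)
        with pytest.raises(KeyError):
            prepare.greedy_distance_filter(genomes, {})

    def test_kept_set_satisfies_box_and_idempotence(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(3, 10))
            genomes = self._ordered(n)
            ids = [g.genome_id for g in genomes]
            d = {}
            for i in range(n):
                for j in range(i + 1, n):
                    d[frozenset((ids[i], ids[j]))] = float(rng.uniform(0, 0.12))
            rep = prepare.greedy_distance_filter(genomes, d)
            kept = rep.kept
            for i, a in enumerate(kept):
                for b in kept[i + 1 :]:
                    assert 1e-4 <= d[frozenset((a, b))] <= 0.06
            again = prepare.greedy_distance_filter(
                [g for g in genomes if g.genome_id in set(kept)], d
            )
            assert again.kept == kept and again.discarded == []
            # first (best-quality) genome always kept
            assert ids[0] in kept


def test_write_prepare_outputs(tmp_path):
    genomes = [asm_with_quality("g1", 1, 2), asm_with_quality("g2", 2, 3)]
    rep = prepare.quality_filter(genomes, l90_max=1)
    prepare.write_prepare_outputs(genomes, [rep], tmp_path)
    info = (tmp_path / "assembly_info.tsv").read_text().splitlines()
    assert len(info) == 3 and info[0].startswith("genome_id")
    disc = (tmp_path / "discarded.tsv").read_text()
    assert "g2\tl90_exceeded" in disc
    assert (tmp_path / "split_fasta" / "g1.fna").exists()
    assert not (tmp_path / "split_fasta" / "g2.fna").exists()
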