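"""Seed matching, duplex MFE, and site scanning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circsponge.energy import EnergyTable, default_table
from circsponge.enumeration import enumerate_duplex_mfe
from circsponge.hybrid import (
    DuplexHit,
    RnaSeq,
    SeedClass,
    duplex_mfe,
    find_seed_matches,
    revcomp,
    scan_sites,
    annotate_ago_support,
)
from conftest import random_rna

rna = st.text(alphabet="ACGU", min_size=1, max_size=30)


class TestRnaSeq:
    def test_normalizes_dna_to_rna(self):
        s = RnaSeq("x", "acgt")
        assert s.seq == "ACGU"

    @pytest.mark.parametrize("bad", ["", "ACGX", "AC GU"])
    def test_rejects_invalid_sequences(self, bad):
        with pytest.raises(ValueError):
            RnaSeq("x", bad)

    def test_conserved_intervals_validated(self):
        RnaSeq("x", "ACGU" * 10, conserved=((0, 10), (20, 30)))
        with pytest.raises(ValueError):
            RnaSeq("x", "ACGU" * 10, conserved=((0, 10), (5, 15)))
        with pytest.raises(ValueError):
            RnaSeq("x", "ACGU", conserved=((0, 10),))


class TestSeedMatches:
    def test_full_complement_gives_single_m8_candidate(self, rng):
        m = RnaSeq("m", random_rna(rng, 22))
        t = RnaSeq("t", random_rna(rng, 40) + revcomp(m.seq) + random_rna(rng, 40))
        found = find_seed_matches(m, t)
        assert len(found) == 1
        assert found[0].seed_class == SeedClass.seed7_m8

    def test_no_complement_possible(self):
        # target has no C or U, so an all-A/G seed cannot pair anywhere
        m = RnaSeq("m", "AGAGAGAG" + "CCCC")
        t = RnaSeq("t", "AG" * 30)
        assert find_seed_matches(m, t) == []

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError):
            find_seed_matches(RnaSeq("m", "ACGUACG"), RnaSeq("t", "ACGU" * 5))

    def test_seed7_a1_requires_target_adenine(self):
        m = RnaSeq("m", "UGGAAUGUAAAGAAGUAUGUAU")  # seed m[1:7] = GGAAUG
        core6 = revcomp(m.seq[1:7])
        # block the m8 extension with a base that cannot pair m[7] = U
        t_a1 = RnaSeq("t", "CCCC" + "C" + core6 + "A" + "CCCC")
        t_6 = RnaSeq("t", "CCCC" + "C" + core6 + "G" + "CCCC")
        (a1,) = find_seed_matches(m, t_a1)
        (m6,) = find_seed_matches(m, t_6)
        assert a1.seed_class == SeedClass.seed7_A1
        assert m6.seed_class == SeedClass.seed6

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_matches_equal_naive_substring_scan(self, data):
        """Anchors agree with an independent position-by-position scan."""
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        m = RnaSeq("m", random_rna(rng, 22))
        t = RnaSeq("t", random_rna(rng, 1000))
        comp = {"A": "U", "C": "G", "G": "C", "U": "A"}
        naive = set()
        for anchor in range(len(t.seq)):
            # miRNA nt k (0-based) pairs target position anchor - (k - 1)
            ok6 = all(
                0 <= anchor - (k - 1) < len(t.seq)
                and t.seq[anchor - (k - 1)] == comp[m.seq[k]]
                for k in range(1, 7)
            )
            if ok6:
                naive.add(anchor)
        assert {sm.anchor for sm in find_seed_matches(m, t)} == naive


class TestDuplexMfe:
    def test_no_duplex_sentinel(self):
        assert duplex_mfe("AAAA", "AAAA") is None

    def test_perfect_gc_8mer_matches_hand_sum(self, table):
        m = "GCGCGCGC"
        res = duplex_mfe(m, revcomp(m), table)
        x, y = m, revcomp(m)[::-1]
        expected = table.init + sum(
            table.stack[((x[i], y[i]), (x[i + 1], y[i + 1]))] for i in range(7)
        )
        assert res.dG == pytest.approx(expected, abs=1e-12)
        assert res.pairing_string == "((((((((&))))))))"

    def test_window_limit_enforced(self):
        with pytest.raises(ValueError, match="scan_sites"):
            duplex_mfe("ACGU" * 3, "ACGU" * 20, max_window=40)

    @settings(max_examples=150, deadline=None)
    @given(data=st.data())
    def test_equals_exhaustive_enumeration(self, table, data):
        """DP minimum equals brute-force enumeration on small pairs."""
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        a = random_rna(rng, int(rng.integers(4, 11)))
        b = random_rna(rng, int(rng.integers(4, 11)))
        res = duplex_mfe(a, b, table)
        ref = enumerate_duplex_mfe(a, b, table)
        if res is None:
            assert ref is None
        else:
            assert res.dG == pytest.approx(ref, abs=1e-9)

    @settings(max_examples=100, deadline=None)
    @given(data=st.data())
    def test_flanking_base_never_raises_minimum(self, table, data):
        # dG is a minimum over structures; adding a window base only
        # enlarges the structure set
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        m = random_rna(rng, 10)
        w = random_rna(rng, 12)
        extra = data.draw(st.sampled_from("ACGU"))
        before = duplex_mfe(m, w, table)
        if before is None:
            return
        for grown in (w + extra, extra + w):
            after = duplex_mfe(m, grown, table)
            assert after is not None and after.dG <= before.dG + 1e-12


def _planted_circ(rng, mirna_seq, offsets, length=300):
    bg = list(random_rna(rng, length))
    site = revcomp(mirna_seq)
    for off in offsets:
        bg[off : off + len(site)] = list(site)
    return RnaSeq("c", "".join(bg))


class TestScanSites:
    def test_recovers_planted_gc_rich_sites(self, rng, table):
        m = RnaSeq("m", "GCUGGCACGGCUAGCCGUAGCC")
        circ = _planted_circ(rng, m.seq, [20, 120, 240])
        hits = scan_sites(m, circ, table, dg_threshold=-20.0)
        assert len(hits) == 3
        assert {h.target_span[0] for h in hits} == {20, 120, 240}
        assert all(h.dG < -20 for h in hits)

    def test_unreachable_threshold_gives_no_hits(self, rng, table):
        m = RnaSeq("m", "GCUGGCACGGCUAGCCGUAGCC")
        circ = _planted_circ(rng, m.seq, [20, 120, 240])
        assert scan_sites(m, circ, table, dg_threshold=-1000.0) == []

    def test_hit_count_monotone_in_threshold(self, rng, table):
        m = RnaSeq("m", "GCUGGCACGGCUAGCCGUAGCC")
        circ = _planted_circ(rng, m.seq, [20, 120, 240])
        counts = [
            len(scan_sites(m, circ, table, dg_threshold=thr))
            for thr in (-10.0, -20.0, -30.0, -50.0, -1000.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_translation_shifts_offsets_only(self, rng, table):
        m = RnaSeq("m", "GCUGGCACGGCUAGCCGUAGCC")
        circ = _planted_circ(rng, m.seq, [60, 180])
        # prepend a pyrimidine-free pad: cannot pair G/C-seed complements
        pad = "".join(np.random.default_rng(7).choice(list("AG"), size=50))
        shifted = RnaSeq("c", pad + circ.seq)
        h0 = scan_sites(m, circ, table)
        h1 = scan_sites(m, shifted, table)
        assert [(h.target_span[0] + 50, round(h.dG, 6)) for h in h0] == [
            (h.target_span[0], round(h.dG, 6)) for h in h1
        ]

    def test_conserved_intervals_restrict_scan(self, rng, table):
        m = RnaSeq("m", "GCUGGCACGGCUAGCCGUAGCC")
        circ = _planted_circ(rng, m.seq, [20, 240])
        restricted = RnaSeq(circ.id, circ.seq, conserved=((0, 100),))
        hits = scan_sites(m, restricted, table)
        assert {h.target_span[0] for h in hits} == {20}

    def test_lowest_dg_site_of_perfect_complement_is_fully_stacked(
        self, rng, table
    ):
        m = RnaSeq("m", "GCUGGCACGGCUAGCCGUAGCC")
        circ = _planted_circ(rng, m.seq, [100])
        (hit,) = scan_sites(m, circ, table)
        n_pairs = hit.pairing_string.split("&")[0].count("(")
        assert n_pairs == len(m.seq)

    def test_ago_annotation_flags_overlaps(self):
        hits = [
            DuplexHit("m", "c", 10, SeedClass.seed6, -25.0, "", (10, 32)),
            DuplexHit("m", "c", 90, SeedClass.seed6, -25.0, "", (90, 112)),
        ]
        annotate_ago_support(hits, [(0, 40)])
        assert hits[0].ago_supported is True
        assert hits[1].ago_supported is False


def test_energy_table_validates_completeness():
    t = default_table()
    with pytest.raises(ValueError):
        EnergyTable(stack={k: v for k, v in list(t.stack.items())[:5]})


def test_reported_hits_must_be_stabilizing():
    with pytest.raises(ValueError):
        DuplexHit("m", "c", 0, SeedClass.seed6, +1.0, "")
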