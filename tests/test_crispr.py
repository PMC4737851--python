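"""CRISPR array detection, curation, grouping, cas typing, proto-spacer
matching and the site-sharing network."""
import numpy as np
import pandas as pd
import pytest

from kryptic.crispr import (
    CasLocus,
    CrisprArray,
    SpacerMember,
    curate_spacers,
    detect_arrays,
    flag_active_arrays,
    group_spacers,
    match_protospacers,
    sharing_network,
    type_cas_locus,
)
from kryptic.seqcore import Sequence, reverse_complement
from kryptic.synthetic_data import _random_seq
from oracles import oracle_scan


def _planted_contig(rng, repeat_len=30, n_spacers=4, spacer_len=35, flank=2000):
    repeat = _random_seq(rng, repeat_len)
    spacers = [_random_seq(rng, spacer_len) for _ in range(n_spacers)]
    array = repeat + "".join(sp + repeat for sp in spacers)
    left = _random_seq(rng, flank)
    contig = Sequence("c", left + array + _random_seq(rng, flank))
    return contig, len(left), len(left) + len(array), repeat, spacers


class TestDetectArrays:
    def test_planted_array_recovered_exactly(self, rng):
        contig, start, end, repeat, spacers = _planted_contig(rng, n_spacers=4)
        arrays = detect_arrays(contig)
        assert len(arrays) == 1
        a = arrays[0]
        assert (a.start, a.end) == (start, end)
        assert a.repeat_seq.residues == repeat
        assert a.n_repeats == 5
        assert [s.residues for s in a.spacers] == spacers
        assert len(a.spacers) == a.n_repeats - 1

    def test_minimum_repeat_count(self, rng):
        # 2 repeats (1 spacer) is below the floor of 3 copies
        repeat = _random_seq(rng, 30)
        seq = _random_seq(rng, 1000) + repeat + _random_seq(rng, 35) + repeat + _random_seq(rng, 1000)
        assert detect_arrays(Sequence("c", seq)) == []

    def test_tandem_repeat_with_no_spacer_rejected(self, rng):
        repeat = _random_seq(rng, 30)
        seq = _random_seq(rng, 1000) + repeat * 6 + _random_seq(rng, 1000)
        assert detect_arrays(Sequence("c", seq)) == []

    def test_false_positive_rate_on_random_contigs(self):
        rng = np.random.default_rng(13)
        fp = sum(
            bool(detect_arrays(Sequence(f"r{i}", _random_seq(rng, 100_000))))
            for i in range(25)
        )
        assert fp == 0

    def test_spacer_count_invariant(self, rng):
        for n_spacers in (2, 5, 9):
            contig, *_ = _planted_contig(rng, n_spacers=n_spacers)
            for a in detect_arrays(contig):
                assert len(a.spacers) == a.n_repeats - 1


class TestCurateSpacers:
    def test_degenerate_tandem_array_dropped(self, rng):
        repeat = _random_seq(rng, 30)
        same = _random_seq(rng, 35)
        arr = CrisprArray("c", 0, 300, Sequence("r", repeat), 4,
                          [Sequence(f"sp{i}", same) for i in range(3)])
        assert curate_spacers([arr]) == []

    def test_bona_fide_array_fully_retained(self, rng):
        contig, *_ = _planted_contig(rng, n_spacers=5)
        arrays = detect_arrays(contig)
        trusted = curate_spacers(arrays)
        assert len(trusted) == 5

    def test_homopolymer_spacer_dropped(self, rng):
        spacers = [Sequence("bad", "A" * 10 + _random_seq(rng, 25))] + [
            Sequence(f"ok{i}", _random_seq(rng, 35)) for i in range(3)
        ]
        arr = CrisprArray("c", 0, 400, Sequence("r", _random_seq(rng, 30)), 5, spacers)
        kept_ids = {sp.id for _, sp in curate_spacers([arr])}
        assert kept_ids == {"ok0", "ok1", "ok2"}

    def test_n_containing_spacer_dropped(self, rng):
        spacers = [Sequence("bad", "N" + _random_seq(rng, 34))] + [
            Sequence(f"ok{i}", _random_seq(rng, 35)) for i in range(2)
        ]
        arr = CrisprArray("c", 0, 400, Sequence("r", _random_seq(rng, 30)), 4, spacers)
        assert {sp.id for _, sp in curate_spacers([arr])} == {"ok0", "ok1"}


class TestGroupSpacers:
    def test_identical_spacers_from_two_sites_merge(self, rng):
        s = _random_seq(rng, 35)
        members = [
            SpacerMember("a", Sequence("a", s), source_site="siteA"),
            SpacerMember("b", Sequence("b", s), source_site="siteB"),
        ]
        groups = group_spacers(members)
        assert len(groups) == 1
        assert groups[0].sites == {"siteA", "siteB"}

    def test_85_percent_identity_stays_separate(self, rng):
        a = _random_seq(rng, 40)
        b = list(a)
        for p in range(0, 12, 2):  # 6 substitutions: 34/40 = 85%
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        groups = group_spacers([
            SpacerMember("a", Sequence("a", a)),
            SpacerMember("b", Sequence("b", "".join(b))),
        ])
        assert len(groups) == 2

    def test_membership_invariant(self, rng):
        from kryptic.seqcore import whole_length_identity
        members = [SpacerMember(f"s{i}", Sequence(f"s{i}", _random_seq(rng, 35)))
                   for i in range(30)]
        for g in group_spacers(members, 90.0):
            for m in g.members:
                assert whole_length_identity(g.representative, m.seq) >= 90.0 or \
                    m.spacer_id == g.members[0].spacer_id


class TestTypeCasLocus:
    def _table(self, genes):
        return pd.DataFrame(
            [("c1", f"g{i}", fam, start, start + 900, "+") for i, (fam, start) in enumerate(genes)],
            columns=["contig_id", "gene_id", "family", "start", "end", "strand"],
        )

    I_B = ["cas8b", "cas7", "cas5"]
    III_A = ["cas10", "csm2", "csm3", "csm4", "csm5"]

    def test_single_subtype_locus(self):
        loci = type_cas_locus(self._table([(f, 1000 * i) for i, f in enumerate(self.I_B)]))
        assert len(loci) == 1
        assert loci[0].subtype_calls == {"I-B"}
        assert not loci[0].fusion

    def test_contiguous_fusion_of_both_subtypes(self):
        genes = [(f, 1000 * i) for i, f in enumerate(self.I_B + self.III_A)]
        loci = type_cas_locus(self._table(genes))
        assert len(loci) == 1
        assert loci[0].fusion
        assert loci[0].subtype_calls == {"I-B", "III-A"}

    def test_distant_loci_are_not_fused(self):
        genes = [(f, 1000 * i) for i, f in enumerate(self.I_B)]
        genes += [(f, 60_000 + 1000 * i) for i, f in enumerate(self.III_A)]
        loci = type_cas_locus(self._table(genes))
        assert len(loci) == 2
        assert all(not l.fusion for l in loci)
        assert [l.subtype_calls for l in loci] == [{"I-B"}, {"III-A"}]

    def test_unknown_family_ignored_with_warning(self):
        table = self._table([("cas8b", 0), ("mystery9", 1000), ("cas7", 2000), ("cas5", 3000)])
        with pytest.warns(UserWarning):
            loci = type_cas_locus(table)
        assert len(loci) == 1


class TestMatchProtospacers:
    def _group(self, spacer, contig_id="host", start=1000, end=1400, site="siteA"):
        member = SpacerMember("sp0", spacer, source_site=site, contig_id=contig_id,
                              array_start=start, array_end=end)
        from kryptic.crispr import SpacerGroup
        return SpacerGroup("sg0", Sequence("sg0", spacer.residues), [member])

    def test_verbatim_hit_in_viral_contig(self, rng):
        spacer = Sequence("sp", _random_seq(rng, 35))
        viral = Sequence("v1", _random_seq(rng, 500) + spacer.residues + _random_seq(rng, 500))
        hits = match_protospacers(
            [self._group(spacer)], {"sampleB": [viral]}, {"v1": "viral"})
        assert len(hits) == 1
        assert hits[0].subject_class == "viral"
        assert hits[0].position == 500
        assert hits[0].mismatches == 0

    def test_four_mismatches_not_reported(self, rng):
        spacer = Sequence("sp", _random_seq(rng, 35))
        mutated = list(spacer.residues)
        for p in (0, 9, 18, 27):
            mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
        subject = Sequence("v1", _random_seq(rng, 300) + "".join(mutated) + _random_seq(rng, 300))
        assert match_protospacers([self._group(spacer)], {"s": [subject]}) == []

    def test_self_hit_inside_source_array_excluded(self, rng):
        spacer = Sequence("sp", _random_seq(rng, 35))
        host = Sequence("host", _random_seq(rng, 1000) + spacer.residues + _random_seq(rng, 1000))
        group = self._group(spacer, contig_id="host", start=1000, end=1035)
        assert match_protospacers([group], {"siteA": [host]}) == []
        # but a second occurrence outside the array is reported
        host2 = Sequence(
            "host", _random_seq(rng, 1000) + spacer.residues
            + _random_seq(rng, 500) + spacer.residues + _random_seq(rng, 500)
        )
        hits = match_protospacers([group], {"siteA": [host2]})
        assert [h.position for h in hits] == [1535]

    def test_equals_sliding_window_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(100):
            spacer = Sequence("sp", _random_seq(rng, int(rng.integers(25, 46))))
            subject = Sequence("t", _random_seq(rng, int(rng.integers(200, 500))))
            group = self._group(spacer, contig_id="elsewhere")
            got = sorted(
                (h.position, h.strand, h.mismatches)
                for h in match_protospacers([group], {"s": [subject]}, max_mismatches=3)
            )
            assert got == oracle_scan(spacer.residues, subject.residues, 3)


class TestSharingNetwork:
    def test_single_shared_group(self, rng):
        s = _random_seq(rng, 35)
        groups = group_spacers([
            SpacerMember("a", Sequence("a", s), source_site="A"),
            SpacerMember("b", Sequence("b", s), source_site="B"),
        ])
        mat = sharing_network(groups, [])
        assert mat.loc["A", "B"] == 1
        assert mat.loc["A", "A"] == 1

    def test_no_sharing_means_zero_offdiagonal(self, rng):
        groups = group_spacers([
            SpacerMember("a", Sequence("a", _random_seq(rng, 35)), source_site="A"),
            SpacerMember("b", Sequence("b", _random_seq(rng, 35)), source_site="B"),
        ])
        mat = sharing_network(groups, [])
        assert mat.loc["A", "B"] == 0

    def test_symmetry_and_label_permutation(self, rng):
        members = []
        for i in range(20):
            site = f"S{i % 4}"
            members.append(SpacerMember(f"m{i}", Sequence(f"m{i}", _random_seq(rng, 35)),
                                        source_site=site))
        shared = _random_seq(rng, 35)
        for i, site in enumerate(["S0", "S2"]):
            members.append(SpacerMember(f"sh{i}", Sequence(f"sh{i}", shared), source_site=site))
        mat = sharing_network(group_spacers(members), [])
        assert (mat.values == mat.values.T).all()
        assert (mat.values >= 0).all()
        assert mat.loc["S0", "S2"] == 1

    def test_shared_pool_rate_recovery(self):
        """Sites built from a shared spacer pool at fraction 0.2 show
        cross-site sharing consistent with that rate."""
        rng = np.random.default_rng(55)
        pool = [_random_seq(rng, 35) for _ in range(30)]
        members = []
        shared_flags = {site: [] for site in "ABCD"}
        for site in "ABCD":
            for i in range(50):
                if rng.random() < 0.2:
                    s = pool[rng.integers(0, len(pool))]
                    shared_flags[site].append(True)
                else:
                    s = _random_seq(rng, 35)
                    shared_flags[site].append(False)
                members.append(SpacerMember(f"{site}{i}", Sequence(f"{site}{i}", s),
                                            source_site=site))
        mat = sharing_network(group_spacers(members), [])
        # each site drew ~10 pool spacers of 30; expected pairwise overlap
        # ~ 30 * (1-(1-1/3)... just require substantial sharing on every pair
        for a in "ABCD":
            for b in "ABCD":
                if a < b:
                    assert mat.loc[a, b] >= 1


class TestFlagActiveArrays:
    def _array(self, contig, start, repeat, rng):
        return CrisprArray(contig, start, start + 300, Sequence("r", repeat), 4,
                           [Sequence(f"s{i}", _random_seq(rng, 35)) for i in range(3)])

    def _locus(self, contig, start):
        return CasLocus("L0", contig, [("g0", "cas7", start, start + 900, "+")])

    def test_array_near_cas_locus_is_active(self, rng):
        arr = self._array("c1", 5000, _random_seq(rng, 30), rng)
        flagged = flag_active_arrays([arr], [self._locus("c1", 7000)])
        assert flagged[0].active
        assert flagged[0].cas_locus_id == "L0"

    def test_repeat_sharing_confers_activity(self, rng):
        repeat = _random_seq(rng, 30)
        near = self._array("c1", 5000, repeat, rng)
        isolated = self._array("c2", 5000, repeat, rng)
        flagged = flag_active_arrays([near, isolated], [self._locus("c1", 7000)])
        assert all(a.active for a in flagged)

    def test_isolated_unique_repeat_inactive(self, rng):
        arr = self._array("c9", 5000, _random_seq(rng, 30), rng)
        assert not flag_active_arrays([arr], [self._locus("c1", 7000)])[0].active

    def test_distance_gate(self, rng):
        arr = self._array("c1", 0, _random_seq(rng, 30), rng)
        far = self._locus("c1", 50_000)
        assert not flag_active_arrays([arr], [far])[0].active
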