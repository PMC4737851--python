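"""SSU fragment discovery, novelty thresholds, primer and probe audits."""
import numpy as np
import pytest

from kryptic.seqcore import IUPAC_SETS, Sequence, reverse_complement
from kryptic.ssu_screen import (
    DEFAULT_NOVELTY_THRESHOLDS,
    SSUFragment,
    classify_novelty,
    find_ssu_fragments,
    primer_audit,
    probe_specificity,
)
from kryptic.synthetic_data import CommunitySpec, _mutate, _random_seq, generate_community
from oracles import oracle_primer_best_site


@pytest.fixture(scope="module")
def screen_community():
    """One 150 kbp contig per genome, template kept for use as reference."""
    rng = np.random.default_rng(99)
    template = Sequence("tpl", _random_seq(rng, 1200))
    spec = CommunitySpec(
        n_genomes=2, genome_length=150_000, contig_length_range=(100_000, 150_000),
        crispr=None, n_markers=5, rng_seed=12, ssu_template=template,
    )
    contigs, coverage, truth = generate_community(spec)
    decoys = [Sequence(f"decoy{i}", _random_seq(rng, 1200)) for i in range(3)]
    return template, contigs, truth, decoys


class TestFindFragments:
    def test_planted_ssu_recovered_with_exact_coordinates(self, screen_community):
        template, contigs, truth, decoys = screen_community
        frags = find_ssu_fragments(contigs, [template] + decoys)
        assert len(frags) == len(truth.ssu)
        by_contig = {f.contig_id: f for f in frags}
        for g, (cid, s, e, strand, seq) in truth.ssu.items():
            f = by_contig[cid]
            assert (f.start, f.end, f.strand) == (s, e, strand)
            assert f.seq.residues == seq
            assert f.best_ref_id == "tpl"

    def test_short_contigs_are_never_scanned(self, screen_community):
        template, contigs, truth, decoys = screen_community
        truncated = [Sequence(c.id, c.residues[:90_000]) for c in contigs]
        assert find_ssu_fragments(truncated, [template] + decoys) == []

    def test_fragment_length_filter_is_strict(self):
        """A planted 100 bp reference match is excluded; 101 bp included.

        Flanks are N so the aligned core cannot extend past the planted
        piece and the boundary is exact by construction."""
        rng = np.random.default_rng(4)
        ref = Sequence("ref", _random_seq(rng, 400))
        for frag_len, expected in [(100, 0), (101, 1)]:
            piece = ref.residues[:frag_len]
            contig = Sequence("c", "N" * 60_000 + piece + "N" * 60_000)
            frags = find_ssu_fragments([contig], [ref], min_contig_len=100_000)
            assert len(frags) == expected
            if expected:
                assert (frags[0].start, frags[0].end) == (60_000, 60_000 + frag_len)

    def test_reverse_strand_detection(self, screen_community):
        template, contigs, truth, decoys = screen_community
        flipped = [reverse_complement(c) for c in contigs]
        frags = find_ssu_fragments(flipped, [template] + decoys)
        strands = {f.contig_id: f.strand for f in frags}
        for g, (cid, s, e, strand, _) in truth.ssu.items():
            assert strands[cid] == ("-" if strand == "+" else "+")

    def test_empty_refdb_rejected(self, screen_community):
        _, contigs, _, _ = screen_community
        with pytest.raises(ValueError):
            find_ssu_fragments(contigs, [])

    def test_recall_at_deep_divergence(self):
        """Planted SSU genes remain detectable at divergence up to 0.25
        from the only reference."""
        rng = np.random.default_rng(17)
        template = Sequence("tpl", _random_seq(rng, 1200))
        for d in (0.1, 0.25):
            spec = CommunitySpec(
                n_genomes=2, genome_length=120_000, contig_length_range=(100_000, 120_000),
                per_lineage_divergence=d, crispr=None, n_markers=5,
                rng_seed=23, ssu_template=template,
            )
            contigs, _, truth = generate_community(spec)
            frags = find_ssu_fragments(contigs, [template])
            assert {f.contig_id for f in frags} == {v[0] for v in truth.ssu.values()}


class TestNovelty:
    def _frag(self, ident):
        return SSUFragment("c", 0, 1200, "+", Sequence("f", "ACGT" * 300), "ref", ident)

    @pytest.mark.parametrize(
        "identity,rank",
        [(100.0, "none"), (98.7, "none"), (98.6, "species"), (95.0, "species"),
         (94.0, "genus"), (83.0, "family"), (80.0, "order"), (78.0, "class"),
         (70.0, "phylum")],
    )
    def test_threshold_table(self, identity, rank):
        assert classify_novelty(self._frag(identity)).novel_rank == rank

    def test_monotonicity_in_identity(self):
        order = ["none", "species", "genus", "family", "order", "class", "phylum"]
        ranks = [
            order.index(classify_novelty(self._frag(i)).novel_rank)
            for i in np.linspace(100, 60, 81)
        ]
        assert ranks == sorted(ranks)

    def test_non_monotone_thresholds_rejected(self):
        bad = dict(DEFAULT_NOVELTY_THRESHOLDS, genus=99.0)
        with pytest.raises(ValueError):
            classify_novelty(self._frag(90.0), thresholds=bad)


PRIMER_926WF = "GAAACTYAAAKGAATTGRCGG"


class TestPrimerAudit:
    def test_exact_recognition_site_is_zero_mismatch(self, rng):
        site = "GAAACTTAAAGGAATTGACGG"  # one concrete expansion of 926wF
        target = Sequence("t", _rand_flanks(rng, site))
        audit = primer_audit("926wF", PRIMER_926WF, [target])[0]
        assert audit.best_site_mismatches == 0
        assert audit.site_position == 200

    def test_degeneracy_satisfied_by_alternate_bases(self, rng):
        # C at the Y position and G at the R position still count as matches
        site = "GAAACTCAAATGAATTGGCGG"
        target = Sequence("t", _rand_flanks(rng, site))
        assert primer_audit("926wF", PRIMER_926WF, [target])[0].best_site_mismatches == 0

    def test_primer_longer_than_target_flagged_no_site(self):
        audit = primer_audit("p", "ACGTACGTACGT", [Sequence("t", "ACGT")])[0]
        assert audit.best_site_mismatches is None

    def test_equals_brute_force_oracle(self):
        rng = np.random.default_rng(31)
        codes = list(IUPAC_SETS)
        for _ in range(200):
            primer = "".join(rng.choice(codes) for _ in range(rng.integers(12, 25)))
            target = Sequence("t", "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(60, 200))))
            audit = primer_audit("p", primer, [target])[0]
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            fwd_sets = [IUPAC_SETS[c] for c in primer]
            rev_sets = [
                {comp[b] for b in IUPAC_SETS[c]} for c in reversed(primer)
            ]
            expected = min(
                oracle_primer_best_site(fwd_sets, target.residues),
                oracle_primer_best_site(rev_sets, target.residues),
            )
            assert audit.best_site_mismatches == expected

    def test_reverse_strand_site_found(self, rng):
        site = "GAAACTTAAAGGAATTGACGG"
        rc = reverse_complement(Sequence("x", site)).residues
        target = Sequence("t", _rand_flanks(rng, rc))
        audit = primer_audit("926wF", PRIMER_926WF, [target])[0]
        assert audit.best_site_mismatches == 0
        assert audit.site_strand == "-"


class TestProbeSpecificity:
    PROBE = Sequence("probe", "CCGTGTCCCTGACTTGCA")

    def test_perfect_match_in_every_target(self, rng):
        targets = [Sequence(f"t{i}", _rand_flanks(rng, self.PROBE.residues)) for i in range(5)]
        report = probe_specificity(self.PROBE, targets, [])
        assert report.perfect_match_count == 5
        assert report.passed

    def test_single_mismatch_nontargets_fail(self, rng):
        site = list(self.PROBE.residues)
        site[8] = {"A": "C", "C": "G", "G": "T", "T": "A"}[site[8]]
        nontargets = [Sequence(f"n{i}", _rand_flanks(rng, "".join(site))) for i in range(3)]
        targets = [Sequence("t", _rand_flanks(rng, self.PROBE.residues))]
        report = probe_specificity(self.PROBE, targets, nontargets)
        assert report.worst_nontarget_mismatches == 1
        assert not report.passed

    def test_19_of_22_targets_with_planted_site_mutations(self):
        """A 22-sequence target set where 3 sequences carry one substitution
        in the probe site yields a perfect-match count of 19."""
        rng = np.random.default_rng(3)
        targets = []
        for i in range(22):
            site = list(self.PROBE.residues)
            if i < 3:
                p = int(rng.integers(0, len(site)))
                site[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[site[p]]
            targets.append(Sequence(f"t{i}", _rand_flanks(rng, "".join(site))))
        report = probe_specificity(self.PROBE, targets, [])
        assert report.perfect_match_count == 19

    def test_empty_target_set_rejected(self):
        with pytest.raises(ValueError):
            probe_specificity(self.PROBE, [], [])


def _rand_flanks(rng, core, flank=200):
    return (
        "".join("ACGT"[i] for i in rng.integers(0, 4, flank))
        + core
        + "".join("ACGT"[i] for i in rng.integers(0, 4, flank))
    )
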