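"""SSU rRNA discovery screen on long assembled contigs.

Only long contigs (default >= 100 kbp) are scanned, mirroring the rationale
that SSU genes on long contigs come with enough genomic context to seed
binning. Candidate regions are found by shared-k-mer seeding against a
reference SSU database, verified by global alignment identity, and kept
when longer than 100 bp (strict). Novelty is called from the best reference
identity using rank-level identity thresholds, and degenerate "universal"
primers and FISH probes are audited for mismatches against target sets —
the blind-spot mechanism by which deeply divergent lineages elude amplicon
surveys.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqcore import (
    IUPAC_SETS,
    Sequence,
    aligned_region,
    reverse_complement,
    reverse_complement_iupac,
)

__all__ = [
    "SSUFragment",
    "NoveltyCall",
    "PrimerAudit",
    "SpecificityReport",
    "DEFAULT_NOVELTY_THRESHOLDS",
    "find_ssu_fragments",
    "classify_novelty",
    "primer_audit",
    "probe_specificity",
]

# rank-level SSU identity thresholds: a fragment whose best reference
# identity falls below a rank's threshold is novel at (at least) that rank
DEFAULT_NOVELTY_THRESHOLDS = {
    "species": 98.7,
    "genus": 94.5,
    "family": 86.5,
    "order": 82.0,
    "class": 78.5,
    "phylum": 75.0,
}
_RANK_ORDER = ["species", "genus", "family", "order", "class", "phylum"]


@dataclass
class SSUFragment:
    contig_id: str
    start: int  # 0-based half-open, forward strand of the contig
    end: int
    strand: str
    seq: Sequence
    best_ref_id: str
    best_identity_pct: float

    @property
    def fragment_id(self) -> str:
        return f"{self.contig_id}:{self.start}-{self.end}({self.strand})"


@dataclass(frozen=True)
class NoveltyCall:
    fragment_id: str
    best_identity_pct: float
    novel_rank: str  # species|genus|family|order|class|phylum|none
    thresholds_used: dict


@dataclass(frozen=True)
class PrimerAudit:
    primer_name: str
    primer_iupac: str
    target_id: str
    best_site_mismatches: int | None  # None = no full-length site exists
    site_position: int | None
    site_strand: str | None


@dataclass(frozen=True)
class SpecificityReport:
    perfect_match_count: int
    worst_nontarget_mismatches: int | None
    passed: bool


def _kmer_positions(residues: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(residues) - k + 1):
        km = residues[i : i + k]
        if "N" not in km:
            idx.setdefault(km, []).append(i)
    return idx


def _candidate_windows(contig_str: str, ref: Sequence, ref_kmers: dict, k: int):
    """Positions on contig_str sharing k-mers with the ref, grouped into
    windows separated by more than one reference length."""
    positions = []
    for i in range(len(contig_str) - k + 1):
        if contig_str[i : i + k] in ref_kmers:
            positions.append(i)
    windows = []
    for p in positions:
        if windows and p - windows[-1][1] <= len(ref):
            windows[-1][1] = p + k
        else:
            windows.append([p, p + k])
    return windows


def find_ssu_fragments(
    contigs: list[Sequence],
    refdb: list[Sequence],
    min_contig_len: int = 100_000,
    min_frag_len: int = 100,
    min_identity: float = 60.0,
    seed_k: int = 12,
    pad: int = 150,
) -> list[SSUFragment]:
    """Locate SSU gene fragments on contigs >= min_contig_len.

    Fragments must exceed min_frag_len (strict) and reach >= min_identity
    to the best reference. The identity floor is deliberately permissive
    (60%) so that even phylum-level novel lineages are retained.
    """
    if not refdb:
        raise ValueError("reference SSU database is empty")
    ref_indexes = [(ref, _kmer_positions(ref.residues, seed_k)) for ref in refdb]
    fragments: list[SSUFragment] = []
    for contig in contigs:
        if len(contig) < min_contig_len:
            continue
        # candidate regions on each strand of the contig, best ref per region
        candidates: list[tuple[int, int, str, float, str]] = []  # start,end,strand,ident,ref
        for strand in "+-":
            cstr = contig.residues if strand == "+" else reverse_complement(contig).residues
            for ref, ref_kmers in ref_indexes:
                for w0, w1 in _candidate_windows(cstr, ref, ref_kmers, seed_k):
                    r0 = max(0, w0 - pad)
                    r1 = min(len(cstr), w1 + pad)
                    region = Sequence("region", cstr[r0:r1])
                    ident, a0, a1, _, _ = aligned_region(region, ref)
                    if ident < min_identity:
                        continue
                    s, e = r0 + a0, r0 + a1
                    if strand == "-":
                        s, e = len(cstr) - e, len(cstr) - s
                    candidates.append((s, e, strand, ident, ref.id))
        # merge overlapping candidates, keeping the best-identity call
        candidates.sort(key=lambda c: (-c[3], c[0]))
        chosen: list[tuple[int, int, str, float, str]] = []
        for cand in candidates:
            if all(cand[1] <= c[0] or cand[0] >= c[1] for c in chosen):
                chosen.append(cand)
        for s, e, strand, ident, ref_id in sorted(chosen):
            if e - s <= min_frag_len:
                continue
            frag_seq = contig.residues[s:e]
            if strand == "-":
                frag_seq = reverse_complement(Sequence("f", frag_seq)).residues
            fragments.append(
                SSUFragment(contig.id, s, e, strand, Sequence(f"{contig.id}:{s}-{e}", frag_seq), ref_id, ident)
            )
    return fragments


def classify_novelty(
    fragment: SSUFragment, thresholds: dict[str, float] | None = None
) -> NoveltyCall:
    """Deepest taxonomic rank at which the fragment is novel.

    The call is identity-consistent novelty only — no tree placement: the
    reported rank is the one with the smallest threshold still above the
    fragment's best reference identity.
    """
    thr = dict(thresholds or DEFAULT_NOVELTY_THRESHOLDS)
    vals = [thr[r] for r in _RANK_ORDER]
    if vals != sorted(vals, reverse=True):
        raise ValueError("novelty thresholds must decrease with rank depth")
    ident = fragment.best_identity_pct
    novel = "none"
    for rank in _RANK_ORDER:
        if ident < thr[rank]:
            novel = rank
    return NoveltyCall(fragment.fragment_id, ident, novel, thr)


def _iupac_lut(primer: str) -> np.ndarray:
    """(len(primer), 5) boolean: does target base code match primer code.
    Column 4 (N in the target) never matches."""
    lut = np.zeros((len(primer), 5), dtype=bool)
    for i, code in enumerate(primer):
        if code not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC code {code!r} in primer")
        for b in IUPAC_SETS[code]:
            lut[i, "ACGT".index(b)] = True
    return lut


def _best_site(primer: str, target: Sequence):
    """Minimum IUPAC-aware mismatch count over all full-length placements on
    either strand; returns (mismatches, position, strand) or (None,)*3."""
    q = len(primer)
    if q > len(target):
        return None, None, None
    sub = target.codes
    n_win = len(target) - q + 1
    best = None  # (mismatches, position, strand_is_minus, strand)
    for strand, pat in (("+", primer.upper()), ("-", reverse_complement_iupac(primer))):
        lut = _iupac_lut(pat)
        matches = np.zeros(n_win, dtype=np.int32)
        for i in range(q):
            matches += lut[i, sub[i : i + n_win]]
        mism = q - matches
        pos = int(np.argmin(mism))  # first position among equal minima
        cand = (int(mism[pos]), pos, strand == "-", strand)
        if best is None or cand[:3] < best[:3]:
            best = cand
    return best[0], best[1], best[3]


def primer_audit(
    primer_name: str, primer_iupac: str, targets: list[Sequence]
) -> list[PrimerAudit]:
    """Per target, the best (fewest-mismatch) full-length primer site over
    both strands, IUPAC degeneracy honoured on the primer side."""
    audits = []
    for t in targets:
        mism, pos, strand = _best_site(primer_iupac, t)
        audits.append(PrimerAudit(primer_name, primer_iupac.upper(), t.id, mism, pos, strand))
    return audits


def probe_specificity(
    probe: Sequence,
    target_set: list[Sequence],
    nontarget_set: list[Sequence],
    min_nontarget_mismatches: int = 2,
) -> SpecificityReport:
    """Count perfect-match targets; pass iff every non-target's best site
    carries at least min_nontarget_mismatches mismatches."""
    if len(probe) < 10:
        raise ValueError("probe too short (< 10 nt)")
    if not target_set:
        raise ValueError("empty target set")
    perfect = sum(
        1 for t in target_set if _best_site(probe.residues, t)[0] == 0
    )
    worst = None
    for t in nontarget_set:
        m, _, _ = _best_site(probe.residues, t)
        if m is not None and (worst is None or m < worst):
            worst = m
    passed = worst is None or worst >= min_nontarget_mismatches
    return SpecificityReport(perfect, worst, passed)
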