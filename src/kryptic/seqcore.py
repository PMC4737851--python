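"""Shared sequence algorithmics.

Everything downstream (SSU screening, binning, CRISPR matching, phylotype
clustering) is expressed in terms of a handful of primitives defined here:
percent identity from a global alignment, IUPAC-aware base matching,
bounded-mismatch scanning of short queries against long subjects, greedy
centroid clustering at an identity threshold, and reverse complementation.

Percent identity follows usearch-style semantics: the alignment is global
(Needleman-Wunsch, match +1, mismatch -1, gap -1, linear), terminal gap
runs are excluded from the denominator, internal gaps count as mismatching
columns, and N never matches. Among score-optimal alignments the one
maximizing matches is used.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence as TySequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._alignment import nw_align

__all__ = [
    "Sequence",
    "PairwiseIdentity",
    "Cluster",
    "ScanHit",
    "IUPAC_SETS",
    "global_identity",
    "whole_length_identity",
    "iupac_matches",
    "bounded_mismatch_scan",
    "greedy_cluster",
    "reverse_complement",
    "reverse_complement_iupac",
    "read_fasta",
    "write_fasta",
    "write_hits_tsv",
]

_ALPHABET = set("ACGTN")
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_DECODE = np.array(list("ACGTN"))
_ENCODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _b, _c in _CODE.items():
    _ENCODE_TABLE[ord(_b)] = _c

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_COMPLEMENT_IUPAC = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

IUPAC_SETS = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


@dataclass
class Sequence:
    """A named nucleotide sequence over {A, C, G, T, N} (uppercased on ingest)."""

    id: str
    residues: str
    description: str = ""
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-ACGTN characters: {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def codes(self) -> np.ndarray:
        """uint8 encoding (A=0 C=1 G=2 T=3 N=4), cached."""
        if self._codes is None:
            self._codes = _ENCODE_TABLE[np.frombuffer(self.residues.encode(), np.uint8)]
        return self._codes


@dataclass(frozen=True)
class PairwiseIdentity:
    query_id: str
    target_id: str
    identity_pct: float
    aligned_cols: int
    matches: int


@dataclass
class Cluster:
    cluster_id: str
    centroid_id: str
    member_ids: list[str]
    threshold_pct: float


@dataclass(frozen=True)
class ScanHit:
    position: int  # 0-based on the forward strand of the subject
    strand: str  # '+' or '-'
    mismatches: int


def encode(residues: str) -> np.ndarray:
    return _ENCODE_TABLE[np.frombuffer(residues.upper().encode(), np.uint8)]


def _align_codes(a: np.ndarray, b: np.ndarray, local: bool = False):
    return nw_align(np.ascontiguousarray(a), np.ascontiguousarray(b), 1 if local else 0)


def _canonical_pair(a: Sequence, b: Sequence) -> tuple[Sequence, Sequence]:
    # tie resolution in the DP depends on which sequence indexes the rows;
    # aligning in a canonical order makes identity exactly symmetric
    if (len(a), a.residues) > (len(b), b.residues):
        return b, a
    return a, b


def global_identity(a: Sequence, b: Sequence) -> PairwiseIdentity:
    """Percent identity of a global alignment of *a* and *b*.

    identity_pct = 100 * matches / aligned columns, where terminal gap runs
    are excluded from the aligned columns and internal gaps count as
    mismatching columns. The pair is aligned in a canonical order (shorter
    first, ties lexicographic), making the result exactly symmetric.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot align empty sequences")
    x, y = _canonical_pair(a, b)
    matches, cols, *_ = _align_codes(x.codes, y.codes)
    if cols == 0:
        return PairwiseIdentity(a.id, b.id, 0.0, 0, 0)
    return PairwiseIdentity(a.id, b.id, 100.0 * matches / cols, int(cols), int(matches))


def aligned_region(a: Sequence, b: Sequence):
    """Local (maximal-segment) alignment of *a* vs *b*; returns
    (identity_pct, a_start, a_end, b_start, b_end). Used to extract the
    homologous region from a padded candidate window."""
    matches, cols, a0, a1, b0, b1, _ = _align_codes(a.codes, b.codes, local=True)
    ident = 100.0 * matches / cols if cols else 0.0
    return ident, int(a0), int(a1), int(b0), int(b1)


def whole_length_identity(a: Sequence, b: Sequence) -> float:
    """Identity with the full (longer) sequence length as denominator.

    Used for spacer grouping, where the threshold applies over the whole
    spacer length rather than the aligned region only.
    """
    x, y = _canonical_pair(a, b)
    matches, *_ = _align_codes(x.codes, y.codes)
    return 100.0 * matches / max(len(a), len(b))


def iupac_matches(observed_base: str, code: str) -> bool:
    """True iff *observed_base* (A/C/G/T) is in the degeneracy set of *code*."""
    if observed_base not in IUPAC_SETS or len(IUPAC_SETS[observed_base]) != 1:
        raise ValueError(f"observed base must be one of A,C,G,T, got {observed_base!r}")
    try:
        return observed_base in IUPAC_SETS[code]
    except KeyError:
        raise ValueError(f"invalid IUPAC code {code!r}") from None


def reverse_complement(s: Sequence) -> Sequence:
    """Reverse complement (N maps to N); an involution."""
    return Sequence(s.id, s.residues.translate(_COMPLEMENT)[::-1], s.description)


def reverse_complement_iupac(residues: str) -> str:
    """Reverse complement of a degenerate (IUPAC) string, e.g. for primers."""
    return residues.upper().translate(_COMPLEMENT_IUPAC)[::-1]


def _window_mismatch_counts(query_codes: np.ndarray, subject_codes: np.ndarray) -> np.ndarray:
    """Hamming mismatches of the query against every subject window (N always
    mismatches). Vectorized over windows."""
    q = len(query_codes)
    windows = np.lib.stride_tricks.sliding_window_view(subject_codes, q)
    mism = (windows != query_codes) | (windows == 4) | (query_codes == 4)
    return mism.sum(axis=1)


def bounded_mismatch_scan(
    query: Sequence, subject: Sequence, max_mismatches: int
) -> list[ScanHit]:
    """All full-length ungapped placements of *query* (both strands) on
    *subject* with Hamming distance <= max_mismatches.

    Positions are 0-based on the forward strand of the subject. A query
    longer than the subject yields an empty result.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    if len(query) > len(subject):
        return []
    hits: list[ScanHit] = []
    sub = subject.codes
    for strand, qcodes in (("+", query.codes), ("-", reverse_complement(query).codes)):
        counts = _window_mismatch_counts(qcodes, sub)
        for pos in np.nonzero(counts <= max_mismatches)[0]:
            hits.append(ScanHit(int(pos), strand, int(counts[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def greedy_cluster(
    seqs: TySequence[Sequence],
    threshold_pct: float,
    identity_fn: Callable[[Sequence, Sequence], float] | None = None,
) -> list[Cluster]:
    """Greedy centroid clustering at an identity threshold.

    Sequences are processed longest-first (ties by id); each joins the first
    existing centroid (in centroid creation order) with identity >=
    threshold_pct, else founds a new cluster. Deterministic.
    """
    if not 0 < threshold_pct <= 100:
        raise ValueError("threshold_pct must be in (0, 100]")
    if identity_fn is None:
        identity_fn = lambda c, s: global_identity(c, s).identity_pct  # noqa: E731
    order = sorted(seqs, key=lambda s: (-len(s), s.id))
    centroids: list[Sequence] = []
    clusters: list[Cluster] = []
    for s in order:
        for cen, cl in zip(centroids, clusters):
            if identity_fn(cen, s) >= threshold_pct:
                cl.member_ids.append(s.id)
                break
        else:
            centroids.append(s)
            clusters.append(
                Cluster(f"cluster{len(clusters)}", s.id, [s.id], threshold_pct)
            )
    return clusters


# ---------------------------------------------------------------------------
# plain-text interchange


def read_fasta(path: str | Path) -> list[Sequence]:
    seqs = [
        Sequence(rec.id, str(rec.seq), rec.description[len(rec.id) :].strip())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs


def write_fasta(seqs: Iterable[Sequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description) for s in seqs
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_hits_tsv(rows, path: str | Path) -> None:
    """Hit rows as TSV: query_id, subject_id, position, strand, mismatches."""
    with open(path, "w") as fh:
        fh.write("query_id\tsubject_id\tposition\tstrand\tmismatches\n")
        for query_id, subject_id, hit in rows:
            fh.write(
                f"{query_id}\t{subject_id}\t{hit.position}\t{hit.strand}\t{hit.mismatches}\n"
            )
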