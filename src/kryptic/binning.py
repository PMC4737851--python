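"""Tetranucleotide-signature binning, completeness, decontamination and ANI.

A contig's tetranucleotide signature is the frequency vector over the 136
canonical 4-mers (each 4-mer pooled with its reverse complement), which is
invariant under reverse complementation of the contig. Recruitment around a
seed contig combines signature distance (Euclidean) with a per-sample
coverage-ratio band, echoing the observation that contigs of one genome
share both composition and abundance profile.

ANI follows the whole-genome species-identifier scheme: the coding regions
of genome A are cut into fixed-length fragments, mapped onto genome B by
k-mer seeding plus global alignment, and ANI is the mean identity over
reciprocal best fragment pairs at >= 70% identity; two genomes are called
the same species at ANI >= 96.5% with aligned fraction >= 0.6.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .seqcore import Sequence, global_identity, reverse_complement

__all__ = [
    "TetraSignature",
    "GenomeBin",
    "ANIResult",
    "tetra_signature",
    "recruit_bin",
    "completeness",
    "decontaminate_sag",
    "ani",
]

_COMP = str.maketrans("ACGT", "TGCA")


def _canonical_map() -> tuple[list[str], np.ndarray]:
    """136 canonical 4-mer keys (lexicographic min of 4-mer / revcomp) and a
    256-entry map from 4-mer index to canonical slot."""
    keys = sorted(
        {min(km, km.translate(_COMP)[::-1]) for km in ("".join(p) for p in product("ACGT", repeat=4))}
    )
    slot = {k: i for i, k in enumerate(keys)}
    mapping = np.empty(256, dtype=np.int64)
    for idx, p in enumerate(product(range(4), repeat=4)):
        km = "".join("ACGT"[b] for b in p)
        mapping[idx] = slot[min(km, km.translate(_COMP)[::-1])]
    return keys, mapping


CANONICAL_4MERS, _CANON_OF_IDX = _canonical_map()


@dataclass
class TetraSignature:
    contig_id: str
    freqs: np.ndarray  # length 136, sums to 1


@dataclass
class GenomeBin:
    bin_id: str
    seed_contig_id: str
    member_contig_ids: list[str]
    completeness_pct: float | None = None
    mean_coverage: pd.Series | None = None


@dataclass
class ANIResult:
    genome_a: str
    genome_b: str
    ani_pct: float | None
    aligned_fraction: float
    same_species: bool


def tetra_signature(contig: Sequence, min_len: int = 2000) -> TetraSignature | None:
    """Canonical 4-mer frequency vector; None (with a warning) for contigs
    below the binning length floor. Windows containing N are skipped."""
    if len(contig) < min_len:
        warnings.warn(f"contig {contig.id} shorter than {min_len} bp; skipped from binning")
        return None
    c = contig.codes.astype(np.int64)
    idx = c[:-3] * 64 + c[1:-2] * 16 + c[2:-1] * 4 + c[3:]
    valid = (c[:-3] < 4) & (c[1:-2] < 4) & (c[2:-1] < 4) & (c[3:] < 4)
    counts256 = np.bincount(idx[valid], minlength=256)
    counts = np.zeros(136, dtype=np.float64)
    np.add.at(counts, _CANON_OF_IDX, counts256)
    total = counts.sum()
    if total == 0:
        warnings.warn(f"contig {contig.id} has no N-free 4-mers; skipped")
        return None
    return TetraSignature(contig.id, counts / total)


def recruit_bin(
    seed_contig_id: str,
    contigs: list[Sequence],
    signatures: dict[str, TetraSignature],
    coverage: pd.DataFrame,
    max_distance: float = 0.04,
    coverage_ratio_band: tuple[float, float] = (0.5, 2.0),
    bin_id: str | None = None,
) -> GenomeBin:
    """Recruit contigs whose signature lies within max_distance (Euclidean)
    of the seed's and whose coverage ratio to the seed stays inside
    coverage_ratio_band in every sample."""
    if seed_contig_id not in signatures:
        raise KeyError(f"unknown or unsigned seed contig {seed_contig_id!r}")
    cov = coverage.pivot(index="contig_id", columns="sample_id", values="mean_coverage")
    seed_sig = signatures[seed_contig_id].freqs
    seed_cov = cov.loc[seed_contig_id]
    lo, hi = coverage_ratio_band
    members = []
    for c in contigs:
        sig = signatures.get(c.id)
        if sig is None:
            continue
        if np.linalg.norm(sig.freqs - seed_sig) > max_distance:
            continue
        ratio = cov.loc[c.id] / seed_cov
        if ((ratio < lo) | (ratio > hi)).any():
            continue
        members.append(c.id)
    if seed_contig_id not in members:
        members.append(seed_contig_id)
    mean_cov = cov.loc[members].mean(axis=0)
    return GenomeBin(bin_id or f"bin_{seed_contig_id}", seed_contig_id, sorted(members), None, mean_cov)


def completeness(
    bin_: GenomeBin, marker_catalog: list[str], contigs: dict[str, Sequence]
) -> float:
    """Percent of catalog marker tokens found (either strand, exact) in the
    bin's member contigs."""
    if len(set(marker_catalog)) != len(marker_catalog):
        raise ValueError("duplicate entries in marker catalog")
    if not marker_catalog:
        raise ValueError("empty marker catalog")
    found = 0
    member_seqs = [
        (contigs[m].residues, reverse_complement(contigs[m]).residues)
        for m in bin_.member_contig_ids
        if m in contigs
    ]
    for token in marker_catalog:
        if any(token in fwd or token in rev for fwd, rev in member_seqs):
            found += 1
    return 100.0 * found / len(marker_catalog)


# ---------------------------------------------------------------------------
# k-mer seeded homologous-span extraction (shared by decontamination and ANI)


def _kmer_index(residues: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(residues) - k + 1):
        km = residues[i : i + k]
        if "N" not in km:
            idx.setdefault(km, []).append(i)
    return idx


def _diagonal_spans(query: str, ref_idx: dict[str, list[int]], k: int, band: int = 20):
    """Shared-k-mer seeds grouped into near-diagonal bands; yields spans
    (q0, q1, r0, r1) covering each band's seed extent."""
    seeds = []  # (diag, qpos, rpos)
    for i in range(len(query) - k + 1):
        for rp in ref_idx.get(query[i : i + k], ()):
            seeds.append((rp - i, i, rp))
    seeds.sort()
    spans = []
    group: list[tuple[int, int, int]] = []
    for s in seeds:
        if group and s[0] - group[-1][0] > band:
            spans.append(group)
            group = []
        group.append(s)
    if group:
        spans.append(group)
    out = []
    for g in spans:
        q0 = min(q for _, q, _ in g)
        q1 = max(q for _, q, _ in g) + k
        r0 = min(r for _, _, r in g)
        r1 = max(r for _, _, r in g) + k
        out.append((q0, q1, r0, r1))
    return out


def decontaminate_sag(
    sag_contigs: list[Sequence],
    reference_bin: list[Sequence],
    min_len: int = 250,
    min_identity: float = 75.0,
    seed_k: int = 12,
) -> tuple[list[Sequence], list[Sequence]]:
    """Split SAG contigs into (kept, flagged) by mapping against a reference
    bin: kept iff some k-mer-seeded span aligns over >= min_len columns at
    >= min_identity percent identity (either strand)."""
    if not reference_bin:
        raise ValueError("reference bin is empty")
    ref_indexes = [(r, _kmer_index(r.residues, seed_k)) for r in reference_bin]
    kept, flagged = [], []
    for sag in sag_contigs:
        hit = False
        for query in (sag, reverse_complement(sag)):
            if hit:
                break
            for ref, ridx in ref_indexes:
                if hit:
                    break
                for q0, q1, r0, r1 in _diagonal_spans(query.residues, ridx, seed_k):
                    if q1 - q0 < min_len:
                        continue
                    pid = global_identity(
                        Sequence("q", query.residues[q0:q1]), Sequence("r", ref.residues[r0:r1])
                    )
                    if pid.aligned_cols >= min_len and pid.identity_pct >= min_identity:
                        hit = True
                        break
        (kept if hit else flagged).append(sag)
    return kept, flagged


def _coding_fragments(genome: str, intervals: list[tuple[int, int]], fragment_len: int) -> list[str]:
    frags = []
    for s, e in intervals:
        for p in range(s, e - fragment_len + 1, fragment_len):
            frags.append(genome[p : p + fragment_len])
    return frags


def _best_fragment_hits(
    frags_a: list[str], frags_b: list[str], k: int, n_candidates: int = 2
) -> dict[int, tuple[int, float]]:
    """For each a-fragment, best b-fragment by alignment identity among the
    top shared-k-mer candidates (orientation decided by seed votes).
    Returns {ia: (ib, identity)}."""
    kmer_to_frag: dict[str, list[tuple[int, bool]]] = {}
    for ib, fb in enumerate(frags_b):
        rc = fb.translate(_COMP)[::-1]
        for s, is_rc in ((fb, False), (rc, True)):
            for i in range(0, len(s) - k + 1):
                kmer_to_frag.setdefault(s[i : i + k], []).append((ib, is_rc))
    hits: dict[int, tuple[int, float]] = {}
    for ia, fa in enumerate(frags_a):
        votes: dict[tuple[int, bool], int] = {}
        for i in range(0, len(fa) - k + 1, 4):  # stride 4: plenty for seeding
            for key in kmer_to_frag.get(fa[i : i + k], ()):
                votes[key] = votes.get(key, 0) + 1
        if not votes:
            continue
        cands = sorted(votes, key=lambda key: -votes[key])[:n_candidates]
        best = None
        for ib, is_rc in cands:
            target = Sequence("b", frags_b[ib])
            if is_rc:
                target = reverse_complement(target)
            ident = global_identity(Sequence("a", fa), target).identity_pct
            if best is None or ident > best[1]:
                best = (ib, ident)
        hits[ia] = best
    return hits


def ani(
    genome_a: str,
    intervals_a: list[tuple[int, int]],
    genome_b: str,
    intervals_b: list[tuple[int, int]],
    name_a: str = "a",
    name_b: str = "b",
    fragment_len: int = 1000,
    min_fragment_identity: float = 70.0,
    species_ani: float = 96.5,
    species_af: float = 0.6,
    seed_k: int = 14,
) -> ANIResult:
    """Coding-region ANI between two genomes (rRNA excluded upstream by the
    caller via the coding intervals)."""
    frags_a = _coding_fragments(genome_a, intervals_a, fragment_len)
    frags_b = _coding_fragments(genome_b, intervals_b, fragment_len)
    if not frags_a or not frags_b:
        return ANIResult(name_a, name_b, None, 0.0, False)
    ab = _best_fragment_hits(frags_a, frags_b, seed_k)
    ba = _best_fragment_hits(frags_b, frags_a, seed_k)
    pair_idents = []
    for ia, (ib, ident) in ab.items():
        if ident < min_fragment_identity:
            continue
        back = ba.get(ib)
        if back is not None and back[0] == ia and back[1] >= min_fragment_identity:
            pair_idents.append(ident)
    if not pair_idents:
        return ANIResult(name_a, name_b, None, 0.0, False)
    ani_pct = float(np.mean(pair_idents))
    af = 2.0 * len(pair_idents) / (len(frags_a) + len(frags_b))
    same = ani_pct >= species_ani and af >= species_af
    return ANIResult(name_a, name_b, ani_pct, af, same)
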