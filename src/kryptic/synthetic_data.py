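"""Synthetic metagenome communities with planted ground truth.

Each genome is sampled from its own order-3 Markov chain, which gives it a
distinct tetranucleotide signature — the premise that composition-based
recruitment exploits. Into each genome the generator plants, without
overlaps and never straddling a contig breakpoint:

* one SSU rRNA gene derived from a common template by i.i.d. substitutions
  at a per-lineage rate ``d`` (default 0.013, so two lineages diverged
  independently from the template have an expected pairwise identity of
  ~100*(1-d)^2 ~= 97.4%), on a random strand;
* optionally a CRISPR array (exact repeat copies interleaved with unique
  spacers, a configurable fraction of which are drawn from a pool shared
  across sites);
* 56 unique 30-bp marker tokens standing in for universal single-copy
  marker genes, for completeness accounting.

Per-sample genome abundances are lognormal; designated partner pairs share
a latent Gaussian factor through a copula calibrated so the *population*
Spearman correlation equals the requested value. Everything is
deterministic under the spec's RNG seed.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._alignment import markov_chain
from .seqcore import Sequence, reverse_complement, write_fasta

__all__ = [
    "CrisprSpec",
    "CommunitySpec",
    "PlantedTruth",
    "generate_community",
    "generate_correlated_abundances",
    "generate_hit_table",
    "write_community",
]

_BASES = "ACGT"


@dataclass
class CrisprSpec:
    repeat_length: int = 30
    n_spacers: int = 8
    spacer_length: int = 35
    shared_pool_fraction: float = 0.2
    shared_pool_size: int = 20
    n_sites: int = 4


@dataclass
class CommunitySpec:
    n_genomes: int = 5
    genome_length: int = 200_000
    ssu_template: Sequence | None = None
    ssu_length: int = 1200
    per_lineage_divergence: float = 0.013
    contig_length_range: tuple[int, int] = (5_000, 40_000)
    n_samples: int = 4
    coverage_log_mean: float = 3.4  # log-space mean; median coverage ~30x
    coverage_log_sigma: float = 1.0
    coverage_jitter_sigma: float = 0.1  # per contig x sample, log-space
    partner_pairs: list[tuple[int, int, float]] = field(default_factory=lambda: [(0, 1, 0.8)])
    crispr: CrisprSpec | None = field(default_factory=CrisprSpec)
    n_markers: int = 56
    marker_length: int = 30
    rng_seed: int = 42

    def __post_init__(self) -> None:
        if not 0 <= self.per_lineage_divergence < 0.5:
            raise ValueError("per_lineage_divergence must be in [0, 0.5)")
        lo, hi = self.contig_length_range
        if not 0 < lo <= hi:
            raise ValueError("invalid contig_length_range")
        if hi > self.genome_length:
            raise ValueError("contig_length_range exceeds genome_length")
        for _, _, rho in self.partner_pairs:
            if abs(rho) > 1:
                raise ValueError("target correlation must be in [-1, 1]")


@dataclass
class PlantedArray:
    contig_id: str
    start: int
    end: int
    repeat: str
    spacers: list[str]
    spacer_from_shared_pool: list[bool]


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside the synthetic assembly."""

    contig_to_genome: dict[str, str]
    genome_seqs: dict[str, str]
    contig_bounds: dict[str, tuple[str, int, int]]  # contig -> (genome, start, end)
    ssu: dict[str, tuple[str, int, int, str, str]]  # genome -> (contig, start, end, strand, seq)
    arrays: dict[str, PlantedArray]
    abundance: pd.DataFrame  # genomes x samples
    markers: dict[str, list[tuple[str, str, int]]]  # genome -> [(token, contig, start)]
    marker_catalog: dict[str, list[str]]
    site_of_genome: dict[str, str]
    module_presence: dict[str, set[str]]
    expected_complements: list[tuple[str, str, str]]  # (module_id, missing_in, complete_in)

    def coding_intervals(self, genome_id: str) -> list[tuple[int, int]]:
        """Genome coordinates with the rRNA gene excised (coding-only view,
        as ANI is computed on protein-coding regions with rRNA removed)."""
        length = len(self.genome_seqs[genome_id])
        if genome_id not in self.ssu:
            return [(0, length)]
        contig, s, e, _, _ = self.ssu[genome_id]
        _, cstart, _ = self.contig_bounds[contig]
        gs, ge = cstart + s, cstart + e
        out = []
        if gs > 0:
            out.append((0, gs))
        if ge < length:
            out.append((ge, length))
        return out


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, length))


def _mutate(residues: str, rate: float, rng: np.random.Generator) -> str:
    """i.i.d. substitutions at the given per-site rate (no indels)."""
    if rate <= 0:
        return residues
    arr = np.frombuffer(residues.encode(), np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def _genome_from_markov(rng: np.random.Generator, length: int) -> str:
    trans = rng.dirichlet(np.ones(4), size=64)
    cum = np.cumsum(trans, axis=1)
    start = int(rng.integers(0, 64))
    codes = markov_chain(cum, np.int64(start), rng.random(length))
    return "".join(_BASES[c] for c in codes)


def _cut_contigs(length: int, lo: int, hi: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    bounds = []
    pos = 0
    while pos < length:
        clen = int(rng.integers(lo, hi + 1))
        if length - pos - clen < lo:
            clen = length - pos
        bounds.append((pos, pos + clen))
        pos += clen
    return bounds


class _Placer:
    """Rejection-samples non-overlapping feature intervals inside contigs."""

    def __init__(self, bounds: list[tuple[int, int]], rng: np.random.Generator):
        self.bounds = bounds
        self.rng = rng
        self.occupied: list[list[tuple[int, int]]] = [[] for _ in bounds]

    def place(self, flen: int, margin: int = 50) -> tuple[int, int]:
        """Returns (contig_index, offset within contig)."""
        fits = [i for i, (s, e) in enumerate(self.bounds) if e - s >= flen + 2 * margin]
        if not fits:
            raise ValueError(f"no contig can host a feature of length {flen}")
        for _ in range(2000):
            ci = fits[self.rng.integers(0, len(fits))]
            s, e = self.bounds[ci]
            off = int(self.rng.integers(margin, e - s - flen - margin + 1))
            if all(off + flen <= a or off >= b for a, b in self.occupied[ci]):
                self.occupied[ci].append((off, off + flen))
                return ci, off
        raise ValueError("could not place feature without overlap")


def spearman_to_pearson_latent(rho_s: float) -> float:
    """Gaussian-copula latent Pearson correlation whose population Spearman
    equals rho_s (rho_p = 2 sin(pi * rho_s / 6))."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def generate_correlated_abundances(
    n_samples: int,
    target_rho: float,
    rng: np.random.Generator,
    log_mean: float = 3.4,
    log_sigma: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two lognormal abundance vectors with population Spearman target_rho."""
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    if abs(target_rho) > 1:
        raise ValueError("target_rho must be in [-1, 1]")
    rp = spearman_to_pearson_latent(target_rho)
    z1 = rng.standard_normal(n_samples)
    z2 = rp * z1 + math.sqrt(max(0.0, 1 - rp * rp)) * rng.standard_normal(n_samples)
    x = np.exp(log_mean + log_sigma * z1)
    y = np.exp(log_mean + log_sigma * z2)
    return x, y


# toy KEGG-style module definitions shipped as data (see data/modules_demo.tsv)
_DEMO_MODULES = {
    "M_HIS": [["K00765"], ["K01496"], ["K01814"], ["K02500", "K02501"], ["K01693"], ["K00817"], ["K00013"]],
    "M_THI": [["K03147"], ["K00788"], ["K00941"], ["K00878"], ["K03149"]],
    "M_BIO": [["K00652"], ["K00833"], ["K01935"], ["K01012"]],
    "M_NOS": [["K00376"]],
}


def _plant_modules(genome_ids: list[str], rng: np.random.Generator):
    """Assign ortholog presence per genome with a planted complementarity
    structure between the first two genomes."""
    presence: dict[str, set[str]] = {g: set() for g in genome_ids}
    expected: list[tuple[str, str, str]] = []
    g0, g1 = genome_ids[0], genome_ids[1]
    for mod, steps in _DEMO_MODULES.items():
        all_kos = [s[0] for s in steps]
        if mod in ("M_HIS", "M_NOS"):
            # complete in the partner, a step knocked out in the focal genome
            presence[g1].update(all_kos)
            presence[g0].update(all_kos[:-1])
            expected.append((mod, g0, g1))
        elif mod == "M_THI":
            presence[g0].update(all_kos)
            presence[g1].update(all_kos[1:])
            expected.append((mod, g1, g0))
        else:
            presence[g0].update(all_kos)
            presence[g1].update(all_kos)
        for g in genome_ids[2:]:
            keep = rng.random(len(all_kos)) < 0.5
            presence[g].update(k for k, f in zip(all_kos, keep) if f)
    return presence, expected


def generate_community(spec: CommunitySpec):
    """Generate (contigs, coverage table, PlantedTruth) for a community spec.

    Returns ``(contigs, coverage, truth)`` where *contigs* is a list of
    Sequence, *coverage* a long-format DataFrame (contig_id, sample_id,
    mean_coverage) and *truth* the planted ground truth.
    """
    rng = np.random.default_rng(spec.rng_seed)
    genome_ids = [f"g{i}" for i in range(spec.n_genomes)]
    template = spec.ssu_template or Sequence("ssu_template", _random_seq(rng, spec.ssu_length))

    # shared spacer pool across sites
    shared_pool: list[str] = []
    if spec.crispr is not None:
        shared_pool = [_random_seq(rng, spec.crispr.spacer_length) for _ in range(spec.crispr.shared_pool_size)]

    contigs: list[Sequence] = []
    contig_to_genome: dict[str, str] = {}
    contig_bounds: dict[str, tuple[str, int, int]] = {}
    genome_seqs: dict[str, str] = {}
    ssu_truth: dict[str, tuple[str, int, int, str, str]] = {}
    arrays: dict[str, PlantedArray] = {}
    markers: dict[str, list[tuple[str, str, int]]] = {}
    marker_catalog: dict[str, list[str]] = {}
    site_of_genome: dict[str, str] = {}
    all_tokens: set[str] = set()

    for gi, gid in enumerate(genome_ids):
        seq = list(_genome_from_markov(rng, spec.genome_length))
        bounds = _cut_contigs(spec.genome_length, *spec.contig_length_range, rng=rng)
        cids = [f"{gid}_c{ci}" for ci in range(len(bounds))]
        placer = _Placer(bounds, rng)
        if spec.crispr is not None:
            site_of_genome[gid] = f"site{gi % spec.crispr.n_sites}"
        else:
            site_of_genome[gid] = f"site{gi}"

        # SSU gene at per-lineage divergence, random strand
        ssu_seq = _mutate(template.residues, spec.per_lineage_divergence, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        planted = ssu_seq if strand == "+" else reverse_complement(Sequence("t", ssu_seq)).residues
        ci, off = placer.place(len(planted))
        gstart = bounds[ci][0] + off
        seq[gstart : gstart + len(planted)] = planted
        ssu_truth[gid] = (cids[ci], off, off + len(planted), strand, ssu_seq)

        # CRISPR array: exact repeats interleaved with spacers
        if spec.crispr is not None:
            cs = spec.crispr
            repeat = _random_seq(rng, cs.repeat_length)
            spacers, from_pool = [], []
            for _ in range(cs.n_spacers):
                if shared_pool and rng.random() < cs.shared_pool_fraction:
                    spacers.append(shared_pool[rng.integers(0, len(shared_pool))])
                    from_pool.append(True)
                else:
                    spacers.append(_random_seq(rng, cs.spacer_length))
                    from_pool.append(False)
            array_seq = repeat + "".join(sp + repeat for sp in spacers)
            ci, off = placer.place(len(array_seq))
            gstart = bounds[ci][0] + off
            seq[gstart : gstart + len(array_seq)] = array_seq
            arrays[gid] = PlantedArray(cids[ci], off, off + len(array_seq), repeat, spacers, from_pool)

        # unique marker tokens
        catalog, placed = [], []
        for mi in range(spec.n_markers):
            while True:
                tok = _random_seq(rng, spec.marker_length)
                if tok not in all_tokens:
                    all_tokens.add(tok)
                    break
            ci, off = placer.place(len(tok), margin=10)
            gstart = bounds[ci][0] + off
            seq[gstart : gstart + len(tok)] = tok
            catalog.append(tok)
            placed.append((tok, cids[ci], off))
        marker_catalog[gid] = catalog
        markers[gid] = placed

        genome = "".join(seq)
        genome_seqs[gid] = genome
        for cid, (s, e) in zip(cids, bounds):
            contigs.append(Sequence(cid, genome[s:e], f"genome={gid}"))
            contig_to_genome[cid] = gid
            contig_bounds[cid] = (gid, s, e)

    # lognormal abundances with copula-correlated partner pairs
    z = rng.standard_normal((spec.n_genomes, spec.n_samples))
    for i, j, rho in spec.partner_pairs:
        rp = spearman_to_pearson_latent(rho)
        z[j] = rp * z[i] + math.sqrt(max(0.0, 1 - rp * rp)) * z[j]
    abund = np.exp(spec.coverage_log_mean + spec.coverage_log_sigma * z)
    sample_ids = [f"s{k}" for k in range(spec.n_samples)]
    abundance = pd.DataFrame(abund, index=genome_ids, columns=sample_ids)

    rows = []
    for c in contigs:
        g = contig_to_genome[c.id]
        jit = np.exp(spec.coverage_jitter_sigma * rng.standard_normal(spec.n_samples))
        for s, sample in enumerate(sample_ids):
            rows.append((c.id, sample, float(abundance.loc[g, sample] * jit[s])))
    coverage = pd.DataFrame(rows, columns=["contig_id", "sample_id", "mean_coverage"])

    module_presence, expected_complements = _plant_modules(genome_ids, rng)
    truth = PlantedTruth(
        contig_to_genome=contig_to_genome,
        genome_seqs=genome_seqs,
        contig_bounds=contig_bounds,
        ssu=ssu_truth,
        arrays=arrays,
        abundance=abundance,
        markers=markers,
        marker_catalog=marker_catalog,
        site_of_genome=site_of_genome,
        module_presence=module_presence,
        expected_complements=expected_complements,
    )
    return contigs, coverage, truth


def generate_hit_table(rng: np.random.Generator, n_random: int = 100) -> pd.DataFrame:
    """Protein/nucleotide hit rows with known pass/fail labels.

    Rows deliberately straddle the screening rule boundaries: the >=30%
    identity / >=50% query-coverage protein rule and the >=250 bp /
    >=75% (97% for rRNA) genomic presence rule. ``protein_pass`` and
    ``genomic_pass`` are the planted labels.
    """
    taxa = ["Armatimonadetes", "Ignavibacteriae", "Chlorobi", "Bacteroidetes"]
    fixed = [
        # (identity, coverage, align_len, is_rrna, protein_pass, genomic_pass)
        (30.0, 50.0, 250, False, True, False),  # inclusive protein boundary
        (29.9, 90.0, 300, False, False, False),
        (35.0, 49.9, 300, False, False, False),
        (80.0, 60.0, 249, False, True, False),  # genomic length rule
        (74.9, 60.0, 400, False, True, False),
        (96.9, 60.0, 400, True, True, False),  # rRNA stricter identity
        (97.0, 60.0, 400, True, True, True),
        (75.0, 60.0, 250, False, True, True),  # inclusive genomic boundary
    ]
    rows = []
    for k, (ident, cov, alen, rrna, ppass, gpass) in enumerate(fixed):
        rows.append((f"q_fix{k}", f"s_fix{k}", taxa[k % len(taxa)], ident, cov, alen, rrna, ppass, gpass))
    for k in range(n_random):
        ppass = bool(rng.random() < 0.5)
        gpass = bool(rng.random() < 0.5)
        rrna = bool(rng.random() < 0.2)
        ident = float(rng.uniform(30, 100) if ppass else rng.uniform(0, 29.99))
        cov = float(rng.uniform(50, 100) if ppass else rng.uniform(0, 100))
        g_floor = 97.0 if rrna else 75.0
        if gpass:
            alen = int(rng.integers(250, 2000))
            ident_g = float(rng.uniform(g_floor, 100))
        else:
            if rng.random() < 0.5:
                alen = int(rng.integers(50, 250))
                ident_g = float(rng.uniform(g_floor, 100))
            else:
                alen = int(rng.integers(250, 2000))
                ident_g = float(rng.uniform(10, g_floor - 0.01))
        # protein and genomic rows are distinct screens; emit one row per screen
        rows.append((f"q_p{k}", f"s_p{k}", taxa[k % len(taxa)], ident, cov, int(rng.integers(100, 500)), False, ppass, None))
        rows.append((f"q_g{k}", f"s_g{k}", taxa[(k + 1) % len(taxa)], ident_g, float(rng.uniform(0, 100)), alen, rrna, None, gpass))
    return pd.DataFrame(
        rows,
        columns=["query_id", "subject_id", "subject_taxon", "identity_pct",
                 "query_coverage_pct", "align_len", "is_rrna", "protein_pass", "genomic_pass"],
    )


def write_community(spec: CommunitySpec, out_dir: str | Path) -> None:
    """Write contigs FASTA, coverage TSV, truth tables and a spec echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contigs, coverage, truth = generate_community(spec)
    write_fasta(contigs, out / "contigs.fasta")
    coverage.to_csv(out / "coverage.tsv", sep="\t", index=False)
    truth.abundance.to_csv(out / "true_abundance.tsv", sep="\t")
    with open(out / "truth_ssu.tsv", "w") as fh:
        fh.write("genome\tcontig_id\tstart\tend\tstrand\n")
        for g, (cid, s, e, strand, _) in truth.ssu.items():
            fh.write(f"{g}\t{cid}\t{s}\t{e}\t{strand}\n")
    echo = {f: str(getattr(spec, f)) for f in spec.__dataclass_fields__ if f != "ssu_template"}
    (out / "spec.json").write_text(json.dumps(echo, indent=2) + "\n")
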