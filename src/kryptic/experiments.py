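"""Parameter-recovery experiments on synthetic communities.

These are the library's own end-to-end checks — each plants a known
structure with the generator, runs the relevant pipeline stage, and
measures how well the planted parameter is recovered. They are shared by
the test suite and the reproduction script.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import binning, cooccurrence, crispr
from .seqcore import Sequence, global_identity
from .synthetic_data import (
    CommunitySpec,
    _mutate,
    _random_seq,
    generate_community,
    generate_correlated_abundances,
)

__all__ = [
    "within_lineage_identity",
    "bin_recovery",
    "ani_divergence_sweep",
    "partner_recovery",
    "crispr_false_positive_rate",
    "spacer_grouping_census",
]


def within_lineage_identity(
    n_pairs: int = 200, divergence: float = 0.013, template_len: int = 1200, seed: int = 0
) -> float:
    """Mean pairwise identity between SSU genes of two lineages each
    diverged from a common template at the given rate (expectation
    ~100*(1-d)^2, i.e. ~97.4% at d=0.013)."""
    rng = np.random.default_rng(seed)
    template = _random_seq(rng, template_len)
    idents = []
    for _ in range(n_pairs):
        a = Sequence("a", _mutate(template, divergence, rng))
        b = Sequence("b", _mutate(template, divergence, rng))
        idents.append(global_identity(a, b).identity_pct)
    return float(np.mean(idents))


def bin_recovery(spec: CommunitySpec | None = None) -> pd.DataFrame:
    """Recruit a bin for every genome of a synthetic community, seeded from
    its largest contig; returns per-genome precision/recall/F1 against the
    planted contig-to-genome map."""
    spec = spec or CommunitySpec()
    contigs, coverage, truth = generate_community(spec)
    sigs = {}
    for c in contigs:
        s = binning.tetra_signature(c)
        if s is not None:
            sigs[c.id] = s
    rows = []
    for g in truth.abundance.index:
        own = [c for c in contigs if truth.contig_to_genome[c.id] == g]
        seed_contig = max(own, key=len).id
        b = binning.recruit_bin(seed_contig, contigs, sigs, coverage)
        tp = sum(1 for m in b.member_contig_ids if truth.contig_to_genome[m] == g)
        n_true = sum(1 for c in own if c.id in sigs)
        prec = tp / len(b.member_contig_ids)
        rec = tp / n_true
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        rows.append((g, prec, rec, f1, len(b.member_contig_ids)))
    return pd.DataFrame(rows, columns=["genome", "precision", "recall", "f1", "n_members"]).set_index("genome")


def ani_divergence_sweep(
    rates=(0.005, 0.01, 0.02, 0.05), genome_len: int = 60_000, seed: int = 0
) -> pd.DataFrame:
    """ANI between a genome and mutated copies over a substitution-rate
    sweep; the closed-form expectation is 100*(1-p)."""
    rng = np.random.default_rng(seed)
    genome = _random_seq(rng, genome_len)
    rows = []
    for p in rates:
        mutant = _mutate(genome, p, rng)
        r = binning.ani(genome, [(0, genome_len)], mutant, [(0, genome_len)],
                        name_a="ref", name_b=f"p{p}")
        rows.append((p, r.ani_pct, r.aligned_fraction, r.same_species, 100 * (1 - p)))
    return pd.DataFrame(rows, columns=["rate", "ani_pct", "aligned_fraction", "same_species", "expected"])


def partner_recovery(
    n_replicates: int = 200,
    n_clusters: int = 30,
    n_samples: int = 22,
    rho: float = 0.8,
    seed: int = 0,
) -> dict:
    """Monte-Carlo partner-ranking experiment.

    Each replicate plants one partner cluster at population Spearman *rho*
    with a focal cluster among otherwise independent lognormal clusters,
    then asks whether the partner ranks first. The null arm repeats the
    experiment with no planted partner and records how often any cluster
    exceeds rho=0.6 with the focal.
    """
    rng = np.random.default_rng(seed)
    top1 = 0
    recovered = []
    for _ in range(n_replicates):
        focal, partner = generate_correlated_abundances(n_samples, rho, rng)
        others = np.exp(3.4 + rng.standard_normal((n_clusters - 2, n_samples)))
        ab = pd.DataFrame(
            np.vstack([focal, partner, others]),
            index=["focal", "partner"] + [f"c{i}" for i in range(n_clusters - 2)],
        )
        ranked = cooccurrence.rank_partners(cooccurrence.spearman_matrix(ab), "focal")
        top1 += ranked[0][0] == "partner"
        recovered.append(float(stats.spearmanr(focal, partner).statistic))
    null_exceed = 0
    for _ in range(n_replicates):
        ab = pd.DataFrame(
            np.exp(3.4 + rng.standard_normal((n_clusters, n_samples))),
            index=[f"c{i}" for i in range(n_clusters)],
        )
        best = cooccurrence.rank_partners(cooccurrence.spearman_matrix(ab), "c0")[0][1]
        null_exceed += best > 0.6
    return {
        "top1_rate": top1 / n_replicates,
        "mean_recovered_rho": float(np.mean(recovered)),
        "null_exceed_rate": null_exceed / n_replicates,
    }


def crispr_false_positive_rate(
    n_contigs: int = 100, contig_len: int = 100_000, seed: int = 0
) -> float:
    """Fraction of random (array-free) contigs on which the CRT-style
    detector reports any array."""
    rng = np.random.default_rng(seed)
    fp = 0
    for i in range(n_contigs):
        c = Sequence(f"rand{i}", _random_seq(rng, contig_len))
        fp += bool(crispr.detect_arrays(c))
    return fp / n_contigs


def spacer_grouping_census(
    n_seeds: int = 795, n_total: int = 1031, spacer_len: int = 35, seed: int = 0
) -> int:
    """Build a spacer table as n_seeds distinct random spacers plus
    duplicates/mutants within the 90% whole-length threshold (ids ordered so
    seeds found the centroids) and return the number of groups formed."""
    rng = np.random.default_rng(seed)
    seeds = [_random_seq(rng, spacer_len) for _ in range(n_seeds)]
    members = [
        crispr.SpacerMember(f"s{i:04d}", Sequence(f"s{i:04d}", s))
        for i, s in enumerate(seeds)
    ]
    max_mut = int(spacer_len * 0.1)  # stay within the 90% threshold
    extra = 0
    while len(members) < n_total:
        i = int(rng.integers(0, n_seeds))
        s = list(seeds[i])
        for p in rng.choice(spacer_len, int(rng.integers(0, max_mut + 1)), replace=False):
            s[p] = str(rng.choice([b for b in "ACGT" if b != s[p]]))
        members.append(crispr.SpacerMember(f"x{extra:04d}", Sequence(f"x{extra:04d}", "".join(s))))
        extra += 1
    return len(crispr.group_spacers(members, 90.0))
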