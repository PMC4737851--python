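"""SSU phylotype clustering, abundance and co-occurrence analysis.

Assembled SSU sequences (>= 300 nt) from many samples are clustered
together with reference sequences at a chosen identity cutoff (94/92/90 in
common use); clusters seen in at least two samples are retained. Cluster
abundance per sample is the sum over members of (sequence length x mean
coverage), zero where absent. Co-occurrence is tie-corrected Spearman rank
correlation across samples, and partner ranking orders other phylotypes by
their correlation with a focal cluster — the route by which a candidate
partner organism is nominated for a lineage of interest.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seqcore import Sequence, greedy_cluster

__all__ = [
    "SSUObservation",
    "PhylotypeCluster",
    "cluster_phylotypes",
    "abundance_matrix",
    "assign_lca_taxonomy",
    "spearman_matrix",
    "rank_partners",
]


@dataclass
class SSUObservation:
    """One assembled SSU sequence with its sample of origin and coverage."""

    seq: Sequence
    sample_id: str
    mean_coverage: float

    def __post_init__(self) -> None:
        if self.mean_coverage < 0:
            raise ValueError(f"negative coverage for {self.seq.id}")


@dataclass
class PhylotypeCluster:
    cluster_id: str
    members: list[SSUObservation]
    ref_ids: list[str]
    taxonomy_path: list[str] | None = None

    @property
    def n_samples(self) -> int:
        return len({m.sample_id for m in self.members})


def cluster_phylotypes(
    observations: list[SSUObservation],
    refs: list[Sequence],
    cutoff_pct: float = 90.0,
    min_length: int = 300,
    min_samples: int = 2,
) -> list[PhylotypeCluster]:
    """Cluster metagenome SSU sequences together with references at
    cutoff_pct; sequences < min_length nt are dropped beforehand and
    clusters observed in fewer than min_samples distinct samples are not
    retained."""
    if not 0 < cutoff_pct <= 100:
        raise ValueError("cutoff must be in (0, 100]")
    obs = [o for o in observations if len(o.seq) >= min_length]
    obs_by_id = {o.seq.id: o for o in obs}
    if len(obs_by_id) != len(obs):
        raise ValueError("duplicate SSU sequence ids")
    ref_ids = {r.id for r in refs}
    pool = [o.seq for o in obs] + [r for r in refs if len(r) >= min_length]
    clusters = []
    for cl in greedy_cluster(pool, cutoff_pct):
        members = [obs_by_id[m] for m in cl.member_ids if m in obs_by_id]
        crefs = [m for m in cl.member_ids if m in ref_ids]
        pc = PhylotypeCluster(cl.cluster_id, members, crefs)
        if pc.n_samples >= min_samples:
            clusters.append(pc)
    return clusters


def abundance_matrix(
    clusters: list[PhylotypeCluster], sample_ids: list[str] | None = None
) -> pd.DataFrame:
    """Clusters x samples abundance: sum over members of length x mean
    coverage; zero for absent cluster-sample pairs."""
    if sample_ids is None:
        sample_ids = sorted({m.sample_id for c in clusters for m in c.members})
    mat = pd.DataFrame(0.0, index=[c.cluster_id for c in clusters], columns=sample_ids)
    for c in clusters:
        for m in c.members:
            mat.loc[c.cluster_id, m.sample_id] += len(m.seq) * m.mean_coverage
    return mat


def assign_lca_taxonomy(
    cluster: PhylotypeCluster,
    refs: list[Sequence],
    taxonomy: dict[str, list[str]],
    broad_cutoff_pct: float = 83.0,
) -> list[str] | str:
    """Last-common-ancestor taxonomy for a phylotype cluster.

    If the cluster contains references, the LCA of their paths; otherwise
    members are co-clustered with the references at the broad cutoff and
    the LCA of references landing in the same broad cluster is used; with
    no reference within reach the cluster is "unassigned".
    """
    depths = {len(p) for p in taxonomy.values()}
    if len(depths) > 1:
        raise ValueError("reference taxonomy paths have inconsistent rank depth")

    def lca(paths: list[list[str]]) -> list[str]:
        out = []
        for level in zip(*paths):
            if len(set(level)) == 1:
                out.append(level[0])
            else:
                break
        return out

    if cluster.ref_ids:
        return lca([taxonomy[r] for r in cluster.ref_ids])
    pool = [m.seq for m in cluster.members] + list(refs)
    member_ids = {m.seq.id for m in cluster.members}
    for cl in greedy_cluster(pool, broad_cutoff_pct):
        ids = set(cl.member_ids)
        if ids & member_ids:
            hit_refs = [r for r in ids if r in taxonomy]
            if hit_refs:
                return lca([taxonomy[r] for r in hit_refs])
    return "unassigned"


def spearman_matrix(abundance: pd.DataFrame) -> pd.DataFrame:
    """Tie-corrected Spearman correlation between cluster abundance rows.

    Pairs involving a constant vector have undefined rank correlation and
    are reported as missing (NaN), not zero; the diagonal is 1 by
    convention.
    """
    if abundance.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    n = len(abundance)
    if n == 1:
        rho = np.array([[1.0]])
    else:
        import warnings

        with warnings.catch_warnings():
            # constant rows yield NaN by design (reported as missing)
            warnings.simplefilter("ignore", stats.ConstantInputWarning)
            rho = stats.spearmanr(abundance.values, axis=1).statistic
        if n == 2:
            r = float(rho)
            rho = np.array([[1.0, r], [r, 1.0]])
    out = pd.DataFrame(rho, index=abundance.index, columns=abundance.index)
    np.fill_diagonal(out.values, 1.0)
    return out


def rank_partners(corr: pd.DataFrame, focal_cluster: str) -> list[tuple[str, float]]:
    """Partners of the focal cluster sorted by correlation, descending;
    ties broken by cluster id; missing correlations ranked last."""
    if focal_cluster not in corr.index:
        raise KeyError(f"unknown focal cluster {focal_cluster!r}")
    col = corr.loc[focal_cluster].drop(focal_cluster)
    entries = sorted(
        col.items(), key=lambda kv: (np.isnan(kv[1]), -(kv[1] if not np.isnan(kv[1]) else 0), kv[0])
    )
    return [(cid, float(v)) for cid, v in entries]
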