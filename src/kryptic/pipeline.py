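"""End-to-end orchestration of the discovery pipeline on a synthetic
community: simulate -> SSU screen -> binning -> CRISPR -> co-occurrence ->
complementarity screens, with a provenance manifest and deterministic
outputs under a fixed seed."""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, binning, cooccurrence, crispr, screens_complement, ssu_screen
from .seqcore import Sequence, read_fasta, write_fasta
from .synthetic_data import (
    CommunitySpec,
    _mutate,
    _random_seq,
    generate_community,
    generate_hit_table,
)

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with their defaults.

    Defaults mirror the screening conventions the stages are built around:
    100 kbp contig floor and >100 bp SSU fragments for discovery, rank
    novelty thresholds from SSU identity, 90% spacer grouping with <=3
    mismatch proto-spacer matching, 94/92/90 phylotype cutoffs with an 83%
    LCA fallback, and the >=30/50 and >=250/75/97 tabular rules.
    """

    rng_seed: int = 42
    # community
    n_genomes: int = 5
    genome_length: int = 200_000
    contig_length_range: tuple[int, int] = (5_000, 40_000)
    n_samples: int = 4
    per_lineage_divergence: float = 0.013
    partner_rho: float = 0.8
    # ssu screen
    min_contig_len: int = 100_000
    min_frag_len: int = 100
    refdb_divergence: float = 0.17
    # binning
    tetra_max_distance: float = 0.04
    coverage_ratio_band: tuple[float, float] = (0.5, 2.0)
    # crispr
    spacer_group_threshold: float = 90.0
    max_spacer_mismatches: int = 3
    # cooccurrence
    phylotype_cutoff: float = 90.0
    broad_cutoff: float = 83.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("contig_length_range", "coverage_ratio_band"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def validate_inputs(
    contigs_path: str | Path | None = None,
    coverage_path: str | Path | None = None,
    taxonomy_path: str | Path | None = None,
) -> dict:
    """Cross-check input files; returns {'errors': [...], 'warnings': [...]}."""
    errors: list[str] = []
    warnings_: list[str] = []
    contig_ids: set[str] = set()
    if contigs_path is not None:
        try:
            contig_ids = {s.id for s in read_fasta(contigs_path)}
        except Exception as exc:  # malformed FASTA, unreadable file
            errors.append(f"{contigs_path}: {exc}")
    if coverage_path is not None:
        try:
            cov = pd.read_csv(coverage_path, sep="\t")
            missing_cols = {"contig_id", "sample_id", "mean_coverage"} - set(cov.columns)
            if missing_cols:
                errors.append(f"{coverage_path}: missing columns {sorted(missing_cols)}")
            elif contig_ids:
                for cid in cov.loc[~cov["contig_id"].isin(contig_ids), "contig_id"].unique():
                    warnings_.append(f"coverage row references missing contig {cid!r}")
        except Exception as exc:
            errors.append(f"{coverage_path}: {exc}")
    if taxonomy_path is not None:
        try:
            tax = pd.read_csv(taxonomy_path, sep="\t")
            depths = tax.iloc[:, 1].astype(str).str.split(";").map(len).unique()
            if len(depths) > 1:
                warnings_.append("taxonomy paths have inconsistent rank depth")
        except Exception as exc:
            errors.append(f"{taxonomy_path}: {exc}")
    return {"errors": errors, "warnings": warnings_}


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run all stages in dependency order; writes stage outputs plus a
    provenance manifest to out_dir and returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.rng_seed,
        "stages": {},
    }
    try:
        _run_stages(config, out, manifest)
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        _write_manifest(manifest, out)
        raise
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _run_stages(cfg: PipelineConfig, out: Path, manifest: dict) -> None:
    rng = np.random.default_rng(cfg.rng_seed)

    # --- simulate ------------------------------------------------------
    spec = CommunitySpec(
        n_genomes=cfg.n_genomes,
        genome_length=cfg.genome_length,
        contig_length_range=cfg.contig_length_range,
        n_samples=cfg.n_samples,
        per_lineage_divergence=cfg.per_lineage_divergence,
        partner_pairs=[(0, 1, cfg.partner_rho)] if cfg.n_genomes >= 2 else [],
        rng_seed=cfg.rng_seed,
    )
    contigs, coverage, truth = generate_community(spec)
    write_fasta(contigs, out / "contigs.fasta")
    coverage.to_csv(out / "coverage.tsv", sep="\t", index=False)
    manifest["stages"]["simulate"] = {"status": "completed", "rows": len(contigs)}
    contig_by_id = {c.id: c for c in contigs}

    # --- ssu screen ----------------------------------------------------
    template = truth.ssu[next(iter(truth.ssu))][4] if truth.ssu else None
    refdb = [
        Sequence("ref_relative", _mutate(template, cfg.refdb_divergence, rng)),
        *[Sequence(f"ref_decoy{i}", _random_seq(rng, len(template))) for i in range(3)],
    ]
    fragments = ssu_screen.find_ssu_fragments(
        contigs, refdb, min_contig_len=cfg.min_contig_len, min_frag_len=cfg.min_frag_len
    )
    frag_rows = []
    for f in fragments:
        call = ssu_screen.classify_novelty(f)
        frag_rows.append(
            (f.contig_id, f.start, f.end, f.strand, round(f.best_identity_pct, 2), f.best_ref_id, call.novel_rank)
        )
    pd.DataFrame(
        frag_rows,
        columns=["contig_id", "start", "end", "strand", "best_identity_pct", "best_ref_id", "novel_rank"],
    ).to_csv(out / "ssu_fragments.tsv", sep="\t", index=False)
    manifest["stages"]["ssu_screen"] = {"status": "completed", "rows": len(frag_rows)}

    # --- binning (seeded from SSU-bearing contigs) ---------------------
    if fragments:
        sigs = {}
        for c in contigs:
            s = binning.tetra_signature(c)
            if s is not None:
                sigs[c.id] = s
        bin_rows = []
        for f in fragments:
            if f.contig_id not in sigs:
                continue
            b = binning.recruit_bin(
                f.contig_id, contigs, sigs, coverage,
                max_distance=cfg.tetra_max_distance,
                coverage_ratio_band=cfg.coverage_ratio_band,
            )
            g = truth.contig_to_genome[f.contig_id]
            b.completeness_pct = binning.completeness(b, truth.marker_catalog[g], contig_by_id)
            for m in b.member_contig_ids:
                bin_rows.append((b.bin_id, b.seed_contig_id, m, round(b.completeness_pct, 2)))
        pd.DataFrame(
            bin_rows, columns=["bin_id", "seed_contig_id", "member_contig_id", "completeness_pct"]
        ).to_csv(out / "bins.tsv", sep="\t", index=False)
        manifest["stages"]["binning"] = {"status": "completed", "rows": len(bin_rows)}
    else:
        manifest["stages"]["binning"] = {"status": "skipped", "rows": 0}

    # --- crispr --------------------------------------------------------
    arrays: list[crispr.CrisprArray] = []
    for c in contigs:
        for a in crispr.detect_arrays(c):
            a.source_site = truth.site_of_genome[truth.contig_to_genome[c.id]]
            arrays.append(a)
    trusted = crispr.curate_spacers(arrays)
    members = [
        crispr.SpacerMember(
            sp.id, sp,
            source_genome=truth.contig_to_genome[arr.contig_id],
            source_site=arr.source_site,
            contig_id=arr.contig_id,
            array_start=arr.start,
            array_end=arr.end,
        )
        for arr, sp in trusted
    ]
    groups = crispr.group_spacers(members, cfg.spacer_group_threshold)
    contig_db = {}
    for c in contigs:
        site = truth.site_of_genome[truth.contig_to_genome[c.id]]
        contig_db.setdefault(site, []).append(c)
    hits = crispr.match_protospacers(groups, contig_db, max_mismatches=cfg.max_spacer_mismatches)
    network = crispr.sharing_network(groups, hits)
    network.to_csv(out / "spacer_sharing.tsv", sep="\t")
    pd.DataFrame(
        [(g.group_id, len(g.members), ";".join(sorted(g.sites))) for g in groups],
        columns=["group_id", "n_members", "sites"],
    ).to_csv(out / "spacer_groups.tsv", sep="\t", index=False)
    manifest["stages"]["crispr"] = {"status": "completed", "rows": len(groups)}

    # --- cooccurrence --------------------------------------------------
    if fragments:
        observations = []
        for g, (cid, s, e, strand, seq) in truth.ssu.items():
            for sample in truth.abundance.columns:
                observations.append(
                    cooccurrence.SSUObservation(
                        Sequence(f"{g}_{sample}_ssu", seq), sample,
                        float(truth.abundance.loc[g, sample]),
                    )
                )
        clusters = cooccurrence.cluster_phylotypes(observations, refdb, cfg.phylotype_cutoff)
        ab = cooccurrence.abundance_matrix(clusters, list(truth.abundance.columns))
        ab.to_csv(out / "phylotype_abundance.tsv", sep="\t")
        if len(ab) >= 2 and ab.shape[1] >= 3:
            corr = cooccurrence.spearman_matrix(ab)
            corr.to_csv(out / "phylotype_spearman.tsv", sep="\t")
            focal = ab.index[0]
            partners = cooccurrence.rank_partners(corr, focal)
            (out / "partners.json").write_text(
                json.dumps({"focal": focal, "partners": partners}, indent=2) + "\n"
            )
        manifest["stages"]["cooccurrence"] = {"status": "completed", "rows": len(clusters)}
    else:
        manifest["stages"]["cooccurrence"] = {"status": "skipped", "rows": 0}

    # --- screens & complementarity ------------------------------------
    hit_table = generate_hit_table(rng)
    labels, freq = screens_complement.best_hit_taxonomy(hit_table)
    freq.to_csv(out / "proteome_taxon_freq.tsv", sep="\t")
    presence = screens_complement.presence_filter(hit_table.assign(sample_id="s0"))
    presence.to_csv(out / "presence.tsv", sep="\t")
    defs = screens_complement.load_module_definitions()
    genome_ids = list(truth.abundance.index)
    calls, joint = screens_complement.complement_calls(
        truth.module_presence[genome_ids[0]],
        truth.module_presence[genome_ids[1]],
        defs,
        name_a=genome_ids[0],
        name_b=genome_ids[1],
    )
    pd.DataFrame(
        [(c.module_id, c.missing_in, c.complete_in, ",".join(map(str, c.missing_steps))) for c in calls],
        columns=["module_id", "missing_in", "complete_in", "missing_steps"],
    ).to_csv(out / "complement_calls.tsv", sep="\t", index=False)
    manifest["stages"]["screens_complement"] = {"status": "completed", "rows": len(calls)}
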