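"""Tabular rule screens: best-hit taxonomy, presence filters, metabolic
complementarity.

Three pure-function stages over hit/annotation tables. All thresholds are
inclusive (>=): a protein query is attributed to the phylum of its best
qualifying hit at >= 30% identity over >= 50% of the query; a sample is
marked as containing the lineage when at least one genomic hit survives
the >= 250 bp length and >= 75% identity filter (97% for rRNA rows); and a
KEGG-style module is complete when every step has at least one ortholog
alternative present, from which between-genome complementarity calls are
derived.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "ModuleDefinition",
    "ComplementCall",
    "best_hit_taxonomy",
    "presence_filter",
    "module_completeness",
    "complement_calls",
    "load_module_definitions",
]


@dataclass(frozen=True)
class ModuleDefinition:
    module_id: str
    name: str
    required_steps: tuple[frozenset, ...]  # alternatives per step

    def __post_init__(self) -> None:
        if not self.required_steps or any(not s for s in self.required_steps):
            raise ValueError(f"module {self.module_id} has empty steps")


@dataclass(frozen=True)
class ComplementCall:
    module_id: str
    missing_in: str
    complete_in: str
    missing_steps: tuple[int, ...]


def best_hit_taxonomy(
    hits: pd.DataFrame,
    min_identity: float = 30.0,
    min_query_cov: float = 50.0,
) -> tuple[pd.Series, pd.Series]:
    """Per-query best-hit taxon attribution.

    Rows qualify at identity >= min_identity and query coverage >=
    min_query_cov; the best row per query maximizes identity x coverage
    (ties by subject_id); queries without a qualifying row are "no match".
    Returns (per-query taxon Series, taxon frequency table).
    """
    df = hits.copy()
    ok = (df["identity_pct"] >= min_identity) & (df["query_coverage_pct"] >= min_query_cov)
    df = df[ok]
    df = df.assign(score=df["identity_pct"] * df["query_coverage_pct"])
    df = df.sort_values(["score", "subject_id"], ascending=[False, True], kind="mergesort")
    best = df.groupby("query_id", sort=True).first()["subject_taxon"]
    labels = pd.Series("no match", index=pd.Index(sorted(hits["query_id"].unique()), name="query_id"))
    labels.loc[best.index] = best
    return labels, labels.value_counts()


def presence_filter(
    hits: pd.DataFrame,
    min_len: int = 250,
    min_identity: float = 75.0,
    rrna_min_identity: float = 97.0,
) -> pd.DataFrame:
    """Per-sample presence from genomic hit rows.

    A row survives iff align_len >= min_len and identity >= (rrna_min_identity
    for rRNA rows else min_identity). Returns a per-sample table with the
    surviving row count and a presence flag. Expects a ``sample_id`` column
    (a single implicit sample if absent).
    """
    df = hits.copy()
    if "sample_id" not in df.columns:
        df["sample_id"] = "sample"
    floor = df["is_rrna"].map(lambda r: rrna_min_identity if r else min_identity)
    survives = (df["align_len"] >= min_len) & (df["identity_pct"] >= floor)
    counts = survives.groupby(df["sample_id"]).sum().astype(int)
    out = pd.DataFrame({"surviving_rows": counts})
    out["present"] = out["surviving_rows"] >= 1
    return out


def module_completeness(
    orthologs: set[str], definitions: list[ModuleDefinition]
) -> pd.DataFrame:
    """Fraction of satisfied steps per module (a step is satisfied when any
    alternative ortholog is present) and a completeness flag."""
    if not definitions:
        raise ValueError("no module definitions supplied")
    rows = []
    for d in definitions:
        satisfied = sum(1 for step in d.required_steps if step & orthologs)
        frac = satisfied / len(d.required_steps)
        rows.append((d.module_id, d.name, frac, frac == 1.0))
    return pd.DataFrame(rows, columns=["module_id", "name", "fraction", "complete"]).set_index("module_id")


def complement_calls(
    orthologs_a: set[str],
    orthologs_b: set[str],
    definitions: list[ModuleDefinition],
    name_a: str = "A",
    name_b: str = "B",
) -> tuple[list[ComplementCall], list[str]]:
    """Modules incomplete in one genome and complete in the other (both
    directions), plus modules completable only jointly (complete in the
    union of ortholog sets but in neither genome alone)."""
    calls: list[ComplementCall] = []
    joint: list[str] = []
    for d in definitions:
        sat_a = [bool(step & orthologs_a) for step in d.required_steps]
        sat_b = [bool(step & orthologs_b) for step in d.required_steps]
        sat_u = [bool(step & (orthologs_a | orthologs_b)) for step in d.required_steps]
        comp_a, comp_b = all(sat_a), all(sat_b)
        if not comp_a and comp_b:
            calls.append(
                ComplementCall(d.module_id, name_a, name_b,
                               tuple(i for i, s in enumerate(sat_a) if not s))
            )
        elif not comp_b and comp_a:
            calls.append(
                ComplementCall(d.module_id, name_b, name_a,
                               tuple(i for i, s in enumerate(sat_b) if not s))
            )
        elif not comp_a and not comp_b and all(sat_u):
            joint.append(d.module_id)
    return calls, joint


def load_module_definitions(path: str | Path | None = None) -> list[ModuleDefinition]:
    """Load module definitions from TSV (module_id, name, step_index,
    comma-separated ortholog alternatives); defaults to the shipped demo set
    of toy biosynthesis modules."""
    if path is None:
        src = resources.files("kryptic").joinpath("data/modules_demo.tsv")
        df = pd.read_csv(src, sep="\t")  # type: ignore[arg-type]
    else:
        df = pd.read_csv(path, sep="\t")
    defs = []
    for (mid, name), grp in df.groupby(["module_id", "name"], sort=True):
        steps = tuple(
            frozenset(str(alts).split(","))
            for _, alts in grp.sort_values("step_index")["alternatives"].items()
        )
        defs.append(ModuleDefinition(str(mid), str(name), steps))
    return defs
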