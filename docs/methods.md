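# Methods

`kryptic` re-creates, on synthetic communities with planted ground truth,
the computational route by which a deeply divergent bacterial lineage can
be discovered and characterized from assembled metagenomes: SSU rRNA
screening of long contigs with identity-based novelty calls and
primer/probe auditing, tetranucleotide-signature genome recruitment with
ANI species delineation, CRISPR repeat-spacer detection with proto-spacer
biogeography, SSU phylotype co-occurrence, and tabular metabolic screens.
This note records the models, the tunable parameters, and the design
choices made where the procedure was genuinely open.

## Sequence identity

Every "% identity" in the pipeline reduces to one definition: a global
Needleman–Wunsch alignment with match +1, mismatch −1, gap −1 (linear),
N never matching anything; identity = 100 × matches / aligned columns,
where terminal gap runs are excluded from the denominator and internal
gaps count as mismatching columns. This matches common usearch-style
semantics. The scheme is deliberately minimal so that an exhaustive
dynamic-programming oracle can reproduce it column for column; the test
suite does exactly that.

Three non-obvious choices, and why:

* **Terminal gaps are penalized in scoring but excluded from identity.**
  A true overlap (end-gap-free) alignment is pathological for unrelated
  pairs: a short spurious corner overlap outscores the negative-scoring
  full alignment and reports ~100% identity, which would collapse greedy
  clustering at high thresholds. Penalizing end gaps forces unrelated
  pairs to align end to end and score ~50%, while the identity
  denominator still ignores pure length differences.
* **Among score-optimal alignments, matches are maximized, and on
  remaining ties the traceback prefers gap moves.** Optional gap runs
  then land at the alignment ends, where they are trimmed: a fragment
  wholly contained in a longer sequence scores ~100% identity instead of
  being punished for its missing length — the behaviour fragment
  clustering and reference co-clustering need.
* **The pair is aligned in canonical order** (shorter sequence first,
  ties broken lexicographically) because tie resolution depends on which
  sequence indexes the DP rows; this makes identity exactly symmetric.

Region *extraction* — finding where a reference gene sits inside a padded
candidate window — uses local (Smith–Waterman) alignment with the same
scores. Overlap or global alignment cannot stop a match mid-matrix when
unaligned sequence remains on both sides, and drags flanking sequence
into the core; the local optimum recovers planted feature boundaries
exactly except when a terminal base of the feature is itself mutated (it
is then trimmed, shifting a coordinate by a base or two).

Spacer grouping uses a stricter flavour, *whole-length identity*:
matches divided by the full (longer) spacer length, so the ≥90% grouping
threshold really spans the entire spacer.

The bounded-mismatch scan (proto-spacer matching, probe/primer sites) is
a full-length ungapped Hamming scan of the query and its reverse
complement over every subject window; N counts as a mismatch.

## Synthetic communities

The generator's defaults are the study conditions the tests measure
against:

| parameter | default | meaning |
|---|---|---|
| `n_genomes` × `genome_length` | 5 × 200 kbp | community size |
| order-3 Markov chain per genome | Dirichlet(1) rows | distinct tetranucleotide signatures |
| `per_lineage_divergence` d | 0.013 | SSU substitutions/site from the common template; two lineages then share ≈100(1−d)² ≈ 97.4% identity |
| `contig_length_range` | 5–40 kbp | fragmentation of each genome |
| `n_samples` | 4 (22 in co-occurrence experiments) | coverage columns |
| coverage model | lognormal, log-mean 3.4, σ 1.0 | median ≈30× per-genome abundance |
| `partner_pairs` | (g0, g1, ρ=0.8) | planted Spearman co-occurrence |
| CRISPR | repeat 30 bp × 9, spacers 8 × 35 bp, 20% from a pool shared across 4 sites | spacer biogeography |
| markers | 56 unique 30-bp tokens per genome | completeness accounting |

Correlated abundances use a Gaussian copula with latent Pearson
ρ_p = 2·sin(πρ_s/6), so the *population* Spearman equals the target;
lognormal marginals are irrelevant to rank statistics. Divergence is
i.i.d. substitution only — no indels — so expected identity has the
closed form used by the tests. Features are planted inside contigs
(never across breakpoints), non-overlapping, SSU on a random strand.

What the generator does **not** emulate: sequencing error, chimeras,
assembly artifacts, strain microdiversity, indel divergence, rRNA operon
copy number, or compositionally similar genomes (unless constructed
deliberately — one test documents that identical Markov parameters are a
confusion mode for binning). Passing tests therefore demonstrate the
*logic* of each stage at realistic signal strengths, not robustness to
every failure mode of real assemblies.

The 56 marker "genes" are exact unique tokens rather than HMM-detectable
proteins: completeness arithmetic is exercised without profile search,
which is outside this package's scope.

## Stage-specific choices

**SSU screen.** Contigs ≥100 kbp are scanned (strictly >100 bp fragments
kept) by shared 12-mer seeding against the reference set, local-alignment
verification, and a permissive 60% identity floor so that even
phylum-level novelty (≈75–83% to references) is retained. Novelty calls
use rank thresholds {species 98.7, genus 94.5, family 86.5, order 82.0,
class 78.5, phylum 75.0}: the reported rank is the one with the smallest
threshold still above the best reference identity. This is
identity-consistent novelty only — no tree placement. Primer audits take
the IUPAC-aware minimum mismatch count over all full-length placements on
both strands; probe specificity requires a 0-mismatch site in targets and
≥2 mismatches everywhere in non-targets.

**Binning.** Signatures are frequencies over the 136 canonical 4-mers
(4-mer pooled with its reverse complement), computed on contigs ≥2 kbp.
Recruitment requires Euclidean signature distance ≤0.04 to the seed *and*
per-sample coverage ratio within 0.5–2.0×. The distance default sits
between the observed within-genome (≤0.02) and between-genome (≥0.07)
distances under the default generator; both knobs are configurable. SAG
decontamination maps contigs by 12-mer diagonal-band seeding and keeps a
contig with any ≥250-column alignment at ≥75% identity. ANI cuts coding
regions (rRNA excised) into 1-kb fragments, maps them by 14-mer voting
(orientation-aware), and averages identity over reciprocal best pairs at
≥70% identity; aligned fraction is 2·pairs/(fragments_a + fragments_b);
same-species at ANI ≥96.5% and AF ≥0.6.

**CRISPR.** Detection chains exact 8-mer seeds recurring at 36–96 bp
periods (repeat 19–48, spacer 17–48, ≥3 copies), extends repeat
boundaries while all copies agree, and validates lengths and per-copy
mismatch (≤1). A seed recurring *closer* than the minimum period marks a
tandem repeat and aborts the chain. All candidate arrays are collected
and maximal non-overlapping ones kept (most repeats, then longest span) —
first-hit acceptance can otherwise be pre-empted by a seed one base into
the flank chaining a truncated subset of copies. Curation (the automated
stand-in for manual review) drops arrays whose spacers resemble each
other (mean pairwise *ungapped* identity >60%; random 35-mers score ~25%
on this statistic, repeat copies ~100%), spacers with N or ≥10-bp
homopolymer runs, and arrays left with <2 spacers. Grouping is greedy
clustering at ≥90% whole-length identity (a 95% switch exists, as both
conventions circulate). Proto-spacer matching allows ≤3 mismatches over
the whole spacer on either strand and excludes hits inside the source
array. Cas typing consumes pre-labelled annotations: genes within 5 kb
merge into loci; I-B requires {cas8b, cas7, cas5}, III-A {cas10,
csm2–csm5}; a locus containing both complete sets is a type I/III fusion.

**Co-occurrence.** SSU sequences ≥300 nt are clustered with references
at 94/92/90% (default 90); clusters seen in ≥2 samples are retained.
Abundance is Σ(length × mean coverage) per sample, zero when absent —
the zeros motivate tie-corrected Spearman (average ranks). Correlations
of constant vectors are reported missing, never imputed as zero.
Taxonomy is the last common ancestor of reference paths in the cluster,
falling back to co-clustering at 83% identity; otherwise "unassigned".
Partner ranking sorts by ρ descending, ties by cluster id, missing last.

**Screens.** All thresholds are inclusive (≥). Best-hit attribution
scores rows by identity × coverage with subject-id tie-breaks, after
filtering at ≥30% identity and ≥50% query coverage; unmatched queries are
"no match". Presence requires one surviving row at ≥250 bp and ≥75%
identity (97% for rRNA rows). Module completeness treats each step as
satisfied by any listed ortholog alternative; complementarity calls are
directional (incomplete in one genome, complete in the other), with
jointly-completable modules reported separately. Module definitions ship
as data (a small demo set of biosynthesis modules), not code.

## Numerical and degenerate-input conventions

Coordinates are 0-based, half-open, forward-strand throughout. Greedy
clustering processes sequences longest-first with lexicographic id
tie-breaks, joining the first centroid at or above threshold — a
deterministic stand-in for UCLUST's unspecified order. Empty inputs
yield empty outputs where the operation is a filter, and errors where a
result would be undefined (empty reference sets, empty marker catalogs,
<3 samples for correlation). Everything downstream of a seed is
deterministic: the pipeline rerun with the same configuration produces
byte-identical outputs, hashed into the manifest.

## Problem sizes

The shipped experiments use 200-kbp genomes (five per community), 50-kbp
genomes for ANI sweeps, 1,200-bp SSU templates, 200 replicate pairs for
divergence recovery, 200 Monte-Carlo replicates (30 clusters × 22
samples) for partner recovery, 100 random 100-kbp contigs for the CRISPR
false-positive experiment, and a 1,031-spacer table for the grouping
census. These sizes were chosen so every recovered statistic has tight
Monte-Carlo error while a full run stays in the tens of seconds.

## Known limitations

* One marginal check is expected to fail by construction: with 22
  samples and 29 independent null comparisons, the probability that the
  best null Spearman exceeds 0.6 is ≈5.8%, so demanding "never above 0.6
  in ≥95% of replicates" sits just past what the null itself delivers.
  The experiment reports the measured rate rather than adjusting it.
* Exact planted-coordinate recovery of SSU fragments assumes the
  feature's terminal bases are unmutated; otherwise the local alignment
  trims them (a 1–2 bp shift). CRISPR coordinates are exact because
  planted repeats are exact copies.
* HMM-based gene detection, tree inference and placement, read
  simulation, assembly, and PAM prediction are all out of scope; where
  the original workflow used them, this package consumes labelled
  annotations or pre-assembled sequence instead.
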