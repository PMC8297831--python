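# Methods

## Model and procedure

The pipeline treats a dataset as a set of contigs (genomes), each carrying
ordered gene calls with protein sequences, plus three optional evidence
tables: domain hits (HMMER `domtblout` or a plain TSV), pairwise homology
hits (tabular BLAST, `outfmt6`) and per-protein best-hit taxonomy.

**ATPase calling.** Two evidence modes, combinable:

- *Domain-table mode.* A hit qualifies when its e-value is ≤ 10⁻³ and its
  name or accession contains `ATP` or `AAA` (case-insensitive substring).
  A protein's domain count is its number of qualifying hits; ≥ 2 makes it a
  multi-ATPase protein.
- *Motif mode.* The Walker-A P-loop `GxxGxGK(T/S)` is scanned with an
  overlapping regex (every window is reported, 1-based positions). The
  Walker-B `hhhhD` with h ∈ {V, I, L, F, M} is searched in a spacing window
  of 60–140 residues after the Walker-A end, around the canonical ~100-residue
  linker. Walker-A is required; Walker-B is supporting evidence. The
  hydrophobic set and window are parameters, since motif definitions vary
  slightly between references.

**Census.** Per-genome rows (length, protein count, GC%, ATPase domain /
protein / multi-ATPase counts) are aggregated into mean, sample SD (ddof = 1;
defined as 0 for a single genome), min and max. The ATPase count is regressed
on genome length with statsmodels OLS; the slope is reported per 100 kbp and
very small p-values are floored in reports at "< 2e-16" (the customary
machine-precision floor). Normality of the response is summarized as the
correlation between sample and theoretical normal quantiles
(`scipy.stats.probplot`), passing at ≥ 0.95 — the quantitative analog of
inspecting a Q-Q plot. Per-category tables report 100 × ATPases / proteins
rounded to 2 decimals with a totals row. The DNA-packaging energy estimate
is round(length / 2) ATP, i.e. ~1 ATP per 2 bp translocated.

**Composite curation.** A composite protein has ≥ 1 qualifying ATPase domain
hit plus ≥ 1 other functional hit. Curation then applies, in any order (the
filters commute):

1. *Cellular exclusion.* Candidates on contigs where strictly more than 50%
   of proteins have bacterial/archaeal best hits are flagged as likely
   cellular; a contig at exactly 50% is retained.
2. *Deduplication.* Gene calls sharing (contig, start, end, strand) or an
   identical protein sequence on the same contig are collapsed with a
   union-find; the lexicographically smallest gene id is kept. The operation
   is idempotent.

Survivors get a functional category from a priority-ordered keyword map
(first matching keyword on any functional hit's name/accession wins);
no match yields `unknown/DUF`.

**Genomic context.** The neighborhood of a focal protein is the window of
k = 3 genes up- and downstream *by gene order* on the contig (not by bp
distance); positions past a contig edge are missing (NaN), not zero.
Neighborhood analysis runs on the deduplicated gene set — a duplicate call at
identical coordinates would otherwise occupy a neighbor slot. Each position
is scored by the number of distinct homologs of the occupying protein at
e ≤ 10⁻³⁰ (self-hits excluded). Profiles are log1p-compressed, pairwise
Euclidean distances are computed over mutually present positions and rescaled
by √(w/m) for m mutual positions out of w, and scipy hierarchical clustering
cuts the tree at 3 clusters. Clusters are labelled deterministically by mean
total homolog count, descending: context-rich, pair-conserved, isolated.
Order conservation between homologous foci is the fraction of
homology-matched neighbor pairs sitting at the same signed offset, averaged
over profile pairs with at least one match (undefined — `None` — when no
neighbor homology exists). Overlapping gene pairs are coordinate intervals
intersecting by ≥ 1 bp (abutting genes do not overlap).

## Synthetic data generator

`simulate_dataset` emits FASTA/TSV files plus a ground-truth JSON, and is
byte-deterministic given (config, seed). Background proteins are i.i.d.
uniform over the 20 residues with Walker-A windows rejected and resampled, so
the scanner's false-positive rate on background is exactly measurable.
ATPase proteins are built from 140-residue domain blocks with a literal
Walker-A planted near the block start and a Walker-B 100 residues after it,
resampled until the scanner's count equals the planted domain count.
Composites additionally get a functional (or DUF) domain hit. Conserved
neighborhoods are emitted as homology rows: operon-type foci share homologs
at every offset across family members (placed on different contigs so
windows do not collide), pair-type foci share only the focal and an
overlapping small partner, isolated foci get background-level hits; weak
(e = 10⁻⁵) rows and self-hits are included to exercise filtering.

| Parameter | Default | Rationale |
|---|---|---|
| `n_genomes` | 353 | survey-scale dataset size |
| `length_range_kbp` | (104, 735) | observed genome length range; lengths drawn Uniform |
| `atpase_rate_per_100kbp` | 4.435 | planted linear rate; counts Poisson(rate·L/100) |
| `mean_gene_length_bp` | 733 | typical prokaryotic/phage gene length |
| `composite_fraction` | 0.09 | ≈ 505 composites per ~5,500 ATPases |
| `multi_atpase_max` | 3 | composite proteins carry 1–3 ATPase domains |
| `n_duplicate_candidates` | 57 | duplicate gene calls planted at identical coordinates |
| `cellular_contig_fraction` | 0.44 | ≈ 441 of 1,003 candidates on majority-cellular contigs |
| `unknown_category_fraction` | 0.384 | share of composites with only DUF functional domains |
| `neighborhood_conserved_fraction` | 0.66 | split of foci into operon/pair vs. isolated contexts |

Uniform lengths (rather than the skewed empirical distribution) keep the
regression design well-conditioned and the count model analytically
tractable; Poisson counts are the natural model for "events per length".

## Numerical and design choices

- **Ward linkage default.** With average linkage, singleton outlier profiles
  can survive to the 3-cluster cut and swallow two true types into one
  (label agreement ~0.65 on unlucky seeds); Ward resists splitting off
  singletons and recovers the planted types with ≥ 0.98 agreement across
  seeds at default conditions. Average/complete remain available as options
  for conventional heatmap-style trees.
- **log1p compression** of homolog counts stops one huge family from
  dominating Euclidean distances.
- **Strictly-greater-than 50%** for cellular exclusion: a contig at exactly
  half cellular best hits is kept, which the fixtures exercise explicitly.
- **Sample SD (ddof = 1)** everywhere; a single genome reports SD 0 rather
  than NaN.
- **Rounding at the reporting layer only**: category fractions to 2 decimals,
  annotation shares to 1 decimal; internal values stay full precision.
- Problem sizes in the test-suite (12–40 genomes) and the acceptance script
  (353 genomes, 50 regression seeds, 1,000 oracle sequences) were chosen to
  keep the suite under a minute while leaving the statistical checks
  well-powered; they are this package's own choices.

## Limitations

- Synthetic sequences are uniform-residue text with planted literal motifs;
  they have no secondary structure, composition bias or phylogenetic signal,
  so scanner performance on them bounds only the combinatorial behavior, not
  sensitivity on real diverged ATPases.
- Homology is emitted directly as tabular rows, not computed from the
  sequences, so alignment-level artifacts (partial hits, paralog ambiguity)
  are out of scope.
- The domain-table mode trusts the keyword rule; ATPase families whose Pfam
  names carry neither `ATP` nor `AAA` require extending the keyword list.
- The category map is keyword-based and priority-ordered; multi-domain
  proteins matching several keywords take the highest-priority category only.
- Cluster labels are assigned by mean profile totals; with data far from the
  three planted context types the fixed label names may not be meaningful
  even though the clustering itself is.
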