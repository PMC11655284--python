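# Methods

This note documents the models, numerical choices and limitations of
`viresig`. It complements the README, which describes the workflow; here
the emphasis is on *why* each component is defined the way it is and what
the synthetic evaluations do and do not demonstrate.

## Genome representation

A genome is a single nucleotide string over {A,C,G,T,N} with 0-based,
half-open coordinates. Multipartite genomes are concatenated in strictly
decreasing segment length, ties broken by lexicographic accession order, so
that a given accession set always yields the same assembled sequence. The
concatenation is a storage convenience, not a biological claim: segment
boundaries are retained and no ORF is ever called across a junction.
IUPAC ambiguity codes other than N are mapped to N (with a warning);
U is normalised to T.

## ORF model

ORFs are maximal stop-to-stop stretches in all six frames; sequence and
segment ends also delimit. The caller is deliberately *not* ATG-anchored:
viral genomes use non-AUG initiation, leaky scanning and reinitiation, and
for profile comparisons the coding stretch matters, not the true start.
The length filter (default **100 aa**, inclusive) suppresses spurious short
frames; it is the first of the four parameters that dominate results in
practice (with the protein-similarity backend and threshold and the profile
hit cutoff). Reported coordinates exclude the stop codon; reverse-strand
ORFs are reported in forward-strand coordinates. Translation uses the
standard genetic code by default (configurable); codons containing N
translate to X, which is scored 0 everywhere downstream.

## Protein families and profiles

Pairwise protein similarity has two native backends with one contract
(an undirected weighted graph, weights in [0,1]):

* `alignment_score` — local alignment under BLOSUM62 with affine gaps
  (open 11, extend 1), normalised by the smaller self-score;
* `kmer_sketch` — bottom-k MinHash over amino-acid 5-mers (sketch size
  1000, keyed 64-bit hash, deterministic per seed); the weight is the
  estimated k-mer Jaccard index.

Edges below the threshold (default 0.25) are dropped. The graph is
clustered by a native dense MCL (inflation 2.0, pruning 1e-5, tolerance
1e-6, ≤200 iterations; clusters are the connected components of the
converged non-zero structure). Each cluster is aligned progressively:
pairwise global alignment scores → UPGMA guide tree → profile-profile
merges under the same scoring.

A profile (PPHMM) is a position-specific scoring model: per-column emission
probabilities `(count + α)/(n_eff + 20α)` with pseudocount α = 0.1,
columns with > 50 % gaps dropped, log2-odds against fixed BLOSUM62
background frequencies, affine gap penalties 11/1. Full three-state
profile-HMMs are not required because the framework consumes only best-hit
scores and locations, which the PSSM preserves; delegating profile building
and search to an external profile-HMM suite is a possible extension point
behind the same signature-table contract.

### Hit scores and the search-space correction

The signature value for (genome, profile) is the best local-alignment
log-odds score over the genome's ORFs, in bits, **minus
log2(profile columns × query length)**. The subtraction removes the
expected chance maximum of the local alignment (Karlin–Altschul with
K = 1): without it, unrelated 200–400 aa proteins reach 16–27 raw "bits"
purely by maximising over the search space, and no fixed cutoff separates
chance from homology. Corrected scores are floored at 0; entries below the
hit cutoff (default **15 bits**) are stored as exactly 0 and carry no
location. Scores are compared, never tested: no E-value calibration is
attempted.

## Genome organisation and signatures

A genome's organisation model (GOM) maps each hit profile to the signed
midpoint of its best-scoring ORF (positive = forward strand); reading frame
is folded into the strand sign. The GOM signature entry for genome *g*
against reference *r* is the distance correlation (Székely dCor,
double-centred pairwise-distance form) between the paired signed midpoints
of profiles present in **both**; fewer than 2 shared profiles, or a
constant location vector, gives 0 (dCor is undefined there). GOMs are
per-genome; per-taxon aggregation is not performed.

## Classification

The generalized Jaccard index Σmin/Σmax of two non-negative signature
vectors is 0 when both vectors are all-zero ("no information" is treated
as "no detectable similarity"). The composite score is J = √(J_P·J_G).
Two alternative schemes serve edge cases: `pphmm_only` (J = J_P) for
genomes dominated by a single very large ORF, where organisation carries
almost no information, and `shared_ratio_weighted`
(J = J_P · n_shared / max(n_g, n_h)) as a conservative weighting for very
large genomes with many profiles.

Dendrograms use a native agglomerative implementation (six linkages, UPGMA
default) on D = 1 − J with a fully specified tie-break: among equidistant
pairs, the lexicographically smallest pair of cluster ids merges first.
Node heights follow the ultrametric half-distance convention (merge at
distance d → height d/2). Bootstrap replicates resample profile columns
with replacement (classic bootstrap; fractional subsampling was considered
and rejected as a default because it adds a second free parameter), then
regenerate GOM databases, GOM signatures, the similarity matrix and the
tree per replicate. Supports are either the fraction of replicates
containing each clade (consensus) or the transfer bootstrap expectation
1 − mean(min transfer index)/(p−1), where p is the lighter-side leaf count
and the transfer index is minimised over all bipartitions (including
trivial ones) of the replicate tree.

Groupings cut the tree at a merge-distance threshold. When no threshold is
given, the grid of midpoints between consecutive merge distances is scanned
and the cut maximising Theil's U(reference | predicted) is chosen, **ties
resolving to the largest threshold**: U(ref | pred) is trivially 1 for the
all-singletons cut, so the coarsest maximising cut is the meaningful one.
Both conditioning directions are reported. When H(reference) = 0 the
coefficient is defined as 1 if predictions are also constant, else 0.
Feature importance is the plug-in mutual information (nats) between each
discretised column (presence/absence by default; quantile binning optional)
and the predicted groups.

## Synthetic data

The fixture generator plants a known taxonomy: each family is a repertoire
of seed proteins (default 5 per family plus 1 hallmark gene shared by all
families, lengths 150–400 aa) in conserved order and strand (25 % reverse);
each family splits into two genera descended from slightly diverged seed
copies. Default scale is 4 families × 6 genomes at 5 % amino-acid
divergence.

Two deliberate design choices keep the generator's guarantees exact:

* **Divergence is applied at the amino-acid level before back-translation.**
  Nucleotide-level mutation at 5 % would create roughly one premature stop
  codon per 300-codon gene, destroying the planted ORF structure the
  fixture must guarantee.
* **Junctions and synonymous codon draws are fixed per family**, so at
  substitution rate 0 all members of a family are byte-identical — making
  "within-family CJS = 1" and "disjoint-repertoire CJS = 0" exact
  statements, not approximations. Junctions embed a palindromic cassette
  with stop codons in all six frames so ORFs never fuse across genes.

What the fixtures do **not** emulate: indels, recombination, codon usage
bias, gene gain/loss within families, overlapping functional genes, and
GC-content structure. Passing the planted-recovery tests therefore shows
that the statistics behave as specified under their own model, not that the
tool matches expert taxonomy on real genomes.

Truncation (suffix removal) emulates non-coding-complete database records;
truncated genomes verifiably lose trailing profiles, which is exactly the
blank-cell pattern the barcode heatmap is designed to expose.

## Pipeline and problem sizes

The pipeline is fire-and-forget: a genome whose processing fails is
excluded and reported in the manifest, never a crash. Identical config and
seed reproduce byte-identical numeric TSVs. Named presets (`similar`,
`divergent`, `long-genome`) bundle parameter sets for common scenarios;
they are this package's own choices, documented in `pipeline.PRESETS`.

Default evaluation sizes — 4 × 6 genomes for structure recovery, 100
bootstrap replicates for support checks, two-genome families for the exact
score semantics — were chosen as the smallest sets on which every claim is
non-trivially exercised; all tests and the acceptance script run on a
single CPU in minutes.

## Known limitations

* PSSM hit scores are uncalibrated (no E-values); the cutoff is a bit-score
  heuristic and should be lowered for remote-homology work (`divergent`
  preset).
* Genomes with different segment counts, or single-polyprotein genomes,
  weaken the organisation signal; use `pphmm_only` there.
* The grouping threshold search needs reference labels; without labels the
  threshold must be supplied.
* Taxon-rank demarcation (which similarity level means "genus" vs
  "family") is outside scope; groupings are relative to the supplied
  reference labels only.
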