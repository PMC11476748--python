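# Methods

This note records the models implemented, the conventions that were
genuinely open choices, the numerical details, and what the synthetic
generators do and do not emulate.

## Genotype model and missingness

Genotypes are diploid, codominant allele-size calls (integers, bp).
Missingness is whole-locus: a locus either yields two allele slots or
nothing, mirroring letter-code fingerprints where `00` marks a primer
with no clear band.  A CSV call with exactly one zero allele is coerced
to fully missing with a warning rather than kept, because the data
model has no single-allele absence; a sample missing at every locus is
rejected outright.  A single amplification peak is recorded as two
identical alleles — no null-allele modelling is attempted, so true
nulls inflate homozygosity here as they do in any dominant-blind SSR
panel.

## Diversity statistics

All statistics are plug-in estimators of the allele frequencies among
scored samples:

* `He = 1 − Σp²` is deliberately the *uncorrected* gene diversity, not
  the small-sample `2n/(2n−1)` form, so the identity `He = 1 − 1/Ne`
  holds exactly for every subset.  This is the convention under which
  the packaged dataset's published summary tables reproduce to three
  decimals.
* Shannon's `I` uses natural logarithms (nats).
* `Ho` divides heterozygote counts by scored (not total) samples.
* PIC is the Botstein form `1 − Σp² − Σ_{i<j} 2p_i²p_j²`; the test
  suite cross-checks it against a literal double-loop enumeration.

Per-population summaries average each statistic over **all** loci, a
locus with zero scored samples in the population contributing 0 (not
NA) to every statistic.  This "zero-for-missing-locus" convention can
push a population's mean Na below 1 (the sparsest accession in the
packaged panel averages 0.75 alleles per locus); it is the convention
the shipped dataset's per-population table was published under, so it
is the default and only behaviour.  Report output rounds half-up to 3
decimals; all internal computation is full precision.

## Nei distance and UPGMA

Nei's standard distance uses locus-averaged `J` terms with pairwise
deletion: loci unscored in either unit are dropped before averaging.
An accession is treated as a one-individual "population" with
frequencies 0/0.5/1 — the convention PowerMarker-style pipelines apply
when every accession is one OTU.  Whether external tools use exactly
this deletion rule is not documented anywhere authoritative; it is
recorded here as an assumption.  Two degenerate cases are kept
distinct: units sharing no commonly scored locus raise an error
(incomparable), while commonly scored units sharing no allele give
`D = +∞`.  For tree building, infinite entries are capped at one more
than the largest finite distance (with a warning) because average
linkage is undefined on infinities and a complete dendrogram over all
units is the point of the exercise.

UPGMA is the naive O(n³) algorithm (n is under a hundred here, so
clarity beats the heap-based O(n² log n) variant) with node height =
merge distance / 2.  Tie-breaking is deterministic: among equally close
pairs, the pair whose clusters hold the lexicographically smallest leaf
labels merges first, and the child with the smaller minimal label is
written first.  The tests verify exact ultrametricity and, on tie-free
random matrices, cophenetic agreement with SciPy's average linkage —
an independent implementation, kept as an oracle rather than used as
the backend precisely because SciPy does not expose this tie rule.
Published dendrogram *topologies* for the packaged panel are not an
acceptance surface (their branch lengths were never printed); the tree
code is validated structurally instead.

## Admixture sampler

The sampler implements the uncorrelated-allele-frequency admixture
model.  Priors are symmetric Dirichlets, λ = 1.0 on cluster frequencies
and α = 1.0 on admixture proportions, with an optional Metropolis
update for α (uniform proposal, sd 0.025, off by default).  The
correlated-frequency model is a deliberate simplification target left
out of scope: it changes efficiency at low divergence, not the model's
identifiable structure, and every validation here uses strongly
diverged synthetic data where the uncorrelated model is adequate.
Burn-in defaults to 10 % of sweeps.  `ln P(D)` is estimated as
`mean(lnL) − var(lnL)/2` over the post-burn-in trace, the estimator
STRUCTURE prints, so ΔK behaves comparably.  Q is reported as the
posterior mean over post-burn-in sweeps.

Cluster labels are non-identifiable; all comparisons against truth use
best-permutation alignment via the Hungarian algorithm
(`align_q`).  With a fixed `random_state` a run is bit-reproducible.

ΔK uses the sample standard deviation (ddof = 1) over replicates and is
undefined (NaN) at the boundary K values and wherever the replicate sd
is zero; arg-max ties break toward smaller K.

Exact replication of published membership coefficients from long MCMC
runs on real data is not attempted — unstated burn-in and run lengths
make that irreproducible in principle.  The validation surfaces are
structural: known-truth recovery (mean |Q − truth| < 0.05 on two fully
diverged populations of 25, 10 loci, 2 000 sweeps) and model selection
(ΔK picks K = 3 on 3-population data — 15 samples each, 12 loci,
Dirichlet concentration 0.05, 600 sweeps × 3 replicates over K = 1..5 —
in ≥ 4 of 5 seeded repetitions).  These problem sizes were chosen as
the smallest at which the expected behaviour is statistically
unambiguous.

## SSR mining

A simple SSR is a maximal perfect tandem run of a primitive 1–6 bp
motif whose complete-repeat count meets the per-unit-length threshold;
partial trailing repeats are trimmed, coordinates are 1-based
inclusive.  Primitivity ("ATAT" is not a tetranucleotide motif) is what
makes lower unit lengths win without any explicit redundancy pass.  `N`
never matches anything, so it breaks runs.  Default thresholds are
8, 5, 4, 3, 2, 2 repeats for mono- through hexanucleotide motifs; a
stricter `TABLE1_PRESET` (10, 6, 5, 5, 5, 5 — the common MISA default)
is provided because summary tables binned from repeat count 5 upward
imply such thresholds.  Summaries therefore include a leading `<5` bin
so that every record falls in exactly one bin under any configuration.

Motif classes canonicalise over all rotations of the motif and of its
reverse complement, printing `smallest/revcomp(smallest)` (e.g. GA, AG,
TC, CT → `AG/CT`).  Adjacent simple records separated by at most
`max_interruption` bp (default 100) merge into a compound record whose
constituents still count individually in summaries.

Correctness is established against an exhaustive brute-force oracle —
an independent enumeration of every (start, unit) candidate — on seeded
random sequences, including the 10 kb × 100-sequence equivalence check
in the acceptance suite.  Genome-scale mining counts from any specific
transcriptome assembly are not a target (the assemblies behind such
tables are generally unpublished); only the frequency and density
arithmetic (SSRs per 100 sequences; bp per SSR) is exercised on printed
totals.

## Synthetic data

`simulate_genotypes` draws K populations' allele frequencies from a
symmetric Dirichlet (concentration controls divergence; 0.3 default is
"strongly structured", values ≥ 10 are near-panmictic), assigns each
sample pure (α = 0) or Dirichlet-admixed ancestry biased toward its
source population, samples the two allele copies independently
(Hardy–Weinberg within clusters), and masks whole loci at the missing
rate (re-scoring one locus if a sample would lose all of them, to keep
every sample valid).  `fixed_private_alleles=True` is the
zero-concentration limit — population k fixed for allele k at every
locus — used where the validation calls for complete divergence rather
than a random draw that merely approximates it.  Allele sizes sit on a
per-locus ladder (offset + unit × index, unit ∈ {2, 3, 4}) so simulated
data exercises the fingerprint coder realistically.  Defaults (3
populations × 29 samples, 8 loci, 8 alleles, 5 % missing) mirror a
small germplasm panel.

What the generator does *not* emulate: mutation processes (no stepwise
mutation model, no homoplasy), linkage between loci, null alleles,
genotyping error, or uneven population sizes.  Passing recovery tests
on this data therefore demonstrates correctness of the inference
machinery, not robustness to those real-data pathologies.

`simulate_transcripts` plants perfect SSRs at fixed positions in
random background and redraws the whole sequence until mining it
returns exactly the implant plan, so its truth table is guaranteed
rather than probable.  Every generator takes an explicit seed; there is
no hidden global random state.

## Packaged dataset

The shipped 87-accession × 8-locus *Passiflora* panel is stored as its
original letter-code fingerprint strings plus the per-primer code
table, and decoded on load.  Encoding the decoded matrix back with the
same tables reproduces all 87 strings byte-for-byte, and rebuilding the
code table from the decoded genotypes reproduces every published
(letter, size) pair — the dataset is exactly self-consistent.  Two
quirks are preserved verbatim: one accession label out of numeric
sequence (a data-entry artifact in the source), and a primer order that
was published as "descending PIC" but differs from the strict PIC sort
at positions 2–5; the decoder uses the published order (the strings are
encoded in it), while `rank_primers_by_pic` sorts strictly.

## Known limitations

* No F-statistics, AMOVA, Hardy–Weinberg exact tests or bootstrap
  support values — outside the analysis surface this package serves.
* The admixture sampler is a single-chain Gibbs sampler; for weakly
  diverged data it can mix slowly, and ΔK inherits its usual inability
  to assess K = 1.
* Accession-level Nei distances from 8 loci are noisy; the dendrogram
  is descriptive, not phylogenetic inference.
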