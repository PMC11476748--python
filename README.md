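# ssrkit

A toolkit for SSR (simple sequence repeat / microsatellite) germplasm
analysis: mining SSR loci from transcript FASTA, computing the standard
genetic-diversity statistics of codominant markers, building
Nei-distance/UPGMA dendrograms, inferring admixture-model population
structure with Evanno ΔK model selection, and constructing letter-code
DNA fingerprint profiles for cultivar identification.

It is aimed at plant-genetics workflows of the kind used to
characterise germplasm collections: a few dozen to a few hundred
accessions genotyped at a handful of polymorphic SSR loci, where the
questions are *how diverse is the collection*, *how is it structured*,
and *can every accession be told apart*.

## The statistics at the core

For a locus with allele frequencies $p_1,\dots,p_k$ estimated from the
scored samples (two gene copies per diploid individual; missing loci
are excluded from the denominator):

* number of alleles $N_a = k$, effective number
  $N_e = 1/\sum_i p_i^2$;
* expected heterozygosity $H_e = 1 - \sum_i p_i^2$
  (so $H_e = 1 - 1/N_e$ identically), observed heterozygosity
  $H_o$ = heterozygous / scored individuals;
* Shannon's index $I = -\sum_i p_i \ln p_i$;
* polymorphism information content (Botstein)
  $\mathrm{PIC} = 1 - \sum_i p_i^2 - \sum_{i<j} 2 p_i^2 p_j^2$.

Between two units (accessions or populations), Nei's standard genetic
distance over commonly scored loci is
$D = -\ln\!\big(J_{xy} / \sqrt{J_x J_y}\big)$ with
$J_{xy} = \overline{\sum_i x_i y_i}$, and trees are built by UPGMA
(average linkage, ultrametric, deterministic tie-breaking).

Population structure follows the admixture model: individual $i$ draws
each allele copy from cluster $k$ with probability $q_{ik}$, clusters
have their own allele frequencies, and a Gibbs sampler alternates
between latent assignments, cluster frequencies and $q$.  The number of
clusters is chosen by the Evanno statistic
$\Delta K = |\bar L(K{+}1) - 2\bar L(K) + \bar L(K{-}1)| / \mathrm{sd}\,L(K)$
over replicate runs of the estimated $\ln P(D)$.

Fingerprint profiles concatenate, per primer in descending-PIC order, a
two-letter code for the two fragment sizes (letters assigned A, B, C, …
by ascending size; `00` = no clear band), giving a compact string per
accession whose exact-match duplicates are reported.

## Worked example

The package ships a real dataset: 87 *Passiflora* germplasm accessions
from 22 species/cultivars, genotyped at 8 SSR loci and stored as
letter-code fingerprint strings plus the per-primer code table.

```python
>>> import ssrkit as sk
>>> m = sk.load_passiflora()          # decode fingerprints -> genotypes
>>> print(sk.locus_summary_table(m).round(3))
           Na     Ne      I     Ho     He    PIC
locus
ssr18  10.000  4.724  1.814  0.449  0.788  0.762
ssr3    6.000  3.645  1.460  0.127  0.726  0.684
ssr32  15.000  3.928  1.786  0.229  0.745  0.711
ssr2    7.000  2.730  1.311  0.079  0.634  0.595
ssr39  15.000  3.248  1.723  0.161  0.692  0.670
ssr30   4.000  2.363  1.062  0.423  0.577  0.523
ssr1    5.000  2.183  1.105  0.244  0.542  0.512
ssr34   7.000  1.977  1.021  0.171  0.494  0.460
Mean    8.625  3.100  1.410  0.235  0.650  0.614
```

Reading the table: ssr18 is the most informative marker (10 alleles,
PIC 0.762, i.e. highly polymorphic), ssr34 the least (PIC 0.460); the
panel averages 8.625 alleles per locus, and the large gap between
$H_o$ (0.235) and $H_e$ (0.650) reflects the many homozygous or
single-band calls typical of a mixed-species collection.

Fingerprint uniqueness — the profiles separate most, but not all,
accessions (replicated cultivars share strings):

```python
>>> profiles, _ = sk.passiflora_profiles()
>>> rep = sk.uniqueness_report(profiles)
>>> print(f"{rep.n_distinct} distinct profiles among {rep.n_profiles}")
75 distinct profiles among 87
>>> rep.duplicate_groups[0]
('11-P. edulis "man tian xing"', '12-P. edulis "man tian xing"')
```

Admixture recovery on synthetic data with known truth — two fully
diverged populations, 25 diploids each, 10 loci:

```python
>>> import numpy as np
>>> spec = sk.SimSpec(n_populations=2, samples_per_population=25,
...                   n_loci=10, alleles_per_locus=4,
...                   fixed_private_alleles=True, missing_rate=0.0, seed=3)
>>> sim = sk.simulate_genotypes(spec)
>>> est = sk.GibbsAdmixture(n_clusters=2, n_sweeps=2000, burn_in=500,
...                         random_state=7).fit(sim.matrix)
>>> q = sk.align_q(est.Q_, sim.q_true)
>>> round(float(np.abs(q - sim.q_true).mean()), 4)
0.0462
```

The mean absolute error of 0.046 against the true 0/1 ancestry matrix
is the Dirichlet-prior shrinkage expected at this sample size; the
sampler has assigned essentially every allele copy to the right
cluster.

A command-line interface mirrors the library
(`ssrkit decode | stats | tree | structure | fingerprint | mine |
simulate | dataset`); e.g. `ssrkit tree genotypes.csv` prints a Newick
UPGMA dendrogram from Nei distances.

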