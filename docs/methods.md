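# Methods

`ssrpop` implements the statistical workflow used to characterise a clonal
*Coffea canephora* collection (44 conspecific genotypes plus one
*C. arabica* outgroup control) with a panel of 21 codominant SSR/EST-SSR
markers: per-locus diversity parameters, pairwise dissimilarity with UPGMA
clustering and Mojena's stopping rule, Loiselle pairwise kinship, and
Bayesian admixture clustering with Evanno Δk model selection.  Because no
raw genotypes for such panels are generally available, the package ships a
synthetic-genotype generator that reproduces the statistical structure the
analysis assumes, so every stage is testable end to end.

## Genotype model

A `GenotypeMatrix` stores, per individual and locus, an unordered pair of
numeric allele codes `1..NA` (`0` = missing), the standard numeric coding
for codominant data: a three-allele locus has homozygotes 11/22/33 and
heterozygotes 12/13/23.  Codes are assigned by first appearance in file
order and the label table is retained, so reports can show original
fragment sizes.  Half-missing pairs are promoted to fully missing with a
warning; ploidy is fixed at two.  GenAlEx codominant CSV (missing `0`) and
STRUCTURE two-rows-per-individual text (missing `-9`) are supported in
both directions and round-trip exactly.

## Synthetic populations

The generator draws, per locus, an allele count in 2–5 (by default with
weights 9:7:3:2, the empirical distribution of the 21-locus coffee panel,
mean 2.9 alleles/locus) and ancestral frequencies from a symmetric
Dirichlet, rejected until at least two alleles have frequency ≥ 0.08 so
each locus remains polymorphic at panel sample sizes while rarer alleles
stay possible.  Cluster allele frequencies follow the Balding–Nichols
F-model, `p_k ~ Dirichlet(p (1 − F_ST)/F_ST)`, the standard generative
counterpart of the admixture model's assumptions.  Within clusters,
genotypes depart from Hardy–Weinberg according to F_IS:
`P(hom k) = p_k² + F_IS p_k (1 − p_k)`.  For F_IS ≥ 0 this is realised
exactly by allele duplication; for F_IS < 0 the genotype distribution is
constructed explicitly with homozygote probabilities clipped at zero
(exact whenever `F_IS ≥ −min_k p_k/(1 − p_k)`).  Clone pairs are exact
genotype copies; sib pairs are Mendelian full siblings of two simulated
cluster parents; the optional outgroup individual is homozygous for a
private allele at each locus with probability ½, which reproduces the
maximal separation of an interspecific control in the dendrogram.
Missing calls are masked uniformly (default rate 0.02 — no rate is
reported for the real panel; configurable).  Everything is reproducible
from one seed (default 2022, recorded in configs and logs).

What the generator does *not* emulate: SSR mutation dynamics (no repeat
length structure), linkage between loci (all estimators here assume
independence), null alleles and genotyping error.  Tests passing on this
generator therefore validate the estimators and their implementation, not
robustness to those artefacts in real data.

## Diversity statistics

Per locus: number of alleles NA, observed heterozygosity Ho, expected
heterozygosity He = 1 − Σp², Shannon information index I = −Σ p ln p
(natural log — verified internally by the biallelic He↔I consistency of
the published panel), and fixation index F = 1 − Ho/He.  He is the plain
1 − Σp² without a small-sample correction: the published panel's own
F = 1 − Ho/He identity holds only without it.  F is reported as undefined
(not 0) for monomorphic loci and the panel mean averages only defined
loci.  Informativeness classes follow the customary thresholds (high
I > 0.5, moderate 0.25 ≤ I ≤ 0.5, uninformative I < 0.25); ties at the
boundaries go to the moderate class.  Panel means are unweighted.

## Dissimilarity and clustering

Three codominant indices are provided.  The shared-allele score of a
genotype pair is the multiset intersection of allele copies (0, 1 or 2),
scaled to [0, 1].  The *weighted* index averages these scores with locus
weights `p_j = a_j/A` (allele count over panel total), renormalised over
the loci typed in both individuals; the *unweighted* index averages them
equally; the *Smouse–Peakall* metric is the codominant squared distance
(half squared Euclidean distance between allele-count vectors) summed
over loci.  The weighted score is scaled to [0, 1] rather than left as a
raw count so that the dissimilarity D = 1 − S stays in [0, 1]; a raw
count of up to 2 per locus would make D negative for similar pairs, and
the published worked pairs (closest pair D = 0.06 sharing 39 of at most
42 copies) are only consistent with the scaled form.

UPGMA uses scipy's average linkage (cluster-size-weighted mean of
original distances); fusion heights are the average distances themselves
(a two-leaf pair fuses at its distance), and the Mojena cut operates on
that same scale: every fusion above mean(h) + k·sd(h) (sample sd,
k = 1.25, the value recommended in the stopping-rule literature) is
undone.  The cophenetic correlation is the Pearson correlation between
the input and dendrogram-implied distances over all pairs; the index used
for the final tree is chosen by the highest cophenetic correlation with
ties resolved in the fixed order weighted, unweighted, Smouse–Peakall.
Tie-breaking inside the linkage follows scipy's deterministic order, so
runs are exactly reproducible.

## Loiselle kinship

The pairwise estimator is the correlation-type coefficient

    F_ij = [ Σ_l Σ_a (p_ila − p̄_la)(p_jla − p̄_la)
             + Σ_l Σ_a p̄_la(1 − p̄_la)/(n_l − 1) ] / Σ_l Σ_a p̄_la(1 − p̄_la)

with within-individual allele dosages in {0, ½, 1}, sample frequencies as
the reference (including the pair itself), and the small-sample
correction included by default (switchable).  Numerators and denominators
are summed over loci before dividing — the single multilocus ratio, which
weights loci by their polymorphism, matching the reference estimator's
default; per-locus averaging is available behind a flag.  Loci not typed
in both members, and monomorphic loci, are excluded.  A useful
calibration: clones ≈ 0.5, parent–offspring ≈ 0.25, and the zero-sum
property of sample-frequency referencing puts the all-pairs mean near
+1/(2(n − 1)) with the correction and −1/(2(n − 1)) without it.  The
histogram uses contiguous half-open bins (−∞,0), [0,0.1), [0.1,0.3),
[0.3,0.5), [0.5,∞), closing the gaps left by prose-style bin labels.

## Bayesian admixture

`AdmixtureModel.fit` is a Gibbs sampler for the admixture model with
independent allele frequencies: per sweep it samples cluster allele
frequencies from Dirichlet(1 + origin counts), individual ancestry
vectors from Dirichlet(α + origin counts), allele-copy origins
proportional to `q_ik p_klx`, and updates the single shared α by a
Metropolis random walk (normal proposal, sd 0.025, uniform prior on
(0, 10] — the reference program's defaults; a fixed-α mode exists for
testing, and an alternative log-scale α walk with Jacobian correction is
selectable for faster per-run equilibration).  Missing copies are skipped everywhere.  `n_iter` counts total
sweeps, of which the first `burn_in` are discarded.  The log-likelihood
is recorded each retained sweep and the model evidence proxy is the
harmonic approximation LnP(D) = mean(lnL) − var(lnL)/2; Q and P are
posterior means.  Runs are bit-reproducible from their seed.  The kernel
is compiled with numba; a campaign of 60 desk-scale runs on a 60 × 21
matrix takes about 1.5 minutes on one core.

`run_campaign` executes replicate runs over a K range and builds the
Evanno table: per K the mean and sd of LnP(D) over replicates, the first
and second differences, and Δk = |L″(K)|/sd(K); the supported K is the
interior argmax.  With the replicate sd in the denominator, Δk inherits
a well-documented sensitivity: for symmetric multi-cluster data the
curvature |L″| at K = 2 is intrinsically large (the first split explains
most structure), and whenever the K = 2 replicates happen to agree
tightly, Δk(2) can exceed Δk at the true K — the "K = 2 attraction" of
the statistic.  At desk-scale run lengths (10,000 sweeps) the between-run
spread is dominated by Monte-Carlo effects, notably the slow α random
walk from its 1.0 start, so single short campaigns select the true K of
a three-cluster population only about two times in three; headline
cluster-number results are therefore reported as the majority over
several seeded campaigns.  The full-scale preset (burn-in 250,000,
1,000,000 total sweeps, 20 replicates, K 1–10) is available where
runtime permits.  Individuals are assigned to their majority
cluster when its ancestry proportion reaches the adherence threshold
(default 0.70) and called admixed otherwise.  The representative run at
the selected K is the replicate with the highest LnP(D) by default;
`lowest` is selectable for strict compatibility with workflows that
report the lowest value.

## Pipeline

`run_pipeline` chains simulate/read → diversity → distance/UPGMA →
kinship → admixture and writes TSV/newick/JSON artifacts plus a combined
markdown report, each stamped with a config hash and the seeds, so reruns
are byte-identical.  Configuration is a pydantic model round-tripped
through YAML (pydantic provides the schema validation).  UPGMA groups and
admixture clusters are cross-tabulated with an adjusted Rand agreement
index.

## Problem sizes used in the test suite

Unit and property tests run on toys (n ≤ 6 brute-force oracle batteries,
hand-worked pairs) and on simulated panels of 20–500 individuals; MCMC
tests use 1,500–10,000 sweeps.  The cluster-number recovery check runs
three seeded desk-scale campaigns (60 individuals, K 1–6, 10 replicates,
10,000 sweeps) and takes the majority; the acceptance script runs five.

## Known limitations

- Eq-style weighted similarity cannot reproduce the published pairwise
  dissimilarities exactly without the undeposited raw genotypes; the
  worked pairs serve as plausibility checks only.
- Δk model selection on desk-scale run lengths is stochastic (see above);
  single short campaigns should not be over-interpreted.
- The simulator's F_IS < 0 construction is approximate beyond the
  feasibility bound noted above.
- No null-allele handling, rarefaction, or exact Hardy–Weinberg tests.
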