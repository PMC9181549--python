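# Methods

`retroscape` re-implements, as one tested toolkit, the analyses commonly
chained together in LTR-retrotransposon (LTR-RE) studies of plant genomes:
structural isolation of full-length elements, lineage annotation from
protein domains, insertion-time dating, read-based genome-proportion
estimation, IRAP dominant-marker fingerprinting with population-structure
inference, and primer–gene proximity enrichment.  Every stage can be
exercised against a synthetic genome whose truth is known exactly, so the
package's claims are statements about recovery of planted signal, not about
any particular real genome.

## 1. The synthetic-data generator

### Mutation model

Sequence divergence is simulated under the Kimura two-parameter (K2P)
process.  `mutate_k2p(seq, d, ts_tv_ratio)` draws each site's fate from the
exact K2P transition-probability matrix at branch length `d` expected
substitutions/site (multiple hits included), with transition rate
α = R·2β and transversion rate 2β partitioned by the
transition:transversion ratio R (default 2:1, the conventional value for
plant nuclear DNA).  Because the matrix exponential is used rather than a
naive per-site Bernoulli substitution, the K2P *estimator* applied to
(input, output) pairs is consistent for `d`; the generator and the
estimator are exact inverses in expectation, which the test suite verifies
by Monte-Carlo.

Indels are not simulated.  The K2P estimator excludes gap columns anyway,
and indel-free truth keeps every downstream coordinate exact.  This is the
main idealisation of the generator: real LTRs accumulate indels and real
boundaries are fuzzier than the planted ones, so the detection and dating
benchmarks here bound what the algorithms can do on clean signal, not on
degraded ancient repeats.

### Elements, genomes, decoys

A `LineageTemplate` holds a lineage's LTR consensus (default 1 kb,
TG…CA-terminated) and an internal consensus carrying GAG–PROT–INT–RT–RH
open reading frames in the superfamily-specific order (INT before RT for
Copia, after RH for Gypsy; ~950 aa of coding in ~4.5 kb internal).
`simulate_element(template, T)` mutates both LTR copies *independently*
with `d = r·T·10⁶` each (rate r defaults to 2×10⁻⁸ substitutions/site/year
— twice a typical synonymous rate, reflecting the faster decay of
repeats), so the expected inter-LTR distance is `K = 2rT`.

`build_genome` inserts elements at well-separated random points of an
i.i.d. background with 5-bp target-site duplications (configurable 4–6 bp),
optionally reverse-complemented (a direct repeat is strand-symmetric, so
detection is orientation-blind), optionally nested inside a previous
element's internal region, plus two decoy classes that real structural
detectors must reject: solo LTRs and truncated element fragments.  Genes
and primer binding sites are placed in element-free background with exact
recorded coordinates.

### Reads and marker populations

Reads are uniform single-end draws (default 85 nt) with i.i.d. base errors
and no quality model — mapping filters here act on identity, not quality.
Dominant-marker matrices follow the standard diploid model: with admixture
vector Q_i and band-allele frequency f_kl, a band is absent only when both
haplotypes carry the absence allele, P(band) = 1 − (Σ_k Q_ik(1−f_kl))².
Two truth generators are provided:

* `generate_population_truth` — correlated allele frequencies
  (Beta-distributed around a shared ancestral frequency with drift
  parameter F_st, default 0.4) and balanced groups with an admixed mass
  m ~ U(0, 0.3) per accession; a generic, moderately structured collection.
* `generate_differentiated_truth` — the *strongly differentiated* regime
  used by the recovery benchmarks: every locus carries a non-constant
  high/low (≈0.85/0.10) frequency pattern across subpopulations
  (diagnostic-locus design), so all subpopulation pairs differ at about
  half the loci *by construction*.  With 40 dominant loci and 25
  accessions, weaker differentiation leaves a third subpopulation carrying
  too little likelihood for any K-selection method — a genuine information
  limit of sparse dominant markers, not of the estimator.

## 2. Structural detection

`find_candidates` indexes exact k-mers (k = 20) and pairs same-diagonal
occurrences whose separation is compatible with a full-length element (LTR
100–3000 bp, element 1–16 kb — common structural-search defaults), chains
them, and extends each repeat copy by ungapped X-drop extension (+1/−2,
drop 15).  Boundaries are then snapped (≤3 bp, applied jointly to both
copies) onto TG…CA termini when present, since chance matches let ungapped
extension overshoot a repeat edge by a base or two.

`refine_and_filter` scores each candidate by global LTR–LTR alignment
identity (edit-distance based), annotates TG…CA and 4–6 bp TSD evidence,
drops candidates under 85% identity or with LTR lengths differing >20%,
and resolves overlaps greedily by a weighted score: identity + 3 for a
shared TSD + 1 for TG…CA on both LTRs.  The bonuses matter: two
same-lineage neighbours (or an element and a nearby solo LTR) form a
spurious "spanning" repeat pair whose raw identity can exceed the true
element's, but a spurious pair essentially never shows a shared 5-bp
duplication (P ≈ 4⁻⁵ per flank pair).  TSD and motif remain annotations,
never hard filters.  Containment is tolerated only when the inner element
lies strictly within the outer's internal region — the geometry of a real
nested insertion; a candidate that "contains" another element's LTRs is in
conflict with it.

On the 2-Mb benchmark (48 elements at 1–2 MYA, 10 solo LTRs, 10
fragments), precision and recall are 0.96–1.0 across seeds; an element-free
megabase yields zero candidates.

## 3. Annotation

Six-frame translations of an element (or its internal region) are locally
aligned (BLOSUM80, gap open −11 / extend −1) against exemplar peptides
labelled `domain|lineage|superfamily`; the best hit per domain type above
`min_score = 250` is kept.  The threshold sits well between unrelated-frame
scores (~150 under these gap costs) and genuine young-domain hits (≥700).
Superfamily comes from the linear order of INT and RT read along the coding
strand (majority frame sign); lineage from the highest-scoring consistent
hit, with exact ties conservatively undetermined.  An element with all five
domains is flagged autonomous.  Elements without domain evidence can adopt
the annotation of their closest classified relative (`homology_rescue`):
semi-global alignment of the shorter sequence into the longer, identity
computed over aligned columns only (a structural deletion is a gap, not
mismatch), defaults 80% identity and 50% coverage of the shorter sequence.

The packaged exemplar set derives from the simulator's templates; any
public protein-domain database converted to the same FASTA header shape
plugs in unchanged.

## 4. Insertion-time dating

`k2p` computes K = −½·ln((1−2P−Q)·√(1−2Q)) over gap-free columns and
raises a saturation error when the logarithm's argument is non-positive;
saturated pairs are excluded and counted, never clamped.  LTR-pair ages are
T = K/(2r).  Global LTR alignment uses affine gap penalties (match 5 /
mismatch −4, gap open 16 / extend 4); equal-length pairs are compared
column-wise.  Unit-cost (gap = mismatch) alignment is deliberately avoided
here: at high divergence it converts mismatch columns into spurious gaps,
which the K2P count then skips, biasing ages downward by tens of percent.
Cohort recovery bias is under 5% for true ages 0.5–5 MYA (200 elements,
1-kb LTRs).

Read-based dating (`rt_read_dating`) maps reads to RT-encoding references
(≥150 nt) with the mapping filters length fraction ≥ 0.9 and similarity ≥
0.8, then applies `k2p` to co-mapped read pairs on their overlap (pairwise
deletion; overlaps < 40 nt skipped as unstable; large pair sets are
sub-sampled under the run seed).  Reads whose alignment required gaps are
excluded from pairing since pair comparison is positional.  Age profiles
are histograms (default 0.25-MYA bins) with burst peaks read from a
Gaussian-smoothed density (bandwidth = bin width) at 5% prominence; a
two-burst cohort at 1 and 10 MYA yields exactly two peaks at the planted
ages.

## 5. Genome proportion

The read mapper is seed-and-verify: a few exact 14-mers vote for
(reference, diagonal) candidates, each candidate is verified by direct
base-wise comparison on its diagonal, with an edit-distance (edlib)
semi-global fallback for gapped cases, and acceptance uses the same
0.9/0.8 filters as above.  Genome proportion is mapped reads / total reads
— the read-fraction-equals-genome-fraction convention; no GC or mappability
correction is attempted.  Reads tying across lineages go to an explicit
`ambiguous` row by default, or are assigned uniformly at random under the
run seed (`tie_policy="random"`) to mimic single-assignment mappers.
Proportions sum to one exactly by construction.  A coverage-20 simulation
of a 30%-element genome is recovered within ±0.02 (observed error ≈ 1e-3;
reads straddling element boundaries are the residual bias, bounded by
read_length/element_length ≈ 1.5%).  Solo-LTR and fragment decoys share
sequence with the library, so genomes built with decoys are estimated
slightly above their full-length-element truth fraction — visible in the
demo pipeline manifest.

## 6. IRAP and population structure

Primer-site scanning is an exhaustive IUPAC-aware sliding comparison on
both strands, allowing `max_mismatches` (default 1) with none in the three
3'-terminal bases (extension cannot start from a mismatched 3' end).
Facing (+,−) site pairs with products of 100–3000 bp (gel-resolvable
range) become amplicons; the product length convention is the inclusive
span between the two primer 5' ends.  Pooled product lengths co-bin within
2% (an agarose-resolution proxy) to form presence/absence band matrices;
PCA of the column-centred matrix ordinates accessions.  The 11-primer panel
used for this marker system is bundled as data.

Admixture inference is the statsmodels-style pair `DominantAdmixture` /
`AdmixtureResults`.  `fit(K)` runs EM on the dominant-marker likelihood
log L = Σ y·log(1−a²) + (1−y)·log(a²), a = Σ_k Q_ik(1−f_kl), treating
per-haplotype ancestries and hidden alleles as latent; the update is
closed-form (posterior haplotype responsibilities, then normalised counts),
monotone in log L (asserted every iteration), run to ΔlogL < 10⁻⁶ or 2000
iterations, best of 7 replicate starts (7 replications per run is the
convention followed here; set `n_replicates=5` for the stricter variant).

K selection uses the Evanno ΔK statistic,
ΔK(K) = |mean L(K+1) − 2·mean L(K) + mean L(K−1)| / sd(L(K)).  ΔK was
designed around Monte-Carlo estimates of Ln P(D): converged EM replicates
at a reliably-solved K are numerically identical, their sd collapses to
~10⁻⁶, and ΔK explodes at the wrong K.  The replicate log-likelihoods fed
to ΔK therefore come from a Gibbs sampler for the same model (conjugate
Beta/Dirichlet updates for f and Q; the admixture concentration α inferred
by a Metropolis step, uniform prior on (0, 10]; 200 burn-in + 300 recorded
sweeps), summarised by the estimator mean(log L) − ½·var(log L), whose
variance penalty also makes L̂(K) plateau above the true K.  On strongly
differentiated 25 × 40 benchmarks this selects K_true in ≥ 8/10
simulations for K_true ∈ {2, 3}, and EM recovers Q with mean absolute
error ≈ 0.05 after greedy-correlation label alignment.  Accessions are
assigned to a subpopulation only when Q_i exceeds 0.8 *strictly*;
otherwise they are admixed.

## 7. Proximity enrichment

Gene windows are [start − flank, end + flank] (flank 100 kb, boundaries
inclusive, clipped at chromosome ends); a gene counts as "with hit" if any
primer 3'-end position falls inside.  Control genes are drawn uniformly
without replacement excluding the focal set.  The 2×2 test is Pearson's
chi-square with Yates continuity correction by default — the corrected
variant is what reproduces the published p-value for the bundled printed
counts (35/103 vs 16/103 → χ² ≈ 8.44, p ≈ 0.0037 corrected vs ≈ 0.0022
uncorrected; the uncorrected variant remains available).  Under null
planting at these margins the corrected test's type-I error is ≤ 6% at
α = 0.05 (2000-table simulation in the test suite).

## 8. Reproducibility and problem sizes

All randomness flows from a single seed through spawned `SeedSequence`
children; re-running any simulation or the demo pipeline with the same
configuration reproduces outputs byte-identically (manifests differ only
in timestamp).  The benchmark sizes used throughout — 2 Mb / ~50 elements
for detection, 200-element cohorts for dating, coverage 20 on ~300 kb for
abundance, 25 accessions × 40 loci × 10 repeats for structure — are the
package's chosen desk-scale study conditions: large enough that sampling
error is well inside each acceptance band, small enough to run on a
laptop in minutes.

## Known limitations

* No indel mutation model; no solo-LTR *formation* (decoys are planted,
  not generated by recombination); TSDs never decay.
* The domain scanner assumes roughly intact reading frames per domain;
  heavily frame-shifted ancient elements would need a profile-HMM scanner.
* Genome-proportion estimation inherits the read-fraction convention's
  biases (no mappability/GC correction).
* ΔK inherits its known blind spots (K = 1 undetectable; hierarchical
  structure reports the uppermost level).
* The in-silico IRAP ignores PCR competition, amplification efficiency and
  gel-band intensity; band co-binning is a fixed fractional tolerance.
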