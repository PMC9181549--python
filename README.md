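# retroscape

Structural annotation, insertion-time dating, genome-proportion estimation
and IRAP marker analysis of **LTR retrotransposons** (LTR-REs), with a
synthetic-genome simulator that provides exact ground truth for every
stage.

LTR-REs are Class I transposable elements flanked by two long terminal
repeats that are identical at the moment of insertion.  That single fact
powers most of what this package does:

* **Detection** — a full-length element is a pair of near-identical direct
  repeats (100–3000 bp each) at an element-like separation (1–16 kb),
  corroborated by TG…CA termini and a 4–6 bp target-site duplication (TSD).
* **Dating** — the two LTRs diverge after insertion, so their Kimura
  two-parameter distance *K* = −½ ln((1−2P−Q)√(1−2Q)) converts to an
  insertion age *T* = *K* / (2*r*), with *r* = 2×10⁻⁸
  substitutions/site/year per LTR by default.  A second, complementary
  estimator compares sequencing reads co-mapped to reverse-transcriptase
  (RT) references, which is less biased against old, fragmented elements.
* **Annotation** — the order of the integrase (INT) and RT domains along
  the Pol polyprotein separates the Copia (…INT–RT–RH) and Gypsy
  (…RT–RH–INT) superfamilies; exemplar peptides assign the lineage.
* **Abundance** — the fraction of reads mapping to the full-length element
  library (≥0.9 of the read aligned at ≥0.8 identity) estimates each
  lineage's genome proportion.
* **IRAP** (inter-retrotransposon amplified polymorphism) — in-silico PCR
  between LTR primer sites predicts dominant presence/absence bands;
  band matrices feed PCA, admixture inference
  (`DominantAdmixture(matrix).fit(K)` → results with Q̂, f̂, log-likelihoods
  and `summary()`), and Evanno ΔK selection of the number of
  subpopulations, with accessions assigned only when an admixture
  coefficient Qᵢ strictly exceeds 0.8.
* **Proximity** — a Yates-corrected 2×2 chi-square tests whether primer
  occurrences are enriched within 100 kb of a focal gene set relative to
  random control genes.

The bundled simulator (`retroscape.simulate`) builds repeat-rich genomes
with elements of known lineage and age, TSDs, nesting, solo-LTR and
fragment decoys, genes, primer sites, 85-nt reads, and admixed
dominant-marker populations — so every claim above is tested as recovery
of planted truth.  See `docs/methods.md` for models, defaults and
limitations.

## Worked example

The umbrella pipeline simulates a 400-kb genome (24 elements of 4 lineages
at 1 and 2 MYA, decoys, genes, planted primer sites), then runs every
analysis stage against it:

```bash
retroscape run --seed 5 --outdir demo
```

which prints the per-stage manifest (abridged):

```json
{
  "simulate":  {"elements": 24, "genes": 40, "reads": 32141},
  "detect":    {"n_predicted": 25, "true_positives": 24,
                "precision": 0.96, "recall": 1.0},
  "annotate":  {"annotated": 25, "autonomous": 24, "undetermined": 0},
  "dating":    {"dated": 25, "saturated_excluded": 0,
                "mean_age_mya": 1.47, "peak_ages_mya": [0.88, 1.88]},
  "abundance": {"mapped_fraction": 0.2779, "truth_element_fraction": 0.2433},
  "irap":      {"primer_sites": 18, "amplicons": 0,
                "selected_k": 2, "k_true": 2},
  "proximity": {"focal_with_hit": 10, "control_with_hit": 3,
                "chi2": 6.042, "p_value": 0.01397}
}
```

Reading it: all 24 planted elements were recovered (one extra call is an
inter-element artifact), all were classified with full domain sets, the
two planted insertion bursts (1 and 2 MYA) appear as the two age-profile
peaks at 0.88 and 1.88 MYA, the read-mapped genome fraction tracks the
24.3% truth (the small
excess is reads from solo-LTR/fragment decoys, which share sequence with
the element library), ΔK recovers the simulated two-subpopulation marker
collection, and the primer sites planted near focal genes produce a
significant 2×2 enrichment (10/12 vs 3/12, p = 0.014).  Re-running with
the same seed reproduces every output byte-for-byte.

Each stage is also a library call and a subcommand
(`retroscape simulate|detect|date|abundance|irap|proximity`); e.g.

```python
from retroscape import detect, read_fasta
elements = detect.detect_elements(read_fasta("genome.fasta"))
```

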