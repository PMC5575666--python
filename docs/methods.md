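# Methods

## Scope and data model

The package operates downstream of read mapping and assembly: its inputs are
a merged transcript set (GTF exon records carrying `transcript_id`,
`gene_id` and an assembler class-code attribute), an FPKM matrix over a
two-group design, optional transcript sequences, and optional tabular
domain/homology hit lists (query id, E-value; the standard 12-column
alignment format is also accepted). Internally all coordinates are 0-based
half-open; GTF I/O converts at the boundary, so window and overlap
arithmetic never special-cases coordinate conventions.

Loci are formed by single-linkage overlap of transcript spans on the same
chromosome *and strand* (matching assembler locus semantics); novelty
classification against an annotation is, by contrast, strand-ignorant span
overlap by default, with exon-level and strand-aware modes available.

## Identification cascade

Six keep-predicates are applied in fixed order, and each removed transcript
is attributed to the first stage it failed:

1. class code equals `u` (intergenic);
2. exon count ≥ 2 **and** spliced length ≥ 200 bp (exactly 200 bp is kept:
   "less than 200 bp" is removed);
3. coding score ≤ 0 on both strands;
4. no domain hit with E < 10⁻⁵ (strict; a hit at exactly 10⁻⁵ survives);
5. no homology hit with E < 10⁻⁵;
6. FPKM ≥ 0.5 in at least one sample (exactly 0.5 is kept: "lower than
   0.5 in all samples" is removed).

The predicates are independent, so reordering stages 2–5 cannot change the
survivor set, only the fate attribution; a test asserts this rather than
assuming it. Transcripts lacking a sequence when the heuristic coding score
is requested fail loudly instead of silently passing stage 3.

**Coding score.** External classifier output (CPC/CPAT-style, sign
convention score > 0 ⇒ coding) is accepted verbatim in `external` mode. The
built-in heuristic scores each strand as
`longest ORF length / transcript length − θ` with θ = 0.3 by default, so
that a transcript whose longest ATG→stop reading frame covers more than 30 %
of its length is flagged coding. θ = 0.3 keeps noncoding transcripts with
incidental short ORFs (a random 1-kb sequence typically carries a
100–250 nt longest ORF, i.e. a fraction of 0.1–0.25) below the cut while
planted coding sequences (ORF fraction 0.8) clear it decisively. Six-frame
translation uses the standard genetic code with stops as `*`; any codon
containing `N` translates to `X` and can neither start, extend, nor
terminate an ORF — conservative and deterministic.

## Differential expression

Per feature, Welch's t on log₂(FPKM + 0.25) between the two groups,
two-sided, with BH adjustment and calls at q < α (default 0.05). Fold
changes are log₂ of the ratio of raw group means with the same pseudocount;
the first-listed group is the numerator (YY in the breed comparison).
Features identical in every sample get p = 1. This is a deliberate,
documented stand-in for assembler-native DE models (which need count-level
data the FPKM matrix no longer carries); externally computed p-values can be
injected per feature so a native DE run can be mirrored exactly.

The pseudocount (0.25) is standard practice for FPKM ratios and keeps
zero-expression features finite. At n = 3 per group Welch's approximate
degrees of freedom impose a practical p-value floor near 10⁻⁴: even
perfectly separated groups rarely reach smaller p, which matters when
choosing strict α for exact-recovery experiments.

## Target prediction and the signed network

**cis.** A potential target is any protein-coding gene whose genomic
footprint (union of its transcripts) lies within 10 kb of the lincRNA span —
strict inequality, gap 0 when they overlap, both directions counted,
strand-ignorant. No co-expression requirement is imposed on cis pairs.

**trans.** All lincRNA × gene pairs with detectable expression (FPKM > 0 in
*every* sample) enter a Pearson screen; BH runs over the full tested pair
family; an edge requires |r| ≥ 0.95 and q ≤ 0.05, keeping r's sign. The
absolute-value rule (rather than r ≥ 0.95 literally) is what makes
discordant ("down-regulated") targets representable at all; a
`positive_only` flag restores the literal reading.

Correlations are computed on **log₂ FPKM** (the detectability filter
guarantees positivity). This matters more than it may appear: a
multiplicative fold-change of 8× between groups, mapped through the
exponential, caps attainable *negative* raw-scale correlations near −0.9 by
convexity, so discordant regulation could never reach the −0.95 bar on raw
FPKM. On the log scale concordant and discordant pairs are symmetric. The
raw-scale screen remains available (`log_scale=False`).

**Direction tallies.** For each differentially expressed lincRNA (DEL), its
differentially expressed targets (DEPTGs) are split into concordant
(fold-change sign matches the DEL's — operationalised as "upregulated by"
the DEL) and discordant. The tally identity `n_up + n_down = n_deptg` holds
by construction; the majority summary counts DELs by which side dominates.
"Upregulated PTG" is nowhere formally defined in the source study; sign
concordance of differential expression is this package's explicit
operationalisation.

**Validation.** Each edge's correlation is recomputed on an independent
expression matrix (18 samples in the emulated design) on the same scale,
reporting per-edge r, p and sign agreement with discovery.

**A documented confounding.** With six pooled samples spanning a group
contrast, any two features that are independently differentially expressed
correlate strongly through the shared group structure. The correlation
screen therefore returns, besides genuinely co-regulated pairs, a population
of co-DE edges — inflated target lists are an expected output of this
design, not a bug. The synthetic ground truth records these confound pairs
separately from planted factor pairs and from null pairs, and the validation
step is what separates them empirically: planted pairs keep their sign in
the independent cohort, co-DE edges do not replicate.

## Enrichment

Per term, the upper-tail hypergeometric probability of the observed overlap
between the query gene set and the term's genes within a declared universe;
BH within each term category (biological process / pathway); results sorted
by p. The EASE-style conservative variant (overlap scored as k−1, floored at
0) is available behind a flag; plain hypergeometric is the default, and
significance is reported at raw p < 0.05 with q also emitted.

## Synthetic data generator

The generator emulates the statistical structure of the emulated study, not
its sequence content:

- **Genome layout.** Two synthetic chromosomes; elements placed sequentially
  with 60 kb spacing so that only deliberately planted cis neighbours fall
  within the 10-kb window (planted gaps: 2–8 kb inside, 12–25 kb outside).
- **Structural profiles.** Exon count = 2 + Poisson, exon lengths
  log-normal; class means default to the published characterisation values
  (novel lincRNAs ≈ 1226 bp / 466 bp / 2.6 exons; known lincRNAs
  1362/451/2.8; coding 1983/228/8.7).
- **Fates.** 20 candidates per removal stage plus 20 retained (12 novel, 8
  overlapping known lincRNAs), 140 in all. Each fated candidate violates
  exactly its fated predicate and passes all earlier ones: wrong class codes
  overlap real genes; stage-3 candidates carry a planted ATG→stop ORF
  covering 80 % of their length; noncoding sequences are rejection-sampled
  until their ORF fraction stays below θ on both strands; hit-table rows use
  E ∈ [10⁻³⁰, 10⁻⁶], with boundary rows at exactly 10⁻⁵ planted on retained
  transcripts; stage-6 candidates draw FPKM uniformly in (0.02, 0.45).
- **Expression.** Log-normal FPKM: log₂ values are a baseline
  (coding ≈ 16 FPKM, lincRNAs ≈ 5 FPKM, spread 1.2) plus signal plus
  N(0, σ) noise with σ = 0.5 by default. Differential expression is planted
  multiplicatively at |log₂FC| = 3 (8-fold, split evenly in direction);
  the simplest model under which a t-test on logs is correctly calibrated.
- **Trans structure.** Each planted pair shares a latent factor:
  `x = b + λ·σ√ρ·f + σ√(1−ρ)·ε` with loading λ = ±1 and target correlation
  ρ = 0.99 on the log scale. Factor group shifts make both ends DE with the
  loading product fixing concordance. Defaults: 8 singleton lincRNA–gene
  pairs (2 negative), one shared group of 2 lincRNAs × 2 genes (yielding
  multi-regulated targets), 4 additional independent DELs, and independent
  DEGs among 15 % of the remaining coding genes. Ground truth lists all
  same-factor pairs as expected edges and all cross co-DE pairs as
  confounds.
- **Validation cohort.** 18 samples drawn from the same latent loadings
  with no group contrast and a wider biological spread, so planted
  correlations replicate and co-DE confounds do not.
- **Determinism.** All randomness flows from one integer seed; identical
  seeds give byte-identical files (fixed float formatting, sorted JSON).

What the generator does **not** emulate: read-level noise, length/GC bias,
assembly artifacts, batch effects, dispersion heterogeneity, or any real
sequence homology (hit tables are declarative). Passing tests demonstrate
the pipeline's logic and statistical calibration under the stated model,
not performance on real libraries.

## Numerical and testing choices

- E-value and window comparisons are strict (`<`), and the 200 bp / 0.5
  FPKM boundaries are kept, exactly as the decision rules are worded.
- BH adjustment delegates to statsmodels; tests compare it elementwise to an
  independent textbook step-up implementation. Pearson r/p delegate to
  scipy; tests compare to a from-scratch covariance/t evaluation at 10⁻¹².
  Hypergeometric tails are checked against exact enumeration with integer
  combinatorics.
- Exact truth-recovery experiments run at σ = 0.05, ρ = 0.9999 and α = 0.005
  — strict enough to exclude null features yet above Welch's p-value floor
  at n = 3. At the default conditions (σ = 0.5, ρ = 0.99, n = 6), a true
  ρ = 0.99 pair realizes |r| < 0.95 in roughly 10 % of draws (Fisher-z
  sampling), so planted-pair recovery is asserted in aggregate (≥ 90 % over
  20 seeds) rather than per pair.
- Null calibration: per-seed Kolmogorov–Smirnov tests of the DE p-values
  against Uniform(0,1) on 50 null matrices (200 features, n = 3 + 3).
  Welch's approximate degrees of freedom leave a small systematic deviation
  visible only when pooling tens of thousands of p-values; per-seed tests at
  the stated resolution pass, and the empirical FDR on mixed fixtures stays
  within α.
- Problem sizes throughout (140 candidates, 120 genes, 20-seed replications)
  are chosen so the full suite and the acceptance script run in seconds
  while keeping every statistical assertion well-powered.

## Known limitations

- The built-in ORF-fraction score is a stand-in for a trained
  coding-potential classifier; on real data, external scores should be
  supplied.
- Welch's t on FPKM is less powerful than count-based models at n = 3 and
  has a p-value floor; the DE stage is best treated as a screen.
- The trans screen's inflated target lists under group contrasts are
  inherent to pooled-sample correlation; interpret edge counts together with
  the validation step.
- Enrichment ignores term hierarchy (no GO graph propagation) and species
  homolog mapping.
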