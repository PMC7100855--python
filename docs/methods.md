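# Methods

## LD estimation from unphased genotypes

For each marker pair the data are reduced to the 3×3 table of joint dosage
counts over samples observed at **both** loci (pairwise-complete deletion —
the simplest defensible policy for unphased panels, applied per pair so a
sporadically missing sample does not shrink the whole matrix). Dosages count
the *empirically* minor allele; the `alleles` metadata column of the HapMap
file is treated as advisory only, and frequency ties break to the
alphabetically first allele so results are reproducible across runs.

The four haplotype frequencies are the maximizers of the multinomial
likelihood of that table under random mating; the only latent structure is
the phase of double heterozygotes, resolved by EM. Allele-frequency margins
are invariant under the EM update and equal the observed allele frequencies
(their MLE), so the estimation is effectively a one-parameter search over
p(AB) in its feasible interval [max(0, pA+pB−1), min(pA, pB)].

Numerical rules:

- convergence when the largest absolute frequency change falls below 1e-8,
  capped at 1000 iterations (cap hits are visible through the reported
  iteration count);
- the EM is started at linkage equilibrium (pA·pB) **and** at two
  near-boundary points of the feasible interval, keeping the
  highest-likelihood solution. The extra starts matter for a measure-zero
  but enumerable family of tables (e.g. all samples doubly heterozygous)
  where the equilibrium point is a stationary point of the likelihood —
  sometimes its minimum on the margin slice — and a single equilibrium
  start would return a non-maximizer;
- exact likelihood ties (symmetric tables admit two maximizers) break
  toward the larger p(AB), i.e. the coupling solution, purely for
  determinism;
- a pair is flagged `monomorphic` when either locus has allele frequency 0
  or 1 among the jointly observed samples, and `insufficient_data` when no
  sample is observed at both loci. Flags are data, not exceptions: the
  triangle matrix always stores n(n−1)/2 entries.

D, r² and D′ follow the standard closed forms (see README); D′ is reported
as |D′|, the heatmap convention. The all-pairs path vectorizes the same EM
across every pair simultaneously (indicator-matrix products give all 3×3
tables at once; an active-set loop retires converged pairs), and is verified
against the scalar implementation in the tests. A deliberately independent
oracle — dense grid search of the same likelihood over p(AB)
(`gwaslink.reference`) — is used only for validation, never as the
implementation.

The lead-SNP LD vector is computed on the association genotype panel; the
triangle may come from a second panel (`--hapmap-ld`). Cross-panel marker
matching is exact on (chromosome, position) — no fuzzy windows, which could
silently link the wrong markers; unmatched markers are reported and their
linking lines stop at the gene track.

## Scope resolution

A figure is scoped either by an explicit window (chrom, left, right) or by a
transcript with up/down flanks. Windows are closed intervals; genes qualify
by overlapping the window at one basepair or more. Flanks are strand-aware:
`up` always extends the 5′ (promoter) side, so on a minus-strand transcript
it grows the genomic right edge — this matches the promoter-analysis use
case of flanking windows. The lead SNP is the user's marker if given, else
the smallest p-value, with ties broken by position then name so plots are
deterministic under row reordering. The significance comparison
−log₁₀(p) ≥ threshold is boundary-inclusive (with a 1e-12 guard against
decimal-to-binary rounding at exact boundaries such as p = 1e-5 vs 5.0).
Linking lines default to the whole threshold-passing set; `link2gene` /
`link2LD` selections override the two segments independently.

## Figure geometry

The layout is computed into a `FigureSpec` before any drawing, with no
randomness anywhere, so identical inputs give identical geometry and
re-rendered SVGs are byte-identical (matplotlib's hash salt is pinned and
timestamps stripped). The three layers share one x-axis in basepairs; layer
y-extents are fixed fractions of the scatter height. The triangle uses
**equal index spacing** (Haploview convention): marker k of an n-marker
panel sits at index k, the cell for pair (i, j) is a half-unit diamond
centred at x = (i+j)/2, y = −(j−i)/2 index units below the top, and the
cells tile the half-matrix without overlap. Linking lines absorb the
genomic-to-index distortion between the gene track and the triangle. LD
values are binned into five intervals (0, .2], (.2, .4], (.4, .6],
(.6, .8], (.8, 1] (0 joins the first bin); bin colors are configurable and
R-style `grayNN` names are accepted alongside matplotlib colors. Pairs with
no estimate use a separate NA color. Overlapping genes are stacked into
lanes greedily by start position; label placement uses a fixed-iteration
deterministic repulsion. Whether scatter points are colored by lead-SNP LD
is tied to the `leadsnp` flag.

## Synthetic data

The generator exists so every layer is testable without external downloads;
its defaults mirror the scale of a typical maize regional analysis
(a 400 kb window, ~200 markers, 104 samples, ten genes).

Genotypes follow a haplotype-block model: a block's sites share one minor
allele frequency f ~ U(maf_range); each of the 2N haplotypes copies one of
two ancestral patterns (all-minor with probability f) and every site is
independently resampled from Bernoulli(f) with probability ε. This gives
exactly E[D] = (1−ε)²·f(1−f) for any within-block pair, hence
|D′| = (1−ε)², so a target |D′| = d is hit by ε = 1 − √d with no tuning;
blocks are mutually independent, and haplotypes are paired at random into
unphased diploids — exactly the data-generating process the EM assumes. The
equal-frequency structure is what makes exact |D′| control possible; its
price is that min(pA·pb, pa·pB) sits at its kink, so the parameter-recovery
check estimates D_max by the generator-model MLE f̄(1−f̄) (pooled margin)
rather than the min form, avoiding an O(1/√n) upward bias that a
phased-counting estimator exhibits equally. Phenotypes are
effect·dosage + N(0, 1) noise, tested per marker with the Pearson t test
(score-test equivalent at these sample sizes).

What the generator does **not** emulate: demography and relatedness
(no population structure, so no inflation of the null), genotyping error,
allele-frequency spectra skewed toward rare variants, LD decay with
distance within a block, or multi-allelic sites. Passing tests therefore
demonstrate correctness of the estimators and geometry on well-behaved
panels, not robustness to structured or noisy real data.

## Problem sizes in the checks

The acceptance checks run the full-scale pair-count identity (2355 markers ×
104 samples, 2,771,835 pairs), the complete enumeration of genotype tables
with up to 6 samples against the grid oracle, |D′| recovery at n = 500 with
targets {0.4, 0.8, 1.0}, cross-block independence at n = 5000, a 500-marker
null scan and 100 seeded power replicates, and all eight documented command
translations on generated fixtures.

## Known limitations

- HapMap and GTF are the only genotype/annotation inputs (no VCF/PLINK);
  association tables are delimiter-sniffed with remappable columns.
- LD is biallelic-only; markers with >2 observed alleles are dropped at
  load (and counted).
- |D′| against a uniform [0,1] color scale saturates for small panels;
  r² is the default measure.
- The figure is static (PNG/SVG/PDF); no interactive output.
- Very large triangles render slowly in vector formats (the 2355-marker
  matrix is meant for computation/export; plots are intended for windows of
  a few hundred markers).
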