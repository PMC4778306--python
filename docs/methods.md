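# Methods

## Population and meiosis model

RILs descend from two fully inbred founders (labelled A and B; A is the
female parent of the cross, and additive effects downstream are
sign-anchored so a positive effect means the B allele increases the trait).
F1 individuals are advanced by single-seed descent: one selfed offspring per
generation, default 10 generations (F11). Meiosis is interference-free —
the crossover count on a chromosome is Poisson with mean equal to its map
length in Morgans, crossover positions are uniform on the genetic scale, and
a gamete starts from a randomly chosen homologue and alternates at each
crossover. Genetic and physical coordinates are related linearly within a
chromosome by default; the relation is pluggable per chromosome so that
recombination-suppressed regions (centromeres) can be emulated.

Two closed-form consequences are used as permanent checks: the expected
residual heterozygous genome fraction after g selfing generations is 2⁻ᵍ
(≈ 0.098 % at F11), and the expected junction count per line approaches
2·L Morgans (the Haldane–Waddington map-expansion factor for selfed RILs;
≈ 31 junctions for a 15.5-Morgan genome).

The default genome (`GenomeSpec.default_maize`) uses the ten maize
chromosome lengths of the target experiment (2059.7 Mb, 1545.65 cM). The
default population size is 314 lines, matching the reference population.

## GBS observation model

Genotyping is modelled at the call level, not the read level (no FASTQ,
barcodes or restriction sites). Each segregating SNP is observed
independently per line with probability `observe_rate` (default 0.05,
emulating the ~5 % of parental SNPs a 0.07×-coverage line touches);
an observed call equals the underlying founder allele except with
probability `allele_error_rate` (default 0.002) it is flipped; heterozygous
segments emit either allele with probability ½, because a single
low-coverage observation cannot reveal heterozygosity. Unobserved entries
are missing. Consequently the caller treats H and N calls identically
(excluded from window counts), mirroring practice of treating unexpected
het calls in a RIL as missing data.

## Phenotype model

For each trait, y(line, env, rep) = μ + env offset + Σq a_q·x_q(line) +
gxe(line, env) + ε, with x_q ∈ {−1, +1, 0} for {A-hom, B-hom, het} at the
QTL position, gxe ~ N(0, σ²ge) per line×environment and ε ~ N(0, σ²) per
replicate. The default plant-architecture truth (three traits over three
environments, two replicates) uses grand means and environment offsets on
the observed scale of the reference experiment (plant height ~209 cm, ear
height ~78 cm, internode number ~15) and variance settings giving line-mean
heritabilities of roughly 0.81–0.92, the range typical of these traits.
What the generator does *not* emulate: polygenic background beyond the
planted QTL, non-uniform recombination, segregation-distortion hotspots,
read-depth heterogeneity, and shared micro-environment (block) effects —
so passing recovery tests demonstrates correctness of the estimators under
the stated model, not robustness to every property of field data.

## Sliding-window caller

Windows of 15 informative SNPs (step one SNP) are labelled A or B when at
least 11 SNPs come from one parent, else heterozygous. When a chromosome
holds fewer than 15 informative SNPs a single truncated window is used with
the proportionally scaled threshold ⌈(11/15)·n⌉, preserving the ~73 %
supermajority. Equal-label window runs merge into blocks with no smoothing
of short runs.

Two geometric conventions required decisions:

* **Block partition.** Window labels flip where counts cross the threshold,
  which happens symmetrically around a clean junction only in terms of
  window *centres*; the partition boundary between two runs is therefore
  drawn at the centre of the left run's final window. (Using window starts
  biases every junction estimate left by about half a window.)
* **Breakpoint uncertainty.** A junction between two runs is localised
  between the last SNP covered only by the left run's windows and the first
  SNP covered only by the right run's windows; the point estimate, when one
  is needed, is the interval midpoint (unbiased under a uniform prior).

A consequence of the 11-of-15 rule worth stating explicitly: a clean
homozygous junction always produces a short run of heterozygous windows
while the counts travel between the two thresholds. Breakpoint extraction
is faithful to the block structure (one breakpoint per adjacent block pair,
heterozygous transition blocks included), so called breakpoints per line run
at roughly twice the true junction count on clean data. Observed breakpoint
counts in real GBS experiments also exceed the 2·L expectation, though by a
smaller factor; the caller's transition behaviour and residual observation
noise are both plausible contributors and the package does not attempt to
resolve the attribution.

## Bin construction

A recombination *event* for bin purposes is a transition between
consecutive homozygous blocks of different label (intervening heterozygous
transition blocks are skipped; hom–het–hom runs returning to the same label
are not events), localised at the midpoint of the enclosing SNP gap. Grid
intervals (100 Kb) containing an event of any line are boundary intervals;
a bin is a maximal run of clean intervals together with the boundary run
immediately before it (boundary intervals attach downstream so bin starts
align with recombination). The alternative literal rule — marking every
grid interval overlapped by a raw breakpoint *uncertainty* interval — is
available as `boundary_mode="overlap"`, but at GBS sparsity those intervals
span hundreds of kilobases to megabases and the rule degenerates (most of a
chromosome becomes boundary and collapses into a handful of bins), so the
midpoint rule is the default.

Per line, a bin's genotype is the label of the block covering the majority
of the bin's base pairs, with one asymmetry: homozygous coverage wins over
heterozygous coverage, and H is assigned only where no homozygous block
overlaps the bin. Without this rule the caller's het transition runs would
label the junction bin H for exactly the recombinant line, and the
recombination would then be invisible to the pairwise map estimator below.
Genuine residual heterozygous segments (which span whole bins) are still
reported as H.

## Genetic map

Adjacent-bin distances use the pairwise estimator R̂ = mismatches /
informative pairs over lines homozygous and non-missing at both bins,
corrected to the meiotic scale by r = R̂/(2(1−R̂)) and converted by
Kosambi's d = 25·ln((1+2r)/(1−2r)). R̂ is clamped at 0.49 and r at 0.4999;
an interval with zero informative pairs contributes 0 cM and is recorded as
a map-gap warning. This pairwise chain approximates the multipoint
(EM/`est.map`-style) estimation used with real data; it is accurate when
transition zones are narrow relative to bins (dense markers, low
missingness). At error-free full observation, simulated chromosome lengths
are recovered within 10 % (the residual downward bias comes from double
crossovers inside single bins and junctions too close to chromosome ends to
be called). At very sparse observation the het transition zones exceed bin
widths and the pairwise estimator undercounts visibly — a known limitation;
multipoint estimation is out of scope.

Map summaries report the average adjacent-marker distance as genetic length
divided by marker count (the convention of the reference map tables, which
divide by n rather than n−1), and report both the genome-total and
mean-of-chromosome average physical spacing, since the two differ.

## QTL scan

Bin genotypes code as x = −1 (A-hom), +1 (B-hom), 0 (het). Missing
genotypes, and optional pseudomarkers every `step` cM, take the conditional
expectation of x given the line's nearest flanking homozygous bins under a
Markov model along the chromosome whose transition probability across a map
gap d is the RIL mismatch probability 2r/(1+2r) with r = Kosambi⁻¹(d) —
equivalent to enumerating the two-locus fixed-RIL genotype table.
Heterozygous observations are used as x = 0 at their own bin but skipped as
flanks (the two-point table applies to fixed lines).

At each evaluation point the trait is regressed on x:
LOD = (n/2)·log₁₀(RSS₀/RSS₁), PVE = 100·(1 − RSS₁/RSS₀), and the additive
effect is the fitted slope (the half-difference between homozygote class
means under ±1 coding; a flag for the full allele-substitution convention is
deliberately not provided — callers can double the value). Genome-wide
thresholds come from permuting phenotypes across lines, sharing each
permutation across all evaluation points and recording the genome-wide
maximum LOD; the threshold is the empirical 1−α quantile (defaults: 1000
permutations, α = 0.05) and the declared threshold never drops below a LOD
floor of 3.5. Support intervals are the maximal contiguous region around a
peak with LOD ≥ peak − 1.5, reported as flanking markers and their outer
physical coordinates; peak ties break toward the lower physical coordinate.

Peaks of the same trait whose support intervals overlap across environments
merge into one named QTL (q{TRAIT}{chrom}, with -1/-2 suffixes by position)
carrying environment tags and the mean LOD/PVE/effect over member
detections. QTL detected in ≥ 2 environments are flagged stable. Per
chromosome, QTL of different traits with overlapping intervals chain into
pleiotropic regions (connected components of the overlap graph) whose
interval is the union of member intervals. A single-QTL scan is the core;
cofactor-based (composite) scanning is not implemented — with the identical
permutation protocol the single-QTL scan is the auditable common ground of
the family of interval-mapping variants.

## Variance components and heritability

On a balanced line × environment × replicate design, method-of-moments
components come from the expected mean squares: σ² = MS_error,
σ²ge = (MS_gxe − MS_error)/r, σ²g = (MS_g − MS_gxe)/(e·r); negative
estimates are clamped to zero with a warning, and unbalanced tables raise
rather than silently switching estimators. Broad-sense heritability on the
multi-environment line-mean basis is H² = σ²g/(σ²g + σ²ge/e + σ²/(e·r));
the error term is divided by e·r (the standard line-mean formulation — the
alternative reading σ²·r/e of an ambiguously typeset formula is
dimensionally implausible and rejected). Skewness and kurtosis are the
bias-adjusted sample statistics with kurtosis reported as excess kurtosis;
CV = 100·SD/mean; trait correlations are Spearman rank correlations with
mid-ranked ties.

## Numerical and reproducibility conventions

Physical coordinates are 1-based inclusive in all reports; the 100-Kb grid
is half-open internally. Call codes are A=0, B=1, H=2, N=3 throughout. One
root seed drives every stage; per-line and per-stage streams are spawned
deterministically (`numpy` SeedSequence), so populations are reproducible
under any generation order and a pipeline re-run is byte-identical. The
simulation studies in the test-suite and acceptance script run at reduced
problem sizes — 2–3 chromosomes of 100 Mb/120 cM, 1500–3000 SNPs per
chromosome, 150–314 lines, 200 permutations — chosen so each study still
leaves the estimators' sampling error well inside the asserted tolerances.
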