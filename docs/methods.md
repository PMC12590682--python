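# Methods

This note documents the models and procedures `microcat` implements, the
defaults and why they are set where they are, what the synthetic fixtures
do and do not emulate, and the numerical choices a maintainer should know
about. Nothing here states a result the test suite or
`scripts/acceptance.py` does not itself compute.

## Catalogue model

A catalogue is a set of genes (id, length, optional sequence), MSPs
(co-abundance gene clusters with an ordered list of signature genes,
rank 1 = most central), functional annotations in namespaced tables
(`KO`, `CAZyme`, `ARG_resfinder`, `ARG_resfinderFG`, `ARG_pcm`,
`uniref90`; terms are opaque strings, so GMM/GBM modules mixing
vocabularies need no special casing), and functional-module definitions.
Catalogue file formats are a documented TSV dialect with a YAML manifest;
loading cross-validates all references and rejects duplicates, dangling
ids and genes claimed by two MSPs. Signature-rank ties are broken by
lexicographic gene id so every reduction is reproducible. `fast` mode
restricts the catalogue to signature genes only — the lightweight
reference for rapid profiling.

Module grammar: whitespace at the top level separates mandatory steps,
a comma separates alternatives within a step, `+` joins jointly-required
terms, parentheses group. Whitespace *inside* parentheses acts as
conjunction, identical to `+`; this keeps the internal representation a
flat list of steps, each a set of alternative term-sets, while still
accepting nested grouping such as `K1+(K2,K3)` (which distributes to the
alternatives `{K1,K2}` and `{K1,K3}`). `enumerate_configurations` guards
the Cartesian product at 10,000 configurations; completeness evaluation
never needs the product (see below).

## Counting

Reads are grouped per read unit (each mate of a pair is an independent
unit by default — an option collapses proper pairs to fragments) from
name-grouped SAM/BAM. Identity is `(aligned_length − NM) / aligned_length`;
records below the threshold (0.95 complete, 0.98 fast) are dropped, and
within a group only the best alignment per gene is kept so `total` mode
never double-counts a read on one gene. Secondary and supplementary
alignments participate (multi-mapping is the point of shared counting);
duplicate-flagged records do not. Records without an NM tag are rejected
and counted in the run log.

Shared counting is single-pass: apportionment weights come from the final
unique counts over the same filtered groups, not from iterative
refinement. The invariants — mass conservation, `unique ≤ shared ≤ total`
per gene, equality with total when every read is unique — are enforced by
property tests against a naive per-read oracle.

## Taxonomic reduction

Coverage normalization divides counts by the effective gene length
`L_eff = L − ℓ + 1` (ℓ = read length, default 80 nt — the number of start
positions a full-length read can occupy) and multiplies by 100; genes
shorter than ℓ fall back to their raw length with a warning. FPKM uses
retained fragments unless a total is supplied.

MSP abundance is the arithmetic mean of the normalized values of the top
`n_signature` (default 100) signature genes, **including zeros**: the
detection rule is a separate gate, so the denominator is fixed and
abundance scales with signal rather than with how many genes happened to
be detected. A switch (`include_zeros=False`) gives the detected-only
mean for sensitivity analyses. Detection means value > 0 (≥ 1 mapped
read). An MSP is zeroed when fewer than `detection_fraction` (0.10
complete / 0.20 fast) of the used signature genes are detected; the
comparison carries a 1e-9 slack so that exactly the threshold fraction
counts as detected (binary floating point would otherwise misclassify
the 10-of-100 boundary).

## Functional profiling

Gene-level term abundance sums the normalized abundance of every gene
carrying the term (a gene with several terms contributes fully to each).
MSP-level abundance sums the abundances of MSPs that harbor at least one
*detected* (≥ 1 raw mapped read — detection is deliberately based on raw
counts, not normalized values) gene with the term.

Module completeness is the fraction of steps satisfied, maximized over
alternative configurations. Because each step chooses its alternative
independently, that maximum decomposes into a per-step check (is any
alternative fully present?), which the tests verify against exhaustive
enumeration on random modules. Completeness counts *steps* as the
functional units; an alternative reading counts individual terms inside
multi-term complexes, which would score partial complexes — we do not.
Carrier status is strict (`completeness > 0.9`): a completeness of
exactly 0.90 is not a carrier. Module potential is the summed abundance
of carriers among detected MSPs, with the carrier list emitted per
sample. The ARG ratio is the fraction of detected genes annotated in any
requested ARG namespace (union by default, per-namespace on request);
unclustered genes participate in gene-level profiles and the ARG ratio
but have no MSP to carry them.

## Strain stage

**Pileup and consensus.** The caller is an internal per-site allele
counter over signature-gene alignments (the same identity filter and
per-read grouping as counting), with a base-quality floor of Q13. Sites
are independent, indels are ignored (aligned match positions only). Per
site: depth < 3 → `N`; otherwise the allele set is the reference base
when it has ≥ 1 supporting read plus every alternate at frequency ≥ f;
an empty set falls back to the majority base (ties → code of the tied
set); multi-allele sets are written as IUPAC ambiguity codes (a four-way
tie degenerates to `N` and is thereafter uninformative). f = 0.1 is the
default "mixed" configuration; f = 0.5 keeps dominant alleles only.

**Breadth filter.** Breadth is the fraction of gene positions at depth
≥ 3 (the same threshold as masking, for internal consistency). A
sample-specific MSP passes when ≥ 80 of its 100 signature genes (scaled
as `ceil(80/100 × n)` for smaller MSPs) reach breadth ≥ 0.5.

**Distance.** Consensus sequences are inherently aligned (substitutions
only), so the pairwise divergence matrix F is tallied over sites that are
non-`N` in both samples; at least 10 informative sites are required. An
ambiguous site pair spreads weight `1/(|A|·|B|)` over the Cartesian
product of its IUPAC sets — unbiased fractional counting, chosen because
no convention is canonical. The mutation rate is the closed-form
paralinear/GTR distance with empirical equilibrium frequencies:
symmetrize and normalize F to F̂, set Π = diag(π) with π the marginals of
F̂, and take `d = −Σ_i π_i [log(Π⁻¹ F̂)]_ii` (matrix logarithm via scipy).
Bases absent from both sequences are dropped from the matrix. Identical
sequences give exactly 0; a non-real logarithm (saturation, e.g. a state
never observed matching) yields a missing value with a reason code
rather than a number. In the equal-frequency limit the estimator reduces
to the JC69 closed form `−(3/4)ln(1 − 4p/3)`, which the tests use as an
independent oracle. The informative-site count is over the per-MSP
concatenate of signature genes.

**Clustering and engraftment.** Complete-linkage agglomerative clustering
cut at a mutation-rate height (default 5e-3, ~99% nucleotide identity);
samples with any missing pairwise value are removed worst-first and
reported unclustered. The engraftment rate of a donor/recipient cohort is
the fraction of conspecific strain pairs (every MSP with a computed
donor–recipient distance) at mutation rate ≤ 1e-4.

## Synthetic fixtures

The generator emulates: random gene catalogues with ranked signature
genes and namespaced annotations; near-duplicate gene copies (1%
diverged, non-signature only) that produce honest multi-mapping with
correct NM values; communities sampled read-by-read proportional to
MSP abundance × gene length; strain variants as seeded substitution
processes (a variant is a pure function of catalogue, MSP, rate and
seed, so cohorts can share or not share strains by construction); and a
base-caller error model in which each base draws a quality from a
two-tier mixture (Q40/Q10 by default) and is miscalled with probability
10^(−Q/10), calibrated so the raw error rate equals `error_rate`
(default 1%). Miscalls therefore concentrate on low-quality bases, which
the pileup's Q13 floor excludes — the property real quality-aware
variant callers rely on.

Default study conditions used by the tests and the acceptance script:
5 MSPs × 120 genes (300–1500 nt) + 20 unclustered genes and 10,000 reads
for taxonomic recovery; 3 MSPs × 40 signature genes (800–1200 nt) at
~60× coverage for strain discrimination (confident consensus genotyping
is a high-coverage regime; coverage ramps down toward gene ends, and at
60× the window where a single high-quality miscall can reach the 10%
allele frequency is small); 200 reads for the counting oracle; 100 kb
for distance recovery.

Not emulated: indels and structural variation, GC/positional coverage
bias, chimeric reads, within-sample strain mixtures (each sample carries
one variant per MSP), host contamination, and real inter-species
sequence homology (multi-mapping only occurs between planted duplicate
copies). Passing recovery tests therefore demonstrates correctness of
the counting/reduction/consensus/distance machinery under a clean
substitution-and-error model, not robustness to every artifact of real
libraries.

Bray–Curtis on log-transformed profiles uses `log10(x + pc)` with
pseudocount `pc = 0.1 ×` the smallest positive relative abundance
observed in either profile, since no convention is fixed for the
transform.

## Numerical choices and degenerate inputs

- Threshold comparisons that sit on exact boundaries (identity 0.95/0.98,
  detection fraction, allele frequency ≥ f) are inclusive, with a 1e-12 …
  1e-9 slack where binary floats would flip the printed-precision
  boundary.
- Group iteration, signature ordering and output tables are sorted so
  identical inputs give bit-identical outputs.
- All-zero MSP profiles refuse relative-abundance normalization; zero
  detected genes refuse the ARG ratio; fewer than two passing samples
  yield an empty distance matrix with a notice; zero eligible
  donor–recipient pairs yield a missing engraftment rate.
- Estimated distances are clamped at 0 (the log-det form can go
  marginally negative at machine precision for near-identical inputs).

## Configuration and orchestration

`RunConfig` carries every tunable with its default; fast mode forces
identity 0.98 and detection 0.20 unless explicitly overridden. Every
output file starts with a header comment carrying the tool version, a
hash of the analytical parameters (the output directory is excluded so
relocated runs remain comparable) and the seed. Per-sample failures in a
sample set are isolated and reported; the CLI maps them to exit code 3.
All randomness in the fixtures flows through one seeded generator.
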