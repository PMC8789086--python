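# Methods

`popgenkit` re-implements, at desk scale and against synthetic truth, the
analysis chain used in continental surveys of Indigenous American
population structure: data curation, relatedness and ancestry filtering,
f-statistics and admixture graphs, IBD sharing networks stratified by
time period, founder-event dating, effective-population-size history,
runs of homozygosity, and hierarchical AMOVA. This note records the
models, the parameters that matter, and the choices made where the
design was genuinely open.

## Data model and QC

Genotypes are ALT-dosage matrices (`0/1/2`, `-1` missing) over biallelic
autosomal SNPs with 1-based bp coordinates and a piecewise-linear bp→cM
map (constant extrapolation beyond the anchors). Phased panels carry a
`2n x S` haplotype matrix whose pair sums must equal the genotypes.

QC applies, in order: per-SNP missingness (default max 5%), per-sample
missingness (max 10%), optional trimming of SNPs within 2 Mb of
chromosome-arm ends, and a Hardy–Weinberg exact test (mid-p; the
removal threshold used for array data is p ≤ 1e-8). The rare-allele
fraction (MAF < 1%) is reported, not filtered. LD pruning is a greedy
left-to-right scan over 50 kb windows stepping 10 kb, dropping the
later SNP of any pair with dosage r² > 0.2; r² uses pairwise-complete
observations. The mid-p exact HWE test was chosen over the chi-square
because it is the array-QC standard and behaves correctly for
monomorphic and low-count sites; it is unit-tested against direct
enumeration of the conditional heterozygote distribution.

PLINK-text output uses a 6-column `.map` (ref/alt appended to the
standard 4 columns) because the bare dialect cannot encode the allele
coding of monomorphic sites; the reader accepts both forms.

## Synthetic data

The generator is a discrete-generation Wright–Fisher forward simulation
of diploid demes. Founder haplotypes are drawn site-wise from
Balding–Nichols allele frequencies: ancestral frequencies uniform on
(0.05, 0.95), an optional group-level divergence F_group, then a
per-deme divergence F_deme, giving hierarchical structure (pairwise
Hudson F_ST between demes ≈ the mean of their divergences plus
accumulated drift ≈ t/2N per generation). Recombination is Poisson on
the cM map without interference — the assumption every downstream
closed form makes. Splits found new demes from a parent's gene pool;
admixture pulses redirect each parental draw to the source deme with
probability α; bottlenecks override deme size over a generation window.
Ancestry labels (founding deme) ride along through every meiosis, so
local-ancestry tracts in the output are exact.

Forward simulation was chosen over coalescent machinery so that planted
IBD/HBD/ROH segments, pedigree relatives, and ancestry tracts are exact
by construction. `plant_fixtures` edits a phased panel directly: copying
a haplotype stretch between individuals creates IBD with known
coordinates; copying one haplotype over its partner creates ROH;
children are regenerated by Mendelian transmission with map-aware
crossovers. The default desk-scale regime is 2–5 demes of ≤ 2,000
diploids, 1–8 chromosomes of 50–100 cM, and 10³–10⁴ SNPs; what passing
tests show is therefore correctness of the estimators under their own
model assumptions, not robustness to array ascertainment, genotyping
error beyond the planted rates, or phasing error (input is truth-phased;
statistical phasing is out of scope).

A separate generative draw (`simulate_ibd_segments`) produces IBD
segment lengths directly from an Ne trajectory: one coalescence time
per haplotype pair from the discrete-generation hazard 1/(2N_g),
Poisson(2gG) breakpoints on a genome of G morgans, maximal tracts
between breakpoints. It is the independent oracle for the closed-form
spectrum and a fast segment source for trajectory-fit tests.

## f-statistics and admixture graphs

Per-SNP moments f2 = (a−b)², f3(C;A,B) = (c−a)(c−b),
f4(A,B;C,D) = (a−b)(c−d), averaged over SNPs with complete frequencies
in all argument populations (listwise rule, exposed as
`bias_correction` and usable per call). f2 and f3 receive the standard
finite-sample corrections h_X = x(1−x)/(n_X−1) with n in haplotypes.
Standard errors come from a weighted delete-one block jackknife over
contiguous 5 cM map blocks (weights = block SNP counts); 5 cM mirrors
common practice for array data. Outgroup-f3 distances are 1 − f3 with
the outgroup as the target population; individuals may be treated as
populations of one for individual-level distance matrices.

Expected graph f-statistics use edge-usage probabilities propagated
leaf→root (admixture nodes split lineage mass by their weights):
E[f4] = Σ_e ℓ_e (p_A−p_B)(p_C−p_D). Fitting minimizes the worst
absolute residual Z — the field's model-selection statistic — via a
least-squares warm start (squared-transform for lengths ≥ 0, logistic
for weights) followed by a Nelder–Mead polish of
max|Z| + 10⁻⁴ Σ Z² (the small quadratic term breaks minimax ties).
Non-identifiability is flagged from rank deficiency of the numerical
prediction Jacobian at the optimum. Placement search attaches a test
leaf to every edge (one-way) and every edge pair through a fresh
admixture node (two-way); ranking prefers any good one-way fit
(worst |Z| < 3), then lower worst |Z|, then fewer outliers —
single-origin models are the more parsimonious explanation.

## Ancestry, ordination, geography

Supervised ancestry maximizes the binomial mixture likelihood of each
sample's alleles under fixed source frequencies by EM on the simplex
(uniform start, relative tolerance 1e-6, 2,000-iteration cap; reference
frequencies clipped to [1e-6, 1−1e-6]). A sample is flagged admixed
when its non-focal mass exceeds 1% (the ≥ 99% focal-ancestry filter).
PCA standardizes dosages by √(p(1−p)) with per-SNP mean imputation of
missing calls; classical MDS is Torgerson double-centering, dropping
negative-eigenvalue axes. Great-circle distances are haversine with
R = 6371.0088 km. Isolation-by-distance regresses upper-triangle
genetic on geographic distances and reports the Mantel permutation p
(label permutation, p = (exceed+1)/(n_perm+1)) as primary — the naive
OLS p ignores the non-independence of matrix entries and is labelled
descriptive only.

## Relatedness and ROH

PI_HAT is the genome-wide method-of-moments IBD estimator: per-pair IBS
counts against their allele-frequency expectations under IBD 0/1/2,
solved sequentially, truncated to [0,1], renormalized;
PI_HAT = P2 + P1/2. The original tool's small-sample allele-frequency
correction factors are omitted; calibration is anchored instead to
planted parent-offspring and full-sib pairs (several chromosomes are
needed before realized sib sharing concentrates near 0.5 — with one or
two chromosomes its standard deviation is of order 0.2). The maximum
unrelated subset (threshold PI_HAT > 0.375, taken at face value) is
exact branch-and-bound maximum independent set on related-pair
components of ≤ 30 vertices and greedy highest-degree removal beyond,
with the mode reported and ties broken toward the lexicographically
smallest id set.

ROH calling is the classic scan: 50-SNP windows with ≤ 1 heterozygote
and ≤ 5 missing calls; a SNP's score is the fraction of spanning
windows that pass (terminal SNPs use the windows available); runs where
the score ≥ 5% are split at > 100 kb gaps and filtered to ≥ 500 kb and
≥ 1 SNP per 50 kb on average. Reported segments are trimmed to start
and end on homozygous calls. F_ROH = summed ROH length / genomic span
covered by the SNPs; population values are means of individual ones.

## IBD segments

Detection operates on phased haplotype pairs. Each site scores
log₁₀ P(obs|IBD)/P(obs|background): matches (1−ε vs p²+q²), mismatches
(ε vs 2pq), ε the error tolerance (default 0.002). All maximal
positive-scoring subsegments (Ruzzo–Tompa) with length > 2 cM and score
> 3 are emitted; HBD is the same scan on an individual's own pair.
Equivalence with any external detector is not claimed — acceptance is
against planted truth, where recovery is exact to a SNP on clean
fixtures. Gap merging joins same-pair segments separated by ≤ 0.6 cM
with ≤ 1 opposite-homozygote site in the gap (the panel is an optional
argument because discordance counting needs genotypes).

Local ancestry assigns 0.2 cM windows by source likelihood and smooths
labels with a Viterbi pass (switch probability 0.01 per window). The
smoothing is essential, not cosmetic: at F_ST 0.1 and ~10 SNPs per
window the optimal independent-window classifier errs on ~20% of
windows, so any usable tract caller must borrow strength across windows
— this is the simplified stand-in for the reference tool's smoothing.
Posteriors reported per tract are the pre-smoothing normalized window
likelihoods. Ancestry masking keeps a segment when at least
`min_overlap_frac` (default 1.0) of its span is target-labelled on both
participating haplotypes.

Segment ages use E[generations] = 3/(2I), I in morgans, at 28
years/generation; sharing periods split at ≤ 8.4 cM (pre-Columbian),
(8.4, 28] (colonial), > 28 cM (recent) — 8.4 cM ↔ ~500 y and
28 cM ↔ ~150 y under that conversion. Sharing networks normalize both
segment count and summed cM by the product of the two population sizes
(the within-population diagonal uses n·n for consistency with the
product rule — a documented convention); pairs averaging ≤ 5 cM are
excluded and recorded. Length-category summaries use lower-inclusive
bins 1–2, 2–4, 4–8, 8–16, > 16 cM.

## Demography

The founder-event statistic is the allele-sharing correlation between
site pairs at genetic distance d, computed from centered per-pair
sharing indicators (g₁g₂ + (2−g₁)(2−g₂))/4 within the focal population,
minus the same quantity for focal-versus-outgroup pairs (ancestral
sharing baseline). The corrected curve is fit as A·e^(−2·FA·d) + c with
d in morgans by weighted nonlinear least squares; FA is the founder age
in generations and FI := 100·A — this package's operationalization of
founder intensity as the fitted zero-distance amplitude. CIs come from
a joint bootstrap over chromosomes *and* focal individuals: a
chromosome-only block bootstrap materially under-covers here because
the realized bottleneck pedigree is shared by the whole genome, and
resampling individuals propagates part of that genome-wide variance
into the interval (bin resampling is the single-chromosome fallback,
strictly weaker). FA is declared unidentifiable when
the exponential term fails an F-test (threshold 10) against a constant
curve. At least 5 focal samples are required; an estimator caveat: the
fit is mildly biased young when ongoing background drift (rate 1/2N per
generation) is not small against the event's intensity, so study
conditions for recovery checks use events several-fold stronger than
the background.

Ne history: with piecewise-constant diploid N_g, a haplotype pair
coalesces at g with probability P(g) = (1/2N_g)·Π_{h<g}(1 − 1/2N_h),
and given g the expected number of maximal shared tracts longer than u
morgans in G morgans of genome is (2g(G−u) + 1)·e^(−2gu) — the exact
Poisson-interval count (the common (2gG+1) form ignores the −u edge
term; the difference only matters for long segments, and the exact form
is validated against the generative oracle to within ~5% per bin). The
fit places 10 log-spaced epochs over a 100-generation horizon and
minimizes Poisson deviance of geometric length-bin counts (≥ 2 cM) plus
a quadratic smoothness penalty on adjacent log₁₀ N (weight 1.0), with
L-BFGS-B on log₁₀ N ∈ [0.5, 8]. Bootstrap CIs resample segments;
flags mark < 50 segments (low confidence), very wide CIs, and retained
related pairs (which bias the most recent generations). Trajectory
change between generations is 100·(N_from − N_to)/N_from; growth is a
negative reduction.

## AMOVA

Genotypes decompose into two allele copies per individual; squared
allele-value differences summed over loci give sums of squares for
among-group / among-population / among-individual / within-individual
levels. Variance components use the standard unequal-size nested
expectations (allele counts as units; the within-individual sublevel is
balanced at 2, so its coefficient is exactly 2 at all higher levels).
Negative components are truncated to zero for percentage reporting and
retained raw. Permutation schemes per level: whole populations among
groups; individuals among populations within their group; allele copies
among a population's slots *independently per locus* — whole-row allele
shuffles would be confounded by the coding convention that puts a
heterozygote's ALT allele in the first slot (the observed statistic is
coding-invariant; only the permutation null needs the per-locus
scheme). p = (exceed+1)/(n_perm+1). With few populations per group the
among-group permutation space is tiny (3 distinct arrangements for
2+2), so small p-values at that level require many populations — a
property of the test, not the implementation. Loci with any missing
genotype are excluded.

## Pipeline

`PipelineConfig` carries every threshold with the defaults above and a
master seed from which each stage derives its own stream
(`SeedSequence([master, stage_index])`). Stages run in dependency order
(qc → relatedness/ancestry → f-stats/ordination/ibd/roh →
networks/demography/amova); disabling an upstream stage skips dependents
with a logged warning; outputs are delimited tables plus a JSON manifest
(versions, seeds, per-stage counts). The CLI (`popgenkit`) wraps
`run-all`, per-stage subcommands, and a `simulate` helper; exit codes:
0 success, 2 validation error, 3 numerical failure.

## Validation experiments and problem sizes

`popgenkit.validation` fixes the experiment battery that
`scripts/acceptance.py` and the acceptance tests run: detector
exactness on 3,000-SNP constructive fixtures; f4 null calibration over
100 replicates of a 2,000-diploid panmictic deme (the deme must be
large — close kin among the 24 sampled individuals shift f4
genome-wide, a real violation of the null rather than a numerical one);
founder-age CI coverage over 50 replicates of a 25-diploid, 2-generation
bottleneck ~10 generations back in a deme of 800 (8 chromosomes × 50 cM
for a meaningful chromosome bootstrap); Ne recovery from 30k–60k
generative pairs over 30 morgans; spectrum oracle at 120k pairs; AMOVA
type-I over 200 label-randomized panels (4 populations × 6 diploids ×
200 SNPs, 99 permutations); and a 5-deme serial-founder chain (3
generations at 25 diploids per founding, 4 × 80 cM chromosomes). These
sizes keep each experiment in seconds-to-minutes while leaving the
stochastic acceptance margins wide.

## Known limitations

No statistical phasing, no multi-allelic sites or sex chromosomes, no
ascertainment modelling; the IBD detector and local-ancestry classifier
are validated against planted truth, not against the external tools
they conceptually replace; FI is an amplitude parameterization that is
not calibrated against any external tool's intensity scale; IBDNe-style
trajectory uncertainty from pair non-independence is only partially
captured by segment-level bootstrap.
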