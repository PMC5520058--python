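# Methods

This note documents the models implemented in `paleodog`, the choices made
where the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Units and conventions

All demographic quantities are mutation-scaled: a divergence time τ is the
expected number of mutations per site accumulated since the split, a
population size θ = 4Nμ, and a pair of lineages in a population of size θ
coalesces at rate 2/θ. Calendar time enters only through
`years = g·τ/μ` with generation time `g` (default 3 years for dogs) and
per-generation mutation rate μ. Coordinates are 1-based for pileup/VCF and
0-based half-open for BED/bedGraph. Dosages are derived-allele counts in
{0, 1, 2} with −1 for missing; "derived" is defined against the
outgroup/ancestral state.

## Synthetic data (`simdata`)

`simulate_genotypes` draws genotype panels from the coalescent via msprime
behind an adapter: time is interpreted in mutation units by setting the
mutation rate to 1 and population sizes to θ/4. One simulated base pair is
one panel site; unlinked sites are approximated by a discrete genome with
free-ish recombination (default 2 crossovers/bp/unit time). Recombination
decorrelates recent genealogy quickly, but the deep portions of the trees
stay correlated over long stretches of a single simulated sequence, so
jackknife blocks cut from one sequence understate the sampling error of
drift-sensitive statistics. `simulate_genotypes` therefore takes an
`n_chromosomes` argument that splits the panel into independently simulated
chromosomes (blocks never span chromosomes); analyses whose standard errors
matter use tens of chromosomes with one block per chromosome. Sites hit by more than one mutation are discarded (infinite-sites
emulation); this removes a fraction of sites that grows with total tree
length, so absolute per-site statistics are deflated by roughly
`exp(−L_tree)`. At realistic mutation-scaled parameters (θ ~ 10⁻⁴) this is
negligible; test demographies keep tree lengths small or compare
length-ratio quantities, which cancel the factor. Ascertainment ("sites
variable in panel X") is applied by rejection until the requested number of
sites accumulates.

`simulate_reads` emulates ancient-DNA read stacks: per-site Poisson coverage
(the study-scale default is 9×), read lengths uniform on 50–90 bp (mean
70 bp, matching the 60–70 bp fragment means of ancient libraries; the true
fragment-length distribution is not specified beyond its mean, so uniform is
a stand-in), random strand, and the site placed uniformly within the read.
The template allele is damaged first — C→T with probability d₅(x₅) and G→A
with d₃(x₃) in template coordinates, presenting as the complementary pattern
on reverse-strand reads — and Phred-rate sequencing error is applied
afterwards. This damage-then-error order is a modelling commitment the
caller mirrors exactly.

`simulate_depth` draws per-position depth as Poisson with mean
`base_depth · (CN/2) · bias(GC)` over a known integer copy-number
segmentation and a per-window GC track, with overlap-checked segments.

What the generator does **not** emulate: recombination within loci,
selection, mapping artefacts (multi-mapping, reference bias), indels,
library-preparation-specific damage (single-stranded protocols, UDG
treatment), machine-specific error profiles, and contamination. Passing
tests therefore demonstrate correctness of the inference machinery under the
stated generative model, not robustness to every artefact of real data.

## Damage model (`damagefit`)

Misincorporation tables count reference-C positions read as T by distance
from the 5′ end, and reference-G read as A from the 3′ end, in
template-strand coordinates (reverse reads are complemented first, so both
strands estimate the same decay). The decay is `d(x) = a·exp(−(x^c)·b)` with
amplitude a ∈ [0,1], rate b ∈ (0,50], shape c ∈ (0,5]; x is the 1-based
position from the relevant end. The model sentence in the source literature
is ambiguous about what x denotes; position-from-end is the only reading
consistent with the functional form and with standard misincorporation
plots, and is used throughout.

Fitting is bounded nonlinear least squares (scipy `least_squares`, trf) with
inverse-variance binomial weights `sqrt(n_x / (p̂(1−p̂)))`, a variance floor
at p̂ = 10⁻³ so near-zero tail positions cannot dominate, initialization
a ← proportion at position 1, b ← log-slope over the first 10 positions,
c ← 1, and a default fit range of the first 25 positions. A sequencing-error
floor estimated from interior positions (beyond the fit range) is subtracted
before fitting (flag, default on). All-zero tables return a degenerate model
(a = 0) that downstream code treats as "no damage". The exponential fit
(c fixed at 1) is available as a nested special case; the free-shape fit
never has a larger weighted residual.

## Damage-aware calling (`damcall`)

Per retained read (mapping quality ≥ 15, base quality ≥ 15, qualities capped
at 40 before conversion to error rates), the probability of the observed
base given a true allele sums over the damaged intermediate:
`P(o|a) = (1−p_dam)·P_err(o|a) + p_dam·P_err(o|dam(a))`, with
`P_err(o|b) = 1−ε` if o = b else ε/3. Forward reads damage reference C at
their 5′ positions and reference G at their 3′ positions; reverse reads the
complement (their own 5′ C→T presents as reference G→A). Diploid genotype
likelihood averages the two alleles per read and sums logs over reads, under
a flat genotype prior.

Calling rules: effective depth < 7 → missing; otherwise the argmax genotype
with GQ = Phred-scaled likelihood ratio to the runner-up; a heterozygous
argmax with GQ < 30 is demoted to the best homozygote. After demotion the GQ
is recomputed against the next-best homozygote — the source description does
not say whether the post-demotion GQ is recomputed or inherited, and
recomputation against the homozygote set is the only choice that keeps GQ
non-negative. Ties at the argmax break by fixed genotype order
(AA, AC, …, TT) for determinism. With a = 0 the caller reduces exactly to
the standard flat-prior likelihood caller.

## f-statistics (`fstats`)

Patterson estimators on per-site derived-allele frequencies:
f2 = E[(a−b)²], f3(C;A,B) = E[(c−a)(c−b)], f4(A,B;C,D) = E[(a−b)(c−d)],
D = Σ(a−b)(c−d) / Σ(a+b−2ab)(c+d−2cd). Finite-sample bias corrections
(ĥ = p̂(1−p̂)/(n−1) per frequency) apply to f2/f3 behind a flag (default on;
both modes are provided because its use for pseudo-haploid ancient samples
is a judgement call). f2 of a population with itself is defined as exactly
zero. Missing data are handled complete-case per statistic.

Standard errors use a weighted delete-one-block jackknife (Busing-type) with
block weights proportional to per-block site counts; blocks default to the
panel's block labels (contiguous 500-site chunks from the simulator), with a
helper to cut 5 cM blocks from a two-column genetic map. The f4-ratio is
jackknifed on the ratio itself and flagged unstable when the denominator f4
is within 2 SE of zero.

Expected f-statistics on an admixture graph use admixture-weighted edge
overlap: w_X(e) is the probability a lineage from X drifts through edge e,
and f4(A,B;C,D) = Σ_e (w_A−w_B)(w_C−w_D)·len(e); f2 and f3 are the
corresponding quadratic forms. Graph fitting minimizes
Σ((obs−expected)/SE)² by bounded least squares over edge lengths (≥ 0) and
admixture proportions ([0,1]); statistics with |Z-residual| ≥ 3 at the
optimum are reported as outliers (3 matching the conventional significance
edge), and a rank-deficient Jacobian flags non-identifiability with the
parameter null space attached. Automated scaffold/topology search is out of
scope: the user supplies the graph.

## Divergence dating (`dating`)

Model: single haploid lineages from the ancient sample (A), Europe (E),
India (I) and Asia (S), polarized by an outgroup. With probability α the
ancient lineage is Asian-derived and cannot coalesce with anything below P₃;
with probability 1−α it is European-side and may coalesce with E on
[τ₁, P₂] at rate 2/θ₁ (the European/Boxer ancestral environment; the Boxer
lineage itself is unsampled and P₀ only constrains the ordering
P₀ ≤ τ₁). On [P₂, P₃] all European-side lineages and I interact at pairwise
rate 2/θ₂; above P₃ every remaining lineage (including S and an
Asian-derived A) coalesces at rate 2/θ₃. θ₃ is not part of the published
conditioning set, so it defaults to θ₂; both the expectation and its oracle
use the same value, and the ratio is insensitive to it in the regimes
tested.

The expected count of sites derived exclusively in {A,E} (or {E,I}) is
proportional to the expected branch length subtending exactly that pair.
These lengths are computed exactly on a continuous-time Markov chain over
the 15 partitions of the four lineages: within each epoch the generator is
constant, occupation times integrate via a matrix exponential of the
augmented generator, and the infinite final epoch uses the fundamental
matrix of the absorbing chain. The epoch below P₂ has closed form (only the
A–E pair can merge), so the τ₁-dependence is analytic and the τ₁-independent
tail is cached — a solve costs milliseconds. `expected_ratio` is strictly
decreasing in τ₁ and in α (verified numerically on grids), and equals 1
exactly at the exchangeability point α = 0, τ₁ = P₂.

`solve_tau1` inverts the monotone map by bisection on [P₀, P₂] to 10⁻¹² in
τ₁; a target outside the attainable interval raises an error naming that
interval. Confidence intervals take the extreme solutions over
(parameter draw, ratio-CI endpoint) pairs; a synthetic posterior generator
(independent log-normal perturbations truncated to the ordering constraints)
stands in for resampled Bayesian posterior draws, which are not published.

The independent Monte-Carlo oracle is a vectorized discrete-event simulator
of the same structured coalescent sharing no code with the CTMC expectation;
it doubles as the site generator: panels allocate the requested number of
segregating sites across simulated genealogies proportionally to branch
length (the fixed-S infinite-sites scheme, which length-biases the hosting
genealogies correctly), emitted as pseudo-haploid dosages. The ancient tip
may be truncated at its sample age; both counted patterns depend only on
branches above τ₁, so the age term cancels from the ratio (the expectation
exposes it only through the ancient singleton class).

Counting rules: strict exclusivity (ASIA required ancestral) is the default.
With the strict flag off, the patterns {A,E,S} and {E,I,S} are also counted —
but {E,I,S} is invariant among the modern samples and is removed again by
modern-ascertainment, making the non-strict counts asymmetric under the
default ascertainment; the expectation mirrors whatever flags are set, and
strict mode is recommended. Restricting to sites variable among moderns is
what shields the ratio from genotyping error private to the ancient sample:
flipping the ancient allele at modern-invariant sites provably cannot change
either count.

Calibration: `mu_upper = g·τ₁/age` (the sample must be younger than the
divergence it subtends) and `calibrate_time = g·τ/μ`, so
`calibrate_time(τ₁, mu_upper(τ₁, age, g), g) = age` holds as an exact
identity.

## Copy number (`cnvdepth`)

Window means (3 kb default) of raw depth are regressed on window GC with
statsmodels lowess (span 0.3) inside user-supplied control regions
(≥ 100 control windows required); corrected depth is
`raw · control_mean / loess(GC)` applied genome-wide, with nearest-endpoint
extrapolation (flagged) outside the fitted GC support. Copy number is
`2 · window_mean / control_mean`; a locus call is the median window CN
rounded half away from zero. The estimator is scale-invariant by
construction. The upstream read-splitting/multi-mapping stage of the
original read-depth pipeline is out of scope: the module consumes
per-position depth tracks.

## Trees and loci (`loci_trees`)

Pairwise divergence is the probability two randomly drawn alleles differ,
`d(x,y) = mean(p_x(1−p_y) + p_y(1−p_x))` with p = dosage/2, dropped
pairwise for missing data. Neighbour joining is the Saitou–Nei algorithm
with deterministic lowest-index tie-breaking and negative branch lengths
clamped at zero; bootstrap support resamples genetic-map windows
(default 5 cM) with replacement and counts recovered bipartitions.

Locus classification: the published description ("average reference allele
counts per window") names no decision rule, so the codified rule is centroid
distance — per window, the mean absolute dosage distance of the query to the
dog and wolf panel centroids is compared, calling dog-like or wolf-like when
the margin exceeds 0.25 dosage units and heterozygous-like otherwise, with a
minimum of 20 usable sites. The minor-allele-frequency filter (0.05–0.49,
computed across the combined dog+wolf panels) is applied for classification
as well; note that with equal-sized panels a fixed dog/wolf difference sits
at frequency 0.5 and is removed by the 0.49 cap, so realistic (unequal)
panel sizes are advisable — the synthetic study uses 8 dogs and 4 wolves.
Classification is invariant to consistent allele relabelling.

## Problem sizes used in validation

The test suite and acceptance script run entirely on synthetic data:
dating recovery uses 100 replicate panels of 2×10⁵ ascertained sites;
the dating oracle grid uses 27 parameter points × 1.5–2×10⁵ genealogies;
caller comparisons use 10⁴ sites at 9×; damage-fit recovery uses 100 tables
at 10⁴ opportunities per position; the f4-ratio uses 2×10⁵ sites; copy
number uses 10⁴ windows for bias removal and ~10⁶ positions per integer-call
fixture. These sizes were chosen so Monte-Carlo error is small against each
test's tolerance.

## Known limitations

- The genotype simulator's site scheme deflates absolute per-site statistics
  by ~exp(−tree length); negligible at realistic mutation-scaled parameters
  but visible if θ or τ are pushed toward 0.1.
- The dating model assumes exactly one sampled chromosome per population and
  a clean (((A,E),I),S) scaffold; violations (deep structure within Europe,
  gene flow after τ₁) are not modelled.
- The caller handles SNVs only (no indels) and treats reads as independent;
  mapping bias and contamination are out of scope.
- Loess GC correction assumes the control regions are truly copy-neutral and
  span the GC range of the loci of interest; outside that support the
  correction is a flagged constant extrapolation.
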