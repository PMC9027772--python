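# Methods

This note records the models, numerical choices and calibrations behind
`halosoil`, and what the synthetic-data tests do and do not demonstrate
about field data.

## EC→salinity conversion

Soluble-salt content is estimated from the electrical conductivity of a
1:5 soil–water suspension by the affine calibration
`salinity = EC/(1000·0.39) − 0.0182` (EC in μS/cm, salinity in g/kg). The
conversion is only meaningful above its intercept (EC ≈ 7.1 μS/cm);
smaller readings are clamped to salinity 0 rather than rejected, since
they simply indicate salt below the calibration's resolution. An
alternative parameterization `(EC/1000 − 0.0182)/0.39` is selectable with
`form="literal"` for comparison against other coastal calibrations.
Class thresholds are left-closed: [0, 1) Non, [1, 4) Mild, [4, ∞) Severe,
so a sample at exactly 4 g/kg is Severe. Full precision is kept
internally; the 2-decimal rounding applied to reported salinities is a
presentation choice of the TSV writers.

## Microcalorimetry

A power–time curve is heat flow per gram soil sampled at strictly
increasing times. Basal (unamended) curves are summarized by their mean
after discarding the first hour by default — the ampoule-insertion
transient; the discard is configurable and the mean requires at least
three remaining points.

Substrate-induced curves are smoothed by a centred moving average
(default width 5 points, shrinking symmetric windows at the edges) before
peak extraction, so P_max/T_max are robust to single-sample noise spikes;
ties in the smoothed maximum resolve to the earliest time. T_max is kept
in hours internally and also reported in minutes, the unit conventional
for peak-power time.

### Growth-model fit

The early-phase model `P = A + B·exp(k·t)` is conditionally linear in
(A, B), so the fit is separable: for each candidate k on a 400-point log
grid spanning 10⁻³–10 h⁻¹ the optimal (A, B) solve a 2×2 normal-equation
system in closed form; candidates violating A ≥ 0 or B > 0 are discarded
(B below ~10⁻⁸ of the curve scale counts as "no growth" — an exactly
constant curve otherwise produces a spurious machine-epsilon B). The best
grid cell is refined by golden-section search on log k to a relative
width of 10⁻⁶. This is deterministic, has no starting-value sensitivity,
and by construction returns an RSS no worse than any grid candidate.
Exponents with k·t_max > 340 are infeasible (float overflow in the
squared sums). The derived lag time is ln(A/B)/k when 0 < B < A — the
time at which the growing component overtakes the uncoupled one — and 0
otherwise.

The fitting window runs from the start of the curve to the earliest time
the smoothed heat flow reaches a fraction (default 0.9) of P_max, with at
least five points required. Two caveats, measured on the package's own
generators: on a clipped-exponential curve the default window biases k by
under 1%, but on a logistic (self-limiting) curve growth departs from the
exponential model well before 90% of peak, and k fitted at frac=0.9 can
be biased low by half. For strongly saturating curves a window fraction
of 0.2–0.5 trades a little variance for much less bias; residual bias of
order 10% remains because a logistic is simply outside the model class.
The batch report therefore carries R² per fit so saturation-degraded fits
are visible.

## Community statistics

Rarefaction draws a without-replacement subsample of exactly `depth`
reads per sample (multivariate hypergeometric), dropping samples below
depth with a warning; it is bit-reproducible given a seed. Bray–Curtis is
computed on the rarefied counts — at equal depth counts and relative
abundances give the same dissimilarity — as Σ|x−y| / Σ(x+y), with 0
defined for a pair of empty samples.

Faith's PD for a sample is the total branch length of the minimal subtree
connecting its present OTUs to the root (root path included, per Faith's
original definition; the root itself carries no branch). The
implementation aggregates per-branch leaf memberships in one postorder
pass and evaluates all samples by a boolean matrix product, and is
cross-checked against scikit-bio's implementation in the tests.

PERMANOVA uses Anderson's pseudo-F from squared distances
(SS_total = Σ_{i<j} d²ᵢⱼ/N, SS_within from within-group pairs scaled by
group size, F = (SS_B/(a−1))/(SS_W/(N−a))) with a label-permutation null.
All permutation p-values use the +1 correction,
p = (1 + #{T_perm ≥ T_obs})/(1 + n_perm), so p is never 0, its resolution
is 1/(n_perm+1), and ties count against rejection — a fully degenerate
distance matrix yields p = 1. Pairwise group comparisons rerun the test
on each pair's sub-matrix and are Holm-adjusted (the multiplicity rule
was an open choice; Holm is conservative without independence
assumptions). The Mantel statistic is the Pearson correlation of upper
triangles with simultaneous row/column permutation of the second matrix;
the test is one-sided (greater), the standard direction for
dissimilarity–dissimilarity association. Both tests reproduce exhaustive
enumeration at small n and hold their nominal type-I error to within
Monte-Carlo tolerance over 1000 null datasets.

Tukey HSD uses the studentized-range criterion with the Tukey–Kramer
allowance for unbalanced groups; the compact letter display is the
insert-and-absorb algorithm over the significance graph, processed and
lettered in descending-mean order, which makes the display deterministic
(highest mean always "a").

## Co-occurrence networks

Per sample group, OTUs present in at least half the samples (configurable)
are retained; correlations are Pearson on log₁₀(relative abundance +
pseudocount), the pseudocount defaulting to the smallest nonzero relative
abundance in the table. Constant columns get correlation 0 rather than
NaN. Groups need at least 4 samples for a correlation to mean anything,
and fewer than 10 retained OTUs triggers a warning; field designs with
3–4 replicate plots per class are below what correlation networks can
support, which is why the synthetic groups default to 10 samples.

The threshold is chosen by the random-matrix-theory transition: as the
cutoff rises, the eigenvalue nearest-neighbour spacing distribution (NNSD)
of the thresholded matrix moves from GOE-like (level repulsion, correlated
noise) to Poisson (exponential spacings, signal only). For each candidate
threshold the matrix with |r| below it zeroed keeps only *distinct*
eigenvalues (thresholding manufactures large degenerate multiplicities
that carry no spacing information), unfolds them through a monotone
(PCHIP) spline fitted to every 5th point of the empirical spectral CDF,
and applies a one-sample KS test of the unit-mean spacings against Exp(1).
The smallest grid value (0.30–0.95, step 0.01) with KS p > 0.05 wins; if
none passes, the best candidate is returned with a warning. Fewer than 10
spacings cannot reject Poisson and are accepted — which also gives the
right answer for matrices with no off-diagonal structure. Unfolding
through a *smooth* CDF estimate is essential: the raw empirical CDF maps
eigenvalues to their ranks and makes every spacing identically 1. Sanity
anchors: a 200×200 GOE matrix is rejected (KS p ≈ 10⁻¹¹) and a random
diagonal matrix accepted (p ≈ 0.6). A fixed threshold override is
available for small matrices (< 20 OTUs, where spacing statistics are
unreliable and the selector refuses to run).

Topology: density 2m/(n(n−1)), average degree 2m/n, Freeman degree
centralization Σ(d_max − dᵢ)/((n−1)(n−2)), transitivity
3·triangles/triples, average geodesic distance over connected pairs only
(disconnected pairs are excluded, not set to ∞), modules by greedy
modularity maximization with Newman Q, counting modules of ≥ 5 nodes.
Null comparisons rewire the observed graph by double edge swaps (10·m
swaps per replicate), which preserves the degree sequence exactly — so
density and average degree are invariant by construction and serve as a
null-model self-check — or draw uniform G(n, m) graphs; z-scores and
two-sided empirical p-values (+1 corrected) are reported per index, with
a fallback to G(n, m) when a graph admits no valid swap.

## Synthetic data

The curve generator produces flat basal traces (a + noise), clipped
exponentials ("ideal": exactly A + B·e^{kt} until a plateau), and
four-phase "realistic" curves — a logistic growth term
cap·b·e^{kt}/(cap + b(e^{kt}−1)) above the baseline, multiplied by
exp(−k_decline·(t − t_decline)) past the substrate-exhaustion time, with
Gaussian noise. Defaults (a = 2 μW/g, p_asym = 60 μW/g, k = 0.35 h⁻¹,
decline after 30 h, σ = 0.3 μW/g, 0.1-h sampling over 48 h) describe a
glucose-amended soil ampoule at realistic instrument noise.

The community generator is a Gaussian-niche gradient model: OTU j has a
niche optimum μⱼ ~ U(0, 12) on the salinity axis (g/kg), width
σⱼ ~ U(6, 12), and base log-abundance ~ N(0, 1); the expected relative
abundance in a sample at salinity s is ∝ exp(base)·exp(−(s−μ)²/2σ²), and
counts are multinomial at a depth drawn from 4500–25000 reads (the
sequencing-depth envelope, with 4500 the rarefaction floor). Salinities
are uniform within class bands (Non 0.2–1, Mild 1–4, Severe 4–12 g/kg),
10 samples per class. The niche width is the single effect-size knob and
its default is a deliberate calibration: widths of 6–12 g/kg against a
12 g/kg gradient shift composition smoothly (global PERMANOVA detects the
gradient in essentially every seed) while leaving rarefied richness
statistically flat across classes (richness ANOVA non-significant in
~100% of seeds). Narrower widths (2–6) make niche edge effects produce a
~2% richness gradient that an ANOVA at n = 10/class detects almost
always, breaking the composition/richness dissociation the generator
exists to emulate. A random coalescent-style tree (uniform joins,
Exp(1) branch lengths) makes PD non-trivial without any biological claim,
and taxonomy strings come from a small fixed lineage pool, archaeal with
probability 0.005.

The chemistry generator draws EC uniformly inside class envelopes
(244–397, 400–800, 2400–4374 μS/cm — the overall range matching the field
envelope 244–4374, and the Non ceiling kept just below the EC at which the
conversion crosses 1 g/kg so drawn class and derived class agree), then
sets pH = 8.6 − 0.9·log₁₀(EC/244) + N(0, 0.1),
Na = 0.12·EC/244 + N(0, 0.1) g/kg, with SOC, available N and
dehydrogenase likewise decreasing in log EC. This reproduces the
qualitative field associations (EC–pH negative, EC–Na positive) in ≥95%
of seeds at survey-sized n.

What the generators do *not* emulate: sequencing error and chimeras,
taxon-specific depth biases, compositional (closure) artefacts beyond
multinomial sampling, phylogenetic signal in niche assignment (tree and
niches are independent, so PD tracks richness closely), spatial
autocorrelation between plots, and instrument drift in calorimetry.
Passing tests therefore demonstrate the statistical machinery and its
calibration on data with known truth — not that field data meet those
assumptions.

## Problem sizes and determinism

Tests and the pipeline default to 30 samples × 300 OTUs at depths
4500–25000, 199–999 permutations, 30–100 null-network replicates, and
100-seed recovery ensembles — sizes chosen so the full suite runs in a
few minutes on one core while keeping Monte-Carlo tolerances meaningful.
All stochastic steps take an explicit seed (numpy `default_rng`; child
seeds drawn below 2³¹), and identical inputs plus seeds give bit-identical
tables, networks and p-values.
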