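# Methods

`loopmed` implements a causal-mediation analysis of closed regulatory
loops — triads in which a miRNA targets both a transcription factor (TF)
and a gene that the TF also targets — together with the surrounding
pipeline: differential-expression filtering, loop inference from
regulator→target tables, correlation screening of loop edges, per-loop
mediation estimation with bootstrap uncertainty, loop classification,
and network-motif detection in the resulting graph. This note records
the statistical model, the tunable parameters, the numerical choices,
and what the synthetic data do and do not emulate.

## The mediation model

For one triad let X be the miRNA, M the TF and Y the gene (expression
across samples). Three linear structural equations define the effects:

    Y = β₁ + c X + e₁            (total effect)
    M = β₂ + a X + e₂            (mediator model)
    Y = β₃ + c′X + b M + e₃      (outcome model)

Under ordinary least squares the decomposition c = a·b + c′ is an exact
algebraic identity. The average causal mediation effect (ACME) is the
part of X's influence routed through M, the average direct effect (ADE)
the remainder:

    ACME = c − c′ = a·b,   ADE = c′,   TE = ACME + ADE.

Point identification requires sequential ignorability: X is as-if random,
and M is as-if random given X. No treatment–mediator interaction term is
modelled (the outcome model is additive).

**Nonlinear edges.** When an edge's Pearson correlation is not
significant but its distance correlation is, the corresponding model is
fitted with cubic regression splines: a truncated-power basis
[1, x, x², x³, (x−k₁)³₊, (x−k₂)³₊, (x−k₃)³₊] with three interior knots
at evenly spaced quantiles of the covariate (knot count configurable).
The basis nests the straight line, so linear data are fitted exactly.
Effects are then computed by counterfactual prediction: mediator values
are predicted under a treated and a control level of X (3rd and 1st
quartile by default), the empirical mediator-model residuals are added
back so nonlinear outcome models are averaged over the mediator's error
distribution, and the outcome model is evaluated with the mediator
values swapped between treatment levels. Both treatment arms are
averaged, which makes TE = ACME + ADE an exact identity in the
counterfactual route too. Effects are divided by the treated−control
contrast so linear and spline routes report on the same per-unit scale
(in the linear case the counterfactual route reduces exactly to a·b and
c′).

**Uncertainty.** Nonparametric bootstrap over sample rows (default
1000 draws), percentile intervals, and a two-sided sign-based p-value
p = 2·min(frac ≤ 0, frac ≥ 0) floored at 2/(n_boot+1). The linear route
is vectorised (closed-form OLS per resample), so 1000 draws at n = 200
cost ~5 ms. Resamples with a degenerate design (zero treatment variance
or collinear treatment/mediator) are redrawn and counted; a warning
fires if they exceed 1% of draws. Bootstrap results are bit-reproducible
under a fixed seed; point estimates are invariant to sample order, while
bootstrap p-values are invariant only in distribution (the resample
indices depend on the seed, not the ordering). The Sobel delta-method
standard error of a·b, √(se_a²b² + se_b²a²), is reported alongside; at
large n it agrees with the bootstrap SD of the ACME to within a few
percent. Note the sign-based bootstrap p is mildly liberal for a
truly-zero coefficient when X and M are strongly collinear (empirical
size ≈ 8% at nominal 5% in the synthetic conditions below); this bounds
the attainable class-recovery rate at roughly 92%.

**Sensitivity analysis.** For linear models the ACME is re-computed as a
function of the correlation ρ between e₂ and e₃ (ρ ≠ 0 is exactly the
violation produced by an unobserved confounder of M and Y):

    ACME(ρ) = a·(s₁/s₂)·[ρ̃ − ρ·√((1−ρ̃²)/(1−ρ²))]

with s₁, s₂ the residual SDs of the total-effect and mediator models and
ρ̃ the correlation of those residuals. ACME(0) equals the point estimate;
the reported `rho_zero` (grid-bracketed Brent root) is the amount of
confounding that would annul the conclusion. The variance-explained
parameterisation is reported with the symmetric split
R̃²_M = R̃²_Y = |ρ| (their product is ρ²); any other split along the curve
is equivalent up to reparameterisation.

## Edge screening

Every loop edge is scored with the Pearson product-moment correlation
(two-sided t test, n−2 df) and the sample distance correlation (double
centering of pairwise |·| distance matrices). Significance of dependence
is decided by the distance-correlation t-test alone: the bias-corrected
dcor r* (U-centered matrices) gives t = √ν·r*/√(1−r*²) with
ν = n(n−3)/2 − 1 degrees of freedom and an upper-tail Student-t p-value.
A loop is retained when all three edges have dcor p ≤ α (α = 0.05
default, no multiple-testing correction across edges; a BH option
exists, off by default). Pearson serves only to label edges
linear/nonlinear for model routing: the mediator model follows the
miRNA→TF edge, the outcome model is linear only if both edges into the
gene are linear.

Known limitation: the t approximation's asymptotics hold as the data
*dimension* grows; for univariate samples the test is mildly liberal
(empirical size ≈ 0.065 at nominal 0.05, roughly independent of n). The
implementation was cross-checked against an independent double-centering
oracle (agreement to 1e-10) and the algebraically distinct Astar form of
the bias-corrected statistic (exact agreement), so this is a property of
the published approximation, not of the code.

## Preprocessing

- **Normalisation**: each sample column is divided by its own 75th
  percentile (chip-to-chip comparability), then each entity row by its
  median across samples. The two-step procedure guarantees unit row
  medians but is *not* idempotent — re-normalising changes values
  because a median-centred matrix has no constraint on its column
  quantiles. One pass is applied, as stated.
- **Differential expression**: fold change = ratio of injured/sham group
  means on the linear scale, reported signed (ratios < 1 as −1/ratio so
  the |fc| ≥ 2 threshold is symmetric); raw p from a Welch two-sample
  t-test per entity (standard for two-group microarray comparisons with
  unequal variances); Benjamini–Hochberg correction across all tested
  entities; pass = |fc| ≥ 2 and BH p ≤ 0.05.
- **Imputation**: per entity, an OLS line of expression on numeric time
  fitted to the observed time points; unobserved time points get the
  fitted predictions. A line is the simplest least-squares model; richer
  time-course bases would need more observed time points than the design
  provides.
- **Probe collapsing**: multi-probe genes take the row of their first
  listed probe.

## Loop inference and motifs

Closed loops are the exact triple join {(mi, tf, g) : mi→tf, mi→g ∈
miRNA targets, tf→g ∈ TF targets}, restricted to differentially
expressed entities, sorted lexicographically. Duplicate regulator–target
rows from multiple sources are merged (sources pooled, best = most
negative score kept); self-regulation rows are dropped.

Motif analysis works on the union graph of mediated loops. Connected
induced k-node subgraphs (k = 3, 4, 5; connectivity ignores direction)
are counted exactly with the ESU enumeration algorithm; each class is
keyed by a canonical integer id — the minimum over all k! node
permutations of the row-major bit encoding of the adjacency matrix, a
complete isomorphism invariant. Under this labelling the 4-node
single-input module (one regulator, three targets) has id 14 and the
bi-fan id 204. For k = 6 a weighted random descent of the ESU tree
(child chosen uniformly, leaf weighted by the product of branching
factors) gives unbiased concentration estimates. The null ensemble is
built by degree-preserving two-edge switches ((u→v, x→y) → (u→y, x→v),
rejecting self-loops and parallel edges; 3 attempted switches per edge,
1000 graphs by default). A motif is significant when
z = (count − null mean)/null SD ≥ 2, add-one p = (1 + #{null ≥
observed})/(1 + n_random) ≤ 0.05, and count ≥ 5. Node kinds
(miRNA/TF/gene) are ignored during isomorphism. Two 4-node motifs can be
composed into candidate 6-node arrangements by overlapping them on two
shared nodes with agreeing edge patterns.

## Loop classification

With α = 0.05: M_T (TF-mediated) if ACME significant only; M_M
(miRNA-only) if ADE significant only; M_TM if both; UNEXPLAINED
otherwise — a partition, which is the only reading of "TF only / miRNA
only / both" that makes the classes exclusive. M_TM loops are
sub-classified by sign agreement of ACME and ADE (supporting vs
opposing) and by whether the target gene's fold-change direction follows
the miRNA's or the TF's. Fold-change signs come from the DE records at
the loop's own time point. Both triad orientations are supported;
default treats the miRNA as treatment, the reverse (TF as treatment,
miRNA as mediator) reproduces the reversed-loop comparison.

## Synthetic data

The generator plants triads whose injured-condition samples satisfy the
structural equations exactly: X = baseline + x_sig with x_sig ~ N(0,1),
M = β₂ + aX + N(0, σ_m), Y = β₃ + c′X + bM + N(0, σ_y). Class patterns:
M_T has a, b ≠ 0, c′ = 0; M_M has a ≠ 0, b = 0, c′ ≠ 0 (all three edges
remain correlated while nothing is routed through the TF); M_TM all
nonzero; NULL all zero. Default coefficient magnitudes are drawn from
(0.75, 1.25) with random signs — effects comparable to the noise scale,
i.e. clearly detectable at n ≈ 100–200 without being trivial. Default
noise SD is 0.5 per structural equation and the default correlation
sample size is 50 injured + 50 sham samples (the replicate count behind
the original arrays is not fixed by the data design, so it is an
explicit parameter everywhere).

Entity baselines are uniform on (8, 12); injured/sham fold changes of
magnitude ≥ 2 (default 2.5, direction random per entity) are planted
multiplicatively on the baselines of loop members and are ~1 for decoys,
so members pass the |fc| ≥ 2 DE filter and decoys do not. Because the
baseline shift is multiplicative between condition groups while the
structural equations hold within each group, screening and mediation run
on the injured-condition columns (within-condition covariation), and DE
compares injured vs sham. Decoy edges are rejection-sampled so they
never close an unplanned triad — the planted truth is the exact loop
set, making precision/recall computable. All randomness flows from one
integer seed; regeneration is byte-identical, and TSVs are written with
%.17g so serialisation round-trips float64 exactly.

What the generator does **not** emulate: probe-level microarray noise,
chip spatial artifacts, heteroskedastic intensity-dependent variance,
correlated regulators, and feedback (the planted graph is feed-forward
by construction). Passing tests therefore demonstrate correctness of the
statistical machinery under the assumed structural model, not robustness
to real-array artifacts.

## Problem sizes and numerical choices

The test suite and the acceptance script regenerate everything at run
time. Monte-Carlo sizes: 1000 random datasets for the OLS identity;
500 triads (n = 200, 1000 bootstrap draws) for parameter recovery and
CI coverage; 2000 pairs (n = 30) for the dependence-test size; 100 loops
per class for classification recovery; 50 seeded runs for planted-motif
recovery (100-graph null ensembles per run, add-one minimum p ≈ 0.0099).
Degenerate inputs: constant vectors are errors for Pearson and the
treatment, dcor of a constant vector is 0 with a warning; ties in
top-effect rankings break lexicographically by loop id; a null SD of 0
leaves a motif's z undefined (not significant). Thresholds throughout
default to α = 0.05, |fc| ≥ 2, 1000 bootstrap draws and 1000 null
graphs.
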