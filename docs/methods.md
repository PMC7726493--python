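# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions at the edges.

## Study design assumed

One expression matrix per cell line: log2 intensities for ~20,000 probes
across a control condition plus several compound treatments (default three:
BPA, BPF, BPS) at 4 replicates each. Compounds are assumed profiled at
matched potency (e.g. their CYP3A IC50), so their responses are directly
comparable. The matrix is taken as already normalized; raw-array
normalization is upstream of this package and out of its scope. Probes,
not collapsed genes, are the analysis unit throughout.

## Differential expression

For each compound-vs-control contrast: log2FC = mean(log2 treated) −
mean(log2 control); a pooled-variance two-sample *t* with n_t + n_c − 2
degrees of freedom; two-sided p; Benjamini–Hochberg step-up adjustment
(sort ascending, multiply p_(i) by m/i, cumulative minimum from the largest
rank, cap at 1); and the call rule with *strict* inequalities at both
gates: up iff 2^log2FC > 1.5 and p_adj < 0.05, down iff 2^log2FC < 1/1.5
and p_adj < 0.05. Thresholds are parameters (`fc_threshold`, `alpha`) with
those defaults.

A deliberate simplification: the test is a plain pooled-variance *t*, not a
moderated (empirical-Bayes) variant. The downstream overlap and concordance
statistics — the point of this package — are agnostic to the upstream test,
and at 4 replicates with the simulator's homoskedastic noise the pooled *t*
is well calibrated (the suite checks raw-p uniformity under the null and
agreement with an exact permutation oracle). The `de_table` pipeline is
small and pluggable if a moderated test is ever needed.

Degenerate probes: zero pooled variance with zero mean difference gives
p = 1 (t = 0); zero pooled variance with a nonzero difference gives p = 0
(t = ±∞). These conventions keep the BH input well defined.

## Overlap ratio

For k sets of sizes n_i over a universe of N probes, the expected
intersection under the independence model (each set drawn uniformly
without replacement, sets mutually independent) is E = n₁n₂/N (k = 2) or
E = n₁n₂n₃/N² (k = 3), and the overlap ratio is O/E. Conventions: O = 0
gives ratio 0 (defined); any n_i = 0 raises an explicit undefined-ratio
error rather than returning infinity or NaN; in pipeline output such rows
carry NaN statistics plus a note naming the empty set. The universe N
defaults to all probes of the supplied matrix (the `universe` option can
restrict it to an expressed subset, mean log2 intensity ≥ 5 by default, for
sensitivity analyses).

The Monte-Carlo sampler draws the k sets exactly per the independence
model and reports the empirical overlap distribution, its mean (which must
converge to E — the suite asserts this on a parameter grid), and a
one-sided exceedance probability (#{O_rep ≥ O_obs}+1)/(reps+1). The
exceedance p is an extension beyond the analytic ratio — useful because the
ratio alone has no scale for "how surprising" — and is labelled
`mc_exceedance_p` in output.

## Concordance

Pairwise Spearman correlation (average ranks for ties) of per-probe log2FC
vectors over the full common probe universe, not only called DE probes:
the statistic summarizes the genome-wide fold-change scatter, and
restricting to significant probes would inflate R by selection. The
restriction is available to callers by subsetting profiles. P-values use
the large-sample *t* approximation with n − 2 df; formatted output floors
values below 2.2 × 10⁻¹⁶, the customary double-precision floor.

A structural fact worth knowing when interpreting R: profiles contrasted
against a *common* control group share that group's sampling noise, so
even completely independent null probes correlate at
Var(control mean)/Var(log2FC) = 1/2. Genome-wide R around 0.4–0.6 is
therefore what a shared-control design produces when the true shared
signal is moderate; the simulator reproduces this property naturally, and
truly independent profiles (no shared control) test at |R| < 0.05.

## PCA

Samples are projected by SVD of the per-probe mean-centered matrix
restricted to the `pca_top_k` = 1000 highest-variance probes (sample
variance across all samples, ties broken by probe order). No unit-variance
scaling: on log2 expression data the high-variance probes are the signal,
and scaling would equalize them with noise. Percent variance explained is
σ_i²/Σσ_j²·100 over all components.

## IC50

Curves are percent-of-vehicle-control responses at strictly increasing
concentrations starting at 0. Replicates at a concentration are averaged
first. The default estimator scans for the first consecutive pair
(x_i, x_{i+1}) with response_i ≥ 50 ≥ response_{i+1}, fits the line
f(x) = ax + b through those two points, and solves f(x) = 50; so the
estimate always lies inside its bracketing interval, equals a tested
concentration whose response is exactly 50, and a curve that never reaches
50 % returns status `not_reached`. Non-monotone curves are resolved by
this first-crossing rule. A curve already below 50 % at its lowest tested
concentration raises an error (the crossing is not bracketed; extrapolation
below the tested range would be invention). A `global` mode fitting one
least-squares line through all points is provided as an alternative; the
bracketing mode is the default because a single line cannot represent the
sigmoidal plateaus and the bracketing rule reproduces `not_reached`
behaviour naturally. Responses above 100 % (stimulation) are permitted;
only the downward crossing is sought.

## Synthetic-data generator

What it emulates: an array-scale (default N = 20,000 probes) log2 matrix
for one labelled cell line; baseline per-probe intensities N(7, 2²) (log2
scale, typical of normalized arrays); i.i.d. Gaussian measurement noise
(default sd 0.25 log2 units, a standard post-normalization approximation);
a *shared core* of `shared_de_count` = 150 probes perturbed by every
compound; `private_de_count` = 100 additional probes per compound; 4
replicates per condition.

Shared-core effect sizes: each shared probe draws one fair-coin sign
applied to all compounds (so shared probes move concordantly up or down,
as the Venn structure of real multi-compound data shows), times a
magnitude vector effect_mean + effect_sd·g with g jointly Gaussian across
compounds under an exchangeable latent correlation. Because the common
sign alone already induces a correlation of mu²/(mu² + sd²) between
compounds' signed effects, the latent correlation is solved as
(ρ(mu² + sd²) − mu²)/sd² so that the *realized* Pearson correlation equals
the configured `effect_correlation` exactly; configurations below the
common-sign floor are rejected with an error naming the bound (this is why
the default effect_sd is as large as 1.5 against a mean of 1.0 — the
default ρ = 0.5 needs sd ≥ mean). The suite verifies the realized
correlation to within 0.05 over 20 seeds. Private-set effects draw
independent signs and magnitudes. Degenerate case: effect_sd = 0 forces
correlation 1 and is only accepted with `effect_correlation = 1`.

Defaults (shared 150, private 100, effect mean 1.0 / sd 1.5, ρ = 0.5,
noise 0.25) were set once to produce per-compound DE counts in the low hundreds,
a strongly enriched but incomplete three-way overlap, and genome-wide
concordance near 0.5 — the regime of the motivating hepatocyte study — and
are exercised as-is by the validation suite.

Dose-response curves: mean structure floor + (100 − floor)/(1 + (x/x₀)^h)
with the midpoint x₀ solved so the response at `true_ic50` is exactly 50 %
(requires floor < 50); with no `true_ic50`, a shallow decay toward a floor
≥ 60 % keeps the mean above 50 everywhere. The vehicle point is pinned at
100 %; Gaussian noise (percent units) applies to treated points only.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: probe-level raw intensities and normalization
artifacts, batch and spatial effects, heteroskedastic or heavy-tailed
noise, probe-probe correlation beyond the planted structure, multiple cell
lines in one matrix (generate one matrix per line), and gene-level
annotation structure. Recovery results certify the statistics and their
implementation, not robustness to those real-world complications.

## Numerical and reproducibility notes

* All randomness flows through `numpy.random.default_rng(seed)`; identical
  (config, seed) pairs give byte-identical serialized outputs, and the
  pipeline manifest records SHA-256 checksums so whole report bundles can
  be compared.
* BH adjustment delegates to statsmodels' `fdr_bh`; the test suite pins it
  against an independent brute-force min-over-tail implementation.
* The Monte-Carlo null samples sets in chunks of 20,000 replicates to
  bound memory at large N.
* Top-variance selection and p_adj ranking use stable sorts, so ties are
  broken by input order deterministically.
* Validation-suite problem sizes (matrices of 10²–2×10⁴ probes, 10–20
  seeds per recovery property, 2×10⁴–2×10⁵ Monte-Carlo replicates) were
  chosen to keep each property's sampling error an order of magnitude
  below the asserted tolerance.
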