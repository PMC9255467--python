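# Methods

## The model

Each study provides a genes × samples matrix on the log2 scale with a
two-level group factor (case/control). The differential-expression stage
fits, per gene g, the two-group linear model

    y_gij = mu_g + beta_g * 1[case] + (batch offsets) + e_gij,
    e_gij ~ N(0, sigma_g^2)

so that `log2FC_g = beta_g` is the case − control mean difference. The
gene variances are modelled hierarchically,

    sigma_g^2 ~ s0^2 * d0 / chi2(d0),

and the empirical-Bayes step replaces the pooled residual variance
`s_g^2` (df `d_g = n1 + n2 − 2`) by the posterior

    s~_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g),

with the moderated t referred to Student-t on `d0 + d_g` df. The
hyperparameters are estimated by the standard closed-form moment match on
`log s_g^2`: the trigamma identity is inverted by Newton iteration
(tolerance 1e-8, 50 iterations max, error on non-convergence). Two
finite-sample conventions are adopted from the reference implementation of
this moderation (the R limma package, against which one test
cross-checks): when the spread of log variances is no larger than
sampling noise the prior collapses (d0 = ∞) and the single variance is
the plain mean of `s_g^2`; and the reference df is capped at the pooled
residual df `d_g × G`, since the moderated t can never be better
calibrated than one pooled-variance t-test.

DEG status uses strict asymmetric thresholds: up means log2FC > 1 and
BH-adjusted p < 0.05; down means log2FC < −0.5 and adjusted p < 0.05.
Adjustment is per study. The asymmetry reflects that downregulation
tends to be broader but shallower in the compendia this pipeline targets.

### Preprocessing choices

* **Scale heuristic** — a matrix whose maximum exceeds 30 is treated as
  linear-scale and transformed as log2(x+1); log2 microarray intensities
  rarely exceed ~20, linear intensities rarely stay below 30. Negative
  values in a linear-judged matrix are an error.
* **Batch removal** — per-gene least squares with the group effect in the
  design, subtracting only the batch component; group estimates are
  untouched (exactly so in balanced designs). A batch factor confounded
  with the group contrast is refused by a rank check.
* **Median filter** — step 1 keeps genes whose per-gene median is `>=`
  the median of per-gene medians (ties kept, so a constant matrix
  survives; the midpoint median is used). Step 2 keeps genes detected
  (value > 0 on the log2(x+1) scale, configurable floor) in strictly
  more than 2 samples. Whether the first step should use medians or
  means, and what "detected" means, are genuinely open conventions;
  both are exposed as parameters.

## Meta-analysis

Genes are matched across studies by uppercase symbol; a gene absent from
a study contributes nothing there (`n_studies_present` tracks this).

* **REM** — within-study variance is recovered from the reported CI as
  `((CI.R − CI.L)/(2·1.96))^2` (floored at 1e-12); DerSimonian–Laird
  `tau^2 = max(0, (Q − (k−1))/C)`; weights `1/(v + tau^2)`; the summary p
  is the two-sided normal tail. With one study the summary reduces to
  that study; with `tau^2 = 0` it is the fixed-effect inverse-variance
  mean.
* **VC** — a study votes up for a gene when `p < 0.05` and `log2FC > 0`
  (down symmetric; both thresholds configurable); `ndiff` counts votes
  and `sign_consistency = n_up − n_down`. Under the global null, `ndiff`
  is Binomial(k, α), which the tests verify by simulation.
* **CA** — Fisher's `−2 Σ ln p` against χ² with `2k` df; p-values are
  floored at 1e-300 before the log. The effect summary is the mean
  log2FC (median behind a flag).

Each strategy ranks genes — REM by summary p (tie: |summary FC|), VC by
`ndiff`, then |sign consistency|, then |mean FC|, CA by Fisher p; all with
a final symbol tie-break for determinism — and keeps the top
`ceil(metathr · G)` genes, where G is the number of genes present in at
least one study (the package's own convention for the denominator). REM
ranking by summary p is a deliberate design choice: confident-effect
ranking methods exist for this purpose, but p-ranking is closed-form,
deterministic and dependency-free, and the top-set extraction is
insensitive to the difference for strong signals. Regulation is the sign
of the strategy's effect summary, and the compiled union refuses genes
whose direction conflicts across strategies.

## Network analysis

Pruning removes nodes of degree < 2 iteratively to a fixed point (the
2-core); a single-pass variant is available behind a flag, since a
one-shot reading of the rule is also defensible. Closeness is the
Centiscape convention 1/Σd (reciprocal summed shortest-path distance,
computed within each connected component; isolated nodes report 0 with a
warning) rather than the normalised (n−1)/Σd variant — the reference
hub tables this package reproduces have closeness magnitudes ~1/Σd.
Betweenness is Brandes' algorithm, undirected, unnormalised, endpoints
excluded, each unordered pair counted once. Hub selection computes the
three means over the pruned network (the convention when the source
tables are silent) and requires all three centralities to strictly exceed
them. Nodes added by an interaction-prediction service participate fully
in centrality and hub selection but carry no regulation direction.

## Over-representation

The background defaults to N = 20000, the conventional protein-coding
universe; this value also reproduces published deviation-formula odds
ratios across several libraries to 5 significant figures, which the test
suite verifies. The combined score uses the raw (not adjusted)
hypergeometric p. Query genes absent from the background are retained in
the query size n. Published enrichment *p-values* from web services are
not reproducible in general — their effective background and query
filtering are service state — so only the OR and combined-score
arithmetic are treated as exactly recomputable.

## Proportion comparisons

The reported count comparisons never name their test; the one-sided
normal approximation with a 0.5 continuity correction on the larger
count,

    z = (max(a,b) − 0.5 − n/2) / sqrt(n/4),  p = P(Z > z),

reproduces every exactly printed reference p-value to printed precision
(the test suite asserts all five), which is why it was frozen as the
default; an exact Binomial(n, ½) tail is available behind ``exact=True``.
p-values are printed at 6 decimal places.

## Synthetic data: what it does and does not emulate

The generator draws per-gene baselines N(7, 1.5²) on the log2 scale,
variances from the scaled inverse-χ² prior (defaults d₀ = 4,
s₀² = 0.25 — mid-range values for moderate-sized microarray studies),
Gaussian noise, optional per-gene per-batch offsets (balanced batch
assignment within groups), and plants `deg_fraction` of genes (default
1%, i.e. 20 of 2000) with a fixed ±1.5 log2FC whose identity and sign
are shared across all studies. Defaults of 16 studies across the four
tissue groups, 10 samples per group and 2000 genes mirror the structure
of the multi-tissue compendium the pipeline was designed around while
keeping the full test suite and validation scripts fast on one CPU.
One master seed drives everything; study i uses substream seed + i, so
collections are reproducible and studies independent.

Deliberately not modelled: array-platform probe effects, many-to-one
probe-to-gene mapping, missing values, heavy-tailed or correlated noise,
and partially shared (rather than fully shared) effect signatures.
Passing recovery tests therefore demonstrates correctness of the
statistical machinery under its own assumptions, not robustness to real
microarray pathology.

## Validation scales

The validation suite uses 5000 genes for hyperparameter recovery (25%
relative tolerance), 200 replicate genes × 8 studies for random-effects
recovery (bias < 0.1 at true FC 1.5, tau² 0.1), 2000 genes × 16 studies
for vote-count null calibration, exhaustive brute-force oracles on all
graphs of ≤ 8 nodes for centralities, and the full 16 × 2000 synthetic
collection for the end-to-end planted-recovery and byte-identical
determinism checks. These sizes are the package's chosen balance between
statistical resolution and a test suite that runs in seconds.

## Known limitations

* The REM stage consumes CI widths, so its within-study variances are
  only as good as the upstream intervals; degenerate zero-width CIs are
  floored rather than refused.
* Vote counting treats studies symmetrically regardless of size.
* The enrichment engine tests every term with non-empty overlap; terms
  with zero overlap are not reported (and not counted in the BH family).
* The hub rule's strict inequalities mean perfectly regular networks
  have no hubs by construction.
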