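# Methods

## The signal model

A near-cis 4C-seq profile records, for every restriction fragment on the
viewpoint chromosome, how often that fragment was ligated to the viewpoint.
Within a ±2 Mb window the profile is dominated by a smooth distance decay,
on top of which specific chromatin loops appear as localized enrichments.
`fourcis` models the expected signal at genomic coordinate `x`, for a
viewpoint at `x_v`, as the sum of three independent contributions:

```
S(x) = B + I · exp(−|x − x_v| / λ) + Σ_i  P_i · exp(−(x − x_i)² / (2σ²))
```

* `B` — constant background (normalized-signal units): non-specific
  ligation spread evenly across the region.
* `I`, `λ` — the viewpoint-proximal intensity and decay length (bp) of the
  monotonic contact-frequency decay. Under default simulation conditions
  λ = 50 kb, a typical near-cis scale.
* `P_i`, `x_i`, `σ` — amplitudes and centers of `N` Gaussian interaction
  peaks sharing a single width σ. The shared width follows the model as
  written (one σ outside the sum); an independent per-peak width is not
  identifiable from typical fragment densities and is not offered.

The model is a function of genomic coordinate; the per-fragment observable
is the model evaluated at the fragment midpoint. All model fitting happens
after preprocessing, so amplitudes are in normalized units (in-window total
scaled to 10⁶).

## Preprocessing

Three fragment filters precede any fitting, applied as independent masks
(hence order-free):

1. **Blind fragments** — both flanks cut by the same enzyme (either
   primary–primary or secondary–secondary) carry no usable ligation
   junction and are dropped. Flanks at the ends of the analysis region are
   labelled `boundary` and never count as "same enzyme": they are
   windowing artifacts, not restriction sites.
2. **Short fragments** — length < 40 bp (strict: exactly 40 bp is kept).
3. **Viewpoint-proximal fragments** — midpoint within a window of total
   width 10 kb centred on `x_v` (i.e. |x − x_v| < 5 kb). The window size
   is read as the *total* width; `--viewpoint-window` accepts other values
   (e.g. 20000 for ±10 kb) for users who prefer the wider reading.

Counts are then scaled so the total within ±2 Mb of the viewpoint equals
10⁶ — a reads-per-million-style convention; only the window is fixed by
the method, the scale is a package choice that makes profiles comparable
across sequencing depths. Window membership is by fragment midpoint with
inclusive bounds.

## Decay fit on the symmetrized profile

The decay is assumed symmetric about the viewpoint, so both arms are
pooled by distance `d = |x − x_v|` into 2-kb bins; each bin carries the
mean signal `m_b`, the number of contributing fragments `w_b`, and — as
its representative distance — the mean fragment distance (less biased than
the bin midpoint when fragment density varies). `(B, I, λ)` minimise
`Σ_b w_b (m_b − B − I e^{−d_b/λ})²` under `B, I ≥ 0, λ > 0`, solved by a
trust-region reflective least-squares solver (relative tolerances 1e-10,
at most 500 function evaluations). Initialisation is robust and
scale-aware: `B₀` is the median of the far half of the bins, `I₀` the
profile maximum above `B₀` (floored at machine epsilon), `λ₀` the first
distance at which the signal drops below `B₀ + I₀/e` (fallback 50 kb). A
flat profile converges to `B` = weighted mean with `I ≈ 0` and an
unidentified λ, and is flagged with a warning rather than an error.

This binned fit only *initialises* the decay: the final decay parameters
come from the joint unbinned refit below, which removes the small Jensen
bias that distance-binning an exponential introduces.

## Noise model and candidate detection

The method's significance threshold (p < 0.0005) needs a null. The package
constructs one empirically: residuals against the decay-only model are
grouped into four log-spaced distance bands (merged until every band holds
at least 20 fragments) and each band gets a robust scale,
`1.4826 · median(|r − median(r)|)` — the normal-consistent MAD, insensitive
to the very peaks still present in the residuals. Count noise is
heteroscedastic (Poisson-like, so larger near the viewpoint); the banding
tracks that without assuming a specific mean–variance law.

Candidate peaks are local maxima of the residual z-score `r_j / scale(d_j)`
after a centred running mean over 5 fragments, accepted when the smoothed
z ≥ 3 and thinned greedily to a minimum separation of 2σ₀ (σ₀ = 3 kb, the
initial peak width). Under a pure-noise profile the smoothed z has standard
deviation ≈ 1/√5, so the threshold is conservative; detection sensitivity
is set by the joint-fit significance test, not by this pre-screen.

## Joint peak fitting and significance

Candidates are added greedily in descending detection z. After each
addition, *all* parameters — `(B, I, λ)`, the shared σ, and every
`(P_i, x_i)` — are refit jointly over the full unbinned profile
(bounds: `P_i ≥ 0`; `x_i` within ±3σ₀ of its candidate; σ between the
minimum fragment spacing and 10σ₀; solver tolerances 1e-12). Each peak's
amplitude gets a Wald test: `SE(P_i)` from the Gauss–Newton covariance
`s²(JᵀJ)⁻¹` at the optimum, one-sided p = 1 − Φ(P_i/SE). Selection stops
at the first candidate whose p-value fails the threshold; that candidate
is dropped. The stopping rule makes the residual RMSE non-increasing over
retained peaks by construction (each refit only adds parameters).

Significance is strict, `p < α` with α = 0.0005 by default, with no
multiplicity correction — a single raw threshold is the method's stated
decision rule. `call_significant(..., fdr="bh")` (CLI `--fdr bh`) instead
thresholds Benjamini–Hochberg adjusted p-values for users who want FDR
control across many viewpoints. The Wald construction is deterministic;
an empirical permutation null was considered as an alternative and not
implemented: it would require ~10³ joint refits per profile for a decision
the Wald test already makes with large margins at realistic depths (true
peaks typically reach |z| > 20, spurious candidates |z| < 3).

## Synthetic data

The generator emulates exactly the structure the model assumes, which is
what makes recovery tests meaningful and bounds what they show:

* **Genomes** — i.i.d. bases at GC 0.41 (human-like). Real sequence has
  repeats and CpG structure that modulate restriction-site density; the
  simulated fragment-length distribution is geometric-like with mean
  ≈ 130 bp for the DpnII/Csp6I pair, which is realistic in aggregate.
* **Profiles** — expected counts `μ_j = c · S(x_j)` at fragment midpoints,
  with `c` chosen so the ±2 Mb expected total equals the target depth;
  counts are independent Poisson(μ_j). Poisson is the minimal model for
  sequencing counts; `dispersion=γ` switches to gamma-Poisson
  (Var = μ + γμ²) for over-dispersion studies, off by default. PCR
  duplicates, mappability and ligation biases are *not* simulated, so
  passing recovery tests demonstrates correctness of the estimator under
  the stated noise model, not robustness to library artifacts.
  A model that is identically zero yields an all-zero profile rather than
  an error; scaling to a target depth is then vacuous.
* **Reference conditions** — 4 Mb region, viewpoint centred, B = 5,
  I = 500, λ = 50 kb, three peaks of amplitudes 150/100/50 at +32 kb
  (an ECR5-like enhancer distance), −150 kb and +600 kb, σ = 3 kb,
  depth 10⁶ within ±2 Mb. These are the package's standard strong-signal
  near-cis conditions; validation studies share one restriction map per
  study (drawn from the base seed) and vary count noise across seeds,
  emulating repeated libraries on a fixed genome.
* **Reporter tables** — four constructs (empty vector, major allele,
  minor allele, positive control) × 4 experiments × 3 replicates, the
  standard dual-luciferase design. Expected RLU are 1, 20, 20·effect and
  31.6; both luminescence channels carry mean-corrected log-normal noise
  with coefficient of variation `cv` (default 0.10), so RLU expectations
  are exact and the RLU coefficient of variation equals `cv`. Defaults:
  effect_ratio 0.75, i.e. a 25% reduction for the minor allele.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open throughout; bedGraph/BED are read and
  written in the same convention; the CLI converts 1-based
  `chrom:start-end` viewpoints and sorts inverted bounds before converting.
* Enzyme cut offsets: DpnII cuts 5′ of GATC (offset 0), Csp6I cuts G^TAC
  (offset 1) — catalog chemistry. `N` bases never match a motif. If both
  enzymes cut at the same coordinate the cut is counted once, labelled
  with the primary enzyme.
* Exactly-zero residual bands (noise-free input) would give zero noise
  scales; the candidate z-scores then fall back to the smallest positive
  band scale (or a tiny floor), and Wald variances are floored at the
  smallest positive float, so noise-free profiles flow through the same
  code path and recover parameters to machine precision.
* The decay fit requires ≥ 5 bins; noise estimation ≥ 20 fragments;
  Shapiro–Wilk (hence `compare_alleles`) ≥ 3 values per group.
* Reporter replicates are pooled across experiments for the Welch test
  (n = 12 per construct under the default design), matching a single
  two-group comparison; `mode="experiment_means"` (n = 4) is available
  for users who prefer batch means. Testing is two-sided.

## Validation study sizes

The acceptance script and test suite use: 20 random 100-kb genomes for
the digestion oracle; 20 seeds at depth 10⁶ for noisy parameter recovery;
100 peak-free simulations for specificity; 1,000 simulated assays for
reporter power; 1,000 × 1,000 random intervals for the annotation oracle.
These sizes give stable medians and rates while keeping a full run in the
tens of seconds on one core.

## Known limitations

* Single-viewpoint, near-cis only: no trans contacts, no far-cis
  statistics, no replicate-aware differential testing.
* The Wald p-value ignores model-selection effects (the peak was chosen
  because it looked large); the specificity study shows the practical
  false-positive rate is near zero at the default threshold, but the
  p-values are not calibrated for marginal peaks.
* Shared σ misfits profiles whose loops have very different footprints;
  such peaks fit with intermediate width and inflated residuals.
* The annotation step reports interval overlap only; nearest-feature
  assignment for non-overlapping peaks is intentionally out of scope.
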