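# Methods

## The measurement being modelled

A two-photon tomograph excites dermal autofluorescence (mostly NAD(P)H,
plus lipofuscin/lipids and the ECM proteins collagen and elastin) with
100 fs pulses at an 80 MHz repetition rate.  Time-correlated single-photon
counting (TCSPC) accumulates photon arrival times into a histogram per
pixel over one excitation period (12.5 ns).  The decay of a cell is
described by a bi-exponential model

    f(t) = a1·exp(−t/τ1) + a2·exp(−t/τ2),   a1 + a2 = 1,

where τ1 (short) tracks free NAD(P)H and τ2 (long) bound NAD(P)H; the
amplitude-weighted mean lifetime is τm = (a1τ1 + a2τ2)/(a1 + a2).
Glycolytic M1 macrophages have short lifetimes and a large a1/a2;
oxidative M2 macrophages have long lifetimes and a1/a2 near 1.

## Reference class table

`tpeflim/data/reference_classes.csv` encodes, per cell class, the mean ±
SD of τ1, τ2, τm, a1/a2 and autofluorescence intensity (photons/mW), the
environment (in vitro / ex vivo / in vivo), the classifier group label
(0 = M1, 1 = M2, 2 = other dermal cell) and the number of cells that the
class contributes to the assembled 399-cell classification dataset
(105 M1 + 95 M2 + 199 other).

Choices that were genuinely open:

- **Counts.**  Where the per-class tallies disagree between sources, the
  dataset-level enumeration wins and per-class ratios are rescaled by
  largest remainder: the in vivo macrophages are 40 M1 + 2 phagocytosing
  M1 + 28 M2 (= 70), and the in vitro mast cells 45 resting + 14
  activated (= 59).  Monocytes are characterised in the table's source
  but are not part of the 399-cell dataset, so they are not bundled.
- **Ex vivo / in vivo mast cells.**  The dataset contains 17 ex vivo and
  82 in vivo mast cells, but no separate decay-parameter distributions
  are published for them.  Their rows are synthetic stand-ins that reuse
  the in vitro resting/activated distributions, split by the same
  43 : 13 ratio.  This is the single most consequential free choice in
  the generator (see "Known limitations").

## Synthetic cell generator

Per-cell ground truth is drawn independently per parameter from the
class's Gaussian, truncated at 0 by resampling; (τ1, τ2) pairs are
redrawn jointly until τ1 < τ2.  The amplitude ratio r = a1/a2 is drawn
the same way and mapped to the unit simplex, a1 = r/(1+r).  τm is never
sampled: it is computed from the sampled parameters, keeping every
feature vector internally consistent (the mean of a nonlinear function
of means need not match the tabulated τm, and does not have to).  All
sampling is bit-reproducible under a fixed `numpy` seed.

## TCSPC simulation and decay fitting

**Forward model.**  Each exponential component convolved with a Gaussian
IRF has the closed exponentially-modified-Gaussian form; the incomplete
decay of earlier pulses under periodic excitation is added analytically
as a geometric series (exact because the IRF width ≪ period).  Expected
channel counts are `total_photons × normalised shape + background`;
observed counts are Poisson draws.  Defaults: 256 channels over 12.5 ns
(≈48.8 ps/channel) and an 80 ps FWHM Gaussian IRF — concrete
instantiations of an unstated ADC resolution and an IRF specified only
as "below 100 ps".  The wrap term contributes ≲1% for τ2 ≈ 2.4 ns but
keeps the model exact, which matters for χ² calibration.

**Fitting.**  Parameters (a1, τ1, τ2, shift, amplitude, offset) are
estimated by minimising the Poisson deviance — the maximum-likelihood
objective for counting noise, which makes the goodness-of-fit band
meaningful; a 1/counts weighted-least-squares mode exists for
cross-checks.  Initialisation is multi-start over a coarse lifetime grid
(τ1 ∈ {100, 300, 600} ps × τ2 ∈ {1200, 2000, 3000} ps); each start gets a
fast linear amplitude/offset solve, and the best two are polished with
L-BFGS-B in a normalised parameter space (lifetimes in ns, amplitude in
log units) so finite-difference gradients are well conditioned.
Convergence: relative deviance change below 1e-11 or 500 iterations.
The IRF shift is fitted within ±3 channels (the reference workflow only
says the shift "was compensated"); the offset is fitted by default.
τ1 ≤ τ2 is enforced by component swap.  Goodness of fit is Pearson χ²
per degree of freedom (whether the reference software uses Pearson or
Neyman weighting is unknown; Pearson is used and documented).  Curves
below 1000 photons are rejected; curves below the 5000-photon analysis
floor are fitted but flagged.

Spatial binning sums the (2b+1)² window around each pixel (b = 3 → 49
pixels) with windows truncated at image borders — border behaviour of
the reference software is unspecified, truncation avoids inventing data.

## Phasor analysis

The first Fourier harmonic at the repetition frequency maps each decay
to (g, s); channel-center times are used for the discrete transform.
Because the Fourier coefficients of a periodised decay equal samples of
its continuous transform, wrapped mono-exponentials land on the
universal semicircle to discretisation error (<1e-3 at 256 channels).
Measured-histogram phasors are reported as-is; an optional calibration
divides out a measured mono-exponential reference (the complex factor
contributed by IRF and electronics).  The intensity mask retains pixels
above a configurable fraction of the maximum (default 0.7; 0.9 is the
other documented choice for figure-style summaries).

## Decision tree

A from-scratch CART with entropy impurity H = −Σ p·log₂p.  Splits
(feature j, threshold t, rule x_j ≤ t) are found by exhaustive scan over
all features and all midpoints between consecutive distinct sorted
values, minimising the sample-weighted child impurity
G = (n_left H_left + n_right H_right)/N.  Hyperparameters are fixed at
the tuned values: max depth 9, min samples split 2, equal sample
weights.  Determinism is total: ties break by lowest feature index, then
lowest threshold, and predictions by lowest class index.  Zero-gain
splits are allowed, as in standard CART — an impure node such as a 2-D
XOR configuration needs one gain-free split before progress is possible;
recursion is still bounded by purity, depth and node size.  Scores for
ROC curves are the leaf class proportions p_mk.  Models serialise to
JSON losslessly.

## Evaluation protocol

The headline metrics are means ± SDs over repeated uniform random 50/50
train/test splits (default 10,000; 1,000 in the acceptance runs, where
the mean is stable to well under a percentage point).  Splits are not
stratified; a repeat whose train or test half misses a class entirely is
redrawn and counted.  Sensitivity and specificity are one-vs-rest per
class from the test-half confusion matrix; the multiclass specificity
convention (one-vs-rest) is this package's choice, as the reference
reports a single specificity per class without defining it.  The
reported ±SD is the SD across repeats (across-fold SD is the other
possible reading).  Fivefold cross-validation uses one shuffled
partition and reports per-fold accuracy and its mean.  Distribution
comparisons use the two-sample Kolmogorov–Smirnov test at α = 0.05.

## Feature vector

The default classifier input is exactly the 8 decay-derived values
(τ1, τ2, a1, a2, τm, τ2/τ1, a1/a2, (a1−a2)/(a1+a2)); intensity
(photons/mW, power-normalised, averaged over the 49-pixel window) and a
circular/noncircular shape flag are opt-in, and cell size is never
included.  τ2/τ1 (≥1) is used rather than its reciprocal; for a
threshold tree on a monotone transform the two are equivalent.  The
"decay curve" itself is not encoded as a feature — no encoding is
specified anywhere, and the 8-value vector is the documented final
model.  2D segmentation gates per-pixel (τ1, a1/a2) values against
per-class mean ± 2·SD boxes pooled from the reference table; pixels in
more than one box are labelled ambiguous rather than forced.

## What the synthetic data does and does not show

The generator reproduces the class structure the analysis assumes:
marginal means and SDs of every printed parameter, the per-class counts,
photon-counting noise, IRF convolution and periodic wrap-around.  It
does **not** reproduce the correlation structure of real cells — each
parameter is drawn independently, so each class fills its whole
parameter box instead of a thinner correlated manifold — and the 99
ex vivo/in vivo mast cells borrow the (wide) in vitro distributions.
Both effects overstate the overlap between M2 macrophages and resting
mast cells.  Consequences, measured with this package and confirmed
against an independent CART implementation:

- M1 metrics and the known-phenotype M1-vs-M2 task reproduce the
  published values (M1 sensitivity ≈ 0.86–0.89 vs 0.88, specificity
  ≈ 0.95 vs 0.89; ground-truth task ≈ 0.99/0.99 vs 0.95/0.97).
- M2 sensitivity saturates near 0.55 (published: 0.82), the pooled
  binary task near 0.71 (0.81) and fivefold CV near 0.76 (0.90), because
  a real M2-vs-mast separation that the published per-cell data
  evidently contained (misclassification occurred only "in rare cases")
  is not representable from marginal summaries alone.

Passing results on this synthetic set therefore validate the pipeline
mechanics and the M1 signature; they do not certify M2 performance on
real data, which requires per-cell measurements.

## Numerical and degenerate-input conventions

Correlation screens report Pearson and Spearman coefficients as NaN
(undefined) for constant columns; confusion-matrix rates with a zero
denominator are NaN, never 0.  The mono-exponential limit τ1 = τ2 is
fitted correctly but flagged degenerate (the amplitude split is then
unidentifiable).  All-zero histograms, overlapping scene ellipses, empty
segmentation gates and mismatched feature counts raise errors rather
than guessing.  Problem sizes used by the bundled checks — 1,000
evaluation repeats, 100 fits per distinct class distribution at 10⁵
photons, 20 oracle datasets of up to 200 samples — were chosen so the
stochastic metrics are stable to a couple of points while the whole
suite stays cheap to run.
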