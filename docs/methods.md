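# Methods

This note records the models, parameter choices and numerical decisions
behind `ramanmatch`, and what the simulation-based tests do and do not
demonstrate about real instrument data.

## Post-processing model

A raw Raman export is treated as irregular samples of
*y(ν) = b(ν) + Σᵢ gᵢ(ν) + ε*, where *b* is a broad smooth fluorescence
background, *gᵢ* are Raman bands, and *ε* is zero-mean detector noise with
occasional single-sample cosmic-ray spikes. The four processing stages
target these components in order.

**Median filter.** The window is defined in physical units
(`median_window_cm1`, default 15 cm⁻¹, centered, truncated at the edges)
rather than in sample counts, because raw sampling varies between roughly
5.5 and 8.3 cm⁻¹ and between instruments; a count-based window would have
a different physical width on every spectrum. The filter is an exact
order-statistic median over all samples within ±half-window; an
independent brute-force loop reproduces it elementwise in the tests. A
window narrower than the smallest sample spacing is rejected as a
configuration error, since every window would then contain only its own
center. Two consequences of a selection median are worth stating
explicitly:

* it rejects isolated spikes completely (a spike occupies one sample of a
  multi-sample window), which is why the simulator's cosmic-ray spikes are
  at least 20× the noise scale — the rejection test is then unambiguous;
* it flattens the top of a band over its window, so the *location* of a
  band apex after the full pipeline is reliable only to about half the
  median window (measured ≲ 3 cm⁻¹ for isolated strong bands), not to the
  1 cm⁻¹ grid. Tests that compare recovered apexes to generative band
  centers use a 5–7.5 cm⁻¹ bound for this reason. Apexes recovered from
  baseline correction *alone* are accurate to ±1 cm⁻¹.

**Baseline correction.** The fluorescence proxy is an iterated
peak-suppressing polynomial fit (modified polyfit): fit a degree-7
polynomial by least squares, clamp the working spectrum to the fitted
curve wherever it exceeds the fit, and repeat. Peaks are progressively
excluded from the fit, which settles under the bands and tracks the
smooth background; the final fit is subtracted. Degree 7
(`baseline_order`) matches the smoothness of fluorescence backgrounds
while being far too stiff to follow Raman bands. Small negative residuals
after subtraction are retained: clipping would bias the SNV moments.

Convergence is declared when the L2 change between successive fits drops
below `baseline_tol` (default 1e-4) *relative to the first change*.
Successive-fit differences cancel any additive polynomial and scale
linearly with detector gain, so the iteration count — and therefore the
whole pipeline — is exactly equivariant under *y → a·y + p* for gain
*a > 0* and any representable polynomial *p*. (A tolerance relative to
the fit norm, the obvious alternative, silently breaks this: the norm
depends on the offset, so two gain-shifted copies of the same spectrum
can stop at different iterations.) Hitting `baseline_max_iter` (default
100) is logged, not an error. Fitting uses `numpy.polynomial` with its
internal domain mapping, so degree 7 over [200, 3400] is well
conditioned.

**Re-gridding.** Baseline correction and continuous representation are
two different jobs: a global degree-7 polynomial cannot represent Raman
bands, so continuity comes from a separate cubic interpolating spline
(`scipy.interpolate.CubicSpline`) evaluated on the canonical grid —
200–3400 cm⁻¹ inclusive at 1 cm⁻¹, 3201 nodes. The raw support must cover
the grid; the error message states the shortfall in cm⁻¹. Re-gridding
precedes normalization so that SNV moments are computed on the shared
axis rather than on instrument-dependent sample positions.

**SNV and rescaling.** Standard normal variate uses the sample (n−1)
standard deviation; min–max rescaling then fixes the range to [0, 1]
exactly. Their composition is invariant under positive affine transforms
of the input, which is what removes gain and offset; Pearson correlation
is invariant under the same group, so matching results are identical
whether computed on SNV'd or rescaled vectors (verified by test).

One known limitation follows from the stage order (median first, as the
routine prescribes): the composition is *not* exactly invariant to adding
a large smooth background to the raw input. A selection median commutes
with an added polynomial only where the sum is monotone within each
window; where sample orderings flip, the error is of order
(sample spacing × background slope), about 0.005–0.01 raw and up to
~0.08 on the final 0–1 scale for backgrounds comparable to the
fluorescence itself. The deviation scales linearly with the background
amplitude and vanishes for backgrounds that are small relative to the
within-window signal variation. The acceptance suite measures this
honestly (`baseline_invariance_max_dev`); every other source of
background sensitivity was eliminated by the equivariant stopping rule
above.

## Matching and clustering

Pearson *r* between processed vectors on the shared grid, distance
*d = 1 − r*; correlations are clipped to [−1, 1] to absorb floating-point
excess. Assignment is nearest neighbor by minimum *d* (equivalently
maximum *r*), with ties broken by ascending specimen id so results are
deterministic under library reordering. No acceptance threshold is
imposed by default; the CLI's `--min-r` flags low-confidence assignments
instead of suppressing them, because a survey wants every fragment scored.
Constant (zero-variance) spectra have no defined correlation and are
reported as errors naming the offending specimen.

Hierarchical clustering runs `scipy.cluster.hierarchy.linkage` on the
condensed Pearson distance matrix; complete linkage is the default (the
usual choice in this ecosystem, and the one under which merge heights are
guaranteed non-decreasing), with average, single and Ward available. Tie
handling among equal-distance pairs follows scipy's deterministic
internal order. Dendrograms export to Newick with merge heights halved,
the ultrametric convention under which the leaf-to-leaf path length
through the tree equals the cophenetic distance; scikit-bio parses the
output in the round-trip tests.

## Peak detection

A node is a peak iff its intensity is the maximum of the centered
101-node window (truncated at the edges) and at least 0.2 on the 0–1
relative scale. Plateau ties resolve to the lowest wavenumber, which both
makes the rule deterministic and guarantees two reported peaks are never
closer than half a window. The implementation uses a maximum filter with
−∞ padding plus an explicit earlier-equal check; the tests verify it node
by node against a literal restatement of the definition. On the 1 cm⁻¹
grid, 101 nodes equal 101 cm⁻¹, wide enough to suppress noise maxima
while separating the major band groups. Group summaries average member
spectra on the common grid, re-rescale to [0, 1], and re-detect — so a
group peak is a peak of the average, not a vote among members.

## Synthetic-spectrum generator

The generator emulates the features the pipeline assumes, with defaults
chosen as plausible study conditions and then left alone:

| parameter | default | rationale |
| --- | --- | --- |
| sampling step | 6.9 cm⁻¹, jittered ±20% | midpoint of the 5.5–8.3 cm⁻¹ instrument resolution range |
| `n_scans` | 100 | multi-scan averaging as acquired |
| per-scan `noise_sd` | 0.2 | SNR ≈ 50 on a unit dominant band after 100-scan averaging |
| `spike_rate` | 0.5 / spectrum | occasional cosmic rays; amplitude ≥ 20× noise scale |
| bands per class | 4–10 | typical number of prominent polymer bands |
| band width | 10–30 cm⁻¹ | typical Raman bandwidths |
| baseline | quadratic, ~3–8× band amplitude | fluorescence dominating the Raman signal |
| class separation | dominant centers ≥ 60 cm⁻¹ apart | distinguishable classes |

Additive noise has standard deviation `noise_sd/√n_scans` (the averaging
law, verified by Monte Carlo at 200 replicates: ratio 0.1 ± 0.02 for 100
vs 1 scans). Counts are floored at zero to honour the non-negativity of
detector counts; with the default baselines the floor is never reached,
so the noise law is unbiased at study conditions. Weathering at severity
*s* inflates band widths by (1 + *s*), jitters amplitudes by ±20 %·*s*,
inflates the baseline by (1 + 2*s*), and adds a broad band near
1715 cm⁻¹ with amplitude proportional to *s* — a generic carbonyl
(oxidation) proxy, a simulator convention rather than a chemical claim.
An optional exponential background term exists for stress-testing the
polynomial baseline stage. Everything is reproducible from an integer
seed.

What the simulator does *not* model: real polymer band dictionaries,
instrument response functions, detector etaloning, sample heterogeneity,
or fluorescence that saturates the detector. Passing the end-to-end tests
therefore shows that the pipeline's stages compose correctly and that
Pearson matching separates classes whose band structure differs — it does
not certify identification accuracy on real weathered environmental
fragments, which depends on library coverage and on spectral variation
the generator does not emulate.

## Package shape

The pipeline is exposed both as module-level functions mirroring each
operation and as scikit-learn estimators (`RamanPreprocessor`,
`PearsonNearestNeighbor`, `PearsonHierarchicalClustering`), because the
preprocessing is transform-shaped and the matcher is a 1-NN classifier;
the estimator form composes with sklearn pipelines and model selection
for free. The preprocessor is stateless (per-spectrum normalization
learns nothing from a training set); `fit` only resolves configuration.

Problem sizes in the test and acceptance suites (10-class libraries, 200
weathered queries, 200 Monte-Carlo replicates, 100-spectrum oracle
corpora) were chosen so the whole suite completes in well under a minute
while keeping binomial/Monte-Carlo uncertainty far from the asserted
bounds (e.g. 200 queries at a true ≥ 99 % recovery rate put the 95 %
threshold many standard errors away).

## Degenerate inputs and edge policies

* Spectra need ≥ 16 points, strictly ascending after duplicate collapse
  (exact duplicate wavenumbers average their intensities).
* Constant spectra are rejected wherever a variance or range is needed
  (SNV, rescale, correlation), with the specimen named.
* Baseline fitting requires at least `baseline_order + 2` points.
* Median and peak windows truncate at the edges rather than pad, so edge
  statistics use only observed samples.
* Library matrices must be complete (every spectrum has metadata and vice
  versa) and already on the [0, 1] scale; orphans are listed in the
  error.
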