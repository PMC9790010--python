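# ramanmatch

Raman spectral preprocessing, library matching and clustering for
identifying anthropogenic and biological polymers — the workflow used to
assign unknown environmental microplastic fragments to entries of an open
Raman reference library.

## The problem

Microplastic surveys recover fragments whose polymer identity must be
established spectroscopically. Raman spectra of the same polymer vary with
detector gain, fluorescence background, weathering state, color and
surface texture, so raw spectra cannot be compared directly. This package
implements the two pieces that make comparison work:

1. **Post-processing** that maps any raw export onto a common, unitless
   representation. For a raw spectrum *y(ν)* sampled irregularly in
   wavenumber *ν*:

   * sliding **median filter** over a ±7.5 cm⁻¹ window (15 cm⁻¹ wide),
     which rejects cosmic-ray spikes and shot noise;
   * **baseline correction** by an iterated peak-suppressing polynomial
     fit of degree 7: after each least-squares fit, points above the
     fitted curve are clamped to it and the fit repeats until it settles
     under the Raman bands, tracking only the broad fluorescence; the
     baseline is subtracted;
   * **re-gridding** by cubic interpolating spline onto the canonical
     200–3400 cm⁻¹ axis at 1 cm⁻¹ (3201 nodes), so every spectrum has an
     identical axis with no missing values;
   * **SNV normalization** *x → (x − x̄)/s* followed by min–max
     **rescaling** to [0, 1], which removes gain and offset entirely.

2. **Pearson-distance matching.** Two processed spectra are compared by
   the product-moment correlation *r*; the Pearson distance *d = 1 − r*
   is 0 for perfectly covarying spectra and up to 2 for anti-correlated
   ones. An unknown is assigned the label of the library spectrum with
   minimum *d* (nearest neighbor); the all-pairs distance matrix also
   feeds agglomerative clustering (dendrograms of polymer relatedness)
   and windowed peak summaries (local maxima of a 101-node moving window
   above a 0.2 relative-intensity floor).

A seeded simulator generates labeled synthetic spectra — Gaussian or
Lorentzian bands on a smooth fluorescence baseline, multi-scan-averaged
noise, cosmic-ray spikes, irregular sampling, and a weathering transform
that broadens bands and grows a carbonyl-like feature near 1715 cm⁻¹ — so
the entire pipeline is testable end to end without any instrument data.

## Worked example

```python
import numpy as np
import ramanmatch as rm

# build a small labeled reference library from the simulator
sim = rm.simulate_library(n_classes=5, reps_per_class=2, seed=7)
pre = rm.RamanPreprocessor().fit()
spectra = [pre.transform_spectrum(s) for s in sim.spectra]
metadata = [
    rm.SpecimenMetadata(unique_id=s.specimen_id, polymer=label,
                        category="pristine anthropogenic")
    for s, label in zip(sim.spectra, sim.truth)
]
library = rm.SpectrumLibrary.from_spectra(spectra, metadata)

# an "unknown": a weathered, noisy replicate of class02
weathered = rm.weather(sim.models["class02"], severity=0.5, seed=1)
raw_query = rm.render_spectrum(weathered, seed=2, specimen_id="beach_fragment")
result = rm.match_query(pre.transform_spectrum(raw_query), library, top_k=3)

for rank, (uid, r, d) in enumerate(result.candidates, 1):
    print(f"{rank}. {uid:12s} polymer={library.metadata[uid].polymer}  "
          f"r={r:.4f}  d={d:.4f}")
```

prints

```
1. class02_r1   polymer=class02  r=0.9261  d=0.0739
2. class02_r2   polymer=class02  r=0.9243  d=0.0757
3. class03_r1   polymer=class03  r=0.2030  d=0.7970
```

Both replicates of the true class rank first with *r* > 0.92 despite
weathering (broadened bands, doubled fluorescence, a new carbonyl band),
while the best wrong-class candidate is far away at *d* ≈ 0.8 — the gap
that makes minimum-distance assignment reliable.

`RamanPreprocessor`, `PearsonNearestNeighbor` and
`PearsonHierarchicalClustering` follow the scikit-learn estimator protocol
(`fit`/`transform`/`predict`, `get_params`), so they drop into sklearn
pipelines and model selection.

## Command line

The same workflow is scriptable:

```sh
ramanmatch simulate --classes 10 --reps 3 --seed 1 --out raw/
ramanmatch build-library --raw-dir raw/ --metadata raw/metadata.csv --out-dir lib/
ramanmatch identify --query unknown.csv --library lib/ --top-k 5 --out report.csv
ramanmatch cluster --library lib/ --out dendrogram.nwk
ramanmatch peaks --library lib/ --group-by polymer --out peaks.csv
```

Every command writes a `run_manifest.json` (configuration, seed, input
hashes) sufficient to reproduce its outputs bit-identically. Metadata rows
without a spectrum file are reported as excluded, not fatal.

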