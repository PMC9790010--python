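"""Synthetic Raman spectrum generator with truth labels.

Emulates the structure the pipeline assumes a raw export to have:
additive Gaussian/Lorentzian bands on a broad smooth fluorescence
baseline, zero-mean detector noise whose standard deviation shrinks as
1/√n_scans under multi-scan averaging, occasional cosmic-ray spikes, and
an irregular sampling axis (step jittered ±20% around the nominal
instrument resolution).  A *weathering* transform perturbs a class model
the way environmental exposure perturbs a polymer: broader bands,
jittered amplitudes, stronger fluorescence, and a growing carbonyl-like
band near 1715 cm⁻¹.

Everything is reproducible from an integer seed: identical
(model, parameters, seed) give byte-identical spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .types import RawSpectrum

__all__ = [
    "Band",
    "SyntheticClassModel",
    "SimulatedLibrary",
    "render_spectrum",
    "weather",
    "simulate_library",
]

GRID_MIN, GRID_MAX = 200.0, 3400.0
#: Nominal sampling step: midpoint of the source instruments' 5.5–8.3 cm⁻¹
#: spectral resolution.
DEFAULT_STEP_CM1 = 6.9
DEFAULT_N_SCANS = 100
#: Per-scan additive noise scale relative to a dominant band amplitude of 1.
DEFAULT_NOISE_SD = 0.2
DEFAULT_SPIKE_RATE = 0.5
#: Carbonyl-region center used by the weathering transform (oxidation proxy).
CARBONYL_CM1 = 1715.0


@dataclass(frozen=True)
class Band:
    center_cm1: float
    width_cm1: float
    amplitude: float
    shape: str = "gaussian"  # or "lorentzian"

    def __post_init__(self) -> None:
        if not (GRID_MIN <= self.center_cm1 <= GRID_MAX):
            raise ValueError(f"band center {self.center_cm1} outside [{GRID_MIN}, {GRID_MAX}]")
        if self.width_cm1 <= 0 or self.amplitude <= 0:
            raise ValueError("band width and amplitude must be > 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def profile(self, w: np.ndarray) -> np.ndarray:
        x = (w - self.center_cm1) / self.width_cm1
        if self.shape == "gaussian":
            return self.amplitude * np.exp(-0.5 * x * x)
        return self.amplitude / (1.0 + x * x)


@dataclass(frozen=True)
class SyntheticClassModel:
    """Generative description of one polymer class.

    ``baseline_coeffs`` are polynomial coefficients (ascending degree,
    degree ≤ 5) in the reduced variable ``t = (w − 200)/3200`` so their
    magnitudes stay O(1); the baseline stands in for fluorescence and must
    be non-negative across the canonical range.  ``exp_background``, when
    set to ``(amplitude, decay_cm1)``, adds a decaying exponential for
    stress-testing the polynomial baseline stage.
    """

    label: str
    bands: tuple[Band, ...]
    baseline_coeffs: tuple[float, ...] = (3.0,)
    noise_sd: float = DEFAULT_NOISE_SD
    spike_rate: float = DEFAULT_SPIKE_RATE
    exp_background: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError(f"{self.label}: a class model needs at least one band")
        if len(self.baseline_coeffs) > 6:
            raise ValueError("baseline polynomial degree must be <= 5")
        if self.noise_sd < 0 or self.spike_rate < 0:
            raise ValueError("noise_sd and spike_rate must be >= 0")
        w = np.linspace(GRID_MIN, GRID_MAX, 401)
        if self.baseline(w).min() < 0:
            raise ValueError(f"{self.label}: baseline goes negative on [{GRID_MIN}, {GRID_MAX}]")

    def baseline(self, w: np.ndarray) -> np.ndarray:
        t = (np.asarray(w, dtype=float) - GRID_MIN) / (GRID_MAX - GRID_MIN)
        out = np.polynomial.polynomial.polyval(t, np.asarray(self.baseline_coeffs))
        if self.exp_background is not None:
            amp, decay = self.exp_background
            out = out + amp * np.exp(-(np.asarray(w) - GRID_MIN) / decay)
        return out

    def mean_curve(self, w: np.ndarray) -> np.ndarray:
        """Noise-free expected intensity: Σ bands + baseline."""
        out = self.baseline(w)
        for b in self.bands:
            out = out + b.profile(w)
        return out

    @property
    def dominant_center(self) -> float:
        return max(self.bands, key=lambda b: b.amplitude).center_cm1


@dataclass(frozen=True)
class SimulatedLibrary:
    """Rendered spectra with their generating models and truth labels."""

    spectra: tuple[RawSpectrum, ...]
    truth: tuple[str, ...]
    models: dict[str, SyntheticClassModel]
    seed: int

    def __post_init__(self) -> None:
        if len(self.spectra) != len(self.truth):
            raise ValueError("one truth label per spectrum required")
        unknown = sorted(set(self.truth) - set(self.models))
        if unknown:
            raise ValueError(f"truth labels without a model: {unknown}")


def _irregular_axis(rng: np.random.Generator, step: float) -> np.ndarray:
    """Strictly ascending axis covering [GRID_MIN, GRID_MAX] with ±20% jitter."""
    pts = [GRID_MIN - step]
    while pts[-1] < GRID_MAX + step:
        pts.append(pts[-1] + step * (1.0 + 0.2 * (2.0 * rng.random() - 1.0)))
    return np.asarray(pts)


def render_spectrum(
    model: SyntheticClassModel,
    n_scans: int = DEFAULT_N_SCANS,
    sampling_step_cm1: float = DEFAULT_STEP_CM1,
    seed: int = 0,
    specimen_id: str | None = None,
) -> RawSpectrum:
    """Draw one raw spectrum from a class model.

    Additive noise has sd = ``noise_sd / sqrt(n_scans)`` (the multi-scan
    averaging law); cosmic-ray spikes are Poisson(``spike_rate``) per
    spectrum with amplitude at least 20× the per-scan noise scale, so a
    spike always stands far above the noise floor.  Counts are floored at
    zero.
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    if not (0.5 <= sampling_step_cm1 <= 10.0):
        raise ValueError("sampling_step_cm1 must lie in [0.5, 10]")
    rng = np.random.default_rng(seed)
    w = _irregular_axis(rng, sampling_step_cm1)
    y = model.mean_curve(w)
    if model.noise_sd > 0:
        y = y + rng.normal(0.0, model.noise_sd / np.sqrt(n_scans), size=w.size)
    n_spikes = rng.poisson(model.spike_rate)
    if n_spikes:
        amp_scale = max(model.noise_sd, 0.05 * max(b.amplitude for b in model.bands))
        pos = rng.integers(0, w.size, size=n_spikes)
        amps = (20.0 + 20.0 * rng.random(n_spikes)) * amp_scale
        y[pos] += amps
    y = np.maximum(y, 0.0)
    return RawSpectrum(specimen_id or model.label, w, y)


def weather(
    model: SyntheticClassModel, severity: float, seed: int = 0
) -> SyntheticClassModel:
    """Perturb a class model to mimic environmental weathering.

    severity 0 returns an unchanged copy; severity s inflates band widths
    by (1 + s), jitters amplitudes by ±20%·s, inflates the fluorescence
    baseline by (1 + 2s), and adds a broad carbonyl-like band near
    1715 cm⁻¹ with amplitude proportional to s.
    """
    if not (0.0 <= severity <= 1.0):
        raise ValueError(f"severity {severity} outside [0, 1]")
    if severity == 0.0:
        return replace(model)
    rng = np.random.default_rng(seed)
    bands = []
    for b in model.bands:
        jitter = 1.0 + 0.2 * severity * (2.0 * rng.random() - 1.0)
        bands.append(
            Band(b.center_cm1, b.width_cm1 * (1.0 + severity), b.amplitude * jitter, b.shape)
        )
    max_amp = max(b.amplitude for b in model.bands)
    bands.append(
        Band(CARBONYL_CM1, 45.0 * (1.0 + severity), 0.3 * severity * max_amp, "gaussian")
    )
    coeffs = tuple(c * (1.0 + 2.0 * severity) for c in model.baseline_coeffs)
    return replace(model, bands=tuple(bands), baseline_coeffs=coeffs)


def _draw_class_model(
    rng: np.random.Generator, label: str, dominant_center: float,
    noise_sd: float, spike_rate: float,
) -> SyntheticClassModel:
    n_bands = int(rng.integers(4, 11))
    bands = [Band(dominant_center, float(rng.uniform(12, 25)), 1.0, "gaussian")]
    for _ in range(n_bands - 1):
        bands.append(
            Band(
                float(rng.uniform(GRID_MIN + 100, GRID_MAX - 100)),
                float(rng.uniform(10, 30)),
                float(rng.uniform(0.2, 0.7)),
                "gaussian" if rng.random() < 0.7 else "lorentzian",
            )
        )
    # fluorescence proxy: quadratic in t = (w-200)/3200, shifted non-negative
    c = np.array([rng.uniform(3, 8), rng.uniform(-2, 4), rng.uniform(-2, 4)])
    t = np.linspace(0, 1, 101)
    lo = np.polynomial.polynomial.polyval(t, c).min()
    if lo < 0.5:
        c[0] += 0.5 - lo
    return SyntheticClassModel(
        label=label,
        bands=tuple(bands),
        baseline_coeffs=tuple(float(v) for v in c),
        noise_sd=noise_sd,
        spike_rate=spike_rate,
    )


def simulate_library(
    n_classes: int = 10,
    reps_per_class: int = 3,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
    spike_rate: float = DEFAULT_SPIKE_RATE,
    n_scans: int = DEFAULT_N_SCANS,
    sampling_step_cm1: float = DEFAULT_STEP_CM1,
    min_separation_cm1: float = 60.0,
) -> SimulatedLibrary:
    """Draw ``n_classes`` polymer-class models and render replicates.

    Dominant band centers of distinct classes are kept at least
    ``min_separation_cm1`` apart (rejection sampling over
    [400, 3200] cm⁻¹); a request that cannot be packed raises.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if reps_per_class < 1:
        raise ValueError("reps_per_class must be >= 1")
    lo, hi = 400.0, 3200.0
    if n_classes * min_separation_cm1 > (hi - lo):
        raise ValueError(
            f"cannot place {n_classes} dominant bands >= {min_separation_cm1} cm^-1 "
            f"apart inside [{lo}, {hi}]"
        )
    rng = np.random.default_rng(seed)
    centers: list[float] = []
    for _ in range(n_classes):
        for _attempt in range(1000):
            c = float(rng.uniform(lo, hi))
            if all(abs(c - c0) >= min_separation_cm1 for c0 in centers):
                centers.append(c)
                break
        else:
            raise ValueError("failed to place well-separated dominant bands")
    models = {}
    for k, c in enumerate(centers):
        label = f"class{k:02d}"
        models[label] = _draw_class_model(rng, label, c, noise_sd, spike_rate)
    spectra: list[RawSpectrum] = []
    truth: list[str] = []
    for label in models:
        for rep in range(reps_per_class):
            child = int(rng.integers(2**31))
            spectra.append(
                render_spectrum(
                    models[label],
                    n_scans=n_scans,
                    sampling_step_cm1=sampling_step_cm1,
                    seed=child,
                    specimen_id=f"{label}_r{rep + 1}",
                )
            )
            truth.append(label)
    return SimulatedLibrary(
        spectra=tuple(spectra), truth=tuple(truth), models=models, seed=seed
    )
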