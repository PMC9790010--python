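"""Four-stage spectral post-processing.

The routine that turns a raw instrument export into a comparable library
vector is:

1. **median filter** — sliding median in a fixed cm⁻¹ window (default
   15 cm⁻¹) to reject narrow artifacts such as cosmic-ray spikes;
2. **baseline correction** — iterated peak-suppressing polynomial fit
   (degree 7 by default): after each least-squares fit, points above the
   fitted curve are clamped down to it and the fit repeats, so the
   polynomial settles under the Raman bands and tracks only the broad
   fluorescence background, which is then subtracted;
3. **re-gridding** — cubic interpolating spline evaluated on the canonical
   200–3400 cm⁻¹, 1 cm⁻¹ grid (3201 nodes), giving every spectrum an
   identical axis with no missing values;
4. **SNV + rescale** — per-spectrum standard normal variate
   (zero mean, unit sample standard deviation) followed by min-max
   rescaling onto a 0–1 relative intensity scale.

Stages 4 make the result invariant to positive affine transforms of the
input, so detector gain and offset drop out before any comparison.

:class:`RamanPreprocessor` packages the routine as a (stateless)
scikit-learn transformer; the module-level functions expose each stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator, TransformerMixin

from .types import ProcessedSpectrum, RawSpectrum, canonical_grid

__all__ = [
    "PreprocessConfig",
    "median_filter",
    "correct_baseline",
    "resample_to_grid",
    "snv",
    "rescale01",
    "preprocess_pipeline",
    "RamanPreprocessor",
]

logger = logging.getLogger(__name__)


class DegenerateSpectrumError(ValueError):
    """Spectrum has no usable variation (constant, or too few points)."""


class CoverageError(ValueError):
    """Raw support does not cover the canonical grid."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable parameters of the post-processing routine.

    median_window_cm1 : physical width of the median window (cm⁻¹).
    baseline_order : degree of the baseline polynomial.
    baseline_max_iter / baseline_tol : stopping rule for the
        peak-suppressing refit (relative L2 change of the fitted curve).
    grid_min_cm1 / grid_max_cm1 / grid_step_cm1 : canonical axis.
    """

    median_window_cm1: float = 15.0
    baseline_order: int = 7
    baseline_max_iter: int = 100
    baseline_tol: float = 1e-4
    grid_min_cm1: float = 200.0
    grid_max_cm1: float = 3400.0
    grid_step_cm1: float = 1.0

    def __post_init__(self) -> None:
        if self.median_window_cm1 <= 0:
            raise ValueError("median_window_cm1 must be > 0")
        if self.baseline_order < 1:
            raise ValueError("baseline_order must be >= 1")
        if not (self.grid_min_cm1 < self.grid_max_cm1):
            raise ValueError("grid_min_cm1 must be < grid_max_cm1")
        if self.grid_step_cm1 <= 0:
            raise ValueError("grid_step_cm1 must be > 0")

    def grid(self) -> np.ndarray:
        return canonical_grid(self.grid_min_cm1, self.grid_max_cm1, self.grid_step_cm1)


def median_filter(raw: RawSpectrum, window_cm1: float = 15.0) -> RawSpectrum:
    """Sliding median over a centered ±window/2 cm⁻¹ window.

    The window is defined in wavenumber units, not sample counts, because
    raw sampling is irregular (5.5–8.3 cm⁻¹ on the source instruments).
    Edge windows are truncated.  Output keeps the input axis.
    """
    if window_cm1 <= 0:
        raise ValueError("median window must be > 0 cm^-1")
    w = raw.wavenumbers
    gaps = np.diff(w)
    if window_cm1 < gaps.min():
        raise ValueError(
            f"median window {window_cm1} cm^-1 is narrower than the smallest "
            f"sample spacing {gaps.min():.3g} cm^-1; every window would be a single point"
        )
    half = window_cm1 / 2.0
    lo = np.searchsorted(w, w - half, side="left")
    hi = np.searchsorted(w, w + half, side="right")
    y = raw.intensities
    out = np.empty_like(y)
    for i in range(w.size):
        out[i] = np.median(y[lo[i]:hi[i]])
    return raw.with_intensities(out)


def _suppressed_polyfit(
    w: np.ndarray, y: np.ndarray, order: int, max_iter: int, tol: float
) -> np.ndarray:
    """Peak-suppressing modified polyfit; returns the baseline estimate.

    Convergence is judged on successive *changes* of the fitted curve,
    relative to the first change.  Differences of fits cancel any additive
    polynomial and scale with detector gain, so the number of iterations —
    and hence the estimate — is exactly equivariant under ``y -> a*y + p``
    for a > 0 and any representable polynomial p.
    """
    work = y.copy()
    prev = None
    first_change = None
    for _ in range(max_iter):
        fit = np.polynomial.Polynomial.fit(w, work, order)(w)
        work = np.minimum(work, fit)
        if prev is not None:
            change = np.linalg.norm(fit - prev)
            if first_change is None:
                first_change = change
                if first_change == 0.0:  # baseline fully representable
                    return fit
            elif change < tol * first_change:
                return fit
        prev = fit
    logger.debug("baseline refit hit the %d-iteration cap", max_iter)
    return prev


def correct_baseline(raw: RawSpectrum, config: PreprocessConfig | None = None) -> RawSpectrum:
    """Subtract the fluorescence background via iterated clamped polyfit.

    The result may contain small negatives; they are retained (clipping
    would distort the SNV moments downstream).  Hitting the iteration cap
    is logged, not an error.
    """
    config = config or PreprocessConfig()
    if raw.n_points < config.baseline_order + 2:
        raise DegenerateSpectrumError(
            f"{raw.specimen_id}: {raw.n_points} points cannot support a "
            f"degree-{config.baseline_order} baseline (need >= {config.baseline_order + 2})"
        )
    baseline = _suppressed_polyfit(
        raw.wavenumbers,
        raw.intensities,
        config.baseline_order,
        config.baseline_max_iter,
        config.baseline_tol,
    )
    return raw.with_intensities(raw.intensities - baseline)


def resample_to_grid(raw: RawSpectrum, config: PreprocessConfig | None = None) -> ProcessedSpectrum:
    """Evaluate a cubic interpolating spline at every canonical grid node."""
    config = config or PreprocessConfig()
    w = raw.wavenumbers
    short_lo = config.grid_min_cm1 - w[0]
    short_hi = w[-1] - config.grid_max_cm1
    if short_lo < 0 or short_hi < 0:
        parts = []
        if short_lo < 0:
            parts.append(f"{-short_lo:.1f} cm^-1 short at the low end")
        if short_hi < 0:
            parts.append(f"{-short_hi:.1f} cm^-1 short at the high end")
        raise CoverageError(
            f"{raw.specimen_id}: raw support [{w[0]:.1f}, {w[-1]:.1f}] does not "
            f"cover the grid [{config.grid_min_cm1}, {config.grid_max_cm1}]: "
            + ", ".join(parts)
        )
    grid = config.grid()
    values = CubicSpline(w, raw.intensities)(grid)
    return ProcessedSpectrum(raw.specimen_id, grid, values, "baseline_corrected")


def snv(p: ProcessedSpectrum) -> ProcessedSpectrum:
    """Standard normal variate: per-spectrum zero mean, unit sample sd."""
    y = p.intensities
    sd = y.std(ddof=1)
    if sd == 0:
        raise DegenerateSpectrumError(f"{p.specimen_id}: zero variance, SNV undefined")
    return p.with_stage((y - y.mean()) / sd, "snv")


def rescale01(p: ProcessedSpectrum) -> ProcessedSpectrum:
    """Min-max rescale onto the 0–1 relative intensity scale."""
    y = p.intensities
    lo, hi = y.min(), y.max()
    if hi == lo:
        raise DegenerateSpectrumError(f"{p.specimen_id}: constant spectrum, rescale undefined")
    return p.with_stage((y - lo) / (hi - lo), "rescaled")


def preprocess_pipeline(
    raw: RawSpectrum, config: PreprocessConfig | None = None
) -> ProcessedSpectrum:
    """Full routine: median filter → baseline → re-grid → SNV → rescale."""
    config = config or PreprocessConfig()
    stages = (
        ("median_filter", lambda s: median_filter(s, config.median_window_cm1)),
        ("correct_baseline", lambda s: correct_baseline(s, config)),
        ("resample_to_grid", lambda s: resample_to_grid(s, config)),
        ("snv", snv),
        ("rescale01", rescale01),
    )
    x = raw
    for name, step in stages:
        try:
            x = step(x)
        except ValueError as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc
    return x


class RamanPreprocessor(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer wrapping the post-processing routine.

    Stateless (``fit`` only validates parameters): every spectrum is
    normalized per-spectrum, so nothing is learned from training data.

    ``transform`` accepts a sequence of :class:`RawSpectrum` (or
    ``(wavenumbers, intensities)`` pairs) and returns an
    ``(n_spectra, n_grid_nodes)`` float array on the canonical grid.

    Examples
    --------
    >>> pre = RamanPreprocessor()
    >>> X = pre.fit_transform(list_of_raw_spectra)   # doctest: +SKIP
    """

    def __init__(
        self,
        median_window_cm1: float = 15.0,
        baseline_order: int = 7,
        baseline_max_iter: int = 100,
        baseline_tol: float = 1e-4,
        grid_min_cm1: float = 200.0,
        grid_max_cm1: float = 3400.0,
        grid_step_cm1: float = 1.0,
    ):
        self.median_window_cm1 = median_window_cm1
        self.baseline_order = baseline_order
        self.baseline_max_iter = baseline_max_iter
        self.baseline_tol = baseline_tol
        self.grid_min_cm1 = grid_min_cm1
        self.grid_max_cm1 = grid_max_cm1
        self.grid_step_cm1 = grid_step_cm1

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            median_window_cm1=self.median_window_cm1,
            baseline_order=self.baseline_order,
            baseline_max_iter=self.baseline_max_iter,
            baseline_tol=self.baseline_tol,
            grid_min_cm1=self.grid_min_cm1,
            grid_max_cm1=self.grid_max_cm1,
            grid_step_cm1=self.grid_step_cm1,
        )

    @staticmethod
    def _coerce(x, i: int) -> RawSpectrum:
        if isinstance(x, RawSpectrum):
            return x
        w, y = x
        return RawSpectrum(f"X[{i}]", np.asarray(w), np.asarray(y))

    def fit(self, X=None, y=None):
        self.config_ = self._config()
        self.grid_ = self.config_.grid()
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "config_"):
            self.fit()
        out = np.empty((len(X), self.grid_.size))
        for i, x in enumerate(X):
            out[i] = self.transform_spectrum(self._coerce(x, i)).intensities
        return out

    def transform_spectrum(self, raw: RawSpectrum) -> ProcessedSpectrum:
        """Process a single spectrum, keeping its id and stage tag."""
        if not hasattr(self, "config_"):
            self.fit()
        return preprocess_pipeline(raw, self.config_)
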