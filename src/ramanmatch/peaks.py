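"""Windowed local-maxima peak extraction and per-group peak summaries.

A grid node is a peak when its intensity is the maximum of a centered
moving window (101 nodes by default, truncated at the spectrum edges) and
clears a minimum relative intensity (0.2 on the 0–1 scale by default).
The wide window suppresses noise wiggles; the threshold drops baseline
ripple.  Plateau ties go to the lowest wavenumber, so two qualifying
nodes can never sit closer than half a window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d

from .types import ProcessedSpectrum, SpectrumLibrary

__all__ = ["PeakConfig", "find_peaks", "peak_summary"]


class StageError(ValueError):
    """Peak detection needs a fully rescaled spectrum."""


@dataclass(frozen=True)
class PeakConfig:
    window_nodes: int = 101
    min_intensity: float = 0.2

    def __post_init__(self) -> None:
        if self.window_nodes < 3 or self.window_nodes % 2 == 0:
            raise ValueError("window_nodes must be odd and >= 3")
        if not (0.0 <= self.min_intensity <= 1.0):
            raise ValueError("min_intensity must lie in [0, 1]")


def _peak_indices(y: np.ndarray, config: PeakConfig) -> np.ndarray:
    half = config.window_nodes // 2
    # max over the centered window, truncated at edges (-inf padding)
    winmax = maximum_filter1d(y, size=config.window_nodes, mode="constant",
                              cval=-np.inf)
    candidates = np.flatnonzero((y >= config.min_intensity) & (y == winmax))
    keep = []
    for i in candidates:
        lo = max(0, i - half)
        # plateau tie: an equal value earlier in the window wins
        if not np.any(y[lo:i] == y[i]):
            keep.append(i)
    return np.asarray(keep, dtype=int)


def find_peaks(p: ProcessedSpectrum, config: PeakConfig | None = None) -> pd.DataFrame:
    """Windowed local maxima of one rescaled spectrum.

    Returns a table with columns ``(specimen_id, wavenumber_cm1, intensity)``
    sorted ascending by wavenumber.
    """
    config = config or PeakConfig()
    if p.stage != "rescaled":
        raise StageError(
            f"{p.specimen_id}: peak detection requires stage 'rescaled', got {p.stage!r}"
        )
    idx = _peak_indices(p.intensities, config)
    return pd.DataFrame(
        {
            "specimen_id": p.specimen_id,
            "wavenumber_cm1": p.grid[idx],
            "intensity": p.intensities[idx],
        }
    )


def peak_summary(
    lib: SpectrumLibrary, group_by: str = "polymer", config: PeakConfig | None = None
) -> pd.DataFrame:
    """Per-group peak table: average spectra within group, re-rescale, detect.

    ``group_by`` is any metadata field (e.g. ``polymer`` or ``category``).
    Returns columns ``(group, wavenumber_cm1, intensity)``.
    """
    config = config or PeakConfig()
    probe = next(iter(lib.metadata.values()))
    if not hasattr(probe, group_by):
        raise KeyError(f"unknown metadata field {group_by!r}")
    groups: dict[str, list[int]] = {}
    for i, uid in enumerate(lib.ids):
        groups.setdefault(getattr(lib.metadata[uid], group_by), []).append(i)
    frames = []
    for label in sorted(groups):
        mean = lib.matrix[groups[label]].mean(axis=0)
        lo, hi = mean.min(), mean.max()
        if hi == lo:
            continue
        p = ProcessedSpectrum(str(label), lib.grid, (mean - lo) / (hi - lo), "rescaled")
        t = find_peaks(p, config).rename(columns={"specimen_id": "group"})
        frames.append(t)
    if not frames:
        return pd.DataFrame(columns=["group", "wavenumber_cm1", "intensity"])
    return pd.concat(frames, ignore_index=True)
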