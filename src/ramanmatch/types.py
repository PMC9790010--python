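"""Core containers for Raman spectra, library metadata and match results.

A spectrum moves through four representations: raw irregular instrument
samples (:class:`RawSpectrum`), processed vectors on the canonical
200–3400 cm⁻¹ grid (:class:`ProcessedSpectrum`), a labeled collection of
processed vectors (:class:`SpectrumLibrary`), and per-query ranked
candidates (:class:`MatchResult`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawSpectrum",
    "ProcessedSpectrum",
    "SpecimenMetadata",
    "SpectrumLibrary",
    "MatchResult",
    "METADATA_COLUMNS",
    "CATEGORIES",
    "PARENT_GROUPS",
    "canonical_grid",
]

#: Metadata schema of the reference library (plus the machine-readable
#: noisy flag this package adds).
METADATA_COLUMNS = (
    "unique_id",
    "color",
    "poly_acronym",
    "polymer",
    "structure",
    "category",
    "description",
    "parent_grp",
    "location_collected",
)

CATEGORIES = frozenset(
    {"pristine anthropogenic", "weathered anthropogenic", "biological"}
)

PARENT_GROUPS = frozenset(
    {
        "biological",
        "industrial",
        "consumer",
        "laboratory",
        "beachcast",
        "agricultural",
        "fishery",
        "building material",
    }
)

#: Processing stages in pipeline order.
STAGES = ("denoised", "baseline_corrected", "snv", "rescaled")


def canonical_grid(min_cm1: float = 200.0, max_cm1: float = 3400.0,
                   step_cm1: float = 1.0) -> np.ndarray:
    """Shared wavenumber axis every processed spectrum lives on.

    Defaults give the 200..3400 cm⁻¹ inclusive axis at 1 cm⁻¹ (3201 nodes).
    """
    n = int(round((max_cm1 - min_cm1) / step_cm1)) + 1
    return min_cm1 + step_cm1 * np.arange(n)


@dataclass(frozen=True)
class RawSpectrum:
    """Irregularly sampled (wavenumber, intensity) pairs from an instrument
    export or the simulator.

    Parameters
    ----------
    specimen_id : str
        Label of the specimen (or query file) this spectrum belongs to.
    wavenumbers : ndarray
        Strictly ascending Raman shifts in cm⁻¹.
    intensities : ndarray
        Non-negative detector counts (arbitrary units), same length.
    excitation_nm : float, optional
        Laser excitation wavelength (532 or 785 nm on the source
        instruments); informational only.
    """

    specimen_id: str
    wavenumbers: np.ndarray
    intensities: np.ndarray
    excitation_nm: float | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", y)
        if w.ndim != 1 or y.ndim != 1 or w.shape != y.shape:
            raise ValueError("wavenumbers and intensities must be equal-length 1-D")
        if w.size < 16:
            raise ValueError(
                f"spectrum {self.specimen_id!r} has {w.size} points; need >= 16"
            )
        if not (np.isfinite(w).all() and np.isfinite(y).all()):
            raise ValueError(f"spectrum {self.specimen_id!r} contains non-finite values")
        if np.any(np.diff(w) <= 0):
            raise ValueError(
                f"spectrum {self.specimen_id!r}: wavenumbers must be strictly ascending"
            )
        if np.any(y < 0):
            raise ValueError(f"spectrum {self.specimen_id!r}: negative intensities")

    @property
    def n_points(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, intensities: np.ndarray) -> "RawSpectrum":
        """Copy with replaced intensities (same axis); used by filter stages.

        Bypasses the non-negativity check because baseline subtraction may
        legitimately leave small negatives.
        """
        out = object.__new__(RawSpectrum)
        object.__setattr__(out, "specimen_id", self.specimen_id)
        object.__setattr__(out, "wavenumbers", self.wavenumbers)
        object.__setattr__(out, "intensities", np.asarray(intensities, dtype=float))
        object.__setattr__(out, "excitation_nm", self.excitation_nm)
        return out


@dataclass(frozen=True)
class ProcessedSpectrum:
    """Intensities on the canonical grid, tagged with the processing stage."""

    specimen_id: str
    grid: np.ndarray
    intensities: np.ndarray
    stage: str

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "intensities", y)
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if g.shape != y.shape or g.ndim != 1:
            raise ValueError("grid and intensities must be equal-length 1-D")
        if not np.isfinite(y).all():
            raise ValueError(
                f"spectrum {self.specimen_id!r}: missing/non-finite processed values"
            )

    def with_stage(self, intensities: np.ndarray, stage: str) -> "ProcessedSpectrum":
        return ProcessedSpectrum(self.specimen_id, self.grid, intensities, stage)


@dataclass(frozen=True)
class SpecimenMetadata:
    """One row of the library metadata table."""

    unique_id: str
    color: str = ""
    poly_acronym: str = ""
    polymer: str = ""
    structure: str = ""
    category: str = "pristine anthropogenic"
    description: str = ""
    parent_grp: str = "laboratory"
    location_collected: str = ""
    noisy_flag: bool = False

    def __post_init__(self) -> None:
        if not self.unique_id:
            raise ValueError("unique_id must be non-empty")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"{self.unique_id}: category {self.category!r} not one of {sorted(CATEGORIES)}"
            )


@dataclass
class SpectrumLibrary:
    """Processed spectra keyed by specimen id, plus per-specimen metadata.

    ``matrix`` holds one processed intensity vector per specimen as rows,
    aligned with ``ids``; every id must have a metadata record and vice
    versa, and all intensities must already be on the rescaled [0, 1] scale.
    """

    grid: np.ndarray
    ids: list[str]
    matrix: np.ndarray
    metadata: dict[str, SpecimenMetadata]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape != (len(self.ids), self.grid.size):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.ids)} ids x {self.grid.size} grid nodes"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate spectrum ids in library")
        meta_keys = set(self.metadata)
        id_set = set(self.ids)
        orphans_m = sorted(meta_keys - id_set)
        orphans_s = sorted(id_set - meta_keys)
        if orphans_m or orphans_s:
            raise ValueError(
                f"library id/metadata mismatch: metadata without spectra {orphans_m}, "
                f"spectra without metadata {orphans_s}"
            )
        if not np.isfinite(self.matrix).all():
            raise ValueError("library matrix contains non-finite values")
        if self.matrix.size and (self.matrix.min() < 0 or self.matrix.max() > 1):
            raise ValueError("library intensities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.ids)

    def spectrum(self, uid: str) -> ProcessedSpectrum:
        i = self.ids.index(uid)
        return ProcessedSpectrum(uid, self.grid, self.matrix[i], "rescaled")

    def metadata_frame(self) -> pd.DataFrame:
        rows = [vars(self.metadata[u]) for u in self.ids]
        return pd.DataFrame(rows, columns=list(METADATA_COLUMNS) + ["noisy_flag"])

    @classmethod
    def from_spectra(
        cls,
        spectra: Sequence[ProcessedSpectrum],
        metadata: Sequence[SpecimenMetadata],
    ) -> "SpectrumLibrary":
        if not spectra:
            raise ValueError("cannot build a library from zero spectra")
        grid = spectra[0].grid
        for s in spectra:
            if s.stage != "rescaled":
                raise ValueError(f"{s.specimen_id}: stage {s.stage!r}, expected 'rescaled'")
            if s.grid.shape != grid.shape or not np.array_equal(s.grid, grid):
                raise ValueError(f"{s.specimen_id}: grid differs from library grid")
        ids = [s.specimen_id for s in spectra]
        matrix = np.vstack([s.intensities for s in spectra])
        meta = {m.unique_id: m for m in metadata}
        return cls(grid=grid, ids=ids, matrix=matrix, metadata=meta)


@dataclass(frozen=True)
class MatchResult:
    """Ranked library candidates for one query.

    ``candidates`` is a list of ``(unique_id, r, d)`` tuples sorted by
    ascending Pearson distance ``d = 1 - r`` (ties by ascending id);
    ``best`` is the first entry and ``metadata_echo`` its library record.
    """

    query_id: str
    candidates: list[tuple[str, float, float]]
    metadata_echo: SpecimenMetadata | None = None

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError(f"{self.query_id}: empty candidate list")
        ds = [c[2] for c in self.candidates]
        if any(b < a for a, b in zip(ds, ds[1:])):
            raise ValueError(f"{self.query_id}: candidates not sorted by distance")

    @property
    def best(self) -> tuple[str, float, float]:
        return self.candidates[0]
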