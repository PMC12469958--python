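"""Core containers for MALDI-MSI datasets and aligned feature matrices.

A mass-spectrometry-imaging run yields one spectrum per pixel of a tissue
section.  After vendor export the natural in-memory shape is a dense table:
every spectrum shares one m/z axis, each row carries pixel coordinates and
patient/slide metadata.  :class:`MSIDataset` wraps that table; after peak
detection and alignment the data collapse to an :class:`AlignedFeatureMatrix`
of spectra x features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

#: outcome labels: recurrence/progression vs. no evidence of disease
RECPRO = "RecPro"
NED = "NED"
OUTCOMES = (RECPRO, NED)

#: metadata columns of the spectra table, in canonical order
OBS_COLUMNS = ["patient_id", "cohort", "slide", "x", "y", "roi_flag"]


class ParameterError(ValueError):
    """An operation was called with out-of-contract parameters."""


class FormatError(ValueError):
    """An on-disk table violates the expected schema."""


class NormalizationError(ValueError):
    """A spectrum cannot be normalized (e.g. all intensities zero)."""


@dataclass
class MSIDataset:
    """Per-pixel spectra with a shared m/z axis plus patient metadata.

    Parameters
    ----------
    mz : strictly increasing m/z axis (Da), shared by all spectra.
    intensities : (n_spectra, n_mz) non-negative array.
    obs : per-spectrum metadata with columns ``patient_id, cohort, slide,
        x, y, roi_flag``.
    patients : optional patient table with columns ``patient_id, outcome,
        cohort, slide``; outcome is ``RecPro`` or ``NED``.
    """

    mz: np.ndarray
    intensities: np.ndarray
    obs: pd.DataFrame
    patients: pd.DataFrame | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mz.ndim != 1:
            raise ParameterError("mz axis must be one-dimensional")
        if self.intensities.shape != (len(self.obs), self.mz.size):
            raise ParameterError(
                f"intensities shape {self.intensities.shape} does not match "
                f"{len(self.obs)} spectra x {self.mz.size} m/z values"
            )
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ParameterError("mz axis must be strictly increasing")
        missing = [c for c in OBS_COLUMNS if c not in self.obs.columns]
        if missing:
            raise FormatError(f"obs table missing columns: {missing}")
        if self.patients is not None:
            known = set(self.patients["patient_id"])
            unknown = set(self.obs["patient_id"]) - known
            if unknown:
                raise FormatError(
                    f"spectra reference unknown patients: {sorted(unknown)[:5]}"
                )

    @property
    def n_spectra(self) -> int:
        return len(self.obs)

    def spectrum(self, i: int) -> tuple[np.ndarray, np.ndarray, pd.Series]:
        """Return (mz, intensities, metadata) view of spectrum ``i``."""
        return self.mz, self.intensities[i], self.obs.iloc[i]

    def __iter__(self) -> Iterator[tuple[np.ndarray, np.ndarray, pd.Series]]:
        for i in range(self.n_spectra):
            yield self.spectrum(i)

    def restrict_to_roi(self) -> "MSIDataset":
        """Keep only spectra inside annotated tumor regions (roi_flag)."""
        keep = self.obs["roi_flag"].to_numpy(dtype=bool)
        return MSIDataset(
            mz=self.mz,
            intensities=self.intensities[keep],
            obs=self.obs.loc[keep].reset_index(drop=True),
            patients=self.patients,
            provenance=self.provenance + ["restrict_to_roi"],
        )

    def outcome_per_spectrum(self) -> pd.Series:
        """Map each spectrum to its patient's outcome label."""
        if self.patients is None:
            raise ParameterError("dataset has no patient table")
        lut = self.patients.set_index("patient_id")["outcome"]
        return self.obs["patient_id"].map(lut)

    def copy(self) -> "MSIDataset":
        return MSIDataset(
            mz=self.mz.copy(),
            intensities=self.intensities.copy(),
            obs=self.obs.copy(),
            patients=None if self.patients is None else self.patients.copy(),
            provenance=list(self.provenance),
        )


@dataclass
class AlignedFeatureMatrix:
    """Spectra x aligned-m/z-features intensity table.

    ``feature_mz`` holds the strictly increasing centroid of every aligned
    feature; each contributing peak lies within ``centroid +/- tolerance``.
    """

    values: np.ndarray
    feature_mz: np.ndarray
    obs: pd.DataFrame
    tolerance: float = 0.2
    patients: pd.DataFrame | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_mz = np.asarray(self.feature_mz, dtype=float)
        if self.values.shape != (len(self.obs), self.feature_mz.size):
            raise ParameterError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.obs)} spectra x {self.feature_mz.size} features"
            )
        if self.feature_mz.size > 1 and not np.all(np.diff(self.feature_mz) > 0):
            raise ParameterError("feature centroids must be strictly increasing")

    @property
    def n_spectra(self) -> int:
        return len(self.obs)

    @property
    def n_features(self) -> int:
        return self.feature_mz.size

    def subset_features(self, indices: Sequence[int]) -> "AlignedFeatureMatrix":
        idx = np.asarray(indices, dtype=int)
        idx = idx[np.argsort(self.feature_mz[idx])]
        return replace(
            self,
            values=self.values[:, idx],
            feature_mz=self.feature_mz[idx],
            provenance=self.provenance + [f"subset_features(n={idx.size})"],
        )

    def subset_spectra(self, mask: np.ndarray) -> "AlignedFeatureMatrix":
        mask = np.asarray(mask)
        return replace(
            self,
            values=self.values[mask],
            obs=self.obs.loc[mask].reset_index(drop=True)
            if mask.dtype == bool
            else self.obs.iloc[mask].reset_index(drop=True),
        )

    def outcome_per_spectrum(self) -> pd.Series:
        if self.patients is None:
            raise ParameterError("feature matrix has no patient table")
        lut = self.patients.set_index("patient_id")["outcome"]
        return self.obs["patient_id"].map(lut)

    def to_dataframe(self) -> pd.DataFrame:
        vals = pd.DataFrame(
            self.values, columns=[f"mz_{mz:.4f}" for mz in self.feature_mz]
        )
        return pd.concat([self.obs.reset_index(drop=True), vals], axis=1)

    def feature_image(self, j: int, patient_id: str | None = None) -> pd.DataFrame:
        """Pixel table (x, y, intensity) of feature ``j``, optionally one patient."""
        df = self.obs[["patient_id", "x", "y"]].copy()
        df["intensity"] = self.values[:, j]
        if patient_id is not None:
            df = df[df["patient_id"] == patient_id].reset_index(drop=True)
        return df
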