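"""Spectrum preprocessing: baseline removal, TIC normalization, peak alignment.

The chain runs in a fixed order — morphological top-hat baseline removal,
then total-ion-count normalization, then peak detection/alignment on the
dataset mean spectrum — and records each step in the dataset provenance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .core import (
    AlignedFeatureMatrix,
    MSIDataset,
    NormalizationError,
    ParameterError,
)

__all__ = [
    "tic_normalize",
    "tophat_baseline",
    "smooth_spectra",
    "preprocess",
    "detect_and_align_peaks",
    "extract_features",
    "downsample_features",
    "per_patient_standardize",
]


def tic_normalize(intensities: np.ndarray) -> np.ndarray:
    """Scale each spectrum to unit total ion count (intensities sum to 1).

    Accepts a single spectrum (1-D) or a stack of spectra (2-D, one row per
    spectrum).  A spectrum with no strictly positive intensity cannot be
    normalized and raises :class:`NormalizationError`; dataset-level callers
    should flag and exclude such pixels beforehand.
    """
    x = np.asarray(intensities, dtype=float)
    sums = x.sum(axis=-1, keepdims=True)
    if np.any(sums <= 0):
        raise NormalizationError("spectrum with non-positive total ion count")
    return x / sums


def tophat_baseline(intensities: np.ndarray, structure_width: int) -> np.ndarray:
    """Morphological top-hat: signal minus its opening with a flat element.

    The opening (erosion then dilation with a flat structuring element of
    ``structure_width`` points) tracks the slowly varying baseline under the
    peaks; subtracting it leaves a non-negative, baseline-free signal that is
    pointwise <= the input.  Boundary handling replicates edge values.
    """
    x = np.asarray(intensities, dtype=float)
    w = int(structure_width)
    if w < 1 or w % 2 == 0:
        raise ParameterError("structure_width must be an odd integer >= 1")
    if w >= x.shape[-1]:
        raise ParameterError(
            f"structure_width {w} must be smaller than the signal length {x.shape[-1]}"
        )
    size = (1,) * (x.ndim - 1) + (w,)
    opening = ndimage.grey_opening(x, size=size, mode="nearest")
    return x - opening


def smooth_spectra(intensities: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving-average denoising along the m/z axis (optional, off by default)."""
    if window < 1 or window % 2 == 0:
        raise ParameterError("smoothing window must be an odd integer >= 1")
    kernel = np.ones(window) / window
    x = np.atleast_2d(np.asarray(intensities, dtype=float))
    out = ndimage.convolve1d(x, kernel, axis=-1, mode="nearest")
    return out if np.ndim(intensities) == 2 else out[0]


def preprocess(
    dataset: MSIDataset,
    structure_width: int = 5,
    denoise: bool = False,
    denoise_window: int = 5,
) -> MSIDataset:
    """Run the fixed preprocessing chain: top-hat -> TIC (-> optional smoothing).

    Spectra whose total ion count is zero after baseline removal are flagged
    and excluded with a warning rather than aborting the run.
    """
    intens = tophat_baseline(dataset.intensities, structure_width)
    steps = [f"tophat_baseline(width={structure_width})"]
    sums = intens.sum(axis=1)
    keep = sums > 0
    obs = dataset.obs
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} all-zero spectra from TIC normalization"
        )
        intens = intens[keep]
        obs = obs.loc[keep].reset_index(drop=True)
        steps.append(f"exclude_zero_tic(n={int((~keep).sum())})")
    intens = tic_normalize(intens)
    steps.append("tic_normalize")
    if denoise:
        intens = smooth_spectra(intens, denoise_window)
        steps.append(f"smooth(window={denoise_window})")
    return MSIDataset(
        mz=dataset.mz,
        intensities=intens,
        obs=obs,
        patients=dataset.patients,
        provenance=dataset.provenance + steps,
    )


def _merge_close_peaks(
    peak_idx: np.ndarray, mz: np.ndarray, heights: np.ndarray, min_sep: float
) -> np.ndarray:
    """Greedy non-maximum suppression: keep the more intense of any pair of
    maxima closer than ``min_sep`` Da."""
    order = np.argsort(heights[peak_idx])[::-1]
    kept: list[int] = []
    for k in peak_idx[order]:
        if all(abs(mz[k] - mz[j]) >= min_sep for j in kept):
            kept.append(k)
    return np.array(sorted(kept), dtype=int)


def detect_and_align_peaks(
    dataset: MSIDataset,
    tolerance: float = 0.2,
    min_prominence: float | None = None,
) -> AlignedFeatureMatrix:
    """Detect features on the mean spectrum and align all spectra to them.

    Local maxima of the dataset mean spectrum with prominence above
    ``min_prominence`` become feature centroids (maxima closer than
    ``2 * tolerance`` are merged to the more intense one); the per-spectrum
    feature value is the maximum intensity within ``centroid +/- tolerance``.
    ``min_prominence`` defaults to 3x the median of the mean spectrum, a
    scale-free cut that separates peaks from the noise floor.
    """
    if tolerance <= 0:
        raise ParameterError("tolerance must be positive")
    mean_spec = dataset.intensities.mean(axis=0)
    if min_prominence is None:
        min_prominence = 3.0 * float(np.median(mean_spec))
    peak_idx, _ = signal.find_peaks(mean_spec, prominence=min_prominence)
    if peak_idx.size == 0:
        warnings.warn("no peaks found on the mean spectrum; empty feature matrix")
        return AlignedFeatureMatrix(
            values=np.empty((dataset.n_spectra, 0)),
            feature_mz=np.empty(0),
            obs=dataset.obs.copy(),
            tolerance=tolerance,
            patients=dataset.patients,
            provenance=dataset.provenance + ["detect_and_align_peaks(n=0)"],
        )
    peak_idx = _merge_close_peaks(peak_idx, dataset.mz, mean_spec, 2 * tolerance)
    centroids = dataset.mz[peak_idx]
    fm = extract_features(dataset, centroids, tolerance)
    fm.provenance = dataset.provenance + [
        f"detect_and_align_peaks(n={centroids.size}, tol={tolerance})"
    ]
    return fm


def extract_features(
    dataset: MSIDataset, centroids: np.ndarray, tolerance: float
) -> AlignedFeatureMatrix:
    """Windowed-maximum extraction of given feature centroids from a dataset.

    Used both during alignment and when projecting a second cohort onto the
    feature space of a trained model.
    """
    centroids = np.asarray(centroids, dtype=float)
    lo = np.searchsorted(dataset.mz, centroids - tolerance, side="left")
    hi = np.searchsorted(dataset.mz, centroids + tolerance, side="right")
    values = np.zeros((dataset.n_spectra, centroids.size))
    for j, (a, b) in enumerate(zip(lo, hi)):
        if b > a:
            values[:, j] = dataset.intensities[:, a:b].max(axis=1)
    return AlignedFeatureMatrix(
        values=values,
        feature_mz=centroids,
        obs=dataset.obs.copy(),
        tolerance=tolerance,
        patients=dataset.patients,
        provenance=dataset.provenance + [f"extract_features(n={centroids.size})"],
    )


def downsample_features(matrix: AlignedFeatureMatrix) -> AlignedFeatureMatrix:
    """2x feature down-sampling: average consecutive non-overlapping pairs.

    The new centroid is the midpoint of each pair; with an odd feature count
    the trailing unpaired column is kept unchanged.  A single-column matrix is
    returned as-is.
    """
    p = matrix.n_features
    if p < 2:
        return matrix
    n_pairs = p // 2
    vals = matrix.values
    paired = 0.5 * (vals[:, 0 : 2 * n_pairs : 2] + vals[:, 1 : 2 * n_pairs : 2])
    mz = 0.5 * (matrix.feature_mz[0 : 2 * n_pairs : 2] + matrix.feature_mz[1 : 2 * n_pairs : 2])
    if p % 2 == 1:
        paired = np.hstack([paired, vals[:, -1:]])
        mz = np.append(mz, matrix.feature_mz[-1])
    return AlignedFeatureMatrix(
        values=paired,
        feature_mz=mz,
        obs=matrix.obs.copy(),
        tolerance=matrix.tolerance,
        patients=matrix.patients,
        provenance=matrix.provenance + [f"downsample_features({p}->{mz.size})"],
    )


def per_patient_standardize(matrix: AlignedFeatureMatrix) -> AlignedFeatureMatrix:
    """Z-score each feature within each patient (own mean/SD spectrum).

    Standardization uses only the patient's own spectra, so applying it before
    cross-validation leaks nothing between train and test patients.  Features
    with zero within-patient SD are set to 0.  SD is the population SD
    (ddof=0).  A patient with a single spectrum has no SD and is rejected.
    """
    values = matrix.values.copy()
    codes, _ = pd.factorize(matrix.obs["patient_id"])
    for g in np.unique(codes):
        rows = codes == g
        if rows.sum() < 2:
            pid = matrix.obs.loc[rows, "patient_id"].iloc[0]
            raise ParameterError(
                f"patient {pid!r} has a single spectrum; cannot standardize"
            )
        block = values[rows]
        mu = block.mean(axis=0)
        sd = block.std(axis=0)
        centered = block - mu
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, centered / sd, 0.0)
        values[rows] = z
    out = AlignedFeatureMatrix(
        values=values,
        feature_mz=matrix.feature_mz.copy(),
        obs=matrix.obs.copy(),
        tolerance=matrix.tolerance,
        patients=matrix.patients,
        provenance=matrix.provenance + ["per_patient_standardize"],
    )
    return out
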