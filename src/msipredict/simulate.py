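"""Synthetic two-cohort MALDI-MSI data with known ground truth.

The generator emulates a tryptic-peptide imaging experiment: two patient
cohorts with imbalanced outcome classes, one rectangular tumor ROI per
patient, log-normal per-pixel peak intensities with spatially correlated
texture, contiguous discordant subclone patches (intratumoral
heterogeneity), per-slide multiplicative batch factors, and a smooth
additive baseline that the morphological top-hat step must remove.  Planted
outcome-associated features are, by default, lower in the
recurrence/progression class, i.e. their RecPro-vs-NED ROC-AUC falls below
0.5.

Intensity model (log scale) for pixel *i* of patient *p* on slide *s*,
feature *j*::

    log I_ij = base_j + b_s + u_pj + f_j(x_i, y_i) + c_ij + e_ij

with ``b_s ~ N(0, batch_sd)`` shared across features (so TIC normalization
removes it, as for a real acquisition batch factor), ``u_pj`` a
patient-feature random effect, ``f_j`` a unit-variance Gaussian random field
scaled to ``spatial_sd``, ``e_ij`` iid pixel noise, and ``c_ij`` the planted
class term.  ``effect_size`` is the *marginal* standardized mean difference
(NED minus RecPro for the default negative direction) in units of the
within-group SD of log-intensity; the core shift is scaled by
``1/(1 - 2*subclone_fraction)`` so that discordant subclone pixels (which
carry the opposite class profile) do not dilute the realized effect.
Features planted for the same synthetic protein share one spatial field per
patient, mimicking co-localized peptides of a single parent protein.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import NED, OBS_COLUMNS, RECPRO, MSIDataset, ParameterError

__all__ = [
    "CohortSpec",
    "SyntheticGroundTruth",
    "generate_cohort",
    "generate_transfer_cohort",
    "generate_peptide_library",
    "default_cddp_spec",
    "default_mmc_spec",
    "PROTON_MASS",
]

#: mass of a proton; MALDI peptide ions are observed as [M+H]+
PROTON_MASS = 1.00728

_AMINO_ACIDS = np.array(list("ACDEFGHILMNPQSTVWY"))


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    Defaults mirror the platinum-treated training cohort: 31 patients
    (20 RecPro / 11 NED), ~200 spectra per patient at desk scale, 700
    aligned features in m/z 600-3200 of which 30 carry outcome signal at a
    standardized effect of 1.0, contiguous subclone patches covering 20% of
    pixels, and 4 slides with a 0.10 log-SD batch factor.
    """

    cohort_id: str = "CDDP"
    n_patients_per_class: tuple[int, int] = (20, 11)  # (RecPro, NED)
    spectra_per_patient: tuple[int, int] = (180, 220)  # inclusive count range
    n_features: int = 700
    mz_range: tuple[float, float] = (600.0, 3200.0)
    n_signal_features: int = 30
    effect_size: float = 1.0
    spatial_correlation_length: float = 2.0  # pixels
    subclone_fraction: float = 0.2
    slide_count: int = 4
    batch_sd: float = 0.10
    # non-tumor margin around the annotated region (fraction of ROI pixels);
    # outcome signal is absent there, and its presence is what lets per-patient
    # normalization statistics retain the tumor class signal
    margin_fraction: float = 0.4
    healthy_shift_sd: float = 0.5  # log-offset of the non-tumor tissue profile
    # noise decomposition of within-group log-intensity variation
    patient_sd: float = 0.15
    spatial_sd: float = 0.30
    pixel_sd: float = 0.35
    # axis construction: background channels between peaks + additive baseline
    background_channels_per_gap: int = 2
    baseline_amplitude: float = 0.5  # relative to the median peak scale
    seed: int = 0

    def validate(self) -> None:
        n1, n2 = self.n_patients_per_class
        lo, hi = self.spectra_per_patient
        if n1 <= 0 or n2 <= 0 or lo <= 0 or hi < lo:
            raise ParameterError("patient and spectra counts must be positive")
        if self.n_features <= 0 or self.slide_count <= 0:
            raise ParameterError("feature and slide counts must be positive")
        if self.n_signal_features > self.n_features or self.n_signal_features < 0:
            raise ParameterError("n_signal_features must be in [0, n_features]")
        if not self.mz_range[0] < self.mz_range[1]:
            raise ParameterError("mz_range must satisfy min < max")
        if not 0.0 <= self.subclone_fraction < 0.5:
            raise ParameterError(
                "subclone_fraction must be in [0, 0.5): the discordant minority "
                "cannot reach half the pixels"
            )
        if self.background_channels_per_gap < 0 or self.baseline_amplitude < 0:
            raise ParameterError("axis parameters must be non-negative")
        if self.margin_fraction < 0:
            raise ParameterError("margin_fraction must be non-negative")

    @property
    def sigma_within(self) -> float:
        """Within-group SD of log-intensity implied by the noise components."""
        return math.sqrt(self.patient_sd**2 + self.spatial_sd**2 + self.pixel_sd**2)


@dataclass
class SyntheticGroundTruth:
    """What was planted: signal features, directions, subclones, outcomes."""

    feature_mzs: np.ndarray
    signal_feature_indices: np.ndarray
    directions: np.ndarray  # -1 = lower in RecPro (default), +1 = higher
    signal_feature_groups: list[list[int]] = field(default_factory=list)
    subclone_mask: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    patient_outcomes: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    healthy_shift: np.ndarray | None = None  # non-tumor tissue log-profile offset
    base_log_mean: np.ndarray | None = None  # per-feature typical log-abundance

    def planted_indices_in(
        self, detected_mz: np.ndarray, tolerance: float = 0.2
    ) -> np.ndarray:
        """Indices of detected features matching a planted signal centroid."""
        detected_mz = np.asarray(detected_mz, float)
        out = []
        for mz in self.feature_mzs[self.signal_feature_indices]:
            j = int(np.argmin(np.abs(detected_mz - mz)))
            if abs(detected_mz[j] - mz) <= tolerance:
                out.append(j)
        return np.array(sorted(set(out)), dtype=int)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_mzs": self.feature_mzs.tolist(),
            "signal_feature_indices": self.signal_feature_indices.tolist(),
            "directions": self.directions.tolist(),
            "signal_feature_groups": [list(map(int, g)) for g in self.signal_feature_groups],
            "subclone_mask": np.asarray(self.subclone_mask, bool).astype(int).tolist(),
            "patient_outcomes": self.patient_outcomes.to_dict(),
            "healthy_shift": None
            if self.healthy_shift is None
            else np.asarray(self.healthy_shift, float).tolist(),
            "base_log_mean": None
            if self.base_log_mean is None
            else np.asarray(self.base_log_mean, float).tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticGroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_mzs=np.asarray(d["feature_mzs"], float),
            signal_feature_indices=np.asarray(d["signal_feature_indices"], int),
            directions=np.asarray(d["directions"], int),
            signal_feature_groups=[list(g) for g in d["signal_feature_groups"]],
            subclone_mask=np.asarray(d["subclone_mask"], int).astype(bool),
            patient_outcomes=pd.Series(d["patient_outcomes"]),
            healthy_shift=None
            if d.get("healthy_shift") is None
            else np.asarray(d["healthy_shift"], float),
            base_log_mean=None
            if d.get("base_log_mean") is None
            else np.asarray(d["base_log_mean"], float),
        )


def default_cddp_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Desk-scale analogue of the platinum-treated training cohort."""
    return CohortSpec(seed=seed, **overrides)


def default_mmc_spec(seed: int = 1, **overrides) -> CohortSpec:
    """Desk-scale analogue of the mitomycin-treated transfer cohort
    (29 patients, 15 RecPro / 14 NED)."""
    overrides.setdefault("cohort_id", "MMC")
    overrides.setdefault("n_patients_per_class", (15, 14))
    return CohortSpec(seed=seed, **overrides)


def _feature_centroids(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid centroids: strictly increasing, well separated."""
    lo, hi = spec.mz_range
    step = (hi - lo) / (spec.n_features + 1)
    grid = lo + step * (1 + np.arange(spec.n_features))
    return grid + rng.uniform(-0.3 * step, 0.3 * step, spec.n_features)


def _smooth_unit_field(
    rng: np.random.Generator, shape: tuple[int, ...], length: float
) -> np.ndarray:
    """Gaussian random field(s), smoothed to the correlation length and
    rescaled to zero mean / unit variance over the grid.

    Demeaning keeps the field a pure within-section texture; patient-level
    offsets are modelled separately by the patient random effect.
    """
    eps = rng.standard_normal(shape)
    sigma = (0,) * (len(shape) - 2) + (length, length)
    f = gaussian_filter(eps, sigma=sigma, mode="reflect")
    mu = f.mean(axis=(-2, -1), keepdims=True)
    sd = f.std(axis=(-2, -1), keepdims=True)
    sd = np.where(sd > 1e-12, sd, 1.0)
    return (f - mu) / sd


def _build_axis(
    centroids: np.ndarray, per_gap: int
) -> tuple[np.ndarray, np.ndarray]:
    """Interleave background channels between peak channels.

    One flanking background channel is added before the first and after the
    last peak so that every peak is an interior local maximum.  Returns the
    full m/z axis and the indices of the peak channels.
    """
    if per_gap == 0:
        return centroids.copy(), np.arange(centroids.size)
    gap = np.median(np.diff(centroids)) if centroids.size > 1 else 1.0
    channels = [centroids[0] - gap / (per_gap + 1), centroids[0]]
    peak_pos = [1]
    for a, b in zip(centroids[:-1], centroids[1:]):
        for k in range(1, per_gap + 1):
            channels.append(a + (b - a) * k / (per_gap + 1))
        channels.append(b)
        peak_pos.append(len(channels) - 1)
    channels.append(centroids[-1] + gap / (per_gap + 1))
    return np.asarray(channels), np.asarray(peak_pos, dtype=int)


def generate_cohort(
    spec: CohortSpec,
    feature_mzs: np.ndarray | None = None,
    signal_feature_indices: np.ndarray | None = None,
    healthy_shift: np.ndarray | None = None,
    base_log_mean: np.ndarray | None = None,
) -> tuple[MSIDataset, SyntheticGroundTruth]:
    """Generate one synthetic cohort; deterministic given ``spec.seed``.

    ``feature_mzs`` / ``signal_feature_indices`` / ``healthy_shift`` allow a
    second cohort to be generated on the feature space (and with the same
    non-tumor tissue profile) of a first one, for transfer experiments.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    centroids = (
        _feature_centroids(spec, rng)
        if feature_mzs is None
        else np.asarray(feature_mzs, float)
    )
    p = centroids.size
    if signal_feature_indices is None:
        sig_idx = np.sort(rng.choice(p, spec.n_signal_features, replace=False))
    else:
        sig_idx = np.sort(np.asarray(signal_feature_indices, int))
    directions = -np.ones(sig_idx.size, dtype=int)  # lower in RecPro
    groups = [list(sig_idx[i : i + 2]) for i in range(0, sig_idx.size, 2)]

    drawn_base = rng.normal(5.0, 1.0, p)
    base = drawn_base if base_log_mean is None else np.asarray(base_log_mean, float)
    drawn_shift = rng.normal(0.0, spec.healthy_shift_sd, p)
    if healthy_shift is None:
        healthy_shift = drawn_shift
    else:
        healthy_shift = np.asarray(healthy_shift, float)
    slide_ids = [f"{spec.cohort_id}-S{k + 1}" for k in range(spec.slide_count)]
    slide_offsets = rng.normal(0.0, spec.batch_sd, spec.slide_count)

    n_rec, n_ned = spec.n_patients_per_class
    outcomes = [RECPRO] * n_rec + [NED] * n_ned
    pids = [f"{spec.cohort_id}-{i + 1:03d}" for i in range(len(outcomes))]
    slide_of = rng.permutation(len(pids)) % spec.slide_count

    f = spec.subclone_fraction
    core_amp = spec.effect_size * spec.sigma_within / (2.0 * (1.0 - 2.0 * f))

    ref_scale = math.exp(5.0)  # median peak intensity scale exp(base mean)
    axis, peak_pos = _build_axis(centroids, spec.background_channels_per_gap)
    baseline_shape = spec.baseline_amplitude * ref_scale * np.exp(
        -(axis - spec.mz_range[0]) / 1000.0
    )

    obs_rows: list[tuple] = []
    blocks: list[np.ndarray] = []
    sub_masks: list[np.ndarray] = []
    lo, hi = spec.spectra_per_patient
    L = spec.spatial_correlation_length

    for pi, (pid, outcome) in enumerate(zip(pids, outcomes)):
        n_roi = int(rng.integers(lo, hi + 1))
        n_margin = int(round(spec.margin_fraction * n_roi))
        n_px = n_roi + n_margin
        h = max(1, int(math.isqrt(n_px)))
        w = int(math.ceil(n_px / h))
        roi = np.zeros(n_px, dtype=bool)
        roi[:n_roi] = True  # tumor rows first, healthy margin below
        u = rng.normal(0.0, spec.patient_sd, p)
        fields = spec.spatial_sd * _smooth_unit_field(rng, (p, h, w), L)
        for g in groups:
            if len(g) > 1:  # same-protein peptides share one spatial field
                fields[g[1:]] = fields[g[0]]
        fields_px = fields.reshape(p, -1)[:, :n_px].T  # (n_px, p)

        sub_field = _smooth_unit_field(rng, (h, w), L).ravel()[:n_px]
        sub = np.zeros(n_px, dtype=bool)
        if f > 0:
            roi_vals = sub_field[roi]
            sub[roi] = roi_vals >= np.quantile(roi_vals, 1.0 - f)

        s_class = 1.0 if outcome == NED else -1.0
        class_term = np.zeros((n_px, p))
        flip = np.where(sub, -1.0, 1.0) * roi  # signal only in tumor pixels
        for d, j in zip(directions, sig_idx):
            class_term[:, j] = (-d) * s_class * core_amp * flip

        log_i = (
            base[None, :]
            + np.where(roi[:, None], 0.0, 1.0) * healthy_shift[None, :]
            + slide_offsets[slide_of[pi]]
            + u[None, :]
            + fields_px
            + class_term
            + rng.normal(0.0, spec.pixel_sd, (n_px, p))
        )
        peaks = np.exp(log_i)

        block = np.zeros((n_px, axis.size))
        block[:, peak_pos] = peaks
        if spec.baseline_amplitude > 0:
            px_scale = np.exp(rng.normal(0.0, 0.1, n_px))
            block += px_scale[:, None] * baseline_shape[None, :]
            block += np.abs(rng.normal(0.0, 0.02 * ref_scale, block.shape))
        blocks.append(block)
        sub_masks.append(sub)

        ys, xs = np.divmod(np.arange(n_px), w)
        slide = slide_ids[slide_of[pi]]
        obs_rows.extend(
            (pid, spec.cohort_id, slide, int(x), int(y), bool(r))
            for x, y, r in zip(xs, ys, roi)
        )

    obs = pd.DataFrame(obs_rows, columns=OBS_COLUMNS)
    patients = pd.DataFrame(
        {
            "patient_id": pids,
            "outcome": outcomes,
            "cohort": spec.cohort_id,
            "slide": [slide_ids[s] for s in slide_of],
        }
    )
    dataset = MSIDataset(
        mz=axis,
        intensities=np.vstack(blocks),
        obs=obs,
        patients=patients,
        provenance=[f"generate_cohort(cohort={spec.cohort_id}, seed={spec.seed})"],
    )
    truth = SyntheticGroundTruth(
        feature_mzs=centroids,
        signal_feature_indices=sig_idx,
        directions=directions,
        signal_feature_groups=groups,
        subclone_mask=np.concatenate(sub_masks),
        patient_outcomes=pd.Series(outcomes, index=pids, name="outcome"),
        healthy_shift=healthy_shift,
        base_log_mean=base,
    )
    return dataset, truth


def generate_transfer_cohort(
    spec: CohortSpec,
    reference: SyntheticGroundTruth,
    shared_signal: bool = False,
) -> tuple[MSIDataset, SyntheticGroundTruth]:
    """Second cohort on the feature space of ``reference``.

    With ``shared_signal=False`` (default) the outcome signal sits on an
    independent, disjoint feature set, so models trained on the reference
    cohort should transfer poorly; with ``shared_signal=True`` the planted
    features coincide and transfer should approach within-cohort performance.
    """
    if shared_signal:
        sig = reference.signal_feature_indices
    else:
        rng = np.random.default_rng(spec.seed + 104729)  # independent pick
        candidates = np.setdiff1d(
            np.arange(reference.feature_mzs.size), reference.signal_feature_indices
        )
        sig = np.sort(rng.choice(candidates, spec.n_signal_features, replace=False))
    return generate_cohort(
        spec,
        feature_mzs=reference.feature_mzs,
        signal_feature_indices=sig,
        healthy_shift=reference.healthy_shift,
        base_log_mean=reference.base_log_mean,
    )


def _random_peptide(rng: np.random.Generator) -> str:
    length = int(rng.integers(7, 15))
    body = "".join(rng.choice(_AMINO_ACIDS, length))
    return body + ("K" if rng.random() < 0.5 else "R")


def generate_peptide_library(
    ground_truth: SyntheticGroundTruth,
    feature_mzs: np.ndarray,
    n_proteins: int = 12,
    peptides_per_protein: int = 2,
    mass_jitter_sd: float = 0.0,
    seed: int = 0,
    n_single_peptide_proteins: int = 0,
) -> pd.DataFrame:
    """Synthetic bottom-up LC-MS/MS peptide library.

    Proteins intended to validate receive ``peptides_per_protein`` (>=2)
    peptides mapped to features of one planted signal group, which share a
    spatial field and therefore co-localize.  ``n_single_peptide_proteins``
    adds proteins supported by a single (non-signal) peptide each, which must
    fail the two-peptide validation rule.  Library masses are neutral
    monoisotopic masses; the observed MALDI feature m/z is the [M+H]+ ion,
    so mass = feature_mz - 1.00728 (+ jitter).
    """
    if peptides_per_protein < 1:
        raise ParameterError("peptides_per_protein must be >= 1")
    rng = np.random.default_rng(seed)
    feature_mzs = np.asarray(feature_mzs, float)
    rows = []
    multi_groups = [g for g in ground_truth.signal_feature_groups if len(g) >= 2]
    pool = list(ground_truth.signal_feature_indices)
    for k in range(n_proteins):
        pid = f"SYNP{k + 1:03d}"
        if peptides_per_protein >= 2 and multi_groups:
            g = multi_groups[k % len(multi_groups)]
            feats = [g[i % len(g)] for i in range(peptides_per_protein)]
        else:
            feats = [pool[(k * peptides_per_protein + i) % len(pool)] for i in range(peptides_per_protein)]
        for j in feats:
            rows.append(
                {
                    "sequence": _random_peptide(rng),
                    "monoisotopic_mass": feature_mzs[j]
                    - PROTON_MASS
                    + (rng.normal(0.0, mass_jitter_sd) if mass_jitter_sd > 0 else 0.0),
                    "protein_id": pid,
                    "protein_name": f"Synthetic protein {pid}",
                    "score": float(rng.uniform(20.0, 120.0)),
                }
            )
    if n_single_peptide_proteins > 0:
        non_signal = np.setdiff1d(
            np.arange(feature_mzs.size), ground_truth.signal_feature_indices
        )
        picks = rng.choice(non_signal, n_single_peptide_proteins, replace=False)
        for k, j in enumerate(picks):
            pid = f"SYNS{k + 1:03d}"
            rows.append(
                {
                    "sequence": _random_peptide(rng),
                    "monoisotopic_mass": feature_mzs[j]
                    - PROTON_MASS
                    + (rng.normal(0.0, mass_jitter_sd) if mass_jitter_sd > 0 else 0.0),
                    "protein_id": pid,
                    "protein_name": f"Synthetic singleton {pid}",
                    "score": float(rng.uniform(20.0, 120.0)),
                }
            )
    columns = ["sequence", "monoisotopic_mass", "protein_id", "protein_name", "score"]
    return pd.DataFrame(rows, columns=columns)
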