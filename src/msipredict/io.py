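"""Readers/writers for the CSV exchange formats.

Spectra table (one row per pixel): ``patient_id, cohort, slide, x, y,
roi_flag`` followed by one ``mz_<value>`` column per m/z channel.  Patient
metadata: ``patient_id, outcome, cohort, slide``.  Peptide library:
``sequence, monoisotopic_mass, protein_id, protein_name, score``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import OBS_COLUMNS, AlignedFeatureMatrix, FormatError, MSIDataset

__all__ = [
    "read_spectra_table",
    "write_spectra_table",
    "read_patient_table",
    "write_patient_table",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_imzml",
]

PATIENT_COLUMNS = ["patient_id", "outcome", "cohort", "slide"]
_MZ_FMT = "mz_{:.4f}"


def write_spectra_table(dataset: MSIDataset, path: str | Path) -> None:
    """Write the per-spectrum intensity table as CSV (UTF-8, comma)."""
    intens = pd.DataFrame(
        dataset.intensities, columns=[_MZ_FMT.format(mz) for mz in dataset.mz]
    )
    df = pd.concat([dataset.obs[OBS_COLUMNS].reset_index(drop=True), intens], axis=1)
    df.to_csv(path, index=False)


def read_spectra_table(
    path: str | Path, patients: pd.DataFrame | None = None
) -> MSIDataset:
    """Read a spectra-table CSV back into an :class:`MSIDataset`.

    Raises :class:`FormatError` on missing metadata columns or duplicate
    (patient_id, x, y) pixel keys.
    """
    df = pd.read_csv(path)
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"spectra table missing columns: {missing}")
    mz_cols = [c for c in df.columns if c.startswith("mz_")]
    if df.duplicated(subset=["patient_id", "x", "y"]).any():
        dup = df[df.duplicated(subset=["patient_id", "x", "y"], keep=False)]
        key = dup.iloc[0][["patient_id", "x", "y"]].tolist()
        raise FormatError(f"duplicate (patient, x, y) pixel key, e.g. {key}")
    mz = np.array([float(c[3:]) for c in mz_cols])
    order = np.argsort(mz)
    mz = mz[order]
    intensities = df[mz_cols].to_numpy(dtype=float)[:, order]
    obs = df[OBS_COLUMNS].copy()
    obs["roi_flag"] = obs["roi_flag"].astype(bool)
    return MSIDataset(mz=mz, intensities=intensities, obs=obs, patients=patients)


def write_patient_table(patients: pd.DataFrame, path: str | Path) -> None:
    patients[PATIENT_COLUMNS].to_csv(path, index=False)


def read_patient_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "slide": str})
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"patient table missing columns: {missing}")
    return df[PATIENT_COLUMNS]


def write_feature_matrix(matrix: AlignedFeatureMatrix, path: str | Path) -> None:
    """Aligned feature matrix as CSV: metadata columns + one mz_ column per
    feature; the alignment tolerance travels in a ``# tolerance=`` header line."""
    df = matrix.to_dataframe()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# tolerance={matrix.tolerance}\n")
        df.to_csv(fh, index=False)


def read_feature_matrix(
    path: str | Path, patients: pd.DataFrame | None = None
) -> AlignedFeatureMatrix:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        tolerance = 0.2
        if first.startswith("# tolerance="):
            tolerance = float(first.split("=", 1)[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"feature matrix missing columns: {missing}")
    mz_cols = [c for c in df.columns if c.startswith("mz_")]
    mz = np.array([float(c[3:]) for c in mz_cols])
    order = np.argsort(mz)
    obs = df[OBS_COLUMNS].copy()
    obs["roi_flag"] = obs["roi_flag"].astype(bool)
    return AlignedFeatureMatrix(
        values=df[mz_cols].to_numpy(float)[:, order],
        feature_mz=mz[order],
        obs=obs,
        tolerance=tolerance,
        patients=patients,
    )


def read_imzml(
    path: str | Path,
    patient_id: str = "unknown",
    cohort: str = "unknown",
    slide: str = "unknown",
) -> MSIDataset:
    """Optional continuous-mode imzML reader (requires ``pyimzml``).

    All pixels of the file are attributed to a single patient/slide; ROI
    flags default to True and can be edited on the returned dataset.
    """
    try:
        from pyimzml.ImzMLParser import ImzMLParser
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading imzML requires the pyimzml package") from exc
    parser = ImzMLParser(str(path))
    mz0, _ = parser.getspectrum(0)
    intensities = np.zeros((len(parser.coordinates), len(mz0)))
    rows = []
    for i, (x, y, *_rest) in enumerate(parser.coordinates):
        mz_i, intens = parser.getspectrum(i)
        if len(mz_i) != len(mz0) or not np.allclose(mz_i, mz0):
            raise FormatError("imzML file is not continuous-mode (shared m/z axis)")
        intensities[i] = intens
        rows.append((patient_id, cohort, slide, int(x), int(y), True))
    obs = pd.DataFrame(rows, columns=OBS_COLUMNS)
    return MSIDataset(mz=np.asarray(mz0, float), intensities=intensities, obs=obs)
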