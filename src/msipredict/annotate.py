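"""Peptide/protein annotation of discriminative m/z features.

Imaging features are matched against a bottom-up LC-MS/MS peptide library by
mass: the observed MALDI feature m/z is treated as the singly protonated ion
[M+H]+, so library monoisotopic masses are offset by +1.00728 Da before
computing deviations (configurable off).  Candidates within the tolerance
are ranked by smallest absolute mass deviation, then highest -logP score.
A protein identification is validated only when at least two of its
peptides are observed as imaging features with similar tissue distribution
(pairwise correlation of their pixel intensity images above a threshold).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import FormatError, ParameterError
from .simulate import PROTON_MASS

__all__ = [
    "load_peptide_library",
    "write_peptide_library",
    "match_mz_features",
    "validate_proteins",
    "annotation_report",
]

LIBRARY_COLUMNS = ["sequence", "monoisotopic_mass", "protein_id", "protein_name", "score"]


def write_peptide_library(library: pd.DataFrame, path: str | Path) -> None:
    library[LIBRARY_COLUMNS].to_csv(path, index=False)


def load_peptide_library(path: str | Path) -> pd.DataFrame:
    """Read a peptide library CSV with schema validation.

    Duplicate (sequence, protein_id) rows are deduplicated keeping the
    highest -logP score.
    """
    df = pd.read_csv(path)
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"peptide library missing columns: {missing}")
    if len(df) and ((df["monoisotopic_mass"] <= 0).any() or (df["score"] < 0).any()):
        raise FormatError("library masses must be > 0 and scores >= 0")
    df = (
        df.sort_values("score", ascending=False)
        .drop_duplicates(subset=["sequence", "protein_id"], keep="first")
        .sort_index()
        .reset_index(drop=True)
    )
    return df[LIBRARY_COLUMNS]


def match_mz_features(
    feature_mzs: np.ndarray,
    library: pd.DataFrame,
    tolerance_da: float = 0.2,
    proton_adduct: bool = True,
) -> pd.DataFrame:
    """Best library peptide for each feature within the mass tolerance.

    Candidates are ranked by (smallest |deviation|, highest score, sequence)
    — the final lexicographic key only breaks exact ties, keeping the result
    independent of library row order.  Features without a candidate are
    returned with ``matched=False``.
    """
    if tolerance_da <= 0:
        raise ParameterError("tolerance must be positive")
    feature_mzs = np.asarray(feature_mzs, float)
    offset = PROTON_MASS if proton_adduct else 0.0
    lib_ion_mass = library["monoisotopic_mass"].to_numpy(float) + offset
    rows = []
    for mz in feature_mzs:
        dev = np.abs(mz - lib_ion_mass)
        cand = np.flatnonzero(dev <= tolerance_da)
        if cand.size == 0:
            rows.append(
                {"feature_mz": mz, "matched": False, "sequence": None,
                 "protein_id": None, "protein_name": None, "score": np.nan,
                 "mass_deviation": np.nan}
            )
            continue
        sub = library.iloc[cand].copy()
        sub["mass_deviation"] = dev[cand]
        sub = sub.sort_values(
            ["mass_deviation", "score", "sequence"],
            ascending=[True, False, True],
            kind="mergesort",
        )
        best = sub.iloc[0]
        rows.append(
            {
                "feature_mz": mz,
                "matched": True,
                "sequence": best["sequence"],
                "protein_id": best["protein_id"],
                "protein_name": best["protein_name"],
                "score": float(best["score"]),
                "mass_deviation": float(best["mass_deviation"]),
            }
        )
    return pd.DataFrame(rows)


def validate_proteins(
    matches: pd.DataFrame,
    feature_images: dict[float, np.ndarray],
    min_peptides: int = 2,
    min_correlation: float = 0.4,
    method: str = "pearson",
) -> pd.DataFrame:
    """Two-stage protein validation.

    Stage 1 keeps proteins supported by at least ``min_peptides`` matched
    imaging features; stage 2 additionally requires a similar tissue
    distribution, quantified as the minimum pairwise correlation (Pearson by
    default, Spearman selectable) of the supporting features' ROI pixel
    intensity vectors reaching ``min_correlation``.  Supports without an
    available image are dropped with a warning.
    """
    if method not in {"pearson", "spearman"}:
        raise ParameterError(f"unknown correlation method {method!r}")
    matched = matches[matches["matched"]].copy()
    rows = []
    for pid, grp in matched.groupby("protein_id", sort=True):
        feats = []
        for mz in grp["feature_mz"]:
            if mz in feature_images:
                feats.append(mz)
            else:
                warnings.warn(f"no intensity image for matched feature m/z {mz}")
        n_support = len(set(feats))
        feats = sorted(set(feats))
        if n_support >= 2:
            cors = []
            for i in range(len(feats)):
                for j in range(i + 1, len(feats)):
                    a = np.asarray(feature_images[feats[i]], float)
                    b = np.asarray(feature_images[feats[j]], float)
                    if method == "pearson":
                        r = stats.pearsonr(a, b).statistic
                    else:
                        r = stats.spearmanr(a, b).statistic
                    cors.append(r)
            min_r = float(np.min(cors))
        else:
            min_r = np.nan
        rows.append(
            {
                "protein_id": pid,
                "protein_name": grp["protein_name"].iloc[0],
                "n_supporting_peptides": n_support,
                "supporting_mzs": feats,
                "min_pairwise_correlation": min_r,
                "validated": bool(
                    n_support >= min_peptides
                    and np.isfinite(min_r)
                    and min_r >= min_correlation
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "protein_name", "n_supporting_peptides",
                 "supporting_mzs", "min_pairwise_correlation", "validated"],
    )


def annotation_report(
    matches: pd.DataFrame,
    proteins: pd.DataFrame,
    feature_stats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join matches with protein validation flags (and screening AUCs)."""
    report = matches.merge(
        proteins[["protein_id", "validated"]], on="protein_id", how="left"
    )
    report["validated"] = report["validated"].astype("boolean").fillna(False).astype(bool)
    if feature_stats is not None:
        report = report.merge(
            feature_stats[["feature_mz", "auc", "p_adj", "selected"]],
            on="feature_mz",
            how="left",
        )
    return report
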