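"""Outcome classification: L1 logistic regression with patient-grouped CV.

The modelling surface follows the model/results convention: build an
:class:`OutcomeModel` from an aligned feature matrix plus a patient table,
call :meth:`OutcomeModel.fit` to run patient-grouped, class-stratified
5-fold cross-validation, and read estimates, metrics and diagnostics off the
returned :class:`OutcomeCVResults` (``summary()``, ``coefficient_stability()``,
``evaluate_transfer()``).

Conventions: NED (no evidence of disease) is the positive class, so
sensitivity is the NED recall and specificity the RecPro recall; balanced
accuracy is their arithmetic mean.  Patient calls sum the per-spectrum class
probabilities and take the argmax (ties fall to RecPro, the conservative
choice when flagging risk).  A patient's majority vote is correct only when
strictly more than 50% of their spectra are individually correct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .core import NED, RECPRO, AlignedFeatureMatrix, ParameterError
from .preprocess import downsample_features, per_patient_standardize

__all__ = [
    "CVPlan",
    "ModelConfig",
    "make_grouped_stratified_folds",
    "fit_l1_logistic",
    "l1_objective",
    "predict_spectra",
    "aggregate_patient",
    "compute_metrics",
    "OutcomeModel",
    "OutcomeCVResults",
]

METRICS = ["b.acc", "AUC", "sensitivity", "specificity"]


@dataclass
class CVPlan:
    """Patient-level fold assignment: each patient in exactly one fold."""

    n_folds: int
    assignments: pd.Series  # patient_id -> fold index

    def test_patients(self, k: int) -> list[str]:
        return list(self.assignments.index[self.assignments == k])

    def train_patients(self, k: int) -> list[str]:
        return list(self.assignments.index[self.assignments != k])

    def check_disjoint(self) -> None:
        for k in range(self.n_folds):
            overlap = set(self.test_patients(k)) & set(self.train_patients(k))
            if overlap:
                raise ParameterError(f"fold {k}: patients in train and test: {overlap}")


@dataclass
class ModelConfig:
    """Configuration of one classification model.

    ``l1_strength`` is the weight of the L1 term in the per-observation
    objective (class-weighted mean negative log-likelihood + lambda*||beta||_1,
    intercept unpenalized).  The vendor-pipeline regularization strengths
    reported for the clinical runs were 7000 (all m/z) and 30 (restricted
    subset) in a library whose parameter scales with the raw spectrum count;
    the defaults here were calibrated once on the synthetic desk-scale cohort.
    """

    feature_mode: str = "all_mz"  # "all_mz" (2x downsampled) or "restricted"
    restricted_indices: np.ndarray | None = None
    l1_strength: float = 0.03
    n_folds: int = 5
    tol: float = 1e-4
    max_iter: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.l1_strength < 0:
            raise ParameterError("l1_strength must be non-negative")
        if self.feature_mode not in {"all_mz", "restricted"}:
            raise ParameterError(f"unknown feature_mode {self.feature_mode!r}")
        if self.feature_mode == "restricted" and self.restricted_indices is None:
            raise ParameterError("restricted mode needs restricted_indices")


def make_grouped_stratified_folds(
    patient_table: pd.DataFrame, n_folds: int = 5, seed: int = 0
) -> CVPlan:
    """Seeded round-robin assignment of shuffled patients, per outcome class.

    Stratification is at patient granularity and therefore approximate (11
    NED patients cannot split evenly over 5 folds); fold class counts are
    balanced within one patient.
    """
    if len(patient_table) < n_folds:
        raise ParameterError("fewer patients than folds")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for outcome in (RECPRO, NED):
        pids = sorted(patient_table.loc[patient_table["outcome"] == outcome, "patient_id"])
        pids = [pids[i] for i in rng.permutation(len(pids))]
        for i, pid in enumerate(pids):
            assignment[pid] = i % n_folds
    ser = pd.Series(assignment, name="fold").sort_index()
    plan = CVPlan(n_folds=n_folds, assignments=ser)
    plan.check_disjoint()
    return plan


def _to_binary(labels: np.ndarray) -> np.ndarray:
    """Map outcome labels to ints with NED (positive class) = 1."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "ifb":
        return arr.astype(int)
    return (arr == NED).astype(int)


def _class_weights(y: np.ndarray) -> np.ndarray:
    """Inverse-frequency weights, normalized so they sum to n."""
    n = y.size
    w = np.where(y == 1, n / (2.0 * max(y.sum(), 1)), n / (2.0 * max(n - y.sum(), 1)))
    return w


def l1_objective(
    X: np.ndarray, y: np.ndarray, coef: np.ndarray, intercept: float, l1_strength: float
) -> float:
    """Class-weighted mean negative log-likelihood + lambda * ||coef||_1."""
    y = _to_binary(y)
    w = _class_weights(y)
    z = X @ np.asarray(coef, float) + intercept
    # log(1 + exp(-s*z)) with s = +/-1, numerically stable
    s = 2 * y - 1
    nll = np.logaddexp(0.0, -s * z)
    return float(np.sum(w * nll) / np.sum(w) + l1_strength * np.abs(coef).sum())


def fit_l1_logistic(
    train_matrix: np.ndarray,
    labels: np.ndarray,
    l1_strength: float,
    tol: float = 1e-4,
    max_iter: int = 3000,
    seed: int = 0,
) -> tuple[np.ndarray, float, bool]:
    """L1-penalized logistic regression with inverse-frequency class weights.

    Minimizes the objective of :func:`l1_objective` (intercept unpenalized)
    via the saga solver; ``l1_strength`` maps to the solver's ``C`` as
    ``1 / (l1_strength * n)`` because the balanced class weights sum to n.
    Returns ``(coefficients, intercept, converged)``; non-convergence at
    ``max_iter`` is flagged, not raised.
    """
    X = np.asarray(train_matrix, float)
    y = _to_binary(labels)
    if np.unique(y).size < 2:
        raise ParameterError("training labels must contain both classes")
    if l1_strength == 0:
        clf = LogisticRegression(
            penalty=None, solver="saga", tol=tol, max_iter=max_iter,
            class_weight="balanced", random_state=seed,
        )
    else:
        clf = LogisticRegression(
            penalty="l1", solver="saga", C=1.0 / (l1_strength * y.size),
            tol=tol, max_iter=max_iter, class_weight="balanced",
            random_state=seed,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    converged = bool(np.all(clf.n_iter_ < max_iter))
    if not converged:
        warnings.warn(f"L1 logistic fit hit max_iter={max_iter} without converging")
    return clf.coef_[0].copy(), float(clf.intercept_[0]), converged


def predict_spectra(
    coef: np.ndarray, intercept: float, matrix: np.ndarray
) -> np.ndarray:
    """Per-spectrum P(NED) through the logistic link 1/(1+exp(-(x.beta+b)))."""
    X = np.asarray(matrix, float)
    coef = np.asarray(coef, float)
    if X.shape[1] != coef.size:
        raise ParameterError(
            f"feature dimension mismatch: matrix has {X.shape[1]}, model {coef.size}"
        )
    z = X @ coef + intercept
    return 1.0 / (1.0 + np.exp(-z))


def aggregate_patient(
    probabilities: np.ndarray,
    patient_ids: np.ndarray,
    true_labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Patient calls from per-spectrum P(NED).

    Sums P(NED) and P(RecPro) = 1 - P(NED) over each patient's spectra; the
    call is the class with the larger sum (exact ties -> RecPro).  When true
    labels are given, also reports the fraction of spectra whose individual
    argmax matches the truth and the strict-majority flag (> 50%).
    """
    p = np.asarray(probabilities, float)
    df = pd.DataFrame({"patient_id": np.asarray(patient_ids), "p_ned": p})
    if true_labels is not None:
        df["y_true"] = _to_binary(true_labels)
    rows = []
    for pid, grp in df.groupby("patient_id", sort=True):
        sum_ned = grp["p_ned"].sum()
        sum_rec = (1.0 - grp["p_ned"]).sum()
        call = NED if sum_ned > sum_rec else RECPRO
        row = {
            "patient_id": pid,
            "n_spectra": len(grp),
            "sum_p_ned": sum_ned,
            "sum_p_recpro": sum_rec,
            "mean_p_ned": grp["p_ned"].mean(),
            "predicted": call,
        }
        if true_labels is not None:
            y = int(grp["y_true"].iloc[0])
            spectra_calls = (grp["p_ned"] > 0.5).astype(int)
            frac = float((spectra_calls == y).mean())
            row.update(
                {
                    "true": NED if y == 1 else RECPRO,
                    "fraction_correct": frac,
                    "majority_correct": frac > 0.5,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def compute_metrics(
    true_labels: np.ndarray,
    predicted_labels: np.ndarray,
    probabilities: np.ndarray | None = None,
) -> dict[str, float]:
    """Sensitivity (NED recall), specificity (RecPro recall), balanced
    accuracy = (sens + spec)/2, and ROC-AUC from the P(NED) scores.

    A class absent from the truth leaves its metric undefined (NaN) and sets
    the ``undefined`` flag.
    """
    y = _to_binary(true_labels)
    yhat = _to_binary(predicted_labels)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    sens = float((yhat[y == 1] == 1).mean()) if n_pos else float("nan")
    spec = float((yhat[y == 0] == 0).mean()) if n_neg else float("nan")
    bacc = (sens + spec) / 2.0
    if probabilities is not None and n_pos and n_neg:
        auc = float(roc_auc_score(y, np.asarray(probabilities, float)))
    else:
        auc = float("nan")
    return {
        "sensitivity": sens,
        "specificity": spec,
        "b.acc": bacc,
        "AUC": auc,
        "undefined": not (n_pos and n_neg),
    }


class OutcomeModel:
    """L1-logistic outcome classifier over an aligned MSI feature matrix.

    Parameters
    ----------
    features : aligned (preprocessed, non-standardized) feature matrix with a
        patient table attached or supplied separately.
    patients : optional patient table overriding ``features.patients``.
    config : :class:`ModelConfig`; ``feature_mode="all_mz"`` applies the 2x
        feature down-sampling, ``"restricted"`` keeps only
        ``restricted_indices`` (e.g. the univariate screening selection).
    """

    def __init__(
        self,
        features: AlignedFeatureMatrix,
        patients: pd.DataFrame | None = None,
        config: ModelConfig | None = None,
    ) -> None:
        self.config = config or ModelConfig()
        self.raw_features = features
        self.patients = patients if patients is not None else features.patients
        if self.patients is None:
            raise ParameterError("OutcomeModel requires a patient table")
        self.features = self._prepare(features)

    @classmethod
    def from_dataset(
        cls,
        dataset,
        tolerance: float = 0.2,
        config: ModelConfig | None = None,
        **preprocess_kwargs,
    ) -> "OutcomeModel":
        """Convenience constructor: preprocess + align a raw dataset first."""
        from .preprocess import detect_and_align_peaks, preprocess

        prepared = preprocess(dataset, **preprocess_kwargs)
        fm = detect_and_align_peaks(prepared, tolerance=tolerance)
        return cls(fm, config=config)

    def _prepare(self, fm: AlignedFeatureMatrix) -> AlignedFeatureMatrix:
        if self.config.feature_mode == "restricted":
            fm = fm.subset_features(self.config.restricted_indices)
        else:
            fm = downsample_features(fm)
        return per_patient_standardize(fm)

    def fit(self, plan: CVPlan | None = None) -> "OutcomeCVResults":
        """Run patient-grouped stratified k-fold CV and collect results."""
        cfg = self.config
        if plan is None:
            plan = make_grouped_stratified_folds(self.patients, cfg.n_folds, cfg.seed)
        plan.check_disjoint()
        fm = self.features
        pid = fm.obs["patient_id"].to_numpy()
        y = _to_binary(fm.outcome_per_spectrum().to_numpy())
        # standardization statistics use every spectrum of a patient (whole
        # section); model training and evaluation are restricted to the
        # annotated tumor region
        roi = fm.obs["roi_flag"].to_numpy(bool)

        coefs, intercepts, converged = [], [], []
        split_metrics: dict[tuple[str, str], list[float]] = {
            (lvl, m): [] for lvl in ("spectra", "patient") for m in METRICS
        }
        prob_records = []
        patient_frames = []
        for k in range(plan.n_folds):
            test_p = set(plan.test_patients(k))
            in_test = np.isin(pid, list(test_p))
            test_rows = in_test & roi
            train_rows = ~in_test & roi
            coef, b, ok = fit_l1_logistic(
                fm.values[train_rows], y[train_rows], cfg.l1_strength,
                tol=cfg.tol, max_iter=cfg.max_iter, seed=cfg.seed,
            )
            coefs.append(coef)
            intercepts.append(b)
            converged.append(ok)

            p_test = predict_spectra(coef, b, fm.values[test_rows])
            y_test = y[test_rows]
            sm = compute_metrics(y_test, (p_test > 0.5).astype(int), p_test)
            for m in METRICS:
                split_metrics[("spectra", m)].append(sm[m])

            agg = aggregate_patient(p_test, pid[test_rows], y_test)
            agg["split"] = k
            patient_frames.append(agg)
            pm = compute_metrics(
                agg["true"].to_numpy(), agg["predicted"].to_numpy(),
                agg["mean_p_ned"].to_numpy(),
            )
            for m in METRICS:
                split_metrics[("patient", m)].append(pm[m])

            prob_records.append(
                pd.DataFrame(
                    {
                        "row": np.flatnonzero(test_rows),
                        "patient_id": pid[test_rows],
                        "split": k,
                        "p_ned": p_test,
                        "y_true": y_test,
                    }
                )
            )

        metrics = pd.DataFrame(
            {f"split_{k + 1}": [split_metrics[key][k] for key in split_metrics]
             for k in range(plan.n_folds)},
            index=pd.MultiIndex.from_tuples(split_metrics, names=["level", "metric"]),
        )
        metrics["mean"] = metrics[[f"split_{k + 1}" for k in range(plan.n_folds)]].mean(axis=1)
        return OutcomeCVResults(
            model=self,
            plan=plan,
            coefs=np.vstack(coefs),
            intercepts=np.asarray(intercepts),
            converged=np.asarray(converged, bool),
            metrics=metrics,
            spectrum_probabilities=pd.concat(prob_records, ignore_index=True),
            patient_predictions=pd.concat(patient_frames, ignore_index=True),
        )


@dataclass
class OutcomeCVResults:
    """Cross-validated fit: per-split estimates, predictions and metrics."""

    model: OutcomeModel
    plan: CVPlan
    coefs: np.ndarray  # (n_splits, n_features)
    intercepts: np.ndarray
    converged: np.ndarray
    metrics: pd.DataFrame  # (level, metric) x (split_1..split_k, mean)
    spectrum_probabilities: pd.DataFrame
    patient_predictions: pd.DataFrame
    transfer_of: str | None = None

    @property
    def feature_mz(self) -> np.ndarray:
        return self.model.features.feature_mz

    def mean_metric(self, level: str, metric: str) -> float:
        return float(self.metrics.loc[(level, metric), "mean"])

    def coefficient_stability(self, min_splits: int = 2) -> pd.DataFrame:
        """Features with a nonzero coefficient in at least ``min_splits``
        splits, with sign consistency (all nonzero coefficients share one
        sign) and the mean coefficient over splits."""
        nz = self.coefs != 0.0
        n_nonzero = nz.sum(axis=0)
        keep = np.flatnonzero(n_nonzero >= min_splits)
        rows = []
        for j in keep:
            vals = self.coefs[:, j][nz[:, j]]
            rows.append(
                {
                    "feature_mz": self.feature_mz[j],
                    "feature_index": int(j),
                    "n_nonzero_splits": int(n_nonzero[j]),
                    "sign_consistent": bool(np.all(vals > 0) or np.all(vals < 0)),
                    "mean_coef": float(self.coefs[:, j].mean()),
                }
            )
        out = pd.DataFrame(
            rows,
            columns=["feature_mz", "feature_index", "n_nonzero_splits",
                     "sign_consistent", "mean_coef"],
        )
        return out.sort_values("feature_mz").reset_index(drop=True)

    def evaluate_transfer(
        self,
        other_features: AlignedFeatureMatrix,
        other_patients: pd.DataFrame | None = None,
    ) -> "OutcomeCVResults":
        """Apply every split's model to another cohort (same feature space).

        The other cohort must carry the same aligned feature centroids; it
        receives the same feature-mode transform and is standardized on its
        own patients.  Metrics are computed over the whole transfer cohort
        for each split model, plus their mean.
        """
        patients = other_patients if other_patients is not None else other_features.patients
        if patients is None:
            raise ParameterError("transfer cohort requires a patient table")
        raw = self.model.raw_features
        if other_features.n_features != raw.n_features or not np.allclose(
            other_features.feature_mz, raw.feature_mz, atol=raw.tolerance
        ):
            raise ParameterError("transfer cohort feature space does not match")
        holder = object.__new__(OutcomeModel)
        holder.config = self.model.config
        holder.raw_features = other_features
        holder.patients = patients
        fm = holder._prepare(other_features)
        roi = fm.obs["roi_flag"].to_numpy(bool)
        fm = fm.subset_spectra(roi)
        holder.features = fm
        pid = fm.obs["patient_id"].to_numpy()
        y = _to_binary(fm.outcome_per_spectrum().to_numpy())
        split_metrics: dict[tuple[str, str], list[float]] = {
            (lvl, m): [] for lvl in ("spectra", "patient") for m in METRICS
        }
        prob_records, patient_frames = [], []
        n_splits = self.coefs.shape[0]
        for k in range(n_splits):
            p = predict_spectra(self.coefs[k], self.intercepts[k], fm.values)
            sm = compute_metrics(y, (p > 0.5).astype(int), p)
            for m in METRICS:
                split_metrics[("spectra", m)].append(sm[m])
            agg = aggregate_patient(p, pid, y)
            agg["split"] = k
            patient_frames.append(agg)
            pm = compute_metrics(
                agg["true"].to_numpy(), agg["predicted"].to_numpy(),
                agg["mean_p_ned"].to_numpy(),
            )
            for m in METRICS:
                split_metrics[("patient", m)].append(pm[m])
            prob_records.append(
                pd.DataFrame(
                    {
                        "row": np.arange(fm.n_spectra),
                        "patient_id": pid,
                        "split": k,
                        "p_ned": p,
                        "y_true": y,
                    }
                )
            )
        metrics = pd.DataFrame(
            {f"split_{k + 1}": [split_metrics[key][k] for key in split_metrics]
             for k in range(n_splits)},
            index=pd.MultiIndex.from_tuples(split_metrics, names=["level", "metric"]),
        )
        metrics["mean"] = metrics[[f"split_{k + 1}" for k in range(n_splits)]].mean(axis=1)
        return OutcomeCVResults(
            model=holder,
            plan=self.plan,
            coefs=self.coefs,
            intercepts=self.intercepts,
            converged=self.converged,
            metrics=metrics,
            spectrum_probabilities=pd.concat(prob_records, ignore_index=True),
            patient_predictions=pd.concat(patient_frames, ignore_index=True),
            transfer_of=self.model.raw_features.obs["cohort"].iloc[0]
            if len(self.model.raw_features.obs)
            else None,
        )

    def summary(self) -> str:
        """Plain-text metrics table, one row per (level, metric)."""
        cfg = self.model.config
        lines = [
            "Outcome classification - cross-validated results",
            f"feature_mode={cfg.feature_mode}  n_features={self.feature_mz.size}  "
            f"l1_strength={cfg.l1_strength}  folds={self.coefs.shape[0]}",
        ]
        if self.transfer_of is not None:
            lines.append(f"transfer evaluation of models trained on {self.transfer_of}")
        if not self.converged.all():
            lines.append(f"WARNING: {int((~self.converged).sum())} split(s) not converged")
        header = ["level", "metric"] + [
            c for c in self.metrics.columns
        ]
        lines.append("  ".join(f"{h:>12s}" for h in header))
        for (level, metric), row in self.metrics.iterrows():
            cells = [f"{level:>12s}", f"{metric:>12s}"] + [
                f"{v:12.3f}" for v in row.to_numpy()
            ]
            lines.append("  ".join(cells))
        return "\n".join(lines)

    def patient_classification_table(self) -> pd.DataFrame:
        """Per-patient calls across splits (test-fold calls for a CV fit)."""
        cols = ["patient_id", "true", "predicted", "fraction_correct",
                "majority_correct", "split"]
        return self.patient_predictions[cols].sort_values(
            ["patient_id", "split"]
        ).reset_index(drop=True)

    def probability_map(self, patient_id: str, split: int | None = None) -> pd.DataFrame:
        """Per-pixel table (x, y, p_ned) for one patient."""
        probs = self.spectrum_probabilities
        sel = probs[probs["patient_id"] == patient_id]
        if split is not None:
            sel = sel[sel["split"] == split]
        obs = self.model.features.obs
        out = obs.iloc[sel["row"].to_numpy()][["x", "y"]].copy().reset_index(drop=True)
        out["p_ned"] = sel["p_ned"].to_numpy()
        return out
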