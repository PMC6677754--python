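"""Activity classifier for membranolytic anticancer peptides.

The central objects follow the fitted-model idiom: :class:`AcpClassifier`
is constructed from a labeled dataset and configured with the training
protocol (correlation-based feature pruning, backward sequential feature
elimination scored by cross-validated Matthews correlation, linear
support-vector machine with C chosen by cross-validation); ``fit()`` returns
an :class:`AcpClassifierResults` carrying the selected features, the linear
decision weights, calibration to a pseudo-probability P_ACP, the k-means
centroids used for applicability-domain similarity scoring, and the training
diagnostics. Screening a peptide library combines P_ACP with the similarity
score S into the design scores

    phi_ACP = (P_ACP + S) / 2        phi_Neg = ((1 - P_ACP) + S) / 2

so that candidates far from the training data are penalized in both
directions (phi_ACP + phi_Neg = 0.5 + S identically).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .descriptors import DESCRIPTOR_NAMES, describe
from .peptide import Peptide, as_peptide

__all__ = [
    "LabeledDataset",
    "MetricsReport",
    "AcpClassifier",
    "AcpClassifierResults",
    "stratified_split",
    "covariance_elimination",
    "sequential_feature_elimination",
    "metrics_from_counts",
    "phi_scores",
]


# ---------------------------------------------------------------------------
# dataset


@dataclass
class LabeledDataset:
    """Peptides with binary activity labels (1 = active) and descriptors."""

    peptides: list
    labels: np.ndarray
    X: pd.DataFrame

    @classmethod
    def from_peptides(cls, peptides: Sequence, labels: Sequence[int]) -> "LabeledDataset":
        peps = [as_peptide(p, id=f"pep{k}") for k, p in enumerate(peptides)]
        if len(peps) != len(labels):
            raise ValueError("labels must align with peptides")
        X = describe(peps)
        X.index = [p.id for p in peps]
        return cls(peps, np.asarray(labels, dtype=int), X)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LabeledDataset":
        """Build from a table with columns id, sequence, label."""
        peps = [Peptide(str(r.id), r.sequence) for r in df.itertuples(index=False)]
        return cls.from_peptides(peps, df["label"].to_numpy())

    def __len__(self) -> int:
        return len(self.peptides)

    def subset(self, idx: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            [self.peptides[i] for i in idx],
            self.labels[idx],
            self.X.iloc[idx],
        )

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for p, y in zip(self.peptides, self.labels):
            h.update(f"{p.id}:{p.sequence}:{int(y)};".encode())
        return h.hexdigest()[:16]


def stratified_split(
    dataset: LabeledDataset, test_fraction: float, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Class-stratified train/test split.

    The test set receives round(N_c * test_fraction) members of each class c,
    so proportions are preserved to within one sample per class. Deterministic
    for a given seed. Classes with fewer than two members are refused.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    labels = dataset.labels
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    train_idx: list[int] = []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if len(members) < 2:
            raise ValueError(f"class {c} has fewer than 2 members")
        n_test = int(round(len(members) * test_fraction))
        n_test = min(max(n_test, 1), len(members) - 1)
        perm = rng.permutation(members)
        test_idx.extend(perm[:n_test])
        train_idx.extend(perm[n_test:])
    return dataset.subset(sorted(train_idx)), dataset.subset(sorted(test_idx))


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and the four classification metrics.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); an undefined
    denominator (all-one-class prediction) is reported as 0 with a warning.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    mcc: float
    accuracy: float
    precision: float
    recall: float
    context: str = "test"
    std: dict = field(default_factory=dict, compare=False)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def metrics_from_counts(
    tp: int, fp: int, tn: int, fn: int, context: str = "test"
) -> MetricsReport:
    n = tp + fp + tn + fn
    if n == 0:
        raise ValueError("empty confusion matrix")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        warnings.warn("degenerate confusion matrix: MCC reported as 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(float(denom))
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        mcc=float(mcc),
        accuracy=(tp + tn) / n,
        precision=float(precision),
        recall=float(recall),
        context=context,
    )


def metrics_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, context: str = "test"
) -> MetricsReport:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return metrics_from_counts(tp, fp, tn, fn, context=context)


def phi_scores(p_acp: float, s: float) -> tuple[float, float]:
    """Similarity-weighted design scores (phi_ACP, phi_Neg).

    phi_ACP = (P_ACP + S)/2 and phi_Neg = ((1 - P_ACP) + S)/2; both lie in
    [0, 1] and phi_ACP + phi_Neg = 0.5 + S exactly.
    """
    return (p_acp + s) / 2.0, ((1.0 - p_acp) + s) / 2.0


# ---------------------------------------------------------------------------
# feature selection


def covariance_elimination(
    X: pd.DataFrame, threshold: float = 0.9
) -> list[str]:
    """Greedy correlation-based feature pruning.

    Scans features in canonical (column) order; a feature is dropped if it
    has zero variance or if its absolute Pearson correlation with any
    already-retained feature exceeds ``threshold``. Returns retained names.
    """
    if len(X) < 3:
        raise ValueError("need at least 3 rows for correlation estimates")
    values = X.to_numpy(dtype=float)
    std = values.std(axis=0)
    retained: list[int] = []
    centered = values - values.mean(axis=0)
    for j in range(values.shape[1]):
        if std[j] == 0:
            continue
        ok = True
        for k in retained:
            r = (centered[:, j] @ centered[:, k]) / (len(X) * std[j] * std[k])
            if abs(r) > threshold:
                ok = False
                break
        if ok:
            retained.append(j)
    return [X.columns[j] for j in retained]


def _mcc(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = np.sum((y_true == 1) & (y_pred == 1))
    fp = np.sum((y_true == 0) & (y_pred == 1))
    tn = np.sum((y_true == 0) & (y_pred == 0))
    fn = np.sum((y_true == 1) & (y_pred == 0))
    denom = float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def _standardized_folds(
    X: np.ndarray, y: np.ndarray, cv_folds: int, seed: int
) -> list[tuple]:
    """Per-fold (train, validation) matrices, z-scored on the training fold.

    Standardization is columnwise, so column subsets of these matrices are
    identical to standardizing the subsets themselves; the fold split is
    computed once and reused across feature subsets.
    """
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = []
    for tr, va in skf.split(X, y):
        if len(np.unique(y[tr])) < 2:
            raise ValueError("degenerate single-class fold; use fewer folds")
        mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        folds.append(((X[tr] - mu) / sd, y[tr], (X[va] - mu) / sd, y[va]))
    return folds


def _subset_cv_mcc(folds: list, cols: np.ndarray, C: float, seed: int) -> float:
    """Mean CV MCC of the margin classifier on a column subset."""
    scores = []
    for Xtr, ytr, Xva, yva in folds:
        clf = LinearSVC(C=C, dual=True, tol=1e-3, max_iter=5000,
                        random_state=seed)
        clf.fit(Xtr[:, cols], ytr)
        scores.append(_mcc(yva, clf.predict(Xva[:, cols])))
    return float(np.mean(scores))


def _cv_mcc(
    X: np.ndarray, y: np.ndarray, cv_folds: int, seed: int, C: float
) -> float:
    """Mean cross-validated MCC of a linear margin classifier."""
    folds = _standardized_folds(np.asarray(X, float), np.asarray(y, int),
                                cv_folds, seed)
    return _subset_cv_mcc(folds, np.arange(X.shape[1]), C, seed)


def _cv_scores(
    X: np.ndarray, y: np.ndarray, cv_folds: int, seed: int, C: float
) -> list[MetricsReport]:
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    reports = []
    for tr, va in skf.split(X, y):
        if len(np.unique(y[tr])) < 2:
            raise ValueError("degenerate single-class fold; use fewer folds")
        mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        clf = LinearSVC(C=C, dual=False, max_iter=5000)
        clf.fit((X[tr] - mu) / sd, y[tr])
        pred = clf.predict((X[va] - mu) / sd)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reports.append(metrics_from_predictions(y[va], pred, context="cv"))
    return reports


def sequential_feature_elimination(
    X: pd.DataFrame,
    y: np.ndarray,
    candidates: Sequence[str] | None = None,
    cv_folds: int = 3,
    seed: int = 42,
    C: float = 1.0,
) -> tuple[list[str], list[dict]]:
    """Backward sequential feature elimination scored by CV MCC.

    At each step the feature whose removal maximizes the cross-validated MCC
    is dropped (ties resolved by dropping the feature latest in canonical
    order). Returns the subset at the path's MCC maximum (ties favor the
    smaller subset) and the full elimination path, one record per subset
    evaluated, each with keys ``features``, ``score`` and ``removed``.
    """
    feats = list(candidates) if candidates is not None else list(X.columns)
    if len(feats) < 2:
        if not feats:
            raise ValueError("need at least one candidate feature")
        return feats, [{"features": list(feats), "score": np.nan, "removed": None}]
    y = np.asarray(y, dtype=int)
    order = {f: i for i, f in enumerate(X.columns)}
    current = sorted(feats, key=order.get)
    Xmat = np.asfortranarray(X[current].to_numpy(float))
    pos = {f: i for i, f in enumerate(current)}
    folds = _standardized_folds(Xmat, y, cv_folds, seed)
    live = np.ones(len(current), dtype=bool)

    def score_without(f: str | None) -> float:
        mask = live.copy()
        if f is not None:
            mask[pos[f]] = False
        return _subset_cv_mcc(folds, np.flatnonzero(mask), C, seed)

    path = [{"features": list(current), "score": score_without(None),
             "removed": None}]
    while len(current) > 1:
        best_score, victim = -np.inf, None
        for f in current:
            score = score_without(f)
            # on ties drop the feature latest in canonical order
            if score > best_score or (score == best_score and victim is not None
                                      and order[f] > order[victim]):
                best_score, victim = score, f
        live[pos[victim]] = False
        current = [g for g in current if g != victim]
        path.append({"features": list(current), "score": best_score, "removed": victim})
    best = max(p["score"] for p in path)
    # ties favor the smaller subset, i.e. the latest path entry at the max
    chosen = [p for p in path if p["score"] == best][-1]
    return list(chosen["features"]), path


# ---------------------------------------------------------------------------
# the classifier


class AcpClassifier:
    """Peptide activity classifier with applicability-domain scoring.

    Parameters
    ----------
    dataset : LabeledDataset
        Training peptides with binary labels (1 = active).
    estimator : {"svm", "rf"}
        Margin model (linear SVM, the primary model) or a 500-tree random
        forest baseline with sqrt(F) features per split.
    corr_threshold : float
        |Pearson r| above which correlated features are pruned.
    select_features : bool
        Run backward sequential feature elimination after pruning.
    C_grid : sequence of float
        Values of the SVM regularization parameter searched by
        cross-validation (CV MCC).
    cv_folds : int
        Folds for hyperparameter search and reported CV scores.
    sfe_cv_folds : int
        Folds used inside feature elimination (smaller for speed).
    seed : int
        Controls fold shuffling and k-means initialization.
    """

    def __init__(
        self,
        dataset: LabeledDataset,
        *,
        estimator: str = "svm",
        corr_threshold: float = 0.9,
        select_features: bool = True,
        C_grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0, 100.0),
        cv_folds: int = 10,
        sfe_cv_folds: int = 3,
        n_centroids: int = 3,
        seed: int = 42,
    ):
        if estimator not in ("svm", "rf"):
            raise ValueError("estimator must be 'svm' or 'rf'")
        if len(C_grid) == 0:
            raise ValueError("C_grid must be non-empty")
        if len(np.unique(dataset.labels)) < 2:
            raise ValueError("both classes must be present for training")
        self.dataset = dataset
        self.estimator = estimator
        self.corr_threshold = corr_threshold
        self.select_features = select_features
        self.C_grid = tuple(C_grid)
        self.cv_folds = cv_folds
        self.sfe_cv_folds = sfe_cv_folds
        self.n_centroids = n_centroids
        self.seed = seed

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "AcpClassifier":
        """Construct from a table with columns id, sequence, label."""
        return cls(LabeledDataset.from_dataframe(df), **kwargs)

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "AcpClassifierResults":
        X_full, y = self.dataset.X, self.dataset.labels
        retained = covariance_elimination(X_full, self.corr_threshold)
        mid_C = self.C_grid[len(self.C_grid) // 2]
        if self.select_features and len(retained) > 1:
            selected, path = sequential_feature_elimination(
                X_full, y, retained,
                cv_folds=self.sfe_cv_folds, seed=self.seed, C=mid_C,
            )
        else:
            selected, path = retained, []
        X = X_full[selected].to_numpy(float)

        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std == 0, 1.0, std)
        Xs = (X - mean) / std

        if self.estimator == "svm":
            cv_by_C = {
                C: _cv_scores(X, y, self.cv_folds, self.seed, C)
                for C in self.C_grid
            }
            mean_mcc = {C: np.mean([r.mcc for r in v]) for C, v in cv_by_C.items()}
            best_C = max(self.C_grid, key=lambda C: (mean_mcc[C], -C))
            clf = LinearSVC(C=best_C, dual=False)
            clf.fit(Xs, y)
            weights = pd.Series(clf.coef_.ravel(), index=selected)
            intercept = float(clf.intercept_[0])
            decision = Xs @ weights.to_numpy() + intercept
            calib = LogisticRegression(C=1e6)
            calib.fit(decision.reshape(-1, 1), y)
            calibration = {
                "kind": "platt",
                "a": float(calib.coef_[0, 0]),
                "b": float(calib.intercept_[0]),
            }
            cv_reports = cv_by_C[best_C]
            model_params = {"C": best_C}
            rf = None
        else:
            rf = RandomForestClassifier(
                n_estimators=500, max_features="sqrt", random_state=self.seed
            )
            skf = StratifiedKFold(self.cv_folds, shuffle=True, random_state=self.seed)
            cv_reports = []
            for tr, va in skf.split(Xs, y):
                m = RandomForestClassifier(
                    n_estimators=500, max_features="sqrt", random_state=self.seed
                ).fit(Xs[tr], y[tr])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cv_reports.append(
                        metrics_from_predictions(y[va], m.predict(Xs[va]), "cv")
                    )
            rf.fit(Xs, y)
            weights = None
            intercept = None
            calibration = {"kind": "forest"}
            best_C = None
            model_params = {"n_estimators": 500, "max_features": "sqrt"}

        km = KMeans(n_clusters=self.n_centroids, n_init=10, random_state=self.seed)
        km.fit(Xs)

        results = AcpClassifierResults(
            model=self,
            estimator=self.estimator,
            selected_features=list(selected),
            weights=weights,
            intercept=intercept,
            calibration=calibration,
            scaler_mean=mean,
            scaler_std=std,
            centroids=km.cluster_centers_.copy(),
            cv_reports=cv_reports,
            elimination_path=path,
            model_params=model_params,
            train_hash=self.dataset.content_hash(),
            seed=self.seed,
            _forest=rf,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results.train_report = metrics_from_predictions(
                y, (results.predict_proba_matrix(X) >= 0.5).astype(int), "train"
            )
        return results


@dataclass
class AcpClassifierResults:
    """Fitted classifier: decision function, calibration, and the
    applicability-domain centroids, plus training diagnostics."""

    model: AcpClassifier
    estimator: str
    selected_features: list
    weights: pd.Series | None
    intercept: float | None
    calibration: dict
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    centroids: np.ndarray
    cv_reports: list
    elimination_path: list
    model_params: dict
    train_hash: str
    seed: int
    _forest: object = None
    train_report: MetricsReport | None = None

    # -- core scoring on raw (unstandardized) selected-feature matrices -----

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.scaler_mean) / self.scaler_std

    def _select(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.selected_features if f not in X.columns]
        if missing:
            raise KeyError(f"descriptor table lacks selected features: {missing}")
        return X[self.selected_features].to_numpy(float)

    def decision_function_matrix(self, X: np.ndarray) -> np.ndarray:
        Xs = self._standardize(X)
        if self.estimator == "svm":
            return Xs @ self.weights.to_numpy() + self.intercept
        raise AttributeError("decision function is defined for the margin model only")

    def predict_proba_matrix(self, X: np.ndarray) -> np.ndarray:
        """Pseudo-probability P_ACP in [0, 1] for rows of a raw
        selected-feature matrix."""
        if self.estimator == "svm":
            d = self.decision_function_matrix(X)
            a, b = self.calibration["a"], self.calibration["b"]
            return 1.0 / (1.0 + np.exp(-(a * d + b)))
        return self._forest.predict_proba(self._standardize(X))[:, 1]

    def similarity_matrix(self, X: np.ndarray) -> np.ndarray:
        """Applicability-domain similarity S = 1 / (1 + mean Euclidean
        distance to the k-means centroids), in (0, 1]."""
        Xs = self._standardize(X)
        d = np.linalg.norm(Xs[:, None, :] - self.centroids[None, :, :], axis=2)
        return 1.0 / (1.0 + d.mean(axis=1))

    # -- peptide-facing API --------------------------------------------------

    def _descriptors_for(self, peptides: Iterable) -> tuple[list, pd.DataFrame]:
        peps = [as_peptide(p, id=f"lib{k}") for k, p in enumerate(peptides)]
        return peps, describe(peps)

    def predict_proba(self, peptides: Iterable) -> np.ndarray:
        _, X = self._descriptors_for(peptides)
        return self.predict_proba_matrix(self._select(X))

    def similarity(self, peptides: Iterable) -> np.ndarray:
        _, X = self._descriptors_for(peptides)
        return self.similarity_matrix(self._select(X))

    def screen(
        self, peptides: Iterable, sort_by: str = "phi_acp"
    ) -> pd.DataFrame:
        """Score a peptide library.

        Returns one row per peptide with columns id, sequence, P_ACP,
        sim_score, phi_acp, phi_neg, predicted_class (P_ACP >= 0.5), sorted
        descending by ``sort_by`` with lexicographic sequence tie-breaks.
        """
        peps, X = self._descriptors_for(peptides)
        if not peps:
            return pd.DataFrame(
                columns=["id", "sequence", "P_ACP", "sim_score",
                         "phi_acp", "phi_neg", "predicted_class"]
            )
        sel = self._select(X)
        p = self.predict_proba_matrix(sel)
        s = self.similarity_matrix(sel)
        phi_a, phi_n = phi_scores(p, s)
        out = pd.DataFrame({
            "id": [pep.id for pep in peps],
            "sequence": [pep.sequence for pep in peps],
            "P_ACP": p,
            "sim_score": s,
            "phi_acp": phi_a,
            "phi_neg": phi_n,
            "predicted_class": (p >= 0.5).astype(int),
        })
        out = out.sort_values(
            [sort_by, "sequence"], ascending=[False, True], kind="stable"
        )
        return out.reset_index(drop=True)

    def evaluate(self, dataset: LabeledDataset, context: str = "test") -> MetricsReport:
        pred = (self.predict_proba_matrix(self._select(dataset.X)) >= 0.5).astype(int)
        return metrics_from_predictions(dataset.labels, pred, context=context)

    @property
    def cv_report(self) -> MetricsReport:
        """Cross-validation metrics, mean over folds with per-metric std."""
        reps = self.cv_reports
        mean = lambda attr: float(np.mean([getattr(r, attr) for r in reps]))
        std = lambda attr: float(np.std([getattr(r, attr) for r in reps]))
        return MetricsReport(
            tp=sum(r.tp for r in reps), fp=sum(r.fp for r in reps),
            tn=sum(r.tn for r in reps), fn=sum(r.fn for r in reps),
            mcc=mean("mcc"), accuracy=mean("accuracy"),
            precision=mean("precision"), recall=mean("recall"),
            context=f"cv({len(reps)} folds)",
            std={k: std(k) for k in ("mcc", "accuracy", "precision", "recall")},
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        cv = self.cv_report
        tr = self.train_report
        lines = [
            "Peptide activity classifier",
            "=" * 60,
            f"estimator:          {self.estimator}",
            f"model params:       {self.model_params}",
            f"selected features:  {len(self.selected_features)}",
            f"training set hash:  {self.train_hash}",
            f"seed:               {self.seed}",
            "",
            f"{'metric':<12}{'CV mean':>10}{'CV std':>10}{'train':>10}",
            "-" * 42,
        ]
        for name in ("mcc", "accuracy", "precision", "recall"):
            lines.append(
                f"{name:<12}{getattr(cv, name):>10.3f}"
                f"{cv.std.get(name, float('nan')):>10.3f}"
                f"{getattr(tr, name):>10.3f}"
            )
        if self.weights is not None:
            lines += ["", "features ranked by |weight|:", "-" * 42]
            ranked = self.weights.reindex(
                self.weights.abs().sort_values(ascending=False).index
            )
            for name, w in ranked.items():
                lines.append(f"  {name:<16}{w:>+9.3f}")
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Serialize the fitted margin model to a single JSON document."""
        if self.estimator != "svm":
            raise NotImplementedError("JSON persistence covers the margin model only")
        doc = {
            "schema": "acpdesign-model/1",
            "estimator": self.estimator,
            "selected_features": self.selected_features,
            "weights": [float(w) for w in self.weights],
            "intercept": self.intercept,
            "calibration": self.calibration,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_std": self.scaler_std.tolist(),
            "centroids": self.centroids.tolist(),
            "model_params": self.model_params,
            "train_hash": self.train_hash,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def load(cls, path) -> "AcpClassifierResults":
        with open(path) as fh:
            doc = json.load(fh)
        for key in ("schema", "selected_features", "weights", "intercept",
                    "calibration", "scaler_mean", "scaler_std", "centroids"):
            if key not in doc:
                raise ModelSchemaError(f"model document missing field {key!r}")
        if doc["schema"] != "acpdesign-model/1":
            raise ModelSchemaError(f"unsupported model schema {doc['schema']!r}")
        return cls(
            model=None,
            estimator=doc["estimator"],
            selected_features=list(doc["selected_features"]),
            weights=pd.Series(doc["weights"], index=doc["selected_features"]),
            intercept=doc["intercept"],
            calibration=doc["calibration"],
            scaler_mean=np.asarray(doc["scaler_mean"], float),
            scaler_std=np.asarray(doc["scaler_std"], float),
            centroids=np.asarray(doc["centroids"], float),
            cv_reports=[],
            elimination_path=[],
            model_params=doc.get("model_params", {}),
            train_hash=doc.get("train_hash", ""),
            seed=doc.get("seed", 0),
        )


class ModelSchemaError(ValueError):
    """A persisted model document does not match the expected schema."""
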