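"""Bootstrap logistic-regression classification with optional PCA.

Cohorts here are small and cfDNA features are collinear, so performance is
estimated by bootstrapping: each iteration resamples the cohort with
replacement (optionally at the *patient* level so biological replicates
never straddle the train/test split), standardizes and optionally
PCA-reduces features on the training resample only, selects the ridge
penalty C by 10-fold cross-validation, fits a class-balanced logistic
regression, and scores the out-of-bag samples.  Per-sample probabilities
are aggregated as the median over iterations where the sample was
out-of-bag; a final model for external validation uses the most frequently
chosen C.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .features import FeatureMatrix

DEFAULT_C_GRID = (1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0)


@dataclass
class BootstrapConfig:
    n_iterations: int = 1000
    seed: int = 0
    pca_variance_target: Optional[float] = 0.80  # None disables PCA
    c_grid: Tuple[float, ...] = DEFAULT_C_GRID
    cv_folds: int = 10
    resample_unit: str = "sample"  # "sample" | "patient"
    first_timepoint_only: bool = False

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.pca_variance_target is not None and not (0 < self.pca_variance_target <= 1):
            raise ValueError("pca_variance_target must lie in (0, 1]")
        if not self.c_grid:
            raise ValueError("C grid must be non-empty")
        if self.resample_unit not in ("sample", "patient"):
            raise ValueError("resample_unit must be 'sample' or 'patient'")


@dataclass
class BootstrapResult:
    auc: np.ndarray  # per-iteration
    accuracy: np.ndarray
    chosen_c: np.ndarray
    oob_probabilities: Dict[str, List[float]]  # sample id -> per-OOB-iteration probs
    n_redrawn: int = 0

    @property
    def median_probability(self) -> pd.Series:
        return pd.Series(
            {s: float(np.median(p)) for s, p in self.oob_probabilities.items() if p}
        ).sort_index()

    def summary(self) -> Dict[str, float]:
        def ci(x):
            return (float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5)))

        return {
            "mean_auc": float(np.mean(self.auc)),
            "auc_ci": ci(self.auc),
            "mean_accuracy": float(np.mean(self.accuracy)),
            "accuracy_ci": ci(self.accuracy),
        }


@dataclass
class FinalModel:
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    pca_components: Optional[np.ndarray]
    pca_mean: Optional[np.ndarray]
    coefficients: np.ndarray
    intercept: float
    c: float
    classes: Tuple
    feature_names: Tuple[str, ...]

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of the positive (second) class for each row."""
        Z = (X[list(self.feature_names)].to_numpy(float) - self.scaler_mean) / self.scaler_scale
        if self.pca_components is not None:
            Z = (Z - self.pca_mean) @ self.pca_components.T
        logits = Z @ self.coefficients + self.intercept
        return 1.0 / (1.0 + np.exp(-logits))

    def to_json(self, path) -> None:
        payload = {
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "pca_components": None if self.pca_components is None else self.pca_components.tolist(),
            "pca_mean": None if self.pca_mean is None else self.pca_mean.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "c": self.c,
            "classes": list(self.classes),
            "feature_names": list(self.feature_names),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FinalModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            np.array(d["scaler_mean"]),
            np.array(d["scaler_scale"]),
            None if d["pca_components"] is None else np.array(d["pca_components"]),
            None if d["pca_mean"] is None else np.array(d["pca_mean"]),
            np.array(d["coefficients"]),
            float(d["intercept"]),
            float(d["c"]),
            tuple(d["classes"]),
            tuple(d["feature_names"]),
        )


# --------------------------------------------------------------------------
# Building blocks
# --------------------------------------------------------------------------
def standardize(train: np.ndarray, test: Optional[np.ndarray] = None):
    """Scale to mean 0, population SD 1; parameters fitted on train only.

    Zero-variance columns map to 0 in both train and test.
    """
    scaler = StandardScaler()
    Zt = scaler.fit_transform(train)
    Ztest = scaler.transform(test) if test is not None else None
    return Zt, Ztest, scaler


def bootstrap_split(
    index: Sequence, metadata: pd.DataFrame, resample_unit: str, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw a bootstrap training multiset and its out-of-bag test set.

    With ``resample_unit='patient'`` the draw is over distinct patients:
    every sample of a drawn patient enters the training set (with the
    patient's multiplicity), and the test set is all samples of undrawn
    patients — no patient can appear on both sides.
    """
    index = np.asarray(index, dtype=object)
    if resample_unit == "patient":
        patients = metadata["patient_id"].to_numpy()
        uniq = np.unique(patients)
        drawn = rng.choice(uniq, size=len(uniq), replace=True)
        counts = Counter(drawn)
        train = []
        for pat, mult in counts.items():
            members = index[patients == pat]
            for _ in range(mult):
                train.extend(members)
        test = index[~np.isin(patients, list(counts))]
        return np.array(train, dtype=object), test
    drawn = rng.integers(0, len(index), size=len(index))
    train = index[drawn]
    test = index[~np.isin(np.arange(len(index)), drawn)]
    return train, test


def pca_reduce(train: np.ndarray, variance_target: float, test: Optional[np.ndarray] = None):
    """Keep the smallest number of components explaining >= variance_target.

    The basis is fitted on the training data only and applied unchanged to
    the test data.
    """
    pca = PCA(random_state=0)
    scores = pca.fit_transform(train)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    n_comp = min(n_comp, scores.shape[1])
    test_scores = pca.transform(test)[:, :n_comp] if test is not None else None
    return scores[:, :n_comp], test_scores, pca, n_comp


def _select_c(
    X: np.ndarray, y: np.ndarray, c_grid: Sequence[float], cv_folds: int, rng: np.random.Generator
) -> float:
    """10-fold CV mean AUC per C; ties broken toward stronger regularization."""
    folds = min(cv_folds, max(2, int(np.bincount(y).min())))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31)))
    grid = sorted(c_grid)
    scores = np.zeros(len(grid))
    splits = list(skf.split(X, y))
    for j, c in enumerate(grid):
        aucs = []
        for tr, te in splits:
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                continue
            clf = LogisticRegression(
                C=c, class_weight="balanced", max_iter=2000
            )
            clf.fit(X[tr], y[tr])
            aucs.append(roc_auc_score(y[te], clf.predict_proba(X[te])[:, 1]))
        scores[j] = np.mean(aucs) if aucs else 0.0
    best = scores.max()
    # smallest C (strongest regularization) among near-ties
    return float(grid[int(np.flatnonzero(scores >= best - 1e-12)[0])])


def bootstrap_train_eval(fm: FeatureMatrix, config: BootstrapConfig) -> BootstrapResult:
    """Run the full bootstrap training / out-of-bag evaluation procedure.

    Deterministic given ``config.seed``: each iteration draws its RNG from
    an independent spawned substream so iteration i is reproducible in
    isolation.  Iterations whose training resample contains a single class
    are redrawn (and counted).
    """
    X = fm.X
    labels = fm.metadata["label"]
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    ymap = {c: i for i, c in enumerate(classes)}
    index = np.asarray(X.index, dtype=object)
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(config.n_iterations)
    aucs, accs, cs = [], [], []
    oob: Dict[str, List[float]] = {s: [] for s in X.index}
    n_redrawn = 0
    first_tp = None
    if config.first_timepoint_only and "timepoint" in fm.metadata:
        tp = fm.metadata["timepoint"]
        first_tp = set(
            fm.metadata.assign(_tp=tp).sort_values("_tp").groupby("patient_id").head(1).index
        )
    for it in range(config.n_iterations):
        rng = np.random.default_rng(streams[it])
        for _ in range(100):
            train_ids, test_ids = bootstrap_split(index, fm.metadata, config.resample_unit, rng)
            y_tr = np.array([ymap[labels[s]] for s in train_ids])
            y_te = np.array([ymap[labels[s]] for s in test_ids])
            if len(np.unique(y_tr)) == 2 and len(test_ids) and len(np.unique(y_te)) == 2:
                break
            n_redrawn += 1
        Xtr = X.loc[train_ids].to_numpy(float)
        Xte = X.loc[test_ids].to_numpy(float)
        Ztr, Zte, _ = standardize(Xtr, Xte)
        if config.pca_variance_target is not None:
            Ztr, Zte, _, _ = pca_reduce(Ztr, config.pca_variance_target, Zte)
        c = _select_c(Ztr, y_tr, config.c_grid, config.cv_folds, rng)
        clf = LogisticRegression(C=c, class_weight="balanced", max_iter=2000)
        clf.fit(Ztr, y_tr)
        prob = clf.predict_proba(Zte)[:, 1]
        for s, p in zip(test_ids, prob):
            oob[s].append(float(p))
        if first_tp is not None:
            keep = np.array([s in first_tp for s in test_ids])
            y_eval, p_eval = y_te[keep], prob[keep]
        else:
            y_eval, p_eval = y_te, prob
        if len(np.unique(y_eval)) == 2:
            aucs.append(roc_auc_score(y_eval, p_eval))
            accs.append(accuracy_score(y_eval, (p_eval >= 0.5).astype(int)))
        else:
            aucs.append(np.nan)
            accs.append(np.nan)
        cs.append(c)
    return BootstrapResult(
        np.array(aucs), np.array(accs), np.array(cs), oob, n_redrawn
    )


def finalize_model(fm: FeatureMatrix, result: BootstrapResult,
                   config: BootstrapConfig) -> FinalModel:
    """Fit one model on the full training cohort with the modal bootstrap C.

    Ties in the most frequent C are broken toward stronger regularization
    (smaller C).
    """
    counts = Counter(result.chosen_c.tolist())
    top = max(counts.values())
    c_star = min(c for c, n in counts.items() if n == top)
    labels = fm.metadata["label"]
    classes = tuple(np.unique(labels))
    y = np.array([classes.index(l) for l in labels])
    Xtr = fm.X.to_numpy(float)
    Ztr, _, scaler = standardize(Xtr)
    pca_comp = pca_mean = None
    if config.pca_variance_target is not None:
        Zred, _, pca, n_comp = pca_reduce(Ztr, config.pca_variance_target)
        pca_comp = pca.components_[:n_comp]
        pca_mean = pca.mean_
        Ztr = Zred
    clf = LogisticRegression(C=c_star, class_weight="balanced", max_iter=2000)
    clf.fit(Ztr, y)
    return FinalModel(
        scaler.mean_,
        scaler.scale_,
        pca_comp,
        pca_mean,
        clf.coef_[0],
        float(clf.intercept_[0]),
        c_star,
        classes,
        tuple(fm.X.columns),
    )


def finalize_and_apply(
    fm_train: FeatureMatrix,
    result: BootstrapResult,
    config: BootstrapConfig,
    fm_validation: FeatureMatrix,
    n_ci_bootstrap: int = 1000,
    seed: int = 0,
) -> Dict:
    """Apply the finalized model to an external validation cohort.

    Returns per-sample probabilities plus validation AUC/accuracy with
    bootstrap confidence intervals obtained by resampling the validation
    cohort with replacement.
    """
    model = finalize_model(fm_train, result, config)
    prob = model.predict_proba(fm_validation.X)
    y = np.array([model.classes.index(l) for l in fm_validation.metadata["label"]])
    auc = float(roc_auc_score(y, prob))
    acc = float(accuracy_score(y, (prob >= 0.5).astype(int)))
    rng = np.random.default_rng(seed)
    boot_auc, boot_acc = [], []
    n = len(y)
    for _ in range(n_ci_bootstrap):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(y[idx])) < 2:
            continue
        boot_auc.append(roc_auc_score(y[idx], prob[idx]))
        boot_acc.append(accuracy_score(y[idx], (prob[idx] >= 0.5).astype(int)))
    return {
        "model": model,
        "probabilities": pd.Series(prob, index=fm_validation.X.index),
        "auc": auc,
        "accuracy": acc,
        "auc_ci": (float(np.percentile(boot_auc, 2.5)), float(np.percentile(boot_auc, 97.5))),
        "accuracy_ci": (float(np.percentile(boot_acc, 2.5)), float(np.percentile(boot_acc, 97.5))),
    }
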