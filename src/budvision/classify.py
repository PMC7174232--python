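"""Shape-feature classification: standardization, PCA exploration, and the
grid-searched KNN / MLP / SVM protocol.

Two tasks are supported on the same feature table: flowering *stage*
(2 classes: fetal vs bloom) and product *type* (7 classes).  The protocol
is: stratified 9:1 train/test split, per-feature z-scoring fitted on
training data only (and refitted inside every cross-validation fold to
avoid leakage), exhaustive hyperparameter grid search by stratified 10-fold
cross-validation on the training set, refit of the winner on the full
training set, and a single evaluation on the held-out test set reported as
integer percent plus a full confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

FAMILIES = ("knn", "mlp", "svm")


@dataclass
class LabeledDataset:
    """Feature table (n x 14) or image stack with per-instance labels."""

    X: np.ndarray
    type_labels: np.ndarray
    stage_labels: np.ndarray
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.type_labels = np.asarray(self.type_labels)
        self.stage_labels = np.asarray(self.stage_labels)
        n = len(self.X)
        if len(self.type_labels) != n or len(self.stage_labels) != n:
            raise ValueError("labels must cover every instance")
        if np.issubdtype(self.X.dtype, np.floating) and not np.all(
            np.isfinite(self.X)
        ):
            raise ValueError("dataset contains NaN/inf")
        if self.ids is None:
            self.ids = np.arange(n)
        # each product type must map to exactly one flowering stage
        for t in np.unique(self.type_labels):
            stages = np.unique(self.stage_labels[self.type_labels == t])
            if len(stages) != 1:
                raise ValueError(f"type {t!r} maps to multiple stages {stages}")

    def labels_for(self, task: str) -> np.ndarray:
        if task == "stage":
            return self.stage_labels
        if task == "type":
            return self.type_labels
        raise ValueError("task must be 'stage' or 'type'")

    @property
    def n(self) -> int:
        return len(self.X)


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.9
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train fraction must be in (0, 1)")


def split_dataset(
    ds: LabeledDataset, spec: SplitSpec = SplitSpec()
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test split of instance indices.

    Stratification (on the type label, which determines the stage label as
    well) keeps per-class proportions within one instance.  Returns
    ``(train_idx, test_idx)``; deterministic per seed.  Raises if any class
    vanishes from the training side.
    """
    if ds.n < 20:
        raise ValueError("need at least 20 instances to split")
    idx = np.arange(ds.n)
    strat = ds.type_labels if spec.stratified else None
    tr, te = train_test_split(
        idx,
        train_size=spec.train_fraction,
        random_state=spec.seed,
        stratify=strat,
        shuffle=True,
    )
    missing = set(np.unique(ds.type_labels)) - set(ds.type_labels[tr])
    if missing:
        raise ValueError(f"classes absent from training split: {sorted(missing)}")
    return np.sort(tr), np.sort(te)


def zscore(
    train: np.ndarray, test: np.ndarray, feature_names: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Z-score both sets with mean/SD (population convention) estimated on
    the training rows only."""
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    sd = train.std(axis=0)
    zero = np.nonzero(sd == 0)[0]
    if len(zero):
        names = (
            [feature_names[i] for i in zero] if feature_names else list(zero)
        )
        raise ValueError(f"zero-variance training feature(s): {names}")
    scaler = StandardScaler().fit(train)
    return scaler.transform(train), scaler.transform(test)


def pca_explore(
    X: np.ndarray, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of a standardized feature matrix.

    Returns ``(scores, loadings, explained_variance_fractions)`` with
    ``loadings`` of shape ``(n_components, n_features)``.  Sign convention:
    the largest-magnitude element of each loading vector is positive.
    """
    X = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    loadings = pca.components_.copy()
    for i in range(len(loadings)):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] *= -1
            scores[:, i] *= -1
    return scores, loadings, pca.explained_variance_ratio_.copy()


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grids and the cross-validation fold count.

    Defaults: KNN neighbours k in 1..5 crossed with Minkowski power p in
    {2, 3} (10 candidates); single-hidden-layer MLP sizes 5, 7, ..., 29
    crossed with ReLU/tanh activation, Adam solver (26 candidates); RBF
    SVM with C = 2^0..2^10 and gamma = 2^-8..2^0 (99 candidates); 10-fold
    CV.  Tie-breaking is by canonical enumeration order: k ascending then p
    ascending; hidden size ascending with ReLU before tanh; C ascending
    then gamma ascending.
    """

    knn_k: tuple[int, ...] = (1, 2, 3, 4, 5)
    knn_p: tuple[int, ...] = (2, 3)
    mlp_hidden: tuple[int, ...] = tuple(range(5, 30, 2))
    mlp_activation: tuple[str, ...] = ("relu", "tanh")
    svm_C: tuple[float, ...] = tuple(2.0**i for i in range(0, 11))
    svm_gamma: tuple[float, ...] = tuple(2.0**i for i in range(-8, 1))
    folds: int = 10
    mlp_max_iter: int = 1000

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("need at least 2 CV folds")

    def candidates(self, family: str) -> list[dict]:
        """Canonically ordered flat list of parameter combinations."""
        if family == "knn":
            return [{"k": k, "p": p} for k in self.knn_k for p in self.knn_p]
        if family == "mlp":
            return [
                {"hidden": h, "activation": a}
                for h in self.mlp_hidden
                for a in self.mlp_activation
            ]
        if family == "svm":
            return [{"C": C, "gamma": g} for C in self.svm_C for g in self.svm_gamma]
        raise ValueError(f"unknown classifier family {family!r}")


def _make_estimator(family: str, params: dict, seed: int):
    if family == "knn":
        return KNeighborsClassifier(
            n_neighbors=params["k"], p=params["p"], metric="minkowski"
        )
    if family == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=(params["hidden"],),
            activation=params["activation"],
            solver="adam",
            max_iter=params.get("max_iter", 1000),
            random_state=seed,
        )
    if family == "svm":
        return SVC(kernel="rbf", C=params["C"], gamma=params["gamma"])
    raise ValueError(f"unknown classifier family {family!r}")


def _pipeline(family: str, params: dict, seed: int) -> Pipeline:
    # the scaler lives inside the pipeline so CV refits it per fold
    return Pipeline(
        [("scale", StandardScaler()), ("clf", _make_estimator(family, params, seed))]
    )


def grid_search_cv(
    family: str,
    X: np.ndarray,
    y: np.ndarray,
    grid: GridSpec = GridSpec(),
    seed: int = 0,
) -> tuple[dict, float]:
    """Exhaustive grid search by stratified k-fold CV on the training set.

    Standardization is refit within each fold.  Returns ``(best params,
    best mean CV accuracy in percent)``; ties resolve to the first
    candidate in canonical order.
    """
    cands = grid.candidates(family)
    cv = StratifiedKFold(n_splits=grid.folds, shuffle=True, random_state=seed)
    if family == "mlp":
        cands = [dict(c, max_iter=grid.mlp_max_iter) for c in cands]
    # one single-point grid per candidate preserves canonical order exactly
    param_grid = []
    for c in cands:
        pg = {}
        if family == "knn":
            pg = {"clf__n_neighbors": [c["k"]], "clf__p": [c["p"]]}
        elif family == "mlp":
            pg = {
                "clf__hidden_layer_sizes": [(c["hidden"],)],
                "clf__activation": [c["activation"]],
            }
        else:
            pg = {"clf__C": [c["C"]], "clf__gamma": [c["gamma"]]}
        param_grid.append(pg)
    gs = GridSearchCV(
        _pipeline(family, cands[0], seed),
        param_grid,
        cv=cv,
        scoring="accuracy",
        refit=False,
    )
    gs.fit(X, y)
    best = cands[int(gs.best_index_)]
    best = {k: v for k, v in best.items() if k != "max_iter"}
    return best, float(gs.best_score_) * 100.0


@dataclass
class ClassifierResult:
    """Outcome of one classifier family on one task."""

    family: str
    task: str
    best_params: dict
    cv_accuracy: float  # mean CV accuracy, percent
    train_accuracy: float
    test_accuracy: float
    confusion: np.ndarray  # counts, rows = true class
    class_names: list[str]

    @property
    def train_accuracy_pct(self) -> int:
        return int(round(self.train_accuracy))

    @property
    def test_accuracy_pct(self) -> int:
        return int(round(self.test_accuracy))

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "task": self.task,
            "best_params": self.best_params,
            "cv_accuracy": self.cv_accuracy,
            "train_accuracy": self.train_accuracy,
            "test_accuracy": self.test_accuracy,
            "train_accuracy_pct": self.train_accuracy_pct,
            "test_accuracy_pct": self.test_accuracy_pct,
            "confusion": self.confusion.tolist(),
            "class_names": list(self.class_names),
        }


def train_eval(
    family: str,
    params: dict,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    task: str = "type",
    seed: int = 0,
) -> ClassifierResult:
    """Refit the selected model on the full training set and evaluate."""
    pipe = _pipeline(family, params, seed)
    pipe.fit(X_train, y_train)
    classes = sorted(set(np.unique(y_train)) | set(np.unique(y_test)))
    cm = confusion_matrix(y_test, pipe.predict(X_test), labels=classes)
    return ClassifierResult(
        family=family,
        task=task,
        best_params=dict(params),
        cv_accuracy=float("nan"),
        train_accuracy=100.0 * pipe.score(X_train, y_train),
        test_accuracy=100.0 * pipe.score(X_test, y_test),
        confusion=cm,
        class_names=[str(c) for c in classes],
    )


def classify_task(
    ds: LabeledDataset,
    task: str,
    family: str,
    grid: GridSpec = GridSpec(),
    split: SplitSpec | None = None,
    seed: int = 0,
) -> ClassifierResult:
    """Full protocol for one family on one task: split, grid search, refit,
    test evaluation."""
    split = split or SplitSpec(seed=seed)
    tr, te = split_dataset(ds, split)
    y = ds.labels_for(task)
    params, cv_acc = grid_search_cv(family, ds.X[tr], y[tr], grid, seed=seed)
    res = train_eval(
        family, params, ds.X[tr], y[tr], ds.X[te], y[te], task=task, seed=seed
    )
    res.cv_accuracy = cv_acc
    return res
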