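"""Random-forest decision model for separating true from false-positive SVs.

Protocol: expert-review labels are adjudicated with an any-dissent-is-FP
rule; the labeled set is split 4:1 into training and testing partitions;
hyperparameters are tuned in two stages (a broad random search followed by a
refining grid search, both scored by mean 10-fold cross-validated accuracy);
the final forest is fit on the full training partition and applied with a
probability threshold (default 0.5).

The shipped default hyperparameters — n_estimators=186, max_features=sqrt,
max_depth=40, min_samples_split=6, min_samples_leaf=1, bootstrap=True — are
the final values of that two-stage search on the original panel cohort, and
are what :func:`train` uses unless told otherwise.
"""

from __future__ import annotations

import io as _io
import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .features import FeatureMatrix

BUNDLE_VERSION = "svjudge-rf-1"

LabelsLike = Union[Sequence[int], np.ndarray]


# ---------------------------------------------------------------------------
# Labels

@dataclass
class LabeledSV:
    id: str
    features: pd.Series
    label: str  # "TP" or "FP"
    reviewer_labels: Optional[List[str]] = None


def adjudicate_labels(reviewer_labels: Sequence[str]) -> str:
    """Consensus rule for expert review: any dissent demotes the call to FP.

    Requires at least two independent reviews.
    """
    if len(reviewer_labels) < 2:
        raise ValueError("insufficient review: need >= 2 reviewer labels")
    bad = set(reviewer_labels) - {"TP", "FP"}
    if bad:
        raise ValueError(f"unknown reviewer labels: {sorted(bad)}")
    return "TP" if all(l == "TP" for l in reviewer_labels) else "FP"


def split_dataset(
    data: Sequence,
    train_fraction: float = 0.8,
    seed: int = 0,
    labels: Optional[LabelsLike] = None,
    stratify: bool = True,
) -> Tuple[list, list]:
    """Random 4:1 (by default) split into training and testing partitions.

    Train size is ``floor(train_fraction * N)`` — 1131 items give 904/227.
    Stratified by label when labels are available, so both partitions keep
    the class mix; set ``stratify=False`` for a plain shuffle split.
    """
    n = len(data)
    if n < 5:
        raise ValueError("need at least 5 items to split 4:1")
    n_train = int(np.floor(train_fraction * n))
    rng = np.random.default_rng(seed)
    if labels is None and data and isinstance(data[0], LabeledSV):
        labels = [d.label for d in data]
    if labels is not None and stratify:
        labels = np.asarray(labels)
        train_idx: List[int] = []
        classes = sorted(set(labels.tolist()), key=str)
        # proportional allocation, largest-remainder rounding to hit n_train
        alloc = {}
        remainders = []
        for c in classes:
            idx = np.flatnonzero(labels == c)
            exact = train_fraction * len(idx)
            alloc[c] = int(np.floor(exact))
            remainders.append((exact - alloc[c], c))
        short = n_train - sum(alloc.values())
        for _, c in sorted(remainders, reverse=True)[:short]:
            alloc[c] += 1
        for c in classes:
            idx = rng.permutation(np.flatnonzero(labels == c))
            train_idx.extend(idx[: alloc[c]].tolist())
        train_set = set(train_idx)
    else:
        perm = rng.permutation(n)
        train_set = set(perm[:n_train].tolist())
    train = [data[i] for i in range(n) if i in train_set]
    test = [data[i] for i in range(n) if i not in train_set]
    if labels is not None:
        train_labels = {labels[i] for i in range(n) if i in train_set}
        if len(train_labels) < 2:
            warnings.warn("training partition contains a single class")
    return train, test


# ---------------------------------------------------------------------------
# Hyperparameters and search spaces

@dataclass(frozen=True)
class HyperParams:
    n_estimators: int = 186
    max_features: str = "sqrt"  # "auto" = all features, "sqrt"
    max_depth: Optional[int] = 40
    min_samples_split: int = 6
    min_samples_leaf: int = 1
    bootstrap: bool = True

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")

    def to_sklearn(self) -> Dict:
        # historical "auto" meant all features for classifiers of this era
        mf = None if self.max_features == "auto" else self.max_features
        return dict(
            n_estimators=self.n_estimators,
            max_features=mf,
            max_depth=self.max_depth,
            min_samples_split=self.min_samples_split,
            min_samples_leaf=self.min_samples_leaf,
            bootstrap=self.bootstrap,
        )


#: Best point of the broad random-search stage (shipped prior for the grid).
RANDOM_STAGE_BEST = HyperParams(
    n_estimators=200, max_features="sqrt", max_depth=40,
    min_samples_split=5, min_samples_leaf=1, bootstrap=True,
)

#: Final tuned values shipped as package defaults.
FINAL_HYPERPARAMS = HyperParams()

_PARAM_ORDER = (
    "n_estimators", "max_features", "max_depth",
    "min_samples_split", "min_samples_leaf", "bootstrap",
)


@dataclass
class SearchSpace:
    """Candidate lists per hyperparameter; enumeration order is the listed
    order (ties in CV score go to the earlier candidate)."""

    candidates: Dict[str, list]

    def __post_init__(self) -> None:
        missing = set(_PARAM_ORDER) - set(self.candidates)
        if missing:
            raise ValueError(f"search space missing parameters: {sorted(missing)}")
        if any(not v for v in self.candidates.values()):
            raise ValueError("empty candidate list in search space")

    @property
    def cardinality(self) -> int:
        out = 1
        for k in _PARAM_ORDER:
            out *= len(self.candidates[k])
        return out

    def point(self, flat_index: int) -> HyperParams:
        kw = {}
        for k in reversed(_PARAM_ORDER):
            opts = self.candidates[k]
            flat_index, j = divmod(flat_index, len(opts))
            kw[k] = opts[j]
        return HyperParams(**kw)

    def enumerate(self):
        for combo in itertools.product(*(self.candidates[k] for k in _PARAM_ORDER)):
            yield HyperParams(**dict(zip(_PARAM_ORDER, combo)))

    @classmethod
    def broad_random_stage(cls) -> "SearchSpace":
        """The wide first-stage space: n_estimators 50..3000 in 60 even
        steps, max_depth None plus 10..500 in 50 even steps, and the
        standard discrete options."""
        return cls(
            {
                "n_estimators": [int(v) for v in np.linspace(50, 3000, 60)],
                "max_features": ["auto", "sqrt"],
                "max_depth": [None] + [int(v) for v in np.linspace(10, 500, 50)],
                "min_samples_split": [2, 5, 10],
                "min_samples_leaf": [1, 2, 4, 8],
                "bootstrap": [True, False],
            }
        )

    @classmethod
    def refining_grid_stage(cls) -> "SearchSpace":
        """The second-stage grid around the random stage's best point:
        n_estimators 180..220 step 1, max_depth 30..50 step 1,
        min_samples_split 3..7, the rest pinned."""
        return cls(
            {
                "n_estimators": list(range(180, 221)),
                "max_features": ["sqrt"],
                "max_depth": list(range(30, 51)),
                "min_samples_split": [3, 4, 5, 6, 7],
                "min_samples_leaf": [1],
                "bootstrap": [True],
            }
        )


def _as_xy(X, y=None):
    if isinstance(X, FeatureMatrix):
        return X.values(), (None if y is None else np.asarray(y))
    return np.asarray(X, dtype=float), (None if y is None else np.asarray(y))


def cv_score(X, y, hp: HyperParams, folds: int = 10, seed: int = 0) -> float:
    """Mean accuracy over stratified k-fold CV for one candidate."""
    Xa, ya = _as_xy(X, y)
    clf = RandomForestClassifier(random_state=seed, n_jobs=1, **hp.to_sklearn())
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return float(cross_val_score(clf, Xa, ya, cv=skf, scoring="accuracy").mean())


def random_search(
    X,
    y,
    space: Optional[SearchSpace] = None,
    n_draws: int = 100,
    folds: int = 10,
    seed: int = 0,
) -> HyperParams:
    """Stage one: score ``n_draws`` distinct candidates drawn uniformly from
    the space; the best mean CV accuracy wins, ties going to the earlier
    draw.  Draws are capped at the space cardinality."""
    space = space or SearchSpace.broad_random_stage()
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    card = space.cardinality
    if n_draws >= card:
        candidates = list(space.enumerate())
    else:
        flat = rng.choice(card, size=n_draws, replace=False)
        candidates = [space.point(int(i)) for i in flat]
    best_hp, best_score = None, -np.inf
    for hp in candidates:
        score = cv_score(X, y, hp, folds=folds, seed=seed)
        if score > best_score:
            best_hp, best_score = hp, score
    return best_hp


def grid_search(
    X, y, space: Optional[SearchSpace] = None, folds: int = 10, seed: int = 0
) -> HyperParams:
    """Stage two: exhaustive evaluation of the grid; best mean CV accuracy
    wins, ties going to the first candidate in enumeration order."""
    space = space or SearchSpace.refining_grid_stage()
    best_hp, best_score = None, -np.inf
    for hp in space.enumerate():
        score = cv_score(X, y, hp, folds=folds, seed=seed)
        if score > best_score:
            best_hp, best_score = hp, score
    if best_hp is None:
        raise ValueError("empty grid")
    return best_hp


# ---------------------------------------------------------------------------
# Training, prediction, metrics

@dataclass
class ModelBundle:
    forest: RandomForestClassifier
    hyperparams: HyperParams
    schema_hash: str
    threshold: float = 0.5
    seed: int = 0
    version: str = BUNDLE_VERSION
    cv_scores: List[float] = field(default_factory=list)

    def save(self, path: str) -> None:
        """Single-file serialization: length-prefixed JSON header + pickled forest."""
        header = {
            "version": self.version,
            "schema_hash": self.schema_hash,
            "threshold": self.threshold,
            "seed": self.seed,
            "cv_scores": self.cv_scores,
            "hyperparams": asdict(self.hyperparams),
        }
        blob = json.dumps(header).encode()
        buf = _io.BytesIO()
        joblib.dump(self.forest, buf)
        with open(path, "wb") as fh:
            fh.write(len(blob).to_bytes(8, "little"))
            fh.write(blob)
            fh.write(buf.getvalue())

    @classmethod
    def load(cls, path: str) -> "ModelBundle":
        with open(path, "rb") as fh:
            n = int.from_bytes(fh.read(8), "little")
            header = json.loads(fh.read(n).decode())
            forest = joblib.load(_io.BytesIO(fh.read()))
        return cls(
            forest=forest,
            hyperparams=HyperParams(**header["hyperparams"]),
            schema_hash=header["schema_hash"],
            threshold=header["threshold"],
            seed=header["seed"],
            version=header["version"],
            cv_scores=header.get("cv_scores", []),
        )


def train(
    X,
    y,
    hp: HyperParams = FINAL_HYPERPARAMS,
    folds: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
    schema_hash: Optional[str] = None,
) -> ModelBundle:
    """Fit the forest on the full training set and record its k-fold CV scores.

    ``y``: 1 = true positive, 0 = false positive.  Both classes must be
    present.
    """
    Xa, ya = _as_xy(X, y)
    if len(np.unique(ya)) < 2:
        raise ValueError("degenerate labels: training set has a single class")
    if schema_hash is None:
        if not isinstance(X, FeatureMatrix):
            raise ValueError("schema_hash required when X is a bare array")
        schema_hash = X.schema_hash
    clf = RandomForestClassifier(random_state=seed, n_jobs=1, **hp.to_sklearn())
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = cross_val_score(clf, Xa, ya, cv=skf, scoring="accuracy")
    clf.fit(Xa, ya)
    return ModelBundle(
        forest=clf,
        hyperparams=hp,
        schema_hash=schema_hash,
        threshold=threshold,
        seed=seed,
        cv_scores=[float(s) for s in scores],
    )


def predict(bundle: ModelBundle, m: FeatureMatrix) -> pd.DataFrame:
    """Per-candidate TP probability and thresholded label.

    Refuses matrices built under a different feature schema.
    """
    if m.schema_hash != bundle.schema_hash:
        raise ValueError(
            f"feature schema mismatch: matrix {m.schema_hash} vs "
            f"model {bundle.schema_hash}"
        )
    if len(m) == 0:
        return pd.DataFrame(columns=["probability", "label"], index=m.data.index)
    classes = list(bundle.forest.classes_)
    proba = bundle.forest.predict_proba(m.values())[:, classes.index(1)]
    labels = np.where(proba >= bundle.threshold, "TP", "FP")
    return pd.DataFrame(
        {"probability": proba, "label": labels}, index=m.data.index
    )


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @classmethod
    def from_labels(cls, y_true, y_pred, positive=1) -> "ConfusionMatrix":
        yt = np.asarray(y_true)
        yp = np.asarray(y_pred)
        if yt.shape != yp.shape:
            raise ValueError("label vectors differ in length")
        return cls(
            TP=int(np.sum((yt == positive) & (yp == positive))),
            FP=int(np.sum((yt != positive) & (yp == positive))),
            TN=int(np.sum((yt != positive) & (yp != positive))),
            FN=int(np.sum((yt == positive) & (yp != positive))),
        )


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy, precision, recall and F1; ``None`` marks an undefined
    metric (zero denominator), which is reported as such, never as 0."""

    accuracy: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]

    def as_dict(self) -> Dict[str, Optional[float]]:
        return asdict(self)


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """The four confusion-matrix metrics:

    accuracy = (TP+TN)/(TP+FP+TN+FN), precision = TP/(TP+FP),
    recall = TP/(TP+FN), F1 = 2*precision*recall/(precision+recall).
    """
    if cm.total == 0:
        raise ValueError("all-zero confusion matrix")
    accuracy = (cm.TP + cm.TN) / cm.total
    precision = cm.TP / (cm.TP + cm.FP) if (cm.TP + cm.FP) > 0 else None
    recall = cm.TP / (cm.TP + cm.FN) if (cm.TP + cm.FN) > 0 else None
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall, f1=f1)
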