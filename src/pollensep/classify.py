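"""Cross-validated species classification and confusion-matrix indicators.

Separated grains, each reduced to the 33-value descriptor, are classified
into 12 species by one of three learner families — a multilayer
perceptron (MLP), a random-tree forest (RTF) and a naive-Bayes network
(BN) — evaluated under stratified s-fold cross validation (s = 2, 5, 10).
All quality indicators derive from the pooled actual×predicted confusion
matrix: per-class TPR (recall), PPV (precision), FPR (fallout) and the
F-measure, plus their support-weighted averages. The weighted TPR equals
trace/total identically.

Feature tables round-trip through CSV and the Weka ARFF dialect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .features import FEATURE_NAMES

__all__ = [
    "FeatureDataset",
    "MetricsReport",
    "LEARNERS",
    "make_learner",
    "stratified_folds",
    "cross_validate",
    "confusion_metrics",
    "write_arff",
    "read_arff",
    "write_csv",
    "read_csv",
]

LEARNERS = ("MLP", "RTF", "BN")

#: the 12 species of the reference airborne-pollen panel (Lagunera region)
DEFAULT_CLASS_NAMES = [
    "Acacia_farnesiana",
    "Medicago_sativa",
    "Chenopodium_murale",
    "Cynodon_dactylon",
    "Helianthus_ciliaris",
    "Morus_alba",
    "Carya_illinoensis",
    "Olea_europaea",
    "Prosopis_glandulosa",
    "Salix_spp",
    "Schinus_molle",
    "Sorghum_halepense",
]


@dataclass
class FeatureDataset:
    """An n×33 feature matrix with integer class labels 1..K."""

    matrix: np.ndarray
    labels: np.ndarray
    class_names: list[str] = field(default_factory=lambda: list(DEFAULT_CLASS_NAMES))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if len(self.labels) != len(self.matrix):
            raise ValueError("label/matrix length mismatch")
        if not np.isfinite(self.matrix).all():
            raise ValueError("feature matrix contains missing/non-finite values")
        k = len(self.class_names)
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > k):
            raise ValueError(f"labels must lie in 1..{k}")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class MetricsReport:
    """Per-class counts/rates plus support-weighted summary indicators."""

    classes: np.ndarray
    support: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    tpr: np.ndarray
    ppv: np.ndarray
    fpr: np.ndarray
    f1: np.ndarray
    weighted_tpr: float
    weighted_ppv: float
    weighted_fpr: float
    weighted_f1: float

    def to_dict(self) -> dict:
        return {
            "per_class": {
                int(c): {
                    "support": int(s), "TP": int(tp), "FP": int(fp),
                    "FN": int(fn), "TN": int(tn),
                    "TPR": float(tpr), "PPV": float(ppv),
                    "FPR": float(fpr), "F1": float(f1),
                }
                for c, s, tp, fp, fn, tn, tpr, ppv, fpr, f1 in zip(
                    self.classes, self.support, self.tp, self.fp, self.fn,
                    self.tn, self.tpr, self.ppv, self.fpr, self.f1
                )
            },
            "weighted": {
                "TPR": self.weighted_tpr, "PPV": self.weighted_ppv,
                "FPR": self.weighted_fpr, "F1": self.weighted_f1,
            },
        }


def make_learner(name: str, seed: int = 0):
    """Instantiate one of the three learner families.

    Hyperparameters emulate the common Weka defaults: the MLP has one
    hidden layer of ⌈(n_features + n_classes)/2⌉ = 23 units, SGD with
    learning rate 0.3 and momentum 0.2 for up to 500 epochs on
    standardized inputs; the RTF is 100 unpruned trees with √33 features
    per split and majority vote; the BN is naive Bayes with Gaussian
    class-conditionals.
    """
    name = name.upper()
    if name == "MLP":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(23,),
                solver="sgd",
                learning_rate_init=0.3,
                momentum=0.2,
                max_iter=500,
                random_state=seed,
            ),
        )
    if name == "RTF":
        return RandomForestClassifier(
            n_estimators=100, max_features="sqrt", random_state=seed
        )
    if name == "BN":
        return GaussianNB()
    raise ValueError(f"unknown learner {name!r}; expected one of {LEARNERS}")


def stratified_folds(labels: np.ndarray, s: int, seed: int = 0) -> list[np.ndarray]:
    """Deterministic stratified s-fold partition of the sample indices.

    Per-class counts across folds differ by at most one. A class with
    fewer than ``s`` members triggers a warning and a best-effort
    stratification (its members are spread over the first folds).
    """
    labels = np.asarray(labels)
    if s < 2:
        raise ValueError("s must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if (counts < s).any():
        warnings.warn(
            "some classes have fewer members than folds; stratification is best-effort",
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=s, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn repeats the small-class warning
        return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def cross_validate(
    ds: FeatureDataset, learner: str, s: int, seed: int = 0
) -> np.ndarray:
    """Pooled K×K confusion matrix (rows actual, columns predicted) from
    stratified s-fold cross validation; every sample is predicted exactly
    once, so the matrix total equals n_samples."""
    model_name = learner  # validated inside make_learner
    folds = stratified_folds(ds.labels, s, seed)
    k = ds.n_classes
    cm = np.zeros((k, k), dtype=np.int64)
    all_idx = np.arange(len(ds.labels))
    for fold in folds:
        train = np.setdiff1d(all_idx, fold)
        model = make_learner(model_name, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence chatter
            model.fit(ds.matrix[train], ds.labels[train])
        pred = model.predict(ds.matrix[fold])
        for a, p in zip(ds.labels[fold], pred):
            cm[a - 1, p - 1] += 1
    return cm


def confusion_metrics(cm: np.ndarray) -> MetricsReport:
    """All quality indicators of a K×K confusion matrix.

    Per class k: TP = cm[k,k], FN = row−TP, FP = col−TP,
    TN = total−TP−FN−FP; TPR = TP/(TP+FN), PPV = TP/(TP+FP),
    FPR = FP/(FP+TN), F1 = 2·PPV·TPR/(PPV+TPR) (0 when both are 0).
    Summary rows are support-weighted averages; undefined per-class rates
    (zero denominators) contribute 0.
    """
    cm = np.asarray(cm, dtype=np.int64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    total = cm.sum()
    if total == 0:
        raise ValueError("all-zero confusion matrix")
    k = cm.shape[0]
    tp = np.diag(cm).astype(float)
    support = cm.sum(axis=1).astype(float)
    colsum = cm.sum(axis=0).astype(float)
    fn = support - tp
    fp = colsum - tp
    tn = total - tp - fn - fp

    def safe_div(num, den):
        return np.divide(num, den, out=np.zeros_like(num, dtype=float),
                         where=den > 0)

    tpr = safe_div(tp, tp + fn)
    ppv = safe_div(tp, tp + fp)
    fpr = safe_div(fp, fp + tn)
    f1 = safe_div(2 * ppv * tpr, ppv + tpr)

    w = support / total
    return MetricsReport(
        classes=np.arange(1, k + 1),
        support=support.astype(int),
        tp=tp.astype(int), fp=fp.astype(int), fn=fn.astype(int),
        tn=tn.astype(int),
        tpr=tpr, ppv=ppv, fpr=fpr, f1=f1,
        weighted_tpr=float((w * tpr).sum()),
        weighted_ppv=float((w * ppv).sum()),
        weighted_fpr=float((w * fpr).sum()),
        weighted_f1=float((w * f1).sum()),
    )


# --------------------------------------------------------------------------
# ARFF / CSV feature-table I/O (Weka dialect: numeric attributes, nominal
# class last)

def write_arff(ds: FeatureDataset, path, relation: str = "pollen_features") -> None:
    names = FEATURE_NAMES if ds.matrix.shape[1] == 33 else [
        f"f{i}" for i in range(ds.matrix.shape[1])
    ]
    with open(path, "w") as fh:
        fh.write(f"@relation {relation}\n\n")
        for name in names:
            fh.write(f"@attribute {name} numeric\n")
        class_list = ",".join(str(c + 1) for c in range(ds.n_classes))
        fh.write(f"@attribute class {{{class_list}}}\n\n@data\n")
        for row, label in zip(ds.matrix, ds.labels):
            fh.write(",".join(repr(float(v)) for v in row) + f",{label}\n")


def read_arff(path) -> FeatureDataset:
    """Parse a Weka-dialect ARFF with numeric attributes and a final
    nominal class; missing values ('?') are rejected."""
    attributes: list[str] = []
    class_values: list[str] | None = None
    rows: list[list[float]] = []
    labels: list[int] = []
    in_data = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if not in_data:
                if low.startswith("@relation"):
                    continue
                if low.startswith("@attribute"):
                    rest = line.split(None, 1)[1]
                    if "{" in rest:
                        name = rest.split("{")[0].strip()
                        vals = rest[rest.index("{") + 1:rest.rindex("}")]
                        class_values = [v.strip() for v in vals.split(",")]
                        attributes.append(name)
                    else:
                        attributes.append(rest.split()[0])
                    continue
                if low.startswith("@data"):
                    in_data = True
                    continue
                raise ValueError(f"line {lineno}: unrecognized header line")
            # data section
            fields_ = [f.strip() for f in line.split(",")]
            if len(fields_) != len(attributes):
                raise ValueError(
                    f"line {lineno}: expected {len(attributes)} fields, got {len(fields_)}"
                )
            if "?" in fields_:
                raise ValueError(f"line {lineno}: missing value token '?'")
            try:
                rows.append([float(v) for v in fields_[:-1]])
                labels.append(int(fields_[-1]))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
    if class_values is None:
        raise ValueError("no nominal class attribute found")
    if not rows:
        raise ValueError("no samples in @data section")
    k = len(class_values)
    names = (
        list(DEFAULT_CLASS_NAMES) if k == 12 else [f"class_{v}" for v in class_values]
    )
    return FeatureDataset(np.asarray(rows), np.asarray(labels), class_names=names)


def write_csv(ds: FeatureDataset, path) -> None:
    names = FEATURE_NAMES if ds.matrix.shape[1] == 33 else [
        f"f{i}" for i in range(ds.matrix.shape[1])
    ]
    df = pd.DataFrame(ds.matrix, columns=names)
    df["class"] = ds.labels
    df.to_csv(path, index=False)


def read_csv(path) -> FeatureDataset:
    df = pd.read_csv(path)
    labels = df.pop("class").to_numpy()
    return FeatureDataset(df.to_numpy(), labels)
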