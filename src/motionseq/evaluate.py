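"""Cross-validated evaluation, rater concordance, and method comparison.

Accuracy is the fraction of correctly classified samples (reported as a
percentage), estimated by k-fold cross-validation with pooled confusion
matrices.  Rater agreement on the ordinal good/pass/fail scale uses
Kendall's tau-b (tie-corrected).  Competing methods' correct/incorrect
counts are compared with Pearson and likelihood-ratio chi-square
statistics on the methods x {correct, incorrect} contingency table.

``assess_pipeline`` ties the stages together: it compresses every motion
of a cohort to 15% keyframes, builds DTW features or quaternion sequences,
and cross-validates the requested method on either task ("recognize":
which of the 8 motions is this; "assess": good/pass/fail against the
teacher's grade, per motion class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from . import classify as _classify
from . import dtw as _dtw
from . import seqmodels as _seq
from .keyframe import CompressionConfig, extract_keyframes
from .motion_io import forward_kinematics, motion_to_quaternions, QuaternionSequence

__all__ = [
    "CVConfig",
    "ConfusionMatrix",
    "ChiSquareResult",
    "EvalReport",
    "GRADE_LEVELS",
    "accuracy",
    "cross_validate",
    "kendall_tau",
    "chi_square_correct_incorrect",
    "assess_pipeline",
    "FeatureClassifier",
    "HMMClassifier",
    "RNNClassifier",
]

GRADE_LEVELS = {"fail": 0, "pass": 1, "good": 2}

DTW_METHODS = ("dtw+knn", "dtw+svm", "dtw+nb", "dtw+logistic", "dtw+dtree", "dtw+bpnn", "dtw+rbfnn")
SEQ_METHODS = ("hmm", "lstm", "bilstm", "gru")


@dataclass
class CVConfig:
    n_folds: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class ConfusionMatrix:
    labels: list
    counts: np.ndarray  # rows = truth, columns = prediction

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        L = len(self.labels)
        if self.counts.shape != (L, L):
            raise ValueError("counts must be square over the label set")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_predictions(cls, truth, predicted, labels=None) -> "ConfusionMatrix":
        truth = np.asarray(truth)
        predicted = np.asarray(predicted)
        if labels is None:
            labels = sorted(set(truth.tolist()) | set(predicted.tolist()))
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(truth, predicted):
            counts[index[t], index[p]] += 1
        return cls(list(labels), counts)

    @property
    def accuracy(self) -> float:
        return 100.0 * np.trace(self.counts) / self.counts.sum()

    def to_dict(self) -> dict:
        return {"labels": [str(x) for x in self.labels], "counts": self.counts.tolist()}


@dataclass
class ChiSquareResult:
    pearson: float
    likelihood_ratio: float
    df: int
    expected: np.ndarray
    n_cells_lt5: int
    min_expected: float

    def to_dict(self) -> dict:
        return {
            "pearson": self.pearson,
            "likelihood_ratio": self.likelihood_ratio,
            "df": self.df,
            "expected": self.expected.tolist(),
            "n_cells_lt5": self.n_cells_lt5,
            "min_expected": self.min_expected,
        }


def accuracy(truth, predicted) -> float:
    """Percentage of correctly classified samples:
    100 x (number correct) / (overall sample size)."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.size == 0:
        raise ValueError("cannot compute accuracy of an empty label set")
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    return float(100.0 * np.mean(truth == predicted))


def kendall_tau(rater_a, rater_b) -> float:
    """Kendall's tau-b (tie-corrected) between two ordinal gradings.

    String grades are mapped fail < pass < good; numeric inputs are used
    as-is.  Undefined (error) when either rating is constant.
    """
    def encode(v):
        v = np.asarray(v)
        if v.dtype.kind in "US" or v.dtype == object:
            return np.array([GRADE_LEVELS[str(x)] for x in v], dtype=float)
        return v.astype(float)

    a, b = encode(rater_a), encode(rater_b)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("ratings must be non-empty and of equal length")
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        raise ValueError("tau-b is undefined for a constant rating")
    tau = stats.kendalltau(a, b, variant="b").statistic
    return float(tau)


def chi_square_correct_incorrect(counts) -> ChiSquareResult:
    """Pearson and likelihood-ratio chi-square on a methods x
    {correct, incorrect} table.

    E_ij = row_i x col_j / n; Pearson = sum (O-E)^2/E; likelihood ratio =
    2 sum O ln(O/E) with 0 ln 0 = 0.  No continuity correction.
    """
    O = np.asarray(counts, dtype=float)
    if O.ndim != 2 or O.shape[0] < 2 or O.shape[1] < 2:
        raise ValueError("counts must be a table with at least 2 rows and 2 columns")
    if np.any(O < 0) or not np.allclose(O, np.round(O)):
        raise ValueError("counts must be non-negative integers")
    rows = O.sum(axis=1)
    cols = O.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero marginal total")
    E = np.outer(rows, cols) / O.sum()
    pearson = float(((O - E) ** 2 / E).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(O > 0, O * np.log(O / E), 0.0)
    lr = float(2.0 * terms.sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    return ChiSquareResult(
        pearson=pearson,
        likelihood_ratio=lr,
        df=df,
        expected=E,
        n_cells_lt5=int((E < 5).sum()),
        min_expected=float(E.min()),
    )


# ---------------------------------------------------------------------------
# cross-validation


def _make_folds(y: np.ndarray, cv: CVConfig):
    n = len(y)
    if cv.n_folds > n:
        raise ValueError(f"n_folds={cv.n_folds} exceeds sample count {n}")
    if cv.stratified:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < cv.n_folds:
            raise ValueError(
                f"smallest class has {counts.min()} members, fewer than "
                f"{cv.n_folds} folds; reduce n_folds or set stratified=False"
            )
        splitter = StratifiedKFold(n_splits=cv.n_folds, shuffle=True, random_state=cv.seed)
        return list(splitter.split(np.zeros(n), y))
    splitter = KFold(n_splits=cv.n_folds, shuffle=True, random_state=cv.seed)
    return list(splitter.split(np.zeros(n)))


@dataclass
class CVResult:
    fold_accuracies: list[float]
    confusion: ConfusionMatrix
    pooled_accuracy: float


def cross_validate(make_estimator, X, y, cv: CVConfig) -> CVResult:
    """k-fold cross-validation of any fit/predict estimator.

    ``make_estimator`` is a zero-argument factory returning an object with
    ``fit(X_train, y_train)`` and ``predict(X_test)``; X may be a feature
    matrix or a list of sequences.  Every sample is tested exactly once
    and the pooled confusion matrix aggregates all test predictions.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation requires at least two classes")
    folds = _make_folds(y, cv)
    labels = sorted(np.unique(y).tolist())
    all_truth: list = []
    all_pred: list = []
    fold_acc: list[float] = []
    for train_idx, test_idx in folds:
        est = make_estimator()
        est.fit(_take(X, train_idx), y[train_idx])
        pred = np.asarray(est.predict(_take(X, test_idx)))
        fold_acc.append(accuracy(y[test_idx], pred))
        all_truth.extend(y[test_idx].tolist())
        all_pred.extend(pred.tolist())
    conf = ConfusionMatrix.from_predictions(all_truth, all_pred, labels)
    return CVResult(fold_acc, conf, accuracy(all_truth, all_pred))


def _take(X, idx):
    if isinstance(X, np.ndarray):
        return X[idx]
    return [X[i] for i in idx]


# ---------------------------------------------------------------------------
# estimator adapters


class FeatureClassifier:
    """classify-module classifier behind the fit/predict protocol."""

    def __init__(self, kind: str, **hyperparams):
        self.spec = _classify.ClassifierSpec(kind, hyperparams)
        self.model = None

    def fit(self, X, y):
        self.model = _classify.train(self.spec, np.asarray(X, dtype=float), y)
        return self

    def predict(self, X):
        return _classify.predict(self.model, np.asarray(X, dtype=float))


class HMMClassifier:
    """One discrete HMM per class over vector-quantised pose sequences.

    The codebook is fitted on the training fold only; classification is
    by highest forward log-likelihood.
    """

    def __init__(self, n_states: int = 5, n_symbols: int = 16, seed: int = 0,
                 max_iter: int = 20, topology: str = "left-to-right"):
        self.n_states = n_states
        self.n_symbols = n_symbols
        self.seed = seed
        self.max_iter = max_iter
        self.topology = topology
        self.codebook = None
        self.models: dict = {}

    def fit(self, sequences, y):
        y = np.asarray(y)
        self.codebook = _seq.fit_codebook(sequences, self.n_symbols, seed=self.seed)
        self.models = {}
        for label in np.unique(y):
            obs = [
                _seq.quantize(s, self.codebook)
                for s, lab in zip(sequences, y)
                if lab == label
            ]
            self.models[label] = _seq.hmm_fit(
                obs,
                self.n_states,
                self.codebook.n_symbols,
                seed=self.seed,
                max_iter=self.max_iter,
                topology=self.topology,
            )
        return self

    def predict(self, sequences):
        return np.array(
            [_seq.hmm_classify(self.models, _seq.quantize(s, self.codebook)) for s in sequences]
        )


class RNNClassifier:
    """LSTM / BiLSTM / GRU sequence classifier behind fit/predict."""

    def __init__(self, kind: str, hidden_dim: int = 32, epochs: int = 200,
                 learning_rate: float = 0.01, seed: int = 0):
        self.kind = kind
        self.hidden_dim = hidden_dim
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.seed = seed
        self.model = None

    def fit(self, sequences, y):
        arrays = [_seq._frames_of(s) for s in sequences]
        self.model = _seq.rnn_fit(
            self.kind,
            arrays,
            y,
            hidden_dim=self.hidden_dim,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            seed=self.seed,
        )
        return self

    def predict(self, sequences):
        arrays = [_seq._frames_of(s) for s in sequences]
        return _seq.rnn_predict(self.model, arrays)


def _make_method_estimator(method: str, params: dict):
    if method in DTW_METHODS:
        kind = method.split("+", 1)[1]
        return lambda: FeatureClassifier(kind, **params)
    if method == "hmm":
        return lambda: HMMClassifier(**params)
    if method in ("lstm", "bilstm", "gru"):
        return lambda: RNNClassifier(method, **params)
    raise ValueError(f"unknown method '{method}'")


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class EvalReport:
    task: str
    method: str
    mean_accuracy: float
    per_class: dict = field(default_factory=dict)
    confusions: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "method": self.method,
            "mean_accuracy": self.mean_accuracy,
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "confusions": {str(k): c.to_dict() for k, c in self.confusions.items()},
            "config": self.config,
        }


def _compress_cohort(cohort, c_rate: float, seed: int) -> dict[str, QuaternionSequence]:
    """Keyframe-compressed canonical quaternion sequences per subject."""
    compressed = {}
    cfg = CompressionConfig(c_rate=c_rate, seed=seed)
    for lm in cohort:
        quat = motion_to_quaternions(lm.motion)
        pos = forward_kinematics(lm.motion)
        kf = extract_keyframes(pos, cfg)
        compressed[lm.subject_id] = QuaternionSequence(quat.quat[kf.indices])
    return compressed


def build_task_datasets(
    cohort,
    method: str,
    task: str,
    c_rate: float = 0.15,
    dtw_config: _dtw.DTWConfig | None = None,
    seed: int = 0,
) -> list[tuple]:
    """Compress a cohort and assemble (key, X, y) datasets for a task.

    Recognition yields a single dataset over all students (labels =
    motion class); assessment yields one dataset per motion class
    (labels = grades).  DTW methods get feature matrices, sequence
    methods get the compressed quaternion sequences themselves.
    """
    if task not in ("recognize", "assess"):
        raise ValueError("task must be 'recognize' or 'assess'")
    if method not in DTW_METHODS + SEQ_METHODS:
        raise ValueError(f"unknown method '{method}'")
    dtw_config = dtw_config or _dtw.DTWConfig()
    teachers = [lm for lm in cohort if lm.role == "teacher"]
    students = [lm for lm in cohort if lm.role == "student"]
    if not teachers or not students:
        raise ValueError("cohort must contain teacher references and students")
    compressed = _compress_cohort(cohort, c_rate, seed)
    library: dict[int, list[QuaternionSequence]] = {}
    for lm in teachers:
        library.setdefault(lm.class_id, []).append(compressed[lm.subject_id])

    if task == "recognize":
        y = np.array([lm.class_id for lm in students])
        if method in DTW_METHODS:
            X = np.array(
                [
                    _dtw.build_recognition_features(compressed[lm.subject_id], library, dtw_config)
                    for lm in students
                ]
            )
        else:
            X = [compressed[lm.subject_id] for lm in students]
        return [("all", X, y)]

    datasets: list[tuple] = []
    for class_id in sorted(library):
        members = [lm for lm in students if lm.class_id == class_id]
        if not members:
            continue
        y = np.array([lm.grade for lm in members])
        if method in DTW_METHODS:
            X = np.array(
                [
                    _dtw.build_assessment_features(
                        compressed[lm.subject_id], library[class_id], dtw_config
                    )
                    for lm in members
                ]
            )
        else:
            X = [compressed[lm.subject_id] for lm in members]
        datasets.append((class_id, X, y))
    return datasets


def _method_params_with_seed(method: str, method_params: dict | None, seed: int) -> dict:
    params = dict(method_params or {})
    if method in SEQ_METHODS or method in ("dtw+bpnn", "dtw+rbfnn", "dtw+dtree"):
        params.setdefault("seed", seed)
    return params


def assess_pipeline(
    cohort,
    method: str,
    task: str,
    cv: CVConfig | None = None,
    c_rate: float = 0.15,
    dtw_config: _dtw.DTWConfig | None = None,
    seed: int = 0,
    method_params: dict | None = None,
) -> EvalReport:
    """Run one method end to end on a labelled cohort.

    task="recognize": cross-validate motion-class prediction over all
    students (DTW methods use the 8-dim distances to each class's teacher
    reference; hmm/lstm/bilstm/gru consume the compressed sequences).
    task="assess": per motion class, cross-validate good/pass/fail
    prediction (DTW methods use the 17 per-joint distances to the class's
    teacher repetitions); reports per-class and mean accuracy.
    """
    cv = cv or CVConfig()
    dtw_config = dtw_config or _dtw.DTWConfig()
    method_params = _method_params_with_seed(method, method_params, seed)
    datasets = build_task_datasets(cohort, method, task, c_rate, dtw_config, seed)
    cfg_echo = {
        "c_rate": c_rate,
        "window_fraction": dtw_config.window_fraction,
        "n_folds": cv.n_folds,
        "stratified": cv.stratified,
        "seed": seed,
        "method_params": {k: repr(v) for k, v in method_params.items()},
    }
    make_est = _make_method_estimator(method, method_params)

    per_class: dict = {}
    confusions: dict = {}
    for key, X, y in datasets:
        res = cross_validate(make_est, X, y, cv)
        per_class[key] = res.pooled_accuracy
        confusions[key] = res.confusion
    return EvalReport(
        task=task,
        method=method,
        mean_accuracy=float(np.mean(list(per_class.values()))),
        per_class={} if task == "recognize" else per_class,
        confusions=confusions,
        config=cfg_echo,
    )


def training_report(
    cohort,
    method: str,
    task: str,
    c_rate: float = 0.15,
    dtw_config: _dtw.DTWConfig | None = None,
    seed: int = 0,
    method_params: dict | None = None,
) -> tuple[EvalReport, dict]:
    """Fit a method on the full cohort and report training accuracy.

    Returns the report and the fitted estimators keyed like the datasets
    ("all" for recognition, class id for assessment).
    """
    dtw_config = dtw_config or _dtw.DTWConfig()
    method_params = _method_params_with_seed(method, method_params, seed)
    datasets = build_task_datasets(cohort, method, task, c_rate, dtw_config, seed)
    make_est = _make_method_estimator(method, method_params)
    per_class: dict = {}
    confusions: dict = {}
    estimators: dict = {}
    for key, X, y in datasets:
        est = make_est()
        est.fit(X, y)
        pred = np.asarray(est.predict(X))
        per_class[key] = accuracy(y, pred)
        confusions[key] = ConfusionMatrix.from_predictions(y, pred)
        estimators[key] = est
    report = EvalReport(
        task=task,
        method=method,
        mean_accuracy=float(np.mean(list(per_class.values()))),
        per_class={} if task == "recognize" else per_class,
        confusions=confusions,
        config={
            "c_rate": c_rate,
            "window_fraction": dtw_config.window_fraction,
            "seed": seed,
            "mode": "training",
            "method_params": {k: repr(v) for k, v in method_params.items()},
        },
    )
    return report, estimators
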