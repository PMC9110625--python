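"""Ada-AdaSVM: AdaBoost over RBF-SVM weak learners with kernel-scale annealing.

The learner is discrete AdaBoost.  Sample weights start at 1/(2a) for the a
positives and 1/(2b) for the b negatives.  Each round trains a weighted
RBF-SVM weak classifier h_t with kernel K(x, x') = exp(-||x - x'||^2 / (2 delta^2))
and soft-margin constant ``C`` (the regularization parameter), computes the
weighted training error

    xi_t = sum_i w_i [y_i != h_t(x_i)],

and, when the weak learner fails to beat chance (xi_t >= 1/2), anneals the
kernel scale delta by the factor delta_step and retries the round — a
narrower kernel restores weak learnability.  Retained rounds receive the
weight alpha_t = (1/2) ln(1/xi_t - 1) and the sample weights update as
w_i <- w_i exp(-alpha_t y_i h_t(x_i)) / N_t with N_t normalizing to 1.  The
strong classifier is H(x) = sgn(sum_t alpha_t h_t(x)).

Feature selection runs the same boosting loop with weak learners restricted
to a single feature per round (1-D RBF-SVM by default, or a decision stump);
the features picked by the earliest rounds carry the most discriminating
information.  Evaluation uses leave-one-subject-out cross-validation
(LOSOCV), so no subject contributes to both the training and the test fold.

The module follows the Model/Results convention: :class:`AdaSVM` is built
from data and ``fit()`` returns an :class:`AdaSVMResults` carrying the
ensemble, its diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .errors import (
    InvalidInputError,
    InvalidParameterError,
    NotFittedError,
)

__all__ = [
    "LabeledDataset",
    "AnnealSchedule",
    "WeakClassifier",
    "AdaSVM",
    "AdaSVMResults",
    "MulticlassAdaSVM",
    "MulticlassResults",
    "init_weights",
    "train_weak",
    "weighted_error",
    "alpha",
    "update_weights",
    "select_features",
    "losocv",
    "load_results",
]

_XI_EPS = 1e-10  # clipping guard for Eq. 19's singularities at 0 and 1/2


# ---------------------------------------------------------------------------
# data container

@dataclass
class LabeledDataset:
    """Binary training set with subject identifiers.

    Labels are +1/-1; ``a`` and ``b`` count positives and negatives and
    N = a + b.
    """

    X: np.ndarray
    y: np.ndarray
    subjects: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise InvalidInputError("X must be 2D (n_samples, n_features)")
        if self.y.shape != (self.X.shape[0],):
            raise InvalidInputError("y must have one label per sample")
        if not np.all(np.isin(self.y, (-1, 1))):
            raise InvalidInputError("labels must be +1/-1")
        if self.subjects is not None:
            self.subjects = np.asarray(self.subjects)
            if self.subjects.shape != (self.X.shape[0],):
                raise InvalidInputError("subjects must align with samples")

    @property
    def a(self) -> int:
        return int(np.sum(self.y == 1))

    @property
    def b(self) -> int:
        return int(np.sum(self.y == -1))

    @property
    def N(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class AnnealSchedule:
    """Kernel-scale annealing schedule: delta starts at delta_ini and is
    divided by delta_step whenever the weak learner fails, down to delta_min."""

    delta_ini: float = 10.0
    delta_min: float = 0.01
    delta_step: float = 2.0

    def __post_init__(self) -> None:
        if not (self.delta_ini > self.delta_min > 0):
            raise InvalidParameterError("require delta_ini > delta_min > 0")
        if not self.delta_step > 1:
            raise InvalidParameterError("delta_step must be > 1 (a division factor)")


# ---------------------------------------------------------------------------
# boosting primitives

def init_weights(data: LabeledDataset) -> np.ndarray:
    """Initial sample weights: 1/(2a) per positive, 1/(2b) per negative."""
    a, b = data.a, data.b
    if a < 1 or b < 1:
        raise InvalidInputError(f"need at least one sample per class (a={a}, b={b})")
    w = np.where(data.y == 1, 1.0 / (2 * a), 1.0 / (2 * b))
    return w


@dataclass
class WeakClassifier:
    """One round's weak learner: a weighted RBF-SVM (optionally 1-D)."""

    delta: float
    C: float
    svc: SVC | None = None
    feature_index: int | None = None  # set in feature-selection mode
    xi: float = float("nan")  # weighted training error
    # decision-stump alternative (selection mode): threshold/polarity on one feature
    stump: tuple[float, int] | None = None

    def _columns(self, X: np.ndarray) -> np.ndarray:
        if self.feature_index is None:
            return X
        return X[:, [self.feature_index]]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xc = self._columns(X)
        if self.stump is not None:
            thr, polarity = self.stump
            return np.where(Xc[:, 0] >= thr, polarity, -polarity).astype(int)
        if self.svc is None:
            raise NotFittedError("weak classifier has not been trained")
        return self.svc.predict(Xc).astype(int)


def train_weak(
    data: LabeledDataset,
    w: np.ndarray,
    delta: float = 0.1,
    C: float = 1.0,
    feature_index: int | None = None,
) -> WeakClassifier:
    """Train a weighted RBF-SVM weak learner.

    The kernel is K(x, x') = exp(-||x - x'||^2 / (2 delta^2)), i.e. sklearn's
    gamma = 1 / (2 delta^2); ``C`` is the soft-margin regularization.  The
    defaults (C, delta) = (1.0, 0.1) are the typical best operating point.
    """
    if delta <= 0 or C <= 0:
        raise InvalidParameterError("delta and C must be positive")
    clf = WeakClassifier(delta=delta, C=C, feature_index=feature_index)
    Xc = clf._columns(data.X)
    gamma = 1.0 / (2.0 * delta * delta)
    svc = SVC(C=C, kernel="rbf", gamma=gamma)
    # scale weights so their mean is 1: libsvm's effective C is C * weight
    svc.fit(Xc, data.y, sample_weight=w * data.N)
    clf.svc = svc
    clf.xi = weighted_error(clf, data, w)
    return clf


def _train_stump(data: LabeledDataset, w: np.ndarray, feature_index: int) -> WeakClassifier:
    """Best weighted decision stump on one feature (fast selection mode)."""
    x = data.X[:, feature_index]
    order = np.argsort(x, kind="stable")
    xs, ys, ws = x[order], data.y[order], w[order]
    # candidate thresholds: midpoints between distinct consecutive values
    # error of (x >= thr -> +1): sum w over (y=+1, x<thr) + (y=-1, x>=thr)
    pos_w = np.where(ys == 1, ws, 0.0)
    neg_w = np.where(ys == -1, ws, 0.0)
    cum_pos = np.concatenate([[0.0], np.cumsum(pos_w)])  # below-threshold positives
    total_neg = neg_w.sum()
    cum_neg = np.concatenate([[0.0], np.cumsum(neg_w)])
    # threshold before index i (i samples below): err+ = cum_pos[i] + (total_neg - cum_neg[i])
    err_plus = cum_pos + (total_neg - cum_neg)
    err_minus = 1.0 - err_plus  # flipping polarity
    i_plus = int(np.argmin(err_plus))
    i_minus = int(np.argmin(err_minus))
    if err_plus[i_plus] <= err_minus[i_minus]:
        i, polarity, err = i_plus, 1, err_plus[i_plus]
    else:
        i, polarity, err = i_minus, -1, err_minus[i_minus]
    if i == 0:
        thr = xs[0] - 1.0
    elif i == len(xs):
        thr = xs[-1] + 1.0
    else:
        thr = 0.5 * (xs[i - 1] + xs[i])
    clf = WeakClassifier(delta=float("nan"), C=float("nan"),
                         feature_index=feature_index, stump=(float(thr), polarity))
    clf.xi = float(err)
    return clf


def weighted_error(h: WeakClassifier, data: LabeledDataset, w: np.ndarray) -> float:
    """xi_t: total weight of misclassified samples."""
    pred = h.predict(data.X)
    return float(np.sum(w[pred != data.y]))


def alpha(xi: float) -> float:
    """Round weight alpha_t = (1/2) ln(1/xi_t - 1), with xi clipped to
    [eps, 1/2 - eps] to guard the singularities."""
    xi = float(np.clip(xi, _XI_EPS, 0.5 - _XI_EPS))
    return 0.5 * math.log(1.0 / xi - 1.0)


def update_weights(
    w: np.ndarray, alpha_t: float, h: WeakClassifier, data: LabeledDataset
) -> np.ndarray:
    """Multiplicative AdaBoost update, renormalized to sum to 1."""
    pred = h.predict(data.X)
    w_new = w * np.exp(-alpha_t * data.y * pred)
    return w_new / w_new.sum()


# ---------------------------------------------------------------------------
# model / results

@dataclass
class AdaSVM:
    """Ada-AdaSVM binary classifier model.

    Parameters
    ----------
    data : LabeledDataset
        Training samples with +1/-1 labels (and optional subject ids).
    schedule : AnnealSchedule
        delta annealing schedule for the RBF scale.
    C : float
        Soft-margin regularization of each weak SVM.
    T : int
        Maximum number of boosting rounds.
    on_chance_failure : str
        "retry" (default) re-runs the failed round with reduced delta and the
        current sample weights; "restart" resets the weights to their initial
        values before re-running.
    weak : str
        "svm" (default) or "stump"; stumps are only meaningful in
        feature-selection mode.
    """

    data: LabeledDataset
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    C: float = 1.0
    T: int = 10
    on_chance_failure: str = "retry"
    weak: str = "svm"
    selection_mode: bool = False  # restrict each round to a single best feature

    def __post_init__(self) -> None:
        if self.T < 1:
            raise InvalidParameterError("T must be >= 1")
        if self.on_chance_failure not in ("retry", "restart"):
            raise InvalidParameterError("on_chance_failure must be 'retry' or 'restart'")
        if self.weak not in ("svm", "stump"):
            raise InvalidParameterError("weak must be 'svm' or 'stump'")

    @classmethod
    def from_dataframe(cls, df, label_col: str = "label",
                       subject_col: str = "subject_id", **kwargs) -> "AdaSVM":
        feature_cols = [c for c in df.columns
                        if c not in (label_col, subject_col, "sample_id")]
        subjects = df[subject_col].to_numpy() if subject_col in df.columns else None
        data = LabeledDataset(df[feature_cols].to_numpy(dtype=float),
                              df[label_col].to_numpy(), subjects)
        return cls(data=data, **kwargs)

    def _round_learner(self, w: np.ndarray, delta: float) -> WeakClassifier:
        """One round's weak learner; in selection mode, the best single feature."""
        if not self.selection_mode:
            return train_weak(self.data, w, delta=delta, C=self.C)
        best: WeakClassifier | None = None
        for f in range(self.data.X.shape[1]):
            if self.weak == "stump":
                cand = _train_stump(self.data, w, f)
            else:
                cand = train_weak(self.data, w, delta=delta, C=self.C, feature_index=f)
            if best is None or cand.xi < best.xi:
                best = cand
        assert best is not None
        return best

    def fit(self, seed: int = 42) -> "AdaSVMResults":
        """Run the boosting loop and return the fitted results object.

        The loop ends after T retained rounds, when delta reaches delta_min
        without a weak learner beating chance (partial ensemble, warning
        flag), or early when a round separates the training set exactly.
        ``seed`` is recorded for provenance; the fit itself is deterministic
        given the data.
        """
        data = self.data
        w = init_weights(data)
        w0 = w.copy()
        delta = self.schedule.delta_ini
        rounds: list[tuple[float, WeakClassifier]] = []
        delta_log: list[float] = [delta]
        weight_sums: list[float] = [float(w.sum())]
        events: list[str] = []
        warning = False
        t = 0
        while t < self.T:
            h = self._round_learner(w, delta)
            xi = h.xi
            if xi >= 0.5 and self.weak != "stump":
                # weak learner no better than chance: anneal the kernel scale
                if delta / self.schedule.delta_step <= self.schedule.delta_min:
                    warning = True
                    events.append(f"round {t + 1}: delta floor reached (xi={xi:.3f})")
                    break
                delta = delta / self.schedule.delta_step
                delta_log.append(delta)
                events.append(f"round {t + 1}: xi={xi:.3f} >= 1/2, delta -> {delta:g}")
                if self.on_chance_failure == "restart":
                    w = w0.copy()
                continue
            a_t = alpha(xi)
            rounds.append((a_t, h))
            w = update_weights(w, a_t, h, data)
            weight_sums.append(float(w.sum()))
            t += 1
            if xi <= _XI_EPS:
                # training set separated exactly; further rounds are identical
                events.append(f"round {t}: xi ~ 0, stopping early")
                break
        if not rounds:
            warning = True
        return AdaSVMResults(
            model=self, rounds=rounds, delta_log=delta_log, events=events,
            warning=warning, seed=seed, final_weights=w, weight_sums=weight_sums,
        )


@dataclass
class AdaSVMResults:
    """Fitted Ada-AdaSVM ensemble with diagnostics."""

    model: AdaSVM
    rounds: list[tuple[float, WeakClassifier]]
    delta_log: list[float]
    events: list[str]
    warning: bool
    seed: int
    final_weights: np.ndarray
    weight_sums: list[float] = field(default_factory=list)  # after init + each round
    class_tag: object | None = None  # set by one-vs-rest training

    @property
    def alphas(self) -> np.ndarray:
        return np.array([a for a, _ in self.rounds])

    @property
    def xis(self) -> np.ndarray:
        return np.array([h.xi for _, h in self.rounds])

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)

    @property
    def selected_features(self) -> list[int]:
        """Distinct single-feature indices in selection order (selection mode)."""
        seen: list[int] = []
        for _, h in self.rounds:
            if h.feature_index is not None and h.feature_index not in seen:
                seen.append(h.feature_index)
        return seen

    def margin(self, X: np.ndarray) -> np.ndarray:
        """Weighted vote sum_t alpha_t h_t(x).

        A partial ensemble that retained no rounds (annealing hit the delta
        floor without a weak learner beating chance; ``warning`` is set)
        yields margin 0 everywhere — the empty vote — so prediction falls
        back to the sign convention rather than raising.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        m = np.zeros(X.shape[0])
        for a_t, h in self.rounds:
            m += a_t * h.predict(X)
        return m

    def predict(self, X: np.ndarray) -> np.ndarray:
        """H(x) = sgn(margin); the tie (margin 0) resolves to +1."""
        m = self.margin(X)
        return np.where(m >= 0, 1, -1)

    @property
    def training_error(self) -> float:
        return float(np.mean(self.predict(self.model.data.X) != self.model.data.y))

    @property
    def error_bound(self) -> float:
        """Classical AdaBoost bound prod_t 2 sqrt(xi_t (1 - xi_t))."""
        xis = self.xis
        return float(np.prod(2.0 * np.sqrt(xis * (1.0 - xis))))

    def summary(self) -> str:
        lines = [
            "Ada-AdaSVM results",
            "==================",
            f"rounds retained:     {self.n_rounds}",
            f"training error:      {self.training_error:.4f}",
            f"error bound:         {self.error_bound:.4g}",
            f"delta schedule:      {' -> '.join(f'{d:g}' for d in self.delta_log)}",
            f"warning flag:        {self.warning}",
            "",
            f"{'round':>5} {'alpha_t':>10} {'xi_t':>10} {'delta':>8} {'feature':>8}",
        ]
        for i, (a_t, h) in enumerate(self.rounds, start=1):
            feat = "-" if h.feature_index is None else str(h.feature_index)
            delta = "-" if math.isnan(h.delta) else f"{h.delta:g}"
            lines.append(f"{i:>5} {a_t:>10.4f} {h.xi:>10.4f} {delta:>8} {feat:>8}")
        for ev in self.events:
            lines.append(f"  [{ev}]")
        return "\n".join(lines)

    # -- serialization ----------------------------------------------------

    def save(self, path) -> None:
        """Write a JSON manifest plus a joblib blob of the SVM parameters."""
        import joblib

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "schedule": {
                "delta_ini": self.model.schedule.delta_ini,
                "delta_min": self.model.schedule.delta_min,
                "delta_step": self.model.schedule.delta_step,
            },
            "C": self.model.C,
            "T": self.model.T,
            "alphas": [a for a, _ in self.rounds],
            "xis": [h.xi for _, h in self.rounds],
            "delta_log": self.delta_log,
            "selected_features": self.selected_features,
            "warning": self.warning,
            "seed": self.seed,
            "class_tag": self.class_tag,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
        joblib.dump([(a, h) for a, h in self.rounds], path / "rounds.joblib")

    @property
    def is_fitted(self) -> bool:
        return bool(self.rounds)


def load_results(path, data: LabeledDataset | None = None) -> AdaSVMResults:
    """Load a saved ensemble; predictions round-trip bit-exactly."""
    import joblib

    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    rounds = joblib.load(path / "rounds.joblib")
    schedule = AnnealSchedule(**manifest["schedule"])
    if data is None:
        data = LabeledDataset(np.zeros((2, 1)), np.array([1, -1]))
    model = AdaSVM(data=data, schedule=schedule, C=manifest["C"], T=manifest["T"])
    return AdaSVMResults(
        model=model, rounds=rounds, delta_log=manifest["delta_log"],
        events=[], warning=manifest["warning"], seed=manifest["seed"],
        final_weights=np.empty(0), class_tag=manifest.get("class_tag"),
    )


# ---------------------------------------------------------------------------
# feature selection

def select_features(
    data: LabeledDataset,
    K: int,
    schedule: AnnealSchedule | None = None,
    seed: int = 42,
    C: float = 1.0,
    weak: str = "svm",
    max_rounds: int | None = None,
) -> list[int]:
    """AdaBoost-driven feature selection.

    Boosting runs with weak learners restricted to one feature per round, the
    round's feature chosen to minimize the weighted error; the first K
    distinct selected indices are returned (selection order).
    """
    d = data.X.shape[1]
    if not 1 <= K <= d:
        raise InvalidParameterError(f"K must be in [1, {d}], got {K}")
    T = max_rounds if max_rounds is not None else max(4 * K, 10)
    model = AdaSVM(
        data=data, schedule=schedule or AnnealSchedule(), C=C, T=T,
        weak=weak, selection_mode=True,
    )
    res = model.fit(seed=seed)
    selected = res.selected_features
    if len(selected) < K:
        # boosting converged on fewer distinct features: complete the list by
        # ascending initial weighted error of the remaining candidates
        w = init_weights(data)
        errs = []
        for f in range(d):
            if f in selected:
                continue
            h = (_train_stump(data, w, f) if weak == "stump"
                 else train_weak(data, w, delta=(schedule or AnnealSchedule()).delta_ini,
                                 C=C, feature_index=f))
            errs.append((h.xi, f))
        for _, f in sorted(errs):
            selected.append(f)
            if len(selected) == K:
                break
    return selected[:K]


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class CVReport:
    """Cross-validation outcome: per-fold errors and overall accuracy."""

    fold_ids: list
    fold_errors: list[float]
    fold_sizes: list[int]
    y_true: np.ndarray
    y_pred: np.ndarray

    @property
    def error(self) -> float:
        return float(np.mean(self.y_pred != self.y_true))

    @property
    def accuracy(self) -> float:
        return 1.0 - self.error

    def confusion_matrix(self, classes=None) -> np.ndarray:
        cls = np.asarray(classes) if classes is not None else np.unique(self.y_true)
        M = np.zeros((len(cls), len(cls)), dtype=int)
        for yt, yp in zip(self.y_true, self.y_pred):
            M[np.searchsorted(cls, yt), np.searchsorted(cls, yp)] += 1
        return M


def losocv(
    X: np.ndarray,
    y: np.ndarray,
    subjects: np.ndarray,
    fit_predict,
) -> CVReport:
    """Leave-one-subject-out cross-validation.

    ``fit_predict(X_train, y_train, subj_train, X_test) -> predictions`` is
    called once per held-out subject; no subject appears in both partitions.
    The reported error is the misclassification rate — for +/-1 labels it
    equals (1/(2n)) sum_i |f(x_i) - y_i| since each mistake contributes 2.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    if len(uniq) < 2:
        raise InvalidInputError("LOSOCV needs at least 2 distinct subjects")
    fold_ids, fold_errors, fold_sizes = [], [], []
    y_true_all, y_pred_all = [], []
    for s in uniq:
        test = subjects == s
        train = ~test
        pred = np.asarray(fit_predict(X[train], y[train], subjects[train], X[test]))
        fold_ids.append(s)
        fold_errors.append(float(np.mean(pred != y[test])))
        fold_sizes.append(int(test.sum()))
        y_true_all.append(y[test])
        y_pred_all.append(pred)
    return CVReport(
        fold_ids=fold_ids, fold_errors=fold_errors, fold_sizes=fold_sizes,
        y_true=np.concatenate(y_true_all), y_pred=np.concatenate(y_pred_all),
    )


# ---------------------------------------------------------------------------
# multiclass (one-vs-rest)

@dataclass
class MulticlassAdaSVM:
    """One-vs-rest wrapper: one Ada-AdaSVM ensemble per class."""

    X: np.ndarray
    y: np.ndarray
    subjects: np.ndarray | None = None
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    C: float = 1.0
    T: int = 10
    classes: tuple | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        present = np.unique(self.y)
        if self.classes is None:
            self.classes = tuple(present.tolist())
        else:
            missing = [c for c in self.classes if c not in present]
            if missing:
                raise InvalidInputError(f"classes absent from training data: {missing}")
        if len(self.classes) < 2:
            raise InvalidInputError("need at least 2 classes")

    def fit(self, seed: int = 42) -> "MulticlassResults":
        per_class = {}
        for c in self.classes:
            y_bin = np.where(self.y == c, 1, -1)
            data = LabeledDataset(self.X, y_bin, self.subjects)
            res = AdaSVM(data=data, schedule=self.schedule, C=self.C, T=self.T).fit(seed=seed)
            res.class_tag = c
            per_class[c] = res
        return MulticlassResults(model=self, per_class=per_class)


@dataclass
class MulticlassResults:
    """Per-class ensembles; prediction is the class of maximal margin
    (ties resolve to the lowest class index)."""

    model: MulticlassAdaSVM
    per_class: dict

    def margins(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack(
            [self.per_class[c].margin(X) for c in self.model.classes]
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        m = self.margins(X)
        idx = np.argmax(m, axis=1)  # first maximum: lowest class index on ties
        return np.asarray(self.model.classes)[idx]

    def summary(self) -> str:
        lines = ["One-vs-rest Ada-AdaSVM", "======================"]
        for c in self.model.classes:
            r = self.per_class[c]
            lines.append(
                f"class {c}: rounds={r.n_rounds} train_err={r.training_error:.4f} "
                f"bound={r.error_bound:.4g} warning={r.warning}"
            )
        return "\n".join(lines)
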