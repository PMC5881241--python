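"""Single-trial classification: features, weighted linear margins, nested CV.

Features are raw time-domain samples of the xDAWN pseudo-channels inside an
inclusive window (early 400–600 ms, late 600–800 ms; six samples per
pseudo-channel at 25 Hz).  Classification uses a soft-margin linear SVM with
per-class penalties (weight 2 on the under-represented class of the 1:12
pairs), the regularisation constant chosen by grid search over
10⁰ … 10⁻⁶ with an inner stratified 5-fold, inside a repeated stratified
10-fold outer loop.  The spatial filter and feature normalisation are refit
on every training split — nothing fitted ever sees test trials.

The headline metric is balanced accuracy (bACC): the arithmetic mean of
per-class true-positive rates, robust to the 1:12 class imbalance
(chance level 0.5 binary, 1/3 multiclass).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .preprocess import EpochSet
from .xdawn import SpatialFilter, apply_filter, fit_xdawn_epochs

#: Inclusive feature windows in ms (six samples each at 25 Hz).
FEATURE_WINDOWS_MS = {"early": (400.0, 600.0), "late": (600.0, 800.0)}

#: Regularisation grid for the margin penalty C.
C_GRID = tuple(10.0 ** (-i) for i in range(7))

#: Pseudo-channel counts per electrode set.
N_COMPONENTS = {"all62": 8, "std62": 8, "parietal6": 1, "parietal2": 1}

#: Which class the spatial filter treats as evoked, per detection pair.
EVOKED_CLASS = {
    ("target", "standard"): "target",
    ("deviant", "standard"): "deviant",
    ("target", "deviant"): "target",
}


# ---------------------------------------------------------------------------
# Features and normalisation
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Trials × features with per-feature provenance (pseudo-channel, time)."""

    X: np.ndarray
    labels: np.ndarray
    provenance: tuple  # of (channel_label, time_ms)
    window: str

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features must be finite")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def select(self, mask) -> "FeatureMatrix":
        mask = np.asarray(mask)
        return FeatureMatrix(self.X[mask], self.labels[mask], self.provenance, self.window)


def extract_features(pseudo_epochs: EpochSet, window) -> FeatureMatrix:
    """Flatten (channel-major) the samples whose time lies in the window."""
    if isinstance(window, str):
        name, (lo, hi) = window, FEATURE_WINDOWS_MS[window]
    else:
        lo, hi = window
        name = f"{lo:g}-{hi:g}"
    times = pseudo_epochs.times_ms()
    sel = (times >= lo - 1e-9) & (times <= hi + 1e-9)
    if not sel.any():
        raise ValueError(f"window [{lo}, {hi}] ms has no samples in the epoch")
    data = pseudo_epochs.data[:, :, sel]
    n_trials = data.shape[0]
    provenance = tuple(
        (ch, float(t))
        for ch in pseudo_epochs.channel_labels
        for t in times[sel]
    )
    return FeatureMatrix(
        X=data.reshape(n_trials, -1),
        labels=pseudo_epochs.labels,
        provenance=provenance,
        window=name,
    )


@dataclass
class NormStats:
    """Per-feature location/scale learned on training trials only."""

    mean: np.ndarray
    scale: np.ndarray


def fit_norm(train: FeatureMatrix | np.ndarray) -> NormStats:
    X = train.X if isinstance(train, FeatureMatrix) else np.asarray(train, float)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)  # degenerate features pass through
    return NormStats(mean=mean, scale=scale)


def apply_norm(features, stats: NormStats) -> np.ndarray:
    X = features.X if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    return (X - stats.mean) / stats.scale


# ---------------------------------------------------------------------------
# Weighted linear classifier
# ---------------------------------------------------------------------------


@dataclass
class ClassifierModel:
    """Linear decision function sign(w·x + b) with training provenance."""

    weights: np.ndarray
    bias: float
    classes: tuple  # (negative, positive) in decision-function convention
    C: float
    weight_map: dict
    provenance: dict = field(default_factory=dict)

    def decision_function(self, X) -> np.ndarray:
        return np.asarray(X, float) @ self.weights + self.bias

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return np.where(scores > 0, self.classes[1], self.classes[0]).astype(object)


def default_weight_map(labels, pair=None) -> dict:
    """Penalty weight 2 on the under-represented class of an imbalanced pair.

    Near-balanced pairs (count ratio below 2, e.g. targets vs deviants) get
    equal weights, matching the rationale of penalising errors on the rare
    class of the 1:12 pairings.
    """
    labels = np.asarray(labels, dtype=object)
    classes = tuple(pair) if pair is not None else tuple(sorted(set(labels)))
    counts = {c: int(np.sum(labels == c)) for c in classes}
    lo = min(classes, key=counts.get)
    hi = max(classes, key=counts.get)
    if lo != hi and counts[lo] > 0 and counts[hi] / counts[lo] >= 2.0:
        return {lo: 2.0, hi: 1.0}
    return {c: 1.0 for c in classes}


def train_weighted_linear(
    X, labels, C: float, weight_map: dict | None = None, provenance: dict | None = None
) -> ClassifierModel:
    """Train a soft-margin linear SVM with per-class penalties C × weight."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if weight_map is None:
        weight_map = default_weight_map(labels)
    svc = LinearSVC(
        C=C,
        class_weight={c: weight_map.get(c, 1.0) for c in classes},
        dual=False,
        tol=1e-5,
        max_iter=20000,
    )
    svc.fit(X, labels.astype(str))
    return ClassifierModel(
        weights=svc.coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        classes=tuple(svc.classes_),  # decision > 0 → classes_[1]
        C=C,
        weight_map=dict(weight_map),
        provenance=provenance or {},
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def confusion_counts(y_true, y_pred, classes) -> np.ndarray:
    classes = list(classes)
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    index = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm


def metrics(confusion: np.ndarray, classes) -> dict:
    """TPR per class, TNR (binary), bACC and ACC from a confusion table.

    ``confusion[i, j]`` counts true class ``classes[i]`` predicted as
    ``classes[j]``.  For binary problems ``classes[0]`` is the positive
    class: bACC = (TPR + TNR)/2.  For multiclass, bACC is the mean of the
    per-class TPRs; ACC is total correct over total.
    """
    confusion = np.asarray(confusion, dtype=float)
    classes = list(classes)
    row_sums = confusion.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = np.where(row_sums > 0, np.diag(confusion) / row_sums, np.nan)
    out = {
        "classes": tuple(classes),
        "tpr": {c: float(tpr[i]) for i, c in enumerate(classes)},
        "bacc": float(np.nanmean(tpr)),
        "acc": float(np.trace(confusion) / confusion.sum()),
    }
    if len(classes) == 2:
        out["tnr"] = float(tpr[1])  # negative class recall
    return out


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------


def grid_search_C(
    X,
    labels,
    weight_map: dict | None = None,
    grid=C_GRID,
    k: int = 5,
    seed: int = 0,
    classes=None,
) -> float:
    """Pick C maximising mean inner-fold bACC; ties go to the larger C."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    cls = list(classes) if classes is not None else sorted(set(labels))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31))
    folds = list(skf.split(X, labels.astype(str)))
    best_c, best_score = None, -np.inf
    for C in sorted(grid, reverse=True):  # larger C first → wins ties
        scores = []
        for tr, te in folds:
            model = train_weighted_linear(X[tr], labels[tr], C, weight_map)
            cm = confusion_counts(labels[te], model.predict(X[te]), cls)
            scores.append(metrics(cm, cls)["bacc"])
        score = float(np.mean(scores))
        if score > best_score + 1e-12:
            best_c, best_score = C, score
    return best_c


# ---------------------------------------------------------------------------
# One-vs-one multiclass voting
# ---------------------------------------------------------------------------


def ovo_predict(models: list[ClassifierModel], X, classes) -> np.ndarray:
    """Vote across pairwise models; ties resolved by summed signed scores,
    then lexicographic class order."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    classes = sorted(classes)
    votes = {c: np.zeros(n) for c in classes}
    confid = {c: np.zeros(n) for c in classes}
    for model in models:
        neg, pos = model.classes
        scores = model.decision_function(X)
        win_pos = scores > 0
        votes[pos] += win_pos
        votes[neg] += ~win_pos
        confid[pos] += scores
        confid[neg] -= scores
    vote_mat = np.stack([votes[c] for c in classes], axis=1)
    conf_mat = np.stack([confid[c] for c in classes], axis=1)
    pred = np.empty(n, dtype=object)
    for i in range(n):
        leaders = np.flatnonzero(vote_mat[i] == vote_mat[i].max())
        if len(leaders) > 1:
            best = conf_mat[i, leaders].max()
            leaders = leaders[np.flatnonzero(conf_mat[i, leaders] == best)]
        pred[i] = classes[leaders[0]]  # lexicographic final tie-break
    return pred


# ---------------------------------------------------------------------------
# Evaluation harness
# ---------------------------------------------------------------------------


@dataclass
class EvalResult:
    """Aggregated cross-validated (or transfer) performance."""

    kind: str  # "binary" | "multiclass"
    classes: tuple
    tpr: dict
    bacc: float
    acc: float
    per_repetition: list
    config: dict
    seed: int
    tnr: float | None = None
    bacc_sem: float | None = None

    def summary_row(self) -> dict:
        row = {**self.config, "bacc": self.bacc, "acc": self.acc}
        if self.bacc_sem is not None:
            row["bacc_sem"] = self.bacc_sem
        for c, v in self.tpr.items():
            row[f"tpr_{c}"] = v
        return row


def _fit_pipeline_on_train(
    train: EpochSet,
    evoked_class: str,
    window,
    n_components: int,
    ridge: float,
    seed: int,
):
    """Training-split-only fits: spatial filter → features → normalisation."""
    filt = fit_xdawn_epochs(train, evoked_class, n_components, ridge)
    feats = extract_features(apply_filter(train, filt), window)
    stats = fit_norm(feats)
    return filt, feats, stats


def _features_for(epochs: EpochSet, filt: SpatialFilter, window, stats: NormStats):
    feats = extract_features(apply_filter(epochs, filt), window)
    return apply_norm(feats, stats), feats.labels


def _train_binary(X, labels, pair, seed):
    weight_map = default_weight_map(labels, pair)
    C = grid_search_C(X, labels, weight_map, classes=list(pair), seed=seed)
    model = train_weighted_linear(X, labels, C, weight_map)
    return model, C


def _train_ovo(X, labels, classes, seed):
    models, cs = [], {}
    pairs = [(a, b) for i, a in enumerate(classes) for b in classes[i + 1 :]]
    for a, b in pairs:
        mask = (labels == a) | (labels == b)
        model, C = _train_binary(X[mask], labels[mask], (a, b), seed)
        models.append(model)
        cs[f"{a}|{b}"] = C
    return models, cs


def crossvalidate(
    epochs: EpochSet,
    *,
    pair: tuple | None = None,
    window="early",
    n_components: int = 8,
    n_repetitions: int = 10,
    n_folds: int = 10,
    ridge: float = 1e-6,
    seed: int = 0,
    config: dict | None = None,
) -> EvalResult:
    """Repeated stratified k-fold with nested model selection.

    ``pair=(positive, negative)`` runs a binary detection problem;
    ``pair=None`` runs the three-class one-vs-one problem.  Per outer
    training split the spatial filter, the feature normalisation, and C (via
    inner 5-fold grid search) are all refit; predictions are pooled per
    repetition and metrics averaged over repetitions.
    """
    if pair is not None:
        mask = np.isin(epochs.labels, list(pair))
        epochs = epochs.select_trials(mask)
        classes = list(pair)
        evoked = EVOKED_CLASS.get(tuple(pair), pair[0])
    else:
        classes = sorted(set(epochs.labels))
        evoked = "target" if "target" in classes else classes[0]
    labels = epochs.labels
    counts = {c: int(np.sum(labels == c)) for c in classes}
    if min(counts.values()) < n_folds:
        raise ValueError(f"too few trials to stratify {n_folds} folds: {counts}")

    rep_metrics = []
    for rep in range(n_repetitions):
        rep_seed = (int(seed) * 1009 + rep) % (2**31)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rep_seed)
        y_true, y_pred = [], []
        for fold, (tr, te) in enumerate(skf.split(epochs.data[:, 0, 0], labels.astype(str))):
            train = epochs.select_trials(tr)
            test = epochs.select_trials(te)
            filt, feats, stats = _fit_pipeline_on_train(
                train, evoked, window, n_components, ridge, rep_seed
            )
            Xtr = apply_norm(feats, stats)
            Xte, yte = _features_for(test, filt, window, stats)
            if pair is not None:
                model, _ = _train_binary(Xtr, feats.labels, pair, rep_seed + fold)
                pred = model.predict(Xte)
            else:
                models, _ = _train_ovo(Xtr, feats.labels, classes, rep_seed + fold)
                pred = ovo_predict(models, Xte, classes)
            y_true.extend(yte)
            y_pred.extend(pred)
        cm = confusion_counts(y_true, y_pred, classes)
        rep_metrics.append(metrics(cm, classes))

    baccs = [m["bacc"] for m in rep_metrics]
    result = EvalResult(
        kind="binary" if pair is not None else "multiclass",
        classes=tuple(classes),
        tpr={c: float(np.mean([m["tpr"][c] for m in rep_metrics])) for c in classes},
        bacc=float(np.mean(baccs)),
        acc=float(np.mean([m["acc"] for m in rep_metrics])),
        per_repetition=rep_metrics,
        config=dict(config or {}, pair="/".join(classes) if pair else "multiclass",
                    window=str(window), n_components=n_components,
                    scheme=f"{n_repetitions}x{n_folds}"),
        seed=int(seed),
        tnr=float(np.mean([m.get("tnr", np.nan) for m in rep_metrics]))
        if pair is not None else None,
        bacc_sem=float(np.std(baccs, ddof=1) / np.sqrt(len(baccs)))
        if len(baccs) > 1 else None,
    )
    return result


def multiclass_ovo(epochs: EpochSet, **kwargs) -> EvalResult:
    """Three-class evaluation (standard/target/deviant) via one-vs-one voting."""
    return crossvalidate(epochs, pair=None, **kwargs)


def transfer_evaluate(
    train_epochs: EpochSet,
    test_epochs: EpochSet,
    *,
    pair: tuple,
    window="early",
    n_components: int = 8,
    ridge: float = 1e-6,
    seed: int = 0,
    config: dict | None = None,
) -> EvalResult:
    """Train on one condition, evaluate on the other.

    The spatial filter, normalisation statistics, C (inner 5-fold on the
    source) and the model are all fitted on the source condition only.
    """
    mask_tr = np.isin(train_epochs.labels, list(pair))
    mask_te = np.isin(test_epochs.labels, list(pair))
    train = train_epochs.select_trials(mask_tr)
    test = test_epochs.select_trials(mask_te)
    evoked = EVOKED_CLASS.get(tuple(pair), pair[0])
    filt, feats, stats = _fit_pipeline_on_train(
        train, evoked, window, n_components, ridge, seed
    )
    Xtr = apply_norm(feats, stats)
    model, C = _train_binary(Xtr, feats.labels, pair, seed)
    Xte, yte = _features_for(test, filt, window, stats)
    cm = confusion_counts(yte, model.predict(Xte), list(pair))
    m = metrics(cm, list(pair))
    direction = f"{train.condition or 'source'}->{test.condition or 'test'}"
    return EvalResult(
        kind="binary",
        classes=tuple(pair),
        tpr=m["tpr"],
        bacc=m["bacc"],
        acc=m["acc"],
        per_repetition=[m],
        config=dict(config or {}, pair="/".join(pair), window=str(window),
                    n_components=n_components, transfer=direction, C=C),
        seed=int(seed),
        tnr=m.get("tnr"),
    )
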