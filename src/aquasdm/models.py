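"""Base species-distribution learners and their evaluation.

Four presence/background classifiers — random forest (RF), a MaxEnt
equivalent, support vector machine (SVM) and boosted regression trees
(BRT) — fitted on stratified 75/25 bootstrap splits of a training
table built from presences plus randomly placed pseudo-absences.
Skill is measured with AUC (rank statistic, ties counted half) and TSS
(max of sensitivity + specificity - 1 over an exhaustive threshold
scan).

The MaxEnt equivalent is an L1-regularized logistic regression of
presence vs background on a MaxEnt-style feature expansion (linear,
quadratic, pairwise products and hinge features at training
quantiles), with the regularization path chosen by held-out
likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .grids import VARIABLES, PredictorStack

ALGORITHMS = ("RF", "MaxEnt", "SVM", "BRT")


@dataclass(frozen=True)
class PseudoAbsenceDesign:
    """How background (pseudo-absence) points are drawn.

    ``one_to_one`` (RF/SVM/BRT) draws as many background cells as
    presences; ``fixed_10000`` (MaxEnt) draws 10,000, capped at the
    number of eligible marine cells.  Presence cells are excluded.
    """

    n_sets: int = 10
    n_fixed: int = 10_000
    seed: int = 0


def sample_pseudo_absences(
    domain: PredictorStack,
    presence_cells: Sequence[int],
    n_background: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, bool]:
    """Uniform sample (without replacement) of eligible background cells.

    Eligible cells are marine, non-missing and not presence cells.
    Returns the background rows (predictor values, label 0, cell index)
    and a flag indicating the request was capped by cell exhaustion.
    Raises if no eligible cell remains or the request exceeds the pool
    while not capped (the 1:1 contract).
    """
    frame = domain.to_frame()
    eligible = frame.index.difference(pd.Index(np.unique(presence_cells)))
    if len(eligible) == 0:
        raise ValueError("no eligible background cells")
    capped = n_background > len(eligible)
    n_draw = min(n_background, len(eligible))
    if capped:
        warnings.warn(
            f"background request of {n_background} capped at {len(eligible)} eligible cells",
            stacklevel=2,
        )
    chosen = rng.choice(eligible.to_numpy(), size=n_draw, replace=False)
    rows = frame.loc[chosen].copy()
    rows["label"] = 0
    rows["cell"] = chosen
    return rows.reset_index(drop=True), capped


def build_training_table(presence_rows: pd.DataFrame, background_rows: pd.DataFrame) -> pd.DataFrame:
    """Stack labelled presence (1) and background (0) rows."""
    pres = presence_rows.copy()
    pres["label"] = 1
    cols = list(VARIABLES) + ["label"] + (["cell"] if "cell" in pres.columns else [])
    table = pd.concat([pres[cols], background_rows[cols]], ignore_index=True)
    if table[list(VARIABLES)].isna().any().any():
        raise ValueError("training table contains missing predictor values")
    return table


def bootstrap_splits(
    table: pd.DataFrame,
    train_frac: float = 0.75,
    n_replicates: int = 10,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Repeated stratified random train/test splits (75/25 by default).

    Each replicate partitions the rows: the test set is the exact
    complement of the train set, stratified by class so both classes
    appear on both sides.  Train sizes per class are allocated by
    largest remainder so the overall fraction is met exactly where
    possible.
    """
    y = table["label"].to_numpy()
    n = len(table)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training table must contain both classes")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 rows to stratify")
    if n < 8:
        raise ValueError("need at least 8 rows")
    total_train = int(round(n * train_frac))
    raw = counts * train_frac
    base = np.floor(raw).astype(int)
    rem = raw - base
    short = total_train - base.sum()
    order = np.argsort(-rem)
    alloc = base.copy()
    for k in range(int(short)):
        alloc[order[k % len(order)]] += 1
    alloc = np.clip(alloc, 1, counts - 1)  # both classes on both sides

    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_replicates):
        train_idx: list[np.ndarray] = []
        for cls, n_train in zip(classes, alloc):
            members = np.flatnonzero(y == cls)
            perm = rng.permutation(members)
            train_idx.append(perm[:n_train])
        tr = np.sort(np.concatenate(train_idx))
        te = np.setdiff1d(np.arange(n), tr)
        splits.append((tr, te))
    return splits


# ---------------------------------------------------------------------------
# models


def _hinge_knots(x: np.ndarray, n_knots: int = 10) -> np.ndarray:
    qs = np.linspace(0, 1, n_knots + 2)[1:-1]
    return np.quantile(x, qs)


class MaxentFeatures:
    """MaxEnt-style basis: linear, quadratic, products, hinge features."""

    def __init__(self, n_knots: int = 10):
        self.n_knots = n_knots
        self.knots_: dict[int, np.ndarray] = {}

    def fit(self, X: np.ndarray) -> "MaxentFeatures":
        self.knots_ = {j: _hinge_knots(X[:, j], self.n_knots) for j in range(X.shape[1])}
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        p = X.shape[1]
        feats = [X, X**2]
        feats += [(X[:, i] * X[:, j])[:, None] for i in range(p) for j in range(i + 1, p)]
        for j in range(p):
            feats.append(np.maximum(0.0, X[:, j][:, None] - self.knots_[j][None, :]))
        return np.hstack(feats)


class _MaxentModel:
    def __init__(self, seed: int):
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_MaxentModel":
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        self.features_ = MaxentFeatures().fit(Xs)
        F = self.features_.transform(Xs)
        self.fscaler_ = StandardScaler().fit(F)
        self.clf_ = LogisticRegressionCV(
            Cs=np.logspace(-3, 2, 8),
            cv=4,
            penalty="l1",
            solver="liblinear",
            scoring="neg_log_loss",
            max_iter=2000,
            random_state=self.seed,
        ).fit(self.fscaler_.transform(F), y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        F = self.features_.transform(self.scaler_.transform(X))
        return self.clf_.predict_proba(self.fscaler_.transform(F))


@dataclass(eq=False)
class SdmModel:
    """A fitted base learner with its training reference statistics."""

    algorithm: str
    estimator: object
    variables: tuple[str, ...]
    train_mean: pd.Series
    train_min: pd.Series
    train_max: pd.Series

    def predict_probability(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Occurrence probability in [0, 1] for rows of predictor values."""
        if isinstance(X, pd.DataFrame):
            X = X[list(self.variables)].to_numpy(dtype=float)
        proba = self.estimator.predict_proba(np.asarray(X, dtype=float))
        return proba[:, 1]

    def predict_stack(self, stack: PredictorStack) -> np.ndarray:
        """Probability field on a grid; NaN propagates from the stack."""
        frame = stack.to_frame()
        out = np.full(stack.spec.shape, np.nan)
        if len(frame):
            out.ravel()[frame.index.to_numpy()] = self.predict_probability(frame)
        return out


def fit_model(algorithm: str, train: pd.DataFrame, seed: int = 0) -> SdmModel:
    """Fit one of the four base learners on a labelled training table.

    RF: 500-tree classification forest (probability = vote fraction).
    SVM: RBF kernel with probability calibration.  BRT: gradient
    boosting with logistic loss, learning rate 0.01, up to 3000 trees
    with internal-holdout early stopping.  MaxEnt: penalized logistic
    regression on the MaxEnt feature expansion.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    X = train[list(VARIABLES)].to_numpy(dtype=float)
    y = train["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")
    if np.isnan(X).any():
        raise ValueError("training data contain missing predictors")
    const = X.std(axis=0) == 0
    if const.any():
        names = [v for v, c in zip(VARIABLES, const) if c]
        warnings.warn(f"constant predictor(s) retained: {names}", stacklevel=2)

    if algorithm == "RF":
        est = RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1).fit(X, y)
    elif algorithm == "SVM":
        est = Pipeline(
            [
                ("scale", StandardScaler()),
                ("svc", SVC(kernel="rbf", probability=True, random_state=seed)),
            ]
        ).fit(X, y)
    elif algorithm == "BRT":
        est = GradientBoostingClassifier(
            learning_rate=0.01,
            n_estimators=3000,
            validation_fraction=0.2,
            n_iter_no_change=10,
            random_state=seed,
        ).fit(X, y)
    else:  # MaxEnt
        est = _MaxentModel(seed=seed).fit(X, y)

    df = train[list(VARIABLES)]
    return SdmModel(
        algorithm=algorithm,
        estimator=est,
        variables=tuple(VARIABLES),
        train_mean=df.mean(),
        train_min=df.min(),
        train_max=df.max(),
    )


# ---------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class Evaluation:
    """Held-out skill of one fitted replicate."""

    auc: float
    tss: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    n_pos: int
    n_neg: int


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U, ties counted half."""
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def tss_scan(y_true: np.ndarray, scores: np.ndarray) -> tuple[float, float, tuple[int, int, int, int]]:
    """Max TSS over all candidate thresholds (the distinct scores).

    A point is predicted present when score >= threshold.  Returns
    (tss, threshold, (tp, fp, tn, fn)) at the maximizing threshold
    (the lowest such threshold on ties).
    """
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("TSS needs both classes")
    thresholds = np.unique(s)
    # counts of scores >= t, vectorized over thresholds
    order = np.argsort(s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    cum_pos = np.cumsum(y_sorted)  # positives with score <= s_sorted[k]
    cum_all = np.arange(1, len(s) + 1)
    pos_below = np.searchsorted(s_sorted, thresholds, side="left")
    tp = n_pos - np.where(pos_below > 0, cum_pos[pos_below - 1], 0)
    pred_pos = len(s) - pos_below
    fp = pred_pos - tp
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    tss = sens + spec - 1.0
    k = int(np.argmin(-tss))  # first (lowest-threshold) maximum
    best = float(thresholds[k])
    tp_k, fp_k = int(tp[k]), int(fp[k])
    return float(tss[k]), best, (tp_k, fp_k, n_neg - fp_k, n_pos - tp_k)


def evaluate(model: SdmModel, test: pd.DataFrame) -> Evaluation:
    """Held-out AUC/TSS for a fitted model on labelled test rows."""
    y = test["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("test set contains a single class")
    scores = model.predict_probability(test)
    return evaluate_scores(y, scores)


def evaluate_scores(y_true: np.ndarray, scores: np.ndarray) -> Evaluation:
    auc = auc_score(y_true, scores)
    tss, thr, (tp, fp, tn, fn) = tss_scan(y_true, scores)
    y = np.asarray(y_true, dtype=int)
    return Evaluation(
        auc=auc,
        tss=tss,
        threshold=thr,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        n_pos=int((y == 1).sum()),
        n_neg=int((y == 0).sum()),
    )


# ---------------------------------------------------------------------------
# interpretation


def variable_importance(
    model: SdmModel,
    data: pd.DataFrame,
    n_permutations: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Permutation importance: 1 - cor(intact, permuted) per variable.

    Importance_j is the mean over permutations of one minus the Pearson
    correlation between the model's predictions on the intact data and
    on data with column j permuted, clipped to [0, 1].  Constant
    predictions yield zero importance with a warning.
    """
    if len(data) < 20:
        raise ValueError("need at least 20 rows for permutation importance")
    rng = np.random.default_rng(seed)
    X = data[list(model.variables)].to_numpy(dtype=float)
    base = model.predict_probability(X)
    if np.std(base) == 0:
        warnings.warn("constant predictions: importance is 0 for all variables", stacklevel=2)
        return pd.Series(0.0, index=list(model.variables))
    out = {}
    for j, name in enumerate(model.variables):
        vals = []
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            pred = model.predict_probability(Xp)
            if np.std(pred) == 0:
                vals.append(1.0)
                continue
            r = np.corrcoef(base, pred)[0, 1]
            vals.append(1.0 - r)
        out[name] = float(np.clip(np.mean(vals), 0.0, 1.0))
    return pd.Series(out, name="importance")


def response_curve(
    model: SdmModel,
    variable: str,
    n_points: int = 100,
    reference: pd.Series | None = None,
) -> pd.DataFrame:
    """Predicted probability as one variable sweeps its training range.

    Other variables are held at the training mean (or a supplied
    reference).  Returns a frame with columns ``value`` and
    ``probability``.
    """
    if variable not in model.variables:
        raise ValueError(f"unknown variable {variable!r}")
    ref = model.train_mean if reference is None else reference
    grid = np.linspace(model.train_min[variable], model.train_max[variable], n_points)
    X = pd.DataFrame({v: np.full(n_points, float(ref[v])) for v in model.variables})
    X[variable] = grid
    prob = model.predict_probability(X)
    return pd.DataFrame({"value": grid, "probability": prob})
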