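"""Supervised classification of behavioral state from metabolic profiles.

Observation units are mouse-hour epochs (hours 1-6) with region-tagged
analyte columns from both regions.  Two classifiers are provided:

* PLSDA — PLS2 regression of one-hot condition labels on the feature matrix
  via the NIPALS deflation algorithm, with VIP (variable importance in
  projection) scores;
* an l2-penalized multinomial logistic classifier minimizing
  ``sum_i -log p(y_i | x_i) + (1 / 2C) ||W||^2`` (intercepts unpenalized),
  the pairwise case reducing to binomial automatically.

Accuracy is estimated by repeated stratified K-fold cross-validation where
folds partition MICE (all epochs of a mouse share a fold, so no mouse leaks
between training and test), with a percentile 95% CI over repetitions, and
significance by mouse-level label-permutation testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .config import RunConfig, log
from .preprocess import ZMatrix


class ParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Epoch x feature matrix with labels and mouse ids for fold grouping."""

    X: pd.DataFrame          # rows = epochs, columns = "region:analyte"
    y: np.ndarray            # condition label per epoch
    mouse: np.ndarray        # mouse id per epoch

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    def mouse_labels(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for m, lab in zip(self.mouse, self.y):
            out[m] = lab
        return out

    def subset_classes(self, keep: tuple[str, ...]) -> "FeatureMatrix":
        mask = np.isin(self.y, keep)
        return FeatureMatrix(
            X=self.X[mask].reset_index(drop=True),
            y=self.y[mask],
            mouse=self.mouse[mask],
        )


def build_feature_matrix(
    zm: ZMatrix, hours: range | list[int] = range(1, 7)
) -> FeatureMatrix:
    """Mouse-hour epochs (default hours 1-6), analytes from both regions
    concatenated with region-tagged names.  Requires a complete (imputed)
    matrix."""
    df = zm.data[zm.data["hour"].isin(list(hours))]
    if df["z"].isna().any():
        raise ParameterError("feature matrix requires an imputed (complete) ZMatrix")
    wide = df.pivot_table(
        index=["mouse", "group", "hour"],
        columns=["region", "analyte"],
        values="z",
        observed=True,
    )
    wide.columns = [f"{r}:{a}" for r, a in wide.columns]
    wide = wide.dropna(axis=0)  # mice missing a whole region contribute nothing
    idx = wide.index.to_frame(index=False)
    return FeatureMatrix(
        X=wide.reset_index(drop=True),
        y=idx["group"].to_numpy(),
        mouse=idx["mouse"].to_numpy(),
    )


def _standardize_train_test(
    Xtr: np.ndarray, Xte: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Column standardization with train-fold statistics only."""
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (Xtr - mu) / sd, (Xte - mu) / sd, mu, sd


# ---------------------------------------------------------------------------
# PLSDA (NIPALS PLS2) and VIP
# ---------------------------------------------------------------------------

@dataclass
class PLSDAModel:
    classes: np.ndarray
    x_weights: np.ndarray     # p x A, unit-norm columns
    x_loadings: np.ndarray    # p x A
    x_scores: np.ndarray      # n x A
    y_loadings: np.ndarray    # K x A
    ssy: np.ndarray           # explained Y sum of squares per component
    x_mean: np.ndarray = field(repr=False, default=None)
    y_mean: np.ndarray = field(repr=False, default=None)
    coef: np.ndarray = field(repr=False, default=None)  # p x K

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        Xc = np.asarray(X, dtype=float) - self.x_mean
        # scores via the weights corrected for deflation
        R = self.x_weights @ np.linalg.inv(
            self.x_loadings.T @ self.x_weights
        )
        return Xc @ R

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xc = np.asarray(X, dtype=float) - self.x_mean
        yhat = Xc @ self.coef + self.y_mean
        return self.classes[np.argmax(yhat, axis=1)]


def fit_plsda(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    n_components: int = 2,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> PLSDAModel:
    """PLS2 of one-hot labels on X via NIPALS with X-score deflation."""
    if n_components < 1:
        raise ParameterError("n_components must be >= 1")
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        j = int(np.argmax(sd == 0))
        name = names[j] if names else str(j)
        raise ParameterError(f"zero-variance column: {name}")
    classes = np.unique(y)
    Y = (y[:, None] == classes[None, :]).astype(float)
    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    E, F = X - x_mean, Y - y_mean
    n, p = E.shape
    if n_components > min(n - 1, p):
        raise ParameterError("n_components exceeds the rank bound of X")

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    Q = np.zeros((Y.shape[1], n_components))
    ssy = np.zeros(n_components)
    for a in range(n_components):
        ss_before = float(np.sum(F**2))
        u = F[:, int(np.argmax(F.var(axis=0)))].copy()
        t_old = np.zeros(n)
        for _ in range(max_iter):
            w = E.T @ u
            w /= np.linalg.norm(w)
            t = E @ w
            q = F.T @ t / float(t @ t)
            denom = float(q @ q)
            if denom == 0:
                break
            u = F @ q / denom
            if np.linalg.norm(t - t_old) < tol * max(1.0, np.linalg.norm(t)):
                break
            t_old = t
        p_load = E.T @ t / float(t @ t)
        q_load = F.T @ t / float(t @ t)
        E = E - np.outer(t, p_load)
        F = F - np.outer(t, q_load)
        W[:, a], P[:, a], T[:, a], Q[:, a] = w, p_load, t, q_load
        ssy[a] = ss_before - float(np.sum(F**2))

    R = W @ np.linalg.inv(P.T @ W)
    coef = R @ Q.T
    return PLSDAModel(
        classes=classes, x_weights=W, x_loadings=P, x_scores=T,
        y_loadings=Q, ssy=ssy, x_mean=x_mean, y_mean=y_mean, coef=coef,
    )


def vip_scores(model: PLSDAModel) -> np.ndarray:
    """VIP_j = sqrt(p * sum_a SSY_a w_ja^2 / sum_a SSY_a); mean VIP^2 = 1."""
    W = model.x_weights
    p = W.shape[0]
    ssy = model.ssy
    num = (W**2) @ ssy
    return np.sqrt(p * num / float(ssy.sum()))


def vip_table(model: PLSDAModel, feature_names: list[str]) -> pd.DataFrame:
    vip = vip_scores(model)
    df = pd.DataFrame({"feature": feature_names, "vip": vip})
    df["region"] = [f.split(":", 1)[0] if ":" in f else "" for f in df["feature"]]
    df = df.sort_values("vip", ascending=False).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


# ---------------------------------------------------------------------------
# penalized multinomial logistic
# ---------------------------------------------------------------------------

@dataclass
class PenalizedLogit:
    classes: np.ndarray
    coef: np.ndarray        # K x p
    intercept: np.ndarray   # K
    C: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.coef.T + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.decision(X), axis=1)]


def fit_penalized_logistic(
    X: np.ndarray, y: np.ndarray, C: float = 0.001
) -> PenalizedLogit:
    """Minimize the penalized multinomial negative log-likelihood.

    Objective: sum_i -log softmax(Wx_i + b)_{y_i} + (1/(2C)) ||W||_F^2.
    Intercepts are unpenalized.  Solved by L-BFGS with analytic gradients
    from a zero start (which keeps the softmax parametrization in the
    sum-to-zero gauge).
    """
    if C <= 0:
        raise ParameterError("C must be positive")
    X = np.asarray(X, dtype=float)
    classes = np.unique(y)
    K = len(classes)
    if K < 2:
        raise ParameterError("need at least 2 classes")
    n, p = X.shape
    Y = (y[:, None] == classes[None, :]).astype(float)
    lam = 1.0 / (2.0 * C)

    def unpack(theta):
        W = theta[: K * p].reshape(K, p)
        b = theta[K * p:]
        return W, b

    def objective(theta):
        W, b = unpack(theta)
        S = X @ W.T + b
        S -= S.max(axis=1, keepdims=True)
        expS = np.exp(S)
        Z = expS.sum(axis=1, keepdims=True)
        logp = S - np.log(Z)
        nll = -float(np.sum(Y * logp))
        Pm = expS / Z
        G = Pm - Y
        gW = G.T @ X + 2 * lam * W
        gb = G.sum(axis=0)
        return nll + lam * float(np.sum(W**2)), np.concatenate(
            [gW.ravel(), gb]
        )

    theta0 = np.zeros(K * p + K)
    res = minimize(
        objective, theta0, jac=True, method="L-BFGS-B",
        options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-9},
    )
    W, b = unpack(res.x)
    return PenalizedLogit(classes=classes, coef=W, intercept=b, C=C)


# ---------------------------------------------------------------------------
# stratified mouse-level folds
# ---------------------------------------------------------------------------

def stratified_mouse_folds(
    mouse_labels: dict[str, str], k: int, rng: np.random.Generator
) -> list[list[str]]:
    """Partition mice into k folds, each condition spread as evenly as
    possible across folds (round-robin after a per-class shuffle)."""
    by_class: dict[str, list[str]] = {}
    for m, lab in mouse_labels.items():
        by_class.setdefault(lab, []).append(m)
    n_min = min(len(v) for v in by_class.values())
    if n_min < k:
        raise ParameterError(
            f"class with {n_min} mice cannot be stratified into {k} folds"
        )
    folds: list[list[str]] = [[] for _ in range(k)]
    for lab in sorted(by_class):
        mice = sorted(by_class[lab])
        rng.shuffle(mice)
        start = int(rng.integers(k))
        for i, m in enumerate(mice):
            folds[(start + i) % k].append(m)
    return folds


# ---------------------------------------------------------------------------
# repeated CV and permutation machinery
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    mean_accuracy: float
    accuracies: np.ndarray
    ci_low: float
    ci_high: float
    labels: tuple[str, ...]
    p_value: float | None = None
    perm_accuracies: np.ndarray | None = None


def _cv_once(
    fm: FeatureMatrix,
    y: np.ndarray,
    k: int,
    C: float,
    rng: np.random.Generator,
    fold_callback=None,
) -> float:
    """One repetition: stratified mouse folds, train-fold standardization,
    penalized-logistic fit, pooled held-out epoch accuracy."""
    labels = {m: lab for m, lab in zip(fm.mouse, y)}
    folds = stratified_mouse_folds(labels, k, rng)
    Xall = fm.X.to_numpy(dtype=float)
    correct = 0
    for fold in folds:
        test_mask = np.isin(fm.mouse, fold)
        Xtr, Xte, mu, sd = _standardize_train_test(
            Xall[~test_mask], Xall[test_mask]
        )
        clf = fit_penalized_logistic(Xtr, y[~test_mask], C)
        pred = clf.predict(Xte)
        correct += int(np.sum(pred == y[test_mask]))
        if fold_callback is not None:
            fold_callback(
                train_mice=sorted(set(fm.mouse[~test_mask])),
                test_mice=sorted(fold),
                mu=mu,
                sd=sd,
            )
    return correct / len(y)


def repeated_stratified_cv(
    fm: FeatureMatrix,
    k: int = 3,
    reps: int = 100,
    C: float = 0.001,
    seed: int | np.random.Generator = 0,
    fold_callback=None,
) -> CVResult:
    """Repeated stratified K-fold CV over mice; percentile 95% CI over reps."""
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    accs = np.array(
        [_cv_once(fm, fm.y, k, C, rng, fold_callback) for _ in range(reps)]
    )
    lo, hi = np.percentile(accs, [2.5, 97.5])
    return CVResult(
        mean_accuracy=float(accs.mean()),
        accuracies=accs,
        ci_low=float(lo),
        ci_high=float(hi),
        labels=tuple(np.unique(fm.y)),
    )


def _permute_mouse_labels(
    fm: FeatureMatrix, rng: np.random.Generator
) -> np.ndarray:
    mice = sorted(set(fm.mouse))
    labels = fm.mouse_labels()
    perm = [labels[m] for m in mice]
    rng.shuffle(perm)
    remap = dict(zip(mice, perm))
    return np.array([remap[m] for m in fm.mouse])


def permutation_test(
    fm: FeatureMatrix,
    observed: float,
    n_permutations: int = 1000,
    k: int = 3,
    perm_reps: int = 10,
    C: float = 0.001,
    seed: int | np.random.Generator = 0,
) -> tuple[float, np.ndarray]:
    """Mouse-level label-permutation null for CV accuracy.

    Per permutation, the condition labels are reassigned across mice and the
    CV accuracy recomputed (mean of ``perm_reps`` repetitions).  Returns the
    small-sample-corrected p-value (1 + #{perm >= obs}) / (1 + n) and the
    permutation accuracies.
    """
    if n_permutations < 1:
        raise ParameterError("need at least one permutation")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    perm_accs = np.empty(n_permutations)
    for i in range(n_permutations):
        y_perm = _permute_mouse_labels(fm, rng)
        accs = [_cv_once(fm, y_perm, k, C, rng) for _ in range(perm_reps)]
        perm_accs[i] = float(np.mean(accs))
    p = (1 + int(np.sum(perm_accs >= observed))) / (1 + n_permutations)
    return float(p), perm_accs


def classify_conditions(
    fm: FeatureMatrix,
    config: RunConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> CVResult:
    """Full machinery for one comparison: repeated CV + permutation test."""
    config = config or RunConfig()
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(config.seed if seed is None else seed)
    )
    cv = repeated_stratified_cv(
        fm, k=config.cv_folds, reps=config.cv_reps, C=config.C, seed=rng
    )
    p, perm = permutation_test(
        fm,
        observed=cv.mean_accuracy,
        n_permutations=config.n_permutations,
        k=config.cv_folds,
        perm_reps=config.perm_reps,
        C=config.C,
        seed=rng,
    )
    cv.p_value = p
    cv.perm_accuracies = perm
    log.info(
        "CV %s: accuracy %.3f [%.3f, %.3f], p = %.4g",
        "/".join(cv.labels), cv.mean_accuracy, cv.ci_low, cv.ci_high, p,
    )
    return cv


def pairwise_comparisons(
    fm: FeatureMatrix,
    pairs: list[tuple[str, str]] | None = None,
    config: RunConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> dict[tuple[str, str], CVResult]:
    """Restrict to each condition pair and run the full CV + permutation
    machinery (chance = 50%)."""
    config = config or RunConfig()
    classes = list(fm.classes)
    if pairs is None:
        pairs = [
            (a, b) for i, a in enumerate(classes) for b in classes[i + 1:]
        ]
    out: dict[tuple[str, str], CVResult] = {}
    for pair in pairs:
        for c in pair:
            if c not in classes:
                raise ParameterError(f"condition {c!r} not present")
        sub = fm.subset_classes(tuple(pair))
        out[pair] = classify_conditions(sub, config, seed)
    return out
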