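"""NIPALS partial least squares with leave-one-out cross-validation.

The single-response NIPALS extraction is deterministic: the weight vector
of each component starts (and, for one response, ends) at the X'y
direction, so no random initialization enters. Fitted statistics follow
the conventional definitions:

* r2 = 1 - RSS / SS_tot
* SEE = sqrt(RSS / (n - c - 1))
* F = (r2 / c) / ((1 - r2) / (n - c - 1)), df (c, n - c - 1)
* PRESS = sum of squared left-out prediction errors
* q2 = 1 - PRESS / SS_tot, SDEP = sqrt(PRESS / n)

For q2, SS_tot is taken per left-out compound about the mean of the n-1
training responses of its fold (``ss_total="fold_mean"``, the default) or
about the overall mean (``ss_total="global_mean"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field_engine import FieldTable

__all__ = [
    "PLSModel",
    "FitStats",
    "CrossValidationResult",
    "FieldContributionSummary",
    "PLSError",
    "fit_pls",
    "loo_cross_validate",
    "conventional_stats",
    "field_contributions",
    "select_components",
]


class PLSError(ValueError):
    pass


@dataclass
class PLSModel:
    """Latent-variable regression y ~ X with ``n_components`` components.

    ``coefficients``/``intercept`` act on the same X scale the model was
    fitted on: predictions are ``X @ coefficients + intercept``.
    """

    n_components: int
    weights: np.ndarray  # (p, c)
    x_loadings: np.ndarray  # (p, c)
    y_loadings: np.ndarray  # (c,)
    scores: np.ndarray  # (n, c)
    coefficients: np.ndarray  # (p,)
    intercept: float
    x_mean: np.ndarray
    y_mean: float
    training_ids: list[str] | None = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.coefficients.shape[0]:
            raise PLSError(
                f"row width {x.shape[1]} does not match model width "
                f"{self.coefficients.shape[0]}"
            )
        return x @ self.coefficients + self.intercept

    def fitted_values(self, x: np.ndarray) -> np.ndarray:
        return self.predict(x)


@dataclass(frozen=True)
class FitStats:
    r2: float
    see: float
    f_value: float
    df: tuple[int, int]
    perfect_fit: bool = False


@dataclass
class CrossValidationResult:
    predictions: np.ndarray  # per-compound left-out predictions
    press: float
    q2: float
    sdep: float
    n_components: int


@dataclass(frozen=True)
class FieldContributionSummary:
    steric_fraction: float
    electrostatic_fraction: float


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Deterministic NIPALS extraction of ``n_components`` latent variables."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise PLSError("X and y disagree on sample count")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise PLSError("non-finite entries in X or y")
    if n_components < 1:
        raise PLSError("need at least one component")
    if n < n_components + 2:
        raise PLSError(f"need at least n_components + 2 = {n_components + 2} rows, got {n}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    e = X - x_mean
    f = y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    for a in range(n_components):
        w = e.T @ f
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            raise PLSError(
                f"component {a + 1} exceeds the rank of X (weight vector vanished)"
            )
        w /= norm
        t = e @ w
        tt = float(t @ t)
        if tt < 1e-24:
            raise PLSError(f"component {a + 1} exceeds the rank of X (zero score)")
        p_a = e.T @ t / tt
        q_a = float(f @ t) / tt
        e = e - np.outer(t, p_a)
        f = f - q_a * t
        W[:, a], P[:, a], Q[a], T[:, a] = w, p_a, q_a, t

    # B = W (P' W)^{-1} q maps centered X to centered y
    coef = W @ np.linalg.solve(P.T @ W, Q)
    intercept = y_mean - float(x_mean @ coef)
    return PLSModel(
        n_components=n_components,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        scores=T,
        coefficients=coef,
        intercept=intercept,
        x_mean=x_mean,
        y_mean=y_mean,
    )


def loo_cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    preprocess=None,
    ss_total: str = "fold_mean",
) -> CrossValidationResult:
    """Leave-one-out cross-validation with optional in-fold preprocessing.

    ``preprocess(X_train, X_left_out)`` may re-derive any data-dependent
    transformation (column filtering, scaling) from the training fold only,
    returning the transformed pair; by default rows are used as passed
    (centering is always re-estimated in-fold by the PLS fit itself).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < n_components + 3:
        raise PLSError(f"LOO needs at least n_components + 3 = {n_components + 3} rows")
    if ss_total not in ("fold_mean", "global_mean"):
        raise PLSError("ss_total must be 'fold_mean' or 'global_mean'")

    predictions = np.empty(n)
    baseline = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        X_tr, y_tr = X[keep], y[keep]
        if np.var(y_tr) == 0:
            raise PLSError(f"fold {i} has zero-variance response")
        X_te = X[i : i + 1]
        if preprocess is not None:
            X_tr, X_te = preprocess(X_tr, X_te)
        model = fit_pls(X_tr, y_tr, n_components)
        predictions[i] = float(model.predict(X_te)[0])
        baseline[i] = y_tr.mean() if ss_total == "fold_mean" else y.mean()

    press = float(np.sum((y - predictions) ** 2))
    ss_tot = float(np.sum((y - baseline) ** 2))
    if ss_tot == 0:
        raise PLSError("zero total sum of squares")
    return CrossValidationResult(
        predictions=predictions,
        press=press,
        q2=1.0 - press / ss_tot,
        sdep=float(np.sqrt(press / n)),
        n_components=n_components,
    )


def conventional_stats(model: PLSModel, X: np.ndarray, y: np.ndarray) -> FitStats:
    """Conventional r2 / SEE / F of a fitted model on its training data."""
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    c = model.n_components
    if n <= c + 1:
        raise PLSError(f"need n > components + 1, got n={n}, components={c}")
    fitted = model.predict(X)
    rss = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise PLSError("zero-variance response")
    r2 = 1.0 - rss / ss_tot
    see = float(np.sqrt(rss / (n - c - 1)))
    perfect = rss <= 1e-300 * max(ss_tot, 1.0) or r2 >= 1.0
    if perfect:
        f_value = float("inf")
    else:
        f_value = (r2 / c) / ((1.0 - r2) / (n - c - 1))
    return FitStats(r2=r2, see=see, f_value=f_value, df=(c, n - c - 1), perfect_fit=perfect)


def field_contributions(model: PLSModel, table: FieldTable) -> FieldContributionSummary:
    """Per-field fraction of sum_j |coef_j| * sd_j over unmasked columns.

    The product |coef| * sd is evaluated on the raw energy scale; it is
    invariant to the stored block scaling, so a model fitted on the scaled
    table can be summarized directly.
    """
    labels = table.field_labels[table.mask]
    if model.coefficients.shape[0] != labels.shape[0]:
        raise PLSError("model was not fitted on this table's unmasked columns")
    sd = table.masked_scaled().std(axis=0, ddof=1) if table.scaled is not None else (
        table.masked_data().std(axis=0, ddof=1)
    )
    weight = np.abs(model.coefficients) * sd
    steric = float(weight[labels == "steric"].sum())
    elec = float(weight[labels == "electrostatic"].sum())
    total = steric + elec
    if total <= 0:
        raise PLSError("zero total field contribution")
    return FieldContributionSummary(
        steric_fraction=steric / total, electrostatic_fraction=elec / total
    )


def select_components(X: np.ndarray, y: np.ndarray, max_components: int) -> int:
    """Component count maximizing LOO q2; ties go to fewer components."""
    if max_components < 1:
        raise PLSError("max_components must be >= 1")
    best_c, best_q2 = 1, -np.inf
    for c in range(1, max_components + 1):
        try:
            q2 = loo_cross_validate(X, y, c).q2
        except PLSError:
            break
        if q2 > best_q2 + 1e-12:
            best_c, best_q2 = c, q2
    return best_c
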