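"""PCA, OPLS-DA with VIP scores, group tests and Pearson correlation matrices.

This is the chemometrics layer applied to the bin table.  OPLS-DA follows
the standard orthogonal-projections-to-latent-structures formulation for a
two-class problem: y-orthogonal variation is estimated and deflated from X,
then a single-component PLS1 on the +/-1 encoded class vector provides the
predictive component.  With zero orthogonal components the model is exactly
single-component PLS1.

VIP (variable importance in projection) for variable j over the predictive
component(s):

    VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a )

with p variables and SSY_a the y-variance explained by component a; the mean
of squared VIPs is 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class Scaler:
    method: str
    mean: np.ndarray
    scale: np.ndarray
    zero_variance: np.ndarray  # boolean flags

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale


def scale_matrix(X: np.ndarray, method: str = "autoscale"
                 ) -> tuple[np.ndarray, Scaler]:
    """Column-wise centering plus autoscale (unit SD), pareto (sqrt SD) or
    centering only.  Zero-variance columns are centered only and flagged."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = sd == 0
    if method == "autoscale":
        scale = np.where(zero, 1.0, sd)
    elif method == "pareto":
        scale = np.where(zero, 1.0, np.sqrt(sd))
    elif method == "center_only":
        scale = np.ones_like(sd)
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    scaler = Scaler(method=method, mean=mean, scale=scale, zero_variance=zero)
    return (X - mean) / scale, scaler


def pca(X_scaled: np.ndarray, n_components: int
        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal components via SVD.

    Returns (scores, loadings, explained variance fractions); loadings are
    orthonormal columns, scores = X @ loadings.
    """
    X = np.asarray(X_scaled, dtype=float)
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if not (1 <= n_components <= max_comp):
        raise ValueError(f"n_components must lie in [1, {max_comp}]")
    u, s, vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
    total = float((s**2).sum())
    loadings = vt[:n_components].T
    scores = X @ loadings
    explained = (s[:n_components] ** 2) / total if total > 0 else \
        np.zeros(n_components)
    return scores, loadings, explained


@dataclass
class OplsdaModel:
    """Fitted OPLS-DA model for a two-class problem."""

    scaler: Scaler
    classes: tuple  # classes encoded as (-1, +1) in this order
    weights: np.ndarray  # predictive weight vector (p,)
    loadings: np.ndarray  # predictive loading vector (p,)
    scores: np.ndarray  # predictive scores (n,)
    y_loading: float
    orth_weights: np.ndarray  # (n_orth, p)
    orth_loadings: np.ndarray  # (n_orth, p)
    orth_scores: np.ndarray  # (n, n_orth)
    ssy_explained: np.ndarray  # y-variance explained per predictive component
    vip: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)

    @property
    def n_orth(self) -> int:
        return self.orth_weights.shape[0]

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Predictive scores of new rows (same preprocessing + deflation)."""
        Xs = self.scaler.transform(X)
        for w_o, p_o in zip(self.orth_weights, self.orth_loadings):
            t_o = Xs @ w_o
            Xs = Xs - np.outer(t_o, p_o)
        return Xs @ self.weights

    def predict_class(self, X: np.ndarray) -> np.ndarray:
        t = self.predict_scores(X)
        pred = np.where(t * self.y_loading >= 0, 1, -1)
        return np.asarray([self.classes[1] if v > 0 else self.classes[0]
                           for v in pred])

    def to_json(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "scaling": {"method": self.scaler.method,
                        "mean": self.scaler.mean.tolist(),
                        "scale": self.scaler.scale.tolist()},
            "weights": self.weights.tolist(),
            "loadings": self.loadings.tolist(),
            "y_loading": self.y_loading,
            "orth_weights": self.orth_weights.tolist(),
            "orth_loadings": self.orth_loadings.tolist(),
            "ssy_explained": self.ssy_explained.tolist(),
            "vip": None if self.vip is None else self.vip.tolist(),
            "feature_names": self.feature_names,
        }


def encode_two_classes(y) -> tuple[np.ndarray, tuple]:
    labels = pd.unique(pd.Series(list(y)))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(labels)}")
    encoded = np.where(np.asarray(y) == labels[1], 1.0, -1.0)
    return encoded, (labels[0], labels[1])


def _pls1_component(X: np.ndarray, y: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Single PLS1 component: weights, scores, X-loadings, y-loading."""
    w = X.T @ y
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("X carries no covariance with y")
    w = w / norm
    t = X @ w
    tt = float(t @ t)
    p = X.T @ t / tt
    c = float(y @ t / tt)
    return w, t, p, c


def select_n_orth(X: np.ndarray, y, max_orth: int = 3,
                  scaling: str = "autoscale") -> int:
    """Choose the orthogonal-component count by leave-one-out Q2.

    Fits OPLS-DA models with 0..max_orth orthogonal components, scoring each
    by leave-one-out predicted y residuals; returns the smallest count within
    one part in a thousand of the best Q2.
    """
    X = np.asarray(X, dtype=float)
    y_enc, _ = encode_two_classes(y)
    n = len(y_enc)
    q2 = []
    for k in range(max_orth + 1):
        press, ss_tot = 0.0, 0.0
        y_mean_all = y_enc.mean()
        for i in range(n):
            keep = np.arange(n) != i
            try:
                model = oplsda(X[keep], y_enc[keep], n_orth=k,
                               scaling=scaling)
            except ValueError:
                press = np.inf
                break
            t = model.predict_scores(X[i: i + 1])
            yhat = float(t[0] * model.y_loading) + y_enc[keep].mean()
            press += (y_enc[i] - yhat) ** 2
            ss_tot += (y_enc[i] - y_mean_all) ** 2
        q2.append(1.0 - press / ss_tot if np.isfinite(press) else -np.inf)
    best = max(q2)
    for k, v in enumerate(q2):
        if v >= best - 1e-3:
            return k
    return int(np.argmax(q2))


def oplsda(X: np.ndarray, y, n_orth: int | str = 1, scaling: str = "autoscale",
           feature_names: list[str] | None = None,
           prescaled: bool = False, scaler: Scaler | None = None) -> OplsdaModel:
    """Fit an OPLS-DA model (one predictive + ``n_orth`` orthogonal components).

    Each orthogonal component captures systematic X-variation orthogonal to
    y and is deflated before the final predictive PLS1 component, so the
    predictive scores are orthogonal to every orthogonal score vector.
    """
    if n_orth == "auto":
        n_orth = select_n_orth(X, y, scaling=scaling)
    if not isinstance(n_orth, int) or n_orth < 0:
        raise ValueError("n_orth must be a non-negative integer or 'auto'")
    y_enc, classes = encode_two_classes(y)
    if prescaled:
        Xs = np.asarray(X, dtype=float).copy()
        if scaler is None:
            scaler = Scaler("precomputed", np.zeros(Xs.shape[1]),
                            np.ones(Xs.shape[1]),
                            np.zeros(Xs.shape[1], dtype=bool))
    else:
        Xs, scaler = scale_matrix(X, scaling)
    yc = y_enc - y_enc.mean()

    orth_w, orth_p, orth_t = [], [], []
    for _ in range(n_orth):
        w, t, p, _c = _pls1_component(Xs, yc)
        w_o = p - float(w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break  # no y-orthogonal structure left
        w_o = w_o / norm
        t_o = Xs @ w_o
        p_o = Xs.T @ t_o / float(t_o @ t_o)
        Xs = Xs - np.outer(t_o, p_o)
        orth_w.append(w_o)
        orth_p.append(p_o)
        orth_t.append(t_o)

    w, t, p, c = _pls1_component(Xs, yc)
    ssy_total = float(yc @ yc)
    ssy_expl = float(c**2 * (t @ t))

    model = OplsdaModel(
        scaler=scaler, classes=classes, weights=w, loadings=p, scores=t,
        y_loading=c,
        orth_weights=np.asarray(orth_w).reshape(len(orth_w), -1)
        if orth_w else np.empty((0, Xs.shape[1])),
        orth_loadings=np.asarray(orth_p).reshape(len(orth_p), -1)
        if orth_p else np.empty((0, Xs.shape[1])),
        orth_scores=np.stack(orth_t, axis=1) if orth_t
        else np.empty((Xs.shape[0], 0)),
        ssy_explained=np.asarray([ssy_expl / ssy_total if ssy_total else 0.0]),
        feature_names=list(feature_names) if feature_names is not None else [],
    )
    model.vip = vip_scores(model)[0]
    return model


def vip_scores(model: OplsdaModel) -> tuple[np.ndarray, list[int]]:
    """Per-variable VIP scores and the descending ranking (indices).

    Ties in the ranking break by ascending variable index (i.e. ascending
    m/z for bin tables built in mass order).
    """
    if model.weights is None:
        raise ValueError("model is not fitted")
    w2 = model.weights**2  # single predictive component
    p = len(w2)
    ssy = model.ssy_explained
    vip = np.sqrt(p * (ssy[0] * w2) / ssy[0]) if ssy[0] > 0 else np.sqrt(p * w2)
    order = np.lexsort((np.arange(p), -vip))
    return vip, list(order)


def r2y(model: OplsdaModel, X: np.ndarray, y) -> float:
    """In-sample fraction of y-variance captured by the predictive component."""
    y_enc, _ = encode_two_classes(y)
    yc = y_enc - y_enc.mean()
    t = model.predict_scores(X)
    yhat = t * model.y_loading
    ss_res = float(((yc - yhat) ** 2).sum())
    ss_tot = float((yc**2).sum())
    return 1.0 - ss_res / ss_tot


def compare_groups(X: pd.DataFrame | np.ndarray, labels,
                   alternative: str = "two-sided") -> pd.DataFrame:
    """Welch two-sample comparison per column, BH-adjusted across the family.

    Returns a frame with effect (difference of group means, second minus
    first label in sorted order), t statistic, p and q (Benjamini-Hochberg).
    """
    from statsmodels.stats.multitest import multipletests

    df = pd.DataFrame(X)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(groups)}")
    a = df[labels == groups[0]]
    b = df[labels == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(b, a, equal_var=False, axis=0, alternative=alternative)
    t = np.atleast_1d(res.statistic).astype(float)
    pvals = np.atleast_1d(res.pvalue).astype(float)
    t = np.where(np.isnan(t), 0.0, t)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    _, qvals, *_ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame({
        "effect": (b.mean(axis=0) - a.mean(axis=0)).to_numpy(dtype=float),
        "t": t, "p": pvals, "q": qvals,
    }, index=df.columns)


def pearson_matrix(X: pd.DataFrame | np.ndarray
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix over columns of an ROIs x variables table.

    Zero-variance columns are excluded and reported in the metadata frame.
    """
    df = pd.DataFrame(X)
    if len(df) < 3:
        raise ValueError("need at least 3 rows for correlation analysis")
    sd = df.std(axis=0, ddof=1)
    excluded = list(df.columns[(sd == 0) | sd.isna()])
    kept = df.drop(columns=excluded)
    corr = pd.DataFrame(np.corrcoef(kept.to_numpy(dtype=float), rowvar=False),
                        index=kept.columns, columns=kept.columns)
    np.fill_diagonal(corr.values, 1.0)
    meta = pd.DataFrame({"excluded_zero_variance": pd.Series(excluded, dtype=object)})
    return corr, meta
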