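"""Multivariate modeling: PCA outlier screening and OPLS-DA.

OPLS-DA is implemented as an orthogonal-signal-corrected NIPALS: at each
round the PLS weight w ∝ X'y is computed, the part of the X-loading
orthogonal to w defines an orthogonal component which is deflated from X,
and the final predictive component is extracted from the filtered matrix.
With zero orthogonal components the model is exactly one-component PLS1.

The model/results split follows the fitted-model convention: ``OPLSDA``
holds the data and configuration, ``OPLSDA.fit()`` returns an
``OPLSDAResults`` carrying estimates (weights, scores, loadings, R²Y,
per-feature Corr/Cov with the predictive score) plus methods for
cross-validated Q², permutation testing, the covariance pseudo-spectrum and
a text summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SkPCA

from .containers import FeatureMatrix

__all__ = [
    "PcaResults",
    "fit_pca",
    "flag_outliers",
    "encode_classes",
    "OPLSDA",
    "OPLSDAResults",
    "fit_opls_da",
    "cross_validated_q2",
    "permutation_test",
    "loading_pseudospectrum",
]


# ---------------------------------------------------------------------------
# PCA with Hotelling T² outlier screening
# ---------------------------------------------------------------------------

@dataclass
class PcaResults:
    loadings: np.ndarray  # (n_components, n_features), orthonormal rows
    scores: np.ndarray  # (n_samples, n_components)
    explained_variance: np.ndarray  # per-component variances (ddof=1)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    sample_ids: list

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]

    def hotelling_t2(self, n_components: int | None = None) -> np.ndarray:
        """Per-sample Hotelling T² on the first ``n_components`` scores."""
        k = n_components or self.n_components
        t = self.scores[:, :k]
        return np.sum(t**2 / self.explained_variance[:k], axis=1)

    def t2_critical(self, alpha: float = 0.05, n_components: int | None = None) -> float:
        """F-based critical value: k(n-1)(n+1) / (n(n-k)) * F_{1-alpha}(k, n-k)."""
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        k = n_components or self.n_components
        n = self.n_samples
        if n <= k:
            raise ValueError("need more samples than components for the T² limit")
        f_crit = stats.f.ppf(1 - alpha, k, n - k)
        return k * (n - 1) * (n + 1) / (n * (n - k)) * f_crit


def fit_pca(fm: FeatureMatrix | np.ndarray, n_components: int = 2) -> PcaResults:
    """PCA for cluster overview and outlier screening."""
    if isinstance(fm, FeatureMatrix):
        X = fm.array()
        ids = fm.sample_ids
    else:
        X = np.asarray(fm, dtype=float)
        ids = list(range(X.shape[0]))
    if n_components > min(X.shape[0] - 1, X.shape[1]):
        raise ValueError("n_components exceeds the rank of the data")
    pca = _SkPCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return PcaResults(
        loadings=pca.components_,
        scores=scores,
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean=pca.mean_,
        sample_ids=ids,
    )


def flag_outliers(
    results: PcaResults, alpha: float = 0.05, n_components: int | None = None
) -> list:
    """Sample ids whose Hotelling T² exceeds the F-based critical value."""
    k = n_components or results.n_components
    t2 = results.hotelling_t2(k)
    crit = results.t2_critical(alpha, k)
    return [sid for sid, v in zip(results.sample_ids, t2) if v > crit]


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

def encode_classes(labels, positive_class: str | None = None):
    """Centered two-level dummy coding of a two-class label vector.

    The positive class is coded +1 and the other 0, then the vector is
    mean-centered (values n0/n and -n1/n), so it has exactly mean zero.
    OPLS-DA directions are invariant to the affine coding chosen.
    """
    labels = pd.Series(list(labels))
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if positive_class is None:
        positive_class = classes[1]
    if positive_class not in classes:
        raise ValueError(f"positive class {positive_class!r} not among {classes}")
    reference = classes[0] if positive_class == classes[1] else classes[1]
    raw = (labels == positive_class).to_numpy(dtype=float)
    y = raw - raw.mean()
    return y, positive_class, reference


def _fit_opls_arrays(X: np.ndarray, y: np.ndarray, n_orthogonal: int):
    """Core NIPALS loop on centered arrays.  Returns a dict of arrays."""
    Xf = X.copy()
    W_o, T_o, P_o = [], [], []
    for _ in range(n_orthogonal):
        w = Xf.T @ y
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("y is uncorrelated with every feature (zero weight)")
        w = w / nw
        t = Xf @ w
        tt = t @ t
        if tt == 0:
            break
        p = Xf.T @ t / tt
        w_o = p - (w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:  # no orthogonal variation left
            break
        w_o = w_o / n_wo
        t_o = Xf @ w_o
        tt_o = t_o @ t_o
        if tt_o == 0:
            break
        p_o = Xf.T @ t_o / tt_o
        Xf = Xf - np.outer(t_o, p_o)
        W_o.append(w_o)
        T_o.append(t_o)
        P_o.append(p_o)

    w = Xf.T @ y
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("y is uncorrelated with every feature (zero weight)")
    w = w / nw
    t_p = Xf @ w
    tt = t_p @ t_p
    if tt == 0:
        raise ValueError("zero-variance filtered matrix")
    p_p = Xf.T @ t_p / tt
    q = (y @ t_p) / tt
    return {
        "w": w,
        "t_p": t_p,
        "p_p": p_p,
        "q": q,
        "W_o": np.array(W_o) if W_o else np.empty((0, X.shape[1])),
        "T_o": np.array(T_o) if T_o else np.empty((0, X.shape[0])),
        "P_o": np.array(P_o) if P_o else np.empty((0, X.shape[1])),
    }


def _predict_arrays(fit: dict, Xnew: np.ndarray) -> np.ndarray:
    """Predicted (centered) y for new rows: deflate orthogonal parts, project."""
    Xf = np.atleast_2d(Xnew).astype(float).copy()
    for w_o, p_o in zip(fit["W_o"], fit["P_o"]):
        t_o = Xf @ w_o
        Xf = Xf - np.outer(t_o, p_o)
    return (Xf @ fit["w"]) * fit["q"]


@dataclass
class OPLSDA:
    """Two-class OPLS-DA model specification.

    Parameters
    ----------
    X : ndarray
        Samples x features matrix, expected Pareto-scaled (mean-centered).
    labels : sequence
        Per-sample class labels (exactly two distinct values).
    n_orthogonal : int
        Number of orthogonal components removed before the predictive one.
    positive_class : str, optional
        Class whose mean predictive score is oriented positive; defaults to
        the lexicographically second label.
    """

    X: np.ndarray
    labels: list
    n_orthogonal: int = 1
    positive_class: str | None = None
    feature_names: list | None = None
    feature_ppm: np.ndarray | None = None

    @classmethod
    def from_feature_matrix(
        cls,
        fm: FeatureMatrix,
        groups: tuple[str, str] | None = None,
        n_orthogonal: int = 1,
        positive_class: str | None = None,
    ) -> "OPLSDA":
        if not fm.pareto:
            raise ValueError("OPLS-DA expects a Pareto-scaled feature matrix")
        if groups is not None:
            fm = fm.subset_groups(groups)
        return cls(
            X=fm.array(),
            labels=list(fm.groups),
            n_orthogonal=n_orthogonal,
            positive_class=positive_class,
            feature_names=fm.feature_names,
            feature_ppm=fm.feature_ppm,
        )

    def fit(self) -> "OPLSDAResults":
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2D")
        if np.allclose(X.std(axis=0), 0):
            raise ValueError("zero-variance X")
        y, positive, reference = encode_classes(self.labels, self.positive_class)
        Xc = X - X.mean(axis=0)
        fit = _fit_opls_arrays(Xc, y, self.n_orthogonal)

        # orient t_p so the positive class scores positive on average
        pos_mask = np.asarray([lab == positive for lab in self.labels])
        if fit["t_p"][pos_mask].mean() < 0:
            fit["w"] = -fit["w"]
            fit["t_p"] = -fit["t_p"]
            fit["p_p"] = -fit["p_p"]
            fit["q"] = -fit["q"]

        resid = y - fit["t_p"] * fit["q"]
        r2y = 1.0 - (resid @ resid) / (y @ y)

        t_p = fit["t_p"]
        n = Xc.shape[0]
        cov = t_p @ Xc / (n - 1)
        sd_t = t_p.std(ddof=1)
        sd_x = Xc.std(axis=0, ddof=1)
        denom = sd_t * sd_x
        corr = np.divide(cov, denom, out=np.zeros_like(cov), where=denom > 0)
        corr = np.clip(corr, -1.0, 1.0)

        names = self.feature_names or [str(i) for i in range(X.shape[1])]
        return OPLSDAResults(
            model=self,
            y=y,
            weights=fit["w"],
            scores_pred=t_p,
            loadings_pred=fit["p_p"],
            q=fit["q"],
            ortho_weights=fit["W_o"],
            ortho_scores=fit["T_o"],
            ortho_loadings=fit["P_o"],
            r2y=float(r2y),
            corr=corr,
            cov=cov,
            feature_names=list(names),
            classes=(reference, positive),
            x_mean=X.mean(axis=0),
        )


@dataclass
class OPLSDAResults:
    """Fitted OPLS-DA estimates and diagnostics."""

    model: OPLSDA
    y: np.ndarray
    weights: np.ndarray  # predictive weight w, unit norm
    scores_pred: np.ndarray  # t_p
    loadings_pred: np.ndarray  # p_p
    q: float
    ortho_weights: np.ndarray  # (n_ortho, n_features)
    ortho_scores: np.ndarray  # (n_ortho, n_samples)
    ortho_loadings: np.ndarray
    r2y: float
    corr: np.ndarray  # Corr(t_p, x_j)
    cov: np.ndarray  # Cov(t_p, x_j)
    feature_names: list
    classes: tuple[str, str]  # (reference, positive)
    x_mean: np.ndarray
    q2y: float | None = field(default=None)
    permutation_p: float | None = field(default=None)
    permutation_q2: np.ndarray | None = field(default=None)

    @property
    def reference_class(self) -> str:
        return self.classes[0]

    @property
    def positive_class(self) -> str:
        return self.classes[1]

    @property
    def n_orthogonal(self) -> int:
        return self.ortho_scores.shape[0]

    def predict(self, Xnew: np.ndarray) -> np.ndarray:
        fit = {
            "W_o": self.ortho_weights,
            "P_o": self.ortho_loadings,
            "w": self.weights,
            "q": self.q,
        }
        return _predict_arrays(fit, np.atleast_2d(Xnew) - self.x_mean)

    def q2(self, folds: int = 7, seed: int = 0) -> float:
        q2 = _q2_arrays(
            np.asarray(self.model.X, dtype=float),
            self.y,
            self.model.n_orthogonal,
            folds,
            seed,
        )
        self.q2y = q2
        return q2

    def permutation_test(self, n_permutations: int = 2000, seed: int = 0, folds: int = 7):
        """Plus-one permutation p-value of the cross-validated Q² statistic."""
        p, null = _permutation_arrays(
            np.asarray(self.model.X, dtype=float),
            self.y,
            self.model.n_orthogonal,
            n_permutations,
            seed,
            folds,
        )
        self.permutation_p = p
        self.permutation_q2 = null
        return p

    def pseudospectrum(self) -> pd.DataFrame:
        return loading_pseudospectrum(self)

    def scores_table(self) -> pd.DataFrame:
        d = {"label": list(self.model.labels), "t_pred": self.scores_pred}
        for i in range(self.n_orthogonal):
            d[f"t_ortho_{i + 1}"] = self.ortho_scores[i]
        return pd.DataFrame(d)

    def summary(self) -> str:
        lines = [
            "OPLS-DA results",
            "===============",
            f"classes:              {self.reference_class} (reference) vs "
            f"{self.positive_class} (positive scores)",
            f"samples / features:   {len(self.y)} / {len(self.feature_names)}",
            f"orthogonal components: {self.n_orthogonal}",
            f"R2Y:                  {self.r2y:.4f}",
        ]
        if self.q2y is not None:
            lines.append(f"Q2Y (cross-validated): {self.q2y:.4f}")
        if self.permutation_p is not None:
            n = len(self.permutation_q2) if self.permutation_q2 is not None else 0
            lines.append(f"permutation p ({n} perms): {self.permutation_p:.4g}")
        order = np.argsort(-np.abs(self.corr))[:10]
        lines.append("top |Corr(tp,X)| features:")
        for i in order:
            lines.append(
                f"  {self.feature_names[i]:<20} corr={self.corr[i]:+.3f} "
                f"cov={self.cov[i]:+.4g}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "n_orthogonal": int(self.n_orthogonal),
            "r2y": self.r2y,
            "q2y": self.q2y,
            "permutation_p": self.permutation_p,
            "feature_names": [str(f) for f in self.feature_names],
            "weights": self.weights.tolist(),
            "scores_pred": self.scores_pred.tolist(),
            "loadings_pred": self.loadings_pred.tolist(),
            "corr": self.corr.tolist(),
            "cov": self.cov.tolist(),
        }


def _stratified_folds(labels01: np.ndarray, folds: int, seed: int):
    """Seeded stratified k-fold assignment.

    Classes are processed in a canonical order (by smallest member index) so
    the partition is invariant under relabeling the two classes; within each
    class the indices are shuffled and dealt round-robin to folds.
    """
    n = len(labels01)
    if folds > n:
        raise ValueError("more folds than samples")
    rng = np.random.default_rng(seed)
    members: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels01):
        members.setdefault(int(lab), []).append(idx)
    fold_bins: list[list[int]] = [[] for _ in range(folds)]
    for lab in sorted(members, key=lambda l: members[l][0]):
        idxs = np.array(members[lab])
        rng.shuffle(idxs)
        for i, ix in enumerate(idxs):
            fold_bins[i % folds].append(int(ix))
    all_idx = np.arange(n)
    splits = []
    for f in fold_bins:
        test = np.array(sorted(f), dtype=int)
        if test.size == 0:
            raise ValueError("empty cross-validation fold")
        train = np.setdiff1d(all_idx, test)
        splits.append((train, test))
    return splits


def _q2_arrays(X: np.ndarray, y: np.ndarray, n_orthogonal: int, folds: int, seed: int) -> float:
    """Q² = 1 - PRESS/SS over a stratified, seed-shuffled k-fold partition."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    # y is a centered two-level coding; recover the binary labels for stratification
    labels01 = (y > y.mean()).astype(int)
    press = 0.0
    for train, test in _stratified_folds(labels01, folds, seed):
        if len(np.unique(labels01[train])) < 2:
            raise ValueError("a training fold lost one of the classes")
        Xtr = X[train]
        ytr = y[train]
        mx = Xtr.mean(axis=0)
        my = ytr.mean()
        fit = _fit_opls_arrays(Xtr - mx, ytr - my, n_orthogonal)
        pred = _predict_arrays(fit, X[test] - mx) + my
        press += float(np.sum((y[test] - pred) ** 2))
    ss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ss


def _permutation_arrays(
    X: np.ndarray,
    y: np.ndarray,
    n_orthogonal: int,
    n_permutations: int,
    seed: int,
    folds: int,
):
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate class vector")
    observed = _q2_arrays(X, y, n_orthogonal, folds, seed)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(len(y))
        null[i] = _q2_arrays(X, y[perm], n_orthogonal, folds, seed)
    p = (1.0 + np.sum(null >= observed)) / (n_permutations + 1.0)
    return float(p), null


# ---------------------------------------------------------------------------
# FeatureMatrix-level convenience surface
# ---------------------------------------------------------------------------

def fit_opls_da(
    fm: FeatureMatrix,
    groups: tuple[str, str] | None = None,
    n_orthogonal: int = 1,
    positive_class: str | None = None,
) -> OPLSDAResults:
    """Fit OPLS-DA between two groups of a Pareto-scaled feature matrix."""
    return OPLSDA.from_feature_matrix(
        fm, groups=groups, n_orthogonal=n_orthogonal, positive_class=positive_class
    ).fit()


def cross_validated_q2(
    fm: FeatureMatrix,
    groups: tuple[str, str] | None = None,
    n_orthogonal: int = 1,
    folds: int = 7,
    seed: int = 0,
) -> float:
    """Stratified k-fold Q²Y for the two-group contrast."""
    if groups is not None:
        fm = fm.subset_groups(groups)
    y, _, _ = encode_classes(list(fm.groups))
    return _q2_arrays(fm.array(), y, n_orthogonal, folds, seed)


def permutation_test(
    fm: FeatureMatrix,
    groups: tuple[str, str] | None = None,
    n_permutations: int = 2000,
    seed: int = 0,
    n_orthogonal: int = 1,
    folds: int = 7,
) -> float:
    """Label-permutation p-value of Q² with the plus-one estimator."""
    if groups is not None:
        fm = fm.subset_groups(groups)
    y, _, _ = encode_classes(list(fm.groups))
    p, _ = _permutation_arrays(fm.array(), y, n_orthogonal, n_permutations, seed, folds)
    return p


def loading_pseudospectrum(results: OPLSDAResults) -> pd.DataFrame:
    """Covariance pseudo-spectrum: Cov(t_p, x_j) heights colored by r²."""
    ppm = results.model.feature_ppm
    return pd.DataFrame(
        {
            "feature": results.feature_names,
            "ppm": ppm if ppm is not None else np.full(len(results.feature_names), np.nan),
            "covariance": results.cov,
            "r2": results.corr**2,
        }
    )
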