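"""Linear discriminant classification of regional DVR (and MMSE) features.

Subjects are classified into control / MCI / AD with linear discriminant
analysis (LDA): class means with a pooled within-class covariance
``Sigma = sum_g (n_g - 1) S_g / (N - G)`` and the rule

    g_hat(x) = argmax_g [ mu_g' Sigma^{-1} x - 1/2 mu_g' Sigma^{-1} mu_g + ln pi_g ].

An exhaustive search fits a model for every non-empty subset of the nine
regional features (optionally augmented with MMSE), ranking by leave-one-out
cross-validation and then resubstitution accuracy.  Because best-subset
search invites survivorship bias, significance of a chosen model is assessed
by a permutation test: group labels are shuffled (group counts preserved),
the model is refit on each permuted labelling, and the p-value is the
fraction of permutations classifying as well or better than the true labels.

The module follows a model/results split: :class:`LinearDiscriminant` is
built from a :class:`FeatureTable` and ``fit()`` returns a
:class:`DiscriminantResults` carrying the estimates, predictions and a
``summary()`` table; the search and permutation helpers operate on the same
objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.linalg

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable", "LinearDiscriminant", "DiscriminantResults",
    "ModelSearchResult", "PermutationResult", "fit_lda",
    "classification_pct", "loocv_pct", "exhaustive_search",
    "permutation_test", "REGIONAL_FEATURES",
]

#: Column names of the nine regional DVR features, in listing order.
REGIONAL_FEATURES = tuple(f"r{i}" for i in range(1, 10))


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------

class FeatureTable:
    """Subjects x features with group labels.

    Wraps a DataFrame with columns ``subject_id``, ``group``, optionally
    ``mmse``, and the regional features ``r1..r9``.
    """

    def __init__(self, df: pd.DataFrame, label_col: str = "group"):
        if label_col not in df.columns:
            raise ValueError(f"missing label column {label_col!r}")
        self.df = df.reset_index(drop=True)
        self.label_col = label_col
        self.groups = tuple(sorted(df[label_col].unique()))
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        codes = {g: i for i, g in enumerate(self.groups)}
        self.y = df[label_col].map(codes).to_numpy(dtype=np.intp)

    @classmethod
    def from_cohort(cls, cohort, regional=None) -> "FeatureTable":
        """Build from a phantom Cohort, using its generated regional DVRs by
        default or a (subject x 9) array of measured values."""
        df = cohort.to_dataframe()
        if regional is not None:
            regional = np.asarray(regional, dtype=float)
            for i in range(9):
                df[f"r{i+1}"] = regional[:, i]
        else:
            df = df.rename(columns={f"dvr_r{i+1}": f"r{i+1}" for i in range(9)})
        return cls(df)

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def group_counts(self) -> dict:
        return {g: int((self.y == i).sum()) for i, g in enumerate(self.groups)}

    def X(self, features) -> np.ndarray:
        missing = [f for f in features if f not in self.df.columns]
        if missing:
            raise KeyError(f"unknown feature(s) {missing}")
        X = self.df[list(features)].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError("missing values in used feature columns")
        return X

    def relabeled(self, y_codes: np.ndarray) -> "FeatureTable":
        """Copy with permuted group labels (same coding)."""
        df = self.df.copy()
        df[self.label_col] = [self.groups[c] for c in y_codes]
        return FeatureTable(df, self.label_col)


# ---------------------------------------------------------------------------
# Core LDA arithmetic (shared fast path)
# ---------------------------------------------------------------------------

def _priors_vector(mode, counts: np.ndarray) -> np.ndarray:
    if isinstance(mode, np.ndarray):
        return mode
    if mode == "equal":
        return np.full(len(counts), 1.0 / len(counts))
    if mode == "proportional":
        return counts / counts.sum()
    raise ValueError("priors must be 'equal' or 'proportional'")


def _fit_arrays(X: np.ndarray, y: np.ndarray, n_groups: int, priors):
    """Fit LDA on raw arrays; returns (means, cov, weights, bias, lam).

    ``weights`` (p x G) and ``bias`` (G,) define scores = X @ weights + bias.
    Ridge ``lam`` is 0 unless the pooled covariance was singular, in which
    case Sigma + lam*I with lam = 1e-6 tr(Sigma)/p (absolute 1e-6 when the
    trace vanishes) is used and the event logged.
    """
    n, p = X.shape
    counts = np.bincount(y, minlength=n_groups).astype(float)
    if np.any(counts < 2):
        raise ValueError("each group needs at least 2 members to fit")
    onehot = np.zeros((n_groups, n))
    onehot[y, np.arange(n)] = 1.0
    means = (onehot @ X) / counts[:, None]
    Xc = X - means[y]
    cov = (Xc.T @ Xc) / (n - n_groups)
    lam = 0.0
    pri = _priors_vector(priors, counts)
    if n <= p + n_groups:
        logger.info("n=%d <= p+G=%d: ridge regularization may engage",
                    n, p + n_groups)
    try:
        # Cholesky both solves and detects a singular (non-PD) pooled cov
        c, low = scipy.linalg.cho_factor(cov, check_finite=False)
        weights = scipy.linalg.cho_solve((c, low), means.T, check_finite=False)
        if not np.all(np.isfinite(weights)):
            raise np.linalg.LinAlgError
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError, ValueError):
        tr = np.trace(cov)
        lam = 1e-6 * tr / p if tr > 0 else 1e-6
        logger.info("singular pooled covariance: ridge lambda=%.3g", lam)
        weights = np.linalg.solve(cov + lam * np.eye(p), means.T)
    bias = -0.5 * np.einsum("gp,pg->g", means, weights) + np.log(pri)
    return means, cov, weights, bias, lam


def _predict_arrays(X: np.ndarray, weights, bias) -> np.ndarray:
    return np.argmax(X @ weights + bias, axis=1)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class LinearDiscriminant:
    """LDA model specification: a feature table, a feature subset, priors."""

    def __init__(self, table: FeatureTable, features=None,
                 priors: str = "equal"):
        self.table = table
        self.features = tuple(features) if features is not None else tuple(
            f for f in REGIONAL_FEATURES if f in table.df.columns
        )
        if not self.features:
            raise ValueError("no features to fit")
        if priors not in ("equal", "proportional"):
            raise ValueError("priors must be 'equal' or 'proportional'")
        self.priors_mode = priors

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, features, label_col="group",
                       priors="equal") -> "LinearDiscriminant":
        return cls(FeatureTable(df, label_col), features, priors)

    def fit(self) -> "DiscriminantResults":
        X = self.table.X(self.features)
        means, cov, weights, bias, lam = _fit_arrays(
            X, self.table.y, self.table.n_groups, self.priors_mode
        )
        counts = np.bincount(self.table.y, minlength=self.table.n_groups)
        pri = _priors_vector(self.priors_mode, counts.astype(float))
        return DiscriminantResults(self, means, cov, pri, weights, bias, lam)


@dataclass
class DiscriminantResults:
    """Fitted LDA: estimates, the classification rule and diagnostics."""

    model: LinearDiscriminant
    _means: np.ndarray
    _cov: np.ndarray
    _priors: np.ndarray
    _weights: np.ndarray
    _bias: np.ndarray
    regularization: float = 0.0

    @property
    def features(self) -> tuple:
        return self.model.features

    @property
    def groups(self) -> tuple:
        return self.model.table.groups

    @property
    def class_means(self) -> pd.DataFrame:
        return pd.DataFrame(self._means, index=list(self.groups),
                            columns=list(self.features))

    @property
    def pooled_cov(self) -> pd.DataFrame:
        return pd.DataFrame(self._cov, index=list(self.features),
                            columns=list(self.features))

    @property
    def priors(self) -> pd.Series:
        return pd.Series(self._priors, index=list(self.groups))

    def decision_scores(self, table: FeatureTable | None = None) -> np.ndarray:
        table = table or self.model.table
        return table.X(self.features) @ self._weights + self._bias

    def predict(self, table: FeatureTable | None = None) -> np.ndarray:
        """Predicted group labels (strings)."""
        codes = np.argmax(self.decision_scores(table), axis=1)
        return np.array([self.groups[c] for c in codes])

    def classification_pct(self, table: FeatureTable | None = None) -> float:
        """Percent of rows classified into their true group, to 0.1%."""
        table = table or self.model.table
        codes = np.argmax(self.decision_scores(table), axis=1)
        return round(100.0 * float((codes == table.y).mean()), 1)

    def summary(self) -> str:
        lines = ["Linear discriminant results",
                 "=" * 45,
                 f"Groups:          {', '.join(self.groups)}",
                 f"Features:        {', '.join(self.features)}",
                 f"N subjects:      {self.model.table.n}",
                 f"Priors:          {self.model.priors_mode}",
                 f"Regularization:  {self.regularization:g}",
                 f"Classification:  {self.classification_pct():.1f}%",
                 "",
                 "Class means:",
                 self.class_means.round(4).to_string()]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Spec-surface helpers
# ---------------------------------------------------------------------------

def fit_lda(table: FeatureTable, subset, priors="equal") -> DiscriminantResults:
    """Fit an LDA model on the given feature subset."""
    return LinearDiscriminant(table, subset, priors).fit()


def classification_pct(results: DiscriminantResults,
                       table: FeatureTable | None = None) -> float:
    return results.classification_pct(table)


def _loocv_correct_loop(X: np.ndarray, y: np.ndarray, n_groups: int,
                        priors) -> int:
    """Per-fold refit LOOCV: the reference (slow) path."""
    n = X.shape[0]
    counts_full = np.bincount(y, minlength=n_groups)
    correct = 0
    idx = np.arange(n)
    for i in range(n):
        if counts_full[y[i]] < 2:
            logger.info("LOOCV fold %d would lose group %d: scored incorrect",
                        i, y[i])
            continue
        tr = idx != i
        try:
            _, _, w, b, _ = _fit_arrays(X[tr], y[tr], n_groups, priors)
        except (ValueError, np.linalg.LinAlgError):
            logger.info("LOOCV fold %d: degenerate fit, scored incorrect", i)
            continue
        if int(np.argmax(X[i] @ w + b)) == y[i]:
            correct += 1
    return correct


def _loocv_correct(X: np.ndarray, y: np.ndarray, n_groups: int,
                   priors) -> int:
    """Number of leave-one-out folds classified correctly.

    Each fold refits the model on the remaining n-1 subjects.  The fast path
    forms every fold's class means and pooled scatter by downdating the full
    fit (algebraically identical to refitting) and solves all folds with one
    batched call; any degeneracy falls back to the explicit per-fold refit.
    """
    n, p = X.shape
    counts = np.bincount(y, minlength=n_groups).astype(float)
    if np.any(counts < 2) or n - 1 <= n_groups:
        return _loocv_correct_loop(X, y, n_groups, priors)

    onehot = np.zeros((n_groups, n))
    onehot[y, np.arange(n)] = 1.0
    means = (onehot @ X) / counts[:, None]
    Xc = X - means[y]
    scatter = Xc.T @ Xc

    # leave-one-out downdates: scatter_i = S - c_g/(c_g-1) d_i d_i'
    cg = counts[y]
    corr = (cg / (cg - 1.0))[:, None, None] * (Xc[:, :, None] * Xc[:, None, :])
    cov_i = (scatter[None] - corr) / (n - 1 - n_groups)
    means_i = np.broadcast_to(means, (n, n_groups, p)).copy()
    means_i[np.arange(n), y] = (cg[:, None] * means[y] - X) / (cg - 1.0)[:, None]
    counts_i = np.broadcast_to(counts, (n, n_groups)).copy()
    counts_i[np.arange(n), y] -= 1.0
    if isinstance(priors, str) and priors == "proportional":
        pri = counts_i / (n - 1.0)
    else:
        pri = np.full((n, n_groups), 1.0 / n_groups)

    try:
        W = np.linalg.solve(cov_i, means_i.transpose(0, 2, 1))  # (n, p, G)
    except np.linalg.LinAlgError:
        return _loocv_correct_loop(X, y, n_groups, priors)
    if not np.all(np.isfinite(W)):
        return _loocv_correct_loop(X, y, n_groups, priors)
    scores = (
        np.einsum("np,npg->ng", X, W)
        - 0.5 * np.einsum("ngp,npg->ng", means_i, W)
        + np.log(pri)
    )
    return int((scores.argmax(axis=1) == y).sum())


def loocv_pct(table: FeatureTable, subset, priors="equal") -> float:
    """Leave-one-out cross-validated classification percentage, to 0.1%."""
    X = table.X(subset)
    correct = _loocv_correct(X, table.y, table.n_groups, priors)
    return round(100.0 * correct / table.n, 1)


@dataclass
class ModelSearchResult:
    features: tuple
    resub_pct: float
    loocv_pct: float
    rank: int = 0


def _region_subsets():
    for k in range(1, 10):
        yield from combinations(REGIONAL_FEATURES, k)


def exhaustive_search(table: FeatureTable, include_mmse: bool = False,
                      priors: str = "equal") -> list:
    """Fit all 511 non-empty regional-feature subsets and rank them.

    Each subset is optionally augmented with MMSE.  Results are ranked by
    LOOCV % (descending), then resubstitution % (descending), then fewer
    features, then lexicographic subset order.
    """
    table.X(REGIONAL_FEATURES)  # validates presence
    if include_mmse and "mmse" not in table.df.columns:
        raise KeyError("mmse column required when include_mmse=True")
    X_all = table.X(
        REGIONAL_FEATURES + (("mmse",) if include_mmse else ())
    )
    y, G = table.y, table.n_groups
    col = {f: i for i, f in enumerate(REGIONAL_FEATURES)}
    results = []
    for subset in _region_subsets():
        feats = subset + (("mmse",) if include_mmse else ())
        cols = [col[f] for f in subset] + ([9] if include_mmse else [])
        X = X_all[:, cols]
        _, _, w, b, _ = _fit_arrays(X, y, G, priors)
        resub = int((_predict_arrays(X, w, b) == y).sum())
        correct = _loocv_correct(X, y, G, priors)
        results.append(ModelSearchResult(
            feats,
            round(100.0 * resub / table.n, 1),
            round(100.0 * correct / table.n, 1),
        ))
    order = sorted(
        range(len(results)),
        key=lambda i: (
            -results[i].loocv_pct, -results[i].resub_pct,
            len(results[i].features), results[i].features,
        ),
    )
    ranked = [results[i] for i in order]
    for rank, r in enumerate(ranked, start=1):
        r.rank = rank
    return ranked


@dataclass
class PermutationResult:
    """Null distribution of classification % under label permutation."""

    n_perm: int
    seed: int
    true_pct: float
    null_pcts: np.ndarray = field(repr=False)
    exceed_count: int = 0

    @property
    def p_value(self) -> float:
        return self.exceed_count / self.n_perm

    @property
    def p_str(self) -> str:
        if self.exceed_count == 0:
            return f"P < {1.0 / self.n_perm:g}"
        return f"P = {self.p_value:g}"


def permutation_test(table: FeatureTable, subset, n_perm: int = 100_000,
                     seed: int = 0, priors: str = "equal",
                     statistic: str = "resub") -> PermutationResult:
    """Group-count-preserving permutation test of a discriminant model.

    For each of ``n_perm`` random relabelings (group counts fixed), the LDA
    model is refit on the permuted labels and its classification percentage
    recorded; the p-value is the fraction of permutations performing as well
    or better than the true labelling.  ``statistic`` selects resubstitution
    accuracy (default) or leave-one-out cross-validation.  A permutation with
    a degenerate fit is scored at the modal-class rate and logged.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic not in ("resub", "loocv"):
        raise ValueError("statistic must be 'resub' or 'loocv'")
    X = table.X(subset)
    y, G, n = table.y, table.n_groups, table.n
    modal = int(np.bincount(y, minlength=G).max())

    def _n_correct(yy: np.ndarray) -> int:
        try:
            if statistic == "loocv":
                return _loocv_correct(X, yy, G, priors)
            _, _, w, b, _ = _fit_arrays(X, yy, G, priors)
            return int((_predict_arrays(X, w, b) == yy).sum())
        except (ValueError, np.linalg.LinAlgError):
            logger.info("degenerate permutation fit: scored at modal rate")
            return modal

    true_correct = _n_correct(y)
    rng = np.random.default_rng(seed)
    null_correct = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        null_correct[i] = _n_correct(rng.permutation(y))
    exceed = int((null_correct >= true_correct).sum())
    return PermutationResult(
        n_perm=n_perm, seed=seed,
        true_pct=round(100.0 * true_correct / n, 1),
        null_pcts=np.round(100.0 * null_correct / n, 1),
        exceed_count=exceed,
    )
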