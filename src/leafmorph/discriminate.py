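"""Leave-one-out linear discriminant analysis of leaf traits.

Species identity (ignoring node) and heteroblastic node (ignoring species)
are predicted from landmark traits, EFD traits, or both concatenated, with a
Gaussian equal-covariance LDA under observed class-frequency priors.  Every
prediction is leave-one-out cross-validated: each leaf is classified by a
discriminant fitted to all other leaves, which compensates for uneven
replication across species and vines.  Node is treated as a categorical class
for the LDA; its ordinal structure is used only when correlating actual with
predicted node by Spearman rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "LeaveOneOutLDA",
    "fit_lda",
    "loo_predict",
    "confusion_matrix",
    "node_rank_rho",
    "feature_set_comparison",
]

_CONSTANT_VARIANCE = 1e-12


def _frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        df = X.copy()
    else:
        X = np.asarray(X, dtype=float)
        df = pd.DataFrame(X, columns=[f"t{i}" for i in range(X.shape[1])])
    if not np.all(np.isfinite(df.to_numpy())):
        raise ValueError("non-finite trait values")
    return df


def _screen(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop near-constant columns; they carry no discriminant information."""
    variances = df.var(axis=0, ddof=1)
    dropped = list(df.columns[variances <= _CONSTANT_VARIANCE])
    if dropped:
        warnings.warn(f"dropped {len(dropped)} near-constant traits: {dropped}")
    kept = df.drop(columns=dropped)
    if kept.shape[1] == 0:
        raise ValueError("all traits constant; nothing to discriminate on")
    return kept, dropped


def _check_labels(labels: pd.Series) -> pd.Series:
    labels = pd.Series(np.asarray(labels), name="label")
    counts = labels.value_counts()
    singletons = counts[counts < 2]
    if len(counts) < 2:
        raise ValueError("need at least 2 classes")
    if len(singletons):
        raise ValueError(
            f"classes with fewer than 2 samples: {sorted(map(str, singletons.index))}"
        )
    return labels


class LeaveOneOutLDA:
    """Gaussian LDA with pooled within-class covariance and LOO prediction.

    The decision rule is the maximum posterior under equal-covariance
    Gaussians with observed class-frequency priors (scikit-learn's
    ``LinearDiscriminantAnalysis`` with the SVD solver, which tolerates a
    singular pooled covariance by truncating negligible directions — the
    role a diagonal ridge would otherwise play).  Near-constant traits are
    screened off and recorded before fitting.

    Attributes (after ``fit``)
    --------------------------
    classes_, priors_, means_ : class labels, frequencies, trait-space means.
    kept_traits_, dropped_traits_ : screening record.
    scalings_ : discriminant axes of the underlying solver.
    """

    def __init__(self, ridge: float = 1e-8):
        self.ridge = ridge  # retained for interface compatibility; see class docstring

    def get_params(self, deep: bool = True) -> dict:
        return {"ridge": self.ridge}

    def set_params(self, **params) -> "LeaveOneOutLDA":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "LeaveOneOutLDA":
        df = _frame(X)
        labels = _check_labels(y)
        kept, dropped = _screen(df)
        self.kept_traits_ = list(kept.columns)
        self.dropped_traits_ = dropped
        self._lda = LinearDiscriminantAnalysis(solver="svd")
        self._lda.fit(kept.to_numpy(), labels.to_numpy())
        self.classes_ = self._lda.classes_
        self.priors_ = self._lda.priors_
        self.means_ = self._lda.means_
        self.scalings_ = self._lda.scalings_
        return self

    def _kept(self, X) -> np.ndarray:
        return _frame(X)[self.kept_traits_].to_numpy()

    def predict(self, X) -> np.ndarray:
        return self._lda.predict(self._kept(X))

    def predict_proba(self, X) -> np.ndarray:
        return self._lda.predict_proba(self._kept(X))

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def loo_predict(self, X, y) -> pd.DataFrame:
        """Leave-one-out prediction: one row per sample, fitted without it.

        Returns a DataFrame with ``actual``, ``predicted`` and one posterior
        column per class.  Any fold whose training split violates the fit
        preconditions raises an error naming the fold.
        """
        df = _frame(X)
        labels = _check_labels(y)
        if len(df) != len(labels):
            raise ValueError("traits and labels must have equal length")
        kept, _ = _screen(df)
        Xv = kept.to_numpy()
        yv = labels.to_numpy()
        classes = np.unique(yv)
        n = len(yv)
        preds = np.empty(n, dtype=object)
        post = np.zeros((n, len(classes)))
        idx = np.arange(n)
        for i in range(n):
            tr = idx != i
            ytr = yv[tr]
            # a fold may reduce the held-out sample's class to one member;
            # the discriminant is still defined as long as 2 classes remain
            if len(np.unique(ytr)) < 2:
                raise ValueError(f"LOO fold {i}: training split violates LDA preconditions")
            lda = LinearDiscriminantAnalysis(solver="svd")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # collinearity warnings per fold
                lda.fit(Xv[tr], ytr)
            p = lda.predict_proba(Xv[i : i + 1])[0]
            # map fold classes onto the global class order
            for c, pc in zip(lda.classes_, p):
                post[i, np.searchsorted(classes, c)] = pc
            preds[i] = lda.predict(Xv[i : i + 1])[0]
        out = pd.DataFrame(
            {"actual": yv, "predicted": preds},
            index=df.index,
        )
        for j, c in enumerate(classes):
            out[f"p_{c}"] = post[:, j]
        return out


def fit_lda(traits, labels, ridge: float = 1e-8) -> LeaveOneOutLDA:
    """Fit a pooled-covariance LDA on a named trait matrix."""
    return LeaveOneOutLDA(ridge=ridge).fit(traits, labels)


def loo_predict(traits, labels) -> pd.DataFrame:
    """Leave-one-out LDA prediction (functional wrapper)."""
    return LeaveOneOutLDA().loo_predict(traits, labels)


@dataclass
class ConfusionMatrix:
    """Row-normalized confusion proportions plus raw counts."""

    labels: list
    proportions: pd.DataFrame  # actual x predicted, rows sum to 1
    counts: pd.DataFrame

    def accuracy(self) -> float:
        total = self.counts.to_numpy().sum()
        diag = sum(
            self.counts.loc[l, l] for l in self.counts.index if l in self.counts.columns
        )
        return float(diag / total)


def confusion_matrix(actual, predicted) -> ConfusionMatrix:
    """Confusion matrix with actual classes as rows, predicted as columns.

    Rows are normalized to proportions (the fill of the matrix display);
    predicted labels absent from the actual set are kept as extra columns.
    """
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    labels = sorted(set(actual.tolist()) | set(predicted.tolist()))
    counts = pd.crosstab(pd.Series(actual, name="actual"), pd.Series(predicted, name="predicted"))
    counts = counts.reindex(index=sorted(set(actual.tolist())), columns=labels, fill_value=0)
    row_sums = counts.sum(axis=1)
    proportions = counts.div(row_sums.replace(0, np.nan), axis=0).fillna(0.0)
    return ConfusionMatrix(labels=labels, proportions=proportions, counts=counts)


def node_rank_rho(actual_nodes, predicted_nodes) -> tuple[float, float]:
    """Spearman rank correlation of actual vs LOO-predicted node positions.

    Tie-corrected rho with a two-sided p-value from the t approximation
    ``t = rho * sqrt((n - 2) / (1 - rho^2))``.
    """
    a = np.asarray(actual_nodes, dtype=float)
    b = np.asarray(predicted_nodes, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need at least 5 paired node values")
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        raise ValueError("constant node vector: rank correlation undefined")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def feature_set_comparison(
    landmark_traits,
    efd_traits,
    labels,
    group_key=None,
    min_group_size: int = 2,
) -> pd.DataFrame:
    """Per-group LOO accuracy of landmark traits, EFD traits, and both.

    ``both`` is the column-concatenation of the two matrices.  Accuracies are
    percent correct within each group (by default the class labels
    themselves, i.e. per-class recall).  The ``max`` column names the best
    feature set, ties broken deterministically both > landmark > efd;
    exact ties are flagged in ``tied``.  Groups smaller than
    ``min_group_size`` are excluded with a warning.
    """
    lm = _frame(landmark_traits)
    ef = _frame(efd_traits)
    if list(lm.index) != list(ef.index):
        raise ValueError("landmark and EFD trait matrices must share sample ids")
    if lm.columns.intersection(ef.columns).size:
        raise ValueError("landmark and EFD trait names overlap")
    labels = pd.Series(np.asarray(labels), index=lm.index, name="label")
    groups = labels if group_key is None else pd.Series(np.asarray(group_key), index=lm.index)

    small = groups.value_counts()
    excluded = small[small < min_group_size].index.tolist()
    if excluded:
        warnings.warn(f"excluded groups with < {min_group_size} samples: {excluded}")
        keep = ~groups.isin(excluded)
        lm, ef, labels, groups = lm[keep], ef[keep], labels[keep], groups[keep]

    both = pd.concat([lm, ef], axis=1)
    sets = {"landmark": lm, "efd": ef, "both": both}
    correct = {}
    for name, mat in sets.items():
        res = loo_predict(mat, labels)
        correct[name] = pd.Series(res["predicted"].to_numpy() == res["actual"].to_numpy(),
                                  index=mat.index)

    rows = []
    precedence = ["both", "landmark", "efd"]
    for g in sorted(groups.unique(), key=str):
        sel = groups == g
        accs = {name: 100.0 * float(correct[name][sel].mean()) for name in sets}
        best = max(precedence, key=lambda nm: (accs[nm], -precedence.index(nm)))
        tied = sum(1 for nm in sets if np.isclose(accs[nm], accs[best])) > 1
        rows.append({"group": g, "n": int(sel.sum()),
                     "landmark_pct": accs["landmark"], "efd_pct": accs["efd"],
                     "both_pct": accs["both"], "max": best, "tied": tied})
    return pd.DataFrame(rows).set_index("group")
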