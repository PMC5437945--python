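"""Covariance PCA morphospaces and eigenleaf reconstruction.

Both trait blocks — superimposed landmark coordinates (x1..x15, y1..y15) and
normalized EFD coefficients (A1..D20) — share units within the block, so the
decomposition is covariance-based (no per-trait standardization).  Eigenleaves
are theoretical shapes obtained by displacing the trait mean along one
principal component by a multiple of that component's standard deviation and
mapping the resulting trait vector back to a landmark configuration or, via
the inverse Fourier series, to a contour.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .efd import HarmonicCoefficients, reconstruct_contour

__all__ = [
    "MorphospacePCA",
    "fit_pca",
    "eigenleaf_landmarks",
    "eigenleaf_contour",
]

_CONSTANT_VARIANCE = 1e-12


class MorphospacePCA:
    """Covariance PCA over a named trait matrix.

    Parameters
    ----------
    drop_constant : bool
        Drop columns with variance below 1e-12 before the decomposition and
        restore them (at their constant values) when reconstructing trait
        vectors (default True).  For normalized EFD traits this removes the
        normalization constants A1 = 1, B1 = C1 = 0, which are invariants of
        the normalization rather than traits.

    Attributes
    ----------
    feature_names_in_, kept_columns_, dropped_columns_ : column bookkeeping;
        ``constant_values_`` holds the value of each dropped column.
    mean_ : per-kept-column means.
    components_ : (n_components, n_kept) orthonormal loadings, each row's
        largest-magnitude entry made positive.
    explained_variance_, explained_variance_ratio_ : eigenvalues (descending)
        and variance fractions (summing to 1).
    scores_ : (n_samples, n_components) training scores.
    """

    def __init__(self, drop_constant: bool = True):
        self.drop_constant = drop_constant

    def get_params(self, deep: bool = True) -> dict:
        return {"drop_constant": self.drop_constant}

    def set_params(self, **params) -> "MorphospacePCA":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @staticmethod
    def _frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            df = X
        else:
            X = np.asarray(X, dtype=float)
            df = pd.DataFrame(X, columns=[f"t{i}" for i in range(X.shape[1])])
        if df.columns.duplicated().any():
            raise ValueError("trait names must be unique")
        if not np.all(np.isfinite(df.to_numpy())):
            raise ValueError("non-finite trait values")
        return df

    def fit(self, X, y=None) -> "MorphospacePCA":
        df = self._frame(X)
        if df.shape[0] < 3:
            raise ValueError("PCA requires at least 3 samples")
        variances = df.var(axis=0, ddof=1)
        if self.drop_constant:
            keep = variances > _CONSTANT_VARIANCE
        else:
            keep = pd.Series(True, index=df.columns)
        self.feature_names_in_ = list(df.columns)
        self.kept_columns_ = list(df.columns[keep])
        self.dropped_columns_ = list(df.columns[~keep])
        self.constant_values_ = df[self.dropped_columns_].mean(axis=0).to_dict()

        kept = df[self.kept_columns_].to_numpy()
        if len(self.kept_columns_) == 0:
            # all traits constant: zero-component model
            self.mean_ = np.zeros(0)
            self.components_ = np.zeros((0, 0))
            self.explained_variance_ = np.zeros(0)
            self.explained_variance_ratio_ = np.zeros(0)
            self.scores_ = np.zeros((df.shape[0], 0))
            self.sample_ids_ = list(df.index)
            return self
        pca = PCA(svd_solver="full")
        scores = pca.fit_transform(kept)
        comps = pca.components_
        # sign convention: largest-|loading| entry of each component positive
        for i in range(comps.shape[0]):
            j = np.argmax(np.abs(comps[i]))
            if comps[i, j] < 0:
                comps[i] = -comps[i]
                scores[:, i] = -scores[:, i]
        self.mean_ = pca.mean_
        self.components_ = comps
        self.explained_variance_ = pca.explained_variance_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.scores_ = scores
        self.sample_ids_ = list(df.index)
        return self

    def transform(self, X) -> np.ndarray:
        df = self._frame(X)
        kept = df[self.kept_columns_].to_numpy()
        return (kept - self.mean_) @ self.components_.T

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).scores_

    def inverse_transform(self, scores: np.ndarray) -> pd.DataFrame:
        """Scores back to the full trait layout, dropped constants restored."""
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        kept = scores @ self.components_ + self.mean_
        out = pd.DataFrame(kept, columns=self.kept_columns_)
        for col in self.dropped_columns_:
            out[col] = self.constant_values_[col]
        return out[self.feature_names_in_]

    @property
    def n_components_(self) -> int:
        return self.components_.shape[0]

    def eigen_trait_vector(self, pc: int, sd_multiplier: float) -> pd.Series:
        """Trait vector at ``mean + sd_multiplier * sqrt(eigenvalue) * loading``.

        ``pc`` is 1-based; ``sd_multiplier = 0`` returns the trait mean.
        """
        if not 1 <= pc <= self.n_components_:
            raise ValueError(f"pc {pc} outside 1..{self.n_components_}")
        i = pc - 1
        kept = self.mean_ + sd_multiplier * np.sqrt(self.explained_variance_[i]) * self.components_[i]
        vec = pd.Series(kept, index=self.kept_columns_)
        for col in self.dropped_columns_:
            vec[col] = self.constant_values_[col]
        return vec[self.feature_names_in_]

    def variance_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "eigenvalue": self.explained_variance_,
                "variance_fraction": self.explained_variance_ratio_,
            },
            index=[f"PC{i}" for i in range(1, self.n_components_ + 1)],
        )


def fit_pca(traits, drop_constant: bool = True) -> MorphospacePCA:
    """Functional wrapper: fit a covariance PCA on a named trait matrix."""
    return MorphospacePCA(drop_constant=drop_constant).fit(traits)


def eigenleaf_landmarks(model: MorphospacePCA, pc: int, sd_multiplier: float) -> np.ndarray:
    """Eigenleaf as a (15, 2) landmark configuration.

    Requires a model trained on the 30 landmark traits x1..x15, y1..y15.
    """
    names = model.feature_names_in_
    k = len(names) // 2
    expected = [f"x{i}" for i in range(1, k + 1)] + [f"y{i}" for i in range(1, k + 1)]
    if names != expected:
        raise ValueError("model was not trained on landmark coordinate traits x1..y15")
    vec = model.eigen_trait_vector(pc, sd_multiplier).to_numpy()
    return np.column_stack([vec[:k], vec[k:]])


def eigenleaf_contour(
    model: MorphospacePCA, pc: int, sd_multiplier: float, n_points: int = 200
) -> np.ndarray:
    """Eigenleaf as a closed contour reconstructed from EFD traits.

    Requires a model trained on the harmonic-coefficient traits A1..Dn; the
    normalization constants dropped as zero-variance are restored before the
    inverse Fourier series is evaluated.
    """
    names = model.feature_names_in_
    n = len(names) // 4
    expected = [f"{ltr}{k}" for ltr in "ABCD" for k in range(1, n + 1)]
    if names != expected:
        raise ValueError("model was not trained on harmonic coefficient traits A1..Dn")
    vec = model.eigen_trait_vector(pc, sd_multiplier).to_numpy()
    coeffs = HarmonicCoefficients.from_trait_vector(vec, n, normalized=False)
    return reconstruct_contour(coeffs, n_use=n, n_points=n_points)
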