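"""Environmental gradient (PCA) and dissolved-organic-matter quality indices.

The multi-lake environmental gradient is the first principal component of the
correlation matrix of the lake morphometric / chemical / land-use / OM-quality
variables, oriented so that catchment forest cover loads negatively (PC1 then
runs from forested, high-DOC lakes to eutrophic agricultural lakes).  SUVA
(specific UV absorbance at 254 nm) and the spectral slope ratio SR
(S275-295 / S350-400 of the log absorption spectrum) characterise DOM
aromaticity and molecular weight; the N:C mass ratio of particulate OM traces
its terrestrial vs. aquatic origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA


def read_spectrum(path):
    """Read a two-column (wavelength nm, decadic absorbance) CSV.

    Returns ``(wavelengths, absorbances)`` arrays sorted by wavelength.
    """
    spec = pd.read_csv(path)
    if spec.shape[1] < 2:
        raise ValueError(f"spectrum file {path} needs two columns (wavelength, absorbance)")
    spec = spec.sort_values(spec.columns[0])
    wl = spec.iloc[:, 0].to_numpy(float)
    ab = spec.iloc[:, 1].to_numpy(float)
    if np.any(ab < 0):
        raise ValueError("absorbances must be >= 0")
    return wl, ab


def compute_suva(wavelengths, absorbances, doc, path_length_m=0.01):
    """Specific UV absorbance at 254 nm, L mg^-1 m^-1.

    ``(A254 / path length in m) / DOC``; A254 is linearly interpolated when
    254 nm is not sampled exactly.  Absorbance is decadic.
    """
    wl = np.asarray(wavelengths, float)
    ab = np.asarray(absorbances, float)
    if doc <= 0:
        raise ValueError("DOC concentration must be > 0")
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    if not (wl[0] <= 254.0 <= wl[-1]):
        raise ValueError("spectrum does not cover 254 nm")
    a254 = float(np.interp(254.0, wl, ab))
    return (a254 / path_length_m) / doc


def _neg_log_slope(wl, ab, lo, hi):
    m = (wl >= lo) & (wl <= hi)
    if m.sum() < 3:
        raise ValueError(f"fewer than 3 spectral points in [{lo}, {hi}] nm")
    if np.any(ab[m] <= 0):
        raise ValueError(f"nonpositive absorbance in [{lo}, {hi}] nm window")
    slope = np.polyfit(wl[m], np.log(ab[m]), 1)[0]
    return -slope


def compute_sr(wavelengths, absorbances):
    """Spectral slope ratio S275-295 / S350-400.

    Each S is the negated OLS slope of ln(absorption) on wavelength over its
    window, so S is positive for a decaying spectrum.
    """
    wl = np.asarray(wavelengths, float)
    ab = np.asarray(absorbances, float)
    s_short = _neg_log_slope(wl, ab, 275.0, 295.0)
    s_long = _neg_log_slope(wl, ab, 350.0, 400.0)
    if s_long == 0:
        raise ZeroDivisionError("long-wavelength spectral slope is zero; SR undefined")
    return s_short / s_long


def compute_nc_ratio(n_mass, c_mass):
    """N:C ratio by mass of particulate organic matter."""
    if c_mass <= 0:
        raise ValueError("carbon mass fraction must be > 0")
    if n_mass < 0:
        raise ValueError("nitrogen mass fraction must be >= 0")
    return n_mass / c_mass


@dataclass
class PcaResult:
    """Scores per lake, loadings as variable-score Pearson correlations,
    variance proportions per component, and the number of variables used."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_ratio: np.ndarray
    n_variables: int


class EnvironmentPCA(BaseEstimator, TransformerMixin):
    """Correlation-matrix PCA of the lake environmental table.

    Variables are standardised to zero mean / unit variance (so the PCA
    operates on the correlation matrix), loadings are reported as Pearson
    correlations between each original variable and each score, and the PC1
    sign is oriented so the forest-cover variable loads negatively (falling
    back to making the largest-magnitude PC1 loading positive when no forest
    column is present).

    Parameters
    ----------
    n_components : int, retained components (default 3).
    forest_col : substring identifying the forest-cover column
        (default ``"forest"``, case-insensitive).
    min_variables : minimum number of complete numeric columns required
        (default 15).

    Attributes
    ----------
    scores_, loadings_, variance_ratio_, n_variables_, columns_
    """

    def __init__(self, n_components: int = 3, forest_col: str = "forest", min_variables: int = 15):
        self.n_components = n_components
        self.forest_col = forest_col
        self.min_variables = min_variables

    def _validate(self, X: pd.DataFrame) -> pd.DataFrame:
        num = X.select_dtypes(include=[np.number])
        if len(num) < 3:
            raise ValueError("PCA needs at least 3 lakes")
        if num.shape[1] < self.min_variables:
            raise ValueError(
                f"PCA needs >= {self.min_variables} complete numeric variables, got {num.shape[1]}"
            )
        na = num.isna()
        if na.any().any():
            col = na.any()[na.any()].index[0]
            lake = num.index[na[col]][0]
            raise ValueError(f"missing environmental value: lake {lake!r}, variable {col!r}")
        zero_var = num.std(ddof=1) == 0
        if zero_var.any():
            raise ValueError(f"constant environmental variable: {zero_var[zero_var].index[0]!r}")
        return num

    def fit(self, X: pd.DataFrame, y=None):
        num = self._validate(X)
        self.columns_ = list(num.columns)
        self.mean_ = num.mean()
        self.std_ = num.std(ddof=1)
        Z = (num - self.mean_) / self.std_
        k = min(self.n_components, Z.shape[1], len(Z) - 1)
        self._pca = PCA(n_components=k)
        scores = self._pca.fit_transform(Z.to_numpy())

        # deterministic sign orientation
        flip = np.ones(k)
        forest_cols = [c for c in self.columns_ if self.forest_col.lower() in c.lower()]
        for j in range(k):
            corr = np.array([np.corrcoef(num[c], scores[:, j])[0, 1] for c in self.columns_])
            if j == 0 and forest_cols:
                if corr[self.columns_.index(forest_cols[0])] > 0:
                    flip[j] = -1.0
            elif corr[np.argmax(np.abs(corr))] < 0:
                flip[j] = -1.0
        scores = scores * flip
        self._flip = flip

        names = [f"PC{j + 1}" for j in range(k)]
        self.scores_ = pd.DataFrame(scores, index=num.index, columns=names)
        self.loadings_ = pd.DataFrame(
            {
                n: [np.corrcoef(num[c], self.scores_[n])[0, 1] for c in self.columns_]
                for n in names
            },
            index=self.columns_,
        )
        self.variance_ratio_ = self._pca.explained_variance_ratio_.copy()
        self.n_variables_ = len(self.columns_)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        Z = (X[self.columns_] - self.mean_) / self.std_
        scores = self._pca.transform(Z.to_numpy()) * self._flip
        return pd.DataFrame(scores, index=X.index, columns=self.scores_.columns)


def run_pca(env: pd.DataFrame, n_components: int = 3, **kwargs) -> PcaResult:
    """Functional wrapper over :class:`EnvironmentPCA`.

    ``env`` may carry a ``lake_id`` column (used as index) plus numeric
    variables.
    """
    if "lake_id" in env.columns:
        env = env.set_index("lake_id")
    est = EnvironmentPCA(n_components=n_components, **kwargs).fit(env)
    return PcaResult(
        scores=est.scores_,
        loadings=est.loadings_,
        variance_ratio=est.variance_ratio_,
        n_variables=est.n_variables_,
    )
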