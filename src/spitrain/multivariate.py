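"""PCA of SPI feature tables, pairwise Pearson correlations, group tests.

The five SPI features live on very different scales (counts in the
thousands, intervals in milliseconds), so each is log10-transformed and
standardized before the singular value decomposition.  The SVD sign is
arbitrary; each component is flipped so that its largest-magnitude loading
is positive, which makes results stable across library versions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .ipi_stats import FEATURE_COLUMNS

__all__ = [
    "PCAResult",
    "validate_feature_table",
    "pca_features",
    "pearson_matrix",
    "compare_groups",
    "group_ellipses",
]


@dataclass
class PCAResult:
    scores: pd.DataFrame        # individuals x components
    loadings: pd.DataFrame      # features x components, unit-norm columns
    explained_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return int(self.explained_fraction.size)


def validate_feature_table(table: pd.DataFrame, features: Sequence[str] = FEATURE_COLUMNS) -> pd.DataFrame:
    missing = [c for c in features if c not in table.columns]
    if missing:
        raise ValueError(f"feature table is missing columns {missing}")
    values = table[list(features)].astype(float)
    if values.isna().any().any():
        raise ValueError("feature table contains missing cells")
    if (values <= 0).any().any():
        bad = [c for c in features if (values[c] <= 0).any()]
        raise ValueError(f"features must be strictly positive (log-transformable): {bad}")
    return values


def _svd_pca(z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of an already-prepared matrix, with the deterministic sign fix.

    Returns (scores, loadings, explained_fraction); loading columns have
    unit norm and the largest-|loading| entry of each component is positive.
    """
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(z)
    loadings = pca.components_.T  # features x components
    for j in range(loadings.shape[1]):
        k = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return scores, loadings, pca.explained_variance_ratio_


def pca_features(table: pd.DataFrame, features: Sequence[str] = FEATURE_COLUMNS) -> PCAResult:
    """Log10-transform, standardize and decompose a feature table.

    Raises ``ValueError`` (naming the feature) if any column is constant
    after the log transform, and if fewer than 3 individuals are supplied.
    """
    values = validate_feature_table(table, features)
    if len(values) < 3:
        raise ValueError("PCA needs at least 3 individuals")
    logged = np.log10(values.to_numpy())
    sd = logged.std(axis=0, ddof=1)
    constant = [f for f, s in zip(features, sd) if s == 0]
    if constant:
        raise ValueError(f"constant feature column(s) after log transform: {constant}")
    z = (logged - logged.mean(axis=0)) / sd
    scores, loadings, explained = _svd_pca(z)
    pcs = [f"PC{j + 1}" for j in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=table.index, columns=pcs),
        loadings=pd.DataFrame(loadings, index=list(features), columns=pcs),
        explained_fraction=explained,
    )


def pearson_matrix(
    table: pd.DataFrame, features: Sequence[str] = FEATURE_COLUMNS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and p-values; constant columns yield NaN."""
    values = validate_feature_table(table, features)
    if len(values) < 3:
        raise ValueError("Pearson matrix needs at least 3 individuals")
    k = len(features)
    r = np.eye(k)
    p = np.zeros((k, k))
    cols = values.to_numpy().T
    for i in range(k):
        for j in range(i + 1, k):
            if cols[i].std() == 0 or cols[j].std() == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", stats.ConstantInputWarning)
                res = stats.pearsonr(cols[i], cols[j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = list(features)
    return pd.DataFrame(r, index=idx, columns=idx), pd.DataFrame(p, index=idx, columns=idx)


def compare_groups(groups: Mapping[str, Sequence[float]], test: str = "two_sample_t") -> dict:
    """Two-sample t (Welch) or Kruskal-Wallis comparison of labelled groups."""
    for label, values in groups.items():
        if len(values) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 values")
    samples = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    labels = list(samples)
    if test == "two_sample_t":
        if len(samples) != 2:
            raise ValueError("two_sample_t requires exactly 2 groups")
        a, b = samples[labels[0]], samples[labels[1]]
        statistic, pvalue = stats.ttest_ind(a, b, equal_var=False)
    elif test == "kruskal_wallis":
        if len(samples) < 2:
            raise ValueError("kruskal_wallis requires at least 2 groups")
        statistic, pvalue = stats.kruskal(*samples.values())
    else:
        raise ValueError(f"unknown test {test!r}")
    means = {k: float(v.mean()) for k, v in samples.items()}
    larger = max(means, key=means.get)
    return {
        "test": test,
        "statistic": float(statistic),
        "pvalue": float(pvalue),
        "means": means,
        "larger_group": larger,
    }


def group_ellipses(
    scores: pd.DataFrame,
    labels: Sequence[str],
    components: tuple[str, str] = ("PC1", "PC2"),
    prob: float = 0.68,
) -> pd.DataFrame:
    """68% normal-contour ellipse parameters per group, as plot annotations.

    Returns one row per group with center, semi-axes and orientation of the
    bivariate-normal contour containing ``prob`` of the mass.
    """
    scale = np.sqrt(stats.chi2.ppf(prob, df=2))
    rows = []
    labels = np.asarray(labels)
    xy = scores[list(components)].to_numpy()
    for group in pd.unique(labels):
        pts = xy[labels == group]
        if len(pts) < 3:
            continue
        cov = np.cov(pts.T)
        eigval, eigvec = np.linalg.eigh(cov)
        rows.append(
            {
                "group": group,
                "center_x": pts[:, 0].mean(),
                "center_y": pts[:, 1].mean(),
                "semi_major": scale * np.sqrt(eigval[1]),
                "semi_minor": scale * np.sqrt(max(eigval[0], 0.0)),
                "angle_deg": float(np.degrees(np.arctan2(eigvec[1, 1], eigvec[0, 1]))),
                "n": len(pts),
            }
        )
    return pd.DataFrame(rows)
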