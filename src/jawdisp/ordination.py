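"""Standardization and principal component analysis of continuous traits.

The continuous measurements are Z-transformed (each trait to mean 0,
sample SD 1 with the n-1 denominator) before PCA so that traits with
different natural scales contribute equal weight. PCA is computed by SVD
of the column-centered table; eigenvalue_k = singular_value_k^2 / (n-1).

The :class:`Ordination` container is shared with the principal coordinate
analysis of discrete characters (see :mod:`jawdisp.characters`); there the
loadings are ``None``. Note that axis importance tables sometimes print
per-axis standard deviations (sqrt of eigenvalue) under an "eigenvalue"
heading, so both are carried.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["Ordination", "z_transform", "pca"]


@dataclass
class Ordination:
    """Scores plus the variance decomposition of an ordination.

    Attributes
    ----------
    scores : DataFrame, species x axes.
    eigenvalues : per-axis variance of the scores (n-1 denominator).
    sdevs : square roots of the eigenvalues.
    proportion : fraction of total (positive-axis) variance per axis.
    loadings : trait x axis coefficients; ``None`` for PCoA.
    method : "pca" or "pcoa".
    """

    scores: pd.DataFrame
    eigenvalues: np.ndarray
    proportion: np.ndarray
    loadings: pd.DataFrame | None = None
    method: str = "pca"

    @property
    def sdevs(self) -> np.ndarray:
        return np.sqrt(self.eigenvalues)

    @property
    def cumulative_proportion(self) -> np.ndarray:
        return np.cumsum(self.proportion)

    def n_axes_for(self, target: float) -> int:
        """Smallest axis count whose cumulative variance reaches ``target``."""
        cum = self.cumulative_proportion
        idx = np.searchsorted(cum, target - 1e-12)
        if idx >= len(cum):
            raise InputError(f"cumulative variance never reaches {target}")
        return int(idx) + 1

    def variance_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "eigenvalue": self.eigenvalues,
                "sdev": self.sdevs,
                "proportion": self.proportion,
                "cumulative": self.cumulative_proportion,
            },
            index=self.scores.columns,
        )


def _check_trait_table(t: pd.DataFrame) -> pd.DataFrame:
    t = t.astype(float)
    if t.shape[0] < 2:
        raise InputError("trait table needs at least 2 species")
    if t.shape[1] < 1:
        raise InputError("trait table needs at least 1 trait")
    if not np.all(np.isfinite(t.to_numpy())):
        bad = t.columns[t.isna().any() | ~np.isfinite(t).all()].tolist()
        raise InputError(f"trait table has non-finite values in columns {bad}")
    return t


def z_transform(t: pd.DataFrame) -> pd.DataFrame:
    """Scale each trait column to mean 0 and sample SD 1 (n-1 denominator)."""
    t = _check_trait_table(t)
    sd = t.std(ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise InputError(f"constant trait column(s): {constant}")
    return (t - t.mean()) / sd


def pca(t: pd.DataFrame) -> Ordination:
    """Principal component analysis via SVD of the centered trait table.

    The caller decides about standardization (the pipeline applies
    :func:`z_transform` first by default). Axis signs are fixed so that
    the largest-magnitude loading of each axis is positive, making score
    tables reproducible across LAPACK builds.
    """
    t = _check_trait_table(t)
    x = t.to_numpy() - t.to_numpy().mean(axis=0)
    n = x.shape[0]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigenvalues = s**2 / (n - 1)

    # deterministic sign: largest-|loading| entry of each axis positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]

    axes = [f"PC{i + 1}" for i in range(len(s))]
    scores = pd.DataFrame(u * s, index=t.index, columns=axes)
    loadings = pd.DataFrame(vt.T, index=t.columns, columns=axes)
    total = eigenvalues.sum()
    if total == 0:
        raise InputError("trait table has zero total variance")
    return Ordination(
        scores=scores,
        eigenvalues=eigenvalues,
        proportion=eigenvalues / total,
        loadings=loadings,
        method="pca",
    )
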