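"""Exploratory views of a spectra table: group mean spectra and PCA.

Mirrors the study's exploratory workflow: relative-reflectance spectra are
averaged per group (cultivar, stage, organ, or combinations) and projected
onto principal components to visualize unsupervised class separation.  PCA is
run on mean-centered, unscaled spectra by default — all columns share units —
with an optional unit-variance scaling flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import SpectraTable

__all__ = ["PCAResult", "GroupMeanSpectra", "pca_explore", "group_mean_spectra"]


@dataclass
class PCAResult:
    scores: np.ndarray  # (samples, components)
    variance_fractions: np.ndarray  # non-increasing, sum <= 1
    loadings: np.ndarray  # (components, wavelengths)
    wavelengths: np.ndarray

    @property
    def variance_percent(self) -> np.ndarray:
        """Explained variance per component, in percent (as reported in plots)."""
        return 100.0 * self.variance_fractions


def pca_explore(
    table: SpectraTable, n_components: int = 2, scale: bool = False
) -> PCAResult:
    """Principal components of the spectral matrix.

    Columns are mean-centered internally (and optionally scaled to unit
    variance).  The sign of each component is fixed so its largest-magnitude
    loading is positive, making scores reproducible across sample orderings.
    """
    X = table.values
    n, p = X.shape
    max_comp = min(n - 1, p)
    if not 1 <= n_components <= max_comp:
        raise ValueError(
            f"n_components={n_components} outside [1, {max_comp}] for {n}x{p} data"
        )
    if scale:
        sd = X.std(axis=0)
        X = X / np.where(sd < 1e-12, 1.0, sd)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    for i in range(n_components):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1
            scores[:, i] *= -1
    return PCAResult(
        scores=scores,
        variance_fractions=pca.explained_variance_ratio_,
        loadings=loadings,
        wavelengths=table.wavelengths,
    )


@dataclass
class GroupMeanSpectra:
    """Wavelength-wise mean and sd per group, groups sorted by label."""

    grouping: tuple
    mean: pd.DataFrame  # index = group labels, columns = wavelengths
    sd: pd.DataFrame
    counts: pd.Series
    wavelengths: np.ndarray


def group_mean_spectra(table: SpectraTable, grouping) -> GroupMeanSpectra:
    """Mean spectrum and spread per metadata group.

    ``grouping`` is a metadata field name or list of names; groups appear in
    sorted label order.  Standard deviation uses ddof=1 (NaN for single-row
    groups).
    """
    if isinstance(grouping, str):
        grouping = [grouping]
    grouping = list(grouping)
    missing = [g for g in grouping if g not in table.metadata.columns]
    if missing:
        raise KeyError(f"grouping fields not in metadata: {missing}")
    df = pd.DataFrame(table.values, columns=table.wavelengths)
    keys = table.metadata.reset_index(drop=True)[grouping]
    grouped = df.groupby([keys[g] for g in grouping], sort=True)
    return GroupMeanSpectra(
        grouping=tuple(grouping),
        mean=grouped.mean(),
        sd=grouped.std(ddof=1),
        counts=grouped.size(),
        wavelengths=table.wavelengths,
    )
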