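"""Phase-specific PCA of log10 mean normalized peak areas.

Replicates are averaged per line within the chosen growth phase, abundances
are log10-transformed and feature-centered (no unit-variance scaling by
default), and the line x feature matrix is decomposed by SVD.  Besides
scores and loadings, the per-feature *contribution* to each component — the
squared loading, normalized to sum 1 over features — identifies which
compounds dominate the separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .peak_table import PeakTable, PeakTableError


@dataclass
class PCAResult:
    phase: str
    scores: pd.DataFrame  # lines x components
    loadings: pd.DataFrame  # features x components
    explained_variance_ratio: np.ndarray
    contributions: pd.DataFrame  # features x components, columns sum to 1
    mean_: pd.Series  # per-feature center
    dropped_features: list


class PhasePCA(BaseEstimator):
    """PCA of replicate-averaged log10 abundances for one growth phase.

    Parameters
    ----------
    phase : str
        Growth phase to analyze ("exponential" or "stationary").
    n_components : int, optional
        Number of components kept; default all.
    scale : bool
        Also divide centered features by their standard deviation.

    Attributes (after fit)
    ----------------------
    scores_, loadings_, explained_variance_ratio_, contributions_, result_.
    Sign convention: within each component the feature with the largest
    absolute loading has a positive loading, so output is reproducible
    across SVD implementations.
    """

    def __init__(self, phase: str, n_components: int | None = None, scale: bool = False):
        self.phase = phase
        self.n_components = n_components
        self.scale = scale

    def fit(self, pt: PeakTable, y=None):
        if pt.stage != "imputed":
            raise PeakTableError(f"PCA expects an imputed table, got stage {pt.stage!r}")
        sids = pt.sample_ids(phase=self.phase)
        if len(sids) < 3:
            raise PeakTableError(f"need >= 3 samples in phase {self.phase!r}, got {len(sids)}")
        if pt.n_features < 2:
            raise PeakTableError("need >= 2 features")
        meta = pt.samples.loc[sids]
        # mean normalized peak area per line, then log10
        means = pt.values[sids].T.groupby(meta["line_id"], sort=False).mean().T
        X = np.log10(means.T.to_numpy())  # lines x features
        lines = list(means.columns)
        features = means.index

        keep = X.std(axis=0) > 0
        if not keep.all():
            dropped = [tuple(f) for f in features[~keep]]
            warnings.warn(f"dropping {len(dropped)} constant feature(s) before PCA", stacklevel=2)
        else:
            dropped = []
        X = X[:, keep]
        features = features[keep]

        center = X.mean(axis=0)
        Xc = X - center
        if self.scale:
            Xc = Xc / Xc.std(axis=0, ddof=1)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        k = min(self.n_components or S.size, S.size)
        U, S, Vt = U[:, :k], S[:k], Vt[:k]
        # fix signs: largest-|loading| feature positive per component
        for m in range(k):
            j = int(np.argmax(np.abs(Vt[m])))
            if Vt[m, j] < 0:
                Vt[m] *= -1.0
                U[:, m] *= -1.0
        comp_names = [f"PC{m + 1}" for m in range(k)]
        var = S**2
        total_var = np.sum(np.linalg.svd(Xc, compute_uv=False) ** 2)
        self.result_ = PCAResult(
            phase=self.phase,
            scores=pd.DataFrame(U * S, index=lines, columns=comp_names),
            loadings=pd.DataFrame(Vt.T, index=features, columns=comp_names),
            explained_variance_ratio=var / total_var,
            contributions=pd.DataFrame(Vt.T**2, index=features, columns=comp_names),
            mean_=pd.Series(center, index=features),
            dropped_features=dropped,
        )
        self.scores_ = self.result_.scores
        self.loadings_ = self.result_.loadings
        self.explained_variance_ratio_ = self.result_.explained_variance_ratio
        self.contributions_ = self.result_.contributions
        return self

    def transform(self, pt: PeakTable) -> pd.DataFrame:
        """Project a table's phase-matched line means onto the fitted axes."""
        sids = pt.sample_ids(phase=self.phase)
        meta = pt.samples.loc[sids]
        means = pt.values[sids].T.groupby(meta["line_id"], sort=False).mean().T
        X = np.log10(means.loc[self.result_.loadings.index].T.to_numpy())
        Xc = X - self.result_.mean_.to_numpy()
        proj = Xc @ self.result_.loadings.to_numpy()
        return pd.DataFrame(proj, index=means.columns, columns=self.result_.loadings.columns)


def pca_by_phase(
    pt: PeakTable, phase: str, n_components: int | None = None, scale: bool = False
) -> PCAResult:
    """Functional wrapper over :class:`PhasePCA`."""
    return PhasePCA(phase, n_components=n_components, scale=scale).fit(pt).result_
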