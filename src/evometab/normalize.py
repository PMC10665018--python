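"""Two-step normalization of raw peak areas.

Step 1 divides each sample by an internal-standard scale factor — the
geometric mean of the sample's spiked-in standard peak areas, relative to the
across-sample geometric mean of the same standards — removing per-sample
instrument response differences.  Step 2 is total-sum scaling (TSS): each
present value becomes a proportion of its sample's total, removing input
amount differences.  Internal standards are excluded from the TSS denominator
and dropped afterwards; they are not biological features.

Both steps are exposed as sklearn-style transformers operating on
:class:`~evometab.peak_table.PeakTable` (fit learns per-sample factors;
transform applies them) and as plain functions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .peak_table import PeakTable, PeakTableError

log = logging.getLogger(__name__)


class StandardNormalizer(BaseEstimator, TransformerMixin):
    """Internal-standard normalization (step 1).

    Parameters
    ----------
    standards : list of (compound, ion_mode) or None
        Features to use as internal standards.  None falls back to the
        table's own ``standard_features`` flags.
    factors : mapping sample_id -> float, optional
        Precomputed per-sample scale factors; when given, standards are not
        consulted (for users with the original standards protocol).

    Attributes
    ----------
    scale_factors_ : pandas.Series
        Per-sample divisor applied to the table.
    """

    def __init__(self, standards=None, factors=None):
        self.standards = standards
        self.factors = factors

    def fit(self, pt: PeakTable, y=None):
        if self.factors is not None:
            self.scale_factors_ = pd.Series(self.factors, dtype=float)[list(pt.values.columns)]
            self.standards_used_ = []
            return self
        standards = self.standards if self.standards is not None else pt.standard_features
        standards = [tuple(s) for s in standards]
        if not standards:
            raise PeakTableError(
                "no internal standards: pass `standards`, flag them on the table, "
                "or provide precomputed `factors`"
            )
        missing_feat = [s for s in standards if s not in pt.values.index]
        if missing_feat:
            raise PeakTableError(f"standards absent from the table: {missing_feat}")
        block = pt.values.loc[standards]
        na = block.isna()
        if na.any().any():
            j = na.any(axis=0).idxmax()
            i = na[j].idxmax()
            raise PeakTableError(f"standard {i} is missing in sample {j!r}")
        logs = np.log(block.to_numpy(dtype=float))
        per_sample = np.exp(logs.mean(axis=0))  # geometric mean per sample
        grand = np.exp(logs.mean())  # across-sample geometric mean
        self.scale_factors_ = pd.Series(per_sample / grand, index=block.columns)
        self.standards_used_ = standards
        return self

    def transform(self, pt: PeakTable) -> PeakTable:
        out = pt.values.div(self.scale_factors_, axis=1)
        standards = self.standards_used_ or pt.standard_features
        return pt.with_values(out, stage="standard_normalized", standard_features=list(standards))


class TotalSumScaler(BaseEstimator, TransformerMixin):
    """Total-sum scaling (step 2): present values become per-sample proportions.

    Internal-standard features never enter the denominator and are dropped
    from the output: they are spiked-in, not biological.

    Parameters
    ----------
    scope : {"mode", "sample"}
        "mode" (default) scales each (sample, ionization mode) block to sum 1
        — each mode is a separate acquisition; "sample" pools both modes.
    """

    def __init__(self, scope: str = "mode"):
        self.scope = scope

    def fit(self, pt: PeakTable, y=None):
        if self.scope not in ("mode", "sample"):
            raise ValueError(f"scope must be 'mode' or 'sample', got {self.scope!r}")
        self.n_features_in_ = pt.n_features
        return self

    def transform(self, pt: PeakTable) -> PeakTable:
        vals = pt.biological_values().copy()
        if self.scope == "sample":
            groups = [("all", vals)]
        else:
            groups = list(vals.groupby(level="ion_mode", sort=False))
        pieces = []
        for name, block in groups:
            totals = block.sum(axis=0, skipna=True)
            n_present = block.notna().sum(axis=0)
            empty = totals.index[n_present == 0]
            if len(empty):
                raise PeakTableError(
                    f"sample {empty[0]!r} has no present values in group {name!r}"
                )
            pieces.append(block.div(totals, axis=1))
        out = pd.concat(pieces).loc[vals.index]
        return pt.with_values(
            out, stage="tss_normalized", norm_scope=self.scope, standard_features=[]
        )

    def fit_transform(self, pt: PeakTable, y=None, **kw) -> PeakTable:
        return self.fit(pt).transform(pt)


def standard_normalize(pt: PeakTable, standard_features=None, factors=None) -> PeakTable:
    """Divide each sample by its internal-standard scale factor."""
    return StandardNormalizer(standards=standard_features, factors=factors).fit_transform(pt)


def tss_normalize(pt: PeakTable, scope: str = "mode") -> PeakTable:
    """Scale present values to proportions of their sample (or sample-mode) total."""
    if pt.stage == "raw" and pt.standard_features:
        log.warning("TSS on a raw table: internal-standard normalization was skipped")
    return TotalSumScaler(scope=scope).fit_transform(pt)
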