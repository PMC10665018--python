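"""End-to-end convenience wrappers over the pipeline stages."""

from __future__ import annotations

import pandas as pd

from .foldchange import call_significance, compute_foldchanges
from .impute import QRILCImputer
from .normalize import StandardNormalizer, TotalSumScaler
from .peak_table import PeakTable


def preprocess(
    pt: PeakTable,
    standards=None,
    factors=None,
    tss_scope: str = "mode",
    impute_seed=None,
) -> PeakTable:
    """raw -> standard-normalized -> TSS proportions -> QRILC-imputed.

    Skips internal-standard normalization when the table flags no standards
    and none are supplied.
    """
    if standards or factors is not None or pt.standard_features:
        pt = StandardNormalizer(standards=standards, factors=factors).fit_transform(pt)
    pt = TotalSumScaler(scope=tss_scope).fit_transform(pt)
    scope = "mode_within_sample" if tss_scope == "mode" else "sample"
    if pt.missing_mask().any().any():
        pt = QRILCImputer(scope=scope, random_state=impute_seed).fit_transform(pt)
    else:
        pt = pt.with_values(pt.values, stage="imputed")
    return pt


def foldchanges_from_raw(
    pt: PeakTable,
    ancestor_map=None,
    tau: float = 1.0,
    impute_seed=None,
    tss_scope: str = "mode",
) -> tuple[PeakTable, pd.DataFrame, pd.DataFrame]:
    """Run the full preprocessing chain and return (imputed, fct, calls)."""
    imputed = preprocess(pt, tss_scope=tss_scope, impute_seed=impute_seed)
    fct = compute_foldchanges(imputed, ancestor_map=ancestor_map)
    calls = call_significance(fct, tau=tau)
    return imputed, fct, calls
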