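import numpy as np
import pandas as pd
import pytest

import evometab as em
from evometab.foldchange import DEFAULT_ANCESTOR_MAP, direction_counts
from evometab.peak_table import PeakTableError


def _imputed_table(values, lines, phases=("exponential",), n_rep=1):
    """Build a minimal imputed-stage table; columns must sum to 1."""
    samples, meta_rows = [], []
    for li in lines:
        for ph in phases:
            for r in range(1, n_rep + 1):
                sid = f"{li}_{ph[:3]}_r{r}"
                samples.append(sid)
                meta_rows.append((sid, li, ph, r))
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "line_id", "phase", "replicate"]
    ).set_index("sample_id")
    idx = pd.MultiIndex.from_tuples(
        [(f"c{i}", "pos") for i in range(len(values))], names=["compound", "ion_mode"]
    )
    vals = pd.DataFrame(values, index=idx, columns=samples, dtype=float)
    return em.PeakTable(vals, meta, stage="imputed", norm_scope="sample")


def test_fold_change_arithmetic():
    # evolved proportions (0.8, 0.2) vs ancestor (0.2, 0.8): fc 4 and 1/4
    pt = _imputed_table([[0.2, 0.8], [0.8, 0.2]], ["R06", "A-1"])
    fct = em.compute_foldchanges(pt)
    fc = fct.set_index("compound")
    assert fc.loc["c0", "fc"] == pytest.approx(4.0)
    assert fc.loc["c0", "log2fc"] == pytest.approx(2.0)
    assert fc.loc["c1", "fc"] == pytest.approx(0.25)


def test_replicate_averaging_before_ratio():
    # evolved replicates (0.75, 0.85) average 0.8 vs ancestor (0.15, 0.25) average 0.2
    pt = _imputed_table(
        [[0.15, 0.25, 0.75, 0.85], [0.85, 0.75, 0.25, 0.15]], ["R06", "A-1"], n_rep=2
    )
    fct = em.compute_foldchanges(pt)
    assert fct.set_index("compound").loc["c0", "fc"] == pytest.approx(4.0)


def test_identical_lines_give_zero_log2fc():
    pt = _imputed_table([[0.3, 0.3], [0.7, 0.7]], ["R06", "A-1"])
    fct = em.compute_foldchanges(pt)
    assert np.allclose(fct["log2fc"], 0.0)


def test_swapping_roles_inverts_fold_changes():
    pt = _imputed_table([[0.2, 0.6], [0.8, 0.4]], ["R06", "A-1"])
    fct = em.compute_foldchanges(pt)
    swapped = _imputed_table([[0.6, 0.2], [0.4, 0.8]], ["R06", "A-1"])
    fct_swapped = em.compute_foldchanges(swapped)
    assert np.allclose(fct["fc"].to_numpy() * fct_swapped["fc"].to_numpy(), 1.0)
    assert np.allclose(fct["log2fc"].to_numpy(), -fct_swapped["log2fc"].to_numpy())


def test_missing_ancestor_mapping_errors():
    pt = _imputed_table([[0.2, 0.8], [0.8, 0.2]], ["R06", "A-1"])
    with pytest.raises(PeakTableError, match="A-1"):
        em.compute_foldchanges(pt, ancestor_map={})


def test_default_ancestor_map_follows_ltee_arms():
    assert DEFAULT_ANCESTOR_MAP["A-3"] == "R06"
    assert DEFAULT_ANCESTOR_MAP["A+5"] == "R07"


def test_planted_effect_recovered(default_pipeline):
    _, gt, _, fct, _ = default_pipeline
    cmps, carriers, block = gt.block_compounds["block0"]  # 10 compounds, +2 in 12 lines
    sel = fct[
        (fct["phase"] == "exponential")
        & fct["compound"].isin(cmps)
        & fct["line_id"].isin(carriers)
    ]
    est = sel["log2fc"]
    se = est.std() / np.sqrt(len(est))
    assert abs(est.mean() - block.effect_log2) < 3 * se + 0.25  # allow compositional shift


def test_significance_boundary_inclusive():
    fct = pd.DataFrame(
        {
            "compound": ["a", "b", "c", "d"],
            "ion_mode": ["pos"] * 4,
            "line_id": ["A-1"] * 4,
            "phase": ["exponential"] * 4,
            "fc": [2.0, 0.5, 1.98, 1.0],
            "log2fc": [1.0, -1.0, 0.99, 0.0],
        }
    )
    calls = em.call_significance(fct, tau=1.0)
    assert calls.set_index("compound")["direction"].tolist() == ["up", "down", "none", "none"]


def test_calls_partition_all_rows(default_pipeline):
    *_, calls = default_pipeline
    counts = direction_counts(calls)
    assert counts.sum() == len(calls)
    assert set(counts.index) <= {"up", "down", "none"}


def test_tau_must_be_positive(default_pipeline):
    fct = default_pipeline[3]
    with pytest.raises(ValueError):
        em.call_significance(fct, tau=0.0)


def test_summarize_pooled_and_per_mode_medians():
    rows = []
    for mode, fcs in (("pos", [2.0, 4.0, 8.0]), ("neg", [1.0, 2.0, 4.0])):
        for li, fc in zip(["A+1", "A+2", "A+3"], fcs):
            rows.append(("nad", mode, li, "exponential", fc, np.log2(fc)))
    fct = pd.DataFrame(
        rows, columns=["compound", "ion_mode", "line_id", "phase", "fc", "log2fc"]
    )
    summ = em.summarize_compounds(fct, ["nad"], phase="exponential").iloc[0]
    assert summ["median_fc_pos"] == pytest.approx(4.0)
    assert summ["median_fc_neg"] == pytest.approx(2.0)
    assert summ["median_fc_pooled"] == pytest.approx(np.median([2, 4, 8, 1, 2, 4]))
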