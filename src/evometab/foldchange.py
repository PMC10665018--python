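"""Evolved-vs-ancestor fold-changes and significance calls.

For every feature (compound x ionization mode), evolved line and growth
phase, the fold-change is the ratio of the line's replicate-averaged peak
proportion to the phase-matched ancestor's.  By default the Ara- lines map
to ancestor REL606 ("R06") and the Ara+ lines to REL607 ("R07"), the clones
each arm of the LTEE descends from; the mapping is configurable.

A feature is called significantly altered in a line when
|log2(fold-change)| >= tau (default tau = 1, i.e. a two-fold change); the
boundary counts as significant.  Calls feed the parallelism analyses.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .peak_table import ANCESTORS, EVOLVED_LINES, PeakTable, PeakTableError

log = logging.getLogger(__name__)

#: Ara- lines descend from REL606, Ara+ lines from REL607.
DEFAULT_ANCESTOR_MAP = {
    li: ("R06" if li.startswith("A-") else "R07") for li in EVOLVED_LINES
}


def compute_foldchanges(
    pt: PeakTable,
    ancestor_map: dict | None = None,
    average: str = "arithmetic",
) -> pd.DataFrame:
    """Replicate-averaged evolved/ancestor ratios per feature, line and phase.

    Parameters
    ----------
    pt : PeakTable at stage "imputed" (no missing cells, so every ratio is
        finite and positive).
    ancestor_map : dict line_id -> ancestor line_id; defaults to the LTEE
        arm mapping (Ara- -> R06, Ara+ -> R07).
    average : {"arithmetic", "geometric"}
        How biological replicates are averaged before the ratio; arithmetic
        mean of peak proportions is the default.

    Returns
    -------
    Tidy DataFrame with columns compound, ion_mode, line_id, phase, fc,
    log2fc.
    """
    if pt.stage != "imputed":
        raise PeakTableError(f"fold-changes need an imputed table, got stage {pt.stage!r}")
    if average not in ("arithmetic", "geometric"):
        raise ValueError(f"average must be arithmetic or geometric, got {average!r}")
    amap = dict(DEFAULT_ANCESTOR_MAP if ancestor_map is None else ancestor_map)
    if ancestor_map is None:
        log.info("using default ancestor map: Ara- -> R06, Ara+ -> R07")

    meta = pt.samples
    lines = list(dict.fromkeys(meta["line_id"]))
    evolved = [li for li in lines if li not in ANCESTORS and li not in set(amap.values())]
    missing = [li for li in evolved if li not in amap]
    if missing:
        raise PeakTableError(f"ancestor_map does not cover evolved lines: {missing}")

    def line_mean(line_id, phase):
        cols = pt.sample_ids(line_id=line_id, phase=phase)
        if not cols:
            return None
        block = pt.values[cols]
        if average == "arithmetic":
            return block.mean(axis=1)
        return np.exp(np.log(block).mean(axis=1))

    phases = list(dict.fromkeys(meta["phase"]))
    frames = []
    for phase in phases:
        anc_means = {}
        for anc in set(amap.values()):
            m = line_mean(anc, phase)
            anc_means[anc] = m
        for li in evolved:
            ev = line_mean(li, phase)
            anc = anc_means[amap[li]]
            if ev is None:
                continue
            if anc is None:
                raise PeakTableError(
                    f"evolved line {li!r} has no ancestor {amap[li]!r} samples in phase {phase!r}"
                )
            fc = ev / anc
            frames.append(
                pd.DataFrame(
                    {
                        "compound": fc.index.get_level_values("compound"),
                        "ion_mode": fc.index.get_level_values("ion_mode"),
                        "line_id": li,
                        "phase": phase,
                        "fc": fc.to_numpy(),
                        "log2fc": np.log2(fc.to_numpy()),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def call_significance(fct: pd.DataFrame, tau: float = 1.0) -> pd.DataFrame:
    """Direction calls per (feature, line, phase): up / down / none.

    up iff log2fc >= tau; down iff log2fc <= -tau (the boundary is
    inclusive); none otherwise.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    out = fct.copy()
    out["direction"] = np.select(
        [out["log2fc"] >= tau, out["log2fc"] <= -tau], ["up", "down"], default="none"
    )
    out.attrs["tau"] = tau
    return out


def summarize_compounds(
    fct: pd.DataFrame, compounds, phase: str | None = None
) -> pd.DataFrame:
    """Median fold-change per compound across the evolved lines.

    Reports the pooled median (both ionization modes, all lines) alongside
    per-mode medians, since published per-compound numbers sometimes pool
    modes and sometimes do not.
    """
    sel = fct[fct["compound"].isin(list(compounds))]
    if phase is not None:
        sel = sel[sel["phase"] == phase]
    rows = []
    for cmp_, grp in sel.groupby("compound", sort=False):
        row = {
            "compound": cmp_,
            "median_fc_pooled": float(grp["fc"].median()),
            "n_values": len(grp),
        }
        for mode, sub in grp.groupby("ion_mode", sort=False):
            row[f"median_fc_{mode}"] = float(sub["fc"].median())
        rows.append(row)
    return pd.DataFrame(rows)


def foldchange_matrix(fct: pd.DataFrame, phase: str, column: str = "log2fc") -> pd.DataFrame:
    """Pivot a tidy fold-change table to features x lines for one phase."""
    sel = fct[fct["phase"] == phase]
    return sel.pivot_table(
        index=["compound", "ion_mode"], columns="line_id", values=column, sort=False
    )


def direction_counts(calls: pd.DataFrame) -> pd.Series:
    """Sanity tally: up + down + none over (feature, line, phase)."""
    return calls["direction"].value_counts()
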