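"""Peak tables, sample metadata and delimited-text I/O.

The central container is :class:`PeakTable`: a features x samples matrix of
nonnegative LC/MS peak areas.  A *feature* is a (compound, ionization mode)
pair — the same compound detected in positive and negative electrospray mode
counts twice, because it is unclear which mode tracks the true abundance
better.  Samples are clones of the *E. coli* long-term evolution experiment
(LTEE): the two ancestors (REL606 "R06", REL607 "R07") and the twelve evolved
lines (Ara+1..6, Ara-1..6), each harvested in exponential (2 h) and stationary
(24 h) phase with two biological replicates.

Missing cells mean "not detected" (below the instrument's limit of detection),
never zero: a measured zero is kept as a value.  Tables carry a processing
``stage`` tag (raw -> standard_normalized -> tss_normalized -> imputed) so
each pipeline step can validate its input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ANCESTORS = ("R06", "R07")
EVOLVED_LINES = tuple(f"A{s}{i}" for s in ("+", "-") for i in range(1, 7))
ALL_LINES = ANCESTORS + EVOLVED_LINES
PHASES = ("exponential", "stationary")
ION_MODES = ("pos", "neg")
STAGES = ("raw", "standard_normalized", "tss_normalized", "imputed")

#: LTEE populations that evolved an elevated point-mutation rate by 50,000
#: generations (annotation only; nothing downstream branches on it).
MUTATOR_LINES = frozenset({"A-1", "A-2", "A-3", "A-4", "A+3", "A+6"})


class PeakTableError(ValueError):
    """Raised when a peak table or its metadata violates the schema."""


def mutator_status(line_id: str) -> str:
    if line_id in ANCESTORS:
        return "ancestor"
    return "mutator" if line_id in MUTATOR_LINES else "nonmutator"


@dataclass
class PeakTable:
    """Features x samples peak-area matrix with sample metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by a (compound, ion_mode) MultiIndex, columns by
        sample_id.  NaN encodes "not detected"; present values must be >= 0.
    samples : pandas.DataFrame
        Indexed by sample_id, with columns ``line_id``, ``phase``,
        ``replicate`` and (optionally) ``mutator_status``.
    stage : str
        One of raw / standard_normalized / tss_normalized / imputed.
    norm_scope : str or None
        For TSS-normalized or imputed tables: "sample" if each sample column
        was scaled to sum 1, "mode" if each (sample, ion mode) block was.
    standard_features : list of (compound, ion_mode)
        Features flagged as internal standards (spiked-in, non-biological).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    stage: str = "raw"
    norm_scope: str | None = None
    standard_features: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        v, s = self.values, self.samples
        if self.stage not in STAGES:
            raise PeakTableError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if not isinstance(v.index, pd.MultiIndex) or v.index.nlevels != 2:
            raise PeakTableError("values must be indexed by a (compound, ion_mode) MultiIndex")
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise PeakTableError(f"duplicate feature keys: {dups}")
        if v.index.names != ["compound", "ion_mode"]:
            v.index = v.index.set_names(["compound", "ion_mode"])
        unknown = [c for c in v.columns if c not in s.index]
        if unknown:
            raise PeakTableError(f"sample columns missing from metadata: {unknown}")
        orphan = [c for c in s.index if c not in v.columns]
        if orphan:
            raise PeakTableError(f"metadata samples missing from table header: {orphan}")
        with np.errstate(invalid="ignore"):
            neg = v.to_numpy(dtype=float) < 0
        if np.any(neg):
            i, j = np.argwhere(neg)[0]
            raise PeakTableError(
                f"negative peak area at feature {tuple(v.index[i])}, sample {v.columns[j]!r}"
            )
        if {"line_id", "phase", "replicate"} - set(s.columns):
            raise PeakTableError("sample metadata needs line_id, phase and replicate columns")
        bad_phase = set(s["phase"]) - set(PHASES)
        if bad_phase:
            raise PeakTableError(f"unknown phases {sorted(bad_phase)}; expected {PHASES}")
        key = s[["line_id", "phase", "replicate"]]
        if key.duplicated().any():
            raise PeakTableError("(line_id, phase, replicate) must be unique across samples")
        # design-balance check is advisory only: real uploads may be ragged
        counts = s.groupby(["line_id", "phase"]).size().unstack(fill_value=0)
        if counts.shape[1] == len(PHASES) and not counts.eq(counts.iloc[:, [0]].values).all().all():
            warnings.warn("unbalanced design: replicate counts differ across phases", stacklevel=2)
        elif counts.shape[1] < len(PHASES) and len(PHASES) > 1:
            warnings.warn("some lines are missing a growth phase", stacklevel=2)
        if self.stage in ("tss_normalized", "imputed"):
            self._check_group_sums()
        if self.stage == "imputed" and v.isna().any().any():
            raise PeakTableError("stage=imputed but table still has missing cells")

    def _check_group_sums(self, tol: float = 1e-9) -> None:
        for name, block in self.iter_norm_groups():
            total = block.sum(skipna=True)
            bad = total[(total - 1.0).abs() > tol]
            if len(bad):
                raise PeakTableError(
                    f"stage={self.stage}: present values in group {name!r} of sample "
                    f"{bad.index[0]!r} sum to {bad.iloc[0]:.12g}, expected 1"
                )

    def iter_norm_groups(self):
        """Yield (label, sub-frame) per normalization group (all rows, or per mode)."""
        if (self.norm_scope or "sample") == "sample":
            yield "all", self.values
        else:
            for mode, block in self.values.groupby(level="ion_mode", sort=False):
                yield mode, block

    # -- convenience --------------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def compounds(self) -> list[str]:
        return list(dict.fromkeys(self.values.index.get_level_values("compound")))

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def sample_ids(self, line_id=None, phase=None) -> list[str]:
        s = self.samples
        keep = pd.Series(True, index=s.index)
        if line_id is not None:
            keep &= s["line_id"] == line_id
        if phase is not None:
            keep &= s["phase"] == phase
        return list(s.index[keep])

    def biological_values(self) -> pd.DataFrame:
        """Values with internal-standard features removed."""
        if not self.standard_features:
            return self.values
        keep = ~self.values.index.isin([tuple(f) for f in self.standard_features])
        return self.values.loc[keep]

    def with_values(self, values: pd.DataFrame, stage: str | None = None, **kw) -> "PeakTable":
        return replace(self, values=values, stage=stage or self.stage, **kw)


def make_sample_id(line_id: str, phase: str, replicate: int) -> str:
    return f"{line_id}_{phase[:3]}_r{replicate}"


def build_sample_metadata(
    lines=ALL_LINES, phases=PHASES, n_replicates: int = 2
) -> pd.DataFrame:
    """Full-factorial sample sheet for the standard design."""
    rows = [
        {
            "sample_id": make_sample_id(li, ph, r),
            "line_id": li,
            "phase": ph,
            "replicate": r,
            "mutator_status": mutator_status(li),
        }
        for li in lines
        for ph in phases
        for r in range(1, n_replicates + 1)
    ]
    return pd.DataFrame(rows).set_index("sample_id")


# -- I/O --------------------------------------------------------------------

def read_peak_table(table_path, meta_path) -> PeakTable:
    """Read a peak table and its sample sheet from delimited text.

    The table is a wide CSV/TSV: columns ``compound`` and ``ion_mode``, an
    optional boolean ``is_standard`` (flags internal-standard features), then
    one column per sample_id; empty cells or "NA" encode missing.  The sample
    sheet has a ``sample_id`` column plus ``line_id``, ``phase``,
    ``replicate`` and optionally ``mutator_status``, ``stage`` (constant;
    declares the processing stage, default raw) and ``norm_scope``.
    """
    sep = "\t" if str(table_path).endswith((".tsv", ".txt")) else ","
    values = pd.read_csv(table_path, sep=sep, na_values=["NA"], keep_default_na=True)
    for col in ("compound", "ion_mode"):
        if col not in values.columns:
            raise PeakTableError(f"peak table {table_path} lacks required column {col!r}")
    values = values.set_index(["compound", "ion_mode"])
    standard_features: list[tuple[str, str]] = []
    if "is_standard" in values.columns:
        flags = values.pop("is_standard").astype(bool)
        standard_features = [tuple(k) for k in values.index[flags]]
    values = values.astype(float)

    msep = "\t" if str(meta_path).endswith((".tsv", ".txt")) else ","
    meta = pd.read_csv(meta_path, sep=msep)
    if "sample_id" not in meta.columns:
        raise PeakTableError(f"metadata {meta_path} lacks a sample_id column")
    meta = meta.set_index("sample_id")
    stage = "raw"
    if "stage" in meta.columns:
        declared = meta.pop("stage").unique()
        if len(declared) > 1:
            raise PeakTableError(f"conflicting stage declarations: {declared.tolist()}")
        stage = str(declared[0])
    norm_scope = None
    if "norm_scope" in meta.columns:
        norm_scope = str(meta.pop("norm_scope").iloc[0])
        if norm_scope in ("", "nan", "None"):
            norm_scope = None
    return PeakTable(
        values=values,
        samples=meta,
        stage=stage,
        norm_scope=norm_scope,
        standard_features=standard_features,
    )


def write_peak_table(pt: PeakTable, table_path, meta_path) -> None:
    """Write a PeakTable as the canonical pair of delimited files (see read)."""
    sep = "\t" if str(table_path).endswith((".tsv", ".txt")) else ","
    out = pt.values
    if pt.standard_features:
        out = out.copy()
        out.insert(0, "is_standard", out.index.isin([tuple(f) for f in pt.standard_features]))
    out.to_csv(table_path, sep=sep, na_rep="NA")
    meta = pt.samples.copy()
    meta["stage"] = pt.stage
    if pt.norm_scope is not None:
        meta["norm_scope"] = pt.norm_scope
    msep = "\t" if str(meta_path).endswith((".tsv", ".txt")) else ","
    meta.to_csv(meta_path, sep=msep, index_label="sample_id")


def detection_summary(pt: PeakTable) -> dict:
    """Per-feature detection counts and compound-completeness totals.

    A compound is "complete in >=1 mode" when at least one of its ionization
    modes was detected in every sample — the study's headline completeness
    count (168 of 196 compounds in the original data).

    Returns a dict with:

    - ``per_feature``: DataFrame indexed by (compound, ion_mode) with
      ``n_detected`` and ``n_samples``;
    - ``complete_any_mode``: boolean Series per compound;
    - ``n_compounds``; ``n_complete_any_mode``; ``n_with_missing`` (compounds
      undetected in >=1 sample in >=1 mode, the study's "remaining 28").
    """
    if pt.stage == "imputed":
        raise PeakTableError("detection_summary is meaningless after imputation")
    present = pt.biological_values().notna()  # spiked standards are not compounds
    per_feature = pd.DataFrame(
        {"n_detected": present.sum(axis=1), "n_samples": pt.n_samples}
    )
    complete_feature = per_feature["n_detected"] == per_feature["n_samples"]
    complete_any = complete_feature.groupby(level="compound", sort=False).any()
    return {
        "per_feature": per_feature,
        "complete_any_mode": complete_any,
        "n_compounds": int(complete_any.size),
        "n_complete_any_mode": int(complete_any.sum()),
        "n_with_missing": int((~complete_any).sum()),
    }
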