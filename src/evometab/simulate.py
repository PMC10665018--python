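"""Synthetic LC/MS peak tables with known ground truth.

The generator emulates the structure of the study design: 2 ancestors + 12
evolved lines x 2 growth phases x 2 biological replicates, ~200 compounds
each measured in positive and negative ionization mode.  Abundances are
lognormal; evolved lines carry planted parallel log2 effects (shared by a
chosen number of lines) plus idiosyncratic per-line effects; every sample is
scaled by a lognormal internal-standard factor; and detection-limit
left-censoring converts the lowest fraction of measured values to missing.

Because every effect, factor and censored cell is recorded in
:class:`GroundTruth`, each downstream pipeline stage (normalization,
imputation, fold-changes, parallelism statistics) can be verified offline
without the deposited dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .peak_table import (
    ALL_LINES,
    ANCESTORS,
    ION_MODES,
    PHASES,
    PeakTable,
    build_sample_metadata,
)

LOG10_2 = np.log10(2.0)


class ConfigError(ValueError):
    """A simulation config field is out of range or inconsistent."""


@dataclass(frozen=True)
class PlantedBlock:
    """A block of compounds sharing the same directional change in k lines."""

    n_features: int
    k_lines: int
    direction: str  # "up" or "down"
    effect_log2: float
    phase: str | None = None  # None = planted in both phases

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise ConfigError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if self.n_features < 1:
            raise ConfigError("n_features must be >= 1")
        if self.effect_log2 < 0:
            raise ConfigError("effect_log2 is a magnitude; use direction='down' for decreases")
        if self.phase is not None and self.phase not in PHASES:
            raise ConfigError(f"unknown phase {self.phase!r}")


# Default planted blocks: strong parallelism at high k in both directions,
# emulating the observed excess of changes shared by many evolved lines.
DEFAULT_BLOCKS = (
    PlantedBlock(10, 12, "up", 2.0),
    PlantedBlock(8, 10, "up", 1.5),
    PlantedBlock(8, 8, "down", 1.5),
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic peak-table generator.

    Scales: baselines and noise are on the log10 peak-area scale; planted and
    background effects are log2 fold-changes (the scale the analysis uses).
    """

    n_compounds: int = 196
    lines: tuple = ALL_LINES
    phases: tuple = PHASES
    n_replicates: int = 2
    ion_modes: tuple = ION_MODES
    baseline_log10_mean: float = 5.0
    baseline_log10_sd: float = 1.0
    replicate_sd: float = 0.1
    phase_shift_sd: float = 0.5
    mode_offset_sd: float = 0.3
    parallel_spec: tuple = DEFAULT_BLOCKS
    background_effect_sd: float = 0.7
    censor_quantile: float = 0.10
    internal_standard_cv: float = 0.2
    n_standards: int = 3
    standard_log10_mean: float = 7.5
    seed: int = 0

    @property
    def evolved_lines(self) -> tuple:
        return tuple(li for li in self.lines if li not in ANCESTORS)

    @property
    def n_evolved(self) -> int:
        return len(self.evolved_lines)

    def __post_init__(self):
        self.parallel_spec = tuple(
            b if isinstance(b, PlantedBlock) else PlantedBlock(*b) for b in self.parallel_spec
        )
        self.validate()

    def validate(self) -> None:
        if self.n_compounds < 1:
            raise ConfigError("n_compounds must be a positive integer")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be a positive integer")
        if not 0 <= self.censor_quantile < 1:
            raise ConfigError("censor_quantile must lie in [0, 1)")
        for name in (
            "replicate_sd",
            "phase_shift_sd",
            "mode_offset_sd",
            "background_effect_sd",
            "internal_standard_cv",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        for b in self.parallel_spec:
            if not 1 <= b.k_lines <= self.n_evolved:
                raise ConfigError(
                    f"planted k_lines={b.k_lines} outside 1..{self.n_evolved} (n_evolved)"
                )
        if sum(b.n_features for b in self.parallel_spec) > self.n_compounds:
            raise ConfigError("parallel_spec blocks claim more compounds than n_compounds")

    def to_json(self) -> str:
        d = asdict(self)
        d["parallel_spec"] = [asdict(b) for b in self.parallel_spec]
        return json.dumps(d, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "parallel_spec" in d:
            d["parallel_spec"] = tuple(
                PlantedBlock(**b) if isinstance(b, dict) else PlantedBlock(*b)
                for b in d["parallel_spec"]
            )
        for key in ("lines", "phases", "ion_modes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover.

    Attributes
    ----------
    effects : pandas.DataFrame
        Tidy table (compound, line_id, phase, log2_effect, source); source is
        a planted-block label ("block0", ...) or "background".
    block_compounds : dict
        block label -> (list of compounds, list of carrier line_ids, block).
    standard_factors : pandas.Series
        True multiplicative internal-standard scale factor per sample.
    censored : pandas.DataFrame
        Boolean mask, True where the pre-censoring value fell below the
        realized detection limit.
    detection_limit : float
        The realized global detection limit on the measured-intensity scale
        (NaN when censor_quantile is 0).
    """

    effects: pd.DataFrame
    block_compounds: dict
    standard_factors: pd.Series
    censored: pd.DataFrame
    detection_limit: float

    def effect_lookup(self) -> pd.Series:
        """(compound, line_id, phase) -> log2 effect, zeros omitted."""
        return self.effects.set_index(["compound", "line_id", "phase"])["log2_effect"]


def simulate_peak_table(config: SimulationConfig) -> tuple[PeakTable, GroundTruth]:
    """Draw one synthetic raw peak table plus its ground truth.

    The measured value of compound c, mode m, line l, phase p, replicate r is

        10 ** (b_c + o_{c,m} + g_{c,p} + log10(2) * e_{c,l,p} + eps) * s_j

    with b_c the compound baseline, o a compound-specific mode offset, g a
    compound-specific phase shift, e the planted-or-background log2 effect
    (zero for ancestors), eps per-cell replicate noise and s_j the sample's
    internal-standard factor.  Cells whose measured value falls below the
    detection limit (the ``censor_quantile`` of the pooled value distribution)
    become missing.  Deterministic for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    compounds = [f"cmp{i:03d}" for i in range(config.n_compounds)]
    meta = build_sample_metadata(config.lines, config.phases, config.n_replicates)
    sample_ids = list(meta.index)
    n_c, n_s = config.n_compounds, len(sample_ids)
    modes = list(config.ion_modes)
    evolved = list(config.evolved_lines)

    baseline = rng.normal(config.baseline_log10_mean, config.baseline_log10_sd, n_c)
    mode_offset = rng.normal(0.0, config.mode_offset_sd, (n_c, len(modes)))
    phase_shift = rng.normal(0.0, config.phase_shift_sd, (n_c, len(config.phases)))

    # planted blocks claim disjoint random compounds; carriers are random lines
    order = rng.permutation(n_c)
    cursor = 0
    effect = np.zeros((n_c, len(config.lines), len(config.phases)))
    line_pos = {li: i for i, li in enumerate(config.lines)}
    phase_pos = {ph: i for i, ph in enumerate(config.phases)}
    block_compounds: dict = {}
    effect_rows = []
    planted_idx: set[int] = set()
    for bi, block in enumerate(config.parallel_spec):
        idx = order[cursor : cursor + block.n_features]
        cursor += block.n_features
        planted_idx.update(int(i) for i in idx)
        carriers = [evolved[i] for i in rng.choice(len(evolved), block.k_lines, replace=False)]
        signed = block.effect_log2 if block.direction == "up" else -block.effect_log2
        phases = config.phases if block.phase is None else (block.phase,)
        label = f"block{bi}"
        for ci in idx:
            for li in carriers:
                for ph in phases:
                    effect[ci, line_pos[li], phase_pos[ph]] += signed
                    effect_rows.append((compounds[ci], li, ph, signed, label))
        block_compounds[label] = (sorted(compounds[int(i)] for i in idx), sorted(carriers), block)

    # idiosyncratic per-line effects on the remaining compounds only, so a
    # planted block lands at its nominal number of carrier lines
    if config.background_effect_sd > 0:
        bg_idx = [i for i in range(n_c) if i not in planted_idx]
        bg = rng.normal(
            0.0, config.background_effect_sd, (len(bg_idx), len(evolved), len(config.phases))
        )
        for row, ci in enumerate(bg_idx):
            for lj, li in enumerate(evolved):
                for pj, ph in enumerate(config.phases):
                    effect[ci, line_pos[li], phase_pos[ph]] += bg[row, lj, pj]
                    effect_rows.append((compounds[ci], li, ph, float(bg[row, lj, pj]), "background"))

    effects = pd.DataFrame(
        effect_rows, columns=["compound", "line_id", "phase", "log2_effect", "source"]
    )

    if config.internal_standard_cv > 0:
        sigma = np.sqrt(np.log1p(config.internal_standard_cv**2))
        factors = rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=n_s)
    else:
        factors = np.ones(n_s)
    standard_factors = pd.Series(factors, index=sample_ids, name="standard_factor")

    feat_index = pd.MultiIndex.from_product(
        [compounds, modes], names=["compound", "ion_mode"]
    )
    log10_vals = np.empty((n_c * len(modes), n_s))
    for j, sid in enumerate(sample_ids):
        li, ph = meta.loc[sid, "line_id"], meta.loc[sid, "phase"]
        cell = (
            baseline
            + phase_shift[:, phase_pos[ph]]
            + LOG10_2 * effect[:, line_pos[li], phase_pos[ph]]
        )
        for mj in range(len(modes)):
            noise = rng.normal(0.0, config.replicate_sd, n_c)
            log10_vals[mj :: len(modes), j] = cell + mode_offset[:, mj] + noise
    values = np.power(10.0, log10_vals) * factors[None, :]

    # internal-standard features: constant true abundance, sample factor only
    std_names = [f"IS{i + 1}" for i in range(config.n_standards)]
    std_rows = []
    std_index = []
    for i, name in enumerate(std_names):
        base = config.standard_log10_mean + 0.1 * i
        for mj, mode in enumerate(modes):
            noise = rng.normal(0.0, config.replicate_sd / 4, n_s)
            std_rows.append(np.power(10.0, base + noise) * factors)
            std_index.append((name, mode))
    if std_rows:
        values = np.vstack([values, np.array(std_rows)])
        feat_index = feat_index.append(
            pd.MultiIndex.from_tuples(std_index, names=["compound", "ion_mode"])
        )

    frame = pd.DataFrame(values, index=feat_index, columns=sample_ids)

    # value-based left-censoring: a global detection limit at censor_quantile
    # of the pooled biological values (standards are spiked high and exempt)
    bio = frame.loc[~frame.index.get_level_values("compound").isin(std_names)]
    if config.censor_quantile > 0:
        limit = float(np.quantile(bio.to_numpy().ravel(), config.censor_quantile))
        censored = (frame < limit) & ~frame.index.get_level_values("compound").isin(
            std_names
        )[:, None]
        censored = pd.DataFrame(censored, index=frame.index, columns=frame.columns)
        frame = frame.mask(censored)
    else:
        limit = float("nan")
        censored = pd.DataFrame(False, index=frame.index, columns=frame.columns)

    pt = PeakTable(
        values=frame,
        samples=meta,
        stage="raw",
        standard_features=[(n, m) for n in std_names for m in modes],
    )
    gt = GroundTruth(
        effects=effects,
        block_compounds=block_compounds,
        standard_factors=standard_factors,
        censored=censored,
        detection_limit=limit,
    )
    return pt, gt


def write_ground_truth(gt: GroundTruth, effects_path, factors_path) -> None:
    """Persist ground truth as sidecar delimited files."""
    gt.effects.to_csv(effects_path, index=False)
    gt.standard_factors.rename_axis("sample_id").to_csv(factors_path)
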