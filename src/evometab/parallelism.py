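"""Parallelism statistics: correlation nulls and the shared-change spectrum.

Two complementary views of how repeatable metabolic evolution is across the
twelve replicate lines:

* **Correlation arm** — all 66 pairwise Spearman correlations between the
  lines' log2 fold-change profiles, compared against a null built by
  independently permuting each line's fold-changes across features (which
  preserves every line's marginal distribution while destroying cross-line
  feature matching).  The observed-vs-null comparison is a two-tailed t-test
  (as published) plus an empirical permutation p-value.

* **Spectrum arm** — for each direction of change, the observed number of
  features significantly altered in exactly k of the n lines, against the
  expectation under independence: with p_i the fraction of features altered
  in line i, the number of lines sharing a change is Poisson-binomial
  distributed (a sum of independent, non-identically distributed Bernoulli
  variables), whose pmf is computed exactly by iterative convolution.
  Excess observed counts at high k indicate parallel (possibly selected)
  metabolic change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .foldchange import foldchange_matrix
from .peak_table import PeakTable


# -- Poisson binomial / SINIB ----------------------------------------------

def poisson_binomial_pmf(p) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(p_i) variables.

    Iterative convolution (dynamic programming): after absorbing each
    Bernoulli the vector holds the pmf of the partial sum; O(n^2) total.
    Returns an array of length n+1 over k = 0..n.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D probability vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    pmf = np.zeros(p.size + 1)
    pmf[0] = 1.0
    for i, pi in enumerate(p):
        prev = pmf[: i + 1].copy()
        pmf[: i + 1] = prev * (1.0 - pi)
        pmf[1 : i + 2] += prev * pi
    return pmf


def sinib_pmf(sizes, p) -> np.ndarray:
    """Pmf of a sum of independent Binomial(n_i, p_i) variables.

    The general sum-of-independent-non-identical-binomials case; with every
    n_i = 1 it reduces to :func:`poisson_binomial_pmf`.  Computed by
    convolving the component binomial pmfs.
    """
    sizes = np.asarray(sizes, dtype=int)
    p = np.asarray(p, dtype=float)
    if sizes.shape != p.shape:
        raise ValueError("sizes and p must have matching shapes")
    if np.any(sizes < 0):
        raise ValueError("sizes must be nonnegative")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    pmf = np.array([1.0])
    for n_i, p_i in zip(sizes, p):
        comp = stats.binom.pmf(np.arange(n_i + 1), n_i, p_i)
        pmf = np.convolve(pmf, comp)
    return pmf


@dataclass
class PoissonBinomialDist:
    """Exact distribution of the number of lines sharing a change."""

    p: np.ndarray
    pmf: np.ndarray = field(init=False)

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        self.pmf = poisson_binomial_pmf(self.p)

    @property
    def mean(self) -> float:
        return float(self.p.sum())


def poisson_binomial(p) -> PoissonBinomialDist:
    return PoissonBinomialDist(p)


# -- Spearman correlations ---------------------------------------------------

def spearman_pairs(fct: pd.DataFrame, phase: str) -> pd.DataFrame:
    """All pairwise Spearman correlations between evolved-line profiles.

    Fold-change profiles are the per-line log2 fold-change vectors over
    features; ties get average ranks; features with a missing value in
    either line of a pair are dropped pairwise.  A line with a constant
    profile yields undefined correlations, recorded as NaN with a warning.

    Returns a DataFrame with columns line_a, line_b, rho (66 rows for 12
    lines).
    """
    mat = foldchange_matrix(fct, phase)
    if mat.shape[0] < 3:
        raise ValueError("need at least 3 features for rank correlations")
    lines = list(mat.columns)
    rows = []
    for i, a in enumerate(lines):
        for b in lines[i + 1 :]:
            x, y = mat[a].to_numpy(), mat[b].to_numpy()
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3 or np.all(x[ok] == x[ok][0]) or np.all(y[ok] == y[ok][0]):
                warnings.warn(f"rho undefined for pair ({a}, {b}); recording NaN", stacklevel=2)
                rho = np.nan
            else:
                rho = stats.spearmanr(x[ok], y[ok]).statistic
            rows.append((a, b, rho))
    return pd.DataFrame(rows, columns=["line_a", "line_b", "rho"])


def _rank_z(mat: np.ndarray) -> np.ndarray:
    """Row-wise average ranks, standardized to zero mean / unit variance."""
    ranks = np.apply_along_axis(stats.rankdata, 1, mat)
    z = ranks - ranks.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, keepdims=True)
    sd[sd == 0] = np.nan
    return z / sd


@dataclass
class CorrelationNullResult:
    """Observed pairwise correlations and their within-line permutation null."""

    phase: str
    pairs: pd.DataFrame  # line_a, line_b, rho (observed)
    null_rhos: np.ndarray  # B x n_pairs
    t_stat: float
    p_value: float  # two-tailed Welch t-test, observed vs pooled null
    p_empirical: float  # permutation p on the mean observed rho
    mean_observed: float
    mean_null: float

    @property
    def rho_observed(self) -> np.ndarray:
        return self.pairs["rho"].to_numpy()


class PermutationCorrelationTest(BaseEstimator):
    """Observed vs within-line-randomized pairwise Spearman correlations.

    Each of ``n_permutations`` iterations independently shuffles every line's
    fold-change values across features and recomputes all pairwise
    correlations.  Because Spearman's rho is Pearson on ranks and shuffling
    values shuffles ranks, the engine permutes pre-standardized rank vectors
    and takes inner products, which keeps 100,000 iterations tractable.

    Attributes (after fit): ``result_`` (:class:`CorrelationNullResult`),
    plus ``t_stat_``, ``p_value_``, ``p_empirical_`` shortcuts.
    """

    def __init__(self, phase: str, n_permutations: int = 100_000, random_state=None):
        self.phase = phase
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, fct: pd.DataFrame, y=None):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        observed = spearman_pairs(fct, self.phase)
        mat = foldchange_matrix(fct, self.phase).to_numpy().T  # lines x features
        L, N = mat.shape
        z = _rank_z(mat)
        rng = np.random.default_rng(self.random_state)
        iu = np.triu_indices(L, k=1)
        B = self.n_permutations
        null = np.empty((B, iu[0].size))
        for b in range(B):
            zp = rng.permuted(z, axis=1)  # independent shuffle of every line
            corr = (zp @ zp.T) / N
            null[b] = corr[iu]

        obs = observed["rho"].to_numpy()
        obs_ok = obs[~np.isnan(obs)]
        pooled = null.ravel()
        pooled = pooled[~np.isnan(pooled)]
        t = stats.ttest_ind(obs_ok, pooled, equal_var=False)
        # empirical two-sided p on the per-iteration mean rho
        null_means = np.nanmean(null, axis=1)
        center = null_means.mean()
        p_emp = (
            1.0 + np.sum(np.abs(null_means - center) >= abs(obs_ok.mean() - center))
        ) / (B + 1.0)

        self.result_ = CorrelationNullResult(
            phase=self.phase,
            pairs=observed,
            null_rhos=null,
            t_stat=float(t.statistic),
            p_value=float(t.pvalue),
            p_empirical=float(p_emp),
            mean_observed=float(obs_ok.mean()),
            mean_null=float(pooled.mean()),
        )
        self.t_stat_ = self.result_.t_stat
        self.p_value_ = self.result_.p_value
        self.p_empirical_ = self.result_.p_empirical
        return self


def permutation_null(
    fct: pd.DataFrame, phase: str, n_permutations: int = 100_000, seed=None
) -> CorrelationNullResult:
    """Within-line randomization null for pairwise fold-change correlations."""
    return (
        PermutationCorrelationTest(phase, n_permutations, random_state=seed)
        .fit(fct)
        .result_
    )


def phase_contrast(cs_exp: CorrelationNullResult, cs_stat: CorrelationNullResult) -> dict:
    """Two-sided t-test of observed exponential vs stationary correlations."""
    a = cs_exp.rho_observed
    b = cs_stat.rho_observed
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if np.array_equal(a, b):
        t_stat, p = 0.0, 1.0
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return {
        "t_stat": t_stat,
        "p_value": p,
        "mean_rho_exponential": float(a.mean()),
        "mean_rho_stationary": float(b.mean()),
        "difference": float(a.mean() - b.mean()),
    }


def within_across_phase_correlations(pt: PeakTable) -> dict:
    """Sample-sample correlations of log abundances, within vs across phase.

    Spearman correlations of log10 abundances for every unordered sample
    pair, labeled "within" when the samples share a growth phase.  Returns
    the tidy pair table plus a Mann-Whitney comparison of the two groups.
    """
    vals = np.log10(pt.values.mask(pt.values <= 0))
    sids = list(vals.columns)
    phases = pt.samples.loc[sids, "phase"]
    rows = []
    for i, a in enumerate(sids):
        for b in sids[i + 1 :]:
            x, y = vals[a].to_numpy(), vals[b].to_numpy()
            ok = ~(np.isnan(x) | np.isnan(y))
            rho = stats.spearmanr(x[ok], y[ok]).statistic if ok.sum() >= 3 else np.nan
            rows.append((a, b, "within" if phases[a] == phases[b] else "across", rho))
    table = pd.DataFrame(rows, columns=["sample_a", "sample_b", "group", "rho"])
    within = table.loc[table["group"] == "within", "rho"].dropna()
    across = table.loc[table["group"] == "across", "rho"].dropna()
    out = {
        "pairs": table,
        "median_within": float(within.median()) if len(within) else np.nan,
        "median_across": float(across.median()) if len(across) else np.nan,
        "single_phase": len(across) == 0,
    }
    if len(across) and len(within):
        mw = stats.mannwhitneyu(within, across, alternative="greater")
        out["mannwhitney_p"] = float(mw.pvalue)
    return out


# -- shared-change spectrum --------------------------------------------------

def line_probabilities(
    calls: pd.DataFrame, phase: str, direction: str, lines=None
) -> pd.Series:
    """Per-line probability of a feature being altered in ``direction``.

    p_i = (# features called ``direction`` in line i) / (# features), for
    the given growth phase.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    sel = calls[calls["phase"] == phase]
    if sel.empty:
        raise ValueError(f"no calls for phase {phase!r}")
    if lines is None:
        lines = list(dict.fromkeys(sel["line_id"]))
    n_features = sel.groupby("line_id").size().reindex(lines)
    hits = (
        sel[sel["direction"] == direction].groupby("line_id").size().reindex(lines).fillna(0)
    )
    return (hits / n_features).rename("p")


@dataclass
class ParallelismSpectrum:
    """Observed vs expected counts of features altered in exactly k lines."""

    phase: str
    direction: str
    k: np.ndarray
    observed: np.ndarray  # O_k, integer counts
    expected: np.ndarray  # E_k = N * PoissonBinomial(p).pmf[k]
    probabilities: pd.Series  # per-line p_i
    n_features: int

    @property
    def excess(self) -> np.ndarray:
        """O_k - E_k, the published observed-minus-expected comparison."""
        return self.observed - self.expected

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k,
                "observed": self.observed,
                "expected": self.expected,
                "excess": self.excess,
            }
        )


def parallelism_spectrum(
    calls: pd.DataFrame, phase: str, direction: str, lines=None
) -> ParallelismSpectrum:
    """Observed vs Poisson-binomial-expected shared-change counts.

    O_k counts the features altered in ``direction`` in exactly k of the n
    evolved lines; E_k = N * pmf[k] with the pmf of the Poisson binomial
    parameterized by the per-line alteration probabilities.  Both sum to the
    number of features N, so the spectrum is a proper redistribution.
    """
    p = line_probabilities(calls, phase, direction, lines=lines)
    lines = list(p.index)
    sel = calls[(calls["phase"] == phase) & (calls["line_id"].isin(lines))]
    hit = sel.assign(hit=(sel["direction"] == direction).astype(int))
    per_feature = hit.pivot_table(
        index=["compound", "ion_mode"], columns="line_id", values="hit", sort=False
    )[lines]
    k_per_feature = per_feature.sum(axis=1).astype(int)
    n = len(lines)
    observed = np.bincount(k_per_feature, minlength=n + 1)
    N = int(per_feature.shape[0])
    expected = N * poisson_binomial_pmf(p.to_numpy())
    return ParallelismSpectrum(
        phase=phase,
        direction=direction,
        k=np.arange(n + 1),
        observed=observed,
        expected=expected,
        probabilities=p,
        n_features=N,
    )


class SharedChangeSpectrum(BaseEstimator):
    """Estimator wrapper around :func:`parallelism_spectrum`.

    fit(calls) computes ``spectrum_`` (a :class:`ParallelismSpectrum`) for
    the configured phase/direction, with ``observed_``, ``expected_`` and
    ``excess_`` shortcuts.
    """

    def __init__(self, phase: str, direction: str, lines=None):
        self.phase = phase
        self.direction = direction
        self.lines = lines

    def fit(self, calls: pd.DataFrame, y=None):
        self.spectrum_ = parallelism_spectrum(
            calls, self.phase, self.direction, lines=self.lines
        )
        self.observed_ = self.spectrum_.observed
        self.expected_ = self.spectrum_.expected
        self.excess_ = self.spectrum_.excess
        return self


def cluster_lines(pairs: pd.DataFrame):
    """Average-linkage hierarchical clustering of lines on distance 1 - rho.

    Returns (line order, scipy linkage matrix); the companion of the
    published network panels where lines are arranged by similarity.
    """
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    lines = sorted(set(pairs["line_a"]) | set(pairs["line_b"]))
    idx = {li: i for i, li in enumerate(lines)}
    d = np.zeros((len(lines), len(lines)))
    for _, row in pairs.iterrows():
        i, j = idx[row["line_a"]], idx[row["line_b"]]
        d[i, j] = d[j, i] = 1.0 - row["rho"]
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    order = [lines[i] for i in hierarchy.leaves_list(link)]
    return order, link
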