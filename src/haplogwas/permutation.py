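"""Permutation null for the association scan: expected hit counts, FDR,
true-positive fractions, and expected-count-calibrated thresholds.

The null shuffles the binary class vector among strains (class counts
preserved; classes are NOT re-derived from frequencies per permutation) and
re-runs the Fisher scan. The expected hit count at a threshold t is the
null-average number of sites with p strictly below t; FDR at t is
expected/observed, reported unclipped.

The scan over permutations is vectorized: per-site minor-allele indicator
matrices are multiplied against the stacked permuted class vectors, the
resulting integer tables are deduplicated, and each distinct table is
evaluated once through the memoized Fisher test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .association import (
    ContingencyTable,
    TWO_SIDED,
    _aligned_strains,
    fisher_p,
    minor_indicator,
)
from .genotype import GenotypeMatrix
from .phenotype import LOW, HIGH, BinaryPhenotype

UNDEFINED = "NA"


@dataclass(frozen=True)
class PermutationPlan:
    """How to build the null: Monte-Carlo shuffles or exhaustive enumeration."""

    n_permutations: int = 1000
    seed: int = 0
    mode: str = "monte_carlo"
    exhaustive_limit: int = 200_000

    def __post_init__(self):
        if self.mode not in ("monte_carlo", "exhaustive"):
            raise ParameterError(f"unknown permutation mode {self.mode!r}")
        if self.mode == "monte_carlo" and self.n_permutations < 1:
            raise ParameterError("n_permutations must be >= 1")


def _n_assignments(n_strains: int, n_low: int) -> int:
    return math.comb(n_strains, n_low)


def permuted_low_matrix(bp: BinaryPhenotype, plan: PermutationPlan, strains=None) -> np.ndarray:
    """Boolean matrix, one row per permutation, True = low label.

    Monte-Carlo rows are uniform shuffles of the observed class vector,
    reproducible from ``plan.seed``; exhaustive rows enumerate every distinct
    placement of the low labels exactly once.
    """
    strains = bp.strains if strains is None else list(strains)
    base = bp.low_vector(strains)
    S = len(strains)
    if plan.mode == "exhaustive":
        n_low = int(base.sum())
        total = _n_assignments(S, n_low)
        if total > plan.exhaustive_limit:
            raise ParameterError(
                f"exhaustive mode needs C({S},{n_low}) = {total} assignments "
                f"> limit {plan.exhaustive_limit}; use monte_carlo"
            )
        out = np.zeros((total, S), dtype=bool)
        for r, combo in enumerate(itertools.combinations(range(S), n_low)):
            out[r, list(combo)] = True
        return out
    rng = np.random.default_rng(plan.seed)
    out = np.empty((plan.n_permutations, S), dtype=bool)
    for r in range(plan.n_permutations):
        out[r] = rng.permutation(base)
    return out


def permute_classes(bp: BinaryPhenotype, plan: PermutationPlan) -> list[BinaryPhenotype]:
    """Materialize permuted phenotypes as BinaryPhenotype objects."""
    strains = bp.strains
    rows = permuted_low_matrix(bp, plan, strains)
    return [
        bp.with_classes({s: (LOW if rows[r, j] else HIGH) for j, s in enumerate(strains)})
        for r in range(rows.shape[0])
    ]


def _null_p_matrix(
    gm: GenotypeMatrix, bp: BinaryPhenotype, low_rows: np.ndarray, sided: str
) -> np.ndarray:
    """p-values for every (permutation, site) pair, via table deduplication."""
    strains = _aligned_strains(gm, bp)
    ind = minor_indicator(gm, strains)  # M x S
    m1 = (ind == 1).astype(np.int64)
    nonmiss = (ind >= 0).astype(np.int64)
    minor_tot = m1.sum(axis=1)  # per site
    nonmiss_tot = nonmiss.sum(axis=1)
    L = low_rows.astype(np.int64).T  # S x P
    A = m1 @ L  # M x P: low & minor
    NL = nonmiss @ L  # low & non-missing
    B = NL - A
    C = minor_tot[:, None] - A
    D = (nonmiss_tot - minor_tot)[:, None] - B
    key = ((A * 200 + B) * 200 + C) * 200 + D
    uniq, inverse = np.unique(key, return_inverse=True)
    p_uniq = np.empty(uniq.shape, dtype=float)
    for k, enc in enumerate(uniq):
        enc = int(enc)
        d = enc % 200
        enc //= 200
        c = enc % 200
        enc //= 200
        b = enc % 200
        a = enc // 200
        if a + c == 0 or b + d == 0:
            p_uniq[k] = 1.0  # monomorphic among tested strains
        else:
            p_uniq[k] = fisher_p(ContingencyTable(a, b, c, d), sided)
    return p_uniq[inverse].reshape(key.shape).T  # P x M


@dataclass
class NullDistribution:
    """Per-permutation p-values of the shuffled-class scan, in compact form."""

    plan: PermutationPlan
    n_sites: int
    n_permutations: int
    min_p: np.ndarray = field(repr=False)
    #: sorted distinct p-values observed anywhere in the null
    grid: np.ndarray = field(repr=False)
    #: (P x G) counts of each grid value within each permutation
    counts: np.ndarray = field(repr=False)

    def hit_counts(self, p_thresh: float) -> np.ndarray:
        """Per-permutation number of sites with p strictly below the threshold."""
        g = int(np.searchsorted(self.grid, p_thresh, side="left"))
        return self.counts[:, :g].sum(axis=1)

    def expected_count(self, p_thresh: float) -> float:
        return float(self.hit_counts(p_thresh).mean())


def build_null(
    gm: GenotypeMatrix,
    bp: BinaryPhenotype,
    plan: PermutationPlan,
    sided: str = TWO_SIDED,
) -> NullDistribution:
    strains = _aligned_strains(gm, bp)
    low_rows = permuted_low_matrix(bp, plan, strains)
    pmat = _null_p_matrix(gm, bp, low_rows, sided)
    grid = np.unique(pmat)
    counts = np.empty((pmat.shape[0], grid.size), dtype=np.int64)
    for r in range(pmat.shape[0]):
        idx = np.searchsorted(grid, pmat[r])
        counts[r] = np.bincount(idx, minlength=grid.size)
    return NullDistribution(
        plan=plan,
        n_sites=pmat.shape[1],
        n_permutations=pmat.shape[0],
        min_p=pmat.min(axis=1) if pmat.size else np.ones(pmat.shape[0]),
        grid=grid,
        counts=counts,
    )


def expected_count(
    gm: GenotypeMatrix,
    bp: BinaryPhenotype,
    plan: PermutationPlan,
    p_thresh: float,
    sided: str = TWO_SIDED,
    null: NullDistribution | None = None,
) -> float:
    """Null-average number of sites with Fisher p < p_thresh (strict)."""
    null = null or build_null(gm, bp, plan, sided)
    return null.expected_count(p_thresh)


def render_percent(fraction: float) -> str:
    """Percent rendering: one decimal below 1%, integer percent otherwise."""
    pct = 100.0 * fraction
    if pct < 1.0:
        return f"{pct:.1f}%"
    return f"{round(pct):d}%"


@dataclass(frozen=True)
class FdrEstimate:
    observed_count: int
    expected_count: float
    fdr: float | None  # None when observed_count == 0 (undefined, not 0)

    @property
    def rendered(self) -> str:
        return UNDEFINED if self.fdr is None else render_percent(self.fdr)


def fdr_estimate(observed_count: int, expected_count: float) -> FdrEstimate:
    """Experiment-wise FDR = expected/observed at a threshold, unclipped."""
    if observed_count < 0 or expected_count < 0:
        raise ParameterError("counts must be non-negative")
    if observed_count == 0:
        return FdrEstimate(0, float(expected_count), None)
    return FdrEstimate(int(observed_count), float(expected_count), expected_count / observed_count)


def tp_fraction(observed_count: int, expected_count: float) -> float:
    """Estimated true-positive fraction, floored at 0."""
    if observed_count <= 0:
        raise ParameterError("tp_fraction requires observed_count > 0")
    if expected_count < 0:
        raise ParameterError("expected_count must be non-negative")
    return max(0.0, (observed_count - expected_count) / observed_count)


def threshold_for_expected(
    gm: GenotypeMatrix,
    bp: BinaryPhenotype,
    plan: PermutationPlan,
    target_expected: float,
    sided: str = TWO_SIDED,
    null: NullDistribution | None = None,
) -> float:
    """Largest threshold on the null p-value grid with expected count <= target.

    Thresholds are taken from the sorted distinct null p-values, so this is a
    grid inversion of :func:`expected_count` (which uses strict ``<``).
    """
    if target_expected < 0:
        raise ParameterError("target_expected must be >= 0")
    null = null or build_null(gm, bp, plan, sided)
    if null.grid.size == 0:
        raise ValidationError("null distribution is degenerate (no p-values)")
    for t in null.grid[::-1]:
        if null.expected_count(float(t)) <= target_expected:
            return float(t)
    raise ValidationError("no grid threshold satisfies the expected-count target")


@dataclass(frozen=True)
class ThresholdSummary:
    p_thresh: float
    observed_count: int
    expected_count: float
    fdr: float | None
    tp_fraction: float | None

    @property
    def fdr_rendered(self) -> str:
        return UNDEFINED if self.fdr is None else render_percent(self.fdr)

    @property
    def tp_rendered(self) -> str:
        return UNDEFINED if self.tp_fraction is None else render_percent(self.tp_fraction)


def summarize_thresholds(
    real_p: np.ndarray, null: NullDistribution, thresholds
) -> list[ThresholdSummary]:
    """ThresholdSummary rows for each queried p-value threshold."""
    real_p = np.asarray(real_p, dtype=float)
    out = []
    for t in thresholds:
        if not (0 < t <= 1):
            raise ParameterError(f"threshold must be in (0, 1], got {t}")
        obs = int(np.sum(real_p < t))
        exp = null.expected_count(t)
        est = fdr_estimate(obs, exp)
        tp = None if obs == 0 else tp_fraction(obs, exp)
        out.append(ThresholdSummary(float(t), obs, exp, est.fdr, tp))
    return out


def summary_frame(summaries: list[ThresholdSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "p_thresh": [s.p_thresh for s in summaries],
            "observed_count": [s.observed_count for s in summaries],
            "expected_count": [s.expected_count for s in summaries],
            "fdr": [s.fdr if s.fdr is not None else float("nan") for s in summaries],
            "fdr_rendered": [s.fdr_rendered for s in summaries],
            "tp_fraction": [
                s.tp_fraction if s.tp_fraction is not None else float("nan")
                for s in summaries
            ],
            "tp_rendered": [s.tp_rendered for s in summaries],
        }
    )
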