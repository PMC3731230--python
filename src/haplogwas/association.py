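"""Per-site Fisher exact tests of allele x communication-class co-inheritance.

The 2x2 table counts strains by (class, allele) at one site, excluding
strains whose call is missing there:

    a = low & minor    b = low & major
    c = high & minor   d = high & major

``fisher_p`` is the exact hypergeometric test with fixed margins, computed
with integer binomial coefficients so the two-sided "point probability <=
observed" comparison is exact (the documented 1e-7 relative tolerance is
subsumed). Results are memoized on (a, b, c, d, sidedness), which makes a
permutation scan's cost scale with the number of distinct tables rather
than sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .genotype import MISSING, GenotypeMatrix, SiteInfo
from .phenotype import BinaryPhenotype

TWO_SIDED = "two"
ONE_SIDED = "one"

#: Relative slack for the two-sided point-probability comparison. With exact
#: integer weights the comparison is already exact; kept for the contract.
REL_TOL = 1e-7


class ContingencyTable(NamedTuple):
    a: int  # low-class strains carrying the minor allele
    b: int  # low-class strains carrying the major allele
    c: int  # high-class strains carrying the minor allele
    d: int  # high-class strains carrying the major allele


@dataclass(frozen=True)
class AssociationResult:
    site: SiteInfo
    table: ContingencyTable
    p_value: float
    degenerate: bool = False
    minor_allele: int = 0

    @property
    def neglog10_p(self) -> float:
        return -math.log10(self.p_value)


@lru_cache(maxsize=None)
def _fisher(a: int, b: int, c: int, d: int, sided: str) -> float:
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0
    r2 = c + d
    lo, hi = max(0, c1 - r2), min(r1, c1)
    # integer point weights: C(r1, x) * C(r2, c1 - x); denominator C(n, c1)
    weights = {x: math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)}
    total = sum(weights.values())
    if sided == ONE_SIDED:
        tail = sum(w for x, w in weights.items() if x >= a)
    else:
        w_obs = weights[a]
        tail = sum(w for w in weights.values() if w <= w_obs)
    return min(1.0, tail / total)


def fisher_p(t: ContingencyTable, sided: str = TWO_SIDED) -> float:
    """Exact Fisher p-value for a 2x2 table.

    Two-sided (default) sums the probabilities of all tables with the same
    margins whose point probability is at most that of the observed table;
    one-sided takes the tail toward enrichment of the minor allele in the
    low class (``a`` large).
    """
    if sided not in (TWO_SIDED, ONE_SIDED):
        raise ParameterError(f"sided must be 'two' or 'one', got {sided!r}")
    a, b, c, d = (int(v) for v in t)
    if min(a, b, c, d) < 0:
        raise ValidationError(f"negative contingency entries: {(a, b, c, d)}")
    return _fisher(a, b, c, d, sided)


def fisher_cache_info():
    return _fisher.cache_info()


def fisher_cache_clear() -> None:
    _fisher.cache_clear()


def _aligned_strains(gm: GenotypeMatrix, bp: BinaryPhenotype) -> list[str]:
    known = set(gm.strains)
    tested = [s for s in bp.strains if s in known]
    if not tested:
        raise ValidationError("genotype and phenotype strain sets are disjoint")
    return tested


def minor_indicator(gm: GenotypeMatrix, strains: list[str]) -> np.ndarray:
    """M x len(strains) int8 matrix: 1 minor, 0 major, -1 missing.

    Minor/major orientation is recomputed per site from the tested strains'
    non-missing counts (ties toward allele 0). The orientation is invariant
    under class permutation, so permutation scans may reuse this matrix.
    """
    cols = [gm.strain_index()[s] for s in strains]
    sub = gm.calls[:, cols] if gm.n_sites else gm.calls
    out = np.full(sub.shape, MISSING, dtype=np.int8)
    for i in range(gm.n_sites):
        if len(gm.sites[i].alleles) > 2:
            raise ValidationError(
                f"association requires biallelic sites; {gm.sites[i].key} has more states"
            )
        row = sub[i]
        n0 = int(np.sum(row == 0))
        n1 = int(np.sum(row == 1))
        minor = 1 if n1 < n0 else 0
        out[i][row == minor] = 1
        out[i][(row != minor) & (row != MISSING)] = 0
    return out


def build_table(gm: GenotypeMatrix, site_index: int, bp: BinaryPhenotype) -> ContingencyTable:
    """Count tested strains by (class, allele) at one site."""
    if not (0 <= site_index < gm.n_sites):
        raise ParameterError(f"site_index {site_index} out of range [0, {gm.n_sites})")
    strains = _aligned_strains(gm, bp)
    ind = minor_indicator(gm.take_sites([site_index]), strains)[0]
    low = bp.low_vector(strains)
    a = int(np.sum((ind == 1) & low))
    b = int(np.sum((ind == 0) & low))
    c = int(np.sum((ind == 1) & ~low))
    d = int(np.sum((ind == 0) & ~low))
    return ContingencyTable(a, b, c, d)


def scan(
    gm: GenotypeMatrix, bp: BinaryPhenotype, sided: str = TWO_SIDED
) -> list[AssociationResult]:
    """One Fisher exact result per site, input order preserved.

    Sites monomorphic among the tested non-missing strains keep p = 1 and a
    degenerate flag rather than being dropped, so site counts reconcile
    across pipeline stages.
    """
    strains = _aligned_strains(gm, bp)
    dropped = set(bp.strains) - set(strains)
    if dropped:
        import logging

        logging.getLogger(__name__).warning(
            "scan: dropping %d phenotyped strains absent from genotypes: %s",
            len(dropped), sorted(dropped),
        )
    ind = minor_indicator(gm, strains)
    low = bp.low_vector(strains)
    cols = [gm.strain_index()[s] for s in strains]
    results = []
    for i, site in enumerate(gm.sites):
        row = ind[i]
        a = int(np.sum((row == 1) & low))
        b = int(np.sum((row == 0) & low))
        c = int(np.sum((row == 1) & ~low))
        d = int(np.sum((row == 0) & ~low))
        table = ContingencyTable(a, b, c, d)
        degenerate = (a + c == 0) or (b + d == 0)
        p = 1.0 if degenerate else fisher_p(table, sided)
        n0 = int(np.sum(gm.calls[i][cols] == 0))
        n1 = a + b + c + d - n0
        results.append(
            AssociationResult(
                site=site,
                table=table,
                p_value=p,
                degenerate=degenerate,
                minor_allele=1 if n1 < n0 else 0,
            )
        )
    return results


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tabular view of scan output (the Manhattan-plot source)."""
    return pd.DataFrame(
        {
            "chrom": [r.site.chromosome for r in results],
            "pos": [r.site.position for r in results],
            "a": [r.table.a for r in results],
            "b": [r.table.b for r in results],
            "c": [r.table.c for r in results],
            "d": [r.table.d for r in results],
            "p": [r.p_value for r in results],
            "neglog10_p": [r.neglog10_p for r in results],
            "flags": ["degenerate" if r.degenerate else "" for r in results],
        }
    )
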