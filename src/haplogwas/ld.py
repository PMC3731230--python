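"""Pairwise linkage disequilibrium (r^2) among haploid biallelic sites.

Strains are haplotypes, so allele-frequency LD applies directly: with
allele-1 frequencies p_i, p_j and joint frequency p_ij over the
pairwise-complete strains, D = p_ij - p_i * p_j and
r^2 = D^2 / (p_i (1 - p_i) p_j (1 - p_j)). Pairs where either site is
monomorphic among the pairwise-complete strains are NaN (undefined), never
0 — zero would assert equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .genotype import MISSING, GenotypeMatrix, SiteInfo


@dataclass
class LDMatrix:
    """Symmetric r^2 grid with per-pair counts of pairwise-complete strains."""

    sites: list[SiteInfo]
    r2: np.ndarray = field(repr=False)
    n_used: np.ndarray = field(repr=False)


def _r2_from_vectors(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    ok = (x != MISSING) & (y != MISSING)
    n = int(ok.sum())
    if n == 0:
        return math.nan, 0
    xi = x[ok].astype(np.int64)
    yi = y[ok].astype(np.int64)
    # integer formulation: r^2 = (n*s_ij - s_i*s_j)^2 / (s_i(n-s_i)s_j(n-s_j));
    # exact, so duplicated vectors give exactly 1.0
    s_i = int(xi.sum())
    s_j = int(yi.sum())
    s_ij = int((xi * yi).sum())
    denom = s_i * (n - s_i) * s_j * (n - s_j)
    if denom == 0:
        return math.nan, n
    num = n * s_ij - s_i * s_j
    return min(1.0, (num * num) / denom), n


def r2_pair(gm: GenotypeMatrix, i: int, j: int) -> float:
    """r^2 between sites i and j over pairwise-complete strains (NaN if undefined)."""
    for k in (i, j):
        if not (0 <= k < gm.n_sites):
            raise ParameterError(f"site index {k} out of range [0, {gm.n_sites})")
        if len(gm.sites[k].alleles) > 2:
            raise ValidationError(f"r2 requires biallelic sites; {gm.sites[k].key}")
    r2, _ = _r2_from_vectors(gm.calls[i], gm.calls[j])
    return r2


def r2_matrix(gm: GenotypeMatrix) -> LDMatrix:
    """All-pairs r^2 for a (typically region-restricted, MAF-filtered) matrix."""
    m = gm.n_sites
    r2 = np.full((m, m), math.nan)
    n_used = np.zeros((m, m), dtype=np.int64)
    for i in range(m):
        for j in range(i, m):
            val, n = _r2_from_vectors(gm.calls[i], gm.calls[j])
            r2[i, j] = r2[j, i] = val
            n_used[i, j] = n_used[j, i] = n
    return LDMatrix(sites=list(gm.sites), r2=r2, n_used=n_used)


def long_format(ldm: LDMatrix, min_pair_n: int = 0) -> pd.DataFrame:
    """Upper-triangle (incl. diagonal) heatmap-ready table."""
    rows = []
    for i, si in enumerate(ldm.sites):
        for j in range(i, len(ldm.sites)):
            if ldm.n_used[i, j] < min_pair_n:
                continue
            sj = ldm.sites[j]
            rows.append(
                (si.chromosome, si.position, sj.position, ldm.r2[i, j], ldm.n_used[i, j])
            )
    return pd.DataFrame(rows, columns=["chrom", "pos_i", "pos_j", "r2", "n_used"])
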