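"""Shared test utilities: matrix builders and independent oracles.

Oracles here are deliberately naive (explicit enumeration, exact rational
arithmetic) and independent of the library code paths they check.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

from haplogwas.genotype import MISSING, GenotypeMatrix, SiteInfo
from haplogwas.phenotype import BinaryPhenotype, FusionMeasurement, PhenotypeTable


def gm_from_strings(rows, strains=None):
    """Build a GenotypeMatrix from [(chrom, pos, "AG.A"), ...] rows.

    Each character is one strain's allele state; '.' is missing. Allele
    tuples are the sorted observed states, calls index into them.
    """
    n = len(rows[0][2]) if rows else 0
    strains = strains or [f"S{i+1:02d}" for i in range(n)]
    sites, calls = [], []
    for chrom, pos, chars in rows:
        observed = tuple(sorted({c for c in chars if c != "."}))
        code = {c: i for i, c in enumerate(observed)}
        sites.append(SiteInfo(chrom, pos, observed))
        calls.append([MISSING if c == "." else code[c] for c in chars])
    arr = np.array(calls, dtype=np.int8) if calls else np.empty((0, len(strains)), dtype=np.int8)
    return GenotypeMatrix(sites=sites, strains=list(strains), calls=arr)


def random_gm(rng, n_sites=20, n_strains=8, missing_rate=0.1, chroms=("I", "II")):
    """Random valid matrix (sorted sites, alleles = observed states)."""
    nucs = "ACGT"
    rows = []
    used = set()
    for _ in range(n_sites):
        chrom = chroms[rng.integers(len(chroms))]
        while True:
            pos = int(rng.integers(1, 10_000))
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                break
        pair = rng.choice(4, size=2, replace=False)
        chars = "".join(
            "." if rng.random() < missing_rate else nucs[pair[rng.integers(2)]]
            for _ in range(n_strains)
        )
        rows.append((chrom, pos, chars))
    rows.sort(key=lambda r: (chroms.index(r[0]), r[1]))
    return gm_from_strings(rows)


def make_bp(classes, grand_mean=0.7, grand_sd=0.2, sd_mode="sample"):
    return BinaryPhenotype(dict(classes), grand_mean, grand_sd, sd_mode)


def pt_from_freqs(freqs, total=100):
    """One measurement per strain with frequency fused/total."""
    ms = []
    for strain, f in freqs.items():
        fused = round(f * total)
        assert abs(fused - f * total) < 1e-9, "frequency not representable"
        ms.append(FusionMeasurement(strain, 1, 1, fused, total))
    return PhenotypeTable(ms)


def fisher_oracle(a, b, c, d, sided="two") -> Fraction:
    """Exact-rational Fisher p by brute-force hypergeometric enumeration."""
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    if n == 0:
        return Fraction(1)
    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {
        x: Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)
        for x in range(lo, hi + 1)
    }
    if sided == "one":
        tail = sum(p for x, p in probs.items() if x >= a)
    else:
        p_obs = probs[a]
        tail = sum(p for p in probs.values() if p <= p_obs)
    return min(Fraction(1), tail)


def brute_force_table(gm, site_index, bp):
    """Naive double loop over strains for the 2x2 (class x allele) table."""
    strains = [s for s in bp.strains if s in gm.strains]
    col = {s: gm.strains.index(s) for s in strains}
    calls = {s: int(gm.calls[site_index, col[s]]) for s in strains}
    observed = [v for v in calls.values() if v != MISSING]
    n0 = sum(1 for v in observed if v == 0)
    n1 = sum(1 for v in observed if v == 1)
    minor = 1 if n1 < n0 else 0
    a = b = c = d = 0
    for s in strains:
        v = calls[s]
        if v == MISSING:
            continue
        low = bp.classes[s] == "low"
        if v == minor:
            if low:
                a += 1
            else:
                c += 1
        else:
            if low:
                b += 1
            else:
                d += 1
    return a, b, c, d


def r2_oracle(x, y):
    """Direct frequency arithmetic over pairwise-complete haploid calls."""
    pairs = [(xi, yi) for xi, yi in zip(x, y) if xi != MISSING and yi != MISSING]
    if not pairs:
        return None
    n = len(pairs)
    p_i = sum(a for a, _ in pairs) / n
    p_j = sum(b for _, b in pairs) / n
    p_ij = sum(1 for a, b in pairs if a == 1 and b == 1) / n
    denom = p_i * (1 - p_i) * p_j * (1 - p_j)
    if denom == 0:
        return None
    dcoef = p_ij - p_i * p_j
    return dcoef * dcoef / denom
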