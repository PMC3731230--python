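"""Synthetic haploid genotype matrices and replicate fusion-count phenotypes.

Genotypes: per chromosome, sites sit at sorted uniform positions; the first
site's alleles are independent Bernoulli draws at a per-site minor-allele
frequency drawn from ``maf_range``, and each subsequent site copies each
strain's previous-site allele with probability ``ld_rho`` (else redraws),
giving r^2 that decays geometrically with site lag.

Phenotypes: each strain's true fusion probability is
logistic(logit(penetrance[allele class]) + strain effect), with the strain
effect Normal(0, strain_effect_sd) on the logit scale; each replicate's
fused count is Binomial(pairs_per_replicate, true probability).

One master seed; sub-streams are derived per chromosome and per strain, so
adding sites never perturbs the phenotype draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .genotype import MISSING, GenotypeMatrix, ROMAN_ORDER, SiteInfo
from .phenotype import FusionMeasurement, PhenotypeTable

_NUCLEOTIDES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimSpec:
    """Generator parameters; defaults emulate a 24-strain, 7-chromosome panel."""

    n_strains: int = 24
    n_chromosomes: int = 7
    n_sites_per_chromosome: int = 50
    chromosome_length: int = 4_000_000
    maf_range: tuple[float, float] = (0.26, 0.5)
    ld_rho: float = 0.5
    causal_site: int | None = None
    penetrance: tuple[float, float] = (0.89, 0.24)  # (major-allele, minor-allele)
    n_replicates: int = 3
    pairs_per_replicate: int = 50
    strain_effect_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ParameterError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not (0 <= self.ld_rho < 1) and self.ld_rho != 1.0:
            raise ParameterError(f"ld_rho must be in [0, 1], got {self.ld_rho}")
        for p in self.penetrance:
            if not (0 <= p <= 1):
                raise ParameterError(f"penetrance values must be in [0, 1], got {p}")
        if not (0 <= self.missing_rate < 1):
            raise ParameterError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if self.pairs_per_replicate < 1 or self.n_replicates < 1:
            raise ParameterError("pairs_per_replicate and n_replicates must be >= 1")
        if self.n_strains < 2 or self.n_chromosomes < 1 or self.n_sites_per_chromosome < 0:
            raise ParameterError("need >= 2 strains and >= 1 chromosome")
        if self.chromosome_length < self.n_sites_per_chromosome:
            raise ParameterError("chromosome_length must be >= sites per chromosome")
        if self.strain_effect_sd < 0:
            raise ParameterError("strain_effect_sd must be >= 0")
        if self.seed < 0:
            raise ParameterError("seed must be non-negative")
        n_total = self.n_chromosomes * self.n_sites_per_chromosome
        if self.causal_site is not None and not (0 <= self.causal_site < n_total):
            raise ParameterError(
                f"causal_site {self.causal_site} out of range [0, {n_total})"
            )


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated dataset."""

    seed: int
    causal_site: int | None = None
    causal_chromosome: str | None = None
    causal_position: int | None = None
    causal_carriers: list[bool] | None = None
    realized_mafs: list[float] = field(default_factory=list)
    true_probs: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n", encoding="utf-8")


def chromosome_labels(n: int) -> list[str]:
    if n <= len(ROMAN_ORDER):
        return list(ROMAN_ORDER[:n])
    return [f"chr{i + 1}" for i in range(n)]


def strain_names(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


def _chrom_rng(seed: int, chrom_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 0, chrom_index]))


def _strain_rng(seed: int, strain_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 1, strain_index]))


def gen_genotypes(spec: SimSpec) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate the genotype matrix and record realized truth."""
    S = spec.n_strains
    m_per = spec.n_sites_per_chromosome
    truth = SimTruth(seed=spec.seed, causal_site=spec.causal_site)
    sites: list[SiteInfo] = []
    rows: list[np.ndarray] = []
    global_index = 0
    for c, label in enumerate(chromosome_labels(spec.n_chromosomes)):
        rng = _chrom_rng(spec.seed, c)
        if m_per == 0:
            continue
        positions = np.sort(rng.choice(spec.chromosome_length, size=m_per, replace=False)) + 1
        mafs = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=m_per)
        causal_local = None
        if spec.causal_site is not None and global_index <= spec.causal_site < global_index + m_per:
            causal_local = spec.causal_site - global_index

        design = np.zeros((m_per, S), dtype=bool)  # True = design allele 1
        for k in range(m_per):
            # the causal site's allele must realize as a bona fide minor allele
            # that survives the MAF filter, else its penetrance labels would
            # contradict the spec; rejection-sample until the carrier count
            # lands inside maf_range (strictly below 1/2)
            for attempt in range(1000):
                fresh = rng.random(S) < mafs[k]
                if k == 0:
                    col = fresh
                else:
                    copy = rng.random(S) < spec.ld_rho
                    col = np.where(copy, design[k - 1], fresh)
                if k != causal_local:
                    break
                frac = col.sum() / S
                if spec.maf_range[0] <= frac < 0.5:
                    break
            else:
                raise ParameterError("could not realize causal-site carriers in maf_range")
            design[k] = col
        missing = rng.random((m_per, S)) < spec.missing_rate
        letter_pairs = np.vstack([rng.permutation(4)[:2] for _ in range(m_per)])

        for k in range(m_per):
            if spec.causal_site is not None and global_index == spec.causal_site:
                missing[k] = False  # keep the causal site fully observed
                truth.causal_chromosome = label
                truth.causal_position = int(positions[k])
                truth.causal_carriers = [bool(v) for v in design[k]]
            l0, l1 = _NUCLEOTIDES[letter_pairs[k]]
            chars = np.where(design[k], l1, l0)
            observed = sorted(set(chars[~missing[k]]))
            code = {ch: i for i, ch in enumerate(observed)}
            row = np.array(
                [MISSING if missing[k][j] else code[chars[j]] for j in range(S)],
                dtype=np.int8,
            )
            n_obs = int(np.sum(row != MISSING))
            n1 = int(np.sum(design[k][~missing[k]]))
            truth.realized_mafs.append(
                min(n1, n_obs - n1) / n_obs if n_obs else math.nan
            )
            sites.append(SiteInfo(label, int(positions[k]), tuple(observed)))
            rows.append(row)
            global_index += 1
    calls = np.vstack(rows) if rows else np.empty((0, S), dtype=np.int8)
    gm = GenotypeMatrix(sites=sites, strains=strain_names(S), calls=calls)
    return gm.validate(), truth


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return math.log(p / (1 - p))


def _expit(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def gen_phenotypes(gm: GenotypeMatrix, truth: SimTruth, spec: SimSpec) -> PhenotypeTable:
    """Simulate replicate fusion counts; true probabilities are stored in truth."""
    pi_major, pi_minor = spec.penetrance
    carriers = truth.causal_carriers
    measurements: list[FusionMeasurement] = []
    for j, strain in enumerate(gm.strains):
        rng = _strain_rng(spec.seed, j)
        effect = float(rng.normal(0.0, spec.strain_effect_sd))
        base = pi_minor if (carriers is not None and carriers[j]) else pi_major
        p_true = _expit(_logit(base) + effect)
        truth.true_probs[strain] = p_true
        for r in range(1, spec.n_replicates + 1):
            fused = int(rng.binomial(spec.pairs_per_replicate, p_true))
            measurements.append(
                FusionMeasurement(strain, r, 1, fused, spec.pairs_per_replicate)
            )
    return PhenotypeTable(measurements)


def gen_dataset(spec: SimSpec) -> tuple[GenotypeMatrix, PhenotypeTable, SimTruth]:
    """Genotypes + phenotypes + truth from a single master seed."""
    gm, truth = gen_genotypes(spec)
    pt = gen_phenotypes(gm, truth, spec)
    return gm, pt, truth
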