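"""End-to-end orchestration: filter -> binarize -> scan -> permute -> LD.

``run_pipeline`` is deterministic given its config (including the
permutation seed) and writes a bundle of plain-text tables plus a
machine-readable manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ParameterError, ValidationError
from .genotype import (
    GenotypeMatrix,
    MafFilterSpec,
    filter_biallelic,
    filter_maf,
    parse_region,
    read_genotype_tsv,
    region_query,
)
from .phenotype import BinaryPhenotype, binarize, class_table, read_phenotype_csv
from .association import AssociationResult, results_frame, scan
from .permutation import (
    NullDistribution,
    PermutationPlan,
    build_null,
    summarize_thresholds,
    summary_frame,
    threshold_for_expected,
)
from .ld import long_format, r2_matrix

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genotype: str = ""
    phenotype: str = ""
    out_dir: str = "haplogwas_out"
    min_maf: float = 0.25
    missing_policy: str = "observed"
    lenient: bool = False
    sd_mode: str = "sample"
    sided: str = "two"
    n_permutations: int = 1000
    seed: int = 0
    perm_mode: str = "monte_carlo"
    thresholds: list[float] = field(default_factory=list)
    target_expected: list[float] = field(default_factory=lambda: [0.1])
    ld_regions: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunBundle:
    """In-memory results of one pipeline run."""

    config: RunConfig
    genotypes: GenotypeMatrix
    binary_phenotype: BinaryPhenotype
    results: list[AssociationResult]
    null: NullDistribution | None
    threshold_table: pd.DataFrame
    manhattan: pd.DataFrame
    ld_tables: dict[str, pd.DataFrame]
    manifest: dict
    dropped_strains: list[str]


def align_strains(gm: GenotypeMatrix, bp: BinaryPhenotype) -> tuple[BinaryPhenotype, list[str]]:
    """Intersect strain sets, logging what is dropped on either side."""
    common = [s for s in bp.strains if s in set(gm.strains)]
    if not common:
        raise ValidationError("no strains shared between genotype and phenotype inputs")
    dropped = sorted(set(bp.strains) - set(common)) + sorted(set(gm.strains) - set(common))
    for s in dropped:
        logger.warning("dropping strain %s: absent from one input [reason=unmatched]", s)
    bp2 = bp.with_classes({s: bp.classes[s] for s in common})
    return bp2, dropped


def manhattan_table(results: list[AssociationResult], threshold_p: float) -> pd.DataFrame:
    """One record per site with a strict significance flag (p < threshold)."""
    if not results:
        raise ValidationError("no association results")
    if not (0 < threshold_p <= 1):
        raise ParameterError(f"threshold must be in (0, 1], got {threshold_p}")
    return pd.DataFrame(
        {
            "chrom": [r.site.chromosome for r in results],
            "pos": [r.site.position for r in results],
            "neglog10_p": [r.neglog10_p for r in results],
            "significant": [r.p_value < threshold_p for r in results],
        }
    )


def run_pipeline(cfg: RunConfig, write: bool = True) -> RunBundle:
    gm = read_genotype_tsv(cfg.genotype, lenient=cfg.lenient)
    n_raw = gm.n_sites
    gm = filter_biallelic(gm)
    n_bi = gm.n_sites
    gm = filter_maf(gm, MafFilterSpec(cfg.min_maf, cfg.missing_policy))
    logger.info("sites: %d raw -> %d biallelic -> %d after MAF filter", n_raw, n_bi, gm.n_sites)
    if gm.n_sites == 0:
        raise ValidationError("no sites survive filtering")

    pt = read_phenotype_csv(cfg.phenotype)
    bp = binarize(pt, sd_mode=cfg.sd_mode)
    bp, dropped = align_strains(gm, bp)
    if bp.n_low == 0:
        logger.warning("degenerate binarization: no low-communicating strains")

    results = scan(gm, bp, sided=cfg.sided)
    real_p = np.array([r.p_value for r in results])

    null = None
    derived_thresholds: list[float] = []
    if cfg.n_permutations > 0:
        plan = PermutationPlan(cfg.n_permutations, cfg.seed, cfg.perm_mode)
        null = build_null(gm, bp, plan, sided=cfg.sided)
        for target in cfg.target_expected:
            derived_thresholds.append(
                threshold_for_expected(gm, bp, plan, target, sided=cfg.sided, null=null)
            )
        all_thresholds = sorted(set(cfg.thresholds) | set(derived_thresholds))
        summaries = summarize_thresholds(real_p, null, all_thresholds)
        threshold_table = summary_frame(summaries)
    else:
        threshold_table = pd.DataFrame()

    flag_threshold = derived_thresholds[0] if derived_thresholds else (
        min(cfg.thresholds) if cfg.thresholds else 1.0
    )
    manhattan = manhattan_table(results, flag_threshold)

    ld_tables: dict[str, pd.DataFrame] = {}
    for region in cfg.ld_regions:
        chrom, start, end = parse_region(region)
        sub = region_query(gm, chrom, start, end)
        ld_tables[region] = long_format(r2_matrix(sub))

    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "n_sites_raw": n_raw,
        "n_sites_biallelic": n_bi,
        "n_sites_tested": gm.n_sites,
        "n_strains_tested": len(bp.strains),
        "n_low": bp.n_low,
        "n_high": len(bp.strains) - bp.n_low,
        "grand_mean": bp.grand_mean,
        "grand_sd": bp.grand_sd,
        "dropped_strains": dropped,
        "derived_thresholds": derived_thresholds,
        "seed": cfg.seed,
    }

    bundle = RunBundle(
        config=cfg,
        genotypes=gm,
        binary_phenotype=bp,
        results=results,
        null=null,
        threshold_table=threshold_table,
        manhattan=manhattan,
        ld_tables=ld_tables,
        manifest=manifest,
        dropped_strains=dropped,
    )
    if write:
        write_bundle(bundle, pt)
    return bundle


def write_bundle(bundle: RunBundle, pt=None) -> None:
    out = Path(bundle.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results_frame(bundle.results).to_csv(out / "association.tsv", sep="\t", index=False)
    bundle.manhattan.to_csv(out / "manhattan.tsv", sep="\t", index=False)
    if not bundle.threshold_table.empty:
        bundle.threshold_table.to_csv(out / "thresholds.tsv", sep="\t", index=False)
    if pt is not None:
        class_table(pt, bundle.binary_phenotype).to_csv(out / "classes.tsv", sep="\t", index=False)
    for region, table in bundle.ld_tables.items():
        safe = region.replace(":", "_").replace("-", "_")
        table.to_csv(out / f"ld_{safe}.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2, default=float) + "\n", encoding="utf-8"
    )
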