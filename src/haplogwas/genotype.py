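"""Haploid SNP genotype matrices: parsing, validation, filtering, regions.

The on-disk dialect is a tab-separated table whose first header cell is the
literal ``site``, remaining header cells are strain names, each data row's
first field is ``CHROM:POS`` and allele cells hold single-nucleotide states
(``A``/``C``/``G``/``T``) or ``.`` for a missing call.

Internally each site's observed states are stored lexicographically sorted
and calls are integer indexes into that tuple (``-1`` = missing), so the
minor/major orientation is always recomputed from counts, never taken from
file order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import BiallelismError, ParameterError, ParseError, ValidationError

logger = logging.getLogger(__name__)

MISSING = -1
_VALID_STATES = frozenset("ACGT")

#: Ordering used when every chromosome label is a Roman numeral I..VII.
ROMAN_ORDER = ("I", "II", "III", "IV", "V", "VI", "VII")


def chromosome_sort_key(labels: Iterable[str]):
    """Return a key function ordering chromosome labels.

    Roman numerals I..VII sort numerically when every label belongs to that
    set; otherwise labels keep their order of first appearance.
    """
    labels = list(dict.fromkeys(labels))
    if labels and all(lab in ROMAN_ORDER for lab in labels):
        rank = {lab: i for i, lab in enumerate(ROMAN_ORDER)}
    else:
        rank = {lab: i for i, lab in enumerate(labels)}
    return lambda lab: rank[lab]


@dataclass(frozen=True)
class SiteInfo:
    """Metadata for one SNP site.

    Parameters
    ----------
    chromosome : str
        Chromosome (or supercontig) label.
    position : int
        1-based coordinate on that chromosome.
    alleles : tuple of str
        Observed single-nucleotide states, lexicographically sorted.
        Validated matrices destined for association carry exactly two.
    """

    chromosome: str
    position: int
    alleles: tuple[str, ...]

    def __post_init__(self):
        if self.position < 1:
            raise ValidationError(
                f"position must be >= 1, got {self.position} on {self.chromosome}"
            )
        if len(set(self.alleles)) != len(self.alleles):
            raise ValidationError(f"duplicate allele states at {self.key}")
        if tuple(sorted(self.alleles)) != tuple(self.alleles):
            raise ValidationError(f"allele states must be sorted at {self.key}")

    @property
    def key(self) -> str:
        return f"{self.chromosome}:{self.position}"


@dataclass
class GenotypeMatrix:
    """M sites x S strains of haploid calls.

    ``calls[i, j]`` indexes into ``sites[i].alleles`` or is :data:`MISSING`.
    """

    sites: list[SiteInfo]
    strains: list[str]
    calls: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.strains)):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sites)} sites x {len(self.strains)} strains"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def validate(self) -> "GenotypeMatrix":
        """Check structural invariants; return self for chaining."""
        if len(set(self.strains)) != len(self.strains):
            raise ValidationError("duplicate strain identifiers")
        seen: set[tuple[str, int]] = set()
        for i, s in enumerate(self.sites):
            if (s.chromosome, s.position) in seen:
                raise ValidationError(f"duplicate site {s.key}")
            seen.add((s.chromosome, s.position))
            row = self.calls[i]
            obs = row[row != MISSING]
            if obs.size and (obs.min() < 0 or obs.max() >= len(s.alleles)):
                raise ValidationError(f"call code out of range at {s.key}")
            observed_states = tuple(sorted({s.alleles[c] for c in obs}))
            if observed_states != s.alleles:
                raise ValidationError(
                    f"allele metadata at {s.key} does not match observed states"
                )
        key = chromosome_sort_key(s.chromosome for s in self.sites)
        order = [(key(s.chromosome), s.position) for s in self.sites]
        if order != sorted(order):
            raise ValidationError("sites not sorted by (chromosome, position)")
        return self

    def sort_sites(self) -> "GenotypeMatrix":
        """Return a copy stably sorted by (chromosome order, position)."""
        key = chromosome_sort_key(s.chromosome for s in self.sites)
        idx = sorted(range(self.n_sites), key=lambda i: (key(self.sites[i].chromosome), self.sites[i].position))
        return GenotypeMatrix(
            sites=[self.sites[i] for i in idx],
            strains=list(self.strains),
            calls=self.calls[idx] if self.n_sites else self.calls,
        )

    def take_sites(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            sites=[self.sites[i] for i in idx],
            strains=list(self.strains),
            calls=self.calls[idx] if idx else np.empty((0, self.n_strains), dtype=np.int8),
        )

    def strain_index(self) -> dict[str, int]:
        return {name: j for j, name in enumerate(self.strains)}


@dataclass(frozen=True)
class MafFilterSpec:
    """Minor-allele-frequency filter with strict ``>`` semantics.

    ``missing_policy`` chooses the denominator: ``"observed"`` counts only
    non-missing strains at each site, ``"total"`` counts all strains.
    """

    min_minor_fraction: float = 0.25
    missing_policy: str = "observed"

    def __post_init__(self):
        if not (0.0 < self.min_minor_fraction <= 0.5):
            raise ParameterError(
                f"min_minor_fraction must be in (0, 0.5], got {self.min_minor_fraction}"
            )
        if self.missing_policy not in ("observed", "total"):
            raise ParameterError(f"unknown missing_policy {self.missing_policy!r}")


def _rebuild_site(site: SiteInfo, row: np.ndarray) -> tuple[SiteInfo, np.ndarray]:
    """Re-derive the allele tuple of a site from its observed calls."""
    obs_codes = sorted({int(c) for c in row if c != MISSING})
    states = tuple(site.alleles[c] for c in obs_codes)
    remap = {old: new for new, old in enumerate(obs_codes)}
    new_row = np.array(
        [MISSING if c == MISSING else remap[int(c)] for c in row], dtype=np.int8
    )
    return SiteInfo(site.chromosome, site.position, states), new_row


def read_genotype_tsv(path, lenient: bool = False) -> GenotypeMatrix:
    """Read a genotype matrix in the TSV dialect described in the module docs.

    With ``lenient=True`` malformed allele cells become missing and sites
    with more than two observed states are admitted (so that
    :func:`filter_biallelic` can drop them); otherwise both are errors.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        cells = header.split("\t")
        if cells[0] != "site":
            raise ParseError(f"{path}: first header cell must be 'site', got {cells[0]!r}")
        strains = cells[1:]
        if len(set(strains)) != len(strains):
            raise ValidationError(f"{path}: duplicate strain names in header")
        n_strains = len(strains)

        sites: list[SiteInfo] = []
        rows: list[np.ndarray] = []
        seen: set[tuple[str, int]] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != n_strains + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_strains + 1} fields, got {len(fields)}"
                )
            key = fields[0]
            chrom, _, pos_str = key.rpartition(":")
            if not chrom:
                raise ParseError(f"{path}:{lineno}: site key {key!r} is not CHROM:POS")
            try:
                pos = int(pos_str)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad position in site key {key!r}")
            if (chrom, pos) in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate site {key}")
            seen.add((chrom, pos))

            states_here: list[str | None] = []
            for cell in fields[1:]:
                cell = cell.strip().upper()
                if cell == ".":
                    states_here.append(None)
                elif cell in _VALID_STATES:
                    states_here.append(cell)
                elif lenient:
                    states_here.append(None)
                else:
                    raise ParseError(
                        f"{path}:{lineno}: malformed allele cell {cell!r} at {key}"
                    )
            distinct = tuple(sorted({s for s in states_here if s is not None}))
            if len(distinct) > 2 and not lenient:
                raise BiallelismError(
                    f"{path}:{lineno}: site {key} has {len(distinct)} allele states {distinct}"
                )
            code = {s: i for i, s in enumerate(distinct)}
            row = np.array(
                [MISSING if s is None else code[s] for s in states_here], dtype=np.int8
            )
            if pos < 1:
                raise ValidationError(f"{path}:{lineno}: position must be >= 1")
            sites.append(SiteInfo(chrom, pos, distinct))
            rows.append(row)

    calls = np.vstack(rows) if rows else np.empty((0, n_strains), dtype=np.int8)
    return GenotypeMatrix(sites=sites, strains=strains, calls=calls).sort_sites()


def write_genotype_tsv(gm: GenotypeMatrix, path) -> None:
    """Write ``gm`` so that :func:`read_genotype_tsv` reproduces it exactly."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(["site", *gm.strains]) + "\n")
        for i, site in enumerate(gm.sites):
            cells = [
                "." if c == MISSING else site.alleles[c] for c in gm.calls[i]
            ]
            fh.write("\t".join([site.key, *cells]) + "\n")


def read_genotype_vcf(path) -> GenotypeMatrix:
    """Read haploid single-allele GT calls from a VCF.

    Biallelic SNP records become sites; multi-allelic or non-SNP records are
    skipped with a logged count. A diploid GT anywhere is an error — this
    pipeline is haploid-only.
    """
    import pysam

    skipped = 0
    sites: list[SiteInfo] = []
    rows: list[np.ndarray] = []
    with pysam.VariantFile(str(path)) as vcf:
        strains = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
                skipped += 1
                continue
            by_char = {0: rec.ref.upper(), 1: alts[0].upper()}
            chars: list[str | None] = []
            for name in strains:
                gt = rec.samples[name].get("GT", (None,))
                gt = tuple(a for a in gt if a is not None) or (None,)
                if len(gt) > 1:
                    raise ValidationError(
                        f"diploid GT for sample {name} at {rec.chrom}:{rec.pos}; "
                        "this pipeline is haploid-only"
                    )
                chars.append(None if gt[0] is None else by_char[gt[0]])
            distinct = tuple(sorted({c for c in chars if c is not None}))
            if not distinct:
                skipped += 1
                continue
            code = {s: i for i, s in enumerate(distinct)}
            rows.append(
                np.array([MISSING if c is None else code[c] for c in chars], dtype=np.int8)
            )
            sites.append(SiteInfo(rec.chrom, rec.pos, distinct))
    if skipped:
        logger.info("read_genotype_vcf: skipped %d non-biallelic-SNP records", skipped)
    calls = np.vstack(rows) if rows else np.empty((0, len(strains)), dtype=np.int8)
    gm = GenotypeMatrix(sites=sites, strains=strains, calls=calls).sort_sites()
    gm.skipped_records = skipped  # type: ignore[attr-defined]
    return gm


def filter_biallelic(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep only sites with exactly two observed non-missing allele states."""
    sites: list[SiteInfo] = []
    rows: list[np.ndarray] = []
    for i, site in enumerate(gm.sites):
        row = gm.calls[i]
        obs = {int(c) for c in row if c != MISSING}
        if len(obs) != 2:
            continue
        new_site, new_row = _rebuild_site(site, row)
        sites.append(new_site)
        rows.append(new_row)
    calls = np.vstack(rows) if rows else np.empty((0, gm.n_strains), dtype=np.int8)
    return GenotypeMatrix(sites=sites, strains=list(gm.strains), calls=calls)


def minor_allele_count(row: np.ndarray) -> tuple[int, int, int]:
    """Return (minor_code, minor_count, n_observed) for a biallelic row.

    Ties in allele counts break toward code 0 as the minor allele.
    """
    n0 = int(np.sum(row == 0))
    n1 = int(np.sum(row == 1))
    if n1 < n0:
        return 1, n1, n0 + n1
    return 0, n0, n0 + n1


def filter_maf(gm: GenotypeMatrix, spec: MafFilterSpec | None = None) -> GenotypeMatrix:
    """Keep sites whose minor-allele fraction strictly exceeds the threshold.

    The denominator follows ``spec.missing_policy``; site order is preserved.
    """
    spec = spec or MafFilterSpec()
    keep: list[int] = []
    for i, site in enumerate(gm.sites):
        if len(site.alleles) != 2:
            raise ValidationError(f"filter_maf requires biallelic input; site {site.key}")
        _, minor, n_obs = minor_allele_count(gm.calls[i])
        denom = n_obs if spec.missing_policy == "observed" else gm.n_strains
        if denom > 0 and minor / denom > spec.min_minor_fraction:
            keep.append(i)
    return gm.take_sites(keep)


def region_query(gm: GenotypeMatrix, chromosome: str, start: int, end: int) -> GenotypeMatrix:
    """Sub-matrix of sites on ``chromosome`` with start <= pos <= end (1-based, closed)."""
    if start > end:
        raise ParameterError(f"region start {start} > end {end}")
    known = {s.chromosome for s in gm.sites}
    if chromosome not in known:
        raise ValidationError(
            f"unknown chromosome {chromosome!r}; known: {sorted(known)}"
        )
    keep = [
        i
        for i, s in enumerate(gm.sites)
        if s.chromosome == chromosome and start <= s.position <= end
    ]
    return gm.take_sites(keep)


def parse_region(text: str) -> tuple[str, int, int]:
    """Parse ``CHROM:START-END`` into its parts."""
    chrom, _, span = text.rpartition(":")
    if not chrom or "-" not in span:
        raise ParameterError(f"region must be CHROM:START-END, got {text!r}")
    lo, _, hi = span.partition("-")
    try:
        return chrom, int(lo), int(hi)
    except ValueError:
        raise ParameterError(f"region bounds must be integers, got {text!r}")
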