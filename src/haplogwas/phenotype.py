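"""Replicate fusion-assay aggregation and standard-deviation binarization.

Each measurement is a (fused, total) pair of germling-pair counts for one
strain at one replicate/timepoint. A strain's quantitative score is the
unweighted mean of its per-measurement frequencies; strains more than one
standard deviation below the grand mean of those scores are classed low.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError

logger = logging.getLogger(__name__)

LOW = "low"
HIGH = "high"

PHENOTYPE_COLUMNS = ["strain", "replicate", "timepoint", "fused", "total"]


@dataclass(frozen=True)
class FusionMeasurement:
    strain: str
    replicate: int
    timepoint: int
    fused: int
    total: int

    def __post_init__(self):
        if self.total < 1:
            raise ValidationError(f"{self.strain}: total must be >= 1, got {self.total}")
        if not (0 <= self.fused <= self.total):
            raise ValidationError(
                f"{self.strain}: fused must be in [0, total], got {self.fused}/{self.total}"
            )
        if self.replicate < 1 or self.timepoint < 1:
            raise ValidationError(f"{self.strain}: replicate/timepoint must be >= 1")

    @property
    def frequency(self) -> float:
        return self.fused / self.total


@dataclass
class PhenotypeTable:
    """Collection of fusion measurements with per-strain mean frequencies."""

    measurements: list[FusionMeasurement]

    def __post_init__(self):
        if not self.measurements:
            raise ValidationError("phenotype table has no measurements")

    @property
    def strains(self) -> list[str]:
        return list(dict.fromkeys(m.strain for m in self.measurements))

    def mean_frequency(self, strain: str) -> float:
        """Unweighted mean of fused/total over the strain's measurements."""
        freqs = [m.frequency for m in self.measurements if m.strain == strain]
        if not freqs:
            raise ValidationError(f"unknown strain {strain!r}")
        return float(np.mean(freqs))

    def pooled_frequency(self, strain: str) -> float:
        """Alternative aggregation: pool raw counts before dividing."""
        rows = [m for m in self.measurements if m.strain == strain]
        if not rows:
            raise ValidationError(f"unknown strain {strain!r}")
        return sum(m.fused for m in rows) / sum(m.total for m in rows)

    def strain_means(self, pooled: bool = False) -> dict[str, float]:
        agg = self.pooled_frequency if pooled else self.mean_frequency
        return {s: agg(s) for s in self.strains}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.strain, m.replicate, m.timepoint, m.fused, m.total) for m in self.measurements],
            columns=PHENOTYPE_COLUMNS,
        )


@dataclass
class BinaryPhenotype:
    """Per-strain {high, low} classes plus the statistics that produced them."""

    classes: dict[str, str]
    grand_mean: float
    grand_sd: float
    sd_mode: str

    def __post_init__(self):
        if self.grand_sd < 0:
            raise ValidationError("grand_sd must be >= 0")
        bad = {v for v in self.classes.values()} - {LOW, HIGH}
        if bad:
            raise ValidationError(f"unknown class labels {bad}")

    @property
    def strains(self) -> list[str]:
        return list(self.classes)

    @property
    def n_low(self) -> int:
        return sum(1 for v in self.classes.values() if v == LOW)

    def low_vector(self, strains=None) -> np.ndarray:
        """Boolean array, True where the strain is low-communicating."""
        strains = self.strains if strains is None else strains
        return np.array([self.classes[s] == LOW for s in strains], dtype=bool)

    def with_classes(self, classes: dict[str, str]) -> "BinaryPhenotype":
        return BinaryPhenotype(dict(classes), self.grand_mean, self.grand_sd, self.sd_mode)


def read_phenotype_csv(path) -> PhenotypeTable:
    """Read a replicate-level phenotype CSV with the documented columns."""
    df = pd.read_csv(Path(path))
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    measurements = []
    for idx, row in df.iterrows():
        try:
            measurements.append(
                FusionMeasurement(
                    strain=str(row["strain"]),
                    replicate=int(row["replicate"]),
                    timepoint=int(row["timepoint"]),
                    fused=int(row["fused"]),
                    total=int(row["total"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {idx + 2}: {exc}") from exc
    return PhenotypeTable(measurements)


def write_phenotype_csv(pt: PhenotypeTable, path) -> None:
    pt.to_frame().to_csv(Path(path), index=False, lineterminator="\n")


def mean_frequency(pt: PhenotypeTable, strain: str) -> float:
    return pt.mean_frequency(strain)


def binarize(pt: PhenotypeTable, sd_mode: str = "sample", pooled: bool = False) -> BinaryPhenotype:
    """Classify strains: low iff mean frequency < grand_mean - grand_sd (strict).

    ``sd_mode`` selects the sample (n-1) or population (n) standard deviation
    of the per-strain means. Requires at least two strains.
    """
    if sd_mode not in ("sample", "population"):
        raise ParameterError(f"sd_mode must be 'sample' or 'population', got {sd_mode!r}")
    means = pt.strain_means(pooled=pooled)
    if len(means) < 2:
        raise ValidationError("binarize requires >= 2 strains")
    values = np.array(list(means.values()), dtype=float)
    grand_mean = float(values.mean())
    ddof = 1 if sd_mode == "sample" else 0
    # identical values must give exactly 0, not float dust, so that the
    # degenerate "all high" rule is exact
    grand_sd = 0.0 if np.ptp(values) == 0 else float(values.std(ddof=ddof))
    cut = grand_mean - grand_sd
    # strict "more than one SD below", robust to float dust at the boundary
    def is_low(v: float) -> bool:
        return v < cut and not math.isclose(v, cut, rel_tol=1e-9, abs_tol=1e-12)

    classes = {s: (LOW if is_low(v) else HIGH) for s, v in means.items()}
    return BinaryPhenotype(classes, grand_mean, grand_sd, sd_mode)


def class_table(pt: PhenotypeTable, bp: BinaryPhenotype, pooled: bool = False) -> pd.DataFrame:
    """Per-strain summary: strain, mean_frequency, class."""
    means = pt.strain_means(pooled=pooled)
    return pd.DataFrame(
        {
            "strain": list(means),
            "mean_frequency": [means[s] for s in means],
            "class": [bp.classes[s] for s in means],
        }
    )


def binned_summary(pt: PhenotypeTable, width: float = 0.05, pooled: bool = False) -> pd.DataFrame:
    """Histogram-ready counts of strain mean frequencies in fixed-width bins.

    Default width is five percentage points; the top edge is inclusive so a
    frequency of exactly 1.0 lands in the last bin.
    """
    if not (0 < width <= 1):
        raise ParameterError("bin width must be in (0, 1]")
    values = np.array(list(pt.strain_means(pooled=pooled).values()))
    n_bins = math.ceil(1.0 / width - 1e-9)
    edges = np.minimum(np.arange(n_bins + 1) * width, 1.0)
    idx = np.minimum((values / width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "n_strains": counts}
    )
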