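"""Digital-PCR quantification via Poisson partition statistics.

A chip distributes template molecules across ~20,000 partitions; with mean
occupancy lambda per partition, the fraction of positive partitions is
``p = 1 - exp(-lambda)``, so ``lambda = -ln(1 - p)`` and absolute copy
number follows without a standard curve. Copies are reported per chip and
per nanogram of loaded DNA. Deletion heteroplasmy is obtained from a pair
of assays: a "full-length" assay whose target lies inside the deletion
(detecting only non-deleted molecules) and a "total" assay outside it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
from scipy.stats import binomtest

from .errors import (
    InvalidParameterError,
    SaturationError,
    UndefinedFractionError,
    UndefinedHeteroplasmyError,
)


@dataclass(frozen=True)
class PartitionCounts:
    """Readout of one dPCR chip (one dye channel)."""

    assay_name: str
    n_valid: int
    n_positive: int
    ng_loaded: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_valid < 1:
            raise InvalidParameterError("n_valid must be >= 1")
        if not 0 <= self.n_positive <= self.n_valid:
            raise InvalidParameterError(
                f"n_positive must lie in [0, n_valid], got "
                f"{self.n_positive}/{self.n_valid}"
            )


@dataclass(frozen=True)
class AssayDef:
    """A dPCR assay target and what it detects.

    ``detects`` is ``full_length_only`` exactly when the target position
    lies inside the declared deletion interval (a deleted molecule lacks
    the target), and ``all_molecules`` otherwise.
    """

    name: str
    target_position: int
    detects: str  # "all_molecules" | "full_length_only"

    @classmethod
    def from_deletion(
        cls, name: str, target_position: int, deletion_start: int, deletion_end: int
    ) -> "AssayDef":
        inside = deletion_start <= target_position <= deletion_end
        return cls(
            name=name,
            target_position=target_position,
            detects="full_length_only" if inside else "all_molecules",
        )


@dataclass(frozen=True)
class CopyNumberResult:
    """Absolute copy number derived from one chip."""

    assay_name: str
    lam: float
    copies_per_chip: float
    copies_per_ng: float
    ci95_per_ng: tuple[float, float]

    @property
    def ci95(self) -> tuple[float, float]:
        return self.ci95_per_ng


@dataclass(frozen=True)
class HeteroplasmyResult:
    """Deletion heteroplasmy from paired full-length/total assays."""

    percent: float
    full_length_assay: str
    total_assay: str
    clamped: bool


def poisson_lambda(n_positive: int, n_valid: int) -> float:
    """Mean copies per partition from positive-partition counts.

    ``lambda = -ln(1 - n_positive / n_valid)``. A fully positive chip is a
    saturation error: occupancy cannot be inferred.
    """
    if n_valid < 1 or n_positive < 0 or n_positive > n_valid:
        raise InvalidParameterError(
            f"invalid partition counts {n_positive}/{n_valid}"
        )
    if n_positive == n_valid:
        raise SaturationError(
            "all partitions positive: occupancy is unbounded; dilute and rerun"
        )
    return -math.log1p(-n_positive / n_valid)


def copies_per_ng(counts: PartitionCounts) -> CopyNumberResult:
    """Copies per chip and per ng DNA, with a 95% confidence interval.

    The interval is a Wilson score interval on the positive-partition
    proportion, transformed through the Poisson occupancy relation and the
    ng normalisation (a choice of convenience: the instrument vendor's
    interval construction is not public).
    """
    lam = poisson_lambda(counts.n_positive, counts.n_valid)
    chip = lam * counts.n_valid
    if not counts.ng_loaded > 0:
        raise InvalidParameterError("ng_loaded must be > 0 for per-ng copies")
    per_ng = chip / counts.ng_loaded
    ci = binomtest(counts.n_positive, counts.n_valid).proportion_ci(
        confidence_level=0.95, method="wilson"
    )
    lo = -math.log1p(-ci.low) * counts.n_valid / counts.ng_loaded
    hi = -math.log1p(-min(ci.high, 1.0 - 1e-12)) * counts.n_valid / counts.ng_loaded
    return CopyNumberResult(
        assay_name=counts.assay_name,
        lam=lam,
        copies_per_chip=chip,
        copies_per_ng=per_ng,
        ci95_per_ng=(lo, hi),
    )


def deletion_heteroplasmy(
    full_length: CopyNumberResult, total: CopyNumberResult
) -> HeteroplasmyResult:
    """Deletion heteroplasmy percent from full-length and total assays.

    ``percent = 100 x (1 - FL / total)`` on ng-normalised copies. Sampling
    noise can push FL above total at low heteroplasmy; the estimate is then
    clamped to 0 with ``clamped=True`` and a warning rather than an error.
    """
    if total.copies_per_ng <= 0:
        raise UndefinedHeteroplasmyError(
            "total copy number is zero; heteroplasmy undefined"
        )
    raw = 100.0 * (1.0 - full_length.copies_per_ng / total.copies_per_ng)
    clamped = False
    if raw < 0.0:
        warnings.warn(
            "full-length copies exceed total copies; clamping heteroplasmy to 0",
            stacklevel=2,
        )
        raw, clamped = 0.0, True
    elif raw > 100.0:
        raw, clamped = 100.0, True
    return HeteroplasmyResult(
        percent=raw,
        full_length_assay=full_length.assay_name,
        total_assay=total.assay_name,
        clamped=clamped,
    )


def dual_probe_fraction(
    counts_allele_a: PartitionCounts, counts_allele_b: PartitionCounts
) -> float:
    """Fraction of allele B in a two-probe (e.g. FAM/VIC) SNP assay.

    Each dye channel is quantified independently through Poisson occupancy;
    double-positive partitions count in both channels (independent-target
    approximation). Returns ``copies_b / (copies_a + copies_b)``.
    """
    lam_a = poisson_lambda(counts_allele_a.n_positive, counts_allele_a.n_valid)
    lam_b = poisson_lambda(counts_allele_b.n_positive, counts_allele_b.n_valid)
    copies_a = lam_a * counts_allele_a.n_valid
    copies_b = lam_b * counts_allele_b.n_valid
    if copies_a + copies_b == 0:
        raise UndefinedFractionError("both channels empty; fraction undefined")
    return copies_b / (copies_a + copies_b)


def read_counts_tsv(path: str | Path) -> list[PartitionCounts]:
    """Read chip readouts from a TSV with columns assay, n_valid, n_positive[, ng_loaded]."""
    df = pd.read_csv(path, sep="\t")
    required = {"assay", "n_valid", "n_positive"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidParameterError(f"counts TSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        ng = float(getattr(row, "ng_loaded", float("nan")))
        out.append(
            PartitionCounts(
                assay_name=str(row.assay),
                n_valid=int(row.n_valid),
                n_positive=int(row.n_positive),
                ng_loaded=ng,
            )
        )
    return out


def write_counts_tsv(counts: list[PartitionCounts], path: str | Path) -> None:
    pd.DataFrame(
        {
            "assay": [c.assay_name for c in counts],
            "n_valid": [c.n_valid for c in counts],
            "n_positive": [c.n_positive for c in counts],
            "ng_loaded": [c.ng_loaded for c in counts],
        }
    ).to_csv(path, sep="\t", index=False)


def quantify_chip(
    counts: PartitionCounts, ng_loaded: Optional[float] = None
) -> CopyNumberResult:
    """Convenience wrapper allowing ng_loaded override at call time."""
    if ng_loaded is not None:
        counts = PartitionCounts(
            assay_name=counts.assay_name,
            n_valid=counts.n_valid,
            n_positive=counts.n_positive,
            ng_loaded=ng_loaded,
        )
    return copies_per_ng(counts)
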