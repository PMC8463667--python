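"""Digital-PCR chip simulation with known true concentrations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..dpcr import PartitionCounts
from ..errors import InvalidParameterError


@dataclass
class ChipSimConfig:
    """True loading conditions of one simulated 20K-partition chip."""

    true_copies_per_ng: float
    ng_loaded: float
    n_partitions: int = 20_000
    valid_fraction: float = 1.0
    seed: int = 0
    assay_name: str = "assay"

    def __post_init__(self) -> None:
        if self.true_copies_per_ng < 0 or self.ng_loaded < 0:
            raise InvalidParameterError("concentration and load must be >= 0")
        if self.n_partitions < 1:
            raise InvalidParameterError("n_partitions must be >= 1")
        if not 0.0 < self.valid_fraction <= 1.0:
            raise InvalidParameterError("valid_fraction must lie in (0, 1]")


def simulate_dpcr(cfg: ChipSimConfig) -> PartitionCounts:
    """Simulate one chip: Poisson molecule count, uniform partitioning.

    The total number of template molecules is drawn
    ``M ~ Poisson(true_copies_per_ng x ng_loaded)``; each molecule lands in
    a uniformly random valid partition and a partition is positive when it
    holds at least one molecule. Partition volume is not modelled: copy
    numbers are expressed per chip and per ng only.
    """
    rng = np.random.default_rng(cfg.seed)
    n_valid = max(1, int(round(cfg.n_partitions * cfg.valid_fraction)))
    mean_molecules = cfg.true_copies_per_ng * cfg.ng_loaded
    m = int(rng.poisson(mean_molecules))
    if m == 0:
        n_positive = 0
    else:
        assignments = rng.integers(0, n_valid, size=m)
        n_positive = int(np.unique(assignments).size)
    return PartitionCounts(
        assay_name=cfg.assay_name,
        n_valid=n_valid,
        n_positive=n_positive,
        ng_loaded=cfg.ng_loaded,
    )


def simulate_dpcr_heteroplasmy(
    total_copies_per_ng: float,
    deletion_heteroplasmy: float,
    cfg: ChipSimConfig,
) -> tuple[PartitionCounts, PartitionCounts]:
    """Simulate the paired chips of a deletion-heteroplasmy measurement.

    The "total" assay detects every mtDNA molecule and is simulated at
    ``total_copies_per_ng``; the "full-length" assay detects only
    non-deleted molecules, i.e. a concentration reduced by the factor
    ``1 - deletion_heteroplasmy``. The two chips are loaded with the same
    template but read independently.

    Returns ``(full_length_counts, total_counts)``.
    """
    if not 0.0 <= deletion_heteroplasmy <= 1.0:
        raise InvalidParameterError("deletion heteroplasmy must lie in [0, 1]")
    if total_copies_per_ng < 0:
        raise InvalidParameterError("total_copies_per_ng must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    base = dict(
        n_partitions=cfg.n_partitions,
        valid_fraction=cfg.valid_fraction,
        ng_loaded=cfg.ng_loaded,
    )
    fl_cfg = ChipSimConfig(
        true_copies_per_ng=total_copies_per_ng * (1.0 - deletion_heteroplasmy),
        seed=int(rng.integers(0, 2**31 - 1)),
        assay_name="full_length",
        **base,
    )
    tot_cfg = ChipSimConfig(
        true_copies_per_ng=total_copies_per_ng,
        seed=int(rng.integers(0, 2**31 - 1)),
        assay_name="total",
        **base,
    )
    return simulate_dpcr(fl_cfg), simulate_dpcr(tot_cfg)
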