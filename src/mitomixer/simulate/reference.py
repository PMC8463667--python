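"""Synthetic reference genomes and donor/recipient haplotype pairs."""

from __future__ import annotations

from typing import Optional

import numpy as np

from ..errors import InvalidParameterError
from ..genomes import (
    BASES,
    RCRS_LENGTH,
    CircularGenome,
    DeletionSpec,
    HaplotypePair,
    decode,
)

_MIN_LENGTH = 100


def make_reference(
    length: int = RCRS_LENGTH, seed: int = 0, name: str = "mt_ref"
) -> CircularGenome:
    """Generate a uniformly random circular reference genome.

    Parameters
    ----------
    length
        Genome size in bp; defaults to the 16,569 bp of human mtDNA.
    seed
        Seed for the base draw; the sequence is deterministic per seed.
    """
    if length < _MIN_LENGTH:
        raise InvalidParameterError(
            f"reference length must be >= {_MIN_LENGTH} bp, got {length}"
        )
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    return CircularGenome(name=name, sequence=decode(codes))


def derive_haplotypes(
    ref: CircularGenome,
    n_snps: int,
    deletion: Optional[DeletionSpec] = None,
    seed: int = 0,
) -> HaplotypePair:
    """Derive a donor/recipient haplotype pair from a reference.

    The recipient keeps the reference sequence; the donor receives ``n_snps``
    substitutions at positions sampled without replacement. When the
    recipient carries a large deletion, no substitution is placed inside the
    deleted interval: at such sites the two haplotypes are represented by
    unequal template numbers, which would distort the allele-frequency
    mixture estimator that assumes equal representation per molecule.

    Returns a :class:`HaplotypePair` whose ``truth_snps`` are exactly the
    positions at which donor and recipient differ.
    """
    if n_snps < 1:
        raise InvalidParameterError(f"n_snps must be >= 1, got {n_snps}")
    if deletion is not None:
        deletion.validate_against(ref)

    candidates = [
        pos
        for pos in range(1, ref.length + 1)
        if deletion is None or not deletion.contains(pos)
    ]
    if n_snps > len(candidates):
        raise InvalidParameterError(
            f"n_snps={n_snps} exceeds the {len(candidates)} positions "
            "available outside the deletion"
        )

    rng = np.random.default_rng(seed)
    positions = sorted(
        int(p) for p in rng.choice(len(candidates), size=n_snps, replace=False)
    )
    positions = [candidates[i] for i in positions]

    donor_seq = list(ref.sequence)
    truth = []
    for pos in positions:
        ref_base = ref.sequence[pos - 1]
        alternatives = [b for b in BASES if b != ref_base]
        donor_base = alternatives[int(rng.integers(0, 3))]
        donor_seq[pos - 1] = donor_base
        truth.append((pos, donor_base, ref_base))

    donor = CircularGenome(name=f"{ref.name}_donor", sequence="".join(donor_seq))
    recipient = CircularGenome(name=f"{ref.name}_recipient", sequence=ref.sequence)
    return HaplotypePair(
        donor=donor,
        recipient=recipient,
        truth_snps=tuple(truth),
        recipient_deletion=deletion,
    )
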