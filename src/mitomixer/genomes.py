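"""Circular genome containers and coordinate helpers.

Human mtDNA is a circular molecule of 16,569 bp (rCRS numbering); all
coordinates in this package are 1-based inclusive and wrap modulo the genome
length, matching the convention of mitochondrial variant nomenclature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InvalidParameterError

#: rCRS length; the default size of the synthetic reference.
RCRS_LENGTH = 16569

BASES = "ACGT"
_BASE_SET = frozenset(BASES)
# uint8 codes 0..3 <-> A,C,G,T; used by the vectorised read simulator.
CODE_TO_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)
_ASCII_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ASCII_TO_CODE[_b] = _i
#: complement of each code (A<->T, C<->G)
COMPLEMENT_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)

_COMPLEMENT_TABLE = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as a uint8 code array (A=0,C=1,G=2,T=3)."""
    codes = _ASCII_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.max(initial=0) > 3:
        raise InvalidParameterError("sequence contains non-ACGT characters")
    return codes


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return CODE_TO_ASCII[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class CircularGenome:
    """A named circular nucleotide sequence.

    Coordinates on the genome are 1-based inclusive and wrap modulo
    ``length``; position ``length + 1`` is position 1.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise InvalidParameterError("genome sequence must be non-empty")
        if not _BASE_SET.issuperset(self.sequence):
            raise InvalidParameterError(
                f"genome {self.name!r} contains characters outside A/C/G/T"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base_at(self, position: int) -> str:
        """Base at a 1-based, circularly wrapped position."""
        return self.sequence[(position - 1) % self.length]

    def codes(self) -> np.ndarray:
        """uint8 code array of the sequence."""
        return encode(self.sequence)


@dataclass(frozen=True)
class DeletionSpec:
    """A large single deletion on the recipient haplotype.

    ``start``/``end`` are 1-based inclusive; ``heteroplasmy`` is the fraction
    of recipient mtDNA molecules that carry the deletion. The default used
    throughout the examples is the Pearson-syndrome deletion spanning
    nt 8470-13,447.
    """

    start: int
    end: int
    heteroplasmy: float

    def __post_init__(self) -> None:
        if not 1 <= self.start < self.end:
            raise InvalidParameterError(
                f"deletion requires 1 <= start < end, got {self.start}..{self.end}"
            )
        if not 0.0 <= self.heteroplasmy <= 1.0:
            raise InvalidParameterError(
                f"heteroplasmy must lie in [0, 1], got {self.heteroplasmy}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def validate_against(self, genome: CircularGenome) -> None:
        if self.end > genome.length:
            raise InvalidParameterError(
                f"deletion end {self.end} exceeds genome length {genome.length}"
            )


@dataclass(frozen=True)
class HaplotypePair:
    """Donor and recipient haplotypes plus the ground truth linking them.

    ``truth_snps`` lists ``(position, donor_allele, recipient_allele)`` for
    exactly the positions where the two sequences differ. The donor never
    carries a deletion; an optional large deletion segregates on the
    recipient at ``recipient_deletion.heteroplasmy``.
    """

    donor: CircularGenome
    recipient: CircularGenome
    truth_snps: tuple = field(default_factory=tuple)
    recipient_deletion: Optional[DeletionSpec] = None

    def __post_init__(self) -> None:
        if self.donor.length != self.recipient.length:
            raise InvalidParameterError(
                "donor and recipient haplotypes must have equal length"
            )
        if self.recipient_deletion is not None:
            self.recipient_deletion.validate_against(self.recipient)
        for pos, d, r in self.truth_snps:
            if self.donor.base_at(pos) != d or self.recipient.base_at(pos) != r:
                raise InvalidParameterError(
                    f"truth SNP at {pos} inconsistent with haplotype sequences"
                )

    @property
    def length(self) -> int:
        return self.donor.length

    def snp_positions(self) -> list[int]:
        return [pos for pos, _, _ in self.truth_snps]
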