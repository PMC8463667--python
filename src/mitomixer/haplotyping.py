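"""Informative-SNP identification between donor and recipient haplotypes.

An informative SNP is a position at which the exogenous (donor) and
endogenous (recipient) mtDNA consensus sequences carry different bases;
the donor-allele frequency at such sites in a mixed sample measures the
mixture. Sites are flagged (and by default excluded downstream) when they
fall inside a declared recipient deletion, inside a caller-supplied
excluded region, or within a homopolymer run, where per-site evidence is
unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import AlignmentRequiredError, ContentError, FormatError
from .genomes import CircularGenome, DeletionSpec

#: homopolymer runs at least this long flag the sites they contain
HOMOPOLYMER_MIN_RUN = 5

#: rCRS hypervariable-region preset (HVS-I, HVS-II, HVS-III), off by default
RCRS_HYPERVARIABLE_REGIONS = ((16024, 16365), (57, 372), (438, 574))

FLAG_IN_DELETION = "in_deletion"
FLAG_HOMOPOLYMER = "homopolymer"
FLAG_EXCLUDED_REGION = "excluded_region"


@dataclass(frozen=True)
class InformativeSNP:
    """A donor/recipient-differentiating site with its filter flags."""

    position: int
    donor_allele: str
    recipient_allele: str
    filter_flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.donor_allele == self.recipient_allele:
            raise ValueError("informative SNP alleles must differ")

    @property
    def passes_filters(self) -> bool:
        return not self.filter_flags


def _in_homopolymer(seq: str, idx: int, min_run: int) -> bool:
    """Whether 0-based ``idx`` sits inside a homopolymer run >= min_run.

    Runs are scanned with circular wrap-around, consistent with the
    circular genome model.
    """
    n = len(seq)
    base = seq[idx]
    run = 1
    j = idx
    for _ in range(n - 1):
        j = (j - 1) % n
        if seq[j] != base:
            break
        run += 1
    j = idx
    for _ in range(n - 1):
        j = (j + 1) % n
        if seq[j] != base:
            break
        run += 1
    return run >= min_run


def find_informative_snps(
    donor: CircularGenome,
    recipient: CircularGenome,
    deletion: Optional[DeletionSpec] = None,
    exclude_regions: Sequence[tuple[int, int]] = (),
    homopolymer_min_run: int = HOMOPOLYMER_MIN_RUN,
) -> list[InformativeSNP]:
    """All single-base differences between two equal-length haplotypes.

    Every differing position is returned; positions inside ``deletion``,
    inside any ``exclude_regions`` interval, or within a homopolymer run of
    length >= ``homopolymer_min_run`` in either haplotype carry the
    corresponding flag and are skipped by the downstream estimator unless
    explicitly retained.
    """
    if donor.length != recipient.length:
        raise AlignmentRequiredError(
            "haplotypes have unequal length; substitution-only comparison "
            "requires pre-aligned equal-length sequences"
        )
    snps = []
    ds, rs = donor.sequence, recipient.sequence
    for idx in range(donor.length):
        if ds[idx] == rs[idx]:
            continue
        pos = idx + 1
        flags = set()
        if deletion is not None and deletion.contains(pos):
            flags.add(FLAG_IN_DELETION)
        if any(a <= pos <= b for a, b in exclude_regions):
            flags.add(FLAG_EXCLUDED_REGION)
        if _in_homopolymer(ds, idx, homopolymer_min_run) or _in_homopolymer(
            rs, idx, homopolymer_min_run
        ):
            flags.add(FLAG_HOMOPOLYMER)
        snps.append(
            InformativeSNP(
                position=pos,
                donor_allele=ds[idx],
                recipient_allele=rs[idx],
                filter_flags=frozenset(flags),
            )
        )
    return snps


def load_haplotype(fasta_path: str | Path, name: Optional[str] = None) -> CircularGenome:
    """Load a single-record FASTA as a circular genome.

    The sequence is uppercased; N or other ambiguity codes are rejected
    because a consensus haplotype with uncalled bases cannot anchor
    informative-SNP identification.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) == 0:
        raise FormatError(f"{fasta_path}: no FASTA records found")
    if len(records) > 1:
        raise FormatError(
            f"{fasta_path}: expected a single record, found {len(records)}"
        )
    rec = records[0]
    seq = str(rec.seq).upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ContentError(
            f"{fasta_path}: disallowed characters {sorted(bad)} in sequence"
        )
    return CircularGenome(name=name or rec.id, sequence=seq)


def write_haplotype(genome: CircularGenome, fasta_path: str | Path) -> None:
    """Write a genome as single-record FASTA (60-column wrapped)."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome.name}\n")
        for i in range(0, genome.length, 60):
            fh.write(genome.sequence[i : i + 60] + "\n")


def snps_to_tsv(snps: Iterable[InformativeSNP], path: str | Path) -> None:
    pd.DataFrame(
        {
            "position": [s.position for s in snps],
            "donor_allele": [s.donor_allele for s in snps],
            "recipient_allele": [s.recipient_allele for s in snps],
            "flags": [",".join(sorted(s.filter_flags)) for s in snps],
        }
    ).to_csv(path, sep="\t", index=False)


def snps_from_tsv(path: str | Path) -> list[InformativeSNP]:
    df = pd.read_csv(path, sep="\t", dtype={"flags": str}, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        flags = frozenset(f for f in str(row.flags).split(",") if f)
        out.append(
            InformativeSNP(
                position=int(row.position),
                donor_allele=str(row.donor_allele),
                recipient_allele=str(row.recipient_allele),
                filter_flags=flags,
            )
        )
    return out
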