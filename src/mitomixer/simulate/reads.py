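"""Paired-end read simulation on a circular genome with truth alignments.

Fragments are drawn from a mixture of donor and recipient mtDNA molecules
(the recipient optionally segregating a large deletion), sequenced as
2 x ``read_length`` bp pairs with i.i.d. substitution error, and written as
FASTQ plus a SAM file whose coordinates are true by construction — no
external aligner is involved. Two amplification geometries are modelled:

``rca_uniform``
    rolling-circle amplification; fragments start uniformly anywhere on the
    circle, including across the origin.
``pcr_two_amplicon``
    two overlapping long-range PCR amplicons; fragments are confined to the
    amplicon intervals, with a configurable per-amplicon depth imbalance.
"""

from __future__ import annotations

import warnings
from itertools import chain
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ..errors import ConfigurationError, InvalidParameterError
from ..genomes import CODE_TO_ASCII, COMPLEMENT_CODE, HaplotypePair

ORIGIN_DONOR = "donor"
ORIGIN_RECIPIENT_FULL = "recipient_full"
ORIGIN_RECIPIENT_DELETED = "recipient_deleted"
_ORIGIN_NAMES = (ORIGIN_DONOR, ORIGIN_RECIPIENT_FULL, ORIGIN_RECIPIENT_DELETED)

#: fixed base quality written for every simulated base (Phred 30)
BASE_QUALITY = 30
_QUAL_CHAR = chr(BASE_QUALITY + 33)
_MAPQ = 60


def default_amplicons(length: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Two overlapping amplicons jointly tiling the circle.

    Placeholder geometry for a two-primer-set long-range PCR design: each
    amplicon covers slightly more than half the genome and the two overlap
    at both junctions, so every position is amplifiable.
    """
    half = length // 2
    pad = max(length // 40, 200)
    return ((1, half + pad), (half - pad, length))


@dataclass
class ReadSimConfig:
    """Parameters of the sequencing simulation.

    ``mixture_fraction`` is the ground-truth fraction of template molecules
    of donor origin — the quantity the informative-SNP estimator recovers as
    "percent exogenous mtDNA". Defaults follow a 2 x 150 bp run at 2500x
    with a 350 bp insert.
    """

    coverage: float = 2500.0
    read_length: int = 150
    error_rate: float = 0.001
    amplification_mode: str = "rca_uniform"
    amplicon_intervals: Optional[Sequence[tuple[int, int]]] = None
    amplicon_depth_ratio: float = 1.0
    mixture_fraction: float = 0.0
    insert_gap: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise InvalidParameterError("coverage must be > 0")
        if self.read_length < 20:
            raise InvalidParameterError("read_length must be >= 20")
        if not 0.0 <= self.error_rate < 0.25:
            raise InvalidParameterError("error_rate must lie in [0, 0.25)")
        if not 0.0 <= self.mixture_fraction <= 1.0:
            raise InvalidParameterError("mixture_fraction must lie in [0, 1]")
        if self.amplification_mode not in ("rca_uniform", "pcr_two_amplicon"):
            raise ConfigurationError(
                f"unknown amplification_mode {self.amplification_mode!r}"
            )
        if self.amplicon_depth_ratio <= 0:
            raise InvalidParameterError("amplicon_depth_ratio must be > 0")

    @property
    def fragment_length(self) -> int:
        return 2 * self.read_length + self.insert_gap


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth origin and placement of one emitted read."""

    read_id: str
    origin: str
    start: int
    strand: str


@dataclass
class ReadSimResult:
    """Paths and summary counts returned by :func:`simulate_reads`."""

    sam_path: Path
    truth_path: Path
    fastq_r1: Optional[Path]
    fastq_r2: Optional[Path]
    n_pairs: int
    n_donor_fragments: int
    warnings: list = field(default_factory=list)

    def truth_table(self) -> pd.DataFrame:
        return pd.read_csv(self.truth_path, sep="\t")


def _deleted_molecule(pair: HaplotypePair) -> tuple[np.ndarray, np.ndarray]:
    """Codes and reference-coordinate map of the deletion-bearing molecule.

    ``refmap[i]`` gives the 1-based reference position of molecule
    coordinate ``i`` (0-based); the deleted interval is simply absent, so
    the map jumps across it at the junction.
    """
    dele = pair.recipient_deletion
    codes = pair.recipient.codes()
    keep = np.ones(pair.length, dtype=bool)
    keep[dele.start - 1 : dele.end] = False
    refmap = np.arange(1, pair.length + 1, dtype=np.int64)[keep]
    return codes[keep], refmap


def _pcr_start_intervals(
    amplicons: Sequence[tuple[int, int]],
    frag_len: int,
    refmap_bounds: Optional[tuple[int, int, int]],
) -> list[tuple[int, int]]:
    """0-based [lo, hi) fragment-start intervals in molecule coordinates.

    For the deletion-bearing molecule the amplicon interval is mapped
    through the deletion (``refmap_bounds`` = (del_start, del_end,
    del_length)): positions inside the deletion vanish and the flanks become
    adjacent, so a reference amplicon maps to one contiguous molecule-
    coordinate interval.
    """
    out = []
    for a, b in amplicons:
        if refmap_bounds is None:
            lo, hi = a - 1, b
        else:
            ds, de, dlen = refmap_bounds

            # endpoints < ds keep their 0-based coordinate; endpoints > de
            # shift down by the deletion length; endpoints inside the
            # deletion collapse onto the junction.
            def _map(x: int) -> int:
                if x < ds:
                    return x - 1
                if x > de:
                    return x - 1 - dlen
                return ds - 1
            lo, hi = _map(a), _map(b) + 1
        if hi - lo >= frag_len:
            out.append((lo, hi - frag_len + 1))
    return out


def _sample_starts_in_intervals(
    rng: np.random.Generator,
    n: int,
    intervals: list[tuple[int, int]],
    weights: list[float],
) -> np.ndarray:
    """Sample fragment starts from weighted union of start intervals."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    which = rng.choice(len(intervals), size=n, p=w)
    starts = np.empty(n, dtype=np.int64)
    for k, (lo, hi) in enumerate(intervals):
        mask = which == k
        starts[mask] = rng.integers(lo, hi, size=int(mask.sum()))
    return starts


def _segment_records(refpos: np.ndarray) -> list[tuple[int, str, int]]:
    """Split a read's per-base reference positions into SAM records.

    Returns ``(pos, cigar, is_supplementary)`` tuples. Consecutive reference
    positions extend an M run; a forward jump becomes a D operation (the
    read spans the deletion junction); a backward jump means the read wraps
    the circular origin and continues as a separate (supplementary) record
    with the remainder soft-clipped in each part.
    """
    n = len(refpos)
    breaks = [0] + [i for i in range(1, n) if refpos[i] <= refpos[i - 1]] + [n]
    records = []
    for r in range(len(breaks) - 1):
        qs, qe = breaks[r], breaks[r + 1]
        ops = []
        if qs > 0:
            ops.append(f"{qs}S")
        run = 1
        for i in range(qs + 1, qe):
            gap = refpos[i] - refpos[i - 1]
            if gap == 1:
                run += 1
            else:
                ops.append(f"{run}M")
                ops.append(f"{gap - 1}D")
                run = 1
        ops.append(f"{run}M")
        if qe < n:
            ops.append(f"{n - qe}S")
        records.append((int(refpos[qs]), "".join(ops), 1 if r > 0 else 0))
    return records


def simulate_reads(
    pair: HaplotypePair,
    cfg: ReadSimConfig,
    out_prefix: str | Path,
    emit_fastq: bool = True,
) -> ReadSimResult:
    """Simulate a paired-end run and write FASTQ/SAM/truth-table files.

    The number of read pairs is ``coverage x genome_length /
    (2 x read_length)``. Each fragment's haplotype is drawn
    Bernoulli(``mixture_fraction``) for donor; recipient fragments carry the
    deletion with probability ``recipient_deletion.heteroplasmy``, in which
    case the fragment is drawn from the shortened molecule and contributes
    no bases inside the deletion. SAM coordinates are truth; reads spanning
    the circular origin are written as two records (primary +
    supplementary), and reads spanning the deletion junction carry a D
    CIGAR operation.

    Output files are ``<out_prefix>.sam``, ``<out_prefix>.truth.tsv`` and,
    when ``emit_fastq``, ``<out_prefix>_R1.fastq`` / ``<out_prefix>_R2.fastq``.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    recorded_warnings: list[str] = []

    L = pair.length
    R = cfg.read_length
    frag = cfg.fragment_length
    if frag > L:
        raise InvalidParameterError("fragment length exceeds genome length")
    n_pairs = int(round(cfg.coverage * L / (2 * R)))

    dele = pair.recipient_deletion
    molecules = {
        0: (pair.donor.codes(), None),
        1: (pair.recipient.codes(), None),
    }
    if dele is not None:
        molecules[2] = _deleted_molecule(pair)

    # Fragment origins. Fragments arise from shearing the pooled DNA mass,
    # so a molecule contributes fragments in proportion to its length: the
    # deletion-bearing molecule (shorter circle) yields proportionally
    # fewer. With this weighting the read-level donor-allele frequency at
    # any site outside the deletion equals mixture_fraction exactly; depth
    # outside the deletion is coverage * L / W where W is the mass-weighted
    # mean molecule length (coverage counts total sequenced bases over L).
    # Without a deletion all molecules have equal length and the draw
    # reduces to Bernoulli(mixture_fraction) per fragment.
    f = cfg.mixture_fraction
    h = dele.heteroplasmy if dele is not None else 0.0
    Ld = L - dele.length if dele is not None else L
    mass_donor = f * L
    mass_rec = (1.0 - f) * ((1.0 - h) * L + h * Ld)
    p_donor = mass_donor / (mass_donor + mass_rec) if mass_donor + mass_rec else 0.0
    is_donor = rng.random(n_pairs) < p_donor
    origin = np.where(is_donor, 0, 1).astype(np.int8)
    if dele is not None and h > 0:
        p_del = h * Ld / ((1.0 - h) * L + h * Ld)
        deleted = (~is_donor) & (rng.random(n_pairs) < p_del)
        origin[deleted] = 2

    # amplicon setup for PCR mode
    if cfg.amplification_mode == "pcr_two_amplicon":
        amplicons = cfg.amplicon_intervals
        if amplicons is None:
            amplicons = default_amplicons(L)
        amplicons = [(int(a), int(b)) for a, b in amplicons]
        if len(amplicons) != 2:
            raise ConfigurationError("pcr_two_amplicon mode requires two amplicons")
        for a, b in amplicons:
            if not 1 <= a < b <= L:
                raise ConfigurationError(f"amplicon {a}..{b} outside genome")
        uncovered = [
            p
            for p in pair.snp_positions()
            if not any(a <= p <= b for a, b in amplicons)
        ]
        if uncovered:
            msg = (
                f"{len(uncovered)} truth SNP position(s) not covered by the "
                f"amplicon intervals: {uncovered[:5]}..."
            )
            recorded_warnings.append(msg)
            warnings.warn(msg, stacklevel=2)

    # fragment starts per molecule class (0-based molecule coordinates)
    starts = np.empty(n_pairs, dtype=np.int64)
    for cls, (codes, refmap) in molecules.items():
        mask = origin == cls
        n_cls = int(mask.sum())
        if n_cls == 0:
            continue
        Lc = len(codes)
        if cfg.amplification_mode == "rca_uniform":
            starts[mask] = rng.integers(0, Lc, size=n_cls)
        else:
            bounds = None
            if refmap is not None:
                bounds = (dele.start, dele.end, dele.length)
            ivals = _pcr_start_intervals(amplicons, frag, bounds)
            if not ivals:
                raise ConfigurationError(
                    "no amplicon can accommodate a fragment on this molecule"
                )
            weights = []
            for k, (lo, hi) in enumerate(ivals):
                depth = cfg.amplicon_depth_ratio if k == 0 else 1.0
                weights.append(depth * (hi - lo))
            starts[mask] = _sample_starts_in_intervals(rng, n_cls, ivals, weights)

    # fragment strand: + means mate1 is the forward (left) read
    frag_plus = rng.random(n_pairs) < 0.5

    # per-mate molecule-coordinate starts (mate "a" = left/forward read,
    # mate "b" = right/reverse read, in molecule orientation)
    a_start = starts
    b_start = starts + frag - R

    # build base matrices per class; reads that wrap the origin or span the
    # deletion junction ("non-plain") get generic CIGAR treatment later
    offsets = np.arange(R, dtype=np.int32)
    seq_a = np.empty((n_pairs, R), dtype=np.uint8)
    seq_b = np.empty((n_pairs, R), dtype=np.uint8)
    pos_a_arr = np.empty(n_pairs, dtype=np.int64)
    pos_b_arr = np.empty(n_pairs, dtype=np.int64)
    plain_a = np.ones(n_pairs, dtype=bool)
    plain_b = np.ones(n_pairs, dtype=bool)
    junction = dele.start - 1 if dele is not None else -1  # 0-based mol coord
    for cls, (codes, refmap) in molecules.items():
        mask = origin == cls
        if not mask.any():
            continue
        Lc = len(codes)
        sa = (a_start[mask] % Lc).astype(np.int32)
        sb = (b_start[mask] % Lc).astype(np.int32)
        seq_a[mask] = codes[(sa[:, None] + offsets) % Lc]
        seq_b[mask] = codes[(sb[:, None] + offsets) % Lc]
        if refmap is None:
            pos_a_arr[mask] = sa + 1
            pos_b_arr[mask] = sb + 1
            plain_a[mask] = sa + R <= Lc
            plain_b[mask] = sb + R <= Lc
        else:
            pos_a_arr[mask] = refmap[sa]
            pos_b_arr[mask] = refmap[sb]
            plain_a[mask] = (sa + R <= Lc) & ~((sa < junction) & (junction < sa + R))
            plain_b[mask] = (sb + R <= Lc) & ~((sb < junction) & (junction < sb + R))

    def _refpos_row(i: int, start: int) -> np.ndarray:
        """Per-base 1-based reference positions of one (non-plain) read."""
        codes, refmap = molecules[origin[i]]
        Lc = len(codes)
        idx = (start + np.arange(R)) % Lc
        return idx + 1 if refmap is None else refmap[idx]

    # i.i.d. substitution errors on every sequenced base
    if cfg.error_rate > 0:
        for mat in (seq_a, seq_b):
            err = rng.random(mat.size) < cfg.error_rate
            n_err = int(err.sum())
            if n_err:
                flat = mat.reshape(-1)
                shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                flat[err] = (flat[err] + shift) % 4

    qual = _QUAL_CHAR * R
    rname = pair.recipient.name

    # mate "a" is always the forward-oriented (left) read, mate "b" the
    # reverse one; fragment strand only swaps the read1/read2 labels.
    FLAG_A_R1 = 0x1 | 0x2 | 0x20 | 0x40   # 99: paired, proper, mate rev, first
    FLAG_B_R2 = 0x1 | 0x2 | 0x10 | 0x80   # 147
    FLAG_A_R2 = 0x1 | 0x2 | 0x20 | 0x80   # 163
    FLAG_B_R1 = 0x1 | 0x2 | 0x10 | 0x40   # 83

    qnames = [f"r{i:07d}" for i in range(n_pairs)]
    plus_list = frag_plus.tolist()
    org_list = [_ORIGIN_NAMES[o] for o in origin.tolist()]

    all_a = CODE_TO_ASCII[seq_a].tobytes().decode("ascii")
    all_b = CODE_TO_ASCII[seq_b].tobytes().decode("ascii")
    seq_a_str = [all_a[i * R : (i + 1) * R] for i in range(n_pairs)]
    seq_b_str = [all_b[i * R : (i + 1) * R] for i in range(n_pairs)]

    pos_a = pos_a_arr.tolist()
    pos_b = pos_b_arr.tolist()
    cigar_plain = f"{R}M"
    flags_a = np.where(frag_plus, FLAG_A_R1, FLAG_A_R2).tolist()
    flags_b = np.where(frag_plus, FLAG_B_R2, FLAG_B_R1).tolist()

    tail = f"\t0\t"  # TLEN field separator (TLEN not modelled)
    mid = f"\t{_MAPQ}\t{cigar_plain}\t=\t"

    def _plain_lines(flags, pos, seqs):
        return [
            f"{qn}\t{fl}\t{rname}\t{p}{mid}{p}{tail}{sq}\t{qual}"
            for qn, fl, p, sq in zip(qnames, flags, pos, seqs)
        ]

    lines_a = _plain_lines(flags_a, pos_a, seq_a_str)
    lines_b = _plain_lines(flags_b, pos_b, seq_b_str)

    # origin-wrapping / junction-spanning reads get their true multi-segment
    # or D-containing CIGARs via the generic path
    for mat_lines, plain, mate_start, flags, pos, seqs in (
        (lines_a, plain_a, a_start, flags_a, pos_a, seq_a_str),
        (lines_b, plain_b, b_start, flags_b, pos_b, seq_b_str),
    ):
        for i in np.flatnonzero(~plain):
            recs = _segment_records(_refpos_row(i, int(mate_start[i])))
            primary = recs[0][0]
            pos[i] = primary
            mat_lines[i] = "\n".join(
                f"{qnames[i]}\t{flags[i] | (0x800 if supp else 0)}\t{rname}"
                f"\t{p}\t{_MAPQ}\t{cig}\t=\t{primary}{tail}{seqs[i]}\t{qual}"
                for p, cig, supp in recs
            )

    mate_a_no = ["1" if p else "2" for p in plus_list]
    mate_b_no = ["2" if p else "1" for p in plus_list]
    truth_a = [
        f"{qn}/{n}\t{org}\t{p}\t+"
        for qn, n, org, p in zip(qnames, mate_a_no, org_list, pos_a)
    ]
    truth_b = [
        f"{qn}/{n}\t{org}\t{p}\t-"
        for qn, n, org, p in zip(qnames, mate_b_no, org_list, pos_b)
    ]

    sam_path = out_prefix.with_suffix(".sam")
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{rname}\tLN:{L}\n")
        fh.write("\n".join(chain.from_iterable(zip(lines_a, lines_b))))
        fh.write("\n")
    truth_path = Path(str(out_prefix) + ".truth.tsv")
    with open(truth_path, "w") as fh:
        fh.write("read_id\torigin\tstart\tstrand\n")
        fh.write("\n".join(chain.from_iterable(zip(truth_a, truth_b))))
        fh.write("\n")

    fastq_r1 = fastq_r2 = None
    if emit_fastq:
        # read1/read2 as sequenced: the reverse-oriented mate is written
        # 5'->3', i.e. reverse-complemented relative to the reference.
        all_rc_a = CODE_TO_ASCII[COMPLEMENT_CODE[seq_a[:, ::-1]]].tobytes().decode("ascii")
        all_rc_b = CODE_TO_ASCII[COMPLEMENT_CODE[seq_b[:, ::-1]]].tobytes().decode("ascii")
        r1_parts: list[str] = []
        r2_parts: list[str] = []
        for i in range(n_pairs):
            qn = qnames[i]
            s = slice(i * R, (i + 1) * R)
            if plus_list[i]:
                r1, r2 = seq_a_str[i], all_rc_b[s]
            else:
                r1, r2 = all_rc_a[s], seq_b_str[i]
            r1_parts.append(f"@{qn}/1\n{r1}\n+\n{qual}\n")
            r2_parts.append(f"@{qn}/2\n{r2}\n+\n{qual}\n")
        fastq_r1 = Path(str(out_prefix) + "_R1.fastq")
        fastq_r2 = Path(str(out_prefix) + "_R2.fastq")
        fastq_r1.write_text("".join(r1_parts))
        fastq_r2.write_text("".join(r2_parts))

    return ReadSimResult(
        sam_path=sam_path,
        truth_path=truth_path,
        fastq_r1=fastq_r1,
        fastq_r2=fastq_r2,
        n_pairs=n_pairs,
        n_donor_fragments=int(is_donor.sum()),
        warnings=recorded_warnings,
    )
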