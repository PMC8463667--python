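"""Independent oracles used by several test modules.

These deliberately avoid the package's own CIGAR walking: the pileup oracle
relies on pysam's ``get_aligned_pairs`` to map query bases to reference
positions, so agreement with ``build_pileup`` cross-checks two separate
coordinate implementations.
"""

from collections import Counter

import pysam


def pileup_oracle(sam_path, positions, min_baseq=20, min_mapq=20):
    """Brute-force per-read base tally at 1-based reference positions.

    Applies the same filters and fragment-level deduplication rules as the
    production pileup (skip secondary/duplicate/unmapped, base and mapping
    quality thresholds, one base per fragment per position with the
    higher-quality call winning) but via pysam's aligned-pairs interface.
    """
    positions = set(int(p) for p in positions)
    best = {}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as af:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_duplicate:
                continue
            if read.mapping_quality < min_mapq:
                continue
            quals = read.query_qualities
            seq = read.query_sequence
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                p = rpos + 1
                if p not in positions:
                    continue
                bq = quals[qpos] if quals is not None else 0
                if bq < min_baseq:
                    continue
                key = (p, read.query_name)
                prev = best.get(key)
                if prev is None or bq > prev[0]:
                    best[key] = (bq, seq[qpos])
    counts = {p: Counter() for p in positions}
    for (p, _qname), (_bq, base) in best.items():
        counts[p][base] += 1
    return counts


def mean_depth(sam_path, genome, positions, min_baseq=0, min_mapq=0):
    """Mean oracle depth over the given positions."""
    counts = pileup_oracle(sam_path, positions, min_baseq, min_mapq)
    return sum(sum(c.values()) for c in counts.values()) / len(positions)
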