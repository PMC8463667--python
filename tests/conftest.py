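"""Shared fixtures: small synthetic datasets reused across test modules."""

import pytest

from mitomixer.genomes import DeletionSpec
from mitomixer.simulate import (
    ReadSimConfig,
    derive_haplotypes,
    make_reference,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_ref():
    return make_reference(length=3000, seed=42, name="mini")


@pytest.fixture(scope="session")
def small_pair(small_ref):
    return derive_haplotypes(small_ref, n_snps=12, seed=7)


@pytest.fixture(scope="session")
def small_sim(small_pair, tmp_path_factory):
    """A modest mixed run (20% donor) with FASTQ, SAM and truth table."""
    out = tmp_path_factory.mktemp("smallsim") / "run"
    cfg = ReadSimConfig(coverage=400, mixture_fraction=0.2, seed=9)
    return simulate_reads(small_pair, cfg, out, emit_fastq=True)


@pytest.fixture(scope="session")
def deletion_pair():
    """Reference-scale pair with the nt 8470-13,447 deletion at 83.5%."""
    ref = make_reference(seed=1)
    dele = DeletionSpec(start=8470, end=13447, heteroplasmy=0.835)
    return derive_haplotypes(ref, n_snps=30, deletion=dele, seed=6)
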