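import numpy as np
import pytest

from seapopgen.io import GenotypeTable, SequenceAlignment
from seapopgen.mtdna import collapse_haplotypes
from seapopgen.simulate import ReferenceConfig, FlowFieldSpec, make_reference_dataset


@pytest.fixture
def two_pop_alignment() -> SequenceAlignment:
    """Two populations, three haplotypes, 10 bp."""
    seqs = {
        "h0": "AAAAAAAAAA",
        "h1": "AAAAAAAAAT",  # 1 diff from h0
        "h2": "AAAAAAATTT",  # 3 diffs from h0, 2 from h1
    }
    sites = [seqs["h0"]] * 4 + [seqs["h1"]] * 2 + [seqs["h1"]] * 3 + [seqs["h2"]] * 3
    pops = ["A"] * 6 + ["B"] * 6
    return SequenceAlignment(
        ids=[f"s{i}" for i in range(12)], population=pops, sites=sites
    )


@pytest.fixture
def two_pop_haplotable(two_pop_alignment):
    return collapse_haplotypes(two_pop_alignment)


def hwe_genotypes(
    n: int, alleles, freqs, rng: np.random.Generator, n_loci: int = 1, pop: str = "P"
) -> GenotypeTable:
    """Random-mating genotypes drawn directly from allele frequencies."""
    calls = []
    for _ in range(n):
        row = []
        for _l in range(n_loci):
            a, b = rng.choice(alleles, size=2, p=freqs)
            row.append((min(a, b), max(a, b)))
        calls.append(row)
    return GenotypeTable(
        ids=[f"{pop}{i}" for i in range(n)],
        population=[pop] * n,
        loci=[f"L{l+1}" for l in range(n_loci)],
        calls=calls,
    )


@pytest.fixture(scope="session")
def reference_bundle(tmp_path_factory):
    """Small synthetic Baltic-like bundle shared across tests."""
    cfg = ReferenceConfig(
        n_per_pop=20,
        flow=FlowFieldSpec(nx=30, ny=48, duration_days=40.0,
                           gyre_period_days=10.0, noise_fraction=1.0),
    )
    out = tmp_path_factory.mktemp("bundle")
    return make_reference_dataset(out, seed=2024, config=cfg)
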