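import numpy as np
import pytest

from srnascan.candidates import CallerConfig, call_candidates
from srnascan.synthetic_data import SimulationConfig, generate_dataset
from srnascan.tracks import StructureScanConfig, scan_local_structures


def random_sequence(n: int, gc: float, seed: int) -> str:
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def hairpin(stem: int, loop: int, seed: int = 0, gc_only: bool = True) -> str:
    """A perfect stem-loop test sequence (GC stem by default)."""
    rng = np.random.default_rng(seed)
    left = []
    for _ in range(stem):
        left.append("G" if rng.random() < 0.5 else "C")
    right = [{"G": "C", "C": "G"}[c] for c in reversed(left)]
    loop_seq = "".join(rng.choice(list("ACGT"), size=loop))
    return "".join(left) + loop_seq + "".join(right)


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study: 100 kb AT-rich genome with planted
    ncRNAs, antisense pairs, ORFs, tRNAs; alignment; both read libraries."""
    return generate_dataset(SimulationConfig(rng_seed=0))


@pytest.fixture(scope="session")
def default_scan(default_dataset):
    genome = default_dataset[0]
    return scan_local_structures(genome, StructureScanConfig(rng_seed=0))


@pytest.fixture(scope="session")
def default_candidates(default_dataset, default_scan):
    from srnascan.synthetic_data import known_annotation

    genome, annotations, truth, blocks, plus_reads, minus_reads = default_dataset
    return call_candidates(
        genome,
        known_annotation(annotations),
        plus_reads + minus_reads,
        maf_blocks={"p": blocks, "t": blocks},
        config=CallerConfig(),
        structures=default_scan,
    )
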