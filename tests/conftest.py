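import numpy as np
import pytest

from asmappraise.io_formats import SequenceRecord


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20110331)


def random_seq(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, n, p=p)])


@pytest.fixture(scope="session")
def small_genome():
    """A 600 kbp two-chromosome truth genome shared across tests."""
    from asmappraise.synthetic import GenomeSpec, generate_genome

    return generate_genome(GenomeSpec(n_chromosomes=2, total_length=600_000, seed=7))


@pytest.fixture(scope="session")
def small_corrupted(small_genome):
    from asmappraise.synthetic import CorruptionSpec, corrupt_assembly

    spec = CorruptionSpec(n_misjoins=1, n_novel_inserts=5, seed=7)
    return corrupt_assembly(small_genome, spec)
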