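import numpy as np
import pytest

from baitforge.formats import ReferenceGenome
from baitforge.synthetic import SyntheticConfig, make_cohort_vcf, make_genome

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_genome(rng: np.random.Generator, lengths: dict[str, int]) -> ReferenceGenome:
    return ReferenceGenome(
        {
            name: rng.choice(BASES, size=n).tobytes().decode("ascii")
            for name, n in lengths.items()
        }
    )


@pytest.fixture(scope="session")
def fixture_config() -> SyntheticConfig:
    return SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def planted_fixture(fixture_config):
    """Seeded genome + repeat set + cohort records with full planted truth."""
    genome, repeats, truth = make_genome(fixture_config)
    records, truth_table = make_cohort_vcf(genome, truth, fixture_config)
    return {
        "config": fixture_config,
        "genome": genome,
        "repeats": repeats,
        "truth": truth,
        "records": records,
        "truth_table": truth_table,
    }
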