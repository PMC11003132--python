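import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ensemblevar import SpikeConfig, make_reference, spike_variants


@pytest.fixture(scope="session")
def small_reference():
    return make_reference(2, [60_000, 40_000], seed=11)


@pytest.fixture(scope="session")
def small_truth(small_reference):
    config = SpikeConfig(
        counts={"SNP": 30, "INDEL": 15, "DEL": 8, "INS": 8, "INV": 4, "DUP": 4},
        het_fraction=0.5,
        seed=11,
    )
    truth, haplotypes = spike_variants(small_reference, config)
    return truth, haplotypes, config
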