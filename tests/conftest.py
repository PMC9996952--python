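import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make _oracles importable

# loaded CI containers: wall-clock deadlines are not meaningful
settings.register_profile(
    "ci", deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from oligoblock import CountTable, TranscriptRecord, Transcriptome


@pytest.fixture
def rng():
    return np.random.default_rng(20230308)


@pytest.fixture
def small_transcriptome():
    return Transcriptome(
        [
            TranscriptRecord("tx1", "ACGT" * 20),
            TranscriptRecord("tx2", "C" * 20 + "A" * 12 + "C" * 20, biotype="rRNA_pseudogene"),
            TranscriptRecord("tx3", "GATTACA" * 10, biotype="miRNA"),
        ]
    )


@pytest.fixture
def tiny_table():
    return CountTable.from_arrays(
        ["g1", "g2", "g3"],
        ["s1", "s2"],
        np.array([[25, 60], [75, 40], [0, 0]]),
    )


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
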