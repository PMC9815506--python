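import pandas as pd
import pytest

from epidrs.io_tables import ModCallTable, TranscriptAnnotation
from epidrs.synthetic import SimConfig, simulate_dataset


@pytest.fixture
def condition_map():
    return {"C1": "control", "C2": "control", "N1": "treated", "N2": "treated"}


@pytest.fixture
def small_table(condition_map):
    rows = []
    for sample in condition_map:
        treated = condition_map[sample] == "treated"
        rows.append(("tx1", 10, "A", sample, 60, 30 if treated else 6))
        rows.append(("tx1", 50, "G", sample, 80, 8))
        rows.append(("tx2", 5, "U", sample, 40, 4))
    df = pd.DataFrame(
        rows,
        columns=["transcript_id", "position", "ref_base", "sample_id",
                 "coverage", "modified_count"],
    )
    return ModCallTable(df, condition_map, condition_order=("control", "treated"))


@pytest.fixture
def annotations():
    return {
        "tx1": TranscriptAnnotation("tx1", 100, 20, 80),
        "tx2": TranscriptAnnotation("tx2", 200, 50, 150),
    }


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic bundle shared across module tests."""
    config = SimConfig(n_transcripts=60, n_planted=12, seed=11)
    return simulate_dataset(config)
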