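import pytest

from enztherm import ActivityRecord, SimConfig, simulate_dataset


@pytest.fixture
def toy_records() -> list[ActivityRecord]:
    """Three sequences: a full profile, a single-temperature one, and a tie."""
    def rec(sid, seq, temp, kcat):
        return ActivityRecord(sid, seq, temp, kcat)

    return [
        rec("A", "ACDEFGHIKL", 30.0, 10.0),
        rec("A", "ACDEFGHIKL", 40.0, 50.0),
        rec("A", "ACDEFGHIKL", 50.0, 20.0),
        rec("B", "MNPQRSTVWY", 37.0, 100.0),
        rec("C", "ACDACDACDA", 30.0, 50.0),
        rec("C", "ACDACDACDA", 40.0, 50.0),
    ]


@pytest.fixture(scope="session")
def small_benchmark():
    """A small synthetic benchmark shared across tests (pure function of seed)."""
    config = SimConfig(
        n_families=8, mutants_per_family=4, seq_length=120, seed=7
    )
    records, sequences, truth, wild_type = simulate_dataset(config)
    return {
        "config": config,
        "records": records,
        "sequences": sequences,
        "truth": truth,
        "wild_type": wild_type,
    }
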