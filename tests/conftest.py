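import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from klrpath import synth
from klrpath.repertoire import ClonotypeTable

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def stage_model():
    return synth.StageModel()


@pytest.fixture(scope="session")
def events_small(stage_model):
    """4,000 events from the default stage model (shared, read-only)."""
    return synth.gen_events(stage_model, 4000, seed=7)


@pytest.fixture(scope="session")
def repertoires():
    """Default stage-wise synthetic repertoires (shared, read-only)."""
    return synth.gen_repertoires(synth.RepertoireModel(), seed=11)


def make_table(counts: dict, label=None) -> ClonotypeTable:
    """Clonotype table from {cdr3: count} with fixed V/J genes."""
    df = pd.DataFrame(
        [("TRBV1", "TRBJ1-1", cdr3, n) for cdr3, n in counts.items()],
        columns=["v_gene", "j_gene", "cdr3_aa", "count"])
    return ClonotypeTable(df, label=label)


def random_table(rng: np.random.Generator, n_clones: int = 50,
                 max_count: int = 500) -> ClonotypeTable:
    counts = {f"CASS{i:04d}F": int(c) for i, c in enumerate(
        rng.integers(1, max_count, size=n_clones))}
    return make_table(counts)
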