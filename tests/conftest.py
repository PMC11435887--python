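import numpy as np
import pandas as pd
import pytest

from fmtkit.feature_table import AsvTable, SampleMetadata, TaxonomyAssignment
from fmtkit.synthetic import TrialSimConfig, make_fixture_dataset, simulate_trial


@pytest.fixture()
def small_table() -> AsvTable:
    counts = pd.DataFrame(
        [[2, 1, 1], [0, 3, 5]],
        index=pd.Index(["s1", "s2"]),
        columns=pd.Index(["a1", "a2", "a3"]),
    )
    return AsvTable(counts)


@pytest.fixture()
def lachno_taxonomy() -> dict[str, TaxonomyAssignment]:
    lachno = ("Bacteria", "Firmicutes", "Clostridia", "Lachnospirales", "Lachnospiraceae")
    return {
        "a1": TaxonomyAssignment(lachno + ("Blautia", "Blautia hansenii")),
        "a2": TaxonomyAssignment(lachno + ("Blautia", "Blautia caecimuris")),
        "a3": TaxonomyAssignment(lachno + ("", "")),  # genus-unassigned
    }


def random_asv_table(rng: np.random.Generator, n_samples: int, n_asvs: int, max_count: int = 50) -> AsvTable:
    counts = pd.DataFrame(
        rng.integers(0, max_count + 1, size=(n_samples, n_asvs)),
        index=pd.Index([f"s{i}" for i in range(n_samples)]),
        columns=pd.Index([f"a{j}" for j in range(n_asvs)]),
    )
    return AsvTable(counts)


@pytest.fixture(scope="session")
def trial_sim() -> dict:
    """One simulated trial at the default study conditions (shared, read-only)."""
    return simulate_trial(TrialSimConfig(seed=7))


@pytest.fixture(scope="session")
def trial_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    cfg = TrialSimConfig(seed=7)
    paths = make_fixture_dataset(cfg, out)
    return cfg, paths


@pytest.fixture()
def paired_metadata() -> SampleMetadata:
    rows = []
    for d in ("d1", "d2", "d3"):
        rows.append({"sample_id": f"{d}_pre", "dog_id": d, "group": "FMT", "visit": "endoscopy"})
        rows.append({"sample_id": f"{d}_post", "dog_id": d, "group": "FMT", "visit": "treatment"})
    return SampleMetadata(pd.DataFrame(rows))
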