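import numpy as np
import pandas as pd
import pytest

import proteosubtype as pst


@pytest.fixture(scope="session")
def genome():
    return pst.default_genome()


@pytest.fixture(scope="session")
def small_cohort():
    """One compact synthetic cohort shared by read-only tests."""
    cfg = pst.SimulationConfig(
        n_samples=30, samples_per_plex=11, n_proteins=700, n_phosphosites=600,
        n_mrna=700, signature_size=40, missing_rate=0.15, missing_mode="random",
        seed=11,
    )
    return pst.simulate_cohort(cfg)


@pytest.fixture()
def toy_matrix():
    data = pd.DataFrame(
        np.array([[1.0, 2.0, 3.0, 4.0],
                  [2.0, 4.0, 6.0, 8.0],
                  [5.0, 5.0, 5.0, 5.0]]),
        index=["F1", "F2", "F3"], columns=["s1", "s2", "s3", "s4"])
    return pst.OmicsMatrix(data, "log2", "protein")


def two_plex_samples(sample_ids, per_plex):
    rows = []
    for i, s in enumerate(sample_ids):
        rows.append({"sample_id": s, "plex_id": f"px{i // per_plex + 1}",
                     "channel_id": f"ch{i % per_plex + 1}",
                     "is_pooled_reference": s.startswith("REF")})
    return pst.SampleTable(pd.DataFrame(rows))
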