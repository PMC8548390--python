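import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from heteroprot import QuantMatrix, SampleDesign

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def make_design(n_replicates: int = 3) -> SampleDesign:
    rows = []
    for genotype, role in (("P1", "female_parent"), ("P2", "male_parent"), ("F1", "hybrid")):
        for rep in range(1, n_replicates + 1):
            rows.append({"sample_id": f"{genotype}_r{rep}", "genotype": genotype,
                         "role": role, "replicate": rep})
    return SampleDesign(pd.DataFrame(rows))


def make_matrix(values_by_protein: dict, n_replicates: int = 3) -> QuantMatrix:
    """Build a trio QuantMatrix from {protein_id: (p1_reps, p2_reps, f1_reps)}."""
    design = make_design(n_replicates)
    rows = {pid: np.concatenate([np.asarray(v, float) for v in triples])
            for pid, triples in values_by_protein.items()}
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=design.sample_ids)
    return QuantMatrix(frame, design)


@pytest.fixture
def trio_design():
    return make_design()


@pytest.fixture
def small_matrix():
    """Noise-free trio matrix: one planted 2x protein among flat ones."""
    return make_matrix({
        "P_up": ([100, 100, 100], [100, 100, 100], [200, 200, 200]),
        "P_flat1": ([50, 50, 50], [50, 50, 50], [50, 50, 50]),
        "P_flat2": ([80, 80, 80], [80, 80, 80], [80, 80, 80]),
    })
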