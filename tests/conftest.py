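import numpy as np
import pandas as pd
import pytest

from circscape.simulate import SimConfig, simulate_cohort


def small_config(**overrides) -> SimConfig:
    """Desk-scale cohort used across tests; big enough to exercise every stage."""
    base = dict(
        n_patients=90,
        n_controls=30,
        n_circ=400,
        n_genes=200,
        n_de=30,
        n_subgroup=12,
        n_subgroup_vetoed=5,
        n_artifacts=15,
        n_drugs=30,
        n_drug_hits=5,
        n_drug_patients=45,
        n_signature_genes=12,
        n_validation_patients=80,
        polya_n_samples=24,
        tool_fp_counts=(25, 25, 25),
        seed=7,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def bundle():
    """One shared small simulated study."""
    return simulate_cohort(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def tiny_annotation(tmp_path):
    """One gene (100-1000) with exons 100-200 and 800-1000, plus a second gene."""
    gtf = tmp_path / "tiny.gtf"
    lines = [
        '1\tsrc\tgene\t100\t1000\t.\t+\t.\tgene_id "GA";',
        '1\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "GA";',
        '1\tsrc\texon\t800\t1000\t.\t+\t.\tgene_id "GA";',
        '2\tsrc\tgene\t500\t2000\t.\t-\t.\tgene_id "GB";',
        '2\tsrc\texon\t500\t700\t.\t-\t.\tgene_id "GB";',
        '2\tsrc\texon\t1500\t2000\t.\t-\t.\tgene_id "GB";',
    ]
    gtf.write_text("\n".join(lines) + "\n")
    return gtf


def counts_frame(values, features=None, samples=None) -> pd.DataFrame:
    values = np.asarray(values)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=features, columns=samples)
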