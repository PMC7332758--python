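"""Shared fixtures: a default simulated study and a tiny handcrafted dataset."""

import numpy as np
import pandas as pd
import pytest

from methylqc.data_model import MethylationDataset
from methylqc.pipeline import PipelineConfig, run_pipeline
from methylqc.synthgen import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def sim_default():
    """One default-scale simulated study (dataset, truth, annotation)."""
    return simulate_dataset(SimConfig(), seed=20)


@pytest.fixture(scope="session")
def sim_csf(sim_default):
    """The CSF biological samples (controls excluded) of the default study."""
    ds, truth, ann = sim_default
    ids = ds.samples.loc[(ds.samples.tissue == "csf")
                         & ~ds.samples.is_control_sample.astype(bool), "sample_id"]
    return ds.subset_samples(ids), truth, ann


def make_tiny_dataset(n_probes=10, n_samples=4, seed=0, constant=False):
    """Small handcrafted dataset with sane controls for unit tests."""
    rng = np.random.default_rng(seed)
    probes = [f"cg{i:03d}" for i in range(n_probes)]
    ids = [f"s{j}" for j in range(n_samples)]
    if constant:
        meth = np.full((n_probes, n_samples), 3000.0)
        unmeth = np.full((n_probes, n_samples), 1000.0)
    else:
        meth = rng.uniform(500, 6000, (n_probes, n_samples))
        unmeth = rng.uniform(500, 6000, (n_probes, n_samples))
    beads = np.full((n_probes, n_samples), 12)
    rows = []
    for ctype, channel, n, level in (("negative", "green", 4, 150.0),
                                     ("negative", "red", 4, 170.0),
                                     ("bisulfite", "green", 3, 4000.0),
                                     ("bisulfite", "red", 3, 4000.0),
                                     ("norm_grn", "green", 3, 3000.0),
                                     ("norm_red", "red", 3, 3000.0)):
        for i in range(n):
            row = {"control_type": ctype, "channel": channel,
                   "probe_id": f"{ctype}_{channel}_{i}"}
            vals = level * (1 + 0.1 * np.sin(np.arange(n_samples) + i))
            row.update(dict(zip(ids, vals)))
            rows.append(row)
    samples = pd.DataFrame({
        "sample_id": ids,
        "subject_id": [f"subj{j}" for j in range(n_samples)],
        "tissue": "blood",
        "collection_day": 1,
        "plate": "P1",
        "chip": "P1_C1",
        "row": [1 + j % 6 for j in range(n_samples)],
        "column": [1 + j // 6 for j in range(n_samples)],
        "replicate_group": [None] * n_samples,
        "trait": [j % 2 for j in range(n_samples)],
        "age": 50.0,
        "sex": ["F", "M"] * (n_samples // 2) + ["F"] * (n_samples % 2),
        "is_control_sample": False,
        "control_beta": np.nan,
    })
    return MethylationDataset(
        meth=pd.DataFrame(meth, index=probes, columns=ids),
        unmeth=pd.DataFrame(unmeth, index=probes, columns=ids),
        beads=pd.DataFrame(beads, index=probes, columns=ids),
        controls=pd.DataFrame(rows),
        samples=samples,
    )


@pytest.fixture
def tiny_dataset():
    return make_tiny_dataset()


@pytest.fixture(scope="session")
def pipeline_run():
    """One full default-scale pipeline run (report, bundle)."""
    return run_pipeline(PipelineConfig(seed=2))
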