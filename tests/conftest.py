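import numpy as np
import pandas as pd
import pytest

from neuroplsc.datamodel import StudyDataset
from neuroplsc.synthetic import generate_two_block, generate_null, make_truth


@pytest.fixture(scope="session")
def planted_small():
    """Moderate planted one-component dataset (fast, clear signal)."""
    truth = make_truth(p=20, q=12, target_r=0.7, seed=11)
    ds, truth = generate_two_block(n=80, p=20, q=12, truth=truth)
    return ds, truth


@pytest.fixture(scope="session")
def null_small():
    return generate_null(n=60, p=10, q=8, seed=5)


@pytest.fixture()
def tiny_dataset():
    """Hand-built n=4 dataset with mixed groups, no missing values."""
    ids = pd.Index(["s1", "s2", "s3", "s4"], name="subject_id")
    behavior = pd.DataFrame(
        {"acc": [0.9, 0.7, 0.8, 0.6], "rt": [500.0, 650.0, 590.0, 700.0]},
        index=ids)
    brain = pd.DataFrame(
        {"roiA": [1.0, 2.0, 1.5, 0.5], "roiB": [0.2, -0.1, 0.0, 0.3],
         "roiC": [2.2, 2.0, 1.8, 2.4]},
        index=ids)
    confounds = pd.DataFrame(
        {"age": [20.0, 30.0, 25.0, 40.0], "sex": [0.0, 1.0, 0.0, 1.0],
         "handedness": [1.0, 1.0, -1.0, 1.0]},
        index=ids)
    groups = pd.Series(["TR", "TR", "DR", "TR"], index=ids, name="group")
    return StudyDataset(behavior=behavior, brain=brain, confounds=confounds,
                        groups=groups,
                        directions={"acc": "higher_is_better",
                                    "rt": "lower_is_better"})


def write_tables(ds: StudyDataset, directory):
    """Write a StudyDataset in the pipeline's three-table TSV layout."""
    directory.mkdir(parents=True, exist_ok=True)
    ds.behavior.to_csv(directory / "behavior.tsv", sep="\t")
    ds.brain.to_csv(directory / "brain.tsv", sep="\t")
    conf = ds.confounds.copy()
    conf["group"] = ds.groups
    conf.to_csv(directory / "confounds.tsv", sep="\t")
    meta = pd.DataFrame({"measure": list(ds.directions),
                         "direction": list(ds.directions.values())})
    meta.to_csv(directory / "measures.tsv", sep="\t", index=False)
    return {
        "behavior": directory / "behavior.tsv",
        "brain": directory / "brain.tsv",
        "confounds": directory / "confounds.tsv",
        "measures": directory / "measures.tsv",
    }
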