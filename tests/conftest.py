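import numpy as np
import pytest

from taskhard.featurizers import EmbeddedDataset

# 20 real drug-like molecules for exercising the descriptor/scaffold paths
REAL_SMILES = [
    "CCO",                                  # ethanol
    "CC(=O)Oc1ccccc1C(=O)O",                # aspirin
    "CC(=O)Nc1ccc(O)cc1",                   # paracetamol
    "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",         # caffeine
    "c1ccccc1",                             # benzene
    "Cc1ccccc1",                            # toluene
    "OCC(O)CO",                             # glycerol
    "NCCc1ccc(O)c(O)c1",                    # dopamine
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",           # ibuprofen
    "Clc1ccccc1",                           # chlorobenzene
    "OC(=O)c1ccccc1O",                      # salicylic acid
    "CCN(CC)CC",                            # triethylamine
    "CC(N)C(=O)O",                          # alanine
    "c1ccc2ccccc2c1",                       # naphthalene
    "CC(C)(C)c1ccc(O)cc1",                  # 4-tert-butylphenol
    "O=C(O)CCCCC(=O)O",                     # adipic acid
    "CN(C)CCOC(c1ccccc1)c1ccccc1",          # diphenhydramine
    "OCCO",                                 # ethylene glycol
    "CSCCC(N)C(=O)O",                       # methionine
    "Nc1ccc(cc1)S(=O)(=O)N",                # sulfanilamide
]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(rng, task_id="task", n=40, d=4, shift=0.0, featurizer="synthetic"):
    """Two-class Gaussian dataset: class means at +/- 1.5 along dim 0, plus shift."""
    n0 = n // 2
    x0 = rng.normal(0.0, 1.0, size=(n0, d)) + np.eye(d)[0] * -1.5
    x1 = rng.normal(0.0, 1.0, size=(n - n0, d)) + np.eye(d)[0] * 1.5
    x = np.vstack([x0, x1]) + shift
    y = np.concatenate([np.zeros(n0, dtype=int), np.ones(n - n0, dtype=int)])
    perm = rng.permutation(n)
    return EmbeddedDataset(task_id, x[perm], y[perm], featurizer)


@pytest.fixture
def separable_dataset(rng):
    """Well-separated two-cluster task (n=200): nearly perfectly learnable."""
    n, d = 200, 4
    x0 = rng.normal(0.0, 0.5, size=(n // 2, d)) - 3.0
    x1 = rng.normal(0.0, 0.5, size=(n // 2, d)) + 3.0
    x = np.vstack([x0, x1])
    y = np.concatenate([np.zeros(n // 2, dtype=int), np.ones(n // 2, dtype=int)])
    perm = rng.permutation(n)
    return EmbeddedDataset("separable", x[perm], y[perm], "synthetic")


@pytest.fixture
def permuted_dataset(separable_dataset):
    """Same features, labels randomly permuted: chance-level task."""
    rng = np.random.default_rng(999)
    return EmbeddedDataset(
        "permuted",
        separable_dataset.features,
        rng.permutation(separable_dataset.labels),
        "synthetic",
    )


def write_task_dir(root, task_id, smiles, labels, proteins=()):
    """Create a task directory in the on-disk layout."""
    import pandas as pd

    path = root / task_id
    path.mkdir(parents=True)
    pd.DataFrame({"smiles": smiles, "label": labels}).to_csv(path / "molecules.csv", index=False)
    if proteins:
        with open(path / "protein.fasta", "w") as fh:
            for i, seq in enumerate(proteins):
                fh.write(f">P{i}\n{seq}\n")
    return path
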