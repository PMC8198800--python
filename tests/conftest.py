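"""Shared fixtures: small synthetic libraries and a small trained ensemble.

Everything is generated programmatically; the heavier trained-ensemble
fixture is session-scoped so model and attribution tests share one fit.
"""

from __future__ import annotations

import numpy as np
import pytest

from lnqspr.data import SplitSpec
from lnqspr.fingerprints import FingerprintSpec, fingerprint_dataset
from lnqspr.model import NetConfig, StabilityModel
from lnqspr.synthetic import SyntheticSpec, generate

#: A deliberately tiny ligand vocabulary: short chains, one small
#: substituent at most, so molecules differ from any background vector
#: at few bits and exact Shapley enumeration stays cheap.
TINY_SPEC = SyntheticSpec(
    n_molecules=24,
    scaffold_grammar={
        "hydroxyl": "O",
        "chloro": "Cl",
        "amino": "N",
        "nitrile": "C#N",
    },
    planted_weights={"hydroxyl": 0.8, "chloro": -1.4, "amino": 0.6},
    chain_lengths=(2, 3, 4),
    count_probs=(0.1, 0.5, 0.4),
    seed=11,
)

TINY_NET = NetConfig(n_layers=1, n_nodes=64, max_epochs=80, patience=10, seed=11)
TINY_SPLIT = SplitSpec(n_folds=4, n_strata_bins=5, seed=11)


@pytest.fixture(scope="session")
def tiny_library():
    ds = generate(TINY_SPEC)
    fp = fingerprint_dataset(ds.smiles, FingerprintSpec())
    return ds, fp


@pytest.fixture(scope="session")
def tiny_fit(tiny_library):
    """A small but genuinely trained CV ensemble on the tiny library."""
    ds, fp = tiny_library
    y = np.array([r.logk for r in ds.records])
    model = StabilityModel(y, fp.X.astype(float), split_spec=TINY_SPLIT)
    res = model.fit(TINY_NET)
    return ds, fp, model, res


@pytest.fixture(scope="session")
def default_library():
    """The reference 200-molecule library (no training attached)."""
    ds = generate(SyntheticSpec(seed=1))
    fp = fingerprint_dataset(ds.smiles, FingerprintSpec())
    return ds, fp
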