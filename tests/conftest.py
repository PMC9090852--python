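from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import triadbalance as tb


@pytest.fixture(scope="session")
def table2_registry() -> tb.TriadRegistry:
    """The packaged wheat Rubiscosome registry (70 loci, 11 genes)."""
    return tb.load_packaged_registry()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20220127)


def make_matrix(records, meta=None, **kwargs) -> tb.ExpressionMatrix:
    """Build an ExpressionMatrix from (locus, sample, tpm) tuples.

    Metadata defaults to study='s1', tissue='leaf', condition='control' for
    every sample mentioned in the records.
    """
    values = pd.DataFrame(records, columns=["locus_id", "sample_id", "tpm"])
    if meta is None:
        samples = sorted(set(values["sample_id"]))
        meta = pd.DataFrame(
            {
                "sample_id": samples,
                "study": "s1",
                "tissue": "leaf",
                "condition": "control",
            }
        ).set_index("sample_id")
    return tb.ExpressionMatrix(values=values, samples=meta, **kwargs)


@pytest.fixture()
def mixed_category_spec() -> tb.SimulationSpec:
    """One gene per balance archetype, noise-free: a known 7-category truth set."""
    centroids = {
        "GeneBal": (1 / 3, 1 / 3, 1 / 3),
        "GeneAdom": (1.0, 0.0, 0.0),
        "GeneBdom": (0.0, 1.0, 0.0),
        "GeneDdom": (0.0, 0.0, 1.0),
        "GeneAsup": (0.0, 0.5, 0.5),
        "GeneBsup": (0.5, 0.0, 0.5),
        "GeneDsup": (0.5, 0.5, 0.0),
    }
    genes = tuple(
        tb.GeneSpec(name, true_fractions=frac, base_total_tpm=60.0)
        for name, frac in centroids.items()
    )
    return tb.SimulationSpec(genes=genes, n_samples=4, noise_cv=0.0, seed=11)
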