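import numpy as np
import pandas as pd
import pytest

from secretonet import synthetic

pytest_plugins: list[str] = []


@pytest.fixture(scope="session")
def small_config() -> synthetic.SyntheticConfig:
    """A reduced study: fast to generate, still separable."""
    return synthetic.SyntheticConfig(
        seed=11,
        n_cm_proteins=20,
        n_control_proteins=6,
        n_shared_proteins=6,
        n_background_edges=30,
        n_psms=1200,
        n_events=4000,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config) -> synthetic.SyntheticBundle:
    return synthetic.generate_all(small_config)


@pytest.fixture()
def toy_psms() -> pd.DataFrame:
    """Six PSMs: targets score 10, 9, 8; decoys 7, 3, 2."""
    return pd.DataFrame(
        {
            "peptide": ["AAAK", "CCCK", "DDDK", "EEEK", "FFFK", "GGGK"],
            "protein_id": ["p1", "p1", "p2", "d1", "d2", "d3"],
            "score": [10.0, 9.0, 8.0, 7.0, 3.0, 2.0],
            "is_decoy": [False, False, False, True, True, True],
            "medium": ["cm"] * 6,
        }
    )


def random_psm_table(rng: np.random.Generator, n_rows: int) -> pd.DataFrame:
    """Random PSM tables for oracle-equivalence checks (<= 200 rows)."""
    n_proteins = int(rng.integers(2, 12))
    is_decoy = rng.random(n_rows) < rng.uniform(0.2, 0.5)
    proteins = np.where(
        is_decoy,
        [f"d{i}" for i in rng.integers(0, n_proteins, n_rows)],
        [f"p{i}" for i in rng.integers(0, n_proteins, n_rows)],
    )
    scores = np.round(
        np.where(is_decoy, rng.normal(4, 2.5, n_rows), rng.normal(8, 2.5, n_rows)), 2
    )
    # small peptide alphabet so shared/duplicated peptides occur
    peptides = [f"PEP{i}K" for i in rng.integers(0, max(3, n_rows // 3), n_rows)]
    return pd.DataFrame(
        {
            "peptide": peptides,
            "protein_id": proteins,
            "score": scores,
            "is_decoy": is_decoy,
            "medium": "cm",
        }
    )
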