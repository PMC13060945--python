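import numpy as np
import pandas as pd
import pytest

from repelscreen.synthetic_data import SyntheticConfig, make_dataset, noise_sd_for_r2


@pytest.fixture(scope="session")
def small_planted():
    """120 chemicals, 30 features, 4 planted with latent R² = 0.9."""
    eff = np.full(4, 2.0)
    config = SyntheticConfig(
        n_chemicals=120,
        n_features=30,
        n_informative=4,
        effect_sizes=eff,
        nuisance_correlation=0.3,
        noise_sd=noise_sd_for_r2(eff, 0.9),
        seed=42,
    )
    return make_dataset(config, binary_top_fraction=0.4)


@pytest.fixture()
def chemicals_csv(tmp_path):
    path = tmp_path / "chems.csv"
    pd.DataFrame(
        {
            "chem_id": ["deet", "picaridin", "linalool"],
            "smiles": ["CCN(CC)C(=O)c1cccc(C)c1", "CCC", "CC(C)=CCCC(C)(O)C=C"],
            "name": ["DEET", "picaridin-like", "linalool"],
            "cas": ["134-62-3", "119515-38-7", "78-70-6"],
        }
    ).to_csv(path, index=False)
    return path
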