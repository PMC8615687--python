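import numpy as np
import pandas as pd
import pytest

from mrmlipid import NormalizedProfile, default_panel, parse_species


@pytest.fixture(scope="session")
def panel():
    return default_panel()


def make_profile(values: dict[str, list[float]],
                 sample_groups: dict[str, str]) -> NormalizedProfile:
    """Build a NormalizedProfile from {species name: per-sample values}."""
    samples = list(sample_groups)
    df = pd.DataFrame(values, index=samples).T.astype(float)
    counts = pd.DataFrame(3, index=df.index, columns=df.columns)
    classes = {name: parse_species(name).lipid_class for name in df.index}
    return NormalizedProfile(df, dict(sample_groups), counts, classes)


@pytest.fixture
def two_group_samples():
    """Five control + five treated sample labels."""
    groups = {f"ctrl_{i}": "control" for i in range(1, 6)}
    groups.update({f"def_{i}": "deficient" for i in range(1, 6)})
    return groups


@pytest.fixture
def small_profile(two_group_samples):
    """Three PC aa species and a carnitine trio over ten samples."""
    rng = np.random.default_rng(7)
    names = ["PC aa C34:1", "PC aa C36:2", "PC aa C38:0",
             "C2", "C16:0", "C18:0"]
    values = {n: (1.0 + 0.05 * rng.standard_normal(10)).tolist()
              for n in names}
    return make_profile(values, two_group_samples)
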