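import numpy as np
import pandas as pd
import pytest

from ilpc.fixtures import FixtureSpec, generate_reference_set
from ilpc.pipeline import build_reference_model


@pytest.fixture(scope="session")
def reference_set():
    """Synthetic 60-IL reference set, seed-fixed."""
    return generate_reference_set(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def bundle(reference_set):
    records, properties, _ = reference_set
    return build_reference_model(records, properties)


@pytest.fixture(scope="session")
def truth_frame(reference_set, bundle):
    """Per-IL generator truth joined with fitted scores and cluster labels."""
    _, _, truth = reference_set
    df = pd.DataFrame(truth["ils"]).set_index("il_id")
    scores = bundle.chemspace.training_scores
    df = df.loc[list(bundle.chemspace.il_ids)]
    df["PC1"] = scores[:, 0]
    df["PC2"] = scores[:, 1]
    df["cluster"] = list(bundle.clusters.labels)
    return df


@pytest.fixture(scope="session")
def property_frame(reference_set):
    _, properties, _ = reference_set
    return pd.DataFrame([{"il_id": p.il_id, "property": p.property,
                          "value": p.value} for p in properties])
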