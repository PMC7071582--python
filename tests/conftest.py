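import numpy as np
import pandas as pd
import pytest

from dtscore.features import FeatureMatrix
from dtscore.pipeline import RunConfig
from dtscore.synthetic import ScenarioConfig, generate_scenario


GMT_CATEGORIES = ("biological_process", "molecular_function", "signaling_pathway")


def run_config_for(paths: dict, outdir, **overrides) -> RunConfig:
    defaults = dict(
        features=str(paths["features"]),
        features_meta=str(paths["features_meta"]),
        expression=[str(paths["expression_1"]), str(paths["expression_2"])],
        edges=str(paths["edges"]),
        gmt=[str(paths[f"gmt_{c}"]) for c in GMT_CATEGORIES],
        catalog=str(paths["catalog"]),
        outdir=str(outdir),
        indication="oncology",
    )
    defaults.update(overrides)
    return RunConfig(**defaults)


@pytest.fixture(scope="session")
def small_scenario(tmp_path_factory):
    """A reduced default scenario for fast end-to-end tests."""
    cfg = ScenarioConfig(
        n_proteins=120,
        n_positives=12,
        n_clinical=8,
        n_ontology_sets=8,
        seed=11,
    )
    outdir = tmp_path_factory.mktemp("small_scenario")
    paths = generate_scenario(cfg, outdir)
    return cfg, paths


@pytest.fixture()
def toy_fm():
    """6 proteins x 3 scaled continuous features; first feature separates p1-p3."""
    rng = np.random.default_rng(5)
    data = pd.DataFrame(
        {
            "sep": [0.9, 0.95, 1.0, 0.05, 0.1, 0.0],
            "noise_a": rng.random(6),
            "noise_b": rng.random(6),
        },
        index=pd.Index([f"p{i}" for i in range(1, 7)], name="protein_id"),
    )
    return FeatureMatrix(data=data)


@pytest.fixture()
def separable_fm():
    """20 proteins where one feature equals the class label exactly."""
    rng = np.random.default_rng(9)
    n = 20
    labels = np.array([1] * 8 + [0] * 12)
    data = pd.DataFrame(
        {
            "oracle": labels.astype(float),
            "junk1": rng.random(n),
            "junk2": rng.random(n),
        },
        index=pd.Index([f"q{i:02d}" for i in range(n)], name="protein_id"),
    )
    fm = FeatureMatrix(data=data)
    positives = frozenset(data.index[labels == 1])
    background = frozenset(data.index[labels == 0])
    return fm, positives, background
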