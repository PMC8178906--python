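import pandas as pd
import pytest
from hypothesis import settings

from snofam.pipeline import run_pipeline
from snofam.synthetic import SyntheticConfig, simulate

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """Default synthetic cohort (seed 42): 200 C/D + 100 H/ACA families."""
    out = tmp_path_factory.mktemp("sim42")
    return simulate(SyntheticConfig(seed=42), out)


@pytest.fixture(scope="session")
def default_result(default_bundle, tmp_path_factory):
    """Full pipeline run over the default synthetic cohort."""
    p = default_bundle.paths
    return run_pipeline(
        p["annotation"], p["abundance"], p["samples"], gtf=p["gtf"],
        conservation=p["conservation"], snps=p["snps"],
        out_dir=tmp_path_factory.mktemp("out42"))


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A fast small cohort for end-to-end tests that re-run the pipeline."""
    cfg = SyntheticConfig(
        seed=7, n_families={"CD": 25, "HACA": 15},
        n_switch_families={"CD": 3, "HACA": 2},
        n_identical_pairs={"CD": 1, "HACA": 1})
    return simulate(cfg, tmp_path_factory.mktemp("sim_small"))


@pytest.fixture()
def toy_panel():
    from snofam.core_io import SamplePanel
    return SamplePanel.from_pairs([
        ("brain_1", "brain"), ("brain_2", "brain"),
        ("liver_1", "liver"), ("liver_2", "liver"),
    ])


@pytest.fixture()
def toy_matrix(toy_panel):
    return pd.DataFrame(
        {"brain_1": [2.0, 0.0], "brain_2": [4.0, 0.2],
         "liver_1": [1.0, 0.4], "liver_2": [3.0, 0.0]},
        index=pd.Index(["snoA", "snoB"], name="snorna_id"))
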