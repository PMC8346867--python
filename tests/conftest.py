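import json
import os

import pandas as pd
import pytest

from p53sig.pipeline import run_all
from p53sig.simulate import SimConfig, make_mini_fixture, simulate_dataset

ACCEPTANCE_SEED = 20250101


@pytest.fixture(scope="session")
def mini_bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("mini_bundle")
    bundle, truth = make_mini_fixture(str(outdir), seed=11)
    return bundle, truth


@pytest.fixture(scope="session")
def mini_results(mini_bundle, tmp_path_factory):
    bundle, truth = mini_bundle
    outdir = tmp_path_factory.mktemp("mini_out")
    summary = run_all(bundle.outdir, str(outdir))
    return bundle, truth, str(outdir), summary


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full default synthetic bundle + pipeline at the fixed study seed."""
    indir = tmp_path_factory.mktemp("default_bundle")
    outdir = tmp_path_factory.mktemp("default_out")
    bundle, truth = simulate_dataset(SimConfig(seed=ACCEPTANCE_SEED), str(indir))
    summary = run_all(str(indir), str(outdir))
    return bundle, truth, str(outdir), summary


@pytest.fixture(scope="session")
def default_calls(default_run):
    _, _, outdir, _ = default_run
    return pd.read_csv(os.path.join(outdir, "signature_calls.tsv"), sep="\t")


def load_summary(outdir):
    with open(os.path.join(outdir, "summary.json")) as fh:
        return json.load(fh)
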