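import json
from pathlib import Path

import pandas as pd
import pytest

from lncse.pipeline import RunConfig, run_all
from lncse.simulate import SimulationConfig, generate_all


@pytest.fixture(scope="session")
def bundle(tmp_path_factory) -> dict:
    """Default synthetic input bundle plus its ground truth."""
    out = tmp_path_factory.mktemp("bundle")
    truth = generate_all(SimulationConfig(seed=11), out)
    return {"dir": out, "truth": truth}


@pytest.fixture(scope="session")
def pipeline_run(bundle, tmp_path_factory) -> dict:
    """One full pipeline run over the session bundle (shared by many tests)."""
    out = tmp_path_factory.mktemp("run")
    cfg = RunConfig.from_bundle(bundle["dir"], out, seed=3, n_iter=200, n_sets=2000)
    report = run_all(cfg)
    return {"bundle_dir": bundle["dir"], "truth": bundle["truth"],
            "dir": Path(out), "report": report, "cfg": cfg}


@pytest.fixture(scope="session")
def classified_ses(pipeline_run) -> pd.DataFrame:
    df = pd.read_csv(pipeline_run["dir"] / "classified_ses.tsv", sep="\t")
    from helpers import match_planted_se

    df["key"] = match_planted_se(df, pipeline_run["truth"]["se_atlas"]["planted_ses"])
    return df


@pytest.fixture(scope="session")
def ground_truth_file(bundle) -> dict:
    with open(Path(bundle["dir"]) / "ground_truth.json") as fh:
        return json.load(fh)
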