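import pandas as pd
import pytest

from npbudget.cli_pipeline import RunConfig, run_pipeline
from npbudget.synthetic_data import WorldSpec, generate_world


@pytest.fixture(scope="session")
def small_world(tmp_path_factory):
    """A small lossless synthetic world plus its pipeline run results."""
    d = tmp_path_factory.mktemp("world")
    spec = WorldSpec(seed=5)
    bundle, gt_terms, gt_ind = generate_world(spec, d / "bundle")
    out = run_pipeline(RunConfig(bundle=str(bundle), out_dir=str(d / "out")))
    return {"spec": spec, "bundle": bundle, "gt_terms": gt_terms,
            "gt_indicators": gt_ind, "result": out, "dir": d}


def rel_diff(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Largest elementwise relative difference (floor 1e-12 on magnitude)."""
    return float(((a - b).abs() / b.abs().clip(lower=1e-12)).max().max())
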