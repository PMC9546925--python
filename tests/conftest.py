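import numpy as np
import pandas as pd
import pytest

import netmedsig as nm


@pytest.fixture(scope="session")
def bundle():
    """Shared synthetic study bundle with planted ground truth."""
    return nm.paper_small_bundle(seed=7)


@pytest.fixture(scope="session")
def corrected_expression(bundle):
    return nm.batch_correct(bundle.expression)


@pytest.fixture(scope="session")
def swim_results(corrected_expression):
    """(deg_table, cartography, correlation network) on the bundle."""
    return nm.swim_analysis(corrected_expression, seed=0)


@pytest.fixture(scope="session")
def pipeline_run(bundle, tmp_path_factory):
    """One full pipeline execution on the written bundle."""
    root = tmp_path_factory.mktemp("pipeline")
    paths = bundle.write(root / "inputs")
    config = nm.PipelineConfig(
        network=str(paths["network"]), seeds=str(paths["seeds"]),
        expression=str(paths["expression"]), metadata=str(paths["metadata"]),
        gene_sets=str(paths["gene_sets"]), outdir=str(root / "out"),
        iterations=120, n_randomizations=1000, master_seed=0)
    result = nm.run_pipeline(config)
    return config, result


@pytest.fixture
def tiny_expr():
    """6 genes x 8 samples, two groups, single batch, fixed values."""
    rng = np.random.default_rng(11)
    values = pd.DataFrame(rng.normal(7, 1, (6, 8)),
                          index=[f"g{i}" for i in range(6)],
                          columns=[f"s{i}" for i in range(8)])
    group = pd.Series(["case"] * 4 + ["control"] * 4, index=values.columns)
    return nm.ExpressionMatrix(values=values, group=group)
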