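import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from megapath.formats_io import CASE, CONTROL, ExpressionStudy

# property tests must behave identically on every run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_study(
    values_by_gene: dict[str, list[float]],
    n_control: int,
    study_id: str = "S1",
    country: str = "USA",
    study_age: int = 5,
) -> ExpressionStudy:
    """Build a study from gene -> value-list with the first n_control
    samples labelled control."""
    genes = list(values_by_gene)
    total = len(next(iter(values_by_gene.values())))
    samples = [f"{study_id}_s{i}" for i in range(total)]
    matrix = pd.DataFrame(
        [values_by_gene[g] for g in genes], index=genes, columns=samples, dtype=float
    )
    groups = pd.Series(
        [CONTROL] * n_control + [CASE] * (total - n_control), index=samples
    )
    return ExpressionStudy(
        study_id=study_id, matrix=matrix, sample_groups=groups,
        country=country, study_age=study_age,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def bundle_run(tmp_path_factory):
    """One synthetic bundle plus a full pipeline run, shared across tests."""
    from megapath.pipeline import bundle_config, run_pipeline, write_bundle

    root = tmp_path_factory.mktemp("bundle_run")
    bundle = write_bundle(root / "bundle", seed=11)
    report = run_pipeline(bundle_config(bundle, root / "out", seed=11))
    return bundle, report
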