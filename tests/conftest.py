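import numpy as np
import pandas as pd
import pytest

from nigranet.preprocess import ExpressionStudy


def make_study(
    matrix: np.ndarray,
    groups: list[str],
    study_id: str = "S1",
    probe_map: pd.Series | None = None,
    covariates: dict | None = None,
    log_scale: bool = True,
) -> ExpressionStudy:
    """Small hand-built cohort for unit tests."""
    n_probes, n_samples = matrix.shape
    probes = [f"p{i}" for i in range(n_probes)]
    samples = [f"{study_id}_s{j}" for j in range(n_samples)]
    if probe_map is None:
        probe_map = pd.Series([f"g{i}" for i in range(n_probes)], index=probes)
    meta = pd.DataFrame({"group": groups}, index=samples)
    for name, vals in (covariates or {}).items():
        meta[name] = vals
    return ExpressionStudy(
        exprs=pd.DataFrame(matrix, index=probes, columns=samples),
        sample_meta=meta,
        probe_map=probe_map,
        study_id=study_id,
        log_scale=log_scale,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
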