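import pandas as pd
import pytest

from mirpair import (
    ExpressionMatrix,
    RunConfig,
    StudyDesign,
    SyntheticConfig,
    generate_study,
    run_pipeline,
)
from mirpair.pipeline import config_for_study


@pytest.fixture(scope="session")
def design() -> StudyDesign:
    return StudyDesign()


@pytest.fixture
def small_matrix(design) -> ExpressionMatrix:
    """3 transcripts x 18 samples with simple integer intensities."""
    rows = {
        "t1": [float(10 + i) for i in range(18)],
        "t2": [50.0] * 18,
        "t3": [float(2 * (i + 1)) for i in range(18)],
    }
    values = pd.DataFrame.from_dict(rows, orient="index", columns=design.samples)
    return ExpressionMatrix(values=values, channel="mrna")


@pytest.fixture(scope="session")
def noiseless_study():
    """Small noiseless study used by several module tests."""
    return generate_study(
        SyntheticConfig(
            seed=11,
            noise_sd=0.0,
            n_repressor_pairs=6,
            n_weak_pairs=2,
            n_cotranscribed_pairs=3,
            n_null_mrnas=20,
            n_null_mirnas=6,
        )
    )


def run_study_pipeline(study, workdir, **overrides) -> tuple[dict, RunConfig]:
    """Write a study to disk and run the full pipeline on it."""
    paths = study.write(workdir / "study")
    cfg = config_for_study(
        paths, outdir=workdir / "run", seed=study.config.seed, **overrides
    )
    manifest = run_pipeline(cfg)
    return manifest, cfg
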