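import pytest
from hypothesis import HealthCheck, settings

from metaboloss import cohort_prep, metabolite_qc
from metaboloss.synthetic_cohort import (
    Confounder,
    SyntheticConfig,
    generate_cohort,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_config():
    """A small cohort with one planted effect, one confounder, a platform
    duplicate, one low-detection feature and one high-CV feature."""
    return SyntheticConfig(
        n_participants=800,
        n_features=30,
        planted_effects=((0, "unintentional_loss", 0.6),),
        confounders=(
            Confounder(
                "conf",
                features=(1,),
                loading=0.8,
                gamma={"unintentional_loss": 0.4},
            ),
        ),
        duplicate_spec=((2, "polar-pos", 0.01),),
        lod_overrides={3: 0.15},
        qc_cv_overrides={4: 0.20},
    )


@pytest.fixture(scope="session")
def demo_tables(demo_config):
    return generate_cohort(demo_config, seed=5)


@pytest.fixture(scope="session")
def demo_cohort(demo_tables):
    participants, matrix, qc_reps, truth = demo_tables
    cohort, tally = cohort_prep.prepare_cohort(participants)
    processed, qc = metabolite_qc.process_metabolites(
        matrix.loc[cohort.index], matrix.attrs["feature_meta"], qc_reps
    )
    return {
        "cohort": cohort,
        "tally": tally,
        "processed": processed,
        "qc": qc,
        "truth": truth,
    }
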