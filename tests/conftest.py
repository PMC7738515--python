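import numpy as np
import pandas as pd
import pytest

from crossrppa.integration import annotate_panels, integrate
from crossrppa.processing import process_platform
from crossrppa.synthetic import (
    DEFAULT_SYNONYMS,
    StudyDesign,
    default_antigen_config,
    default_platforms,
    simulate_study,
)


def process_study(study, method="dilution_fit"):
    """Process every platform of a synthetic study with one method."""
    mats = []
    for p in study.platforms:
        render = study.renders[p.platform_id]
        mats.append(
            process_platform(
                render.spots,
                p.platform_id,
                method=method,
                total_protein=render.total_protein,
                detection_floor=p.detection_floor,
            )
        )
    return mats


def integrate_study(study, subset=None, method="dilution_fit"):
    """Process and integrate a study, optionally restricted to a sample subset."""
    import dataclasses

    mats = process_study(study, method=method)
    if subset is not None:
        mats = [
            dataclasses.replace(m, values=m.values.loc[subset], qc=m.qc.loc[subset])
            for m in mats
        ]
    ann = annotate_panels(study.raw_annotations, DEFAULT_SYNONYMS)
    return integrate(mats, ann)


def control_design() -> StudyDesign:
    """Vehicle-only design (6 cell lines x DMSO x 20 min x 3 replicates)."""
    from crossrppa.synthetic import default_design

    base = default_design()
    return StudyDesign(
        cell_lines=base.cell_lines,
        treatments=["DMSO"],
        timepoints_min=[20],
        n_replicates=base.n_replicates,
    )


@pytest.fixture(scope="session")
def study_moderate():
    """Default full study (108 samples, three platforms, moderate noise)."""
    return simulate_study(11)


@pytest.fixture(scope="session")
def integrated_all(study_moderate):
    return integrate_study(study_moderate)


@pytest.fixture(scope="session")
def integrated_control(study_moderate):
    ctrl = study_moderate.sample_table.query(
        "treatment == 'DMSO' and timepoint_min == 20"
    ).index
    return integrate_study(study_moderate, subset=list(ctrl))


@pytest.fixture(scope="session")
def study_noise_free():
    """Full study with zero noise everywhere and unit gain."""
    return simulate_study(
        11,
        antigen_config=default_antigen_config(replicate_sd=0.0),
        platforms=default_platforms(noise_free=True),
    )


@pytest.fixture(scope="session")
def integrated_noise_free(study_noise_free):
    return integrate_study(study_noise_free)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
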