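"""Shared fixtures: one small synthetic study, curated and featurized once."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from casel import curation, descriptors, synth

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_study() -> synth.SyntheticStudy:
    """A 300-compound synthetic study at the default noise conditions."""
    return synth.generate_study(synth.SyntheticStudyConfig(n_compounds=300, seed=11))


@pytest.fixture(scope="session")
def small_export(small_study, tmp_path_factory) -> str:
    outdir = tmp_path_factory.mktemp("study")
    return str(small_study.write(outdir)["export"])


@pytest.fixture(scope="session")
def curated_small(small_export) -> pd.DataFrame:
    frame, _ = curation.curate(small_export)
    return frame


@pytest.fixture(scope="session")
def features_small(curated_small) -> pd.DataFrame:
    """Retained-descriptor matrix (PCC = 0.95) for the small study."""
    unique = curated_small.drop_duplicates("compound_id")
    table = descriptors.compute_descriptors(
        list(zip(unique.compound_id, unique.smiles))
    )
    table = descriptors.drop_failed_compounds(table)
    return descriptors.filter_correlated(table, 0.95).to_frame(retained_only=True)


@pytest.fixture(scope="session")
def activities_ii(curated_small) -> dict:
    sub = curated_small[curated_small.isoform == "hCA_II"]
    return dict(zip(sub.compound_id, sub.activity_nM))


@pytest.fixture(scope="session")
def blobs():
    """Well-separated two-class Gaussian blobs (trivially separable)."""
    rng = np.random.default_rng(0)
    X = np.vstack([
        rng.normal(0.0, 0.5, size=(100, 5)),
        rng.normal(6.0, 0.5, size=(100, 5)),
    ])
    y = np.array([0] * 100 + [1] * 100)
    return X, y
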