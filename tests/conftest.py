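"""Shared fixtures: small montages and cohorts for fast end-to-end tests."""

import logging

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, max_examples=50,
                          derandomize=True)
settings.load_profile("ci")

logging.getLogger("specmdd").setLevel(logging.ERROR)

# Reduced montage covering every scalp region (4 frontal, 3 central,
# 2 temporal, 4 parietal, 2 occipital) for fast simulation studies.
SMALL_MONTAGE = ("FZ", "F3", "F4", "FCZ", "CZ", "C3", "C4", "T7", "T8",
                 "PZ", "P3", "P4", "POZ", "OZ", "O1")

# Even smaller montage for smoke tests: one electrode per region plus spares.
TINY_MONTAGE = ("FZ", "F3", "CZ", "C3", "T7", "PZ", "P3", "OZ")


@pytest.fixture(scope="session")
def feature_cohort():
    """Default-condition cohort without signal synthesis (fast path):
    74 HC / 40 MDD with generative truth, source features and scores."""
    from specmdd.synth import CohortConfig, make_cohort

    cfg = CohortConfig(channel_labels=SMALL_MONTAGE, duration=40.0, seed=11)
    return make_cohort(cfg, signals=False)


@pytest.fixture(scope="session")
def tiny_fitted_run():
    """Tiny but complete run: 10+10 subjects, 8 channels, 30 s -> spectra,
    models and feature table."""
    from specmdd import features as feat
    from specmdd.pipeline import RunConfig, fit_cohort
    from specmdd.synth import CohortConfig, make_cohort

    cfg = CohortConfig(n_hc=10, n_mdd=10, channel_labels=TINY_MONTAGE,
                       duration=30.0, seed=21)
    cohort = make_cohort(cfg)
    run = RunConfig(cohort=cfg, seed=21)
    spectra, models = fit_cohort(cohort, run)
    table = feat.build_feature_table(cohort, models, spectra)
    return cohort, spectra, models, table
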