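"""Shared fixtures: synthetic study, trained coding model, audit fixture."""

import warnings

import numpy as np
import pytest

from lncforge.coding import (
    sequence_features,
    train_hexamer_table,
    train_logistic,
)
from lncforge.pipeline import RunConfig, run_pipeline
from lncforge.simulate import (
    generate_audit_fixture,
    generate_training_corpus,
    simulate_study,
)

STUDY_SEED = 100


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """The full synthetic study on disk at the reference seed."""
    outdir = tmp_path_factory.mktemp("study")
    return simulate_study(str(outdir), seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_run(study, tmp_path_factory):
    """One end-to-end pipeline run over the session study."""
    outdir = tmp_path_factory.mktemp("study_run")
    cfg = RunConfig.from_yaml(study.paths["config"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_pipeline(cfg, str(outdir))
    return report, str(outdir)


@pytest.fixture(scope="session")
def training_corpus():
    return generate_training_corpus(n_coding=200, n_noncoding=200, seed=5)


@pytest.fixture(scope="session")
def coding_model(training_corpus):
    """A hexamer table and logistic model trained on the synthetic corpus."""
    coding, noncoding = training_corpus
    table = train_hexamer_table(coding, noncoding)
    feats = np.array([sequence_features(s, table) for s in coding + noncoding])
    labels = [1] * len(coding) + [0] * len(noncoding)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = train_logistic(feats, labels)
    return model, table


@pytest.fixture(scope="session")
def audit_fixture():
    return generate_audit_fixture(seed=0)
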