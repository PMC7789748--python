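import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import octreport as oc
from octreport.synthetic import CorpusSpec, generate_corpus
from octreport.value_reader import TrainConfig, train

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: Desk-scale training conditions shared by the accuracy tests and the
#: acceptance script (scripts/acceptance.py mirrors these numbers).
DESK_CORPUS_N = 20_000
DESK_ITERATIONS = 11_000


@pytest.fixture(scope="session")
def catalog():
    return oc.default_catalog()


@pytest.fixture(scope="session")
def reference(catalog):
    return oc.ReferenceRecognizer(catalog.charset)


@pytest.fixture(scope="session")
def trained_model(catalog):
    """Desk-scale Value Reader checkpoint (trained once per session)."""
    spec = CorpusSpec(n_total=DESK_CORPUS_N, seed=42, charset=catalog.charset)
    train_set, val_set = generate_corpus(spec)
    cfg = TrainConfig(iterations=DESK_ITERATIONS, seed=1, hidden=48,
                      eval_every=1500, val_subset=150)
    model, curves = train(train_set, val_set, cfg, charset=catalog.charset)
    model.curves = curves
    return model


@pytest.fixture(scope="session")
def finding_model():
    return oc.train_finding_classifier(n_train=240, seed=3, iterations=300)


@pytest.fixture(scope="session")
def report_fixtures(catalog):
    """Ten clean synthetic reports per layout type, fixed seed."""
    return oc.generate_reports(catalog, n_per_type=10, seed=2024)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
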