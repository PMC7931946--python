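import pytest

from otsa import OTSAConfig, QueryItem, SyntheticSpec, generate_query_set, generate_reference_db
from otsa.ensemble import predict_interactions
from otsa.predictors import fit_all


@pytest.fixture(scope="session")
def default_config():
    return OTSAConfig()


@pytest.fixture(scope="session")
def synthetic_db():
    """Default synthetic reference database + ground truth (seed 17)."""
    return generate_reference_db(SyntheticSpec())


@pytest.fixture(scope="session")
def small_db():
    """A smaller, cheaper database for predictor unit tests."""
    spec = SyntheticSpec(
        n_targets=4, chemotypes_per_target=1, actives_per_chemotype=10,
        decoy_count=30, withhold_fraction=0.2,
        planted_cross_activities=[("c0_0", "t2", 0.3)], seed=17,
    )
    return generate_reference_db(spec)


@pytest.fixture(scope="session")
def fitted_small(small_db, default_config):
    db, _ = small_db
    return fit_all(db, default_config, seed=17)


@pytest.fixture(scope="session")
def pipeline_run(synthetic_db, default_config):
    """Full pipeline on the default synthetic conditions, run once per session."""
    db, truth = synthetic_db
    queries, expected = generate_query_set(db, truth)
    ensemble = fit_all(db, default_config, seed=17)
    items = [QueryItem(q, q.mol_id, "parent") for q in queries]
    predictions, no_signal = predict_interactions(ensemble, items, default_config)
    return {
        "db": db,
        "truth": truth,
        "queries": queries,
        "expected": expected,
        "ensemble": ensemble,
        "predictions": predictions,
        "no_signal": no_signal,
    }
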