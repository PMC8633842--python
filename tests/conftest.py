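import pytest
from hypothesis import settings

from kampo_claims import ClaimsBundle, SimParams, StudyConfig, simulate_bundle

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def config():
    return StudyConfig()


@pytest.fixture(scope="session")
def sim300():
    """A default-conditions bundle: 15% ineligible mothers, full dates."""
    params = SimParams(n_mothers=300, seed=11)
    bundle, truth = simulate_bundle(params)
    return params, bundle, truth


@pytest.fixture(scope="session")
def recovery_sim():
    """Noise-free recovery conditions: every mother carries a delivery-week
    GA diagnosis, a selected delivery entry, full dates, and full coverage."""
    params = SimParams(
        n_mothers=2000,
        seed=20210501,
        p_ga_diagnosis_at_delivery=1.0,
        p_selected_delivery_entry=1.0,
        p_ineligible=0.0,
    )
    bundle, truth = simulate_bundle(params)
    return params, bundle, truth


def make_bundle(persons, links=(), diagnoses=(), entries=(), drugs=()) -> ClaimsBundle:
    return ClaimsBundle({p.person_id: p for p in persons}, list(links),
                        list(diagnoses), list(entries), list(drugs))
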