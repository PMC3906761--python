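import pytest
from hypothesis import settings

import pharmaboost as pb
from pharmaboost.corpus_io import DrugLexicon, SideEffectLexicon

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_drug_lexicon() -> DrugLexicon:
    return DrugLexicon(
        frozenset({"cetuximab", "warfarin", "baclofen", "irinotecan", "carboplatin"}),
        {"erbitux": "cetuximab", "coumadin": "warfarin"},
    )


@pytest.fixture(scope="session")
def tiny_se_lexicon() -> SideEffectLexicon:
    terms = frozenset(
        {
            "nausea",
            "decreased activity",
            "myocardial infarction",
            "colorectal cancer",
            "toxicity",
        }
    )
    return SideEffectLexicon(
        terms,
        {
            "myocardial infarction": frozenset({"cardiac disorders"}),
            "colorectal cancer": frozenset({"gastrointestinal disorders"}),
        },
    )


@pytest.fixture(scope="session")
def small_sim() -> pb.SimConfig:
    """A fast, small replica of the reference regime for unit-level checks."""
    return pb.SimConfig(n_drugs=20, n_ses=40, n_reports=400, seed=11)


@pytest.fixture(scope="session")
def small_sim_data(small_sim):
    return pb.simulate(small_sim)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One end-to-end run at the reference study conditions (shared: ~10 s)."""
    data = pb.simulate(pb.SimConfig())
    result = pb.run_on_simulated(data, tmp_path_factory.mktemp("default_run"))
    return data, result
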