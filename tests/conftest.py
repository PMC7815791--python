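import pytest

from psa_mri_sim import config as cfgmod
from psa_mri_sim import outcomes, synthetic


@pytest.fixture(scope="session")
def default_cfg():
    return cfgmod.resolve_config(synthetic.default_config())


@pytest.fixture(scope="session")
def fixture_life_table(default_cfg):
    return default_cfg.life_table


@pytest.fixture(scope="session")
def paired_run_100k(default_cfg):
    """One large paired run shared by the direction/coupling checks."""
    return outcomes.run_paired_simulation(100_000, default_cfg, seed=20210119)


@pytest.fixture(scope="session")
def toy_model():
    return synthetic.analytic_toy_model()


TOY_N = 100_000


@pytest.fixture(scope="session")
def toy_run(toy_model):
    """Monte-Carlo run of the analytic toy at n=1e5, shared by oracle checks."""
    raw, expect = toy_model
    cfg = cfgmod.resolve_config(raw)
    ns, reg, mri, records, summary = outcomes.run_paired_simulation(TOY_N, cfg, seed=17)
    return expect, reg, records, summary
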