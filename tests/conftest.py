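import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from lncgx import enselect
from lncgx.simdata import SimulationConfig, simulate_cell_line_panel


@pytest.fixture(scope="session")
def small_sim():
    """Small panel for unit tests: 60 lines x 100 lncRNAs, 4 agents."""
    cfg = SimulationConfig(
        n_cell_lines=60, n_tumors=120, n_lncRNAs=100, n_pcgs=300,
        n_agents=4, n_cancer_types=3, n_pathways=2, k_true_per_agent=5,
        seed=11,
    )
    expr, panel, labels, truth = simulate_cell_line_panel(cfg)
    return cfg, expr, panel, labels, truth


@pytest.fixture(scope="session")
def study_panel():
    """The study-scale recovery panel: 100 cell lines x 500 lncRNAs,
    10 planted lncRNAs per agent, effect 0.8, noise 0.5."""
    cfg = SimulationConfig(seed=1)
    expr, panel, labels, truth = simulate_cell_line_panel(cfg)
    return cfg, expr, panel, labels, truth


@pytest.fixture(scope="session")
def study_selection(study_panel):
    """Tuned + bootstrapped (B=200) selection for one agent of the study panel."""
    cfg, expr, panel, labels, truth = study_panel
    agent = "DRUG000"
    y = panel.ln_ic50[agent]
    alpha, lam = enselect.tune_hyperparams(expr, y, seed=1)
    bs, ps = enselect.bootstrap_ps(
        expr.data, y, alpha, lam, B=200, seed=2, agent_id=agent
    )
    return {"agent": agent, "alpha": alpha, "lam": lam, "bootstrap": bs, "ps": ps}
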