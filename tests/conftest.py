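import pytest
from hypothesis import HealthCheck, settings

from genescape import fixtures, funnel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_fixture():
    return fixtures.make_reference_fixture()


@pytest.fixture(scope="session")
def funnel_run(reference_fixture):
    """Full funnel over the reference fixture: colors and all stage lists."""
    fx = reference_fixture
    table = fx.evidence_table
    core0 = funnel.provisional_core(table, fx.de_genes)
    counts = funnel.count_core_partners(fx.interaction_edges, core0)
    colors = funnel.assign_colors(
        table, fx.de_genes, counts, k_min=5, grey_genes=fx.grey_genes
    )
    candidates = funnel.build_candidate_list(colors)
    final = funnel.finalize_landscape(candidates, fx.interaction_edges)
    return final
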