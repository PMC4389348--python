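import numpy as np
import pytest

from condact import lambda_switch as lam
from condact.ca_analytic import analytic_ca_matrix
from condact.kinetics import build_rate_matrix, stationarity_check
from condact.model_core import enumerate_microstates
from condact.thermo import (
    Condition,
    equilibrium,
    mutual_information,
    site_entropy,
    site_marginal,
)


@pytest.fixture(scope="module")
def synthetic_system():
    params = lam.synthetic_parameters()
    spec = lam.build_lambda_model(params)
    ms = enumerate_microstates(spec)
    cond = Condition(310.0, {"CI2": 1e-7, "Cro2": 1e-9, "RNAP": 1e-7})
    dist = equilibrium(spec, ms, cond)
    return params, spec, ms, cond, dist


def test_full_model_has_1200_microstates(synthetic_system):
    _, spec, ms, _, _ = synthetic_system
    assert len(ms) == 1200


def test_right_operator_submodel_has_40_states():
    sub = lam.right_operator_submodel()
    assert len(enumerate_microstates(sub)) == 40


def test_factorization_right_times_left():
    """No exclusion crosses the operators: 40 x 30 = 1200."""
    spec = lam.build_lambda_model(lam.zero_parameters())
    left_sites = set(lam.LEFT_SITES)
    right_assignments = set()
    left_assignments = set()
    for ms in enumerate_microstates(spec):
        right_assignments.add(
            tuple(ms.assignment[s] for s in lam.RIGHT_SITES)
        )
        left_assignments.add(tuple(ms.assignment[s] for s in left_sites))
    assert len(right_assignments) == 40
    assert len(left_assignments) == 30
    assert 40 * 30 == 1200


def test_without_exclusions_count_is_unconstrained_product():
    spec = lam.build_lambda_model(lam.zero_parameters())
    spec.exclusions = []
    assert len(enumerate_microstates(spec)) == 3**6 * 2**3


def test_incomplete_parameters_listed():
    params = lam.zero_parameters()
    del params.intrinsic_energies[("O_R2", "CI2")]
    with pytest.raises(ValueError, match="O_R2:CI2"):
        lam.build_lambda_model(params)


def test_projection_aggregates_exactly_30_states_each(synthetic_system):
    _, spec, ms, _, dist = synthetic_system
    proj = lam.project_to_right_operator(dist, spec, ms)
    assert len(proj) == 40
    assert sum(proj.values()) == pytest.approx(1.0, abs=1e-12)
    counts = {}
    for m in ms:
        key = tuple(m.assignment[s] for s in lam.RIGHT_SITES)
        counts[key] = counts.get(key, 0) + 1
    assert set(counts.values()) == {30}


def test_uniform_distribution_projects_uniformly():
    spec = lam.build_lambda_model(lam.zero_parameters())
    ms = enumerate_microstates(spec)
    cond = Condition(310.0, {"CI2": 1.0, "Cro2": 1.0, "RNAP": 1.0})
    dist = equilibrium(spec, ms, cond)
    proj = lam.project_to_right_operator(dist, spec, ms)
    assert np.allclose(list(proj.values()), 1.0 / 40)


def test_detailed_balance_on_lambda(synthetic_system):
    _, spec, ms, _, dist = synthetic_system
    rm = build_rate_matrix(spec, ms, dist, 1.0)
    k = dist.probabilities
    lhs = k[rm.edge_i] * rm.rates[rm.edge_i, rm.edge_j]
    rhs = k[rm.edge_j] * rm.rates[rm.edge_j, rm.edge_i]
    assert np.allclose(lhs, rhs, rtol=1e-12, atol=0)
    assert stationarity_check(rm, dist) < 1e-10
    assert rm.is_irreducible()


def test_mi_bounded_by_entropies_on_lambda(synthetic_system):
    _, spec, ms, _, dist = synthetic_system
    ent = {s: site_entropy(site_marginal(dist, spec, ms, s)) for s in spec.site_names}
    for i, a in enumerate(spec.site_names):
        for b in spec.site_names[i + 1:]:
            mi = mutual_information(dist, spec, ms, a, b)
            assert -1e-12 <= mi <= min(ent[a], ent[b]) + 1e-9


def test_placeholder_parameters_are_refused():
    params = lam.load_lambda_parameters()
    assert params.placeholder
    assert params.missing_intrinsic() == []  # schema-complete
    cond = lam.LambdaCondition(
        "lysogenic", Condition(310.0, {"CI2": 1e-7, "Cro2": 1e-9, "RNAP": 1e-7})
    )
    with pytest.raises(lam.PlaceholderParameterError):
        lam.pathway_report(params, cond)


def test_placeholder_condition_files_are_refused():
    with pytest.raises(lam.PlaceholderParameterError):
        lam.load_lambda_condition("lysogenic")
    with pytest.raises(lam.PlaceholderParameterError):
        lam.load_lambda_condition("lytic")


def test_all_zero_placeholder_report_is_noninteracting():
    """Zero energies and unit concentrations: uniform occupancies, and zero
    MI between sites in different steric-overlap clusters.  (Sites within
    one overlap cluster stay correlated even at zero energy, because the
    uniform law lives on the exclusion-constrained state space.)"""
    params = lam.load_lambda_parameters()  # all delta_g -> 0.0, flagged
    cond = lam.LambdaCondition(
        "neutral", Condition(310.0, {"CI2": 1.0, "Cro2": 1.0, "RNAP": 1.0})
    )
    report = lam.pathway_report(params, cond, allow_placeholder=True)
    assert np.allclose(report.dist.probabilities, 1.0 / 1200)
    clusters = [
        {"O_R1", "O_R2", "P_R"},
        {"O_R3", "P_RM"},
        {"O_L1", "O_L2", "P_L"},
        {"O_L3"},
    ]
    names = report.spec.site_names
    cluster_of = {s: k for k, c in enumerate(clusters) for s in c}
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j and cluster_of[a] != cluster_of[b]:
                assert report.mi[i, j] < 1e-9, (a, b)
    # overlapping sites remain anticorrelated by steric exclusion alone
    assert report.mi[names.index("O_R3"), names.index("P_RM")] > 0.01


def test_pathway_report_is_deterministic(synthetic_system):
    params, _, _, cond, _ = synthetic_system
    lcond = lam.LambdaCondition("lysogenic", cond)
    r1 = lam.pathway_report(params, lcond)
    r2 = lam.pathway_report(params, lcond)
    assert np.array_equal(r1.dist.probabilities, r2.dist.probabilities)
    assert r1.top_states == r2.top_states
    for a in r1.ca:
        for b in r1.ca[a]:
            assert r1.ca[a][b] == r2.ca[a][b]


def test_octamer_states_dominate_under_strong_looping(synthetic_system):
    """With CI-favoring concentrations and a looping term, top states carry
    CI dimers at O_R1, O_R2, O_L1, O_L2 (structural sanity check)."""
    params, _, _, _, _ = synthetic_system
    lcond = lam.LambdaCondition(
        "lysogenic-like", Condition(310.0, {"CI2": 1e-7, "Cro2": 1e-10, "RNAP": 1e-8})
    )
    report = lam.pathway_report(params, lcond)
    top = report.top_states[0][1]
    for site in ("O_R1", "O_R2", "O_L1", "O_L2"):
        assert top[site] == "CI2"
    assert report.ca_failures == {}
    assert 0.0 <= report.p_rnap_pr <= 1.0
    assert 0.0 <= report.p_rnap_prm <= 1.0
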