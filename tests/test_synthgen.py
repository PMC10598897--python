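"""Synthetic generator: determinism, degenerate settings, ground-truth
recovery through the pipeline, and calibration of the defaults."""

import numpy as np
import pytest

from orgties.netbuild import build_contact_network
from orgties.stability_qap import jaccard
from orgties.synthgen import (
    SynthConfig,
    WAVES,
    emit_survey,
    generate_population,
    generate_true_networks,
    simulate,
)


def test_population_counts_and_determinism():
    cfg = SynthConfig(n_orgs=119, seed=7)
    roster = generate_population(cfg)
    assert len(roster) == 119
    gk_types = {o.gatekeeper_type for o in roster.gatekeepers()}
    assert gk_types == {"center_youth_family", "general_practitioner", "child_health_care"}
    assert len(roster.gatekeepers()) == sum(cfg.n_gatekeepers.values())
    again = generate_population(SynthConfig(n_orgs=119, seed=7))
    assert again.ids == roster.ids
    assert again.organizations == roster.organizations


def test_degenerate_sector_weights():
    weights = tuple([0.0, 1.0] + [0.0] * 9)  # everything in sector 2
    cfg = SynthConfig(n_orgs=30, sector_weights=weights, seed=1)
    roster = generate_population(cfg)
    non_gk = [o for o in roster.organizations if not o.is_gatekeeper]
    assert all(o.sector == 2 for o in non_gk)


def test_too_many_gatekeepers_rejected():
    cfg = SynthConfig(n_orgs=5, n_gatekeepers={"general_practitioner": 10})
    with pytest.raises(ValueError, match="gatekeepers"):
        generate_population(cfg)


def test_invalid_probabilities_rejected():
    with pytest.raises(ValueError, match="retention"):
        SynthConfig(retention=1.5).validate()
    with pytest.raises(ValueError, match="sector_weights"):
        SynthConfig(sector_weights=tuple([0.5] * 11)).validate()


def test_retention_edge_cases():
    roster = generate_population(SynthConfig(n_orgs=40, seed=3))
    keep_all = generate_true_networks(roster, SynthConfig(n_orgs=40, seed=3, retention=1.0, churn=0.0))
    assert np.array_equal(keep_all.contact["w1"].freq, keep_all.contact["w2"].freq)
    assert keep_all.realized_retention == 1.0
    drop_all = generate_true_networks(roster, SynthConfig(n_orgs=40, seed=3, retention=0.0, churn=0.0))
    assert drop_all.contact["w2"].freq.sum() == 0


def test_truth_networks_symmetric_zero_diagonal():
    roster, truth, _ = simulate(SynthConfig(n_orgs=60, seed=5))
    for w in WAVES:
        net = truth.contact[w]
        for m in (net.freq, net.ek, net.cr):
            assert np.array_equal(m, m.T)
            assert np.all(np.diag(m) == 0)


def test_same_seed_identical_surveys():
    a = simulate(SynthConfig(n_orgs=50, seed=11))
    b = simulate(SynthConfig(n_orgs=50, seed=11))
    assert a[2] == b[2]


def test_full_response_recovers_ground_truth_exactly():
    """With response_rate=1 every tie is reported by both endpoints, so
    the built contact network equals the generator's truth."""
    cfg = SynthConfig(n_orgs=80, response_rate=1.0, seed=13)
    roster, truth, surveys = simulate(cfg)
    for w in WAVES:
        built = build_contact_network(surveys[w], roster, w)
        assert built.nodes == truth.contact[w].nodes
        assert np.array_equal(built.freq, truth.contact[w].freq)
        assert np.array_equal(built.ek, truth.contact[w].ek)
        assert np.array_equal(built.cr, truth.contact[w].cr)


def test_nonresponder_ties_recovered_from_partners():
    """A tie reported by only one endpoint survives symmetrization; only
    ties between two non-responders can be lost."""
    cfg = SynthConfig(n_orgs=60, response_rate=0.58, seed=21)
    roster, truth, surveys = simulate(cfg)
    built = build_contact_network(surveys["w1"], roster, "w1")
    reporters = {n.reporter for n in surveys["w1"]}
    truth_net = truth.contact["w1"]
    for i, a in enumerate(truth_net.nodes):
        for j in range(i + 1, len(truth_net.nodes)):
            b = truth_net.nodes[j]
            if truth_net.freq[i, j] and (a in reporters or b in reporters):
                assert built.freq[i, j] == truth_net.freq[i, j]
    # built network never invents ties
    assert np.all(built.contact <= truth_net.contact)


def test_gatekeepers_always_respond():
    cfg = SynthConfig(n_orgs=60, response_rate=0.3, core_always_respond=True, seed=2)
    roster, truth, surveys = simulate(cfg)
    reporters = {n.reporter for n in surveys["w1"]}
    for gk in roster.gatekeepers():
        pos = truth.contact["w1"].nodes.index(gk.org_id)
        if truth.contact["w1"].freq[pos].sum() > 0:
            assert gk.org_id in reporters


def test_hub_degree_dominance():
    """Hub gatekeepers give a max strong degree far above the median
    (heavily skewed degree distribution)."""
    ratios = []
    for seed in range(10):
        _, truth, _ = simulate(SynthConfig(seed=seed))
        deg = truth.strong["w1"].degrees()
        ratios.append(deg.max() / max(np.median(deg), 1))
    assert np.mean(ratios) >= 5


def test_realized_jaccard_tracks_model_expectation():
    jacs, exps = [], []
    for seed in range(8):
        _, truth, _ = simulate(SynthConfig(seed=seed))
        jacs.append(jaccard(truth.strong["w1"].adj, truth.strong["w2"].adj))
        exps.append(truth.expected_jaccard)
    assert abs(np.mean(jacs) - np.mean(exps)) < 0.05
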