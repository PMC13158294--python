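"""Differential networks: edge classification, comparisons, node roles."""
import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polarnet as pn
from polarnet import diffnet
from conftest import PLANTED_COUNTS, PLANTED_ROLES


# ---------------------------------------------------------------- edges
@pytest.mark.parametrize(
    "r, sign, tier",
    [
        (0.75, "positive", "strong"),
        (0.7499999, "positive", "medium"),
        (0.25, "positive", "medium"),
        (0.2499999, "positive", "weak"),
        (-0.75, "negative", "strong"),
        (-0.30, "negative", "medium"),
        (1.0, "positive", "strong"),
        (-1.0, "negative", "strong"),
    ],
)
def test_edge_classification_boundaries(r, sign, tier):
    e = diffnet.classify_edge(r)
    assert (e.sign, e.tier) == (sign, tier)


def test_zero_correlation_positive_by_convention_and_flagged():
    e = diffnet.classify_edge(0.0)
    assert e.sign == "positive" and e.tier == "weak" and e.zero_flagged


def test_out_of_range_correlation_rejected():
    with pytest.raises(ValueError):
        diffnet.classify_edge(1.001)
    with pytest.raises(ValueError):
        diffnet.classify_edge(float("nan"))


@settings(deadline=None, derandomize=True, max_examples=200)
@given(r=st.floats(min_value=-1, max_value=1, allow_nan=False))
def test_tier_partition_is_exhaustive_and_exclusive(r):
    e = diffnet.classify_edge(r)
    a = abs(r)
    expected = "strong" if a >= 0.75 else ("medium" if a >= 0.25 else "weak")
    assert e.tier == expected
    assert e.sign == ("negative" if r < 0 else "positive")


# ------------------------------------------------------- correlation matrix
def test_correlation_of_identical_and_opposite_series():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    df = pd.DataFrame({"x": x, "y": x, "z": -x})
    corr = diffnet.correlation_matrix(df)
    assert corr.r("x", "y") == pytest.approx(1.0)
    assert corr.r("x", "z") == pytest.approx(-1.0)


def test_correlation_matches_product_moment_formula():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([1.0, 2.0, 4.0, 8.0])
    n = len(x)
    num = n * (x * y).sum() - x.sum() * y.sum()
    den = np.sqrt(n * (x**2).sum() - x.sum() ** 2) * np.sqrt(n * (y**2).sum() - y.sum() ** 2)
    corr = diffnet.correlation_matrix(pd.DataFrame({"x": x, "y": y}))
    assert corr.r("x", "y") == pytest.approx(num / den, abs=1e-12)


def test_correlation_oracle_equivalence_on_random_matrix():
    """numpy path equals the textbook product-moment formula to 1e-12."""
    rng = np.random.default_rng(11)
    A = rng.normal(0, 1, (10, 10))
    corr = diffnet.correlation_matrix(pd.DataFrame(A, columns=[f"v{i}" for i in range(10)]))
    xc = A - A.mean(axis=0)
    oracle = (xc.T @ xc) / np.sqrt(np.outer((xc**2).sum(axis=0), (xc**2).sum(axis=0)))
    np.testing.assert_allclose(corr.values, oracle, atol=1e-12)


def test_zero_variance_variable_named_in_error():
    df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
    with pytest.raises(ValueError, match="flat"):
        diffnet.correlation_matrix(df)


def test_min_n_enforced():
    df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
    with pytest.raises(ValueError, match="at least 3"):
        diffnet.correlation_matrix(df)


# ------------------------------------------------------- gene-trait block
def test_affine_trait_of_gene_gives_unit_correlation(study, expression):
    _, traits, _ = study
    gene_wide = diffnet.expression_matrix(expression, "Misr2")
    synth = traits[traits["genotype"] == "Misr2"].copy()
    lookup = gene_wide["TaHSP70"]
    mask = synth["trait"] == "mda"
    synth.loc[mask, "value"] = synth.loc[mask].apply(
        lambda row: 2.0 * lookup.loc[(row["treatment"], row["bio_rep"])] + 1.0, axis=1
    )
    block = diffnet.gene_trait_correlations(expression, synth, "Misr2")
    assert block.loc["TaHSP70", "mda"] == pytest.approx(1.0)


def test_independent_noise_gives_small_correlations():
    """Under the null, 95% of |r| stays below the two-sided critical value."""
    rng = np.random.default_rng(21)
    n, reps = 30, 400
    crit = 2.0 / np.sqrt(n)  # ~95% normal-approximation bound for r under the null
    rs = np.array(
        [np.corrcoef(rng.normal(0, 1, n), rng.normal(0, 1, n))[0, 1] for _ in range(reps)]
    )
    assert (np.abs(rs) < crit).mean() >= 0.90


def test_planted_gene_to_yield_sign_flip_detected(study, expression):
    """TaSOD's yield correlation is planted positive in Misr2, negative in
    Line4 (the phenotypic-switcher signature)."""
    _, traits, _ = study
    a = diffnet.gene_trait_correlations(expression, traits, "Misr2")
    b = diffnet.gene_trait_correlations(expression, traits, "Line4")
    assert a.loc["TaSOD", "grain_yield"] > 0 > b.loc["TaSOD", "grain_yield"]
    frac = diffnet.trait_reversal_fractions(a, b)
    assert frac["TaSOD"] == pytest.approx(1.0)


# ------------------------------------------------------- network comparison
def _corr(values, labels=("a", "b", "c")):
    return diffnet.CorrelationMatrix(labels=tuple(labels), values=np.array(values), n=6)


def test_identical_networks_have_no_reversals():
    v = [[1, 0.8, -0.4], [0.8, 1, 0.3], [-0.4, 0.3, 1]]
    comps = diffnet.compare_networks(_corr(v), _corr(v))
    assert len(comps) == 3
    assert not any(c.polarity_reversed for c in comps)


def test_sign_flipped_network_reverses_every_edge():
    v = np.array([[1, 0.8, -0.4], [0.8, 1, 0.3], [-0.4, 0.3, 1]])
    flipped = -v.copy()
    np.fill_diagonal(flipped, 1.0)
    comps = diffnet.compare_networks(_corr(v), _corr(flipped))
    assert all(c.polarity_reversed for c in comps)
    counts = diffnet.node_reversal_counts(comps)
    assert counts == {"a": 2, "b": 2, "c": 2}


def test_variable_set_mismatch_rejected():
    v = [[1, 0.5], [0.5, 1]]
    with pytest.raises(ValueError, match="differ"):
        diffnet.compare_networks(_corr(v, ("a", "b")), _corr(v, ("a", "c")))


def test_reversal_counts_symmetric_in_genotype_order():
    rng = np.random.default_rng(2)
    A = rng.normal(0, 1, (6, 5))
    B = rng.normal(0, 1, (6, 5))
    labels = [f"g{i}" for i in range(5)]
    ca = diffnet.correlation_matrix(pd.DataFrame(A, columns=labels))
    cb = diffnet.correlation_matrix(pd.DataFrame(B, columns=labels))
    fwd = diffnet.node_reversal_counts(diffnet.compare_networks(ca, cb))
    rev = diffnet.node_reversal_counts(diffnet.compare_networks(cb, ca))
    assert fwd == rev


def test_complete_reversal_on_eight_genes_gives_count_seven():
    rng = np.random.default_rng(0)
    L = rng.normal(0, 1, (8, 1))
    v = L @ L.T
    d = np.sqrt(np.diag(v))
    v = v / np.outer(d, d)
    labels = tuple(f"g{i}" for i in range(8))
    flipped = -v.copy()
    np.fill_diagonal(flipped, 1.0)
    comps = diffnet.compare_networks(
        _corr(v, labels), _corr(flipped, labels)
    )
    counts = diffnet.node_reversal_counts(comps)
    assert all(c == 7 for c in counts.values())
    assert len(comps) == 28  # C(8,2)


def test_zero_edges_never_count_as_reversals():
    a = [[1, 0.0], [0.0, 1]]
    b = [[1, -0.5], [-0.5, 1]]
    comps = diffnet.compare_networks(_corr(a, ("x", "y")), _corr(b, ("x", "y")))
    assert not comps[0].polarity_reversed


# ------------------------------------------------------- roles
def test_planted_reversal_counts_recovered(fitted_network):
    assert fitted_network.reversal_counts_ == PLANTED_COUNTS


def test_planted_roles_recovered(fitted_network):
    assert fitted_network.roles_ == PLANTED_ROLES


def test_pex114_shows_four_strong_to_medium_downgrades(fitted_network):
    nodes = fitted_network.node_table().set_index("gene")
    assert nodes.loc["TaPEX11.4", "tier_downgrade_count"] == 4


def test_all_zero_metrics_make_everyone_a_responder():
    v = np.eye(3) * 0 + 0.5
    np.fill_diagonal(v, 1.0)
    comps = diffnet.compare_networks(_corr(v), _corr(v))
    roles = diffnet.classify_roles(
        comps, upregulated_tolerant={g: False for g in "abc"}
    )
    assert all(p.role == "contextual_responder" for p in roles)


def test_hub_set_shrinks_as_theta_rev_grows(fitted_network, expression, study):
    _, traits, _ = study
    hubs = {}
    for theta in (1, 3, 5, 6):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = pn.DifferentialNetwork(theta_rev=theta).fit(expression, traits)
        hubs[theta] = {g for g, r in m.roles_.items() if r == "hub"}
    assert hubs[6] <= hubs[5] <= hubs[3] <= hubs[1]


def test_missing_metric_raises():
    v = np.eye(2) * 0 + 0.5
    np.fill_diagonal(v, 1.0)
    comps = diffnet.compare_networks(_corr(v, ("a", "b")), _corr(v, ("a", "b")))
    with pytest.raises(ValueError, match="up-regulation"):
        diffnet.classify_roles(comps, upregulated_tolerant={"a": True})


# ------------------------------------------------------- export
def test_export_edge_table_and_graphml_roundtrip(tmp_path, fitted_network):
    paths = diffnet.export_network(fitted_network, tmp_path)
    names = {p.name for p in paths}
    assert "edges_compared.tsv" in names and "network.graphml" in names
    edges = pd.read_csv(tmp_path / "edges_compared.tsv", sep="\t")
    assert len(edges) == 28
    G = nx.read_graphml(tmp_path / "network.graphml")
    assert set(G.nodes) == set(pn.PAPER_GENES)
    roles = nx.get_node_attributes(G, "role")
    assert roles == fitted_network.roles_
    tiers = sorted(d["tier_susceptible"] for _, _, d in G.edges(data=True))
    expected = sorted(c.b.tier for c in fitted_network.comparisons_)
    assert tiers == expected


def test_dot_export_uses_legend_encoding(tmp_path, fitted_network):
    diffnet.export_network(fitted_network, tmp_path, formats=("dot",))
    dot = (tmp_path / "network_Misr2.dot").read_text()
    assert '"TaHSP70" [style=filled, fillcolor=red]' in dot  # hub
    assert '"TaSOD" [style=filled, fillcolor=green]' in dot  # switcher
    assert '"TaFIS1A" [style=filled, fillcolor=orange]' in dot  # responder
    # tolerant network edges are all strong: bold style, signed colors
    assert "style=bold" in dot and "color=green" in dot and "color=red" in dot
    assert "style=dashed" not in dot
    sus = (tmp_path / "network_Line4.dot").read_text()
    assert "style=dashed" in sus  # weak edges exist in the susceptible network


def test_unknown_export_format_rejected(tmp_path, fitted_network):
    with pytest.raises(ValueError, match="unknown formats"):
        diffnet.export_network(fitted_network, tmp_path, formats=("xml",))
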