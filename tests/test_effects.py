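"""Effect statistics: frozen worked examples, change-statistic vs
full-statistic-difference oracle, and structural symmetries."""

import numpy as np
import pytest

from ergmee import AttributeSet, DirectedGraph, EffectSpec, ModelSpec
from ergmee.effects import (ALTERNATING_EFFECTS, ATTR_KIND, EFFECT_NAMES,
                            change_stat, full_stat, stat_vector)

from conftest import random_attrs, random_graph


def all_effects(lam=2.0):
    specs = []
    for name in EFFECT_NAMES:
        kwargs = {}
        if name in ALTERNATING_EFFECTS:
            kwargs["lam"] = lam
        if name in ATTR_KIND:
            kwargs["attr"] = {"binary": "b", "categorical": "c",
                              "continuous": "u"}[ATTR_KIND[name]]
        specs.append(EffectSpec(name, **kwargs))
    return specs


# ---------------------------------------------------------------------------
# frozen examples
# ---------------------------------------------------------------------------

def test_arc_and_reciprocity_on_mutual_dyad():
    g = DirectedGraph.from_arcs(2, [(0, 1), (1, 0)])
    assert full_stat(EffectSpec("Arc"), g) == 2.0
    assert full_stat(EffectSpec("Reciprocity"), g) == 1.0


def test_alternating_out_star_on_three_star():
    # out-star 0->{1,2,3}: S2=3, S3=1, lambda=2 -> 3 - 1/2 = 2.5
    g = DirectedGraph.from_arcs(4, [(0, 1), (0, 2), (0, 3)])
    assert full_stat(EffectSpec("AoutS", lam=2), g) == pytest.approx(2.5)
    assert full_stat(EffectSpec("AinS", lam=2), g) == pytest.approx(0.0)


def test_alternating_transitive_triangle():
    # {0->1, 1->2, 0->2}: L2(0,2)=1 on arc (0,2) -> 2*(1-(1/2)^1) = 1
    g = DirectedGraph.from_arcs(3, [(0, 1), (1, 2), (0, 2)])
    assert full_stat(EffectSpec("AT-T", lam=2), g) == pytest.approx(1.0)
    # same triangle contains no cycle
    assert full_stat(EffectSpec("AT-C", lam=2), g) == pytest.approx(0.0)


def test_cyclic_triangle_counted_by_atc():
    g = DirectedGraph.from_arcs(3, [(0, 1), (1, 2), (2, 0)])
    # each arc closes the cycle: 3 * 2 * (1 - 1/2) = 3
    assert full_stat(EffectSpec("AT-C", lam=2), g) == pytest.approx(3.0)
    assert full_stat(EffectSpec("AT-T", lam=2), g) == pytest.approx(0.0)


def test_isolates_count_and_change():
    g = DirectedGraph(4)
    assert full_stat(EffectSpec("Isolates"), g) == 4.0
    assert change_stat(EffectSpec("Isolates"), g, None, 0, 1, True) == -2.0
    g.add_arc(0, 1)
    assert full_stat(EffectSpec("Isolates"), g) == 2.0
    assert change_stat(EffectSpec("Isolates"), g, None, 1, 2, True) == -1.0


def test_arc_change_is_constant():
    g = DirectedGraph.from_arcs(3, [(0, 1)])
    assert change_stat(EffectSpec("Arc"), g, None, 1, 2, True) == 1.0
    assert change_stat(EffectSpec("Arc"), g, None, 0, 1, False) == -1.0


def test_reciprocity_change():
    g = DirectedGraph.from_arcs(3, [(1, 0)])
    assert change_stat(EffectSpec("Reciprocity"), g, None, 0, 1, True) == 1.0
    assert change_stat(EffectSpec("Reciprocity"), g, None, 0, 2, True) == 0.0


def test_aouts_change_third_arc():
    # d_out(0) = 2 before the toggle -> lambda(1-(1-1/lambda)^2) = 1.5
    g = DirectedGraph.from_arcs(4, [(0, 1), (0, 2)])
    assert change_stat(EffectSpec("AoutS", lam=2), g, None, 0, 3,
                       True) == pytest.approx(1.5)


def test_att_change_closing_two_path():
    g = DirectedGraph.from_arcs(3, [(0, 1), (1, 2)])
    assert change_stat(EffectSpec("AT-T", lam=2), g, None, 0, 2,
                       True) == pytest.approx(1.0)


def test_matching_change_kronecker():
    attrs = AttributeSet.empty(3)
    attrs.add_categorical("c", [0, 0, 1])
    e = EffectSpec("Matching", attr="c")
    g = DirectedGraph(3)
    assert change_stat(e, g, attrs, 0, 1, True) == 1.0
    assert change_stat(e, g, attrs, 0, 2, True) == 0.0


def test_stat_vector_empty_graph_and_composition(rng):
    attrs = random_attrs(rng, 6, missing=0.0)
    model = ModelSpec(all_effects())
    g = DirectedGraph(6)
    v = stat_vector(model, g, attrs)
    iso = model.labels.index("Isolates")
    expected = np.zeros(len(model))
    expected[iso] = 6.0
    np.testing.assert_allclose(v, expected)
    h = random_graph(rng, 6, 0.3)
    vh = stat_vector(model, h, attrs)
    for k, eff in enumerate(model):
        assert vh[k] == pytest.approx(full_stat(eff, h, attrs))


def test_validation_errors():
    with pytest.raises(ValueError):
        EffectSpec("Foo")
    with pytest.raises(ValueError):
        EffectSpec("AinS", lam=0.5)
    with pytest.raises(ValueError):
        EffectSpec("Sender")            # attribute required
    with pytest.raises(ValueError):
        EffectSpec("Arc", lam=2)
    with pytest.raises(ValueError):
        ModelSpec(["Reciprocity"])      # Arc must come first
    with pytest.raises(ValueError):
        ModelSpec(["Arc", "Arc"])
    g = DirectedGraph(3)
    with pytest.raises((KeyError, ValueError)):
        full_stat(EffectSpec("Sender", attr="b"), g, AttributeSet.empty(3))


# ---------------------------------------------------------------------------
# oracle equivalence and symmetries
# ---------------------------------------------------------------------------

def _oracle_cases(rng, n_cases, lams=(1.5, 2.0, 5.0)):
    for _ in range(n_cases):
        n = int(rng.integers(3, 10))
        g = random_graph(rng, n, float(rng.uniform(0.1, 0.5)))
        attrs = random_attrs(rng, n)
        i, j = g.random_dyad(rng)
        lam = float(rng.choice(lams))
        yield g, attrs, i, j, lam


def test_change_stat_equals_full_stat_difference(rng):
    """change_stat == z(after) - z(before) for every effect, both
    directions, on random graphs (N <= 10, several lambdas)."""
    for g, attrs, i, j, lam in _oracle_cases(rng, 150):
        is_add = not g.has_arc(i, j)
        for eff in all_effects(lam):
            before = full_stat(eff, g, attrs)
            delta = change_stat(eff, g, attrs, i, j, is_add)
            if is_add:
                g.add_arc(i, j)
            else:
                g.delete_arc(i, j)
            after = full_stat(eff, g, attrs)
            # restore
            if is_add:
                g.delete_arc(i, j)
            else:
                g.add_arc(i, j)
            assert delta == pytest.approx(after - before, abs=1e-9), \
                f"{eff.label} toggle ({i},{j}) add={is_add}"


def test_change_stat_antisymmetry(rng):
    """delta(add) on x equals -delta(delete) on x + arc."""
    for g, attrs, i, j, lam in _oracle_cases(rng, 25):
        if g.has_arc(i, j):
            g.delete_arc(i, j)
        for eff in all_effects(lam):
            d_add = change_stat(eff, g, attrs, i, j, True)
            g.add_arc(i, j)
            d_del = change_stat(eff, g, attrs, i, j, False)
            g.delete_arc(i, j)
            assert d_add == pytest.approx(-d_del, abs=1e-12)


def test_a2ptd_combination_rule(rng):
    """z_A2P-TD = z_A2P-T + z_A2P-D / 2, as full and change statistics."""
    for g, attrs, i, j, lam in _oracle_cases(rng, 25):
        t = EffectSpec("A2P-T", lam=lam)
        d = EffectSpec("A2P-D", lam=lam)
        td = EffectSpec("A2P-TD", lam=lam)
        assert full_stat(td, g) == pytest.approx(
            full_stat(t, g) + full_stat(d, g) / 2)
        is_add = not g.has_arc(i, j)
        assert change_stat(td, g, attrs, i, j, is_add) == pytest.approx(
            change_stat(t, g, attrs, i, j, is_add)
            + change_stat(d, g, attrs, i, j, is_add) / 2)


def test_a2pd_a2pu_pair_relabelling_invariance(rng):
    """L2D and L2U are symmetric: the statistics are unchanged when the
    graph is relabelled by an arbitrary node permutation."""
    for _ in range(10):
        n = 8
        g = random_graph(rng, n, 0.3)
        perm = rng.permutation(n)
        h = DirectedGraph(n)
        for (i, j) in g.arc_list:
            h.add_arc(int(perm[i]), int(perm[j]))
        for name in ("A2P-D", "A2P-U"):
            eff = EffectSpec(name, lam=2)
            assert full_stat(eff, g) == pytest.approx(full_stat(eff, h))


def test_missing_attribute_terms_contribute_zero():
    attrs = AttributeSet.empty(3)
    attrs.add_binary("b", [1.0, np.nan, 1.0])
    attrs.add_categorical("c", [0, -1, 0])
    attrs.add_continuous("u", [1.0, np.nan, 2.0])
    g = DirectedGraph.from_arcs(3, [(0, 1), (1, 0), (0, 2), (2, 0)])
    # arcs from 0 and 2 count (b=1); node 1's arc is missing-valued
    assert full_stat(EffectSpec("Sender", attr="b"), g, attrs) == 3.0
    assert full_stat(EffectSpec("Interaction", attr="b"), g, attrs) == 2.0
    assert full_stat(EffectSpec("Matching", attr="c"), g, attrs) == 2.0
    assert full_stat(EffectSpec("Diff", attr="u"), g, attrs) == 2.0
    e = EffectSpec("Receiver", attr="b")
    assert change_stat(e, g, attrs, 2, 1, True) == 0.0
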