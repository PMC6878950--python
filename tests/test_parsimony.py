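"""Fitch/Hartigan length, MPR enumeration, ACCTRAN/DELTRAN optimization."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from venomrepevo.parsimony import (ACCTRAN, DELTRAN, OverrideRecord,
                                   apply_overrides, enumerate_mprs,
                                   fitch_length, optimize_character)
from venomrepevo.simulate import random_topology
from venomrepevo.trees import parse_newick

BALANCED = "((A,B)ab,(C,D)cd)root;"


def _random_char(tree, rng, p_unknown=0.0):
    labels = [l.label for l in tree.leaves()]
    char = {}
    for l in labels:
        r = rng.random()
        char[l] = None if r < p_unknown else int(rng.random() < 0.5)
    if all(v in (0, None) for v in char.values()):
        char[labels[0]] = 1
    return char


def test_fitch_constant_character_is_zero():
    tree = parse_newick(BALANCED)
    assert fitch_length(tree, {"A": 1, "B": 1, "C": 1, "D": 1}) == 0


def test_fitch_single_presence_is_one():
    tree = parse_newick(BALANCED)
    assert fitch_length(tree, {"A": 1, "B": 0, "C": 0, "D": 0}) == 1


def test_fitch_missing_leaf_raises():
    tree = parse_newick(BALANCED)
    with pytest.raises(KeyError, match="missing"):
        fitch_length(tree, {"A": 1, "B": 0, "C": 0})


@pytest.mark.parametrize("seed", range(30))
def test_fitch_equals_exhaustive_minimum_on_random_trees(seed):
    rng = np.random.default_rng(seed)
    tree = random_topology(int(rng.integers(4, 9)), seed)
    char = _random_char(tree, rng, p_unknown=0.15)
    assert fitch_length(tree, char) == enumerate_mprs(tree, char).length


def test_fitch_handles_polytomies():
    # star tree with 2 presences out of 5: two changes whatever the root
    tree = parse_newick("(A,B,C,D,E);")
    char = {"A": 1, "B": 1, "C": 0, "D": 0, "E": 0}
    assert fitch_length(tree, char) == 2
    # Hartigan majority at a 3-child node
    tree2 = parse_newick("((A,B,C)x,(D,E)y);")
    assert fitch_length(tree2, {"A": 1, "B": 1, "C": 0, "D": 0, "E": 0}) == 2


def test_mpr_enumeration_on_balanced_quartet():
    tree = parse_newick(BALANCED)
    mprs = enumerate_mprs(tree, {"A": 1, "B": 0, "C": 1, "D": 0})
    assert len(mprs) == 2 and mprs.length == 2
    assert {"ab": 0, "cd": 0, "root": 0} in mprs
    assert {"ab": 1, "cd": 1, "root": 1} in mprs


def test_mpr_enumeration_trivial_cases():
    tree = parse_newick(BALANCED)
    constant = enumerate_mprs(tree, {"A": 1, "B": 1, "C": 1, "D": 1})
    assert len(constant) == 1 and constant.length == 0
    assert constant.assignments[0] == {"ab": 1, "cd": 1, "root": 1}
    single = enumerate_mprs(tree, {"A": 1, "B": 0, "C": 0, "D": 0})
    assert len(single) == 1 and single.length == 1
    assert single.assignments[0] == {"ab": 0, "cd": 0, "root": 0}


def test_enumeration_guard():
    tree = random_topology(25, 0)
    char = {l.label: 0 for l in tree.leaves()}
    char[tree.leaves()[0].label] = 1
    with pytest.raises(ValueError, match="exhaustive"):
        enumerate_mprs(tree, char)


def test_acctran_prefers_stem_recruitment_plus_loss():
    tree = parse_newick(BALANCED)
    char = {"A": 1, "B": 0, "C": 1, "D": 0}
    recon = optimize_character(tree, char, ACCTRAN)
    assert recon.node_states["root"] == 1
    assert sorted(recon.events) == [("B", "loss"), ("D", "loss"),
                                    ("root", "gain")]
    assert recon.length == 2


def test_deltran_prefers_convergent_gains():
    tree = parse_newick(BALANCED)
    recon = optimize_character(tree, {"A": 1, "B": 0, "C": 1, "D": 0}, DELTRAN)
    assert recon.node_states["root"] == 0
    assert sorted(recon.events) == [("A", "gain"), ("C", "gain")]


def test_two_distant_clades_resolve_to_convergent_gains_under_both(species_tree):
    # a family in both scutigeromorphs and all scolopendromorphs: two
    # convergent recruitments beat a stem recruitment plus losses
    char = {"Sc": 1, "Tl": 1, "Lf": 0, "Ct": 0, "Stm": 0,
            "Er": 1, "Cw": 1, "Ss": 1, "Sm": 1}
    for method in (ACCTRAN, DELTRAN):
        recon = optimize_character(species_tree, char, method)
        assert sorted(recon.events) == [("Scolopendromorpha", "gain"),
                                        ("Scutigeromorpha", "gain")]


def test_constant_present_character_has_no_changes():
    tree = parse_newick(BALANCED)
    char = {"A": 1, "B": 1, "C": 1, "D": 1}
    for method in (ACCTRAN, DELTRAN):
        recon = optimize_character(tree, char, method,
                                   count_root_origin=False)
        assert recon.events == [] and recon.length == 0
        assert all(s == 1 for s in recon.node_states.values())
    with_origin = optimize_character(tree, char, ACCTRAN,
                                     count_root_origin=True)
    assert with_origin.events == [("root", "gain")]
    assert with_origin.length == 0


def test_unknown_leaf_is_unscored_and_costs_nothing():
    tree = parse_newick(BALANCED)
    recon = optimize_character(tree, {"A": 1, "B": None, "C": 0, "D": 0},
                               ACCTRAN)
    assert recon.node_states["B"] is None
    assert recon.length == 1


@pytest.mark.parametrize("seed", range(60))
def test_optimizations_are_mprs_with_ordered_gain_loss_counts(seed):
    rng = np.random.default_rng(1000 + seed)
    tree = random_topology(int(rng.integers(4, 9)), seed)
    char = _random_char(tree, rng, p_unknown=0.1)
    mprs = enumerate_mprs(tree, char)
    acc = optimize_character(tree, char, ACCTRAN, count_root_origin=False)
    dlt = optimize_character(tree, char, DELTRAN, count_root_origin=False)
    assert acc.internal_states() in mprs
    assert dlt.internal_states() in mprs
    assert acc.length == dlt.length == mprs.length
    assert acc.gains <= dlt.gains
    assert acc.losses >= dlt.losses
    assert acc.gains + acc.losses == acc.length
    for recon in (acc, dlt):
        states = recon.node_states
        for branch, kind in recon.events:
            assert states[branch] == (1 if kind == "gain" else 0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10 ** 6), pattern=st.integers(1, 2 ** 7 - 1))
def test_event_counts_sum_to_length_property(seed, pattern):
    tree = random_topology(7, seed % 1000)
    labels = [l.label for l in tree.leaves()]
    char = {l: (pattern >> i) & 1 for i, l in enumerate(labels)}
    acc = optimize_character(tree, char, ACCTRAN, count_root_origin=False)
    dlt = optimize_character(tree, char, DELTRAN, count_root_origin=False)
    assert acc.gains + acc.losses == dlt.gains + dlt.losses
    assert acc.length == fitch_length(tree, char)


# -- overrides ---------------------------------------------------------------

def test_pin_override_dominates_method():
    tree = parse_newick(BALANCED)
    char = {"A": 1, "B": 0, "C": 1, "D": 0}
    recon = optimize_character(tree, char, ACCTRAN, family="X")
    pinned = apply_overrides(recon, [OverrideRecord(
        family="X", kind="pin_state", node="root", state=0)])
    assert pinned.node_states["root"] == 0
    assert sorted(pinned.events) == [("A", "gain"), ("C", "gain")]


def test_single_origin_override_forces_deep_gain(species_tree):
    char = {"Sc": 1, "Tl": 1, "Lf": 0, "Ct": 0, "Stm": 0,
            "Er": 1, "Cw": 1, "Ss": 1, "Sm": 1}
    recon = optimize_character(species_tree, char, DELTRAN, family="X")
    forced = apply_overrides(recon, [OverrideRecord(family="X",
                                                    kind="single_origin")])
    gains = [b for b, k in forced.events if k == "gain"]
    assert gains == ["Chilopoda"]  # one origin: the root
    # minimal-change among single-origin assignments: verify by constrained
    # re-enumeration over all internal assignments
    best = _constrained_minimum(species_tree, char, origins=1)
    assert forced.length == best


def _constrained_minimum(tree, char, origins):
    root = tree.root
    internals = [n for n in root.postorder() if not n.is_leaf]
    leaves = root.leaves()
    parents = {}
    for node in root.preorder():
        for c in node.children:
            parents[id(c)] = node
    best = None
    for combo in itertools.product((0, 1), repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, combo)}
        for l in leaves:
            assign[id(l)] = char[l.label]
        changes = gains = 0
        for node in root.postorder():
            if node is root:
                continue
            s, t = assign[id(parents[id(node)])], assign[id(node)]
            if s != t:
                changes += 1
                gains += t
        if gains + assign[id(root)] == origins:
            if best is None or changes < best:
                best = changes
    return best


def test_multi_origin_override_counts_origins(species_tree):
    char = {"Sc": 1, "Tl": 0, "Lf": 1, "Ct": 0, "Stm": 0,
            "Er": 0, "Cw": 0, "Ss": 0, "Sm": 0}
    recon = optimize_character(species_tree, char, ACCTRAN, family="Y")
    # ACCTRAN alone reads this as a stem recruitment with two losses
    assert [b for b, k in recon.events if k == "gain"] == ["Chilopoda"]
    forced = apply_overrides(recon, [OverrideRecord(
        family="Y", kind="multi_origin", count=2)])
    gains = sorted(b for b, k in forced.events if k == "gain")
    assert gains == ["Lf", "Sc"] and forced.losses == 0


def test_empty_override_list_is_identity():
    tree = parse_newick(BALANCED)
    recon = optimize_character(tree, {"A": 1, "B": 0, "C": 1, "D": 0}, ACCTRAN,
                               family="X")
    assert apply_overrides(recon, []) is recon
    assert apply_overrides(recon, [OverrideRecord(
        family="OTHER", kind="single_origin")]) is recon


def test_conflicting_pins_raise():
    tree = parse_newick(BALANCED)
    recon = optimize_character(tree, {"A": 1, "B": 0, "C": 1, "D": 0}, ACCTRAN,
                               family="X")
    with pytest.raises(ValueError, match="conflicting pins"):
        apply_overrides(recon, [
            OverrideRecord(family="X", kind="pin_state", node="root", state=0),
            OverrideRecord(family="X", kind="pin_state", node="root", state=1)])


def test_unsatisfiable_origin_count_raises():
    tree = parse_newick(BALANCED)
    recon = optimize_character(tree, {"A": 1, "B": 1, "C": 1, "D": 1}, ACCTRAN,
                               family="X")
    with pytest.raises(ValueError, match="constraints"):
        apply_overrides(recon, [OverrideRecord(
            family="X", kind="multi_origin", count=20)])
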