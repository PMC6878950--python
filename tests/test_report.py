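"""Whole-repertoire reports: cocktails, branch events, summaries, deltas."""

import pandas as pd
import pytest

from venomrepevo.matrix import RepertoireMatrix
from venomrepevo.parsimony import ACCTRAN, DELTRAN
from venomrepevo.report import (convention_grid, lineage_deltas,
                                reconstruct_venom_evolution, summarize_events)


def _single_family_matrix(species, value=1.0):
    return RepertoireMatrix(
        data=pd.DataFrame({sp: [value] for sp in species}, index=["ONLY"]))


@pytest.fixture(scope="module")
def preset_reports(preset, species_tree):
    matrix, _ = preset
    acc = reconstruct_venom_evolution(matrix, species_tree, ACCTRAN)
    dlt = reconstruct_venom_evolution(matrix, species_tree, DELTRAN)
    return matrix, acc, dlt


def test_single_family_everywhere_root_cocktail_no_events(species_tree):
    m = _single_family_matrix(sorted(species_tree.leaf_set))
    rep = reconstruct_venom_evolution(m, species_tree, ACCTRAN,
                                      count_root_origin=False)
    assert rep.cocktail("Chilopoda") == {"ONLY"}
    assert rep.branch_events == {}
    summary = summarize_events(rep, species_tree.taxonomy)
    assert summary.total_events == 0


def test_terminal_cocktails_equal_matrix_columns(preset_reports, species_tree):
    matrix, acc, _ = preset_reports
    for sp in matrix.species:
        expected = {f for f in matrix.families if matrix.data.at[f, sp] == 1}
        assert acc.cocktail(sp) == expected


def test_cocktail_sizes_follow_branch_events(preset_reports, species_tree):
    _, acc, dlt = preset_reports
    parents = species_tree.parent_map()
    for rep in (acc, dlt):
        for node in species_tree.root.postorder():
            parent = parents[id(node)]
            if parent is None:
                continue
            nid = species_tree.node_id(node)
            events = rep.branch_events.get(nid, [])
            gains = sum(1 for _, k in events if k == "gain")
            losses = sum(1 for _, k in events if k == "loss")
            parent_size = len(rep.cocktail(species_tree.node_id(parent)))
            assert len(rep.cocktail(nid)) == parent_size + gains - losses


def test_acctran_and_deltran_agree_on_length_but_not_loss_split(
        preset_reports, species_tree):
    matrix, acc, dlt = preset_reports
    for fam in matrix.families:
        assert acc.reconstructions[fam].length == dlt.reconstructions[fam].length
    sa = summarize_events(acc, species_tree.taxonomy)
    sd = summarize_events(dlt, species_tree.taxonomy)
    assert sa.total_losses >= sd.total_losses
    assert sa.total_events == sa.total_gains + sa.total_losses
    assert sa.within_order_events + sa.stem_events == sa.total_events


def test_per_species_totals_are_root_to_tip_path_sums(preset_reports,
                                                      species_tree):
    _, acc, _ = preset_reports
    summary = summarize_events(acc, species_tree.taxonomy)
    parents = species_tree.parent_map()
    for leaf in species_tree.root.leaves():
        total = 0
        node = leaf
        while parents[id(node)] is not None:
            total += len(acc.branch_events.get(species_tree.node_id(node), []))
            node = parents[id(node)]
        assert summary.per_species_event_totals[leaf.label] == total


def test_lineage_deltas_to_self_is_empty(preset_reports):
    _, acc, _ = preset_reports
    assert lineage_deltas(acc, "Epimorpha", "Epimorpha") == ([], [])


def test_lineage_deltas_are_path_additive(preset_reports):
    _, acc, _ = preset_reports
    g1, l1 = lineage_deltas(acc, "Chilopoda", "Epimorpha")
    g2, l2 = lineage_deltas(acc, "Epimorpha", "Scolopendra")
    g_all, l_all = lineage_deltas(acc, "Chilopoda", "Scolopendra")
    assert g_all == g1 + g2
    assert l_all == l1 + l2


def test_lineage_deltas_reject_non_ancestral_pairs(preset_reports):
    _, acc, _ = preset_reports
    with pytest.raises(ValueError, match="not an ancestor"):
        lineage_deltas(acc, "Scutigeromorpha", "Sm")


def test_deltas_replay_cocktail_sizes(preset_reports):
    _, acc, _ = preset_reports
    start = acc.cocktail("Phylactometria")
    gains, losses = lineage_deltas(acc, "Phylactometria", "Epimorpha")
    assert len(acc.cocktail("Epimorpha")) == len(start) + len(gains) - len(losses)


def test_convention_grid_reports_all_combinations(preset, species_tree):
    matrix, _ = preset
    grid = convention_grid(matrix, species_tree, species_tree.taxonomy)
    assert len(grid) == 4
    assert set(grid["method"]) == {"ACCTRAN", "DELTRAN"}
    # root-origination counting only ever adds stem recruitments
    for method in ("ACCTRAN", "DELTRAN"):
        sub = grid[grid["method"] == method]
        on = sub[sub["count_root_origin"]].iloc[0]
        off = sub[~sub["count_root_origin"]].iloc[0]
        assert on["total_events"] >= off["total_events"]
        assert on["losses"] == off["losses"]


def test_matrix_species_must_be_tree_leaves(species_tree):
    m = _single_family_matrix(["Sc", "NOPE"])
    with pytest.raises(ValueError, match="NOPE"):
        reconstruct_venom_evolution(m, species_tree, ACCTRAN)


def test_report_serialization_round_trips(preset_reports, tmp_path):
    import json
    _, acc, _ = preset_reports
    payload = json.loads(acc.to_json())
    assert payload["method"] == "ACCTRAN"
    assert set(payload["ancestral_cocktails"]) == set(acc.ancestral_cocktails)
    table = acc.event_table()
    assert set(table.columns) == {"branch", "family", "event"}
    assert len(table) == sum(len(v) for v in acc.branch_events.values())
    assert "[&cocktail=" in acc.annotated_newick()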