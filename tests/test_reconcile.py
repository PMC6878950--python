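"""LCA reconciliation, proteome annotation, recruitment multiplicity."""

import pytest

from venomrepevo.reconcile import (AnnotatedGeneTree, annotate_proteome,
                                   lca_reconcile, recruitment_multiplicity,
                                   split_leaf_label)
from venomrepevo.simulate import simulate_gene_tree
from venomrepevo.trees import parse_newick

CONGRUENT = "((Sc_x,Tl_x),(Lf_x,(Ct_x,(Stm_x,(Er_x,(Cw_x,(Ss_x,Sm_x)))))));"


def test_leaf_label_convention():
    assert split_leaf_label("Sm_toxin_7") == ("Sm", "toxin_7")


def test_congruent_tree_has_no_duplications(species_tree):
    res = lca_reconcile(AnnotatedGeneTree(tree=parse_newick(CONGRUENT)),
                        species_tree)
    assert res.duplication_count == 0


def test_hand_worked_duplication_at_root(species_tree):
    gt = parse_newick("((Sc_a,(Lf_a,Sm_a)),(Sc_b,(Lf_b,Sm_b)));")
    res = lca_reconcile(AnnotatedGeneTree(tree=gt), species_tree)
    assert [sp for _, sp in res.duplications] == ["Chilopoda"]
    assert res.duplications_by_species_node() == {"Chilopoda": 1}


def test_nested_duplications_map_to_correct_clades(species_tree):
    # two copies in all scolopendromorphs, one elsewhere: duplication on
    # the scolopendromorph stem
    gt = parse_newick(
        "(Lf_a,((Er_a,(Cw_a,(Ss_a,Sm_a))),(Er_b,(Cw_b,(Ss_b,Sm_b)))));")
    res = lca_reconcile(AnnotatedGeneTree(tree=gt), species_tree)
    assert res.duplications_by_species_node() == {"Scolopendromorpha": 1}


def test_polytomy_counts_at_most_one_duplication(species_tree):
    gt = parse_newick("(Sm_a,Sm_b,Sm_c);")
    res = lca_reconcile(AnnotatedGeneTree(tree=gt), species_tree)
    assert res.duplication_count == 1


def test_unmapped_species_label_raises(species_tree):
    gt = parse_newick("((Sc_a,ZZ_a),Sm_a);")
    with pytest.raises(KeyError, match="ZZ"):
        lca_reconcile(AnnotatedGeneTree(tree=gt), species_tree)


def test_outgroup_leaves_are_excluded_from_mapping(species_tree):
    gt = parse_newick("(OUT_x,(Sc_a,(Lf_a,Sm_a)));")
    ann = AnnotatedGeneTree(tree=gt, outgroup_flags={"OUT_x": True})
    res = lca_reconcile(ann, species_tree)
    assert res.duplication_count == 0
    assert "OUT_x" not in res.species_map


def test_duplication_count_invariant_under_child_order(species_tree):
    a = parse_newick("((Sc_a,(Lf_a,Sm_a)),(Sc_b,(Lf_b,Sm_b)));")
    b = parse_newick("(((Sm_b,Lf_b),Sc_b),((Sm_a,Lf_a),Sc_a));")
    ra = lca_reconcile(AnnotatedGeneTree(tree=a), species_tree)
    rb = lca_reconcile(AnnotatedGeneTree(tree=b), species_tree)
    assert ra.duplication_count == rb.duplication_count


# -- proteome annotation -----------------------------------------------------

def test_annotate_no_hits_all_false():
    gt = parse_newick(CONGRUENT)
    ann = annotate_proteome(gt, {})
    assert not any(ann.proteome_flags.values())


def test_annotate_all_hits_all_true():
    gt = parse_newick(CONGRUENT)
    hits = {split_leaf_label(l.label)[0]: {"x"} for l in gt.leaves()}
    ann = annotate_proteome(gt, hits)
    assert all(ann.proteome_flags.values())


def test_annotate_mixed_counts_by_set_arithmetic():
    gt = parse_newick("((Sc_1,Sc_2),(Sm_1,(Sm_2,Sm_3)));")
    ann = annotate_proteome(gt, {"Sm": {"1", "3", "99"}, "Sc": {"2"}})
    flagged = {l for l, f in ann.proteome_flags.items() if f}
    assert flagged == {"Sm_1", "Sm_3", "Sc_2"}


def test_annotate_rejects_duplicate_leaf_ids():
    from venomrepevo.trees import TreeNode
    gt = TreeNode(children=[TreeNode(label="Sc_1"), TreeNode(label="Sc_1")])
    with pytest.raises(ValueError, match="duplicate"):
        annotate_proteome(gt, {})


# -- recruitment multiplicity ------------------------------------------------

def test_single_clade_of_flagged_leaves_is_single_origin(species_tree):
    gt = parse_newick("(OUT_x,((Sc_1,Sc_2),(Sm_1,Sm_2)));")
    ann = annotate_proteome(gt, {"Sc": {"1", "2"}, "Sm": {"1", "2"}},
                            family="F", outgroup=lambda l: l.startswith("OUT"))
    rec, = recruitment_multiplicity(ann, species_tree)
    assert rec.kind == "single_origin"


def test_two_separated_flagged_clades_are_two_origins(species_tree):
    gt = parse_newick("(OUT_x,((Sc_1,Sc_2),((Lf_1,Lf_2),(Sm_1,Sm_2))));")
    ann = annotate_proteome(gt, {"Sc": {"1", "2"}, "Sm": {"1", "2"}},
                            family="F", outgroup=lambda l: l.startswith("OUT"))
    rec, = recruitment_multiplicity(ann, species_tree)
    assert rec.kind == "multi_origin" and rec.count == 2


def test_nested_unflagged_leaves_report_expression_loss(species_tree):
    # a paraphyletic flagged group with nested non-proteome sequences:
    # one origin plus a within-clade loss of venom expression
    gt = parse_newick("(OUT_x,(Sc_1,(Sc_2,(Sc_3,(Sc_4,Sc_5)))));")
    ann = annotate_proteome(gt, {"Sc": {"1", "2", "4", "5"}}, family="M12A",
                            outgroup=lambda l: l.startswith("OUT"))
    rec, = recruitment_multiplicity(ann, species_tree)
    assert rec.kind == "single_origin"
    assert rec.expression_losses == 1


# -- simulated gene trees ----------------------------------------------------

@pytest.mark.parametrize("seed", range(25))
def test_zero_loss_duplication_counts_recovered_exactly(species_tree, seed):
    ann, true_dups = simulate_gene_tree(
        species_tree, duplication_rate=0.3, gene_loss_rate=0.0,
        proteome_flag_prob=0.5, seed=seed)
    res = lca_reconcile(ann, species_tree)
    assert res.duplication_count == len(true_dups)
    assert sorted(sp for _, sp in res.duplications) == sorted(true_dups)


@pytest.mark.parametrize("seed", range(25))
def test_with_losses_inferred_duplications_never_exceed_truth(species_tree,
                                                              seed):
    ann, true_dups = simulate_gene_tree(
        species_tree, duplication_rate=0.3, gene_loss_rate=0.15,
        proteome_flag_prob=0.5, seed=1000 + seed)
    res = lca_reconcile(ann, species_tree)
    assert res.duplication_count <= len(true_dups)
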