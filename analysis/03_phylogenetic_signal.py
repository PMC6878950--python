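"""Does venom composition retain phylogenetic signal?

Runs the exact branch-and-bound maximum-parsimony search over the binary
repertoire matrix, writes all most-parsimonious trees and their strict
consensus, and reports which clades of the accepted species tree the
consensus recovers.
"""

import argparse
import json
import os

from venomrepevo import (branch_and_bound_search, canonical_species_tree,
                         read_matrix, strict_consensus)
from venomrepevo.trees import bipartitions, to_newick


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--matrix", default="results/preset_matrix.tsv")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    tree = canonical_species_tree()
    matrix = read_matrix(args.matrix)
    res = branch_and_bound_search(matrix)
    cons = strict_consensus(res.mp_trees) if len(res.mp_trees) > 1 \
        else res.mp_trees[0]

    os.makedirs(args.out, exist_ok=True)
    with open(os.path.join(args.out, "mp_trees.nwk"), "w") as fh:
        fh.write("\n".join(res.newicks) + "\n")
    with open(os.path.join(args.out, "consensus.nwk"), "w") as fh:
        fh.write(to_newick(cons, include_lengths=False) + "\n")

    true_splits = bipartitions(tree.root)
    cons_splits = bipartitions(cons)
    recovered = sorted(
        "".join(sorted(s)) for s in true_splits & cons_splits)
    log = {"best_length": res.best_length,
           "n_mp_trees": len(res.mp_trees),
           "explored_partial_trees": res.explored,
           "n_taxa": len(matrix.species),
           "true_splits_recovered": len(true_splits & cons_splits),
           "true_splits_total": len(true_splits)}
    with open(os.path.join(args.out, "search_log.json"), "w") as fh:
        json.dump(log, fh, indent=1)

    print(f"branch and bound: {log['n_mp_trees']} most-parsimonious "
          f"tree(s) of length {log['best_length']} "
          f"({log['explored_partial_trees']} partial trees visited)")
    print(f"  strict consensus recovers {log['true_splits_recovered']}/"
          f"{log['true_splits_total']} clades of the accepted species tree")
    print(f"wrote {args.out}/mp_trees.nwk, consensus.nwk, search_log.json")


if __name__ == "__main__":
    main()
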