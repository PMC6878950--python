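"""Summarize a repertoire matrix: richness, uniqueness, order sharing.

Reads the matrix written by 01_simulate_repertoires.py (or any matrix in
the same format, e.g. a real proteome presence/absence table) and writes
the per-species summaries and the order-sharing spectrum.
"""

import argparse
import json
import os

from venomrepevo import canonical_species_tree, read_matrix
from venomrepevo.matrix import (order_sharing_spectrum, species_richness,
                                unique_family_stats)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--matrix", default="results/preset_matrix.tsv")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    tree = canonical_species_tree()
    matrix = read_matrix(args.matrix)
    richness = species_richness(matrix)
    unique = unique_family_stats(matrix)
    spectrum = order_sharing_spectrum(matrix, tree.taxonomy)

    os.makedirs(args.out, exist_ok=True)
    with open(os.path.join(args.out, "matrix_summaries.json"), "w") as fh:
        json.dump({
            "n_families": len(matrix.families),
            "richness": richness,
            "unique_families": {sp: {"count": n, "fraction": round(f, 4)}
                                for sp, (n, f) in unique.items()},
            "sharing_spectrum": spectrum.as_dict(),
        }, fh, indent=1, ensure_ascii=False)

    print(f"{len(matrix.families)} families across {len(matrix.species)} "
          f"species ({matrix.source} data)")
    most = max(richness, key=richness.get)
    least = min(richness, key=richness.get)
    print(f"  most complex venom: {most} ({richness[most]} families); "
          f"simplest: {least} ({richness[least]})")
    print("  families found in k orders (k=1..5): "
          + "/".join(str(spectrum.as_dict()[k]) for k in range(1, 6)))
    single = spectrum.counts.get(1, 0)
    print(f"  {single}/{spectrum.n_families} families are confined to a "
          f"single order")
    print(f"wrote {args.out}/matrix_summaries.json")


if __name__ == "__main__":
    main()
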