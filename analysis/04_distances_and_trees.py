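#!/usr/bin/env python
"""Chord-distance matrix of the simulated panel and NJ / UPGMA trees."""

import argparse
from pathlib import Path

import numpy as np

from germdiv import (
    distance_matrix,
    nj_tree,
    read_genotypes,
    upgma_tree,
    write_newick,
    write_phylip,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/trees"))
    ap.add_argument("--scale", choices=["cavalli", "none"], default="cavalli")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    gm = read_genotypes(args.data / "genotypes.csv")
    dm = distance_matrix(gm, scale=args.scale)
    write_phylip(dm, args.outdir / "distances.phy")
    s = dm.summary()
    print(f"chord distances: min {s['min']:.2f}, mean {s['mean']:.2f}, max {s['max']:.2f}")

    labels = np.array([a.population for a in gm.accessions])
    same = np.equal.outer(labels, labels)
    iu = np.triu_indices(len(labels), 1)
    print(
        f"mean within-population distance {dm.values[iu][same[iu]].mean():.2f}, "
        f"between {dm.values[iu][~same[iu]].mean():.2f}"
    )

    write_newick(nj_tree(dm), args.outdir / "tree_nj.nwk")
    write_newick(upgma_tree(dm), args.outdir / "tree_upgma.nwk")
    print(f"wrote NJ and UPGMA Newick trees to {args.outdir}")


if __name__ == "__main__":
    main()
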