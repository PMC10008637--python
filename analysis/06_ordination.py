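#!/usr/bin/env python
"""Principal coordinate analysis of the chord-distance matrix."""

import argparse
from pathlib import Path

from germdiv import pcoa, read_genotypes, read_phylip


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument(
        "--distances", type=Path, default=Path("results/trees/distances.phy")
    )
    ap.add_argument("--outdir", type=Path, default=Path("results/ordination"))
    ap.add_argument("--axes", type=int, default=2)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    dm = read_phylip(args.distances)
    res = pcoa(dm, n_axes=args.axes)
    coords = res.coordinates.copy()
    gm = read_genotypes(args.data / "genotypes.csv")
    coords["population"] = list(gm.populations.reindex(coords.index))
    coords.round(5).to_csv(args.outdir / "pcoa_coordinates.csv", index_label="id")

    props = ", ".join(
        f"PCo{i + 1} {p:.1%}" for i, p in enumerate(res.proportion_explained[: args.axes])
    )
    print(f"axis variance explained: {props}")
    if res.negative_eigenvalue_mass > 0:
        print(f"dropped negative eigenvalue mass: {res.negative_eigenvalue_mass:.3g}")


if __name__ == "__main__":
    main()
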