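#!/usr/bin/env python
"""Generate the paper-like synthetic panel and write it in both input formats.

The panel mirrors the structure of the real pepper collection: 179 diploid
accessions (80 landrace-like LLR + 75 breeding-line-like CBL + 24 admixed),
27 SSR/InDel loci with 2-20 alleles, and 22 qualitative + 13 quantitative
traits whose generating frequencies are the published panel values.
"""

import argparse
from pathlib import Path

from germdiv import paperlike_spec, simulate_dataset, write_genotypes, write_traits


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    gm, tt, source, q_true = simulate_dataset(paperlike_spec(seed=args.seed))
    write_genotypes(gm, args.outdir / "genotypes.csv", dialect="delimited")
    write_genotypes(gm, args.outdir / "genotypes.str", dialect="structure")
    write_traits(tt, args.outdir / "traits.csv")
    source.to_csv(args.outdir / "true_source.csv", header=True, index_label="id")

    n_miss = gm.missing_mask().mean()
    print(
        f"wrote {gm.n_accessions} accessions x {gm.n_loci} loci "
        f"({n_miss:.1%} missing calls) and {len(tt.qualitative.columns)} + "
        f"{len(tt.quantitative.columns)} traits to {args.outdir}"
    )


if __name__ == "__main__":
    main()
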