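"""Heterogeneity of NF-kB subunit gene expression across a DLBCL panel.

Generates the synthetic 21-line expression library (REL, RELA, RELB,
NFKB1, NFKB2), standardises it, and reports the per-gene spread and
pairwise gene correlations. The library emulates the empirical picture
this project starts from: strongly heterogeneous and mutually uncorrelated
expression of the NF-kB transcription-factor subunits across cell lines.

Writes results/expression_library/{expression_library.csv, zscores.csv,
gene_correlations.csv}.
"""

import argparse
from pathlib import Path

from nfkbfp.cell_lines import standardize_library
from nfkbfp.synth import LibrarySpec, generate_expression_library


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/expression_library"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    lib = generate_expression_library(LibrarySpec(seed=args.seed))
    z = standardize_library(lib.matrix)
    corr = lib.matrix.corr()

    lib.matrix.to_csv(args.out / "expression_library.csv")
    z.to_csv(args.out / "zscores.csv")
    corr.to_csv(args.out / "gene_correlations.csv")

    spread = lib.matrix.max() / lib.matrix.min()
    off_diag = corr.where(~(corr == 1.0)).abs().max().max()
    print(f"library: {lib.matrix.shape[0]} lines x {lib.matrix.shape[1]} genes")
    print(f"fold-range across lines per gene:\n{spread.round(1).to_string()}")
    print(f"largest |pairwise gene correlation|: {off_diag:.2f} "
          "(heterogeneous, essentially uncorrelated subunit expression)")


if __name__ == "__main__":
    main()
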