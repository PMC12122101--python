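"""Cluster regional return-rate series: 1 - correlation distances and the
neighbor-joining tree used to decide which regions to merge.
"""

import argparse
from pathlib import Path

import pandas as pd

from chumrun import clustering

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    rates_path = args.out / "return_rates.csv"
    if not rates_path.exists():
        raise SystemExit("run analysis/02_reconstruct.py first")

    rates = pd.read_csv(rates_path)
    dmat = clustering.correlation_distance_matrix(rates)
    tree = clustering.neighbor_joining(dmat)
    dmat.to_csv(args.out / "distance_matrix.csv")
    (args.out / "tree.nwk").write_text(tree.newick() + "\n")
    print("1 - r distance matrix:")
    print(dmat.round(3).to_string())
    print("\nneighbor-joining tree:")
    print(tree.newick())


if __name__ == "__main__":
    main()
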