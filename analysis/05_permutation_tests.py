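"""Test community correlates with the four permutation procedures.

Asks whether detected communities are assorted by biparental
relatedness, matrilineal haplotype, foraging strategy and water depth,
each against its permutation or binomial-randomisation null (10,000
iterations, doubled-tail p-values). Writes per-test JSON and a violin
figure under results/permtests/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

import finsoc as fs
from finsoc.io import read_attributes, read_relatedness, read_sightings
from finsoc.plots import permutation_violin


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument(
        "--labels", type=Path, default=Path("results/communities/communities.csv")
    )
    parser.add_argument("--outdir", type=Path, default=Path("results/permtests"))
    parser.add_argument("--n-perm", type=int, default=10_000)
    args = parser.parse_args()

    sightings = read_sightings(args.datadir / "sightings.csv")
    attributes = read_attributes(args.datadir / "attributes.csv")
    relatedness = read_relatedness(args.datadir / "relatedness.csv")
    labels = (
        pd.read_csv(args.labels).set_index("individual_id")["community"].to_dict()
    )

    attrs = attributes.set_index("individual_id")
    observed_depth = sightings.groupby("individual_id")["depth"].mean()

    results = {
        "relatedness": fs.perm_relatedness(
            relatedness, labels, args.n_perm, seed=args.seed
        ),
        "haplotype": fs.perm_haplotype(
            attrs["haplotype"], labels, args.n_perm, seed=args.seed + 1
        ),
        "foraging": fs.perm_foraging(
            attrs["sponger"], labels, args.n_perm, seed=args.seed + 2
        ),
        "depth_sd": fs.perm_depth_sd(
            observed_depth, labels, args.n_perm, seed=args.seed + 3
        ),
    }

    for name, res in results.items():
        sig = [k for k, p in res.p.items() if p < 0.05]
        print(f"{name}: significant for {sig or 'none'}")
        for key in res.observed:
            print(
                f"  {key}: observed {res.observed[key]:.3f}, "
                f"permuted mean {res.permuted[key].mean():.3f}, "
                f"p = {res.p_label[key]}"
            )

    args.outdir.mkdir(parents=True, exist_ok=True)
    (args.outdir / "permutation_tests.json").write_text(
        json.dumps({k: v.to_dict() for k, v in results.items()}, indent=2)
    )
    permutation_violin(results, str(args.outdir / "permutations.png"))
    print(f"results written to {args.outdir}")


if __name__ == "__main__":
    main()
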