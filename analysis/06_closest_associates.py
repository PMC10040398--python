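"""Closest-associate foraging homophily with Bonferroni binomial tests.

For every individual, finds the partner with the highest SRI and asks,
per foraging class, whether same-strategy closest associates occur more
often than the class's share of potential partners predicts.
"""

import argparse
from pathlib import Path

import finsoc as fs
from finsoc.io import read_attributes, read_sightings


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--outdir", type=Path, default=Path("results/closest"))
    args = parser.parse_args()

    sightings = read_sightings(args.datadir / "sightings.csv")
    attributes = read_attributes(args.datadir / "attributes.csv")
    kept = fs.filter_individuals(sightings)
    assoc = fs.compute_sri(sightings, kept)
    assoc = assoc.apply_mask(fs.demographic_mask(sightings, kept))
    overlap = fs.overlap_matrix(sightings, kept)
    assoc = assoc.apply_mask(fs.geographic_mask(overlap, kept))

    closest = fs.closest_associates(assoc)
    attrs = attributes.set_index("individual_id")
    report = fs.homophily_binomial_test(closest, attrs["sponger"].loc[kept])

    for _, row in report.per_class.iterrows():
        print(
            f"{row['class']}: {100 * row['proportion_same']:.0f}% same-strategy "
            f"closest associates (n={row['n']}, expected "
            f"{100 * row['expected_p']:.0f}%), "
            f"Bonferroni p = {row['p_bonferroni']:.2g}"
        )

    args.outdir.mkdir(parents=True, exist_ok=True)
    per_ind = report.per_individual.copy()
    per_ind["closest"] = per_ind["closest"].map(";".join)
    per_ind.to_csv(args.outdir / "closest_associates.csv", index=False)
    report.per_class.to_csv(args.outdir / "homophily_tests.csv", index=False)
    print(f"report written to {args.outdir}")


if __name__ == "__main__":
    main()
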