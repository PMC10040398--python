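import numpy as np
import pandas as pd
import pytest

import finsoc as fs


def make_sightings(records):
    """Build a sighting table from (survey, group, individual) tuples."""
    rows = []
    for rec in records:
        survey, group, ind = rec[:3]
        depth = rec[3] if len(rec) > 3 else 5.0
        date = rec[4] if len(rec) > 4 else f"2010-01-{int(survey[1:]) % 28 + 1:02d}"
        rows.append(
            {
                "survey_id": survey,
                "date": date,
                "group_id": group,
                "individual_id": ind,
                "depth": depth,
                "x": 0.0,
                "y": 0.0,
            }
        )
    columns = ["survey_id", "date", "group_id", "individual_id", "depth", "x", "y"]
    df = pd.DataFrame(rows, columns=columns)
    df["date"] = pd.to_datetime(df["date"])
    return df


def brute_force_sri(sightings, a, b):
    """Independent SRI recount straight off the raw rows."""
    surveys_a = set(sightings.loc[sightings.individual_id == a, "survey_id"])
    surveys_b = set(sightings.loc[sightings.individual_id == b, "survey_id"])
    either = surveys_a | surveys_b
    if not either:
        return None
    keys_a = set(
        map(
            tuple,
            sightings.loc[
                sightings.individual_id == a, ["survey_id", "group_id"]
            ].itertuples(index=False),
        )
    )
    keys_b = set(
        map(
            tuple,
            sightings.loc[
                sightings.individual_id == b, ["survey_id", "group_id"]
            ].itertuples(index=False),
        )
    )
    return len(keys_a & keys_b) / len(either)


def random_sighting_table(rng, n_ind=12, n_surveys=25):
    """Random grouped survey data for oracle comparisons."""
    inds = [f"I{k:02d}" for k in range(n_ind)]
    rows = []
    for s in range(n_surveys):
        present = [i for i in inds if rng.random() < 0.6]
        rng.shuffle(present)
        gid = 0
        while present:
            size = min(len(present), 1 + rng.geometric(0.5))
            for ind in present[:size]:
                rows.append((f"S{s:03d}", gid, ind))
            present = present[size:]
            gid += 1
    return make_sightings(rows)


@pytest.fixture(scope="session")
def small_society():
    """A 30-female society with surveys, shared across tests."""
    cfg = fs.PopulationConfig(n_females=30, n_surveys=80, seed=42)
    individuals, pedigree = fs.generate_population(cfg)
    relatedness = fs.simulate.population_relatedness(individuals, pedigree)
    sightings = fs.simulate_surveys(individuals, relatedness, cfg)
    return {
        "config": cfg,
        "individuals": individuals,
        "pedigree": pedigree,
        "relatedness": relatedness,
        "sightings": sightings,
        "attributes": fs.simulate.attributes_frame(individuals),
    }


@pytest.fixture(scope="session")
def small_fit(small_society):
    """A fitted dyadic model on the small society (short chains)."""
    soc = small_society
    kept = fs.filter_individuals(soc["sightings"])
    assoc = fs.compute_sri(soc["sightings"], kept)
    dyads = fs.build_dyad_table(assoc, soc["attributes"], soc["relatedness"])
    fit = fs.fit_zib_glmm(
        dyads, fs.ZIBModelSpec(chains=2, iterations=1500), seed=9, max_retries=1
    )
    return {"dyads": dyads, "fit": fit, "assoc": assoc}
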