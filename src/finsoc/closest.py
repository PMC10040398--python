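"""Closest-associate foraging homophily.

Each individual's closest associate is the unmasked partner with the
highest SRI. Per foraging class, the proportion of individuals whose
closest associate shares their class is compared against the class's
prevalence among potential partners with an exact one-sided binomial
test, Bonferroni-corrected for the two classes tested.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import AssociationMatrix, MaskState

logger = logging.getLogger(__name__)

__all__ = ["ClosestAssociateReport", "closest_associates", "homophily_binomial_test"]


@dataclass
class ClosestAssociateReport:
    per_individual: pd.DataFrame
    per_class: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            row["class"]: {
                "n": int(row["n"]),
                "k_same": float(row["k_same"]),
                "proportion_same": float(row["proportion_same"]),
                "expected_p": float(row["expected_p"]),
                "p_raw": float(row["p_raw"]),
                "p_bonferroni": float(row["p_bonferroni"]),
            }
            for _, row in self.per_class.iterrows()
        }


def closest_associates(assoc: AssociationMatrix) -> pd.DataFrame:
    """Top associate(s) per individual (ties all retained).

    Individuals with no unmasked partner carrying a finite SRI are
    excluded (logged). Returns one row per individual with the list of
    tied closest partners.
    """
    if assoc.n < 2:
        raise ValueError("need at least two individuals")
    rows = []
    sri = assoc.sri
    mask = assoc.mask
    for i, ind in enumerate(assoc.ids):
        valid = (mask[i] == MaskState.VALUE) & np.isfinite(sri[i])
        valid[i] = False
        if not valid.any():
            logger.warning("individual %s has no applicable partners; excluded", ind)
            continue
        row_vals = np.where(valid, sri[i], -np.inf)
        best = row_vals.max()
        partners = [assoc.ids[j] for j in np.flatnonzero(row_vals == best)]
        rows.append((ind, partners, float(best)))
    return pd.DataFrame(rows, columns=["individual_id", "closest", "sri"])


def homophily_binomial_test(
    closest: pd.DataFrame, sponger: pd.Series, n_tests: int = 2
) -> ClosestAssociateReport:
    """Exact binomial tests of same-strategy closest associates.

    For each class, k_same sums per-individual same-class indicators
    (ties contribute fractionally); the null probability p0 is the
    class's share among the focal individual's potential partners (the
    focal excluded). The test is one-sided upper (homophily direction);
    the tail uses k_same rounded to the nearest count. Bonferroni
    multiplies by ``n_tests``, capped at 1.
    """
    classes = sponger.dropna().astype(bool)
    n_total = classes.size
    n_sponger = int(classes.sum())
    if n_sponger == 0 or n_sponger == n_total:
        logger.warning("one foraging class is empty; its test is skipped")

    per_ind = closest.copy()
    focal_class = classes.reindex(per_ind["individual_id"]).to_numpy()
    frac_same = []
    for (_, row), cls in zip(per_ind.iterrows(), focal_class):
        partners = row["closest"]
        flags = classes.reindex(partners)
        frac_same.append(float((flags == cls).mean()))
    per_ind["same_strategy"] = frac_same
    per_ind["sponger"] = focal_class

    out_rows = []
    for cls_name, is_sponger in (("sponger", True), ("non_sponger", False)):
        n_class = n_sponger if is_sponger else n_total - n_sponger
        if n_class == 0:
            continue
        sub = per_ind[per_ind["sponger"] == is_sponger]
        n = len(sub)
        if n == 0:
            continue
        k_same = float(sub["same_strategy"].sum())
        # class share among potential partners, focal excluded
        p0 = (n_class - 1) / (n_total - 1)
        k_int = int(round(k_same))
        p_raw = float(stats.binom.sf(k_int - 1, n, p0))  # P(K >= k_int)
        out_rows.append(
            {
                "class": cls_name,
                "n": n,
                "k_same": k_same,
                "proportion_same": k_same / n,
                "expected_p": p0,
                "p_raw": p_raw,
                "p_bonferroni": min(1.0, n_tests * p_raw),
            }
        )
    per_class = pd.DataFrame(out_rows)
    return ClosestAssociateReport(per_individual=per_ind, per_class=per_class)
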