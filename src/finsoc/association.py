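"""Simple Ratio Index association networks with "not applicable" masking.

Associations follow the gambit of the group: two individuals associate in
a survey when they are recorded in the same group. The Simple Ratio
Index for a dyad is x / n_either — the number of surveys the two were
grouped together over the number of surveys in which either was seen.
Dyads that could never have associated (non-overlapping sighting spans,
or home-range overlap below threshold) are masked "not applicable" and
carry no index value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MaskState",
    "AssociationMatrix",
    "filter_individuals",
    "compute_sri",
    "demographic_mask",
    "geographic_mask",
]


class MaskState(IntEnum):
    VALUE = 0
    NOT_APPLICABLE_DEMOGRAPHIC = 1
    NOT_APPLICABLE_GEOGRAPHIC = 2


@dataclass
class AssociationMatrix:
    """Symmetric SRI matrix plus a three-state applicability mask.

    ``sri[i, j]`` is meaningful only where ``mask[i, j] == MaskState.VALUE``;
    masked cells are NaN. The diagonal is excluded (NaN, mask VALUE).
    """

    ids: list[str]
    sri: np.ndarray
    mask: np.ndarray
    together: np.ndarray | None = None
    n_either: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.ids)
        assert self.sri.shape == (n, n) and self.mask.shape == (n, n)

    @property
    def n(self) -> int:
        return len(self.ids)

    def masked_weights(self) -> np.ndarray:
        """Weights for graph algorithms: masked cells contribute 0."""
        w = np.where(self.mask == MaskState.VALUE, self.sri, 0.0)
        w = np.nan_to_num(w, nan=0.0)
        np.fill_diagonal(w, 0.0)
        return w

    def value_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sri, index=self.ids, columns=self.ids)

    def mask_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mask, index=self.ids, columns=self.ids)

    def edge_list(self) -> pd.DataFrame:
        """Upper-triangle weighted edge list of unmasked, positive dyads."""
        rows = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if self.mask[i, j] == MaskState.VALUE and self.sri[i, j] > 0:
                    rows.append((self.ids[i], self.ids[j], float(self.sri[i, j])))
        return pd.DataFrame(rows, columns=["id_a", "id_b", "sri"])

    def apply_mask(self, updates: np.ndarray) -> "AssociationMatrix":
        """Overlay additional mask states; VALUE never overrides an NA."""
        new_mask = np.where(self.mask == MaskState.VALUE, updates, self.mask)
        sri = self.sri.copy()
        sri[new_mask != MaskState.VALUE] = np.nan
        return AssociationMatrix(
            self.ids, sri, new_mask.astype(np.int8), self.together, self.n_either
        )


def filter_individuals(
    sightings: pd.DataFrame,
    mode: str = "in_association",
    min_sightings: int = 10,
) -> list[str]:
    """Apply the minimum-sightings inclusion filter.

    mode="in_association" counts only surveys in which the individual's
    group held at least one other animal; mode="any" counts all surveys.
    """
    if sightings.empty:
        raise ValueError("empty sighting table")
    if mode not in ("in_association", "any"):
        raise ValueError(f"unknown filter mode {mode!r}")
    df = sightings.copy()
    gsize = df.groupby(["survey_id", "group_id"])["individual_id"].transform("size")
    if mode == "in_association":
        df = df[gsize >= 2]
    counts = df.groupby("individual_id")["survey_id"].nunique()
    kept = sorted(counts.index[counts >= min_sightings])
    if not kept:
        logger.warning("inclusion filter removed every individual; empty network")
    return kept


def compute_sri(sightings: pd.DataFrame, individuals: list[str]) -> AssociationMatrix:
    """Unmasked SRI matrix over the given individuals.

    n_either counts distinct surveys (an individual sighted in two groups
    of one survey counts once). A dyad never observed in any common or
    separate survey (n_either = 0) is coded demographically not
    applicable.
    """
    n = len(individuals)
    idx = {ind: k for k, ind in enumerate(individuals)}
    df = sightings[sightings["individual_id"].isin(idx)]

    surveys: list[set] = [set() for _ in range(n)]
    for ind, sub in df.groupby("individual_id")["survey_id"]:
        surveys[idx[ind]] = set(sub)

    together = np.zeros((n, n))
    for _, grp in df.groupby(["survey_id", "group_id"])["individual_id"]:
        members = sorted({idx[g] for g in grp})
        for a_pos, a in enumerate(members):
            for b in members[a_pos + 1 :]:
                together[a, b] += 1
                together[b, a] += 1

    sri = np.full((n, n), np.nan)
    mask = np.zeros((n, n), dtype=np.int8)
    either = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            n_either = len(surveys[i] | surveys[j])
            either[i, j] = either[j, i] = n_either
            if n_either == 0:
                mask[i, j] = mask[j, i] = MaskState.NOT_APPLICABLE_DEMOGRAPHIC
                continue
            sri[i, j] = sri[j, i] = together[i, j] / n_either
    return AssociationMatrix(
        list(individuals), sri, mask, together=together.astype(np.int64), n_either=either
    )


def demographic_mask(
    sightings: pd.DataFrame, individuals: list[str]
) -> np.ndarray:
    """Mask dyads whose first-last sighting intervals do not overlap.

    Intervals sharing a single day overlap. Returns a mask-update matrix
    to overlay via :meth:`AssociationMatrix.apply_mask`.
    """
    df = sightings[sightings["individual_id"].isin(individuals)]
    dates = pd.to_datetime(df["date"])
    spans = (
        df.assign(date=dates)
        .groupby("individual_id")["date"]
        .agg(["min", "max"])
        .reindex(individuals)
    )
    first = spans["min"].to_numpy()
    last = spans["max"].to_numpy()
    disjoint = (last[:, None] < first[None, :]) | (last[None, :] < first[:, None])
    updates = np.where(
        disjoint, MaskState.NOT_APPLICABLE_DEMOGRAPHIC, MaskState.VALUE
    ).astype(np.int8)
    np.fill_diagonal(updates, MaskState.VALUE)
    return updates


def geographic_mask(
    overlap: pd.DataFrame, individuals: list[str], threshold: float = 0.25
) -> np.ndarray:
    """Mask dyads with home-range volume-of-intersection below threshold.

    The comparison is strict (< threshold masks; exactly threshold is
    kept). Missing overlap values are treated as masked and logged.
    """
    ov = overlap.reindex(index=individuals, columns=individuals).to_numpy(dtype=float)
    missing = ~np.isfinite(ov)
    np.fill_diagonal(missing, False)
    if missing.any():
        logger.warning(
            "%d dyads lack home-range overlap values; masking them", missing.sum() // 2
        )
    below = missing | (ov < threshold)
    updates = np.where(
        below, MaskState.NOT_APPLICABLE_GEOGRAPHIC, MaskState.VALUE
    ).astype(np.int8)
    np.fill_diagonal(updates, MaskState.VALUE)
    return updates
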