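"""Pedigrees and pedigree-derived biparental relatedness.

Relatedness between two non-inbred individuals is twice their kinship
coefficient: the probability that alleles sampled at random from each are
identical by descent. Parent-offspring and full-sib pairs have r = 0.5,
half sibs 0.25, and so on. The diagonal of the relatedness matrix is
1 + f, where f is the individual's inbreeding coefficient (the kinship of
its parents).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Pedigree", "PedigreeError", "pedigree_relatedness"]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (e.g. cycles)."""


@dataclass
class Pedigree:
    """Parent map over individuals.

    Parameters
    ----------
    parents
        Mapping ``id -> (mother_id | None, father_id | None)``. Founders
        have ``(None, None)``. Parents referenced but absent from the map
        are treated as founders.
    """

    parents: dict[str, tuple[str | None, str | None]]
    generations: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        # ensure referenced parents exist as entries
        for mid, fid in list(self.parents.values()):
            for p in (mid, fid):
                if p is not None and p not in self.parents:
                    self.parents[p] = (None, None)
        self._order = self._topological_order()
        depth = {i: 0 for i in self._order}
        for ind in self._order:
            m, f = self.parents[ind]
            depth[ind] = 1 + max(
                depth.get(m, -1) if m else -1, depth.get(f, -1) if f else -1
            )
        self.generations = max(depth.values()) + 1 if depth else 0

    @property
    def individuals(self) -> list[str]:
        return list(self._order)

    def _topological_order(self) -> list[str]:
        """Order with parents before offspring; raises on cycles."""
        state: dict[str, int] = {}  # 0 visiting, 1 done
        order: list[str] = []

        for root in self.parents:
            if state.get(root) == 1:
                continue
            stack = [(root, False)]
            while stack:
                node, processed = stack.pop()
                if processed:
                    state[node] = 1
                    order.append(node)
                    continue
                if state.get(node) == 1:
                    continue
                if state.get(node) == 0:
                    raise PedigreeError(f"pedigree contains a cycle through {node!r}")
                state[node] = 0
                stack.append((node, True))
                for p in self.parents.get(node, (None, None)):
                    if p is not None and state.get(p) != 1:
                        if state.get(p) == 0:
                            raise PedigreeError(
                                f"pedigree contains a cycle through {p!r}"
                            )
                        stack.append((p, False))
        return order


def pedigree_relatedness(pedigree: Pedigree) -> pd.DataFrame:
    """Biparental relatedness matrix from a pedigree.

    Uses the tabular kinship recursion over a parents-first ordering:
    phi(a, a) = (1 + phi(m_a, f_a)) / 2 and, for b ordered after a,
    phi(a, b) = (phi(a, m_b) + phi(a, f_b)) / 2, with phi = 0 against
    unknown parents. Returned values are 2 * phi (so the diagonal is
    1 + f).

    Returns
    -------
    pandas.DataFrame
        Symmetric matrix indexed by individual id.
    """
    ids = pedigree.individuals
    idx = {ind: k for k, ind in enumerate(ids)}
    n = len(ids)
    phi = np.zeros((n, n))

    for j, ind in enumerate(ids):
        m, f = pedigree.parents[ind]
        mi = idx[m] if m is not None else -1
        fi = idx[f] if f is not None else -1
        # self-kinship
        phi[j, j] = 0.5 * (1.0 + (phi[mi, fi] if mi >= 0 and fi >= 0 else 0.0))
        # kinship with everyone ordered earlier
        for i in range(j):
            val = 0.0
            if mi >= 0:
                val += 0.5 * phi[i, mi]
            if fi >= 0:
                val += 0.5 * phi[i, fi]
            phi[i, j] = phi[j, i] = val

    return pd.DataFrame(2.0 * phi, index=ids, columns=ids)
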