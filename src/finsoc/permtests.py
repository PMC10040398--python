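"""Permutation tests for community correlates.

Four null procedures ask whether communities are assorted by kinship,
matriline, foraging culture and habitat:

* relatedness — individuals' community labels are shuffled (community
  sizes preserved) and per-community mean dyadic relatedness recomputed;
* haplotype identity — each dyad's sharing indicator is redrawn from a
  binomial with the pooled observed sharing proportion, and within- /
  between-community means recomputed;
* foraging identity — the same binomial randomisation on same-class
  indicators;
* habitat — individuals' mean depths are reassigned to communities of
  the observed sizes and the per-community standard deviation of depth
  recomputed (smaller observed SD = more habitat-homogeneous community).

p-values use the doubled-tail rule: twice the proportion of permuted
values at least as extreme as the observed value, capped at 1. With
``direction="auto"`` the tail is picked by the sign of observed minus
the null median, which keeps the two-sided test calibrated; the literal
upper-tail rule is available via ``direction="upper"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PermutationResult",
    "two_sided_p",
    "perm_relatedness",
    "perm_haplotype",
    "perm_foraging",
    "perm_depth_sd",
]


def two_sided_p(
    observed: float, permuted: np.ndarray, direction: str = "auto"
) -> tuple[float, str]:
    """Doubled-tail permutation p-value.

    Returns ``(p, label)``: ``p = 2 * #{perm >= obs} / n_perm`` (upper),
    ``2 * #{perm <= obs} / n_perm`` (lower), with ``auto`` choosing the
    tail from the sign of ``obs - median(perm)``. p is capped at 1; a
    zero count is reported as "< 2/n_perm" with p floored there so p
    stays in (0, 1].
    """
    permuted = np.asarray(permuted, dtype=float)
    n_perm = permuted.size
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    if direction == "auto":
        direction = "lower" if observed < np.median(permuted) else "upper"
    if direction == "upper":
        count = int((permuted >= observed).sum())
    elif direction == "lower":
        count = int((permuted <= observed).sum())
    else:
        raise ValueError(f"unknown direction {direction!r}")
    floor = 2.0 / n_perm
    if count == 0:
        return floor, f"< {floor:g}"
    p = min(1.0, 2.0 * count / n_perm)
    return p, f"{p:g}"


@dataclass
class PermutationResult:
    statistic: str
    observed: dict[str, float]
    permuted: dict[str, np.ndarray]
    p: dict[str, float] = field(default_factory=dict)
    p_label: dict[str, str] = field(default_factory=dict)
    n_perm: int = 0
    seed: int | None = None

    def summarise(self, direction: str = "auto") -> "PermutationResult":
        for key, obs in self.observed.items():
            if not np.isfinite(obs):
                self.p[key] = float("nan")
                self.p_label[key] = "undefined"
                continue
            p, label = two_sided_p(obs, self.permuted[key], direction)
            self.p[key] = p
            self.p_label[key] = label
        return self

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": {k: float(v) for k, v in self.observed.items()},
            "p": {k: float(v) for k, v in self.p.items()},
            "p_label": dict(self.p_label),
            "permuted_mean": {
                k: float(np.mean(v)) for k, v in self.permuted.items()
            },
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def _labels_to_array(
    ids: list[str], partition_labels: dict[str, int]
) -> np.ndarray:
    return np.array([partition_labels[i] for i in ids])


def _within_mask(labels: np.ndarray) -> np.ndarray:
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    return np.triu(same, 1)


def _community_pair_means(
    values: np.ndarray, labels: np.ndarray, communities: np.ndarray
) -> np.ndarray:
    """Mean off-diagonal dyadic value within each community (NaN if < 2)."""
    out = np.full(communities.size, np.nan)
    for k, c in enumerate(communities):
        members = np.flatnonzero(labels == c)
        if members.size < 2:
            continue
        sub = values[np.ix_(members, members)]
        iu = np.triu_indices(members.size, 1)
        vals = sub[iu]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            out[k] = vals.mean()
    return out


def _random_assignments(
    n: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """n_perm random permutations of individual indices (rows)."""
    return np.argsort(rng.random((n_perm, n)), axis=1)


def _pair_mean_null(
    values: np.ndarray,
    assignments: np.ndarray,
    positions: np.ndarray,
) -> np.ndarray:
    """Null mean within-community dyadic value for one community.

    ``assignments[b]`` is a random permutation; the community's members in
    permutation b are ``assignments[b, positions]`` (size preserved).
    """
    members = assignments[:, positions]  # (n_perm, m)
    sub = values[members[:, :, None], members[:, None, :]]
    m = positions.size
    iu = np.triu_indices(m, 1)
    pair_vals = sub[:, iu[0], iu[1]]
    with np.errstate(invalid="ignore"):
        return np.nanmean(pair_vals, axis=1)


def perm_relatedness(
    relatedness: pd.DataFrame,
    partition_labels: dict[str, int],
    n_perm: int = 10_000,
    seed: int = 0,
    direction: str = "auto",
) -> PermutationResult:
    """Per-community mean relatedness versus size-preserving label shuffles."""
    ids = [i for i in partition_labels if i in relatedness.index]
    r = relatedness.loc[ids, ids].to_numpy(dtype=float)
    labels = _labels_to_array(ids, partition_labels)
    communities = np.unique(labels)
    rng = np.random.default_rng(seed)

    observed = _community_pair_means(r, labels, communities)
    assignments = _random_assignments(labels.size, n_perm, rng)
    perm = np.full((n_perm, communities.size), np.nan)
    for k, c in enumerate(communities):
        positions = np.flatnonzero(labels == c)
        if positions.size >= 2:
            perm[:, k] = _pair_mean_null(r, assignments, positions)

    names = [f"community_{c}" for c in communities]
    result = PermutationResult(
        statistic="mean_within_community_relatedness",
        observed=dict(zip(names, observed)),
        permuted={name: perm[:, k] for k, name in enumerate(names)},
        n_perm=n_perm,
        seed=seed,
    )
    return result.summarise(direction)


def _binomial_randomisation(
    indicator: np.ndarray,
    labels: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    p_hat: float,
) -> tuple[dict[str, float], dict[str, np.ndarray]]:
    within = _within_mask(labels)
    iu = np.triu_indices(labels.size, 1)
    w_flags = within[iu]
    vals = indicator[iu]
    ok = np.isfinite(vals)
    vals, w_flags = vals[ok], w_flags[ok]
    if vals.size == 0:
        raise ValueError("no dyads with data for the binomial randomisation")

    observed = {
        "within": float(vals[w_flags].mean()) if w_flags.any() else float("nan"),
        "between": float(vals[~w_flags].mean()) if (~w_flags).any() else float("nan"),
    }
    draws = rng.random((n_perm, vals.size)) < p_hat
    permuted = {
        "within": draws[:, w_flags].mean(axis=1)
        if w_flags.any()
        else np.full(n_perm, np.nan),
        "between": draws[:, ~w_flags].mean(axis=1)
        if (~w_flags).any()
        else np.full(n_perm, np.nan),
    }
    return observed, permuted


def _sharing_matrix(values: pd.Series, ids: list[str]) -> np.ndarray:
    """Dyadic same-value indicator; NaN where either individual lacks data."""
    v = values.reindex(ids)
    arr = v.to_numpy()
    have = v.notna().to_numpy()
    same = (arr[:, None] == arr[None, :]).astype(float)
    same[~have[:, None] | ~have[None, :]] = np.nan
    return same


def perm_haplotype(
    haplotypes: pd.Series,
    partition_labels: dict[str, int],
    n_perm: int = 10_000,
    seed: int = 0,
    direction: str = "auto",
    p_hat_mode: str = "dyadic",
) -> PermutationResult:
    """Within/between-community haplotype sharing vs binomial randomisation.

    Dyads lacking haplotype data are excluded. The null redraws each
    dyad's sharing indicator Bernoulli(p-hat); ``p_hat_mode="dyadic"``
    (default) uses the pooled observed proportion of sharing dyads,
    ``"freq"`` the expected sharing from haplotype frequencies
    (sum of squared frequencies).
    """
    ids = list(partition_labels)
    labels = _labels_to_array(ids, partition_labels)
    same = _sharing_matrix(haplotypes, ids)
    iu = np.triu_indices(len(ids), 1)
    vals = same[iu]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no genotyped dyads")
    if p_hat_mode == "dyadic":
        p_hat = float(vals.mean())
    elif p_hat_mode == "freq":
        freqs = haplotypes.dropna().value_counts(normalize=True).to_numpy()
        p_hat = float((freqs**2).sum())
    else:
        raise ValueError(f"unknown p_hat_mode {p_hat_mode!r}")

    rng = np.random.default_rng(seed)
    observed, permuted = _binomial_randomisation(same, labels, n_perm, rng, p_hat)
    result = PermutationResult(
        statistic="mean_haplotype_identity",
        observed=observed,
        permuted=permuted,
        n_perm=n_perm,
        seed=seed,
    )
    return result.summarise(direction)


def perm_foraging(
    sponger: pd.Series,
    partition_labels: dict[str, int],
    n_perm: int = 10_000,
    seed: int = 0,
    direction: str = "auto",
    p_hat_mode: str = "dyadic",
) -> PermutationResult:
    """Within/between-community foraging identity vs binomial randomisation.

    The indicator is 1 for sponger-sponger and non-sponger-non-sponger
    dyads, 0 for mixed. ``p_hat_mode="dyadic"`` (default) draws the null
    from the pooled observed same-class dyad proportion — slightly
    conservative because the null centre is estimated from the same
    dyads; ``"freq"`` uses the class frequencies (q^2 + (1-q)^2), which
    is nearly exactly calibrated.
    """
    ids = list(partition_labels)
    labels = _labels_to_array(ids, partition_labels)
    same = _sharing_matrix(sponger.astype(float), ids)
    iu = np.triu_indices(len(ids), 1)
    vals = same[iu]
    vals = vals[np.isfinite(vals)]
    if p_hat_mode == "dyadic":
        p_hat = float(vals.mean())
    elif p_hat_mode == "freq":
        q = float(sponger.dropna().astype(bool).mean())
        p_hat = q**2 + (1 - q) ** 2
    else:
        raise ValueError(f"unknown p_hat_mode {p_hat_mode!r}")
    rng = np.random.default_rng(seed)
    observed, permuted = _binomial_randomisation(same, labels, n_perm, rng, p_hat)
    result = PermutationResult(
        statistic="mean_foraging_identity",
        observed=observed,
        permuted=permuted,
        n_perm=n_perm,
        seed=seed,
    )
    return result.summarise(direction)


def perm_depth_sd(
    mean_depths: pd.Series,
    partition_labels: dict[str, int],
    n_perm: int = 10_000,
    seed: int = 0,
    direction: str = "auto",
) -> PermutationResult:
    """Per-community SD of member depths vs size-preserving reassignment.

    A smaller observed than permuted SD indicates habitat-homogeneous
    communities, so the informative tail is the lower one; ``auto``
    selects it from the data.
    """
    ids = [i for i in partition_labels if pd.notna(mean_depths.get(i))]
    depths = mean_depths.reindex(ids).to_numpy(dtype=float)
    labels = _labels_to_array(ids, partition_labels)
    communities = np.unique(labels)
    rng = np.random.default_rng(seed)

    def _sds(lab: np.ndarray) -> np.ndarray:
        out = np.full(communities.size, np.nan)
        for k, c in enumerate(communities):
            members = depths[lab == c]
            if members.size >= 2:
                out[k] = members.std(ddof=1)
        return out

    observed = _sds(labels)
    assignments = _random_assignments(labels.size, n_perm, rng)
    perm = np.full((n_perm, communities.size), np.nan)
    for k, c in enumerate(communities):
        positions = np.flatnonzero(labels == c)
        if positions.size >= 2:
            perm[:, k] = depths[assignments[:, positions]].std(ddof=1, axis=1)

    names = [f"community_{c}" for c in communities]
    result = PermutationResult(
        statistic="sd_within_community_depth",
        observed=dict(zip(names, observed)),
        permuted={name: perm[:, k] for k, name in enumerate(names)},
        n_perm=n_perm,
        seed=seed,
    )
    return result.summarise(direction)
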