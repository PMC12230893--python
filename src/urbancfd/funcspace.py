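"""Functional trait space: Gower dissimilarity, functional trees, dispersion.

Trait dissimilarity between species is measured with Gower's coefficient for
mixed continuous/binary data, averaged within the predefined trait groups so
that a group of (say) eight foraging categories carries the same weight as a
single continuous trait.  The resulting distance matrix is summarized as an
unrooted neighbour-joining functional tree, and community-level functional
dispersion is the mean patristic distance between all pairs of co-occurring
species on that tree (the divergence component of functional diversity,
computed on presence/absence only).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import TraitTable
from .trees import Tree, nj_tree, patristic, validate_distance_matrix

__all__ = [
    "gower_distance",
    "nj_tree",
    "patristic",
    "dispersion",
    "dispersion_matrix",
    "Tree",
]

MIN_COMMUNITY_SIZE = 3


def gower_distance(
    table: TraitTable, service: str, *, group_weighting: bool = True
) -> pd.DataFrame:
    """Pairwise Gower dissimilarity over one service's trait set.

    Each trait group contributes equally: the group score is the mean
    absolute difference across the group's (0/1 or [0,1]-scaled) columns, and
    the distance is the mean of group scores.  With ``group_weighting=False``
    every column carries equal weight instead.

    Parameters
    ----------
    table
        Analysis-ready trait table (continuous columns scaled to [0, 1]).
    service
        ``"cultural"`` or ``"regulating"``.

    Returns
    -------
    Square DataFrame in [0, 1], zero diagonal, indexed by species.
    """
    cols = table.service_columns(service)
    if not cols:
        raise ValueError(f"no traits available for service {service!r}")
    values = table.values[cols]
    if values.isna().any().any():
        raise ValueError("missing trait values; prepare the table first")
    x = values.to_numpy(dtype=float)
    lo, hi = x.min(), x.max()
    if lo < -1e-9 or hi > 1 + 1e-9:
        raise ValueError("trait values outside [0, 1]; scale before Gower")

    groups = table.meta.loc[cols, "group"]
    if not group_weighting:
        groups = pd.Series(cols, index=cols)  # every column its own group

    n = x.shape[0]
    dist = np.zeros((n, n))
    n_groups = groups.nunique()
    for _, members in groups.groupby(groups):
        idx = [cols.index(c) for c in members.index]
        sub = x[:, idx]
        score = np.abs(sub[:, None, :] - sub[None, :, :]).mean(axis=2)
        dist += score
    dist /= n_groups
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=values.index, columns=values.index)


def dispersion(tree: Tree, community: set[str] | list[str]) -> float:
    """Functional (or phylogenetic) dispersion of one community.

    The mean patristic distance over all unordered pairs of the community's
    species on ``tree``.  Communities below three species are rejected: with
    fewer than three members the mean pairwise distance is dominated by a
    single pair and is a biased diversity estimate.
    """
    comm = sorted(set(community))
    if len(comm) < MIN_COMMUNITY_SIZE:
        raise ValueError(f"community has {len(comm)} species; need >= {MIN_COMMUNITY_SIZE}")
    missing = set(comm) - set(tree.tips)
    if missing:
        raise KeyError(f"species not on tree: {sorted(missing)}")
    d = patristic(tree).loc[comm, comm].to_numpy()
    iu = np.triu_indices(len(comm), k=1)
    return float(d[iu].mean())


def dispersion_matrix(dist: pd.DataFrame, presence: pd.DataFrame) -> pd.Series:
    """Vectorized dispersion for many communities against one distance matrix.

    Parameters
    ----------
    dist
        Square patristic (or other) distance matrix over the species pool.
    presence
        Cells-by-species 0/1 matrix; species must be a subset of ``dist``'s
        labels and every row must contain at least three species.

    Returns
    -------
    Series of mean pairwise distances indexed by cell.
    """
    validate_distance_matrix(dist)
    sp = list(presence.columns)
    d = dist.loc[sp, sp].to_numpy()
    s = presence.to_numpy(dtype=float)
    k = s.sum(axis=1)
    if np.any(k < MIN_COMMUNITY_SIZE):
        bad = presence.index[k < MIN_COMMUNITY_SIZE]
        raise ValueError(f"communities below {MIN_COMMUNITY_SIZE} species: {list(bad)[:5]}")
    # s_i^T D s_i counts each unordered pair twice (zero diagonal)
    total = np.einsum("ij,jk,ik->i", s, d, s)
    return pd.Series(total / (k * (k - 1)), index=presence.index, name="dispersion")
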