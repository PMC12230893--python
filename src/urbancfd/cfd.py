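"""Corrected functional dispersion (CFD): phylogenetic correction and
null-model standardized effect sizes.

Functional dispersion (FD) of a community partly reflects shared ancestry:
close relatives tend to be functionally similar.  The correction regresses
FD on phylogenetic dispersion (PD) across communities and keeps the
residuals — the component of functional dispersion not explained by
evolutionary history.  Because residual dispersion still depends on species
richness, each community's observed residual is then standardized against a
null distribution obtained by randomizing species' positions on the
functional and phylogenetic trees (tip-label permutation, equivalent to
drawing random species sets of the same richness), giving

    SES = (observed residual - mean(null residuals)) / sd(null residuals)

with the sample (n-1) standard deviation.  SES > 0 marks overdispersed
communities (more ecosystem-service breadth than expected at that
richness), SES < 0 underdispersed ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CommunityMatrix
from .funcspace import dispersion_matrix
from .trees import Tree, patristic

__all__ = [
    "phylo_correct",
    "null_distributions",
    "null_dispersion",
    "ses",
    "corrected_dispersion",
    "CFDResult",
]

DEFAULT_N_ITER = 999


def _ols_residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals of y on x with intercept (one predictor, closed form)."""
    xc = x - x.mean()
    denom = (xc**2).sum()
    slope = (xc * (y - y.mean())).sum() / denom if denom > 0 else 0.0
    return y - (y.mean() + slope * xc)


def phylo_correct(fd: pd.Series, pd_disp: pd.Series) -> pd.Series:
    """Residuals of functional on phylogenetic dispersion (OLS, intercept).

    Both vectors must share community ids.  The residuals are exactly
    uncorrelated with PD — the orthogonality that makes them a
    phylogeny-free measure of functional dispersion.
    """
    if set(fd.index) != set(pd_disp.index):
        raise ValueError("community ids differ between FD and PD")
    if len(fd) < 3:
        raise ValueError("need at least 3 communities to fit the FD~PD line")
    pd_disp = pd_disp.loc[fd.index]
    resid = _ols_residuals(fd.to_numpy(dtype=float), pd_disp.to_numpy(dtype=float))
    return pd.Series(resid, index=fd.index, name="resid")


def null_distributions(
    ftree: Tree,
    ptree: Tree,
    communities: CommunityMatrix,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    *,
    shared_permutation: bool = True,
    permutations: np.ndarray | None = None,
) -> pd.DataFrame:
    """Expected (null) residuals under tip-label randomization.

    Per iteration one uniform permutation of species names is applied to the
    functional and phylogenetic trees (a single shared permutation by
    default, so a species' functional and phylogenetic positions move
    together; set ``shared_permutation=False`` to shuffle the two trees
    independently).  FD and PD dispersion are recomputed for every
    community, the FD~PD line is refit within the iteration, and its
    residuals are stored.

    Relabelling tips is equivalent to permuting rows/columns of the
    patristic matrices, which is how it is implemented.

    Returns
    -------
    DataFrame of shape (communities, n_iter).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rich = communities.richness()
    if (rich < 3).any():
        raise ValueError("communities with < 3 species must be filtered out first")
    sp = list(communities.presence.columns)
    df = patristic(ftree).loc[sp, sp].to_numpy()
    dp = patristic(ptree).loc[sp, sp].to_numpy()
    s = communities.presence.to_numpy(dtype=float)
    k = s.sum(axis=1)
    norm = k * (k - 1)

    n_sp = len(sp)
    out = np.empty((s.shape[0], n_iter))
    # one independent child stream per iteration: reproducible and
    # order-independent under any parallel split
    seeds = np.random.SeedSequence(seed).spawn(n_iter)
    if permutations is not None and permutations.shape != (n_iter, n_sp):
        raise ValueError("permutations must have shape (n_iter, n_species)")
    for it in range(n_iter):
        rng = np.random.default_rng(seeds[it])
        if permutations is not None:
            p = q = np.asarray(permutations[it])
        else:
            p = rng.permutation(n_sp)
            q = p if shared_permutation else rng.permutation(n_sp)
        sf = s[:, np.argsort(p)]  # community membership under the relabelling
        sq = sf if shared_permutation else s[:, np.argsort(q)]
        fd = np.einsum("ij,jk,ik->i", sf, df, sf) / norm
        pdd = np.einsum("ij,jk,ik->i", sq, dp, sq) / norm
        out[:, it] = _ols_residuals(fd, pdd)
    return pd.DataFrame(out, index=communities.presence.index)


def null_dispersion(
    tree: Tree, communities: CommunityMatrix, n_iter: int, seed: int = 0
) -> pd.DataFrame:
    """Null dispersion values alone (no regression): per iteration, one
    uniform tip-label permutation of ``tree`` and the resulting mean
    pairwise distance of every community.  Shape (communities, n_iter)."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    sp = list(communities.presence.columns)
    d = patristic(tree).loc[sp, sp].to_numpy()
    s = communities.presence.to_numpy(dtype=float)
    k = s.sum(axis=1)
    norm = k * (k - 1)
    seeds = np.random.SeedSequence(seed).spawn(n_iter)
    out = np.empty((s.shape[0], n_iter))
    for it in range(n_iter):
        p = np.random.default_rng(seeds[it]).permutation(len(sp))
        sf = s[:, np.argsort(p)]
        out[:, it] = np.einsum("ij,jk,ik->i", sf, d, sf) / norm
    return pd.DataFrame(out, index=communities.presence.index)


@dataclass
class CFDResult:
    """Per-community corrected functional dispersion for one service."""

    table: pd.DataFrame  # columns: fd, pd, resid, null_mean, null_sd, ses, degenerate
    service: str
    n_iter: int
    seed: int

    def write(self, path) -> None:
        out = self.table.copy()
        out["service"] = self.service
        out["n_iter"] = self.n_iter
        out["seed"] = self.seed
        out.to_csv(path, sep="\t", index_label="community_id")


def ses(observed: pd.Series, null: pd.DataFrame) -> pd.DataFrame:
    """Standard effect sizes of observed residuals against the null matrix.

    SES_i = (obs_i - mean(null_i)) / sd(null_i) with the sample (n-1) sd.
    A degenerate null (sd = 0) yields SES = NaN with ``degenerate=True``,
    never +/-infinity.
    """
    if set(observed.index) != set(null.index):
        raise ValueError("community ids differ between observed and null")
    null = null.loc[observed.index]
    mu = null.mean(axis=1)
    sd = null.std(axis=1, ddof=1) if null.shape[1] > 1 else pd.Series(0.0, index=null.index)
    degenerate = sd <= 0
    z = (observed - mu).where(~degenerate) / sd.where(~degenerate)
    return pd.DataFrame(
        {"resid": observed, "null_mean": mu, "null_sd": sd, "ses": z, "degenerate": degenerate}
    )


def corrected_dispersion(
    ftree: Tree,
    ptree: Tree,
    communities: CommunityMatrix,
    *,
    service: str = "",
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    shared_permutation: bool = True,
) -> CFDResult:
    """Observed FD/PD dispersion, phylogenetic correction, null SES — the
    full corrected-functional-dispersion computation for one service."""
    sp = list(communities.presence.columns)
    df = patristic(ftree).loc[sp, sp]
    dp = patristic(ptree).loc[sp, sp]
    fd = dispersion_matrix(df, communities.presence)
    pdd = dispersion_matrix(dp, communities.presence)
    resid = phylo_correct(fd, pdd)
    null = null_distributions(
        ftree, ptree, communities, n_iter=n_iter, seed=seed, shared_permutation=shared_permutation
    )
    table = ses(resid, null)
    table.insert(0, "pd", pdd)
    table.insert(0, "fd", fd)
    return CFDResult(table=table, service=service, n_iter=n_iter, seed=seed)
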