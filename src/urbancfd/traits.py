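"""Trait preparation: derived traits, scaling and collinearity screening.

Raw trait tables carry morphometrics (body mass, tail length, colour scores,
crest class) and binary life-history categories (social degree, nesting,
diet, foraging).  The analysis-ready table used for Gower dissimilarities
replaces tail length with its allometric residual, adds inverse body mass as
a small-size aesthetic proxy, min-max scales every continuous trait to
[0, 1] (mass and tail length on the log scale first, to tame extreme
values), and drops one member of any within-service trait pair whose Pearson
correlation exceeds the collinearity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CULTURAL, REGULATING, TraitTable

__all__ = [
    "TRAIT_GROUPS",
    "derive_relative_tail_length",
    "derive_inverse_body_mass",
    "scale_continuous",
    "screen_collinearity",
    "prepare_traits",
    "CollinearityReport",
]

# The nine trait groups.  Cultural traits are single-member groups; the
# binary regulating categories are grouped so each group contributes one
# Gower component.  Categories within a group are not mutually exclusive.
TRAIT_GROUPS: dict[str, dict] = {
    "relative_tail_length": {"group": "tail", "service": CULTURAL, "kind": "continuous"},
    "colour_diversity": {"group": "colour_diversity", "service": CULTURAL, "kind": "continuous"},
    "colour_elaboration": {"group": "colour_elaboration", "service": CULTURAL, "kind": "continuous"},
    "crest": {"group": "crest", "service": CULTURAL, "kind": "continuous"},
    "inverse_body_mass": {"group": "body_mass", "service": CULTURAL, "kind": "continuous"},
    "body_mass": {"group": "body_mass", "service": REGULATING, "kind": "continuous"},
    **{
        f"social_{c}": {"group": "social", "service": REGULATING, "kind": "binary"}
        for c in ("solitary", "semicolonial", "colonial")
    },
    **{
        f"nest_{c}": {"group": "nesting", "service": REGULATING, "kind": "binary"}
        for c in ("ground", "cavity", "open", "close_to_ground", "closed_arboreal")
    },
    **{
        f"diet_{c}": {"group": "diet", "service": REGULATING, "kind": "binary"}
        for c in ("granivore", "folivore", "frugivore", "invertebrates", "vertebrates", "carrion")
    },
    **{
        f"forage_{c}": {"group": "foraging", "service": REGULATING, "kind": "binary"}
        for c in ("air_pursuit", "sally", "foliage_glean", "pounce", "peck", "dig", "overturn", "probe")
    },
}

LOG_BEFORE_SCALING = ("body_mass", "tail_length")


def default_trait_meta() -> pd.DataFrame:
    return pd.DataFrame.from_dict(TRAIT_GROUPS, orient="index").rename_axis("trait")


@dataclass
class CollinearityReport:
    """Record of the collinearity screen: one entry per dropped trait."""

    threshold: float
    scope: str  # "per-service"
    dropped: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"threshold": self.threshold, "scope": self.scope, "dropped": self.dropped}


def derive_relative_tail_length(table: TraitTable) -> TraitTable:
    """Add tail length corrected for allometry.

    Ordinary least-squares residuals of log tail length on log body mass;
    residuals are mean-zero by construction, so a long-tailed-for-its-size
    species scores positive regardless of absolute size.
    """
    for col in ("tail_length", "body_mass"):
        if col not in table.values.columns:
            raise KeyError(f"missing column {col!r}")
        if (table.values[col] <= 0).any():
            raise ValueError(f"non-positive values in {col!r}")
    y = np.log(table.values["tail_length"].to_numpy(dtype=float))
    x = np.log(table.values["body_mass"].to_numpy(dtype=float))
    xc = x - x.mean()
    denom = (xc**2).sum()
    slope = (xc * (y - y.mean())).sum() / denom if denom > 0 else 0.0
    resid = y - (y.mean() + slope * xc)
    out = table.values.copy()
    out["relative_tail_length"] = resid
    return TraitTable(values=out, meta=table.meta, nonnative=table.nonnative)


def derive_inverse_body_mass(table: TraitTable) -> TraitTable:
    """Add 1/mass (pre-scaling), the small-bird aesthetic-preference proxy."""
    if "body_mass" not in table.values.columns:
        raise KeyError("missing column 'body_mass'")
    if (table.values["body_mass"] <= 0).any():
        raise ValueError("non-positive body mass")
    out = table.values.copy()
    out["inverse_body_mass"] = 1.0 / out["body_mass"]
    return TraitTable(values=out, meta=table.meta, nonnative=table.nonnative)


def scale_continuous(table: TraitTable) -> TraitTable:
    """Min-max scale continuous traits to [0, 1]; binary traits untouched.

    Body mass and tail length are log-transformed first.  A constant column
    maps to all zeros rather than NaN — it carries no dissimilarity
    information either way.
    """
    out = table.values.copy()
    continuous = [
        c for c in out.columns if table.meta.get("kind", pd.Series()).get(c, "continuous") == "continuous"
    ]
    for col in continuous:
        x = out[col].to_numpy(dtype=float)
        lo, hi = x.min(), x.max()
        if hi - lo <= 0:
            out[col] = 0.0  # constant column: carries no information
            continue
        if abs(lo) <= 1e-12 and abs(hi - 1.0) <= 1e-12:
            continue  # already spans [0, 1]: idempotent
        if col in LOG_BEFORE_SCALING:
            if lo <= 0:
                raise ValueError(f"non-positive values in {col!r}; cannot log-transform")
            x = np.log(x)
            lo, hi = x.min(), x.max()
        out[col] = (x - lo) / (hi - lo)
    return TraitTable(values=out, meta=table.meta, nonnative=table.nonnative)


def screen_collinearity(
    table: TraitTable, threshold: float = 0.70
) -> tuple[TraitTable, CollinearityReport]:
    """Drop traits until no within-service pair has |Pearson r| > threshold.

    The screen runs separately inside the cultural and regulating sets
    (cross-service correlation is irrelevant: the two sets never enter the
    same dissimilarity).  At each step the worst-offending pair is found and
    the member with the larger mean absolute correlation against all other
    retained columns is removed; this is deterministic given column order.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    report = CollinearityReport(threshold=threshold, scope="per-service")
    keep_all: list[str] = []
    for service in (CULTURAL, REGULATING):
        cols = table.service_columns(service)
        if not cols:
            continue
        keep = list(cols)
        while len(keep) > 1:
            corr = table.values[keep].corr().to_numpy()
            corr = np.nan_to_num(corr, nan=0.0)  # constant columns: no correlation
            np.fill_diagonal(corr, 0.0)
            absmax = np.abs(corr).max()
            if absmax <= threshold:
                break
            i, j = np.unravel_index(np.abs(corr).argmax(), corr.shape)
            mean_abs = np.abs(corr).mean(axis=0)
            drop = i if mean_abs[i] >= mean_abs[j] else j
            partner = j if drop == i else i
            report.dropped.append(
                {
                    "trait": keep[drop],
                    "partner": keep[partner],
                    "r": float(corr[i, j]),
                    "service": service,
                }
            )
            del keep[drop]
        keep_all.extend(keep)
    if not keep_all:
        raise ValueError("collinearity screen removed every trait")
    return table.subset(keep_all), report


def prepare_traits(
    raw: TraitTable, *, threshold: float = 0.70
) -> tuple[TraitTable, CollinearityReport]:
    """Full preparation: derive, restrict to analysis traits, scale, screen.

    Returns the analysis-ready table (all columns in [0, 1], metadata for
    every retained trait) and the collinearity report.
    """
    t = derive_relative_tail_length(raw)
    t = derive_inverse_body_mass(t)
    meta = default_trait_meta()
    analysis_cols = [c for c in meta.index if c in t.values.columns]
    t = TraitTable(values=t.values[analysis_cols], meta=meta.loc[analysis_cols], nonnative=t.nonnative)
    t = scale_continuous(t)
    return screen_collinearity(t, threshold=threshold)
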