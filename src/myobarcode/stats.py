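"""Downstream kinetics and descriptive statistics.

Percent changes of population counts, ordinary-least-squares nuclear-domain
fits (myofiber volume regressed on myonucleus count), weekly transcript
reduction rates, delta-delta-Ct qPCR fold changes, autophagic-puncta
fractions, newborn-fiber cluster detection from label-map adjacency, and
growth summaries. Hypothesis testing is out of scope: output is descriptive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "NuclearDomainFit",
    "QPCRResult",
    "percent_change",
    "nuclear_domain_fit",
    "weekly_reduction_rate",
    "ddct_fold_change",
    "puncta_fraction",
    "detect_birth_clusters",
    "summarize_growth",
    "format_percent",
]


@dataclass
class NuclearDomainFit:
    """OLS fit of volume (µm³) on nucleus count: V = slope*N + intercept."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must be in [0, 1]")


@dataclass
class QPCRResult:
    """Per-biological-sample ddCt quantities and replicate summaries."""

    table: pd.DataFrame          # sample-level ΔCt, ΔΔCt, fold change
    group_means: pd.DataFrame    # per-group mean/sd of fold change

    @property
    def fold_changes(self) -> pd.Series:
        return self.table["fold_change"]


def percent_change(before: float, after: float) -> float:
    """(after - before) / before × 100; requires before > 0."""
    if before <= 0:
        raise ValueError("before must be > 0")
    return (after - before) / before * 100.0


def nuclear_domain_fit(volumes, nucleus_counts) -> NuclearDomainFit:
    """OLS of fiber volume on nucleus count: slope is the nuclear-domain size.

    Requires at least 3 fibers and non-constant nucleus counts.
    """
    v = np.asarray(volumes, dtype=float)
    n = np.asarray(nucleus_counts, dtype=float)
    if len(v) < 3 or len(v) != len(n):
        raise ValueError("need >= 3 paired observations")
    if np.ptp(n) == 0:
        raise ValueError("degenerate design: nucleus counts all equal")
    res = sps.linregress(n, v)
    r2 = float(res.rvalue ** 2)
    if math.isnan(r2):  # zero variance in volume: no explainable variation
        r2 = 0.0
    return NuclearDomainFit(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=r2)


def weekly_reduction_rate(levels: dict[float, float],
                          convention: str = "linear") -> float:
    """Reduction rate of a normalized abundance, percentage points per week.

    ``levels`` maps time in weeks to normalized abundance (first level > 0).
    The default linear convention divides the total percent reduction by the
    elapsed weeks; the exponential variant reports the per-week decay
    percentage 100*(1 - (l_end/l_0)^(1/weeks)).
    """
    times = sorted(levels)
    if len(times) < 2:
        raise ValueError("need >= 2 time points")
    if levels[times[0]] <= 0:
        raise ValueError("first level must be > 0")
    weeks = times[-1] - times[0]
    if weeks <= 0:
        raise ValueError("non-monotone time grid")
    l0, l1 = levels[times[0]], levels[times[-1]]
    if convention == "linear":
        return (l0 - l1) / l0 * 100.0 / weeks
    if convention == "exponential":
        return 100.0 * (1.0 - (l1 / l0) ** (1.0 / weeks))
    raise ValueError("convention must be 'linear' or 'exponential'")


def ddct_fold_change(ct_table: pd.DataFrame, reference_gene: str,
                     control_group, group_col: str = "time",
                     target_gene: str | None = None) -> QPCRResult:
    """Relative qPCR quantification by the delta-delta-Ct method.

    Technical replicates are averaged within each biological replicate
    first; ΔCt = Ct_target − Ct_reference per biological sample; ΔΔCt is
    taken against the control group's mean ΔCt; fold change = 2^−ΔΔCt
    (amplification efficiency fixed at 2.0). Adding a constant Ct offset to
    every well leaves fold changes unchanged.
    """
    required = {group_col, "bio_rep", "gene", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"ct table must have columns {sorted(required)}")
    genes = set(ct_table["gene"].unique())
    if reference_gene not in genes:
        raise ValueError(f"reference gene {reference_gene!r} absent")
    if target_gene is None:
        targets = genes - {reference_gene}
        if len(targets) != 1:
            raise ValueError("target gene ambiguous; pass target_gene")
        target_gene = targets.pop()

    bio = (ct_table.groupby([group_col, "bio_rep", "gene"])["ct"]
           .mean().unstack("gene"))
    if bio[reference_gene].isna().any() or bio[target_gene].isna().any():
        raise ValueError("missing reference or target Ct for some sample")
    dct = (bio[target_gene] - bio[reference_gene]).rename("dct")
    groups = dct.index.get_level_values(group_col)
    if control_group not in set(groups):
        raise ValueError(f"control group {control_group!r} absent")
    control_mean = dct[groups == control_group].mean()
    ddct = (dct - control_mean).rename("ddct")
    fold = np.power(2.0, -ddct).rename("fold_change")
    table = pd.concat([dct, ddct, fold], axis=1).reset_index()
    gm = (table.groupby(group_col)["fold_change"]
          .agg(["mean", "std", "count"]).reset_index())
    return QPCRResult(table=table, group_means=gm)


def puncta_fraction(fiber_table: pd.DataFrame, group: str
                    ) -> tuple[float, int, int]:
    """Percent of fibers in a group carrying autophagic puncta, with counts.

    ``group`` is 'deformed' or 'normal'; fiber_table needs boolean columns
    ``deformed`` and ``puncta``.
    """
    if group not in ("deformed", "normal"):
        raise ValueError("group must be 'deformed' or 'normal'")
    sel = fiber_table["deformed"] if group == "deformed" \
        else ~fiber_table["deformed"].astype(bool)
    sub = fiber_table[sel]
    if len(sub) == 0:
        raise ValueError(f"empty group {group!r}")
    pos = int(sub["puncta"].sum())
    return 100.0 * pos / len(sub), pos, int(len(sub))


def format_percent(p: float) -> str:
    """Report convention: nearest integer, except <1% shown to one decimal."""
    if p < 1.0:
        return f"{p:.1f}%"
    return f"{round(p):.0f}%"


def detect_birth_clusters(newborn_ids: set[int], labels: np.ndarray,
                          min_size: int = 5) -> list[list[int]]:
    """Clusters of adjacent concurrent newborn fibers in a label map.

    Adjacency is rook (4-connected) contact between labels; clusters are
    connected components of the newborn-adjacency graph with at least
    ``min_size`` members (five or more adjacent newborns by default).
    Returns cluster member lists sorted by size descending, then by smallest
    member id; invariant to fiber-id permutation up to that canonical order.
    """
    labels = np.asarray(labels)
    ids = sorted(newborn_ids)
    if not ids:
        return []
    idx = {fid: i for i, fid in enumerate(ids)}
    pairs = set()
    for sh in ((0, 1), (1, 0)):
        a = labels[: labels.shape[0] - sh[0], : labels.shape[1] - sh[1]]
        b = labels[sh[0]:, sh[1]:]
        diff = a != b
        for la, lb in zip(a[diff].ravel(), b[diff].ravel()):
            la, lb = int(la), int(lb)
            if la in idx and lb in idx:
                pairs.add((min(la, lb), max(la, lb)))
    n = len(ids)
    if pairs:
        rows, cols = zip(*((idx[a], idx[b]) for a, b in pairs))
        adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    else:
        adj = coo_matrix((n, n))
    n_comp, comp = connected_components(adj, directed=False)
    clusters = []
    for c in range(n_comp):
        members = [ids[i] for i in range(n) if comp[i] == c]
        if len(members) >= min_size:
            clusters.append(sorted(members))
    clusters.sort(key=lambda m: (-len(m), m[0]))
    return clusters


def summarize_growth(animal_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-time descriptive growth summary across animals (mean ± sd).

    Each table is one animal's fiber table with columns ``time``,
    ``fiber_id``, ``volume``, ``nucleus_count``, ``myotome_id``. Empty
    myotomes are excluded with a warning; a single animal reports NaN sd.
    """
    if not animal_tables:
        raise ValueError("need >= 1 animal")
    per_animal = []
    for i, tab in enumerate(animal_tables):
        if len(tab) == 0:
            warnings.warn(f"animal {i}: empty table excluded")
            continue
        g = tab.groupby("time").agg(
            n_fibers=("fiber_id", "count"),
            total_nuclei=("nucleus_count", "sum"),
            mean_volume=("volume", "mean")).reset_index()
        g["animal"] = i
        per_animal.append(g)
    if not per_animal:
        raise ValueError("all animal tables empty")
    allg = pd.concat(per_animal, ignore_index=True)
    out = (allg.groupby("time")
           .agg(n_fibers_mean=("n_fibers", "mean"),
                n_fibers_sd=("n_fibers", "std"),
                total_nuclei_mean=("total_nuclei", "mean"),
                total_nuclei_sd=("total_nuclei", "std"),
                mean_volume_mean=("mean_volume", "mean"),
                mean_volume_sd=("mean_volume", "std"),
                n_animals=("animal", "nunique"))
           .reset_index().sort_values("time").reset_index(drop=True))
    return out
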