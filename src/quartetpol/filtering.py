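"""Topology support scores, RISK/DIST filters, and threshold optimisation.

For each species-quartet the raw support of topology x is
``S(x) = Na(x) - Nc(x)``: observed synapomorphies minus the expected
convergent (chance-similarity) count under the rival fitted models.
Negative raw supports are clamped to zero and the clamped values are
normalised to a three-way score s(x) in [0, 1].  Two filters then decide
whether a quartet's signal is trustworthy:

* DIST rejects quartets whose best and second-best topologies are nearly
  tied (support distance SD12 = s(best) - s(second) below L_DIST);
* RISK rejects quartets whose winning topology is dominated by expected
  convergence (RISK = Nc(best)/Na(best) above L_RISK).

A quartet is retained only if it passes both filters; rejected quartets
are dropped entirely — the second-best topology never substitutes for the
best one.  Thresholds are optimised per clade-quartet by a grid search
that balances post-filter decisiveness against the retained fraction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix_io import CladeAssignment
from .quartets import TOPOLOGY_IDS, PatternCounts, SpeciesQuartet

logger = logging.getLogger(__name__)

RETAINED = "retained"
REJECTED_DIST = "rejected_dist"
REJECTED_RISK = "rejected_risk"
UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class SpeciesQuartetScore:
    """Per-quartet support, SD12 and RISK, plus filter status."""

    quartet: SpeciesQuartet
    na: dict[str, int]
    nc: dict[str, float]
    raw: dict[str, float]
    s: dict[str, float] | None  # None when uninformative
    best: str | None
    second: str | None
    sd12: float | None
    risk: float | None
    status: str = RETAINED

    @property
    def informative(self) -> bool:
        return self.s is not None


@dataclass(frozen=True)
class FilterThresholds:
    """DIST and RISK cutoffs, either optimised or user-supplied."""

    l_dist: float
    l_risk: float
    provenance: str = "optimized"

    def __post_init__(self) -> None:
        if not (0.0 <= self.l_dist <= 1.0 and 0.0 <= self.l_risk <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")


def compute_risk(na_best: float, nc_best: float) -> float:
    """RISK = Nc(best)/Na(best); +inf when the best topology has no Na."""
    if na_best <= 0:
        return math.inf
    return nc_best / na_best


def score_quartet(
    quartet: SpeciesQuartet,
    pc: PatternCounts,
    nc: Mapping[str, float],
) -> SpeciesQuartetScore:
    """Raw and normalised topology supports for one species-quartet.

    Negative raw supports are clamped to 0 before normalisation; if no
    topology has positive support the quartet is marked uninformative.
    Exact ties for best are broken by canonical topology order (logged).
    """
    raw = {x: float(pc.na[x]) - float(nc[x]) for x in TOPOLOGY_IDS}
    clamped = {x: max(v, 0.0) for x, v in raw.items()}
    total = sum(clamped.values())
    if total <= 0.0:
        return SpeciesQuartetScore(
            quartet=quartet,
            na=dict(pc.na),
            nc=dict(nc),
            raw=raw,
            s=None,
            best=None,
            second=None,
            sd12=None,
            risk=None,
            status=UNINFORMATIVE,
        )
    s = {x: clamped[x] / total for x in TOPOLOGY_IDS}
    order = sorted(TOPOLOGY_IDS, key=lambda x: (-s[x], TOPOLOGY_IDS.index(x)))
    best, second = order[0], order[1]
    if s[best] == s[second]:
        logger.info("tie for best topology in quartet %s; canonical order used", quartet.id)
    sd12 = s[best] - s[second]
    risk = compute_risk(pc.na[best], nc[best])
    return SpeciesQuartetScore(
        quartet=quartet,
        na=dict(pc.na),
        nc=dict(nc),
        raw=raw,
        s=s,
        best=best,
        second=second,
        sd12=sd12,
        risk=risk,
        status=RETAINED,
    )


def _passes(score: SpeciesQuartetScore, th: FilterThresholds) -> str:
    if not score.informative:
        return UNINFORMATIVE
    if score.sd12 < th.l_dist:
        return REJECTED_DIST
    if score.risk > th.l_risk:
        return REJECTED_RISK
    return RETAINED


def apply_filters(
    scores: Sequence[SpeciesQuartetScore], thresholds: FilterThresholds
) -> list[SpeciesQuartetScore]:
    """Retain quartets with SD12 >= L_DIST and RISK <= L_RISK (both inclusive).

    DIST is checked first purely for reporting the rejection reason; the
    retained set does not depend on the order.  Idempotent.
    """
    return [replace(sc, status=_passes(sc, thresholds)) for sc in scores]


def _median_margin(scores: Sequence[SpeciesQuartetScore]) -> float:
    """Best-minus-second margin of per-topology medians over retained scores."""
    med = {
        x: float(np.median([sc.s[x] for sc in scores])) for x in TOPOLOGY_IDS
    }
    vals = sorted(med.values(), reverse=True)
    return vals[0] - vals[1]


def _quantile_grid(values: np.ndarray, grid_points: int = 10) -> np.ndarray:
    """Observed-value quantiles (default deciles) plus the endpoints 0 and 1."""
    qs = (
        np.quantile(values, np.linspace(0.0, 1.0, grid_points + 1))
        if values.size
        else np.array([])
    )
    grid = np.unique(np.concatenate([qs, [0.0, 1.0]]))
    return np.unique(np.clip(grid, 0.0, 1.0))


def optimize_thresholds(
    scores: Sequence[SpeciesQuartetScore],
    grid_points: int = 10,
) -> FilterThresholds:
    """Grid-search L_DIST/L_RISK for one clade-quartet's scores.

    Candidates are the deciles of the observed SD12 and RISK values plus
    the endpoints 0 and 1.  The objective is the post-filter clade-quartet
    median margin times the square root of the retained fraction, subject
    to at least one retained quartet; ties prefer the larger retained set,
    then the larger L_RISK, then the smaller L_DIST.  Preferring the
    larger equivalent L_RISK makes an ineffective risk filter report the
    saturated threshold 1.0 (informative quartets always have RISK < 1,
    since the winning topology must have Na > Nc), which is how heavily
    conflicted clade combinations surface in the threshold report.
    """
    informative = [sc for sc in scores if sc.informative]
    if not informative:
        raise ValueError("no informative quartets; thresholds undefined")
    sd = np.array([sc.sd12 for sc in informative])
    risk = np.array([min(sc.risk, 1.0) if math.isfinite(sc.risk) else 1.0 for sc in informative])
    dist_grid = _quantile_grid(sd, grid_points)
    risk_grid = _quantile_grid(risk, grid_points)
    n = len(informative)
    best_key = None
    best_th = None
    for ld in dist_grid:
        for lr in risk_grid:
            kept = [
                sc
                for sc in informative
                if sc.sd12 >= ld and sc.risk <= lr
            ]
            if not kept:
                continue
            frac = len(kept) / n
            objective = _median_margin(kept) * math.sqrt(frac)
            key = (objective, len(kept), lr, -ld)
            if best_key is None or key > best_key:
                best_key = key
                best_th = FilterThresholds(l_dist=float(ld), l_risk=float(lr))
    assert best_th is not None  # grid always contains (0, 1): everything kept
    return best_th


def optimize_thresholds_by_clade_quartet(
    scores: Sequence[SpeciesQuartetScore],
    grid_points: int = 10,
) -> dict[str, FilterThresholds]:
    """Per-clade-quartet optimised thresholds; empty groups are skipped."""
    groups: dict[str, list[SpeciesQuartetScore]] = {}
    for sc in scores:
        groups.setdefault(sc.quartet.clade_quartet.id, []).append(sc)
    out: dict[str, FilterThresholds] = {}
    for cq_id, group in sorted(groups.items()):
        if not any(sc.informative for sc in group):
            logger.warning("clade-quartet %s has no informative quartet; marked empty", cq_id)
            continue
        out[cq_id] = optimize_thresholds(group, grid_points)
    return out


def filter_scores(
    scores: Sequence[SpeciesQuartetScore],
    thresholds: Mapping[str, FilterThresholds],
) -> list[SpeciesQuartetScore]:
    """Apply per-clade-quartet thresholds across the full score set."""
    out = []
    for sc in scores:
        th = thresholds.get(sc.quartet.clade_quartet.id)
        if th is None:
            out.append(replace(sc, status=UNINFORMATIVE if not sc.informative else sc.status))
            continue
        out.append(replace(sc, status=_passes(sc, th)))
    return out


def rejection_summary(
    scores: Iterable[SpeciesQuartetScore],
    assignment: CladeAssignment,
    flag_threshold: float = 80.0,
) -> pd.DataFrame:
    """Per-species (x clade-quartet) participation/rejection table.

    Flags species at >= ``flag_threshold`` percent rejections (partial)
    and at 100 percent (complete), following the skull-mark convention of
    per-species rejection reporting.
    """
    rows = []
    for sc in scores:
        rejected = sc.status in (REJECTED_DIST, REJECTED_RISK)
        for sp in sc.quartet.ingroup_species:
            rows.append(
                {
                    "species": sp,
                    "clade": assignment.clade_of[sp],
                    "clade_quartet": sc.quartet.clade_quartet.id,
                    "rejected": rejected,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["species", "clade", "clade_quartet", "n_quartets", "n_rejected", "pct_rejected", "flag"]
        )
    df = pd.DataFrame(rows)
    grouped = (
        df.groupby(["species", "clade", "clade_quartet"], as_index=False)
        .agg(n_quartets=("rejected", "size"), n_rejected=("rejected", "sum"))
    )
    grouped["pct_rejected"] = 100.0 * grouped["n_rejected"] / grouped["n_quartets"]
    grouped["flag"] = np.select(
        [grouped["pct_rejected"] >= 100.0, grouped["pct_rejected"] >= flag_threshold],
        ["complete", "partial"],
        default="",
    )
    return grouped.sort_values(["clade_quartet", "species"]).reset_index(drop=True)


def species_rejection_totals(summary: pd.DataFrame) -> pd.DataFrame:
    """Collapse a rejection summary over clade-quartets to one row per species."""
    if summary.empty:
        return summary
    tot = (
        summary.groupby(["species", "clade"], as_index=False)
        .agg(n_quartets=("n_quartets", "sum"), n_rejected=("n_rejected", "sum"))
    )
    tot["pct_rejected"] = 100.0 * tot["n_rejected"] / tot["n_quartets"]
    return tot.sort_values("pct_rejected", ascending=False).reset_index(drop=True)
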