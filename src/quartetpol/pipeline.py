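"""End-to-end orchestration: alignment -> quartet scores -> filters -> ranking.

``analyze`` is the library entry point used by the CLI, the test-suite
and downstream scripts; ``run_pipeline`` wraps it with config handling
and writes the full report directory (scores, summaries, ranking,
rejection table, ternary coordinates, provenance log).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import dendropy

from . import __version__
from .matrix_io import (
    CladeAssignment,
    Supermatrix,
    load_clade_assignment,
    read_alignment,
)
from .quartets import (
    TOPOLOGY_IDS,
    PatternCounts,
    SpeciesQuartet,
    check_min_informative,
    count_polarized_patterns,
    enumerate_clade_quartets,
    enumerate_species_quartets,
    extract_quartet_subalignment,
)
from .models import UninformativeQuartetError, convergence_estimates, fit_gtr_gamma_i
from .filtering import (
    FilterThresholds,
    SpeciesQuartetScore,
    UNINFORMATIVE,
    filter_scores,
    optimize_thresholds_by_clade_quartet,
    rejection_summary,
    score_quartet,
    species_rejection_totals,
)
from .supertree import CladeTreeRanking, summarize_all, rank_trees, to_newick
from .simulate import SimulatedDataset, preset_scenarios, simulate_dataset

logger = logging.getLogger(__name__)

_TRIANGLE_CORNERS = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3.0) / 2.0]])


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of (``alignment_path`` + ``clades_path``) or ``preset``
    must be given.
    """

    out_dir: Path
    alignment_path: Path | None = None
    clades_path: Path | None = None
    alignment_format: str = "fasta"
    preset: str | None = None
    seed: int = 0
    n_loci: int = 100
    locus_length: int = 500
    min_cols: int = 20
    risk_mode: str = "mean"
    l_dist: float | None = None  # fixed-threshold overrides
    l_risk: float | None = None
    workers: int = 1

    def __post_init__(self) -> None:
        has_paths = self.alignment_path is not None and self.clades_path is not None
        if has_paths == (self.preset is not None):
            raise ValueError("give either input paths or a preset, not both")
        if self.risk_mode not in ("mean", "max"):
            raise ValueError("risk_mode must be 'mean' or 'max'")

    def digest(self) -> str:
        payload = {k: str(v) for k, v in sorted(vars(self).items())}
        return hashlib.sha256(json.dumps(payload).encode()).hexdigest()[:16]


@dataclass
class AnalysisResult:
    """Everything the pipeline computed for one dataset."""

    assignment: CladeAssignment
    pattern_counts: dict[str, PatternCounts]
    scores: list[SpeciesQuartetScore]  # post-filter statuses
    unfiltered_scores: list[SpeciesQuartetScore]
    thresholds: dict[str, FilterThresholds]
    summaries: dict
    ranking: CladeTreeRanking | None  # None when nothing could be scored
    excluded_quartets: list[SpeciesQuartet] = field(default_factory=list)


def _score_one(
    sq: SpeciesQuartet,
    rows,
    usable,
    pc: PatternCounts,
    risk_mode: str,
) -> SpeciesQuartetScore | None:
    try:
        fits = {x: fit_gtr_gamma_i(rows, usable, x) for x in TOPOLOGY_IDS}
    except UninformativeQuartetError:
        return None
    nc = convergence_estimates(fits, pc.n_usable, mode=risk_mode)
    return score_quartet(sq, pc, nc)


def analyze(
    matrix: Supermatrix,
    assignment: CladeAssignment,
    min_cols: int = 20,
    risk_mode: str = "mean",
    fixed_thresholds: FilterThresholds | None = None,
    progress: bool = False,
    workers: int = 1,
) -> AnalysisResult:
    """Score, filter and rank clade trees for one supermatrix.

    Stages: enumerate clade- and species-quartets; count polarized site
    patterns; fit GTR+Γ+I per topology and estimate the convergent signal
    Nc; compute supports, SD12 and RISK; optimise (or take fixed)
    RISK/DIST thresholds per clade-quartet; aggregate medians; rank all
    rooted clade trees exhaustively.  ``workers`` > 1 parallelises the
    per-quartet model fits; the reduction order is fixed, so results are
    independent of the worker count.
    """
    assignment.validate_against(matrix.taxa)
    pattern_counts: dict[str, PatternCounts] = {}
    excluded: list[SpeciesQuartet] = []
    tasks = []
    clade_quartets = enumerate_clade_quartets(assignment)
    for cq in clade_quartets:
        for sq in enumerate_species_quartets(cq, assignment):
            rows, usable = extract_quartet_subalignment(matrix, sq)
            pc = count_polarized_patterns(rows, usable)
            pattern_counts[sq.id] = pc
            if not check_min_informative(pc, min_cols):
                excluded.append(sq)
                continue
            tasks.append((sq, rows, usable, pc))
    if workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=workers)(
            delayed(_score_one)(sq, rows, usable, pc, risk_mode)
            for sq, rows, usable, pc in tasks
        )
    else:
        results = [
            _score_one(sq, rows, usable, pc, risk_mode)
            for sq, rows, usable, pc in tasks
        ]
    scores: list[SpeciesQuartetScore] = []
    for (sq, _, _, _), sc in zip(tasks, results):
        if sc is None:
            excluded.append(sq)
        else:
            scores.append(sc)
            if progress:
                logger.info("scored quartet %s (%s)", sq.id, sq.clade_quartet.id)
    if fixed_thresholds is not None:
        thresholds = {cq.id: fixed_thresholds for cq in clade_quartets}
    else:
        thresholds = optimize_thresholds_by_clade_quartet(scores)
    filtered = filter_scores(scores, thresholds)
    summaries = summarize_all(filtered)
    if summaries and any(not s.empty for s in summaries.values()):
        ranking = rank_trees(summaries, assignment.ingroup_clades)
    else:
        logger.warning("no clade-quartet carries retained signal; no ranking produced")
        ranking = None
    return AnalysisResult(
        assignment=assignment,
        pattern_counts=pattern_counts,
        scores=filtered,
        unfiltered_scores=scores,
        thresholds=thresholds,
        summaries=summaries,
        ranking=ranking,
        excluded_quartets=excluded,
    )


# ---------------------------------------------------------------------------
# report tables


def scores_table(
    result: AnalysisResult, thresholds: Mapping[str, FilterThresholds]
) -> pd.DataFrame:
    rows = []
    for sc in result.scores:
        cq_id = sc.quartet.clade_quartet.id
        th = thresholds.get(cq_id)
        pc = result.pattern_counts[sc.quartet.id]
        row = {
            "quartet": sc.quartet.id,
            "clade_quartet": cq_id,
            "n_usable": pc.n_usable,
            "n_informative": pc.n_informative,
            "status": sc.status,
            "best": sc.best or "",
            "second": sc.second or "",
            "sd12": sc.sd12 if sc.sd12 is not None else np.nan,
            "risk": sc.risk if sc.risk is not None else np.nan,
            "l_dist": th.l_dist if th else np.nan,
            "l_risk": th.l_risk if th else np.nan,
        }
        for x in TOPOLOGY_IDS:
            row[f"na_{x}"] = sc.na[x]
            row[f"nc_{x}"] = sc.nc[x]
            row[f"s_{x}"] = sc.s[x] if sc.s else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def summaries_table(result: AnalysisResult) -> pd.DataFrame:
    rows = []
    for cq_id, summ in result.summaries.items():
        row = {
            "clade_quartet": cq_id,
            "n_retained": summ.n_retained,
            "n_total": summ.n_total,
            "empty": summ.empty,
        }
        for x in TOPOLOGY_IDS:
            row[f"median_{x}"] = summ.medians[x] if summ.medians else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def ranking_table(ranking: CladeTreeRanking) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(ranking.trees) + 1),
            "newick": ranking.newicks,
            "support": ranking.supports,
            "distance_to_best": ranking.distances(),
        }
    )


def ternary_coordinates(scores: Sequence[SpeciesQuartetScore]) -> pd.DataFrame:
    """Barycentric embedding of the three-way supports in the unit triangle.

    Corner k carries the weight s(xk); the centroid corresponds to the
    fully conflicted (1/3, 1/3, 1/3) case, edge midpoints to two-way
    conflict.
    """
    rows = []
    for sc in scores:
        if not sc.informative:
            continue
        w = np.array([sc.s[x] for x in TOPOLOGY_IDS])
        xy = w @ _TRIANGLE_CORNERS
        rows.append(
            {
                "quartet": sc.quartet.id,
                "clade_quartet": sc.quartet.clade_quartet.id,
                "x": xy[0],
                "y": xy[1],
                "status": sc.status,
            }
        )
    return pd.DataFrame(rows)


def barycentric_weights(x: float, y: float) -> np.ndarray:
    """Invert the ternary embedding back to the three support weights."""
    A = np.vstack([_TRIANGLE_CORNERS.T, np.ones(3)])
    return np.linalg.solve(A, np.array([x, y, 1.0]))


def root_to_tip_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Per-leaf sum of branch lengths from the root."""
    rows = []
    dist = {}
    for nd in tree.preorder_node_iter():
        parent = nd.parent_node
        dist[nd] = (dist[parent] if parent else 0.0) + (nd.edge.length or 0.0)
        if nd.is_leaf():
            rows.append(
                {"species": nd.taxon.label.replace(" ", "_"), "root_to_tip": dist[nd]}
            )
    return pd.DataFrame(rows).sort_values("species").reset_index(drop=True)


# ---------------------------------------------------------------------------
# run directory


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full pipeline per config; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset: SimulatedDataset | None = None
    if cfg.preset is not None:
        presets = preset_scenarios(cfg.seed, n_loci=cfg.n_loci, locus_length=cfg.locus_length)
        if cfg.preset not in presets:
            raise ValueError(
                f"unknown preset {cfg.preset!r}; choose from {sorted(presets)}"
            )
        dataset = simulate_dataset(presets[cfg.preset])
        matrix, assignment = dataset.supermatrix, dataset.assignment
    else:
        matrix = read_alignment(cfg.alignment_path, cfg.alignment_format)
        assignment = load_clade_assignment(cfg.clades_path)
    fixed = None
    if cfg.l_dist is not None or cfg.l_risk is not None:
        fixed = FilterThresholds(
            l_dist=cfg.l_dist if cfg.l_dist is not None else 0.0,
            l_risk=cfg.l_risk if cfg.l_risk is not None else 1.0,
            provenance="user",
        )
    result = analyze(
        matrix,
        assignment,
        min_cols=cfg.min_cols,
        risk_mode=cfg.risk_mode,
        fixed_thresholds=fixed,
        workers=cfg.workers,
    )
    _write_tsv(scores_table(result, result.thresholds), out / "scores.tsv")
    _write_tsv(summaries_table(result), out / "summaries.tsv")
    if result.ranking is None:
        raise RuntimeError(
            f"no informative quartet signal; partial outputs written to {out}"
        )
    _write_tsv(ranking_table(result.ranking), out / "ranking.tsv")
    _write_tsv(
        rejection_summary(result.scores, assignment), out / "rejections.tsv"
    )
    _write_tsv(
        species_rejection_totals(rejection_summary(result.scores, assignment)),
        out / "rejections_by_species.tsv",
    )
    _write_tsv(ternary_coordinates(result.scores), out / "ternary.tsv")
    (out / "best_tree.nwk").write_text(result.ranking.newicks[0] + "\n")
    ranking_json = {
        "best": result.ranking.newicks[0],
        "second_best": result.ranking.newicks[1],
        "supports": result.ranking.supports.tolist(),
        "newicks": result.ranking.newicks,
        "thresholds": {
            k: {"l_dist": v.l_dist, "l_risk": v.l_risk, "provenance": v.provenance}
            for k, v in result.thresholds.items()
        },
    }
    (out / "ranking.json").write_text(json.dumps(ranking_json, indent=2))
    log = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.digest(),
        "n_quartets_scored": len(result.scores),
        "n_quartets_excluded_preliminary": len(result.excluded_quartets),
    }
    if dataset is not None:
        log["provenance"] = dataset.provenance
        (out / "true_tree.nwk").write_text(dataset.species_tree_newick + "\n")
        (out / "true_clade_tree.nwk").write_text(
            to_newick(dataset.true_clade_tree, ";") + "\n"
        )
    (out / "run.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return out


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
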