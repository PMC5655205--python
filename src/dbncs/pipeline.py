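"""End-to-end inference: expression matrix in, time-delayed GRN out.

Stage order: CMI2NI skeleton learning -> RO pruning -> per-edge delay
estimation -> component scoring + background standardization -> clique
orientation -> assembly. Everything downstream of the data is
deterministic, so identical inputs and configuration always give
byte-identical output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io_formats import ExpressionMatrix, TimeDelayedGRN
from .regulation_strength import ROConfig, prune_skeleton
from .scoring_assembly import (
    CSConfig,
    EdgeComponents,
    assemble,
    compute_components,
    decompose_cliques,
    orient_clique,
    standardize_components,
)
from .structure_learning import Skeleton, SkeletonConfig, learn_skeleton
from .temporal import DelayMatrix, build_delay_matrix

__all__ = ["PipelineConfig", "InferenceResult", "infer_grn", "ranking_scores"]

log = logging.getLogger("dbncs")


@dataclass
class PipelineConfig:
    """All tunables of one inference run (defaults = small-benchmark setting)."""

    theta: float = 0.15
    order_limit: int | None = None
    aggregation: str = "max"
    lam: float = 1.0
    theta0: float | None = None  # None: inherit theta
    max_delay: int = 5
    sigma: float = 0.6
    omega: float = 0.5
    change_eps: float = 0.0

    def skeleton_config(self) -> SkeletonConfig:
        return SkeletonConfig(
            theta=self.theta, order_limit=self.order_limit, aggregation=self.aggregation
        )

    def ro_config(self) -> ROConfig:
        theta0 = self.theta if self.theta0 is None else self.theta0
        return ROConfig(lam=self.lam, theta0=theta0)

    def cs_config(self) -> CSConfig:
        return CSConfig(sigma=self.sigma, omega=self.omega)


@dataclass
class InferenceResult:
    grn: TimeDelayedGRN
    skeleton: Skeleton
    pruned: Skeleton
    delays: DelayMatrix
    components: EdgeComponents = field(repr=False)


def infer_grn(expr: ExpressionMatrix, config: PipelineConfig | None = None) -> InferenceResult:
    """Run the full pipeline on one expression matrix."""
    config = config or PipelineConfig()
    log.info(
        "inference: N=%d genes, T=%d time points, theta=%g, k=%d, "
        "lambda=%g, sigma=%g, omega=%g, aggregation=%s",
        expr.n_genes, expr.n_timepoints, config.theta, config.max_delay,
        config.lam, config.sigma, config.omega, config.aggregation,
    )
    skel = learn_skeleton(expr, config.skeleton_config())
    log.info("skeleton: %d edges, order reached %d", skel.n_edges, skel.order_reached)
    pruned = prune_skeleton(expr, skel, config.ro_config())
    log.info("after RO pruning: %d edges", pruned.n_edges)
    delays = build_delay_matrix(expr, pruned, config.max_delay)
    comp = standardize_components(
        compute_components(expr, pruned, delays, config.change_eps)
    )
    cs_cfg = config.cs_config()
    oriented = [
        orient_clique(clq, expr.gene_ids, delays, comp, cs_cfg)
        for clq in decompose_cliques(pruned)
    ]
    grn = assemble(oriented, expr.gene_ids, k_max=config.max_delay)
    log.info("final GRN: %d directed edges", grn.prior.n_edges)
    return InferenceResult(grn=grn, skeleton=skel, pruned=pruned, delays=delays, components=comp)


def ranking_scores(result: InferenceResult, config: PipelineConfig | None = None):
    """Edge-confidence map over ordered gene pairs, for ROC/AUC ranking.

    Pairs removed during skeleton learning or pruning score 0; both
    directions of every surviving clique get their comprehensive score
    before the orientation tie-break, so the ranking reflects the method's
    own confidence rather than the hard decision.
    """
    from .scoring_assembly import comprehensive_score

    cs_cfg = (config or PipelineConfig()).cs_config()
    genes = result.pruned.gene_ids
    comp = result.components
    scores: dict[tuple[str, str], float] = {}
    for (a, b) in comp.b_ro:
        scores[(genes[a], genes[b])] = comprehensive_score(
            comp.b_ro[(a, b)], comp.b_mi[(a, b)], comp.trs_val[(a, b)], cs_cfg
        )
    return scores
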