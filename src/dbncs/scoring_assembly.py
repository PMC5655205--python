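"""Comprehensive score, clique decomposition, orientation, assembly.

The pruned skeleton is decomposed losslessly into pair cliques — one per
surviving undirected edge. Inside each clique the two candidate directions
are scored with the comprehensive score

    CS = sigma * (omega * |beta_RO| + (1 - omega) * beta_MI)^2
         + (1 - sigma) * TRS^2

combining linear evidence (the RO regulation strength), non-linear evidence
(delay-aligned Gaussian MI) and dynamic evidence (TRS), each background-
standardized to [0, 1] over the population of all candidate ordered pairs
so the three components are commensurable. The higher-scoring direction
wins (exact ties break to the lexicographically smaller regulator and are
flagged); the oriented edges and their optimal delays assemble into the
final time-delayed GRN: prior network = directed edge union, transfer
network = the delay matrix restricted to those edges. Cross-slice structure
only — an edge connects slice t to slice t+delay, never within a slice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .info_theory import DegenerateInputError, gaussian_mi
from .io_formats import ExpressionMatrix, Network, TimeDelayedGRN
from .structure_learning import Skeleton
from .temporal import DegenerateTargetError, DelayMatrix, TRSInput, recombine, trs

__all__ = [
    "CSConfig",
    "Clique",
    "OrientedEdge",
    "EdgeComponents",
    "background_standardize",
    "comprehensive_score",
    "decompose_cliques",
    "compute_components",
    "standardize_components",
    "orient_clique",
    "assemble",
]


@dataclass
class CSConfig:
    """Comprehensive-score weights.

    sigma: trade-off between the (linear + non-linear) beta composite and
        the dynamic TRS term; in [0, 1], default 0.6. sigma = 1 ignores the
        dynamics entirely (the static-network setting).
    omega: weight of the RO strength against the MI component inside the
        beta composite; in [0, 1].
    """

    sigma: float = 0.6
    omega: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError("sigma must be in [0, 1]")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must be in [0, 1]")


@dataclass(frozen=True)
class Clique:
    """A co-expressed gene pair — the unit of orientation. i < j by index."""

    i: int
    j: int
    weight: float


@dataclass
class OrientedEdge:
    regulator: str
    target: str
    delay: int
    cs: float
    tie_broken: bool = False
    undirected: bool = False


@dataclass
class EdgeComponents:
    """Per-ordered-pair score components, raw or background-standardized."""

    b_ro: dict[tuple[int, int], float] = field(default_factory=dict)
    b_mi: dict[tuple[int, int], float] = field(default_factory=dict)
    trs_val: dict[tuple[int, int], float] = field(default_factory=dict)
    degenerate: set[tuple[int, int]] = field(default_factory=set)


def background_standardize(values: np.ndarray) -> np.ndarray:
    """Min-max normalize a component over the candidate-edge population.

    All-equal input maps to all-0.5 (no information either way). The output
    is invariant to affine transforms of the input.
    """
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.full_like(v, 0.5)
    return (v - lo) / (hi - lo)


def comprehensive_score(
    beta_ro: float, beta_mi: float, trs_val: float, config: CSConfig
) -> float:
    """CS of one candidate direction from its standardized components."""
    composite = config.omega * abs(beta_ro) + (1.0 - config.omega) * beta_mi
    return config.sigma * composite**2 + (1.0 - config.sigma) * trs_val**2


def decompose_cliques(skel: Skeleton) -> list[Clique]:
    """One pair clique per surviving skeleton edge (lossless by definition)."""
    return [Clique(i=i, j=j, weight=float(skel.weight[i, j])) for i, j in skel.edges()]


def compute_components(
    expr: ExpressionMatrix,
    skel: Skeleton,
    delays: DelayMatrix,
    change_eps: float = 0.0,
) -> EdgeComponents:
    """Raw CS components for both directions of every clique.

    beta_RO comes from the pruning stage (skeleton ``beta``; zeros if the
    skeleton was not pruned). beta_MI is the Gaussian MI of the series
    recombined at the direction's optimal delay, which is what makes the
    two directions distinguishable. TRS is computed on the same recombined
    series; a degenerate TRS (target never changes) is substituted with 0
    and a warning, and fully degenerate directions are flagged.
    """
    comp = EdgeComponents()
    beta = skel.beta if skel.beta is not None else np.zeros_like(skel.weight)
    for clq in decompose_cliques(skel):
        for a, b in ((clq.i, clq.j), (clq.j, clq.i)):
            comp.b_ro[(a, b)] = float(beta[a, b])
            m = int(delays.delays[a, b])
            if m < 1:
                # delay estimation failed for this direction
                comp.b_mi[(a, b)] = 0.0
                comp.trs_val[(a, b)] = 0.0
                comp.degenerate.add((a, b))
                continue
            xa, yb = recombine(expr.values[a], expr.values[b], m)
            try:
                comp.b_mi[(a, b)] = gaussian_mi(xa, yb)
            except DegenerateInputError:
                comp.b_mi[(a, b)] = 0.0
                comp.degenerate.add((a, b))
            try:
                comp.trs_val[(a, b)] = trs(
                    TRSInput(regulator_series=xa, target_series=yb), change_eps
                )
            except DegenerateTargetError:
                warnings.warn(
                    f"TRS degenerate for {expr.gene_ids[a]}->{expr.gene_ids[b]}; using 0"
                )
                comp.trs_val[(a, b)] = 0.0
    return comp


def standardize_components(comp: EdgeComponents) -> EdgeComponents:
    """Background-standardize each component over all candidate ordered pairs."""
    out = EdgeComponents(degenerate=set(comp.degenerate))
    for src, dst in (
        (comp.b_ro, "b_ro"),
        (comp.b_mi, "b_mi"),
        (comp.trs_val, "trs_val"),
    ):
        if not src:
            continue
        keys = list(src)
        norm = background_standardize(np.array([src[k] for k in keys]))
        getattr(out, dst).update(dict(zip(keys, norm)))
    return out


def orient_clique(
    clique: Clique,
    gene_ids: list[str],
    delays: DelayMatrix,
    components: EdgeComponents,
    config: CSConfig,
) -> OrientedEdge:
    """Pick the direction of one clique by comparing the two CS values.

    ``components`` must already be background-standardized. Exact ties go to
    the lexicographically smaller regulator with ``tie_broken`` set; if both
    directions were degenerate the edge is additionally flagged
    ``undirected``.
    """
    i, j = clique.i, clique.j
    cs = {}
    for a, b in ((i, j), (j, i)):
        cs[(a, b)] = comprehensive_score(
            components.b_ro[(a, b)],
            components.b_mi[(a, b)],
            components.trs_val[(a, b)],
            config,
        )
    both_degenerate = (i, j) in components.degenerate and (j, i) in components.degenerate
    if both_degenerate:
        warnings.warn(
            f"both directions degenerate for ({gene_ids[i]}, {gene_ids[j]}); "
            "emitting undirected-flagged edge"
        )
    tie = cs[(i, j)] == cs[(j, i)]
    if tie:
        a, b = (i, j) if gene_ids[i] < gene_ids[j] else (j, i)
    else:
        a, b = max(cs, key=cs.get)
    delay = int(delays.delays[a, b])
    return OrientedEdge(
        regulator=gene_ids[a],
        target=gene_ids[b],
        delay=max(delay, 1),
        cs=cs[(a, b)],
        tie_broken=tie,
        undirected=both_degenerate,
    )


def assemble(edges: list[OrientedEdge], gene_ids: list[str], k_max: int) -> TimeDelayedGRN:
    """Integrate oriented pair subnetworks into the final time-delayed GRN."""
    idx = {g: i for i, g in enumerate(gene_ids)}
    best: dict[tuple[str, str], OrientedEdge] = {}
    for e in edges:
        key = (e.regulator, e.target)
        if key in best:
            warnings.warn(f"duplicate directed edge {key}; keeping max-CS instance")
            if e.cs <= best[key].cs:
                continue
        best[key] = e
    n = len(gene_ids)
    delays = np.zeros((n, n), dtype=int)
    scores: dict[tuple[str, str], float] = {}
    edge_set: set[tuple[str, str]] = set()
    for (u, v), e in best.items():
        edge_set.add((u, v))
        delays[idx[u], idx[v]] = e.delay
        scores[(u, v)] = e.cs
    prior = Network(gene_ids=list(gene_ids), edges=edge_set, scores=dict(scores), directed=True)
    return TimeDelayedGRN(
        prior=prior, delays=DelayMatrix(delays=delays, k_max=k_max), edge_scores=scores
    )
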