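"""Co-regulatory (cooperativity) network construction.

Two regulators are linked when their regulons (the union of targets
each one activates or represses across the inferred network) share at
least ``min_shared`` targets and the overlap is significant at
``alpha`` under a one-sided hypergeometric test whose universe is the
set of distinct targets in the network. Edge strength is the Jaccard
coefficient |T_i ∩ T_j| / |T_i ∪ T_j|.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

from scipy.stats import hypergeom

from .grn import EvidenceSet

__all__ = [
    "CoopEdge",
    "CoRegNetwork",
    "jaccard",
    "edge_significance",
    "build_coregnet",
    "annotate_edges",
    "regulons_from_grn",
]

PPI = "ppi"
REGULATION = "regulation"
INFERRED = "inferred-only"


@dataclass(frozen=True)
class CoopEdge:
    tf_i: str
    tf_j: str
    shared_targets: int
    jaccard: float
    p_value: float
    evidence_tag: str = INFERRED

    def __post_init__(self):
        if self.tf_i == self.tf_j:
            raise ValueError("self-edges are not allowed")
        if self.tf_i > self.tf_j:  # canonical order
            lo, hi = self.tf_j, self.tf_i
            object.__setattr__(self, "tf_i", lo)
            object.__setattr__(self, "tf_j", hi)

    @property
    def pair(self) -> tuple:
        return (self.tf_i, self.tf_j)


@dataclass
class CoRegNetwork:
    """Regulator nodes (with regulon sizes) plus cooperative edges."""

    nodes: dict = field(default_factory=dict)  # regulator -> regulon size
    edges: list = field(default_factory=list)

    def __post_init__(self):
        for e in self.edges:
            if e.tf_i not in self.nodes or e.tf_j not in self.nodes:
                raise ValueError(f"edge {e.pair} references unknown node")


def jaccard(targets_i, targets_j) -> float:
    """|∩| / |∪| of two target sets."""
    a, b = set(targets_i), set(targets_j)
    if not a and not b:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(a & b) / len(a | b)


def edge_significance(overlap: int, n_i: int, n_j: int, universe: int) -> float:
    """One-sided overlap p-value P(X ≥ overlap), X hypergeometric.

    Models drawing ``n_j`` targets from a universe in which ``n_i`` are
    marked; the upper tail at the observed overlap quantifies how
    surprising the shared-target count is.
    """
    if not (0 <= overlap <= min(n_i, n_j) <= max(n_i, n_j) <= universe):
        raise ValueError(
            f"inconsistent counts: overlap={overlap}, n_i={n_i}, n_j={n_j}, universe={universe}"
        )
    return float(hypergeom.sf(overlap - 1, universe, n_i, n_j))


def regulons_from_grn(grn) -> dict:
    """Regulator → set of targets it activates or represses."""
    regulons: dict = {}
    for prog in grn:
        for r in prog.regulators:
            regulons.setdefault(r, set()).add(prog.target)
    return regulons


def build_coregnet(grn, min_shared: int = 5, alpha: float = 0.01) -> CoRegNetwork:
    """Build the cooperativity network from inferred programs.

    Keeps an edge only when both filters pass: shared targets ≥
    ``min_shared`` and hypergeometric p < ``alpha``.
    """
    programs = list(grn)
    if not programs:
        raise ValueError("cannot build a network from an empty GRN")
    regulons = regulons_from_grn(programs)
    universe = len({p.target for p in programs})
    nodes = {r: len(t) for r, t in regulons.items()}
    edges = []
    for a, b in itertools.combinations(sorted(regulons), 2):
        shared = regulons[a] & regulons[b]
        if len(shared) < min_shared:
            continue
        p = edge_significance(len(shared), len(regulons[a]), len(regulons[b]), universe)
        if p >= alpha:
            continue
        edges.append(
            CoopEdge(
                tf_i=a,
                tf_j=b,
                shared_targets=len(shared),
                jaccard=jaccard(regulons[a], regulons[b]),
                p_value=p,
            )
        )
    return CoRegNetwork(nodes=nodes, edges=edges)


def annotate_edges(net: CoRegNetwork, evidence: EvidenceSet | None) -> CoRegNetwork:
    """Tag each edge by its best external support.

    Precedence: protein–protein cooperation evidence > directed
    regulation evidence (either direction) > inferred-only. Idempotent.
    """
    if evidence is None:
        evidence = EvidenceSet()
    new_edges = []
    for e in net.edges:
        if evidence.has_cooperation(e.tf_i, e.tf_j):
            tag = PPI
        elif (e.tf_i, e.tf_j) in evidence.regulation_pairs or (
            e.tf_j,
            e.tf_i,
        ) in evidence.regulation_pairs:
            tag = REGULATION
        else:
            tag = INFERRED
        new_edges.append(replace(e, evidence_tag=tag))
    return CoRegNetwork(nodes=dict(net.nodes), edges=new_edges)
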