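"""Compound-disease network proximity on the PPI graph.

The raw proximity between a compound's target genes C_G and a disease's
genes D_G is the bidirectional closest-distance average

    raw(C_G, D_G) = [ Σ_{g∈C_G} min_{g'∈D_G} d(g, g')
                    + Σ_{g'∈D_G} min_{g∈C_G} d(g, g') ] / n_finite,

where d is the unweighted shortest-path length in the PPI network and
n_finite counts the terms that are defined: genes absent from the graph,
or with no path to the other set, contribute no term.  A pair with no
finite term at all is flagged undefined.

Raw distances are then min-max normalized over a batch and inverted,

    cds = 1 - (raw - min) / (max - min),

so the closest pair in the batch scores 1 and the farthest 0; undefined
pairs score 0.  Normalization runs globally over the batch by default,
or per disease.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Set

import networkx as nx

from .datamodel import DiseaseGeneMap, PPINetwork, TargetProfile
from .errors import EmptyGeneSetError


@dataclass
class ProximityResult:
    """Raw and normalized proximity for one (compound, disease) pair."""

    compound_id: str
    disease_id: str
    raw_distance: float  # NaN when undefined
    n_terms_used: int
    cds: Optional[float] = None

    @property
    def defined(self) -> bool:
        return self.n_terms_used > 0 and math.isfinite(self.raw_distance)


def distances_from_gene_set(graph: nx.Graph, genes: Set[str]) -> Dict[str, int]:
    """Shortest-path length from the *set* ``genes`` to every reachable node.

    Multi-source BFS; genes not present in the graph are ignored.  Returns
    an empty mapping when no member is in the graph.
    """
    sources = [g for g in genes if g in graph]
    if not sources:
        return {}
    return dict(nx.multi_source_dijkstra_path_length(graph, sources, weight=None))


def _proximity_terms(
    genes: Set[str], dist_from_other: Dict[str, int]
) -> List[int]:
    return [dist_from_other[g] for g in genes if g in dist_from_other]


def raw_proximity(
    compound_genes: Set[str],
    disease_genes: Set[str],
    network: PPINetwork,
    compound_id: str = "",
    disease_id: str = "",
) -> ProximityResult:
    """Raw bidirectional closest-distance proximity between two gene sets."""
    if not compound_genes or not disease_genes:
        raise EmptyGeneSetError("proximity requires two non-empty gene sets")
    if network.n_nodes == 0:
        raise EmptyGeneSetError("proximity requires a non-empty PPI network")
    g = network.graph
    from_disease = distances_from_gene_set(g, disease_genes)
    from_compound = distances_from_gene_set(g, compound_genes)
    terms = _proximity_terms(compound_genes, from_disease)
    terms += _proximity_terms(disease_genes, from_compound)
    n = len(terms)
    raw = sum(terms) / n if n else math.nan
    return ProximityResult(
        compound_id=compound_id,
        disease_id=disease_id,
        raw_distance=raw,
        n_terms_used=n,
    )


def normalize_cds(results: List[ProximityResult], mode: str = "global") -> List[ProximityResult]:
    """Set ``cds`` on a batch of proximity results by inverted min-max.

    ``mode="global"`` normalizes over the whole batch (default);
    ``mode="per_disease"`` normalizes within each disease separately.
    If all defined raw distances in a group are equal, every defined entry
    gets cds = 1; undefined entries always get cds = 0.  An empty batch,
    or a global batch with no defined entry, is fatal.
    """
    if mode not in ("global", "per_disease"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if not results:
        raise ValueError("cannot normalize an empty batch")

    if mode == "global":
        groups = {None: results}
    else:
        groups = {}
        for r in results:
            groups.setdefault(r.disease_id, []).append(r)

    any_defined = False
    for group in groups.values():
        raws = [r.raw_distance for r in group if r.defined]
        if raws:
            any_defined = True
        lo, hi = (min(raws), max(raws)) if raws else (0.0, 0.0)
        span = hi - lo
        for r in group:
            if not r.defined:
                r.cds = 0.0
            elif span == 0:
                r.cds = 1.0
            else:
                r.cds = 1.0 - (r.raw_distance - lo) / span
    if not any_defined:
        raise ValueError("no defined raw distance in batch; nothing to normalize")
    return results


def proximity_table(
    profiles: Dict[str, TargetProfile],
    disease_maps: Dict[str, DiseaseGeneMap],
    network: PPINetwork,
    mode: str = "global",
) -> List[ProximityResult]:
    """Proximity for every (compound profile, disease) pair, normalized.

    BFS distance maps are computed once per gene set and reused across
    pairs, which keeps the batch linear in |compounds| + |diseases| BFS
    runs instead of quadratic.
    """
    g = network.graph
    from_disease = {
        d: distances_from_gene_set(g, m.genes) for d, m in disease_maps.items()
    }
    from_compound = {
        c: distances_from_gene_set(g, p.targets) for c, p in profiles.items()
    }
    results: List[ProximityResult] = []
    for d in sorted(disease_maps):
        d_genes = disease_maps[d].genes
        for c in sorted(profiles):
            terms = _proximity_terms(profiles[c].targets, from_disease[d])
            terms += _proximity_terms(d_genes, from_compound[c])
            n = len(terms)
            raw = sum(terms) / n if n else math.nan
            results.append(
                ProximityResult(compound_id=c, disease_id=d, raw_distance=raw, n_terms_used=n)
            )
    return normalize_cds(results, mode=mode)
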