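"""Core domain types.

Identifiers are treated as opaque strings with shape-only validation:
compounds carry standard InChIKeys (14-10-1 uppercase-letter blocks),
protein targets carry UniProt-style accessions, and diseases carry UMLS
concept IDs (``C`` followed by seven digits).  The caller is responsible
for harmonizing the gene/protein namespace between the bioactivity,
PPI and disease-gene inputs (in practice everything is mapped to
UniProt before scoring).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import FrozenSet, Iterable, Optional, Set, Tuple

import networkx as nx

INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")
CUI_RE = re.compile(r"^C\d{7}$")


def is_valid_inchikey(value: str) -> bool:
    """Shape-only InChIKey check (no checksum validation)."""
    return bool(INCHIKEY_RE.match(value))


def is_valid_cui(value: str) -> bool:
    """Shape-only UMLS CUI check."""
    return bool(CUI_RE.match(value))


class CompoundRole(str, Enum):
    APPROVED_DRUG = "approved_drug"
    CANDIDATE = "candidate"


@dataclass(frozen=True)
class CompoundRecord:
    """One chemical entity: identifier, structure string and pipeline role."""

    compound_id: str
    smiles: str
    role: CompoundRole = CompoundRole.CANDIDATE


@dataclass(frozen=True)
class BioactivityRecord:
    """One compound-target interaction.

    ``potency_nm`` is the measured activity concentration (IC50/Kd/Ki) in
    nanomolar; ``None`` marks a unary record — a curated interaction with
    no quantitative measurement attached.
    """

    compound_id: str
    target_id: str
    potency_nm: Optional[float] = None
    source: str = "quantitative"

    @property
    def is_unary(self) -> bool:
        return self.potency_nm is None


@dataclass(frozen=True)
class TargetProfile:
    """A compound's set of potent protein targets."""

    compound_id: str
    targets: FrozenSet[str]

    def __post_init__(self):
        object.__setattr__(self, "targets", frozenset(self.targets))


@dataclass
class PPINetwork:
    """Undirected protein-protein interaction graph (simple, no self-loops)."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(cls, edges: Iterable[Tuple[str, str]]) -> "PPINetwork":
        g = nx.Graph()
        for a, b in edges:
            if a == b:
                continue
            g.add_edge(a, b)
        return cls(graph=g)

    @property
    def nodes(self) -> Set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> Set[FrozenSet[str]]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return node in self.graph


@dataclass(frozen=True)
class DiseaseGeneMap:
    """Genes associated with one disease (UMLS CUI keyed)."""

    disease_id: str
    genes: FrozenSet[str]

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))


@dataclass(frozen=True)
class ApprovedIndication:
    """One approved (drug, disease) pair."""

    drug_id: str
    disease_id: str
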