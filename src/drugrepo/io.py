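"""Readers and writers for the five tabular input formats.

All files are delimiter-separated text with a mandatory header row
(tab-separated by default; pass ``sep=","`` for CSV).  Validation is
shape-only and row-level: malformed rows are skipped and reported in the
returned warnings rather than aborting the load, so large noisy database
dumps still parse.  Structural problems (missing file, missing required
column, zero valid rows) are fatal.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Dict, Generic, List, TypeVar

import pandas as pd

from .datamodel import (
    ApprovedIndication,
    BioactivityRecord,
    CompoundRecord,
    CompoundRole,
    DiseaseGeneMap,
    PPINetwork,
    is_valid_cui,
    is_valid_inchikey,
)
from .errors import InputFormatError

T = TypeVar("T")

FLOAT_FORMAT = "%.4f"


@dataclass
class ReadResult(Generic[T]):
    """A parsed collection plus row-level warnings accumulated while reading."""

    value: T
    warnings: List[str] = field(default_factory=list)

    @property
    def n_warnings(self) -> int:
        return len(self.warnings)


def _read_table(path, required_cols, sep: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in required_cols:
        if col not in df.columns:
            raise InputFormatError(f"{path}: missing required column {col!r}")
    return df


def read_compound_table(
    path, role: CompoundRole = CompoundRole.CANDIDATE, sep: str = "\t"
) -> ReadResult[List[CompoundRecord]]:
    """Read a compound table (columns ``compound_id``, ``smiles``).

    Rows with a malformed InChIKey or empty SMILES are skipped with a
    warning naming the row; duplicate compound IDs collapse to the first
    occurrence.  Zero valid rows is fatal.
    """
    df = _read_table(path, ("compound_id", "smiles"), sep)
    records: List[CompoundRecord] = []
    warnings: List[str] = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        cid, smiles = row.compound_id.strip(), row.smiles.strip()
        if not is_valid_inchikey(cid):
            warnings.append(f"row {i}: invalid InChIKey {cid!r}, skipped")
            continue
        if not smiles:
            warnings.append(f"row {i}: empty SMILES for {cid}, skipped")
            continue
        if cid in seen:
            warnings.append(f"row {i}: duplicate compound_id {cid}, kept first occurrence")
            continue
        seen.add(cid)
        records.append(CompoundRecord(compound_id=cid, smiles=smiles, role=role))
    if not records:
        raise InputFormatError(f"{path}: no valid compound rows")
    return ReadResult(records, warnings)


def read_bioactivity_table(path, sep: str = "\t") -> ReadResult[List[BioactivityRecord]]:
    """Read a bioactivity table (``compound_id``, ``target_id``, optional
    ``potency_nm`` and ``source`` columns).

    An empty potency cell yields a unary record; a non-numeric or
    non-positive potency rejects the row with a warning.
    """
    df = _read_table(path, ("compound_id", "target_id"), sep)
    has_potency = "potency_nm" in df.columns
    has_source = "source" in df.columns
    records: List[BioactivityRecord] = []
    warnings: List[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        cid, tid = row.compound_id.strip(), row.target_id.strip()
        if not is_valid_inchikey(cid):
            warnings.append(f"row {i}: invalid InChIKey {cid!r}, skipped")
            continue
        if not tid:
            warnings.append(f"row {i}: empty target_id, skipped")
            continue
        raw = getattr(row, "potency_nm", "").strip() if has_potency else ""
        if raw == "":
            potency = None
        else:
            try:
                potency = float(raw)
            except ValueError:
                warnings.append(f"row {i}: non-numeric potency {raw!r}, skipped")
                continue
            if not math.isfinite(potency) or potency <= 0:
                warnings.append(f"row {i}: non-positive potency {potency}, skipped")
                continue
        source = row.source.strip() if has_source else ""
        if not source:
            source = "unary" if potency is None else "quantitative"
        records.append(
            BioactivityRecord(compound_id=cid, target_id=tid, potency_nm=potency, source=source)
        )
    if not records:
        raise InputFormatError(f"{path}: no valid bioactivity rows")
    return ReadResult(records, warnings)


def read_ppi_edges(path, sep: str = "\t") -> ReadResult[PPINetwork]:
    """Read a two-column undirected edge list into a PPI network.

    Self-loops are dropped with a warning; duplicate and reversed
    duplicate edges collapse silently.  Zero edges is fatal.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise InputFormatError(f"{path}: PPI edge list needs two columns")
    warnings: List[str] = []
    edges = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        # positional access: header names for the two endpoint columns are free
        a, b = str(row[0]).strip(), str(row[1]).strip()
        if not a or not b:
            warnings.append(f"row {i}: empty endpoint, skipped")
            continue
        if a == b:
            warnings.append(f"row {i}: self-loop on {a}, dropped")
            continue
        edges.append((a, b))
    network = PPINetwork.from_edges(edges)
    if network.n_edges == 0:
        raise InputFormatError(f"{path}: no valid edges")
    return ReadResult(network, warnings)


def read_disease_genes(path, sep: str = "\t") -> ReadResult[Dict[str, DiseaseGeneMap]]:
    """Read disease-gene associations (``disease_id``, ``gene_id``) grouped by CUI."""
    df = _read_table(path, ("disease_id", "gene_id"), sep)
    warnings: List[str] = []
    grouped: Dict[str, set] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        cui, gene = row.disease_id.strip(), row.gene_id.strip()
        if not is_valid_cui(cui):
            warnings.append(f"row {i}: invalid CUI {cui!r}, skipped")
            continue
        if not gene:
            warnings.append(f"row {i}: empty gene_id, skipped")
            continue
        grouped.setdefault(cui, set()).add(gene)
    if not grouped:
        raise InputFormatError(f"{path}: no valid disease-gene rows")
    maps = {cui: DiseaseGeneMap(disease_id=cui, genes=frozenset(genes)) for cui, genes in grouped.items()}
    return ReadResult(maps, warnings)


def read_indications(path, sep: str = "\t") -> ReadResult[List[ApprovedIndication]]:
    """Read approved (drug, disease) indications (``drug_id``, ``disease_id``)."""
    df = _read_table(path, ("drug_id", "disease_id"), sep)
    warnings: List[str] = []
    records: List[ApprovedIndication] = []
    seen = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        drug, cui = row.drug_id.strip(), row.disease_id.strip()
        if not is_valid_inchikey(drug):
            warnings.append(f"row {i}: invalid InChIKey {drug!r}, skipped")
            continue
        if not is_valid_cui(cui):
            warnings.append(f"row {i}: invalid CUI {cui!r}, skipped")
            continue
        if (drug, cui) in seen:
            warnings.append(f"row {i}: duplicate indication ({drug}, {cui}), collapsed")
            continue
        seen.add((drug, cui))
        records.append(ApprovedIndication(drug_id=drug, disease_id=cui))
    if not records:
        raise InputFormatError(f"{path}: no valid indication rows")
    return ReadResult(records, warnings)


# ---------------------------------------------------------------------------
# Writers (inverse of the readers; used by the fixture generator and exports)
# ---------------------------------------------------------------------------


def write_compound_table(records: List[CompoundRecord], path, sep: str = "\t") -> None:
    pd.DataFrame(
        {"compound_id": [r.compound_id for r in records], "smiles": [r.smiles for r in records]}
    ).to_csv(path, sep=sep, index=False)


def write_bioactivity_table(records: List[BioactivityRecord], path, sep: str = "\t") -> None:
    pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "target_id": [r.target_id for r in records],
            "potency_nm": ["" if r.potency_nm is None else repr(r.potency_nm) for r in records],
            "source": [r.source for r in records],
        }
    ).to_csv(path, sep=sep, index=False)


def write_ppi_edges(network: PPINetwork, path, sep: str = "\t") -> None:
    pairs = sorted(tuple(sorted(e)) for e in network.edges)
    pd.DataFrame(pairs, columns=["protein_a", "protein_b"]).to_csv(path, sep=sep, index=False)


def write_disease_genes(maps: Dict[str, DiseaseGeneMap], path, sep: str = "\t") -> None:
    rows = [
        (cui, gene)
        for cui in sorted(maps)
        for gene in sorted(maps[cui].genes)
    ]
    pd.DataFrame(rows, columns=["disease_id", "gene_id"]).to_csv(path, sep=sep, index=False)


def write_indications(records: List[ApprovedIndication], path, sep: str = "\t") -> None:
    pd.DataFrame(
        {"drug_id": [r.drug_id for r in records], "disease_id": [r.disease_id for r in records]}
    ).to_csv(path, sep=sep, index=False)
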