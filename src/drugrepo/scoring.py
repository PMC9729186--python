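"""Composite repurposing score and per-disease ranked candidate tables.

For a disease with approved drugs A_1..A_k and a candidate compound C,
each surviving (A_i, C) pair contributes a structural similarity TC and
a target-overlap OCTS; pairs with TC below ``tc_min`` (0.2 by default)
are dropped before averaging, and the surviving per-drug scores are
averaged.  Together with the compound-disease network score CDS, the
composite score is the arithmetic mean

    DrugRepo = (TC + OCTS + CDS) / 3,

in [0, 1]; candidates below ``score_min`` (0.4 by default) are dropped
and the rest are ranked by score, ties broken lexicographically by
candidate ID so runs are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Tuple

import pandas as pd

from .chem import Fingerprint, tanimoto
from .datamodel import ApprovedIndication, TargetProfile
from .errors import NoApprovedDrugError
from .targets import octs

logger = logging.getLogger(__name__)

DEFAULT_TC_MIN = 0.2
DEFAULT_SCORE_MIN = 0.4


@dataclass(frozen=True)
class RepurposingRecord:
    """One scored (disease, approved-drug set, candidate) row."""

    disease_id: str
    approved_drugs: FrozenSet[str]
    candidate_id: str
    tc: float
    octs: float
    cds: float
    drugrepo: float


def drugrepo_score(tc: float, octs_score: float, cds: float) -> float:
    """Arithmetic mean of the three component scores; all must be in [0, 1]."""
    for name, v in (("tc", tc), ("octs", octs_score), ("cds", cds)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} component out of [0, 1]: {v}")
    return (tc + octs_score + cds) / 3.0


def repurpose_disease(
    disease_id: str,
    indications: Iterable[ApprovedIndication],
    profiles: Dict[str, TargetProfile],
    fingerprints: Dict[str, Fingerprint],
    cds_table: Mapping[Tuple[str, str], float],
    tc_min: float = DEFAULT_TC_MIN,
    score_min: float = DEFAULT_SCORE_MIN,
    pairwise_tc_filter: bool = True,
) -> List[RepurposingRecord]:
    """Rank candidate compounds for one disease.

    Candidates are every compound with both a target profile and a
    fingerprint, minus the drugs approved for this disease (drugs
    approved for *other* diseases remain candidates).  ``cds_table``
    maps (candidate_id, disease_id) to the normalized CDS; a missing
    entry counts as 0.

    With ``pairwise_tc_filter`` (default) the TC >= tc_min cut is applied
    per (approved drug, candidate) pair before multi-drug averaging and a
    candidate survives if at least one pair passes; with it off, a
    candidate survives if any pair passes but averaging runs over all
    pairs.
    """
    indications = list(indications)
    approved_all = {ind.drug_id for ind in indications if ind.disease_id == disease_id}
    if not approved_all:
        raise NoApprovedDrugError(disease_id, "no indication on record")
    approved = {
        d for d in approved_all if d in profiles and d in fingerprints
    }
    if not approved:
        raise NoApprovedDrugError(disease_id, "approved drugs lack profile or fingerprint")

    scoreable = set(profiles) & set(fingerprints)
    candidates = sorted(scoreable - approved_all)
    n_skipped = len((set(profiles) | set(fingerprints)) - scoreable - approved_all)
    if n_skipped:
        logger.info(
            "disease %s: %d compounds lack a fingerprint or target profile, skipped",
            disease_id,
            n_skipped,
        )

    records: List[RepurposingRecord] = []
    for cand in candidates:
        pair_scores = []  # (tc, octs) per approved drug
        for drug in sorted(approved):
            tc = tanimoto(fingerprints[drug], fingerprints[cand])
            oc = octs(profiles[drug].targets, profiles[cand].targets)
            pair_scores.append((tc, oc))
        surviving = [(t, o) for t, o in pair_scores if t >= tc_min]
        if not surviving:
            continue
        averaged_over = surviving if pairwise_tc_filter else pair_scores
        mean_tc = sum(t for t, _ in averaged_over) / len(averaged_over)
        mean_octs = sum(o for _, o in averaged_over) / len(averaged_over)
        cds = float(cds_table.get((cand, disease_id), 0.0))
        score = drugrepo_score(mean_tc, mean_octs, cds)
        if score < score_min:
            continue
        records.append(
            RepurposingRecord(
                disease_id=disease_id,
                approved_drugs=frozenset(approved),
                candidate_id=cand,
                tc=mean_tc,
                octs=mean_octs,
                cds=cds,
                drugrepo=score,
            )
        )
    records.sort(key=lambda r: (-r.drugrepo, r.candidate_id))
    return records


def records_to_frame(records: Iterable[RepurposingRecord]) -> pd.DataFrame:
    """Flatten ranked records into the output table (rank is per disease)."""
    rows = []
    rank: Dict[str, int] = {}
    for r in records:
        rank[r.disease_id] = rank.get(r.disease_id, 0) + 1
        rows.append(
            {
                "disease_id": r.disease_id,
                "candidate_id": r.candidate_id,
                "tc": r.tc,
                "octs": r.octs,
                "cds": r.cds,
                "drugrepo": r.drugrepo,
                "rank": rank[r.disease_id],
            }
        )
    return pd.DataFrame(
        rows, columns=["disease_id", "candidate_id", "tc", "octs", "cds", "drugrepo", "rank"]
    )
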