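"""Potency filtering, compound-target profiles and the overlap score OCTS.

A compound-target pair is *potent* when at least one quantitative
measurement (IC50/Kd/Ki) is at or below the potency threshold
(1000 nM by default), or when a curated unary interaction exists for the
pair.  OCTS between an approved drug's target set Drug_T and a candidate
compound's Compound_T is

    OCTS = |Drug_T ∩ Compound_T| / min(|Drug_T|, |Compound_T|),

the overlap (Szymkiewicz-Simpson) coefficient on potent-target sets.
It ranges over [0, 1] and equals 1 whenever one set contains the other.
"""

from __future__ import annotations

import statistics
from typing import Dict, Iterable, List, Set, Tuple

from .datamodel import BioactivityRecord, TargetProfile
from .errors import EmptyTargetSetError

DEFAULT_POTENCY_NM = 1000.0


def filter_potent(
    records: Iterable[BioactivityRecord],
    threshold_nm: float = DEFAULT_POTENCY_NM,
    aggregate: str = "any",
) -> List[Tuple[str, str]]:
    """Reduce bioactivity records to unique potent (compound, target) pairs.

    Parameters
    ----------
    threshold_nm : float
        Potency cutoff in nanomolar; must be positive.
    aggregate : {"any", "median"}
        How multiple quantitative measurements for one pair are combined:
        ``"any"`` keeps the pair if any single measurement passes (default),
        ``"median"`` requires the median of all measurements to pass.
        Unary records qualify a pair under either rule.

    Returns sorted unique pairs; an empty result is allowed.
    """
    if threshold_nm <= 0:
        raise ValueError("threshold_nm must be positive")
    if aggregate not in ("any", "median"):
        raise ValueError(f"unknown aggregate rule {aggregate!r}")

    quantitative: Dict[Tuple[str, str], List[float]] = {}
    unary: Set[Tuple[str, str]] = set()
    for rec in records:
        key = (rec.compound_id, rec.target_id)
        if rec.is_unary:
            unary.add(key)
        else:
            quantitative.setdefault(key, []).append(rec.potency_nm)

    kept: Set[Tuple[str, str]] = set(unary)
    for key, values in quantitative.items():
        if aggregate == "any":
            if min(values) <= threshold_nm:
                kept.add(key)
        else:
            if statistics.median(values) <= threshold_nm:
                kept.add(key)
    return sorted(kept)


def build_target_profiles(pairs: Iterable[Tuple[str, str]]) -> Dict[str, TargetProfile]:
    """Group potent (compound, target) pairs into per-compound profiles.

    Compounds with no potent target are simply absent from the result.
    """
    grouped: Dict[str, Set[str]] = {}
    for compound_id, target_id in pairs:
        grouped.setdefault(compound_id, set()).add(target_id)
    return {
        cid: TargetProfile(compound_id=cid, targets=frozenset(targets))
        for cid, targets in grouped.items()
    }


def octs(drug_targets: Set[str], compound_targets: Set[str]) -> float:
    """Overlapping compound-target score between two potent-target sets."""
    if not drug_targets or not compound_targets:
        raise EmptyTargetSetError("OCTS is undefined for an empty target set")
    shared = len(set(drug_targets) & set(compound_targets))
    return shared / min(len(drug_targets), len(compound_targets))
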