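"""Validation statistics for predicted compound-disease associations.

Given a reference set of compounds C_d known to associate with disease d
(e.g. a curated toxicogenomics resource), a predicted set C_r, and the
universe of C_all scoreable compounds, the per-disease enrichment is

    N_overlap  = |C_d ∩ C_r|
    N_expected = |C_d| · |C_r| / |C_all|
    Sig_d      = N_overlap − N_expected,

where N_expected is the mean overlap of a uniformly random draw of
|C_r| compounds from the universe.  Sig_d > 0 means the predictions
recover more reference associations than chance.  Sig_d is a raw excess
count; it carries no variance or p-value.

The hit ratio sweeps a score threshold t and reports, among predictions
scoring >= t, the percentage present in the reference set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple, Union

import pandas as pd

from .scoring import RepurposingRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignificanceResult:
    """Per-disease observed vs expected overlap with a reference set."""

    disease_id: str
    n_overlap: int
    n_expected: float
    sig: float
    n_reference: int
    n_predicted: int
    n_universe: int


def significance_score(
    reference_set: Set[str],
    predicted_set: Set[str],
    universe: Union[int, Set[str]],
    disease_id: str = "",
) -> SignificanceResult:
    """Excess of observed over expected overlap between two compound sets.

    ``universe`` may be the universe size or the universe set itself; when
    the set is given, members of either input outside it are reported in
    the log (the statistic itself is computed as-is).
    """
    reference_set, predicted_set = set(reference_set), set(predicted_set)
    if isinstance(universe, int):
        n_universe = universe
    else:
        n_universe = len(universe)
        outside = (reference_set | predicted_set) - set(universe)
        if outside:
            logger.warning(
                "disease %s: %d set members outside the universe", disease_id, len(outside)
            )
    if n_universe <= 0:
        raise ValueError("universe must be non-empty")
    if not reference_set or not predicted_set:
        raise ValueError("reference and predicted sets must be non-empty")
    if n_universe < max(len(reference_set), len(predicted_set)):
        raise ValueError("universe smaller than an input set")

    n_overlap = len(reference_set & predicted_set)
    n_expected = len(reference_set) * len(predicted_set) / n_universe
    return SignificanceResult(
        disease_id=disease_id,
        n_overlap=n_overlap,
        n_expected=n_expected,
        sig=n_overlap - n_expected,
        n_reference=len(reference_set),
        n_predicted=len(predicted_set),
        n_universe=n_universe,
    )


def significance_table(
    reference_map: Dict[str, Set[str]],
    predicted_map: Dict[str, Set[str]],
    universe: Union[int, Set[str]],
) -> pd.DataFrame:
    """Per-disease significance over the diseases present in both maps."""
    rows = []
    for disease in sorted(set(reference_map) & set(predicted_map)):
        if not reference_map[disease] or not predicted_map[disease]:
            continue
        r = significance_score(
            reference_map[disease], predicted_map[disease], universe, disease_id=disease
        )
        rows.append(
            {
                "disease_id": r.disease_id,
                "n_reference": r.n_reference,
                "n_predicted": r.n_predicted,
                "n_universe": r.n_universe,
                "n_overlap": r.n_overlap,
                "n_expected": r.n_expected,
                "sig": r.sig,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "disease_id",
            "n_reference",
            "n_predicted",
            "n_universe",
            "n_overlap",
            "n_expected",
            "sig",
        ],
    )


def hit_ratio(
    predictions: Iterable[RepurposingRecord],
    reference: Set[Tuple[str, str]],
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Hit percentage of predictions against a reference, per score threshold.

    ``reference`` holds (disease_id, compound_id) pairs.  For each
    threshold t in [0, 1]: predictions with score >= t form the
    denominator, those also in the reference the numerator.  Thresholds
    with an empty denominator are absent from the output.
    """
    preds: List[RepurposingRecord] = list(predictions)
    for t in thresholds:
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"threshold out of [0, 1]: {t}")
    rows = []
    for t in thresholds:
        kept = [p for p in preds if p.drugrepo >= t]
        if not kept:
            continue
        hits = sum(1 for p in kept if (p.disease_id, p.candidate_id) in reference)
        rows.append(
            {
                "threshold": t,
                "n_predicted": len(kept),
                "n_hits": hits,
                "pct": 100.0 * hits / len(kept),
            }
        )
    return pd.DataFrame(rows, columns=["threshold", "n_predicted", "n_hits", "pct"])
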