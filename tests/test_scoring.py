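"""Composite score arithmetic and per-disease ranking behaviour."""

import numpy as np
import pytest

from drugrepo.chem import Fingerprint
from drugrepo.datamodel import ApprovedIndication, TargetProfile
from drugrepo.errors import NoApprovedDrugError
from drugrepo.scoring import (
    drugrepo_score,
    records_to_frame,
    repurpose_disease,
)

from conftest import make_inchikey

DISEASE = "C0000001"
DRUG = make_inchikey(0)
X, Y, Z = make_inchikey(1), make_inchikey(2), make_inchikey(3)


def fp(positions, n_bits=64):
    bits = np.zeros(n_bits, dtype=np.uint8)
    bits[list(positions)] = 1
    return Fingerprint(bits=bits)


@pytest.fixture
def micro_world():
    """One disease, one approved drug, three candidates with known scores."""
    indications = [ApprovedIndication(drug_id=DRUG, disease_id=DISEASE)]
    profiles = {
        DRUG: TargetProfile(DRUG, frozenset({"P1", "P2", "P3"})),
        X: TargetProfile(X, frozenset({"P1", "P2", "P3"})),       # identical targets
        Y: TargetProfile(Y, frozenset({"P1", "P9"})),             # partial overlap
        Z: TargetProfile(Z, frozenset({"P7", "P8"})),             # disjoint
    }
    fingerprints = {
        DRUG: fp(range(10)),
        X: fp(range(10)),                                # TC = 1 to the drug
        Y: fp(list(range(5)) + list(range(20, 25))),     # TC = 5/15 = 1/3
        Z: fp([0] + list(range(30, 48))),                # TC = 1/28 < 0.2
    }
    cds = {(X, DISEASE): 1.0, (Y, DISEASE): 0.5, (Z, DISEASE): 1.0}
    return indications, profiles, fingerprints, cds


class TestDrugRepoScore:
    @pytest.mark.parametrize(
        "tc, oc, cds, expected",
        [(1, 1, 1, 1.0), (0.2, 0.4, 0.9, 0.5), (0, 0, 0, 0.0)],
    )
    def test_mean_of_components(self, tc, oc, cds, expected):
        assert drugrepo_score(tc, oc, cds) == pytest.approx(expected)

    def test_out_of_range_component_fatal(self):
        with pytest.raises(ValueError):
            drugrepo_score(1.2, 0.5, 0.5)
        with pytest.raises(ValueError):
            drugrepo_score(0.5, -0.1, 0.5)


class TestRepurposeDisease:
    def test_perfect_mimic_ranks_first_with_top_score(self, micro_world):
        inds, profiles, fps, cds = micro_world
        records = repurpose_disease(DISEASE, inds, profiles, fps, cds)
        assert records[0].candidate_id == X
        assert records[0].drugrepo == pytest.approx(1.0)
        assert records[0].drugrepo == pytest.approx(
            (records[0].tc + records[0].octs + records[0].cds) / 3, abs=1e-9
        )

    def test_low_tc_candidate_absent(self, micro_world):
        inds, profiles, fps, cds = micro_world
        records = repurpose_disease(DISEASE, inds, profiles, fps, cds)
        assert Z not in {r.candidate_id for r in records}

    def test_approved_drug_never_its_own_candidate(self, micro_world):
        inds, profiles, fps, cds = micro_world
        records = repurpose_disease(DISEASE, inds, profiles, fps, cds, score_min=0.0)
        assert DRUG not in {r.candidate_id for r in records}

    def test_ties_break_lexicographically(self, micro_world):
        inds, profiles, fps, cds = micro_world
        # clone X under a lexicographically later ID with identical scores
        last = "Z" + X[1:]
        profiles = dict(profiles, **{last: profiles[X]})
        fps = dict(fps, **{last: fps[X]})
        cds = {**cds, (last, DISEASE): 1.0}
        records = repurpose_disease(DISEASE, inds, profiles, fps, cds)
        tied = [r.candidate_id for r in records if r.drugrepo == records[0].drugrepo]
        assert tied == sorted(tied)

    def test_no_approved_drug_raises_with_disease(self):
        with pytest.raises(NoApprovedDrugError, match="C0000009"):
            repurpose_disease("C0000009", [], {}, {}, {})

    def test_missing_cds_counts_as_zero(self, micro_world):
        inds, profiles, fps, _ = micro_world
        records = repurpose_disease(DISEASE, inds, profiles, fps, {}, score_min=0.0)
        x = next(r for r in records if r.candidate_id == X)
        assert x.cds == 0.0
        assert x.drugrepo == pytest.approx(2 / 3)

    def test_single_approved_drug_averaging_is_identity(self, micro_world):
        inds, profiles, fps, cds = micro_world
        records = repurpose_disease(DISEASE, inds, profiles, fps, cds, score_min=0.0)
        y = next(r for r in records if r.candidate_id == Y)
        assert y.tc == pytest.approx(1 / 3)
        assert y.octs == pytest.approx(1 / 2)

    @pytest.mark.parametrize("knob", ["tc_min", "score_min"])
    def test_raising_thresholds_shrinks_output(self, micro_world, knob):
        inds, profiles, fps, cds = micro_world
        previous = None
        for value in (0.0, 0.3, 0.6, 0.9):
            records = repurpose_disease(
                DISEASE, inds, profiles, fps, cds, **{knob: value},
                **({"score_min": 0.0} if knob == "tc_min" else {}),
            )
            ids = {r.candidate_id for r in records}
            if previous is not None:
                assert ids <= previous
            previous = ids

    def test_output_sorted_non_increasing_and_in_unit_interval(self, micro_world):
        inds, profiles, fps, cds = micro_world
        records = repurpose_disease(DISEASE, inds, profiles, fps, cds, score_min=0.0)
        scores = [r.drugrepo for r in records]
        assert scores == sorted(scores, reverse=True)
        for r in records:
            for v in (r.tc, r.octs, r.cds, r.drugrepo):
                assert 0.0 <= v <= 1.0


class TestMultiDrugAveraging:
    def test_tc_filter_applied_per_pair_before_averaging(self):
        """A pair below tc_min drops out of the average; the candidate survives
        through the passing pair alone."""
        drug2 = make_inchikey(9)
        inds = [
            ApprovedIndication(DRUG, DISEASE),
            ApprovedIndication(drug2, DISEASE),
        ]
        profiles = {
            DRUG: TargetProfile(DRUG, frozenset({"P1", "P2"})),
            drug2: TargetProfile(drug2, frozenset({"P5", "P6"})),
            X: TargetProfile(X, frozenset({"P1", "P2"})),
        }
        fps = {
            DRUG: fp(range(10)),
            drug2: fp(range(40, 60)),  # TC to X = 0 < tc_min
            X: fp(range(10)),
        }
        cds = {(X, DISEASE): 1.0}
        [rec] = repurpose_disease(DISEASE, inds, profiles, fps, cds)
        assert rec.tc == pytest.approx(1.0)   # averaged over the surviving pair only
        assert rec.octs == pytest.approx(1.0)
        all_pairs = repurpose_disease(
            DISEASE, inds, profiles, fps, cds, pairwise_tc_filter=False, score_min=0.0
        )
        assert all_pairs[0].tc == pytest.approx(0.5)  # averaged over both pairs


def test_records_to_frame_ranks_per_disease(micro_world):
    inds, profiles, fps, cds = micro_world
    records = repurpose_disease(DISEASE, inds, profiles, fps, cds, score_min=0.0)
    frame = records_to_frame(records)
    assert list(frame["rank"]) == list(range(1, len(records) + 1))
    assert list(frame.columns) == [
        "disease_id", "candidate_id", "tc", "octs", "cds", "drugrepo", "rank",
    ]
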