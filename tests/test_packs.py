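"""Pack assembly, the proximity rule, and breeder-turnover tracking."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wolfscr.packs import (
    BREEDER_F,
    BREEDER_M,
    OFFSPRING,
    UNDETECTED_INFERRED,
    UNRELATED_ADOPTEE,
    PackAssembler,
    assign_unrelated,
    build_packs,
    sampling_year,
    turnover_report,
)
from wolfscr.synthetic import pack_fixture


def rel(a, b, relation="parent_offspring", probability=0.95, year=None):
    return {"individual_a": a, "individual_b": b, "relation": relation,
            "probability": probability, "year": year}


def sample(ind, day, x, y, age="fresh", sid=None):
    return {"sample_id": sid or f"{ind}_{day}_{x}", "individual_id": ind,
            "date": day, "x": x, "y": y, "field_age_class": age}


class TestBuildPacks:
    def test_nuclear_family_one_pack(self):
        relations = pd.DataFrame(
            [rel("F1", "K1"), rel("F1", "K2"), rel("F1", "K3"),
             rel("M1", "K1"), rel("M1", "K2"), rel("M1", "K3"),
             rel("K1", "K2", "full_sib"), rel("K1", "K3", "full_sib"),
             rel("K2", "K3", "full_sib")])
        sexes = {"F1": "F", "M1": "M", "K1": "F", "K2": "M", "K3": "M"}
        packs, unassigned = build_packs(relations, sexes)
        assert len(packs) == 1 and unassigned == []
        roles = packs[0].members
        assert roles["F1"] == BREEDER_F and roles["M1"] == BREEDER_M
        assert all(roles[k] == OFFSPRING for k in ("K1", "K2", "K3"))

    def test_empty_relations_all_unassigned(self):
        relations = pd.DataFrame(
            columns=["individual_a", "individual_b", "relation",
                     "probability"])
        packs, unassigned = build_packs(relations, {"A": "F", "B": "M"})
        assert packs == [] and unassigned == ["A", "B"]

    def test_low_probability_edges_dropped(self):
        relations = pd.DataFrame([rel("F1", "K1", probability=0.5)])
        packs, unassigned = build_packs(relations, {"F1": "F", "K1": "M"})
        assert packs == []
        assert set(unassigned) == {"F1", "K1"}

    def test_undetected_parent_retained_as_placeholder(self):
        relations = pd.DataFrame([rel("GHOST", "K1"), rel("F1", "K1")])
        packs, _ = build_packs(relations, {"F1": "F", "K1": "M"})
        assert packs[0].members["GHOST"] == UNDETECTED_INFERRED

    def test_pedigree_cycle_rejected(self):
        relations = pd.DataFrame([rel("A", "B"), rel("B", "C"), rel("C", "A")])
        with pytest.raises(ValueError, match="ancestor"):
            build_packs(relations, {"A": "F", "B": "M", "C": "M"})

    def test_half_sibs_do_not_connect_packs(self):
        relations = pd.DataFrame(
            [rel("F1", "K1"), rel("F2", "K2"),
             rel("K1", "K2", "half_sib")])
        packs, _ = build_packs(
            relations, {"F1": "F", "K1": "M", "F2": "F", "K2": "M"})
        assert len(packs) == 2


class TestAssignUnrelated:
    def _one_pack(self):
        relations = pd.DataFrame([rel("F1", "K1")])
        sexes = {"F1": "F", "K1": "M", "U1": "M"}
        return build_packs(relations, sexes)

    @pytest.mark.parametrize(
        "dx, day, age, adopted",
        [
            (290.0, "2020-01-05", "fresh", True),    # within 500 m, same day
            (501.0, "2020-01-05", "fresh", False),   # beyond the threshold
            (100.0, "2020-01-06", "fresh", False),   # different day
            (100.0, "2020-01-05", "3-5d", False),    # different sample age
            (500.0, "2020-01-05", "fresh", True),    # boundary: 500 m counts
        ])
    def test_proximity_rule(self, dx, day, age, adopted):
        packs, unassigned = self._one_pack()
        samples = pd.DataFrame([
            sample("F1", "2020-01-05", 0.0, 0.0),
            sample("U1", day, dx, 0.0, age=age),
        ])
        packs, still, log = assign_unrelated(packs, unassigned, samples)
        if adopted:
            assert packs[0].members.get("U1") == UNRELATED_ADOPTEE
            assert len(log) == 1 and log.iloc[0]["distance_m"] == dx
        else:
            assert "U1" in still

    def test_tie_broken_by_distance_and_order_independent(self):
        relations = pd.DataFrame([rel("F1", "K1"), rel("F2", "K2")])
        sexes = {"F1": "F", "K1": "M", "F2": "F", "K2": "M",
                 "U1": "M", "U2": "F"}
        samples = pd.DataFrame([
            sample("F1", "2020-01-05", 0.0, 0.0),
            sample("F2", "2020-01-05", 1000.0, 0.0),
            sample("U1", "2020-01-05", 400.0, 0.0),   # 400 vs 600: pack 1
            sample("U2", "2020-01-05", 700.0, 0.0),   # 700 vs 300: pack 2
        ])
        packs, unassigned = build_packs(relations, sexes)
        for order in (["U1", "U2"], ["U2", "U1"]):
            p, still, _ = assign_unrelated(
                [pk for pk in build_packs(relations, sexes)[0]], order,
                samples)
            assert p[0].members.get("U1") == UNRELATED_ADOPTEE
            assert p[1].members.get("U2") == UNRELATED_ADOPTEE
            assert still == []


class TestTurnover:
    def test_stable_breeders_no_turnover(self):
        relations = pd.DataFrame(
            [rel("F1", "K1", year=2019), rel("M1", "K1", year=2019),
             rel("F1", "K2", year=2020), rel("M1", "K2", year=2020)])
        sexes = {"F1": "F", "M1": "M", "K1": "M", "K2": "F"}
        packs, _ = build_packs(relations, sexes)
        samples = pd.DataFrame([
            sample("F1", "2019-12-01", 0, 0), sample("F1", "2020-12-01", 0, 0)])
        report = turnover_report(packs, samples)
        assert len(report["turnover"]) == 0

    def test_replaced_male_is_one_event(self):
        relations = pd.DataFrame(
            [rel("F1", "K1", year=2019), rel("M1", "K1", year=2019),
             rel("F1", "K2", year=2021), rel("M2", "K2", year=2021)])
        sexes = {"F1": "F", "M1": "M", "M2": "M", "K1": "M", "K2": "F"}
        packs, _ = build_packs(relations, sexes)
        samples = pd.DataFrame([sample("F1", "2019-12-01", 0, 0)])
        report = turnover_report(packs, samples)
        assert len(report["turnover"]) == 1
        ev = report["turnover"].iloc[0]
        assert ev["role"] == "M"
        assert (ev["breeder_from"], ev["breeder_to"]) == ("M1", "M2")

    def test_disperser_detected(self):
        relations = pd.DataFrame([rel("F1", "K1"), rel("F2", "K2")])
        sexes = {"F1": "F", "K1": "M", "F2": "F", "K2": "M", "D1": "M"}
        packs, unassigned = build_packs(relations, sexes)
        samples = pd.DataFrame([
            sample("F1", "2019-12-01", 0, 0),
            sample("D1", "2019-12-01", 100, 0),
            sample("F2", "2020-12-01", 50_000, 0),
            sample("D1", "2020-12-01", 50_100, 0),
        ])
        packs, still, _ = assign_unrelated(packs, unassigned, samples)
        report = turnover_report(packs, samples)
        moves = report["dispersers"]
        assert len(moves) == 1
        assert moves.iloc[0]["individual_id"] == "D1"
        assert (moves.iloc[0]["pack_from"], moves.iloc[0]["pack_to"]) == (
            "pack_01", "pack_02")


class TestSamplingYear:
    @pytest.mark.parametrize("date, year", [
        ("2019-07-01", 2019), ("2020-06-30", 2019), ("2020-07-01", 2020),
        ("2019-11-15", 2019), ("2020-03-15", 2019)])
    def test_july_to_june_season(self, date, year):
        assert sampling_year(date) == year


class TestSixPackFixture:
    def test_truth_recovered_exactly(self):
        relations, sexes, samples, truth = pack_fixture()
        assembler = PackAssembler().fit(relations, sexes, samples)
        packs = assembler.packs_
        assert len(packs) == truth["n_packs"]
        # pedigree members land in their true packs
        assignment = {ind: p.pack_id for p in packs for ind in p.member_ids}
        for ind, pack_id in truth["pack_of"].items():
            assert assignment[ind] == pack_id
        # programmed adoptions, including both boundary rejections
        for ind, pack_id in truth["adopted"].items():
            assert assignment.get(ind) == pack_id
            role = next(p for p in packs if p.pack_id == pack_id).members[ind]
            assert role == UNRELATED_ADOPTEE
        for ind in truth["rejected"]:
            assert ind in assembler.unassigned_
        # exactly the two programmed breeder turnovers
        assert len(assembler.report_["turnover"]) == truth["n_turnovers"]
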