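"""Pack assembly from pedigree relations plus the spatial-proximity rule.

Wolf packs are family groups: a breeding pair and their offspring, sometimes
accompanied by genetically unrelated animals.  Pedigree reconstruction
(parentage and sibship assignment, e.g. from Colony) is consumed here as a
relations table, never computed.  Packs are the connected components of the
parent-offspring / full-sibling graph; unrelated individuals are adopted into
a pack when one of their samples was collected on the same day, within 500 m,
and with the same field-estimated sample age as a sample of any pack member.
Breeder turnover across sampling years is tracked from litter years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date

import networkx as nx
import numpy as np
import pandas as pd

BREEDER_F = "breeder_F"
BREEDER_M = "breeder_M"
OFFSPRING = "offspring"
UNRELATED_ADOPTEE = "unrelated_adoptee"
UNDETECTED_INFERRED = "undetected_inferred"

RELATIONS = ("parent_offspring", "full_sib", "half_sib")

DEFAULT_ADOPTION_RADIUS_M = 500.0
DEFAULT_PROBABILITY_THRESHOLD = 0.8


def sampling_year(d) -> int:
    """Sampling-year index of a date under a July-to-June season.

    Returns the calendar year in which the season started (e.g. any date from
    2019-07-01 to 2020-06-30 maps to 2019).
    """
    d = pd.Timestamp(d)
    return d.year if d.month >= 7 else d.year - 1


@dataclass
class Pack:
    """One pack: static roles, per-year breeders, and adoption records."""

    pack_id: str
    members: dict = field(default_factory=dict)  # individual_id -> role
    breeder_years: dict = field(default_factory=dict)  # year -> {"F": id, "M": id}
    adoptions: list = field(default_factory=list)

    @property
    def member_ids(self) -> set:
        return set(self.members)

    def detected_members(self, samples: pd.DataFrame, year: int) -> set:
        sub = samples[samples["individual_id"].isin(self.members)]
        years = sub["date"].map(sampling_year)
        return set(sub.loc[years == year, "individual_id"])

    def territory(self, samples: pd.DataFrame, year: int | None = None):
        """Naive territory: convex hull of member sample coordinates."""
        from shapely.geometry import MultiPoint

        sub = samples[samples["individual_id"].isin(self.members)]
        if year is not None:
            sub = sub[sub["date"].map(sampling_year) == year]
        if len(sub) == 0:
            return None
        return MultiPoint(list(zip(sub["x"], sub["y"]))).convex_hull


def _validate_relations(relations: pd.DataFrame) -> pd.DataFrame:
    required = {"individual_a", "individual_b", "relation", "probability"}
    missing = required - set(relations.columns)
    if missing:
        raise ValueError(f"relations table lacks columns: {sorted(missing)}")
    bad = set(relations["relation"]) - set(RELATIONS)
    if bad:
        raise ValueError(f"unknown relation types: {sorted(bad)}")
    if ((relations["probability"] < 0) | (relations["probability"] > 1)).any():
        raise ValueError("relation probabilities must be in [0, 1]")
    return relations


def build_packs(
    relations: pd.DataFrame,
    sexes: dict,
    probability_threshold: float = DEFAULT_PROBABILITY_THRESHOLD,
):
    """Assemble packs from a pedigree-relations table.

    Parameters
    ----------
    relations : DataFrame
        Columns ``individual_a`` (parent for parent_offspring rows),
        ``individual_b`` (offspring), ``relation``, ``probability`` and an
        optional ``year`` (litter sampling-year for parent_offspring rows,
        used to date breeder tenures).
    sexes : dict
        individual_id -> {"F", "M", "U"} for the detected individuals.  IDs
        appearing in the relations table but not here are retained as
        undetected inferred members (e.g. a never-sampled breeder).

    Returns
    -------
    (packs, unassigned) : packs are connected components of the
        parent-offspring / full-sib graph; ``unassigned`` lists detected
        individuals in no component.
    """
    relations = _validate_relations(relations)
    kept = relations[relations["probability"] >= probability_threshold]

    parent_edges = kept[kept["relation"] == "parent_offspring"]
    pedigree = nx.DiGraph()
    pedigree.add_edges_from(zip(parent_edges["individual_a"],
                                parent_edges["individual_b"]))
    if not nx.is_directed_acyclic_graph(pedigree):
        cycle = nx.find_cycle(pedigree)
        raise ValueError(f"individual appears as its own ancestor: {cycle}")

    graph = nx.Graph()
    graph.add_nodes_from(sexes)
    connecting = kept[kept["relation"].isin(["parent_offspring", "full_sib"])]
    graph.add_edges_from(zip(connecting["individual_a"],
                             connecting["individual_b"]))

    components = [sorted(c) for c in nx.connected_components(graph) if len(c) > 1]
    components.sort(key=lambda c: c[0])

    packs = []
    for k, comp in enumerate(components, start=1):
        pack = Pack(pack_id=f"pack_{k:02d}")
        parents = {u for u, v in pedigree.edges if u in comp}
        for ind in comp:
            if ind not in sexes:
                pack.members[ind] = UNDETECTED_INFERRED
            elif ind in parents:
                sex = sexes.get(ind, "U")
                pack.members[ind] = BREEDER_F if sex == "F" else BREEDER_M
            else:
                pack.members[ind] = OFFSPRING
        pack.breeder_years = _breeder_tenures(parent_edges, comp, sexes)
        packs.append(pack)

    assigned = set().union(*(p.member_ids for p in packs)) if packs else set()
    unassigned = sorted(set(sexes) - assigned)
    return packs, unassigned


def _breeder_tenures(parent_edges: pd.DataFrame, comp, sexes: dict) -> dict:
    """Per litter-year breeding pair of a component, when years are known.

    The breeder of a role in year t is the parent of the most recent litter
    with year <= t, so a replacement starts a new tenure.
    """
    if "year" not in parent_edges.columns:
        return {}
    edges = parent_edges[parent_edges["individual_a"].isin(comp)].dropna(subset=["year"])
    if len(edges) == 0:
        return {}
    litters: dict[int, dict] = {}
    for _, row in edges.iterrows():
        year = int(row["year"])
        parent = row["individual_a"]
        role = "F" if sexes.get(parent, "U") == "F" else "M"
        litters.setdefault(year, {})[role] = parent
    years = sorted(litters)
    tenures: dict[int, dict] = {}
    current: dict[str, object] = {"F": None, "M": None}
    for y in range(min(years), max(years) + 1):
        if y in litters:
            current.update(litters[y])
        tenures[y] = dict(current)
    return tenures


def assign_unrelated(
    packs: list[Pack],
    unassigned: list,
    samples: pd.DataFrame,
    max_distance: float = DEFAULT_ADOPTION_RADIUS_M,
):
    """Adopt unrelated individuals into packs by the spatial-proximity rule.

    An unassigned individual joins a pack iff at least one of its samples was
    collected on the same calendar day as a sample of any pack member, within
    ``max_distance`` meters (strictly within or equal), with the same
    field-estimated age class of the sample.  Ties across packs are broken by
    minimum distance; an exact tie leaves the individual unassigned.  The
    result is independent of the processing order of unassigned individuals:
    adoptees are not treated as pack members when evaluating other candidates.

    Returns ``(packs, still_unassigned, adoption_log)``.
    """
    required = {"sample_id", "individual_id", "date", "x", "y", "field_age_class"}
    if not required <= set(samples.columns):
        raise ValueError(f"samples table needs columns {sorted(required)}")
    samples = samples.copy()
    samples["day"] = pd.to_datetime(samples["date"]).dt.date

    member_samples = {
        p.pack_id: samples[samples["individual_id"].isin(p.member_ids)]
        for p in packs
    }
    log_rows = []
    still = []
    for ind in unassigned:
        own = samples[samples["individual_id"] == ind]
        best: tuple[float, str, dict] | None = None
        tie = False
        for pack in packs:
            ms = member_samples[pack.pack_id]
            d = _min_proximity(own, ms)
            if d is None or d[0] > max_distance:
                continue
            if best is None or d[0] < best[0]:
                best = (d[0], pack.pack_id, d[1])
                tie = False
            elif d[0] == best[0] and pack.pack_id != best[1]:
                tie = True
        if best is None or tie:
            still.append(ind)
            continue
        dist, pack_id, just = best
        pack = next(p for p in packs if p.pack_id == pack_id)
        pack.members[ind] = UNRELATED_ADOPTEE
        record = {"individual_id": ind, "pack_id": pack_id,
                  "distance_m": dist, **just}
        pack.adoptions.append(record)
        log_rows.append(record)
    log = pd.DataFrame(
        log_rows, columns=["individual_id", "pack_id", "distance_m",
                           "sample_id", "member_sample_id", "day",
                           "field_age_class"])
    return packs, still, log


def _min_proximity(own: pd.DataFrame, member_samples: pd.DataFrame):
    """Minimum same-day, same-age-class distance between two sample sets."""
    merged = own.merge(
        member_samples, on=["day", "field_age_class"], suffixes=("", "_member"))
    if len(merged) == 0:
        return None
    d = np.hypot(merged["x"] - merged["x_member"],
                 merged["y"] - merged["y_member"])
    i = int(np.argmin(d.to_numpy()))
    row = merged.iloc[i]
    just = {"sample_id": row["sample_id"],
            "member_sample_id": row["sample_id_member"],
            "day": row["day"], "field_age_class": row["field_age_class"]}
    return float(d.iloc[i]), just


def turnover_report(packs: list[Pack], samples: pd.DataFrame) -> dict:
    """Breeder turnover, membership change, and dispersal across years.

    Returns a dict with

    * ``turnover``: DataFrame (pack_id, year_from, year_to, role,
      breeder_from, breeder_to) with one row per breeder replacement;
    * ``membership``: DataFrame (pack_id, year_from, year_to, gained, lost)
      of detected-member changes between consecutive detected years;
    * ``dispersers``: DataFrame (individual_id, pack_from, year_from,
      pack_to, year_to) for individuals detected in different packs over time.
    """
    samples = samples.copy()
    samples["year"] = pd.to_datetime(samples["date"]).map(sampling_year)

    turnover_rows = []
    member_rows = []
    for pack in packs:
        years = sorted(pack.breeder_years)
        for y0, y1 in zip(years, years[1:]):
            for role in ("F", "M"):
                b0 = pack.breeder_years[y0].get(role)
                b1 = pack.breeder_years[y1].get(role)
                if b0 is not None and b1 is not None and b0 != b1:
                    turnover_rows.append({
                        "pack_id": pack.pack_id, "year_from": y0,
                        "year_to": y1, "role": role,
                        "breeder_from": b0, "breeder_to": b1})
        det_years = sorted({sampling_year(d) for d in samples.loc[
            samples["individual_id"].isin(pack.member_ids), "date"]})
        for y0, y1 in zip(det_years, det_years[1:]):
            m0 = pack.detected_members(samples, y0)
            m1 = pack.detected_members(samples, y1)
            member_rows.append({
                "pack_id": pack.pack_id, "year_from": y0, "year_to": y1,
                "gained": sorted(m1 - m0), "lost": sorted(m0 - m1)})
    disperser_rows = _dispersers(packs, samples)

    return {
        "turnover": pd.DataFrame(
            turnover_rows, columns=["pack_id", "year_from", "year_to", "role",
                                    "breeder_from", "breeder_to"]),
        "membership": pd.DataFrame(
            member_rows, columns=["pack_id", "year_from", "year_to",
                                  "gained", "lost"]),
        "dispersers": pd.DataFrame(
            disperser_rows, columns=["individual_id", "pack_from",
                                     "year_from", "pack_to", "year_to"]),
    }


def _dispersers(packs: list[Pack], samples: pd.DataFrame) -> list[dict]:
    """Individuals attending different packs in different years.

    Year-by-year attendance is decided by sample proximity (same day, within
    the adoption radius, same field-estimated sample age) to another pack
    member's samples, falling back to the individual's static pack when no
    proximity signal exists; a change of attendance between detected years is
    a dispersal event.
    """
    if len(samples) == 0:
        return []
    samples = samples.copy()
    if "day" not in samples.columns:
        samples["day"] = pd.to_datetime(samples["date"]).dt.date
    if "field_age_class" not in samples.columns:
        samples["field_age_class"] = "unknown"
    samples["year"] = pd.to_datetime(samples["date"]).map(sampling_year)
    pack_of = {ind: p.pack_id for p in packs for ind in p.member_ids}

    attendance: dict[str, list] = {}
    for (ind, year), own in samples.groupby(["individual_id", "year"]):
        best = None
        for pack in packs:
            others = samples[
                samples["individual_id"].isin(pack.member_ids - {ind})
                & (samples["year"] == year)]
            d = _min_proximity(own, others)
            if d is not None and d[0] <= DEFAULT_ADOPTION_RADIUS_M:
                if best is None or d[0] < best[0]:
                    best = (d[0], pack.pack_id)
        attended = best[1] if best is not None else pack_of.get(ind)
        if attended is not None:
            attendance.setdefault(ind, []).append((int(year), attended))

    rows = []
    for ind, visits in attendance.items():
        visits = sorted(set(visits))
        for (y0, p0), (y1, p1) in zip(visits, visits[1:]):
            if p0 != p1:
                rows.append({"individual_id": ind, "pack_from": p0,
                             "year_from": y0, "pack_to": p1, "year_to": y1})
    return rows


class PackAssembler:
    """Estimator wrapper: relations + samples -> packs with adoptions."""

    def __init__(self,
                 probability_threshold: float = DEFAULT_PROBABILITY_THRESHOLD,
                 adoption_radius_m: float = DEFAULT_ADOPTION_RADIUS_M):
        self.probability_threshold = probability_threshold
        self.adoption_radius_m = adoption_radius_m

    def get_params(self, deep=True):
        return {"probability_threshold": self.probability_threshold,
                "adoption_radius_m": self.adoption_radius_m}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, relations: pd.DataFrame, sexes: dict,
            samples: pd.DataFrame):
        packs, unassigned = build_packs(
            relations, sexes, self.probability_threshold)
        packs, unassigned, log = assign_unrelated(
            packs, unassigned, samples, self.adoption_radius_m)
        self.packs_ = packs
        self.unassigned_ = unassigned
        self.adoption_log_ = log
        self.report_ = turnover_report(packs, samples)
        return self
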