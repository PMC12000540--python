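"""Readers/writers for the pipeline's plain-text formats and the
sample-accounting report.

All tables are uncompressed CSV.  Replicate microsatellite calls travel in
long format (sample_id, replicate, locus, allele1, allele2; blank alleles =
no amplification; the Amelogenin sex locus uses the reserved locus id
``AMEL`` with X/Y letters).  Coordinates are projected meters throughout.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import NO_CALL, ConsensusGenotype, Individual, ReplicateSet
from .prep import DetectorGrid, HabitatMask

AMEL_LOCUS = "AMEL"

OUTCOMES = ("genotyped", "mixed", "poor", "nontarget")


# ---------------------------------------------------------------------------
# Replicate genotype tables
# ---------------------------------------------------------------------------

def write_replicate_calls(replicate_sets: list[ReplicateSet], path) -> None:
    rows = []
    for rs in replicate_sets:
        for r in range(rs.n_replicates):
            for l, locus in enumerate(rs.locus_ids):
                a1, a2 = rs.calls[r, l]
                rows.append((rs.sample_id, r + 1, locus,
                             "" if a1 == NO_CALL else int(a1),
                             "" if a2 == NO_CALL else int(a2)))
            amel = rs.amel[r]
            if amel is None:
                rows.append((rs.sample_id, r + 1, AMEL_LOCUS, "", ""))
            else:
                rows.append((rs.sample_id, r + 1, AMEL_LOCUS,
                             amel[0], amel[1]))
    pd.DataFrame(rows, columns=["sample_id", "replicate", "locus",
                                "allele1", "allele2"]).to_csv(path, index=False)


def read_replicate_calls(path) -> list[ReplicateSet]:
    df = pd.read_csv(path, dtype={"allele1": str, "allele2": str},
                     keep_default_na=False)
    out = []
    for sample_id, grp in df.groupby("sample_id", sort=True):
        loci = [l for l in grp["locus"].unique() if l != AMEL_LOCUS]
        reps = sorted(grp["replicate"].unique())
        calls = np.full((len(reps), len(loci), 2), NO_CALL, dtype=int)
        amel: list = [None] * len(reps)
        locus_idx = {l: i for i, l in enumerate(loci)}
        rep_idx = {r: i for i, r in enumerate(reps)}
        for _, row in grp.iterrows():
            r = rep_idx[row["replicate"]]
            if row["locus"] == AMEL_LOCUS:
                if row["allele1"]:
                    amel[r] = f"{row['allele1']}{row['allele2']}"
                continue
            if row["allele1"]:
                calls[r, locus_idx[row["locus"]]] = sorted(
                    (int(float(row["allele1"])), int(float(row["allele2"]))))
        out.append(ReplicateSet(sample_id=str(sample_id), calls=calls,
                                amel=amel, locus_ids=loci))
    return out


# ---------------------------------------------------------------------------
# Consensus genotypes and individuals
# ---------------------------------------------------------------------------

def _format_call(alleles, ambiguous: bool) -> str:
    if alleles[0] == NO_CALL:
        return ""
    s = f"{int(alleles[0])}/{int(alleles[1])}"
    return s + "*" if ambiguous else s


def write_consensus(genotypes: list[ConsensusGenotype], path) -> None:
    """One row per sample; per-locus calls as ``a1/a2`` (``*`` marks a
    dropout-ambiguous provisional homozygote, blank a missing locus)."""
    rows = []
    for g in genotypes:
        row = {"sample_id": g.sample_id, "sex": g.sex,
               "quality_index": g.quality_index,
               "reliability": g.reliability,
               "n_replicates": g.n_replicates}
        for l, locus in enumerate(g.locus_ids):
            row[locus] = _format_call(g.alleles[l], bool(g.ambiguous[l]))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_consensus(path) -> list[ConsensusGenotype]:
    df = pd.read_csv(path, keep_default_na=False)
    meta_cols = {"sample_id", "sex", "quality_index", "reliability",
                 "n_replicates"}
    loci = [c for c in df.columns if c not in meta_cols]
    out = []
    for _, row in df.iterrows():
        alleles = np.full((len(loci), 2), NO_CALL, dtype=int)
        ambiguous = np.zeros(len(loci), dtype=bool)
        for l, locus in enumerate(loci):
            cell = str(row[locus])
            if not cell:
                continue
            if cell.endswith("*"):
                ambiguous[l] = True
                cell = cell[:-1]
            a1, a2 = cell.split("/")
            alleles[l] = (int(a1), int(a2))
        out.append(ConsensusGenotype(
            sample_id=str(row["sample_id"]), alleles=alleles,
            ambiguous=ambiguous, locus_ids=loci,
            quality_index=float(row["quality_index"]),
            reliability=float(row["reliability"]),
            sex=str(row["sex"]),
            n_replicates=int(row["n_replicates"])))
    return out


def write_individuals(individuals: list[Individual], path) -> None:
    rows = [{"individual_id": ind.individual_id, "sex": ind.sex,
             "n_samples": len(ind.sample_ids),
             "sample_ids": ";".join(ind.sample_ids),
             "flagged_for_review": ind.flagged_for_review}
            for ind in individuals]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# SCR tables
# ---------------------------------------------------------------------------

def write_detectors(detectors: DetectorGrid, path) -> None:
    df = pd.DataFrame({"detector": np.arange(detectors.n_detectors),
                       "x": detectors.coords[:, 0],
                       "y": detectors.coords[:, 1],
                       "effort": detectors.effort})
    with open(path, "w") as fh:
        fh.write(f"# cell_size_m={detectors.cell_size} "
                 f"origin_x={detectors.origin[0]} "
                 f"origin_y={detectors.origin[1]}\n")
        df.to_csv(fh, index=False)


def read_detectors(path) -> DetectorGrid:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(kv.split("=") for kv in header.split())
        df = pd.read_csv(fh)
    return DetectorGrid(
        coords=df[["x", "y"]].to_numpy(float),
        effort=df["effort"].to_numpy(float),
        cell_size=float(meta["cell_size_m"]),
        origin=(float(meta["origin_x"]), float(meta["origin_y"])))


def write_mask(mask: HabitatMask, path) -> None:
    df = pd.DataFrame({"x": mask.coords[:, 0], "y": mask.coords[:, 1]})
    with open(path, "w") as fh:
        fh.write(f"# cell_size_m={mask.cell_size} buffer_m={mask.buffer_m}\n")
        df.to_csv(fh, index=False)


def read_mask(path) -> HabitatMask:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(kv.split("=") for kv in header.split())
        df = pd.read_csv(fh)
    return HabitatMask(coords=df[["x", "y"]].to_numpy(float),
                       cell_size=float(meta["cell_size_m"]),
                       buffer_m=float(meta["buffer_m"]))


def write_encounters(y: np.ndarray, individual_ids: list, path) -> None:
    df = pd.DataFrame(y, index=pd.Index(individual_ids, name="individual_id"),
                      columns=[f"d{j}" for j in range(y.shape[1])])
    df.to_csv(path)


def read_encounters(path):
    df = pd.read_csv(path, index_col="individual_id")
    return df.to_numpy(int), list(df.index)


def mask_to_geojson(mask: HabitatMask, values: np.ndarray | None = None) -> dict:
    """Mask cells (optionally carrying a density value) as GeoJSON polygons."""
    h = mask.cell_size / 2.0
    features = []
    for i, (x, y) in enumerate(mask.coords):
        ring = [[x - h, y - h], [x + h, y - h], [x + h, y + h],
                [x - h, y + h], [x - h, y - h]]
        props = {"cell": i}
        if values is not None:
            props["density"] = float(values[i])
        features.append({"type": "Feature",
                         "geometry": {"type": "Polygon",
                                      "coordinates": [ring]},
                         "properties": props})
    return {"type": "FeatureCollection", "features": features}


# ---------------------------------------------------------------------------
# Sample accounting (genotyping-success report)
# ---------------------------------------------------------------------------

def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def accounting_report(samples: pd.DataFrame) -> pd.DataFrame:
    """Genotyping-success table: counts per sample type and outcome, plus a
    total row with round-half-up percentages of all samples (one decimal).

    ``samples`` needs columns ``sample_type`` and ``outcome`` with outcomes
    in {genotyped, mixed, poor, nontarget}; alternatively pass a
    pre-aggregated table with columns ``sample_type``, one column per
    outcome, and counts.
    """
    if set(OUTCOMES) <= set(samples.columns):
        counts = samples.set_index("sample_type")[list(OUTCOMES)].fillna(0)
    else:
        bad = set(samples["outcome"]) - set(OUTCOMES)
        if bad:
            raise ValueError(f"unlabeled or unknown outcomes: {sorted(bad)}")
        counts = (samples.groupby(["sample_type", "outcome"])
                  .size().unstack(fill_value=0)
                  .reindex(columns=list(OUTCOMES), fill_value=0))
    counts = counts.astype(int)
    counts.insert(0, "n_samples", counts.sum(axis=1))
    total_n = int(counts["n_samples"].sum())
    if total_n == 0:
        raise ValueError("no samples to report")
    total = {"n_samples": total_n}
    for outcome in OUTCOMES:
        total[outcome] = _round_half_up(
            100.0 * counts[outcome].sum() / total_n)
    out = counts.copy().astype(object)
    out.loc["Total"] = pd.Series(total)
    return out


def accounting_percentages(samples: pd.DataFrame) -> dict:
    """Just the total percentages per outcome (round-half-up, one decimal)."""
    table = accounting_report(samples)
    return {o: float(table.loc["Total", o]) for o in OUTCOMES}


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline run settings; serializable to/from JSON."""

    output_dir: str = "wolfscr_out"
    seed: int = 0
    stages: list = field(default_factory=lambda: [
        "simulate", "genotype", "match", "packs", "prep", "fit", "gof",
        "report"])
    crs: str = "EPSG:32635"  # UTM 35N; internal distances in meters
    # thresholds and model settings (defaults match the module defaults)
    reliability_threshold: float = 0.98
    quality_threshold: float = 0.4
    probability_threshold: float = 0.8
    adoption_radius_m: float = 500.0
    autocorr_radius_m: float = 1000.0
    cell_size_m: float = 2500.0
    buffer_m: float = 10_000.0
    mask_cell_m: float = 500.0
    chains: int = 3
    iters: int = 50_000
    burnin: int = 1_000
    thin: int = 5
    M: int | None = None
    # input paths (optional when the simulate stage provides them)
    replicate_calls: str | None = None
    sample_metadata: str | None = None
    relations: str | None = None
    tracks: str | None = None

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))
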