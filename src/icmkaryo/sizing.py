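"""Integrated optical density and proportional chromosomal DNA allocation.

The chromosomal DNA amounts are obtained by distributing the nuclear 2C
value (from flow cytometry) over the chromosome complement in proportion to
integrated optical density (IOD):

    IOD_c = mean over metaphases of the two homologs' summed IOD (per pair)
    IOD_t = sum of IOD_c over all pairs
    2C_c  = 2C_n * IOD_c / IOD_t        (per pair)
    2C_b  = 2C_n * IOD_b / IOD_t        (per arm / satellite portion)

so pair values sum exactly to the nuclear 2C and arm values sum exactly to
their pair value.  Standard deviations come from per-metaphase allocations,
mirroring the between-metaphase variation of the published +-SD columns.
pg <-> bp conversion uses 1 pg = 0.978e9 bp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .densitometry import ODMap
from .errors import ValidationError
from .fcm import NuclearDNAEstimate
from .reference import BP_PER_PG

ARM_ORDER = ("SAT", "S", "L")


@dataclass
class IODResult:
    """Area, mean OD and their product (IOD) over one mask."""

    area_um2: float
    mean_od: float
    iod: float
    saturated: bool = False


def integrate_iod(od_map, mask, um2_per_px: float | None = None) -> IODResult:
    """Integrate optical density over a mask.

    area = pixel count x um^2/px, mean_od = mean OD over the mask, and
    iod = area x mean_od, identical to the per-pixel sum of OD x um^2/px.
    The result is flagged when the mask contains saturated (capped) pixels.
    """
    if isinstance(od_map, ODMap):
        od = od_map.od
        a = od_map.pixel_area_um2 if um2_per_px is None else um2_per_px
        sat = od_map.saturation
    else:
        od = np.asarray(od_map, dtype=float)
        a = 1.0 if um2_per_px is None else um2_per_px
        sat = None
    mask = np.asarray(mask, dtype=bool)
    npx = int(mask.sum())
    if npx == 0:
        raise ValidationError("empty mask")
    mean_od = float(od[mask].mean())
    area = npx * a
    saturated = bool(sat[mask].any()) if sat is not None else False
    return IODResult(area, mean_od, area * mean_od, saturated)


@dataclass
class IODRecord:
    """Aggregated IOD of one pair over n metaphases.

    ``per_metaphase`` maps metaphase id -> (pair IOD, {arm -> arm IOD}) for
    the metaphases in which both homologs were measured.
    """

    pair_id: int
    iod_c: float
    arm_iod_b: dict
    n: int
    per_metaphase: dict = field(default_factory=dict)


def aggregate_pair_iod(records) -> dict[int, IODRecord]:
    """Aggregate per-homolog IODs into per-pair means over metaphases.

    ``records`` is a list over metaphases; each entry maps pair id to the
    list of homolog measurements, each a dict with ``total`` (IOD of the
    chromosome) and ``arms`` ({portion -> IOD}; portions absent from a
    homolog count as zero).  A metaphase contributing a number of homologs
    other than two for some pair is excluded for that pair with a warning.
    """
    pair_ids = sorted({pid for meta in records for pid in meta})
    out: dict[int, IODRecord] = {}
    for pid in pair_ids:
        per_meta = {}
        for mid, meta in enumerate(records):
            homologs = meta.get(pid, [])
            if len(homologs) != 2:
                warnings.warn(
                    f"pair {pid}: metaphase {mid} has {len(homologs)} homolog(s); excluded"
                )
                continue
            pair_sum = sum(h["total"] for h in homologs)
            arms: dict[str, float] = {}
            for h in homologs:
                for arm, v in h["arms"].items():
                    arms[arm] = arms.get(arm, 0.0) + v
            per_meta[mid] = (pair_sum, arms)
        if not per_meta:
            raise ValidationError(f"pair {pid}: no complete metaphase")
        n = len(per_meta)
        iod_c = sum(v[0] for v in per_meta.values()) / n
        arm_keys = sorted({a for _, arms in per_meta.values() for a in arms})
        arm_iod_b = {
            a: sum(arms.get(a, 0.0) for _, arms in per_meta.values()) / n
            for a in arm_keys
        }
        out[pid] = IODRecord(pid, iod_c, arm_iod_b, n, per_meta)
    return out


@dataclass
class AllocEntry:
    pg: float
    sd: float | None = None


@dataclass
class DNAAllocation:
    """Per-pair and per-arm 2C DNA amounts allocated from IOD shares."""

    nuclear_2C_pg: float
    iod_t: float
    pairs: dict = field(default_factory=dict)  # pair -> AllocEntry
    arms: dict = field(default_factory=dict)  # (pair, portion) -> AllocEntry

    def one_c_bp(self, pair_id: int, arm: str | None = None) -> float:
        """1C value in bp of a pair or one of its portions."""
        entry = self.pairs[pair_id] if arm is None else self.arms[(pair_id, arm)]
        return two_c_to_one_c(entry.pg) * BP_PER_PG / 1.0  # pg -> bp

    def to_table(self, ndigits: int = 3) -> pd.DataFrame:
        """Tabulate arm-level values in the published layout.

        Columns: chromosome, portion, 2C pg (+sd) and the 1C value in units
        of 1e9 bp; pg and bp are rounded to ``ndigits`` decimals.
        """
        rows = []
        for (pid, arm) in sorted(
            self.arms, key=lambda k: (k[0], ARM_ORDER.index(k[1]))
        ):
            e = self.arms[(pid, arm)]
            rows.append(
                {
                    "chromosome": pid,
                    "portion": arm,
                    "2C_pg": round(e.pg, ndigits),
                    "sd_pg": round(e.sd, ndigits) if e.sd is not None else None,
                    "1C_bp_e9": round(two_c_to_one_c(e.pg) * BP_PER_PG / 1e9, ndigits),
                }
            )
        return pd.DataFrame(rows)

    def pair_one_c_bp_rounded(self, ndigits: int = 3) -> dict[int, float]:
        """Pair-level 1C values in bp after rounding at 1e9-bp scale.

        Matches the published practice of comparing values printed to three
        decimals of 1e9 bp.
        """
        return {
            pid: round(two_c_to_one_c(e.pg) * BP_PER_PG / 1e9, ndigits) * 1e9
            for pid, e in self.pairs.items()
        }


def _nuclear_pg(nuclear) -> float:
    if isinstance(nuclear, NuclearDNAEstimate):
        return nuclear.mean_2C
    return float(nuclear)


def _as_records(pair_iods) -> dict[int, IODRecord]:
    recs = {}
    for pid, v in pair_iods.items():
        if isinstance(v, IODRecord):
            recs[pid] = v
        else:
            recs[pid] = IODRecord(pid, float(v), {}, 1, {})
    return recs


def allocate_2C(nuclear, pair_iods) -> DNAAllocation:
    """Allocate the nuclear 2C over pairs in proportion to their IOD_c.

    ``pair_iods`` maps pair id to either a plain IOD value or an
    ``IODRecord``; with records, per-metaphase allocations provide the SD.
    The pair values sum to the nuclear 2C exactly.
    """
    two_c_n = _nuclear_pg(nuclear)
    recs = _as_records(pair_iods)
    if any(r.iod_c <= 0 for r in recs.values()):
        raise ValidationError("all pair IODs must be positive")
    iod_t = sum(r.iod_c for r in recs.values())
    if iod_t <= 0:
        raise ValidationError("total IOD is zero")
    alloc = DNAAllocation(two_c_n, iod_t)
    per_meta_alloc = _per_metaphase_allocations(two_c_n, recs)
    for pid, r in recs.items():
        sd = _sd_or_none(per_meta_alloc.get(pid))
        alloc.pairs[pid] = AllocEntry(two_c_n * r.iod_c / iod_t, sd)
    return alloc


def allocate_arm_2C(nuclear, pair_records) -> DNAAllocation:
    """Allocate 2C down to arms/satellites: 2C_b = 2C_n * IOD_b / IOD_t.

    Uses the same complement total IOD_t as the pair-level allocation, so
    arm values sum exactly to their pair value and pairs to the nuclear 2C.
    """
    two_c_n = _nuclear_pg(nuclear)
    recs = _as_records(pair_records)
    iod_t = sum(r.iod_c for r in recs.values())
    if iod_t <= 0:
        raise ValidationError("total IOD is zero")
    alloc = DNAAllocation(two_c_n, iod_t)
    per_meta_pair = _per_metaphase_allocations(two_c_n, recs)
    per_meta_arm = _per_metaphase_allocations(two_c_n, recs, arms=True)
    for pid, r in recs.items():
        alloc.pairs[pid] = AllocEntry(
            two_c_n * r.iod_c / iod_t, _sd_or_none(per_meta_pair.get(pid))
        )
        if not r.arm_iod_b:
            raise ValidationError(f"pair {pid} has no arm-level IODs")
        for arm, iod_b in r.arm_iod_b.items():
            alloc.arms[(pid, arm)] = AllocEntry(
                two_c_n * iod_b / iod_t, _sd_or_none(per_meta_arm.get((pid, arm)))
            )
    return alloc


def _per_metaphase_allocations(two_c_n, recs, arms: bool = False):
    """Per-metaphase allocated pg values, for SD estimation.

    Only metaphases in which every pair was measured contribute (the
    per-metaphase complement total must be complete to normalise).
    """
    metas = None
    for r in recs.values():
        ids = set(r.per_metaphase)
        metas = ids if metas is None else metas & ids
    if not metas:
        return {}
    out: dict = {}
    for mid in sorted(metas):
        iod_t_m = sum(r.per_metaphase[mid][0] for r in recs.values())
        if iod_t_m <= 0:
            continue
        for pid, r in recs.items():
            pair_sum, arm_sums = r.per_metaphase[mid]
            if arms:
                for arm, v in arm_sums.items():
                    out.setdefault((pid, arm), []).append(two_c_n * v / iod_t_m)
            else:
                out.setdefault(pid, []).append(two_c_n * pair_sum / iod_t_m)
    return out


def _sd_or_none(values):
    if not values or len(values) < 2:
        return None
    return float(np.std(values, ddof=1))


def two_c_to_one_c(pg: float) -> float:
    """Halve a 2C amount (pg) to its 1C amount."""
    if pg < 0:
        raise ValidationError("DNA amount must be non-negative")
    return pg / 2.0


def pg_to_bp(pg: float) -> float:
    """Convert a DNA mass in pg to base pairs (1 pg = 0.978e9 bp)."""
    if pg < 0:
        raise ValidationError("DNA amount must be non-negative")
    return pg * BP_PER_PG
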