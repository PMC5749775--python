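"""Homolog pairing, chromosome numbering, karyogram and ideogram assembly.

Within a metaphase, homologs are paired by greedy minimum-distance matching
on z-scored features (total length, centromeric index, IOD) — the DNA
amount is what disambiguates morphologically similar pairs.  Pairs are then
numbered either by decreasing length or by nearest-neighbour assignment to
a reference table, which preserves conventional numbers even where they are
not strictly size-ordered (in maize, chromosome 9 carries more DNA and area
than chromosome 8).  Karyogram tables aggregate the per-pair morphometry
and DNA across metaphases; the ideogram is rendered as a simple SVG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import ValidationError
from .morphometry import ChromosomeMeasurement, classify_class
from .sizing import DNAAllocation, two_c_to_one_c
from .reference import BP_PER_PG


# ---------------------------------------------------------------------------
# Homolog pairing
# ---------------------------------------------------------------------------

@dataclass
class PairingResult:
    pairs: list  # list of (i, j) measurement-index tuples
    ambiguous: bool
    distances: list


def _features(measurements) -> np.ndarray:
    return np.array(
        [[m.total_length_um, m.ci, m.iod] for m in measurements], dtype=float
    )


def pair_homologs(
    measurements, weights=(1.0, 1.0, 1.0), tie_tol: float = 1e-9
) -> PairingResult:
    """Pair homologs by greedy minimum-weight matching on feature distance.

    Features (total length, CI, IOD) are z-scored and weighted; the closest
    unmatched couple is paired repeatedly.  Ties within ``tie_tol`` are
    broken by object index and flag the result as ambiguous.
    """
    n = len(measurements)
    if n % 2 != 0:
        raise ValidationError(f"odd number of chromosomes ({n}); cannot pair")
    feats = _features(measurements)
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    z = (feats - feats.mean(axis=0)) / sd * np.asarray(weights, dtype=float)
    diff = z[:, None, :] - z[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    cand = sorted(
        ((dist[i, j], i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    free = set(range(n))
    pairs, dists = [], []
    ambiguous = False
    k = 0
    while free and k < len(cand):
        d, i, j = cand[k]
        if i in free and j in free:
            nxt = next(
                (
                    c
                    for c in cand[k + 1 :]
                    if c[1] in free and c[2] in free
                    and (c[1] in (i, j) or c[2] in (i, j))
                ),
                None,
            )
            if nxt is not None and abs(nxt[0] - d) <= tie_tol:
                ambiguous = True
            pairs.append((i, j))
            dists.append(float(d))
            free -= {i, j}
        k += 1
    pairs.sort()
    return PairingResult(pairs, ambiguous, dists)


# ---------------------------------------------------------------------------
# Numbering
# ---------------------------------------------------------------------------

@dataclass
class NumberingResult:
    numbers: dict  # pair index (into the pairs list) -> chromosome number
    inversions: list  # numbers where conventional and size order disagree
    mode: str


def _pair_feature_table(measurements, pairs):
    rows = []
    for (i, j) in pairs:
        a, b = measurements[i], measurements[j]
        rows.append(
            {
                "length": (a.total_length_um + b.total_length_um) / 2.0,
                "ci": (a.ci + b.ci) / 2.0,
                "iod": (a.iod + b.iod) / 2.0,
            }
        )
    return pd.DataFrame(rows)


def assign_numbers(
    measurements,
    pairs,
    mode: str = "by_length",
    reference: pd.DataFrame | None = None,
) -> NumberingResult:
    """Assign chromosome numbers 1..n to homolog pairs.

    ``by_length`` numbers by decreasing mean total length (ties broken by
    decreasing CI, then pair order).  ``reference_map`` assigns each pair to
    the nearest row of a reference table with columns ``number``, ``length``
    and ``ci`` (one-to-one, minimum total normalized distance), preserving
    conventional numbering; any disagreement with the pure length order is
    reported in ``inversions``.
    """
    tab = _pair_feature_table(measurements, pairs)
    n = len(tab)
    order = sorted(
        range(n), key=lambda k: (-tab.length[k], -tab.ci[k], k)
    )
    by_length = {pair_idx: rank + 1 for rank, pair_idx in enumerate(order)}
    if mode == "by_length":
        return NumberingResult(by_length, [], mode)
    if mode != "reference_map":
        raise ValidationError(f"unknown numbering mode: {mode}")
    if reference is None or len(reference) != n:
        raise ValidationError(
            f"reference table must have exactly {n} rows (got "
            f"{0 if reference is None else len(reference)})"
        )
    q = tab[["length", "ci"]].to_numpy()
    r = reference[["length", "ci"]].to_numpy()
    scale = q.std(axis=0)
    scale[scale == 0] = 1.0
    cost = np.linalg.norm(
        (q[:, None, :] - r[None, :, :]) / scale, axis=2
    )
    rows, cols = linear_sum_assignment(cost)
    numbers = {
        int(i): int(reference["number"].iloc[j]) for i, j in zip(rows, cols)
    }
    inversions = sorted(
        numbers[k] for k in range(n) if numbers[k] != by_length[k]
    )
    return NumberingResult(numbers, inversions, mode)


# ---------------------------------------------------------------------------
# Karyogram table
# ---------------------------------------------------------------------------

@dataclass
class KaryogramTable:
    """Per-pair karyotype summary across metaphases."""

    table: pd.DataFrame

    def class_counts(self) -> dict:
        return self.table["class"].value_counts().to_dict()


def build_karyogram(numbered_metaphases) -> KaryogramTable:
    """Aggregate numbered pair measurements across metaphases.

    ``numbered_metaphases`` is a list (one entry per metaphase) of dicts
    mapping chromosome number -> (measurement, measurement).  The output
    rows hold per-pair means over metaphases: lengths (total, S, L, SAT),
    arm ratio, CI, class (from the mean arm ratio), relative length (% of
    the complement) and mean pair IOD.
    """
    if not numbered_metaphases:
        raise ValidationError("at least one metaphase is required")
    numbers = sorted({n for meta in numbered_metaphases for n in meta})
    rows = []
    for num in numbers:
        tot, s_len, l_len, sat_len, ratios, cis, iods = [], [], [], [], [], [], []
        count = 0
        for meta in numbered_metaphases:
            if num not in meta:
                continue
            count += 1
            ms = meta[num]
            tot.append(np.mean([m.total_length_um for m in ms]))
            s_len.append(np.mean([m.short_um for m in ms]))
            l_len.append(np.mean([m.long_um for m in ms]))
            sat_len.append(np.mean([m.lengths_um.get("SAT", 0.0) for m in ms]))
            ratios.append(np.mean([m.arm_ratio for m in ms]))
            cis.append(np.mean([m.ci for m in ms]))
            iods.append(np.sum([m.iod for m in ms]))
        mean_ratio = float(np.mean(ratios))
        rows.append(
            {
                "number": num,
                "n_metaphases": count,
                "total_um": float(np.mean(tot)),
                "S_um": float(np.mean(s_len)),
                "L_um": float(np.mean(l_len)),
                "SAT_um": float(np.mean(sat_len)),
                "arm_ratio": mean_ratio,
                "ci": float(np.mean(cis)),
                "class": classify_class(mean_ratio),
                "mean_pair_iod": float(np.mean(iods)),
            }
        )
    tab = pd.DataFrame(rows)
    tab["relative_length_pct"] = 100.0 * tab["total_um"] / tab["total_um"].sum()
    return KaryogramTable(tab)


# ---------------------------------------------------------------------------
# Ideogram (SVG)
# ---------------------------------------------------------------------------

def build_ideogram(
    karyogram: KaryogramTable,
    px_per_um: float = 18.0,
    bar_width: float = 16.0,
    gap: float = 46.0,
) -> str:
    """Render the karyogram as an SVG ideogram string.

    One vertical bar per pair, split at the centromere, with the satellite
    drawn as a detached distal block on the short arm; the annotation under
    each bar gives the relative arm lengths (S/L) and the arm ratio.
    """
    tab = karyogram.table.sort_values("number")
    top_pad, bottom_pad = 30.0, 56.0
    max_len = tab["total_um"].max() * px_per_um
    height = top_pad + max_len + bottom_pad
    width = gap * (len(tab) + 0.5)
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
        f'height="{height:.0f}" font-family="sans-serif" font-size="9">'
    ]
    for k, (_, row) in enumerate(tab.iterrows()):
        x = gap * (k + 0.5)
        s_px = row.S_um * px_per_um
        l_px = row.L_um * px_per_um
        sat_px = row.SAT_um * px_per_um
        # bars hang from a common centromere line so arms are comparable
        cen_y = top_pad + tab["S_um"].max() * px_per_um + 6.0
        if sat_px > 1:
            parts.append(
                f'<rect x="{x:.1f}" y="{cen_y - s_px - sat_px - 3:.1f}" '
                f'width="{bar_width}" height="{sat_px:.1f}" rx="3" '
                f'fill="#c9a86a" stroke="#333"/>'
            )
        parts.append(
            f'<rect x="{x:.1f}" y="{cen_y - s_px:.1f}" width="{bar_width}" '
            f'height="{s_px:.1f}" rx="4" fill="#7f9fc4" stroke="#333"/>'
        )
        parts.append(
            f'<rect x="{x:.1f}" y="{cen_y + 2:.1f}" width="{bar_width}" '
            f'height="{l_px:.1f}" rx="4" fill="#4f6d96" stroke="#333"/>'
        )
        label_y = cen_y + l_px + 14
        total = row.S_um + row.L_um
        parts.append(
            f'<text x="{x + bar_width / 2:.1f}" y="{label_y:.1f}" '
            f'text-anchor="middle">{int(row.number)}</text>'
        )
        parts.append(
            f'<text x="{x + bar_width / 2:.1f}" y="{label_y + 11:.1f}" '
            f'text-anchor="middle">{100 * row.S_um / total:.0f}/'
            f'{100 * row.L_um / total:.0f}</text>'
        )
        parts.append(
            f'<text x="{x + bar_width / 2:.1f}" y="{label_y + 22:.1f}" '
            f'text-anchor="middle">r={row.arm_ratio:.2f}</text>'
        )
    parts.append("</svg>")
    return "\n".join(parts)


# ---------------------------------------------------------------------------
# Cross-study comparison
# ---------------------------------------------------------------------------

def compare_to_reference(query: dict, reference: dict, query_name="query",
                         ref_name="reference") -> pd.DataFrame:
    """Percent differences between two chromosome-keyed value sets.

    For every key of ``reference`` the report gives both directions
    explicitly: ``pct_query_vs_ref`` = 100*(query - ref)/ref (positive when
    the query exceeds the reference) and the converse with the query as
    denominator.  Raises on missing keys.
    """
    missing = [k for k in reference if k not in query]
    if missing:
        raise ValidationError(f"query lacks chromosome keys: {missing}")
    rows = []
    for k in sorted(reference):
        q, r = float(query[k]), float(reference[k])
        rows.append(
            {
                "chromosome": k,
                query_name: q,
                ref_name: r,
                "pct_query_vs_ref": 100.0 * (q - r) / r,
                "pct_ref_vs_query": 100.0 * (r - q) / q,
            }
        )
    return pd.DataFrame(rows)


def allocation_comparison_values(alloc: DNAAllocation, ndigits: int = 3) -> dict:
    """Pair-level 1C bp values rounded as printed, for cross-study reports."""
    return {
        pid: round(two_c_to_one_c(e.pg) * BP_PER_PG / 1e9, ndigits) * 1e9
        for pid, e in alloc.pairs.items()
    }
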