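"""End-to-end pipeline: simulate -> calibrate -> fcm -> measure -> allocate
-> karyotype -> compare, with a JSON manifest of every stage's metrics.

The pipeline is configuration-driven (``PipelineConfig``, YAML round-trip):
every stochastic stage carries an explicit seed, so a config re-run yields
an identical manifest.  ``reproduce_published_numbers`` recomputes the
published summary values from their printed inputs (no images needed) and
reports pass/fail at the stated tolerances.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import densitometry, fcm, karyotyping, morphometry, reference, sizing, synthetic
from .errors import IcmError, StageError, ValidationError


@dataclass
class PipelineConfig:
    """All pipeline parameters; every stochastic stage has an explicit seed."""

    outdir: str = "icmkaryo_out"
    seed: int = 1
    n_metaphases: int = 5
    # imaging
    bit_depth: int = 12
    background: float = 3000.0
    pixel_size_um: float = 0.08
    noise_sd: float = 8.0
    gradient_amplitude: float = 0.0
    canvas: tuple[int, int] = (560, 560)
    # flow cytometry
    standard_2C_pg: float = reference.STANDARD_2C_PG
    cv_standard_pct: float = reference.CV_STANDARD_PCT
    cv_sample_pct: float = reference.CV_SAMPLE_PCT
    fcm_replicates: int = 5
    fcm_nuclei: int = 10_000
    # analysis
    min_area_px: int = 50
    numbering_mode: str = "reference_map"
    write_images: bool = True

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "canvas" in data:
            data["canvas"] = tuple(data["canvas"])
        return cls(**data)

    def image_params(self, seed: int) -> synthetic.ImageParams:
        return synthetic.ImageParams(
            bit_depth=self.bit_depth,
            background=self.background,
            pixel_size_um=self.pixel_size_um,
            noise_sd=self.noise_sd,
            gradient_amplitude=self.gradient_amplitude,
            canvas_shape=tuple(self.canvas),
            seed=seed,
        )


def maize_reference_table(spec=None) -> pd.DataFrame:
    """Reference (number, length, CI) table for conventional maize numbering."""
    spec = spec or synthetic.default_maize_spec()
    rows = [
        {
            "number": p.pair_id,
            "length": p.total_um,
            "ci": 100.0 * p.short_arm_um / (p.short_arm_um + p.long_arm_um),
        }
        for p in spec.pairs
    ]
    return pd.DataFrame(rows)


def match_measurements_to_truth(measurements, truth, shape) -> None:
    """Assign pair ids to measurements by best mask overlap with ground truth.

    Fills ``measurement.pair_id`` in place; used by recovery tests and the
    manifest's oracle checks, independent of the blind pairing/numbering.
    """
    gt_masks = [(t.pair_id, t.full_mask(shape)) for t in truth.chromosomes]
    for m in measurements:
        best, best_iou = None, 0.0
        for pid, g in gt_masks:
            inter = np.logical_and(m.mask, g).sum()
            if inter == 0:
                continue
            union = np.logical_or(m.mask, g).sum()
            iou = inter / union
            if iou > best_iou:
                best, best_iou = pid, iou
        m.pair_id = best


def measurements_to_iod_records(per_metaphase_measurements):
    """Build the aggregation input from per-metaphase measurement lists.

    Each measurement must carry a ``pair_id``; homologs are grouped per
    metaphase and pair, then aggregated by ``sizing.aggregate_pair_iod``.
    """
    records = []
    for measurements in per_metaphase_measurements:
        meta: dict[int, list] = {}
        for m in measurements:
            if m.pair_id is None:
                continue
            meta.setdefault(m.pair_id, []).append(
                {
                    "total": m.iod,
                    "arms": {arm: s.iod for arm, s in m.arm_stats.items()},
                }
            )
        records.append(meta)
    return records


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full simulated-slide pipeline; returns the manifest dict.

    Writes images (TIFF), histograms (CSV), the calibration report, the
    allocation table, the karyogram table, the ideogram (SVG), comparison
    reports and a JSON manifest into ``config.outdir``.  Raises
    ``StageError`` naming the failing stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "files": [], "stages": {}}

    def _record(path: Path):
        manifest["files"].append(str(path))

    # -- simulate ----------------------------------------------------------
    try:
        spec = synthetic.default_maize_spec(config.seed)
        spec_path = out / "karyotype_spec.json"
        spec.to_json(spec_path)
        _record(spec_path)
        targets = synthetic.render_calibration_targets(
            config.image_params(config.seed)
        )
        plates = []
        for i in range(config.n_metaphases):
            params = config.image_params(config.seed + 1000 + i)
            image, truth = synthetic.render_metaphase(spec, params)
            plates.append((image, truth))
            if config.write_images:
                p = out / f"metaphase_{i:02d}.tiff"
                image.to_tiff(p)
                _record(p)
                g = out / f"metaphase_{i:02d}_truth.json"
                truth.to_json(g)
                _record(g)
        hists = []
        for rrep in range(config.fcm_replicates):
            h = synthetic.simulate_fcm_histogram(
                standard_2C=config.standard_2C_pg,
                sample_2C=spec.nuclear_2C_pg,
                cv_standard=config.cv_standard_pct,
                cv_sample=config.cv_sample_pct,
                n_nuclei=config.fcm_nuclei,
                seed=config.seed + 2000 + rrep,
            )
            hp = out / f"fcm_replicate_{rrep}.csv"
            h.to_csv(hp)
            _record(hp)
            hists.append(h)
        manifest["stages"]["simulate"] = {
            "n_metaphases": config.n_metaphases,
            "nuclear_2C_true_pg": spec.nuclear_2C_pg,
        }
    except IcmError as e:
        raise StageError("simulate", str(e)) from e

    # -- calibrate ---------------------------------------------------------
    try:
        odmap_cal = densitometry.to_od(
            targets.stepped_image,
            densitometry.estimate_background(targets.blank_image),
            config.pixel_size_um,
        )
        r2 = densitometry.linearity_test(
            targets.step_ods, targets.band_masks, odmap_cal
        )
        cv = densitometry.uniformity_test(targets.blank_image)
        trace = synthetic.simulate_stability_trace(seed=config.seed)
        stabilized, t_stable = densitometry.stability_test(trace)
        report = densitometry.CalibrationReport(
            linearity_r2=r2,
            uniformity_cv_pct=cv,
            stability_trace=trace,
            stabilized=stabilized,
            stabilization_time_min=t_stable,
            um_per_px=config.pixel_size_um,
            background=float(densitometry.estimate_background(targets.blank_image)),
        )
        cal_path = out / "calibration_report.json"
        report.to_json(cal_path)
        _record(cal_path)
        manifest["stages"]["calibrate"] = {
            "linearity_r2": r2,
            "uniformity_cv_pct": cv,
            "stabilized": stabilized,
            "stabilization_time_min": t_stable,
        }
    except IcmError as e:
        raise StageError("calibrate", str(e)) from e

    # -- fcm ---------------------------------------------------------------
    try:
        replicate_2C = []
        for h in hists:
            est, _peaks = fcm.estimate_2C_from_histogram(h, config.standard_2C_pg)
            replicate_2C.append(est)
        nuclear = fcm.mean_over_replicates(replicate_2C)
        manifest["stages"]["fcm"] = {
            "replicate_2C_pg": replicate_2C,
            "mean_2C_pg": nuclear.mean_2C,
            "sd_pg": nuclear.sd,
        }
    except IcmError as e:
        raise StageError("fcm", str(e)) from e

    # -- measure -----------------------------------------------------------
    try:
        per_meta_measurements = []
        counts = []
        for i, (image, truth) in enumerate(plates):
            i0 = densitometry.estimate_background(image.pixels)
            odmap = densitometry.to_od(image.pixels, i0, image.pixel_size_um)
            masks = morphometry.segment_chromosomes(
                odmap, min_area_px=config.min_area_px, expected_count=20
            )
            counts.append(len(masks))
            ms = [
                morphometry.measure_chromosome(odmap, m, source_id=f"metaphase_{i:02d}")
                for m in masks
            ]
            per_meta_measurements.append(ms)
        manifest["stages"]["measure"] = {"object_counts": counts}
    except IcmError as e:
        raise StageError("measure", str(e)) from e

    # -- karyotype ---------------------------------------------------------
    try:
        ref_table = maize_reference_table(spec)
        numbered_metaphases = []
        inversions_seen = set()
        for ms in per_meta_measurements:
            pairing = karyotyping.pair_homologs(ms)
            numbering = karyotyping.assign_numbers(
                ms,
                pairing.pairs,
                mode=config.numbering_mode,
                reference=ref_table if config.numbering_mode == "reference_map" else None,
            )
            inversions_seen |= set(numbering.inversions)
            numbered = {}
            for pair_idx, (i, j) in enumerate(pairing.pairs):
                num = numbering.numbers[pair_idx]
                numbered[num] = (ms[i], ms[j])
                ms[i].pair_id = num
                ms[j].pair_id = num
            numbered_metaphases.append(numbered)
        karyogram = karyotyping.build_karyogram(numbered_metaphases)
        kar_path = out / "karyogram.csv"
        karyogram.table.to_csv(kar_path, index=False)
        _record(kar_path)
        svg = karyotyping.build_ideogram(karyogram)
        svg_path = out / "ideogram.svg"
        svg_path.write_text(svg)
        _record(svg_path)
        manifest["stages"]["karyotype"] = {
            "class_counts": karyogram.class_counts(),
            "numbering_inversions": sorted(inversions_seen),
        }
    except IcmError as e:
        raise StageError("karyotype", str(e)) from e

    # -- allocate ----------------------------------------------------------
    try:
        records = measurements_to_iod_records(per_meta_measurements)
        pair_records = sizing.aggregate_pair_iod(records)
        alloc = sizing.allocate_arm_2C(nuclear, pair_records)
        table = alloc.to_table()
        tab_path = out / "dna_allocation.csv"
        table.to_csv(tab_path, index=False)
        _record(tab_path)
        conservation = abs(
            sum(e.pg for e in alloc.pairs.values()) - nuclear.mean_2C
        )
        manifest["stages"]["allocate"] = {
            "pair_2C_pg": {pid: e.pg for pid, e in sorted(alloc.pairs.items())},
            "conservation_abs_error_pg": conservation,
            "conservation_ok": bool(conservation < 1e-9),
        }
    except IcmError as e:
        raise StageError("allocate", str(e)) from e

    # -- compare -----------------------------------------------------------
    try:
        query = karyotyping.allocation_comparison_values(alloc)
        comparisons = {}
        for name, ref_vals in (
            ("flow_karyotyping", reference.FLOW_KARYOTYPE_1C_BP),
            ("sequencing", reference.SEQUENCING_1C_BP),
            ("bmsc_icm", reference.BMSC_ICM_1C_BP),
        ):
            rep = karyotyping.compare_to_reference(
                query, ref_vals, query_name="icm_1C_bp", ref_name=name
            )
            p = out / f"comparison_{name}.csv"
            rep.to_csv(p, index=False)
            _record(p)
            comparisons[name] = {
                int(row.chromosome): row.pct_query_vs_ref for row in rep.itertuples()
            }
        manifest["stages"]["compare"] = comparisons
    except IcmError as e:
        raise StageError("compare", str(e)) from e

    man_path = out / "manifest.json"
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest


# ---------------------------------------------------------------------------
# Reproduction of the published summary numbers from printed inputs
# ---------------------------------------------------------------------------

def reproduce_published_numbers(include_synthetic_calibration: bool = True) -> pd.DataFrame:
    """Recompute the published summary values from their printed inputs.

    Each row names a check, the recomputed value, the published value and
    whether they agree at the printed precision.  The calibration rows run
    a small synthetic stepped-filter/blank-field qualification; everything
    else is closed-form from the bundled reference tables.
    """
    rows = []

    def check(name, value, expected, tol):
        rows.append(
            {
                "check": name,
                "value": value,
                "expected": expected,
                "tolerance": tol,
                "ok": bool(abs(value - expected) <= tol),
            }
        )

    est = fcm.estimate_2C_from_peaks(
        reference.STANDARD_PEAK_CHANNEL,
        reference.SAMPLE_PEAK_CHANNEL,
        reference.STANDARD_2C_PG,
    )
    check("nuclear 2C from peak ratio (pg)", round(est, 2), reference.NUCLEAR_2C_PG, 0.005)
    diff_pct = 100.0 * (reference.NUCLEAR_2C_PG - reference.STANDARD_2C_PG) / reference.STANDARD_2C_PG
    check("intraspecific difference (%)", round(diff_pct, 2), 9.52, 0.005)
    check(
        "chromosome 9 pair 2C from arm sums (pg)",
        reference.pair_total_2c_pg(9),
        0.561,
        5e-4,
    )
    check(
        "complement total 2C (pg)",
        round(reference.complement_total_2c_pg(), 2),
        reference.NUCLEAR_2C_PG,
        0.005,
    )
    iod10 = sizing.integrate_iod(np.array([[1.117]]), np.array([[True]]), 4.652).iod
    check("chromosome 10 IOD (area x OD)", round(iod10, 3), reference.MEAN_IOD[10], 5e-4)
    one_c = sizing.two_c_to_one_c
    check(
        "chr1 S arm 1C (1e9 bp)",
        round(sizing.pg_to_bp(one_c(reference.TABLE_2C_ARM_PG[1]["S"][0])) / 1e9, 3),
        reference.TABLE_1C_ARM_BP_E9[1]["S"],
        5e-4,
    )
    check(
        "chr6 satellite 1C (1e9 bp)",
        round(sizing.pg_to_bp(one_c(reference.TABLE_2C_ARM_PG[6]["SAT"][0])) / 1e9, 3),
        reference.TABLE_1C_ARM_BP_E9[6]["SAT"],
        5e-4,
    )
    chr1_1c = round(sizing.pg_to_bp(one_c(reference.pair_total_2c_pg(1))) / 1e9, 3)
    check("chr1 1C (1e9 bp)", chr1_1c, 0.393, 5e-4)
    chr10_1c = round(sizing.pg_to_bp(one_c(reference.pair_total_2c_pg(10))) / 1e9, 3)
    rep = karyotyping.compare_to_reference(
        {1: chr1_1c * 1e9}, reference.FLOW_KARYOTYPE_1C_BP
    )
    check(
        "chr1 vs flow karyotyping (%)",
        round(float(rep.pct_query_vs_ref.iloc[0]), 2),
        7.67,
        0.005,
    )
    rep = karyotyping.compare_to_reference(
        {10: chr10_1c * 1e9}, {10: reference.SEQUENCING_1C_BP[10]}
    )
    check(
        "chr10 vs sequencing (%)",
        round(float(rep.pct_query_vs_ref.iloc[0]), 2),
        26.00,
        0.005,
    )
    if include_synthetic_calibration:
        params = synthetic.ImageParams(seed=0)
        targets = synthetic.render_calibration_targets(params)
        odmap = densitometry.to_od(
            targets.stepped_image,
            densitometry.estimate_background(targets.blank_image),
            params.pixel_size_um,
        )
        r2 = densitometry.linearity_test(targets.step_ods, targets.band_masks, odmap)
        rows.append(
            {
                "check": "synthetic linearity R^2 >= 0.999",
                "value": r2,
                "expected": reference.LINEARITY_R2_MIN,
                "tolerance": 0.0,
                "ok": bool(r2 >= reference.LINEARITY_R2_MIN),
            }
        )
        cv = densitometry.uniformity_test(targets.blank_image)
        rows.append(
            {
                "check": "synthetic uniformity CV < 3.0%",
                "value": cv,
                "expected": reference.UNIFORMITY_CV_MAX_PCT,
                "tolerance": 0.0,
                "ok": bool(cv < reference.UNIFORMITY_CV_MAX_PCT),
            }
        )
        stabilized, t_stable = densitometry.stability_test(
            synthetic.simulate_stability_trace(seed=0)
        )
        rows.append(
            {
                "check": "synthetic warm-up stabilization (min)",
                "value": float(t_stable),
                "expected": reference.STABILIZATION_TIME_MIN,
                "tolerance": 0.0,
                "ok": bool(stabilized and t_stable == reference.STABILIZATION_TIME_MIN),
            }
        )
    return pd.DataFrame(rows)
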