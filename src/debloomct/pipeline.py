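"""End-to-end experiment runner: simulate -> bloom -> de-bloom -> measure -> evaluate.

One global seed drives every stochastic draw (material HU and per-volume
noise realizations) through :class:`numpy.random.SeedSequence` spawn keys,
so re-running a config with the same seed reproduces all outputs
byte-for-byte.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np

from . import io as vio
from .debloom import DebloomConfig, debloom
from .evaluate import bland_altman, compare_groups, diagnostic_performance
from .phantom import DEFAULT_SPACING, PhantomSpec, TruthRecord, make_stenosis_series
from .quantify import (
    MeasurementError,
    calcium_volume,
    measure_area_stenosis,
    measure_diameter_stenosis,
    snr,
)
from .scanner import ScannerConfig, apply_blooming, build_psf
from .volume import ImageVolume

log = logging.getLogger("debloomct")

DEFAULT_STENOSES = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0)

MEASUREMENT_COLUMNS = [
    "vessel_id",
    "kernel",
    "lumen_diameter_mm",
    "true_stenosis_pct",
    "plaque_hu",
    "contrast_hu",
    "true_calcium_volume_mm3",
    "os_diameter_pct",
    "os_area_pct",
    "os_calcium_volume_mm3",
    "os_snr",
    "os_noise_hu",
    "ds_diameter_pct",
    "ds_area_pct",
    "ds_calcium_volume_mm3",
    "ds_snr",
    "ds_noise_hu",
]


@dataclass
class RunConfig:
    """Declarative description of a full phantom experiment."""

    lumen_diameters: tuple[float, ...] = (4.0,)
    stenoses: tuple[float, ...] = DEFAULT_STENOSES
    kernels: tuple[str, ...] = ("STND", "HD_STND")
    grid_shape: tuple[int, int, int] = (256, 256, 64)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    plaque_length: float = 4.0
    wall_thickness: float = 1.0
    seed: int = 7
    draw_hu: bool = True  # draw plaque/contrast HU from material ranges
    debloom_enabled: bool = True
    write_volumes: bool = True
    thresholds: tuple[float, ...] = (50.0, 70.0)
    calcium_threshold: float = 450.0
    supersample: int = 4
    noise_sd: float | None = None  # None -> kernel default
    rim_strength: float = 0.05
    debloom_max_iter: int = 50
    debloom_tikhonov: float = 0.01
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("lumen_diameters", "stenoses", "kernels", "grid_shape", "spacing", "thresholds"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, cast in (
            ("lumen_diameters", float),
            ("stenoses", float),
            ("thresholds", float),
            ("kernels", str),
            ("grid_shape", int),
            ("spacing", float),
        ):
            if key in d:
                d[key] = tuple(cast(v) for v in d[key])
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def member_seed(base_seed: int, *key: int) -> int:
    """Deterministic child seed for one (lumen, stenosis, kernel) leg."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0])


def slice_ranges(spec: PhantomSpec, margin_mm: float = 3.0) -> tuple[tuple[int, int], tuple[int, int]]:
    """(reference, lesion) slice index ranges along the vessel axis.

    The lesion range covers the (centered) plaque extent; the reference
    range sits beyond it by ``margin_mm`` at the high-index end, clear of
    both the plaque and the volume border.
    """
    nz = spec.grid_shape[spec.vessel_axis]
    dz = spec.spacing[spec.vessel_axis]
    zc = (nz - 1) / 2.0
    half = spec.plaque_length / 2.0
    les_lo = max(int(math.floor(zc - half / dz)), 0)
    les_hi = min(int(math.ceil(zc + half / dz)) + 1, nz)
    ref_lo = int(math.ceil(zc + (half + margin_mm) / dz))
    ref_hi = max(nz - 2, ref_lo + 1)
    if ref_lo >= ref_hi or ref_hi > nz:
        raise MeasurementError(
            "grid too short along the vessel axis for a plaque-free reference"
        )
    return (ref_lo, ref_hi), (les_lo, les_hi)


def _rois(spec: PhantomSpec, ref_range: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Vessel (plaque-free lumen) and periphery (background) ROI masks."""
    shape = spec.grid_shape
    ax_v = spec.vessel_axis
    inplane = [a for a in (0, 1, 2) if a != ax_v]
    coords = []
    for a in (0, 1, 2):
        c = (np.arange(shape[a]) - (shape[a] - 1) / 2.0) * spec.spacing[a]
        coords.append(c)
    grids = np.meshgrid(*coords, indexing="ij")
    r = np.hypot(grids[inplane[0]], grids[inplane[1]])
    z_idx = np.arange(shape[ax_v])
    in_ref = (z_idx >= ref_range[0]) & (z_idx < ref_range[1])
    ref_mask = np.moveaxis(
        np.broadcast_to(in_ref, [shape[a] for a in inplane] + [shape[ax_v]]),
        2,
        ax_v,
    )
    lumen_r = spec.lumen_diameter / 2.0
    vessel = (r <= lumen_r * 0.5) & ref_mask
    periphery = (r >= lumen_r + spec.wall_thickness + 2.0) & ref_mask
    return vessel, periphery


def _fmt(value, digits: int) -> str:
    if value is None:
        return ""
    return f"{value:.{digits}f}"


def _measure_volume(
    vol: ImageVolume,
    spec: PhantomSpec,
    ref_range,
    les_range,
    calcium_threshold: float,
) -> dict:
    d = measure_diameter_stenosis(
        vol,
        axis=spec.vessel_axis,
        reference_slices=ref_range,
        lesion_slices=les_range,
        calcium_threshold=calcium_threshold,
    )
    a = measure_area_stenosis(
        vol,
        axis=spec.vessel_axis,
        reference_slices=ref_range,
        lesion_slices=les_range,
        calcium_threshold=calcium_threshold,
    )
    cv = calcium_volume(vol, calcium_threshold)
    vroi, proi = _rois(spec, ref_range)
    s = snr(vol, vroi, proi)
    return {
        "diameter_pct": d,
        "area_pct": a,
        "calcium_volume": cv,
        "snr": s.snr,
        "noise": s.noise,
    }


def run_experiment(config: RunConfig, out_dir) -> dict:
    """Run the full phantom experiment and write its report bundle.

    Writes (under ``out_dir``): NIfTI volumes (optional), ``manifest.csv``,
    ``measurements.csv``, ``report.json`` and ``run.log``.  Returns the
    in-memory report dictionary.  A failing series member is logged and
    skipped; it does not abort the run.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)

    handler = logging.FileHandler(os.path.join(out_dir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))

    rows: list[dict] = []
    manifest: list[dict] = []
    try:
        for li, lumen in enumerate(config.lumen_diameters):
            base = PhantomSpec(
                lumen_diameter=lumen,
                wall_thickness=config.wall_thickness,
                plaque_length=config.plaque_length,
                grid_shape=config.grid_shape,
                spacing=config.spacing,
            )
            hu_seed = member_seed(config.seed, li) if config.draw_hu else None
            series = make_stenosis_series(
                base, list(config.stenoses), seed=hu_seed, supersample=config.supersample
            )
            for mi, (truth, record) in enumerate(series):
                spec = record.spec
                vid = f"L{lumen:.1f}_S{spec.stenosis_pct:04.1f}"
                ref_range, les_range = slice_ranges(spec)
                if config.write_volumes:
                    tpath = os.path.join(out_dir, f"truth_{vid}.nii.gz")
                    vio.write_volume(truth, tpath)
                    manifest.append(_manifest_row(vid, "truth", "", tpath, spec, record))
                for ki, kernel in enumerate(config.kernels):
                    try:
                        rows_k = _run_leg(
                            config, truth, record, vid, kernel,
                            member_seed(config.seed, li, mi, ki),
                            ref_range, les_range, out_dir, manifest,
                        )
                        rows.append(rows_k)
                    except (MeasurementError, ValueError) as exc:
                        log.warning("skipping %s/%s: %s", vid, kernel, exc)
        report = _evaluate_rows(rows, config)
        _write_csv(os.path.join(out_dir, "measurements.csv"), rows)
        _write_manifest(os.path.join(out_dir, "manifest.csv"), manifest)
        with open(os.path.join(out_dir, "report.json"), "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        log.info("experiment complete: %d measurement rows", len(rows))
    finally:
        log.removeHandler(handler)
        handler.close()
    return report


def _run_leg(config, truth, record: TruthRecord, vid, kernel, noise_seed,
             ref_range, les_range, out_dir, manifest) -> dict:
    spec = record.spec
    overrides = {"seed": noise_seed, "rim_strength": config.rim_strength}
    if config.noise_sd is not None:
        overrides["noise_sd"] = config.noise_sd
    scfg = ScannerConfig.for_kernel(kernel, **overrides)
    bloomed = apply_blooming(truth, scfg)
    psf = build_psf(scfg, truth.spacing)

    row = {
        "vessel_id": vid,
        "kernel": kernel,
        "lumen_diameter_mm": spec.lumen_diameter,
        "true_stenosis_pct": record.true_stenosis_pct,
        "plaque_hu": spec.plaque_hu,
        "contrast_hu": spec.contrast_hu,
        "true_calcium_volume_mm3": record.true_calcium_volume,
    }
    os_m = _measure_volume(bloomed, spec, ref_range, les_range, config.calcium_threshold)
    row.update({f"os_{k}": v for k, v in _rename(os_m).items()})

    if config.write_volumes:
        bpath = os.path.join(out_dir, f"bloomed_{kernel}_{vid}.nii.gz")
        vio.write_volume(bloomed, bpath)
        manifest.append(_manifest_row(vid, "bloomed", kernel, bpath, spec, record))

    if config.debloom_enabled:
        dcfg = DebloomConfig(
            max_iter=config.debloom_max_iter,
            tikhonov=config.debloom_tikhonov,
            mask_threshold=config.calcium_threshold,
        )
        corrected, _ = debloom(bloomed, psf, dcfg)
        ds_m = _measure_volume(corrected, spec, ref_range, les_range, config.calcium_threshold)
        row.update({f"ds_{k}": v for k, v in _rename(ds_m).items()})
        if config.write_volumes:
            dpath = os.path.join(out_dir, f"debloomed_{kernel}_{vid}.nii.gz")
            vio.write_volume(corrected, dpath)
            manifest.append(_manifest_row(vid, "debloomed", kernel, dpath, spec, record))
    else:
        row.update({f"ds_{k}": None for k in ("diameter_pct", "area_pct",
                                              "calcium_volume_mm3", "snr", "noise_hu")})
    return row


def _rename(m: dict) -> dict:
    return {
        "diameter_pct": m["diameter_pct"],
        "area_pct": m["area_pct"],
        "calcium_volume_mm3": m["calcium_volume"],
        "snr": m["snr"],
        "noise_hu": m["noise"],
    }


def _manifest_row(vid, role, kernel, path, spec: PhantomSpec, record: TruthRecord) -> dict:
    return {
        "vessel_id": vid,
        "role": role,
        "kernel": kernel,
        "path": path,
        "lumen_diameter_mm": f"{spec.lumen_diameter:.3f}",
        "wall_thickness_mm": f"{spec.wall_thickness:.3f}",
        "stenosis_pct": f"{spec.stenosis_pct:.1f}",
        "plaque_length_mm": f"{spec.plaque_length:.3f}",
        "plaque_hu": f"{spec.plaque_hu:.1f}",
        "contrast_hu": f"{spec.contrast_hu:.1f}",
        "true_calcium_volume_mm3": f"{record.true_calcium_volume:.4f}",
    }


def _write_manifest(path, manifest: list[dict]) -> None:
    cols = [
        "vessel_id", "role", "kernel", "path", "lumen_diameter_mm",
        "wall_thickness_mm", "stenosis_pct", "plaque_length_mm",
        "plaque_hu", "contrast_hu", "true_calcium_volume_mm3",
    ]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        writer.writerows(manifest)


def _write_csv(path, rows: list[dict]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MEASUREMENT_COLUMNS)
        for row in rows:
            out = []
            for col in MEASUREMENT_COLUMNS:
                v = row.get(col)
                if col in ("vessel_id", "kernel"):
                    out.append(v)
                elif col.endswith("_pct") or col.endswith("_hu") or col == "lumen_diameter_mm":
                    out.append(_fmt(v, 1))
                elif col.endswith("_mm3"):
                    out.append(_fmt(v, 4))
                else:  # snr
                    out.append(_fmt(v, 2))
            writer.writerow(out)


def _group(rows, kernel):
    return [r for r in rows if r["kernel"] == kernel]


def _ba_dict(measured, reference):
    res = bland_altman(measured, reference)
    return {
        "bias": res.bias,
        "sd": res.sd,
        "loa_low": res.loa_low,
        "loa_high": res.loa_high,
        "n": res.n,
    }


def _dp_dict(measured, truth, threshold):
    dp = diagnostic_performance(measured, truth, threshold)
    out = {"tp": dp.tp, "fp": dp.fp, "tn": dp.tn, "fn": dp.fn}
    for name in ("sensitivity", "specificity", "ppv", "npv"):
        out[name] = getattr(dp, name)
        ci = getattr(dp, f"{name}_ci")
        out[f"{name}_ci"] = list(ci) if ci is not None else None
    return out


def _evaluate_rows(rows: list[dict], config: RunConfig) -> dict:
    report: dict = {"n_rows": len(rows), "seed": config.seed, "kernels": {}}
    for kernel in config.kernels:
        grp = _group(rows, kernel)
        if len(grp) < 2:
            continue
        rs = [r["true_stenosis_pct"] for r in grp]
        osd = [r["os_diameter_pct"] for r in grp]
        entry: dict = {"bland_altman": {"os_rs": _ba_dict(osd, rs)}}
        entry["diagnostic"] = {
            f"ge{int(t)}": {"os": _dp_dict(osd, rs, t)} for t in config.thresholds
        }
        has_ds = all(r.get("ds_diameter_pct") is not None for r in grp)
        if has_ds:
            dsd = [r["ds_diameter_pct"] for r in grp]
            entry["bland_altman"]["ds_rs"] = _ba_dict(dsd, rs)
            for t in config.thresholds:
                entry["diagnostic"][f"ge{int(t)}"]["ds"] = _dp_dict(dsd, rs, t)
            reductions = {
                "rcv": [
                    (r["os_calcium_volume_mm3"] - r["ds_calcium_volume_mm3"])
                    / r["os_calcium_volume_mm3"] * 100.0
                    for r in grp
                    if r["os_calcium_volume_mm3"] > 0
                ],
                "rds": [
                    (r["os_diameter_pct"] - r["ds_diameter_pct"]) / r["os_diameter_pct"] * 100.0
                    for r in grp
                    if r["os_diameter_pct"] > 0
                ],
                "ras": [
                    (r["os_area_pct"] - r["ds_area_pct"]) / r["os_area_pct"] * 100.0
                    for r in grp
                    if r["os_area_pct"] > 0
                ],
            }
            entry["plaque_change"] = {
                k: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
                    "n": len(v)}
                for k, v in reductions.items()
                if v
            }
            os_noise = [r["os_noise_hu"] for r in grp]
            ds_noise = [r["ds_noise_hu"] for r in grp]
            os_snr = [r["os_snr"] for r in grp if r["os_snr"] is not None]
            ds_snr = [r["ds_snr"] for r in grp if r["ds_snr"] is not None]
            tstat, pval = compare_groups(os_noise, ds_noise)
            entry["image_quality"] = {
                "os_noise_mean": float(np.mean(os_noise)),
                "ds_noise_mean": float(np.mean(ds_noise)),
                "os_snr_mean": float(np.mean(os_snr)) if os_snr else None,
                "ds_snr_mean": float(np.mean(ds_snr)) if ds_snr else None,
                "noise_ttest_p": pval,
            }
        report["kernels"][kernel] = entry
    return report
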