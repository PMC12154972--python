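"""End-to-end orchestration: synthesize or ingest a cohort, measure,
summarize, compare, and persist a reproducible report.

Synthetic mode generates the full experiment (2 conditions x 2
timepoints x 2 layers x 2 replicates) from one master seed, measures
the six morphometric variables at the study's sample sizes, and runs
the comparison plan. Real mode replays the identical measurement path
on user-supplied images and annotation sidecars listed in a manifest.
All outputs are deterministic functions of (config, master seed): no
timestamps, stable orderings, canonical JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ecm import amorphous_percentage, full_roi, select_threshold
from .images import (
    CalibratedImage,
    Polyline,
    load_image,
    mask_to_rle,
    save_image,
)
from .morphometry import (
    bundle_thickness,
    d_band_period,
    linearity_index,
    measure_fibrils,
    perpendicular_transect,
    sample_profile,
    trace_centerline,
)
from .stats import (
    ComparisonResult,
    comparisons_to_frame,
    run_comparison_plan,
    summarize_groups,
)
from .synthetic import (
    CohortDesign,
    CohortItem,
    SynthGroundTruth,
    control_design,
    generate_cohort,
    paper_effect_design,
)

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = [
    "image_path",
    "kind",
    "condition",
    "timepoint",
    "layer",
    "replicate",
    "seed",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "synthetic"  # synthetic | real
    design: str = "control"  # control | paper_effect (synthetic mode)
    master_seed: int = 0
    out_dir: str = "run_out"
    persist_images: bool = False
    scale: float = 1.0  # raster scale factor for simulation studies
    threshold_method: str = "otsu"  # otsu | fixed
    threshold_value: float | None = None
    input_manifest: str | None = None  # real mode
    counts: dict = field(default_factory=dict)  # n_lm/n_bundle/n_fibril/n_dband

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        return cls(**raw)

    def canonical(self) -> str:
        # out_dir is where results land, not what the experiment is
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return json.dumps(payload, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]

    def build_design(self) -> CohortDesign:
        factory = {"control": control_design, "paper_effect": paper_effect_design}
        if self.design not in factory:
            raise ValueError(f"unknown design {self.design!r}")
        d = factory[self.design]()
        for key, val in self.counts.items():
            if not hasattr(d, key):
                raise ValueError(f"unknown count field {key!r}")
            setattr(d, key, int(val))
        if self.scale != 1.0:
            d = d.scaled(self.scale)
        return d


@dataclass
class RunReport:
    """All tables of one run plus its provenance block."""

    measurements: pd.DataFrame
    summaries: pd.DataFrame
    comparisons: list[ComparisonResult]
    provenance: dict
    exclusions: list[str] = field(default_factory=list)

    def summaries_json(self) -> str:
        """Group -> {n, mean, sem} nested per variable (stable order)."""
        out: dict = {}
        for _, row in self.summaries.sort_values(
            ["variable", "condition", "timepoint", "layer"]
        ).iterrows():
            out.setdefault(row["variable"], {})[row["group"]] = {
                "n": int(row["n"]),
                "mean": float(row["mean"]),
                "sem": float(row["sem"]),
            }
        return json.dumps(
            {"provenance": self.provenance, "groups": out}, sort_keys=True, indent=1
        )


# ---------------------------------------------------------------------------
# measurement of one image
# ---------------------------------------------------------------------------

FIBRIL_STATIONS = (0.35, 0.5, 0.65)


def central_fibril_and_gap(
    image: CalibratedImage,
    centerline: Polyline,
    stations: tuple[float, ...] = FIBRIL_STATIONS,
) -> tuple[float, float | None]:
    """One diameter and one gap for the fibril nearest the bundle axis.

    The same central fibril (and its adjacent gap) is probed by a
    perpendicular transect at several centerline stations; the medians
    over stations give a single measurement each, damping edge noise the
    way the thickness estimator's multiple probes do.
    """
    diams: list[float] = []
    gaps: list[float] = []
    for st in stations:
        p0, p1 = perpendicular_transect(image, centerline, st)
        prof = sample_profile(image, p0, p1)
        try:
            seg = measure_fibrils(prof)
        except ValueError:
            continue
        mid_nm = prof.positions_nm[-1] / 2.0
        centers = [0.5 * (a + b) for a, b in seg.intervals_nm]
        i = int(np.argmin([abs(c - mid_nm) for c in centers]))
        diams.append(seg.diameters_nm[i])
        if seg.gaps_nm:
            gap_centers = [
                0.5 * (seg.intervals_nm[j][1] + seg.intervals_nm[j + 1][0])
                for j in range(len(seg.gaps_nm))
            ]
            j = int(np.argmin([abs(c - mid_nm) for c in gap_centers]))
            gaps.append(seg.gaps_nm[j])
    if not diams:
        raise ValueError("no fibril measurable on any transect station")
    return float(np.median(diams)), (float(np.median(gaps)) if gaps else None)


def measure_one(
    kind: str,
    image: CalibratedImage,
    centerline: Polyline | None,
    threshold_method: str = "otsu",
    threshold_value: float | None = None,
) -> list[dict]:
    """Measure one image; returns one record dict per measured variable.

    One measurement per bundle/fibril per image: each bundle-scale image
    yields one thickness and one linearity value; each fibril-scale
    image yields the central fibril's diameter and its adjacent gap;
    each D-band image yields one period.
    """
    if kind == "lm":
        roi = full_roi(image)
        thr = select_threshold(image, roi, threshold_method, threshold_value)
        res = amorphous_percentage(image, roi, thr)
        return [{"variable": "amorphous_pct", "value": res.amorphous_pct, "units": "%"}]
    if centerline is None:
        raise ValueError(f"{kind} measurement needs a centerline annotation")
    if kind == "bundle":
        # the annotated centerline midpoint may sit in a bright gap between
        # fibrils; seed the trace on the darkest pixel of a small window
        mid = centerline.points[len(centerline) // 2]
        r0, c0 = int(round(mid[0])), int(round(mid[1]))
        rad = 8
        rows, cols = image.shape
        win = image.intensities[
            max(r0 - rad, 0) : min(r0 + rad + 1, rows),
            max(c0 - rad, 0) : min(c0 + rad + 1, cols),
        ]
        dr, dc = np.unravel_index(np.argmin(win), win.shape)
        seed = (max(r0 - rad, 0) + int(dr), max(c0 - rad, 0) + int(dc))
        traced = trace_centerline(image, seed)
        return [
            {
                "variable": "bundle_thickness",
                "value": bundle_thickness(image, traced),
                "units": "nm",
            },
            {
                "variable": "linearity_index",
                "value": linearity_index(traced),
                "units": "ratio",
            },
        ]
    if kind == "fibril":
        diam, gap = central_fibril_and_gap(image, centerline)
        recs = [{"variable": "fibril_size", "value": diam, "units": "nm"}]
        if gap is not None:
            recs.append(
                {"variable": "interfibrillar_distance", "value": gap, "units": "nm"}
            )
        return recs
    if kind == "dband":
        est = d_band_period(image, centerline)
        return [
            {
                "variable": "d_band_length",
                "value": est.period_nm,
                "units": "nm",
                "low_confidence": est.low_confidence,
            }
        ]
    raise ValueError(f"unknown image kind {kind!r}")


def measure_cohort(
    items: list[CohortItem],
    threshold_method: str = "otsu",
    threshold_value: float | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Measurement table for a cohort; failed images are excluded and
    reported by name."""
    rows: list[dict] = []
    excluded: list[str] = []
    for it in items:
        try:
            recs = measure_one(
                it.kind, it.image, it.truth.centerline, threshold_method, threshold_value
            )
        except ValueError as exc:
            logger.warning("excluding %s: %s", it.name, exc)
            excluded.append(it.name)
            continue
        for r in recs:
            r.update(
                image=it.name,
                condition=it.condition,
                timepoint=it.timepoint,
                layer=it.layer,
                replicate=it.replicate,
                seed=it.seed,
            )
            rows.append(r)
    df = pd.DataFrame(rows)
    return df, excluded


# ---------------------------------------------------------------------------
# cohort export / ingestion
# ---------------------------------------------------------------------------

def _truth_payload(truth: SynthGroundTruth) -> dict:
    payload: dict = {}
    if truth.amorphous_mask is not None:
        payload["amorphous_mask"] = mask_to_rle(truth.amorphous_mask)
    if truth.centerline is not None:
        payload["centerline"] = truth.centerline.points.tolist()
    for key in (
        "true_linearity_index",
        "true_bundle_thickness_nm",
        "true_d_period_nm",
    ):
        val = getattr(truth, key)
        if val is not None:
            payload[key] = float(val)
    payload["true_fibril_diameters_nm"] = [float(v) for v in truth.true_fibril_diameters_nm]
    payload["true_gaps_nm"] = [float(v) for v in truth.true_gaps_nm]
    return payload


def export_cohort(items: list[CohortItem], out_dir: str | Path) -> Path:
    """Write images (16-bit TIFF), ground-truth sidecars (JSON) and the
    seed manifest (CSV); returns the manifest path."""
    out = Path(out_dir)
    imgdir = out / "images"
    imgdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for it in items:
        ipath = imgdir / f"{it.name}.tiff"
        save_image(it.image, ipath)
        (imgdir / f"{it.name}.json").write_text(
            json.dumps(_truth_payload(it.truth), sort_keys=True)
        )
        rows.append(
            {
                "image_path": str(ipath.relative_to(out)),
                "kind": it.kind,
                "condition": it.condition,
                "timepoint": it.timepoint,
                "layer": it.layer,
                "replicate": it.replicate,
                "seed": it.seed,
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def _load_sidecar_centerline(path: Path) -> Polyline | None:
    if not path.exists():
        return None
    payload = json.loads(path.read_text())
    if "centerline" not in payload:
        return None
    return Polyline(np.asarray(payload["centerline"], dtype=float))


def ingest_manifest(manifest_path: str | Path) -> tuple[list[dict], list[str]]:
    """Load images + annotations listed in a manifest CSV.

    Returns (entries, exclusions): per-file errors exclude the file and
    the run continues.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    base = manifest_path.parent
    table = pd.read_csv(manifest_path)
    if table.empty:
        raise ValueError(f"manifest {manifest_path} lists no images")
    entries: list[dict] = []
    excluded: list[str] = []
    for _, row in table.iterrows():
        ipath = base / str(row["image_path"])
        try:
            image = load_image(ipath)
        except (OSError, ValueError) as exc:
            logger.warning("excluding %s: %s", ipath, exc)
            excluded.append(str(row["image_path"]))
            continue
        centerline = _load_sidecar_centerline(ipath.with_suffix(".json"))
        entries.append(
            {
                "name": ipath.stem,
                "kind": str(row["kind"]),
                "image": image,
                "centerline": centerline,
                "condition": str(row["condition"]),
                "timepoint": int(row["timepoint"]),
                "layer": str(row["layer"]),
                "replicate": int(row["replicate"]),
                "seed": int(row["seed"]),
            }
        )
    return entries, excluded


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

def _finalize(
    config: RunConfig,
    measurements: pd.DataFrame,
    exclusions: list[str],
    write: bool = True,
) -> RunReport:
    summaries = summarize_groups(measurements)
    comparisons = run_comparison_plan(measurements)
    provenance = {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "mode": config.mode,
        "design": config.design if config.mode == "synthetic" else None,
        "version": __version__,
        "n_excluded": len(exclusions),
    }
    report = RunReport(measurements, summaries, comparisons, provenance, exclusions)
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        measurements.to_csv(out / "measurements.csv", index=False)
        summaries.to_csv(out / "group_summaries.csv", index=False)
        comparisons_to_frame(comparisons).to_csv(out / "comparisons.csv", index=False)
        (out / "summaries.json").write_text(report.summaries_json())
    return report


def run_synthetic_experiment(config: RunConfig, write: bool = True) -> RunReport:
    """Generate -> measure -> summarize -> compare, from one master seed."""
    if config.mode != "synthetic":
        raise ValueError("config.mode must be 'synthetic'")
    design = config.build_design()
    items = generate_cohort(design, config.master_seed)
    if config.persist_images:
        export_cohort(items, Path(config.out_dir))
    measurements, excluded = measure_cohort(
        items, config.threshold_method, config.threshold_value
    )
    return _finalize(config, measurements, excluded, write=write)


def run_real_experiment(config: RunConfig, write: bool = True) -> RunReport:
    """Measure a cohort of on-disk images listed in a manifest, then run
    the identical statistics path (no ground-truth validation)."""
    if config.mode != "real":
        raise ValueError("config.mode must be 'real'")
    if not config.input_manifest:
        raise ValueError("real mode requires input_manifest")
    entries, excluded = ingest_manifest(config.input_manifest)
    rows = []
    for e in entries:
        try:
            recs = measure_one(
                e["kind"],
                e["image"],
                e["centerline"],
                config.threshold_method,
                config.threshold_value,
            )
        except ValueError as exc:
            logger.warning("excluding %s: %s", e["name"], exc)
            excluded.append(e["name"])
            continue
        for r in recs:
            r.update(
                image=e["name"],
                condition=e["condition"],
                timepoint=e["timepoint"],
                layer=e["layer"],
                replicate=e["replicate"],
                seed=e["seed"],
            )
            rows.append(r)
    measurements = pd.DataFrame(rows)
    return _finalize(config, measurements, excluded, write=write)
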