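"""Pipeline orchestration: select -> segment (adapter) -> postprocess ->
measure, with tabular outputs and reproducible configuration.

The segmentation stage is an adapter boundary: measurements accept
pre-computed instance masks from any source (an external network, the
annotation tooling, or the bundled intensity-band segmenter used with
synthetic imagery). Downstream of that boundary everything is deterministic
classical machine vision.

Replacing the manual review step of extreme data points, every row carries
machine-readable validity flags and an optional robust outlier report
(median +/- 5 MAD) is provided — report-only, rows are never auto-dropped.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from skimage import measure as skmeasure

from .core import EggRecord, FeatureClass, LabeledRegion, LarvaRecord, PixelScale
from .morphometry import measure_individual
from .postprocess import PostprocessConfig, postprocess

LARVA_ENDPOINTS = [
    "standard_length_mm",
    "body_area_mm2",
    "total_volume_mm3",
    "yolk_length_mm",
    "yolk_width_mm",
    "yolk_volume_mm3",
    "structural_volume_mm3",
    "eye_length_mm",
    "eye_width_mm",
    "eye_volume_mm3",
]
EGG_ENDPOINTS = [
    "egg_major_mm",
    "egg_minor_mm",
    "egg_diameter_mm",
    "egg_radius_mm",
    "egg_volume_mm3",
    "circularity",
]


@dataclass
class RunConfig:
    """Full configuration of one pipeline run (serialized with every output)."""

    mode: str = "larva"
    scale_mm_per_px: float = 0.0036
    window: int = 50
    threshold: float = 25.0
    min_area_mm2: float = 0.2
    min_bbox_side_mm: float = 0.0
    connectivity: int = 8
    containment_slack_px: float = 0.0
    eye_solidity_threshold: float = 0.85
    seed: int = 0

    @property
    def scale(self) -> PixelScale:
        return PixelScale(self.scale_mm_per_px)

    def postprocess_config(self) -> PostprocessConfig:
        return PostprocessConfig(
            containment_slack_px=self.containment_slack_px,
            eye_solidity_threshold=self.eye_solidity_threshold,
        )

    def to_text(self) -> str:
        lines = [f"{k} = {v}" for k, v in sorted(dataclasses.asdict(self).items())]
        return "\n".join(lines) + "\n"

    def hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:12]

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        kwargs = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line or "=" not in line:
                continue
            k, v = (s.strip() for s in line.split("=", 1))
            if k not in fields:
                raise KeyError(f"unknown config key {k!r}")
            current = cls.__dataclass_fields__[k].default
            kwargs[k] = type(current)(v) if not isinstance(current, str) else v
        return cls(**kwargs)


def null_segmenter(
    image: np.ndarray,
    mode: str = "larva",
    background: float = 220.0,
    body_threshold: float = 200.0,
    eye_threshold: float = 60.0,
    yolk_band: tuple[float, float] = (120.0, 180.0),
    min_area_px: int = 50,
) -> list[LabeledRegion]:
    """Intensity-band segmenter for synthetic imagery.

    Stands in for an external instance segmenter when exercising the
    end-to-end path on rendered scenes: the body is everything darker than
    the background, eyes are near-black, the yolk a mid-contrast band.
    Useless on real imagery; the adapter exists precisely so a trained
    network can be swapped in.
    """
    img = image.astype(float)
    regions: list[LabeledRegion] = []

    def components(mask: np.ndarray, cls: FeatureClass) -> None:
        labels = skmeasure.label(mask, connectivity=2)
        for rp in skmeasure.regionprops(labels):
            if rp.area >= min_area_px:
                regions.append(LabeledRegion(cls, labels == rp.label))

    if mode == "larva":
        components(img < body_threshold, FeatureClass.BODY)
        components(img < eye_threshold, FeatureClass.EYE)
        components((img > yolk_band[0]) & (img < yolk_band[1]), FeatureClass.YOLK)
    else:
        components(img < body_threshold, FeatureClass.EGG)
    return regions


def _record_row(rec: LarvaRecord | EggRecord, frame_id, seg_id) -> dict:
    row = {"frame_id": frame_id, "segmentation_id": seg_id}
    d = dataclasses.asdict(rec)
    flags = d.pop("flags")
    facing = d.pop("facing_direction", None)
    row.update(d)
    if facing is not None:
        row["facing_drow"], row["facing_dcol"] = facing
    row["flags"] = ";".join(flags)
    return row


def measure_frame(
    regions: Sequence[LabeledRegion],
    image_shape: tuple[int, int],
    config: RunConfig,
    frame_id="frame0",
) -> tuple[list, list]:
    """Postprocess one frame's raw regions and measure every individual."""
    segs, audit = postprocess(
        regions, image_shape, mode=config.mode, config=config.postprocess_config()
    )
    records = []
    for j, seg in enumerate(segs):
        rec = measure_individual(seg, config.scale, mode=config.mode)
        records.append(_record_row(rec, frame_id, j))
    return records, audit


def run_pipeline(
    frames: Iterable[tuple[object, np.ndarray, Sequence[LabeledRegion]]],
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run postprocess + measurement over (frame_id, image, regions) triples.

    Returns ``(results, audit)`` tables. Failures are isolated per frame: a
    frame whose measurement raises is logged in the audit with reason
    ``measurement_error`` and skipped.
    """
    rows, audits = [], []
    for frame_id, image, regions in frames:
        try:
            recs, audit = measure_frame(regions, image.shape, config, frame_id)
        except Exception as exc:  # pragma: no cover - defensive isolation
            audits.append(
                {"frame_id": frame_id, "feature_class": "", "reason":
                 f"measurement_error: {exc}", "area_px": 0}
            )
            continue
        rows.extend(recs)
        for a in audit:
            audits.append(
                {"frame_id": frame_id, "feature_class": a.feature_class,
                 "reason": a.reason, "area_px": a.area_px}
            )
    results = pd.DataFrame(rows)
    audit_df = pd.DataFrame(
        audits, columns=["frame_id", "feature_class", "reason", "area_px"]
    )
    return results, audit_df


def summarize(
    table: pd.DataFrame,
    group_by: Optional[str] = None,
    endpoints: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-group mean, SD, quartiles and n for each endpoint column.

    Only rows whose relevant validity flag is set contribute; the number of
    excluded (invalid) rows is reported per endpoint. SD is absent (NaN) for
    single-observation groups.
    """
    if table.empty:
        return pd.DataFrame(
            columns=["group", "endpoint", "mean", "sd", "q25", "median", "q75",
                     "n", "n_excluded"]
        )
    if endpoints is None:
        candidates = LARVA_ENDPOINTS + EGG_ENDPOINTS
        endpoints = [c for c in candidates if c in table.columns]
    validity_for = {
        **{e: "body_valid" for e in ("standard_length_mm", "body_area_mm2",
                                     "total_volume_mm3", "structural_volume_mm3")},
        **{e: "yolk_valid" for e in ("yolk_length_mm", "yolk_width_mm",
                                     "yolk_volume_mm3")},
        **{e: "eyes_valid" for e in ("eye_length_mm", "eye_width_mm",
                                     "eye_volume_mm3")},
        **{e: "egg_valid" for e in EGG_ENDPOINTS},
    }
    groups = table.groupby(group_by) if group_by else [("all", table)]
    rows = []
    for gname, sub in groups:
        for ep in endpoints:
            vcol = validity_for.get(ep)
            valid = sub[sub[vcol]] if vcol and vcol in sub.columns else sub
            vals = valid[ep].dropna().astype(float)
            n = len(vals)
            if n == 0:
                continue
            rows.append(
                {
                    "group": gname,
                    "endpoint": ep,
                    "mean": vals.mean(),
                    "sd": vals.std(ddof=1) if n > 1 else np.nan,
                    "q25": vals.quantile(0.25),
                    "median": vals.median(),
                    "q75": vals.quantile(0.75),
                    "n": n,
                    "n_excluded": len(sub) - n,
                }
            )
    return pd.DataFrame(rows)


def outlier_report(
    table: pd.DataFrame, endpoints: Optional[Sequence[str]] = None, n_mad: float = 5.0
) -> pd.DataFrame:
    """Report-only robust outlier scan: values beyond median +/- n_mad * MAD.

    Nothing is dropped; the report supports the manual audit that replaces
    by-hand exclusion of extreme data points.
    """
    if endpoints is None:
        endpoints = [c for c in LARVA_ENDPOINTS + EGG_ENDPOINTS if c in table.columns]
    rows = []
    for ep in endpoints:
        vals = table[ep].dropna().astype(float)
        if len(vals) < 3:
            continue
        med = vals.median()
        mad = (vals - med).abs().median()
        if mad == 0:
            continue
        mask = (vals - med).abs() > n_mad * mad
        for idx in vals.index[mask]:
            rows.append({"row": idx, "endpoint": ep, "value": vals[idx],
                         "median": med, "mad": mad})
    return pd.DataFrame(rows, columns=["row", "endpoint", "value", "median", "mad"])


def write_results(table: pd.DataFrame, path) -> None:
    """Write a results CSV with fixed float formatting (byte-stable reruns)."""
    table.to_csv(path, index=False, float_format="%.6g")


def write_config_echo(config: RunConfig, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = out / "config_echo.txt"
    p.write_text(config.to_text() + f"config_hash = {config.hash()}\n")
    return p
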