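"""Batch driver: manifests, config files, and the segment-to-tables run.

A batch is described by a manifest CSV with columns
``path, genotype_id, replicate, timepoint, week`` (plus optional
``pixels_per_cm`` and ``truth_path``), or by a directory of images whose
filenames follow ``<genotype>_<replicate>_<Y#C#>_<W#>.jpg``.  Per-image
failures never abort a run: each image yields a CSV row with a status.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .composite import composite_vote, overlay_outline, validate_detection
from .imaging import read_image, write_mask
from .segmentation import METHOD_NAMES, SegmentationConfig, segment_all
from .traits import pixels_to_area

__all__ = [
    "BatchManifest",
    "parse_manifest",
    "load_config",
    "save_config",
    "run_batch",
]

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("path", "genotype_id", "replicate", "timepoint", "week")

_FILENAME_RE = re.compile(
    r"^(?P<genotype>[^_]+)_(?P<rep>\d+)_(?P<tp>Y\d+C\d+)_(?P<week>W[01])\.(jpg|jpeg|png)$",
    re.IGNORECASE,
)
_TIMEPOINT_RE = re.compile(r"^Y\d+C\d+$")


@dataclass
class BatchManifest:
    """Validated batch description plus the rows that failed validation."""

    rows: pd.DataFrame
    errors: list[str] = field(default_factory=list)
    pixels_per_cm: float = 74.36

    def __len__(self) -> int:
        return len(self.rows)


def parse_filename(name: str) -> dict | None:
    """Decode ``<genotype>_<rep>_<Y#C#>_<W#>.<ext>`` image names."""
    m = _FILENAME_RE.match(name)
    if not m:
        return None
    return {
        "genotype_id": m.group("genotype"),
        "replicate": int(m.group("rep")),
        "timepoint": m.group("tp").upper(),
        "week": m.group("week").upper(),
    }


def parse_manifest(path, default_pixels_per_cm: float = 74.36) -> BatchManifest:
    """Read a manifest CSV, or scan a directory of convention-named images.

    Malformed rows (missing file, bad week/timepoint labels, duplicate
    genotype x replicate x timepoint x week keys) are collected in the
    error report; the remaining rows proceed.  Zero valid rows is fatal.
    """
    path = Path(path)
    errors: list[str] = []
    if path.is_dir():
        records = []
        for img in sorted(path.iterdir()):
            if img.suffix.lower() not in (".jpg", ".jpeg", ".png"):
                continue
            meta = parse_filename(img.name)
            if meta is None:
                errors.append(f"{img.name}: filename does not follow the naming convention")
                continue
            records.append({"path": str(img), **meta})
        df = pd.DataFrame(records, columns=["path", *MANIFEST_COLUMNS[1:]])
    else:
        df = pd.read_csv(path)
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"manifest is missing required columns: {missing}")

    if "pixels_per_cm" not in df.columns:
        df["pixels_per_cm"] = default_pixels_per_cm
    df["pixels_per_cm"] = df["pixels_per_cm"].fillna(default_pixels_per_cm)
    if "truth_path" not in df.columns:
        df["truth_path"] = None

    keep = np.ones(len(df), dtype=bool)
    seen: set[tuple] = set()
    for i, row in df.iterrows():
        if not Path(row["path"]).exists():
            errors.append(f"{row['path']}: file not found")
            keep[i] = False
            continue
        if row["week"] not in ("W0", "W1"):
            errors.append(f"{row['path']}: week must be W0 or W1, got {row['week']!r}")
            keep[i] = False
            continue
        if not _TIMEPOINT_RE.match(str(row["timepoint"])):
            errors.append(f"{row['path']}: bad timepoint label {row['timepoint']!r}")
            keep[i] = False
            continue
        key = (row["genotype_id"], int(row["replicate"]), row["timepoint"], row["week"])
        if key in seen:
            errors.append(f"{row['path']}: duplicate key {key}, keeping the first row")
            keep[i] = False
            continue
        seen.add(key)
    valid = df[keep].reset_index(drop=True)
    if valid.empty:
        raise ValueError(f"manifest {path} contains zero valid rows: {errors}")
    return BatchManifest(valid, errors, default_pixels_per_cm)


def load_config(path) -> SegmentationConfig:
    """Load a flat key-value (YAML) config file; absent keys keep defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must hold a flat key-value mapping")
    return SegmentationConfig.from_flat_dict(data)


def save_config(cfg: SegmentationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_flat_dict(), fh, sort_keys=True)


def run_batch(
    manifest: BatchManifest,
    cfg: SegmentationConfig | None = None,
    out_dir=None,
    min_votes: int = 4,
    write_masks: bool = False,
    write_overlays: bool = False,
) -> pd.DataFrame:
    """Run segmentation + composite over every manifest row.

    Returns one row per image: identity columns, ``area_px``, ``area_cm2``,
    the vote histogram, and a status (``ok`` / ``empty`` / ``implausible`` /
    ``failed``).  Unreadable images yield status ``failed`` rather than
    aborting.  With ``out_dir`` set, writes ``detections.csv`` and a config
    snapshot (``config_snapshot.yaml``) echoing the run parameters; mask and
    overlay PNGs are optional.
    """
    cfg = cfg or SegmentationConfig()
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for _, row in manifest.rows.iterrows():
        image_id = Path(row["path"]).stem
        rec = {
            "image_id": image_id,
            "genotype_id": row["genotype_id"],
            "replicate": int(row["replicate"]),
            "timepoint": row["timepoint"],
            "week": row["week"],
        }
        try:
            rgb = read_image(row["path"])
            masks = segment_all(rgb, cfg, image_id=image_id)
            det = composite_vote(masks, min_votes=min_votes)
            truth = None
            if row["truth_path"]:
                truth = read_image(row["truth_path"]).pixels[:, :, 0] > 127
            status = validate_detection(det, truth)
            hist = det.vote_histogram()
            rec.update(
                area_px=det.area_px,
                area_cm2=pixels_to_area(det.area_px, float(row["pixels_per_cm"])),
                status=status,
                valid=status == "ok",
                **{f"votes_{k}": int(hist[k]) for k in range(9)},
            )
            if out_dir is not None and write_masks:
                write_mask(out_dir / f"{image_id}_composite.png", det.composite)
            if out_dir is not None and write_overlays:
                from imageio.v3 import imwrite

                imwrite(
                    out_dir / f"{image_id}_overlay.png",
                    overlay_outline(rgb, det).pixels,
                )
        except Exception as exc:  # noqa: BLE001 - per-image isolation policy
            logger.exception("image %s failed", row["path"])
            rec.update(area_px=0, area_cm2=0.0, status="failed", valid=False)
        records.append(rec)
    detections = pd.DataFrame(records)
    if out_dir is not None:
        detections.to_csv(out_dir / "detections.csv", index=False)
        save_config(cfg, out_dir / "config_snapshot.yaml")
        summary = (
            detections.groupby(["timepoint", "week"])["valid"]
            .mean()
            .rename("ok_fraction")
            .reset_index()
        )
        summary.to_csv(out_dir / "success_by_timepoint.csv", index=False)
        if manifest.errors:
            (out_dir / "manifest_errors.txt").write_text("\n".join(manifest.errors) + "\n")
    return detections
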