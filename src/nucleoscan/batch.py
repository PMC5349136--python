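"""Batch orchestration: run one analysis over a library of images.

A run is described by a single YAML config naming the analysis (layers /
condensation / tunel), the detection parameters, module-specific parameters,
and a manifest CSV of input files. Outputs are deterministic given config and
seed: a summary CSV (one row per sample, plus mean ± SEM of the run's ratio —
the aggregation behind per-strain bar charts), per-sample detail CSVs, and for
condensation a per-nucleus scatter CSV (effective radius, intensity, branch,
state) to support recalibration. Per-sample failures are recorded as error
rows without aborting the batch.
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

from .condensation import (
    CalibrationRegions,
    CondensationParams,
    condensation_ratio,
    default_calibration,
)
from .detect import DetectionParams, detections_to_records
from .errors import ConfigError
from .imageio_roi import load_polygon_roi, read_image, read_zstack
from .layers import count_stack
from .tunel import tunel_ratio

logger = logging.getLogger(__name__)

MODULES = ("layers", "condensation", "tunel")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one batch run."""

    module: str
    manifest: str
    out_dir: str
    detection: DetectionParams = field(default_factory=DetectionParams)
    condensation: CondensationParams = field(default_factory=CondensationParams)
    calibration: CalibrationRegions | None = None
    channel: str = "auto"
    link_distance: float | None = None
    match_distance: float | None = None
    max_shift: int = 16
    roi_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module not in MODULES:
            raise ConfigError(f"module must be one of {MODULES}, got {self.module!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            detection = DetectionParams(**raw.get("detection", {}))
            cond = CondensationParams(**raw.get("condensation", {}))
            calib = (
                CalibrationRegions(regions=raw["calibration"])
                if "calibration" in raw
                else None
            )
            return cls(
                module=raw["module"],
                manifest=raw["manifest"],
                out_dir=raw.get("out_dir", "."),
                detection=detection,
                condensation=cond,
                calibration=calib,
                channel=raw.get("channel", "auto"),
                link_distance=raw.get("link_distance"),
                match_distance=raw.get("match_distance"),
                max_shift=raw.get("max_shift", 16),
                roi_path=raw.get("roi"),
                seed=raw.get("seed", 0),
            )
        except KeyError as exc:
            raise ConfigError(f"config missing required key: {exc}") from exc

    def fingerprint(self) -> str:
        """Stable hash of the configuration, stamped on every result row."""
        payload = {
            "module": self.module,
            "detection": asdict(self.detection),
            "condensation": asdict(self.condensation),
            "calibration": self.calibration.to_dict() if self.calibration else None,
            "channel": self.channel,
            "link_distance": self.link_distance,
            "match_distance": self.match_distance,
            "max_shift": self.max_shift,
            "seed": self.seed,
        }
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass(frozen=True)
class SampleResult:
    """Per-sample outcome row of a batch run."""

    sample_id: str
    module: str
    value: float  # total_nuclei | percent_condensed | percent_tunel
    n_total: int
    detail_path: str
    fingerprint: str
    error: str = ""


def _read_manifest(config: RunConfig) -> pd.DataFrame:
    path = Path(config.manifest)
    if not path.exists():
        raise ConfigError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise ConfigError(f"manifest is empty: {path}")
    if config.module == "tunel":
        needed = {"dapi_path", "gfp_path"}
        if not needed.issubset(df.columns):
            raise ConfigError(f"tunel manifest needs columns {sorted(needed)}")
    elif "path" not in df.columns:
        raise ConfigError("manifest needs a 'path' column")
    sort_col = "path" if "path" in df.columns else "dapi_path"
    return df.sort_values(sort_col, kind="stable").reset_index(drop=True)


def _run_one(config: RunConfig, row: pd.Series, out_dir: Path,
             sample_id: str) -> tuple[float, int, str]:
    """Run the configured module on one manifest row.

    Returns (headline value, n_total, detail CSV path).
    """
    roi = None
    if config.roi_path:
        # lazily sized per sample below
        pass
    if config.module == "layers":
        stack = read_zstack(row["path"], channel=config.channel)
        if config.roi_path:
            roi = load_polygon_roi(config.roi_path, stack.shape)
        res = count_stack(
            stack, config.detection, link_distance=config.link_distance, roi=roi
        )
        detail = pd.DataFrame(
            detections_to_records(list(res.kept), image=row["path"])
        )
        detail_path = out_dir / f"{sample_id}_detections.csv"
        detail.to_csv(detail_path, index=False)
        return float(res.total_nuclei), res.total_nuclei, str(detail_path)
    if config.module == "condensation":
        plane = read_image(row["path"], channel=config.channel)
        if config.roi_path:
            roi = load_polygon_roi(config.roi_path, plane.shape)
        calibration = config.calibration or default_calibration(
            (config.detection.radius_min, config.detection.radius_max)
        )
        res = condensation_ratio(
            plane,
            detection=config.detection,
            calibration=calibration,
            params=config.condensation,
            roi=roi,
            seed=config.seed,
        )
        detail = pd.DataFrame(
            [
                {
                    "image": row["path"],
                    "row": m.circle.row,
                    "col": m.circle.col,
                    "radius_px": m.circle.radius,
                    "effective_radius": m.effective_radius,
                    "intensity": m.intensity,
                    "branch": m.rule_branch,
                    "state": m.state,
                }
                for m in res.measurements
            ]
        )
        detail_path = out_dir / f"{sample_id}_scatter.csv"
        detail.to_csv(detail_path, index=False)
        return res.percent_condensed, res.n_total, str(detail_path)
    # tunel
    dapi = read_image(row["dapi_path"], channel=config.channel, channel_label="dapi")
    gfp = read_image(row["gfp_path"], channel=config.channel, channel_label="gfp")
    res = tunel_ratio(
        dapi, gfp,
        params=config.detection,
        match_distance=config.match_distance,
        max_shift=config.max_shift,
    )
    detail = pd.DataFrame(
        [
            {
                "dapi_path": row["dapi_path"],
                "gfp_path": row["gfp_path"],
                "n_dapi": res.n_dapi,
                "n_matched_gfp": res.n_matched_gfp,
                "n_rejected_gfp": res.n_rejected_gfp,
                "shift_row": res.shift[0],
                "shift_col": res.shift[1],
                "registration_ok": res.registration_ok,
            }
        ]
    )
    detail_path = out_dir / f"{sample_id}_tunel.csv"
    detail.to_csv(detail_path, index=False)
    return res.percent_tunel, res.n_dapi, str(detail_path)


def run_batch(config: RunConfig) -> list[SampleResult]:
    """Run the configured analysis over every manifest row.

    Samples are processed in sorted-path order; a failing sample yields an
    error row and the batch continues. Writes ``summary.csv`` to the output
    directory: per-sample rows followed by the mean and standard error of the
    run's headline ratio over the successful samples.
    """
    manifest = _read_manifest(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fp = config.fingerprint()
    results: list[SampleResult] = []
    for i, row in manifest.iterrows():
        sample_id = str(row.get("sample_id") or f"sample{i:03d}")
        try:
            value, n_total, detail_path = _run_one(config, row, out_dir, sample_id)
            results.append(
                SampleResult(sample_id, config.module, value, n_total, detail_path, fp)
            )
        except Exception as exc:  # noqa: BLE001 - fault isolation per sample
            logger.error("sample %s failed: %s", sample_id, exc)
            results.append(
                SampleResult(sample_id, config.module, float("nan"), 0, "", fp,
                             error=str(exc))
            )
    summary = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "module": r.module,
                "value": r.value,
                "n_total": r.n_total,
                "detail_path": r.detail_path,
                "fingerprint": r.fingerprint,
                "error": r.error,
            }
            for r in results
        ]
    )
    ok = summary[summary["error"] == ""]["value"]
    mean = float(ok.mean()) if len(ok) else float("nan")
    sem = float(ok.std(ddof=1) / np.sqrt(len(ok))) if len(ok) > 1 else float("nan")
    summary.loc[len(summary)] = {
        "sample_id": "__aggregate__",
        "module": config.module,
        "value": mean,
        "n_total": int(summary["n_total"].sum()),
        "detail_path": f"sem={sem:.6g}",
        "fingerprint": fp,
        "error": "",
    }
    summary.to_csv(out_dir / "summary.csv", index=False)
    return results
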