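"""End-to-end analysis: raw digitizations -> coordinates, orientations, report.

For each scapula the chain is: mean landmarks over all observers and
measures -> average scapula frame -> every record re-expressed in that
frame -> rotated into the thorax frame at the resting pose -> a
per-measure scapula frame whose YXZ decomposition gives the three
orientation angles.  The twelve parameter series (9 average-frame
coordinates + 3 angles) then feed the reliability machinery.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import ValidationError
from .geometry import (
    DEFAULT_AREA_EPSILON,
    DEFAULT_GIMBAL_TOL,
    ThoraxPose,
    apply_thorax_rotation,
    build_scapula_frame,
    euler_yxz_extract,
    mean_landmarks,
    thorax_rotation,
    to_average_cs,
)
from .landmark_io import (
    LANDMARK_NAMES,
    StudyDataset,
    mirror_to_right,
    read_landmark_csv,
    validate_dataset,
)
from .reliability import (
    ParameterSeries,
    reliability_table,
    table_to_frame,
)

logger = logging.getLogger(__name__)

COORD_COLUMNS = ["scapula_id", "observer_id", "measure_idx", "landmark",
                 "x_acs", "y_acs", "z_acs"]
ANGLE_COLUMNS = ["scapula_id", "observer_id", "measure_idx", "e1_deg", "e2_deg", "e3_deg"]


@dataclass(frozen=True)
class RunConfig:
    input_path: str
    output_dir: str
    thorax_pose: ThoraxPose = field(default_factory=ThoraxPose)
    side_policy: str = "none"  # "none" | "mirror_left"
    area_epsilon: float = DEFAULT_AREA_EPSILON
    gimbal_tol: float = DEFAULT_GIMBAL_TOL
    seed: int = 0
    log_level: str = "INFO"

    def digest(self) -> str:
        # analysis-relevant settings only: file locations don't change results
        payload = asdict(self)
        payload.pop("input_path")
        payload.pop("output_dir")
        payload["version"] = __version__
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def compute_coordinates_and_orientations(
    dataset: StudyDataset,
    pose: ThoraxPose = ThoraxPose(),
    side_policy: str = "none",
    area_epsilon: float = DEFAULT_AREA_EPSILON,
    gimbal_tol: float = DEFAULT_GIMBAL_TOL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average-frame landmark coordinates and thorax-frame orientation angles.

    Returns one coordinates row per (scapula, observer, measure, landmark)
    and one orientation row per (scapula, observer, measure).
    """
    if side_policy not in ("none", "mirror_left"):
        raise ValueError(f"unknown side_policy {side_policy!r}")
    r_acs_tcs = thorax_rotation(pose)
    coord_rows, angle_rows = [], []
    for sid in dataset.scapula_ids:
        records = sorted(
            dataset.records_for_scapula(sid), key=lambda r: (r.observer_id, r.measure_idx)
        )
        if side_policy == "mirror_left":
            records = [mirror_to_right(r, dataset.side_of(sid)) for r in records]
        avg_frame = build_scapula_frame(mean_landmarks(records), area_epsilon=area_epsilon)
        for rec in records:
            rec_acs = to_average_cs(rec, avg_frame)
            for lm in LANDMARK_NAMES:
                p = getattr(rec_acs.landmarks, lm)
                coord_rows.append([sid, rec.observer_id, rec.measure_idx, lm, *p])
            rec_tcs = apply_thorax_rotation(rec_acs, r_acs_tcs)
            try:
                frame = build_scapula_frame(rec_tcs.landmarks, area_epsilon=area_epsilon)
                angles = euler_yxz_extract(frame, gimbal_tol=gimbal_tol)
            except Exception as exc:
                raise type(exc)(
                    f"scapula={sid} observer={rec.observer_id} "
                    f"measure={rec.measure_idx}: {exc}"
                ) from exc
            angle_rows.append([sid, rec.observer_id, rec.measure_idx, *angles.as_array()])
    coords = pd.DataFrame(coord_rows, columns=COORD_COLUMNS)
    angles = pd.DataFrame(angle_rows, columns=ANGLE_COLUMNS)
    return coords, angles


def build_parameter_series(
    coords: pd.DataFrame, angles: pd.DataFrame
) -> list[ParameterSeries]:
    """Pivot the output tables into the 12 balanced parameter series."""
    scapulae = sorted(coords["scapula_id"].unique())
    observers = sorted(coords["observer_id"].unique())
    measures = sorted(coords["measure_idx"].unique())
    shape = (len(scapulae), len(observers), len(measures))
    s_ix = {v: i for i, v in enumerate(scapulae)}
    o_ix = {v: i for i, v in enumerate(observers)}
    m_ix = {v: i for i, v in enumerate(measures)}

    series: list[ParameterSeries] = []
    for lm in LANDMARK_NAMES:
        sub = coords[coords["landmark"] == lm]
        for axis, col in zip("XYZ", ("x_acs", "y_acs", "z_acs")):
            grid = np.full(shape, np.nan)
            for sid, oid, mix, val in zip(
                sub["scapula_id"], sub["observer_id"], sub["measure_idx"], sub[col]
            ):
                grid[s_ix[sid], o_ix[oid], m_ix[mix]] = val
            if np.isnan(grid).any():
                raise ValidationError(f"incomplete grid for {lm}_{axis}")
            series.append(ParameterSeries(f"{lm}_{axis}", "mm", grid))
    for pid, col in (("e1", "e1_deg"), ("e2", "e2_deg"), ("e3", "e3_deg")):
        grid = np.full(shape, np.nan)
        for sid, oid, mix, val in zip(
            angles["scapula_id"], angles["observer_id"], angles["measure_idx"], angles[col]
        ):
            grid[s_ix[sid], o_ix[oid], m_ix[mix]] = val
        if np.isnan(grid).any():
            raise ValidationError(f"incomplete grid for {pid}")
        series.append(ParameterSeries(pid, "deg", grid))
    return series


def _write_csv(df: pd.DataFrame, path: Path, provenance: list[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in provenance:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run the full analysis and write its four artifacts.

    Outputs (under ``config.output_dir``): ``coordinates.csv``,
    ``orientations.csv``, ``reliability.csv`` (display rounding: 1 decimal
    for mm/deg, 2 for ICC), and ``reliability.json`` with full-precision
    values and variance-component diagnostics.  Runs are reproducible
    bit-for-bit for a fixed config.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset = read_landmark_csv(config.input_path)
    report = validate_dataset(dataset, area_epsilon=config.area_epsilon)
    if not report.usable:
        raise ValidationError("dataset not usable for reliability analysis:\n" + report.summary())
    logger.info(
        "dataset: %d scapulae x %d observers x %d measures",
        dataset.n_scapulae, dataset.n_observers, dataset.n_measures,
    )
    coords, angles = compute_coordinates_and_orientations(
        dataset,
        pose=config.thorax_pose,
        side_policy=config.side_policy,
        area_epsilon=config.area_epsilon,
        gimbal_tol=config.gimbal_tol,
    )
    rows = reliability_table(build_parameter_series(coords, angles))
    provenance = [
        f"scapreli version={__version__} config_sha={config.digest()} seed={config.seed}"
    ]
    paths = {
        "coordinates": outdir / "coordinates.csv",
        "orientations": outdir / "orientations.csv",
        "reliability": outdir / "reliability.csv",
        "reliability_json": outdir / "reliability.json",
    }
    _write_csv(coords, paths["coordinates"], provenance)
    _write_csv(angles, paths["orientations"], provenance)
    _write_csv(table_to_frame(rows, rounded=True), paths["reliability"], provenance)
    payload = {
        "provenance": provenance[0],
        "rows": [
            {
                "parameter": r.parameter_id,
                "unit": r.unit,
                "mad": asdict(r.mad),
                "variance_components": {
                    "sigma2_scapula": r.components.sigma2_scapula,
                    "sigma2_observer": r.components.sigma2_observer,
                    "sigma2_measure": r.components.sigma2_measure,
                    "sigma2_residual": r.components.sigma2_residual,
                    "sigma2_total": r.components.sigma2_total,
                    "raw_pre_truncation": list(r.components.raw),
                },
                "icc_intra": None if np.isnan(r.icc_intra) else r.icc_intra,
                "icc_inter": None if np.isnan(r.icc_inter) else r.icc_inter,
                "sem_intra": r.sem_intra,
                "sem_inter": r.sem_inter,
                "icc_intra_class": r.icc_intra_class.value,
                "icc_inter_class": r.icc_inter_class.value,
            }
            for r in rows
        ],
    }
    paths["reliability_json"].write_text(json.dumps(payload, indent=2))
    return paths
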