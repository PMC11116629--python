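"""Plate metadata: longitudinal tracking of larvae across wells and timepoints.

The automated imaging platform returns each larva to its original well, so
the well coordinate is the stable identity linking timepoints.  The plate
table (CSV) carries one row per (well, timepoint, channel) with the video
path and physical calibration; rows are merged into one LarvaRecord per
(well, timepoint) holding a channel -> path map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["LarvaRecord", "load_plate", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ("well", "group", "timepoint", "channel", "path", "pixel_size_um", "frame_rate_fps")


@dataclass
class LarvaRecord:
    """One larva at one timepoint, with its per-channel video files."""

    well: str
    group: str
    timepoint: str
    videos: dict[str, Path] = field(default_factory=dict)
    pixel_size_um: float = 1.3
    frame_rate_fps: float = 96.8

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(sorted(self.videos))


def load_plate(metadata_csv: str | Path, check_paths: bool = True) -> list[LarvaRecord]:
    """Read a plate metadata CSV into validated LarvaRecords.

    Raises on missing columns, duplicate (well, timepoint, channel) keys,
    inconsistent group labels for a well, and (unless ``check_paths`` is
    False) video paths that do not exist.  Relative paths are resolved
    against the CSV's directory.
    """
    metadata_csv = Path(metadata_csv)
    df = pd.read_csv(metadata_csv)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{metadata_csv}: missing required columns {missing_cols}")

    dup = df.duplicated(subset=["well", "timepoint", "channel"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["well", "timepoint", "channel"]].drop_duplicates().itertuples(index=False)
        raise ValueError(
            "duplicate (well, timepoint, channel) keys: "
            + ", ".join(f"({k.well}, {k.timepoint}, {k.channel})" for k in keys)
        )

    group_per_well = df.groupby("well")["group"].nunique()
    bad_wells = group_per_well[group_per_well > 1].index.tolist()
    if bad_wells:
        raise ValueError(f"wells with inconsistent group labels across rows: {bad_wells}")

    base = metadata_csv.parent
    records: dict[tuple[str, str], LarvaRecord] = {}
    missing_paths: list[str] = []
    for row in df.itertuples(index=False):
        path = Path(row.path)
        if not path.is_absolute():
            path = base / path
        if check_paths and not path.exists():
            missing_paths.append(str(path))
        key = (str(row.well), str(row.timepoint))
        rec = records.get(key)
        if rec is None:
            rec = LarvaRecord(
                well=str(row.well),
                group=str(row.group),
                timepoint=str(row.timepoint),
                pixel_size_um=float(row.pixel_size_um),
                frame_rate_fps=float(row.frame_rate_fps),
            )
            records[key] = rec
        rec.videos[str(row.channel)] = path
    if missing_paths:
        raise FileNotFoundError(f"plate references missing video files: {missing_paths}")
    logger.info("loaded %d larva records from %s", len(records), metadata_csv)
    return list(records.values())
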