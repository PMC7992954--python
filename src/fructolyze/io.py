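"""File IO: TIFF frames, manifests, and annotated CSV tables.

Images travel as 16-bit grayscale TIFF, one file per frame per channel,
named ``{well}_{channel}_{hours}h.tif``; a manifest CSV (columns: path,
well, channel, hours) makes the mapping explicit and is what the readers
trust.  Every table the pipeline writes carries ``#``-prefixed header
comments recording the tool version, config hash, and seed, and is read
back with ``comment='#'``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile

from .errors import ValidationError
from .growth import ConfluencyTimeSeries
from .imaging import ImageFrame

__all__ = [
    "write_frame",
    "write_image_series",
    "read_manifest",
    "write_table",
    "read_table",
    "read_confluency_csv",
]


def _scale_to_uint16(pixels: np.ndarray) -> np.ndarray:
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi <= lo:
        return np.zeros(pixels.shape, dtype=np.uint16)
    return ((pixels - lo) / (hi - lo) * 65535.0).round().astype(np.uint16)


def write_frame(frame: ImageFrame, directory: Path, raw: bool = True) -> Path:
    """Write one frame as 16-bit TIFF named {well}_{channel}_{hours}h.tif.

    With ``raw`` (default) intensities are rounded and clipped into the
    uint16 range so synthetic values survive a round trip; otherwise the
    frame is min-max rescaled to the full range.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    hours = f"{frame.time_h:g}"
    path = directory / f"{frame.well or 'well'}_{frame.channel}_{hours}h.tif"
    if raw:
        data = np.clip(np.round(frame.pixels), 0, 65535).astype(np.uint16)
    else:
        data = _scale_to_uint16(frame.pixels)
    tifffile.imwrite(path, data)
    return path


def write_image_series(
    series: Iterable[tuple[float, ImageFrame, ImageFrame]], directory: Path
) -> pd.DataFrame:
    """Write a (time, phase, red) series plus its manifest CSV."""
    directory = Path(directory)
    rows = []
    for t, phase, red in series:
        for frame in (phase, red):
            path = write_frame(frame, directory)
            rows.append(
                {"path": path.name, "well": frame.well, "channel": frame.channel,
                 "hours": t}
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


def read_manifest(manifest_path: Path) -> list[tuple[float, ImageFrame, ImageFrame]]:
    """Load a phase+red image series described by a manifest CSV."""
    manifest_path = Path(manifest_path)
    directory = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    needed = {"path", "well", "channel", "hours"}
    if not needed <= set(manifest.columns):
        raise ValidationError(f"manifest needs columns {sorted(needed)}")
    series = []
    for (well, hours), grp in manifest.groupby(["well", "hours"]):
        frames = {}
        for _, row in grp.iterrows():
            pixels = tifffile.imread(directory / row["path"]).astype(float)
            frames[row["channel"]] = ImageFrame(
                pixels, channel=row["channel"], time_h=float(hours), well=str(well)
            )
        if "phase" not in frames:
            raise ValidationError(f"no phase frame for well {well} at {hours} h")
        series.append((float(hours), frames["phase"], frames.get("red")))
    return sorted(series, key=lambda x: x[0])


def write_table(
    df: pd.DataFrame, path: Path, version: str, config_hash: str, seed: int
) -> Path:
    """CSV with provenance header comments (version, config hash, seed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# fructolyze {version}\n")
        fh.write(f"# config_hash={config_hash}\n")
        fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_confluency_csv(path: Path) -> list[ConfluencyTimeSeries]:
    """Read long-format confluency CSV into per-well series.

    Expected columns: well, cell_line, condition, concentration_mm,
    hours, confluency_pct.
    """
    df = read_table(path)
    needed = {"well", "cell_line", "condition", "concentration_mm", "hours",
              "confluency_pct"}
    if not needed <= set(df.columns):
        raise ValidationError(f"confluency CSV needs columns {sorted(needed)}")
    out = []
    keys = ["well", "cell_line", "condition", "concentration_mm"]
    for (well, line, cond, conc), grp in df.groupby(keys):
        grp = grp.sort_values("hours")
        out.append(
            ConfluencyTimeSeries(
                times_h=grp["hours"].to_numpy(dtype=float),
                confluency_pct=grp["confluency_pct"].to_numpy(dtype=float),
                well=str(well),
                cell_line=str(line),
                condition=str(cond),
                concentration_mm=float(conc),
            )
        )
    return out
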