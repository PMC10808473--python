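"""Reading and writing of images, tables and truth files.

Images are TIFF with a YAML sidecar carrying the µm-per-pixel scale (the
sidecar is ``<image>.yaml``); tables are plain CSV/TSV with documented
headers; planted-truth records are YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .density import TissueImage

__all__ = [
    "write_tissue_image",
    "read_tissue_image",
    "write_truth",
    "read_truth",
    "read_fish_csv",
    "read_segments_csv",
    "read_survival_csv",
]


def write_tissue_image(image: TissueImage, path: str | Path) -> Path:
    """Write the image channels as a TIFF plus a YAML scale sidecar."""
    path = Path(path)
    stack = image.image[None] if image.ki67 is None else np.stack([image.image, image.ki67])
    tifffile.imwrite(path, stack.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".yaml")
    sidecar.write_text(
        yaml.safe_dump(
            {"scale_um_per_px": float(image.scale_um_per_px), "channels": stack.shape[0]}
        )
    )
    return path


def read_tissue_image(path: str | Path) -> TissueImage:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing scale sidecar {sidecar}")
    meta = yaml.safe_load(sidecar.read_text())
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    ki67 = stack[1].astype(float) if stack.shape[0] > 1 else None
    return TissueImage(
        image=stack[0].astype(float), scale_um_per_px=float(meta["scale_um_per_px"]), ki67=ki67
    )


def write_truth(truth: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(truth, sort_keys=True))
    return path


def read_truth(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def _require(df: pd.DataFrame, cols: set[str], path) -> pd.DataFrame:
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_fish_csv(path: str | Path) -> pd.DataFrame:
    """FISH table: area_id, nucleus_id, test_count, control_count."""
    return _require(pd.read_csv(path), {"area_id", "test_count", "control_count"}, path)


def read_segments_csv(path: str | Path) -> pd.DataFrame:
    """Segment table: case_id, area_label, arm, start, end, log2_ratio
    (1-based inclusive coordinates)."""
    return _require(
        pd.read_csv(path),
        {"case_id", "area_label", "arm", "start", "end", "log2_ratio"},
        path,
    )


def read_survival_csv(path: str | Path) -> pd.DataFrame:
    """Cohort table: case_id, time_months, event, covariate."""
    return _require(pd.read_csv(path), {"case_id", "time_months", "event", "covariate"}, path)
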