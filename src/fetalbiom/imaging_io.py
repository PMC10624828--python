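"""Reading cine-loops and masks; report (de)serialization.

All physical lengths inside the package are centimetres.  DICOM
PixelSpacing (0028,0030) is stated in millimetres, row spacing first;
it is converted to cm exactly once, here, at ingest.

Supported cine-loop containers:

* multi-frame DICOM (uncompressed / JPEG-baseline transfer syntaxes,
  whatever ``pydicom`` can decode in this environment),
* a directory of ordered image frames plus a flat key--value sidecar
  (``loop.meta``),
* video containers, delegated to :mod:`imageio` when a decoding plugin
  is present.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import (
    MaskFormatError,
    MissingSpacingError,
    SerializationError,
    UnreadableFrameError,
)

LOOP_KINDS = ("cephalic", "abdominal", "femoral", "amniotic")
ANATOMY_LABELS = ("brain", "abdomen", "femur", "af_pocket")

SIDECAR_NAME = "loop.meta"

# ITU-R BT.601 luma weights, used to collapse color frames to intensity.
_LUMA = np.array([0.299, 0.587, 0.114])


def _to_gray(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        gray = arr[..., :3].astype(np.float64) @ _LUMA
        return np.clip(np.rint(gray), 0, np.iinfo(np.uint8).max).astype(np.uint8)
    raise UnreadableFrameError(f"cannot interpret array of shape {arr.shape} as a frame")


@dataclass(frozen=True)
class Frame:
    """One grayscale ultrasound frame with its physical pixel size."""

    index: int
    pixels: np.ndarray
    row_spacing_cm: float
    col_spacing_cm: float

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("frame index must be >= 0")
        if self.pixels.ndim != 2:
            raise ValueError("frame pixels must be a 2-D grid")
        rows, cols = self.pixels.shape
        if rows < 16 or cols < 16:
            raise ValueError(f"frame must be at least 16x16, got {rows}x{cols}")
        for s in (self.row_spacing_cm, self.col_spacing_cm):
            if not (0.0 < s < 1.0):
                raise ValueError(f"pixel spacing must be in (0, 1) cm, got {s}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class CineLoop:
    """An ordered sweep of frames sharing dimensions and spacing."""

    frames: tuple[Frame, ...]
    kind: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in LOOP_KINDS:
            raise ValueError(f"unknown loop kind {self.kind!r}")
        if len(self.frames) < 1:
            raise ValueError("a cine-loop needs at least one frame")
        first = self.frames[0]
        prev = -1
        for f in self.frames:
            if f.shape != first.shape:
                raise ValueError("all frames in a loop must share dimensions")
            if (f.row_spacing_cm, f.col_spacing_cm) != (
                first.row_spacing_cm,
                first.col_spacing_cm,
            ):
                raise ValueError("all frames in a loop must share pixel spacing")
            if f.index <= prev:
                raise ValueError("frame indices must be strictly increasing")
            prev = f.index

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    @property
    def row_spacing_cm(self) -> float:
        return self.frames[0].row_spacing_cm

    @property
    def col_spacing_cm(self) -> float:
        return self.frames[0].col_spacing_cm


@dataclass(frozen=True)
class LabelMask:
    """A binary occupancy grid for one anatomical structure."""

    grid: np.ndarray
    label: str

    def __post_init__(self) -> None:
        if self.label not in ANATOMY_LABELS:
            raise ValueError(f"unknown anatomy label {self.label!r}")
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        if self.grid.dtype != bool:
            object.__setattr__(self, "grid", self.grid.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def count(self) -> int:
        return int(self.grid.sum())


# ---------------------------------------------------------------------------
# cine-loop readers
# ---------------------------------------------------------------------------


def _parse_sidecar(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        meta[key.strip()] = value.strip()
    return meta


def _natural_key(name: str) -> tuple:
    return tuple(int(t) if t.isdigit() else t for t in re.split(r"(\d+)", name))


def _read_dicom_loop(path: Path, kind: str, default_spacing_cm: float | None) -> CineLoop:
    import pydicom

    ds = pydicom.dcmread(str(path))
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is not None:
        # DICOM PS3.3: row spacing then column spacing, in mm.
        row_cm, col_cm = float(spacing[0]) / 10.0, float(spacing[1]) / 10.0
    elif default_spacing_cm is not None:
        row_cm = col_cm = float(default_spacing_cm)
    else:
        raise MissingSpacingError(f"{path}: no PixelSpacing tag and no default spacing")
    try:
        arr = ds.pixel_array
    except Exception as exc:  # pragma: no cover - codec-dependent
        raise UnreadableFrameError(f"{path}: cannot decode pixel data: {exc}") from exc
    n_frames = int(getattr(ds, "NumberOfFrames", 1))
    if n_frames > 1 or arr.ndim == 3 and arr.shape[-1] not in (3, 4):
        stack = [arr[i] for i in range(arr.shape[0])] if arr.ndim >= 3 else [arr]
    else:
        stack = [arr]
    frames = tuple(
        Frame(i, _to_gray(np.asarray(fr)), row_cm, col_cm) for i, fr in enumerate(stack)
    )
    return CineLoop(frames, kind, source_id=str(path))


def _read_directory_loop(path: Path, kind: str, default_spacing_cm: float | None) -> CineLoop:
    from PIL import Image

    sidecar = path / SIDECAR_NAME
    meta = _parse_sidecar(sidecar) if sidecar.exists() else {}
    if "row_spacing_cm" in meta and "col_spacing_cm" in meta:
        row_cm = float(meta["row_spacing_cm"])
        col_cm = float(meta["col_spacing_cm"])
    elif default_spacing_cm is not None:
        row_cm = col_cm = float(default_spacing_cm)
    else:
        raise MissingSpacingError(f"{path}: no sidecar spacing and no default spacing")
    glob = meta.get("frame_glob", "*.png")
    files = sorted(path.glob(glob), key=lambda p: _natural_key(p.name))
    if not files:
        raise UnreadableFrameError(f"{path}: no frames matching {glob!r}")
    frames = []
    for i, f in enumerate(files):
        try:
            arr = np.asarray(Image.open(f))
        except Exception as exc:
            raise UnreadableFrameError(f"{f}: {exc}", frame_index=i) from exc
        frames.append(Frame(i, _to_gray(arr), row_cm, col_cm))
    return CineLoop(tuple(frames), kind, source_id=str(path))


def _read_video_loop(path: Path, kind: str, default_spacing_cm: float | None) -> CineLoop:
    sidecar = path.with_suffix(path.suffix + ".meta")
    meta = _parse_sidecar(sidecar) if sidecar.exists() else {}
    if "row_spacing_cm" in meta and "col_spacing_cm" in meta:
        row_cm = float(meta["row_spacing_cm"])
        col_cm = float(meta["col_spacing_cm"])
    elif default_spacing_cm is not None:
        row_cm = col_cm = float(default_spacing_cm)
    else:
        raise MissingSpacingError(
            f"{path}: video carries no spacing; provide a '{sidecar.name}' sidecar "
            "or a config default"
        )
    import imageio.v3 as iio

    frames = []
    try:
        for i, arr in enumerate(iio.imiter(str(path))):
            frames.append(Frame(i, _to_gray(np.asarray(arr)), row_cm, col_cm))
    except Exception as exc:
        raise UnreadableFrameError(f"{path}: cannot decode video: {exc}") from exc
    if not frames:
        raise UnreadableFrameError(f"{path}: video contains no frames")
    return CineLoop(tuple(frames), kind, source_id=str(path))


_VIDEO_SUFFIXES = {".mp4", ".avi", ".mov", ".mkv", ".webm", ".mpg", ".mpeg"}


def read_cineloop(
    path: str | Path, kind: str, *, default_spacing_cm: float | None = None
) -> CineLoop:
    """Read a cine-loop from DICOM, a frame directory, or a video file.

    Parameters
    ----------
    path
        Multi-frame DICOM file, directory of image frames (with a
        ``loop.meta`` sidecar), or a video container (with a
        ``<name>.<ext>.meta`` sidecar for spacing).
    kind
        One of ``cephalic``, ``abdominal``, ``femoral``, ``amniotic``.
    default_spacing_cm
        Fallback isotropic spacing when the source carries none.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        return _read_directory_loop(path, kind, default_spacing_cm)
    if path.suffix.lower() in _VIDEO_SUFFIXES:
        return _read_video_loop(path, kind, default_spacing_cm)
    return _read_dicom_loop(path, kind, default_spacing_cm)


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


def read_mask(path: str | Path, label: str) -> LabelMask:
    """Read a mask from a single-channel image or a run-length JSON record."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rec = json.loads(path.read_text())
        return _mask_from_rle(rec, label)
    from PIL import Image

    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        if arr.shape[2] in (3, 4) and _channels_agree(arr):
            arr = arr[..., 0]
        else:
            raise MaskFormatError(
                f"{path}: multi-channel mask with disagreeing channels"
            )
    return LabelMask(arr > 0, label)


def _channels_agree(arr: np.ndarray) -> bool:
    return bool(np.all(arr[..., 0] == arr[..., 1]) and np.all(arr[..., 0] == arr[..., 2]))


def write_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a mask as an 8-bit PNG (0/255) or run-length JSON record."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(_mask_to_rle(mask), sort_keys=True))
        return
    from PIL import Image

    Image.fromarray(np.where(mask.grid, 255, 0).astype(np.uint8)).save(path)


def _mask_to_rle(mask: LabelMask) -> dict:
    flat = mask.grid.ravel(order="C")
    runs: list[list[int]] = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], flat.view(np.int8), [0]))))
    for start, stop in zip(idx[::2], idx[1::2]):
        runs.append([int(start), int(stop - start)])
    return {"shape": list(mask.shape), "label": mask.label, "runs": runs}


def _mask_from_rle(rec: dict, label: str) -> LabelMask:
    try:
        shape = tuple(rec["shape"])
        runs = rec["runs"]
    except (KeyError, TypeError) as exc:
        raise MaskFormatError(f"bad run-length record: {exc}") from exc
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    for start, length in runs:
        flat[start : start + length] = True
    return LabelMask(flat.reshape(shape), label)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def _check_no_nan(obj, path: str = "$") -> None:
    if isinstance(obj, dict):
        for k, v in obj.items():
            _check_no_nan(v, f"{path}.{k}")
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            _check_no_nan(v, f"{path}[{i}]")
    elif isinstance(obj, float) and not math.isfinite(obj):
        raise SerializationError(f"non-finite value at {path}")


def dump_report_json(report_dict: dict) -> str:
    """Serialize a report dict deterministically (sorted keys, fixed floats).

    NaN/inf are forbidden by the schema.
    """
    _check_no_nan(report_dict)
    return json.dumps(report_dict, sort_keys=True, indent=2, allow_nan=False) + "\n"


def write_report(report, path: str | Path) -> None:
    """Write a :class:`~fetalbiom.pipeline.BiometryReport` as canonical JSON."""
    Path(path).write_text(dump_report_json(report.to_dict()))


def read_report(path: str | Path):
    from .pipeline import BiometryReport

    return BiometryReport.from_dict(json.loads(Path(path).read_text()))
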