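"""Acquisition and mask containers plus readers/writers.

An acquisition is an ordered stack of grayscale frames with isotropic pixel
spacing (mm), a frame rate, and the index of the first contrast-enhanced
frame.  Supported containers: multi-frame DICOM, TIFF stacks and numbered
16-bit PNG sequences; TIFF/PNG carry their acquisition metadata in a YAML
sidecar (spacing_mm, fps, contrast_onset), since those formats have no
native tags for it.  Masks are lossless single-channel 0/255 PNGs.

Conventions used everywhere in the package: image coordinates with origin
at the top-left corner, row-major, 0-based; offsets are (row, col);
intensities are floats in [0, 1], obtained by dividing by the container's
maximum representable value.
"""

from __future__ import annotations

import dataclasses
import pathlib
import warnings

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

__all__ = [
    "FrameSequence",
    "MaskImage",
    "read_sequence",
    "write_sequence",
    "read_mask",
    "write_mask",
]


@dataclasses.dataclass
class FrameSequence:
    """An ordered grayscale 2DCA acquisition.

    frames
        float array of shape (n_frames, height, width), intensities in [0, 1].
    pixel_spacing
        isotropic pixel size in mm/pixel (> 0); required because Hausdorff
        distances are reported in millimeters.
    fps
        acquisition frame rate in frames per second.
    contrast_onset
        index of the first contrast-enhanced frame (0 < onset < n_frames);
        frames before it are non-contrast.
    """

    frames: np.ndarray
    pixel_spacing: float
    fps: float
    contrast_onset: int
    acquisition_id: str = ""

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, height, width) stack")
        n = self.frames.shape[0]
        if not (0 < self.contrast_onset < n):
            raise ValueError(
                f"contrast_onset must lie strictly inside the sequence "
                f"(got {self.contrast_onset} for {n} frames)"
            )
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive (mm/pixel)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclasses.dataclass
class MaskImage:
    """A binary pixel mask aligned to one frame of a sequence."""

    pixels: np.ndarray
    frame_index: int = 0

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 2:
            raise ValueError("mask must be 2D")
        uniq = np.unique(p)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        self.pixels = p.astype(np.uint8)

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    def __eq__(self, other) -> bool:  # masks compare by content
        return (
            isinstance(other, MaskImage)
            and self.frame_index == other.frame_index
            and np.array_equal(self.pixels, other.pixels)
        )


# ---------------------------------------------------------------------------
# Sequence I/O
# ---------------------------------------------------------------------------

_SIDECAR_KEYS = ("spacing_mm", "fps", "contrast_onset")


def _sidecar_path(path: pathlib.Path) -> pathlib.Path:
    if path.is_dir():
        return path / "metadata.yaml"
    return path.with_suffix(path.suffix + ".yaml")


def _read_sidecar(path: pathlib.Path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(
            f"metadata sidecar {sc} not found; spacing_mm/fps/contrast_onset "
            "are required (Hausdorff distances in mm are undefined without spacing)"
        )
    meta = yaml.safe_load(sc.read_text())
    missing = [k for k in _SIDECAR_KEYS if k not in meta]
    if missing:
        raise ValueError(f"sidecar {sc} missing keys: {missing}")
    return meta


def write_sequence(seq: FrameSequence, path, fmt: str = "tiff_stack") -> pathlib.Path:
    """Write an acquisition as a 16-bit TIFF stack or numbered 16-bit PNGs.

    Frames are quantized to the 65535-level grid; sequences whose
    intensities already sit on that grid round-trip bit-exactly.
    """
    path = pathlib.Path(path)
    data = np.round(np.clip(seq.frames, 0.0, 1.0) * 65535.0).astype(np.uint16)
    meta = {
        "spacing_mm": float(seq.pixel_spacing),
        "fps": float(seq.fps),
        "contrast_onset": int(seq.contrast_onset),
        "acquisition_id": seq.acquisition_id,
    }
    if fmt == "tiff_stack":
        tifffile.imwrite(path, data)
        _sidecar_path(path).write_text(yaml.safe_dump(meta))
    elif fmt == "png_sequence":
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(data):
            iio.imwrite(path / f"frame_{i:04d}.png", frame)
        _sidecar_path(path).write_text(yaml.safe_dump(meta))
    else:
        raise ValueError(f"unsupported write format: {fmt}")
    return path


def read_sequence(path, fmt: str | None = None) -> FrameSequence:
    """Read an acquisition (dicom_multiframe | tiff_stack | png_sequence).

    The format is inferred from the path when not given.  Intensities are
    rescaled to [0, 1] by the container's maximum representable value.
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        if path.is_dir():
            fmt = "png_sequence"
        elif path.suffix.lower() in (".tif", ".tiff"):
            fmt = "tiff_stack"
        elif path.suffix.lower() in (".dcm", ".dicom"):
            fmt = "dicom_multiframe"
        else:
            raise ValueError(f"cannot infer container format for {path}")

    if fmt == "dicom_multiframe":
        return _read_dicom(path)

    meta = _read_sidecar(path)
    if fmt == "tiff_stack":
        raw = tifffile.imread(path)
        if raw.ndim == 2:
            raw = raw[None]
    elif fmt == "png_sequence":
        files = sorted(path.glob("frame_*.png"))
        if not files:
            raise FileNotFoundError(f"no frame_*.png files in {path}")
        arrs = [iio.imread(f) for f in files]
        shapes = {a.shape for a in arrs}
        if len(shapes) > 1:
            raise ValueError(f"mixed frame shapes in {path}: {shapes}")
        raw = np.stack(arrs)
    else:
        raise ValueError(f"unsupported format: {fmt}")

    frames = _normalize(raw)
    return FrameSequence(
        frames=frames,
        pixel_spacing=float(meta["spacing_mm"]),
        fps=float(meta["fps"]),
        contrast_onset=int(meta["contrast_onset"]),
        acquisition_id=str(meta.get("acquisition_id", path.stem)),
    )


def _normalize(raw: np.ndarray) -> np.ndarray:
    if raw.dtype == np.uint8:
        return raw.astype(np.float32) / 255.0
    if raw.dtype == np.uint16:
        return raw.astype(np.float32) / 65535.0
    if np.issubdtype(raw.dtype, np.floating):
        return raw.astype(np.float32)
    raise ValueError(f"unsupported pixel dtype {raw.dtype}")


def _read_dicom(path: pathlib.Path) -> FrameSequence:
    import pydicom

    ds = pydicom.dcmread(path)
    raw = ds.pixel_array
    if raw.ndim == 2:
        raw = raw[None]
    if raw.ndim != 3:
        raise ValueError("expected a grayscale multi-frame DICOM")
    spacing = getattr(ds, "PixelSpacing", None) or getattr(ds, "ImagerPixelSpacing", None)
    if spacing is None:
        raise ValueError(
            "DICOM is missing PixelSpacing/ImagerPixelSpacing; spacing (mm) "
            "is required to report Hausdorff distances in mm"
        )
    if abs(float(spacing[0]) - float(spacing[1])) > 1e-6:
        warnings.warn("anisotropic pixel spacing; using the row spacing")
    fps = None
    if getattr(ds, "CineRate", None):
        fps = float(ds.CineRate)
    elif getattr(ds, "FrameTime", None):
        fps = 1000.0 / float(ds.FrameTime)
    if fps is None:
        raise ValueError("DICOM is missing CineRate/FrameTime (fps)")
    onset = ds.get((0x00F1, 0x1001))  # private tag written by this package
    if onset is None:
        sc = path.with_suffix(path.suffix + ".yaml")
        if sc.exists():
            onset = int(yaml.safe_load(sc.read_text())["contrast_onset"])
        else:
            raise ValueError("contrast_onset not found (private tag or sidecar)")
    else:
        onset = int(onset.value)
    maxval = float(2 ** int(ds.BitsStored) - 1) if getattr(ds, "BitsStored", None) else float(raw.max() or 1)
    return FrameSequence(
        frames=raw.astype(np.float32) / maxval,
        pixel_spacing=float(spacing[0]),
        fps=fps,
        contrast_onset=onset,
        acquisition_id=str(getattr(ds, "SeriesInstanceUID", path.stem)),
    )


# ---------------------------------------------------------------------------
# Mask I/O
# ---------------------------------------------------------------------------

def write_mask(mask: MaskImage, path) -> pathlib.Path:
    path = pathlib.Path(path)
    iio.imwrite(path, (mask.pixels * 255).astype(np.uint8))
    return path


def read_mask(path, frame_index: int = 0) -> MaskImage:
    raw = iio.imread(path)
    if raw.ndim != 2:
        raise ValueError(f"{path}: mask PNG must be single-channel")
    uniq = np.unique(raw)
    if not np.all(np.isin(uniq, (0, 255))):
        raise ValueError(f"{path}: mask PNG must contain only 0 and 255, got {uniq[:10]}")
    return MaskImage(pixels=(raw > 0).astype(np.uint8), frame_index=frame_index)
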