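"""Synthetic 2D coronary angiography phantom.

Generates acquisitions with a known cardiac period, contrast onset, vessel
motion and calcification (CAC) blobs, so every downstream stage — frame
synchronization, patching, training, evaluation — has a fixture whose
ground truth is exact.

The phantom emulates the acquisition geometry of clinical 2DCA runs:
~200 frames at 15 fps, 512x512 pixels, isotropic spacing of 0.20-0.39 mm,
the first half without contrast and the second half contrast-enhanced.
The vessel tree is a set of 2-4 random-walk polylines rendered with a
Gaussian cross-section; motion is a global sinusoidal translation with a
small per-branch phase offset, which reproduces the repetitive pattern of
the image-dissimilarity signal without a cardiac simulator.  CACs are
faint ellipses rigidly attached to a vessel vertex, present (and equally
faint) in both halves — calcifications are static features that do not
enhance with contrast.  Noise is additive Gaussian, clipped to [0, 1].

It does not model X-ray projection physics, breathing motion or table
panning; see docs/methods.md for what that implies for the tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion, gaussian_filter
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line
from skimage.morphology import disk

from .io import FrameSequence, MaskImage

__all__ = ["PhantomSpec", "PhantomAcquisition", "generate_acquisition", "simulate_annotators"]


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of one synthetic acquisition.

    Defaults mirror the clinical acquisition protocol the package targets
    (200 frames at 15 fps, 512 px, 0.30 mm spacing, contrast from the
    midpoint); the CAC size/contrast parameters are free choices of the
    phantom, not estimates of clinical data.
    """

    n_frames: int = 200
    period: int = 20                 # frames per cardiac cycle (0.75 Hz at 15 fps)
    frame_size: int = 512
    pixel_spacing: float = 0.30      # mm/pixel
    fps: float = 15.0
    contrast_onset: int | None = None  # default: n_frames // 2
    n_cacs: int = 3
    cac_radius_px: float = 6.0
    cac_contrast: float = 0.12       # intensity deficit of a CAC blob, in [0, 1]
    noise_sd: float = 0.01
    motion_amplitude_px: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.contrast_onset is None:
            self.contrast_onset = self.n_frames // 2
        if self.n_frames <= 0 or self.frame_size <= 0 or self.period <= 0:
            raise ValueError("n_frames, frame_size and period must be positive")
        if not self.period < self.n_frames / 2:
            raise ValueError("period must be < n_frames/2 (two cycles per contrast phase)")
        if self.contrast_onset < self.period or self.n_frames - self.contrast_onset < self.period:
            raise ValueError("both contrast phases must contain at least one full period")
        if not 0.0 <= self.cac_contrast <= 1.0:
            raise ValueError("cac_contrast must be in [0, 1]")
        if self.noise_sd < 0 or self.pixel_spacing <= 0 or self.fps <= 0:
            raise ValueError("noise_sd must be >= 0; pixel_spacing and fps > 0")
        if self.n_cacs < 0 or self.cac_radius_px <= 0:
            raise ValueError("n_cacs must be >= 0 and cac_radius_px > 0")


@dataclasses.dataclass
class PhantomAcquisition:
    """Generator output: the sequence, exact per-frame CAC masks, and the
    internal motion trace (n_frames, n_branches, 2) in (row, col) pixels,
    exposed so tests can verify periodicity and paired-frame alignment."""

    sequence: FrameSequence
    cac_masks: list[MaskImage]
    motion_trace: np.ndarray

    def __iter__(self):  # allows seq, masks = generate_acquisition(spec)
        return iter((self.sequence, self.cac_masks))


def _branch_polyline(rng: np.random.Generator, size: int) -> np.ndarray:
    """A smooth random-walk polyline spanning a good part of the frame."""
    n_pts = 40
    step = size / 45.0
    pos = np.array([rng.uniform(0.15, 0.85) * size, rng.uniform(0.1, 0.3) * size])
    theta = rng.uniform(0.25 * np.pi, 0.75 * np.pi)  # heading roughly downward
    pts = [pos.copy()]
    for _ in range(n_pts - 1):
        theta += rng.normal(0.0, 0.25)
        pos = pos + step * np.array([np.sin(theta), np.cos(theta)])
        pos = np.clip(pos, 4, size - 5)
        pts.append(pos.copy())
    return np.array(pts)


def _render_tree(polylines, shifts, size: int, sigma: float = 2.2) -> np.ndarray:
    """Rasterize shifted polylines and blur them into soft tubes in [0, 1]."""
    canvas = np.zeros((size, size), dtype=np.float32)
    for pts, d in zip(polylines, shifts):
        p = np.clip(np.round(pts + d).astype(int), 0, size - 1)
        for a, b in zip(p[:-1], p[1:]):
            rr, cc = draw_line(a[0], a[1], b[0], b[1])
            canvas[rr, cc] = 1.0
    tube = gaussian_filter(canvas, sigma)
    peak = sigma * np.sqrt(2.0 * np.pi)  # ~inverse of the blurred line's peak
    return np.clip(tube * peak, 0.0, 1.0)


def generate_acquisition(spec: PhantomSpec) -> PhantomAcquisition:
    """Generate one synthetic acquisition with exact CAC masks.

    Deterministic: the same spec (including seed) yields bit-identical
    frames, masks and motion trace.  Frames are quantized to the 16-bit
    grid so that writing and re-reading a TIFF/PNG container is lossless.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.frame_size
    n_branches = int(rng.integers(2, 5))
    polylines = [_branch_polyline(rng, size) for _ in range(n_branches)]
    phase = rng.uniform(0.0, 0.3, size=n_branches)  # small per-branch offsets

    # each CAC rides on a random vertex of a random branch
    cac_branch = rng.integers(0, n_branches, size=spec.n_cacs)
    cac_vertex = rng.integers(5, 35, size=spec.n_cacs)
    cac_axes = np.stack(
        [
            rng.uniform(0.7, 1.0, spec.n_cacs) * spec.cac_radius_px,
            rng.uniform(0.5, 0.8, spec.n_cacs) * spec.cac_radius_px,
        ],
        axis=1,
    )
    cac_rot = rng.uniform(0.0, np.pi, size=spec.n_cacs)

    # background: gentle illumination gradient, fixed per acquisition
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32) / size
    background = 0.65 + 0.08 * (xx - 0.5) + 0.05 * (yy - 0.5)

    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_frames, size, size)).astype(np.float32)

    amp = spec.motion_amplitude_px
    frames = np.empty((spec.n_frames, size, size), dtype=np.float32)
    masks: list[MaskImage] = []
    trace = np.empty((spec.n_frames, n_branches, 2), dtype=np.float64)

    for t in range(spec.n_frames):
        theta = 2.0 * np.pi * t / spec.period
        shifts = np.stack(
            [
                amp * np.sin(theta + phase),          # row displacement
                0.6 * amp * np.cos(theta + phase),    # col displacement
            ],
            axis=1,
        )
        trace[t] = shifts
        tube = _render_tree(polylines, shifts, size)
        vessel_depth = 0.45 if t >= spec.contrast_onset else 0.06
        frame = background - vessel_depth * tube

        mask = np.zeros((size, size), dtype=np.uint8)
        for i in range(spec.n_cacs):
            center = polylines[cac_branch[i]][cac_vertex[i]] + shifts[cac_branch[i]]
            rr, cc = draw_ellipse(
                center[0], center[1], cac_axes[i, 0], cac_axes[i, 1],
                shape=(size, size), rotation=cac_rot[i],
            )
            mask[rr, cc] = 1
        # CACs are faint soft-edged densities present in both halves
        if spec.n_cacs:
            frame -= spec.cac_contrast * gaussian_filter(mask.astype(np.float32), 1.5)

        frame = np.clip(frame + noise[t], 0.0, 1.0)
        frames[t] = np.round(frame * 65535.0) / 65535.0  # 16-bit grid
        masks.append(MaskImage(pixels=mask, frame_index=t))

    seq = FrameSequence(
        frames=frames,
        pixel_spacing=spec.pixel_spacing,
        fps=spec.fps,
        contrast_onset=spec.contrast_onset,
        acquisition_id=f"phantom-{spec.seed}",
    )
    return PhantomAcquisition(sequence=seq, cac_masks=masks, motion_trace=trace)


def simulate_annotators(
    true_mask: MaskImage, n: int, jitter_px: int, seed: int
) -> list[MaskImage]:
    """Simulate n human annotations of one CAC mask.

    Each annotation perturbs the true mask by a random morphological
    dilation or erosion with a disk of radius <= jitter_px, mimicking
    over-/under-segmentation at the boundary.  jitter_px = 0 reproduces
    the true mask exactly.
    """
    if n < 1:
        raise ValueError("need at least one annotator")
    if jitter_px < 0:
        raise ValueError("jitter_px must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[MaskImage] = []
    base = true_mask.pixels.astype(bool)
    for _ in range(n):
        radius = int(rng.integers(0, jitter_px + 1))
        if radius == 0 or not base.any():
            perturbed = base.copy()
        elif rng.random() < 0.5:
            perturbed = binary_dilation(base, structure=disk(radius))
        else:
            perturbed = binary_erosion(base, structure=disk(radius))
        out.append(MaskImage(pixels=perturbed.astype(np.uint8), frame_index=true_mask.frame_index))
    return out
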