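"""Synthetic capillaroscopy phantoms with known ground truth.

The clinical recordings this pipeline targets show dark, tortuous capillaries
on a brighter textured mucosa background.  Red blood cells flow through the
finer vessels intermittently, so in any single frame only part of the vessel
network is visible ("stroke-like" appearance); the hand-held probe adds rigid
inter-frame jitter (translation + small rotation); the sensor adds noise.
This module generates videos with exactly that statistical structure together
with everything a test needs to score the pipeline: the full vessel mask, the
per-frame visible masks, and the exact rigid motion applied to every frame.

It makes no attempt at physical realism (optics, rheology, RBC velocimetry);
it reproduces the structure the processing stages assume, nothing more.

All randomness flows from ``PhantomSpec.seed``; identical specs give
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage as ndi

from .core_io import DEFAULT_FRAME_RATE, FrameSequence
from .stabilization import RigidMotion

__all__ = ["PhantomSpec", "PhantomOutput", "generate_phantom", "phantom_dataset"]


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of a synthetic capillary video.

    Defaults describe a plausible oral-mucosa field of view at the working
    magnification: a handful of tortuous vessels a few pixels wide, moderate
    vessel/background contrast, per-arc flow visibility around 0.6, probe
    jitter of a few pixels and a fraction of a degree between consecutive
    frames at 120 fps, and mild sensor noise.
    """

    width: int = 640
    height: int = 480
    n_frames: int = 20
    n_vessels: int = 4
    vessel_width: tuple[float, float] = (3.0, 7.0)
    tortuosity: float = 0.25  # std of per-step heading change, radians
    background_level: float = 155.0
    vessel_contrast: float = 60.0
    flow_visibility: float = 0.6
    segment_length: float = 40.0  # centerline arc length per visibility unit, px
    jitter_translation: float = 3.0  # max |dx|, |dy| per frame, px
    jitter_rotation: float = 0.8  # max |theta| per frame, degrees
    jitter_mode: str = "independent"  # or "walk" (drifting probe)
    noise_sigma: float = 4.0
    blob_features: int = 30
    frame_rate: float = DEFAULT_FRAME_RATE
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.flow_visibility <= 1.0):
            raise ValueError("flow_visibility must be in [0, 1]")
        if min(self.width, self.height) < 8 or self.n_frames < 1:
            raise ValueError("degenerate frame geometry")
        if self.vessel_width[1] >= min(self.width, self.height):
            raise ValueError("vessel wider than the frame")
        if self.jitter_mode not in ("independent", "walk"):
            raise ValueError("jitter_mode must be 'independent' or 'walk'")


@dataclasses.dataclass
class PhantomOutput:
    """Frames plus every piece of ground truth the pipeline can be scored on."""

    frames: FrameSequence
    truth_mask: np.ndarray  # full vessel network, frame-0 coordinates
    true_motions: list[RigidMotion]  # motion frame k -> frame k+1, length N-1
    per_frame_visible_masks: list[np.ndarray]


def _vessel_centerline(
    rng: np.random.Generator, h: int, w: int, tortuosity: float
) -> np.ndarray:
    """Random smooth curve through the canvas as (n_points, 2) row/col floats."""
    # Start on a random border point heading inward, then random-walk the
    # heading; step length 1 px keeps the polyline dense enough to rasterize.
    side = rng.integers(4)
    if side == 0:  # top
        r, c, heading = 0.0, rng.uniform(0.1, 0.9) * w, np.pi / 2
    elif side == 1:  # bottom
        r, c, heading = float(h - 1), rng.uniform(0.1, 0.9) * w, -np.pi / 2
    elif side == 2:  # left
        r, c, heading = rng.uniform(0.1, 0.9) * h, 0.0, 0.0
    else:  # right
        r, c, heading = rng.uniform(0.1, 0.9) * h, float(w - 1), np.pi
    n_steps = int(1.5 * max(h, w))
    pts = np.empty((n_steps, 2))
    for i in range(n_steps):
        pts[i] = (r, c)
        heading += rng.normal(0.0, tortuosity)
        r += np.sin(heading)
        c += np.cos(heading)
        if not (0 <= r < h and 0 <= c < w):
            pts = pts[: i + 1]
            break
    return pts


def _rasterize_arcs(
    pts: np.ndarray, radius: float, shape: tuple[int, int], seg_len: float
) -> list[np.ndarray]:
    """Split a centerline into arcs of ~seg_len and rasterize each to a mask."""
    h, w = shape
    n = len(pts)
    per_arc = max(2, int(round(seg_len)))
    masks = []
    for start in range(0, n, per_arc):
        arc = pts[start : start + per_arc + 1]
        m = np.zeros(shape, dtype=bool)
        rr = np.clip(np.rint(arc[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.rint(arc[:, 1]).astype(int), 0, w - 1)
        m[rr, cc] = True
        # dilate the 1-px polyline to the vessel width
        m = ndi.binary_dilation(m, ndi.generate_binary_structure(2, 2), iterations=max(1, int(round(radius))))
        masks.append(m)
    return masks


def _pose_matrix(dx: float, dy: float, theta_deg: float, center: tuple[float, float]) -> np.ndarray:
    """3x3 homogeneous (x, y) transform: rotation about center then translation."""
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    cx, cy = center
    rot = np.array([[c, -s, cx - c * cx + s * cy], [s, c, cy - s * cx - c * cy], [0, 0, 1.0]])
    trans = np.array([[1, 0, dx], [0, 1, dy], [0, 0, 1.0]])
    return trans @ rot


def _warp_scene(scene: np.ndarray, pose: np.ndarray, out_shape: tuple[int, int],
                pad: int, order: int) -> np.ndarray:
    """Sample the padded scene so that frame coords x_f map to scene coords.

    ``pose`` maps scene(frame-0) coordinates to frame-k coordinates; we need
    the inverse mapping for resampling.
    """
    h, w = out_shape
    inv = np.linalg.inv(pose)
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    ones = np.ones_like(ii, dtype=float)
    coords = np.stack([jj.astype(float), ii.astype(float), ones])  # (3, H, W) in x,y,1
    src = np.tensordot(inv, coords.reshape(3, -1), axes=1)
    sx = src[0].reshape(h, w) + pad
    sy = src[1].reshape(h, w) + pad
    return ndi.map_coordinates(scene, [sy, sx], order=order, mode="constant", cval=0.0)


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Render a jittered capillary video with full ground truth.

    The static scene (textured background + bright stationary blobs + dark
    vessels) lives on a canvas padded beyond the frame by the maximum possible
    jitter excursion, so rigid motion never drags empty border into view.
    Frame k is the scene under pose P_k cropped to the frame; the returned
    motion log holds M_k = P_{k+1} ∘ P_k^{-1}, the transform taking frame-k
    image coordinates to frame-(k+1) image coordinates — exactly what the
    stabilization stage estimates.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    pad = int(np.ceil(3 * spec.jitter_translation + 0.02 * max(h, w) + 8))
    ch, cw = h + 2 * pad, w + 2 * pad

    # --- static scene ---------------------------------------------------
    mottle = ndi.gaussian_filter(rng.normal(0.0, 1.0, (ch, cw)), 12.0)
    sd = mottle.std()
    if sd > 0:
        mottle *= 5.0 / sd  # smooth low-frequency tissue mottle, ~5 gray levels
    background = spec.background_level + mottle
    # Bright stationary texture blobs: guaranteed keypoint anchors.  Each is
    # an anisotropic Gaussian with its own axis ratio and orientation, so
    # different blobs stay distinguishable to a local appearance descriptor
    # (perfectly round identical spots would be mutually ambiguous in a way
    # real tissue texture is not).
    for _ in range(spec.blob_features):
        br = rng.uniform(pad, pad + h)
        bc = rng.uniform(pad, pad + w)
        s1 = rng.uniform(2.0, 5.5)
        s2 = s1 * rng.uniform(0.45, 1.0)
        phi = rng.uniform(0.0, np.pi)
        amp = rng.uniform(45.0, 85.0)
        rr = np.arange(ch)[:, None] - br
        cc = np.arange(cw)[None, :] - bc
        u = rr * np.cos(phi) + cc * np.sin(phi)
        v = -rr * np.sin(phi) + cc * np.cos(phi)
        background += amp * np.exp(-(u**2 / (2 * s1**2) + v**2 / (2 * s2**2)))

    arcs: list[np.ndarray] = []
    for _ in range(spec.n_vessels):
        pts = _vessel_centerline(rng, ch, cw, spec.tortuosity)
        radius = rng.uniform(*spec.vessel_width) / 2.0
        arcs.extend(_rasterize_arcs(pts, radius, (ch, cw), spec.segment_length))
    full_vessel = np.any(arcs, axis=0) if arcs else np.zeros((ch, cw), dtype=bool)

    # --- per-frame poses -------------------------------------------------
    center = (w / 2.0, h / 2.0)
    poses = [np.eye(3)]
    state = np.zeros(3)  # dx, dy, theta for walk mode
    for _ in range(1, spec.n_frames):
        dx = rng.uniform(-spec.jitter_translation, spec.jitter_translation)
        dy = rng.uniform(-spec.jitter_translation, spec.jitter_translation)
        th = rng.uniform(-spec.jitter_rotation, spec.jitter_rotation)
        if spec.jitter_mode == "walk":
            state = state + (dx, dy, th)
            dx, dy, th = state
        poses.append(_pose_matrix(dx, dy, th, center))

    # --- per-frame visibility and rendering ------------------------------
    visibility = rng.random((spec.n_frames, len(arcs))) < spec.flow_visibility
    if spec.flow_visibility >= 1.0:
        visibility[:] = True

    frames = np.empty((spec.n_frames, h, w), dtype=np.uint8)
    visible_masks: list[np.ndarray] = []
    soft_arcs = [ndi.gaussian_filter(a.astype(float), 0.8) for a in arcs]
    for k in range(spec.n_frames):
        scene = background.copy()
        vis_mask = np.zeros((ch, cw), dtype=bool)
        for a_idx, soft in enumerate(soft_arcs):
            if visibility[k, a_idx]:
                scene -= spec.vessel_contrast * soft
                vis_mask |= arcs[a_idx]
        img = _warp_scene(scene, poses[k], (h, w), pad, order=1)
        img += rng.normal(0.0, spec.noise_sigma, (h, w))
        frames[k] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        vm = _warp_scene(vis_mask.astype(float), poses[k], (h, w), pad, order=0)
        visible_masks.append((vm > 0.5).astype(np.uint8))

    truth = _warp_scene(full_vessel.astype(float), poses[0], (h, w), pad, order=0)
    truth_mask = (truth > 0.5).astype(np.uint8)

    motions = []
    for k in range(spec.n_frames - 1):
        m = poses[k + 1] @ np.linalg.inv(poses[k])
        theta = np.rad2deg(np.arctan2(m[1, 0], m[0, 0]))
        motions.append(RigidMotion(dx=m[0, 2], dy=m[1, 2], theta_deg=theta))

    seq = FrameSequence(frames, frame_rate=spec.frame_rate)
    return PhantomOutput(
        frames=seq,
        truth_mask=truth_mask,
        true_motions=motions,
        per_frame_visible_masks=visible_masks,
    )


def phantom_dataset(
    spec: PhantomSpec, n_images: int, width: int = 620, height: int = 476
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Independent static phantom images with masks, one per synthetic patient.

    Structural stand-in for a small expert-annotated capillaroscopy image
    database: ``n_images`` single still images (full vessel visibility, no
    jitter) sized like typical study images so that tiling arithmetic on
    non-multiple-of-tile dimensions is exercised.
    """
    if n_images < 2:
        raise ValueError("need at least 2 images for leave-one-out evaluation")
    images: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    for i in range(n_images):
        sub = dataclasses.replace(
            spec,
            width=width,
            height=height,
            n_frames=1,
            flow_visibility=1.0,
            jitter_translation=0.0,
            jitter_rotation=0.0,
            seed=(spec.seed * 100003 + i) % (2**31 - 1),
        )
        out = generate_phantom(sub)
        images.append(out.frames.frame(0))
        masks.append(out.truth_mask)
    return images, masks
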