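"""Capillary segmentation: tile preparation, network training, prediction.

Expert-annotated capillaroscopy databases are small (tens of images), so the
segmentation network is fed 160×160 tiles cut from each image on a regular
grid, the images are augmented by rotation about their center, and tiles
whose mask carries almost no capillary signal (fewer than ``min_white`` white
pixels, default 200) are discarded.  Because full images are not multiples of
the tile size, the last grid row/column is anchored flush with the border:
full coverage, possibly overlapping the previous tile.

Training uses class-weighted categorical cross-entropy (capillary pixels are
a small minority; weights are inverse-frequency, w_c = total/(2·count_c)),
the Adam optimizer, and leave-one-out cross-validation over source images:
one training per image, every tile derived from the held-out image (including
its rotations) excluded from that fold's training set, and the checkpoint at
minimum validation loss used for prediction.

Prediction tiles the input with the same flush-anchor grid, averages
foreground probabilities where tiles overlap, and binarizes at 0.5
(equivalently arg-max for two classes).

A classical fallback segmenter (:func:`threshold_segment`) is also provided:
Otsu thresholding of the (dark-vessel) image plus small-object removal.  It
is deterministic and training-free, which makes it the natural readout for
preprocessing ablations where the segmenter must be held fixed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.transform import rotate as _sk_rotate

from . import nn
from .metrics import MetricsReport, confusion, report

__all__ = [
    "Tile",
    "TileDataset",
    "NetworkSpec",
    "TrainingConfig",
    "FoldResult",
    "tile_image",
    "augment_rotations",
    "filter_sparse_tiles",
    "compute_class_weights",
    "equally_spaced_angles",
    "build_tile_dataset",
    "build_network",
    "train_model",
    "train_loocv",
    "predict_mask",
    "threshold_segment",
]

TILE_SIZE = 160


@dataclasses.dataclass
class Tile:
    """One 160×160 image/mask patch with its provenance."""

    image: np.ndarray  # float in [0, 1]
    mask: np.ndarray  # {0, 1}
    source_id: str
    offset: tuple[int, int]  # (row, col) of top-left in the parent image
    rotation: float = 0.0  # augmentation angle, degrees

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("tile image values must lie in [0, 1]")

    @property
    def white_pixels(self) -> int:
        return int(self.mask.sum())


@dataclasses.dataclass
class TileDataset:
    tiles: list[Tile]
    min_white_pixels: int = 200
    rotation_angles: tuple[float, ...] = ()

    def source_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.tiles:
            seen.setdefault(t.source_id)
        return list(seen)

    def by_source(self, source_id: str) -> list[Tile]:
        return [t for t in self.tiles if t.source_id == source_id]

    def __len__(self) -> int:
        return len(self.tiles)


@dataclasses.dataclass
class NetworkSpec:
    """Architecture of the encoder–decoder segmentation network."""

    encoder_filters: tuple[int, ...] = (32, 64, 128, 256)
    input_size: int = TILE_SIZE
    n_classes: int = 2

    def validate(self) -> None:
        div = 2 ** (len(self.encoder_filters) - 1)
        if self.input_size % div:
            raise ValueError(
                f"input size {self.input_size} not divisible by {div}"
            )


@dataclasses.dataclass
class TrainingConfig:
    epochs: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 4
    seed: int = 0
    class_weights: np.ndarray | None = None  # derived from data when None


@dataclasses.dataclass
class FoldResult:
    held_out_id: str
    predicted_mask: np.ndarray
    metrics: MetricsReport
    best_epoch: int
    history: list[tuple[float, float]]  # (train_loss, val_loss) per epoch


def _grid_positions(extent: int, tile: int, stride: int) -> list[int]:
    """Stride grid with the last tile anchored flush with the border."""
    pos = list(range(0, extent - tile + 1, stride))
    if pos[-1] != extent - tile:
        pos.append(extent - tile)
    return pos


def tile_image(
    image: np.ndarray,
    mask: np.ndarray,
    tile_size: int = TILE_SIZE,
    stride: int | None = None,
    source_id: str = "image",
    rotation: float = 0.0,
) -> list[Tile]:
    """Cut an image/mask pair into tiles on a regular flush-anchored grid.

    ``image`` may be uint8 (rescaled to [0, 1]) or already float in [0, 1].
    """
    stride = stride or tile_size
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    h, w = image.shape
    if h < tile_size or w < tile_size:
        raise ValueError(f"image {h}x{w} smaller than tile size {tile_size}")
    if image.dtype == np.uint8:
        image = image / 255.0
    tiles = []
    for r in _grid_positions(h, tile_size, stride):
        for c in _grid_positions(w, tile_size, stride):
            tiles.append(
                Tile(
                    image=image[r : r + tile_size, c : c + tile_size],
                    mask=(mask[r : r + tile_size, c : c + tile_size] > 0).astype(np.uint8),
                    source_id=source_id,
                    offset=(r, c),
                    rotation=rotation,
                )
            )
    return tiles


def augment_rotations(
    image: np.ndarray, mask: np.ndarray, angles: Sequence[float]
) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """Original pair plus one rotated copy per angle (degrees, in (0, 360)).

    Rotation is about the image center; the image is interpolated bilinearly,
    the mask nearest-neighbour and re-binarized; corners uncovered by the
    rotation are filled with background.
    """
    out = [(np.asarray(image), (np.asarray(mask) > 0).astype(np.uint8), 0.0)]
    for a in angles:
        if not (0.0 < a < 360.0):
            raise ValueError(f"angle {a} outside (0, 360)")
        img_f = np.asarray(image, dtype=float)
        scale = 255.0 if image.dtype == np.uint8 else 1.0
        rot_img = _sk_rotate(img_f / scale, a, preserve_range=True, order=1, cval=0.0)
        rot_img = np.clip(rot_img * scale, 0, scale)
        if image.dtype == np.uint8:
            rot_img = np.rint(rot_img).astype(np.uint8)
        rot_mask = _sk_rotate(mask.astype(float), a, preserve_range=True, order=0, cval=0.0)
        out.append((rot_img, (rot_mask > 0.5).astype(np.uint8), float(a)))
    return out


def filter_sparse_tiles(tiles: Sequence[Tile], min_white: int = 200) -> list[Tile]:
    """Retain tiles whose mask has at least ``min_white`` white pixels."""
    return [t for t in tiles if t.white_pixels >= min_white]


def compute_class_weights(dataset: TileDataset) -> np.ndarray:
    """Inverse-frequency class weights (background, capillary).

    w_c = total_pixels / (2 · count_c): the minority class (capillary) gets
    the larger weight, and a balanced dataset gets (1, 1).
    """
    if not dataset.tiles:
        raise ValueError("empty dataset")
    white = sum(t.white_pixels for t in dataset.tiles)
    total = sum(t.mask.size for t in dataset.tiles)
    black = total - white
    if white == 0 or black == 0:
        raise ValueError("degenerate dataset: a class has zero pixels")
    return np.array([total / (2.0 * black), total / (2.0 * white)])


def equally_spaced_angles(k: int) -> tuple[float, ...]:
    """k rotation angles equally spaced in the open interval (0°, 360°)."""
    return tuple(360.0 * (i + 1) / (k + 1) for i in range(k))


def build_tile_dataset(
    images: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    angles: Sequence[float] = (),
    tile_size: int = TILE_SIZE,
    stride: int | None = None,
    min_white: int = 200,
    source_ids: Sequence[str] | None = None,
) -> TileDataset:
    """Full data-preparation pipeline: rotate, tile, filter sparse tiles."""
    if len(images) != len(masks):
        raise ValueError("images and masks counts differ")
    ids = source_ids or [f"img{i:03d}" for i in range(len(images))]
    tiles: list[Tile] = []
    for img, msk, sid in zip(images, masks, ids):
        for rot_img, rot_mask, angle in augment_rotations(img, msk, angles):
            tiles.extend(
                tile_image(rot_img, rot_mask, tile_size, stride, source_id=sid,
                           rotation=angle)
            )
    tiles = filter_sparse_tiles(tiles, min_white)
    return TileDataset(tiles=tiles, min_white_pixels=min_white,
                       rotation_angles=tuple(angles))


def build_network(spec: NetworkSpec, seed: int = 0) -> nn.UNet:
    """Instantiate the encoder–decoder network for 160×160 [0,1] inputs."""
    spec.validate()
    return nn.UNet(filters=spec.encoder_filters, n_classes=spec.n_classes, seed=seed)


def _tiles_to_arrays(tiles: Sequence[Tile]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([t.image for t in tiles])[..., None].astype(np.float64)
    y = np.stack([t.mask for t in tiles]).astype(np.int64)
    return x, y


def train_model(
    model: nn.UNet,
    train_tiles: Sequence[Tile],
    val_tiles: Sequence[Tile],
    cfg: TrainingConfig,
) -> tuple[int, list[tuple[float, float]]]:
    """Train with Adam + weighted cross-entropy; restore the best checkpoint.

    Returns (best_epoch, history); ``model`` ends up holding the parameters
    of the epoch with minimum validation loss.
    """
    if not train_tiles or not val_tiles:
        raise ValueError("fold with empty training or validation tile set")
    weights = cfg.class_weights
    if weights is None:
        weights = compute_class_weights(TileDataset(list(train_tiles)))
    x_tr, y_tr = _tiles_to_arrays(train_tiles)
    x_va, y_va = _tiles_to_arrays(val_tiles)
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    best_state = model.get_state()
    best_val = np.inf
    best_epoch = 0
    history: list[tuple[float, float]] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x_tr))
        train_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.forward(x_tr[idx])
            loss, dlogits = nn.weighted_softmax_cross_entropy(logits, y_tr[idx], weights)
            model.backward(dlogits)
            opt.step()
            train_losses.append(loss)
        val_losses = []
        for start in range(0, len(x_va), cfg.batch_size):
            logits = model.forward(x_va[start : start + cfg.batch_size])
            loss, _ = nn.weighted_softmax_cross_entropy(
                logits, y_va[start : start + cfg.batch_size], weights
            )
            val_losses.append(loss)
        val_loss = float(np.mean(val_losses))
        history.append((float(np.mean(train_losses)), val_loss))
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_state = model.get_state()
    model.set_state(best_state)
    return best_epoch, history


def predict_mask(
    model: nn.UNet,
    image: np.ndarray,
    tile_size: int = TILE_SIZE,
    stride: int | None = None,
) -> np.ndarray:
    """Predict a full-size binary capillary mask.

    The image is tiled with the flush-anchor grid; per-pixel foreground
    probabilities of overlapping tiles are averaged before binarizing at 0.5.
    """
    image = np.asarray(image)
    if image.dtype == np.uint8:
        image = image / 255.0
    stride = stride or tile_size
    h, w = image.shape
    prob = np.zeros((h, w))
    weight = np.zeros((h, w))
    for r in _grid_positions(h, tile_size, stride):
        for c in _grid_positions(w, tile_size, stride):
            patch = image[r : r + tile_size, c : c + tile_size]
            p = model.predict_proba(patch[None, ..., None])[0, ..., 1]
            prob[r : r + tile_size, c : c + tile_size] += p
            weight[r : r + tile_size, c : c + tile_size] += 1.0
    return (prob / weight > 0.5).astype(np.uint8)


def train_loocv(
    images: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    dataset: TileDataset,
    net_spec: NetworkSpec,
    cfg: TrainingConfig,
    source_ids: Sequence[str] | None = None,
    stride: int | None = None,
) -> list[FoldResult]:
    """Leave-one-out cross-validation over source images.

    One training per image: all tiles whose ``source_id`` matches the held-out
    image — rotations included — form the validation set and are excluded from
    training; the best-validation-loss checkpoint predicts the held-out
    image's full mask, which is scored against its expert mask.
    """
    ids = list(source_ids or [f"img{i:03d}" for i in range(len(images))])
    if len(ids) < 2:
        raise ValueError("leave-one-out needs at least 2 source images")
    results: list[FoldResult] = []
    for fold_idx, held_out in enumerate(ids):
        train_tiles = [t for t in dataset.tiles if t.source_id != held_out]
        val_tiles = dataset.by_source(held_out)
        model = build_network(net_spec, seed=cfg.seed + fold_idx)
        best_epoch, history = train_model(model, train_tiles, val_tiles, cfg)
        pred = predict_mask(model, images[fold_idx], net_spec.input_size, stride)
        fold_metrics = report(confusion(pred, masks[fold_idx]))
        results.append(
            FoldResult(
                held_out_id=held_out,
                predicted_mask=pred,
                metrics=fold_metrics,
                best_epoch=best_epoch,
                history=history,
            )
        )
    return results


def threshold_segment(
    image: np.ndarray, min_object_px: int = 40, dark_vessels: bool = True
) -> np.ndarray:
    """Training-free classical segmentation of dark tubular structures.

    Smooths lightly, removes the low-frequency illumination field, applies
    Otsu's threshold to the dark residual, and removes connected components
    smaller than ``min_object_px``.  Deterministic, so it is a fixed readout
    for comparing preprocessing variants.
    """
    img = np.asarray(image, dtype=float)
    smooth = ndi.gaussian_filter(img, 1.5)
    background = ndi.gaussian_filter(img, 25.0)
    residual = background - smooth if dark_vessels else smooth - background
    thr = threshold_otsu(residual)
    binary = residual > thr
    labels, n = ndi.label(binary)
    if n:
        sizes = ndi.sum_labels(binary, labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_object_px) + 1
        binary = np.isin(labels, keep)
    return binary.astype(np.uint8)
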