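"""Geometric data augmentation applied jointly to image and mask.

The core enhancement is the 8-element dihedral orbit of the square
(compositions of horizontal flip with 0/90/180/270-degree rotations),
optionally extended with random crops that are resized back to the
original resolution (bilinear for images, nearest for masks so labels
stay crisp).
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
from skimage.transform import resize

from .data_io import Sample

__all__ = ["DIHEDRAL_KINDS", "apply_dihedral", "dihedral_orbit", "random_crop", "augment_dataset"]

# Fixed order of the dihedral group elements; index = op id everywhere.
DIHEDRAL_KINDS = (
    "identity",
    "rot90",
    "rot180",
    "rot270",
    "hflip",
    "hflip_rot90",
    "hflip_rot180",
    "hflip_rot270",
)


def _apply_array(arr: np.ndarray, kind: str) -> np.ndarray:
    """Apply one dihedral op to an (H, W) or (H, W, C) array."""
    out = arr
    if kind.startswith("hflip"):
        out = np.flip(out, axis=1)
    rot_name = kind.replace("hflip", "").lstrip("_")
    rot = {"": 0, "identity": 0, "rot90": 1, "rot180": 2, "rot270": 3}[rot_name]
    if rot:
        out = np.rot90(out, k=rot, axes=(0, 1))
    return np.ascontiguousarray(out)


def apply_dihedral(sample: Sample, kind: str) -> Sample:
    if kind not in DIHEDRAL_KINDS:
        raise ValueError(f"unknown dihedral op '{kind}'")
    return Sample(
        image=_apply_array(sample.image, kind),
        mask=None if sample.mask is None else _apply_array(sample.mask, kind),
        identifier=f"{sample.identifier}:{kind}",
    )


def dihedral_orbit(sample: Sample) -> List[Sample]:
    """The 8 flip/rotation variants of a sample, in the fixed kind order.

    Image and mask undergo the identical transform, so ground truth stays
    pixel-aligned.
    """
    return [apply_dihedral(sample, kind) for kind in DIHEDRAL_KINDS]


def random_crop(sample: Sample, size: Tuple[int, int], seed: int) -> Sample:
    """Crop a (h, w) window at a uniformly random valid offset.

    The same offset is applied to image and mask; deterministic given seed.
    """
    ch, cw = size
    h, w = sample.image.shape[:2]
    if ch > h or cw > w:
        raise ValueError(f"crop size {size} exceeds sample size {(h, w)}")
    rng = np.random.default_rng(seed)
    top = int(rng.integers(0, h - ch + 1))
    left = int(rng.integers(0, w - cw + 1))
    return Sample(
        image=np.ascontiguousarray(sample.image[top : top + ch, left : left + cw]),
        mask=None
        if sample.mask is None
        else np.ascontiguousarray(sample.mask[top : top + ch, left : left + cw]),
        identifier=f"{sample.identifier}:crop{top},{left}",
    )


def _resize_sample(sample: Sample, size: Tuple[int, int]) -> Sample:
    h, w = size
    image = resize(sample.image, (h, w), order=1, preserve_range=True, anti_aliasing=False)
    mask = None
    if sample.mask is not None:
        mask = resize(sample.mask, (h, w), order=0, preserve_range=True, anti_aliasing=False)
        mask = mask.astype(sample.mask.dtype)
    return Sample(np.clip(image, 0, 255).astype(np.uint8), mask, sample.identifier)


def augment_dataset(
    samples: Sequence[Sample],
    ops: Sequence[str] = ("orbit",),
    seed: int = 0,
    crops_per_sample: int = 1,
    crop_size: Tuple[int, int] | None = None,
) -> List[Sample]:
    """Amplify a sample pool: dihedral orbit (8x) plus optional random crops.

    ``ops`` may contain ``"orbit"`` and/or ``"random_crop"``. Crops are taken
    from the original samples and resized back to their resolution; per-crop
    seeds derive deterministically from (seed, sample index, crop index).
    """
    ops = tuple(ops)
    if not ops:
        raise ValueError("ops must be nonempty")
    unknown = set(ops) - {"orbit", "random_crop"}
    if unknown:
        raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")
    out: List[Sample] = []
    for idx, sample in enumerate(samples):
        if "orbit" in ops:
            out.extend(dihedral_orbit(sample))
        if "random_crop" in ops:
            h, w = sample.image.shape[:2]
            size = crop_size or (int(h * 0.75), int(w * 0.75))
            for j in range(crops_per_sample):
                sub = int(np.random.SeedSequence([seed, idx, j]).generate_state(1)[0] % (2**31))
                out.append(_resize_sample(random_crop(sample, size, sub), (h, w)))
    return out
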