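"""Full-volume prediction by overlapping-subvolume inference.

The volume is tiled with fixed-size patches on a regular stride grid
(boundary patches clamped inside), each patch is predicted by the network
in evaluation mode, and the per-voxel results are fused: the hard label is
the majority over the hard labels of all covering patches (ties broken by
the mean foreground probability), and the probability volume is the
arithmetic mean of the per-patch foreground probabilities — the input the
level-set refinement consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .volio import LabelMask, VolumeImage


@dataclass
class ProbabilityVolume:
    """Per-voxel foreground probability on the source grid."""

    data: np.ndarray
    spacing: tuple

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.min() < 0 or self.data.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class TileGrid:
    patch: int
    stride: int
    origins: list  # list of (i, j, k) patch origins

    def __iter__(self):
        return iter(self.origins)

    def __len__(self):
        return len(self.origins)


def tile_coordinates(shape, patch: int = 32, stride: int = 16) -> TileGrid:
    """Regular grid of patch origins covering every voxel.

    Origins lie at multiples of ``stride``; the final origin per axis is
    clamped to ``extent - patch`` so boundary patches stay inside.
    """
    shape = tuple(int(s) for s in shape)
    if not 1 <= stride <= patch:
        raise ValueError(f"stride must be in [1, patch], got {stride}")
    if any(s < patch for s in shape):
        raise ValueError(f"volume shape {shape} smaller than patch {patch}")
    per_axis = []
    for s in shape:
        last = s - patch
        ax = sorted(set(list(range(0, last + 1, stride)) + [last]))
        per_axis.append(ax)
    return TileGrid(patch, stride, list(product(*per_axis)))


def predict_volume(net, volume: VolumeImage, patch: int = 32, stride: int = 16,
                   batch_tiles: int = 4):
    """Fused prediction of a whole volume.

    Returns ``(LabelMask, ProbabilityVolume)``.  Volumes with odd dimensions
    are zero-padded to even before inference and cropped after (the network
    needs one factor of 2).  Dropout is disabled; two calls give identical
    results.
    """
    data = np.asarray(volume.data, dtype=np.float32)
    orig_shape = data.shape
    pad = [(0, s % 2) for s in orig_shape]
    if any(p[1] for p in pad):
        data = np.pad(data, pad)
    grid = tile_coordinates(data.shape, patch, stride)

    votes_fg = np.zeros(data.shape, dtype=np.int32)
    cover = np.zeros(data.shape, dtype=np.int32)
    prob_sum = np.zeros(data.shape, dtype=np.float64)

    origins = grid.origins
    for s in range(0, len(origins), batch_tiles):
        chunk = origins[s:s + batch_tiles]
        x = np.stack([data[o[0]:o[0] + patch, o[1]:o[1] + patch,
                           o[2]:o[2] + patch] for o in chunk])[:, None]
        probs = net.predict_proba(x)  # (n, 2, p, p, p)
        fg = probs[:, 1]
        hard = (probs.argmax(axis=1) == 1)
        for i, o in enumerate(chunk):
            sl = tuple(slice(o[d], o[d] + patch) for d in range(3))
            votes_fg[sl] += hard[i]
            cover[sl] += 1
            prob_sum[sl] += fg[i]

    mean_prob = prob_sum / cover
    # strict majority; exact ties fall back to the fused probability
    hard = votes_fg * 2 > cover
    tie = votes_fg * 2 == cover
    hard |= tie & (mean_prob >= 0.5)

    sl = tuple(slice(0, s) for s in orig_shape)
    return (LabelMask(hard[sl].astype(np.uint8), volume.spacing),
            ProbabilityVolume(np.clip(mean_prob[sl], 0.0, 1.0), volume.spacing))
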