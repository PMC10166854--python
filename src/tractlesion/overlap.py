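"""Lesion-tract and lesion-nucleus overlap metrics.

Two measures quantify how an ablation relates to its anatomical targets:

* transection overlap — the percentage of a bundle's streamlines passing
  through a binary ablation mask (100% = complete transection of the
  fibre tract);
* label overlap volume — for each nucleus of a hard segmentation, the
  volume (mm^3) of voxels shared with the ablation mask.

Streamline membership is decided by point sampling: each streamline is
resampled at a fixed arc-length step and a sample point is inside the mask
if its nearest voxel (round-half-away-from-zero per index) is nonzero.
Points falling outside the grid are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .spatial import LabelVolume, Tractogram, resample_streamline, _arc_lengths

__all__ = [
    "StreamlineOverlapResult",
    "LabelOverlapResult",
    "streamline_mask_overlap",
    "label_overlap_volumes",
]


@dataclass
class StreamlineOverlapResult:
    """Transection overlap of one bundle with one ablation mask."""

    bundle_name: str
    n_streamlines: int
    n_transected: int

    @property
    def percent(self) -> float:
        return 100.0 * self.n_transected / self.n_streamlines


@dataclass
class LabelOverlapResult:
    """Per-label overlap volumes (mm^3) between a segmentation and an ablation."""

    volumes_mm3: dict
    label_names: dict = field(default_factory=dict)

    def volume(self, label: int) -> float:
        return self.volumes_mm3.get(int(label), 0.0)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero, elementwise (fixed for reproducibility)."""
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.intp)


def _default_step(mask: LabelVolume) -> float:
    edges = np.linalg.norm(mask.affine[:3, :3], axis=0)
    return float(edges.min()) / 2.0


def streamline_mask_overlap(t: Tractogram, mask: LabelVolume,
                            step: float | None = None,
                            bundle_name: str = "bundle") -> StreamlineOverlapResult:
    """Percentage of streamlines transected by a binary ablation mask.

    Each streamline is resampled at arc-length spacing at most ``step``
    (default: half the smallest voxel edge) and counts as transected if any
    sample maps to a nonzero voxel. Tractogram and mask must carry matching
    space tags (unless either is "unknown").
    """
    if len(t) == 0:
        raise ValidationError("empty tractogram")
    if not mask.is_binary():
        raise ValidationError("ablation mask must be binary (labels {0, 1})")
    if ("unknown" not in (t.space_id, mask.space_id)
            and t.space_id != mask.space_id):
        raise ValidationError(
            f"space mismatch: tractogram '{t.space_id}' vs mask '{mask.space_id}'"
        )
    if step is None:
        step = _default_step(mask)
    if step <= 0:
        raise ValidationError("sampling step must be positive")

    inv = np.linalg.inv(mask.affine)
    grid = mask.grid
    shape = np.array(grid.shape)
    n_transected = 0
    for s in t.streamlines:
        length = _arc_lengths(np.asarray(s))[-1]
        n_samples = max(int(np.ceil(length / step)) + 1, 2)
        pts = resample_streamline(s, n_samples)
        vox = _round_half_away(pts @ inv[:3, :3].T + inv[:3, 3])
        ok = np.all((vox >= 0) & (vox < shape), axis=1)
        if ok.any() and grid[vox[ok, 0], vox[ok, 1], vox[ok, 2]].any():
            n_transected += 1
    return StreamlineOverlapResult(bundle_name=bundle_name,
                                   n_streamlines=len(t),
                                   n_transected=n_transected)


def label_overlap_volumes(seg: LabelVolume, ablation: LabelVolume,
                          include_background: bool = False) -> LabelOverlapResult:
    """Overlap volume (mm^3) between each segmentation label and an ablation.

    For label L the volume is (voxels where ``seg == L`` and
    ``ablation == 1``) times the voxel volume. The two volumes must share
    grid shape and affine (resampling, if needed, is the caller's duty).
    """
    if seg.grid.shape != ablation.grid.shape:
        raise ValidationError(
            f"grid shape mismatch: {seg.grid.shape} vs {ablation.grid.shape}"
        )
    if not np.allclose(seg.affine, ablation.affine, atol=1e-4):
        raise ValidationError("affine mismatch beyond 1e-4 tolerance")
    if not ablation.is_binary():
        raise ValidationError("ablation mask must be binary")
    vv = seg.voxel_volume
    hit = seg.grid[ablation.grid == 1]
    minlen = int(seg.grid.max()) + 1 if seg.grid.size else 1
    counts = np.bincount(hit.ravel(), minlength=minlen)
    volumes = {int(lab): float(counts[lab]) * vv
               for lab in np.unique(seg.grid)
               if include_background or lab != 0}
    return LabelOverlapResult(volumes_mm3=volumes, label_names=dict(seg.label_names))
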