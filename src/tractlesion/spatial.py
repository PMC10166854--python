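"""Spatial primitives: streamlines, label volumes, transforms and their I/O.

Coordinates are RAS millimetres throughout. A streamline is an ``(n, 3)``
float array of ordered points (``n >= 2``); a tractogram is a list of
streamlines tagged with a free-text spatial reference. Label volumes pair a
3-D integer grid with a voxel-index-to-mm affine in the NIfTI convention
(index ``(0, 0, 0)`` maps to the centre of the first voxel; indices are
0-based).

File formats are delegated to nibabel: MRtrix TCK for tractograms and
NIfTI-1 for label volumes and displacement fields. Geometry (arc-length
resampling, the minimum average direct-flip distance, transform
application) is implemented here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

from .errors import FormatError, ValidationError

__all__ = [
    "Tractogram",
    "LabelVolume",
    "SpatialTransform",
    "as_streamline",
    "resample_streamline",
    "mdf_distance",
    "transform_tractogram",
    "read_tractogram",
    "write_tractogram",
    "read_label_volume",
    "write_label_volume",
    "read_affine_text",
    "read_displacement_field",
]

#: Default number of points streamlines are resampled to before distance
#: computations (QuickBundles convention).
DEFAULT_N_POINTS = 12


def as_streamline(points) -> np.ndarray:
    """Validate and return a streamline as an ``(n, 3)`` float64 array."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError(f"streamline must be (n, 3), got shape {pts.shape}")
    if pts.shape[0] < 2:
        raise ValidationError("streamline needs at least 2 points")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("streamline contains non-finite coordinates")
    return pts


@dataclass
class Tractogram:
    """A collection of streamlines sharing one spatial reference.

    Parameters
    ----------
    streamlines : list of (n, 3) arrays
        Ordered 3-D points in RAS mm.
    space_id : str
        Free-text tag naming the space the coordinates live in
        (e.g. ``"native-T1"``, ``"template"``). Overlap computations
        assert agreement of these tags rather than guessing from headers.
    """

    streamlines: list = field(default_factory=list)
    space_id: str = "unknown"

    def __post_init__(self):
        self.streamlines = [as_streamline(s) for s in self.streamlines]

    def __len__(self):
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def __getitem__(self, i):
        return self.streamlines[i]


@dataclass
class LabelVolume:
    """3-D integer label grid with a voxel-to-mm affine.

    Holds hard segmentations (each voxel carries exactly one label) such
    as thalamic-nuclei parcellations, and binary ablation masks
    (labels {0, 1}).
    """

    grid: np.ndarray
    affine: np.ndarray
    label_names: dict = field(default_factory=dict)
    space_id: str = "unknown"

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValidationError(f"grid must be 3-D, got {self.grid.ndim}-D")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValidationError("label grid must hold integers")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is not invertible")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the 3x3 affine block)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def labels(self) -> np.ndarray:
        return np.unique(self.grid)

    def is_binary(self) -> bool:
        return bool(np.all((self.grid == 0) | (self.grid == 1)))


@dataclass
class SpatialTransform:
    """Affine plus optional dense displacement field, applied affine-first.

    The displacement field is a vector image: ``field`` has shape
    ``(X, Y, Z, 3)`` holding mm offsets, with its own voxel-to-mm affine
    ``field_affine``. A point ``p`` maps to ``A @ p + d(A @ p)`` where the
    displacement is sampled trilinearly at the affinely mapped position.
    """

    affine: np.ndarray = None
    field: np.ndarray = None
    field_affine: np.ndarray = None

    def __post_init__(self):
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValidationError("transform affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValidationError("transform affine is not invertible")
        if self.field is not None:
            self.field = np.asarray(self.field, dtype=np.float64)
            if self.field.ndim != 4 or self.field.shape[-1] != 3:
                raise ValidationError("displacement field must be (X, Y, Z, 3)")
            if not np.all(np.isfinite(self.field)):
                raise ValidationError("displacement field contains non-finite values")
            if self.field_affine is None:
                raise ValidationError("displacement field requires its own affine")
            self.field_affine = np.asarray(self.field_affine, dtype=np.float64)

    @classmethod
    def identity(cls) -> "SpatialTransform":
        return cls(affine=np.eye(4))


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _arc_lengths(pts: np.ndarray) -> np.ndarray:
    """Cumulative arc length at each point of a polyline, starting at 0."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _resample_pass(pts: np.ndarray, k: int) -> np.ndarray:
    """One pass of piecewise-linear resampling at equal arc-length targets."""
    arc = _arc_lengths(pts)
    target = np.linspace(0.0, arc[-1], k)
    out = np.empty((k, 3))
    for d in range(3):
        out[:, d] = np.interp(target, arc, pts[:, d])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def resample_streamline(s, k: int) -> np.ndarray:
    """Resample a streamline to ``k`` points with equal consecutive spacing.

    Piecewise-linear interpolation along the polyline (no spline
    smoothing), iterated to the fixed point at which the chord lengths
    between consecutive output points are equal. The iteration makes the
    operation idempotent at fixed ``k``; endpoints are preserved exactly.
    A degenerate streamline of zero total length yields ``k`` copies of
    its first point.
    """
    if k < 2:
        raise ValidationError(f"resampling needs k >= 2, got {k}")
    pts = as_streamline(s)
    if _arc_lengths(pts)[-1] == 0.0:
        return np.repeat(pts[:1], k, axis=0)
    out = _resample_pass(pts, k)
    for _ in range(100):
        nxt = _resample_pass(out, k)
        if np.abs(nxt - out).max() < 1e-9:
            return nxt
        out = nxt
    return out


def mdf_distance(a, b, k: int = DEFAULT_N_POINTS) -> float:
    """Minimum average direct-flip (MDF) distance between two streamlines, mm.

    Both streamlines are resampled to ``k`` equally spaced points (skipped
    when already of length ``k``); the distance is the mean point-wise
    Euclidean distance, minimised over reversing one streamline. Symmetric,
    non-negative and flip-invariant.
    """
    ra = np.asarray(a, dtype=np.float64)
    rb = np.asarray(b, dtype=np.float64)
    if ra.shape != (k, 3):
        ra = resample_streamline(ra, k)
    if rb.shape != (k, 3):
        rb = resample_streamline(rb, k)
    direct = np.linalg.norm(ra - rb, axis=1).mean()
    flipped = np.linalg.norm(ra - rb[::-1], axis=1).mean()
    return float(min(direct, flipped))


def _apply_displacement(points: np.ndarray, xf: SpatialTransform,
                        streamline_index: int) -> np.ndarray:
    """Sample the displacement field trilinearly at mm positions."""
    inv = np.linalg.inv(xf.field_affine)
    vox = points @ inv[:3, :3].T + inv[:3, 3]
    shape = xf.field.shape[:3]
    eps = 1e-9
    inside = np.all((vox >= -eps) & (vox <= np.array(shape) - 1 + eps), axis=1)
    if not np.all(inside):
        raise ValidationError(
            f"streamline {streamline_index}: {int((~inside).sum())} point(s) "
            "fall outside the displacement-field domain"
        )
    coords = np.clip(vox, 0, np.array(shape) - 1).T
    disp = np.stack(
        [map_coordinates(xf.field[..., d], coords, order=1, mode="nearest")
         for d in range(3)], axis=1,
    )
    return points + disp


def transform_tractogram(t: Tractogram, xf: SpatialTransform,
                         space_id: str = "transformed") -> Tractogram:
    """Map every point of a tractogram through a spatial transform.

    The affine is applied first, then the displacement field (if any).
    Streamline and point counts are unchanged; the returned tractogram
    carries ``space_id``. A point outside the displacement-field domain
    raises, naming the offending streamline.
    """
    out = []
    A = xf.affine
    for i, s in enumerate(t.streamlines):
        p = s @ A[:3, :3].T + A[:3, 3]
        if xf.field is not None:
            p = _apply_displacement(p, xf, i)
        out.append(p)
    return Tractogram(out, space_id=space_id)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_tractogram(path, space_id: str = "unknown") -> Tractogram:
    """Read an MRtrix TCK file (coordinates in mm)."""
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        tck = nib.streamlines.TckFile.load(str(path), lazy_load=False)
    except Exception as exc:  # nibabel raises HeaderError/DataError subclasses
        raise FormatError(f"not a readable TCK file: {path} ({exc})") from exc
    streamlines = [np.asarray(s, dtype=np.float64) for s in tck.streamlines]
    return Tractogram(streamlines, space_id=space_id)


def write_tractogram(t: Tractogram, path) -> str:
    """Write a tractogram as TCK (float32, mm)."""
    nib_t = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in t.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    nib.streamlines.TckFile(nib_t).save(str(path))
    return str(path)


def read_label_volume(path, space_id: str = "unknown") -> LabelVolume:
    """Read a NIfTI-1 label volume; data must be integer-valued."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if np.issubdtype(data.dtype, np.floating):
        if not np.all(np.isfinite(data)) or not np.all(data == np.round(data)):
            raise ValidationError(
                f"{path}: label volume holds non-integer values"
            )
        data = data.astype(np.int32)
    return LabelVolume(grid=data.astype(np.int32), affine=img.affine,
                       space_id=space_id)


def write_label_volume(v: LabelVolume, path) -> str:
    """Write a label volume as NIfTI-1 (int32)."""
    img = nib.Nifti1Image(v.grid.astype(np.int32), v.affine)
    nib.save(img, str(path))
    return str(path)


def read_affine_text(path) -> np.ndarray:
    """Read a 4x4 affine from a whitespace-delimited text file."""
    mat = np.loadtxt(path)
    if mat.shape != (4, 4):
        raise FormatError(f"{path}: expected a 4x4 matrix, got {mat.shape}")
    return mat


def read_displacement_field(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a vector-valued NIfTI (3 components/voxel); returns (field, affine)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    data = np.squeeze(data)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise FormatError(
            f"{path}: expected a 3-component vector image, got shape {data.shape}"
        )
    return data, img.affine
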