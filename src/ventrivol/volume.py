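"""Core CT volume containers, geometry and resampling.

Conventions
-----------
Voxel arrays are indexed ``(k, r, c)`` = (slice, row, column).  Physical
coordinates are millimetres, ordered ``(z, y, x)`` to match the array axes:
``z`` runs along the scan axis (``slice_positions``, slice *centres*), ``y``
along rows and ``x`` along columns, both with in-plane spacing
``pixel_spacing`` measured at voxel centres from the first row/column.
Slice spacing may be non-uniform (per-slice thickness is carried
explicitly); all interpolation works in millimetres, never in index units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "CTVolume", "RigidTransform", "VentricleMask", "GeometryError",
    "read_volume", "write_volume", "trilinear_sample", "resample_rigid",
]


class GeometryError(ValueError):
    """Inconsistent or degenerate volume geometry."""


@dataclass
class CTVolume:
    """A 3-D CT image with anisotropic physical spacing.

    Parameters
    ----------
    voxels : ndarray, shape (K, R, C)
        Scalar intensities, slice-major.
    pixel_spacing : float
        In-plane spacing in mm/pixel (square pixels).
    slice_thickness : ndarray, shape (K,)
        Nominal thickness of each slice in mm; may vary slice to slice.
    slice_positions : ndarray, shape (K,)
        Centre of each slice along the scan axis, mm, strictly increasing.
    bit_depth : int
        Descriptor of the stored intensity range (8 for the phantom scale).
    valid : ndarray of bool or None
        Optional per-voxel validity mask (used by :func:`resample_rigid` to
        mark voxels that fell outside the source volume).
    """

    voxels: np.ndarray
    pixel_spacing: float
    slice_thickness: np.ndarray
    slice_positions: np.ndarray
    bit_depth: int = 8
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise GeometryError("voxels must be a 3-D (slice, row, col) array")
        self.slice_thickness = np.broadcast_to(
            np.asarray(self.slice_thickness, dtype=np.float64), (self.voxels.shape[0],)
        ).copy()
        self.slice_positions = np.asarray(self.slice_positions, dtype=np.float64)
        if self.slice_positions.shape != (self.voxels.shape[0],):
            raise GeometryError("slice_positions must have one entry per slice")
        if self.pixel_spacing <= 0 or np.any(self.slice_thickness <= 0):
            raise GeometryError("all spacings must be positive")
        if self.voxels.shape[0] > 1 and np.any(np.diff(self.slice_positions) <= 0):
            raise GeometryError("slice_positions must be strictly increasing")
        if not np.all(np.isfinite(self.voxels)):
            raise GeometryError("voxels must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def physical_center(self) -> np.ndarray:
        """Centre of the voxel-centre bounding box, (z, y, x) mm."""
        K, R, C = self.voxels.shape
        return np.array([
            0.5 * (self.slice_positions[0] + self.slice_positions[-1]),
            0.5 * (R - 1) * self.pixel_spacing,
            0.5 * (C - 1) * self.pixel_spacing,
        ])

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (k, r, c) to physical (z, y, x) mm."""
        idx = np.atleast_2d(np.asarray(idx, dtype=np.float64))
        z = np.interp(idx[:, 0], np.arange(self.n_slices), self.slice_positions)
        return np.column_stack([z, idx[:, 1] * self.pixel_spacing, idx[:, 2] * self.pixel_spacing])

    def physical_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map physical (z, y, x) mm to fractional voxel indices (k, r, c).

        Out-of-range ``z`` extrapolates linearly with the edge slice spacing so
        that out-of-bounds points can be detected by the caller.
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        pos = self.slice_positions
        k = np.interp(pts[:, 0], pos, np.arange(self.n_slices))
        # np.interp clamps; extend beyond the edges with the edge spacing
        if self.n_slices > 1:
            lo, hi = pos[0], pos[-1]
            d0 = pos[1] - pos[0]
            d1 = pos[-1] - pos[-2]
            below = pts[:, 0] < lo
            above = pts[:, 0] > hi
            k = np.where(below, (pts[:, 0] - lo) / d0, k)
            k = np.where(above, (self.n_slices - 1) + (pts[:, 0] - hi) / d1, k)
        return np.column_stack([k, pts[:, 1] / self.pixel_spacing, pts[:, 2] / self.pixel_spacing])

    def copy_with(self, voxels: np.ndarray, valid: np.ndarray | None = None) -> "CTVolume":
        return CTVolume(
            voxels=np.asarray(voxels, dtype=np.float64),
            pixel_spacing=self.pixel_spacing,
            slice_thickness=self.slice_thickness.copy(),
            slice_positions=self.slice_positions.copy(),
            bit_depth=self.bit_depth,
            valid=valid,
        )


@dataclass
class RigidTransform:
    """Six-parameter rigid transform ``alpha = (tx, ty, tz, rx, ry, rz)``.

    Translations are mm, rotations degrees about the physical axes x (columns),
    y (rows) and z (scan axis), composed in 'xyz' intrinsic-free (fixed-axis)
    order and applied about ``center`` (z, y, x) mm.  ``apply`` maps a point p
    to ``R (p - c) + c + t``.  By convention the transform maps *reference*
    (t1) coordinates into *moving* (t2) space, i.e. it is used for backward
    (pull) warping.
    """

    alpha: np.ndarray = field(default_factory=lambda: np.zeros(6))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=np.float64).reshape(6)
        self.center = np.asarray(self.center, dtype=np.float64).reshape(3)

    @property
    def translation(self) -> np.ndarray:
        """Translation (z, y, x) mm, reordered from (tx, ty, tz)."""
        return self.alpha[[2, 1, 0]]

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_euler("xyz", self.alpha[3:6], degrees=True)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        """Transform physical points, shape (N, 3) ordered (z, y, x)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        xyz = (pts - self.center)[:, ::-1]          # (x, y, z) for scipy
        out = self.rotation.apply(xyz)[:, ::-1]     # back to (z, y, x)
        return out + self.center + self.translation

    def apply_vectors(self, vecs: np.ndarray) -> np.ndarray:
        """Rotate direction vectors (z, y, x); no translation."""
        vecs = np.atleast_2d(np.asarray(vecs, dtype=np.float64))
        return self.rotation.apply(vecs[:, ::-1])[:, ::-1]

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.inv()
        rx, ry, rz = rinv.as_euler("xyz", degrees=True)
        # p' = R(p-c)+c+t  =>  p = Rinv(p'-c-t)+c = Rinv(p'-c)+c - Rinv(t)
        t_zyx = -rinv.apply(self.translation[::-1])[::-1]
        return RigidTransform(
            alpha=np.array([t_zyx[2], t_zyx[1], t_zyx[0], rx, ry, rz]),
            center=self.center.copy(),
        )

    @classmethod
    def identity(cls, center: np.ndarray | None = None) -> "RigidTransform":
        return cls(np.zeros(6), np.zeros(3) if center is None else np.asarray(center, float))


@dataclass
class VentricleMask:
    """Binary per-slice ventricle masks aligned with a :class:`CTVolume`."""

    data: np.ndarray  # (K, R, C) bool

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise GeometryError("mask must be 3-D (slice, row, col)")

    @property
    def n_vk(self) -> np.ndarray:
        """Ventricle pixel count per slice."""
        return self.data.reshape(self.data.shape[0], -1).sum(axis=1)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


# ---------------------------------------------------------------------------
# Interpolation and resampling
# ---------------------------------------------------------------------------

OUTSIDE = np.nan  # sentinel for out-of-overlap samples; excluded, never zero-filled


def trilinear_sample(vol: CTVolume, points: np.ndarray, fill: float = OUTSIDE):
    """Trilinear interpolation of ``vol`` at physical (z, y, x) points.

    Returns ``(values, inside)``.  Points whose 8-voxel neighbourhood is not
    fully inside the grid are flagged ``inside=False`` and get ``fill``
    (NaN by default) so that statistical measures can exclude them rather
    than absorbing a zero-filled background.
    """
    idx = vol.physical_to_index(points)
    return _trilinear_at_index(vol.voxels, idx, fill)


def _trilinear_at_index(arr: np.ndarray, idx: np.ndarray, fill: float = OUTSIDE):
    n = np.array(arr.shape)
    inside = np.all((idx >= 0) & (idx <= n - 1), axis=1)
    i0 = np.clip(np.floor(idx).astype(np.int64), 0, np.maximum(n - 2, 0))
    t = np.clip(idx - i0, 0.0, 1.0)
    k0, r0, c0 = i0[:, 0], i0[:, 1], i0[:, 2]
    k1 = np.minimum(k0 + 1, n[0] - 1)
    r1 = np.minimum(r0 + 1, n[1] - 1)
    c1 = np.minimum(c0 + 1, n[2] - 1)
    tz, ty, tx = t[:, 0], t[:, 1], t[:, 2]
    v = (
        arr[k0, r0, c0] * (1 - tz) * (1 - ty) * (1 - tx)
        + arr[k0, r0, c1] * (1 - tz) * (1 - ty) * tx
        + arr[k0, r1, c0] * (1 - tz) * ty * (1 - tx)
        + arr[k0, r1, c1] * (1 - tz) * ty * tx
        + arr[k1, r0, c0] * tz * (1 - ty) * (1 - tx)
        + arr[k1, r0, c1] * tz * (1 - ty) * tx
        + arr[k1, r1, c0] * tz * ty * (1 - tx)
        + arr[k1, r1, c1] * tz * ty * tx
    )
    v = np.where(inside, v, fill)
    return v, inside


def resample_rigid(
    vol: CTVolume,
    transform: RigidTransform,
    reference: CTVolume,
    fill: float = 0.0,
) -> CTVolume:
    """Warp ``vol`` onto the grid of ``reference`` through ``transform``.

    ``transform`` maps reference physical coordinates into ``vol``'s space
    (backward warping): each output voxel takes the trilinear sample of
    ``vol`` at the mapped location.  Out-of-overlap voxels are filled with
    ``fill`` and recorded in the returned volume's ``valid`` mask.
    """
    K, R, C = reference.shape
    if K == 0 or R == 0 or C == 0:
        raise GeometryError("degenerate reference geometry")
    kk, rr, cc = np.meshgrid(np.arange(K), np.arange(R), np.arange(C), indexing="ij")
    idx = np.column_stack([kk.ravel(), rr.ravel(), cc.ravel()]).astype(np.float64)
    pts = reference.index_to_physical(idx)
    mapped = transform.apply(pts)
    vals, inside = trilinear_sample(vol, mapped, fill=np.nan)
    vals = np.where(inside, vals, fill)
    return reference.copy_with(
        voxels=vals.reshape(K, R, C), valid=inside.reshape(K, R, C)
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_volume(vol: CTVolume, path) -> None:
    """Write a volume as NIfTI-1 (mm units in the affine).

    NIfTI cannot carry a per-slice thickness, so when slice spacing or
    thickness is non-uniform a JSON sidecar ``<path>.json`` is written with
    the exact ``slice_positions`` and ``slice_thickness``; :func:`read_volume`
    restores them.
    """
    import nibabel as nib

    path = Path(path)
    K = vol.n_slices
    dz = float(vol.slice_thickness[0]) if K == 1 else float(np.mean(np.diff(vol.slice_positions)))
    affine = np.diag([vol.pixel_spacing, vol.pixel_spacing, dz, 1.0])
    affine[2, 3] = vol.slice_positions[0]
    data = np.ascontiguousarray(vol.voxels.transpose(2, 1, 0))
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))

    uniform = (
        K <= 1
        or (
            np.allclose(np.diff(vol.slice_positions), vol.slice_thickness[0])
            and np.allclose(vol.slice_thickness, vol.slice_thickness[0])
        )
    )
    sidecar = path.with_name(path.name + ".json")
    if not uniform:
        sidecar.write_text(json.dumps({
            "slice_positions": vol.slice_positions.tolist(),
            "slice_thickness": vol.slice_thickness.tolist(),
            "bit_depth": vol.bit_depth,
        }))
    elif sidecar.exists():
        sidecar.unlink()


def read_volume(path, format: str | None = None) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    DICOM slices are sorted by position along the scan axis regardless of
    file order; ``RescaleSlope``/``RescaleIntercept`` are applied when
    present.  Slices must share in-plane geometry.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "dicom_series" if path.is_dir() else "nifti"
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom_series":
        return _read_dicom_series(path)
    raise ValueError(f"unknown format: {format!r}")


def _read_nifti(path: Path) -> CTVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise GeometryError("expected a 3-D NIfTI volume")
    affine = img.affine
    ps = float(np.linalg.norm(affine[:3, 0]))
    ps_y = float(np.linalg.norm(affine[:3, 1]))
    if not np.isclose(ps, ps_y, rtol=1e-4):
        raise GeometryError("non-square in-plane pixels are not supported")
    dz = float(np.linalg.norm(affine[:3, 2]))
    z0 = float(affine[2, 3])
    K = data.shape[2]
    positions = z0 + dz * np.arange(K)
    thickness = np.full(K, dz)
    bit_depth = 8
    sidecar = path.with_name(path.name + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        positions = np.asarray(meta["slice_positions"], dtype=np.float64)
        thickness = np.asarray(meta["slice_thickness"], dtype=np.float64)
        bit_depth = int(meta.get("bit_depth", 8))
    return CTVolume(
        voxels=data.transpose(2, 1, 0),
        pixel_spacing=ps,
        slice_thickness=thickness,
        slice_positions=positions,
        bit_depth=bit_depth,
    )


def _read_dicom_series(path: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in {".dcm", ""})
    if not files:
        raise FileNotFoundError(f"no DICOM files in {path}")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception as exc:  # pragma: no cover - corrupt input path
            raise IOError(f"cannot read DICOM file {f}: {exc}") from exc
        slices.append(ds)

    def zpos(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "SliceLocation", getattr(ds, "InstanceNumber", 0)))

    slices.sort(key=zpos)
    ps_list = [tuple(float(v) for v in ds.PixelSpacing) for ds in slices]
    shapes = {ds.pixel_array.shape for ds in slices}
    if len(set(ps_list)) > 1 or len(shapes) > 1:
        raise GeometryError("inconsistent in-plane geometry across slices")
    ps_r, ps_c = ps_list[0]
    if not np.isclose(ps_r, ps_c, rtol=1e-4):
        raise GeometryError("non-square in-plane pixels are not supported")
    arr = []
    for ds in slices:
        a = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr.append(a * slope + intercept)
    positions = np.array([zpos(ds) for ds in slices])
    thickness = np.array([float(getattr(ds, "SliceThickness", 1.0)) for ds in slices])
    bits = int(getattr(slices[0], "BitsStored", 16))
    return CTVolume(
        voxels=np.stack(arr),
        pixel_spacing=float(ps_r),
        slice_thickness=thickness,
        slice_positions=positions,
        bit_depth=bits,
    )


def write_mask(mask: VentricleMask, like: CTVolume, path) -> None:
    """Write a ventricle mask as an unsigned-integer NIfTI aligned with ``like``."""
    vol = like.copy_with(voxels=mask.data.astype(np.float64))
    write_volume(vol, path)


def read_mask(path) -> VentricleMask:
    vol = read_volume(path, format="nifti")
    return VentricleMask(vol.voxels > 0.5)
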