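"""Digital head phantom with a connected multi-compartment ventricle cavity.

The phantom stands in for physical agar/water models: a smooth ellipsoidal
"brain" matrix containing a fluid cavity built from parametric solids that
mirror the components of the human ventricular system — two C-shaped lateral
ventricle tubes, the foramina of Monro, a midline third-ventricle slab, a
narrow cerebral aqueduct and a fourth-ventricle lobe.  The ground-truth
cavity volume ``V_M`` is obtained by high-resolution supersampled
voxelization of the union of solids, so segmentation and volumetry can be
validated against an exactly known volume.

Scanning emulates clinical CT acquisition: each voxel records the mean
intensity of supersampled sub-voxel material points (reproducing the partial
volume effect, strongest across thick slices) plus additive Gaussian noise;
the slicing plane can be tilted (gantry angle) and the phantom rigidly
displaced between scans, mimicking head repositioning in serial studies.

Intensities use an 8-bit-like scale: background 0, fluid 30, brain 100
(CSF is hypodense relative to brain on CT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import CTVolume, RigidTransform, VentricleMask, GeometryError

__all__ = [
    "PhantomSpec", "ScanProtocol", "make_phantom", "simulate_ct",
    "scan_phantom", "ground_truth_masks", "supersampled_volume",
    "default_phantom_suite",
]


# ---------------------------------------------------------------------------
# Parametric solids.  Points are (N, 3) arrays ordered (z, y, x) in mm in the
# phantom's own frame (origin at brain centre).
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]  # (z, y, x)
    semi_axes: tuple[float, float, float]

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d = (pts - np.asarray(self.center)) / np.asarray(self.semi_axes)
        return (d * d).sum(axis=1) <= 1.0

    def bounds(self):
        c, s = np.asarray(self.center), np.asarray(self.semi_axes)
        return c - s, c + s


@dataclass(frozen=True)
class Box:
    center: tuple[float, float, float]
    half: tuple[float, float, float]

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d = np.abs(pts - np.asarray(self.center))
        return np.all(d <= np.asarray(self.half), axis=1)

    def bounds(self):
        c, h = np.asarray(self.center), np.asarray(self.half)
        return c - h, c + h


@dataclass(frozen=True)
class Capsule:
    """Cylinder with spherical caps between two endpoints."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float

    def contains(self, pts: np.ndarray) -> np.ndarray:
        p0 = np.asarray(self.p0, dtype=float)
        axis = np.asarray(self.p1, dtype=float) - p0
        L2 = float(axis @ axis)
        t = np.clip((pts - p0) @ axis / L2, 0.0, 1.0)
        closest = p0 + t[:, None] * axis
        d2 = ((pts - closest) ** 2).sum(axis=1)
        return d2 <= self.radius ** 2

    def bounds(self):
        p0, p1 = np.asarray(self.p0), np.asarray(self.p1)
        lo = np.minimum(p0, p1) - self.radius
        hi = np.maximum(p0, p1) + self.radius
        return lo, hi


@dataclass(frozen=True)
class ArcTube:
    """Tube of radius ``tube_radius`` around a circular arc in a sagittal plane.

    The arc lies in the plane x = ``x_plane``; its circle has centre
    (z=``zc``, y=``yc``) and radius ``arc_radius``; the arc spans polar angles
    ``theta0``..``theta1`` (degrees, measured from +y toward +z).  Ends are
    capped with spheres.  This is the lateral-ventricle analogue: a fat
    C-shaped cavity arching over the third ventricle.
    """

    x_plane: float
    yc: float
    zc: float
    arc_radius: float
    tube_radius: float
    theta0: float
    theta1: float

    def contains(self, pts: np.ndarray) -> np.ndarray:
        dy = pts[:, 1] - self.yc
        dz = pts[:, 0] - self.zc
        dx = pts[:, 2] - self.x_plane
        rho = np.hypot(dy, dz)
        theta = np.degrees(np.arctan2(dz, dy))
        # wrap angles into the arc's frame
        t0, t1 = self.theta0, self.theta1
        rel = (theta - t0) % 360.0
        span = (t1 - t0) % 360.0
        on_arc = rel <= span
        d_ring = np.sqrt((rho - self.arc_radius) ** 2 + dx ** 2)
        inside = on_arc & (d_ring <= self.tube_radius)
        for th in (t0, t1):
            end = np.array([
                self.zc + self.arc_radius * np.sin(np.radians(th)),
                self.yc + self.arc_radius * np.cos(np.radians(th)),
                self.x_plane,
            ])
            d2 = ((pts - end) ** 2).sum(axis=1)
            inside |= d2 <= self.tube_radius ** 2
        return inside

    def bounds(self):
        r = self.arc_radius + self.tube_radius
        lo = np.array([self.zc - r, self.yc - r, self.x_plane - self.tube_radius])
        hi = np.array([self.zc + r, self.yc + r, self.x_plane + self.tube_radius])
        return lo, hi


@dataclass
class PhantomSpec:
    """Parametric phantom description with exactly known cavity volume.

    ``ventricle_solids`` is the list of parametric solids whose (connected)
    union forms the fluid cavity; ``v_m_mm3`` is its ground-truth volume from
    supersampled voxelization (filled in by :func:`make_phantom`).
    """

    brain_semi_axes: tuple[float, float, float] = (66.0, 80.0, 68.0)  # (z, y, x)
    ventricle_solids: list = field(default_factory=list)
    landmark_solids: list = field(default_factory=list)  # (solid, intensity)
    brain_mean: float = 100.0
    fluid_mean: float = 30.0
    background: float = 0.0
    v_m_mm3: float = 0.0
    size_scale: float = 1.0
    seed: int = 0

    def intensity_lut(self) -> np.ndarray:
        base = [self.background, self.brain_mean, self.fluid_mean]
        base.extend(inten for _, inten in self.landmark_solids)
        return np.array(base)

    def material(self, pts: np.ndarray) -> np.ndarray:
        """Material code per point: 0 background, 1 brain, 2 fluid, 3+ landmarks.

        Landmarks are hypodense imaging structures (orbital analogues)
        embedded in the brain matrix; they break the near-rotational
        symmetry of the ellipsoid the way facial structures do on real
        head CT, which is what makes out-of-plane registration
        identifiable.  Fluid takes precedence over landmarks.
        """
        brain = Ellipsoid((0.0, 0.0, 0.0), self.brain_semi_axes).contains(pts)
        out = np.zeros(len(pts), dtype=np.uint8)
        out[brain] = 1
        for i, (solid, _) in enumerate(self.landmark_solids):
            out[brain & solid.contains(pts)] = 3 + i
        # ventricle solids are only evaluated inside the cavity bounding box
        lo, hi = self.fluid_bounds()
        cand = brain & np.all((pts >= lo) & (pts <= hi), axis=1)
        if np.any(cand):
            sub = pts[cand]
            fluid = np.zeros(len(sub), dtype=bool)
            for s in self.ventricle_solids:
                fluid |= s.contains(sub)
            idx = np.flatnonzero(cand)[fluid]
            out[idx] = 2
        return out

    def intensity(self, pts: np.ndarray) -> np.ndarray:
        return self.intensity_lut()[self.material(pts)]

    def fluid_bounds(self):
        if not hasattr(self, "_fluid_bounds"):
            los, his = zip(*(s.bounds() for s in self.ventricle_solids))
            self._fluid_bounds = (np.min(los, axis=0), np.max(his, axis=0))
        return self._fluid_bounds


@dataclass
class ScanProtocol:
    """CT acquisition parameters for the digital scanner.

    The slice schedule mirrors the clinical protocol for hydrocephalus
    studies: thin slices (default 3 mm) over the posterior-fossa zone at the
    level of the fourth ventricle, thick slices (default 7 mm) above it.
    ``gantry_deg`` tilts the slicing plane about the in-plane column axis.
    """

    gantry_deg: float = 0.0
    fov_mm: float = 200.0
    grid: int = 192  # ~1 mm pixels: a down-scaled stand-in for the
    # 512-pixel / 20 cm clinical acquisition matrix
    z_min: float = -66.0
    z_max: float = 66.0
    fine_thickness: float = 3.0
    coarse_thickness: float = 7.0
    fine_zone_top: float = -20.0  # below this z the scanner uses fine slices
    noise_sigma: float = 2.0
    supersample: int = 3  # odd counts put a sample at the voxel midpoint,
    # which makes the >=0.5 coverage threshold unbiased at straight edges

    def __post_init__(self) -> None:
        if self.supersample < 2:
            raise ValueError("supersample must be >= 2")
        if self.fine_thickness <= 0 or self.coarse_thickness <= 0:
            raise ValueError("thickness schedule must be positive")

    @property
    def pixel_spacing(self) -> float:
        return self.fov_mm / self.grid

    def slice_schedule(self) -> tuple[np.ndarray, np.ndarray]:
        """(centres, thicknesses) of the slice stack covering [z_min, z_max]."""
        centres, thick = [], []
        z = self.z_min
        while z < self.z_max:
            tau = self.fine_thickness if z < self.fine_zone_top else self.coarse_thickness
            centres.append(z + tau / 2.0)
            thick.append(tau)
            z += tau
        return np.asarray(centres), np.asarray(thick)


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------

def _build_solids(s: float, rng: np.random.Generator) -> list:
    """Ventricular-system solids at size scale ``s`` with mild seeded jitter."""
    j = lambda lo, hi: float(rng.uniform(lo, hi))
    lat_r = s * (11.0 + j(-0.3, 0.3))          # lateral-ventricle tube radius
    arc_R = s * (28.0 + j(-0.8, 0.8))
    x_off = s * (15.0 + j(-0.5, 0.5))          # lateral offset from midline
    yc = s * j(3.5, 5.5)
    zc = s * (16.0 + j(-1.0, 1.0))
    third = Box(center=(s * 4.0, s * 0.0, 0.0), half=(s * 13.0, s * 12.0, s * 3.0))
    solids = [
        ArcTube(x_plane=+x_off, yc=yc, zc=zc, arc_radius=arc_R,
                tube_radius=lat_r, theta0=-145.0, theta1=75.0),
        ArcTube(x_plane=-x_off, yc=yc, zc=zc, arc_radius=arc_R,
                tube_radius=lat_r, theta0=-145.0, theta1=75.0),
        third,
        # foramina of Monro: channels from the third ventricle up into each
        # lateral ventricle's frontal horn region
        Capsule(p0=(s * 12.0, s * 8.0, 0.0),
                p1=(s * 24.0, s * 24.0, +x_off), radius=s * 3.0),
        Capsule(p0=(s * 12.0, s * 8.0, 0.0),
                p1=(s * 24.0, s * 24.0, -x_off), radius=s * 3.0),
        # cerebral aqueduct: narrow channel running down and posterior
        Capsule(p0=(-s * 8.0, s * 2.0, 0.0),
                p1=(-s * 30.0, s * 9.0, 0.0), radius=s * 2.0),
        # fourth ventricle lobe
        Ellipsoid(center=(-s * 36.0, s * 9.0, 0.0),
                  semi_axes=(s * 8.0, s * 9.0, s * 8.0)),
    ]
    return solids


def supersampled_volume(spec: PhantomSpec, resolution: float = 0.5) -> float:
    """Ground-truth cavity volume by dense voxelization (the V_M oracle).

    Counts ``resolution``-spaced grid points inside the cavity-and-brain
    intersection; also verifies the cavity is one connected component.
    """
    lo, hi = spec.fluid_bounds()
    lo -= resolution
    hi += resolution
    zs = np.arange(lo[0], hi[0] + resolution, resolution)
    ys = np.arange(lo[1], hi[1] + resolution, resolution)
    xs = np.arange(lo[2], hi[2] + resolution, resolution)
    count = 0
    stack = np.zeros((len(zs), len(ys), len(xs)), dtype=bool)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    flat_yx = np.column_stack([yy.ravel(), xx.ravel()])
    for i, z in enumerate(zs):
        pts = np.column_stack([np.full(len(flat_yx), z), flat_yx])
        fluid = spec.material(pts) == 2
        stack[i] = fluid.reshape(len(ys), len(xs))
        count += int(fluid.sum())
    nlab = ndimage.label(stack)[1]
    if nlab != 1:
        raise GeometryError(f"ventricle cavity is not connected ({nlab} components)")
    return count * resolution ** 3


def make_phantom(size_scale: float = 1.0, seed: int = 0,
                 oracle_resolution: float = 0.5) -> PhantomSpec:
    """Construct a phantom at the given size scale with seeded shape jitter.

    ``size_scale`` near 1 gives a cavity of roughly 100 cm³; the supported
    range (0.7–1.35) spans roughly 35–250 cm³, comfortably covering the
    physical-model range of ~88–132 cm³ (scales ~0.95–1.09).  The ground-truth volume is computed by
    supersampled voxelization and stored on the spec; a scale whose cavity
    comes out disconnected raises :class:`GeometryError`.
    """
    if not (0.7 <= size_scale <= 1.35):
        raise ValueError("size_scale outside supported range [0.7, 1.35]")
    rng = np.random.default_rng(seed)
    landmarks = [
        (Ellipsoid(center=(-33.0, 56.0, +26.0), semi_axes=(12.0, 12.0, 12.0)), 5.0),
        (Ellipsoid(center=(-33.0, 56.0, -26.0), semi_axes=(12.0, 12.0, 12.0)), 5.0),
        # single off-midline posterior landmark: breaks left-right mirror
        # symmetry so in-plane flips/rotations are unambiguous too
        (Ellipsoid(center=(-20.0, -58.0, -18.0), semi_axes=(9.0, 9.0, 9.0)), 40.0),
    ]
    spec = PhantomSpec(
        ventricle_solids=_build_solids(size_scale, rng),
        landmark_solids=landmarks,
        size_scale=size_scale,
        seed=seed,
    )
    spec.v_m_mm3 = supersampled_volume(spec, oracle_resolution)
    return spec


def default_phantom_suite(seeds=(1, 2, 3, 4, 5)) -> list[PhantomSpec]:
    """Five phantoms with cavity volumes spanning roughly 88–132 cm³."""
    scales = (0.951, 0.995, 1.0, 1.03, 1.088)
    return [make_phantom(sc, sd) for sc, sd in zip(scales, seeds)]


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _scan_points_to_phantom(pts_scan: np.ndarray, protocol: ScanProtocol,
                            displacement: RigidTransform | None) -> np.ndarray:
    """Map scanner-frame sample points into the phantom frame.

    Gantry tilt rotates the slicing plane about the in-plane column (x)
    axis; a head displacement D moves the phantom in world space, so the
    material at world point p is the phantom evaluated at D^-1(p).
    """
    g = np.radians(protocol.gantry_deg)
    if g != 0.0:
        cz, cy = np.cos(g), np.sin(g)
        z = pts_scan[:, 0] * cz - pts_scan[:, 1] * cy
        y = pts_scan[:, 0] * cy + pts_scan[:, 1] * cz
        pts_world = np.column_stack([z, y, pts_scan[:, 2]])
    else:
        pts_world = pts_scan
    if displacement is not None:
        pts_world = displacement.inverse().apply(pts_world)
    return pts_world


def _sample_slices(spec: PhantomSpec, protocol: ScanProtocol,
                   displacement: RigidTransform | None):
    """Per-voxel supersampled means: intensity and fluid fraction.

    In-plane, each voxel is subdivided into ``supersample``² midpoint
    samples; through the slice, one sample per ~2 mm of thickness (rounded
    up to an odd count of at least 3, so the slice midpoint is sampled).
    Values are mean-pooled back to the voxel grid.  Returns per-voxel mean
    intensity and fluid fraction in one pass.
    """
    centres, thick = protocol.slice_schedule()
    n = protocol.grid
    ps = protocol.pixel_spacing
    ss = protocol.supersample
    ns = n * ss
    # supersampled in-plane coordinates: midpoints of the ss x ss sub-cells
    fine = (np.arange(ns) - (ns - 1) / 2.0) * (ps / ss)
    yy, xx = np.meshgrid(fine, fine, indexing="ij")
    flat_yx = np.column_stack([yy.ravel(), xx.ravel()])
    lut = spec.intensity_lut()
    intens = np.empty((len(centres), n, n))
    frac = np.empty((len(centres), n, n))
    border_hit = False
    for k, (zc, tau) in enumerate(zip(centres, thick)):
        mz = max(3, int(np.ceil(tau / 2.0)))
        if mz % 2 == 0:
            mz += 1
        zsub = zc + ((np.arange(mz) + 0.5) / mz - 0.5) * tau
        acc_i = np.zeros(ns * ns)
        acc_f = np.zeros(ns * ns)
        for z in zsub:
            pts = np.column_stack([np.full(len(flat_yx), z), flat_yx])
            ph = _scan_points_to_phantom(pts, protocol, displacement)
            m = spec.material(ph)
            acc_i += lut[m]
            acc_f += (m == 2)
        intens[k] = (acc_i / mz).reshape(ns, ns).reshape(n, ss, n, ss).mean(axis=(1, 3))
        frac[k] = (acc_f / mz).reshape(ns, ns).reshape(n, ss, n, ss).mean(axis=(1, 3))
        edge = np.concatenate([intens[k][0], intens[k][-1],
                               intens[k][:, 0], intens[k][:, -1]])
        if np.any(edge > spec.background + 1.0):
            border_hit = True
    if border_hit:
        raise GeometryError("phantom extends beyond the in-plane field of view")
    return intens, frac, centres, thick


def scan_phantom(spec: PhantomSpec, protocol: ScanProtocol,
                 displacement: RigidTransform | None = None,
                 seed: int = 0) -> tuple[CTVolume, VentricleMask]:
    """Scan and ground-truth segment the phantom in one sampling pass."""
    means, frac, centres, thick = _sample_slices(spec, protocol, displacement)
    rng = np.random.default_rng(seed)
    if protocol.noise_sigma > 0:
        means = means + rng.normal(0.0, protocol.noise_sigma, size=means.shape)
    vol = CTVolume(
        voxels=means,
        pixel_spacing=protocol.pixel_spacing,
        slice_thickness=thick,
        slice_positions=centres,
        bit_depth=8,
    )
    return vol, VentricleMask(frac >= 0.5)


def simulate_ct(spec: PhantomSpec, protocol: ScanProtocol,
                displacement: RigidTransform | None = None,
                seed: int = 0) -> CTVolume:
    """Scan the phantom: supersampled partial-volume intensities plus noise.

    Each voxel's intensity is the mean of material intensities over a
    supersampled sub-voxel grid (``supersample``² in-plane points and at
    least three points through the slice), which reproduces the partial
    volume effect at tissue boundaries and slice edges.  Gaussian noise of
    standard deviation ``protocol.noise_sigma`` is then added (seeded;
    ``sigma=0`` gives the exact partial-volume means).
    """
    return scan_phantom(spec, protocol, displacement, seed)[0]


def ground_truth_masks(spec: PhantomSpec, protocol: ScanProtocol,
                       displacement: RigidTransform | None = None) -> VentricleMask:
    """Reference segmentation on the scan grid: fluid fraction >= 0.5.

    The mask is the simulator's substitute for expert manual segmentation:
    a pixel is ventricle iff at least half of its (supersampled) voxel
    extent lies in fluid.
    """
    _, frac, _, _ = _sample_slices(spec, protocol, displacement)
    return VentricleMask(frac >= 0.5)
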