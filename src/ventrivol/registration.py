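"""3-D rigid registration by gradient-weighted normalized mutual information.

The later (moving, t2) CT study is aligned to the earlier (reference, t1)
study by maximizing

    In'(A, B) = G(A, B) * In(A, B),

where ``In = (H(A)+H(B))/H(A,B)`` is normalized mutual information computed
from a joint histogram built with partial-volume (PV) interpolation — each
in-overlap reference voxel spreads a unit mass over the intensities of the
8 surrounding moving-grid voxels with trilinear weights — and ``G`` is a
gradient-agreement term: a sum over corresponding sample pairs of
``w(angle) * min(|grad_ref|, |grad_mov|)`` with ``w(a) = (cos 2a + 1)/2``,
which rewards alignments where strong edges coincide and is insensitive to
intensity inversions.

The six rigid parameters are optimized with Nelder-Mead simplex search over
a coarse-to-fine in-plane wavelet pyramid: the optimum at each level
initializes the next finer level (translations are carried in mm, so they
transfer across levels unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage
from scipy.optimize import minimize

from .volume import CTVolume, RigidTransform, resample_rigid
from .volume import _trilinear_at_index

__all__ = [
    "RegistrationConfig", "RegistrationResult", "JointHistogram",
    "joint_histogram_pv", "normalized_mi", "gradient_term",
    "combined_measure", "wavelet_pyramid", "register",
]


@dataclass
class JointHistogram:
    """B x B joint intensity histogram (reference rows, moving columns)."""

    bins: np.ndarray

    @property
    def mass(self) -> float:
        return float(self.bins.sum())

    def marginals(self) -> tuple[np.ndarray, np.ndarray]:
        return self.bins.sum(axis=1), self.bins.sum(axis=0)


@dataclass
class RegistrationConfig:
    """Knobs of the registration search.

    bins: joint-histogram size after linear rescale of each volume to [0, B).
    sigma_mm: Gaussian scale of the image gradients in the G term.
    levels: pyramid depth (level 0 = full resolution), in-plane decimation.
    max_evals: simplex measure-evaluation budget per level.
    initial_step: simplex initial displacement, mm for translations and
        degrees for rotations, applied at the coarsest level and halved at
        each finer level.
    stride: take every n-th in-plane reference voxel when building the
        measure (1 = all in-overlap voxels).
    """

    bins: int = 64
    sigma_mm: float = 1.5
    levels: int = 3
    max_evals: int = 400
    initial_step: float = 5.0
    xatol: float = 0.01
    stride: int = 1
    initial: np.ndarray | None = None


@dataclass
class RegistrationResult:
    transform: RigidTransform          # alpha* mapping reference into moving space
    registered: CTVolume               # moving volume resampled on the reference grid
    measure_trace: list = field(default_factory=list)  # (level, In') pairs
    converged: bool = True
    n_evaluations: int = 0


# ---------------------------------------------------------------------------
# Joint histogram with partial-volume interpolation
# ---------------------------------------------------------------------------

def _rescale_bins(vol: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = float(vol.min()), float(vol.max())
    if hi <= lo:
        return np.zeros(vol.shape, dtype=np.int64)
    idx = ((vol - lo) / (hi - lo) * bins).astype(np.int64)
    return np.clip(idx, 0, bins - 1)


def _sample_grid(ref: CTVolume, stride: int) -> np.ndarray:
    K, R, C = ref.shape
    kk, rr, cc = np.meshgrid(
        np.arange(0, K), np.arange(0, R, stride), np.arange(0, C, stride),
        indexing="ij",
    )
    return np.column_stack([kk.ravel(), rr.ravel(), cc.ravel()]).astype(np.float64)


def _pv_weights(mov: CTVolume, pts_phys: np.ndarray):
    """Eight-corner trilinear weights of mapped points on the moving grid.

    Returns (corner flat indices (n, 8), weights (n, 8), in-overlap mask).
    """
    idx = mov.physical_to_index(pts_phys)
    n = np.array(mov.shape)
    inside = np.all((idx >= 0) & (idx <= n - 1), axis=1)
    idx = idx[inside]
    i0 = np.clip(np.floor(idx).astype(np.int64), 0, np.maximum(n - 2, 0))
    t = np.clip(idx - i0, 0.0, 1.0)
    offs = np.array([[a, b, c] for a in (0, 1) for b in (0, 1) for c in (0, 1)])
    corners = i0[:, None, :] + offs[None, :, :]
    w = np.ones((len(idx), 8))
    for ax in range(3):
        ta = t[:, ax]
        w *= np.where(offs[None, :, ax] == 1, ta[:, None], 1.0 - ta[:, None])
    flat = (corners[:, :, 0] * n[1] + corners[:, :, 1]) * n[2] + corners[:, :, 2]
    return flat, w, inside


def joint_histogram_pv(ref: CTVolume, mov: CTVolume, transform: RigidTransform,
                       bins: int = 64, stride: int = 1) -> JointHistogram:
    """Joint histogram under ``transform`` with PV interpolation.

    Each in-overlap reference voxel contributes exactly unit mass, split
    over the 8 nearest moving-grid neighbours with trilinear weights;
    out-of-overlap voxels contribute nothing (they are excluded, not
    zero-filled, because zero-filling biases the intensity statistics).
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    ref_bins = _rescale_bins(ref.voxels, bins)
    mov_bins = _rescale_bins(mov.voxels, bins).ravel()
    grid = _sample_grid(ref, stride)
    pts = ref.index_to_physical(grid)
    mapped = transform.apply(pts)
    flat, w, inside = _pv_weights(mov, mapped)
    if not np.any(inside):
        raise ValueError("no overlap between volumes under this transform")
    rb = ref_bins.ravel()[
        np.ravel_multi_index(grid[inside].astype(np.int64).T, ref.shape)
    ]
    h = np.zeros(bins * bins)
    for c in range(8):
        pair = rb * bins + mov_bins[flat[:, c]]
        h += np.bincount(pair, weights=w[:, c], minlength=bins * bins)
    return JointHistogram(h.reshape(bins, bins))


def normalized_mi(h: JointHistogram) -> float:
    """Normalized mutual information (H(A)+H(B))/H(A,B) of a histogram.

    Lies in [1, 2]; equals 2 for identical aligned images and tends to 1
    for independent ones.  0*log(0) is treated as 0.
    """
    total = h.mass
    if total <= 0:
        raise ValueError("zero-mass histogram")
    p = h.bins / total
    pa, pb = p.sum(axis=1), p.sum(axis=0)

    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    hab = ent(p.ravel())
    if hab == 0.0:
        # single occupied cell: marginals are deterministic too; the
        # measure attains its supremum
        return 2.0
    return (ent(pa) + ent(pb)) / hab


# ---------------------------------------------------------------------------
# Gradient term
# ---------------------------------------------------------------------------

def _gaussian_gradient(vol: CTVolume, sigma_mm: float) -> np.ndarray:
    """Gaussian-derivative gradient field in 1/mm units, shape (K, R, C, 3).

    In-plane derivatives are separable Gaussian derivatives at scale
    ``sigma_mm``.  Slice spacing may be non-uniform, so the through-plane
    derivative is a finite difference of the in-plane-smoothed volume
    against the true slice positions.
    """
    s_px = sigma_mm / vol.pixel_spacing
    sm = ndimage.gaussian_filter(vol.voxels, sigma=(0, s_px, s_px))
    gy = ndimage.gaussian_filter(vol.voxels, sigma=(0, s_px, s_px), order=(0, 1, 0))
    gx = ndimage.gaussian_filter(vol.voxels, sigma=(0, s_px, s_px), order=(0, 0, 1))
    gy /= vol.pixel_spacing
    gx /= vol.pixel_spacing
    if vol.n_slices > 1:
        gz = np.gradient(sm, vol.slice_positions, axis=0)
    else:
        gz = np.zeros_like(sm)
    return np.stack([gz, gy, gx], axis=-1)


def gradient_term(ref: CTVolume, mov: CTVolume, transform: RigidTransform,
                  sigma_mm: float = 1.5, stride: int = 1,
                  _cache: dict | None = None) -> float:
    """Gradient agreement G(A, B) between reference and mapped moving image.

    For every in-overlap reference voxel x with mapped point x~, the term
    accumulates w(a)*min(|grad(x)|, |grad(x~)|) where a is the angle
    between the two Gaussian-scale gradient vectors and w(a) = (cos 2a + 1)/2.
    Moving-volume gradients are trilinearly interpolated from a precomputed
    field and rotated back into the reference orientation; pairs with a
    zero gradient on either side contribute nothing (their angle is
    undefined and min(...) = 0 anyway).
    """
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    if _cache is not None and "gref" in _cache:
        gref, gmov = _cache["gref"], _cache["gmov"]
    else:
        gref = _gaussian_gradient(ref, sigma_mm)
        gmov = _gaussian_gradient(mov, sigma_mm)
        if _cache is not None:
            _cache.update(gref=gref, gmov=gmov)
    grid = _sample_grid(ref, stride)
    pts = ref.index_to_physical(grid)
    mapped = transform.apply(pts)
    flat, w, inside = _pv_weights(mov, mapped)
    if not np.any(inside):
        return 0.0
    g1 = gref.reshape(-1, 3)[
        np.ravel_multi_index(grid[inside].astype(np.int64).T, ref.shape)
    ]
    gm_flat = gmov.reshape(-1, 3)
    g2 = np.einsum("nc,ncd->nd", w, gm_flat[flat])
    # the moving gradient lives in moving space; rotate back into the
    # reference frame before comparing directions
    g2 = transform.rotation.inv().apply(g2[:, ::-1])[:, ::-1]
    n1 = np.linalg.norm(g1, axis=1)
    n2 = np.linalg.norm(g2, axis=1)
    ok = (n1 > 0) & (n2 > 0)
    if not np.any(ok):
        return 0.0
    cosang = np.einsum("nd,nd->n", g1[ok], g2[ok]) / (n1[ok] * n2[ok])
    cosang = np.clip(cosang, -1.0, 1.0)
    wang = cosang ** 2  # (cos 2a + 1)/2 == cos^2 a
    return float((wang * np.minimum(n1[ok], n2[ok])).sum())


def combined_measure(ref: CTVolume, mov: CTVolume, transform: RigidTransform,
                     sigma_mm: float = 1.5, bins: int = 64, stride: int = 1,
                     _cache: dict | None = None) -> float:
    """Gradient-weighted normalized mutual information In' = G * In.

    Computes the PV joint histogram and the gradient term from a single
    shared point mapping (they use the same sample set by design).
    """
    cache = _cache if _cache is not None else {}
    if "pts" not in cache:
        grid = _sample_grid(ref, stride)
        # off-grid sampling: a fixed sub-voxel jitter of the sample points
        # removes the interpolation artifact that otherwise inflates the
        # measure whenever the two slice stacks coincide exactly (a spurious
        # maximum at zero out-of-plane rotation).  The jitter is seeded and
        # built once per cache, so the objective stays smooth and
        # deterministic.
        rng = np.random.default_rng(1234567)
        jitter = rng.uniform(-0.5, 0.5, size=grid.shape)
        jit = grid + jitter
        n = np.array(ref.shape, dtype=float)
        jit = np.clip(jit, 0.0, n - 1.0001)
        cache["pts"] = ref.index_to_physical(jit)
        ref_vals, _ = _trilinear_at_index(ref.voxels, jit, fill=0.0)
        lo, hi = float(ref.voxels.min()), float(ref.voxels.max())
        if hi > lo:
            rb = np.clip(((ref_vals - lo) / (hi - lo) * bins).astype(np.int64),
                         0, bins - 1)
        else:
            rb = np.zeros(len(jit), dtype=np.int64)
        cache["ref_bins_flat"] = rb
        cache["mov_bins"] = _rescale_bins(mov.voxels, bins).ravel()
        gref = _gaussian_gradient(ref, sigma_mm)
        g1 = np.stack([
            _trilinear_at_index(gref[..., d], jit, fill=0.0)[0] for d in range(3)
        ], axis=-1)
        cache["gref_flat"] = g1
        cache["gmov_flat"] = _gaussian_gradient(mov, sigma_mm).reshape(-1, 3)
    mapped = transform.apply(cache["pts"])
    flat, w, inside = _pv_weights(mov, mapped)
    if not np.any(inside):
        raise ValueError("no overlap between volumes under this transform")
    # histogram part
    rb = cache["ref_bins_flat"][inside]
    h = np.zeros(bins * bins)
    mov_bins = cache["mov_bins"]
    for c in range(8):
        pair = rb * bins + mov_bins[flat[:, c]]
        h += np.bincount(pair, weights=w[:, c], minlength=bins * bins)
    in_ = normalized_mi(JointHistogram(h.reshape(bins, bins)))
    # gradient part
    g1 = cache["gref_flat"][inside]
    g2 = np.einsum("nc,ncd->nd", w, cache["gmov_flat"][flat])
    g2 = transform.rotation.inv().apply(g2[:, ::-1])[:, ::-1]
    n1 = np.linalg.norm(g1, axis=1)
    n2 = np.linalg.norm(g2, axis=1)
    ok = (n1 > 0) & (n2 > 0)
    if not np.any(ok):
        return 0.0
    cosang = np.einsum("nd,nd->n", g1[ok], g2[ok]) / (n1[ok] * n2[ok])
    cosang = np.clip(cosang, -1.0, 1.0)
    g = float((cosang ** 2 * np.minimum(n1[ok], n2[ok])).sum())
    return g * in_


# ---------------------------------------------------------------------------
# Multiresolution pyramid and the search loop
# ---------------------------------------------------------------------------

def wavelet_pyramid(vol: CTVolume, levels: int = 3) -> list[CTVolume]:
    """In-plane wavelet multiresolution pyramid, fine to coarse.

    Level 0 is the original volume; level l is the l-fold Daubechies-4
    approximation band of each slice with pixel spacing doubled per level
    (the lowpass DC gain of 2 per step is divided out so intensities stay
    on the original scale).  Decimation is in-plane only: through-plane
    resolution is already coarse at 3–7 mm slices.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    out = [vol]
    cur = vol
    for _ in range(levels - 1):
        K, R, C = cur.shape
        if min(R, C) < 8:
            raise ValueError("volume too small for the requested pyramid depth")
        slices = [pywt.dwt2(cur.voxels[k], "db4", mode="periodization")[0]
                  for k in range(K)]
        cur = CTVolume(
            voxels=np.stack(slices) / 2.0,
            pixel_spacing=cur.pixel_spacing * 2.0,
            slice_thickness=cur.slice_thickness.copy(),
            slice_positions=cur.slice_positions.copy(),
            bit_depth=cur.bit_depth,
        )
        out.append(cur)
    return out


def register(ref: CTVolume, mov: CTVolume,
             config: RegistrationConfig | None = None) -> RegistrationResult:
    """Find the rigid transform aligning ``mov`` to ``ref``.

    Nelder-Mead maximization of In' at the coarsest pyramid level starting
    from ``config.initial`` (default: zero displacement), each finer level
    re-initialized at the previous optimum; translations are expressed in
    mm and rotations in degrees throughout, so parameters carry across
    levels unchanged.  Returns the optimal parameters, the resampled
    moving volume and the per-level measure trace; if a level exhausts its
    evaluation budget the result is flagged ``converged=False`` with the
    best parameters so far.
    """
    cfg = config or RegistrationConfig()
    center = ref.physical_center()
    pyr_ref = wavelet_pyramid(ref, cfg.levels)
    pyr_mov = wavelet_pyramid(mov, cfg.levels)
    alpha = np.zeros(6) if cfg.initial is None else np.asarray(cfg.initial, float).copy()
    trace = []
    converged = True
    n_eval_total = 0

    for li in range(cfg.levels - 1, -1, -1):
        r, m = pyr_ref[li], pyr_mov[li]
        cache: dict = {}

        def neg_measure(a, _r=r, _m=m, _cache=cache):
            t = RigidTransform(a, center)
            try:
                return -combined_measure(_r, _m, t, sigma_mm=cfg.sigma_mm,
                                         bins=cfg.bins, stride=cfg.stride,
                                         _cache=_cache)
            except ValueError:
                return 0.0  # no overlap: worst possible measure

        step = cfg.initial_step * (0.5 ** (cfg.levels - 1 - li))
        simplex = np.vstack([alpha] + [alpha + step * e for e in np.eye(6)])
        res = minimize(neg_measure, alpha, method="Nelder-Mead",
                       options={"initial_simplex": simplex,
                                "maxfev": cfg.max_evals,
                                "xatol": cfg.xatol, "fatol": 1e-8,
                                "disp": False})
        n_eval_total += int(res.nfev)
        if res.nfev >= cfg.max_evals and not res.success:
            converged = False
        if -res.fun >= -neg_measure(alpha):
            alpha = res.x.copy()
        trace.append((li, float(-res.fun)))

    transform = RigidTransform(alpha, center)
    registered = resample_rigid(mov, transform, ref, fill=float(mov.voxels.min()))
    return RegistrationResult(
        transform=transform,
        registered=registered,
        measure_trace=trace,
        converged=converged,
        n_evaluations=n_eval_total,
    )
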