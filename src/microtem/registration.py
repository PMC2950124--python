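"""Tile montaging, lens correction, MLS section warps, mipmaps, rendering.

Montaging follows an as-rigid-as-possible scheme: every tile receives its own
2D rigid transform, estimated simultaneously from all tile-to-tile feature
correspondences (within a section and with the previous/subsequent sections).
An iterative optimizer relaxes the configuration until the sum of squared
correspondence inter-distances is minimal.  A per-section non-linear warp is
then fit with the Moving-Least-Squares (MLS) method using tile centers as
control points.  Lens deformation, constant across tiles, is corrected with a
polynomial model estimated from heavily overlapping tile placements.

Conventions
-----------
* Pixel coordinates are (x, y), 0-based, x rightward, y downward.
* A rigid transform maps tile-local px to section-global px.
* The polynomial lens model is the *correction*: it maps observed (distorted)
  tile-local coordinates to ideal coordinates and is identity at the image
  center (its non-linear terms are expressed in center-relative coordinates
  and it has no constant or linear part).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Correspondence",
    "RigidTransform2D",
    "PolynomialDistortion2D",
    "MLSWarp2D",
    "MontageSolution",
    "match_features",
    "estimate_lens_distortion",
    "montage_residual",
    "solve_montage",
    "fit_section_warp",
    "apply_mls",
    "build_mipmaps",
    "render_section",
]


@dataclass(frozen=True)
class Correspondence:
    """A matched point pair between two tiles, in tile-local pixels."""

    tile_a: str
    tile_b: str
    point_a: Tuple[float, float]
    point_b: Tuple[float, float]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.tile_a == self.tile_b:
            raise ValueError("correspondence must link two distinct tiles")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")


@dataclass
class RigidTransform2D:
    """Rotation (radians) followed by translation, orthonormal by construction."""

    angle: float = 0.0
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.angle), np.sin(self.angle)
        return np.array([[c, -s], [s, c]])

    def apply(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix.T + self.translation
        return out if np.ndim(points) > 1 else out[0]

    __call__ = apply

    def inverse(self) -> "RigidTransform2D":
        R = self.matrix
        return RigidTransform2D(angle=-self.angle, translation=-(R.T @ self.translation))


def _poly_basis(uv: np.ndarray, degree: int) -> np.ndarray:
    """Monomials u^i v^j with 2 <= i+j <= degree, for center-relative coords."""
    u, v = uv[:, 0], uv[:, 1]
    cols = []
    for d in range(2, degree + 1):
        for i in range(d, -1, -1):
            cols.append(u ** i * v ** (d - i))
    return np.stack(cols, axis=1)


def n_poly_terms(degree: int) -> int:
    return sum(d + 1 for d in range(2, degree + 1))


@dataclass
class PolynomialDistortion2D:
    """Polynomial lens correction, identity-constrained at ``center``.

    ``coef_x`` / ``coef_y`` weight the monomial basis of :func:`_poly_basis`
    evaluated at center-relative coordinates; the corrected point is
    ``p + (B(p-center) @ coef_x, B(p-center) @ coef_y)``.
    """

    degree: int
    coef_x: np.ndarray
    coef_y: np.ndarray
    center: np.ndarray

    def __post_init__(self) -> None:
        m = n_poly_terms(self.degree)
        self.coef_x = np.asarray(self.coef_x, dtype=float).reshape(m)
        self.coef_y = np.asarray(self.coef_y, dtype=float).reshape(m)
        self.center = np.asarray(self.center, dtype=float).reshape(2)

    @classmethod
    def identity(cls, degree: int, center) -> "PolynomialDistortion2D":
        m = n_poly_terms(degree)
        return cls(degree, np.zeros(m), np.zeros(m), np.asarray(center, dtype=float))

    def apply(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        B = _poly_basis(pts - self.center, self.degree)
        out = pts + np.stack([B @ self.coef_x, B @ self.coef_y], axis=1)
        return out if np.ndim(points) > 1 else out[0]

    __call__ = apply

    def inverse_apply(self, points, tol: float = 1e-10, max_iter: int = 50) -> np.ndarray:
        """Numerically invert the correction (Newton fixed-point iteration)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        x = pts.copy()
        for _ in range(max_iter):
            f = self.apply(x)
            err = f - pts
            if np.max(np.abs(err)) < tol:
                break
            x = x - err  # quasi-Newton with Jacobian ~ identity (mild distortion)
        return x if np.ndim(points) > 1 else x[0]


# ---------------------------------------------------------------------------
# Moving Least Squares warps


@dataclass
class MLSWarp2D:
    """Moving-Least-Squares 2D warp with rigid or affine local model.

    Each query point receives its own weighted best-fit transform with
    weights ``w_i = 1 / |p_i - v|^(2 alpha)``; the warp interpolates the
    control points exactly and reproduces any global transform within its
    local-model class.
    """

    control: np.ndarray
    target: np.ndarray
    alpha: float = 1.0
    model: str = "rigid"  # "rigid" | "affine"

    def __post_init__(self) -> None:
        self.control = np.atleast_2d(np.asarray(self.control, dtype=float))
        self.target = np.atleast_2d(np.asarray(self.target, dtype=float))
        if self.control.shape != self.target.shape or self.control.shape[0] < 1:
            raise ValueError("control and target must be equal-length, non-empty")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.model not in ("rigid", "affine"):
            raise ValueError(f"unknown local model {self.model!r}")

    def apply(self, points) -> np.ndarray:
        out = apply_mls(self, np.atleast_2d(np.asarray(points, dtype=float)))
        return out if np.ndim(points) > 1 else out[0]

    __call__ = apply

    def inverse_warp(self) -> "MLSWarp2D":
        """Approximate inverse: the MLS warp with control/target swapped."""
        return MLSWarp2D(self.target, self.control, alpha=self.alpha, model=self.model)


def fit_section_warp(
    tile_centers_before,
    tile_centers_after,
    alpha: float = 1.0,
    local_model: str = "rigid",
) -> MLSWarp2D:
    """Fit the per-section MLS warp from tile centers before/after relaxation."""
    before = np.atleast_2d(np.asarray(tile_centers_before, dtype=float))
    after = np.atleast_2d(np.asarray(tile_centers_after, dtype=float))
    if before.shape != after.shape:
        raise ValueError("center lists must have equal length")
    # Duplicate sources mapping to different targets make interpolation ill-posed
    for i in range(len(before)):
        for j in range(i + 1, len(before)):
            if np.allclose(before[i], before[j]) and not np.allclose(after[i], after[j]):
                raise ValueError(
                    f"duplicate control point {before[i]} with conflicting targets"
                )
    return MLSWarp2D(before, after, alpha=alpha, model=local_model)


def apply_mls(warp: MLSWarp2D, points: np.ndarray) -> np.ndarray:
    """Evaluate an MLS warp at an (n, 2) array of query points."""
    v = np.atleast_2d(np.asarray(points, dtype=float))
    p, q = warp.control, warp.target
    nq, nc = v.shape[0], p.shape[0]
    out = np.empty_like(v)

    d2 = np.sum((v[:, None, :] - p[None, :, :]) ** 2, axis=2)  # (nq, nc)
    coincident = d2 < 1e-24
    hit = coincident.any(axis=1)
    if hit.any():
        out[hit] = q[np.argmax(coincident[hit], axis=1)]
    free = ~hit
    if not free.any():
        return out
    vf = v[free]
    w = 1.0 / d2[free] ** warp.alpha  # (m, nc)
    wsum = w.sum(axis=1, keepdims=True)
    pstar = (w @ p) / wsum
    qstar = (w @ q) / wsum
    phat = p[None, :, :] - pstar[:, None, :]  # (m, nc, 2)
    qhat = q[None, :, :] - qstar[:, None, :]
    vrel = vf - pstar

    if warp.model == "affine":
        # Per-query 2x2 normal equations: (sum w p^T p) M = sum w p^T q
        A = np.einsum("mc,mci,mcj->mij", w, phat, phat)
        Bm = np.einsum("mc,mci,mcj->mij", w, phat, qhat)
        res = np.empty_like(vrel)
        # solve A^T x = ... ; f(v) = vrel @ M + qstar with M = A^{-1} B
        dets = np.linalg.det(A)
        ok = np.abs(dets) > 1e-18 * np.maximum(1.0, np.einsum("mii->m", A)) ** 2
        if ok.any():
            M = np.linalg.solve(A[ok], Bm[ok])
            res[ok] = np.einsum("mi,mij->mj", vrel[ok], M)
        if (~ok).any():
            for k in np.nonzero(~ok)[0]:
                M, *_ = np.linalg.lstsq(A[k], Bm[k], rcond=None)
                res[k] = vrel[k] @ M
        out[free] = res + qstar
    else:
        # Weighted Procrustes rotation per query point
        num = np.einsum("mc,mc->m", w, phat[..., 0] * qhat[..., 1] - phat[..., 1] * qhat[..., 0])
        den = np.einsum("mc,mc->m", w, phat[..., 0] * qhat[..., 0] + phat[..., 1] * qhat[..., 1])
        theta = np.arctan2(num, den)
        c, s = np.cos(theta), np.sin(theta)
        rx = c * vrel[:, 0] - s * vrel[:, 1]
        ry = s * vrel[:, 0] + c * vrel[:, 1]
        out[free] = np.stack([rx, ry], axis=1) + qstar
    return out


# ---------------------------------------------------------------------------
# Feature matching


def match_features(
    image_a: np.ndarray,
    image_b: np.ndarray,
    tile_a: str = "a",
    tile_b: str = "b",
    max_ratio: float = 0.92,
    consensus_tol: float = 3.0,
    use_consensus: bool = True,
) -> List[Correspondence]:
    """SIFT feature matching between two tiles.

    Candidate matches pass a nearest-neighbor descriptor ratio test
    (``max_ratio``), then an optional displacement-consensus filter that
    keeps matches within ``consensus_tol`` px of the median displacement.
    Deterministic given fixed inputs.  Returns an empty list when either
    image yields no features or no matches survive.
    """
    from skimage.feature import SIFT, match_descriptors

    out: List[Correspondence] = []
    det_a, det_b = SIFT(), SIFT()
    try:
        det_a.detect_and_extract(np.asarray(image_a, dtype=float))
        det_b.detect_and_extract(np.asarray(image_b, dtype=float))
    except RuntimeError:  # no features found
        return out
    if len(det_a.keypoints) == 0 or len(det_b.keypoints) == 0:
        return out
    matches = match_descriptors(
        det_a.descriptors, det_b.descriptors, cross_check=True, max_ratio=max_ratio
    )
    if len(matches) == 0:
        return out
    # keypoints are (row, col) = (y, x); convert to (x, y)
    ka = det_a.keypoints[matches[:, 0]][:, ::-1].astype(float)
    kb = det_b.keypoints[matches[:, 1]][:, ::-1].astype(float)
    if use_consensus and len(ka) > 0:
        disp = kb - ka
        med = np.median(disp, axis=0)
        keep = np.linalg.norm(disp - med, axis=1) <= consensus_tol
        ka, kb = ka[keep], kb[keep]
    for pa, pb in zip(ka, kb):
        out.append(Correspondence(tile_a, tile_b, tuple(pa), tuple(pb)))
    return out


# ---------------------------------------------------------------------------
# Montage solver


@dataclass
class MontageSolution:
    """Result of the iterative rigid relaxation."""

    transforms: Dict[str, RigidTransform2D]
    residual: float  # mean squared correspondence distance (px^2)
    iterations: int
    residual_history: List[float] = field(default_factory=list)
    section_warps: Dict[int, MLSWarp2D] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.residual < 0:
            raise ValueError("residual must be non-negative")


def _connected_components(tile_ids: Sequence[str], corrs: Sequence[Correspondence]):
    parent = {t: t for t in tile_ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for c in corrs:
        ra, rb = find(c.tile_a), find(c.tile_b)
        if ra != rb:
            parent[ra] = rb
    comps: Dict[str, List[str]] = {}
    for t in tile_ids:
        comps.setdefault(find(t), []).append(t)
    return list(comps.values())


def montage_residual(
    transforms: Dict[str, RigidTransform2D], corrs: Sequence[Correspondence]
) -> float:
    """Weighted mean squared distance between mapped correspondence points."""
    num = 0.0
    den = 0.0
    for c in corrs:
        pa = transforms[c.tile_a].apply(np.asarray(c.point_a))
        pb = transforms[c.tile_b].apply(np.asarray(c.point_b))
        num += c.weight * float(np.sum((pa - pb) ** 2))
        den += c.weight
    return num / den if den > 0 else 0.0


def _rot_apply(pts: np.ndarray, ang: np.ndarray, trans: np.ndarray) -> np.ndarray:
    """Apply per-point rotations/translations: pts (n,2), ang (n,), trans (n,2)."""
    c, s = np.cos(ang), np.sin(ang)
    return np.stack(
        [c * pts[:, 0] - s * pts[:, 1], s * pts[:, 0] + c * pts[:, 1]], axis=1
    ) + trans


def _fit_rigid_weighted(src: np.ndarray, dst: np.ndarray, w: np.ndarray) -> RigidTransform2D:
    wsum = w.sum()
    ps = (w[:, None] * src).sum(axis=0) / wsum
    qs = (w[:, None] * dst).sum(axis=0) / wsum
    sh, dh = src - ps, dst - qs
    num = float(np.sum(w * (sh[:, 0] * dh[:, 1] - sh[:, 1] * dh[:, 0])))
    den = float(np.sum(w * (sh[:, 0] * dh[:, 0] + sh[:, 1] * dh[:, 1])))
    if num == 0.0 and den == 0.0:  # degenerate scatter: translation only
        theta = 0.0
    else:
        theta = float(np.arctan2(num, den))
    t = RigidTransform2D(angle=theta)
    t.translation = qs - t.matrix @ ps
    return t


def solve_montage(
    tile_ids: Sequence[str],
    correspondences: Sequence[Correspondence],
    anchor_tile: str,
    initial: Optional[Dict[str, RigidTransform2D]] = None,
    tol: float = 1e-9,
    max_iter: int = 10000,
    atol: float = 1e-18,
) -> MontageSolution:
    """Relax per-tile rigid transforms until the correspondence residual is minimal.

    Alternating closed-form weighted Procrustes fits: each sweep re-fits every
    tile (except the anchor, fixed to its initial transform for gauge fixing)
    against the current positions of its correspondence partners.  Each
    per-tile update minimises the terms of the global objective involving
    that tile with all others held fixed, so the residual is non-increasing
    every update.  Stops when the relative residual change over a sweep falls
    below ``tol`` or after ``max_iter`` sweeps.
    """
    tile_ids = list(tile_ids)
    if anchor_tile not in tile_ids:
        raise ValueError(f"anchor tile {anchor_tile!r} not among tiles")
    comps = _connected_components(tile_ids, correspondences)
    if len(comps) > 1:
        raise ValueError(
            "correspondence graph is disconnected; components: "
            + "; ".join(",".join(sorted(c)) for c in comps)
        )

    index = {t: k for k, t in enumerate(tile_ids)}
    T = len(tile_ids)
    angles = np.zeros(T)
    trans = np.zeros((T, 2))
    for t in tile_ids:
        if initial and t in initial:
            angles[index[t]] = initial[t].angle
            trans[index[t]] = initial[t].translation

    n = len(correspondences)
    ia = np.array([index[c.tile_a] for c in correspondences], dtype=int)
    ib = np.array([index[c.tile_b] for c in correspondences], dtype=int)
    pa = np.array([c.point_a for c in correspondences], dtype=float).reshape(n, 2)
    pb = np.array([c.point_b for c in correspondences], dtype=float).reshape(n, 2)
    wts = np.array([c.weight for c in correspondences], dtype=float)
    wsum_all = wts.sum()

    # Per-tile gather: local points, partner tile index, partner local points
    own_pts: List[np.ndarray] = []
    partner_idx: List[np.ndarray] = []
    partner_pts: List[np.ndarray] = []
    tile_w: List[np.ndarray] = []
    for k in range(T):
        ma, mb = ia == k, ib == k
        own_pts.append(np.concatenate([pa[ma], pb[mb]]))
        partner_idx.append(np.concatenate([ib[ma], ia[mb]]))
        partner_pts.append(np.concatenate([pb[ma], pa[mb]]))
        tile_w.append(np.concatenate([wts[ma], wts[mb]]))

    def residual() -> float:
        if wsum_all == 0:
            return 0.0
        wa = _rot_apply(pa, angles[ia], trans[ia])
        wb = _rot_apply(pb, angles[ib], trans[ib])
        return float(np.sum(wts * np.sum((wa - wb) ** 2, axis=1)) / wsum_all)

    anchor_k = index[anchor_tile]
    history = [residual()]

    # Guarded global Gauss-Newton steps give fast convergence on large
    # grids; each step is accepted only if it does not increase the
    # residual (backtracking line search), so the history stays monotone.
    # Gauss-Seidel sweeps below then polish to the requested tolerance.
    free = np.array([k for k in range(T) if k != anchor_k], dtype=int)
    col = {k: 3 * j for j, k in enumerate(free)}
    for _ in range(12):
        ca, sa = np.cos(angles[ia]), np.sin(angles[ia])
        cb, sb = np.cos(angles[ib]), np.sin(angles[ib])
        wa = _rot_apply(pa, angles[ia], trans[ia])
        wb = _rot_apply(pb, angles[ib], trans[ib])
        r_vec = (wa - wb)  # (n, 2)
        sw = np.sqrt(wts)
        J = np.zeros((2 * n, 3 * len(free)))
        # d(R(theta) p)/dtheta = (-s x - c y, c x - s y)
        da = np.stack([-sa * pa[:, 0] - ca * pa[:, 1], ca * pa[:, 0] - sa * pa[:, 1]], axis=1)
        db = np.stack([-sb * pb[:, 0] - cb * pb[:, 1], cb * pb[:, 0] - sb * pb[:, 1]], axis=1)
        col_of = np.full(T, -1, dtype=int)
        for k in free:
            col_of[k] = col[k]
        rows = np.arange(n)
        for sign, idx_arr, dmat in ((1.0, ia, da), (-1.0, ib, db)):
            cols = col_of[idx_arr]
            m = cols >= 0
            rj, cj = rows[m], cols[m]
            np.add.at(J, (2 * rj, cj), sign * sw[m] * dmat[m, 0])
            np.add.at(J, (2 * rj + 1, cj), sign * sw[m] * dmat[m, 1])
            np.add.at(J, (2 * rj, cj + 1), sign * sw[m])
            np.add.at(J, (2 * rj + 1, cj + 2), sign * sw[m])
        rw = (r_vec * sw[:, None]).ravel()
        try:
            step, *_ = np.linalg.lstsq(J, -rw, rcond=None)
        except np.linalg.LinAlgError:
            break
        base = history[-1]
        scale = 1.0
        improved = False
        for _bt in range(12):
            a_try = angles.copy()
            t_try = trans.copy()
            for k in free:
                c0 = col[k]
                a_try[k] += scale * step[c0]
                t_try[k] += scale * step[c0 + 1 : c0 + 3]
            angles_bak, trans_bak = angles, trans
            angles, trans = a_try, t_try
            r_new = residual()
            if r_new <= base:
                improved = True
                break
            angles, trans = angles_bak, trans_bak
            scale *= 0.5
        if not improved:
            break
        history.append(r_new)
        if r_new <= atol or abs(base - r_new) <= tol * max(base, atol):
            break

    it = 0
    for it in range(1, max_iter + 1):
        for k in range(T):
            if k == anchor_k or own_pts[k].size == 0 or tile_w[k].sum() == 0:
                continue
            dst = _rot_apply(partner_pts[k], angles[partner_idx[k]], trans[partner_idx[k]])
            fit = _fit_rigid_weighted(own_pts[k], dst, tile_w[k])
            angles[k] = fit.angle
            trans[k] = fit.translation
        r = residual()
        history.append(r)
        prev = history[-2]
        if r <= atol or abs(prev - r) <= tol * max(prev, atol):
            break
    transforms = {
        t: RigidTransform2D(float(angles[index[t]]), trans[index[t]].copy()) for t in tile_ids
    }
    return MontageSolution(
        transforms=transforms, residual=history[-1], iterations=it, residual_history=history
    )


# ---------------------------------------------------------------------------
# Lens-distortion estimation


def estimate_lens_distortion(
    correspondences: Sequence[Correspondence],
    center,
    degree: int = 2,
    n_outer: int = 100,
    tol: float = 1e-12,
) -> PolynomialDistortion2D:
    """Estimate the polynomial lens correction from overlapping placements.

    ``correspondences`` link heavily overlapping placements of the same scene
    (tile ids identify placements).  Alternates between (a) estimating one
    rigid transform per placement from the currently corrected points, and
    (b) a linear least-squares fit of the shared polynomial coefficients
    that makes corrected correspondences mutually consistent under those
    rigids.  The correction is identity-constrained at ``center``.

    Raises ``ValueError`` when degree < 2 or the design matrix is
    rank-deficient (too few / degenerate correspondences).
    """
    if degree < 2:
        raise ValueError("polynomial degree must be >= 2")
    center = np.asarray(center, dtype=float).reshape(2)
    ids = sorted({c.tile_a for c in correspondences} | {c.tile_b for c in correspondences})
    if not ids:
        raise ValueError("no correspondences given")
    anchor = ids[0]
    m = n_poly_terms(degree)
    coef = np.zeros(2 * m)

    pa_all = np.array([c.point_a for c in correspondences], dtype=float)
    pb_all = np.array([c.point_b for c in correspondences], dtype=float)
    Ba = _poly_basis(pa_all - center, degree)
    Bb = _poly_basis(pb_all - center, degree)

    for _ in range(n_outer):
        corr = PolynomialDistortion2D(degree, coef[:m], coef[m:], center)
        ca_pts = corr.apply(pa_all)
        cb_pts = corr.apply(pb_all)
        corrected = [
            Correspondence(c.tile_a, c.tile_b, (a[0], a[1]), (b[0], b[1]), c.weight)
            for c, a, b in zip(correspondences, ca_pts, cb_pts)
        ]
        sol = solve_montage(ids, corrected, anchor)
        # Linear system in the 2m polynomial coefficients
        n = len(correspondences)
        A = np.zeros((2 * n, 2 * m))
        rhs = np.zeros(2 * n)
        for k, c in enumerate(correspondences):
            Ra = sol.transforms[c.tile_a]
            Rb = sol.transforms[c.tile_b]
            ca, sa = np.cos(Ra.angle), np.sin(Ra.angle)
            cb, sb = np.cos(Rb.angle), np.sin(Rb.angle)
            base = Ra.apply(pa_all[k]) - Rb.apply(pb_all[k])
            rhs[2 * k : 2 * k + 2] = -base
            # x-residual row: + (ca*Nx(pa) - sa*Ny(pa)) - (cb*Nx(pb) - sb*Ny(pb))
            A[2 * k, :m] = ca * Ba[k] - cb * Bb[k]
            A[2 * k, m:] = -sa * Ba[k] + sb * Bb[k]
            # y-residual row
            A[2 * k + 1, :m] = sa * Ba[k] - sb * Bb[k]
            A[2 * k + 1, m:] = ca * Ba[k] - cb * Bb[k]
        new_coef, _, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
        if rank < 2 * m:
            raise ValueError(
                f"rank-deficient lens design matrix (rank {rank} < {2 * m}): "
                "correspondences too few or degenerate (e.g. collinear)"
            )
        if np.max(np.abs(new_coef - coef)) < tol:
            coef = new_coef
            break
        coef = new_coef
    return PolynomialDistortion2D(degree, coef[:m], coef[m:], center)


# ---------------------------------------------------------------------------
# Mipmaps


def build_mipmaps(image: np.ndarray) -> List[np.ndarray]:
    """Multiresolution pyramid by 2x2 mean downsampling.

    Level 0 is the input; each level halves both dimensions (ceil for odd
    sizes, the trailing block averaging the available pixels); the pyramid
    ends at 1x1.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2D array")
    levels = [img]
    while levels[-1].shape != (1, 1):
        cur = levels[-1]
        h, w = cur.shape
        if h % 2:
            cur = np.concatenate([cur, cur[-1:, :]], axis=0)
        if w % 2:
            cur = np.concatenate([cur, cur[:, -1:]], axis=1)
        nh, nw = cur.shape[0] // 2, cur.shape[1] // 2
        levels.append(cur.reshape(nh, 2, nw, 2).mean(axis=(1, 3)))
    return levels


# ---------------------------------------------------------------------------
# Rendering


def render_section(
    images: Dict[str, np.ndarray],
    transforms: Dict[str, RigidTransform2D],
    canvas_shape: Tuple[int, int],
    canvas_origin: Tuple[float, float] = (0.0, 0.0),
    section_warp: Optional[MLSWarp2D] = None,
    lens_correction: Optional[PolynomialDistortion2D] = None,
    blend: str = "feather",
) -> np.ndarray:
    """Composite the tiles of one section into a single raster.

    Each tile is pushed through lens correction, its rigid transform and the
    section warp; compositing uses inverse mapping with bilinear sampling.
    ``blend`` is ``"feather"`` (distance-to-edge weighted mean, the default)
    or ``"last"`` (last writer wins).  Output shape equals ``canvas_shape``
    (rows, cols) exactly.
    """
    from scipy.ndimage import map_coordinates

    if blend not in ("feather", "last"):
        raise ValueError(f"unknown blend mode {blend!r}")
    H, W = canvas_shape
    ox, oy = canvas_origin
    acc = np.zeros((H, W))
    wacc = np.zeros((H, W))
    out_last = np.zeros((H, W))
    inv_warp = section_warp.inverse_warp() if section_warp is not None else None

    for tile_id, img in images.items():
        if img is None:
            raise ValueError(f"missing image for tile {tile_id!r}")
        img = np.asarray(img, dtype=float)
        h, w = img.shape
        if tile_id not in transforms:
            raise ValueError(f"no transform for tile {tile_id!r}")
        T = transforms[tile_id]

        # Forward-map tile corners to bound the canvas region to fill
        corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], dtype=float)
        if lens_correction is not None:
            corners = lens_correction.apply(corners)
        corners = T.apply(corners)
        if section_warp is not None:
            corners = section_warp.apply(corners)
        margin = 3.0
        x0 = max(0, int(np.floor(corners[:, 0].min() - ox - margin)))
        x1 = min(W, int(np.ceil(corners[:, 0].max() - ox + margin)) + 1)
        y0 = max(0, int(np.floor(corners[:, 1].min() - oy - margin)))
        y1 = min(H, int(np.ceil(corners[:, 1].max() - oy + margin)) + 1)
        if x0 >= x1 or y0 >= y1:
            continue

        gx, gy = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
        pts = np.stack([gx.ravel() + ox, gy.ravel() + oy], axis=1).astype(float)
        if inv_warp is not None:
            pts = inv_warp.apply(pts)
        pts = T.inverse().apply(pts)
        if lens_correction is not None:
            pts = lens_correction.inverse_apply(pts)

        inside = (
            (pts[:, 0] >= 0) & (pts[:, 0] <= w - 1) & (pts[:, 1] >= 0) & (pts[:, 1] <= h - 1)
        )
        if not inside.any():
            continue
        sample = np.zeros(pts.shape[0])
        sample[inside] = map_coordinates(
            img, [pts[inside, 1], pts[inside, 0]], order=1, mode="nearest"
        )
        if blend == "feather":
            wt = np.zeros(pts.shape[0])
            wt[inside] = 1.0 + np.minimum(
                np.minimum(pts[inside, 0], w - 1 - pts[inside, 0]),
                np.minimum(pts[inside, 1], h - 1 - pts[inside, 1]),
            )
            acc[y0:y1, x0:x1] += (sample * wt).reshape(y1 - y0, x1 - x0)
            wacc[y0:y1, x0:x1] += wt.reshape(y1 - y0, x1 - x0)
        else:
            mask = inside.reshape(y1 - y0, x1 - x0)
            block = out_last[y0:y1, x0:x1]
            block[mask] = sample.reshape(y1 - y0, x1 - x0)[mask]
            wacc[y0:y1, x0:x1] += mask

    if blend == "feather":
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(wacc > 0, acc / np.where(wacc > 0, wacc, 1.0), 0.0)
        return out
    return out_last
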