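"""Cross-modal (confocal → TEM) registration, reslicing, overlap scoring.

No unsupervised algorithm can recognise the same structures in both TEM and
confocal images, so registration is driven by user-picked fiduciary marks
(e.g. intersections of axon fascicles) common to both stacks.  From the
fiducial pairs a non-linear transformation is estimated with the
Moving-Least-Squares method over local 3D affine models; the confocal volume
is then resliced at a TEM section plane as a thin slab (default 50 nm) and
the resulting profiles are compared to TEM-derived profiles with simple
overlap fractions.

All physical coordinates here are micrometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "FiducialSet",
    "MLSAffine3D",
    "ResliceSpec",
    "fit_mls_affine3d",
    "reslice",
    "profile_overlap",
]


@dataclass
class FiducialSet:
    """Paired 3D landmarks (source µm, target µm) with unique labels."""

    source: np.ndarray  # (n, 3)
    target: np.ndarray  # (n, 3)
    labels: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.source = np.atleast_2d(np.asarray(self.source, dtype=float))
        self.target = np.atleast_2d(np.asarray(self.target, dtype=float))
        if self.source.shape != self.target.shape or self.source.shape[1] != 3:
            raise ValueError("source/target must be matching (n, 3) arrays")
        if not self.labels:
            self.labels = tuple(f"f{i}" for i in range(len(self.source)))
        if len(self.labels) != len(self.source):
            raise ValueError("one label per fiducial pair required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("fiducial labels must be unique")

    def __len__(self) -> int:
        return len(self.source)


def _coplanar(points: np.ndarray, tol: float = 1e-9) -> bool:
    if len(points) < 4:
        return True
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s[-1] <= tol * max(1.0, s[0])


@dataclass
class MLSAffine3D:
    """MLS deformation with local 3D affine models, exact at the controls."""

    control: np.ndarray
    target: np.ndarray
    alpha: float = 1.0

    def __post_init__(self) -> None:
        self.control = np.atleast_2d(np.asarray(self.control, dtype=float))
        self.target = np.atleast_2d(np.asarray(self.target, dtype=float))
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")

    def apply(self, points) -> np.ndarray:
        v = np.atleast_2d(np.asarray(points, dtype=float))
        p, q = self.control, self.target
        out = np.empty_like(v)
        d2 = np.sum((v[:, None, :] - p[None, :, :]) ** 2, axis=2)
        coincident = d2 < 1e-24
        hit = coincident.any(axis=1)
        if hit.any():
            out[hit] = q[np.argmax(coincident[hit], axis=1)]
        free = ~hit
        if free.any():
            vf = v[free]
            w = 1.0 / d2[free] ** self.alpha
            wsum = w.sum(axis=1, keepdims=True)
            pstar = (w @ p) / wsum
            qstar = (w @ q) / wsum
            phat = p[None, :, :] - pstar[:, None, :]
            qhat = q[None, :, :] - qstar[:, None, :]
            A = np.einsum("mc,mci,mcj->mij", w, phat, phat)
            B = np.einsum("mc,mci,mcj->mij", w, phat, qhat)
            res = np.empty_like(vf)
            dets = np.abs(np.linalg.det(A))
            ok = dets > 1e-24 * np.maximum(1.0, np.einsum("mii->m", A)) ** 3
            if ok.any():
                M = np.linalg.solve(A[ok], B[ok])
                res[ok] = np.einsum("mi,mij->mj", vf[ok] - pstar[ok], M)
            for k in np.nonzero(~ok)[0]:
                M, *_ = np.linalg.lstsq(A[k], B[k], rcond=None)
                res[k] = (vf[k] - pstar[k]) @ M
            out[free] = res + qstar
        return out if np.ndim(points) > 1 else out[0]

    __call__ = apply

    def inverse_transform(self) -> "MLSAffine3D":
        """Approximate inverse (controls and targets swapped)."""
        return MLSAffine3D(self.target, self.control, alpha=self.alpha)


def fit_mls_affine3d(fiducials: FiducialSet, alpha: float = 1.0) -> MLSAffine3D:
    """Fit the MLS 3D-affine transform from fiducial pairs.

    Requires at least 4 non-coplanar control points so the local affine
    model is well posed.
    """
    if len(fiducials) < 4:
        raise ValueError("at least 4 fiducial pairs required")
    if _coplanar(fiducials.source):
        raise ValueError("fiducial source points are coplanar; 3D affine ill-posed")
    return MLSAffine3D(fiducials.source, fiducials.target, alpha=alpha)


@dataclass
class ResliceSpec:
    """Output plane description for reslicing the confocal volume.

    The output grid lies in the TEM section plane ``z = section_index *
    section_thickness_nm / 1000`` µm; intensities are averaged over a slab of
    ``slab_thickness_nm`` (50 nm by default) using ``n_subplanes`` uniformly
    spaced sample planes.
    """

    section_index: int
    slab_thickness_nm: float = 50.0
    section_thickness_nm: float = 60.0
    grid_shape: Tuple[int, int] = (64, 64)  # (rows, cols)
    pixel_size_um: float = 0.1
    origin_um: Tuple[float, float] = (0.0, 0.0)
    n_subplanes: int = 5

    def __post_init__(self) -> None:
        if self.slab_thickness_nm <= 0:
            raise ValueError("slab thickness must be > 0")
        if self.n_subplanes < 1:
            raise ValueError("n_subplanes must be >= 1")


def reslice(
    confocal_stack: np.ndarray,
    voxel_size_um: Tuple[float, float, float],
    transform: Optional[MLSAffine3D],
    spec: ResliceSpec,
) -> Tuple[np.ndarray, np.ndarray]:
    """Reslice the confocal volume at a TEM section plane.

    Parameters
    ----------
    confocal_stack : (nz, ny, nx) array
        Confocal intensities; axis order z, y, x.
    voxel_size_um : (dz, dy, dx)
        Physical voxel size in µm.
    transform : MLSAffine3D or None
        Maps TEM µm coordinates into confocal µm coordinates (the pull-back
        direction used for sampling).  ``None`` means identity.  A transform
        fit in the confocal→TEM direction can be inverted approximately with
        :meth:`MLSAffine3D.inverse_transform`.
    spec : ResliceSpec
        Output plane and slab description.

    Returns
    -------
    image : (rows, cols) float array — slab-averaged trilinear samples.
    valid : (rows, cols) bool array — False where every sub-plane sample fell
        outside the confocal volume (those pixels are zero).  If the whole
        slab lies outside the volume a warning is emitted.
    """
    from scipy.ndimage import map_coordinates

    vol = np.asarray(confocal_stack, dtype=float)
    dz, dy, dx = voxel_size_um
    rows, cols = spec.grid_shape
    z_um = spec.section_index * spec.section_thickness_nm / 1000.0
    half = spec.slab_thickness_nm / 2000.0  # nm -> µm, half-thickness
    if spec.n_subplanes == 1:
        offsets = np.array([0.0])
    else:
        offsets = np.linspace(-half, half, spec.n_subplanes)

    gx, gy = np.meshgrid(np.arange(cols), np.arange(rows))
    px = spec.origin_um[0] + gx.ravel() * spec.pixel_size_um
    py = spec.origin_um[1] + gy.ravel() * spec.pixel_size_um

    acc = np.zeros(rows * cols)
    cnt = np.zeros(rows * cols)
    for off in offsets:
        pts = np.stack([px, py, np.full_like(px, z_um + off)], axis=1)
        if transform is not None:
            pts = transform.apply(pts)
        # µm -> voxel index (x/dx, y/dy, z/dz); sample in (z, y, x) order
        ix, iy, iz = pts[:, 0] / dx, pts[:, 1] / dy, pts[:, 2] / dz
        inside = (
            (ix >= 0) & (ix <= vol.shape[2] - 1)
            & (iy >= 0) & (iy <= vol.shape[1] - 1)
            & (iz >= 0) & (iz <= vol.shape[0] - 1)
        )
        if inside.any():
            vals = map_coordinates(
                vol, [iz[inside], iy[inside], ix[inside]], order=1, mode="nearest"
            )
            acc[inside] += vals
            cnt[inside] += 1
    valid = cnt > 0
    if not valid.any():
        warnings.warn("reslice slab lies entirely outside the confocal volume")
    img = np.where(valid, acc / np.where(valid, cnt, 1), 0.0)
    return img.reshape(rows, cols), valid.reshape(rows, cols)


def profile_overlap(mask_a: np.ndarray, mask_b: np.ndarray) -> Dict[str, float]:
    """Overlap report between two binary profiles on a common grid.

    Returns ``fraction_a_in_b`` (|A∩B|/|A|), ``fraction_b_in_a`` (|A∩B|/|B|)
    and ``dice`` (2|A∩B|/(|A|+|B|)).  A fraction with an empty denominator is
    reported as NaN (missing).
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a common pixel grid")
    inter = float(np.count_nonzero(a & b))
    na, nb = float(np.count_nonzero(a)), float(np.count_nonzero(b))
    return {
        "fraction_a_in_b": inter / na if na else float("nan"),
        "fraction_b_in_a": inter / nb if nb else float("nan"),
        "dice": 2.0 * inter / (na + nb) if (na + nb) else float("nan"),
    }
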