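"""Essential dynamics: PCA of ensembles, convergence and hinge geometry.

Collective motions are obtained by diagonalizing the covariance matrix of
Cα positions after best-fit superposition of every conformer onto the
reference structure.  Subspace convergence between ensemble subsets is
measured by the root-mean-square inner product (RMSIP) of the leading
modes.  Hinge descriptors reduce an interface to two β-sheet long axes and
report per-conformer tilt / twist / bend angles relative to the reference
interface frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from dynevo.ensemble import Ensemble, superpose_ensemble


@dataclass
class PCResult:
    """Principal components of an ensemble's Cα coordinates.

    eigenvalues are descending and non-negative (nm²); eigenvectors are the
    orthonormal 3N-dimensional modes stored as columns; fractions are
    eigenvalue / total variance (summing to 1 over all 3N directions, the
    tail beyond the stored modes carried by ``total_variance``).
    """

    eigenvalues: np.ndarray      # (K,)
    eigenvectors: np.ndarray     # (3N, K), columns are modes
    fractions: np.ndarray        # (K,)
    mean: np.ndarray             # (3N,)
    total_variance: float

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "eigenvalue_nm2": self.eigenvalues,
                "fraction": self.fractions,
                "cumulative": np.cumsum(self.fractions),
            },
            index=pd.RangeIndex(1, self.n_modes + 1, name="pc"),
        )


@dataclass
class HingeSeries:
    """Per-conformer interface angles (degrees), zero at the reference."""

    tilt: np.ndarray
    twist: np.ndarray
    bend: np.ndarray
    degenerate: np.ndarray  # bool per conformer: collinear axis set

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tilt": self.tilt, "twist": self.twist, "bend": self.bend}
        )


def pca(e: Ensemble) -> PCResult:
    """PCA of the Cα coordinate covariance after reference superposition.

    Deterministic up to sign; the sign convention makes each mode's
    largest-magnitude component positive.  A zero-variance ensemble yields
    all-zero eigenvalues without error.
    """
    if e.m < 2:
        raise ValueError("need at least 2 conformers")
    fitted = superpose_ensemble(e).reshape(e.m, -1)
    mean = fitted.mean(axis=0)
    x = fitted - mean
    # economical SVD: eigenvalues of cov = s² / (M-1)
    _, svals, vt = np.linalg.svd(x, full_matrices=False)
    lam = svals**2 / (e.m - 1)
    vecs = vt.T
    # sign convention
    for k in range(vecs.shape[1]):
        imax = np.argmax(np.abs(vecs[:, k]))
        if vecs[imax, k] < 0:
            vecs[:, k] = -vecs[:, k]
    total = float(lam.sum())
    fractions = lam / total if total > 0 else np.zeros_like(lam)
    return PCResult(
        eigenvalues=lam,
        eigenvectors=vecs,
        fractions=fractions,
        mean=mean,
        total_variance=total,
    )


def project_onto_modes(e: Ensemble, pc: PCResult, k: int = 3) -> np.ndarray:
    """(M, k) projections of the superposed ensemble onto the top *k* modes."""
    fitted = superpose_ensemble(e).reshape(e.m, -1)
    return (fitted - pc.mean) @ pc.eigenvectors[:, :k]


def subspace_overlap(a: PCResult, b: PCResult, k: int = 10) -> float:
    """RMSIP between the top *k* modes of two PCA results, in [0, 1]."""
    if k <= 0:
        raise ValueError("k must be positive")
    if a.eigenvectors.shape[0] != b.eigenvectors.shape[0]:
        raise ValueError("mode dimensionality mismatch")
    if k > a.n_modes or k > b.n_modes:
        raise ValueError("k exceeds available modes")
    inner = a.eigenvectors[:, :k].T @ b.eigenvectors[:, :k]
    return float(np.sqrt(np.sum(inner**2) / k))


def _long_axis(coords: np.ndarray, ref_axis: np.ndarray | None = None) -> tuple[np.ndarray, bool]:
    """Unit inertial long axis of a residue set; sign fixed toward ref_axis.

    Returns (axis, degenerate) where degenerate flags near-isotropic sets.
    """
    x = coords - coords.mean(axis=0)
    cov = x.T @ x
    w, v = np.linalg.eigh(cov)
    axis = v[:, -1]
    degenerate = bool(w[-1] < 1e-12 or (w[-2] / max(w[-1], 1e-30)) > 0.999)
    if ref_axis is not None and axis @ ref_axis < 0:
        axis = -axis
    return axis, degenerate


def hinge_descriptors(
    e: Ensemble,
    axes: tuple[Sequence[int], Sequence[int]],
) -> HingeSeries:
    """Tilt / twist / bend series for an interface defined by two axis sets.

    Each axis set (residue indices, ≥ 2 each) defines a β-sheet long axis
    via its inertial tensor.  The reference conformer (topology) defines
    the frame: e1 = reference axis of set B, e3 = interface normal
    (normalized cross product of the two reference axes), e2 = e3 × e1.
    Per conformer, with set-B axis components (c1, c2, c3) in this frame:

    * twist = in-plane rotation about the interface normal, atan2(c2, c1);
    * bend  = out-of-plane elevation toward the normal, asin(c3);
    * tilt  = change of the inter-axis angle between sets A and B.

    All angles in degrees, zero at the reference.
    """
    set_a, set_b = (np.asarray(list(a), int) for a in axes)
    if set_a.size < 2 or set_b.size < 2:
        raise ValueError("each axis set needs at least 2 residues")
    ref = e.topology.coords
    ua0, dega = _long_axis(ref[set_a])
    ub0, degb = _long_axis(ref[set_b])
    if dega or degb:
        raise ValueError("reference axis set is degenerate (collinear selection)")
    normal = np.cross(ua0, ub0)
    nn = np.linalg.norm(normal)
    e1 = ub0
    if nn > 1e-6:
        e3 = normal / nn
    else:
        # parallel axes (e.g. stacked helices): take the interface normal
        # perpendicular to the B axis and the inter-set displacement
        disp = ref[set_a].mean(axis=0) - ref[set_b].mean(axis=0)
        disp = disp - (disp @ e1) * e1
        dn = np.linalg.norm(disp)
        if dn < 1e-9:
            raise ValueError("degenerate interface frame: parallel axes and "
                             "collinear centroids")
        e3 = np.cross(e1, disp / dn)
    e2 = np.cross(e3, e1)
    ref_angle = np.arccos(np.clip(ua0 @ ub0, -1, 1))

    # anchor each conformer on set A so the angles report the motion of
    # set B relative to set A (and are invariant to global rigid motion)
    from dynevo.ensemble import kabsch

    m = e.m
    tilt = np.zeros(m)
    twist = np.zeros(m)
    bend = np.zeros(m)
    degen = np.zeros(m, dtype=bool)
    for kk in range(m):
        rot, trans, _ = kabsch(ref[set_a], e.coords[kk, set_a])
        conf = e.coords[kk] @ rot.T + trans
        ua, da = _long_axis(conf[set_a], ua0)
        ub, db = _long_axis(conf[set_b], ub0)
        degen[kk] = da or db
        c1, c2, c3 = ub @ e1, ub @ e2, ub @ e3
        twist[kk] = np.degrees(np.arctan2(c2, c1))
        bend[kk] = np.degrees(np.arcsin(np.clip(c3, -1, 1)))
        tilt[kk] = np.degrees(np.arccos(np.clip(ua @ ub, -1, 1)) - ref_angle)
    return HingeSeries(tilt=tilt, twist=twist, bend=bend, degenerate=degen)


def project(e: Ensemble, pc: PCResult, h: HingeSeries, n_pcs: int = 3) -> pd.DataFrame:
    """Pearson correlation of PC projections with hinge angle series.

    Zero-variance series yield NaN (reported as missing, not an error).
    """
    proj = project_onto_modes(e, pc, k=n_pcs)
    series = {"tilt": h.tilt, "twist": h.twist, "bend": h.bend}
    if proj.shape[0] != h.tilt.shape[0]:
        raise ValueError("conformer count mismatch between ensemble and hinge series")
    rows = {}
    for name, y in series.items():
        sy = y.std()
        vals = []
        for k in range(n_pcs):
            x = proj[:, k]
            sx = x.std()
            if sx == 0 or sy == 0:
                vals.append(np.nan)
            else:
                vals.append(float(np.corrcoef(x, y)[0, 1]))
        rows[name] = vals
    return pd.DataFrame(rows, index=[f"PC{k + 1}" for k in range(n_pcs)]).T
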