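"""Helical screw operators on coordinate models.

A helical filament is generated by a screw operator: a rotation (twist, in
degrees, right-handed positive about the axis direction) combined with a
translation (rise, in Å) along the same axis.  The thread filament is
left-handed: consecutive subunits are related by a twist of −103.234° and a
rise of 31.649 Å, and the dominant symmetry peak seen in a coarse search
window of 80–120 Å rise corresponds to the 3-fold composition of that
operator (rise ≈ 94.95 Å), not to the minimal generator itself.

This module estimates the operator from pairs of chains (Kabsch
superposition followed by screw decomposition), composes and applies
operators, scores candidate operators by coordinate self-match, and reduces
a composite symmetry peak to the minimal per-subunit generator.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .io import Atom, Chain, Residue, StructureModel, logger


def wrap_angle(deg: float) -> float:
    """Wrap an angle into (−180, 180]."""
    w = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if w == -180.0 else w


@dataclass
class HelicalOperator:
    """Screw transform relating consecutive subunits.

    twist is in degrees, positive = right-handed about the axis direction;
    rise is in Å along the axis direction.
    """

    twist: float
    rise: float
    axis_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_dir: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.axis_point = np.asarray(self.axis_point, dtype=float)
        d = np.asarray(self.axis_dir, dtype=float)
        norm = np.linalg.norm(d)
        if not np.isfinite(norm) or norm == 0:
            raise ValueError("axis direction must be a nonzero vector")
        self.axis_dir = d / norm
        if not -180.0 < self.twist <= 180.0:
            self.twist = wrap_angle(self.twist)
        if not np.isfinite(self.rise):
            raise ValueError("rise must be finite")

    def matrix(self, k: int = 1) -> tuple[np.ndarray, np.ndarray]:
        """Rotation matrix and translation of the k-fold composition."""
        rot = Rotation.from_rotvec(np.deg2rad(k * self.twist) * self.axis_dir).as_matrix()
        trans = self.axis_point - rot @ self.axis_point + k * self.rise * self.axis_dir
        return rot, trans

    def transform(self, xyz: np.ndarray, k: int = 1) -> np.ndarray:
        rot, trans = self.matrix(k)
        return xyz @ rot.T + trans


@dataclass
class SymmetryPeak:
    operator: HelicalOperator
    score: float  # mean per-atom self-match distance, Å
    rank: int


# ---------------------------------------------------------------------------
# Operator estimation


def _paired_coords(chain_a: Chain, chain_b: Chain) -> tuple[np.ndarray, np.ndarray]:
    index_b = {
        (r.seq_position, a.name): a.xyz for r in chain_b.residues if not r.hetero for a in r.atoms
    }
    pa, pb = [], []
    for r in chain_a.residues:
        if r.hetero:
            continue
        for a in r.atoms:
            xyz_b = index_b.get((r.seq_position, a.name))
            if xyz_b is not None:
                pa.append(a.xyz)
                pb.append(xyz_b)
    if len(pa) < 3:
        raise ValueError(
            f"chains {chain_a.chain_id} and {chain_b.chain_id} share fewer than 3 atoms"
        )
    return np.array(pa), np.array(pb)


def estimate_operator(
    model: StructureModel,
    chain_a: str,
    chain_b: str,
    rmsd_warn: float = 5.0,
) -> HelicalOperator:
    """Estimate the screw operator mapping chain_a onto chain_b.

    Least-squares (Kabsch) superposition of the shared (seq_position, atom)
    subset, then decomposition of the rigid transform into rotation about and
    translation along the screw axis.  The axis direction is oriented so that
    the rise is non-negative; the twist sign follows from that choice.
    """
    a, b = _paired_coords(model.chain(chain_a), model.chain(chain_b))
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    rot_obj, rssd = Rotation.align_vectors(b - cb, a - ca)
    rmsd = rssd / np.sqrt(len(a))
    if rmsd > rmsd_warn:
        logger.warning(
            "superposition %s->%s RMSD %.2f Å exceeds %.1f Å; operator may be meaningless",
            chain_a, chain_b, rmsd, rmsd_warn,
        )
    rot = rot_obj.as_matrix()
    trans = cb - rot @ ca
    rotvec = rot_obj.as_rotvec()
    angle = np.linalg.norm(rotvec)
    if angle < 1e-9:
        # pure translation: twist 0, axis along the translation
        tnorm = np.linalg.norm(trans)
        if tnorm < 1e-12:
            return HelicalOperator(0.0, 0.0)
        return HelicalOperator(0.0, tnorm, axis_point=ca, axis_dir=trans / tnorm)
    axis = rotvec / angle
    twist = np.rad2deg(angle)
    rise = float(trans @ axis)
    if rise < 0:
        axis, twist, rise = -axis, -twist, -rise
    # axis point: solve (I - R) p = t_perp  (singular along the axis -> lstsq)
    t_perp = trans - rise * axis
    p, *_ = np.linalg.lstsq(np.eye(3) - rot, t_perp, rcond=None)
    return HelicalOperator(wrap_angle(twist), rise, axis_point=p, axis_dir=axis)


def compose_operator(op: HelicalOperator, k: int) -> HelicalOperator:
    """The k-fold composition: twist wrapped into (−180, 180], rise scaled."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return HelicalOperator(
        wrap_angle(k * op.twist), k * op.rise, axis_point=op.axis_point, axis_dir=op.axis_dir
    )


# ---------------------------------------------------------------------------
# Filament building


def chain_label(i: int) -> str:
    """A, B, ... Z, then AA, AB, ... (axial order)."""
    letters = string.ascii_uppercase
    if i < 26:
        return letters[i]
    return letters[i // 26 - 1] + letters[i % 26]


def apply_operator(subunit: StructureModel, op: HelicalOperator, n: int) -> StructureModel:
    """Build an n-subunit filament by repeated application of the operator.

    Chain k of the result is the (single-chain) subunit transformed k times;
    chain ids are assigned in axial order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(subunit.chains) != 1:
        raise ValueError("subunit must have exactly one chain")
    src = subunit.chains[0]
    chains = []
    for k in range(n):
        rot, trans = op.matrix(k)
        residues = [
            Residue(
                r.seq_position,
                r.name,
                [Atom(a.name, a.element, rot @ a.xyz + trans) for a in r.atoms],
                r.hetero,
            )
            for r in src.residues
        ]
        chains.append(Chain(chain_label(k), residues))
    return StructureModel(chains)


# ---------------------------------------------------------------------------
# Axis estimation and self-match scoring


def _orient(d: np.ndarray) -> np.ndarray:
    # deterministic orientation: positive z, tie-broken by x then y
    for comp in (2, 0, 1):
        if abs(d[comp]) > 1e-9:
            return -d if d[comp] < 0 else d
    return d


def axis_from_centroids(model: StructureModel) -> tuple[np.ndarray, np.ndarray]:
    """Helical axis estimated from the chain centroids.

    Consecutive-subunit centroids lie on a helix, so their second
    differences are radial (perpendicular to the axis): the axis direction
    is the null direction of the stacked second differences, and the axis
    point is an algebraic circle fit of the centroids projected onto the
    perpendicular plane.  With fewer than 4 chains (or a twist-free
    filament, where second differences vanish) the centroid principal axis
    is used instead — exact in the pure-translation case.
    """
    if len(model.chains) < 2:
        raise ValueError("need at least 2 chains to estimate an axis")
    cents = np.array([c.coords(hetero=False).mean(axis=0) for c in model.chains])
    center = cents.mean(axis=0)
    if len(cents) >= 4:
        d2 = cents[2:] - 2.0 * cents[1:-1] + cents[:-2]
        scale = np.linalg.norm(cents - center, axis=1).max()
        if np.linalg.norm(d2, axis=1).min() > 1e-6 * max(scale, 1.0):
            _, s, vt = np.linalg.svd(d2)
            mean_step = (cents[1:] - cents[:-1]).mean(axis=0)
            step_norm = np.linalg.norm(mean_step)
            # accept the null direction only when the radial plane is well
            # determined AND the mean centroid step is mostly axial (i.e. the
            # centroids actually trace a helix, not noise)
            if (
                len(s) >= 2
                and s[1] > 1e-6 * s[0]
                and step_norm > 0
                and abs(mean_step @ vt[-1]) >= 0.8 * step_norm
            ):
                d = _orient(vt[-1])
                # circle fit (Kåsa) of centroids projected onto the plane ⊥ d
                ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
                u = np.cross(ref, d)
                u /= np.linalg.norm(u)
                v = np.cross(d, u)
                rel = cents - center
                x, y = rel @ u, rel @ v
                A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
                sol, *_ = np.linalg.lstsq(A, x**2 + y**2, rcond=None)
                return center + sol[0] * u + sol[1] * v, d
    if len(cents) == 2:
        d = cents[1] - cents[0]
    else:
        _, _, vt = np.linalg.svd(cents - center)
        d = vt[0]
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        raise ValueError("chain centroids are coincident; no axis")
    return center, _orient(d / norm)


def _axis_frame(points: np.ndarray, axis_point: np.ndarray, axis_dir: np.ndarray) -> np.ndarray:
    """Coordinates in a frame whose +z is the axis direction."""
    z = axis_dir
    ref = np.array([1.0, 0.0, 0.0]) if abs(z[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    x = np.cross(ref, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return (points - axis_point) @ np.stack([x, y, z], axis=1)


def _self_match(pts_frame: np.ndarray, tree: cKDTree, zmax: float, twist: float, rise: float,
                min_fraction: float = 0.2) -> float:
    c, s = np.cos(np.deg2rad(twist)), np.sin(np.deg2rad(twist))
    q = np.empty_like(pts_frame)
    q[:, 0] = c * pts_frame[:, 0] - s * pts_frame[:, 1]
    q[:, 1] = s * pts_frame[:, 0] + c * pts_frame[:, 1]
    q[:, 2] = pts_frame[:, 2] + rise
    keep = q[:, 2] <= zmax
    if keep.sum() < min_fraction * len(q):
        return np.inf
    d, _ = tree.query(q[keep])
    return float(d.mean())


def self_match_score(
    model: StructureModel,
    op: HelicalOperator,
    atom_names: set[str] | None = None,
) -> float:
    """Mean per-atom distance between the op-transformed model and itself.

    Transformed atoms that land above the top of the model (no partner
    subunit exists there) are excluded from the mean.
    """
    atom_names = atom_names or {"CA"}
    pts = model.coords(atom_names=atom_names, hetero=False)
    frame = _axis_frame(pts, op.axis_point, op.axis_dir)
    tree = cKDTree(frame)
    return _self_match(frame, tree, frame[:, 2].max(), op.twist, op.rise)


def symmetry_search(
    model: StructureModel,
    twist_range: tuple[float, float] = (-180.0, 180.0),
    rise_range: tuple[float, float] = (80.0, 120.0),
    twist_step: float = 1.0,
    rise_step: float = 0.5,
    n_peaks: int = 5,
    atom_names: set[str] | None = None,
    refine_factor: int = 10,
    refine_axis: bool = False,
) -> list[SymmetryPeak]:
    """Grid search for screw operators that map the filament onto itself.

    Every grid candidate is scored by self-match (mean distance of each
    transformed atom to its nearest model atom); local minima are ranked
    ascending and the best peak is refined once on a ``refine_factor``-times
    finer grid.  Optionally the axis tilt is refined by minimizing the best
    peak's score over two tilt parameters.
    """
    if len(model.chains) < 2:
        raise ValueError("symmetry search needs at least 2 chains")
    atom_names = atom_names or {"CA"}
    axis_point, axis_dir = axis_from_centroids(model)
    pts = model.coords(atom_names=atom_names, hetero=False)

    def grid_scores(frame, twists, rises):
        tree = cKDTree(frame)
        zmax = frame[:, 2].max()
        scores = np.empty((len(twists), len(rises)))
        for i, tw in enumerate(twists):
            for j, rs in enumerate(rises):
                scores[i, j] = _self_match(frame, tree, zmax, tw, rs)
        return scores

    frame = _axis_frame(pts, axis_point, axis_dir)
    twists = np.arange(twist_range[0], twist_range[1], twist_step)
    rises = np.arange(rise_range[0], rise_range[1] + 1e-9, rise_step)
    scores = grid_scores(frame, twists, rises)

    # local minima on the grid (twist wraps around, rise does not)
    peaks: list[tuple[float, float, float]] = []
    nt, nr = scores.shape
    for i in range(nt):
        for j in range(nr):
            s = scores[i, j]
            if not np.isfinite(s):
                continue
            neigh = [
                scores[(i - 1) % nt, j], scores[(i + 1) % nt, j],
                scores[i, j - 1] if j > 0 else np.inf,
                scores[i, j + 1] if j < nr - 1 else np.inf,
            ]
            if all(s <= v for v in neigh):
                peaks.append((s, twists[i], rises[j]))
    peaks.sort()
    peaks = peaks[:n_peaks]
    if not peaks:
        raise ValueError("no symmetry peak found in the searched window")

    def refine(tw0, rs0, frame):
        ft = np.arange(tw0 - twist_step, tw0 + twist_step + 1e-9, twist_step / refine_factor)
        fr = np.arange(
            max(rise_range[0], rs0 - rise_step),
            min(rise_range[1], rs0 + rise_step) + 1e-9,
            rise_step / refine_factor,
        )
        sc = grid_scores(frame, ft, fr)
        i, j = np.unravel_index(np.argmin(sc), sc.shape)
        return sc[i, j], ft[i], fr[j]

    best_score, best_tw, best_rs = refine(peaks[0][1], peaks[0][2], frame)

    if refine_axis:
        def tilt_score(tilt):
            rot = Rotation.from_euler("xy", tilt, degrees=True).as_matrix()
            d = rot @ axis_dir
            fr = _axis_frame(pts, axis_point, d / np.linalg.norm(d))
            tree = cKDTree(fr)
            return _self_match(fr, tree, fr[:, 2].max(), best_tw, best_rs)

        res = minimize(tilt_score, [0.0, 0.0], method="Nelder-Mead",
                       options={"maxiter": 40, "xatol": 0.05, "fatol": 1e-4})
        rot = Rotation.from_euler("xy", res.x, degrees=True).as_matrix()
        axis_dir = rot @ axis_dir
        axis_dir /= np.linalg.norm(axis_dir)
        frame = _axis_frame(pts, axis_point, axis_dir)
        best_score, best_tw, best_rs = refine(best_tw, best_rs, frame)

    out = [SymmetryPeak(HelicalOperator(wrap_angle(best_tw), best_rs, axis_point, axis_dir),
                        best_score, 0)]
    for rank, (s, tw, rs) in enumerate(peaks[1:], start=1):
        out.append(SymmetryPeak(HelicalOperator(wrap_angle(tw), rs, axis_point, axis_dir), s, rank))
    return out


def reduce_operator(
    peak: HelicalOperator,
    model: StructureModel,
    k_max: int = 6,
    tol: float = 0.5,
    atom_names: set[str] | None = None,
) -> HelicalOperator:
    """Reduce a composite symmetry peak to the minimal per-subunit generator.

    A peak found at rise r may correspond to k repeating subunits; the
    per-subunit candidates are (twist + 360·m)/k, r/k for k = 2..k_max and
    branch m = −k..k.  Each candidate is self-match scored on the model; the
    smallest-rise candidate whose score is within ``tol`` Å of the peak's own
    score wins (ties broken by smaller |twist|).  If no candidate matches,
    the peak itself is already minimal.
    """
    peak_score = self_match_score(model, peak, atom_names)
    candidates: list[tuple[float, float, HelicalOperator]] = []
    for k in range(2, k_max + 1):
        for m in range(-k, k + 1):
            tw = (peak.twist + 360.0 * m) / k
            if not -180.0 < tw <= 180.0:
                continue
            cand = HelicalOperator(tw, peak.rise / k, peak.axis_point, peak.axis_dir)
            score = self_match_score(model, cand, atom_names)
            if score <= peak_score + tol:
                candidates.append((cand.rise, abs(cand.twist), cand))
    if not candidates:
        return peak
    candidates.sort(key=lambda c: (c[0], c[1]))
    return candidates[0][2]
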