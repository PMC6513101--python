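"""Rigid-body pose sampling, ranking, clustering and blockade filtering.

The sampler is a seeded toy generator, not an FFT docking engine: each
trial draws a uniform random orientation and approach direction, slides the
binder inward until the minimum cross heavy-atom distance equals the touch
distance (4.0 A by default, which puts interfaces inside interaction
cutoffs without steric clashes), and accepts the pose if it satisfies the
configured interface constraints.  Accepted poses are scored with the
stand-in binding energy and ranked (more negative first, ties by pose id).

Clustering is greedy leader clustering on binder C-alpha RMSD in the fixed
target frame (no re-superposition), mirroring how docking programs group
near-duplicate poses.

The blockade filter checks receptor-blockade geometry against a surrogate
receptor-ligand complex: the pose's antigen is superposed onto the
surrogate ligand through a user-supplied residue-pair mapping and the
antibody is tested for steric overlap with the receptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .interface import buried_surface
from .scoring import EnergyParams, binding_energy
from .structures import (Complex, RigidTransform, kabsch_superpose,
                         merge_complexes, transform_apply)

__all__ = [
    "DockedPose",
    "PoseConstraints",
    "PoseGenerationError",
    "generate_poses",
    "realise_pose",
    "cluster_poses",
    "blockade_filter",
]


class PoseGenerationError(RuntimeError):
    pass


@dataclass
class DockedPose:
    pose_id: int
    transform: RigidTransform
    score: float
    contact_sasa: float | None = None
    cluster: int | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("pose score must be finite")


@dataclass
class PoseConstraints:
    """Interface constraints applied during sampling.

    ``blocked_residues`` must not be interfacial (5.0 A); every residue in
    ``required_residues`` must have an atom within ``required_distance`` of
    the target.  Residue sets hold ``(chain_id, author_pos)`` pairs on the
    binder.
    """

    blocked_residues: frozenset = frozenset()
    required_residues: frozenset = frozenset()
    required_distance: float = 10.0
    touch_distance: float = 4.0
    interfacial_cutoff: float = 5.0

    def __post_init__(self) -> None:
        overlap = set(self.blocked_residues) & set(self.required_residues)
        if overlap:
            raise ValueError(f"blocked and required residues overlap: {sorted(overlap)}")


def realise_pose(binder: Complex, target: Complex,
                 transform: RigidTransform) -> Complex:
    """Materialise a docked pose as a combined binder+target complex."""
    placed = transform_apply(binder, list(binder.chains), transform)
    return merge_complexes(placed, target)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalised quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _touch_transform(binder_coords: np.ndarray, binder_centroid: np.ndarray,
                     target_tree: cKDTree, target_centroid: np.ndarray,
                     rotation: np.ndarray, direction: np.ndarray,
                     touch: float, tol: float = 1e-3) -> RigidTransform | None:
    """Place the rotated binder along ``direction`` at the touch distance.

    Returns the transform whose minimum cross heavy-atom distance equals
    ``touch`` (within ``tol``), or None when no crossing is bracketed.
    """
    rotated = (binder_coords - binder_centroid) @ rotation.T
    r_b = float(np.max(np.linalg.norm(rotated, axis=1)))
    d_t, _ = target_tree.query(target_centroid, k=1)

    def min_dist(s: float) -> float:
        pts = rotated + target_centroid + s * direction
        d, _ = target_tree.query(pts, k=1)
        return float(np.min(d))

    s_hi = r_b + float(d_t) + touch + 5.0
    while min_dist(s_hi) <= touch:
        s_hi += 5.0
    s_lo = 0.0
    if min_dist(s_lo) > touch:
        return None  # binder would have to pass through the target centre
    for _ in range(48):
        mid = 0.5 * (s_lo + s_hi)
        if min_dist(mid) > touch:
            s_hi = mid
        else:
            s_lo = mid
        if s_hi - s_lo < 1e-5:
            break
    s = 0.5 * (s_lo + s_hi)
    if abs(min_dist(s) - touch) > tol:
        return None
    translation = target_centroid + s * direction - rotation @ binder_centroid
    return RigidTransform(rotation, translation)


def generate_poses(binder: Complex, target: Complex, n: int, seed: int,
                   constraints: PoseConstraints | None = None,
                   params: EnergyParams | None = None,
                   max_trials: int | None = None,
                   with_sasa: bool = False) -> list[DockedPose]:
    """Sample ``n`` accepted rigid-body poses of ``binder`` against ``target``.

    Poses are returned sorted by score ascending (more negative = better),
    ties broken by pose id.  Raises :class:`PoseGenerationError` when the
    acceptance rate is zero after ``max_trials`` attempts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    constraints = constraints or PoseConstraints()
    params = params or EnergyParams()
    max_trials = max_trials if max_trials is not None else max(200 * n, 2000)
    rng = np.random.default_rng(seed)

    b_coords, b_refs = binder.heavy_atom_table()
    t_coords, _ = target.heavy_atom_table()
    b_centroid = b_coords.mean(axis=0)
    t_centroid = t_coords.mean(axis=0)
    t_tree = cKDTree(t_coords)

    blocked_idx = [i for i, (res, _a) in enumerate(b_refs)
                   if (res.chain_id, res.author_pos) in constraints.blocked_residues]
    required_groups = {}
    for i, (res, _a) in enumerate(b_refs):
        key = (res.chain_id, res.author_pos)
        if key in constraints.required_residues:
            required_groups.setdefault(key, []).append(i)
    missing = set(constraints.required_residues) - set(required_groups)
    if missing:
        raise KeyError(f"required residues not in binder: {sorted(missing)}")

    accepted: list[DockedPose] = []
    pose_id = 0
    for _trial in range(max_trials):
        if len(accepted) >= n:
            break
        rotation = _random_rotation(rng)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        t = _touch_transform(b_coords, b_centroid, t_tree, t_centroid,
                             rotation, direction, constraints.touch_distance)
        if t is None:
            continue
        placed = t.apply(b_coords)
        dists, _ = t_tree.query(placed, k=1)
        if float(np.min(dists)) < params.clash_distance:
            continue
        ok = True
        for key, idxs in required_groups.items():
            if float(np.min(dists[idxs])) > constraints.required_distance:
                ok = False
                break
        if ok and blocked_idx:
            if float(np.min(dists[blocked_idx])) <= constraints.interfacial_cutoff:
                ok = False
        if not ok:
            continue
        pose_cx = realise_pose(binder, target, t)
        score = binding_energy(pose_cx, params)
        sasa = buried_surface(pose_cx) if with_sasa else None
        accepted.append(DockedPose(pose_id, t, score, contact_sasa=sasa))
        pose_id += 1

    if len(accepted) < n:
        raise PoseGenerationError(
            f"only {len(accepted)}/{n} poses accepted after {max_trials} trials; "
            "consider loosening the constraints"
        )
    accepted.sort(key=lambda p: (p.score, p.pose_id))
    return accepted


def cluster_poses(poses: list[DockedPose], binder: Complex,
                  rmsd_threshold: float = 5.0) -> list[int]:
    """Greedy leader clustering on binder C-alpha RMSD (fixed target frame).

    ``poses`` must be in rank order.  Walking down the list, each pose
    joins the first leader within ``rmsd_threshold`` or founds a new
    cluster; labels are the leaders' positions in the input list.  Labels
    are also written to each pose's ``cluster`` field.
    """
    if not poses:
        return []
    ca = binder.ca_coords()
    coords = [p.transform.apply(ca) for p in poses]
    leaders: list[int] = []
    labels: list[int] = []
    for i, ci in enumerate(coords):
        assigned = None
        for lead in leaders:
            rmsd = float(np.sqrt(np.mean(np.sum((ci - coords[lead]) ** 2, axis=1))))
            if rmsd <= rmsd_threshold:
                assigned = lead
                break
        if assigned is None:
            leaders.append(i)
            assigned = i
        labels.append(assigned)
        poses[i].cluster = assigned
    return labels


def blockade_filter(poses: list[DockedPose], binder: Complex, target: Complex,
                    surrogate: Complex, antigen_to_ligand_pairs,
                    clash_count_threshold: int = 25,
                    clash_cutoff: float = 2.5) -> list[DockedPose]:
    """Flag poses whose antibody sterically blocks the receptor site.

    Each pose's antigen C-alphas are superposed onto the surrogate-ligand
    C-alphas through ``antigen_to_ligand_pairs`` (a list of
    ``(antigen_author_pos, ligand_author_pos)``); the antibody is carried
    along and antibody-receptor heavy-atom pairs closer than
    ``clash_cutoff`` are counted.  A pose is ``blocking`` when the count
    reaches ``clash_count_threshold``.
    """
    pairs = list(antigen_to_ligand_pairs)
    if len(pairs) < 3:
        raise ValueError("need at least 3 antigen-to-ligand residue pairs")
    receptor_chains = surrogate.chains_with_role("receptor")
    ligand_chains = surrogate.chains_with_role("surrogate_ligand")
    if not receptor_chains or not ligand_chains:
        raise ValueError("surrogate complex needs receptor and surrogate_ligand roles")
    if not target.target_chains:
        raise ValueError("target complex needs an antigen role")
    ant_chain = target.target_chains[0]
    lig_chain = ligand_chains[0]

    def ca_of(cx: Complex, chain: str, pos: int) -> np.ndarray:
        res = cx.get_residue(chain, pos)
        ca = res.get_atom("CA")
        if ca is None:
            raise KeyError(f"residue {chain}:{pos} lacks CA")
        return ca.position

    lig_pts = np.array([ca_of(surrogate, lig_chain, lp) for _ap, lp in pairs])
    rec_coords, _ = surrogate.heavy_atom_table(receptor_chains)
    rec_tree = cKDTree(rec_coords)

    out = []
    for pose in poses:
        pose_cx = realise_pose(binder, target, pose.transform)
        ant_pts = np.array([ca_of(pose_cx, ant_chain, ap) for ap, _lp in pairs])
        t, _rmsd = kabsch_superpose(ant_pts, lig_pts)
        ab_coords, _ = pose_cx.heavy_atom_table(pose_cx.binder_chains)
        moved = t.apply(ab_coords)
        n_overlap = int(rec_tree.count_neighbors(cKDTree(moved), clash_cutoff))
        flags = set(pose.flags)
        if n_overlap >= clash_count_threshold:
            flags.add("blocking")
        else:
            flags.discard("blocking")
        out.append(replace(pose, flags=flags))
    return out
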