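"""Interface analysis: SASA, buried surface, and intermolecular interactions.

Solvent-accessible surface area uses Shrake-Rupley-style sphere-point
quadrature over heavy atoms with element van der Waals radii and a
deterministic golden-section spiral point set (no random seeds involved).

Cross-interface contacts are classified geometrically into hydrogen bonds,
salt bridges, pi-cation, pi-pi and hydrophobic contacts.  The default
cutoffs are chosen so that the canonical pi-cation geometries observed in
antibody-chemokine interfaces (4.9 A at 28.5 deg, and the weaker
5.7 A at 51.5 deg) are classified as interactions; all cutoffs are
configurable through :class:`InteractionGeometry`.

Because the energy model downstream is residue-level, every kind is
reported at most once per (binder residue, target residue) pair, with the
closest qualifying geometry.  A residue pair forming a salt bridge does not
additionally emit a hydrogen bond (the nitrogen-oxygen pair would otherwise
be counted twice).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structures import Complex, Residue, subcomplex

__all__ = [
    "VDW_RADII",
    "InteractionGeometry",
    "InteractionRecord",
    "InterfaceProfile",
    "compute_sasa",
    "buried_surface",
    "interfacial_residues",
    "detect_interactions",
    "interaction_profile",
    "count_cross_clashes",
]

#: element van der Waals radii in Angstrom ("X" is the pseudo side-chain
#: centroid used by the mutation model)
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "X": 1.70,
}

APOLAR_RESIDUES = frozenset({
    "ALA", "VAL", "LEU", "ILE", "PRO", "MET", "PHE", "TRP", "CYS",
})

CATIONIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2")}
ANIONIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


@dataclass
class InteractionGeometry:
    """Geometric cutoffs for cross-interface interaction classification."""

    hbond_max: float = 3.5          # donor-heavy to acceptor-heavy, N/O pairs
    salt_bridge_max: float = 4.0    # side-chain cationic N to anionic O
    pi_cation_max: float = 6.0      # cation centroid to ring centroid
    pi_cation_angle_max: float = 60.0   # vs ring normal, degrees
    pi_pi_max: float = 5.5          # ring centroid to ring centroid
    hydrophobic_max: float = 4.5    # apolar side-chain carbon pair
    pseudo_slack: float = 1.0       # extra reach for pseudo side-chain centroids

    @property
    def max_cutoff(self) -> float:
        return max(self.hbond_max, self.salt_bridge_max, self.pi_cation_max,
                   self.pi_pi_max, self.hydrophobic_max)


@dataclass(frozen=True)
class InteractionRecord:
    kind: str                        # hbond | salt_bridge | pi_cation | pi_pi | hydrophobic
    binder_residue: tuple[str, int, str]
    target_residue: tuple[str, int, str]
    binder_label: str
    target_label: str
    distance: float
    angle: float | None = None

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("interaction distance must be positive")


@dataclass
class InterfaceProfile:
    """Per-binder-residue, per-kind interaction counts for one pose."""

    pose_id: object
    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def count_at(self, residue_label: str) -> int:
        return sum(v for (label, _kind), v in self.counts.items()
                   if label == residue_label)


# ---------------------------------------------------------------------------
# solvent-accessible surface area
# ---------------------------------------------------------------------------

def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral point set on the unit sphere."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def compute_sasa(cx: Complex, probe_radius: float = 1.4, n_points: int = 960,
                 radii: dict[str, float] | None = None) -> dict:
    """Per-residue solvent-accessible surface area in A^2 (heavy atoms).

    Shrake-Rupley-style quadrature: for each atom, points on the expanded
    sphere of radius r_vdw + probe are tested for occlusion by neighbouring
    atoms' expanded spheres.
    """
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a usable quadrature")
    radii = radii or VDW_RADII
    coords, refs = cx.heavy_atom_table()
    if len(refs) == 0:
        return {}
    atom_r = np.empty(len(refs))
    for idx, (res, atom) in enumerate(refs):
        r = radii.get(atom.element)
        if r is None:
            raise ValueError(
                f"no van der Waals radius for element {atom.element!r} "
                f"(atom {atom.name} in {res.label})"
            )
        atom_r[idx] = r
    expanded = atom_r + probe_radius
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    rmax = expanded.max()
    areas: dict = {}
    for i in range(len(refs)):
        ri = expanded[i]
        neigh = tree.query_ball_point(coords[i], ri + rmax)
        neigh = [j for j in neigh
                 if j != i and np.linalg.norm(coords[j] - coords[i]) < ri + expanded[j]]
        pts = coords[i] + unit * ri
        if neigh:
            d = np.linalg.norm(pts[:, None, :] - coords[neigh][None, :, :], axis=2)
            exposed = np.all(d >= expanded[neigh][None, :], axis=1)
            frac = float(np.count_nonzero(exposed)) / n_points
        else:
            frac = 1.0
        res = refs[i][0]
        areas[res.key] = areas.get(res.key, 0.0) + frac * 4.0 * math.pi * ri * ri
    return areas


def buried_surface(cx: Complex, probe_radius: float = 1.4,
                   n_points: int = 960) -> float:
    """Contact SASA in A^2, reported per side (half the total buried area).

    Computed as (SASA(binder alone) + SASA(target alone) - SASA(complex)) / 2
    over the binder (heavy+light) and antigen chains.
    """
    cx.require_roles()
    binder = subcomplex(cx, cx.binder_chains)
    target = subcomplex(cx, cx.target_chains)
    pair = subcomplex(cx, cx.binder_chains + cx.target_chains)
    s_b = sum(compute_sasa(binder, probe_radius, n_points).values())
    s_t = sum(compute_sasa(target, probe_radius, n_points).values())
    s_bt = sum(compute_sasa(pair, probe_radius, n_points).values())
    return (s_b + s_t - s_bt) / 2.0


def interfacial_residues(cx: Complex, cutoff: float = 5.0
                         ) -> tuple[set, set]:
    """Residue keys on each side with any heavy atom within ``cutoff``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    cx.require_roles()
    bc, brefs = cx.heavy_atom_table(cx.binder_chains)
    tc, trefs = cx.heavy_atom_table(cx.target_chains)
    if len(brefs) == 0 or len(trefs) == 0:
        return set(), set()
    pairs = cKDTree(bc).query_ball_tree(cKDTree(tc), cutoff)
    binder_set, target_set = set(), set()
    for bi, hits in enumerate(pairs):
        if hits:
            binder_set.add(brefs[bi][0].key)
            for ti in hits:
                target_set.add(trefs[ti][0].key)
    return binder_set, target_set


# ---------------------------------------------------------------------------
# interaction detection
# ---------------------------------------------------------------------------

class _Features:
    """Cached per-residue geometric features used by the classifier."""

    __slots__ = ("polar", "cationic", "cat_centroid", "anionic", "ring_centroid",
                 "ring_normal", "apolar", "pseudo_pos", "chemo")

    def __init__(self, res: Residue):
        heavy = res.heavy_atoms()
        self.polar = np.array([a.position for a in heavy
                               if not a.is_pseudo and a.element in ("N", "O")]
                              ).reshape(-1, 3)
        cat_names = CATIONIC_ATOMS.get(res.aa3, ())
        cat = [a.position for a in heavy if a.name in cat_names]
        self.cationic = np.array(cat).reshape(-1, 3)
        self.cat_centroid = self.cationic.mean(axis=0) if cat else None
        an_names = ANIONIC_ATOMS.get(res.aa3, ())
        self.anionic = np.array(
            [a.position for a in heavy if a.name in an_names or a.name == "OXT"]
        ).reshape(-1, 3)
        ring_names = RING_ATOMS.get(res.aa3, ())
        ring = [a.position for a in heavy if a.name in ring_names]
        if len(ring) >= 3:
            ring = np.asarray(ring)
            self.ring_centroid = ring.mean(axis=0)
            _, _, vt = np.linalg.svd(ring - self.ring_centroid)
            self.ring_normal = vt[2]
        else:
            self.ring_centroid = None
            self.ring_normal = None
        self.apolar = np.array(
            [a.position for a in heavy
             if not a.is_pseudo and a.element == "C" and not a.is_backbone
             and (res.aa3 in APOLAR_RESIDUES or a.name == "CB")]
        ).reshape(-1, 3)
        pseudo = [a.position for a in heavy if a.is_pseudo]
        self.pseudo_pos = pseudo[0] if pseudo else None
        self.chemo = res.pseudo_chemotypes if pseudo else frozenset()


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    if a.size == 0 or b.size == 0:
        return math.inf
    return float(np.min(np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)))


def _point_min_dist(p, b: np.ndarray) -> float:
    if p is None or b.size == 0:
        return math.inf
    return float(np.min(np.linalg.norm(b - p, axis=1)))


def _candidate_pairs(cx: Complex, cutoff: float):
    bc, brefs = cx.heavy_atom_table(cx.binder_chains)
    tc, trefs = cx.heavy_atom_table(cx.target_chains)
    if len(brefs) == 0 or len(trefs) == 0:
        return []
    hits = cKDTree(bc).query_ball_tree(cKDTree(tc), cutoff)
    seen = set()
    pairs = []
    for bi, tlist in enumerate(hits):
        for ti in tlist:
            rb, rt = brefs[bi][0], trefs[ti][0]
            k = (rb.key, rt.key)
            if k not in seen:
                seen.add(k)
                pairs.append((rb, rt))
    return pairs


def _pi_cation_geometry(cat_centroid, ring_centroid, ring_normal):
    v = cat_centroid - ring_centroid
    d = float(np.linalg.norm(v))
    if d == 0.0:
        return d, 0.0
    cosang = abs(float(np.dot(v / d, ring_normal)))
    ang = math.degrees(math.acos(min(1.0, cosang)))
    return d, ang


def detect_interactions(cx: Complex,
                        params: InteractionGeometry | None = None
                        ) -> list[InteractionRecord]:
    """Classify cross-interface contacts between binder and antigen chains.

    Residues mutated to a pseudo side-chain centroid participate through
    their chemotypes using class cutoffs widened by ``pseudo_slack``, with
    no angle test.
    """
    params = params or InteractionGeometry()
    cx.require_roles()
    prefilter = params.max_cutoff + params.pseudo_slack + 4.0
    feats: dict = {}

    def F(res: Residue) -> _Features:
        if res.key not in feats:
            feats[res.key] = _Features(res)
        return feats[res.key]

    records: list[InteractionRecord] = []
    for rb, rt in _candidate_pairs(cx, prefilter):
        fb, ft = F(rb), F(rt)
        pair_records: dict[str, InteractionRecord] = {}

        def emit(kind: str, distance: float, angle=None):
            prev = pair_records.get(kind)
            if prev is None or distance < prev.distance:
                pair_records[kind] = InteractionRecord(
                    kind, rb.key, rt.key, rb.label, rt.label,
                    round(distance, 6),
                    None if angle is None else round(angle, 3))

        # salt bridge: side-chain cationic N to anionic O
        d = min(_min_dist(fb.cationic, ft.anionic), _min_dist(fb.anionic, ft.cationic))
        if d <= params.salt_bridge_max:
            emit("salt_bridge", d)
        slack_cut = params.salt_bridge_max + params.pseudo_slack
        for p, chemo, other in ((fb.pseudo_pos, fb.chemo, ft), (ft.pseudo_pos, ft.chemo, fb)):
            if p is not None:
                if "cationic" in chemo and _point_min_dist(p, other.anionic) <= slack_cut:
                    emit("salt_bridge", _point_min_dist(p, other.anionic))
                if "anionic" in chemo and _point_min_dist(p, other.cationic) <= slack_cut:
                    emit("salt_bridge", _point_min_dist(p, other.cationic))
        if fb.pseudo_pos is not None and ft.pseudo_pos is not None:
            if (("cationic" in fb.chemo and "anionic" in ft.chemo)
                    or ("anionic" in fb.chemo and "cationic" in ft.chemo)):
                d = float(np.linalg.norm(fb.pseudo_pos - ft.pseudo_pos))
                if d <= slack_cut:
                    emit("salt_bridge", d)

        # hydrogen bond: N/O heavy-atom pairs (suppressed by a salt bridge)
        if "salt_bridge" not in pair_records:
            d = _min_dist(fb.polar, ft.polar)
            if d <= params.hbond_max:
                emit("hbond", d)
            hcut = params.hbond_max + params.pseudo_slack
            for p, chemo, other in ((fb.pseudo_pos, fb.chemo, ft),
                                    (ft.pseudo_pos, ft.chemo, fb)):
                if p is not None and "polar" in chemo:
                    dp = _point_min_dist(p, other.polar)
                    if dp <= hcut:
                        emit("hbond", dp)

        # pi-cation (both orientations)
        for cat, ring_c, ring_n in ((fb.cat_centroid, ft.ring_centroid, ft.ring_normal),
                                    (ft.cat_centroid, fb.ring_centroid, fb.ring_normal)):
            if cat is not None and ring_c is not None:
                d, ang = _pi_cation_geometry(cat, ring_c, ring_n)
                if d <= params.pi_cation_max and ang <= params.pi_cation_angle_max:
                    emit("pi_cation", d, ang)
        pcut = params.pi_cation_max + params.pseudo_slack
        for p, chemo, other in ((fb.pseudo_pos, fb.chemo, ft), (ft.pseudo_pos, ft.chemo, fb)):
            if p is None:
                continue
            if "cationic" in chemo and other.ring_centroid is not None:
                d = float(np.linalg.norm(p - other.ring_centroid))
                if d <= pcut:
                    emit("pi_cation", d)
            if "aromatic" in chemo and other.cat_centroid is not None:
                d = float(np.linalg.norm(p - other.cat_centroid))
                if d <= pcut:
                    emit("pi_cation", d)

        # pi-pi stacking
        if fb.ring_centroid is not None and ft.ring_centroid is not None:
            d = float(np.linalg.norm(fb.ring_centroid - ft.ring_centroid))
            if d <= params.pi_pi_max:
                ang = math.degrees(math.acos(min(1.0, abs(float(
                    np.dot(fb.ring_normal, ft.ring_normal))))))
                emit("pi_pi", d, ang)
        ppcut = params.pi_pi_max + params.pseudo_slack
        for p, chemo, other in ((fb.pseudo_pos, fb.chemo, ft), (ft.pseudo_pos, ft.chemo, fb)):
            if p is not None and "aromatic" in chemo and other.ring_centroid is not None:
                d = float(np.linalg.norm(p - other.ring_centroid))
                if d <= ppcut:
                    emit("pi_pi", d)

        # hydrophobic: apolar side-chain carbon pairs, once per residue pair
        d = _min_dist(fb.apolar, ft.apolar)
        if d <= params.hydrophobic_max:
            emit("hydrophobic", d)
        hycut = params.hydrophobic_max + params.pseudo_slack
        for p, chemo, other in ((fb.pseudo_pos, fb.chemo, ft), (ft.pseudo_pos, ft.chemo, fb)):
            if p is not None and "apolar" in chemo:
                dp = _point_min_dist(p, other.apolar)
                if dp <= hycut:
                    emit("hydrophobic", dp)
        if fb.pseudo_pos is not None and ft.pseudo_pos is not None \
                and "apolar" in fb.chemo and "apolar" in ft.chemo:
            d = float(np.linalg.norm(fb.pseudo_pos - ft.pseudo_pos))
            if d <= hycut:
                emit("hydrophobic", d)

        records.extend(pair_records.values())

    records.sort(key=lambda r: (r.binder_residue, r.target_residue, r.kind))
    return records


def interaction_profile(cx: Complex, pose_id: object = "pose",
                        params: InteractionGeometry | None = None
                        ) -> InterfaceProfile:
    """Aggregate :func:`detect_interactions` into per-residue, per-kind counts."""
    profile = InterfaceProfile(pose_id)
    for rec in detect_interactions(cx, params):
        key = (rec.binder_label, rec.kind)
        profile.counts[key] = profile.counts.get(key, 0) + 1
    return profile


def count_cross_clashes(cx: Complex, clash_distance: float = 2.4) -> int:
    """Number of binder-target heavy-atom pairs closer than ``clash_distance``."""
    bc, brefs = cx.heavy_atom_table(cx.binder_chains)
    tc, trefs = cx.heavy_atom_table(cx.target_chains)
    if len(brefs) == 0 or len(trefs) == 0:
        return 0
    return int(cKDTree(bc).count_neighbors(
        cKDTree(tc), clash_distance, p=2.0))
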