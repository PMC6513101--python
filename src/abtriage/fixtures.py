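"""Seeded synthetic complexes with planted interfacial interactions.

The generator emulates an antibody Fv bound to a small chemokine-like
antigen at toy scale: idealised extended chains (C-alpha spacing 3.8 A,
C-beta offset toward the interface) with full heavy-atom side-chain
templates installed only at planted positions, so the interaction ground
truth is exact by construction.  Each planted interaction (salt bridge,
H-bond, pi-cation, pi-pi or hydrophobic contact) is realised at a
specified distance (and, for pi-cation, ring-normal angle) to within
0.05 A / 2 degrees; everything else is alanine.

The built complex is itself the "true" docked pose; decoy ensembles are
produced around it with the pose sampler, and phenotype labels are implied
by the planted hotspots: a strong planted interaction (salt bridge,
H-bond, pi-cation) makes alanine replacement non-binding, a weak
(hydrophobic-only) site gives reduced binding, and untouched positions
retain binding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .posegen import DockedPose, generate_poses, realise_pose
from .scoring import EnergyParams, binding_energy
from .structures import (AA1_TO_3, Atom, Complex, Residue, RigidTransform,
                         save_pdb, subcomplex)
from .triage import PhenotypeTable

__all__ = [
    "PlantedInteraction",
    "FixtureSpec",
    "GroundTruth",
    "FixtureGeometryError",
    "default_fixture_spec",
    "make_toy_complex",
    "split_binder_target",
    "make_surrogate_complex",
    "make_decoy_set",
    "simulate_phenotypes",
    "write_fixture",
]

CA_SPACING = 3.8
CB_LENGTH = 1.53
STRONG_KINDS = frozenset({"salt_bridge", "hbond", "pi_cation"})

#: default residue types per planted interaction kind (binder aa, antigen aa)
KIND_TEMPLATES = {
    "salt_bridge": ("R", "D"),
    "hbond": ("Q", "N"),
    "pi_cation": ("R", "Y"),
    "pi_pi": ("F", "F"),
    "hydrophobic": ("L", "L"),
}

#: generous C-beta -> functional-tip reach in Angstrom, for feasibility checks
MAX_TIP_REACH = {
    "R": 5.5, "K": 4.6, "E": 4.0, "Q": 4.0, "Y": 4.2, "F": 3.8, "W": 3.7,
    "D": 2.8, "N": 2.8, "L": 2.9, "I": 2.6, "M": 4.0, "S": 1.8, "T": 1.8,
    "H": 3.0,
}


class FixtureGeometryError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedInteraction:
    kind: str
    binder_chain: str       # H or L
    binder_pos: int
    antigen_pos: int
    distance: float
    angle: float | None = None    # pi-cation: angle to the ring normal, degrees
    binder_aa: str | None = None  # defaults per kind (KIND_TEMPLATES)
    antigen_aa: str | None = None

    def resolved_aas(self) -> tuple[str, str]:
        b, a = KIND_TEMPLATES[self.kind]
        return (self.binder_aa or b, self.antigen_aa or a)


@dataclass
class FixtureSpec:
    seed: int = 0
    binder_lengths: dict[str, int] = field(default_factory=lambda: {"H": 12, "L": 10})
    antigen_length: int = 20
    planted: list[PlantedInteraction] = field(default_factory=list)
    control_positions: list[tuple[str, int]] = field(default_factory=list)
    decoys: int = 200
    separation: float = 10.0   # backbone-line separation, A

    def __post_init__(self) -> None:
        for p in self.planted:
            if p.binder_chain not in self.binder_lengths:
                raise ValueError(f"planted interaction on unknown chain {p.binder_chain}")
            if not (1 <= p.binder_pos <= self.binder_lengths[p.binder_chain]):
                raise ValueError(f"planted binder position {p.binder_pos} out of range")
            if not (1 <= p.antigen_pos <= self.antigen_length):
                raise ValueError(f"planted antigen position {p.antigen_pos} out of range")


def default_fixture_spec(seed: int = 0, decoys: int = 200) -> FixtureSpec:
    """The standard study condition: 3 strong hotspots + 1 weak site.

    Salt bridge, pi-cation (at the canonical 4.9 A / 28.5 deg geometry) and
    H-bond hotspots plus one hydrophobic-only weak site, with two
    non-interacting control positions per the validation-panel convention.
    """
    return FixtureSpec(
        seed=seed,
        planted=[
            PlantedInteraction("salt_bridge", "H", 3, 3, 3.0),
            PlantedInteraction("pi_cation", "H", 8, 8, 4.9, angle=28.5),
            PlantedInteraction("hbond", "L", 3, 16, 3.0),
            PlantedInteraction("hydrophobic", "L", 6, 19, 4.0),
        ],
        control_positions=[("H", 11), ("L", 9)],
        decoys=decoys,
    )


@dataclass
class GroundTruth:
    true_pose_transform: RigidTransform
    planted: list[PlantedInteraction]
    hotspot_positions: set[tuple[str, int]]   # >=1 strong planted interaction
    weak_positions: set[tuple[str, int]]      # hydrophobic-only sites
    panel: list[tuple[str, int, str]]         # (chain, pos, wt_aa) scanned positions
    true_pose_id: int | None = None

    def to_json(self) -> str:
        return json.dumps({
            "true_pose_transform": self.true_pose_transform.as_flat().tolist(),
            "planted": [vars(p) | {"resolved_aas": p.resolved_aas()}
                        for p in self.planted],
            "hotspot_positions": sorted(self.hotspot_positions),
            "weak_positions": sorted(self.weak_positions),
            "panel": self.panel,
            "true_pose_id": self.true_pose_id,
        }, indent=2)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    p = np.cross(u, ref)
    p /= np.linalg.norm(p)
    q = np.cross(u, p)
    return p, q


def _sidechain_atoms(aa: str, cb: np.ndarray, tip: np.ndarray,
                     planted: PlantedInteraction, is_binder: bool,
                     partner_tip: np.ndarray) -> list[Atom]:
    """Heavy-atom side-chain template reaching from CB to the tip point."""
    u = tip - cb
    norm = np.linalg.norm(u)
    u = u / norm if norm > 0 else np.array([0.0, 1.0, 0.0])
    p, q = _perp_basis(u)
    A = lambda name, elem, pos: Atom(name, elem, np.asarray(pos, dtype=float))
    mid = lambda x, y: (np.asarray(x) + np.asarray(y)) / 2.0

    if aa == "R":
        if planted.kind == "pi_cation":
            # guanidinium nitrogen centroid exactly at the tip
            ne = tip + 1.1 * p
            nh1 = tip + 1.1 * (-0.5 * p + 0.866 * q)
            nh2 = tip + 1.1 * (-0.5 * p - 0.866 * q)
            cz = tip - 0.8 * u
            cd = tip - 2.2 * u
            return [A("CG", "C", mid(cb, cd)), A("CD", "C", cd), A("NE", "N", ne),
                    A("CZ", "C", cz), A("NH1", "N", nh1), A("NH2", "N", nh2)]
        nh1 = tip
        cz = tip - 1.33 * u
        nh2 = cz + 1.33 * p
        ne = tip - 2.66 * u
        cd = tip - 4.0 * u
        return [A("CG", "C", mid(cb, cd)), A("CD", "C", cd), A("NE", "N", ne),
                A("CZ", "C", cz), A("NH1", "N", nh1), A("NH2", "N", nh2)]
    if aa == "K":
        return [A("CG", "C", mid(cb, tip - 2.9 * u)), A("CD", "C", tip - 2.9 * u),
                A("CE", "C", tip - 1.5 * u), A("NZ", "N", tip)]
    if aa == "D":
        cg = tip - 1.25 * u
        return [A("CG", "C", cg), A("OD1", "O", tip),
                A("OD2", "O", cg + 0.96 * p - 0.8 * u)]
    if aa == "E":
        cd = tip - 1.25 * u
        return [A("CG", "C", mid(cb, cd)), A("CD", "C", cd), A("OE1", "O", tip),
                A("OE2", "O", cd + 0.96 * p - 0.8 * u)]
    if aa == "N":
        cg = tip - 1.33 * u
        return [A("CG", "C", cg), A("OD1", "O", tip),
                A("ND2", "N", cg + 0.96 * p - 0.8 * u)]
    if aa == "Q":
        cd = tip - 1.33 * u
        return [A("CG", "C", mid(cb, cd)), A("CD", "C", cd), A("NE2", "N", tip),
                A("OE1", "O", cd + 0.96 * p - 0.8 * u)]
    if aa == "S":
        return [A("OG", "O", tip)]
    if aa == "L":
        cg = tip - 1.54 * u
        return [A("CG", "C", cg), A("CD1", "C", tip),
                A("CD2", "C", cg + 1.2 * p - 0.8 * u)]
    if aa in ("F", "Y"):
        # hexagonal ring centred at the tip; normal from the planted angle
        w = partner_tip - tip
        wn = np.linalg.norm(w)
        w = w / wn if wn > 0 else u
        if planted.kind == "pi_cation" and planted.angle is not None:
            theta = np.radians(planted.angle)
            pw, _ = _perp_basis(w)
            normal = np.cos(theta) * w + np.sin(theta) * pw
        else:
            normal = w
        e1, e2 = _perp_basis(normal)
        names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        atoms = []
        for k, name in enumerate(names):
            ang = np.radians(60.0 * k)
            pos = tip + 1.39 * (np.cos(ang) * e1 + np.sin(ang) * e2)
            atoms.append(A(name, "C", pos))
        return atoms
    raise FixtureGeometryError(f"no side-chain template for residue type {aa!r}")


# ---------------------------------------------------------------------------
# complex construction
# ---------------------------------------------------------------------------

def _backbone(x: float, y0: float, dy: float, index: int) -> list[Atom]:
    # small alternating z offset keeps the C-alpha trace non-collinear
    # (superposition on a perfectly straight chain would be degenerate)
    z = 0.4 if index % 2 else -0.4
    ca = np.array([x, y0, z])
    n = ca + np.array([-1.2, -0.5 * dy, 0.0])
    c = ca + np.array([1.2, -0.5 * dy, 0.0])
    o = c + np.array([0.0, -1.23 * dy, 0.0])
    return [Atom("N", "N", n), Atom("CA", "C", ca), Atom("C", "C", c),
            Atom("O", "O", o)]


def make_toy_complex(spec: FixtureSpec) -> tuple[Complex, GroundTruth]:
    """Build the idealised complex and its ground truth.

    Binder chains run along one line at y=0 with side chains pointing
    toward the antigen line at y=separation; planted side-chain tips meet
    on the segment between the paired C-betas at the specified geometry.
    Raises :class:`FixtureGeometryError` naming the first planted
    interaction whose geometry cannot be realised.
    """
    chain_offsets: dict[str, int] = {}
    offset = 0
    for cid, length in spec.binder_lengths.items():
        chain_offsets[cid] = offset
        offset += length + 1  # one-spacing gap between binder chains

    def binder_x(cid: str, pos: int) -> float:
        return CA_SPACING * (chain_offsets[cid] + pos - 1)

    def antigen_x(pos: int) -> float:
        return CA_SPACING * (pos - 1)

    chains: dict[str, list[Residue]] = {}
    for cid, length in spec.binder_lengths.items():
        chains[cid] = []
        for i in range(1, length + 1):
            atoms = _backbone(binder_x(cid, i), 0.0, +1.0, i)
            atoms.append(Atom("CB", "C",
                              np.array([binder_x(cid, i), CB_LENGTH, 0.0])))
            chains[cid].append(Residue(cid, i, "ALA", atoms,
                                       imgt_label=f"{cid}:{i}"))
    chains["A"] = []
    for k in range(1, spec.antigen_length + 1):
        atoms = _backbone(antigen_x(k), spec.separation, -1.0, k)
        atoms.append(Atom("CB", "C",
                          np.array([antigen_x(k), spec.separation - CB_LENGTH, 0.0])))
        chains["A"].append(Residue("A", k, "ALA", atoms, imgt_label=f"A:{k}"))

    cx = Complex(chains, {cid: ("heavy" if cid == "H" else "light")
                          for cid in spec.binder_lengths} | {"A": "antigen"})

    planted_at: dict[tuple[str, int], list[PlantedInteraction]] = {}
    for planted in spec.planted:
        b_aa, a_aa = planted.resolved_aas()
        bres = cx.get_residue(planted.binder_chain, planted.binder_pos)
        ares = cx.get_residue("A", planted.antigen_pos)
        cb_b = bres.get_atom("CB").position
        cb_a = ares.get_atom("CB").position
        v = cb_a - cb_b
        L = float(np.linalg.norm(v))
        u = v / L
        slackL = L - planted.distance
        r_b = MAX_TIP_REACH.get(b_aa, 2.0)
        r_a = MAX_TIP_REACH.get(a_aa, 2.0)
        if slackL < 0 or slackL > r_b + r_a:
            raise FixtureGeometryError(
                f"planted {planted.kind} {planted.binder_chain}:{planted.binder_pos}"
                f" <-> A:{planted.antigen_pos}: CB separation {L:.2f} A cannot host "
                f"distance {planted.distance:.2f} A with {b_aa}/{a_aa} side chains"
            )
        a_len = slackL * r_b / (r_b + r_a)
        b_len = slackL - a_len
        tip_b = cb_b + a_len * u
        tip_a = cb_a - b_len * u

        bres.atoms = [at for at in bres.atoms if at.name != "CB"] \
            + [Atom("CB", "C", cb_b.copy())] \
            + _sidechain_atoms(b_aa, cb_b, tip_b, planted, True, tip_a)
        bres.aa3 = AA1_TO_3[b_aa]
        ares.atoms = [at for at in ares.atoms if at.name != "CB"] \
            + [Atom("CB", "C", cb_a.copy())] \
            + _sidechain_atoms(a_aa, cb_a, tip_a, planted, False, tip_b)
        ares.aa3 = AA1_TO_3[a_aa]
        planted_at.setdefault((planted.binder_chain, planted.binder_pos),
                              []).append(planted)

    hotspots = {site for site, plist in planted_at.items()
                if any(p.kind in STRONG_KINDS for p in plist)}
    weak = {site for site, plist in planted_at.items()
            if site not in hotspots}

    panel_sites = sorted(planted_at) + sorted(set(spec.control_positions)
                                              - set(planted_at))
    panel = []
    for cid, pos in panel_sites:
        res = cx.get_residue(cid, pos)
        panel.append((cid, pos, res.aa1))
        res.annotations.add(f"CDR{cid}1")
    for res in cx.residues(list(spec.binder_lengths)):
        if not res.annotations:
            res.annotations.add("FR")

    truth = GroundTruth(RigidTransform.identity(), list(spec.planted),
                        hotspots, weak, panel)
    return cx, truth


def split_binder_target(cx: Complex) -> tuple[Complex, Complex]:
    """Copy out the binder (heavy+light) and antigen as separate complexes."""
    return (subcomplex(cx, cx.binder_chains).copy(),
            subcomplex(cx, cx.target_chains).copy())


def make_surrogate_complex(cx: Complex) -> tuple[Complex, list[tuple[int, int]]]:
    """A surrogate receptor-ligand complex for blockade-geometry checks.

    The surrogate ligand is a copy of the antigen (chain S); the receptor
    (chain R) occupies the volume of the true-pose antibody, so a pose
    whose antibody sits on the antigen's receptor-binding face overlaps the
    receptor after superposition.  Returns the surrogate complex and the
    identity antigen-to-ligand residue-pair mapping.
    """
    cx.require_roles()
    ligand = [r.copy() for r in cx.residues(cx.target_chains)]
    pairs = [(r.author_pos, r.author_pos) for r in ligand]
    for r in ligand:
        r.chain_id = "S"
    receptor = []
    pos = 0
    for r in cx.residues(cx.binder_chains):
        pos += 1
        rc = r.copy()
        rc.chain_id = "R"
        rc.author_pos = pos
        rc.imgt_label = None
        receptor.append(rc)
    surrogate = Complex({"R": receptor, "S": ligand},
                        {"R": "receptor", "S": "surrogate_ligand"})
    return surrogate, pairs


def make_decoy_set(truth: GroundTruth, binder: Complex, target: Complex,
                   n_decoys: int, seed: int,
                   params: EnergyParams | None = None) -> list[DockedPose]:
    """The true pose (id 0) plus ``n_decoys`` clash-free random poses."""
    params = params or EnergyParams()
    true_cx = realise_pose(binder, target, truth.true_pose_transform)
    true_pose = DockedPose(0, truth.true_pose_transform,
                           binding_energy(true_cx, params))
    decoys = []
    if n_decoys >= 1:
        for i, pose in enumerate(generate_poses(binder, target, n_decoys, seed,
                                                params=params), start=1):
            pose.pose_id = i
            decoys.append(pose)
    truth.true_pose_id = 0
    return [true_pose] + decoys


def simulate_phenotypes(truth: GroundTruth) -> PhenotypeTable:
    """Phenotype labels implied by the planted hotspots.

    Alanine replacement at a position with a strong planted interaction is
    non-binding, hydrophobic-only sites give reduced binding, and
    positions without planted interactions retain binding.
    """
    entries = {}
    for chain, pos, wt in truth.panel:
        site = (chain, pos)
        if site in truth.hotspot_positions:
            label = "non_binding"
        elif site in truth.weak_positions:
            label = "reduced"
        else:
            label = "retained"
        entries[f"{chain}:{wt}{pos}A"] = label
    return PhenotypeTable(entries)


def write_fixture(spec: FixtureSpec, out_dir) -> GroundTruth:
    """Write PDB files, numbering map, phenotypes and ground truth to disk."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cx, truth = make_toy_complex(spec)
    binder, target = split_binder_target(cx)
    (out / "complex.pdb").write_text(save_pdb(cx))
    (out / "binder.pdb").write_text(save_pdb(binder))
    (out / "antigen.pdb").write_text(save_pdb(target))
    rows = ["chain_id\tauthor_pos\timgt_label\tannotation"]
    for res in cx.residues(cx.binder_chains):
        ann = sorted(res.annotations)[0]
        rows.append(f"{res.chain_id}\t{res.author_pos}\t{res.imgt_label}\t{ann}")
    (out / "numbering_map.tsv").write_text("\n".join(rows) + "\n")
    (out / "phenotypes.csv").write_text(simulate_phenotypes(truth).to_csv())
    (out / "ground_truth.json").write_text(truth.to_json())
    return truth
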