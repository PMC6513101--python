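"""Residue-contact stand-in energy and point-mutation scoring.

The energy is a transparent bookkeeping score over the classified
cross-interface interactions, in arbitrary units (AU):

    E_binding = sum of per-kind weights over detected interactions
                + clash_penalty * (# cross heavy-atom pairs < clash distance)

with stabilising contributions negative (salt bridge -2.0, H-bond -1.0,
pi-cation -1.25, pi-pi -0.75, hydrophobic -0.25 AU by default).  The scale
is calibrated so a single salt bridge is worth about 2 AU, which places
hotspot alanine ddE values in the 1-4 AU range and makes the triage
thresholds (0.00 / 0.50 AU) meaningful.  This is an explicit stand-in for
force-field scoring, not a reproduction of any molecular-mechanics energy.

Mutations are modelled deterministically, without repacking or
minimisation:

* to Ala/Gly: the side chain is truncated at C-beta (Gly: at C-alpha);
* to any other residue: the side chain is replaced by a single pseudo
  side-chain centroid placed along the C-alpha -> C-beta direction at a
  residue-specific reach, carrying the residue type's chemotypes
  (cationic, anionic, aromatic, polar donor/acceptor, apolar).

ddE_binding = E_binding(mutant) - E_binding(wild type); ddE_stability is
the change in intramolecular clash count times the clash penalty.  The
``tolerant`` mode, which stands in for local minimisation with a fixed
5.0 A radius, ignores new clashes against side chains of residues near the
mutated site (backbone clashes always count).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interface import InteractionGeometry, count_cross_clashes, detect_interactions
from .structures import AA1_TO_3, Atom, Complex, Residue

__all__ = [
    "AMINO_ACIDS",
    "Mutation",
    "DdEResult",
    "EnergyParams",
    "binding_energy",
    "apply_mutation",
    "ddE",
    "alanine_scan",
    "species_switch",
    "saturation_scan",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: chemotype sets per one-letter residue code, used by pseudo side chains
CHEMOTYPES: dict[str, frozenset] = {
    aa: frozenset(
        (["cationic"] if aa in "KRH" else [])
        + (["anionic"] if aa in "DE" else [])
        + (["aromatic"] if aa in "FYWH" else [])
        + (["polar"] if aa in "STNQYHKRDEW" else [])
        + (["apolar"] if aa in "AVLIMPFWC" else [])
    )
    for aa in AMINO_ACIDS
}

#: mean C-beta -> side-chain-centroid distance (Angstrom) per residue type;
#: fixed constants giving one deterministic pseudo-side-chain geometry each
PSEUDO_REACH = {
    "G": 0.0, "A": 0.0, "S": 1.0, "C": 1.2, "T": 1.1, "P": 1.2, "V": 1.2,
    "D": 1.6, "N": 1.7, "I": 1.8, "L": 1.9, "H": 2.2, "E": 2.3, "M": 2.3,
    "F": 2.4, "Q": 2.4, "W": 2.6, "K": 2.9, "Y": 2.9, "R": 4.1,
}

_MUTATION_RE = re.compile(r"^([HLA]):([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class Mutation:
    """A point mutation in ``chain:wt pos mut`` notation, e.g. ``H:S28R``."""

    chain: str          # H, L or A
    pos: str            # IMGT (preferred) or author position label
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        if self.chain not in "HLA":
            raise ValueError(f"chain must be H, L or A, got {self.chain!r}")
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in AMINO_ACIDS:
                raise ValueError(f"unknown amino acid {aa!r}")

    @classmethod
    def parse(cls, text: str) -> "Mutation":
        m = _MUTATION_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse mutation {text!r} (expected e.g. H:S28R)")
        chain, wt, pos, mut = m.groups()
        return cls(chain, pos, wt, mut)

    def __str__(self) -> str:
        return f"{self.chain}:{self.wt_aa}{self.pos}{self.mut_aa}"

    @property
    def site_key(self) -> tuple[str, str]:
        return (self.chain, self.pos)

    @property
    def identity_key(self) -> tuple[str, str, str]:
        """Key used for consensus/dedup: (chain, position, mutant residue)."""
        return (self.chain, self.pos, self.mut_aa)


@dataclass(frozen=True)
class DdEResult:
    mutation: Mutation
    pose_id: object
    ddE_binding: float
    ddE_stability: float
    mode: str  # rigid | tolerant

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ddE_binding) and np.isfinite(self.ddE_stability)):
            raise ValueError("ddE values must be finite")
        if self.mode not in ("rigid", "tolerant"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class EnergyParams:
    weights: dict[str, float] = field(default_factory=lambda: {
        "salt_bridge": -2.0, "hbond": -1.0, "pi_cation": -1.25,
        "pi_pi": -0.75, "hydrophobic": -0.25,
    })
    clash_distance: float = 2.4
    clash_penalty: float = 5.0
    pseudo_sidechain_slack: float = 1.0
    tolerant_radius: float = 5.0

    def __post_init__(self) -> None:
        if any(w > 0 for w in self.weights.values()):
            raise ValueError("favourable interaction weights must be <= 0")
        if self.clash_penalty < 0:
            raise ValueError("clash penalty must be >= 0")

    def geometry(self, base: InteractionGeometry | None = None) -> InteractionGeometry:
        geo = base or InteractionGeometry()
        geo.pseudo_slack = self.pseudo_sidechain_slack
        return geo


def binding_energy(cx: Complex, params: EnergyParams | None = None,
                   geometry: InteractionGeometry | None = None) -> float:
    """Cross-interface stand-in energy in AU (more negative = better)."""
    params = params or EnergyParams()
    geo = params.geometry(geometry)
    e = sum(params.weights[r.kind] for r in detect_interactions(cx, geo))
    n_clash = count_cross_clashes(cx, params.clash_distance)
    return float(e + params.clash_penalty * n_clash)


# ---------------------------------------------------------------------------
# mutation modelling
# ---------------------------------------------------------------------------

def _resolve_residue(cx: Complex, mutation: Mutation) -> Residue:
    cid = cx.chain_for_letter(mutation.chain)
    residues = cx.chains[cid]
    # prefer the IMGT label when the chain carries numbering
    for res in residues:
        if res.imgt_label is not None:
            num = re.sub(r"^[A-Z]+:", "", res.imgt_label)
            if num == mutation.pos:
                return res
    for res in residues:
        if str(res.author_pos) == mutation.pos and not res.icode:
            return res
    raise KeyError(f"position {mutation.chain}:{mutation.pos} not found")


def _ideal_cb(res: Residue) -> np.ndarray:
    """Idealised C-beta direction from the backbone (used when CB is absent)."""
    n, ca, c = (res.get_atom(x) for x in ("N", "CA", "C"))
    if ca is None:
        raise ValueError(f"residue {res.label} lacks CA")
    if n is None or c is None:
        return ca.position + np.array([0.0, 1.53, 0.0])
    u1 = ca.position - n.position
    u2 = ca.position - c.position
    u1 /= np.linalg.norm(u1)
    u2 /= np.linalg.norm(u2)
    bis = u1 + u2
    bis /= np.linalg.norm(bis)
    perp = np.cross(u2, u1)
    perp /= np.linalg.norm(perp)
    d = bis + perp
    return ca.position + 1.53 * d / np.linalg.norm(d)


def apply_mutation(cx: Complex, mutation: Mutation,
                   params: EnergyParams | None = None) -> Complex:
    """Return a copy of ``cx`` with one residue mutated.

    Raises if the position is absent or the stated wild-type residue does
    not match the structure.  A self-mutation returns an unmodified copy.
    """
    new = cx.copy()
    res = _resolve_residue(new, mutation)
    if res.aa1 != mutation.wt_aa:
        raise ValueError(
            f"wild-type mismatch at {mutation.chain}:{mutation.pos}: "
            f"structure has {res.aa1}, mutation says {mutation.wt_aa}"
        )
    if mutation.mut_aa == mutation.wt_aa:
        return new

    backbone = [a for a in res.atoms if a.is_backbone]
    cb = res.get_atom("CB")
    ca = res.get_atom("CA")
    if mutation.mut_aa == "G":
        res.atoms = backbone
        res.aa3 = "GLY"
        res.pseudo_chemotypes = frozenset()
        return new

    cb_pos = cb.position.copy() if cb is not None else _ideal_cb(res)
    new_atoms = backbone + [Atom("CB", "C", cb_pos.copy())]
    if mutation.mut_aa == "A":
        res.atoms = new_atoms
        res.aa3 = "ALA"
        res.pseudo_chemotypes = frozenset()
        return new

    reach = PSEUDO_REACH[mutation.mut_aa]
    direction = cb_pos - ca.position
    norm = np.linalg.norm(direction)
    direction = direction / norm if norm > 0 else np.array([0.0, 1.0, 0.0])
    centroid = cb_pos + reach * direction
    new_atoms.append(Atom("SCC", "X", centroid, is_pseudo=True))
    res.atoms = new_atoms
    res.aa3 = AA1_TO_3[mutation.mut_aa]
    res.pseudo_chemotypes = CHEMOTYPES[mutation.mut_aa]
    return new


# ---------------------------------------------------------------------------
# stability clash census
# ---------------------------------------------------------------------------

def _molecule_chains(cx: Complex, chain_letter: str) -> list[str]:
    if chain_letter in "HL":
        return cx.binder_chains
    return cx.target_chains


def _neighbour_keys(cx: Complex, res: Residue, radius: float) -> set:
    """Keys of residues with any heavy atom within ``radius`` of ``res``."""
    own = np.array([a.position for a in res.heavy_atoms()]).reshape(-1, 3)
    out = set()
    for other in cx.residues():
        if other.key == res.key:
            continue
        pts = np.array([a.position for a in other.heavy_atoms()]).reshape(-1, 3)
        if pts.size and own.size:
            d = np.min(np.linalg.norm(own[:, None, :] - pts[None, :, :], axis=2))
            if d <= radius:
                out.add(other.key)
    return out


def _intra_clashes(cx: Complex, res_key, molecule_chain_ids, clash_distance: float,
                   tolerant_exempt: set | None) -> int:
    """Clashes of one residue's side chain against its own molecule.

    Same-residue contacts and adjacent residues' backbone atoms are always
    excluded.  When ``tolerant_exempt`` is given, clashes against side-chain
    atoms of the listed residues are ignored (backbone clashes still count).
    """
    res = None
    for r in cx.residues(molecule_chain_ids):
        if r.key == res_key:
            res = r
            break
    if res is None:
        raise KeyError(f"residue {res_key} not in molecule")
    side = np.array([a.position for a in res.heavy_atoms() if not a.is_backbone]
                    ).reshape(-1, 3)
    if side.size == 0:
        return 0
    count = 0
    for other in cx.residues(molecule_chain_ids):
        if other.key == res.key:
            continue
        adjacent = (other.chain_id == res.chain_id
                    and abs(other.author_pos - res.author_pos) == 1)
        for atom in other.heavy_atoms():
            if adjacent and atom.is_backbone:
                continue
            if tolerant_exempt is not None and other.key in tolerant_exempt \
                    and not atom.is_backbone:
                continue
            if np.min(np.linalg.norm(side - atom.position, axis=1)) < clash_distance:
                count += 1
    return count


# ---------------------------------------------------------------------------
# ddE and scans
# ---------------------------------------------------------------------------

def ddE(cx: Complex, mutation: Mutation, mode: str = "rigid",
        params: EnergyParams | None = None,
        geometry: InteractionGeometry | None = None,
        pose_id: object = "pose",
        _wt_energy: float | None = None) -> DdEResult:
    """ddE_binding and ddE_stability (AU) for one mutation in one pose."""
    if mode not in ("rigid", "tolerant"):
        raise ValueError(f"unknown mode {mode!r}")
    params = params or EnergyParams()
    if mutation.mut_aa == mutation.wt_aa:
        _resolve_residue(cx, mutation)  # still validate position/wt
        return DdEResult(mutation, pose_id, 0.0, 0.0, mode)
    wt_e = binding_energy(cx, params, geometry) if _wt_energy is None else _wt_energy
    mutant = apply_mutation(cx, mutation, params)
    mut_e = binding_energy(mutant, params, geometry)

    res = _resolve_residue(cx, mutation)
    mol = _molecule_chains(cx, mutation.chain)
    exempt = (_neighbour_keys(cx, res, params.tolerant_radius)
              if mode == "tolerant" else None)
    c_wt = _intra_clashes(cx, res.key, mol, params.clash_distance, exempt)
    c_mut = _intra_clashes(mutant, res.key, mol, params.clash_distance, exempt)
    return DdEResult(mutation, pose_id,
                     float(mut_e - wt_e),
                     float((c_mut - c_wt) * params.clash_penalty),
                     mode)


def _pos_sort_key(chain: str, pos: str):
    m = re.match(r"(\d+)([A-Z]?)", pos)
    return (chain, int(m.group(1)) if m else 0, m.group(2) if m else "")


def alanine_scan(cx: Complex, positions, params: EnergyParams | None = None,
                 geometry: InteractionGeometry | None = None,
                 pose_id: object = "pose") -> list[DdEResult]:
    """Rigid-mode alanine scan over antibody positions.

    ``positions`` is an iterable of ``(chain_letter, pos_label)`` pairs or
    ``"H:55"``-style strings.  Gly/Ala positions are scanned as no-ops with
    both energies zero.  Results are ordered by chain, then position.
    """
    params = params or EnergyParams()
    norm: list[tuple[str, str]] = []
    for p in positions:
        if isinstance(p, str):
            chain, pos = p.split(":")
        else:
            chain, pos = p
        if chain not in "HL":
            raise ValueError(f"alanine scan position {chain}:{pos} is not on the antibody")
        norm.append((chain, pos))
    norm.sort(key=lambda cp: _pos_sort_key(*cp))
    wt_e = binding_energy(cx, params, geometry)
    results = []
    for chain, pos in norm:
        res = _resolve_residue(cx, Mutation(chain, pos, "A", "A"))
        wt = res.aa1
        if wt in ("A", "G"):
            results.append(DdEResult(Mutation(chain, pos, wt, wt), pose_id,
                                     0.0, 0.0, "rigid"))
            continue
        m = Mutation(chain, pos, wt, "A")
        results.append(ddE(cx, m, "rigid", params, geometry, pose_id,
                           _wt_energy=wt_e))
    return results


def species_switch(cx: Complex, substitutions: list[Mutation],
                   params: EnergyParams | None = None,
                   geometry: InteractionGeometry | None = None) -> float:
    """Total ddE_binding (AU) of simultaneous antigen substitutions.

    Emulates switching the antigen species: all substitutions are applied
    at once and the change in binding energy is returned.  A pose is called
    specificity-consistent when the value is at or above a configurable
    threshold (default 0.0 AU).
    """
    params = params or EnergyParams()
    for m in substitutions:
        if m.chain != "A":
            raise ValueError(f"species switch accepts antigen mutations only, got {m}")
    if not substitutions:
        return 0.0
    mutant = cx
    for m in substitutions:
        mutant = apply_mutation(mutant, m, params)
    return float(binding_energy(mutant, params, geometry)
                 - binding_energy(cx, params, geometry))


def saturation_scan(cx: Complex, designable,
                    params: EnergyParams | None = None,
                    geometry: InteractionGeometry | None = None,
                    pose_id: object = "pose") -> pd.DataFrame:
    """Saturation mutagenesis over designable positions, both clash modes.

    Returns a DataFrame with ``|designable| * 20 * 2`` rows (self-mutations
    included with both energies zero) and columns ``mutation``, ``mode``,
    ``ddE_binding_AU``, ``ddE_stability_AU``.
    """
    params = params or EnergyParams()
    norm = []
    for p in designable:
        if isinstance(p, str):
            chain, pos = p.split(":")
        else:
            chain, pos = p
        norm.append((chain, pos))
    if not norm:
        raise ValueError("designable set must be non-empty")
    norm.sort(key=lambda cp: _pos_sort_key(*cp))
    wt_e = binding_energy(cx, params, geometry)
    rows = []
    for chain, pos in norm:
        res = _resolve_residue(cx, Mutation(chain, pos, "A", "A"))
        wt = res.aa1
        for mut_aa in AMINO_ACIDS:
            for mode in ("rigid", "tolerant"):
                m = Mutation(chain, pos, wt, mut_aa)
                if mut_aa == wt:
                    r = DdEResult(m, pose_id, 0.0, 0.0, mode)
                else:
                    r = ddE(cx, m, mode, params, geometry, pose_id, _wt_energy=wt_e)
                rows.append({
                    "pose_id": pose_id, "mutation": str(m), "mode": mode,
                    "ddE_binding_AU": r.ddE_binding,
                    "ddE_stability_AU": r.ddE_stability,
                })
    return pd.DataFrame(rows)
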