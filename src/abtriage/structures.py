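"""Structure data model, PDB I/O, rigid transforms and least-squares superposition.

The package works on small multi-chain protein complexes: an antibody Fv
(heavy + light chain), an antigen, and optionally a surrogate receptor-ligand
complex used for receptor-blockade geometry checks.  Coordinates are in
Angstroms, author numbering is 1-based as in the PDB, and hydrogens are
ignored by default throughout (all geometry is heavy-atom only).

IMGT labels and CDR/Vernier annotations are supplied externally via a
tab-separated numbering map (antibody numbering is a solved problem outside
this package's scope) and attached to residues with
:func:`apply_numbering_map`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Complex",
    "RigidTransform",
    "PDBParseError",
    "DegenerateGeometryError",
    "load_pdb",
    "save_pdb",
    "transform_apply",
    "kabsch_superpose",
    "compose",
    "read_numbering_map",
    "apply_numbering_map",
    "merge_complexes",
    "subcomplex",
]

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

#: chain-role vocabulary
ROLES = ("heavy", "light", "antigen", "receptor", "surrogate_ligand")
#: one-letter chain designators used in mutation notation
ROLE_LETTER = {"heavy": "H", "light": "L", "antigen": "A"}


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input (carries the line number)."""


class DegenerateGeometryError(ValueError):
    """Raised when a superposition problem is underdetermined."""


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray
    is_pseudo: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")

    @property
    def is_backbone(self) -> bool:
        return (not self.is_pseudo) and self.name in BACKBONE_NAMES

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.position.copy(), self.is_pseudo)


@dataclass
class Residue:
    chain_id: str
    author_pos: int
    aa3: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""
    imgt_label: str | None = None
    annotations: set[str] = field(default_factory=set)
    #: chemotypes carried by a pseudo side-chain centroid after mutation
    pseudo_chemotypes: frozenset[str] = frozenset()

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.author_pos, self.icode)

    @property
    def label(self) -> str:
        """Human-readable residue label, IMGT when available."""
        if self.imgt_label:
            return self.imgt_label
        return f"{self.chain_id}:{self.author_pos}{self.icode}"

    @property
    def aa1(self) -> str:
        return AA3_TO_1.get(self.aa3, "X")

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element not in ("H", "D")]

    def copy(self) -> "Residue":
        return Residue(
            self.chain_id, self.author_pos, self.aa3,
            [a.copy() for a in self.atoms], self.icode, self.imgt_label,
            set(self.annotations), self.pseudo_chemotypes,
        )


@dataclass
class Complex:
    """A multi-chain structure with per-chain role assignments.

    ``roles`` maps every chain id to one of :data:`ROLES`.  The binder side
    is the union of ``heavy`` + ``light`` chains; the target side is the
    ``antigen`` chain(s).
    """

    chains: dict[str, list[Residue]]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, role in self.roles.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for chain {cid!r}")
            if cid not in self.chains:
                raise ValueError(f"role assigned to missing chain {cid!r}")

    # ---- chain-role helpers -------------------------------------------------
    def chains_with_role(self, *roles: str) -> list[str]:
        return [cid for cid in self.chains if self.roles.get(cid) in roles]

    @property
    def binder_chains(self) -> list[str]:
        return self.chains_with_role("heavy", "light")

    @property
    def target_chains(self) -> list[str]:
        return self.chains_with_role("antigen")

    def require_roles(self) -> None:
        if not self.binder_chains or not self.target_chains:
            raise ValueError(
                "complex needs chains with heavy/light and antigen roles; "
                f"got roles {self.roles!r}"
            )

    def chain_for_letter(self, letter: str) -> str:
        """Map a mutation-notation chain letter (H/L/A) to a chain id."""
        wanted = {v: k for k, v in ROLE_LETTER.items()}.get(letter)
        if wanted is None:
            raise ValueError(f"unknown chain letter {letter!r}")
        ids = self.chains_with_role(wanted)
        if not ids:
            raise ValueError(f"no chain with role {wanted!r} in complex")
        return ids[0]

    # ---- residue / atom access ---------------------------------------------
    def residues(self, chain_ids=None):
        if chain_ids is None:
            chain_ids = list(self.chains)
        for cid in chain_ids:
            yield from self.chains[cid]

    def get_residue(self, chain_id: str, author_pos: int, icode: str = "") -> Residue:
        for res in self.chains[chain_id]:
            if res.author_pos == author_pos and res.icode == icode:
                return res
        raise KeyError(f"no residue {chain_id}:{author_pos}{icode}")

    def heavy_atom_table(self, chain_ids=None):
        """All heavy atoms of the listed chains.

        Returns ``(coords, refs)`` where ``coords`` is an (n, 3) array and
        ``refs`` a parallel list of ``(residue, atom)`` pairs.
        """
        coords, refs = [], []
        for res in self.residues(chain_ids):
            for atom in res.heavy_atoms():
                coords.append(atom.position)
                refs.append((res, atom))
        if not coords:
            return np.empty((0, 3)), refs
        return np.asarray(coords), refs

    def ca_coords(self, chain_ids=None) -> np.ndarray:
        pts = []
        for res in self.residues(chain_ids):
            ca = res.get_atom("CA")
            if ca is not None:
                pts.append(ca.position)
        return np.asarray(pts) if pts else np.empty((0, 3))

    def copy(self) -> "Complex":
        return Complex(
            {cid: [r.copy() for r in reslist] for cid, reslist in self.chains.items()},
            dict(self.roles),
        )

    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())


@dataclass
class RigidTransform:
    """A proper rigid motion x -> R @ x + t (rotation + translation, Angstrom)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        err = np.linalg.norm(self.rotation @ self.rotation.T - np.eye(3))
        if err > 1e-8:
            raise ValueError(f"rotation is not orthonormal (|RR^T - I| = {err:.2e})")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation must have determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def as_flat(self) -> np.ndarray:
        """12-number serialisation (row-major rotation, then translation)."""
        return np.concatenate([self.rotation.ravel(), self.translation])

    @classmethod
    def from_flat(cls, values) -> "RigidTransform":
        v = np.asarray(values, dtype=float)
        if v.shape != (12,):
            raise ValueError("expected 12 numbers")
        return cls(v[:9].reshape(3, 3), v[9:])


def compose(t2: RigidTransform, t1: RigidTransform) -> RigidTransform:
    """The transform equivalent to applying ``t1`` first, then ``t2``."""
    return RigidTransform(t2.rotation @ t1.rotation,
                          t2.rotation @ t1.translation + t2.translation)


# ---------------------------------------------------------------------------
# PDB I/O (fixed-column ATOM/TER/END subset)
# ---------------------------------------------------------------------------

def load_pdb(text: str, roles: dict[str, str] | None = None,
             keep_hydrogens: bool = False) -> Complex:
    """Parse a PDB-format string into a :class:`Complex`.

    Only ``ATOM`` records are read; ``TER``/``END``/headers are skipped.
    Alternate locations keep the first-listed conformer (an atom name that
    already exists in the current residue is dropped).  Hydrogens are dropped
    unless ``keep_hydrogens`` is set.

    Raises :class:`PDBParseError` (with the offending line number) for
    malformed ATOM records or input without any ATOM record.
    """
    chains: dict[str, list[Residue]] = {}
    current: Residue | None = None
    n_atoms = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith("ATOM"):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: ATOM record too short")
        try:
            name = line[12:16].strip()
            resname = line[17:20].strip()
            chain_id = line[21].strip()
            author_pos = int(line[22:26])
            icode = line[26].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: malformed ATOM record ({exc})") from exc
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = next((c for c in name if c.isalpha()), "C")
        if element in ("H", "D") and not keep_hydrogens:
            continue
        if not chain_id:
            chain_id = "A"
        if current is None or current.key != (chain_id, author_pos, icode):
            current = Residue(chain_id, author_pos, resname, icode=icode)
            chains.setdefault(chain_id, []).append(current)
        if current.get_atom(name) is not None:
            continue  # keep-first altloc rule
        current.atoms.append(Atom(name, element, np.array([x, y, z])))
        n_atoms += 1
    if n_atoms == 0:
        raise PDBParseError("line 0: no ATOM records in input")
    return Complex(chains, roles or {})


def save_pdb(cx: Complex) -> str:
    """Serialise a :class:`Complex` as fixed-column PDB text.

    Coordinates are written with 3 decimals; a ``TER`` record separates
    chains and the file ends with ``END``.
    """
    if cx.n_residues() == 0:
        raise ValueError("cannot save an empty complex")
    out = io.StringIO()
    serial = 0
    for cid, residues in cx.chains.items():
        if len(cid) != 1:
            raise ValueError(f"chain id {cid!r} must be a single character")
        for res in residues:
            for atom in res.atoms:
                serial += 1
                name = atom.name
                # PDB atom-name column convention
                if len(name) < 4 and len(atom.element) == 1:
                    name = " " + name
                x, y, z = atom.position
                out.write(
                    f"ATOM  {serial:5d} {name:<4s} {res.aa3:<3s} {cid}"
                    f"{res.author_pos:4d}{res.icode or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}\n"
                )
        serial += 1
        out.write(f"TER   {serial:5d}\n")
    out.write("END\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# rigid motions
# ---------------------------------------------------------------------------

def transform_apply(cx: Complex, chain_ids, t: RigidTransform) -> Complex:
    """Return a copy of ``cx`` with ``t`` applied to the listed chains."""
    chain_ids = set(chain_ids)
    unknown = chain_ids - set(cx.chains)
    if unknown:
        raise KeyError(f"unknown chain id(s): {sorted(unknown)}")
    new = cx.copy()
    for cid in chain_ids:
        for res in new.chains[cid]:
            for atom in res.atoms:
                atom.position = t.apply(atom.position)
    return new


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray
                     ) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Returns the optimal :class:`RigidTransform` and the residual RMSD in
    Angstrom.  Requires at least three non-collinear point pairs.
    """
    m = np.asarray(moving, dtype=float)
    f = np.asarray(fixed, dtype=float)
    if m.shape != f.shape or m.ndim != 2 or m.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    n = m.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 point pairs")
    cm, cf = m.mean(axis=0), f.mean(axis=0)
    mc, fc = m - cm, f - cf
    for label, pts in (("moving", mc), ("fixed", fc)):
        sv = np.linalg.svd(pts, compute_uv=False)
        if sv[1] <= 1e-8 * max(sv[0], 1.0):
            raise DegenerateGeometryError(f"{label} points are collinear")
    h = mc.T @ fc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cf - rot @ cm
    t = RigidTransform(rot, trans)
    rmsd = float(np.sqrt(np.mean(np.sum((t.apply(m) - f) ** 2, axis=1))))
    return t, rmsd


# ---------------------------------------------------------------------------
# numbering map
# ---------------------------------------------------------------------------

def read_numbering_map(text: str) -> list[dict]:
    """Parse a tab-separated numbering map.

    Columns: ``chain_id``, ``author_pos``, ``imgt_label``, ``annotation``
    with annotation in {CDRH1..CDRL3, Vernier, FR}.  A header line is
    detected and skipped.
    """
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "chain_id":
            continue
        if len(parts) != 4:
            raise ValueError(f"numbering map line {lineno}: expected 4 columns")
        rows.append({
            "chain_id": parts[0],
            "author_pos": int(parts[1]),
            "imgt_label": parts[2],
            "annotation": parts[3],
        })
    return rows


def apply_numbering_map(cx: Complex, rows: list[dict]) -> None:
    """Attach IMGT labels and CDR/Vernier annotations to residues in place."""
    seen: dict[str, set[str]] = {}
    for row in rows:
        cid = row["chain_id"]
        if cid not in cx.chains:
            continue
        label = row["imgt_label"]
        if label in seen.setdefault(cid, set()):
            raise ValueError(f"duplicate IMGT label {label!r} in chain {cid!r}")
        seen[cid].add(label)
        res = cx.get_residue(cid, row["author_pos"])
        res.imgt_label = label
        res.annotations.add(row["annotation"])


# ---------------------------------------------------------------------------
# complex surgery helpers
# ---------------------------------------------------------------------------

def merge_complexes(*parts: Complex) -> Complex:
    """Combine complexes with disjoint chain ids into one (copies residues)."""
    chains: dict[str, list[Residue]] = {}
    roles: dict[str, str] = {}
    for part in parts:
        for cid, residues in part.chains.items():
            if cid in chains:
                raise ValueError(f"duplicate chain id {cid!r} while merging")
            chains[cid] = [r.copy() for r in residues]
        roles.update(part.roles)
    return Complex(chains, roles)


def subcomplex(cx: Complex, chain_ids) -> Complex:
    """A view-like complex restricted to the given chains (shares residues).

    Intended for read-only use (e.g. per-side SASA).
    """
    chain_ids = list(chain_ids)
    return Complex({cid: cx.chains[cid] for cid in chain_ids},
                   {cid: cx.roles[cid] for cid in chain_ids if cid in cx.roles})
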