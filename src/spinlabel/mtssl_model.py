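"""The MTSSL (R1) side-chain model: geometry, attachment, torsion kinematics.

MTSSL attaches to a cysteine through a disulfide bridge and carries a
2,2,5,5-tetramethyl-pyrroline-N-oxyl ring at the end of the linker.  Five
rotatable bonds (chi1..chi5) separate the protein backbone from the ring, so
the unpaired electron — localized on the nitroxide N-O group — can sit
anywhere in a large tether-in-a-cone volume more than 7 A from the C-alpha.
This module defines the label's atoms, bonds and torsions, attaches the
template to a residue by backbone superposition, and converts between chi
vectors and Cartesian conformers.

The template's reference coordinates are generated from ideal internal
coordinates (standard bond lengths and angles) at import time, so the
geometry is reproducible and carries no provenance from any particular
crystal structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from ._geometry import dihedral_deg, ideal_cb, kabsch, place_internal, rotate_about_axis
from .structure_io import Atom, SiteRef, Structure, select_residue

__all__ = [
    "TorsionDef",
    "LabelTemplate",
    "AttachedLabel",
    "Conformer",
    "mtssl_template",
    "attach",
    "apply_torsions",
    "measure_torsions",
    "normalize_chi",
    "template_to_text",
    "template_from_text",
]


@dataclass(frozen=True)
class TorsionDef:
    """One rotatable bond: dihedral quadruple (a, b, c, d) and the atoms moved.

    Changing the angle rotates ``rotating_set`` about the b-c bond.
    """

    name: str
    quadruple: tuple[str, str, str, str]
    rotating_set: frozenset[str]


@dataclass
class Conformer:
    """One placed label conformation."""

    chi: np.ndarray | None
    coordinates: np.ndarray  # (n_atoms, 3), ordered as LabelTemplate.atom_names
    clash_count: int = 0
    contact_count: int | None = None
    snuggly: bool | None = None


@dataclass
class LabelTemplate:
    """Atoms, bonds, torsions and anchor frame of a spin label."""

    residue_name: str
    atom_names: list[str]
    elements: list[str]
    coordinates: np.ndarray  # reference geometry, (n_atoms, 3)
    bonds: list[tuple[str, str]]
    torsions: list[TorsionDef]
    anchor_names: tuple[str, str, str]
    spin_center_name: str
    side_chain_names: list[str]
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {n: i for i, n in enumerate(self.atom_names)}
        if len(self.torsions) != 5:
            raise ValueError("an MTSSL-style template must define exactly 5 torsions")
        for k in range(len(self.torsions) - 1):
            outer = self.torsions[k].rotating_set
            inner = self.torsions[k + 1].rotating_set
            if not (inner < outer):
                raise ValueError(
                    f"rotating set of {self.torsions[k + 1].name} must be strictly "
                    f"contained in that of {self.torsions[k].name}"
                )
        for t in self.torsions:
            if self.spin_center_name not in t.rotating_set:
                raise ValueError("spin center must move under every torsion")

    def index(self, name: str) -> int:
        return self._index[name]

    def positions(self, coords: np.ndarray, names) -> np.ndarray:
        return coords[[self._index[n] for n in names]]

    def bond_graph_distances(self) -> np.ndarray:
        """Matrix of bond-graph separations (number of bonds) between atoms."""
        n = len(self.atom_names)
        rows, cols = [], []
        for a, b in self.bonds:
            i, j = self._index[a], self._index[b]
            rows += [i, j]
            cols += [j, i]
        graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        return shortest_path(graph, method="BF", unweighted=True)

    def nonbonded_pairs(self, min_separation: int = 4) -> np.ndarray:
        """Index pairs separated by at least ``min_separation`` bonds."""
        d = self.bond_graph_distances()
        i, j = np.triu_indices(len(self.atom_names), k=1)
        keep = d[i, j] >= min_separation
        return np.stack([i[keep], j[keep]], axis=1)


@dataclass
class AttachedLabel:
    """A template rigidly placed onto one labeling site."""

    site: SiteRef
    template: LabelTemplate
    base_coordinates: np.ndarray
    anchor_rmsd: float
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Built-in MTSSL template, generated from ideal internal coordinates.
# Internal-coordinate rows: (name, element, ref_a, ref_b, ref_c, bond, angle,
# dihedral). The first three atoms seed the frame directly.

_CHAIN_ZMATRIX = [
    # side-chain linker; dihedrals here are the template's intrinsic chi values
    ("SG", "S", "N", "CA", "CB", 1.810, 114.0, 180.0),   # chi1
    ("SD", "S", "CA", "CB", "SG", 2.030, 104.0, 180.0),  # chi2
    ("CE", "C", "CB", "SG", "SD", 1.810, 104.0, 180.0),  # chi3
    ("C3", "C", "SG", "SD", "CE", 1.500, 114.0, 180.0),  # chi4
    # pyrroline ring, planar; chi5 is the ring twist about CE-C3
    ("C4", "C", "SD", "CE", "C3", 1.330, 124.0, 90.0),   # chi5
    ("C5", "C", "CE", "C3", "C4", 1.505, 112.0, 180.0),
    ("N1", "N", "C3", "C4", "C5", 1.480, 100.5, 0.0),
    ("C2", "C", "C4", "C5", "N1", 1.480, 114.0, 0.0),
    ("O1", "O", "C4", "C5", "N1", 1.270, 123.0, 180.0),
    # gem-dimethyls, tetrahedral, above/below the ring plane
    ("C6", "C", "C3", "C4", "C5", 1.520, 112.0, 119.0),
    ("C7", "C", "C3", "C4", "C5", 1.520, 112.0, -119.0),
    ("C8", "C", "C5", "N1", "C2", 1.520, 112.0, 119.0),
    ("C9", "C", "C5", "N1", "C2", 1.520, 112.0, -119.0),
]

_BONDS = [
    ("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB"),
    ("CB", "SG"), ("SG", "SD"), ("SD", "CE"), ("CE", "C3"),
    ("C3", "C4"), ("C4", "C5"), ("C5", "N1"), ("N1", "C2"), ("C2", "C3"),
    ("N1", "O1"),
    ("C5", "C6"), ("C5", "C7"), ("C2", "C8"), ("C2", "C9"),
]

_TORSION_QUADS = {
    "chi1": ("N", "CA", "CB", "SG"),
    "chi2": ("CA", "CB", "SG", "SD"),
    "chi3": ("CB", "SG", "SD", "CE"),
    "chi4": ("SG", "SD", "CE", "C3"),
    "chi5": ("SD", "CE", "C3", "C4"),
}

_SIDE_CHAIN = ["SG", "SD", "CE", "C3", "C4", "C5", "N1", "C2", "O1", "C6", "C7", "C8", "C9"]


def _build_reference_coordinates() -> tuple[list[str], list[str], np.ndarray]:
    coords: dict[str, np.ndarray] = {}
    elements: dict[str, str] = {}
    # backbone seed: CA at origin, N on x, C in the xy-plane
    coords["CA"] = np.zeros(3)
    coords["N"] = np.array([1.458, 0.0, 0.0])
    coords["C"] = place_internal(
        np.array([1.0, 1.0, 0.0]), coords["N"], coords["CA"], 1.525, 111.0, 120.0
    )
    coords["O"] = place_internal(coords["N"], coords["CA"], coords["C"], 1.231, 120.5, 180.0)
    coords["CB"] = ideal_cb(coords["N"], coords["CA"], coords["C"])
    elements.update({"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"})
    for name, element, a, b, c, bond, angle, dihedral in _CHAIN_ZMATRIX:
        coords[name] = place_internal(coords[a], coords[b], coords[c], bond, angle, dihedral)
        elements[name] = element
    names = ["N", "CA", "C", "O", "CB"] + [row[0] for row in _CHAIN_ZMATRIX]
    xyz = np.array([coords[n] for n in names])
    return names, [elements[n] for n in names], xyz


def _rotating_sets(names: list[str], bonds, quads) -> dict[str, frozenset[str]]:
    """Atoms on the far side of each torsion's b-c bond (breadth-first)."""
    adj: dict[str, set[str]] = {n: set() for n in names}
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)
    out = {}
    for tname, (a, b, c, d) in quads.items():
        seen = {b, c}
        stack = [c]
        moved = set()
        while stack:
            cur = stack.pop()
            for nxt in adj[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    moved.add(nxt)
                    stack.append(nxt)
        out[tname] = frozenset(moved)
    return out


def mtssl_template() -> LabelTemplate:
    """The built-in MTSSL (R1 side chain) template.

    Backbone N, CA, C, O plus CB anchor the label to the residue; the side
    chain runs CB-SG-SD-CE into the nitroxide ring (C3, C4, C5, N1, C2 with
    the N1-O1 nitroxide and four ring methyls). The spin center used for
    distance prediction is the nitroxide nitrogen N1.
    """
    names, elements, xyz = _build_reference_coordinates()
    sets = _rotating_sets(names, _BONDS, _TORSION_QUADS)
    torsions = [
        TorsionDef(name=k, quadruple=_TORSION_QUADS[k], rotating_set=sets[k])
        for k in ("chi1", "chi2", "chi3", "chi4", "chi5")
    ]
    return LabelTemplate(
        residue_name="R1A",
        atom_names=names,
        elements=elements,
        coordinates=xyz,
        bonds=list(_BONDS),
        torsions=torsions,
        anchor_names=("N", "CA", "CB"),
        spin_center_name="N1",
        side_chain_names=list(_SIDE_CHAIN),
    )


def normalize_chi(chi) -> np.ndarray:
    """Reduce a 5-vector of torsion angles to [0, 360) degrees."""
    chi = np.asarray(chi, dtype=float)
    if chi.shape != (5,):
        raise ValueError("chi must have exactly 5 angles")
    return np.mod(chi, 360.0)


def _anchor_positions(residue_atoms: list[Atom], needed: tuple[str, ...]) -> np.ndarray:
    by_name = {a.name: a for a in residue_atoms}
    positions = []
    for name in needed:
        if name == "CB" and "CB" not in by_name:
            # glycine: construct an ideal CB from the backbone frame
            try:
                positions.append(
                    ideal_cb(
                        by_name["N"].position,
                        by_name["CA"].position,
                        by_name["C"].position,
                    )
                )
                continue
            except KeyError:
                raise ValueError("cannot anchor label: missing backbone atoms") from None
        if name not in by_name:
            raise ValueError(f"cannot anchor label: residue lacks atom {name}")
        positions.append(by_name[name].position)
    return np.array(positions)


def attach(t: LabelTemplate, s: Structure, site: SiteRef) -> AttachedLabel:
    """Rigidly superpose the template's anchor atoms onto the site's backbone.

    The residue's own side chain plays no further role: labeling implies the
    site was (or will be) mutated to a labeled cysteine.
    """
    residue = select_residue(s, site)
    target = _anchor_positions(residue, t.anchor_names)
    source = t.positions(t.coordinates, t.anchor_names)
    rot, trans, rmsd = kabsch(target, source)
    placed = t.coordinates @ rot.T + trans
    warnings = []
    if rmsd > 0.5:
        warnings.append(
            f"anchor rmsd {rmsd:.2f} A at {site}: backbone geometry deviates "
            "strongly from ideal"
        )
    return AttachedLabel(
        site=site, template=t, base_coordinates=placed, anchor_rmsd=rmsd, warnings=warnings
    )


def apply_torsions(a: AttachedLabel, chi) -> Conformer:
    """Build the conformer with the given chi1..chi5 (degrees).

    Each torsion is set by rotating its rotating set about the b-c bond, in
    order chi1 -> chi5; bond lengths and angles of the template are exact
    rigid-motion invariants of this operation.
    """
    chi = normalize_chi(chi)
    t = a.template
    coords = a.base_coordinates.copy()
    for k, torsion in enumerate(t.torsions):
        ia, ib, ic, id_ = (t.index(n) for n in torsion.quadruple)
        current = dihedral_deg(coords[ia], coords[ib], coords[ic], coords[id_])
        delta = chi[k] - current
        moving = [t.index(n) for n in torsion.rotating_set]
        coords[moving] = rotate_about_axis(
            coords[moving], coords[ib], coords[ic] - coords[ib], delta
        )
    return Conformer(chi=chi, coordinates=coords)


def measure_torsions(c: Conformer, t: LabelTemplate) -> np.ndarray:
    """Measure chi1..chi5 of a conformer, each reported in [0, 360) degrees."""
    out = []
    for torsion in t.torsions:
        ia, ib, ic, id_ = (t.index(n) for n in torsion.quadruple)
        out.append(
            dihedral_deg(
                c.coordinates[ia], c.coordinates[ib], c.coordinates[ic], c.coordinates[id_]
            )
        )
    return np.mod(np.array(out), 360.0)


# --- simple text serialization so alternative labels can be defined ---------


def template_to_text(t: LabelTemplate) -> str:
    """Serialize a template: atom table, bond list, torsion list, roles.

    Sections are introduced by ``[atoms]`` (name element x y z),
    ``[bonds]`` (name name), ``[torsions]`` (name a b c d) and ``[roles]``
    (residue_name / anchors / spin_center / side_chain key-value lines).
    """
    lines = ["[atoms]"]
    for name, element, xyz in zip(t.atom_names, t.elements, t.coordinates):
        lines.append(f"{name} {element} {xyz[0]:.4f} {xyz[1]:.4f} {xyz[2]:.4f}")
    lines.append("[bonds]")
    lines += [f"{a} {b}" for a, b in t.bonds]
    lines.append("[torsions]")
    lines += [f"{tor.name} {' '.join(tor.quadruple)}" for tor in t.torsions]
    lines.append("[roles]")
    lines.append(f"residue_name {t.residue_name}")
    lines.append(f"anchors {' '.join(t.anchor_names)}")
    lines.append(f"spin_center {t.spin_center_name}")
    lines.append(f"side_chain {' '.join(t.side_chain_names)}")
    return "\n".join(lines) + "\n"


def template_from_text(text: str) -> LabelTemplate:
    section = None
    names: list[str] = []
    elements: list[str] = []
    coords: list[list[float]] = []
    bonds: list[tuple[str, str]] = []
    quads: dict[str, tuple[str, str, str, str]] = {}
    roles: dict[str, list[str]] = {}
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("["):
            section = line.strip("[]")
            continue
        parts = line.split()
        if section == "atoms":
            names.append(parts[0])
            elements.append(parts[1])
            coords.append([float(x) for x in parts[2:5]])
        elif section == "bonds":
            bonds.append((parts[0], parts[1]))
        elif section == "torsions":
            quads[parts[0]] = tuple(parts[1:5])
        elif section == "roles":
            roles[parts[0]] = parts[1:]
    sets = _rotating_sets(names, bonds, quads)
    torsions = [TorsionDef(name=k, quadruple=quads[k], rotating_set=sets[k]) for k in quads]
    return LabelTemplate(
        residue_name=roles["residue_name"][0],
        atom_names=names,
        elements=elements,
        coordinates=np.array(coords),
        bonds=bonds,
        torsions=torsions,
        anchor_names=tuple(roles["anchors"]),
        spin_center_name=roles["spin_center"][0],
        side_chain_names=roles["side_chain"],
    )
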