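"""Synthetic structures for exercising every part of the labeling pipeline.

Each generator returns a small, fully deterministic :class:`Structure` that
isolates one geometric situation a labeling site can present:

* ``make_gxg_peptide`` — an exposed site with essentially no occlusion
  (a Gly-Ala-Gly tripeptide in an extended conformation);
* ``make_cone_pocket`` — the site at the apex of a cone-shaped cavity, as
  found for labels buried in channel vestibules; the aperture controls how
  much of the torsion space survives the clash test;
* ``make_wall`` — a dense plane of pseudo-atoms the label cannot penetrate;
* ``make_cage`` — a closed spherical shell that forbids every conformer;
* ``make_symmetric_dimer`` — two copies of the tripeptide related by an
  exact rotation about z, for testing ensemble transfer between
  symmetry-equivalent sites.

Barrier pseudo-atoms are carbon records spaced 1.5 A apart, so they are
impervious to the label at every legal vdW cutoff (>= 2.6 A).
"""

from __future__ import annotations

import numpy as np

from ._geometry import ideal_cb, place_internal, rotate_about_axis
from .structure_io import Atom, SiteRef, Structure

__all__ = [
    "make_gxg_peptide",
    "make_cone_pocket",
    "make_wall",
    "make_cage",
    "make_symmetric_dimer",
    "GXG_SITE",
]

GXG_SITE = SiteRef("A", 2)

# extended-chain backbone torsions
_PHI, _PSI, _OMEGA = -140.0, 135.0, 180.0


def _backbone_chain(n_res: int) -> list[dict[str, np.ndarray]]:
    """Ideal extended backbone: N, CA, C, O per residue."""
    residues: list[dict[str, np.ndarray]] = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    c = place_internal(np.array([0.0, 1.0, 0.0]), n, ca, 1.525, 111.0, 60.0)
    for i in range(n_res):
        res = {"N": n, "CA": ca, "C": c}
        res["O"] = place_internal(n, ca, c, 1.231, 120.5, _PSI - 180.0)
        residues.append(res)
        if i + 1 < n_res:
            n_next = place_internal(n, ca, c, 1.329, 116.2, _PSI)
            ca_next = place_internal(ca, c, n_next, 1.458, 121.7, _OMEGA)
            c_next = place_internal(c, n_next, ca_next, 1.525, 111.0, _PHI)
            n, ca, c = n_next, ca_next, c_next
    return residues


def make_gxg_peptide() -> Structure:
    """Gly-Ala-Gly tripeptide, extended; the middle residue is the labeling site."""
    residues = _backbone_chain(3)
    names = ["GLY", "ALA", "GLY"]
    atoms: list[Atom] = []
    for i, (res, res_name) in enumerate(zip(residues, names), start=1):
        order = ["N", "CA", "C", "O"]
        coords = dict(res)
        if res_name == "ALA":
            coords["CB"] = ideal_cb(res["N"], res["CA"], res["C"])
            order.append("CB")
        for atom_name in order:
            element = atom_name[0]
            atoms.append(
                Atom(
                    name=atom_name,
                    element=element,
                    position=coords[atom_name],
                    residue_number=i,
                    insertion_code="",
                    chain_id="A",
                    residue_name=res_name,
                )
            )
    return Structure(atoms=atoms, source_id="gxg")


def _pseudo_atoms(points: np.ndarray, start_residue: int = 100, chain: str = "X") -> list[Atom]:
    return [
        Atom(
            name="C",
            element="C",
            position=p,
            residue_number=start_residue + i,
            insertion_code="",
            chain_id=chain,
            residue_name="PSD",
        )
        for i, p in enumerate(points)
    ]


def _site_frame(peptide: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Apex (CA of the site) and outward side-chain axis (CA->CB) of the site."""
    atoms = {a.name: a for a in peptide.atoms if a.residue_number == GXG_SITE.residue_number}
    ca = atoms["CA"].position
    cb = atoms["CB"].position
    axis = cb - ca
    return ca, axis / np.linalg.norm(axis)


def make_cone_pocket(
    aperture_deg: float = 90.0, depth: float = 14.0, clearance: float = 6.0
) -> Structure:
    """Tripeptide whose labeling site sits at the apex of a cone-shaped cavity.

    Pseudo-atoms tile a funnel around the site's side-chain direction: at
    height ``d`` along the axis the wall radius is
    ``clearance + d * tan(aperture_deg / 2)``, with ~1.5 A point spacing up
    to ``depth``.  The clearance leaves a core the tether itself can occupy
    at every aperture, so the aperture alone controls how much of the
    label's torsion space survives the clash test: narrower cones accept
    fewer conformers and confine the chi angles more tightly.
    """
    if not (10.0 < aperture_deg < 180.0):
        raise ValueError("aperture must be in (10, 180) degrees")
    if depth <= 0 or clearance <= 0:
        raise ValueError("depth and clearance must be positive")
    peptide = make_gxg_peptide()
    apex, axis = _site_frame(peptide)
    half = np.radians(aperture_deg / 2.0)
    # orthonormal frame around the axis
    seed = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(seed, axis)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, seed)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    points = []
    spacing = 1.5
    for d in np.arange(0.0, depth, spacing * np.cos(half)):
        ring_r = clearance + d * np.tan(half)
        n_pts = max(6, int(np.ceil(2 * np.pi * ring_r / spacing)))
        for theta in np.arange(n_pts) * (2 * np.pi / n_pts):
            points.append(apex + d * axis + ring_r * (np.cos(theta) * u + np.sin(theta) * v))
    atoms = peptide.atoms + _pseudo_atoms(np.array(points))
    return Structure(atoms=atoms, source_id=f"cone{aperture_deg:.0f}")


def make_wall(offset: float = 10.0) -> Structure:
    """Tripeptide plus a solid plane of pseudo-atoms at x = offset.

    The plane extends +-15 A in y and z with 1.5 A spacing; the peptide is
    translated so the labeling site's CA sits at the origin with its
    side-chain axis along +x, pointing at the wall.
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    peptide = make_gxg_peptide()
    apex, axis = _site_frame(peptide)
    # rotate the peptide so the side-chain axis is +x, then center the apex
    target = np.array([1.0, 0.0, 0.0])
    rot_axis = np.cross(axis, target)
    coords = peptide.coordinates()
    if np.linalg.norm(rot_axis) > 1e-9:
        angle = np.degrees(np.arccos(np.clip(np.dot(axis, target), -1, 1)))
        coords = rotate_about_axis(coords, apex, rot_axis, angle)
    coords = coords - apex
    moved = [
        Atom(
            name=a.name, element=a.element, position=p, residue_number=a.residue_number,
            insertion_code=a.insertion_code, chain_id=a.chain_id, residue_name=a.residue_name,
        )
        for a, p in zip(peptide.atoms, coords)
    ]
    grid = np.arange(-15.0, 15.0 + 1e-9, 1.5)
    yy, zz = np.meshgrid(grid, grid)
    points = np.stack([np.full(yy.size, offset), yy.ravel(), zz.ravel()], axis=1)
    return Structure(atoms=moved + _pseudo_atoms(points), source_id="wall")


def make_cage(radius: float = 2.5) -> Structure:
    """Tripeptide enclosed in a closed spherical shell of pseudo-atoms.

    The shell is centered on the site's CB with ~1.5 A point spacing
    (Fibonacci sphere); at small radii no label conformer can avoid it.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    peptide = make_gxg_peptide()
    atoms = {a.name: a for a in peptide.atoms if a.residue_number == GXG_SITE.residue_number}
    center = atoms["CB"].position
    n_pts = max(20, int(np.ceil(4 * np.pi * radius**2 / (1.5**2) * 4)))
    i = np.arange(n_pts)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    zf = 1.0 - 2.0 * (i + 0.5) / n_pts
    rf = np.sqrt(1.0 - zf**2)
    theta = golden * i
    points = center + radius * np.stack(
        [rf * np.cos(theta), rf * np.sin(theta), zf], axis=1
    )
    return Structure(atoms=peptide.atoms + _pseudo_atoms(points), source_id="cage")


def make_symmetric_dimer(rotation_deg: float = 180.0, axis_offset: float = 15.0) -> Structure:
    """Two copies of the tripeptide related by an exact rotation about z.

    The rotation axis is vertical through (axis_offset, 0, 0); chain A is the
    original, chain B the rotated copy. Backbone superposition of the two
    sites recovers the generating rotation exactly.
    """
    peptide = make_gxg_peptide()
    coords = peptide.coordinates()
    origin = np.array([axis_offset, 0.0, 0.0])
    rotated = rotate_about_axis(coords, origin, np.array([0.0, 0.0, 1.0]), rotation_deg)
    atoms = list(peptide.atoms)
    for a, p in zip(peptide.atoms, rotated):
        atoms.append(
            Atom(
                name=a.name, element=a.element, position=p,
                residue_number=a.residue_number, insertion_code=a.insertion_code,
                chain_id="B", residue_name=a.residue_name,
            )
        )
    return Structure(atoms=atoms, source_id=f"dimer{rotation_deg:.0f}")
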