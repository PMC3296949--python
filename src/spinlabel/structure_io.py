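"""Reading, selecting and writing protein structures (PDB format).

The module keeps a deliberately small in-memory model: a :class:`Structure`
is an ordered list of :class:`Atom` records from one coordinate MODEL.
Parsing is delegated to :mod:`gemmi`; alternate locations are resolved to
the highest-occupancy conformer (ties prefer altloc ``A``), and a
:class:`SpatialIndex` provides the radius queries used by clash and contact
tests.

Boundary convention: radius queries are closed balls (distance <= r).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "SiteRef",
    "SpatialIndex",
    "PDBParseError",
    "SiteError",
    "read_pdb",
    "read_models",
    "select_residue",
    "environment_for_site",
    "build_spatial_index",
    "query_radius",
    "write_pdb",
    "write_ensemble_pdb",
    "read_ensemble_pdb",
]

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input."""


class SiteError(KeyError):
    """Raised when a site reference does not resolve to exactly one residue."""


@dataclass(frozen=True)
class Atom:
    """One atom record (coordinates in angstroms)."""

    name: str
    element: str
    position: np.ndarray
    residue_number: int
    insertion_code: str
    chain_id: str
    residue_name: str
    is_hetero: bool = False

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")


@dataclass
class Structure:
    """Atoms of one coordinate model."""

    atoms: list[Atom]
    model_number: int = 1
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def residues(self) -> dict[tuple[str, int, str], list[Atom]]:
        """Atoms grouped by (chain_id, residue_number, insertion_code), in file order."""
        out: dict[tuple[str, int, str], list[Atom]] = {}
        for a in self.atoms:
            out.setdefault((a.chain_id, a.residue_number, a.insertion_code), []).append(a)
        return out


@dataclass(frozen=True)
class SiteRef:
    """Reference to one residue: chain id, author residue number, insertion code."""

    chain_id: str
    residue_number: int
    insertion_code: str = ""

    def __str__(self) -> str:
        icode = self.insertion_code or ""
        return f"{self.chain_id}:{self.residue_number}{icode}"

    @classmethod
    def parse(cls, text: str) -> "SiteRef":
        """Parse ``CHAIN:RESNUM[ICODE]`` (e.g. ``A:65`` or ``A:65B``)."""
        chain, _, res = text.partition(":")
        if not chain or not res:
            raise ValueError(f"cannot parse site {text!r}; expected CHAIN:RESNUM")
        icode = ""
        if res and res[-1].isalpha():
            icode = res[-1]
            res = res[:-1]
        return cls(chain_id=chain, residue_number=int(res), insertion_code=icode)


def _validate_coordinate_fields(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")) and len(line) >= 54:
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBParseError(
                        f"malformed coordinate field {line[lo:hi]!r} on line {lineno}"
                    ) from None


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Pick one location per atom name: highest occupancy, ties prefer 'A'."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for atom in residue:
        by_name.setdefault(atom.name, []).append(atom)
    chosen = []
    for alts in by_name.values():
        alts.sort(key=lambda a: (-a.occ, a.altloc if a.altloc != "\0" else "A"))
        chosen.append(alts[0])
    return chosen


def _convert_model(model: gemmi.Model, source_id: str, model_number: int) -> Structure:
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            het = residue.het_flag == "H"
            for atom in _resolve_altlocs(residue):
                atoms.append(
                    Atom(
                        name=atom.name,
                        element=atom.element.name,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        residue_number=residue.seqid.num,
                        insertion_code=(residue.seqid.icode or "").strip(),
                        chain_id=chain.name,
                        residue_name=residue.name,
                        is_hetero=het,
                    )
                )
    return Structure(atoms=atoms, model_number=model_number, source_id=source_id)


def _read_gemmi(source: str | Path) -> tuple[gemmi.Structure, str]:
    text: str
    source_id: str
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        path = Path(source)
        text = path.read_text()
        source_id = path.stem
    else:
        text = source
        source_id = "inline"
    _validate_coordinate_fields(text)
    st = gemmi.read_pdb_string(text)
    return st, source_id


def read_pdb(source: str | Path, model_index: int = 0) -> Structure:
    """Read PDB text or a file path; returns one coordinate model.

    ``model_index`` selects among MODEL blocks of multi-model (e.g. NMR)
    entries; the default is the first model. ANISOU/CONECT records are
    ignored; alternate locations are resolved to the highest-occupancy copy.
    """
    st, source_id = _read_gemmi(source)
    if len(st) == 0:
        raise PDBParseError("no coordinate models in input")
    if not (0 <= model_index < len(st)):
        raise IndexError(f"model_index {model_index} out of range (file has {len(st)} models)")
    model = st[model_index]
    structure = _convert_model(model, source_id, model_index + 1)
    if len(structure) == 0:
        raise PDBParseError("no ATOM records in input")
    return structure


def read_models(source: str | Path) -> list[Structure]:
    """Read every MODEL of a multi-model PDB file."""
    st, source_id = _read_gemmi(source)
    models = [_convert_model(m, source_id, i + 1) for i, m in enumerate(st)]
    models = [m for m in models if len(m) > 0]
    if not models:
        raise PDBParseError("no ATOM records in input")
    return models


def select_residue(s: Structure, site: SiteRef) -> list[Atom]:
    """All atoms of the residue ``site`` refers to."""
    matches = [
        a
        for a in s.atoms
        if a.chain_id == site.chain_id
        and a.residue_number == site.residue_number
        and a.insertion_code == (site.insertion_code or "")
    ]
    if not matches:
        raise SiteError(f"site not found: {site}")
    names = {a.residue_name for a in matches}
    if len(names) > 1:
        raise SiteError(f"ambiguous site {site}: residues {sorted(names)}")
    return matches


def environment_for_site(
    s: Structure,
    site: SiteRef,
    include_hetero: bool = False,
    include_waters: bool = False,
) -> list[Atom]:
    """Heavy atoms a label at ``site`` can clash with.

    Excludes every atom of the labeled residue itself, all hydrogens, and
    (by default) waters and hetero records such as ligands and ions.
    """
    select_residue(s, site)  # validates resolution
    env = []
    for a in s.atoms:
        if (
            a.chain_id == site.chain_id
            and a.residue_number == site.residue_number
            and a.insertion_code == (site.insertion_code or "")
        ):
            continue
        if a.is_hydrogen:
            continue
        if a.residue_name in WATER_NAMES:
            if not include_waters:
                continue
        elif a.is_hetero and not include_hetero:
            continue
        env.append(a)
    return env


class SpatialIndex:
    """Uniform hash grid over atom positions for fast radius queries.

    Queries return exactly the atoms within a closed ball (d <= r) and are
    verified against a brute-force scan in the test suite.
    """

    def __init__(self, atoms: Sequence[Atom], cell_size: float = 4.0):
        if cell_size <= 0:
            raise ValueError("cell_size must be positive")
        self.cell_size = float(cell_size)
        self.atoms = list(atoms)
        self.coords = (
            np.array([a.position for a in self.atoms])
            if self.atoms
            else np.empty((0, 3))
        )
        self.cells: dict[tuple[int, int, int], np.ndarray] = {}
        if self.atoms:
            keys = np.floor(self.coords / self.cell_size).astype(np.int64)
            buckets: dict[tuple[int, int, int], list[int]] = {}
            for i, key in enumerate(map(tuple, keys)):
                buckets.setdefault(key, []).append(i)
            self.cells = {k: np.array(v, dtype=np.intp) for k, v in buckets.items()}

    def __len__(self) -> int:
        return len(self.atoms)

    def _candidates(self, point: np.ndarray, r: float) -> np.ndarray:
        lo = np.floor((point - r) / self.cell_size).astype(np.int64)
        hi = np.floor((point + r) / self.cell_size).astype(np.int64)
        idx: list[np.ndarray] = []
        for i in range(lo[0], hi[0] + 1):
            for j in range(lo[1], hi[1] + 1):
                for k in range(lo[2], hi[2] + 1):
                    hit = self.cells.get((i, j, k))
                    if hit is not None:
                        idx.append(hit)
        if not idx:
            return np.empty(0, dtype=np.intp)
        return np.concatenate(idx)

    def query(self, point: np.ndarray, r: float) -> tuple[np.ndarray, np.ndarray]:
        """Indices and distances of atoms with distance <= r from ``point``."""
        if r <= 0:
            raise ValueError("query radius must be positive")
        point = np.asarray(point, dtype=float)
        cand = self._candidates(point, r)
        if cand.size == 0:
            return cand, np.empty(0)
        d = np.linalg.norm(self.coords[cand] - point, axis=1)
        keep = d <= r
        return cand[keep], d[keep]

    def query_radius(self, point: np.ndarray, r: float) -> list[Atom]:
        idx, _ = self.query(point, r)
        return [self.atoms[i] for i in idx]

    def query_many(self, points: np.ndarray, r: float) -> dict[int, float]:
        """Minimum distance to any of ``points``, for every atom within r of one.

        Maps atom index -> min over the query points of the distance, keeping
        only atoms whose minimum is <= r. This is the primitive behind both
        the clash count and the contact-shell count.
        """
        best: dict[int, float] = {}
        for p in np.asarray(points, dtype=float):
            idx, d = self.query(p, r)
            for i, di in zip(idx.tolist(), d.tolist()):
                if i not in best or di < best[i]:
                    best[i] = di
        return best


def build_spatial_index(atoms: Iterable[Atom], cell_size: float = 4.0) -> SpatialIndex:
    return SpatialIndex(list(atoms), cell_size)


def query_radius(idx: SpatialIndex, point: np.ndarray, r: float) -> list[Atom]:
    return idx.query_radius(point, r)


_ELEMENT_TO_PDB = {"N": " N", "C": " C", "O": " O", "S": " S", "H": " H"}


def _format_atom_line(
    serial: int,
    name: str,
    res_name: str,
    chain_id: str,
    res_num: int,
    icode: str,
    pos: np.ndarray,
    element: str,
    hetero: bool = False,
) -> str:
    record = "HETATM" if hetero else "ATOM  "
    if len(name) < 4 and len(element) == 1:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    return (
        f"{record}{serial:>5d} {name_field} {res_name:<3s}{chain_id[:1] or 'A':>2s}"
        f"{res_num:>4d}{icode or ' ':1s}   "
        f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write a single-model structure as plain ATOM/HETATM records."""
    lines = []
    for i, a in enumerate(s.atoms, start=1):
        lines.append(
            _format_atom_line(
                i,
                a.name,
                a.residue_name,
                a.chain_id,
                a.residue_number,
                a.insertion_code,
                a.position,
                a.element,
                a.is_hetero,
            )
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


SNUGGLY_REMARK = "REMARK 999 SNUGGLY"


def write_ensemble_pdb(ensemble, path: str | Path) -> None:
    """Write an ensemble of label conformers as a multi-MODEL PDB file.

    One MODEL per conformer; the label residue keeps the template's residue
    name and the labeled site's chain/number. A header REMARK per model
    records whether the conformer carries the snuggly-fit flag.
    """
    if not ensemble.conformers:
        raise ValueError("cannot write an empty ensemble")
    template = ensemble.template
    site = ensemble.site
    lines = [f"REMARK 999 LABEL ENSEMBLE SITE {site} N {len(ensemble.conformers)}"]
    for m, conf in enumerate(ensemble.conformers, start=1):
        flag = "TRUE" if conf.snuggly else "FALSE"
        lines.append(f"{SNUGGLY_REMARK} MODEL {m:>4d} {flag}")
    for m, conf in enumerate(ensemble.conformers, start=1):
        lines.append(f"MODEL     {m:>4d}")
        for i, (name, element) in enumerate(
            zip(template.atom_names, template.elements), start=1
        ):
            lines.append(
                _format_atom_line(
                    i,
                    name,
                    template.residue_name,
                    site.chain_id,
                    site.residue_number,
                    site.insertion_code,
                    conf.coordinates[i - 1],
                    element,
                )
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ensemble_pdb(path: str | Path):
    """Re-read a multi-MODEL ensemble file written by :func:`write_ensemble_pdb`.

    Returns an :class:`~spinlabel.conformer_search.Ensemble` whose conformers
    carry coordinates, re-measured chi angles, and the snuggly flags recorded
    in the file's REMARK lines. Search parameters are not recoverable from
    the file and are left unset.
    """
    from .conformer_search import Ensemble
    from .mtssl_model import Conformer, measure_torsions, mtssl_template

    path = Path(path)
    text = path.read_text()
    flags: dict[int, bool] = {}
    for line in text.splitlines():
        if line.startswith(SNUGGLY_REMARK):
            parts = line.split()
            flags[int(parts[4])] = parts[5] == "TRUE"
    models = read_models(path)
    template = mtssl_template()
    conformers = []
    site = None
    for m, model in enumerate(models, start=1):
        by_name = {a.name: a for a in model.atoms}
        missing = [n for n in template.atom_names if n not in by_name]
        if missing:
            raise PDBParseError(f"model {m} lacks label atoms: {missing}")
        coords = np.array([by_name[n].position for n in template.atom_names])
        first = model.atoms[0]
        site = SiteRef(first.chain_id, first.residue_number, first.insertion_code)
        conf = Conformer(chi=None, coordinates=coords, clash_count=0)
        conf.chi = measure_torsions(conf, template)
        conf.snuggly = flags.get(m)
        conformers.append(conf)
    return Ensemble(
        site=site,
        conformers=conformers,
        params=None,
        trials_run=len(conformers),
        source_structure_id=path.stem,
        template=template,
    )
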