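"""Transfer of a conformer ensemble to a symmetry-related site ("copy and move").

In a symmetric multimer every protomer presents the same local environment,
so a search needs to run only once per unique site: the resulting ensemble
is transplanted onto the equivalent residue of another chain by a rigid
superposition of the two residues' backbone frames.  The move is an exact
isometry, so all intra-ensemble geometry (and hence any distance
distribution computed from it) is preserved.

For pseudo-symmetric assemblies the target environment may differ; passing
``revalidate=True`` re-runs the external clash test at the target site and
drops violating conformers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from ._geometry import ideal_cb, kabsch
from .conformer_search import Ensemble, clash_count
from .mtssl_model import Conformer
from .structure_io import SiteRef, SpatialIndex, Structure, environment_for_site, select_residue

__all__ = ["RigidTransform", "superpose", "copy_move"]

logger = logging.getLogger(__name__)

_ANCHOR_NAMES = ("N", "CA", "C", "O", "CB")


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    fit_rmsd: float

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        if r.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("reflections are not rigid motions of a chiral molecule")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation


def superpose(ref_points: np.ndarray, mov_points: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid transform mapping ``mov_points`` onto ``ref_points``."""
    rot, trans, rmsd = kabsch(np.asarray(ref_points), np.asarray(mov_points))
    return RigidTransform(rotation=rot, translation=trans, fit_rmsd=rmsd)


def _backbone_frame(s: Structure, site: SiteRef) -> np.ndarray:
    atoms = {a.name: a for a in select_residue(s, site)}
    missing = [n for n in ("N", "CA", "C") if n not in atoms]
    if missing:
        raise ValueError(f"site {site} lacks backbone atoms {missing}")
    points = []
    for name in _ANCHOR_NAMES:
        if name in atoms:
            points.append(atoms[name].position)
        elif name == "CB":
            points.append(
                ideal_cb(atoms["N"].position, atoms["CA"].position, atoms["C"].position)
            )
        elif name == "O":
            continue  # tolerate a missing carbonyl O on either side
        else:
            raise ValueError(f"site {site} lacks backbone atom {name}")
    return np.array(points)


def copy_move(
    e: Ensemble,
    s: Structure,
    target: SiteRef,
    revalidate: bool = False,
) -> tuple[Ensemble, RigidTransform]:
    """Transplant ensemble ``e`` onto ``target`` via backbone superposition.

    The transform maps the source residue's backbone (N, CA, C, O, CB; an
    ideal CB is constructed for glycine) onto the target's.  With
    ``revalidate`` the external clash test is repeated against the target
    site's environment and violating conformers are dropped.
    """
    source_frame = _backbone_frame(s, e.site)
    target_frame = _backbone_frame(s, target)
    if len(source_frame) != len(target_frame):
        # can differ only through a missing carbonyl O on one side
        n = min(len(source_frame), len(target_frame))
        source_frame, target_frame = source_frame[:n], target_frame[:n]
    transform = superpose(target_frame, source_frame)
    if transform.fit_rmsd > 0.5:
        logger.warning(
            "backbone fit rmsd %.2f A moving %s -> %s: sites may not be "
            "symmetry-equivalent", transform.fit_rmsd, e.site, target,
        )
    moved = [
        Conformer(
            chi=None if c.chi is None else c.chi.copy(),
            coordinates=transform.apply(c.coordinates),
            clash_count=c.clash_count,
            contact_count=c.contact_count,
            snuggly=c.snuggly,
        )
        for c in e.conformers
    ]
    if revalidate:
        cutoff = e.params.vdw_cutoff if e.params is not None else 3.4
        allowed = e.params.allowed_clashes if e.params is not None else 0
        env = SpatialIndex(environment_for_site(s, target), cell_size=4.0)
        kept = []
        for c in moved:
            n_clash = clash_count(c, env, cutoff, e.template)
            if n_clash <= allowed:
                c.clash_count = n_clash
                kept.append(c)
        dropped = len(moved) - len(kept)
        if dropped:
            logger.info(
                "revalidation at %s dropped %d of %d conformers", target, dropped, len(moved)
            )
        moved = kept
    new_ensemble = replace(e, site=target, conformers=moved, attached=None)
    return new_ensemble, transform
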