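"""The "snuggly fit" surface-complementarity heuristic.

A label conformation seated in a surface pocket touches many protein atoms
just beyond clash range; one pointing into solvent touches few.  For every
accepted conformer the number of environment atoms in the shell between the
vdW cutoff and 4.5 A of any label side-chain atom is counted, and the
conformer with the most such contacts — plus every conformer with at least
75% of that maximum — is flagged as a snuggly fit.  The heuristic only makes
sense on a densely sampled ensemble, so by default it insists on a
painstaking-depth search.

This is a flag for human inspection, not a score: it sums contacts without
distinguishing attractive from repulsive interactions, and has been observed
to work better for hydrophobic pockets than for polar crevices.
"""

from __future__ import annotations

from dataclasses import dataclass

from .conformer_search import Ensemble
from .mtssl_model import Conformer, LabelTemplate
from .structure_io import SpatialIndex

__all__ = ["ContactParams", "contact_count", "flag_snuggly"]


@dataclass(frozen=True)
class ContactParams:
    shell_radius: float = 4.5
    flag_fraction: float = 0.75
    requires_painstaking: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.flag_fraction <= 1.0):
            raise ValueError("flag_fraction must be in (0, 1]")
        if self.shell_radius <= 0:
            raise ValueError("shell_radius must be positive")


def contact_count(
    c: Conformer,
    env: SpatialIndex,
    vdw_cutoff: float,
    shell: float,
    template: LabelTemplate,
) -> int:
    """Environment atoms in the near-contact shell of a non-clashing conformer.

    Counts distinct environment atoms whose minimum distance to any label
    side-chain atom lies in [vdw_cutoff, shell]; both boundaries are
    inclusive (an atom exactly at the cutoff is a contact, not a clash).
    """
    if shell <= vdw_cutoff:
        raise ValueError("contact shell must be larger than the vdW cutoff")
    points = template.positions(c.coordinates, template.side_chain_names)
    near = env.query_many(points, shell)
    return sum(1 for d in near.values() if d >= vdw_cutoff)


def flag_snuggly(
    e: Ensemble, env: SpatialIndex, p: ContactParams = ContactParams()
) -> Ensemble:
    """Fill contact counts and snuggly flags for every conformer in place.

    The maximum contact count M over the ensemble defines the threshold
    ``flag_fraction * M``; a conformer is flagged iff its count reaches it.
    When M == 0 (nothing near the shell anywhere) no conformer is flagged.
    """
    if (
        p.requires_painstaking
        and e.params is not None
        and e.params.thoroughness != "painstaking"
    ):
        raise ValueError(
            "snuggly-fit flagging needs a painstaking-depth ensemble; sparser "
            "searches do not sample the conformational space well enough"
        )
    if not e.conformers:
        return e
    vdw = e.params.vdw_cutoff if e.params is not None else 3.4
    for conf in e.conformers:
        conf.contact_count = contact_count(conf, env, vdw, p.shell_radius, e.template)
    apply_snuggly_threshold(e.conformers, p.flag_fraction)
    return e


def apply_snuggly_threshold(conformers, flag_fraction: float = 0.75) -> None:
    """Set snuggly flags from already-computed contact counts (in place)."""
    if not conformers:
        return
    maximum = max(c.contact_count for c in conformers)
    threshold = flag_fraction * maximum
    for c in conformers:
        c.snuggly = maximum > 0 and c.contact_count >= threshold
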