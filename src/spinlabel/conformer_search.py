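"""Randomized conformer search with clash rejection.

The search draws chi1..chi5 independently and uniformly on [0, 360) — no
rotamer-probability weighting and no energy model — and keeps a conformation
only if it has no internal clash and at most ``allowed_clashes`` contacts
with the protein closer than the vdW cutoff.  Search depth is set by a
thoroughness preset: painstaking (1500 trials), thorough (300), normal (90)
or quick (10).

The vdW cutoff (default 3.4 A, a typical carbon-carbon packing distance in
a hydrophobic core) applies uniformly to all element pairs; it may be
lowered to 2.6 A (a hydrogen-bond heavy-atom distance) and the allowed-clash
budget raised to 5 to tolerate conformational uncertainty at the labeling
site (flexible surface residues, NMR or homology models).  Values outside
those ranges require an explicit override and are reported with a caution.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np

from .mtssl_model import (
    AttachedLabel,
    Conformer,
    LabelTemplate,
    attach,
    apply_torsions,
    mtssl_template,
)
from .structure_io import SiteRef, SpatialIndex, Structure, environment_for_site

__all__ = [
    "THOROUGHNESS_TRIALS",
    "SearchParams",
    "Ensemble",
    "clash_count",
    "internal_clash",
    "run_search",
    "ZERO_CONFORMER_ADVICE",
]

logger = logging.getLogger(__name__)

THOROUGHNESS_TRIALS = {"painstaking": 1500, "thorough": 300, "normal": 90, "quick": 10}

VDW_CUTOFF_RANGE = (2.6, 3.4)
ALLOWED_CLASHES_RANGE = (0, 5)

ZERO_CONFORMER_ADVICE = (
    "no conformers found: the site may be too occluded for MTSSL. If the site "
    "is known to label experimentally, consider lowering --vdw (down to 2.6), "
    "raising --clashes (up to 5), or increasing the thoroughness; judge such "
    "deviations from the defaults critically."
)


@dataclass(frozen=True)
class SearchParams:
    """User-facing knobs of the conformer search."""

    thoroughness: str = "normal"
    vdw_cutoff: float = 3.4
    allowed_clashes: int = 0
    internal_clash_cutoff: float = 2.0
    seed: int = 0
    trials: int | None = None  # overrides the thoroughness preset when set
    force: bool = False  # permit out-of-range cutoff/clash values, with a caution

    def __post_init__(self) -> None:
        if self.thoroughness not in THOROUGHNESS_TRIALS:
            raise ValueError(
                f"unknown thoroughness {self.thoroughness!r}; "
                f"choose from {sorted(THOROUGHNESS_TRIALS)}"
            )
        lo, hi = VDW_CUTOFF_RANGE
        if not (lo <= self.vdw_cutoff <= hi):
            if not self.force:
                raise ValueError(
                    f"vdw_cutoff {self.vdw_cutoff} outside the supported range "
                    f"[{lo}, {hi}]; pass force=True to override"
                )
            logger.warning(
                "caution: vdw_cutoff %.2f is outside [%.1f, %.1f]",
                self.vdw_cutoff, lo, hi,
            )
        lo_c, hi_c = ALLOWED_CLASHES_RANGE
        if not (lo_c <= self.allowed_clashes <= hi_c):
            if not self.force:
                raise ValueError(
                    f"allowed_clashes {self.allowed_clashes} outside [{lo_c}, {hi_c}]; "
                    "pass force=True to override"
                )
            logger.warning(
                "caution: allowed_clashes %d is outside [%d, %d]",
                self.allowed_clashes, lo_c, hi_c,
            )
        if self.internal_clash_cutoff <= 0:
            raise ValueError("internal_clash_cutoff must be positive")

    @property
    def n_trials(self) -> int:
        return self.trials if self.trials is not None else THOROUGHNESS_TRIALS[self.thoroughness]


@dataclass
class Ensemble:
    """Accepted conformers at one site, with the parameters that produced them."""

    site: SiteRef
    conformers: list[Conformer]
    params: SearchParams | None
    trials_run: int
    source_structure_id: str = ""
    template: LabelTemplate = field(default_factory=mtssl_template)
    attached: AttachedLabel | None = None

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def acceptance_fraction(self) -> float:
        return len(self.conformers) / self.trials_run if self.trials_run else 0.0

    def spin_centers(self) -> np.ndarray:
        idx = self.template.index(self.template.spin_center_name)
        return np.array([c.coordinates[idx] for c in self.conformers])

    def chi_matrix(self) -> np.ndarray:
        return np.array([c.chi for c in self.conformers])

    def subset(self, snuggly_only: bool) -> "Ensemble":
        confs = (
            [c for c in self.conformers if c.snuggly]
            if snuggly_only
            else list(self.conformers)
        )
        return replace(self, conformers=confs)


def clash_count(
    c: Conformer, env: SpatialIndex, cutoff: float, template: LabelTemplate
) -> int:
    """Number of environment atoms strictly closer than ``cutoff`` to the label.

    Only the side-chain atoms of the label are tested (the anchor/backbone
    atoms coincide with the labeled residue); each environment atom counts at
    most once, however many label atoms it approaches. An atom at exactly the
    cutoff distance is NOT a clash.
    """
    points = template.positions(c.coordinates, template.side_chain_names)
    near = env.query_many(points, cutoff)
    return sum(1 for d in near.values() if d < cutoff)


def internal_clash(c: Conformer, cutoff: float, template: LabelTemplate) -> bool:
    """True iff two label atoms more than 3 bonds apart come closer than ``cutoff``.

    The bond-graph exemption keeps 1-2/1-3/1-4 neighbors, whose proximity is
    dictated by fixed bonds and angles, from ever counting as clashes.
    """
    pairs = _nonbonded_pairs(template)
    d = np.linalg.norm(c.coordinates[pairs[:, 0]] - c.coordinates[pairs[:, 1]], axis=1)
    return bool(np.any(d < cutoff))


_pair_cache: dict[int, np.ndarray] = {}


def _nonbonded_pairs(template: LabelTemplate) -> np.ndarray:
    key = id(template)
    if key not in _pair_cache:
        _pair_cache[key] = template.nonbonded_pairs(min_separation=4)
    return _pair_cache[key]


def run_search(
    s: Structure,
    site: SiteRef,
    p: SearchParams,
    template: LabelTemplate | None = None,
    environment: SpatialIndex | None = None,
) -> Ensemble:
    """Run the full randomized search at one site.

    Attaches the template, then for each trial draws five fresh uniform
    angles, builds the conformer and keeps it iff it passes the internal and
    external clash tests. One seeded generator drives the whole search and
    each trial consumes exactly five draws, so a given seed reproduces the
    identical trial sequence regardless of which trials are accepted.
    """
    template = template or mtssl_template()
    attached = attach(template, s, site)
    if environment is None:
        environment = SpatialIndex(environment_for_site(s, site), cell_size=4.0)
    rng = np.random.default_rng(p.seed)
    accepted: list[Conformer] = []
    t0 = time.perf_counter()
    n = p.n_trials
    for _ in range(n):
        chi = rng.uniform(0.0, 360.0, size=5)
        conf = apply_torsions(attached, chi)
        if internal_clash(conf, p.internal_clash_cutoff, template):
            continue
        n_clash = clash_count(conf, environment, p.vdw_cutoff, template)
        if n_clash > p.allowed_clashes:
            continue
        conf.clash_count = n_clash
        accepted.append(conf)
    elapsed = time.perf_counter() - t0
    logger.info(
        "search %s: %d/%d conformers accepted (vdw %.2f, clashes <= %d) in %.2f s",
        site, len(accepted), n, p.vdw_cutoff, p.allowed_clashes, elapsed,
    )
    if not accepted:
        logger.warning("%s", ZERO_CONFORMER_ADVICE)
    return Ensemble(
        site=site,
        conformers=accepted,
        params=p,
        trials_run=n,
        source_structure_id=s.source_id,
        template=template,
        attached=attached,
    )
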