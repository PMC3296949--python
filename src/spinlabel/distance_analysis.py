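"""Inter-label distance distributions and summaries.

Once two sites carry conformer ensembles, every ordered pair of conformers
contributes one N-N distance (between the nitroxide nitrogens, where the
unpaired electron resides), giving n_a * n_b values.  All conformers weigh
equally — the search makes no rotamer-probability assumptions, so neither
does the distribution.  Summaries are the arithmetic mean, median, shortest
and longest distance, the C-beta/C-beta distance between the two sites, and
whether the mean falls inside the 15-80 A window accessible to PELDOR/DEER.

The C-beta/C-beta distance on its own underestimates the inter-spin distance
by about 6.5 A on average (the label tether points outward); adding 6.5 A to
it is a serviceable first guess when no ensemble has been computed yet
(:func:`quick_estimate`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .conformer_search import Ensemble
from ._geometry import ideal_cb
from .structure_io import SiteRef, Structure, select_residue

__all__ = [
    "PELDOR_WINDOW",
    "DistanceSet",
    "DistanceStats",
    "Histogram",
    "pairwise_nn_distances",
    "summarize",
    "make_histogram",
    "render_histogram",
    "modal_distance",
    "cb_distance",
    "quick_estimate",
    "chi_histogram",
]

PELDOR_WINDOW = (15.0, 80.0)


@dataclass
class DistanceSet:
    """All-pairs spin-center distances between two ensembles (angstroms)."""

    values: np.ndarray
    site_a: SiteRef
    site_b: SiteRef
    n_a: int
    n_b: int
    subset_label: str = "all"

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class DistanceStats:
    mean: float
    median: float
    min: float
    max: float
    cb_cb: float
    in_peldor_window: bool


@dataclass
class Histogram:
    """Half-open bins [lo, hi); the last edge is exclusive like all others."""

    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def normalized(self) -> np.ndarray:
        """Counts scaled to [0, 1] (for overlaying distributions of different size)."""
        top = self.counts.max()
        return self.counts / top if top > 0 else self.counts.astype(float)


def pairwise_nn_distances(a: Ensemble, b: Ensemble) -> DistanceSet:
    """Euclidean N-N distance for every ordered conformer pair (i in a, j in b)."""
    if not a.conformers or not b.conformers:
        raise ValueError("label site first: both ensembles must be non-empty")
    ca = a.spin_centers()
    cb = b.spin_centers()
    diff = ca[:, None, :] - cb[None, :, :]
    values = np.sqrt((diff**2).sum(axis=2)).ravel()
    return DistanceSet(
        values=values,
        site_a=a.site,
        site_b=b.site,
        n_a=len(a.conformers),
        n_b=len(b.conformers),
    )


def cb_distance(s: Structure, a: SiteRef, b: SiteRef) -> float:
    """C-beta/C-beta distance between two sites (ideal CB constructed for Gly)."""
    positions = []
    for site in (a, b):
        atoms = {at.name: at for at in select_residue(s, site)}
        if "CB" in atoms:
            positions.append(atoms["CB"].position)
        else:
            try:
                positions.append(
                    ideal_cb(atoms["N"].position, atoms["CA"].position, atoms["C"].position)
                )
            except KeyError:
                raise ValueError(
                    f"site {site} lacks CB and a complete backbone to construct one"
                ) from None
    return float(np.linalg.norm(positions[0] - positions[1]))


def quick_estimate(cb: float) -> float:
    """Rule-of-thumb inter-label distance: C-beta/C-beta distance plus 6.5 A."""
    if cb < 0:
        raise ValueError("a distance cannot be negative")
    return cb + 6.5


def summarize(d: DistanceSet, s: Structure) -> DistanceStats:
    """Mean / median / extremes of the distance set plus the CB-CB reference."""
    if len(d) == 0:
        raise ValueError("empty distance set")
    values = np.asarray(d.values, dtype=float)
    mean = float(values.mean())
    lo, hi = PELDOR_WINDOW
    return DistanceStats(
        mean=mean,
        median=float(np.median(values)),
        min=float(values.min()),
        max=float(values.max()),
        cb_cb=cb_distance(s, d.site_a, d.site_b),
        in_peldor_window=lo <= mean <= hi,
    )


def make_histogram(values, bin_width: float = 1.0) -> Histogram:
    """Histogram with half-open bins [k*w, (k+1)*w) covering the data range.

    A value exactly on an edge belongs to the upper bin. ``values`` may be a
    DistanceSet or any array of distances.
    """
    if isinstance(values, DistanceSet):
        values = values.values
    values = np.asarray(values, dtype=float)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if values.size == 0:
        raise ValueError("cannot histogram an empty set")
    lo = math.floor(values.min() / bin_width)
    hi = math.floor(values.max() / bin_width)  # index of the bin holding the max
    idx = np.floor(values / bin_width).astype(int) - lo
    counts = np.bincount(idx, minlength=hi - lo + 1)
    edges = (np.arange(lo, hi + 2)) * bin_width
    return Histogram(bin_edges=edges, counts=counts)


def render_histogram(h: Histogram, width: int = 50) -> str:
    """Text rendering: one row per bin with a proportional bar."""
    top = max(1, int(h.counts.max()))
    rows = []
    for lo, hi, n in zip(h.bin_edges[:-1], h.bin_edges[1:], h.counts):
        bar = "#" * round(width * n / top)
        rows.append(f"{lo:7.1f} -{hi:7.1f} A |{bar:<{width}s}| {n}")
    return "\n".join(rows)


def modal_distance(h: Histogram) -> float:
    """Center of the most populated bin; ties broken toward the shorter distance."""
    k = int(np.argmax(h.counts))  # argmax takes the first = shortest on ties
    return float(h.centers[k])


def chi_histogram(e: Ensemble, bin_width_deg: float = 30.0) -> dict[str, Histogram]:
    """Circular histogram of each torsion angle over the ensemble.

    Bins tile [0, 360) half-open; per-angle counts sum to the ensemble size.
    """
    if not e.conformers:
        raise ValueError("empty ensemble")
    if bin_width_deg <= 0 or 360.0 % bin_width_deg > 1e-9:
        raise ValueError("bin width must evenly divide 360 degrees")
    nbins = int(round(360.0 / bin_width_deg))
    edges = np.arange(nbins + 1) * bin_width_deg
    chis = e.chi_matrix()
    out = {}
    for k, torsion in enumerate(e.template.torsions):
        idx = np.floor(np.mod(chis[:, k], 360.0) / bin_width_deg).astype(int)
        counts = np.bincount(idx, minlength=nbins)
        out[torsion.name] = Histogram(bin_edges=edges.copy(), counts=counts)
    return out


def plot_chi_polar(histograms: dict[str, Histogram], path) -> None:
    """Polar bar plots of the chi-angle histograms, one panel per angle."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(
        1, len(histograms), subplot_kw={"projection": "polar"}, figsize=(3 * len(histograms), 3)
    )
    if len(histograms) == 1:
        axes = [axes]
    for ax, (name, h) in zip(axes, histograms.items()):
        theta = np.radians(h.centers)
        widths = np.radians(np.diff(h.bin_edges))
        ax.bar(theta, h.counts, width=widths, bottom=0.0, alpha=0.7)
        ax.set_title(name)
        ax.set_yticklabels([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
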