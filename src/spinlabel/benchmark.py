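"""Benchmark against published inter-label EPR distances.

The package ships a 52-pair table of PELDOR/CW-EPR distances for doubly
spin-labeled T4 lysozyme and (H3-H4)2 histone, together with the search
settings each pair needs (a few occluded sites only label with a lowered
vdW cutoff or a deeper search).  Structures are user-supplied — the tool
never downloads anything: place ``2lzm.pdb`` and ``1tzy.pdb`` in a directory
and run ``spinlabel benchmark``.

For every pair the residual is Delta_r = prediction - experiment, evaluated
for two predictors: the mean of the simulated N-N distance distribution and
the bare C-beta/C-beta distance.  The summary reports the mean residual
<Delta_r> and its standard deviation for both.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .conformer_search import SearchParams, run_search
from .distance_analysis import cb_distance, pairwise_nn_distances
from .structure_io import SiteRef, read_pdb

__all__ = ["BenchmarkPair", "BenchmarkReport", "load_pairs", "run_benchmark"]


@dataclass(frozen=True)
class BenchmarkPair:
    dataset: str
    pdb: str
    site_a: SiteRef
    site_b: SiteRef
    epr_mean: float
    epr_peak: float | None
    thoroughness: str
    vdw: float


@dataclass
class PairResult:
    pair: BenchmarkPair
    predicted_mean: float | None
    cb_cb: float
    n_a: int
    n_b: int


@dataclass
class BenchmarkReport:
    results: list[PairResult]

    def _residuals(self, predictor: str) -> np.ndarray:
        vals = []
        for r in self.results:
            pred = r.predicted_mean if predictor == "label" else r.cb_cb
            if pred is not None:
                vals.append(pred - r.pair.epr_mean)
        return np.array(vals)

    def summary(self) -> dict[str, float]:
        label = self._residuals("label")
        cb = self._residuals("cb")
        return {
            "n_pairs": len(self.results),
            "n_predicted": len(label),
            "label_mean_dr": float(label.mean()) if label.size else float("nan"),
            "label_sigma_dr": float(label.std(ddof=1)) if label.size > 1 else float("nan"),
            "cb_mean_dr": float(cb.mean()),
            "cb_sigma_dr": float(cb.std(ddof=1)),
        }


def load_pairs(path: str | Path | None = None) -> list[BenchmarkPair]:
    """Load the pairs table (the packaged 52-pair set by default)."""
    if path is None:
        source = resources.files("spinlabel.data").joinpath("benchmark_pairs.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    pairs = []
    for row in reader:
        pairs.append(
            BenchmarkPair(
                dataset=row["dataset"],
                pdb=row["pdb"],
                site_a=SiteRef(row["chain_a"], int(row["res_a"])),
                site_b=SiteRef(row["chain_b"], int(row["res_b"])),
                epr_mean=float(row["epr_mean"]),
                epr_peak=float(row["epr_peak"]) if row["epr_peak"] else None,
                thoroughness=row["thoroughness"],
                vdw=float(row["vdw"]),
            )
        )
    return pairs


def _find_structure(structures_dir: Path, pdb_id: str) -> Path | None:
    for candidate in (f"{pdb_id}.pdb", f"{pdb_id.upper()}.pdb", f"pdb{pdb_id}.ent"):
        p = structures_dir / candidate
        if p.exists():
            return p
    return None


def _remap(site: SiteRef, chain_map: dict[str, str] | None) -> SiteRef:
    if chain_map and site.chain_id in chain_map:
        return SiteRef(chain_map[site.chain_id], site.residue_number, site.insertion_code)
    return site


def run_benchmark(
    structures_dir: str | Path,
    pairs: list[BenchmarkPair] | None = None,
    seed: int = 0,
    chain_map: dict[str, str] | None = None,
    progress=None,
) -> BenchmarkReport:
    """Label every benchmark site and compare predictions to experiment.

    Raises FileNotFoundError listing the structures to fetch when any needed
    PDB file is absent from ``structures_dir``.
    """
    structures_dir = Path(structures_dir)
    pairs = pairs if pairs is not None else load_pairs()
    needed = sorted({p.pdb for p in pairs})
    missing = [pdb for pdb in needed if _find_structure(structures_dir, pdb) is None]
    if missing:
        raise FileNotFoundError(
            "missing structure files; fetch these PDB entries into "
            f"{structures_dir}: " + ", ".join(f"{m}.pdb" for m in missing)
        )
    structures = {pdb: read_pdb(_find_structure(structures_dir, pdb)) for pdb in needed}
    ensembles: dict[tuple, object] = {}
    results = []
    for pair in pairs:
        s = structures[pair.pdb]
        site_a = _remap(pair.site_a, chain_map)
        site_b = _remap(pair.site_b, chain_map)
        params = SearchParams(
            thoroughness=pair.thoroughness, vdw_cutoff=pair.vdw, seed=seed
        )
        ens = []
        for site in (site_a, site_b):
            key = (pair.pdb, str(site), pair.thoroughness, pair.vdw)
            if key not in ensembles:
                ensembles[key] = run_search(s, site, params)
            ens.append(ensembles[key])
        if len(ens[0]) and len(ens[1]):
            predicted = float(pairwise_nn_distances(ens[0], ens[1]).values.mean())
        else:
            predicted = None
        results.append(
            PairResult(
                pair=pair,
                predicted_mean=predicted,
                cb_cb=cb_distance(s, site_a, site_b),
                n_a=len(ens[0]),
                n_b=len(ens[1]),
            )
        )
        if progress is not None:
            progress(pair, results[-1])
    return BenchmarkReport(results=results)
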