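"""Degree-grid assignment and per-cell diversity, endemism and differentiation.

Samples are binned into square cells of a degree grid (half-open intervals,
floor rule), and for every retained cell (at least three individuals) four
statistics are computed per species:

* ``NAe`` -- Nielsen et al. (2003) unbiased effective number of haplotypes,
* ``He`` -- gene diversity corrected for sample size (Nei),
* ``v``  -- gene diversity with ordered alleles: the mean mutation-step
  distance between two individuals drawn from the cell,
* ``End`` -- haplotypic endemism: the proportion of individuals carrying
  haplotypes whose total geographic range (maximum great-circle distance
  among all carriers, dataset-wide) is at most a threshold (200 km default).

Global differentiation among cells follows the Pons & Petit (1996)
estimators: ``GST`` from haplotype frequencies alone and ``NST`` weighting
haplotype pairs by their mutation-step distance.  A permutation test on the
haplotype labels of the distance matrix tests for phylogeographic signal
(``NST > GST``: related haplotypes co-occur geographically).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import HaplotypeSet, InsufficientDataError, SampleTable
from .network import MutationDistanceMatrix

log = logging.getLogger(__name__)

__all__ = [
    "EARTH_RADIUS_KM",
    "GridSpec",
    "GridAssignment",
    "DifferentiationResult",
    "MonomorphicError",
    "great_circle_km",
    "assign_cells",
    "gene_diversity",
    "nielsen_effective_haplotypes",
    "ordered_gene_diversity",
    "pons_petit_components",
    "cell_diversity",
    "haplotype_ranges",
    "cell_endemism",
    "cell_statistics",
    "global_differentiation",
]

EARTH_RADIUS_KM = 6371.0


class MonomorphicError(ValueError):
    """Raised when differentiation is undefined (no global diversity)."""


def great_circle_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine great-circle distance in km between (lat, lon) points."""
    lat1, lon1 = math.radians(a[0]), math.radians(a[1])
    lat2, lon2 = math.radians(b[0]), math.radians(b[1])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def _pairwise_km(lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    """Full pairwise haversine matrix (vectorised)."""
    lat = np.radians(np.asarray(lats, dtype=float))
    lon = np.radians(np.asarray(lons, dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """A square degree grid: cells of ``cell_size`` degrees anchored at
    ``origin`` (lon0, lat0).  Cells are half-open: a point exactly on an
    upper edge belongs to the next cell."""

    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell size must be > 0")

    def cell_of(self, lat: float, lon: float) -> str:
        ix = int(math.floor((lon - self.origin[0]) / self.cell_size))
        iy = int(math.floor((lat - self.origin[1]) / self.cell_size))
        return f"{ix}_{iy}"


@dataclass(frozen=True)
class GridAssignment:
    """Mapping of samples to grid cells with the per-cell retention rule."""

    grid: GridSpec
    cell_of_sample: Mapping[str, str]
    members: Mapping[str, tuple[str, ...]]
    centroids: Mapping[str, tuple[float, float]]  # cell -> (lat, lon) mean
    min_cell_n: int = 3

    @property
    def retained(self) -> tuple[str, ...]:
        """Cells with at least ``min_cell_n`` members, in sorted order."""
        return tuple(
            sorted(c for c, m in self.members.items() if len(m) >= self.min_cell_n)
        )

    def is_retained(self, cell: str) -> bool:
        return cell in self.members and len(self.members[cell]) >= self.min_cell_n


def assign_cells(
    samples: SampleTable, grid: GridSpec, min_cell_n: int = 3
) -> GridAssignment:
    """Assign every sample to its grid cell (floor rule, half-open intervals).

    Cell centroids are arithmetic means of member coordinates, an acceptable
    approximation at the equatorial latitudes this grid is meant for.
    """
    cell_of_sample: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    for sid in samples.ids:
        lat, lon = samples.coords(sid)
        cell = grid.cell_of(lat, lon)
        cell_of_sample[sid] = cell
        members.setdefault(cell, []).append(sid)
    centroids = {}
    for cell, mem in members.items():
        lats = [samples.coords(s)[0] for s in mem]
        lons = [samples.coords(s)[1] for s in mem]
        centroids[cell] = (float(np.mean(lats)), float(np.mean(lons)))
    return GridAssignment(
        grid=grid,
        cell_of_sample=cell_of_sample,
        members={c: tuple(m) for c, m in members.items()},
        centroids=centroids,
        min_cell_n=min_cell_n,
    )


# ---------------------------------------------------------------------------
# per-cell estimators (pure functions on counts)
# ---------------------------------------------------------------------------


def gene_diversity(counts: Sequence[int]) -> float:
    """Nei's gene diversity corrected for sample size:
    ``He = n/(n-1) (1 - sum p^2)``."""
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    if n < 2:
        raise InsufficientDataError("gene diversity requires n >= 2")
    p = c / n
    return float(n / (n - 1) * (1.0 - np.sum(p * p)))


def nielsen_effective_haplotypes(counts: Sequence[int]) -> float:
    """Nielsen et al. (2003) unbiased effective number of haplotypes:

    ``NAe = (n-1)^2 / [ (sum p^2)(n+1)(n-2) + 3 - n ]``

    Equals 1 for a monomorphic sample and approaches ``1 / sum p^2`` for
    large n with even frequencies.
    """
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    if n < 3:
        raise InsufficientDataError("NAe estimator requires n >= 3")
    s2 = float(np.sum((c / n) ** 2))
    return float((n - 1) ** 2 / (s2 * (n + 1) * (n - 2) + 3 - n))


def ordered_gene_diversity(counts: Sequence[int], pi: np.ndarray) -> float:
    """Gene diversity with ordered alleles: mean mutation steps between two
    individuals drawn without replacement,
    ``v = n/(n-1) sum_{h,g} p_h p_g pi_hg``."""
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    if n < 2:
        raise InsufficientDataError("ordered diversity requires n >= 2")
    p = c / n
    return float(n / (n - 1) * (p @ np.asarray(pi, dtype=float) @ p))


def pons_petit_components(
    P: np.ndarray,
    nk: np.ndarray,
    pi: np.ndarray,
    weighting: str = "equal",
) -> dict[str, float]:
    """Pons & Petit (1996) diversity components for GST/NST.

    Parameters
    ----------
    P : (cells x haplotypes) observed frequency matrix (rows sum to 1)
    nk : per-cell sample sizes
    pi : haplotype mutation-step distance matrix
    weighting : "equal" (each cell weighted equally, the cited estimator's
        convention and the default) or "size" (cells weighted by sample size)

    Returns ``hS``, ``hT``, ``vS``, ``vT``.  With equal weights the total
    diversities carry the published small-sample correction
    ``hT = 1 - sum(xbar^2) + hS/(n * ntilde)`` with ``ntilde`` the harmonic
    mean sample size; with size weights the exact weighted correction
    ``sum_k w_k^2 h_k / n_k`` is applied.
    """
    P = np.asarray(P, dtype=float)
    nk = np.asarray(nk, dtype=float)
    pi = np.asarray(pi, dtype=float)
    ncell = P.shape[0]
    if ncell < 2:
        raise InsufficientDataError("differentiation requires >= 2 cells")
    corr = nk / (nk - 1.0)
    hk = corr * (1.0 - np.einsum("ki,ki->k", P, P))
    vk = corr * np.einsum("ki,ij,kj->k", P, pi, P)
    if weighting == "equal":
        hS = float(hk.mean())
        vS = float(vk.mean())
        xbar = P.mean(axis=0)
        ntilde = ncell / np.sum(1.0 / nk)
        hT = float(1.0 - xbar @ xbar + hS / (ntilde * ncell))
        vT = float(xbar @ pi @ xbar + vS / (ntilde * ncell))
    elif weighting == "size":
        w = nk / nk.sum()
        hS = float(w @ hk)
        vS = float(w @ vk)
        xbar = w @ P
        hT = float(1.0 - xbar @ xbar + np.sum(w * w * hk / nk))
        vT = float(xbar @ pi @ xbar + np.sum(w * w * vk / nk))
    else:
        raise ValueError("weighting must be 'equal' or 'size'")
    return {"hS": hS, "hT": hT, "vS": vS, "vT": vT}


# ---------------------------------------------------------------------------
# per-cell tables
# ---------------------------------------------------------------------------


def _cell_counts(
    assign: GridAssignment, haps: HaplotypeSet
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Haplotype count matrix over retained cells (hap-assigned members only)."""
    hap_of = haps.assignment()
    idx = {h: i for i, h in enumerate(haps.ids)}
    cells = []
    rows = []
    for cell in assign.retained:
        counts = np.zeros(len(haps.ids))
        for s in assign.members[cell]:
            h = hap_of.get(s)
            if h is not None:
                counts[idx[h]] += 1
        n = counts.sum()
        if n < assign.min_cell_n:
            log.info(
                "cell %s skipped: %d haplotype-assigned members (< %d)",
                cell, int(n), assign.min_cell_n,
            )
            continue
        cells.append(cell)
        rows.append(counts)
    if not cells:
        raise InsufficientDataError("no cell has enough haplotype-assigned members")
    C = np.stack(rows)
    return cells, C, C.sum(axis=1)


def cell_diversity(
    assign: GridAssignment, haps: HaplotypeSet, D: MutationDistanceMatrix
) -> pd.DataFrame:
    """Per retained cell: n, NAe, He and v.  Cells are rows, sorted by id."""
    if tuple(D.ids) != tuple(haps.ids):
        D = D.submatrix(haps.ids)
    cells, C, nk = _cell_counts(assign, haps)
    rows = []
    for i, cell in enumerate(cells):
        counts = C[i][C[i] > 0]
        full = C[i]
        rows.append(
            {
                "cell": cell,
                "n": int(nk[i]),
                "NAe": nielsen_effective_haplotypes(full[full > 0]),
                "He": gene_diversity(full[full > 0]),
                "v": ordered_gene_diversity(full, D.matrix),
            }
        )
    return pd.DataFrame(rows).set_index("cell")


def haplotype_ranges(haps: HaplotypeSet, samples: SampleTable) -> pd.Series:
    """Geographic range of each haplotype: the maximum great-circle distance
    (km) among all its carriers, across the whole dataset.  Singletons have
    range 0."""
    out = {}
    for h in haps.ids:
        carr = haps.carriers[h]
        if len(carr) < 2:
            out[h] = 0.0
            continue
        lats = np.array([samples.coords(s)[0] for s in carr])
        lons = np.array([samples.coords(s)[1] for s in carr])
        out[h] = float(_pairwise_km(lats, lons).max())
    return pd.Series(out, name="range_km")


def cell_endemism(
    assign: GridAssignment,
    haps: HaplotypeSet,
    samples: SampleTable,
    threshold_km: float = 200.0,
) -> tuple[pd.Series, pd.Series]:
    """Per-cell endemism and the per-haplotype range table.

    ``End(cell)`` is the proportion of the cell's (haplotype-assigned)
    members whose haplotype has a dataset-wide range of at most
    ``threshold_km``.  The range is computed over all carrier pairs, not
    per cell: a haplotype whose carriers span more than the threshold is
    not endemic anywhere, even where all of its local carriers co-occur.
    """
    ranges = haplotype_ranges(haps, samples)
    endemic = {h for h in haps.ids if ranges[h] <= threshold_km}
    hap_of = haps.assignment()
    cells, C, nk = _cell_counts(assign, haps)
    end = {}
    for cell in cells:
        mem = [s for s in assign.members[cell] if s in hap_of]
        k = sum(1 for s in mem if hap_of[s] in endemic)
        end[cell] = k / len(mem)
    return pd.Series(end, name="End"), ranges


def cell_statistics(
    assign: GridAssignment,
    haps: HaplotypeSet,
    D: MutationDistanceMatrix,
    samples: SampleTable,
    endemism_km: float = 200.0,
) -> pd.DataFrame:
    """Combined per-cell table: n, NAe, He, v, End."""
    div = cell_diversity(assign, haps, D)
    end, _ = cell_endemism(assign, haps, samples, threshold_km=endemism_km)
    div["End"] = end
    return div


# ---------------------------------------------------------------------------
# global differentiation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DifferentiationResult:
    """GST/NST with components and the NST>GST permutation test."""

    gst: float
    nst: float
    h_s: float
    h_t: float
    v_s: float
    v_t: float
    p_nst_gt_gst: float
    n_perm: int
    seed: int
    n_cells: int
    weighting: str


def global_differentiation(
    assign: GridAssignment,
    haps: HaplotypeSet,
    D: MutationDistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    weighting: str = "equal",
) -> DifferentiationResult:
    """Pons & Petit GST and NST among retained cells, with the
    phylogeographic-signal permutation test.

    The test permutes the haplotype labels on the rows/columns of the
    mutation-distance matrix, leaving the frequency structure untouched, and
    recomputes NST; the one-sided p-value uses the add-one convention
    ``p = (1 + #{NST_perm >= NST_obs}) / (1 + n_perm)``.
    """
    if tuple(D.ids) != tuple(haps.ids):
        D = D.submatrix(haps.ids)
    cells, C, nk = _cell_counts(assign, haps)
    if len(cells) < 2:
        raise InsufficientDataError("differentiation requires >= 2 retained cells")
    P = C / nk[:, None]
    pi = D.matrix.astype(float)
    comp = pons_petit_components(P, nk, pi, weighting=weighting)
    if comp["hT"] <= 1e-12:
        raise MonomorphicError("total gene diversity is zero: GST/NST undefined")
    gst = (comp["hT"] - comp["hS"]) / comp["hT"]
    nst = (comp["vT"] - comp["vS"]) / comp["vT"]

    rng = np.random.default_rng(seed)
    H = pi.shape[0]
    count = 0
    for _ in range(n_perm):
        sig = rng.permutation(H)
        pp = pi[np.ix_(sig, sig)]
        c = pons_petit_components(P, nk, pp, weighting=weighting)
        nst_perm = (c["vT"] - c["vS"]) / c["vT"]
        if nst_perm >= nst - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return DifferentiationResult(
        gst=float(gst),
        nst=float(nst),
        h_s=comp["hS"],
        h_t=comp["hT"],
        v_s=comp["vS"],
        v_t=comp["vT"],
        p_nst_gt_gst=float(p),
        n_perm=n_perm,
        seed=seed,
        n_cells=len(cells),
        weighting=weighting,
    )
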