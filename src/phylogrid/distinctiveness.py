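"""Between-cell phylogenetic distances and standardized distinctiveness.

For each pair of retained cells *i*, *j* the mean mutation-step distance
between one individual drawn from *i* and one from *j* is

    v_ij = sum_{h,g} p_ih p_jg pi_hg        (no self-pair correction),

and d_ij is the great-circle distance between the centroids of the two
cells' members.  Because genetic distance typically decays with geographic
distance, raw v_ij confounds isolation with remoteness; distinctiveness
removes the trend: if a one-sided Mantel test finds a significant positive
correlation between v_ij and ln(d_ij), S'_ij are the residuals of the
ordinary least-squares regression of v_ij on ln(d_ij), otherwise they are
the centred v_ij values.  A cell's distinctiveness S'_i is the mean of
S'_ij over all pairs involving it; high values flag genetically isolated
areas beyond what their geographic position explains.
"""

from __future__ import annotations

import logging
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import HaplotypeSet, SampleTable
from .network import MutationDistanceMatrix
from .gridstats import GridAssignment, _cell_counts, great_circle_km

log = logging.getLogger(__name__)

__all__ = [
    "CellPairMatrix",
    "DistinctivenessResult",
    "MantelResult",
    "InsufficientCellsError",
    "DegenerateGeometryError",
    "between_cell_matrices",
    "mantel_test",
    "distinctiveness_scores",
]


class InsufficientCellsError(ValueError):
    """Fewer than three retained cells: the Mantel decision is meaningless."""


class DegenerateGeometryError(ValueError):
    """Distinct cells with co-located centroids (ln distance undefined)."""


MantelResult = namedtuple("MantelResult", ["r", "p", "n_perm", "alternative"])


@dataclass(frozen=True)
class CellPairMatrix:
    """Pairwise mean mutation steps (v_ij) and centroid distances (d_ij, km)
    between retained cells.  The diagonal of ``v`` holds the uncorrected
    within-cell mean distance and is never used by the statistics."""

    cells: tuple[str, ...]
    v: np.ndarray
    d_km: np.ndarray


def between_cell_matrices(
    assign: GridAssignment,
    haps: HaplotypeSet,
    D: MutationDistanceMatrix,
    samples: SampleTable | None = None,
) -> CellPairMatrix:
    """Build v_ij and d_ij over retained cells.

    ``samples`` is accepted for interface symmetry; centroids come from the
    grid assignment (means of member coordinates).
    """
    if tuple(D.ids) != tuple(haps.ids):
        D = D.submatrix(haps.ids)
    cells, C, nk = _cell_counts(assign, haps)
    if len(cells) < 3:
        raise InsufficientCellsError(
            f"distinctiveness requires >= 3 retained cells, got {len(cells)}"
        )
    P = C / nk[:, None]
    pi = D.matrix.astype(float)
    v = P @ pi @ P.T
    m = len(cells)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d[i, j] = d[j, i] = great_circle_km(
                assign.centroids[cells[i]], assign.centroids[cells[j]]
            )
            if d[i, j] <= 0.0:
                raise DegenerateGeometryError(
                    f"cells {cells[i]} and {cells[j]} have co-located centroids"
                )
    return CellPairMatrix(cells=tuple(cells), v=v, d_km=d)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("zero variance: correlation undefined")
    return float((xc @ yc) / denom)


def mantel_test(
    A: np.ndarray,
    B: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test between two symmetric cell-pair matrices.

    ``r`` is the Pearson correlation over the off-diagonal upper-triangle
    entries.  The null distribution permutes rows and columns of ``B``
    simultaneously; the p-value uses the add-one convention.
    ``alternative`` is "greater" (positive association, used for the
    distance-decay decision) or "two-sided" (used for cross-species
    congruence, where matrices could agree or disagree in either sign).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of identical shape")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    n = A.shape[0]
    iu = np.triu_indices(n, 1)
    a = A[iu]
    r_obs = _pearson(a, B[iu])

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    Bp = B[perms[:, :, None], perms[:, None, :]]  # (n_perm, n, n)
    bp = Bp[:, iu[0], iu[1]]  # (n_perm, n_pairs)
    ac = a - a.mean()
    bc = bp - bp.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac @ ac) * np.einsum("ij,ij->i", bc, bc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r_perm = (bc @ ac) / denom
    r_perm = np.where(np.isfinite(r_perm), r_perm, 0.0)
    if alternative == "greater":
        count = int(np.sum(r_perm >= r_obs - 1e-12))
    else:
        count = int(np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12))
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm, alternative=alternative)


@dataclass(frozen=True)
class DistinctivenessResult:
    """S'_ij matrix, per-cell S'_i, and the Mantel decision that chose the
    branch ("residuals" of v_ij on ln d_ij, or "centered" v_ij)."""

    cells: tuple[str, ...]
    sij: pd.DataFrame
    si: pd.Series
    mantel: MantelResult
    branch: str
    alpha: float


def distinctiveness_scores(
    M: CellPairMatrix,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> DistinctivenessResult:
    """Standardized distinctiveness from the cell-pair matrices.

    If the one-sided Mantel test of v_ij against ln(d_ij) is significant at
    ``alpha`` (distance decay present), S'_ij are OLS residuals of v_ij on
    ln(d_ij) fitted over unique unordered pairs; otherwise S'_ij are the
    centred v_ij.  Either way the off-diagonal S'_ij average to zero and
    S'_i is the mean over all pairs involving cell i.
    """
    m = len(M.cells)
    iu = np.triu_indices(m, 1)
    lnd = np.zeros_like(M.d_km)
    lnd[iu] = np.log(M.d_km[iu])
    lnd.T[iu] = lnd[iu]

    res = mantel_test(M.v, lnd, n_perm=n_perm, seed=seed, alternative="greater")
    sij = np.zeros((m, m))
    if res.p < alpha:
        slope, intercept = np.polyfit(lnd[iu], M.v[iu], 1)
        resid = M.v[iu] - (slope * lnd[iu] + intercept)
        branch = "residuals"
    else:
        resid = M.v[iu] - M.v[iu].mean()
        branch = "centered"
    sij[iu] = resid
    sij.T[iu] = resid
    log.info("distinctiveness branch: %s (Mantel r=%.3f p=%.4f)", branch, res.r, res.p)

    # mean over j != i
    si = (sij.sum(axis=1)) / (m - 1)
    sij_df = pd.DataFrame(sij, index=list(M.cells), columns=list(M.cells))
    si_s = pd.Series(si, index=list(M.cells), name="Si")
    return DistinctivenessResult(
        cells=M.cells, sij=sij_df, si=si_s, mantel=res, branch=branch, alpha=alpha
    )
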