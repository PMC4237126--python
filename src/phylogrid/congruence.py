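"""Cross-species congruence of grid-cell genetic patterns.

Per-cell metrics (NAe, He, v, End, S'i) are first centred and reduced
within species (z-scores with the sample standard deviation), which makes
cells comparable across species with different absolute diversity levels.
Congruence is then tested three ways:

* pairwise Pearson correlation of a metric between two species over the
  cells retained for both (pairs with too few shared cells are reported as
  untested rather than silently dropped);
* a one-way fixed-effects ANOVA with grid cells as the factor and species
  z-values as observations -- a significant cell effect means species
  agree on where the metric is high or low (species cannot be a second
  factor because the design is very unbalanced);
* Mantel tests between species' pairwise-distinctiveness matrices (S'_ij)
  restricted to shared cells, two-sided because congruence could run in
  either direction.

Multi-species maps are summarised by the per-cell mean z over species.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats

from .seqio import InsufficientDataError
from .distinctiveness import mantel_test

log = logging.getLogger(__name__)

__all__ = [
    "StandardizedMetricTable",
    "AnovaResult",
    "standardize_metrics",
    "species_pair_correlation",
    "multispecies_anova",
    "congruence_mantel",
    "multispecies_cell_means",
]


@dataclass(frozen=True)
class StandardizedMetricTable:
    """Long-format z-scores: one row per (species, cell, metric)."""

    data: pd.DataFrame  # columns: species, cell, metric, z
    stats: pd.DataFrame  # columns: species, metric, mean, sd, n_cells
    excluded: tuple[tuple[str, str, str], ...]  # (species, metric, reason)

    def zvec(self, species: str, metric: str) -> pd.Series:
        sub = self.data[
            (self.data["species"] == species) & (self.data["metric"] == metric)
        ]
        return pd.Series(sub["z"].to_numpy(), index=sub["cell"].to_numpy())

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["species"].unique()))

    @property
    def metrics(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["metric"].unique()))


def standardize_metrics(
    tables: Mapping[str, pd.DataFrame],
    metrics: tuple[str, ...] | None = None,
) -> StandardizedMetricTable:
    """Centre and reduce per-cell metrics within each species.

    ``tables`` maps species to a DataFrame indexed by cell id with one
    column per metric (a column named ``n`` is ignored).  z-scores use the
    sample (n-1) standard deviation.  A species is excluded from a metric
    when it has fewer than two retained cells or zero variance.
    """
    rows = []
    stats_rows = []
    excluded: list[tuple[str, str, str]] = []
    for species in sorted(tables):
        df = tables[species]
        cols = metrics if metrics is not None else tuple(
            c for c in df.columns if c != "n"
        )
        for metric in cols:
            if metric not in df.columns:
                excluded.append((species, metric, "metric missing"))
                continue
            x = df[metric].astype(float)
            if len(x) < 2:
                excluded.append((species, metric, "fewer than 2 cells"))
                log.warning("%s/%s excluded: fewer than 2 cells", species, metric)
                continue
            mean = float(x.mean())
            sd = float(x.std(ddof=1))
            if sd == 0.0:
                excluded.append((species, metric, "zero variance"))
                log.warning("%s/%s excluded: zero variance", species, metric)
                continue
            z = (x - mean) / sd
            stats_rows.append(
                {"species": species, "metric": metric, "mean": mean, "sd": sd,
                 "n_cells": len(x)}
            )
            for cell, val in z.items():
                rows.append(
                    {"species": species, "cell": cell, "metric": metric,
                     "z": float(val)}
                )
    data = pd.DataFrame(rows, columns=["species", "cell", "metric", "z"])
    stats = pd.DataFrame(
        stats_rows, columns=["species", "metric", "mean", "sd", "n_cells"]
    )
    return StandardizedMetricTable(
        data=data, stats=stats, excluded=tuple(excluded)
    )


def species_pair_correlation(
    z: StandardizedMetricTable, metric: str, min_shared: int = 5
) -> pd.DataFrame:
    """Pearson correlation of a metric between species pairs on shared cells.

    Pairs with fewer than ``min_shared`` shared cells, or zero variance on
    the shared subset, are reported with ``tested = False`` and a reason.
    """
    out = []
    species = [s for s in z.species if metric in set(
        z.data.loc[z.data["species"] == s, "metric"])]
    for a, b in itertools.combinations(sorted(species), 2):
        za, zb = z.zvec(a, metric), z.zvec(b, metric)
        shared = sorted(set(za.index) & set(zb.index))
        row = {"species_a": a, "species_b": b, "n_shared": len(shared),
               "r": np.nan, "p": np.nan, "tested": False, "note": ""}
        if len(shared) < min_shared:
            row["note"] = f"fewer than {min_shared} shared cells"
        else:
            xa = za[shared].to_numpy()
            xb = zb[shared].to_numpy()
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                row["note"] = "zero variance on shared cells"
            else:
                r, p = scipy.stats.pearsonr(xa, xb)
                row.update(r=float(r), p=float(p), tested=True)
        out.append(row)
    return pd.DataFrame(
        out, columns=["species_a", "species_b", "n_shared", "r", "p",
                      "tested", "note"]
    )


@dataclass(frozen=True)
class AnovaResult:
    """One-way fixed-effects ANOVA with grid cells as the factor."""

    f: float
    p: float
    df_between: int
    df_within: int
    n_groups: int
    n_obs: int
    singleton_cells: tuple[str, ...]


def multispecies_anova(z: StandardizedMetricTable, metric: str) -> AnovaResult:
    """Test for a common geographic structure of a standardized metric.

    Groups are grid cells; observations are the species z-values available
    in each cell.  Cells with a single observation carry no within-group
    information and are excluded (but reported).  The unbalanced design is
    handled by ordinary sums of squares.
    """
    sub = z.data[z.data["metric"] == metric]
    groups: dict[str, np.ndarray] = {}
    singletons = []
    for cell, grp in sub.groupby("cell"):
        vals = grp["z"].to_numpy(dtype=float)
        if len(vals) >= 2:
            groups[str(cell)] = vals
        else:
            singletons.append(str(cell))
    if len(groups) < 2:
        raise InsufficientDataError(
            f"ANOVA needs >= 2 cells with >= 2 observations, got {len(groups)}"
        )
    allv = np.concatenate(list(groups.values()))
    grand = allv.mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ssw = sum(float(np.sum((v - v.mean()) ** 2)) for v in groups.values())
    dfb = len(groups) - 1
    dfw = len(allv) - len(groups)
    if ssw == 0.0:
        if ssb == 0.0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ssb / dfb) / (ssw / dfw)
        p = float(scipy.stats.f.sf(f_stat, dfb, dfw))
    return AnovaResult(
        f=float(f_stat), p=float(p), df_between=dfb, df_within=dfw,
        n_groups=len(groups), n_obs=len(allv),
        singleton_cells=tuple(sorted(singletons)),
    )


def congruence_mantel(
    sij_by_species: Mapping[str, pd.DataFrame],
    n_perm: int = 999,
    seed: int = 0,
    min_shared: int = 4,
) -> pd.DataFrame:
    """Mantel tests between species' S'_ij matrices over shared cells.

    Two-sided p-values; pairs with fewer than ``min_shared`` shared cells
    are reported untested with the shared-cell count.
    """
    out = []
    names = sorted(sij_by_species)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names) * (len(names) - 1) // 2)
    for k, (a, b) in enumerate(itertools.combinations(names, 2)):
        sa, sb = sij_by_species[a], sij_by_species[b]
        shared = sorted(set(sa.index) & set(sb.index))
        row = {"species_a": a, "species_b": b, "n_shared": len(shared),
               "r": np.nan, "p": np.nan, "tested": False, "note": ""}
        if len(shared) < min_shared:
            row["note"] = f"fewer than {min_shared} shared cells"
        else:
            A = sa.loc[shared, shared].to_numpy(dtype=float)
            B = sb.loc[shared, shared].to_numpy(dtype=float)
            sub_seed = int(children[k].generate_state(1)[0] % (2**31))
            try:
                res = mantel_test(
                    A, B, n_perm=n_perm, seed=sub_seed, alternative="two-sided"
                )
            except ValueError as exc:
                row["note"] = str(exc)
            else:
                row.update(r=res.r, p=res.p, tested=True)
        out.append(row)
    return pd.DataFrame(
        out, columns=["species_a", "species_b", "n_shared", "r", "p",
                      "tested", "note"]
    )


def multispecies_cell_means(
    z: StandardizedMetricTable, metric: str
) -> pd.DataFrame:
    """Per-cell mean z over species plus the contributing-species count."""
    sub = z.data[z.data["metric"] == metric]
    if sub.empty:
        return pd.DataFrame(columns=["mean_z", "n_species"])
    agg = sub.groupby("cell")["z"].agg(["mean", "count"])
    agg.columns = ["mean_z", "n_species"]
    agg["n_species"] = agg["n_species"].astype(int)
    return agg.sort_index()
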