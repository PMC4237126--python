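"""End-to-end comparative phylogeography pipeline.

Runs, for one or several species, the full chain: indel coding, haplotype
collapsing, polymorphism summary, mutation-distance matrix, grid
assignment at one or more cell sizes, per-cell diversity/endemism,
GST/NST differentiation with the phylogeographic-signal test, cell
distinctiveness, and (across species) standardization, pairwise Pearson
tests, the cells-as-factor ANOVA, S'_ij Mantel congruence tests and
multi-species cell means.  All randomness derives from a single master
seed via spawned seed sequences, so outputs are reproducible
byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import congruence as cg
from . import distinctiveness as dist
from . import gridstats as gs
from . import network as nw
from . import seqio

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "SpeciesGridResult",
    "SpeciesResult",
    "ComparativeResult",
    "analyze_species",
    "analyze_comparative",
    "write_all",
]

_METRICS = ("NAe", "He", "v", "End", "Si")


@dataclass(frozen=True)
class PipelineConfig:
    """Run configuration: grid systems, thresholds, permutations, seed."""

    grid_sizes: tuple[float, ...] = (0.75, 1.5, 3.0)
    origin: tuple[float, float] = (0.0, 0.0)
    min_cell_n: int = 3
    endemism_km: float = 200.0
    n_permutations: int = 999
    alpha: float = 0.05
    min_shared_pearson: int = 5
    min_shared_mantel: int = 4
    weighting: str = "equal"
    seed: int = 0
    site_mask: tuple[int, ...] = ()  # alignment columns (0-based) to drop

    def label(self, size: float) -> str:
        return f"{size:g}deg"


def _derive_seed(master: int, *key: int) -> int:
    return int(np.random.SeedSequence([master, *key]).generate_state(1)[0] % (2**31))


def _apply_site_mask(aln: seqio.Alignment, mask: tuple[int, ...]) -> seqio.Alignment:
    if not mask:
        return aln
    drop = set(mask)
    keep = [i for i in range(aln.length) if i not in drop]
    return seqio.Alignment(
        {s: "".join(seq[i] for i in keep) for s, seq in aln.records.items()}
    )


@dataclass(frozen=True)
class SpeciesGridResult:
    grid_size: float
    assignment: gs.GridAssignment
    cell_stats: pd.DataFrame  # n, NAe, He, v, End per retained cell
    differentiation: gs.DifferentiationResult | None
    differentiation_note: str
    distinct: dist.DistinctivenessResult | None
    distinct_note: str


@dataclass(frozen=True)
class SpeciesResult:
    species: str
    haplotypes: seqio.HaplotypeSet
    distances: nw.MutationDistanceMatrix
    polymorphism: seqio.PolymorphismSummary
    per_grid: Mapping[float, SpeciesGridResult]


@dataclass(frozen=True)
class ComparativeResult:
    config: PipelineConfig
    species: Mapping[str, SpeciesResult]
    standardized: Mapping[float, cg.StandardizedMetricTable]
    pearson: Mapping[float, Mapping[str, pd.DataFrame]]
    anova: Mapping[float, Mapping[str, cg.AnovaResult | None]]
    mantel_sij: Mapping[float, pd.DataFrame]
    cell_means: Mapping[float, Mapping[str, pd.DataFrame]]


def analyze_species(
    aln: seqio.Alignment,
    samples: seqio.SampleTable,
    cfg: PipelineConfig,
    species: str = "sp1",
    species_index: int = 0,
) -> SpeciesResult:
    """Single-species analysis over all configured grid sizes."""
    aln = _apply_site_mask(aln, cfg.site_mask)
    coded = seqio.code_indels(aln)
    haps = seqio.collapse_haplotypes(coded, samples)
    poly = seqio.summarize_polymorphism(aln, coded)
    D = nw.mutation_distance_matrix(haps)
    per_grid: dict[float, SpeciesGridResult] = {}
    for gi, size in enumerate(cfg.grid_sizes):
        grid = gs.GridSpec(size, origin=cfg.origin)
        assign = gs.assign_cells(samples, grid, min_cell_n=cfg.min_cell_n)
        stats = gs.cell_statistics(
            assign, haps, D, samples, endemism_km=cfg.endemism_km
        )
        diff = None
        diff_note = ""
        try:
            diff = gs.global_differentiation(
                assign, haps, D,
                n_perm=cfg.n_permutations,
                seed=_derive_seed(cfg.seed, 0, species_index, gi),
                weighting=cfg.weighting,
            )
        except (seqio.InsufficientDataError, gs.MonomorphicError) as exc:
            diff_note = str(exc)
            log.warning("%s @ %s: differentiation skipped: %s", species, size, exc)
        distinct = None
        distinct_note = ""
        try:
            pair = dist.between_cell_matrices(assign, haps, D)
            distinct = dist.distinctiveness_scores(
                pair,
                n_perm=cfg.n_permutations,
                seed=_derive_seed(cfg.seed, 1, species_index, gi),
                alpha=cfg.alpha,
            )
        except (dist.InsufficientCellsError, dist.DegenerateGeometryError,
                seqio.InsufficientDataError, ValueError) as exc:
            distinct_note = str(exc)
            log.warning("%s @ %s: distinctiveness skipped: %s", species, size, exc)
        per_grid[size] = SpeciesGridResult(
            grid_size=size,
            assignment=assign,
            cell_stats=stats,
            differentiation=diff,
            differentiation_note=diff_note,
            distinct=distinct,
            distinct_note=distinct_note,
        )
    return SpeciesResult(
        species=species, haplotypes=haps, distances=D,
        polymorphism=poly, per_grid=per_grid,
    )


def analyze_comparative(
    datasets: Mapping[str, tuple[seqio.Alignment, seqio.SampleTable]],
    cfg: PipelineConfig,
) -> ComparativeResult:
    """Multi-species analysis: per-species pipelines plus congruence tests."""
    names = sorted(datasets)
    species_results = {
        name: analyze_species(*datasets[name], cfg, species=name, species_index=i)
        for i, name in enumerate(names)
    }
    standardized = {}
    pearson = {}
    anova = {}
    mantel_sij = {}
    cell_means = {}
    for gi, size in enumerate(cfg.grid_sizes):
        tables = {}
        sij = {}
        for name in names:
            res = species_results[name].per_grid[size]
            df = res.cell_stats.copy()
            if res.distinct is not None:
                df["Si"] = res.distinct.si
                sij[name] = res.distinct.sij
            tables[name] = df
        z = cg.standardize_metrics(tables, metrics=_METRICS)
        standardized[size] = z
        pearson[size] = {
            m: cg.species_pair_correlation(z, m, min_shared=cfg.min_shared_pearson)
            for m in _METRICS
        }
        per_metric_anova: dict[str, cg.AnovaResult | None] = {}
        for m in _METRICS:
            try:
                per_metric_anova[m] = cg.multispecies_anova(z, m)
            except seqio.InsufficientDataError as exc:
                log.warning("ANOVA for %s @ %s skipped: %s", m, size, exc)
                per_metric_anova[m] = None
        anova[size] = per_metric_anova
        mantel_sij[size] = cg.congruence_mantel(
            sij,
            n_perm=cfg.n_permutations,
            seed=_derive_seed(cfg.seed, 2, gi),
            min_shared=cfg.min_shared_mantel,
        )
        cell_means[size] = {m: cg.multispecies_cell_means(z, m) for m in _METRICS}
    return ComparativeResult(
        config=cfg,
        species=species_results,
        standardized=standardized,
        pearson=pearson,
        anova=anova,
        mantel_sij=mantel_sij,
        cell_means=cell_means,
    )


# ---------------------------------------------------------------------------
# deterministic TSV output
# ---------------------------------------------------------------------------

_FLOAT = "%.6g"


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT, index=index)


def write_all(result: ComparativeResult, outdir: str | Path) -> None:
    """Write every result table as deterministic TSV files under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    names = sorted(result.species)

    poly_rows = []
    member_rows = []
    for name in names:
        sp = result.species[name]
        p = sp.polymorphism
        poly_rows.append(
            {"species": name, "n": p.n_samples, "n_haplotypes": p.n_haplotypes,
             "snp_incl_indels": p.n_snps, "pi": p.pi, "pi_sd": p.pi_sd}
        )
        for h in sp.haplotypes.ids:
            for s in sp.haplotypes.carriers[h]:
                member_rows.append({"species": name, "sample": s, "haplotype": h})
    _write(pd.DataFrame(poly_rows), out / "polymorphism.tsv")
    _write(pd.DataFrame(member_rows), out / "haplotype_membership.tsv")

    for size in cfg.grid_sizes:
        lbl = cfg.label(size)
        stats_rows = []
        diff_rows = []
        si_rows = []
        for name in names:
            res = result.species[name].per_grid[size]
            df = res.cell_stats.reset_index()
            df.insert(0, "species", name)
            stats_rows.append(df)
            d = res.differentiation
            diff_rows.append(
                {"species": name, "grid": lbl,
                 "n_cells": d.n_cells if d else 0,
                 "GST": d.gst if d else np.nan,
                 "NST": d.nst if d else np.nan,
                 "p_NST_gt_GST": d.p_nst_gt_gst if d else np.nan,
                 "note": res.differentiation_note}
            )
            if res.distinct is not None:
                si = res.distinct.si.reset_index()
                si.columns = ["cell", "Si"]
                si.insert(0, "species", name)
                si["branch"] = res.distinct.branch
                si["mantel_r"] = res.distinct.mantel.r
                si["mantel_p"] = res.distinct.mantel.p
                si_rows.append(si)
        _write(pd.concat(stats_rows, ignore_index=True), out / f"cell_stats_{lbl}.tsv")
        _write(pd.DataFrame(diff_rows), out / f"differentiation_{lbl}.tsv")
        if si_rows:
            _write(pd.concat(si_rows, ignore_index=True),
                   out / f"distinctiveness_{lbl}.tsv")

        z = result.standardized[size]
        _write(z.data, out / f"standardized_{lbl}.tsv")
        for m in _METRICS:
            _write(result.pearson[size][m], out / f"pearson_{m}_{lbl}.tsv")
            cm = result.cell_means[size][m]
            _write(cm.reset_index(), out / f"cell_means_{m}_{lbl}.tsv")
        an_rows = []
        for m in _METRICS:
            a = result.anova[size][m]
            an_rows.append(
                {"metric": m,
                 "F": a.f if a else np.nan,
                 "p": a.p if a else np.nan,
                 "df_between": a.df_between if a else 0,
                 "df_within": a.df_within if a else 0,
                 "n_obs": a.n_obs if a else 0}
            )
        _write(pd.DataFrame(an_rows), out / f"anova_{lbl}.tsv")
        _write(result.mantel_sij[size], out / f"mantel_sij_{lbl}.tsv")
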