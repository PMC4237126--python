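"""Synthetic phylogeographic scenarios for end-to-end pipeline testing.

Generates aligned haplotype sequences plus georeferenced samples under
controlled spatial scenarios, together with the ground truth needed to
check what the analysis should recover:

* ``panmixia``    -- every individual draws its haplotype i.i.d. from the
  global frequencies; no spatial structure, no phylogeographic signal.
* ``refugia``     -- each refuge centre seeds one haplogroup (haplogroups
  separated by a configurable number of mutation steps); sites draw from
  the haplogroups with distance-decaying admixture, and sites inside a
  refuge carry additional locally endemic derived haplotypes.
* ``expansion``   -- one widespread central haplotype everywhere plus rare
  derived haplotypes concentrated near the origin of the expansion.
* ``contact``     -- two divergent haplogroups whose ranges overlap in a
  longitudinal band, where both mix at high frequency (secondary contact:
  high phylogenetic diversity without endemism).

Mutations follow an infinite-sites model (every mutation hits a fresh
alignment column), so mutation-step distances between haplotypes equal
path lengths on the simulated genealogy exactly and network/distance
oracles are exact.  An optional homoplasy rate re-uses sites to stress the
network code.  Indels are simulated as single-column gaps with a
configurable fraction.  The default geography is an equatorial African
rainforest-like box (8-16E, 6S-8N) so the default degree grids produce
realistic cell counts; default sample sizes (20 sites x 6 samples, ~800 bp,
12 haplotypes, 20 mutations) match the scale of published plastid
phylogeography datasets.

Identical seeds produce byte-identical FASTA and sample tables.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import Alignment, SampleTable
from .gridstats import GridSpec, great_circle_km

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_REGION",
    "SCENARIOS",
    "ConfigError",
    "ScenarioConfig",
    "ScenarioTruth",
    "SimulatedHaplotypes",
    "SimulatedDataset",
    "simulate_haplotypes",
    "simulate_dataset",
    "simulate_divergent_cell",
    "expected_pattern",
    "evaluate_expected_pattern",
    "write_truth",
]

# lon_min, lon_max, lat_min, lat_max -- Lower-Guinea-like equatorial box
DEFAULT_REGION = (8.0, 16.0, -6.0, 8.0)
SCENARIOS = ("panmixia", "refugia", "expansion", "contact")

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Raised for inconsistent simulation parameters."""


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of a simulated phylogeographic scenario.

    ``seed`` is mandatory: every random draw flows from it.
    """

    scenario: str
    seed: int
    species: str = "sp1"
    region: tuple[float, float, float, float] = DEFAULT_REGION
    n_sites: int = 20
    samples_per_site: int = 6
    seq_length: int = 800
    n_haplotypes: int = 12
    total_mutations: int = 20
    indel_fraction: float = 0.1
    homoplasy_rate: float = 0.0
    separation: int = 5
    n_refugia: int = 2
    refuge_centers: tuple[tuple[float, float], ...] | None = None  # (lon, lat)
    refuge_radius_km: float = 250.0
    admixture_scale_km: float = 150.0
    contact_band: tuple[float, float] = (11.5, 12.5)  # lon interval
    site_jitter_deg: float = 0.05

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        for name in ("n_sites", "samples_per_site", "seq_length",
                     "n_haplotypes", "total_mutations", "n_refugia"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.separation < 1:
            raise ConfigError("separation must be >= 1")
        lon0, lon1, lat0, lat1 = self.region
        if not (lon0 < lon1 and lat0 < lat1):
            raise ConfigError("degenerate region box")
        if self.refuge_centers is not None:
            for lon, lat in self.refuge_centers:
                if not (lon0 <= lon <= lon1 and lat0 <= lat <= lat1):
                    raise ConfigError(
                        f"refuge centre ({lon}, {lat}) outside region {self.region}"
                    )


@dataclass(frozen=True)
class SimulatedHaplotypes:
    """Haplotype sequences with their genealogy and exact path distances."""

    ids: tuple[str, ...]
    sequences: Mapping[str, str]
    genealogy: tuple[tuple[str, str, int], ...]  # (parent, child, steps)
    distances: np.ndarray  # genealogy path lengths, ids order


@dataclass(frozen=True)
class ScenarioTruth:
    """Ground truth emitted alongside a simulated dataset."""

    scenario: str
    genealogy: tuple[tuple[str, str, int], ...]
    haplogroup: Mapping[str, int]
    site_lonlat: tuple[tuple[float, float], ...]
    sample_site: Mapping[str, int]
    sample_hap: Mapping[str, str]
    special_sites: Mapping[str, tuple[int, ...]]
    centers: Mapping[str, tuple[float, float]]  # name -> (lon, lat)
    expectations: Mapping[str, bool]

    def to_json(self) -> dict:
        d = asdict(self)
        d["haplogroup"] = dict(self.haplogroup)
        return d

    @classmethod
    def from_json(cls, d: Mapping) -> "ScenarioTruth":
        return cls(
            scenario=d["scenario"],
            genealogy=tuple((p, c, int(m)) for p, c, m in d["genealogy"]),
            haplogroup={k: int(v) for k, v in d["haplogroup"].items()},
            site_lonlat=tuple((float(a), float(b)) for a, b in d["site_lonlat"]),
            sample_site={k: int(v) for k, v in d["sample_site"].items()},
            sample_hap=dict(d["sample_hap"]),
            special_sites={k: tuple(v) for k, v in d["special_sites"].items()},
            centers={k: (float(v[0]), float(v[1])) for k, v in d["centers"].items()},
            expectations={k: bool(v) for k, v in d["expectations"].items()},
        )


@dataclass(frozen=True)
class SimulatedDataset:
    alignment: Alignment
    samples: SampleTable
    truth: ScenarioTruth


# ---------------------------------------------------------------------------
# genealogy machinery
# ---------------------------------------------------------------------------


def _grow_sequences(
    rng: np.random.Generator,
    n_nodes: int,
    edges: Sequence[tuple[int, int, int]],
    seq_length: int,
    indel_fraction: float,
    homoplasy_rate: float,
) -> dict[int, str]:
    """Walk a genealogy (topologically ordered edges) placing mutations.

    Infinite sites by default: each mutation consumes a fresh alignment
    column (substitution to a different base, or a single-column gap with
    probability ``indel_fraction``).  With ``homoplasy_rate`` > 0 a
    mutation may instead re-hit a previously mutated column.
    """
    total = sum(m for _, _, m in edges)
    if seq_length <= total:
        raise ConfigError(
            f"seq_length ({seq_length}) must exceed total mutations ({total})"
        )
    site_pool = list(rng.permutation(seq_length))
    used: list[int] = []
    gap_sites: set[int] = set()
    seqs: dict[int, np.ndarray] = {0: rng.choice(_BASES, size=seq_length)}
    for parent, child, m in edges:
        s = seqs[parent].copy()
        for _ in range(m):
            if homoplasy_rate > 0 and used and rng.random() < homoplasy_rate:
                site = int(used[rng.integers(len(used))])
                cur = s[site]
                alts = [b for b in "ACGT" if b != cur]
                s[site] = alts[rng.integers(len(alts))]
            else:
                site = int(site_pool.pop())
                used.append(site)
                # adjacent single-column gaps would merge into one run and
                # make the shorter span ambiguous; keep gap columns isolated
                gap_ok = not ({site - 1, site + 1} & gap_sites)
                if gap_ok and rng.random() < indel_fraction:
                    s[site] = "-"
                    gap_sites.add(site)
                else:
                    cur = s[site]
                    alts = [b for b in "ACGT" if b != cur]
                    s[site] = alts[rng.integers(len(alts))]
        seqs[child] = s
    return {i: "".join(seqs[i]) for i in range(n_nodes)}


def _tree_distances(n: int, edges: Sequence[tuple[int, int, int]]) -> np.ndarray:
    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n)}
    for p, c, m in edges:
        adj[p].append((c, m))
        adj[c].append((p, m))
    D = np.zeros((n, n), dtype=int)
    for src in range(n):
        seen = {src: 0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, m in adj[u]:
                if v not in seen:
                    seen[v] = seen[u] + m
                    stack.append(v)
        for v, d in seen.items():
            D[src, v] = d
    return D


def _spread_extra(
    rng: np.random.Generator, base: list[int], extra: int
) -> list[int]:
    """Distribute ``extra`` additional mutations over edges, multinomially."""
    if extra > 0 and base:
        add = rng.multinomial(extra, np.full(len(base), 1.0 / len(base)))
        return [b + int(a) for b, a in zip(base, add)]
    return base


def simulate_haplotypes(
    n_haplotypes: int,
    seq_length: int,
    total_mutations: int,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    indel_fraction: float = 0.0,
    homoplasy_rate: float = 0.0,
    topology: str = "random",
    prefix: str = "H",
) -> SimulatedHaplotypes:
    """Simulate haplotypes on a random genealogy under infinite sites.

    Every haplotype (including internal ones) is a potential sample; edge
    mutation counts are at least 1 with the remaining budget spread
    multinomially.  ``topology`` is "random" (uniform attachment) or "star"
    (every haplotype derived directly from the first).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_haplotypes < 1:
        raise ConfigError("need at least one haplotype")
    if n_haplotypes > 1 and total_mutations < n_haplotypes - 1:
        raise ConfigError("total_mutations must be >= n_haplotypes - 1")
    if seq_length <= total_mutations:
        raise ConfigError("seq_length must exceed total_mutations")
    parents = []
    for k in range(1, n_haplotypes):
        parents.append(0 if topology == "star" else int(rng.integers(0, k)))
    counts = _spread_extra(
        rng, [1] * (n_haplotypes - 1), total_mutations - (n_haplotypes - 1)
    )
    edges = [(parents[k - 1], k, counts[k - 1]) for k in range(1, n_haplotypes)]
    seqs = _grow_sequences(
        rng, n_haplotypes, edges, seq_length, indel_fraction, homoplasy_rate
    )
    ids = tuple(f"{prefix}{i + 1}" for i in range(n_haplotypes))
    return SimulatedHaplotypes(
        ids=ids,
        sequences={ids[i]: seqs[i] for i in range(n_haplotypes)},
        genealogy=tuple((ids[p], ids[c], m) for p, c, m in edges),
        distances=_tree_distances(n_haplotypes, edges),
    )


def _grouped_haplotypes(
    rng: np.random.Generator,
    sizes: Sequence[int],
    separation: int,
    seq_length: int,
    total_mutations: int,
    indel_fraction: float,
    homoplasy_rate: float = 0.0,
    extra_to: str = "within",
    within_topology: str = "random",
) -> tuple[SimulatedHaplotypes, dict[str, int], list[str]]:
    """Haplogroups on a backbone chain: group ancestors ``separation`` steps
    apart, members grown within groups.  Cross-group distances are at least
    ``separation``.  The leftover mutation budget goes either to the
    within-group edges (``extra_to="within"``: deep haplogroups) or to the
    backbone (``extra_to="backbone"``: shallow haplogroups, wider split).
    Returns (haplotypes, haplogroup map, ancestor ids)."""
    k = len(sizes)
    n = int(sum(sizes))
    backbone = (k - 1) * separation
    within_base = n - k
    extra = total_mutations - backbone - within_base
    if extra < 0:
        raise ConfigError(
            f"total_mutations={total_mutations} too small for {k} haplogroups "
            f"of sizes {tuple(sizes)} separated by {separation} steps"
        )
    edges: list[tuple[int, int, int]] = []
    group_of: dict[int, int] = {}
    ancestors: list[int] = []
    backbone_edges_idx: list[int] = []
    nxt = 0
    for g in range(k):
        anc = nxt
        nxt += 1
        ancestors.append(anc)
        group_of[anc] = g
        if g > 0:
            edges.append((ancestors[g - 1], anc, separation))
            backbone_edges_idx.append(len(edges) - 1)
    within_edges_idx: list[int] = []
    for g in range(k):
        pool = [ancestors[g]]
        for _ in range(sizes[g] - 1):
            if within_topology == "star":
                parent = ancestors[g]
            else:
                parent = pool[rng.integers(len(pool))]
            child = nxt
            nxt += 1
            group_of[child] = g
            edges.append((parent, child, 1))
            within_edges_idx.append(len(edges) - 1)
            pool.append(child)
    target_idx = (
        backbone_edges_idx if extra_to == "backbone" and backbone_edges_idx
        else within_edges_idx
    )
    if extra > 0 and target_idx:
        add = rng.multinomial(
            extra, np.full(len(target_idx), 1.0 / len(target_idx))
        )
        for j, a in zip(target_idx, add):
            p, c, m = edges[j]
            edges[j] = (p, c, m + int(a))
    # re-sort edges topologically (children always created after parents)
    edges.sort(key=lambda e: e[1])
    seqs = _grow_sequences(rng, n, edges, seq_length, indel_fraction, homoplasy_rate)
    ids = tuple(f"H{i + 1}" for i in range(n))
    hapsim = SimulatedHaplotypes(
        ids=ids,
        sequences={ids[i]: seqs[i] for i in range(n)},
        genealogy=tuple((ids[p], ids[c], m) for p, c, m in edges),
        distances=_tree_distances(n, edges),
    )
    haplogroup = {ids[i]: group_of[i] for i in range(n)}
    return hapsim, haplogroup, [ids[a] for a in ancestors]


def _rank_freqs(n: int, ratio: float = 0.65) -> np.ndarray:
    w = ratio ** np.arange(n)
    return w / w.sum()


def _balanced_sizes(n: int, k: int) -> list[int]:
    base = n // k
    sizes = [base + (1 if g < n % k else 0) for g in range(k)]
    if min(sizes) < 1:
        raise ConfigError(f"cannot split {n} haplotypes into {k} haplogroups")
    return sizes


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


def _default_centers(region, k: int) -> list[tuple[float, float]]:
    lon0, lon1, lat0, lat1 = region
    return [
        (
            lon0 + (g + 0.5) / k * (lon1 - lon0),
            lat0 + (g + 0.5) / k * (lat1 - lat0),
        )
        for g in range(k)
    ]


def _uniform_sites(rng, region, n: int) -> list[tuple[float, float]]:
    lon0, lon1, lat0, lat1 = region
    return [
        (float(rng.uniform(lon0, lon1)), float(rng.uniform(lat0, lat1)))
        for _ in range(n)
    ]


def _near(rng, center, region, sd_deg: float = 0.15) -> tuple[float, float]:
    lon0, lon1, lat0, lat1 = region
    lon = float(np.clip(center[0] + rng.normal(0, sd_deg), lon0, lon1))
    lat = float(np.clip(center[1] + rng.normal(0, sd_deg), lat0, lat1))
    return lon, lat


def _scenario_panmixia(cfg: ScenarioConfig, rng):
    hs = simulate_haplotypes(
        cfg.n_haplotypes, cfg.seq_length, cfg.total_mutations, rng=rng,
        indel_fraction=cfg.indel_fraction, homoplasy_rate=cfg.homoplasy_rate,
    )
    # frequency ranks are shuffled over haplotypes so that abundance carries
    # no information about genealogical position (a common haplotype is not
    # automatically central): i.i.d. sampling in its strictest sense
    freqs = rng.permutation(_rank_freqs(cfg.n_haplotypes))
    sites = _uniform_sites(rng, cfg.region, cfg.n_sites)
    hap_of = []
    for _ in range(cfg.n_sites):
        for _ in range(cfg.samples_per_site):
            hap_of.append(hs.ids[int(rng.choice(cfg.n_haplotypes, p=freqs))])
    return (
        hs, sites, hap_of, {h: 0 for h in hs.ids}, {}, {},
        {"no_phylogeographic_signal": True},
    )


def _scenario_refugia(cfg: ScenarioConfig, rng):
    k = cfg.n_refugia
    centers = list(cfg.refuge_centers or _default_centers(cfg.region, k))
    if len(centers) != k:
        raise ConfigError("need one refuge centre per refugium")
    sizes = _balanced_sizes(cfg.n_haplotypes, k)
    # leftover mutation budget deepens the split between haplogroups (the
    # configured separation remains the guaranteed minimum), keeping local
    # variants shallow relative to the refugial divergence
    hs, haplogroup, ancestors = _grouped_haplotypes(
        rng, sizes, cfg.separation, cfg.seq_length, cfg.total_mutations,
        cfg.indel_fraction, cfg.homoplasy_rate, extra_to="backbone",
    )
    r_per = max(1, min(3, cfg.n_sites // (2 * k)))
    sites: list[tuple[float, float]] = []
    refuge_sites: dict[int, list[int]] = {g: [] for g in range(k)}
    for g in range(k):
        for _ in range(r_per):
            refuge_sites[g].append(len(sites))
            sites.append(_near(rng, centers[g], cfg.region))
    sites.extend(_uniform_sites(rng, cfg.region, cfg.n_sites - len(sites)))

    # locally endemic derived haplotypes: round-robin over the refuge sites
    local_pool: dict[int, list[str]] = {i: [] for i in range(cfg.n_sites)}
    for g in range(k):
        derived = [h for h in hs.ids if haplogroup[h] == g and h != ancestors[g]]
        for j, h in enumerate(derived):
            local_pool[refuge_sites[g][j % r_per]].append(h)

    hap_of = []
    for s, (lon, lat) in enumerate(sites):
        d = np.array(
            [great_circle_km((lat, lon), (c[1], c[0])) for c in centers]
        )
        w = np.exp(-d / cfg.admixture_scale_km)
        probs = w / w.sum()
        for _ in range(cfg.samples_per_site):
            g = int(rng.choice(k, p=probs))
            if s in refuge_sites[g] and local_pool[s] and rng.random() < 0.5:
                hap = local_pool[s][int(rng.integers(len(local_pool[s])))]
            else:
                hap = ancestors[g]
            hap_of.append(hap)
    special = {"refuge": tuple(i for g in range(k) for i in refuge_sites[g])}
    cent = {f"refuge_{g}": tuple(centers[g]) for g in range(k)}
    return (
        hs, sites, hap_of, haplogroup, special, cent,
        {"phylogeographic_signal": True, "refuge_endemism": True},
    )


def _scenario_contact(cfg: ScenarioConfig, rng):
    """Two haplogroups meeting in a longitudinal band.

    Flank sites carry almost exclusively their side's ancestor haplotype,
    with locally endemic derived haplotypes confined to a few core sites on
    each flank (the source refugia); band sites mix the two widespread
    ancestors 50:50.  The diagnostic contrast follows: band cells show high
    phylogenetic diversity v (divergent haplotypes co-occur) but no
    endemism, while endemism sits on the flanks.
    """
    lon0, lon1, lat0, lat1 = cfg.region
    band = cfg.contact_band
    if not (lon0 < band[0] < band[1] < lon1):
        raise ConfigError(f"contact band {band} outside region longitudes")
    sizes = _balanced_sizes(cfg.n_haplotypes, 2)
    hs, haplogroup, ancestors = _grouped_haplotypes(
        rng, sizes, cfg.separation, cfg.seq_length, cfg.total_mutations,
        cfg.indel_fraction, cfg.homoplasy_rate,
        extra_to="backbone", within_topology="star",
    )
    n_band = min(3, cfg.n_sites)
    r_per = max(1, min(3, (cfg.n_sites - n_band) // 4))
    core_centers = [
        ((lon0 + band[0]) / 2, (lat0 + lat1) / 2),
        ((band[1] + lon1) / 2, (lat0 + lat1) / 2),
    ]
    sites = [
        (float(rng.uniform(band[0], band[1])), float(rng.uniform(lat0, lat1)))
        for _ in range(n_band)
    ]
    core_sites: dict[int, list[int]] = {0: [], 1: []}
    for g in (0, 1):
        for _ in range(r_per):
            core_sites[g].append(len(sites))
            sites.append(_near(rng, core_centers[g], cfg.region))
    # remaining sites sample the flanks (outside the overlap band)
    flank_widths = np.array([band[0] - lon0, lon1 - band[1]])
    for _ in range(cfg.n_sites - len(sites)):
        side = int(rng.random() < flank_widths[1] / flank_widths.sum())
        lon = (
            float(rng.uniform(lon0, band[0])) if side == 0
            else float(rng.uniform(band[1], lon1))
        )
        sites.append((lon, float(rng.uniform(lat0, lat1))))

    local_pool: dict[int, list[str]] = {i: [] for i in range(cfg.n_sites)}
    for g in (0, 1):
        derived = [h for h in hs.ids if haplogroup[h] == g and h != ancestors[g]]
        for j, h in enumerate(derived):
            local_pool[core_sites[g][j % r_per]].append(h)

    hap_of = []
    for s, (lon, lat) in enumerate(sites):
        in_band = band[0] <= lon <= band[1]
        p2 = 0.05 if lon < band[0] else 0.95
        for r in range(cfg.samples_per_site):
            if in_band:
                g = r % 2  # balanced mixture in the overlap band
            else:
                g = int(rng.random() < p2)
            if s in core_sites[g] and local_pool[s] and rng.random() < 0.5:
                hap_of.append(local_pool[s][int(rng.integers(len(local_pool[s])))])
            else:
                hap_of.append(ancestors[g])
    special = {
        "contact_band": tuple(range(n_band)),
        "flank_core": tuple(core_sites[0] + core_sites[1]),
    }
    cent = {f"flank_{g}": tuple(core_centers[g]) for g in (0, 1)}
    return (
        hs, sites, hap_of, haplogroup, special, cent,
        {"contact_signature": True},
    )


def _scenario_expansion(cfg: ScenarioConfig, rng):
    hs = simulate_haplotypes(
        cfg.n_haplotypes, cfg.seq_length, cfg.total_mutations, rng=rng,
        indel_fraction=cfg.indel_fraction, homoplasy_rate=cfg.homoplasy_rate,
        topology="star",
    )
    lon0, lon1, lat0, lat1 = cfg.region
    if cfg.refuge_centers:
        origin = cfg.refuge_centers[0]
    else:
        origin = ((lon0 + lon1) / 2, (lat0 + lat1) / 2)
    n_origin = min(3, cfg.n_sites)
    sites = [_near(rng, origin, cfg.region) for _ in range(n_origin)]
    sites.extend(_uniform_sites(rng, cfg.region, cfg.n_sites - n_origin))
    ancestor = hs.ids[0]
    derived = list(hs.ids[1:])
    hap_of = []
    core = set(range(n_origin))
    for s, (lon, lat) in enumerate(sites):
        p_anc = 0.4 if s in core else 0.9
        for _ in range(cfg.samples_per_site):
            if derived and rng.random() >= p_anc:
                hap_of.append(derived[int(rng.integers(len(derived)))])
            else:
                hap_of.append(ancestor)
    special = {"origin": tuple(sorted(core))}
    return (
        hs, sites, hap_of, {h: 0 for h in hs.ids},
        special, {"origin": tuple(origin)},
        {"origin_max_diversity": True, "one_widespread_haplotype": True},
    )


_SCENARIO_FN = {
    "panmixia": _scenario_panmixia,
    "refugia": _scenario_refugia,
    "contact": _scenario_contact,
    "expansion": _scenario_expansion,
}


def simulate_dataset(cfg: ScenarioConfig) -> SimulatedDataset:
    """Simulate an aligned dataset plus sample table under a scenario.

    Individuals get jittered site coordinates (normal, ``site_jitter_deg``,
    clipped to the region) so cell centroids are never exactly co-located.
    """
    rng = np.random.default_rng(cfg.seed)
    hs, sites, hap_of, haplogroup, special, centers, expectations = _SCENARIO_FN[
        cfg.scenario
    ](cfg, rng)
    lon0, lon1, lat0, lat1 = cfg.region
    records: dict[str, str] = {}
    rows = []
    sample_site: dict[str, int] = {}
    sample_hap: dict[str, str] = {}
    i = 0
    for s, (lon, lat) in enumerate(sites):
        for _ in range(cfg.samples_per_site):
            sid = f"{cfg.species}_{i:04d}"
            jlon = float(np.clip(lon + rng.normal(0, cfg.site_jitter_deg), lon0, lon1))
            jlat = float(np.clip(lat + rng.normal(0, cfg.site_jitter_deg), lat0, lat1))
            hap = hap_of[i]
            records[sid] = hs.sequences[hap]
            rows.append((sid, cfg.species, jlat, jlon))
            sample_site[sid] = s
            sample_hap[sid] = hap
            i += 1
    truth = ScenarioTruth(
        scenario=cfg.scenario,
        genealogy=hs.genealogy,
        haplogroup=haplogroup,
        site_lonlat=tuple(sites),
        sample_site=sample_site,
        sample_hap=sample_hap,
        special_sites=special,
        centers=centers,
        expectations=expectations,
    )
    return SimulatedDataset(
        alignment=Alignment.from_sequences(records),
        samples=SampleTable.from_records(rows),
        truth=truth,
    )


def simulate_divergent_cell(
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    n_cells: int = 8,
    samples_per_cell: int = 6,
    separation: int = 8,
    n_background: int = 6,
    background_mutations: int = 10,
    seq_length: int = 800,
    region: tuple[float, float, float, float] = DEFAULT_REGION,
    cell_size: float = 0.75,
    jitter_deg: float = 0.05,
) -> tuple[Alignment, SampleTable, str, GridSpec]:
    """Isolated-refuge instance: one grid cell fixed for a divergent
    haplogroup, all others drawing i.i.d. from a shallow background
    haplogroup.  Returns (alignment, samples, planted cell id, grid)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    total = separation + background_mutations
    hs, haplogroup, ancestors = _grouped_haplotypes(
        rng, [n_background, 1], separation, seq_length, total, 0.0
    )
    divergent = ancestors[1]
    background = [h for h in hs.ids if haplogroup[h] == 0]
    freqs = _rank_freqs(len(background))
    grid = GridSpec(cell_size)
    lon0, lon1, lat0, lat1 = region
    points: list[tuple[float, float]] = []
    cells: list[str] = []
    while len(points) < n_cells:
        lon = float(rng.uniform(lon0, lon1))
        lat = float(rng.uniform(lat0, lat1))
        c = grid.cell_of(lat, lon)
        if c not in cells:
            cells.append(c)
            # anchor the site at the cell centre so jittered samples stay put
            ix, iy = (int(t) for t in c.split("_"))
            points.append(
                ((ix + 0.5) * cell_size, (iy + 0.5) * cell_size)
            )
    planted = int(rng.integers(n_cells))
    records = {}
    rows = []
    i = 0
    for j, (lon, lat) in enumerate(points):
        for _ in range(samples_per_cell):
            sid = f"dc_{i:03d}"
            if j == planted:
                hap = divergent
            else:
                hap = background[int(rng.choice(len(background), p=freqs))]
            jlon = float(np.clip(lon + rng.normal(0, jitter_deg), lon0, lon1))
            jlat = float(np.clip(lat + rng.normal(0, jitter_deg), lat0, lat1))
            records[sid] = hs.sequences[hap]
            rows.append((sid, "dc", jlat, jlon))
            i += 1
    return (
        Alignment.from_sequences(records),
        SampleTable.from_records(rows),
        cells[planted],
        grid,
    )


# ---------------------------------------------------------------------------
# expectations
# ---------------------------------------------------------------------------


def expected_pattern(truth: ScenarioTruth) -> dict[str, bool]:
    """The machine-checkable expectations attached to a scenario."""
    return dict(truth.expectations)


def _top_quartile(series: pd.Series, cells: set[str], strictly_positive: bool) -> bool:
    if not cells or not cells <= set(series.index):
        return False
    q = max(1, math.ceil(len(series) / 4))
    thr = np.sort(series.to_numpy())[::-1][q - 1]
    ok = all(series[c] >= thr for c in cells)
    if strictly_positive:
        ok = ok and all(series[c] > 0 for c in cells)
    return bool(ok)


def evaluate_expected_pattern(
    truth: ScenarioTruth,
    assign,
    stats: pd.DataFrame | None = None,
    diff=None,
    alpha: float = 0.05,
) -> dict[str, bool]:
    """Check a scenario's expectations against computed grid statistics.

    ``assign`` is the GridAssignment used for the analysis, ``stats`` the
    per-cell statistics table (NAe/He/v/End) and ``diff`` the
    DifferentiationResult.  Only checks whose inputs were supplied appear
    in the returned mapping.
    """
    checks: dict[str, bool] = {}
    grid = assign.grid

    def special_cells(name: str) -> set[str]:
        cells = {
            grid.cell_of(truth.site_lonlat[i][1], truth.site_lonlat[i][0])
            for i in truth.special_sites.get(name, ())
        }
        if stats is not None:
            cells &= set(stats.index)
        return cells

    if truth.scenario == "panmixia" and diff is not None:
        checks["no_phylogeographic_signal"] = diff.p_nst_gt_gst >= alpha
    elif truth.scenario == "refugia":
        if diff is not None:
            checks["nst_gt_gst_significant"] = (
                diff.nst > diff.gst and diff.p_nst_gt_gst < alpha
            )
        if stats is not None:
            checks["refuge_cells_top_end_quartile"] = _top_quartile(
                stats["End"], special_cells("refuge"), strictly_positive=True
            )
    elif truth.scenario == "contact" and stats is not None:
        cells = special_cells("contact_band")
        checks["contact_cells_top_v_quartile"] = _top_quartile(
            stats["v"], cells, strictly_positive=False
        )
        med = float(stats["End"].median())
        checks["contact_cells_low_end"] = bool(cells) and all(
            stats.at[c, "End"] <= med + 1e-12 for c in cells
        )
    elif truth.scenario == "expansion" and stats is not None:
        cells = special_cells("origin")
        checks["origin_cell_max_nae"] = bool(cells) and (
            max(stats.at[c, "NAe"] for c in cells) >= stats["NAe"].max() - 1e-12
        )
    return checks


def write_truth(truth: ScenarioTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json(), fh, indent=1, sort_keys=True)
        fh.write("\n")
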