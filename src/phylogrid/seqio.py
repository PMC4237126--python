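"""Alignment I/O, indel coding and haplotype collapsing for organellar loci.

The unit of analysis is the haplotype: a distinct sequence variant of a
non-recombining (here chloroplast) locus.  Aligned sequences over
``{A, C, G, T, -, N}`` are reduced to a character matrix in which

* every alignment column showing at least two nucleotide states among the
  ungapped samples contributes one *substitution* character, and
* every maximal gap run shared identically (same start and end) by one or
  more samples contributes one binary *indel* character (simple indel
  coding), so that an indel of any length counts as a single mutation step.

Samples whose coded vectors are identical are collapsed into haplotypes.
``N`` is treated as missing data; a sample that is missing at any coded
character cannot be assigned unambiguously to a haplotype and is dropped
with a warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

__all__ = [
    "Alignment",
    "SampleTable",
    "CodedAlignment",
    "HaplotypeSet",
    "PolymorphismSummary",
    "AlignmentError",
    "SampleTableError",
    "InsufficientDataError",
    "read_alignment",
    "read_sample_table",
    "code_indels",
    "collapse_haplotypes",
    "concatenate_coded",
    "summarize_polymorphism",
    "write_fasta",
    "write_haplotype_membership",
    "write_haplotype_fasta",
]

_NUCLEOTIDES = frozenset("ACGT")
_VALID = frozenset("ACGT-N")


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent alignments."""


class SampleTableError(ValueError):
    """Raised for malformed sample metadata tables."""


class InsufficientDataError(ValueError):
    """Raised when a statistic is requested from too few samples."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment keyed by sample id.

    Residues are uppercase over ``{A, C, G, T, -, N}``; any other symbol is
    normalised to ``N`` on construction via :meth:`from_sequences`.
    """

    records: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment contains no sequences")
        lengths = {len(s) for s in self.records.values()}
        if len(lengths) != 1:
            raise AlignmentError(
                f"unequal sequence lengths: {sorted(lengths)}"
            )
        if next(iter(lengths)) < 1:
            raise AlignmentError("alignment length must be >= 1")
        for sid, seq in self.records.items():
            bad = set(seq) - _VALID
            if bad:
                raise AlignmentError(
                    f"invalid residues {sorted(bad)} in sequence {sid!r}"
                )

    @classmethod
    def from_sequences(cls, mapping: Mapping[str, str]) -> "Alignment":
        """Build an alignment, uppercasing and mapping unknown symbols to N."""
        norm = {}
        for sid, seq in mapping.items():
            s = seq.upper()
            if set(s) - _VALID:
                s = "".join(c if c in _VALID else "N" for c in s)
            norm[sid] = s
        return cls(norm)

    @property
    def length(self) -> int:
        return len(next(iter(self.records.values())))

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.records)

    @property
    def n(self) -> int:
        return len(self.records)

    def subset(self, ids: Iterable[str]) -> "Alignment":
        ids = list(ids)
        missing = [i for i in ids if i not in self.records]
        if missing:
            raise AlignmentError(f"unknown sample ids: {missing}")
        return Alignment({i: self.records[i] for i in ids})


@dataclass(frozen=True)
class SampleTable:
    """Georeferenced sample metadata: id -> (species, lat, lon), WGS84 degrees."""

    df: pd.DataFrame  # index: sample id; columns: species, lat, lon

    def __post_init__(self) -> None:
        required = {"species", "lat", "lon"}
        missing = required - set(self.df.columns)
        if missing:
            raise SampleTableError(f"missing column(s): {sorted(missing)}")
        if self.df.index.has_duplicates:
            dups = self.df.index[self.df.index.duplicated()].tolist()
            raise SampleTableError(f"duplicate sample id(s): {dups}")
        lat = self.df["lat"].to_numpy(dtype=float)
        lon = self.df["lon"].to_numpy(dtype=float)
        if np.isnan(lat).any() or np.isnan(lon).any():
            raise SampleTableError("non-numeric or missing coordinates")
        if (np.abs(lat) > 90).any():
            bad = self.df.index[np.abs(lat) > 90].tolist()
            raise SampleTableError(f"latitude out of range [-90, 90] for {bad}")
        if (np.abs(lon) > 180).any():
            bad = self.df.index[np.abs(lon) > 180].tolist()
            raise SampleTableError(f"longitude out of range [-180, 180] for {bad}")

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, float, float]]
    ) -> "SampleTable":
        """Build from (id, species, lat, lon) tuples."""
        rows = list(records)
        df = pd.DataFrame(rows, columns=["id", "species", "lat", "lon"])
        df = df.set_index("id")
        return cls(df)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.df.index)

    def species_of(self, sample_id: str) -> str:
        return str(self.df.at[sample_id, "species"])

    def coords(self, sample_id: str) -> tuple[float, float]:
        """Return (lat, lon) of a sample."""
        row = self.df.loc[sample_id]
        return float(row["lat"]), float(row["lon"])

    def for_species(self, species: str) -> "SampleTable":
        sub = self.df[self.df["species"] == species]
        if sub.empty:
            raise SampleTableError(f"no samples for species {species!r}")
        return SampleTable(sub.copy())


@dataclass(frozen=True)
class CodedAlignment:
    """Character-coded alignment: substitution columns plus binary indel runs.

    ``matrix`` maps each sample to a coded vector laid out as all
    substitution characters (in ``sub_columns`` order) followed by all indel
    characters (in ``indel_spans`` order).  ``None`` marks missing data
    (``N``/gap at a substitution column, or a gap run strictly subsuming an
    indel span).  ``indel_spans`` are half-open ``[start, stop)`` alignment
    column intervals.
    """

    sample_ids: tuple[str, ...]
    length: int
    sub_columns: tuple[int, ...]
    indel_spans: tuple[tuple[int, int], ...]
    matrix: Mapping[str, tuple]

    @property
    def n_sub(self) -> int:
        return len(self.sub_columns)

    @property
    def n_indel(self) -> int:
        return len(self.indel_spans)

    @property
    def n_characters(self) -> int:
        return self.n_sub + self.n_indel

    @property
    def char_labels(self) -> tuple[str, ...]:
        """Provenance labels: s<col> for substitutions, g<start>-<stop> for indels
        (1-based, inclusive)."""
        subs = tuple(f"s{c + 1}" for c in self.sub_columns)
        gaps = tuple(f"g{a + 1}-{b}" for a, b in self.indel_spans)
        return subs + gaps


@dataclass(frozen=True)
class HaplotypeSet:
    """Distinct coded sequence variants with frequencies and carriers."""

    ids: tuple[str, ...]
    vectors: Mapping[str, tuple]
    counts: Mapping[str, int]
    carriers: Mapping[str, tuple[str, ...]]

    @property
    def n(self) -> int:
        """Total number of assigned samples."""
        return int(sum(self.counts.values()))

    def frequencies(self) -> dict[str, float]:
        n = self.n
        return {h: self.counts[h] / n for h in self.ids}

    def assignment(self) -> dict[str, str]:
        """Sample id -> haplotype id."""
        out: dict[str, str] = {}
        for h in self.ids:
            for s in self.carriers[h]:
                out[s] = h
        return out

    def expand(self) -> dict[str, tuple]:
        """Round trip: per-sample coded vectors recovered from the collapse."""
        return {s: tuple(self.vectors[h]) for h, ss in self.carriers.items() for s in ss}

    @classmethod
    def from_vectors(
        cls,
        vectors: Mapping[str, Sequence],
        counts: Mapping[str, int] | None = None,
        carriers: Mapping[str, Sequence[str]] | None = None,
    ) -> "HaplotypeSet":
        """Convenience constructor used by the simulator and tests."""
        ids = tuple(vectors)
        vecs = {h: tuple(vectors[h]) for h in ids}
        if carriers is not None:
            carr = {h: tuple(carriers.get(h, ())) for h in ids}
            cnts = {h: len(carr[h]) for h in ids}
            if counts is not None:
                cnts = {h: int(counts[h]) for h in ids}
        else:
            cnts = {h: int(counts[h]) if counts else 1 for h in ids}
            carr = {h: tuple(f"{h}_{k}" for k in range(cnts[h])) for h in ids}
        return cls(ids=ids, vectors=vecs, counts=cnts, carriers=carr)


@dataclass(frozen=True)
class PolymorphismSummary:
    """Polymorphic-site count (indels included) and per-site nucleotide diversity."""

    n_snps: int
    pi: float
    pi_sd: float
    n_samples: int
    n_haplotypes: int


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file.

    Sequence ids are the first whitespace-delimited token of each header.
    Residues are uppercased; symbols outside ``{A,C,G,T,-,N}`` become ``N``.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    mapping: dict[str, str] = {}
    for rec in records:
        if rec.id in mapping:
            raise AlignmentError(f"duplicate sequence id {rec.id!r} in {path}")
        mapping[rec.id] = str(rec.seq)
    return Alignment.from_sequences(mapping)


_COLUMN_SYNONYMS = {
    "id": "id",
    "sample": "id",
    "sample_id": "id",
    "species": "species",
    "lat": "lat",
    "latitude": "lat",
    "lon": "lon",
    "long": "lon",
    "longitude": "lon",
}


def read_sample_table(path: str | Path) -> SampleTable:
    """Read a tab-delimited sample table with id/species/lat/lon columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    renamed = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _COLUMN_SYNONYMS:
            renamed[col] = _COLUMN_SYNONYMS[key]
    df = df.rename(columns=renamed)
    missing = {"id", "species", "lat", "lon"} - set(df.columns)
    if missing:
        raise SampleTableError(f"missing column(s): {sorted(missing)}")
    try:
        df["lat"] = pd.to_numeric(df["lat"], errors="raise")
        df["lon"] = pd.to_numeric(df["lon"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise SampleTableError(f"non-numeric coordinates: {exc}") from exc
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise SampleTableError(f"duplicate sample id(s): {dups}")
    df = df.set_index("id")[["species", "lat", "lon"]]
    return SampleTable(df)


# ---------------------------------------------------------------------------
# indel coding and collapsing
# ---------------------------------------------------------------------------


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal runs of '-' as half-open [start, stop) intervals."""
    runs = []
    start = None
    for i, c in enumerate(seq):
        if c == "-":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def code_indels(aln: Alignment) -> CodedAlignment:
    """Code an alignment with simple indel coding.

    Each maximal gap run with identical start and end across the samples
    sharing it becomes one binary character; overlapping but non-identical
    runs become separate characters.  A sample whose gap strictly subsumes a
    span is coded missing at that character.  Substitution characters are
    taken from columns with >= 2 nucleotide states among ungapped samples.
    """
    sample_ids = aln.ids
    seqs = {s: aln.records[s] for s in sample_ids}
    L = aln.length

    runs_per_sample = {s: set(_gap_runs(seq)) for s, seq in seqs.items()}
    spans = tuple(sorted({r for runs in runs_per_sample.values() for r in runs}))

    # column-wise scan for substitution characters (numpy for speed)
    arr = np.frombuffer(
        "".join(seqs[s] for s in sample_ids).encode("ascii"), dtype="S1"
    ).reshape(len(sample_ids), L)
    sub_cols = []
    nt_bytes = [b"A", b"C", b"G", b"T"]
    present = np.stack([(arr == b).any(axis=0) for b in nt_bytes])  # 4 x L
    variable = present.sum(axis=0) >= 2
    sub_cols = tuple(int(c) for c in np.flatnonzero(variable))

    matrix: dict[str, tuple] = {}
    for si, s in enumerate(sample_ids):
        row = seqs[s]
        sub_vals = tuple(
            row[c] if row[c] in _NUCLEOTIDES else None for c in sub_cols
        )
        indel_vals = []
        for a, b in spans:
            if (a, b) in runs_per_sample[s]:
                indel_vals.append(1)
            elif all(row[i] == "-" for i in range(a, b)):
                indel_vals.append(None)  # subsumed by a longer gap
            else:
                indel_vals.append(0)
        matrix[s] = sub_vals + tuple(indel_vals)

    return CodedAlignment(
        sample_ids=sample_ids,
        length=L,
        sub_columns=sub_cols,
        indel_spans=spans,
        matrix=matrix,
    )


def concatenate_coded(parts: Sequence[CodedAlignment]) -> CodedAlignment:
    """Concatenate coded alignments (multi-locus haplotypes) keyed by sample id.

    All parts must cover the same sample set; columns of later loci are
    offset by the cumulative alignment length so provenance stays unique.
    """
    if not parts:
        raise AlignmentError("nothing to concatenate")
    base_ids = set(parts[0].sample_ids)
    for p in parts[1:]:
        if set(p.sample_ids) != base_ids:
            diff = base_ids.symmetric_difference(p.sample_ids)
            raise SampleTableError(
                f"loci cover different sample sets; mismatched ids: {sorted(diff)[:10]}"
            )
    sample_ids = parts[0].sample_ids
    offset = 0
    sub_columns: list[int] = []
    indel_spans: list[tuple[int, int]] = []
    sub_vals = {s: [] for s in sample_ids}
    indel_vals = {s: [] for s in sample_ids}
    for p in parts:
        sub_columns.extend(c + offset for c in p.sub_columns)
        indel_spans.extend((a + offset, b + offset) for a, b in p.indel_spans)
        for s in sample_ids:
            vec = p.matrix[s]
            sub_vals[s].extend(vec[: p.n_sub])
            indel_vals[s].extend(vec[p.n_sub:])
        offset += p.length
    matrix = {
        s: tuple(sub_vals[s]) + tuple(indel_vals[s]) for s in sample_ids
    }
    return CodedAlignment(
        sample_ids=sample_ids,
        length=offset,
        sub_columns=tuple(sub_columns),
        indel_spans=tuple(indel_spans),
        matrix=matrix,
    )


def collapse_haplotypes(
    coded: CodedAlignment,
    samples: SampleTable | None = None,
    prefix: str = "H",
) -> HaplotypeSet:
    """Merge identical coded vectors into haplotypes.

    Haplotype ids are assigned in decreasing count, ties broken by first
    appearance in the alignment.  Samples missing data at any coded
    character (N or subsumed gap at a variable character) cannot be placed
    and are dropped with a warning.
    """
    if samples is not None:
        absent = [s for s in coded.sample_ids if s not in set(samples.ids)]
        if absent:
            raise SampleTableError(
                f"samples missing from the sample table: {absent[:10]}"
            )
    complete = [s for s in coded.sample_ids if None not in coded.matrix[s]]
    dropped = [s for s in coded.sample_ids if s not in set(complete)]
    if dropped:
        log.warning(
            "dropping %d sample(s) with ambiguous/missing coded states: %s",
            len(dropped),
            dropped[:10],
        )
    if not complete:
        raise InsufficientDataError("all samples dropped: no complete coded vectors")

    groups: dict[tuple, list[str]] = {}
    order: dict[tuple, int] = {}
    for i, s in enumerate(complete):
        vec = tuple(coded.matrix[s])
        if vec not in groups:
            groups[vec] = []
            order[vec] = i
        groups[vec].append(s)

    ranked = sorted(groups, key=lambda v: (-len(groups[v]), order[v]))
    ids = tuple(f"{prefix}{k + 1}" for k in range(len(ranked)))
    vectors = {ids[k]: ranked[k] for k in range(len(ranked))}
    counts = {ids[k]: len(groups[ranked[k]]) for k in range(len(ranked))}
    carriers = {ids[k]: tuple(groups[ranked[k]]) for k in range(len(ranked))}
    return HaplotypeSet(ids=ids, vectors=vectors, counts=counts, carriers=carriers)


# ---------------------------------------------------------------------------
# polymorphism summary
# ---------------------------------------------------------------------------


def coded_distance(u: Sequence, v: Sequence) -> int:
    """Mutation steps between coded vectors: differing characters, one step per
    substitution or indel character; missing values are skipped pairwise."""
    return sum(
        1 for a, b in zip(u, v) if a is not None and b is not None and a != b
    )


def summarize_polymorphism(
    aln: Alignment, coded: CodedAlignment
) -> PolymorphismSummary:
    """Polymorphic sites (indels counted once) and per-site nucleotide diversity.

    Nucleotide diversity is the average number of differences per site
    between two sequences, ``pi = n/(n-1) * sum_{h,g} p_h p_g d_hg / L``,
    with ``d_hg`` counting substitution differences plus one per differing
    indel character.  The standard deviation follows the Nei (1987) total
    variance formula for pi, as classical population-genetics software
    reports it:

        V(pi) = (n+1)/(3(n-1)L) * pi + 2(n^2+n+3)/(9n(n-1)) * pi^2
    """
    haps = collapse_haplotypes(coded)
    n = haps.n
    if n < 2:
        raise InsufficientDataError("nucleotide diversity requires >= 2 sequences")
    L = aln.length
    ids = haps.ids
    H = len(ids)
    d = np.zeros((H, H))
    for i in range(H):
        for j in range(i + 1, H):
            d[i, j] = d[j, i] = coded_distance(haps.vectors[ids[i]], haps.vectors[ids[j]])
    p = np.array([haps.counts[h] for h in ids], dtype=float) / n
    pi = (n / (n - 1)) * float(p @ d @ p) / L
    var = (n + 1) / (3 * (n - 1) * L) * pi + (
        2 * (n * n + n + 3) / (9 * n * (n - 1))
    ) * pi * pi
    return PolymorphismSummary(
        n_snps=coded.n_characters,
        pi=pi,
        pi_sd=math.sqrt(max(var, 0.0)),
        n_samples=n,
        n_haplotypes=H,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_fasta(aln: Alignment, path: str | Path) -> None:
    """Write an alignment as single-line-per-sequence FASTA (deterministic)."""
    with open(path, "w") as fh:
        for sid in aln.ids:
            fh.write(f">{sid}\n{aln.records[sid]}\n")


def write_haplotype_membership(haps: HaplotypeSet, path: str | Path) -> None:
    """TSV mapping each sample id to its haplotype id."""
    rows = [(s, h) for h in haps.ids for s in haps.carriers[h]]
    pd.DataFrame(rows, columns=["sample", "haplotype"]).to_csv(
        path, sep="\t", index=False
    )


def write_haplotype_fasta(
    haps: HaplotypeSet, aln: Alignment, path: str | Path
) -> None:
    """One representative (first carrier) aligned sequence per haplotype."""
    with open(path, "w") as fh:
        for h in haps.ids:
            rep = haps.carriers[h][0]
            fh.write(f">{h} n={haps.counts[h]} rep={rep}\n{aln.records[rep]}\n")
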