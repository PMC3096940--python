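"""Aligned-sequence and population-metadata I/O.

Reads one aligned FASTA per locus and a tab-separated population map
(sample -> population -> geographic group, with coordinates), collapses
sampled sequences into haplotype classes, and classifies alignment sites
into monomorphic / polymorphic / parsimony-informative categories.

Conventions used throughout the package:

* Sequences are normalised to upper case over the nucleotide alphabet
  ``A C G T``, the gap symbol ``-`` and the IUPAC ambiguity codes.
* All downstream statistics use *complete deletion*: any column containing
  a non-ACGT symbol in any sequence is excluded for every sequence.
* Haplotype identity is defined over the retained (usable) sites only, so
  indel columns never distinguish haplotypes.
* Site indices are 0-based half-open internally; report writers print
  1-based positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceAlignment",
    "PopulationMap",
    "HaplotypeTable",
    "SiteClasses",
    "AlignmentError",
    "read_alignment",
    "read_population_map",
    "parse_coordinate",
    "usable_sites",
    "collapse_haplotypes",
    "classify_sites",
    "write_haplotype_table",
]

#: Nucleotides, gap, missing and IUPAC ambiguity codes accepted on input.
ALPHABET = frozenset("ACGT-NRYSWKMBDHV")
#: Unambiguous nucleotide states; only columns made of these are "usable".
ACGT = frozenset("ACGT")


class AlignmentError(ValueError):
    """Raised for malformed alignments or inconsistent population maps."""


@dataclass(frozen=True)
class SequenceAlignment:
    """An aligned set of equal-length nucleotide sequences for one locus."""

    locus_name: str
    sample_ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise AlignmentError("sample_ids and sequences differ in length")
        if not self.sequences:
            raise AlignmentError("empty alignment")
        L = len(self.sequences[0])
        if L == 0:
            raise AlignmentError("zero-length sequences")
        for sid, seq in zip(self.sample_ids, self.sequences):
            if len(seq) != L:
                raise AlignmentError(
                    f"unaligned input: record {sid!r} has length {len(seq)}, "
                    f"expected {L}"
                )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise AlignmentError("duplicate sample ids in alignment")
        for sid, seq in zip(self.sample_ids, self.sequences):
            for pos, ch in enumerate(seq):
                if ch not in ALPHABET:
                    raise AlignmentError(
                        f"illegal character {ch!r} in record {sid!r} "
                        f"at position {pos + 1}"
                    )

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        """Alignment length L in sites."""
        return len(self.sequences[0])

    def to_array(self) -> np.ndarray:
        """Return the alignment as an (n, L) array of single characters."""
        return np.array([list(s) for s in self.sequences], dtype="U1")


def read_alignment(path: str | Path, locus_name: str | None = None) -> SequenceAlignment:
    """Read an aligned FASTA file, preserving record order.

    Sequences are upper-cased; ragged record lengths, an empty file or
    characters outside the nucleotide/IUPAC alphabet raise
    :class:`AlignmentError`.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    ids = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)
    return SequenceAlignment(
        locus_name=locus_name or path.stem, sample_ids=ids, sequences=seqs
    )


def write_alignment(aln: SequenceAlignment, path: str | Path) -> None:
    """Write an alignment back out as FASTA (one line per sequence)."""
    with open(path, "w") as fh:
        for sid, seq in zip(aln.sample_ids, aln.sequences):
            fh.write(f">{sid}\n{seq}\n")


def parse_coordinate(text: str | float) -> float:
    """Convert a coordinate to decimal degrees.

    Accepts plain decimal degrees or the degree-minute(-second) dialect
    used in field tables (e.g. ``23°31′N``, ``23'31''N``, ``120'49E``,
    ``24°08"N``): numeric tokens are read in order as degrees, minutes,
    seconds, whatever separators appear between them. South and west are
    returned negative.
    """
    if isinstance(text, (int, float)):
        return float(text)
    s = str(text).strip()
    try:
        return float(s)
    except ValueError:
        pass
    numbers = re.findall(r"\d+(?:\.\d+)?", s)
    hemis = re.findall(r"[NSEWnsew]", re.sub(r"\d+(?:\.\d+)?", " ", s))
    leftover = re.sub(r"[\d.\s°'′″\"dDmM]|[NSEWnsew]", "", s)
    if not numbers or len(numbers) > 3 or len(hemis) != 1 or leftover:
        raise AlignmentError(f"unparseable coordinate {text!r}")
    parts = [float(x) for x in numbers] + [0.0, 0.0]
    value = parts[0] + parts[1] / 60.0 + parts[2] / 3600.0
    if hemis[0].upper() in "SW":
        value = -value
    return value


@dataclass(frozen=True)
class PopulationMap:
    """sample -> population -> group assignment with deme coordinates."""

    table: pd.DataFrame  # columns: sample_id, population, group, lat_dd, lon_dd

    def __post_init__(self) -> None:
        required = ["sample_id", "population", "group", "lat_dd", "lon_dd"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise AlignmentError(f"population map missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise AlignmentError(f"duplicate sample ids in population map: {list(dups)}")
        groups_per_pop = self.table.groupby("population")["group"].nunique()
        bad = groups_per_pop[groups_per_pop > 1]
        if not bad.empty:
            raise AlignmentError(
                f"populations mapped to multiple groups: {list(bad.index)}"
            )
        coords_per_pop = self.table.groupby("population")[["lat_dd", "lon_dd"]].nunique()
        if (coords_per_pop > 1).any().any():
            raise AlignmentError("population with inconsistent coordinates")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def populations(self) -> list[str]:
        """Population codes in order of first appearance."""
        return list(dict.fromkeys(self.table["population"]))

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def population_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise AlignmentError(f"sample {sample_id!r} not in population map")
        return row["population"].iloc[0]

    def group_of(self, population: str) -> str:
        row = self.table.loc[self.table["population"] == population]
        if row.empty:
            raise AlignmentError(f"population {population!r} not in map")
        return row["group"].iloc[0]

    def population_sizes(self) -> dict[str, int]:
        return self.table.groupby("population", sort=False).size().to_dict()

    def coordinates(self) -> dict[str, tuple[float, float]]:
        """Per-population (lat, lon) in decimal degrees."""
        out: dict[str, tuple[float, float]] = {}
        for pop, sub in self.table.groupby("population", sort=False):
            out[pop] = (float(sub["lat_dd"].iloc[0]), float(sub["lon_dd"].iloc[0]))
        return out


def read_population_map(path: str | Path) -> PopulationMap:
    """Read a population map TSV with header
    ``sample_id population group lat_dd lon_dd``.

    Coordinates may be decimal degrees or degree-minute strings
    (see :func:`parse_coordinate`).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "population", "group", "lat_dd", "lon_dd"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AlignmentError(f"population map missing columns: {missing}")
    df = df[required].copy()
    df["lat_dd"] = df["lat_dd"].map(parse_coordinate)
    df["lon_dd"] = df["lon_dd"].map(parse_coordinate)
    return PopulationMap(df.reset_index(drop=True))


def usable_sites(aln: SequenceAlignment, policy: str = "complete_deletion") -> list[int]:
    """Indices (0-based, ascending) of columns containing only A/C/G/T.

    ``complete_deletion`` is the only supported policy: a column with a gap,
    N or ambiguity code in *any* sequence is dropped for every sequence.
    """
    if policy != "complete_deletion":
        raise ValueError(f"unknown gap policy {policy!r}")
    arr = aln.to_array()
    ok = np.ones(aln.length, dtype=bool)
    for ch in set("".join(aln.sequences)) - ACGT:
        ok &= ~(arr == ch).any(axis=0)
    return [int(i) for i in np.nonzero(ok)[0]]


@dataclass(frozen=True)
class HaplotypeTable:
    """Unique haplotypes with a haplotype x population count matrix."""

    haplotype_ids: tuple[str, ...]
    haplotype_sequences: tuple[str, ...]  # over usable sites only
    populations: tuple[str, ...]
    counts: np.ndarray  # shape (H, P), non-negative ints
    usable_sites: tuple[int, ...]
    locus_name: str = "locus"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.haplotype_ids), len(self.populations)):
            raise AlignmentError("count matrix shape mismatch")
        if (counts < 0).any():
            raise AlignmentError("negative haplotype counts")
        if (counts.sum(axis=1) < 1).any():
            raise AlignmentError("haplotype with zero total count")
        if len(set(self.haplotype_sequences)) != len(self.haplotype_sequences):
            raise AlignmentError("duplicate haplotype sequences")

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_ids)

    @property
    def n_samples(self) -> int:
        return int(np.asarray(self.counts).sum())

    def population_counts(self, population: str) -> np.ndarray:
        return np.asarray(self.counts)[:, self.populations.index(population)]

    def expand(self, populations: list[str] | None = None) -> list[str]:
        """Repeat each haplotype sequence by its count (optionally within a
        subset of populations), reconstructing the sampled multiset."""
        cols = (
            range(len(self.populations))
            if populations is None
            else [self.populations.index(p) for p in populations]
        )
        counts = np.asarray(self.counts)
        out: list[str] = []
        for h, seq in enumerate(self.haplotype_sequences):
            total = int(sum(counts[h, c] for c in cols))
            out.extend([seq] * total)
        return out

    def frequencies(self, populations: list[str] | None = None) -> np.ndarray:
        """Haplotype count vector pooled over the selected populations."""
        counts = np.asarray(self.counts)
        if populations is None:
            return counts.sum(axis=1)
        cols = [self.populations.index(p) for p in populations]
        return counts[:, cols].sum(axis=1)


def collapse_haplotypes(
    aln: SequenceAlignment,
    popmap: PopulationMap,
    sites: list[int] | None = None,
) -> HaplotypeTable:
    """Collapse sampled sequences into haplotype equivalence classes.

    Haplotypes are classes of identical sequences over the usable sites;
    ids are assigned in order of first appearance (H01, H02, ...).
    """
    if sites is None:
        sites = usable_sites(aln)
    pop_by_sample = dict(zip(popmap.table["sample_id"], popmap.table["population"]))
    unmapped = [s for s in aln.sample_ids if s not in pop_by_sample]
    if unmapped:
        raise AlignmentError(f"samples missing from population map: {unmapped}")
    pops = popmap.populations
    pop_index = {p: i for i, p in enumerate(pops)}

    hap_index: dict[str, int] = {}
    hap_seqs: list[str] = []
    rows: list[np.ndarray] = []
    for sid, seq in zip(aln.sample_ids, aln.sequences):
        key = "".join(seq[i] for i in sites)
        h = hap_index.get(key)
        if h is None:
            h = len(hap_seqs)
            hap_index[key] = h
            hap_seqs.append(key)
            rows.append(np.zeros(len(pops), dtype=int))
        rows[h][pop_index[pop_by_sample[sid]]] += 1

    width = max(2, len(str(len(hap_seqs))))
    ids = tuple(f"H{i + 1:0{width}d}" for i in range(len(hap_seqs)))
    return HaplotypeTable(
        haplotype_ids=ids,
        haplotype_sequences=tuple(hap_seqs),
        populations=tuple(pops),
        counts=np.vstack(rows),
        usable_sites=tuple(sites),
        locus_name=aln.locus_name,
    )


@dataclass(frozen=True)
class SiteClasses:
    """Partition of alignment columns by their variation pattern."""

    monomorphic: int
    polymorphic: int  # S
    singleton: int
    parsimony_informative: int
    excluded: int  # gap/ambiguity columns removed by complete deletion
    length: int

    def __post_init__(self) -> None:
        if self.monomorphic + self.polymorphic + self.excluded != self.length:
            raise AlignmentError("site-class counts do not partition the alignment")
        if self.singleton + self.parsimony_informative != self.polymorphic:
            raise AlignmentError("singleton/informative split does not sum to S")


def classify_sites(
    aln: SequenceAlignment, popmap: PopulationMap | None = None
) -> SiteClasses:
    """Classify usable columns as monomorphic, singleton or
    parsimony-informative.

    Counts are taken over all sampled sequences (each record weighted once;
    an alignment of expanded samples therefore weights haplotypes by their
    frequency). A column is polymorphic when >= 2 states occur and
    parsimony-informative when >= 2 states each occur in >= 2 sequences.
    """
    sites = usable_sites(aln)
    arr = aln.to_array()
    mono = single = inform = 0
    for j in sites:
        _, counts = np.unique(arr[:, j], return_counts=True)
        if len(counts) < 2:
            mono += 1
        elif (counts >= 2).sum() >= 2:
            inform += 1
        else:
            single += 1
    S = single + inform
    return SiteClasses(
        monomorphic=mono,
        polymorphic=S,
        singleton=single,
        parsimony_informative=inform,
        excluded=aln.length - len(sites),
        length=aln.length,
    )


def write_haplotype_table(table: HaplotypeTable, path: str | Path) -> None:
    """Write a haplotype x population frequency TSV (rows = haplotypes)."""
    df = pd.DataFrame(
        np.asarray(table.counts),
        index=pd.Index(table.haplotype_ids, name="haplotype"),
        columns=list(table.populations),
    )
    df["total"] = df.sum(axis=1)
    df.to_csv(path, sep="\t")
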