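"""GATC-fragment coordinate system for DamID-seq.

Dam methyltransferase marks GATC sites, and DpnII digestion releases the
interval between consecutive GATC motifs, so the natural resolution unit of a
DamID experiment is the *GATC fragment*: the genome partitioned at every
occurrence of the (palindromic) motif GATC.  This module builds that partition
from a genome, assigns GATC-anchored read evidence to fragments, and reads and
writes the fragment map (BED4) and per-fragment count tables (TSV).

Coordinates are 0-based half-open throughout.  A fragment "begins" at the G of
its left GATC motif; reads on the minus strand anchor at the right boundary of
a fragment, matching DpnII fragment ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

MOTIF = "GATC"

VALID_GENOTYPES = ("wt", "bam", "aly", "can", "comr", "mip40", "custom")


def _find_motif_positions(seq: str, motif: str = MOTIF) -> np.ndarray:
    """All start positions of ``motif`` in ``seq`` (forward strand only;

    GATC is its own reverse complement, so one strand suffices).
    Overlapping occurrences are impossible for GATC but the scan would find
    them anyway.
    """
    positions = []
    i = seq.find(motif)
    while i != -1:
        positions.append(i)
        i = seq.find(motif, i + 1)
    return np.asarray(positions, dtype=np.int64)


@dataclass
class FragmentMap:
    """Ordered partition of each chromosome into GATC-delimited fragments.

    ``boundaries[chrom]`` holds fragment start positions plus the chromosome
    length as a trailing sentinel, so fragment ``i`` on that chromosome spans
    ``[boundaries[i], boundaries[i + 1])``.  Fragment ids are global integers,
    assigned in chromosome order.
    """

    chroms: list[str]
    boundaries: dict[str, np.ndarray]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            self.chrom_lengths = {
                c: int(self.boundaries[c][-1]) for c in self.chroms
            }
        self._offsets = {}
        off = 0
        for c in self.chroms:
            self._offsets[c] = off
            off += len(self.boundaries[c]) - 1
        self._n_fragments = off

    @property
    def n_fragments(self) -> int:
        return self._n_fragments

    def n_fragments_chrom(self, chrom: str) -> int:
        return len(self.boundaries[chrom]) - 1

    def chrom_offset(self, chrom: str) -> int:
        return self._offsets[chrom]

    def fragment_lengths(self) -> np.ndarray:
        """Lengths of all fragments, in global fragment-id order."""
        return np.concatenate(
            [np.diff(self.boundaries[c]) for c in self.chroms]
        )

    def iter_fragments(self) -> Iterator[tuple[int, str, int, int]]:
        """Yield (fragment_id, chrom, start, end)."""
        fid = 0
        for c in self.chroms:
            b = self.boundaries[c]
            for i in range(len(b) - 1):
                yield fid, c, int(b[i]), int(b[i + 1])
                fid += 1

    def fragment_at(self, chrom: str, pos: int) -> int:
        """Global id of the fragment containing position ``pos``.

        Raises ``ValueError`` if the position falls outside the chromosome.
        """
        if chrom not in self._offsets:
            raise ValueError(f"unknown chromosome {chrom!r}")
        b = self.boundaries[chrom]
        if pos < 0 or pos >= b[-1]:
            raise ValueError(f"position {pos} outside chromosome {chrom!r}")
        i = int(np.searchsorted(b, pos, side="right")) - 1
        return self._offsets[chrom] + i

    def fragments_in_window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global ids of fragments overlapping [start, end)."""
        if chrom not in self._offsets:
            raise ValueError(f"unknown chromosome {chrom!r}")
        b = self.boundaries[chrom]
        start = max(0, start)
        end = min(int(b[-1]), end)
        if end <= start:
            return np.empty(0, dtype=np.int64)
        lo = int(np.searchsorted(b, start, side="right")) - 1
        hi = int(np.searchsorted(b, end, side="left"))
        return np.arange(lo, hi, dtype=np.int64) + self._offsets[chrom]

    def fragment_interval(self, fragment_id: int) -> tuple[str, int, int]:
        """(chrom, start, end) of a global fragment id."""
        for c in self.chroms:
            n = self.n_fragments_chrom(c)
            off = self._offsets[c]
            if off <= fragment_id < off + n:
                i = fragment_id - off
                b = self.boundaries[c]
                return c, int(b[i]), int(b[i + 1])
        raise ValueError(f"fragment id {fragment_id} out of range")

    def fragment_midpoints(self) -> pd.DataFrame:
        """DataFrame (fragment_id, chrom, start, end, midpoint)."""
        rows = []
        for c in self.chroms:
            b = self.boundaries[c]
            starts = b[:-1]
            ends = b[1:]
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": c,
                        "start": starts,
                        "end": ends,
                        "midpoint": (starts + ends) // 2,
                    }
                )
            )
        df = pd.concat(rows, ignore_index=True)
        df.index.name = "fragment_id"
        return df

    def to_bed(self, path: str | Path) -> None:
        """Write the map as BED4 (chrom, start, end, fragment_id)."""
        with open(path, "w") as fh:
            for fid, chrom, start, end in self.iter_fragments():
                fh.write(f"{chrom}\t{start}\t{end}\t{fid}\n")

    @classmethod
    def from_bed(cls, path: str | Path) -> "FragmentMap":
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "fragment_id"],
            dtype={"chrom": str},
        )
        chroms = list(dict.fromkeys(df["chrom"]))
        boundaries = {}
        for c in chroms:
            sub = df[df["chrom"] == c]
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            if len(starts) > 1 and not np.array_equal(starts[1:], ends[:-1]):
                raise ValueError(f"fragments on {c!r} do not tile the chromosome")
            boundaries[c] = np.concatenate([starts, ends[-1:]])
        return cls(chroms=chroms, boundaries=boundaries)


def _as_sequences(genome) -> Iterator[tuple[str, str]]:
    """Normalise supported genome inputs to (name, sequence) pairs.

    Accepts a mapping of name -> sequence, a pyfaidx.Fasta, a path to a FASTA
    file, or an iterable of Biopython-style records with .id/.seq.
    """
    if isinstance(genome, Mapping):
        yield from ((str(k), str(v)) for k, v in genome.items())
        return
    if isinstance(genome, (str, Path)):
        from pyfaidx import Fasta

        with Fasta(str(genome)) as fa:
            for name in fa.keys():
                yield name, str(fa[name][:])
        return
    for rec in genome:  # pyfaidx.Fasta iterates records; Bio.SeqRecord too
        name = getattr(rec, "name", None) or getattr(rec, "id", None)
        yield str(name), str(getattr(rec, "seq", rec)[:])


def build_fragment_map(genome) -> FragmentMap:
    """Partition every chromosome of ``genome`` at GATC motif occurrences.

    Boundaries fall at the G of each GATC, so each internal fragment begins
    with the motif.  Case-insensitive.  A chromosome without any GATC yields a
    single fragment spanning it (with a warning); an empty sequence is an
    error.
    """
    chroms: list[str] = []
    boundaries: dict[str, np.ndarray] = {}
    for name, seq in _as_sequences(genome):
        if len(seq) == 0:
            raise ValueError(f"chromosome {name!r} has empty sequence")
        pos = _find_motif_positions(seq.upper())
        if len(pos) == 0:
            warnings.warn(
                f"chromosome {name!r} contains no GATC motif; "
                "emitting a single fragment",
                stacklevel=2,
            )
        b = pos[pos > 0]  # a motif at 0 coincides with the chromosome start
        boundaries[name] = np.concatenate(
            [[0], b, [len(seq)]]
        ).astype(np.int64)
        chroms.append(name)
    if not chroms:
        raise ValueError("genome contains no sequences")
    return FragmentMap(chroms=chroms, boundaries=boundaries)


@dataclass
class FragmentCounts:
    """Per-fragment read counts for one library (channel x replicate)."""

    sample_id: str
    genotype: str
    construct: str  # "dam_fusion" | "dam_alone"
    replicate: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.construct not in ("dam_fusion", "dam_alone"):
            raise ValueError(f"unknown construct {self.construct!r}")
        if self.genotype not in VALID_GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"fragment_id": np.arange(len(self.counts)), "count": self.counts}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        sample_id: str = "sample",
        genotype: str = "custom",
        construct: str = "dam_fusion",
        replicate: int = 1,
        n_fragments: int | None = None,
    ) -> "FragmentCounts":
        df = pd.read_csv(path, sep="\t")
        if not {"fragment_id", "count"} <= set(df.columns):
            raise ValueError("count table must have fragment_id and count columns")
        n = n_fragments if n_fragments is not None else int(df["fragment_id"].max()) + 1
        counts = np.zeros(n, dtype=np.int64)
        counts[df["fragment_id"].to_numpy()] = df["count"].to_numpy()
        return cls(sample_id, genotype, construct, replicate, counts)


@dataclass
class Read:
    """Minimal mapped-read record for GATC filtering."""

    sequence: str
    chrom: str
    position: int  # genomic position of the 5' base of the read
    strand: str  # "+" or "-"
    is_multimapping: bool = False


@dataclass
class ReadFilterStats:
    kept: int = 0
    discarded_no_gatc: int = 0
    discarded_unanchored: int = 0
    discarded_outside_map: int = 0
    discarded_multimapping: int = 0

    @property
    def discarded(self) -> int:
        return (
            self.discarded_no_gatc
            + self.discarded_unanchored
            + self.discarded_outside_map
            + self.discarded_multimapping
        )


def filter_and_count_reads(
    reads: Iterable[Read],
    fmap: FragmentMap,
    sample_id: str = "sample",
    genotype: str = "custom",
    construct: str = "dam_fusion",
    replicate: int = 1,
    drop_multimapping: bool = True,
) -> tuple[FragmentCounts, ReadFilterStats]:
    """Filter reads by the GATC rule and assign survivors to fragments.

    DamID amplicons start at a DpnII cut, so a genuine read must begin with
    GATC; anything else is a non-specific product and is discarded.  A
    plus-strand read anchors at the fragment whose left boundary equals its
    mapped start; a minus-strand read (5' base at position p) anchors at the
    fragment whose *right* boundary is the motif start p - 3.  Reads whose
    5' position does not coincide with a fragment boundary, or that map
    outside the map, are discarded and tallied.
    """
    counts = np.zeros(fmap.n_fragments, dtype=np.int64)
    stats = ReadFilterStats()
    for read in reads:
        if drop_multimapping and read.is_multimapping:
            stats.discarded_multimapping += 1
            continue
        if not read.sequence.upper().startswith(MOTIF):
            stats.discarded_no_gatc += 1
            continue
        if read.chrom not in fmap.boundaries:
            stats.discarded_outside_map += 1
            continue
        b = fmap.boundaries[read.chrom]
        off = fmap.chrom_offset(read.chrom)
        if read.strand == "+":
            anchor = read.position
            # fragment starting exactly at the motif
            i = int(np.searchsorted(b[:-1], anchor))
            if i >= len(b) - 1 or b[i] != anchor:
                stats.discarded_unanchored += 1
                continue
            counts[off + i] += 1
        elif read.strand == "-":
            motif_start = read.position - len(MOTIF) + 1
            # fragment whose right boundary is the motif start
            i = int(np.searchsorted(b, motif_start))
            if i == 0 or i >= len(b) or b[i] != motif_start:
                stats.discarded_unanchored += 1
                continue
            counts[off + i - 1] += 1
        else:
            raise ValueError(f"invalid strand {read.strand!r}")
        stats.kept += 1
    fc = FragmentCounts(sample_id, genotype, construct, replicate, counts)
    return fc, stats


def reads_from_sam(path: str | Path) -> Iterator[Read]:
    """Adapt a SAM/BAM file (via pysam) to the Read records used here."""
    import pysam

    with pysam.AlignmentFile(str(path)) as af:
        for aln in af:
            if aln.is_unmapped:
                continue
            multi = aln.has_tag("NH") and aln.get_tag("NH") > 1
            if aln.is_reverse:
                pos = aln.reference_end - 1  # 5' base of a minus-strand read
                seq = _revcomp(aln.query_sequence or "")
            else:
                pos = aln.reference_start
                seq = aln.query_sequence or ""
            yield Read(
                sequence=seq,
                chrom=aln.reference_name,
                position=pos,
                strand="-" if aln.is_reverse else "+",
                is_multimapping=bool(multi),
            )


_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]
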