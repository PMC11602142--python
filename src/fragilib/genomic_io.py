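"""Genome sequences, intervals and breakpoint sets.

Coordinate conventions
----------------------
All coordinates are 0-based half-open (BED convention) internally. A
breakpoint is a *bond*: the phosphodiester position between base ``b-1``
and base ``b`` on the plus strand, so bond indices run 1..L-1 on a
chromosome of length L. Bonds carry no strand (a double-strand break is
strand-invariant).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class GenomeSequence:
    """Named chromosome sequences, uppercase, alphabet A/C/G/T/N."""

    sequences: Dict[str, str]

    def __post_init__(self) -> None:
        clean = {}
        for name, seq in self.sequences.items():
            if len(seq) == 0:
                raise ValueError(f"empty sequence for record {name!r}")
            clean[name] = seq.upper()
        self.sequences = clean

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(s) for name, s in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(
                f"window [{start},{end}) outside {chrom} (length {len(seq)})"
            )
        return seq[start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)


def read_fasta(path) -> GenomeSequence:
    """Load a FASTA file; records are uppercased, multi-line records are
    concatenated, duplicate record names are an error."""
    records: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA record name: {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSequence(records)


def write_fasta(genome: GenomeSequence, path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


@dataclass(frozen=True, order=True)
class Interval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start},{self.end})")

    def __len__(self) -> int:
        return self.end - self.start


class IntervalSet:
    """Per-chromosome sorted collection of 0-based half-open intervals."""

    def __init__(self, intervals: Iterable[Interval] = ()) -> None:
        self._by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for iv in intervals:
            self._by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom in self._by_chrom:
            self._by_chrom[chrom].sort()

    def __iter__(self) -> Iterator[Interval]:
        for chrom in sorted(self._by_chrom):
            for s, e in self._by_chrom[chrom]:
                yield Interval(chrom, s, e)

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and list(self) == list(other)

    @property
    def chroms(self) -> List[str]:
        return sorted(self._by_chrom)

    def arrays(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        pairs = self._by_chrom.get(chrom, [])
        if not pairs:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        a = np.asarray(pairs, dtype=np.int64)
        return a[:, 0], a[:, 1]

    def total_length(self) -> int:
        return sum(e - s for ivs in self._by_chrom.values() for s, e in ivs)

    def merge(self) -> "IntervalSet":
        """Union of the set: no two output intervals overlap or abut."""
        out = []
        for chrom in sorted(self._by_chrom):
            cur_s = cur_e = None
            for s, e in self._by_chrom[chrom]:
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:  # overlap or abutting
                    cur_e = max(cur_e, e)
                else:
                    out.append(Interval(chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            if cur_s is not None:
                out.append(Interval(chrom, cur_s, cur_e))
        return IntervalSet(out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Base-level set difference self \\ other."""
        other = other.merge()
        out = []
        for iv in self.merge():
            os, oe = other.arrays(iv.chrom)
            pieces = [(iv.start, iv.end)]
            for s, e in zip(os, oe):
                nxt = []
                for ps, pe in pieces:
                    if e <= ps or s >= pe:
                        nxt.append((ps, pe))
                        continue
                    if ps < s:
                        nxt.append((ps, s))
                    if e < pe:
                        nxt.append((e, pe))
                pieces = nxt
            out.extend(Interval(iv.chrom, s, e) for s, e in pieces)
        return IntervalSet(out)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        starts, ends = self.arrays(chrom)
        if starts.size == 0:
            return False
        i = np.searchsorted(starts, end)
        return bool((ends[:i] > start).any())


def read_intervals(path, one_based: bool = False) -> IntervalSet:
    """Read BED3+ (tab-separated, >=3 columns). With ``one_based=True``
    the input is treated as 1-based inclusive and shifted to the internal
    0-based half-open convention."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 columns")
            chrom, s_raw, e_raw = fields[0], fields[1], fields[2]
            try:
                start, end = int(s_raw), int(e_raw)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            if one_based:
                start -= 1
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end ({start} >= {end})")
            out.append(Interval(chrom, start, end))
    return IntervalSet(out)


def write_intervals(ivs: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for iv in ivs:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


@dataclass
class BreakpointSet:
    """Strand-invariant cut positions stored as inter-base bond indices.

    Bond ``b`` on a chromosome denotes the backbone position between base
    ``b-1`` and base ``b`` (plus strand numbering); valid bonds satisfy
    0 < b < chromosome length.
    """

    bonds: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bonds = {
            c: np.unique(np.asarray(b, dtype=np.int64)) for c, b in self.bonds.items()
        }

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, int]]) -> "BreakpointSet":
        d: Dict[str, List[int]] = {}
        for chrom, b in pairs:
            d.setdefault(chrom, []).append(int(b))
        return cls({c: np.asarray(v) for c, v in d.items()})

    @classmethod
    def from_intervals(cls, ivs: IntervalSet) -> "BreakpointSet":
        """Breakpoint = 5' end of the aligned fragment = BED start."""
        d: Dict[str, List[int]] = {}
        for iv in ivs:
            d.setdefault(iv.chrom, []).append(iv.start)
        return cls({c: np.asarray(v) for c, v in d.items()})

    def validate(self, genome: GenomeSequence) -> None:
        for chrom, b in self.bonds.items():
            L = genome.lengths[chrom]
            if b.size and (b.min() <= 0 or b.max() >= L):
                raise ValueError(f"bond outside (0,{L}) on {chrom}")

    def __len__(self) -> int:
        return sum(b.size for b in self.bonds.values())

    @property
    def chroms(self) -> List[str]:
        return sorted(self.bonds)


def subtract_blacklist(breaks: BreakpointSet, blacklist: IntervalSet) -> BreakpointSet:
    """Drop bonds lying inside any blacklist interval.

    A bond is inside an interval [s, e) when either of its flanking bases
    (b-1 or b) is, i.e. when s <= b <= e; bonds at both interval edges
    are therefore removed.
    """
    merged = blacklist.merge()
    out: Dict[str, np.ndarray] = {}
    for chrom, bonds in breaks.bonds.items():
        starts, ends = merged.arrays(chrom)
        if starts.size == 0 or bonds.size == 0:
            out[chrom] = bonds.copy()
            continue
        # interval index whose start is the rightmost <= b
        idx = np.searchsorted(starts, bonds, side="right") - 1
        inside = np.zeros(bonds.shape, dtype=bool)
        valid = idx >= 0
        inside[valid] = bonds[valid] <= ends[idx[valid]]
        out[chrom] = bonds[~inside]
    return BreakpointSet(out)


def breakpoints_to_regions(breaks: BreakpointSet, flank: int, genome: GenomeSequence) -> IntervalSet:
    """Expand each bond into [b-flank, b+flank), clipped to the
    chromosome, and merge overlaps — the 'breakage regions' used for
    control-region construction."""
    out = []
    for chrom, bonds in breaks.bonds.items():
        L = genome.lengths[chrom]
        for b in bonds:
            s, e = max(0, int(b) - flank), min(L, int(b) + flank)
            if s < e:
                out.append(Interval(chrom, s, e))
    return IntervalSet(out).merge()
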