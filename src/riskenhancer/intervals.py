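"""Genome coordinate conventions and interval-track utilities.

Internal coordinates are 0-based half-open throughout ([start, end)); VCF
positions are 1-based and converted on ingest, BED is native half-open.  A
point query for a SNP therefore uses its 0-based position, and a SNP sitting
exactly at an interval's ``end`` is not a member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names and lengths of the working (synthetic) genome."""

    chromosomes: tuple[str, ...]
    lengths: tuple[int, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.chromosomes) != len(set(self.chromosomes)):
            raise ValueError("chromosome names must be unique")
        if len(self.chromosomes) != len(self.lengths):
            raise ValueError("one length per chromosome required")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def length_by_chrom(self) -> dict[str, int]:
        return dict(zip(self.chromosomes, self.lengths))

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))


class IntervalTrack:
    """One named set of half-open genomic intervals with point/range queries."""

    def __init__(self, name: str, frame: pd.DataFrame):
        required = {"chrom", "start", "end"}
        if not required.issubset(frame.columns):
            raise ValueError(f"track needs columns {sorted(required)}")
        bad = frame["end"] <= frame["start"]
        if bad.any():
            row = frame[bad].iloc[0]
            raise ValueError(
                f"malformed interval in {name!r}: {row.chrom}:{row.start}-{row.end}"
            )
        self.name = name
        self.frame = frame.reset_index(drop=True)
        self._trees: dict[str, IntervalTree] = {}
        for chrom, sub in frame.groupby("chrom", sort=False):
            self._trees[str(chrom)] = IntervalTree.from_tuples(
                zip(sub["start"].astype(int), sub["end"].astype(int))
            )

    def __len__(self) -> int:
        return len(self.frame)

    def contains_point(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos0))

    def overlaps_range(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))


@dataclass
class TrackSet:
    """Named biofeature tracks, queried together for SNP membership."""

    tracks: dict[str, IntervalTrack] = field(default_factory=dict)

    @classmethod
    def from_frames(cls, frames: Mapping[str, pd.DataFrame]) -> "TrackSet":
        return cls({name: IntervalTrack(name, f) for name, f in frames.items()})

    def add(self, track: IntervalTrack) -> None:
        self.tracks[track.name] = track

    def names(self) -> list[str]:
        return list(self.tracks)

    def memberships(self, chrom: str, pos0: int) -> set[str]:
        return {name for name, t in self.tracks.items()
                if t.contains_point(chrom, pos0)}


def read_bed(path: str | Path, name: str | None = None) -> IntervalTrack:
    """Read BED3/BED6 into a track (half-open, as BED is natively)."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    frame.columns = BED6_COLUMNS[: frame.shape[1]]
    return IntervalTrack(name or Path(path).stem, frame)


def write_bed(frame: pd.DataFrame, path: str | Path) -> None:
    """Write BED6 (missing optional columns filled with '.' / 0 / '+')."""
    out = frame.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", "+")):
        if col not in out.columns:
            out[col] = default
    out[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def random_sequences(spec: GenomeSpec, seed: int) -> dict[str, str]:
    """IID random genome sequences for motif-profile work on synthetic data."""
    rng = np.random.default_rng(seed)
    out = {}
    for chrom, length in zip(spec.chromosomes, spec.lengths):
        out[chrom] = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
    return out


class SequenceProvider:
    """Fetch genomic subsequences from an in-memory dict or a FASTA file."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = sequences

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SequenceProvider":
        from Bio import SeqIO

        return cls({rec.id: str(rec.seq).upper()
                    for rec in SeqIO.parse(str(path), "fasta")})

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self._seqs[chrom]
        if start < 0 or end > len(seq):
            raise ValueError(f"range {chrom}:{start}-{end} outside sequence")
        return seq[start:end]

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")
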