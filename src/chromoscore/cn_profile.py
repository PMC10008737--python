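"""Copy-number profile data model, SEG I/O and preprocessing.

A profile is a per-sample list of contiguous integer-copy-number
segments. Coordinates are 1-based inclusive (SEG convention); interval
arithmetic is done half-open internally and converted at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeBuild

__all__ = [
    "CNSegment",
    "CNProfile",
    "Breakpoint",
    "read_seg",
    "write_seg",
    "filter_profile",
    "tumor_ploidy",
    "breakpoints",
    "SegParseError",
]

SEG_COLUMNS = ["sample", "chromosome", "start", "end", "copy_number"]


class SegParseError(ValueError):
    """Raised on malformed SEG input, citing the offending line."""


@dataclass(frozen=True, order=True)
class CNSegment:
    chromosome: str
    start: int  # 1-based inclusive
    end: int    # inclusive
    copy_number: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Breakpoint:
    chromosome: str
    position: int  # first base of the right-hand segment
    left_cn: int
    right_cn: int


@dataclass
class CNProfile:
    """Ordered, non-overlapping CN segments for one sample."""

    sample_id: str
    segments: list[CNSegment]
    genome: GenomeBuild

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments)
        prev: CNSegment | None = None
        for seg in self.segments:
            if prev is not None and seg.chromosome == prev.chromosome and seg.start <= prev.end:
                raise ValueError(
                    f"{self.sample_id}: overlapping segments on {seg.chromosome} "
                    f"({prev.start}-{prev.end} and {seg.start}-{seg.end})"
                )
            prev = seg

    def by_chromosome(self) -> dict[str, list[CNSegment]]:
        out: dict[str, list[CNSegment]] = {}
        for seg in self.segments:
            out.setdefault(seg.chromosome, []).append(seg)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.sample_id, s.chromosome, s.start, s.end, s.copy_number) for s in self.segments],
            columns=SEG_COLUMNS,
        )


def read_seg(path, genome: GenomeBuild | None = None) -> list[CNProfile]:
    """Read a tab-delimited SEG file into per-sample profiles.

    Expected columns: sample, chromosome, start, end, copy_number.
    Malformed rows raise :class:`SegParseError` naming the line number.
    When ``genome`` is omitted, a minimal build is inferred with each
    chromosome length taken as the maximal observed end and the arm
    boundary at the midpoint.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise SegParseError(f"{path}: missing column(s) {missing}")
    if df.empty:
        return []
    records = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # 1-based, after header
        try:
            start, end, cn = int(row["start"]), int(row["end"]), int(row["copy_number"])
        except (TypeError, ValueError) as exc:
            raise SegParseError(f"{path} line {line_no}: non-integer field ({exc})") from None
        if start > end:
            raise SegParseError(f"{path} line {line_no}: start {start} > end {end}")
        if cn < 0:
            raise SegParseError(f"{path} line {line_no}: negative copy number")
        records.append((str(row["sample"]), str(row["chromosome"]), start, end, cn))
    frame = pd.DataFrame(records, columns=SEG_COLUMNS)
    if genome is None:
        ends = frame.groupby("chromosome")["end"].max()
        genome = GenomeBuild(
            lengths={c: int(e) for c, e in ends.items()},
            arm_boundaries={c: max(1, int(e) // 2) for c, e in ends.items()},
        )
    profiles = []
    for sample, grp in frame.groupby("sample", sort=True):
        segs = [
            CNSegment(r.chromosome, r.start, r.end, r.copy_number)
            for r in grp.itertuples(index=False)
        ]
        profiles.append(CNProfile(sample_id=str(sample), segments=segs, genome=genome))
    return profiles


def write_seg(profiles: list[CNProfile], path) -> None:
    frames = [p.to_frame() for p in profiles]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=SEG_COLUMNS)
    out.to_csv(path, sep="\t", index=False)


def _merge_adjacent(segs: list[CNSegment]) -> list[CNSegment]:
    """Merge contiguous equal-CN neighbours (per chromosome)."""
    merged: list[CNSegment] = []
    for seg in segs:
        if (
            merged
            and merged[-1].chromosome == seg.chromosome
            and merged[-1].copy_number == seg.copy_number
            and merged[-1].end + 1 == seg.start
        ):
            merged[-1] = replace(merged[-1], end=seg.end)
        else:
            merged.append(seg)
    return merged


def _subtract_interval(seg: CNSegment, start: int, end: int) -> list[CNSegment]:
    """Remove [start, end] (1-based inclusive) from a segment."""
    if end < seg.start or start > seg.end:
        return [seg]
    parts = []
    if seg.start < start:
        parts.append(replace(seg, end=start - 1))
    if seg.end > end:
        parts.append(replace(seg, start=end + 1))
    return parts


def tumor_ploidy(profile: CNProfile) -> int:
    """Length-weighted median integer copy number over autosomal segments.

    The weight of each segment is its length in bp; the weighted median
    is taken over the implied per-base multiset of copy numbers. When the
    median falls exactly between two values the lower one is returned
    (conservative, deterministic).
    """
    segs = [s for s in profile.segments if s.chromosome not in profile.genome.sex_chromosomes]
    if not segs:
        raise ValueError(f"{profile.sample_id}: no autosomal segments, ploidy undefined")
    cns = np.array([s.copy_number for s in segs], dtype=float)
    weights = np.array([s.length for s in segs], dtype=float)
    order = np.argsort(cns, kind="stable")
    cns, weights = cns[order], weights[order]
    cum = np.cumsum(weights)
    half = cum[-1] / 2.0
    idx = int(np.searchsorted(cum, half))  # first index with cum >= half -> lower median
    return int(round(cns[idx]))


def breakpoints(profile: CNProfile) -> list[Breakpoint]:
    """Copy-number transitions between adjacent segments.

    One breakpoint per adjacent pair with differing CN; chromosome ends
    are never breakpoints. The position is the first base of the
    right-hand segment.
    """
    out: list[Breakpoint] = []
    for _, segs in profile.by_chromosome().items():
        for left, right in zip(segs, segs[1:]):
            if left.copy_number != right.copy_number:
                out.append(
                    Breakpoint(right.chromosome, right.start, left.copy_number, right.copy_number)
                )
    return out


def filter_profile(
    profile: CNProfile,
    min_change_len: int = 50_000,
    excluded_regions: list[tuple[str, int, int]] | None = None,
) -> CNProfile:
    """Preprocess a profile for signature analysis.

    Drops sex chromosomes whole, subtracts excluded intervals (Ig loci
    by default when the genome build carries them), reverts CN-changed
    segments shorter than ``min_change_len`` to the sample's baseline
    ploidy, and merges contiguous equal-CN neighbours. "Changed" is
    judged against the length-weighted median ploidy computed before
    filtering. Idempotent.
    """
    if excluded_regions is None:
        excluded_regions = list(profile.genome.excluded_regions)
    try:
        ploidy = tumor_ploidy(profile)
    except ValueError:
        ploidy = None

    segs = [s for s in profile.segments if s.chromosome not in profile.genome.sex_chromosomes]
    for chrom, start, end in excluded_regions:
        segs = [part for seg in segs for part in (
            _subtract_interval(seg, start, end) if seg.chromosome == chrom else [seg]
        )]
    segs = sorted(segs)
    if ploidy is not None:
        segs = [
            replace(s, copy_number=ploidy)
            if s.copy_number != ploidy and s.length < min_change_len
            else s
            for s in segs
        ]
    segs = _merge_adjacent(segs)
    return CNProfile(sample_id=profile.sample_id, segments=segs, genome=profile.genome)


def warn_if_unfiltered(profile: CNProfile) -> None:
    sex = {s.chromosome for s in profile.segments} & set(profile.genome.sex_chromosomes)
    if sex:
        warnings.warn(
            f"{profile.sample_id}: profile still carries sex chromosome(s) {sorted(sex)}; "
            "apply filter_profile first",
            stacklevel=2,
        )
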