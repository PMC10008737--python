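"""Genome build description: chromosome lengths and arm boundaries.

Coordinates are 1-based inclusive throughout the public API (SEG
convention). Arm boundaries mark the last base of the p arm; positions
greater than the boundary belong to the q arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = ["GenomeBuild", "default_genome"]


@dataclass(frozen=True)
class GenomeBuild:
    """Chromosome lengths (bp) and p/q arm boundaries (bp, 1-based).

    Parameters
    ----------
    lengths
        Mapping chromosome name -> length in bp.
    arm_boundaries
        Mapping chromosome name -> last base of the p arm.
    sex_chromosomes
        Names excluded from autosomal computations (ploidy, wGII) and
        dropped whole by the profile filter.
    """

    lengths: dict[str, int]
    arm_boundaries: dict[str, int]
    sex_chromosomes: tuple[str, ...] = ("chrX", "chrY", "X", "Y")
    excluded_regions: tuple[tuple[str, int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
            bound = self.arm_boundaries.get(name)
            if bound is not None and not (0 < bound < length):
                raise ValueError(f"arm boundary of {name} outside chromosome")

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.lengths if c not in self.sex_chromosomes]

    def arms(self, chromosome: str) -> list[tuple[str, int, int]]:
        """Return (arm name, start, end) intervals, 1-based inclusive."""
        length = self.lengths[chromosome]
        bound = self.arm_boundaries.get(chromosome)
        if bound is None:
            return [(f"{chromosome}", 1, length)]
        return [(f"{chromosome}p", 1, bound), (f"{chromosome}q", bound + 1, length)]

    @classmethod
    def from_yaml(cls, path) -> "GenomeBuild":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            lengths={str(k): int(v) for k, v in raw["lengths"].items()},
            arm_boundaries={str(k): int(v) for k, v in raw.get("arm_boundaries", {}).items()},
            sex_chromosomes=tuple(raw.get("sex_chromosomes", ("chrX", "chrY", "X", "Y"))),
            excluded_regions=tuple(
                (str(c), int(s), int(e)) for c, s, e in raw.get("excluded_regions", [])
            ),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "lengths": dict(self.lengths),
                    "arm_boundaries": dict(self.arm_boundaries),
                    "sex_chromosomes": list(self.sex_chromosomes),
                    "excluded_regions": [list(r) for r in self.excluded_regions],
                },
                fh,
                sort_keys=False,
            )


# Ig loci are dropped from CN profiles before signature analysis because
# physiological V(D)J recombination mimics somatic CN change there.
# GRCh38 coordinates: IGH 14q32, IGK 2p11, IGL 22q11.
GRCH38_IG_REGIONS: tuple[tuple[str, int, int], ...] = (
    ("chr2", 88_857_361, 90_235_368),    # IGK
    ("chr14", 105_586_437, 106_879_844),  # IGH
    ("chr22", 22_026_076, 22_922_913),    # IGL
)


def default_genome(n_autosomes: int = 8, include_x: bool = True) -> GenomeBuild:
    """Compact synthetic genome used by the simulator and examples.

    Eight autosomes spanning 110-200 Mb with arm boundaries at 40% of
    chromosome length, plus an X chromosome so the preprocessing filter
    has something to drop. Total autosomal span ~1.19 Gb.
    """
    lengths_mb = [200, 180, 160, 150, 140, 130, 120, 110, 105, 100, 95, 90][:n_autosomes]
    lengths = {f"chr{i + 1}": mb * 1_000_000 for i, mb in enumerate(lengths_mb)}
    if include_x:
        lengths["chrX"] = 155_000_000
    arm_boundaries = {name: int(0.4 * length) for name, length in lengths.items()}
    return GenomeBuild(lengths=lengths, arm_boundaries=arm_boundaries)
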