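"""Criteria-based chromothripsis calling on copy-number profiles.

Chromothripsis leaves two footprints that are visible in a CN-only
profile: breakpoints clustered in a confined region (criterion A) and
copy number oscillating among a small set of states (criterion B). The
caller tests both per chromosome. Criteria that need SV orientation,
haplotype or fragment-join data (C-F) are structurally unavailable from
segmented CN input and are deliberately not approximated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .cn_profile import CNProfile, CNSegment, breakpoints, warn_if_unfiltered

__all__ = [
    "CTThresholds",
    "ChromothripsisCall",
    "breakpoint_cluster_test",
    "oscillation_stats",
    "call_chromothripsis",
    "calls_to_frame",
]


@dataclass(frozen=True)
class CTThresholds:
    """Caller configuration; every default is echoed into call output.

    window            scan-window width in bp for the cluster test
    alpha             significance level on the scan-statistic p-value
    min_breakpoints   minimum breakpoints inside the densest window
    max_states        maximum distinct CN values in the candidate region
    min_oscillation   minimum oscillation fraction in the region
    n_null            Monte-Carlo draws for the scan-statistic null
    """

    window: float = 50e6
    alpha: float = 0.05
    min_breakpoints: int = 10
    max_states: int = 3
    min_oscillation: float = 0.5
    n_null: int = 2000


@dataclass(frozen=True)
class ChromothripsisCall:
    sample_id: str
    chromosome: str
    region_start: int
    region_end: int
    n_breakpoints: int
    n_cn_states: int
    oscillation_fraction: float
    cluster_pvalue: float
    is_chromothripsis: bool


def _max_window_counts(x: np.ndarray, width: float) -> np.ndarray:
    """Row-wise maximum point count in any window [x_j, x_j + width].

    ``x`` is (B, n), each row sorted ascending. Fully vectorised by
    embedding rows into disjoint value ranges.
    """
    b, n = x.shape
    span = x.max() + width + 1.0
    offsets = np.arange(b)[:, None] * span
    flat = (x + offsets).ravel()
    targets = flat + width
    hi = np.searchsorted(flat, targets, side="right")
    counts = hi - np.arange(b * n)
    return counts.reshape(b, n).max(axis=1)


def breakpoint_cluster_test(
    positions: np.ndarray | list[int],
    chrom_length: int,
    window: float = 50e6,
    n_null: int = 2000,
) -> tuple[float, tuple[int, int], int]:
    """Scan-statistic test for breakpoint clustering on one chromosome.

    Under the null of ``n`` breakpoints placed uniformly on the
    chromosome, estimates by Monte Carlo the probability of observing at
    least the attained maximum count in any window of the configured
    width. Returns ``(p_value, (window_start, window_end), k_in_window)``.
    The null stream is derived deterministically from (n, window/length)
    so repeated calls are reproducible without threading a seed.
    """
    pos = np.sort(np.asarray(positions, dtype=float))
    n = pos.size
    if n < 2:
        raise ValueError("cluster test needs >= 2 breakpoints")
    counts = np.searchsorted(pos, pos + window, side="right") - np.arange(n)
    j = int(np.argmax(counts))
    k_obs = int(counts[j])
    region = (int(pos[j]), int(min(pos[j] + window, chrom_length)))

    frac = window / chrom_length
    if frac >= 1.0:
        return 1.0, region, k_obs
    seed = np.random.SeedSequence([9201, n, int(round(frac * 10**6))])
    rng = np.random.default_rng(seed)
    null = np.sort(rng.random((n_null, n)), axis=1)
    null_max = _max_window_counts(null, frac)
    p = (1.0 + np.count_nonzero(null_max >= k_obs)) / (1.0 + n_null)
    return float(p), region, k_obs


def oscillation_stats(copy_numbers: list[int] | np.ndarray) -> tuple[int, float, int]:
    """Oscillation summary of a CN segment sequence.

    Returns ``(n_cn_states, oscillation_fraction, longest_chain)``:
    distinct CN values; fraction of interior segments differing from
    both neighbours while the neighbours agree; and the longest run of
    segments alternating between exactly two CN states.
    """
    cn = list(copy_numbers)
    n = len(cn)
    n_states = len(set(cn))
    if n < 3:
        return n_states, 0.0, n
    interior_osc = sum(
        1
        for i in range(1, n - 1)
        if cn[i] != cn[i - 1] and cn[i] != cn[i + 1] and cn[i - 1] == cn[i + 1]
    )
    frac = interior_osc / (n - 2)
    best = chain = 1
    for i in range(1, n):
        if cn[i] == cn[i - 1]:
            chain = 1
        elif chain >= 2 and cn[i] == cn[i - 2]:
            chain += 1
        else:
            chain = 2
        best = max(best, chain)
    return n_states, frac, best


def _region_segments(segs: list[CNSegment], start: int, end: int) -> list[CNSegment]:
    return [s for s in segs if s.end >= start and s.start <= end]


def call_chromothripsis(
    profile: CNProfile,
    thresholds: CTThresholds | None = None,
) -> tuple[list[ChromothripsisCall], bool]:
    """Flag chromothripsis per chromosome and for the sample.

    A chromosome is flagged when the densest scan window holds at least
    ``min_breakpoints`` breakpoints, the cluster p-value is at most
    ``alpha``, and the segments overlapping that window show at most
    ``max_states`` CN states with oscillation fraction at least
    ``min_oscillation``. The sample flag is the OR over chromosomes.
    Chromosomes failing the breakpoint-count gate are reported with a
    NaN p-value and not flagged (the Monte-Carlo test is skipped).
    """
    t = thresholds or CTThresholds()
    warn_if_unfiltered(profile)
    by_chrom = profile.by_chromosome()
    bps_by_chrom: dict[str, list[int]] = {}
    for bp in breakpoints(profile):
        bps_by_chrom.setdefault(bp.chromosome, []).append(bp.position)

    calls: list[ChromothripsisCall] = []
    for chrom, segs in by_chrom.items():
        positions = bps_by_chrom.get(chrom, [])
        length = profile.genome.lengths.get(chrom, max(s.end for s in segs))
        if len(positions) < 2:
            calls.append(
                ChromothripsisCall(
                    profile.sample_id, chrom, 0, 0, len(positions),
                    len({s.copy_number for s in segs}), 0.0, math.nan, False,
                )
            )
            continue
        pos = np.sort(np.asarray(positions, dtype=float))
        counts = np.searchsorted(pos, pos + t.window, side="right") - np.arange(pos.size)
        j = int(np.argmax(counts))
        k = int(counts[j])
        region = (int(pos[j]), int(min(pos[j] + t.window, length)))
        if k < t.min_breakpoints:
            pval = math.nan
        else:
            pval, region, k = breakpoint_cluster_test(
                positions, length, window=t.window, n_null=t.n_null
            )
        reg_segs = _region_segments(segs, region[0], region[1])
        n_states, osc_frac, _ = oscillation_stats([s.copy_number for s in reg_segs])
        flagged = (
            k >= t.min_breakpoints
            and not math.isnan(pval)
            and pval <= t.alpha
            and n_states <= t.max_states
            and osc_frac >= t.min_oscillation
        )
        calls.append(
            ChromothripsisCall(
                profile.sample_id, chrom, region[0], region[1], k,
                n_states, osc_frac, pval, flagged,
            )
        )
    return calls, any(c.is_chromothripsis for c in calls)


def calls_to_frame(calls: list[ChromothripsisCall]) -> pd.DataFrame:
    return pd.DataFrame([asdict(c) for c in calls])
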