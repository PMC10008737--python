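"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure of the study inputs: segmented
integer copy-number profiles with optionally planted chromothripsis
(clustered breakpoints oscillating among few CN states in a confined
region), somatic mutation tables with a controllable non-silent rate,
log-scale expression matrices with planted cell-type signature shifts
that differ by chromothripsis status, and survival/response tables from
a proportional-hazards model driven by a chromothripsis score.

All randomness flows from ``SimConfig.seed`` through named substreams,
so a fixed seed fixes every output byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cn_profile import CNProfile, CNSegment
from .genome import GenomeBuild, default_genome

__all__ = [
    "SimConfig",
    "SimulatedProfile",
    "simulate_cn_profile",
    "simulate_mutations",
    "simulate_expression",
    "simulate_survival",
    "simulate_cohort",
    "substream",
]

_STREAMS = {"labels": 1, "profiles": 2, "mutations": 3, "expression": 4, "survival": 5,
            "genes": 6}

CELL_TYPE_NAMES = (
    "CD8_T_cells", "Tregs", "TAM", "MDSC", "NK_cells", "B_cells",
    "CD4_T_cells", "Th1_cells", "Th2_cells", "Th17_cells", "Tfh_cells",
    "Gamma_delta_T_cells", "Memory_B_cells", "Plasma_cells", "Monocytes",
    "Macrophages_M1", "Macrophages_M2", "Dendritic_cells", "pDC",
    "Mast_cells", "Eosinophils", "Neutrophils", "NKT_cells",
    "Immature_DC", "Activated_DC", "Central_memory_CD8", "Effector_memory_CD8",
    "Naive_CD8_T_cells",
)

PATHWAY_NAMES = (
    "Antigen_processing_presentation", "CD8_TCR_downstream", "IL2_signaling",
    "IL15_signaling", "NK_mediated_cytotoxicity", "IFN_gamma_pathway",
)

ICB_SIGNATURE_NAMES = ("ICB_response_signature_A", "ICB_response_signature_B")

# sets whose genes are shifted up in non-chromothripsis samples
CYTOTOXIC_SETS = ("CD8_T_cells", "NK_cells") + PATHWAY_NAMES + ICB_SIGNATURE_NAMES

CYTOKINES = ("IFNG", "IL1A", "IL1B", "IL2", "IL4", "IL10", "IL11", "TGFB1")
PRO_CYTOKINES = ("IFNG", "IL1A", "IL1B", "IL2")

# individual biomarker genes carried by every expression matrix; CD8A
# tracks cytotoxic infiltration and is shifted with the cytotoxic sets
MARKER_GENES = ("CD8A", "CD274")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    The defaults define the conditions every downstream closure test is
    run under; see the methods note for the rationale behind each.
    """

    n_samples: int = 200
    chromothripsis_fraction: float = 0.5
    genome: GenomeBuild = field(default_factory=default_genome)
    baseline_ploidy: int = 2
    ct_region_length: int = 30_000_000
    ct_n_breakpoints: int = 20
    ct_cn_states: int = 2
    background_breakpoint_rate: float = 0.01  # CNA events per Mb
    background_cna_length: tuple[int, int] = (1_000_000, 10_000_000)
    n_genes: int = 2000
    n_cell_signatures: int = 28
    set_size: int = 10
    signature_effect: float = 2.0  # log2-fold shift of cytotoxic sets
    hazard_log_hr_per_cps: float = float(np.log(1.9))
    censoring_rate: float = 0.2
    nonsilent_rate: float = 2.0  # mutations per Mb
    exome_size_mb: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1 or self.n_cell_signatures < 1:
            raise ValueError("counts must be >= 1")
        if not 0 <= self.chromothripsis_fraction <= 1:
            raise ValueError("chromothripsis_fraction must be in [0, 1]")
        if not 0 <= self.censoring_rate <= 1:
            raise ValueError("censoring_rate must be in [0, 1]")
        if self.baseline_ploidy < 1 or self.ct_cn_states < 2 or self.ct_n_breakpoints < 2:
            raise ValueError("invalid chromothripsis parameters")
        min_len = min(self.genome.lengths[c] for c in self.genome.autosomes)
        if self.ct_region_length > min_len:
            raise ValueError("ct_region_length exceeds the shortest autosome")


def substream(cfg: SimConfig, name: str) -> np.random.Generator:
    """Named, seed-derived random substream."""
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, _STREAMS[name]]))


@dataclass
class SimulatedProfile:
    profile: CNProfile
    has_chromothripsis: bool
    ct_chromosome: str | None
    ct_region: tuple[int, int] | None


def _overlay(pieces: list[tuple[int, int, int]], start: int, end: int, cn: int):
    """Overlay a CN alteration on a sorted piecewise-constant profile."""
    out = []
    for s, e, c in pieces:
        if e < start or s > end:
            out.append((s, e, c))
            continue
        if s < start:
            out.append((s, start - 1, c))
        if e > end:
            out.append((end + 1, e, c))
    out.append((start, end, cn))
    return sorted(out)


def _compress(pieces: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    merged = []
    for s, e, c in sorted(pieces):
        if merged and merged[-1][2] == c and merged[-1][1] + 1 == s:
            merged[-1] = (merged[-1][0], e, c)
        else:
            merged.append((s, e, c))
    return merged


def _ct_interval_values(cfg: SimConfig, k: int) -> list[int]:
    """CN values of the k-1 intervals between k breakpoints.

    Deterministic alternation: non-baseline levels interleaved with the
    baseline so criterion B holds in ground truth; the first and last
    intervals are forced off-baseline so the planted region contributes
    exactly k breakpoints.
    """
    b = cfg.baseline_ploidy
    nonbase = [b + 1 + i for i in range(cfg.ct_cn_states - 1)]
    values = []
    for i in range(k - 1):
        if i % 2 == 0:
            values.append(nonbase[(i // 2) % len(nonbase)])
        else:
            values.append(b)
    if values and values[-1] == b:
        prev = values[-2] if len(values) > 1 else b
        values[-1] = next(v for v in nonbase if v != prev)
    return values


def simulate_cn_profile(
    cfg: SimConfig,
    has_ct: bool,
    rng: np.random.Generator,
    sample_id: str = "S1",
) -> SimulatedProfile:
    """One whole-genome profile, optionally with planted chromothripsis.

    Background CNAs are single-segment +-1 gains/losses of 1-10 Mb at
    ``background_breakpoint_rate`` events per Mb; they never overlap the
    planted region, keeping the ground-truth label unambiguous.
    """
    b = cfg.baseline_ploidy
    chrom_pieces = {c: [(1, L, b)] for c, L in cfg.genome.lengths.items()}

    ct_chrom = ct_region = None
    if has_ct:
        autosomes = [c for c in cfg.genome.autosomes
                     if cfg.genome.lengths[c] >= cfg.ct_region_length]
        ct_chrom = autosomes[int(rng.integers(len(autosomes)))]
        L = cfg.genome.lengths[ct_chrom]
        r0 = int(rng.integers(2, L - cfg.ct_region_length + 1))
        positions = set()
        while len(positions) < cfg.ct_n_breakpoints:
            positions.update(
                int(p) for p in rng.integers(
                    r0, r0 + cfg.ct_region_length,
                    cfg.ct_n_breakpoints - len(positions),
                )
            )
        pos = sorted(positions)
        ct_region = (pos[0], pos[-1])
        values = _ct_interval_values(cfg, len(pos))
        pieces = chrom_pieces[ct_chrom]
        for (s, e), v in zip(zip(pos, pos[1:]), values):
            pieces = _overlay(pieces, s, e - 1, v)
        chrom_pieces[ct_chrom] = pieces

    genome_mb = sum(cfg.genome.lengths.values()) / 1e6
    n_events = int(rng.poisson(cfg.background_breakpoint_rate * genome_mb))
    chroms = list(cfg.genome.lengths)
    weights = np.array([cfg.genome.lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    lo, hi = cfg.background_cna_length
    for _ in range(n_events):
        for _attempt in range(20):
            c = chroms[int(rng.choice(len(chroms), p=weights))]
            L = cfg.genome.lengths[c]
            elen = int(rng.integers(lo, hi + 1))
            if elen >= L:
                continue
            start = int(rng.integers(1, L - elen + 1))
            end = start + elen - 1
            if c == ct_chrom and ct_region and end >= ct_region[0] and start <= ct_region[1]:
                continue
            # only alter currently-baseline territory (no event stacking)
            if any(s <= end and e >= start and cv != b for s, e, cv in chrom_pieces[c]):
                continue
            cn = b + int(rng.choice([-1, 1]))
            chrom_pieces[c] = _overlay(chrom_pieces[c], start, end, max(cn, 0))
            break

    segments = [
        CNSegment(c, s, e, cn)
        for c in cfg.genome.lengths
        for s, e, cn in _compress(chrom_pieces[c])
    ]
    profile = CNProfile(sample_id=sample_id, segments=segments, genome=cfg.genome)
    return SimulatedProfile(profile, has_ct, ct_chrom, ct_region)


def simulate_mutations(
    cfg: SimConfig,
    rng: np.random.Generator,
    sample_ids: list[str],
    nonsilent_rate: float | np.ndarray | None = None,
    exome_size_mb: float | None = None,
) -> pd.DataFrame:
    """Mutation table: Poisson non-silent records plus silent records.

    Non-silent records pass the variant filters by construction
    (coverage >= 5, rare in every database); silent records are flagged
    ``Silent``. The silent rate is half the non-silent rate.
    """
    rate = cfg.nonsilent_rate if nonsilent_rate is None else nonsilent_rate
    mb = cfg.exome_size_mb if exome_size_mb is None else exome_size_mb
    rates = np.broadcast_to(np.asarray(rate, dtype=float), (len(sample_ids),))
    if np.any(rates < 0):
        raise ValueError("nonsilent_rate must be >= 0")
    nonsilent_classes = ["Missense_Mutation", "Nonsense_Mutation",
                        "Frame_Shift_Del", "Frame_Shift_Ins", "Splice_Site"]
    genes = [f"G{i:04d}" for i in range(1, cfg.n_genes + 1)]
    chroms = list(cfg.genome.lengths)
    rows = []
    for sid, r in zip(sample_ids, rates):
        for classification, lam in (("nonsilent", r * mb), ("Silent", 0.5 * r * mb)):
            for _ in range(int(rng.poisson(lam))):
                chrom = chroms[int(rng.integers(len(chroms)))]
                rows.append(
                    {
                        "sample": sid,
                        "gene": genes[int(rng.integers(len(genes)))],
                        "variant_classification": (
                            nonsilent_classes[int(rng.integers(len(nonsilent_classes)))]
                            if classification == "nonsilent" else "Silent"
                        ),
                        "chromosome": chrom,
                        "position": int(rng.integers(1, cfg.genome.lengths[chrom] + 1)),
                        "allele_fraction": float(np.round(rng.beta(2, 2), 4)),
                        "coverage": int(5 + rng.poisson(60)),
                        "popfreq_1000G": 0.0,
                        "popfreq_ExAC": 0.0,
                    }
                )
    cols = ["sample", "gene", "variant_classification", "chromosome", "position",
            "allele_fraction", "coverage", "popfreq_1000G", "popfreq_ExAC"]
    return pd.DataFrame(rows, columns=cols)


def _gene_sets(cfg: SimConfig) -> tuple[dict[str, list[str]], dict[str, str]]:
    names = list(CELL_TYPE_NAMES[: cfg.n_cell_signatures])
    for i in range(len(names), cfg.n_cell_signatures):
        names.append(f"Cell_type_{i + 1:02d}")
    sets: dict[str, list[str]] = {}
    roles: dict[str, str] = {}
    idx = 1
    for name in names:
        sets[name] = [f"G{j:04d}" for j in range(idx, idx + cfg.set_size)]
        roles[name] = "cell_type"
        idx += cfg.set_size
    for name in PATHWAY_NAMES:
        sets[name] = [f"G{j:04d}" for j in range(idx, idx + cfg.set_size)]
        roles[name] = "pathway"
        idx += cfg.set_size
    for name in ICB_SIGNATURE_NAMES:
        sets[name] = [f"G{j:04d}" for j in range(idx, idx + cfg.set_size)]
        roles[name] = "icb_signature"
        idx += cfg.set_size
    if idx - 1 + len(CYTOKINES) > cfg.n_genes:
        raise ValueError("n_genes too small for the signature gene sets")
    return sets, roles


def simulate_expression(
    cfg: SimConfig,
    labels,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, list[str]], dict[str, str]]:
    """log2 expression matrix with planted signature shifts.

    Baseline N(5, 1) per gene/sample. Genes of the designated cytotoxic
    sets (CD8 T cells, NK cells, the immune pathways, the ICB signatures)
    and the pro-inflammatory cytokines are shifted up by
    ``signature_effect`` in samples *without* chromothripsis, matching
    the lower-infiltration-with-chromothripsis direction.
    """
    labels = np.asarray(labels, dtype=bool)
    if len(labels) != cfg.n_samples:
        raise ValueError("labels length must equal n_samples")
    sets, roles = _gene_sets(cfg)
    genes = [f"G{i:04d}" for i in range(1, cfg.n_genes + 1)] + list(CYTOKINES) + list(MARKER_GENES)
    samples = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]
    expr = rng.normal(5.0, 1.0, size=(len(genes), len(samples)))
    shifted = {g for name in CYTOTOXIC_SETS for g in sets.get(name, [])}
    shifted.update(PRO_CYTOKINES)
    shifted.add("CD8A")
    gene_idx = [i for i, g in enumerate(genes) if g in shifted]
    expr[np.ix_(gene_idx, np.where(~labels)[0])] += cfg.signature_effect
    frame = pd.DataFrame(np.round(expr, 5), index=genes, columns=samples)
    return frame, sets, roles


def simulate_gene_annotation(cfg: SimConfig, gene_length: int = 30_000) -> pd.DataFrame:
    """Place the gene universe uniformly on the genome (1-based inclusive).

    Deterministic given the config seed; feeds the CNA-burden overlap.
    """
    rng = substream(cfg, "genes")
    chroms = list(cfg.genome.lengths)
    weights = np.array([cfg.genome.lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    genes = [f"G{i:04d}" for i in range(1, cfg.n_genes + 1)]
    rows = []
    for g in genes:
        c = chroms[int(rng.choice(len(chroms), p=weights))]
        start = int(rng.integers(1, cfg.genome.lengths[c] - gene_length))
        rows.append({"chromosome": c, "start": start, "end": start + gene_length - 1,
                     "name": g})
    return pd.DataFrame(rows)


def simulate_survival(
    cps,
    cfg: SimConfig,
    rng: np.random.Generator,
    sample_ids: list[str] | None = None,
    standardize: bool = True,
) -> pd.DataFrame:
    """Clinical table from an exponential proportional-hazards model.

    Hazard ``lambda_0 * exp(beta * z)`` with ``beta =
    hazard_log_hr_per_cps``, ``z`` the (optionally standardised) score
    and baseline median survival 24 months. Censoring is independent
    exponential, its rate solved so the expected censored fraction
    equals ``censoring_rate``. Response labels are logistic in ``z``
    with a ~35% responder base rate, decreasing in the score.
    """
    cps = np.asarray(cps, dtype=float)
    if not np.all(np.isfinite(cps)):
        raise ValueError("scores must be finite")
    n = len(cps)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    if standardize:
        sd = cps.std()
        z = (cps - cps.mean()) / sd if sd > 0 else np.zeros(n)
    else:
        z = cps
    lam0 = np.log(2) / 24.0
    lam = lam0 * np.exp(cfg.hazard_log_hr_per_cps * z)
    t_event = rng.exponential(1.0 / lam)

    if cfg.censoring_rate >= 1.0:
        time, event = t_event, np.zeros(n, dtype=int)
    elif cfg.censoring_rate <= 0.0:
        time, event = t_event, np.ones(n, dtype=int)
    else:
        target = cfg.censoring_rate

        def mean_censored(c):
            return float(np.mean(c / (c + lam))) - target

        c_rate = brentq(mean_censored, 1e-9, 1e4)
        t_cens = rng.exponential(1.0 / c_rate, size=n)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)

    p_resp = expit(logit(0.35) - 1.0 * z)
    responder = rng.random(n) < p_resp
    labels = np.where(
        responder,
        np.where(rng.random(n) < 0.2, "CR", "PR"),
        np.where(rng.random(n) < 0.4, "SD", "PD"),
    )
    sd_duration = np.where(labels == "SD", np.round(rng.exponential(4.0, n), 2), np.nan)
    return pd.DataFrame(
        {
            "sample": sample_ids,
            "os_months": np.round(time, 4),
            "os_event": event,
            "response": labels,
            "sd_duration_months": sd_duration,
        }
    )


def simulate_cohort(cfg: SimConfig) -> dict:
    """Generate profiles, labels, mutations, expression and gene sets.

    The clinical table is produced separately (:func:`simulate_survival`)
    once a per-sample score is available, since the outcome model is
    driven by the chromothripsis score.
    """
    n_ct = int(round(cfg.n_samples * cfg.chromothripsis_fraction))
    labels = np.zeros(cfg.n_samples, dtype=bool)
    labels[:n_ct] = True
    substream(cfg, "labels").shuffle(labels)

    rng_p = substream(cfg, "profiles")
    sims = [
        simulate_cn_profile(cfg, bool(labels[i]), rng_p, sample_id=f"S{i + 1:04d}")
        for i in range(cfg.n_samples)
    ]
    sample_ids = [s.profile.sample_id for s in sims]
    mutations = simulate_mutations(cfg, substream(cfg, "mutations"), sample_ids)
    expr, sets, roles = simulate_expression(cfg, labels, substream(cfg, "expression"))
    return {
        "config": cfg,
        "labels": pd.Series(labels, index=sample_ids, name="has_chromothripsis"),
        "simulated_profiles": sims,
        "profiles": [s.profile for s in sims],
        "mutations": mutations,
        "expression": expr,
        "gene_sets": sets,
        "gene_set_roles": roles,
    }
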