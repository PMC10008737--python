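"""Per-sample genomic covariates: variant filtering, TMB, key-gene
mutation frequencies, CNA burden and the weighted genome instability
index (wGII)."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .cn_profile import CNProfile, tumor_ploidy

__all__ = [
    "NONSILENT_CLASSES",
    "MAF_COLUMN_MAP",
    "read_maf",
    "read_bed",
    "filter_variants",
    "compute_tmb",
    "mutation_frequency_by_group",
    "cna_burden",
    "compute_wgii",
    "compute_covariates",
]

# missense, nonsense, frameshift and splice-site variants count as non-silent
NONSILENT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "Splice_Site",
    }
)

MAF_COLUMN_MAP = {
    "Tumor_Sample_Barcode": "sample",
    "Hugo_Symbol": "gene",
    "Variant_Classification": "variant_classification",
    "Chromosome": "chromosome",
    "Start_Position": "position",
}

POPFREQ_PREFIX = "popfreq_"


def read_maf(path) -> pd.DataFrame:
    """Read a minimal MAF into the canonical mutation-table columns.

    Canonical columns: sample, gene, variant_classification, chromosome,
    position, plus optional allele_fraction, coverage and any number of
    ``popfreq_<db>`` population-frequency columns.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.rename(columns=MAF_COLUMN_MAP)


def read_bed(path) -> pd.DataFrame:
    """Read BED (0-based half-open) gene intervals to 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chromosome", "start", "end", "name"],
                     usecols=[0, 1, 2, 3])
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return df


def filter_variants(
    mutations: pd.DataFrame,
    min_coverage: int = 5,
    min_allele_fraction: float = 0.05,
    max_popfreq: float = 0.005,
    nonsilent: frozenset[str] = NONSILENT_CLASSES,
) -> pd.DataFrame:
    """Apply the three somatic-variant confidence filters.

    Keeps records that (1) have coverage of at least ``min_coverage``
    OR allele fraction above ``min_allele_fraction`` (the two criteria
    are deliberately combined with OR), (2) are non-silent, and (3) are
    rare in every provided population database (< ``max_popfreq``).
    Idempotent. Missing population-frequency columns skip rule 3 with a
    warning.
    """
    df = mutations
    keep = (df["coverage"] >= min_coverage) | (df["allele_fraction"] > min_allele_fraction)
    keep &= df["variant_classification"].isin(nonsilent)
    popcols = [c for c in df.columns if c.startswith(POPFREQ_PREFIX)]
    if popcols:
        for c in popcols:
            keep &= df[c].fillna(0.0) < max_popfreq
    else:
        warnings.warn("no population-frequency columns; rarity filter skipped", stacklevel=2)
    return df.loc[keep].reset_index(drop=True)


def compute_tmb(
    mutations: pd.DataFrame,
    region_size_mb: float = 30.0,
    samples: list[str] | None = None,
) -> pd.Series:
    """Mutations per megabase per sample.

    ``samples`` lists the cohort so samples without any qualifying
    mutation report 0 rather than being absent.
    """
    if region_size_mb <= 0:
        raise ValueError("region_size_mb must be positive")
    counts = mutations.groupby("sample").size()
    if samples is not None:
        counts = counts.reindex(samples, fill_value=0)
    return (counts / region_size_mb).rename("tmb")


def mutation_frequency_by_group(
    mutations: pd.DataFrame,
    genes: list[str],
    groups: pd.Series,
) -> pd.DataFrame:
    """Per-gene mutation frequency in two groups with Fisher exact tests.

    ``groups`` maps sample id -> boolean flag (e.g. chromothripsis). A
    sample counts as mutated in a gene if it carries >= 1 record for it.
    Two-sided Fisher p per gene plus BH-adjusted q across the panel.
    """
    groups = groups.astype(bool)
    samples = groups.index
    rows = []
    present_genes = set(mutations["gene"])
    for gene in genes:
        mutated = set(mutations.loc[mutations["gene"] == gene, "sample"])
        flags = pd.Series([s in mutated for s in samples], index=samples)
        a = int((flags & groups).sum())        # mutated, group True
        b = int((~flags & groups).sum())
        c = int((flags & ~groups).sum())
        d = int((~flags & ~groups).sum())
        _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "gene": gene,
                "freq_group": a / max(a + b, 1),
                "freq_other": c / max(c + d, 1),
                "n_group": a + b,
                "n_other": c + d,
                "fisher_p": p,
                "present_in_table": gene in present_genes,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fisher_q"] = multipletests(out["fisher_p"], method="fdr_bh")[1]
    return out


def cna_burden(
    profile: CNProfile,
    genes: pd.DataFrame,
    ploidy: int | None = None,
) -> tuple[int, int]:
    """Count genes overlapped by gain / loss segments.

    A gene is gained (lost) if at least 1 bp of it overlaps any segment
    with CN above (below) the sample ploidy; each gene counts at most
    once per direction. ``genes`` carries 1-based inclusive
    chromosome/start/end/name columns (see :func:`read_bed`).
    """
    if ploidy is None:
        ploidy = tumor_ploidy(profile)
    trees: dict[str, IntervalTree] = {}
    for seg in profile.segments:
        if seg.copy_number == ploidy:
            continue
        # half-open internally: [start, end + 1)
        trees.setdefault(seg.chromosome, IntervalTree()).addi(
            seg.start, seg.end + 1, seg.copy_number
        )
    gained = lost = 0
    for row in genes.itertuples(index=False):
        tree = trees.get(row.chromosome)
        if tree is None:
            continue
        hits = tree.overlap(row.start, row.end + 1)
        if any(h.data > ploidy for h in hits):
            gained += 1
        if any(h.data < ploidy for h in hits):
            lost += 1
    return gained, lost


def compute_wgii(profile: CNProfile, ploidy: int | None = None) -> float:
    """Weighted genome instability index.

    Per autosome: the fraction of covered bases whose CN differs from
    the sample ploidy; wGII is the unweighted mean of those fractions
    over autosomes with any coverage. In [0, 1].
    """
    if ploidy is None:
        ploidy = tumor_ploidy(profile)
    altered: dict[str, int] = {}
    covered: dict[str, int] = {}
    for seg in profile.segments:
        if seg.chromosome in profile.genome.sex_chromosomes:
            continue
        covered[seg.chromosome] = covered.get(seg.chromosome, 0) + seg.length
        if seg.copy_number != ploidy:
            altered[seg.chromosome] = altered.get(seg.chromosome, 0) + seg.length
    if not covered:
        raise ValueError(f"{profile.sample_id}: no autosomal coverage, wGII undefined")
    fracs = [altered.get(c, 0) / covered[c] for c in covered]
    return float(np.mean(fracs))


def compute_covariates(
    profiles: list[CNProfile],
    mutations: pd.DataFrame,
    genes: pd.DataFrame,
    region_size_mb: float = 30.0,
) -> pd.DataFrame:
    """Assemble the per-sample covariate table (TMB, CNA burden, wGII, ploidy)."""
    tmb = compute_tmb(mutations, region_size_mb, samples=[p.sample_id for p in profiles])
    rows = []
    for p in profiles:
        ploidy = tumor_ploidy(p)
        gain, loss = cna_burden(p, genes, ploidy=ploidy)
        rows.append(
            {
                "sample": p.sample_id,
                "tmb": float(tmb[p.sample_id]),
                "cna_gain_burden": gain,
                "cna_loss_burden": loss,
                "wgii": compute_wgii(p, ploidy=ploidy),
                "ploidy": ploidy,
            }
        )
    return pd.DataFrame(rows).set_index("sample")
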