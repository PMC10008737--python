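"""Expression-based tumor-microenvironment quantification.

Single-sample gene-set enrichment (ssGSEA) scores the coordinate
expression of a gene set within one sample via a weighted running-sum
statistic. Because ssGSEA scores can be negative, cell-type ratios
(CD8/Treg, CD8/TAM, CD8/MDSC) and the pro-/anti-inflammatory cytokine
ratio are instead computed from geometric-mean signature scores, which
are positive and scale-equivariant. Group-level pathway enrichment is
summarised by Welch t statistics over per-sample set scores with
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata, ttest_ind
from statsmodels.stats.multitest import multipletests

__all__ = [
    "read_gmt",
    "write_gmt",
    "ssgsea",
    "geometric_mean_scores",
    "total_infiltration",
    "cell_ratios",
    "cytokine_ratio",
    "pathway_differential",
    "PRO_INFLAMMATORY",
    "ANTI_INFLAMMATORY",
]

# markers of immune stimulation vs immunosuppressive molecules
PRO_INFLAMMATORY = ("IFNG", "IL1A", "IL1B", "IL2")
ANTI_INFLAMMATORY = ("IL4", "IL10", "IL11", "TGFB1")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def _restrict(sets: dict[str, list[str]], genes: pd.Index) -> dict[str, list[str]]:
    present = set(genes)
    out = {}
    for name, members in sets.items():
        inter = [g for g in members if g in present]
        if not inter:
            warnings.warn(f"gene set {name!r} has no overlap with the matrix; skipped",
                          stacklevel=3)
            continue
        if len(inter) < len(members):
            warnings.warn(f"gene set {name!r}: {len(members) - len(inter)} gene(s) "
                          "missing from the matrix", stacklevel=3)
        out[name] = inter
    return out


def ssgsea(
    expr: pd.DataFrame,
    sets: dict[str, list[str]],
    weight: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """ssGSEA enrichment scores, sets x samples.

    Per sample, genes are ordered by decreasing expression; the score is
    the integral (sum over list positions) of the difference between the
    weighted in-set ECDF (weights ``rank^weight``, ranks ascending with
    ties averaged) and the unweighted out-set ECDF. With ``normalize``
    the integral is divided by the range (max - min) of the running
    difference, making scores comparable across samples.
    """
    if expr.index.has_duplicates:
        raise ValueError("duplicate gene identifiers in expression matrix")
    sets = _restrict(sets, expr.index)
    n = expr.shape[0]
    values = expr.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(expr.index)}
    out = np.zeros((len(sets), expr.shape[1]))
    set_masks = {}
    for name, members in sets.items():
        mask = np.zeros(n, dtype=bool)
        mask[[gene_pos[g] for g in members]] = True
        set_masks[name] = mask
    for j in range(expr.shape[1]):
        col = values[:, j]
        ranks = rankdata(col)  # ascending, ties averaged
        order = np.argsort(-col, kind="stable")
        w = ranks[order] ** weight
        for si, (name, mask) in enumerate(set_masks.items()):
            in_set = mask[order]
            m = int(in_set.sum())
            win = np.where(in_set, w, 0.0)
            denom_in = win.sum()
            p_in = np.cumsum(win) / denom_in
            n_out = n - m
            if n_out > 0:
                p_out = np.cumsum(np.where(in_set, 0.0, 1.0)) / n_out
            else:
                p_out = np.zeros(n)
            running = p_in - p_out
            es = running.sum()
            if normalize:
                rng = running.max() - running.min()
                if rng > 0:
                    es = es / rng
            out[si, j] = es
    result = pd.DataFrame(out, index=list(set_masks), columns=expr.columns)
    result.attrs["method"] = "ssgsea"
    return result


def geometric_mean_scores(
    expr: pd.DataFrame,
    sets: dict[str, list[str]],
    pseudocount: float = 1.0,
    expr_scale: str = "linear",
) -> pd.DataFrame:
    """Geometric mean of set-gene expression per sample, sets x samples.

    ``expr_scale='log2'`` exponentiates the matrix first; the geometric
    mean is then taken over ``value + pseudocount`` on the linear scale.
    """
    if expr_scale == "log2":
        expr = 2.0 ** expr
    elif expr_scale != "linear":
        raise ValueError("expr_scale must be 'linear' or 'log2'")
    sets = _restrict(sets, expr.index)
    shifted = expr.to_numpy(dtype=float) + pseudocount
    if np.any(shifted <= 0):
        gi, sj = np.argwhere(shifted <= 0)[0]
        raise ValueError(
            f"non-positive value after pseudocount at gene {expr.index[gi]!r}, "
            f"sample {expr.columns[sj]!r}"
        )
    logged = np.log(shifted)
    gene_pos = {g: i for i, g in enumerate(expr.index)}
    rows = {
        name: np.exp(logged[[gene_pos[g] for g in members]].mean(axis=0))
        for name, members in sets.items()
    }
    result = pd.DataFrame(rows, index=expr.columns).T
    result.attrs["method"] = "geometric_mean"
    return result


def total_infiltration(scores: pd.DataFrame) -> pd.Series:
    """Total immune-cell infiltration: mean of the per-set scores."""
    return scores.mean(axis=0).rename("total_infiltration")


def cell_ratios(
    scores: pd.DataFrame,
    cd8: str = "CD8_T_cells",
    treg: str = "Tregs",
    tam: str = "TAM",
    mdsc: str = "MDSC",
) -> pd.DataFrame:
    """CD8/Treg, CD8/TAM and CD8/MDSC ratios (raw and log2) per sample.

    Requires geometric-mean scores: ssGSEA scores can be negative, which
    makes ratios meaningless.
    """
    if scores.attrs.get("method") == "ssgsea":
        raise ValueError("cell ratios require geometric-mean scores, not ssGSEA")
    out = {}
    num = scores.loc[cd8]
    for label, denom_name in (("cd8_treg", treg), ("cd8_tam", tam), ("cd8_mdsc", mdsc)):
        denom = scores.loc[denom_name]
        ratio = num / denom.replace(0.0, np.nan)
        out[label] = ratio
        out[f"log2_{label}"] = np.log2(ratio)
    return pd.DataFrame(out)


def cytokine_ratio(
    expr: pd.DataFrame,
    pro: tuple[str, ...] = PRO_INFLAMMATORY,
    anti: tuple[str, ...] = ANTI_INFLAMMATORY,
    pseudocount: float = 1.0,
    expr_scale: str = "linear",
) -> pd.Series:
    """log2 ratio of pro- to anti-inflammatory cytokine geometric means."""
    panels = {"pro": list(pro), "anti": list(anti)}
    gm = geometric_mean_scores(expr, panels, pseudocount=pseudocount, expr_scale=expr_scale)
    return np.log2(gm.loc["pro"] / gm.loc["anti"]).rename("cytokine_ratio")


def pathway_differential(scores: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Welch t statistic per set between groups, BH-adjusted.

    ``groups`` maps sample -> chromothripsis flag. Positive t means the
    set scores higher in the non-chromothripsis group.
    """
    groups = groups.reindex(scores.columns).astype(bool)
    a = scores.loc[:, ~groups.values]  # non-chromothripsis
    b = scores.loc[:, groups.values]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("both groups need >= 2 samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = ttest_ind(a, b, axis=1, equal_var=False)
    out = pd.DataFrame({"t": t, "p": p}, index=scores.index)
    out["degenerate"] = ~np.isfinite(t)
    finite = np.isfinite(out["p"])
    out["q"] = np.nan
    if finite.any():
        out.loc[finite, "q"] = multipletests(out.loc[finite, "p"], method="fdr_bh")[1]
    return out
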