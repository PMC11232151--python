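"""Genomic interpretation of the response groups.

The chain filters a genes x patients expression matrix (expressed fraction,
missingness, top variance), associates each surviving gene with the ordinal
response group via least-squares regression, runs a one-way ANOVA across the
three groups, and tests pathway over-representation of the significant genes
with a hypergeometric tail and Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class GeneFilterConfig:
    """Gene pre-filters: genes expressed in <= ``min_expressed_fraction`` of
    patients are dropped, as are genes with any remaining missing values;
    the ``top_variance_n`` most variable survivors are kept. "Expressed"
    means non-missing and above ``expression_floor`` (by default the 10th
    percentile of all finite values in the matrix)."""

    min_expressed_fraction: float = 0.20
    top_variance_n: int = 2000
    expression_floor: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.min_expressed_fraction < 1.0:
            raise ValueError("min_expressed_fraction must be in (0, 1)")
        if self.top_variance_n < 1:
            raise ValueError("top_variance_n must be >= 1")


def filter_genes(expr: pd.DataFrame, cfg: GeneFilterConfig
                 ) -> tuple[pd.DataFrame, dict]:
    """Apply the three sequential filters; the log records counts per stage."""
    if expr.empty:
        raise ValueError("empty expression matrix")
    if expr.index.duplicated().any():
        raise ValueError("gene ids are not unique")
    values = expr.to_numpy(dtype=float)
    floor = cfg.expression_floor
    if floor is None:
        finite = values[np.isfinite(values)]
        floor = float(np.percentile(finite, 10)) if finite.size else 0.0
    expressed = np.isfinite(values) & (values > floor)
    frac = expressed.mean(axis=1)
    stage1 = expr.loc[frac > cfg.min_expressed_fraction]
    stage2 = stage1.dropna(axis=0, how="any")
    variances = stage2.var(axis=1, ddof=1).fillna(0.0)
    if len(stage2) <= cfg.top_variance_n:
        if len(stage2) < cfg.top_variance_n:
            log.warning("only %d genes survive the expression filters "
                        "(requested top %d)", len(stage2), cfg.top_variance_n)
        survivors = stage2
    else:
        keep = variances.sort_values(ascending=False, kind="mergesort")
        pos = np.sort(stage2.index.get_indexer(keep.index[:cfg.top_variance_n]))
        survivors = stage2.iloc[pos]  # original gene order, byte-deterministic
    filter_log = {
        "input": len(expr),
        "expression_floor": floor,
        "after_expressed_fraction": len(stage1),
        "after_missingness": len(stage2),
        "after_variance": len(survivors),
    }
    return survivors, filter_log


def _check_alignment(expr: pd.DataFrame, groups: pd.Series) -> np.ndarray:
    if not set(expr.columns) == set(groups.index):
        raise ValueError("expression patients and group assignment are misaligned")
    g = groups.loc[list(expr.columns)].to_numpy(dtype=float)
    census = pd.Series(g).value_counts()
    if (census < 3).any():
        log.warning("a response group has fewer than 3 patients: %s",
                    census.to_dict())
    return g


def associate_genes(expr: pd.DataFrame, groups: pd.Series,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene least-squares regression of expression on the ordinal group
    code (1 = nonpCR/non-CS ... 3 = pCR). Positive slope means expression
    rises toward pCR. Returns slope, t, p and the significance flag; genes
    constant across patients get an undefined (NaN) p and are flagged."""
    g = _check_alignment(expr, groups)
    x = g - g.mean()
    sxx = float((x ** 2).sum())
    if sxx == 0:
        raise ValueError("all patients are in one group")
    Y = expr.to_numpy(dtype=float)
    n = Y.shape[1]
    ybar = Y.mean(axis=1, keepdims=True)
    slope = (Y - ybar) @ x / sxx
    resid = Y - ybar - slope[:, None] * x[None, :]
    dof = n - 2
    s2 = (resid ** 2).sum(axis=1) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2 / sxx)
        tstat = slope / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    constant = expr.nunique(axis=1).to_numpy() <= 1
    slope[constant] = 0.0
    tstat[constant] = np.nan
    p[constant] = np.nan
    out = pd.DataFrame({
        "slope": slope, "t": tstat, "p_value": p,
        "significant": (p < alpha) & ~np.isnan(p),
        "undefined": constant,
    }, index=expr.index)
    return out


def anova_groups(expr: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """One-way ANOVA of expression across the response groups, per gene.
    Groups with a single patient are flagged rather than crashing."""
    g = _check_alignment(expr, groups)
    codes = np.unique(g)
    if len(codes) < 2:
        raise ValueError("ANOVA needs at least two groups")
    Y = expr.to_numpy(dtype=float)
    n = Y.shape[1]
    grand = Y.mean(axis=1, keepdims=True)
    ss_between = np.zeros(Y.shape[0])
    ss_within = np.zeros(Y.shape[0])
    for c in codes:
        sel = g == c
        m = Y[:, sel].mean(axis=1, keepdims=True)
        ss_between += sel.sum() * ((m - grand) ** 2).ravel()
        ss_within += ((Y[:, sel] - m) ** 2).sum(axis=1)
    df_b = len(codes) - 1
    df_w = n - len(codes)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_b) / (ss_within / df_w)
    p = stats.f.sf(F, df_b, df_w)
    degenerate = min(int((g == c).sum()) for c in codes) < 2
    flagged = ~np.isfinite(F)
    return pd.DataFrame({
        "F": F, "p_value": p,
        "flagged": flagged | degenerate,
    }, index=expr.index)


@dataclass
class EnrichmentResult:
    pathway: str
    p_value: float
    corrected_p: float
    overlap: tuple[str, ...]
    pathway_size: int


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def enrich_pathways(significant: set[str], universe: set[str],
                    gene_sets: dict[str, set[str]]) -> list[EnrichmentResult]:
    """Over-representation analysis.

    Each pathway is restricted to the universe; the hypergeometric upper
    tail of its overlap with the significant set gives the raw p, corrected
    across pathways with Benjamini-Hochberg. Results sorted by corrected p.
    """
    if not universe:
        raise ValueError("empty gene universe")
    significant = set(significant) & set(universe)
    if not significant <= set(universe):
        raise ValueError("significant genes must lie in the universe")
    N = len(universe)
    n_sig = len(significant)
    rows = []
    for name, genes in gene_sets.items():
        in_universe = genes & universe
        if not in_universe:
            continue
        overlap = tuple(sorted(significant & in_universe))
        K = len(in_universe)
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n_sig)) if k > 0 else 1.0
        rows.append((name, p, overlap, K))
    if not rows:
        return []
    raw = [r[1] for r in rows]
    corrected = multipletests(raw, method="fdr_bh")[1]
    results = [EnrichmentResult(name, p, float(cp), overlap, K)
               for (name, p, overlap, K), cp in zip(rows, corrected)]
    results.sort(key=lambda r: (r.corrected_p, r.p_value, r.pathway))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Flat table with the pathway, raw p, corrected p and the pipe-joined
    overlapping gene markers."""
    return pd.DataFrame([{
        "pathway": r.pathway,
        "p_value": r.p_value,
        "corrected_p": r.corrected_p,
        "gene_markers": "|".join(r.overlap),
        "pathway_size": r.pathway_size,
    } for r in results])
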