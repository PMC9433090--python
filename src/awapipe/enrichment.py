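"""Fold-change gene-set selection and chemoreceptor-family enrichment.

Implements the differential-expression readout used for the fasting study:
per-gene fasted/fed fold change with a pseudocount, strict >threshold /
<1/threshold selection of up/down gene sets, a one-sided Fisher exact test
for family overrepresentation in a set, and per-neuron enrichment of the
upregulated family members against a binary neuron x gene expression atlas
(ratio statistic, chi-squared with Fisher fallback, Bonferroni over tested
neurons).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats


@dataclass
class GeneSets:
    """Up/down-regulated gene sets at a strict fold-change threshold."""

    upregulated: set
    downregulated: set
    threshold: float = 4.0

    def __post_init__(self):
        if self.upregulated & self.downregulated:
            raise ValueError("up and down sets must be disjoint")


def compute_fold_changes(table: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-gene fasted/fed ratio of replicate-mean abundances.

    ``ratio = (mean fasted + pseudocount) / (mean fed + pseudocount)``.

    Parameters
    ----------
    table
        Long-format expression table with columns gene_id, family, condition
        (``fed`` / ``fasted``), replicate, abundance.

    Returns a DataFrame with one row per gene: gene_id, family, fed_mean,
    fasted_mean, ratio.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if np.any(table["abundance"].to_numpy() < 0):
        raise ValueError("abundances must be non-negative")
    means = (
        table.pivot_table(index=["gene_id", "family"], columns="condition",
                          values="abundance", aggfunc="mean")
        .reset_index()
    )
    for cond in ("fed", "fasted"):
        if cond not in means.columns:
            raise ValueError(f"no '{cond}' replicates present")
        bad = means.loc[means[cond].isna(), "gene_id"]
        if len(bad):
            raise ValueError(f"gene {bad.iloc[0]!r} missing condition {cond!r}")
    out = means.rename(columns={"fed": "fed_mean", "fasted": "fasted_mean"})
    out["ratio"] = (out["fasted_mean"] + pseudocount) / (out["fed_mean"] + pseudocount)
    out.columns.name = None
    return out[["gene_id", "family", "fed_mean", "fasted_mean", "ratio"]]


def select_regulated(records: pd.DataFrame, threshold: float = 4.0) -> GeneSets:
    """Strictly-more-than-threshold selection of regulated gene sets.

    ``upregulated`` holds genes with ratio > threshold, ``downregulated``
    those with ratio < 1/threshold; genes exactly at either boundary are
    excluded.
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    r = records["ratio"].to_numpy()
    genes = records["gene_id"].to_numpy()
    up = set(genes[r > threshold])
    down = set(genes[r < 1.0 / threshold])
    return GeneSets(up, down, threshold)


def family_enrichment_test(
    sets: GeneSets,
    family_label: str,
    universe: pd.DataFrame,
    direction: str = "up",
) -> tuple[float, float, np.ndarray]:
    """One-sided Fisher exact test for family overrepresentation in a set.

    The 2x2 table is [[in-set & family, in-set & not], [out-of-set & family,
    out-of-set & not]] over the detected-gene universe; the alternative is
    overrepresentation (greater).

    Parameters
    ----------
    universe
        Any table with one or more rows per gene carrying gene_id and family
        columns (the full expression table works).

    Returns (odds ratio, p, table).
    """
    fam = universe.drop_duplicates("gene_id").set_index("gene_id")["family"]
    if family_label not in set(fam):
        raise ValueError(f"family {family_label!r} absent from universe")
    selected = sets.upregulated if direction == "up" else sets.downregulated
    if not selected:
        warnings.warn("empty gene set; enrichment p = 1")
        return float("nan"), 1.0, np.zeros((2, 2), dtype=int)
    in_set = fam.index.isin(selected)
    is_fam = (fam == family_label).to_numpy()
    table = np.array([
        [int((in_set & is_fam).sum()), int((in_set & ~is_fam).sum())],
        [int((~in_set & is_fam).sum()), int((~in_set & ~is_fam).sum())],
    ])
    odds, p = stats.fisher_exact_2x2(table, alternative="greater")
    return odds, p, table


def neuron_enrichment(
    up_family_genes,
    family_genes,
    atlas: pd.DataFrame,
    alpha: float = 0.05,
    yates: bool = False,
) -> pd.DataFrame:
    """Per-neuron enrichment of upregulated family genes against an atlas.

    For each neuron with k = upregulated family genes expressed, K = total
    upregulated family genes, m = all family genes expressed, M = family
    universe size, the enrichment ratio is (k/K) / (m/M) — the fraction of
    upregulated family members the neuron expresses relative to the fraction
    of the whole family it expresses. Significance is assessed on the 2x2
    table [[k, K-k], [m-k, (M-K)-(m-k)]] by chi-squared (no Yates correction
    by default, Fisher exact fallback when an expected cell is below 5),
    Bonferroni-corrected over the neurons actually tested (those with m > 0).

    Returns a DataFrame with columns neuron, k, K, m, M, ratio, p_raw, p_adj,
    significant, tested.
    """
    up = set(up_family_genes)
    fam = list(dict.fromkeys(family_genes))  # order-preserving unique
    if not up <= set(fam):
        raise ValueError("up_family_genes must be a subset of family_genes")
    missing = [g for g in fam if g not in atlas.columns]
    if missing:
        raise ValueError(f"atlas does not cover gene {missing[0]!r}")
    K = len(up)
    M = len(fam)
    up_cols = [g for g in fam if g in up]

    rows = []
    for neuron in atlas.index:
        expressed = atlas.loc[neuron, fam].astype(bool)
        m = int(expressed.sum())
        k = int(atlas.loc[neuron, up_cols].astype(bool).sum()) if up_cols else 0
        tested = m > 0 and K > 0
        if tested:
            ratio = (k / K) / (m / M)
            table = np.array([[k, K - k], [m - k, (M - K) - (m - k)]])
            res = stats.chi_squared_2x2(table, yates=yates)
            p_raw = res.p_raw
        else:
            ratio, p_raw = float("nan"), float("nan")
        rows.append({"neuron": neuron, "k": k, "K": K, "m": m, "M": M,
                     "ratio": ratio, "p_raw": p_raw, "tested": tested})
    out = pd.DataFrame(rows)
    n_tested = int(out["tested"].sum())
    out["p_adj"] = np.where(out["tested"],
                            np.minimum(1.0, out["p_raw"] * max(n_tested, 1)),
                            np.nan)
    out["significant"] = out["tested"] & (out["p_adj"] < alpha)
    return out[["neuron", "k", "K", "m", "M", "ratio",
                "p_raw", "p_adj", "significant", "tested"]]
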