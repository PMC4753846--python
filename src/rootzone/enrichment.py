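"""Category over-representation statistics for responsive gene sets.

Two complementary tests against the expressed-gene background: per-category
one-sided Fisher's exact tests (singular enrichment analysis, BH-adjusted,
default 5% FDR) for open-ended systems such as GO-like annotations, and a
global chi-square goodness-of-fit over a fixed partition (e.g. 32 pathway
bins or 55 transcription-factor families) with per-category standardized
residuals.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from rootzone.de import adjust_fdr


def _category_map(annotation: pd.DataFrame) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for gene, cat in zip(annotation["gene_id"], annotation["category"]):
        out.setdefault(str(cat), set()).add(str(gene))
    return out


def fisher_enrichment(
    de_genes: set[str],
    background: set[str],
    annotation: pd.DataFrame,
    fdr_cut: float = 0.05,
    annotated_background_only: bool = False,
) -> pd.DataFrame:
    """One-sided Fisher's exact over-representation per category.

    ``background`` is the expressed-gene universe; unannotated genes count in
    the totals unless ``annotated_background_only``.  Per category the 2x2
    table (in/out of category x in/out of the responsive set) gives a
    hypergeometric upper-tail p-value; q-values are BH across categories and
    ``enriched`` means q < fdr_cut.
    """
    de_genes = set(de_genes)
    background = set(background)
    if not de_genes:
        raise ValueError("the responsive gene set is empty")
    if not de_genes <= background:
        raise ValueError("de_genes must be a subset of the background")
    cats = {
        c: members & background for c, members in _category_map(annotation).items()
    }
    if annotated_background_only:
        annotated = set().union(*cats.values()) if cats else set()
        background = background & annotated
        de_genes = de_genes & background
    n_bg = len(background)
    n_de = len(de_genes)
    rows = []
    for cat in sorted(cats):
        members = cats[cat]
        n_bg_in = len(members)
        n_de_in = len(members & de_genes)
        # upper tail: P(X >= n_de_in), X ~ Hypergeom(n_bg, n_bg_in, n_de)
        p = float(stats.hypergeom.sf(n_de_in - 1, n_bg, n_bg_in, n_de))
        rows.append((cat, n_de_in, n_de, n_bg_in, n_bg, min(p, 1.0)))
    frame = pd.DataFrame(
        rows,
        columns=["category", "n_de_in", "n_de", "n_bg_in", "n_bg", "p_value"],
    )
    frame["q_value"] = adjust_fdr(frame["p_value"].to_numpy())
    frame["enriched"] = frame["q_value"] < fdr_cut
    return frame


def chisq_distribution_test(
    de_genes: set[str],
    background: set[str],
    partition: pd.DataFrame,
    multi_assignment: str = "duplicate",
    alpha: float = 0.05,
) -> dict:
    """Global chi-square test of the responsive genes' category distribution.

    Expected counts per category follow the background proportions; categories
    with zero expectation are merged into ``other``.  Per-category
    over-representation is flagged from standardized (Pearson) residuals
    against a normal reference at ``alpha``.  ``multi_assignment`` resolves
    genes annotated to several partition bins: ``duplicate`` counts them in
    each bin, ``primary`` keeps only the first listed.
    """
    de_genes = set(de_genes) & set(background)
    if not de_genes:
        raise ValueError("the responsive gene set is empty")
    if multi_assignment not in ("duplicate", "primary"):
        raise ValueError("multi_assignment must be 'duplicate' or 'primary'")
    part = partition[partition["gene_id"].isin(background)]
    if multi_assignment == "primary":
        part = part.drop_duplicates(subset="gene_id", keep="first")
    # keep every category of the partition, including ones with no expressed
    # member (zero expectation -> merged below)
    cats = sorted(partition["category"].unique())
    bg_counts = np.array([
        (part["category"] == c).sum() for c in cats
    ], dtype=float)
    de_part = part[part["gene_id"].isin(de_genes)]
    de_counts = np.array([
        (de_part["category"] == c).sum() for c in cats
    ], dtype=float)

    total_bg = bg_counts.sum()
    total_de = de_counts.sum()
    if total_de == 0:
        raise ValueError(
            "no responsive gene is annotated in the partition"
        )
    expected = total_de * bg_counts / total_bg
    merged = expected <= 0
    if merged.any():
        warnings.warn(
            f"merging {int(merged.sum())} empty-expectation categories "
            "into 'other'"
        )
        keep = ~merged
        cats = [c for c, k in zip(cats, keep) if k] + ["other"]
        de_counts = np.append(de_counts[keep], de_counts[merged].sum())
        expected = np.append(expected[keep], expected[merged].sum())
        if expected[-1] == 0:
            cats, de_counts, expected = cats[:-1], de_counts[:-1], expected[:-1]

    chi2 = float(np.sum((de_counts - expected) ** 2 / expected))
    dof = len(cats) - 1
    global_p = float(stats.chi2.sf(chi2, dof))
    std_resid = (de_counts - expected) / np.sqrt(expected)
    z_crit = stats.norm.isf(alpha)
    per_category = pd.DataFrame(
        {
            "category": cats,
            "observed": de_counts.astype(int),
            "expected": expected,
            "std_residual": std_resid,
            "over_represented": std_resid > z_crit,
        }
    )
    return {
        "chi2": chi2,
        "df": dof,
        "p_value": global_p,
        "per_category": per_category,
    }
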