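"""Per-group functional summaries, rank tests, and term enrichment.

Produces the per-group attribute table (gene counts, essentiality and
annotation fractions, interaction participation, protein-length summaries),
pairwise Mann-Whitney U comparisons between groups, and hypergeometric
annotation-term enrichment of a gene subset against the genome-wide
background with Bonferroni correction.

Annotation terms are compared exactly as given in the catalog; no ontology
propagation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from genesisnet.classification import Classification, group_label
from genesisnet.dataio import GeneCatalog

#: largest min-sample size for which the exact Mann-Whitney branch is used
EXACT_MW_LIMIT = 8


def attribute_table(
    catalog: GeneCatalog,
    classification: Classification,
    net: nx.Graph | None = None,
    pfam_coverage: Mapping | None = None,
) -> pd.DataFrame:
    """Table of per-(age, origin)-group functional attribute summaries.

    Columns: group, n_genes, fraction_essential, go_process/function/
    component coverage (fraction with >= 1 term), fraction_with_interactions
    (fraction that are vertices of *net*), length quartiles, and mean
    pfam_coverage when a per-gene fraction map is supplied.
    """
    vertices = set(net.nodes()) if net is not None else set()
    rows: dict[str, dict] = {}
    for rec in catalog.non_dubious():
        if rec.gene_id not in classification:
            continue
        cls = classification[rec.gene_id]
        group = group_label(cls.age, cls.origin)
        row = rows.setdefault(
            group,
            {
                "lengths": [],
                "essential": 0,
                "process": 0,
                "function": 0,
                "component": 0,
                "with_interactions": 0,
                "pfam": [],
            },
        )
        row["lengths"].append(rec.length_aa)
        row["essential"] += int(rec.essential)
        for aspect in ("process", "function", "component"):
            row[aspect] += int(bool(rec.terms_for(aspect)))
        row["with_interactions"] += int(rec.gene_id in vertices)
        if pfam_coverage is not None and rec.gene_id in pfam_coverage:
            row["pfam"].append(float(pfam_coverage[rec.gene_id]))

    out = []
    for group in sorted(rows):
        row = rows[group]
        lengths = np.array(row["lengths"], dtype=float)
        n = len(lengths)
        entry = {
            "group": group,
            "n_genes": n,
            "fraction_essential": row["essential"] / n,
            "go_process_coverage": row["process"] / n,
            "go_function_coverage": row["function"] / n,
            "go_component_coverage": row["component"] / n,
            "fraction_with_interactions": row["with_interactions"] / n,
            "length_median": float(np.median(lengths)),
            "length_q1": float(np.percentile(lengths, 25)),
            "length_q3": float(np.percentile(lengths, 75)),
        }
        if pfam_coverage is not None:
            entry["pfam_coverage"] = float(np.mean(row["pfam"])) if row["pfam"] else float("nan")
        out.append(entry)
    return pd.DataFrame(out)


def mann_whitney(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two samples.

    Returns (U statistic of *sample_a*, two-sided p).  The exact null
    distribution is used when the smaller sample has at most
    :data:`EXACT_MW_LIMIT` observations and there are no ties across the
    pooled data; otherwise the tie-corrected normal approximation applies.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= EXACT_MW_LIMIT and not has_ties) else "asymptotic"
    result = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(result.statistic), float(result.pvalue)


def pairwise_group_tests(values: Mapping, labels: Mapping) -> pd.DataFrame:
    """Mann-Whitney comparison of a per-gene statistic between every group pair."""
    by_group: dict[str, list[float]] = {}
    for gene, value in values.items():
        group = labels.get(gene)
        if group is not None:
            by_group.setdefault(group, []).append(float(value))
    groups = sorted(by_group)
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            u, p = mann_whitney(by_group[ga], by_group[gb])
            rows.append(
                {"group_a": ga, "group_b": gb, "n_a": len(by_group[ga]),
                 "n_b": len(by_group[gb]), "u_statistic": u, "p_value": p}
            )
    return pd.DataFrame(rows)


@dataclass
class EnrichmentResult:
    term: str
    k_subset: int
    n_subset: int
    K_background: int
    N_background: int
    p_raw: float
    p_adjusted: float


def term_enrichment(
    subset: Iterable,
    catalog: GeneCatalog,
    aspect: str = "function",
    alpha: float = 0.01,
    correction: str = "bonferroni",
    include_unannotated: bool = False,
) -> list:
    """Upper-tail hypergeometric enrichment of terms in a gene subset.

    The background is the non-dubious catalog genes carrying at least one
    term in *aspect* (all non-dubious genes with ``include_unannotated``).
    For each term present in the subset, the raw p is the hypergeometric
    probability of drawing at least the observed number of term-annotated
    genes; Bonferroni adjustment multiplies by the number of tested terms.
    Results are sorted by ascending raw p.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    subset = set(subset)
    background = [
        rec for rec in catalog.non_dubious()
        if include_unannotated or rec.terms_for(aspect)
    ]
    bg_ids = {rec.gene_id for rec in background}
    sub_ids = subset & bg_ids
    N = len(bg_ids)
    n = len(sub_ids)
    if n == 0:
        return []

    term_background: dict[str, int] = {}
    term_subset: dict[str, int] = {}
    for rec in background:
        for term in rec.terms_for(aspect):
            term_background[term] = term_background.get(term, 0) + 1
            if rec.gene_id in sub_ids:
                term_subset[term] = term_subset.get(term, 0) + 1

    n_tested = len(term_subset)
    results = []
    for term, k in term_subset.items():
        K = term_background[term]
        p_raw = float(stats.hypergeom.sf(k - 1, N, K, n))
        p_adj = min(1.0, p_raw * n_tested) if correction == "bonferroni" else p_raw
        results.append(
            EnrichmentResult(
                term=term, k_subset=k, n_subset=n, K_background=K,
                N_background=N, p_raw=p_raw, p_adjusted=p_adj,
            )
        )
    results.sort(key=lambda r: (r.p_raw, r.term))
    return results


def enrichment_frame(results: list, alpha: float = 0.01) -> pd.DataFrame:
    """Tabular view of :func:`term_enrichment` output with a significance flag."""
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "k_subset": r.k_subset,
                "n_subset": r.n_subset,
                "K_background": r.K_background,
                "N_background": r.N_background,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "significant": r.p_adjusted < alpha,
            }
            for r in results
        ]
    )
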