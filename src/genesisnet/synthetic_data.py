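"""Ground-truthed synthetic datasets emulating the study's input tables.

Generates, at configurable scale and from a single seed:

* a gene catalog with group-specific lognormal protein lengths and
  Bernoulli essentiality / annotation flags (plus optional dubious decoys);
* evolution-evidence fixtures (families, ancestral reconstruction, ortholog
  profiles) constructed so the classification module recovers the true
  labels exactly, including WGD pairs, the subtelomeric ortholog rule, and
  the progenitor-variant relabeling;
* an interaction network from a degree-corrected block model with a planted
  symmetric group-mixing matrix omega: edge (i, j) appears independently
  with probability ``min(1, theta_i * theta_j * omega[g_i, g_j] / C)``,
  where the propensities theta follow a truncated power law and C normalizes
  to the target mean degree.

Default parameters echo the magnitudes of the study's five groups (sizes
about 1434/2696/1087/314/239, young-novel median length 180 aa vs 400 aa,
interaction participation 25-81%) without claiming to fit the real data.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from genesisnet.classification import GROUPS, group_label
from genesisnet.dataio import (
    EdgeTable,
    EvolutionEvidence,
    GeneCatalog,
    GeneRecord,
    write_catalog,
    write_edge_list,
    write_evolution_inputs,
)

#: divergence rank per species; ranks >= PRE_WGD_RANK diverged before the WGD
DEFAULT_SPECIES_RANKS = {f"sp{i}": i for i in range(1, 9)}
PRE_WGD_RANK = 5

_DEFAULT_GROUP_SIZES = {
    ("pre_wgd", "duplicate"): 1434,
    ("pre_wgd", "novel"): 2696,
    ("wgd", "duplicate"): 1086,  # must be even: WGD genes come in pairs
    ("post_wgd", "duplicate"): 314,
    ("post_wgd", "novel"): 239,
}

_DEFAULT_LENGTH_MEDIAN = {
    ("pre_wgd", "duplicate"): 450.0,
    ("pre_wgd", "novel"): 398.0,
    ("wgd", "duplicate"): 420.0,
    ("post_wgd", "duplicate"): 400.0,
    ("post_wgd", "novel"): 180.0,
}

_DEFAULT_ESSENTIAL_PROB = {
    ("pre_wgd", "duplicate"): 0.30,
    ("pre_wgd", "novel"): 0.30,
    ("wgd", "duplicate"): 0.08,
    ("post_wgd", "duplicate"): 0.02,
    ("post_wgd", "novel"): 0.00,
}

_DEFAULT_ANNOTATION_PROB = {
    ("pre_wgd", "duplicate"): 0.88,
    ("pre_wgd", "novel"): 0.67,
    ("wgd", "duplicate"): 0.76,
    ("post_wgd", "duplicate"): 0.60,
    ("post_wgd", "novel"): 0.22,
}

_DEFAULT_PFAM_MEAN = {
    ("pre_wgd", "duplicate"): 0.57,
    ("pre_wgd", "novel"): 0.36,
    ("wgd", "duplicate"): 0.45,
    ("post_wgd", "duplicate"): 0.53,
    ("post_wgd", "novel"): 0.12,
}

_DEFAULT_INTERACTION_PROB = {
    ("pre_wgd", "duplicate"): 0.81,
    ("pre_wgd", "novel"): 0.77,
    ("wgd", "duplicate"): 0.72,
    ("post_wgd", "duplicate"): 0.55,
    ("post_wgd", "novel"): 0.25,
}


def neutral_mixing() -> dict:
    """Mixing matrix with every group-pair weight equal to 1."""
    return {tuple(sorted((group_label(*a), group_label(*b)))): 1.0
            for a in GROUPS for b in GROUPS}


def assortative_mixing(within: float, between: float = 1.0) -> dict:
    """Mixing matrix with one weight on the diagonal and another off it."""
    mix = {}
    for a in GROUPS:
        for b in GROUPS:
            key = tuple(sorted((group_label(*a), group_label(*b))))
            mix[key] = within if a == b else between
    return mix


@dataclass
class SyntheticConfig:
    """All knobs of the generator; probabilities are per (age, origin) group."""

    group_sizes: dict = field(default_factory=lambda: dict(_DEFAULT_GROUP_SIZES))
    length_median: dict = field(default_factory=lambda: dict(_DEFAULT_LENGTH_MEDIAN))
    length_sigma: float = 0.55
    essential_prob: dict = field(default_factory=lambda: dict(_DEFAULT_ESSENTIAL_PROB))
    annotation_prob: dict = field(default_factory=lambda: dict(_DEFAULT_ANNOTATION_PROB))
    pfam_mean: dict = field(default_factory=lambda: dict(_DEFAULT_PFAM_MEAN))
    interaction_prob: dict = field(default_factory=lambda: dict(_DEFAULT_INTERACTION_PROB))
    subtelomeric_prob: float = 0.05
    n_dubious: int = 50
    n_annotation_terms: int = 40
    degree_exponent: float = 2.5
    degree_min: float = 1.0
    degree_max: float = 50.0
    mean_degree: float = 6.0
    high_throughput_prob: float = 0.7
    mixing: dict = field(default_factory=neutral_mixing)
    seed: int = 0

    def validate(self) -> None:
        for key, size in self.group_sizes.items():
            if tuple(key) not in GROUPS:
                raise ValueError(f"unknown group {key!r}")
            if size < 0:
                raise ValueError(f"negative group size for {key!r}")
        if self.group_sizes.get(("wgd", "duplicate"), 0) % 2:
            raise ValueError("the (wgd, duplicate) group size must be even (pairs)")
        for name in ("essential_prob", "annotation_prob", "interaction_prob"):
            for key, p in getattr(self, name).items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{key!r}] = {p} outside [0, 1]")
        if not 0.0 <= self.subtelomeric_prob <= 1.0:
            raise ValueError("subtelomeric_prob outside [0, 1]")
        for key, w in self.mixing.items():
            if w < 0:
                raise ValueError(f"mixing weight {key!r} must be >= 0")
        if self.mean_degree <= 0 or self.degree_min <= 0 or self.degree_max < self.degree_min:
            raise ValueError("invalid degree model parameters")

    def scaled(self, factor: float) -> "SyntheticConfig":
        """Copy with group sizes scaled by *factor* (WGD size kept even)."""
        sizes = {}
        for key, size in self.group_sizes.items():
            scaled = max(2, int(round(size * factor)))
            if tuple(key) == ("wgd", "duplicate") and scaled % 2:
                scaled += 1
            sizes[key] = scaled
        out = copy.deepcopy(self)
        out.group_sizes = sizes
        return out


@dataclass
class SyntheticTruth:
    """Ground truth used by recovery tests: true labels and model parameters."""

    labels: dict  # gene -> (age, origin)
    families: dict  # gene -> family id (true partition, post-merge)
    wgd_pairs: list  # list of sorted gene pairs
    subtelomeric: set
    progenitors: set  # genes relabeled novel by the progenitor variant
    theta: dict = field(default_factory=dict)  # network propensity per participant
    participating: set = field(default_factory=set)
    mixing: dict = field(default_factory=dict)
    realized_mixing: dict = field(default_factory=dict)

    def group_labels(self) -> dict:
        return {g: group_label(a, o) for g, (a, o) in self.labels.items()}

    def progenitor_labels(self) -> dict:
        """gene -> (age, origin) after the progenitor-variant relabeling."""
        out = {}
        for gene, (age, origin) in self.labels.items():
            out[gene] = (age, "novel" if gene in self.progenitors else origin)
        return out


@dataclass
class SyntheticDataset:
    catalog: GeneCatalog
    evidence: EvolutionEvidence
    edges: EdgeTable
    truth: SyntheticTruth
    pfam_coverage: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_catalog(self.catalog, outdir / "catalog.tsv")
        write_edge_list(self.edges, outdir / "edges.tsv")
        write_evolution_inputs(
            self.evidence,
            outdir / "families.tsv",
            outdir / "reconstruction.tsv",
            outdir / "orthologs.tsv",
        )
        with open(outdir / "pfam.tsv", "w", encoding="utf-8") as fh:
            fh.write("gene_id\tpfam_fraction\n")
            for gene in sorted(self.pfam_coverage):
                fh.write(f"{gene}\t{self.pfam_coverage[gene]:.6f}\n")
        truth = {
            "labels": {g: list(v) for g, v in sorted(self.truth.labels.items())},
            "families": dict(sorted(self.truth.families.items())),
            "wgd_pairs": sorted(self.truth.wgd_pairs),
            "subtelomeric": sorted(self.truth.subtelomeric),
            "progenitors": sorted(self.truth.progenitors),
            "participating": sorted(self.truth.participating),
        }
        with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------


def _draw_length(rng, median: float, sigma: float) -> int:
    return max(10, int(round(float(rng.lognormal(np.log(median), sigma)))))


def generate_catalog(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[GeneCatalog, SyntheticTruth, dict]:
    """Catalog + truth skeleton: labels, flags, attribute draws per group."""
    config.validate()
    records = []
    labels: dict[str, tuple[str, str]] = {}
    subtelomeric: set = set()
    pfam: dict[str, float] = {}
    counter = 0
    for age, origin in GROUPS:
        size = config.group_sizes.get((age, origin), 0)
        key = (age, origin)
        for _ in range(size):
            counter += 1
            gene = f"SYN{counter:05d}"
            labels[gene] = (age, origin)
            # WGD genes sit inside the reconstruction, never subtelomeric
            is_subtel = age != "wgd" and rng.random() < config.subtelomeric_prob
            if is_subtel:
                subtelomeric.add(gene)
            annotated = {
                aspect: (
                    frozenset(
                        f"T{aspect[:1].upper()}{rng.integers(config.n_annotation_terms):03d}"
                        for _ in range(1 + int(rng.integers(3)))
                    )
                    if rng.random() < config.annotation_prob[key]
                    else frozenset()
                )
                for aspect in ("process", "function", "component")
            }
            records.append(
                GeneRecord(
                    gene_id=gene,
                    length_aa=_draw_length(rng, config.length_median[key], config.length_sigma),
                    essential=bool(rng.random() < config.essential_prob[key]),
                    dubious=False,
                    subtelomeric=is_subtel,
                    terms=annotated,
                )
            )
            pfam[gene] = float(np.clip(rng.normal(config.pfam_mean[key], 0.1), 0.0, 1.0))
    for _ in range(config.n_dubious):
        counter += 1
        gene = f"SYN{counter:05d}"
        records.append(
            GeneRecord(gene_id=gene, length_aa=_draw_length(rng, 120.0, 0.4), dubious=True)
        )
    truth = SyntheticTruth(
        labels=labels,
        families={},
        wgd_pairs=[],
        subtelomeric=subtelomeric,
        progenitors=set(),
        mixing=dict(config.mixing),
    )
    return GeneCatalog(records), truth, pfam


# ---------------------------------------------------------------------------
# evolution evidence
# ---------------------------------------------------------------------------


def _partition_families(genes: list, rng: np.random.Generator) -> list:
    """Split genes into families of size >= 2 (sizes drawn from {2, 3, 4})."""
    genes = list(genes)
    rng.shuffle(genes)
    families = []
    i = 0
    while i < len(genes):
        remaining = len(genes) - i
        if remaining <= 3:
            size = remaining
        else:
            size = int(rng.choice([2, 2, 3, 4]))
            if remaining - size == 1:  # never strand a singleton
                size += 1
        families.append(genes[i:i + size])
        i += size
    return families


def generate_evolution_fixtures(
    truth: SyntheticTruth, rng: np.random.Generator
) -> EvolutionEvidence:
    """Families / reconstruction / orthologs consistent with the true labels.

    Construction guarantees exact label recovery by the classification
    module: WGD pairs occupy tracks A/B of shared loci (each member starts in
    its own family so the merge step is exercised); other pre-WGD genes get
    single-track loci, except subtelomeric ones which instead receive an
    ortholog in a pre-WGD-diverging species; duplicate genes share families
    and novel genes are singletons.  Within each non-WGD multi-member family
    one designated progenitor gets a strictly deeper ortholog than its
    mates, so the progenitor-variant relabeling is deterministic.
    """
    evidence = EvolutionEvidence()
    truth.families = {}
    truth.wgd_pairs = []
    truth.progenitors = set()
    by_group: dict[tuple[str, str], list] = {}
    for gene, key in sorted(truth.labels.items()):
        by_group.setdefault(key, []).append(gene)

    locus_n = 0
    family_n = 0

    def next_locus() -> str:
        nonlocal locus_n
        locus_n += 1
        return f"L{locus_n:05d}"

    def next_family() -> str:
        nonlocal family_n
        family_n += 1
        return f"F{family_n:05d}"

    def add_ortholog(gene: str, rank: int) -> None:
        flag = rank >= PRE_WGD_RANK
        evidence.ortholog_profile.setdefault(gene, set()).add((f"sp{rank}", flag))

    # WGD pairs: shared locus, tracks A/B, separate families (merged later)
    wgd_genes = list(by_group.get(("wgd", "duplicate"), []))
    rng.shuffle(wgd_genes)
    for i in range(0, len(wgd_genes), 2):
        g1, g2 = sorted(wgd_genes[i:i + 2])
        locus = next_locus()
        evidence.reconstruction.append((locus, "A", g1))
        evidence.reconstruction.append((locus, "B", g2))
        for g in (g1, g2):
            fam = next_family()
            evidence.family_map[g] = fam
        truth.wgd_pairs.append((g1, g2))
        merged = evidence.family_map[g1]  # merge step will union to g1's family
        truth.families[g1] = merged
        truth.families[g2] = merged

    def place_pre_wgd(gene: str, mate_rank: int | None = None) -> None:
        """Reconstruction presence, or the subtelomeric ortholog route."""
        if gene in truth.subtelomeric:
            rank = mate_rank if mate_rank is not None else int(rng.integers(5, 8))
            add_ortholog(gene, rank)
        else:
            track = "A" if rng.random() < 0.5 else "B"
            evidence.reconstruction.append((next_locus(), track, gene))
            if mate_rank is not None:
                add_ortholog(gene, mate_rank)

    # pre-WGD duplicates: multi-member families, progenitor gets rank 8
    for members in _partition_families(by_group.get(("pre_wgd", "duplicate"), []), rng):
        fam = next_family()
        progenitor = members[int(rng.integers(len(members)))]
        truth.progenitors.add(progenitor)
        for gene in members:
            evidence.family_map[gene] = fam
            truth.families[gene] = fam
            if gene == progenitor:
                # subtelomeric progenitors still age pre_wgd via the deep ortholog
                if gene in truth.subtelomeric:
                    add_ortholog(gene, 8)
                else:
                    evidence.reconstruction.append(
                        (next_locus(), "A" if rng.random() < 0.5 else "B", gene)
                    )
                    add_ortholog(gene, 8)
            else:
                place_pre_wgd(gene, mate_rank=int(rng.integers(5, 8)))

    # pre-WGD novels: singleton families
    for gene in by_group.get(("pre_wgd", "novel"), []):
        fam = next_family()
        evidence.family_map[gene] = fam
        truth.families[gene] = fam
        place_pre_wgd(gene)

    # post-WGD duplicates: families of young genes, shallow orthologs only
    for members in _partition_families(by_group.get(("post_wgd", "duplicate"), []), rng):
        fam = next_family()
        progenitor = members[int(rng.integers(len(members)))]
        truth.progenitors.add(progenitor)
        for gene in members:
            evidence.family_map[gene] = fam
            truth.families[gene] = fam
            add_ortholog(gene, 4 if gene == progenitor else int(rng.integers(1, 4)))

    # post-WGD novels: singletons, no pre-WGD orthologs
    for gene in by_group.get(("post_wgd", "novel"), []):
        fam = next_family()
        evidence.family_map[gene] = fam
        truth.families[gene] = fam
        if gene in truth.subtelomeric and rng.random() < 0.5:
            add_ortholog(gene, int(rng.integers(1, PRE_WGD_RANK)))

    return evidence


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


def _truncated_power_law(rng, size: int, exponent: float, lo: float, hi: float) -> np.ndarray:
    """Inverse-CDF sample from p(x) ~ x^-exponent on [lo, hi]."""
    u = rng.random(size)
    a = 1.0 - exponent
    return (lo**a + u * (hi**a - lo**a)) ** (1.0 / a)


def generate_network(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    rng: np.random.Generator,
) -> EdgeTable:
    """Degree-corrected block-model network over the participating genes.

    Which genes participate is Bernoulli per group
    (``interaction_prob``); each participant draws a propensity theta from a
    truncated power law, and edges appear independently with probability
    ``min(1, theta_i * theta_j * omega_ij / C)`` where C is set so the
    expected mean degree matches ``mean_degree``.
    """
    config.validate()
    genes = sorted(truth.labels)
    group_of = truth.group_labels()
    participating = [
        g for g in genes
        if rng.random() < config.interaction_prob[truth.labels[g]]
    ]
    n = len(participating)
    if n < 2:
        raise ValueError("fewer than two genes participate in the network")
    if config.mean_degree >= n:
        raise ValueError(
            f"mean degree {config.mean_degree} infeasible for {n} participating genes"
        )
    theta = _truncated_power_law(
        rng, n, config.degree_exponent, config.degree_min, config.degree_max
    )
    labels = np.array([group_of[g] for g in participating])
    unique_groups = sorted(set(labels))
    g_idx = {g: i for i, g in enumerate(unique_groups)}
    lab = np.array([g_idx[g] for g in labels])

    def omega(ga: str, gb: str) -> float:
        return truth.mixing.get(tuple(sorted((ga, gb))), 1.0)

    # normalization: sum over i<j of theta_i theta_j omega = n * mean_degree / 2
    weight_sum = 0.0
    group_theta_sum = {g: float(theta[lab == g_idx[g]].sum()) for g in unique_groups}
    group_theta_sq = {g: float((theta[lab == g_idx[g]] ** 2).sum()) for g in unique_groups}
    for i, ga in enumerate(unique_groups):
        for gb in unique_groups[i:]:
            if ga == gb:
                pair_sum = (group_theta_sum[ga] ** 2 - group_theta_sq[ga]) / 2.0
            else:
                pair_sum = group_theta_sum[ga] * group_theta_sum[gb]
            weight_sum += omega(ga, gb) * pair_sum
    if weight_sum <= 0:
        raise ValueError("mixing matrix leaves no possible edges")
    C = weight_sum / (n * config.mean_degree / 2.0)

    table = EdgeTable()
    realized: dict[tuple[str, str], int] = {}
    # sample block-wise to keep memory bounded
    idx_by_group = {g: np.flatnonzero(lab == g_idx[g]) for g in unique_groups}
    for i, ga in enumerate(unique_groups):
        for gb in unique_groups[i:]:
            w = omega(ga, gb)
            if w == 0.0:
                continue
            ia = idx_by_group[ga]
            ib = idx_by_group[gb]
            probs = np.minimum(1.0, np.outer(theta[ia], theta[ib]) * (w / C))
            draws = rng.random(probs.shape) < probs
            if ga == gb:
                draws = np.triu(draws, k=1)
            rows, cols = np.nonzero(draws)
            for r, c in zip(rows, cols):
                u, v = participating[ia[r]], participating[ib[c]]
                if u == v:
                    continue
                a, b = (u, v) if u <= v else (v, u)
                source = (
                    "high_throughput"
                    if rng.random() < config.high_throughput_prob
                    else "small_scale"
                )
                table.edges.append((a, b, source))
                key = tuple(sorted((ga, gb)))
                realized[key] = realized.get(key, 0) + 1

    truth.participating = set(participating)
    truth.theta = {g: float(t) for g, t in zip(participating, theta)}
    truth.realized_mixing = realized
    return table


# ---------------------------------------------------------------------------
# one-call generation
# ---------------------------------------------------------------------------


def generate_dataset(config: SyntheticConfig | None = None, seed=None) -> SyntheticDataset:
    """Catalog, evidence, network and truth from one seed (deterministic).

    *seed* may be an int or a ``numpy.random.SeedSequence``; defaults to
    ``config.seed``.
    """
    config = config or SyntheticConfig()
    if seed is None:
        seed = config.seed
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_catalog, rng_evolution, rng_network = (
        np.random.default_rng(s) for s in root.spawn(3)
    )
    catalog, truth, pfam = generate_catalog(config, rng_catalog)
    evidence = generate_evolution_fixtures(truth, rng_evolution)
    edges = generate_network(config, truth, rng_network)
    return SyntheticDataset(
        catalog=catalog, evidence=evidence, edges=edges, truth=truth, pfam_coverage=pfam
    )
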