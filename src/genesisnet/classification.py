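"""Assign each non-dubious gene an age and a mechanism of origin.

Ages are ordered ``pre_wgd < wgd < post_wgd`` relative to the ancient
whole-genome duplication (WGD).  Origins are ``duplicate`` (the gene has at
least one paralog in the genome, i.e. belongs to a homologous family of size
>= 2) or ``novel`` (no paralog).

Rule precedence for age (applied per gene):

1. membership in a WGD-retained pair (one ancestral locus with descendants
   on both syntenic tracks) -> ``wgd``;
2. presence anywhere in the ancestral reconstruction -> ``pre_wgd``;
3. subtelomeric genes absent from the reconstruction: an ortholog in a
   species that diverged before the WGD -> ``pre_wgd``;
4. otherwise ``post_wgd``.

Families containing WGD paralogs are merged before origin assignment, and
WGD-pair members are always ``duplicate`` (they have a paralog by
construction).  The (wgd, novel) group is therefore empty by design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from genesisnet.dataio import DataError, EvolutionEvidence, GeneCatalog

logger = logging.getLogger(__name__)

AGES = ("pre_wgd", "wgd", "post_wgd")
ORIGINS = ("duplicate", "novel")

#: the five populated (age, origin) groups, in canonical order
GROUPS = (
    ("pre_wgd", "duplicate"),
    ("pre_wgd", "novel"),
    ("wgd", "duplicate"),
    ("post_wgd", "duplicate"),
    ("post_wgd", "novel"),
)


def group_label(age: str, origin: str) -> str:
    """Canonical string label for an (age, origin) group."""
    return f"{age}/{origin}"


@dataclass(frozen=True)
class ClassificationRecord:
    gene_id: str
    age: str
    origin: str
    evidence: str = ""


class Classification:
    """Per-gene (age, origin) labels plus the rule that fired for each."""

    def __init__(self, records: Iterable[ClassificationRecord], families: Mapping | None = None):
        self._records: dict[str, ClassificationRecord] = {}
        for rec in records:
            if rec.gene_id in self._records:
                raise DataError(f"gene {rec.gene_id!r} classified twice")
            if rec.age not in AGES:
                raise DataError(f"unknown age label {rec.age!r}")
            if rec.origin not in ORIGINS:
                raise DataError(f"unknown origin label {rec.origin!r}")
            if rec.age == "wgd" and rec.origin == "novel":
                raise DataError(f"gene {rec.gene_id!r}: (wgd, novel) is forbidden")
            self._records[rec.gene_id] = rec
        #: merged family partition used for origin calls (gene -> family id)
        self.families: dict = dict(families) if families else {}

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._records

    def __getitem__(self, gene_id: str) -> ClassificationRecord:
        return self._records[gene_id]

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self._records)

    def labels(self) -> dict:
        """gene_id -> "age/origin" group label."""
        return {g: group_label(r.age, r.origin) for g, r in self._records.items()}

    def group_counts(self) -> dict:
        counts = {group_label(a, o): 0 for a in AGES for o in ORIGINS}
        for rec in self._records.values():
            counts[group_label(rec.age, rec.origin)] = (
                counts.get(group_label(rec.age, rec.origin), 0) + 1
            )
        return counts

    def rows(self) -> list:
        """(gene_id, age, origin, evidence) rows for :func:`dataio.write_classification`."""
        return [(r.gene_id, r.age, r.origin, r.evidence) for r in self._records.values()]


# ---------------------------------------------------------------------------
# WGD pair detection and family merging
# ---------------------------------------------------------------------------


@dataclass
class WgdPairSet:
    """Unordered gene pairs retained from the WGD, tagged by ancestral locus."""

    pairs: dict = field(default_factory=dict)  # frozenset({g1, g2}) -> locus

    def __post_init__(self) -> None:
        seen: set = set()
        for pair in self.pairs:
            for gene in pair:
                if gene in seen:
                    raise DataError(f"gene {gene!r} appears in more than one WGD pair")
                seen.add(gene)
        self._genes = seen

    @property
    def genes(self) -> set:
        return set(self._genes)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def detect_wgd_pairs(evidence: EvolutionEvidence) -> WgdPairSet:
    """Find WGD-retained pairs: ancestral loci with descendants on both tracks.

    The reconstruction format pre-resolves syntenic tracks, so the
    double-region signature reduces to a locus having one gene on track A and
    one on track B.  A locus carrying more than one gene on a single track is
    malformed input.
    """
    by_locus: dict[str, dict[str, str]] = {}
    for locus, track, gene in evidence.reconstruction:
        tracks = by_locus.setdefault(locus, {})
        if track in tracks:
            raise DataError(
                f"ancestor locus {locus!r} has more than one gene on track {track}"
            )
        tracks[track] = gene
    pairs = {
        frozenset((tracks["A"], tracks["B"])): locus
        for locus, tracks in by_locus.items()
        if "A" in tracks and "B" in tracks
    }
    return WgdPairSet(pairs)


def merge_wgd_families(family_map: Mapping, pairs: WgdPairSet) -> dict:
    """Union families that contain members of the same WGD pair.

    Uses union-find over family ids; genes absent from *family_map* are
    treated as singleton families named after the gene.  Returns a new
    gene -> family-id map (a valid partition).
    """
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        root = x
        while parent.setdefault(root, root) != root:
            root = parent[root]
        while parent[x] != root:  # path compression
            parent[x], x = root, parent[x]
        return root

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    def family_of(gene: str) -> str:
        return family_map.get(gene, f"__singleton__{gene}")

    merged = {gene: family_of(gene) for gene in family_map}
    for pair in pairs:
        g1, g2 = sorted(pair)
        merged.setdefault(g1, family_of(g1))
        merged.setdefault(g2, family_of(g2))
        union(merged[g1], merged[g2])
    return {gene: find(fam) for gene, fam in merged.items()}


# ---------------------------------------------------------------------------
# origin and age assignment
# ---------------------------------------------------------------------------


def assign_origin(
    catalog: GeneCatalog,
    family_map: Mapping,
    pairs: WgdPairSet | None = None,
) -> dict:
    """Origin per non-dubious gene: family size >= 2 -> duplicate, else novel.

    Family sizes count only non-dubious genes present in the catalog (dubious
    ORFs are excluded before everything else).  WGD-pair members are always
    duplicate regardless of family size.
    """
    pair_genes = pairs.genes if pairs is not None else set()
    sizes: dict[str, int] = {}
    for rec in catalog.non_dubious():
        fam = family_map.get(rec.gene_id)
        if fam is not None:
            sizes[fam] = sizes.get(fam, 0) + 1
    origins: dict[str, str] = {}
    for rec in catalog.non_dubious():
        gene = rec.gene_id
        if gene in pair_genes:
            origins[gene] = "duplicate"
            continue
        fam = family_map.get(gene)
        size = sizes.get(fam, 1) if fam is not None else 1
        origins[gene] = "duplicate" if size >= 2 else "novel"
    return origins


def assign_age(
    catalog: GeneCatalog,
    evidence: EvolutionEvidence,
    pairs: WgdPairSet,
) -> tuple[dict, dict]:
    """Age per non-dubious gene, with the rule that fired.

    Returns (gene -> age, gene -> evidence string).  Genes both present in
    the reconstruction and flagged subtelomeric follow the reconstruction
    (logged).
    """
    in_reconstruction = {gene for _, _, gene in evidence.reconstruction}
    pair_genes = pairs.genes
    ages: dict[str, str] = {}
    rules: dict[str, str] = {}
    for rec in catalog.non_dubious():
        gene = rec.gene_id
        if gene in pair_genes:
            ages[gene] = "wgd"
            rules[gene] = "wgd_pair"
        elif gene in in_reconstruction:
            if rec.subtelomeric:
                logger.info(
                    "gene %s is subtelomeric but present in reconstruction; "
                    "reconstruction wins",
                    gene,
                )
            ages[gene] = "pre_wgd"
            rules[gene] = "ancestor_present"
        elif rec.subtelomeric:
            profile = evidence.ortholog_profile.get(gene, set())
            if any(flag for _, flag in profile):
                ages[gene] = "pre_wgd"
                rules[gene] = "subtelomeric_pre_wgd_ortholog"
            else:
                ages[gene] = "post_wgd"
                rules[gene] = "subtelomeric_no_pre_wgd_ortholog"
        else:
            ages[gene] = "post_wgd"
            rules[gene] = "absent_from_ancestor"
    return ages, rules


def classify(catalog: GeneCatalog, evidence: EvolutionEvidence) -> Classification:
    """Full family-based classification of every non-dubious catalog gene."""
    pairs = detect_wgd_pairs(evidence)
    families = merge_wgd_families(evidence.family_map, pairs)
    origins = assign_origin(catalog, families, pairs)
    ages, rules = assign_age(catalog, evidence, pairs)
    records = [
        ClassificationRecord(
            gene_id=rec.gene_id,
            age=ages[rec.gene_id],
            origin=origins[rec.gene_id],
            evidence=rules[rec.gene_id],
        )
        for rec in catalog.non_dubious()
    ]
    return Classification(records, families=families)


# ---------------------------------------------------------------------------
# progenitor variant
# ---------------------------------------------------------------------------


def ortholog_depth(gene: str, evidence: EvolutionEvidence, species_ranks: Mapping) -> int | None:
    """Deepest divergence rank among a gene's orthologs (None if no data)."""
    profile = evidence.ortholog_profile.get(gene)
    if not profile:
        return None
    ranks = [species_ranks.get(sp, 0) for sp, _ in profile]
    return max(ranks) if ranks else None


def apply_progenitor_variant(
    classification: Classification,
    evidence: EvolutionEvidence,
    species_ranks: Mapping,
    seed: int | None = None,
) -> Classification:
    """Relabel one gene per multi-member family as the family's progenitor.

    The progenitor — the family member with the most distant ortholog
    (deepest divergence rank; ties broken uniformly at random) — is assigned
    origin ``novel``; all other members stay ``duplicate``.  Families with no
    ortholog data pick the progenitor uniformly at random (logged).

    WGD-pair members (age ``wgd``) are never relabeled: relabeling one would
    create the forbidden (wgd, novel) combination, and pair members have a
    paralog by construction.  All-wgd families are skipped.
    """
    rng = np.random.default_rng(seed)
    by_family: dict[str, list[str]] = {}
    for rec in classification:
        fam = classification.families.get(rec.gene_id, f"__singleton__{rec.gene_id}")
        by_family.setdefault(fam, []).append(rec.gene_id)

    relabel: set = set()
    for fam in sorted(by_family):
        members = sorted(by_family[fam])
        if len(members) < 2:
            continue
        candidates = [g for g in members if classification[g].age != "wgd"]
        if not candidates:
            logger.info("family %s: all members are WGD-pair genes; no progenitor", fam)
            continue
        depths = {g: ortholog_depth(g, evidence, species_ranks) for g in candidates}
        known = {g: d for g, d in depths.items() if d is not None}
        if known:
            best = max(known.values())
            tied = sorted(g for g, d in known.items() if d == best)
        else:
            logger.info("family %s: no ortholog data; progenitor chosen at random", fam)
            tied = candidates
        relabel.add(tied[int(rng.integers(len(tied)))] if len(tied) > 1 else tied[0])

    records = [
        ClassificationRecord(
            gene_id=rec.gene_id,
            age=rec.age,
            origin="novel" if rec.gene_id in relabel else rec.origin,
            evidence=("progenitor" if rec.gene_id in relabel else rec.evidence),
        )
        for rec in classification
    ]
    return Classification(records, families=classification.families)


# ---------------------------------------------------------------------------
# agreement between classifications
# ---------------------------------------------------------------------------


@dataclass
class AgreementSummary:
    n_common: int
    origin_agreement: float
    age_agreement: float
    both_agreement: float
    crosstab: pd.DataFrame
    only_in_a: int = 0
    only_in_b: int = 0


def compare_classifications(a: Classification, b: Classification) -> AgreementSummary:
    """Fractional agreement on origin/age plus a full group cross-tabulation.

    Computed over the intersection of the two gene universes; an empty
    intersection is an error.
    """
    common = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not common:
        raise DataError("classifications share no genes")
    origin_hits = sum(a[g].origin == b[g].origin for g in common)
    age_hits = sum(a[g].age == b[g].age for g in common)
    both_hits = sum(
        a[g].age == b[g].age and a[g].origin == b[g].origin for g in common
    )
    labels_a = [group_label(a[g].age, a[g].origin) for g in common]
    labels_b = [group_label(b[g].age, b[g].origin) for g in common]
    crosstab = pd.crosstab(
        pd.Series(labels_a, name="a"), pd.Series(labels_b, name="b")
    )
    n = len(common)
    return AgreementSummary(
        n_common=n,
        origin_agreement=origin_hits / n,
        age_agreement=age_hits / n,
        both_agreement=both_hits / n,
        crosstab=crosstab,
        only_in_a=len(set(a.gene_ids) - set(b.gene_ids)),
        only_in_b=len(set(b.gene_ids) - set(a.gene_ids)),
    )
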