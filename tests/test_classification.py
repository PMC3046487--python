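"""classification: WGD pairs, family merging, origin/age rules, variants."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from genesisnet.classification import (
    Classification,
    ClassificationRecord,
    WgdPairSet,
    apply_progenitor_variant,
    assign_age,
    assign_origin,
    classify,
    compare_classifications,
    detect_wgd_pairs,
    group_label,
    merge_wgd_families,
)
from genesisnet.dataio import DataError, EvolutionEvidence, GeneCatalog, GeneRecord


def catalog_of(*gene_ids, **flags):
    return GeneCatalog(
        [GeneRecord(gene_id=g, length_aa=100, **flags.get(g, {})) for g in gene_ids]
    )


class TestDetectWgdPairs:
    def test_double_track_locus_yields_pair(self):
        evidence = EvolutionEvidence(reconstruction=[("L1", "A", "g1"), ("L1", "B", "g2")])
        pairs = detect_wgd_pairs(evidence)
        assert set(pairs) == {frozenset({"g1", "g2"})}
        assert pairs.pairs[frozenset({"g1", "g2"})] == "L1"

    def test_single_track_locus_yields_no_pair(self):
        evidence = EvolutionEvidence(reconstruction=[("L2", "A", "g3")])
        assert len(detect_wgd_pairs(evidence)) == 0

    def test_two_genes_on_one_track_is_error(self):
        evidence = EvolutionEvidence(
            reconstruction=[("L1", "A", "g1"), ("L1", "A", "g2")]
        )
        with pytest.raises(DataError, match="L1"):
            detect_wgd_pairs(evidence)

    def test_random_loci_match_brute_force(self, rng):
        # oracle: scan for loci carrying both tracks
        reconstruction = []
        expected = set()
        for i in range(50):
            locus = f"L{i}"
            tracks = ["A", "B"] if rng.random() < 0.5 else [rng.choice(["A", "B"])]
            genes = [f"g{i}_{t}" for t in tracks]
            for t, g in zip(tracks, genes):
                reconstruction.append((locus, t, g))
            if len(tracks) == 2:
                expected.add(frozenset(genes))
        pairs = detect_wgd_pairs(EvolutionEvidence(reconstruction=reconstruction))
        assert set(pairs) == expected

    def test_gene_in_two_pairs_is_error(self):
        with pytest.raises(DataError, match="more than one"):
            WgdPairSet(
                pairs={frozenset({"g1", "g2"}): "L1", frozenset({"g1", "g3"}): "L2"}
            )


class TestMergeWgdFamilies:
    def test_single_union(self):
        merged = merge_wgd_families(
            {"g1": "F1", "g2": "F2", "g3": "F2"},
            WgdPairSet(pairs={frozenset({"g1", "g2"}): "L1"}),
        )
        assert merged["g1"] == merged["g2"] == merged["g3"]

    def test_pair_within_family_is_noop(self):
        family_map = {"g1": "F1", "g2": "F1"}
        merged = merge_wgd_families(
            family_map, WgdPairSet(pairs={frozenset({"g1", "g2"}): "L1"})
        )
        assert merged["g1"] == merged["g2"]
        assert set(merged) == set(family_map)

    def test_chained_pairs_match_transitive_closure(self):
        family_map = {"a1": "F1", "a2": "F1", "b1": "F2", "b2": "F2", "c1": "F3"}
        pairs = WgdPairSet(
            pairs={frozenset({"a1", "b1"}): "L1", frozenset({"b2", "c1"}): "L2"}
        )
        merged = merge_wgd_families(family_map, pairs)
        # oracle: transitive closure over shared-family and paired relations
        adjacency = {g: set() for g in family_map}
        for g1 in family_map:
            for g2 in family_map:
                if family_map[g1] == family_map[g2]:
                    adjacency[g1].add(g2)
        for pair in pairs:
            g1, g2 = tuple(pair)
            adjacency[g1].add(g2)
            adjacency[g2].add(g1)
        component = {"a1"}
        while True:
            nxt = set().union(*(adjacency[g] for g in component)) | component
            if nxt == component:
                break
            component = nxt
        assert component == {"a1", "a2", "b1", "b2", "c1"}
        assert len({merged[g] for g in component}) == 1


class TestAssignOrigin:
    def test_family_of_two_is_duplicate(self):
        catalog = catalog_of("g1", "g2")
        origins = assign_origin(catalog, {"g1": "F1", "g2": "F1"})
        assert origins == {"g1": "duplicate", "g2": "duplicate"}

    def test_singleton_is_novel(self):
        catalog = catalog_of("g4")
        assert assign_origin(catalog, {"g4": "F9"}) == {"g4": "novel"}
        assert assign_origin(catalog, {}) == {"g4": "novel"}  # implicit singleton

    def test_dubious_genes_do_not_count_toward_family_size(self):
        catalog = GeneCatalog(
            [
                GeneRecord(gene_id="g1", length_aa=50),
                GeneRecord(gene_id="g2", length_aa=50, dubious=True),
            ]
        )
        origins = assign_origin(catalog, {"g1": "F1", "g2": "F1"})
        assert origins == {"g1": "novel"}

    def test_post_wgd_duplication_partner_is_duplicate(self):
        # a young gene with one same-genome paralog from a post-WGD event
        catalog = catalog_of("YMR303C", "YOL086C")
        evidence = EvolutionEvidence(
            family_map={"YMR303C": "ADH", "YOL086C": "ADH"}
        )
        labels = classify(catalog, evidence)
        assert labels["YMR303C"].origin == "duplicate"
        assert labels["YMR303C"].age == "post_wgd"


class TestAssignAge:
    def evidence(self):
        return EvolutionEvidence(
            reconstruction=[
                ("L1", "A", "gw1"),
                ("L1", "B", "gw2"),
                ("L2", "A", "gpre"),
            ],
            ortholog_profile={
                "gsub_old": {("sp7", True), ("sp1", False)},
                "gsub_young": {("sp2", False)},
            },
        )

    def test_rule_precedence(self):
        catalog = catalog_of(
            "gw1", "gw2", "gpre", "gsub_old", "gsub_young", "gnew",
            gsub_old={"subtelomeric": True}, gsub_young={"subtelomeric": True},
        )
        evidence = self.evidence()
        ages, rules = assign_age(catalog, evidence, detect_wgd_pairs(evidence))
        assert ages["gw1"] == ages["gw2"] == "wgd"
        assert ages["gpre"] == "pre_wgd" and rules["gpre"] == "ancestor_present"
        assert ages["gsub_old"] == "pre_wgd"
        assert rules["gsub_old"] == "subtelomeric_pre_wgd_ortholog"
        assert ages["gsub_young"] == "post_wgd"
        assert ages["gnew"] == "post_wgd"

    def test_reconstruction_beats_subtelomeric_flag(self):
        catalog = catalog_of("gpre", gpre={"subtelomeric": True})
        evidence = EvolutionEvidence(reconstruction=[("L2", "A", "gpre")])
        ages, _ = assign_age(catalog, evidence, detect_wgd_pairs(evidence))
        assert ages["gpre"] == "pre_wgd"


class TestClassificationInvariants:
    def test_partition_covers_non_dubious_and_wgd_novel_empty(self):
        from conftest import small_sim_config
        from genesisnet.synthetic_data import generate_dataset

        dataset = generate_dataset(small_sim_config(seed=2))
        labels = classify(dataset.catalog, dataset.evidence)
        non_dubious = {r.gene_id for r in dataset.catalog.non_dubious()}
        assert set(labels.gene_ids) == non_dubious
        counts = Counter((labels[g].age, labels[g].origin) for g in labels.gene_ids)
        assert counts[("wgd", "novel")] == 0

    def test_wgd_novel_record_is_rejected(self):
        with pytest.raises(DataError, match="forbidden"):
            Classification([ClassificationRecord("g1", "wgd", "novel")])

    def test_row_order_invariance(self):
        from conftest import small_sim_config
        from genesisnet.synthetic_data import generate_dataset

        dataset = generate_dataset(small_sim_config(seed=3))
        labels_fwd = classify(dataset.catalog, dataset.evidence)
        evidence_rev = EvolutionEvidence(
            family_map=dict(reversed(list(dataset.evidence.family_map.items()))),
            reconstruction=list(reversed(dataset.evidence.reconstruction)),
            ortholog_profile=dataset.evidence.ortholog_profile,
        )
        labels_rev = classify(dataset.catalog, evidence_rev)
        assert {(r.gene_id, r.age, r.origin) for r in labels_fwd} == {
            (r.gene_id, r.age, r.origin) for r in labels_rev
        }


class TestProgenitorVariant:
    def family_fixture(self, depths):
        genes = [f"g{i}" for i in range(len(depths))]
        catalog = catalog_of(*genes)
        evidence = EvolutionEvidence(
            family_map={g: "F1" for g in genes},
            ortholog_profile={
                g: {(f"sp{d}", d >= 5)} for g, d in zip(genes, depths) if d
            },
        )
        return catalog, evidence

    def test_deepest_gene_becomes_novel(self):
        catalog, evidence = self.family_fixture([5, 2, 2])
        labels = classify(catalog, evidence)
        ranks = {f"sp{i}": i for i in range(1, 9)}
        variant = apply_progenitor_variant(labels, evidence, ranks, seed=0)
        assert variant["g0"].origin == "novel"
        assert variant["g1"].origin == variant["g2"].origin == "duplicate"

    def test_tie_broken_deterministically_given_seed(self):
        catalog, evidence = self.family_fixture([4, 4])
        labels = classify(catalog, evidence)
        ranks = {f"sp{i}": i for i in range(1, 9)}
        first = apply_progenitor_variant(labels, evidence, ranks, seed=7)
        second = apply_progenitor_variant(labels, evidence, ranks, seed=7)
        assert [r.origin for r in first] == [r.origin for r in second]

    def test_symmetric_tie_is_near_uniform(self):
        catalog, evidence = self.family_fixture([4, 4])
        labels = classify(catalog, evidence)
        ranks = {f"sp{i}": i for i in range(1, 9)}
        chosen = Counter()
        for seed in range(1000):
            variant = apply_progenitor_variant(labels, evidence, ranks, seed=seed)
            chosen[[r.gene_id for r in variant if r.origin == "novel"][0]] += 1
        # binomial(1000, 0.5): +-5 percentage points around 50%
        assert 450 <= chosen["g0"] <= 550
        assert chosen["g0"] + chosen["g1"] == 1000

    def test_family_without_ortholog_data_picks_randomly(self):
        catalog, evidence = self.family_fixture([0, 0])
        labels = classify(catalog, evidence)
        variant = apply_progenitor_variant(labels, evidence, {}, seed=1)
        assert sorted(r.origin for r in variant) == ["duplicate", "novel"]

    def test_wgd_pair_members_never_relabeled(self):
        catalog = catalog_of("g1", "g2")
        evidence = EvolutionEvidence(
            family_map={"g1": "F1", "g2": "F1"},
            reconstruction=[("L1", "A", "g1"), ("L1", "B", "g2")],
            ortholog_profile={"g1": {("sp8", True)}, "g2": {("sp8", True)}},
        )
        labels = classify(catalog, evidence)
        ranks = {f"sp{i}": i for i in range(1, 9)}
        variant = apply_progenitor_variant(labels, evidence, ranks, seed=0)
        assert all(r.origin == "duplicate" for r in variant)


class TestCompareClassifications:
    def build(self, assignments):
        return Classification(
            [ClassificationRecord(g, age, origin) for g, (age, origin) in assignments.items()]
        )

    def test_identical_inputs_agree_fully(self):
        a = self.build({"g1": ("pre_wgd", "novel"), "g2": ("post_wgd", "duplicate")})
        summary = compare_classifications(a, a)
        assert summary.origin_agreement == 1.0
        assert summary.age_agreement == 1.0
        assert summary.both_agreement == 1.0

    def test_complement_origins_agree_zero(self):
        a = self.build({"g1": ("pre_wgd", "novel"), "g2": ("pre_wgd", "duplicate")})
        b = self.build({"g1": ("pre_wgd", "duplicate"), "g2": ("pre_wgd", "novel")})
        summary = compare_classifications(a, b)
        assert summary.origin_agreement == 0.0
        assert summary.age_agreement == 1.0

    def test_random_labelings_match_hand_count(self, rng):
        genes = [f"g{i}" for i in range(60)]
        ages = ["pre_wgd", "post_wgd"]
        origins = ["duplicate", "novel"]
        la = {g: (str(rng.choice(ages)), str(rng.choice(origins))) for g in genes}
        lb = {g: (str(rng.choice(ages)), str(rng.choice(origins))) for g in genes}
        summary = compare_classifications(self.build(la), self.build(lb))
        # oracle: direct counting
        origin_hits = sum(la[g][1] == lb[g][1] for g in genes)
        age_hits = sum(la[g][0] == lb[g][0] for g in genes)
        assert summary.origin_agreement == pytest.approx(origin_hits / 60)
        assert summary.age_agreement == pytest.approx(age_hits / 60)
        label_pairs = Counter(
            (group_label(*la[g]), group_label(*lb[g])) for g in genes
        )
        for (ga, gb), count in label_pairs.items():
            assert summary.crosstab.loc[ga, gb] == count

    def test_empty_intersection_is_error(self):
        a = self.build({"g1": ("pre_wgd", "novel")})
        b = self.build({"g2": ("pre_wgd", "novel")})
        with pytest.raises(DataError):
            compare_classifications(a, b)
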