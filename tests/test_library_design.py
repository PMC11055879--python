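import numpy as np
import pytest

from crisparray.library_design import (
    INTERNAL_DRS,
    INZOLIA_PROFILE,
    PROTOTYPE_PROFILE,
    AccountingError,
    AssemblyError,
    ArraySlot,
    DesignInputError,
    DesignProfile,
    ExpressionSummary,
    InfourArray,
    ParalogCandidate,
    ParalogFamily,
    assemble_oligo,
    build_arrays,
    cluster_families,
    manifest_accounting,
    planned_accounting,
    reagents_per_pair,
    select_pairs,
)


def _expr(*genes, mean=3.0, std=1.0):
    return {g: ExpressionSummary(g, mean, std) for g in genes}


class TestCandidateArithmetic:
    def test_mean_and_delta_identity(self):
        c = ParalogCandidate("A", "B", 60.0, 50.0)
        assert c.mean_identity == 55.0
        assert c.delta_identity == 10.0

    def test_identity_bounds_validated(self):
        with pytest.raises(DesignInputError):
            ParalogCandidate("A", "B", 120.0, 50.0)


class TestSelectPairs:
    def test_pair_inside_all_prototype_filters_accepted(self):
        c = ParalogCandidate("A", "B", 57.5, 52.5)  # mean 55, delta 5
        accepted, rejected = select_pairs([c], _expr("A", "B"), PROTOTYPE_PROFILE)
        assert accepted == [c] and not rejected

    def test_delta_exactly_ten_rejected_by_prototype_only(self):
        c = ParalogCandidate("A", "B", 60.0, 50.0)  # delta exactly 10
        accepted, rejected = select_pairs([c], _expr("A", "B"), PROTOTYPE_PROFILE)
        assert not accepted and "delta" in rejected[0][1]
        accepted, _ = select_pairs([c], _expr("A", "B"), INZOLIA_PROFILE)
        assert accepted == [c]

    @pytest.mark.parametrize("mean_id, ok", [(30.0, False), (30.5, True), (98.5, True), (99.0, False)])
    def test_identity_band_strict(self, mean_id, ok):
        c = ParalogCandidate("A", "B", mean_id, mean_id)
        accepted, _ = select_pairs([c], _expr("A", "B"), PROTOTYPE_PROFILE)
        assert bool(accepted) is ok

    def test_expression_filters(self):
        c = ParalogCandidate("A", "B", 55.0, 55.0)
        low = {**_expr("A"), **_expr("B", mean=1.5)}
        accepted, rejected = select_pairs([c], low, PROTOTYPE_PROFILE)
        assert not accepted and "B" in rejected[0][1]
        noisy = {**_expr("A"), **_expr("B", std=2.0)}
        assert not select_pairs([c], noisy, PROTOTYPE_PROFILE)[0]
        # variance filter disabled in the production profile
        assert select_pairs([c], noisy, INZOLIA_PROFILE)[0] == [c]

    def test_missing_expression_is_a_rejection_not_an_error(self):
        c = ParalogCandidate("A", "B", 55.0, 55.0)
        accepted, rejected = select_pairs([c], _expr("A"), PROTOTYPE_PROFILE)
        assert not accepted and "no expression" in rejected[0][1]

    def test_all_filters_disabled_returns_everything(self):
        wide_open = DesignProfile(
            name="open", identity_min=-1, identity_max=None, delta_max=None,
            expr_mean_min=None, expr_std_max=None,
        )
        cands = [ParalogCandidate("A", "B", 5.0, 99.0), ParalogCandidate("C", "D", 99.5, 0.5)]
        accepted, rejected = select_pairs(cands, {}, wide_open)
        assert accepted == cands and not rejected


class TestClusterFamilies:
    def test_small_drop_joins_family(self):
        fams = cluster_families({"A": [("B", 80.0), ("C", 75.0)]}, PROTOTYPE_PROFILE)
        assert [f.members for f in fams] == [("A", "B", "C")]

    def test_drop_fifteen_prototype_vs_inzolia(self):
        identities = {"A": [("B", 80.0), ("C", 65.0)]}
        proto = cluster_families(identities, PROTOTYPE_PROFILE)
        assert [f.members for f in proto] == [("A", "B")]
        inz = cluster_families(identities, INZOLIA_PROFILE)
        assert [f.members for f in inz] == [("A", "B", "C")]

    def test_truncated_to_four_by_smallest_drop(self):
        identities = {"A": [("B", 80.0), ("C", 79.0), ("D", 78.0), ("E", 77.0), ("F", 76.0)]}
        (fam,) = cluster_families(identities, PROTOTYPE_PROFILE)
        assert len(fam.members) == 4
        assert set(fam.members) == {"A", "B", "C", "D"}

    def test_deterministic_given_sorted_input(self):
        identities = {"A": [("B", 70.0)], "C": [("D", 60.0), ("E", 55.0)]}
        f1 = cluster_families(identities, PROTOTYPE_PROFILE)
        f2 = cluster_families(dict(reversed(list(identities.items()))), PROTOTYPE_PROFILE)
        assert f1 == f2


def _guides(genes, n=6, seed=0):
    rng = np.random.default_rng(seed)
    return {g: ["".join(rng.choice(list("ACGT"), size=20)) for _ in range(n)] for g in genes}


class TestBuildArrays:
    def test_single_gene_two_orders_same_guides(self):
        guides = _guides(["X"])
        arrays = build_arrays(["X"], [], guides)
        assert len(arrays) == 2
        a1, a2 = arrays
        assert sorted(a1.spacers) == sorted(a2.spacers) == sorted(guides["X"][:4])
        assert a1.spacers != a2.spacers

    def test_pair_interleaves_genes_two_each(self):
        guides = _guides(["A", "B"])
        fam = ParalogFamily(("A", "B"))
        a1, a2 = build_arrays([], [fam], guides)
        assert [s.target for s in a1.slots] == ["A", "B", "A", "B"]
        assert [s.target for s in a2.slots] == ["B", "A", "B", "A"]
        assert sorted(a1.spacers) == sorted(a2.spacers)

    def test_triples_padded_and_disjoint_across_siblings(self):
        guides = _guides(["A", "B", "C"])
        pads = [("T" * 20, "NE1"), ("G" * 20, "NE2")]
        fam = ParalogFamily(("A", "B", "C"))
        a1, a2 = build_arrays([], [fam], guides, pad_guides=pads)
        assert [s.target for s in a1.slots] == ["A", "B", "C", "NE1"]
        assert [s.target for s in a2.slots] == ["A", "B", "C", "NE2"]
        assert not set(a1.spacers) & set(a2.spacers)

    def test_quads_one_guide_per_gene_disjoint(self):
        guides = _guides(["A", "B", "C", "D"])
        fam = ParalogFamily(("A", "B", "C", "D"))
        a1, a2 = build_arrays([], [fam], guides)
        assert len({s.target for s in a1.slots}) == 4
        assert not set(a1.spacers) & set(a2.spacers)

    def test_insufficient_guides_names_gene(self):
        with pytest.raises(DesignInputError, match="X"):
            build_arrays(["X"], [], {"X": ["ACGT" * 5]})


def _array(spacers, array_id="arr"):
    slots = tuple(
        ArraySlot(sp, "A", i if i else None) for i, sp in enumerate(spacers)
    )
    return InfourArray(array_id, ("A",), slots, "single")


class TestOligoAssembly:
    def test_prototype_is_212mer(self):
        rec = assemble_oligo(_array(["ACGT" * 5] * 4), "prototype")
        assert len(rec.sequence) == 212
        assert sum(len(s) for _, s in rec.segment_map) == 212

    def test_inzolia_is_208mer(self):
        rec = assemble_oligo(_array(["ACGT" * 5] * 4), "inzolia")
        assert len(rec.sequence) == 208

    def test_internal_drs_in_printed_order_at_computed_offsets(self):
        rec = assemble_oligo(_array(["A" * 20, "C" * 20, "G" * 20, "T" * 20]), "prototype")
        offset = 0
        found = []
        for label, seg in rec.segment_map:
            if label.startswith("DR_"):
                assert rec.sequence[offset : offset + len(seg)] == seg
                found.append(seg)
            offset += len(seg)
        assert tuple(found) == INTERNAL_DRS
        for dr in INTERNAL_DRS:
            assert rec.sequence.count(dr) == 1

    def test_bsmbi_cores_live_in_the_restriction_segments(self):
        rec = assemble_oligo(_array(["ACGT" * 5] * 4), "prototype")
        segments = dict(rec.segment_map)
        assert "cgtctc" in segments["restriction_5p"].lower()
        assert "gagacg" in segments["restriction_3p"].lower()  # bottom-strand site
        for label in ("DR_a", "DR_b", "DR_c", "terminator"):
            assert "cgtctc" not in segments[label].lower()
            assert "gagacg" not in segments[label].lower()

    def test_injective_on_distinct_spacer_tuples(self):
        rng = np.random.default_rng(1)
        seen = {}
        for i in range(500):
            spacers = ["".join(rng.choice(list("ACGT"), size=20)) for _ in range(4)]
            seq = assemble_oligo(_array(spacers, f"a{i}"), "prototype").sequence
            key = tuple(spacers)
            assert seq not in seen or seen[seq] == key
            seen[seq] = key
        assert len(set(seen)) == 500

    @pytest.mark.parametrize("bad", [["ACGT" * 5] * 3 + ["ACG"], ["ACGX" + "A" * 16] + ["ACGT" * 5] * 3])
    def test_invalid_spacers_rejected(self, bad):
        with pytest.raises(AssemblyError):
            assemble_oligo(_array(bad), "prototype")


class TestAccounting:
    def test_prototype_manifest_total(self):
        counts = planned_accounting(19687, 2082, 167, 48, n_control_arrays=4)
        assert counts["total"] == 43972

    def test_inzolia_family_arrays_and_controls(self):
        counts = planned_accounting(19687, 4435, 376, 100, n_control_arrays=20 + 500 + 50)
        assert counts["family_arrays"] == 9822
        assert counts["control"] == 570

    def test_reagents_per_pair_fivefold_reduction(self):
        assert reagents_per_pair() == 6
        assert 30 // reagents_per_pair() == 5

    def test_built_arrays_counted_and_unique(self):
        guides = _guides(["A", "B", "X"])
        arrays = build_arrays(["X"], [ParalogFamily(("A", "B"))], guides)
        counts = manifest_accounting(arrays, template="prototype")
        assert counts["single"] == 2 and counts["pair"] == 2 and counts["total"] == 4

    def test_duplicate_sequences_rejected(self):
        guides = {"X": ["ACGT" * 5] * 4 + ["TTTT" * 5] * 4}
        arrays = build_arrays(["X"], [], guides)  # identical guides -> sibling oligos collide
        with pytest.raises(AccountingError):
            manifest_accounting(arrays, template="prototype")

    def test_empty_design_all_zero(self):
        counts = manifest_accounting([])
        assert counts["total"] == 0 and counts["family_arrays"] == 0
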