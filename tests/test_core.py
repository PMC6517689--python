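import random

import pytest

from frigg.core import (
    CandidateCluster,
    combine_runs,
    compute_homology_counts,
    family_size_cutoff,
    filter_essential,
    filter_recurrent,
    filter_single_copy,
    grid_configs,
    run_grid,
    run_pipeline,
    select_clusters_alternative,
    select_clusters_strict,
)
from frigg.model import FriggError, IntegrityError, PipelineConfig

import oracles
from conftest import build_dataset


def counts_of(dataset):
    return compute_homology_counts(dataset)


class TestHomologyCounts:
    def test_manual_enumeration_example(self):
        # cluster {p1 singleton, p2 sharing a family with free-standing p9}
        ds = build_dataset(
            {"a": "s"},
            {"f1": [("a", "p1")], "f2": [("a", "p2"), ("a", "p9")]},
            {"c1": ("a", ["p1", "p2"])},
        )
        rows = {(r.protein_id): (r.copies_in_organism, r.copies_in_clusters) for r in counts_of(ds)}
        assert rows == {"p1": (1, 1), "p2": (2, 1)}

    def test_all_singletons_copies_one(self):
        ds = build_dataset(
            {"a": "s"},
            {f"f{i}": [("a", f"p{i}")] for i in range(6)},
            {"c1": ("a", ["p0", "p1", "p2"])},
        )
        assert all(r.copies_in_organism == 1 for r in counts_of(ds))

    def test_three_copies_two_in_clusters(self):
        ds = build_dataset(
            {"a": "s"},
            {
                "f1": [("a", "p1"), ("a", "p2"), ("a", "p3")],
                "f2": [("a", "q1")],
                "f3": [("a", "q2")],
            },
            {"c1": ("a", ["p1", "q1"]), "c2": ("a", ["p2", "q2"])},
        )
        rows = {r.protein_id: (r.copies_in_organism, r.copies_in_clusters) for r in counts_of(ds)}
        assert rows["p1"] == (3, 2)
        assert rows["p2"] == (3, 2)

    def test_one_row_per_cluster_member(self, planted):
        dataset, _ = planted
        rows = counts_of(dataset)
        expected = sum(len(c.members) for c in dataset.clusters.values())
        assert len(rows) == expected

    def test_counts_match_brute_force(self, planted):
        dataset, _ = planted
        for r in counts_of(dataset):
            assert (r.copies_in_organism, r.copies_in_clusters) == oracles.brute_copy_counts(
                dataset, r.organism_id, r.protein_id
            )

    def test_requires_families(self):
        ds = build_dataset({"a": "s"}, {"f1": [("a", "p1")]}, {"c1": ("a", ["p1"])})
        ds.families = None
        with pytest.raises(FriggError, match="family"):
            compute_homology_counts(ds)


class TestFamilySizeCutoff:
    def test_51_organisms_x2(self):
        assert family_size_cutoff(51, 2) == 102

    def test_51_organisms_x3(self):
        assert family_size_cutoff(51, 3) == 153

    def test_5_organisms_x2(self):
        assert family_size_cutoff(5, 2) == 10

    def test_nonpositive_inputs_error(self):
        with pytest.raises(FriggError):
            family_size_cutoff(0, 2)
        with pytest.raises(FriggError):
            family_size_cutoff(5, 0)


def toy_strict_dataset():
    """One conformant cluster: p2 has a single extra copy outside clusters."""
    return build_dataset(
        {"a": "s"},
        {
            "f1": [("a", "p1")],
            "f2": [("a", "p2"), ("a", "p9")],
            "f3": [("a", "p3")],
        },
        {"c1": ("a", ["p1", "p2", "p3"])},
    )


class TestStrictSelection:
    def test_conformant_cluster_selected(self):
        ds = toy_strict_dataset()
        (cand,) = select_clusters_strict(counts_of(ds), ds)
        assert cand.cluster_id == "c1"
        assert cand.resistance_protein_id == "p2"
        assert cand.resistance_family_id == "f2"
        assert cand.target_protein_ids == ("p9",)
        assert cand.exempt_protein_ids == ()
        assert cand.pattern == "strict"

    def test_two_members_with_homologs_rejected(self):
        ds = build_dataset(
            {"a": "s"},
            {
                "f1": [("a", "p1"), ("a", "p8")],
                "f2": [("a", "p2"), ("a", "p9")],
            },
            {"c1": ("a", ["p1", "p2"])},
        )
        assert select_clusters_strict(counts_of(ds), ds) == []

    def test_extra_copy_inside_another_cluster_rejected(self):
        # the homolog must not be part of any predicted cluster
        ds = build_dataset(
            {"a": "s"},
            {"f1": [("a", "p1")], "f2": [("a", "p2"), ("a", "p9")], "f3": [("a", "q1")]},
            {"c1": ("a", ["p1", "p2"]), "c2": ("a", ["p9", "q1"])},
        )
        assert select_clusters_strict(counts_of(ds), ds) == []

    def test_three_copies_rejected(self):
        ds = build_dataset(
            {"a": "s"},
            {"f1": [("a", "p1")], "f2": [("a", "p2"), ("a", "p8"), ("a", "p9")]},
            {"c1": ("a", ["p1", "p2"])},
        )
        assert select_clusters_strict(counts_of(ds), ds) == []

    def test_mpa_like_four_gene_cluster_filtered_in_step2(self):
        # PKS and P450 single-copy; methyltransferase and the candidate gene
        # each carry one extra genome copy -> two multi-copy members
        ds = build_dataset(
            {"a": "s"},
            {
                "pks": [("a", "pks1")],
                "p450": [("a", "cyp1")],
                "mt": [("a", "mt1"), ("a", "mt2")],
                "res": [("a", "res1"), ("a", "res2")],
            },
            {"mpa": ("a", ["pks1", "cyp1", "mt1", "res1"])},
        )
        assert select_clusters_strict(counts_of(ds), ds) == []
        # the methyltransferase family is small, so the alternative pattern
        # does not rescue it either
        assert select_clusters_alternative(counts_of(ds), ds, x_input=2) == []


def eleven_member_family_dataset():
    """5 organisms; cluster in org a with a tailoring gene from an 11-member
    family plus a proper resistance architecture."""
    tail = [("a", "t1"), ("a", "t2")]
    tail += [(o, f"t{i}") for i, o in enumerate(["b", "b", "c", "c", "d", "d", "e", "e", "e"], start=3)]
    assert len(tail) == 11
    return build_dataset(
        {o: "s" for o in "abcde"},
        {
            "bb": [("a", "bb1")],
            "res": [("a", "r1"), ("a", "r2")],
            "tail": tail,
        },
        {"c1": ("a", ["bb1", "r1", "t1"])},
    )


class TestAlternativeSelection:
    def test_large_family_exempt_at_x2(self):
        ds = eleven_member_family_dataset()
        # cutoff = 2 x 5 = 10 < 11 -> tailoring family exempt
        (cand,) = select_clusters_alternative(counts_of(ds), ds, x_input=2)
        assert cand.cluster_id == "c1"
        assert cand.resistance_protein_id == "r1"
        assert cand.exempt_protein_ids == ("t1",)
        assert cand.pattern == "alternative"

    def test_exemption_lost_when_cutoff_reaches_family_size(self):
        ds = eleven_member_family_dataset()
        # cutoff = 2.2 x 5 = 11; exemption requires size strictly > cutoff
        assert select_clusters_alternative(counts_of(ds), ds, x_input=2.2) == []

    def test_strict_rejects_same_cluster(self):
        ds = eleven_member_family_dataset()
        assert select_clusters_strict(counts_of(ds), ds) == []

    def test_exempt_member_ineligible_as_resistance_gene(self):
        # the only multi-copy member belongs to the exempt family -> no
        # resistance gene -> not selected
        fam = {}
        fam["tail"] = [("a", "t1"), ("a", "t2")]
        for i, o in enumerate(["b", "c", "d", "e"] * 3, start=1):
            fam["tail"].append((o, f"t{i}"))
        fam["bb"] = [("a", "bb1")]
        ds = build_dataset({o: "s" for o in "abcde"}, fam, {"c1": ("a", ["bb1", "t1"])})
        assert len(ds.families["tail"]) == 14  # cutoff 10 at x=2 -> exempt
        assert select_clusters_alternative(counts_of(ds), ds, x_input=2) == []

    def test_limit_equivalence_with_huge_cutoff(self, planted):
        dataset, _ = planted
        rows = counts_of(dataset)
        biggest = max(len(m) for m in dataset.families.values())
        x = (biggest + 1) / len(dataset.organisms)
        alt = select_clusters_alternative(rows, dataset, x_input=x)
        strict = select_clusters_strict(rows, dataset)
        assert [(c.cluster_id, c.resistance_protein_id) for c in alt] == [
            (c.cluster_id, c.resistance_protein_id) for c in strict
        ]


def _cand(cid, org, fam, pid="r1"):
    return CandidateCluster(
        cluster_id=cid,
        organism_id=org,
        resistance_protein_id=pid,
        resistance_family_id=fam,
        target_protein_ids=("t1",),
    )


class TestRecurrenceFilter:
    def test_singleton_family_removed(self):
        cands = [_cand("c1", "a", "fX"), _cand("c2", "b", "fY"), _cand("c3", "c", "fY")]
        kept = filter_recurrent(cands)
        assert {c.cluster_id for c in kept} == {"c2", "c3"}

    def test_two_candidates_same_organism_count_by_default(self):
        cands = [_cand("c1", "a", "fX"), _cand("c2", "a", "fX")]
        assert len(filter_recurrent(cands)) == 2
        assert filter_recurrent(cands, distinct_organisms=True) == []

    def test_empty_in_empty_out(self):
        assert filter_recurrent([]) == []


def presence_dataset(n_orgs, present_orgs, multicopy_orgs=()):
    """Dataset with one family 'RF' in the given organisms (2 copies where
    multicopy) plus per-organism filler singletons."""
    orgs = {f"o{i:02d}": "s" for i in range(1, n_orgs + 1)}
    fams = {"RF": []}
    for i, org in enumerate(orgs):
        fams[f"fill{i}"] = [(org, "z1")]
    for org in present_orgs:
        fams["RF"].append((org, "r1"))
    for org in multicopy_orgs:
        fams["RF"].append((org, "r2"))
    return build_dataset(orgs, fams, {})


class TestEssentialFilter:
    def test_46_of_51_passes_90(self):
        orgs = [f"o{i:02d}" for i in range(1, 52)]
        ds = presence_dataset(51, orgs[:46])
        cand = _cand("c1", "o01", "RF")
        assert filter_essential([cand], ds, 90) == [cand]  # 90.2% >= 90%

    def test_46_of_51_fails_98(self):
        orgs = [f"o{i:02d}" for i in range(1, 52)]
        ds = presence_dataset(51, orgs[:46])
        assert filter_essential([_cand("c1", "o01", "RF")], ds, 98) == []

    def test_all_organisms_passes_100(self):
        orgs = [f"o{i:02d}" for i in range(1, 9)]
        ds = presence_dataset(8, orgs)
        cand = _cand("c1", "o01", "RF")
        assert filter_essential([cand], ds, 100) == [cand]

    def test_out_of_range_pct(self):
        ds = presence_dataset(3, ["o01"])
        with pytest.raises(FriggError):
            filter_essential([], ds, 101)


class TestSingleCopyFilter:
    def test_26_of_51_multicopy_removed(self):
        orgs = [f"o{i:02d}" for i in range(1, 52)]
        ds = presence_dataset(51, orgs, multicopy_orgs=orgs[:26])
        assert filter_single_copy([_cand("c1", "o01", "RF")], ds, 50) == []  # 50.98% > 50%

    def test_exactly_half_retained(self):
        orgs = [f"o{i:02d}" for i in range(1, 9)]
        ds = presence_dataset(8, orgs, multicopy_orgs=orgs[:4])
        cand = _cand("c1", "o01", "RF")
        assert filter_single_copy([cand], ds, 50) == [cand]  # boundary is strict

    def test_all_single_copy_retained(self):
        orgs = [f"o{i:02d}" for i in range(1, 9)]
        ds = presence_dataset(8, orgs)
        cand = _cand("c1", "o01", "RF")
        assert filter_single_copy([cand], ds, 50) == [cand]

    def test_family_organisms_only_denominator(self):
        orgs = [f"o{i:02d}" for i in range(1, 9)]
        # present in 4 organisms, multicopy in 3: 3/8 <= 50% but 3/4 > 50%
        ds = presence_dataset(8, orgs[:4], multicopy_orgs=orgs[:3])
        cand = _cand("c1", "o01", "RF")
        assert filter_single_copy([cand], ds, 50) == [cand]
        assert filter_single_copy([cand], ds, 50, family_organisms_only=True) == []


class TestRunPipeline:
    def test_no_clusters_all_steps_empty(self):
        ds = build_dataset({"a": "s"}, {"f1": [("a", "p1")]}, {})
        res = run_pipeline(ds, PipelineConfig())
        assert res.after_step2 == ()
        assert res.after_step3 == ()
        assert res.after_step4 == ()
        assert res.after_step5 == ()

    def test_step3_skipped_recorded_as_none(self):
        ds = toy_strict_dataset()
        res = run_pipeline(ds, PipelineConfig(skip_step3=True))
        assert res.after_step3 is None
        assert "step3" not in res.step_counts

    def test_nesting_invariant_across_grid(self, planted_grid):
        for res in planted_grid:
            chain = [res.after_step2]
            if res.after_step3 is not None:
                chain.append(res.after_step3)
            chain.append(res.after_step4)
            if res.after_step5 is not None:
                chain.append(res.after_step5)
            for prev, nxt in zip(chain, chain[1:]):
                assert set(nxt) <= set(prev)

    def test_parameter_monotonicity(self, planted):
        dataset, _ = planted
        base = run_pipeline(dataset, PipelineConfig(essential_pct=90))
        stricter = run_pipeline(dataset, PipelineConfig(essential_pct=98))
        assert set(stricter.after_step4) <= set(base.after_step4)
        loose5 = run_pipeline(dataset, PipelineConfig(majority_pct=80))
        tight5 = run_pipeline(dataset, PipelineConfig(majority_pct=20))
        assert set(tight5.after_step5) <= set(loose5.after_step5)

    def test_deterministic(self, planted):
        dataset, _ = planted
        cfg = PipelineConfig(pattern="alternative", x_input=2)
        assert run_pipeline(dataset, cfg) == run_pipeline(dataset, cfg)


class TestCombineRuns:
    def test_identical_runs_union_equals_single(self, planted):
        dataset, _ = planted
        r1 = run_pipeline(dataset, PipelineConfig(essential_pct=90))
        r2 = run_pipeline(dataset, PipelineConfig(essential_pct=98))
        fams, matrix = combine_runs([r1, r2])
        fams1 = {c.resistance_family_id for c in r1.final_candidates}
        fams2 = {c.resistance_family_id for c in r2.final_candidates}
        assert set(fams) == fams1 | fams2

    def test_disjoint_unions_add(self):
        r1 = _run_with_families(["fa", "fb", "fc"], label_ess=90)
        r2 = _run_with_families(["fd", "fe", "ff", "fg"], label_ess=98)
        fams, _ = combine_runs([r1, r2])
        assert len(fams) == 7

    def test_grid_union_matches_set_oracle(self, planted_grid):
        fams, matrix = combine_runs(planted_grid)
        oracle_union = set()
        for r in planted_grid:
            oracle_union |= {c.resistance_family_id for c in r.final_candidates}
        assert set(fams) == oracle_union
        for fid in fams:
            for r in planted_grid:
                expected = int(
                    fid in {c.resistance_family_id for c in r.final_candidates}
                )
                assert matrix[fid][r.config.setting_label] == expected

    def test_different_datasets_rejected(self, planted):
        dataset, _ = planted
        r1 = run_pipeline(dataset, PipelineConfig())
        r2 = run_pipeline(dataset, PipelineConfig(essential_pct=98))
        r2.dataset_fingerprint = (1, 2, 3, 4)
        with pytest.raises(IntegrityError, match="different datasets"):
            combine_runs([r1, r2])

    def test_empty_rejected(self):
        with pytest.raises(FriggError):
            combine_runs([])


def _run_with_families(family_ids, label_ess):
    from frigg.core import RunResult

    cands = tuple(_cand(f"c_{f}", "a", f) for f in family_ids)
    return RunResult(
        config=PipelineConfig(essential_pct=label_ess),
        after_step2=cands,
        after_step3=cands,
        after_step4=cands,
        after_step5=cands,
        dataset_fingerprint=("shared",),
    )


class TestGridConfigs:
    def test_twelve_settings(self):
        cfgs = grid_configs()
        assert len(cfgs) == 12
        labels = {c.setting_label for c in cfgs}
        assert len(labels) == 12
        assert all(c.apply_step5 for c in cfgs)

    def test_grid_runs_share_counts(self, planted, planted_grid):
        assert len(planted_grid) == 12


class TestOracleEquivalence:
    """Each step against the brute-force re-derivation, on random datasets."""

    @pytest.mark.parametrize("seed", range(20))
    def test_full_chain_matches_oracle(self, seed):
        rng = random.Random(seed)
        ds = oracles.random_dataset(rng)
        for pattern in ("strict", "alternative"):
            for skip3 in (False, True):
                for ess in (90, 98):
                    cfg = PipelineConfig(
                        pattern=pattern, x_input=2, skip_step3=skip3, essential_pct=ess
                    )
                    res = run_pipeline(ds, cfg)
                    expect = oracles.brute_chain(ds, pattern, 2, skip3, ess)
                    got = {
                        "step2": {c.cluster_id for c in res.after_step2},
                        "step3": None
                        if res.after_step3 is None
                        else {c.cluster_id for c in res.after_step3},
                        "step4": {c.cluster_id for c in res.after_step4},
                        "step5": {c.cluster_id for c in res.after_step5},
                    }
                    assert got == expect, f"seed={seed} {cfg.setting_label}"

    @pytest.mark.parametrize("seed", range(5))
    def test_resistance_gene_matches_oracle(self, seed):
        rng = random.Random(1000 + seed)
        ds = oracles.random_dataset(rng)
        res = select_clusters_strict(compute_homology_counts(ds), ds)
        expect = oracles.brute_select(ds)
        assert {c.cluster_id: (c.resistance_protein_id, c.resistance_family_id) for c in res} == expect
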