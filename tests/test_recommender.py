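"""Incidence matrix, Jaccard similarity, top-K recommendation, evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comorec.claims import GYNECOLOGIC_RANGES, ClaimsDataset, ClaimsError
from comorec.recommender import (
    SimilarityModel,
    build_incidence,
    evaluate_rs,
    jaccard_similarity,
    recommend,
    train_test_split,
)
from comorec.synth import AssociationSpec, DiseaseSpec, PopulationSpec, generate_population
from conftest import make_record


def dataset_from_baskets(baskets):
    """Build a dataset whose patient i carries exactly the codes in baskets[i]."""
    return ClaimsDataset(
        [make_record(f"P{i}", diagnoses=frozenset(b)) for i, b in enumerate(baskets)]
    )


class TestBuildIncidence:
    def test_category_level_collapses_siblings(self):
        m = build_incidence(dataset_from_baskets([{"N80.1", "N80.3"}, {"N30.0"}]))
        assert m.category_index == ["N30", "N80"]
        assert m.presence.toarray().tolist() == [[0, 1], [1, 0]]

    def test_full_level_no_collapse(self):
        m = build_incidence(
            dataset_from_baskets([{"N80.1", "N80.3"}, {"N30.0"}]), code_level="full"
        )
        assert m.presence.shape == (2, 3)

    def test_binary_despite_duplicates(self):
        # same category via two sibling codes still contributes a single 1
        m = build_incidence(dataset_from_baskets([{"N80.1", "N80.9"}]))
        assert m.presence.max() == 1

    def test_diagnosis_free_patients_dropped(self):
        ds = ClaimsDataset(
            [make_record("A", diagnoses=("N80.1",)), make_record("B", diagnoses=())]
        )
        m = build_incidence(ds)
        assert m.n_dropped_patients == 1 and len(m.patient_index) == 1

    def test_empty_dataset_raises(self):
        with pytest.raises(ClaimsError):
            build_incidence(ClaimsDataset([]))


class TestTrainTestSplit:
    def test_partition_contract(self):
        ds = dataset_from_baskets([{"N80.1"}] * 0 + [{f"A{i % 10:02d}"} for i in range(100)])
        train, test = train_test_split(ds, 0.8, seed=3)
        assert len(train) == 80 and len(test) == 20
        ids = {r.patient_id for r in train} | {r.patient_id for r in test}
        assert ids == {r.patient_id for r in ds}
        assert not ({r.patient_id for r in train} & {r.patient_id for r in test})

    def test_determinism(self):
        ds = dataset_from_baskets([{f"A{i % 10:02d}"} for i in range(50)])
        a = train_test_split(ds, 0.8, seed=9)
        b = train_test_split(ds, 0.8, seed=9)
        assert [r.patient_id for r in a[0]] == [r.patient_id for r in b[0]]

    def test_rounding_on_odd_sizes(self):
        ds = dataset_from_baskets([{f"A{i:02d}"} for i in range(5)])
        train, test = train_test_split(ds, 0.5, seed=1)
        assert sorted([len(train), len(test)]) == [2, 3]

    def test_bad_fraction(self):
        ds = dataset_from_baskets([{"A00"}])
        with pytest.raises(Exception):
            train_test_split(ds, 1.5, seed=0)


class TestJaccard:
    def test_hand_enumerated_overlap(self):
        # P_a = {0,1,2}, P_b = {1,2,3}: |inter| 2, |union| 4
        baskets = [{"A00"}, {"A00", "B00"}, {"A00", "B00"}, {"B00"}]
        model = jaccard_similarity(build_incidence(dataset_from_baskets(baskets)))
        assert model.similarity("A00", "B00") == pytest.approx(0.5)

    def test_identical_patient_sets(self):
        model = jaccard_similarity(
            build_incidence(dataset_from_baskets([{"A00", "B00"}, {"A00", "B00"}]))
        )
        assert model.similarity("A00", "B00") == 1.0

    def test_disjoint_sets(self):
        model = jaccard_similarity(
            build_incidence(dataset_from_baskets([{"A00"}, {"B00"}]))
        )
        assert model.similarity("A00", "B00") == 0.0

    def test_diagonal_symmetry_and_range(self):
        spec = PopulationSpec(
            n_patients=2000,
            diseases=[
                DiseaseSpec("N80", {"N80.1": 1.0}, 0.2),
                DiseaseSpec("D24", {"D24": 1.0}, 0.3),
                DiseaseSpec("N30", {"N30.0": 1.0}, 0.25),
            ],
            seed=8,
        )
        model = jaccard_similarity(build_incidence(generate_population(spec)))
        s = model.sim
        assert np.allclose(s, s.T)
        assert (s >= 0).all() and (s <= 1).all()
        assert np.allclose(np.diag(s), 1.0)

    @given(
        st.integers(1, 10),
        st.integers(1, 6),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_sets(self, n_patients, n_cats, seed):
        """Sparse-matrix Jaccard equals a direct set computation on random
        small incidence configurations."""
        rng = np.random.default_rng(seed)
        cats = [f"A{i:02d}" for i in range(n_cats)]
        mat = rng.random((n_patients, n_cats)) < 0.5
        baskets = [
            {cats[j] for j in range(n_cats) if mat[i, j]} for i in range(n_patients)
        ]
        baskets = [b for b in baskets if b]
        if not baskets:
            return
        model = jaccard_similarity(build_incidence(dataset_from_baskets(baskets)))
        patients_of = {
            c: {i for i, b in enumerate(baskets) if c in b}
            for c in model.category_index
        }
        for a in model.category_index:
            for b in model.category_index:
                pa, pb = patients_of[a], patients_of[b]
                expected = len(pa & pb) / len(pa | pb) if pa | pb else 0.0
                assert model.similarity(a, b) == pytest.approx(expected)


def toy_model(sims):
    """SimilarityModel over categories of `sims` plus a query category Q00."""
    cats = sorted(sims) + ["Q00"]
    idx = {c: i for i, c in enumerate(cats)}
    m = np.eye(len(cats))
    for c, s in sims.items():
        m[idx[c], idx["Q00"]] = m[idx["Q00"], idx[c]] = s
    return SimilarityModel(category_index=cats, sim=m)


class TestRecommend:
    def test_full_ranking(self):
        model = toy_model({"A00": 0.5, "B00": 0.2})
        rec = recommend(model, "Q00", k=2)
        assert rec.ranked == [("A00", 0.5), ("B00", 0.2)]

    def test_truncation(self):
        model = toy_model({"A00": 0.5, "B00": 0.2})
        assert recommend(model, "Q00", k=1).categories == ["A00"]

    def test_query_never_recommended(self):
        model = toy_model({"A00": 0.5})
        assert "Q00" not in recommend(model, "Q00", k=10).categories

    def test_tie_break_lexicographic(self):
        model = toy_model({"C00": 0.3, "A00": 0.3, "B00": 0.3})
        assert recommend(model, "Q00", k=3).categories == ["A00", "B00", "C00"]

    def test_exclusion_after_topk_shrinks_list(self):
        """23 gynecologic categories inside the top 30 leave 7 survivors."""
        gyn = [f"N{i}" for i in range(80, 99)] + ["N70", "N71", "O03", "D25"]
        keep = ["D24", "N60", "N64", "N30", "E04", "D50", "D64"]
        sims = {c: 0.9 - 0.01 * i for i, c in enumerate(gyn + keep)}
        sims["Z99"] = 0.01  # outside the top 30
        model = toy_model(sims)
        top = recommend(model, "Q00", k=30)
        assert len(top.ranked) == 30
        survivors = recommend(model, "Q00", k=30, exclusions=GYNECOLOGIC_RANGES)
        assert len(survivors.ranked) == 7
        assert set(survivors.categories) == set(keep)

    def test_exclude_before_ranking_backfills(self):
        gyn = [f"N{i}" for i in range(80, 99)]
        keep = ["D24", "N30"]
        sims = {c: 0.9 - 0.01 * i for i, c in enumerate(gyn + keep)}
        model = toy_model(sims)
        rec = recommend(
            model, "Q00", k=2, exclusions=GYNECOLOGIC_RANGES,
            exclude_before_ranking=True,
        )
        assert rec.categories == ["D24", "N30"]

    def test_unknown_query_raises(self):
        with pytest.raises(ClaimsError):
            recommend(toy_model({"A00": 0.5}), "X99", k=1)

    def test_permutation_invariance(self):
        cats = ["A00", "B00", "C00", "Q00"]
        rng = np.random.default_rng(0)
        base = np.array(
            [[1.0, 0.1, 0.2, 0.4],
             [0.1, 1.0, 0.3, 0.4],
             [0.2, 0.3, 1.0, 0.6],
             [0.4, 0.4, 0.6, 1.0]]
        )
        ref = recommend(SimilarityModel(cats, base), "Q00", k=3).ranked
        perm = rng.permutation(4)
        model2 = SimilarityModel(
            [cats[i] for i in perm], base[np.ix_(perm, perm)]
        )
        assert recommend(model2, "Q00", k=3).ranked == ref


class TestEvaluate:
    def test_perfect_retrieval(self):
        model = toy_model({"A00": 0.9})
        # patient has {Q00, A00}; whichever is held out, the other is top-1
        ds = dataset_from_baskets([{"Q00", "A00"}])
        v = evaluate_rs(model, ds, n_rec=1, seed=0)
        assert v.mean_precision == 1.0 and v.mean_recall == 1.0

    def test_total_miss(self):
        model = toy_model({"A00": 0.9, "B00": 0.5})
        ds = dataset_from_baskets([{"Q00", "Z99"}])
        v = evaluate_rs(model, ds, n_rec=2, seed=0)
        assert v.mean_precision == 0.0 and v.mean_recall == 0.0

    def test_partial_hit_counts(self):
        # query Q00; the patient's 3 other categories all sit inside the
        # top-5 recommendations: precision 3/5, recall 3/3
        model = toy_model({"A00": 0.9, "B00": 0.8, "C00": 0.7, "D00": 0.6, "E00": 0.5})
        top5 = recommend(model, "Q00", 5).categories
        hits = len(set(top5) & {"A00", "B00", "C00"})
        assert hits / 5 == pytest.approx(0.6)
        assert hits / 3 == pytest.approx(1.0)

    def test_metrics_bounded(self):
        spec = PopulationSpec(
            n_patients=3000,
            diseases=[
                DiseaseSpec("N80", {"N80.1": 1.0}, 0.2),
                DiseaseSpec("D24", {"D24": 1.0}, 0.3),
                DiseaseSpec("N30", {"N30.0": 1.0}, 0.25),
                DiseaseSpec("E04", {"E04.1": 1.0}, 0.15),
            ],
            associations=[AssociationSpec("N80", "D24", 3.0)],
            seed=13,
        )
        ds = generate_population(spec)
        train, test = train_test_split(ds, 0.8, seed=13)
        model = jaccard_similarity(build_incidence(train))
        v = evaluate_rs(model, test, n_rec=2, seed=13)
        assert 0.0 <= v.mean_precision <= 1.0
        assert 0.0 <= v.mean_recall <= 1.0
        assert v.n_eval_patients > 0

    def test_determinism(self):
        model = toy_model({"A00": 0.9, "B00": 0.5})
        ds = dataset_from_baskets(
            [{"Q00", "A00", "B00"}, {"Q00", "B00"}, {"A00", "B00"}]
        )
        a = evaluate_rs(model, ds, n_rec=1, seed=5)
        b = evaluate_rs(model, ds, n_rec=1, seed=5)
        assert a == b

    def test_no_eligible_patients_raises(self):
        model = toy_model({"A00": 0.9})
        ds = dataset_from_baskets([{"A00"}])
        with pytest.raises(ClaimsError):
            evaluate_rs(model, ds, n_rec=1, seed=0)


class TestPlantedSignalRetrieval:
    def test_associated_disease_outranks_null_peers(self):
        """With one planted association, the partner disease ranks above the
        median of unassociated diseases of the same prevalence."""
        prev = 0.05
        diseases = [DiseaseSpec("N80", {"N80.1": 1.0}, prev)] + [
            DiseaseSpec(f"A{i:02d}", {f"A{i:02d}": 1.0}, prev) for i in range(10)
        ] + [DiseaseSpec("D24", {"D24": 1.0}, prev)]
        spec = PopulationSpec(
            n_patients=30_000,
            diseases=diseases,
            associations=[AssociationSpec("N80", "D24", 3.0)],
            seed=21,
        )
        ds = generate_population(spec)
        model = jaccard_similarity(build_incidence(ds))
        ranked = recommend(model, "N80", k=len(model.category_index)).categories
        rank_d24 = ranked.index("D24")
        null_ranks = [ranked.index(f"A{i:02d}") for i in range(10)]
        assert rank_d24 < np.median(null_ranks)
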