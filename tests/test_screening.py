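"""Library scoring, nearest-repellent lookup, and the filter cascade."""

import numpy as np
import pandas as pd
import pytest

from repelscreen.chem_table import DescriptorMatrix, standardize
from repelscreen.models import ModelSpec, build_ensemble
from repelscreen.screening import (
    CandidateRecord,
    FilterConfig,
    apply_filters,
    ld50_to_epa_category,
    nearest_known_repellent,
    predict_ca_activity,
    score_library,
)
from repelscreen.synthetic_data import (
    SyntheticConfig,
    make_dataset,
    noise_sd_for_r2,
)


@pytest.fixture(scope="module")
def trained():
    eff = np.full(3, 2.0)
    cfg = SyntheticConfig(n_chemicals=150, n_features=8, n_informative=3,
                          effect_sizes=eff, noise_sd=noise_sd_for_r2(eff, 0.9),
                          seed=30)
    ds = make_dataset(cfg)
    X_std = standardize(ds.descriptors)
    ens = build_ensemble(ModelSpec("random_forest", "regression", {"trees": 40}),
                         X_std, ds.response, X_std.feature_names,
                         n_members=6, features_per_member=5, seed=30)
    return ds, X_std, ens


class TestScoreLibrary:
    def test_training_chemicals_score_as_direct_predictions(self, trained):
        ds, X_std, ens = trained
        scored = score_library(ens, X_std)
        direct = pd.Series(ens.predict(X_std.data), index=X_std.chem_ids)
        assert np.allclose(scored["score"].sort_index(), direct.sort_index())

    def test_reference_chemical_scores_100(self, trained):
        _, X_std, ens = trained
        ref = X_std.chem_ids[0]
        scored = score_library(ens, X_std, reference_chem=ref)
        assert scored.loc[ref, "score"] == pytest.approx(100.0)

    def test_chunked_scoring_bit_identical(self, trained):
        _, X_std, ens = trained
        whole = score_library(ens, X_std, chunk_size=10_000)
        chunked = score_library(ens, X_std, chunk_size=7)
        assert whole.equals(chunked)

    def test_missing_features_reported(self, trained):
        _, X_std, ens = trained
        partial = X_std.subset_features(X_std.feature_names[:2])
        with pytest.raises(ValueError, match="lacks model features"):
            score_library(ens, partial)

    def test_relative_scores_invariant_to_output_rescaling(self, trained):
        _, X_std, ens = trained

        class Scaled:
            def __init__(self, base, c):
                self.members = base.members
                self._base, self._c = base, c

            def predict(self, X):
                return self._c * self._base.predict(X)

        ref = X_std.chem_ids[0]
        a = score_library(ens, X_std, reference_chem=ref)
        b = score_library(Scaled(ens, 7.3), X_std, reference_chem=ref)
        assert np.allclose(a["score"], b["score"])


class TestNearestKnownRepellent:
    def test_identical_candidate_at_distance_zero(self, trained):
        _, X_std, _ = trained
        known = X_std.subset_rows([0, 1, 2])
        chem, dist = nearest_known_repellent(X_std.data.iloc[1], known)
        assert chem == X_std.chem_ids[1] and dist == 0.0

    def test_invariant_to_feature_permutation(self, trained):
        _, X_std, _ = trained
        known = X_std.subset_rows([0, 1, 2])
        cand = X_std.data.iloc[10]
        perm = list(np.random.default_rng(0).permutation(X_std.feature_names))
        known_perm = DescriptorMatrix(known.data[perm])
        assert nearest_known_repellent(cand, known)[1] == pytest.approx(
            nearest_known_repellent(cand[perm], known_perm)[1])

    def test_matches_brute_force_on_toy_set(self):
        rng = np.random.default_rng(31)
        lib = rng.normal(size=(50, 20))
        known = rng.normal(size=(12, 20))
        K = DescriptorMatrix(pd.DataFrame(
            known, index=[f"k{i:02d}" for i in range(12)],
            columns=[f"f{j}" for j in range(20)]))
        for i in range(50):
            cand = pd.Series(lib[i], index=K.feature_names)
            chem, dist = nearest_known_repellent(cand, K)
            brute = np.sqrt(((known - lib[i]) ** 2).sum(axis=1))
            assert dist == pytest.approx(brute.min())
            assert chem == f"k{brute.argmin():02d}"

    def test_empty_known_set_rejected(self, trained):
        _, X_std, _ = trained
        empty = DescriptorMatrix(X_std.data.iloc[:0])
        with pytest.raises(ValueError, match="empty"):
            nearest_known_repellent(X_std.data.iloc[0], empty)


def _records():
    return [
        CandidateRecord("a", 90.0, {"fruity"}, ca_activity=0.2, tox_category="III"),
        CandidateRecord("b", 80.0, {"musty"}, ca_activity=0.9, tox_category="II"),
        CandidateRecord("c", 70.0, set(), ca_activity=None, tox_category="IV"),
        CandidateRecord("d", 60.0, {"fruity", "minty"}, ca_activity=0.1,
                        tox_category="I"),
    ]


class TestApplyFilters:
    def test_epa_category_II_fails_toxicity_filter(self):
        survivors, annotated = apply_filters(_records(), FilterConfig())
        by_id = {r.chem_id: r for r in annotated}
        assert by_id["b"].filter_verdicts["toxicity"] == "fail"
        assert by_id["b"].final is False
        assert by_id["d"].final is False  # category I likewise

    def test_all_filters_disabled_passes_everything_ranked(self):
        cfg = FilterConfig(excluded_tox_categories=set(), top_n=10)
        survivors, _ = apply_filters(_records(), cfg)
        assert [r.chem_id for r in survivors] == ["a", "b", "c", "d"]

    @pytest.mark.parametrize("loose,tight", [
        (dict(min_repellency_score=65.0), dict(min_repellency_score=85.0)),
        (dict(max_ca_activity=1.0), dict(max_ca_activity=0.15)),
        (dict(excluded_tox_categories={"I"}),
         dict(excluded_tox_categories={"I", "II", "III"})),
    ])
    def test_tightening_never_grows_survivor_set(self, loose, tight):
        base = dict(excluded_tox_categories=set(), lenient_missing=True, top_n=10)
        loose_set = {r.chem_id for r in
                     apply_filters(_records(), FilterConfig(**{**base, **loose}))[0]}
        tight_set = {r.chem_id for r in
                     apply_filters(_records(), FilterConfig(**{**base, **tight}))[0]}
        assert tight_set <= loose_set

    def test_missing_inputs_fail_closed_unless_lenient(self):
        cfg = FilterConfig(max_ca_activity=1.0, excluded_tox_categories=set())
        survivors, annotated = apply_filters(_records(), cfg)
        c = next(r for r in annotated if r.chem_id == "c")
        assert c.filter_verdicts["ca_activity"] == "unknown"
        assert c.final is False
        lenient = FilterConfig(max_ca_activity=1.0, excluded_tox_categories=set(),
                               lenient_missing=True)
        survivors2, _ = apply_filters(_records(), lenient)
        assert "c" in {r.chem_id for r in survivors2}

    def test_percept_requirements(self):
        cfg = FilterConfig(required_percepts={"fruity"},
                           forbidden_percepts={"musty"},
                           excluded_tox_categories=set())
        survivors, _ = apply_filters(_records(), cfg)
        assert {r.chem_id for r in survivors} == {"a", "d"}


class TestToxCategories:
    @pytest.mark.parametrize("ld50,cat", [
        (10.0, "I"), (50.0, "I"), (200.0, "II"), (500.0, "II"),
        (2000.0, "III"), (10_000.0, "IV"), (float("nan"), "unknown"),
    ])
    def test_oral_ld50_breakpoints(self, ld50, cat):
        assert ld50_to_epa_category(ld50) == cat


class TestPredictCaActivity:
    def test_planted_calcium_signal_recovered_out_of_sample(self):
        eff = np.full(3, 2.0)
        cfg = SyntheticConfig(n_chemicals=300, n_features=8, n_informative=3,
                              effect_sizes=eff,
                              noise_sd=noise_sd_for_r2(eff, 0.9), seed=32)
        ds = make_dataset(cfg)
        X_std = standardize(ds.descriptors)
        train = X_std.subset_rows(list(range(240)))
        test = X_std.subset_rows(list(range(240, 300)))
        ens = build_ensemble(
            ModelSpec("random_forest", "regression", {"trees": 100}),
            train, ds.response[:240], train.feature_names,
            n_members=10, features_per_member=5, seed=32)
        pred = predict_ca_activity(ens, test)
        r = np.corrcoef(pred.to_numpy(), ds.response[240:])[0, 1]
        assert r >= 0.8
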