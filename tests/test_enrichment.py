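"""Early-recognition metrics: AUCc identity, EF, RIE, BEDROC, screening."""

from itertools import combinations

import numpy as np
import pytest

from bcrpqsar import (
    CompoundRecord,
    PolyspecificGeneratorConfig,
    ScoredRanking,
    accumulation_auc,
    bedroc,
    enrichment_factor,
    enrichment_report,
    generate_polyspecific,
    rie,
    roc_auc_from_aucc,
    run_screening_campaign,
    screening_library,
    empirical_roc,
)
from conftest import random_ranking


def exhaustive_rankings(n, a):
    """All placements of a hits among n ranks, as ScoredRankings."""
    for hit_pos in combinations(range(n), a):
        is_hit = np.zeros(n, bool)
        is_hit[list(hit_pos)] = True
        yield ScoredRanking(ids=[str(i) for i in range(n)],
                            scores=np.arange(n, 0, -1, dtype=float),
                            is_hit=is_hit)


class TestAccumulationAUC:
    @pytest.mark.parametrize("ties", [False, True])
    def test_identity_with_roc_auc_on_random_rankings(self, rng, ties):
        for _ in range(60):
            n = int(rng.integers(10, 300))
            a = int(rng.integers(1, n))
            r = random_ranking(rng, n, a, ties)
            aucc = accumulation_auc(r)
            assert roc_auc_from_aucc(aucc, a / n) == pytest.approx(
                empirical_roc(r).auc, abs=1e-10
            )

    def test_all_hits_first_geometry(self):
        r = ScoredRanking(ids=[str(i) for i in range(10)],
                          scores=np.arange(10, 0, -1, dtype=float),
                          is_hit=np.arange(10) < 4)
        assert accumulation_auc(r) == pytest.approx(1 - 0.4 / 2, abs=1e-12)

    def test_chance_value_with_balanced_hits(self, rng):
        r = random_ranking(rng, 5000, 2500)
        assert accumulation_auc(r) == pytest.approx(0.5, abs=0.02)


class TestEnrichmentFactor:
    def test_fully_hit_selection_on_paper_shaped_library(self):
        # N=164, A=85, top 16 all hits
        is_hit = np.zeros(164, bool)
        is_hit[:16] = True
        is_hit[16:85] = True  # remaining hits below the selection
        r = ScoredRanking(ids=[str(i) for i in range(164)],
                          scores=np.arange(164, 0, -1, dtype=float), is_hit=is_hit)
        assert enrichment_factor(r, n_select=16) == pytest.approx(164 / 85, abs=1e-9)

    def test_small_example_and_bounds(self, rng):
        is_hit = np.array([True, False, True, False, True, False, True, False, True, False])
        r = ScoredRanking(ids=[str(i) for i in range(10)],
                          scores=np.arange(10, 0, -1, dtype=float), is_hit=is_hit)
        assert enrichment_factor(r, x=0.1) == pytest.approx(2.0)
        for _ in range(20):
            rr = random_ranking(rng, 50, int(rng.integers(1, 50)))
            ef = enrichment_factor(rr, x=0.2)
            assert ef * (rr.n_hits / 50) <= 1 + 1e-12

    def test_chance_expectation_is_one(self, rng):
        efs = [enrichment_factor(random_ranking(rng, 200, 50), x=0.25)
               for _ in range(200)]
        assert np.mean(efs) == pytest.approx(1.0, abs=0.05)

    def test_empty_selection_raises(self, make_ranking):
        with pytest.raises(ValueError, match="empty"):
            enrichment_factor(make_ranking(n=5, n_hits=2), x=0.1)


def rie_direct(is_hit_sorted, alpha):
    """Direct-summation oracle for RIE on an explicit ordering."""
    n = len(is_hit_sorted)
    a = int(np.sum(is_hit_sorted))
    s = sum(np.exp(-alpha * (i + 1) / n) for i in range(n) if is_hit_sorted[i])
    rand = (1.0 / n) * (1 - np.exp(-alpha)) / (np.exp(alpha / n) - 1)
    return (s / a) / rand


def bedroc_direct(is_hit_sorted, alpha):
    n = len(is_hit_sorted)
    ra = np.sum(is_hit_sorted) / n
    r = rie_direct(is_hit_sorted, alpha)
    return (r * ra * np.sinh(alpha / 2)
            / (np.cosh(alpha / 2) - np.cosh(alpha / 2 - alpha * ra))
            + 1 / (1 - np.exp(alpha * (1 - ra))))


class TestRIEAndBEDROC:
    def test_single_hit_at_top_hand_value(self):
        r = ScoredRanking(ids=list("abcd"), scores=[4.0, 3, 2, 1],
                          is_hit=[True, False, False, False])
        expected = np.exp(-5) * 4 * (np.exp(5) - 1) / (1 - np.exp(-20))
        assert rie(r, alpha=20) == pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(3.9731, abs=1e-3)

    def test_hit_at_bottom_approaches_zero(self):
        r = ScoredRanking(ids=[str(i) for i in range(50)],
                          scores=np.arange(50, 0, -1, dtype=float),
                          is_hit=np.arange(50) == 49)
        assert rie(r, alpha=100) == pytest.approx(0.0, abs=1e-6)

    def test_random_expectation_is_one(self, rng):
        n, a = 40, 8
        vals = []
        for _ in range(10_000):
            is_hit = np.zeros(n, bool)
            is_hit[rng.choice(n, a, replace=False)] = True
            r = ScoredRanking(ids=[str(i) for i in range(n)],
                              scores=np.arange(n, 0, -1, dtype=float), is_hit=is_hit)
            vals.append(rie(r, alpha=20))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.03)

    @pytest.mark.parametrize("n,alpha", [(6, 5.0), (8, 20.0)])
    def test_agree_with_direct_sum_on_exhaustive_rankings(self, n, alpha):
        for a in range(1, n):
            for r in exhaustive_rankings(n, a):
                order = r.order()
                is_hit_sorted = r.is_hit[order]
                assert rie(r, alpha) == pytest.approx(
                    rie_direct(is_hit_sorted, alpha), abs=1e-12)
                assert bedroc(r, alpha) == pytest.approx(
                    bedroc_direct(is_hit_sorted, alpha), abs=1e-12)

    def test_bedroc_bounds_and_extremes(self):
        n = 200
        worst = ScoredRanking(ids=[str(i) for i in range(n)],
                              scores=np.arange(n, 0, -1, dtype=float),
                              is_hit=np.arange(n) >= n - 10)
        best = ScoredRanking(ids=[str(i) for i in range(n)],
                             scores=np.arange(n, 0, -1, dtype=float),
                             is_hit=np.arange(n) < 10)
        assert bedroc(worst, 20) == pytest.approx(0.0, abs=1e-3)
        b = bedroc(best, 20)
        assert b <= 1.0 + 1e-12
        assert b == pytest.approx(bedroc_direct(best.is_hit[best.order()], 20))

    def test_bedroc_stable_under_library_duplication(self):
        n, a = 100, 10
        is_hit = np.zeros(n, bool)
        is_hit[::10] = True
        base = ScoredRanking(ids=[str(i) for i in range(n)],
                             scores=np.arange(n, 0, -1, dtype=float), is_hit=is_hit)
        doubled = ScoredRanking(ids=[str(i) for i in range(2 * n)],
                                scores=np.arange(2 * n, 0, -1, dtype=float),
                                is_hit=np.repeat(is_hit, 2))
        assert bedroc(doubled, 20) == pytest.approx(bedroc(base, 20), abs=5e-2)


@pytest.fixture(scope="module")
def split_dataset():
    ds = generate_polyspecific(PolyspecificGeneratorConfig(n_compounds=130, seed=21))
    nonsub = [r.id for r in ds.records if r.label == -1][:27]
    sub = [r.id for r in ds.records if r.label == 1][:71]
    chosen = set(nonsub + sub)
    for r in ds.records:
        r.set = "test" if r.id in chosen else "train"
    return ds


class TestScreeningCampaign:

    def test_paper_shaped_library_metrics(self, split_dataset):
        records, matrix = screening_library(split_dataset, n_decoys=479, seed=3)
        score_fn = lambda m: m.values.iloc[:, 0].to_numpy()  # arbitrary scorer
        report, ranking = run_screening_campaign(score_fn, records, matrix)
        assert report.n_library == 577
        assert report.n_hits == 27
        assert report.r_a == pytest.approx(27 / 577)
        assert not report.saturated
        # identity between AUCc-derived and directly computed ROC AUC
        assert report.roc_auc == pytest.approx(empirical_roc(ranking).auc, abs=1e-10)

    def test_test_set_only_triggers_saturation(self, split_dataset):
        records, matrix = screening_library(split_dataset, n_decoys=0, seed=3)
        report, _ = run_screening_campaign(
            lambda m: m.values.iloc[:, 0].to_numpy(), records, matrix)
        assert report.n_library == 98 and report.n_hits == 27
        assert report.r_a == pytest.approx(27 / 98)
        assert report.saturated

    def test_reversed_scores_drop_bedroc(self, split_dataset):
        records, matrix = screening_library(split_dataset, n_decoys=100, seed=3)
        # a scorer correlated with the truth: negative site score
        fwd = lambda m: -(split_dataset.site1.scores(m))
        rev = lambda m: split_dataset.site1.scores(m)
        rep_f, _ = run_screening_campaign(fwd, records, matrix)
        rep_r, _ = run_screening_campaign(rev, records, matrix)
        if rep_f.bedroc > 0.3:  # only meaningful when forward beats random
            assert rep_r.bedroc < rep_f.bedroc

    def test_library_without_known_nonsubstrates_rejected(self, split_dataset):
        records, matrix = screening_library(split_dataset, n_decoys=10, seed=3)
        only_subs = [r for r in records if r.label == 1]
        with pytest.raises(ValueError, match="nonsubstrates"):
            run_screening_campaign(
                lambda m: m.values.iloc[:, 0].to_numpy(), only_subs, matrix)

    def test_report_states_conventions(self, split_dataset):
        records, matrix = screening_library(split_dataset, n_decoys=50, seed=3)
        report, _ = run_screening_campaign(
            lambda m: m.values.iloc[:, 0].to_numpy(), records, matrix)
        text = report.text_table()
        assert "alpha" in text and "nonsubstrate_is_hit" in text
        d = report.as_dict()
        assert d["alpha"] == 20.0 and d["EF_n_selected"] == report.ef_n_selected
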