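import numpy as np
import pandas as pd
import pytest
from scipy import stats

from strainflow.data_model import AlleleBackground, SampleTable, ScoreResult
from strainflow.filtering import select_informative_snvs
from strainflow.transmission_scoring import (
    TaxonPairScores,
    allele_incidence,
    background_distribution,
    bh_adjust,
    classify_taxa,
    pair_likelihood,
    pair_likelihood_matrix,
    score_taxon,
    score_taxon_pairs,
    transmission_score,
)
from strainflow.synthetic_cohort import SimulationConfig, SpeciesSpec, simulate_cohort

from conftest import make_profile, random_profile, samples_for_profile
from reference_impl import naive_clamped_incidence, naive_pair_likelihood


def _uniform_background(n_alleles, f=0.5, taxon="t1"):
    arr = np.full(n_alleles, float(f))
    return AlleleBackground(taxon, [f"{taxon}:{i + 1}:A>C" for i in range(n_alleles)],
                            arr.copy(), arr.copy(),
                            np.full(n_alleles, 100), np.full(n_alleles, 100))


# --- allele incidence ------------------------------------------------------


def test_incidence_is_present_over_covered():
    # allele covered in 10 oral samples, present in 3 of them
    profile = make_profile(
        np.array([[1, 1, 1, 0, 0, 0, 0, 0, 0, 0] + [1, 0, 0, 0, 0, 0, 0, 0, 0, 0]]),
        [f"S{i + 1:02d}_oral_t0" for i in range(10)]
        + [f"S{i + 1:02d}_gut_t0" for i in range(10)],
    )
    bg = allele_incidence(profile, samples_for_profile(10, 10))
    assert bg.f_oral[0] == pytest.approx(0.3)
    assert bg.f_gut[0] == pytest.approx(0.1)


def test_symmetric_half_frequencies_give_quarter_probabilities():
    bg = _uniform_background(1, f=0.5)
    for p in (bg.p_11, bg.p_00, bg.p_10, bg.p_01):
        assert p[0] == pytest.approx(0.25)


def test_saturated_frequency_clamped_to_half_count():
    # present in all 10 covered gut samples -> clamped to 1 - 1/(2*10)
    profile = make_profile(
        np.array([[1, 0, 0, 0, 0, 0, 0, 0, 0, 0] + [1] * 10]),
        [f"S{i + 1:02d}_oral_t0" for i in range(10)]
        + [f"S{i + 1:02d}_gut_t0" for i in range(10)],
    )
    bg = allele_incidence(profile, samples_for_profile(10, 10))
    assert bg.f_gut[0] == pytest.approx(0.95)


def test_probabilities_partition_to_one(small_cohort):
    _, (samples, profiles, _, _) = small_cohort
    profile = select_informative_snvs(profiles[0], samples)
    bg = allele_incidence(profile, samples)
    total = bg.p_11 + bg.p_00 + bg.p_10 + bg.p_01
    np.testing.assert_allclose(total, 1.0, atol=1e-12)
    ref_o = naive_clamped_incidence(
        profile.matrix,
        [profile.column_index(s) for s in profile.sample_ids
         if samples.site_of(s) == "oral"])
    np.testing.assert_allclose(bg.f_oral, ref_o, atol=1e-12)


def test_uncovered_allele_raises():
    profile = make_profile(np.array([[-1, -1, 1, 1]]),
                           ["S01_oral_t0", "S02_oral_t0",
                            "S01_gut_t0", "S02_gut_t0"])
    with pytest.raises(ValueError, match="zero covered"):
        allele_incidence(profile, samples_for_profile(2, 2))


# --- pair likelihoods ------------------------------------------------------


@pytest.mark.parametrize("oral,gut,expected_praw", [
    (1, 1, 1.0),    # agreement in the least likely configuration
    (1, 0, -1.0),   # pure disagreement mirrors it
])
def test_single_allele_hand_cases(oral, gut, expected_praw):
    profile = make_profile(np.array([[oral, gut]]), ["o1", "g1"])
    bg = _uniform_background(1)
    ps = pair_likelihood("o1", "g1", profile, bg, min_shared=1)
    assert ps.L_min == pytest.approx(np.log(0.25))
    assert ps.P_raw == pytest.approx(expected_praw)


def test_agreement_and_disagreement_cancel_to_zero():
    profile = make_profile(np.array([[1, 1], [1, 0]]), ["o1", "g1"])
    bg = _uniform_background(2)
    ps = pair_likelihood("o1", "g1", profile, bg, min_shared=1)
    assert ps.L_obs == pytest.approx(0.0)
    assert ps.P_raw == pytest.approx(0.0)


def test_pair_below_shared_threshold_rejected():
    profile = make_profile(np.array([[1, 1]] * 5), ["o1", "g1"])
    with pytest.raises(ValueError, match="19|5"):
        pair_likelihood("o1", "g1", profile, _uniform_background(5), min_shared=20)


def test_likelihood_matches_naive_loop_and_matrix_path():
    rng = np.random.default_rng(7)
    samples = samples_for_profile()
    for _ in range(50):
        profile = select_informative_snvs(
            random_profile(rng, n_alleles=40), samples,
            min_cov_oral=3, min_cov_gut=3)
        if profile.n_alleles < 2:
            continue
        bg = allele_incidence(profile, samples)
        oral = [s for s in profile.sample_ids if samples.site_of(s) == "oral"]
        gut = [s for s in profile.sample_ids if samples.site_of(s) == "gut"]
        P, n_shared = pair_likelihood_matrix(profile, bg, oral, gut, min_shared=1)
        for i, o in enumerate(oral):
            for j, g in enumerate(gut):
                ref = naive_pair_likelihood(
                    profile.column(o), profile.column(g), bg.f_oral, bg.f_gut)
                single = pair_likelihood(o, g, profile, bg, min_shared=1)
                assert abs(single.L_obs - ref[0]) < 1e-10
                assert abs(single.P_raw - ref[2]) < 1e-10
                assert abs(P[i, j] - ref[2]) < 1e-10


def test_praw_bounded_by_one_on_random_profiles():
    rng = np.random.default_rng(21)
    samples = samples_for_profile()
    for _ in range(30):
        profile = select_informative_snvs(
            random_profile(rng, n_alleles=50), samples,
            min_cov_oral=3, min_cov_gut=3)
        if profile.n_alleles < 1:
            continue
        bg = allele_incidence(profile, samples)
        oral = [s for s in profile.sample_ids if samples.site_of(s) == "oral"]
        gut = [s for s in profile.sample_ids if samples.site_of(s) == "gut"]
        P, _ = pair_likelihood_matrix(profile, bg, oral, gut, min_shared=1)
        assert np.nanmax(P) <= 1.0 + 1e-12


def test_score_invariant_to_allele_and_sample_order():
    rng = np.random.default_rng(5)
    samples = samples_for_profile()
    profile = select_informative_snvs(random_profile(rng, n_alleles=40),
                                      samples, min_cov_oral=3, min_cov_gut=3)
    bg = allele_incidence(profile, samples)
    ps = pair_likelihood("S01_oral_t0", "S01_gut_t0", profile, bg, min_shared=1)

    perm = rng.permutation(profile.n_alleles)
    shuffled = profile.subset_alleles(perm)
    bg2 = allele_incidence(shuffled, samples)
    ps2 = pair_likelihood("S01_oral_t0", "S01_gut_t0", shuffled, bg2, min_shared=1)
    assert ps2.P_raw == pytest.approx(ps.P_raw, abs=1e-12)

    cols = list(profile.sample_ids)
    rng.shuffle(cols)
    recol = profile.subset_samples(cols)
    bg3 = allele_incidence(recol, samples)
    ps3 = pair_likelihood("S01_oral_t0", "S01_gut_t0", recol, bg3, min_shared=1)
    assert ps3.P_raw == pytest.approx(ps.P_raw, abs=1e-12)


# --- backgrounds -----------------------------------------------------------


def _pair_scores_fixture():
    """3x3 P_raw grid over three subjects; finite inter-individual values
    are exactly {0.1, 0.2, 0.3}."""
    samples = samples_for_profile(3, 3)
    P = np.array([
        [np.nan, 0.1, 0.2],
        [np.nan, np.nan, 0.3],
        [np.nan, np.nan, np.nan],
    ])
    return TaxonPairScores(
        "t1",
        ["S01_oral_t0", "S02_oral_t0", "S03_oral_t0"],
        ["S01_gut_t0", "S02_gut_t0", "S03_gut_t0"],
        P, np.full((3, 3), 100), samples,
    )


def test_background_mean_and_sd_use_n_minus_one():
    pairs = _pair_scores_fixture()
    mu, sigma, values = background_distribution(
        pairs, "S01", mode="global", min_background_pairs=3)
    assert sorted(values.tolist()) == [0.1, 0.2, 0.3]
    assert mu == pytest.approx(0.2)
    assert sigma == pytest.approx(0.1)


def test_too_few_background_pairs_flags_unavailable():
    pairs = _pair_scores_fixture()
    mu, sigma, values = background_distribution(
        pairs, "S01", mode="global", min_background_pairs=10)
    assert np.isnan(mu) and np.isnan(sigma)


def test_cohort_background_never_mixes_cohorts():
    cfg = SimulationConfig(
        species=[SpeciesSpec("sp001", "none", 80)],
        n_subjects=12, n_cohorts=2, dropout=0.0, seed=2)
    samples, (profile,), _, _ = simulate_cohort(cfg)
    fp = select_informative_snvs(profile, samples)
    pairs = score_taxon_pairs(fp, samples)
    from strainflow.transmission_scoring import _background_mask
    for subj in samples.subject_ids:
        cohort = samples.frame.loc[
            samples.frame.subject_id == subj, "cohort"].iloc[0]
        mask = _background_mask(pairs, subj, "cohort")
        for i, j in np.argwhere(mask):
            assert samples.cohort_of(pairs.oral_samples[i]) == cohort
            assert samples.cohort_of(pairs.gut_samples[j]) == cohort


def test_same_subject_pairs_excluded_across_timepoints():
    cfg = SimulationConfig(
        species=[SpeciesSpec("sp001", "none", 80)],
        n_subjects=8, n_cohorts=1, n_timepoints=2, dropout=0.0, seed=2)
    samples, (profile,), _, _ = simulate_cohort(cfg)
    fp = select_informative_snvs(profile, samples)
    pairs = score_taxon_pairs(fp, samples)
    from strainflow.transmission_scoring import _background_mask
    for subj in samples.subject_ids:
        mask = _background_mask(pairs, subj, "global")
        for i, j in np.argwhere(mask):
            assert (samples.subject_of(pairs.oral_samples[i])
                    != samples.subject_of(pairs.gut_samples[j]))


def test_family_members_excluded_from_background():
    cfg = SimulationConfig(
        species=[SpeciesSpec("sp001", "none", 80)],
        n_subjects=10, n_cohorts=1, dropout=0.0, seed=2,
        family_fraction=0.8, family_sharing=0.5)
    samples, (profile,), _, _ = simulate_cohort(cfg)
    assert samples.frame.family_id.notna().sum() > 0
    fp = select_informative_snvs(profile, samples)
    pairs = score_taxon_pairs(fp, samples)
    from strainflow.transmission_scoring import _background_mask
    mask = _background_mask(pairs, "S0001", "global")
    for i, j in np.argwhere(mask):
        fo = samples.family_of(pairs.oral_samples[i])
        fg = samples.family_of(pairs.gut_samples[j])
        assert fo is None or fg is None or fo != fg


def test_transmission_score_is_standardization():
    assert transmission_score(0.8, 0.2, 0.3) == pytest.approx(2.0)
    assert transmission_score(0.2, 0.2, 0.3) == 0.0


def test_frequent_transmitters_score_above_zero():
    cfg = SimulationConfig(
        species=[SpeciesSpec("sp001", "frequent", 200, tau=0.8)],
        n_subjects=50, n_cohorts=1, dropout=0.1, seed=17)
    samples, (profile,), _, _ = simulate_cohort(cfg)
    fp = select_informative_snvs(profile, samples)
    results = score_taxon(fp, samples, mode="cohort")
    st = np.array([r.S_T for r in results if r.available])
    assert len(st) >= 40
    assert st.mean() > 0
    assert stats.wilcoxon(st, alternative="greater").pvalue < 0.05


# --- classification --------------------------------------------------------


def _fake_scores(taxon, values):
    return [
        ScoreResult(taxon, f"S{i:03d}", np.nan, 0.0, 1.0, v, "cohort", 100)
        for i, v in enumerate(values)
    ]


def test_uniformly_high_scores_classify_frequent():
    rng = np.random.default_rng(0)
    scores = _fake_scores("tA", 3.0 + rng.normal(0, 0.1, 20))
    for k in range(19):  # other taxa at null, to give BH a family
        scores += _fake_scores(f"t{k:02d}", rng.normal(0, 1, 20))
    cls = {c.taxon_id: c for c in classify_taxa(scores)}
    assert cls["tA"].status == "frequent"


def test_single_extreme_subject_classifies_occasional():
    rng = np.random.default_rng(1)
    values = rng.normal(0, 0.3, 20)
    values[7] = 6.0
    scores = _fake_scores("tA", values)
    for k in range(19):
        scores += _fake_scores(f"t{k:02d}", rng.normal(0, 0.3, 20))
    cls = {c.taxon_id: c for c in classify_taxa(scores)}
    assert cls["tA"].status == "occasional"
    assert min(cls["tA"].z_p_adj.values()) < 0.05


def test_null_scores_classify_none_at_controlled_rate():
    rng = np.random.default_rng(2)
    n_false = 0
    n_taxa = 20
    for rep in range(10):
        scores = []
        for k in range(n_taxa):
            scores += _fake_scores(f"t{k:02d}", rng.normal(0, 1, 30))
        cls = classify_taxa(scores)
        n_false += sum(1 for c in cls if c.status == "frequent")
    assert n_false / (10 * n_taxa) <= 0.05


def test_too_few_subjects_only_occasional_branch():
    scores = _fake_scores("tA", [6.0, 5.5, 6.2])  # 3 subjects < min_subjects
    cls = {c.taxon_id: c for c in classify_taxa(scores)}
    assert np.isnan(cls["tA"].wilcoxon_p_adj)
    assert cls["tA"].status == "occasional"


def test_bh_adjustment_matches_reference_and_is_monotone():
    from reference_impl import naive_bh
    rng = np.random.default_rng(3)
    p = rng.random(50)
    adj = bh_adjust(p)
    np.testing.assert_allclose(adj, naive_bh(p), atol=1e-12)
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()


from hypothesis import given, settings, strategies as st


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
def test_bh_adjustment_properties(p_values):
    """Adjusted p-values are valid probabilities, bound raw values from
    above, and preserve the raw ordering."""
    p = np.array(p_values)
    adj = bh_adjust(p)
    assert ((adj >= p - 1e-12) & (adj <= 1.0 + 1e-12)).all()
    order = np.argsort(p, kind="stable")
    assert (np.diff(adj[order]) >= -1e-12).all()
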