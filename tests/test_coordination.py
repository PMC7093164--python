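import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genecoord.coordination import (
    CorrelationMatrix,
    CorrelationProfile,
    PcRecord,
    coherence_summary,
    composite_correlation,
    extract_correlated_set,
    filter_high_expression,
    pairwise_correlation,
    pearson_r,
    rank_by_pc,
    transcriptome_profiles,
)
from genecoord.io import AnalysisConfig
from genecoord.simulate import SimulationConfig, combine_groups, simulate_dataset

from conftest import make_design, make_matrix


def brute_force_pearson(x, y):
    """Independent oracle: literal product-moment formula in pure Python."""
    n = len(x)
    xb = sum(x) / n
    yb = sum(y) / n
    num = sum((xi - xb) * (yi - yb) for xi, yi in zip(x, y))
    den = math.sqrt(sum((xi - xb) ** 2 for xi in x)
                    * sum((yi - yb) ** 2 for yi in y))
    return num / den


# ---------------------------------------------------------------------------
# pearson_r
# ---------------------------------------------------------------------------


def test_pearson_identity():
    assert pearson_r([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0, abs=1e-12)


def test_pearson_anticorrelation():
    assert pearson_r([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0, abs=1e-12)


def test_pearson_matches_brute_force_example():
    x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 6]
    assert pearson_r(x, y) == pytest.approx(brute_force_pearson(x, y), abs=1e-12)


def test_pearson_constant_vector_undefined():
    assert pearson_r([1, 1, 1, 1], [1, 2, 3, 4]) is None


def test_pearson_length_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        pearson_r([1, 2, 3], [1, 2, 3, 4])


def test_pearson_too_short():
    with pytest.raises(ValueError, match=">= 3"):
        pearson_r([1, 2], [3, 4])


@settings(max_examples=200, deadline=None)
@given(st.lists(st.floats(-100, 100), min_size=3, max_size=12),
       st.integers(0, 2**32 - 1))
def test_pearson_agrees_with_oracle(x, seed):
    rng = np.random.default_rng(seed)
    y = rng.normal(size=len(x)).tolist()
    r = pearson_r(x, y)
    if r is None:
        # numerically constant: the centered sum of squares underflows to 0
        xb = sum(x) / len(x)
        yb = sum(y) / len(y)
        assert math.sqrt(sum((xi - xb) ** 2 for xi in x)) == 0.0 or \
            math.sqrt(sum((yi - yb) ** 2 for yi in y)) == 0.0
    else:
        assert r == pytest.approx(brute_force_pearson(x, y), abs=1e-9)
        assert -1.0 <= r <= 1.0


# ---------------------------------------------------------------------------
# filter_high_expression
# ---------------------------------------------------------------------------


def test_filter_inclusive_boundary():
    # NOR means 100, 70, 69.9 at min_reads=70: "at least 70" keeps the first two
    m = make_matrix([[100, 100, 100, 0, 0, 0],
                     [70, 70, 70, 0, 0, 0],
                     [69.9, 69.9, 69.9, 0, 0, 0]])
    design = make_design(3, 3)
    cfg = AnalysisConfig(min_reads=70)
    assert filter_high_expression(m, design, cfg) == ["G1", "G2"]


def test_filter_zero_threshold_keeps_all():
    m = make_matrix(np.zeros((4, 6)))
    design = make_design(3, 3)
    assert filter_high_expression(m, design, AnalysisConfig(min_reads=0)) == \
        ["G1", "G2", "G3", "G4"]


def test_filter_percentile_threshold_matches_independent_count():
    rng = np.random.default_rng(42)
    values = rng.uniform(0.0, 500.0, (500, 16))
    m = make_matrix(values)
    design = make_design(8, 8)
    # independent oracle: recompute reference means directly from the array
    nor_means = values[:, :8].mean(axis=1)
    threshold = float(np.percentile(nor_means, 90.0))
    expected = int((nor_means >= threshold).sum())
    selected = filter_high_expression(m, design,
                                      AnalysisConfig(min_reads=threshold))
    assert len(selected) == expected == 50


@pytest.mark.parametrize("aggregation,expected", [
    ("mean", ["G1", "G2"]),
    ("min", ["G1"]),
    ("sum", ["G1", "G2", "G3"]),
])
def test_filter_aggregation_modes(aggregation, expected):
    m = make_matrix([[50, 50, 50, 0, 0, 0],
                     [90, 30, 30, 0, 0, 0],
                     [20, 20, 20, 0, 0, 0]])
    design = make_design(3, 3)
    cfg = AnalysisConfig(min_reads=50, read_aggregation=aggregation)
    assert filter_high_expression(m, design, cfg) == expected


def test_filter_none_pass_warns(caplog):
    m = make_matrix(np.ones((3, 6)))
    design = make_design(3, 3)
    with caplog.at_level(logging.WARNING):
        out = filter_high_expression(m, design, AnalysisConfig(min_reads=1e6))
    assert out == []
    assert any("no gene" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# pairwise_correlation / coherence_summary
# ---------------------------------------------------------------------------


def test_pairwise_identical_rows_give_unit_correlation(config):
    m = make_matrix([[1, 2, 3, 9, 9, 9], [1, 2, 3, 9, 9, 9]])
    design = make_design(3, 3)
    cm = pairwise_correlation(m, ["G1", "G2"], design, "NOR", config)
    assert cm.values[0, 1] == pytest.approx(1.0, abs=1e-12)


def test_pairwise_symmetry_and_unit_diagonal(config):
    rng = np.random.default_rng(1)
    m = make_matrix(rng.gamma(2, 10, (12, 10)))
    design = make_design(5, 5)
    cm = pairwise_correlation(m, m.gene_ids, design, "FRA", config)
    np.testing.assert_allclose(cm.values, cm.values.T, atol=1e-12)
    np.testing.assert_allclose(np.diag(cm.values), 1.0, atol=0)
    assert np.nanmax(np.abs(cm.values)) <= 1.0


def test_pairwise_unknown_gene(config):
    m = make_matrix(np.ones((2, 6)))
    design = make_design(3, 3)
    with pytest.raises(KeyError, match="G9"):
        pairwise_correlation(m, ["G1", "G9"], design, "NOR", config)


def test_pairwise_zero_variance_flagged(config):
    m = make_matrix([[5, 5, 5, 1, 2, 3], [1, 2, 3, 1, 2, 3]])
    design = make_design(3, 3)
    cm = pairwise_correlation(m, ["G1", "G2"], design, "NOR", config)
    assert not cm.defined[0, 0] and not cm.defined[0, 1]
    assert cm.defined[1, 1]


def test_pairwise_matches_copula_monte_carlo_oracle(config):
    """Mean off-diagonal R of a one-module fixture vs a 1e5-sample MC oracle."""
    from scipy.stats import nbinom, norm

    rho, disp, log_mu = 0.8, 0.2, 5.0
    cfg = SimulationConfig(
        n_genes=10, n_samples_ref=50, n_samples_cond=3, n_modules=1,
        module_size=10, latent_rho=rho, coherence_amplification=1.0,
        n_seed_genes=10, n_rewired=0, nb_dispersion=disp,
        mean_log_range=(log_mu, log_mu + 1e-9), rng_seed=7,
    )
    matrix_ref, _, truth = simulate_dataset(cfg)
    design = make_design(50, 3)
    # pad 3 dummy condition samples so the design is valid
    padded = make_matrix(
        np.hstack([matrix_ref.values, matrix_ref.values[:, :3]]),
        gene_ids=matrix_ref.gene_ids,
    )
    cm = pairwise_correlation(padded, padded.gene_ids, design, "NOR", config)
    observed = cm.offdiagonal().mean()

    # independent oracle: two-gene copula simulated at n = 1e5
    rng = np.random.default_rng(123)
    n = 100_000
    f = rng.standard_normal(n)
    z1 = np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.standard_normal(n)
    z2 = np.sqrt(rho) * f + np.sqrt(1 - rho) * rng.standard_normal(n)
    r_nb = 1.0 / disp
    p_nb = r_nb / (r_nb + np.exp(log_mu))
    c1 = nbinom.ppf(norm.cdf(z1), r_nb, p_nb)
    c2 = nbinom.ppf(norm.cdf(z2), r_nb, p_nb)
    implied = np.corrcoef(c1, c2)[0, 1]
    assert observed == pytest.approx(implied, abs=0.1)


def test_coherence_summary_single_pair():
    values = np.array([[1.0, 0.6], [0.6, 1.0]])
    s = coherence_summary(CorrelationMatrix(["G1", "G2"], values, "NOR"))
    assert s.mean_r == pytest.approx(0.6)
    assert s.fraction_above(0.5) == 1.0


def test_coherence_summary_signed_vs_absolute():
    values = np.eye(3)
    values[0, 1] = values[1, 0] = 0.2
    values[0, 2] = values[2, 0] = -0.2
    values[1, 2] = values[2, 1] = np.nan
    s = coherence_summary(CorrelationMatrix(["G1", "G2", "G3"], values, "NOR"))
    assert s.mean_r == pytest.approx(0.0, abs=1e-15)
    assert s.mean_abs_r == pytest.approx(0.2)


def test_coherence_summary_all_undefined_is_error():
    values = np.full((2, 2), np.nan)
    with pytest.raises(ValueError, match="no defined"):
        coherence_summary(CorrelationMatrix(["G1", "G2"], values, "NOR"))


def test_coherence_amplification_raises_mean_abs_r(config):
    """Condition-group mean |R| exceeds reference in every seeded replicate."""
    for seed in range(20):
        cfg = SimulationConfig(
            n_genes=178, n_samples_ref=100, n_samples_cond=100, n_modules=4,
            module_size=40, latent_rho=0.7, coherence_amplification=1.15,
            n_seed_genes=100, n_rewired=0, rng_seed=seed,
        )
        matrix_ref, matrix_cond, truth = simulate_dataset(cfg)
        combined, design = combine_groups(matrix_ref, matrix_cond)
        ref = coherence_summary(pairwise_correlation(
            combined, truth.seed_genes, design, "NOR", config))
        cond = coherence_summary(pairwise_correlation(
            combined, truth.seed_genes, design, "FRA", config))
        assert cond.mean_abs_r > ref.mean_abs_r, f"replicate {seed}"


# ---------------------------------------------------------------------------
# transcriptome_profiles
# ---------------------------------------------------------------------------


def test_profiles_exclude_seed_itself(config):
    rng = np.random.default_rng(2)
    m = make_matrix(rng.gamma(2, 10, (5, 8)))
    design = make_design(4, 4)
    pairs = transcriptome_profiles(m, ["G1"], design, config)
    assert pairs["G1"].ref.background_gene_ids == ["G2", "G3", "G4", "G5"]
    assert pairs["G1"].ref.background_gene_ids == \
        pairs["G1"].cond.background_gene_ids


def test_profiles_shared_background_drops_constant_in_either_group(config):
    rng = np.random.default_rng(3)
    values = rng.gamma(2, 10, (5, 8))
    values[2, 4:] = 7.0  # constant in the condition group only
    m = make_matrix(values)
    design = make_design(4, 4)
    pairs = transcriptome_profiles(m, ["G1"], design, config)
    assert "G3" not in pairs["G1"].ref.background_gene_ids
    assert "G3" not in pairs["G1"].cond.background_gene_ids


def test_profiles_duplicate_seed_warns(config, caplog):
    rng = np.random.default_rng(4)
    m = make_matrix(rng.gamma(2, 10, (5, 8)))
    design = make_design(4, 4)
    with caplog.at_level(logging.WARNING):
        pairs = transcriptome_profiles(m, ["G1", "G1"], design, config)
    assert list(pairs) == ["G1"]
    assert any("duplicate seed" in r.message for r in caplog.records)


def test_profiles_r_matches_pearson_r(config):
    rng = np.random.default_rng(5)
    m = make_matrix(rng.gamma(2, 10, (6, 10)))
    design = make_design(5, 5)
    pairs = transcriptome_profiles(m, ["G2"], design, config)
    prof = pairs["G2"].ref
    for gene, r in zip(prof.background_gene_ids, prof.r_values):
        i = m.gene_ids.index(gene)
        expected = pearson_r(m.values[1, :5], m.values[i, :5])
        assert r == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# composite_correlation
# ---------------------------------------------------------------------------


def _profile(seed, group, r_values, bg=None):
    r_values = np.asarray(r_values, dtype=float)
    bg = bg or [f"B{i}" for i in range(len(r_values))]
    return CorrelationProfile(seed, group, bg, r_values)


def test_pc_identity(config):
    r = [0.1, -0.5, 0.9, 0.3]
    rec = composite_correlation(_profile("G1", "NOR", r),
                                _profile("G1", "FRA", r), config)
    assert rec.pc == pytest.approx(1.0, abs=1e-12)
    assert rec.n_common_background == 4


def test_pc_negation(config):
    r = np.array([0.1, -0.5, 0.9, 0.3])
    rec = composite_correlation(_profile("G1", "NOR", r),
                                _profile("G1", "FRA", -r), config)
    assert rec.pc == pytest.approx(-1.0, abs=1e-12)


def test_pc_mismatched_seeds(config):
    with pytest.raises(ValueError, match="mismatched seeds"):
        composite_correlation(_profile("G1", "NOR", [0.1, 0.2, 0.3]),
                              _profile("G2", "FRA", [0.1, 0.2, 0.3]), config)


def test_pc_symmetric_in_arguments(config):
    rng = np.random.default_rng(6)
    a = _profile("G1", "NOR", rng.uniform(-1, 1, 30))
    b = _profile("G1", "FRA", rng.uniform(-1, 1, 30))
    assert composite_correlation(a, b, config).pc == pytest.approx(
        composite_correlation(b, a, config).pc, abs=1e-12)


def test_pc_undefined_small_overlap(config):
    a = _profile("G1", "NOR", [0.1, np.nan, np.nan, 0.2])
    b = _profile("G1", "FRA", [0.3, np.nan, np.nan, 0.4])
    rec = composite_correlation(a, b, config)
    assert rec.pc is None
    assert rec.n_common_background == 2


def test_pc_spearman_option():
    cfg = AnalysisConfig(pc_method="spearman")
    # monotone but nonlinear relation: Spearman = 1
    a = _profile("G1", "NOR", [0.0, 0.1, 0.2, 0.3, 0.4])
    b = _profile("G1", "FRA", [0.0, 0.01, 0.5, 0.6, 0.9])
    assert composite_correlation(a, b, cfg).pc == pytest.approx(1.0, abs=1e-12)


def test_pc_condition_copy_of_reference_gives_unit_pc(config):
    rng = np.random.default_rng(7)
    ref = rng.gamma(2, 20, (30, 8))
    m = make_matrix(np.hstack([ref, ref]))
    design = make_design(8, 8)
    pairs = transcriptome_profiles(m, m.gene_ids[:10], design, config)
    for seed, pair in pairs.items():
        rec = composite_correlation(pair.ref, pair.cond, config)
        assert rec.pc == pytest.approx(1.0, abs=1e-12), seed


def test_sample_permutation_within_group_is_invariant(config, small_sim):
    cfg, combined, design, truth = small_sim
    rng = np.random.default_rng(8)
    perm_ref = rng.permutation(cfg.n_samples_ref)
    order = list(perm_ref) + list(range(cfg.n_samples_ref, combined.n_samples))
    shuffled = make_matrix(combined.values[:, order],
                           gene_ids=combined.gene_ids,
                           sample_ids=[combined.sample_ids[j] for j in order])
    seeds = truth.seed_genes[:5]
    for matrix in (combined, shuffled):
        pairs = transcriptome_profiles(matrix, seeds, design, config)
        pcs = {s: composite_correlation(p.ref, p.cond, config).pc
               for s, p in pairs.items()}
        if matrix is combined:
            baseline = pcs
    assert pcs == pytest.approx(baseline, abs=1e-12)


# ---------------------------------------------------------------------------
# rank_by_pc / extract_correlated_set
# ---------------------------------------------------------------------------


def test_rank_bottom_selection():
    records = [PcRecord("GA", 0.3, 9), PcRecord("GB", -0.1, 9),
               PcRecord("GC", 0.5, 9)]
    ranking = rank_by_pc(records, AnalysisConfig(bottom_k=1, top_k=1))
    assert [r.seed_gene for r in ranking.bottom] == ["GB"]
    assert [r.seed_gene for r in ranking.top] == ["GC"]


def test_rank_tie_break_lexicographic():
    records = [PcRecord("GB", 0.2, 9), PcRecord("GA", 0.2, 9)]
    ranking = rank_by_pc(records, AnalysisConfig(bottom_k=1, top_k=1))
    assert [r.seed_gene for r in ranking.records] == ["GA", "GB"]


def test_rank_undefined_last_and_never_selected():
    records = [PcRecord("GA", None, 1), PcRecord("GB", 0.9, 9),
               PcRecord("GC", 0.1, 9)]
    ranking = rank_by_pc(records, AnalysisConfig(bottom_k=2, top_k=2))
    assert ranking.records[-1].seed_gene == "GA"
    assert all(r.defined for r in ranking.bottom + ranking.top)


def test_rank_all_undefined_is_error():
    with pytest.raises(ValueError, match="undefined"):
        rank_by_pc([PcRecord("GA", None, 0)], AnalysisConfig())


def test_rank_recovers_planted_rewiring():
    """All 10 rewired seeds fall in the bottom 20 ranks at generator defaults."""
    cfg = SimulationConfig(rng_seed=11)  # defaults: 2000 genes, 50+50, 10 rewired
    matrix_ref, matrix_cond, truth = simulate_dataset(cfg)
    combined, design = combine_groups(matrix_ref, matrix_cond)
    config = AnalysisConfig()
    pairs = transcriptome_profiles(combined, truth.seed_genes, design, config)
    records = [composite_correlation(p.ref, p.cond, config)
               for p in pairs.values()]
    ranking = rank_by_pc(records, config)
    bottom20 = {r.seed_gene for r in ranking.records[:20]}
    assert truth.rewired <= bottom20


def test_extract_strict_cutoff():
    prof = _profile("G1", "NOR", [0.6, 0.5, 0.51, -0.9])
    gs = extract_correlated_set(prof, AnalysisConfig(r_cutoff=0.5))
    assert gs.gene_ids == ["B0", "B2"]  # 0.5 itself is excluded (strict >)


def test_extract_high_cutoff_empty():
    prof = _profile("G1", "NOR", [0.6, 0.5, 0.51, -0.9])
    gs = extract_correlated_set(prof, AnalysisConfig(r_cutoff=0.99))
    assert len(gs) == 0


def test_extract_skips_undefined():
    prof = _profile("G1", "NOR", [0.9, np.nan, 0.8])
    gs = extract_correlated_set(prof, AnalysisConfig())
    assert gs.gene_ids == ["B0", "B2"]


def test_unrewired_sets_overlap_more_than_rewired(config):
    """NOR/FRA correlated-set Jaccard: unrewired seeds beat rewired, 20 reps."""
    rew, unrew = [], []
    for seed in range(20):
        cfg = SimulationConfig(
            n_genes=300, n_samples_ref=25, n_samples_cond=25, n_modules=4,
            module_size=40, n_seed_genes=20, n_rewired=4, rng_seed=seed,
        )
        matrix_ref, matrix_cond, truth = simulate_dataset(cfg)
        combined, design = combine_groups(matrix_ref, matrix_cond)
        pairs = transcriptome_profiles(combined, truth.seed_genes, design,
                                       config)
        for gene, pair in pairs.items():
            a = extract_correlated_set(pair.ref, config).as_set()
            b = extract_correlated_set(pair.cond, config).as_set()
            if a or b:
                j = len(a & b) / len(a | b)
                (rew if gene in truth.rewired else unrew).append(j)
    assert np.mean(unrew) > np.mean(rew)
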