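"""Clumping, region exclusion, weighted scoring, threshold series."""

import numpy as np
import pandas as pd
import pytest

from tauprs.prs import (
    APOE_REGION,
    DEFAULT_THRESHOLDS,
    GenomicRegion,
    clump,
    exclude_region,
    score,
    threshold_series,
)
from tauprs.synthetic import CausalConfig, simulate_genotypes, simulate_summary_stats

from conftest import make_panel


def stats_for(panel, p_values, betas=None):
    v = panel.variants
    return pd.DataFrame(
        {
            "SNP": v["id"],
            "CHR": v["chrom"],
            "BP": v["pos"],
            "A1": v["a1"],
            "A2": v["a2"],
            "BETA": betas if betas is not None else np.ones(len(v)),
            "SE": np.ones(len(v)),
            "P": p_values,
        }
    )


# --------------------------------------------------------------------- clump


def test_clump_keeps_most_significant_of_correlated_pair():
    base = np.array([0, 1, 2, 1, 0, 2, 1, 1], dtype=float)
    panel = make_panel(
        np.column_stack([base, base]), positions=[1_000_000, 1_010_000]
    )
    stats = stats_for(panel, [1e-8, 1e-4])
    assert clump(stats, panel) == ["v0"]
    stats2 = stats_for(panel, [1e-4, 1e-8])
    assert clump(stats2, panel) == ["v1"]


def test_clump_different_chromosomes_all_retained():
    base = np.array([0, 1, 2, 1, 0, 2], dtype=float)
    panel = make_panel(
        np.column_stack([base, base, base]),
        chrom=["1", "2", "3"],
        positions=[100, 100, 100],
    )
    stats = stats_for(panel, [1e-8, 1e-6, 1e-4])
    assert sorted(clump(stats, panel)) == ["v0", "v1", "v2"]


def test_clump_outside_window_retained():
    base = np.array([0, 1, 2, 1, 0, 2], dtype=float)
    panel = make_panel(
        np.column_stack([base, base]), positions=[1_000_000, 2_000_001]
    )
    stats = stats_for(panel, [1e-8, 1e-4])
    assert sorted(clump(stats, panel)) == ["v0", "v1"]


def test_clump_empty_stats():
    panel = make_panel(np.array([[0.0], [1.0], [2.0]]))
    assert clump(stats_for(panel, [0.5]).iloc[:0], panel) == []


def greedy_clump_oracle(stats, panel, r2_max=0.1, window=1_000_000):
    """Independent brute-force restatement of the greedy rule."""
    d = {v: panel.dosage_of(v) for v in stats["SNP"]}
    meta = stats.set_index("SNP")
    order = stats.sort_values(["P", "BP", "SNP"], kind="mergesort")["SNP"].tolist()
    removed, kept = set(), []
    for vid in order:
        if vid in removed:
            continue
        kept.append(vid)
        for other in order:
            if other == vid or other in removed or other in kept:
                continue
            if meta.at[other, "CHR"] != meta.at[vid, "CHR"]:
                continue
            if abs(int(meta.at[other, "BP"]) - int(meta.at[vid, "BP"])) > window:
                continue
            x, y = d[vid], d[other]
            if x.std() == 0 or y.std() == 0:
                continue
            if np.corrcoef(x, y)[0, 1] ** 2 >= r2_max:
                removed.add(other)
    return kept


def test_clump_matches_independent_oracle(rng):
    panel = simulate_genotypes(300, 30, ld_block_size=5, ld_rho=0.8, seed=77)
    pvals = rng.uniform(1e-9, 1.0, 30)
    stats = stats_for(panel, pvals)
    assert clump(stats, panel) == greedy_clump_oracle(stats, panel)


def test_clump_invariant_no_retained_high_ld_pair():
    for seed in (2, 9, 31):
        panel = simulate_genotypes(250, 24, ld_block_size=6, ld_rho=0.9, seed=seed)
        p = np.random.default_rng(seed).uniform(size=24)
        stats = stats_for(panel, p)
        kept = clump(stats, panel)
        meta = stats.set_index("SNP")
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                if meta.at[a, "CHR"] != meta.at[b, "CHR"]:
                    continue
                if abs(int(meta.at[a, "BP"]) - int(meta.at[b, "BP"])) > 1_000_000:
                    continue
                r = np.corrcoef(panel.dosage_of(a), panel.dosage_of(b))[0, 1]
                assert r**2 < 0.1


# ------------------------------------------------------------------- regions


@pytest.mark.parametrize(
    "chrom,pos,removed",
    [
        ("19", 44_400_000, True),  # inclusive lower bound
        ("19", 46_500_000, True),  # inclusive upper bound
        ("19", 44_399_999, False),
        ("19", 46_500_001, False),
        ("18", 45_000_000, False),  # chromosome mismatch
    ],
)
def test_exclude_region_boundaries(chrom, pos, removed):
    stats = pd.DataFrame(
        {
            "SNP": ["x"], "CHR": [chrom], "BP": [pos], "A1": ["A"],
            "A2": ["G"], "BETA": [0.1], "SE": [0.1], "P": [0.5],
        }
    )
    out = exclude_region(stats, APOE_REGION)
    assert (len(out) == 0) == removed


def test_region_validation():
    with pytest.raises(ValueError):
        GenomicRegion(chrom="1", start=10, end=5)


# --------------------------------------------------------------------- score


def test_score_arithmetic():
    panel = make_panel(np.array([[2.0, 1.0]]))
    assert score(panel, {"v0": 0.2, "v1": -0.1})[0] == pytest.approx(0.3)


def test_score_zero_weights():
    panel = make_panel(np.array([[2.0, 1.0], [0.0, 1.0]]))
    assert np.all(score(panel, {"v0": 0.0, "v1": 0.0}) == 0.0)


def test_score_missing_mean_imputed():
    # effect-allele frequency 0.25 -> mean dosage 0.5 fills the gap
    col = np.array([0, 1, 0, 1, np.nan], dtype=float)
    panel = make_panel(col[:, None])
    got = score(panel, {"v0": 0.4})
    expected = np.array([0.0, 0.4, 0.0, 0.4, 0.4 * 0.5])
    assert got == pytest.approx(expected, abs=1e-15)


def test_score_allele_flip_reflects_dosage():
    panel = make_panel(np.array([[2.0], [0.0], [1.0]]))
    flipped = score(panel, {"v0": 0.5}, stats_alleles={"v0": ("G", "A")})
    assert flipped == pytest.approx(0.5 * np.array([0.0, 2.0, 1.0]))


def test_score_allele_mismatch_errors():
    panel = make_panel(np.array([[1.0], [1.0]]))  # panel alleles A/G
    with pytest.raises(ValueError, match="strand-ambiguous"):
        score(panel, {"v0": 0.5}, stats_alleles={"v0": ("T", "C")})
    with pytest.raises(ValueError, match="allele mismatch"):
        score(panel, {"v0": 0.5}, stats_alleles={"v0": ("A", "C")})


def test_score_absent_variant_errors():
    panel = make_panel(np.array([[1.0], [1.0]]))
    with pytest.raises(ValueError, match="absent"):
        score(panel, {"v0": 0.1, "ghost": 0.2})


def test_score_matches_bruteforce(random_panel, rng):
    ids = random_panel.variant_ids[:12]
    weights = {v: rng.normal() for v in ids}
    got = score(random_panel, weights)
    d = random_panel.imputed()
    expected = np.zeros(random_panel.n_individuals)
    for v, b in weights.items():
        expected += b * d[:, random_panel.column_index(v)]
    assert np.abs(got - expected).max() < 1e-12


# ---------------------------------------------------------- threshold series


def test_default_thresholds():
    assert DEFAULT_THRESHOLDS == (0.05, 5e-3, 5e-4, 5e-5, 5e-6, 5e-7, 5e-8)


def test_threshold_series_nested_and_counted(rng):
    panel = simulate_genotypes(300, 60, seed=55)
    cfg = CausalConfig(
        dependent_set=tuple(panel.variant_ids[:5]),
        independent_set=tuple(panel.variant_ids[5:10]),
    )
    stats = simulate_summary_stats(panel, cfg, seed=56)
    models = threshold_series(stats, panel)
    assert [m.label for m in models] == [f"PRS{i}" for i in range(1, 8)]
    clumped = clump(stats, panel)
    sub = stats.set_index("SNP").loc[clumped]
    for m in models:
        # counting oracle: clumped variants at p <= threshold
        assert m.n_variants == int((sub["P"] <= m.threshold).sum())
        assert all(p <= m.threshold for p in sub.loc[m.variant_ids, "P"])
        if m.n_variants:
            assert abs(m.scores.mean()) < 1e-10
            assert m.scores.std() == pytest.approx(1.0, abs=1e-8)
    for loose, strict in zip(models, models[1:]):
        assert set(strict.variant_ids) <= set(loose.variant_ids)


def test_threshold_series_empty_model_warns():
    panel = make_panel(np.array([[0.0, 1], [1, 1], [2, 0], [1, 2]]))
    stats = stats_for(panel, [0.04, 0.5])
    with pytest.warns(UserWarning, match="no variants"):
        models = threshold_series(stats, panel, thresholds=[0.05, 1e-30])
    assert models[1].n_variants == 0
    assert np.all(models[1].scores == 0.0)
    assert models[1].warning is not None


def test_threshold_series_requires_decreasing():
    panel = make_panel(np.array([[0.0], [1.0]]))
    stats = stats_for(panel, [0.5])
    with pytest.raises(ValueError, match="decreasing"):
        threshold_series(stats, panel, thresholds=[1e-4, 0.05])
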