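import numpy as np
import pytest

from eurostruct.io import MISSING, GeoPanel
from eurostruct.sim import (
    SimConfig,
    default_config,
    make_study_design,
    simulate_dataset,
    simulate_frequencies,
    simulate_genotypes,
    simulate_mixture_cohort,
)

from conftest import two_pop_config


def test_config_validation():
    geo = GeoPanel.from_dict({"A": (50, 0), "B": (51, 0)})
    with pytest.raises(ValueError):
        SimConfig(["A"], [10], 100, [0.01], geo.subset(["A"]))  # one population
    with pytest.raises(ValueError):
        SimConfig(["A", "B"], [10, 10], 100, [0.0, 0.01], geo)  # F <= 0
    with pytest.raises(ValueError):
        SimConfig(["A", "B"], [10, 10], 100, [0.01, 0.01], geo, ld_block_size=3)
    with pytest.raises(ValueError):
        SimConfig(["A", "B"], [10, 10], 100, [0.01, 0.01], geo,
                  region_per_pop=["X", "Y"], fst_per_region={"X": 0.001})


def test_determinism_bit_identical():
    cfg = two_pop_config(n_per_pop=20, n_snps=200, missing_rate=0.05)
    a = simulate_dataset(cfg)
    b = simulate_dataset(cfg)
    assert a == b


def test_no_differentiation_limit():
    """F -> 0 with no cline leaves population frequencies at the ancestral."""
    cfg = two_pop_config(n_per_pop=10, n_snps=1000, f=1e-6)
    fm = simulate_frequencies(cfg)
    assert np.max(np.abs(fm.pop_freq - fm.ancestral_freq)) < 0.01


def test_balding_nichols_variance_identity():
    """Mean of (p1-p2)^2 / (2 pbar qbar) matches the Beta-variance identity:
    with Var(p_i) = F p0 q0 and independent draws the ratio's expectation is
    (F1+F2)/2 = F, checked across seeds at the model (frequency) level."""
    f = 0.01
    stats = []
    for seed in range(1, 6):
        cfg = two_pop_config(n_per_pop=2, n_snps=20_000, f=f, seed=seed,
                             locus_f_model="none")
        fm = simulate_frequencies(cfg)
        p1, p2 = fm.pop_freq
        pbar = (p1 + p2) / 2
        stats.append(np.mean((p1 - p2) ** 2) / np.mean(2 * pbar * (1 - pbar)))
    assert abs(np.mean(stats) / f - 1) < 0.15


def test_cline_mean_square_invariant():
    """The cline's mean-squared frequency difference between two populations
    d km apart is (strength*d/1000)^2 * E[g^2] with E[g^2] = 2, independent
    of the susceptibility sparsity."""
    for sparsity in (1.0, 0.05):
        diffs = []
        for seed in range(1, 4):
            cfg = two_pop_config(
                n_per_pop=2, n_snps=30_000, f=1e-6, seed=seed, km_apart=1000.0,
                cline_axes=[(0.0, 0.02)], cline_sparsity=sparsity,
                locus_f_model="none",
            )
            fm = simulate_frequencies(cfg)
            diffs.append(np.mean((fm.pop_freq[0] - fm.pop_freq[1]) ** 2))
        expected = 0.02**2 * 2
        assert abs(np.mean(diffs) / expected - 1) < 0.2


def test_genotype_sampling_matches_frequency():
    cfg = two_pop_config(n_per_pop=10_000, n_snps=1, f=1e-6, seed=3)
    fm = simulate_frequencies(cfg)
    fm.pop_freq[:] = 0.5
    ds = simulate_genotypes(fm, cfg)
    assert abs(ds.dosages.mean() / 2 - 0.5) < 0.01


def test_ld_blocks_duplicate_at_zero_flip():
    cfg = two_pop_config(n_per_pop=50, n_snps=40, ld_block_size=4, ld_flip_prob=0.0)
    ds = simulate_dataset(cfg)
    d = ds.dosages
    for b in range(0, 40, 4):
        for j in range(b + 1, b + 4):
            assert np.array_equal(d[:, b], d[:, j])


def test_ld_blocks_flip_r2():
    """First-vs-member dosage r^2 is (1-2f)^2 at allele frequency 0.5 (away
    from 0.5 the symmetric flip pulls members toward 0.5 and attenuates r)."""
    f = 0.1
    cfg = two_pop_config(n_per_pop=2000, n_snps=40, ld_block_size=4, ld_flip_prob=f, seed=5)
    fm = simulate_frequencies(cfg)
    fm.pop_freq[:] = 0.5
    ds = simulate_genotypes(fm, cfg)
    d = ds.dosages.astype(float)
    r2 = [
        np.corrcoef(d[:, b], d[:, j])[0, 1] ** 2
        for b in range(0, 40, 4)
        for j in range(b + 1, b + 4)
    ]
    assert abs(np.mean(r2) - (1 - 2 * f) ** 2) < 0.05


def test_missing_rate_zero_and_positive():
    cfg = two_pop_config(n_per_pop=50, n_snps=100, missing_rate=0.0)
    assert not np.any(simulate_dataset(cfg).dosages == MISSING)
    cfg = two_pop_config(n_per_pop=50, n_snps=100, missing_rate=0.2)
    rate = np.mean(simulate_dataset(cfg).dosages == MISSING)
    assert 0.15 < rate < 0.25


def test_region_deviations_shared_within_region():
    geo = GeoPanel.from_dict({c: (50 + i, 5) for i, c in enumerate("ABCD")})
    cfg = SimConfig(
        populations=list("ABCD"), samples_per_pop=[5] * 4, n_snps=5000,
        fst_per_pop=[1e-6] * 4, geo=geo,
        region_per_pop=["R1", "R1", "R2", "R2"],
        fst_per_region={"R1": 0.01, "R2": 0.01}, seed=2,
    )
    fm = simulate_frequencies(cfg)
    same = np.corrcoef(fm.pop_freq[0] - fm.ancestral_freq, fm.pop_freq[1] - fm.ancestral_freq)[0, 1]
    diff = np.corrcoef(fm.pop_freq[0] - fm.ancestral_freq, fm.pop_freq[2] - fm.ancestral_freq)[0, 1]
    assert same > 0.95 and abs(diff) < 0.2


class TestStudyDesign:
    def _cohort(self, sizes, seed=0, n_snps=50):
        pops = [f"P{i}" for i in range(len(sizes))]
        geo = GeoPanel.from_dict({p: (45 + i, 5) for i, p in enumerate(pops)})
        cfg = SimConfig(pops, list(sizes), n_snps, [0.01] * len(pops), geo, seed=seed)
        return simulate_dataset(cfg)

    def test_exact_size_population_contributes_no_test_samples(self):
        ds = self._cohort([70, 100])
        ref, test, held = make_study_design(ds, reference_size=70)
        assert sum(p == "P0" for p in ref.populations) == 70
        assert "P0" not in test.populations

    def test_small_leftover_excluded_from_test(self):
        """75 samples leave 5 after the 70-draw; 5 <= 10 so none are tested."""
        ds = self._cohort([75, 100])
        ref, test, held = make_study_design(ds, reference_size=70, min_test=10)
        assert sum(p == "P0" for p in ref.populations) == 70
        assert "P0" not in test.populations
        assert sum(p == "P1" for p in test.populations) == 30

    def test_undersized_population_excluded_from_reference(self):
        ds = self._cohort([39, 100])
        with pytest.warns(UserWarning):
            ref, test, held = make_study_design(ds, reference_size=70)
        assert "P0" not in ref.populations
        assert "P0" not in test.populations

    def test_held_out_population_isolated(self):
        ds = self._cohort([80, 100, 90])
        ref, test, held = make_study_design(ds, reference_size=70, held_out_pops=["P2"])
        assert set(held.populations) == {"P2"}
        assert held.n_samples == 90
        assert "P2" not in ref.populations and "P2" not in test.populations

    def test_partition_is_disjoint_and_conserving(self):
        ds = self._cohort([85, 100, 90])
        ref, test, held = make_study_design(ds, reference_size=70, held_out_pops=["P2"])
        ids = ref.sample_ids + test.sample_ids + held.sample_ids
        assert len(ids) == len(set(ids))
        # retained pops partition fully: 70 ref each, leftovers tested
        assert len(ids) == 85 + 100 + 90

    def test_no_population_large_enough_raises(self):
        ds = self._cohort([30, 40])
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                make_study_design(ds, reference_size=70)


def test_mixture_cohort_fractions_and_labels():
    cfg = two_pop_config(n_per_pop=5, n_snps=800, f=0.05, seed=4)
    fm = simulate_frequencies(cfg)
    cohort = simulate_mixture_cohort(
        fm, cfg, components=["A", "B"], n_samples=400, weights=[0.75, 0.25],
        mode="discrete", label="MIX", seed=9,
    )
    assert cohort.populations == ["MIX"] * 400
    assert cohort.n_snps == cfg.n_snps
    with pytest.raises(ValueError):
        simulate_mixture_cohort(fm, cfg, ["A", "B"], 0)


def test_admixed_mode_interpolates_frequencies():
    cfg = two_pop_config(n_per_pop=5, n_snps=2000, f=0.2, seed=4)
    fm = simulate_frequencies(cfg)
    cohort = simulate_mixture_cohort(fm, cfg, ["A", "B"], 300, mode="admixed", seed=9)
    mean_freq = cohort.dosages.mean(axis=0) / 2
    expected = (fm.pop_freq[0] + fm.pop_freq[1]) / 2
    assert np.mean((mean_freq - expected) ** 2) < np.mean((mean_freq - fm.pop_freq[0]) ** 2)


def test_default_config_is_the_study_scale():
    cfg = default_config(n_snps=1000)
    assert cfg.n_populations == 13
    assert min(cfg.samples_per_pop) == 39 and max(cfg.samples_per_pop) == 475
    assert "SE" in cfg.populations and "FI" in cfg.populations
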