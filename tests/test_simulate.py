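import numpy as np
import pytest

import sweepmodes as sm
from sweepmodes.coancestry import standardize_matrix
from sweepmodes.kernels import SweepParams
from sweepmodes.simulate import (
    EXAMPLE_GS,
    EXAMPLE_MIGS,
    EXAMPLE_SELS,
    EXAMPLE_SOURCES,
    EXAMPLE_TIMES,
    default_coancestry,
    example_scenario,
    simulate_neutral,
    simulate_selected_region,
)

from conftest import SEED, small_scenario


def test_default_coancestry_is_valid():
    F = default_coancestry(6)
    np.testing.assert_allclose(F, F.T, atol=1e-15)
    eigs = np.linalg.eigvalsh(F)
    assert eigs.min() > -1e-12
    # centered representative: zero row sums
    np.testing.assert_allclose(F.sum(axis=1), 0.0, atol=1e-12)


def test_same_seed_reproduces_data_exactly():
    a = simulate_neutral(small_scenario(seed=77))
    b = simulate_neutral(small_scenario(seed=77))
    np.testing.assert_array_equal(a.freqs, b.freqs)
    c = simulate_selected_region(small_scenario(seed=77))
    d = simulate_selected_region(small_scenario(seed=77))
    np.testing.assert_array_equal(c.freqs, d.freqs)
    e = simulate_neutral(small_scenario(seed=78))
    assert not np.array_equal(a.freqs, e.freqs)


def test_zero_coancestry_frequencies_track_eps(rng):
    """With F ~ 0 and no sampling, every population sits at eps."""
    sc = small_scenario(
        F_true=np.eye(6) * 1e-8, n_neutral_sites=200, binomial_sampling=False
    )
    data = simulate_neutral(sc)
    assert np.abs(data.freqs - data.freqs.mean(axis=0)).max() < 0.01


def test_marginal_moments_match_model():
    """Per-population mean eps and variance eps(1-eps) F_ii, exactly on [0, 1]."""
    F = default_coancestry(6)
    sc = small_scenario(n_neutral_sites=150_000, binomial_sampling=False)
    data = simulate_neutral(sc)
    Z, eps, usable = standardize_matrix(data.freqs)
    emp = (Z[:, usable] ** 2).mean(axis=1)
    np.testing.assert_allclose(emp, np.diag(F), atol=0.01)
    assert data.freqs.min() >= 0.0 and data.freqs.max() <= 1.0


def test_neutral_mode_selected_region_matches_neutral_structure():
    """mode='neutral' selected-region sites share the neutral covariance."""
    sc = small_scenario(
        mode="neutral", binomial_sampling=False,
        positions=np.linspace(0.001, 1, 20_000), n_neutral_sites=20_000,
    )
    neu = simulate_neutral(sc)
    selreg = simulate_selected_region(sc)
    covs = []
    for data in (neu, selreg):
        Z, _, usable = standardize_matrix(data.freqs)
        Zu = Z[:, usable]
        covs.append((Zu @ Zu.T) / Zu.shape[1])
    assert np.abs(covs[0] - covs[1]).max() < 0.01


def test_sweep_tail_sites_revert_to_neutral_coancestry():
    """Far from the selected site the per-site covariance approaches F."""
    sc = small_scenario(
        binomial_sampling=False,
        # r = rec * 40 puts retention below 1e-12: far tail of the sweep
        positions=np.linspace(40.0, 41.0, 30_000),
        n_neutral_sites=10,
    )
    data = simulate_selected_region(sc)
    Z, _, usable = standardize_matrix(data.freqs)
    Zu = Z[:, usable]
    cov = (Zu @ Zu.T) / Zu.shape[1]
    assert np.abs(cov - sc.F_true).max() < 0.01


def test_sweep_site_covariance_matches_kernel():
    """At r ~ 0 the generated covariance equals the kernel's F'(r), including
    diagonals pushed to ~1 (verified on the known-eps scale)."""
    from sweepmodes.kernels import model_covariance

    L = 30_000
    sc = small_scenario(
        binomial_sampling=False,
        positions=1e-6 + np.arange(L) * 1e-12,
        n_neutral_sites=10,
        eps_range=(0.5, 0.5),  # pin eps so truth-scale standardization is exact
    )
    data = simulate_selected_region(sc)
    dev = (data.freqs - 0.5) / 0.5
    cov = (dev @ dev.T) / L
    expected = model_covariance(
        sc.F_true, 1e-6 * sc.rec, sc.mode, sc.params, sc.selected_pops0
    )
    assert np.abs(cov - expected).max() < 0.03
    for i in [0, 2, 4]:
        assert cov[i, i] > 0.9


def test_non_psd_truth_rejected():
    F = np.array([[1.0, 2.0], [2.0, 1.0]])
    with pytest.raises(sm.ValidationError, match="positive semi-definite"):
        small_scenario(k=2, F_true=F, sample_sizes=np.full(2, 10),
                       selected_pops0=[0])


def test_example_fixture_files_and_grid(tmp_path):
    paths = sm.make_example_fixture(tmp_path, seed=SEED,
                                    n_neutral_sites=300, n_selected_sites=40)
    cfg = sm.load_config(paths["config"])
    assert len(cfg.sels) == 23
    assert len(cfg.times) == 9
    assert len(cfg.gs) == 5
    assert len(cfg.migs) == 5
    assert cfg.sources == [1, 3, 5]
    assert cfg.selected_pops == [1, 3, 5]
    assert cfg.Ne == 10_000 and cfg.rec == 0.005
    assert cfg.sample_sizes == [10] * 6

    neutral = sm.read_frequency_table(paths["neutral"], sample_sizes=cfg.sample_sizes)
    positions = sm.read_positions(paths["positions"])
    selected = sm.read_frequency_table(
        paths["selected"], sample_sizes=cfg.sample_sizes, positions=positions
    )
    assert neutral.n_pops == 6 and selected.n_pops == 6
    assert selected.n_sites == 40
    ctx = sm.build_context(cfg, neutral, selected)
    assert len(ctx.proposed_sites) == 10


def test_example_grid_values_verbatim():
    assert EXAMPLE_SELS[:3] == [1e-4, 1e-3, 0.01]
    assert EXAMPLE_SELS[3] == pytest.approx(0.02) and EXAMPLE_SELS[15] == pytest.approx(0.14)
    assert EXAMPLE_TIMES == [0.0, 5.0, 25.0, 50.0, 100.0, 500.0, 1000.0, 1e4, 1e6]
    assert EXAMPLE_GS[0] == pytest.approx(5e-5)
    assert EXAMPLE_MIGS == [1e-5, 1e-3, 1e-1, 0.5, 1.0]
    assert EXAMPLE_SOURCES == [1, 3, 5]


def _composite_at(ctx, mode, params, proposed_site):
    from sweepmodes.kernels import model_covariance
    from sweepmodes.likelihood import bin_distances, composite_loglik

    bins = bin_distances(ctx.positions, proposed_site, ctx.rec, ctx.num_bins)
    return composite_loglik(
        ctx.Z_sel, ctx.sample_sizes,
        lambda r: model_covariance(ctx.F.F, r, mode, params, ctx.selected_pops0),
        bins, ctx.C,
    )


@pytest.mark.parametrize(
    "mode, true_params",
    [
        ("independent", dict(s=0.05)),
        ("migration", dict(s=0.05, m=0.1, source=0)),
        ("standing", dict(s=0.05, g=0.01, t=100.0)),
        ("standing_source", dict(s=0.05, g=0.01, t=100.0, source=0)),
    ],
)
def test_likelihood_prefers_truth_over_distant_parameters(mode, true_params):
    """For each mode, the composite likelihood at the true grid point beats a
    distant one (s off 5x, site off by half the region) in >= 90% of 50
    replicates."""
    from conftest import small_config

    wins = 0
    n_reps = 50
    for seed in range(1, n_reps + 1):
        sc = small_scenario(seed=seed, mode=mode,
                            params=SweepParams(Ne=10_000.0, **true_params))
        ctx = sm.build_context(small_config(), simulate_neutral(sc),
                               simulate_selected_region(sc))
        truth = _composite_at(ctx, mode, sc.params, sc.true_site)
        wrong = dict(true_params)
        wrong["s"] = true_params["s"] / 5.0
        distant = _composite_at(ctx, mode, SweepParams(Ne=10_000.0, **wrong),
                                sc.true_site + 0.5)
        wins += truth > distant
    assert wins >= 0.9 * n_reps


def test_independent_data_prefers_independent_over_migration():
    """Weak mode-identifiability: independent-sweep data score at least as
    high under the independent model as under migration in a majority of 20
    replicates."""
    from conftest import small_config

    wins = 0
    n_reps = 20
    for seed in range(101, 101 + n_reps):
        sc = small_scenario(seed=seed)
        ctx = sm.build_context(small_config(), simulate_neutral(sc),
                               simulate_selected_region(sc))
        ind = sm.fit_mode(ctx, "independent").cle.max()
        mig = sm.fit_mode(ctx, "migration").cle.max()
        wins += ind >= mig
    assert wins > n_reps / 2
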