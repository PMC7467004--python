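import numpy as np
import pytest

import sweepmodes as sm
from sweepmodes.kernels import (
    ModeSpec,
    SweepParams,
    kernel_independent,
    kernel_migration,
    kernel_multi,
    kernel_neutral,
    kernel_standing,
    model_covariance,
    standing_phase_coalescence,
    sweep_retention,
    sweep_duration,
)

from conftest import random_psd_coancestry

NE = 10_000.0
S = [0, 2, 4]


@pytest.fixture()
def F(rng):
    return random_psd_coancestry(rng, 6)


def r_far(s: float) -> float:
    """Distance at which retention is below 1e-12."""
    return 30.0 * s / np.log(4 * NE * s)


def test_retention_at_zero_distance_is_one():
    assert sweep_retention(0.0, 0.05, NE) == 1.0


def test_retention_half_life_algebra():
    s = 0.05
    r_half = s * np.log(2.0) / np.log(4 * NE * s)
    assert sweep_retention(r_half, s, NE) == pytest.approx(0.5, rel=1e-12)


def test_retention_direct_evaluation():
    # exp(-(1e-4/0.05) * ln(2000)) evaluated to 5 decimals
    y = sweep_retention(1e-4, 0.05, NE)
    assert y == pytest.approx(0.98491, abs=5e-6)


def test_retention_monotone_decreasing():
    r = np.logspace(-7, -1, 40)
    y = sweep_retention(r, 0.05, NE)
    assert (np.diff(y) < 0).all()


def test_weak_selection_rejected():
    with pytest.raises(sm.ParameterError):
        sweep_duration(1e-6, 100.0)


def test_standing_phase_limits():
    g, t = 0.01, 100.0
    assert standing_phase_coalescence(0.1, g, 0.0, NE) == 0.0
    # t -> inf at r=0: certain coalescence
    assert standing_phase_coalescence(0.0, g, 1e12, NE) == pytest.approx(1.0)
    # t -> inf: competing-exponentials closed form kappa/(kappa + 2r)
    kappa = 1.0 / (2 * NE * g)
    r = 3e-4
    assert standing_phase_coalescence(r, g, 1e12, NE) == pytest.approx(kappa / (kappa + 2 * r))


def test_neutral_kernel_is_identity(F):
    np.testing.assert_array_equal(kernel_neutral(F), F)
    np.testing.assert_array_equal(kernel_neutral(F, r=0.37), F)


def test_independent_hand_arithmetic():
    F = np.diag([0.2, 0.2])
    # y = 0.5 via the half-life distance
    s = 0.05
    r_half = s * np.log(2.0) / np.log(4 * NE * s)
    out = kernel_independent(F, r_half, s, NE, [0])
    assert out[0, 0] == pytest.approx(0.25 + 0.75 * 0.2)
    assert out[1, 1] == pytest.approx(0.2)


def test_independent_r_zero_forces_coalescence(F):
    out = kernel_independent(F, 0.0, 0.05, NE, S)
    for i in S:
        assert out[i, i] == pytest.approx(1.0)


@pytest.mark.parametrize("mode", ["independent", "standing", "standing_source", "migration"])
def test_all_kernels_return_to_neutral_far_away(F, mode):
    params = SweepParams(Ne=NE, s=0.05, m=0.01, t=100.0, g=0.01, source=0)
    out = model_covariance(F, r_far(0.05), mode, params, S)
    np.testing.assert_allclose(out, F, atol=1e-10)


@pytest.mark.parametrize("mode", ["independent", "standing", "standing_source", "migration"])
def test_kernels_symmetric_bounded_and_leave_nonselected_alone(F, mode):
    params = SweepParams(Ne=NE, s=0.05, m=0.01, t=100.0, g=0.01, source=0)
    r_grid = np.logspace(-7, -2, 25)
    stack = model_covariance(F, r_grid, mode, params, S)
    lo, hi = F.min() - 1e-9, 1.0 + 1e-9
    nonsel = [i for i in range(6) if i not in S]
    for out in stack:
        np.testing.assert_allclose(out, out.T, atol=1e-12)
        assert out.min() >= lo and out.max() <= hi
        np.testing.assert_array_equal(out[nonsel][:, nonsel], F[nonsel][:, nonsel])
        # cross blocks between selected and non-selected are untouched too
        np.testing.assert_array_equal(out[np.ix_(nonsel, S)], F[np.ix_(nonsel, S)])


@pytest.mark.parametrize("mode", ["independent", "standing", "standing_source", "migration"])
def test_added_coancestry_decays_with_distance(F, mode):
    params = SweepParams(Ne=NE, s=0.05, m=0.01, t=100.0, g=0.01, source=0)
    r_grid = np.logspace(-7, -2, 30)
    stack = model_covariance(F, r_grid, mode, params, S)
    for i in S:
        added = stack[:, i, i] - F[i, i]
        assert (np.diff(added) <= 1e-12).all()


def test_standing_rare_variant_acts_like_shared_haplotype(F):
    """g -> 0 at small r t: pair sharing probability approaches 1 and the
    selected pair behaves like a single shared haplotype."""
    r = 1e-4
    out = kernel_standing(F, r, 0.05, 1e-9, 1.0, NE, S)
    y2 = sweep_retention(r, 0.05, NE) ** 2
    i, j = S[0], S[1]
    expected = y2 * 1.0 + (1 - y2) * F[i, j]
    assert out[i, j] == pytest.approx(expected, rel=1e-3)


def test_standing_time_reduces_between_population_sharing(F):
    """Longer standing time gives more chances to recombine off before the
    ancestral coalescent: between-population coancestry decreases with t."""
    r = 1e-4
    i, j = S[0], S[1]
    vals = [kernel_standing(F, r, 0.05, 0.01, t, NE, S)[i, j]
            for t in (0.0, 100.0, 1e4, 1e6)]
    assert (np.diff(vals) < 0).all()
    # while the within-population diagonal is t-free
    diags = {round(float(kernel_standing(F, r, 0.05, 0.01, t, NE, S)[i, i]), 14)
             for t in (0.0, 100.0, 1e6)}
    assert len(diags) == 1


def test_standing_selected_block_is_psd(F):
    """Within the selected block the standing construction is a convex
    mixture toward a shared haplotype, hence PSD there.  (The full matrix
    can lose strict positive definiteness — the reason the pseudo-inverse
    fallback exists.)"""
    for t in (0.0, 100.0, 1e4):
        stack = kernel_standing(F, np.logspace(-7, -2, 20), 0.05, 0.01, t, NE, S)
        for out in stack:
            block = out[np.ix_(S, S)]
            assert np.linalg.eigvalsh(block).min() > -1e-10


def test_standing_forced_coalescence_diag(F):
    # y = 1 (r = 0) and p_coal = 1 (enormous t): diagonal pinned at 1
    out = kernel_standing(F, 0.0, 0.05, 0.01, 1e12, NE, S)
    for i in S:
        assert out[i, i] == pytest.approx(1.0)


def test_standing_source_diagonal_uses_sweep_form(F):
    src = S[0]
    r = 2e-4
    with_src = kernel_standing(F, r, 0.05, 0.01, 100.0, NE, S, with_source=True, source=src)
    ind = kernel_independent(F, r, 0.05, NE, S)
    assert with_src[src, src] == pytest.approx(ind[src, src])
    # non-source selected diagonals differ from the sweep-only form
    other = S[1]
    assert with_src[other, other] != pytest.approx(ind[other, other])


def test_migration_instant_migration_shares_haplotype(F):
    out = kernel_migration(F, 0.0, 0.05, 1e9, NE, S, source=S[0])
    assert out[S[1], S[0]] == pytest.approx(1.0)


def test_migration_monotone_in_rate(F):
    r = 2e-4
    vals = [
        kernel_migration(F, r, 0.05, m, NE, S, source=S[0])[S[1], S[0]]
        for m in np.logspace(-5, 0, 12)
    ]
    assert (np.diff(vals) > 0).all()


def test_migration_rejects_bad_rate(F):
    with pytest.raises(sm.ParameterError):
        kernel_migration(F, 1e-4, 0.05, 0.0, NE, S, source=S[0])


def test_multi_single_group_matches_single_mode_bitwise(F):
    params = SweepParams(Ne=NE, s=0.05)
    spec = ModeSpec(sets=[S], modes=["independent"], selected_pops=S)
    r = np.logspace(-6, -2, 10)
    np.testing.assert_array_equal(
        kernel_multi(F, r, params, spec),
        kernel_independent(F, r, 0.05, NE, S),
    )


def test_multi_mixed_groups_match_constituents(F):
    """standing_source on {0,2} and independent on {4}, per-entry."""
    params = SweepParams(Ne=NE, s=0.05, t=100.0, g=0.01, source=0)
    spec = ModeSpec(sets=[[0, 2], [4]], modes=["standing_source", "independent"], selected_pops=S)
    r = 1.3e-4
    out = kernel_multi(F, r, params, spec)
    sv = kernel_standing(F, r, 0.05, 0.01, 100.0, NE, [0, 2], with_source=True, source=0)
    ind = kernel_independent(F, r, 0.05, NE, [4])
    assert out[4, 4] == ind[4, 4]
    assert out[0, 0] == sv[0, 0] and out[2, 2] == sv[2, 2] and out[0, 2] == sv[0, 2]
    # no cross-group coancestry added
    assert out[0, 4] == F[0, 4] and out[2, 4] == F[2, 4]


def test_mode_spec_validation():
    with pytest.raises(sm.ValidationError, match="disjoint"):
        ModeSpec(sets=[[0, 2], [2]], modes=["independent", "independent"])
    with pytest.raises(sm.ValidationError, match="partition"):
        ModeSpec(sets=[[0]], modes=["independent"], selected_pops=[0, 2])
    with pytest.raises(sm.ValidationError, match="unknown mode"):
        ModeSpec(sets=[[0]], modes=["parallel"])
    with pytest.raises(sm.ValidationError, match="source-requiring"):
        ModeSpec(sets=[[0], [2]], modes=["migration", "standing_source"])
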