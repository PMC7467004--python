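"""Synthetic allele-frequency data with the statistical structure the
likelihood assumes.

The generator draws, per site, an ancestral frequency ``eps`` and population
frequencies whose covariance is ``eps (1 - eps) F``, where ``F`` is the
neutral coancestry matrix for neutral sites and the mode kernel ``F'(r)``
for selected-region sites at distance ``r`` from the true selected position.
Frequencies are produced by a Gaussian copula with Balding–Nichols Beta
marginals: population ``i`` gets ``Beta(eps (1 - F_ii)/F_ii,
(1 - eps)(1 - F_ii)/F_ii)``, which has mean ``eps`` and variance
``eps (1 - eps) F_ii`` exactly on [0, 1] and degenerates to the correct
two-point {0, 1} law as coancestry approaches 1 (complete coalescence),
while the copula correlation ``F_ij / sqrt(F_ii F_jj)`` reproduces the
across-population coancestry.  (Clamping plain Gaussian deviations to [0, 1]
instead would destroy variance precisely where the sweep kernels push
coancestry toward 1, biasing parameter recovery.)  Optionally, binomial
sampling with the per-population sample sizes is layered on top.  Sampling
from the model's own covariance structure (rather than a forward
Wright–Fisher simulation) makes parameter-recovery tests
exact-by-construction; fidelity to real sweep genealogies is a non-goal.

The example fixture mirrors the shape of the worked example these models are
usually demonstrated on: six populations over a region rescaled to [0, 1],
three of which (indices 1, 3, 5) independently swept a beneficial allele at
position 0 with s = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError
from .io import FrequencyMatrix, RunConfig
from .kernels import ModeSpec, SweepParams, model_covariance

#: Grid vectors of the worked example: 23 selection coefficients, 9 standing
#: times, 5 standing frequencies, 5 migration rates, 3 proposed sources.
EXAMPLE_SELS = [
    1e-4, 1e-3, 0.01,
    *np.round(np.arange(0.02, 0.1401, 0.01), 10).tolist(),
    *np.round(np.arange(0.15, 0.3001, 0.05), 10).tolist(),
    *np.round(np.arange(0.4, 0.6001, 0.1), 10).tolist(),
]
EXAMPLE_TIMES = [0.0, 5.0, 25.0, 50.0, 100.0, 500.0, 1000.0, 1e4, 1e6]
EXAMPLE_GS = [1.0 / (2 * 10000), 1e-4, 1e-3, 1e-2, 1e-1]
EXAMPLE_MIGS = [1e-5, 1e-3, 1e-1, 0.5, 1.0]
EXAMPLE_SOURCES = [1, 3, 5]


def default_coancestry(k: int = 6) -> np.ndarray:
    """Two-clade drift coancestry for ``k`` populations, mean-centered.

    Populations split into two clades sharing a branch of length 0.03, with
    terminal branches of 0.05 (F_ST-scale drift).  Only the mean-centered
    component of coancestry is identifiable from deviations measured against
    the across-population mean, so the centered representative is returned;
    it has (numerically) zero row sums and is PSD.
    """
    half = k // 2
    F = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            same_clade = (i < half) == (j < half)
            F[i, j] = 0.03 if (same_clade and i != j) else 0.0
        F[i, i] = 0.03 + 0.05
    P = np.eye(k) - np.full((k, k), 1.0 / k)
    return P @ F @ P


@dataclass
class SimulationScenario:
    """Study conditions for one synthetic data set.

    ``mode`` is one of the convergence modes (or "neutral"); ``params``
    carries the true sweep parameters; ``binomial_sampling`` controls whether
    the finite-sample binomial layer is applied on top of the population
    frequencies.
    """

    k: int
    F_true: np.ndarray
    mode: str
    params: SweepParams
    true_site: float
    positions: np.ndarray
    sample_sizes: np.ndarray
    selected_pops0: list[int]
    n_neutral_sites: int
    rec: float
    seed: int
    eps_range: tuple[float, float] = (0.05, 0.95)
    binomial_sampling: bool = True
    mode_spec: ModeSpec | None = None
    pop_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.F_true = np.asarray(self.F_true, dtype=float)
        if self.F_true.shape != (self.k, self.k):
            raise ValidationError("F_true must be k x k")
        if not np.allclose(self.F_true, self.F_true.T, atol=1e-12):
            raise ValidationError("F_true must be symmetric")
        eigs = np.linalg.eigvalsh((self.F_true + self.F_true.T) / 2.0)
        if eigs.min() < -1e-10 * max(1.0, abs(eigs.max())):
            raise ValidationError("F_true must be positive semi-definite")
        self.positions = np.sort(np.asarray(self.positions, dtype=float))
        self.sample_sizes = np.asarray(self.sample_sizes, dtype=int)


def _draw_sites(
    rng: np.random.Generator,
    cov_stack: np.ndarray,
    eps: np.ndarray,
    sample_sizes: np.ndarray,
    binomial_sampling: bool,
) -> np.ndarray:
    """Draw one frequency vector per site given per-site coancestry matrices.

    Gaussian copula with Balding–Nichols Beta marginals: exact per-population
    mean ``eps`` and variance ``eps (1 - eps) F_ii`` on [0, 1], coupled with
    correlation ``F_ij / sqrt(F_ii F_jj)``.
    """
    from scipy.special import ndtr
    from scipy.stats import beta as beta_dist

    k = cov_stack.shape[-1]
    L = eps.size
    # coancestry diagonals are drift intensities in (0, 1]
    Fii = np.clip(np.diagonal(cov_stack, axis1=1, axis2=2), 1.0e-8, 1.0 - 1.0e-12)
    sd = np.sqrt(Fii)
    rho = cov_stack / (sd[:, :, None] * sd[:, None, :])
    # PSD repair + renormalization so copula marginals stay standard normal
    vals, vecs = np.linalg.eigh((rho + np.swapaxes(rho, 1, 2)) / 2.0)
    vals = np.clip(vals, 0.0, None)
    roots = vecs * np.sqrt(vals)[:, None, :]  # (L, k, k)
    g = np.einsum("lij,lj->li", roots, rng.standard_normal((L, k)))
    g_sd = np.sqrt(np.clip(np.einsum("lij,lij->li", roots, roots), 1.0e-12, None))
    u = ndtr(g / g_sd)
    a = eps[:, None] * (1.0 - Fii) / Fii
    b = (1.0 - eps[:, None]) * (1.0 - Fii) / Fii
    x = beta_dist.ppf(u, a, b)  # (L, k)
    if binomial_sampling:
        n = sample_sizes[None, :]
        x = rng.binomial(n, x) / n
    return x.T  # (k, L)


def simulate_neutral(scenario: SimulationScenario, seed: int | None = None) -> FrequencyMatrix:
    """Simulate unlinked neutral sites under the neutral coancestry model."""
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    L = scenario.n_neutral_sites
    eps = rng.uniform(*scenario.eps_range, size=L)
    cov = np.repeat(scenario.F_true[None], L, axis=0)
    freqs = _draw_sites(rng, cov, eps, scenario.sample_sizes, scenario.binomial_sampling)
    # sample size 1 marks frequencies carrying no binomial sampling error
    sizes = scenario.sample_sizes if scenario.binomial_sampling else np.ones(scenario.k, int)
    return FrequencyMatrix(freqs, sample_sizes=sizes, pop_labels=list(scenario.pop_labels))


def simulate_selected_region(
    scenario: SimulationScenario, seed: int | None = None
) -> FrequencyMatrix:
    """Simulate the selected region under the scenario's mode kernel.

    Each site at distance ``r = rec * |position - true_site|`` from the true
    selected position gets covariance ``eps (1 - eps) F'(r)``.
    """
    rng = np.random.default_rng(scenario.seed + 1 if seed is None else seed)
    r = scenario.rec * np.abs(scenario.positions - scenario.true_site)
    cov = model_covariance(
        scenario.F_true, r, scenario.mode, scenario.params,
        scenario.selected_pops0, scenario.mode_spec,
    )
    eps = rng.uniform(*scenario.eps_range, size=r.size)
    freqs = _draw_sites(rng, cov, eps, scenario.sample_sizes, scenario.binomial_sampling)
    sizes = scenario.sample_sizes if scenario.binomial_sampling else np.ones(scenario.k, int)
    return FrequencyMatrix(
        freqs,
        sample_sizes=sizes,
        positions=scenario.positions,
        pop_labels=list(scenario.pop_labels),
    )


def example_scenario(
    seed: int,
    n_neutral_sites: int = 10_000,
    n_selected_sites: int = 200,
    s: float = 0.05,
    binomial_sampling: bool = True,
) -> SimulationScenario:
    """The packaged-example-shaped scenario: 6 populations, selected indices
    1, 3, 5 (1-based) independently swept at position 0 with s = 0.05."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 911]))
    positions = np.sort(rng.uniform(0.0, 1.0, size=n_selected_sites))
    return SimulationScenario(
        k=6,
        F_true=default_coancestry(6),
        mode="independent",
        params=SweepParams(Ne=10_000, s=s),
        true_site=0.0,
        positions=positions,
        sample_sizes=np.full(6, 10),
        selected_pops0=[0, 2, 4],
        n_neutral_sites=n_neutral_sites,
        rec=0.005,
        seed=seed,
        binomial_sampling=binomial_sampling,
    )


def example_config(n_sites: int = 10) -> RunConfig:
    """Run configuration matching the worked example's printed grids."""
    return RunConfig(
        Ne=10_000,
        rec=0.005,
        selected_pops=[1, 3, 5],
        sels=list(EXAMPLE_SELS),
        migs=list(EXAMPLE_MIGS),
        times=list(EXAMPLE_TIMES),
        gs=list(EXAMPLE_GS),
        sources=list(EXAMPLE_SOURCES),
        num_bins=1000,
        sample_sizes=[10] * 6,
        n_sites=n_sites,
        locus_name="test_locus",
    )


def make_example_fixture(out_dir: str | Path, seed: int, **scenario_kwargs) -> dict[str, Path]:
    """Write the example data set and its configuration to ``out_dir``.

    Produces ``neutral_freqs.csv``, ``selected_freqs.csv``, ``positions.txt``
    and ``config.yaml``; returns the paths.  Data are deterministic given the
    seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scenario = example_scenario(seed, **scenario_kwargs)
    neutral = simulate_neutral(scenario)
    selected = simulate_selected_region(scenario)
    cfg = example_config()

    paths = {
        "neutral": out_dir / "neutral_freqs.csv",
        "selected": out_dir / "selected_freqs.csv",
        "positions": out_dir / "positions.txt",
        "config": out_dir / "config.yaml",
    }
    np.savetxt(paths["neutral"], neutral.freqs, delimiter=",", fmt="%.17g")
    np.savetxt(paths["selected"], selected.freqs, delimiter=",", fmt="%.17g")
    np.savetxt(paths["positions"], selected.positions, fmt="%.17g")
    cfg_dict = {
        "Ne": cfg.Ne, "rec": cfg.rec, "selected_pops": cfg.selected_pops,
        "sels": [float(v) for v in cfg.sels], "migs": [float(v) for v in cfg.migs],
        "times": [float(v) for v in cfg.times], "gs": [float(v) for v in cfg.gs],
        "sources": cfg.sources, "num_bins": cfg.num_bins,
        "sample_sizes": cfg.sample_sizes, "n_sites": cfg.n_sites,
        "locus_name": cfg.locus_name, "cholesky": True,
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=False)
    return paths
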