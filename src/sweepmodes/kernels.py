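"""Covariance kernels for the convergence modes.

Each kernel transforms the neutral coancestry matrix ``F`` into the model
covariance ``F'(r)`` at recombination distance ``r`` (Morgans) from a proposed
selected site, for one of the modes:

``independent``
    Each selected population gained the beneficial mutation by its own
    mutation event.  Lineages that stay associated with the beneficial
    background through the sweep (probability ``y`` each) coalesce within
    their population; no coancestry is added between populations.
``standing`` / ``standing_source``
    The beneficial allele was standing at frequency ``g`` for ``t``
    generations before selection.  Lineages retained through the sweep ride
    the standing haplotype, where a pair coalesces at rate ``kappa = 1/(2 Ne g)``
    while each lineage recombines off at rate ``r``.  With a source
    population, the source itself carries a new mutation (independent-sweep
    form on its diagonal).
``migration``
    The mutation arose once in a source population and spread to the other
    selected populations by migration at rate ``m``.  A lineage in a
    recipient that is retained through the local sweep traces back into the
    source sweep with probability ``exp(-r/m)`` (the migrant haplotype is
    exposed to recombination for the ~``1/m`` generations it waits to
    establish).
``multi``
    Disjoint groups of selected populations follow different modes; groups
    share no added coancestry (their convergence events are independent).

All functions accept a scalar ``r`` (returning a ``(k, k)`` matrix) or a
length-``B`` vector of distances (returning a ``(B, k, k)`` stack).  Entries
involving non-selected populations are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, ValidationError

SINGLE_MODES = ("independent", "standing", "standing_source", "migration")
SOURCE_MODES = ("migration", "standing_source")


@dataclass
class SweepParams:
    """One grid point of sweep parameters.

    s : selection coefficient per generation (> 0)
    m : migration rate, proportion of migrant origin per generation (> 0)
    t : time the variant was standing before selection, generations (>= 0)
    g : frequency of the standing variant, in (0, 1)
    source : 0-based index of the source population (migration / standing_source)
    Ne : effective population size (shared by all populations)
    """

    Ne: float
    s: float | None = None
    m: float | None = None
    t: float | None = None
    g: float | None = None
    source: int | None = None


@dataclass
class ModeSpec:
    """Partition of the selected populations into per-mode groups.

    ``sets`` holds disjoint groups of 0-based population indices and
    ``modes`` one mode label per group.
    """

    sets: list[list[int]]
    modes: list[str]
    selected_pops: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sets) != len(self.modes):
            raise ValidationError("sets and modes must have equal length")
        for mode in self.modes:
            if mode not in SINGLE_MODES:
                raise ValidationError(
                    f"unknown mode label {mode!r}; must be one of {SINGLE_MODES}"
                )
        flat = [p for group in self.sets for p in group]
        if len(flat) != len(set(flat)):
            raise ValidationError("sets must be disjoint")
        if self.selected_pops and set(flat) != set(self.selected_pops):
            raise ValidationError("sets must partition selected_pops exactly")
        n_sourced = sum(m in SOURCE_MODES for m in self.modes)
        if n_sourced > 1:
            raise ValidationError(
                "at most one group may use a source-requiring mode "
                "(migration / standing_source) in a mixed fit"
            )

    @property
    def uses(self) -> set[str]:
        """Grid axes consumed by this mixed specification."""
        axes = {"sels"}
        if any(m == "migration" for m in self.modes):
            axes.add("migs")
        if any(m in ("standing", "standing_source") for m in self.modes):
            axes.update(("times", "gs"))
        if any(m in SOURCE_MODES for m in self.modes):
            axes.add("sources")
        return axes

    @property
    def source_group(self) -> list[int] | None:
        """Members of the (single) group whose mode requires a source."""
        for group, mode in zip(self.sets, self.modes):
            if mode in SOURCE_MODES:
                return list(group)
        return None


def sweep_duration(s: float, Ne: float) -> float:
    """Approximate fixation time of a hard sweep, ``ln(4 Ne s) / s`` generations."""
    if 4.0 * Ne * s <= 1.0:
        raise ParameterError(
            f"4*Ne*s = {4 * Ne * s:g} <= 1: sweep approximation invalid (selection too weak)"
        )
    return float(np.log(4.0 * Ne * s) / s)


def sweep_retention(r, s: float, Ne: float):
    """Probability a lineage at distance ``r`` stays on the sweeping background.

    ``y = exp(-r * t_s)`` with sweep duration ``t_s = ln(4 Ne s)/s``; equals 1
    at ``r = 0`` and decays monotonically with distance.
    """
    r = np.asarray(r, dtype=float)
    if (r < 0).any():
        raise ParameterError("recombination distance r must be >= 0")
    return np.exp(-r * sweep_duration(s, Ne))


def standing_phase_coalescence(r, g: float, t: float, Ne: float):
    """Probability two background lineages coalesce during the standing phase.

    Coalescence (rate ``kappa = 1/(2 Ne g)``) competes with either lineage
    recombining off (total rate ``2 r``) over ``t`` generations:
    ``p = kappa/(kappa + 2 r) * (1 - exp(-(kappa + 2 r) t))``.
    """
    if not (0.0 < g < 1.0):
        raise ParameterError("standing frequency g must be in (0, 1)")
    if t < 0:
        raise ParameterError("standing time t must be >= 0")
    r = np.asarray(r, dtype=float)
    kappa = 1.0 / (2.0 * Ne * g)
    total = kappa + 2.0 * r
    return (kappa / total) * -np.expm1(-total * t)


def _as_stack(F: np.ndarray, r) -> tuple[np.ndarray, np.ndarray, bool]:
    """Broadcast ``F`` to a (B, k, k) stack matching ``r``; notes scalar input."""
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    scalar = np.ndim(r) == 0
    stack = np.repeat(np.asarray(F, dtype=float)[None, :, :], r_arr.size, axis=0)
    return stack, r_arr, scalar


def _maybe_squeeze(stack: np.ndarray, scalar: bool) -> np.ndarray:
    return stack[0] if scalar else stack


def kernel_neutral(F: np.ndarray, r=0.0) -> np.ndarray:
    """Neutral mode: the coancestry matrix is unchanged at every distance."""
    stack, _, scalar = _as_stack(F, r)
    return _maybe_squeeze(stack, scalar)


def _apply_independent(stack: np.ndarray, F: np.ndarray, y: np.ndarray, S) -> None:
    y2 = y * y
    for i in S:
        stack[:, i, i] = y2 + (1.0 - y2) * F[i, i]


def kernel_independent(F: np.ndarray, r, s: float, Ne: float, S) -> np.ndarray:
    """Independent-mutations kernel: inflate selected diagonals toward 1.

    ``F'[i,i] = y^2 + (1 - y^2) F[i,i]`` for selected ``i``; everything else
    unchanged.
    """
    stack, r_arr, scalar = _as_stack(F, r)
    y = sweep_retention(r_arr, s, Ne)
    _apply_independent(stack, F, y, S)
    return _maybe_squeeze(stack, scalar)


def _apply_standing(
    stack: np.ndarray,
    F: np.ndarray,
    r_arr: np.ndarray,
    y: np.ndarray,
    g: float,
    t: float,
    Ne: float,
    S,
    with_source: bool = False,
    source: int | None = None,
) -> None:
    # Within a population, a retained pair coalesces on the standing
    # haplotype either during the local standing phase (time-limited,
    # kappa/(kappa+2r) * (1 - exp(-(kappa+2r) t))) or, having survived it
    # untouched (exp(-(kappa+2r) t)), in the ancestral population where the
    # same competition runs without a time limit; the two stages sum exactly
    # to the unbounded-time probability kappa/(kappa+2r).  Between
    # populations, each lineage must first survive its own standing phase
    # without recombining off (exp(-r t) each) before the ancestral
    # coalescent, so sharing decays with standing time.
    y2 = y * y
    kappa = 1.0 / (2.0 * Ne * g)
    p_within = kappa / (kappa + 2.0 * r_arr)
    p_between = np.exp(-2.0 * r_arr * t) * p_within
    for i in S:
        if with_source and i == source:
            stack[:, i, i] = y2 + (1.0 - y2) * F[i, i]
        else:
            stack[:, i, i] = y2 * (p_within + (1.0 - p_within) * F[i, i]) + (1.0 - y2) * F[i, i]
    for a, i in enumerate(S):
        for j in S[a + 1:]:
            val = y2 * (p_between + (1.0 - p_between) * F[i, j]) + (1.0 - y2) * F[i, j]
            stack[:, i, j] = val
            stack[:, j, i] = val


def kernel_standing(
    F: np.ndarray,
    r,
    s: float,
    g: float,
    t: float,
    Ne: float,
    S,
    with_source: bool = False,
    source: int | None = None,
) -> np.ndarray:
    """Standing-variation kernel (with or without a source population).

    Retained pairs within a selected population coalesce on the standing
    haplotype with the unbounded-time probability
    ``p = kappa / (kappa + 2 r)`` (local standing phase plus its ancestral
    continuation); pairs from different selected populations share the
    haplotype with probability ``exp(-2 r t) * p`` — each lineage must
    survive its own standing phase of ``t`` generations without recombining
    before reaching the common ancestral copy, so between-population sharing
    decays with standing time.  When ``with_source`` is set the source
    population's diagonal takes the independent-sweep form (the allele is a
    new mutation there).
    """
    if with_source:
        if source is None or source not in list(S):
            raise ParameterError("standing_source requires a source within the selected set")
    stack, r_arr, scalar = _as_stack(F, r)
    y = sweep_retention(r_arr, s, Ne)
    _apply_standing(stack, F, r_arr, y, g, t, Ne, list(S), with_source, source)
    return _maybe_squeeze(stack, scalar)


def _apply_migration(
    stack: np.ndarray,
    F: np.ndarray,
    r_arr: np.ndarray,
    y: np.ndarray,
    m: float,
    S,
    source: int,
) -> None:
    y2 = y * y
    # migrant haplotype waits ~1/m generations to establish, exposed to
    # recombination the whole time
    q = y * np.exp(-r_arr / m)
    recipients = [i for i in S if i != source]
    for i in S:
        stack[:, i, i] = y2 + (1.0 - y2) * F[i, i]
    for i in recipients:
        val = q * (y + (1.0 - y) * F[i, source]) + (1.0 - q) * F[i, source]
        stack[:, i, source] = val
        stack[:, source, i] = val
    for a, i in enumerate(recipients):
        for j in recipients[a + 1:]:
            val = q * q + (1.0 - q * q) * F[i, j]
            stack[:, i, j] = val
            stack[:, j, i] = val


def kernel_migration(
    F: np.ndarray, r, s: float, m: float, Ne: float, S, source: int
) -> np.ndarray:
    """Migration kernel: one origin in ``source``, spread to the other
    selected populations.

    All selected diagonals take the within-sweep (independent) form — a pair
    sampled in one population coalesces during its local sweep when both
    lineages are retained.  A retained recipient lineage additionally traces
    into the source with probability ``q = y exp(-r/m)``, adding
    recipient–source and recipient–recipient coancestry.
    """
    if m <= 0:
        raise ParameterError("migration rate m must be > 0")
    S = list(S)
    if source not in S:
        raise ParameterError("source must be one of the selected populations")
    stack, r_arr, scalar = _as_stack(F, r)
    y = sweep_retention(r_arr, s, Ne)
    _apply_migration(stack, F, r_arr, y, m, S, source)
    return _maybe_squeeze(stack, scalar)


def kernel_multi(F: np.ndarray, r, params: SweepParams, spec: ModeSpec) -> np.ndarray:
    """Mixed-modes kernel: apply each group's kernel to its populations.

    Groups never add coancestry across group boundaries; with a single group
    the result is bitwise identical to the corresponding single-mode kernel.
    """
    stack, r_arr, scalar = _as_stack(F, r)
    y = sweep_retention(r_arr, params.s, params.Ne)
    for group, mode in zip(spec.sets, spec.modes):
        group = list(group)
        if mode == "independent":
            _apply_independent(stack, F, y, group)
        elif mode == "standing":
            _apply_standing(stack, F, r_arr, y, params.g, params.t, params.Ne, group)
        elif mode == "standing_source":
            if params.source is None or params.source not in group:
                raise ParameterError(
                    "standing_source group requires a source population within the group"
                )
            _apply_standing(
                stack, F, r_arr, y, params.g, params.t, params.Ne, group,
                with_source=True, source=params.source,
            )
        elif mode == "migration":
            if params.source is None or params.source not in group:
                raise ParameterError(
                    "migration group requires a source population within the group"
                )
            _apply_migration(stack, F, r_arr, y, params.m, group, params.source)
        else:  # pragma: no cover - ModeSpec already validates labels
            raise ValidationError(f"unknown mode label {mode!r}")
    return _maybe_squeeze(stack, scalar)


def model_covariance(
    F: np.ndarray, r, mode: str, params: SweepParams, S, spec: ModeSpec | None = None
) -> np.ndarray:
    """Dispatch to the kernel for ``mode`` at distance(s) ``r``."""
    if mode == "neutral":
        return kernel_neutral(F, r)
    if mode == "independent":
        return kernel_independent(F, r, params.s, params.Ne, S)
    if mode == "standing":
        return kernel_standing(F, r, params.s, params.g, params.t, params.Ne, S)
    if mode == "standing_source":
        return kernel_standing(
            F, r, params.s, params.g, params.t, params.Ne, S,
            with_source=True, source=params.source,
        )
    if mode == "migration":
        return kernel_migration(F, r, params.s, params.m, params.Ne, S, params.source)
    if mode == "multi":
        if spec is None:
            raise ParameterError("multi mode requires a ModeSpec")
        return kernel_multi(F, r, params, spec)
    raise ParameterError(f"unknown mode {mode!r}")
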