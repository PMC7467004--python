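"""Shared model context, per-mode grid fits, and tidy result tables.

The context (colloquially the "barge") holds everything reused across mode
fits: the estimated neutral coancestry matrix, standardized selected-region
sites, proposed selected sites, the parameter grids and bookkeeping.  A fit
evaluates the composite log-likelihood at every point of the mode's grid and
returns one row per grid point in a fixed 10-column schema, so tables from
different modes concatenate cleanly.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coancestry import CoancestryMatrix, centering_projection, estimate_neutral_F, standardize_matrix
from .errors import ConfigError, FitError
from .io import RESULT_COLUMNS, FrequencyMatrix, RunConfig
from .kernels import ModeSpec, SweepParams, model_covariance
from .likelihood import bin_distances, composite_loglik

#: Grid axes each mode consumes, in the nested-loop order used for rows:
#: selected_sites (outer) -> sels -> migs -> times -> gs -> sources (inner).
MODE_AXES = {
    "neutral": (),
    "independent": ("sels",),
    "migration": ("sels", "migs", "sources"),
    "standing": ("sels", "times", "gs"),
    "standing_source": ("sels", "times", "gs", "sources"),
}
AXIS_ORDER = ("sels", "migs", "times", "gs", "sources")


@dataclass
class ModelContext:
    """All precomputed quantities shared by every mode fit."""

    F: CoancestryMatrix
    C: np.ndarray
    Z_sel: np.ndarray
    positions: np.ndarray
    proposed_sites: np.ndarray
    sels: np.ndarray
    migs: np.ndarray
    times: np.ndarray
    gs: np.ndarray
    sources0: list[int]
    selected_pops0: list[int]
    sample_sizes: np.ndarray
    Ne: float
    rec: float
    num_bins: int
    locus_name: str = "locus"
    cholesky: bool = True
    mode_spec: ModeSpec | None = None
    n_sites_dropped: int = 0
    _site_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def selected_pops_label(self) -> str:
        return "-".join(str(p + 1) for p in self.selected_pops0)

    @property
    def path(self) -> str:
        return "cholesky" if self.cholesky else "pseudoinverse"


def build_context(
    config: RunConfig, neutral: FrequencyMatrix, selected: FrequencyMatrix
) -> ModelContext:
    """Assemble the shared context from validated inputs.

    Estimates the neutral coancestry matrix, standardizes the selected-region
    sites (dropping monomorphic ones), and places the proposed selected sites
    uniformly from ``min(positions)`` to ``max(positions)`` when ``n_sites``
    is given, or uses ``sel_sites`` verbatim.
    """
    if neutral.n_pops != selected.n_pops:
        raise ConfigError(
            f"neutral ({neutral.n_pops}) and selected ({selected.n_pops}) matrices "
            "disagree on the number of populations"
        )
    if selected.positions is None:
        raise ConfigError("selected-region matrix requires per-site positions")
    k = neutral.n_pops
    if any(not (0 <= p < k) for p in config.selected_pops0):
        raise ConfigError("selected_pops indices out of range")
    if config.sample_sizes is not None:
        sample_sizes = np.asarray(config.sample_sizes, dtype=int)
        if sample_sizes.size != k:
            raise ConfigError(f"sample_sizes has length {sample_sizes.size}, expected {k}")
    else:
        sample_sizes = np.asarray(neutral.sample_sizes, dtype=int)
    if config.n_sites is not None and config.n_sites > selected.n_sites:
        raise ConfigError(
            f"n_sites = {config.n_sites} exceeds the number of selected-region "
            f"sites ({selected.n_sites})"
        )

    F = estimate_neutral_F(neutral)
    Z, _, usable = standardize_matrix(selected.freqs)
    Z_sel = Z[:, usable]
    positions = selected.positions[usable]
    if config.n_sites is not None:
        proposed = np.linspace(
            selected.positions.min(), selected.positions.max(), config.n_sites
        )
    else:
        proposed = np.asarray(config.sel_sites, dtype=float)

    ctx = ModelContext(
        F=F,
        C=centering_projection(k),
        Z_sel=Z_sel,
        positions=positions,
        proposed_sites=proposed,
        sels=np.asarray(config.sels, dtype=float),
        migs=np.asarray(config.migs, dtype=float),
        times=np.asarray(config.times, dtype=float),
        gs=np.asarray(config.gs, dtype=float),
        sources0=list(config.sources0),
        selected_pops0=list(config.selected_pops0),
        sample_sizes=sample_sizes,
        Ne=float(config.Ne),
        rec=float(config.rec),
        num_bins=int(config.num_bins),
        locus_name=config.locus_name,
        cholesky=config.cholesky,
        n_sites_dropped=int(selected.n_sites - usable.sum()),
    )
    if config.sets is not None:
        ctx = update_mode(ctx, config.sets, config.modes)
    return ctx


def update_mode(ctx: ModelContext, sets, modes) -> ModelContext:
    """Attach a mixed-mode specification (1-based population indices).

    All precomputed quantities are reused; only the mode specification is
    replaced, so repeated updates are cheap and the last one wins.
    """
    sets0 = [[p - 1 for p in (group if isinstance(group, (list, tuple)) else [group])]
             for group in sets]
    spec = ModeSpec(sets=sets0, modes=list(modes), selected_pops=ctx.selected_pops0)
    return replace(ctx, mode_spec=spec, _site_cache=ctx._site_cache)


def _site_bins(ctx: ModelContext, proposed_site: float):
    key = float(proposed_site)
    if key not in ctx._site_cache:
        ctx._site_cache[key] = bin_distances(
            ctx.positions, proposed_site, ctx.rec, ctx.num_bins
        )
    return ctx._site_cache[key]


def _axis_values(ctx: ModelContext, mode: str) -> dict[str, np.ndarray | list]:
    if mode == "multi":
        spec = ctx.mode_spec
        if spec is None:
            raise FitError('mode "multi" requires a mixed-mode specification (update_mode)')
        uses = spec.uses
        sources = ctx.sources0
        if "sources" in uses:
            group = spec.source_group
            sources = [s for s in ctx.sources0 if s in group]
            if not sources:
                raise FitError(
                    "no proposed source lies within the source-requiring group "
                    f"{[p + 1 for p in group]}"
                )
        return {
            "sels": ctx.sels if "sels" in uses else [None],
            "migs": ctx.migs if "migs" in uses else [None],
            "times": ctx.times if "times" in uses else [None],
            "gs": ctx.gs if "gs" in uses else [None],
            "sources": sources if "sources" in uses else [None],
        }
    if mode not in MODE_AXES:
        raise FitError(f"unknown mode {mode!r}")
    axes = MODE_AXES[mode]
    out: dict[str, np.ndarray | list] = {}
    for name in AXIS_ORDER:
        if name not in axes:
            out[name] = [None]
        elif name == "sources":
            out[name] = ctx.sources0
        else:
            out[name] = getattr(ctx, name)
    return out


def _model_label(ctx: ModelContext, mode: str) -> str:
    if mode != "multi":
        return mode
    spec = ctx.mode_spec
    mode_of = {p: m for group, m in zip(spec.sets, spec.modes) for p in group}
    return "-".join(mode_of[p] for p in sorted(ctx.selected_pops0))


def fit_mode(ctx: ModelContext, mode: str) -> pd.DataFrame:
    """Evaluate the composite log-likelihood over the mode's full grid.

    Returns a tidy table with exactly the 10 columns
    ``selected_sites, sels, migs, times, gs, sources, cle, selected_pops,
    locus_name, model`` — one row per grid point, with grid parameters the
    mode does not use left missing.  Deterministic: row order is the nested
    loop selected_sites -> sels -> migs -> times -> gs -> sources.
    """
    axes = _axis_values(ctx, mode)
    label = _model_label(ctx, mode)
    S = ctx.selected_pops0
    rows: list[tuple] = []
    for site in ctx.proposed_sites:
        bins = _site_bins(ctx, site)
        if mode == "neutral" and rows:
            # constant in the proposed site: reuse the first site's value
            rows.append((site, *rows[0][1:]))
            continue
        for sel, mig, t, g, src in itertools.product(
            axes["sels"], axes["migs"], axes["times"], axes["gs"], axes["sources"]
        ):
            params = SweepParams(Ne=ctx.Ne, s=sel, m=mig, t=t, g=g, source=src)
            cle = composite_loglik(
                ctx.Z_sel,
                ctx.sample_sizes,
                lambda r: model_covariance(ctx.F.F, r, mode, params, S, ctx.mode_spec),
                bins,
                ctx.C,
                path=ctx.path,
            )
            rows.append((site, sel, mig, t, g, src, cle))

    df = pd.DataFrame(rows, columns=["selected_sites", *AXIS_ORDER, "cle"])
    df["sources"] = df["sources"].map(lambda s: np.nan if s is None else float(s + 1))
    for col in ("sels", "migs", "times", "gs"):
        df[col] = df[col].astype(float)
    df["selected_pops"] = ctx.selected_pops_label
    df["locus_name"] = ctx.locus_name
    df["model"] = label
    return df[list(RESULT_COLUMNS)]


def mcle_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Row(s) attaining the maximum composite log-likelihood per model.

    Ties break to the first occurrence in grid order.
    """
    if len(results) == 0:
        raise FitError("empty result table")
    idx = results.groupby("model", sort=False)["cle"].idxmax()
    return results.loc[idx].reset_index(drop=True)


def profile(results: pd.DataFrame, neutral_cle: float, axis: str) -> pd.DataFrame:
    """Per-axis profile of the composite likelihood relative to neutral.

    For each model, groups rows by the value of ``axis`` and returns
    ``max(cle) - neutral_cle``, suitable for likelihood-profile plots by
    position or by any grid parameter.
    """
    if axis not in ("selected_sites", "sels", "migs", "times", "gs"):
        raise FitError(f"cannot profile over {axis!r}")
    out = []
    for model, sub in results.groupby("model", sort=False):
        sub = sub[sub[axis].notna()]
        if len(sub) == 0:
            warnings.warn(f"model {model!r} does not use axis {axis!r}; omitted")
            continue
        prof = sub.groupby(axis, sort=True)["cle"].max() - neutral_cle
        out.append(pd.DataFrame({axis: prof.index, "model": model, "mcle": prof.values}))
    if not out:
        return pd.DataFrame(columns=[axis, "model", "mcle"])
    return pd.concat(out, ignore_index=True)
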