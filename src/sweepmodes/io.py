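"""Reading and writing of frequency matrices, run configurations and results.

Frequency matrices are delimited text with populations as rows and sites as
columns.  Configurations are flat YAML key-value files whose grid vectors are
explicit lists.  Results are written as CSV with a fixed 10-column schema
(see :mod:`sweepmodes.fit`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ValidationError

#: Exact output schema, in order. Six grid-parameter columns, the composite
#: log-likelihood, and three identification columns.
RESULT_COLUMNS = (
    "selected_sites",
    "sels",
    "migs",
    "times",
    "gs",
    "sources",
    "cle",
    "selected_pops",
    "locus_name",
    "model",
)

MODES = ("neutral", "independent", "migration", "standing", "standing_source", "multi")


@dataclass
class FrequencyMatrix:
    """Sample allele frequencies for ``k`` populations at ``L`` sites.

    Parameters
    ----------
    freqs
        ``(k, L)`` array with entries in ``[0, 1]``; rows are populations.
    sample_sizes
        Haploid sample size per population (twice the number of diploid
        individuals); used as the binomial denominator of sampling noise.
    positions
        Genomic coordinate per column, required for selected-region data.
        Columns are sorted so positions are strictly increasing.
    pop_labels
        Optional row labels; defaults to ``pop1..popk``.
    """

    freqs: np.ndarray
    sample_sizes: np.ndarray | None = None
    positions: np.ndarray | None = None
    pop_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2:
            raise ValidationError("freqs must be a 2-D populations x sites matrix")
        k, n_sites = self.freqs.shape
        if not np.isfinite(self.freqs).all():
            bad = np.argwhere(~np.isfinite(self.freqs))[0]
            raise ValidationError(
                f"missing/non-finite frequency at row {bad[0] + 1}, column {bad[1] + 1}"
            )
        if (self.freqs < 0).any() or (self.freqs > 1).any():
            bad = np.argwhere((self.freqs < 0) | (self.freqs > 1))[0]
            raise ValidationError(
                f"frequency outside [0, 1] at row {bad[0] + 1}, column {bad[1] + 1}: "
                f"{self.freqs[bad[0], bad[1]]!r}"
            )
        if self.sample_sizes is None:
            self.sample_sizes = np.ones(k, dtype=int)
        self.sample_sizes = np.asarray(self.sample_sizes, dtype=int)
        if self.sample_sizes.shape != (k,):
            raise ValidationError(
                f"sample_sizes has length {self.sample_sizes.size}, expected {k}"
            )
        if (self.sample_sizes < 1).any():
            raise ValidationError("all sample sizes must be >= 1")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != (n_sites,):
                raise ValidationError(
                    f"positions has length {self.positions.size}, expected {n_sites}"
                )
            order = np.argsort(self.positions, kind="stable")
            self.positions = self.positions[order]
            self.freqs = self.freqs[:, order]
            if (np.diff(self.positions) <= 0).any():
                raise ValidationError("positions must be distinct (strictly increasing after sort)")
        if not self.pop_labels:
            self.pop_labels = [f"pop{i + 1}" for i in range(k)]
        if len(self.pop_labels) != k:
            raise ValidationError("pop_labels length does not match number of populations")

    @property
    def n_pops(self) -> int:
        return self.freqs.shape[0]

    @property
    def n_sites(self) -> int:
        return self.freqs.shape[1]


@dataclass
class RunConfig:
    """Validated run parameters shared by every mode fit.

    Population indices (``selected_pops``, ``sources``, mixed-mode ``sets``)
    are 1-based, matching how users count populations in their input rows;
    conversion to 0-based indexing happens at the model boundary.
    """

    Ne: float
    rec: float
    selected_pops: list[int]
    sels: list[float]
    migs: list[float]
    times: list[float]
    gs: list[float]
    sources: list[int]
    num_bins: int
    sample_sizes: list[int] | None = None
    n_sites: int | None = None
    sel_sites: list[float] | None = None
    locus_name: str = "locus"
    cholesky: bool = True
    sets: list[list[int]] | None = None
    modes: list[str] | None = None

    def __post_init__(self) -> None:
        if self.Ne <= 0:
            raise ConfigError("Ne must be positive")
        if self.rec <= 0:
            raise ConfigError("rec must be positive")
        if (self.n_sites is None) == (self.sel_sites is None):
            raise ConfigError("exactly one of n_sites / sel_sites must be provided")
        if self.n_sites is not None and self.n_sites < 1:
            raise ConfigError("n_sites must be a positive integer")
        if self.num_bins < 1:
            raise ConfigError("num_bins must be >= 1")
        if len(self.selected_pops) == 0:
            raise ConfigError("selected_pops must be non-empty")
        if any(m <= 0 for m in self.migs):
            raise ConfigError("migration rates must be > 0 (migs cannot contain 0)")
        if any(s <= 0 for s in self.sels):
            raise ConfigError("selection coefficients must be > 0")
        if any(not (0 < g < 1) for g in self.gs):
            raise ConfigError("standing frequencies gs must be in (0, 1)")
        if any(t < 0 for t in self.times):
            raise ConfigError("standing times must be >= 0")
        missing = [src for src in self.sources if src not in self.selected_pops]
        if missing:
            raise ConfigError(
                f"source population(s) {missing} not in selected_pops: "
                "the source must be one of the selected populations"
            )
        if (self.sets is None) != (self.modes is None):
            raise ConfigError("sets and modes must be given together")

    @property
    def selected_pops0(self) -> list[int]:
        """Selected populations as 0-based indices."""
        return [p - 1 for p in self.selected_pops]

    @property
    def sources0(self) -> list[int]:
        return [s - 1 for s in self.sources]


def read_frequency_table(
    path: str | Path,
    delimiter: str = ",",
    sample_sizes=None,
    positions=None,
) -> FrequencyMatrix:
    """Read a populations x sites allele-frequency matrix from delimited text.

    The file must be a rectangular numeric table with no header.  Positions,
    when needed, are supplied separately (``positions`` argument or
    :func:`read_positions`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = line.split(delimiter)
            row = []
            for col_no, cell in enumerate(cells, start=1):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ValidationError(
                        f"{path}: non-numeric cell at row {line_no}, column {col_no}: {cell!r}"
                    ) from None
            rows.append(row)
    if not rows:
        raise ValidationError(f"{path}: empty frequency table")
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise ValidationError(f"{path}: ragged rows (widths {sorted(widths)})")
    return FrequencyMatrix(
        np.asarray(rows, dtype=float), sample_sizes=sample_sizes, positions=positions
    )


def read_positions(path: str | Path) -> np.ndarray:
    """Read a one-column file of genomic positions."""
    vals = np.loadtxt(path, dtype=float, ndmin=1)
    return vals


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a flat YAML run configuration.

    Required keys mirror the shared parameter list: ``Ne``, ``rec``,
    ``selected_pops``, ``sels``, ``migs``, ``times``, ``gs``, ``sources``,
    ``num_bins`` and one of ``n_sites`` / ``sel_sites``.  ``locus_name``
    defaults to ``"locus"`` and ``cholesky`` to true.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping of keys to values")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    required = {
        "Ne", "rec", "selected_pops", "sels", "migs", "times", "gs", "sources", "num_bins",
    }
    missing = required - set(raw)
    if missing:
        raise ConfigError(f"{path}: missing required config keys {sorted(missing)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from None


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy result table as CSV with the exact 10-column schema."""
    if tuple(results.columns) != RESULT_COLUMNS:
        raise ValidationError(
            f"result table columns {tuple(results.columns)} != required schema {RESULT_COLUMNS}"
        )
    results.to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a result CSV written by :func:`write_results`."""
    df = pd.read_csv(
        path,
        dtype={
            "selected_sites": float, "sels": float, "migs": float, "times": float,
            "gs": float, "sources": float, "cle": float,
            "selected_pops": str, "locus_name": str, "model": str,
        },
    )
    if tuple(df.columns) != RESULT_COLUMNS:
        raise ValidationError(f"{path}: unexpected result columns {tuple(df.columns)}")
    return df
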