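"""Mid-infrared spectrum containers, CSV I/O, and resampling onto the analysis grid.

A single absorbance trace is held as a :class:`Spectrum`; a set of traces
interpolated onto a common wavenumber axis becomes a :class:`SpectralMatrix`,
the predictor block of the downstream latent-variable regression.  The default
analysis window is 1800-400 cm^-1 sampled at 250 points (descending), the
fingerprint region in which charring chemistry is expressed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import GridRangeError, ParseError, ValidationError

__all__ = [
    "Spectrum",
    "GridSpec",
    "SpectralMatrix",
    "CalibrationSet",
    "read_spectrum",
    "load_sidecar_meta",
    "resample_to_grid",
    "stack",
]


@dataclass
class GridSpec:
    """Uniform wavenumber grid, stored descending from ``high`` to ``low`` cm^-1."""

    high: float = 1800.0
    low: float = 400.0
    n_points: int = 250

    def __post_init__(self) -> None:
        if not self.high > self.low:
            raise ValidationError(f"grid high ({self.high}) must exceed low ({self.low})")
        if self.n_points < 2:
            raise ValidationError("grid needs at least 2 points")

    @property
    def axis(self) -> np.ndarray:
        return np.linspace(self.high, self.low, self.n_points)


@dataclass
class Spectrum:
    """One MIR absorbance trace on a strictly monotone wavenumber axis."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValidationError("wavenumbers and intensities must be 1-D")
        if len(self.wavenumbers) != len(self.intensities):
            raise ValidationError(
                f"axis length {len(self.wavenumbers)} != intensity length {len(self.intensities)}"
            )
        if len(self.wavenumbers) < 2:
            raise ValidationError("a spectrum needs at least 2 points")
        diffs = np.diff(self.wavenumbers)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValidationError("wavenumbers must be strictly monotone (no duplicates)")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities must be finite")

    def __len__(self) -> int:
        return len(self.wavenumbers)


@dataclass
class SpectralMatrix:
    """n_samples x n_points absorbance block sharing one wavenumber axis."""

    grid: np.ndarray
    values: np.ndarray
    sample_meta: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.grid):
            raise ValidationError(
                f"matrix has {self.values.shape[1]} columns but grid has {len(self.grid)} points"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("matrix values must be finite")
        if not self.sample_meta:
            self.sample_meta = [{} for _ in range(self.values.shape[0])]
        if len(self.sample_meta) != self.values.shape[0]:
            raise ValidationError("sample_meta length must match number of rows")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_points(self) -> int:
        return self.values.shape[1]

    def row(self, i: int) -> Spectrum:
        return Spectrum(self.grid.copy(), self.values[i].copy(), dict(self.sample_meta[i]))


@dataclass
class CalibrationSet:
    """Spectral matrix paired with known charring temperatures for one taxon."""

    matrix: SpectralMatrix
    temperatures: np.ndarray
    taxon: str = "custom"

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if len(self.temperatures) != self.matrix.n_samples:
            raise ValidationError("one temperature per calibration spectrum is required")


def _read_table(path: str | Path | io.IOBase) -> pd.DataFrame:
    """Read a CSV with comma or semicolon separator, header auto-detected."""
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
        name = str(path)
    else:
        text = path.read()
        name = "<stream>"
    sep = ";" if text.splitlines() and text.splitlines()[0].count(";") > text.splitlines()[0].count(",") else ","
    first = text.splitlines()[0].split(sep) if text.strip() else []

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    header = 0 if first and not all(_numeric(t) for t in first if t.strip()) else None
    try:
        df = pd.read_csv(io.StringIO(text), sep=sep, header=header)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{name}: {exc}") from exc
    return df


def _require_numeric(df: pd.DataFrame, name: str, skip_first_col: bool = False) -> np.ndarray:
    cols = df.columns[1:] if skip_first_col else df.columns
    block = df[cols]
    coerced = block.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & block.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{name}: non-numeric value {block.iloc[r, c]!r} at row {r + 1}, column {cols[c]!r}"
        )
    if coerced.isna().to_numpy().any():
        r, c = np.argwhere(coerced.isna().to_numpy())[0]
        raise ParseError(f"{name}: missing value at row {r + 1}, column {cols[c]!r}")
    return coerced.to_numpy(dtype=float)


def read_spectrum(
    path: str | Path,
    dialect: str = "two-column",
    meta: dict | None = None,
) -> Spectrum | list[Spectrum]:
    """Read spectra from CSV.

    ``two-column`` files carry one spectrum as wavenumber,intensity rows and
    return a single :class:`Spectrum`.  ``wide-matrix`` files carry one sample
    per row, sample id in the first column and wavenumber-labelled intensity
    columns, and return a list of :class:`Spectrum` sharing one axis.
    """
    if dialect not in ("two-column", "wide-matrix"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    name = str(path)
    df = _read_table(path)
    base_meta = dict(meta or {})
    if dialect == "two-column":
        if df.shape[1] < 2:
            raise ParseError(f"{name}: expected two columns, found {df.shape[1]}")
        arr = _require_numeric(df.iloc[:, :2], name)
        wn, inten = arr[:, 0], arr[:, 1]
        if len(np.unique(wn)) != len(wn):
            raise ValidationError(f"{name}: duplicate wavenumbers")
        return Spectrum(wn, inten, base_meta)
    # wide-matrix
    try:
        wn = np.asarray([float(c) for c in df.columns[1:]])
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{name}: wide-matrix column headers must be wavenumbers") from exc
    values = _require_numeric(df, name, skip_first_col=True)
    spectra = []
    for i in range(values.shape[0]):
        m = dict(base_meta)
        m.setdefault("sample_id", str(df.iloc[i, 0]))
        spectra.append(Spectrum(wn.copy(), values[i], m))
    return spectra


def load_sidecar_meta(path: str | Path) -> dict[str, dict]:
    """Read a sample-metadata sidecar: YAML mapping or CSV with a sample_id column.

    Returns {sample_id: {field: value, ...}} for fields such as taxon, source,
    known_temperature and stratigraphic unit.  Use with
    ``apply_sidecar_meta`` to annotate spectra read from a wide-matrix file.
    """
    import yaml

    p = Path(path)
    if p.suffix.lower() in (".yml", ".yaml"):
        data = yaml.safe_load(p.read_text()) or {}
        if not isinstance(data, dict):
            raise ParseError(f"{p}: sidecar YAML must map sample ids to metadata")
        return {str(k): dict(v or {}) for k, v in data.items()}
    df = pd.read_csv(p)
    if "sample_id" not in df.columns:
        raise ParseError(f"{p}: sidecar CSV needs a sample_id column")
    return {
        str(row["sample_id"]): {
            k: v for k, v in row.items() if k != "sample_id" and pd.notna(v)
        }
        for _, row in df.iterrows()
    }


def apply_sidecar_meta(spectra: Iterable[Spectrum], meta: dict[str, dict]) -> None:
    """Merge sidecar metadata into spectra in place, keyed by sample_id."""
    for s in spectra:
        sid = str(s.meta.get("sample_id", ""))
        if sid in meta:
            s.meta.update(meta[sid])


def resample_to_grid(s: Spectrum, g: GridSpec) -> Spectrum:
    """Linearly interpolate a spectrum onto the uniform analysis grid.

    No extrapolation: the grid must lie inside the source span.
    """
    lo, hi = float(np.min(s.wavenumbers)), float(np.max(s.wavenumbers))
    if g.low < lo or g.high > hi:
        raise GridRangeError(
            f"grid [{g.low}, {g.high}] extends beyond source span [{lo}, {hi}]"
        )
    axis = g.axis
    # np.interp wants ascending abscissae
    order = np.argsort(s.wavenumbers)
    wn_sorted = s.wavenumbers[order]
    in_sorted = s.intensities[order]
    if len(s) == g.n_points and np.array_equal(s.wavenumbers, axis):
        return Spectrum(axis, s.intensities.copy(), dict(s.meta))
    resampled = np.interp(axis[::-1], wn_sorted, in_sorted)[::-1]
    return Spectrum(axis, resampled, dict(s.meta))


def stack(spectra: Sequence[Spectrum] | Iterable[Spectrum], g: GridSpec) -> SpectralMatrix:
    """Resample spectra onto ``g`` and stack them row-wise in input order."""
    spectra = list(spectra)
    if not spectra:
        raise ValidationError("cannot stack an empty list of spectra")
    rows = [resample_to_grid(s, g) for s in spectra]
    values = np.vstack([r.intensities for r in rows])
    return SpectralMatrix(g.axis, values, [dict(r.meta) for r in rows])
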