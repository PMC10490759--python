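"""Reading, writing, resampling and normalizing Raman spectra.

A spectrum lives on a fixed, evenly spaced, ascending wavenumber grid. The
default acquisition grid is 2068 points over 170-3200 cm^-1 (the range and
pixel count of the portable spectrometer the tool targets), and intensities
are min-max normalized to [0, 1] per spectrum before any modelling.

Supported text formats: two-column CSV or whitespace-delimited tables
(wavenumber, intensity), optionally with ``#`` comment lines, and RRUFF-style
plain text (``##KEY=value`` header lines followed by ``wavenumber, intensity``
rows). No vendor binary formats.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "DEFAULT_GRID",
    "POSTURES",
    "AxisGrid",
    "Spectrum",
    "SpectraDataset",
    "SpectrumFormatError",
    "read_spectrum_table",
    "write_spectrum_table",
    "resample_to_grid",
    "min_max_normalize",
    "save_dataset",
    "load_dataset",
]

#: Measurement geometries; interference from the vessel wall depends on which
#: one was used (probing through the bottle bottom picks up the least glass
#: signal, upright/side the most).
POSTURES = ("upright", "side", "bottom")


class SpectrumFormatError(ValueError):
    """Raised when a spectrum file cannot be parsed."""


@dataclass(frozen=True)
class AxisGrid:
    """Evenly spaced ascending wavenumber axis.

    Parameters
    ----------
    start, stop : float
        First and last wavenumber (cm^-1), ``start < stop``.
    n_points : int
        Number of grid points, at least 2.
    """

    start: float
    stop: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError(f"grid start {self.start} must be < stop {self.stop}")
        if self.n_points < 2:
            raise ValueError("grid needs at least 2 points")

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.n_points)

    @property
    def step(self) -> float:
        return (self.stop - self.start) / (self.n_points - 1)

    def index_of(self, wavenumber: float) -> int:
        """Index of the grid point closest to ``wavenumber``."""
        return int(round((wavenumber - self.start) / self.step))


#: The spectrometer's native axis: 170-3200 cm^-1 sampled at 2068 pixels.
DEFAULT_GRID = AxisGrid(170.0, 3200.0, 2068)


@dataclass
class Spectrum:
    """One Raman spectrum on a fixed grid, optionally labelled.

    ``label`` is the chemical-class identifier; ``posture`` records the
    detection geometry (one of :data:`POSTURES`) when known.
    """

    grid: AxisGrid
    intensities: np.ndarray
    label: str | None = None
    posture: str | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1:
            raise ValueError("intensities must be one-dimensional")
        if len(self.intensities) != self.grid.n_points:
            raise ValueError(
                f"intensity length {len(self.intensities)} does not match grid "
                f"({self.grid.n_points} points)"
            )
        if self.posture is not None and self.posture not in POSTURES:
            raise ValueError(f"unknown posture {self.posture!r}")

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.grid.wavenumbers

    def __len__(self) -> int:
        return self.grid.n_points


def _parse_rows(lines: Iterator[tuple[int, str]]) -> tuple[np.ndarray, np.ndarray]:
    xs: list[float] = []
    ys: list[float] = []
    for lineno, raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            # plain comments and RRUFF "##KEY=value" headers alike
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise SpectrumFormatError(f"line {lineno}: expected two columns, got {line!r}")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumFormatError(f"line {lineno}: non-numeric row {line!r}") from exc
    return np.asarray(xs), np.asarray(ys)


def read_spectrum_table(
    path: str | Path,
    label: str | None = None,
    posture: str | None = None,
) -> tuple[np.ndarray, np.ndarray, Spectrum | None]:
    """Read a two-column (wavenumber, intensity) text file.

    Accepts CSV, whitespace-delimited tables and RRUFF-style plain text
    (``##KEY=value`` headers). Rows are returned sorted by ascending
    wavenumber regardless of file order.

    Returns
    -------
    wavenumbers, intensities : ndarray
        The raw (sorted) columns as stored in the file.
    spectrum : Spectrum or None
        A :class:`Spectrum` on the file's own axis if that axis is evenly
        spaced (to within 1e-6 relative step jitter), else ``None``; in either
        case the raw columns are authoritative and can be resampled with
        :func:`resample_to_grid`.
    """
    path = Path(path)
    with path.open() as fh:
        xs, ys = _parse_rows(enumerate(fh, start=1))
    if len(xs) < 2:
        raise SpectrumFormatError(f"{path}: fewer than 2 data rows")
    order = np.argsort(xs, kind="stable")
    xs, ys = xs[order], ys[order]
    spectrum = None
    steps = np.diff(xs)
    if steps.min() > 0 and np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        grid = AxisGrid(float(xs[0]), float(xs[-1]), len(xs))
        spectrum = Spectrum(grid, ys, label=label, posture=posture)
    return xs, ys, spectrum


def write_spectrum_table(spectrum: Spectrum, path: str | Path, fmt: str = "%.8g") -> None:
    """Write a spectrum as two-column CSV ``wavenumber,intensity``."""
    data = np.column_stack([spectrum.wavenumbers, spectrum.intensities])
    np.savetxt(path, data, fmt=fmt, delimiter=",")


def resample_to_grid(
    wavenumbers: np.ndarray | Spectrum,
    intensities: np.ndarray | AxisGrid | None = None,
    grid: AxisGrid = DEFAULT_GRID,
    label: str | None = None,
    posture: str | None = None,
) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid``.

    Grid points outside the source range take the nearest-edge value (linear
    interpolation with edge-hold extrapolation). Accepts either raw
    ``(wavenumbers, intensities)`` arrays or a :class:`Spectrum` plus target
    grid.
    """
    if isinstance(wavenumbers, Spectrum):
        src = wavenumbers
        if isinstance(intensities, AxisGrid):
            grid = intensities
        label = label if label is not None else src.label
        posture = posture if posture is not None else src.posture
        xs, ys = src.wavenumbers, src.intensities
    else:
        xs = np.asarray(wavenumbers, dtype=float)
        ys = np.asarray(intensities, dtype=float)
    if xs.size < 2:
        raise ValueError("need at least 2 source points to resample")
    # np.interp holds edge values outside the source range
    out = np.interp(grid.wavenumbers, xs, ys)
    return Spectrum(grid, out, label=label, posture=posture)


def min_max_normalize(spectrum: Spectrum | np.ndarray) -> Spectrum | np.ndarray:
    """Rescale intensities linearly to [0, 1] (per-spectrum min-max).

    A constant spectrum has no dynamic range; it is mapped to all zeros and a
    warning is emitted rather than raising, so batch pipelines stay alive.
    """
    if isinstance(spectrum, Spectrum):
        out = min_max_normalize(spectrum.intensities)
        return replace(spectrum, intensities=out)
    v = np.asarray(spectrum, dtype=float)
    if v.size == 0:
        raise ValueError("cannot normalize an empty spectrum")
    lo, hi = v.min(), v.max()
    if hi == lo:
        warnings.warn("constant spectrum normalized to all zeros", stacklevel=2)
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


@dataclass
class SpectraDataset:
    """A labelled collection of spectra sharing one grid.

    Stored columnar: an ``(n_spectra, n_points)`` intensity matrix plus
    parallel label and posture columns, which is both the on-disk layout and
    what the network consumes.
    """

    grid: AxisGrid
    intensities: np.ndarray
    labels: np.ndarray
    class_names: list[str]
    postures: np.ndarray | None = None
    _label_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        self.labels = np.asarray(self.labels)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D matrix")
        if self.intensities.shape[1] != self.grid.n_points:
            raise ValueError("matrix width does not match the grid")
        if len(self.labels) != len(self.intensities):
            raise ValueError("labels and intensities disagree in length")
        unknown = set(map(str, self.labels)) - set(self.class_names)
        if unknown:
            raise ValueError(f"labels not in class_names: {sorted(unknown)}")
        if self.postures is not None:
            self.postures = np.asarray(self.postures)
            if len(self.postures) != len(self.intensities):
                raise ValueError("postures and intensities disagree in length")
        self._label_index = {name: i for i, name in enumerate(self.class_names)}

    def __len__(self) -> int:
        return len(self.intensities)

    def __getitem__(self, i: int) -> Spectrum:
        posture = None if self.postures is None else str(self.postures[i])
        return Spectrum(
            self.grid,
            np.asarray(self.intensities[i], dtype=float),
            label=str(self.labels[i]),
            posture=posture,
        )

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def label_indices(self) -> np.ndarray:
        """Integer class index per spectrum, in ``class_names`` order."""
        return np.asarray([self._label_index[str(l)] for l in self.labels])

    def subset(self, indices: Sequence[int]) -> "SpectraDataset":
        idx = np.asarray(indices)
        return SpectraDataset(
            self.grid,
            self.intensities[idx],
            self.labels[idx],
            list(self.class_names),
            None if self.postures is None else self.postures[idx],
        )


def save_dataset(dataset: SpectraDataset, path: str | Path) -> None:
    """Save a dataset as a packed ``.npz`` container.

    Arrays stored: ``intensities`` (n x n_points float32), ``labels``,
    ``postures`` (strings), ``wavenumbers``, plus a JSON-encoded header with
    the grid and class names.
    """
    header = json.dumps(
        {
            "grid": {
                "start": dataset.grid.start,
                "stop": dataset.grid.stop,
                "n_points": dataset.grid.n_points,
            },
            "class_names": dataset.class_names,
        }
    )
    postures = (
        dataset.postures
        if dataset.postures is not None
        else np.array([""] * len(dataset))
    )
    arrays = {
        "header": np.array(header),
        "intensities": dataset.intensities,
        "labels": dataset.labels.astype(str),
        "postures": postures.astype(str),
        "wavenumbers": dataset.grid.wavenumbers,
    }
    # Write the zip by hand with a fixed timestamp so identical datasets
    # produce byte-identical files (np.savez embeds file mtimes).
    import io as _io
    import zipfile

    with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
        for name, arr in arrays.items():
            buf = _io.BytesIO()
            np.lib.format.write_array(buf, np.asarray(arr), allow_pickle=False)
            info = zipfile.ZipInfo(name + ".npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())


def load_dataset(path: str | Path) -> SpectraDataset:
    """Load a dataset saved by :func:`save_dataset`."""
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        grid = AxisGrid(**header["grid"])
        postures = z["postures"]
        if all(p == "" for p in postures):
            postures = None
        return SpectraDataset(
            grid,
            z["intensities"],
            z["labels"],
            list(header["class_names"]),
            postures,
        )
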