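"""Calibration, normalization, spectral similarity and CSV I/O for labeled spectra.

The in-memory exchange object throughout the package is :class:`SpectraSet`:
a matrix of reflectance spectra on a shared wavelength grid, optionally
paired with leaf water potential labels (Psi_leaf, MPa, negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_N_BANDS",
    "DEFAULT_WAVELENGTH_RANGE_NM",
    "WavelengthGrid",
    "Spectrum",
    "RawFrames",
    "SpectraSet",
    "calibrate_reflectance",
    "max_abs_normalize",
    "spectral_angle",
    "read_spectra_csv",
    "write_spectra_csv",
]

#: Band count and span of the push-broom imager the default grid emulates.
DEFAULT_N_BANDS = 176
DEFAULT_WAVELENGTH_RANGE_NM = (393.7, 1001.4)

PROVENANCE_MEASURED = "measured"
PROVENANCE_CGAN = "cgan_generated"


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelengths in nm shared by all spectra of a set."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("wavelength grid must be a nonempty 1-D array")
        if not np.all(np.diff(values) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "values", values)

    @property
    def n_bands(self) -> int:
        return int(self.values.size)

    @classmethod
    def default(cls) -> "WavelengthGrid":
        lo, hi = DEFAULT_WAVELENGTH_RANGE_NM
        return cls(np.linspace(lo, hi, DEFAULT_N_BANDS))

    def __eq__(self, other: object) -> bool:  # frozen dataclass + ndarray field
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and np.allclose(
            self.values, other.values
        )

    def __hash__(self) -> int:
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))


@dataclass
class Spectrum:
    """A single reflectance spectrum on a wavelength grid."""

    grid: WavelengthGrid
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.reflectance, dtype=float)
        if r.ndim != 1 or r.size != self.grid.n_bands:
            raise ValueError(
                f"reflectance length {r.size} != grid length {self.grid.n_bands}"
            )
        if not np.all(np.isfinite(r)):
            raise ValueError("reflectance must be finite")
        self.reflectance = r


@dataclass
class RawFrames:
    """Raw sensor intensities for reflectance calibration.

    ``original``, ``white`` and ``dark`` are per-band intensity vectors of
    the sample, the white reference panel and the closed-shutter dark frame;
    ``panel_reflectance`` is the (near-unity) reflectance of the panel.
    """

    original: np.ndarray
    white: np.ndarray
    dark: np.ndarray
    panel_reflectance: float = 1.0

    def __post_init__(self) -> None:
        self.original = np.asarray(self.original, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if not (self.original.shape == self.white.shape == self.dark.shape):
            raise ValueError(
                "original/white/dark frames must have equal shapes, got "
                f"{self.original.shape}, {self.white.shape}, {self.dark.shape}"
            )


@dataclass
class SpectraSet:
    """A labeled (or unlabeled) collection of spectra on one grid.

    ``psi`` holds leaf water potential in MPa (non-positive) or ``None`` for
    unlabeled sets. ``provenance`` flags each row as ``"measured"`` or
    ``"cgan_generated"``.
    """

    grid: WavelengthGrid
    spectra: np.ndarray
    psi: np.ndarray | None = None
    sample_ids: list[str] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        s = np.asarray(self.spectra, dtype=float)
        if s.ndim != 2 or s.shape[1] != self.grid.n_bands:
            raise ValueError(
                f"spectra shape {s.shape} incompatible with {self.grid.n_bands}-band grid"
            )
        self.spectra = s
        n = s.shape[0]
        if self.psi is not None:
            psi = np.asarray(self.psi, dtype=float)
            if psi.shape != (n,):
                raise ValueError(f"psi length {psi.shape} != n_samples {n}")
            if np.any(psi > 0):
                raise ValueError("leaf water potential must be <= 0 MPa")
            self.psi = psi
        if not self.sample_ids:
            self.sample_ids = [f"s{i:04d}" for i in range(n)]
        elif len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")
        if not self.provenance:
            self.provenance = [PROVENANCE_MEASURED] * n
        elif len(self.provenance) != n:
            raise ValueError("provenance length mismatch")

    @property
    def n_samples(self) -> int:
        return int(self.spectra.shape[0])

    @property
    def is_labeled(self) -> bool:
        return self.psi is not None

    def subset(self, indices) -> "SpectraSet":
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(
            grid=self.grid,
            spectra=self.spectra[idx].copy(),
            psi=None if self.psi is None else self.psi[idx].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            provenance=[self.provenance[i] for i in idx],
        )

    def concat(self, other: "SpectraSet") -> "SpectraSet":
        if self.grid != other.grid:
            raise ValueError("cannot concatenate sets on different wavelength grids")
        if (self.psi is None) != (other.psi is None):
            raise ValueError("cannot concatenate labeled with unlabeled set")
        return SpectraSet(
            grid=self.grid,
            spectra=np.vstack([self.spectra, other.spectra]),
            psi=None if self.psi is None else np.concatenate([self.psi, other.psi]),
            sample_ids=list(self.sample_ids) + list(other.sample_ids),
            provenance=list(self.provenance) + list(other.provenance),
        )


def calibrate_reflectance(frames: RawFrames) -> Spectrum:
    """Convert raw intensities to reflectance with white/dark references.

    R_c = (I_o - I_d) / (I_w - I_d) * R_w, elementwise per band, where R_w is
    the reflectance of the white reference panel (about 100%). Negative
    outputs (possible under sensor noise) are clipped to zero; values above
    one are kept, since a sample may out-reflect the panel at some band.
    """
    denom = frames.white - frames.dark
    zero = np.flatnonzero(denom == 0)
    if zero.size:
        raise ValueError(
            f"white minus dark is zero at band index {int(zero[0])}; cannot calibrate"
        )
    r = (frames.original - frames.dark) / denom * frames.panel_reflectance
    r = np.clip(r, 0.0, None)
    n = r.size
    if n == DEFAULT_N_BANDS:
        grid = WavelengthGrid.default()
    else:
        lo, hi = DEFAULT_WAVELENGTH_RANGE_NM
        grid = WavelengthGrid(np.linspace(lo, hi, n))
    return Spectrum(grid=grid, reflectance=r)


def max_abs_normalize(x: np.ndarray, axis: int | None = -1) -> np.ndarray:
    """Scale by the maximum absolute value so the largest magnitude becomes 1.

    With ``axis=-1`` on a 2-D array each spectrum (row) is scaled by its own
    max-abs; ``axis=0`` normalizes per band instead; ``axis=None`` uses one
    global factor. Idempotent. Raises on an all-zero slice.
    """
    x = np.asarray(x, dtype=float)
    m = np.max(np.abs(x), axis=axis, keepdims=axis is not None)
    if np.any(m == 0):
        raise ValueError("cannot max-abs normalize an all-zero spectrum")
    return x / m


def spectral_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Spectral Angle Mapper: angle in radians between two spectra.

    Scale-invariant similarity in [0, pi]; 0 means identical shapes.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("spectral angle undefined for a zero spectrum")
    cos = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.arccos(cos))


def _band_columns(grid: WavelengthGrid) -> list[str]:
    return [f"r{w:.1f}" for w in grid.values]


def write_spectra_csv(sset: SpectraSet, path, unit: str = "MPa") -> None:
    """Write a SpectraSet to CSV (`sample_id, psi_mpa, r393.7, ...`).

    ``unit`` controls the label column on disk: "MPa" writes ``psi_mpa``,
    "bar" writes ``psi_bar`` (1 MPa = 10 bar).
    """
    cols = {"sample_id": sset.sample_ids}
    if sset.psi is not None:
        if unit == "MPa":
            cols["psi_mpa"] = sset.psi
        elif unit == "bar":
            cols["psi_bar"] = sset.psi * 10.0
        else:
            raise ValueError(f"unknown unit {unit!r}; expected 'MPa' or 'bar'")
    cols["provenance"] = sset.provenance
    df = pd.DataFrame(cols)
    bands = pd.DataFrame(sset.spectra, columns=_band_columns(sset.grid))
    pd.concat([df, bands], axis=1).to_csv(path, index=False)


def read_spectra_csv(path, grid: WavelengthGrid | None = None) -> SpectraSet:
    """Read a spectra CSV written by :func:`write_spectra_csv`.

    Band columns are named by wavelength (``r393.7`` ...), so the grid is
    self-describing; pass ``grid`` to enforce an expected one. A missing
    psi column yields an unlabeled set. Labels in a ``psi_bar`` column are
    converted to MPa on load.
    """
    df = pd.read_csv(path)
    band_cols = [c for c in df.columns if c.startswith("r") and c[1:2].isdigit()]
    if not band_cols:
        raise ValueError("no band columns (r<wavelength>) found")
    wavelengths = np.array([float(c[1:]) for c in band_cols])
    file_grid = WavelengthGrid(wavelengths)
    if grid is not None and file_grid != grid:
        raise ValueError(
            f"file has {file_grid.n_bands} bands, expected {grid.n_bands}"
        )
    spectra = df[band_cols].to_numpy(dtype=float)
    psi = None
    if "psi_mpa" in df.columns:
        psi = df["psi_mpa"].to_numpy(dtype=float)
    elif "psi_bar" in df.columns:
        psi = df["psi_bar"].to_numpy(dtype=float) / 10.0
    ids = (
        df["sample_id"].astype(str).tolist()
        if "sample_id" in df.columns
        else []
    )
    prov = df["provenance"].astype(str).tolist() if "provenance" in df.columns else []
    return SpectraSet(
        grid=file_grid, spectra=spectra, psi=psi, sample_ids=ids, provenance=prov
    )
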