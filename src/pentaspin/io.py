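"""Plain-text interchange formats for pulse-EPR traces and distance distributions.

The on-disk trace format is deliberately simple so that spectrometer exports
(converted upstream from vendor formats) can be dropped in::

    #freq_GHz: 34.0
    #g_value: 2.006
    #tau_ns: 140
    #label: TbF88R1_ND
    # time  real  [imag]
    0.000   1.0000
    0.008   0.9987
    ...

DEER traces carry time in microseconds, ESEEM traces in nanoseconds; the unit
is recorded in the header (``#time_unit``) and enforced by the pipelines.
Distance distributions are two columns, distance (nm) and probability density
(1/nm), normalised to unit trapezoid integral.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("pentaspin")

__all__ = [
    "TimeTrace",
    "DistanceDistribution",
    "PipelineError",
    "read_trace",
    "write_trace",
    "read_distribution",
    "write_distribution",
]

#: metadata applied when a trace file carries no header
DEFAULT_META = {"freq_GHz": 9.5, "g_value": 2.006}


class PipelineError(ValueError):
    """Raised on invalid inputs or unusable data anywhere in the pipeline."""


def _check_axis(axis: np.ndarray) -> None:
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 2:
        raise PipelineError("time axis must be 1-D with at least two points")
    steps = np.diff(axis)
    if np.any(steps <= 0):
        bad = int(np.argmax(steps <= 0))
        raise PipelineError(f"time axis not strictly increasing at index {bad + 1}")
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=0.0):
        raise PipelineError("time axis must be uniformly sampled (1e-6 rel. tol.)")


@dataclass
class TimeTrace:
    """A sampled pulse-EPR signal with acquisition metadata.

    Parameters
    ----------
    axis : ndarray
        Time values, strictly increasing and uniform. Microseconds for DEER,
        nanoseconds for ESEEM (recorded in ``meta['time_unit']``).
    real : ndarray
        Real (in-phase) channel.
    imag : ndarray, optional
        Imaginary (quadrature) channel.
    meta : dict
        Acquisition metadata: ``freq_GHz``, ``g_value``, ``tau_ns`` (ESEEM),
        free-form ``label``.
    """

    axis: np.ndarray
    real: np.ndarray
    imag: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.real = np.asarray(self.real, dtype=float)
        _check_axis(self.axis)
        if self.real.shape != self.axis.shape:
            raise PipelineError("real channel and axis must have the same length")
        if not np.all(np.isfinite(self.real)):
            bad = np.flatnonzero(~np.isfinite(self.real))
            raise PipelineError(f"non-finite signal values at rows {bad[:5].tolist()}")
        if self.imag is not None:
            self.imag = np.asarray(self.imag, dtype=float)
            if self.imag.shape != self.axis.shape:
                raise PipelineError("imaginary channel and axis must have the same length")

    @property
    def dt(self) -> float:
        """Sampling step (same unit as the axis)."""
        return float(self.axis[1] - self.axis[0])

    @property
    def complex(self) -> np.ndarray:
        im = self.imag if self.imag is not None else np.zeros_like(self.real)
        return self.real + 1j * im

    def copy(self, **updates) -> "TimeTrace":
        kw = dict(
            axis=self.axis.copy(),
            real=self.real.copy(),
            imag=None if self.imag is None else self.imag.copy(),
            meta=dict(self.meta),
        )
        kw.update(updates)
        return TimeTrace(**kw)


@dataclass
class DistanceDistribution:
    """Probability density P(r) on a uniform distance grid (nm)."""

    r: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        _check_axis(self.r)
        if self.density.shape != self.r.shape:
            raise PipelineError("density and r grid must have the same length")
        if np.any(self.density < 0):
            raise PipelineError("distance distribution density must be non-negative")

    @property
    def dr(self) -> float:
        return float(self.r[1] - self.r[0])

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.r))

    def normalized(self) -> "DistanceDistribution":
        z = self.integral()
        if z <= 0:
            raise PipelineError("cannot normalize an all-zero distribution")
        return DistanceDistribution(self.r.copy(), self.density / z)

    def mean(self) -> float:
        return float(np.trapezoid(self.r * self.density, self.r) / self.integral())


# ---------------------------------------------------------------------------
# text formats


def _parse_meta_value(raw: str):
    raw = raw.strip()
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    return raw


def read_trace(path, dialect: str = "auto") -> TimeTrace:
    """Read a plain-text time trace.

    ``dialect`` is one of ``auto``, ``two-column``, ``three-column``,
    ``headered`` (``#key: value`` metadata lines before the columns).
    Missing acquisition metadata is filled with defaults
    (9.5 GHz, g = 2.006) with a warning.
    """
    meta: dict = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = _parse_meta_value(val)
                continue
            parts = line.split()
            try:
                values = [float(p) for p in parts]
            except ValueError as exc:
                raise PipelineError(f"{path}: unparseable data at line {lineno}: {line!r}") from exc
            if np.any(~np.isfinite(values)):
                raise PipelineError(f"{path}: NaN/inf value at line {lineno}")
            rows.append(values)
    if not rows:
        raise PipelineError(f"{path}: no data rows (header-only or empty file)")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise PipelineError(f"{path}: inconsistent column count")
    if dialect == "two-column" and ncol != 2:
        raise PipelineError(f"{path}: expected 2 columns, found {ncol}")
    if dialect == "three-column" and ncol != 3:
        raise PipelineError(f"{path}: expected 3 columns, found {ncol}")
    if ncol not in (2, 3):
        raise PipelineError(f"{path}: expected 2 or 3 columns, found {ncol}")
    data = np.asarray(rows, dtype=float)
    for key, val in DEFAULT_META.items():
        if key not in meta:
            warnings.warn(f"{path}: no '{key}' in header, defaulting to {val}", stacklevel=2)
            meta[key] = val
    imag = data[:, 2] if ncol == 3 else None
    return TimeTrace(axis=data[:, 0], real=data[:, 1], imag=imag, meta=meta)


def write_trace(trace: TimeTrace, path) -> None:
    with open(path, "w") as fh:
        for key, val in trace.meta.items():
            fh.write(f"#{key}: {val}\n")
        for i, t in enumerate(trace.axis):
            cols = [f"{t:.12g}", f"{trace.real[i]:.12g}"]
            if trace.imag is not None:
                cols.append(f"{trace.imag[i]:.12g}")
            fh.write("  ".join(cols) + "\n")


def read_distribution(path) -> DistanceDistribution:
    """Read a two-column (r_nm, density) distribution; renormalise with a
    warning if the stored integral drifts from 1 by more than 1e-3."""
    data_rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise PipelineError(f"{path}: expected 2 columns at line {lineno}")
            data_rows.append([float(p) for p in parts])
    if not data_rows:
        raise PipelineError(f"{path}: empty distribution file")
    data = np.asarray(data_rows, dtype=float)
    pr = DistanceDistribution(data[:, 0], data[:, 1])
    z = pr.integral()
    if abs(z - 1.0) > 1e-3:
        warnings.warn(f"{path}: integral {z:.6g} != 1, renormalizing", stacklevel=2)
        pr = pr.normalized()
    return pr


def write_distribution(pr: DistanceDistribution, path) -> None:
    pr = pr.normalized()
    with open(path, "w") as fh:
        fh.write("# r_nm  density_per_nm\n")
        for r, p in zip(pr.r, pr.density):
            fh.write(f"{r:.12g}  {p:.12g}\n")
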