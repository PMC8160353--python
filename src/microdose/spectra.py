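"""Microdosimetric formalism: lineal-energy histograms and their mean values.

Lineal energy ``y`` is the energy imparted to a micrometric site by a single
event divided by the site's mean chord length (keV/um).  A beam at a point is
characterized by the probability density ``f(y)``, its dose-weighted
counterpart ``d(y) = y f(y) / integral(y f(y) dy)``, and three scalar
summaries:

* the frequency-mean lineal energy  ``y_F = E[y]``,
* the dose-mean lineal energy       ``y_D = E[y^2] / E[y]``,
* the saturation-corrected dose-mean lineal energy (Kase form)

  .. math::

     \\bar{y}^* = y_0^2 \\,
        \\frac{\\int (1 - e^{-(y/y_0)^2})\\, f(y)\\, dy}{\\int y f(y)\\, dy}

  which damps contributions far above the saturation parameter ``y_0``
  (overkill correction) and reduces to ``y_D`` when all events are well
  below ``y_0``.

Spectra are binned on a logarithmic grid; the standard TEPC analysis grid is
150 bins covering 7 decades starting at 0.01 keV/um.  Moments computed from a
histogram use the geometric bin midpoint as the representative value; when raw
events are available the exact sample moments are used instead, avoiding a
second discretization.

All histogram moments are implemented as ratios of weighted sums, so they are
invariant under a global rescaling of ``f`` — a property the resampling stage
relies on, since perturbed replicate spectra are not renormalized.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateInputError, DomainError, ParseError

__all__ = [
    "LogBinGrid",
    "EventSample",
    "LinealEnergySpectrum",
    "MicrodosimetricSummary",
    "SummarySource",
    "make_log_grid",
    "histogram_events",
    "normalize",
    "dose_distribution",
    "y_frequency_mean",
    "y_dose_mean",
    "y_saturation_corrected",
    "summarize",
    "write_spectrum",
    "read_spectrum",
    "write_events",
    "read_events",
]

log = logging.getLogger(__name__)

#: text-format float precision (9 significant digits, round-trip stable)
_FMT = "%.9g"

#: mean chord of a sphere under mu-randomness: 4V/S = (2/3) d
SPHERE_CHORD_FACTOR = 2.0 / 3.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogBinGrid:
    """Geometric (log-uniform) binning of lineal energy.

    ``edges`` has ``n_bins + 1`` strictly increasing entries with a constant
    ratio ``10**(n_decades/n_bins)``; ``edges[0] == y_min`` and
    ``edges[-1] == y_min * 10**n_decades``.
    """

    y_min: float
    n_decades: float
    n_bins: int
    edges: np.ndarray = field(repr=False)

    @property
    def midpoints(self) -> np.ndarray:
        """Geometric bin midpoints sqrt(edge_i * edge_{i+1})."""
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def ratio(self) -> float:
        """Constant edge ratio 10**(n_decades/n_bins)."""
        return 10.0 ** (self.n_decades / self.n_bins)


@dataclass(frozen=True)
class EventSample:
    """Raw single-event lineal energies for one site.

    The energy imparted per event is recoverable as ``epsilon = y * mean_chord``
    (keV).  For a spherical site traversed under mu-randomness the mean chord
    is ``(2/3) * diameter``.
    """

    y: np.ndarray
    site_diameter: float = 1.0
    mean_chord: float | None = None

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "y", y)
        if self.site_diameter <= 0:
            raise DomainError("site_diameter must be positive")
        if self.mean_chord is None:
            object.__setattr__(self, "mean_chord", SPHERE_CHORD_FACTOR * self.site_diameter)
        if self.mean_chord <= 0:
            raise DomainError("mean_chord must be positive")
        if y.size and not np.all(y > 0):
            raise DomainError("all lineal energies must be strictly positive")

    @property
    def n_events(self) -> int:
        return int(self.y.size)

    @property
    def energies_imparted(self) -> np.ndarray:
        """Per-event energy imparted epsilon = y * mean_chord (keV)."""
        return self.y * self.mean_chord


@dataclass(frozen=True)
class LinealEnergySpectrum:
    """Log-binned ``f(y)`` histogram with per-bin standard errors.

    ``f`` is a frequency density (per keV/um); ``sigma`` is the standard error
    of each bin's density (same units) or ``None`` when unknown.  Out-of-range
    events encountered during histogramming are tallied in ``underflow`` /
    ``overflow`` rather than silently dropped.
    """

    grid: LogBinGrid
    f: np.ndarray
    sigma: np.ndarray | None = None
    n_events: int = 0
    normalized: bool = False
    underflow: int = 0
    overflow: int = 0
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        f = np.asarray(self.f, dtype=float)
        object.__setattr__(self, "f", f)
        if f.shape != (self.grid.n_bins,):
            raise DomainError(
                f"f has {f.shape} entries, grid has {self.grid.n_bins} bins")
        if np.any(f < 0):
            raise DomainError("f must be non-negative")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", s)
            if s.shape != f.shape:
                raise DomainError("sigma must have the same shape as f")
            if np.any(s < 0):
                raise DomainError("sigma must be non-negative")

    @property
    def integral(self) -> float:
        """sum_i f_i * dy_i (1 for a normalized spectrum)."""
        return float(np.sum(self.f * self.grid.widths))


class SummarySource(enum.Enum):
    EVENTS = "events"
    HISTOGRAM = "histogram"


@dataclass(frozen=True)
class MicrodosimetricSummary:
    """Scalar summary of one spectrum: y_F <= y_D and 0 < y* <= y_D."""

    y_F: float
    y_D: float
    y_star: float
    source: SummarySource


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def make_log_grid(y_min: float = 0.01, n_decades: float = 7,
                  n_bins: int = 150) -> LogBinGrid:
    """Build a geometric lineal-energy grid.

    Defaults reproduce the standard TEPC analysis grid: 150 bins from
    0.01 keV/um over 7 decades (up to 1e5 keV/um).
    """
    if y_min <= 0:
        raise DomainError("y_min must be positive")
    if n_decades <= 0:
        raise DomainError("n_decades must be positive")
    if n_bins < 1:
        raise DomainError("n_bins must be at least 1")
    exponents = n_decades * np.arange(n_bins + 1) / n_bins
    edges = y_min * 10.0 ** exponents
    return LogBinGrid(y_min=float(y_min), n_decades=float(n_decades),
                      n_bins=int(n_bins), edges=edges)


def histogram_events(events: EventSample, grid: LogBinGrid) -> LinealEnergySpectrum:
    """Bin single-event lineal energies into a normalized density f(y).

    Per-bin density ``f_i = count_i / (n * dy_i)`` and Poisson standard error
    ``sigma_i = sqrt(count_i) / (n * dy_i)`` with ``n`` the number of in-range
    events.  Events outside the grid are counted in the underflow/overflow
    tallies and excluded from the normalization (a warning is logged).
    """
    if events.n_events == 0:
        raise DegenerateInputError("cannot histogram an empty event sample")
    y = events.y
    under = int(np.count_nonzero(y < grid.edges[0]))
    over = int(np.count_nonzero(y >= grid.edges[-1]))
    counts, _ = np.histogram(y, bins=grid.edges)
    # np.histogram includes the right edge in the last bin; treat it as overflow
    counts[-1] -= int(np.count_nonzero(y == grid.edges[-1]))
    n_in = int(counts.sum())
    if under or over:
        log.warning("histogram_events: %d underflow / %d overflow events "
                    "outside [%g, %g) excluded from normalization",
                    under, over, grid.edges[0], grid.edges[-1])
    if n_in == 0:
        raise DegenerateInputError("no events fall inside the grid")
    widths = grid.widths
    f = counts / (n_in * widths)
    sigma = np.sqrt(counts) / (n_in * widths)
    return LinealEnergySpectrum(grid=grid, f=f, sigma=sigma, n_events=n_in,
                                normalized=True, underflow=under, overflow=over)


def normalize(spec: LinealEnergySpectrum) -> LinealEnergySpectrum:
    """Rescale f (and sigma) so that sum_i f_i dy_i = 1."""
    total = spec.integral
    if total <= 0:
        raise DegenerateInputError("cannot normalize an all-zero spectrum")
    sigma = None if spec.sigma is None else spec.sigma / total
    return replace(spec, f=spec.f / total, sigma=sigma, normalized=True)


def dose_distribution(spec: LinealEnergySpectrum) -> np.ndarray:
    """Per-bin dose density d_i = y_i f_i / sum_j y_j f_j dy_j.

    Uses the geometric bin midpoint for y_i; the result integrates to 1.
    """
    mids = spec.grid.midpoints
    widths = spec.grid.widths
    first_moment = float(np.sum(mids * spec.f * widths))
    if first_moment <= 0:
        raise DegenerateInputError("spectrum has zero first moment")
    return mids * spec.f / first_moment


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------

def _hist_weights(spec: LinealEnergySpectrum):
    w = spec.f * spec.grid.widths
    total = float(w.sum())
    if total <= 0:
        raise DegenerateInputError("spectrum is all zero")
    return spec.grid.midpoints, w


def y_frequency_mean(data: EventSample | LinealEnergySpectrum) -> float:
    """Frequency-mean lineal energy y_F = E[y] (keV/um)."""
    if isinstance(data, EventSample):
        if data.n_events == 0:
            raise DegenerateInputError("empty event sample")
        return float(np.mean(data.y))
    mids, w = _hist_weights(data)
    return float(np.sum(mids * w) / np.sum(w))


def y_dose_mean(data: EventSample | LinealEnergySpectrum) -> float:
    """Dose-mean lineal energy y_D = E[y^2] / E[y] (keV/um)."""
    if isinstance(data, EventSample):
        if data.n_events == 0:
            raise DegenerateInputError("empty event sample")
        m1 = float(np.mean(data.y))
        if m1 <= 0:
            raise DegenerateInputError("zero first moment")
        return float(np.mean(data.y ** 2) / m1)
    mids, w = _hist_weights(data)
    m1 = float(np.sum(mids * w))
    if m1 <= 0:
        raise DegenerateInputError("zero first moment")
    return float(np.sum(mids ** 2 * w) / m1)


def y_saturation_corrected(data: EventSample | LinealEnergySpectrum,
                           y0: float = 150.0) -> float:
    """Saturation-corrected dose-mean lineal energy ybar* (keV/um).

    Kase form: ``y0^2 * E[1 - exp(-(y/y0)^2)] / E[y]``.  Satisfies
    ``0 < ybar* <= y_D``; tends to ``y_D`` as ``y0 -> inf`` and to
    ``y0^2 / y_F`` when all events are far above ``y0``.
    """
    if y0 <= 0:
        raise DomainError("saturation parameter y0 must be positive")
    if isinstance(data, EventSample):
        if data.n_events == 0:
            raise DegenerateInputError("empty event sample")
        y = data.y
        num = float(np.mean(-np.expm1(-((y / y0) ** 2))))
        den = float(np.mean(y))
    else:
        mids, w = _hist_weights(data)
        num = float(np.sum(-np.expm1(-((mids / y0) ** 2)) * w) / np.sum(w))
        den = float(np.sum(mids * w) / np.sum(w))
    if den <= 0:
        raise DegenerateInputError("zero first moment")
    return y0 ** 2 * num / den


def summarize(data: EventSample | LinealEnergySpectrum,
              y0: float = 150.0) -> MicrodosimetricSummary:
    """Compute y_F, y_D and ybar* in one pass; prefers the exact event path."""
    source = (SummarySource.EVENTS if isinstance(data, EventSample)
              else SummarySource.HISTOGRAM)
    return MicrodosimetricSummary(
        y_F=y_frequency_mean(data),
        y_D=y_dose_mean(data),
        y_star=y_saturation_corrected(data, y0),
        source=source,
    )


# ---------------------------------------------------------------------------
# file formats (tab-separated text with '#' metadata headers)
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return _FMT % x


def write_spectrum(path, spec: LinealEnergySpectrum,
                   extra_header: dict | None = None) -> None:
    """Write a spectrum file: '#' headers then y_low, y_high, f, sigma columns."""
    header = {
        "y_min": spec.grid.y_min,
        "n_decades": spec.grid.n_decades,
        "n_bins": spec.grid.n_bins,
        "n_events": spec.n_events,
        "normalized": int(spec.normalized),
        "underflow": spec.underflow,
        "overflow": spec.overflow,
    }
    if "mean_chord" in spec.meta:
        header["mean_chord"] = spec.meta["mean_chord"]
    if extra_header:
        header.update(extra_header)
    sigma = spec.sigma if spec.sigma is not None else np.zeros_like(spec.f)
    with open(path, "w") as fh:
        fh.write("# microdose spectrum v1\n")
        for k, v in header.items():
            v = _fmt(v) if isinstance(v, float) else v
            fh.write(f"# {k}={v}\n")
        fh.write("# columns: y_low\ty_high\tf\tsigma\n")
        e = spec.grid.edges
        for i in range(spec.grid.n_bins):
            fh.write("\t".join(_fmt(v) for v in
                               (e[i], e[i + 1], spec.f[i], sigma[i])) + "\n")


def read_spectrum(path) -> LinealEnergySpectrum:
    """Read a spectrum file written by :func:`write_spectrum`.

    The grid is reconstructed from the y_min / n_decades / n_bins header
    entries; malformed content raises :class:`ParseError` with a line number.
    """
    header: dict[str, str] = {}
    rows: list[tuple[float, float, float, float]] = []
    path_s = str(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, _, v = body.partition("=")
                    header[k.strip()] = v.strip()
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"expected 4 tab-separated columns, got {len(parts)}",
                                 path_s, lineno)
            try:
                rows.append(tuple(float(p) for p in parts))
            except ValueError:
                raise ParseError(f"non-numeric value in {parts!r}", path_s, lineno)
    for key in ("y_min", "n_decades", "n_bins"):
        if key not in header:
            raise ParseError(f"missing required header '# {key}='", path_s)
    try:
        grid = make_log_grid(float(header["y_min"]), float(header["n_decades"]),
                             int(header["n_bins"]))
    except (ValueError, DomainError) as exc:
        raise ParseError(f"invalid grid header: {exc}", path_s)
    if len(rows) != grid.n_bins:
        raise ParseError(f"expected {grid.n_bins} data rows, found {len(rows)}", path_s)
    data = np.array(rows, dtype=float)
    meta = {k: v for k, v in header.items()
            if k not in ("y_min", "n_decades", "n_bins", "n_events",
                         "normalized", "underflow", "overflow")}
    if "mean_chord" in meta:
        meta["mean_chord"] = float(meta["mean_chord"])
    return LinealEnergySpectrum(
        grid=grid, f=data[:, 2], sigma=data[:, 3],
        n_events=int(header.get("n_events", 0)),
        normalized=bool(int(header.get("normalized", 0))),
        underflow=int(header.get("underflow", 0)),
        overflow=int(header.get("overflow", 0)),
        meta=meta,
    )


def write_events(path, events: EventSample,
                 extra_header: dict | None = None) -> None:
    """Write an event file: one lineal energy (keV/um) per line."""
    with open(path, "w") as fh:
        fh.write("# microdose events v1\n")
        fh.write(f"# site_diameter={_fmt(events.site_diameter)}\n")
        fh.write(f"# mean_chord={_fmt(events.mean_chord)}\n")
        fh.write(f"# n={events.n_events}\n")
        if extra_header:
            for k, v in extra_header.items():
                fh.write(f"# {k}={v}\n")
        for y in events.y:
            fh.write(_fmt(y) + "\n")


def read_events(path) -> EventSample:
    """Read an event file written by :func:`write_events`."""
    header: dict[str, str] = {}
    ys: list[float] = []
    path_s = str(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, _, v = body.partition("=")
                    header[k.strip()] = v.strip()
                continue
            try:
                ys.append(float(line))
            except ValueError:
                raise ParseError(f"non-numeric lineal energy {line!r}", path_s, lineno)
    if not ys:
        raise ParseError("event file contains no events", path_s)
    diameter = float(header.get("site_diameter", 1.0))
    chord = float(header["mean_chord"]) if "mean_chord" in header else None
    return EventSample(y=np.array(ys), site_diameter=diameter, mean_chord=chord)


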