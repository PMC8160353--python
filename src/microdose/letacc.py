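"""Per-voxel dose and unrestricted dose-averaged LET accumulation.

The dose-averaged LET in a voxel is

    Ld = integral( S_el(E) D(E) dE ) / integral( D(E) dE )

with ``S_el`` the electronic stopping power.  Operationally it is tallied
step by step: every charged step depositing ``E_d`` (keV) at kinetic energy
``E_k`` contributes ``E_d * S_el(E_k)`` to a numerator sum and ``E_d`` to a
denominator sum in its voxel; the ratio at the end of the pass is ``Ld``.

Statistical uncertainty on the voxel dose uses the history-by-history
estimator (relative standard error of the mean over primary histories); the
relative uncertainty on ``Ld`` is approximated as twice the dose uncertainty,
since the dose enters the ratio twice.  Voxels below a configurable fraction
of the maximum dose (default 0.1%) are masked as statistically unreliable.

Voxel indexing is 0-based ``(ix, iy, iz)`` with z varying fastest in flat
order.  Before summation the step log is brought into a canonical order, so
the tally is bit-identical under any permutation of the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import ConfigurationError, DegenerateInputError, DomainError, ParseError

__all__ = [
    "StoppingPowerTable",
    "StepDeposit",
    "VoxelTally",
    "MaskedProfile",
    "lookup_stopping_power",
    "accumulate",
    "dose_uncertainty",
    "let_uncertainty",
    "mask_low_dose",
    "analytic_dose_averaged_let",
    "read_stopping_power",
    "write_step_log",
    "read_step_log",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StoppingPowerTable:
    """Electronic stopping power vs kinetic energy for one particle kind.

    ``energy`` (MeV) strictly increasing, ``s_el`` (keV/um) positive.
    Interpolation between rows is linear in log-log space, the standard choice
    for stopping-power tables which are close to power laws piecewise.
    """

    particle_kind: str
    energy: np.ndarray
    s_el: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energy, dtype=float)
        s = np.asarray(self.s_el, dtype=float)
        object.__setattr__(self, "energy", e)
        object.__setattr__(self, "s_el", s)
        if e.size < 2 or e.size != s.size:
            raise DomainError("stopping-power table needs >= 2 (E, S_el) rows")
        if np.any(np.diff(e) <= 0):
            raise DomainError("table energies must be strictly increasing")
        if np.any(e <= 0) or np.any(s <= 0):
            raise DomainError("table energies and stopping powers must be positive")


@dataclass(frozen=True)
class StepDeposit:
    """One simulation step: energy deposited in a voxel by one particle."""

    voxel_index: tuple[int, int, int]
    history_id: int
    particle_kind: str
    kinetic_energy: float   # MeV
    deposited_energy: float  # keV
    is_charged: bool = True

    def __post_init__(self):
        if self.deposited_energy < 0:
            raise DomainError("deposited energy must be non-negative")
        if self.is_charged and self.kinetic_energy <= 0:
            raise DomainError("charged steps need a positive kinetic energy")


@dataclass
class VoxelTally:
    """Accumulated per-voxel sums; ``let`` is defined only where dose > 0."""

    shape: tuple[int, ...]
    sum_ed: np.ndarray        # keV, LET denominator (charged steps)
    sum_ed_s: np.ndarray      # keV * keV/um, LET numerator
    dose: np.ndarray          # keV, all deposited energy (masking/uncertainty)
    sum_x2: np.ndarray        # sum over histories of (per-history dose)^2
    n_histories: int
    let_step_min: np.ndarray = field(default=None, repr=False)
    let_step_max: np.ndarray = field(default=None, repr=False)

    @property
    def let(self) -> np.ndarray:
        """Dose-averaged LET Ld = sum(Ed*S)/sum(Ed), NaN where undefined."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.sum_ed > 0, self.sum_ed_s / np.maximum(self.sum_ed, 1e-300), np.nan)


@dataclass(frozen=True)
class MaskedProfile:
    """Dose/LET maps with low-dose voxels flagged; underlying sums untouched."""

    dose: np.ndarray
    let: np.ndarray
    mask: np.ndarray  # True where the voxel is masked out
    fraction: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def lookup_stopping_power(table: StoppingPowerTable, energy):
    """Interpolate S_el(E) log-log; clamp (with a warning) outside the table."""
    e = np.asarray(energy, dtype=float)
    if np.any(e <= 0):
        raise DomainError("kinetic energy must be positive")
    lo, hi = table.energy[0], table.energy[-1]
    n_out = int(np.count_nonzero((e < lo) | (e > hi)))
    if n_out:
        log.warning("lookup_stopping_power(%s): %d energies outside table range "
                    "[%g, %g] MeV clamped to end values",
                    table.particle_kind, n_out, lo, hi)
    s = np.exp(np.interp(np.log(e), np.log(table.energy), np.log(table.s_el)))
    return float(s) if e.ndim == 0 else s


def _canonical_order(steps: list[StepDeposit]) -> list[StepDeposit]:
    return sorted(steps, key=lambda s: (s.voxel_index, s.history_id, s.particle_kind,
                                        s.kinetic_energy, s.deposited_energy,
                                        s.is_charged))


def accumulate(steps: Iterable[StepDeposit],
               tables: Mapping[str, StoppingPowerTable],
               shape: tuple[int, ...],
               kinds: Iterable[str] | None = None,
               n_histories: int | None = None) -> VoxelTally:
    """Tally per-voxel dose and dose-averaged-LET sums from a step log.

    All steps contribute deposited energy to the dose map; charged steps
    (optionally restricted to ``kinds``, e.g. the primary particle only)
    additionally contribute ``E_d * S_el(E_k)`` to the LET sums.  The result
    is independent of the order of the input stream.

    ``n_histories`` defaults to the number of distinct history ids in the log;
    pass the true number of simulated primaries when some deposited nothing.
    """
    steps = _canonical_order(list(steps))
    kinds = None if kinds is None else set(kinds)
    nvox = int(np.prod(shape))
    sum_ed = np.zeros(nvox)
    sum_ed_s = np.zeros(nvox)
    dose = np.zeros(nvox)
    smin = np.full(nvox, np.inf)
    smax = np.full(nvox, -np.inf)
    hist_dose: dict[tuple[int, int], float] = {}
    histories: set[int] = set()

    for st in steps:
        try:
            flat = int(np.ravel_multi_index(st.voxel_index, shape))
        except ValueError:
            raise DomainError(f"voxel index {st.voxel_index} outside grid {shape}")
        histories.add(st.history_id)
        dose[flat] += st.deposited_energy
        key = (flat, st.history_id)
        hist_dose[key] = hist_dose.get(key, 0.0) + st.deposited_energy
        if not st.is_charged:
            continue
        if kinds is not None and st.particle_kind not in kinds:
            continue
        table = tables.get(st.particle_kind)
        if table is None:
            raise ConfigurationError(
                f"no stopping-power table for particle kind '{st.particle_kind}'")
        s_el = lookup_stopping_power(table, st.kinetic_energy)
        sum_ed[flat] += st.deposited_energy
        sum_ed_s[flat] += st.deposited_energy * s_el
        if st.deposited_energy > 0:
            smin[flat] = min(smin[flat], s_el)
            smax[flat] = max(smax[flat], s_el)

    sum_x2 = np.zeros(nvox)
    for (flat, _), x in sorted(hist_dose.items()):
        sum_x2[flat] += x * x

    return VoxelTally(
        shape=tuple(shape),
        sum_ed=sum_ed.reshape(shape),
        sum_ed_s=sum_ed_s.reshape(shape),
        dose=dose.reshape(shape),
        sum_x2=sum_x2.reshape(shape),
        n_histories=int(n_histories if n_histories is not None else len(histories)),
        let_step_min=smin.reshape(shape),
        let_step_max=smax.reshape(shape),
    )


def dose_uncertainty(tally: VoxelTally) -> np.ndarray:
    """History-by-history relative standard error of the per-voxel dose.

    sigma_rel = sqrt((sum x_h^2 / N - (sum x_h / N)^2) / (N - 1)) / mean(x),
    with x_h the energy deposited by history h and N the history count.
    Exactly 0 where all histories deposited identically; NaN where no dose.
    """
    n = tally.n_histories
    if n < 2:
        raise DegenerateInputError("need at least 2 histories for an uncertainty")
    mean = tally.dose / n
    var = (tally.sum_x2 / n - mean ** 2) / (n - 1)
    var = np.maximum(var, 0.0)  # guard float cancellation
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(mean > 0, np.sqrt(var) / np.maximum(mean, 1e-300), np.nan)
    return rel


def let_uncertainty(dose_rel_err):
    """Relative uncertainty on Ld: exactly twice the dose relative error."""
    return 2.0 * np.asarray(dose_rel_err, dtype=float)


def mask_low_dose(tally: VoxelTally, fraction: float = 0.001) -> MaskedProfile:
    """Flag voxels whose dose is below ``fraction`` of the maximum dose.

    Masked voxels get NaN in the returned dose/LET maps; the tally's sums are
    left untouched.  The default 0.1% threshold suppresses the large
    end-of-range fluctuations of the Ld ratio.
    """
    if fraction < 0:
        raise DomainError("mask fraction must be non-negative")
    dmax = float(tally.dose.max(initial=0.0))
    if dmax <= 0:
        raise DegenerateInputError("tally holds no dose; nothing to mask")
    mask = tally.dose < fraction * dmax
    dose = np.where(mask, np.nan, tally.dose)
    let = np.where(mask, np.nan, tally.let)
    return MaskedProfile(dose=dose, let=let, mask=mask, fraction=fraction)


def analytic_dose_averaged_let(spectrum, table: StoppingPowerTable) -> float:
    """Continuous-form Ld: sum(w_i * S_el(E_i)) / sum(w_i) over (E, dose-weight).

    Serves as the quadrature oracle for :func:`accumulate` on synthetic step
    logs drawn from the same spectrum.
    """
    pairs = list(spectrum)
    if not pairs:
        raise DegenerateInputError("empty spectrum")
    e = np.array([p[0] for p in pairs], dtype=float)
    w = np.array([p[1] for p in pairs], dtype=float)
    if np.any(w < 0):
        raise DomainError("dose weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise DegenerateInputError("all dose weights are zero")
    return float(np.sum(w * lookup_stopping_power(table, e)) / total)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_stopping_power(path, particle_kind: str) -> StoppingPowerTable:
    """Read a two-column (E [MeV], S_el [keV/um]) text table; '#' lines ignored."""
    energies, s_els = [], []
    path_s = str(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"expected 2 columns, got {len(parts)}", path_s, lineno)
            try:
                energies.append(float(parts[0]))
                s_els.append(float(parts[1]))
            except ValueError:
                raise ParseError(f"non-numeric row {parts!r}", path_s, lineno)
    if len(energies) < 2:
        raise ParseError("stopping-power table needs at least 2 rows", path_s)
    return StoppingPowerTable(particle_kind, np.array(energies), np.array(s_els))


_STEP_COLUMNS = "ix\tiy\tiz\thistory\tkind\tE_MeV\tEd_keV\tcharged"


def write_step_log(path, steps: Iterable[StepDeposit], shape: tuple[int, ...],
                   extra_header: dict | None = None) -> None:
    """Write a tab-separated step log with the grid shape in the header."""
    with open(path, "w") as fh:
        fh.write("# microdose steplog v1\n")
        fh.write("# shape=" + " ".join(str(s) for s in shape) + "\n")
        fh.write("# voxel order: 0-based (ix iy iz), z fastest in flat order\n")
        if extra_header:
            for k, v in extra_header.items():
                fh.write(f"# {k}={v}\n")
        fh.write(f"# columns: {_STEP_COLUMNS}\n")
        for s in steps:
            ix, iy, iz = s.voxel_index
            fh.write(f"{ix}\t{iy}\t{iz}\t{s.history_id}\t{s.particle_kind}\t"
                     f"{s.kinetic_energy:.9g}\t{s.deposited_energy:.9g}\t"
                     f"{int(s.is_charged)}\n")


def read_step_log(path) -> tuple[list[StepDeposit], tuple[int, ...]]:
    """Read a step log; returns (steps, grid shape)."""
    steps: list[StepDeposit] = []
    shape: tuple[int, ...] | None = None
    path_s = str(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("shape="):
                    try:
                        shape = tuple(int(t) for t in body[len("shape="):].split())
                    except ValueError:
                        raise ParseError(f"bad shape header {body!r}", path_s, lineno)
                continue
            parts = line.split("\t")
            if len(parts) != 8:
                raise ParseError(f"expected 8 columns, got {len(parts)}", path_s, lineno)
            try:
                steps.append(StepDeposit(
                    voxel_index=(int(parts[0]), int(parts[1]), int(parts[2])),
                    history_id=int(parts[3]),
                    particle_kind=parts[4],
                    kinetic_energy=float(parts[5]),
                    deposited_energy=float(parts[6]),
                    is_charged=bool(int(parts[7])),
                ))
            except (ValueError, DomainError) as exc:
                raise ParseError(f"bad step row: {exc}", path_s, lineno)
    if shape is None:
        raise ParseError("missing '# shape=' header", path_s)
    if not steps:
        raise ParseError("step log contains no steps", path_s)
    return steps, shape
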