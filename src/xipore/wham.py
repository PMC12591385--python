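"""Umbrella sampling datasets, a WHAM solver, and a surrogate sampler.

The weighted histogram analysis method (WHAM) combines biased histograms
from harmonic umbrella windows into one unbiased free-energy profile
F(xi) (a potential of mean force, PMF).  With window biases
``U_i(xi) = 0.5 k_i (xi - c_i)^2``, per-window sample counts ``n_i(b)``
on a common bin grid and sample totals ``N_i``, the self-consistent
equations are

    P(b)  propto  sum_i n_i(b) / sum_j N_j exp[(f_j - U_j(xi_b)) / kT]
    f_j   =  -kT ln sum_b P(b) exp(-U_j(xi_b) / kT)

iterated until the shifts ``f_j`` stop moving; then
``F(b) = -kT ln P(b)``, re-anchored to zero at its minimum.

The module follows the model/results idiom: :class:`WHAM` is built from
an :class:`UmbrellaDataset`, its :meth:`WHAM.fit` returns a
:class:`PMFProfile` carrying the profile, window shifts, convergence
diagnostics and a :meth:`PMFProfile.summary` table.
:func:`sample_surrogate` generates synthetic window samples by
Metropolis sampling over a known free-energy curve, which makes
end-to-end recovery testable without any molecular dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, List, Sequence

import numpy as np

from .protocol import WindowGrid

__all__ = [
    "KB_KJ_PER_MOL_K",
    "UmbrellaWindow",
    "UmbrellaDataset",
    "PMFProfile",
    "WHAM",
    "CoverageError",
    "wham_solve",
    "sample_surrogate",
    "convergence_series",
    "delta_g",
    "replica_mean_se",
    "write_umbrella_dataset",
    "read_umbrella_dataset",
]

KB_KJ_PER_MOL_K = 0.0083144626  # Boltzmann constant, kJ/mol/K

#: samples must stay within the physically meaningful coordinate range
XI_DOMAIN = (0.0, 1.2)


class CoverageError(ValueError):
    """Adjacent umbrella windows do not share any occupied bin."""


@dataclass
class UmbrellaWindow:
    """One umbrella window: center, force constant, and its xi samples."""

    center: float
    force_constant: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.force_constant <= 0:
            raise ValueError("force constant must be positive")
        if self.samples.size == 0:
            raise ValueError("window sample series is empty")
        if self.samples.min() < XI_DOMAIN[0] - 1e-9 or self.samples.max() > XI_DOMAIN[1] + 1e-9:
            raise ValueError(f"samples outside the xi domain {XI_DOMAIN}")

    def bias(self, xi: np.ndarray) -> np.ndarray:
        return 0.5 * self.force_constant * (np.asarray(xi) - self.center) ** 2


@dataclass
class UmbrellaDataset:
    """Per-window xi sample series plus the sampling temperature."""

    windows: List[UmbrellaWindow]
    temperature: float = 310.0

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValueError("dataset has no windows")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kt(self) -> float:
        return KB_KJ_PER_MOL_K * self.temperature

    def truncated(self, fraction: float) -> "UmbrellaDataset":
        """Dataset using only the first ``fraction`` of each window's samples."""
        if not 0.0 < fraction <= 1.0:
            raise ValueError("fraction must lie in (0, 1]")
        windows = []
        for w in self.windows:
            n = int(round(fraction * len(w.samples)))
            if n == 0:
                raise CoverageError(
                    f"fraction {fraction} leaves window at {w.center} empty"
                )
            windows.append(UmbrellaWindow(w.center, w.force_constant, w.samples[:n]))
        return UmbrellaDataset(windows=windows, temperature=self.temperature)


@dataclass
class PMFProfile:
    """Fitted free-energy profile and WHAM diagnostics.

    ``free_energy`` is NaN on bins with zero total count; finite bins
    are anchored so the profile minimum is exactly zero.
    """

    bin_centers: np.ndarray
    free_energy: np.ndarray
    probability: np.ndarray
    f_shifts: np.ndarray
    window_centers: np.ndarray
    n_iterations: int
    converged: bool
    temperature: float
    max_shift_change: float = np.nan

    def interpolate(self, xi: float) -> float:
        """Linearly interpolated free energy at ``xi`` (finite bins only)."""
        ok = np.isfinite(self.free_energy)
        x = self.bin_centers[ok]
        if not len(x) or xi < x[0] - 1e-9 or xi > x[-1] + 1e-9:
            raise ValueError(f"xi = {xi} outside the profile support [{x[0]}, {x[-1]}]")
        return float(np.interp(xi, x, self.free_energy[ok]))

    def summary(self) -> str:
        ok = np.isfinite(self.free_energy)
        lines = [
            "WHAM potential of mean force",
            "=" * 44,
            f"temperature        {self.temperature:10.1f} K",
            f"windows            {len(self.f_shifts):10d}",
            f"bins (occupied)    {int(ok.sum()):10d} / {len(self.bin_centers)}",
            f"iterations         {self.n_iterations:10d}",
            f"converged          {str(self.converged):>10s}",
            f"max |delta f|      {self.max_shift_change:10.3e} kJ/mol",
            f"support            [{self.bin_centers[ok][0]:.3f}, {self.bin_centers[ok][-1]:.3f}]",
            f"max free energy    {np.nanmax(self.free_energy):10.2f} kJ/mol",
            "=" * 44,
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Write the profile as two-column text (xi, kJ/mol), NaN rows dropped."""
        ok = np.isfinite(self.free_energy)
        np.savetxt(path, np.column_stack([self.bin_centers[ok], self.free_energy[ok]]),
                   fmt="%.6f", header="xi free_energy_kJ_per_mol", comments="# ")


class WHAM:
    """WHAM model over an :class:`UmbrellaDataset`.

    Parameters
    ----------
    data : UmbrellaDataset
    n_bins : int
        Histogram bins over ``bin_range`` (bins with zero global count
        are masked in the result, not zero-filled).
    bin_range : (lo, hi)
        Coordinate range of the histogram grid.
    """

    def __init__(self, data: UmbrellaDataset, n_bins: int = 200,
                 bin_range: tuple[float, float] = (0.15, 1.05)) -> None:
        self.data = data
        self.n_bins = int(n_bins)
        self.bin_range = (float(bin_range[0]), float(bin_range[1]))
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        edges = np.linspace(self.bin_range[0], self.bin_range[1], self.n_bins + 1)
        self.bin_edges = edges
        self.bin_centers = 0.5 * (edges[:-1] + edges[1:])
        # per-window histograms on the common grid
        self.counts = np.stack([
            np.histogram(w.samples, bins=edges)[0].astype(np.float64)
            for w in data.windows
        ])
        self.n_samples = self.counts.sum(axis=1)
        clipped = sum(
            int(np.sum((w.samples < edges[0]) | (w.samples > edges[-1])))
            for w in data.windows
        )
        if clipped:
            total = int(sum(len(w.samples) for w in data.windows))
            if clipped > 0.01 * total:
                raise ValueError(
                    f"{clipped} of {total} samples fall outside the bin range {bin_range}"
                )
        self._check_coverage()

    def _check_coverage(self) -> None:
        order = np.argsort([w.center for w in self.data.windows])
        occupied = [set(np.flatnonzero(self.counts[i] > 0)) for i in order]
        centers = [self.data.windows[i].center for i in order]
        for a, b in zip(range(len(order) - 1), range(1, len(order))):
            if not occupied[a] & occupied[b]:
                raise CoverageError(
                    f"windows at xi = {centers[a]:.3f} and {centers[b]:.3f} share no "
                    "occupied histogram bin"
                )

    def fit(self, tolerance: float = 1e-6, max_iterations: int = 100000) -> PMFProfile:
        """Iterate the WHAM equations to self-consistency.

        ``tolerance`` is the convergence threshold on the maximum change
        of any window shift ``f_j`` per iteration, in kJ/mol.  A profile
        that hits the iteration cap is returned with
        ``converged=False`` rather than raising.
        """
        kt = self.data.kt
        # bias energy of every window at every bin center, (windows, bins)
        bias = np.stack([w.bias(self.bin_centers) for w in self.data.windows])
        log_n_total = np.log(self.counts.sum(axis=0).clip(min=1e-300))
        occupied = self.counts.sum(axis=0) > 0
        log_N = np.log(self.n_samples)

        f = np.zeros(len(self.data.windows))
        max_change = np.inf
        iteration = 0
        for iteration in range(1, max_iterations + 1):
            # log denominator per bin: logsumexp_j [log N_j + (f_j - U_j(b))/kT]
            a = log_N[:, None] + (f[:, None] - bias) / kt
            a_max = a.max(axis=0)
            log_denom = a_max + np.log(np.exp(a - a_max).sum(axis=0))
            log_p = np.where(occupied, log_n_total - log_denom, -np.inf)
            # normalize
            finite = np.isfinite(log_p)
            m = log_p[finite].max()
            log_z = m + math.log(np.exp(log_p[finite] - m).sum())
            log_p = log_p - log_z
            # new shifts: f_j = -kT logsumexp_b [log P(b) - U_j(b)/kT]
            b_mat = log_p[None, :] - bias / kt
            b_max = np.max(np.where(np.isfinite(b_mat), b_mat, -np.inf), axis=1)
            f_new = -kt * (b_max + np.log(
                np.exp(np.clip(b_mat - b_max[:, None], -700, 0)).sum(axis=1)
            ))
            f_new = f_new - f_new[0]
            max_change = float(np.max(np.abs(f_new - f)))
            f = f_new
            if max_change <= tolerance:
                break

        free = np.where(occupied, -kt * log_p, np.nan)
        free = free - np.nanmin(free)
        prob = np.where(occupied, np.exp(log_p), 0.0)
        return PMFProfile(
            bin_centers=self.bin_centers.copy(),
            free_energy=free,
            probability=prob,
            f_shifts=f,
            window_centers=np.array([w.center for w in self.data.windows]),
            n_iterations=iteration,
            converged=max_change <= tolerance,
            temperature=self.data.temperature,
            max_shift_change=max_change,
        )


def wham_solve(data: UmbrellaDataset, n_bins: int = 200, tolerance: float = 1e-6,
               bin_range: tuple[float, float] = (0.15, 1.05),
               max_iterations: int = 100000) -> PMFProfile:
    """One-call WHAM: build the model and fit it."""
    return WHAM(data, n_bins=n_bins, bin_range=bin_range).fit(
        tolerance=tolerance, max_iterations=max_iterations
    )


def sample_surrogate(
    pmf_true: Callable[[float], float],
    grid: WindowGrid,
    n_samples: int = 5000,
    seed: int = 0,
    temperature: float = 310.0,
    n_burnin: int = 1000,
    thin: int = 10,
) -> UmbrellaDataset:
    """Metropolis-sample umbrella windows over a known free-energy curve.

    For each window the chain targets ``pmf_true(xi) + 0.5 k (xi - c)^2``
    at the given temperature.  The Gaussian proposal width is auto-tuned
    during burn-in toward a 20-50% acceptance rate, and one sample is
    recorded every ``thin`` steps — the surrogate analogue of saving
    umbrella-window configurations at fixed time intervals rather than
    every integration step.  Fully reproducible from the seed.
    """
    if thin < 1:
        raise ValueError("thin must be at least 1")
    if n_samples < 100:
        raise ValueError("n_samples must be at least 100")
    kt = KB_KJ_PER_MOL_K * temperature
    rng = np.random.default_rng(seed)
    windows: List[UmbrellaWindow] = []
    for center, k in zip(grid.centers, grid.force_constants):
        def energy(x: float) -> float:
            return pmf_true(x) + 0.5 * k * (x - center) ** 2

        width = 2.0 * math.sqrt(kt / k)
        x = float(center)
        e = energy(x)
        # burn-in with width adaptation in blocks
        block = max(50, n_burnin // 10)
        done = 0
        while done < n_burnin:
            accepted = 0
            for _ in range(block):
                prop = x + rng.normal(0.0, width)
                if XI_DOMAIN[0] <= prop <= XI_DOMAIN[1]:
                    e_prop = energy(prop)
                    if e_prop <= e or rng.uniform() < math.exp(-(e_prop - e) / kt):
                        x, e = prop, e_prop
                        accepted += 1
            rate = accepted / block
            if rate < 0.2:
                width /= 1.4
            elif rate > 0.5:
                width *= 1.4
            done += block
        samples = np.empty(n_samples)
        for i in range(n_samples):
            for _ in range(thin):
                prop = x + rng.normal(0.0, width)
                if XI_DOMAIN[0] <= prop <= XI_DOMAIN[1]:
                    e_prop = energy(prop)
                    if e_prop <= e or rng.uniform() < math.exp(-(e_prop - e) / kt):
                        x, e = prop, e_prop
            samples[i] = x
        windows.append(UmbrellaWindow(center=float(center), force_constant=float(k),
                                      samples=samples))
    return UmbrellaDataset(windows=windows, temperature=temperature)


def convergence_series(data: UmbrellaDataset, fractions: Sequence[float],
                       n_bins: int = 200,
                       bin_range: tuple[float, float] = (0.15, 1.05)) -> List[PMFProfile]:
    """PMFs from growing prefixes of each window's samples.

    Mirrors convergence-versus-cumulative-sampling-time analysis: one
    profile per fraction, each using the first ``fraction`` of every
    window's series.
    """
    fracs = list(fractions)
    if any(f2 <= f1 for f1, f2 in zip(fracs, fracs[1:])) or not fracs:
        raise ValueError("fractions must be nonempty and strictly increasing")
    if fracs[0] <= 0 or fracs[-1] > 1:
        raise ValueError("fractions must lie in (0, 1]")
    return [wham_solve(data.truncated(f), n_bins=n_bins, bin_range=bin_range)
            for f in fracs]


def delta_g(profile_a: PMFProfile, profile_b: PMFProfile, xi_eval: float = 1.0) -> float:
    """Free-energy difference ``F_a(xi) - F_b(xi)`` between two profiles.

    Each profile is anchored at its own minimum (as fitted), so this is
    the pore-formation free-energy difference when both profiles share
    the flat-membrane minimum near xi = 0.2.
    """
    return profile_a.interpolate(xi_eval) - profile_b.interpolate(xi_eval)


def replica_mean_se(profiles: Sequence[PMFProfile]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise mean and standard error across replica profiles.

    Returns (bin_centers, mean, standard error); bins missing in any
    replica are NaN.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two replicas")
    centers = profiles[0].bin_centers
    for p in profiles[1:]:
        if not np.allclose(p.bin_centers, centers):
            raise ValueError("replica profiles must share a bin grid")
    stack = np.stack([p.free_energy for p in profiles])
    mean = np.mean(stack, axis=0)
    se = np.std(stack, axis=0, ddof=1) / math.sqrt(len(profiles))
    return centers, mean, se


# ---------------------------------------------------------------------------
# plain-text umbrella dataset layout
# ---------------------------------------------------------------------------

def write_umbrella_dataset(data: UmbrellaDataset, directory: str | Path,
                           save_interval: float = 0.1) -> Path:
    """Write per-window (time, xi) files plus a metadata index.

    Layout: ``window_XX.dat`` two-column text per window and a
    ``windows.meta`` file listing ``filename center force_constant``
    per line with the temperature in the header.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta_lines = [f"# temperature_K {data.temperature}"]
    for i, w in enumerate(data.windows):
        fname = f"window_{i:02d}.dat"
        times = np.arange(len(w.samples)) * save_interval
        np.savetxt(directory / fname, np.column_stack([times, w.samples]),
                   fmt="%.6f", header="time_ns xi", comments="# ")
        meta_lines.append(f"{fname} {w.center:.6f} {w.force_constant:.6f}")
    meta = directory / "windows.meta"
    meta.write_text("\n".join(meta_lines) + "\n")
    return meta


def read_umbrella_dataset(meta_path: str | Path) -> UmbrellaDataset:
    """Read an umbrella dataset from its ``windows.meta`` index file."""
    meta_path = Path(meta_path)
    directory = meta_path.parent
    temperature = 310.0
    windows: List[UmbrellaWindow] = []
    for line in meta_path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if len(parts) == 2 and parts[0] == "temperature_K":
                temperature = float(parts[1])
            continue
        fname, center, k = line.split()
        arr = np.loadtxt(directory / fname, ndmin=2)
        windows.append(UmbrellaWindow(center=float(center), force_constant=float(k),
                                      samples=arr[:, 1]))
    return UmbrellaDataset(windows=windows, temperature=temperature)
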