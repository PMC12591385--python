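"""Long-time-scale pore equilibration scheduling and umbrella window grids.

Pore formation in cholesterol-containing and thick RBC-mimetic bilayers
is too slow for plain steered pulls, so window extraction is preceded by
a long hold at an intermediate defect size ``xi_long``: pull the
nucleation coordinate from the flat value 0.2 to ``xi_long`` over 50 ns,
hold for 5 microseconds, and check for peptide pore lining at the
decision time ``t_cutoff`` = 5.05 us.  If no peptide lines the defect,
restart with ``xi_long`` raised by 0.025.  Once lining is observed, the
defect is grown by alternating 50 ns pulls and 500 ns holds at each
multiple of 0.1 above ``xi_long`` until the full pore at xi = 1.0, where
windows are extracted (no hold after the final pull).

This module only *plans*: it emits explicit, testable phase schedules
and window grids.  Executing a plan on synthetic data means carving
pores and generating toy frames per phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Sequence

import numpy as np

__all__ = [
    "ProtocolPhase",
    "ProtocolSchedule",
    "WindowGrid",
    "plan_equilibration",
    "next_xi_long",
    "run_xi_long_search",
    "make_window_grid",
    "SearchExhaustedError",
]

PULL_DURATION_NS = 50.0
LONG_HOLD_NS = 5000.0
STEP_HOLD_NS = 500.0
HARMONIC_K = 30000.0  # kJ/mol, maintained across the equilibration run
XI_FLAT = 0.2
XI_LONG_START = 0.7
XI_LONG_INCREMENT = 0.025


class SearchExhaustedError(RuntimeError):
    """The xi_long search reached the full-pore bound without success."""


@dataclass(frozen=True)
class ProtocolPhase:
    """One pull or hold phase of the equilibration schedule."""

    kind: str            # "pull" | "hold"
    xi_start: float
    xi_end: float
    duration: float      # ns
    force_constant: float = HARMONIC_K

    def __post_init__(self) -> None:
        if self.kind not in ("pull", "hold"):
            raise ValueError("phase kind must be 'pull' or 'hold'")
        if self.duration <= 0:
            raise ValueError("phase duration must be positive")
        if self.kind == "pull" and not self.xi_end > self.xi_start:
            raise ValueError("pull phases must increase xi")
        if self.kind == "hold" and self.xi_start != self.xi_end:
            raise ValueError("hold phases must keep xi constant")


@dataclass(frozen=True)
class ProtocolSchedule:
    """Ordered phases of one long-time-scale equilibration run."""

    phases: tuple[ProtocolPhase, ...]
    xi_long: float

    @property
    def total_time(self) -> float:
        """Total scheduled simulation time in ns."""
        return sum(p.duration for p in self.phases)

    @property
    def t_cutoff(self) -> float:
        """Pore-lining decision time: first pull plus the first hold, ns."""
        return self.phases[0].duration + self.phases[1].duration

    def describe(self) -> str:
        lines = [f"xi_long = {self.xi_long:.3f}"]
        t = 0.0
        for p in self.phases:
            t += p.duration
            lines.append(
                f"  {p.kind:<4s} xi {p.xi_start:.3f} -> {p.xi_end:.3f}  "
                f"{p.duration:8.1f} ns  (cumulative {t:8.1f} ns)"
            )
        lines.append(f"total {self.total_time:.1f} ns; t_cutoff {self.t_cutoff:.1f} ns")
        return "\n".join(lines)


def plan_equilibration(xi_long: float) -> ProtocolSchedule:
    """Build the pull/hold schedule for a given ``xi_long``.

    50 ns pull from 0.2 to ``xi_long``, a 5 us hold, then for every
    multiple of 0.1 strictly above ``xi_long`` up to 1.0 a 50 ns pull
    followed by a 500 ns hold — except after the final pull to 1.0,
    which is the window-extraction point and has no hold.  For
    ``xi_long`` in [0.7, 0.775] this totals 6.2 us; in [0.8, 0.875],
    5.65 us; ``t_cutoff`` is always 5.05 us.
    """
    if not XI_FLAT < xi_long < 1.0:
        raise ValueError("xi_long must lie strictly between 0.2 and 1.0")
    phases: List[ProtocolPhase] = [
        ProtocolPhase("pull", XI_FLAT, xi_long, PULL_DURATION_NS),
        ProtocolPhase("hold", xi_long, xi_long, LONG_HOLD_NS),
    ]
    targets = [round(0.1 * k, 10) for k in range(1, 11)
               if 0.1 * k > xi_long + 1e-9 and 0.1 * k <= 1.0 + 1e-9]
    prev = xi_long
    for i, tgt in enumerate(targets):
        phases.append(ProtocolPhase("pull", prev, tgt, PULL_DURATION_NS))
        if tgt < 1.0 - 1e-9:
            phases.append(ProtocolPhase("hold", tgt, tgt, STEP_HOLD_NS))
        prev = tgt
    return ProtocolSchedule(phases=tuple(phases), xi_long=xi_long)


def next_xi_long(current: float) -> float:
    """Raise xi_long by one search increment (0.025), rounded to 3 decimals."""
    if current >= 1.0:
        raise ValueError("current xi_long must be below 1.0")
    nxt = round(current + XI_LONG_INCREMENT, 3)
    if nxt >= 1.0:
        raise SearchExhaustedError(
            f"xi_long search exhausted: {current:.3f} + {XI_LONG_INCREMENT} reaches 1.0"
        )
    return nxt


def run_xi_long_search(
    lining_oracle: Callable[[float], bool], start: float = XI_LONG_START
) -> tuple[float, int]:
    """Find the smallest xi_long at which pore lining is observed.

    Starting at 0.7 and stepping by 0.025, query ``lining_oracle`` at
    each candidate until it reports lining at t_cutoff.  Returns the
    successful xi_long and the number of attempts.
    """
    xi = start
    attempts = 0
    while True:
        attempts += 1
        if lining_oracle(xi):
            return xi, attempts
        xi = next_xi_long(xi)  # raises SearchExhaustedError at the bound


@dataclass(frozen=True)
class WindowGrid:
    """Umbrella-sampling window centers with per-window force constants."""

    centers: np.ndarray
    force_constants: np.ndarray
    duration_per_window: float   # ns
    discard: float = 0.0         # ns equilibration discarded per window
    save_interval: float = 0.1   # ns between saved samples

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=np.float64)
        ks = np.asarray(self.force_constants, dtype=np.float64)
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "force_constants", ks)
        if len(centers) != len(ks):
            raise ValueError("one force constant per window center required")
        if np.any(np.diff(centers) <= 0):
            raise ValueError("window centers must be strictly increasing")

    @property
    def n_windows(self) -> int:
        return len(self.centers)

    @property
    def retained_samples_per_window(self) -> int:
        return int(round((self.duration_per_window - self.discard) / self.save_interval))


def make_window_grid(mode: str = "cg") -> WindowGrid:
    """Standard 23-window grid over xi in [0.2, 1.0].

    Eleven windows from 0.2 to 0.7 at 0.05 spacing plus twelve from
    0.725 to 1.0 at 0.025 spacing.  Coarse-grained mode uses
    10,000 / 20,000 kJ/mol force constants and 500 ns per window;
    atomistic mode 5,000 / 10,000 kJ/mol, 50 ns per window with the
    first 10 ns discarded and samples saved every 0.1 ns.
    """
    if mode not in ("cg", "aa"):
        raise ValueError("mode must be 'cg' or 'aa'")
    coarse = np.round(np.arange(0.2, 0.7 + 1e-9, 0.05), 10)
    fine = np.round(np.arange(0.725, 1.0 + 1e-9, 0.025), 10)
    centers = np.concatenate([coarse, fine])
    if mode == "cg":
        ks = np.concatenate([np.full(len(coarse), 10000.0), np.full(len(fine), 20000.0)])
        return WindowGrid(centers, ks, duration_per_window=500.0, discard=0.0,
                          save_interval=0.1)
    ks = np.concatenate([np.full(len(coarse), 5000.0), np.full(len(fine), 10000.0)])
    return WindowGrid(centers, ks, duration_per_window=50.0, discard=10.0,
                      save_interval=0.1)
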