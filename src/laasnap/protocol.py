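"""Four-stage pressure-loading protocol.

The study protocol drives the appendage cavity pressure through four
piecewise-linear stages:

1. a suction ramp from the resting atrial pressure down to -225 mmHg
   (about -30 kPa) over 6 s, to provoke inversion;
2. a ramp back up to the physiological atrial pressure (9 mmHg) over 3 s;
3. a 0.5 s plateau at the physiological pressure, to test for spontaneous
   recovery;
4. a further ramp at the same slope as stage 2, adding 100 mmHg
   (about 13.33 kPa) above the physiological value, to force recovery.

Pressures are stored in mmHg and converted at the solver boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import mmhg_to_kpa  # noqa: F401  (re-exported for convenience)

__all__ = ["PressureProtocol", "standard_protocol", "zero_protocol"]


@dataclass(frozen=True)
class PressureProtocol:
    """Piecewise-linear pressure-versus-time curve.

    Parameters
    ----------
    times:
        Strictly increasing breakpoint times, s.
    pressures:
        Pressure at each breakpoint, mmHg.
    stage_bounds:
        Times separating consecutive stages (including start and end), used
        for stage labelling; must be a subset of the time span.
    """

    times: tuple[float, ...]
    pressures: tuple[float, ...]
    stage_bounds: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size < 2:
            raise ValueError("protocol needs at least two breakpoints")
        if not np.all(np.diff(t) > 0):
            raise ValueError("breakpoint times must be strictly increasing")
        if len(self.pressures) != t.size:
            raise ValueError("times and pressures length mismatch")

    @property
    def t_start(self) -> float:
        return self.times[0]

    @property
    def t_end(self) -> float:
        return self.times[-1]

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def pressure_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """Pressure (mmHg) at time ``t`` by linear interpolation.

        Raises
        ------
        ValueError
            If ``t`` lies outside the protocol span (no extrapolation).
        """
        t_arr = np.asarray(t, dtype=float)
        tol = 1e-12 * max(1.0, abs(self.t_end))
        if np.any(t_arr < self.t_start - tol) or np.any(t_arr > self.t_end + tol):
            raise ValueError(
                f"time {t!r} outside protocol span "
                f"[{self.t_start}, {self.t_end}] s"
            )
        out = np.interp(np.clip(t_arr, self.t_start, self.t_end),
                        self.times, self.pressures)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    def stage_of(self, t: float) -> int:
        """1-based stage index containing time ``t`` (end time of a stage
        belongs to the later stage, except the final endpoint)."""
        if not self.stage_bounds:
            return 1
        b = np.asarray(self.stage_bounds)
        if t < b[0] or t > b[-1]:
            raise ValueError(f"time {t} outside protocol span")
        idx = int(np.searchsorted(b, t, side="right"))
        return min(idx, len(b) - 1)

    def scaled(self, *, pressure: float = 1.0, time: float = 1.0) -> "PressureProtocol":
        """Return a copy with pressures and/or the time axis scaled.

        Time compression (``time < 1``) is how desk-scale explicit runs
        shorten the 10.8 s protocol; pressure scaling adapts the curve to
        benchmark structures whose critical loads differ from the appendage.
        """
        return PressureProtocol(
            times=tuple(t * time for t in self.times),
            pressures=tuple(p * pressure for p in self.pressures),
            stage_bounds=tuple(t * time for t in self.stage_bounds),
        )

    def sample(self, n: int = 200) -> np.ndarray:
        """(n, 2) array of (time, pressure) samples over the full span."""
        t = np.linspace(self.t_start, self.t_end, n)
        return np.column_stack([t, self.pressure_at(t)])


def standard_protocol(
    p_start: float = 9.0,
    p_suction: float = -225.0,
    t_suction: float = 6.0,
    t_restore: float = 3.0,
    t_plateau: float = 0.5,
    p_overpressure: float = 100.0,
) -> PressureProtocol:
    """The study's four-stage curve with its default parameters.

    Stage 2's slope is (p_start - p_suction) / t_restore = 78 mmHg/s with the
    defaults, and stage 4 reuses it, so the stage-4 ramp to
    ``p_start + p_overpressure`` lasts ``p_overpressure * t_restore /
    (p_start - p_suction)`` ≈ 1.282 s.
    """
    if t_suction <= 0 or t_restore <= 0 or t_plateau < 0:
        raise ValueError("stage durations must be positive")
    slope2 = (p_start - p_suction) / t_restore
    t4 = p_overpressure / slope2
    t0, t1, t2, t3 = 0.0, t_suction, t_suction + t_restore, t_suction + t_restore + t_plateau
    t_end = t3 + t4
    return PressureProtocol(
        times=(t0, t1, t2, t3, t_end),
        pressures=(p_start, p_suction, p_start, p_start, p_start + p_overpressure),
        stage_bounds=(t0, t1, t2, t3, t_end),
    )


def zero_protocol(duration: float = 1.0) -> PressureProtocol:
    """A zero-pressure hold, used for equilibrium sanity checks."""
    return PressureProtocol(times=(0.0, duration), pressures=(0.0, 0.0),
                            stage_bounds=(0.0, duration))
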