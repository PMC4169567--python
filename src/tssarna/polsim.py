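"""Deterministic RNA-polymerase pausing/traffic model of TSSaRNA biogenesis.

A virtual gene of ``L`` bp is transcribed by polymerases that enter at
position 1 every ``dtau`` ("intrinsic transcription initiation interval")
time units and advance ``v`` bp per unit.  Designated pause positions hold a
polymerase for a site-specific stall time ``dt`` before it resumes.  A
polymerase whose next base pair is occupied by a stalled polymerase cannot
go further: it immediately releases the transcript synthesized so far and
detaches.  These early terminations, one base pair behind each pause, are
the modelled origin of TSS-associated small RNAs; polymerases that reach
position ``L`` release the full-length (cognate gene) transcript.  The model
has no random component.

Steady state admits a closed form.  Pause entries are locked to the
initiation grid: with a single pause the entry cycle is
``dtau * ceil(dt / dtau)``, so the full-length rate is the reciprocal of
that cycle and every other initiation terminates one bp short of the pause.
When ``dt <= dtau`` (or ``dt`` is a multiple of ``dtau``) this reduces to
the smooth limits ``1/max(dtau, dt)`` and ``1/dtau - 1/max(dtau, dt)``.
The closed form extends to multiple pauses by propagating the cycle, which
requires site stall times to increase along the gene for downstream pauses
to produce any truncated transcripts at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

try:  # optional JIT; the kernel is exact either way
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    def _njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@dataclass(frozen=True)
class PolSimConfig:
    """Parameters of one simulation run.

    ``pauses`` is a sequence of (position, stall_time) pairs with 1-based
    positions strictly increasing along the gene; ``burn_in`` time units are
    excluded from rate estimates (default 10 x the slowest interval).
    """

    L: int
    dtau: int
    pauses: tuple[tuple[int, int], ...] = ()
    v: int = 1
    T: int = 10_000
    burn_in: Optional[int] = None

    def __post_init__(self) -> None:
        if self.L < 1 or self.dtau < 1 or self.v < 1:
            raise ValueError("L, dtau and v must be >= 1")
        prev = 0
        for pos, dt in self.pauses:
            if not (1 <= pos <= self.L):
                raise ValueError(f"pause position {pos} outside gene [1, {self.L}]")
            if pos <= prev:
                raise ValueError("pause positions must be strictly increasing")
            if dt < 0:
                raise ValueError("stall times must be >= 0")
            prev = pos
        if self.T <= self.effective_burn_in:
            raise ValueError("T must exceed burn_in")

    @property
    def effective_burn_in(self) -> int:
        if self.burn_in is not None:
            return self.burn_in
        max_dt = max((dt for _, dt in self.pauses), default=0)
        return 10 * max(self.dtau, max_dt)


@dataclass
class PolSimResult:
    """Transcript census of one run.

    Whole-run counts satisfy, exactly:
    ``initiations == full_length_count + sum(truncated_counts.values())
    + blocked_initiations + in_progress``.
    Rates are per time unit over the post-burn-in window.
    """

    config: PolSimConfig
    initiations: int
    blocked_initiations: int
    full_length_count: int
    truncated_counts: dict[int, int]
    in_progress: int
    full_length_rate: float
    truncated_rate: float
    truncated_counts_steady: dict[int, int] = field(default_factory=dict)

    @property
    def truncated_total(self) -> int:
        return sum(self.truncated_counts.values())


@_njit(cache=False)
def _kernel(L, dtau, v, T, burn_in, dwell):  # pragma: no cover - exercised via simulate
    cap = L + 2
    pos = np.zeros(cap, np.int64)
    wait = np.zeros(cap, np.int64)
    npos = np.zeros(cap, np.int64)
    nwait = np.zeros(cap, np.int64)
    trunc_all = np.zeros(L + 1, np.int64)
    trunc_win = np.zeros(L + 1, np.int64)
    n = 0
    init_total = 0
    blocked_total = 0
    full_total = 0
    full_win = 0
    for t in range(T):
        m = 0
        prev_after = np.int64(L + 10)  # sentinel: no polymerase ahead
        prev_exists = False
        for i in range(n):
            p = pos[i]
            w = wait[i]
            if w > 0:
                npos[m] = p
                nwait[m] = w - 1
                m += 1
                prev_after = p
                prev_exists = True
            else:
                q = p
                released = 0  # 1 full-length, 2 collision
                for _s in range(v):
                    nxt = q + 1
                    if prev_exists and nxt == prev_after:
                        released = 2
                        break
                    if nxt > L:
                        released = 1
                        break
                    q = nxt
                    if dwell[q] > 1:
                        break
                if released == 1:
                    full_total += 1
                    if t >= burn_in:
                        full_win += 1
                elif released == 2:
                    trunc_all[q] += 1
                    if t >= burn_in:
                        trunc_win[q] += 1
                else:
                    npos[m] = q
                    nwait[m] = dwell[q] - 1
                    m += 1
                    prev_after = q
                    prev_exists = True
        if t % dtau == 0:
            init_total += 1
            if m > 0 and npos[m - 1] == 1:
                blocked_total += 1
            else:
                npos[m] = 1
                nwait[m] = dwell[1] - 1
                m += 1
        tmp = pos; pos = npos; npos = tmp
        tmp = wait; wait = nwait; nwait = tmp
        n = m
    return init_total, blocked_total, full_total, full_win, n, trunc_all, trunc_win


def simulate(config: PolSimConfig) -> PolSimResult:
    """Run the pausing model for ``config.T`` unit time steps.

    Within a step, polymerases are updated from the most 3' to the most 5'
    (so a pause vacated this step can be entered this step), then initiation
    is attempted; an initiation onto an occupied first base is counted as
    blocked and produces no transcript.
    """
    dwell = np.ones(config.L + 2, np.int64)
    for pos, dt in config.pauses:
        dwell[pos] = max(1, dt)
    burn_in = config.effective_burn_in
    init_total, blocked, full_total, full_win, in_prog, trunc_all, trunc_win = _kernel(
        config.L, config.dtau, config.v, config.T, burn_in, dwell
    )
    window = config.T - burn_in
    return PolSimResult(
        config=config,
        initiations=int(init_total),
        blocked_initiations=int(blocked),
        full_length_count=int(full_total),
        truncated_counts={int(l): int(c) for l, c in enumerate(trunc_all) if c > 0},
        in_progress=int(in_prog),
        full_length_rate=full_win / window,
        truncated_rate=int(trunc_win.sum()) / window,
        truncated_counts_steady={int(l): int(c) for l, c in enumerate(trunc_win) if c > 0},
    )


def length_histogram(result: PolSimResult, steady_state: bool = True) -> dict[int, int]:
    """Truncated-transcript length histogram (post-burn-in by default)."""
    return dict(result.truncated_counts_steady if steady_state else result.truncated_counts)


def modal_lengths(histogram: dict[int, int]) -> list[int]:
    """Local maxima of the length histogram (isolated lengths count)."""
    return sorted(
        l for l, c in histogram.items()
        if c >= histogram.get(l - 1, 0) and c >= histogram.get(l + 1, 0)
    )


# ---------------------------------------------------------------------------
# closed-form steady state


def steady_state_rates(
    dtau: int, pauses: Sequence[tuple[int, int]]
) -> tuple[float, dict[int, float]]:
    """Exact steady-state rates (full_length_rate, {length: truncated_rate}).

    Pause entries are locked to the arrival grid set by the upstream cycle
    ``c`` (initially ``dtau``): each pause multiplies the cycle by
    ``ceil(dt / c)`` and terminates the intervening arrivals one bp short.
    """
    c = dtau
    trunc: dict[int, float] = {}
    for pos, dt in sorted(pauses):
        k = math.ceil(dt / c) if dt > 0 else 1
        c_new = c * k
        if k > 1:
            trunc[pos - 1] = 1.0 / c - 1.0 / c_new
        c = c_new
    return 1.0 / c, trunc


def smooth_steady_state_rates(dtau: int, dt: int) -> tuple[float, float]:
    """Continuum limit for a single pause: full-length rate 1/max(dtau, dt),
    truncated rate 1/dtau - 1/max(dtau, dt).  Exact whenever ``dt <= dtau``
    or ``dt`` is a multiple of ``dtau``."""
    slow = max(dtau, dt)
    full = 1.0 / slow
    return full, max(0.0, 1.0 / dtau - full)


def _auto_T(dtau: int, pauses: Sequence[tuple[int, int]], L: int, cycles: int) -> tuple[int, int]:
    full_rate, _ = steady_state_rates(dtau, pauses)
    cycle = round(1.0 / full_rate)
    max_dt = max((dt for _, dt in pauses), default=0)
    burn_in = 10 * max(dtau, max_dt) + 2 * L
    return burn_in + cycles * cycle, burn_in


# ---------------------------------------------------------------------------
# parameter scan and growth-curve rhythm


def levels(result: PolSimResult, tssarna_len: int, mode: str = "rate") -> tuple[float, float]:
    """(TSSaRNA level, cognate level) from one run.

    ``rate`` counts transcript production rates; ``coverage`` instead counts
    per-base signal over the first ``tssarna_len`` bases, the probe-style
    alternative (all transcripts contribute there, so the level tracks the
    initiation rate)."""
    if mode == "rate":
        return result.truncated_rate, result.full_length_rate
    if mode == "coverage":
        window = result.config.T - result.config.effective_burn_in
        cov = sum(
            min(l, tssarna_len) * c for l, c in result.truncated_counts_steady.items()
        ) / window
        cov += tssarna_len * result.full_length_rate
        return cov, result.full_length_rate
    raise ValueError(f"unknown level mode {mode!r}")


def run_cell(
    dtau: int,
    dt: int,
    L: int = 2000,
    pause_pos: int = 36,
    v: int = 1,
    cycles: int = 300,
) -> PolSimResult:
    """Simulate one (dtau, dt) cell to steady state (~``cycles`` full-length
    releases after burn-in)."""
    T, burn_in = _auto_T(dtau, [(pause_pos, dt)], L, cycles)
    cfg = PolSimConfig(L=L, dtau=dtau, pauses=((pause_pos, dt),), v=v, T=T, burn_in=burn_in)
    return simulate(cfg)


def scan_parameters(
    dtau_grid: Sequence[int],
    dt_grid: Sequence[int],
    L: int = 2000,
    pause_pos: int = 36,
    ref: Optional[tuple[int, int]] = None,
    level_mode: str = "rate",
    cycles: int = 300,
) -> pd.DataFrame:
    """Scan (dtau, dt) cells; report levels and log2 folds versus ``ref``.

    ``ref`` is a (dtau, dt) pair naming the reference cell (defaults to the
    first cell of the grid).  TSSaRNA level is the truncated-transcript
    production rate, cognate level the full-length rate (``level_mode``
    switches to the coverage-style alternative)."""
    tssarna_len = pause_pos - 1
    if ref is None:
        ref = (dtau_grid[0], dt_grid[0])
    rows = []
    cache: dict[tuple[int, int], tuple[float, float]] = {}

    def cell(dtau: int, dt: int) -> tuple[float, float]:
        if (dtau, dt) not in cache:
            res = run_cell(dtau, dt, L=L, pause_pos=pause_pos, cycles=cycles)
            cache[(dtau, dt)] = levels(res, tssarna_len, level_mode)
        return cache[(dtau, dt)]

    ref_tss, ref_cog = cell(*ref)
    for dtau in dtau_grid:
        for dt in dt_grid:
            tss, cog = cell(dtau, dt)
            rows.append(
                {
                    "dtau": dtau,
                    "dt": dt,
                    "tssarna_level": tss,
                    "cognate_level": cog,
                    "log2_tssarna_fold": np.log2(tss / ref_tss) if ref_tss > 0 and tss > 0 else np.nan,
                    "log2_cognate_fold": np.log2(cog / ref_cog) if ref_cog > 0 and cog > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RhythmSchedule:
    """Per-growth-curve-time-point model parameters.

    Each entry fully specifies (dtau, pauses) for that time point; the
    reference time point provides I_ref."""

    points: tuple[tuple[int, tuple[tuple[int, int], ...]], ...]
    ref_index: int = 0

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("schedule needs at least one time point")
        if not (0 <= self.ref_index < len(self.points)):
            raise ValueError("ref_index out of range")


def simulate_growth_curve(
    schedule: RhythmSchedule,
    L: int = 2000,
    tssarna_len: Optional[int] = None,
    v: int = 1,
    cycles: int = 300,
    level_mode: str = "rate",
) -> pd.DataFrame:
    """One steady-state run per time point; log2(I_t / I_ref) profiles for
    the TSSaRNA and its cognate gene, in the shape the differential
    expression procedure consumes."""
    lv = []
    for dtau, pauses in schedule.points:
        T, burn_in = _auto_T(dtau, pauses, L, cycles)
        cfg = PolSimConfig(L=L, dtau=dtau, pauses=tuple(pauses), v=v, T=T, burn_in=burn_in)
        res = simulate(cfg)
        tl = tssarna_len if tssarna_len is not None else (pauses[0][0] - 1 if pauses else 1)
        lv.append(levels(res, tl, level_mode))
    ref_tss, ref_cog = lv[schedule.ref_index]
    rows = [
        {
            "timepoint": i,
            "log2_tssarna": np.log2(t / ref_tss) if ref_tss > 0 and t > 0 else np.nan,
            "log2_cognate": np.log2(c / ref_cog) if ref_cog > 0 and c > 0 else np.nan,
        }
        for i, (t, c) in enumerate(lv)
    ]
    return pd.DataFrame(rows)
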