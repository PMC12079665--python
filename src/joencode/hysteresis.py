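"""History dependence of position encoding under the stair protocol.

The stair visits the same hold levels during dorsal-going (ascending) and
ventral-going (descending) traversals.  Steady-state rates at matched levels
are overlaid per traversal direction and the hysteresis is the absolute
(shoelace) area of the loop traced by one ascending-plus-descending cycle in
the (position, steady-state rate) plane, in Hz.deg.  The first and last
three holds of the protocol (the lead-in/lead-out legs) are excluded from
the quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BranchError
from .rates import RateEstimate, steady_state_rate, _window_slice
from .stimulus import DORSAL, VENTRAL, RAMP, StimulusTrace

N_EDGE_HOLDS_EXCLUDED = 3
LEVEL_PAIR_TOL_DEG = 0.05


@dataclass
class StairBranches:
    """Steady-state rates per hold level, split by traversal direction.

    ``positions_deg`` is ascending; ``up_rates_hz`` are from dorsal-going
    (ascending) approaches, ``down_rates_hz`` from ventral-going ones.  A
    turning-point level visited by only one branch carries the same rate in
    both arrays so the loop polygon closes; ``shared_levels`` marks them.
    """

    positions_deg: np.ndarray
    up_rates_hz: np.ndarray
    down_rates_hz: np.ndarray
    up_sd_hz: np.ndarray
    down_sd_hz: np.ndarray
    excluded_levels: list = field(default_factory=list)
    shared_levels: list = field(default_factory=list)

    @property
    def n_levels(self) -> int:
        return len(self.positions_deg)


@dataclass(frozen=True)
class HysteresisResult:
    loop_area_hz_deg: float
    n_levels: int


def _hold_records(rate: RateEstimate, stair: StimulusTrace):
    """(level_deg, approach_direction, hold_window_s, ss_rate, ss_sd) per hold,
    in protocol order."""
    records = []
    phases = stair.phases
    for i, ph in enumerate(phases):
        if ph.label != "hold":
            continue
        if i == 0 or phases[i - 1].label != RAMP:
            continue  # baseline hold with no approach ramp
        window = stair.phase_window_s(ph)
        level = float(np.median(stair.position_deg[ph.start:ph.stop]))
        ss = steady_state_rate(rate, window)
        sl = _window_slice(rate, window[1] - 1.5, window[1] - 0.5)
        sd = float(np.mean(rate.sd_hz[sl]))
        records.append((level, phases[i - 1].direction, window, ss, sd))
    return records


def extract_branches(rate: RateEstimate, stair: StimulusTrace) -> StairBranches:
    """Group steady-state rates by traversal direction at matched levels.

    Levels are paired across branches within 0.05 deg (the repeatability of
    the delivered stimulus).  Non-turning levels present in only one branch
    raise an error.
    """
    records = _hold_records(rate, stair)
    if len(records) < 2 * N_EDGE_HOLDS_EXCLUDED + 4:
        raise BranchError(
            f"stair has {len(records)} holds; nothing survives excluding the "
            f"first and last {N_EDGE_HOLDS_EXCLUDED}"
        )
    excluded = records[:N_EDGE_HOLDS_EXCLUDED] + records[-N_EDGE_HOLDS_EXCLUDED:]
    kept = records[N_EDGE_HOLDS_EXCLUDED:-N_EDGE_HOLDS_EXCLUDED]
    up = [(lvl, ss, sd) for lvl, d, _, ss, sd in kept if d == DORSAL]
    down = [(lvl, ss, sd) for lvl, d, _, ss, sd in kept if d == VENTRAL]
    if not up or not down:
        raise BranchError("both traversal directions are required")

    all_levels = np.array([lvl for lvl, *_ in up + down])
    lo, hi = all_levels.min(), all_levels.max()
    positions, u_r, d_r, u_s, d_s, shared = [], [], [], [], [], []
    down_left = list(down)
    for lvl, ss, sd in sorted(up):
        match = [x for x in down_left if abs(x[0] - lvl) <= LEVEL_PAIR_TOL_DEG]
        if match:
            m = min(match, key=lambda x: abs(x[0] - lvl))
            down_left.remove(m)
            positions.append(lvl)
            u_r.append(ss); u_s.append(sd)
            d_r.append(m[1]); d_s.append(m[2])
        elif abs(lvl - hi) <= LEVEL_PAIR_TOL_DEG or abs(lvl - lo) <= LEVEL_PAIR_TOL_DEG:
            # turning point visited once: shared vertex closing the loop
            positions.append(lvl)
            u_r.append(ss); u_s.append(sd)
            d_r.append(ss); d_s.append(sd)
            shared.append(lvl)
        else:
            raise BranchError(f"hold level {lvl:.3f} deg has no partner in the other branch")
    for lvl, ss, sd in down_left:
        if abs(lvl - hi) <= LEVEL_PAIR_TOL_DEG or abs(lvl - lo) <= LEVEL_PAIR_TOL_DEG:
            positions.append(lvl)
            u_r.append(ss); u_s.append(sd)
            d_r.append(ss); d_s.append(sd)
            shared.append(lvl)
        else:
            raise BranchError(f"hold level {lvl:.3f} deg has no partner in the other branch")

    order = np.argsort(positions)
    return StairBranches(
        np.asarray(positions)[order],
        np.asarray(u_r)[order],
        np.asarray(d_r)[order],
        np.asarray(u_s)[order],
        np.asarray(d_s)[order],
        excluded_levels=[lvl for lvl, *_ in excluded],
        shared_levels=shared,
    )


def loop_area(branches: StairBranches) -> HysteresisResult:
    """Absolute shoelace area of the (position, rate) cycle.

    Vertices run up-branch by ascending position, then down-branch by
    descending position.  The signed shoelace sum equals the difference of
    the two branch integrals, so identical branches give exactly zero.
    """
    if branches.n_levels < 2:
        raise BranchError("need >= 2 paired levels for a loop")
    x = np.concatenate([branches.positions_deg, branches.positions_deg[::-1]])
    y = np.concatenate([branches.up_rates_hz, branches.down_rates_hz[::-1]])
    if np.ptp(branches.positions_deg) == 0:
        raise BranchError("degenerate polygon: all levels at one position")
    area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return HysteresisResult(float(abs(area)), branches.n_levels)


def hysteresis_population_summary(loop_areas_hz_deg, bin_edges=None) -> dict:
    """Histogram of loop areas across neurons, with the observed range."""
    areas = np.asarray(list(loop_areas_hz_deg), float)
    if areas.size == 0:
        raise BranchError("no hysteresis results supplied")
    if bin_edges is None:
        top = max(5.0 * np.ceil(areas.max() / 5.0), 5.0)
        bin_edges = np.arange(0.0, top + 5.0, 5.0)
    counts, edges = np.histogram(areas, bins=bin_edges)
    return {
        "counts": counts,
        "bin_edges": edges,
        "min_hz_deg": float(areas.min()),
        "max_hz_deg": float(areas.max()),
        "n": int(areas.size),
    }
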