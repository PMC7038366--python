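"""Gait-event detection and stride assembly for cane-assisted walking.

Two independent algorithms segment continuous walking into strides:

* **GPD** (gyroscope peak detection) operates on an AP angular-velocity
  stream.  Supra-threshold excursions mark peak swing (PS); the local
  minimum before a PS is terminal contact (TC), the local minimum after it
  is the next initial contact (IC), and during continuous walking the end
  of contact (EC) of one cycle is the IC of the next.
* **MSMF** (multi-sensor matched filter) operates on cane strain plus the
  cane AP velocity.  A normalized cross-correlation of a loading-bump
  template against the strain stream marks candidate cycles (similarity
  threshold 50%); IC is the positive strain zero-crossing nearest the
  similarity peak (within +-0.5 s), TC the following negative crossing, PS
  the AP-velocity maximum after TC, and EC the next positive crossing.

Zero-crossing detection uses hysteresis (the signal must travel from below
-h to above +h) with the crossing time interpolated linearly at zero, which
keeps sub-sample timing and rejects chatter near the baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .exceptions import DataError, ParameterError, SynchronizationError
from .io_filter import CaneRecording, ShankRecording, unloaded_level

__all__ = [
    "GaitEvent",
    "Stride",
    "SegConfig",
    "detect_ps_gpd",
    "events_from_ps_gpd",
    "auto_threshold",
    "build_template",
    "msmf_trace",
    "detect_events_msmf",
    "assemble_strides",
    "sync_offset",
]

EVENT_KINDS = ("IC", "TC", "PS", "EC")
SOURCES = ("MSMF", "GPD")

# EC sorts before IC at equal times: during continuous walking one cycle's
# EC coincides exactly with the next cycle's IC.
_SORT_RANK = {"EC": 0, "IC": 1, "TC": 2, "PS": 3}


@dataclass
class GaitEvent:
    kind: str
    t: float
    source: str
    stride_index: Optional[int] = None

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ParameterError(f"unknown event kind {self.kind!r}")
        if self.source not in SOURCES:
            raise ParameterError(f"unknown event source {self.source!r}")


@dataclass
class Stride:
    """One gait cycle bounded by IC and EC (= next cycle's IC)."""
    ic: GaitEvent
    tc: GaitEvent
    ps: GaitEvent
    ec: GaitEvent
    valid: bool = True
    reason: str = ""

    @property
    def stance(self) -> float:
        return self.tc.t - self.ic.t

    @property
    def swing(self) -> float:
        return self.ec.t - self.tc.t


@dataclass
class SegConfig:
    similarity_threshold: float = 0.5
    ic_window_s: float = 0.5
    template_strides: int = 5
    gpd_threshold: object = "auto"
    min_stride_s: float = 0.4
    max_stride_s: float = 3.0
    min_prominence: float = 5.0      # local-minimum prominence floor (deg/s)
    min_valley_depth: float = 15.0   # IC/TC valleys must reach below this (deg/s)
    hysteresis_floor: float = 1.0    # strain crossing hysteresis floor (counts)

    def __post_init__(self):
        if not 0.0 < self.similarity_threshold <= 1.0:
            raise ParameterError("similarity_threshold must be in (0, 1]")
        if self.ic_window_s <= 0:
            raise ParameterError("ic_window_s must be positive")


# ---------------------------------------------------------------------------
# helpers

def _refine_peak(x: np.ndarray, i: int, dt: float, t0: float = 0.0) -> Tuple[float, float]:
    """Parabolic sub-sample refinement of a sample-level maximum."""
    if 0 < i < x.size - 1:
        y0, y1, y2 = x[i - 1], x[i], x[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:
            off = 0.5 * (y0 - y2) / denom
            off = float(np.clip(off, -0.5, 0.5))
            return t0 + (i + off) * dt, y1 - 0.25 * (y0 - y2) * off
    return t0 + i * dt, float(x[i])


def hysteresis_crossings(signal: np.ndarray, sample_rate: float,
                         h_lo: float, h_hi: Optional[float] = None
                         ) -> Tuple[np.ndarray, np.ndarray]:
    """Positive and negative zero-crossing times with hysteresis.

    A positive crossing fires when the signal, having been below ``-h_lo``
    (the unloaded band), rises above ``+h_hi`` (clearly loaded); its time is
    the zero crossing of the rising segment, linearly interpolated.
    Negative crossings transit the other way.  ``h_hi`` defaults to ``h_lo``
    (symmetric hysteresis); a larger ``h_hi`` rejects filter ripple next to
    large loading bumps without touching the unloaded-band arming level.
    """
    x = np.asarray(signal, dtype=float)
    if h_hi is None:
        h_hi = h_lo
    dt = 1.0 / sample_rate
    sign = np.where(x > h_hi, 1, np.where(x < -h_lo, -1, 0))
    # carry the last nonzero state forward
    state = sign.copy()
    nz = state != 0
    idx = np.where(nz, np.arange(x.size), 0)
    np.maximum.accumulate(idx, out=idx)
    state = state[idx]
    flips = np.where(state[1:] != state[:-1])[0] + 1
    pos, neg = [], []
    for i in flips:
        if state[i - 1] == 0:
            continue
        rising = state[i] > state[i - 1]
        # walk back to the zero crossing of the monotone segment ending at i
        j = i
        if rising:
            while j > 0 and x[j - 1] > 0:
                j -= 1
            while j > 0 and x[j] > 0:
                j -= 1
        else:
            while j > 0 and x[j - 1] < 0:
                j -= 1
            while j > 0 and x[j] < 0:
                j -= 1
        if j + 1 >= x.size or x[j + 1] == x[j]:
            continue
        tcross = (j + (0.0 - x[j]) / (x[j + 1] - x[j])) * dt
        (pos if rising else neg).append(tcross)
    return np.asarray(pos), np.asarray(neg)


def strain_hysteresis(strain: np.ndarray, floor: float = 1.0) -> float:
    """Noise-scaled hysteresis: 3 x the unloaded-phase noise spread."""
    _, spread = unloaded_level(strain)
    return max(floor, 3.0 * spread)


def _local_minima(g: np.ndarray, sample_rate: float, prominence: float,
                  depth: float = 15.0) -> np.ndarray:
    """Negative-going local minima (impact valleys), sub-sample refined.

    Gait contacts decelerate the limb/cane, so the IC/TC landmarks are
    pronounced valleys well below zero; requiring ``value <= -depth``
    rejects shallow wiggles on the swing profile and its plateaus.
    """
    idx, _ = find_peaks(-g, prominence=prominence, height=depth)
    dt = 1.0 / sample_rate
    return np.array([_refine_peak(-g, i, dt)[0] for i in idx])


# ---------------------------------------------------------------------------
# GPD

def detect_ps_gpd(gyro_ap: np.ndarray, sample_rate: float, threshold: float,
                  min_stride_s: float = 0.4) -> List[GaitEvent]:
    """Peak-swing events: one per contiguous supra-threshold excursion.

    When two excursion maxima fall closer than ``min_stride_s`` the smaller
    one is discarded.
    """
    if threshold <= 0:
        raise ParameterError("GPD threshold must be positive")
    g = np.asarray(gyro_ap, dtype=float)
    dt = 1.0 / sample_rate
    above = g > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(g.size)
    cands = []
    for s, e in zip(starts, ends):
        i = s + int(np.argmax(g[s:e]))
        t, v = _refine_peak(g, i, dt)
        cands.append((v, t))
    kept: List[float] = []
    for v, t in sorted(cands, reverse=True):
        if all(abs(t - k) >= min_stride_s for k in kept):
            kept.append(t)
    return [GaitEvent("PS", t, "GPD") for t in sorted(kept)]


def events_from_ps_gpd(gyro_ap: np.ndarray, sample_rate: float,
                       ps_events: Sequence[GaitEvent],
                       min_prominence: float = 5.0,
                       max_stride_s: float = 3.0,
                       min_valley_depth: float = 15.0) -> List[GaitEvent]:
    """TC / IC / EC events bracketing each PS via local minima.

    Per cycle: TC is the nearest local minimum before PS, IC the nearest
    after; EC equals the next cycle's IC (the last cycle's EC is the next
    minimum after its IC, which the generator's trailing plant provides).
    The first cycle additionally receives a leading IC from the minimum that
    precedes its TC, so the opening stride is recoverable.  Cycles missing a
    bracketing minimum are dropped.
    """
    g = np.asarray(gyro_ap, dtype=float)
    minima = _local_minima(g, sample_rate, min_prominence,
                            min_valley_depth)
    events: List[GaitEvent] = []
    if len(ps_events) == 0 or minima.size == 0:
        return events
    cycles = []
    for ev in ps_events:
        before = minima[(minima < ev.t) & (minima > ev.t - max_stride_s)]
        after = minima[(minima > ev.t) & (minima < ev.t + max_stride_s)]
        if before.size == 0 or after.size == 0:
            continue
        cycles.append((float(before[-1]), ev.t, float(after[0])))
    stride = 0
    for k, (tc, ps, ic_next) in enumerate(cycles):
        if k == 0:
            lead = minima[(minima < tc) & (minima > tc - max_stride_s)]
            if lead.size:
                events.append(GaitEvent("IC", float(lead[-1]), "GPD", stride))
        events.append(GaitEvent("TC", tc, "GPD", stride))
        events.append(GaitEvent("PS", ps, "GPD", stride))
        events.append(GaitEvent("EC", ic_next, "GPD", stride))
        if k + 1 < len(cycles):
            events.append(GaitEvent("IC", ic_next, "GPD", stride + 1))
        stride += 1
    return sorted(events, key=lambda e: (e.t, _SORT_RANK[e.kind]))


def auto_threshold(gyro_ap: np.ndarray) -> float:
    """Default GPD threshold: half the 95th percentile of positive samples."""
    g = np.asarray(gyro_ap, dtype=float)
    pos = g[g > 0]
    if pos.size == 0:
        raise ParameterError("no positive samples; cannot set a GPD threshold")
    return 0.5 * float(np.percentile(pos, 95))


# ---------------------------------------------------------------------------
# MSMF

def build_template(strain: np.ndarray, sample_rate: float,
                   n: int = 5) -> np.ndarray:
    """Average of the first ``n`` loading bumps, duration-normalized.

    Bumps are found with a conservative scan (contiguous runs above half the
    global maximum, extended to the surrounding zero-crossings), linearly
    resampled to the median bump length, averaged, mean-removed and scaled
    to unit energy.
    """
    x = np.asarray(strain, dtype=float)
    if x.size == 0:
        raise DataError("empty strain signal")
    if np.max(x) <= 0:
        raise DataError("no positive loading bumps in strain")

    def scan(level):
        above = x > level
        edges = np.diff(above.astype(int))
        starts = np.where(edges == 1)[0] + 1
        ends = np.where(edges == -1)[0] + 1
        segs = []
        for s, e in zip(starts, ends):
            a = s
            while a > 0 and x[a - 1] > 0:
                a -= 1
            b = e
            while b < x.size and x[b] > 0:
                b += 1
            if b - a >= 3:
                segs.append((a, b))
        uniq = []          # de-duplicate overlapping extensions
        for seg in segs:
            if not uniq or seg[0] >= uniq[-1][1]:
                uniq.append(seg)
        return uniq

    # loading-bump amplitudes vary several-fold between strides, so relax
    # the scan level until enough bumps are found
    level = 0.5 * np.max(x)
    uniq = scan(level)
    while len(uniq) < n and level > 0.02 * np.max(x):
        level *= 0.6
        uniq = scan(level)
    if len(uniq) < n:
        raise DataError(f"found {len(uniq)} loading bumps; need {n}")
    uniq = uniq[:n]
    length = int(np.median([b - a for a, b in uniq]))
    grid = np.linspace(0.0, 1.0, length)
    acc = np.zeros(length)
    for a, b in uniq:
        seg = x[a:b]
        acc += np.interp(grid, np.linspace(0.0, 1.0, seg.size), seg)
    tmpl = acc / n
    tmpl = tmpl - tmpl.mean()
    norm = np.linalg.norm(tmpl)
    if norm == 0:
        raise DataError("degenerate (zero-energy) template")
    return tmpl / norm


def msmf_trace(strain: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Normalized (Pearson) cross-correlation trace in [-1, 1].

    The value at index ``i`` is the correlation of the template with the
    strain window centred at ``i``; edge alignments are 0.
    """
    x = np.asarray(strain, dtype=float)
    t = np.asarray(template, dtype=float)
    m = t.size
    if m >= x.size:
        raise ParameterError("template must be shorter than the signal")
    t = t - t.mean()
    tnorm = np.linalg.norm(t)
    if tnorm == 0:
        raise ParameterError("zero-energy template")
    num = np.correlate(x, t, mode="valid")              # sum(x_w * t~)
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    wsum = c1[m:] - c1[:-m]
    wsq = c2[m:] - c2[:-m]
    var = np.maximum(wsq - wsum * wsum / m, 0.0)
    denom = tnorm * np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 1e-12, num / denom, 0.0)
    # index by the alignment *start*: a similarity peak then sits near the
    # loading-bump onset (the IC crossing), keeping the IC search window
    # valid even when stance durations vary several-fold
    trace = np.zeros_like(x)
    trace[:r.size] = np.clip(r, -1.0, 1.0)
    return trace


def detect_events_msmf(strain: np.ndarray, cane_gyro_ap: np.ndarray,
                       sample_rate: float, template: np.ndarray,
                       cfg: SegConfig = SegConfig()) -> List[GaitEvent]:
    """MSMF gait events from cane strain + AP velocity.

    For each similarity-trace peak above the threshold: IC is the positive
    strain crossing nearest the peak (within ``ic_window_s``), TC the first
    negative crossing after IC, PS the AP-velocity maximum between TC and
    the next candidate IC (bounded by ``max_stride_s``), EC the first
    positive crossing after PS.  Cycles failing any step or the stride
    duration bounds are dropped.
    """
    x = np.asarray(strain, dtype=float)
    g = np.asarray(cane_gyro_ap, dtype=float)
    if x.size != g.size:
        raise DataError("strain and gyro streams must share the time base")
    dt = 1.0 / sample_rate
    trace = msmf_trace(x, template)
    pk, _ = find_peaks(trace, height=cfg.similarity_threshold,
                       distance=max(1, int(cfg.min_stride_s * sample_rate)))
    if pk.size == 0:
        return []
    h = strain_hysteresis(x, cfg.hysteresis_floor)
    pos, neg = hysteresis_crossings(x, sample_rate, h, max(4.0, 3.0 * h))
    if pos.size == 0 or neg.size == 0:
        return []
    # IC candidate per trace peak
    ics = []
    for i in pk:
        tpk = i * dt
        j = np.argmin(np.abs(pos - tpk))
        if abs(pos[j] - tpk) <= cfg.ic_window_s:
            ics.append(pos[j])
    ics = sorted(set(ics))
    events: List[GaitEvent] = []
    stride = 0
    for k, ic in enumerate(ics):
        nxt = ics[k + 1] if k + 1 < len(ics) else ic + cfg.max_stride_s
        after_ic = neg[neg > ic]
        if after_ic.size == 0:
            continue
        tc = float(after_ic[0])
        if tc >= nxt:
            continue
        lo = int(math.ceil(tc / dt))
        hi = min(int(min(nxt, tc + cfg.max_stride_s) / dt), g.size - 1)
        if hi <= lo + 1:
            continue
        rel = int(np.argmax(g[lo:hi]))
        ps_t, _ = _refine_peak(g, lo + rel, dt)
        after_ps = pos[pos > ps_t]
        if after_ps.size == 0:
            continue
        ec = float(after_ps[0])
        dur = ec - ic
        if not (cfg.min_stride_s <= dur <= cfg.max_stride_s):
            continue
        if not ic < tc < ps_t < ec:
            continue
        events.append(GaitEvent("IC", ic, "MSMF", stride))
        events.append(GaitEvent("TC", tc, "MSMF", stride))
        events.append(GaitEvent("PS", ps_t, "MSMF", stride))
        events.append(GaitEvent("EC", ec, "MSMF", stride))
        stride += 1
    return events


# ---------------------------------------------------------------------------
# stride assembly and synchronization

def assemble_strides(events: Sequence[GaitEvent]) -> List[Stride]:
    """Group an ordered event list into (IC, TC, PS, EC) strides.

    Events are grouped greedily in time order; each IC opens a stride and
    the following TC/PS/EC complete it.  Groups with missing events or
    violating IC < TC < PS < EC are returned invalid with a reason.
    """
    evs = sorted(events, key=lambda e: (e.t, _SORT_RANK[e.kind]))
    strides: List[Stride] = []
    slots = {}
    for ev in evs:
        if ev.kind == "IC":
            if slots.get("IC") is not None:
                strides.append(_close(slots))
            slots = {"IC": ev}
        elif slots.get("IC") is not None:
            if ev.kind == "EC":
                slots["EC"] = ev
                strides.append(_close(slots))
                slots = {}
            else:
                slots.setdefault(ev.kind, ev)
    if slots.get("IC") is not None:
        strides.append(_close(slots))
    for i, s in enumerate(strides):
        for ev in (s.ic, s.tc, s.ps, s.ec):
            if ev is not None:
                ev.stride_index = i
    return strides


def _close(slots) -> Stride:
    missing = [k for k in EVENT_KINDS if slots.get(k) is None]
    if missing:
        dummy = {k: slots.get(k) or GaitEvent(k, float("nan"),
                                              slots["IC"].source)
                 for k in EVENT_KINDS}
        return Stride(dummy["IC"], dummy["TC"], dummy["PS"], dummy["EC"],
                      valid=False, reason=f"missing {','.join(missing)}")
    s = Stride(slots["IC"], slots["TC"], slots["PS"], slots["EC"])
    if not s.ic.t < s.tc.t < s.ps.t < s.ec.t:
        s.valid = False
        s.reason = "order"
    return s


def sync_offset(cane: CaneRecording, shank: ShankRecording,
                min_depth: float = 10.0,
                hysteresis_floor: float = 1.0) -> float:
    """Stream-clock offset from the trial-start landmarks.

    Both streams begin with quiet standing; the cane's first positive strain
    zero-crossing and the shank's first prominent AP-velocity local minimum
    mark the same instant (the first cane plant / heel strike).  Returns
    cane-clock time minus shank-clock time of that instant; subtracting the
    offset from cane times aligns the streams.
    """
    h = strain_hysteresis(cane.strain, hysteresis_floor)
    pos, _ = hysteresis_crossings(cane.strain, cane.sample_rate, h,
                                 max(4.0, 3.0 * h))
    if pos.size == 0:
        raise SynchronizationError("no positive strain zero-crossing found")
    g = shank.gyro_ap
    idx, _ = find_peaks(-g, prominence=min_depth, height=min_depth)
    if idx.size == 0:
        raise SynchronizationError("no AP-velocity local minimum found")
    t_shank = _refine_peak(-g, int(idx[0]), 1.0 / shank.sample_rate)[0]
    t_cane = float(pos[0]) + float(cane.time[0])
    t_shank += float(shank.time[0])
    return t_cane - t_shank
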