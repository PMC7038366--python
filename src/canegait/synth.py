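"""Synthetic cane / shank sensor-stream generator with known ground truth.

Real recordings of cane-assisted gait are not redistributable, so every
downstream stage (filtering, matched-filter and gyroscope-peak segmentation,
feature extraction, condition statistics) is exercised against synthetic
trials whose per-condition feature statistics are set to the published
per-condition means and standard deviations for eleven walking conditions
(control, plantar-/dorsiflexed gait, up-/downhill, up-/downstairs, fogged
glasses, eyes closed, long/short cane).

Signal model (one gait cycle, events IC < TC < PS < EC):

* strain (ADC counts): unloaded level ``-EPS``; during loading a smooth bump
  that undershoots to ``-B`` (B = 12% of the peak) on both sides so that the
  positive (IC) and negative (TC) zero-crossings sit mid-slope, where the
  waveform is locally odd and therefore invariant under the zero-phase
  low-pass filters applied downstream.  The apex (``strain_peak``) falls at
  ``IC + strain_peak_offset``; by default the stance duration is twice that
  offset, making the bump symmetric about its apex so filtering cannot move
  the apex either.
* cane AP angular velocity (deg/s): a small half-lobe peaking at ``v_stance``
  during stance; during swing a rise to a symmetric apex cap peaking at
  ``v_swing`` at ``TC + ps_offset`` (the PS event), then a plateau whose
  level is solved in closed form so that the time-integral of the swing-phase
  velocity equals the pendulum sweep angle
  ``theta = 2 * arcsin(stride_length / (2 * cane_length))``;
  after EC a mirror-symmetric valley whose minimum sits at
  ``EC + gpd_ic_lag`` — the landmark a gyroscope peak detector reads as IC.
* shank AP angular velocity: a keyframe chain (IC valley, stance lobe, TC
  valley, swing peak, next IC valley) at the same wall-clock event times.

All extrema are locally even and all strain crossings locally odd, so the
6th-order zero-phase Butterworth preprocessing shifts every detectable
landmark by well under one sample — the generator is self-consistent under
the pipeline it feeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from numpy.random import Generator, SeedSequence, default_rng
from scipy.special import ndtr, ndtri

from .exceptions import DataError, ParameterError
from .io_filter import CaneRecording, ShankRecording

__all__ = [
    "Gaussian",
    "ConditionProfile",
    "StudyConfig",
    "TrialTruth",
    "StudyTrial",
    "default_profiles",
    "synth_stride",
    "generate_trial",
    "generate_study",
    "draw_study_parameters",
]

# ---------------------------------------------------------------------------
# waveform geometry constants (seconds / counts / deg/s)

EPS = 2.0                 # unloaded strain level magnitude (counts)
UNDERSHOOT_FRAC = 0.12    # strain undershoot depth as a fraction of the peak
RECOVER_S = 0.14          # baseline <-> undershoot ramp duration

CAP_HW_S = 0.10           # swing-apex cap half-width
RISE_MIN_S = 0.16         # minimum swing-onset rise duration (anti-ringing)
RAMP1_S = 0.12            # post-cap ramp duration to the plateau
DIP_HW_S = 0.08           # post-swing valley half-width
DIP_PLATEAU_S = 0.06      # mirrored plateau on the valley's right side
DIP_EXIT_S = 0.06         # ramp from the mirrored plateau down to zero
DIP_DEPTH = 40.0          # post-swing valley depth (deg/s)
APEX_FRAC = 0.90          # default cap-edge level as a fraction of v_swing
PLATEAU_MIN = -12.0       # plateau floor; keeps it clear of the GPD valleys
RAMP_SLOPE_MAX = 900.0    # max post-cap ramp steepness (deg/s per s)
DESCENT_SLOPE_MAX = 1500.0  # max valley-descent steepness (deg/s per s)

SHANK_VALLEY = 45.0       # shank IC/TC contact-notch depth (deg/s)
SHANK_NOTCH_S = 0.09      # contact-notch half-width (s)
SHANK_STANCE_FRAC = 0.22  # shank stance-lobe amplitude vs swing peak

_LEAD_IN_S = 3.0          # quiet standing before the first IC
_LEAD_OUT_S = 3.0         # quiet standing after the trailing plant

# rise shape s(u) = ((1 - cos(pi u)) / 2) ** p on u in [0, 1], p = 1..4:
# full-interval means, plus cumulative integrals on a fine grid for
# partial-rise bookkeeping when the onset starts before TC.
_RISE_AREA = {1: 0.5, 2: 0.375, 3: 0.3125, 4: 0.2734375}
_RISE_U = np.linspace(0.0, 1.0, 1025)
_RISE_CUM = {}
for _p in (1, 2, 3, 4):
    _s = (0.5 * (1.0 - np.cos(np.pi * _RISE_U))) ** _p
    _RISE_CUM[_p] = np.concatenate(
        ([0.0], np.cumsum(0.5 * (_s[1:] + _s[:-1]) * np.diff(_RISE_U))))


def _rise_partial(p: int, u: float) -> float:
    """Integral of the rise shape over [0, u]."""
    return float(np.interp(u, _RISE_U, _RISE_CUM[p]))


def _rise_value(p: int, u) -> float:
    return (0.5 * (1.0 - np.cos(np.pi * np.clip(u, 0.0, 1.0)))) ** p


@dataclass(frozen=True)
class Gaussian:
    """Mean and standard deviation of one stride-level quantity."""
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd < 0:
            raise ParameterError("sd must be non-negative")


@dataclass(frozen=True)
class ConditionProfile:
    """Stride-statistics of one walking condition.

    Velocity fields are in deg/s, durations in s, strain in ADC counts,
    stride length in m.  ``gpd_ic_lag_s`` is the lag of the cane-gyroscope
    post-swing minimum behind the strain IC crossing (a positive lag means
    a negative IC difference between the matched-filter and gyroscope-peak
    detections).
    """
    name: str
    stance_s: Gaussian
    swing_s: Gaussian
    v_swing: Gaussian
    v_stance: Gaussian
    ps_offset_s: Gaussian
    strain_peak: Gaussian
    strain_peak_offset_s: Gaussian
    stride_length_m: Gaussian
    gpd_ic_lag_s: Gaussian
    cane_length_m: float = 0.90
    shank_v_swing: Gaussian = None
    shank_stance_s: Gaussian = None
    shank_swing_s: Gaussian = None

    def __post_init__(self):
        if self.shank_v_swing is None:
            object.__setattr__(self, "shank_v_swing", self.v_swing)
        if self.shank_stance_s is None:
            object.__setattr__(self, "shank_stance_s", self.stance_s)
        if self.shank_swing_s is None:
            object.__setattr__(self, "shank_swing_s", self.swing_s)
        for f in ("stance_s", "swing_s", "ps_offset_s", "strain_peak_offset_s"):
            if getattr(self, f).mean <= 0:
                raise ParameterError(f"{f} must be positive")
        if not self.v_swing.mean > self.v_stance.mean >= 0:
            raise ParameterError("require v_swing > v_stance >= 0")
        if self.ps_offset_s.mean >= self.swing_s.mean:
            raise ParameterError("ps_offset must fall inside the swing phase")
        if self.strain_peak_offset_s.mean >= self.stance_s.mean:
            raise ParameterError("strain apex must fall inside the stance phase")
        if self.stride_length_m.mean < 0:
            raise ParameterError("stride length must be non-negative")
        if self.cane_length_m <= 0:
            raise ParameterError("cane length must be positive")


@dataclass
class StudyConfig:
    """Study-level simulation parameters."""
    n_participants: int = 30
    strides_per_trial: int = 40
    conditions: Sequence[str] = ("control",)
    seed: int = 0
    fs_cane: float = 231.0
    fs_shank: float = 100.0
    noise_sd_strain: float = 1.0
    noise_sd_gyro: float = 1.0
    between_participant_sd_scale: float = 0.5

    def __post_init__(self):
        if self.n_participants < 1 or self.strides_per_trial < 1:
            raise ParameterError("counts must be >= 1")
        if not 0.0 <= self.between_participant_sd_scale <= 1.0:
            raise ParameterError("between_participant_sd_scale must be in [0, 1]")

    def to_yaml(self, path) -> None:
        d = {k: (list(v) if isinstance(v, (tuple, list)) else v)
             for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)


@dataclass
class TrialTruth:
    """Ground truth for one trial.

    ``strides`` has one row per stride with the exact generated event times
    (``ic``, ``tc``, ``ps``, ``ec`` and ``gpd_ic``, all in seconds of the
    cane stream clock) and the drawn per-stride parameters.  Shank events
    occur at the same wall-clock instants; in the shank stream clock they are
    shifted by ``-offset_s``.  ``offset_s`` is the cane-to-shank stream start
    offset (cane clock minus shank clock of the same instant).
    """
    strides: pd.DataFrame
    offset_s: float
    n_clamped: int = 0

    def shank_events(self) -> pd.DataFrame:
        """Event times expressed in the shank stream clock.

        The shank swing peak sits at mid-swing (``ps_shank``); IC/TC/EC
        coincide with the cane events in wall time.
        """
        out = self.strides[["stride", "ic", "tc", "ps_shank", "ec"]].copy()
        out = out.rename(columns={"ps_shank": "ps"})
        for c in ("ic", "tc", "ps", "ec"):
            out[c] = out[c] - self.offset_s
        return out


@dataclass
class StudyTrial:
    participant: int
    condition: str
    cane: CaneRecording
    shank: ShankRecording
    truth: TrialTruth


# ---------------------------------------------------------------------------
# condition tables
#
# Per-condition (mean, sd) of: swing-phase peak AP velocity, stance-phase
# peak AP velocity, PS time after TC (ms; None -> scaled control default),
# swing/stance ratio, peak strain, strain-apex time after IC (ms; None ->
# control default), stride length, and the MSMF-GPD IC difference (ms,
# negative; the generator lag is its negation).

_TABLE = {
    #                v_swing         v_stance      pv_t      ratio        strain          strain_t      stride      diff_ic
    "control":        ((246.5, 55.5), (156.4, 33.3), (258, 58),     (1.0, 0.2), (110.6, 57.7),  (361.9, 73.2), (1.1, 0.4), (-12.6, 6.6)),
    "plantarflexion": ((228.3, 73.8), (148.8, 28.5), (217.3, 52.4), (0.9, 0.7), (179.3, 93.3),  (412.1, 99.9), (0.9, 0.3), (-20.2, 11.6)),
    "dorsiflexion":   ((204.9, 61.6), (124.6, 23.3), (204.8, 35.9), (0.8, 0.2), (188.0, 83.0),  (419.0, 80.0), (0.8, 0.3), (-25.0, 14.1)),
    "uphill":         ((270.0, 73.0), (166.3, 27.5), None,          (1.0, 0.5), (159.7, 74.5),  None,          (1.1, 0.4), (-19.3, 12.8)),
    "downhill":       ((268.1, 76.2), (189.6, 33.5), None,          (1.0, 0.3), (135.7, 67.3),  None,          (1.2, 0.4), (-12.5, 6.8)),
    "upstairs":       ((68.3, 21.3),  (37.4, 8.8),   None,          (0.7, 0.2), (201.7, 122.9), None,          (0.3, 0.2), (-78.7, 29.7)),
    "downstairs":     ((79.6, 26.4),  (38.3, 14.2),  None,          (0.7, 0.3), (179.8, 104.7), None,          (0.2, 0.1), (-63.3, 27.4)),
    "fogged_glasses": ((243.5, 63.6), (147.4, 24.9), None,          (0.9, 0.2), (141.9, 80.9),  None,          (1.1, 0.3), (-19.3, 10.5)),
    "eyes_closed":    ((194.8, 54.2), (104.1, 23.3), None,          (0.8, 0.3), (147.2, 76.3),  None,          (0.8, 0.3), (-28.4, 15.9)),
    "long_cane":      ((243.3, 61.7), (146.9, 27.7), None,          (0.9, 0.3), (143.4, 77.7),  None,          (1.3, 0.4), (-21.6, 10.2)),
    "short_cane":     ((246.9, 65.4), (153.2, 28.3), None,          (1.0, 0.3), (167.0, 85.1),  None,          (0.8, 0.3), (-23.3, 13.0)),
}

_TWO_INCHES_M = 0.0508
_BASE_CANE_M = 0.90


def default_profiles() -> Dict[str, ConditionProfile]:
    """The eleven walking-condition profiles.

    Fields printed in the per-condition tables are transcribed as-is.  The
    tables do not print stance/swing durations, so stance defaults to twice
    the strain-apex offset (making the loading bump symmetric about its
    apex) and swing to the printed swing/stance ratio times stance.  Where a
    condition's PS timing / strain-apex timing are not printed, the control
    values are used (PS timing scaled with swing duration).  Duration sds
    come from the printed ratio sd, split evenly between stance and swing
    and capped at 25% of the mean.
    """
    ctrl_sw, ctrl_st_t = _TABLE["control"][2], _TABLE["control"][5]
    ctrl_swing = _TABLE["control"][3][0] * 2 * ctrl_st_t[0] / 1000.0
    profiles = {}
    for name, row in _TABLE.items():
        v_sw, v_st, pv_t, ratio, strain, strain_t, stride, diff_ic = row
        if strain_t is None:
            strain_t = ctrl_st_t
        stance_mean = 2 * strain_t[0] / 1000.0
        swing_mean = ratio[0] * stance_mean
        if pv_t is None:
            scale = swing_mean / ctrl_swing
            pv_t = (ctrl_sw[0] * scale, ctrl_sw[1] * scale)
        sd_t = ratio[1] * stance_mean / math.sqrt(1.0 + ratio[0] ** 2)
        cane_len = _BASE_CANE_M
        if name == "long_cane":
            cane_len += _TWO_INCHES_M
        elif name == "short_cane":
            cane_len -= _TWO_INCHES_M
        profiles[name] = ConditionProfile(
            name=name,
            stance_s=Gaussian(stance_mean, min(sd_t, 0.25 * stance_mean)),
            swing_s=Gaussian(swing_mean, min(sd_t, 0.25 * swing_mean)),
            v_swing=Gaussian(*v_sw),
            v_stance=Gaussian(*v_st),
            ps_offset_s=Gaussian(pv_t[0] / 1000.0, pv_t[1] / 1000.0),
            strain_peak=Gaussian(*strain),
            strain_peak_offset_s=Gaussian(strain_t[0] / 1000.0, strain_t[1] / 1000.0),
            stride_length_m=Gaussian(*stride),
            gpd_ic_lag_s=Gaussian(-diff_ic[0] / 1000.0, diff_ic[1] / 1000.0),
            cane_length_m=cane_len,
        )
    return profiles


# ---------------------------------------------------------------------------
# swing-shape solver

@dataclass
class _SwingShape:
    y_a: float      # cap-edge level (deg/s)
    p: int          # rise-shape exponent
    c: float        # plateau level (deg/s)
    w_a: float      # cap half-width (s)
    w1: float       # post-cap ramp duration (s)
    w2: float       # valley half-width (s)
    r0: float       # rise duration (s); may start before TC
    u0: float       # rise phase at TC (0 when the rise starts at/after TC)


def _ramp_integral(t0: float, t1: float, a: float, b: float):
    """Integral pieces of a raised-cosine ramp y0->y1 on [t0,t1] over [a,b].

    Returns (length, s_int) with
    integral = y0 * (length - s_int) + y1 * s_int.
    """
    lo, hi = max(t0, a), min(t1, b)
    if hi <= lo:
        return 0.0, 0.0
    w = t1 - t0
    u0, u1 = (lo - t0) / w, (hi - t0) / w
    # primitive of (1 - cos(pi u)) / 2 is (u - sin(pi u)/pi) / 2
    s = 0.5 * ((u1 - math.sin(math.pi * u1) / math.pi)
               - (u0 - math.sin(math.pi * u0) / math.pi))
    return hi - lo, s * w


def _swing_geometry(ps: float, swing: float, lag: float,
                    w2: float = DIP_HW_S):
    w_a = min(CAP_HW_S, 0.45 * ps)
    t_d = swing + lag
    t1 = t_d - w2                      # descent start
    span = t1 - (ps + w_a)             # ramp + plateau span
    if span <= 0.0:
        raise ParameterError("swing too short for the valley geometry")
    w1 = 0.8 * span                    # gentle ramp, short plateau
    r0 = max(ps - w_a, RISE_MIN_S)     # slow rise; may start before TC
    u0 = max(0.0, (r0 - (ps - w_a)) / r0)   # rise phase reached at TC
    return w_a, w1, w2, t1, t_d, span, r0, u0


def _solve_swing(v: float, vst: float, ps: float, swing: float, lag: float,
                 theta_deg: float, w2: float = DIP_HW_S,
                 _retry: bool = True) -> _SwingShape:
    """Solve (y_a, p, c) so the swing integral over (TC, EC] equals theta.

    The swing integral is linear in both the cap-edge level ``y_a`` and the
    plateau level ``c``; the rise-shape exponent ``p`` shrinks the rise area
    for very short strides.  When the drawn PS offset is short, the rise is
    stretched to at least ``RISE_MIN_S`` (starting before TC, riding on the
    stance lobe), and ``y_a`` is capped so the pre-TC onset cannot disturb
    the stance-phase maximum.  Raises :class:`ParameterError` when no shape
    in the admissible box reaches the target.
    """
    if not (v > 0):
        raise ParameterError("v_swing must be positive")
    w_a, w1, w2, t1, t_d, span, r0, u0 = _swing_geometry(ps, swing, lag, w2)
    ec = swing
    # the swing plateau is bounded by the apex only; the valley's right side
    # re-ascends to min(c, 0.85 * v_stance) so the stance maximum is safe
    c_min, c_max = PLATEAU_MIN, 0.92 * v
    # pieces after the cap, clipped to (ps + w_a, ec]:
    l1, s1 = _ramp_integral(ps + w_a, ps + w_a + w1, ps + w_a, ec)   # y_a -> c
    lp = max(0.0, min(t1, ec) - (ps + w_a + w1))                      # plateau c
    l2, s2 = _ramp_integral(t1, t_d, t1, ec)                          # c -> -d

    y_lo = 0.3 * v

    def coeffs(p: int):
        base = w_a * v - DIP_DEPTH * s2
        rise_area = r0 * (_RISE_AREA[p] - _rise_partial(p, u0))
        alpha = rise_area + w_a + (l1 - s1)
        gamma = s1 + lp + (l2 - s2)
        return base, alpha, gamma

    def y_hi(p: int):
        cap = 0.97 * v
        if u0 > 0.0:
            onset = _rise_value(p, u0)
            if onset > 1e-9:
                cap = min(cap, 0.8 * max(vst, 1e-9) / onset)
        return cap

    slope_cap = RAMP_SLOPE_MAX * w1   # max cap-edge-to-plateau drop

    too_large = False
    candidate = None
    for p in (1, 2, 3, 4):
        hi = y_hi(p)
        if hi < y_lo:
            continue
        base, alpha, gamma = coeffs(p)
        y_a = min(APEX_FRAC * v, hi)
        if gamma > 1e-12:
            c = (theta_deg - base - alpha * y_a) / gamma
        else:
            c = c_min - 1.0 if theta_deg < base + alpha * y_a else c_max + 1.0
        if c_min <= c <= c_max:
            candidate = _SwingShape(y_a, p, c, w_a, w1, w2, r0, u0)
            break
        c = c_max if c > c_max else c_min
        if alpha > 1e-12:
            y_a = (theta_deg - base - gamma * c) / alpha
        if c == c_max:
            if y_lo <= y_a <= hi:
                candidate = _SwingShape(y_a, p, c, w_a, w1, w2, r0, u0)
                break
            if y_a > hi:
                too_large = True
        else:
            if y_lo <= y_a <= min(APEX_FRAC * v, hi):
                candidate = _SwingShape(y_a, p, c, w_a, w1, w2, r0, u0)
                break
            # else: try a more convex rise (larger p)
    shape = None
    if candidate is not None and candidate.y_a - candidate.c <= slope_cap:
        shape = candidate
    else:
        # the free-plateau solution descends too steeply after the apex
        # (the sharp ramp would ring through the downstream low-pass
        # filter); tie the plateau to the cap edge at the slope bound
        for p in (1, 2, 3, 4):
            hi = y_hi(p)
            if hi < y_lo:
                continue
            base, alpha, gamma = coeffs(p)
            if alpha + gamma <= 1e-12:
                continue
            y_a = (theta_deg - base + gamma * slope_cap) / (alpha + gamma)
            c = y_a - slope_cap
            if y_lo <= y_a <= hi and c_min <= c <= c_max:
                shape = _SwingShape(y_a, p, c, w_a, w1, w2, r0, u0)
                break
    if shape is None:
        raise ParameterError(
            f"swing integral target {theta_deg:.1f} deg unreachable "
            f"(v_swing={v:.1f}, swing={swing:.3f}s): "
            + ("too large" if too_large else "too small"))
    if _retry and (shape.c + DIP_DEPTH) / shape.w2 > DESCENT_SLOPE_MAX:
        # high plateau: widen the valley descent so it stays smooth
        try:
            return _solve_swing(v, vst, ps, swing, lag, theta_deg,
                                w2=(shape.c + DIP_DEPTH) / DESCENT_SLOPE_MAX,
                                _retry=False)
        except ParameterError:
            pass
    return shape


def _sweep_angle_deg(stride_length: float, cane_length: float) -> float:
    x = stride_length / (2.0 * cane_length)
    if x > 0.996:
        raise ParameterError(
            f"stride length {stride_length:.3f} m exceeds the pendulum chord "
            f"for cane length {cane_length:.3f} m")
    if x < 0.0:
        raise ParameterError("stride length must be non-negative")
    return math.degrees(2.0 * math.asin(x))


# ---------------------------------------------------------------------------
# parameter draws

_INDEP_FIELDS = ("stance_s", "swing_s", "ps_offset_s", "strain_peak",
                 "gpd_ic_lag_s")
_VIGOR_FIELDS = ("v_swing", "v_stance", "stride_length_m", "shank_v_swing")
SHIFT_FIELDS = _INDEP_FIELDS + ("vigor",)

_LAG_LO, _LAG_HI = 0.004, 0.18
_PS_LO = 0.15
_PEAK_LO = 15.0
# the strain apex stays near mid-stance (the loading bump is built
# symmetric about its apex so zero-phase filtering cannot move it); the
# apex-offset jitter below is the residual rise/fall asymmetry
_APEX_JITTER_SD = 0.020
_APEX_JITTER_MAX = 0.045


def _tnorm(rng: Generator, bound: float, size=None):
    """Standard normal truncated to [-bound, bound] (inverse-CDF sampling)."""
    b = max(bound, 1e-6)
    lo = ndtr(-b)
    u = rng.uniform(lo, 1.0 - lo, size=size)
    return ndtri(u)


def _sym_draw(rng: Generator, mean: float, sd: float, lo=None, hi=None,
              max_z: float = 3.0) -> float:
    """One draw from a normal truncated SYMMETRICALLY inside [lo, hi].

    Symmetric truncation keeps the drawn mean exactly at ``mean``; if the
    mean itself violates a bound it is clamped to it.
    """
    if sd <= 0:
        return float(np.clip(mean, lo if lo is not None else -np.inf,
                             hi if hi is not None else np.inf))
    z = max_z
    if lo is not None:
        z = min(z, (mean - lo) / sd)
    if hi is not None:
        z = min(z, (hi - mean) / sd)
    if z <= 0:
        return float(np.clip(mean, lo if lo is not None else -np.inf,
                             hi if hi is not None else np.inf))
    return mean + sd * float(_tnorm(rng, z))


def draw_participant_shifts(cfg: StudyConfig, rng: Generator) -> pd.DataFrame:
    """Standardized per-participant mean offsets, one column per field.

    Shifts are drawn once per participant and shared across all of that
    participant's conditions (giving the repeated-measures structure), and
    centered across the cohort so study-level grand means stay at the
    profile means.  The scalar ``vigor`` column shifts the four
    speed-coupled fields together.
    """
    n = cfg.n_participants
    data = {}
    for f in SHIFT_FIELDS:
        u = np.atleast_1d(_tnorm(rng, 2.5, size=n))
        if n > 1:
            u = u - u.mean()
        data[f] = u
    return pd.DataFrame(data, index=pd.RangeIndex(n, name="participant"))


def _participant_mean(profile: ConditionProfile, f: str, shift, sb: float) -> float:
    g: Gaussian = getattr(profile, f)
    s = float(shift[f]) if shift is not None and f in shift else 0.0
    return g.mean + sb * g.sd * s


def _vigor_mean(profile: ConditionProfile, f: str, shift, sb: float) -> float:
    g: Gaussian = getattr(profile, f)
    s = float(shift["vigor"]) if shift is not None and "vigor" in shift else 0.0
    return g.mean + sb * g.sd * s


def _vigor_feasible_bound(mu: dict, sw_sd: dict, ps, swing, lag,
                          cane_length: float) -> float:
    """Largest z such that the swing shape is solvable on [-z, z]."""
    def ok(z: float) -> bool:
        v = mu["v_swing"] + sw_sd["v_swing"] * z
        vst = mu["v_stance"] + sw_sd["v_stance"] * z
        s_len = mu["stride_length_m"] + sw_sd["stride_length_m"] * z
        if v <= 1e-6 or s_len < 0 or s_len / (2 * cane_length) > 0.996:
            return False
        try:
            _solve_swing(v, vst, ps, swing, lag,
                         _sweep_angle_deg(s_len, cane_length))
        except ParameterError:
            return False
        return True

    def boundary(sign: float) -> float:
        if ok(sign * 3.0):
            return 3.0
        lo, hi = 0.0, 3.0
        for _ in range(6):
            mid = 0.5 * (lo + hi)
            if ok(sign * mid):
                lo = mid
            else:
                hi = mid
        return lo

    if not ok(0.15) or not ok(-0.15):
        return 0.0
    return min(boundary(1.0), boundary(-1.0))


def draw_trial_parameters(profile: ConditionProfile, cfg: StudyConfig,
                          participant_shift=None,
                          rng: Optional[Generator] = None) -> pd.DataFrame:
    """Per-stride parameters for one trial.

    Independent fields use symmetric truncated-normal draws inside their
    physical bounds.  The four speed-coupled fields share one latent factor
    per stride, truncated symmetrically at the per-stride feasibility bound
    of the pendulum sweep constraint; symmetric truncation keeps every drawn
    mean at the (participant-shifted) profile mean.
    """
    rng = default_rng() if rng is None else rng
    beta = cfg.between_participant_sd_scale
    sb, sw = math.sqrt(beta), math.sqrt(1.0 - beta)
    mu = {f: _participant_mean(profile, f, participant_shift, sb)
          for f in _INDEP_FIELDS}
    vmu = {f: _vigor_mean(profile, f, participant_shift, sb)
           for f in _VIGOR_FIELDS}
    sd = {f: sw * getattr(profile, f).sd
          for f in _INDEP_FIELDS + _VIGOR_FIELDS}

    rows = []
    n_clamped = 0
    prev_lag = 0.0
    for k in range(cfg.strides_per_trial):
        stance = _sym_draw(rng, mu["stance_s"], sd["stance_s"],
                           lo=max(0.40, prev_lag + 0.34))
        off = 0.5 * stance + _sym_draw(rng, 0.0, _APEX_JITTER_SD,
                                       lo=-_APEX_JITTER_MAX,
                                       hi=_APEX_JITTER_MAX)
        ps = _sym_draw(rng, mu["ps_offset_s"], sd["ps_offset_s"], lo=_PS_LO)
        swing = _sym_draw(rng, mu["swing_s"], sd["swing_s"],
                          lo=max(0.30, ps + 0.28))
        peak = _sym_draw(rng, mu["strain_peak"], sd["strain_peak"], lo=_PEAK_LO)
        lag = _sym_draw(rng, mu["gpd_ic_lag_s"], sd["gpd_ic_lag_s"],
                        lo=_LAG_LO, hi=_LAG_HI)
        z_star = _vigor_feasible_bound(vmu, sd, ps, swing, lag,
                                       profile.cane_length_m)
        if z_star >= 0.15:
            z = float(_tnorm(rng, z_star))
        else:
            z = 0.0
        v_sw = max(vmu["v_swing"] + sd["v_swing"] * z, 5.0)
        v_st = vmu["v_stance"] + sd["v_stance"] * z
        # tail guard: peak velocity in swing exceeds stance by construction
        v_st = float(np.clip(v_st, 0.0, 0.92 * v_sw))
        s_len = vmu["stride_length_m"] + sd["stride_length_m"] * z
        sh_v = max(vmu["shank_v_swing"] + sd["shank_v_swing"] * z, 5.0)
        s_len = max(s_len, 0.0)
        # fall back to a clamped stride length if even z = 0 is infeasible
        try:
            _solve_swing(v_sw, v_st, ps, swing, lag,
                         _sweep_angle_deg(s_len, profile.cane_length_m))
        except ParameterError:
            n_clamped += 1
            s_len = _max_feasible_stride(v_sw, v_st, ps, swing, lag,
                                         profile.cane_length_m, s_len)
        prev_lag = lag
        rows.append(dict(stride=k, stance_s=stance, swing_s=swing,
                         ps_offset_s=ps, strain_peak=peak,
                         strain_peak_offset_s=off, gpd_ic_lag_s=lag,
                         v_swing=v_sw, v_stance=v_st, stride_length_m=s_len,
                         shank_v_swing=sh_v))
    df = pd.DataFrame(rows)
    df.attrs["n_clamped"] = n_clamped
    return df


def _max_feasible_stride(v, vst, ps, swing, lag, cane_length, s_target) -> float:
    """Feasible stride length nearest to s_target.

    Used only for draws whose target sweep angle falls outside the
    waveform's reachable area range (e.g. near-zero strides below the
    minimum swing-bump area).
    """
    def ok(s):
        try:
            _solve_swing(v, vst, ps, swing, lag, _sweep_angle_deg(s, cane_length))
            return True
        except ParameterError:
            return False

    grid = np.linspace(0.0, 2 * cane_length * 0.995, 240)
    feas = [s for s in grid if ok(s)]
    if not feas:
        raise ParameterError("no feasible stride length for this draw")
    return float(min(feas, key=lambda s: abs(s - s_target)))


# ---------------------------------------------------------------------------
# waveform synthesis

def _cos_ramp(t, t0, t1, y0, y1):
    u = (t - t0) / (t1 - t0)
    return y0 + (y1 - y0) * 0.5 * (1.0 - np.cos(np.pi * u))


def _add_strain_bump(t: np.ndarray, x: np.ndarray, ic: float, stance: float,
                     peak: float, apex_offset: float) -> None:
    """Add one loading bump (deviation from the -EPS baseline) in place."""
    tau = ic + apex_offset
    tc = ic + stance
    b = max(UNDERSHOOT_FRAC * peak, 2.5)   # keep crossings armed vs hysteresis
    phi_r = math.acos((peak - b) / (peak + b)) / math.pi
    t_r0 = (ic - phi_r * tau) / (1.0 - phi_r)
    phi_f = math.acos(-(peak - b) / (peak + b)) / math.pi
    t_f1 = tau + (tc - tau) / phi_f
    pieces = [
        (t_r0 - RECOVER_S, t_r0, -EPS, -b),
        (t_r0, tau, -b, peak),
        (tau, t_f1, peak, -b),
        (t_f1, t_f1 + RECOVER_S, -b, -EPS),
    ]
    for (a0, a1, y0, y1) in pieces:
        m = (t >= a0) & (t < a1)
        if m.any():
            x[m] += _cos_ramp(t[m], a0, a1, y0, y1) - (-EPS)


def _fill(t, x, a0, a1, y0, y1):
    m = (t >= a0) & (t < a1)
    if m.any():
        x[m] = _cos_ramp(t[m], a0, a1, y0, y1)


def _fill_stance_lobe(t, g, t_start, t_end, vst):
    mid = 0.5 * (t_start + t_end)
    _fill(t, g, t_start, mid, 0.0, vst)
    _fill(t, g, mid, t_end, vst, 0.0)


def _fill_cane_swing(t, g, tc, ps_t, ec, lag, shape: _SwingShape, v, vst):
    """Swing bump + post-swing valley on [rise start, valley exit].

    The rise is added on top of whatever is already in ``g`` (it may start
    before TC, riding on the tail of the stance lobe); everything from the
    apex cap onward overwrites.  The valley re-ascends only to
    ``min(c, 0.85 * v_stance)`` — its right side lies in the next stance
    window — with the ascent width chosen so the curvature at the minimum
    matches the descent (the minimum stays put under zero-phase filtering).
    """
    w_a, w1, w2 = shape.w_a, shape.w1, shape.w2
    t_d = ec + lag
    t1 = t_d - w2
    rise_start = ps_t - w_a - shape.r0
    m = (t >= rise_start) & (t < ps_t - w_a)
    if m.any():
        u = (t[m] - rise_start) / shape.r0
        g[m] += shape.y_a * (0.5 * (1.0 - np.cos(np.pi * u))) ** shape.p
    m = (t >= ps_t - w_a) & (t < ps_t + w_a)
    if m.any():
        g[m] = shape.y_a + (v - shape.y_a) * 0.5 * (
            1.0 + np.cos(np.pi * (t[m] - ps_t) / w_a))
    _fill(t, g, ps_t + w_a, ps_t + w_a + w1, shape.y_a, shape.c)
    m = (t >= ps_t + w_a + w1) & (t < t1)
    g[m] = shape.c
    _fill(t, g, t1, t_d, shape.c, -DIP_DEPTH)
    c2 = min(shape.c, 0.85 * vst)
    w3 = w2 * math.sqrt((c2 + DIP_DEPTH) / (shape.c + DIP_DEPTH))
    _fill(t, g, t_d, t_d + w3, -DIP_DEPTH, c2)
    m = (t >= t_d + w3) & (t < t_d + w3 + DIP_PLATEAU_S)
    g[m] = c2
    exit0 = t_d + w3 + DIP_PLATEAU_S
    _fill(t, g, exit0, exit0 + DIP_EXIT_S, c2, 0.0)
    return exit0 + DIP_EXIT_S


def _build_cane_signals(t: np.ndarray, params: pd.DataFrame, t_ic1: float):
    """Noise-free strain and cane AP velocity plus the truth event table."""
    strain = np.full_like(t, -EPS)
    gyro = np.zeros_like(t)
    events = []
    ic = t_ic1
    shapes = []
    n = len(params)
    for k, row in params.iterrows():
        tc = ic + row.stance_s
        ec = tc + row.swing_s
        ps_t = tc + row.ps_offset_s
        theta = _sweep_angle_deg(row.stride_length_m, params.attrs.get(
            "cane_length_m", _BASE_CANE_M))
        shape = _solve_swing(row.v_swing, row.v_stance, row.ps_offset_s,
                             row.swing_s, row.gpd_ic_lag_s, theta)
        shapes.append(shape)
        events.append(dict(stride=k, ic=ic, tc=tc, ps=ps_t, ec=ec,
                           gpd_ic=ec + row.gpd_ic_lag_s,
                           ps_shank=tc + 0.5 * row.swing_s))
        ic = ec
    # strain bumps (stride stances + trailing plant re-using the last draws)
    for ev, (_, row) in zip(events, params.iterrows()):
        _add_strain_bump(t, strain, ev["ic"], row.stance_s, row.strain_peak,
                         row.strain_peak_offset_s)
    last = params.iloc[-1]
    _add_strain_bump(t, strain, events[-1]["ec"], last.stance_s,
                     last.strain_peak, last.strain_peak_offset_s)
    # gyro: initial stance lobe, then swing + valley + next stance lobe
    first = params.iloc[0]
    _fill_stance_lobe(t, gyro, events[0]["ic"], events[0]["tc"], first.v_stance)
    for k, (ev, (_, row), shape) in enumerate(zip(events, params.iterrows(),
                                                  shapes)):
        lobe_start = _fill_cane_swing(t, gyro, ev["tc"], ev["ps"], ev["ec"],
                                      row.gpd_ic_lag_s, shape, row.v_swing,
                                      row.v_stance)
        if k + 1 < n:
            nxt = params.iloc[k + 1]
            _fill_stance_lobe(t, gyro, lobe_start,
                              events[k + 1]["ic"] + nxt.stance_s, nxt.v_stance)
        else:
            _fill_stance_lobe(t, gyro, lobe_start,
                              ev["ec"] + last.stance_s, last.v_stance)
    return strain, gyro, pd.DataFrame(events)


def _add_lobe(t: np.ndarray, g: np.ndarray, center: float, amp: float,
              half_width: float) -> None:
    """Add a raised-cosine lobe (symmetric, compact support) in place."""
    if half_width <= 0.0:
        return
    m = (t >= center - half_width) & (t <= center + half_width)
    if m.any():
        g[m] += amp * 0.5 * (1.0 + np.cos(np.pi * (t[m] - center) / half_width))


def _build_shank_signal(t_wall: np.ndarray, params: pd.DataFrame,
                        events: pd.DataFrame) -> np.ndarray:
    """Additive lobes + contact notches on a zero baseline.

    Per stride: a narrow symmetric negative notch at IC and TC (the impact
    deceleration a gyroscope peak detector reads), a broad stance lobe, and
    a broad swing lobe peaking at PS.  Lobes are wide raised cosines, so the
    8 Hz zero-phase preprocessing passes them essentially unchanged; the
    notches are symmetric, so their minima cannot move.
    """
    g = np.zeros_like(t_wall)
    w_n = SHANK_NOTCH_S
    for k in range(len(events)):
        ev = events.iloc[k]
        row = params.iloc[k]
        ic, tc, ps_t, ec = (float(ev.ic), float(ev.tc), float(ev.ps_shank),
                            float(ev.ec))
        _add_lobe(t_wall, g, ic, -SHANK_VALLEY, w_n)
        _add_lobe(t_wall, g, tc, -SHANK_VALLEY, w_n)
        s_amp = SHANK_STANCE_FRAC * row.shank_v_swing
        _add_lobe(t_wall, g, 0.5 * (ic + tc), s_amp,
                  max(0.5 * (tc - ic) - w_n - 0.02, 0.05))
        w_s = max(min(ps_t - tc, ec - ps_t) - w_n - 0.02, 0.05)
        _add_lobe(t_wall, g, ps_t, row.shank_v_swing, w_s)
    _add_lobe(t_wall, g, float(events.iloc[-1].ec), -SHANK_VALLEY, w_n)
    return g


def synth_stride(profile: ConditionProfile, draw: dict,
                 fs_cane: float = 231.0, fs_shank: float = 100.0):
    """Generate one isolated stride from an explicit parameter draw.

    ``draw`` must provide the per-stride fields (``stance_s``, ``swing_s``,
    ``v_swing``, ``v_stance``, ``ps_offset_s``, ``strain_peak``,
    ``strain_peak_offset_s``, ``stride_length_m``, ``gpd_ic_lag_s``;
    ``shank_v_swing`` defaults to ``v_swing``).  Returns
    ``(strain, cane_gyro, shank_gyro, events)`` where events is a dict of
    exact IC/TC/PS/EC (and ``gpd_ic``) times on the returned time base.
    Raises :class:`ParameterError` when the pendulum sweep constraint is
    unsatisfiable for the draw.
    """
    draw = dict(draw)
    draw.setdefault("shank_v_swing", draw["v_swing"])
    params = pd.DataFrame([{**draw, "stride": 0}])
    params.attrs["cane_length_m"] = profile.cane_length_m
    pad = 1.5
    t_end = pad + draw["stance_s"] + draw["swing_s"] + draw["stance_s"] + pad
    t = np.arange(int(round(t_end * fs_cane))) / fs_cane
    strain, gyro, events = _build_cane_signals(t, params, pad)
    t_sh = np.arange(int(round(t_end * fs_shank))) / fs_shank
    shank = _build_shank_signal(t_sh, params, events)
    ev = events.iloc[0].to_dict()
    return strain, gyro, shank, ev


def generate_trial(profile: ConditionProfile, cfg: StudyConfig,
                   participant_shift=None, seed=0):
    """One walking trial: quiet standing, strides, quiet standing.

    Returns ``(CaneRecording, ShankRecording, TrialTruth)``.  The shank
    stream starts a random 0.3-1.0 s after the cane stream; the offset is
    stored in the truth.  Fixing the seed fixes every output byte.
    """
    rng = default_rng(seed)
    params = draw_trial_parameters(profile, cfg, participant_shift, rng)
    params.attrs["cane_length_m"] = profile.cane_length_m
    offset = float(rng.uniform(0.3, 1.0))
    t_ic1 = _LEAD_IN_S
    total = (t_ic1 + params.stance_s.sum() + params.swing_s.sum()
             + params.stance_s.iloc[-1] + _LEAD_OUT_S)
    n_cane = int(round(total * cfg.fs_cane))
    t_cane = np.arange(n_cane) / cfg.fs_cane
    strain, gyro, events = _build_cane_signals(t_cane, params, t_ic1)
    n_sh = int(round((total - offset) * cfg.fs_shank))
    t_sh = np.arange(n_sh) / cfg.fs_shank
    shank_g = _build_shank_signal(t_sh + offset, params, events)

    strain = strain + rng.normal(0.0, cfg.noise_sd_strain, n_cane)
    gyro = gyro + rng.normal(0.0, cfg.noise_sd_gyro, n_cane)
    gy = rng.normal(0.0, cfg.noise_sd_gyro, n_cane)
    gz = rng.normal(0.0, cfg.noise_sd_gyro, n_cane)
    shank_g = shank_g + rng.normal(0.0, cfg.noise_sd_gyro, n_sh)

    meta = {"condition": profile.name, "cane_length_m": profile.cane_length_m}
    cane = CaneRecording(
        time=t_cane, strain=strain, gyro_x=gyro, gyro_y=gy, gyro_z=gz,
        accel_x=np.zeros(n_cane), accel_y=np.zeros(n_cane),
        accel_z=np.zeros(n_cane), sample_rate=cfg.fs_cane, meta=dict(meta))
    shank = ShankRecording(time=t_sh, gyro_ap=shank_g,
                           sample_rate=cfg.fs_shank, meta=dict(meta))
    truth = TrialTruth(strides=events.merge(params, on="stride"),
                       offset_s=offset,
                       n_clamped=params.attrs.get("n_clamped", 0))
    return cane, shank, truth


def generate_study(cfg: StudyConfig,
                   profiles: Optional[Dict[str, ConditionProfile]] = None
                   ) -> List[StudyTrial]:
    """All participants x conditions trials with shared participant shifts."""
    profiles = default_profiles() if profiles is None else profiles
    missing = [c for c in cfg.conditions if c not in profiles]
    if missing:
        raise ParameterError(f"unknown condition(s): {missing}")
    ss = SeedSequence(cfg.seed)
    children = ss.spawn(1 + cfg.n_participants * len(cfg.conditions))
    shifts = draw_participant_shifts(cfg, default_rng(children[0]))
    trials = []
    idx = 1
    for p in range(cfg.n_participants):
        for cond in cfg.conditions:
            cane, shank, truth = generate_trial(
                profiles[cond], cfg, shifts.iloc[p], seed=children[idx])
            cane.meta["participant"] = p
            shank.meta["participant"] = p
            trials.append(StudyTrial(p, cond, cane, shank, truth))
            idx += 1
    return trials


def draw_study_parameters(cfg: StudyConfig,
                          profiles: Optional[Dict[str, ConditionProfile]] = None
                          ) -> pd.DataFrame:
    """Drawn per-stride parameters for a whole study, without waveforms.

    Uses the same seeds, shifts and truncation machinery as
    :func:`generate_study`; useful for statistics on the injected
    parameters themselves (e.g. power studies).
    """
    profiles = default_profiles() if profiles is None else profiles
    ss = SeedSequence(cfg.seed)
    children = ss.spawn(1 + cfg.n_participants * len(cfg.conditions))
    shifts = draw_participant_shifts(cfg, default_rng(children[0]))
    frames = []
    idx = 1
    for p in range(cfg.n_participants):
        for cond in cfg.conditions:
            rng = default_rng(children[idx])
            df = draw_trial_parameters(profiles[cond], cfg, shifts.iloc[p], rng)
            df.insert(0, "participant", p)
            df.insert(1, "condition", cond)
            frames.append(df)
            idx += 1
    return pd.concat(frames, ignore_index=True)
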