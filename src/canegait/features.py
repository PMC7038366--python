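"""Per-stride gait features from segmented cane (and shank) data.

Eight features characterize each gait cycle: peak AP velocity in swing and
stance (deg/s), the time of the swing peak relative to TC (ms), the
swing/stance duration ratio, the peak strain (ADC counts), the time of the
strain peak relative to IC (ms), the stride length (m), and the difference
between the IC times found by the matched-filter and gyroscope-peak
algorithms on the same cane recording (ms).

Stride length uses a pendulum model: the cane sweeps an angle
``theta = integral of the AP velocity over the swing phase`` and the tip
travels the chord ``2 * L * sin(theta / 2)`` of a circle with the cane
length ``L`` as radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import FeatureError
from .io_filter import CaneRecording, ShankRecording
from .segmentation import GaitEvent, Stride, _refine_peak

__all__ = [
    "StrideFeatures",
    "stride_features",
    "stride_length_pendulum",
    "diff_ic",
    "shank_features",
    "feature_table",
    "condition_summary",
    "FEATURE_NAMES",
]

FEATURE_NAMES = (
    "max_pv_swing",
    "max_pv_stance",
    "max_pv_time_wrt_tc",
    "swing_stance_ratio",
    "max_strain",
    "max_strain_time_wrt_ic",
    "stride_length",
    "diff_ic",
)


@dataclass
class StrideFeatures:
    """The eight per-stride quantities (``None`` where not measurable)."""
    max_pv_swing: Optional[float] = None
    max_pv_stance: Optional[float] = None
    max_pv_time_wrt_tc: Optional[float] = None
    swing_stance_ratio: Optional[float] = None
    max_strain: Optional[float] = None
    max_strain_time_wrt_ic: Optional[float] = None
    stride_length: Optional[float] = None
    diff_ic: Optional[float] = None
    stride_index: Optional[int] = None
    source: str = "MSMF"


def _window_max(signal: np.ndarray, time: np.ndarray, t0: float, t1: float,
                sample_rate: float) -> Tuple[float, float]:
    """Sub-sample-refined maximum of ``signal`` on [t0, t1]."""
    lo = int(np.searchsorted(time, t0, side="left"))
    hi = int(np.searchsorted(time, t1, side="right"))
    if hi - lo < 1:
        raise FeatureError(f"empty window [{t0:.3f}, {t1:.3f}]")
    i = lo + int(np.argmax(signal[lo:hi]))
    t, v = _refine_peak(signal, i, 1.0 / sample_rate, t0=float(time[0]))
    return t, v


def stride_length_pendulum(cane_gyro_ap: np.ndarray, stride: Stride,
                           sample_rate: float, cane_length: float) -> float:
    """Pendulum stride length from the swing-phase AP velocity integral.

    theta is the trapezoidal integral of the AP velocity (converted to
    radians) over (TC, EC]; the stride length is the chord
    ``2 * cane_length * sin(theta / 2)``, clamped at 0 for negative sweeps.
    """
    if cane_length <= 0:
        raise FeatureError("cane length must be positive")
    g = np.asarray(cane_gyro_ap, dtype=float)
    t = np.arange(g.size) / sample_rate
    t0, t1 = stride.tc.t, stride.ec.t
    lo = int(np.searchsorted(t, t0, side="right"))
    hi = int(np.searchsorted(t, t1, side="right"))
    if hi <= lo:
        return 0.0
    theta = float(np.trapezoid(g[lo:hi], t[lo:hi]))
    # partial-sample edge corrections by linear interpolation
    if lo > 0:
        g0 = float(np.interp(t0, t, g))
        theta += 0.5 * (g0 + g[lo]) * (t[lo] - t0)
    if hi < g.size:
        g1 = float(np.interp(t1, t, g))
        theta += 0.5 * (g[hi - 1] + g1) * (t1 - t[hi - 1])
    theta = math.radians(theta)
    if theta <= 0:
        return 0.0
    return 2.0 * cane_length * math.sin(min(theta, math.pi) / 2.0)


def stride_features(stride: Stride, cane: CaneRecording,
                    cane_length: float) -> StrideFeatures:
    """All cane-derived features for one valid stride."""
    if not stride.valid:
        raise FeatureError(
            f"stride {stride.ic.stride_index} invalid: {stride.reason}")
    fs = cane.sample_rate
    ic, tc, ec = stride.ic.t, stride.tc.t, stride.ec.t
    if not (cane.time[0] <= ic and ec <= cane.time[-1]):
        raise FeatureError("stride events outside the recording span")
    ps_t, pv_swing = _window_max(cane.gyro_x, cane.time, tc, ec, fs)
    _, pv_stance = _window_max(cane.gyro_x, cane.time, ic, tc, fs)
    st_t, st_max = _window_max(cane.strain, cane.time, ic, tc, fs)
    return StrideFeatures(
        max_pv_swing=pv_swing,
        max_pv_stance=pv_stance,
        max_pv_time_wrt_tc=(ps_t - tc) * 1000.0,
        swing_stance_ratio=(ec - tc) / (tc - ic),
        max_strain=st_max,
        max_strain_time_wrt_ic=(st_t - ic) * 1000.0,
        stride_length=stride_length_pendulum(cane.gyro_x, stride, fs,
                                             cane_length),
        stride_index=stride.ic.stride_index,
        source="MSMF",
    )


def shank_features(stride: Stride, shank: ShankRecording,
                   limb_length: float = 0.9) -> StrideFeatures:
    """Gyroscope-derived feature subset from a shank-segmented stride.

    Strain-based features stay ``None``; the stride length uses the same
    pendulum form with a configurable effective limb length (a validation
    convenience, not a biomechanical claim).
    """
    if not stride.valid:
        raise FeatureError(
            f"stride {stride.ic.stride_index} invalid: {stride.reason}")
    fs = shank.sample_rate
    ic, tc, ec = stride.ic.t, stride.tc.t, stride.ec.t
    ps_t, pv_swing = _window_max(shank.gyro_ap, shank.time, tc, ec, fs)
    _, pv_stance = _window_max(shank.gyro_ap, shank.time, ic, tc, fs)
    return StrideFeatures(
        max_pv_swing=pv_swing,
        max_pv_stance=pv_stance,
        max_pv_time_wrt_tc=(ps_t - tc) * 1000.0,
        swing_stance_ratio=(ec - tc) / (tc - ic),
        stride_length=stride_length_pendulum(shank.gyro_ap, stride, fs,
                                             limb_length),
        stride_index=stride.ic.stride_index,
        source="GPD",
    )


@dataclass
class DiffICResult:
    """IC pairing between the two detection algorithms on one recording."""
    diffs_ms: np.ndarray          # per pair, MSMF minus GPD, sorted by time
    msmf_t: np.ndarray            # matched MSMF IC times
    gpd_t: np.ndarray             # matched GPD IC times
    unpaired_msmf: list
    unpaired_gpd: list


def diff_ic(msmf_events: Sequence[GaitEvent],
            gpd_events_on_cane: Sequence[GaitEvent],
            max_pair_s: float = 0.2) -> DiffICResult:
    """Per-pair IC time differences (MSMF minus GPD) in milliseconds.

    IC events are paired greedily by smallest absolute gap within
    ``max_pair_s``; each event participates in at most one pair.  The window
    defaults to half the minimum plausible stride duration — far wider than
    any plausible detection lag, yet narrow enough that an IC missed by one
    algorithm cannot steal the partner of its neighbour.  Unpaired ICs
    (either algorithm) are reported separately, never imputed.
    """
    t_m = sorted(e.t for e in msmf_events if e.kind == "IC")
    t_g = sorted(e.t for e in gpd_events_on_cane if e.kind == "IC")
    pairs = []
    for i, tm in enumerate(t_m):
        for j, tg in enumerate(t_g):
            gap = abs(tm - tg)
            if gap <= max_pair_s:
                pairs.append((gap, i, j))
    pairs.sort()
    used_m, used_g = set(), set()
    matches = []
    for gap, i, j in pairs:
        if i in used_m or j in used_g:
            continue
        used_m.add(i)
        used_g.add(j)
        matches.append((t_m[i], t_g[j]))
    matches.sort()
    diffs = np.asarray([(tm - tg) * 1000.0 for tm, tg in matches])
    un_m = [t for i, t in enumerate(t_m) if i not in used_m]
    un_g = [t for j, t in enumerate(t_g) if j not in used_g]
    return DiffICResult(diffs,
                        np.asarray([tm for tm, _ in matches]),
                        np.asarray([tg for _, tg in matches]),
                        un_m, un_g)


def feature_table(records: List[dict]) -> pd.DataFrame:
    """Tidy feature table: one row per stride x feature."""
    rows = []
    for rec in records:
        feats: StrideFeatures = rec["features"]
        for name in FEATURE_NAMES:
            v = getattr(feats, name)
            if v is None:
                continue
            rows.append(dict(participant=rec.get("participant"),
                             condition=rec.get("condition"),
                             stride_index=feats.stride_index,
                             source=feats.source, feature=name, value=v))
    return pd.DataFrame(rows)


def condition_summary(table: pd.DataFrame):
    """Per-condition mean and sd per feature, plus per-participant means.

    Returns ``(summary, subject_means)``: the first indexed by
    (condition, feature, source) with columns mean/sd/n (sd of a single
    stride is 0); the second the per-participant mean matrix handed to the
    repeated-measures statistics.
    """
    if table.empty:
        raise FeatureError("empty feature table")
    g = table.groupby(["condition", "feature", "source"])["value"]
    summary = g.agg(mean="mean", sd="std", n="count").reset_index()
    summary["sd"] = summary["sd"].fillna(0.0)
    subj = (table.groupby(["feature", "source", "participant", "condition"])
            ["value"].mean().reset_index())
    return summary, subj
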