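"""End-to-end study pipeline: preprocess -> segment -> features -> stats."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .exceptions import DataError
from .features import (StrideFeatures, condition_summary, diff_ic,
                       feature_table, shank_features, stride_features)
from .io_filter import CaneRecording, ShankRecording, preprocess
from .segmentation import (SegConfig, assemble_strides, auto_threshold,
                           build_template, detect_events_msmf, detect_ps_gpd,
                           events_from_ps_gpd)
from .stats_report import (AnovaResult, PairwiseComparison,
                           bonferroni_pairwise, make_report,
                           normalize_to_control, rm_anova_oneway,
                           subject_matrix)
from .synth import StudyConfig, StudyTrial, default_profiles, generate_study

__all__ = ["TrialResult", "StudyResult", "run_trial", "run_study"]


@dataclass
class TrialResult:
    """Segmentation + features for one trial."""
    msmf_events: list
    msmf_strides: list
    cane_features: List[StrideFeatures]
    gpd_cane_events: list
    diff_ic_ms: np.ndarray
    shank_strides: list = field(default_factory=list)
    shank_features: List[StrideFeatures] = field(default_factory=list)


@dataclass
class StudyResult:
    table: pd.DataFrame
    summary: pd.DataFrame
    subject_means: pd.DataFrame
    anovas: Dict[str, AnovaResult]
    pairwise: Dict[str, List[PairwiseComparison]]
    report: pd.DataFrame
    normalized: Optional[pd.DataFrame]


def run_trial(cane: CaneRecording, shank: Optional[ShankRecording] = None,
              cane_length: float = 0.90, seg: SegConfig = SegConfig(),
              limb_length: float = 0.90) -> TrialResult:
    """Full single-trial analysis on raw recordings.

    MSMF segments the cane data and yields the strain/velocity features;
    GPD applied to the same cane gyroscope provides the second IC estimate
    for the IC-difference feature; GPD on the shank stream (when present)
    yields the validation feature subset.
    """
    cane_p, shank_p = preprocess(cane, shank)
    fs = cane_p.sample_rate
    template = build_template(cane_p.strain, fs, seg.template_strides)
    msmf_events = detect_events_msmf(cane_p.strain, cane_p.gyro_x, fs,
                                     template, seg)
    strides = [s for s in assemble_strides(msmf_events) if s.valid]
    feats = [stride_features(s, cane_p, cane_length) for s in strides]

    thr = (auto_threshold(cane_p.gyro_x) if seg.gpd_threshold == "auto"
           else float(seg.gpd_threshold))
    ps = detect_ps_gpd(cane_p.gyro_x, fs, thr, seg.min_stride_s)
    gpd_cane = events_from_ps_gpd(cane_p.gyro_x, fs, ps,
                                  seg.min_prominence, seg.max_stride_s,
                                  seg.min_valley_depth)
    pairing = diff_ic(msmf_events, gpd_cane, seg.min_stride_s / 2.0)
    by_ic = {round(t, 9): d for t, d in zip(pairing.msmf_t, pairing.diffs_ms)}
    for s, f in zip(strides, feats):
        f.diff_ic = by_ic.get(round(s.ic.t, 9))

    sh_strides: list = []
    sh_feats: List[StrideFeatures] = []
    if shank_p is not None:
        fs_sh = shank_p.sample_rate
        thr_sh = (auto_threshold(shank_p.gyro_ap) if seg.gpd_threshold == "auto"
                  else float(seg.gpd_threshold))
        ps_sh = detect_ps_gpd(shank_p.gyro_ap, fs_sh, thr_sh, seg.min_stride_s)
        ev_sh = events_from_ps_gpd(shank_p.gyro_ap, fs_sh, ps_sh,
                                   seg.min_prominence, seg.max_stride_s,
                                   seg.min_valley_depth)
        sh_strides = [s for s in assemble_strides(ev_sh) if s.valid]
        sh_feats = [shank_features(s, shank_p, limb_length)
                    for s in sh_strides]
    return TrialResult(msmf_events, strides, feats, gpd_cane,
                       pairing.diffs_ms, sh_strides, sh_feats)


def run_study(cfg: StudyConfig, seg: SegConfig = SegConfig(),
              profiles=None, include_shank: bool = True,
              trials: Optional[List[StudyTrial]] = None) -> StudyResult:
    """Simulate (or take) a study, run every trial, summarize and test."""
    profiles = default_profiles() if profiles is None else profiles
    if trials is None:
        trials = generate_study(cfg, profiles)
    records = []
    for tr in trials:
        cane_length = profiles[tr.condition].cane_length_m
        res = run_trial(tr.cane, tr.shank if include_shank else None,
                        cane_length=cane_length, seg=seg)
        for f in res.cane_features:
            records.append(dict(participant=tr.participant,
                                condition=tr.condition, features=f))
        for f in res.shank_features:
            records.append(dict(participant=tr.participant,
                                condition=tr.condition, features=f))
    table = feature_table(records)
    if table.empty:
        raise DataError("no strides segmented in the whole study")
    summary, subj = condition_summary(table)
    conditions = list(cfg.conditions)
    anovas: Dict[str, AnovaResult] = {}
    pairwise: Dict[str, List[PairwiseComparison]] = {}
    if len(conditions) >= 2:
        for feature in table.feature.unique():
            try:
                m = subject_matrix(subj, feature, conditions, source="MSMF")
            except DataError:
                continue
            anovas[feature] = rm_anova_oneway(m, feature)
            pairwise[feature] = bonferroni_pairwise(m, conditions=conditions,
                                                    feature=feature)
    report = make_report(summary, anovas, pairwise)
    normalized = None
    if "control" in conditions:
        normalized = normalize_to_control(summary)
    return StudyResult(table, summary, subj, anovas, pairwise, report,
                       normalized)
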