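"""End-to-end IMU-to-segment pairing and the simulated validation harness.

``pair_bout`` runs the full chain on the 1-8 sensors of one walking bout:
4 Hz low-pass filtering, location-agnostic stride time (median over
sensors), stride-scaled feature extraction, decision-tree segment labels,
then side identification.  Foot sides come from functional calibration plus
the 3-feature tree; shank/thigh sides from the smaller-swing-during-foot-
flat rule, which needs both pair members and one sided foot.

Side identification operates on the unfiltered signals: the 5 deg/s
foot-flat threshold and the push-off peak values are physical quantities
that a 4 Hz low-pass distorts badly at high cadence (at a 0.45 s stride the
filter passes little beyond the stride fundamental, and a band-limited
signal cannot sit below 5 deg/s for 15% of the cycle).  Filtering is for
the spectra and amplitude statistics.

``run_experiment`` reproduces the shape of the validation study on
synthetic cohorts: train on healthy subjects (75-25 subject-wise train/dev
split for the feature-count curves), test on a disjoint pathological
cohort, report one-vs-rest metrics per class.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import side_id as sid
from .features import (
    DEFAULT_SEGMENT_FEATURES,
    FeatureVector,
    extract_features,
    features_to_frame,
    fit_zscore,
)
from .gait_sim import SENSOR_ROSTER, SimConfig, SyntheticBout, generate_dataset, sensor_name
from .imu_signals import ImuRecording, load_recording, lowpass_filter
from .segment_model import (
    DecisionTreeModel,
    RankedFeatures,
    SelectionResult,
    evaluate,
    mrmr_rank,
    select_count,
    train_tree,
)
from .stride_time import estimate_stride_time

logger = logging.getLogger(__name__)

#: the eight pairing classes of a full sensor set
PAIRING_CLASSES = tuple(sensor_name(seg, side) for seg, side in SENSOR_ROSTER)


class PipelineError(ValueError):
    pass


@dataclasses.dataclass
class SensorResult:
    segment: str
    side: Optional[str]  # left/right, None (no side applies), or "unknown"
    reason: Optional[str]  # why a side is unknown
    stride_time: float  # this sensor's own fused estimate
    chosen_channel: Optional[str]
    leaf_purity: float

    def pairing_label(self) -> str:
        if self.side in ("left", "right"):
            return f"{self.segment}_{self.side}"
        if self.side == "unknown":
            return "unknown"
        return self.segment


@dataclasses.dataclass
class PairingResult:
    """Per-sensor segment/side labels plus bout-level diagnostics."""

    sensors: dict[str, SensorResult]
    stride_time: float


def _foot_flat_total(rec: ImuRecording, stride_time: float) -> float:
    try:
        flats = sid.detect_foot_flat(rec, stride_time)
    except sid.SideIdError:
        return 0.0
    return sum(e - s for s, e in flats.intervals) / rec.fs


def pair_bout(
    recordings: Union[Mapping[str, ImuRecording], Sequence[ImuRecording]],
    segment_model: DecisionTreeModel,
    foot_side_model: Optional[DecisionTreeModel] = None,
    cutoff: float = 4.0,
) -> PairingResult:
    """Pair every sensor of one walking bout with a segment and a side."""
    if not isinstance(recordings, Mapping):
        recordings = {rec.sensor_id: rec for rec in recordings}
    if not recordings:
        raise PipelineError("no recordings given")
    raw = dict(recordings)
    filt = {k: lowpass_filter(r, cutoff=cutoff) for k, r in raw.items()}

    estimates = {k: estimate_stride_time(r) for k, r in filt.items()}
    stride = float(np.median([e.mean_stride_time for e in estimates.values()]))
    logger.info("bout stride time %.3f s from %d sensors", stride, len(raw))

    labels: dict[str, str] = {}
    purities: dict[str, float] = {}
    probs: dict[str, dict[str, float]] = {}
    for k, r in filt.items():
        fv = extract_features(r, stride)
        lab, pur, pr = segment_model.predict_detail(fv)
        labels[k], purities[k], probs[k] = lab, pur, pr
        logger.info("sensor %s -> %s (purity %.2f)", k, lab, pur)

    # more than two "foot" labels cannot all be right: keep the two sensors
    # with the longest total foot-flat time, demote the rest to their leaf's
    # next-most-probable class
    feet = [k for k, lab in labels.items() if lab == "foot"]
    if len(feet) > 2:
        feet_sorted = sorted(
            feet, key=lambda k: _foot_flat_total(raw[k], stride), reverse=True
        )
        for k in feet_sorted[2:]:
            alt = {c: p for c, p in probs[k].items() if c != "foot"}
            labels[k] = max(alt, key=alt.get) if any(alt.values()) else "shank"
            logger.info("demoted surplus foot sensor %s -> %s", k, labels[k])

    results: dict[str, SensorResult] = {}
    for k in raw:
        results[k] = SensorResult(
            segment=labels[k],
            side=None,
            reason=None,
            stride_time=estimates[k].mean_stride_time,
            chosen_channel=estimates[k].chosen_channel,
            leaf_purity=purities[k],
        )

    # foot sides via functional calibration + 3-feature tree
    sided_feet: list[tuple[str, str]] = []
    for k in (k for k, lab in labels.items() if lab == "foot"):
        if foot_side_model is None:
            results[k].side, results[k].reason = "unknown", "no foot-side model"
            continue
        try:
            flats = sid.detect_foot_flat(raw[k], stride)
            cal = sid.functional_calibration(raw[k], flats)
            feats = sid.foot_side_features(sid.apply_calibration(raw[k], cal), flats)
            side = sid.classify_foot_side(feats, foot_side_model)
            results[k].side = side
            sided_feet.append((k, side))
        except sid.SideIdError as exc:
            results[k].side, results[k].reason = "unknown", str(exc)

    # shank/thigh sides from one labeled foot (both pair members required)
    for segment in ("shank", "thigh"):
        members = [k for k, lab in labels.items() if lab == segment]
        if not members:
            continue
        if len(members) != 2:
            for k in members:
                results[k].side = "unknown"
                results[k].reason = f"unpaired {segment} ({len(members)} present)"
            continue
        if not sided_feet:
            for k in members:
                results[k].side, results[k].reason = "unknown", "no sided foot sensor"
            continue
        foot_k, foot_side = sided_feet[0]
        try:
            assignment = sid.assign_limb_side(
                {k: raw[k] for k in members}, raw[foot_k], foot_side, stride
            )
            for k, side in assignment.items():
                results[k].side = side
        except sid.SideIdError as exc:
            for k in members:
                results[k].side, results[k].reason = "unknown", str(exc)

    return PairingResult(sensors=results, stride_time=stride)


# ---------------------------------------------------------------------------
# Training and the simulated validation experiment
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BoutFeatures:
    """Cached per-sensor features of one bout (training plumbing)."""

    subject_id: str
    stride_estimate: float
    true_stride_time: float
    vectors: dict[str, FeatureVector]
    truth: dict[str, tuple[str, Optional[str]]]


def bout_features(bout: SyntheticBout, cutoff: float = 4.0) -> BoutFeatures:
    filt = {k: lowpass_filter(r, cutoff=cutoff) for k, r in bout.recordings.items()}
    stride = float(
        np.median([estimate_stride_time(r).mean_stride_time for r in filt.values()])
    )
    vectors = {k: extract_features(r, stride) for k, r in filt.items()}
    return BoutFeatures(
        subject_id=bout.subject_id,
        stride_estimate=stride,
        true_stride_time=bout.true_stride_time,
        vectors=vectors,
        truth=dict(bout.truth),
    )


def _foot_side_rows(
    bouts: Sequence[SyntheticBout], strides: Sequence[float]
) -> tuple[list[sid.SideFeatures], list[str]]:
    feats: list[sid.SideFeatures] = []
    sides: list[str] = []
    for bout, stride in zip(bouts, strides):
        for name, (segment, side) in bout.truth.items():
            if segment != "foot":
                continue
            rec = bout.recordings[name]
            try:
                flats = sid.detect_foot_flat(rec, stride)
                cal = sid.functional_calibration(rec, flats)
                feats.append(
                    sid.foot_side_features(sid.apply_calibration(rec, cal), flats)
                )
                sides.append(side)
            except sid.SideIdError:
                continue
    return feats, sides


@dataclasses.dataclass
class TrainedModels:
    segment: DecisionTreeModel
    foot_side: DecisionTreeModel
    ranked: Optional[RankedFeatures] = None
    selection: Optional[SelectionResult] = None


def train_models(
    healthy: Sequence[SyntheticBout],
    feature_names: Optional[Sequence[str]] = None,
    split_seed: int = 0,
    run_selection: bool = True,
    max_k: int = 15,
) -> TrainedModels:
    """Fit the segment tree and the foot-side tree on a healthy cohort.

    Subjects are split 75-25 into training and development sets for the
    MRMR feature-count curves; the final tree uses ``feature_names``
    (default: the shipped 7-feature set) and is refit on all subjects.
    """
    feats = [bout_features(b) for b in healthy]
    subjects = sorted({bf.subject_id for bf in feats})
    rng = np.random.default_rng(split_seed)
    rng.shuffle(subjects)
    n_train = max(1, int(round(0.75 * len(subjects))))
    train_subj = set(subjects[:n_train])

    def frame(rows: Sequence[BoutFeatures]) -> tuple[pd.DataFrame, np.ndarray]:
        vecs, labs = [], []
        for bf in rows:
            for name, fv in bf.vectors.items():
                vecs.append(fv)
                labs.append(bf.truth[name][0])
        return features_to_frame(vecs), np.asarray(labs)

    X_all, y_all = frame(feats)
    zscore = fit_zscore(X_all)
    cols = list(zscore.feature_names)

    def z(df: pd.DataFrame) -> pd.DataFrame:
        return (df[cols] - pd.Series(zscore.mean)) / pd.Series(zscore.std)

    ranked = selection = None
    if run_selection and len(subjects) >= 2:
        tr = [bf for bf in feats if bf.subject_id in train_subj]
        dv = [bf for bf in feats if bf.subject_id not in train_subj]
        X_tr, y_tr = frame(tr)
        X_dv, y_dv = frame(dv)
        ranked = mrmr_rank(z(X_tr), y_tr)
        selection = select_count(ranked, z(X_tr), y_tr, z(X_dv), y_dv, max_k=max_k)
        logger.info("feature-count curves selected k=%d", selection.k)

    names = list(feature_names) if feature_names else list(DEFAULT_SEGMENT_FEATURES)
    segment = train_tree(z(X_all), y_all, names, zscore=zscore)
    side_feats, side_labels = _foot_side_rows(healthy, [bf.stride_estimate for bf in feats])
    foot_side = sid.train_foot_side_model(side_feats, side_labels)
    return TrainedModels(segment=segment, foot_side=foot_side, ranked=ranked, selection=selection)


@dataclasses.dataclass
class ExperimentReport:
    models: TrainedModels
    metrics: pd.DataFrame  # Table-2-shaped, 8 pairing classes + overall
    segment_metrics: pd.DataFrame  # 5 segment classes + overall
    stride_errors: np.ndarray  # per test bout, estimated - true (s)
    n_test_bouts: int

    @property
    def weighted_accuracy(self) -> float:
        return float(self.metrics.loc["overall", "accuracy"])


def run_experiment(
    seed: int = 0,
    n_healthy: int = 12,
    healthy_bouts: int = 42,
    n_patients: int = 22,
    patient_bouts: int = 24,
    feature_names: Optional[Sequence[str]] = None,
    run_selection: bool = False,
) -> ExperimentReport:
    """Train on simulated healthy subjects, test on a pathological cohort.

    Defaults mirror the validation study's shape: 504 healthy bouts
    (12 x 42) for training/development and 528 pathological bouts (22 x 24)
    for testing, all 8 sensors per bout.
    """
    healthy_cfg = SimConfig(n_subjects=n_healthy, bouts_per_subject=healthy_bouts, seed=seed)
    patient_cfg = SimConfig(
        n_subjects=n_patients,
        bouts_per_subject=patient_bouts,
        pathology=True,
        seed=seed + 104729,
    )
    healthy, _ = generate_dataset(healthy_cfg)
    patients, _ = generate_dataset(patient_cfg)
    models = train_models(healthy, feature_names=feature_names,
                          split_seed=seed, run_selection=run_selection)

    truths, preds = [], []
    seg_truths, seg_preds = [], []
    stride_errors = []
    for bout in patients:
        result = pair_bout(bout.recordings, models.segment, models.foot_side)
        stride_errors.append(result.stride_time - bout.true_stride_time)
        for name, (segment, side) in bout.truth.items():
            truths.append(sensor_name(segment, side))
            preds.append(result.sensors[name].pairing_label())
            seg_truths.append(segment)
            seg_preds.append(result.sensors[name].segment)
    classes = list(PAIRING_CLASSES) + ["unknown"]
    metrics = evaluate(preds, truths, classes=classes)
    segment_metrics = evaluate(seg_preds, seg_truths)
    return ExperimentReport(
        models=models,
        metrics=metrics,
        segment_metrics=segment_metrics,
        stride_errors=np.asarray(stride_errors),
        n_test_bouts=len(patients),
    )


def configuration_sweep(
    bouts: Sequence[SyntheticBout],
    segment_model: DecisionTreeModel,
    foot_side_model: Optional[DecisionTreeModel] = None,
) -> pd.DataFrame:
    """Pairing accuracy for all 255 non-empty sensor subsets.

    Every bout is re-paired using only the sensors of the subset; the
    returned table has one row per subset with the fraction of correct
    segment labels (and of correct full labels where a side is defined).
    """
    names = [sensor_name(seg, side) for seg, side in SENSOR_ROSTER]
    rows = []
    for mask in range(1, 1 << len(names)):
        subset = [names[i] for i in range(len(names)) if mask >> i & 1]
        seg_ok = seg_n = full_ok = full_n = 0
        for bout in bouts:
            recs = {k: bout.recordings[k] for k in subset}
            result = pair_bout(recs, segment_model, foot_side_model)
            for k in subset:
                segment, side = bout.truth[k]
                seg_n += 1
                seg_ok += result.sensors[k].segment == segment
                full_n += 1
                full_ok += result.sensors[k].pairing_label() == sensor_name(segment, side)
        rows.append(
            {
                "subset": "+".join(subset),
                "n_sensors": len(subset),
                "segment_accuracy": seg_ok / seg_n,
                "pairing_accuracy": full_ok / full_n,
            }
        )
    return pd.DataFrame(rows)
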