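"""Histopathology-driven, segment-wise adjustment of the voxel TCP model.

Biopsy reports divide the prostate into 6-12 anatomical segments (left/right
x base/mid/apex, optionally x anterior/posterior) and state, per segment, a
Gleason Score and the percentage of adenocarcinoma found in the core.  This
module reproduces that structure on the voxel grid and builds the per-voxel
model parameters for the four adjustment methods:

1. no adjustment (atlas cell density, sampled alpha, single alpha/beta);
2. cell density scaled by the segment's % adenocarcinoma (1% floor for
   benign segments);
3. as 2, plus fixed Gleason-Pattern-dependent alpha applied 75:25
   (primary:secondary pattern) within each voxel;
4. as 2, plus Gleason-Score-dependent alpha/beta per segment.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .tcp_core import (
    GS_LABELS,
    ProstateModel,
    RadiosensitivityParams,
    TreatmentSchedule,
    VoxelGrid,
)

__all__ = [
    "SEGMENTS_6",
    "SEGMENTS_12",
    "SegmentFinding",
    "HistopathReport",
    "SegmentLabelMap",
    "segment_prostate",
    "parse_report",
    "write_report",
    "adjust_clonogens",
    "assign_method_params",
    "build_patient_model",
]

_SIDES = ("left", "right")
_THIRDS = ("base", "mid", "apex")
_DEPTHS = ("anterior", "posterior")

#: Canonical six-segment labels ("left base", ..., "right apex").
SEGMENTS_6: tuple[str, ...] = tuple(
    f"{s} {t}" for s in _SIDES for t in _THIRDS
)
#: Twelve-segment labels with an anterior/posterior split.
SEGMENTS_12: tuple[str, ...] = tuple(
    f"{s} {t} {d}" for s in _SIDES for t in _THIRDS for d in _DEPTHS
)

_VALID_SEGMENTS = set(SEGMENTS_6) | set(SEGMENTS_12)

#: Fraction of atlas cell density retained in benign segments, accounting
#: for potential tumor sites the biopsy missed.
BENIGN_DENSITY_FLOOR = 0.01


# ---------------------------------------------------------------------------
# Report structures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentFinding:
    """One biopsy segment's findings.

    Benign segments have both Gleason patterns absent and 0% adenocarcinoma.
    """

    segment: str
    gleason_primary: Optional[int] = None
    gleason_secondary: Optional[int] = None
    percent_adenocarcinoma: float = 0.0

    def __post_init__(self) -> None:
        if self.segment not in _VALID_SEGMENTS:
            raise ValueError(f"unknown segment label {self.segment!r}")
        p, s = self.gleason_primary, self.gleason_secondary
        if (p is None) != (s is None):
            raise ValueError(
                f"segment {self.segment!r}: primary and secondary Gleason "
                "patterns must both be present or both absent"
            )
        if p is not None:
            for name, v in (("primary", p), ("secondary", s)):
                if v not in (2, 3, 4, 5):
                    raise ValueError(
                        f"segment {self.segment!r}: {name} Gleason pattern "
                        f"{v} outside 2..5"
                    )
        pct = self.percent_adenocarcinoma
        if not (0.0 <= pct <= 100.0):
            raise ValueError(
                f"segment {self.segment!r}: percent_adenocarcinoma {pct} "
                "outside [0, 100]"
            )
        if (pct == 0.0) != (p is None):
            raise ValueError(
                f"segment {self.segment!r}: percent_adenocarcinoma must be 0 "
                "exactly when Gleason patterns are absent"
            )

    @property
    def is_benign(self) -> bool:
        return self.gleason_primary is None

    @property
    def gleason_score(self) -> Optional[str]:
        """'a+b' string, or None for benign segments."""
        if self.is_benign:
            return None
        return f"{self.gleason_primary}+{self.gleason_secondary}"


@dataclass(frozen=True)
class HistopathReport:
    """Structured per-segment biopsy report for one patient."""

    patient_id: str
    findings: tuple[SegmentFinding, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "findings", tuple(self.findings))
        labels = [f.segment for f in self.findings]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate segment label(s) {dupes}")
        if not (6 <= len(labels) <= 12):
            raise ValueError(
                f"report must cover 6-12 segments, got {len(labels)}"
            )

    def finding(self, segment: str) -> SegmentFinding:
        for f in self.findings:
            if f.segment == segment:
                return f
        raise KeyError(f"no finding for segment {segment!r}")

    @property
    def segments(self) -> tuple[str, ...]:
        return tuple(f.segment for f in self.findings)


def _finding_from_row(segment: str, gleason: str, percent) -> SegmentFinding:
    gleason = str(gleason).strip().lower()
    if gleason in ("benign", "", "none"):
        return SegmentFinding(segment.strip().lower(), None, None, 0.0)
    parts = gleason.split("+")
    if len(parts) != 2:
        raise ValueError(f"malformed Gleason score {gleason!r} (expect 'a+b')")
    return SegmentFinding(
        segment.strip().lower(),
        int(parts[0]),
        int(parts[1]),
        float(percent),
    )


def parse_report(path: Union[str, Path]) -> HistopathReport:
    """Read a structured histopathology report (JSON or CSV).

    JSON schema::

        {"patient_id": "...",
         "findings": [{"segment": "left apex", "gleason": "3+4",
                       "percent_adenocarcinoma": 20}, ...]}

    CSV dialect: columns ``patient_id, segment, gleason,
    percent_adenocarcinoma`` (``gleason`` is 'a+b' or 'benign').
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        findings = [
            _finding_from_row(
                f["segment"], f["gleason"], f.get("percent_adenocarcinoma", 0)
            )
            for f in raw["findings"]
        ]
        return HistopathReport(str(raw["patient_id"]), tuple(findings))
    if path.suffix.lower() == ".csv":
        with path.open(newline="") as fh:
            rows = list(csv.DictReader(fh))
        if not rows:
            raise ValueError(f"empty report file {path}")
        pids = {r["patient_id"] for r in rows}
        if len(pids) != 1:
            raise ValueError("report CSV must describe a single patient")
        findings = [
            _finding_from_row(
                r["segment"], r["gleason"], r.get("percent_adenocarcinoma", 0)
            )
            for r in rows
        ]
        return HistopathReport(pids.pop(), tuple(findings))
    raise ValueError(f"unsupported report format {path.suffix!r}")


def write_report(report: HistopathReport, path: Union[str, Path]) -> None:
    """Serialize a report to JSON or CSV (inverse of :func:`parse_report`)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "patient_id": report.patient_id,
            "findings": [
                {
                    "segment": f.segment,
                    "gleason": f.gleason_score or "benign",
                    "percent_adenocarcinoma": f.percent_adenocarcinoma,
                }
                for f in report.findings
            ],
        }
        path.write_text(json.dumps(payload, indent=2))
    elif path.suffix.lower() == ".csv":
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["patient_id", "segment", "gleason", "percent_adenocarcinoma"]
            )
            for f in report.findings:
                w.writerow(
                    [
                        report.patient_id,
                        f.segment,
                        f.gleason_score or "benign",
                        f.percent_adenocarcinoma,
                    ]
                )
    else:
        raise ValueError(f"unsupported report format {path.suffix!r}")


# ---------------------------------------------------------------------------
# Geometric segmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentLabelMap:
    """Partition of the prostate mask into anatomical segments.

    ``labels`` holds an integer code per voxel (-1 outside the mask);
    ``names[code]`` is the segment label.
    """

    labels: np.ndarray
    names: tuple[str, ...]

    @property
    def mask(self) -> np.ndarray:
        return self.labels >= 0

    def mask_for(self, name: str) -> np.ndarray:
        try:
            code = self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown segment {name!r}") from None
        return self.labels == code

    def validate_partition(self) -> None:
        mask = self.mask
        codes = self.labels[mask]
        if codes.min(initial=0) < 0 or codes.max(initial=0) >= len(self.names):
            raise ValueError("label codes out of range")
        counts = np.bincount(codes, minlength=len(self.names))
        empty = [self.names[i] for i, c in enumerate(counts) if c == 0]
        if empty:
            raise ValueError(f"empty segment(s): {empty}")


def segment_prostate(
    mask: np.ndarray,
    n_segments: int = 6,
    si_axis: int = 2,
    lr_axis: int = 0,
    ap_axis: int = 1,
    plane_offsets: tuple[float, float] = (0.0, 0.0),
) -> SegmentLabelMap:
    """Divide a prostate mask into 6 or 12 biopsy-style segments.

    Left/right at the mask centroid's sagittal plane (offset configurable,
    in voxels), base/mid/apex as equal-extent thirds of the mask's
    superior-inferior span (base = superior third), and, for 12 segments,
    anterior/posterior at the centroid coronal plane.
    """
    mask = np.asarray(mask, dtype=bool)
    if n_segments not in (6, 12):
        raise ValueError("n_segments must be 6 or 12")
    if not mask.any():
        raise ValueError("empty mask")
    idx = np.argwhere(mask)
    centroid = idx.mean(axis=0)

    lr = idx[:, lr_axis]
    is_left = lr >= centroid[lr_axis] + plane_offsets[0]

    si = idx[:, si_axis]
    lo, hi = si.min(), si.max()
    extent = hi - lo + 1
    # thirds of equal superior-inferior extent; base is the superior third
    third = np.minimum(2, ((si - lo) * 3) // extent).astype(int)
    third_name = {2: "base", 1: "mid", 0: "apex"}

    names = SEGMENTS_6 if n_segments == 6 else SEGMENTS_12
    code_of = {n: i for i, n in enumerate(names)}
    labels = np.full(mask.shape, -1, dtype=np.int16)

    if n_segments == 6:
        seg_names = [
            f"{'left' if l else 'right'} {third_name[t]}"
            for l, t in zip(is_left, third)
        ]
    else:
        ap = idx[:, ap_axis]
        is_post = ap >= centroid[ap_axis] + plane_offsets[1]
        seg_names = [
            f"{'left' if l else 'right'} {third_name[t]}"
            f" {'posterior' if p else 'anterior'}"
            for l, t, p in zip(is_left, third, is_post)
        ]
    labels[tuple(idx.T)] = [code_of[n] for n in seg_names]

    out = SegmentLabelMap(labels, names)
    out.validate_partition()
    return out


# ---------------------------------------------------------------------------
# Parameter-field construction
# ---------------------------------------------------------------------------


def _check_report_covers(labelmap: SegmentLabelMap, report: HistopathReport) -> None:
    have = set(report.segments)
    need = set(labelmap.names)
    missing = sorted(need - have)
    if missing:
        raise ValueError(f"report lacks findings for segment(s) {missing}")
    extra = sorted(have - need)
    if extra:
        raise ValueError(f"report has findings for unknown segment(s) {extra}")


def adjust_clonogens(
    cd_atlas: np.ndarray,
    labelmap: SegmentLabelMap,
    report: HistopathReport,
    tp_atlas: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Scale atlas cell density by each segment's % adenocarcinoma.

    ``N_i = CD_i * max(p_seg, 0.01) * (TP_i if supplied else 1)`` where
    ``p_seg`` is the segment's fraction of adenocarcinoma; benign segments
    receive the 1% floor.  Returns a full-grid clonogen map (0 outside the
    mask).
    """
    cd_atlas = np.asarray(cd_atlas, dtype=float)
    if cd_atlas.shape != labelmap.labels.shape:
        raise ValueError("cell-density atlas and label map grids differ")
    if tp_atlas is not None:
        tp_atlas = np.asarray(tp_atlas, dtype=float)
        if tp_atlas.shape != labelmap.labels.shape:
            raise ValueError("tumor-probability atlas and label map grids differ")
    _check_report_covers(labelmap, report)

    factor = np.zeros(labelmap.labels.shape)
    for name in labelmap.names:
        f = report.finding(name)
        p = max(f.percent_adenocarcinoma / 100.0, BENIGN_DENSITY_FLOOR)
        factor[labelmap.mask_for(name)] = p
    out = np.where(labelmap.mask, cd_atlas * factor, 0.0)
    if tp_atlas is not None:
        out = out * np.where(labelmap.mask, tp_atlas, 0.0)
    return out


def assign_method_params(
    labelmap: SegmentLabelMap,
    report: HistopathReport,
    params: RadiosensitivityParams,
    method: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel radiosensitivity assignment for one adjustment method.

    Returns ``(alpha_sample, alpha_values, alpha_weights, ab_per_voxel)``
    over mask voxels in ``np.flatnonzero(mask)`` order.

    * Methods 1 and 2: sampled alpha everywhere, ``ab_single``.
    * Method 3: fixed alpha mixture per voxel — (alpha_GP(primary), 0.75)
      and (alpha_GP(secondary), 0.25); benign segments get
      (alpha_GP2, 1.0); ``ab_single`` everywhere.
    * Method 4: sampled alpha; alpha/beta = ``gs_ab[segment GS]``, benign
      segments get ``gs_ab['2+2']``.
    """
    if method not in (1, 2, 3, 4):
        raise ValueError("method must be 1, 2, 3 or 4")
    if method == 3 and params.gp_alpha is None:
        raise ValueError("method 3 requires Gleason-Pattern-dependent alpha")
    if method == 4 and params.gs_ab is None:
        raise ValueError("method 4 requires Gleason-Score-dependent alpha/beta")
    _check_report_covers(labelmap, report)

    mask = labelmap.mask
    n_m = int(mask.sum())
    flat_codes = labelmap.labels[mask]  # per mask voxel, C order

    if method in (1, 2):
        return (
            np.ones(n_m, dtype=bool),
            np.full((n_m, 1), np.nan),
            np.zeros((n_m, 1)),
            np.full(n_m, params.ab_single),
        )

    if method == 3:
        seg_vals = np.zeros((len(labelmap.names), 2))
        seg_wts = np.zeros((len(labelmap.names), 2))
        for code, name in enumerate(labelmap.names):
            f = report.finding(name)
            if f.is_benign:
                seg_vals[code] = (params.gp_alpha[2], np.nan)
                seg_wts[code] = (1.0, 0.0)
            elif f.gleason_primary == f.gleason_secondary:
                seg_vals[code] = (params.gp_alpha[f.gleason_primary], np.nan)
                seg_wts[code] = (1.0, 0.0)
            else:
                seg_vals[code] = (
                    params.gp_alpha[f.gleason_primary],
                    params.gp_alpha[f.gleason_secondary],
                )
                seg_wts[code] = (0.75, 0.25)
        return (
            np.zeros(n_m, dtype=bool),
            seg_vals[flat_codes],
            seg_wts[flat_codes],
            np.full(n_m, params.ab_single),
        )

    # method 4
    seg_ab = np.zeros(len(labelmap.names))
    for code, name in enumerate(labelmap.names):
        f = report.finding(name)
        gs = f.gleason_score or GS_LABELS[0]
        if gs not in params.gs_ab:
            raise ValueError(f"no alpha/beta ratio for Gleason score {gs!r}")
        seg_ab[code] = params.gs_ab[gs]
    return (
        np.ones(n_m, dtype=bool),
        np.full((n_m, 1), np.nan),
        np.zeros((n_m, 1)),
        seg_ab[flat_codes],
    )


def build_patient_model(
    cd_atlas: np.ndarray,
    tp_atlas: Optional[np.ndarray],
    dose: Union[np.ndarray, None],
    schedule: TreatmentSchedule,
    labelmap: SegmentLabelMap,
    report: HistopathReport,
    params: RadiosensitivityParams,
    method: int,
    grid: Optional[VoxelGrid] = None,
    use_tp_atlas: bool = False,
) -> ProstateModel:
    """Assemble the complete voxel model for one patient and method.

    ``dose`` is a full-grid dose-per-fraction array; if None, a uniform
    distribution is assumed from the schedule's prescription
    (``d_i = prescription / n_fractions`` on every mask voxel).  Method 1
    uses raw atlas clonogens; methods 2-4 apply the % adenocarcinoma
    adjustment.  The tumor-probability atlas participates multiplicatively
    only when ``use_tp_atlas`` is set.
    """
    mask = labelmap.mask
    if grid is None:
        grid = VoxelGrid(mask.shape, (1.0, 1.0, 1.0))
    cd_atlas = np.asarray(cd_atlas, dtype=float)
    if cd_atlas.shape != mask.shape:
        raise ValueError("cell-density atlas grid mismatch")

    tp = tp_atlas if use_tp_atlas else None
    if method == 1:
        clonogens = np.where(mask, cd_atlas, 0.0)
        if tp is not None:
            clonogens = clonogens * np.where(mask, np.asarray(tp, float), 0.0)
        _check_report_covers(labelmap, report)
    else:
        clonogens = adjust_clonogens(cd_atlas, labelmap, report, tp)

    if dose is None:
        d = np.zeros(mask.shape)
        d[mask] = schedule.dose_per_fraction
    else:
        d = np.asarray(dose, dtype=float)
        if d.shape != mask.shape:
            raise ValueError("dose grid mismatch")

    alpha_sample, alpha_values, alpha_weights, ab = assign_method_params(
        labelmap, report, params, method
    )
    model = ProstateModel(
        grid=grid,
        mask=mask,
        clonogens=clonogens,
        dose_per_fraction=d,
        alpha_sample=alpha_sample,
        alpha_values=alpha_values,
        alpha_weights=alpha_weights,
        ab_per_voxel=ab,
    )
    model.validate()
    return model
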