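"""Spot histology classification from pathologist annotation masks.

Each capture spot is a 55 um disk on the tissue.  The pathologist exports one
binary raster per annotation class (stroma, lumen, tissue fold, lymphocytes,
non-cancer gland, cancer Grade Group 1-5, uncertain); the fraction of each
class under a spot is the fraction of raster pixel centers inside the spot
disk that are set in that class raster.  Pixels covered by no class form an
implicit "outside tissue" class.

The rule engine then follows the published protocol literally, with strict
inequalities throughout:

* exclusion: outside > 50%, tissue fold > 50%, lumen > 80% or uncertain > 50%;
* assignment: stroma if stroma > 55%, else the dominating class among
  lymphocytes, non-cancer gland and cancer GG1-5 (GG1-2 -> low-grade cancer,
  GG3-5 -> high-grade cancer);
* stroma spots are subclassified per sample as normal / LG-cancer / HG-cancer
  stroma according to the worst cancer grade present anywhere in the sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import (
    CANCER_CLASSES,
    EPITHELIUM_CLASS,
    HG_CLASSES,
    LG_CLASSES,
    PipelineConfig,
)
from .io import MaskRaster, SpotGeometry

EXCLUDED = "excluded"
STROMA = "stroma"
STROMA_CALLS = ("stroma normal", "stroma LG cancer", "stroma HG cancer")

#: argmax candidates for the dominating-class rule, and the tie-break order
#: (cancer beats lymphocytes beats non-cancer epithelium; within cancer the
#: higher grade wins).  The rule is deterministic and the fired rule is logged.
_CANDIDATE_PRIORITY = list(CANCER_CLASSES[::-1]) + ["lymphocytes", EPITHELIUM_CLASS]


@dataclass
class SpotFractions:
    spot_id: str
    fractions: dict[str, float]

    def get(self, cls: str) -> float:
        return self.fractions.get(cls, 0.0)


@dataclass
class HistologyCall:
    spot_id: str
    call: str
    reason: str
    sample_id: str = ""


@dataclass
class SampleGradeSummary:
    sample_id: str
    contains_LG: bool
    contains_HG: bool


class AnnotationError(ValueError):
    pass


def spot_class_fractions(
    spot: SpotGeometry, masks: Mapping[str, MaskRaster]
) -> SpotFractions:
    """Per-class area fractions of one spot via pixel-center-in-disk counting.

    No partial-pixel weighting is applied: a pixel belongs to the spot iff its
    center lies within the disk, matching the binary-mask export convention.
    """
    if not masks:
        raise AnnotationError("no masks supplied")
    first = next(iter(masks.values()))
    ps = first.pixel_size
    shape = first.shape
    for name, m in masks.items():
        if m.shape != shape or m.pixel_size != ps:
            raise AnnotationError(f"mask {name!r} disagrees in shape or pixel size")

    r = spot.diameter / 2.0
    # bounding box of the disk in pixel indices (pixel centers at (i+0.5)*ps)
    i0 = max(int(np.floor((spot.center_y - r) / ps - 0.5)), 0)
    i1 = min(int(np.ceil((spot.center_y + r) / ps - 0.5)) + 1, shape[0])
    j0 = max(int(np.floor((spot.center_x - r) / ps - 0.5)), 0)
    j1 = min(int(np.ceil((spot.center_x + r) / ps - 0.5)) + 1, shape[1])
    if i1 <= i0 or j1 <= j0:
        raise AnnotationError(
            f"spot {spot.spot_id} covers no pixel centers (resolution too coarse)"
        )
    yy = (np.arange(i0, i1) + 0.5) * ps - spot.center_y
    xx = (np.arange(j0, j1) + 0.5) * ps - spot.center_x
    inside = (yy[:, None] ** 2 + xx[None, :] ** 2) <= r**2
    n_in = int(inside.sum())
    if n_in == 0:
        raise AnnotationError(
            f"spot {spot.spot_id} covers no pixel centers (resolution too coarse)"
        )

    fractions: dict[str, float] = {}
    covered = np.zeros_like(inside)
    for name, m in masks.items():
        sub = m.mask[i0:i1, j0:j1]
        hit = sub & inside
        fractions[name] = float(hit.sum()) / n_in
        covered |= hit
    fractions["outside"] = float((inside & ~covered).sum()) / n_in
    return SpotFractions(spot_id=spot.spot_id, fractions=fractions)


def apply_exclusion_rules(
    f: SpotFractions, cfg: PipelineConfig, report_all: bool = False
) -> tuple[bool, str]:
    """Return (excluded, reason).  Rules use strict '>' on raw fractions.

    The first matching rule (in the fixed order outside, fold, lumen,
    uncertain) is reported; with ``report_all`` every firing rule is listed.
    """
    fired = [
        cls
        for cls in ("outside", "fold", "lumen", "uncertain")
        if f.get(cls) > cfg.exclusion_thresholds[cls]
    ]
    if not fired:
        return False, ""
    return True, ",".join(fired) if report_all else fired[0]


def assign_histology(f: SpotFractions, cfg: PipelineConfig) -> HistologyCall:
    """Provisional histology call for one retained spot."""
    if f.get(STROMA) > cfg.stroma_threshold:
        return HistologyCall(f.spot_id, STROMA, f"stroma>{cfg.stroma_threshold}")
    best, best_frac = None, 0.0
    for cls in _CANDIDATE_PRIORITY:
        frac = f.get(cls)
        if frac > best_frac:  # strict: earlier (higher-priority) class wins ties
            best, best_frac = cls, frac
    if best is None:
        raise AnnotationError(f"spot {f.spot_id} unclassifiable: all fractions zero")
    if best in LG_CLASSES:
        call = "LG cancer"
    elif best in HG_CLASSES:
        call = "HG cancer"
    elif best == "lymphocytes":
        call = "lymphocytes"
    else:
        call = EPITHELIUM_CLASS
    return HistologyCall(f.spot_id, call, f"dominant={best}")


def sample_grade_summary(
    calls: Iterable[HistologyCall], sample_id: str = ""
) -> SampleGradeSummary:
    """Grade content of a sample, from its non-stroma spot calls only."""
    calls = list(calls)
    return SampleGradeSummary(
        sample_id=sample_id,
        contains_LG=any(c.call == "LG cancer" for c in calls),
        contains_HG=any(c.call == "HG cancer" for c in calls),
    )


def subclassify_stroma(
    calls: Sequence[HistologyCall],
    override: SampleGradeSummary | None = None,
    sample_id: str = "",
) -> list[HistologyCall]:
    """Final calls for one sample: stroma spots inherit the sample's grade.

    ``override`` lets a pathologist-supplied sample-level grade replace the
    grade derived from the spot calls.
    """
    summary = override if override is not None else sample_grade_summary(calls, sample_id)
    if summary.contains_HG:
        stroma_call = "stroma HG cancer"
    elif summary.contains_LG:
        stroma_call = "stroma LG cancer"
    else:
        stroma_call = "stroma normal"
    out = []
    for c in calls:
        if c.call == STROMA:
            out.append(HistologyCall(c.spot_id, stroma_call, c.reason, c.sample_id))
        else:
            out.append(c)
    return out


def classify_spots(
    spots: Sequence[SpotGeometry],
    masks: Mapping[str, MaskRaster],
    cfg: PipelineConfig,
    sample_id: str = "sample",
    override: SampleGradeSummary | None = None,
) -> pd.DataFrame:
    """Full per-sample chain: fractions -> exclusion -> assignment -> stroma subclass.

    Returns one row per spot with every class fraction, the final call and the
    rule that fired.
    """
    fracs = [spot_class_fractions(s, masks) for s in spots]
    provisional: list[HistologyCall] = []
    for f in fracs:
        excluded, reason = apply_exclusion_rules(f, cfg)
        if excluded:
            provisional.append(HistologyCall(f.spot_id, EXCLUDED, reason, sample_id))
        else:
            call = assign_histology(f, cfg)
            call.sample_id = sample_id
            provisional.append(call)
    final = subclassify_stroma(
        [c for c in provisional], override=override, sample_id=sample_id
    )
    classes = sorted({k for f in fracs for k in f.fractions})
    rows = []
    for f, c in zip(fracs, final):
        row = {"spot_id": f.spot_id, "sample_id": sample_id, "call": c.call,
               "reason": c.reason}
        row.update({f"frac_{cls}": f.get(cls) for cls in classes})
        rows.append(row)
    return pd.DataFrame(rows)
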