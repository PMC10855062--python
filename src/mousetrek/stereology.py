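"""Stereological estimation of newborn-neuron totals from sampled sections.

Adult-born neurons (BrdU/NeuN double-positive cells) are counted on every
sixth serial coronal section through the dentate gyrus.  Sections anterior to
bregma -2.80 mm belong to the dorsal (septal) segment and the remainder to
the ventral (temporal) segment.  The per-segment total is the scaled mean

    estimate = (sum of counted cells / number of counted sections)
               x (total sections in the segment)

with typical section totals of about 45 dorsal and 30 ventral, and the
whole-hippocampus estimate is the sum of the two segment estimates.
Estimates are real numbers, never rounded, since the estimator is a scaled
mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Anterior-posterior boundary between dorsal and ventral dentate gyrus (mm
#: from bregma).
DORSAL_VENTRAL_BOUNDARY_MM = -2.80

DEFAULT_TOTAL_SECTIONS = {"dorsal": 45, "ventral": 30}
SEGMENTS = ("dorsal", "ventral")


def assign_segment(
    bregma_mm: float, boundary_mm: float = DORSAL_VENTRAL_BOUNDARY_MM
) -> str:
    """Dorsal iff the section lies anterior to (strictly above) the boundary.

    A section at exactly the boundary coordinate is assigned ventral.
    """
    if not np.isfinite(bregma_mm):
        raise ValueError("bregma coordinate must be finite")
    return "dorsal" if bregma_mm > boundary_mm else "ventral"


@dataclass
class StereologyCounts:
    """Per-section double-positive cell counts for one animal.

    ``sections`` is a DataFrame with columns ``bregma_mm`` and ``counted``
    (an optional ``segment`` column is recomputed from the bregma rule).
    """

    sections: pd.DataFrame
    sampling_interval: int = 6
    total_sections: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TOTAL_SECTIONS)
    )
    boundary_mm: float = DORSAL_VENTRAL_BOUNDARY_MM

    def __post_init__(self) -> None:
        df = self.sections.copy()
        if "bregma_mm" not in df.columns or "counted" not in df.columns:
            raise ValueError("sections needs 'bregma_mm' and 'counted' columns")
        if (df["counted"] < 0).any():
            raise ValueError("counted cells must be non-negative")
        if self.sampling_interval < 1:
            raise ValueError("sampling_interval must be >= 1")
        df["segment"] = [
            assign_segment(b, self.boundary_mm) for b in df["bregma_mm"]
        ]
        self.sections = df


@dataclass
class StereologyEstimate:
    dorsal: float | None
    ventral: float | None
    whole: float | None

    def to_dict(self) -> dict:
        return {"dorsal": self.dorsal, "ventral": self.ventral, "whole": self.whole}


def estimate_segment_total(
    counted: np.ndarray, total_sections: int
) -> float:
    """Scaled-mean estimator for one segment: mean count x total sections."""
    counted = np.asarray(counted, dtype=float)
    if counted.size == 0:
        raise ValueError("no counted sections in segment")
    return float(counted.mean() * total_sections)


def estimate_total(counts: StereologyCounts) -> StereologyEstimate:
    """Per-segment and whole-hippocampus newborn-neuron estimates.

    A segment with no counted section yields a missing (None) estimate with a
    warning; the whole-hippocampus value is only defined when both segments
    are.
    """
    import warnings

    per: dict[str, float | None] = {}
    for seg in SEGMENTS:
        sub = counts.sections.loc[counts.sections["segment"] == seg, "counted"]
        if len(sub) == 0:
            warnings.warn(f"no counted sections in {seg} segment; estimate missing")
            per[seg] = None
        else:
            per[seg] = estimate_segment_total(
                sub.to_numpy(), counts.total_sections[seg]
            )
    whole = (
        per["dorsal"] + per["ventral"]
        if per["dorsal"] is not None and per["ventral"] is not None
        else None
    )
    return StereologyEstimate(dorsal=per["dorsal"], ventral=per["ventral"], whole=whole)


def read_counts_csv(path) -> dict[str, StereologyCounts]:
    """Read a (animal_id, bregma_mm, counted) CSV into per-animal counts."""
    df = pd.read_csv(path)
    required = {"animal_id", "bregma_mm", "counted"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts CSV needs columns {sorted(required)}")
    return {
        str(animal): StereologyCounts(sections=sub[["bregma_mm", "counted"]])
        for animal, sub in df.groupby("animal_id")
    }
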