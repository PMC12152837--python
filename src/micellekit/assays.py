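"""TEER (transepithelial electrical resistance) assay arithmetic.

TEER = (R_total − R_blank) × membrane area, in Ω·cm²; time courses are
reported as percent of a matched control series.  A quality cutoff
(default 120 Ω·cm², the accepted threshold for a confluent Caco-2
monolayer) flags readings from membranes that never sealed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["TeerReading", "teer", "teer_percent_of_control", "flag_below_cutoff",
           "DEFAULT_MEMBRANE_AREA_CM2", "DEFAULT_TEER_CUTOFF"]

DEFAULT_MEMBRANE_AREA_CM2 = 1.12
DEFAULT_TEER_CUTOFF = 120.0  # Ω·cm²


@dataclass
class TeerReading:
    """One resistance reading: total and blank resistances (Ω), membrane area
    (cm²), timepoint (h) and condition label."""

    r_total: float
    r_blank: float
    membrane_area: float = DEFAULT_MEMBRANE_AREA_CM2
    timepoint: float = 0.0
    condition: str = ""
    flagged_negative: bool = False

    def __post_init__(self) -> None:
        if self.membrane_area <= 0:
            raise ValueError("membrane_area must be > 0")
        if self.r_total < self.r_blank:
            # physically odd but retained; flag rather than reject
            self.flagged_negative = True


def teer(reading: TeerReading) -> float:
    """TEER in Ω·cm²: (R_total − R_blank) × membrane area."""
    return (reading.r_total - reading.r_blank) * reading.membrane_area


def flag_below_cutoff(teer_value: float, cutoff: float = DEFAULT_TEER_CUTOFF) -> bool:
    """True when a reading falls below the monolayer-quality cutoff."""
    return teer_value < cutoff


def teer_percent_of_control(series: Sequence[TeerReading],
                            control_series: Sequence[TeerReading]) -> pd.DataFrame:
    """Percent-of-control TEER per timepoint.

    Both series must cover matching timepoints; a missing control
    timepoint is an alignment error.
    """
    def to_frame(readings):
        return pd.DataFrame({
            "timepoint": [r.timepoint for r in readings],
            "teer": [teer(r) for r in readings],
        }).groupby("timepoint", as_index=True)["teer"].mean()

    s = to_frame(series)
    c = to_frame(control_series)
    missing = sorted(set(s.index) - set(c.index))
    if missing:
        raise ValueError(f"control series lacks timepoints: {missing}")
    pct = 100.0 * s / c.loc[s.index]
    return pd.DataFrame({"timepoint": s.index, "teer": s.values,
                         "teer_control": c.loc[s.index].values,
                         "percent_of_control": pct.values}).reset_index(drop=True)
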