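"""AUC over 24-h terms anchored to the initial haemodialysis session.

The exposure metric is the AUC of the simulated profile over consecutive
24-h windows counted from the end of the first HD session: term 1 covers
0-24 h after the anchor, term 2 (the working PK/PD metric) 24-48 h, term 3
48-72 h when the inter-dialysis interval is 72 h.  Each term AUC is the
arithmetic mean of the simulated concentrations at grid points inside the
window (inclusive start, exclusive end) multiplied by the 24-h width, and
is divided by the organism's MIC for the pharmacodynamic ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field

from .pk import ConcentrationProfile

TERM_HOURS = 24.0
DEFAULT_AUC_MIC_TARGET = 400.0


class MicValue(BaseModel):
    mic: float = Field(gt=0, description="ug/mL, broth microdilution")


@dataclass(frozen=True)
class TermAUC:
    term_index: int
    window_start: float
    window_end: float
    auc: float
    auc_over_mic: float | None = None

    def over_mic(self, mic: float | MicValue) -> "TermAUC":
        m = mic.mic if isinstance(mic, MicValue) else float(mic)
        if m <= 0:
            raise ValueError("MIC must be > 0")
        return TermAUC(self.term_index, self.window_start, self.window_end,
                       self.auc, self.auc / m)


def term_auc(profile: ConcentrationProfile, anchor: float, term_index: int) -> TermAUC:
    """AUC over [anchor + 24*(k-1), anchor + 24*k) by the mean-concentration rule.

    Windows are inclusive-start/exclusive-end on the fixed grid so adjacent
    terms never double-count a grid point.  Incomplete window coverage is an
    error, never a silent partial window.
    """
    if term_index < 1:
        raise ValueError("term_index must be >= 1")
    w0 = anchor + TERM_HOURS * (term_index - 1)
    w1 = w0 + TERM_HOURS
    if not profile.covers(w0, w1):
        raise ValueError(
            f"profile [{profile.grid[0]:g}, {profile.grid[-1]:g}] h does not cover "
            f"term {term_index} window [{w0:g}, {w1:g}] h"
        )
    mask = (profile.grid >= w0 - 1e-9) & (profile.grid < w1 - 1e-9)
    if not mask.any():
        raise ValueError("no grid points inside the term window")
    auc = float(np.mean(profile.conc[mask]) * TERM_HOURS)
    return TermAUC(term_index=term_index, window_start=w0, window_end=w1, auc=auc)


def auc_mic_flag(term: TermAUC, mic: float | MicValue,
                 threshold: float = DEFAULT_AUC_MIC_TARGET) -> bool:
    """True iff AUC/MIC >= threshold (inclusive boundary)."""
    m = mic.mic if isinstance(mic, MicValue) else float(mic)
    if m <= 0:
        raise ValueError("MIC must be > 0")
    return term.auc / m >= threshold
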