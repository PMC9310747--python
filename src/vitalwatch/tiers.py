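"""Duration x severity abnormality tiers.

Each tier pairs a severity threshold with a minimum persistence, so that a
brief dip below a mild threshold is not an episode while the same dip below
a severe threshold is.  The default registry holds the sixteen tiers used
for postoperative ward monitoring, derived from Early Warning Score alert
thresholds:

======== =========== ================
channel  threshold   persistence
======== =========== ================
SpO2     < 92 %      >= 60 min
SpO2     < 88 %      >= 10 min
SpO2     < 85 %      >= 5 min
SpO2     < 80 %      >= 1 min
RR       < 5 /min    >= 1 min
RR       < 11 /min   >= 5 min
RR       > 24 /min   >= 5 min
RR       > 30 /min   >= 1 min
HR       < 30 /min   >= 5 min
HR       < 40 /min   >= 5 min
HR       > 110 /min  >= 60 min
HR       > 130 /min  >= 30 min
SBP      < 70 mmHg   >= 2 consecutive
SBP      < 90 mmHg   >= 2 consecutive
SBP      > 180 mmHg  >= 2 consecutive
SBP      > 220 mmHg  >= 2 consecutive
======== =========== ================

Inequalities are strict in both directions.  SBP is measured
intermittently, so its tiers count consecutive measurements rather than
minutes.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, model_validator

from .config import ChannelName

Direction = Literal["below", "above"]


class ThresholdTier(BaseModel):
    """One duration x severity abnormality rule.

    Continuous channels (HR, RR, SPO2) use ``min_persistence`` minutes of
    condition-true time; SBP uses ``min_consecutive`` measurements in a row.
    """

    channel: ChannelName
    direction: Direction
    threshold: float
    min_persistence: Optional[int] = None  # minutes, continuous channels
    min_consecutive: Optional[int] = None  # count, SBP

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "ThresholdTier":
        if self.channel == "SBP":
            if self.min_consecutive is None or self.min_consecutive < 1:
                raise ValueError("SBP tiers require min_consecutive >= 1")
        else:
            if self.min_persistence is None or self.min_persistence < 1:
                raise ValueError("continuous-channel tiers require min_persistence >= 1")
        return self

    @property
    def is_bp(self) -> bool:
        return self.channel == "SBP"

    @property
    def label(self) -> str:
        """Human-readable tier name, e.g. ``SPO2<92>=60min``."""
        op = "<" if self.direction == "below" else ">"
        val = f"{self.threshold:g}"
        if self.is_bp:
            return f"SBP{op}{val}>={self.min_consecutive}x"
        return f"{self.channel}{op}{val}>={self.min_persistence}min"

    def condition(self, values):
        """Element-wise condition-true mask (NaN compares False)."""
        if self.direction == "below":
            return values < self.threshold
        return values > self.threshold


def _t(channel, direction, threshold, **kw) -> ThresholdTier:
    return ThresholdTier(channel=channel, direction=direction, threshold=threshold, **kw)


DEFAULT_TIERS: tuple[ThresholdTier, ...] = (
    _t("SPO2", "below", 92, min_persistence=60),
    _t("SPO2", "below", 88, min_persistence=10),
    _t("SPO2", "below", 85, min_persistence=5),
    _t("SPO2", "below", 80, min_persistence=1),
    _t("RR", "below", 5, min_persistence=1),
    _t("RR", "below", 11, min_persistence=5),
    _t("RR", "above", 24, min_persistence=5),
    _t("RR", "above", 30, min_persistence=1),
    _t("HR", "below", 30, min_persistence=5),
    _t("HR", "below", 40, min_persistence=5),
    _t("HR", "above", 110, min_persistence=60),
    _t("HR", "above", 130, min_persistence=30),
    _t("SBP", "below", 70, min_consecutive=2),
    _t("SBP", "below", 90, min_consecutive=2),
    _t("SBP", "above", 180, min_consecutive=2),
    _t("SBP", "above", 220, min_consecutive=2),
)


def tiers_to_yaml(tiers=DEFAULT_TIERS) -> str:
    return yaml.safe_dump(
        [t.model_dump(exclude_none=True) for t in tiers], sort_keys=False
    )


def tiers_from_yaml(text: str) -> tuple[ThresholdTier, ...]:
    return tuple(ThresholdTier.model_validate(d) for d in yaml.safe_load(text))


def load_tiers(path) -> tuple[ThresholdTier, ...]:
    with open(path) as fh:
        return tiers_from_yaml(fh.read())
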