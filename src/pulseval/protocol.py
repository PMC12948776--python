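"""Exercise protocol definition and stage-to-intensity labelling.

The reference session is 5 min seated rest, four 10-min cycling stages at
increasing fractions of age-predicted maximal heart rate, and 10 min of
seated recovery (55 min total).  Matched 30-s epochs are labelled with the
protocol stage covering the epoch start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: canonical intensity labels in protocol order
INTENSITY_LEVELS = ("rest", "very_light", "light", "moderate", "vigorous", "recovery")

#: exercise-stage labels used when the protocol has the canonical four stages
_STAGE_LABELS_4 = ("very_light", "light", "moderate", "vigorous")


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing and target intensities of one laboratory session.

    ``stage_fractions`` are the target heart rates of the exercise stages
    as fractions of age-predicted HRmax; ``ramp_s`` is the time allowed to
    reach each stage target.
    """

    rest_s: float = 300.0
    stage_s: float = 600.0
    stage_fractions: tuple[float, ...] = (0.50, 0.60, 0.70, 0.80)
    recovery_s: float = 600.0
    ramp_s: float = 120.0

    def __post_init__(self):
        if min(self.rest_s, self.stage_s, self.recovery_s, self.ramp_s) <= 0:
            raise ValueError("protocol durations must be positive")
        fr = self.stage_fractions
        if not fr or any(f <= 0 or f >= 1 for f in fr):
            raise ValueError("stage fractions must lie in (0, 1)")
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise ValueError("stage fractions must be strictly increasing")
        if self.ramp_s > self.stage_s:
            raise ValueError("ramp longer than the stage itself")

    @property
    def n_stages(self) -> int:
        return len(self.stage_fractions)

    @property
    def total_s(self) -> float:
        return self.rest_s + self.n_stages * self.stage_s + self.recovery_s

    def expected_epochs(self, epoch_s: float = 30.0) -> int:
        """Number of epochs a complete session should produce."""
        return math.ceil(self.total_s / epoch_s)

    def stage_labels(self) -> tuple[str, ...]:
        if self.n_stages == len(_STAGE_LABELS_4):
            return _STAGE_LABELS_4
        return tuple(f"stage_{i + 1}" for i in range(self.n_stages))

    def schedule(self) -> list[tuple[str, float, float]]:
        """Half-open [start, end) intervals in session seconds, per stage."""
        out = [("rest", 0.0, self.rest_s)]
        t = self.rest_s
        for label in self.stage_labels():
            out.append((label, t, t + self.stage_s))
            t += self.stage_s
        out.append(("recovery", t, t + self.recovery_s))
        return out

    def intensity_at(self, t_s: float) -> str:
        """Stage label covering session time ``t_s`` (seconds from start).

        Times at or beyond the protocol end are clamped to recovery; negative
        times are invalid.
        """
        if t_s < 0:
            raise ValueError("time before session start")
        for label, start, end in self.schedule():
            if start <= t_s < end:
                return label
        return "recovery"
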