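"""The bivariate facultative sex-ratio trait."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SexRatioStrategy"]


@dataclass(frozen=True)
class SexRatioStrategy:
    """Condition-dependent primary sex ratio ``s = (s1, s2)``.

    ``s_j`` is the proportion of male births produced by condition-``j``
    mothers.  Both components live in [0, 1]; the corners (0, 0) and (1, 1)
    produce a single-sex population and are not viable resident strategies
    (``viable`` is False there), though the rate builders still accept them
    for degenerate-limit analyses.
    """

    s1: float
    s2: float

    def __post_init__(self) -> None:
        for name, val in (("s1", self.s1), ("s2", self.s2)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} = {val} outside [0, 1]")

    @property
    def viable(self) -> bool:
        return not ((self.s1 == 0.0 and self.s2 == 0.0) or (self.s1 == 1.0 and self.s2 == 1.0))

    def as_array(self) -> np.ndarray:
        return np.array([self.s1, self.s2], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "SexRatioStrategy":
        a = np.asarray(arr, dtype=float)
        return cls(float(np.clip(a[0], 0.0, 1.0)), float(np.clip(a[1], 0.0, 1.0)))

    def __iter__(self):
        yield self.s1
        yield self.s2
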