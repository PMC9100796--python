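"""The closed 24-h time-use composition.

A day is exhaustively partitioned into four movement behaviours — sleep,
sedentary behaviour (SB), light physical activity (LPA) and
moderate-to-vigorous physical activity (MVPA) — whose durations are
co-dependent and sum to 24 h (1440 min).  Every stage of the pipeline
(questionnaire scoring, device processing, simulation) produces values of
this type, so closure can be asserted uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

MINUTES_PER_DAY = 1440.0
CLOSURE_TOL = 1e-6

BEHAVIOURS = ("sleep", "sb", "lpa", "mvpa")


@dataclass(frozen=True)
class TimeUseComposition:
    """Minutes/day of sleep, SB, LPA and MVPA, closed to 1440 when valid.

    ``valid=False`` marks records that violate closure or positivity
    (e.g. over-reported behaviours forcing negative LPA); such records are
    carried through with diagnostics rather than silently truncated.
    """

    sleep: float
    sb: float
    lpa: float
    mvpa: float
    valid: bool = True
    flags: tuple[str, ...] = field(default=())

    @property
    def total(self) -> float:
        return self.sleep + self.sb + self.lpa + self.mvpa

    def is_closed(self, tol: float = CLOSURE_TOL) -> bool:
        return abs(self.total - MINUTES_PER_DAY) <= tol

    def as_dict(self) -> dict[str, float]:
        return {b: getattr(self, b) for b in BEHAVIOURS}

    def with_flag(self, flag: str, *, valid: bool | None = None) -> "TimeUseComposition":
        return replace(
            self,
            flags=self.flags + (flag,),
            valid=self.valid if valid is None else valid,
        )

    def __post_init__(self) -> None:
        if self.valid:
            if not self.is_closed():
                raise ValueError(
                    f"valid composition must close to {MINUTES_PER_DAY} min: "
                    f"got total {self.total:.6f}"
                )
            if min(self.sleep, self.sb, self.lpa, self.mvpa) < 0:
                raise ValueError("valid composition must have non-negative parts")


def close_composition(
    sleep: float, sb: float, mvpa: float, *, flags: tuple[str, ...] = ()
) -> TimeUseComposition:
    """Close a composition by assigning the 24-h remainder to LPA.

    If the remainder is negative (over-reporting) the record is returned
    with ``valid=False`` and an explanatory flag instead of being truncated.
    """
    lpa = MINUTES_PER_DAY - sleep - sb - mvpa
    if lpa < 0 or min(sleep, sb, mvpa) < 0:
        return TimeUseComposition(
            sleep, sb, lpa, mvpa, valid=False, flags=flags + ("negative_lpa",)
        )
    return TimeUseComposition(sleep, sb, lpa, mvpa, valid=True, flags=flags)
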