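"""Block-design timeline for the fixation / vergence eye-movement experiment.

The experiment alternates 20 s of sustained fixation ("off") with 20 s of
vergence eye movements ("on"), repeated for 3.5 cycles, giving a 140 s run
(70 volumes at TR = 2 s).  During each eye-movement phase one of three LED
targets (near/middle/far, vergence demands 4/3/2 deg) is illuminated for a
random duration of 3-5 s, so the subject cannot anticipate target or timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FIXATION = "fixation"
MOVEMENT = "movement"

#: Full vergence-angle demand of each LED target (deg).
TARGET_DEMANDS_DEG = {"near": 4.0, "middle": 3.0, "far": 2.0}


@dataclass(frozen=True)
class IlluminationEvent:
    """A single LED illumination within an eye-movement phase."""

    target: str
    demand_deg: float
    onset_s: float
    duration_s: float


@dataclass(frozen=True)
class Phase:
    label: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class DesignTimeline:
    """Alternating fixation/movement schedule plus its illumination events.

    Phases always alternate starting with fixation.  ``boxcar`` samples the
    on/off state at volume midpoints; ``phase_labels`` does the same after
    volume trimming and an optional hemodynamic-delay shift.
    """

    phases: list[Phase]
    illuminations: list[IlluminationEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("timeline needs at least one phase")
        expected = FIXATION
        for ph in self.phases:
            if ph.label != expected:
                raise ValueError(
                    "phases must alternate starting with fixation; got "
                    f"{[p.label for p in self.phases]}"
                )
            expected = MOVEMENT if expected == FIXATION else FIXATION

    @property
    def total_duration_s(self) -> float:
        return self.phases[-1].end_s

    def label_at(self, t: float) -> str:
        """Phase label at time ``t``; times before the run count as fixation."""
        if t < 0:
            return FIXATION
        for ph in self.phases:
            if ph.start_s <= t < ph.end_s:
                return ph.label
        return self.phases[-1].label

    def n_volumes(self, tr: float) -> int:
        n = self.total_duration_s / tr
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"run duration {self.total_duration_s} s is not a whole number "
                f"of volumes at TR {tr} s"
            )
        return int(round(n))

    def boxcar(self, tr: float, n_volumes: int | None = None) -> np.ndarray:
        """0/1 per volume (fixation 0, movement 1), sampled at volume midpoints."""
        if n_volumes is None:
            n_volumes = self.n_volumes(tr)
        mids = (np.arange(n_volumes) + 0.5) * tr
        return np.array([1.0 if self.label_at(t) == MOVEMENT else 0.0 for t in mids])

    def phase_labels(
        self, tr: float, n_volumes: int, n_drop: int = 0, shift_s: float = 0.0
    ) -> np.ndarray:
        """Boolean movement labels for volumes ``n_drop..n_volumes-1``.

        ``shift_s`` delays the timeline before labelling, so that volumes are
        assigned to the phase whose hemodynamic response they carry.
        """
        mids = (np.arange(n_drop, n_volumes) + 0.5) * tr
        return np.array([self.label_at(t - shift_s) == MOVEMENT for t in mids])


def generate_block_timeline(
    phase_s: float,
    n_cycles: float,
    illum_min: float,
    illum_max: float,
    seed: int,
) -> DesignTimeline:
    """Build the alternating block design with randomized target illuminations.

    Parameters
    ----------
    phase_s:
        Duration of each fixation or movement phase (s); 20 s in the study
        protocol.
    n_cycles:
        Number of fixation+movement cycles; 3.5 gives the 140 s run.
    illum_min, illum_max:
        Bounds of the uniform illumination duration (s); 3 and 5 in the
        protocol.  The last illumination of a phase is truncated at phase end.
    seed:
        Seeds the illumination sequence; identical seeds reproduce it exactly.
    """
    if phase_s <= 0:
        raise ValueError("phase_s must be positive")
    if n_cycles <= 0:
        raise ValueError("n_cycles must be positive")
    if not (0 < illum_min <= illum_max):
        raise ValueError("need 0 < illum_min <= illum_max")

    rng = np.random.default_rng(seed)
    total = phase_s * 2.0 * n_cycles
    phases: list[Phase] = []
    t = 0.0
    label = FIXATION
    while t < total - 1e-9:
        end = min(t + phase_s, total)
        phases.append(Phase(label, t, end))
        t = end
        label = MOVEMENT if label == FIXATION else FIXATION

    targets = list(TARGET_DEMANDS_DEG)
    events: list[IlluminationEvent] = []
    prev = None
    for ph in phases:
        if ph.label != MOVEMENT:
            continue
        t = ph.start_s
        while t < ph.end_s - 1e-9:
            # a new target must light up to evoke a movement: no immediate repeats
            choices = [tg for tg in targets if tg != prev]
            target = choices[rng.integers(len(choices))]
            dur = float(rng.uniform(illum_min, illum_max))
            dur = min(dur, ph.end_s - t)
            events.append(
                IlluminationEvent(target, TARGET_DEMANDS_DEG[target], t, dur)
            )
            prev = target
            t += dur

    return DesignTimeline(phases=phases, illuminations=events)
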