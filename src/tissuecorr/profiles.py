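"""Step-function transcription profiles and weighted candidate sets.

A single cell's transcriptional history is represented as a right-continuous
step function: the transcription rate holds a constant level between switch
times.  Bayesian switch inference (run upstream of this package) does not
return one profile per cell but a set of candidate profiles, each with a
posterior probability of occurrence; :class:`SwitchProfileSet` holds that
weighted set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidConfigError

__all__ = ["StepProfile", "SwitchProfileSet", "read_profiles_json", "write_profiles_json"]


@dataclass(frozen=True)
class StepProfile:
    """A step function: ``levels[k]`` holds on ``[switch_times[k-1], switch_times[k])``.

    ``len(levels) == len(switch_times) + 1``; switch times strictly increasing.
    """

    switch_times: np.ndarray
    levels: np.ndarray
    weight: float = 1.0

    def __post_init__(self) -> None:
        st = np.asarray(self.switch_times, dtype=float)
        lv = np.asarray(self.levels, dtype=float)
        object.__setattr__(self, "switch_times", st)
        object.__setattr__(self, "levels", lv)
        if lv.size != st.size + 1:
            raise InvalidConfigError(
                f"levels must have one more entry than switch_times "
                f"({lv.size} vs {st.size})"
            )
        if st.size and np.any(np.diff(st) <= 0):
            raise InvalidConfigError("switch_times must be strictly increasing")
        if np.any(lv < 0):
            raise InvalidConfigError("transcription levels must be non-negative")
        if self.weight <= 0:
            raise InvalidConfigError("candidate weight must be positive")

    def sample(self, grid: np.ndarray) -> np.ndarray:
        """Evaluate the step function on a time grid (right-continuous)."""
        grid = np.asarray(grid, dtype=float)
        idx = np.searchsorted(self.switch_times, grid, side="right")
        return self.levels[idx]

    def switch_directions(self) -> np.ndarray:
        """Sign of the level change at each switch (+1 up, -1 down, 0 no change)."""
        return np.sign(np.diff(self.levels))


@dataclass
class SwitchProfileSet:
    """Weighted candidate step-function profiles for one cell.

    Weights are normalised to sum to one on construction.
    """

    candidates: list[StepProfile] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.candidates:
            raise InvalidConfigError("a profile set needs at least one candidate")
        total = sum(c.weight for c in self.candidates)
        if total <= 0:
            raise InvalidConfigError("candidate weights must sum to a positive value")
        self.candidates = [
            StepProfile(c.switch_times, c.levels, c.weight / total)
            for c in self.candidates
        ]

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.candidates])

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)


def write_profiles_json(profiles: dict[str, SwitchProfileSet], path) -> None:
    """Serialise per-cell profile sets to JSON.

    Layout: ``{cell_id: [{"weight": w, "switch_times_h": [...], "levels": [...]}]}``.
    """
    payload = {
        str(cid): [
            {
                "weight": c.weight,
                "switch_times_h": c.switch_times.tolist(),
                "levels": c.levels.tolist(),
            }
            for c in pset
        ]
        for cid, pset in profiles.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_profiles_json(path) -> dict[str, SwitchProfileSet]:
    with open(path) as fh:
        payload = json.load(fh)
    return {
        cid: SwitchProfileSet(
            [
                StepProfile(
                    np.asarray(c["switch_times_h"], dtype=float),
                    np.asarray(c["levels"], dtype=float),
                    float(c["weight"]),
                )
                for c in cands
            ]
        )
        for cid, cands in payload.items()
    }
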