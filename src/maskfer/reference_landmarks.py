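"""Traditional 68-point facial landmark index sets and distance arithmetic.

The classic 68-landmark annotation scheme splits into an *upper* set
(jaw corners, eyebrows, upper nose bridge, eyes) that survives a facial
mask, and a *lower* set (jawline, lower nose, mouth) that a mask hides.
Only 26 of the 68 landmarks (38%) remain visible on a masked face, and of
those only the 12 eye-area landmarks (18% of all 68) move appreciably
between emotions — the quantitative motivation for a flexible landmark
detector on the upper face.

Indices are 1-based throughout, matching the standard L1..L68 labelling;
conversion to 0-based offsets happens only at array access.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

N_TRADITIONAL = 68

#: eye-area landmarks L37..L48 (both eyes, 6 points each)
EYE_AREA = tuple(range(37, 49))


@dataclass(frozen=True)
class LandmarkIndexSet:
    """A named, ordered set of 1-based landmark indices."""

    name: str
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError(f"duplicate indices in set {self.name!r}")
        if any(not (1 <= i <= N_TRADITIONAL) for i in self.indices):
            raise ValueError(f"indices of {self.name!r} must lie in 1..68")

    def __len__(self) -> int:
        return len(self.indices)

    def __contains__(self, index: int) -> bool:
        return index in self.indices

    def percent_of_total(self) -> int:
        """Share of the full 68-point set, rounded half away from zero."""
        return _round_half_away(100.0 * len(self) / N_TRADITIONAL)


@dataclass(frozen=True)
class LabeledLandmark:
    """One landmark coordinate annotated with the emotion it was observed under."""

    index: int
    x: float
    y: float
    emotion: str

    def __post_init__(self) -> None:
        if not (1 <= self.index <= N_TRADITIONAL):
            raise ValueError("landmark index must lie in 1..68")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("landmark coordinates must be finite")
        if self.x < 0 or self.y < 0:
            raise ValueError("landmark coordinates must be non-negative")


def _round_half_away(v: float) -> int:
    return int(math.floor(v + 0.5)) if v >= 0 else -int(math.floor(-v + 0.5))


def upper_set() -> LandmarkIndexSet:
    """Landmarks that remain visible above a facial mask.

    The union {1,17} ∪ {18..22} ∪ {23..27} ∪ {28,29} ∪ {37..48}: the two
    jaw-top corners, both eyebrows, the upper nose bridge and both eyes —
    26 indices in total.
    """
    indices = (
        (1, 17)
        + tuple(range(18, 23))
        + tuple(range(23, 28))
        + (28, 29)
        + tuple(range(37, 49))
    )
    return LandmarkIndexSet("upper", indices)


def lower_set() -> LandmarkIndexSet:
    """Landmarks hidden by a facial mask.

    {2..16} ∪ {30..36} ∪ {49..68}: the jawline, the lower nose and the
    whole mouth — 42 indices.
    """
    indices = tuple(range(2, 17)) + tuple(range(30, 37)) + tuple(range(49, 69))
    return LandmarkIndexSet("lower", indices)


def eye_area_set() -> LandmarkIndexSet:
    """The 12 eye-contour landmarks L37..L48."""
    return LandmarkIndexSet("eye_area", EYE_AREA)


def all_set() -> LandmarkIndexSet:
    return LandmarkIndexSet("all", tuple(range(1, N_TRADITIONAL + 1)))


def landmark_distance(a: LabeledLandmark, b: LabeledLandmark) -> float:
    """Euclidean distance between the same landmark under two emotions."""
    if a.index != b.index:
        raise ValueError(
            f"cannot compare landmark L{a.index} with L{b.index}: "
            "displacement is defined per landmark index"
        )
    return math.hypot(b.x - a.x, b.y - a.y)


def partition_stats() -> dict[str, dict[str, int]]:
    """Counts and integer percentages for the upper/lower/eye-area sets.

    Percentages are of the full 68-point set, rounded half away from zero
    (26/68 -> 38, 42/68 -> 62, 12/68 -> 18).
    """
    stats: dict[str, dict[str, int]] = {}
    for s in (upper_set(), lower_set(), eye_area_set()):
        stats[s.name] = {"count": len(s), "percent": s.percent_of_total()}
    return stats


def read_landmark_table(path) -> list[LabeledLandmark]:
    """Read a landmark sidecar CSV with columns index,x,y,emotion."""
    df = pd.read_csv(path)
    required = {"index", "x", "y", "emotion"}
    if not required.issubset(df.columns):
        raise ValueError(f"landmark table must have columns {sorted(required)}")
    return [
        LabeledLandmark(int(r.index), float(r.x), float(r.y), str(r.emotion))
        for r in df.itertuples(index=False)
    ]


def displacement_table(landmarks: list[LabeledLandmark]) -> pd.DataFrame:
    """Pairwise per-landmark displacement between every pair of emotions.

    Returns a tidy frame (index, emotion_a, emotion_b, distance, region)
    where region is "upper" or "lower".
    """
    upper = upper_set()
    by_index: dict[int, list[LabeledLandmark]] = {}
    for lm in landmarks:
        by_index.setdefault(lm.index, []).append(lm)
    rows = []
    for idx, group in sorted(by_index.items()):
        region = "upper" if idx in upper else "lower"
        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                if a.emotion == b.emotion:
                    continue
                rows.append(
                    {
                        "index": idx,
                        "emotion_a": a.emotion,
                        "emotion_b": b.emotion,
                        "distance": landmark_distance(a, b),
                        "region": region,
                    }
                )
    return pd.DataFrame(rows, columns=["index", "emotion_a", "emotion_b", "distance", "region"])
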