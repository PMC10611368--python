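"""Real-time mode-fusion feedback engine.

A 4-row label matrix accumulates one column per second (rows: EEG
{0,1}, ECG {2,3}, phone {4,5}, lane {6,7}; the higher label in each row
is the abnormal one). A 5-column sliding window stepping one column per
second takes the per-row mode, looks the resulting 4-tuple pattern up
in a severity dictionary, and emits severe/mild only when the same
non-normal key has persisted for more than ``T_persist`` seconds;
otherwise the output is normal.

Two dictionary builders are provided: the listed variant (the default;
exactly one severe pattern (1,3,4,7), three mild, rest normal) and a
prose-rule variant in which phone use excuses a lane departure and
either abnormal biosignal alone is mild.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from drowsyfuse.synthgen import ROW_ALPHABETS

SEVERE = "severe_fatigue"
MILD = "mild_fatigue"
NORMAL = "normal"

#: Abnormal label per row (ties break toward these: safety bias).
ABNORMAL = (1, 3, 5, 7)

Pattern = Tuple[int, int, int, int]


def all_patterns() -> Iterator[Pattern]:
    return product(*ROW_ALPHABETS)


def listed_dictionary() -> Dict[Pattern, str]:
    """The default pattern dictionary: (1,3,4,7) severe; (1,3,5,7),
    (1,3,5,6), (1,3,4,6) mild; every other tuple normal."""
    d = {p: NORMAL for p in all_patterns()}
    d[(1, 3, 4, 7)] = SEVERE
    for p in ((1, 3, 5, 7), (1, 3, 5, 6), (1, 3, 4, 6)):
        d[p] = MILD
    return d


def prose_rule_dictionary() -> Dict[Pattern, str]:
    """Alternative dictionary from the narrative rules.

    - Phone use (5) together with a lane departure (7) excuses the
      departure: not treated as fatigue evidence.
    - No phone (4) + lane departure (7) + at least one abnormal
      biosignal -> severe (abnormal external expression).
    - Otherwise a single abnormal biosignal (EEG or ECG) -> mild.
    - Both biosignals abnormal -> mild (severe only with the external
      lane evidence above).
    """
    d = {}
    for p in all_patterns():
        eeg, ecg, phone, lane = p
        bio_abnormal = (eeg == 1) + (ecg == 3)
        if phone == 4 and lane == 7 and bio_abnormal >= 1:
            d[p] = SEVERE
        elif bio_abnormal >= 1 and not (phone == 5 and lane == 7):
            d[p] = MILD
        else:
            d[p] = NORMAL
    return d


def dictionary_to_json(d: Dict[Pattern, str], path: str) -> None:
    payload = {",".join(map(str, k)): v for k, v in d.items()}
    payload["default"] = NORMAL
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def dictionary_from_json(path: str) -> Dict[Pattern, str]:
    with open(path) as fh:
        payload = json.load(fh)
    default = payload.pop("default", NORMAL)
    d = {p: default for p in all_patterns()}
    for key, level in payload.items():
        d[tuple(int(v) for v in key.split(","))] = level
    return d


class LabelMatrix:
    """Append-only 4-row categorical stream, one column per second."""

    def __init__(self, columns: Optional[Sequence[Sequence[int]]] = None):
        self._cols: List[Pattern] = []
        if columns is not None:
            for col in columns:
                self.append_second(col)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "LabelMatrix":
        arr = np.asarray(arr, dtype=int)
        if arr.shape[0] != 4:
            raise ValueError("label matrix must have exactly 4 rows")
        return cls(arr.T)

    def append_second(self, labels: Sequence[int]) -> "LabelMatrix":
        if len(labels) != 4:
            raise ValueError("need one label per row (4)")
        for row, lab in enumerate(labels):
            if int(lab) not in ROW_ALPHABETS[row]:
                raise ValueError(
                    f"label {lab} not in row-{row + 1} alphabet {ROW_ALPHABETS[row]}"
                )
        self._cols.append(tuple(int(v) for v in labels))
        return self

    @property
    def n_cols(self) -> int:
        return len(self._cols)

    def to_array(self) -> np.ndarray:
        if not self._cols:
            return np.zeros((4, 0), dtype=int)
        return np.asarray(self._cols, dtype=int).T

    def to_csv(self, path: str) -> None:
        np.savetxt(path, self.to_array(), fmt="%d", delimiter=",")

    @classmethod
    def from_csv(cls, path: str) -> "LabelMatrix":
        return cls.from_array(np.loadtxt(path, dtype=int, delimiter=",", ndmin=2))


@dataclass
class SeverityResult:
    """Fused output for one window position."""

    window_end_time: int  # seconds (1-based end column)
    pattern: Pattern
    level: str
    delta_t: float  # seconds the current non-normal key has persisted

    def to_dict(self) -> dict:
        return {
            "window_end_time": self.window_end_time,
            "pattern": list(self.pattern),
            "level": self.level,
            "delta_t": self.delta_t,
        }


def window_modes(
    matrix: LabelMatrix, end_col: int, window: int = 5
) -> Pattern:
    """Per-row mode over the ``window`` columns ending at ``end_col``.

    Ties (possible only for even windows) break toward the row's
    abnormal label. Raises ValueError while the matrix is still warming
    up (fewer than ``window`` columns before ``end_col``).
    """
    if end_col < window - 1:
        raise ValueError("warming up: not enough columns for a full window")
    if end_col >= matrix.n_cols:
        raise ValueError("end_col beyond matrix")
    arr = matrix.to_array()[:, end_col - window + 1 : end_col + 1]
    pattern = []
    for row in range(4):
        normal_lab, abnormal_lab = ROW_ALPHABETS[row][0], ABNORMAL[row]
        n_abnormal = int(np.sum(arr[row] == abnormal_lab))
        pattern.append(abnormal_lab if 2 * n_abnormal >= window else normal_lab)
    return tuple(pattern)


def map_pattern(pattern: Pattern, dictionary: Dict[Pattern, str]) -> str:
    """Dictionary lookup; unlisted patterns resolve to normal."""
    return dictionary.get(tuple(pattern), NORMAL)


@dataclass
class FusionState:
    """Streaming persistence tracker for the severity rule."""

    window: int = 5
    t_persist: float = 3.0
    dictionary: Dict[Pattern, str] = field(default_factory=listed_dictionary)
    _current_key: Optional[str] = None
    _delta_t: float = 0.0

    def update(self, level_key: str) -> Tuple[str, float]:
        """Advance one second with the window's mapped key; returns
        (output level, delta_t). delta_t is the elapsed time since the
        current non-normal key first appeared in an unbroken run of
        windows (0 at first appearance, +1 per consecutive second); it
        resets whenever the key changes or is normal."""
        if level_key == NORMAL or level_key != self._current_key:
            self._current_key = None if level_key == NORMAL else level_key
            self._delta_t = 0.0
        else:
            self._delta_t += 1.0
        if self._current_key is not None and self._delta_t > self.t_persist:
            return self._current_key, self._delta_t
        return NORMAL, self._delta_t


def feedback_stream(
    matrix: LabelMatrix,
    dictionary: Optional[Dict[Pattern, str]] = None,
    t_persist: float = 3.0,
    window: int = 5,
) -> List[SeverityResult]:
    """Run the full sliding-window feedback pass over a label matrix.

    Emits one result per window position (n_cols - window + 1 results);
    the output level is severe/mild only when its key has persisted for
    delta_t > t_persist consecutive seconds, else normal.
    """
    dictionary = dictionary if dictionary is not None else listed_dictionary()
    if matrix.n_cols < window:
        raise ValueError(f"need at least {window} columns")
    state = FusionState(window=window, t_persist=t_persist, dictionary=dictionary)
    results = []
    for end in range(window - 1, matrix.n_cols):
        pattern = window_modes(matrix, end, window)
        key = map_pattern(pattern, dictionary)
        level, delta_t = state.update(key)
        results.append(SeverityResult(end + 1, pattern, level, delta_t))
    return results
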