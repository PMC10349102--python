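"""Inter-observer-agreement (IOA) series and the aggregated description matrix.

Multiple observers mark intervals (seconds) where a character expresses an
attribute.  IOA at a timepoint bin is the fraction of observers whose
interval overlaps the bin; bipolar attributes (arousal high/low, valence
positive/negative, direction self/other) subtract the opposing pole's IOA.
Absolute-thresholded IOA runs define emotional episodes, which aggregate
into the T x A annotation matrix used by the linkage and PLS stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INTERVAL_COLUMNS = [
    "observer_id",
    "character",
    "attribute",
    "start_s",
    "end_s",
    "value",
]


@dataclass
class AnnotationMatrix:
    """T x A description matrix plus per-attribute metadata."""

    values: np.ndarray
    attributes: list[str]
    kinds: dict[str, str]  # attribute -> unipolar | bipolar | binary
    categories: dict[str, str]  # attribute -> emotion | place | other

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.attributes):
            raise ValueError("attribute list does not match column count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.attributes)


@dataclass(frozen=True)
class Episode:
    """A maximal above-threshold run for one character."""

    character: str
    start_bin: int
    end_bin: int  # exclusive
    attribute_medians: dict


def compute_ioa(
    intervals: pd.DataFrame,
    attribute: str,
    n_observers: int,
    T: int,
    tr_seconds: float,
    character: str | None = None,
    value: str | None = None,
) -> np.ndarray:
    """Per-bin fraction of observers marking ``attribute``.

    A bin t is covered by an interval iff the interval intersects
    ``[t*TR, (t+1)*TR)`` with positive measure.  Intervals outside the
    movie span are clipped with a warning.  Multiple intervals from one
    observer count once per bin.
    """
    if n_observers < 1:
        raise ValueError("n_observers must be >= 1")
    sel = intervals[intervals["attribute"] == attribute]
    if character is not None:
        sel = sel[sel["character"] == character]
    if value is not None:
        sel = sel[sel["value"] == value]
    horizon = T * tr_seconds
    marked = np.zeros((n_observers, T), dtype=bool)
    n_clipped = 0
    for row in sel.itertuples(index=False):
        start, end = float(row.start_s), float(row.end_s)
        if start < 0 or end > horizon:
            n_clipped += 1
            start, end = max(start, 0.0), min(end, horizon)
        if end <= start:
            continue
        first = int(np.floor(start / tr_seconds))
        last = int(np.ceil(end / tr_seconds)) - 1
        obs = int(row.observer_id) - 1
        if 0 <= obs < n_observers:
            marked[obs, first : min(last, T - 1) + 1] = True
    if n_clipped:
        logger.warning("clipped %d interval(s) to the movie span", n_clipped)
    return marked.sum(axis=0) / float(n_observers)


def bipolar_ioa(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Difference of opposing-pole IOA series, in [-1, 1]."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.shape != neg.shape:
        raise ValueError(f"length mismatch: {pos.shape} vs {neg.shape}")
    return pos - neg


def detect_episodes(
    ioa_set: dict[str, np.ndarray],
    threshold: float = 0.5,
    character: str = "",
    median_attributes: list[str] | None = None,
) -> list[Episode]:
    """Maximal runs where any attribute's |IOA| >= threshold.

    ``median_attributes`` (default: all) get a per-episode median value
    recorded (even-length medians use the midpoint average).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    series = {k: np.asarray(v, dtype=float) for k, v in ioa_set.items()}
    lengths = {v.size for v in series.values()}
    if len(lengths) != 1:
        raise ValueError("IOA series lengths differ")
    T = lengths.pop()
    active = np.zeros(T, dtype=bool)
    for v in series.values():
        active |= np.abs(v) >= threshold
    episodes: list[Episode] = []
    t = 0
    med_attrs = series.keys() if median_attributes is None else median_attributes
    while t < T:
        if active[t]:
            start = t
            while t < T and active[t]:
                t += 1
            medians = {
                a: float(np.median(series[a][start:t]))
                for a in med_attrs
                if a in series
            }
            episodes.append(Episode(character, start, t, medians))
        else:
            t += 1
    return episodes


def aggregate_annotation_series(
    episodes_by_character: dict[str, list[Episode]],
    T: int,
    attributes: list[str],
    kinds: dict[str, str],
    categories: dict[str, str],
    passthrough: dict[str, np.ndarray] | None = None,
) -> AnnotationMatrix:
    """Aggregate per-character episodes into the T x A description matrix.

    Graded (unipolar/bipolar) attributes take the maximal per-episode
    median across overlapping episodes and characters; binary attributes
    are 1 inside any episode recording them and 0 elsewhere.  Binary
    location/time series may be passed through unchanged.
    """
    passthrough = passthrough or {}
    values = np.zeros((T, len(attributes)))
    col = {a: j for j, a in enumerate(attributes)}
    for episodes in episodes_by_character.values():
        for ep in episodes:
            for attr, med in ep.attribute_medians.items():
                if attr not in col:
                    continue
                j = col[attr]
                span = slice(ep.start_bin, ep.end_bin)
                if kinds.get(attr) == "binary":
                    values[span, j] = np.where(med != 0, 1.0, values[span, j])
                elif kinds.get(attr) == "bipolar":
                    # keep the extreme of larger magnitude
                    cur = values[span, j]
                    values[span, j] = np.where(np.abs(med) >= np.abs(cur), med, cur)
                else:
                    values[span, j] = np.maximum(values[span, j], med)
    for attr, series in passthrough.items():
        if attr in col:
            values[:, col[attr]] = np.asarray(series, dtype=float)[:T]
    return AnnotationMatrix(values, list(attributes), dict(kinds), dict(categories))


def build_description_matrix(
    intervals: pd.DataFrame,
    n_observers: int,
    T: int,
    tr_seconds: float,
    attributes: list[str],
    kinds: dict[str, str],
    categories: dict[str, str],
    emotion_labels: list[str],
    threshold: float = 0.5,
    passthrough: dict[str, np.ndarray] | None = None,
) -> AnnotationMatrix:
    """Full IOA pipeline: intervals -> per-character IOA -> episodes -> T x A matrix.

    ``arousal`` and ``direction`` are bipolar (high-low, self-other);
    ``valence_positive``/``valence_negative`` are unipolar pole IOAs;
    discrete emotion labels are binary; place/other series come in via
    ``passthrough``.
    """
    episodes_by_character: dict[str, list[Episode]] = {}
    for character in sorted(intervals["character"].unique()):
        series: dict[str, np.ndarray] = {}
        series["arousal"] = bipolar_ioa(
            compute_ioa(intervals, "arousal", n_observers, T, tr_seconds,
                        character=character, value="high"),
            compute_ioa(intervals, "arousal", n_observers, T, tr_seconds,
                        character=character, value="low"),
        )
        series["direction"] = bipolar_ioa(
            compute_ioa(intervals, "direction", n_observers, T, tr_seconds,
                        character=character, value="self"),
            compute_ioa(intervals, "direction", n_observers, T, tr_seconds,
                        character=character, value="other"),
        )
        series["valence_positive"] = compute_ioa(
            intervals, "valence", n_observers, T, tr_seconds,
            character=character, value="positive",
        )
        series["valence_negative"] = compute_ioa(
            intervals, "valence", n_observers, T, tr_seconds,
            character=character, value="negative",
        )
        for label in emotion_labels:
            series[label] = compute_ioa(
                intervals, label, n_observers, T, tr_seconds, character=character
            )
        eps = detect_episodes(series, threshold=threshold, character=character)
        # binary attributes express an episode only when their own IOA
        # cleared the threshold over the episode's span
        resolved = []
        for ep in eps:
            medians = dict(ep.attribute_medians)
            for label in emotion_labels:
                medians[label] = 1.0 if medians.get(label, 0.0) >= threshold else 0.0
            resolved.append(Episode(ep.character, ep.start_bin, ep.end_bin, medians))
        episodes_by_character[character] = resolved
    return aggregate_annotation_series(
        episodes_by_character,
        T,
        attributes,
        kinds,
        categories,
        passthrough=passthrough,
    )


def read_intervals_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(INTERVAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"intervals table missing columns: {sorted(missing)}")
    return df
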