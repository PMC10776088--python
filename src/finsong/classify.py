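"""INI song-type classification and per-group type percentages.

Songs are assigned to known INI types (by default 19 s and 12 s, each with
a ±2.5 s window), to "hybrid" when their INI series contains both types in
non-trivial proportion, or to "unclassified" when the evidence is too thin.
Percentages per (season, location) are computed over classified songs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .songs import Song

__all__ = [
    "IniTypeDef",
    "SongTypeLabel",
    "default_ini_types",
    "classify_song",
    "type_percentages",
    "suggest_type_centers",
    "HYBRID",
    "UNCLASSIFIED",
]

log = logging.getLogger(__name__)

HYBRID = "hybrid"
UNCLASSIFIED = "unclassified"

#: a song is hybrid when at least two types each hold this fraction of its
#: classified INIs; a single type must hold at least 1 − this fraction
DEFAULT_MIN_FRACTION = 0.10
#: minimum classified INIs to label a song at all
DEFAULT_MIN_COUNT = 5


@dataclass
class IniTypeDef:
    """One known INI type: a window of |ini − center| <= tolerance."""

    label: str
    center: float
    tolerance: float

    def __post_init__(self) -> None:
        if self.center <= 0 or self.tolerance <= 0:
            raise ValueError("center and tolerance must be positive")

    def contains(self, ini: float) -> bool:
        return abs(ini - self.center) <= self.tolerance


def default_ini_types() -> list[IniTypeDef]:
    return [IniTypeDef("19s", 19.0, 2.5), IniTypeDef("12s", 12.0, 2.5)]


def _check_disjoint(types: list[IniTypeDef]) -> None:
    for i, a in enumerate(types):
        for b in types[i + 1 :]:
            if abs(a.center - b.center) <= a.tolerance + b.tolerance:
                raise ValueError(
                    f"INI type windows {a.label} and {b.label} overlap; "
                    "windows must be disjoint"
                )


@dataclass
class SongTypeLabel:
    song_id: str
    label: str
    counts: dict[str, int] = field(default_factory=dict)
    fractions: dict[str, float] = field(default_factory=dict)
    n_classified: int = 0
    season_label: str = ""
    location: str = ""


def classify_song(
    song: Song,
    types: list[IniTypeDef] | None = None,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    min_count: int = DEFAULT_MIN_COUNT,
) -> SongTypeLabel:
    """Label one song from its INI series.

    Each INI is assigned to the type whose window contains it (windows are
    disjoint), else left unassigned.  The song is labelled:

    - a single type when it holds at least ``1 − min_fraction`` of the
      classified INIs,
    - ``hybrid`` when at least two types each hold at least ``min_fraction``
      and there are at least ``min_count`` classified INIs,
    - ``unclassified`` otherwise (too few INIs in any window, or no rule
      fires).

    Deterministic and invariant to the order of INIs within the song.
    """
    types = types if types is not None else default_ini_types()
    _check_disjoint(types)
    if song.ini is None or len(song.ini) == 0:
        raise ValueError(f"song {song.song_id} has no INI series to classify")
    counts = {t.label: 0 for t in types}
    for ini in song.ini.values:
        for t in types:
            if t.contains(ini):
                counts[t.label] += 1
                break
    n_classified = sum(counts.values())
    result = SongTypeLabel(
        song_id=song.song_id,
        label=UNCLASSIFIED,
        counts=counts,
        n_classified=n_classified,
        season_label=song.season_label,
        location=song.location,
    )
    if n_classified == 0:
        return result
    fractions = {k: v / n_classified for k, v in counts.items()}
    result.fractions = fractions
    represented = [k for k, f in fractions.items() if f >= min_fraction]
    if n_classified >= min_count and len(represented) >= 2:
        result.label = HYBRID
    else:
        dominant = max(fractions, key=lambda k: (fractions[k], -types_index(types, k)))
        if fractions[dominant] >= 1.0 - min_fraction and n_classified >= min_count:
            result.label = dominant
    return result


def types_index(types: list[IniTypeDef], label: str) -> int:
    for i, t in enumerate(types):
        if t.label == label:
            return i
    return -1


def type_percentages(labels: list[SongTypeLabel]) -> pd.DataFrame:
    """Percentage of songs of each type per (season, location).

    Unclassified songs are excluded from the denominator; groups with no
    classified song are omitted (with a logged warning).  Columns:
    season, location, one ``pct_<type>`` per label seen, n_songs.
    Percentages within a group sum to 100.
    """
    type_labels = sorted(
        {l.label for l in labels if l.label != UNCLASSIFIED},
        key=lambda s: (s == HYBRID, s),
    )
    rows = []
    groups: dict[tuple[str, str], list[SongTypeLabel]] = {}
    for l in labels:
        groups.setdefault((l.season_label, l.location), []).append(l)
    for (season, location), members in sorted(groups.items()):
        classified = [m for m in members if m.label != UNCLASSIFIED]
        if not classified:
            log.warning("group (%s, %s): all songs unclassified, omitted", season, location)
            continue
        n = len(classified)
        row = {"season": season, "location": location, "n_songs": n}
        for t in type_labels:
            row[f"pct_{t}"] = 100.0 * sum(1 for m in classified if m.label == t) / n
        rows.append(row)
    cols = ["season", "location"] + [f"pct_{t}" for t in type_labels] + ["n_songs"]
    return pd.DataFrame(rows, columns=cols)


def suggest_type_centers(
    inis: np.ndarray, bin_width: float = 0.5, min_separation: float = 2.0
) -> list[float]:
    """Histogram peak picking on pooled INIs, to suggest type centers for a
    new dataset (e.g. a region whose INI distribution is bimodal).

    Returns local-maximum bin centers, strongest first, peaks closer than
    ``min_separation`` to a stronger one suppressed.
    """
    inis = np.asarray(inis, dtype=float)
    if inis.size == 0:
        return []
    lo = np.floor(inis.min() / bin_width) * bin_width
    hi = np.ceil(inis.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(inis, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    order = np.argsort(-counts)
    peaks: list[float] = []
    for i in order:
        if counts[i] == 0:
            break
        left = counts[i - 1] if i > 0 else 0
        right = counts[i + 1] if i < counts.size - 1 else 0
        if counts[i] < max(left, right):
            continue
        c = float(centers[i])
        if all(abs(c - p) >= min_separation for p in peaks):
            peaks.append(c)
    return peaks
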