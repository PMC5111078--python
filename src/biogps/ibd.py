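"""Post-processing of identity-by-descent (IBD) segment calls.

The haplotype-based IBD detector is run several times with different random
seeds; its raw output is post-processed here in a fixed order:

1. :func:`combine_runs` — keep segments whose detection score is strictly
   below the threshold (default e^-10; lower score = stronger evidence) and,
   per unordered pair and chromosome, merge the union of their marker
   intervals (overlapping or adjacent intervals join; the merged score is the
   minimum of the contributors);
2. :func:`concatenate_gaps` — consecutive segments of the same pair and
   chromosome separated by fewer than `max_gap` marker indexes (default 50,
   strict) are assumed to flank a false-negative gap and are joined;
3. :func:`filter_length` — keep segments of at least `min_cm` centimorgans
   (default 1.0, boundary inclusive).

Marker indexes are 0-based and inclusive at both ends; the gap between
[a, b] and [c, d] (b < c) is c - b - 1, the number of markers strictly
between them. Centimorgan lengths of merged intervals use the per-marker cM
density of the contributing segments (total cM over total markers times the
merged span); the gap contribution when concatenating is the gap size times
the mean flanking density, or zero with ``gap_mode="ignore"``.

:func:`max_pairwise_sharing` summarises, for a focal individual, the maximum
over a population's members of the total cM shared with that member.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .errors import InputError

__all__ = [
    "IBDSegment",
    "SCORE_THRESHOLD",
    "combine_runs",
    "concatenate_gaps",
    "filter_length",
    "max_pairwise_sharing",
    "postprocess",
]

#: default detection-score cutoff (scores strictly below pass)
SCORE_THRESHOLD = math.exp(-10.0)


@dataclass(frozen=True)
class IBDSegment:
    """A shared haplotype interval between two individuals."""

    pair: tuple[str, str]  # unordered; stored sorted
    chromosome: str
    start: int  # marker index, 0-based inclusive
    end: int  # marker index, 0-based inclusive
    length_cm: float
    score: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair", tuple(sorted(map(str, self.pair))))
        if self.start > self.end:
            raise InputError(
                f"malformed segment {self.pair}/{self.chromosome}: start {self.start} > end {self.end}"
            )
        if self.length_cm < 0:
            raise InputError(f"segment {self.pair}: negative cM length")
        if not math.isfinite(self.score):
            raise InputError(f"segment {self.pair}: non-finite score")

    @property
    def n_markers(self) -> int:
        return self.end - self.start + 1

    @property
    def density(self) -> float:
        """cM per marker."""
        return self.length_cm / self.n_markers


def _grouped(segments: Iterable[IBDSegment]):
    groups: dict[tuple, list[IBDSegment]] = {}
    for s in segments:
        groups.setdefault((s.pair, s.chromosome), []).append(s)
    for key in sorted(groups):
        yield key, sorted(groups[key], key=lambda s: (s.start, s.end))


def combine_runs(
    runs: Sequence[Sequence[IBDSegment]],
    score_threshold: float = SCORE_THRESHOLD,
) -> list[IBDSegment]:
    """Union of below-threshold segments across detector runs.

    For each pair/chromosome, overlapping or adjacent marker intervals from
    any run with score strictly below `score_threshold` are merged; the
    merged segment's score is the minimum of the contributors and its cM
    length is the merged span times the contributors' pooled cM density.
    """
    if not runs:
        raise InputError("need at least one detector run")
    passing = [s for run in runs for s in run if s.score < score_threshold]
    out: list[IBDSegment] = []
    for (pair, chrom), segs in _grouped(passing):
        cluster: list[IBDSegment] = []

        def flush(cluster: list[IBDSegment]) -> None:
            start = min(s.start for s in cluster)
            end = max(s.end for s in cluster)
            pooled_density = sum(s.length_cm for s in cluster) / sum(s.n_markers for s in cluster)
            out.append(
                IBDSegment(
                    pair=pair,
                    chromosome=chrom,
                    start=start,
                    end=end,
                    length_cm=(end - start + 1) * pooled_density,
                    score=min(s.score for s in cluster),
                )
            )

        for s in segs:
            if cluster and s.start <= max(c.end for c in cluster) + 1:
                cluster.append(s)
            else:
                if cluster:
                    flush(cluster)
                cluster = [s]
        if cluster:
            flush(cluster)
    return out


def concatenate_gaps(
    segments: Iterable[IBDSegment],
    max_gap: int = 50,
    *,
    gap_mode: str = "interpolate",
) -> list[IBDSegment]:
    """Join same-pair, same-chromosome segments separated by short gaps.

    A gap of strictly fewer than `max_gap` marker indexes (markers strictly
    between the two segments) is treated as a detector false negative. Joined
    length is the sum of the parts plus, with ``gap_mode="interpolate"``, the
    gap size times the mean flanking cM density (``"ignore"`` adds nothing).
    """
    if gap_mode not in ("interpolate", "ignore"):
        raise InputError("gap_mode must be 'interpolate' or 'ignore'")
    out: list[IBDSegment] = []
    for _key, segs in _grouped(segments):
        current = segs[0]
        for nxt in segs[1:]:
            gap = nxt.start - current.end - 1
            if gap < max_gap:
                gap_cm = (
                    max(gap, 0) * (current.density + nxt.density) / 2.0
                    if gap_mode == "interpolate"
                    else 0.0
                )
                current = replace(
                    current,
                    end=max(current.end, nxt.end),
                    length_cm=current.length_cm + nxt.length_cm + gap_cm,
                    score=min(current.score, nxt.score),
                )
            else:
                out.append(current)
                current = nxt
        out.append(current)
    return out


def filter_length(segments: Iterable[IBDSegment], min_cm: float = 1.0) -> list[IBDSegment]:
    """Keep segments at least `min_cm` centimorgans long (inclusive)."""
    return [s for s in segments if s.length_cm >= min_cm]


def postprocess(
    runs: Sequence[Sequence[IBDSegment]],
    score_threshold: float = SCORE_THRESHOLD,
    max_gap: int = 50,
    min_cm: float = 1.0,
    *,
    gap_mode: str = "interpolate",
) -> list[IBDSegment]:
    """The fixed pipeline: combine runs, concatenate gaps, filter by length."""
    return filter_length(
        concatenate_gaps(combine_runs(runs, score_threshold), max_gap, gap_mode=gap_mode),
        min_cm,
    )


def max_pairwise_sharing(
    segments: Iterable[IBDSegment], focal: str, population: Iterable[str]
) -> float:
    """Maximum over population members of total cM shared with `focal`.

    Members without any shared segment contribute 0; the focal individual is
    excluded from the population with a warning if present.
    """
    members = set(map(str, population))
    if not members:
        raise InputError("population is empty")
    if focal in members:
        warnings.warn(f"focal individual {focal!r} excluded from its own population")
        members.discard(focal)
        if not members:
            raise InputError("population contains only the focal individual")
    totals = dict.fromkeys(members, 0.0)
    for s in segments:
        if focal in s.pair:
            other = s.pair[0] if s.pair[1] == focal else s.pair[1]
            if other in totals:
                totals[other] += s.length_cm
    return max(totals.values())
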