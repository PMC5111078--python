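"""Uniparental haplogroup frequency statistics.

Works on count tables of basal mitochondrial or Y-chromosome haplogroups per
population. Provides per-population frequencies, the "most common" rule
(frequency >= 5%, boundary inclusive), combined frequencies of haplogroup
subsets, and Fisher's exact comparisons of a haplogroup (or subset) between a
focal population and comparison populations, individually or pooled.

Declarative collapse rules let basal units be redefined before tabulation,
e.g. treating "R excluding R1a" as one unit::

    CollapseRule(name="R_xR1a", include=["R", "R1b", "R2"], exclude=["R1a"])

Fisher's two-sided p follows the point-probability rule (the sum of
hypergeometric point probabilities no larger than the observed table's),
matching common statistical software; the odds ratio is the sample odds ratio
ad/bc, infinite (and flagged) when bc = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError

__all__ = [
    "CollapseRule",
    "HaplogroupTable",
    "frequencies",
    "most_common",
    "combined_frequency",
    "fisher_exact_2x2",
    "population_sweep",
    "SweepRow",
]


@dataclass
class CollapseRule:
    """Collapse several raw haplogroup labels into one unit before tabulation."""

    name: str
    include: Sequence[str]
    exclude: Sequence[str] = ()


class HaplogroupTable:
    """Counts of basal haplogroups per population.

    Construct from a mapping ``{population: {haplogroup: count}}`` or a tidy
    DataFrame with columns (population, haplogroup, count). `marker` tags the
    system ("mtDNA" or "Y").
    """

    def __init__(
        self,
        counts: Mapping[str, Mapping[str, int]] | pd.DataFrame,
        marker: str = "mtDNA",
        collapse_rules: Sequence[CollapseRule] = (),
    ):
        if isinstance(counts, pd.DataFrame):
            counts = {
                pop: dict(zip(sub["haplogroup"], sub["count"]))
                for pop, sub in counts.groupby("population")
            }
        data: dict[str, dict[str, int]] = {}
        for pop, hgs in counts.items():
            row: dict[str, int] = {}
            for hg, c in hgs.items():
                c = int(c)
                if c < 0:
                    raise InputError(f"negative count for {pop}/{hg}")
                row[str(hg)] = row.get(str(hg), 0) + c
            data[str(pop)] = row
        self._counts = data
        self.marker = marker
        if collapse_rules:
            self._counts = self._apply_rules(collapse_rules)

    def _apply_rules(self, rules: Sequence[CollapseRule]) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for pop, row in self._counts.items():
            new: dict[str, int] = {}
            consumed: set[str] = set()
            for rule in rules:
                excl = set(rule.exclude)
                total = sum(c for hg, c in row.items() if hg in set(rule.include) - excl)
                consumed |= set(rule.include) - excl
                if total:
                    new[rule.name] = new.get(rule.name, 0) + total
            for hg, c in row.items():
                if hg not in consumed:
                    new[hg] = new.get(hg, 0) + c
            out[pop] = new
        return out

    @property
    def populations(self) -> list[str]:
        return list(self._counts)

    def haplogroups(self, population: str | None = None) -> list[str]:
        if population is not None:
            return sorted(self._pop(population))
        return sorted({hg for row in self._counts.values() for hg in row})

    def _pop(self, population: str) -> dict[str, int]:
        try:
            return self._counts[str(population)]
        except KeyError:
            raise InputError(f"unknown population {population!r}") from None

    def count(self, population: str, haplogroup: str | Iterable[str]) -> int:
        row = self._pop(population)
        if isinstance(haplogroup, str):
            return row.get(haplogroup, 0)
        return sum(row.get(h, 0) for h in haplogroup)

    def total(self, population: str) -> int:
        return sum(self._pop(population).values())

    def pooled(self, populations: Sequence[str]) -> dict[str, int]:
        """Summed counts across several populations."""
        out: dict[str, int] = {}
        for pop in populations:
            for hg, c in self._pop(pop).items():
                out[hg] = out.get(hg, 0) + c
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"population": pop, "haplogroup": hg, "count": c}
            for pop, row in self._counts.items()
            for hg, c in sorted(row.items())
        ]
        return pd.DataFrame(rows, columns=["population", "haplogroup", "count"])


def frequencies(table: HaplogroupTable, population: str) -> dict[str, float]:
    """Haplogroup relative frequencies for one population (sum to 1)."""
    total = table.total(population)
    if total <= 0:
        raise InputError(f"population {population!r} has zero total count")
    return {hg: c / total for hg, c in table._pop(population).items()}


def most_common(freqs: Mapping[str, float], threshold: float = 0.05) -> set[str]:
    """Haplogroups at or above the frequency threshold (boundary inclusive)."""
    return {hg for hg, f in freqs.items() if f >= threshold}


def combined_frequency(freqs: Mapping[str, float], subset: Iterable[str]) -> float:
    """Sum of the frequencies of a haplogroup subset."""
    subset = list(subset)
    unknown = [hg for hg in subset if hg not in freqs]
    if unknown:
        raise InputError(f"unknown haplogroups in subset: {unknown}")
    return float(sum(freqs[hg] for hg in subset))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test of the 2x2 table [[a, b], [c, d]].

    Returns ``(p, odds_ratio)`` with the point-probability two-sided p and the
    sample odds ratio ad/bc (``inf`` when bc = 0 and ad > 0, ``nan`` for 0/0).
    """
    vals = (a, b, c, d)
    if any(int(v) != v or v < 0 for v in vals):
        raise InputError("Fisher table entries must be non-negative integers")
    a, b, c, d = map(int, vals)
    if a + b + c + d == 0:
        raise InputError("Fisher table is all zero")
    if min(a + b, c + d, a + c, b + d) == 0:
        raise InputError("Fisher table has an empty margin")
    p = float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)
    if b * c == 0:
        orr = math.inf if a * d > 0 else math.nan
    else:
        orr = (a * d) / (b * c)
    return min(p, 1.0), orr


@dataclass
class SweepRow:
    """One focal-vs-comparison Fisher result."""

    comparison: str
    table: tuple[int, int, int, int]  # (focal carrier, focal other, comp carrier, comp other)
    p_value: float
    odds_ratio: float
    infinite_or: bool = field(default=False)


def population_sweep(
    table: HaplogroupTable,
    haplogroups: str | Sequence[str],
    focal: str,
    comparisons: Sequence[str],
    *,
    pooled: bool = False,
) -> list[SweepRow]:
    """Fisher comparisons of a haplogroup (or subset) between focal and others.

    Builds, per comparison population (or one pooled "all others" group when
    ``pooled=True``), the 2x2 table of carrier vs non-carrier counts in focal
    vs comparison and applies :func:`fisher_exact_2x2`.
    """
    if isinstance(haplogroups, str):
        haplogroups = [haplogroups]
    fa = table.count(focal, haplogroups)
    fb = table.total(focal) - fa
    groups: list[tuple[str, int, int]] = []
    if pooled:
        counts = table.pooled(comparisons)
        ca = sum(counts.get(h, 0) for h in haplogroups)
        cb = sum(counts.values()) - ca
        groups.append(("+".join(comparisons), ca, cb))
    else:
        for comp in comparisons:
            ca = table.count(comp, haplogroups)
            cb = table.total(comp) - ca
            groups.append((comp, ca, cb))
    rows = []
    for name, ca, cb in groups:
        p, orr = fisher_exact_2x2(fa, fb, ca, cb)
        rows.append(SweepRow(name, (fa, fb, ca, cb), p, orr, infinite_or=math.isinf(orr)))
    return rows
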