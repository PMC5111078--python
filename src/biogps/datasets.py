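"""Bundled synthetic example datasets.

The haplogroup tables here are *synthetic stand-ins*: integer count tables
constructed so that the Druze marginal frequencies reproduce values reported
for Israeli Druze in uniparental haplogroup surveys (mtDNA: H 31.88%,
K 12.81%, X 12.81%, U1 5.63%, J 5.63%; Y: most-common set 94.17%, K+L
combined 14.58%, J1+J2 33.53%). The per-haplogroup split inside aggregate
figures and all comparison-population counts are invented, plausible-order
values for worked examples and tests — they are not measurements.
"""

from __future__ import annotations

from .haplogroups import HaplogroupTable

__all__ = ["druze_mtdna_table_synthetic", "druze_y_table_synthetic"]


def druze_mtdna_table_synthetic() -> HaplogroupTable:
    """Synthetic mtDNA haplogroup counts for a Druze-like community (n=320).

    Druze counts are chosen so H=102/320, K=41/320, X=41/320, U1=18/320 and
    J=18/320 reproduce the frequencies above; the five most common
    haplogroups jointly cover 220/320 = 68.75% of individuals. Two synthetic
    Levantine comparison populations are included for Fisher worked examples.
    """
    counts = {
        "Druze": {
            "H": 102,
            "K": 41,
            "X": 41,
            "U1": 18,
            "J": 18,
            # filler lineages, each kept below the 5% (16/320) threshold
            "T": 15,
            "HV": 15,
            "N": 15,
            "U3": 15,
            "L2": 14,
            "W": 13,
            "I": 13,
        },
        # invented comparison groups with Levantine-order frequencies
        "Levantine_A": {
            "H": 75,
            "K": 26,
            "X": 6,
            "U1": 11,
            "J": 30,
            "T": 45,
            "HV": 40,
            "N": 35,
            "U3": 20,
            "L2": 12,
        },
        "Levantine_B": {
            "H": 52,
            "K": 18,
            "X": 3,
            "U1": 7,
            "J": 24,
            "T": 30,
            "HV": 28,
            "N": 22,
            "U3": 10,
            "L2": 6,
        },
    }
    return HaplogroupTable(counts, marker="mtDNA")


def druze_y_table_synthetic() -> HaplogroupTable:
    """Synthetic Y haplogroup counts for a Druze-like community (n=343).

    Druze counts reproduce a most-common set (E1b1b, G, J1, J2, K, L, R
    excluding R1a) covering 323/343 = 94.17%, combined K+L = 50/343 = 14.58%
    and combined J1+J2 = 115/343 = 33.53%. The split of the aggregates and
    the comparison population are invented.
    """
    counts = {
        "Druze": {
            "E1b1b": 70,
            "G": 40,
            "J1": 57,
            "J2": 58,
            "K": 25,
            "L": 25,
            "R_xR1a": 48,
            "Q": 8,
            "T": 7,
            "R1a": 5,
        },
        "Levantine_A": {
            "E1b1b": 60,
            "G": 15,
            "J1": 95,
            "J2": 80,
            "K": 6,
            "L": 5,
            "R_xR1a": 30,
            "Q": 4,
            "T": 10,
            "R1a": 8,
        },
    }
    return HaplogroupTable(counts, marker="Y")
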