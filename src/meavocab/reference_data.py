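"""Published per-culture summary statistics used as reference inputs.

Summary table of the 16 cultured-network experiments (11 with prolonged
stimulation, 5 unstimulated controls) this pipeline was designed around:
spontaneous bursts/hour, vocabulary size (number of retained clusters) and
percent of bursts explained, each measured in the 4-hour epochs before and
after the 10-hour stimulation (or rest) period, plus how many of the 3
selected stimulation sites were robust and existing post hoc.

These numbers serve as consistency anchors: e.g. the mean before-epoch
burst rate across all 16 networks, converted to per-minute, rounds to the
canonical 8 bursts/min.
"""

from __future__ import annotations

import pandas as pd

_COLUMNS = ["mea", "age_div", "bursts_per_hour_before", "n_clusters_before",
            "pct_explained_before", "stimulated_existing_of_3",
            "bursts_per_hour_after", "n_clusters_after", "pct_explained_after",
            "group"]

_STIMULATION_ROWS = [
    ("26550", 19, 260, 9, 85, 3, 530, 8, 83),
    ("26549", 20, 292, 14, 98, 1, 651, 11, 97),
    ("38428", 18, 274, 18, 95, 1, 686, 20, 85),
    ("38427", 20, 694, 13, 87, 2, 739, 14, 92),
    ("26532", 20, 497, 16, 89, 1, 463, 16, 87),
    ("26550", 19, 617, 17, 93, 1, 563, 18, 89),
    ("38426", 19, 691, 14, 90, 1, 688, 19, 92),
    ("26549", 19, 679, 7, 66, 1, 605, 8, 98),
    ("26550", 20, 626, 18, 97, 2, 647, 10, 95),
    ("N/A", 21, 548, 12, 89, 2, 607, 7, 88),
    ("38428", 21, 301, 7, 96, 3, 392, 8, 94),
]

_CONTROL_ROWS = [
    ("26550", 21, 553, 11, 81, 3, 664, 8, 71),
    ("39740", 18, 609, 17, 88, 1, 659, 10, 79),
    ("38427", 21, 632, 18, 97, 3, 600, 16, 85),
    ("26536", 20, 234, 15, 94, 3, 453, 17, 83),
    ("38427", 21, 566, 9, 84, 2, 631, 17, 88),
]

#: example-network bookkeeping: 1017 spontaneous bursts before stimulation,
#: 9 retained clusters, 151 bursts unclassified; 2092 bursts after.
EXAMPLE_NETWORK = {"n_bursts_before": 1017, "n_clusters": 9,
                   "n_unclassified": 151, "n_bursts_after": 2092}


def reference_experiments() -> pd.DataFrame:
    """The 16-experiment summary table (stimulation + control groups)."""
    rows = [r + ("stimulation",) for r in _STIMULATION_ROWS] \
        + [r + ("control",) for r in _CONTROL_ROWS]
    return pd.DataFrame(rows, columns=_COLUMNS)


def mean_burst_rate_per_min(epoch: str = "before") -> float:
    """Mean bursts/minute across all 16 reference networks for one epoch."""
    df = reference_experiments()
    col = f"bursts_per_hour_{epoch}"
    return float(df[col].mean() / 60.0)
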