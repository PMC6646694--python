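"""Classification of significant edges into connectivity-change patterns.

Each significant edge carries a group-mean Fisher-z value per group.  The
sign configuration of the two means defines three patterns of change in
the patient group relative to controls:

``pathological_positive``
    the edge is anticorrelated (negative) in controls but positive in
    patients — a between-network antagonism flipped into synergy;
``hyperconnectivity``
    an already-positive edge grows stronger;
``hypoconnectivity``
    a negative edge rises toward zero but stays negative.

A positive control edge that weakens or flips negative in patients is not
covered by these definitions and is labelled ``indeterminate`` rather
than silently binned.
"""

from __future__ import annotations

from collections import Counter

import pandas as pd

PATHOLOGICAL_POSITIVE = "pathological_positive"
HYPERCONNECTIVITY = "hyperconnectivity"
HYPOCONNECTIVITY = "hypoconnectivity"
INDETERMINATE = "indeterminate"

PATTERNS = (PATHOLOGICAL_POSITIVE, HYPERCONNECTIVITY, HYPOCONNECTIVITY,
            INDETERMINATE)


def classify_edge(mean_patient: float, mean_control: float) -> str:
    """Pattern label from the two signed group-mean z values.

    Total function of the two signs (and, for hyperconnectivity, their
    order); scale-invariant under any common positive rescaling.
    """
    if mean_control < 0 and mean_patient > 0:
        return PATHOLOGICAL_POSITIVE
    if mean_control > 0 and mean_patient > mean_control:
        return HYPERCONNECTIVITY
    if mean_control < 0 and mean_patient < 0:
        return HYPOCONNECTIVITY
    return INDETERMINATE


def count_patterns(records: pd.DataFrame) -> dict[str, int]:
    """Count edges per pattern.  ``records`` needs ``mean_t2d`` /
    ``mean_control`` columns (or a precomputed ``pattern`` column)."""
    if "pattern" in records.columns:
        labels = records["pattern"]
    else:
        labels = [classify_edge(p, c) for p, c in
                  zip(records["mean_t2d"], records["mean_control"])]
    counts = Counter(labels)
    return {p: counts.get(p, 0) for p in PATTERNS}


def component_regions(records: pd.DataFrame) -> tuple[list[str], dict[str, int]]:
    """Distinct regions touched by the edges and the per-region degree
    (number of incident edges; degrees sum to twice the edge count)."""
    degree: Counter = Counter()
    for a, b in zip(records["region_a"], records["region_b"]):
        degree[a] += 1
        degree[b] += 1
    return sorted(degree), dict(degree)


def annotate_patterns(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a ``pattern`` column appended."""
    out = records.copy()
    out["pattern"] = [classify_edge(p, c) for p, c in
                      zip(out["mean_t2d"], out["mean_control"])]
    return out


def annotate_between_within(records: pd.DataFrame, partition) -> pd.DataFrame:
    """Label each edge with its network pair and a between/within flag.

    ``partition`` is a :class:`fconn.networks.NetworkPartition`.  Unknown
    region names raise with the full list of offenders.
    """
    assignment = partition.assignment
    unknown = sorted({r for col in ("region_a", "region_b")
                      for r in records[col] if r not in assignment})
    if unknown:
        raise KeyError(f"regions not in partition: {unknown}")
    out = records.copy()
    out["network_a"] = [assignment[r] for r in out["region_a"]]
    out["network_b"] = [assignment[r] for r in out["region_b"]]
    out["scope"] = ["within" if a == b else "between"
                    for a, b in zip(out["network_a"], out["network_b"])]
    return out
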