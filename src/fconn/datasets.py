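"""Bundled reference tables."""

from __future__ import annotations

import importlib.resources

import pandas as pd


def load_significant_edges() -> pd.DataFrame:
    """The published set of 33 group-different edges with their per-group
    mean Fisher-z connection strengths and edge p-values.

    Kept verbatim as printed, including one region pair that appears
    twice ('SMA.R'--'C45.L'); region counting therefore de-duplicates by
    label while the row count stays 33.
    """
    ref = importlib.resources.files("fconn.data") / "table2_edges.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
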