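"""Network-level connectivity strengths and group comparison.

The 116 regions are partitioned into seven resting-state networks
(default-mode, attention, visual, auditory, sensory-motor, subcortical,
cerebellum).  Per subject this yields 7 within-network strengths

    W_X = mean of the n_X (n_X - 1) / 2 distinct z_ij with i, j in X

and 21 between-network strengths

    W_XY = mean of the n_X * n_Y cross entries z_ij, i in X, j in Y.

The weighted mean of all 28 strengths (weights = their pair counts)
recovers the global off-diagonal mean exactly, which the tests use as an
identity check.  Group comparison is a two-sided pooled-variance t-test
per measure with Benjamini-Hochberg FDR across all 28 simultaneously.

The default partition shipped with the package is a reconstruction of
the usual AAL-based seven-network grouping (the cerebellum's 26 regions
form their own network); studies with their own assignment should pass a
two-column (region, network) table instead.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

DEFAULT_NETWORKS = ("default-mode", "attention", "visual", "auditory",
                    "sensory-motor", "subcortical", "cerebellum")


@dataclass
class NetworkPartition:
    """Region -> network assignment over an ordered region list."""

    assignment: dict[str, str]
    networks: tuple[str, ...] = DEFAULT_NETWORKS

    def __post_init__(self):
        missing = {n for n in self.assignment.values()} - set(self.networks)
        if missing:
            raise ValueError(f"assignment uses unlisted networks: {sorted(missing)}")

    @property
    def regions(self) -> list[str]:
        return list(self.assignment)

    def members(self, network: str) -> list[str]:
        return [r for r, n in self.assignment.items() if n == network]

    def indices(self, region_order: list[str]) -> dict[str, np.ndarray]:
        """Network -> integer indices into ``region_order``."""
        unknown = [r for r in region_order if r not in self.assignment]
        if unknown:
            raise KeyError(f"regions not in partition: {unknown}")
        return {net: np.array([i for i, r in enumerate(region_order)
                               if self.assignment[r] == net], dtype=int)
                for net in self.networks}

    @classmethod
    def from_table(cls, path_or_df) -> "NetworkPartition":
        df = (path_or_df if isinstance(path_or_df, pd.DataFrame)
              else pd.read_csv(path_or_df, sep="\t"))
        assignment = dict(zip(df["region"], df["network"]))
        networks = tuple(dict.fromkeys(df["network"]))
        return cls(assignment, networks)


def default_partition() -> NetworkPartition:
    """The bundled AAL-116 seven-network reconstruction."""
    ref = importlib.resources.files("fconn.data") / "aal116_7networks.tsv"
    with importlib.resources.as_file(ref) as path:
        return NetworkPartition.from_table(path)


def within_strength(matrix: np.ndarray, idx: np.ndarray) -> float:
    """Mean of the distinct off-diagonal entries inside one network."""
    if idx.size < 2:
        raise ValueError("within-network strength needs >= 2 regions")
    block = np.asarray(matrix)[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(block[iu].mean())


def between_strength(matrix: np.ndarray, idx_x: np.ndarray,
                     idx_y: np.ndarray) -> float:
    """Mean of the n_X * n_Y cross entries; symmetric in (X, Y)."""
    if np.intersect1d(idx_x, idx_y).size:
        raise ValueError("networks overlap; use within_strength for X == X")
    if idx_x.size == 0 or idx_y.size == 0:
        raise ValueError("both networks must be nonempty")
    # canonical block orientation makes the symmetry in (X, Y) exact,
    # not merely up to summation order
    if idx_y[0] < idx_x[0]:
        idx_x, idx_y = idx_y, idx_x
    return float(np.asarray(matrix)[np.ix_(idx_x, idx_y)].mean())


def network_strengths(matrix: np.ndarray, partition: NetworkPartition,
                      region_order: list[str]) -> pd.Series:
    """All 7 within + 21 between strengths for one subject, indexed by
    'X' or 'X|Y' measure names in partition network order."""
    idx = partition.indices(region_order)
    nets = list(partition.networks)
    values = {}
    for net in nets:
        values[net] = within_strength(matrix, idx[net])
    for i, x in enumerate(nets):
        for y in nets[i + 1:]:
            values[f"{x}|{y}"] = between_strength(matrix, idx[x], idx[y])
    return pd.Series(values)


def strengths_table(matrices: np.ndarray, partition: NetworkPartition,
                    region_order: list[str],
                    subject_ids=None) -> pd.DataFrame:
    rows = [network_strengths(m, partition, region_order) for m in matrices]
    df = pd.DataFrame(rows)
    if subject_ids is not None:
        df.index = list(subject_ids)
    return df


def compare_network_strengths(matrices: np.ndarray, groups,
                              partition: NetworkPartition,
                              region_order: list[str],
                              patient_label=1, fdr_q: float = 0.05,
                              ) -> pd.DataFrame:
    """Two-sided pooled t-test per strength measure with BH-FDR across
    the 28-measure family.  Rows with degenerate (zero) variance in both
    groups are flagged and excluded from the FDR family."""
    groups = np.asarray(groups)
    table = strengths_table(matrices, partition, region_order)
    pat = table[groups == patient_label]
    ctl = table[groups != patient_label]
    t, p = stats.ttest_ind(pat, ctl, equal_var=True)
    out = pd.DataFrame({
        "measure": table.columns,
        "scope": ["within" if "|" not in m else "between" for m in table.columns],
        "mean_patient": pat.mean().to_numpy(),
        "mean_control": ctl.mean().to_numpy(),
        "t": t, "p": p,
    })
    ok = np.isfinite(out["p"].to_numpy())
    out["p_fdr"] = np.nan
    if ok.any():
        out.loc[ok, "p_fdr"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["significant"] = out["p_fdr"] < fdr_q
    return out


class NetworkStrengthComparison(BaseEstimator):
    """Group comparison of the 28 network-level strengths, sklearn style.

    ``fit(X, y)`` with X a (n_subjects, n_regions, n_regions) stack and y
    group labels fills ``strengths_`` (per-subject table) and
    ``results_`` (per-measure t / p / BH-adjusted p / significance).
    """

    def __init__(self, partition: NetworkPartition | None = None,
                 region_order: list[str] | None = None,
                 patient_label=1, fdr_q: float = 0.05):
        self.partition = partition
        self.region_order = region_order
        self.patient_label = patient_label
        self.fdr_q = fdr_q

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        part = self.partition or default_partition()
        order = self.region_order or part.regions
        if X.shape[1] != len(order):
            raise ValueError(f"matrices have {X.shape[1]} regions but the "
                             f"partition orders {len(order)}")
        self.strengths_ = strengths_table(X, part, order)
        self.results_ = compare_network_strengths(
            X, y, part, order, patient_label=self.patient_label,
            fdr_q=self.fdr_q)
        return self
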