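"""Synthetic two-group connectome studies with planted structure.

The generator emulates the statistical structure the analysis assumes:
two groups (33 patients vs 24 controls by default) of 116-region time
series, 243 retained frames at TR = 2 s, drawn frame-by-frame from a
multivariate Gaussian whose correlation matrix carries

* a positive within-network baseline (mean r = 0.3),
* a negative sensory-motor <-> auditory between-network baseline
  (r = -0.15) standing in for the anticorrelation seen in healthy
  resting-state data,
* per-group target correlations on a planted edge set — by default a
  connected 30-edge sensory-motor/auditory component whose control-group
  anticorrelation is flipped positive in patients,
* per-subject clinical covariates drawn around realistic demographic /
  glycaemic summaries, optionally coupled to the subject-level planted
  edge strength through ``clinical_effect``.

Arbitrary target overrides can break positive semi-definiteness, so the
implied correlation matrix is repaired by eigenvalue flooring (1e-6) and
rescaling to unit diagonal.  Frames are i.i.d. (white noise); no
haemodynamic or autocorrelated noise model is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .networks import NetworkPartition, default_partition
from .timeseries import RoiTimeSeries, pearson_connectivity

#: clinical covariate distributions: name -> (patient mean, sd), (control
#: mean, sd); loosely matched to a demographic table of an early-T2D cohort
CLINICAL_DISTRIBUTIONS = {
    "age": ((49.11, 9.68), (52.50, 9.66)),
    "education": ((13.03, 3.53), (11.88, 3.30)),
    "FPG": ((8.48, 3.22), (5.20, 0.40)),
    "2hPG": ((12.31, 5.37), (5.71, 1.06)),
    "HbA1c": ((7.30, 1.97), (5.60, 0.25)),
    "HOMA-IR": ((2.02, 1.30), (1.25, 0.76)),
    "MoCA": ((26.32, 2.42), (24.38, 3.99)),
}
FEMALE_PROPORTION = {"patient": 20 / 33, "control": 14 / 24}


@dataclass
class PlantedEdge:
    """One edge with per-group target correlations."""
    region_a: str
    region_b: str
    r_control: float
    r_patient: float


@dataclass
class SimulationConfig:
    n_patients: int = 33
    n_controls: int = 24
    n_frames: int = 243
    sampling_interval: float = 2.0
    partition: NetworkPartition | None = None
    within_r: float = 0.3
    anticorrelated_pairs: tuple = (("sensory-motor", "auditory"),)
    between_r: float = -0.15
    planted_edges: list[PlantedEdge] = field(default_factory=list)
    noise_sd: float = 0.0
    clinical_effect: float = 0.0   # z units per unit of clinical_variable
    clinical_variable: str = "FPG"
    seed: int = 0

    def resolved_partition(self) -> NetworkPartition:
        return self.partition or default_partition()


@dataclass
class Study:
    """A two-group study: series, connectivity, labels, covariates."""
    timeseries: list[RoiTimeSeries]
    matrices: np.ndarray                # (n_subjects, n_regions, n_regions)
    groups: np.ndarray                  # 1 = patient, 0 = control
    covariates: pd.DataFrame
    region_labels: list[str]
    config: SimulationConfig


def default_planted_component(partition: NetworkPartition | None = None,
                              n_edges: int = 30, r_control: float = -0.15,
                              r_patient: float = 0.15) -> list[PlantedEdge]:
    """A connected bipartite component between sensory-motor and auditory
    regions with sign-flipped correlation in patients."""
    part = partition or default_partition()
    sm = part.members("sensory-motor")
    aud = part.members("auditory")
    edges = []
    for i, a in enumerate(sm):
        for b in aud:
            edges.append(PlantedEdge(a, b, r_control, r_patient))
    if n_edges > len(edges):
        raise ValueError(f"at most {len(edges)} sensory-motor/auditory edges")
    return edges[:n_edges]


def effect_size_to_delta_z(d: float, n_frames: int) -> float:
    """Convert a per-edge Cohen's d (on subject-level Fisher z) to a
    group difference in z, using the large-sample z standard deviation
    1 / sqrt(n_frames - 3)."""
    return d / np.sqrt(n_frames - 3)


def build_correlation_matrix(config: SimulationConfig, group: str,
                             region_order: list[str],
                             planted_z_shift: float = 0.0) -> np.ndarray:
    """Target correlation matrix for one group (optionally with a
    per-subject shift, in z units, added to every planted edge)."""
    part = config.resolved_partition()
    idx = part.indices(region_order)
    n = len(region_order)
    C = np.full((n, n), 0.0)
    for net, ii in idx.items():
        C[np.ix_(ii, ii)] = config.within_r
    for x, y in config.anticorrelated_pairs:
        C[np.ix_(idx[x], idx[y])] = config.between_r
        C[np.ix_(idx[y], idx[x])] = config.between_r
    pos = {r: i for i, r in enumerate(region_order)}
    for e in config.planted_edges:
        r = e.r_patient if group == "patient" else e.r_control
        if planted_z_shift:
            r = np.tanh(np.arctanh(r) + planted_z_shift)
        C[pos[e.region_a], pos[e.region_b]] = r
        C[pos[e.region_b], pos[e.region_a]] = r
    np.fill_diagonal(C, 1.0)
    return repair_correlation(C)


def repair_correlation(C: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Nearest-ish PSD repair: floor eigenvalues, rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh(C)
    if vals.min() >= floor:
        return C
    vals = np.maximum(vals, floor)
    C = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(C))
    if np.any(d <= 0):
        raise ValueError("correlation repair failed: nonpositive diagonal")
    C = C / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return 0.5 * (C + C.T)


def _draw_covariates(rng: np.random.Generator, group: str, n: int,
                     ) -> pd.DataFrame:
    cols = {}
    means = {k: v[0] if group == "patient" else v[1]
             for k, v in CLINICAL_DISTRIBUTIONS.items()}
    for name, (mu, sd) in means.items():
        cols[name] = rng.normal(mu, sd, size=n)
    cols["sex"] = (rng.random(n) < FEMALE_PROPORTION[group]).astype(int)
    return pd.DataFrame(cols)


def generate_study(config: SimulationConfig) -> Study:
    """Draw a full two-group study, reproducibly from ``config.seed``.

    Connectivity matrices are the Fisher-z Pearson correlations of the
    generated series (the series are white, so no filtering or nuisance
    regression is required before correlation).
    """
    rng = np.random.default_rng(config.seed)
    region_order = config.resolved_partition().regions
    n_regions = len(region_order)
    series, matrices, groups, cov_frames = [], [], [], []
    mean_var = {g: CLINICAL_DISTRIBUTIONS[config.clinical_variable]
                [0 if g == "patient" else 1]
                for g in ("patient", "control")}
    base_chol: dict[str, np.ndarray] = {}
    for group, count, label in (("patient", config.n_patients, 1),
                                ("control", config.n_controls, 0)):
        covs = _draw_covariates(rng, group, count)
        cov_frames.append(covs)
        for s in range(count):
            shift = config.clinical_effect * (
                covs[config.clinical_variable].iloc[s] - mean_var[group][0])
            if shift == 0.0 and group in base_chol:
                L = base_chol[group]
            else:
                C = build_correlation_matrix(config, group, region_order,
                                             planted_z_shift=shift)
                L = np.linalg.cholesky(C + 1e-10 * np.eye(n_regions))
                if shift == 0.0:
                    base_chol[group] = L
            X = rng.standard_normal((config.n_frames, n_regions)) @ L.T
            if config.noise_sd:
                X = X + rng.normal(0.0, config.noise_sd, size=X.shape)
            ts = RoiTimeSeries(f"{group}-{s:03d}", X,
                               config.sampling_interval, region_order)
            series.append(ts)
            matrices.append(pearson_connectivity(ts))
            groups.append(label)
    covariates = pd.concat(cov_frames, ignore_index=True)
    covariates.insert(0, "subject_id", [t.subject_id for t in series])
    covariates["group"] = groups
    return Study(series, np.stack(matrices), np.asarray(groups), covariates,
                 region_order, config)


def generate_null_study(config: SimulationConfig) -> Study:
    """Both groups share one correlation structure (planted edges are
    given to both groups at the control target): the type-I / FWE
    calibration input."""
    null_edges = [PlantedEdge(e.region_a, e.region_b, e.r_control, e.r_control)
                  for e in config.planted_edges]
    null_config = SimulationConfig(**{**asdict(config),
                                      "partition": config.partition,
                                      "planted_edges": null_edges,
                                      "clinical_effect": 0.0})
    return generate_study(null_config)
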