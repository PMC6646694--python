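"""Calibration and recovery experiments for the NBS pipeline.

These are the package's self-checks, run on synthetic studies from
:mod:`fconn.simulate`:

* familywise error calibration of the full NBS pass on null studies;
* statistical power to detect a planted connected component;
* agreement of component sizes with an independent breadth-first-search
  oracle;
* the exact grand-mean decomposition identity of network strengths;
* coverage and type-I behaviour of the covariate-adjusted association;
* edge-pattern recovery on sign-flipped planted components.

Every experiment takes an explicit seed and returns plain dictionaries
of counts and rates.
"""

from __future__ import annotations

import numpy as np

from .clinical import adjusted_association
from .nbs import NetworkBasedStatistic, suprathreshold_components
from .networks import default_partition, network_strengths
from .patterns import PATHOLOGICAL_POSITIVE, classify_edge
from .simulate import (PlantedEdge, SimulationConfig,
                       default_planted_component, effect_size_to_delta_z,
                       generate_null_study, generate_study)


def planted_edges_with_effect(d: float, n_frames: int = 243,
                              baseline_r: float = -0.15,
                              n_edges: int = 30) -> list[PlantedEdge]:
    """The default sensory-motor/auditory component with patient-group
    correlations shifted off the negative baseline by ``d`` standard
    deviations of the subject-level Fisher z."""
    delta = effect_size_to_delta_z(d, n_frames)
    base = default_planted_component(n_edges=n_edges, r_control=baseline_r,
                                     r_patient=baseline_r)
    return [PlantedEdge(e.region_a, e.region_b, baseline_r,
                        float(np.tanh(np.arctanh(baseline_r) + delta)))
            for e in base]


def fwe_calibration(n_studies: int = 200, n_perm: int = 500,
                    threshold=("t", 3.0), alpha: float = 0.05,
                    n_patients: int = 33, n_controls: int = 24,
                    seed: int = 0) -> dict:
    """Familywise false-positive rate of a one-tailed NBS pass over
    synthetic null studies that keep the full baseline structure
    (within-network blocks, anticorrelated block, planted edges at their
    control value in both groups)."""
    rng = np.random.default_rng(seed)
    base = default_planted_component()
    rejections = 0
    for _ in range(n_studies):
        study_seed, nbs_seed = rng.integers(2 ** 31, size=2)
        study = generate_null_study(SimulationConfig(
            n_patients=n_patients, n_controls=n_controls,
            planted_edges=base, seed=int(study_seed)))
        model = NetworkBasedStatistic(threshold=threshold, n_perm=n_perm,
                                      tail="greater",
                                      random_state=int(nbs_seed))
        model.fit(study.matrices, study.groups)
        rejections += bool(model.significant_components(alpha))
    return {"rejections": rejections, "n_studies": n_studies,
            "rate": rejections / n_studies}


def planted_component_power(n_sims: int = 100, n_perm: int = 1000,
                            effect_d: float = 1.0, threshold=("t", 3.0),
                            alpha: float = 0.05, n_patients: int = 33,
                            n_controls: int = 24, seed: int = 0) -> dict:
    """Fraction of simulations in which some FWE-significant component
    overlaps the planted 30-edge component."""
    rng = np.random.default_rng(seed)
    planted = planted_edges_with_effect(effect_d)
    planted_set = {frozenset((e.region_a, e.region_b)) for e in planted}
    hits = 0
    for _ in range(n_sims):
        study_seed, nbs_seed = rng.integers(2 ** 31, size=2)
        study = generate_study(SimulationConfig(
            n_patients=n_patients, n_controls=n_controls,
            planted_edges=planted, seed=int(study_seed)))
        model = NetworkBasedStatistic(threshold=threshold, n_perm=n_perm,
                                      tail="greater",
                                      random_state=int(nbs_seed))
        model.fit(study.matrices, study.groups)
        order = study.region_labels
        for comp in model.significant_components(alpha):
            names = {frozenset((order[i], order[j])) for i, j in comp.edges}
            if names & planted_set:
                hits += 1
                break
    return {"hits": hits, "n_sims": n_sims, "rate": hits / n_sims}


def bfs_component_sizes(adjacency: np.ndarray) -> list[int]:
    """Edge counts of connected components by plain breadth-first search
    — deliberately independent of the sparse-graph implementation."""
    n = adjacency.shape[0]
    visited = np.zeros(n, dtype=bool)
    sizes = []
    for start in range(n):
        if visited[start] or not adjacency[start].any():
            continue
        queue = [start]
        visited[start] = True
        members = [start]
        while queue:
            u = queue.pop(0)
            for v in np.flatnonzero(adjacency[u]):
                if not visited[v]:
                    visited[v] = True
                    members.append(int(v))
                    queue.append(int(v))
        sub = adjacency[np.ix_(members, members)]
        sizes.append(int(sub.sum()) // 2)
    return [s for s in sizes if s > 0]


def component_oracle_agreement(n_graphs: int = 500, n_nodes: int = 20,
                               edge_p: float = 0.08, seed: int = 0) -> dict:
    """Compare component sizes from the thresholded-statistic extractor
    against the BFS oracle on random graphs."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_graphs):
        iu = np.triu_indices(n_nodes, 1)
        on = rng.random(iu[0].size) < edge_p
        t = np.zeros((n_nodes, n_nodes))
        t[iu[0][on], iu[1][on]] = 5.0
        t = t + t.T
        stat_map = {"t": t, "mask": ~np.eye(n_nodes, dtype=bool), "df": 20}
        comps = suprathreshold_components(stat_map, ("t", 3.0))
        if sorted(c.size for c in comps) == sorted(bfs_component_sizes(t > 3.0)):
            agree += 1
    return {"agreements": agree, "n_graphs": n_graphs,
            "rate": agree / n_graphs}


def strength_decomposition_error(n_matrices: int = 100, seed: int = 0) -> dict:
    """Maximum absolute error of the grand-mean identity: the pair-count
    weighted mean of the 28 network strengths equals the global
    off-diagonal mean."""
    rng = np.random.default_rng(seed)
    partition = default_partition()
    order = partition.regions
    idx = partition.indices(order)
    sizes = {net: len(ii) for net, ii in idx.items()}
    nets = list(partition.networks)
    worst = 0.0
    sym_gap = 0.0
    n = len(order)
    for _ in range(n_matrices):
        m = rng.standard_normal((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        s = network_strengths(m, partition, order)
        total = sum(s[net] * sizes[net] * (sizes[net] - 1) / 2 for net in nets)
        weight = sum(sizes[net] * (sizes[net] - 1) / 2 for net in nets)
        for i, x in enumerate(nets):
            for y in nets[i + 1:]:
                total += s[f"{x}|{y}"] * sizes[x] * sizes[y]
                weight += sizes[x] * sizes[y]
        iu = np.triu_indices(n, 1)
        worst = max(worst, abs(total / weight - m[iu].mean()))
        from .networks import between_strength
        x, y = idx[nets[0]], idx[nets[1]]
        sym_gap = max(sym_gap, abs(between_strength(m, x, y)
                                   - between_strength(m, y, x)))
    return {"max_abs_error": worst, "max_symmetry_gap": sym_gap,
            "n_matrices": n_matrices}


def association_recovery(n_sims: int = 1000, n: int = 33,
                         slope: float = 0.05, seed: int = 0) -> dict:
    """Coverage of the planted slope by the 95% CI, and the type-I rate
    at 0.05 under an independent (null) clinical variable."""
    rng = np.random.default_rng(seed)
    covered = 0
    type_one = 0
    for _ in range(n_sims):
        age = rng.normal(50, 9.7, n)
        sex = (rng.random(n) < 0.6).astype(float)
        education = rng.normal(13, 3.5, n)
        fpg = 8.5 + 0.15 * (age - 50) + rng.normal(0, 2.5, n)
        edge = 0.05 - 0.002 * (age - 50) + slope * fpg + rng.normal(0, 0.2, n)
        res = adjusted_association(edge, fpg, age, sex, education)
        lo, hi = res.confidence_interval(0.95)
        covered += lo <= slope <= hi
        null_var = rng.normal(8.5, 2.5, n)
        res0 = adjusted_association(rng.normal(0, 0.2, n), null_var, age,
                                    sex, education)
        type_one += res0.p < 0.05
    return {"coverage": covered / n_sims, "type_one_rate": type_one / n_sims,
            "n_sims": n_sims}


def pattern_recovery(n_sims: int = 20, n_perm: int = 300,
                     n_patients: int = 33, n_controls: int = 24,
                     seed: int = 0) -> dict:
    """On sign-flipped planted components, the fraction of detected
    planted edges labeled pathological-positive by the classifier."""
    rng = np.random.default_rng(seed)
    planted = default_planted_component()
    planted_set = {frozenset((e.region_a, e.region_b)) for e in planted}
    labeled, detected = 0, 0
    for _ in range(n_sims):
        study_seed, nbs_seed = rng.integers(2 ** 31, size=2)
        study = generate_study(SimulationConfig(
            n_patients=n_patients, n_controls=n_controls,
            planted_edges=planted, seed=int(study_seed)))
        model = NetworkBasedStatistic(n_perm=n_perm, tail="greater",
                                      random_state=int(nbs_seed))
        model.fit(study.matrices, study.groups)
        order = study.region_labels
        pat = study.groups == 1
        for comp in model.significant_components(0.05):
            for i, j in comp.edges:
                if frozenset((order[i], order[j])) not in planted_set:
                    continue
                detected += 1
                label = classify_edge(study.matrices[pat, i, j].mean(),
                                      study.matrices[~pat, i, j].mean())
                labeled += label == PATHOLOGICAL_POSITIVE
    return {"detected": detected, "pathological_positive": labeled,
            "rate": labeled / detected if detected else float("nan"),
            "n_sims": n_sims}
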