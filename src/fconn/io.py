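"""Readers, writers and full-pipeline orchestration.

File dialects
-------------
* time series: one TSV per subject, header row of region names, one row
  per frame; subject id = file stem;
* connectivity matrices: TSV with region names as header row and first
  column, full float precision (``repr`` round-trip);
* partition: two-column TSV (region, network);
* group/covariate table: TSV with ``subject_id``, ``group`` (1 = patient,
  0 = control) and numeric covariate columns.

``run_full_pipeline`` composes the stages in study order — preprocess ->
connectivity -> NBS -> edge patterns -> network level -> clinical
associations — writing each stage's tables atomically (to a temporary
directory renamed into place) with the config hash stamped on every
table, so a fixed seed yields byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import shutil
import tempfile
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import associate_edges
from .nbs import NetworkBasedStatistic
from .networks import NetworkPartition, NetworkStrengthComparison, default_partition
from .patterns import annotate_between_within, annotate_patterns, count_patterns
from .timeseries import ConnectivityTransformer, RoiTimeSeries

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run; round-trips losslessly
    through YAML/JSON and is echoed (with its hash) into the manifest."""

    series_dir: str = ""
    groups_file: str = ""
    partition_file: str = ""
    out_dir: str = "results"
    mask_alpha: float = 0.05
    threshold: str = "t=3"
    n_perm: int = 5000
    seed: int = 42
    tails: str = "both"
    discard_frames: int = 0
    low_hz: float = 0.01
    high_hz: float = 0.08
    filter_order: int = 4
    filter_ripple_db: float = 0.5
    sampling_interval: float = 2.0
    bandpass: bool = True
    clinical_variables: list[str] = field(
        default_factory=lambda: ["FPG", "2hPG", "HbA1c", "HOMA-IR", "MoCA"])

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def analysis_dict(self) -> dict:
        """The configuration that defines the analysis: everything except
        the output location, which is what the config hash covers and
        what result manifests echo (so bundles written to different
        directories can be compared byte for byte)."""
        return {k: v for k, v in asdict(self).items() if k != "out_dir"}

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.analysis_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_timeseries(path, sampling_interval: float = 2.0) -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    bad = df.columns[df.dtypes == object]
    if len(bad):
        col = bad[0]
        row = int(df[col].map(lambda v: not _is_number(v)).idxmax())
        raise ValueError(f"{path}: non-numeric cell at row {row + 2}, "
                         f"column {col!r}")
    return RoiTimeSeries(Path(path).stem, df.to_numpy(dtype=float),
                         sampling_interval, list(df.columns))


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def read_timeseries_dir(path, sampling_interval: float = 2.0,
                        ) -> list[RoiTimeSeries]:
    """Read every per-subject TSV in a directory, enforcing one region
    set across subjects (column order is realigned by name)."""
    files = sorted(Path(path).glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no .tsv series files in {path}")
    subjects = [read_timeseries(f, sampling_interval) for f in files]
    reference = subjects[0].region_labels
    for ts, f in zip(subjects, files):
        if ts.region_labels != reference:
            if sorted(ts.region_labels) != sorted(reference):
                raise ValueError(
                    f"region set of {f.name} differs from {files[0].name}")
            logger.warning("realigning shuffled columns of %s", f.name)
            order = [ts.region_labels.index(r) for r in reference]
            ts.data = ts.data[:, order]
            ts.region_labels = list(reference)
    return subjects


def write_timeseries(ts: RoiTimeSeries, path) -> None:
    pd.DataFrame(ts.data, columns=ts.region_labels).to_csv(
        path, sep="\t", index=False)


def write_matrix(matrix: np.ndarray, region_labels, path,
                 config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        pd.DataFrame(matrix, index=region_labels,
                     columns=region_labels).to_csv(fh, sep="\t",
                                                   float_format="%.17g")


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                     float_precision="round_trip")
    return df.to_numpy(dtype=float), list(df.columns)


def read_matrix_dir(path) -> tuple[np.ndarray, list[str], list[str]]:
    files = sorted(Path(path).glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no matrix files in {path}")
    mats, labels = zip(*(read_matrix(f) for f in files))
    for f, lab in zip(files, labels):
        if lab != labels[0]:
            raise ValueError(f"region labels of {f.name} differ from "
                             f"{files[0].name}")
    return np.stack(mats), list(labels[0]), [f.stem for f in files]


def write_table(df: pd.DataFrame, path, config_hash: str | None = None,
                index: bool = False) -> None:
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_groups(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "subject_id" not in df.columns or "group" not in df.columns:
        raise ValueError(f"{path}: need subject_id and group columns")
    return df


class _Stage:
    """Context manager: logs timing, prefixes errors with the stage name,
    and commits the stage directory atomically on success."""

    def __init__(self, name: str, out_dir: Path):
        self.name = name
        self.final = out_dir / name
        self.tmp = Path(tempfile.mkdtemp(prefix=f".{name}-", dir=out_dir))

    def __enter__(self) -> Path:
        self.t0 = time.perf_counter()
        return self.tmp

    def __exit__(self, exc_type, exc, tb):
        if exc_type is not None:
            shutil.rmtree(self.tmp, ignore_errors=True)
            raise RuntimeError(f"stage {self.name!r} failed: {exc}") from exc
        if self.final.exists():
            shutil.rmtree(self.final)
        os.replace(self.tmp, self.final)
        logger.info("stage %s finished in %.2f s", self.name,
                    time.perf_counter() - self.t0)
        return False


def run_full_pipeline(config: RunConfig, subjects=None, groups_table=None,
                      ) -> dict:
    """Run every stage and write the results bundle under
    ``config.out_dir``.  ``subjects`` / ``groups_table`` may be passed
    directly (e.g. from the simulator) instead of being read from the
    configured paths.  Deterministic given the seed."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash

    if subjects is None:
        subjects = read_timeseries_dir(config.series_dir,
                                       config.sampling_interval)
    if groups_table is None:
        groups_table = read_groups(config.groups_file)
    groups_table = groups_table.set_index("subject_id").loc[
        [ts.subject_id for ts in subjects]].reset_index()
    y = groups_table["group"].to_numpy()
    partition = (NetworkPartition.from_table(config.partition_file)
                 if config.partition_file else default_partition())
    region_order = subjects[0].region_labels

    with _Stage("connectivity", out_dir) as stage:
        transformer = ConnectivityTransformer(
            low_hz=config.low_hz, high_hz=config.high_hz,
            filter_order=config.filter_order,
            filter_ripple_db=config.filter_ripple_db,
            discard_frames=config.discard_frames,
            sampling_interval=config.sampling_interval,
            bandpass=config.bandpass)
        Z = transformer.fit_transform(subjects)
        for ts, mat in zip(subjects, Z):
            write_matrix(mat, region_order, stage / f"{ts.subject_id}.tsv",
                         config_hash=chash)

    with _Stage("nbs", out_dir) as stage:
        model = NetworkBasedStatistic(
            mask_alpha=config.mask_alpha, threshold=config.threshold,
            n_perm=config.n_perm, tail=config.tails,
            random_state=config.seed).fit(Z, y)
        edge_rows = []
        for ci, comp in enumerate(model.components_):
            for i, j in comp.edges:
                edge_rows.append({
                    "component": ci, "tail": comp.tail,
                    "region_a": region_order[i], "region_b": region_order[j],
                    "t": model.stat_map_["t"][i, j],
                    "mean_t2d": Z[y == 1][:, i, j].mean(),
                    "mean_control": Z[y == 0][:, i, j].mean(),
                    "p": (model.stat_map_["p_greater"]
                          if comp.tail == "greater"
                          else model.stat_map_["p_less"])[i, j],
                    "p_fwe_component": comp.p_fwe,
                })
        edges_df = pd.DataFrame(edge_rows, columns=[
            "component", "tail", "region_a", "region_b", "t", "mean_t2d",
            "mean_control", "p", "p_fwe_component"])
        write_table(edges_df, stage / "component_edges.tsv", chash)
        for tail, null in model.null_max_sizes_.items():
            np.savetxt(stage / f"null_max_sizes_{tail}.txt", null, fmt="%d")
        summary = {
            "components": [{"size": c.size, "tail": c.tail, "p_fwe": c.p_fwe}
                           for c in model.components_],
            "n_masked_edges": int(model.mask_.sum() // 2),
            "seed": config.seed, "config": config.analysis_dict(),
            "config_hash": chash, "version": __version__,
        }
        (stage / "summary.json").write_text(json.dumps(summary, indent=2))

    with _Stage("patterns", out_dir) as stage:
        if len(edges_df):
            significant = edges_df[edges_df["p_fwe_component"] < 0.05]
            annotated = annotate_patterns(significant)
            annotated = annotate_between_within(annotated, partition)
            counts = count_patterns(annotated)
        else:
            annotated = edges_df.copy()
            counts = count_patterns(pd.DataFrame(
                {"mean_t2d": [], "mean_control": []}))
        write_table(annotated, stage / "edge_patterns.tsv", chash)
        (stage / "pattern_counts.json").write_text(
            json.dumps({"counts": counts, "config_hash": chash}, indent=2))

    with _Stage("network_level", out_dir) as stage:
        comparison = NetworkStrengthComparison(
            partition=partition, region_order=region_order).fit(Z, y)
        write_table(comparison.results_, stage / "network_strengths.tsv", chash)

    with _Stage("clinical", out_dir) as stage:
        covs = groups_table[groups_table["group"] == 1].reset_index(drop=True)
        available = [v for v in config.clinical_variables if v in covs.columns]
        if available and len(edges_df) and {"age", "sex", "education"} <= set(covs.columns):
            sig = edges_df[edges_df["p_fwe_component"] < 0.05]
            edge_cols = {}
            for _, r in sig.iterrows():
                i = region_order.index(r["region_a"])
                j = region_order.index(r["region_b"])
                edge_cols[f"{r['region_a']}--{r['region_b']}"] = Z[y == 1][:, i, j]
            if edge_cols:
                assoc = associate_edges(pd.DataFrame(edge_cols), covs, available)
            else:
                assoc = pd.DataFrame()
        else:
            assoc = pd.DataFrame()
        write_table(assoc, stage / "associations.tsv", chash)

    manifest = {"config": config.analysis_dict(), "config_hash": chash,
                "version": __version__,
                "n_subjects": int(len(subjects)),
                "n_patients": int((y == 1).sum()),
                "n_controls": int((y == 0).sum())}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"edges": edges_df, "pattern_counts": counts,
            "network_level": comparison.results_, "associations": assoc,
            "manifest": manifest, "nbs_summary": summary}
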