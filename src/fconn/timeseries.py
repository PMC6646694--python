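"""ROI time-series preprocessing and Fisher-z connectivity.

The chain implemented here mirrors standard resting-state practice:
voxel-to-region averaging, Chebyshev band-pass filtering (0.01-0.08 Hz by
default), nuisance regression against mean white-matter / CSF / global
signals and motion parameters plus their first-order derivatives, and
finally Pearson correlation between region series with Fisher's r-to-z
transform.  All operations are pure functions of their inputs; the
:class:`ConnectivityTransformer` wraps the chain in a scikit-learn
transformer so it composes with pipelines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

#: correlation magnitude is clipped here before atanh so z stays finite
R_CLIP = 1.0 - 1e-7

#: head-motion exclusion thresholds used at acquisition time (mm, degrees);
#: kept as documented constants, not applied at this level
MAX_TRANSLATION_MM = 2.0
MAX_ROTATION_DEG = 2.0

#: frames discarded at scan start to avoid magnetic-saturation transients
DEFAULT_DISCARD_FRAMES = 10

MIN_FRAMES_FOR_CORRELATION = 10


@dataclass
class RoiTimeSeries:
    """Per-subject region time series.

    Parameters
    ----------
    subject_id : str
        Subject label.
    data : ndarray of shape (n_frames, n_regions)
        One column per region, arbitrary signal units.
    sampling_interval : float
        Seconds per frame (TR); 2.0 s for the reference acquisition.
    region_labels : list of str
        Ordered region names; shared by all subjects in a study.
    """

    subject_id: str
    data: np.ndarray
    sampling_interval: float = 2.0
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (frames x regions)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"subject {self.subject_id}: non-finite values in series")
        if self.region_labels and len(self.region_labels) != self.data.shape[1]:
            raise ValueError(
                f"subject {self.subject_id}: {len(self.region_labels)} labels "
                f"for {self.data.shape[1]} regions"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "RoiTimeSeries":
        return RoiTimeSeries(self.subject_id, data, self.sampling_interval,
                             list(self.region_labels))


def average_labeled_voxels(voxel_series: np.ndarray, labels, region_order=None,
                           subject_id: str = "", sampling_interval: float = 2.0,
                           ) -> RoiTimeSeries:
    """Average voxel time series within each labeled region.

    Parameters
    ----------
    voxel_series : ndarray (n_frames, n_voxels)
    labels : sequence of length n_voxels
        Region label per voxel.
    region_order : sequence of region labels, optional
        Output column order; defaults to sorted unique labels.  Every
        region listed must have at least one voxel.
    """
    voxel_series = np.asarray(voxel_series, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != voxel_series.shape[1]:
        raise ValueError("one label per voxel required")
    if region_order is None:
        region_order = sorted(np.unique(labels).tolist())
    cols = []
    for region in region_order:
        idx = np.flatnonzero(labels == region)
        if idx.size == 0:
            raise ValueError(f"region {region!r} has no voxels")
        cols.append(voxel_series[:, idx].mean(axis=1))
    return RoiTimeSeries(subject_id, np.column_stack(cols), sampling_interval,
                         [str(r) for r in region_order])


def build_confound_matrix(nuisance: np.ndarray) -> np.ndarray:
    """Append first-order derivatives (backward differences, zero-padded at
    the first frame) to a frames x k nuisance matrix."""
    nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
    if nuisance.shape[1] and nuisance.shape[0] == 1:
        nuisance = nuisance.T
    deriv = np.diff(nuisance, axis=0, prepend=nuisance[:1])
    deriv[0] = 0.0
    return np.hstack([nuisance, deriv])


def regress_confounds(ts: RoiTimeSeries, confounds: np.ndarray,
                      add_derivatives: bool = False) -> RoiTimeSeries:
    """OLS-residualise every region series against the confound matrix.

    An intercept column is always included, so residuals are additionally
    mean-centred.  Collinear confound columns are pruned (QR rank check)
    with a warning rather than raising, since motion parameters are often
    near-duplicated in short runs.

    Set ``add_derivatives=True`` to augment the confounds with first-order
    derivatives first (see :func:`build_confound_matrix`).
    """
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.size and confounds.shape[0] != ts.n_frames:
        raise ValueError(
            f"confound frames ({confounds.shape[0]}) != series frames ({ts.n_frames})"
        )
    if add_derivatives:
        confounds = build_confound_matrix(confounds)
    design = np.column_stack([np.ones(ts.n_frames), confounds]) if confounds.size \
        else np.ones((ts.n_frames, 1))
    # prune collinear columns: greedy QR-based selection keeps the earliest
    # independent ones (intercept always kept)
    q, r = np.linalg.qr(design)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r[0, 0]))
    if not np.all(keep):
        dropped = np.flatnonzero(~keep).tolist()
        warnings.warn(f"pruned collinear confound columns {dropped}")
        logger.warning("pruned collinear confound columns %s", dropped)
        design = design[:, keep]
    beta, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    return ts.with_data(ts.data - design @ beta)


def bandpass_chebyshev(ts: RoiTimeSeries, low_hz: float = 0.01,
                       high_hz: float = 0.08, order: int = 4,
                       ripple_db: float = 0.5) -> RoiTimeSeries:
    """Zero-phase Chebyshev type-I band-pass filter.

    The filter is applied forward and backward (``filtfilt``) so that no
    phase shift distorts inter-regional correlations; the effective
    magnitude response is the square of the single-pass response.
    """
    nyquist = 1.0 / (2.0 * ts.sampling_interval)
    if not 0.0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz ({high_hz}) must be below Nyquist ({nyquist})")
    sos = signal.cheby1(order, ripple_db, [low_hz, high_hz], btype="bandpass",
                        fs=1.0 / ts.sampling_interval, output="sos")
    filtered = signal.sosfiltfilt(sos, ts.data, axis=0)
    return ts.with_data(filtered)


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Variance-stabilising r-to-z transform, atanh with |r| clipped to
    keep degenerate (duplicate-series) correlations finite."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def pearson_connectivity(ts: RoiTimeSeries) -> np.ndarray:
    """Region x region Fisher-z connectivity matrix.

    Zero-variance regions get zero rows/columns with a warning; the
    diagonal is always zero (self-connectivity is not defined here).
    """
    if ts.n_frames < MIN_FRAMES_FOR_CORRELATION:
        raise ValueError(
            f"need >= {MIN_FRAMES_FOR_CORRELATION} frames, got {ts.n_frames}"
        )
    data = ts.data
    sd = data.std(axis=0)
    degenerate = np.flatnonzero(sd == 0.0)
    if degenerate.size:
        names = [ts.region_labels[i] if ts.region_labels else str(i)
                 for i in degenerate]
        warnings.warn(f"zero-variance regions set to 0: {names}")
        logger.warning("zero-variance regions set to 0: %s", names)
        data = data.copy()
        # give them unit noise-free placeholder variance; rows zeroed below
        data[:, degenerate] = np.arange(ts.n_frames)[:, None]
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(data, rowvar=False)
    z = fisher_z(r)
    z[degenerate, :] = 0.0
    z[:, degenerate] = 0.0
    np.fill_diagonal(z, 0.0)
    return 0.5 * (z + z.T)  # enforce exact symmetry


class ConnectivityTransformer(BaseEstimator, TransformerMixin):
    """Time series -> Fisher-z connectivity matrices, scikit-learn style.

    ``transform`` accepts a list of :class:`RoiTimeSeries` (or plain
    frames x regions arrays) and returns an array of shape
    (n_subjects, n_regions, n_regions).

    Parameters
    ----------
    low_hz, high_hz : float
        Band-pass edges; defaults 0.01 and 0.08 Hz.
    filter_order, filter_ripple_db : filter design of
        :func:`bandpass_chebyshev`.
    filter_before_regression : bool
        If True (default), filter first and regress confounds from the
        filtered series; if False, regress first.
    discard_frames : int
        Initial frames dropped before any processing (default 0: assume
        the caller already discarded the saturation frames).
    sampling_interval : float
        TR in seconds, used when plain arrays are passed.
    """

    def __init__(self, low_hz: float = 0.01, high_hz: float = 0.08,
                 filter_order: int = 4, filter_ripple_db: float = 0.5,
                 filter_before_regression: bool = True,
                 discard_frames: int = 0, sampling_interval: float = 2.0,
                 bandpass: bool = True, confound_derivatives: bool = True):
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.filter_order = filter_order
        self.filter_ripple_db = filter_ripple_db
        self.filter_before_regression = filter_before_regression
        self.discard_frames = discard_frames
        self.sampling_interval = sampling_interval
        self.bandpass = bandpass
        self.confound_derivatives = confound_derivatives

    def fit(self, X, y=None):
        self.n_features_in_ = len(X)
        return self

    def fit_transform(self, X, y=None, confounds=None):
        return self.fit(X, y).transform(X, confounds=confounds)

    def transform(self, X, confounds=None) -> np.ndarray:
        matrices = []
        for i, ts in enumerate(X):
            if not isinstance(ts, RoiTimeSeries):
                ts = RoiTimeSeries(str(i), np.asarray(ts),
                                   self.sampling_interval)
            conf = None if confounds is None else np.asarray(confounds[i], dtype=float)
            if self.discard_frames:
                ts = ts.with_data(ts.data[self.discard_frames:])
                if conf is not None:
                    conf = conf[self.discard_frames:]
            matrices.append(self._single(ts, conf))
        return np.stack(matrices)

    def _single(self, ts: RoiTimeSeries, conf) -> np.ndarray:
        steps = []
        if self.bandpass:
            steps.append(lambda t: bandpass_chebyshev(
                t, self.low_hz, self.high_hz, self.filter_order,
                self.filter_ripple_db))
        if conf is not None:
            steps.append(lambda t: regress_confounds(
                t, conf, add_derivatives=self.confound_derivatives))
        if not self.filter_before_regression:
            steps.reverse()
        for step in steps:
            ts = step(ts)
        return pearson_connectivity(ts)
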