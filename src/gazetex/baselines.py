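"""I-VT event segmentation and the three comparison matchers.

Besides the texture method, the comparative experiments use simplified
re-implementations of three classical eye-movement biometrics:

* **LVD** — local-velocity-direction histograms scored by a GMM universal
  background model with mean-only MAP adaptation (log-likelihood-ratio
  scores).
* **FDM** — duration-weighted fixation density maps compared with
  histogram intersection (SIM), Pearson correlation, or symmetrised KL
  divergence.
* **CEM** — an 11-number summary of fixation/saccade statistics,
  classified through the same LDA + SVM pipeline as the texture features
  (a deliberate simplification of the original weighted-comparison
  scheme, flagged as such in reports).

Events come from a velocity-threshold (I-VT) segmenter: samples whose
angular velocity stays below the threshold form fixations, the rest form
saccades.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.mixture import GaussianMixture

from .gaze_core import (GazeDataError, GazeRecording, ScreenGeometry,
                        pixels_to_degrees)

logger = logging.getLogger("gazetex")

#: Community-default I-VT parameters.
DEFAULT_VELOCITY_THRESHOLD_DEG_S = 30.0
DEFAULT_MIN_FIXATION_S = 0.060

KLD_EPS = 1e-12


@dataclass(frozen=True)
class FixationEvent:
    start_t: float
    end_t: float
    centroid_x: float
    centroid_y: float

    def __post_init__(self) -> None:
        if self.end_t <= self.start_t:
            raise ValueError("fixation must have positive duration")

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t


@dataclass(frozen=True)
class SaccadeEvent:
    start_t: float
    end_t: float
    amplitude_deg: float
    mean_velocity_deg_s: float
    peak_velocity_deg_s: float

    def __post_init__(self) -> None:
        if self.end_t <= self.start_t:
            raise ValueError("saccade must have positive duration")
        if self.peak_velocity_deg_s < self.mean_velocity_deg_s:
            raise ValueError("peak velocity must be >= mean velocity")

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t


def sample_velocities(rec: GazeRecording,
                      geometry: ScreenGeometry) -> np.ndarray:
    """Per-sample angular speed (deg/s) by central finite differences.

    Endpoints use one-sided differences.  Assumes the recording has been
    validity-filtered.
    """
    n = len(rec)
    if n < 2:
        raise GazeDataError("need at least 2 samples for velocities")
    x, y, t = rec.x, rec.y, rec.t

    def chord_deg(dist_px: np.ndarray) -> np.ndarray:
        span_mm = dist_px / geometry.px_per_mm
        return np.degrees(2.0 * np.arctan2(span_mm / 2.0,
                                           geometry.viewing_distance_mm))

    v = np.empty(n)
    # central differences over position, chord length in degrees
    dist_px = np.hypot(x[2:] - x[:-2], y[2:] - y[:-2])
    v[1:-1] = chord_deg(dist_px) / (t[2:] - t[:-2])
    v[0] = chord_deg(np.hypot(x[1] - x[0], y[1] - y[0])) / (t[1] - t[0])
    v[-1] = chord_deg(np.hypot(x[-1] - x[-2], y[-1] - y[-2])) / (t[-1] - t[-2])
    return v


def ivt_segment(rec: GazeRecording,
                velocity_threshold_deg_s: float = DEFAULT_VELOCITY_THRESHOLD_DEG_S,
                geometry: ScreenGeometry | None = None,
                min_fixation_s: float = DEFAULT_MIN_FIXATION_S,
                ) -> tuple[list[FixationEvent], list[SaccadeEvent]]:
    """Velocity-threshold segmentation into fixations and saccades.

    Fixation runs shorter than ``min_fixation_s`` are relabelled as
    saccade samples (merged into the surrounding saccade), so the two
    event classes always partition the samples.
    """
    geometry = geometry or ScreenGeometry()
    if rec.n_valid == 0:
        raise GazeDataError("recording has no valid samples")
    clean_mask = rec.valid
    from .gaze_core import filter_validity
    clean, _ = filter_validity(rec)
    if len(clean) < 2:
        raise GazeDataError("need at least 2 valid samples to segment")
    v = sample_velocities(clean, geometry)
    is_fix = v < velocity_threshold_deg_s

    # drop too-short fixation runs (relabel as saccade)
    for start, stop in _runs(is_fix, True):
        if clean.t[stop - 1] - clean.t[start] < min_fixation_s:
            is_fix[start:stop] = False

    fixations = []
    saccades = []
    for start, stop in _runs(is_fix, True):
        t0, t1 = float(clean.t[start]), float(clean.t[stop - 1])
        if t1 <= t0:
            t1 = t0 + 1.0 / clean.rate_hz
        fixations.append(FixationEvent(
            start_t=t0, end_t=t1,
            centroid_x=float(clean.x[start:stop].mean()),
            centroid_y=float(clean.y[start:stop].mean())))
    for start, stop in _runs(is_fix, False):
        t0, t1 = float(clean.t[start]), float(clean.t[stop - 1])
        if t1 <= t0:
            t1 = t0 + 1.0 / clean.rate_hz
        amp = pixels_to_degrees(geometry, float(np.hypot(
            clean.x[stop - 1] - clean.x[start],
            clean.y[stop - 1] - clean.y[start])))
        vv = v[start:stop]
        mean_v = float(max(vv.mean(), 1e-9))
        peak_v = float(max(vv.max(), mean_v))
        saccades.append(SaccadeEvent(start_t=t0, end_t=t1, amplitude_deg=amp,
                                     mean_velocity_deg_s=mean_v,
                                     peak_velocity_deg_s=peak_v))
    return fixations, saccades


def _runs(mask: np.ndarray, value: bool):
    """Yield (start, stop) index pairs of contiguous runs equal to value."""
    n = len(mask)
    i = 0
    while i < n:
        if mask[i] == value:
            j = i
            while j < n and mask[j] == value:
                j += 1
            yield i, j
            i = j
        else:
            i += 1


# ---------------------------------------------------------------------------
# LVD: local velocity direction histograms + GMM-UBM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LVDConfig:
    """Local-velocity-direction matcher parameters (27 bins, 16-Gaussian
    UBM, relevance factor 16)."""

    n_bins: int = 27
    n_gaussians: int = 16
    relevance_r: float = 16.0
    window_len_samples: int = 300
    window_hop: int = 30

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.n_gaussians < 1:
            raise ValueError("n_gaussians must be >= 1")
        if self.relevance_r < 0:
            raise ValueError("relevance_r must be non-negative")


def lvd_histograms(rec: GazeRecording, cfg: LVDConfig) -> np.ndarray:
    """Sliding-window direction histograms of sample-to-sample motion.

    Displacement directions (atan2, mapped to [0, 2 pi)) are binned into
    ``n_bins`` equal arcs per window; zero-displacement steps are
    skipped, windows with no nonzero displacement are dropped with a
    warning.  Each row sums to 1.
    """
    if cfg.window_len_samples > len(rec):
        raise GazeDataError("window longer than the recording")
    dx = np.diff(rec.x)
    dy = np.diff(rec.y)
    moving = (dx != 0) | (dy != 0)
    angles = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
    bins = np.minimum((angles / (2.0 * np.pi) * cfg.n_bins).astype(int),
                      cfg.n_bins - 1)
    hists = []
    n_dropped = 0
    for start in range(0, len(dx) - cfg.window_len_samples + 2,
                       cfg.window_hop):
        stop = min(start + cfg.window_len_samples - 1, len(dx))
        sel = slice(start, stop)
        m = moving[sel]
        if not m.any():
            n_dropped += 1
            continue
        h = np.bincount(bins[sel][m], minlength=cfg.n_bins).astype(float)
        hists.append(h / h.sum())
    if n_dropped:
        logger.warning("dropped %d all-zero-displacement windows", n_dropped)
    return np.asarray(hists).reshape(-1, cfg.n_bins)


def train_ubm(histograms: np.ndarray, cfg: LVDConfig, seed: int) -> GaussianMixture:
    """Fit the diagonal-covariance universal background model by EM."""
    histograms = np.asarray(histograms, float)
    if len(histograms) < cfg.n_gaussians * 10:
        raise GazeDataError(
            f"need at least {cfg.n_gaussians * 10} rows to train the UBM")
    gmm = GaussianMixture(n_components=cfg.n_gaussians,
                          covariance_type="diag", random_state=seed,
                          reg_covar=1e-6, max_iter=200, n_init=1)
    gmm.fit(histograms)
    return gmm


def map_adapt(ubm: GaussianMixture, subject_histograms: np.ndarray,
              relevance_r: float) -> GaussianMixture:
    """Mean-only MAP adaptation of the UBM to one subject's data.

    Component means move from the UBM mean toward the data's soft mean:
    ``m_k' = (n_k xbar_k + r m_k) / (n_k + r)`` with soft counts ``n_k``.
    Weights and covariances are kept from the UBM.
    """
    X = np.asarray(subject_histograms, float)
    resp = ubm.predict_proba(X)                     # (n, K)
    n_k = resp.sum(axis=0)                          # (K,)
    soft_sum = resp.T @ X                           # (K, d)
    with np.errstate(invalid="ignore", divide="ignore"):
        xbar = np.where(n_k[:, None] > 0, soft_sum / n_k[:, None],
                        ubm.means_)
    denom = n_k[:, None] + relevance_r
    if relevance_r == 0:
        new_means = np.where(n_k[:, None] > 0, xbar, ubm.means_)
    else:
        new_means = (n_k[:, None] * xbar + relevance_r * ubm.means_) / denom
    import copy

    adapted = copy.deepcopy(ubm)
    adapted.means_ = new_means
    return adapted


def lvd_score(subject_model: GaussianMixture, ubm: GaussianMixture,
              probe_histograms: np.ndarray) -> float:
    """Average log-likelihood ratio of the probe under subject vs UBM."""
    X = np.asarray(probe_histograms, float)
    if X.shape[1] != ubm.means_.shape[1]:
        raise ValueError("probe dimensionality does not match the models")
    return float(np.mean(subject_model.score_samples(X)
                         - ubm.score_samples(X)))


# ---------------------------------------------------------------------------
# FDM: fixation density maps
# ---------------------------------------------------------------------------

@dataclass
class FixationDensityMap:
    """Duration-weighted, smoothed spatial distribution of fixations."""

    weights: np.ndarray
    grid_size: int
    smoothing_sigma_px: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        if self.weights.shape != (self.grid_size, self.grid_size):
            raise ValueError("weights must be grid_size x grid_size")
        if np.any(self.weights < 0):
            raise ValueError("density weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("density must sum to 1")


def fdm_build(fixations: Sequence[FixationEvent], grid_size: int,
              smoothing_sigma_px: float,
              geometry: ScreenGeometry) -> FixationDensityMap:
    """Duration-weighted 2-D histogram of centroids, Gaussian smoothed.

    ``smoothing_sigma_px`` is expressed in *grid* cells of the map.
    """
    fixations = list(fixations)
    if not fixations:
        raise GazeDataError("need at least one fixation")
    total = sum(f.duration for f in fixations)
    if total <= 0:
        raise GazeDataError("zero total fixation duration")
    grid = np.zeros((grid_size, grid_size))
    for f in fixations:
        col = int(np.clip(f.centroid_x * grid_size / geometry.width_px,
                          0, grid_size - 1))
        row = int(np.clip(f.centroid_y * grid_size / geometry.height_px,
                          0, grid_size - 1))
        grid[row, col] += f.duration
    if smoothing_sigma_px > 0:
        grid = gaussian_filter(grid, smoothing_sigma_px)
    grid /= grid.sum()
    return FixationDensityMap(weights=grid, grid_size=grid_size,
                              smoothing_sigma_px=smoothing_sigma_px)


def fdm_similarity(p: FixationDensityMap, q: FixationDensityMap,
                   metric: Literal["SIM", "PCC", "KLD"] = "SIM") -> float:
    """Similarity of two density maps; larger always means more similar.

    SIM is the histogram intersection ``sum(min(p, q))`` in [0, 1]; PCC
    the Pearson correlation of the flattened cells; KLD the symmetrised
    Kullback-Leibler divergence with an epsilon floor, negated.
    """
    if p.grid_size != q.grid_size:
        raise ValueError("density maps live on different grids")
    a = p.weights.ravel()
    b = q.weights.ravel()
    if metric == "SIM":
        return float(np.minimum(a, b).sum())
    if metric == "PCC":
        return float(np.corrcoef(a, b)[0, 1])
    if metric == "KLD":
        a = np.maximum(a, KLD_EPS)
        b = np.maximum(b, KLD_EPS)
        kl_ab = float(np.sum(a * np.log(a / b)))
        kl_ba = float(np.sum(b * np.log(b / a)))
        return -0.5 * (kl_ab + kl_ba)
    raise ValueError(f"unknown metric {metric!r}")


def group_recording_probes(recs_by_subject: dict[str, list[GazeRecording]],
                           NoET: int, n_probes: int, seed: int
                           ) -> list[tuple[str, list[GazeRecording]]]:
    """Recording-level probes: NoET distinct recordings per probe.

    The recording-level analogue of feature-vector probe assembly, for
    matchers (LVD, FDM) that pool raw data rather than average feature
    vectors.
    """
    rng = np.random.default_rng(seed)
    probes = []
    for subject in sorted(recs_by_subject):
        pool = recs_by_subject[subject]
        if len(pool) < NoET:
            raise GazeDataError(
                f"subject {subject} has {len(pool)} recordings; "
                f"NoET={NoET} needs more")
        for _ in range(n_probes):
            idx = rng.choice(len(pool), size=NoET, replace=False)
            probes.append((subject, [pool[i] for i in idx]))
    return probes


def lvd_score_matrix(train: dict[str, list[GazeRecording]],
                     test_probes: list[tuple[str, list[GazeRecording]]],
                     cfg: LVDConfig, seed: int
                     ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Full LVD experiment: UBM + per-subject MAP models + LLR scores.

    The UBM is trained on all subjects' training histograms pooled;
    each subject's model is mean-only MAP adaptation of the UBM to
    their own training histograms; each probe pools the histograms of
    its NoET recordings and scores every subject by the mean
    log-likelihood ratio.  Returns (scores, genuine mask, subjects).
    """
    subjects = sorted(train)
    per_subject = {s: np.vstack([lvd_histograms(r, cfg) for r in train[s]])
                   for s in subjects}
    ubm = train_ubm(np.vstack(list(per_subject.values())), cfg, seed=seed)
    models = {s: map_adapt(ubm, per_subject[s], cfg.relevance_r)
              for s in subjects}
    scores = np.empty((len(test_probes), len(subjects)))
    genuine = np.zeros_like(scores, dtype=bool)
    for i, (owner, recs) in enumerate(test_probes):
        hists = np.vstack([lvd_histograms(r, cfg) for r in recs])
        for j, s in enumerate(subjects):
            scores[i, j] = lvd_score(models[s], ubm, hists)
            genuine[i, j] = owner == s
    return scores, genuine, subjects


def fdm_score_matrix(train: dict[str, list[GazeRecording]],
                     test_probes: list[tuple[str, list[GazeRecording]]],
                     geometry: ScreenGeometry, grid_size: int = 64,
                     smoothing_sigma_px: float = 1.0,
                     metric: Literal["SIM", "PCC", "KLD"] = "SIM",
                     velocity_threshold_deg_s: float = DEFAULT_VELOCITY_THRESHOLD_DEG_S,
                     ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Full FDM experiment: enrolment maps vs probe maps.

    Each subject's enrolment density map pools the fixations of all
    their training recordings; each probe's map pools its NoET
    recordings; entries are map similarities (SIM by default).
    """
    subjects = sorted(train)

    def fixations_of(recs):
        out = []
        for r in recs:
            fixes, _ = ivt_segment(r, velocity_threshold_deg_s, geometry)
            out.extend(fixes)
        return out

    enrolled = {
        s: fdm_build(fixations_of(train[s]), grid_size, smoothing_sigma_px,
                     geometry)
        for s in subjects
    }
    scores = np.empty((len(test_probes), len(subjects)))
    genuine = np.zeros_like(scores, dtype=bool)
    for i, (owner, recs) in enumerate(test_probes):
        probe_map = fdm_build(fixations_of(recs), grid_size,
                              smoothing_sigma_px, geometry)
        for j, s in enumerate(subjects):
            scores[i, j] = fdm_similarity(probe_map, enrolled[s], metric)
            genuine[i, j] = owner == s
    return scores, genuine, subjects


# ---------------------------------------------------------------------------
# CEM: fixation/saccade summary features
# ---------------------------------------------------------------------------

@dataclass
class CEMFeatureVector:
    """11 scalar fixation/saccade statistics (+ empty-class flags)."""

    fixation_count: float
    mean_fixation_duration: float
    std_fixation_duration: float
    mean_saccade_amplitude: float
    std_saccade_amplitude: float
    mean_saccade_duration: float
    std_saccade_duration: float
    mean_saccade_mean_velocity: float
    std_saccade_mean_velocity: float
    mean_saccade_peak_velocity: float
    std_saccade_peak_velocity: float
    no_fixations: bool = False
    no_saccades: bool = False

    def to_array(self) -> np.ndarray:
        return np.array([
            self.fixation_count,
            self.mean_fixation_duration, self.std_fixation_duration,
            self.mean_saccade_amplitude, self.std_saccade_amplitude,
            self.mean_saccade_duration, self.std_saccade_duration,
            self.mean_saccade_mean_velocity, self.std_saccade_mean_velocity,
            self.mean_saccade_peak_velocity, self.std_saccade_peak_velocity,
        ])


def _mean_std(values: list[float]) -> tuple[float, float]:
    if not values:
        return 0.0, 0.0
    arr = np.asarray(values, float)
    return float(arr.mean()), float(arr.std())


def cem_features(fixations: Sequence[FixationEvent],
                 saccades: Sequence[SaccadeEvent]) -> CEMFeatureVector:
    """Summarise event lists into the 11-number CEM descriptor.

    An empty event class yields zero features and sets the matching
    flag; a single-member class has std 0.
    """
    fd_mean, fd_std = _mean_std([f.duration for f in fixations])
    sa_mean, sa_std = _mean_std([s.amplitude_deg for s in saccades])
    sd_mean, sd_std = _mean_std([s.duration for s in saccades])
    sv_mean, sv_std = _mean_std([s.mean_velocity_deg_s for s in saccades])
    sp_mean, sp_std = _mean_std([s.peak_velocity_deg_s for s in saccades])
    return CEMFeatureVector(
        fixation_count=float(len(fixations)),
        mean_fixation_duration=fd_mean, std_fixation_duration=fd_std,
        mean_saccade_amplitude=sa_mean, std_saccade_amplitude=sa_std,
        mean_saccade_duration=sd_mean, std_saccade_duration=sd_std,
        mean_saccade_mean_velocity=sv_mean, std_saccade_mean_velocity=sv_std,
        mean_saccade_peak_velocity=sp_mean, std_saccade_peak_velocity=sp_std,
        no_fixations=not fixations, no_saccades=not saccades,
    )
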