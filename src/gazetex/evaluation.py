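"""Biometric evaluation: DET/EER, CMC, score normalization and fusion,
and the aging / robustness experiment drivers.

Verification is summarised by the equal error rate (EER), the operating
point where the false positive rate (impostors accepted) equals the
false negative rate (genuine users rejected), read off the DET curve by
linear interpolation.  Identification is summarised by the cumulative
match characteristic (CMC): rank-k identification rate is the fraction
of probes whose genuine subject scores within the top k.

Score-level fusion first maps each matcher's raw scores through the
tanh normalization ``s' = tanh(0.01 (s - mu) / sigma) + 1`` (mu, sigma
estimated from that matcher's training-phase score pool) and then sums
the normalized matrices entrywise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd


@dataclass
class ScoreMatrix:
    """Match scores of test probes (rows) against enrolled subjects
    (columns) with a one-per-row genuine mask."""

    scores: np.ndarray
    genuine: np.ndarray
    subjects: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float)
        self.genuine = np.asarray(self.genuine, bool)
        if self.scores.shape != self.genuine.shape:
            raise ValueError("scores and genuine mask must share a shape")
        if not np.all(self.genuine.sum(axis=1) == 1):
            raise ValueError("each row must have exactly one genuine entry")

    @property
    def genuine_scores(self) -> np.ndarray:
        return self.scores[self.genuine]

    @property
    def impostor_scores(self) -> np.ndarray:
        return self.scores[~self.genuine]


@dataclass
class DETCurve:
    """(FPR, FNR) trade-off over all decision thresholds, plus the EER."""

    thresholds: np.ndarray
    fpr: np.ndarray
    fnr: np.ndarray
    eer: float


@dataclass
class CMCCurve:
    """Rank-k identification rates, k = 1..K (closed set)."""

    rates: np.ndarray

    @property
    def rank1(self) -> float:
        return float(self.rates[0])


@dataclass(frozen=True)
class NormalizationParams:
    """Location/scale of a matcher's raw scores for tanh normalization."""

    mu: float
    sigma: float
    c: float = 0.01

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


# ---------------------------------------------------------------------------
# Verification metrics
# ---------------------------------------------------------------------------

def compute_det(scores: ScoreMatrix | None = None, *,
                genuine: np.ndarray | None = None,
                impostor: np.ndarray | None = None) -> DETCurve:
    """DET curve and EER from labelled scores (larger = more genuine).

    Accepts either a :class:`ScoreMatrix` or explicit genuine/impostor
    arrays.  The threshold sweep runs over the pooled score set (ties
    grouped at one threshold); the EER interpolates linearly between the
    bracketing thresholds where FPR - FNR changes sign.
    """
    if scores is not None:
        genuine = scores.genuine_scores
        impostor = scores.impostor_scores
    genuine = np.asarray(genuine, float)
    impostor = np.asarray(impostor, float)
    if genuine.size == 0 or impostor.size == 0:
        raise ValueError("need at least one genuine and one impostor score")

    thresholds = np.unique(np.concatenate([genuine, impostor]))
    # accept iff score >= threshold; add a top threshold rejecting all
    thresholds = np.append(thresholds, thresholds[-1] + 1.0)
    fpr = np.array([(impostor >= th).mean() for th in thresholds])
    fnr = np.array([(genuine < th).mean() for th in thresholds])

    diff = fpr - fnr  # non-increasing minus non-decreasing: monotone down
    idx = int(np.argmax(diff <= 0))
    if diff[idx] == 0 or idx == 0:
        eer = (fpr[idx] + fnr[idx]) / 2.0
    else:
        # linear interpolation between bracketing thresholds
        d0, d1 = diff[idx - 1], diff[idx]
        w = d0 / (d0 - d1)
        eer = float((1 - w) * (fpr[idx - 1] + fnr[idx - 1]) / 2
                    + w * (fpr[idx] + fnr[idx]) / 2)
    return DETCurve(thresholds=thresholds, fpr=fpr, fnr=fnr, eer=float(eer))


# ---------------------------------------------------------------------------
# Identification metrics
# ---------------------------------------------------------------------------

def compute_cmc(scores: ScoreMatrix,
                tie_policy: Literal["optimistic", "pessimistic"] = "optimistic"
                ) -> CMCCurve:
    """CMC curve from a closed-set score matrix.

    The genuine rank is 1 + the number of strictly greater scores in the
    row (optimistic ties) or 1 + the number of greater-or-equal scores
    among the impostors (pessimistic).
    """
    S = scores.scores
    g = S[scores.genuine][:, None]  # (n_rows, 1)
    if tie_policy == "optimistic":
        ranks = 1 + (S > g).sum(axis=1)
    elif tie_policy == "pessimistic":
        ranks = 1 + ((S >= g).sum(axis=1) - 1)  # exclude the genuine itself
    else:
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    K = S.shape[1]
    rates = np.array([(ranks <= k).mean() for k in range(1, K + 1)])
    return CMCCurve(rates=rates)


# ---------------------------------------------------------------------------
# Normalization and fusion
# ---------------------------------------------------------------------------

def fit_normalization(training_scores: np.ndarray,
                      c: float = 0.01) -> NormalizationParams:
    """Estimate mu/sigma from a matcher's training-phase score pool."""
    arr = np.asarray(training_scores, float).ravel()
    sigma = float(arr.std())
    if sigma <= 0:
        raise ValueError("training scores have zero spread")
    return NormalizationParams(mu=float(arr.mean()), sigma=sigma, c=c)


def tanh_normalize(s, params: NormalizationParams):
    """``s' = tanh(c (s - mu) / sigma) + 1`` — strictly increasing, in (0, 2)."""
    return np.tanh(params.c * (np.asarray(s, float) - params.mu)
                   / params.sigma) + 1.0


def fuse_sum(matrices: Sequence[ScoreMatrix],
             params: Sequence[NormalizationParams]) -> ScoreMatrix:
    """Sum-rule fusion of tanh-normalized score matrices.

    All matrices must be aligned (same shape and genuine mask); the
    output keeps the shared mask.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("nothing to fuse")
    if len(params) != len(matrices):
        raise ValueError("one NormalizationParams per matrix required")
    ref = matrices[0]
    for m in matrices[1:]:
        if m.scores.shape != ref.scores.shape or not np.array_equal(
                m.genuine, ref.genuine):
            raise ValueError("score matrices are not aligned")
    fused = np.zeros_like(ref.scores)
    for m, p in zip(matrices, params):
        fused += tanh_normalize(m.scores, p)
    return ScoreMatrix(scores=fused, genuine=ref.genuine.copy(),
                       subjects=ref.subjects)


# ---------------------------------------------------------------------------
# Report arithmetic
# ---------------------------------------------------------------------------

def relative_change_report(baseline, comparison,
                           kind: Literal["increase", "loss"] = "loss"):
    """Percent change between aligned result columns, 2-decimal rounded.

    ``loss``: 100 (baseline - comparison) / baseline (e.g. Rank-1 drop
    from the short-term to the long-term dataset); ``increase``:
    100 (comparison - baseline) / baseline.  A zero baseline yields NaN.
    """
    b = np.asarray(baseline, float)
    c = np.asarray(comparison, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if kind == "loss":
            out = 100.0 * (b - c) / b
        elif kind == "increase":
            out = 100.0 * (c - b) / b
        else:
            raise ValueError(f"unknown kind {kind!r}")
        out = np.where(b == 0, np.nan, out)
    return np.round(out, 2)


# ---------------------------------------------------------------------------
# Experiment drivers
# ---------------------------------------------------------------------------

def _split_st(question_ids: np.ndarray, train_frac: float,
              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(len(question_ids))
    n_train = int(round(train_frac * len(question_ids)))
    return question_ids[perm[:n_train]], question_ids[perm[n_train:]]


def evaluate_features(features: pd.DataFrame, NoET: int, seed: int,
                      dataset: Literal["ST", "LT"] = "ST",
                      n_train_probes: int = 20, n_test_probes: int = 6,
                      train_frac: float = 0.7, svm_kernel: str = "linear",
                      return_matrices: bool = False):
    """One train/test evaluation of a feature table.

    ``features`` is a tidy frame with columns ``subject``, ``trial``,
    ``question`` and feature columns ``f0..fd``.  The short-term (ST)
    protocol splits trial-1 recordings 70/30 per subject; the long-term
    (LT) protocol trains on trial 1 and tests on trial 2.  Probes are
    assembled per subject (means of NoET vectors), features are z-scored
    and LDA-projected, and the one-vs-one SVM score matrix yields EER
    and Rank-1.
    """
    from . import recognition as rec

    rng = np.random.default_rng(seed)
    feat_cols = [c for c in features.columns
                 if c not in ("subject", "trial", "question")]
    train_feats: dict[str, np.ndarray] = {}
    test_feats: dict[str, np.ndarray] = {}
    for subject, group in features.groupby("subject", sort=True):
        t1 = group[group["trial"] == 1]
        if dataset == "ST":
            qids = t1["question"].to_numpy()
            tr, te = _split_st(qids, train_frac, rng)
            train_feats[subject] = t1[t1["question"].isin(tr)][feat_cols].to_numpy()
            test_feats[subject] = t1[t1["question"].isin(te)][feat_cols].to_numpy()
        elif dataset == "LT":
            t2 = group[group["trial"] == 2]
            if not len(t2):
                raise ValueError("LT protocol requires trial-2 recordings")
            train_feats[subject] = t1[feat_cols].to_numpy()
            test_feats[subject] = t2[feat_cols].to_numpy()
        else:
            raise ValueError(f"unknown dataset {dataset!r}")

    train_probes = rec.assemble_probes(train_feats, NoET, n_train_probes,
                                       seed=int(rng.integers(2 ** 31)))
    test_probes = rec.assemble_probes(test_feats, NoET, n_test_probes,
                                      seed=int(rng.integers(2 ** 31)))
    X = np.vstack([p.vector for p in train_probes])
    y = [p.subject_id for p in train_probes]
    reduction = rec.fit_reduction(X, y)
    matcher = rec.fit_matchers(train_probes, reduction, kernel=svm_kernel)
    S, mask, subjects = rec.score_matrix(matcher, test_probes)
    matrix = ScoreMatrix(scores=S, genuine=mask, subjects=tuple(subjects))

    train_S, train_mask, _ = rec.score_matrix(matcher, train_probes)
    det = compute_det(matrix)
    cmc = compute_cmc(matrix)
    result = {"eer": det.eer, "rank1": cmc.rank1,
              "intrinsic_dim": reduction.intrinsic_dim,
              "n_components": reduction.n_components}
    if return_matrices:
        result["matrix"] = matrix
        result["norm_params"] = fit_normalization(train_S)
        result["cmc"] = cmc
        result["det"] = det
    return result


def run_aging_experiment(feature_tables: dict[str, pd.DataFrame],
                         NoET_grid: Sequence[int] = (2, 4, 8, 16),
                         n_partitions: int = 10, seed: int = 0,
                         datasets: Sequence[str] = ("ST", "LT"),
                         **eval_kwargs) -> pd.DataFrame:
    """EER / Rank-1 per method x NoET x dataset, averaged over random
    partitions, with LT - ST difference (DIF) columns when both
    protocols are run."""
    ss = np.random.SeedSequence(seed)
    rows = []
    for method, table in feature_tables.items():
        for NoET in NoET_grid:
            agg = {ds: {"eer": [], "rank1": []} for ds in datasets}
            for child in ss.spawn(n_partitions):
                s = int(child.generate_state(1)[0] % (2 ** 31))
                for ds in datasets:
                    res = evaluate_features(table, NoET, seed=s, dataset=ds,
                                            **eval_kwargs)
                    agg[ds]["eer"].append(res["eer"])
                    agg[ds]["rank1"].append(res["rank1"])
            row = {"method": method, "NoET": NoET}
            for ds in datasets:
                row[f"eer_{ds.lower()}"] = float(np.mean(agg[ds]["eer"]))
                row[f"rank1_{ds.lower()}"] = float(np.mean(agg[ds]["rank1"]))
            if {"ST", "LT"} <= set(datasets):
                row["eer_dif"] = row["eer_lt"] - row["eer_st"]
                row["rank1_dif"] = row["rank1_lt"] - row["rank1_st"]
            rows.append(row)
    return pd.DataFrame(rows)


def run_robustness_experiment(recordings, geometry, featurizer,
                              NoET: int = 8,
                              temporal_grid: Sequence[float] = (300, 150, 75, 30),
                              spatial_grid_deg: Sequence[float] = (0, 1, 2, 3),
                              n_partitions: int = 3, seed: int = 0,
                              **eval_kwargs) -> pd.DataFrame:
    """Re-extract features from degraded gaze and re-evaluate.

    ``featurizer(recordings) -> tidy feature DataFrame`` is applied to
    each degraded copy of the 300 Hz source recordings: one condition
    per temporal rate (pure decimation) and per spatial noise level
    (Gaussian, in visual degrees).  Returns EER / Rank-1 per condition.
    """
    from .gaze_core import add_spatial_noise, downsample

    src_rate = recordings[0].rate_hz
    rows = []
    conditions = ([("temporal", hz) for hz in temporal_grid]
                  + [("spatial", deg) for deg in spatial_grid_deg if deg > 0])
    ss = np.random.SeedSequence(seed)
    for kind, level in conditions:
        if kind == "temporal":
            if src_rate % level:
                raise ValueError(f"{level} Hz does not divide {src_rate} Hz")
            degraded = [downsample(r, level) for r in recordings]
        else:
            noise_seeds = ss.spawn(1)[0].generate_state(len(recordings))
            degraded = [add_spatial_noise(r, level, geometry,
                                          seed=int(s % (2 ** 31)))
                        for r, s in zip(recordings, noise_seeds)]
        table = featurizer(degraded)
        eers, r1s = [], []
        for child in ss.spawn(n_partitions):
            s = int(child.generate_state(1)[0] % (2 ** 31))
            res = evaluate_features(table, NoET, seed=s, dataset="ST",
                                    **eval_kwargs)
            eers.append(res["eer"]); r1s.append(res["rank1"])
        rows.append({"condition": kind, "level": level,
                     "eer": float(np.mean(eers)),
                     "rank1": float(np.mean(r1s)), "NoET": NoET,
                     "seed": seed})
    return pd.DataFrame(rows)
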