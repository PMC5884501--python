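"""Probe assembly, dimensionality reduction, and SVM verification /
identification.

A *probe* is the arithmetic mean of NoET single-trajectory feature
vectors of one subject; averaging shrinks within-subject feature
variance (Var of a mean of n samples is sigma^2/n), which is why the
matcher improves with NoET.  Features are z-scored, the intrinsic
dimension is estimated with the Levina-Bickel maximum-likelihood
estimator, and linear discriminant analysis projects to
min(d_hat, k - 1) dimensions.  Matching uses one-vs-one linear SVMs:
k(k-1)/2 pairwise classifiers for identification (vote counting), and
for verification the k-1 classifiers involving the claimed subject,
scored by their mean signed margin oriented toward the claim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


@dataclass
class Probe:
    """Mean of NoET feature vectors of one subject."""

    subject_id: str
    vector: np.ndarray
    NoET: int
    member_ids: tuple = ()

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, float)
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValueError("member_ids must be distinct within a probe")


def assemble_probes(features: dict[str, np.ndarray], NoET: int,
                    n_probes: int, seed: int) -> list[Probe]:
    """Build per-subject probes by within-probe sampling w/o replacement.

    ``features`` maps subject id to an (n_i, d) matrix of per-trajectory
    feature vectors.  For each subject, ``n_probes`` probes are drawn;
    within a probe the NoET constituent vectors are distinct (a fresh
    shuffle per probe, so different probes of one subject may overlap).
    """
    if NoET < 1 or n_probes < 1:
        raise ValueError("NoET and n_probes must be positive")
    rng = np.random.default_rng(seed)
    probes: list[Probe] = []
    for subject in sorted(features):
        X = np.asarray(features[subject], float)
        if len(X) < NoET:
            raise ValueError(
                f"subject {subject} has {len(X)} vectors; NoET={NoET} needs more")
        for _ in range(n_probes):
            idx = rng.choice(len(X), size=NoET, replace=False)
            probes.append(Probe(subject_id=subject,
                                vector=X[idx].mean(axis=0), NoET=NoET,
                                member_ids=tuple(int(i) for i in idx)))
    return probes


# ---------------------------------------------------------------------------
# Intrinsic dimension (Levina-Bickel MLE)
# ---------------------------------------------------------------------------

def estimate_intrinsic_dim(X: np.ndarray, k_min: int = 6,
                           k_max: int = 12) -> float:
    """Maximum-likelihood intrinsic dimension, averaged over k_min..k_max.

    For each point, the local estimate at neighbourhood size k is the
    inverse mean log distance ratio to the k-th neighbour; estimates are
    averaged over points and then over k.  Duplicate points (zero
    distances) are jittered by a tiny epsilon with a warning.
    """
    X = np.asarray(X, float)
    n = len(X)
    if n < k_max + 2:
        raise ValueError(f"need at least {k_max + 2} rows, got {n}")
    nn = NearestNeighbors(n_neighbors=k_max + 1).fit(X)
    dist, _ = nn.kneighbors(X)
    dist = dist[:, 1:]  # drop self-distance
    if np.any(dist <= 0):
        eps = max(1e-12, 1e-9 * float(dist.max()))
        warnings.warn("duplicate rows detected; jittering zero distances")
        dist = np.maximum(dist, eps)
    log_d = np.log(dist)
    estimates = []
    for k in range(k_min, k_max + 1):
        # mean over j<k of log(T_k / T_j), inverted
        inv = (log_d[:, k - 1][:, None] - log_d[:, :k - 1]).mean(axis=1)
        estimates.append(np.mean(1.0 / np.maximum(inv, 1e-12)))
    return float(np.mean(estimates))


# ---------------------------------------------------------------------------
# Reduction: standardization + LDA
# ---------------------------------------------------------------------------

@dataclass
class ReductionModel:
    """Fitted z-scoring + LDA projection to at most k-1 dimensions."""

    scaler: StandardScaler | None
    lda: LinearDiscriminantAnalysis
    intrinsic_dim: float
    n_components: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return self.lda.transform(X)


def fit_reduction(X: np.ndarray, labels: Sequence[str],
                  target_dim: int | None = None,
                  standardize: bool = True,
                  estimate_dim: bool = True) -> ReductionModel:
    """Standardize and fit LDA, choosing the output dimensionality.

    The default target dimension is min(round(d_hat), k-1, n_features)
    with d_hat the Levina-Bickel estimate on the training matrix.
    Singular within-class scatter triggers shrinkage regularization with
    a warning.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")
    max_dim = min(len(classes) - 1, X.shape[1])

    scaler = None
    Xs = X
    if standardize:
        scaler = StandardScaler().fit(X)
        Xs = scaler.transform(X)

    d_hat = float(max_dim)
    if target_dim is None:
        if estimate_dim and len(X) >= 14:
            d_hat = estimate_intrinsic_dim(Xs)
            target_dim = int(np.clip(round(d_hat), 1, max_dim))
        else:
            target_dim = max_dim
    if not (1 <= target_dim <= max_dim):
        raise ValueError(f"target_dim must be in [1, {max_dim}]")

    lda = LinearDiscriminantAnalysis(solver="eigen", n_components=target_dim)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lda.fit(Xs, labels)
    except np.linalg.LinAlgError:
        warnings.warn("singular within-class scatter; applying shrinkage")
        lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage="auto",
                                         n_components=target_dim)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lda.fit(Xs, labels)
    return ReductionModel(scaler=scaler, lda=lda, intrinsic_dim=d_hat,
                          n_components=target_dim)


# ---------------------------------------------------------------------------
# One-vs-one SVM matcher
# ---------------------------------------------------------------------------

@dataclass
class MatcherModel:
    """k(k-1)/2 pairwise linear SVMs in the reduced feature space."""

    svc: SVC
    reduction: ReductionModel
    subjects: tuple[str, ...]
    pair_index: tuple[tuple[int, int], ...]

    @property
    def n_classifiers(self) -> int:
        k = len(self.subjects)
        return k * (k - 1) // 2

    def _decisions(self, probe: "Probe") -> np.ndarray:
        """Signed one-vs-one margins, ordered (0,1),(0,2),...,(k-2,k-1).

        A positive value of pair (i, j) supports subject i.
        """
        Z = self.reduction.transform(probe.vector[None, :])
        return self.svc.decision_function(Z)[0]


def fit_matchers(train_probes: Sequence[Probe], reduction: ReductionModel,
                 kernel: str = "linear", C: float = 1.0,
                 gamma: str | float = "scale") -> MatcherModel:
    """Train the one-vs-one SVM ensemble on reduced training probes."""
    train_probes = list(train_probes)
    subjects = sorted({p.subject_id for p in train_probes})
    if len(subjects) < 2:
        raise ValueError("need at least 2 enrolled subjects")
    counts = {s: sum(p.subject_id == s for p in train_probes) for s in subjects}
    thin = [s for s, c in counts.items() if c < 2]
    if thin:
        raise ValueError(f"subjects with fewer than 2 training probes: {thin}")
    X = np.vstack([p.vector for p in train_probes])
    y = np.array([p.subject_id for p in train_probes])
    Z = reduction.transform(X)
    svc = SVC(kernel=kernel, C=C, gamma=gamma,
              decision_function_shape="ovo")
    svc.fit(Z, y)
    # sklearn orders ovo pairs (0,1),(0,2),...,(k-2,k-1) over sorted classes
    k = len(subjects)
    pairs = tuple((i, j) for i in range(k) for j in range(i + 1, k))
    order = [str(c) for c in svc.classes_]
    assert order == subjects
    return MatcherModel(svc=svc, reduction=reduction,
                        subjects=tuple(subjects), pair_index=pairs)


def _per_subject_margins(matcher: MatcherModel,
                         decisions: np.ndarray) -> np.ndarray:
    """(k, k-1) array: for each subject, the margins of its k-1
    classifiers oriented so positive supports that subject."""
    k = len(matcher.subjects)
    out = [[] for _ in range(k)]
    for d, (i, j) in zip(decisions, matcher.pair_index):
        out[i].append(d)
        out[j].append(-d)
    return np.array(out)


def verify(matcher: MatcherModel, probe: Probe,
           claimed_subject: str) -> dict:
    """Score a claim: mean oriented margin of the k-1 relevant SVMs.

    Returns the continuous score plus the fraction of classifiers that
    vote for the claim (the discrete rule).
    """
    if claimed_subject not in matcher.subjects:
        raise KeyError(f"subject {claimed_subject!r} is not enrolled")
    idx = matcher.subjects.index(claimed_subject)
    margins = _per_subject_margins(matcher, matcher._decisions(probe))[idx]
    return {"score": float(margins.mean()),
            "vote_fraction": float((margins > 0).mean())}


def identify(matcher: MatcherModel, probe: Probe) -> list[tuple[str, int, float]]:
    """Closed-set identification: rank subjects by pairwise-SVM votes.

    Each of the k(k-1)/2 classifiers casts one vote; ties are broken by
    summed oriented margins, then lexicographic subject id.  Returns
    (subject, votes, summed_margin) best first.
    """
    decisions = matcher._decisions(probe)
    margins = _per_subject_margins(matcher, decisions)
    votes = (margins > 0).sum(axis=1)
    sums = margins.sum(axis=1)
    order = sorted(range(len(matcher.subjects)),
                   key=lambda i: (-votes[i], -sums[i], matcher.subjects[i]))
    return [(matcher.subjects[i], int(votes[i]), float(sums[i]))
            for i in order]


def score_matrix(matcher: MatcherModel, test_probes: Sequence[Probe]
                 ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Verification scores of every test probe against every subject.

    Returns (scores, genuine_mask, subjects): scores has one row per
    probe, one column per enrolled subject (mean oriented margins);
    genuine_mask marks the claimed-identity column of each row.
    """
    subjects = list(matcher.subjects)
    rows = []
    genuine = []
    for p in test_probes:
        margins = _per_subject_margins(matcher, matcher._decisions(p))
        rows.append(margins.mean(axis=1))
        genuine.append([p.subject_id == s for s in subjects])
    return np.asarray(rows), np.asarray(genuine, bool), subjects
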