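"""Enrollment, Mahalanobis verification/identification, majority voting.

Each registered subject is summarized by the mean (cluster center) and
per-dimension variance of their training latents; a probe latent z scores

    d(z, s) = sqrt( sum_d (z_d - center_{s,d})^2 / var_{s,d} )

against subject s.  Verification accepts a claimed identity iff d is
strictly below the subject's threshold (distance == threshold rejects);
identification returns the nearest enrolled center.  Five-beat majority
voting aggregates per-beat decisions with a 3-of-5 rule (verification) or
the per-beat mode (identification, ties broken by smallest mean distance,
then lowest id).

The covariance is per-subject and diagonal with a small floor: with a
50-dimensional latent space and tens of enrollment samples a full covariance
would be singular, and the diagonal form keeps distances well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "GalleryEntry",
    "SubjectGallery",
    "AuthOutcome",
    "enroll",
    "mahalanobis",
    "verify_beat",
    "verify_voted",
    "identify_beat",
    "identify_voted",
    "MahalanobisAuthenticator",
]

VOTE_SIZE = 5


@dataclass
class GalleryEntry:
    center: np.ndarray
    diag_covariance: np.ndarray
    n_enrolled: int
    threshold: float | None = None


@dataclass
class SubjectGallery:
    """Per-subject latent centers, diagonal covariances and thresholds."""

    entries: dict[int, GalleryEntry] = field(default_factory=dict)
    epsilon: float = 1e-6

    @property
    def subject_ids(self) -> list[int]:
        return sorted(self.entries)

    def __getitem__(self, subject_id: int) -> GalleryEntry:
        if subject_id not in self.entries:
            raise KeyError(f"subject {subject_id} is not enrolled")
        return self.entries[subject_id]

    def set_threshold(self, subject_id: int, threshold: float) -> None:
        self[subject_id].threshold = float(threshold)


@dataclass
class AuthOutcome:
    """Voted verification outcome over one five-beat probe group."""

    claimed_id: int
    distances: np.ndarray
    decisions: np.ndarray  # per-beat booleans, True = accept
    accepted: bool
    votes_for: int


def enroll(
    latent_means_by_subject: dict[int, np.ndarray], epsilon: float = 1e-6
) -> SubjectGallery:
    """Build a gallery from each subject's training latent means.

    center = per-dimension mean; diag covariance = per-dimension sample
    variance (n-1 convention) floored at ``epsilon``.  Subjects need at
    least two points for a variance estimate.
    """
    gallery = SubjectGallery(epsilon=epsilon)
    for sid in sorted(latent_means_by_subject):
        Z = np.asarray(latent_means_by_subject[sid], dtype=np.float64)
        if Z.ndim != 2 or Z.shape[0] < 2:
            raise ValueError(f"subject {sid}: need >= 2 latent points to enroll")
        var = np.maximum(Z.var(axis=0, ddof=1), epsilon)
        gallery.entries[int(sid)] = GalleryEntry(
            center=Z.mean(axis=0), diag_covariance=var, n_enrolled=Z.shape[0]
        )
    return gallery


def mahalanobis(z: np.ndarray, entry: GalleryEntry) -> float:
    """Diagonal Mahalanobis distance from z to a subject's cluster."""
    z = np.asarray(z, dtype=np.float64)
    if z.shape != entry.center.shape:
        raise ValueError("latent dimension mismatch")
    d2 = ((z - entry.center) ** 2 / entry.diag_covariance).sum()
    return float(np.sqrt(d2))


def verify_beat(
    z: np.ndarray, claimed_id: int, gallery: SubjectGallery,
    threshold: float | None = None,
) -> tuple[bool, float]:
    """Accept iff the distance to the claimed subject is strictly below the
    threshold (the subject's enrolled threshold unless overridden)."""
    entry = gallery[claimed_id]
    thr = entry.threshold if threshold is None else threshold
    if thr is None:
        raise ValueError(f"no decision threshold set for subject {claimed_id}")
    d = mahalanobis(z, entry)
    return d < thr, d


def verify_voted(
    z_sequence: np.ndarray, claimed_id: int, gallery: SubjectGallery,
    threshold: float | None = None,
) -> AuthOutcome:
    """Majority vote over exactly five consecutive-beat latents (3-of-5)."""
    Z = np.asarray(z_sequence, dtype=np.float64)
    if Z.ndim != 2 or Z.shape[0] != VOTE_SIZE:
        raise ValueError(f"voting requires exactly {VOTE_SIZE} latents")
    results = [verify_beat(z, claimed_id, gallery, threshold) for z in Z]
    decisions = np.asarray([r[0] for r in results])
    distances = np.asarray([r[1] for r in results])
    votes = int(decisions.sum())
    return AuthOutcome(
        claimed_id=int(claimed_id),
        distances=distances,
        decisions=decisions,
        accepted=votes >= (VOTE_SIZE // 2 + 1),
        votes_for=votes,
    )


def identify_beat(z: np.ndarray, gallery: SubjectGallery) -> int:
    """Nearest enrolled center by Mahalanobis distance; ties -> lowest id."""
    if not gallery.entries:
        raise ValueError("gallery is empty")
    ids = gallery.subject_ids
    dists = np.asarray([mahalanobis(z, gallery.entries[s]) for s in ids])
    return ids[int(np.argmin(dists))]  # argmin returns first minimum -> lowest id


def identify_voted(z_sequence: np.ndarray, gallery: SubjectGallery) -> int:
    """Mode of five per-beat identifications; tie -> smallest mean distance
    over the five beats, further tie -> lowest id."""
    Z = np.asarray(z_sequence, dtype=np.float64)
    if Z.ndim != 2 or Z.shape[0] != VOTE_SIZE:
        raise ValueError(f"voting requires exactly {VOTE_SIZE} latents")
    per_beat = [identify_beat(z, gallery) for z in Z]
    counts: dict[int, int] = {}
    for sid in per_beat:
        counts[sid] = counts.get(sid, 0) + 1
    top = max(counts.values())
    tied = sorted(s for s, c in counts.items() if c == top)
    if len(tied) == 1:
        return tied[0]
    mean_d = {
        s: float(np.mean([mahalanobis(z, gallery.entries[s]) for z in Z]))
        for s in tied
    }
    best = min(mean_d.values())
    return min(s for s, d in mean_d.items() if d == best)


class MahalanobisAuthenticator(BaseEstimator):
    """Gallery-based open-set verifier / closed-set identifier.

    scikit-learn protocol: ``fit(Z, y)`` enrolls latents grouped by subject
    label; ``predict(Z)`` identifies each row (nearest center).  Verification
    thresholds are set per subject via :meth:`set_threshold` (typically at
    the equal-error-rate operating point of a threshold sweep).
    """

    def __init__(self, epsilon: float = 1e-6):
        self.epsilon = epsilon

    def fit(self, Z: np.ndarray, y: np.ndarray) -> "MahalanobisAuthenticator":
        Z = np.asarray(Z, dtype=np.float64)
        y = np.asarray(y)
        groups = {int(s): Z[y == s] for s in np.unique(y)}
        self.gallery_ = enroll(groups, epsilon=self.epsilon)
        return self

    def set_threshold(self, subject_id: int, threshold: float) -> None:
        self.gallery_.set_threshold(subject_id, threshold)

    def decision_distance(self, Z: np.ndarray, claimed_id: int) -> np.ndarray:
        entry = self.gallery_[claimed_id]
        return np.asarray([mahalanobis(z, entry) for z in np.atleast_2d(Z)])

    def predict(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray([identify_beat(z, self.gallery_) for z in np.atleast_2d(Z)])

    def verify(self, Z: np.ndarray, claimed_id: int,
               threshold: float | None = None) -> np.ndarray:
        return np.asarray(
            [verify_beat(z, claimed_id, self.gallery_, threshold)[0]
             for z in np.atleast_2d(Z)]
        )
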