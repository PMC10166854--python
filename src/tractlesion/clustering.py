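"""Streamline bundle clustering and coherence filtering.

The clustering metric is the minimum average direct-flip (MDF) distance
between streamlines resampled to a fixed number of points. `QuickBundles`
is the classic single-pass incremental algorithm: each streamline joins
the cluster whose running-mean centroid is nearest by MDF if that distance
is under the threshold, otherwise it founds a new cluster. The pass is
order-dependent; streamlines are processed in stored order.

On top of it sit the operations used to decompose a cerebellothalamic
tract into anterior / middle / posterior sub-bundles: an adaptive
threshold search (`select_amp_clusters`), forced assignment of streamlines
to the three selected centroids (`assign_to_centroids`), a coherence
filter retaining the streamlines most similar to the rest of their bundle,
and pooling of per-subject clusters into template bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .errors import SearchFailureError, ValidationError
from .spatial import DEFAULT_N_POINTS, Tractogram, resample_streamline

__all__ = [
    "Cluster",
    "ClusterDecomposition",
    "QuickBundles",
    "quickbundles",
    "select_amp_clusters",
    "assign_to_centroids",
    "coherence_filter",
    "coherence_scores",
    "build_template_bundle",
]

ROLES = ("anterior", "middle", "posterior")


@dataclass
class Cluster:
    """One streamline cluster: a running-mean centroid plus member indices."""

    centroid: np.ndarray
    member_ids: list = field(default_factory=list)


@dataclass
class ClusterDecomposition:
    """Partition of a tractogram into clusters.

    ``labels[i]`` is the cluster index of streamline ``i``; ``amp_roles``
    maps cluster index -> role name for the three clusters identified as
    anterior / middle / posterior (set by `select_amp_clusters`).
    """

    clusters: list
    threshold_mm: float
    labels: np.ndarray
    amp_roles: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def role_centroids(self) -> dict:
        """Map role -> centroid for the role-labelled clusters."""
        return {role: self.clusters[ci].centroid
                for ci, role in self.amp_roles.items()}


def _resample_all(streamlines, k: int) -> np.ndarray:
    return np.stack([resample_streamline(s, k) for s in streamlines])


class QuickBundles(ClusterMixin, BaseEstimator):
    """Single-pass incremental MDF clustering of streamlines.

    Parameters
    ----------
    threshold : float
        MDF distance (mm) under which a streamline joins the nearest
        existing cluster instead of founding a new one.
    n_points : int
        Number of points streamlines are resampled to before distance
        computation.

    Attributes
    ----------
    labels_ : (n,) int array
        Cluster index per streamline.
    centroids_ : list of (n_points, 3) arrays
        Running mean of flip-aligned resampled members, per cluster.
    cluster_sizes_ : (n_clusters,) int array

    Notes
    -----
    The pass is order-dependent by construction; `fit` consumes
    streamlines in the given order. A streamline is flip-aligned to the
    centroid it joins (reversed when the flipped distance is smaller)
    before entering the running mean.
    """

    def __init__(self, threshold: float = 10.0, n_points: int = DEFAULT_N_POINTS):
        self.threshold = threshold
        self.n_points = n_points

    def fit(self, X, y=None):
        """Cluster a sequence of streamlines (arrays or a Tractogram)."""
        if self.threshold <= 0:
            raise ValidationError("threshold must be positive")
        streamlines = list(X)
        if len(streamlines) == 0:
            raise ValidationError("cannot cluster an empty tractogram")
        k = self.n_points
        R = _resample_all(streamlines, k)

        centroid_sum = []   # sum of aligned members, per cluster
        counts = []
        members = []
        labels = np.empty(len(streamlines), dtype=np.intp)

        for i, s in enumerate(R):
            if centroid_sum:
                C = np.stack([cs / n for cs, n in zip(centroid_sum, counts)])
                direct = np.linalg.norm(C - s, axis=2).mean(axis=1)
                flipped = np.linalg.norm(C - s[::-1], axis=2).mean(axis=1)
                dist = np.minimum(direct, flipped)
                j = int(np.argmin(dist))
                if dist[j] < self.threshold:
                    aligned = s if direct[j] <= flipped[j] else s[::-1]
                    centroid_sum[j] += aligned
                    counts[j] += 1
                    members[j].append(i)
                    labels[i] = j
                    continue
            centroid_sum.append(s.copy())
            counts.append(1)
            members.append([i])
            labels[i] = len(centroid_sum) - 1

        self.labels_ = labels
        self.centroids_ = [cs / n for cs, n in zip(centroid_sum, counts)]
        self.cluster_sizes_ = np.array([len(m) for m in members])
        self._members = members
        return self

    def decomposition(self) -> ClusterDecomposition:
        """Return the fitted partition as a `ClusterDecomposition`."""
        clusters = [Cluster(c, m) for c, m in zip(self.centroids_, self._members)]
        return ClusterDecomposition(clusters=clusters,
                                    threshold_mm=self.threshold,
                                    labels=self.labels_.copy())


def quickbundles(t, threshold: float, k: int = DEFAULT_N_POINTS) -> ClusterDecomposition:
    """Functional wrapper around the `QuickBundles` estimator."""
    return QuickBundles(threshold=threshold, n_points=k).fit(t).decomposition()


def _role_rank(centroids, anterior_axis: int, slab_fraction=(1 / 3, 2 / 3)):
    """Order three centroids by mean anterior coordinate within the mid-tract slab.

    Returns roles aligned with ``centroids``: the centroid with the largest
    mean anterior coordinate is "anterior", the smallest "posterior". The
    slab restricts to the middle portion of centroid points so convergent
    endpoint regions do not dominate.
    """
    k = centroids[0].shape[0]
    lo = int(np.floor(slab_fraction[0] * k))
    hi = max(lo + 1, int(np.ceil(slab_fraction[1] * k)))
    means = [float(c[lo:hi, anterior_axis].mean()) for c in centroids]
    order = np.argsort(means)  # ascending: posterior first
    roles = [None] * 3
    roles[order[0]] = "posterior"
    roles[order[1]] = "middle"
    roles[order[2]] = "anterior"
    return roles


def select_amp_clusters(t, start_threshold: float = 2.0, step: float = 1.0,
                        max_threshold: float = 30.0, k: int = DEFAULT_N_POINTS,
                        min_fraction: float = 0.05, min_coverage: float = 0.9,
                        anterior_axis: int = 1,
                        slab_fraction=(1 / 3, 2 / 3)) -> ClusterDecomposition:
    """Adaptive-threshold search for anterior/middle/posterior clusters.

    Runs `quickbundles` at ``start_threshold``, ``start_threshold + step``,
    ... until a decomposition qualifies: at least three clusters each hold
    at least ``min_fraction`` of the streamlines, and the three largest of
    those jointly hold at least ``min_coverage`` of them (so the search
    does not stop while the tract is still fragmented into many partial
    clusters). The three largest qualifying clusters are role-labelled by
    the rank of the mean anterior-axis coordinate of their centroid points
    inside the mid-tract slab (largest -> anterior, smallest ->
    posterior).

    Raises
    ------
    SearchFailureError
        If no threshold up to ``max_threshold`` qualifies; the error
        carries the (threshold, n_clusters) trajectory.
    """
    if not (0 < start_threshold < max_threshold):
        raise ValidationError("need 0 < start_threshold < max_threshold")
    if step <= 0:
        raise ValidationError("step must be positive")
    n = len(list(t))
    trajectory = []
    thr = start_threshold
    while thr <= max_threshold + 1e-9:
        dec = quickbundles(t, threshold=thr, k=k)
        sizes = np.array([len(c.member_ids) for c in dec.clusters])
        qualifying = np.where(sizes >= min_fraction * n)[0]
        trajectory.append((thr, dec.n_clusters))
        if len(qualifying) >= 3:
            top3 = qualifying[np.argsort(sizes[qualifying])[::-1][:3]]
            if sizes[top3].sum() < min_coverage * n:
                thr += step
                continue
            roles = _role_rank([dec.clusters[i].centroid for i in top3],
                               anterior_axis, slab_fraction)
            dec.amp_roles = {int(ci): role for ci, role in zip(top3, roles)}
            return dec
        thr += step
    raise SearchFailureError(
        f"no threshold up to {max_threshold} mm produced >= 3 clusters of "
        f">= {min_fraction:.0%} of {n} streamlines covering "
        f">= {min_coverage:.0%} jointly; "
        f"trajectory (threshold, n_clusters): {trajectory}",
        trajectory=trajectory,
    )


def assign_to_centroids(t, centroids: dict, k: int = DEFAULT_N_POINTS) -> dict:
    """Assign every streamline to the role of its nearest centroid (forced).

    ``centroids`` maps role -> centroid streamline. Each streamline is
    resampled and compared by MDF to all centroids; flip orientation is
    handled inside the distance. Returns ``{streamline_index: role}``.
    """
    streamlines = list(t)
    if len(streamlines) == 0:
        raise ValidationError("cannot assign an empty tractogram")
    if len(centroids) != 3:
        raise ValidationError(f"expected 3 centroids, got {len(centroids)}")
    roles = list(centroids)
    C = np.stack([resample_streamline(centroids[r], k) for r in roles])
    R = _resample_all(streamlines, k)
    out = {}
    for i, s in enumerate(R):
        direct = np.linalg.norm(C - s, axis=2).mean(axis=1)
        flipped = np.linalg.norm(C - s[::-1], axis=2).mean(axis=1)
        out[i] = roles[int(np.argmin(np.minimum(direct, flipped)))]
    return out


def _pairwise_mdf_sums(R: np.ndarray, block: int = 64) -> np.ndarray:
    """Row sums of the full pairwise MDF matrix, computed in blocks.

    ``R`` is the (n, k, 3) resampled stack. The self-distance is zero and
    contributes nothing to the sums.
    """
    n = R.shape[0]
    Rf = R[:, ::-1]
    sums = np.zeros(n)
    for lo in range(0, n, block):
        hi = min(lo + block, n)
        diff = R[lo:hi, None] - R[None, :]          # (b, n, k, 3)
        direct = np.linalg.norm(diff, axis=3).mean(axis=2)
        diff_f = R[lo:hi, None] - Rf[None, :]
        flipped = np.linalg.norm(diff_f, axis=3).mean(axis=2)
        sums[lo:hi] = np.minimum(direct, flipped).sum(axis=1)
    return sums


def coherence_scores(t, k: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Mean MDF distance of each streamline to all others (lower = more coherent)."""
    streamlines = list(t)
    n = len(streamlines)
    if n == 0:
        raise ValidationError("empty tractogram")
    if n == 1:
        return np.zeros(1)
    R = _resample_all(streamlines, k)
    return _pairwise_mdf_sums(R) / (n - 1)


def coherence_filter(t: Tractogram, n_keep: int = 1000,
                     k: int = DEFAULT_N_POINTS) -> Tractogram:
    """Keep the ``n_keep`` most coherent streamlines of a tractogram.

    Coherence of a streamline is its mean MDF distance to every other
    streamline (exact O(n^2) computation); the smallest scores are kept,
    ties broken by original index. If ``n_keep`` is at least the streamline
    count the tractogram is returned unchanged.
    """
    if n_keep < 1:
        raise ValidationError("n_keep must be >= 1")
    streamlines = list(t)
    if len(streamlines) <= n_keep:
        return Tractogram(streamlines, space_id=t.space_id)
    scores = coherence_scores(t, k)
    keep = np.argsort(scores, kind="stable")[:n_keep]
    keep.sort()
    return Tractogram([streamlines[i] for i in keep], space_id=t.space_id)


def build_template_bundle(per_subject: list, n_keep: int = 1000,
                          k: int = DEFAULT_N_POINTS) -> Tractogram:
    """Pool one cluster across subjects and keep its most coherent core.

    All input tractograms must share one space tag (template space);
    streamlines are concatenated and passed through `coherence_filter`.
    Output streamlines are selected, never averaged.
    """
    if not per_subject:
        raise ValidationError("need at least one subject tractogram")
    tags = {t.space_id for t in per_subject}
    if len(tags) > 1:
        raise ValidationError(f"mixed space tags: {sorted(tags)}")
    pooled = Tractogram(
        [s for t in per_subject for s in t.streamlines],
        space_id=per_subject[0].space_id,
    )
    return coherence_filter(pooled, n_keep=n_keep, k=k)
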