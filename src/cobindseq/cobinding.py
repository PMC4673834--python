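"""Two-factor co-binding classification from z-scored coverage profiles.

The binding-site sets of two factors (A and B) are merged: sites whose
centers lie within a pairing distance (default 250 bp) become a single
`paired` site centered on the midpoint, the rest stay factor-specific.
Around every combined site the background-equalized, control-subtracted
coverage of both factors is summarized in 25-bp sub-windows across
+/- 500 bp, standardized to z-scores in each sub-window (by default per
sub-window column across sites; a per-site, per-track mode is available),
and the resulting matrix is clustered with K-means (K = 3). The three
clusters are labeled A_only / B_only / shared from their mean raw signal
per factor track, turning the heatmap reading into a deterministic rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .consensus import BindingSiteSet, NBBackground
from .genome import CoverageTrack, GenomicInterval

Source = Literal["A_only", "B_only", "paired"]
SEMANTIC_LABELS = ("A_only", "B_only", "shared")


@dataclass(frozen=True)
class CombinedSite:
    chrom: str
    center: int
    source: str  # A_only | B_only | paired
    index_a: int | None = None
    index_b: int | None = None


@dataclass
class ClusterAssignment:
    """K-means output plus (for K=3) semantic cluster labels."""

    labels: np.ndarray  # per-site cluster id, 0..k-1
    centroids: np.ndarray
    inertia: float
    semantics: dict[int, str] | None = None  # cluster id -> semantic label
    ambiguous: bool = False

    @property
    def site_classes(self) -> np.ndarray:
        if self.semantics is None:
            raise ValueError("semantic labels not assigned")
        return np.array([self.semantics[int(l)] for l in self.labels])


def merge_factor_sites(
    sites_a: BindingSiteSet | Sequence[GenomicInterval],
    sites_b: BindingSiteSet | Sequence[GenomicInterval],
    pairing_distance: int = 250,
) -> list[CombinedSite]:
    """Pair A and B sites whose centers are within pairing_distance.

    Greedy nearest-center matching: candidate pairs are taken in order of
    increasing center distance, each site used at most once. Paired sites
    get the midpoint center; leftovers are emitted as A_only / B_only.
    Conservation: |A_only| + |B_only| + 2*|paired| = |A| + |B|.
    """
    ivs_a = sites_a.intervals() if isinstance(sites_a, BindingSiteSet) else list(sites_a)
    ivs_b = sites_b.intervals() if isinstance(sites_b, BindingSiteSet) else list(sites_b)
    centers_a = [(iv.chrom, iv.center) for iv in ivs_a]
    centers_b = [(iv.chrom, iv.center) for iv in ivs_b]

    candidates: list[tuple[int, int, int]] = []  # (distance, ia, ib)
    by_chrom_b: dict[str, list[int]] = {}
    for ib, (chrom, _) in enumerate(centers_b):
        by_chrom_b.setdefault(chrom, []).append(ib)
    for ia, (chrom, ca) in enumerate(centers_a):
        for ib in by_chrom_b.get(chrom, ()):
            d = abs(ca - centers_b[ib][1])
            if d <= pairing_distance:
                candidates.append((d, ia, ib))
    candidates.sort()

    used_a: set[int] = set()
    used_b: set[int] = set()
    combined: list[CombinedSite] = []
    for d, ia, ib in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        chrom, ca = centers_a[ia]
        cb = centers_b[ib][1]
        combined.append(
            CombinedSite(chrom, (ca + cb) // 2, "paired", index_a=ia, index_b=ib)
        )
    for ia, (chrom, ca) in enumerate(centers_a):
        if ia not in used_a:
            combined.append(CombinedSite(chrom, ca, "A_only", index_a=ia))
    for ib, (chrom, cb) in enumerate(centers_b):
        if ib not in used_b:
            combined.append(CombinedSite(chrom, cb, "B_only", index_b=ib))
    combined.sort(key=lambda s: (s.chrom, s.center, s.source))
    return combined


def subtract_control(
    sample: CoverageTrack,
    control: CoverageTrack,
    bg: NBBackground,
    clamp: bool = True,
) -> CoverageTrack:
    """Background-equalized control subtraction: max(0, sample - scale*control).

    The scale comes from the fitted background model, equalizing background
    levels between the antibody and IgG tracks before subtraction. Set
    clamp=False to keep negative residuals (useful for oracle checks).
    """
    if sample.genome != control.genome:
        raise ValueError("sample and control are on different genomes")
    data = {}
    for chrom in sample.genome:
        diff = sample[chrom] - bg.scale * control[chrom]
        data[chrom] = np.maximum(diff, 0.0) if clamp else diff
    return CoverageTrack(sample.genome, data)


def profile_matrix(
    sites: Sequence[CombinedSite],
    subtracted_a: CoverageTrack,
    subtracted_b: CoverageTrack,
    half_window: int = 500,
    subwindow: int = 25,
) -> np.ndarray:
    """Mean subtracted coverage per 25-bp sub-window around each site.

    Returns an (n_sites, 2 * half_window*2/subwindow) matrix: the factor-A
    sub-windows followed by the factor-B sub-windows, left to right across
    [center - half_window, center + half_window). Windows reaching past a
    chromosome end are zero-padded.
    """
    if half_window % subwindow != 0:
        raise ValueError("half_window must be divisible by subwindow")
    w = 2 * half_window // subwindow
    out = np.zeros((len(sites), 2 * w), dtype=np.float64)
    for i, site in enumerate(sites):
        for t, track in enumerate((subtracted_a, subtracted_b)):
            L = track.genome[site.chrom]
            lo = site.center - half_window
            hi = site.center + half_window
            window = np.zeros(2 * half_window, dtype=np.float64)
            s, e = max(0, lo), min(L, hi)
            if s < e:
                window[s - lo : e - lo] = track[site.chrom][s:e]
            out[i, t * w : (t + 1) * w] = window.reshape(w, subwindow).mean(axis=1)
    return out


def zscore_rows(
    matrix: np.ndarray,
    n_tracks: int = 2,
    mode: str = "site",
) -> np.ndarray:
    """Standardize profile segments to z-scores.

    mode="site": each row x track segment is standardized independently
    with the population SD, so cluster structure reflects profile shape
    rather than amplitude; zero-variance segments become all-zero.
    mode="column": each 25-bp sub-window column is standardized across
    sites, preserving the relative amplitude between tracks — this is
    what the co-binding classifier uses by default, because per-site
    standardization makes a single stray background read in the silent
    track indistinguishable from a true peak.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("profile matrix contains non-finite values")
    if matrix.shape[1] % n_tracks != 0:
        raise ValueError("column count not divisible by n_tracks")
    z = np.zeros_like(matrix)
    if mode == "column":
        mu = matrix.mean(axis=0)
        sd = matrix.std(axis=0)
        nz = sd > 0
        z[:, nz] = (matrix[:, nz] - mu[nz]) / sd[nz]
        return z
    if mode != "site":
        raise ValueError(f"unknown z-score mode {mode!r}")
    w = matrix.shape[1] // n_tracks
    for t in range(n_tracks):
        seg = matrix[:, t * w : (t + 1) * w]
        mu = seg.mean(axis=1, keepdims=True)
        sd = seg.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            zs = (seg - mu) / sd
        zs[np.broadcast_to(sd == 0, zs.shape)] = 0.0
        z[:, t * w : (t + 1) * w] = zs
    return z


def kmeans_cluster(
    z: np.ndarray, k: int = 3, seed: int | None = None, n_init: int = 10
) -> ClusterAssignment:
    """Lloyd's K-means with k-means++ init, best of n_init restarts."""
    z = np.asarray(z, dtype=np.float64)
    if z.shape[0] < k:
        raise ValueError(f"{z.shape[0]} rows < k={k}")
    km = KMeans(
        n_clusters=k, n_init=n_init, random_state=seed, init="k-means++",
        algorithm="lloyd",
    ).fit(z)
    return ClusterAssignment(
        labels=km.labels_.copy(),
        centroids=km.cluster_centers_.copy(),
        inertia=float(km.inertia_),
    )


def label_clusters(
    assignment: ClusterAssignment,
    raw_profiles: np.ndarray,
    n_tracks: int = 2,
) -> ClusterAssignment:
    """Assign A_only / B_only / shared semantics to the K=3 clusters.

    Per cluster, the mean raw (un-z-scored) signal of each factor track is
    computed; clusters are ranked by mean(A) - mean(B): the top cluster is
    A_only, the bottom B_only and the middle shared. Ties (ambiguous
    centroids) are flagged and broken by cluster id.
    """
    k = assignment.centroids.shape[0]
    if k != len(SEMANTIC_LABELS):
        raise ValueError("semantic labeling requires k = 3")
    raw_profiles = np.asarray(raw_profiles, dtype=np.float64)
    w = raw_profiles.shape[1] // n_tracks
    scores = []
    for c in range(k):
        rows = raw_profiles[assignment.labels == c]
        mean_a = rows[:, :w].mean() if len(rows) else 0.0
        mean_b = rows[:, w : 2 * w].mean() if len(rows) else 0.0
        scores.append(mean_a - mean_b)
    scores = np.asarray(scores)
    ambiguous = len(np.unique(scores)) < k
    order = np.argsort(scores, kind="stable")  # low -> high
    semantics = {
        int(order[0]): "B_only",
        int(order[1]): "shared",
        int(order[2]): "A_only",
    }
    assignment.semantics = semantics
    assignment.ambiguous = bool(ambiguous)
    return assignment


class CoBindingClassifier(ClusterMixin, BaseEstimator):
    """K-means co-binding classifier over two-factor profile matrices.

    fit(X) takes the raw (un-z-scored) profile matrix with the factor-A
    sub-window block followed by the factor-B block, standardizes it to
    z-scores (per sub-window across sites by default; zscore_mode="site"
    standardizes each site x track segment instead), clusters with
    K-means and — when n_clusters=3 — labels the clusters A_only /
    B_only / shared from their mean raw signal per track.

    Attributes (after fit)
    ----------------------
    zmatrix_ : the standardized matrix that was clustered
    labels_ : integer cluster id per site
    site_classes_ : semantic class per site (n_clusters=3 only)
    cluster_semantics_ : cluster id -> semantic label
    cluster_centers_, inertia_ : K-means outputs
    ambiguous_ : True when two clusters tied in the labeling rule
    """

    def __init__(
        self,
        n_clusters: int = 3,
        n_init: int = 10,
        random_state: int | None = None,
        zscore_mode: str = "column",
        n_tracks: int = 2,
    ):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.random_state = random_state
        self.zscore_mode = zscore_mode
        self.n_tracks = n_tracks

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        self.zmatrix_ = zscore_rows(X, n_tracks=self.n_tracks, mode=self.zscore_mode)
        assignment = kmeans_cluster(
            self.zmatrix_, k=self.n_clusters, seed=self.random_state,
            n_init=self.n_init,
        )
        if self.n_clusters == len(SEMANTIC_LABELS):
            assignment = label_clusters(assignment, X, n_tracks=self.n_tracks)
            self.cluster_semantics_ = assignment.semantics
            self.site_classes_ = assignment.site_classes
            self.ambiguous_ = assignment.ambiguous
        self.assignment_ = assignment
        self.labels_ = assignment.labels
        self.cluster_centers_ = assignment.centroids
        self.inertia_ = assignment.inertia
        return self
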