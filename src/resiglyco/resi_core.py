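"""From per-channel DNA-PAINT localizations to a merged table of
super-resolved binding-site positions.

Each DNA-barcoded sugar site is sampled repeatedly over an imaging round,
leaving a tight clump of localizations.  The steps here are:

1. per-channel density clustering with radius ``r`` (~2.35x the
   localization precision) and a minimum of ``n_min`` localizations;
2. time-domain filtering of the surviving clusters, removing traces whose
   binding-event structure looks like nonspecific sticking;
3. cluster-centre computation — averaging the K member localizations
   improves precision by 1/sqrt(K), into the angstrom range;
4. translation-only channel alignment from fiducial markers and merging of
   all channels into one table (distinct barcodes are distinct molecules,
   so no cross-channel deduplication).

The clustering algorithm is deterministic: localizations with the locally
maximal neighbour count within ``r`` become seeds (ties broken by higher
count, then lower frame, then lower x, then lower y), every localization
joins its nearest seed within ``r`` or is labelled noise, and clusters
below ``n_min`` are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io_formats import (
    AlignmentError,
    ClusteringConfig,
    TraceFilterConfig,
    ValidationError,
    get_logger,
)

__all__ = [
    "SiteCluster",
    "ChannelShifts",
    "cluster_channel",
    "cluster_labels",
    "filter_time_traces",
    "count_events",
    "compute_centers",
    "align_channels",
    "merge_channels",
    "suggest_radius",
    "suggest_nmin",
]

RESI_COLUMNS = ("x", "y", "channel", "K", "sigma_resi")


@dataclass
class SiteCluster:
    """One candidate binding site: a cluster of localizations in a channel."""

    channel: int
    members: np.ndarray  # indices into the channel's localization table
    frames: np.ndarray
    points: np.ndarray  # member positions, shape (K, 2), nm
    precisions: np.ndarray | None = None  # member per-localization precisions
    centre: tuple[float, float] | None = None
    K: int = 0
    sigma_resi: float = float("nan")
    n_events: int | None = None
    sigma_fallback: bool = False  # True when K=1 and sigma is the loc precision

    def __post_init__(self) -> None:
        if self.K == 0:
            self.K = int(np.asarray(self.points).shape[0])


@dataclass
class ChannelShifts:
    """Per-channel translation (dx, dy) in nm onto the reference channel."""

    shifts: dict[int, tuple[float, float]]
    reference_channel: int
    residuals: dict[int, float] = field(default_factory=dict)

    def get(self, channel: int) -> tuple[float, float]:
        if channel not in self.shifts:
            raise ValidationError(f"no shift available for channel {channel}")
        return self.shifts[channel]


# --------------------------------------------------------------------------
# per-channel clustering
# --------------------------------------------------------------------------

def cluster_labels(points: np.ndarray, frames: np.ndarray, r: float, n_min: int) -> np.ndarray:
    """Label array for the seeded density clustering (-1 = noise).

    Seeds are localizations whose r-neighbourhood count is a strict local
    maximum (ties by higher count, then lower frame, then lower x, then
    lower y); every localization is assigned to the nearest seed within
    ``r``; clusters with fewer than ``n_min`` members are dropped.
    """
    if r <= 0:
        raise ValidationError("cluster radius r must be positive")
    if n_min < 1:
        raise ValidationError("n_min must be >= 1")
    n = points.shape[0]
    if n == 0:
        return np.empty(0, dtype=np.int64)
    tree = cKDTree(points)
    counts = tree.query_ball_point(points, r, return_length=True)  # includes self

    # priority rank: higher rank wins; lexicographic on
    # (count desc, frame asc, x asc, y asc)
    order = np.lexsort((-points[:, 1], -points[:, 0], -frames, counts))
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)

    # neighbourhood maximum of rank over all pairs within r
    nbr_max = np.full(n, -1, dtype=np.int64)
    pairs = tree.query_pairs(r, output_type="ndarray")
    if pairs.size:
        np.maximum.at(nbr_max, pairs[:, 0], rank[pairs[:, 1]])
        np.maximum.at(nbr_max, pairs[:, 1], rank[pairs[:, 0]])
    is_seed = rank > nbr_max
    # a seed's cluster can never exceed its own neighbour count
    is_seed &= counts >= n_min
    seed_idx = np.flatnonzero(is_seed)
    if seed_idx.size == 0:
        return np.full(n, -1, dtype=np.int64)

    seed_tree = cKDTree(points[seed_idx])
    dist, j = seed_tree.query(points, k=1, distance_upper_bound=r)
    labels = np.where(np.isfinite(dist), j, -1).astype(np.int64)

    # enforce n_min and compact labels
    sizes = np.bincount(labels[labels >= 0], minlength=seed_idx.size)
    keep = sizes >= n_min
    remap = np.full(seed_idx.size, -1, dtype=np.int64)
    remap[keep] = np.arange(int(keep.sum()))
    labels = np.where(labels >= 0, remap[np.maximum(labels, 0)], -1)
    return labels


def cluster_channel(table: pd.DataFrame, params: ClusteringConfig) -> list[SiteCluster]:
    """Cluster one channel's localizations into candidate binding sites."""
    if len(table) == 0:
        return []
    points = table[["x", "y"]].to_numpy()
    frames = table["frame"].to_numpy()
    channel = int(table["channel"].iloc[0]) if "channel" in table.columns else 0
    labels = cluster_labels(points, frames, params.r, params.n_min)
    return _clusters_from_labels(points, frames, labels, channel, table)


def _clusters_from_labels(
    points: np.ndarray,
    frames: np.ndarray,
    labels: np.ndarray,
    channel: int,
    table: pd.DataFrame,
) -> list[SiteCluster]:
    clusters: list[SiteCluster] = []
    if labels.size == 0 or labels.max() < 0:
        return clusters
    order = np.argsort(labels, kind="stable")
    sorted_labels = labels[order]
    start = np.searchsorted(sorted_labels, 0)  # skip noise (-1)
    boundaries = np.flatnonzero(np.diff(sorted_labels[start:])) + 1
    groups = np.split(order[start:], boundaries)
    precisions = table["precision"].to_numpy()
    for members in groups:
        members = np.sort(members)
        c = SiteCluster(
            channel=channel,
            members=members,
            frames=frames[members],
            points=points[members],
            precisions=precisions[members],
        )
        _summarize(c)
        clusters.append(c)
    return clusters


# --------------------------------------------------------------------------
# time-trace filtering
# --------------------------------------------------------------------------

def count_events(frames: np.ndarray, gap_frames: int) -> int:
    """Number of binding events after closing frame gaps <= ``gap_frames``."""
    if frames.size == 0:
        return 0
    f = np.sort(frames)
    return 1 + int((np.diff(f) > gap_frames).sum())


def filter_time_traces(
    clusters: list[SiteCluster],
    params: TraceFilterConfig,
    n_frames: int,
) -> list[SiteCluster]:
    """Drop clusters whose time trace looks nonspecific.

    A genuine binding site is revisited by imagers throughout the
    acquisition; a nonspecific event is one short burst.  Frames within a
    cluster are merged into events (gaps <= ``gap_frames`` close), and
    clusters with fewer than ``min_events`` events or a first-to-last frame
    span below ``min_span_fraction * n_frames`` are removed.  Survivors
    carry their event count.
    """
    min_span = params.min_span_fraction * n_frames
    kept: list[SiteCluster] = []
    for c in clusters:
        c.n_events = count_events(c.frames, params.gap_frames)
        span = float(c.frames.max() - c.frames.min()) if c.frames.size else 0.0
        if c.n_events >= params.min_events and span >= min_span:
            kept.append(c)
    return kept


# --------------------------------------------------------------------------
# centres and merging
# --------------------------------------------------------------------------

def _summarize(c: SiteCluster) -> SiteCluster:
    """Fill centre, K and sigma_resi from the member positions."""
    pts = np.asarray(c.points, dtype=float)
    c.K = pts.shape[0]
    c.centre = (float(pts[:, 0].mean()), float(pts[:, 1].mean()))
    if c.K > 1:
        s2 = 0.5 * (pts[:, 0].var(ddof=1) + pts[:, 1].var(ddof=1))
        c.sigma_resi = float(np.sqrt(s2 / c.K))
        c.sigma_fallback = False
    else:
        c.sigma_resi = float(c.precisions[0]) if c.precisions is not None else float("nan")
        c.sigma_fallback = True
    return c


def compute_centers(clusters: list[SiteCluster]) -> pd.DataFrame:
    """Cluster centres as a single-channel table of super-resolved sites.

    The centre is the arithmetic mean of the K member localizations and
    ``sigma_resi = s / sqrt(K)`` with ``s`` the sample sd pooled over x and
    y — averaging K localizations improves precision by 1/sqrt(K).  For
    K = 1 the localization's own precision is used and the record flagged.
    """
    for c in clusters:
        _summarize(c)
    return pd.DataFrame(
        {
            "x": np.array([c.centre[0] for c in clusters]),
            "y": np.array([c.centre[1] for c in clusters]),
            "channel": np.array([c.channel for c in clusters], dtype=np.int64),
            "K": np.array([c.K for c in clusters], dtype=np.int64),
            "sigma_resi": np.array([c.sigma_resi for c in clusters]),
            "n_events": np.array(
                [-1 if c.n_events is None else c.n_events for c in clusters], dtype=np.int64
            ),
            "sigma_fallback": np.array([c.sigma_fallback for c in clusters], dtype=bool),
        }
    )


def _collapse_fiducials(locs: pd.DataFrame, link_radius: float) -> np.ndarray:
    """Collapse fiducial localizations to per-fiducial centres (link-radius
    connected components; fiducials are far apart relative to their spread)."""
    pts = locs[["x", "y"]].to_numpy()
    if pts.shape[0] == 0:
        return np.empty((0, 2))
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    tree = cKDTree(pts)
    pairs = tree.query_pairs(link_radius, output_type="ndarray")
    n = pts.shape[0]
    adj = coo_matrix(
        (np.ones(pairs.shape[0]), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, comp = connected_components(adj, directed=False)
    centres = np.column_stack(
        [np.bincount(comp, weights=pts[:, 0]), np.bincount(comp, weights=pts[:, 1])]
    ) / np.bincount(comp)[:, None]
    return centres


def align_channels(
    fiducials: dict[int, pd.DataFrame],
    reference_channel: int = 0,
    max_match_distance: float = 100.0,
    link_radius: float = 50.0,
) -> ChannelShifts:
    """Estimate per-channel translations from fiducial markers.

    Fiducial localizations are collapsed to per-fiducial centres, matched
    mutual-nearest-neighbour to the reference channel's centres within
    ``max_match_distance``, and the shift is the mean displacement of the
    matched pairs.  The RMS residual after applying the shift is reported
    per channel.
    """
    log = get_logger("align")
    if reference_channel not in fiducials:
        raise AlignmentError(f"reference channel {reference_channel} has no fiducials")
    ref = _collapse_fiducials(fiducials[reference_channel], link_radius)
    if ref.shape[0] == 0:
        raise AlignmentError("reference channel has zero fiducials")
    if ref.shape[0] >= 2:
        tree = cKDTree(ref)
        d, _ = tree.query(ref, k=2)
        if (d[:, 1] < 2 * max_match_distance).any():
            log.warning("fiducials closer than 2x max match distance; matches may be ambiguous")

    shifts: dict[int, tuple[float, float]] = {reference_channel: (0.0, 0.0)}
    residuals: dict[int, float] = {reference_channel: 0.0}
    ref_tree = cKDTree(ref)
    for ch, locs in fiducials.items():
        if ch == reference_channel:
            continue
        cen = _collapse_fiducials(locs, link_radius)
        if cen.shape[0] == 0:
            raise AlignmentError(f"channel {ch} has zero fiducials")
        d_fwd, j_fwd = ref_tree.query(cen, k=1, distance_upper_bound=max_match_distance)
        cen_tree = cKDTree(cen)
        _, j_bwd = cen_tree.query(ref, k=1, distance_upper_bound=max_match_distance)
        matched = [
            (i, j_fwd[i])
            for i in range(cen.shape[0])
            if np.isfinite(d_fwd[i]) and j_fwd[i] < ref.shape[0] and j_bwd[j_fwd[i]] == i
        ]
        if not matched:
            raise AlignmentError(f"channel {ch}: no mutual fiducial matches within "
                                 f"{max_match_distance} nm of the reference")
        disp = np.array([ref[j] - cen[i] for i, j in matched])
        shift = disp.mean(axis=0)
        shifts[ch] = (float(shift[0]), float(shift[1]))
        residuals[ch] = float(np.sqrt(((disp - shift) ** 2).sum(axis=1).mean()))
    return ChannelShifts(shifts=shifts, reference_channel=reference_channel, residuals=residuals)


def merge_channels(resi_tables: dict[int, pd.DataFrame], shifts: ChannelShifts) -> pd.DataFrame:
    """Translate each channel's site centres by its shift and concatenate.

    Record count is conserved: distinct barcodes label distinct molecules,
    so no cross-channel deduplication is performed; channel provenance is
    retained.
    """
    parts = []
    for ch in sorted(resi_tables):
        t = resi_tables[ch]
        dx, dy = shifts.get(ch)  # raises on missing channel
        t = t.copy()
        t["x"] = t["x"] + dx
        t["y"] = t["y"] + dy
        parts.append(t)
    if not parts:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in RESI_COLUMNS})
    return pd.concat(parts, ignore_index=True)


# --------------------------------------------------------------------------
# parameter suggestion rules
# --------------------------------------------------------------------------

def suggest_radius(precisions: np.ndarray, factor: float = 2.35) -> float:
    """Cluster radius rule: ``factor`` times the median localization
    precision (2.35 sigma is the FWHM of a Gaussian, a radius that captures
    a site's localizations while keeping false detections low)."""
    precisions = np.asarray(precisions, dtype=float)
    if precisions.size == 0:
        raise ValidationError("cannot suggest a radius from zero precisions")
    return float(factor * np.median(precisions))


def suggest_nmin(per_cluster_loc_counts: np.ndarray) -> int:
    """Minimum-localizations rule: ``round(mean - std)`` of a pilot pass'
    per-cluster counts, floored at 2 — the compromise between false
    positives (short nonspecific traces) and false negatives."""
    counts = np.asarray(per_cluster_loc_counts, dtype=float)
    if counts.size == 0:
        raise ValidationError("cannot suggest n_min from zero clusters")
    return max(2, int(np.rint(counts.mean() - counts.std())))
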