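"""Spatial point-pattern statistics of super-resolved sugar positions.

Quantifies how sugar sites are organized relative to complete spatial
randomness (CSR):

* DBSCAN clustering of site positions (epsilon = 10 nm, minPts = 2 by
  default) and cluster-size statistics;
* selection of N analysis areas (0.5 um^2 squares) of apparently
  homogeneous density;
* matched-count CSR reference simulations per area;
* the Delta-clustered statistic — the relative excess of the clustered
  fraction over its CSR mean — with one-sample (vs 0, one-sided) and
  two-sample (Welch, two-sided) t-tests;
* 1st..Kth nearest-neighbour distance (NND) distributions with the
  closed-form 2-D Poisson reference curves.

``min_pts`` counts the point itself, so minPts = 2 means "at least one
neighbour within epsilon" and clusters are exactly the connected
components of the epsilon-neighbourhood graph.  DBSCAN is computed here
from that graph (scipy KD-tree pairs + sparse connected components), which
keeps label assignment deterministic (components ordered by lowest member
index) and supports toroidal geometry for the null simulations; the
scikit-learn implementation serves as an independent cross-check in the
test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .io_formats import DbscanConfig, ValidationError, get_logger

__all__ = [
    "AreaPick",
    "ClusterStats",
    "CsrReference",
    "DeltaClustered",
    "NndResult",
    "TestResult",
    "dbscan_cluster",
    "cluster_size_stats",
    "pick_areas",
    "simulate_csr_reference",
    "delta_clustered",
    "knn_distances",
    "nnd_analytic_csr",
    "nnd_mean_csr",
    "compare_conditions",
]

NM2_PER_UM2 = 1e6


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass
class AreaPick:
    """One analysis square: origin (lower-left, nm), side (nm), members."""

    origin: tuple[float, float]
    side: float
    indices: np.ndarray


@dataclass
class ClusterStats:
    """DBSCAN cluster-size statistics of one point set."""

    labels: np.ndarray
    size_hist: dict[int, int]
    f_clustered: float  # fraction of records in clusters of size >= 2
    density: float  # records per um^2
    n_records: int
    n_noise: int


@dataclass
class CsrReference:
    """Matched-count CSR replicates for one observed point set."""

    f_clustered: np.ndarray  # per replicate
    size_hists: list[dict[int, int]]
    nnd: np.ndarray  # pooled (n_reps * n_points, k_max) distances
    f_mean: float
    f_std: float
    n_reps: int
    seed: int | None


@dataclass
class DeltaClustered:
    """Relative excess of clustered fraction over CSR, per analysis area."""

    deltas: np.ndarray
    abs_deltas: np.ndarray  # absolute differences f_data - f_csr, also logged
    mean: float
    sem: float
    n_areas: int


@dataclass
class NndResult:
    """kth nearest-neighbour distances (columns k=1..k_max) and histograms."""

    distances: np.ndarray  # (n_points, k_max)
    k_max: int
    bin_width: float

    def histogram(self, k: int, d_max: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        if not 1 <= k <= self.k_max:
            raise ValidationError(f"k={k} outside 1..{self.k_max}")
        d = self.distances[:, k - 1]
        hi = float(d.max()) if d_max is None else d_max
        edges = np.arange(0.0, hi + self.bin_width, self.bin_width)
        counts, edges = np.histogram(d, bins=edges)
        return counts, edges


@dataclass
class TestResult:
    statistic: float
    p_value: float
    sidedness: str
    dof: float
    label: str
    flagged: bool = False


# --------------------------------------------------------------------------
# DBSCAN
# --------------------------------------------------------------------------

def _epsilon_pairs(points: np.ndarray, epsilon: float, box: tuple[float, float] | None) -> np.ndarray:
    if box is not None:
        b = np.asarray(box, dtype=float)
        tree = cKDTree(np.mod(points, b), boxsize=b)
    else:
        tree = cKDTree(points)
    return tree.query_pairs(epsilon, output_type="ndarray")


def dbscan_cluster(
    points: np.ndarray | pd.DataFrame,
    params: DbscanConfig | None = None,
    box: tuple[float, float] | None = None,
) -> np.ndarray:
    """DBSCAN labels (-1 = noise), deterministic and optionally toroidal.

    Core points have at least ``min_pts`` points (themselves included)
    within ``epsilon``; clusters are connected components of the core-core
    epsilon graph, border points join the cluster of their lowest-index
    core neighbour, and clusters are numbered by their lowest member index.
    With ``min_pts=2`` this is exactly the connected components of the
    epsilon-neighbourhood graph, isolated points being noise.  ``box``
    switches to toroidal distances on the given (width, height).
    """
    params = params or DbscanConfig()
    if params.epsilon <= 0:
        raise ValidationError("epsilon must be positive")
    if params.min_pts < 2:
        raise ValidationError("min_pts must be >= 2")
    if isinstance(points, pd.DataFrame):
        points = points[["x", "y"]].to_numpy()
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if not np.isfinite(points).all():
        raise ValidationError("non-finite coordinates")

    pairs = _epsilon_pairs(points, params.epsilon, box)
    counts = np.ones(n, dtype=np.int64)
    if pairs.size:
        np.add.at(counts, pairs[:, 0], 1)
        np.add.at(counts, pairs[:, 1], 1)
    core = counts >= params.min_pts

    labels = np.full(n, -1, dtype=np.int64)
    if core.any():
        if pairs.size:
            cc_mask = core[pairs[:, 0]] & core[pairs[:, 1]]
            cc = pairs[cc_mask]
        else:
            cc = np.empty((0, 2), dtype=np.int64)
        core_idx = np.flatnonzero(core)
        pos = np.full(n, -1, dtype=np.int64)
        pos[core_idx] = np.arange(core_idx.size)
        adj = coo_matrix(
            (np.ones(cc.shape[0]), (pos[cc[:, 0]], pos[cc[:, 1]])),
            shape=(core_idx.size, core_idx.size),
        )
        _, comp = connected_components(adj, directed=False)
        labels[core_idx] = comp
        # border points: non-core with a core neighbour -> lowest-index core nbr
        if pairs.size:
            border_mask = core[pairs[:, 0]] ^ core[pairs[:, 1]]
            bp = pairs[border_mask]
            # orient as (border, core)
            flip = core[bp[:, 0]]
            bp[flip] = bp[flip][:, ::-1]
            order = np.lexsort((bp[:, 1], bp[:, 0]))
            bp = bp[order]
            first = np.unique(bp[:, 0], return_index=True)[1]
            labels[bp[first, 0]] = labels[bp[first, 1]]
    # renumber by lowest member index
    assigned = labels >= 0
    if assigned.any():
        first_idx: dict[int, int] = {}
        for i in np.flatnonzero(assigned):
            first_idx.setdefault(int(labels[i]), int(i))
        order = sorted(first_idx, key=first_idx.get)
        remap = {old: new for new, old in enumerate(order)}
        labels[assigned] = np.array([remap[int(l)] for l in labels[assigned]])
    return labels


def cluster_size_stats(labels: np.ndarray, area_nm2: float) -> ClusterStats:
    """Cluster-size histogram, clustered fraction and density of one set."""
    labels = np.asarray(labels)
    n = labels.size
    n_noise = int((labels == -1).sum())
    sizes = np.bincount(labels[labels >= 0]) if n - n_noise else np.empty(0, dtype=int)
    hist: dict[int, int] = {}
    for s in sizes:
        if s > 0:
            hist[int(s)] = hist.get(int(s), 0) + 1
    n_clustered = int(sizes[sizes >= 2].sum()) if sizes.size else 0
    return ClusterStats(
        labels=labels,
        size_hist=hist,
        f_clustered=n_clustered / n if n else 0.0,
        density=n / (area_nm2 / NM2_PER_UM2) if area_nm2 > 0 else float("nan"),
        n_records=n,
        n_noise=n_noise,
    )


# --------------------------------------------------------------------------
# area picking
# --------------------------------------------------------------------------

def pick_areas(
    table: pd.DataFrame,
    n_areas: int,
    side: float,
    fov: tuple[float, float],
    density_band: tuple[float, float] = (0.5, 1.5),
    seed: int | np.random.SeedSequence = 0,
    rois: list[tuple[float, float]] | None = None,
) -> list[AreaPick]:
    """Select non-overlapping square analysis areas of homogeneous density.

    Candidate squares tile the FOV from the origin; squares whose record
    density lies within ``density_band`` times the median candidate density
    are eligible, and ``n_areas`` of them are sampled without replacement.
    An explicit ``rois`` list of lower-left origins bypasses selection.
    """
    x = table["x"].to_numpy()
    y = table["y"].to_numpy()
    if rois is not None:
        picks = []
        for ox, oy in rois:
            idx = np.flatnonzero((x >= ox) & (x < ox + side) & (y >= oy) & (y < oy + side))
            picks.append(AreaPick(origin=(ox, oy), side=side, indices=idx))
        return picks

    nx = int(fov[0] // side)
    ny = int(fov[1] // side)
    if nx * ny < n_areas:
        raise ValidationError(
            f"FOV holds only {nx * ny} candidate squares of side {side}; {n_areas} requested"
        )
    ix = np.floor(x / side).astype(int)
    iy = np.floor(y / side).astype(int)
    valid = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    cell = ix * ny + iy
    counts = np.bincount(cell[valid], minlength=nx * ny)
    median = np.median(counts)
    lo, hi = density_band
    eligible = np.flatnonzero((counts >= lo * median) & (counts <= hi * median))
    if eligible.size < n_areas:
        raise ValidationError(
            f"only {eligible.size} squares within the density band; {n_areas} requested"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(eligible, size=n_areas, replace=False)
    picks = []
    for c in sorted(int(c) for c in chosen):
        cx, cy = divmod(c, ny)
        idx = np.flatnonzero(valid & (cell == c))
        picks.append(AreaPick(origin=(cx * side, cy * side), side=side, indices=idx))
    return picks


# --------------------------------------------------------------------------
# CSR reference and Delta clustered
# --------------------------------------------------------------------------

def simulate_csr_reference(
    n_points: int,
    area: tuple[float, float],
    params: DbscanConfig | None = None,
    k_max: int = 4,
    n_reps: int = 100,
    seed: int | np.random.SeedSequence = 0,
    toroidal: bool = True,
) -> CsrReference:
    """Matched-count CSR replicates: the null for one observed point set.

    Each replicate draws exactly ``n_points`` uniform points on ``area``
    (conditioning on the observed count removes count noise from the null)
    and computes cluster statistics and kth-NND samples, toroidally by
    default to avoid edge bias.
    """
    if n_points < 2:
        raise ValidationError("n_points must be >= 2")
    if n_reps < 2:
        raise ValidationError("n_reps must be >= 2 (s.d. undefined otherwise)")
    params = params or DbscanConfig()
    rng = np.random.default_rng(seed)
    box = tuple(area) if toroidal else None
    f_vals = np.empty(n_reps)
    hists: list[dict[int, int]] = []
    nnds = []
    area_nm2 = area[0] * area[1]
    k_eff = min(k_max, n_points - 1)
    for rep in range(n_reps):
        pts = np.column_stack(
            [rng.uniform(0.0, area[0], size=n_points), rng.uniform(0.0, area[1], size=n_points)]
        )
        labels = dbscan_cluster(pts, params, box=box)
        cs = cluster_size_stats(labels, area_nm2)
        f_vals[rep] = cs.f_clustered
        hists.append(cs.size_hist)
        if k_eff >= 1:
            nnds.append(knn_distances(pts, k_max=k_eff, mode="toroidal" if toroidal else "plain",
                                      box=box).distances)
    nnd = np.vstack(nnds) if nnds else np.empty((0, k_max))
    return CsrReference(
        f_clustered=f_vals,
        size_hists=hists,
        nnd=nnd,
        f_mean=float(f_vals.mean()),
        f_std=float(f_vals.std(ddof=1)),
        n_reps=n_reps,
        seed=seed if isinstance(seed, int) else None,
    )


def delta_clustered(
    area_stats: list[ClusterStats],
    refs: list[CsrReference],
) -> DeltaClustered:
    """Per-area Delta = (f_data - f_CSR_mean) / f_CSR_mean, with mean and
    s.e.m. over areas; areas whose CSR mean is zero are excluded (logged)."""
    if len(area_stats) != len(refs):
        raise ValidationError("need one CSR reference per area")
    log = get_logger("stats")
    deltas, abs_deltas = [], []
    for i, (cs, ref) in enumerate(zip(area_stats, refs)):
        if ref.f_mean == 0.0:
            log.warning("area %d: CSR clustered fraction is 0; Delta undefined, excluded", i)
            continue
        deltas.append((cs.f_clustered - ref.f_mean) / ref.f_mean)
        abs_deltas.append(cs.f_clustered - ref.f_mean)
    if not deltas:
        raise ValidationError("Delta clustered undefined for every area")
    d = np.asarray(deltas)
    return DeltaClustered(
        deltas=d,
        abs_deltas=np.asarray(abs_deltas),
        mean=float(d.mean()),
        sem=float(d.std(ddof=1) / math.sqrt(d.size)) if d.size > 1 else float("nan"),
        n_areas=d.size,
    )


# --------------------------------------------------------------------------
# nearest-neighbour distances
# --------------------------------------------------------------------------

def knn_distances(
    points: np.ndarray | pd.DataFrame,
    k_max: int = 4,
    mode: str = "plain",
    box: tuple[float, float] | None = None,
    bin_width: float = 0.5,
) -> NndResult:
    """Distances from every point to its 1st..k_max-th nearest neighbour."""
    if isinstance(points, pd.DataFrame):
        points = points[["x", "y"]].to_numpy()
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    if n < k_max + 1:
        raise ValidationError(f"need at least {k_max + 1} points for k_max={k_max}")
    if mode == "toroidal":
        if box is None:
            raise ValidationError("toroidal mode requires a box")
        b = np.asarray(box, dtype=float)
        pts = np.mod(points, b)
        tree = cKDTree(pts, boxsize=b)
        d, _ = tree.query(pts, k=k_max + 1)
    elif mode == "plain":
        tree = cKDTree(points)
        d, _ = tree.query(points, k=k_max + 1)
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return NndResult(distances=d[:, 1:], k_max=k_max, bin_width=bin_width)


def nnd_analytic_csr(
    density: float,
    k: int,
    d_grid: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form kth-NND law of a 2-D Poisson process.

    With intensity lambda (``density`` in um^-2, converted to nm^-2) the
    kth-NND cdf is ``F_k(d) = P(N(disc_d) >= k) = P(k, lambda*pi*d^2)``
    (regularized lower incomplete gamma), equivalently
    ``1 - exp(-m) * sum_{j<k} m^j/j!`` with ``m = lambda*pi*d^2``; the pdf
    is its derivative.  Returns (pdf, cdf) on ``d_grid`` (nm).
    """
    if density <= 0:
        raise ValidationError("density must be positive")
    if k < 1:
        raise ValidationError("k must be >= 1")
    lam = density / NM2_PER_UM2
    d = np.asarray(d_grid, dtype=float)
    m = lam * math.pi * d**2
    cdf = special.gammainc(k, m)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pdf = np.log(2 * lam * math.pi * d) + (k - 1) * np.log(m) - m - special.gammaln(k)
        pdf = np.where(d > 0, np.exp(log_pdf), 0.0)
    return pdf, cdf


def nnd_mean_csr(density: float, k: int = 1) -> float:
    """Mean kth-NND of a 2-D Poisson process; for k=1 this is 1/(2 sqrt(lambda))."""
    if density <= 0:
        raise ValidationError("density must be positive")
    lam = density / NM2_PER_UM2
    # E[D_k] = Gamma(k + 1/2) / (Gamma(k) * sqrt(lambda * pi))
    return float(
        math.exp(special.gammaln(k + 0.5) - special.gammaln(k)) / math.sqrt(lam * math.pi)
    )


# --------------------------------------------------------------------------
# hypothesis tests
# --------------------------------------------------------------------------

def compare_conditions(
    deltas_a: DeltaClustered | np.ndarray,
    deltas_b: DeltaClustered | np.ndarray | None = None,
) -> TestResult:
    """Student t-tests on Delta-clustered samples.

    Against the null value 0 (``deltas_b=None``): one-sample t-test,
    one-sided with H1: mean > 0.  Between two conditions: two-sample Welch
    (unequal-variance) t-test, two-sided.  A zero-variance sample is
    handled degenerately (p -> 0 or 1) and flagged.
    """
    a = deltas_a.deltas if isinstance(deltas_a, DeltaClustered) else np.asarray(deltas_a, float)
    if a.size < 2:
        raise ValidationError("need at least 2 values per sample")
    if deltas_b is None:
        if a.std(ddof=1) == 0.0:
            p = 0.0 if a.mean() > 0 else 1.0
            stat = math.inf if a.mean() > 0 else (-math.inf if a.mean() < 0 else 0.0)
            return TestResult(stat, p, "one-sided", float(a.size - 1),
                             "delta vs 0 (degenerate variance)", flagged=True)
        res = stats.ttest_1samp(a, 0.0, alternative="greater")
        return TestResult(float(res.statistic), float(res.pvalue), "one-sided",
                          float(res.df), "delta vs 0")
    b = deltas_b.deltas if isinstance(deltas_b, DeltaClustered) else np.asarray(deltas_b, float)
    if b.size < 2:
        raise ValidationError("need at least 2 values per sample")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        equal = a.mean() == b.mean()
        return TestResult(0.0 if equal else math.inf, 1.0 if equal else 0.0, "two-sided",
                          float(a.size + b.size - 2), "condition A vs B (degenerate variance)",
                          flagged=True)
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue), "two-sided",
                      float(res.df), "condition A vs B")
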