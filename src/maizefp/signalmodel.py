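"""Normalized polar intensity space, cluster files, and genotype calling.

Two-channel signals (X = A-allele channel, Y = B-allele channel) are
mapped to ``theta = (2/pi)*arctan(y/x)`` in [0, 1] — 0 for a pure A
signal, 1 for pure B, 0.5 for a balanced heterozygote — and a total
signal ``r = x + y`` (Manhattan convention, matching the angle
normalization; a Euclidean radius is available behind a switch).

A :class:`ClusterFile` stores, per locus, three genotype call regions in
theta with a signal floor. Construction follows four rules: call regions
must be disjoint; the missing rate is minimized subject to that; region
centers default to the canonical 0 / 0.5 / 1.0 positions; and a center
is shifted to the observed cluster mean when enough points support it.
Calling a point assigns the unique region containing its theta whose
floor it exceeds, otherwise "failed" (NC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import GENOTYPES, NO_CALL, decode_calls

__all__ = [
    "to_theta_r",
    "ClusterRegion",
    "LocusClusters",
    "ClusterFile",
    "ClusterBuildConfig",
    "build_cluster_file",
    "call_genotypes",
    "CallResult",
]

#: canonical theta centers for AA, AB, BB
CANONICAL_CENTERS = (0.0, 0.5, 1.0)


def to_theta_r(x_signal, y_signal, *, radius: str = "manhattan"):
    """Polar transform of two-channel intensities.

    Returns ``(theta, r)`` with ``theta = (2/pi)*arctan(y/x)`` in [0, 1]
    and ``r = x + y`` (or the Euclidean norm when ``radius='euclidean'``).
    Accepts scalars or arrays. A point with both channels zero has no
    defined angle and raises ``ValueError`` (array inputs: any such
    element raises; callers that want an NC instead should pre-filter).
    """
    x = np.asarray(x_signal, dtype=float)
    y = np.asarray(y_signal, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("channel intensities must be nonnegative")
    both_zero = (x == 0) & (y == 0)
    if both_zero.any():
        raise ValueError("theta undefined for points with x = y = 0")
    theta = (2.0 / math.pi) * np.arctan2(y, x)
    if radius == "manhattan":
        r = x + y
    elif radius == "euclidean":
        r = np.hypot(x, y)
    else:
        raise ValueError(f"unknown radius convention {radius!r}")
    if theta.ndim == 0:
        return float(theta), float(r)
    return theta, r


@dataclass(frozen=True)
class ClusterRegion:
    """One genotype call region on the theta axis."""

    genotype: str
    theta_center: float
    theta_halfwidth: float
    r_floor: float
    occupied: bool

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.theta_halfwidth <= 0:
            raise ValueError("theta_halfwidth must be > 0")


@dataclass(frozen=True)
class LocusClusters:
    """Three ordered call regions (AA < AB < BB in theta) for one locus."""

    locus_id: str
    regions: tuple[ClusterRegion, ClusterRegion, ClusterRegion]
    r_floor: float
    weak: bool = False  # all panel points fell below the floor

    def __post_init__(self) -> None:
        centers = [r.theta_center for r in self.regions]
        if sorted(centers) != centers:
            raise ValueError(f"{self.locus_id}: regions must be ordered by theta_center")

    def bounds(self) -> np.ndarray:
        """Effective (lo, hi) per region: center +/- halfwidth, truncated
        at midpoints between adjacent centers so regions are disjoint."""
        c = np.array([r.theta_center for r in self.regions])
        h = np.array([r.theta_halfwidth for r in self.regions])
        lo = c - h
        hi = c + h
        mid01 = 0.5 * (c[0] + c[1])
        mid12 = 0.5 * (c[1] + c[2])
        hi[0] = min(hi[0], mid01)
        lo[1] = max(lo[1], mid01)
        hi[1] = min(hi[1], mid12)
        lo[2] = max(lo[2], mid12)
        return np.column_stack([lo, hi])


@dataclass
class ClusterFile:
    """Per-locus cluster geometry used for automatic genotype calling."""

    loci: dict[str, LocusClusters]
    provenance: dict = field(default_factory=dict)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self.loci

    def __getitem__(self, locus_id: str) -> LocusClusters:
        return self.loci[locus_id]

    def __len__(self) -> int:
        return len(self.loci)


@dataclass(frozen=True)
class ClusterBuildConfig:
    """Knobs for cluster-file construction.

    r_floor_frac
        per-locus signal floor as a fraction of the locus median R.
    r_floor_abs
        absolute lower bound on the floor, so loci whose every point is
        weak are flagged rather than rescaled into callability.
    min_halfwidth
        minimum region halfwidth (also the width of default regions for
        genotypes unobserved in the build panel, so rare heterozygotes
        remain callable later).
    shift_min_support
        minimum points in a cluster before its center is shifted from
        the canonical position to the observed mean.
    """

    r_floor_frac: float = 0.20
    r_floor_abs: float = 0.20
    min_halfwidth: float = 0.05
    sd_multiplier: float = 3.0
    shift_min_support: int = 3
    max_iter: int = 50
    radius: str = "manhattan"


def _theta_r_zero_as_nan(x, y, radius):
    # bulk variant: a dead point (x = y = 0) has no angle and is treated
    # as a failed measurement (theta NaN, r 0) instead of raising
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dead = (x == 0) & (y == 0)
    if dead.any():
        x = np.where(dead, 1.0, x)
        theta, r = to_theta_r(x, y, radius=radius)
        theta = np.where(dead, np.nan, theta)
        r = np.where(dead, 0.0, r)
        return theta, r
    return to_theta_r(x, y, radius=radius)


def _seeded_three_means(thetas: np.ndarray, max_iter: int) -> tuple[np.ndarray, np.ndarray]:
    """One-dimensional three-means with fixed seeds at 0, 0.5, 1.0.

    Returns (centers, labels). A cluster that captures no points keeps
    its canonical seed (callers mark it unoccupied); this preserves the
    genotype identity of each slot, which generic k-means (with empty-
    cluster relocation) would not.
    """
    centers = np.array(CANONICAL_CENTERS, dtype=float)
    labels = np.zeros(len(thetas), dtype=np.int8)
    for _ in range(max_iter):
        d = np.abs(thetas[:, None] - centers[None, :])
        new_labels = np.argmin(d, axis=1).astype(np.int8)
        new_centers = centers.copy()
        for k in range(3):
            pts = thetas[new_labels == k]
            if len(pts):
                new_centers[k] = pts.mean()
        if np.array_equal(new_labels, labels) and np.allclose(new_centers, centers):
            break
        labels, centers = new_labels, new_centers
    # 1-D Lloyd from ordered seeds keeps center order; guard regardless
    order = np.argsort(centers, kind="stable")
    centers = centers[order]
    labels = np.argsort(order)[labels].astype(np.int8)
    return centers, labels


def build_cluster_file(
    intensities: pd.DataFrame,
    sample_meta: pd.DataFrame | None = None,
    build_config: ClusterBuildConfig | None = None,
    *,
    provenance: dict | None = None,
) -> ClusterFile:
    """Construct a cluster file from a labeled build panel.

    ``intensities`` is long-format (sample_id, locus_id, x, y). Per
    locus: points below the signal floor are excluded; remaining thetas
    are clustered by seeded one-dimensional three-means anchored at the
    canonical 0 / 0.5 / 1.0 genotype positions; occupied clusters with at
    least ``shift_min_support`` points get their observed mean as center,
    smaller or empty ones keep the canonical center as an (unoccupied)
    default region. Region halfwidth is ``max(sd_multiplier * SD,
    min_halfwidth)``; disjointness is enforced by truncating at midpoints
    between adjacent centers at call time.
    """
    cfg = build_config or ClusterBuildConfig()
    theta, r = _theta_r_zero_as_nan(intensities["x"].to_numpy(),
                                    intensities["y"].to_numpy(), cfg.radius)
    df = pd.DataFrame({
        "locus_id": intensities["locus_id"].to_numpy(),
        "theta": theta,
        "r": r,
    })

    loci: dict[str, LocusClusters] = {}
    for locus_id, grp in df.groupby("locus_id", sort=True):
        rs = grp["r"].to_numpy()
        floor = max(cfg.r_floor_frac * float(np.median(rs)), cfg.r_floor_abs)
        keep = rs >= floor
        thetas = grp["theta"].to_numpy()[keep]
        if len(thetas) == 0:
            regions = tuple(
                ClusterRegion(g, CANONICAL_CENTERS[k], cfg.min_halfwidth, floor, False)
                for k, g in enumerate(GENOTYPES)
            )
            loci[str(locus_id)] = LocusClusters(str(locus_id), regions, floor, weak=True)
            continue
        centers, labels = _seeded_three_means(thetas, cfg.max_iter)
        regions = []
        for k, g in enumerate(GENOTYPES):
            pts = thetas[labels == k]
            occupied = len(pts) > 0
            if len(pts) >= cfg.shift_min_support:
                center = float(pts.mean())
                halfwidth = max(cfg.sd_multiplier * float(pts.std(ddof=0)), cfg.min_halfwidth)
            else:
                # too little evidence to shift the center off its canonical
                # position, but the region still widens to cover the observed
                # points (missing rate is minimized subject to disjointness)
                center = CANONICAL_CENTERS[k]
                halfwidth = cfg.min_halfwidth
                if len(pts):
                    halfwidth = max(halfwidth,
                                    float(np.abs(pts - center).max()) + 1e-9)
            regions.append(ClusterRegion(g, center, halfwidth, floor, occupied))
        regions.sort(key=lambda reg: (reg.theta_center, reg.genotype))
        # keep genotype identity AA<AB<BB even if shifted centers crossed
        regions = tuple(
            ClusterRegion(g, reg.theta_center, reg.theta_halfwidth, reg.r_floor, reg.occupied)
            for g, reg in zip(GENOTYPES, regions)
        )
        loci[str(locus_id)] = LocusClusters(str(locus_id), regions, floor)

    prov = dict(provenance or {})
    prov.setdefault("n_points", int(len(df)))
    prov.setdefault("n_samples", int(intensities["sample_id"].nunique()))
    prov.setdefault("config", cfg.__dict__.copy())
    return ClusterFile(loci=loci, provenance=prov)


@dataclass
class CallResult:
    """Genotype calls and per-call confidences (samples x loci)."""

    calls: pd.DataFrame
    confidence: pd.DataFrame


def call_genotypes(intensities: pd.DataFrame, cluster_file: ClusterFile) -> CallResult:
    """Call genotypes for a long-format intensity table against a cluster file.

    A point is assigned the region whose effective theta interval
    contains it and whose floor its total signal exceeds; with more than
    one candidate (shared boundary) the nearer center wins and an exact
    midpoint goes to the lower-theta region. Points matching no region
    are NC. Confidence is ``1 - min(|theta - center| / halfwidth, 1)``.
    """
    missing = sorted(set(intensities["locus_id"]) - set(cluster_file.loci))
    if missing:
        raise KeyError(f"loci absent from cluster file: {missing[:10]}"
                       + ("..." if len(missing) > 10 else ""))

    radius = cluster_file.provenance.get("config", {}).get("radius", "manhattan")
    theta, r = _theta_r_zero_as_nan(intensities["x"].to_numpy(),
                                    intensities["y"].to_numpy(), radius)
    sample_ids = pd.unique(intensities["sample_id"])
    locus_ids = pd.unique(intensities["locus_id"])
    s_idx = pd.Index(sample_ids).get_indexer(intensities["sample_id"])
    l_idx = pd.Index(locus_ids).get_indexer(intensities["locus_id"])

    n_s, n_l = len(sample_ids), len(locus_ids)
    T = np.full((n_s, n_l), np.nan)
    R = np.full((n_s, n_l), np.nan)
    T[s_idx, l_idx] = theta
    R[s_idx, l_idx] = r

    centers = np.empty((3, n_l))
    halfw = np.empty((3, n_l))
    lo = np.empty((3, n_l))
    hi = np.empty((3, n_l))
    floors = np.empty(n_l)
    for j, lid in enumerate(locus_ids):
        lc = cluster_file[lid]
        b = lc.bounds()
        for k in range(3):
            centers[k, j] = lc.regions[k].theta_center
            halfw[k, j] = lc.regions[k].theta_halfwidth
            lo[k, j], hi[k, j] = b[k]
        floors[j] = lc.r_floor

    dist = np.abs(T[None, :, :] - centers[:, None, :])  # (3, n_s, n_l)
    inside = (T[None, :, :] >= lo[:, None, :]) & (T[None, :, :] <= hi[:, None, :])
    above = R[None, :, :] >= floors[None, None, :]
    eligible = inside & above
    dist_masked = np.where(eligible, dist, np.inf)
    best = np.argmin(dist_masked, axis=0)  # ties -> lowest index = lower theta center
    any_ok = eligible.any(axis=0) & np.isfinite(T)

    codes = np.where(any_ok, best, -1).astype(np.int8)
    conf = np.clip(1.0 - np.take_along_axis(dist, best[None], axis=0)[0]
                   / np.take_along_axis(halfw[:, None, :].repeat(n_s, axis=1),
                                        best[None], axis=0)[0], 0.0, 1.0)
    conf = np.where(any_ok, conf, 0.0)
    conf = np.where(np.isfinite(T), conf, 0.0)

    calls = decode_calls(codes, index=list(sample_ids), columns=list(locus_ids))
    confidence = pd.DataFrame(conf, index=list(sample_ids), columns=list(locus_ids))
    return CallResult(calls=calls, confidence=confidence)
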