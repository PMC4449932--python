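"""Per-locus genotyping quality scores and defect detection.

The composite quality score is an open analog of the proprietary
clustering-quality score used by array genotyping software. It is the
geometric mean of four subscores on [0, 1], derived from the same four
cluster characteristics that score advertises — angle (separation of
adjacent cluster centers), dispersion (within-cluster tightness),
overlap (points intruding into a neighboring cluster's band), and
intensity (fraction of points above the signal floor). Values are
comparable within this package only, not to any vendor's score.

Defect detection recovers the classic failure patterns of array
markers: all-weak signal, excess failed samples, pedigree-inconsistent
parent/F1 trios, heterozygous calls in inbred lines, and clusters
shifted away from their canonical angles. All count thresholds are
strict ("more than N"), so a locus exactly at a threshold is not
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import GENOTYPES, NO_CALL
from .signalmodel import CANONICAL_CENTERS, ClusterFile, LocusClusters, _theta_r_zero_as_nan

__all__ = [
    "QcThresholds",
    "LocusQuality",
    "quality_score",
    "detect_defects",
    "reproducibility",
    "score_panel",
]


@dataclass(frozen=True)
class QcThresholds:
    """Defect-detection thresholds (all strict inequalities).

    high_missing_rate
        flag when the failed-sample fraction exceeds this rate (0.05;
        the count form "more than 5 of 96" is its instantiation).
    pedigree_fail_triplets / het_inbred_count
        flag when more than this many trios are Mendelian-inconsistent /
        more than this many inbred lines are heterozygous.
    shifted_tolerance
        flag when an occupied center deviates more than this from its
        canonical 0 / 0.5 / 1.0 position.
    dispersion_cap
        within-cluster theta SD at which the dispersion subscore reaches 0.
    """

    high_missing_rate: float = 0.05
    pedigree_fail_triplets: int = 3
    het_inbred_count: int = 5
    shifted_tolerance: float = 0.15
    dispersion_cap: float = 0.10

    def __post_init__(self) -> None:
        if self.high_missing_rate < 0 or self.shifted_tolerance < 0:
            raise ValueError("rate thresholds must be nonnegative")
        if self.pedigree_fail_triplets < 0 or self.het_inbred_count < 0:
            raise ValueError("count thresholds must be nonnegative integers")


@dataclass
class LocusQuality:
    """Quality subscores, composite, and defect flags for one locus."""

    locus_id: str
    quality_score: float
    angle_separation: float
    dispersion: float
    overlap: float
    intensity: float
    missing_count: int = 0
    missing_rate: float = 0.0
    het_inbred_count: int = 0
    inconsistent_triplet_count: int = 0
    reproducibility: float = float("nan")
    defect_flags: set[str] = field(default_factory=set)


def quality_score(
    theta: np.ndarray,
    r: np.ndarray,
    clusters: LocusClusters,
    thresholds: QcThresholds | None = None,
    *,
    locus_id: str = "",
) -> LocusQuality:
    """Compute the four subscores and their geometric-mean composite.

    * angle_separation — minimum gap between adjacent *occupied* centers,
      normalized by the ideal half-spacing 0.5 (1 when fewer than two
      genotypes are present);
    * dispersion — ``1 - mean within-cluster theta SD / cap``;
    * overlap — 1 minus the fraction of above-floor points lying inside
      another occupied region's untruncated band (center +/- halfwidth);
    * intensity — fraction of points at or above the signal floor.

    A locus whose every point is below the floor scores 0 and carries the
    ``weak_signal`` flag.
    """
    th = thresholds or QcThresholds()
    theta = np.asarray(theta, dtype=float)
    r = np.asarray(r, dtype=float)
    if len(theta) < 2:
        raise ValueError("quality_score needs at least 2 points")

    floor = clusters.r_floor
    above = (r >= floor) & np.isfinite(theta)
    intensity = float(above.mean())
    if not above.any():
        return LocusQuality(locus_id, 0.0, 0.0, 0.0, 0.0, 0.0,
                            defect_flags={"weak_signal"})

    t = theta[above]
    centers = np.array([reg.theta_center for reg in clusters.regions])
    halfw = np.array([reg.theta_halfwidth for reg in clusters.regions])
    occ = np.array([reg.occupied for reg in clusters.regions])

    # assignment by nearest center, for dispersion/overlap measurement
    labels = np.argmin(np.abs(t[:, None] - centers[None, :]), axis=1)

    occ_centers = np.sort(centers[occ])
    if len(occ_centers) >= 2:
        angle = float(min(np.min(np.diff(occ_centers)) / 0.5, 1.0))
    else:
        angle = 1.0

    sds = [t[labels == k].std(ddof=0) for k in range(3) if (labels == k).sum() > 0]
    dispersion = float(np.clip(1.0 - np.mean(sds) / th.dispersion_cap, 0.0, 1.0))

    # a point "overlaps" when it falls inside the raw band of an occupied
    # region other than its own
    in_band = np.abs(t[:, None] - centers[None, :]) <= halfw[None, :]
    other = in_band & occ[None, :]
    other[np.arange(len(t)), labels] = False
    overlap = float(1.0 - other.any(axis=1).mean())

    composite = float(np.clip((max(angle, 0.0) * dispersion * overlap * intensity) ** 0.25, 0.0, 1.0))
    return LocusQuality(locus_id, composite, angle, dispersion, overlap, intensity)


def detect_defects(
    r: np.ndarray,
    calls: pd.Series,
    sample_meta: pd.DataFrame,
    clusters: LocusClusters,
    thresholds: QcThresholds | None = None,
    *,
    trios: list[tuple[str, str, str]] | None = None,
) -> tuple[set[str], dict]:
    """Flag the five defect classes for one locus.

    ``r`` holds the per-point total signals; ``calls`` is indexed by
    sample_id; ``sample_meta`` needs ``role`` (inbred/hybrid) and, for
    pedigree checks, the trios. Returns the flag set plus counters
    (missing count/rate, het-inbred count, inconsistent-trio count).
    Thresholds are strict: a locus exactly at a boundary is not flagged.
    """
    from .fingerprint_eval import _mendelian_consistent

    import math

    th = thresholds or QcThresholds()
    flags: set[str] = set()
    n = len(calls)
    missing = int((calls == NO_CALL).sum())
    rate = missing / n if n else 0.0
    # count semantics: "more than 5 of 96" keeps a locus with exactly 5
    # failures even though 5/96 > 5 %, so the allowance is ceil(rate * n)
    if missing > math.ceil(th.high_missing_rate * n):
        flags.add("high_missing")

    if clusters.weak or float(np.median(np.asarray(r, dtype=float))) < clusters.r_floor:
        flags.add("weak_signal")

    inbred_ids = sample_meta.index[sample_meta["role"] == "inbred"]
    het_count = int((calls.reindex(inbred_ids) == "AB").sum())
    if het_count > th.het_inbred_count:
        flags.add("het_inbred")

    bad_trios = 0
    for p1, p2, f1 in trios or []:
        g = [calls.get(p1, NO_CALL), calls.get(p2, NO_CALL), calls.get(f1, NO_CALL)]
        if NO_CALL in g:
            continue
        if not _mendelian_consistent(g[0], g[1], g[2]):
            bad_trios += 1
    if bad_trios > th.pedigree_fail_triplets:
        flags.add("pedigree_fail")

    for k, reg in enumerate(clusters.regions):
        if reg.occupied and abs(reg.theta_center - CANONICAL_CENTERS[k]) > th.shifted_tolerance:
            flags.add("shifted")
            break

    counters = {
        "missing_count": missing,
        "missing_rate": rate,
        "het_inbred_count": het_count,
        "inconsistent_triplet_count": bad_trios,
    }
    return flags, counters


def reproducibility(calls: pd.DataFrame, duplicate_pairs: list[tuple[str, str]]) -> pd.Series:
    """Per-locus duplicate-sample concordance.

    For each locus: the fraction of duplicate pairs whose two calls are
    identical and non-NC; pairs with any NC at the locus are excluded
    from the denominator. A locus with no informative pair gets NaN (it
    is not penalized downstream).
    """
    if not duplicate_pairs:
        raise ValueError("reproducibility needs at least one duplicate pair")
    agree = np.zeros(calls.shape[1])
    informative = np.zeros(calls.shape[1])
    for a, b in duplicate_pairs:
        ca = calls.loc[a].to_numpy()
        cb = calls.loc[b].to_numpy()
        ok = (ca != NO_CALL) & (cb != NO_CALL)
        informative += ok
        agree += ok & (ca == cb)
    with np.errstate(invalid="ignore"):
        out = np.where(informative > 0, agree / np.maximum(informative, 1), np.nan)
    return pd.Series(out, index=calls.columns, name="reproducibility")


def score_panel(
    intensities: pd.DataFrame,
    calls: pd.DataFrame,
    cluster_file: ClusterFile,
    sample_meta: pd.DataFrame,
    thresholds: QcThresholds | None = None,
) -> pd.DataFrame:
    """QC report for every locus: subscores, composite, counters, flags.

    ``sample_meta`` is indexed by sample_id with columns ``role``,
    ``parent1_id``, ``parent2_id``, ``duplicate_of`` (empty string when
    unset). Returns one row per locus, indexed by locus_id; flags are a
    frozenset per row, reproducibility NaN when no duplicate pairs exist.
    """
    th = thresholds or QcThresholds()
    radius = cluster_file.provenance.get("config", {}).get("radius", "manhattan")
    theta, r = _theta_r_zero_as_nan(intensities["x"].to_numpy(),
                                    intensities["y"].to_numpy(), radius)
    df = pd.DataFrame({
        "locus_id": intensities["locus_id"].to_numpy(),
        "sample_id": intensities["sample_id"].to_numpy(),
        "theta": theta,
        "r": r,
    })

    ids = {s for s in sample_meta.index}
    trios = [
        (row["parent1_id"], row["parent2_id"], sid)
        for sid, row in sample_meta.iterrows()
        if row.get("role") == "hybrid"
        and row.get("parent1_id") in ids and row.get("parent2_id") in ids
    ]
    dup_pairs = [
        (row["duplicate_of"], sid)
        for sid, row in sample_meta.iterrows()
        if row.get("duplicate_of") and row["duplicate_of"] in ids
    ]
    repro = reproducibility(calls, dup_pairs) if dup_pairs else None

    rows = []
    for locus_id, grp in df.groupby("locus_id", sort=True):
        lc = cluster_file[locus_id]
        lq = quality_score(grp["theta"].to_numpy(), grp["r"].to_numpy(), lc, th,
                           locus_id=str(locus_id))
        locus_calls = calls[locus_id]
        flags, counters = detect_defects(grp["r"].to_numpy(), locus_calls,
                                         sample_meta, lc, th, trios=trios)
        lq.defect_flags |= flags
        lq.missing_count = counters["missing_count"]
        lq.missing_rate = counters["missing_rate"]
        lq.het_inbred_count = counters["het_inbred_count"]
        lq.inconsistent_triplet_count = counters["inconsistent_triplet_count"]
        if repro is not None:
            lq.reproducibility = float(repro[locus_id]) if pd.notna(repro[locus_id]) else float("nan")
        rows.append(lq)

    n_samples = len(calls.index)
    report = pd.DataFrame({
        "locus_id": [q.locus_id for q in rows],
        "n_samples": n_samples,
        "quality_score": [q.quality_score for q in rows],
        "angle_separation": [q.angle_separation for q in rows],
        "dispersion": [q.dispersion for q in rows],
        "overlap": [q.overlap for q in rows],
        "intensity": [q.intensity for q in rows],
        "missing_count": [q.missing_count for q in rows],
        "missing_rate": [q.missing_rate for q in rows],
        "het_inbred_count": [q.het_inbred_count for q in rows],
        "inconsistent_triplet_count": [q.inconsistent_triplet_count for q in rows],
        "reproducibility": [q.reproducibility for q in rows],
        "defect_flags": [frozenset(q.defect_flags) for q in rows],
    }).set_index("locus_id", drop=False)
    return report
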