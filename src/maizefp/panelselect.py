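"""Staged marker selection for a fixed fingerprinting panel.

The screen runs four nested stages over the candidate loci:

1. **clustering quality** — keep loci whose composite quality score is
   at least ``quality_min`` (boundary inclusive);
2. **data quality** — keep loci with missing rate at most
   ``missing_rate_max``, no detected defect (weak signal, excess
   missing, pedigree inconsistency, heterozygous inbreds, shifted
   clusters), and perfect duplicate reproducibility where measurable;
3. **population genetics** — drop multi-copy loci (copy number >= 2)
   and loci with minor allele frequency below ``maf_min`` (0.20 itself
   is kept), then keep the single best marker per genic region by
   category priority exon > promoter > utr3 > utr5 > intron, ties
   broken by quality score then position;
4. **assay designability** — drop scores strictly below
   ``designability_delete_below``; if survivors still exceed the target
   panel size, trim to size preferring well-designable (>= 0.60),
   high-quality markers while keeping the per-window genomic
   distribution as even as possible.

Every removed locus is labeled with its *first* failing criterion, and
the stage survivor sets are nested by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import GENIC_PRIORITY

__all__ = [
    "SelectionConfig",
    "PanelReport",
    "stage1_quality",
    "stage2_dataquality",
    "stage3_population",
    "stage4_designability",
    "run_pipeline",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds for the staged screen (boundary semantics follow the
    usual wording: quality >= min, missing rate "more than" excluded at
    stage 2's rate gate, MAF "under" strict, copy number ">= 2" dropped,
    designability "below" strict)."""

    quality_min: float = 0.70
    missing_rate_max: float = 0.05
    maf_min: float = 0.20
    copy_number_max_exclusive: int = 2
    designability_delete_below: float = 0.40
    designability_good: float = 0.60
    target_panel_size: int = 3072
    window_size: int = 1_000_000

    def __post_init__(self) -> None:
        for name in ("quality_min", "missing_rate_max", "maf_min",
                     "designability_delete_below", "designability_good"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.target_panel_size < 1:
            raise ValueError("target_panel_size must be >= 1")
        if self.copy_number_max_exclusive < 1:
            raise ValueError("copy_number_max_exclusive must be >= 1")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")


@dataclass
class PanelReport:
    """Stagewise selection outcome.

    ``first_failure`` maps every dropped locus to the first criterion it
    failed; ``stages`` holds the (nested) survivor sets after each stage;
    ``final_panel`` is the selected locus list in map order.
    """

    per_locus: pd.DataFrame
    stages: dict[str, set[str]] = field(default_factory=dict)
    final_panel: list[str] = field(default_factory=list)
    stage_counts: dict[str, int] = field(default_factory=dict)


def stage1_quality(qualities: pd.DataFrame, config: SelectionConfig) -> set[str]:
    """Keep loci with composite quality score >= ``quality_min``."""
    ok = qualities["quality_score"] >= config.quality_min
    return set(qualities.index[ok])


def stage2_dataquality(qualities: pd.DataFrame, config: SelectionConfig) -> set[str]:
    """Keep loci with acceptable missing data, no defect flags and,
    where duplicate pairs are informative, perfect reproducibility.

    The missing-data gate uses count semantics: up to
    ``ceil(missing_rate_max * n_samples)`` failed samples are tolerated,
    so "more than 5 of 96" keeps a locus with exactly 5 failures even
    though 5/96 marginally exceeds 5 %.
    """
    allowed = np.ceil(config.missing_rate_max * qualities["n_samples"])
    ok = (
        (qualities["missing_count"] <= allowed)
        & (qualities["defect_flags"].map(len) == 0)
        & (qualities["reproducibility"].isna() | (qualities["reproducibility"] == 1.0))
    )
    return set(qualities.index[ok])


def stage3_population(
    loci: pd.DataFrame,
    maf_table: pd.DataFrame,
    config: SelectionConfig,
    qualities: pd.DataFrame | None = None,
) -> set[str]:
    """Copy-number and MAF gates, then one best marker per genic region.

    ``loci`` is a locus map restricted to the current candidates (needs
    ``copy_number``, ``genic_region_id``, ``genic_category``,
    ``position``). Loci whose MAF is undefined (no informative calls)
    are dropped. Priority within a region: genic category first (exon
    best), then higher quality score, then lower position.
    """
    maf = maf_table["maf"].reindex(loci.index)
    keep = (
        (loci["copy_number"] < config.copy_number_max_exclusive)
        & maf.notna()
        & (maf >= config.maf_min)
    )
    cand = loci[keep].copy()
    if cand.empty:
        return set()
    cand["_prio"] = cand["genic_category"].map(GENIC_PRIORITY)
    cand["_quality"] = (
        qualities["quality_score"].reindex(cand.index) if qualities is not None else 0.0
    )
    cand = cand.sort_values(["genic_region_id", "_prio", "_quality", "position"],
                            ascending=[True, True, False, True], kind="stable")
    best = cand.groupby("genic_region_id", sort=False).head(1)
    return set(best.index)


def stage4_designability(
    loci: pd.DataFrame,
    config: SelectionConfig,
    qualities: pd.DataFrame | None = None,
) -> set[str]:
    """Designability gate plus evenness-preserving trim to target size.

    Drops designability strictly below the delete threshold. If more
    survivors remain than ``target_panel_size``, markers are removed one
    at a time from the currently densest genomic window, worst-ranked
    first, where rank prefers designability >= ``designability_good``,
    then quality score, then designability.
    """
    ok = loci[loci["designability"] >= config.designability_delete_below].copy()
    if len(ok) <= config.target_panel_size:
        return set(ok.index)

    quality = (
        qualities["quality_score"].reindex(ok.index).fillna(0.0)
        if qualities is not None else pd.Series(0.0, index=ok.index)
    )
    ok["_window"] = list(zip(ok["chromosome"],
                             (ok["position"] - 1) // config.window_size + 1))
    # higher tuple = better marker; trim removes the minimum
    rank = {
        lid: (ok.at[lid, "designability"] >= config.designability_good,
              float(quality[lid]), float(ok.at[lid, "designability"]))
        for lid in ok.index
    }
    by_window: dict = {}
    for lid, win in ok["_window"].items():
        by_window.setdefault(win, []).append(lid)
    for win in by_window:
        by_window[win].sort(key=lambda lid: rank[lid])  # worst first

    n_excess = len(ok) - config.target_panel_size
    survivors = set(ok.index)
    for _ in range(n_excess):
        win = max(by_window, key=lambda w: (len(by_window[w]), w))
        victim = by_window[win].pop(0)
        if not by_window[win]:
            del by_window[win]
        survivors.discard(victim)
    return survivors


def run_pipeline(
    qualities: pd.DataFrame,
    locus_map: pd.DataFrame,
    maf_table: pd.DataFrame,
    config: SelectionConfig | None = None,
) -> PanelReport:
    """Run all four stages and assemble the audit report.

    ``qualities`` is a QC report indexed by locus (from
    :func:`maizefp.locusqc.score_panel`), ``locus_map`` the full locus
    table, ``maf_table`` a MAF table over the same loci. Survivor sets
    are nested; each dropped locus carries exactly one first-failure
    label.
    """
    cfg = config or SelectionConfig()
    all_loci = list(locus_map.index)
    missing_qc = [l for l in all_loci if l not in qualities.index]
    if missing_qc:
        raise KeyError(f"loci without QC scores: {missing_qc[:10]}")

    s1 = stage1_quality(qualities, cfg) & set(all_loci)
    s2 = stage2_dataquality(qualities.loc[sorted(s1)], cfg)
    s3 = stage3_population(locus_map.loc[sorted(s2)], maf_table, cfg,
                           qualities=qualities)
    s4 = stage4_designability(locus_map.loc[sorted(s3)], cfg, qualities=qualities)

    maf = maf_table["maf"].reindex(locus_map.index)
    first_failure = {}
    for lid in all_loci:
        q = qualities.loc[lid]
        if lid not in s1:
            first_failure[lid] = "quality_score"
        elif lid not in s2:
            if q["missing_count"] > np.ceil(cfg.missing_rate_max * q["n_samples"]):
                first_failure[lid] = "missing_rate"
            elif len(q["defect_flags"]) > 0:
                first_failure[lid] = "defect:" + ";".join(sorted(q["defect_flags"]))
            else:
                first_failure[lid] = "reproducibility"
        elif lid not in s3:
            if locus_map.at[lid, "copy_number"] >= cfg.copy_number_max_exclusive:
                first_failure[lid] = "copy_number"
            elif pd.isna(maf[lid]):
                first_failure[lid] = "maf_undefined"
            elif maf[lid] < cfg.maf_min:
                first_failure[lid] = "maf"
            else:
                first_failure[lid] = "genic_region_redundant"
        elif lid not in s4:
            if locus_map.at[lid, "designability"] < cfg.designability_delete_below:
                first_failure[lid] = "designability"
            else:
                first_failure[lid] = "panel_trim"
        else:
            first_failure[lid] = ""

    per_locus = pd.DataFrame({
        "locus_id": all_loci,
        "stage1_quality": [l in s1 for l in all_loci],
        "stage2_dataquality": [l in s2 for l in all_loci],
        "stage3_population": [l in s3 for l in all_loci],
        "stage4_designability": [l in s4 for l in all_loci],
        "first_failure": [first_failure[l] for l in all_loci],
    }).set_index("locus_id", drop=False)

    final = [l for l in all_loci if l in s4]
    return PanelReport(
        per_locus=per_locus,
        stages={"stage1": s1, "stage2": s2, "stage3": s3, "stage4": s4},
        final_panel=final,
        stage_counts={
            "input": len(all_loci),
            "stage1": len(s1), "stage2": len(s2),
            "stage3": len(s3), "stage4": len(s4),
        },
    )
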