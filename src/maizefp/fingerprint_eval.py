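"""Panel evaluation statistics for fingerprinting SNP sets.

Implements the standard battery used to judge a variety-identification
panel: per-locus minor allele frequency on the inbred lines, parent/F1
Mendelian (pedigree) consistency over trios, pairwise differential-locus
rates and their histogram, genetic similarity of near-identical lines,
cross-platform call concordance, genomic window distribution, and a
side-by-side comparative summary of two panels.

Missing calls are handled by complete-case analysis throughout: a locus
enters a pairwise or trio statistic only when every involved sample has
a non-NC call there.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import NO_CALL, encode_calls

__all__ = [
    "compute_maf",
    "pedigree_consistency",
    "pairwise_differences",
    "genetic_similarity",
    "platform_concordance",
    "genomic_distribution",
    "comparative_report",
    "PairwiseResult",
    "TripletResult",
]

#: expected F1 genotype sets under Mendelian inheritance
_EXPECTED_F1 = {
    ("AA", "AA"): {"AA"},
    ("AA", "AB"): {"AA", "AB"},
    ("AA", "BB"): {"AB"},
    ("AB", "AB"): {"AA", "AB", "BB"},
    ("AB", "BB"): {"AB", "BB"},
    ("BB", "BB"): {"BB"},
}


def _mendelian_consistent(p1: str, p2: str, f1: str) -> bool:
    key = tuple(sorted((p1, p2)))
    return f1 in _EXPECTED_F1[key]


def compute_maf(matrix: pd.DataFrame, sample_subset: list[str] | None = None) -> pd.DataFrame:
    """Per-locus minor allele frequency over a sample subset.

    Allele counting: AA contributes two A alleles, BB two B, AB one of
    each; NC contributes nothing. MAF = min(freq_A, freq_B) in [0, 0.5].
    Loci with no informative sample get NaN. Returns a table indexed by
    locus with columns ``maf``, ``n_a``, ``n_b``, ``n_informative``.
    """
    sub = matrix.loc[sample_subset] if sample_subset is not None else matrix
    if len(sub) == 0:
        raise ValueError("sample subset is empty")
    codes = encode_calls(sub)
    called = codes >= 0
    n_a = ((codes == 0) * 2 + (codes == 1)).sum(axis=0)
    n_b = ((codes == 2) * 2 + (codes == 1)).sum(axis=0)
    total = n_a + n_b
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(total > 0, np.minimum(n_a, n_b) / np.maximum(total, 1), np.nan)
    return pd.DataFrame(
        {"maf": maf, "n_a": n_a, "n_b": n_b, "n_informative": called.sum(axis=0)},
        index=matrix.columns,
    )


@dataclass(frozen=True)
class TripletResult:
    """Pedigree-consistency outcome for one parent/parent/F1 trio."""

    parent1_id: str
    parent2_id: str
    f1_id: str
    n_scorable: int
    n_consistent: int
    verdicts: pd.Series  # per-locus: True/False/NaN (NaN = not scorable)

    @property
    def consistency(self) -> float:
        return self.n_consistent / self.n_scorable if self.n_scorable else float("nan")


def pedigree_consistency(matrix: pd.DataFrame, triplet: tuple[str, str, str]) -> TripletResult:
    """Mendelian consistency of an F1 against its two parents.

    Only loci called in all three samples are scorable. The F1 is
    consistent at a locus when its call lies in the Mendelian expectation
    set of the parents' calls (e.g. AA x BB -> {AB}, AA x AB -> {AA, AB}).
    """
    p1, p2, f1 = triplet
    for sid in triplet:
        if sid not in matrix.index:
            raise KeyError(f"triplet sample {sid!r} not in matrix")
    g1, g2, gf = matrix.loc[p1], matrix.loc[p2], matrix.loc[f1]
    scorable = (g1 != NO_CALL) & (g2 != NO_CALL) & (gf != NO_CALL)
    verdicts = pd.Series(np.nan, index=matrix.columns, dtype=object)
    n_cons = 0
    for locus in matrix.columns[scorable]:
        ok = _mendelian_consistent(g1[locus], g2[locus], gf[locus])
        verdicts[locus] = ok
        n_cons += ok
    return TripletResult(p1, p2, f1, int(scorable.sum()), int(n_cons), verdicts)


@dataclass(frozen=True)
class PairwiseResult:
    """Differential-locus outcome for one unordered sample pair."""

    sample_a: str
    sample_b: str
    n_cocalled: int
    n_differing: int

    @property
    def differential_rate(self) -> float:
        return self.n_differing / self.n_cocalled if self.n_cocalled else float("nan")


def pairwise_differences(
    matrix: pd.DataFrame,
    sample_set: list[str] | None = None,
    *,
    bin_width: float = 0.05,
) -> tuple[list[PairwiseResult], pd.Series]:
    """All n(n-1)/2 pairwise differential-locus rates plus a histogram.

    Any call mismatch (including homozygote vs heterozygote) counts as a
    difference; loci with NC in either sample are excluded from that
    pair. The histogram bins defined rates at ``bin_width`` over [0, 1];
    its mass equals the number of pairs with a defined rate.
    """
    samples = list(sample_set) if sample_set is not None else list(matrix.index)
    if len(samples) < 2:
        raise ValueError("pairwise_differences needs at least 2 samples")
    codes = encode_calls(matrix.loc[samples])
    called = codes >= 0
    results = []
    for i, j in itertools.combinations(range(len(samples)), 2):
        both = called[i] & called[j]
        n_co = int(both.sum())
        n_diff = int((codes[i][both] != codes[j][both]).sum())
        results.append(PairwiseResult(samples[i], samples[j], n_co, n_diff))

    rates = [p.differential_rate for p in results if p.n_cocalled > 0]
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(rates, bins=edges)
    # numpy closes the final bin on the right, so a rate of exactly 1.0 lands there
    hist = pd.Series(
        counts,
        index=pd.IntervalIndex.from_breaks(np.round(edges, 10), closed="left"),
        name="n_pairs",
    )
    return results, hist


def genetic_similarity(matrix: pd.DataFrame, sample_pair: tuple[str, str]) -> float:
    """1 minus the pair's differential-locus rate over co-called loci."""
    a, b = sample_pair
    codes = encode_calls(matrix.loc[[a, b]])
    both = (codes[0] >= 0) & (codes[1] >= 0)
    if not both.any():
        raise ValueError(f"samples {a!r} and {b!r} share no co-called locus")
    return 1.0 - float((codes[0][both] != codes[1][both]).mean())


def platform_concordance(
    matrix_a: pd.DataFrame, matrix_b: pd.DataFrame
) -> tuple[float, pd.Series]:
    """Call concordance between two platforms on shared samples x loci.

    Complete-case: entries where either platform reports NC are excluded.
    Returns the overall concordant fraction and a per-locus breakdown.
    """
    samples = matrix_a.index.intersection(matrix_b.index)
    loci = matrix_a.columns.intersection(matrix_b.columns)
    if len(samples) == 0 or len(loci) == 0:
        raise ValueError("matrices share no (sample, locus) entries")
    ca = encode_calls(matrix_a.loc[samples, loci])
    cb = encode_calls(matrix_b.loc[samples, loci])
    both = (ca >= 0) & (cb >= 0)
    if not both.any():
        raise ValueError("no co-called entries between the two platforms")
    agree = (ca == cb) & both
    per_locus = pd.Series(
        np.where(both.sum(axis=0) > 0, agree.sum(axis=0) / np.maximum(both.sum(axis=0), 1), np.nan),
        index=loci, name="concordance",
    )
    return float(agree.sum() / both.sum()), per_locus


def genomic_distribution(
    panel: list[str],
    locus_map: pd.DataFrame,
    window_size: int = 1_000_000,
) -> tuple[pd.DataFrame, pd.Series]:
    """SNP counts per fixed-size chromosome window plus genic-category mix.

    Windows are 1-based and half-open upward: window k on a chromosome
    covers positions [ (k-1)*w + 1, k*w ]. Counts sum to the panel size.
    Category proportions are over {exon, promoter, utr3, utr5, intron}
    and sum to 1.
    """
    unmapped = [l for l in panel if l not in locus_map.index]
    if unmapped:
        raise KeyError(f"unmapped panel loci: {unmapped[:10]}")
    sub = locus_map.loc[panel]
    window = (sub["position"] - 1) // window_size + 1
    counts = (
        pd.DataFrame({"chromosome": sub["chromosome"], "window": window})
        .value_counts()
        .rename("n_snps")
        .reset_index()
        .sort_values(["chromosome", "window"])
        .reset_index(drop=True)
    )
    proportions = sub["genic_category"].value_counts(normalize=True).rename("proportion")
    return counts, proportions


def comparative_report(panel_a_results: dict, panel_b_results: dict) -> pd.DataFrame:
    """Side-by-side comparative table for two evaluated panels.

    Each input is a dict with keys ``name``, ``qc`` (QC report with
    ``quality_score`` and ``defect_flags``), ``maf`` (MAF table), and
    ``matrix`` plus ``sample_meta`` for the differential-rate rows.
    Rows: marker success rate (fraction of loci passing QC, i.e. no
    defect flags and quality above 0), average MAF, fraction of loci
    with quality score above 0.6 and above 0.7, and the mean pairwise
    differential-locus rate among inbreds and among hybrids.
    """
    cols = {}
    sample_ref = None
    for res in (panel_a_results, panel_b_results):
        meta = res["sample_meta"]
        if sample_ref is None:
            sample_ref = set(meta.index)
        elif set(meta.index) != sample_ref:
            raise ValueError("panels must be evaluated on the same sample set")
        qc = res["qc"]
        maf = res["maf"]["maf"]
        matrix = res["matrix"]
        success = ((qc["defect_flags"].map(len) == 0) & (qc["quality_score"] > 0)).mean()
        row = {
            "marker_success_rate": float(success),
            "average_maf": float(maf.dropna().mean()),
            "frac_quality_gt_0.6": float((qc["quality_score"] > 0.6).mean()),
            "frac_quality_gt_0.7": float((qc["quality_score"] > 0.7).mean()),
        }
        for role in ("inbred", "hybrid"):
            ids = list(meta.index[meta["role"] == role])
            if len(ids) >= 2:
                pairs, _ = pairwise_differences(matrix, ids)
                rates = [p.differential_rate for p in pairs if p.n_cocalled > 0]
                row[f"mean_differential_rate_{role}"] = float(np.mean(rates))
            else:
                row[f"mean_differential_rate_{role}"] = float("nan")
        cols[res.get("name", f"panel_{len(cols) + 1}")] = row
    return pd.DataFrame(cols)
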