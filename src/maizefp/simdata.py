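"""Synthetic genotyping-array panels with the structure of a maize
fingerprinting study.

The generator produces three layers, each reproducible from one seed via
named substreams:

* a **locus universe** — markers laid out on 10 maize-sized chromosomes
  with genic-region annotations, copy numbers, assay designability scores
  and planted per-locus defect classes;
* a **population** — inbred lines drawn per heterotic group from a
  Balding–Nichols-style allele-frequency model, F1 hybrids as Mendelian
  combinations of two inbred parents, near-identical line series
  (backcross or mutant derivatives), and exact duplicate samples;
* **two-channel intensities** — per (sample, locus) X/Y signals whose
  polar transform places the three genotypes near theta 0.05 / 0.50 /
  0.95, with defect classes perturbing signal strength, cluster position
  or cluster identity the way failing array markers do.

Ground truth (true genotypes, planted defect classes, planted-good locus
sets) is retained so downstream calling, QC and selection stages can be
scored against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import substream
from .constants import DEFECT_CLASSES, GENIC_CATEGORIES

__all__ = [
    "LocusRecord",
    "SampleRecord",
    "TruthSet",
    "NoiseProfile",
    "SimilarLineSpec",
    "generate_locus_universe",
    "generate_population",
    "generate_intensities",
    "planted_selection_universe",
    "study_panel",
    "triplets",
    "universe_frame",
    "samples_frame",
]

#: approximate physical lengths of maize chromosomes 1-10 (bp)
CHROMOSOME_LENGTHS_BP = (
    307_000_000, 244_000_000, 235_000_000, 246_000_000, 223_000_000,
    173_000_000, 182_000_000, 181_000_000, 159_000_000, 150_000_000,
)

#: the six heterotic groups of Chinese maize germplasm used as defaults
DEFAULT_GROUPS = ("STPT", "P", "ImprovedReid", "Lancaster", "Waxy", "Landrace")

#: designability-score mixture: (low, high, mass) triples
DEFAULT_DESIGNABILITY_MIXTURE = (
    (0.40, 0.60, 0.015),
    (0.60, 0.80, 0.275),
    (0.80, 1.00, 0.710),
)

#: genic-category proportions of a curated genic-region SNP panel
DEFAULT_GENIC_PROPORTIONS = {
    "exon": 0.43,
    "promoter": 0.21,
    "utr3": 0.22,
    "utr5": 0.09,
    "intron": 0.05,
}

DEFAULT_DEFECT_FRACTIONS = {
    "weak_signal": 0.02,
    "high_missing": 0.03,
    "pedigree_fail": 0.02,
    "het_inbred": 0.02,
    "shifted": 0.03,
    "multicopy_compressed": 0.02,
}


@dataclass(frozen=True)
class LocusRecord:
    """One array marker and its ground-truth attributes."""

    locus_id: str
    chromosome: int
    position: int
    genic_category: str
    genic_region_id: str
    copy_number: int
    designability: float
    defect_class: str
    allele_freq_by_group: dict[str, float]

    def __post_init__(self) -> None:
        if not (0.0 <= self.designability <= 1.0):
            raise ValueError(f"designability must be in [0,1], got {self.designability}")
        if self.copy_number < 1:
            raise ValueError(f"copy_number must be >= 1, got {self.copy_number}")
        if self.defect_class not in DEFECT_CLASSES:
            raise ValueError(f"unknown defect class {self.defect_class!r}")
        if self.genic_category not in GENIC_CATEGORIES:
            raise ValueError(f"unknown genic category {self.genic_category!r}")


@dataclass(frozen=True)
class SampleRecord:
    """One panel sample: an inbred line or an F1 hybrid."""

    sample_id: str
    role: str  # "inbred" | "hybrid"
    group: str
    parent1_id: str | None = None
    parent2_id: str | None = None
    duplicate_of: str | None = None
    purity: float = 1.0

    def __post_init__(self) -> None:
        if self.role not in ("inbred", "hybrid"):
            raise ValueError(f"role must be 'inbred' or 'hybrid', got {self.role!r}")
        if self.role == "hybrid" and (self.parent1_id is None or self.parent2_id is None):
            raise ValueError(f"hybrid {self.sample_id} must have both parents set")
        if self.role == "inbred" and (self.parent1_id or self.parent2_id):
            raise ValueError(f"inbred {self.sample_id} must not have parents")
        if not (0.0 <= self.purity <= 1.0):
            raise ValueError(f"purity must be in [0,1], got {self.purity}")


@dataclass(frozen=True)
class TruthSet:
    """Ground-truth genotypes (samples x loci over {AA,AB,BB}) plus the
    set of loci planted to satisfy every selection criterion."""

    true_genotypes: pd.DataFrame
    planted_good_loci: frozenset[str] = frozenset()


@dataclass(frozen=True)
class SimilarLineSpec:
    """A series of near-identical inbred lines derived from one base line.

    ``mutation_fraction`` 0 emulates a radiation-mutant series (no
    detectable differences); 0.01-0.03 emulates backcross derivatives
    (>97 % identity).
    """

    n_members: int
    mutation_fraction: float


@dataclass(frozen=True)
class NoiseProfile:
    """Signal-generation parameters.

    theta_sd
        within-cluster SD of the normalized angle (default 0.02).
    signal_mean, signal_sd
        mean and SD of total signal R = X + Y for healthy points.
    cluster_thetas
        nominal AA/AB/BB cluster angles.
    """

    theta_sd: float = 0.02
    signal_mean: float = 1.0
    signal_sd: float = 0.10
    cluster_thetas: tuple[float, float, float] = (0.05, 0.50, 0.95)
    # defect-class knobs
    shift_offset: float = 0.20
    compression: float = 0.40
    weak_signal_scale: float = 0.05
    weak_signal_sample_frac: float = 0.90
    missing_sample_frac: float = 0.08
    missing_signal_scale: float = 0.02
    het_inbred_count: int = 8
    pedigree_fail_triplets: int = 5


# ---------------------------------------------------------------------------
# locus universe


def _validate_fractions(fractions: dict[str, float]) -> None:
    for name, frac in fractions.items():
        if name not in DEFECT_CLASSES or name == "none":
            raise ValueError(f"unknown defect class in defect_fractions: {name!r}")
        if frac < 0:
            raise ValueError(f"defect_fractions[{name!r}] is negative: {frac}")
    total = sum(fractions.values())
    if total > 1.0 + 1e-12:
        raise ValueError(f"defect_fractions sum to {total:.4f} > 1")


def generate_locus_universe(
    n_loci: int,
    n_chromosomes: int = 10,
    defect_fractions: dict[str, float] | None = None,
    designability_mixture=DEFAULT_DESIGNABILITY_MIXTURE,
    *,
    genic_proportions: dict[str, float] | None = None,
    groups: tuple[str, ...] = DEFAULT_GROUPS,
    divergence: float = 0.05,
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95),
    genic_region_size: int = 1,
    seed: int,
) -> list[LocusRecord]:
    """Generate ``n_loci`` markers laid out on maize-sized chromosomes.

    Positions are strictly increasing within each chromosome. Per-group
    allele frequencies follow a Balding–Nichols model: a uniform
    ancestral frequency per locus, with each heterotic group's frequency
    drawn from Beta(p(1-F)/F, (1-p)(1-F)/F) at divergence ``F``.
    Designability scores come from a uniform mixture over score bands;
    defect classes are assigned independently at the requested fractions.
    """
    if n_loci < 1:
        raise ValueError(f"n_loci must be >= 1, got {n_loci}")
    if not (1 <= n_chromosomes <= len(CHROMOSOME_LENGTHS_BP)):
        raise ValueError(f"n_chromosomes must be in 1..{len(CHROMOSOME_LENGTHS_BP)}")
    fractions = DEFAULT_DEFECT_FRACTIONS if defect_fractions is None else defect_fractions
    _validate_fractions(fractions)
    props = genic_proportions or DEFAULT_GENIC_PROPORTIONS
    if abs(sum(props.values()) - 1.0) > 1e-9:
        raise ValueError("genic_proportions must sum to 1")
    mix_mass = sum(m for _, _, m in designability_mixture)
    if abs(mix_mass - 1.0) > 1e-9:
        raise ValueError("designability_mixture masses must sum to 1")

    rng = substream(seed, "locus_universe")
    lengths = np.array(CHROMOSOME_LENGTHS_BP[:n_chromosomes], dtype=float)
    # loci per chromosome proportional to physical length
    alloc = np.floor(n_loci * lengths / lengths.sum()).astype(int)
    for i in range(n_loci - alloc.sum()):  # distribute the remainder
        alloc[i % n_chromosomes] += 1

    # per-locus attribute draws
    cat_names = list(props)
    categories = rng.choice(cat_names, size=n_loci, p=[props[c] for c in cat_names])
    bands = rng.choice(len(designability_mixture), size=n_loci,
                       p=[m for _, _, m in designability_mixture])
    lo = np.array([b[0] for b in designability_mixture])
    hi = np.array([b[1] for b in designability_mixture])
    designability = rng.uniform(lo[bands], hi[bands])

    defect_names = list(fractions)
    probs = [fractions[d] for d in defect_names] + [1.0 - sum(fractions.values())]
    defects = rng.choice(defect_names + ["none"], size=n_loci, p=probs)

    p_anc = rng.uniform(*ancestral_freq_range, size=n_loci)
    if divergence > 0:
        f = divergence
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        group_freqs = {g: np.clip(rng.beta(a, b), 0.01, 0.99) for g in groups}
    else:
        group_freqs = {g: p_anc.copy() for g in groups}

    records: list[LocusRecord] = []
    i = 0
    for chrom_idx, n_on_chrom in enumerate(alloc):
        if n_on_chrom == 0:
            continue
        chrom = chrom_idx + 1
        positions = np.sort(rng.choice(int(lengths[chrom_idx]), size=n_on_chrom, replace=False)) + 1
        for k, pos in enumerate(positions):
            region_idx = k // max(genic_region_size, 1)
            records.append(LocusRecord(
                locus_id=f"SNP{i + 1:05d}",
                chromosome=chrom,
                position=int(pos),
                genic_category=str(categories[i]),
                genic_region_id=f"gene_{chrom}_{region_idx}",
                copy_number=2 if defects[i] == "multicopy_compressed" else 1,
                designability=float(designability[i]),
                defect_class=str(defects[i]),
                allele_freq_by_group={g: float(group_freqs[g][i]) for g in groups},
            ))
            i += 1
    return records


def universe_frame(universe: list[LocusRecord]) -> pd.DataFrame:
    """Tabular view of a locus universe (one row per locus, indexed by id)."""
    return pd.DataFrame(
        {
            "locus_id": [l.locus_id for l in universe],
            "chromosome": [l.chromosome for l in universe],
            "position": [l.position for l in universe],
            "genic_category": [l.genic_category for l in universe],
            "genic_region_id": [l.genic_region_id for l in universe],
            "copy_number": [l.copy_number for l in universe],
            "designability": [l.designability for l in universe],
            "defect_class": [l.defect_class for l in universe],
        }
    ).set_index("locus_id", drop=False)


# ---------------------------------------------------------------------------
# population


def generate_population(
    universe: list[LocusRecord],
    n_inbreds_per_group: int,
    groups: tuple[str, ...] = DEFAULT_GROUPS,
    n_hybrids: int = 0,
    n_triplets: int = 0,
    n_duplicates: int = 0,
    similar_line_spec: list[SimilarLineSpec] | None = None,
    *,
    purity: float = 1.0,
    exact_group_freqs: bool = False,
    seed: int,
) -> tuple[list[SampleRecord], TruthSet]:
    """Draw a sample panel and its true genotypes from the universe.

    Inbreds are fully homozygous, drawn per group from the locus's
    group allele frequency (impurity, 1 - ``purity``, replaces a call
    with the off-type homozygote). Hybrids are Mendelian F1s of two
    inbred parents from different groups; the first ``n_triplets``
    hybrids, with their parents, constitute the pedigree-check triplets.
    Similar-line series copy a base inbred and flip a configured
    fraction of loci; duplicates copy a sample exactly.

    ``exact_group_freqs`` replaces the independent Bernoulli genotype
    draws with stratified assignment: per group and locus, exactly
    ``round(p * n)`` randomly placed lines carry the B allele. Used by
    planted-truth scenarios so empirical allele frequencies cannot
    wander across a selection threshold.
    """
    for g in groups:
        if any(g not in l.allele_freq_by_group for l in universe):
            raise ValueError(f"group {g!r} has no allele frequencies in the universe")
    if n_triplets > n_hybrids:
        raise ValueError("n_triplets cannot exceed n_hybrids")
    n_pairs_possible = (n_inbreds_per_group * len(groups)) ** 2
    if n_hybrids > 0 and (len(groups) < 2 or n_hybrids > n_pairs_possible):
        raise ValueError("not enough inbreds to construct the requested hybrids")

    rng = substream(seed, "population")
    locus_ids = [l.locus_id for l in universe]
    n_loci = len(locus_ids)
    freq = {g: np.array([l.allele_freq_by_group[g] for l in universe]) for g in groups}

    samples: list[SampleRecord] = []
    genotype_rows: dict[str, np.ndarray] = {}  # codes 0=AA 1=AB 2=BB

    for g in groups:
        n = n_inbreds_per_group
        if exact_group_freqs:
            k = np.round(freq[g] * n).astype(int)  # B-carriers per locus
            u = rng.random((n, n_loci))
            ranks = u.argsort(axis=0, kind="stable").argsort(axis=0, kind="stable")
            block = np.where(ranks < k[None, :], 2, 0).astype(np.int8)
        else:
            block = np.where(rng.random((n, n_loci)) < freq[g][None, :], 2, 0).astype(np.int8)
        for j in range(n):
            sid = f"{g}_I{j + 1:02d}"
            codes = block[j].copy()
            if purity < 1.0:
                flip = rng.random(n_loci) < (1.0 - purity)
                codes[flip] = 2 - codes[flip]
            samples.append(SampleRecord(sid, "inbred", g, purity=purity))
            genotype_rows[sid] = codes

    inbred_ids = [s.sample_id for s in samples]
    inbred_group = {s.sample_id: s.group for s in samples}

    # hybrids: parents from two different heterotic groups
    used_pairs: set[tuple[str, str]] = set()
    for h in range(n_hybrids):
        for _ in range(10_000):
            p1, p2 = rng.choice(inbred_ids, size=2, replace=False)
            if inbred_group[p1] != inbred_group[p2] and (p1, p2) not in used_pairs:
                used_pairs.add((p1, p2))
                break
        else:  # pragma: no cover - guarded by the pre-check above
            raise ValueError("could not construct the requested hybrids")
        sid = f"HYB{h + 1:03d}"
        f1 = ((genotype_rows[p1] + genotype_rows[p2]) // 2).astype(np.int8)
        samples.append(SampleRecord(sid, "hybrid", "F1", parent1_id=str(p1), parent2_id=str(p2)))
        genotype_rows[sid] = f1

    # similar-line series (members are additional inbreds)
    if similar_line_spec:
        for si, spec in enumerate(similar_line_spec):
            base = inbred_ids[si % len(inbred_ids)]
            for m in range(spec.n_members):
                sid = f"SIM{si + 1}_{m + 1}"
                codes = genotype_rows[base].copy()
                if spec.mutation_fraction > 0:
                    mut = rng.random(n_loci) < spec.mutation_fraction
                    codes[mut] = 2 - codes[mut]
                samples.append(SampleRecord(sid, "inbred", inbred_group[base]))
                genotype_rows[sid] = codes

    # exact duplicates
    dup_sources = [s.sample_id for s in samples]
    for d in range(n_duplicates):
        src = dup_sources[d % len(dup_sources)]
        src_rec = next(s for s in samples if s.sample_id == src)
        sid = f"DUP{d + 1}"
        samples.append(replace(src_rec, sample_id=sid, duplicate_of=src))
        genotype_rows[sid] = genotype_rows[src].copy()

    from .constants import decode_calls

    codes = np.vstack([genotype_rows[s.sample_id] for s in samples])
    truth = decode_calls(codes, index=[s.sample_id for s in samples], columns=locus_ids)
    good = frozenset(l.locus_id for l in universe if l.defect_class == "none")
    return samples, TruthSet(true_genotypes=truth, planted_good_loci=good)


def triplets(samples: list[SampleRecord]) -> list[tuple[str, str, str]]:
    """(parent1, parent2, F1) trios for every hybrid whose parents are present."""
    ids = {s.sample_id for s in samples}
    return [
        (s.parent1_id, s.parent2_id, s.sample_id)
        for s in samples
        if s.role == "hybrid" and s.parent1_id in ids and s.parent2_id in ids
    ]


def samples_frame(samples: list[SampleRecord]) -> pd.DataFrame:
    """Tabular view of sample metadata (one row per sample)."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "role": [s.role for s in samples],
            "group": [s.group for s in samples],
            "parent1_id": [s.parent1_id or "" for s in samples],
            "parent2_id": [s.parent2_id or "" for s in samples],
            "duplicate_of": [s.duplicate_of or "" for s in samples],
            "purity": [s.purity for s in samples],
        }
    ).set_index("sample_id", drop=False)


def study_panel(
    universe: list[LocusRecord], *, seed: int, purity: float = 1.0,
    exact_group_freqs: bool = False,
) -> tuple[list[SampleRecord], TruthSet]:
    """A 96-sample evaluation panel shaped like the study design:
    48 base inbreds (8 per heterotic group), two similar-line series
    (a mutant series with no differences and a backcross series at 2 %
    divergence), 2 duplicate samples, and 40 hybrids of which the first
    22 form parent/parent/F1 triplets."""
    return generate_population(
        universe,
        n_inbreds_per_group=8,
        groups=DEFAULT_GROUPS,
        n_hybrids=40,
        n_triplets=22,
        n_duplicates=2,
        similar_line_spec=[SimilarLineSpec(3, 0.0), SimilarLineSpec(3, 0.02)],
        purity=purity,
        exact_group_freqs=exact_group_freqs,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# intensities


def _theta_to_xy(theta: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # inverse of the Manhattan polar transform: theta = (2/pi) atan(y/x), r = x+y
    a = theta * (math.pi / 2.0)
    c, s = np.cos(a), np.sin(a)
    denom = c + s  # >= 1 for theta in [0,1]
    return r * c / denom, r * s / denom


def generate_intensities(
    universe: list[LocusRecord],
    samples: list[SampleRecord],
    truth: TruthSet,
    noise_profile: NoiseProfile | None = None,
    *,
    seed: int,
) -> pd.DataFrame:
    """Emit a long-format intensity table (sample_id, locus_id, x, y).

    Healthy points sit at the nominal cluster angle for their true
    genotype with Gaussian angle noise and Gaussian total signal. Defect
    classes perturb emission:

    * ``weak_signal`` — scales total signal to a few percent of nominal
      for most samples, below any sensible calling floor;
    * ``high_missing`` — pushes >5 % of samples into the failed zone;
    * ``shifted`` — displaces every cluster angle by a fixed offset;
    * ``multicopy_compressed`` — compresses the angle span toward 0.5 so
      homozygotes masquerade as heterozygote-like intermediate clusters;
    * ``het_inbred`` — emits heterozygous signals for >5 inbred lines;
    * ``pedigree_fail`` — corrupts the F1 signal in >3 triplets.
    """
    prof = noise_profile or NoiseProfile()
    rng = substream(seed, "intensities")
    from .constants import encode_calls

    sample_ids = [s.sample_id for s in samples]
    locus_ids = [l.locus_id for l in universe]
    codes = encode_calls(truth.true_genotypes.loc[sample_ids, locus_ids])
    if (codes < 0).any():
        raise ValueError("truth genotypes must not contain NC")

    n_s, n_l = codes.shape
    centers = np.asarray(prof.cluster_thetas)[codes]  # (n_s, n_l)
    r = rng.normal(prof.signal_mean, prof.signal_sd, size=(n_s, n_l))
    np.clip(r, 0.01 * prof.signal_mean, None, out=r)

    defect = np.array([l.defect_class for l in universe])
    inbred_rows = np.array([i for i, s in enumerate(samples) if s.role == "inbred"])
    trio_list = triplets(samples)
    row_of = {sid: i for i, sid in enumerate(sample_ids)}

    for j in np.flatnonzero(defect == "shifted"):
        centers[:, j] = np.clip(centers[:, j] + prof.shift_offset, 0.0, 1.0)
    for j in np.flatnonzero(defect == "multicopy_compressed"):
        centers[:, j] = 0.5 + (centers[:, j] - 0.5) * prof.compression
    for j in np.flatnonzero(defect == "het_inbred"):
        k = min(prof.het_inbred_count, len(inbred_rows))
        rows = rng.choice(inbred_rows, size=k, replace=False)
        centers[rows, j] = prof.cluster_thetas[1]
    for j in np.flatnonzero(defect == "pedigree_fail"):
        if not trio_list:
            raise ValueError("pedigree_fail defect requires triplets in the panel")
        k = min(prof.pedigree_fail_triplets, len(trio_list))
        pick = rng.choice(len(trio_list), size=k, replace=False)
        for t in pick:
            f1_row = row_of[trio_list[t][2]]
            wrong = (codes[f1_row, j] + 1) % 3  # any genotype != Mendelian expectation
            centers[f1_row, j] = prof.cluster_thetas[wrong]
    for j in np.flatnonzero(defect == "weak_signal"):
        k = max(1, int(round(prof.weak_signal_sample_frac * n_s)))
        rows = rng.choice(n_s, size=k, replace=False)
        r[rows, j] *= prof.weak_signal_scale
    for j in np.flatnonzero(defect == "high_missing"):
        k = max(1, int(math.ceil(prof.missing_sample_frac * n_s)))
        rows = rng.choice(n_s, size=k, replace=False)
        r[rows, j] *= prof.missing_signal_scale

    theta = centers
    if prof.theta_sd > 0:
        theta = theta + rng.normal(0.0, prof.theta_sd, size=(n_s, n_l))
    theta = np.clip(theta, 0.0, 1.0)

    x, y = _theta_to_xy(theta, r)
    return pd.DataFrame(
        {
            "sample_id": np.repeat(sample_ids, n_l),
            "locus_id": np.tile(locus_ids, n_s),
            "x": x.ravel(),
            "y": y.ravel(),
        }
    )


# ---------------------------------------------------------------------------
# planted-truth selection scenario

#: violation kinds cycled over the non-good loci of a planted universe
_VIOLATIONS = (
    "weak_signal",
    "high_missing",
    "pedigree_fail",
    "het_inbred",
    "shifted",
    "multicopy_compressed",
    "copy_number",
    "low_maf",
    "low_designability",
)


def planted_selection_universe(
    n_loci: int,
    n_good: int,
    *,
    seed: int,
    groups: tuple[str, ...] = DEFAULT_GROUPS,
) -> tuple[list[LocusRecord], frozenset[str]]:
    """A universe where ``n_good`` loci satisfy every selection criterion
    by construction and every other locus violates exactly one.

    Good loci get group allele frequencies in [0.40, 0.60] (safe margin
    over the 0.20 MAF gate when the population is drawn with
    ``exact_group_freqs``), designability >= 0.6, copy number 1 and no
    defect. Violators cycle deterministically through the defect classes
    plus a metadata-only copy-number-2 locus, a low-frequency locus
    (group frequencies 0.03) and a low-designability locus (0.30).
    """
    if not (0 <= n_good <= n_loci):
        raise ValueError("n_good must be between 0 and n_loci")
    base = generate_locus_universe(
        n_loci, defect_fractions={}, groups=groups, divergence=0.0,
        genic_region_size=1, seed=seed,
    )
    rng = substream(seed, "planted_selection")
    order = rng.permutation(n_loci)
    good_idx = set(order[:n_good].tolist())

    out: list[LocusRecord] = []
    v = 0
    for i, rec in enumerate(base):
        if i in good_idx:
            p = float(rng.uniform(0.40, 0.60))
            out.append(replace(
                rec,
                designability=float(rng.uniform(0.60, 1.00)),
                copy_number=1,
                defect_class="none",
                allele_freq_by_group={g: p for g in groups},
            ))
            continue
        kind = _VIOLATIONS[v % len(_VIOLATIONS)]
        v += 1
        p = float(rng.uniform(0.40, 0.60))
        freqs = {g: p for g in groups}
        if kind == "low_maf":
            freqs = {g: 0.03 for g in groups}
            out.append(replace(rec, defect_class="none", copy_number=1,
                               designability=max(rec.designability, 0.6),
                               allele_freq_by_group=freqs))
        elif kind == "low_designability":
            out.append(replace(rec, defect_class="none", copy_number=1,
                               designability=0.30, allele_freq_by_group=freqs))
        elif kind == "copy_number":
            out.append(replace(rec, defect_class="none", copy_number=2,
                               designability=max(rec.designability, 0.6),
                               allele_freq_by_group=freqs))
        else:
            out.append(replace(rec, defect_class=kind,
                               copy_number=2 if kind == "multicopy_compressed" else 1,
                               designability=max(rec.designability, 0.6),
                               allele_freq_by_group=freqs))
    good_ids = frozenset(out[i].locus_id for i in good_idx)
    return out, good_ids
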