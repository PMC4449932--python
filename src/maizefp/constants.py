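"""Shared vocabulary: genotype symbols, defect classes, genic categories."""

from __future__ import annotations

import numpy as np
import pandas as pd

GENOTYPES = ("AA", "AB", "BB")
NO_CALL = "NC"

#: integer codes used internally; NC maps to -1
GENOTYPE_CODES = {"AA": 0, "AB": 1, "BB": 2, NO_CALL: -1}
CODE_TO_GENOTYPE = {v: k for k, v in GENOTYPE_CODES.items()}

GENIC_CATEGORIES = ("exon", "promoter", "utr3", "utr5", "intron")

#: genic-category priority used when one marker is kept per genic region
GENIC_PRIORITY = {"exon": 0, "promoter": 1, "utr3": 2, "utr5": 3, "intron": 4}

DEFECT_CLASSES = (
    "none",
    "weak_signal",
    "high_missing",
    "pedigree_fail",
    "het_inbred",
    "shifted",
    "multicopy_compressed",
)


def encode_calls(matrix: pd.DataFrame) -> np.ndarray:
    """Map a samples x loci call table over {AA,AB,BB,NC} to int8 codes."""
    arr = matrix.to_numpy()
    out = np.empty(arr.shape, dtype=np.int8)
    for geno, code in GENOTYPE_CODES.items():
        out[arr == geno] = code
    known = np.isin(arr, list(GENOTYPE_CODES))
    if not known.all():
        bad = arr[~known]
        raise ValueError(f"unknown genotype symbols: {sorted(set(map(str, bad.ravel())))[:5]}")
    return out


def decode_calls(codes: np.ndarray, index, columns) -> pd.DataFrame:
    """Inverse of :func:`encode_calls`."""
    arr = np.empty(codes.shape, dtype=object)
    for code, geno in CODE_TO_GENOTYPE.items():
        arr[codes == code] = geno
    return pd.DataFrame(arr, index=index, columns=columns)
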