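"""Grantham amino-acid distance matrix and severity banding.

The Grantham distance combines differences in side-chain composition,
polarity and molecular volume into a single chemical-dissimilarity score
between amino-acid pairs (identity = 0, maximum = Cys/Trp at 215).
Nonsynonymous substitutions are banded into four conventional severity
classes; "radical" (>150) marks the chemically most dissimilar — and
most likely protein-disrupting — substitutions.
"""

from __future__ import annotations

CONSERVATIVE = "conservative"
MODERATELY_CONSERVATIVE = "moderately_conservative"
MODERATELY_RADICAL = "moderately_radical"
RADICAL = "radical"

_ORDER = "SRLPTAVGIFYCHQNKDEMW"

# Upper triangle of the published distance matrix, row by row in _ORDER.
_UPPER = [
    [110, 145, 74, 58, 99, 124, 56, 142, 155, 144, 112, 89, 68, 46, 121, 65, 80, 135, 177],  # S
    [102, 103, 71, 112, 96, 125, 97, 97, 77, 180, 29, 43, 86, 26, 96, 54, 91, 101],  # R
    [98, 92, 96, 32, 138, 5, 22, 36, 198, 99, 113, 153, 107, 172, 138, 15, 61],  # L
    [38, 27, 68, 42, 95, 114, 110, 169, 77, 76, 91, 103, 108, 93, 87, 147],  # P
    [58, 69, 59, 89, 103, 92, 149, 47, 42, 65, 78, 85, 65, 81, 128],  # T
    [64, 60, 94, 113, 112, 195, 86, 91, 111, 106, 126, 107, 84, 148],  # A
    [109, 29, 50, 55, 192, 84, 96, 133, 97, 152, 121, 21, 88],  # V
    [135, 153, 147, 159, 98, 87, 80, 127, 94, 98, 127, 184],  # G
    [21, 33, 198, 94, 109, 149, 102, 168, 134, 10, 61],  # I
    [22, 205, 100, 116, 158, 102, 177, 140, 28, 40],  # F
    [194, 83, 99, 143, 85, 160, 122, 36, 37],  # Y
    [174, 154, 139, 202, 154, 170, 196, 215],  # C
    [24, 68, 32, 81, 40, 87, 115],  # H
    [46, 53, 61, 29, 101, 130],  # Q
    [94, 23, 42, 142, 174],  # N
    [101, 56, 95, 110],  # K
    [45, 160, 181],  # D
    [126, 152],  # E
    [67],  # M
]


def _build() -> dict[tuple[str, str], int]:
    table: dict[tuple[str, str], int] = {}
    for i, a in enumerate(_ORDER):
        table[(a, a)] = 0
        for j_off, score in enumerate(_UPPER[i] if i < len(_UPPER) else []):
            b = _ORDER[i + 1 + j_off]
            table[(a, b)] = score
            table[(b, a)] = score
    table[(_ORDER[-1], _ORDER[-1])] = 0
    return table


GRANTHAM_MATRIX: dict[tuple[str, str], int] = _build()


def grantham_score(aa_from: str, aa_to: str) -> int:
    """Distance between two standard amino acids (one-letter codes)."""
    a, b = aa_from.upper(), aa_to.upper()
    if (a, b) not in GRANTHAM_MATRIX:
        raise KeyError(f"nonstandard amino acid pair {aa_from}/{aa_to}")
    return GRANTHAM_MATRIX[(a, b)]


def severity_band(score: int) -> str:
    """Conventional Grantham severity bands.

    <=50 conservative; 51-100 moderately conservative; 101-150 moderately
    radical; >150 radical.
    """
    if score < 0:
        raise ValueError("negative score")
    if score <= 50:
        return CONSERVATIVE
    if score <= 100:
        return MODERATELY_CONSERVATIVE
    if score <= 150:
        return MODERATELY_RADICAL
    return RADICAL


def grantham_severity(aa_from: str, aa_to: str) -> tuple[int, str]:
    score = grantham_score(aa_from, aa_to)
    return score, severity_band(score)
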