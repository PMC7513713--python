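"""Pairwise allele-sharing similarity D_AB between opposite-sex individuals.

The statistic descends from multilocus DNA-fingerprint band sharing.  For a
female A and male B, over the loci at which both were genotyped, let F_A be
the summed count of A's distinct alleles per locus (1 for a homozygote, 2
for a heterozygote), F_B likewise for B, and F_AB the summed count of
distinct alleles they share per locus.  Then

    D_AB = 2 * F_AB / (F_A + F_B)

lies in [0, 1]: 1 when the pair carries identical allele sets at every
shared locus, 0 when they share no allele anywhere.  Loci missing in either
member contribute nothing to any of the three sums.  The ratio is formed
once per pair from locus-summed counts, so loci are weighted equally no
matter which individuals happen to be missing where.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .panels import MISSING, GenotypePanel, RosterEntry

__all__ = [
    "PairSimilarity",
    "UndefinedSimilarityError",
    "pair_similarity",
    "similarity_matrix",
    "cross_similarity",
]


class UndefinedSimilarityError(ValueError):
    """Raised when a pair shares no typed locus, leaving D_AB undefined."""


@dataclass(frozen=True)
class PairSimilarity:
    female_id: str
    male_id: str
    panel_id: str
    n_shared_loci: int
    d_ab: float


def _pair_counts(codes_a: np.ndarray, codes_b: np.ndarray) -> tuple[int, int, int, int]:
    """(F_A, F_B, F_AB, n_shared) from two (L, 2) sorted allele-code arrays."""
    shared = (codes_a[:, 0] != MISSING) & (codes_b[:, 0] != MISSING)
    a1, a2 = codes_a[:, 0], codes_a[:, 1]
    b1, b2 = codes_b[:, 0], codes_b[:, 1]
    size_a = 1 + (a1 != a2)
    size_b = 1 + (b1 != b2)
    inter = ((a1 == b1) | (a1 == b2)).astype(np.int64) + (
        (a2 != a1) & ((a2 == b1) | (a2 == b2))
    )
    return (
        int(size_a[shared].sum()),
        int(size_b[shared].sum()),
        int(inter[shared].sum()),
        int(shared.sum()),
    )


def pair_similarity(panel: GenotypePanel, id_a: str, id_b: str) -> PairSimilarity:
    """D_AB for one pair, over loci typed in both; errors if no locus is shared."""
    ia, ib = panel.index_of(id_a), panel.index_of(id_b)
    f_a, f_b, f_ab, n_shared = _pair_counts(panel.codes[ia], panel.codes[ib])
    if n_shared == 0:
        raise UndefinedSimilarityError(
            f"pair ({id_a}, {id_b}) on panel {panel.panel_id!r}: no locus typed in both"
        )
    return PairSimilarity(
        female_id=id_a,
        male_id=id_b,
        panel_id=panel.panel_id,
        n_shared_loci=n_shared,
        d_ab=2.0 * f_ab / (f_a + f_b),
    )


def cross_similarity(
    panel: GenotypePanel, female_ids: Sequence[str], male_ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized D_AB for every female × male combination.

    Returns ``(d, n_shared)`` arrays of shape ``(n_females, n_males)``;
    entries with no shared typed locus are NaN in ``d`` and 0 in
    ``n_shared``.
    """
    fi = np.array([panel.index_of(i) for i in female_ids])
    mi = np.array([panel.index_of(i) for i in male_ids])
    A = panel.codes[fi]  # (nF, L, 2)
    B = panel.codes[mi]  # (nM, L, 2)
    a1, a2 = A[:, None, :, 0], A[:, None, :, 1]
    b1, b2 = B[None, :, :, 0], B[None, :, :, 1]
    shared = (a1 != MISSING) & (b1 != MISSING)
    size_a = np.where(shared, 1 + (a1 != a2), 0)
    size_b = np.where(shared, 1 + (b1 != b2), 0)
    inter = np.where(
        shared,
        ((a1 == b1) | (a1 == b2)).astype(np.int64)
        + ((a2 != a1) & ((a2 == b1) | (a2 == b2))),
        0,
    )
    f_a = size_a.sum(axis=2)
    f_b = size_b.sum(axis=2)
    f_ab = inter.sum(axis=2)
    n_shared = shared.sum(axis=2)
    denom = f_a + f_b
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(n_shared > 0, 2.0 * f_ab / np.where(denom > 0, denom, 1), np.nan)
    return d, n_shared


def similarity_matrix(
    panel: GenotypePanel,
    roster: Sequence[RosterEntry],
    enclosure_year_id: str | None = None,
    min_shared_loci: int = 1,
) -> tuple[list[PairSimilarity], int]:
    """All defined opposite-sex pair similarities for one enclosure-year.

    Individuals in the roster but absent from the panel are dropped
    (unsequenced animals); pairs with fewer than ``min_shared_loci`` shared
    typed loci are skipped.  Returns the pair list and the count of skipped
    (undefined or under-threshold) pairs.
    """
    entries = roster
    if enclosure_year_id is not None:
        entries = [e for e in roster if e.enclosure_year_id == enclosure_year_id]
    females = sorted({e.individual_id for e in entries if e.sex == "F"} & set(panel.individual_ids))
    males = sorted({e.individual_id for e in entries if e.sex == "M"} & set(panel.individual_ids))
    if not females or not males:
        raise UndefinedSimilarityError(
            f"enclosure-year {enclosure_year_id!r}: no genotyped opposite-sex pair available"
        )
    d, n_shared = cross_similarity(panel, females, males)
    out: list[PairSimilarity] = []
    skipped = 0
    for i, f in enumerate(females):
        for j, m in enumerate(males):
            if n_shared[i, j] >= min_shared_loci and np.isfinite(d[i, j]):
                out.append(
                    PairSimilarity(f, m, panel.panel_id, int(n_shared[i, j]), float(d[i, j]))
                )
            else:
                skipped += 1
    if not out:
        raise UndefinedSimilarityError(
            f"enclosure-year {enclosure_year_id!r}: every opposite-sex pair has an "
            "undefined similarity"
        )
    return out, skipped


def similarity_table(pairs: Sequence[PairSimilarity]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "female_id": [p.female_id for p in pairs],
            "male_id": [p.male_id for p in pairs],
            "panel_id": [p.panel_id for p in pairs],
            "n_shared_loci": [p.n_shared_loci for p in pairs],
            "d_ab": [p.d_ab for p in pairs],
        }
    )
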