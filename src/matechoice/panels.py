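"""Genotype panels, roster tables, and standardized multilocus heterozygosity.

A :class:`GenotypePanel` holds diploid calls for a named marker panel —
typically a genome-wide biallelic SNP panel ("GW") and a much smaller
multi-allelic MHC-linked microsatellite panel ("MHC"). Calls are stored as a
dense integer-coded array so that per-individual heterozygosity and pairwise
allele-sharing can be computed with vectorized arithmetic; allele labels are
kept per locus so microsatellite fragment sizes and SNP bases round-trip
exactly.

Standardized multilocus heterozygosity (sMLH) is an individual's count of
heterozygous loci divided by the sum, over the loci that individual was
actually typed at, of the population mean observed heterozygosity at each of
those loci.  The standardization makes individuals comparable under missing
data, and with complete data the population mean of sMLH is exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypePanel",
    "RosterEntry",
    "HetResult",
    "PanelValidationError",
    "read_genotypes",
    "read_roster",
    "read_pairs",
    "standardized_heterozygosity",
    "match_roster_to_panel",
]

MISSING = -1


class PanelValidationError(ValueError):
    """Raised when a genotype panel, roster, or pair table violates its invariants."""


@dataclass
class GenotypePanel:
    """Diploid genotype calls for a set of individuals at a named set of loci.

    Parameters
    ----------
    panel_id:
        Label for the marker panel, e.g. ``"GW"`` or ``"MHC"``.
    individual_ids:
        Ordered individual identifiers (studbook-style strings).
    loci:
        Ordered locus identifiers; must be unique.
    codes:
        ``(n_individuals, n_loci, 2)`` integer array.  ``codes[i, l]`` holds
        the two allele codes of individual *i* at locus *l*, sorted ascending,
        or ``(-1, -1)`` for a missing call.  Codes index into
        ``alleles[l]``.
    alleles:
        Per-locus list of allele labels; ``alleles[l][c]`` is the label of
        code ``c`` at locus *l*.
    """

    panel_id: str
    individual_ids: list[str]
    loci: list[str]
    codes: np.ndarray
    alleles: list[list[str]]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int32)
        n, L = len(self.individual_ids), len(self.loci)
        if L < 1:
            raise PanelValidationError(f"panel {self.panel_id!r}: needs at least 1 locus")
        if n < 1:
            raise PanelValidationError(f"panel {self.panel_id!r}: needs at least 1 individual")
        if len(set(self.loci)) != L:
            raise PanelValidationError(f"panel {self.panel_id!r}: duplicate locus ids")
        if len(set(self.individual_ids)) != n:
            raise PanelValidationError(f"panel {self.panel_id!r}: duplicate individual ids")
        if self.codes.shape != (n, L, 2):
            raise PanelValidationError(
                f"panel {self.panel_id!r}: codes shape {self.codes.shape} != {(n, L, 2)}"
            )
        half = (self.codes == MISSING).sum(axis=2) == 1
        if half.any():
            raise PanelValidationError(
                f"panel {self.panel_id!r}: half-calls present; encode them as missing"
            )
        # calls stored sorted so heterozygosity is a single comparison
        self.codes = np.sort(self.codes, axis=2)
        self._index = {iid: i for i, iid in enumerate(self.individual_ids)}

    # -- construction -----------------------------------------------------

    @classmethod
    def from_calls(
        cls,
        panel_id: str,
        calls: Mapping[str, Mapping[str, tuple | None]],
        loci: Sequence[str] | None = None,
    ) -> "GenotypePanel":
        """Build a panel from a nested ``{individual: {locus: (a, b) | None}}`` mapping.

        Allele labels may be any hashable (bases, fragment sizes); a call of
        ``None`` or an absent locus entry is a missing call.
        """
        ids = list(calls)
        if loci is None:
            seen: dict[str, None] = {}
            for row in calls.values():
                for loc in row:
                    seen.setdefault(loc, None)
            loci = list(seen)
        loci = list(loci)
        allele_maps: list[dict[str, int]] = [{} for _ in loci]
        codes = np.full((len(ids), len(loci), 2), MISSING, dtype=np.int32)
        for i, iid in enumerate(ids):
            row = calls[iid]
            for l, loc in enumerate(loci):
                call = row.get(loc)
                if call is None:
                    continue
                a, b = call
                amap = allele_maps[l]
                for j, lab in enumerate((str(a), str(b))):
                    codes[i, l, j] = amap.setdefault(lab, len(amap))
        alleles = [list(m) for m in allele_maps]
        return cls(panel_id, ids, loci, codes, alleles)

    # -- access -----------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def index_of(self, individual_id: str) -> int:
        try:
            return self._index[individual_id]
        except KeyError:
            raise KeyError(
                f"individual {individual_id!r} not in panel {self.panel_id!r}"
            ) from None

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._index

    def call(self, individual_id: str, locus: str) -> frozenset[str] | None:
        """Allele-label set of one call (size 1 homozygote, 2 heterozygote), or None."""
        i = self.index_of(individual_id)
        l = self.loci.index(locus)
        c = self.codes[i, l]
        if c[0] == MISSING:
            return None
        labs = self.alleles[l]
        return frozenset({labs[c[0]], labs[c[1]]})

    def typed_mask(self) -> np.ndarray:
        """Boolean ``(n, L)`` array: True where the call is non-missing."""
        return self.codes[:, :, 0] != MISSING

    def subset(self, individual_ids: Iterable[str]) -> "GenotypePanel":
        idx = [self.index_of(i) for i in individual_ids]
        return GenotypePanel(
            self.panel_id,
            [self.individual_ids[i] for i in idx],
            list(self.loci),
            self.codes[idx].copy(),
            [list(a) for a in self.alleles],
        )


@dataclass(frozen=True)
class RosterEntry:
    """One individual in one enclosure-year.

    ``bred`` is 1 iff the individual produced at least one offspring that
    survived to weaning in that enclosure-year; females carry at most four
    young, so female ``n_offspring`` is capped at 4.
    """

    individual_id: str
    enclosure_year_id: str
    sex: str
    age: int
    weight: float | None
    bred: int
    n_offspring: int

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise PanelValidationError(
                f"{self.individual_id}: unknown sex code {self.sex!r} (expected F or M)"
            )
        if self.age < 1:
            raise PanelValidationError(f"{self.individual_id}: age must be >= 1")
        if self.n_offspring < 0:
            raise PanelValidationError(f"{self.individual_id}: negative offspring count")
        if (self.bred == 1) != (self.n_offspring >= 1):
            raise PanelValidationError(
                f"{self.individual_id}: bred={self.bred} inconsistent with "
                f"n_offspring={self.n_offspring}"
            )
        if self.sex == "F" and self.n_offspring > 4:
            raise PanelValidationError(
                f"{self.individual_id}: female offspring count {self.n_offspring} exceeds "
                "the biological litter cap of 4"
            )
        if self.weight is not None and not self.weight > 0:
            raise PanelValidationError(f"{self.individual_id}: weight must be positive")


@dataclass(frozen=True)
class HetResult:
    """Per-individual standardized multilocus heterozygosity on one panel."""

    individual_id: str
    panel_id: str
    n_typed: int
    h_raw: int
    h_std: float  # NaN when undefined (no typed loci, or zero denominator)

    @property
    def defined(self) -> bool:
        return np.isfinite(self.h_std)


# ---------------------------------------------------------------------------
# readers


def _parse_wide_call(token: str) -> tuple[str, str] | None:
    token = token.strip()
    if token in ("", ".", "..", "NA", "nan", "./.", ".|."):
        return None
    if "/" in token:
        a, b = token.split("/", 1)
    elif "|" in token:
        a, b = token.split("|", 1)
    elif len(token) == 2:
        a, b = token[0], token[1]
    else:
        raise ValueError(f"cannot parse genotype call {token!r}")
    a, b = a.strip(), b.strip()
    if a in ("", ".") or b in ("", "."):
        return None  # half-call: treated as missing
    return a, b


def _read_wide_csv(path: Path, panel_id: str) -> GenotypePanel:
    df = pd.read_csv(path, dtype=str).fillna("")
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise PanelValidationError(f"{path}: duplicate individual id {dup!r}")
    calls: dict[str, dict[str, tuple | None]] = {}
    loci = list(df.columns[1:])
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        iid = row[0]
        rec: dict[str, tuple | None] = {}
        for loc, token in zip(loci, row[1:]):
            try:
                rec[loc] = _parse_wide_call(token)
            except ValueError as exc:
                raise PanelValidationError(f"{path}: line {row_no}: {exc}") from None
        calls[iid] = rec
    return GenotypePanel.from_calls(panel_id, calls, loci)


def _read_two_col_csv(path: Path, panel_id: str) -> GenotypePanel:
    """GenAlEx-style: id column then two columns per locus (``Loc.1, Loc.2``).

    A 0 or empty cell is a missing allele; a half-typed locus is treated as
    missing entirely.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    id_col = df.columns[0]
    cols = list(df.columns[1:])
    if len(cols) % 2 != 0:
        raise PanelValidationError(f"{path}: odd number of allele columns")
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise PanelValidationError(f"{path}: duplicate individual id {dup!r}")
    loci = []
    for c1, c2 in zip(cols[::2], cols[1::2]):
        base = c1.rsplit(".", 1)[0] if "." in c1 else c1
        base2 = c2.rsplit(".", 1)[0] if "." in c2 else c2
        if base != base2:
            raise PanelValidationError(f"{path}: allele columns {c1!r}/{c2!r} do not pair")
        loci.append(base)
    calls: dict[str, dict[str, tuple | None]] = {}
    for row in df.itertuples(index=False):
        iid = row[0]
        rec: dict[str, tuple | None] = {}
        for l, loc in enumerate(loci):
            a, b = str(row[1 + 2 * l]).strip(), str(row[2 + 2 * l]).strip()
            if a in ("", "0", "NA") or b in ("", "0", "NA"):
                rec[loc] = None
            else:
                rec[loc] = (a, b)
        calls[iid] = rec
    return GenotypePanel.from_calls(panel_id, calls, loci)


def _read_vcf(path: Path, panel_id: str) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    if len(set(ids)) != len(ids):
        raise PanelValidationError(f"{path}: duplicate sample id in VCF header")
    loci: list[str] = []
    rows: list[np.ndarray] = []
    alleles: list[list[str]] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise PanelValidationError(
                f"{path}: record {var.CHROM}:{var.POS} is not biallelic "
                f"(ALT={var.ALT}); split or filter multi-allelic sites upstream"
            )
        loci.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        alleles.append([var.REF, var.ALT[0]])
        gt = np.array([g[:2] for g in var.genotypes], dtype=np.int32)
        gt[(gt < 0).any(axis=1)] = MISSING  # half-calls -> missing
        rows.append(gt)
    if not loci:
        raise PanelValidationError(f"{path}: VCF contains no variant records")
    codes = np.stack(rows, axis=1)  # (n, L, 2)
    return GenotypePanel(panel_id, ids, loci, codes, alleles)


def read_genotypes(path: str | Path, format: str, panel_id: str | None = None) -> GenotypePanel:
    """Read a genotype panel from ``vcf``, ``wide_csv``, or ``two_col_csv``.

    Missing calls are preserved as missing; half-calls are demoted to missing.
    Multi-allelic VCF records are rejected with a message naming the site.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pid = panel_id if panel_id is not None else path.stem
    readers = {"vcf": _read_vcf, "wide_csv": _read_wide_csv, "two_col_csv": _read_two_col_csv}
    if format not in readers:
        raise ValueError(f"unknown genotype format {format!r}; expected one of {sorted(readers)}")
    return readers[format](path, pid)


ROSTER_COLUMNS = ["individual_id", "enclosure_year_id", "sex", "age", "weight", "bred", "n_offspring"]


def read_roster(path: str | Path) -> list[RosterEntry]:
    """Read the individual × enclosure-year roster CSV and validate every row."""
    df = pd.read_csv(path)
    missing_cols = [c for c in ROSTER_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PanelValidationError(f"{path}: roster is missing columns {missing_cols}")
    entries = []
    for rec in df.to_dict("records"):
        w = rec["weight"]
        entries.append(
            RosterEntry(
                individual_id=str(rec["individual_id"]),
                enclosure_year_id=str(rec["enclosure_year_id"]),
                sex=str(rec["sex"]),
                age=int(rec["age"]),
                weight=None if pd.isna(w) else float(w),
                bred=int(rec["bred"]),
                n_offspring=int(rec["n_offspring"]),
            )
        )
    seen = set()
    for e in entries:
        key = (e.individual_id, e.enclosure_year_id)
        if key in seen:
            raise PanelValidationError(f"{path}: duplicate roster row for {key}")
        seen.add(key)
    return entries


def read_pairs(path: str | Path) -> pd.DataFrame:
    """Read the successful-pairs CSV (female_id, male_id, enclosure_year_id, n_offspring)."""
    df = pd.read_csv(path, dtype={"female_id": str, "male_id": str, "enclosure_year_id": str})
    required = ["female_id", "male_id", "enclosure_year_id", "n_offspring"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise PanelValidationError(f"{path}: pairs table is missing columns {missing_cols}")
    return df


def match_roster_to_panel(
    roster: Sequence[RosterEntry], panel: GenotypePanel
) -> tuple[list[RosterEntry], list[str]]:
    """Split roster entries into (genotyped, unmatched ids).

    Individuals without a genotype (e.g. never sampled or failed sequencing)
    are excluded from genetic analyses; the caller gets the list of ids for
    reporting.
    """
    matched = [e for e in roster if e.individual_id in panel]
    unmatched = sorted({e.individual_id for e in roster if e.individual_id not in panel})
    return matched, unmatched


# ---------------------------------------------------------------------------
# standardized heterozygosity


def standardized_heterozygosity(panel: GenotypePanel) -> list[HetResult]:
    """Compute sMLH for every individual in the panel.

    For individual *i*, ``h_std(i) = h_raw(i) / sum over typed(i) of Hbar_l``
    where ``Hbar_l`` is the mean 0/1 heterozygosity indicator at locus *l*
    over the individuals with a non-missing call there.  Loci typed in nobody
    are dropped with a warning; individuals whose denominator is zero (no
    typed loci, or only monomorphic-in-observation loci) get ``h_std = NaN``.
    """
    typed = panel.typed_mask()
    locus_counts = typed.sum(axis=0)
    dead = locus_counts == 0
    if dead.any():
        dropped = [panel.loci[l] for l in np.flatnonzero(dead)]
        warnings.warn(
            f"panel {panel.panel_id!r}: dropping {len(dropped)} loci typed in no individual: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
    keep = ~dead
    typed = typed[:, keep]
    het = (panel.codes[:, keep, 0] != panel.codes[:, keep, 1]) & typed
    with np.errstate(invalid="ignore", divide="ignore"):
        hbar = het.sum(axis=0) / typed.sum(axis=0)
    h_raw = het.sum(axis=1)
    denom = typed @ hbar
    with np.errstate(invalid="ignore", divide="ignore"):
        h_std = np.where(denom > 0, h_raw / np.where(denom > 0, denom, 1.0), np.nan)
    results = []
    for i, iid in enumerate(panel.individual_ids):
        results.append(
            HetResult(
                individual_id=iid,
                panel_id=panel.panel_id,
                n_typed=int(typed[i].sum()),
                h_raw=int(h_raw[i]),
                h_std=float(h_std[i]),
            )
        )
    return results


def heterozygosity_table(panel: GenotypePanel) -> pd.DataFrame:
    """sMLH results as a tidy DataFrame (one row per individual)."""
    res = standardized_heterozygosity(panel)
    return pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in res],
            "panel_id": [r.panel_id for r in res],
            "n_typed": [r.n_typed for r in res],
            "h_raw": [r.h_raw for r in res],
            "h_std": [r.h_std for r in res],
        }
    )
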