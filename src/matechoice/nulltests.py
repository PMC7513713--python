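"""Structured randomization tests of mate choice against random mating.

Within one enclosure-year, every opposite-sex combination is a possible
pairing; random mating is emulated by drawing, many times, the same number
of distinct pairings as actually bred from that pool, uniformly and without
replacement of pairs (an individual may recur across drawn pairs, since
observed breeding was polygamous).  The statistic of interest — the mean
pair similarity for the "advantage of dissimilar mates" hypothesis, the
standard deviation of pair similarities for the "optimum genetic distance"
hypothesis — is recorded for each draw, giving a null distribution with a
2.5/97.5-percentile confidence band.  Evidence for a hypothesis is an
observed statistic falling below that band.

A pooled variant preserves the enclosure-year structure: each draw samples
the observed number of pairs independently within every stratum and pools
all drawn similarities before computing the statistic.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .similarity import PairSimilarity

__all__ = [
    "ObservedPairs",
    "NullDistribution",
    "MateChoiceTestResult",
    "simulate_null",
    "test_enclosure",
    "test_pooled",
    "enumerate_null_exact",
    "stratum_seed",
]

HYPOTHESIS_STATISTIC = {"dissimilar_mates": "mean", "optimum_distance": "sd"}

# rows-per-chunk cap keeps the random matrix used for subset draws ~tens of MB
_CHUNK_CELLS = 4_000_000


@dataclass(frozen=True)
class ObservedPairs:
    """Successful breeding pairs of one enclosure-year."""

    enclosure_year_id: str
    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple((str(f), str(m)) for f, m in self.pairs))
        if len(self.pairs) < 1:
            raise ValueError(f"{self.enclosure_year_id}: needs at least one observed pair")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError(f"{self.enclosure_year_id}: duplicate observed pair")

    @property
    def k(self) -> int:
        return len(self.pairs)


@dataclass
class NullDistribution:
    """Monte-Carlo (or exact) draws of a pairing statistic under random mating."""

    statistic: str  # "mean" or "sd"
    draws: np.ndarray
    n_sims: int
    expected: float
    ci_low: float
    ci_high: float
    sim_min: float
    sim_max: float

    @classmethod
    def from_draws(cls, statistic: str, draws: np.ndarray) -> "NullDistribution":
        draws = np.asarray(draws, dtype=float)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        return cls(
            statistic=statistic,
            draws=draws,
            n_sims=len(draws),
            expected=float(draws.mean()),
            ci_low=float(lo),
            ci_high=float(hi),
            sim_min=float(draws.min()),
            sim_max=float(draws.max()),
        )


@dataclass
class MateChoiceTestResult:
    scope: str  # enclosure-year id or "pooled"
    panel_id: str
    hypothesis: str
    observed: float
    null: NullDistribution
    outcome: str  # below_ci / within_ci / above_ci
    empirical_p: float
    k: int
    n_sims: int
    seed: int
    n_dropped_pairs: int = 0


def stratum_seed(master_seed: int, stratum_id: str) -> np.random.SeedSequence:
    """Deterministic per-stratum seed, independent of stratum processing order."""
    return np.random.SeedSequence([int(master_seed), zlib.crc32(stratum_id.encode())])


def _stat_from_sums(s1: np.ndarray, s2: np.ndarray, k: int, statistic: str) -> np.ndarray:
    """Mean or sample SD from a sum and sum-of-squares; shared by every code path

    so that pooled and per-enclosure results agree bit-for-bit on one stratum."""
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if statistic == "mean":
        return s1 / k
    if statistic == "sd":
        if k < 2:
            raise ValueError("sd statistic requires at least 2 pairs")
        var = (s2 - s1 * s1 / k) / (k - 1)
        return np.sqrt(np.maximum(var, 0.0))
    raise ValueError(f"unknown statistic {statistic!r}")


def observed_statistic(values: Sequence[float], statistic: str) -> float:
    v = np.asarray(values, dtype=float)
    return float(_stat_from_sums(v.sum(), (v * v).sum(), len(v), statistic))


def _unique_counts_per_row(idx: np.ndarray) -> np.ndarray:
    s = np.sort(idx, axis=1)
    return (np.diff(s, axis=1) != 0).sum(axis=1) + 1


def _draw_sums(
    d: np.ndarray,
    k: int,
    n_sims: int,
    rng: np.random.Generator,
    null_mode: str = "uniform_pairs",
    degree_target: tuple[int, int] | None = None,
    fidx: np.ndarray | None = None,
    midx: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw (sum, sum of squares) of k pair similarities sampled without
    replacement from the pool ``d``."""
    n = len(d)
    if k > n:
        raise ValueError(f"cannot draw {k} distinct pairs from a pool of {n}")
    d2 = d * d
    if k == n:
        s1 = np.full(n_sims, d.sum())
        s2 = np.full(n_sims, d2.sum())
        return s1, s2
    chunk = max(1, min(n_sims, _CHUNK_CELLS // max(n, 1)))
    s1 = np.empty(n_sims)
    s2 = np.empty(n_sims)
    filled = 0
    attempts = 0
    while filled < n_sims:
        want = min(chunk, n_sims - filled)
        r = rng.random((want, n))
        idx = np.argpartition(r, k - 1, axis=1)[:, :k]
        if null_mode == "match_degrees":
            ok = (_unique_counts_per_row(fidx[idx]) == degree_target[0]) & (
                _unique_counts_per_row(midx[idx]) == degree_target[1]
            )
            idx = idx[ok]
            attempts += 1
            if attempts > 10_000 and filled == 0:
                raise RuntimeError(
                    "match_degrees rejection sampling accepted no draw in 10,000 chunks; "
                    "the observed degree pattern may be unreachable"
                )
        take = idx[: n_sims - filled]
        vals1 = d[take].sum(axis=1)
        vals2 = d2[take].sum(axis=1)
        s1[filled : filled + len(take)] = vals1
        s2[filled : filled + len(take)] = vals2
        filled += len(take)
    return s1, s2


def _pair_arrays(
    similarities: Sequence[PairSimilarity],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[tuple[str, str], float], str]:
    d = np.array([p.d_ab for p in similarities], dtype=float)
    females = {p.female_id for p in similarities}
    males = {p.male_id for p in similarities}
    fmap = {f: i for i, f in enumerate(sorted(females))}
    mmap = {m: i for i, m in enumerate(sorted(males))}
    fidx = np.array([fmap[p.female_id] for p in similarities])
    midx = np.array([mmap[p.male_id] for p in similarities])
    lookup = {(p.female_id, p.male_id): p.d_ab for p in similarities}
    panel_id = similarities[0].panel_id if similarities else ""
    return d, fidx, midx, lookup, panel_id


def simulate_null(
    similarities: Sequence[PairSimilarity],
    observed: ObservedPairs,
    n_sims: int,
    seed: int | np.random.SeedSequence,
    statistic: str = "mean",
    null_mode: str = "uniform_pairs",
) -> NullDistribution:
    """Null distribution of the mean or SD of k random pair similarities.

    Each draw selects ``observed.k`` distinct pairs uniformly without
    replacement from all defined opposite-sex pairs of the enclosure-year and
    records the statistic of their similarities.  ``null_mode =
    "match_degrees"`` additionally conditions draws on reproducing the
    observed numbers of distinct females and distinct males (rejection
    sampling).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if statistic not in ("mean", "sd"):
        raise ValueError(f"unknown statistic {statistic!r}")
    k = observed.k
    if statistic == "sd" and k < 2:
        raise ValueError(
            f"{observed.enclosure_year_id}: SD statistic undefined for a single pair; "
            "enclosure-years with one successful pair are excluded from this test"
        )
    d, fidx, midx, _, _ = _pair_arrays(similarities)
    if k > len(d):
        raise ValueError(
            f"{observed.enclosure_year_id}: {k} observed pairs exceed the "
            f"{len(d)} available distinct pairs"
        )
    degree_target = None
    if null_mode == "match_degrees":
        degree_target = (
            len({f for f, _ in observed.pairs}),
            len({m for _, m in observed.pairs}),
        )
    elif null_mode != "uniform_pairs":
        raise ValueError(f"unknown null_mode {null_mode!r}")
    rng = np.random.default_rng(seed)
    s1, s2 = _draw_sums(d, k, n_sims, rng, null_mode, degree_target, fidx, midx)
    return NullDistribution.from_draws(statistic, _stat_from_sums(s1, s2, k, statistic))


def _resolve_observed(
    similarities: Sequence[PairSimilarity], observed: ObservedPairs
) -> tuple[list[float], int]:
    """Similarity values of the observed pairs; pairs lacking a defined
    similarity (e.g. an unsequenced parent) are dropped with a warning."""
    _, _, _, lookup, _ = _pair_arrays(similarities)
    values, dropped = [], 0
    for f, m in observed.pairs:
        if (f, m) in lookup:
            values.append(lookup[(f, m)])
        else:
            dropped += 1
    if dropped:
        warnings.warn(
            f"{observed.enclosure_year_id}: dropped {dropped} observed pair(s) with no "
            "defined similarity; k reduced accordingly",
            stacklevel=3,
        )
    return values, dropped


def _categorize(observed: float, null: NullDistribution) -> str:
    if observed < null.ci_low:
        return "below_ci"
    if observed > null.ci_high:
        return "above_ci"
    return "within_ci"


def _empirical_p(observed: float, draws: np.ndarray) -> float:
    # add-one rule avoids reporting p = 0 from a finite simulation
    return (1 + int((draws <= observed).sum())) / (1 + len(draws))


def test_enclosure(
    similarities: Sequence[PairSimilarity],
    observed: ObservedPairs,
    hypothesis: str,
    n_sims: int,
    seed: int,
    null_mode: str = "uniform_pairs",
) -> MateChoiceTestResult:
    """Observed-vs-expected test for one enclosure-year.

    ``hypothesis="dissimilar_mates"`` compares the observed mean pair
    similarity to the random-mating null; ``"optimum_distance"`` compares the
    observed SD.  The outcome category states where the observed value falls
    relative to the null 95% percentile band, and ``empirical_p`` is the
    (add-one-smoothed) fraction of null draws at or below the observed value.
    """
    statistic = HYPOTHESIS_STATISTIC[hypothesis]
    values, dropped = _resolve_observed(similarities, observed)
    if not values:
        raise ValueError(f"{observed.enclosure_year_id}: no observed pair has a defined similarity")
    if statistic == "sd" and len(values) < 2:
        raise ValueError(
            f"{observed.enclosure_year_id}: SD statistic undefined for a single pair; "
            "enclosure-years with one successful pair are excluded from this test"
        )
    effective = ObservedPairs(
        observed.enclosure_year_id,
        tuple(p for p in observed.pairs if p in {(q.female_id, q.male_id) for q in similarities}),
    )
    ss = stratum_seed(seed, observed.enclosure_year_id)
    null = simulate_null(similarities, effective, n_sims, ss, statistic, null_mode)
    obs = observed_statistic(values, statistic)
    return MateChoiceTestResult(
        scope=observed.enclosure_year_id,
        panel_id=similarities[0].panel_id,
        hypothesis=hypothesis,
        observed=obs,
        null=null,
        outcome=_categorize(obs, null),
        empirical_p=_empirical_p(obs, null.draws),
        k=len(values),
        n_sims=n_sims,
        seed=seed,
        n_dropped_pairs=dropped,
    )


def test_pooled(
    strata: Sequence[tuple[Sequence[PairSimilarity], ObservedPairs]],
    hypothesis: str,
    n_sims: int,
    seed: int,
    null_mode: str = "uniform_pairs",
) -> MateChoiceTestResult:
    """Pooled observed-vs-expected test across enclosure-years.

    Each draw independently samples k_e pairs within every stratum e (the
    same scheme as :func:`simulate_null`, with a per-stratum seed derived
    from the master seed and stratum id) and computes the statistic over the
    concatenated similarities, preserving the enclosure-year structure of the
    data under the null.
    """
    statistic = HYPOTHESIS_STATISTIC[hypothesis]
    per_stratum: dict[str, tuple[np.ndarray, np.ndarray, int, list[float]]] = {}
    total_dropped = 0
    panel_id = ""
    for similarities, observed in strata:
        values, dropped = _resolve_observed(similarities, observed)
        total_dropped += dropped
        if not values:
            warnings.warn(
                f"{observed.enclosure_year_id}: skipped (no observed pair with defined "
                "similarity)",
                stacklevel=2,
            )
            continue
        panel_id = similarities[0].panel_id
        effective = ObservedPairs(
            observed.enclosure_year_id,
            tuple(
                p
                for p in observed.pairs
                if p in {(q.female_id, q.male_id) for q in similarities}
            ),
        )
        d, fidx, midx, _, _ = _pair_arrays(similarities)
        k = effective.k
        if k > len(d):
            raise ValueError(
                f"{observed.enclosure_year_id}: {k} observed pairs exceed the "
                f"{len(d)} available distinct pairs"
            )
        degree_target = None
        if null_mode == "match_degrees":
            degree_target = (
                len({f for f, _ in effective.pairs}),
                len({m for _, m in effective.pairs}),
            )
        rng = np.random.default_rng(stratum_seed(seed, observed.enclosure_year_id))
        s1, s2 = _draw_sums(d, k, n_sims, rng, null_mode, degree_target, fidx, midx)
        per_stratum[observed.enclosure_year_id] = (s1, s2, k, values)
    if not per_stratum:
        raise ValueError("no stratum contributed a valid observed pair")
    # accumulate in stratum-id order so results do not depend on input order
    s1_tot = np.zeros(n_sims)
    s2_tot = np.zeros(n_sims)
    k_tot = 0
    all_values: list[float] = []
    for eid in sorted(per_stratum):
        s1, s2, k, values = per_stratum[eid]
        s1_tot += s1
        s2_tot += s2
        k_tot += k
        all_values.extend(values)
    if statistic == "sd" and k_tot < 2:
        raise ValueError("pooled SD statistic requires at least 2 pooled pairs")
    null = NullDistribution.from_draws(statistic, _stat_from_sums(s1_tot, s2_tot, k_tot, statistic))
    obs = observed_statistic(all_values, statistic)
    return MateChoiceTestResult(
        scope="pooled",
        panel_id=panel_id,
        hypothesis=hypothesis,
        observed=obs,
        null=null,
        outcome=_categorize(obs, null),
        empirical_p=_empirical_p(obs, null.draws),
        k=k_tot,
        n_sims=n_sims,
        seed=seed,
        n_dropped_pairs=total_dropped,
    )


def enumerate_null_exact(
    similarities: Sequence[PairSimilarity],
    k: int,
    statistic: str = "mean",
    cap: int = 1_000_000,
) -> NullDistribution:
    """Exhaustive null over all k-subsets of the available pairs.

    A test oracle for the Monte-Carlo machinery; refuses when the number of
    subsets exceeds ``cap``.
    """
    d = np.array([p.d_ab for p in similarities], dtype=float)
    n = len(d)
    if k > n:
        raise ValueError(f"cannot choose {k} pairs from {n}")
    n_outcomes = math.comb(n, k)
    if n_outcomes > cap:
        raise ValueError(f"C({n},{k}) = {n_outcomes} exceeds the enumeration cap {cap}")
    if statistic == "sd" and k < 2:
        raise ValueError("sd statistic requires k >= 2")
    idx = np.array(list(combinations(range(n), k)), dtype=np.intp)
    vals = d[idx]
    s1 = vals.sum(axis=1)
    s2 = (vals * vals).sum(axis=1)
    return NullDistribution.from_draws(statistic, _stat_from_sums(s1, s2, k, statistic))
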