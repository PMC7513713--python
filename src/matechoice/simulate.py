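"""Synthetic group-housed breeding studies with known ground truth.

The generator emulates the structure of a multi-year conservation breeding
dataset from free-range enclosures: a handful of enclosure-years each
holding up to ~21 adults in a roughly even sex ratio, ages 2-5, sex-specific
weights, a genome-wide panel of biallelic SNPs (Hardy-Weinberg draws with
minor-allele frequencies above the usual 5% filter) plus a small
multi-allelic microsatellite panel, reproductive skew in which roughly 60%
of individuals fail to breed, and litters of one to four young.

Mate choice is configurable: ``random`` mating, a ``dissimilarity_preference``
in which a breeding female favours genetically dissimilar males, an
``optimum_distance`` preference peaked at an intermediate pair similarity,
or a ``het_advantage`` in which individual heterozygosity raises breeding
success.  Ground-truth effect sizes are stored on the same 2-SD standardized
logit scale the regression models estimate, so recovery tests compare like
with like.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .panels import GenotypePanel, RosterEntry
from .similarity import cross_similarity

__all__ = ["SimConfig", "SyntheticStudy", "simulate_genotypes", "simulate_breeding",
           "simulate_study", "write_study", "read_study"]

MECHANISMS = ("random", "dissimilarity_preference", "optimum_distance", "het_advantage")

# stage codes keep per-stage random streams independent under one master seed
_STAGE_ROSTER, _STAGE_GENO, _STAGE_BREED = 1, 2, 3


@dataclass(frozen=True)
class SimConfig:
    """Study-design and mechanism parameters for one synthetic study."""

    n_enclosure_years: int = 10
    n_females: int = 10          # per enclosure-year; total adults <= 21
    n_males: int = 10
    age_range: tuple[int, int] = (2, 5)
    female_weight_mean: float = 7.5   # kg; adult female devils ~6-9 kg
    female_weight_sd: float = 0.8
    male_weight_mean: float = 10.0    # kg; adult males ~8-12 kg
    male_weight_sd: float = 1.0
    n_snp_loci: int = 1948
    n_msat_loci: int = 12
    msat_allele_range: tuple[int, int] = (2, 10)
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.05
    breeding_prob: float = 0.4        # baseline female success; ~60% fail to breed
    litter_probs: tuple[float, ...] = (0.2, 0.3, 0.3, 0.2)  # litter sizes 1..4
    mechanism: str = "random"
    beta_dis: float = 0.0             # dissimilarity preference strength
    d_opt: float = 0.85               # optimum pair similarity
    sigma_opt: float = 0.02           # width of the optimum preference
    beta_het: float = 0.0             # heterozygosity effect on success (2-SD logit scale)
    beta_age: float = 0.0             # age effect on success (2-SD logit scale)
    beta_weight: float = 0.0          # weight effect on success (2-SD logit scale)
    choice_panel: str = "GW"          # panel driving pair-similarity-based choice
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_enclosure_years < 1:
            raise ValueError("n_enclosure_years must be >= 1")
        if self.n_females < 1 or self.n_males < 1:
            raise ValueError("need at least one adult of each sex per enclosure")
        if self.n_females + self.n_males > 21:
            raise ValueError("free-range enclosures hold at most 21 adults")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 < self.breeding_prob < 1.0:
            raise ValueError("breeding_prob must be in (0, 1)")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if abs(sum(self.litter_probs) - 1.0) > 1e-9 or min(self.litter_probs) < 0:
            raise ValueError("litter_probs must be a probability vector over sizes 1..4")
        if len(self.litter_probs) != 4:
            raise ValueError("litter_probs must have 4 entries (litter sizes 1..4)")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        for b in (self.beta_dis, self.beta_het, self.beta_age, self.beta_weight):
            if not np.isfinite(b):
                raise ValueError("effect sizes must be finite")


@dataclass
class SyntheticStudy:
    config: SimConfig
    gw: GenotypePanel
    mhc: GenotypePanel | None
    roster: list[RosterEntry]
    pairs: pd.DataFrame  # female_id, male_id, enclosure_year_id, n_offspring
    truth: dict


def _stream(seed: int, stage: int, item: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage, item]))


def _enclosure_ids(config: SimConfig) -> list[str]:
    # two sites alternated over years, mirroring a two-enclosure multi-year design
    sites = ["A", "B"]
    return [f"{sites[e % 2]}{2011 + e // 2}" for e in range(config.n_enclosure_years)]


def _make_individuals(config: SimConfig) -> tuple[list[str], list[str], list[str]]:
    """(ids, sexes, enclosure_year of each individual)."""
    ids, sexes, encs = [], [], []
    for ey in _enclosure_ids(config):
        for i in range(config.n_females):
            ids.append(f"{ey}-F{i + 1:02d}")
            sexes.append("F")
            encs.append(ey)
        for i in range(config.n_males):
            ids.append(f"{ey}-M{i + 1:02d}")
            sexes.append("M")
            encs.append(ey)
    return ids, sexes, encs


def simulate_genotypes(
    config: SimConfig, seed: int | None = None, individual_ids: Sequence[str] | None = None
) -> tuple[GenotypePanel, GenotypePanel | None]:
    """Draw the genome-wide SNP panel and (optionally) the microsatellite panel.

    SNP minor-allele frequencies are uniform on ``maf_range`` with
    Hardy-Weinberg genotype draws; microsatellite loci get 2-10 alleles with
    Dirichlet(1) frequencies.  Missing calls are masked at ``missing_rate``.
    """
    if seed is None:
        seed = config.seed
    if individual_ids is None:
        individual_ids, _, _ = _make_individuals(config)
    ids = list(individual_ids)
    n = len(ids)
    rng = _stream(seed, _STAGE_GENO)

    # --- SNPs: codes 0 = major, 1 = minor allele
    L = config.n_snp_loci
    p = rng.uniform(*config.maf_range, size=L)
    g = rng.binomial(2, p[None, :], size=(n, L))  # minor-allele dosage
    codes = np.empty((n, L, 2), dtype=np.int32)
    codes[:, :, 0] = (g == 2).astype(np.int32)
    codes[:, :, 1] = (g >= 1).astype(np.int32)
    if config.missing_rate > 0:
        mask = rng.random((n, L)) < config.missing_rate
        codes[mask] = -1
    bases = np.array(["A", "C", "G", "T"])
    ref = rng.integers(0, 4, size=L)
    alt = (ref + rng.integers(1, 4, size=L)) % 4
    alleles = [[bases[r], bases[a]] for r, a in zip(ref, alt)]
    gw = GenotypePanel("GW", ids, [f"snp{l + 1}" for l in range(L)], codes, alleles)

    if config.n_msat_loci == 0:
        return gw, None

    # --- microsatellites
    M = config.n_msat_loci
    mcodes = np.empty((n, M, 2), dtype=np.int32)
    malleles: list[list[str]] = []
    lo, hi = config.msat_allele_range
    for l in range(M):
        n_all = int(rng.integers(lo, hi + 1))
        freqs = rng.dirichlet(np.ones(n_all))
        mcodes[:, l, :] = rng.choice(n_all, size=(n, 2), p=freqs)
        base = 100 + 20 * l
        malleles.append([str(base + 2 * a) for a in range(n_all)])
    if config.missing_rate > 0:
        mask = rng.random((n, M)) < config.missing_rate
        mcodes[mask] = -1
    mhc = GenotypePanel("MHC", ids, [f"mhc{l + 1}" for l in range(M)], mcodes, malleles)
    return gw, mhc


def make_roster(config: SimConfig, seed: int | None = None) -> list[dict]:
    """Demographic skeleton: one row per individual × enclosure-year, no outcomes yet."""
    if seed is None:
        seed = config.seed
    ids, sexes, encs = _make_individuals(config)
    rng = _stream(seed, _STAGE_ROSTER)
    rows = []
    for iid, sex, ey in zip(ids, sexes, encs):
        age = int(rng.integers(config.age_range[0], config.age_range[1] + 1))
        if sex == "F":
            w = rng.normal(config.female_weight_mean, config.female_weight_sd)
        else:
            w = rng.normal(config.male_weight_mean, config.male_weight_sd)
        rows.append(
            {
                "individual_id": iid,
                "enclosure_year_id": ey,
                "sex": sex,
                "age": age,
                "weight": round(max(float(w), 3.0), 2),
            }
        )
    return rows


def _two_sd_z(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=1)
    if sd == 0:
        return np.zeros_like(values, dtype=float)
    return (values - values.mean()) / (2.0 * sd)


def simulate_breeding(
    gw: GenotypePanel,
    mhc: GenotypePanel | None,
    roster_rows: list[dict],
    config: SimConfig,
    seed: int | None = None,
) -> tuple[list[RosterEntry], pd.DataFrame]:
    """Assign breeding outcomes under the configured mate-choice mechanism.

    Each female's attempt succeeds with probability
    ``logit^-1(alpha + beta_age*z_age + beta_weight*z_weight
    [+ beta_het*z_het under het_advantage])`` where alpha is the logit of the
    baseline breeding probability and the z's are 2-SD standardized across
    females.  A successful female's mate is drawn from her enclosure's males
    with mechanism-dependent weights on pair similarity; her litter size is
    drawn from the configured distribution on 1-4.  Male outcomes follow
    from the litters they sired.
    """
    if seed is None:
        seed = config.seed
    df = pd.DataFrame(roster_rows)
    if (df["sex"] == "M").groupby(df["enclosure_year_id"]).sum().min() == 0:
        raise ValueError("an enclosure-year has no males; breeding cannot be simulated")
    alpha = logit(config.breeding_prob)

    females = df[df["sex"] == "F"].reset_index(drop=True)
    eta = np.full(len(females), alpha)
    if config.beta_age != 0.0:
        eta += config.beta_age * _two_sd_z(females["age"].to_numpy(dtype=float))
    if config.beta_weight != 0.0:
        eta += config.beta_weight * _two_sd_z(females["weight"].to_numpy(dtype=float))
    if config.mechanism == "het_advantage" and config.beta_het != 0.0:
        from .panels import standardized_heterozygosity

        panel = gw if config.choice_panel == "GW" else mhc
        het = {r.individual_id: r.h_std for r in standardized_heterozygosity(panel)}
        hvals = np.array([het[i] for i in females["individual_id"]])
        hvals = np.where(np.isfinite(hvals), hvals, np.nanmean(hvals))
        eta += config.beta_het * _two_sd_z(hvals)
    success_prob = expit(eta)

    choice_panel = gw if config.choice_panel == "GW" else mhc
    pair_rows = []
    offspring = {iid: 0 for iid in df["individual_id"]}
    for e, ey in enumerate(_enclosure_ids(config)):
        rng = _stream(seed, _STAGE_BREED, e)
        fmask = (females["enclosure_year_id"] == ey).to_numpy()
        f_ids = females["individual_id"][fmask].tolist()
        m_ids = df.loc[(df["sex"] == "M") & (df["enclosure_year_id"] == ey), "individual_id"].tolist()
        probs = success_prob[fmask]
        d, _ = cross_similarity(choice_panel, f_ids, m_ids)
        success = rng.random(len(f_ids)) < probs
        for i, fid in enumerate(f_ids):
            if not success[i]:
                continue
            drow = d[i]
            ok = np.isfinite(drow)
            if not ok.any():
                continue  # no male with a defined similarity; attempt fails
            if config.mechanism == "dissimilarity_preference":
                logw = config.beta_dis * (1.0 - drow[ok])
                w = np.exp(logw - logw.max())
            elif config.mechanism == "optimum_distance":
                logw = -((drow[ok] - config.d_opt) ** 2) / (2.0 * config.sigma_opt**2)
                w = np.exp(logw - logw.max())
            else:
                w = np.ones(ok.sum())
            w = w / w.sum()
            mate = np.asarray(m_ids)[ok][rng.choice(ok.sum(), p=w)]
            litter = int(rng.choice(4, p=np.asarray(config.litter_probs)) + 1)
            offspring[fid] += litter
            offspring[mate] += litter
            pair_rows.append(
                {"female_id": fid, "male_id": str(mate), "enclosure_year_id": ey,
                 "n_offspring": litter}
            )

    entries = []
    for row in roster_rows:
        k = offspring[row["individual_id"]]
        entries.append(
            RosterEntry(
                individual_id=row["individual_id"],
                enclosure_year_id=row["enclosure_year_id"],
                sex=row["sex"],
                age=row["age"],
                weight=row["weight"],
                bred=int(k > 0),
                n_offspring=k,
            )
        )
    pairs = pd.DataFrame(pair_rows, columns=["female_id", "male_id", "enclosure_year_id", "n_offspring"])
    return entries, pairs


def simulate_study(config: SimConfig) -> SyntheticStudy:
    """Generate a complete study: genotypes, roster, and breeding outcomes."""
    gw, mhc = simulate_genotypes(config)
    rows = make_roster(config)
    roster, pairs = simulate_breeding(gw, mhc, rows, config)
    truth = {
        "config": asdict(config),
        "alpha_logit": float(logit(config.breeding_prob)),
        "effects_2sd_scale": {
            "age": config.beta_age,
            "weight": config.beta_weight,
            "heterozygosity": config.beta_het,
        },
        "n_successful_pairs": int(len(pairs)),
    }
    return SyntheticStudy(config=config, gw=gw, mhc=mhc, roster=roster, pairs=pairs, truth=truth)


# ---------------------------------------------------------------------------
# writing to the exact file dialects the readers consume


def _write_vcf(panel: GenotypePanel, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.individual_ids) + "\n")
        for l, locus in enumerate(panel.loci):
            ref, alt = panel.alleles[l][0], panel.alleles[l][1]
            gts = []
            for i in range(panel.n_individuals):
                a, b = panel.codes[i, l]
                gts.append("./." if a < 0 else f"{a}/{b}")
            fh.write(f"1\t{l + 1}\t{locus}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def _write_two_col_csv(panel: GenotypePanel, path: Path) -> None:
    header = ["individual_id"]
    for locus in panel.loci:
        header += [f"{locus}.1", f"{locus}.2"]
    with open(path, "w") as fh:
        fh.write(",".join(header) + "\n")
        for i, iid in enumerate(panel.individual_ids):
            cells = [iid]
            for l in range(panel.n_loci):
                a, b = panel.codes[i, l]
                if a < 0:
                    cells += ["0", "0"]
                else:
                    cells += [panel.alleles[l][a], panel.alleles[l][b]]
            fh.write(",".join(cells) + "\n")


def write_study(study: SyntheticStudy, directory: str | Path) -> dict[str, Path]:
    """Emit the study in the readers' file dialects plus a ground-truth sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "gw": directory / "genotypes_gw.vcf",
        "mhc": directory / "genotypes_mhc.csv",
        "roster": directory / "roster.csv",
        "pairs": directory / "pairs.csv",
        "truth": directory / "truth.json",
    }
    _write_vcf(study.gw, paths["gw"])
    if study.mhc is not None:
        _write_two_col_csv(study.mhc, paths["mhc"])
    else:
        paths.pop("mhc")
    roster_df = pd.DataFrame(
        [
            {
                "individual_id": e.individual_id,
                "enclosure_year_id": e.enclosure_year_id,
                "sex": e.sex,
                "age": e.age,
                "weight": e.weight,
                "bred": e.bred,
                "n_offspring": e.n_offspring,
            }
            for e in study.roster
        ]
    )
    roster_df.to_csv(paths["roster"], index=False)
    study.pairs.to_csv(paths["pairs"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(study.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def read_study(directory: str | Path) -> SyntheticStudy:
    """Round-trip reader for a written study directory."""
    from .panels import read_genotypes, read_pairs, read_roster

    directory = Path(directory)
    gw = read_genotypes(directory / "genotypes_gw.vcf", "vcf", panel_id="GW")
    mhc_path = directory / "genotypes_mhc.csv"
    mhc = read_genotypes(mhc_path, "two_col_csv", panel_id="MHC") if mhc_path.exists() else None
    roster = read_roster(directory / "roster.csv")
    pairs = read_pairs(directory / "pairs.csv")
    with open(directory / "truth.json") as fh:
        truth = json.load(fh)
    config = SimConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in truth["config"].items()})
    return SyntheticStudy(config=config, gw=gw, mhc=mhc, roster=roster, pairs=pairs, truth=truth)
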