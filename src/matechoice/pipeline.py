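"""End-to-end analysis pipeline: heterozygosity → similarity → randomization
tests → breeding-success models, with CSV outputs and a reproducibility
manifest."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .models import ModelSpec, averaged_table, model_average, standardize_2sd, standardize_within_group, two_sd_constants
from .nulltests import ObservedPairs, test_enclosure, test_pooled
from .panels import GenotypePanel, heterozygosity_table, read_genotypes, read_pairs, read_roster
from .similarity import similarity_matrix, similarity_table

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

ANALYSES = ("overall", "h1", "h2", "h3")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    genotypes_gw: str | Path
    roster: str | Path
    pairs: str | Path | None = None
    genotypes_mhc: str | Path | None = None
    gw_format: str = "vcf"
    mhc_format: str = "two_col_csv"
    analyses: tuple[str, ...] = ("overall", "h1", "h2", "h3")
    n_sims: int = 100_000
    seed: int | None = None
    null_mode: str = "uniform_pairs"
    min_shared_loci: int = 1
    delta_aicc: float = 2.0
    out_dir: str | Path = "results"
    make_plots: bool = False

    def __post_init__(self) -> None:
        bad = [a for a in self.analyses if a not in ANALYSES]
        if bad:
            raise ValueError(f"unknown analyses {bad}; choose from {ANALYSES}")
        if not self.analyses:
            raise ValueError("no analyses requested")
        if ("h2" in self.analyses or "h3" in self.analyses):
            if self.seed is None:
                raise ValueError("a seed is required when a stochastic analysis (h2/h3) is requested")
            if self.pairs is None:
                raise ValueError("h2/h3 require the successful-pairs table")


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps({k: str(v) for k, v in asdict(config).items()}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _model_data(roster_df: pd.DataFrame, panels: dict[str, GenotypePanel]) -> pd.DataFrame:
    df = roster_df.copy()
    for key, col in (("GW", "h_gw"), ("MHC", "h_mhc")):
        if key in panels:
            het = heterozygosity_table(panels[key]).set_index("individual_id")["h_std"]
            df[col] = df["individual_id"].map(het)
    return df


def _fit_sex_models(
    data: pd.DataFrame,
    predictors: list[str],
    delta_aicc: float,
    analysis: str,
    standardize: bool = True,
) -> pd.DataFrame:
    """Per-sex success and offspring-count model averaging; returns a tidy table.

    ``standardize=False`` is for predictors already on a 2-SD scale (the
    within-group relative measures), which must not be rescaled again."""
    frames = []
    for sex in ("F", "M"):
        sub = data[data["sex"] == sex].dropna(subset=predictors).copy()
        if sub.empty:
            continue
        std_cols = []
        for pred in predictors:
            col = f"s_{pred}"
            if standardize:
                try:
                    sub[col] = standardize_2sd(sub[pred].to_numpy(dtype=float), name=pred)
                except ValueError:
                    warnings.warn(
                        f"{analysis}/{sex}: predictor {pred!r} constant; dropped", stacklevel=2
                    )
                    continue
            else:
                sub[col] = sub[pred].to_numpy(dtype=float)
            std_cols.append(col)
        # random intercepts only where the grouping factor repeats (adequate variation)
        if sex == "M":
            rand = "individual_id" if sub["individual_id"].duplicated().any() else None
        else:
            rand = "enclosure_year_id" if sub["enclosure_year_id"].duplicated().any() else None

        runs = [("success", ModelSpec("bred", "binomial", tuple(std_cols), rand))]
        breeders = sub[sub["bred"] == 1]
        if len(breeders) > len(std_cols) + 3:
            fam = "binomial_out_of_4" if sex == "F" else "poisson"
            runs.append(("offspring", ModelSpec("n_offspring", fam, tuple(std_cols), None)))
        for response_label, spec in runs:
            frame = sub if response_label == "success" else breeders
            try:
                avg = model_average(spec, frame, delta_threshold=delta_aicc)
            except Exception as exc:
                warnings.warn(f"{analysis}/{sex}/{response_label}: modeling failed ({exc})", stacklevel=2)
                continue
            tab = averaged_table(avg)
            tab["predictor"] = tab["predictor"].str.replace("^s_", "", regex=True)
            tab.insert(0, "analysis", analysis)
            tab.insert(1, "sex", sex)
            tab.insert(2, "response", response_label)
            frames.append(tab)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def _test_rows(result) -> dict:
    return {
        "scope": result.scope,
        "panel_id": result.panel_id,
        "hypothesis": result.hypothesis,
        "observed": result.observed,
        "expected": result.null.expected,
        "ci_low": result.null.ci_low,
        "ci_high": result.null.ci_high,
        "sim_min": result.null.sim_min,
        "sim_max": result.null.sim_max,
        "outcome": result.outcome,
        "empirical_p": result.empirical_p,
        "k": result.k,
        "n_sims": result.n_sims,
        "seed": result.seed,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested analyses in a fixed order and write results.

    Returns a bundle with the in-memory results and the paths written.
    Stages run heterozygosity → similarity → randomization tests → models;
    any stage failure aborts with a stage-named error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"outputs": {}}

    try:
        panels: dict[str, GenotypePanel] = {
            "GW": read_genotypes(config.genotypes_gw, config.gw_format, panel_id="GW")
        }
        if config.genotypes_mhc is not None:
            panels["MHC"] = read_genotypes(config.genotypes_mhc, config.mhc_format, panel_id="MHC")
        roster = read_roster(config.roster)
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
                for e in roster
            ]
        )
        pairs_df = read_pairs(config.pairs) if config.pairs is not None else None
    except Exception as exc:
        raise PipelineError(f"input stage failed: {exc}") from exc

    # --- heterozygosity ---------------------------------------------------
    try:
        for key, panel in panels.items():
            tab = heterozygosity_table(panel)
            path = out / f"heterozygosity_{key.lower()}.csv"
            tab.to_csv(path, index=False, float_format="%.10g")
            bundle["outputs"][f"heterozygosity_{key.lower()}"] = path
            bundle.setdefault("heterozygosity", {})[key] = tab
    except Exception as exc:
        raise PipelineError(f"heterozygosity stage failed: {exc}") from exc

    # --- similarity -------------------------------------------------------
    need_similarity = {"h2", "h3"} & set(config.analyses)
    similarities: dict[str, dict[str, list]] = {}
    if need_similarity:
        try:
            enclosures = sorted(roster_df["enclosure_year_id"].unique())
            for key, panel in panels.items():
                per_enc = {}
                frames = []
                for ey in enclosures:
                    try:
                        sims, _ = similarity_matrix(
                            panel, roster, ey, min_shared_loci=config.min_shared_loci
                        )
                    except Exception:
                        continue
                    per_enc[ey] = sims
                    tab = similarity_table(sims)
                    tab.insert(0, "enclosure_year_id", ey)
                    frames.append(tab)
                similarities[key] = per_enc
                path = out / f"similarity_{key.lower()}.csv"
                pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")
                bundle["outputs"][f"similarity_{key.lower()}"] = path
        except Exception as exc:
            raise PipelineError(f"similarity stage failed: {exc}") from exc

    # --- randomization tests ----------------------------------------------
    if need_similarity:
        try:
            rows = []
            results = []
            hypotheses = []
            if "h2" in config.analyses:
                hypotheses.append("dissimilar_mates")
            if "h3" in config.analyses:
                hypotheses.append("optimum_distance")
            for key in panels:
                per_enc = similarities[key]
                observed_by_ey = {
                    ey: ObservedPairs(ey, [tuple(x) for x in g[["female_id", "male_id"]].to_numpy()])
                    for ey, g in pairs_df.groupby("enclosure_year_id")
                    if ey in per_enc
                }
                for hyp in hypotheses:
                    strata = []
                    for ey, obs in sorted(observed_by_ey.items()):
                        strata.append((per_enc[ey], obs))
                        try:
                            res = test_enclosure(
                                per_enc[ey], obs, hyp, config.n_sims, config.seed, config.null_mode
                            )
                        except ValueError:
                            continue  # e.g. single-pair stratum under the SD test
                        results.append(res)
                        rows.append(_test_rows(res))
                    if len(strata) >= 2:
                        res = test_pooled(strata, hyp, config.n_sims, config.seed, config.null_mode)
                        results.append(res)
                        rows.append(_test_rows(res))
            tests_tab = pd.DataFrame(rows)
            path = out / "mate_choice_tests.csv"
            tests_tab.to_csv(path, index=False, float_format="%.10g")
            bundle["outputs"]["mate_choice_tests"] = path
            bundle["mate_choice_tests"] = tests_tab
            if config.make_plots and not tests_tab.empty:
                from .plotting import plot_observed_vs_expected

                for hyp in tests_tab["hypothesis"].unique():
                    fig_path = out / f"figure_{hyp}.png"
                    plot_observed_vs_expected(tests_tab[tests_tab["hypothesis"] == hyp], fig_path)
                    bundle["outputs"][f"figure_{hyp}"] = fig_path
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"randomization-test stage failed: {exc}") from exc

    # --- breeding-success models -------------------------------------------
    model_analyses = {"overall", "h1"} & set(config.analyses)
    if model_analyses:
        try:
            data = _model_data(roster_df, panels)
            predictors = [c for c in ("age", "weight", "h_gw", "h_mhc") if c in data.columns]
            frames = []
            if "overall" in model_analyses:
                frames.append(_fit_sex_models(data, predictors, config.delta_aicc, "overall"))
            if "h1" in model_analyses:
                rel = standardize_within_group(
                    data.dropna(subset=predictors), predictors, ("enclosure_year_id", "sex")
                )
                # relative predictors are already on the within-group 2-SD scale
                rel = rel.rename(columns={f"z_{p}": f"rel_{p}" for p in predictors})
                frames.append(
                    _fit_sex_models(
                        rel, [f"rel_{p}" for p in predictors], config.delta_aicc, "h1",
                        standardize=False,
                    )
                )
            models_tab = pd.concat([f for f in frames if not f.empty], ignore_index=True)
            path = out / "model_averages.csv"
            models_tab.to_csv(path, index=False, float_format="%.10g")
            bundle["outputs"]["model_averages"] = path
            bundle["model_averages"] = models_tab
        except Exception as exc:
            raise PipelineError(f"modeling stage failed: {exc}") from exc

    manifest = {
        "package": "matechoice",
        "version": __version__,
        "seed": config.seed,
        "config": {k: str(v) for k, v in asdict(config).items()},
        "config_hash": _config_hash(config),
        "outputs": sorted(str(p.name) for p in bundle["outputs"].values()),
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    bundle["outputs"]["manifest"] = manifest_path
    bundle["manifest"] = manifest
    return bundle
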