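"""End-to-end orchestration: colony -> events -> networks -> songs -> models.

:func:`run_full_analysis` chains every stage and emits an
:class:`AnalysisReport` holding (i) the tutor-choice table (one row per
juvenile male: treatment, primary tutor, father rank, relation of the
rank-1 tutor), (ii) slope/s.e./statistic tables for the four regression
analyses with permutation p-values and 95% null coefficient ranges for the
permuted slopes, and (iii) a provenance block (seed, config, versions).

A single global seed is fanned out to the stages through a documented hash
scheme (stage name -> child seed), so any stage can be rerun in isolation
and reproduce its part of the pipeline bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from ._util import child_seed
from .events import build_gbi, detect_events, summarize_events
from .models import (
    FitResult,
    build_accuracy_table,
    build_association_table,
    build_dissimilarity_table,
    build_tutor_choice_table,
    fit_glmm_binomial,
    fit_lmm,
)
from .networks import daily_network_series, father_son_dyads
from .permutation import NETWORK_COLUMNS, permutation_test
from .song import (
    motif_dissimilarity_matrix,
    standardize_elements,
    tutor_ranking,
)
from .synthetic import ColonyConfig, generate_colony, simulate_visit_stream, synthesize_songs

log = logging.getLogger("finchnet")

DISSIM_FIXED = [
    "cort_treatment",
    "father_son_association",
    "father_gregariousness",
    "son_gregariousness",
]


@dataclass
class RunConfig:
    """Switches and inputs of one full analysis run.

    Exactly one of ``colony`` (generator config) or ``input_dir`` (a
    directory holding stream.csv, truth.json, songs.csv) drives the run.
    """

    colony: ColonyConfig | None = field(default_factory=ColonyConfig)
    input_dir: str | None = None
    event_method: str = "gap"
    gap_threshold_s: float = 120.0
    merge_window_s: float = 60.0
    dtw_normalize: bool = True
    aggregate: str = "day"
    n_permutations: int = 10_000
    permutation_refit: str = "gls"
    seed: int = 0
    outdir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.colony is None) == (self.input_dir is None):
            raise ValueError(
                "exactly one of generator config and input paths must be set"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        colony = raw.pop("colony", None)
        if colony is not None:
            colony = ColonyConfig(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in colony.items()
            })
        elif "input_dir" not in raw:
            colony = ColonyConfig()
        return cls(colony=colony, **raw)


@dataclass
class AnalysisReport:
    tutor_table: pd.DataFrame
    models: dict  # name -> DataFrame (term, slope, se, stat, p_rand, null range)
    random_effects: dict  # name -> dict of variance components
    event_summary: dict
    provenance: dict

    def to_text(self) -> str:
        lines = ["tutor choice (one row per juvenile male)", "-" * 46]
        lines.append(self.tutor_table.to_string(index=False))
        for name, tab in self.models.items():
            lines += ["", name, "-" * len(name), tab.to_string()]
            re = self.random_effects.get(name)
            if re:
                lines.append(
                    "random effects: "
                    + ", ".join(
                        f"{k}={v:.4g}" if isinstance(v, (int, float)) else f"{k}={v}"
                        for k, v in re.items()
                    )
                )
        lines += ["", "provenance: " + json.dumps(self.provenance, default=str)]
        return "\n".join(lines)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.tutor_table.to_csv(outdir / "tutor_choice.csv", index=False)
        for name, tab in self.models.items():
            tab.to_csv(outdir / f"model_{name}.csv")
        (outdir / "report.txt").write_text(self.to_text())
        (outdir / "provenance.json").write_text(
            json.dumps(self.provenance, indent=1, default=str)
        )


def classify_relation(son_row: pd.Series, tutor_row: pd.Series) -> str:
    """father / brother / unrelated adult / unrelated peer, from metadata."""
    same_family = tutor_row["family_id"] == son_row["family_id"]
    if same_family and tutor_row["role"] == "father":
        return "father"
    if same_family and tutor_row["role"] == "son":
        return "brother"
    return "unrelated adult" if tutor_row["role"] == "father" else "unrelated peer"


def tutor_choice_table(rankings: dict, birds: pd.DataFrame) -> pd.DataFrame:
    """Tutor-choice rows: treatment, primary tutor, father rank, relation."""
    meta = birds.set_index("bird_id")
    rows = []
    for son in sorted(rankings):
        r = rankings[son]
        if son not in meta.index or r.primary_tutor not in meta.index:
            raise ValueError(f"missing metadata for {son} or its primary tutor")
        rows.append({
            "son_id": son,
            "treatment": meta.loc[son, "treatment"],
            "primary_tutor": r.primary_tutor,
            "father_rank": r.father_rank,
            "relation": classify_relation(meta.loc[son], meta.loc[r.primary_tutor]),
            "primary_dissimilarity": r.primary_dissimilarity,
        })
    return pd.DataFrame(rows)


def rank_all_tutors(D: pd.DataFrame, birds: pd.DataFrame) -> dict:
    """Tutor rankings for every juvenile male against all other males with songs."""
    meta = birds.set_index("bird_id")
    males = [b for b in D.index if b in meta.index]
    fathers = meta[meta["role"] == "father"]["family_id"]
    out = {}
    for son in sorted(meta[meta["role"] == "son"].index):
        if son not in D.index:
            continue
        candidates = [b for b in males if b != son]
        fam = meta.loc[son, "family_id"]
        father = next((b for b, f in fathers.items() if f == fam), None)
        out[son] = tutor_ranking(D, son, candidates, father=father)
    return out


def _model_frame(fit: FitResult, perms: dict | None = None) -> pd.DataFrame:
    tab = fit.fixed.copy()
    tab["p_rand"] = np.nan
    tab["null_2.5"] = np.nan
    tab["null_97.5"] = np.nan
    if perms:
        for term, pr in perms.items():
            tab.loc[term, "p_rand"] = pr.p_rand
            tab.loc[term, ["null_2.5", "null_97.5"]] = pr.null_range_95
    return tab


def _placeholder_frame(terms: list) -> pd.DataFrame:
    tab = pd.DataFrame(
        np.nan, index=["intercept", *terms],
        columns=["slope", "se", "stat", "p_rand", "null_2.5", "null_97.5"],
    )
    return tab


def _re_dict(fit: FitResult) -> dict:
    return {
        "family_variance": fit.random_variance,
        "residual_variance": fit.residual_variance,
        "family_pct": fit.variance_pct["family"],
        "residual_pct": fit.variance_pct["residual"],
    }


def run_full_analysis(config: RunConfig) -> AnalysisReport:
    """Run the whole pipeline and return the report (writing files if asked).

    Stage order: simulate/load -> event detection -> daily SRI networks ->
    song dissimilarity + tutor ranks -> tutor-choice GLMM -> father-son
    dissimilarity LMM (both covariate variants, permutation p for the network
    slopes) -> CORT-on-association LMM (permutation p) -> copy-accuracy LMM.
    """
    logging.basicConfig(level=config.log_level)
    t0 = time.time()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # ---- stage: data ------------------------------------------------------
    if config.input_dir:
        indir = Path(config.input_dir)
        colony = fio.read_truth(indir / "truth.json")
        stream = fio.read_visit_stream(indir / "stream.csv")
        songs = fio.read_song_traces(indir / "songs.csv")
    else:
        colony_cfg = replace(config.colony, seed=child_seed(config.seed, "generator"))
        colony = generate_colony(colony_cfg)
        stream, _labels = simulate_visit_stream(colony, colony_cfg)
        songs = synthesize_songs(colony, colony_cfg)
    log.info("data: %d birds, %d detections", len(colony.birds), len(stream))
    if outdir and not config.input_dir:
        fio.write_visit_stream(stream, outdir / "stream.csv")
        fio.write_truth(colony, outdir / "truth.json")
        fio.write_song_traces(songs, outdir / "songs.csv")

    # ---- stage: events ----------------------------------------------------
    events = detect_events(
        stream, config.event_method,
        gap_threshold=config.gap_threshold_s, merge_window=config.merge_window_s,
    )
    if not events:
        raise RuntimeError("event detection produced no events")
    rosters = {a: colony.roster(a) for a in colony.aviaries}
    days = sorted(stream["day"].unique())
    gbis = build_gbi(events, rosters, days=days)
    mean_dur, d_lo, d_hi = summarize_events(events)
    event_summary = {
        "n_events": len(events), "mean_duration_s": mean_dur,
        "duration_p2.5_s": d_lo, "duration_p97.5_s": d_hi,
    }
    log.info("events: %d (mean duration %.0f s)", len(events), mean_dur)
    if outdir:
        fio.write_events(events, outdir / "events.csv")

    # ---- stage: networks --------------------------------------------------
    dyads = father_son_dyads(colony.birds)
    matrices, metrics = daily_network_series(gbis, dyads)
    if outdir:
        fio.write_sri_long(matrices, outdir / "sri.csv")
        metrics.to_csv(outdir / "network_metrics.csv", index=False)

    # ---- stage: songs -----------------------------------------------------
    std = standardize_elements(songs)
    D = motif_dissimilarity_matrix(std, normalize=config.dtw_normalize)
    rankings = rank_all_tutors(D, colony.birds)
    tutors = tutor_choice_table(rankings, colony.birds)
    if outdir:
        fio.write_matrix(D, outdir / "motif_dissimilarity.csv")
        fio.write_rankings(rankings, outdir / "rankings.csv")
    log.info("songs: %d males ranked", len(rankings))

    # ---- stage: models ----------------------------------------------------
    fam_sizes = colony.family_sizes()
    models: dict = {}
    random_effects: dict = {}

    glmm_tab = build_tutor_choice_table(tutors, colony.birds, fam_sizes)
    try:
        glmm = fit_glmm_binomial(glmm_tab, "response", ["cort_treatment"])
        models["tutor_choice_glmm"] = _model_frame(glmm)
        random_effects["tutor_choice_glmm"] = _re_dict(glmm)
    except (ValueError, RuntimeError) as exc:
        # e.g. every juvenile copied the father: no information in the response
        log.warning("tutor-choice GLMM degenerate: %s", exc)
        models["tutor_choice_glmm"] = _placeholder_frame(["cort_treatment"])
        random_effects["tutor_choice_glmm"] = {"error": str(exc)}

    father_son_dissim = {
        d["son_id"]: float(D.loc[d["father_id"], d["son_id"]])
        for _, d in dyads.iterrows()
    }
    for covariate in ("n_fledglings", "n_male_offspring"):
        name = f"father_son_dissimilarity_{covariate}"
        fixed = DISSIM_FIXED + [covariate]
        try:
            tab = build_dissimilarity_table(
                metrics, colony.birds, fam_sizes, father_son_dissim,
                aggregate="day",
            )
            perms = permutation_test(
                gbis, dyads, tab, "response", fixed,
                n_permutations=config.n_permutations,
                seed=child_seed(config.seed, f"perm/{name}"),
                refit=config.permutation_refit,
                focal_terms=[t for t in fixed if t in NETWORK_COLUMNS],
            )
            fit = fit_lmm(tab, "response", fixed)
            models[name] = _model_frame(fit, perms)
            random_effects[name] = _re_dict(fit)
            # the per-son aggregated variant is always reported alongside the
            # day-level fit, bracketing the day-resolution choice
            agg = build_dissimilarity_table(
                metrics, colony.birds, fam_sizes, father_son_dissim,
                aggregate="mean",
            )
            afit = fit_lmm(agg, "response", fixed)
            models[name + "_aggregated"] = _model_frame(afit)
            random_effects[name + "_aggregated"] = _re_dict(afit)
        except (ValueError, RuntimeError) as exc:
            log.warning("%s degenerate: %s", name, exc)
            models[name] = _placeholder_frame(fixed)
            random_effects[name] = {"error": str(exc)}

    try:
        assoc_tab = build_association_table(metrics, colony.birds, fam_sizes)
        assoc_perms = permutation_test(
            gbis, dyads, assoc_tab, "response", ["cort_treatment"],
            response_is_network=True,
            n_permutations=config.n_permutations,
            seed=child_seed(config.seed, "perm/association"),
            refit=config.permutation_refit,
            focal_terms=["cort_treatment"],
        )
        assoc_fit = fit_lmm(assoc_tab, "response", ["cort_treatment"])
        models["association_cort"] = _model_frame(assoc_fit, assoc_perms)
        random_effects["association_cort"] = _re_dict(assoc_fit)
    except (ValueError, RuntimeError) as exc:
        log.warning("association model degenerate: %s", exc)
        models["association_cort"] = _placeholder_frame(["cort_treatment"])
        random_effects["association_cort"] = {"error": str(exc)}

    try:
        acc_tab = build_accuracy_table(tutors, colony.birds, fam_sizes)
        acc_fit = fit_lmm(acc_tab, "response", ["cort_treatment"])
        models["copy_accuracy_cort"] = _model_frame(acc_fit)
        random_effects["copy_accuracy_cort"] = _re_dict(acc_fit)
    except (ValueError, RuntimeError) as exc:
        log.warning("copy-accuracy model degenerate: %s", exc)
        models["copy_accuracy_cort"] = _placeholder_frame(["cort_treatment"])
        random_effects["copy_accuracy_cort"] = {"error": str(exc)}

    provenance = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "n_birds": len(colony.birds),
        "n_detections": int(len(stream)),
        "elapsed_s": round(time.time() - t0, 2),
    }
    report = AnalysisReport(
        tutor_table=tutors, models=models, random_effects=random_effects,
        event_summary=event_summary, provenance=provenance,
    )
    if outdir:
        report.write(outdir)
    log.info("done in %.1f s", time.time() - t0)
    return report
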