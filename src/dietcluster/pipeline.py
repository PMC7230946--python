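"""End-to-end pipeline: synthesize -> derive -> cluster -> classify -> associate.

Each stage reads its inputs from and writes its outputs to a run
directory, so stages are individually re-runnable.  ``run_pipeline``
chains them and writes a manifest with configuration, seeds, the
exclusion tally, the chosen number of clusters, the selected exposures
and SHA-256 checksums of every text output; a rerun with the same
configuration reproduces the checksums exactly.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import pandas as pd

from . import __version__
from .associations import (
    assign_quartiles,
    association_row,
    build_results_table,
    coadjustment_quartiles,
    results_markdown,
    sensitivity_suite,
)
from .clustering import (
    bic_scan,
    embed_variables,
    hierarchical_cluster,
    index_vote,
    select_representatives,
    selected_exposures,
    silhouette_values,
)
from .cmr import outcome_table
from .config import RunConfig
from .diaries import (
    ExposureMatrix,
    derive_exposure_matrix,
    transform_exposures,
    validate_and_exclude,
)
from .exceptions import DietClusterError, FitError
from .synthesize import CohortConfig, generate_cohort

_TEXT_OUTPUTS = (
    "diaries.csv",
    "participants.csv",
    "exclusions.json",
    "exposures.csv",
    "exposures_transformed.csv",
    "cluster_assignment.csv",
    "bic_scan.csv",
    "index_votes.csv",
    "dendrogram.nwk",
    "correlations.csv",
    "outcome.csv",
    "results_main.csv",
    "results_main.md",
    "results_bmi_restricted.csv",
    "results_glucose_only.csv",
)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def stage_synth(cfg: RunConfig, outdir: Path) -> None:
    cohort = generate_cohort(
        CohortConfig(n_participants=cfg.n_participants, n_days=cfg.n_days, seed=cfg.seed)
    )
    cohort.write(outdir)


def stage_derive(cfg: RunConfig, outdir: Path) -> None:
    diaries = pd.read_csv(outdir / "diaries.csv")
    participants = pd.read_csv(outdir / "participants.csv", index_col="participant_id")
    t = cfg.thresholds

    matrix_all = derive_exposure_matrix(
        diaries, valid_day_kcal=t.valid_day_kcal, occasion_kcal=t.occasion_kcal,
        participant_ids=participants.index,
    )
    report = validate_and_exclude(
        diaries,
        participants,
        chronic_disease=participants.get("chronic_disease"),
        outcome_complete=participants.get("outcome_complete"),
        valid_day_kcal=t.valid_day_kcal,
        min_valid_days=t.min_valid_days,
        missing_diet=matrix_all.missing_flags(),
    )
    (outdir / "exclusions.json").write_text(json.dumps(report.tally, indent=1))

    included = report.included_ids
    # clustering 45 variables needs clearly more observations than variables
    if len(included) < 100:
        warnings.warn(
            f"only {len(included)} participants included; clustering will be unstable",
            stacklevel=2,
        )
    matrix = ExposureMatrix(raw=matrix_all.raw.loc[included])
    matrix = transform_exposures(matrix)
    matrix.write(outdir / "exposures.csv")
    matrix.transformed.to_csv(outdir / "exposures_transformed.csv", index_label="participant_id")


def _load_matrix(outdir: Path) -> ExposureMatrix:
    raw = pd.read_csv(outdir / "exposures.csv", index_col="participant_id")
    return transform_exposures(ExposureMatrix(raw=raw))


def stage_cluster(cfg: RunConfig, outdir: Path) -> dict:
    matrix = _load_matrix(outdir)
    emb = embed_variables(matrix)

    scan = bic_scan(emb, k_range=cfg.k_range, n_restarts=cfg.n_restarts, seed=cfg.seed)
    scan.table.to_csv(outdir / "bic_scan.csv", index=False)

    k = scan.chosen_k
    sol = scan.solutions[k]
    if k >= 2:
        sol.silhouettes = silhouette_values(emb, sol.assignment, method=cfg.silhouette_method)
    else:
        sol.silhouettes = pd.Series(0.0, index=emb.names)
    corr = matrix.transformed.corr()
    corr.to_csv(outdir / "correlations.csv")
    sol = select_representatives(sol, corr, cfg.thresholds.correlation_cutoff)

    assignment = pd.DataFrame(
        {
            "variable": sol.assignment.index,
            "cluster": sol.assignment.to_numpy(),
            "silhouette": sol.silhouettes.reindex(sol.assignment.index).to_numpy(),
        }
    )
    reps = set(sol.representatives.values())
    hits = set(sol.second_hits.loc[sol.second_hits["retained"], "variable"])
    assignment["is_representative"] = assignment["variable"].isin(reps)
    assignment["is_second_hit"] = assignment["variable"].isin(hits)
    assignment.to_csv(outdir / "cluster_assignment.csv", index=False)

    lo = max(cfg.k_range[0], 2)
    votes = index_vote(emb, k_range=(lo, cfg.k_range[1]), seed=cfg.seed)
    votes.to_csv(outdir / "index_votes.csv", index=False)

    dendro = hierarchical_cluster(matrix, linkage=cfg.linkage)
    (outdir / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")

    if cfg.plots:
        _plots(outdir, scan.table, dendro, corr)
    return {
        "chosen_k": k,
        "representatives": {str(c): v for c, v in sol.representatives.items()},
        "selected_exposures": selected_exposures(sol),
    }


def _plots(outdir: Path, bic_table: pd.DataFrame, dendro, corr: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster import hierarchy

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(bic_table["k"], bic_table["bic"], marker="o")
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("BIC")
    fig.tight_layout()
    fig.savefig(outdir / "bic_curve.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(10, 6))
    hierarchy.dendrogram(dendro.linkage_matrix, labels=dendro.names, ax=ax, leaf_font_size=6)
    fig.tight_layout()
    fig.savefig(outdir / "dendrogram.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    fig.colorbar(im, ax=ax)
    ax.set_xticks(range(len(corr)), corr.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(len(corr)), corr.index, fontsize=5)
    fig.tight_layout()
    fig.savefig(outdir / "correlation_heatmap.png", dpi=120)
    plt.close(fig)


def stage_outcome(cfg: RunConfig, outdir: Path) -> None:
    participants = pd.read_csv(outdir / "participants.csv", index_col="participant_id")
    out = outcome_table(participants)
    out.to_csv(outdir / "outcome.csv", index_label="participant_id")


def stage_associate(cfg: RunConfig, outdir: Path, cluster_info: dict) -> None:
    matrix = _load_matrix(outdir)
    raw = matrix.raw
    participants = pd.read_csv(outdir / "participants.csv", index_col="participant_id").loc[raw.index]
    outcome = pd.read_csv(outdir / "outcome.csv", index_col="participant_id").loc[raw.index]
    y = outcome["case"].astype(bool)
    y_glu = outcome["glucose_only_case"].astype(bool)
    reps = {int(c): v for c, v in cluster_info["representatives"].items()}
    selected = cluster_info["selected_exposures"]

    def covariates(target: str, index: pd.Index, model: int) -> pd.DataFrame:
        cov = pd.DataFrame(
            {"age": participants.loc[index, "age"], "sex": participants.loc[index, "sex"]}
        )
        co = coadjustment_quartiles(raw.loc[index], reps, target)
        cov = pd.concat([cov, co], axis=1)
        if model == 2:
            for c in cfg.model2_covariates:
                cov[c] = participants.loc[index, c]
        return cov

    rows = []
    summaries = {}
    for name in selected:
        q = assign_quartiles(raw[name], name=name)
        summaries[name] = q
        for model in (1, 2):
            try:
                rows.append(association_row(name, model, y, q, covariates(name, raw.index, model)))
            except FitError as exc:
                warnings.warn(f"model {model} for {name} not estimable: {exc}", stacklevel=2)
    table = build_results_table(rows)
    table.to_csv(outdir / "results_main.csv", index=False)
    (outdir / "results_main.md").write_text(results_markdown(table, summaries))

    try:
        sens = sensitivity_suite(
            raw_exposures=raw,
            selected=selected,
            outcome=y,
            glucose_outcome=y_glu,
            covariates_builder=lambda target, index: covariates(target, index, 1),
            bmi=participants["bmi"],
        )
    except FitError as exc:
        warnings.warn(f"sensitivity analyses not estimable: {exc}", stacklevel=2)
        sens = {"bmi_restricted": build_results_table([]), "glucose_only": build_results_table([])}
    sens["bmi_restricted"].to_csv(outdir / "results_bmi_restricted.csv", index=False)
    sens["glucose_only"].to_csv(outdir / "results_glucose_only.csv", index=False)


def stage_report(cfg: RunConfig, outdir: Path, extra: dict | None = None) -> dict:
    tally = json.loads((outdir / "exclusions.json").read_text())
    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "exclusion_tally": tally,
        "checksums": {
            name: _sha256(outdir / name)
            for name in _TEXT_OUTPUTS
            if (outdir / name).exists()
        },
    }
    if extra:
        manifest.update(extra)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Run every stage in order and return the manifest.

    On a stage failure the run aborts with the stage name; a partial
    manifest covering the completed stages is still written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cluster_info: dict = {}
    stages = [
        ("synth", lambda: stage_synth(cfg, outdir)),
        ("derive", lambda: stage_derive(cfg, outdir)),
        ("cluster", lambda: cluster_info.update(stage_cluster(cfg, outdir))),
        ("outcome", lambda: stage_outcome(cfg, outdir)),
        ("associate", lambda: stage_associate(cfg, outdir, cluster_info)),
    ]
    for name, fn in stages:
        try:
            fn()
        except Exception as exc:
            stage_report(cfg, outdir, {"failed_stage": name, "error": str(exc)})
            raise DietClusterError(f"pipeline stage {name!r} failed: {exc}") from exc
    return stage_report(cfg, outdir, cluster_info)
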