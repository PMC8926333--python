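"""End-to-end experiment orchestration and reporting.

An experiment is: generate (or load) a dataset, build the matched design per
behavior, run cross-validated prediction under a training-population arm,
summarize group-wise accuracy, test predictability (multilevel block
permutation) and the group accuracy difference (flip-label permutation),
recover association patterns and relate pattern validity to accuracy. All
stages are seeded and every output is a TSV/JSON file listed, with its
SHA-256, in a manifest — re-running the same config reproduces the bundle
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import association as assoc
from . import inference, io, matching, metrics, modeling
from .synthetic import SyntheticConfig, SyntheticDataset, generate_suite

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment",
           "compare_training_arms", "plot_group_accuracy"]

log = logging.getLogger("fairconn")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one experiment.

    Demo scale defaults: 40 ROIs / 500 subjects / 6 behaviors with graded
    weight-pattern similarity, 3 matched splits with 30 draw iterations, and
    100 permutations (raise ``n_perm`` to 1000 for confirmatory runs).
    """

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    behaviors: Mapping[str, float] = field(
        default_factory=lambda: {
            f"beh{i}": rho for i, rho in enumerate([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
        }
    )
    scheme: str = "hcp_splits"
    model_type: str = "kernel"
    confound_policy: str = "regress"
    training_arm: str = "full"
    cost_variables: Sequence[str] = ("age", "mean_fd")
    categorical_vars: Sequence[str] = ("gender",)
    n_folds: int = 10
    n_splits: int = 3
    n_iter: int = 30
    n_perm: int = 100
    inner_folds: int = 5
    lambda_grid: Sequence[float] | None = None
    seed: int = 0

    def stage_seed(self, stage: str, extra: int | str = 0) -> int:
        """Stable (process-independent) per-stage seed below 2**31."""
        h = hashlib.sha256(f"{self.seed}:{stage}:{extra}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class ExperimentResult:
    dataset: SyntheticDataset
    designs: dict[str, matching.MatchedDesign]
    predictions: dict[str, modeling.PredictionResult]
    group_accuracy: pd.DataFrame
    inference_table: pd.DataFrame
    similarity_table: pd.DataFrame
    similarity_accuracy_corr: float
    manifest: dict


def _build_design(
    config: ExperimentConfig, dataset: SyntheticDataset, behavior: str
) -> matching.MatchedDesign:
    table = dataset.table()
    spec = matching.MatchCostSpec(
        variables=list(config.cost_variables)
        + list(config.categorical_vars)
        + [behavior],
        categorical_vars=list(config.categorical_vars),
    )
    if config.scheme == "hcp_splits":
        return matching.select_matched_splits_hcp(
            table,
            spec,
            n_folds=config.n_folds,
            n_iter=config.n_iter,
            n_splits=config.n_splits,
            seed=config.stage_seed("design", behavior),
            behaviors_for_prepass=list(config.behaviors),
            confounds_for_prepass=list(config.cost_variables)
            + list(config.categorical_vars),
        )
    if config.scheme == "abcd_sites":
        pairs_by_site: dict[int, list[tuple[str, str]]] = {}
        excluded: list[str] = []
        for site, sub in table.groupby("site", sort=True):
            pairs, excl = matching.iterative_site_match(sub, spec)
            pairs_by_site[int(site)] = pairs
            excluded.extend(excl)
        site_to_fold = matching.merge_sites_to_folds(
            {s: len(p) for s, p in pairs_by_site.items()}, config.n_folds
        )
        fold_of = {
            str(sid): site_to_fold[int(site)]
            for sid, site in zip(table["subject_id"], table["site"])
        }
        all_pairs = [p for plist in pairs_by_site.values() for p in plist]
        design = matching.MatchedDesign(
            scheme="abcd_sites",
            pairs={0: all_pairs},
            fold_of_subject={0: fold_of},
            splits=[0],
            excluded_minority_ids=excluded,
            n_folds=config.n_folds,
            meta={"site_to_fold": site_to_fold},
        )
        design.validate()
        return design
    raise ValueError(f"unknown scheme {config.scheme!r}")


def _behavior_inference(
    config: ExperimentConfig,
    dataset: SyntheticDataset,
    design: matching.MatchedDesign,
    result: modeling.PredictionResult,
    acc: pd.DataFrame,
    behavior: str,
) -> dict:
    """Predictability and group-difference tests for one behavior.

    Predictability uses the first split's whole-test-set predictions (each
    subject is tested exactly once per split) with family exchangeability
    blocks; the group difference flips matched-pair labels on the first
    split's pooled pairs, using predictive COD with that split's mean SST.
    """
    table = result.table
    first = min(design.pairs) if design.scheme == "abcd_sites" else min(result.split_meta)
    sub = table[table["split"] == first]
    fam_of = dict(zip(dataset.subject_ids, dataset.families))
    merged = sub.set_index("subject_id")
    blocks = np.asarray([fam_of[s] for s in merged.index])
    pred = inference.block_permutation_predictability(
        merged["y_true"].to_numpy(),
        merged["y_pred"].to_numpy(),
        blocks,
        n_perm=config.n_perm,
        seed=config.stage_seed("blockperm", behavior),
    )

    pairs = design.pairs[first if design.scheme == "hcp_splits" else 0]
    # multi-site scheme: only pairs whose two members are tested in this split
    pairs = [
        (a, b) for a, b in pairs if a in merged.index and b in merged.index
    ]
    ta = merged.loc[[a for a, _ in pairs]]
    tb = merged.loc[[b for _, b in pairs]]
    sst = float(np.mean(list(result.split_meta[first]["sst"].values())))
    flip = inference.flip_label_test(
        lambda yt, yp: metrics.predictive_cod(yt, yp, sst),
        ta["y_true"].to_numpy(), ta["y_pred"].to_numpy(),
        tb["y_true"].to_numpy(), tb["y_pred"].to_numpy(),
        n_perm=config.n_perm,
        seed=config.stage_seed("flip", behavior),
    )

    amean = acc.groupby("group")["predictive_cod"].mean()
    rmean = acc.groupby("group")["pearson_r"].mean()
    return {
        "behavior": behavior,
        "predictability_r": pred.observed,
        "predictability_p": pred.p,
        "cod_minority": float(amean["minority"]),
        "cod_majority": float(amean["majority"]),
        "cod_difference": float(amean["minority"] - amean["majority"]),
        "r_minority": float(rmean["minority"]),
        "r_majority": float(rmean["majority"]),
        "flip_observed": flip.observed,
        "flip_p": flip.p,
        "mean_r": float(
            np.mean(
                [
                    metrics.pearson_accuracy(
                        d["y_true"].to_numpy(), d["y_pred"].to_numpy()
                    )
                    for _, d in table.groupby("split")
                ]
            )
        ),
    }


def _behavior_association(
    dataset: SyntheticDataset,
    design: matching.MatchedDesign,
    result: modeling.PredictionResult,
    config: ExperimentConfig,
    behavior: str,
) -> dict:
    """Split-averaged pattern-validity similarities for one behavior.

    The learned map uses in-sample predictions on the residualized training
    data of each split's first fold model refit; true maps use matched test
    subjects only.
    """
    ids = np.asarray(dataset.subject_ids)
    id_index = {s: i for i, s in enumerate(ids)}
    y_all = np.asarray(dataset.scores[behavior], float)
    fc_all = dataset.fc
    conf_all = dataset.confounds.to_numpy(float)

    sims_min, sims_maj = [], []
    for split in result.split_meta:
        fold_of = design.fold_of_subject[
            split if design.scheme == "hcp_splits" else 0
        ]
        pairs = design.pairs[split if design.scheme == "hcp_splits" else 0]
        # training set of the split's first evaluation unit
        if design.scheme == "hcp_splits":
            test_folds = {0}
        else:
            test_folds = set(modeling.abcd_split_folds(design.n_folds, 3)[split])
        train_ids = [s for s in ids if fold_of[s] not in test_folds]
        test_ids = [s for s in ids if fold_of[s] in test_folds]
        tr = np.asarray([id_index[s] for s in train_ids], int)
        y_tr, fc_tr = y_all[tr], fc_all[tr]
        cm = None
        if result.confound_policy == "regress":
            cm = modeling.fit_confound_model(
                y_tr, fc_tr, conf_all[tr], list(dataset.confounds.columns)
            )
            y_tr, fc_tr = modeling.apply_confound_model(
                cm, y_tr, fc_tr, conf_all[tr]
            )
        lam_key = 0
        lam = result.split_meta[split]["lambda"][lam_key]
        K = modeling.correlation_kernel(fc_tr, fc_tr)
        alpha = modeling.fit_krr(K, y_tr, lam)
        y_hat_tr = K @ alpha
        learned = assoc.model_learned_association(fc_tr, y_hat_tr, split=split)

        test_set = set(test_ids)
        for glabel, members, store in (
            ("minority", [a for a, _ in pairs], sims_min),
            ("majority", [b for _, b in pairs], sims_maj),
        ):
            gids = [s for s in members if s in test_set]
            if len(gids) < 3:
                continue
            gi = np.asarray([id_index[s] for s in gids], int)
            y_g, fc_g = y_all[gi], fc_all[gi]
            if cm is not None:
                y_g, fc_g = modeling.apply_confound_model(
                    cm, y_g, fc_g, conf_all[gi]
                )
            tmap = assoc.true_association(fc_g, y_g, group=glabel, split=split)
            store.append(assoc.association_similarity(learned, tmap))
    return {
        "behavior": behavior,
        "sim_minority": float(np.mean(sims_min)) if sims_min else np.nan,
        "sim_majority": float(np.mean(sims_maj)) if sims_maj else np.nan,
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_experiment(
    config: ExperimentConfig,
    outdir: Path | str,
    dataset: SyntheticDataset | None = None,
    designs: dict[str, matching.MatchedDesign] | None = None,
) -> ExperimentResult:
    """Run every stage and write the result bundle plus manifest to outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    if dataset is None:
        dataset = generate_suite(config.synthetic, dict(config.behaviors))
    io.write_dataset(dataset, outdir / "dataset")
    log.info("dataset: %d subjects, %d behaviors (%.1fs)",
             dataset.n_subjects, len(dataset.behaviors), time.time() - t0)

    if designs is None:
        designs = {
            b: _build_design(config, dataset, b) for b in dataset.behaviors
        }
    predictions: dict[str, modeling.PredictionResult] = {}
    acc_frames, inf_rows, sim_rows = [], [], []
    for b_idx, behavior in enumerate(dataset.behaviors):
        t1 = time.time()
        design = designs[behavior]
        io.write_design(design, outdir / f"design_{behavior}.json")
        result = modeling.run_prediction(
            dataset,
            design,
            behavior=behavior,
            model_type=config.model_type,
            confound_policy=config.confound_policy,
            lambda_grid=config.lambda_grid,
            training_arm=config.training_arm,
            inner_folds=config.inner_folds,
            seed=config.stage_seed("predict", b_idx),
        )
        predictions[behavior] = result
        result.table.to_csv(
            outdir / f"predictions_{behavior}.tsv", sep="\t", index=False,
            float_format="%.10g",
        )
        acc = metrics.summarize_groups(result, design)
        acc.insert(0, "behavior", behavior)
        acc_frames.append(acc)
        inf_rows.append(
            _behavior_inference(config, dataset, design, result, acc, behavior)
        )
        sim_rows.append(
            _behavior_association(dataset, design, result, config, behavior)
        )
        log.info("behavior %s done (%.1fs)", behavior, time.time() - t1)

    group_accuracy = pd.concat(acc_frames, ignore_index=True)
    inference_table = pd.DataFrame(inf_rows)
    inference_table["flip_fdr_reject"] = inference.fdr_bh(
        inference_table["flip_p"].to_numpy()
    )
    sim_table = pd.DataFrame(sim_rows).merge(
        inference_table[["behavior", "cod_difference"]], on="behavior"
    )
    sim_table["delta_similarity"] = (
        sim_table["sim_majority"] - sim_table["sim_minority"]
    )
    sim_table["delta_accuracy"] = -sim_table["cod_difference"]
    per_behavior = {
        r["behavior"]: (r["delta_similarity"], r["delta_accuracy"])
        for _, r in sim_table.iterrows()
    }
    try:
        sim_corr, _ = assoc.similarity_accuracy_relation(per_behavior)
    except ValueError:
        sim_corr = float("nan")

    group_accuracy.to_csv(outdir / "group_accuracy.tsv", sep="\t", index=False,
                          float_format="%.10g")
    inference_table.to_csv(outdir / "inference.tsv", sep="\t", index=False,
                           float_format="%.10g")
    sim_table.to_csv(outdir / "association_similarity.tsv", sep="\t",
                     index=False, float_format="%.10g")
    summary = {
        "similarity_accuracy_correlation": sim_corr,
        "training_arm": config.training_arm,
        "scheme": config.scheme,
        "seed": config.seed,
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True)
    )

    files = sorted(
        str(p.relative_to(outdir))
        for p in outdir.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": {
            "seed": config.seed,
            "scheme": config.scheme,
            "model_type": config.model_type,
            "confound_policy": config.confound_policy,
            "training_arm": config.training_arm,
            "n_perm": config.n_perm,
            "n_splits": config.n_splits,
        },
        "files": {f: _sha256(outdir / f) for f in files},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    log.info("experiment complete (%.1fs)", time.time() - t0)
    return ExperimentResult(
        dataset=dataset,
        designs=designs,
        predictions=predictions,
        group_accuracy=group_accuracy,
        inference_table=inference_table,
        similarity_table=sim_table,
        similarity_accuracy_corr=sim_corr,
        manifest=manifest,
    )


def compare_training_arms(
    config: ExperimentConfig,
    outdir: Path | str,
    arms: Sequence[str] = ("full", "minority_only", "majority_only", "balanced"),
) -> pd.DataFrame:
    """Run the experiment once per training-population arm over a shared
    dataset and matched design; summarize the signed significant direction of
    the group difference per behavior and arm, with per-arm counts."""
    outdir = Path(outdir)
    dataset = generate_suite(config.synthetic, dict(config.behaviors))
    designs = {b: _build_design(config, dataset, b) for b in dataset.behaviors}
    rows = []
    for arm in arms:
        arm_cfg = dataclasses.replace(config, training_arm=arm)
        res = run_experiment(arm_cfg, outdir / arm, dataset=dataset,
                             designs=designs)
        for _, r in res.inference_table.iterrows():
            if not r["flip_fdr_reject"]:
                direction = "no_significant_difference"
            elif r["cod_difference"] > 0:
                direction = "minority_better"
            else:
                direction = "majority_better"
            rows.append(
                {
                    "arm": arm,
                    "behavior": r["behavior"],
                    "cod_difference": r["cod_difference"],
                    "flip_p": r["flip_p"],
                    "direction": direction,
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "training_arms.tsv", sep="\t", index=False,
                 float_format="%.10g")
    return table


def plot_group_accuracy(group_accuracy: pd.DataFrame, path: Path | str) -> None:
    """Boxplot of per-split predictive COD by behavior and group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    behaviors = sorted(group_accuracy["behavior"].unique())
    fig, ax = plt.subplots(figsize=(1.6 * len(behaviors) + 2, 4))
    positions, data, colors = [], [], []
    for i, b in enumerate(behaviors):
        for j, (g, color) in enumerate(
            (("minority", "#1f77b4"), ("majority", "#2ca02c"))
        ):
            vals = group_accuracy.query("behavior == @b and group == @g")[
                "predictive_cod"
            ]
            positions.append(i * 3 + j)
            data.append(vals.to_numpy())
            colors.append(color)
    boxes = ax.boxplot(data, positions=positions, patch_artist=True, widths=0.8)
    for patch, color in zip(boxes["boxes"], colors):
        patch.set_facecolor(color)
    ax.set_xticks([i * 3 + 0.5 for i in range(len(behaviors))])
    ax.set_xticklabels(behaviors)
    ax.set_ylabel("predictive COD")
    ax.axhline(0, color="gray", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
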