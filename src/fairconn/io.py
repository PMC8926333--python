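"""Tabular interchange format for subject tables, FC matrices and designs.

A dataset on disk is: ``subjects.tsv`` (subject_id, group, site, family,
confound columns, one column per behavior), ``fc.tsv`` (subjects × edges)
with a JSON sidecar ``fc.json`` recording the ROI count and the
lower-triangular column-major edge ordering, and ``config.yaml``. Matched
designs serialize as JSON; prediction/metric tables as TSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .matching import MatchedDesign
from .synthetic import ConfoundSpec, SyntheticConfig, SyntheticDataset

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_design",
    "read_design",
    "config_to_yaml",
    "config_from_yaml",
]

EDGE_ORDER = "lower_triangular_column_major"


def config_to_yaml(config: SyntheticConfig, path: Path | str) -> None:
    d = dataclasses.asdict(config)
    for key in ("w_majority", "w_minority"):
        if d[key] is not None:
            d[key] = np.asarray(d[key]).tolist()
    d["family_size_distribution"] = {
        int(k): float(v) for k, v in d["family_size_distribution"].items()
    }
    d["motion_params"] = {k: float(v) for k, v in d["motion_params"].items()}
    d["confound_loadings"] = [dict(c) for c in d["confound_loadings"]]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def config_from_yaml(path: Path | str) -> SyntheticConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["confound_loadings"] = tuple(
        ConfoundSpec(**c) for c in d.get("confound_loadings", [])
    )
    for key in ("w_majority", "w_minority"):
        if d.get(key) is not None:
            d[key] = np.asarray(d[key], float)
    return SyntheticConfig(**d)


def write_dataset(dataset: SyntheticDataset, outdir: Path | str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.table().to_csv(outdir / "subjects.tsv", sep="\t", index=False)
    np.savetxt(outdir / "fc.tsv", dataset.fc, delimiter="\t", fmt="%.10g")
    sidecar = {
        "n_roi": dataset.config.n_roi,
        "n_edges": dataset.config.n_edges,
        "edge_order": EDGE_ORDER,
        "scale": "fisher_z",
        "n_subjects": dataset.n_subjects,
    }
    (outdir / "fc.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    config_to_yaml(dataset.config, outdir / "config.yaml")


def read_dataset(indir: Path | str) -> SyntheticDataset:
    indir = Path(indir)
    config = config_from_yaml(indir / "config.yaml")
    table = pd.read_csv(indir / "subjects.tsv", sep="\t")
    fc = np.loadtxt(indir / "fc.tsv", delimiter="\t", ndmin=2)
    sidecar = json.loads((indir / "fc.json").read_text())
    if sidecar["edge_order"] != EDGE_ORDER:
        raise ValueError(f"unsupported edge ordering {sidecar['edge_order']!r}")
    if fc.shape != (len(table), sidecar["n_edges"]):
        raise ValueError("FC matrix shape disagrees with sidecar/subject table")
    conf_names = [s.name for s in config.confound_loadings]
    structural = {"subject_id", "group", "site", "family", *conf_names}
    behaviors = [c for c in table.columns if c not in structural]
    return SyntheticDataset(
        config=config,
        subject_ids=table["subject_id"].astype(str).tolist(),
        groups=table["group"].to_numpy(),
        sites=table["site"].to_numpy(),
        families=table["family"].to_numpy(),
        confounds=table[conf_names].copy(),
        fc=fc,
        scores={b: table[b].to_numpy(float) for b in behaviors},
        truth={},
    )


def write_design(design: MatchedDesign, path: Path | str) -> None:
    payload = {
        "scheme": design.scheme,
        "n_folds": design.n_folds,
        "splits": design.splits,
        "pairs": {str(k): v for k, v in design.pairs.items()},
        "fold_of_subject": {str(k): v for k, v in design.fold_of_subject.items()},
        "excluded_minority_ids": design.excluded_minority_ids,
        "meta": design.meta,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_design(path: Path | str) -> MatchedDesign:
    d = json.loads(Path(path).read_text())
    return MatchedDesign(
        scheme=d["scheme"],
        pairs={int(k): [tuple(p) for p in v] for k, v in d["pairs"].items()},
        fold_of_subject={
            int(k): {s: int(f) for s, f in v.items()}
            for k, v in d["fold_of_subject"].items()
        },
        splits=[int(s) for s in d["splits"]],
        excluded_minority_ids=list(d["excluded_minority_ids"]),
        n_folds=int(d["n_folds"]),
        meta=d.get("meta", {}),
    )
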