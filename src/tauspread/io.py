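"""Readers and writers for the pipeline's plain-text formats.

Adjacency TSVs carry region labels as the header row and first column;
SUVR tables are long-format CSV (subject_id, region, suvr); metadata and
result tables are ordinary headered CSV with NA for missing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def write_adjacency_tsv(path, adjacency: np.ndarray, labels) -> None:
    df = pd.DataFrame(np.asarray(adjacency, dtype=float),
                      index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t")


def read_adjacency_tsv(path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: adjacency not square ({df.shape})")
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels disagree")
    return df.to_numpy(dtype=float), tuple(map(str, df.columns))


def write_suvr_long(path, suvr: pd.DataFrame) -> None:
    long = suvr.stack().rename("suvr").reset_index()
    long.columns = ["subject_id", "region", "suvr"]
    long.to_csv(path, index=False)


def read_suvr_long(path) -> pd.DataFrame:
    long = pd.read_csv(path)
    needed = {"subject_id", "region", "suvr"}
    if not needed.issubset(long.columns):
        raise ValueError(f"{path}: expected columns {sorted(needed)}")
    return long.pivot(index="subject_id", columns="region", values="suvr")


def write_cohort(cohort, out_dir) -> None:
    """Write a synthetic cohort's files: per-subject connectome TSVs,
    long-format baseline/follow-up SUVR, metadata, ground truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = cohort.config.region_labels
    for sid, adj in cohort.subject_adjacencies.items():
        write_adjacency_tsv(out / f"{sid}_connectome.tsv", adj, labels)
    write_suvr_long(out / "suvr_baseline.csv", cohort.suvr_baseline)
    write_suvr_long(out / "suvr_followup.csv", cohort.suvr_followup)
    meta = cohort.metadata.copy()
    meta["interval_years"] = cohort.intervals
    meta.to_csv(out / "metadata.csv")
    truth = {
        "epicenters": {s: list(e) for s, e in cohort.truth.epicenters.items()},
        "severity": cohort.truth.severity,
        "amyloid_positive": cohort.truth.amyloid_positive,
        "unimodal_regions": [r for r, u in cohort.truth.unimodal.items() if u],
        "distance_effect": list(cohort.truth.distance_effect),
        "seed": cohort.config.seed,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))


def read_connectome_dir(path) -> tuple[dict[str, np.ndarray], tuple[str, ...]]:
    path = Path(path)
    adjacencies: dict[str, np.ndarray] = {}
    labels: tuple[str, ...] | None = None
    for f in sorted(path.glob("*_connectome.tsv")):
        sid = f.name.removesuffix("_connectome.tsv")
        adj, labs = read_adjacency_tsv(f)
        if labels is None:
            labels = labs
        elif labs != labels:
            raise ValueError(f"{f}: region labels differ from other subjects")
        adjacencies[sid] = adj
    if not adjacencies:
        raise ValueError(f"no *_connectome.tsv files under {path}")
    return adjacencies, labels


def write_epicenters_json(path, sets: dict) -> None:
    payload = {
        s.subject: {"regions": list(s.regions), "zscores": s.zscores,
                    "threshold": s.threshold, "degenerate": s.degenerate}
        for s in sets.values()
    }
    Path(path).write_text(json.dumps(payload, indent=1))
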