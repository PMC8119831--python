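"""File formats: TSV matrices, cohort CSV, YAML configs, GraphML.

Matrix files are tab-separated with a header row of node labels and a
leading label column; the parcellation is a 3-column TSV (index, label,
hemisphere); volumes are 2-column TSV (label, mm^3). Cohort tables are
CSV with one row per subject. Simulation configs round-trip through
YAML/JSON-compatible dictionaries.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .cohort import COGNITION_TESTS, COVARIATES
from .network import SubjectRaw, WeightedNetwork
from .parcellation import Parcellation
from .simulate import (
    CognitionConfig,
    CohortConfig,
    EdgeEffect,
    GroupCovariates,
    TemplateConfig,
)

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_volumes",
    "read_volumes",
    "write_parcellation",
    "read_parcellation",
    "write_cohort",
    "read_cohort",
    "write_subject_raw",
    "read_subject_raw",
    "network_to_graphml",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
]


class FileFormatError(ValueError):
    """Raised when an on-disk matrix or table violates its contract."""

    def __init__(self, path, message):
        super().__init__(f"{path}: {message}")
        self.path = str(path)


def write_matrix(path, matrix: np.ndarray, labels: tuple[str, ...]) -> None:
    pd.DataFrame(matrix, index=list(labels), columns=list(labels)).to_csv(path, sep="\t")


def read_matrix(path, labels: tuple[str, ...] | None = None) -> tuple[np.ndarray, list[str]]:
    """Read a labeled square matrix; optionally check against ``labels``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FileFormatError(path, f"matrix is not square: {df.shape}")
    if list(df.index) != list(df.columns):
        raise FileFormatError(path, "row labels differ from column labels")
    if labels is not None and list(df.columns) != list(labels):
        raise FileFormatError(path, "node labels do not match the parcellation")
    return df.to_numpy(float), list(df.columns)


def write_volumes(path, volumes: np.ndarray, labels: tuple[str, ...]) -> None:
    pd.DataFrame({"label": list(labels), "volume_mm3": volumes}).to_csv(
        path, sep="\t", index=False
    )


def read_volumes(path, labels: tuple[str, ...] | None = None) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if labels is not None and list(df["label"]) != list(labels):
        raise FileFormatError(path, "volume labels do not match the parcellation")
    return df["volume_mm3"].to_numpy(float)


def write_parcellation(path, parcellation: Parcellation) -> None:
    parcellation.to_frame().to_csv(path, sep="\t", index=False)


def read_parcellation(path) -> Parcellation:
    return Parcellation.from_frame(pd.read_csv(path, sep="\t"))


def write_cohort(path, cohort: pd.DataFrame) -> None:
    cols = ["subject_id", "group", "adci", "lbci", *COVARIATES]
    cols += [t for t in COGNITION_TESTS if t in cohort.columns]
    extra = [c for c in cohort.columns if c not in cols]
    cohort[cols + extra].to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_subject_raw(directory, raw: SubjectRaw, labels: tuple[str, ...]) -> None:
    """Write one subject's counts/FA/volumes/ICV under ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_matrix(d / "counts.tsv", raw.counts, labels)
    write_matrix(d / "mean_fa.tsv", raw.mean_fa, labels)
    write_volumes(d / "volumes.tsv", raw.volumes, labels)
    (d / "meta.json").write_text(
        json.dumps({"subject_id": raw.subject_id, "icv_mm3": raw.icv})
    )


def read_subject_raw(directory, labels: tuple[str, ...] | None = None) -> SubjectRaw:
    d = Path(directory)
    counts, read_labels = read_matrix(d / "counts.tsv", labels)
    fa, _ = read_matrix(d / "mean_fa.tsv", labels or tuple(read_labels))
    volumes = read_volumes(d / "volumes.tsv", labels or tuple(read_labels))
    meta = json.loads((d / "meta.json").read_text())
    return SubjectRaw(
        counts=counts.astype(np.int64),
        mean_fa=fa,
        volumes=volumes,
        icv=float(meta["icv_mm3"]),
        subject_id=str(meta["subject_id"]),
    )


def network_to_graphml(path, net: WeightedNetwork) -> None:
    g = nx.Graph()
    for i, lab in enumerate(net.parcellation.labels):
        g.add_node(lab, hemisphere=net.parcellation.hemispheres[i])
    ii, jj = np.nonzero(np.triu(net.weights, 1))
    for i, j in zip(ii, jj):
        g.add_edge(
            net.parcellation.labels[i],
            net.parcellation.labels[j],
            weight=float(net.weights[i, j]),
        )
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# config serialization


def config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["effects"] = [dataclasses.asdict(e) for e in config.effects]
    return json.loads(json.dumps(d))  # tuples -> lists, plain types only


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    kwargs: dict = {}
    if "template" in d:
        kwargs["template"] = TemplateConfig(**d["template"])
    if "covariates" in d:
        kwargs["covariates"] = {
            g: GroupCovariates(
                age=tuple(v["age"]),
                education=tuple(v["education"]),
                female_p=v["female_p"],
                dwmh_probs=tuple(v["dwmh_probs"]),
                pwmh_probs=tuple(v["pwmh_probs"]),
                icv=tuple(v["icv"]),
            )
            for g, v in d["covariates"].items()
        }
    if "effects" in d:
        kwargs["effects"] = tuple(
            EdgeEffect(
                flag=e["flag"],
                scope=tuple(tuple(p) for p in e["scope"])
                if isinstance(e["scope"], list)
                else e["scope"],
                count_scale=e.get("count_scale", 1.0),
                fa_scale=e.get("fa_scale", 1.0),
            )
            for e in d["effects"]
        )
    if "cognition" in d:
        kwargs["cognition"] = CognitionConfig(
            loadings={k: dict(v) for k, v in d["cognition"]["loadings"].items()},
            noise_sd=d["cognition"].get("noise_sd", 1.0),
        )
    for key in (
        "group_sizes",
        "subject_count_log_sd",
        "subject_fa_sd",
        "subject_volume_log_sd",
        "min_streamlines",
        "seed",
    ):
        if key in d:
            kwargs[key] = d[key]
    return CohortConfig(**kwargs)


def save_config(path, config: CohortConfig) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def load_config(path) -> CohortConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})
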