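"""End-to-end pipeline: simulate/load -> construct -> measure -> infer.

``run_pipeline`` consumes a :class:`RunConfig` that either points at an
input directory (cohort CSV + per-subject matrix files) or embeds a
simulation block, runs the cohort analysis, and writes stable file
outputs: the per-subject measure table, global/local disease-effect
tables, group contrasts, cognition model tables, and a JSON run
manifest recording seeds and model-selection decisions. Outputs are
byte-identical across reruns with the same configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import DEFAULT_CONTRASTS, ConnectomeCohortModel, ConnectomeCohortResults
from .cohort import COGNITION_TESTS, COVARIATES, records_to_frame
from .io import (
    config_from_dict,
    config_to_dict,
    read_cohort,
    read_matrix,
    read_parcellation,
    read_subject_raw,
    read_volumes,
    write_cohort,
    write_parcellation,
    write_subject_raw,
)
from .network import SubjectRaw
from .nullmodel import NullEnsembleSpec
from .parcellation import Parcellation, default_parcellation
from .simulate import CohortConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "write_simulated_cohort"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration: exactly one of ``input_dir``/``simulate``."""

    output_dir: str
    input_dir: str | None = None
    simulate: CohortConfig | None = None
    min_streamlines: int = 3
    null_spec: NullEnsembleSpec = NullEnsembleSpec()
    normalize: bool = True
    interaction_screening: bool = True
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.simulate is None):
            raise ValueError("exactly one of input_dir / simulate must be given")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "simulate" in d and d["simulate"] is not None:
            d["simulate"] = config_from_dict(d["simulate"])
        if "null_spec" in d:
            d["null_spec"] = NullEnsembleSpec(**d["null_spec"])
        if "contrasts" in d:
            d["contrasts"] = tuple(tuple(c) for c in d["contrasts"])
        return cls(**d)


def _load_inputs(
    input_dir: str,
) -> tuple[pd.DataFrame, list[SubjectRaw], Parcellation]:
    d = Path(input_dir)
    parc_path = d / "parcellation.tsv"
    parcellation = read_parcellation(parc_path) if parc_path.exists() else default_parcellation()
    cohort = read_cohort(d / "cohort.csv")
    raws = []
    for sid in cohort["subject_id"]:
        raws.append(read_subject_raw(d / "subjects" / str(sid), parcellation.labels))
    return cohort, raws, parcellation


def validate_inputs(input_dir: str) -> list[dict]:
    """Validate an input directory; returns one violation dict per issue
    (empty list = fully valid)."""
    violations: list[dict] = []

    def bad(path, message):
        violations.append({"file": str(path), "violation": message})

    d = Path(input_dir)
    parc_path = d / "parcellation.tsv"
    try:
        parcellation = read_parcellation(parc_path) if parc_path.exists() else default_parcellation()
    except Exception as e:  # noqa: BLE001
        bad(parc_path, str(e))
        return violations
    labels = parcellation.labels

    cohort_path = d / "cohort.csv"
    if not cohort_path.exists():
        bad(cohort_path, "missing cohort table")
        return violations
    cohort = read_cohort(cohort_path)
    for col in ["subject_id", "group", *COVARIATES, *COGNITION_TESTS]:
        if col not in cohort.columns:
            bad(cohort_path, f"missing column {col!r}")

    for sid in cohort.get("subject_id", []):
        sdir = d / "subjects" / str(sid)
        for name in ("counts.tsv", "mean_fa.tsv", "volumes.tsv"):
            if not (sdir / name).exists():
                bad(sdir / name, "missing file")
        try:
            counts, _ = read_matrix(sdir / "counts.tsv", labels)
            fa, _ = read_matrix(sdir / "mean_fa.tsv", labels)
            volumes = read_volumes(sdir / "volumes.tsv", labels)
        except Exception as e:  # noqa: BLE001
            bad(sdir, str(e))
            continue
        if not np.allclose(counts, counts.T, atol=1e-8):
            bad(sdir / "counts.tsv", "matrix is not symmetric")
        if (counts < 0).any():
            bad(sdir / "counts.tsv", "negative streamline counts")
        if not np.allclose(fa, fa.T, atol=1e-8):
            bad(sdir / "mean_fa.tsv", "matrix is not symmetric")
        if ((fa < 0) | (fa > 1)).any():
            ii, jj = np.nonzero((fa < 0) | (fa > 1))
            bad(sdir / "mean_fa.tsv", f"FA out of [0,1] at ({ii[0]},{jj[0]}): {fa[ii[0], jj[0]]}")
        if (fa[counts == 0] != 0).any():
            bad(sdir / "mean_fa.tsv", "nonzero FA on zero-count pairs")
        if (volumes <= 0).any():
            bad(sdir / "volumes.tsv", "nonpositive volume")
    return violations


def write_simulated_cohort(config: CohortConfig, out_dir: str, parcellation=None) -> None:
    """Materialize a simulated cohort as an input directory on disk."""
    parcellation = parcellation or default_parcellation()
    records, raws = generate_cohort(config, parcellation)
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    write_parcellation(d / "parcellation.tsv", parcellation)
    write_cohort(d / "cohort.csv", records_to_frame(records))
    for raw in raws:
        write_subject_raw(d / "subjects" / raw.subject_id, raw, parcellation.labels)
    (d / "simulation_config.yaml").write_text(
        yaml.safe_dump(config_to_dict(config), sort_keys=False)
    )


def run_pipeline(config: RunConfig) -> ConnectomeCohortResults:
    """Run the full analysis and write the report bundle to
    ``config.output_dir``."""
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        parcellation = default_parcellation()
        records, raws = generate_cohort(config.simulate, parcellation)
        cohort = records_to_frame(records)
        min_streamlines = config.simulate.min_streamlines
    else:
        cohort, raws, parcellation = _load_inputs(config.input_dir)
        min_streamlines = config.min_streamlines
    logger.info("cohort loaded: %d subjects (%.1fs)", len(cohort), time.time() - t0)

    model = ConnectomeCohortModel(
        cohort,
        raws,
        parcellation=parcellation,
        min_streamlines=min_streamlines,
        null_spec=config.null_spec,
        normalize=config.normalize,
        interaction_screening=config.interaction_screening,
        contrasts=config.contrasts,
    )
    results = model.fit()
    logger.info("analysis fitted (%.1fs)", time.time() - t0)

    write_cohort(out / "cohort.csv", cohort)
    results.measures.to_csv(out / "measures.csv", index=False)
    results.global_effects.table.to_csv(out / "global_effects.csv", index=False)
    for meas, tab in results.local_effects.items():
        tab.table.to_csv(out / f"local_effects_{meas}.csv", index=False)
    for (a, b), tabs in results.contrasts.items():
        tabs["global"].table.to_csv(out / f"contrast_{b}_vs_{a}_global.csv", index=False)
        for meas, tab in tabs["local"].items():
            tab.table.to_csv(out / f"contrast_{b}_vs_{a}_{meas}.csv", index=False)
    for name, models in results.cognition.items():
        for key, tab in models.items():
            tab.table.to_csv(out / f"cognition_{name}_{key}.csv", index=False)

    manifest = {
        "wmnet_version": __version__,
        "n_subjects": int(len(cohort)),
        "n_nodes": parcellation.n_nodes,
        "min_streamlines": min_streamlines,
        "null_ensemble": dataclasses.asdict(config.null_spec),
        "normalized": config.normalize,
        "simulation": config_to_dict(config.simulate) if config.simulate else None,
        "input_dir": config.input_dir,
        "model_selection": results.model_selection,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "summary.txt").write_text(results.summary() + "\n")
    logger.info("report bundle written to %s", out)
    return results
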