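"""Cohort-level analysis as a Model / Results pair.

:class:`ConnectomeCohortModel` bundles a cohort table with the
subjects' raw connectome inputs; ``fit()`` builds every subject's
weighted network, computes the five local and nine global measures
(normalizing the global ones against degree-preserving random-graph
ensembles), estimates the independent ADCI and LBCI effects with
interaction screening and AIC model choice, runs group-wise contrasts,
and fits the cognition models for every measure showing a disease
effect. The returned :class:`ConnectomeCohortResults` carries the
per-subject measure table and all effect tables, with FDR control
across the 92 nodes (local measures) and across the 14
neuropsychological tests (cognition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import COVARIATES, records_to_frame, validate_cohort_frame
from .glm import (
    ALPHA,
    EffectTable,
    batch_ols,
    cognition_models,
    disease_effect_model,
    fdr_correct,
    select_model_by_aic,
)
from .measures import LOCAL_MEASURE_NAMES, measure_network
from .network import SubjectRaw, build_network
from .nullmodel import NullEnsembleSpec, normalize_globals, subject_seed
from .parcellation import Parcellation, default_parcellation

__all__ = ["ConnectomeCohortModel", "ConnectomeCohortResults"]

logger = logging.getLogger(__name__)

DEFAULT_CONTRASTS = (("control", "mixed"), ("control", "pure_lbci"), ("control", "pure_adci"))


class ConnectomeCohortModel:
    """Disease-effect analysis of a cohort of structural connectomes.

    Parameters
    ----------
    cohort
        One row per subject (id, group, flags, covariates, cognition).
    raws
        Raw connectome inputs in the same order as ``cohort`` rows.
    min_streamlines
        Edge-retention threshold on streamline counts (default 3).
    null_spec
        Random-graph ensemble used to normalize global measures.
    normalize
        Skip null normalization when False (gamma/lambda/sigma columns
        are then absent).
    interaction_screening
        Screen the ADCI x LBCI term and choose models by AIC.
    contrasts
        Group pairs for covariate-adjusted group-wise comparisons.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        raws: list[SubjectRaw],
        parcellation: Parcellation | None = None,
        min_streamlines: int = 3,
        null_spec: NullEnsembleSpec = NullEnsembleSpec(),
        normalize: bool = True,
        interaction_screening: bool = True,
        contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS,
        cognition_predictors: list[str] | None = None,
    ) -> None:
        validate_cohort_frame(cohort)
        if len(cohort) != len(raws):
            raise ValueError("cohort table and raw subject list differ in length")
        self.cohort = cohort.reset_index(drop=True)
        self.raws = raws
        self.parcellation = parcellation or default_parcellation()
        self.min_streamlines = min_streamlines
        self.null_spec = null_spec
        self.normalize = normalize
        self.interaction_screening = interaction_screening
        self.contrasts = contrasts
        self.cognition_predictors = cognition_predictors

    @classmethod
    def from_simulation(cls, config=None, parcellation=None, **options) -> "ConnectomeCohortModel":
        """Simulate a cohort (see :mod:`wmnet.simulate`) and wrap it."""
        from .simulate import default_config, generate_cohort

        if config is None:
            config = default_config()
        parcellation = parcellation or default_parcellation()
        records, raws = generate_cohort(config, parcellation)
        return cls(
            records_to_frame(records),
            raws,
            parcellation=parcellation,
            min_streamlines=config.min_streamlines,
            **options,
        )

    # ------------------------------------------------------------------
    def compute_measures(self) -> pd.DataFrame:
        """Per-subject measure table: 5 x n_nodes local columns named
        ``<measure>_<label>`` plus ``global_<name>`` columns."""
        labels = self.parcellation.labels
        rows = []
        for raw in self.raws:
            net = build_network(raw, self.min_streamlines, self.parcellation)
            loc, glob = measure_network(net)
            if self.normalize:
                spec = NullEnsembleSpec(
                    n_graphs=self.null_spec.n_graphs,
                    swaps_per_edge=self.null_spec.swaps_per_edge,
                    seed=subject_seed(self.null_spec.seed, raw.subject_id),
                )
                glob = normalize_globals(net, glob, spec)
            row: dict[str, float] = {"subject_id": raw.subject_id}
            for name, vec in loc.as_dict().items():
                row.update({f"{name}_{lab}": v for lab, v in zip(labels, vec)})
            for name, v in glob.as_dict().items():
                if v is not None:
                    row[f"global_{name}"] = v
            rows.append(row)
        df = pd.DataFrame(rows)
        return df

    def _disease_design(self, cohort: pd.DataFrame, interaction: bool) -> pd.DataFrame:
        design = pd.DataFrame(
            {
                "const": 1.0,
                "adci": cohort["adci"].astype(float),
                "lbci": cohort["lbci"].astype(float),
            },
            index=cohort.index,
        )
        if interaction:
            design["adci_x_lbci"] = design["adci"] * design["lbci"]
        for c in COVARIATES:
            design[c] = cohort[c].astype(float)
        return design

    def _global_effects(self, measures: pd.DataFrame) -> tuple[EffectTable, list[dict]]:
        rows, rationales = [], []
        global_cols = [c for c in measures.columns if c.startswith("global_")]
        for col in global_cols:
            y = measures[col].to_numpy()
            fit_no = disease_effect_model(y, self.cohort, with_interaction=False, outcome=col)
            if self.interaction_screening:
                fit_with = disease_effect_model(y, self.cohort, with_interaction=True, outcome=col)
                _, _, p_int = fit_with.coef("adci_x_lbci")
                chosen, rationale = select_model_by_aic(fit_with, fit_no, p_int)
                rationales.append(rationale)
            else:
                chosen = fit_no
            for pred in ("adci", "lbci") + (
                ("adci_x_lbci",) if "adci_x_lbci" in chosen.predictors else ()
            ):
                beta, se, p = chosen.coef(pred)
                rows.append(
                    {"outcome": col, "predictor": pred, "beta": beta, "se": se, "p": p}
                )
        return EffectTable(pd.DataFrame(rows), scope="none"), rationales

    def _local_effects(self, measures: pd.DataFrame) -> dict[str, EffectTable]:
        labels = self.parcellation.labels
        out: dict[str, EffectTable] = {}
        x_no = self._disease_design(self.cohort, False).to_numpy(float)
        names_no = list(self._disease_design(self.cohort, False).columns)
        x_with = self._disease_design(self.cohort, True).to_numpy(float)
        names_with = list(self._disease_design(self.cohort, True).columns)
        for meas in LOCAL_MEASURE_NAMES:
            y = measures[[f"{meas}_{lab}" for lab in labels]].to_numpy(float)
            res_no = batch_ols(x_no, y, names_no)
            if self.interaction_screening:
                res_with = batch_ols(x_with, y, names_with)
                i_int = names_with.index("adci_x_lbci")
                # interaction kept when significant; otherwise lower AIC wins
                use_with = (res_with["p"][i_int] < ALPHA) | (
                    (res_with["p"][i_int] >= ALPHA) & (res_with["aic"] < res_no["aic"])
                )
            else:
                res_with = None
                use_with = np.zeros(len(labels), dtype=bool)
            rows = []
            for pred in ("adci", "lbci"):
                ia, iw = names_no.index(pred), names_with.index(pred)
                for j, lab in enumerate(labels):
                    src, i = (res_with, iw) if use_with[j] else (res_no, ia)
                    rows.append(
                        {
                            "outcome": lab,
                            "predictor": pred,
                            "beta": src["beta"][i, j],
                            "se": src["se"][i, j],
                            "p": src["p"][i, j],
                        }
                    )
            df = pd.DataFrame(rows)
            df["p_fdr"] = np.concatenate(
                [fdr_correct(df.loc[df["predictor"] == pred, "p"].to_numpy()) for pred in ("adci", "lbci")]
            )
            out[meas] = EffectTable(df, scope="92 nodes")
        return out

    def _contrast_tables(self, measures: pd.DataFrame) -> dict:
        out: dict = {}
        labels = self.parcellation.labels
        for a, b in self.contrasts:
            sub = self.cohort[self.cohort["group"].isin([a, b])]
            if sub["group"].nunique() < 2:
                continue
            design = pd.DataFrame({"const": 1.0, "group": (sub["group"] == b).astype(float)}, index=sub.index)
            for c in COVARIATES:
                design[c] = sub[c].astype(float)
            x = design.to_numpy(float)
            if np.linalg.matrix_rank(x) < x.shape[1]:
                # degenerate subset (e.g. a covariate constant within the
                # two groups): skip this contrast rather than abort
                logger.warning(
                    "contrast %s vs %s skipped: rank-deficient design on %d subjects",
                    b, a, len(sub),
                )
                continue
            names = list(design.columns)
            ig = names.index("group")
            grows = []
            for col in [c for c in measures.columns if c.startswith("global_")]:
                res = batch_ols(x, measures.loc[sub.index, col].to_numpy(float), names)
                grows.append(
                    {
                        "outcome": col,
                        "predictor": f"{b}_vs_{a}",
                        "beta": res["beta"][ig, 0],
                        "se": res["se"][ig, 0],
                        "p": res["p"][ig, 0],
                    }
                )
            local = {}
            for meas in LOCAL_MEASURE_NAMES:
                y = measures.loc[sub.index, [f"{meas}_{lab}" for lab in labels]].to_numpy(float)
                res = batch_ols(x, y, names)
                df = pd.DataFrame(
                    {
                        "outcome": labels,
                        "predictor": f"{b}_vs_{a}",
                        "beta": res["beta"][ig],
                        "se": res["se"][ig],
                        "p": res["p"][ig],
                    }
                )
                df["p_fdr"] = fdr_correct(df["p"].to_numpy())
                local[meas] = EffectTable(df, scope="92 nodes")
            out[(a, b)] = {
                "global": EffectTable(pd.DataFrame(grows), scope="none"),
                "local": local,
            }
        return out

    def _cognition_tables(
        self,
        measures: pd.DataFrame,
        global_effects: EffectTable,
        local_effects: dict[str, EffectTable],
    ) -> dict:
        """Cognition GLMs for every measure with a significant disease
        effect (the disease flag concerned becomes the Model 2 control)."""
        chosen: dict[str, str] = {}
        if self.cognition_predictors is not None:
            chosen = {name: "lbci" for name in self.cognition_predictors}
        else:
            ge = global_effects.table
            for _, r in ge[(ge["p"] < ALPHA) & ge["predictor"].isin(["adci", "lbci"])].iterrows():
                chosen.setdefault(r["outcome"], r["predictor"])
            for meas, tab in local_effects.items():
                t = tab.table
                sig = t[(t["p_fdr"] < ALPHA) & t["predictor"].isin(["adci", "lbci"])]
                for _, r in sig.iterrows():
                    chosen.setdefault(f"{meas}_{r['outcome']}", r["predictor"])
        out = {}
        for name, flag in chosen.items():
            if name not in measures.columns:
                continue
            out[name] = cognition_models(
                self.cohort,
                measures[name].to_numpy(float),
                predictor_name=name,
                model2_disease=flag,
            )
        return out

    # ------------------------------------------------------------------
    def fit(self, measures: pd.DataFrame | None = None) -> "ConnectomeCohortResults":
        """Run the full analysis; a precomputed measure table (from
        :meth:`compute_measures`) may be supplied to skip recomputation."""
        if measures is None:
            logger.info("computing measures for %d subjects", len(self.raws))
            measures = self.compute_measures()
        measures = measures.reset_index(drop=True)
        if "subject_id" in measures.columns:
            order = {sid: i for i, sid in enumerate(self.cohort["subject_id"])}
            measures = (
                measures.sort_values("subject_id", key=lambda s: s.map(order))
                .reset_index(drop=True)
            )
        global_effects, rationales = self._global_effects(measures)
        local_effects = self._local_effects(measures)
        contrasts = self._contrast_tables(measures)
        cognition = self._cognition_tables(measures, global_effects, local_effects)
        return ConnectomeCohortResults(
            model=self,
            measures=measures,
            global_effects=global_effects,
            local_effects=local_effects,
            contrasts=contrasts,
            cognition=cognition,
            model_selection=rationales,
        )


@dataclass
class ConnectomeCohortResults:
    """Fitted cohort analysis: measure table and all effect tables."""

    model: ConnectomeCohortModel
    measures: pd.DataFrame
    global_effects: EffectTable
    local_effects: dict[str, EffectTable]
    contrasts: dict
    cognition: dict
    model_selection: list[dict] = field(default_factory=list)

    def global_effect(self, measure: str, predictor: str) -> tuple[float, float, float]:
        """(beta, SE, p) of a disease predictor on a global measure."""
        t = self.global_effects.table
        row = t[(t["outcome"] == f"global_{measure}") & (t["predictor"] == predictor)]
        if row.empty:
            raise KeyError(f"no effect row for {measure!r} / {predictor!r}")
        r = row.iloc[0]
        return float(r["beta"]), float(r["se"]), float(r["p"])

    def local_effect(self, measure: str, node: str, predictor: str) -> dict:
        t = self.local_effects[measure].table
        row = t[(t["outcome"] == node) & (t["predictor"] == predictor)]
        if row.empty:
            raise KeyError(f"no effect row for {measure}/{node}/{predictor}")
        return row.iloc[0].to_dict()

    def summary(self) -> str:
        n = len(self.model.cohort)
        counts = self.model.cohort["group"].value_counts()
        lines = [
            "Structural connectome cohort analysis",
            "=" * 54,
            f"subjects: {n} "
            + "(" + ", ".join(f"{g}={counts.get(g, 0)}" for g in ("control", "pure_adci", "pure_lbci", "mixed")) + ")",
            f"nodes: {self.model.parcellation.n_nodes}, edge rule: >= "
            f"{self.model.min_streamlines} streamlines",
            "",
            "Disease effects on global measures (beta (SE), p):",
        ]
        t = self.global_effects.table
        for outcome in t["outcome"].unique():
            parts = []
            for pred in ("adci", "lbci"):
                row = t[(t["outcome"] == outcome) & (t["predictor"] == pred)]
                if len(row):
                    r = row.iloc[0]
                    parts.append(f"{pred}: {r['beta']:.3g} ({r['se']:.3g}), p={r['p']:.3f}")
            lines.append(f"  {outcome.removeprefix('global_'):<32}" + "; ".join(parts))
        lines.append("")
        lines.append("FDR-significant local effects (q < 0.05, across 92 nodes):")
        any_sig = False
        for meas, tab in self.local_effects.items():
            sig = tab.significant()
            for _, r in sig.iterrows():
                any_sig = True
                lines.append(
                    f"  {meas:<12} {r['outcome']:<26} {r['predictor']}: "
                    f"beta={r['beta']:.3g}, p_fdr={r['p_fdr']:.4f}"
                )
        if not any_sig:
            lines.append("  (none)")
        if self.cognition:
            lines.append("")
            lines.append("Cognition models fitted for: " + ", ".join(self.cognition))
        return "\n".join(lines)

    def plot_local_effects(self, measure: str, predictor: str = "lbci", ax=None):
        """Bar plot of per-node t-values for one local measure."""
        import matplotlib.pyplot as plt

        t = self.local_effects[measure].table
        sub = t[t["predictor"] == predictor]
        if ax is None:
            _, ax = plt.subplots(figsize=(14, 3))
        tv = sub["beta"] / sub["se"]
        ax.bar(range(len(sub)), tv, color=np.where(sub["p_fdr"] < ALPHA, "crimson", "grey"))
        ax.set_xticks(range(len(sub)))
        ax.set_xticklabels(sub["outcome"], rotation=90, fontsize=4)
        ax.set_ylabel(f"t ({predictor} on {measure})")
        return ax
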