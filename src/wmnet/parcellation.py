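"""Brain parcellation schemes for network nodes.

The default scheme is the 90-region cortical + subcortical AAL atlas
(45 regions per hemisphere, interleaved left/right in standard atlas
order) extended with the bilateral substantia innominata, giving 92
network nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["Parcellation", "default_parcellation", "AAL_BASE_REGIONS"]

# The 45 AAL base regions of one hemisphere, in standard atlas order
# (39 cortical + 6 subcortical: caudate, putamen, pallidum, thalamus
# are counted among them together with hippocampus and amygdala).
AAL_BASE_REGIONS: tuple[str, ...] = (
    "Precentral",
    "Frontal_Sup",
    "Frontal_Sup_Orb",
    "Frontal_Mid",
    "Frontal_Mid_Orb",
    "Frontal_Inf_Oper",
    "Frontal_Inf_Tri",
    "Frontal_Inf_Orb",
    "Rolandic_Oper",
    "Supp_Motor_Area",
    "Olfactory",
    "Frontal_Sup_Medial",
    "Frontal_Med_Orb",
    "Rectus",
    "Insula",
    "Cingulum_Ant",
    "Cingulum_Mid",
    "Cingulum_Post",
    "Hippocampus",
    "ParaHippocampal",
    "Amygdala",
    "Calcarine",
    "Cuneus",
    "Lingual",
    "Occipital_Sup",
    "Occipital_Mid",
    "Occipital_Inf",
    "Fusiform",
    "Postcentral",
    "Parietal_Sup",
    "Parietal_Inf",
    "SupraMarginal",
    "Angular",
    "Precuneus",
    "Paracentral_Lobule",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Thalamus",
    "Heschl",
    "Temporal_Sup",
    "Temporal_Pole_Sup",
    "Temporal_Mid",
    "Temporal_Pole_Mid",
    "Temporal_Inf",
)

# Coarse lobe assignment of each base region, used by the synthetic
# template generator to impose a modular block structure.
_LOBE_OF_REGION: dict[str, str] = {
    **{r: "frontal" for r in AAL_BASE_REGIONS[0:15]},
    **{r: "limbic" for r in AAL_BASE_REGIONS[15:21]},
    **{r: "occipital" for r in AAL_BASE_REGIONS[21:28]},
    **{r: "parietal" for r in AAL_BASE_REGIONS[28:35]},
    **{r: "subcortical" for r in AAL_BASE_REGIONS[35:39]},
    **{r: "temporal" for r in AAL_BASE_REGIONS[39:45]},
}
_LOBE_OF_REGION["Substantia_Innominata"] = "subcortical"


class ParcellationError(ValueError):
    """Raised for inconsistent parcellation definitions or unknown labels."""


@dataclass(frozen=True)
class Parcellation:
    """An ordered node scheme: (index, label, hemisphere) triples.

    Parameters
    ----------
    labels
        Unique node labels, e.g. ``"Caudate_L"``.
    hemispheres
        One of ``"L"``/``"R"`` per node.
    """

    labels: tuple[str, ...]
    hemispheres: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.hemispheres):
            raise ParcellationError("labels and hemispheres differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise ParcellationError("node labels must be unique")
        bad = sorted(set(self.hemispheres) - {"L", "R"})
        if bad:
            raise ParcellationError(f"hemisphere codes must be L/R, got {bad}")
        object.__setattr__(
            self, "_index", {lab: i for i, lab in enumerate(self.labels)}
        )

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        """Resolve a node label to its matrix index."""
        try:
            return self._index[label]
        except KeyError:
            raise ParcellationError(f"unknown node label: {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def lobes(self) -> tuple[str, ...]:
        """Coarse lobe (module) assignment per node, for simulation."""
        out = []
        for lab in self.labels:
            base = lab[:-2] if lab.endswith(("_L", "_R")) else lab
            out.append(_LOBE_OF_REGION.get(base, "other"))
        return tuple(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": range(self.n_nodes),
                "label": self.labels,
                "hemisphere": self.hemispheres,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Parcellation":
        required = {"label", "hemisphere"}
        missing = required - set(df.columns)
        if missing:
            raise ParcellationError(f"missing columns: {sorted(missing)}")
        if "index" in df.columns:
            df = df.sort_values("index")
        return cls(tuple(df["label"]), tuple(df["hemisphere"]))


def default_parcellation() -> Parcellation:
    """The 92-node scheme: 45 AAL regions per hemisphere plus bilateral
    substantia innominata, interleaved left/right."""
    labels: list[str] = []
    hemis: list[str] = []
    for region in AAL_BASE_REGIONS + ("Substantia_Innominata",):
        for h in ("L", "R"):
            labels.append(f"{region}_{h}")
            hemis.append(h)
    return Parcellation(tuple(labels), tuple(hemis))
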