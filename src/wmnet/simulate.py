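"""Synthetic cohort generator emulating the study design.

Generates a four-group cohort (controls, pure ADCI, pure LBCI, mixed
disease; default sizes 37/22/19/36) of raw connectome inputs plus
metadata and cognition, with known planted effects, so that the whole
construction -> measurement -> inference chain can be exercised and its
parameter recovery checked without any real data.

The generative model, briefly:

* A population *template* connectome is drawn once per cohort: a
  modular random graph (within-lobe edge probability a few times the
  between-lobe probability — a simulation device, not a claim about
  anatomy), with log-normal streamline counts, Gaussian mean-FA values,
  and log-normal parcel volumes.
* Each subject perturbs the template with multiplicative log-normal
  count noise, additive FA noise, and volume noise; disease effects are
  *multiplicative scalings* of counts and/or FA on designated edge sets
  (e.g. all edges incident to the left caudate for LBCI), applied
  before counts are rounded back to integers. Scaled counts that round
  below 1 remove the edge — this is how planted scalings translate into
  degree and topology changes once the >= 3-streamline rule is applied.
* Cognition scores are linear in the subject's own (noise-free-score)
  network measures, disease flags and covariates, plus Gaussian noise,
  so recovery tests have an exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import COGNITION_TESTS, GROUPS, CohortRecord
from .measures import (
    local_clustering,
    node_degree,
    node_strength,
    global_measures,
    shortest_path_distances,
    nodal_path_length,
    betweenness,
)
from .network import SubjectRaw, build_network
from .parcellation import Parcellation, default_parcellation

__all__ = [
    "TemplateConfig",
    "EdgeEffect",
    "GroupCovariates",
    "CognitionConfig",
    "CohortConfig",
    "generate_template",
    "generate_cohort",
    "default_config",
    "integration_deficit_config",
]


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass(frozen=True)
class TemplateConfig:
    """Population template parameters.

    ``density`` is the expected edge density; within-module pairs are
    ``within_between_ratio`` times as likely to be connected as
    between-module pairs. Streamline counts are log-normal
    (``exp(N(count_log_mean, count_log_sd))`` rounded to integers), FA
    is Gaussian, volumes are log-normal (mm^3).
    """

    density: float = 0.25
    within_between_ratio: float = 4.0
    count_log_mean: float = 2.0
    count_log_sd: float = 1.0
    fa_mean: float = 0.45
    fa_sd: float = 0.06
    volume_log_mean: float = 8.9
    volume_log_sd: float = 0.45

    def __post_init__(self) -> None:
        if not 0 <= self.density <= 1:
            raise ConfigError("density must lie in [0, 1]")
        if self.within_between_ratio <= 0:
            raise ConfigError("within_between_ratio must be positive")


@dataclass(frozen=True)
class EdgeEffect:
    """A multiplicative disease scaling on a designated edge set.

    ``flag`` is ``"adci"``, ``"lbci"`` or ``"interaction"`` (applied to
    mixed-disease subjects only). ``scope`` is ``"all"``,
    ``"between_module"``, ``"node:<Label>"`` (edges incident to one
    node), or an explicit list of label pairs. Scales act on the
    subject's counts / FA before integer rounding and must lie in
    (0, 1.5].
    """

    flag: str
    scope: str | tuple = "all"
    count_scale: float = 1.0
    fa_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.flag not in ("adci", "lbci", "interaction"):
            raise ConfigError(f"unknown effect flag {self.flag!r}")
        for s in (self.count_scale, self.fa_scale):
            if not 0 < s <= 1.5:
                raise ConfigError(f"effect scales must lie in (0, 1.5], got {s}")

    def applies(self, adci: int, lbci: int) -> bool:
        if self.flag == "adci":
            return bool(adci)
        if self.flag == "lbci":
            return bool(lbci)
        return bool(adci and lbci)


@dataclass(frozen=True)
class GroupCovariates:
    """Per-group covariate distributions (means/SDs and probabilities)."""

    age: tuple[float, float]
    education: tuple[float, float]
    female_p: float
    dwmh_probs: tuple[float, float, float]
    pwmh_probs: tuple[float, float, float]
    icv: tuple[float, float]

    def __post_init__(self) -> None:
        for probs in (self.dwmh_probs, self.pwmh_probs):
            if abs(sum(probs) - 1) > 1e-9 or any(p < 0 for p in probs):
                raise ConfigError("ordinal probabilities must be a distribution")
        if not 0 <= self.female_p <= 1:
            raise ConfigError("female_p must lie in [0, 1]")


@dataclass(frozen=True)
class CognitionConfig:
    """Linear generative model for the 14 cognition z-scores.

    ``loadings`` maps each test to ``{key: coefficient}`` where a key is
    a local measure (``"degree:<Label>"``, ``"strength:<Label>"``,
    ``"clustering:<Label>"``, ``"path_length:<Label>"``,
    ``"betweenness:<Label>"``), a raw global measure (``"mean_degree"``,
    ``"mean_strength"``, ``"clustering"``, ``"path_length"``,
    ``"global_efficiency"``), a covariate (``"age"`` ...), or a disease
    flag (``"adci"`` / ``"lbci"``). Gaussian noise with ``noise_sd`` is
    added on top.
    """

    loadings: dict[str, dict[str, float]]
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ConfigError("cognition noise SD must be > 0")
        extra = set(self.loadings) - set(COGNITION_TESTS)
        if extra:
            raise ConfigError(f"loadings given for unknown tests: {sorted(extra)}")


@dataclass(frozen=True)
class CohortConfig:
    """Full cohort simulation configuration (see module docstring)."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "control": 37,
            "pure_adci": 22,
            "pure_lbci": 19,
            "mixed": 36,
        }
    )
    template: TemplateConfig = TemplateConfig()
    covariates: dict[str, GroupCovariates] = field(
        default_factory=lambda: dict(_DEFAULT_COVARIATES)
    )
    effects: tuple[EdgeEffect, ...] = (
        # LBCI: strong dropout of left-caudate connections, plus a
        # milder loss of long-range (between-lobe) connections giving a
        # global-integration deficit (raised lambda, lowered normalized
        # E_glob). ADCI: diffuse FA reduction with no topology change.
        EdgeEffect(flag="lbci", scope="node:Caudate_L", count_scale=0.5),
        EdgeEffect(flag="lbci", scope="between_module", count_scale=0.95),
        EdgeEffect(flag="adci", scope="all", fa_scale=0.99),
    )
    cognition: CognitionConfig = None  # type: ignore[assignment]
    subject_count_log_sd: float = 0.4
    subject_fa_sd: float = 0.02
    subject_volume_log_sd: float = 0.05
    min_streamlines: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cognition is None:
            object.__setattr__(self, "cognition", _default_cognition())
        unknown = set(self.group_sizes) - set(GROUPS)
        if unknown:
            raise ConfigError(f"unknown groups: {sorted(unknown)}")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ConfigError("group sizes must be nonnegative")

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())

    def with_null_effects(self) -> "CohortConfig":
        """A copy with every planted scaling removed (all-null cohort)."""
        return replace(self, effects=())


_DEFAULT_COVARIATES: dict[str, GroupCovariates] = {
    "control": GroupCovariates(
        age=(70.2, 5.6),
        education=(11.6, 4.7),
        female_p=0.676,
        dwmh_probs=(0.90, 0.10, 0.00),
        pwmh_probs=(0.90, 0.10, 0.00),
        icv=(1.43e6, 1.3e5),
    ),
    "pure_adci": GroupCovariates(
        age=(69.8, 9.1),
        education=(10.9, 3.7),
        female_p=0.636,
        dwmh_probs=(0.50, 0.40, 0.10),
        pwmh_probs=(0.60, 0.30, 0.10),
        icv=(1.43e6, 1.3e5),
    ),
    "pure_lbci": GroupCovariates(
        age=(75.4, 8.8),
        education=(9.4, 4.6),
        female_p=0.632,
        dwmh_probs=(0.55, 0.35, 0.10),
        pwmh_probs=(0.45, 0.30, 0.25),
        icv=(1.43e6, 1.3e5),
    ),
    "mixed": GroupCovariates(
        age=(74.5, 7.3),
        education=(10.9, 5.1),
        female_p=0.472,
        dwmh_probs=(0.55, 0.40, 0.05),
        pwmh_probs=(0.35, 0.50, 0.15),
        icv=(1.43e6, 1.3e5),
    ),
}


def _default_cognition() -> CognitionConfig:
    # Every battery score depends positively on left-caudate degree and
    # negatively on each disease flag; broad and uniform by design.
    loadings = {
        test: {"degree:Caudate_L": 0.08, "adci": -0.5, "lbci": -0.5}
        for test in COGNITION_TESTS
    }
    return CognitionConfig(loadings=loadings, noise_sd=1.0)


def default_config(seed: int = 0) -> CohortConfig:
    """The default study-design configuration (group sizes 37/22/19/36)."""
    return CohortConfig(seed=seed)


def integration_deficit_config(seed: int = 0) -> CohortConfig:
    """Study conditions with a pronounced LBCI global-integration deficit.

    Strengthens the loss of long-range (between-lobe) connections
    (count scale 0.75) so the disease effect on normalized path length
    and normalized global efficiency is clearly expressed; used when
    studying global network effects.
    """
    cfg = CohortConfig(seed=seed)
    effects = tuple(
        EdgeEffect(flag=e.flag, scope=e.scope, count_scale=0.75, fa_scale=e.fa_scale)
        if e.flag == "lbci" and e.scope == "between_module"
        else e
        for e in cfg.effects
    )
    return replace(cfg, effects=effects)


# ---------------------------------------------------------------------------
# template


def _round_robin_modules(n_nodes: int, n_modules: int = 4) -> tuple[str, ...]:
    return tuple(f"m{i % n_modules}" for i in range(n_nodes))


def _parcellation_modules(parcellation: Parcellation) -> tuple[str, ...]:
    return tuple(
        f"{lobe}_{h}" for lobe, h in zip(parcellation.lobes(), parcellation.hemispheres)
    )


def generate_template(
    n_nodes: int,
    seed: int,
    config: TemplateConfig = TemplateConfig(),
    modules: tuple[str, ...] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw a population base connectome: (counts, mean FA, volumes).

    Counts are symmetric nonnegative integers with zero diagonal; FA is
    in [0, 1] exactly where the count is positive; volumes are positive
    (mm^3). Identical arguments give bitwise-identical output.
    """
    if n_nodes < 3:
        raise ConfigError("n_nodes must be >= 3")
    if modules is None:
        modules = _round_robin_modules(n_nodes)
    if len(modules) != n_nodes:
        raise ConfigError("modules must have one entry per node")
    rng = np.random.default_rng(seed)
    mods = np.asarray(modules)
    within = mods[:, None] == mods[None, :]
    iu = np.triu_indices(n_nodes, 1)
    frac_within = float(within[iu].mean())
    r = config.within_between_ratio
    p_between = config.density / (frac_within * r + (1 - frac_within))
    p_within = min(r * p_between, 1.0)
    p_between = min(p_between, 1.0)

    prob = np.where(within[iu], p_within, p_between)
    present = rng.random(len(prob)) < prob
    counts_u = np.zeros(len(prob))
    counts_u[present] = np.maximum(
        np.rint(np.exp(rng.normal(config.count_log_mean, config.count_log_sd, present.sum()))),
        1,
    )
    fa_u = np.zeros(len(prob))
    fa_u[present] = np.clip(
        rng.normal(config.fa_mean, config.fa_sd, present.sum()), 0.05, 0.95
    )

    counts = np.zeros((n_nodes, n_nodes))
    fa = np.zeros((n_nodes, n_nodes))
    counts[iu] = counts_u
    fa[iu] = fa_u
    counts += counts.T
    fa += fa.T
    volumes = np.exp(rng.normal(config.volume_log_mean, config.volume_log_sd, n_nodes))
    return counts.astype(np.int64), fa, volumes


# ---------------------------------------------------------------------------
# effect scopes


def resolve_scope(
    scope: str | tuple,
    parcellation: Parcellation,
    modules: tuple[str, ...],
) -> np.ndarray:
    """Boolean symmetric edge mask (zero diagonal) for an effect scope."""
    n = parcellation.n_nodes
    mask = np.zeros((n, n), dtype=bool)
    if scope == "all":
        mask[:] = True
    elif scope == "between_module":
        mods = np.asarray(modules)
        mask = mods[:, None] != mods[None, :]
    elif isinstance(scope, str) and scope.startswith("node:"):
        i = parcellation.index_of(scope[5:])
        mask[i, :] = True
        mask[:, i] = True
    elif isinstance(scope, (list, tuple)):
        for a, b in scope:
            i, j = parcellation.index_of(a), parcellation.index_of(b)
            mask[i, j] = mask[j, i] = True
    else:
        raise ConfigError(f"unknown effect scope {scope!r}")
    np.fill_diagonal(mask, False)
    return mask


# ---------------------------------------------------------------------------
# cognition measure keys

_GLOBAL_KEYS = ("mean_degree", "mean_strength", "clustering", "path_length", "global_efficiency")
_LOCAL_PREFIXES = ("degree", "strength", "clustering", "path_length", "betweenness")


def _measure_value(key: str, cache: dict, weights: np.ndarray, parc: Parcellation) -> float:
    """Evaluate one measure key on a subject's network, caching vectors."""
    if ":" in key:
        prefix, label = key.split(":", 1)
        if prefix not in _LOCAL_PREFIXES:
            raise ConfigError(f"unknown local measure {prefix!r} in loading {key!r}")
        if prefix not in cache:
            if prefix == "degree":
                cache[prefix] = node_degree(weights)
            elif prefix == "strength":
                cache[prefix] = node_strength(weights)
            elif prefix == "clustering":
                cache[prefix] = local_clustering(weights)
            elif prefix == "path_length":
                cache[prefix] = nodal_path_length(_distances(cache, weights))
            else:
                cache[prefix] = betweenness(weights)
        return float(cache[prefix][parc.index_of(label)])
    if key in _GLOBAL_KEYS:
        if "globals" not in cache:
            cache["globals"] = global_measures(weights, _distances(cache, weights)).as_dict()
        return float(cache["globals"][key])
    raise ConfigError(f"unknown measure key {key!r}")


def _distances(cache: dict, weights: np.ndarray) -> np.ndarray:
    if "distances" not in cache:
        cache["distances"] = shortest_path_distances(weights)
    return cache["distances"]


# ---------------------------------------------------------------------------
# cohort


def _symmetric(rng_draw: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    out[iu] = rng_draw
    return out + out.T


def generate_cohort(
    config: CohortConfig,
    parcellation: Parcellation | None = None,
) -> tuple[list[CohortRecord], list[SubjectRaw]]:
    """Generate one cohort: one :class:`SubjectRaw` per record.

    Fully reproducible from ``config.seed``; subjects are emitted in
    group order (control, pure ADCI, pure LBCI, mixed).
    """
    if parcellation is None:
        parcellation = default_parcellation()
    n = parcellation.n_nodes
    modules = _parcellation_modules(parcellation)
    template_seed = np.random.SeedSequence([config.seed, 0])
    t_counts, t_fa, t_vol = generate_template(
        n, template_seed, config.template, modules=modules
    )
    # resolve scopes once (raises on unknown labels before any sampling)
    masks = [resolve_scope(e.scope, parcellation, modules) for e in config.effects]

    n_pairs = n * (n - 1) // 2
    records: list[CohortRecord] = []
    raws: list[SubjectRaw] = []
    idx = 0
    for group in GROUPS:
        size = config.group_sizes.get(group, 0)
        cov = config.covariates[group]
        for _ in range(size):
            # deterministic per-subject stream independent of group layout
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, idx]))
            sid = f"sub-{idx + 1:03d}"
            adci = int(group in ("pure_adci", "mixed"))
            lbci = int(group in ("pure_lbci", "mixed"))

            counts = t_counts * np.exp(
                _symmetric(rng.normal(0.0, config.subject_count_log_sd, n_pairs), n)
            )
            fa = np.where(
                t_counts > 0,
                np.clip(t_fa + _symmetric(rng.normal(0.0, config.subject_fa_sd, n_pairs), n), 0.01, 0.99),
                0.0,
            )
            for effect, mask in zip(config.effects, masks):
                if effect.applies(adci, lbci):
                    counts = np.where(mask, counts * effect.count_scale, counts)
                    fa = np.where(mask, np.clip(fa * effect.fa_scale, 0.0, 0.99), fa)
            counts = np.rint(counts)
            counts[counts < 1] = 0
            fa = np.where(counts > 0, fa, 0.0)
            np.fill_diagonal(counts, 0)
            np.fill_diagonal(fa, 0.0)

            volumes = t_vol * np.exp(rng.normal(0.0, config.subject_volume_log_sd, n))
            icv = float(rng.normal(*cov.icv))
            raw = SubjectRaw(
                counts=counts.astype(np.int64),
                mean_fa=fa,
                volumes=volumes,
                icv=icv,
                subject_id=sid,
            )

            age = float(rng.normal(*cov.age))
            sex = int(rng.random() < cov.female_p)  # 1 = female
            education = float(max(rng.normal(*cov.education), 0.0))
            dwmh = int(rng.choice((1, 2, 3), p=cov.dwmh_probs))
            pwmh = int(rng.choice((1, 2, 3), p=cov.pwmh_probs))

            net = build_network(raw, config.min_streamlines, parcellation)
            cache: dict = {}
            covariate_values = {
                "age": age,
                "sex": float(sex),
                "education": education,
                "dwmh": float(dwmh),
                "pwmh": float(pwmh),
                "icv": icv,
                "adci": float(adci),
                "lbci": float(lbci),
            }
            cognition = {}
            for test in COGNITION_TESTS:
                loadings = config.cognition.loadings.get(test, {})
                value = 0.0
                for key, coef in loadings.items():
                    if key in covariate_values:
                        value += coef * covariate_values[key]
                    else:
                        value += coef * _measure_value(key, cache, net.weights, parcellation)
                cognition[test] = value + float(rng.normal(0.0, config.cognition.noise_sd))

            records.append(
                CohortRecord(
                    subject_id=sid,
                    group=group,
                    age=age,
                    sex=sex,
                    education=education,
                    dwmh=dwmh,
                    pwmh=pwmh,
                    icv=icv,
                    cognition=cognition,
                )
            )
            raws.append(raw)
            idx += 1
    return records, raws
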