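import dataclasses

import numpy as np
import pytest

import wmnet
from wmnet.cohort import records_to_frame
from wmnet.glm import batch_ols
from wmnet.measures import node_degree
from wmnet.network import build_network
from wmnet.simulate import (
    CognitionConfig,
    ConfigError,
    EdgeEffect,
    TemplateConfig,
    generate_cohort,
    generate_template,
)


class TestTemplate:
    def test_deterministic_under_fixed_seed(self):
        a = generate_template(92, seed=1)
        b = generate_template(92, seed=1)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_contracts_symmetry_diagonal_fa_range(self):
        counts, fa, volumes = generate_template(92, seed=2)
        assert np.array_equal(counts, counts.T)
        assert np.all(np.diag(counts) == 0)
        assert np.all(counts >= 0)
        assert np.all((fa >= 0) & (fa <= 1))
        assert np.all(fa[counts == 0] == 0)
        assert np.all(fa[counts > 0] > 0)
        assert np.all(volumes > 0)

    def test_zero_density_gives_empty_template(self):
        counts, fa, _ = generate_template(10, seed=3, config=TemplateConfig(density=0.0))
        assert counts.sum() == 0
        assert fa.sum() == 0

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ConfigError, match="n_nodes"):
            generate_template(2, seed=0)

    def test_density_roughly_matches_request(self):
        counts, _, _ = generate_template(92, seed=4, config=TemplateConfig(density=0.3))
        realized = np.count_nonzero(np.triu(counts, 1)) / (92 * 91 / 2)
        assert realized == pytest.approx(0.3, abs=0.05)


class TestCohort:
    def test_default_group_sizes(self):
        records, raws = generate_cohort(wmnet.default_config(seed=0))
        counts = {g: sum(r.group == g for r in records) for g in wmnet.GROUPS}
        assert counts == {"control": 37, "pure_adci": 22, "pure_lbci": 19, "mixed": 36}
        assert len(raws) == 114

    def test_bitwise_reproducible(self):
        r1, w1 = generate_cohort(wmnet.default_config(seed=5))
        r2, w2 = generate_cohort(wmnet.default_config(seed=5))
        assert [r.cognition for r in r1] == [r.cognition for r in r2]
        assert [(r.age, r.sex, r.dwmh) for r in r1] == [(r.age, r.sex, r.dwmh) for r in r2]
        for a, b in zip(w1, w2):
            assert np.array_equal(a.counts, b.counts)
            assert np.array_equal(a.mean_fa, b.mean_fa)
            assert np.array_equal(a.volumes, b.volumes)

    def test_flags_match_groups(self):
        records, _ = generate_cohort(wmnet.default_config(seed=0))
        for r in records:
            assert r.adci == (r.group in ("pure_adci", "mixed"))
            assert r.lbci == (r.group in ("pure_lbci", "mixed"))
            assert len(r.cognition) == 14

    def test_unknown_effect_node_rejected(self):
        cfg = dataclasses.replace(
            wmnet.default_config(),
            effects=(EdgeEffect(flag="lbci", scope="node:Nucleus_Basalis_L"),),
        )
        with pytest.raises(Exception, match="unknown node label"):
            generate_cohort(cfg)

    def test_effect_scale_bounds_enforced(self):
        with pytest.raises(ConfigError, match="scales"):
            EdgeEffect(flag="lbci", scope="all", count_scale=1.6)
        with pytest.raises(ConfigError, match="scales"):
            EdgeEffect(flag="lbci", scope="all", count_scale=0.0)

    def test_raw_subjects_satisfy_network_contracts(self):
        _, raws = generate_cohort(wmnet.default_config(seed=6))
        raws[0].validate(wmnet.default_parcellation())
        net = build_network(raws[0])
        assert net.weights.shape == (92, 92)


class TestPlantedEffects:
    def test_null_config_groups_equivalent(self):
        """With all scalings removed, group means of mean degree agree."""
        cfg = wmnet.default_config(seed=8).with_null_effects()
        records, raws = generate_cohort(cfg)
        md = np.array([node_degree(build_network(r).weights).mean() for r in raws])
        lbci = np.array([r.lbci for r in records], bool)
        # two-sample comparison: no planted effect -> modest t statistic
        diff = md[lbci].mean() - md[~lbci].mean()
        pooled = md.std(ddof=1) * np.sqrt(1 / lbci.sum() + 1 / (~lbci).sum())
        assert abs(diff / pooled) < 4

    def test_caudate_scaling_lowers_lbci_degree(self):
        """A 0.5 count scaling on left-caudate edges lowers mean caudate
        degree for lbci=1 subjects in a 200-subject cohort."""
        cfg = dataclasses.replace(
            wmnet.default_config(seed=9),
            group_sizes={"control": 100, "pure_adci": 0, "pure_lbci": 100, "mixed": 0},
            effects=(EdgeEffect(flag="lbci", scope="node:Caudate_L", count_scale=0.5),),
        )
        records, raws = generate_cohort(cfg)
        ci = wmnet.default_parcellation().index_of("Caudate_L")
        deg = np.array([node_degree(build_network(r).weights)[ci] for r in raws])
        lbci = np.array([r.lbci for r in records], bool)
        assert deg[lbci].mean() < deg[~lbci].mean()

    def test_cognition_generated_from_stated_linear_model(self):
        """With a single loading and near-zero noise, the generated score
        is an affine function of the subject's caudate degree."""
        loadings = {t: {} for t in wmnet.COGNITION_TESTS}
        loadings["k_mmse"] = {"degree:Caudate_L": 0.1}
        cfg = dataclasses.replace(
            wmnet.default_config(seed=10),
            group_sizes={"control": 20, "pure_adci": 0, "pure_lbci": 20, "mixed": 0},
            cognition=CognitionConfig(loadings=loadings, noise_sd=1e-9),
        )
        records, raws = generate_cohort(cfg)
        ci = wmnet.default_parcellation().index_of("Caudate_L")
        deg = np.array([node_degree(build_network(r).weights)[ci] for r in raws])
        scores = np.array([r.cognition["k_mmse"] for r in records])
        assert np.allclose(scores, 0.1 * deg, atol=1e-6)
        assert np.allclose([r.cognition["k_bnt"] for r in records], 0, atol=1e-6)

    def test_disease_betas_centered_at_zero_under_null(self):
        """Across 500 replicate null cohorts the ADCI and LBCI GLM betas
        on mean degree average to ~0 (within 3 standard errors)."""
        sizes = {"control": 10, "pure_adci": 8, "pure_lbci": 8, "mixed": 10}
        betas = np.empty((500, 2))
        for rep in range(500):
            cfg = dataclasses.replace(
                wmnet.default_config(seed=20000 + rep), group_sizes=sizes
            ).with_null_effects()
            records, raws = generate_cohort(cfg)
            cohort = records_to_frame(records)
            y = np.array([node_degree(build_network(r).weights).mean() for r in raws])
            x = np.column_stack(
                [
                    np.ones(len(cohort)),
                    cohort["adci"],
                    cohort["lbci"],
                    cohort[list(wmnet.COVARIATES)].to_numpy(float),
                ]
            )
            res = batch_ols(x, y)
            betas[rep] = res["beta"][1:3, 0]
        for j, name in enumerate(["adci", "lbci"]):
            se = betas[:, j].std(ddof=1) / np.sqrt(len(betas))
            assert abs(betas[:, j].mean()) < 3 * se, name
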