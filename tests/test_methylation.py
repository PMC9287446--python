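"""Differential methylation: M-values, DMPs, DMRs, prioritization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import uvmeth as uv
from uvmeth import methylation as meth


class TestMvalues:
    def test_known_values(self):
        assert meth.mvalue_transform(np.array([0.5]))[0] == pytest.approx(0.0)
        assert meth.mvalue_transform(np.array([0.8]))[0] == pytest.approx(2.0)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=0.001, max_value=0.999))
    def test_roundtrip(self, b):
        assert meth.beta_from_m(meth.mvalue_transform(np.array([b])))[0] == pytest.approx(
            b, abs=1e-10
        )

    def test_dataframe_shape_preserved(self):
        df = pd.DataFrame([[0.2, 0.8]], index=["p"], columns=["a", "b"])
        m = meth.mvalue_transform(df)
        assert list(m.index) == ["p"] and list(m.columns) == ["a", "b"]


class TestFilterProbes:
    def _beta(self, probes):
        return pd.DataFrame(0.5, index=probes, columns=["s1", "s2"])

    def _ann(self, probes, cross, sex):
        return pd.DataFrame(
            {"probe": probes, "cross_reactive_flag": cross, "sex_chrom_flag": sex}
        )

    def test_mixed_flags_counted(self):
        probes = [f"p{i}" for i in range(10)]
        cross = [i in (0, 1) for i in range(10)]
        sex = [i == 2 for i in range(10)]
        out = uv.filter_probes(self._beta(probes), self._ann(probes, cross, sex))
        assert len(out) == 7

    def test_no_flags_is_identity(self):
        probes = ["a", "b"]
        out = uv.filter_probes(self._beta(probes), self._ann(probes, [False] * 2, [False] * 2))
        assert list(out.index) == probes

    def test_all_flagged_yields_empty(self):
        probes = ["a", "b"]
        out = uv.filter_probes(self._beta(probes), self._ann(probes, [True] * 2, [False] * 2))
        assert out.empty

    def test_unannotated_probe_rejected(self):
        with pytest.raises(ValueError):
            uv.filter_probes(self._beta(["a", "b"]), self._ann(["a"], [False], [False]))


def _groups(n_uv, n_nonuv):
    idx = [f"s{i}" for i in range(n_uv + n_nonuv)]
    return pd.Series(["uv"] * n_uv + ["nonuv"] * n_nonuv, index=idx)


class TestFitDmp:
    def test_symmetric_probe_has_near_zero_coefficient(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 20)
        mv = pd.DataFrame(
            np.vstack([np.r_[base, base]]).reshape(1, 40),
            index=["p0"],
            columns=[f"s{i}" for i in range(40)],
        )
        res = uv.fit_dmp(mv, _groups(20, 20))
        assert abs(res.loc["p0", "coef"]) < 1e-8

    def test_matches_ols_when_no_observation_downweighted(self):
        # residuals follow a symmetric linear pattern with max/MAD = 7/4,
        # below the Huber cutoff c/0.6745 ~ 1.99: no observation is ever
        # downweighted, so the robust fit must coincide with OLS
        rng = np.random.default_rng(1)
        n = 30
        g = np.r_[np.ones(15), np.zeros(15)]
        pattern = np.arange(-7, 8, dtype=float)  # zero-mean within each group
        noise = np.stack([
            np.r_[rng.permutation(pattern), rng.permutation(pattern)]
            * rng.uniform(0.01, 0.05)
            for _ in range(40)
        ])
        Y = 0.5 * g[None, :] + noise
        cols = [f"s{i}" for i in range(n)]
        mv = pd.DataFrame(Y, index=[f"p{i}" for i in range(40)], columns=cols)
        groups = pd.Series(np.where(g == 1, "uv", "nonuv"), index=cols)
        robust = uv.fit_dmp(mv, groups, method="huber")
        ols = uv.fit_dmp(mv, groups, method="ols")
        assert np.allclose(robust["coef"], ols["coef"], atol=1e-6)
        assert np.allclose(robust["se"], ols["se"], atol=1e-6)

    def test_close_to_statsmodels_rlm_with_outliers(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        n = 40
        g = np.r_[np.ones(20), np.zeros(20)]
        Y = 0.8 * g[None, :] + rng.normal(0, 0.4, size=(5, n))
        Y[:, 3] += 4.0  # gross outlier
        cols = [f"s{i}" for i in range(n)]
        mv = pd.DataFrame(Y, index=[f"p{i}" for i in range(5)], columns=cols)
        groups = pd.Series(np.where(g == 1, "uv", "nonuv"), index=cols)
        res = uv.fit_dmp(mv, groups)
        X = np.c_[np.ones(n), g]
        for i in range(5):
            ref = sm.RLM(Y[i], X, M=sm.robust.norms.HuberT()).fit()
            assert res["coef"].iloc[i] == pytest.approx(ref.params[1], abs=0.05)

    def test_planted_effect_detected_across_seeds(self):
        detected = 0
        n_seeds = 25
        for seed in range(n_seeds):
            cfg = uv.CohortConfig(
                seed=seed, n_uv=25, n_nonuv=25, n_probes=300, n_genes=5,
                dmr_specs=[dict(chrom="chr1", start=10_000, n_cpgs=1, spacing=100,
                                delta_beta=0.2, direction="hyper")],
            )
            cohort = uv.generate_cohort(cfg)
            beta = uv.filter_probes(cohort.beta, cohort.annotation)
            res = uv.fit_dmp(uv.mvalue_transform(beta), cohort.groups, beta=beta)
            probe = cohort.truth.dmrs[0]["probes"][0]
            detected += res.loc[probe, "q"] < 0.05
        assert detected / n_seeds >= 0.95

    def test_constant_probe_flagged(self):
        mv = pd.DataFrame(
            [[1.0] * 10, list(np.arange(10) / 10)],
            index=["flat", "vary"],
            columns=[f"s{i}" for i in range(10)],
        )
        res = uv.fit_dmp(mv, _groups(5, 5))
        assert res.loc["flat", "flagged"] and res.loc["flat", "p"] == 1.0

    def test_coefficient_sign_agrees_with_delta_beta(self, small_dmps):
        dmps, _ = small_dmps
        strong = dmps[dmps["delta_beta"].abs() > 0.05]
        agree = np.sign(strong["coef"]) == np.sign(strong["delta_beta"])
        assert agree.mean() > 0.99


class TestLambda:
    def test_all_half_pvalues_give_unity(self):
        assert uv.genomic_inflation_lambda([0.5] * 100) == pytest.approx(1.0)

    def test_uniform_null_calibrated(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=100_000)
        assert uv.genomic_inflation_lambda(p) == pytest.approx(1.0, abs=0.02)

    def test_doubled_statistics_double_lambda(self):
        rng = np.random.default_rng(1)
        chi = stats.chi2.rvs(1, size=50_000, random_state=2)
        p1 = stats.chi2.sf(chi, 1)
        p2 = stats.chi2.sf(2 * chi, 1)
        lam1 = uv.genomic_inflation_lambda(p1)
        lam2 = uv.genomic_inflation_lambda(p2)
        assert lam2 / lam1 == pytest.approx(2.0, rel=0.03)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            uv.genomic_inflation_lambda([])


def _toy_dmps(positions, z=3.0, coef=0.5, delta=0.12, chrom="chr1", snp=False):
    p = 2 * stats.norm.sf(abs(z))
    probes = [f"p{i}" for i in range(len(positions))]
    dmps = pd.DataFrame(
        {
            "coef": coef, "se": abs(coef / z), "stat": z, "p": p, "q": p,
            "delta_beta": delta, "flagged": False,
        },
        index=pd.Index(probes, name="probe"),
    )
    ann = pd.DataFrame(
        {
            "probe": probes, "chrom": chrom, "pos": positions,
            "snp_flag": snp, "cross_reactive_flag": False, "sex_chrom_flag": False,
        }
    )
    return dmps, ann


class TestCallDmrs:
    def test_gaps_within_window_chain_into_one_region(self):
        dmps, ann = _toy_dmps([100, 900, 1700])
        out = uv.call_dmrs(dmps, ann)
        assert len(out) == 1
        assert (out.loc[0, "start"], out.loc[0, "end"], out.loc[0, "n_cpgs"]) == (100, 1700, 3)

    def test_large_gap_splits_regions(self):
        dmps, ann = _toy_dmps([100, 900, 2400, 3000])
        out = uv.call_dmrs(dmps, ann)
        assert len(out) == 2
        assert list(out["n_cpgs"]) == [2, 2]

    def test_stouffer_closed_form_for_independent_members(self):
        dmps, ann = _toy_dmps([100, 300, 500, 700], z=2.0)
        out = uv.call_dmrs(dmps, ann)  # no mvalues => rbar = 0
        assert out.loc[0, "z"] == pytest.approx(4 * 2 / np.sqrt(4), rel=1e-9)

    def test_full_correlation_reduces_to_single_z(self):
        dmps, ann = _toy_dmps([100, 300, 500], z=2.0)
        mv = pd.DataFrame(
            np.tile(np.arange(10.0), (3, 1)), index=["p0", "p1", "p2"],
            columns=[f"s{i}" for i in range(10)],
        )
        out = uv.call_dmrs(dmps, ann, mvalues=mv)
        # r̄ -> 1: denominator sqrt(n^2), Z == member z
        assert out.loc[0, "z"] == pytest.approx(2.0, abs=1e-3)

    def test_members_partition_significant_probes(self, small_dmps, small_cohort):
        dmps, mv = small_dmps
        out = uv.call_dmrs(dmps, small_cohort.annotation, mvalues=mv)
        members = [m for row in out["members"] for m in row.split(",")]
        assert len(members) == len(set(members))

    def test_insignificant_probes_yield_no_regions(self):
        dmps, ann = _toy_dmps([100, 300], z=0.5)
        dmps["q"] = 0.9
        assert len(uv.call_dmrs(dmps, ann)) == 0


class TestPrioritize:
    def _region(self, **kw):
        base = dict(chrom="chr1", start=1, end=500, n_cpgs=3, members="a,b,c",
                    z=4.0, p=1e-4, coef=0.5, se=0.1, mean_delta_beta=0.12,
                    direction_consistent=True, snp_fraction=0.0, rbar=0.1, q=1e-3)
        base.update(kw)
        return base

    def test_two_cpg_region_excluded(self):
        dmrs = pd.DataFrame([self._region(n_cpgs=2)])
        kept, att = uv.prioritize_dmrs(dmrs)
        assert len(kept) == 0 and att["min_cpgs"] == 0

    def test_inconsistent_direction_excluded(self):
        dmrs = pd.DataFrame([self._region(direction_consistent=False)])
        kept, _ = uv.prioritize_dmrs(dmrs)
        assert len(kept) == 0

    def test_compliant_region_retained(self):
        dmrs = pd.DataFrame([self._region()])
        kept, att = uv.prioritize_dmrs(dmrs)
        assert len(kept) == 1 and att["snp_fraction"] == 1

    def test_small_effect_and_snp_enriched_excluded(self):
        dmrs = pd.DataFrame(
            [self._region(mean_delta_beta=0.05), self._region(snp_fraction=0.7)]
        )
        kept, _ = uv.prioritize_dmrs(dmrs)
        assert len(kept) == 0

    @settings(max_examples=50, deadline=None)
    @given(
        min_cpgs=st.integers(min_value=2, max_value=6),
        min_delta=st.floats(min_value=0.0, max_value=0.3),
        snp_max=st.floats(min_value=0.1, max_value=1.0),
    )
    def test_tightening_thresholds_is_monotone(self, min_cpgs, min_delta, snp_max):
        rng = np.random.default_rng(7)
        dmrs = pd.DataFrame(
            [
                self._region(
                    n_cpgs=int(rng.integers(2, 8)),
                    mean_delta_beta=float(rng.normal(0, 0.15)),
                    snp_fraction=float(rng.random()),
                    direction_consistent=bool(rng.random() < 0.7),
                )
                for _ in range(30)
            ]
        )
        loose, _ = uv.prioritize_dmrs(dmrs, min_cpgs=min_cpgs,
                                      min_abs_delta_beta=min_delta,
                                      snp_fraction_max=snp_max)
        tight, _ = uv.prioritize_dmrs(dmrs, min_cpgs=min_cpgs + 1,
                                      min_abs_delta_beta=min_delta + 0.05,
                                      snp_fraction_max=snp_max / 2)
        loose_ids = set(map(tuple, loose[["chrom", "start", "n_cpgs"]].to_numpy()))
        tight_ids = set(map(tuple, tight[["chrom", "start", "n_cpgs"]].to_numpy()))
        assert tight_ids <= loose_ids or len(tight) <= len(loose)


class TestRegionClassEnrichment:
    def _ann(self, n=400, island_frac=0.25, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "probe": [f"p{i}" for i in range(n)],
                "regulatory_class": rng.choice(meth.REGULATORY_CLASSES, size=n),
                "density_class": np.where(
                    rng.random(n) < island_frac, "island", "open_sea"
                ),
            }
        )

    def test_proportional_selection_is_null(self):
        ann = self._ann()
        islands = ann[ann["density_class"] == "island"]["probe"]
        others = ann[ann["density_class"] != "island"]["probe"]
        sel = list(islands[: len(islands) // 2]) + list(others[: len(others) // 2])
        out = uv.region_class_enrichment(sel, ann, class_axis="density")
        island_row = out[out["class"] == "island"].iloc[0]
        assert island_row["p"] > 0.5
        assert island_row["odds_ratio"] == pytest.approx(1.0, abs=0.15)

    def test_island_only_selection_enriched(self):
        ann = self._ann()
        sel = ann[ann["density_class"] == "island"]["probe"].iloc[:40]
        out = uv.region_class_enrichment(sel, ann, class_axis="density")
        island_row = out[out["class"] == "island"].iloc[0]
        assert island_row["odds_ratio"] > 1 and island_row["p"] < 0.05

    def test_chi_square_matches_hand_formula(self):
        ann = self._ann(seed=3)
        sel = ann["probe"].iloc[:50]
        out = uv.region_class_enrichment(sel, ann, class_axis="density")
        for _, row in out.iterrows():
            in_cls = ann["density_class"] == row["class"]
            in_sel = ann["probe"].isin(sel)
            table = np.array(
                [
                    [(in_sel & in_cls).sum(), (in_sel & ~in_cls).sum()],
                    [(~in_sel & in_cls).sum(), (~in_sel & ~in_cls).sum()],
                ],
                dtype=float,
            )
            exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
            chi2 = ((table - exp) ** 2 / exp).sum()
            assert row["chi2"] == pytest.approx(chi2, abs=1e-10)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            uv.region_class_enrichment([], self._ann(), class_axis="density")
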