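import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from tcrgwas import association as assoc
from tcrgwas.association import (AssociationResult, ModelSpec,
                                 clustered_bootstrap_p, conditional_scan,
                                 fit_gene_conditioned, fit_simple,
                                 fit_trbd2_corrected, genome_scan)
from tcrgwas.io_formats import GenotypeMatrix


def _simple_table(y, subjects=None, feature="v_trim", productivity="productive"):
    subjects = subjects or [f"S{i}" for i in range(len(y))]
    return pd.DataFrame({
        "subject_id": subjects, "mean": y, "count": 10,
        "feature": feature, "productivity": productivity,
    })


def _grouped_table(records, feature="v_trim", productivity="productive"):
    df = pd.DataFrame(records, columns=["subject_id", "group_id", "mean",
                                        "count"])
    w = df.groupby("subject_id")["count"].transform("sum")
    df["weight"] = df["count"] / w
    df["feature"] = feature
    df["productivity"] = productivity
    return df


def _dosage(values, subjects=None, name="snp1"):
    subjects = subjects or [f"S{i}" for i in range(len(values))]
    return pd.Series(np.asarray(values, dtype=float), index=subjects, name=name)


class TestFitSimple:
    def test_exact_line_degenerate(self):
        x = [0, 1, 2, 0, 1, 2]
        y = [2 * v + 1 for v in x]
        res = fit_simple(_simple_table(y), _dosage(x))
        assert res.beta1 == pytest.approx(2.0)
        assert res.flag == "degenerate"
        assert res.se == 0.0

    def test_orthogonal_x_gives_zero_slope(self):
        y = [1.0, -1.0, 1.0, -1.0]
        x = [1, 1, 0, 0]
        res = fit_simple(_simple_table(y), _dosage(x))
        assert res.beta1 == pytest.approx(0.0, abs=1e-12)

    def test_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        n = 50
        x = rng.integers(0, 3, size=n).astype(float)
        pcs = pd.DataFrame(rng.normal(size=(n, 3)),
                           index=[f"S{i}" for i in range(n)],
                           columns=["PC1", "PC2", "PC3"])
        y = 0.5 * x + pcs["PC1"].values + rng.normal(size=n)
        res = fit_simple(_simple_table(list(y)), _dosage(x), pcs,
                         ModelSpec(n_pcs=3))
        X = sm.add_constant(np.column_stack([x, pcs.values]))
        m = sm.OLS(y, X).fit()
        assert res.beta1 == pytest.approx(m.params[1], abs=1e-10)
        assert res.se == pytest.approx(m.bse[1], abs=1e-10)

    def test_missing_dosage_complete_case(self):
        x = [0, 1, 2, np.nan, 1]
        y = [0.0, 1.0, 2.0, 99.0, 1.0]
        res = fit_simple(_simple_table(y), _dosage(x))
        assert res.n_subjects == 4
        assert res.beta1 == pytest.approx(1.0)

    def test_rank_deficient_flagged(self):
        res = fit_simple(_simple_table([1.0, 2.0, 3.0]), _dosage([1, 1, 1]))
        assert res.flag == "unestimable"


class TestFitGeneConditioned:
    def test_pure_group_effects_zero_slope(self):
        recs = []
        for i in range(12):
            recs.append((f"S{i}", "g1", 1.0, 10))
            recs.append((f"S{i}", "g2", 5.0, 10))
        x = _dosage(np.tile([0, 1, 2], 4), [f"S{i}" for i in range(12)])
        res = fit_gene_conditioned(_grouped_table(recs), x)
        assert res.beta1 == pytest.approx(0.0, abs=1e-12)

    def test_weighted_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        subjects = [f"S{i}" for i in range(40)]
        x = _dosage(rng.integers(0, 3, size=40).astype(float), subjects)
        recs = []
        for s in subjects:
            for g, gamma in (("g1", 0.0), ("g2", 1.5), ("g3", -0.7)):
                if rng.random() < 0.2:
                    continue
                y = gamma + 0.4 * x[s] + rng.normal()
                recs.append((s, g, y, int(rng.integers(5, 40))))
        tab = _grouped_table(recs)
        res = fit_gene_conditioned(tab, x)
        df = tab.copy()
        df["x"] = df["subject_id"].map(x)
        dummies = pd.get_dummies(df["group_id"], drop_first=True).astype(float)
        X = sm.add_constant(pd.concat([df["x"], dummies], axis=1))
        m = sm.WLS(df["mean"], X, weights=df["weight"]).fit()
        assert res.beta1 == pytest.approx(m.params["x"], abs=1e-10)
        assert res.se == pytest.approx(m.bse["x"], abs=1e-10)

    def test_single_subject_group_retained(self):
        recs = [(f"S{i}", "g1", float(i), 10) for i in range(10)]
        recs.append(("S0", "rare", 3.0, 2))
        x = _dosage(np.arange(10) % 3, [f"S{i}" for i in range(10)])
        res = fit_gene_conditioned(_grouped_table(recs), x)
        assert res.flag == "ok"
        assert res.n_rows == 11


class TestTrbd2Corrected:
    def _balanced(self, rng, beta=0.0, z_effect=0.0, confounded=False):
        subjects, recs, zs, xs = [], [], {}, {}
        i = 0
        for x in (0, 1, 2):
            for z in ("TRBD2*01 homozygous", "heterozygous",
                      "TRBD2*02 homozygous"):
                for _ in range(6):
                    s = f"S{i}"
                    subjects.append(s)
                    zs[s] = z
                    xs[s] = float(x)
                    znum = ["TRBD2*01 homozygous", "heterozygous",
                            "TRBD2*02 homozygous"].index(z)
                    y = beta * x + z_effect * znum + rng.normal()
                    recs.append((s, "g1", y, 10))
                    recs.append((s, "g2", y + 1.0, 10))
                    i += 1
        return (_grouped_table(recs), _dosage([xs[s] for s in subjects],
                                              subjects),
                pd.Series(zs))

    def test_independent_z_equals_uncorrected(self):
        rng = np.random.default_rng(2)
        tab, x, z = self._balanced(rng)
        corrected = fit_trbd2_corrected(tab, x, z=z)
        uncorrected = fit_gene_conditioned(tab, x)
        assert corrected.beta1 == pytest.approx(uncorrected.beta1, abs=1e-8)

    def test_all_heterozygous_equals_uncorrected(self):
        rng = np.random.default_rng(3)
        tab, x, z = self._balanced(rng)
        z[:] = "heterozygous"
        with pytest.warns(UserWarning, match="constant"):
            corrected = fit_trbd2_corrected(tab, x, z=z)
        uncorrected = fit_gene_conditioned(tab, x)
        assert corrected.beta1 == pytest.approx(uncorrected.beta1, abs=1e-12)

    def test_confound_attenuation(self):
        # y depends only on z; x correlated with z -> correction shrinks beta
        rng = np.random.default_rng(4)
        subjects, recs, zs, xs = [], [], {}, {}
        levels = ["TRBD2*01 homozygous", "heterozygous", "TRBD2*02 homozygous"]
        for i in range(90):
            s = f"S{i}"
            znum = int(rng.integers(0, 3))
            x = float(np.clip(znum + rng.integers(-1, 2), 0, 2))  # correlated
            y = 2.0 * znum + 0.3 * rng.normal()
            subjects.append(s)
            zs[s] = levels[znum]
            xs[s] = x
            recs.append((s, "g1", y, 10))
            recs.append((s, "g2", y + 0.5, 10))
        tab = _grouped_table(recs)
        x = _dosage([xs[s] for s in subjects], subjects)
        z = pd.Series(zs)
        uncorrected = fit_gene_conditioned(tab, x)
        corrected = fit_trbd2_corrected(tab, x, z=z)
        assert abs(corrected.beta1) < abs(uncorrected.beta1)

    def test_unknown_fraction_guard(self):
        rng = np.random.default_rng(5)
        tab, x, z = self._balanced(rng)
        z.iloc[: len(z) // 2] = "unknown"
        with pytest.raises(ValueError, match="90%"):
            fit_trbd2_corrected(tab, x, z=z)


class TestClusteredBootstrap:
    def test_identical_subjects_degenerate(self):
        # every subject carries the identical row set: the bootstrap
        # coefficient estimates cannot vary
        recs = []
        for i in range(10):
            recs += [(f"S{i}", "g1", 1.0, 10), (f"S{i}", "g1", 3.0, 10),
                     (f"S{i}", "g2", 2.0, 10)]
        x = _dosage(np.arange(10) % 3, [f"S{i}" for i in range(10)])
        res = fit_gene_conditioned(_grouped_table(recs), x)
        assert res.flag == "ok"
        out = clustered_bootstrap_p(res, ModelSpec(bootstrap_reps=20, seed=0))
        assert out.flag == "degenerate"

    def test_bootstrap_close_to_analytic_iid(self):
        # one row per subject, homoskedastic noise: bootstrap se within
        # 25% of the analytic se at B = 200
        rng = np.random.default_rng(6)
        n = 150
        subjects = [f"S{i}" for i in range(n)]
        x = _dosage(rng.integers(0, 3, size=n).astype(float), subjects)
        y = 0.3 * x.values + rng.normal(size=n)
        res = fit_simple(_simple_table(list(y), subjects), x)
        spec = ModelSpec(bootstrap_reps=200, seed=1)
        out = clustered_bootstrap_p(res, spec)
        se_boot = abs(res.beta1 / _t_from_p(out.p_bootstrap, res.beta1))
        assert se_boot == pytest.approx(res.se, rel=0.25)

    def test_intra_subject_correlation_inflates_se(self):
        # shared subject-level noise: bootstrap se > naive analytic se
        rng = np.random.default_rng(7)
        hits = 0
        reps = 20
        for _ in range(reps):
            subjects = [f"S{i}" for i in range(60)]
            x = _dosage(rng.integers(0, 3, size=60).astype(float), subjects)
            recs = []
            for s in subjects:
                u = rng.normal() * 2.0  # strong shared noise
                for g in ("g1", "g2", "g3", "g4"):
                    recs.append((s, g, u + rng.normal() * 0.1, 10))
            res = fit_gene_conditioned(_grouped_table(recs), x)
            out = clustered_bootstrap_p(res, ModelSpec(bootstrap_reps=60,
                                                       seed=int(rng.integers(1e6))))
            se_boot = abs(res.beta1 / _t_from_p(out.p_bootstrap, res.beta1))
            if se_boot > res.se:
                hits += 1
        assert hits >= int(0.95 * reps)


def _t_from_p(p, beta):
    from scipy import stats
    t = stats.norm.isf(p / 2)
    return np.sign(beta) * t


def _gm_from(dosage):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    return GenotypeMatrix(
        subject_ids=[f"S{i}" for i in range(n)],
        snp_ids=[f"chr1:{1000 + j}:s{j}" for j in range(m)],
        chrom=["chr1"] * m, pos=[1000 + j for j in range(m)],
        dosage=dosage,
    )


class TestConditionalScan:
    def test_self_conditioning_guard(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 3, size=60).astype(float)
        subjects = [f"S{i}" for i in range(60)]
        y = _simple_table(list(0.8 * x + rng.normal(size=60) * 0.3), subjects)
        res = assoc._fit_for_model(
            "simple", y, _dosage(x, subjects, "snpA"), None,
            ModelSpec(n_pcs=0), "snpA",
            conditioning={"snpA": _dosage(x, subjects, "snpA")})
        assert res.flag == "unestimable"

    def test_perfect_ld_proxies_one_signal(self):
        rng = np.random.default_rng(9)
        n = 120
        causal = rng.integers(0, 3, size=n).astype(float)
        dosage = np.column_stack([causal] * 11)  # causal + 10 perfect proxies
        gm = _gm_from(dosage)
        y = _simple_table(list(0.8 * causal + rng.normal(size=n) * 0.4),
                          gm.subject_ids)
        hits = conditional_scan(gm, gm.snp_ids, y, None,
                                ModelSpec(model="simple", n_pcs=0),
                                threshold=1e-4)
        assert len(hits) == 1

    def test_two_independent_causals_two_signals(self):
        rng = np.random.default_rng(10)
        n = 200
        x1 = rng.integers(0, 3, size=n).astype(float)
        x2 = rng.integers(0, 3, size=n).astype(float)
        noise = [rng.integers(0, 3, size=n).astype(float) for _ in range(4)]
        gm = _gm_from(np.column_stack([x1, x2] + noise))
        y = _simple_table(list(0.9 * x1 + 0.9 * x2
                               + rng.normal(size=n) * 0.4), gm.subject_ids)
        hits = conditional_scan(gm, gm.snp_ids, y, None,
                                ModelSpec(model="simple", n_pcs=0),
                                threshold=1e-4)
        assert sorted(hits) == [gm.snp_ids[0], gm.snp_ids[1]]

    def test_empty_locus_rejected(self):
        gm = _gm_from(np.zeros((5, 1)))
        with pytest.raises(ValueError):
            conditional_scan(gm, [], _simple_table([1.0] * 5), None,
                             ModelSpec(), 0.05)


class TestGenomeScan:
    def test_deterministic_repeat(self):
        rng = np.random.default_rng(11)
        gm = _gm_from(rng.integers(0, 3, size=(40, 15)).astype(float))
        y = _simple_table(list(rng.normal(size=40)), gm.subject_ids,
                          feature="n_total")
        condensed = {("n_total", "productive"): y}
        spec = ModelSpec(model="simple", n_pcs=0, seed=3)
        a = genome_scan(gm, condensed, spec=spec)
        b = genome_scan(gm, condensed, spec=spec)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_snp_is_top_hit(self):
        rng = np.random.default_rng(12)
        n = 100
        gm = _gm_from(rng.integers(0, 3, size=(n, 30)).astype(float))
        x = gm.dosage[:, 7]
        y = _simple_table(list(0.7 * x + rng.normal(size=n) * 0.5),
                          gm.subject_ids, feature="n_total")
        out = genome_scan(gm, {("n_total", "productive"): y},
                          spec=ModelSpec(model="simple", n_pcs=0, seed=0))
        top = out.loc[out["p"].idxmin(), "snp_id"]
        assert top == gm.snp_ids[7]

    def test_propagates_flags_without_aborting(self):
        gm = _gm_from(np.column_stack([
            np.ones(30), np.random.default_rng(13).integers(0, 3, 30),
        ]))
        y = _simple_table(list(np.random.default_rng(14).normal(size=30)),
                          gm.subject_ids, feature="n_total")
        out = genome_scan(gm, {("n_total", "productive"): y},
                          spec=ModelSpec(model="simple", n_pcs=0))
        flags = out.set_index("snp_id")["flag"]
        assert flags[gm.snp_ids[0]] == "unestimable"
        assert flags[gm.snp_ids[1]] == "ok"


class TestModelSpecValidation:
    def test_negative_pcs_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(n_pcs=-1)

    def test_zero_bootstrap_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(bootstrap_reps=0)


class TestOneTailedValidationMode:
    def test_matching_direction_halves_p(self):
        rng = np.random.default_rng(30)
        n = 80
        x = rng.integers(0, 3, size=n).astype(float)
        y = 0.5 * x + rng.normal(size=n)
        subjects = [f"S{i}" for i in range(n)]
        tab = _simple_table(list(y), subjects)
        dosage = _dosage(x, subjects)
        two = fit_simple(tab, dosage, spec=ModelSpec(n_pcs=0))
        one = fit_simple(tab, dosage,
                         spec=ModelSpec(n_pcs=0, one_tailed_sign=+1.0))
        assert one.beta1 == pytest.approx(two.beta1)
        assert one.p_analytic == pytest.approx(two.p_analytic / 2)

    def test_opposite_direction_complements(self):
        rng = np.random.default_rng(31)
        n = 80
        x = rng.integers(0, 3, size=n).astype(float)
        y = 0.5 * x + rng.normal(size=n)
        subjects = [f"S{i}" for i in range(n)]
        tab = _simple_table(list(y), subjects)
        dosage = _dosage(x, subjects)
        up = fit_simple(tab, dosage,
                        spec=ModelSpec(n_pcs=0, one_tailed_sign=+1.0))
        down = fit_simple(tab, dosage,
                          spec=ModelSpec(n_pcs=0, one_tailed_sign=-1.0))
        assert up.p_analytic + down.p_analytic == pytest.approx(1.0)
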