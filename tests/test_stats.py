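import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import tuneplast as tp
from tuneplast.stats import EFFECT_NAMES, _posthoc_family, _wide_by_phase
from tuneplast.synth import simulate_parameter_cohort


def _balanced_table(n_per_cell, seed, deltas=None):
    deltas = deltas or {}
    return simulate_parameter_cohort(
        seed=seed, n_units={(d, s): n_per_cell for d in ("tPA", "saline")
                            for s in ("above", "below")},
        effects=deltas)


def _split_plot_oracle(df):
    """Hand split-plot SS decomposition for a balanced 2x2x(2) design.

    Independent of the package's regression-based route: sums of squares
    from marginal means, subject error from per-subject means, within
    error by subtraction.
    """
    y = df["value"].to_numpy(float)
    grand = y.mean()
    N = len(y)

    def margin_ss(cols):
        ss = 0.0
        groups = df.groupby(cols)["value"]
        means = groups.mean()
        counts = groups.size()
        if len(cols) == 1:
            for lev in means.index:
                ss += counts[lev] * (means[lev] - grand) ** 2
        return ss

    def two_way_ss(c1, c2):
        m12 = df.groupby([c1, c2])["value"].agg(["mean", "size"])
        m1 = df.groupby(c1)["value"].mean()
        m2 = df.groupby(c2)["value"].mean()
        ss = 0.0
        for (l1, l2), row in m12.iterrows():
            ss += row["size"] * (row["mean"] - m1[l1] - m2[l2] + grand) ** 2
        return ss

    ss = {c: margin_ss([c]) for c in ("drug", "side", "phase")}
    ss["drug:side"] = two_way_ss("drug", "side")
    ss["phase:drug"] = two_way_ss("phase", "drug")
    ss["phase:side"] = two_way_ss("phase", "side")
    cell = df.groupby(["drug", "side", "phase"])["value"].agg(["mean", "size"])
    md = df.groupby("drug")["value"].mean()
    ms = df.groupby("side")["value"].mean()
    mp = df.groupby("phase")["value"].mean()
    mds = df.groupby(["drug", "side"])["value"].mean()
    mdp = df.groupby(["drug", "phase"])["value"].mean()
    msp = df.groupby(["side", "phase"])["value"].mean()
    ss3 = 0.0
    for (d, s, p), row in cell.iterrows():
        ss3 += row["size"] * (row["mean"] - mds[(d, s)] - mdp[(d, p)] - msp[(s, p)]
                              + md[d] + ms[s] + mp[p] - grand) ** 2
    ss["phase:drug:side"] = ss3
    # subject error: per-subject means about their cell mean (x2 phases)
    subj = df.groupby(["unit_id", "drug", "side"])["value"].mean().reset_index()
    cellm = df.groupby(["drug", "side"])["value"].mean()
    ss_subj = 2 * sum((row["value"] - cellm[(row["drug"], row["side"])]) ** 2
                      for _, row in subj.iterrows())
    ss_total = float(np.sum((y - grand) ** 2))
    ss_within_err = ss_total - sum(ss.values()) - ss_subj
    n_subj = subj.shape[0]
    df_err = n_subj - 4
    out = {}
    for name in EFFECT_NAMES:
        err = ss_subj if name in ("drug", "side", "drug:side") else ss_within_err
        F = (ss[name] / 1) / (err / df_err)
        out[name] = (F, ss[name] / (ss[name] + err))
    return out


class TestClassifyPairingSide:
    @pytest.mark.parametrize("bf_hz,pairing_hz,expected", [
        (11000, 9510, "below"),    # conditioning tone below the BF
        (16000, 19020, "above"),   # conditioning tone above the BF
    ])
    def test_examples(self, bf_hz, pairing_hz, expected):
        bf = tp.octave_distance(1000, bf_hz)
        pairing = tp.octave_distance(1000, pairing_hz)
        assert tp.classify_pairing_side(bf, pairing) == expected

    def test_tie_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            tp.classify_pairing_side(3.0, 3.0)
        with pytest.raises(ValueError):
            tp.classify_pairing_side(np.nan, 3.0)


class TestMixedAnova:
    def test_structure(self):
        df = _balanced_table(5, seed=0)
        effects = tp.mixed_anova(df)
        assert [e.factor for e in effects] == list(EFFECT_NAMES)
        for e in effects:
            assert e.F >= 0 and 0 <= e.p <= 1 and 0 <= e.eta_sq_p <= 1
            assert e.df1 == 1 and e.df2 == 4 * 5 - 4

    @pytest.mark.parametrize("seed,n", [(1, 4), (2, 6), (3, 3), (4, 8)])
    def test_matches_classical_split_plot_on_balanced_tables(self, seed, n):
        """The regression route equals the textbook sums-of-squares
        decomposition (F and partial eta squared) on balanced data."""
        df = _balanced_table(n, seed=seed,
                             deltas={("tPA", "above"): 0.8})
        effects = {e.factor: e for e in tp.mixed_anova(df)}
        oracle = _split_plot_oracle(df)
        for name in EFFECT_NAMES:
            assert effects[name].F == pytest.approx(oracle[name][0], rel=1e-8)
            assert effects[name].eta_sq_p == pytest.approx(oracle[name][1], rel=1e-8)

    def test_matches_statsmodels_type3_when_unbalanced(self):
        """Between and within strata agree with statsmodels Type-III OLS
        ANOVA on effect-coded factors for unbalanced cells."""
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        df = simulate_parameter_cohort(seed=9)  # 20/17/15/14 cells
        effects = {e.factor: e for e in tp.mixed_anova(df)}
        wide = _wide_by_phase(df, "value")
        wide["m"] = (wide["pre"] + wide["post"]) / 2
        wide["d"] = wide["pre"] - wide["post"]
        for col, mapping in (("m", {"drug": "drug", "side": "side",
                                    "drug:side": "C(drug, Sum):C(side, Sum)"}),
                             ("d", {"phase": "Intercept", "phase:drug": "drug",
                                    "phase:side": "side",
                                    "phase:drug:side": "C(drug, Sum):C(side, Sum)"})):
            model = smf.ols(f"{col} ~ C(drug, Sum) * C(side, Sum)", data=wide).fit()
            table = anova_lm(model, typ=3)
            for factor, sm_name in mapping.items():
                key = [k for k in table.index
                       if k == sm_name or (sm_name in ("drug", "side") and sm_name in k
                                           and ":" not in k)]
                assert len(key) == 1
                assert effects[factor].F == pytest.approx(table.loc[key[0], "F"],
                                                          rel=1e-8)

    def test_empty_cell_rejected(self):
        df = _balanced_table(3, seed=0)
        df = df[~((df["drug"] == "saline") & (df["side"] == "below"))]
        with pytest.raises(ValueError, match="saline/below"):
            tp.mixed_anova(df)

    def test_three_way_power_at_default_cohort(self):
        """An injected 1-SD phase x drug x side pattern is detected in well
        over 80% of replicates at the default cohort sizes."""
        hits = 0
        reps = 150
        deltas = {("tPA", "above"): 1.0, ("tPA", "below"): -1.0,
                  ("saline", "above"): -1.0, ("saline", "below"): 1.0}
        for r in range(reps):
            df = simulate_parameter_cohort(seed=50_000 + r, effects=deltas)
            three_way = {e.factor: e for e in tp.mixed_anova(df)}["phase:drug:side"]
            hits += three_way.p < 0.05
        assert hits / reps > 0.80


class TestPosthocPaired:
    def test_near_identical_gives_tiny_t(self, rng):
        pre = rng.normal(size=12)
        row = tp.posthoc_paired(pre, pre + rng.normal(0, 1e-9, 12))
        assert abs(row.t) < 1.0 and abs(row.diff) < 1e-8

    def test_dz_equals_t_over_sqrt_n(self, rng):
        pre = rng.normal(size=15)
        post = pre + rng.normal(0.3, 0.5, size=15)
        row = tp.posthoc_paired(pre, post)
        assert row.effect_size == pytest.approx(row.t / np.sqrt(15), rel=1e-10)
        assert row.effect_kind == "Dz" and row.paired
        assert row.ci_low <= row.diff <= row.ci_high

    def test_constant_shift_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            tp.posthoc_paired([1, 2, 3], [2, 3, 4])

    def test_direction_convention(self, rng):
        """diff = mean(pre) - mean(post): a post-pairing increase is negative."""
        pre = rng.normal(0, 1, 20)
        post = pre + 1 + rng.normal(0, 0.2, 20)
        row = tp.posthoc_paired(pre, post)
        assert row.diff < 0 and row.t < 0

    def test_order_invariance(self, rng):
        pre = rng.normal(size=10)
        post = pre + rng.normal(0.5, 1, 10)
        perm = rng.permutation(10)
        a = tp.posthoc_paired(pre, post)
        b = tp.posthoc_paired(pre[perm], post[perm])
        assert a.t == pytest.approx(b.t) and a.p == pytest.approx(b.p)


class TestPosthocIndependent:
    def test_identical_groups(self, rng):
        g = rng.normal(size=10)
        row = tp.posthoc_independent(g, g.copy())
        assert row.t == pytest.approx(0.0) and row.diff == 0.0
        assert row.effect_kind == "D" and not row.paired

    def test_antisymmetry(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(1, 1, 12)
        r1 = tp.posthoc_independent(a, b)
        r2 = tp.posthoc_independent(b, a)
        assert r1.effect_size == pytest.approx(-r2.effect_size)
        assert r1.t == pytest.approx(-r2.t)

    def test_textbook_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.5, 3.5, 4.5])
        na, nb = 4, 3
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        row = tp.posthoc_independent(a, b)
        assert row.t == pytest.approx(t_hand, abs=1e-10)
        assert row.effect_size == pytest.approx((a.mean() - b.mean()) / np.sqrt(sp2),
                                                abs=1e-10)
        assert row.df == 5

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError):
            tp.posthoc_independent([1, 1], [2, 2])


class TestFDR:
    def test_step_up_hand_rule(self):
        assert np.allclose(tp.fdr_bh([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_all_equal_and_singleton(self):
        assert np.allclose(tp.fdr_bh([0.2, 0.2, 0.2]), 0.2)
        assert tp.fdr_bh([0.07]) == pytest.approx([0.07])

    def test_never_decreases_and_preserves_ranking(self, rng):
        p = rng.uniform(size=20)
        q = tp.fdr_bh(p)
        assert np.all(q >= p - 1e-12)
        # step-up adjustment may tie neighbours but never reorders
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_manual_step_up(self, rng):
        """Adjusted values equal the hand-applied BH step-up rule."""
        p = rng.uniform(size=9)
        m = len(p)
        order = np.argsort(p)
        q = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            running = min(running, p[order[rank - 1]] * m / rank)
            q[order[rank - 1]] = running
        assert np.allclose(tp.fdr_bh(p), q)


@pytest.fixture(scope="module")
def param_table():
    rng = np.random.default_rng(77)
    rows = []
    uid = 0
    for d in ("tPA", "saline"):
        for s in ("above", "below"):
            for _ in range(6):
                base = {p: rng.normal(1, 0.5) for p in ("offset", "gain",
                                                        "fwhm", "bf")}
                for phase in ("pre", "post"):
                    rows.append({"unit_id": f"u{uid}", "drug": d, "side": s,
                                 "phase": phase,
                                 **{p: base[p] + rng.normal(0, 0.3)
                                    for p in base}})
                uid += 1
    return pd.DataFrame(rows)


class TestFullAnalysis:
    def test_structure(self, param_table):
        out = tp.full_analysis(param_table)
        assert set(out) == {"offset", "gain", "fwhm", "bf"}
        for tables in out.values():
            assert len(tables["anova"]) == 7
            assert len(tables["posthoc"]) == 16
            assert tables["posthoc"]["p_fdr"].ge(tables["posthoc"]["p"] - 1e-12).all()

    def test_drug_relabel_flips_between_drug_diffs(self, param_table):
        out1 = tp.full_analysis(param_table, parameters=("bf",))
        flipped = param_table.assign(
            drug=param_table["drug"].map({"tPA": "saline", "saline": "tPA"}))
        out2 = tp.full_analysis(flipped, parameters=("bf",))
        row1 = out1["bf"]["posthoc"]
        row2 = out2["bf"]["posthoc"]
        mask = row1["comparison"] == "tPA vs saline: pre-post difference"
        assert row1.loc[mask, "diff"].iloc[0] == pytest.approx(
            -row2.loc[mask, "diff"].iloc[0])

    def test_missing_parameter_column(self, param_table):
        with pytest.raises(ValueError, match="no column"):
            tp.full_analysis(param_table.drop(columns=["gain"]))


class TestPairingStudy:
    def test_fit_and_summary(self):
        df = _balanced_table(5, seed=21, deltas={("tPA", "above"): 1.5})
        df = df.rename(columns={"value": "bf"})
        for extra in ("offset", "gain", "fwhm"):
            df[extra] = df["bf"] + np.random.default_rng(0).normal(
                0, 0.1, size=len(df))
        study = tp.PairingStudy(df)
        res = study.fit()
        assert res.n_units == 20
        assert "bf" in res.summary()
        d = res.to_dict()
        assert set(d["parameters"]) == set(res.parameters)
        flat = res.flat_posthoc_table()
        assert len(flat) == 16 * 4
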