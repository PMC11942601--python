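import numpy as np
import pandas as pd
import pytest

from rohped import pedigree as pm
from rohped.io_qc import PedigreeTable

from oracles import wright_path_inbreeding


def ped_from(rows):
    df = pd.DataFrame(rows, columns=["id", "sire", "dam", "birth_year"])
    return PedigreeTable(df)


FULL_SIB_LOOP = ped_from([
    ("a", None, None, 1), ("b", None, None, 1),
    ("s1", "a", "b", 2), ("s2", "a", "b", 2),
    ("x", "s1", "s2", 3),
])

HALF_SIB_LOOP = ped_from([
    ("a", None, None, 1), ("b", None, None, 1), ("c", None, None, 1),
    ("h1", "a", "b", 2), ("h2", "a", "c", 2),
    ("x", "h1", "h2", 3),
])

# ancestral-inbreeding loop: z's parents are both inbred (full-sib offspring)
DEEP_LOOP = ped_from([
    ("a", None, None, 1), ("b", None, None, 1),
    ("s1", "a", "b", 2), ("s2", "a", "b", 2),
    ("x", "s1", "s2", 3), ("y", "s1", "s2", 3),
    ("z", "x", "y", 4),
])


def random_pedigree(rng, n_founders=6, n_generations=5, per_gen=5):
    rows = [(f"f{i}", None, None, 0) for i in range(n_founders)]
    prev = [r[0] for r in rows]
    for g in range(1, n_generations + 1):
        cur = []
        for k in range(per_gen):
            s, d = rng.choice(prev, 2, replace=False)
            name = f"g{g}_{k}"
            rows.append((name, s, d, g))
            cur.append(name)
        prev = cur + list(rng.choice(prev, min(2, len(prev)), replace=False))
    return ped_from(rows)


class TestMeuwissenLuo:
    def test_full_sib_offspring(self):
        assert pm.meuwissen_luo_f(FULL_SIB_LOOP)["x"] == pytest.approx(0.25)

    def test_half_sib_offspring(self):
        assert pm.meuwissen_luo_f(HALF_SIB_LOOP)["x"] == pytest.approx(0.125)

    def test_founders_zero(self):
        f = pm.meuwissen_luo_f(FULL_SIB_LOOP)
        assert f["a"] == 0 and f["b"] == 0

    def test_matches_wright_path_counting_on_random_pedigrees(self, rng):
        for _ in range(15):
            ped = random_pedigree(rng)
            got = pm.meuwissen_luo_f(ped)
            expected = wright_path_inbreeding(ped.parents())
            for ind, val in expected.items():
                assert got[ind] == pytest.approx(val, abs=1e-12), ind


class TestEquivalentGenerations:
    def test_parents_only(self):
        ped = ped_from([("a", None, None, 1), ("b", None, None, 1), ("x", "a", "b", 2)])
        assert pm.equivalent_generations(ped)["x"] == 1.0

    def test_founder_zero(self):
        assert pm.equivalent_generations(FULL_SIB_LOOP)["a"] == 0.0

    def test_complete_three_generations(self):
        rows = [(f"gp{i}", None, None, 0) for i in range(8)]
        rows += [("p1", "gp0", "gp1", 1), ("p2", "gp2", "gp3", 1),
                 ("q1", "gp4", "gp5", 1), ("q2", "gp6", "gp7", 1)]
        rows += [("m", "p1", "p2", 2), ("d", "q1", "q2", 2), ("x", "m", "d", 3)]
        assert pm.equivalent_generations(ped_from(rows))["x"] == pytest.approx(3.0)


class TestDeltaF:
    @pytest.mark.parametrize("f,ge,expected", [
        (0.25, 2.0, 0.25),
        (0.0, 9.0, 0.0),
        (0.099, 15.6691, 0.0071),
    ])
    def test_closed_form(self, f, ge, expected):
        got = pm.delta_f_ped(pd.Series([f]), pd.Series([ge])).iloc[0]
        assert round(got, 4) == pytest.approx(expected, abs=5e-5)

    def test_shallow_pedigree_reports_zero(self):
        assert pm.delta_f_ped(pd.Series([0.2]), pd.Series([1.0])).iloc[0] == 0.0

    def test_invalid_f_rejected(self):
        with pytest.raises(ValueError):
            pm.delta_f_ped(pd.Series([1.2]), pd.Series([3.0]))


class TestGeneDrop:
    def test_founders_all_zero(self):
        out = pm.gene_drop_ancestral(FULL_SIB_LOOP, pm.GeneDropConfig(rounds=2000, seed=1))
        assert (out.loc[["a", "b"]].to_numpy() == 0).all()

    def test_full_sib_offspring_is_new_inbreeding(self):
        out = pm.gene_drop_ancestral(FULL_SIB_LOOP, pm.GeneDropConfig(mode="exhaustive"))
        assert out.loc["x", "f_new"] == pytest.approx(0.25)
        assert out.loc["x", "f_a_kal"] == 0.0
        assert out.loc["x", "f_a_bal"] == 0.0

    def test_monte_carlo_matches_exhaustive_within_3se(self):
        exact = pm.gene_drop_ancestral(DEEP_LOOP, pm.GeneDropConfig(mode="exhaustive"))
        rounds = 40_000
        mc = pm.gene_drop_ancestral(DEEP_LOOP, pm.GeneDropConfig(rounds=rounds, seed=11))
        for col in exact.columns:
            p = exact[col].clip(0.01, 0.99)
            se = np.sqrt(p * (1 - p) / rounds)
            assert (np.abs(mc[col] - exact[col]) <= 3 * se + 1e-9).all(), col

    def test_decomposition_exact_under_enumeration(self):
        exact = pm.gene_drop_ancestral(DEEP_LOOP, pm.GeneDropConfig(mode="exhaustive"))
        f_ped = pm.meuwissen_luo_f(DEEP_LOOP)
        np.testing.assert_allclose(exact["f_new"] + exact["f_a_kal"], f_ped[exact.index],
                                   atol=1e-12)
        np.testing.assert_allclose(exact["f_drop"], f_ped[exact.index], atol=1e-12)

    def test_ancestral_ordering(self):
        out = pm.gene_drop_ancestral(DEEP_LOOP, pm.GeneDropConfig(rounds=20_000, seed=2))
        assert (out["ahc"] >= out["f_a_bal"] - 1e-12).all()
        assert (out["f_a_bal"] >= out["f_a_kal"] - 1e-12).all()

    def test_relabeling_invariance(self):
        out1 = pm.gene_drop_ancestral(DEEP_LOOP, pm.GeneDropConfig(rounds=5000, seed=3))
        relabeled = DEEP_LOOP.df.copy()
        mapping = {k: f"horse_{k}" for k in relabeled["id"]}
        for col in ("id", "sire", "dam"):
            relabeled[col] = relabeled[col].map(lambda x: mapping.get(x) if x else None)
        out2 = pm.gene_drop_ancestral(PedigreeTable(relabeled), pm.GeneDropConfig(rounds=5000, seed=3))
        out2.index = [k.removeprefix("horse_") for k in out2.index]
        pd.testing.assert_frame_equal(out1, out2.loc[out1.index])

    def test_gene_drop_converges_to_meuwissen_luo(self, rng):
        ped = random_pedigree(rng, n_founders=5, n_generations=6)
        rounds = 100_000
        mc = pm.gene_drop_ancestral(ped, pm.GeneDropConfig(rounds=rounds, seed=5))
        f = pm.meuwissen_luo_f(ped)
        se = np.sqrt(f.clip(lower=0.005) * (1 - f.clip(lower=0.005)) / rounds)
        assert (np.abs(mc["f_drop"] - f[mc.index]) <= 3 * se[mc.index] + 1e-9).all()


class TestTable:
    def test_combined_table_columns(self):
        t = pm.pedigree_inbreeding_table(DEEP_LOOP, pm.GeneDropConfig(rounds=2000, seed=1))
        assert list(t.columns) == ["f_ped", "ge", "delta_f_ped", "f_a_bal", "f_a_kal", "f_new", "ahc"]
        assert t.loc["z", "f_ped"] == pytest.approx(0.375)
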