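from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dreep import prediction as dr
from dreep.types import BiomarkerRanking, BulkPanel, DrugResponsePanel, StructuralError


# ---------------------------------------------------------------------------
# independent brute-force oracle for the running-sum statistic

def es_brute(genes, weights, gene_set, alpha=1.0):
    hits = {g for g in gene_set if g in set(genes)}
    n, nh = len(genes), len(hits)
    wsum = sum(abs(w) ** alpha for g, w in zip(genes, weights) if g in hits)
    run, pos, neg = 0.0, 0.0, 0.0
    for g, w in zip(genes, weights):
        if g in hits:
            run += (abs(w) ** alpha / wsum) if wsum > 0 else 1.0 / nh
        else:
            run -= 1.0 / (n - nh)
        pos, neg = max(pos, run), min(neg, run)
    return pos if pos >= -neg - 1e-12 else neg


def _ranking(genes, pccs, drug="d0"):
    return BiomarkerRanking([drug], {drug: list(genes)},
                            {drug: np.asarray(pccs, dtype=float)})


class TestTrainingFilter:
    def _panels(self, n_genes=20, n_lines=30, n_drugs=3, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n_genes)]
        lines = [f"l{i}" for i in range(n_lines)]
        bulk = BulkPanel(genes, lines, rng.uniform(0.5, 3, (n_genes, n_lines)))
        resp = DrugResponsePanel([f"d{i}" for i in range(n_drugs)], lines,
                                 rng.normal(10, 2, (n_drugs, n_lines)))
        return bulk, resp

    def test_drug_below_min_lines_dropped(self):
        bulk, resp = self._panels()
        resp.auc[1, : 30 - 24] = np.nan  # 24 measured lines -> dropped
        fb, fr = dr.filter_training_panel(bulk, resp, min_lines=25)
        assert fr.drug_ids == ["d0", "d2"]

    def test_constant_gene_dropped(self):
        bulk, resp = self._panels()
        bulk.values[3, :] = 1.7
        fb, _ = dr.filter_training_panel(bulk, resp, entropy_pctile=5)
        assert "g3" not in fb.gene_ids

    def test_exactly_lowest_entropy_percentile_removed(self):
        rng = np.random.default_rng(1)
        n = 100
        genes = [f"g{i:03d}" for i in range(n)]
        lines = [f"l{i}" for i in range(40)]
        values = rng.uniform(1, 3, (n, 40))
        # five genes made nearly constant -> lowest binned entropy
        for i in range(5):
            values[i] = 2.0 + 1e-9 * rng.random(40)
        bulk = BulkPanel(genes, lines, values)
        resp = DrugResponsePanel(["d"], lines, rng.normal(10, 2, (1, 40)))
        fb, _ = dr.filter_training_panel(bulk, resp, entropy_pctile=5)
        assert len(fb.gene_ids) == 95
        assert not any(g in fb.gene_ids for g in genes[:5])


class TestRankings:
    def test_affine_gene_ranks_first_and_negated_last(self):
        rng = np.random.default_rng(2)
        lines = [f"l{i}" for i in range(30)]
        auc = rng.normal(10, 2, 30)
        values = np.vstack([
            rng.uniform(0, 3, (3, 30)),
            0.1 * auc + 0.5,        # PCC +1
            -0.1 * auc + 3.0,       # PCC -1
        ])
        bulk = BulkPanel([f"g{i}" for i in range(5)], lines, np.clip(values, 0, None))
        resp = DrugResponsePanel(["d"], lines, auc[None, :])
        rk = dr.rank_drug_biomarkers(bulk, resp)
        assert rk.genes["d"][0] == "g3" and rk.pcc["d"][0] == pytest.approx(1.0)
        assert rk.genes["d"][-1] == "g4" and rk.pcc["d"][-1] == pytest.approx(-1.0)

    def test_constant_gene_excluded_from_list(self):
        lines = [f"l{i}" for i in range(10)]
        bulk = BulkPanel(["a", "b"], lines,
                         np.vstack([np.full(10, 2.0), np.linspace(0, 1, 10)]))
        resp = DrugResponsePanel(["d"], lines, np.linspace(1, 2, 10)[None, :])
        rk = dr.rank_drug_biomarkers(bulk, resp)
        assert rk.genes["d"] == ["b"]

    def test_planted_sensitivity_genes_sink_to_bottom_decile(self):
        from dreep.synthgen import GeneratorSpec, make_training_panel
        spec = GeneratorSpec(seed=21, n_lines=200, n_genes=1000, n_drugs=5,
                             n_planted_drugs=1)
        bulk, resp, truth = make_training_panel(spec)
        fb, fr = dr.filter_training_panel(bulk, resp)
        rk = dr.rank_drug_biomarkers(fb, fr)
        genes = rk.genes["DRUG000"]
        bottom = set(genes[int(len(genes) * 0.9):])
        sens = [g for g in truth["DRUG000"]["sensitivity"] if g in set(genes)]
        frac = np.mean([g in bottom for g in sens])
        assert frac >= 0.95


class TestEnrichmentScore:
    def test_top_packed_set_positive(self):
        genes = [f"g{i}" for i in range(10)]
        es = dr.enrichment_score(genes, np.ones(10), genes[:3])
        assert es == pytest.approx(1.0)  # no retreat before the last hit

    def test_bottom_set_negative(self):
        genes = [f"g{i}" for i in range(10)]
        es = dr.enrichment_score(genes, np.ones(10), genes[-3:])
        assert es == pytest.approx(-1.0)

    def test_hand_computed_walk(self):
        # 10-gene list, hits at ranks 0, 4, 9 (0-based), unit weights:
        # walk: +1/3 at hits, -1/7 at misses
        genes = [f"g{i}" for i in range(10)]
        es = dr.enrichment_score(genes, np.ones(10), ["g0", "g4", "g9"])
        walk, run = [], 0.0
        for i in range(10):
            run += (1 / 3) if i in (0, 4, 9) else (-1 / 7)
            walk.append(run)
        expected = max(walk) if max(walk) >= -min(walk) - 1e-12 else min(walk)
        assert es == pytest.approx(expected)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_and_stays_bounded(self, data):
        n = data.draw(st.integers(4, 14))
        k = data.draw(st.integers(1, min(3, n - 1)))
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        genes = [f"g{i}" for i in range(n)]
        w = np.sort(rng.uniform(-1, 1, n))[::-1]
        gene_set = list(rng.choice(genes, size=k, replace=False))
        es = dr.enrichment_score(genes, w, gene_set)
        assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12
        assert es == pytest.approx(es_brute(genes, w, gene_set), abs=1e-12)

    def test_antisymmetric_under_list_reversal_unit_weights(self, rng):
        genes = [f"g{i}" for i in range(12)]
        gene_set = list(rng.choice(genes, size=4, replace=False))
        w = np.ones(12)
        es_fwd = dr.enrichment_score(genes, w, gene_set)
        es_rev = dr.enrichment_score(genes[::-1], w, gene_set)
        assert es_fwd == pytest.approx(-es_rev)


class TestGseaPreranked:
    def test_small_instance_equals_exhaustive_enumeration(self, rng):
        for n, k in [(8, 2), (10, 3), (6, 1)]:
            genes = [f"g{i}" for i in range(n)]
            w = np.sort(rng.uniform(-1, 1, n))[::-1]
            gene_set = list(rng.choice(genes, size=k, replace=False))
            es, p = dr.gsea_preranked(genes, w, gene_set, n_perm=1000, seed=0)
            # oracle: brute-force ES over every same-size set
            null = [es_brute(genes, w, [genes[i] for i in c])
                    for c in combinations(range(n), k)]
            same = [e for e in null if (e >= 0) == (es >= 0)]
            extreme = [e for e in same if abs(e) >= abs(es) - 1e-12]
            assert p == pytest.approx((1 + len(extreme)) / (1 + len(same)))

    def test_top_packed_set_attains_minimum_p(self):
        genes = [f"g{i}" for i in range(200)]
        w = np.linspace(1, -1, 200)
        es, p = dr.gsea_preranked(genes, w, genes[:5], n_perm=500, seed=1)
        assert es > 0
        assert p <= 2 / 501

    def test_calibrated_under_random_sets(self, rng):
        genes = [f"g{i}" for i in range(300)]
        w = np.sort(rng.uniform(-1, 1, 300))[::-1]
        ps = []
        for i in range(200):
            gene_set = list(rng.choice(genes, size=20, replace=False))
            _, p = dr.gsea_preranked(genes, w, gene_set, n_perm=200, seed=i)
            ps.append(p)
        assert 0.01 < np.mean(np.array(ps) < 0.2) < 0.45  # ~0.2 expected


def _mixture(seed=3, **kw):
    from dreep.synthgen import GeneratorSpec, make_two_population_mixture
    defaults = dict(n_genes=800, n_drugs=8, n_cells_per_line=40, signature_size=80)
    defaults.update(kw)
    return make_two_population_mixture(GeneratorSpec(seed=seed, **defaults))


class TestPredictCells:
    def test_constructed_sensitive_cell_called(self):
        rng = np.random.default_rng(4)
        n = 600
        genes = [f"g{i}" for i in range(n)]
        pcc = np.sort(rng.uniform(-1, 1, n))[::-1]
        order = list(rng.permutation(genes))
        rk = _ranking(order, pcc, drug="d0")
        expr = pd.Series(0.0, index=genes, name="cell0")
        expr[order[-250:]] = rng.uniform(1, 10, 250)  # sensitivity tail expressed
        out = dr.predict_cells(pd.DataFrame(expr), rk, top_n=250, n_perm=500, seed=0)
        row = out.iloc[0]
        assert row["es"] < 0 and row["call"] == "d0"

    def test_uniform_random_cell_mostly_unclassified(self):
        counts, labels, rk, flags = _mixture()
        rng = np.random.default_rng(9)
        calls = []
        for i in range(10):
            expr = pd.Series(rng.uniform(0, 1, 800),
                             index=[f"G{j:05d}" for j in range(800)], name=f"c{i}")
            out = dr.predict_cells(pd.DataFrame(expr), rk, top_n=250,
                                   n_perm=300, seed=i)
            calls.append(out["call"].iloc[0])
        assert calls.count("unclassified") >= 7

    def test_positive_es_only_is_unclassified(self):
        genes = [f"g{i}" for i in range(400)]
        rk = _ranking(genes, np.sort(np.random.default_rng(0).uniform(-1, 1, 400))[::-1])
        expr = pd.Series(0.0, index=genes, name="c")
        expr[genes[:250]] = 1.0  # resistance end only -> es > 0
        out = dr.predict_cells(pd.DataFrame(expr), rk, top_n=250, n_perm=300, seed=0)
        assert out.iloc[0]["es"] > 0
        assert out.iloc[0]["call"] == "unclassified"

    def test_invariant_to_monotone_transform(self):
        counts, labels, rk, flags = _mixture()
        sub = counts.subset_cells(np.arange(5))
        raw = pd.DataFrame(sub.counts.toarray().astype(float),
                           index=sub.gene_ids, columns=sub.cell_ids)
        a = dr.predict_cells(raw, rk, top_n=100, n_perm=300, seed=0)
        b = dr.predict_cells(np.log1p(raw) ** 2, rk, top_n=100, n_perm=300, seed=0)
        pd.testing.assert_frame_equal(a, b)

    def test_deterministic_and_order_invariant(self):
        counts, labels, rk, flags = _mixture()
        sub = counts.subset_cells(np.arange(6))
        rev = counts.subset_cells(np.arange(5, -1, -1))
        a = dr.predict_cells(sub, rk, top_n=100, n_perm=200, seed=7)
        b = dr.predict_cells(rev, rk, top_n=100, n_perm=200, seed=7)
        merged = a.merge(b, on=["cell_id", "drug_id"], suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["es_a"], merged["es_b"])
        np.testing.assert_allclose(merged["p_value_a"], merged["p_value_b"])


class TestPopulationAndDifferential:
    def test_population_call_is_majority_drug(self):
        t = pd.DataFrame({
            "cell_id": np.repeat([f"c{i}" for i in range(10)], 2),
            "drug_id": ["A", "B"] * 10,
            "es": [-0.5, -0.4] * 10,
            "fdr": ([0.01, 0.01] * 6) + ([0.01, 0.5] * 4),
            "call": ["A"] * 20,
        })
        summary, call = dr.predict_population(t)
        frac = summary.set_index("drug_id")["sensitive_fraction"]
        assert frac["A"] == 1.0 and frac["B"] == 0.6
        assert call == "A"

    def test_all_unclassified_population(self):
        t = pd.DataFrame({"cell_id": ["c0", "c1"], "drug_id": ["A", "A"],
                          "es": [0.3, 0.2], "fdr": [0.8, 0.9],
                          "call": ["unclassified"] * 2})
        _, call = dr.predict_population(t)
        assert call == "unclassified"

    def test_separated_groups_are_group_specific(self):
        es = pd.DataFrame({"d": [-0.5] * 20 + [0.5] * 20})
        labels = np.array(["g1"] * 20 + ["g2"] * 20)
        out = dr.differential_sensitivity(es, labels)
        assert out.iloc[0]["class"] == "group1-specific"
        assert out.iloc[0]["fdr"] < 0.05

    def test_identical_groups_unclassified(self, rng):
        vals = rng.normal(0, 0.1, 30)
        es = pd.DataFrame({f"d{i}": vals for i in range(5)})
        labels = np.array(["g1"] * 15 + ["g2"] * 15)
        out = dr.differential_sensitivity(es, labels)
        assert not out["class"].str.endswith("specific").any()

    def test_shared_when_both_medians_negative(self, rng):
        es = pd.DataFrame({"d": np.concatenate([
            rng.normal(-0.4, 0.05, 20), rng.normal(-0.4, 0.05, 20)])})
        labels = np.array(["g1"] * 20 + ["g2"] * 20)
        out = dr.differential_sensitivity(es, labels)
        assert out.iloc[0]["class"] == "shared"

    def test_mixture_planted_drug_detected(self):
        counts, labels, rk, flags = _mixture(seed=31, n_cells_per_line=60)
        table = dr.predict_cells(counts, rk, top_n=200, n_perm=300, seed=0)
        es = table.pivot(index="cell_id", columns="drug_id", values="es") \
            .loc[counts.cell_ids]
        out = dr.differential_sensitivity(es, labels).set_index("drug_id")
        planted = flags[flags].index[0]
        assert out.loc[planted, "class"] == "group1-specific"


class TestGoldenStandard:
    def _resp(self, n_lines=100, seed=0):
        rng = np.random.default_rng(seed)
        return DrugResponsePanel(["d0", "d1"], [f"l{i}" for i in range(n_lines)],
                                 rng.normal(10, 2, (2, n_lines)))

    def test_exactly_five_percent_sensitive(self):
        g = dr.build_golden_standard(self._resp(100), pctile=5)
        assert g.sensitive.sum(axis=1).tolist() == [5, 5]

    def test_minimum_auc_line_always_sensitive(self):
        resp = self._resp(100)
        g = dr.build_golden_standard(resp, pctile=5)
        for di in range(2):
            assert g.sensitive[di, np.argmin(resp.auc[di])]

    def test_affine_invariance(self):
        resp = self._resp(60)
        g1 = dr.build_golden_standard(resp, pctile=5)
        resp2 = DrugResponsePanel(resp.drug_ids, resp.sample_ids,
                                  3.0 * resp.auc + 7.0)
        g2 = dr.build_golden_standard(resp2, pctile=5)
        np.testing.assert_array_equal(g1.sensitive, g2.sensitive)

    def test_constant_auc_warns_no_sensitive(self):
        resp = DrugResponsePanel(["d"], [f"l{i}" for i in range(30)],
                                 np.full((1, 30), 5.0))
        with pytest.warns(UserWarning, match="constant"):
            g = dr.build_golden_standard(resp)
        assert g.sensitive.sum() == 0


class TestEvaluation:
    def test_perfect_predictions_score_one(self):
        rng = np.random.default_rng(5)
        resp = DrugResponsePanel([f"d{i}" for i in range(3)],
                                 [f"l{i}" for i in range(40)],
                                 rng.normal(10, 2, (3, 40)))
        golden = dr.build_golden_standard(resp, pctile=10)
        pred = pd.DataFrame(golden.sensitive.astype(float),
                            index=golden.drug_ids, columns=golden.sample_ids)
        curve = dr.evaluate_ppv_recall(pred, golden, fraction_grid=[0.5, 1.0])
        assert (curve["ppv"] == 1.0).all()
        assert (curve["recall"] == 1.0).all()

    def test_random_predictions_ppv_near_prevalence(self):
        rng = np.random.default_rng(6)
        n_drugs, n_lines = 50, 40
        resp = DrugResponsePanel([f"d{i}" for i in range(n_drugs)],
                                 [f"l{i}" for i in range(n_lines)],
                                 rng.normal(10, 2, (n_drugs, n_lines)))
        golden = dr.build_golden_standard(resp, pctile=10)
        prevalence = golden.sensitive.mean()
        pred = pd.DataFrame(rng.random((n_drugs, n_lines)),
                            index=golden.drug_ids, columns=golden.sample_ids)
        curve = dr.evaluate_ppv_recall(pred, golden, fraction_grid=[0.2, 0.5])
        assert np.nanmax(np.abs(curve["ppv"] - prevalence)) < 0.08
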