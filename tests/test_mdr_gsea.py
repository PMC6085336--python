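import itertools
import math

import numpy as np
import pandas as pd
import pytest

from lncgx.dataio import GeneSetCollection, ValidationError
from lncgx.enselect import PairTable
from lncgx.mdr_gsea import (
    correlation_profile,
    flag_mdr,
    gsea_preranked,
    mdr_lncrnas,
    pathway_vectors,
    shannon_entropy,
    top_predictor_pathway_enrichment,
)


def pair_table(rows):
    df = pd.DataFrame(rows, columns=["feature", "agent"])
    df["ps"] = 0.5
    return PairTable(table=df, cutoff=0.25)


def entropy_oracle(labels):
    """Direct formula evaluation: H = -sum p log2 p over label frequencies."""
    m = len(labels)
    return -sum(
        (labels.count(u) / m) * math.log2(labels.count(u) / m)
        for u in set(labels)
    )


class TestShannonEntropy:
    def test_single_pathway_is_zero(self):
        assert shannon_entropy(["mitosis"] * 7) == 0.0

    def test_uniform_four_pathways_is_two_bits(self):
        assert shannon_entropy(list("ABCD")) == pytest.approx(2.0)

    def test_two_thirds_one_third(self):
        assert shannon_entropy(["A", "A", "B"]) == pytest.approx(0.9183, abs=1e-4)

    def test_matches_oracle_on_all_small_multisets(self):
        # every multiset of size <= 6 over 4 labels vs the direct formula
        labels = list("ABCD")
        for m in range(1, 7):
            for combo in itertools.combinations_with_replacement(labels, m):
                got = shannon_entropy(list(combo))
                want = entropy_oracle(list(combo))
                assert got == pytest.approx(want, abs=1e-12)
                assert -1e-12 <= got <= math.log2(len(set(combo))) + 1e-12

    def test_empty_multiset_rejected(self):
        with pytest.raises(ValidationError):
            shannon_entropy([])


class TestPathwayVectors:
    def test_duplicates_preserved_and_counts_conserved(self):
        pairs = pair_table([
            ("L1", "d1"), ("L1", "d2"), ("L1", "d3"), ("L2", "d1")
        ])
        vectors = pathway_vectors(
            pairs, {"d1": "mitosis", "d2": "mitosis", "d3": "mitosis"}
        )
        assert vectors["L1"] == ["mitosis"] * 3
        assert sum(len(v) for v in vectors.values()) == len(pairs.table)
        assert "L3" not in vectors

    def test_unmapped_agent_rejected(self):
        pairs = pair_table([("L1", "d1")])
        with pytest.raises(ValidationError, match="d1"):
            pathway_vectors(pairs, {})


class TestFlagMDR:
    def test_broad_lncrna_flagged_among_narrow_peers(self):
        rows = [(f"L{i}", f"d{i}a") for i in range(10)]
        rows += [(f"L{i}", f"d{i}b") for i in range(10)]
        rows += [("Lbroad", f"dx{j}") for j in range(8)]
        mapping = {}
        for i in range(10):
            mapping[f"d{i}a"] = mapping[f"d{i}b"] = f"PW{i}"
        for j in range(8):
            mapping[f"dx{j}"] = f"PWX{j}"
        out = mdr_lncrnas(pair_table(rows), mapping)
        assert bool(out.at["Lbroad", "mdr"])
        assert not out.drop("Lbroad")["mdr"].any()

    def test_equal_entropies_flag_nothing(self, caplog):
        entropies = pd.Series({"L1": 1.0, "L2": 1.0, "L3": 1.0})
        with caplog.at_level("WARNING"):
            out = flag_mdr(entropies)
        assert not out["mdr"].any()

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        entropies = pd.Series(rng.uniform(0, 3, 20),
                              index=[f"L{i}" for i in range(20)])
        a = flag_mdr(entropies)
        b = flag_mdr(entropies.sample(frac=1, random_state=1))
        assert set(a[a["mdr"]].index) == set(b[b["mdr"]].index)

    def test_too_few_lncrnas_rejected(self):
        with pytest.raises(ValidationError):
            flag_mdr(pd.Series({"L1": 0.0, "L2": 1.0}))


class TestCorrelationProfile:
    def test_identical_and_negated_genes_at_extremes(self):
        rng = np.random.default_rng(1)
        lnc = pd.Series(rng.standard_normal(30),
                        index=[f"S{i}" for i in range(30)])
        pcg = pd.DataFrame(
            {"same": lnc, "anti": -lnc, "noise": rng.standard_normal(30)},
            index=lnc.index,
        )
        ranked = correlation_profile(lnc, pcg)
        assert ranked.index[0] == "same" and ranked.iloc[0] == pytest.approx(1.0)
        assert ranked.index[-1] == "anti" and ranked.iloc[-1] == pytest.approx(-1.0)

    def test_constant_gene_gets_zero_with_flag(self, caplog):
        lnc = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        pcg = pd.DataFrame({"flat": [5.0, 5.0, 5.0]}, index=list("abc"))
        with caplog.at_level("WARNING"):
            ranked = correlation_profile(lnc, pcg)
        assert ranked["flat"] == 0.0


def naive_es(ranked: pd.Series, members: set[str], exponent: float = 1.0) -> float:
    """Independent O(N) running-sum oracle for the enrichment score."""
    hits = np.array([g in members for g in ranked.index])
    w = np.abs(ranked.to_numpy()) ** exponent
    nr = w[hits].sum()
    dec = 1.0 / (len(ranked) - hits.sum())
    run, best = 0.0, 0.0
    for i in range(len(ranked)):
        run = run + w[i] / nr if hits[i] else run - dec
        if abs(run) > abs(best):
            best = run
    return best


class TestGSEA:
    def ranking(self, n=400, seed=2):
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.standard_normal(n))[::-1]
        return pd.Series(scores, index=[f"G{i:04d}" for i in range(n)])

    def test_es_matches_naive_running_sum_oracle(self):
        ranked = self.ranking()
        rng = np.random.default_rng(3)
        sets = {
            f"S{k}": sorted(rng.choice(ranked.index, size=s, replace=False))
            for k, s in enumerate([5, 17, 40, 80])
        }
        result = gsea_preranked(ranked, GeneSetCollection(sets), n_perm=50, seed=0)
        for name, members in sets.items():
            assert result.table.at[name, "es"] == pytest.approx(
                naive_es(ranked, set(members)), abs=1e-12
            )

    def test_top_block_set_is_extreme(self):
        ranked = self.ranking()
        top = list(ranked.index[:20])
        result = gsea_preranked(
            ranked, GeneSetCollection({"top": top}), n_perm=200, seed=0
        )
        row = result.table.loc["top"]
        assert row["es"] > 0
        # no permuted set reaches the observed ES: p at its floor
        assert row["p"] < 0.02

    def test_reversed_ranking_negates_es(self):
        ranked = self.ranking()
        rng = np.random.default_rng(4)
        sets = GeneSetCollection({
            f"S{k}": sorted(rng.choice(ranked.index, size=25, replace=False))
            for k in range(5)
        })
        fwd = gsea_preranked(ranked, sets, n_perm=20, seed=0)
        rev = gsea_preranked(-ranked, sets, n_perm=20, seed=0)
        np.testing.assert_allclose(
            fwd.table["es"].to_numpy(), -rev.table["es"].to_numpy(), atol=1e-12
        )

    def test_small_sets_skipped(self):
        ranked = self.ranking(50)
        result = gsea_preranked(
            ranked, GeneSetCollection({"tiny": list(ranked.index[:3])}),
            n_perm=20, seed=0,
        )
        assert result.table.empty

    def test_matches_external_gsea_implementation(self):
        gseapy = pytest.importorskip("gseapy")
        ranked = self.ranking(300, seed=5)
        rng = np.random.default_rng(6)
        sets = {
            f"S{k}": sorted(rng.choice(ranked.index, size=20, replace=False))
            for k in range(3)
        }
        ours = gsea_preranked(ranked, GeneSetCollection(sets), n_perm=100, seed=0)
        theirs = gseapy.prerank(
            rnk=ranked.reset_index().rename(columns={"index": "gene", 0: "score"}),
            gene_sets=sets, permutation_num=10, outdir=None, seed=1,
            min_size=3, max_size=500, no_plot=True, threads=1,
        ).res2d.set_index("Term")
        for name in sets:
            assert ours.table.at[name, "es"] == pytest.approx(
                float(theirs.at[name, "ES"]), abs=1e-6
            )


class TestTopPredictorEnrichment:
    def test_saturated_agent(self):
        universe = [f"L{i}" for i in range(100)]
        top = universe[:20]
        sig = pd.DataFrame(False, index=universe, columns=["PW1"])
        sig.loc[top, "PW1"] = True
        out = top_predictor_pathway_enrichment({"d": top}, sig, k=20)
        row = out.iloc[0]
        assert row["n_enriched"] == 20
        assert row["p"] < 1e-15

    def test_counts_follow_hypergeometric_under_independence(self):
        rng = np.random.default_rng(7)
        universe = [f"L{i}" for i in range(200)]
        ps = []
        for rep in range(50):
            sig = pd.DataFrame(
                {"PW1": rng.random(200) < 0.3}, index=universe
            )
            top = list(rng.choice(universe, size=20, replace=False))
            out = top_predictor_pathway_enrichment({"d": top}, sig, k=20)
            ps.append(out.iloc[0]["p"])
        # conservative discrete p-values: sub-uniform
        assert (np.array(ps) < 0.05).mean() <= 0.10
        assert np.median(ps) > 0.2
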