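"""Phenotype summaries and trait-related transcript calling."""

import numpy as np
import pandas as pd
import pytest

from trastools.io import ExpressionMatrix, PhenotypeTable, SnpRecord
from trastools.popstruct import significance_thresholds
from trastools.tras import (call_trait_related, expression_trait_correlation,
                            map_snps_to_transcripts, summarize_phenotypes,
                            trait_related_frame)


def _pheno(**cols):
    n = len(next(iter(cols.values())))
    samples = [f"s{i}" for i in range(n)]
    return PhenotypeTable(samples, pd.DataFrame(cols, index=samples))


class Hit:
    def __init__(self, snp_id, p=1e-8):
        self.snp_id = snp_id
        self.p_value = p


class TestSummarize:
    def test_fold_range_display(self):
        P = _pheno(CN=[5.8, 12.0, 20.0, 35.3])
        s = summarize_phenotypes(P)
        assert s.per_trait.loc["CN", "fold_range"] == pytest.approx(35.3 / 5.8)
        assert s.fold_range_display("CN") == "6.1"

    def test_nonpositive_minimum_flags_fold_range_undefined(self):
        P = _pheno(BW=[0.0, 2.0, 5.0])
        s = summarize_phenotypes(P)
        assert np.isnan(s.per_trait.loc["BW", "fold_range"])
        assert s.fold_range_display("BW") == "undefined"

    def test_constant_trait_flags_correlations(self):
        P = _pheno(A=[2.0, 2.0, 2.0, 2.0], B=[1.0, 2.0, 3.0, 4.0])
        s = summarize_phenotypes(P)
        assert s.per_trait.loc["A", "sd"] == 0.0
        assert s.correlations["r"].isna().all()

    def test_matches_direct_recomputation(self, default_cohort):
        P = default_cohort.phenotypes
        s = summarize_phenotypes(P)
        for t in P.trait_names:
            v = P.traits[t]
            assert s.per_trait.loc[t, "mean"] == pytest.approx(v.mean())
            assert s.per_trait.loc[t, "sd"] == pytest.approx(v.std(ddof=1))
            assert s.per_trait.loc[t, "fold_range"] == \
                pytest.approx(v.max() / v.min())
        from scipy import stats
        got = s.correlations.set_index(["trait_a", "trait_b"])
        r, p = stats.pearsonr(P.traits["BW"], P.traits["BD"])
        assert got.loc[("BW", "BD"), "r"] == pytest.approx(r)
        assert got.loc[("BW", "BD"), "p"] == pytest.approx(p)


class TestMapping:
    SNPS = [SnpRecord("a", "T1", 1, "A", "G"), SnpRecord("b", "T1", 5, "A", "G"),
            SnpRecord("c", "T2", 3, "A", "G")]

    def test_groups_by_transcript(self):
        mapping = map_snps_to_transcripts([Hit("a"), Hit("b"), Hit("c")],
                                          self.SNPS)
        assert mapping == {"T1": ["a", "b"], "T2": ["c"]}

    def test_empty_hits(self):
        assert map_snps_to_transcripts([], self.SNPS) == {}

    def test_unknown_snp_is_hard_error(self):
        with pytest.raises(KeyError):
            map_snps_to_transcripts([Hit("nope")], self.SNPS)


class TestExpressionCorrelation:
    def _expr(self, cols):
        names = sorted(cols)
        n = len(next(iter(cols.values())))
        return ExpressionMatrix([f"s{i}" for i in range(n)], names,
                                np.column_stack([cols[t] for t in names]),
                                transformed=True)

    def test_perfect_and_collinear(self):
        y = np.array([2.0, 4, 6, 8, 10])
        E = self._expr({"t1": np.arange(1.0, 6.0)})
        out = expression_trait_correlation(E, y, ["t1"])
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "p"] < 1e-10

    def test_orthogonal_expression(self):
        y = np.array([-1.0, 1, -1, 1, -1, 1])
        e = np.array([1.0, 1, -1, -1, 1, 1])
        e -= e.mean()
        e -= (e @ (y - y.mean())) / ((y - y.mean()) @ (y - y.mean())) * (y - y.mean())
        E = self._expr({"t1": e + 5})
        out = expression_trait_correlation(E, y, ["t1"])
        assert abs(out.loc[0, "r"]) < 1e-10

    def test_zero_variance_flagged(self):
        E = self._expr({"t1": np.ones(5)})
        out = expression_trait_correlation(E, np.arange(5.0), ["t1"])
        assert out.loc[0, "degenerate"]
        assert out.loc[0, "p"] == 1.0


class TestCallTraitRelated:
    def _inputs(self):
        mapping = {"T1": ["a"], "T2": ["b"], "T3": ["c"]}
        best_p = {"T1": 1e-7, "T2": 1e-8, "T3": 1e-9}
        corr = pd.DataFrame({
            "transcript_id": ["T1", "T2", "T3"],
            "r": [0.5, -0.4, 0.01],
            "p": [0.001, 0.03, 0.9],
            "degenerate": [False] * 3,
        })
        th = significance_thresholds(100, 100.0, 0.05)
        return mapping, best_p, corr, th

    def test_intersection_and_direction(self):
        mapping, best_p, corr, th = self._inputs()
        calls = call_trait_related(mapping, best_p, corr, "BW", th)
        assert [(c.transcript_id, c.direction) for c in calls] == \
            [("T1", "+"), ("T2", "-")]
        assert all(c.best_genotype_p <= th.bonferroni_p for c in calls)
        assert {c.transcript_id for c in calls} <= set(mapping)

    def test_direction_flips_with_correlation_sign(self):
        mapping, best_p, corr, th = self._inputs()
        corr2 = corr.copy()
        corr2["r"] = -corr2["r"]
        a = call_trait_related(mapping, best_p, corr, "BW", th)
        b = call_trait_related(mapping, best_p, corr2, "BW", th)
        assert [c.transcript_id for c in a] == [c.transcript_id for c in b]
        assert all(x.direction != y.direction for x, y in zip(a, b))

    def test_disjoint_sets_give_empty_list(self):
        mapping, best_p, corr, th = self._inputs()
        corr["p"] = 0.5
        assert call_trait_related(mapping, best_p, corr, "BW", th) == []

    def test_bh_option_is_stricter(self):
        mapping, best_p, corr, th = self._inputs()
        raw = call_trait_related(mapping, best_p, corr, "BW", th)
        bh = call_trait_related(mapping, best_p, corr, "BW", th, adjust="bh")
        assert {c.transcript_id for c in bh} <= {c.transcript_id for c in raw}

    def test_frame_counts_and_pleiotropy(self):
        mapping, best_p, corr, th = self._inputs()
        calls = call_trait_related(mapping, best_p, corr, "BW", th)
        calls += call_trait_related(mapping, best_p, corr, "CN", th)
        df = trait_related_frame(calls)
        assert set(df.columns) >= {"trait", "transcript_id", "direction",
                                   "pleiotropic"}
        assert df["pleiotropic"].all()  # same transcripts hit both traits


class TestRecoveryOnCohort:
    def test_planted_transcripts_called_with_true_direction(
            self, default_cohort, default_pipeline):
        truth = default_cohort.truth.causal_transcripts
        calls = {(c.trait, c.transcript_id): c.direction
                 for c in default_pipeline.trait_related}
        overlap = [(k, d) for k, d in calls.items()
                   if k[1] in truth.get(k[0], {})]
        assert overlap, "no planted transcript recovered on the default cohort"
        assert all(truth[t][tr] == d for (t, tr), d in overlap)

    def test_counts_are_nested(self, default_pipeline):
        counts = default_pipeline.counts["per_trait"]
        for t, c in counts.items():
            assert c["n_trait_related"] <= c["n_snp_located_transcripts"] \
                <= c["n_significant_snps"]
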