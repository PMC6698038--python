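"""Module eigengenes, module-trait correlation, partner sets, GO enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from trastools.coexpr import (correlation_partners, go_enrichment,
                              lncrna_partners, module_eigengene,
                              module_trait_correlation)
from trastools.io import ExpressionMatrix, PhenotypeTable


def _expr(values, names=None):
    values = np.asarray(values, float)
    names = names or [f"t{j}" for j in range(values.shape[1])]
    return ExpressionMatrix([f"s{i}" for i in range(values.shape[0])],
                            names, values, transformed=True)


class TestEigengene:
    def test_two_identical_transcripts(self, rng):
        profile = rng.standard_normal(20)
        E = _expr(np.column_stack([profile, profile]))
        modules = {"t0": "M1", "t1": "M1"}
        eg = module_eigengene(E, modules, "M1")
        z = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(eg, z / np.linalg.norm(z), atol=1e-10)

    def test_recovers_latent_factor(self, rng):
        n, t, snr = 102, 40, 2.0
        f = rng.standard_normal(n)
        load = np.sqrt(snr / (1 + snr))
        X = load * f[:, None] + np.sqrt(1 / (1 + snr)) * rng.standard_normal((n, t))
        E = _expr(X)
        eg = module_eigengene(E, {f"t{j}": "M1" for j in range(t)}, "M1")
        assert abs(np.corrcoef(eg, f)[0, 1]) >= 0.9

    def test_invariant_to_transcript_order(self, rng):
        X = rng.standard_normal((30, 8))
        E1 = _expr(X)
        perm = rng.permutation(8)
        E2 = _expr(X[:, perm], names=[f"t{j}" for j in perm])
        mods = {f"t{j}": "M1" for j in range(8)}
        np.testing.assert_allclose(module_eigengene(E1, mods, "M1"),
                                   module_eigengene(E2, mods, "M1"),
                                   atol=1e-10)

    def test_column_sign_flip_preserves_trait_correlation(self, rng):
        X = rng.standard_normal((40, 6)) + rng.standard_normal(40)[:, None]
        y = rng.standard_normal(40)
        mods = {f"t{j}": "M1" for j in range(6)}
        r1 = np.corrcoef(module_eigengene(_expr(X), mods, "M1"), y)[0, 1]
        r2 = np.corrcoef(module_eigengene(_expr(-X), mods, "M1"), y)[0, 1]
        assert abs(abs(r1) - abs(r2)) < 1e-10

    def test_singleton_module_warns(self, rng):
        E = _expr(rng.standard_normal((10, 2)))
        with pytest.warns(UserWarning, match="singleton"):
            eg = module_eigengene(E, {"t0": "M1"}, "M1")
        assert np.linalg.norm(eg) == pytest.approx(1.0)

    def test_unknown_module_raises(self, rng):
        E = _expr(rng.standard_normal((10, 2)))
        with pytest.raises(KeyError):
            module_eigengene(E, {"t0": "M1"}, "M9")


class TestModuleTraitCorrelation:
    def _pheno(self, y):
        samples = [f"s{i}" for i in range(len(y))]
        return PhenotypeTable(samples, pd.DataFrame({"CN": y}, index=samples))

    def test_identical_vector_gives_unit_correlation(self, rng):
        y = rng.standard_normal(30)
        out = module_trait_correlation({"M1": y.copy()}, self._pheno(y))
        row = out.iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["significant"]

    def test_permutation_null_calibrates(self, rng):
        n = 60
        eg = rng.standard_normal(n)
        hits = 0
        for _ in range(100):
            y = rng.permutation(eg) + rng.standard_normal(n)
            out = module_trait_correlation({"M1": eg}, self._pheno(y))
            hits += int(out.iloc[0]["significant"])
        assert hits / 100 <= 0.12  # ~alpha, generous 3-sigma band

    def test_recovers_planted_module_trait_link(self, default_cohort,
                                                default_pipeline):
        co = default_cohort
        mc = default_pipeline.module_corr
        row = mc[(mc["module"] == co.truth.cn_module) & (mc["trait"] == "CN")]
        assert len(row) == 1
        assert row.iloc[0]["r"] == pytest.approx(0.452, abs=0.15)
        assert row.iloc[0]["significant"]


class TestPartners:
    MODULES = {"lnc": "M7", "a": "M7", "b": "M7", "c": "M7", "d": "M7",
               "x": "M2", "solo": "M9"}

    def test_shared_module_membership(self):
        assert lncrna_partners("lnc", self.MODULES) == {"a", "b", "c", "d"}

    def test_singleton_module_empty(self):
        assert lncrna_partners("solo", self.MODULES) == set()

    def test_unassigned_warns_empty(self):
        with pytest.warns(UserWarning, match="not assigned"):
            assert lncrna_partners("ghost", self.MODULES) == set()

    def test_matches_planted_co_members(self, small_cohort):
        truth = small_cohort.truth
        lnc = [t for t in truth.lncrna_ids
               if truth.module_labels.get(t, "M00") != "M00"][0]
        got = lncrna_partners(lnc, truth.module_labels)
        want = {t for t, m in truth.module_labels.items()
                if m == truth.module_labels[lnc] and t != lnc}
        assert got == want

    def test_correlation_partner_alternative(self, rng):
        f = rng.standard_normal(50)
        X = np.column_stack([f, 0.95 * f + 0.1 * rng.standard_normal(50),
                             rng.standard_normal(50)])
        E = _expr(X, names=["lnc", "buddy", "noise"])
        assert correlation_partners(E, "lnc", min_abs_r=0.7) == {"buddy"}


class TestGoEnrichment:
    def _annotation(self, term_members):
        rows = [(t, term, term) for term, members in term_members.items()
                for t in members]
        return pd.DataFrame(rows, columns=["transcript_id", "term_id",
                                           "term_name"])

    def test_closed_form_extreme_case(self):
        background = {f"g{i}" for i in range(20)}
        target = {f"g{i}" for i in range(5)}
        ann = self._annotation({"GO:1": target})
        res = go_enrichment(target, background, ann, return_all=True)
        assert res[0].p_value == pytest.approx(1.0 / math.comb(20, 5))

    def test_invariants_and_term_order_independence(self, rng):
        background = {f"g{i}" for i in range(60)}
        terms = {f"GO:{k}": set(rng.choice(sorted(background), 12,
                                           replace=False))
                 for k in range(6)}
        target = set(rng.choice(sorted(background), 20, replace=False))
        ann = self._annotation(terms)
        res = go_enrichment(target, background, ann, return_all=True)
        for e in res:
            assert e.q_value >= e.p_value - 1e-15
            assert 0 < e.p_value <= 1 and 0 < e.q_value <= 1
            assert e.k_in_set <= min(e.K_in_background, e.n_set)
        shuffled = ann.sample(frac=1, random_state=0).reset_index(drop=True)
        res2 = go_enrichment(target, background, shuffled, return_all=True)
        assert [(e.term_id, e.p_value, e.q_value) for e in res] == \
               [(e.term_id, e.p_value, e.q_value) for e in res2]

    def test_bh_step_up_monotone(self, rng):
        background = {f"g{i}" for i in range(100)}
        terms = {f"GO:{k}": set(rng.choice(sorted(background), 15,
                                           replace=False))
                 for k in range(10)}
        target = set(rng.choice(sorted(background), 30, replace=False))
        res = go_enrichment(target, background, self._annotation(terms),
                            return_all=True)
        by_p = sorted(res, key=lambda e: e.p_value)
        qs = [e.q_value for e in by_p]
        assert qs == sorted(qs)

    def test_target_outside_background_rejected(self):
        with pytest.raises(ValueError):
            go_enrichment({"a"}, {"b"}, self._annotation({"GO:1": {"b"}}))
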