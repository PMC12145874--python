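"""FCS gene-sampling, ORA contingency tests, UGS criterion, FDR combination."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phresp.enrichment import (
    EnrichmentCall,
    GeneSamplingNull,
    adjust_and_combine,
    fcs,
    ora,
    run_enrichment,
    ugs,
)
from phresp.scoring import call_degs
from phresp.synthetic import DESimConfig, simulate_de


def _scored_from_scores(scores, labels=None):
    genes = [f"g{i:03d}" for i in range(len(scores))]
    return pd.DataFrame(
        {"slfdr": np.asarray(scores, float),
         "deg_label": labels if labels is not None else ["none"] * len(scores)},
        index=pd.Index(genes, name="gene_id"),
    ), genes


class TestFCS:
    def test_maximal_separation_is_extreme_and_enriched(self):
        scored, genes = _scored_from_scores([-10.0] * 5 + [0.0] * 95)
        call = fcs(scored, genes[:5], n_perm=999, seed=0)
        assert call.direction == "enriched"
        # near the permutation floor (only same-extreme draws can tie)
        assert call.p <= 3 / 1000

    def test_exact_enumeration_matches_brute_force(self):
        """Small universes switch to exhaustive subset enumeration; verify it
        against an independent itertools oracle."""
        rng = np.random.default_rng(7)
        for n, k in ((8, 3), (10, 4), (7, 2)):
            scores = rng.normal(size=n)
            scored, genes = _scored_from_scores(scores)
            call = fcs(scored, genes[:k], n_perm=10_000, seed=1)
            ranks = stats.rankdata(scores)
            expected_w = k * (n + 1) / 2
            obs = ranks[:k].sum()
            null = [
                ranks[list(c)].sum() for c in itertools.combinations(range(n), k)
            ]
            p_oracle = sum(
                abs(w - expected_w) >= abs(obs - expected_w) - 1e-9 for w in null
            ) / len(null)
            assert call.p == pytest.approx(p_oracle, abs=1e-12)

    def test_null_sets_rarely_called_at_fdr(self):
        """In-set scores drawn from the out-of-set law stay uncalled at FDR .01."""
        rng = np.random.default_rng(3)
        scores = rng.normal(size=300)
        scored, genes = _scored_from_scores(scores)
        from dataclasses import replace

        engine = GeneSamplingNull(scored["slfdr"].to_numpy(), n_perm=500, seed=3)
        sets = {f"N{i}": list(rng.choice(genes, size=10, replace=False)) for i in range(100)}
        calls = {
            "FCS": [
                replace(fcs(scored, members, engine=engine), set_id=sid)
                for sid, members in sets.items()
            ]
        }
        with pytest.warns(UserWarning):
            adjusted, composites = adjust_and_combine(calls, alpha=0.01)
        n_called = sum(c.enriched or c.depleted for c in composites)
        assert n_called <= 1

    def test_permutation_p_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=60)
        scored, genes = _scored_from_scores(scores)
        members = genes[:8]
        p1 = fcs(scored, members, n_perm=400, seed=5).p
        transformed, _ = _scored_from_scores(np.exp(scores) + 3)
        p2 = fcs(transformed, members, n_perm=400, seed=5).p
        assert p1 == p2

    def test_asymptotic_mode_agrees_in_direction(self):
        scored, genes = _scored_from_scores([-5.0] * 10 + [0.5] * 90)
        samp = fcs(scored, genes[:10], n_perm=500, seed=2)
        asym = fcs(scored, genes[:10], mode="asymptotic")
        assert samp.direction == asym.direction == "enriched"
        assert 0 <= asym.p <= 1

    def test_degenerate_sets_rejected(self):
        scored, genes = _scored_from_scores([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="universe"):
            fcs(scored, genes)
        with pytest.raises(ValueError, match="empty"):
            fcs(scored, [])


class TestORA:
    def test_hand_computed_enrichment(self):
        # set of 10 with 8 up-DEGs; universe 1000 with 20 up-DEGs total
        labels = ["up"] * 8 + ["none"] * 2 + ["up"] * 12 + ["none"] * 978
        scored, genes = _scored_from_scores(np.zeros(1000), labels)
        call = ora(scored, genes[:10])
        # closed-form chi-square for [[8, 2], [12, 978]]
        n, r1, c1 = 1000, 10, 20
        expected = [[r1 * c1 / n, r1 * (n - c1) / n],
                    [(n - r1) * c1 / n, (n - r1) * (n - c1) / n]]
        obs = [[8, 2], [12, 978]]
        chi2 = sum((obs[i][j] - expected[i][j]) ** 2 / expected[i][j]
                   for i in range(2) for j in range(2))
        p_hand = stats.chi2.sf(chi2, 1)
        assert call.direction == "enriched"
        assert call.p_enriched == pytest.approx(p_hand, rel=1e-9)

    def test_identical_proportions_give_none(self):
        # 10% up everywhere: in-set 1/10 equals out-of-set proportion
        labels = (["up"] + ["none"] * 9) * 10
        scored, genes = _scored_from_scores(np.zeros(100), labels)
        call = ora(scored, genes[:10])
        assert call.direction == "none"

    def test_bidirectional_set_called_both(self):
        labels = (["up"] * 4 + ["down"] * 4 + ["none"] * 2
                  + (["up"] * 5 + ["down"] * 5 + ["none"] * 980))
        scored, genes = _scored_from_scores(np.zeros(1000), labels)
        call = ora(scored, genes[:10])
        assert call.direction == "both"
        for attr in ("p_enriched", "p_depleted"):
            # verify each 2x2 table against scipy directly
            assert getattr(call, attr) < 1e-4

    def test_zero_margin_degenerates_to_p_one(self):
        labels = ["none"] * 50
        scored, genes = _scored_from_scores(np.zeros(50), labels)
        with pytest.warns(UserWarning, match="degenerate"):
            call = ora(scored, genes[:5])
        assert call.p == 1.0
        assert call.direction == "none"


class TestUGS:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            (["up", "up", "none", "none"], "enriched"),
            (["up", "down", "none", "none"], "none"),
            (["down", "down", "down", "none"], "depleted"),
            (["up", "none", "none", "none"], "none"),  # below min_degs
        ],
    )
    def test_rule(self, labels, expected):
        scored, genes = _scored_from_scores(np.zeros(10), labels + ["none"] * 6)
        assert ugs(scored, genes[: len(labels)], min_degs=2).direction == expected

    def test_min_degs_one_flags_singletons(self):
        scored, genes = _scored_from_scores(np.zeros(6), ["up"] + ["none"] * 5)
        assert ugs(scored, genes[:3], min_degs=1).direction == "enriched"

    def test_matches_label_scan_on_simulated_data(self):
        table, coll, _ = simulate_de(
            DESimConfig(n_genes=400, n_sets=25, set_size_range=(5, 20),
                        frac_enriched_sets=0.2, frac_depleted_sets=0.2,
                        deg_rate_null=0.05, seed=31)
        )
        scored = call_degs(table)
        labels = scored["deg_label"]
        for sid, members in coll.sets.items():
            call = ugs(scored, members)
            in_labels = labels.loc[sorted(members)]
            ups = (in_labels == "up").sum()
            downs = (in_labels == "down").sum()
            expected = (
                "enriched" if ups >= 2 and downs == 0
                else "depleted" if downs >= 2 and ups == 0
                else "none"
            )
            assert call.direction == expected


class TestCombine:
    def _call(self, method, set_id, direction, p=None, **kw):
        defaults = dict(statistic=None, p=p, fdr=None, n_deg_up=0, n_deg_down=0, n_set=5)
        defaults.update(kw)
        return EnrichmentCall(set_id=set_id, method=method, direction=direction, **defaults)

    def test_ugs_alone_supports_composite(self):
        calls = {
            "UGS": [self._call("UGS", "S1", "enriched")],
            "FCS": [self._call("FCS", "S1", "enriched", p=0.9)],
            "ORA": [self._call("ORA", "S1", "none", p=1.0, p_enriched=1.0, p_depleted=1.0)],
        }
        _, composites = adjust_and_combine(calls, alpha=0.01)
        (comp,) = composites
        assert comp.enriched and not comp.depleted
        assert comp.supporting_enriched == ("UGS",)

    def test_opposite_methods_set_both_flags(self):
        calls = {
            "UGS": [self._call("UGS", "S1", "none")],
            "FCS": [self._call("FCS", "S1", "enriched", p=1e-6)],
            "ORA": [self._call("ORA", "S1", "depleted", p=1e-6,
                               p_enriched=0.9, p_depleted=1e-6)],
        }
        _, composites = adjust_and_combine(calls, alpha=0.01)
        (comp,) = composites
        assert comp.enriched and comp.depleted
        assert comp.supporting_enriched == ("FCS",)
        assert comp.supporting_depleted == ("ORA",)

    def test_bh_never_decreases_raw_p(self):
        rng = np.random.default_rng(8)
        calls = {"FCS": [
            self._call("FCS", f"S{i}", "enriched", p=float(p))
            for i, p in enumerate(rng.uniform(size=40))
        ]}
        with pytest.warns(UserWarning, match="without methods"):
            adjusted, _ = adjust_and_combine(calls, alpha=0.01)
        for call in adjusted:
            if call.fdr is not None and call.p is not None:
                assert call.fdr >= call.p - 1e-12

    def test_missing_method_warns_but_combines(self):
        calls = {"UGS": [self._call("UGS", "S1", "depleted")]}
        with pytest.warns(UserWarning, match="without methods"):
            _, composites = adjust_and_combine(calls)
        assert composites[0].depleted


def test_ugs_and_fcs_agree_on_strong_unidirectional_signal():
    """With every in-set gene a same-direction DEG, both methods call the set."""
    table, coll, truth = simulate_de(
        DESimConfig(n_genes=1500, n_sets=10, set_size_range=(15, 15),
                    frac_enriched_sets=0.2, frac_depleted_sets=0.2,
                    effect_deg_rate=1.0, effect_unidirectional=True,
                    deg_rate_null=0.02, seed=41)
    )
    scored = call_degs(table)
    calls_df, _ = run_enrichment(scored, coll.sets, n_perm=1000, seed=41)
    for sid, status in truth.planted_sets.items():
        if status == "null":
            continue
        want = "enriched" if status == "enriched" else "depleted"
        for method in ("FCS", "UGS"):
            row = calls_df[(calls_df.set_id == sid) & (calls_df.method == method)]
            assert row["direction"].iloc[0] == want, (sid, method)
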