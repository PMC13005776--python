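"""Count normalization, expressed filter, BH FDR and the response test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import zero_noise_config
from mirogtt.response import (
    CountDataError,
    CountMatrix,
    baseline_de,
    bh_fdr,
    differential_response,
    filter_expressed,
    moderate_variances,
    size_factors_median_of_ratios,
)
from mirogtt.simulate import SimulationConfig, simulate_cohort, simulate_counts


def bh_oracle(p):
    """Independent BH q-values via the step-up *decision rule*: q_i is the
    smallest candidate level at which i is rejected."""
    p = np.asarray(p, float)
    m = len(p)

    def rejected_at(alpha):
        order = np.argsort(p)
        # epsilon guards the boundary case p == alpha*k/m against fp error
        ks = [k for k in range(1, m + 1)
              if p[order[k - 1]] <= alpha * k / m + 1e-12]
        if not ks:
            return set()
        return set(order[:max(ks)])

    candidates = sorted({min(1.0, m * pj / rank) for rank, pj in
                         enumerate(np.sort(p), start=1)} | {1.0})
    q = np.empty(m)
    for i in range(m):
        q[i] = next(a for a in candidates if i in rejected_at(a))
    return q


class TestSizeFactors:
    def test_doubling_a_sample_doubles_its_factor(self, rng):
        base = rng.poisson(100, size=(30, 1)).astype(float) + 1
        counts = pd.DataFrame(np.hstack([base, 2 * base]),
                              index=[f"m{i}" for i in range(30)],
                              columns=["s1", "s2"])
        sf = size_factors_median_of_ratios(counts)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)

    def test_identical_samples_give_equal_factors(self):
        col = np.array([10.0, 20, 30, 40])
        counts = pd.DataFrame({f"s{i}": col for i in range(4)})
        sf = size_factors_median_of_ratios(counts)
        assert sf.nunique() == 1

    def test_scaling_one_sample_scales_only_its_relative_factor(self, rng):
        # scaling a sample moves the per-miRNA geometric means too, so
        # absolute factors are defined up to scale: the invariant is that
        # the scaled sample's factor grows 10x *relative* to every other
        # sample, whose pairwise ratios are untouched
        counts = pd.DataFrame(
            rng.negative_binomial(20, 0.2, size=(100, 6)) + 1,
            columns=[f"s{i}" for i in range(6)])
        sf = size_factors_median_of_ratios(counts)
        scaled = counts.copy()
        scaled["s3"] *= 10
        sf2 = size_factors_median_of_ratios(scaled)
        others = ["s0", "s1", "s2", "s4", "s5"]
        for c in others:
            assert sf2["s3"] / sf2[c] == pytest.approx(10 * sf["s3"] / sf[c])
        for a in others:
            for b in others:
                assert sf2[a] / sf2[b] == pytest.approx(sf[a] / sf[b])

    def test_no_all_positive_mirna_requires_pseudo_reference(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]},
                              index=["a", "b"]).astype(float)
        with pytest.raises(CountDataError, match="pseudo_reference"):
            size_factors_median_of_ratios(counts)
        sf = size_factors_median_of_ratios(counts, pseudo_reference=True)
        assert (sf > 0).all()


class TestExpressedFilter:
    @pytest.mark.parametrize("values, retained", [
        ((6, 6, 1, 1), True),    # exactly 50% above 5 -> kept (inclusive)
        ((6, 1, 1, 1), False),   # 25%
        ((5, 5, 5, 5), False),   # "more than five" is strict
        ((5.01, 5.01, 1, 1), True),
    ])
    def test_boundary(self, values, retained):
        norm = pd.DataFrame([values], index=["m"],
                            columns=[f"s{i}" for i in range(4)])
        kept = filter_expressed(norm)
        assert ("m" in kept) is retained


class TestBhFdr:
    def test_worked_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert (bh_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    def test_against_decision_rule_oracle(self, rng):
        for _ in range(25):
            m = rng.integers(1, 7)
            p = np.round(rng.uniform(0, 1, m), 3)
            assert np.allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_against_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 50)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_fdr(p), q_ref)

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(0, 1, 40)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


def paired_cm(counts_by_participant, groups):
    """counts_by_participant: {pid: (baseline col, sixty col)} arrays."""
    cols, data, meta = [], [], []
    for pid, (c0, c60) in counts_by_participant.items():
        for tp, col in ((-1, c0), (60, c60)):
            sid = f"{pid}_t{tp}"
            cols.append(sid)
            data.append(np.asarray(col, float))
            meta.append({"sample_id": sid, "participant_id": pid,
                         "timepoint_min": tp, "group": groups[pid]})
    counts = pd.DataFrame(np.column_stack(data),
                          index=[f"m{i}" for i in range(len(data[0]))],
                          columns=cols)
    return CountMatrix(counts, pd.DataFrame(meta).set_index("sample_id"))


class TestDifferentialResponse:
    def test_interaction_effect_equals_difference_of_differences(self):
        # 2x2-participant toy: the effect must equal the exhaustive
        # difference-of-differences of log2 normalized counts
        cm = paired_cm(
            {"n1": ([100, 50], [100, 50]), "n2": ([80, 40], [80, 40]),
             "c1": ([100, 50], [400, 50]), "c2": ([80, 40], [320, 40])},
            {"n1": "NGT", "n2": "NGT", "c1": "CFRD", "c2": "CFRD"},
        )
        res = differential_response(cm, "CFRD", expressed_only=False,
                                    pseudocount=0.5)
        norm = cm.normalized()
        manual = []
        for pid in ("n1", "n2", "c1", "c2"):
            r = np.log2((norm[f"{pid}_t60"] + 0.5) / (norm[f"{pid}_t-1"] + 0.5))
            manual.append(r)
        n1, n2, c1, c2 = manual
        expected = ((c1 + c2) / 2 - (n1 + n2) / 2)
        got = res.set_index("mirna")["interaction_effect"]
        for m in norm.index:
            assert got[m] == pytest.approx(expected[m], abs=1e-12)

    def test_identical_responses_give_zero_effect_and_p_one(self):
        cm = paired_cm(
            {"n1": ([100], [200]), "n2": ([50], [100]),
             "c1": ([100], [200]), "c2": ([50], [100])},
            {"n1": "NGT", "n2": "NGT", "c1": "CFRD", "c2": "CFRD"},
        )
        res = differential_response(cm, "CFRD", expressed_only=False)
        assert res["interaction_effect"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert res["z"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_swapping_timepoint_labels_negates_effects(self):
        cfg = SimulationConfig(
            seed=17, n_per_group={"NGT": 3, "INDET": 0, "IGT": 0, "CFRD": 3},
            response_log2fc={("miR-223-3p", "CFRD"): 1.0})
        participants, _ = simulate_cohort(cfg)
        counts, meta, _ = simulate_counts(participants, cfg)
        cm = CountMatrix(counts, meta)
        fwd = differential_response(cm, "CFRD").set_index("mirna")
        meta_sw = meta.copy()
        meta_sw["timepoint_min"] = meta_sw["timepoint_min"].map({-1: 60, 60: -1})
        rev = differential_response(CountMatrix(counts, meta_sw),
                                    "CFRD").set_index("mirna")
        common = fwd.index
        assert np.allclose(fwd.loc[common, "interaction_effect"],
                           -rev.loc[common, "interaction_effect"])
        assert np.allclose(fwd.loc[common, "p"], rev.loc[common, "p"])

    def test_unpaired_participant_rejected(self):
        cm_data = {"n1": ([10], [10]), "n2": ([10], [10]),
                   "c1": ([10], [10]), "c2": ([10], [10])}
        cm = paired_cm(cm_data, {"n1": "NGT", "n2": "NGT",
                                 "c1": "CFRD", "c2": "CFRD"})
        broken_meta = cm.meta.drop("c1_t60")
        broken = cm.counts.drop(columns="c1_t60")
        with pytest.raises(CountDataError, match="pair"):
            differential_response(CountMatrix(broken, broken_meta), "CFRD")

    def test_single_participant_group_refused(self):
        cm = paired_cm({"n1": ([10], [10]), "n2": ([10], [10]),
                        "c1": ([10], [10])},
                       {"n1": "NGT", "n2": "NGT", "c1": "CFRD"})
        with pytest.raises(CountDataError, match=">=2"):
            differential_response(cm, "CFRD")

    def test_injected_interaction_top_ranked(self):
        cfg = SimulationConfig(
            seed=0, n_per_group={"NGT": 3, "INDET": 0, "IGT": 0, "CFRD": 3},
            baseline_log2fc={}, analyte_coupling={},
            response_log2fc={("miR-223-3p", "CFRD"): 2.0},
            nb_dispersion=0.01)
        hits = 0
        for seed in range(1, 21):
            rng = np.random.default_rng(seed)
            participants, _ = simulate_cohort(cfg, rng)
            counts, meta, _ = simulate_counts(participants, cfg, rng)
            res = differential_response(CountMatrix(counts, meta), "CFRD")
            top = res.assign(a=res["z"].abs()).nlargest(1, "a")["mirna"].iloc[0]
            hits += top == "miR-223-3p"
        assert hits >= 18

    def test_shuffled_pairing_inflates_null_variance(self):
        # destroying the within-participant pairing couples unrelated
        # library/participant factors into the ratio, inflating its spread
        cfg = zero_noise_config(
            n_per_group={"NGT": 10, "INDET": 0, "IGT": 0, "CFRD": 10},
            participant_sd_log2=1.0, nb_dispersion=0.01, seed=23)
        participants, _ = simulate_cohort(cfg)
        counts, meta, _ = simulate_counts(participants, cfg)
        from mirogtt.response import _paired_log_ratios

        cm = CountMatrix(counts, meta)
        paired = _paired_log_ratios(cm, 0.5)
        meta_sh = meta.copy()
        base_rows = meta_sh["timepoint_min"] == -1
        rng = np.random.default_rng(5)
        meta_sh.loc[base_rows, "participant_id"] = rng.permutation(
            meta_sh.loc[base_rows, "participant_id"].to_numpy())
        shuffled = _paired_log_ratios(CountMatrix(counts, meta_sh), 0.5)
        assert (shuffled.var(axis=1).median()
                > 2 * paired.var(axis=1).median())


class TestBaselineDe:
    def test_identical_groups_give_zero_effects(self):
        cm = paired_cm({"n1": ([10, 100], [10, 100]),
                        "n2": ([10, 100], [10, 100]),
                        "c1": ([10, 100], [10, 100]),
                        "c2": ([10, 100], [10, 100])},
                       {"n1": "NGT", "n2": "NGT",
                        "c1": "CFRD", "c2": "CFRD"})
        res = baseline_de(cm, "NGT", "CFRD", expressed_only=False)
        assert np.allclose(res["log2fc"], 0.0)

    def test_injected_baseline_shift_ranks_first(self):
        # unpaired baseline comparison: both the NB dispersion and the
        # between-participant spread must be low for n=3 to rank the
        # injected 2-fold shift first among 200 nulls
        cfg = SimulationConfig(
            seed=0, n_per_group={"NGT": 3, "INDET": 3, "IGT": 0, "CFRD": 0},
            baseline_log2fc={("miR-122-5p", "INDET"): 1.0},
            response_log2fc={}, analyte_coupling={}, nb_dispersion=0.005,
            participant_sd_log2=0.1)
        hits = 0
        for seed in range(1, 21):
            rng = np.random.default_rng(seed)
            participants, _ = simulate_cohort(cfg, rng)
            counts, meta, _ = simulate_counts(participants, cfg, rng)
            res = baseline_de(CountMatrix(counts, meta), "NGT", "INDET")
            if res["mirna"].iloc[0] == "miR-122-5p":
                hits += 1
                assert res["log2fc"].iloc[0] == pytest.approx(1.0, abs=0.5)
        assert hits >= 18

    def test_library_size_invariance(self):
        cm = paired_cm({"n1": ([10, 100], [10, 100]),
                        "n2": ([12, 110], [12, 110]),
                        "c1": ([40, 100], [40, 100]),
                        "c2": ([44, 108], [44, 108])},
                       {"n1": "NGT", "n2": "NGT",
                        "c1": "CFRD", "c2": "CFRD"})
        doubled = cm.counts.copy().astype(float)
        cfrd_cols = [c for c in doubled.columns if c.startswith("c")]
        doubled[cfrd_cols] *= 2
        # size-factor normalization cancels a per-group library rescaling
        # exactly on the count scale; with pseudocount 0 the invariance is
        # exact, with the default 0.5 it holds to the pseudocount's order
        res0 = baseline_de(cm, "NGT", "CFRD", expressed_only=False,
                           pseudocount=0.0)
        res0d = baseline_de(CountMatrix(doubled, cm.meta), "NGT", "CFRD",
                            expressed_only=False, pseudocount=0.0)
        assert np.allclose(res0["log2fc"], res0d["log2fc"], atol=1e-9)
        assert np.allclose(res0["p"], res0d["p"], atol=1e-9)
        res = baseline_de(cm, "NGT", "CFRD", expressed_only=False)
        resd = baseline_de(CountMatrix(doubled, cm.meta), "NGT", "CFRD",
                           expressed_only=False)
        assert np.allclose(res["log2fc"], resd["log2fc"], atol=0.05)


class TestModeratedVariance:
    def test_shrinks_toward_common_value(self, rng):
        s2 = rng.chisquare(4, 300) / 4 * 0.25  # true variance 0.25, 4 df
        mod, d0, s0 = moderate_variances(s2, 4)
        assert s0 == pytest.approx(0.25, rel=0.3)
        assert mod.var() < s2.var()
        assert (mod > 0).all()

    def test_zero_variances_receive_prior(self, rng):
        s2 = np.concatenate([rng.chisquare(4, 100) / 4, [0.0, 0.0]])
        mod, _, _ = moderate_variances(s2, 4)
        assert (mod[-2:] > 0).all()
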