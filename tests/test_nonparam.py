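"""Nonparametric condition comparisons against textbook/hand-computed values."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from avspan.nonparam import (
    PipelineError,
    cluster_noise_sensitivity,
    kruskal_wallis,
    posthoc_matrix,
    subgroup_contrasts,
    wilcoxon_paired,
)

CONDS = ["C_1-NoSupp", "C_2-VisRhythmSupp", "C_3-AudSupp", "C_4-AVRhythmSupp"]


def toy_dataset(values_by_condition):
    rows = []
    for cond, values in values_by_condition.items():
        for i, v in enumerate(values):
            rows.append({"participant": f"p{i}", "sequence_id": i + 1,
                         "condition": cond, "score": float(v)})
    return pd.DataFrame(rows)


class TestKruskalWallis:
    def test_identical_groups(self):
        data = toy_dataset({c: [1, 1, 1] for c in CONDS})
        res = kruskal_wallis(data, "score")
        assert res.statistic == 0.0
        assert res.p == 1.0
        assert res.warning is not None

    def test_matches_hand_computed_ranks(self):
        # 3 observations x 4 groups, no ties: H has a closed form from ranks
        groups = {CONDS[0]: [1, 2, 3], CONDS[1]: [4, 5, 6],
                  CONDS[2]: [7, 8, 9], CONDS[3]: [10, 11, 12]}
        data = toy_dataset(groups)
        res = kruskal_wallis(data, "score")
        n = 12
        rank_sums = [6, 15, 24, 33]  # ranks 1..12 in blocks of three
        h = 12 / (n * (n + 1)) * sum(r**2 / 3 for r in rank_sums) - 3 * (n + 1)
        assert res.statistic == pytest.approx(h)
        assert res.p == pytest.approx(stats.chi2.sf(h, 3))

    def test_detects_planted_shift(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(40):
            data = toy_dataset({
                c: rng.normal(0.6 if c in CONDS[2:] else 0.4, 0.15, 40)
                for c in CONDS
            })
            if kruskal_wallis(data, "score").p < 0.05:
                hits += 1
        assert hits >= 36


class TestWilcoxon:
    def test_identical_pairs_degenerate(self):
        data = toy_dataset({CONDS[0]: [1, 2, 3, 4], CONDS[2]: [1, 2, 3, 4]})
        res = wilcoxon_paired(data, "score", CONDS[0], CONDS[2])
        assert res.p == 1.0
        assert res.warning is not None

    def test_matches_exact_enumeration(self):
        # pairs (1,2),(2,4),(3,6),(5,6): diffs -1,-2,-3,-1 -> W+ = 0
        data = toy_dataset({CONDS[0]: [1, 2, 3, 5], CONDS[2]: [2, 4, 6, 6]})
        res = wilcoxon_paired(data, "score", CONDS[0], CONDS[2])
        diffs = np.array([-1.0, -2.0, -3.0, -1.0])
        # exhaustive null: all sign assignments of |diffs| ranks
        ranks = stats.rankdata(np.abs(diffs))
        w_obs = ranks[diffs > 0].sum()
        dist = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=4)
        ]
        # two-sided exact p: P(W+ <= w) + P(W+ >= W_max - w)
        w_max = ranks.sum()
        p_exact = (
            sum(w <= w_obs for w in dist) + sum(w >= w_max - w_obs for w in dist)
        ) / len(dist)
        assert res.p == pytest.approx(min(1.0, p_exact))

    def test_no_pairs_error(self):
        data = toy_dataset({CONDS[0]: [1, 2]})
        with pytest.raises(PipelineError):
            wilcoxon_paired(data, "score", CONDS[0], CONDS[2])


class TestPosthoc:
    def make_data(self, rng):
        rows = []
        for p in range(10):
            for s in range(10):
                for c in CONDS:
                    mu = 0.6 if c in CONDS[2:] else 0.45
                    rows.append({"participant": p, "sequence_id": s,
                                 "condition": c, "score": rng.normal(mu, 0.1)})
        return pd.DataFrame(rows)

    def test_six_pairs_and_symmetry(self):
        data = self.make_data(np.random.default_rng(2))
        mat = posthoc_matrix(data, "score")
        assert len(mat) == 6
        a = wilcoxon_paired(data, "score", CONDS[0], CONDS[2])
        b = wilcoxon_paired(data, "score", CONDS[2], CONDS[0])
        assert a.p == pytest.approx(b.p)

    def test_null_type_one_error(self):
        rng = np.random.default_rng(3)
        sig = total = 0
        for _ in range(40):
            rows = []
            for p in range(12):
                for s in range(10):
                    for c in CONDS:
                        rows.append({"participant": p, "sequence_id": s,
                                     "condition": c, "score": rng.normal(0, 1)})
            mat = posthoc_matrix(pd.DataFrame(rows), "score")
            sig += (mat["p"] < 0.05).sum()
            total += len(mat)
        rate = sig / total
        # 240 tests at alpha = .05 -> binomial CI around 0.05
        assert 0.01 <= rate <= 0.10

    def test_holm_adjustment_monotone(self):
        data = self.make_data(np.random.default_rng(4))
        mat = posthoc_matrix(data, "score", holm=True)
        assert (mat["p_holm"] >= mat["p"] - 1e-12).all()


class TestSubgroups:
    def make_data(self, rng, moderated):
        rows = []
        for p in range(16):
            support = p < 8  # half report support
            for s in range(10):
                for c in CONDS:
                    audio = c in CONDS[2:]
                    mu = 0.45
                    if audio and (support or not moderated):
                        mu += 0.2
                    rows.append({
                        "participant": p, "sequence_id": s, "condition": c,
                        "score": rng.normal(mu, 0.1),
                        "PercSoundSupport": 4 if support else 1,
                    })
        return pd.DataFrame(rows)

    def test_planted_moderation(self):
        data = self.make_data(np.random.default_rng(5), moderated=True)
        res = subgroup_contrasts(data, "score", "PercSoundSupport", "midpoint")
        audio_contrast = res[
            (res["condition_a"] == CONDS[0]) & (res["condition_b"] == CONDS[2])
        ].set_index("subgroup")["p"]
        assert audio_contrast["high"] < 0.05  # "supporting" subgroup benefits
        assert audio_contrast["low"] > 0.05  # "disturbing" subgroup does not

    def test_null_split_agrees_in_direction(self):
        data = self.make_data(np.random.default_rng(6), moderated=False)
        res = subgroup_contrasts(data, "score", "PercSoundSupport", "midpoint")
        both = res[
            (res["condition_a"] == CONDS[0]) & (res["condition_b"] == CONDS[2])
        ]
        assert (both.set_index("subgroup")["p"].loc[["low", "high"]] < 0.05).all()

    def test_degenerate_subgroup_flagged(self):
        data = self.make_data(np.random.default_rng(7), moderated=False)
        data["PercSoundSupport"] = 5  # everyone "high"
        with pytest.warns(UserWarning, match="skipped"):
            res = subgroup_contrasts(data, "score", "PercSoundSupport", "midpoint")
        assert (res[res["subgroup"] == "low"]["method"] == "skipped").all()


class TestNoiseSensitivity:
    def test_separated_groups_recovered(self):
        rng = np.random.default_rng(8)
        low = rng.normal(2, 0.5, size=(10, 5))
        high = rng.normal(8, 0.5, size=(10, 5))
        items = pd.DataFrame(np.vstack([low, high]),
                             index=[f"p{i}" for i in range(20)])
        labels = cluster_noise_sensitivity(items, rng_seed=0)
        assert (labels.iloc[:10] == "tolerant").all()
        assert (labels.iloc[10:] == "sensitive").all()

    def test_identical_responses_rejected(self):
        items = pd.DataFrame(np.full((5, 5), 3.0))
        with pytest.raises(PipelineError):
            cluster_noise_sensitivity(items)

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        items = pd.DataFrame(
            np.vstack([rng.normal(2, 0.5, (8, 5)), rng.normal(8, 0.5, (8, 5))]),
            index=[f"p{i}" for i in range(16)],
        )
        a = cluster_noise_sensitivity(items, rng_seed=0)
        b = cluster_noise_sensitivity(items.sample(frac=1.0, random_state=1), rng_seed=0)
        assert (a.sort_index() == b.sort_index()).all()
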