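"""Nonparametric condition-level analysis of the outcome scores.

Kruskal-Wallis serves as the omnibus test across the four conditions;
pairwise post-hoc comparisons use the Wilcoxon signed-rank test, pairing
observations on (participant, sequence) since every sequence is measured in
every condition.  Subgroup contrasts split participants on a questionnaire
covariate and compare conditions within, and subgroups against each other
with unpaired rank-sum tests.  Raw p-values are reported by default; Holm
adjustment is available as a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .design import CONDITIONS

SCORES = ("per_digit", "levenshtein", "distraction")


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    n: int
    method: str
    warning: str | None = None


def kruskal_wallis(dataset: pd.DataFrame, score: str) -> TestResult:
    """Tie-corrected Kruskal-Wallis H across conditions at trial level."""
    groups = [g[score].to_numpy(float) for _, g in dataset.groupby("condition")]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise PipelineError("need at least two non-empty conditions")
    values = np.concatenate(groups)
    if np.all(values == values[0]):
        return TestResult(0.0, 1.0, len(values), "kruskal-wallis",
                          warning="all values identical")
    h, p = stats.kruskal(*groups)
    return TestResult(float(h), float(p), len(values), "kruskal-wallis")


def _paired_values(
    dataset: pd.DataFrame, score: str, condition_a: str, condition_b: str
) -> tuple[np.ndarray, np.ndarray]:
    sub = dataset[dataset["condition"].isin([condition_a, condition_b])]
    wide = sub.pivot_table(
        index=["participant", "sequence_id"],
        columns="condition",
        values=score,
        aggfunc="mean",
    ).dropna()
    if wide.empty or condition_a not in wide.columns or condition_b not in wide.columns:
        raise PipelineError(
            f"no complete (participant, sequence) pairs for "
            f"{condition_a} vs {condition_b}"
        )
    return wide[condition_a].to_numpy(float), wide[condition_b].to_numpy(float)


def wilcoxon_paired(
    dataset: pd.DataFrame,
    score: str,
    condition_a: str,
    condition_b: str,
    *,
    zero_method: str = "wilcox",
) -> TestResult:
    """Signed-rank test on (participant, sequence)-paired condition scores.

    Zero differences are dropped (classic Wilcoxon); the exact null
    distribution is used for small samples (n <= 25), a tie-corrected
    normal approximation otherwise.
    """
    a, b = _paired_values(dataset, score, condition_a, condition_b)
    diffs = a - b
    nz = diffs[diffs != 0]
    if len(nz) == 0:
        return TestResult(0.0, 1.0, len(a), "wilcoxon",
                          warning="all paired differences are zero")
    method = "exact" if len(nz) <= 25 else "approx"
    res = stats.wilcoxon(a, b, zero_method=zero_method, method=method)
    return TestResult(float(res.statistic), float(res.pvalue), len(a), "wilcoxon")


def posthoc_matrix(
    dataset: pd.DataFrame, score: str, *, holm: bool = False
) -> pd.DataFrame:
    """All six pairwise condition comparisons as a tidy table."""
    codes = [c.code for c in CONDITIONS if c.code in set(dataset["condition"])]
    rows = []
    for a, b in combinations(codes, 2):
        r = wilcoxon_paired(dataset, score, a, b)
        rows.append({"score": score, "condition_a": a, "condition_b": b,
                     "statistic": r.statistic, "p": r.p, "n": r.n})
    out = pd.DataFrame(rows)
    if holm and len(out):
        order = np.argsort(out["p"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p"].iloc[idx])
            adj[idx] = min(running, 1.0)
        out["p_holm"] = adj
    return out


# preset dichotomizations for the questionnaire scales (0..5 six-point scales)
SPLIT_RULES: dict[str, Callable[[pd.Series], pd.Series]] = {
    # disturbing (below midpoint) vs supporting (at or above)
    "midpoint": lambda s: np.where(s.astype(float) >= 2.5, "high", "low"),
    # easy/medium vs hard at the upper third of the six-point scale
    "upper_third": lambda s: np.where(s.astype(float) >= 4, "high", "low"),
    "binary": lambda s: np.where(s.astype(bool), "high", "low"),
}


def subgroup_contrasts(
    dataset: pd.DataFrame,
    score: str,
    split_covariate: str,
    split_rule: str | Callable[[pd.Series], pd.Series] = "midpoint",
) -> pd.DataFrame:
    """Condition contrasts within covariate subgroups plus between-subgroup tests.

    The split rule maps covariate values to the labels ``low``/``high``.
    Within each subgroup the full paired post-hoc matrix is computed; in
    addition each condition is compared between subgroups with an unpaired
    rank-sum (Mann-Whitney U) test.  Degenerate subgroups (< 2 participants)
    are flagged and skipped.
    """
    if split_covariate not in dataset.columns:
        raise PipelineError(f"covariate {split_covariate!r} not in dataset")
    rule = SPLIT_RULES[split_rule] if isinstance(split_rule, str) else split_rule
    labels = pd.Series(rule(dataset[split_covariate]), index=dataset.index)
    rows = []
    for lab in ("low", "high"):
        sub = dataset[labels == lab]
        n_part = sub["participant"].nunique()
        if n_part < 2:
            warnings.warn(
                f"subgroup {split_covariate}={lab} has {n_part} participant(s); skipped"
            )
            rows.append({"score": score, "subgroup": lab, "condition_a": None,
                         "condition_b": None, "statistic": np.nan, "p": np.nan,
                         "n": n_part, "method": "skipped"})
            continue
        mat = posthoc_matrix(sub, score)
        for _, r in mat.iterrows():
            rows.append({"score": score, "subgroup": lab,
                         "condition_a": r["condition_a"],
                         "condition_b": r["condition_b"],
                         "statistic": r["statistic"], "p": r["p"], "n": r["n"],
                         "method": "wilcoxon"})
    low, high = dataset[labels == "low"], dataset[labels == "high"]
    if low["participant"].nunique() >= 2 and high["participant"].nunique() >= 2:
        for code in sorted(set(dataset["condition"])):
            x = low[low["condition"] == code][score].to_numpy(float)
            y = high[high["condition"] == code][score].to_numpy(float)
            u, p = stats.mannwhitneyu(x, y, alternative="two-sided")
            rows.append({"score": score, "subgroup": "low-vs-high",
                         "condition_a": code, "condition_b": code,
                         "statistic": float(u), "p": float(p),
                         "n": len(x) + len(y), "method": "mann-whitney"})
    return pd.DataFrame(rows)


def cluster_noise_sensitivity(
    items: pd.DataFrame, rng_seed: int = 0, n_restarts: int = 20
) -> pd.Series:
    """2-means on the five noise-sensitivity item responses (0-10 scale).

    Returns a participant-indexed series of ``tolerant``/``sensitive``
    labels; the cluster with the higher mean item score is ``sensitive``.
    """
    X = items.to_numpy(float)
    if len(X) < 2 or len(np.unique(X, axis=0)) < 2:
        raise PipelineError("noise-sensitivity clustering needs >= 2 distinct profiles")
    km = KMeans(n_clusters=2, n_init=n_restarts,
                random_state=int(rng_seed) % (2**31), algorithm="lloyd").fit(X)
    sensitive = int(np.argmax(km.cluster_centers_.mean(axis=1)))
    labels = np.where(km.labels_ == sensitive, "sensitive", "tolerant")
    return pd.Series(labels, index=items.index, name="NoiseSensitivity")


def analyze_conditions(dataset: pd.DataFrame, scores: Sequence[str] = SCORES) -> dict:
    """Omnibus + post-hoc summary for each outcome score."""
    out = {}
    for score in scores:
        out[score] = {
            "kruskal_wallis": kruskal_wallis(dataset, score),
            "posthoc": posthoc_matrix(dataset, score),
        }
    return out


def report_text(results: dict) -> str:
    """Human-readable summary mirroring the condition-comparison structure."""
    lines = []
    for score, res in results.items():
        kw = res["kruskal_wallis"]
        lines.append(f"{score}: Kruskal-Wallis H = {kw.statistic:.3f}, "
                     f"p = {kw.p:.3g} (n = {kw.n})")
        for _, r in res["posthoc"].iterrows():
            lines.append(f"  {r['condition_a']} vs {r['condition_b']}: "
                         f"W = {r['statistic']:.1f}, p = {r['p']:.3g}")
    return "\n".join(lines)
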