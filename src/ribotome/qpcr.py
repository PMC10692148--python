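"""ddCT qPCR quantification of IP-versus-total enrichment.

For each biological pair the target's Ct is normalized against the
arithmetic mean Ct of the reference transcripts (equivalent to the
geometric mean of their expression), separately in the IP and the total
sample; the fold-of-total enrichment is 2^-(dCt_IP - dCt_total).
Technical replicates are averaged on the Ct scale first.  Group
comparisons use the two-tailed Mann-Whitney U test with an exact
small-sample p-value.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .counts import IP_FRACTION, TOTAL_FRACTION

EXACT_LIMIT = 400   # exact Mann-Whitney enumeration while n1 * n2 <= this


class UndetectedError(ValueError):
    """A required well is undetected; the fold is not computable."""


def _mean_ct(plate: pd.DataFrame, sample_id: str, target: str) -> float:
    wells = plate[(plate["sample_id"] == sample_id)
                  & (plate["target"] == target)]
    if wells.empty:
        raise KeyError(f"no wells for target {target!r} in sample {sample_id!r}")
    if "undetected" in wells.columns and wells["undetected"].any():
        raise UndetectedError(
            f"target {target!r} undetected in sample {sample_id!r}")
    return float(wells["ct"].mean())


def ddct_fold(plate: pd.DataFrame, target: str, refs: Sequence[str],
              pair_id: str) -> float:
    """Fold-of-total for one target in one IP/total pair.

    dCt = Ct_target - mean(Ct_refs) per sample;
    ddCt = dCt_IP - dCt_total; fold = 2^-ddCt.
    """
    pair = plate[plate["pair_id"] == pair_id]
    samples: Dict[str, str] = {}
    for fraction in (IP_FRACTION, TOTAL_FRACTION):
        ids = pair.loc[pair["fraction"] == fraction, "sample_id"].unique()
        if len(ids) != 1:
            raise ValueError(f"pair {pair_id!r} needs exactly one {fraction} "
                             f"sample, found {len(ids)}")
        samples[fraction] = ids[0]
    dct = {}
    for fraction, sid in samples.items():
        ref_ct = np.mean([_mean_ct(plate, sid, r) for r in refs])
        dct[fraction] = _mean_ct(plate, sid, target) - ref_ct
    ddct = dct[IP_FRACTION] - dct[TOTAL_FRACTION]
    return float(2.0 ** (-ddct))


def fold_change_table(plate: pd.DataFrame, targets: Sequence[str],
                      refs: Sequence[str]) -> pd.DataFrame:
    """Per (pair, target) fold plus per (condition, target) mean and sd.

    Pairs with undetected required wells get a missing fold and a reason.
    """
    meta = (plate[["pair_id", "condition"]].drop_duplicates()
            .set_index("pair_id")["condition"])
    rows = []
    for pair_id in meta.index:
        for target in targets:
            try:
                fold = ddct_fold(plate, target, refs, pair_id)
                reason = ""
            except UndetectedError as exc:
                fold, reason = np.nan, str(exc)
            rows.append({"pair_id": pair_id, "condition": meta[pair_id],
                         "target": target, "fold": fold, "reason": reason})
    per_pair = pd.DataFrame(rows)
    summary = (per_pair.groupby(["condition", "target"], sort=False)["fold"]
               .agg(mean="mean", sd="std", n="count").reset_index())
    return per_pair.merge(summary, on=["condition", "target"], how="left")


def _rank_sum_distribution(double_ranks: np.ndarray, n1: int) -> Dict[int, float]:
    """Exact null distribution of the group-1 doubled-rank sum over all
    choices of n1 pooled observations, by subset-sum dynamic programming.

    Mid-ranks are doubled so ties produce integer sums; counts stay exact
    in float64 up to C(40, 20).
    """
    total = int(double_ranks.sum())
    # dp[k][s] = number of size-k subsets with doubled-rank sum s
    dp = [np.zeros(total + 1) for _ in range(n1 + 1)]
    dp[0][0] = 1.0
    for r in double_ranks:
        r = int(r)
        for k in range(min(n1, len(double_ranks)), 0, -1):
            dp[k][r:] += dp[k - 1][: total + 1 - r]
    n_total = comb(len(double_ranks), n1)
    return {s: dp[n1][s] / n_total
            for s in range(total + 1) if dp[n1][s] > 0}


def mann_whitney_two_sided(x: Sequence[float], y: Sequence[float]) -> dict:
    """Two-tailed Mann-Whitney U test.

    Exact permutation p over the observed data (mid-ranks, so ties are
    handled by enumeration of the realized pooled sample) while
    n1 * n2 <= 400; the tie-corrected normal approximation otherwise.
    The two-sided p is 2 * min(P(U <= u), P(U >= u)), capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("each group needs at least one observation")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)          # mid-ranks
    u_stat = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if n1 * n2 <= EXACT_LIMIT:
        double_ranks = np.rint(2.0 * ranks).astype(int)
        dist = _rank_sum_distribution(double_ranks, n1)
        obs = int(round(2.0 * ranks[:n1].sum()))
        p_le = sum(p for s, p in dist.items() if s <= obs)
        p_ge = sum(p for s, p in dist.items() if s >= obs)
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
        p = float(res.pvalue)
    return {"U": u_stat, "p": float(p), "n1": n1, "n2": n2}


def enumerate_mann_whitney(x: Sequence[float], y: Sequence[float]) -> float:
    """Brute-force two-sided exact p by explicit enumeration of all
    C(n1+n2, n1) group assignments of the pooled observed values.

    Independent oracle for the DP route; only usable for tiny samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    obs = ranks[:n1].sum()
    sums = np.array([ranks[list(c)].sum()
                     for c in combinations(range(len(pooled)), n1)])
    p_le = np.mean(sums <= obs + 1e-9)
    p_ge = np.mean(sums >= obs - 1e-9)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))
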