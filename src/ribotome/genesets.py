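"""Gene-set overlap statistics.

Two flavours are provided: the exact hypergeometric overlap test with the
representation factor (observed / expected-by-chance overlap), used for
cell-type marker contamination panels, and a resampling z-score that
compares an observed operon overlap against random same-size draws from
the expressed universe, with the analytic hypergeometric moments reported
alongside as a sanity anchor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .counts import bh_adjust


@dataclass
class OverlapResult:
    k: int                      # observed overlap
    n1: int
    n2: int
    N: int                      # universe size
    expected: float             # n1 * n2 / N
    representation_factor: float
    p_hyper: float              # upper-tail P(X >= k)
    n_dropped: int = 0          # list members outside the universe


@dataclass
class OperonZResult:
    operon_id: str
    k_observed: int
    null_mean: float
    null_sd: float              # sample sd over R resamples (R - 1)
    null_sd_population: float
    z: float
    n_resamples: int
    seed: int
    analytic_mean: float
    analytic_sd: float


def hypergeom_overlap(list1: Sequence[str], list2: Sequence[str],
                      universe: Sequence[str]) -> OverlapResult:
    """Exact upper-tail hypergeometric overlap test.

    Members outside the universe are dropped with a warning count.
    Representation factor is k / (n1 n2 / N); 1 means chance-level overlap.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    s1, s2 = set(list1), set(list2)
    dropped = len(s1 - uni) + len(s2 - uni)
    if dropped:
        warnings.warn(f"{dropped} gene(s) outside the universe dropped",
                      stacklevel=2)
    s1 &= uni
    s2 &= uni
    N, n1, n2 = len(uni), len(s1), len(s2)
    k = len(s1 & s2)
    expected = n1 * n2 / N
    rf = k / expected if expected > 0 else float("nan")
    p = float(stats.hypergeom.sf(k - 1, N, n1, n2))
    return OverlapResult(k=k, n1=n1, n2=n2, N=N, expected=expected,
                         representation_factor=rf, p_hyper=p,
                         n_dropped=dropped)


def analytic_overlap_moments(n: int, K: int, N: int) -> tuple[float, float]:
    """Mean and sd of the overlap of a uniform size-n draw with a fixed
    K-subset of an N universe (hypergeometric moments)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K, n <= N")
    if N == 0:
        return 0.0, 0.0
    mean = n * K / N
    if N == 1:
        return mean, 0.0
    var = n * K * (N - K) * (N - n) / (N ** 2 * (N - 1))
    return mean, float(np.sqrt(var))


def operon_zscore(query_set: Sequence[str], operon_set: Sequence[str],
                  expressed_universe: Sequence[str], R: int = 10,
                  seed: int = 0, operon_id: str = "operon") -> OperonZResult:
    """Overlap z-score of a query list versus random expressed gene sets.

    Draws ``R`` uniform subsets of the expressed universe matching the
    query size and scores the observed operon overlap against their mean
    and sample standard deviation.  R=10 follows common practice but is
    statistically fragile, hence the warning below and the analytic
    hypergeometric moments reported alongside.
    """
    if R < 2:
        raise ValueError("R must be >= 2 (sample sd undefined)")
    if R < 100:
        warnings.warn(f"R={R} resamples give a noisy null sd; analytic "
                      "moments are reported alongside", stacklevel=2)
    universe = np.asarray(sorted(set(expressed_universe)))
    query = set(query_set) & set(universe)
    if len(query) > len(universe):
        raise ValueError("query larger than expressed universe")
    operon = set(operon_set) & set(universe)
    k_obs = len(query & operon)

    rng = np.random.default_rng(seed)
    n = len(query)
    overlaps = np.empty(R)
    for i in range(R):
        draw = rng.choice(universe, size=n, replace=False)
        overlaps[i] = len(set(draw) & operon)
    null_mean = float(overlaps.mean())
    null_sd = float(overlaps.std(ddof=1))
    null_sd_pop = float(overlaps.std(ddof=0))
    z = (k_obs - null_mean) / null_sd if null_sd > 0 else float("nan")
    a_mean, a_sd = analytic_overlap_moments(n, len(operon), len(universe))
    return OperonZResult(operon_id=operon_id, k_observed=k_obs,
                         null_mean=null_mean, null_sd=null_sd,
                         null_sd_population=null_sd_pop, z=z, n_resamples=R,
                         seed=seed, analytic_mean=a_mean, analytic_sd=a_sd)


def operon_panel(query_set: Sequence[str], operon_sets: Mapping[str, List[str]],
                 expressed_universe: Sequence[str], R: int = 10,
                 seed: int = 0) -> pd.DataFrame:
    """Run operon_zscore for every operon; one row per operon."""
    rows = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(operon_sets))
    for (name, members), child in zip(operon_sets.items(), children):
        child_seed = int(child.generate_state(1)[0] % (2 ** 31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = operon_zscore(query_set, members, expressed_universe, R=R,
                                seed=child_seed, operon_id=name)
        rows.append(vars(res))
    return pd.DataFrame(rows).sort_values("z", ascending=False,
                                          na_position="last").reset_index(drop=True)


def marker_contamination_panel(deg_lists: Mapping[str, Sequence[str]],
                               marker_sets: Mapping[str, Sequence[str]],
                               universe: Sequence[str],
                               q_cut: float = 0.05) -> pd.DataFrame:
    """Marker-overlap diagnostic: one hypergeometric test per
    (DEG list, cell type).

    A cell type is flagged for a DEG list when its representation factor
    exceeds 1 with BH-adjusted p < ``q_cut`` across the whole panel —
    the signature of contamination by that cell type's transcripts.
    """
    rows = []
    for list_name, degs in deg_lists.items():
        for cell_type, markers in marker_sets.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = hypergeom_overlap(degs, markers, universe)
            rows.append({"deg_list": list_name, "cell_type": cell_type,
                         **vars(res)})
    panel = pd.DataFrame(rows)
    if panel.empty:
        return panel
    panel["qvalue"] = bh_adjust(panel["p_hyper"].to_numpy())
    panel["flagged"] = (panel["representation_factor"] > 1.0) & \
        (panel["qvalue"] < q_cut)
    return panel
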