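"""Canonical validation scenarios built from the synthetic generator.

Three study conditions are used throughout the validation suite:

* the **global null** — no planted effects, constant mixture, pure IP —
  to check the calibration of the Wald and LRT p-values;
* the **recovery** scenario — planted OL-specific log2 effects of +-1 and
  +-2, 200 genes each, pure IP — to check estimator bias and RMSE in
  isolation from admixture attenuation;
* the **contamination** scenario — the generator's defaults: an acute
  microglial mRNA surge, 25% ambient IP admixture at the acute timepoint —
  to check that the two-arm filter rejects contamination-driven calls
  while retaining planted OL responses.

Each function returns the fitted profile plus whatever the scenario
measures, and takes only a seed, so acceptance checks and tests share one
code path.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
import pandas as pd
from scipy import stats

from .counts import (build_design, estimate_dispersions,
                     estimate_size_factors, filter_low_counts, fit_nb_glm,
                     lrt_interaction)
from .enrichment import Thresholds, call_sci_degs, compute_profile, \
    two_arm_filter
from .genesets import marker_contamination_panel
from .pipeline import filtration_metrics
from .simulate import (DEFAULT_CELL_TYPES, DEFAULT_CONDITIONS,
                       DEFAULT_MIXTURE, SimConfig, generate_experiment)

PURE = {c: 1.0 for c in DEFAULT_CONDITIONS}
FLAT_MIXTURE = {c: dict(DEFAULT_MIXTURE["naive"]) for c in DEFAULT_CONDITIONS}
NO_MARKERS = {t: 0 for t in DEFAULT_CELL_TYPES}


def fit_profile(config: SimConfig, with_lrt: bool = False):
    """Simulate, normalize, fit full (and optionally reduced) models and
    return (profile, count matrix, truth)."""
    cm, truth = generate_experiment(config)
    cm_f = filter_low_counts(cm)
    sf = estimate_size_factors(cm_f)
    alpha = estimate_dispersions(cm_f, sf)
    conditions = list(config.conditions)
    full = build_design(cm_f.samples, conditions)
    fit = fit_nb_glm(cm_f, sf, alpha, full)
    unpaired = build_design(cm_f.samples, conditions, pair_term=False)
    fit_unp = fit_nb_glm(cm_f, sf, alpha, unpaired)
    lrt = None
    if with_lrt:
        reduced = build_design(cm_f.samples, conditions, interaction=False)
        lrt = lrt_interaction(fit, fit_nb_glm(cm_f, sf, alpha, reduced))
    profile = compute_profile(fit, conditions, lrt=lrt, fit_unpaired=fit_unp)
    return profile, cm_f, truth


def null_config(seed: int, n_genes: int = 5000) -> SimConfig:
    return SimConfig(n_genes=n_genes, mixture=FLAT_MIXTURE,
                     ip_target_purity=PURE, n_regulated_ol=0,
                     n_regulated_shared=0, n_inflammatory=0,
                     marker_set_sizes=NO_MARKERS, lib_size_mean=4e6,
                     seed=seed)


def global_null_calibration(seed: int, n_genes: int = 5000) -> Dict[str, float]:
    """Wald p uniformity (KS) and realized rejection rate at q < 0.05
    under the no-effect simulation."""
    profile, _, _ = fit_profile(null_config(seed, n_genes))
    tab = profile.ip_vs_baseline["dpi2"]
    p = tab["pvalue"].dropna().to_numpy()
    ks = stats.kstest(p, "uniform")
    q = tab["qvalue"].to_numpy()
    return {"ks_pvalue": float(ks.pvalue),
            "fp_fraction_q05": float(np.mean(q[np.isfinite(q)] < 0.05)),
            "n_genes": int(len(p))}


def recovery_config(seed: int, n_genes: int = 5000) -> SimConfig:
    return SimConfig(n_genes=n_genes, ip_target_purity=PURE,
                     n_regulated_ol=800,
                     ol_effect_sizes=(1.0, 2.0, -1.0, -2.0),
                     ol_random_sign=False, ol_effect_pattern="sustained",
                     n_regulated_shared=0, n_inflammatory=0,
                     lib_size_mean=4e6, seed=seed)


def effect_recovery(seed: int, n_genes: int = 5000) -> pd.DataFrame:
    """Bias and RMSE of the estimated acute IP log2 fold change for each
    planted effect size (+-1, +-2; 200 genes each)."""
    profile, _, truth = fit_profile(recovery_config(seed, n_genes))
    est = profile.ip_vs_baseline["dpi2"]["log2fc"]
    planted = truth.true_lfc_ol["dpi2"]
    rows = []
    for effect in (1.0, 2.0, -1.0, -2.0):
        genes = planted.index[planted == effect]
        genes = genes[genes.isin(est.index)]
        err = est.loc[genes] - effect
        rows.append({"effect": effect, "n": len(genes),
                     "bias": float(err.mean()),
                     "rmse": float(np.sqrt((err ** 2).mean()))})
    return pd.DataFrame(rows)


def contamination_config(seed: int, n_genes: int = 12000) -> SimConfig:
    # the generator's default study design, desk-scale gene count
    return SimConfig(n_genes=n_genes, seed=seed)


def contamination_filtration(seed: int, n_genes: int = 12000) -> dict:
    """Run the default contamination scenario end to end.

    Returns the two-arm filtration metrics at the acute timepoint plus the
    microglia marker representation-factor flags before and after
    filtration.
    """
    config = contamination_config(seed, n_genes)
    profile, cm_f, truth = fit_profile(config)
    th = Thresholds()
    degs = call_sci_degs(profile, th, "dpi2")
    verdicts = two_arm_filter(degs, profile, th, "dpi2")
    metrics = filtration_metrics(verdicts, truth, "dpi2")

    universe = list(cm_f.gene_ids)
    hc_up = sorted(verdicts.loc[verdicts["high_confidence"]
                                & (verdicts["direction"] == "up"), "gene_id"])
    pre = marker_contamination_panel({"up_dpi2": degs["up"]},
                                     truth.marker_sets, universe)
    post = marker_contamination_panel({"up_dpi2": hc_up},
                                      truth.marker_sets, universe)

    def _mg(panel):
        row = panel[panel["cell_type"] == "microglia"].iloc[0]
        return {"rf": float(row["representation_factor"]),
                "flagged": bool(row["flagged"])}

    return {**metrics,
            "n_highconf_up": len(hc_up),
            "microglia_pre": _mg(pre), "microglia_post": _mg(post),
            "verdicts": verdicts, "profile": profile, "truth": truth}
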