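"""Translatome enrichment profiles and the two-arm contamination filter.

From the fitted interaction model this module derives, per gene:

* ``Log2FC(Total)`` — IP-versus-paired-total enrichment at each condition
  (fraction main effect plus the condition's interaction term);
* ``delta Log2FC`` — the change of that enrichment at an injury timepoint
  relative to baseline (the interaction coefficient itself);
* IP-fraction and total-fraction injury-versus-baseline fold changes.

Injury-regulated transcripts (|Log2FC vs baseline| > 1, q < 0.05 in the IP
fraction) are then filtered: a raw call is kept as a high-confidence
cell-type response only if its enrichment changed concordantly
(arm 1: |delta Log2FC| > 1, q < 0.05, same sign as the call) or if the gene
is constitutively strongly enriched in the tagged cell type
(arm 2: Log2FC(Total) > 1, q < 0.05 at baseline and at the focal
timepoint).  Everything else is treated as probable ambient contamination
from other cell types.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd

from .counts import Design, ModelFit, bh_adjust, contrast_vector, wald_contrast


@dataclass
class Thresholds:
    """Log2-scale decision thresholds (field-standard defaults)."""

    enrich_lfc: float = 0.5        # enriched / depleted boundary
    high_specific_lfc: float = 2.0  # highly selective expression
    deg_lfc: float = 1.0           # injury DEG call
    delta_lfc: float = 1.0         # arm-1 differential enrichment
    arm2_total_lfc: float = 1.0    # arm-2 constitutive enrichment
    q_cut: float = 0.05

    def __post_init__(self) -> None:
        for name in ("enrich_lfc", "high_specific_lfc", "deg_lfc",
                     "delta_lfc", "arm2_total_lfc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.q_cut < 1.0):
            raise ValueError("q_cut must be in (0, 1)")


@dataclass
class EnrichmentProfile:
    """Per-gene contrast tables keyed by condition.

    Each entry is a ContrastResult DataFrame (log2fc, se, stat, pvalue,
    qvalue, baseMean) indexed by gene.  ``delta``, ``ip_vs_baseline`` and
    ``total_vs_baseline`` exist only for non-baseline conditions.
    """

    conditions: List[str]
    total_enrichment: Dict[str, pd.DataFrame]
    delta: Dict[str, pd.DataFrame]
    ip_vs_baseline: Dict[str, pd.DataFrame]
    total_vs_baseline: Dict[str, pd.DataFrame]
    lrt: pd.DataFrame | None = None

    @property
    def baseline(self) -> str:
        return self.conditions[0]

    @property
    def gene_ids(self) -> pd.Index:
        return self.total_enrichment[self.baseline].index


def compute_profile(fit: ModelFit, conditions: List[str],
                    lrt: pd.DataFrame | None = None,
                    fit_unpaired: ModelFit | None = None
                    ) -> EnrichmentProfile:
    """Derive all per-condition contrasts from the full-model fit.

    Enrichment and differential-enrichment contrasts (fraction and
    interaction terms) come from ``fit``, which should carry pair effects:
    they are within-pair comparisons and pairing removes tissue-level
    baseline variation.  Condition contrasts (injury versus baseline in
    either fraction) are between-pair comparisons; with pair effects
    nested in condition they would be identified through the reference
    pairs alone, so they are taken from ``fit_unpaired`` (a fit of the
    same model without pair columns) when provided.  BH adjustment is
    applied per contrast across genes.
    """
    design: Design = fit.design
    if not design.interaction:
        raise ValueError("profile requires the interaction (full) design")
    cond_fit = fit_unpaired if fit_unpaired is not None else fit
    if not cond_fit.gene_ids.equals(fit.gene_ids):
        raise ValueError("paired and unpaired fits cover different genes")
    baseline = conditions[0]
    total_enr, delta, ip_vs, tot_vs = {}, {}, {}, {}
    for c in conditions:
        terms = {"fraction[OL]": 1.0}
        if c != baseline:
            terms[f"fraction[OL]:condition[{c}]"] = 1.0
        total_enr[c] = wald_contrast(fit, contrast_vector(design, terms))
        if c == baseline:
            continue
        delta[c] = wald_contrast(fit, contrast_vector(
            design, {f"fraction[OL]:condition[{c}]": 1.0}))
        ip_vs[c] = wald_contrast(cond_fit, contrast_vector(
            cond_fit.design, {f"condition[{c}]": 1.0,
                              f"fraction[OL]:condition[{c}]": 1.0}))
        tot_vs[c] = wald_contrast(cond_fit, contrast_vector(
            cond_fit.design, {f"condition[{c}]": 1.0}))
    return EnrichmentProfile(conditions=list(conditions),
                             total_enrichment=total_enr, delta=delta,
                             ip_vs_baseline=ip_vs, total_vs_baseline=tot_vs,
                             lrt=lrt)


def classify_ol_expression(profile: EnrichmentProfile, th: Thresholds,
                           condition: str) -> pd.Series:
    """Label each gene enriched / highly_specific / depleted / neutral at a
    condition from its Log2FC(Total) and q."""
    tab = profile.total_enrichment[condition]
    lfc = tab["log2fc"].to_numpy()
    q = tab["qvalue"].to_numpy()
    sig = np.isfinite(q) & (q < th.q_cut)
    label = np.full(len(tab), "neutral", dtype=object)
    label[sig & (lfc > th.enrich_lfc)] = "enriched"
    label[sig & (lfc > th.high_specific_lfc)] = "highly_specific"
    label[sig & (lfc < -th.enrich_lfc)] = "depleted"
    return pd.Series(label, index=tab.index, name=f"ol_class_{condition}")


def call_sci_degs(profile: EnrichmentProfile, th: Thresholds,
                  timepoint: str) -> Dict[str, List[str]]:
    """Raw injury DEGs in the IP fraction: |Log2FC vs baseline| > deg_lfc,
    q < q_cut, split by direction."""
    if timepoint not in profile.ip_vs_baseline:
        return {"up": [], "down": []}
    tab = profile.ip_vs_baseline[timepoint]
    sig = np.isfinite(tab["qvalue"]) & (tab["qvalue"] < th.q_cut)
    up = tab.index[sig & (tab["log2fc"] > th.deg_lfc)]
    down = tab.index[sig & (tab["log2fc"] < -th.deg_lfc)]
    return {"up": list(up), "down": list(down)}


def two_arm_filter(degs: Dict[str, List[str]], profile: EnrichmentProfile,
                   th: Thresholds, timepoint: str) -> pd.DataFrame:
    """Apply both filtration arms to the raw DEG calls of one timepoint.

    Returns the verdict table with one row per (gene, direction):
    is_raw_deg, passes_arm1, passes_arm2 and
    high_confidence = arm1 OR arm2.
    """
    genes = profile.gene_ids
    missing = [g for d in ("up", "down") for g in degs.get(d, [])
               if g not in genes]
    if missing:
        raise KeyError(f"DEG genes absent from profile: {missing[:5]}")
    delta = profile.delta[timepoint]
    enr_base = profile.total_enrichment[profile.baseline]
    enr_tp = profile.total_enrichment[timepoint]

    rows = []
    for direction, sign in (("up", 1.0), ("down", -1.0)):
        for g in degs.get(direction, []):
            d_lfc = delta.at[g, "log2fc"]
            d_q = delta.at[g, "qvalue"]
            arm1 = (np.isfinite(d_q) and d_q < th.q_cut
                    and abs(d_lfc) > th.delta_lfc
                    and np.sign(d_lfc) == sign)
            arm2 = all(
                np.isfinite(tab.at[g, "qvalue"])
                and tab.at[g, "qvalue"] < th.q_cut
                and tab.at[g, "log2fc"] > th.arm2_total_lfc
                for tab in (enr_base, enr_tp))
            rows.append({"gene_id": g, "timepoint": timepoint,
                         "direction": direction, "is_raw_deg": True,
                         "passes_arm1": bool(arm1), "passes_arm2": bool(arm2),
                         "high_confidence": bool(arm1 or arm2)})
    columns = ["gene_id", "timepoint", "direction", "is_raw_deg",
               "passes_arm1", "passes_arm2", "high_confidence"]
    return pd.DataFrame(rows, columns=columns)


def acute_candidates(verdicts_up: pd.DataFrame, profile: EnrichmentProfile,
                     th: Thresholds, acute: str = "dpi2",
                     late: str = "dpi42") -> List[str]:
    """Acute-phase candidate regulators among high-confidence acutely
    upregulated genes.

    Keep a gene if its late response is not a significant upregulation
    (q >= q_cut or Log2FC <= deg_lfc) or if its late Log2FC is at least one
    log2 unit (two-fold) below the acute one.
    """
    ip_acute = profile.ip_vs_baseline[acute]
    ip_late = profile.ip_vs_baseline[late]
    kept = []
    hc = verdicts_up.loc[verdicts_up["high_confidence"]
                         & (verdicts_up["direction"] == "up"), "gene_id"]
    for g in hc:
        late_lfc = ip_late.at[g, "log2fc"]
        late_q = ip_late.at[g, "qvalue"]
        not_sig_late = (not np.isfinite(late_q)) or late_q >= th.q_cut \
            or late_lfc <= th.deg_lfc
        halved = late_lfc <= ip_acute.at[g, "log2fc"] - 1.0
        if not_sig_late or halved:
            kept.append(g)
    return kept


def summarize_geneset(geneset: List[str], profile: EnrichmentProfile,
                      timepoint: str, lfc_cut: float = 0.5,
                      q_cut: float = 0.05) -> dict:
    """Regulation summary of a gene set at one timepoint.

    Counts set members moving up/down in the IP fraction past ``lfc_cut``
    at q < ``q_cut`` and reports the median Log2FC of the regulated subset.
    Unmapped set members are reported, not an error.
    """
    tab = profile.ip_vs_baseline[timepoint]
    mapped = [g for g in geneset if g in tab.index]
    unmapped = [g for g in geneset if g not in tab.index]
    sub = tab.loc[mapped]
    sig = np.isfinite(sub["qvalue"]) & (sub["qvalue"] < q_cut)
    up = sub.loc[sig & (sub["log2fc"] > lfc_cut)]
    down = sub.loc[sig & (sub["log2fc"] < -lfc_cut)]
    regulated = pd.concat([up, down])
    per_gene = sub[["log2fc", "qvalue"]].copy()
    per_gene["regulated"] = np.where(
        per_gene.index.isin(up.index), "up",
        np.where(per_gene.index.isin(down.index), "down", "no"))
    return {
        "n_expressed": len(mapped),
        "n_unmapped": len(unmapped),
        "n_up": int(len(up)),
        "n_down": int(len(down)),
        "median_lfc_of_regulated": (float(regulated["log2fc"].median())
                                    if len(regulated) else float("nan")),
        "per_gene": per_gene,
    }


def verdicts_with_screen(verdicts: pd.DataFrame, profile: EnrichmentProfile,
                         th: Thresholds) -> pd.DataFrame:
    """Optionally intersect arm-1 passes with the gene-level LRT screen.

    When an LRT table is attached to the profile, arm-1 additionally
    requires the gene to pass the interaction screen at q < q_cut.
    """
    if profile.lrt is None or verdicts.empty:
        return verdicts
    q = profile.lrt["qvalue"]
    screened = verdicts.copy()
    ok = screened["gene_id"].map(q).to_numpy()
    pass_screen = np.isfinite(ok) & (ok < th.q_cut)
    screened["passes_arm1"] &= pass_screen
    screened["high_confidence"] = screened["passes_arm1"] | screened["passes_arm2"]
    return screened
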