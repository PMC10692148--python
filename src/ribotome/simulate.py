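"""Synthetic Ribotag experiment generator with planted ground truth.

Emulates the design of a paired IP/total translatome study in mouse spinal
cord: four conditions (uninjured baseline plus three days-post-injury
timepoints), three biological replicate pairs per condition, and two
fractions per pair — the immunoprecipitated (IP) oligodendrocyte polysome
RNA and the bulk "total" input RNA it was purified from.  The tissue is a
mixture of cell types whose mRNA-pool proportions shift after injury
(an inflammatory surge acutely), and the IP library is an imperfect
purification: a configurable fraction of it is ambient admixture drawn
from the total-RNA composition, the mechanism proposed for bead-adsorbed
contamination of affinity-purified polysomes.

Everything downstream (normalization, the negative-binomial interaction
model, the two-arm contamination filter, gene-set statistics, qPCR
quantification) can therefore be validated against planted truth without
any external download.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .counts import CountMatrix

OL = "OL"
DEFAULT_CELL_TYPES = (OL, "neuron", "astrocyte", "microglia")
DEFAULT_CONDITIONS = ("naive", "dpi2", "dpi10", "dpi42")

# Baseline mRNA-pool composition with an acute microglial surge at dpi2 that
# partially resolves by dpi42.  OLs are ~20% of the uninjured pool.
DEFAULT_MIXTURE = {
    "naive": {OL: 0.20, "neuron": 0.40, "astrocyte": 0.25, "microglia": 0.15},
    "dpi2":  {OL: 0.14, "neuron": 0.28, "astrocyte": 0.23, "microglia": 0.35},
    "dpi10": {OL: 0.17, "neuron": 0.33, "astrocyte": 0.25, "microglia": 0.25},
    "dpi42": {OL: 0.19, "neuron": 0.37, "astrocyte": 0.26, "microglia": 0.18},
}

# IP purity: fraction of the IP library that originates from tagged OL
# polysomes.  Contamination (1 - purity) peaks acutely when inflammatory
# mRNAs are most abundant.
DEFAULT_IP_PURITY = {"naive": 0.90, "dpi2": 0.75, "dpi10": 0.85, "dpi42": 0.90}


class ConfigurationError(ValueError):
    """Raised when a SimConfig is internally inconsistent."""


class GenerationError(RuntimeError):
    """Raised when sample expectations become non-finite."""


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    ``dispersion`` is either a scalar NB dispersion alpha shared by all
    genes or a ``(shape, scale)`` tuple of a gamma distribution from which
    per-gene alphas are drawn.  ``ol_effect_sizes`` are planted
    OL-specific log2 fold changes versus baseline; each regulated gene is
    assigned one magnitude and one of three temporal patterns (acute-only,
    decaying, sustained).
    """

    n_genes: int = 16000
    cell_types: Tuple[str, ...] = DEFAULT_CELL_TYPES
    conditions: Tuple[str, ...] = DEFAULT_CONDITIONS
    mixture: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_MIXTURE.items()})
    ip_target_purity: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IP_PURITY))
    n_pairs_per_condition: int = 3
    lib_size_mean: float = 4e6
    lib_size_cv: float = 0.15
    # NB dispersion for pooled-animal biological replicates: gamma with
    # mean 0.02 (each replicate pools two animals, which suppresses
    # between-replicate biological variability)
    dispersion: float | Tuple[float, float] = (2.0, 0.01)
    n_regulated_ol: int = 300
    ol_effect_sizes: Tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0)
    # regulated genes are drawn from transcripts detectably expressed in
    # the OL pool: relative expression at least this fraction of the mean
    regulated_min_rel_expr: float = 0.25
    ol_random_sign: bool = True
    ol_effect_pattern: str = "mixed"   # mixed | acute | decay | sustained
    n_regulated_shared: int = 200
    shared_effect_sizes: Tuple[float, ...] = (1.0, 2.0)
    n_inflammatory: int = 150
    inflammatory_surge_log2: Mapping[str, float] = field(
        default_factory=lambda: {"dpi2": 3.0, "dpi10": 1.5, "dpi42": 0.5})
    marker_set_sizes: Mapping[str, int] = field(
        default_factory=lambda: {t: 500 for t in DEFAULT_CELL_TYPES})
    marker_fold_range: Tuple[float, float] = (10.0, 50.0)
    operon_sizes: Tuple[int, ...] = (700, 500, 400, 350, 300)
    operon_hit_rate: float = 0.45
    n_reference_genes: int = 3
    qpcr_noise_sd: float = 0.15
    qpcr_ct_baseline: float = 8.0
    qpcr_ct_max: float = 40.0
    qpcr_technical_replicates: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_pairs_per_condition < 1:
            raise ConfigurationError("n_genes and n_pairs_per_condition must be >= 1")
        for c in self.conditions:
            props = self.mixture.get(c)
            if props is None:
                raise ConfigurationError(f"mixture proportions missing for {c!r}")
            total = sum(props[t] for t in self.cell_types)
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"mixture proportions for {c!r} sum to {total}, not 1")
            p = self.ip_target_purity.get(c)
            if p is None or not (0.0 < p <= 1.0):
                raise ConfigurationError(
                    f"ip_target_purity for {c!r} must be in (0, 1], got {p}")
        if OL not in self.cell_types:
            raise ConfigurationError(f"cell_types must include {OL!r}")
        n_markers = sum(self.marker_set_sizes.get(t, 0) for t in self.cell_types)
        if n_markers + self.n_reference_genes > self.n_genes:
            raise ConfigurationError(
                f"{n_markers} marker genes + {self.n_reference_genes} reference "
                f"genes exceed n_genes={self.n_genes}")
        for sizes in (self.ol_effect_sizes, self.shared_effect_sizes):
            if not all(np.isfinite(sizes)):
                raise ConfigurationError("effect sizes must be finite")
        if isinstance(self.dispersion, tuple):
            shape, scale = self.dispersion
            if shape <= 0 or scale <= 0:
                raise ConfigurationError("gamma dispersion parameters must be > 0")
        elif self.dispersion < 0:
            raise ConfigurationError("scalar dispersion must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mixture"] = {c: dict(v) for c, v in self.mixture.items()}
        d["ip_target_purity"] = dict(self.ip_target_purity)
        return d


@dataclass
class CellTypeProfiles:
    """Relative expression of every gene in every cell type.

    ``profiles`` columns are cell types; each column sums to 1 (mRNA-pool
    shares at baseline).  Declared marker genes are, by construction, at
    least 8-fold higher in their own type than the mean of the others.
    """

    profiles: pd.DataFrame                 # genes x cell types
    marker_membership: pd.Series           # gene -> cell type label or ""
    reference_genes: List[str]             # equal expression in all types

    def marker_sets(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for t in self.profiles.columns:
            out[t] = list(self.marker_membership.index[self.marker_membership == t])
        return out


@dataclass
class SynthTruth:
    """Planted ground truth aligned with the emitted count matrix."""

    profiles: CellTypeProfiles
    true_lfc_ol: pd.DataFrame              # genes x SCI conditions, log2
    true_lfc_shared: pd.DataFrame          # genes x SCI conditions, log2
    true_lfc_microglia: pd.DataFrame       # genes x SCI conditions, log2
    contamination_fraction: pd.Series      # per IP sample, 1 - purity
    marker_sets: Dict[str, List[str]]
    operon_sets: Dict[str, List[str]]
    regulated_ol_genes: List[str]
    regulated_shared_genes: List[str]
    inflammatory_genes: List[str]
    reference_genes: List[str]
    expected_total_composition: pd.DataFrame   # genes x conditions, sums to 1
    expected_ip_composition: pd.DataFrame      # genes x conditions, sums to 1


def _gene_ids(n: int) -> List[str]:
    width = max(5, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def generate_profiles(config: SimConfig,
                      rng: np.random.Generator | None = None) -> CellTypeProfiles:
    """Draw per-cell-type relative expression profiles with planted markers.

    Non-marker genes get a shared lognormal abundance modulated by an
    independent lognormal factor per cell type, so most genes are expressed
    everywhere but with broad cross-type ratios.  Marker genes of a type are
    strongly skewed toward it (fold drawn from ``marker_fold_range``, which
    keeps the >= 8-fold marker rule true by construction).  Reference genes
    (qPCR housekeeping analogues) are forced equal across types.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    types = list(config.cell_types)
    base = rng.lognormal(mean=1.0, sigma=1.2, size=config.n_genes)
    type_factor = rng.lognormal(mean=0.0, sigma=1.0,
                                size=(config.n_genes, len(types)))
    prof = base[:, None] * type_factor

    membership = pd.Series("", index=pd.Index(genes, name="gene_id"), dtype=object)
    cursor = 0
    for ti, t in enumerate(types):
        size = int(config.marker_set_sizes.get(t, 0))
        idx = np.arange(cursor, cursor + size)
        cursor += size
        lo, hi = config.marker_fold_range
        fold = rng.uniform(lo, hi, size=size)
        own = base[idx] * 3.0
        prof[idx, :] = (own / fold)[:, None]
        prof[idx, ti] = own
        membership.iloc[idx] = t

    ref_idx = np.arange(cursor, cursor + config.n_reference_genes)
    prof[ref_idx, :] = (base[ref_idx] * 2.0)[:, None]
    reference_genes = [genes[i] for i in ref_idx]

    profiles = pd.DataFrame(prof, index=pd.Index(genes, name="gene_id"),
                            columns=types)
    profiles = profiles / profiles.sum(axis=0)
    # pin reference genes to exactly equal shares in every cell type (the
    # housekeeping property ddCT normalization relies on), rescaling the
    # remaining genes so each column still sums to 1
    ref_share = profiles.loc[reference_genes].mean(axis=1)
    other = ~profiles.index.isin(reference_genes)
    for col in profiles.columns:
        scale = (1.0 - ref_share.sum()) / profiles.loc[other, col].sum()
        profiles.loc[other, col] *= scale
        profiles.loc[reference_genes, col] = ref_share
    return CellTypeProfiles(profiles=profiles, marker_membership=membership,
                            reference_genes=reference_genes)


def _plant_effects(config: SimConfig, profiles: CellTypeProfiles,
                   rng: np.random.Generator):
    """Assign planted log2 effects: OL-specific, shared, and microglial surge."""
    genes = profiles.profiles.index
    sci = [c for c in config.conditions[1:]]
    zeros = lambda: pd.DataFrame(0.0, index=genes, columns=sci)
    lfc_ol, lfc_shared, lfc_mg = zeros(), zeros(), zeros()

    membership = profiles.marker_membership
    ol_share = profiles.profiles[OL]
    detectable = (ol_share >= config.regulated_min_rel_expr
                  / config.n_genes).to_numpy()
    free = genes[(membership == "").to_numpy() & detectable
                 & ~genes.isin(profiles.reference_genes)]
    ol_markers = genes[(membership == OL).to_numpy() & detectable]
    mg_markers = genes[(membership == "microglia").to_numpy()]

    # OL-regulated genes: a mix of strongly OL-specific (marker-like) genes
    # and ordinary OL-expressed genes, as in a real translatome response.
    n_from_markers = min(int(round(0.4 * config.n_regulated_ol)), len(ol_markers))
    n_from_free = config.n_regulated_ol - n_from_markers
    reg_ol = list(rng.choice(ol_markers, size=n_from_markers, replace=False)) + \
        list(rng.choice(free, size=n_from_free, replace=False))
    rng.shuffle(reg_ol)
    # effect sizes and temporal patterns cycle round-robin over the
    # (shuffled) regulated genes, so the planted design is balanced
    if config.ol_effect_pattern == "mixed":
        patterns = ("acute", "decay", "sustained")
    else:
        patterns = (config.ol_effect_pattern,)
    for i, g in enumerate(reg_ol):
        mag = config.ol_effect_sizes[i % len(config.ol_effect_sizes)]
        if config.ol_random_sign:
            mag = mag * rng.choice([-1.0, 1.0])
        pattern = patterns[i % len(patterns)]
        if pattern == "acute":
            eff = {"dpi2": mag}
        elif pattern == "decay":
            eff = {"dpi2": mag, "dpi10": mag / 2.0, "dpi42": mag / 4.0}
        elif pattern == "sustained":
            eff = {c: mag for c in sci}
        else:
            raise ConfigurationError(
                f"unknown ol_effect_pattern {pattern!r}")
        for c, v in eff.items():
            if c in lfc_ol.columns:
                lfc_ol.loc[g, c] = v

    remaining = free[~free.isin(reg_ol)]
    reg_shared = list(rng.choice(remaining, size=config.n_regulated_shared,
                                 replace=False))
    for g in reg_shared:
        mag = rng.choice(config.shared_effect_sizes) * rng.choice([-1.0, 1.0])
        for c in sci:
            lfc_shared.loc[g, c] = mag

    n_inf = min(config.n_inflammatory, len(mg_markers))
    inflammatory = list(rng.choice(mg_markers, size=n_inf, replace=False))
    for c, surge in config.inflammatory_surge_log2.items():
        if c in lfc_mg.columns:
            lfc_mg.loc[inflammatory, c] = surge

    return lfc_ol, lfc_shared, lfc_mg, reg_ol, reg_shared, inflammatory


def expected_compositions(config: SimConfig, profiles: CellTypeProfiles,
                          lfc_ol: pd.DataFrame, lfc_shared: pd.DataFrame,
                          lfc_mg: pd.DataFrame):
    """Closed-form expected mRNA composition of total and IP samples.

    For condition c the total pool is sum_t pi_tc * e_gtc with e the
    effect-modulated profile of type t; the IP pool is
    purity * (OL pool, renormalized) + (1 - purity) * (total pool,
    renormalized) — ambient admixture proportional to total-RNA
    composition.  Both returned tables are normalized to sum to 1 per
    condition.
    """
    genes = profiles.profiles.index
    types = list(config.cell_types)
    total = pd.DataFrame(index=genes, columns=list(config.conditions), dtype=float)
    ip = pd.DataFrame(index=genes, columns=list(config.conditions), dtype=float)
    for c in config.conditions:
        pool = np.zeros(len(genes))
        ol_pool = None
        for t in types:
            lfc = np.zeros(len(genes))
            if c != config.conditions[0]:
                lfc = lfc_shared[c].to_numpy().copy()
                if t == OL:
                    lfc = lfc + lfc_ol[c].to_numpy()
                if t == "microglia":
                    lfc = lfc + lfc_mg[c].to_numpy()
            expr = profiles.profiles[t].to_numpy() * np.exp2(lfc)
            if not np.all(np.isfinite(expr)):
                bad = genes[~np.isfinite(expr)][0]
                raise GenerationError(f"non-finite expectation for gene {bad}")
            pool += config.mixture[c][t] * expr
            if t == OL:
                ol_pool = expr
        total[c] = pool / pool.sum()
        p = config.ip_target_purity[c]
        ip[c] = p * (ol_pool / ol_pool.sum()) + (1.0 - p) * total[c].to_numpy()
    return total, ip


def _draw_dispersions(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(config.dispersion, tuple):
        shape, scale = config.dispersion
        return rng.gamma(shape, scale, size=config.n_genes)
    return np.full(config.n_genes, float(config.dispersion))


def _draw_counts(mean: np.ndarray, alpha: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """NB(mean, alpha) counts; alpha below 1e-8 degenerates to Poisson."""
    counts = np.empty_like(mean, dtype=np.int64)
    poisson = alpha < 1e-8
    if poisson.any():
        counts[poisson] = rng.poisson(mean[poisson])
    nb = ~poisson
    if nb.any():
        r = 1.0 / alpha[nb]
        p = r / (r + mean[nb])
        counts[nb] = rng.negative_binomial(r, p)
    return counts


def generate_experiment(config: SimConfig) -> Tuple[CountMatrix, SynthTruth]:
    """Generate the paired IP/total count matrix plus its ground truth.

    All randomness flows from a single generator seeded by ``config.seed``,
    so identical configs give bit-identical experiments.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    profiles = generate_profiles(config, rng)
    lfc_ol, lfc_shared, lfc_mg, reg_ol, reg_shared, inflammatory = \
        _plant_effects(config, profiles, rng)
    total_comp, ip_comp = expected_compositions(
        config, profiles, lfc_ol, lfc_shared, lfc_mg)
    alpha = _draw_dispersions(config, rng)

    sigma = np.sqrt(np.log1p(config.lib_size_cv ** 2))
    mu_log = np.log(config.lib_size_mean) - sigma ** 2 / 2.0

    rows = []
    count_cols: Dict[str, np.ndarray] = {}
    contamination = {}
    for c in config.conditions:
        for k in range(1, config.n_pairs_per_condition + 1):
            pair = f"{c}_p{k}"
            for fraction, comp in (("total", total_comp[c]), (OL, ip_comp[c])):
                sample = f"{pair}_{fraction}"
                lib = rng.lognormal(mu_log, sigma)
                mean = comp.to_numpy() * lib
                count_cols[sample] = _draw_counts(mean, alpha, rng)
                rows.append({"sample_id": sample, "fraction": fraction,
                             "condition": c, "pair_id": pair})
                if fraction == OL:
                    contamination[sample] = 1.0 - config.ip_target_purity[c]

    counts = pd.DataFrame(count_cols, index=profiles.profiles.index)
    samples = pd.DataFrame(rows)
    cm = CountMatrix(counts=counts, samples=samples,
                     conditions=list(config.conditions))
    marker_sets = profiles.marker_sets()
    operons = _plant_operons(config, profiles, lfc_ol, rng)
    truth = SynthTruth(
        profiles=profiles,
        true_lfc_ol=lfc_ol, true_lfc_shared=lfc_shared, true_lfc_microglia=lfc_mg,
        contamination_fraction=pd.Series(contamination, name="contamination"),
        marker_sets=marker_sets, operon_sets=operons,
        regulated_ol_genes=reg_ol, regulated_shared_genes=reg_shared,
        inflammatory_genes=inflammatory,
        reference_genes=profiles.reference_genes,
        expected_total_composition=total_comp,
        expected_ip_composition=ip_comp,
    )
    return cm, truth


def _plant_operons(config: SimConfig, profiles: CellTypeProfiles,
                   lfc_ol: pd.DataFrame, rng: np.random.Generator
                   ) -> Dict[str, List[str]]:
    """Operon gene sets; the first one is enriched among planted acutely
    OL-upregulated genes (a PRC2-target-like de-silencing signature), the
    rest are uniform draws."""
    genes = profiles.profiles.index.to_numpy()
    up_acute = lfc_ol.index[(lfc_ol["dpi2"] > 0).to_numpy()] \
        if "dpi2" in lfc_ol.columns else lfc_ol.index[:0]
    operons: Dict[str, List[str]] = {}
    for i, size in enumerate(config.operon_sizes):
        name = f"operon_{i + 1:02d}"
        if i == 0 and len(up_acute) > 0:
            hits = up_acute[rng.random(len(up_acute)) < config.operon_hit_rate]
            rest_pool = genes[~np.isin(genes, hits)]
            n_rest = max(0, size - len(hits))
            members = list(hits) + list(
                rng.choice(rest_pool, size=n_rest, replace=False))
        else:
            members = list(rng.choice(genes, size=size, replace=False))
        operons[name] = sorted(members)
    return operons


DEFAULT_QPCR_TARGETS = {OL: 3, "astrocyte": 2, "neuron": 2, "microglia": 2}


def generate_qpcr(truth: SynthTruth, config: SimConfig) -> pd.DataFrame:
    """Emulate a marker-panel qPCR plate over every IP/total pair.

    Ct is linear in -log2(expected expression share) plus Gaussian noise;
    reference genes have equal expression in every cell type and hence the
    same expectation in IP and total fractions.  Wells whose expected
    expression is zero are set to ``qpcr_ct_max`` and flagged undetected.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    targets: List[str] = []
    for t, n in DEFAULT_QPCR_TARGETS.items():
        targets.extend(truth.marker_sets.get(t, [])[:n])
    targets.extend(truth.reference_genes)

    rows = []
    for c in config.conditions:
        for k in range(1, config.n_pairs_per_condition + 1):
            pair = f"{c}_p{k}"
            for fraction, comp in (("total", truth.expected_total_composition[c]),
                                   (OL, truth.expected_ip_composition[c])):
                sample = f"{pair}_{fraction}"
                for g in targets:
                    share = comp.loc[g]
                    for rep in range(1, config.qpcr_technical_replicates + 1):
                        if share <= 0:
                            ct, undetected = config.qpcr_ct_max, True
                        else:
                            ct = (config.qpcr_ct_baseline - np.log2(share)
                                  + rng.normal(0.0, config.qpcr_noise_sd))
                            ct, undetected = min(ct, config.qpcr_ct_max), False
                        rows.append({"sample_id": sample, "fraction": fraction,
                                     "condition": c, "pair_id": pair,
                                     "target": g, "technical_replicate": rep,
                                     "ct": ct, "undetected": undetected})
    return pd.DataFrame(rows)


def write_simulation(cm: CountMatrix, truth: SynthTruth, config: SimConfig,
                     outdir) -> Dict[str, str]:
    """Emit the simulated experiment as plain-text files and return paths."""
    import os

    from . import io as rio

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def _p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    rio.write_counts_tsv(cm.counts, _p("counts.tsv"))
    rio.write_sample_sheet(cm.samples, _p("samples.tsv"))
    rio.write_gmt(truth.marker_sets, _p("markers.gmt"))
    rio.write_gmt(truth.operon_sets, _p("operons.gmt"))
    rio.write_table(truth.true_lfc_ol, _p("truth_lfc_ol.tsv"), index=True,
                    index_label="gene_id")
    rio.write_table(truth.true_lfc_shared, _p("truth_lfc_shared.tsv"),
                    index=True, index_label="gene_id")
    rio.write_table(truth.true_lfc_microglia, _p("truth_lfc_microglia.tsv"),
                    index=True, index_label="gene_id")
    rio.write_table(truth.contamination_fraction.rename_axis("sample_id")
                    .reset_index(), _p("truth_contamination.tsv"))
    rio.write_gene_list(truth.regulated_ol_genes, _p("truth_regulated_ol.txt"))
    rio.write_gene_list(truth.inflammatory_genes, _p("truth_inflammatory.txt"))
    plate = generate_qpcr(truth, config)
    plate.to_csv(paths.setdefault("qpcr.tsv", os.path.join(outdir, "qpcr.tsv")),
                 sep="\t", index=False, float_format="%.6g")
    rio.write_yaml(config.to_dict(), _p("config.yaml"))
    return paths
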