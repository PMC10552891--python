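"""Synthetic multi-omics cohort generator with known planted structure.

Emulates the statistical shape of a three-layer luminal breast cancer
cohort: miRNA microarray log2 intensities (123 samples x 280 miRNAs after
filtering, three acquisition batches), an mRNA-seq count matrix restricted
to a 113-gene oxysterol-related panel (67 samples, 56 overlapping with the
miRNA set), a per-sample somatic-variant table from panel DNA sequencing,
and a clinical table with two censored endpoints (OS, DFS).

Structure is planted through shared latent Gaussian factors:

* a co-expression cluster with target pairwise correlation r gives each
  member ``z = sqrt(r) f + sqrt(1-r) e`` for a shared factor ``f``, so the
  population correlation between members is exactly r (closed form
  ``r = v / (v + sigma^2)`` with loading variance v = r, noise 1-r);
* a signed cross-omics edge ties a miRNA latent to an mRNA latent with the
  requested sign; the latent correlation is inflated to compensate for the
  count-sampling noise of the mRNA layer (delta-method attenuation), so the
  observed log-TPM correlation lands near the target;
* counts are negative binomial around log-normal means, batch shifts are
  added on the log2 scale, and survival times follow an exponential
  proportional-hazards model with uniform administrative censoring.

Every planted fact is recorded in a :class:`PlantedStructure` that
serializes losslessly to JSON.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as oio
from .containers import ExpressionMatrix, GeneSet, InteractionDB, OxynetError

logger = logging.getLogger("oxynet.simulate")

LN2 = math.log(2.0)

# Gene symbols of the oxysterol panel's most discussed members, padded with
# synthetic OSG### symbols up to the requested panel size.
PANEL_GENES = [
    "ESR1", "CH25H", "INSIG1", "ABCA9", "STARD5", "CYP46A1", "SC5D", "EBP",
    "DHCR7", "PPARGC1B", "OSBP", "LDLR", "ABCG8", "SREBF1", "AHR", "NCOA1",
    "NCOA2", "NCOA3", "NCOR1", "CYP3A4", "PPARGC1A", "CYP7B1", "CYP27A1",
    "CYP39A1", "HSD3B7", "CYP7A1", "CYP11A1", "CYP3A5", "ABCA1", "ABCG1",
    "APOE", "LRP1", "NR1H2", "NR1H3", "RORA", "RORC", "SOAT1", "SREBF2",
    "STARD4", "OSBPL1A",
]

MIRNAS = [
    "hsa-miR-100-5p", "hsa-miR-125b-5p", "hsa-miR-99a-5p", "hsa-miR-143-3p",
    "hsa-miR-199b-5p", "hsa-miR-376a-3p", "hsa-miR-376c-3p", "hsa-miR-130a-3p",
    "hsa-miR-145-5p", "hsa-miR-200c-3p", "hsa-miR-494-3p", "hsa-miR-19b-3p",
    "hsa-let-7c-5p", "hsa-miR-199a-3p", "hsa-miR-199a-5p",
]

VARIANT_CLASSES = ["missense_variant", "stop_gained", "frameshift_variant",
                   "splice_acceptor_variant", "inframe_deletion"]


def gene_names(n: int) -> list[str]:
    names = list(PANEL_GENES[:n])
    names += [f"OSG{i:03d}" for i in range(1, n - len(names) + 1)]
    return names[:n]


def mirna_names(n: int) -> list[str]:
    names = list(MIRNAS[:n])
    names += [f"hsa-miR-{9000 + i}-5p" for i in range(1, n - len(names) + 1)]
    return names[:n]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ClusterSpec:
    member_count: int
    target_within_r: float

    def __post_init__(self) -> None:
        if self.member_count < 2:
            raise OxynetError(f"cluster needs >=2 members, got {self.member_count}")
        if not 0 < self.target_within_r < 1:
            raise OxynetError(f"cluster target r must be in (0,1), got {self.target_within_r}")


@dataclass
class EdgeSpec:
    mrna_id: str
    mirna_id: str
    sign: int            # +1 or -1
    target_r: float      # |r| in (0, 1)

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise OxynetError(f"edge sign must be +-1, got {self.sign}")
        if not 0 < self.target_r < 1:
            raise OxynetError(f"edge target |r| must be in (0,1), got {self.target_r}")


@dataclass
class MutationSpec:
    label: str
    genes: tuple[str, ...]            # grouping genes ("any variant" rule)
    mutated_fraction: float
    affected_genes: dict              # gene -> planted log2FC (mutated over wild type)

    def __post_init__(self) -> None:
        if not self.genes:
            raise OxynetError(f"mutation spec {self.label!r} lists no genes")
        if not 0 < self.mutated_fraction < 1:
            raise OxynetError(
                f"mutation spec {self.label!r}: fraction must be in (0,1)")


@dataclass
class ClinicalEffectSpec:
    """Expression effect tied to a clinical category (e.g. nodal status)."""

    column: str
    positive_level: str
    affected_genes: dict              # gene -> log2FC (positive over negative)


@dataclass
class SurvivalSpec:
    baseline_hazard: float = LN2 / 60.0     # per month; median ~60 months
    coefficients: dict = field(default_factory=dict)  # feature -> log hazard per SD
    censoring_rate: float = 0.4

    def __post_init__(self) -> None:
        if not 0 <= self.censoring_rate < 1:
            raise OxynetError("censoring rate must be in [0,1)")
        if self.baseline_hazard <= 0:
            raise OxynetError("baseline hazard must be positive")


@dataclass
class SimConfig:
    """All knobs of the cohort generator; defaults mirror the study scale."""

    n_mirna_samples: int = 123
    n_mrna_samples: int = 67
    n_shared_samples: int = 56
    n_mirna: int = 280
    n_mrna: int = 113
    n_batches: int = 3
    batch_shift_sd: float = 0.5          # log2 units
    noise_sd: float = 1.0                # per-feature expression SD (log2)
    nb_dispersion: float = 0.1
    detection_floor: float = 6.0         # log2 intensity noise floor
    low_expressed_fraction: float = 0.15
    cluster_specs: tuple[ClusterSpec, ...] = ()
    edge_specs: tuple[EdgeSpec, ...] = ()
    mutation_specs: tuple[MutationSpec, ...] = ()
    clinical_effect_specs: tuple[ClinicalEffectSpec, ...] = ()
    survival_spec: SurvivalSpec = field(default_factory=SurvivalSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mirna_samples, self.n_mrna_samples, self.n_mirna, self.n_mrna) < 1:
            raise OxynetError("dimensions must be positive")
        if self.n_shared_samples > min(self.n_mirna_samples, self.n_mrna_samples):
            raise OxynetError("shared samples exceed a layer's sample count")
        if self.n_batches < 1:
            raise OxynetError("need >=1 batch")

    @property
    def n_samples(self) -> int:
        return self.n_mirna_samples + self.n_mrna_samples - self.n_shared_samples


def default_config(seed: int = 0) -> SimConfig:
    """Study-scale configuration with the planted structure used throughout.

    Cluster sizes mirror the reported co-expression groups (one 15-member
    group, three of 5, one of 3, one of 8); ten signed cross-omics edges at
    |r| = 0.6 reproduce the sign pattern of the most prominent gene-miRNA
    axes; mutation contrasts and the nodal-status effect carry the reported
    fold changes; one miRNA drives disease-free survival.
    """
    string_cyp46a1 = ("CYP46A1", "CYP7B1", "CYP27A1", "CYP39A1", "HSD3B7",
                      "CYP7A1", "CYP11A1", "CYP3A4", "CYP3A5", "ABCA1")
    return SimConfig(
        cluster_specs=(
            ClusterSpec(15, 0.9), ClusterSpec(5, 0.85), ClusterSpec(5, 0.85),
            ClusterSpec(5, 0.85), ClusterSpec(3, 0.85), ClusterSpec(8, 0.82),
        ),
        edge_specs=(
            EdgeSpec("ESR1", "hsa-miR-100-5p", -1, 0.6),
            EdgeSpec("ESR1", "hsa-miR-125b-5p", -1, 0.6),
            EdgeSpec("ESR1", "hsa-miR-99a-5p", -1, 0.6),
            EdgeSpec("CH25H", "hsa-miR-143-3p", +1, 0.6),
            EdgeSpec("CH25H", "hsa-miR-199b-5p", +1, 0.6),
            EdgeSpec("CH25H", "hsa-miR-376a-3p", +1, 0.6),
            EdgeSpec("INSIG1", "hsa-miR-130a-3p", -1, 0.6),
            EdgeSpec("ABCA9", "hsa-miR-376c-3p", -1, 0.6),
            EdgeSpec("NCOA2", "hsa-miR-200c-3p", -1, 0.6),
            EdgeSpec("SC5D", "hsa-miR-145-5p", +1, 0.6),
        ),
        mutation_specs=(
            MutationSpec("CYP46A1", ("CYP46A1",), 4 / 67,
                         {"EBP": 2.74, "DHCR7": 2.24, "PPARGC1B": 2.09}),
            MutationSpec("SC5D", ("SC5D",), 2 / 67,
                         {"SC5D": 3.06, "SREBF1": 2.43, "AHR": 1.93}),
            MutationSpec("STRING-CYP46A1", string_cyp46a1, 15 / 67,
                         {"EBP": 1.44, "DHCR7": 1.04, "PPARGC1B": 0.93, "OSBP": 0.76}),
        ),
        clinical_effect_specs=(
            ClinicalEffectSpec("pN", "N1", {"STARD5": 3.26}),
        ),
        survival_spec=SurvivalSpec(
            coefficients={"hsa-miR-19b-3p": math.log(2.5)},
            censoring_rate=0.5,
        ),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# planted-structure record
# ---------------------------------------------------------------------------

@dataclass
class PlantedStructure:
    """Serializable ground truth of one simulated cohort."""

    mirna_ids: list
    gene_ids: list
    mirna_sample_ids: list
    mrna_sample_ids: list
    cluster_membership: dict          # mirna_id -> cluster index
    true_edges: list                  # [gene, mirna, sign, target_r] rows
    true_de: dict                     # contrast label -> {gene: log2FC}
    mutated_samples: dict             # contrast label -> [sample ids]
    true_log_hazards: dict            # feature -> log hazard per SD
    batch_assignments: dict           # sample -> batch label

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedStructure":
        return cls(**{f.name: d[f.name] for f in dataclasses.fields(cls)})

    def validate(self) -> None:
        genes = set(self.gene_ids)
        mirnas = set(self.mirna_ids)
        for g, m, _, _ in self.true_edges:
            if g not in genes or m not in mirnas:
                raise OxynetError(f"planted edge references unknown feature: {g}-{m}")
        for m in self.cluster_membership:
            if m not in mirnas:
                raise OxynetError(f"planted cluster member unknown: {m}")


@dataclass
class MultiOmicsCohort:
    """One simulated cohort: expression layers, clinical and variant tables,
    per-gene transcript lengths, and the planted ground truth."""

    mirna: ExpressionMatrix                 # log2 intensities + detection flags
    mrna: ExpressionMatrix                  # counts (or log2 for validation cohorts)
    clinical: pd.DataFrame
    variants: pd.DataFrame
    truth: PlantedStructure
    gene_lengths_kb: Optional[pd.Series] = None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        oio.write_expression(self.mirna, outdir / "mirna_log2.tsv")
        if self.mirna.detection is not None:
            oio.write_detection(self.mirna.detection, outdir / "mirna_detection.tsv")
        suffix = "counts" if self.mrna.scale == "counts" else "log2"
        oio.write_expression(self.mrna, outdir / f"mrna_{suffix}.tsv")
        if self.mrna.scale == "counts" and self.gene_lengths_kb is not None:
            from .preprocess import counts_to_tpm, log2_transform
            log_tpm = log2_transform(counts_to_tpm(self.mrna, self.gene_lengths_kb),
                                     offset=1.0)
            oio.write_expression(log_tpm, outdir / "mrna_log2tpm.tsv")
        oio.write_clinical(self.clinical, outdir / "clinical.tsv")
        oio.write_variants(self.variants, outdir / "variants.tsv")
        if self.gene_lengths_kb is not None:
            self.gene_lengths_kb.rename("length_kb").to_frame().reset_index(
                names="feature_id").to_csv(outdir / "gene_lengths.tsv", sep="\t",
                                           index=False, float_format="%.15g")
        oio.write_truth(self.truth.to_dict(), outdir / "truth.json")


# ---------------------------------------------------------------------------
# latent structure
# ---------------------------------------------------------------------------

def _assign_structure(config: SimConfig, mirnas: Sequence[str],
                      genes: Sequence[str], rng: np.random.Generator):
    """Resolve cluster memberships and check edge feasibility."""
    gene_set = set(genes)
    mirna_set = set(mirnas)
    edge_mirnas: set[str] = set()
    for e in config.edge_specs:
        if e.mrna_id not in gene_set:
            raise OxynetError(f"edge references unknown gene {e.mrna_id!r}")
        if e.mirna_id not in mirna_set:
            raise OxynetError(f"edge references unknown miRNA {e.mirna_id!r}")
        if e.mirna_id in edge_mirnas:
            raise OxynetError(
                "infeasible correlation structure: miRNA "
                f"{e.mirna_id!r} appears in more than one edge spec")
        edge_mirnas.add(e.mirna_id)
    pool = [m for m in mirnas if m not in edge_mirnas]
    needed = sum(c.member_count for c in config.cluster_specs)
    if needed > len(pool):
        raise OxynetError(
            f"infeasible correlation structure: clusters need {needed} miRNAs "
            f"but only {len(pool)} are available outside edges")
    pool = list(rng.permutation(pool))
    membership: dict[str, int] = {}
    start = 0
    for ci, spec in enumerate(config.cluster_specs):
        for m in pool[start:start + spec.member_count]:
            membership[m] = ci
        start += spec.member_count
    return membership


def _log_tpm_denominator_var(mu_gene_log2: np.ndarray, lengths_kb: np.ndarray,
                             noise_sd: float) -> float:
    """Approximate across-sample variance (log2 units) of the per-sample
    total length-normalized rate that the TPM transform divides by."""
    v = (noise_sd * LN2) ** 2
    w = 2.0 ** mu_gene_log2 / lengths_kb
    w = w / w.sum()
    cv_sq = (math.exp(v) - 1.0) * float((w ** 2).sum())
    return math.log1p(cv_sq) / LN2 ** 2


def _latent_matrix(config: SimConfig, mirnas: Sequence[str], genes: Sequence[str],
                   membership: dict, mu_gene_log2: np.ndarray,
                   lengths_kb: np.ndarray,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Unit-variance latent signals (features x all samples) for both layers."""
    n = config.n_samples
    z_gene = rng.standard_normal((len(genes), n))
    gene_index = {g: i for i, g in enumerate(genes)}
    mirna_index = {m: i for i, m in enumerate(mirnas)}

    z_mirna = rng.standard_normal((len(mirnas), n))
    # clusters: shared factor per cluster
    for ci, spec in enumerate(config.cluster_specs):
        members = [m for m, c in membership.items() if c == ci]
        f = rng.standard_normal(n)
        r = spec.target_within_r
        for m in sorted(members):
            i = mirna_index[m]
            z_mirna[i] = math.sqrt(r) * f + math.sqrt(1 - r) * rng.standard_normal(n)
    # cross-omics edges: miRNA latent tied to the gene latent. The latent
    # (Pearson) correlation is inflated so the observed rank correlation of
    # the log-TPM values lands on target: Gaussian-copula Spearman->Pearson
    # conversion, then division by the delta-method attenuation from count
    # sampling noise and the TPM denominator.
    v_t = _log_tpm_denominator_var(mu_gene_log2, lengths_kb, config.noise_sd)
    for e in config.edge_specs:
        gi = gene_index[e.mrna_id]
        mi = mirna_index[e.mirna_id]
        # E[1/count mean] over the latent (Jensen: e^{+v/2} / 2^mu)
        inv_mu = math.exp((config.noise_sd * LN2) ** 2 / 2) / 2.0 ** mu_gene_log2[gi]
        var_count_log2 = (inv_mu + config.nb_dispersion) / LN2 ** 2
        kappa = math.sqrt(config.noise_sd ** 2
                          / (config.noise_sd ** 2 + var_count_log2 + v_t))
        rho_pearson = 2.0 * math.sin(math.pi * e.target_r / 6.0)
        rho = min(rho_pearson / kappa, 0.99)
        if rho > e.target_r + 0.25:
            logger.warning("edge %s-%s: heavy count-noise attenuation; latent "
                           "correlation raised to %.3f", e.mrna_id, e.mirna_id, rho)
        z_mirna[mi] = (e.sign * rho * z_gene[gi]
                       + math.sqrt(1 - rho ** 2) * rng.standard_normal(n))
    return z_mirna, z_gene


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _censoring_horizon(rates: np.ndarray, censoring_rate: float) -> float:
    """Administrative horizon U such that Uniform(0, U) censoring yields the
    requested average censoring probability (bisection; deterministic)."""

    def mean_cens(u: float) -> float:
        lu = rates * u
        return float(np.mean((1.0 - np.exp(-lu)) / lu))

    lo, hi = 1e-6, 1e3 / np.median(rates)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_cens(mid) > censoring_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(config: SimConfig) -> MultiOmicsCohort:
    """Simulate one multi-omics cohort from a :class:`SimConfig`.

    Deterministic for a fixed (config, seed): two calls produce identical
    matrices. See the module docstring for the generative model.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    if n < 4:
        logger.warning("only %d samples: correlation inference will be underpowered", n)
    samples = [f"S{i:04d}" for i in range(1, n + 1)]
    # first block: miRNA-only, middle: shared, last: mRNA-only
    mirna_samples = samples[:config.n_mirna_samples]
    mrna_samples = samples[config.n_mirna_samples - config.n_shared_samples:]
    mirnas = mirna_names(config.n_mirna)
    genes = gene_names(config.n_mrna)

    membership = _assign_structure(config, mirnas, genes, rng)

    # per-gene baseline log2 mean counts; edge genes kept well expressed so
    # count noise does not drown the planted correlation
    # median ~256 counts/gene: a 113-gene panel's share of a standard
    # mRNA-seq library; shallower means would leave TMM-visible composition
    # artifacts no count pipeline can normalize away
    mu_gene = rng.normal(8.0, 1.5, size=len(genes))
    edge_gene_idx = {genes.index(e.mrna_id) for e in config.edge_specs}
    for gi in edge_gene_idx:
        mu_gene[gi] = max(mu_gene[gi], rng.normal(8.5, 0.5))
    gene_lengths = pd.Series(rng.uniform(0.3, 10.0, size=len(genes)),
                             index=genes, name="length_kb")

    z_mirna, z_gene = _latent_matrix(config, mirnas, genes, membership, mu_gene,
                                     gene_lengths.to_numpy(), rng)

    # ----- clinical covariates and batches --------------------------------
    batch_labels = [f"B{1 + i % config.n_batches}" for i in range(n)]
    batch_labels = list(rng.permutation(batch_labels))
    pT = rng.choice(["pT1", "pT2", "pT3"], size=n, p=[0.5, 0.4, 0.1])
    pN = rng.choice(["N0", "N1"], size=n, p=[0.56, 0.44])
    stage = rng.choice(["I", "II", "IIIA"], size=n, p=[0.4, 0.5, 0.1])
    subtype = rng.choice(["luminal A", "luminal B"], size=n, p=[0.4, 0.6])
    binaries = {c: rng.choice([0, 1], size=n, p=pr) for c, pr in
                (("PR", (0.2, 0.8)), ("ER", (0.02, 0.98)), ("ERBB2", (0.85, 0.15)),
                 ("Ki67", (0.45, 0.55)), ("menopause", (0.35, 0.65)))}

    # ----- variants -------------------------------------------------------
    spec_genes = set().union(*(set(s.genes) for s in config.mutation_specs)) \
        if config.mutation_specs else set()
    variant_rows = []
    mutated_samples: dict[str, list[str]] = {}
    for spec in config.mutation_specs:
        k = max(1, round(spec.mutated_fraction * n))
        chosen = sorted(rng.choice(samples, size=k, replace=False))
        mutated_samples[spec.label] = chosen
        for s in chosen:
            n_var = 1 + rng.poisson(0.3)
            for _ in range(n_var):
                variant_rows.append({
                    "sample_id": s,
                    "gene_symbol": str(rng.choice(spec.genes)),
                    "variant_class": str(rng.choice(VARIANT_CLASSES)),
                })
    background_genes = sorted(set(genes) - spec_genes)
    if background_genes:
        for s in samples:
            if rng.random() < 0.05:
                variant_rows.append({
                    "sample_id": s,
                    "gene_symbol": str(rng.choice(background_genes)),
                    "variant_class": str(rng.choice(VARIANT_CLASSES)),
                })
    variants = pd.DataFrame(variant_rows,
                            columns=["sample_id", "gene_symbol", "variant_class"])
    variants = variants.drop_duplicates().reset_index(drop=True)

    # ----- miRNA intensities ---------------------------------------------
    n_low = round(config.low_expressed_fraction * len(mirnas))
    low_idx = rng.choice(len(mirnas), size=n_low, replace=False)
    baseline = rng.normal(9.0, 1.5, size=len(mirnas))
    baseline[low_idx] = rng.normal(4.5, 1.0, size=n_low)
    batch_shift = rng.normal(0.0, config.batch_shift_sd,
                             size=(config.n_batches, len(mirnas)))
    batch_of = {f"B{b+1}": b for b in range(config.n_batches)}
    shift_per_sample = np.array([batch_shift[batch_of[b]] for b in batch_labels]).T
    mirna_vals = baseline[:, None] + config.noise_sd * z_mirna + shift_per_sample
    mirna_df = pd.DataFrame(mirna_vals, index=mirnas, columns=samples)[mirna_samples]
    detection = mirna_df > config.detection_floor
    mirna = ExpressionMatrix(mirna_df, layer="miRNA", scale="log2",
                             detection=detection)

    # ----- mRNA counts ----------------------------------------------------
    log_mean = mu_gene[:, None] + config.noise_sd * z_gene
    gene_index = {g: i for i, g in enumerate(genes)}
    sample_index = {s: j for j, s in enumerate(samples)}
    true_de: dict[str, dict] = {}
    for spec in config.mutation_specs:
        true_de[spec.label] = dict(spec.affected_genes)
        cols = [sample_index[s] for s in mutated_samples[spec.label]]
        for g, lfc in spec.affected_genes.items():
            log_mean[gene_index[g], cols] += lfc
    for spec in config.clinical_effect_specs:
        level_vals = {"pT": pT, "pN": pN, "stage": stage, "subtype": subtype}
        vals = level_vals.get(spec.column)
        if vals is None:
            raise OxynetError(f"clinical effect on unknown column {spec.column!r}")
        cols = np.flatnonzero(vals == spec.positive_level)
        label = f"{spec.column}={spec.positive_level}"
        true_de[label] = dict(spec.affected_genes)
        mutated_samples[label] = [samples[j] for j in cols]
        for g, lfc in spec.affected_genes.items():
            log_mean[gene_index[g], cols] += lfc

    lib_factor = np.exp(rng.normal(0.0, 0.2, size=n))
    mean_counts = (2.0 ** log_mean) * lib_factor[None, :]
    phi = config.nb_dispersion
    if phi > 0:
        size = 1.0 / phi
        counts = rng.negative_binomial(size, size / (size + mean_counts))
    else:
        counts = rng.poisson(mean_counts)
    counts_df = pd.DataFrame(counts.astype(float), index=genes,
                             columns=samples)[mrna_samples]
    mrna = ExpressionMatrix(counts_df, layer="mRNA", scale="counts")

    # ----- survival -------------------------------------------------------
    spec = config.survival_spec
    lp = np.zeros(n)
    for feat, coef in sorted(spec.coefficients.items()):
        if feat in gene_index:
            sig = z_gene[gene_index[feat]]
        elif feat in set(mirnas):
            sig = z_mirna[mirnas.index(feat)]
        else:
            raise OxynetError(f"survival coefficient on unknown feature {feat!r}")
        lp += coef * (sig - sig.mean()) / sig.std()
    rates = spec.baseline_hazard * np.exp(lp)

    clinical_cols = {"sample_id": samples, "pT": pT, "pN": pN, "stage": stage,
                     "subtype": subtype, **binaries, "batch": batch_labels}
    for endpoint, h_scale in (("DFS", 1.0), ("OS", 0.7)):
        ev_time = rng.exponential(1.0 / (rates * h_scale))
        if spec.censoring_rate > 0:
            horizon = _censoring_horizon(rates * h_scale, spec.censoring_rate)
            cens = rng.uniform(0.0, horizon, size=n)
        else:
            cens = np.full(n, np.inf)
        observed = np.minimum(ev_time, cens)
        clinical_cols[f"{endpoint}_time"] = np.maximum(observed, 1e-3)
        clinical_cols[f"{endpoint}_event"] = (ev_time <= cens).astype(int)
    clinical = pd.DataFrame(clinical_cols)

    truth = PlantedStructure(
        mirna_ids=mirnas, gene_ids=genes,
        mirna_sample_ids=mirna_samples, mrna_sample_ids=mrna_samples,
        cluster_membership=membership,
        true_edges=[[e.mrna_id, e.mirna_id, e.sign, e.target_r]
                    for e in config.edge_specs],
        true_de=true_de,
        mutated_samples=mutated_samples,
        true_log_hazards=dict(spec.coefficients),
        batch_assignments=dict(zip(samples, batch_labels)),
    )
    truth.validate()
    logger.info("simulated cohort: %d miRNA x %d samples, %d mRNA x %d samples "
                "(%d shared), %d variants", len(mirnas), len(mirna_samples),
                len(genes), len(mrna_samples), config.n_shared_samples, len(variants))
    return MultiOmicsCohort(mirna=mirna, mrna=mrna, clinical=clinical,
                            variants=variants, truth=truth,
                            gene_lengths_kb=gene_lengths)


def generate_null_cohort(n_samples: int, n_mirna: int, n_mrna: int,
                         seed: int = 0) -> MultiOmicsCohort:
    """Cohort with all features mutually independent and no planted effects.

    All samples carry both layers (full overlap) and a single batch; used
    for type-I-error and FDR calibration.
    """
    if min(n_samples, n_mirna, n_mrna) < 1:
        raise OxynetError("dimensions must be positive")
    config = SimConfig(
        n_mirna_samples=n_samples, n_mrna_samples=n_samples,
        n_shared_samples=n_samples, n_mirna=n_mirna, n_mrna=n_mrna,
        n_batches=1, batch_shift_sd=0.0,
        cluster_specs=(), edge_specs=(), mutation_specs=(),
        clinical_effect_specs=(),
        survival_spec=SurvivalSpec(coefficients={}, censoring_rate=0.4),
        seed=seed,
    )
    return generate_cohort(config)


# ---------------------------------------------------------------------------
# validation cohorts
# ---------------------------------------------------------------------------

VALIDATION_PLAN_CLASSES = ("confirmed_both", "confirmed_one", "not_found",
                           "disputed_one", "disputed_both")

_PLAN_SIGNS = {
    # per class: multiplier of the discovery edge's signed correlation in
    # (validation cohort 1, validation cohort 2); 0 = absent
    "confirmed_both": (1, 1),
    "confirmed_one": (1, 0),
    "not_found": (0, 0),
    "disputed_one": (-1, 0),
    "disputed_both": (-1, -1),
}


def generate_validation_cohorts(truth: PlantedStructure, plan: dict,
                                seeds: tuple[int, int] = (1, 2),
                                n_samples: tuple[int, int] = (157, 374),
                                noise_sd: float = 1.0) -> tuple[MultiOmicsCohort, MultiOmicsCohort]:
    """Build two validation cohorts whose population correlations follow a plan.

    ``plan`` maps (gene, mirna) of a planted discovery edge to one of the
    five replication classes; each cohort then carries the same-signed,
    opposite-signed or zero population correlation for that edge. Both
    layers are emitted as log2-scale matrices with full sample overlap,
    emulating preprocessed public validation data.
    """
    known = {(g, m): (s, r) for g, m, s, r in truth.true_edges}
    for pair, cls in plan.items():
        if tuple(pair) not in known:
            raise OxynetError(f"validation plan references unknown edge {pair}")
        if cls not in VALIDATION_PLAN_CLASSES:
            raise OxynetError(f"unknown validation class {cls!r} for edge {pair}")

    cohorts = []
    for which, (seed, n) in enumerate(zip(seeds, n_samples)):
        rng = np.random.default_rng(seed)
        samples = [f"V{which+1}_{i:04d}" for i in range(1, n + 1)]
        z_gene = rng.standard_normal((len(truth.gene_ids), n))
        z_mirna = rng.standard_normal((len(truth.mirna_ids), n))
        gene_index = {g: i for i, g in enumerate(truth.gene_ids)}
        mirna_index = {m: i for i, m in enumerate(truth.mirna_ids)}
        for (g, m), cls in sorted(plan.items()):
            sign0, rho = known[(g, m)]
            mult = _PLAN_SIGNS[cls][which]
            if mult == 0:
                continue
            s = sign0 * mult
            z_mirna[mirna_index[m]] = (s * rho * z_gene[gene_index[g]]
                                       + math.sqrt(1 - rho ** 2)
                                       * rng.standard_normal(n))
        mirna_vals = (rng.normal(9.0, 1.5, size=len(truth.mirna_ids))[:, None]
                      + noise_sd * z_mirna)
        gene_vals = (rng.normal(8.0, 1.5, size=len(truth.gene_ids))[:, None]
                     + noise_sd * z_gene)
        mirna = ExpressionMatrix(pd.DataFrame(mirna_vals, index=truth.mirna_ids,
                                              columns=samples),
                                 layer="miRNA", scale="log2")
        mrna = ExpressionMatrix(pd.DataFrame(gene_vals, index=truth.gene_ids,
                                             columns=samples),
                                layer="mRNA", scale="log2")
        val_truth = PlantedStructure(
            mirna_ids=list(truth.mirna_ids), gene_ids=list(truth.gene_ids),
            mirna_sample_ids=samples, mrna_sample_ids=samples,
            cluster_membership={}, true_edges=[
                [g, m, known[(g, m)][0] * _PLAN_SIGNS[cls][which],
                 known[(g, m)][1]]
                for (g, m), cls in sorted(plan.items())
                if _PLAN_SIGNS[cls][which] != 0],
            true_de={}, mutated_samples={}, true_log_hazards={},
            batch_assignments={s: "B1" for s in samples},
        )
        clinical = pd.DataFrame({
            "sample_id": samples,
            "OS_time": np.full(n, 1.0), "OS_event": np.zeros(n, int),
            "DFS_time": np.full(n, 1.0), "DFS_event": np.zeros(n, int),
        })
        variants = pd.DataFrame(columns=["sample_id", "gene_symbol", "variant_class"])
        cohorts.append(MultiOmicsCohort(mirna=mirna, mrna=mrna, clinical=clinical,
                                        variants=variants, truth=val_truth))
    return cohorts[0], cohorts[1]


# ---------------------------------------------------------------------------
# interaction-database fixtures
# ---------------------------------------------------------------------------

def generate_database_fixture(true_edges: Sequence[tuple[str, str]],
                              n_decoys: int,
                              n_predicted_dbs: int = 8,
                              n_validated_dbs: int = 3,
                              enrichment: float = 1.0,
                              validated_rate: float = 0.5,
                              genes: Optional[Sequence[str]] = None,
                              mirnas: Optional[Sequence[str]] = None,
                              seed: int = 0) -> list[InteractionDB]:
    """Predicted + validated interaction tables with planted true edges.

    Predicted tables contain every true edge plus ``n_decoys`` decoy pairs;
    with probability ``enrichment`` a true edge's score is drawn above the
    decoy range so it survives the top-quintile filter; otherwise its score
    is exchangeable with the decoys. Validated tables include each true edge
    with probability ``validated_rate`` (no scores).
    """
    if n_decoys < 0:
        raise OxynetError("n_decoys must be >= 0")
    rng = np.random.default_rng(seed)
    true_edges = [tuple(e) for e in true_edges]
    if genes is None:
        genes = sorted({g for g, _ in true_edges} | set(gene_names(40)))
    if mirnas is None:
        mirnas = sorted({m for _, m in true_edges} | set(mirna_names(40)))
    true_set = set(true_edges)
    decoy_pool = [(g, m) for g in genes for m in mirnas if (g, m) not in true_set]
    if n_decoys > len(decoy_pool):
        raise OxynetError(f"cannot draw {n_decoys} decoys from {len(decoy_pool)} pairs")

    dbs: list[InteractionDB] = []
    for d in range(n_predicted_dbs):
        idx = rng.choice(len(decoy_pool), size=n_decoys, replace=False)
        rows = []
        for i in idx:
            g, m = decoy_pool[i]
            rows.append({"gene_symbol": g, "mirna_id": m,
                         "score": rng.uniform(0.0, 0.8)})
        for g, m in true_edges:
            if rng.random() < enrichment:
                score = rng.uniform(0.9, 1.0)
            else:
                score = rng.uniform(0.0, 0.8)
            rows.append({"gene_symbol": g, "mirna_id": m, "score": score})
        dbs.append(InteractionDB(name=f"predicted_{d+1}", kind="predicted",
                                 table=pd.DataFrame(rows)))
    for d in range(n_validated_dbs):
        rows = [{"gene_symbol": g, "mirna_id": m} for g, m in true_edges
                if rng.random() < validated_rate]
        n_val_decoys = min(max(1, n_decoys // 10), len(decoy_pool))
        idx = rng.choice(len(decoy_pool), size=n_val_decoys, replace=False)
        rows += [{"gene_symbol": decoy_pool[i][0], "mirna_id": decoy_pool[i][1]}
                 for i in idx]
        table = pd.DataFrame(rows, columns=["gene_symbol", "mirna_id"]).drop_duplicates()
        dbs.append(InteractionDB(name=f"validated_{d+1}", kind="validated",
                                 table=table))
    return dbs
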