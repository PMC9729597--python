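"""Synthetic multiplex-pedigree exome cohorts with a machine-readable truth.

The generator emulates the statistical structure a familial
serious-mental-illness exome analysis assumes, so every downstream module
can be exercised offline:

* ~75 multi-generation families (founder couple, children, in-marrying
  spouses, grandchildren), a designated subset guaranteed to contribute
  >= 3 sequenced cases ("multi-sample" families), and 60 unrelated
  population controls;
* Mendelian gene-dropping of founder alleles for both a rare exome-wide
  variant panel (~10^2 rare carriers per sample) and a common-variant
  panel used for kinship/PCA, with founders drawn from three diverged
  sub-populations (Balding-Nichols drift) to create broad ancestry
  clusters;
* a liability-threshold phenotype with a family-level random effect
  producing familial aggregation, plus planted rare predicted-deleterious
  variants with configurable penetrance (penetrance-1 carriers are always
  affected) concentrated in a designated "CNS" gene subset;
* annotation fields shaped like the real inputs: panel allele frequencies
  drawn by binomial sampling around the true frequency (ultra-rare alleles
  land on exact zero / panel-absent), consequence classes, five predictor
  calls with class-dependent deleteriousness probability and missingness.

Everything is deterministic under the config seed, and :func:`emit`
round-trips through the VCF/PED readers byte-consistently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING_GT,
    PREDICTOR_NAMES,
    AnnotatedVariant,
    Cohort,
    Consequence,
    Diagnosis,
    PredictorCall,
    Role,
    Sample,
)

__all__ = [
    "PlantedVariant",
    "SimulationConfig",
    "SimulatedData",
    "TruthTable",
    "simulate",
    "simulate_pedigrees",
    "gene_drop",
    "assign_phenotypes",
    "generate_annotations",
    "emit",
    "random_gene_sets",
]


@dataclass(frozen=True)
class PlantedVariant:
    """A causal variant planted into specific families.

    ``maf_annotated`` is what the panels report for it (0.0 means
    panel-absent, written as missing); ``consequence`` must satisfy the
    rare-predicted-deleterious definition by construction.
    """

    gene: str
    penetrance: float
    carrier_families: tuple[str, ...]
    maf_annotated: float = 0.0
    consequence: Consequence = Consequence.STOPGAIN
    min_carriers_per_family: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Study-condition knobs of the synthetic cohort.

    Defaults emulate the familial design the analysis is built for:
    75 families of which 16 are multi-sample (>= 3 sequenced cases),
    sequenced cases per family in 1..6 with median 2, and 60 unrelated
    controls; roughly 2x10^4 rare exome variants over 1,000 genes of
    which 120 form the synthetic "CNS" set.
    """

    n_families: int = 75
    n_multisample_families: int = 16
    n_unrelated_controls: int = 60
    children_range: tuple[int, int] = (3, 5)
    grandchildren_range: tuple[int, int] = (0, 3)
    max_sequenced_cases: int = 6
    family_control_prob: float = 0.75  # multi-sample family has >= 1 control
    n_genes: int = 1000
    n_cns_genes: int = 120
    variants_per_gene: int = 20
    rare_freq_range: tuple[float, float] = (2e-5, 8e-3)  # log-uniform
    n_common_variants: int = 3000
    common_freq_range: tuple[float, float] = (0.05, 0.5)
    fst: float = 0.05
    n_subpops: int = 3
    panel_size_sas: int = 15308
    panel_size_global: int = 70000
    baseline_prevalence: float = 0.01
    family_effect_var: float = 0.5
    planted_variants: tuple[PlantedVariant, ...] | None = None  # None = defaults
    planted_cns_fraction: float = 0.75
    predictor_deleterious_probability: dict | None = None
    annotation_missingness_rate: float = 0.05
    diagnosis_probs: tuple[float, ...] = (0.35, 0.35, 0.15, 0.15)  # SCZ/BD/OCD/SUD
    seed: int = 17

    def __post_init__(self) -> None:
        if self.n_multisample_families > self.n_families:
            raise ValueError("n_multisample_families cannot exceed n_families")
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must be in (0, 1)")
        if self.n_cns_genes > self.n_genes:
            raise ValueError("n_cns_genes cannot exceed n_genes")

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    @property
    def cns_genes(self) -> list[str]:
        return self.gene_names[: self.n_cns_genes]


#: Consequence-class proportions of background exome variants.
_CSQ_PROBS = {
    Consequence.SYNONYMOUS: 0.36,
    Consequence.MISSENSE: 0.44,
    Consequence.OTHER: 0.10,
    Consequence.STOPGAIN: 0.02,
    Consequence.STOPLOSS: 0.004,
    Consequence.STARTLOSS: 0.004,
    Consequence.CANONICAL_SPLICE: 0.012,
    Consequence.FRAMESHIFT_INDEL: 0.03,
    Consequence.INFRAME_INDEL: 0.03,
}

#: Per-class probability that one predictor calls the variant deleterious.
_DEFAULT_DELET_PROB = {
    Consequence.MISSENSE: 0.30,
    Consequence.SYNONYMOUS: 0.02,
    Consequence.OTHER: 0.05,
}


@dataclass
class _Member:
    """One pedigree member (sequenced or not)."""

    member_id: str
    family_id: str
    father: int | None  # index within the family member list
    mother: int | None
    sex: int
    subpop: int
    generation: int


@dataclass
class _Family:
    family_id: str
    members: list[_Member]
    multisample: bool


@dataclass
class TruthTable:
    """Ground truth emitted alongside the synthetic cohort."""

    variants: pd.DataFrame  # vid, gene, true_freq, planted, penetrance, ...
    genes: pd.DataFrame  # gene, cns
    samples: pd.DataFrame  # sample_id, family, role, liability, affected, diagnosis


@dataclass
class SimulatedData:
    """In-memory bundle: cohort, annotated variants, common panel, truth."""

    cohort: Cohort
    variants: list[AnnotatedVariant]
    common_genotypes: np.ndarray  # (n_samples, n_common) dosages
    truth: TruthTable
    config: SimulationConfig


# -- pedigree structure ------------------------------------------------------


def _build_family(
    family_id: str, subpop: int, rng: np.random.Generator, cfg: SimulationConfig
) -> _Family:
    members: list[_Member] = []

    def add(father, mother, sex, generation) -> int:
        idx = len(members)
        members.append(
            _Member(
                member_id=f"{family_id}_{idx:02d}",
                family_id=family_id,
                father=father,
                mother=mother,
                sex=sex,
                subpop=subpop,
                generation=generation,
            )
        )
        return idx

    f0 = add(None, None, 1, 0)
    m0 = add(None, None, 2, 0)
    n_children = rng.integers(cfg.children_range[0], cfg.children_range[1] + 1)
    for _ in range(n_children):
        child_sex = int(rng.integers(1, 3))
        c = add(f0, m0, child_sex, 1)
        if rng.random() < 0.5:
            spouse_sex = 3 - child_sex
            s = add(None, None, spouse_sex, 1)  # marries in: founder
            lo, hi = cfg.grandchildren_range
            for _ in range(rng.integers(lo, hi + 1)):
                father_i, mother_i = (c, s) if child_sex == 1 else (s, c)
                add(father_i, mother_i, int(rng.integers(1, 3)), 2)
    return _Family(family_id=family_id, members=members, multisample=False)


def simulate_pedigrees(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[_Family]:
    """Generate the family structures (members, links) without genotypes.

    The first ``n_multisample_families`` are flagged for the >= 3 sequenced
    case guarantee enforced later by variant planting.
    """
    rng = rng or np.random.default_rng(config.seed)
    families = []
    for i in range(config.n_families):
        subpop = int(i % config.n_subpops)
        fam = _build_family(f"F{i + 1:03d}", subpop, rng, config)
        fam.multisample = i < config.n_multisample_families
        families.append(fam)
    return families


# -- gene dropping -----------------------------------------------------------


def gene_drop(
    fathers: np.ndarray,
    mothers: np.ndarray,
    founder_freqs: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Drop alleles down one pedigree.

    ``fathers``/``mothers`` are per-member parent indices (-1 for
    founders) where parents must appear before children; ``founder_freqs``
    gives the per-variant allele frequency founders are drawn from in
    Hardy-Weinberg proportions. Returns an (n_members, m, 2) allele array.
    """
    n = fathers.size
    m = founder_freqs.size
    if np.any((fathers >= np.arange(n)) & (fathers >= 0)) or np.any(
        (mothers >= np.arange(n)) & (mothers >= 0)
    ):
        raise ValueError("pedigree is not topologically ordered (cycle?)")
    alleles = np.zeros((n, m, 2), dtype=np.int8)
    for i in range(n):
        if fathers[i] < 0:
            alleles[i, :, 0] = rng.random(m) < founder_freqs
            alleles[i, :, 1] = rng.random(m) < founder_freqs
        else:
            pick_f = rng.integers(0, 2, size=m)
            pick_m = rng.integers(0, 2, size=m)
            alleles[i, :, 0] = alleles[fathers[i], np.arange(m), pick_f]
            alleles[i, :, 1] = alleles[mothers[i], np.arange(m), pick_m]
    return alleles


def _drop_family(
    fam: _Family, founder_freqs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    fathers = np.array([-1 if m.father is None else m.father for m in fam.members])
    mothers = np.array([-1 if m.mother is None else m.mother for m in fam.members])
    return gene_drop(fathers, mothers, founder_freqs, rng)


def _plant_in_family(
    fam: _Family, min_carriers: int, rng: np.random.Generator, max_tries: int = 2000
) -> np.ndarray:
    """Place one heterozygous founder allele and re-drop until at least
    ``min_carriers`` family members carry it."""
    fathers = np.array([-1 if m.father is None else m.father for m in fam.members])
    mothers = np.array([-1 if m.mother is None else m.mother for m in fam.members])
    n = len(fam.members)
    for _ in range(max_tries):
        alleles = np.zeros((n, 1, 2), dtype=np.int8)
        founder_rows = np.where(fathers < 0)[0]
        seed_founder = founder_rows[0]  # pedigree patriarch
        alleles[seed_founder, 0, rng.integers(0, 2)] = 1
        for i in range(n):
            if fathers[i] < 0:
                continue
            alleles[i, 0, 0] = alleles[fathers[i], 0, rng.integers(0, 2)]
            alleles[i, 0, 1] = alleles[mothers[i], 0, rng.integers(0, 2)]
        carriers = alleles.sum(axis=2)[:, 0] >= 1
        if carriers.sum() >= min_carriers:
            return carriers
    raise RuntimeError(
        f"could not plant {min_carriers} carriers in family {fam.family_id} "
        f"({n} members)"
    )


# -- phenotypes --------------------------------------------------------------


def assign_phenotypes(
    families: list[_Family],
    planted_carrier: dict[str, np.ndarray],  # member_id -> per-planted bool
    planted_penetrance: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, bool], dict[str, float], dict[str, Diagnosis]]:
    """Liability-threshold affection with a family random effect.

    liability = family effect + N(0,1) noise; affected when the liability
    exceeds the threshold set by ``baseline_prevalence`` on the marginal
    scale. Carriers of a planted variant are additionally affected with
    probability equal to its penetrance (probability 1 when penetrance is
    1). Families are ascertained: liabilities are re-drawn until the
    family reaches its recruitment minimum of affected members (most
    families were recruited through >= 2 affected relatives), emulating
    proband-driven sampling.
    """
    from scipy.stats import norm

    thresh = norm.ppf(1 - config.baseline_prevalence) * math.sqrt(
        config.family_effect_var + 1.0
    )
    affected: dict[str, bool] = {}
    liability: dict[str, float] = {}
    diagnosis: dict[str, Diagnosis] = {}
    diag_labels = [Diagnosis.SCZ, Diagnosis.BD, Diagnosis.OCD, Diagnosis.SUD]

    for fam in families:
        ids = [m.member_id for m in fam.members]
        planted_hit = np.zeros(len(ids), dtype=bool)
        for j, mid in enumerate(ids):
            carr = planted_carrier.get(mid)
            if carr is not None and carr.any():
                pen = planted_penetrance[carr].max()
                planted_hit[j] = rng.random() < pen
        min_aff = 1 if (planted_hit.sum() >= 2 or rng.random() > 0.7) else 2
        aff = planted_hit.copy()
        liab = np.zeros(len(ids))
        for _ in range(2000):
            a_f = rng.normal(0.0, math.sqrt(config.family_effect_var))
            liab = a_f + rng.normal(0.0, 1.0, size=len(ids))
            aff = (liab > thresh) | planted_hit
            if aff.sum() >= min_aff:
                break
        else:
            # fall back to the single-proband minimum
            aff[int(np.argmax(liab))] = True
        for j, mid in enumerate(ids):
            affected[mid] = bool(aff[j])
            liability[mid] = float(liab[j])
            if aff[j]:
                diagnosis[mid] = diag_labels[
                    rng.choice(len(diag_labels), p=config.diagnosis_probs)
                ]
    return affected, liability, diagnosis


# -- annotations -------------------------------------------------------------


def _panel_maf(
    true_freq: np.ndarray, panel_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Reference-panel allele frequency: binomial resampling of 2N panel
    chromosomes around the true frequency (ultra-rare alleles give exact
    zeros, i.e. panel absence)."""
    counts = rng.binomial(2 * panel_size, true_freq)
    return counts / (2 * panel_size)


def generate_annotations(
    true_freqs: np.ndarray,
    genes: list[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw consequence classes, panel MAFs and predictor calls for the
    background variant panel."""
    m = true_freqs.size
    csq_classes = list(_CSQ_PROBS)
    csq = rng.choice(
        len(csq_classes), size=m, p=np.array(list(_CSQ_PROBS.values()))
    )
    consequences = [csq_classes[i] for i in csq]

    maf_sas = _panel_maf(true_freqs, config.panel_size_sas, rng)
    maf_global = _panel_maf(true_freqs, config.panel_size_global, rng)
    # a slice of sites simply lacks the frequency annotation
    sas_missing = rng.random(m) < config.annotation_missingness_rate
    glob_missing = rng.random(m) < config.annotation_missingness_rate

    delet_prob = dict(_DEFAULT_DELET_PROB)
    if config.predictor_deleterious_probability:
        delet_prob.update(config.predictor_deleterious_probability)

    npred = len(PREDICTOR_NAMES)
    p_del = np.array([delet_prob.get(c, 0.05) for c in consequences])
    miss = rng.random((m, npred)) < config.annotation_missingness_rate
    delet = rng.random((m, npred)) < p_del[:, None]
    call_of = {
        0: PredictorCall.TOLERATED,
        1: PredictorCall.DELETERIOUS,
        2: PredictorCall.MISSING,
    }
    codes = np.where(miss, 2, delet.astype(int))
    predictors = [tuple(call_of[c] for c in row) for row in codes]

    return pd.DataFrame(
        {
            "gene": genes,
            "consequence": consequences,
            "true_freq": true_freqs,
            "maf_sas": [
                None if sas_missing[i] else float(maf_sas[i]) for i in range(m)
            ],
            "maf_global": [
                None if glob_missing[i] else float(maf_global[i]) for i in range(m)
            ],
            "predictors": predictors,
        }
    )


# -- top-level generator -----------------------------------------------------


def _default_planted(
    families: list[_Family], cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[PlantedVariant, ...]:
    """One fully penetrant variant per multi-sample family, concentrated
    in the synthetic CNS gene set."""
    multis = [f.family_id for f in families if f.multisample]
    n = len(multis)
    n_cns = int(round(cfg.planted_cns_fraction * n))
    cns_pick = rng.choice(cfg.n_cns_genes, size=min(n_cns, cfg.n_cns_genes), replace=False)
    other_pool = np.arange(cfg.n_cns_genes, cfg.n_genes)
    other_pick = rng.choice(other_pool, size=n - len(cns_pick), replace=False)
    gene_idx = list(cns_pick) + list(other_pick)
    genes = [cfg.gene_names[i] for i in gene_idx]
    csqs = [Consequence.STOPGAIN, Consequence.FRAMESHIFT_INDEL, Consequence.MISSENSE]
    return tuple(
        PlantedVariant(
            gene=genes[i],
            penetrance=1.0,
            carrier_families=(multis[i],),
            consequence=csqs[i % len(csqs)],
        )
        for i in range(n)
    )


def simulate(config: SimulationConfig | None = None) -> SimulatedData:
    """Generate a full synthetic cohort under the config seed."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)

    families = simulate_pedigrees(cfg, rng)
    planted = (
        cfg.planted_variants
        if cfg.planted_variants is not None
        else _default_planted(families, cfg, rng)
    )

    # ---- background rare panel
    m_rare = cfg.n_genes * cfg.variants_per_gene
    lo, hi = cfg.rare_freq_range
    rare_freqs = np.exp(rng.uniform(math.log(lo), math.log(hi), size=m_rare))
    gene_names = cfg.gene_names
    rare_genes = [gene_names[i // cfg.variants_per_gene] for i in range(m_rare)]

    # ---- common panel with Balding-Nichols subpopulation drift
    p_anc = rng.uniform(*cfg.common_freq_range, size=cfg.n_common_variants)
    a = p_anc * (1 - cfg.fst) / cfg.fst
    b = (1 - p_anc) * (1 - cfg.fst) / cfg.fst
    subpop_freqs = np.stack(
        [np.clip(rng.beta(a, b), 0.01, 0.99) for _ in range(cfg.n_subpops)]
    )

    # ---- genotypes per family (rare + common dropped together)
    member_rows: dict[str, np.ndarray] = {}
    member_rows_common: dict[str, np.ndarray] = {}
    planted_carrier: dict[str, np.ndarray] = {}
    fam_by_id = {f.family_id: f for f in families}
    n_planted = len(planted)

    for fam in families:
        drop = _drop_family(fam, rare_freqs, rng)
        common = _drop_family(fam, subpop_freqs[fam.members[0].subpop], rng)
        carr = np.zeros((len(fam.members), n_planted), dtype=bool)
        for pi, pv in enumerate(planted):
            if fam.family_id in pv.carrier_families:
                carr[:, pi] = _plant_in_family(
                    fam, pv.min_carriers_per_family, rng
                )
        for j, memb in enumerate(fam.members):
            member_rows[memb.member_id] = drop[j].sum(axis=1)
            member_rows_common[memb.member_id] = common[j].sum(axis=1)
            planted_carrier[memb.member_id] = carr[j]

    # ---- phenotypes
    penetrances = np.array([pv.penetrance for pv in planted])
    affected, liability, diagnosis = assign_phenotypes(
        families, planted_carrier, penetrances, cfg, rng
    )

    # ---- sequencing selection and roles
    samples: list[Sample] = []
    for fam in families:
        aff_ids = [m.member_id for m in fam.members if affected[m.member_id]]
        unaff_ids = [m.member_id for m in fam.members if not affected[m.member_id]]
        # affected planted carriers are always sequenced so the segregation
        # signal survives the subsampling
        carriers_aff = [mid for mid in aff_ids if planted_carrier[mid].any()]
        others = [mid for mid in aff_ids if mid not in carriers_aff]
        if fam.multisample:
            target = cfg.max_sequenced_cases
            n_fc = 0
            if unaff_ids and rng.random() < cfg.family_control_prob:
                n_fc = int(rng.integers(1, min(2, len(unaff_ids)) + 1))
        else:
            target = max(len(carriers_aff), 2 if rng.random() < 0.8 else 1)
            n_fc = int(rng.random() < 0.3 and len(unaff_ids) > 0)
        case_ids = list(carriers_aff)
        room = target - len(case_ids)
        if room > 0 and others:
            fill = rng.choice(others, size=min(room, len(others)), replace=False)
            case_ids.extend(str(x) for x in fill)
        case_ids = case_ids[: cfg.max_sequenced_cases]
        fc_ids = (
            [str(x) for x in rng.choice(unaff_ids, size=n_fc, replace=False)]
            if n_fc
            else []
        )
        sequenced = set(case_ids) | set(fc_ids)
        id_by_member = {m.member_id: m for m in fam.members}
        for mid in sorted(sequenced):
            memb = id_by_member[mid]
            father = memb.father
            mother = memb.mother
            father_id = (
                fam.members[father].member_id
                if father is not None
                and fam.members[father].member_id in sequenced
                else None
            )
            mother_id = (
                fam.members[mother].member_id
                if mother is not None
                and fam.members[mother].member_id in sequenced
                else None
            )
            is_case = mid in case_ids
            samples.append(
                Sample(
                    sample_id=mid,
                    family_id=fam.family_id,
                    father_id=father_id,
                    mother_id=mother_id,
                    sex=memb.sex,
                    affected=affected[mid],
                    role=Role.CASE if is_case else Role.FAMILY_CONTROL,
                    diagnosis=diagnosis.get(mid) if is_case else None,
                )
            )

    # ---- unrelated controls: unaffected draws from the subpopulations
    thresh_sd = math.sqrt(cfg.family_effect_var + 1.0)
    from scipy.stats import norm

    thresh = norm.ppf(1 - cfg.baseline_prevalence) * thresh_sd
    uc_rare: list[np.ndarray] = []
    uc_common: list[np.ndarray] = []
    for i in range(cfg.n_unrelated_controls):
        uid = f"UC{i + 1:03d}"
        while True:
            liab = rng.normal(0.0, thresh_sd)
            if liab <= thresh:
                break
        liability[uid] = float(liab)
        affected[uid] = False
        subpop = i % cfg.n_subpops
        uc_rare.append(rng.binomial(2, rare_freqs).astype(np.int8))
        uc_common.append(
            rng.binomial(2, subpop_freqs[subpop]).astype(np.int8)
        )
        samples.append(
            Sample(
                sample_id=uid,
                family_id="",
                sex=int(rng.integers(1, 3)),
                affected=False,
                role=Role.UNRELATED_CONTROL,
            )
        )

    cohort = Cohort(samples=samples)
    n = len(cohort)

    # ---- assemble genotype matrices in cohort order
    rare_G = np.zeros((n, m_rare), dtype=np.int8)
    common_G = np.zeros((n, cfg.n_common_variants), dtype=np.int8)
    planted_G = np.zeros((n, n_planted), dtype=np.int8)
    uc_i = 0
    for i, s in enumerate(cohort.samples):
        if s.role is Role.UNRELATED_CONTROL:
            rare_G[i] = uc_rare[uc_i]
            common_G[i] = uc_common[uc_i]
            uc_i += 1
        else:
            rare_G[i] = member_rows[s.sample_id]
            common_G[i] = member_rows_common[s.sample_id]
            planted_G[i] = planted_carrier[s.sample_id].astype(np.int8)

    # sporadic missing genotype calls in the rare panel
    miss_mask = rng.random(rare_G.shape) < 0.002
    rare_G = np.where(miss_mask, np.int8(MISSING_GT), rare_G)

    # ---- annotations and AnnotatedVariant assembly
    ann = generate_annotations(rare_freqs, rare_genes, cfg, rng)
    variants: list[AnnotatedVariant] = []
    truth_rows = []
    chrom_of = lambda g: f"chr{(int(g[1:]) % 22) + 1}"  # noqa: E731
    pos_counter: dict[str, int] = {}

    def next_pos(chrom: str) -> int:
        pos_counter[chrom] = pos_counter.get(chrom, 10_000) + 137
        return pos_counter[chrom]

    csq_col = ann["consequence"].tolist()
    maf_sas_col = ann["maf_sas"].tolist()
    maf_glob_col = ann["maf_global"].tolist()
    pred_col = ann["predictors"].tolist()
    for i in range(m_rare):
        gene = rare_genes[i]
        chrom = chrom_of(gene)
        pos = next_pos(chrom)
        csq = csq_col[i]
        maf_s = maf_sas_col[i]
        maf_g = maf_glob_col[i]
        maf_s = None if maf_s is None or maf_s != maf_s else float(maf_s)
        maf_g = None if maf_g is None or maf_g != maf_g else float(maf_g)
        ref, alt = ("AC", "A") if "indel" in csq.value else ("A", "G")
        v = AnnotatedVariant(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            gene=gene,
            consequence=csq,
            maf_sas=maf_s,
            maf_global=maf_g,
            predictor_calls=pred_col[i],
            genotypes=rare_G[:, i],
        )
        variants.append(v)
        truth_rows.append(
            {
                "vid": v.vid,
                "gene": gene,
                "true_freq": float(rare_freqs[i]),
                "planted": False,
                "penetrance": np.nan,
                "consequence": csq.value,
                "n_carriers": int((rare_G[:, i] >= 1).sum()),
            }
        )

    for pi, pv in enumerate(planted):
        chrom = chrom_of(pv.gene)
        pos = next_pos(chrom)
        if pv.consequence is Consequence.MISSENSE:
            calls = tuple([PredictorCall.DELETERIOUS] * 5)
        else:
            calls = tuple([PredictorCall.MISSING] * 5)
        maf = None if pv.maf_annotated == 0.0 else pv.maf_annotated
        ref, alt = ("AC", "A") if "indel" in pv.consequence.value else ("C", "T")
        v = AnnotatedVariant(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            gene=pv.gene,
            consequence=pv.consequence,
            maf_sas=maf,
            maf_global=maf,
            predictor_calls=calls,
            genotypes=planted_G[:, pi],
        )
        variants.append(v)
        truth_rows.append(
            {
                "vid": v.vid,
                "gene": pv.gene,
                "true_freq": 0.0,
                "planted": True,
                "penetrance": pv.penetrance,
                "consequence": pv.consequence.value,
                "n_carriers": int((planted_G[:, pi] >= 1).sum()),
            }
        )

    truth = TruthTable(
        variants=pd.DataFrame(truth_rows),
        genes=pd.DataFrame(
            {
                "gene": cfg.gene_names,
                "cns": [g in set(cfg.cns_genes) for g in cfg.gene_names],
            }
        ),
        samples=pd.DataFrame(
            {
                "sample_id": cohort.sample_ids,
                "family": [s.family_id for s in cohort.samples],
                "role": [s.role.value for s in cohort.samples],
                "affected": [s.affected for s in cohort.samples],
                "liability": [liability[s.sample_id] for s in cohort.samples],
                "diagnosis": [
                    s.diagnosis.value if s.diagnosis else "" for s in cohort.samples
                ],
            }
        ),
    )
    return SimulatedData(
        cohort=cohort,
        variants=variants,
        common_genotypes=common_G.astype(np.int8),
        truth=truth,
        config=replace(cfg, planted_variants=planted),
    )


def simulate_null_family_cohort(
    n_families: int = 50,
    family_size: int = 4,
    m_rare: int = 20,
    m_common: int = 6000,
    rare_freq: tuple[float, float] = (0.005, 0.03),
    prevalence: float = 0.3,
    family_effect_var: float = 1.0,
    rng: np.random.Generator | None = None,
) -> dict:
    """Small nuclear-family cohort with NO genotype-phenotype association.

    Families are founder couples with ``family_size - 2`` children; both a
    common panel (for kinship) and a rare panel (the test unit) are
    gene-dropped, so genotypes carry the family correlation, and the
    binary phenotype gets its own family random effect — phenotypic and
    genotypic clustering coincide without any causal link. This is the
    null world for type-I-error calibration of the kinship-adjusted score
    test (an unadjusted test on the same data is inflated).

    Returns a dict with ``y``, ``rare`` (n, m_rare), ``common``
    (n, m_common) and ``family`` labels.
    """
    from scipy.stats import norm

    rng = rng or np.random.default_rng()
    n_kids = family_size - 2
    freqs_c = rng.uniform(0.1, 0.9, m_common)
    freqs_r = rng.uniform(*rare_freq, m_rare)
    fathers = np.array([-1, -1] + [0] * n_kids)
    mothers = np.array([-1, -1] + [1] * n_kids)
    common_rows, rare_rows, fam = [], [], []
    for f in range(n_families):
        ac = gene_drop(fathers, mothers, freqs_c, rng).sum(axis=2)
        ar = gene_drop(fathers, mothers, freqs_r, rng).sum(axis=2)
        common_rows.append(ac)
        rare_rows.append(ar)
        fam.extend([f] * family_size)
    common = np.vstack(common_rows)
    rare = np.vstack(rare_rows)
    fam = np.asarray(fam)
    thresh = norm.ppf(1 - prevalence) * math.sqrt(family_effect_var + 1.0)
    a_f = rng.normal(0.0, math.sqrt(family_effect_var), n_families)
    liab = a_f[fam] + rng.normal(0.0, 1.0, fam.size)
    y = (liab > thresh).astype(float)
    return {"y": y, "rare": rare, "common": common, "family": fam}


def random_gene_sets(
    universe: list[str],
    n_sets: int,
    set_size: int,
    rng: np.random.Generator,
    prefix: str = "set",
):
    """Draw disjoint-seeded random gene sets from a universe (for
    specificity-scan null experiments)."""
    from .datamodel import GeneSet

    out = []
    for i in range(n_sets):
        genes = rng.choice(universe, size=set_size, replace=False)
        out.append(
            GeneSet(
                name=f"{prefix}{i + 1}",
                genes=frozenset(genes),
                universe_size=len(universe),
            )
        )
    return out


# -- file emission -----------------------------------------------------------

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING_GT: "./."}


def emit(data: SimulatedData, outdir: str | Path) -> dict[str, Path]:
    """Write VCF, 7-column PED, gene lists and the truth table.

    Files parse back through :mod:`pedseg.io` into an identical in-memory
    model (same variants, genotypes and cohort).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "ped": outdir / "cohort.ped",
        "cns_genes": outdir / "cns_genes.txt",
        "all_genes": outdir / "all_genes.txt",
        "truth_variants": outdir / "truth_variants.tsv",
        "truth_samples": outdir / "truth_samples.tsv",
    }

    cohort = data.cohort
    contigs = sorted(
        {v.chrom for v in data.variants}, key=lambda c: int(c.replace("chr", ""))
    )
    header = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c}>" for c in contigs],
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">',
        '##INFO=<ID=AF_SAS,Number=1,Type=Float,Description="Panel AF, South Asian">',
        '##INFO=<ID=AF_GLOBAL,Number=1,Type=Float,Description="Panel AF, global">',
    ]
    for key in ("SIFT", "LRT", "MT", "MA", "MSVM"):
        header.append(
            f'##INFO=<ID={key},Number=1,Type=String,Description="Predictor call">'
        )
    header.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(cohort.sample_ids)
    )

    def chrom_rank(c: str) -> int:
        return int(c.replace("chr", ""))

    body = []
    pred_keys = ("SIFT", "LRT", "MT", "MA", "MSVM")
    for v in sorted(data.variants, key=lambda v: (chrom_rank(v.chrom), v.pos, v.alt)):
        info = [f"GENE={v.gene}", f"CSQ={v.consequence.value}"]
        if v.maf_sas is not None:
            info.append(f"AF_SAS={v.maf_sas:.6g}")
        if v.maf_global is not None:
            info.append(f"AF_GLOBAL={v.maf_global:.6g}")
        for key, call in zip(pred_keys, v.predictor_calls):
            if call is not PredictorCall.MISSING:
                info.append(f"{key}={call.value}")
        gts = "\t".join(_GT_STR[int(g)] for g in v.genotypes)
        body.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
            + ";".join(info)
            + f"\tGT\t{gts}"
        )
    paths["vcf"].write_text("\n".join(header + body) + "\n")

    ped_lines = []
    for s in cohort.samples:
        ped_lines.append(
            "\t".join(
                [
                    s.family_id or "0",
                    s.sample_id,
                    s.father_id or "0",
                    s.mother_id or "0",
                    str(s.sex),
                    "2" if s.affected else "1",
                    s.role.value,
                    s.diagnosis.value if s.diagnosis else ".",
                ]
            )
        )
    paths["ped"].write_text("\n".join(ped_lines) + "\n")

    paths["cns_genes"].write_text("\n".join(data.config.cns_genes) + "\n")
    paths["all_genes"].write_text("\n".join(data.config.gene_names) + "\n")
    data.truth.variants.to_csv(paths["truth_variants"], sep="\t", index=False)
    data.truth.samples.to_csv(paths["truth_samples"], sep="\t", index=False)
    return paths
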