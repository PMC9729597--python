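"""Within-pedigree prioritization of segregating RPD variants.

Two nested tiers of evidence:

* **shared-broad (sb-RPD)** — an RPD variant carried by >= 3 affected,
  sequenced members of one multiplex family and by zero unrelated
  population controls.
* **shared-stringent (ss-RPD)** — an sb-RPD variant that additionally
  passes the stringent rarity threshold (1e-4 in both panels) and is
  carried by at most one unaffected family control, the tolerance for a
  single control carrier allowing for incomplete penetrance.

Only families with >= 3 sequenced cases ("multi-sample" families) are
eligible; a variant may segregate in more than one family and then yields
one result row per family. Carrier status ignores zygosity: heterozygous,
homozygous-alternate and hemizygous genotypes all count as carrying.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .datamodel import AnnotatedVariant, Cohort, Role
from .prioritize import MAF_STRINGENT, RpdCall

__all__ = [
    "Tier",
    "SegregationResult",
    "count_carriers",
    "select_multisample_families",
    "find_shared_broad",
    "find_shared_stringent",
    "cross_family_overlap",
    "gene_summary",
]


class Tier(str, Enum):
    NONE = "none"
    SHARED_BROAD = "shared_broad"
    SHARED_STRINGENT = "shared_stringent"


@dataclass
class SegregationResult:
    """One (variant, family) segregation record."""

    call: RpdCall
    family_id: str
    affected_carriers: int
    affected_sequenced: int
    family_control_carriers: int
    unrelated_control_carriers: int
    tier: Tier

    @property
    def variant(self) -> AnnotatedVariant:
        return self.call.variant


def count_carriers(variant: AnnotatedVariant, cohort: Cohort, sample_ids) -> int:
    """Number of the given samples carrying >= 1 alternate allele.

    Missing genotypes count as non-carriers (presence/absence reading).
    """
    idx = cohort.indices_of(sample_ids)
    if idx.size == 0:
        return 0
    return int((variant.genotypes[idx] >= 1).sum())


def select_multisample_families(cohort: Cohort, min_cases: int = 3) -> list[str]:
    """Families with at least ``min_cases`` sequenced affected members."""
    return sorted(
        fid
        for fid in cohort.families
        if len(cohort.cases_in_family(fid)) >= min_cases
    )


def find_shared_broad(
    rpd_calls: list[RpdCall],
    cohort: Cohort,
    min_shared: int = 3,
) -> list[SegregationResult]:
    """Identify sb-RPD variants: shared by >= min_shared cases of one
    multiplex family and absent from all unrelated controls.

    Returns one result per qualifying (variant, family) pair, sorted by
    (family, chrom, pos, alt) for reproducible output. Family-control and
    unrelated-control carrier counts are recorded for the stringent tier.
    """
    families = select_multisample_families(cohort, min_cases=min_shared)
    uc_ids = [s.sample_id for s in cohort.by_role(Role.UNRELATED_CONTROL)]
    uc_idx = cohort.indices_of(uc_ids)
    fc_all = [s.sample_id for s in cohort.by_role(Role.FAMILY_CONTROL)]
    fc_idx = cohort.indices_of(fc_all)

    fam_case_idx = {
        fid: cohort.indices_of(cohort.cases_in_family(fid)) for fid in families
    }

    results: list[SegregationResult] = []
    for call in rpd_calls:
        gt = call.variant.genotypes
        carrier = gt >= 1
        uc_carriers = int(carrier[uc_idx].sum()) if uc_idx.size else 0
        if uc_carriers > 0:
            continue
        fc_carriers = int(carrier[fc_idx].sum()) if fc_idx.size else 0
        for fid in families:
            case_idx = fam_case_idx[fid]
            n_aff = int(carrier[case_idx].sum())
            if n_aff >= min_shared:
                results.append(
                    SegregationResult(
                        call=call,
                        family_id=fid,
                        affected_carriers=n_aff,
                        affected_sequenced=int(case_idx.size),
                        family_control_carriers=fc_carriers,
                        unrelated_control_carriers=uc_carriers,
                        tier=Tier.SHARED_BROAD,
                    )
                )
    results.sort(
        key=lambda r: (r.family_id, r.variant.chrom, r.variant.pos, r.variant.alt)
    )
    return results


def find_shared_stringent(
    broad_results: list[SegregationResult],
    max_family_control_carriers: int = 1,
    maf_stringent: float = MAF_STRINGENT,
) -> list[SegregationResult]:
    """Upgrade the sb-RPD subset meeting the stringent criteria to ss-RPD.

    The family-control carrier limit is applied across all sequenced
    family controls cohort-wide.
    """
    out: list[SegregationResult] = []
    for r in broad_results:
        if not r.call.passes_rarity_stringent:
            continue
        if r.family_control_carriers > max_family_control_carriers:
            continue
        out.append(
            SegregationResult(
                call=r.call,
                family_id=r.family_id,
                affected_carriers=r.affected_carriers,
                affected_sequenced=r.affected_sequenced,
                family_control_carriers=r.family_control_carriers,
                unrelated_control_carriers=r.unrelated_control_carriers,
                tier=Tier.SHARED_STRINGENT,
            )
        )
    return out


@dataclass
class OverlapReport:
    """Cross-family overlap between segregating hits and the small families."""

    genes_shared: set[str]
    gene_overlap: set[str]
    variant_overlap: set[tuple[str, int, str, str]]
    provenance: pd.DataFrame  # one row per overlap hit with carrier counts


def cross_family_overlap(
    shared_results: list[SegregationResult],
    small_family_rpd: list[RpdCall],
    cohort: Cohort,
) -> OverlapReport:
    """Query the segregating genes/variants against RPDs seen in the
    remaining (< min_shared cases) families.

    ``small_family_rpd`` should be the RPD calls restricted to carriers in
    the excluded small families; a call counts here when at least one case
    from a non-multisample family carries it and no unrelated control does.
    """
    shared_genes = {r.variant.gene for r in shared_results}
    shared_keys = {r.variant.key for r in shared_results}
    multi = set(select_multisample_families(cohort))
    small_case_ids = [
        s.sample_id
        for s in cohort.by_role(Role.CASE)
        if s.family_id and s.family_id not in multi
    ]
    small_idx = cohort.indices_of(small_case_ids)
    uc_idx = cohort.indices_of(
        [s.sample_id for s in cohort.by_role(Role.UNRELATED_CONTROL)]
    )

    gene_overlap: set[str] = set()
    variant_overlap: set[tuple[str, int, str, str]] = set()
    rows = []
    for call in small_family_rpd:
        gt = call.variant.genotypes
        if uc_idx.size and (gt[uc_idx] >= 1).any():
            continue
        n_small = int((gt[small_idx] >= 1).sum()) if small_idx.size else 0
        if n_small == 0:
            continue
        v = call.variant
        hit_gene = v.gene in shared_genes
        hit_variant = v.key in shared_keys
        if hit_gene:
            gene_overlap.add(v.gene)
        if hit_variant:
            variant_overlap.add(v.key)
        if hit_gene or hit_variant:
            rows.append(
                {
                    "gene": v.gene,
                    "variant": v.vid,
                    "small_family_case_carriers": n_small,
                    "gene_level": hit_gene,
                    "variant_level": hit_variant,
                }
            )
    provenance = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "variant",
            "small_family_case_carriers",
            "gene_level",
            "variant_level",
        ],
    )
    return OverlapReport(
        genes_shared=shared_genes,
        gene_overlap=gene_overlap,
        variant_overlap=variant_overlap,
        provenance=provenance,
    )


def gene_summary(shared_results: list[SegregationResult]) -> pd.DataFrame:
    """One row per gene: families segregating, best tier, maximum burden.

    "Burden" is the affected-carrier count within a family, the per-family
    case burden of the segregating variant.
    """
    by_gene: dict[str, list[SegregationResult]] = {}
    for r in shared_results:
        by_gene.setdefault(r.variant.gene, []).append(r)
    rows = []
    for gene in sorted(by_gene):
        rs = by_gene[gene]
        families = sorted({r.family_id for r in rs})
        tier = (
            Tier.SHARED_STRINGENT
            if any(r.tier is Tier.SHARED_STRINGENT for r in rs)
            else Tier.SHARED_BROAD
        )
        rows.append(
            {
                "gene": gene,
                "n_families": len(families),
                "families": ",".join(families),
                "tier": tier.value,
                "max_burden": max(r.affected_carriers for r in rs),
                "n_variants": len({r.variant.key for r in rs}),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "n_families", "families", "tier", "max_burden", "n_variants"],
    )


def segregation_table(results: list[SegregationResult]) -> pd.DataFrame:
    """Flat per-(variant, family) table mirroring the report layout
    (chr:position, ref>alt, gene, family, burden)."""
    rows = [
        {
            "chr_position": f"{r.variant.chrom}:{r.variant.pos}",
            "ref_alt": f"{r.variant.ref}>{r.variant.alt}",
            "gene": r.variant.gene,
            "family": r.family_id,
            "burden_case": r.affected_carriers,
            "family_control_carriers": r.family_control_carriers,
            "tier": r.tier.value,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chr_position",
            "ref_alt",
            "gene",
            "family",
            "burden_case",
            "family_control_carriers",
            "tier",
        ],
    )
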