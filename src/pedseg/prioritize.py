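"""Rare predicted-deleterious (RPD) variant classification.

A variant is RPD when it is rare in both reference panels (alternate-allele
frequency <= 1e-3 in the South-Asian and the global gnomAD panels, with
panel-absence read as unobserved, i.e. rare) and predicted deleterious:
either protein-truncating (stop-gain, stop-loss, start-loss, canonical
splice-site, or frameshift indel) or missense with a deleterious call from
at least 4 of the 5 prediction tools. A stricter rarity tier at 1e-4 feeds
the stringent within-family selection downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datamodel import AnnotatedVariant, Consequence, PredictorCall

__all__ = [
    "MAF_BROAD",
    "MAF_STRINGENT",
    "PTV_CONSEQUENCES",
    "RpdCall",
    "classify_ptv",
    "deleterious_consensus",
    "passes_rarity",
    "filter_rpd",
]

MAF_BROAD = 1e-3
MAF_STRINGENT = 1e-4

#: Protein-truncating consequence classes. In-frame indels do not qualify:
#: only out-of-frame (frameshift) indels truncate.
PTV_CONSEQUENCES = frozenset(
    {
        Consequence.STOPGAIN,
        Consequence.STOPLOSS,
        Consequence.STARTLOSS,
        Consequence.CANONICAL_SPLICE,
        Consequence.FRAMESHIFT_INDEL,
    }
)


@dataclass
class RpdCall:
    """Classification outcome for one variant."""

    variant: AnnotatedVariant
    is_ptv: bool
    deleterious_votes: int
    votes_available: int
    passes_rarity_broad: bool
    passes_rarity_stringent: bool
    is_rpd: bool


def classify_ptv(variant: AnnotatedVariant) -> bool:
    """True iff the consequence is protein-truncating."""
    return variant.consequence in PTV_CONSEQUENCES


def deleterious_consensus(
    predictor_calls: tuple[PredictorCall, ...],
    min_votes: int = 4,
    rule: str = "strict",
) -> tuple[int, bool]:
    """Count deleterious votes across the five predictors.

    Under the default ``strict`` rule a missing call is a non-vote, so a
    variant with more than one missing predictor can never reach the
    4-of-5 threshold. The ``lenient`` alternative applies the same 4/5
    proportion to the predictors that returned a call
    (``votes >= ceil(min_votes/5 * available)``, failing when no call is
    available).

    Returns
    -------
    (votes, passes)
        Number of deleterious calls and whether the consensus threshold
        is met.
    """
    if rule not in ("strict", "lenient"):
        raise ValueError(f"unknown consensus rule {rule!r}")
    votes = sum(1 for c in predictor_calls if c is PredictorCall.DELETERIOUS)
    available = sum(1 for c in predictor_calls if c is not PredictorCall.MISSING)
    if rule == "strict":
        passes = votes >= min_votes
    else:
        needed = -(-min_votes * available // 5)  # ceil
        passes = available > 0 and votes >= needed
    return votes, passes


def passes_rarity(variant: AnnotatedVariant, threshold: float) -> bool:
    """True iff both panel frequencies are <= threshold.

    A frequency missing from a panel means the allele was never observed
    there, which for rare-variant work is the strongest evidence of rarity;
    missing therefore passes any threshold.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    for maf in (variant.maf_sas, variant.maf_global):
        if maf is not None and maf > threshold:
            return False
    return True


def classify_variant(
    variant: AnnotatedVariant,
    maf_broad: float = MAF_BROAD,
    maf_stringent: float = MAF_STRINGENT,
    consensus_rule: str = "strict",
    min_votes: int = 4,
) -> RpdCall:
    """Full RPD classification of one variant (all tiers computed)."""
    is_ptv = classify_ptv(variant)
    votes, consensus_passes = deleterious_consensus(
        variant.predictor_calls, min_votes=min_votes, rule=consensus_rule
    )
    available = sum(
        1 for c in variant.predictor_calls if c is not PredictorCall.MISSING
    )
    broad = passes_rarity(variant, maf_broad)
    stringent = passes_rarity(variant, maf_stringent)
    deleterious = is_ptv or (
        variant.consequence is Consequence.MISSENSE and consensus_passes
    )
    return RpdCall(
        variant=variant,
        is_ptv=is_ptv,
        deleterious_votes=votes,
        votes_available=available,
        passes_rarity_broad=broad,
        passes_rarity_stringent=stringent,
        is_rpd=broad and deleterious,
    )


def filter_rpd(
    variants: list[AnnotatedVariant],
    maf_broad: float = MAF_BROAD,
    maf_stringent: float = MAF_STRINGENT,
    consensus_rule: str = "strict",
    min_votes: int = 4,
) -> list[RpdCall]:
    """Classify all variants and keep the RPD subset.

    Output order follows genomic coordinates (chrom, pos, alt, gene) so
    the result is invariant to input order.
    """
    calls = [
        classify_variant(
            v,
            maf_broad=maf_broad,
            maf_stringent=maf_stringent,
            consensus_rule=consensus_rule,
            min_votes=min_votes,
        )
        for v in variants
    ]
    kept = [c for c in calls if c.is_rpd]
    kept.sort(key=lambda c: (c.variant.chrom, c.variant.pos, c.variant.alt, c.variant.gene))
    return kept
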