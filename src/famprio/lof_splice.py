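"""Loss-of-function branch of the cascade.

Stop-gain, frameshift and canonical splice-site variants that already pass
the shared filters are assessed here: variants in the last exon of a gene
are excluded (they often escape nonsense-mediated decay), the rest are
reported with advisory tiers — MutPred2 pathogenicity (>= 0.50 is the
recommended conservative threshold), SpliceAI delta tiers (>= 0.5
confident, >= 0.8 high) and MMSplice tiers (|score| > 2 high, > 1.5
medium) — plus the LOEUF gene-constraint flag (< 0.6 constrained).
Only the last-exon rule can reject; tiers annotate, they never filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .cohort_io import TableFormatError, VariantRecord
from .prioritization import (
    CANONICAL_SPLICE,
    FAIL,
    FRAMESHIFT,
    LOF_CLASSES,
    NOT_EVALUABLE,
    PASS,
    STOP_GAIN,
    Thresholds,
    classify_consequence,
)

log = logging.getLogger(__name__)

# MutPred2 tiers
PATHOGENIC_LIKELY = "pathogenic_likely"
BELOW_THRESHOLD = "below_threshold"
NOT_AVAILABLE = "not_available"

# splice tiers
TIER_HIGH = "high"
TIER_CONFIDENT = "confident"
TIER_MEDIUM = "medium"
TIER_NONE = "none"


@dataclass
class LofAssessment:
    category: str
    last_exon_excluded: bool
    mutpred_tier: str = NOT_AVAILABLE
    splice_tier: str = NOT_AVAILABLE
    mmsplice_tier: str = NOT_AVAILABLE
    loeuf_constrained: Optional[bool] = None


def last_exon_exclusion(record: VariantRecord) -> str:
    """Fail (exclude) iff the variant falls in the gene's last exon.

    A missing flag retains the variant with a warning — the annotation is
    an upstream input and its absence should not silently drop reportable
    variants.
    """
    flag = record.annotations.last_exon
    if flag is None:
        log.warning("%s: last_exon flag missing; variant retained", record.key)
        return NOT_EVALUABLE
    return FAIL if flag else PASS


def assess_mutpred(score: Optional[float], thresholds: Optional[Thresholds] = None) -> str:
    thresholds = thresholds or Thresholds()
    if score is None:
        return NOT_AVAILABLE
    if not 0.0 <= score <= 1.0:
        raise TableFormatError(f"MutPred2 score {score} outside [0, 1]")
    return PATHOGENIC_LIKELY if score >= thresholds.mutpred_min else BELOW_THRESHOLD


def assess_splice(
    spliceai_delta: Optional[float],
    mmsplice: Optional[float],
    thresholds: Optional[Thresholds] = None,
) -> tuple[str, str]:
    """Tier the two splice predictors independently.

    SpliceAI delta: >= 0.8 high, >= 0.5 confident, else none.
    MMSplice (absolute value): > 2 high, > 1.5 medium, else none.
    """
    thresholds = thresholds or Thresholds()
    if spliceai_delta is None:
        splice_tier = NOT_AVAILABLE
    elif spliceai_delta >= thresholds.spliceai_high:
        splice_tier = TIER_HIGH
    elif spliceai_delta >= thresholds.spliceai_confident:
        splice_tier = TIER_CONFIDENT
    else:
        splice_tier = TIER_NONE
    if mmsplice is None:
        mm_tier = NOT_AVAILABLE
    elif abs(mmsplice) > thresholds.mmsplice_high:
        mm_tier = TIER_HIGH
    elif abs(mmsplice) > thresholds.mmsplice_medium:
        mm_tier = TIER_MEDIUM
    else:
        mm_tier = TIER_NONE
    return splice_tier, mm_tier


def assess_lof(record: VariantRecord, thresholds: Optional[Thresholds] = None) -> LofAssessment:
    """Compose the LoF assessment for one already-classified variant.

    MutPred2 applies to protein-truncating categories (stop-gain,
    frameshift); splice tiers apply to canonical splice variants; excluded
    last-exon variants carry no tiers at all.
    """
    thresholds = thresholds or Thresholds()
    category = classify_consequence(record)
    if category not in LOF_CLASSES:
        raise ValueError(f"{record.key}: {category} is not a LoF category")
    a = record.annotations
    excluded = last_exon_exclusion(record) == FAIL
    assessment = LofAssessment(category=category, last_exon_excluded=excluded)
    if a.loeuf is not None:
        assessment.loeuf_constrained = a.loeuf < thresholds.loeuf_max
    if excluded:
        return assessment
    if category in (STOP_GAIN, FRAMESHIFT):
        assessment.mutpred_tier = assess_mutpred(a.mutpred2, thresholds)
    if category == CANONICAL_SPLICE:
        assessment.splice_tier, assessment.mmsplice_tier = assess_splice(
            a.spliceai_delta, a.mmsplice, thresholds
        )
    return assessment
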