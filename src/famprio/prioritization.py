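"""The variant prioritization cascade.

Ordered criteria applied to each variant (per carrier family):

1. canonical-transcript restriction
2. consequence classification (missense / LoF kept, everything else out)
3. gnomAD frequency filter (overall, NFE and popmax all < 0.1%)
4. CADD PHRED deleteriousness (> 20)
5. family segregation (present in every sequenced affected; single-proband
   mode for double-primary cases)
6. missense branch: 11-tool ensemble vote (> 50% weighted support) and
   conservation consensus (>= 2 of GERP > 2.0, PhastCons > 0.3, PhyloP >= 3.0)
   -- LoF branch rules live in :mod:`famprio.lof_splice`.

Each variant receives a complete :class:`DecisionTrail`; rejection records
the first failing criterion while later criteria are still evaluated for
reporting (verdict ``not_applicable``, raw outcome kept in the inputs).
Gene-constraint annotations (missense Z > 0, LOEUF < 0.6) are advisory and
never reject.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .cohort_io import AnnotationBundle, FamilyCohort, VariantKey, VariantRecord
from .predictors import BENIGN, DELETERIOUS, INTERMEDIATE, MISSING, PREDICTORS

log = logging.getLogger(__name__)

PASS = "pass"
FAIL = "fail"
NOT_APPLICABLE = "not_applicable"
NOT_EVALUABLE = "not_evaluable"

PRIORITIZED = "prioritized"
REJECTED = "rejected"

# consequence classes
MISSENSE = "missense"
STOP_GAIN = "stop_gain"
FRAMESHIFT = "frameshift"
CANONICAL_SPLICE = "canonical_splice"
OTHER = "other"
LOF_CLASSES = (STOP_GAIN, FRAMESHIFT, CANONICAL_SPLICE)
CONSEQUENCE_CLASSES = (MISSENSE, STOP_GAIN, FRAMESHIFT, CANONICAL_SPLICE, OTHER)

#: fixed criterion order; every trail carries all of them exactly once
CRITERIA = (
    "canonical",
    "consequence_class",
    "frequency",
    "cadd",
    "segregation",
    "deleteriousness_vote",
    "conservation",
    "last_exon",
)


@dataclass
class Thresholds:
    """Every numeric cutoff of the cascade, with its comparison strictness.

    Strictness is part of the contract: CADD and the vote fraction are
    strict (20.0 and exactly 50% fail), PhyloP and MutPred2 are inclusive
    (3.0 and 0.50 pass).
    """

    maf_max: float = 0.001          # strict <
    cadd_min: float = 20.0          # strict >
    vote_fraction: float = 0.5      # strict >
    gerp_min: float = 2.0           # strict >
    phastcons_min: float = 0.3      # strict >
    phylop_min: float = 3.0         # inclusive >=
    conservation_min_positive: int = 2
    mutpred_min: float = 0.50       # inclusive >=
    spliceai_confident: float = 0.5
    spliceai_high: float = 0.8
    mmsplice_high: float = 2.0      # strict > on |score|
    mmsplice_medium: float = 1.5    # strict > on |score|
    loeuf_max: float = 0.6          # strict <
    canonical_fail_closed: bool = False  # missing canonical flag rejects if True


@dataclass
class VoteResult:
    credits: float
    n_tools_with_call: int
    fraction: Optional[float]
    verdict: str


@dataclass
class CriterionEntry:
    criterion: str
    inputs: dict
    threshold: Optional[object]
    verdict: str


@dataclass
class DecisionTrail:
    variant: VariantKey
    family_id: Optional[str]
    gene: str
    consequence_class: str
    entries: list[CriterionEntry] = field(default_factory=list)
    final_status: str = PRIORITIZED
    rejection_reason: Optional[str] = None
    advisory: dict = field(default_factory=dict)

    def verdict(self, criterion: str) -> str:
        for e in self.entries:
            if e.criterion == criterion:
                return e.verdict
        raise KeyError(criterion)


# ---------------------------------------------------------------------------
# individual criteria
# ---------------------------------------------------------------------------

_HGVS_INTRON_RE = re.compile(r"c\.[*\d_]+[+-](\d+)")

_CONSEQUENCE_MAP = {
    "missense_variant": MISSENSE,
    "missense": MISSENSE,
    "stop_gained": STOP_GAIN,
    "stop_gain": STOP_GAIN,
    "nonsense": STOP_GAIN,
    "frameshift_variant": FRAMESHIFT,
    "frameshift": FRAMESHIFT,
    "splice_donor_variant": CANONICAL_SPLICE,
    "splice_acceptor_variant": CANONICAL_SPLICE,
    "canonical_splice": CANONICAL_SPLICE,
}


def classify_consequence(record: VariantRecord) -> str:
    """Deterministic consequence class from the annotation term plus HGVSc.

    ``canonical_splice`` requires the +-1/+-2 intronic positions of a
    donor/acceptor; generic "splice_region" terms only qualify when the
    HGVSc offset confirms a canonical site.  Unknown vocabulary degrades to
    ``other`` with a log message.
    """
    term = (record.annotations.consequence or "").strip().lower().replace(" ", "_")
    # VEP-style multi-term annotations: first recognized term wins
    for t in re.split(r"[,&;]", term):
        if t in _CONSEQUENCE_MAP:
            return _CONSEQUENCE_MAP[t]
    if "splice" in term:
        m = _HGVS_INTRON_RE.search(record.annotations.hgvsc.replace(" ", ""))
        if m and int(m.group(1)) <= 2:
            return CANONICAL_SPLICE
        return OTHER
    if term and term not in _CONSEQUENCE_MAP:
        log.debug("unknown consequence term %r classified as other", term)
    return OTHER


def filter_canonical(record: VariantRecord, thresholds: Optional[Thresholds] = None) -> str:
    flag = record.annotations.canonical
    if flag is None:
        if thresholds is not None and thresholds.canonical_fail_closed:
            return FAIL
        return NOT_EVALUABLE
    return PASS if flag else FAIL


def filter_frequency(annotations: AnnotationBundle, thresholds: Thresholds) -> str:
    """Pass iff every non-missing gnomAD frequency is < maf_max.

    All-missing passes: absence from gnomAD is evidence of rarity.
    """
    for af in (annotations.af_overall, annotations.af_nfe, annotations.af_popmax):
        if af is not None and not (af < thresholds.maf_max):
            return FAIL
    return PASS


def filter_cadd(cadd_phred: Optional[float], thresholds: Thresholds) -> str:
    """Pass iff CADD PHRED strictly exceeds the cutoff; missing fails."""
    if cadd_phred is None:
        return FAIL
    return PASS if cadd_phred > thresholds.cadd_min else FAIL


def variant_present(record: VariantRecord, sample_id: str) -> bool:
    """Presence = het or hom_alt; a missing genotype counts as absent."""
    return record.genotypes.get(sample_id, "missing") in ("het", "hom_alt")


def segregates(record: VariantRecord, family) -> bool:
    """Family segregation predicate.

    multi_case: present in ALL sequenced affected members.
    single_case: present in the (sole sequenced) proband.
    """
    members = family.sequenced_affected() if family.mode == "multi_case" else family.sequenced()
    if not members:
        return False
    return all(variant_present(record, m.sample_id) for m in members)


def segregation_filter(
    cohort: FamilyCohort, records: Sequence[VariantRecord]
) -> dict[str, list[VariantRecord]]:
    """Per-family sets of segregating variants."""
    out: dict[str, list[VariantRecord]] = {}
    for fam_id, fam in cohort.families.items():
        genotyped = [m for m in fam.sequenced() if any(m.sample_id in r.genotypes for r in records)]
        if records and not genotyped:
            raise ValueError(f"family {fam_id} has no genotyped members in the variant table")
        out[fam_id] = [r for r in records if segregates(r, fam)]
    return out


_CREDIT = {DELETERIOUS: 1.0, INTERMEDIATE: 0.5, BENIGN: 0.0}


def deleteriousness_vote(calls: dict[str, str], thresholds: Thresholds) -> VoteResult:
    """Weighted ensemble vote over the 11 predictors.

    deleterious = 1 credit, intermediate = 0.5, benign = 0; missing calls
    leave the denominator.  Pass iff credits / n_called > vote_fraction
    (strict, so exactly 50% fails); no call at all is not evaluable.
    """
    unknown = set(calls) - set(PREDICTORS)
    if unknown or set(PREDICTORS) - set(calls):
        raise KeyError(
            f"vote requires exactly the configured predictors; unexpected={sorted(unknown)} "
            f"missing={sorted(set(PREDICTORS) - set(calls))}"
        )
    credits = 0.0
    n = 0
    for tool, call in calls.items():
        if call == MISSING:
            continue
        if call not in _CREDIT:
            raise ValueError(f"{tool}: unknown call category {call!r}")
        credits += _CREDIT[call]
        n += 1
    if n == 0:
        return VoteResult(0.0, 0, None, NOT_EVALUABLE)
    frac = credits / n
    return VoteResult(credits, n, frac, PASS if frac > thresholds.vote_fraction else FAIL)


def conservation_consensus(
    gerp: Optional[float],
    phastcons: Optional[float],
    phylop: Optional[float],
    thresholds: Thresholds,
) -> tuple[int, str]:
    """Count positive conservation calls; pass at >= 2 positives.

    GERP and PhastCons are strict (>), PhyloP inclusive (>=); missing
    scores simply cannot contribute a positive.
    """
    positives = 0
    if gerp is not None and gerp > thresholds.gerp_min:
        positives += 1
    if phastcons is not None and phastcons > thresholds.phastcons_min:
        positives += 1
    if phylop is not None and phylop >= thresholds.phylop_min:
        positives += 1
    verdict = PASS if positives >= thresholds.conservation_min_positive else FAIL
    return positives, verdict


def constraint_annotation(
    missense_z: Optional[float], loeuf: Optional[float], thresholds: Thresholds
) -> dict[str, bool]:
    """Advisory gene-constraint flags; never rejects a variant."""
    flags: dict[str, bool] = {}
    if missense_z is not None:
        flags["z_constrained"] = missense_z > 0
    if loeuf is not None:
        flags["loeuf_constrained"] = loeuf < thresholds.loeuf_max
    return flags


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------

def _carrier_families(record: VariantRecord, cohort: FamilyCohort) -> list[str]:
    fams = []
    for fam_id, fam in cohort.families.items():
        if any(variant_present(record, m.sample_id) for m in fam.sequenced()):
            fams.append(fam_id)
    return fams


def _trail_for(record, fam, fam_id, thresholds) -> DecisionTrail:
    from . import lof_splice  # local import: lof_splice depends on this module

    a = record.annotations
    cls = classify_consequence(record)
    trail = DecisionTrail(
        variant=record.key, family_id=fam_id, gene=record.gene, consequence_class=cls
    )
    failed: Optional[str] = None

    def add(criterion: str, inputs: dict, threshold, verdict: str) -> None:
        nonlocal failed
        if failed is not None:
            inputs = dict(inputs, raw_verdict=verdict)
            verdict = NOT_APPLICABLE
        trail.entries.append(CriterionEntry(criterion, inputs, threshold, verdict))
        if verdict == FAIL and failed is None:
            failed = criterion

    add("canonical", {"canonical": a.canonical}, True, filter_canonical(record, thresholds))
    add(
        "consequence_class",
        {"consequence": a.consequence, "class": cls},
        f"one of {MISSENSE}/{'/'.join(LOF_CLASSES)}",
        PASS if cls != OTHER else FAIL,
    )
    add(
        "frequency",
        {"af_overall": a.af_overall, "af_nfe": a.af_nfe, "af_popmax": a.af_popmax},
        thresholds.maf_max,
        filter_frequency(a, thresholds),
    )
    add("cadd", {"cadd_phred": a.cadd_phred}, thresholds.cadd_min, filter_cadd(a.cadd_phred, thresholds))

    if fam is None:
        add("segregation", {"mode": None, "carriers": sorted(record.carriers())}, "all affected", FAIL)
    else:
        add(
            "segregation",
            {"mode": fam.mode, "carriers": sorted(record.carriers())},
            "all sequenced affected" if fam.mode == "multi_case" else "proband",
            PASS if segregates(record, fam) else FAIL,
        )

    if cls == MISSENSE:
        vote = deleteriousness_vote(a.predictor_calls, thresholds)
        add(
            "deleteriousness_vote",
            {"credits": vote.credits, "n_tools": vote.n_tools_with_call, "fraction": vote.fraction},
            thresholds.vote_fraction,
            vote.verdict,
        )
        positives, cons_verdict = conservation_consensus(a.gerp, a.phastcons, a.phylop, thresholds)
        add(
            "conservation",
            {"gerp": a.gerp, "phastcons": a.phastcons, "phylop": a.phylop, "positives": positives},
            thresholds.conservation_min_positive,
            cons_verdict,
        )
        add("last_exon", {"last_exon": a.last_exon}, None, NOT_APPLICABLE)
    elif cls in LOF_CLASSES:
        add("deleteriousness_vote", {}, thresholds.vote_fraction, NOT_APPLICABLE)
        add("conservation", {}, thresholds.conservation_min_positive, NOT_APPLICABLE)
        add(
            "last_exon",
            {"last_exon": a.last_exon},
            False,
            lof_splice.last_exon_exclusion(record),
        )
        if failed is None or failed == "last_exon":
            trail.advisory["lof"] = lof_splice.assess_lof(record, thresholds)
    else:
        add("deleteriousness_vote", {}, None, NOT_APPLICABLE)
        add("conservation", {}, None, NOT_APPLICABLE)
        add("last_exon", {"last_exon": a.last_exon}, None, NOT_APPLICABLE)

    trail.advisory["constraint"] = constraint_annotation(a.missense_z, a.loeuf, thresholds)
    trail.final_status = REJECTED if failed is not None else PRIORITIZED
    trail.rejection_reason = failed
    return trail


def prioritize(
    records: Iterable[VariantRecord],
    cohort: FamilyCohort,
    thresholds: Optional[Thresholds] = None,
) -> list[DecisionTrail]:
    """Run the full cascade; one trail per variant x carrier family.

    A record carried by no family in the cohort yields a single trail
    (family ``None``) that fails segregation, so every input row remains
    auditable.  The prioritized set is the trails with
    ``final_status == "prioritized"``.
    """
    thresholds = thresholds or Thresholds()
    trails: list[DecisionTrail] = []
    for record in records:
        fams = _carrier_families(record, cohort)
        if not fams:
            trails.append(_trail_for(record, None, None, thresholds))
            continue
        for fam_id in fams:
            trails.append(_trail_for(record, cohort.families[fam_id], fam_id, thresholds))
    return trails


def prioritized_set(trails: Iterable[DecisionTrail]) -> list[DecisionTrail]:
    return [t for t in trails if t.final_status == PRIORITIZED]


def known_gene_screen(
    records: Iterable[VariantRecord], gene_list: Iterable[str]
) -> list[VariantRecord]:
    """Pre-cascade screen for variants in established predisposition genes.

    Matching is case-insensitive on the gene symbol; applied to the raw
    records before any filtering, as a safety net for known pathogenic
    variants the cascade might discard.
    """
    genes = {g.strip().upper() for g in gene_list if g and g.strip()}
    if not genes:
        raise ValueError("known-gene list is empty")
    return [r for r in records if r.gene.strip().upper() in genes]
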