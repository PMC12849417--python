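"""Synthetic cohorts, networks and report tables with ground truth.

The real sequencing data behind this kind of study is controlled-access,
so every pipeline stage is exercised on simulated inputs that carry the
statistical structure the analysis assumes:

* multi-family cohorts in which each family's planted causal variants are
  shared by all of its sequenced affected members and carry
  high-deleteriousness annotations, against a background of rare,
  non-segregating variants private to single genomes;
* planted-partition protein networks whose within-block edges carry
  channel scores that survive the 0.400 combined-score filter;
* deterministic prioritized-variant tables with configurable per-family
  and per-class margins, for exercising the tally stage.

All generators are deterministic under their seed, and every declared
distribution is test-visible (moment checks in the suite).  The score
models are deliberately simple parametric stand-ins; see docs/methods.md
for what they do and do not emulate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import GENOTYPE_PREFIX, FamilyCohort, Family, Member
from .predictors import PREDICTORS
from .prioritization import (
    CANONICAL_SPLICE,
    FRAMESHIFT,
    MISSENSE,
    OTHER,
    STOP_GAIN,
    Thresholds,
)

_BASES = ("A", "C", "G", "T")

_CLASS_TERMS = {
    MISSENSE: "missense_variant",
    STOP_GAIN: "stop_gained",
    FRAMESHIFT: "frameshift_variant",
    CANONICAL_SPLICE: "splice_donor_variant",
    OTHER: "synonymous_variant",
}


@dataclass
class CohortSimParams:
    """Declared generative model for a synthetic familial cohort.

    Defaults emulate the study conditions: 22 families of which 7 are
    single-proband double-primary cases, 2-4 sequenced affected members in
    the multi-case families, ~200 rare background variants per sequenced
    genome and 2 planted causal variants per family.  Causal variants draw
    CADD ~ U(20.1, 45), deleterious predictor count ~ Binomial(11, 0.85),
    all-positive conservation with probability 0.9 and gnomAD AF = 0;
    background variants draw CADD ~ Normal(10, 5) truncated at 0,
    deleterious count ~ Binomial(11, 0.2) and AF from a mixture with mass
    on both sides of the 0.1% cutoff.
    """

    n_families: int = 22
    n_single_case: int = 7
    members_per_family: tuple[int, int] = (4, 8)
    n_sequenced_affected: tuple[int, int] = (2, 4)
    background_variants_per_genome: float = 200.0
    n_causal_per_family: int = 2
    # causal score model
    causal_cadd_range: tuple[float, float] = (20.1, 45.0)
    causal_deleterious_prob: float = 0.85
    causal_conservation_all_positive_prob: float = 0.9
    causal_consequence_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            MISSENSE: 0.686, STOP_GAIN: 0.120, CANONICAL_SPLICE: 0.050, FRAMESHIFT: 0.144,
        }
    )
    # background score model
    background_cadd_mean: float = 10.0
    background_cadd_sd: float = 5.0
    background_deleterious_prob: float = 0.2
    background_rare_fraction: float = 0.4
    background_common_af_max: float = 0.05
    background_consequence_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            OTHER: 0.50, MISSENSE: 0.35, STOP_GAIN: 0.06, CANONICAL_SPLICE: 0.02,
            FRAMESHIFT: 0.07,
        }
    )
    background_canonical_prob: float = 0.9
    background_last_exon_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or not (0 <= self.n_single_case <= self.n_families):
            raise ValueError("need n_families >= 1 and 0 <= n_single_case <= n_families")
        if self.members_per_family[0] < 1 or self.members_per_family[0] > self.members_per_family[1]:
            raise ValueError("members_per_family range is empty or infeasible")
        lo, hi = self.n_sequenced_affected
        if lo < 1 or lo > hi or hi > self.members_per_family[1]:
            raise ValueError("n_sequenced_affected range infeasible")
        for p in (
            self.causal_deleterious_prob,
            self.causal_conservation_all_positive_prob,
            self.background_deleterious_prob,
            self.background_rare_fraction,
            self.background_canonical_prob,
            self.background_last_exon_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for weights in (self.causal_consequence_weights, self.background_consequence_weights):
            if abs(sum(weights.values()) - 1.0) > 1e-9:
                raise ValueError("consequence weights must sum to 1")

    @classmethod
    def threshold_clearing(cls, **overrides) -> "CohortSimParams":
        """Preset in which every causal variant clears every cascade
        threshold with probability one (deterministic 100% recall)."""
        base = dict(causal_deleterious_prob=1.0, causal_conservation_all_positive_prob=1.0)
        base.update(overrides)
        return cls(**base)


def background_cascade_pass_prob(
    params: CohortSimParams, thresholds: Optional[Thresholds] = None
) -> float:
    """Analytic probability that one background variant passes the
    frequency, CADD and ensemble-vote filters jointly.

    Closed form from the declared distributions: the three gnomAD fields
    share one mixture draw (pass prob = rare fraction); CADD passes with
    the truncated-normal upper-tail mass above the cutoff; the vote passes
    when the Binomial(11, p_bg) deleterious count exceeds half of the 11
    recorded calls.
    """
    t = thresholds or Thresholds()
    p_freq = params.background_rare_fraction
    mu, sd = params.background_cadd_mean, params.background_cadd_sd
    p_cadd = stats.norm.sf(t.cadd_min, mu, sd) / stats.norm.sf(0.0, mu, sd)
    n_tools = len(PREDICTORS)
    # smallest count whose fraction strictly exceeds the vote threshold
    k_min = int(np.floor(t.vote_fraction * n_tools)) + 1
    p_vote = stats.binom.sf(k_min - 1, n_tools, params.background_deleterious_prob)
    return float(p_freq * p_cadd * p_vote)


def _random_key(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        chrom = str(rng.integers(1, 23))
        pos = int(rng.integers(1_000_000, 200_000_000))
        ref, alt = rng.choice(len(_BASES), size=2, replace=False)
        key = f"{chrom}_{pos}_{_BASES[ref]}_{_BASES[alt]}"
        if key not in used:
            used.add(key)
            return key


def _weighted_choice(rng: np.random.Generator, weights: Mapping[str, float]) -> str:
    labels = list(weights)
    return labels[rng.choice(len(labels), p=np.array([weights[c] for c in labels]))]


def _predictor_calls(rng: np.random.Generator, p_deleterious: float) -> dict[str, str]:
    n_del = int(rng.binomial(len(PREDICTORS), p_deleterious))
    order = rng.permutation(len(PREDICTORS))
    calls = {}
    for rank, idx in enumerate(order):
        calls[PREDICTORS[idx]] = "deleterious" if rank < n_del else "benign"
    return calls


def _causal_annotations(rng: np.random.Generator, params: CohortSimParams) -> dict:
    cls = _weighted_choice(rng, params.causal_consequence_weights)
    lo, hi = params.causal_cadd_range
    ann: dict = {
        "consequence": _CLASS_TERMS[cls],
        "canonical": 1,
        "last_exon": 0,
        "gnomad_af": 0.0,
        "gnomad_nfe_af": 0.0,
        "gnomad_popmax_af": 0.0,
        "cadd_phred": float(rng.uniform(lo, hi)),
        "missense_z": float(rng.normal(1.5, 1.0)),
        "loeuf": float(rng.uniform(0.1, 1.2)),
    }
    if rng.random() < params.causal_conservation_all_positive_prob:
        ann.update(
            gerp=float(rng.uniform(2.5, 6.0)),
            phastcons=float(rng.uniform(0.35, 1.0)),
            phylop=float(rng.uniform(3.0, 9.0)),
        )
    else:
        ann.update(
            gerp=float(rng.uniform(-2.0, 2.0)),
            phastcons=float(rng.uniform(0.0, 0.3)),
            phylop=float(rng.uniform(-2.0, 2.9)),
        )
    ann.update(_predictor_calls(rng, params.causal_deleterious_prob))
    if cls in (STOP_GAIN, FRAMESHIFT):
        ann["mutpred2"] = float(rng.uniform(0.3, 0.95))
    if cls == CANONICAL_SPLICE:
        ann["spliceai_delta"] = float(rng.uniform(0.5, 1.0))
        ann["mmsplice"] = float(rng.choice([-1, 1]) * rng.uniform(1.6, 3.0))
    return ann


def _background_annotations(rng: np.random.Generator, params: CohortSimParams) -> dict:
    cls = _weighted_choice(rng, params.background_consequence_weights)
    if rng.random() < params.background_rare_fraction:
        af = float(rng.uniform(0.0, 0.001))
    else:
        af = float(rng.uniform(0.001, params.background_common_af_max))
    cadd = -1.0
    while cadd < 0.0:  # truncation at 0
        cadd = float(rng.normal(params.background_cadd_mean, params.background_cadd_sd))
    ann: dict = {
        "consequence": _CLASS_TERMS[cls],
        "canonical": int(rng.random() < params.background_canonical_prob),
        "last_exon": int(rng.random() < params.background_last_exon_prob),
        "gnomad_af": af,
        "gnomad_nfe_af": af,
        "gnomad_popmax_af": af,
        "cadd_phred": cadd,
        "gerp": float(rng.normal(0.0, 2.0)),
        "phastcons": float(rng.beta(1.0, 3.0)),
        "phylop": float(rng.normal(0.0, 2.0)),
        "missense_z": float(rng.normal(0.0, 1.0)),
        "loeuf": float(rng.uniform(0.2, 1.5)),
    }
    ann.update(_predictor_calls(rng, params.background_deleterious_prob))
    if cls in (STOP_GAIN, FRAMESHIFT):
        ann["mutpred2"] = float(rng.uniform(0.0, 1.0))
    if cls == CANONICAL_SPLICE:
        ann["spliceai_delta"] = float(rng.beta(1.0, 10.0))
        ann["mmsplice"] = float(rng.normal(0.0, 1.0))
    return ann


def simulate_cohort(
    params: Optional[CohortSimParams] = None,
) -> tuple[pd.DataFrame, FamilyCohort, set[tuple[str, str]]]:
    """Generate (variant table, cohort, truth set).

    The truth set lists every planted causal (family_id, variant_key)
    pair; causal variants are het in all sequenced affected members of
    their family and hom_ref elsewhere, background variants are private to
    one sequenced genome.  Identical seed, identical output.
    """
    params = params or CohortSimParams()
    rng = np.random.default_rng(params.seed)
    n_multi = params.n_families - params.n_single_case

    families: dict[str, Family] = {}
    for i in range(params.n_families):
        single = i >= n_multi
        fam_id = f"Mx{i - n_multi + 1}" if single else f"F{i + 1}"
        n_members = int(rng.integers(params.members_per_family[0], params.members_per_family[1] + 1))
        members: list[Member] = []
        father_id, mother_id = f"{fam_id}_S1", f"{fam_id}_S2"
        if single:
            n_seq = 1
        else:
            lo, hi = params.n_sequenced_affected
            n_seq = int(rng.integers(lo, min(hi, n_members) + 1))
        seq_idx = set(rng.choice(n_members, size=n_seq, replace=False).tolist())
        for j in range(n_members):
            sid = f"{fam_id}_S{j + 1}"
            is_founder = j < 2
            sequenced = j in seq_idx
            affected = sequenced or (rng.random() < 0.2)
            members.append(
                Member(
                    sample_id=sid,
                    family_id=fam_id,
                    father=None if is_founder else father_id,
                    mother=None if is_founder else mother_id,
                    sex="male" if j % 2 == 0 else "female",
                    affected=affected,
                    sequenced=sequenced,
                )
            )
        families[fam_id] = Family(family_id=fam_id, members=members)
    cohort = FamilyCohort(families=families)

    all_sequenced = sorted(m.sample_id for f in families.values() for m in f.sequenced())
    used_keys: set[str] = set()
    truth: set[tuple[str, str]] = set()
    rows: list[dict] = []

    def base_row(key: str, gene: str, ann: dict, carriers: set[str]) -> dict:
        row = {"variant_key": key, "gene": gene, **ann}
        for s in all_sequenced:
            row[GENOTYPE_PREFIX + s] = "het" if s in carriers else "hom_ref"
        return row

    gene_counter = itertools.count(1)
    for fam_id, fam in families.items():
        affected_seq = {m.sample_id for m in fam.sequenced() if m.affected}
        for _ in range(params.n_causal_per_family):
            key = _random_key(rng, used_keys)
            gene = f"GENE{next(gene_counter):04d}"
            rows.append(base_row(key, gene, _causal_annotations(rng, params), affected_seq))
            truth.add((fam_id, key))
        for m in fam.sequenced():
            n_bg = int(rng.poisson(params.background_variants_per_genome))
            for _ in range(n_bg):
                key = _random_key(rng, used_keys)
                gene = f"BG{next(gene_counter):05d}"
                rows.append(
                    base_row(key, gene, _background_annotations(rng, params), {m.sample_id})
                )

    columns = (
        ["variant_key", "gene", "consequence", "canonical", "last_exon",
         "gnomad_af", "gnomad_nfe_af", "gnomad_popmax_af", "cadd_phred",
         "gerp", "phastcons", "phylop", "missense_z", "loeuf",
         "mutpred2", "spliceai_delta", "mmsplice"]
        + list(PREDICTORS)
        + [GENOTYPE_PREFIX + s for s in all_sequenced]
    )
    df = pd.DataFrame(rows).reindex(columns=columns)
    return df, cohort, truth


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

@dataclass
class NetworkSimParams:
    """Planted-partition graph with STRING-style channel scores.

    Within-block pairs connect with probability ``p_within`` and carry
    channel scores drawn high enough that their combined score exceeds
    0.400 essentially always; between-block edges are sparse and weak.
    """

    block_sizes: tuple[int, ...] = (15, 15)
    p_within: float = 0.8
    p_between: float = 0.05
    within_channel_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "experiments": (0.55, 0.95), "databases": (0.40, 0.90), "coexpression": (0.30, 0.80),
        }
    )
    between_channel_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "experiments": (0.0, 0.35), "databases": (0.0, 0.35), "coexpression": (0.0, 0.35),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.block_sizes or any(b < 1 for b in self.block_sizes):
            raise ValueError("block sizes must be positive")
        for p in (self.p_within, self.p_between):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"edge probability {p} outside [0, 1]")

    @property
    def n_nodes(self) -> int:
        return sum(self.block_sizes)


def simulate_network(
    params: Optional[NetworkSimParams] = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Generate (edge table, truth block labels) for a planted partition."""
    params = params or NetworkSimParams()
    rng = np.random.default_rng(params.seed)
    labels: dict[str, int] = {}
    node_id = 0
    for b, size in enumerate(params.block_sizes):
        for _ in range(size):
            labels[f"P{node_id:03d}"] = b
            node_id += 1
    nodes = sorted(labels)
    rows = []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            same = labels[a] == labels[b]
            p = params.p_within if same else params.p_between
            if rng.random() >= p:
                continue
            ranges = params.within_channel_ranges if same else params.between_channel_ranges
            row = {"protein_a": a, "protein_b": b}
            for chan, (lo, hi) in ranges.items():
                row[chan] = float(rng.uniform(lo, hi))
            rows.append(row)
    cols = ["protein_a", "protein_b"] + list(params.within_channel_ranges)
    return pd.DataFrame(rows, columns=cols), labels


# ---------------------------------------------------------------------------
# deterministic prioritized-table stand-in for the tally stage
# ---------------------------------------------------------------------------

#: per-family row counts and class-by-mode margins characteristic of the
#: familial CRC cohort this package targets (15 segregation families plus
#: 7 double-primary probands, 258 prioritized variant x family rows).
STUDY_MARGINS: dict = {
    "family_rows": {
        "F1": 10, "F2": 6, "F3": 1, "F4": 5, "F5": 7, "F6": 9, "F7": 8, "F8": 6,
        "F9": 7, "F10": 9, "F11": 8, "F12": 22, "F13": 8, "F14": 9, "F15": 9,
        "Mx6": 20, "Mx7": 27, "Mx8": 21, "Mx29": 17, "Mx34": 20, "Mx36": 18, "Mx46": 11,
    },
    "modes": {
        **{f"F{i}": "multi_case" for i in range(1, 16)},
        **{m: "single_case" for m in ("Mx6", "Mx7", "Mx8", "Mx29", "Mx34", "Mx36", "Mx46")},
    },
    "class_totals": {
        "multi_case": {MISSENSE: 89, STOP_GAIN: 17, CANONICAL_SPLICE: 3, FRAMESHIFT: 15},
        "single_case": {MISSENSE: 88, STOP_GAIN: 14, CANONICAL_SPLICE: 10, FRAMESHIFT: 22},
    },
    "recurrent_genes": [("APCDD1", 9), ("SRC", 5), ("CYBA", 5), ("PTK7", 2)],
}


def synthetic_prioritized_table(margins: Optional[Mapping] = None) -> pd.DataFrame:
    """Deterministic SYNTHETIC stand-in for a prioritized variant table.

    Builds one row per variant x family that exactly realizes the given
    margins: per-family row counts, per-mode consequence-class totals and
    a list of (gene, n_families) recurrences realized as identical
    missense variant keys shared across that many families.  The table is
    synthetic — gene symbols other than the recurrent ones are
    placeholders — but its marginal structure is the configured one, so
    tally arithmetic can be validated against known totals.
    """
    m = dict(STUDY_MARGINS if margins is None else margins)
    family_rows: Mapping[str, int] = m["family_rows"]
    modes: Mapping[str, str] = m["modes"]
    class_totals: Mapping[str, Mapping[str, int]] = m["class_totals"]
    recurrent: Sequence[tuple[str, int]] = m.get("recurrent_genes", [])

    for mode, totals in class_totals.items():
        fams = [f for f in family_rows if modes[f] == mode]
        if sum(totals.values()) != sum(family_rows[f] for f in fams):
            raise ValueError(f"{mode}: class totals do not match family row totals")

    rows: list[dict] = []
    key_counter = itertools.count(0)

    def next_key() -> str:
        i = next(key_counter)
        chrom = str(i % 22 + 1)
        ref, alt = _BASES[i % 4], _BASES[(i + 1) % 4]
        return f"{chrom}_{1_000_000 + 137 * i}_{ref}_{alt}"

    for mode, totals in class_totals.items():
        labels = [c for c, cnt in totals.items() for _ in range(cnt)]
        pos = 0
        for fam in [f for f in family_rows if modes[f] == mode]:
            for _ in range(family_rows[fam]):
                cls = labels[pos]
                pos += 1
                rows.append(
                    {
                        "family_id": fam,
                        "mode": mode,
                        "gene": f"SYN{len(rows):04d}",
                        "variant_key": next_key(),
                        "consequence_class": cls,
                    }
                )

    df = pd.DataFrame(rows)
    overridden: set[int] = set()
    for gene, n_fams in recurrent:
        shared_key = next_key().replace("_", "_9", 1)  # distinct chrom namespace
        counts = (
            df[(df["consequence_class"] == MISSENSE) & (~df.index.isin(overridden))]
            .groupby("family_id").size().sort_values(ascending=False)
        )
        if len(counts) < n_fams:
            raise ValueError(f"not enough families with missense rows for {gene}")
        for fam in counts.index[:n_fams]:
            idx = df[
                (df["family_id"] == fam)
                & (df["consequence_class"] == MISSENSE)
                & (~df.index.isin(overridden))
            ].index[0]
            df.loc[idx, ["gene", "variant_key"]] = [gene, shared_key]
            overridden.add(idx)
    return df
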