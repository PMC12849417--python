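"""Readers and writers for every external artifact of the pipeline.

Formats handled:

* annotated variant tables — TSV with a documented column registry, or a
  VEP-style annotated VCF mapped through a configurable field map (cyvcf2);
* pedigrees — 6-column PED plus one extension column ``sequenced``;
* weighted protein-interaction edge lists — STRING-export-style TSV with
  per-channel scores;
* gene-set collections — GMT;
* decision trails — TSV, one row per variant x criterion (round-trippable).

Coordinates are 1-based GRCh38 throughout; the string form of a variant is
``chrom_pos_ref_alt`` (e.g. ``7_128840655_G_A``).  Missing cells stay
missing (``None``), never silently zero.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .predictors import MISSING, PREDICTORS, normalize_call

log = logging.getLogger(__name__)

_VALID_CHROMS = {str(i) for i in range(1, 23)} | {"X", "Y"}
_ALLELE_RE = re.compile(r"^[ACGT]+$")

GENOTYPE_STATES = ("hom_ref", "het", "hom_alt", "missing")

#: VCF-style genotype tokens accepted in TSV genotype cells
_GT_TOKENS = {
    "hom_ref": "hom_ref", "0/0": "hom_ref", "0|0": "hom_ref", "0": "hom_ref",
    "het": "het", "0/1": "het", "1/0": "het", "0|1": "het", "1|0": "het", "1": "het",
    "hom_alt": "hom_alt", "1/1": "hom_alt", "1|1": "hom_alt", "2": "hom_alt",
    "missing": "missing", "./.": "missing", ".|.": "missing", ".": "missing", "": "missing",
}


class TableFormatError(ValueError):
    """A table cell or line cannot be parsed."""


class ConfigurationError(ValueError):
    """Required columns/fields are absent or misconfigured."""


class PedigreeError(ValueError):
    """A pedigree violates the cohort contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class VariantKey:
    """Genomic identity of one bi-allelic variant, 1-based GRCh38."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.chrom not in _VALID_CHROMS:
            raise TableFormatError(f"invalid chromosome {self.chrom!r}")
        if self.pos < 1:
            raise TableFormatError(f"position must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not _ALLELE_RE.match(allele):
                raise TableFormatError(f"invalid {name} allele {allele!r}")
        if self.ref == self.alt:
            raise TableFormatError("ref and alt alleles are identical")

    def __str__(self) -> str:
        return f"{self.chrom}_{self.pos}_{self.ref}_{self.alt}"


def parse_variant_key(text: str) -> VariantKey:
    """Parse ``chrom_pos_ref_alt`` (Table-style, e.g. ``7_128840655_G_A``)."""
    if not text:
        raise TableFormatError("empty variant key")
    parts = text.strip().split("_")
    if len(parts) != 4:
        raise TableFormatError(
            f"variant key {text!r}: expected 4 underscore-separated fields, got {len(parts)}"
        )
    chrom, pos_s, ref, alt = parts
    chrom = chrom.removeprefix("chr")
    if not pos_s.isdigit():
        raise TableFormatError(f"variant key {text!r}: position {pos_s!r} is not numeric")
    return VariantKey(chrom=chrom, pos=int(pos_s), ref=ref.upper(), alt=alt.upper())


@dataclass
class AnnotationBundle:
    """The full annotation payload of one variant on its canonical transcript."""

    af_overall: Optional[float] = None
    af_nfe: Optional[float] = None
    af_popmax: Optional[float] = None
    cadd_phred: Optional[float] = None
    predictor_calls: dict[str, str] = field(
        default_factory=lambda: {p: MISSING for p in PREDICTORS}
    )
    gerp: Optional[float] = None
    phastcons: Optional[float] = None
    phylop: Optional[float] = None
    missense_z: Optional[float] = None
    loeuf: Optional[float] = None
    mutpred2: Optional[float] = None
    mutpred2_mechanisms: str = ""
    spliceai_delta: Optional[float] = None
    mmsplice: Optional[float] = None
    consequence: str = ""
    canonical: Optional[bool] = None
    last_exon: Optional[bool] = None
    transcript_id: str = ""
    hgvsc: str = ""
    hgvsp: str = ""

    def __post_init__(self) -> None:
        for name in ("af_overall", "af_nfe", "af_popmax", "phastcons", "mutpred2", "spliceai_delta"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise TableFormatError(f"{name}={v} outside [0, 1]")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise TableFormatError(f"cadd_phred={self.cadd_phred} negative")
        if self.loeuf is not None and self.loeuf <= 0:
            raise TableFormatError(f"loeuf={self.loeuf} must be positive")
        if set(self.predictor_calls) != set(PREDICTORS):
            raise ConfigurationError(
                "predictor_calls must carry exactly the 11 configured predictors; "
                f"got {sorted(self.predictor_calls)}"
            )


@dataclass
class VariantRecord:
    key: VariantKey
    gene: str
    annotations: AnnotationBundle
    genotypes: dict[str, str] = field(default_factory=dict)

    def carriers(self) -> set[str]:
        """Samples in which the variant is present (het or hom_alt)."""
        return {s for s, g in self.genotypes.items() if g in ("het", "hom_alt")}


@dataclass
class Member:
    sample_id: str
    family_id: str
    father: Optional[str]
    mother: Optional[str]
    sex: Optional[str]
    affected: bool
    sequenced: bool


@dataclass
class Family:
    family_id: str
    members: list[Member]

    @property
    def mode(self) -> str:
        """single_case iff exactly one sequenced member, else multi_case."""
        n_seq = sum(m.sequenced for m in self.members)
        return "single_case" if n_seq == 1 else "multi_case"

    def sequenced_affected(self) -> list[Member]:
        return [m for m in self.members if m.sequenced and m.affected]

    def sequenced(self) -> list[Member]:
        return [m for m in self.members if m.sequenced]


@dataclass
class FamilyCohort:
    families: dict[str, Family]

    def __post_init__(self) -> None:
        ids: set[str] = set()
        for fam in self.families.values():
            present = {m.sample_id for m in fam.members}
            for m in fam.members:
                if m.sample_id in ids:
                    raise PedigreeError(f"duplicate sample ID {m.sample_id!r}")
                ids.add(m.sample_id)
                for parent in (m.father, m.mother):
                    if parent is not None and parent not in present:
                        raise PedigreeError(
                            f"{m.sample_id}: parent {parent!r} not in family {fam.family_id}"
                        )
            if not fam.sequenced_affected():
                raise PedigreeError(
                    f"family {fam.family_id} has no sequenced affected member"
                )

    def sample_ids(self) -> set[str]:
        return {m.sample_id for fam in self.families.values() for m in fam.members}


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

#: registry column -> (attribute on AnnotationBundle, parser)
_FLOAT_COLUMNS = {
    "gnomad_af": "af_overall",
    "gnomad_nfe_af": "af_nfe",
    "gnomad_popmax_af": "af_popmax",
    "cadd_phred": "cadd_phred",
    "gerp": "gerp",
    "phastcons": "phastcons",
    "phylop": "phylop",
    "missense_z": "missense_z",
    "loeuf": "loeuf",
    "mutpred2": "mutpred2",
    "spliceai_delta": "spliceai_delta",
    "mmsplice": "mmsplice",
}
_STR_COLUMNS = {
    "consequence": "consequence",
    "transcript_id": "transcript_id",
    "hgvsc": "hgvsc",
    "hgvsp": "hgvsp",
    "mutpred2_mechanisms": "mutpred2_mechanisms",
}
_BOOL_COLUMNS = {"canonical": "canonical", "last_exon": "last_exon"}

MANDATORY_COLUMNS = (
    "variant_key",
    "gene",
    "consequence",
    "canonical",
    "cadd_phred",
    "gnomad_af",
    "gnomad_nfe_af",
    "gnomad_popmax_af",
)

GENOTYPE_PREFIX = "gt_"

_MISSING_CELLS = {"", ".", "na", "nan", "none"}


def _cell_missing(v: object) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return str(v).strip().lower() in _MISSING_CELLS


def _parse_float(v: object, row: int, col: str) -> Optional[float]:
    if _cell_missing(v):
        return None
    try:
        return float(v)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise TableFormatError(f"row {row}, column {col!r}: cannot parse {v!r} as number")


def _parse_bool(v: object, row: int, col: str) -> Optional[bool]:
    if _cell_missing(v):
        return None
    token = str(v).strip().lower()
    if token in ("1", "true", "yes", "y", "t"):
        return True
    if token in ("0", "false", "no", "n", "f"):
        return False
    raise TableFormatError(f"row {row}, column {col!r}: cannot parse {v!r} as boolean")


def _parse_genotype(v: object) -> str:
    if _cell_missing(v):
        return "missing"
    token = str(v).strip().lower()
    if token in _GT_TOKENS:
        return _GT_TOKENS[token]
    raise TableFormatError(f"unrecognized genotype token {v!r}")


def records_from_frame(
    df: pd.DataFrame,
    call_overrides: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> list[VariantRecord]:
    """Build VariantRecords from a registry-conformant DataFrame."""
    missing_cols = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ConfigurationError(f"missing mandatory columns: {missing_cols}")
    gt_cols = [c for c in df.columns if c.startswith(GENOTYPE_PREFIX)]
    records: list[VariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        key = parse_variant_key(str(row_d["variant_key"]))
        kwargs: dict = {}
        for col, attr in _FLOAT_COLUMNS.items():
            if col in df.columns:
                kwargs[attr] = _parse_float(row_d[col], i, col)
        for col, attr in _STR_COLUMNS.items():
            if col in df.columns:
                kwargs[attr] = "" if _cell_missing(row_d[col]) else str(row_d[col])
        for col, attr in _BOOL_COLUMNS.items():
            if col in df.columns:
                kwargs[attr] = _parse_bool(row_d[col], i, col)
        calls = {
            p: normalize_call(p, None if p not in df.columns else row_d[p], call_overrides)
            for p in PREDICTORS
        }
        kwargs["predictor_calls"] = calls
        genotypes = {
            c[len(GENOTYPE_PREFIX):]: _parse_genotype(row_d[c]) for c in gt_cols
        }
        records.append(
            VariantRecord(
                key=key,
                gene="" if _cell_missing(row_d["gene"]) else str(row_d["gene"]),
                annotations=AnnotationBundle(**kwargs),
                genotypes=genotypes,
            )
        )
    return records


def frame_from_records(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Inverse of :func:`records_from_frame` (round-trips losslessly)."""
    samples = sorted({s for r in records for s in r.genotypes})
    rows = []
    for r in records:
        a = r.annotations
        row: dict[str, object] = {"variant_key": str(r.key), "gene": r.gene}
        for col, attr in _FLOAT_COLUMNS.items():
            row[col] = getattr(a, attr)
        for col, attr in _STR_COLUMNS.items():
            row[col] = getattr(a, attr) or None
        for col, attr in _BOOL_COLUMNS.items():
            v = getattr(a, attr)
            row[col] = None if v is None else int(v)
        for p in PREDICTORS:
            call = a.predictor_calls.get(p, MISSING)
            row[p] = None if call == MISSING else call
        for s in samples:
            row[GENOTYPE_PREFIX + s] = r.genotypes.get(s, "missing")
        rows.append(row)
    return pd.DataFrame(rows)


def read_variant_table(
    path: str | Path,
    dialect: str = "tsv",
    field_map: Optional[Mapping[str, str]] = None,
    call_overrides: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> list[VariantRecord]:
    """Read an annotated variant table (TSV registry or annotated VCF).

    ``field_map`` (VCF only) maps registry column names to INFO keys; the
    default assumes INFO keys equal registry names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        return records_from_frame(df, call_overrides)
    if dialect == "vcf":
        return _read_vcf(path, field_map or {}, call_overrides)
    raise ConfigurationError(f"unknown dialect {dialect!r}")


def _read_vcf(path, field_map, call_overrides):
    from cyvcf2 import VCF  # heavy import kept local

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    for v in vcf:
        for alt in v.ALT:
            row: dict[str, object] = {
                "variant_key": f"{str(v.CHROM).removeprefix('chr')}_{v.POS}_{v.REF}_{alt}",
                "gene": v.INFO.get(field_map.get("gene", "gene")),
            }
            for col in (
                list(_FLOAT_COLUMNS) + list(_STR_COLUMNS) + list(_BOOL_COLUMNS) + list(PREDICTORS)
            ):
                row[col] = v.INFO.get(field_map.get(col, col))
            for idx, s in enumerate(samples):
                gt = v.genotypes[idx]
                alleles = [a for a in gt[:-1] if a is not None and a >= 0]
                if not alleles:
                    row[GENOTYPE_PREFIX + s] = "missing"
                else:
                    n_alt = sum(a > 0 for a in alleles)
                    row[GENOTYPE_PREFIX + s] = (
                        "hom_ref" if n_alt == 0 else "het" if n_alt < len(alleles) else "hom_alt"
                    )
            rows.append(row)
    return records_from_frame(pd.DataFrame(rows), call_overrides)


def write_variant_table(records: Sequence[VariantRecord], path: str | Path) -> None:
    frame_from_records(records).to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------

def read_pedigree(path: str | Path) -> FamilyCohort:
    """Read a PED file (+ optional 7th column ``sequenced``).

    Columns: family, sample, father, mother, sex, phenotype[, sequenced].
    Phenotype 2 = affected.  Without the extension column, sequenced
    defaults to the affected flag.
    """
    families: dict[str, Family] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (6, 7):
                raise PedigreeError(f"line {lineno}: expected 6 or 7 columns, got {len(parts)}")
            fam_id, sid, father, mother, sex, pheno = parts[:6]
            affected = pheno == "2"
            sequenced = (parts[6] == "1") if len(parts) == 7 else affected
            member = Member(
                sample_id=sid,
                family_id=fam_id,
                father=None if father in ("0", ".") else father,
                mother=None if mother in ("0", ".") else mother,
                sex={"1": "male", "2": "female"}.get(sex),
                affected=affected,
                sequenced=sequenced,
            )
            families.setdefault(fam_id, Family(family_id=fam_id, members=[])).members.append(member)
    return FamilyCohort(families=families)


def write_pedigree(cohort: FamilyCohort, path: str | Path) -> None:
    with open(path, "w") as fh:
        for fam in cohort.families.values():
            for m in fam.members:
                sex = {"male": "1", "female": "2"}.get(m.sex or "", "0")
                fh.write(
                    "\t".join(
                        [
                            fam.family_id,
                            m.sample_id,
                            m.father or "0",
                            m.mother or "0",
                            sex,
                            "2" if m.affected else "1",
                            "1" if m.sequenced else "0",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# edge lists and gene sets
# ---------------------------------------------------------------------------

CHANNEL_COLUMNS = ("experiments", "databases", "coexpression")


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read a STRING-export-style weighted edge list.

    Self-edges are dropped (logged); duplicate pairs (either orientation)
    are merged keeping the channel-wise maximum.  Scores must lie in [0, 1].
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"protein_a", "protein_b"}
    if not needed <= set(df.columns):
        raise ConfigurationError(f"edge list must have columns {sorted(needed)}")
    channels = [c for c in df.columns if c not in ("protein_a", "protein_b")]
    if not any(c in channels for c in CHANNEL_COLUMNS):
        raise ConfigurationError(
            f"edge list needs at least one channel column among {CHANNEL_COLUMNS}"
        )
    for c in channels:
        df[c] = pd.to_numeric(df[c], errors="raise")
        bad = df[c].dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise TableFormatError(f"channel {c!r} has scores outside [0, 1]")
    n_self = int((df["protein_a"] == df["protein_b"]).sum())
    if n_self:
        log.info("dropping %d self-edge rows", n_self)
        df = df[df["protein_a"] != df["protein_b"]]
    a = df["protein_a"].where(df["protein_a"] < df["protein_b"], df["protein_b"])
    b = df["protein_b"].where(df["protein_a"] < df["protein_b"], df["protein_a"])
    df = df.assign(protein_a=a, protein_b=b)
    merged = df.groupby(["protein_a", "protein_b"], as_index=False)[channels].max()
    return merged


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into {term: set of uppercase gene symbols}."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        log.warning("gene-set file %s is empty", path)
        return sets
    for lineno, line in enumerate(lines, 1):
        parts = line.split("\t")
        if len(parts) < 3:
            raise TableFormatError(f"GMT line {lineno}: fewer than 3 fields")
        term = parts[0]
        genes = {g.strip().upper() for g in parts[2:] if g.strip()}
        if genes:
            sets[term] = genes
    return sets


# ---------------------------------------------------------------------------
# decision trails
# ---------------------------------------------------------------------------

def write_decision_table(trails: Iterable, path: str | Path) -> None:
    """Serialize decision trails: one TSV row per variant x criterion."""
    rows = []
    for t in trails:
        for e in t.entries:
            rows.append(
                {
                    "variant_key": str(t.variant),
                    "family_id": t.family_id if t.family_id is not None else "",
                    "gene": t.gene,
                    "consequence_class": t.consequence_class,
                    "criterion": e.criterion,
                    "inputs": json.dumps(e.inputs, sort_keys=True),
                    "threshold": "" if e.threshold is None else str(e.threshold),
                    "verdict": e.verdict,
                    "final_status": t.final_status,
                    "rejection_reason": t.rejection_reason or "",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_decision_table(path: str | Path) -> list:
    """Re-read a decision-trail TSV into DecisionTrail objects."""
    from .prioritization import CriterionEntry, DecisionTrail  # avoid cycle

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    trails: dict[tuple, DecisionTrail] = {}
    for row in df.itertuples(index=False):
        fam = row.family_id if row.family_id != "" else None
        k = (row.variant_key, fam)
        if k not in trails:
            trails[k] = DecisionTrail(
                variant=parse_variant_key(row.variant_key),
                family_id=fam,
                gene=row.gene,
                consequence_class=row.consequence_class,
                entries=[],
                final_status=row.final_status,
                rejection_reason=row.rejection_reason or None,
            )
        trails[k].entries.append(
            CriterionEntry(
                criterion=row.criterion,
                inputs=json.loads(row.inputs),
                threshold=None if row.threshold == "" else row.threshold,
                verdict=row.verdict,
            )
        )
    return list(trails.values())
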