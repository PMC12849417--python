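"""Registry of in-silico deleteriousness predictors and call normalization.

Eleven missense predictors are consulted by the ensemble vote: SIFT,
PolyPhen-2, LRT, MutationTaster, MutationAssessor, FATHMM, MetaSVM, MetaLR,
PROVEAN, AlphaMissense and REVEL.  Each tool emits its own vocabulary
("probably_damaging", "D", "likely_pathogenic", ...); the cascade works on a
normalized three-level scale plus missing.  The shipped normalization table
maps tool tokens onto that scale and can be overridden per run.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional

log = logging.getLogger(__name__)

PREDICTORS: tuple[str, ...] = (
    "sift",
    "polyphen2",
    "lrt",
    "mutation_taster",
    "mutation_assessor",
    "fathmm",
    "metasvm",
    "metalr",
    "provean",
    "alphamissense",
    "revel",
)

DELETERIOUS = "deleterious"
INTERMEDIATE = "intermediate"
BENIGN = "benign"
MISSING = "missing"
CALL_CATEGORIES = (DELETERIOUS, INTERMEDIATE, BENIGN, MISSING)

#: tokens treated as an absent call for every tool
_MISSING_TOKENS = {"", ".", "na", "nan", "none", "unknown", "u", "-"}

#: tool-agnostic token map; lowercased before lookup
_DEFAULT_TOKEN_MAP: dict[str, str] = {
    "d": DELETERIOUS,
    "deleterious": DELETERIOUS,
    "damaging": DELETERIOUS,
    "probably_damaging": DELETERIOUS,
    "disease_causing": DELETERIOUS,
    "disease_causing_automatic": DELETERIOUS,
    "a": DELETERIOUS,  # MutationTaster disease_causing_automatic
    "h": DELETERIOUS,  # MutationAssessor high
    "high": DELETERIOUS,
    "likely_pathogenic": DELETERIOUS,
    "pathogenic": DELETERIOUS,
    "p": INTERMEDIATE,  # PolyPhen-2 possibly_damaging
    "possibly_damaging": INTERMEDIATE,
    "m": INTERMEDIATE,  # MutationAssessor medium
    "medium": INTERMEDIATE,
    "ambiguous": INTERMEDIATE,
    "intermediate": INTERMEDIATE,
    "t": BENIGN,
    "tolerated": BENIGN,
    "b": BENIGN,
    "benign": BENIGN,
    "n": BENIGN,
    "neutral": BENIGN,
    "l": BENIGN,  # MutationAssessor low
    "low": BENIGN,
    "polymorphism": BENIGN,
    "polymorphism_automatic": BENIGN,
    "likely_benign": BENIGN,
    DELETERIOUS: DELETERIOUS,
    BENIGN: BENIGN,
}

#: per-tool overrides applied on top of the default map
_TOOL_TOKEN_MAPS: dict[str, dict[str, str]] = {
    # LRT's "U" (unknown) carries no information
    "lrt": {"u": MISSING},
}


def normalize_call(
    tool: str,
    raw: Optional[str],
    overrides: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> str:
    """Map one tool-specific call token onto the normalized scale.

    Unknown predictor names raise; unknown tokens degrade to ``missing``
    with a warning so a single odd annotation cannot abort a run.
    """
    if tool not in PREDICTORS:
        raise KeyError(f"unknown predictor name: {tool!r}")
    if raw is None:
        return MISSING
    token = str(raw).strip().lower().replace(" ", "_")
    if token in _MISSING_TOKENS:
        return MISSING
    table = dict(_DEFAULT_TOKEN_MAP)
    table.update(_TOOL_TOKEN_MAPS.get(tool, {}))
    if overrides and tool in overrides:
        table.update({k.lower(): v for k, v in overrides[tool].items()})
    if token in table:
        return table[token]
    log.warning("unrecognized %s call %r treated as missing", tool, raw)
    return MISSING
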