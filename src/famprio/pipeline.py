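"""End-to-end orchestration: config, stage running, tallies, reports.

``run_pipeline`` wires the stages together — read inputs, run the
prioritization cascade, write decision trails and a prioritized variant
table, run the network stage (combined-score filtering, PPI enrichment,
MCL clustering, per-cluster gene-set enrichment) and emit a tally report
plus a JSON run manifest.  All randomness flows from the single config
seed, so re-running a config is bit-identical in every tabular output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import cohort_io, network as net, prioritization as prio
from .prioritization import Thresholds

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Single config object carrying every path and threshold of a run."""

    variants: Optional[str] = None
    pedigree: Optional[str] = None
    edges: Optional[str] = None
    gene_sets: Optional[str] = None
    known_genes: Optional[str] = None
    out_dir: str = "famprio_out"
    thresholds: Thresholds = field(default_factory=Thresholds)
    min_edge_score: float = 0.400
    channel_prior: float = net.STRING_PRIOR
    mcl: net.MCLParams = field(default_factory=net.MCLParams)
    enrichment_method: str = "permutation"
    enrichment_reps: int = 1000
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "thresholds" in raw:
            raw["thresholds"] = Thresholds(**raw["thresholds"])
        if "mcl" in raw:
            raw["mcl"] = net.MCLParams(**raw["mcl"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class TallyReport:
    """Funnel bookkeeping over a prioritized variant table.

    Counts rows (variant x family assignments) by consequence class,
    overall and split by cohort mode, per family with min/max, and tabulates
    recurrence: variant keys shared by more than one family/case.
    """

    total_rows: int
    class_counts: dict[str, int]
    class_counts_by_mode: dict[str, dict[str, int]]
    per_family: dict[str, int]
    family_range: dict[str, dict[str, object]]
    recurrence: dict[str, list[str]]
    distinct_variants: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def tally_report(
    prioritized: pd.DataFrame,
    known_families: Optional[Mapping[str, str]] = None,
) -> TallyReport:
    """Tally a prioritized table (columns family_id, mode,
    consequence_class, variant_key).

    ``known_families`` (family -> mode) validates the table's family IDs;
    an unknown family raises.
    """
    required = {"family_id", "consequence_class", "variant_key"}
    missing = required - set(prioritized.columns)
    if missing:
        raise cohort_io.ConfigurationError(f"tally input missing columns: {sorted(missing)}")
    df = prioritized.copy()
    if known_families is not None:
        unknown = set(df["family_id"]) - set(known_families)
        if unknown:
            raise ValueError(f"rows with unknown family IDs: {sorted(unknown)}")
        if "mode" not in df.columns:
            df["mode"] = df["family_id"].map(dict(known_families))
    if "mode" not in df.columns:
        df["mode"] = "multi_case"

    class_counts = df["consequence_class"].value_counts().to_dict()
    by_mode = {
        mode: sub["consequence_class"].value_counts().to_dict()
        for mode, sub in df.groupby("mode")
    }
    per_family = df.groupby("family_id").size().to_dict()
    family_range: dict[str, dict[str, object]] = {}
    for mode, sub in df.groupby("mode"):
        counts = sub.groupby("family_id").size()
        family_range[str(mode)] = {
            "min": int(counts.min()), "min_family": str(counts.idxmin()),
            "max": int(counts.max()), "max_family": str(counts.idxmax()),
        }
    rec = {
        key: sorted(set(sub["family_id"]))
        for key, sub in df.groupby("variant_key")
        if sub["family_id"].nunique() > 1
    }
    return TallyReport(
        total_rows=int(len(df)),
        class_counts={k: int(v) for k, v in class_counts.items()},
        class_counts_by_mode={m: {k: int(v) for k, v in d.items()} for m, d in by_mode.items()},
        per_family={k: int(v) for k, v in per_family.items()},
        family_range=family_range,
        recurrence=rec,
        distinct_variants=int(df["variant_key"].nunique()),
    )


def prioritized_frame(trails, cohort: cohort_io.FamilyCohort) -> pd.DataFrame:
    """Table-style summary of the prioritized trails (one row per
    variant x family), with the scores a reviewer wants next to each call."""
    rows = []
    modes = {fid: f.mode for fid, f in cohort.families.items()}
    for t in prio.prioritized_set(trails):
        vote = next(e for e in t.entries if e.criterion == "deleteriousness_vote")
        lof = t.advisory.get("lof")
        rows.append(
            {
                "family_id": t.family_id,
                "mode": modes.get(t.family_id, ""),
                "gene": t.gene,
                "variant_key": str(t.variant),
                "consequence_class": t.consequence_class,
                "vote_credits": vote.inputs.get("credits"),
                "vote_n_tools": vote.inputs.get("n_tools"),
                "mutpred_tier": getattr(lof, "mutpred_tier", ""),
                "splice_tier": getattr(lof, "splice_tier", ""),
                "mmsplice_tier": getattr(lof, "mmsplice_tier", ""),
                "z_constrained": t.advisory.get("constraint", {}).get("z_constrained"),
                "loeuf_constrained": t.advisory.get("constraint", {}).get("loeuf_constrained"),
            }
        )
    cols = ["family_id", "mode", "gene", "variant_key", "consequence_class",
            "vote_credits", "vote_n_tools", "mutpred_tier", "splice_tier",
            "mmsplice_tier", "z_constrained", "loeuf_constrained"]
    return pd.DataFrame(rows, columns=cols)


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; returns the output bundle as a dict of
    paths and summary objects.  Any stage error aborts with the stage name."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "thresholds": dataclasses.asdict(config.thresholds),
        "stages": {},
    }
    bundle: dict = {"manifest": manifest}

    try:
        records = cohort_io.read_variant_table(config.variants)
        cohort = cohort_io.read_pedigree(config.pedigree)
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError("cohort_io", e) from e
    manifest["stages"]["cohort_io"] = {
        "n_records": len(records),
        "n_families": len(cohort.families),
    }

    try:
        trails = prio.prioritize(records, cohort, config.thresholds)
        cohort_io.write_decision_table(trails, out / "decision_trails.tsv")
        prioritized = prioritized_frame(trails, cohort)
        prioritized.to_csv(out / "prioritized.tsv", sep="\t", index=False)
        if config.known_genes:
            genes = [g.strip() for g in Path(config.known_genes).read_text().split() if g.strip()]
            hits = prio.known_gene_screen(records, genes)
            pd.DataFrame(
                {"variant_key": [str(r.key) for r in hits], "gene": [r.gene for r in hits]}
            ).to_csv(out / "known_gene_hits.tsv", sep="\t", index=False)
            manifest["stages"]["known_gene_screen"] = {"n_hits": len(hits)}
    except Exception as e:
        raise StageError("prioritization", e) from e
    manifest["stages"]["prioritization"] = {
        "n_trails": len(trails),
        "n_prioritized": int(len(prioritized)),
    }
    bundle["prioritized"] = prioritized
    bundle["trails"] = trails

    try:
        tally = tally_report(
            prioritized,
            known_families={fid: f.mode for fid, f in cohort.families.items()},
        ) if len(prioritized) else None
        with open(out / "tally.json", "w") as fh:
            json.dump(tally.to_dict() if tally else {"total_rows": 0}, fh, indent=2)
        bundle["tally"] = tally
    except Exception as e:
        raise StageError("report", e) from e

    if config.edges:
        try:
            edge_df = cohort_io.read_edge_list(config.edges)
            full = net.Network.from_edge_table(edge_df, prior=config.channel_prior)
            filtered = net.filter_edges(full, config.min_edge_score)
            query = sorted(set(prioritized["gene"]) & filtered.nodes)
            network_out: dict = {"n_query_in_network": len(query)}
            if len(query) >= 2:
                enr = net.ppi_enrichment(
                    filtered, query, method=config.enrichment_method,
                    reps=config.enrichment_reps, seed=config.seed,
                )
                network_out["ppi"] = {
                    "observed_edges": enr.observed_edges,
                    "expected_edges": enr.expected_edges,
                    "p_value": enr.p_value,
                    "method": enr.method,
                }
                clusters = net.mcl_cluster(filtered, config.mcl, nodes=query)
                pd.DataFrame(
                    [
                        {"cluster": i, "size": len(c), "proteins": ";".join(sorted(c))}
                        for i, c in enumerate(clusters.clusters)
                    ]
                ).to_csv(out / "clusters.tsv", sep="\t", index=False)
                network_out["n_clusters"] = len(clusters)
                if config.gene_sets:
                    sets = cohort_io.read_gene_sets(config.gene_sets)
                    universe = filtered.nodes
                    rows = []
                    for i, cluster in enumerate(clusters.clusters):
                        if len(cluster) < 2:
                            continue
                        res = net.gene_set_enrichment(cluster, sets, universe)
                        top = res.terms.head(5).assign(cluster=i)
                        rows.append(top)
                    terms = (
                        pd.concat(rows, ignore_index=True)
                        if rows
                        else pd.DataFrame(columns=["cluster", "term", "p", "q"])
                    )
                    terms.to_csv(out / "cluster_terms.tsv", sep="\t", index=False)
            with open(out / "network.json", "w") as fh:
                json.dump(network_out, fh, indent=2)
            manifest["stages"]["network"] = network_out
        except Exception as e:
            raise StageError("network", e) from e

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return bundle
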