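"""End-to-end pipeline: inputs -> mapping -> features -> comparisons -> enrichment.

A run consumes either file-based inputs (FASTA, gene lists, mapping table,
profile/track directories, edge list, OBO + GAF) or the synthetic generator,
and writes plain TSV tables plus a machine-readable JSON summary into a run
directory, so any stage can be rerun or replaced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from . import __version__
from .errors import DegcharError, InputError
from .compare import ComparisonResult, compare_feature, length_matched_sample
from .enrichment import (
    ALPHA,
    MIN_FOLD,
    MIN_OBSERVED,
    GeneOntology,
    analyze_enrichment,
    enrichment_table,
    propagate_annotations,
    read_gaf,
)
from .features import (
    PPINetwork,
    compute_feature_table,
    read_profile,
    read_tracks,
    write_feature_table,
)
from .mapping import (
    ProteinRecord,
    map_to_proteins,
    merge_gene_lists,
    read_fasta,
    read_gene_list,
    read_mapping_table,
    split_by_regulation,
    write_protein_table,
)
from .synthetic_data import (
    SimulationConfig,
    SyntheticGO,
    generate_deg_lists,
    generate_disorder_tracks,
    generate_go,
    generate_ppi,
    generate_profiles,
    generate_proteome,
    write_fasta,
)

log = logging.getLogger("degchar")

FEATURE_COLUMNS = {
    "conservation": "conservation_nats",
    "disorder": "disorder_content",
    "ppi": "degree",
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run (synthetic or file-based)."""

    mode: str = "synthetic"  # synthetic | files
    seed: int = 0
    out_dir: str = "degchar_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # feature toggles
    conservation: bool = True
    disorder: bool = True
    ppi: bool = True
    enrichment: bool = True
    # analysis settings (study defaults)
    with_mann_whitney: bool = True
    min_observed: int = MIN_OBSERVED
    min_fold: float = MIN_FOLD
    alpha: float = ALPHA
    go_cluster_top: int = 3  # retained terms used as Fig.-3-style clusters
    shared_background: bool = True  # one background sample for all comparisons
    # file-based inputs
    fasta: Optional[str] = None
    list_a: Optional[str] = None
    list_b: Optional[str] = None
    mapping_table: Optional[str] = None
    profiles_dir: Optional[str] = None
    tracks_dir: Optional[str] = None
    edge_list: Optional[str] = None
    obo: Optional[str] = None
    gaf: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise InputError(f"unknown mode {self.mode!r}")
        if self.mode == "files":
            required = ["fasta", "list_a", "list_b", "mapping_table"]
            if self.enrichment:
                required += ["obo", "gaf"]
            if self.ppi:
                required += ["edge_list"]
            if self.conservation:
                required += ["profiles_dir"]
            if self.disorder:
                required += ["tracks_dir"]
            missing = [k for k in required if getattr(self, k) is None]
            if missing:
                raise InputError(f"files mode requires paths for: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise InputError("run config must be a YAML mapping")
        sim = raw.pop("simulation", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
        bad = set(sim) - sim_fields
        if bad:
            raise InputError(f"unknown simulation keys: {sorted(bad)}")
        if "planted_terms" in sim:
            sim["planted_terms"] = tuple(tuple(t) for t in sim["planted_terms"])
        for key in ("predictor_flip_rates", "deg_list_sizes"):
            if key in sim:
                sim[key] = tuple(sim[key])
        sim.setdefault("seed", raw.get("seed", 0))
        return cls(simulation=SimulationConfig(**sim), **raw)


def _summary_dict(result: ComparisonResult) -> dict[str, Any]:
    def summ(s):
        return None if s is None else dataclasses.asdict(s)

    return {
        "feature": result.feature,
        "performed": result.performed,
        "significant": result.significant,
        "ks_D": result.ks_D,
        "ks_p": result.ks_p,
        "mw_U": result.mw_U,
        "mw_p": result.mw_p,
        "n_focal": result.n_focal,
        "n_background": result.n_background,
        "n_excluded": result.n_excluded,
        "focal": summ(result.focal_summary),
        "background": summ(result.background_summary),
        "note": result.note,
    }


def _comparison_rows(group: str, results: list[ComparisonResult]) -> list[dict]:
    rows = []
    for r in results:
        rows.append(
            {
                "group": group,
                "feature": r.feature,
                "performed": r.performed,
                "ks_D": r.ks_D,
                "ks_p": r.ks_p,
                "mw_U": r.mw_U,
                "mw_p": r.mw_p,
                "n_focal": r.n_focal,
                "n_background": r.n_background,
                "n_excluded": r.n_excluded,
                "focal_median": None if r.focal_summary is None else r.focal_summary.median,
                "background_median": None if r.background_summary is None else r.background_summary.median,
                "note": r.note,
            }
        )
    return rows


def run_pipeline(config: RunConfig) -> Path:
    """Execute all enabled stages; returns the run directory.

    On a stage failure a FAILED marker naming the stage is written next to
    any partial outputs and the exception is re-raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    stage = "setup"
    try:
        summary: dict[str, Any] = {
            "version": __version__,
            "seed": config.seed,
            "mode": config.mode,
        }
        log.info("degchar %s starting run (mode=%s, seed=%d)",
                 __version__, config.mode, config.seed)

        stage = "inputs"
        synthetic_go: Optional[SyntheticGO] = None
        if config.mode == "synthetic":
            sim = config.simulation
            records = generate_proteome(sim)
            deg = generate_deg_lists(records, sim)
            list_a, list_b = deg.list_a, deg.list_b
            mapping_rows = deg.mapping_table
            sequences = {r.accession: r.sequence for r in records}
            inputs_dir = out / "inputs"
            inputs_dir.mkdir(exist_ok=True)
            write_fasta(inputs_dir / "proteome.fasta", records)
            network = generate_ppi(records, sim,
                                   inputs_dir / "ppi_edges.tsv") if config.ppi else None
            if config.enrichment:
                synthetic_go = generate_go(records, sim,
                                           inputs_dir / "ontology.obo",
                                           inputs_dir / "annotations.gaf")
        else:
            sequences = read_fasta(config.fasta)
            records = [
                ProteinRecord(acc, gene_id="", sequence=seq)
                for acc, seq in sequences.items()
            ]
            list_a = read_gene_list(config.list_a)
            list_b = read_gene_list(config.list_b)
            mapping_rows = read_mapping_table(config.mapping_table)
            network = (
                PPINetwork.from_edge_list(config.edge_list) if config.ppi else None
            )

        stage = "mapping"
        merged = merge_gene_lists(list_a, list_b)
        if merged.conflicts:
            log.warning("direction conflicts excluded: %s",
                        [c[0] for c in merged.conflicts])
        mapped = map_to_proteins(merged.genes, mapping_rows, sequences)
        focal = mapped.proteins
        ups, downs = split_by_regulation(focal)
        write_protein_table(out / "proteins.tsv", focal)
        (out / "unmapped_genes.tsv").write_text(
            "gene_id\n" + "".join(f"{g}\n" for g in sorted(mapped.unmapped))
        )
        (out / "conflicts.tsv").write_text(
            "gene_id\tdirection_a\tdirection_b\n"
            + "".join(f"{g}\t{a}\t{b}\n" for g, a, b in merged.conflicts)
        )
        summary["mapping"] = {
            "n_genes_union": len(merged.genes) + len(merged.conflicts),
            "n_genes_merged": len(merged.genes),
            "n_conflicts": len(merged.conflicts),
            "n_unmapped": len(mapped.unmapped),
            "n_mapped_genes": len({p.gene_id for p in focal}),
            "n_proteins": len(focal),
            "n_up": len(ups),
            "n_down": len(downs),
        }
        log.info("mapping: %d proteins (%d up / %d down) from %d genes, "
                 "%d unmapped", len(focal), len(ups), len(downs),
                 len({p.gene_id for p in focal}), len(mapped.unmapped))

        stage = "background"
        focal_accs = {p.accession for p in focal}
        pool = [rec for rec in records if rec.accession not in focal_accs]
        background = length_matched_sample(pool, focal, seed=config.seed)
        summary["background"] = {"n": len(background)}

        stage = "features"
        analysis_records = focal + background
        group = {p.accession: "focal" for p in focal}
        group.update({p.accession: "background" for p in background})
        profiles = tracks = None
        if config.conservation:
            if config.mode == "synthetic":
                profiles = generate_profiles(analysis_records, config.simulation)
            else:
                profiles = {
                    r.accession: read_profile(
                        Path(config.profiles_dir) / f"{r.accession}.tsv", r.accession
                    )
                    for r in analysis_records
                }
        if config.disorder:
            if config.mode == "synthetic":
                tracks = generate_disorder_tracks(analysis_records, config.simulation)
            else:
                tracks = {
                    r.accession: read_tracks(
                        Path(config.tracks_dir) / f"{r.accession}.tsv", r.accession
                    )
                    for r in analysis_records
                }
        table = compute_feature_table(
            analysis_records, profiles=profiles, tracks=tracks,
            network=network if config.ppi else None, group=group,
        )
        write_feature_table(out / "features.tsv", table)
        if config.ppi and network is not None:
            n_absent = int(table["degree"].isna().sum())
            log.info("PPI: %d of %d proteins without network information",
                     n_absent, len(table))

        stage = "enrichment"
        enrichment_summary: dict[str, Any] = {}
        retained_terms: list[str] = []
        annotations = None
        ontology = None
        if config.enrichment:
            if config.mode == "synthetic":
                ontology = GeneOntology.from_synthetic(synthetic_go)
                direct = synthetic_go.direct_annotations
            else:
                ontology = GeneOntology.from_obo(config.obo)
                direct = read_gaf(config.gaf)
                direct = {acc: direct.get(acc, set()) for acc in sequences}
            records_enr = analyze_enrichment(
                ontology, direct, focal_accs,
                min_observed=config.min_observed,
                min_fold=config.min_fold, alpha=config.alpha,
            )
            df = enrichment_table(records_enr)
            df.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                      float_format="%.6g")
            annotations = propagate_annotations(ontology, direct)
            passing = df[df["passes_filters"] == True]  # noqa: E712
            retained = df[df["retained_after_reduction"] == True]  # noqa: E712
            retained_terms = list(
                retained.sort_values("fold", ascending=False)["term"]
            )[: config.go_cluster_top]
            enrichment_summary = {
                "n_terms": len(df),
                "n_passing": int(len(passing)),
                "n_retained": int(len(retained)),
                "retained_terms": retained_terms,
            }
            log.info("enrichment: %d terms pass filters, %d retained",
                     len(passing), len(retained))
        summary["enrichment"] = enrichment_summary

        stage = "compare"
        bg_mask = table["group"] == "background"
        up_accs = {p.accession for p in ups}
        down_accs = {p.accession for p in downs}
        subsets = {"all": set(focal_accs), "up": up_accs, "down": down_accs}
        for term in retained_terms:
            members = {
                acc for acc in focal_accs if term in annotations.get(acc, ())
            }
            subsets[f"go:{term}"] = members
        features_on = [
            name for name in FEATURE_COLUMNS if getattr(config, name)
        ]
        comparison_rows = []
        summary["comparisons"] = {}
        for label, accs in subsets.items():
            focal_mask = table["accession"].isin(accs)
            results = []
            for name in features_on:
                col = FEATURE_COLUMNS[name]
                results.append(
                    compare_feature(
                        table.loc[focal_mask, col],
                        table.loc[bg_mask, col],
                        feature=name,
                        with_mann_whitney=config.with_mann_whitney,
                    )
                )
            comparison_rows += _comparison_rows(label, results)
            summary["comparisons"][label] = [_summary_dict(r) for r in results]
        pd.DataFrame(comparison_rows).to_csv(
            out / "comparisons.tsv", sep="\t", index=False, float_format="%.6g"
        )

        stage = "summary"
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        log.info("run complete: %s", out)
        return out
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        log.error("stage %s failed: %s", stage, exc)
        raise DegcharError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
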