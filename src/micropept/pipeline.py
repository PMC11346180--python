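"""Pipeline orchestration and study-style reports.

``run_pipeline`` executes the full identification-validation chain on a
dataset directory (typically written by the synthetic generator):
database build (90%-identity collapse of the microbiota proteins +
combined database), origin classification of the PSM peptides,
single-substitution (SAP) homology filtering, equal-division fractional
spectral counting with phylum and body-site aggregation, the 36-pattern
cleavage enrichment scan, and the physicochemical group comparison.
Every stage logs its input/output record counts and all artifacts are
deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .cleavage import run_catalogue
from .homology import PeptideRecord, ProteomeIndex, classify_origin, filter_sap_homologs
from .physchem import compare_aa_composition, compare_groups, comparisons_to_frame, descriptor_table
from .seqdb import build_combined_db, cluster_by_identity, read_fasta, write_manifest
from .taxcount import (
    TaxonomyTree,
    aggregate_rank,
    body_site_profile,
    map_occurrences,
    read_site_annotation,
    spectral_count_db,
    write_count_table,
)

__all__ = [
    "RunConfig",
    "GroupSummaryRow",
    "summary_table",
    "timecourse_report",
    "run_pipeline",
    "PipelineError",
]

logger = logging.getLogger("micropept")

DEFAULT_THRESHOLDS = {
    "alc_spectrum": 80.0,
    "alc_candidate": 50.0,
    "sap_max_mismatch": 1,
    "identity": 0.90,
    "max_internal_sites": 2,
    "correlation_tolerance": 0.05,
    "cv_limit": 0.20,
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs, thresholds and output location for one pipeline run."""

    input_dir: Path
    output_dir: Path
    seed: int = 0
    protease_rules: Sequence[str] | None = None  # None = full catalogue
    thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        if not 0 < self.thresholds["identity"] <= 1:
            raise ValueError("identity threshold must be in (0, 1]")
        if self.thresholds["sap_max_mismatch"] not in (0, 1):
            raise ValueError("sap_max_mismatch must be 0 or 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            input_dir=Path(data["input_dir"]),
            output_dir=Path(data["output_dir"]),
            seed=int(data.get("seed", 0)),
            protease_rules=data.get("protease_rules"),
            thresholds=data.get("thresholds", {}),
        )


@dataclass(frozen=True)
class GroupSummaryRow:
    group: str
    n_human: int
    n_microbiota: int
    pct_microbiota: float  # percent, half-up to 2 decimals


def _round_pct(n_microbiota: int, n_human: int) -> float:
    total = n_human + n_microbiota
    if total == 0:
        raise ValueError("group with zero peptides")
    pct = Decimal(100 * n_microbiota) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summary_table(records: pd.DataFrame) -> list[GroupSummaryRow]:
    """Per-group unique-peptide counts by origin plus a pooled Total row.

    ``records`` needs columns ``group``, ``sequence`` and ``origin``
    (human/microbiota); the percentage column is the microbiota share of
    each group's unique peptides, rounded half-up to 2 decimals.
    """
    rows: list[GroupSummaryRow] = []

    def count(frame: pd.DataFrame) -> tuple[int, int]:
        human = frame.loc[frame["origin"] == "human", "sequence"].nunique()
        microbiota = frame.loc[frame["origin"] == "microbiota", "sequence"].nunique()
        return human, microbiota

    for group, frame in records.groupby("group", sort=True):
        n_h, n_m = count(frame)
        rows.append(GroupSummaryRow(str(group), n_h, n_m, _round_pct(n_m, n_h)))
    n_h, n_m = count(records)
    rows.append(GroupSummaryRow("Total", n_h, n_m, _round_pct(n_m, n_h)))
    return rows


def summary_from_counts(groups: Mapping[str, tuple[int, int]]) -> list[GroupSummaryRow]:
    """Summary rows straight from (n_human, n_microbiota) count pairs,
    with a pooled Total row."""
    rows = [
        GroupSummaryRow(g, h, m, _round_pct(m, h))
        for g, (h, m) in groups.items()
    ]
    tot_h = sum(h for h, _ in groups.values())
    tot_m = sum(m for _, m in groups.values())
    rows.append(GroupSummaryRow("Total", tot_h, tot_m, _round_pct(tot_m, tot_h)))
    return rows


def timecourse_report(
    records: pd.DataFrame,
    occurrences: Mapping[str, Sequence[tuple[str, int]]],
    tree: TaxonomyTree,
    time_points: Sequence[str] = ("pre-meal", "3h", "5h", "7h", "9h"),
) -> pd.DataFrame:
    """Per-time-point non-human spectral counts by phylum.

    ``records`` needs columns ``time_label``, ``peptide``,
    ``spectral_count`` and ``origin``; rows with origin "human" are
    excluded, the rest are counted by equal division and aggregated at
    the phylum rank.  Counts are conserved per time point.
    """
    known = set(time_points)
    bad = set(records["time_label"]) - known
    if bad:
        raise ValueError(f"unknown time label(s): {sorted(bad)}")
    blocks = []
    for label in time_points:
        sub = records[
            (records["time_label"] == label) & (records["origin"] != "human")
        ]
        if sub.empty:
            continue
        counts = spectral_count_db(sub, occurrences, tree)
        fractions = aggregate_rank(counts, "phylum", tree)
        total = counts.total()
        for taxon, frac in sorted(fractions.items()):
            blocks.append(
                dict(
                    time_label=label,
                    phylum=taxon,
                    fractional_count=frac * total,
                    fraction=frac,
                    n_bacterial_spectra=total,
                )
            )
    return pd.DataFrame(blocks)


# --- full pipeline -------------------------------------------------------

def _stage(name: str):
    logger.info("stage %s", name)
    return name


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages on a dataset directory and write the report
    artifacts plus a machine-readable run manifest.

    Expects in ``input_dir``: ``human.fasta``, ``microbiota.fasta``,
    ``taxonomy.tsv``, ``psm.tsv`` and optionally ``sites.tsv``.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "setup"
    counts_log: dict[str, dict[str, int]] = {}
    try:
        stage = _stage("load_inputs")
        human = read_fasta(config.input_dir / "human.fasta", origin="human")
        microbiota = read_fasta(config.input_dir / "microbiota.fasta", origin="microbiota")
        tree = TaxonomyTree.from_tsv(config.input_dir / "taxonomy.tsv")
        psm = pd.read_csv(config.input_dir / "psm.tsv", sep="\t")
        sites_path = config.input_dir / "sites.tsv"
        site_annotation = read_site_annotation(sites_path) if sites_path.exists() else {}
        counts_log[stage] = {
            "human_proteins": len(human),
            "microbiota_proteins": len(microbiota),
            "psm_rows": len(psm),
        }

        stage = _stage("build_db")
        clusters = cluster_by_identity(microbiota, threshold=config.thresholds["identity"])
        combined = build_combined_db(human, clusters.representatives)
        write_manifest(combined, out / "database_manifest.tsv")
        counts_log[stage] = {
            "microbiota_input": len(microbiota),
            "microbiota_representatives": len(clusters),
            "combined_entries": len(combined),
        }

        stage = _stage("classify_origin")
        human_index = ProteomeIndex(human, origin="human")
        # occurrence counting runs against the database *before* the
        # homology collapse, so the full microbiota set is indexed
        microbiota_index = ProteomeIndex(microbiota, origin="microbiota")
        peptides = sorted(set(psm["peptide"]))
        origin_of = {
            p: classify_origin(p, human_index, microbiota_index) for p in peptides
        }
        psm = psm.assign(origin=psm["peptide"].map(origin_of))
        counts_log[stage] = {
            "unique_peptides": len(peptides),
            "human": sum(1 for v in origin_of.values() if v == "human"),
            "microbiota": sum(1 for v in origin_of.values() if v == "microbiota"),
            "unmatched": sum(1 for v in origin_of.values() if v == "unmatched"),
        }

        stage = _stage("sap_filter")
        microbiota_records = [
            PeptideRecord(sequence=p, origin="microbiota")
            for p, o in sorted(origin_of.items())
            if o == "microbiota"
        ]
        retained, removed = filter_sap_homologs(microbiota_records, human_index)
        retained_seqs = {r.sequence for r in retained}
        removed_seqs = {r.sequence for r in removed}
        validated = psm[
            (psm["origin"] == "human") | psm["peptide"].isin(retained_seqs)
        ]
        pd.DataFrame(
            {
                "sequence": sorted(retained_seqs) + sorted(removed_seqs),
                "removal_reason": [""] * len(retained_seqs)
                + ["sap_homolog"] * len(removed_seqs),
            }
        ).to_csv(out / "sap_filter.tsv", sep="\t", index=False)
        counts_log[stage] = {
            "input": len(microbiota_records),
            "retained": len(retained),
            "removed": len(removed),
        }

        stage = _stage("spectral_counting")
        bact = validated[validated["origin"] == "microbiota"]
        occurrences = {
            p: map_occurrences(p, microbiota_index) for p in sorted(set(bact["peptide"]))
        }
        counts = spectral_count_db(bact, occurrences, tree)
        write_count_table(counts, tree, out / "taxon_counts.tsv")
        counts_log[stage] = {"bacterial_spectra": int(len(bact))}

        stage = _stage("aggregate_phylum")
        if counts.counts:
            phylum = aggregate_rank(counts, "phylum", tree)
            pd.DataFrame(
                sorted(phylum.items()), columns=["label", "fraction"]
            ).to_csv(out / "phylum_fractions.tsv", sep="\t", index=False)

        stage = _stage("body_sites")
        organism_counts = {
            k: v for k, v in counts.counts.items() if isinstance(k, int)
        }
        profile = body_site_profile(organism_counts, site_annotation)
        pd.DataFrame(
            sorted(profile.items()), columns=["site", "percentage"]
        ).to_csv(out / "body_sites.tsv", sep="\t", index=False)

        stage = _stage("cleavage_stats")
        bact_peps = sorted(retained_seqs)
        human_peps = sorted(
            set(psm.loc[psm["origin"] == "human", "peptide"])
        )
        if bact_peps and human_peps:
            rules = config.protease_rules
            cleavage_df = run_catalogue(
                bact_peps,
                human_peps,
                rules=rules,
                max_sites=int(config.thresholds["max_internal_sites"]),
            )
            cleavage_df.to_csv(out / "cleavage_enrichment.tsv", sep="\t", index=False)

        stage = _stage("physchem")
        if len(bact_peps) >= 2 and len(human_peps) >= 2:
            b_desc = descriptor_table(bact_peps)
            h_desc = descriptor_table(human_peps)
            desc = comparisons_to_frame(compare_groups(b_desc, h_desc))
            desc.to_csv(out / "physchem_comparison.tsv", sep="\t", index=False)
            aa = comparisons_to_frame(compare_aa_composition(bact_peps, human_peps))
            aa.to_csv(out / "aa_composition_comparison.tsv", sep="\t", index=False)

        stage = _stage("report")
        grouped = validated.assign(
            group=validated["sample_id"], sequence=validated["peptide"]
        )
        rows = summary_table(grouped[grouped["origin"].isin(["human", "microbiota"])])
        pd.DataFrame([r.__dict__ for r in rows]).to_csv(
            out / "summary_table.tsv", sep="\t", index=False
        )
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "input_dir": str(config.input_dir),
            "thresholds": config.thresholds,
            "stage_counts": counts_log,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return out
    except Exception as exc:  # surface the failing stage
        raise PipelineError(stage, str(exc)) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
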