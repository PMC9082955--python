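"""End-to-end orchestration: refine -> quantify -> associate -> summarize."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import association, io, psi, qc
from .refine import DEFAULT_CUT_HEIGHT, EnhancerInterval, RefinedEnhancer, call_presence, refine_enhancers


@dataclass
class PipelineResult:
    """All intermediate and final tables of one association run."""

    refined: list[RefinedEnhancer]
    presence: pd.DataFrame
    psi_table: pd.DataFrame
    records: pd.DataFrame
    summary: pd.DataFrame
    degrees: dict[str, float]
    log: dict[str, int] = field(default_factory=dict)


def run_pipeline(
    intervals: list[EnhancerInterval],
    junctions: pd.DataFrame,
    sample_map: pd.DataFrame,
    pairings: pd.DataFrame,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    min_range: float = psi.DEFAULT_MIN_RANGE,
    z_cut: float = psi.DEFAULT_Z_CUT,
    or_hi: float = association.DEFAULT_OR_HI,
    or_lo: float = association.DEFAULT_OR_LO,
    min_effect: float = association.DEFAULT_MIN_EFFECT,
    fdr: float = association.DEFAULT_FDR,
    joint_bh: bool = True,
    bh_scope: str = "all",
    tissue_level: bool = False,
) -> PipelineResult:
    """Run the full association analysis on in-memory inputs."""
    refined = refine_enhancers(intervals, cut_height=cut_height)
    tissues = sorted(set(sample_map["tissue"]) | {iv.tissue for iv in intervals})
    presence = call_presence(refined, tissues)

    psi_table = psi.quantify(
        junctions, sample_map, min_range=min_range, z_cut=z_cut, tissue_level=tissue_level
    )
    records = association.run_association(
        presence,
        psi_table,
        pairings,
        or_hi=or_hi,
        or_lo=or_lo,
        min_effect=min_effect,
        fdr=fdr,
        joint_bh=joint_bh,
        bh_scope=bh_scope,
    )
    summary = association.summarize_counts(records)
    degrees = association.enhancers_per_gene(records, pairings)

    n_events_in = junctions["event_id"].nunique()
    n_events_kept = psi_table["event_id"].nunique() if len(psi_table) else 0
    log = {
        "n_input_intervals": len(intervals),
        "n_refined_enhancers": len(refined),
        "n_input_events": int(n_events_in),
        "n_events_after_range_filter": int(n_events_kept),
        "n_events_dropped_by_range_filter": int(n_events_in - n_events_kept),
        "n_pairings": len(pairings),
        "n_skipped_pairings": int(records.attrs.get("n_skipped_pairings", 0)),
        "n_records": len(records),
        "n_tested_records": int(records["prefilter_pass"].sum()) if len(records) else 0,
        "n_dropped_by_prefilter": int((~records["prefilter_pass"]).sum()) if len(records) else 0,
        "n_significant": int(records["significant"].sum()) if len(records) else 0,
    }
    return PipelineResult(refined, presence, psi_table, records, summary, degrees, log)


def load_bundle(bundle_dir: str | Path) -> dict:
    """Load a fixture bundle written by ``synthetic.emit_fixture_bundle``."""
    bundle = Path(bundle_dir)
    bed_paths = sorted((bundle / "enhancers").glob("*.bed"))
    if not bed_paths:
        raise FileNotFoundError(f"no enhancer BED files under {bundle / 'enhancers'}")
    return {
        "intervals": io.read_enhancer_beds(bed_paths),
        "junctions": io.read_junction_counts(bundle / "junctions.tsv"),
        "sample_map": io.read_sample_map(bundle / "samples.tsv"),
        "pairings": io.read_pairings(bundle / "pairs.tsv"),
    }


def run_bundle(bundle_dir: str | Path, **params) -> PipelineResult:
    """Load a bundle directory and run the pipeline on it."""
    inputs = load_bundle(bundle_dir)
    return run_pipeline(
        inputs["intervals"], inputs["junctions"], inputs["sample_map"], inputs["pairings"], **params
    )


def write_results(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write refined enhancers, presence, PSI, association, and summary tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "refined": io.write_refined_bed(result.refined, out / "refined_enhancers.tsv"),
        "presence": io.write_presence_matrix(result.presence, out / "presence_matrix.tsv"),
        "psi": io.write_table(result.psi_table, out / "psi_table.tsv"),
        "associations": io.write_table(result.records, out / "associations.tsv"),
        "summary": io.write_table(result.summary, out / "summary_counts.tsv"),
    }
    log_df = pd.DataFrame(sorted(result.log.items()), columns=["quantity", "count"])
    paths["log"] = io.write_table(log_df, out / "run_log.tsv")
    return paths


def sample_similarity(result: PipelineResult, pairings: pd.DataFrame) -> pd.DataFrame:
    """Pairwise sample-similarity (QC) matrix for a finished run."""
    calls = qc.sample_call_matrix(result.presence, result.psi_table, pairings)
    return qc.jaccard_matrix(calls)
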