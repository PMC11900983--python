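"""End-to-end orchestration of the analysis stages.

``run_all`` chains simulation (or loading), lncRNA screening,
differential expression over the 12 time contrasts, calcium attribution,
osmotic-set selection, co-expression module detection and cis-target
prediction, and can write every stage's tables under an output
directory.  The CLI is a thin wrapper over these functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import attribution, cis, coexpress, diffexpr, identify
from . import io as cio
from .simulate import SimulationBundle, SimulationConfig, simulate_all
from .types import ExpressionMatrix, TranscriptRecord

log = logging.getLogger(__name__)


@dataclass
class PipelineInputs:
    records: list
    profiles: dict
    hits: list
    known_lnc_ids: list
    matrix: ExpressionMatrix
    sequences: Optional[dict] = None


def load_inputs(data_dir) -> PipelineInputs:
    """Read a directory laid out the way ``simulate`` writes it."""
    d = Path(data_dir)
    records = cio.read_transcripts(d / "transcripts.gtf")
    seq_path = d / "transcripts.fa"
    sequences = cio.read_fasta(seq_path) if seq_path.exists() else None
    return PipelineInputs(
        records=records,
        profiles=cio.read_coding_potential(d / "coding_potential.tsv"),
        hits=cio.read_homology(d / "homology_hits.tsv"),
        known_lnc_ids=cio.read_id_list(d / "known_lncrna_ids.txt"),
        matrix=cio.read_expression(d / "fpkm.tsv", d / "sample_sheet.tsv"),
        sequences=sequences,
    )


@dataclass
class PipelineResult:
    screening: identify.ScreeningReport
    features: identify.FeatureSummary
    de_results: dict                      # Contrast -> ContrastResult frame
    regulation: attribution.RegulationAssignment
    osmotic: dict                         # time_h -> {class -> set}
    coexpression: Optional[coexpress.CoexpressionResult]
    cis_result: cis.CisResult
    bundle: Optional[SimulationBundle] = None


def _pcg_records(inputs: PipelineInputs) -> list[TranscriptRecord]:
    """Reference-matching transcripts not on the known-lncRNA list are
    treated as protein-coding genes."""
    known = set(inputs.known_lnc_ids)
    return [
        r for r in inputs.records
        if r.class_code == "=" and r.transcript_id not in known
    ]


def abs_lfc_of_de(de_results: dict) -> dict:
    """Per gene, the largest |log2FC| over the contrasts where it is DE."""
    out: dict[str, float] = {}
    for df in de_results.values():
        de = df[df.is_DE]
        for tid, lfc in zip(de.index, de.log2fc.abs()):
            out[tid] = max(out.get(tid, 0.0), float(lfc))
    return out


def run_analysis(
    inputs: PipelineInputs,
    net_config: Optional[coexpress.NetworkConfig] = None,
    run_network: bool = True,
    coding_rule: str = "all_noncoding",
    expression_unit: str = "sample",
    cis_window_bp: int = 100_000,
    cis_pcc_min: float = 0.9,
    cis_p_max: float = 0.05,
) -> PipelineResult:
    """All analysis stages on already-loaded inputs."""
    # 1. screening + characterization
    report = identify.screen(
        inputs.records, inputs.profiles, inputs.hits, inputs.matrix,
        inputs.known_lnc_ids, coding_rule=coding_rule,
        expression_unit=expression_unit,
    )
    features = identify.characterize(report.novel_lncRNAs, inputs.sequences)

    # 2. differential expression over the 12 contrasts
    de_results = diffexpr.run_all_contrasts(inputs.matrix)
    sets = diffexpr.de_sets(de_results)

    # 3. calcium attribution, pooled over all conditions
    regulation = attribution.attribute_from_de(sets)

    # 4. osmotic responders: per time, intersect NaCl- and
    #    sorbitol-derived class sets
    osmotic = {}
    for h in (6, 24):
        by_treat = {}
        for t in ("NaCl", "sorbitol"):
            assign = attribution.attribute_from_de(sets, conditions=[(t, h)])
            by_treat[t] = assign.classes
        osmotic[h] = cis.select_osmotic_lncrnas(by_treat["NaCl"], by_treat["sorbitol"])

    # 5. co-expression network on the expression-supported universe
    coexpr = None
    if run_network:
        universe = set()
        for t in ("NaCl", "sorbitol"):
            for comp in ("cyt", "nuc"):
                universe |= attribution.select_universe(inputs.matrix, t, comp)
        values = inputs.matrix.values.loc[sorted(universe)]
        traits = coexpress.group_trait_indicators(inputs.matrix.samples)
        traits.index = list(values.columns)
        coexpr = coexpress.run_coexpress(
            values, net_config or coexpress.NetworkConfig(), traits=traits
        )

    # 6. cis-target prediction for the screened lncRNAs
    known_expressed = set(report.expressed_known_lncRNAs)
    lnc_records = list(report.novel_lncRNAs) + [
        r for r in inputs.records if r.transcript_id in known_expressed
    ]
    cis_result = cis.predict_cis_targets(
        lnc_records, _pcg_records(inputs), inputs.matrix,
        window_bp=cis_window_bp, pcc_min=cis_pcc_min, p_max=cis_p_max,
    )
    return PipelineResult(
        screening=report, features=features, de_results=de_results,
        regulation=regulation, osmotic=osmotic, coexpression=coexpr,
        cis_result=cis_result,
    )


def run_all(
    sim_config: Optional[SimulationConfig] = None,
    net_config: Optional[coexpress.NetworkConfig] = None,
    out_dir=None,
    **kwargs,
) -> PipelineResult:
    """Simulate a dataset and run every stage on it."""
    sim_config = sim_config or SimulationConfig()
    data_dir = Path(out_dir) / "data" if out_dir is not None else None
    bundle = simulate_all(sim_config, out_dir=data_dir)
    inputs = PipelineInputs(
        records=bundle.records,
        profiles=bundle.profiles,
        hits=bundle.hits,
        known_lnc_ids=bundle.known_lnc_ids,
        matrix=bundle.matrix,
        sequences=bundle.sequences,
    )
    result = run_analysis(inputs, net_config=net_config, **kwargs)
    result.bundle = bundle
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


# ---------------------------------------------------------------------------
# output writers (shared by the CLI subcommands)
# ---------------------------------------------------------------------------

def write_identify_outputs(report, features, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cio.write_gtf(report.novel_lncRNAs, out / "novel_lncrna.gtf")
    cio.write_id_list(report.expressed_known_lncRNAs, out / "known_expressed.txt")
    report.to_frame().to_csv(out / "screening_report.tsv", sep="\t", index=False)
    features.to_frame().to_csv(out / "features.tsv", sep="\t", index_label="transcript_id")
    features.chromosome_counts.to_frame("count").assign(
        fraction=features.chromosome_fractions
    ).to_csv(out / "chromosome_distribution.tsv", sep="\t", index_label="chrom")


def write_de_outputs(de_results, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for c, df in de_results.items():
        df.to_csv(out / f"de_{c.name}.tsv", sep="\t", index_label="transcript_id")


def write_attribution_outputs(regulation, comparisons, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    regulation.table.to_csv(out / "regulation.tsv", sep="\t")
    comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False)


def write_coexpress_outputs(result, out_dir, term_map=None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.kme_table.to_csv(out / "modules.tsv", sep="\t", index=False)
    result.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t", index_label="sample_id")
    result.fit_table.to_csv(out / "soft_threshold_fit.tsv", sep="\t", index=False)
    if result.module_trait is not None:
        result.module_trait.to_csv(out / "module_trait.tsv", sep="\t", index=False)
    net = coexpress.NetworkConfig()
    for mod in sorted(set(result.labels) - {coexpress.GREY}):
        edges, nodes = coexpress.export_network(
            result.tom, result.gene_ids, net.edge_weight_threshold,
            labels=result.labels, module=mod,
        )
        edges.to_csv(out / f"edges_{mod}.tsv", sep="\t", index=False)
        nodes.to_csv(out / f"nodes_{mod}.tsv", sep="\t", index=False)
    if term_map:
        frames = []
        universe = list(result.labels.index)
        for mod in sorted(set(result.labels) - {coexpress.GREY}):
            members = list(result.labels.index[result.labels == mod])
            df = coexpress.enrich_hypergeometric(members, term_map, universe)
            df.insert(0, "module", mod)
            frames.append(df)
        if frames:
            pd.concat(frames).to_csv(out / "enrichment.tsv", sep="\t", index=False)


def write_cis_outputs(cis_result, records, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cis_result.candidates.to_csv(out / "cis_candidates.tsv", sep="\t", index=False)
    cis_result.pairs.to_csv(out / "cis_pairs.tsv", sep="\t", index=False)
    passing = cis_result.passing
    paired_ids = set(passing.lncrna_id) | set(passing.pcg_id)
    by_id = {r.transcript_id: r for r in records}
    cio.write_bed(
        [by_id[t] for t in sorted(paired_ids) if t in by_id],
        out / "cis_paired_loci.bed",
    )


def write_outputs(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    write_identify_outputs(result.screening, result.features, out / "identify")
    write_de_outputs(result.de_results, out / "de")

    lnc_ids = result.screening.novel_ids | set(result.screening.expressed_known_lncRNAs)
    comparisons = attribution.class_comparison_table(
        result.regulation.classes, lnc_ids, abs_lfc_of_de(result.de_results)
    )
    write_attribution_outputs(result.regulation, comparisons, out / "attribute")
    rows = [
        {"time_h": h, "calcium_class": k, "transcript_id": t}
        for h, classes in result.osmotic.items()
        for k, members in classes.items()
        for t in sorted(members)
    ]
    pd.DataFrame(rows, columns=["time_h", "calcium_class", "transcript_id"]).to_csv(
        out / "attribute" / "osmotic_sets.tsv", sep="\t", index=False
    )
    if result.coexpression is not None:
        write_coexpress_outputs(result.coexpression, out / "coexpress")
    records = result.bundle.records if result.bundle is not None else []
    write_cis_outputs(result.cis_result, records, out / "cis")
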