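"""Readers and writers for the standard formats the pipeline touches.

GTF coordinates are 1-based inclusive and are preserved as such in the
in-memory records; BED export converts to 0-based half-open.  Attribute
parsing is delegated to :mod:`gffutils` so the usual GTF quoting
dialects are handled.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from gffutils.feature import feature_from_line

from .types import (
    CODING_PREDICTORS,
    CodingPotentialProfile,
    ExpressionMatrix,
    GtfParseError,
    HomologyHit,
    SampleDescriptor,
    TranscriptRecord,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_transcripts(path, class_code_attribute: str = "class_code") -> list[TranscriptRecord]:
    """Read an assembled-transcript GTF into :class:`TranscriptRecord` s.

    Transcripts are grouped by ``transcript_id``; the class code is read
    from ``class_code_attribute`` on the transcript (or first exon)
    feature and defaults to ``"="`` when absent.  Exon features without
    a parent transcript_id raise; malformed lines raise
    :class:`GtfParseError` naming the line number.
    """
    path = Path(path)
    spans: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") < 8:
                raise GtfParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise GtfParseError(f"{path}:{lineno}: {exc}") from exc
            if feat.featuretype not in ("transcript", "exon"):
                continue
            try:
                tid = feat.attributes["transcript_id"][0]
            except KeyError:
                raise GtfParseError(
                    f"{path}:{lineno}: {feat.featuretype} feature lacks transcript_id"
                )
            entry = spans.get(tid)
            if entry is None:
                entry = {
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                    "locus": feat.attributes.get("gene_id", [tid])[0],
                    "class_code": None,
                    "exons": [],
                    "has_transcript": False,
                }
                spans[tid] = entry
                order.append(tid)
            cc = feat.attributes.get(class_code_attribute)
            if cc:
                entry["class_code"] = cc[0]
            if feat.featuretype == "transcript":
                entry["has_transcript"] = True
            else:
                entry["exons"].append((feat.start, feat.end))

    records = []
    for tid in order:
        e = spans[tid]
        if not e["exons"]:
            raise GtfParseError(f"{path}: transcript {tid} has no exon features")
        start = min(a for a, _ in e["exons"])
        end = max(b for _, b in e["exons"])
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                locus_id=e["locus"],
                chrom=e["chrom"],
                start=start,
                end=end,
                strand=e["strand"],
                exons=e["exons"],
                class_code=e["class_code"] if e["class_code"] is not None else "=",
            )
        )
    if not records:
        log.warning("no transcripts read from %s", path)
    return records


def write_gtf(records: Iterable[TranscriptRecord], path,
              class_code_attribute: str = "class_code") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for r in records:
            attrs = (
                f'gene_id "{r.locus_id}"; transcript_id "{r.transcript_id}"; '
                f'{class_code_attribute} "{r.class_code}";'
            )
            fh.write(
                f"{r.chrom}\tcalnc\ttranscript\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t{attrs}\n"
            )
            for (a, b) in r.exons:
                fh.write(f"{r.chrom}\tcalnc\texon\t{a}\t{b}\t.\t{r.strand}\t.\t{attrs}\n")


def write_bed(records: Sequence[TranscriptRecord], path) -> None:
    """BED6 export: 0-based half-open, score 0, strand preserved."""
    path = Path(path)
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.transcript_id}\t0\t{r.strand}\n"
            )


# ---------------------------------------------------------------------------
# FASTA (transcript sequences)
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Expression matrix + sample sheet
# ---------------------------------------------------------------------------

SHEET_COLUMNS = ("sample_id", "genotype", "treatment", "time_h", "replicate")


def read_sample_sheet(path) -> list[SampleDescriptor]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet {path} lacks columns {sorted(missing)}")
    return [
        SampleDescriptor(
            sample_id=row.sample_id,
            genotype=row.genotype,
            treatment=row.treatment,
            time_h=int(row.time_h),
            replicate=int(row.replicate),
        )
        for row in df.itertuples()
    ]


def write_sample_sheet(samples: Sequence[SampleDescriptor], path) -> None:
    pd.DataFrame(
        [
            (s.sample_id, s.genotype, s.treatment, s.time_h, s.replicate)
            for s in samples
        ],
        columns=list(SHEET_COLUMNS),
    ).to_csv(path, sep="\t", index=False)


def read_expression(matrix_path, sample_sheet_path) -> ExpressionMatrix:
    """Read a transcripts x samples FPKM TSV validated against its sheet."""
    samples = read_sample_sheet(sample_sheet_path)
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    mat = ExpressionMatrix(df, samples)
    log.info(
        "read %d transcripts x %d samples (%d design groups)",
        df.shape[0], df.shape[1], len(mat.groups()),
    )
    return mat


def write_expression(matrix: ExpressionMatrix, matrix_path, sample_sheet_path=None) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="transcript_id")
    if sample_sheet_path is not None:
        write_sample_sheet(matrix.samples, sample_sheet_path)


# ---------------------------------------------------------------------------
# Coding-potential verdicts, homology hits, ID lists
# ---------------------------------------------------------------------------

def read_coding_potential(path) -> dict[str, CodingPotentialProfile]:
    """TSV: transcript_id + one coding/noncoding column per predictor."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = ({"transcript_id"} | set(CODING_PREDICTORS)) - set(df.columns)
    if missing:
        raise ValueError(f"verdict table {path} lacks columns {sorted(missing)}")
    out = {}
    for row in df.itertuples():
        tid = row.transcript_id
        out[tid] = CodingPotentialProfile(
            transcript_id=tid,
            verdicts={p: getattr(row, p) for p in CODING_PREDICTORS},
        )
    return out


def write_coding_potential(profiles: Iterable[CodingPotentialProfile], path) -> None:
    rows = [
        {"transcript_id": p.transcript_id, **{k: p.verdicts[k] for k in CODING_PREDICTORS}}
        for p in profiles
    ]
    pd.DataFrame(rows, columns=["transcript_id", *CODING_PREDICTORS]).to_csv(
        path, sep="\t", index=False
    )


def read_homology(path) -> list[HomologyHit]:
    """Tabular BLAST-style hits with columns query, subject, pident, evalue."""
    df = pd.read_csv(path, sep="\t")
    missing = {"query", "subject", "pident", "evalue"} - set(df.columns)
    if missing:
        raise ValueError(f"homology table {path} lacks columns {sorted(missing)}")
    return [
        HomologyHit(
            query_id=str(row.query),
            subject_id=str(row.subject),
            identity_pct=float(row.pident),
            e_value=float(row.evalue),
        )
        for row in df.itertuples()
    ]


def write_homology(hits: Iterable[HomologyHit], path) -> None:
    pd.DataFrame(
        [(h.query_id, h.subject_id, h.identity_pct, h.e_value) for h in hits],
        columns=["query", "subject", "pident", "evalue"],
    ).to_csv(path, sep="\t", index=False)


def read_id_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_id_list(ids: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")
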