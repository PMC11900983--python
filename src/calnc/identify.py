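"""Five-step novel-lncRNA screen and basic feature characterization.

The screen keeps assembled transcripts that (1) carry a novel class code
(i/o/j/u/x), (2) have spliced length >= 200 nt, (3) are judged noncoding
by the coding-potential predictors, (4) lack a stringent homology hit to
known mRNA/ncRNA (E < 1e-10 and identity > 90, both strict), and
(5) reach FPKM >= 0.1 in at least one sample.  Known lncRNAs pass only
through the expression filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    NOVEL_CLASS_CODES,
    CalncError,
    CodingPotentialProfile,
    ExpressionMatrix,
    HomologyHit,
    TranscriptRecord,
)

log = logging.getLogger(__name__)

STEP_NAMES = ("class_code", "length", "coding", "homology", "expression")


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------

def filter_class_codes(records: Sequence[TranscriptRecord]) -> list[TranscriptRecord]:
    """Keep transcripts whose class code is one of i/o/j/u/x."""
    kept, dropped = [], []
    for r in records:
        (kept if r.class_code in NOVEL_CLASS_CODES else dropped).append(r)
    unknown = {r.class_code for r in dropped} - {"="}
    if unknown:
        log.info("dropped non-candidate class codes: %s", sorted(unknown))
    return kept


def filter_length(records: Sequence[TranscriptRecord], min_len: int = 200) -> list[TranscriptRecord]:
    """Keep transcripts with spliced length >= min_len (strictly shorter excluded)."""
    return [r for r in records if r.length >= min_len]


def filter_coding_potential(
    records: Sequence[TranscriptRecord],
    profiles: Mapping[str, CodingPotentialProfile],
    rule: str = "all_noncoding",
) -> list[TranscriptRecord]:
    """Keep transcripts judged noncoding.

    ``all_noncoding`` (default): any 'coding' verdict, including a Pfam
    hit, eliminates.  ``majority``: eliminated only when more than half
    the predictors say 'coding'.
    """
    if rule not in ("all_noncoding", "majority"):
        raise ValueError(f"unknown coding-potential rule {rule!r}")
    kept = []
    for r in records:
        prof = profiles.get(r.transcript_id)
        if prof is None:
            raise CalncError(f"no coding-potential profile for {r.transcript_id}")
        n_coding = prof.n_coding
        if rule == "all_noncoding":
            ok = n_coding == 0
        else:
            ok = n_coding <= len(prof.verdicts) / 2
        if ok:
            kept.append(r)
    return kept


def filter_homology(
    records: Sequence[TranscriptRecord],
    hits: Iterable[HomologyHit],
    max_e: float = 1e-10,
    min_ident: float = 90.0,
) -> list[TranscriptRecord]:
    """Eliminate transcripts with >= 1 hit at e_value < max_e AND
    identity > min_ident (both comparisons strict)."""
    eliminated = set()
    for h in hits:
        if h.e_value < max_e and h.identity_pct > min_ident:
            eliminated.add(h.query_id)
    return [r for r in records if r.transcript_id not in eliminated]


def filter_expression(
    records: Sequence[TranscriptRecord],
    matrix: ExpressionMatrix,
    min_fpkm: float = 0.1,
    unit: str = "sample",
) -> list[TranscriptRecord]:
    """Keep transcripts reaching min_fpkm in >= 1 sample (unit='sample')
    or with group-mean FPKM >= min_fpkm in >= 1 design group
    (unit='group')."""
    if unit not in ("sample", "group"):
        raise ValueError(f"unknown expression-filter unit {unit!r}")
    missing = [r.transcript_id for r in records if r.transcript_id not in matrix.values.index]
    if missing:
        raise CalncError(f"transcripts absent from expression matrix: {missing[:5]}")
    if unit == "sample":
        maxima = matrix.values.max(axis=1)
    else:
        maxima = matrix.group_means().max(axis=1)
    return [r for r in records if maxima[r.transcript_id] >= min_fpkm]


# ---------------------------------------------------------------------------
# the full screen
# ---------------------------------------------------------------------------

@dataclass
class ScreeningReport:
    step_counts: dict            # step name -> surviving count (after the step)
    elimination_reason: dict     # transcript_id -> first-failing step
    novel_lncRNAs: list          # surviving TranscriptRecords
    expressed_known_lncRNAs: list  # known lncRNA ids passing the expression filter

    @property
    def novel_ids(self) -> set:
        return {r.transcript_id for r in self.novel_lncRNAs}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"transcript_id": t, "eliminated_at": s} for t, s in self.elimination_reason.items()
        ] + [
            {"transcript_id": t, "eliminated_at": "none"} for t in sorted(self.novel_ids)
        ]
        return pd.DataFrame(rows).sort_values("transcript_id").reset_index(drop=True)


def screen(
    records: Sequence[TranscriptRecord],
    profiles: Mapping[str, CodingPotentialProfile],
    hits: Iterable[HomologyHit],
    matrix: ExpressionMatrix,
    known_lnc_ids: Iterable[str],
    coding_rule: str = "all_noncoding",
    min_len: int = 200,
    max_e: float = 1e-10,
    min_ident: float = 90.0,
    min_fpkm: float = 0.1,
    expression_unit: str = "sample",
) -> ScreeningReport:
    """Apply screening steps 1-5 in order; known lncRNAs get only the
    expression filter.  Each eliminated transcript is tagged with its
    first-failing step."""
    known = set(known_lnc_ids)
    candidates = [r for r in records if r.transcript_id not in known]
    hits = list(hits)

    reasons: dict[str, str] = {}
    counts: dict[str, int] = {}
    current = candidates
    steps = [
        ("class_code", lambda rs: filter_class_codes(rs)),
        ("length", lambda rs: filter_length(rs, min_len=min_len)),
        ("coding", lambda rs: filter_coding_potential(rs, profiles, rule=coding_rule)),
        ("homology", lambda rs: filter_homology(rs, hits, max_e=max_e, min_ident=min_ident)),
        ("expression", lambda rs: filter_expression(rs, matrix, min_fpkm=min_fpkm, unit=expression_unit)),
    ]
    for name, step in steps:
        survivors = step(current)
        surviving_ids = {r.transcript_id for r in survivors}
        for r in current:
            if r.transcript_id not in surviving_ids:
                reasons[r.transcript_id] = name
        counts[name] = len(survivors)
        current = survivors

    known_records = [r for r in records if r.transcript_id in known]
    expressed_known = [
        r.transcript_id
        for r in filter_expression(known_records, matrix, min_fpkm=min_fpkm, unit=expression_unit)
    ]
    return ScreeningReport(
        step_counts=counts,
        elimination_reason=reasons,
        novel_lncRNAs=current,
        expressed_known_lncRNAs=sorted(expressed_known),
    )


# ---------------------------------------------------------------------------
# characterization
# ---------------------------------------------------------------------------

@dataclass
class FeatureSummary:
    chromosome_counts: pd.Series
    chromosome_fractions: pd.Series
    length_histogram: pd.Series      # 200-bp bins labelled "200-399", ...
    exon_histogram: pd.Series
    gc_content: Optional[pd.Series] = None   # in [0, 1]
    gc_skew: Optional[pd.Series] = None      # (G - C)/(G + C), in [-1, 1]

    def to_frame(self) -> pd.DataFrame:
        data = {}
        if self.gc_content is not None:
            data["gc_content"] = self.gc_content
            data["gc_skew"] = self.gc_skew
        return pd.DataFrame(data)


def gc_metrics(sequence: str) -> tuple[float, float]:
    """GC content (G+C)/len and GC skew (G-C)/(G+C) of one sequence."""
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise CalncError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    g, c = seq.count("G"), seq.count("C")
    content = (g + c) / len(seq) if seq else float("nan")
    skew = (g - c) / (g + c) if (g + c) else float("nan")
    return content, skew


def _length_bin_label(length: int, width: int = 200) -> str:
    lo = (length // width) * width
    return f"{lo}-{lo + width - 1}"


def characterize(
    lncRNAs: Sequence[TranscriptRecord],
    sequences: Optional[Mapping[str, str]] = None,
    bin_width: int = 200,
) -> FeatureSummary:
    """Chromosomal distribution, length bins, exon counts and (when
    sequences are available) GC content and GC skew of a lncRNA set."""
    chroms = pd.Series([r.chrom for r in lncRNAs], dtype=object)
    counts = chroms.value_counts().sort_index()
    fractions = counts / counts.sum() if len(lncRNAs) else counts

    lengths = pd.Series(
        [_length_bin_label(r.length, bin_width) for r in lncRNAs], dtype=object
    ).value_counts()
    lengths = lengths.reindex(
        sorted(lengths.index, key=lambda s: int(s.split("-")[0]))
    )
    exons = pd.Series([r.n_exons for r in lncRNAs]).value_counts().sort_index()

    gc_content = gc_skew = None
    seq_of = dict(sequences) if sequences is not None else {}
    for r in lncRNAs:
        if r.sequence is not None and r.transcript_id not in seq_of:
            seq_of[r.transcript_id] = r.sequence
    have = [r.transcript_id for r in lncRNAs if r.transcript_id in seq_of]
    if len(have) == len(lncRNAs) and lncRNAs:
        metrics = {t: gc_metrics(seq_of[t]) for t in have}
        gc_content = pd.Series({t: m[0] for t, m in metrics.items()})
        gc_skew = pd.Series({t: m[1] for t, m in metrics.items()})
    elif lncRNAs:
        log.warning(
            "sequences available for %d/%d lncRNAs; GC metrics omitted",
            len(have), len(lncRNAs),
        )
    return FeatureSummary(
        chromosome_counts=counts,
        chromosome_fractions=fractions,
        length_histogram=lengths,
        exon_histogram=exons,
        gc_content=gc_content,
        gc_skew=gc_skew,
    )
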