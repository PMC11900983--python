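"""Cis-target prediction: genomic windowing plus expression correlation.

A lncRNA's candidate cis targets are the protein-coding genes within a
100 kb window on either side (strand-agnostic, boundary inclusive,
distance = gap between closest interval ends, 0 on overlap).  Candidates
pass when |Pearson r| >= 0.9 across the configured samples and the
two-sided correlation p-value is < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import CalncError, ExpressionMatrix, TranscriptRecord

log = logging.getLogger(__name__)


def select_osmotic_lncrnas(
    ca_sets_nacl: Mapping[str, set],
    ca_sets_sorbitol: Mapping[str, set],
) -> dict[str, set]:
    """Per calcium class, the responders shared by the NaCl- and
    sorbitol-derived sets: osmotic stress is the component common to
    both treatments."""
    out = {}
    for klass in sorted(set(ca_sets_nacl) | set(ca_sets_sorbitol)):
        out[klass] = set(ca_sets_nacl.get(klass, set())) & set(
            ca_sets_sorbitol.get(klass, set())
        )
    return out


def interval_gap(a: TranscriptRecord, b: TranscriptRecord) -> int:
    """Gap in bp between closest interval ends; 0 when they overlap."""
    return max(0, max(a.start, b.start) - min(a.end, b.end) - 1)


def window_pairs(
    lncrnas: Sequence[TranscriptRecord],
    pcgs: Sequence[TranscriptRecord],
    window_bp: int = 100_000,
) -> pd.DataFrame:
    """Candidate (lncRNA, PCG) pairs on the same chromosome with gap <=
    window_bp (inclusive); strand is ignored.  Columns: lncrna_id,
    pcg_id, chrom, distance_bp."""
    by_chrom: dict[str, list[TranscriptRecord]] = {}
    for p in pcgs:
        by_chrom.setdefault(p.chrom, []).append(p)
    rows = []
    for l in lncrnas:
        for p in by_chrom.get(l.chrom, ()):
            gap = interval_gap(l, p)
            if gap <= window_bp:
                rows.append(
                    {"lncrna_id": l.transcript_id, "pcg_id": p.transcript_id,
                     "chrom": l.chrom, "distance_bp": gap}
                )
    return pd.DataFrame(rows, columns=["lncrna_id", "pcg_id", "chrom", "distance_bp"])


def pearson(x, y) -> float:
    """Product-moment correlation; raises on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise CalncError("pearson needs equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CalncError("pearson undefined for constant vectors")
    r = float(np.corrcoef(x, y)[0, 1])
    return max(-1.0, min(1.0, r))


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson r from the t transform with n - 2 df."""
    if n < 3:
        raise CalncError("correlation p-value needs n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("|r| must be <= 1")
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df=n - 2))


def call_cis_pairs(
    candidates: pd.DataFrame,
    matrix: ExpressionMatrix,
    pcc_min: float = 0.9,
    p_max: float = 0.05,
    sample_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Correlate each candidate pair over the chosen samples (default:
    all) and flag passes: |r| >= pcc_min (inclusive) AND p < p_max
    (strict).  Pairs with a member missing from the matrix or with
    constant expression are dropped with a log message."""
    cols = list(sample_ids) if sample_ids is not None else [s.sample_id for s in matrix.samples]
    vals = matrix.values[cols]
    rows = []
    n_dropped = 0
    for c in candidates.itertuples():
        if c.lncrna_id not in vals.index or c.pcg_id not in vals.index:
            n_dropped += 1
            continue
        x = vals.loc[c.lncrna_id].to_numpy()
        y = vals.loc[c.pcg_id].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            n_dropped += 1
            continue
        r = pearson(x, y)
        p = correlation_pvalue(r, len(cols))
        rows.append({
            "lncrna_id": c.lncrna_id, "pcg_id": c.pcg_id, "chrom": c.chrom,
            "distance_bp": c.distance_bp, "pcc": r, "p": p,
            "passes": bool(abs(r) >= pcc_min and p < p_max),
        })
    if n_dropped:
        log.info("dropped %d candidate pairs (missing or constant expression)", n_dropped)
    return pd.DataFrame(
        rows, columns=["lncrna_id", "pcg_id", "chrom", "distance_bp", "pcc", "p", "passes"]
    )


@dataclass
class CisResult:
    candidates: pd.DataFrame
    pairs: pd.DataFrame    # with pcc/p/passes

    @property
    def passing(self) -> pd.DataFrame:
        return self.pairs[self.pairs.passes]


def predict_cis_targets(
    lncrnas: Sequence[TranscriptRecord],
    pcgs: Sequence[TranscriptRecord],
    matrix: ExpressionMatrix,
    window_bp: int = 100_000,
    pcc_min: float = 0.9,
    p_max: float = 0.05,
    sample_ids: Optional[Sequence[str]] = None,
) -> CisResult:
    cand = window_pairs(lncrnas, pcgs, window_bp=window_bp)
    pairs = call_cis_pairs(cand, matrix, pcc_min=pcc_min, p_max=p_max,
                           sample_ids=sample_ids)
    log.info("%d candidate pairs, %d passing", len(cand), int(pairs.passes.sum()))
    return CisResult(candidates=cand, pairs=pairs)
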