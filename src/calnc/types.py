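"""Shared domain types for the stress-lncRNA analysis pipeline.

The experimental design is a 3-genotype (WT, PV-NES, NLS-PV) x
2-treatment (NaCl, sorbitol) x 3-timepoint (0, 6, 24 h) factorial with
three biological replicates per cell: 18 groups, 54 samples.  The two
parvalbumin transgenics buffer cytosolic (PV-NES) or nucleosolic
(NLS-PV) calcium, so contrasts against WT isolate compartment-specific
calcium regulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "PV_NES", "NLS_PV")
TREATMENTS = ("NaCl", "sorbitol")
TIMEPOINTS = (0, 6, 24)

#: predictor names expected in every coding-potential profile
CODING_PREDICTORS = ("CPC2", "LGC", "CPAT", "Pfam")

#: gffcompare class codes accepted as novel-lncRNA candidates
NOVEL_CLASS_CODES = frozenset("iojux")


class CalncError(Exception):
    """Base class for pipeline errors."""


class GtfParseError(CalncError):
    """Raised on a malformed annotation line; carries the line number."""


@dataclass(frozen=True)
class SampleDescriptor:
    sample_id: str
    genotype: str
    treatment: str
    time_h: int
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}; expected one of {GENOTYPES}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}")
        if self.time_h not in TIMEPOINTS:
            raise ValueError(f"time_h must be one of {TIMEPOINTS}, got {self.time_h}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")

    @property
    def group(self) -> tuple[str, str, int]:
        """(genotype, treatment, time_h) — the 18 design cells."""
        return (self.genotype, self.treatment, self.time_h)


@dataclass
class TranscriptRecord:
    """One assembled transcript with 1-based inclusive coordinates."""

    transcript_id: str
    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    class_code: str = "="
    biotype: str = "candidate"
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.transcript_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = None
        for (a, b) in self.exons:
            if a > b:
                raise ValueError(f"{self.transcript_id}: exon {a}-{b} inverted")
            if a < self.start or b > self.end:
                raise ValueError(
                    f"{self.transcript_id}: exon {a}-{b} outside span "
                    f"{self.start}-{self.end}"
                )
            if prev_end is not None and a <= prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = b

    @property
    def length(self) -> int:
        """Spliced (exonic) length in nt, the lncRNA length convention."""
        return sum(b - a + 1 for a, b in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class CodingPotentialProfile:
    """Per-transcript verdicts from the four coding-potential predictors.

    A Pfam domain hit is folded into ``verdicts["Pfam"] == "coding"``.
    """

    transcript_id: str
    verdicts: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = set(CODING_PREDICTORS) - set(self.verdicts)
        if missing:
            raise ValueError(
                f"{self.transcript_id}: missing predictor verdicts {sorted(missing)}"
            )
        bad = {v for v in self.verdicts.values() if v not in ("coding", "noncoding")}
        if bad:
            raise ValueError(f"{self.transcript_id}: bad verdict values {sorted(bad)}")

    @property
    def n_coding(self) -> int:
        return sum(self.verdicts[p] == "coding" for p in CODING_PREDICTORS)


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    identity_pct: float
    e_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError(f"identity_pct {self.identity_pct} outside [0, 100]")
        if self.e_value < 0:
            raise ValueError("e_value must be non-negative")


class ExpressionMatrix:
    """FPKM values (transcripts x samples) tied to a validated sample sheet.

    Wraps a :class:`pandas.DataFrame` whose column order matches the
    sample sheet exactly; all cells must be present and non-negative.
    """

    def __init__(self, values: pd.DataFrame, samples: Sequence[SampleDescriptor]):
        samples = list(samples)
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_ids in sample sheet")
        keys = [(s.genotype, s.treatment, s.time_h, s.replicate) for s in samples]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (genotype, treatment, time, replicate) in sheet")
        extra = set(values.columns) - set(ids)
        missing = set(ids) - set(values.columns)
        if extra or missing:
            raise ValueError(
                "matrix columns and sample sheet disagree; "
                f"only in matrix: {sorted(extra)}, only in sheet: {sorted(missing)}"
            )
        values = values.loc[:, ids].astype(float)
        if values.isna().any().any():
            raise ValueError("expression matrix contains missing cells")
        if (values.to_numpy() < 0).any():
            bad = values.index[(values < 0).any(axis=1)][:5].tolist()
            raise ValueError(f"negative FPKM values (e.g. in {bad})")
        self.values = values
        self.samples = samples
        self._by_id = {s.sample_id: s for s in samples}

    # -- design helpers -------------------------------------------------
    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_ids(
        self,
        genotype: Optional[str] = None,
        treatment: Optional[str] = None,
        time_h: Optional[int] = None,
    ) -> list[str]:
        out = []
        for s in self.samples:
            if genotype is not None and s.genotype != genotype:
                continue
            if treatment is not None and s.treatment != treatment:
                continue
            if time_h is not None and s.time_h != time_h:
                continue
            out.append(s.sample_id)
        return out

    def groups(self) -> dict[tuple[str, str, int], list[str]]:
        out: dict[tuple[str, str, int], list[str]] = {}
        for s in self.samples:
            out.setdefault(s.group, []).append(s.sample_id)
        return out

    def group_means(self) -> pd.DataFrame:
        """Mean FPKM per transcript for each of the design groups."""
        groups = self.groups()
        data = {
            "|".join(map(str, g)): self.values[cols].mean(axis=1)
            for g, cols in groups.items()
        }
        return pd.DataFrame(data, index=self.values.index)

    def subset(self, transcript_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [t for t in transcript_ids]
        return ExpressionMatrix(self.values.loc[ids], self.samples)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ExpressionMatrix({self.values.shape[0]} transcripts x "
            f"{self.values.shape[1]} samples, {len(self.groups())} groups)"
        )


def full_design(replicates: int = 3) -> list[SampleDescriptor]:
    """The complete 3 x 2 x 3 x replicates design (54 samples by default).

    0 h controls are kept separate per treatment arm.
    """
    out = []
    for g in GENOTYPES:
        for t in TREATMENTS:
            for h in TIMEPOINTS:
                for r in range(1, replicates + 1):
                    out.append(
                        SampleDescriptor(
                            sample_id=f"{g}_{t}_{h}h_r{r}",
                            genotype=g,
                            treatment=t,
                            time_h=h,
                            replicate=r,
                        )
                    )
    return out
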