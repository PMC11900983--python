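"""Synthetic RNA-seq world with planted ground truth.

Emulates the post-alignment layer of a 3-genotype x 2-treatment x
3-timepoint x 3-replicate stress experiment (54 samples): assembled
transcripts with gffcompare-style class codes, coding-potential and
homology tables, and a log-normal FPKM matrix carrying planted

* novel lncRNAs plus decoys that each fail exactly one screening filter,
* condition effects whose genotype pattern encodes a calcium class
  (cytosolic-only, nucleosolic-only, both, or calcium-independent),
* lncRNA-PCG cis pairs within 100 kb sharing a latent profile tuned to a
  target Pearson correlation,
* block co-expression modules loading on per-module latent factors.

Latent (co-expression and cis) factors are normalized to unit mean
within each replicate group, so planted correlation structure is exactly
orthogonal to planted condition effects: in the noise-free limit every
downstream stage recovers its planted labels exactly.

Expression is simulated on the FPKM scale directly (log-normal), not via
read counts; the pipeline consumes FPKM and never uses count-level
information.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import io as cio
from .types import (
    CODING_PREDICTORS,
    CodingPotentialProfile,
    ExpressionMatrix,
    HomologyHit,
    TranscriptRecord,
    full_design,
)

log = logging.getLogger(__name__)

_LN2SQ = math.log(2.0) ** 2


@dataclass
class SimulationConfig:
    """Stated world for the generator; defaults are a desk-scale rendering
    of the design the analysis assumes (see docs/methods.md)."""

    n_chromosomes: int = 5
    n_pcg: int = 300
    n_known_lnc: int = 40
    n_known_lnc_low: int = 5          # known lncRNAs below the expression filter
    n_novel_lnc: dict = field(
        default_factory=lambda: {"j": 30, "u": 6, "o": 5, "x": 5, "i": 4}
    )
    n_coding_decoys: int = 8
    n_short_decoys: int = 5
    n_homology_decoys: int = 5
    n_low_expression_decoys: int = 5
    # expression model
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    lnc_baseline_shift: float = -2.0  # lncRNAs are lower expressed than PCGs
    noise_sd: float = 0.25            # replicate noise sigma, log2 units
    effect_size: float = 3.0          # planted |log2FC| of stress responses
    # calcium-dependence scheme: class -> number of responder genes
    calcium_scheme: dict = field(
        default_factory=lambda: {"none": 16, "cyt_only": 10, "nuc_only": 10, "both": 10}
    )
    lnc_responder_fraction: float = 0.25   # fraction of each class drawn from novel lncRNAs
    osmotic_fraction: float = 0.5          # fraction responding to BOTH treatments
    mutant_gain: bool = True               # effect present in mutant, absent in WT
    # cis pairs
    n_cis_pairs: int = 8
    cis_target_r: float = 0.95
    cis_max_gap: int = 90_000
    cis_min_gap: int = 5_000
    # co-expression modules
    module_sizes: tuple = (60, 50, 40)
    module_loading: float = 0.9
    # geometry
    locus_spacing: int = 150_000     # > cis window, so non-pairs never pair
    chrom_length: Optional[int] = None   # None = auto-size
    seed: int = 1

    def __post_init__(self) -> None:
        counts = [
            self.n_pcg, self.n_known_lnc, self.n_coding_decoys, self.n_short_decoys,
            self.n_homology_decoys, self.n_low_expression_decoys, self.n_cis_pairs,
            *self.n_novel_lnc.values(), *self.calcium_scheme.values(),
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if not (0.0 < self.cis_target_r <= 1.0):
            raise ValueError("cis_target_r must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 < self.module_loading <= 1.0):
            raise ValueError("module_loading must lie in (0, 1]")
        bad = set(self.calcium_scheme) - {"none", "cyt_only", "nuc_only", "both"}
        if bad:
            raise ValueError(f"unknown calcium classes {sorted(bad)}")
        bad = set(self.n_novel_lnc) - set("iojux")
        if bad:
            raise ValueError(f"novel class codes must come from i/o/j/u/x, got {sorted(bad)}")


@dataclass
class SyntheticTruth:
    """Planted labels: one row per transcript plus a long effects table."""

    transcripts: pd.DataFrame     # indexed by transcript_id
    effects: pd.DataFrame         # transcript_id, genotype, treatment, time_h, log2fc
    cis_pairs: pd.DataFrame       # lncrna_id, pcg_id, chrom, gap_bp, target_r

    def de_set(self, genotype: str, treatment: str, time_h: int) -> set[str]:
        e = self.effects
        m = (
            (e.genotype == genotype) & (e.treatment == treatment)
            & (e.time_h == time_h) & (e.log2fc != 0)
        )
        return set(e.loc[m, "transcript_id"])

    def novel_lncrna_ids(self) -> set[str]:
        t = self.transcripts
        return set(t.index[t.is_novel_lncRNA])

    def calcium_class_sets(self) -> dict[str, set[str]]:
        t = self.transcripts
        return {
            c: set(t.index[t.calcium_class == c])
            for c in ("cyt_only", "nuc_only", "both")
        }

    def osmotic_sets(self, time_h: int) -> dict[str, set[str]]:
        """Per calcium class, responders shared by both treatments (the
        osmotic component) at the given time."""
        t = self.transcripts
        shared = t.responds_nacl & t.responds_sorbitol
        return {
            c: set(t.index[(t.calcium_class == c) & shared])
            for c in ("cyt_only", "nuc_only", "both")
        }

    def module_labels(self) -> pd.Series:
        return self.transcripts.module

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        self.transcripts.to_csv(out / "truth.tsv", sep="\t", index_label="transcript_id")
        self.effects.to_csv(out / "truth_effects.tsv", sep="\t", index=False)
        self.cis_pairs.to_csv(out / "truth_cis_pairs.tsv", sep="\t", index=False)


@dataclass
class SimulationBundle:
    records: list
    sequences: dict
    known_lnc_ids: list
    known_target_ids: list
    profiles: dict
    hits: list
    truth: SyntheticTruth
    matrix: Optional[ExpressionMatrix] = None

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cio.write_gtf(self.records, out / "transcripts.gtf")
        cio.write_fasta(self.sequences, out / "transcripts.fa")
        cio.write_id_list(self.known_lnc_ids, out / "known_lncrna_ids.txt")
        cio.write_id_list(self.known_target_ids, out / "known_mrna_ncrna_ids.txt")
        cio.write_coding_potential(self.profiles.values(), out / "coding_potential.tsv")
        cio.write_homology(self.hits, out / "homology_hits.tsv")
        self.truth.write(out)
        if self.matrix is not None:
            cio.write_expression(
                self.matrix, out / "fpkm.tsv", out / "sample_sheet.tsv"
            )


# ---------------------------------------------------------------------------
# calibration helpers
# ---------------------------------------------------------------------------

def loading_scale(loading: float, sigma: float) -> float:
    """Latent scale lambda (log2 units) so cor(log-expression, factor)
    equals ``loading`` given replicate noise ``sigma``; 1.0 when noise-free
    (correlation is then 1 regardless of scale)."""
    if sigma == 0:
        return 1.0
    return sigma * loading / math.sqrt(1.0 - loading**2)


def _normalized_multiplier_g(lam: float, n_quad: int = 24) -> float:
    """Second moment E[m^2] of the group-normalized latent multiplier
    m = 2^(lam z_1) / mean_j 2^(lam z_j) over a replicate triple of iid
    standard normals (E[m] = 1 by construction), via 3-d Gauss-Hermite
    quadrature."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    p = weights / weights.sum()
    w = np.exp2(lam * nodes)
    w1 = w[:, None, None]
    w2 = w[None, :, None]
    w3 = w[None, None, :]
    prob = p[:, None, None] * p[None, :, None] * p[None, None, :]
    m_sq = (3.0 * w1 / (w1 + w2 + w3)) ** 2
    return float((prob * m_sq).sum())


def cis_loading(target_r: float, sigma: float) -> float:
    """Shared-latent scale lambda so two partners sharing the
    group-normalized multiplier, each with independent N(0, sigma^2)
    log2 noise, have FPKM-scale Pearson correlation ``target_r``.

    With m the shared multiplier and h = exp(sigma^2 ln^2 2) the noise
    moment ratio, r = (g - 1)/(g h - 1) where g = E[m^2]/E[m]^2; g is
    computed by quadrature and the relation inverted for lambda.
    """
    if sigma == 0:
        return 1.0   # correlation is exactly 1 in the noise-free limit
    h = math.exp(sigma**2 * _LN2SQ)
    ceiling = 1.0 / h
    if target_r >= ceiling:
        raise ValueError(
            f"cis_target_r={target_r} unreachable: with independent log2 noise "
            f"sigma={sigma} the FPKM-scale correlation of a log-normal pair is "
            f"bounded by exp(-sigma^2 ln^2 2) = {ceiling:.4f}; lower noise_sd "
            "or the target"
        )
    g_target = (1.0 - target_r) / (1.0 - target_r * h)

    def f(lam: float) -> float:
        return _normalized_multiplier_g(lam) - g_target

    hi = 1.0
    while f(hi) < 0:
        hi *= 2
    return brentq(f, 1e-9, hi, xtol=1e-12)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    bases = np.array(list("ACGT"))
    return "".join(rng.choice(bases, size=length, p=[0.3, 0.2, 0.2, 0.3]))


def _make_exons(rng: np.random.Generator, start: int, total_len: int) -> list:
    """1-4 exons summing to total_len, separated by short introns."""
    n = int(rng.integers(1, 5)) if total_len >= 80 else 1
    cuts = np.sort(rng.choice(np.arange(1, total_len), size=n - 1, replace=False)) if n > 1 else np.array([], dtype=int)
    pieces = np.diff(np.concatenate([[0], cuts, [total_len]]))
    exons = []
    pos = start
    for piece in pieces:
        exons.append((pos, pos + int(piece) - 1))
        pos += int(piece) + int(rng.integers(50, 500))  # intron
    return exons


def _assign_treatments(rng: np.random.Generator, n: int, osmotic_fraction: float) -> list:
    """Treatment-response pattern per responder: 'both' for the osmotic
    fraction, remainder alternating NaCl-only / sorbitol-only."""
    n_both = int(round(n * osmotic_fraction))
    rest = n - n_both
    pats = ["both"] * n_both + ["NaCl", "sorbitol"] * (rest // 2 + 1)
    pats = pats[:n]
    rng.shuffle(pats)
    return pats


_CLASS_GENOTYPES_GAIN = {
    "none": ("WT", "PV_NES", "NLS_PV"),
    "cyt_only": ("PV_NES",),
    "nuc_only": ("NLS_PV",),
    "both": ("PV_NES", "NLS_PV"),
}
# converse scheme: the effect is lost in the buffered compartment's mutant
_CLASS_GENOTYPES_LOSS = {
    "none": ("WT", "PV_NES", "NLS_PV"),
    "cyt_only": ("WT", "NLS_PV"),
    "nuc_only": ("WT", "PV_NES"),
    "both": ("WT",),
}


def simulate_annotation(config: SimulationConfig, rng: Optional[np.random.Generator] = None):
    """Build the annotation layer: transcripts with planted roles, their
    sequences, known-ID lists, coding-potential verdicts and homology hits.

    Returns a :class:`SimulationBundle` whose ``matrix`` is still None;
    truth carries every planted label needed downstream.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cfg = config

    n_novel = sum(cfg.n_novel_lnc.values())
    n_ca = sum(cfg.calcium_scheme.values())
    n_ca_lnc = {
        c: int(round(k * cfg.lnc_responder_fraction)) for c, k in cfg.calcium_scheme.items()
    }
    if sum(n_ca_lnc.values()) + cfg.n_cis_pairs > n_novel:
        raise ValueError(
            "not enough novel lncRNAs for the requested calcium responders "
            "and cis pairs; increase n_novel_lnc"
        )
    n_ca_pcg = {c: k - n_ca_lnc[c] for c, k in cfg.calcium_scheme.items()}
    n_module = sum(cfg.module_sizes)
    if sum(n_ca_pcg.values()) + n_module + cfg.n_cis_pairs > cfg.n_pcg:
        raise ValueError(
            "n_pcg too small for the requested calcium responders, module "
            "members and cis partners; increase n_pcg"
        )

    # ---- enumerate transcripts with roles -----------------------------
    rows = []   # (tid, role, biotype, class_code, filter_failure, length)

    def add(prefix, i, role, biotype, class_code, failure, length):
        tid = f"{prefix}_{i:05d}"
        rows.append([tid, role, biotype, class_code, failure, int(length)])
        return tid

    pcg_ids = [
        add("PCG", i, "pcg", "pcg", "=", "class_code",
            rng.integers(600, 3000))
        for i in range(cfg.n_pcg)
    ]
    known_ids = [
        add("KNLNC", i, "known_lnc", "known_lncRNA", "=", "class_code",
            rng.integers(200, 2000))
        for i in range(cfg.n_known_lnc)
    ]
    novel_ids = []
    i = 0
    for code in sorted(cfg.n_novel_lnc):
        for _ in range(cfg.n_novel_lnc[code]):
            novel_ids.append(
                add("NOVEL", i, "novel_lnc", "candidate", code, "none",
                    rng.integers(200, 2000))
            )
            i += 1
    coding_decoys = [
        add("CODDEC", i, "coding_decoy", "candidate", "u", "coding",
            rng.integers(400, 2000))
        for i in range(cfg.n_coding_decoys)
    ]
    short_decoys = [
        add("SHORTDEC", i, "short_decoy", "candidate", "u", "length",
            rng.integers(60, 200))
        for i in range(cfg.n_short_decoys)
    ]
    homology_decoys = [
        add("HOMDEC", i, "homology_decoy", "candidate", "u", "homology",
            rng.integers(300, 2000))
        for i in range(cfg.n_homology_decoys)
    ]
    lowexpr_decoys = [
        add("LOWDEC", i, "low_expression_decoy", "candidate", "u", "expression",
            rng.integers(300, 2000))
        for i in range(cfg.n_low_expression_decoys)
    ]

    truth = pd.DataFrame(
        rows,
        columns=["transcript_id", "role", "biotype", "class_code",
                 "filter_failure", "length"],
    ).set_index("transcript_id")
    truth["is_novel_lncRNA"] = truth.role == "novel_lnc"
    truth["calcium_class"] = "none_class"
    truth["responds_nacl"] = False
    truth["responds_sorbitol"] = False
    truth["module"] = ""
    truth["cis_partner"] = ""
    truth["known_expressed"] = False

    # ---- role assignment within pools ---------------------------------
    novel_pool = list(novel_ids)
    pcg_pool = list(pcg_ids)
    cis_lnc = [novel_pool.pop() for _ in range(cfg.n_cis_pairs)]
    cis_pcg = [pcg_pool.pop() for _ in range(cfg.n_cis_pairs)]
    responders: list[tuple[str, str]] = []   # (tid, class)
    for c in sorted(cfg.calcium_scheme):
        for _ in range(n_ca_lnc[c]):
            responders.append((novel_pool.pop(0), c))
        for _ in range(n_ca_pcg[c]):
            responders.append((pcg_pool.pop(0), c))
    module_members: list[tuple[str, str]] = []
    for m, size in enumerate(cfg.module_sizes):
        name = f"M{m + 1}"
        for _ in range(size):
            module_members.append((pcg_pool.pop(0), name))

    for tid, c in responders:
        truth.loc[tid, "calcium_class"] = c
    for tid, name in module_members:
        truth.loc[tid, "module"] = name
    for l, p in zip(cis_lnc, cis_pcg):
        truth.loc[l, "cis_partner"] = p
        truth.loc[p, "cis_partner"] = l

    # known lncRNAs below the expression filter
    low_known = known_ids[: cfg.n_known_lnc_low]
    truth.loc[known_ids, "known_expressed"] = True
    truth.loc[low_known, "known_expressed"] = False

    # ---- planted effects ---------------------------------------------
    geno_map = _CLASS_GENOTYPES_GAIN if cfg.mutant_gain else _CLASS_GENOTYPES_LOSS
    patterns = _assign_treatments(rng, len(responders), cfg.osmotic_fraction)
    eff_rows = []
    for (tid, c), pat in zip(responders, patterns):
        treatments = ("NaCl", "sorbitol") if pat == "both" else (pat,)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        truth.loc[tid, "responds_nacl"] = "NaCl" in treatments
        truth.loc[tid, "responds_sorbitol"] = "sorbitol" in treatments
        for g in geno_map[c]:
            for tr in treatments:
                for h in (6, 24):
                    eff_rows.append([tid, g, tr, h, sign * cfg.effect_size])
    effects = pd.DataFrame(
        eff_rows, columns=["transcript_id", "genotype", "treatment", "time_h", "log2fc"]
    )

    # ---- genomic placement -------------------------------------------
    chroms = [f"Chr{i + 1}" for i in range(cfg.n_chromosomes)]
    cursor = {c: 1 for c in chroms}
    placement: dict[str, tuple[str, int, int]] = {}
    cis_geometry = []

    pair_of = dict(zip(cis_lnc, cis_pcg))
    singles = [t for t in truth.index if t not in pair_of and t not in set(cis_pcg)]
    units = [(l,) for l in cis_lnc] + [(t,) for t in singles]
    rng.shuffle(units)
    for u, unit in enumerate(units):
        chrom = chroms[u % len(chroms)]
        tid = unit[0]
        glen = int(truth.loc[tid, "length"] * 1.5)   # genomic span > spliced length
        start = cursor[chrom]
        placement[tid] = (chrom, start, start + glen - 1)
        end = start + glen - 1
        if tid in pair_of:
            p = pair_of[tid]
            gap = int(rng.integers(cfg.cis_min_gap, cfg.cis_max_gap + 1))
            pstart = end + gap + 1
            pglen = int(truth.loc[p, "length"] * 1.5)
            placement[p] = (chrom, pstart, pstart + pglen - 1)
            end = pstart + pglen - 1
            cis_geometry.append([tid, p, chrom, gap, cfg.cis_target_r])
        cursor[chrom] = end + cfg.locus_spacing
    needed = max(cursor.values())
    if cfg.chrom_length is not None and needed > cfg.chrom_length:
        raise ValueError(
            f"chrom_length {cfg.chrom_length} too small to place the requested "
            f"loci; use at least {needed}"
        )

    # ---- build records and sequences ---------------------------------
    records, sequences = [], {}
    for tid in truth.index:
        chrom, start, end = placement[tid]
        exons = _make_exons(rng, start, int(truth.loc[tid, "length"]))
        end = exons[-1][1]
        seq = _random_sequence(rng, int(truth.loc[tid, "length"]))
        rec = TranscriptRecord(
            transcript_id=tid,
            locus_id=f"LOC_{tid}",
            chrom=chrom,
            start=start,
            end=end,
            strand="+" if rng.random() < 0.5 else "-",
            exons=exons,
            class_code=str(truth.loc[tid, "class_code"]),
            biotype=str(truth.loc[tid, "biotype"]),
            sequence=seq,
        )
        records.append(rec)
        sequences[tid] = seq

    # exon/intron realization can shift transcript ends a little relative
    # to the provisional spans used for placement: re-measure pair gaps
    rec_by_id = {r.transcript_id: r for r in records}
    for row in cis_geometry:
        a, b = rec_by_id[row[0]], rec_by_id[row[1]]
        row[3] = max(0, max(a.start, b.start) - min(a.end, b.end) - 1)

    # ---- coding-potential verdicts ------------------------------------
    profiles = {}
    for tid in truth.index:
        role = truth.loc[tid, "role"]
        if role == "pcg":
            verdicts = {p: "coding" for p in CODING_PREDICTORS}
        elif role == "coding_decoy":
            # flagged coding by at least one predictor
            k = int(rng.integers(1, len(CODING_PREDICTORS) + 1))
            chosen = rng.choice(len(CODING_PREDICTORS), size=k, replace=False)
            verdicts = {
                p: ("coding" if j in chosen else "noncoding")
                for j, p in enumerate(CODING_PREDICTORS)
            }
        else:
            verdicts = {p: "noncoding" for p in CODING_PREDICTORS}
        profiles[tid] = CodingPotentialProfile(transcript_id=tid, verdicts=verdicts)

    # ---- homology hits ------------------------------------------------
    known_target_ids = [f"ATMRNA_{i:04d}" for i in range(max(1, cfg.n_homology_decoys))]
    hits = []
    for j, tid in enumerate(homology_decoys):
        hits.append(
            HomologyHit(
                query_id=tid,
                subject_id=known_target_ids[j % len(known_target_ids)],
                identity_pct=float(rng.uniform(91.0, 99.9)),
                e_value=float(10.0 ** rng.uniform(-40, -11)),
            )
        )
    if novel_ids:
        # one sub-threshold hit: high E-value branch must NOT eliminate
        hits.append(
            HomologyHit(
                query_id=novel_ids[0],
                subject_id=known_target_ids[0],
                identity_pct=85.0,
                e_value=1e-12,
            )
        )

    truth = truth.drop(columns=["length"])
    bundle = SimulationBundle(
        records=records,
        sequences=sequences,
        known_lnc_ids=known_ids,
        known_target_ids=known_target_ids,
        profiles=profiles,
        hits=hits,
        truth=SyntheticTruth(
            transcripts=truth,
            effects=effects,
            cis_pairs=pd.DataFrame(
                cis_geometry,
                columns=["lncrna_id", "pcg_id", "chrom", "gap_bp", "target_r"],
            ),
        ),
    )
    return bundle


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _group_normalized_latent(
    factor: np.ndarray, lam: float, group_idx: list[np.ndarray]
) -> np.ndarray:
    """Multiplier 2^(lam * factor) normalized to mean 1 within each
    replicate group, so planted correlation never shifts group means."""
    mult = np.exp2(lam * factor)
    out = mult.copy()
    for idx in group_idx:
        out[idx] = mult[idx] / mult[idx].mean()
    return out


def simulate_expression(
    bundle: SimulationBundle,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> ExpressionMatrix:
    """FPKM = 2^(baseline + planted effects + N(0, sigma^2)) times the
    group-normalized latent multipliers for cis pairs and modules."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    cfg = config
    truth = bundle.truth.transcripts
    samples = full_design(replicates=3)
    n_s = len(samples)
    tids = list(truth.index)
    tpos = {t: i for i, t in enumerate(tids)}

    groups: dict[tuple, list[int]] = {}
    for j, s in enumerate(samples):
        groups.setdefault(s.group, []).append(j)
    group_idx = [np.asarray(v) for v in groups.values()]

    # baselines
    base = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=len(tids))
    responder_ids = set(bundle.truth.effects.transcript_id)
    for i, tid in enumerate(tids):
        role = truth.loc[tid, "role"]
        if role in ("novel_lnc", "known_lnc"):
            base[i] += cfg.lnc_baseline_shift
        # responders must clear the fold-change threshold even at low baselines
        if tid in responder_ids:
            base[i] = max(base[i], 3.0)
        if role == "novel_lnc" or (
            truth.loc[tid, "role"] == "known_lnc" and truth.loc[tid, "known_expressed"]
        ):
            base[i] = max(base[i], 0.0)   # guarantee the expression filter passes
    # planted-low transcripts sit far below the 0.1 FPKM screen
    low_base = math.log2(0.05) - 10.0 * cfg.noise_sd
    for i, tid in enumerate(tids):
        role = truth.loc[tid, "role"]
        if role == "low_expression_decoy" or (
            role == "known_lnc" and not truth.loc[tid, "known_expressed"]
        ):
            base[i] = low_base

    log2mu = np.tile(base[:, None], (1, n_s))

    # condition effects
    sample_group = [s.group for s in samples]
    for row in bundle.truth.effects.itertuples():
        i = tpos[row.transcript_id]
        for j, g in enumerate(sample_group):
            if g == (row.genotype, row.treatment, row.time_h):
                log2mu[i, j] += row.log2fc

    noise = rng.normal(0.0, cfg.noise_sd, size=log2mu.shape) if cfg.noise_sd > 0 else 0.0
    fpkm = np.exp2(log2mu + noise)

    # group-mean normalization centres the latent within each replicate
    # triple, shrinking its variance by (1 - 1/n_rep); inflate to compensate
    center_infl = math.sqrt(3.0 / 2.0)

    # latent multipliers: modules
    lam_mod = loading_scale(cfg.module_loading, cfg.noise_sd) * center_infl
    for name in sorted(set(truth.module) - {""}):
        z = rng.normal(size=n_s)
        members = truth.index[truth.module == name]
        for tid in members:
            mult = _group_normalized_latent(z, lam_mod, group_idx)
            fpkm[tpos[tid], :] *= mult

    # latent multipliers: cis pairs (shared factor, shared scale)
    # (cis_loading already accounts for the group normalization)
    lam_cis = cis_loading(cfg.cis_target_r, cfg.noise_sd)
    for row in bundle.truth.cis_pairs.itertuples():
        z = rng.normal(size=n_s)
        mult = _group_normalized_latent(z, lam_cis, group_idx)
        fpkm[tpos[row.lncrna_id], :] *= mult
        fpkm[tpos[row.pcg_id], :] *= mult

    fpkm = np.maximum(fpkm, 0.0)
    values = pd.DataFrame(fpkm, index=tids, columns=[s.sample_id for s in samples])
    matrix = ExpressionMatrix(values, samples)
    bundle.matrix = matrix
    return matrix


def simulate_all(config: SimulationConfig, out_dir=None) -> SimulationBundle:
    """Generate annotation + expression; optionally write all files."""
    rng = np.random.default_rng(config.seed)
    bundle = simulate_annotation(config, rng)
    simulate_expression(bundle, config, rng)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
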