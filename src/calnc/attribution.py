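"""Regional-calcium attribution of DE genes, plus the count/level
comparison statistics.

A gene is "calcium affected" in a condition when it is DE in a
parvalbumin mutant but not in WT under the same (treatment, time): the
buffered compartment's missing calcium signal is the only difference, so
DE-in-mutant-only isolates genes whose stress response is normally held
in check by that compartment's calcium.  Pooling such sets across
conditions for the cytosolic (PV-NES) and nucleosolic (NLS-PV) buffers
and intersecting yields the cytosolic-only / nucleosolic-only /
co-regulated partition.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import CalncError, ExpressionMatrix

log = logging.getLogger(__name__)

COMPARTMENT_MUTANT = {"cyt": "PV_NES", "nuc": "NLS_PV"}


def calcium_affected(de_mutant: set, de_wt: set) -> set:
    """DE in the mutant, excluding genes also DE in WT: de_mutant \\ de_wt."""
    return set(de_mutant) - set(de_wt)


@dataclass
class RegulationAssignment:
    table: pd.DataFrame            # index transcript_id; class + per-condition flags
    cyt_only: set
    nuc_only: set
    both: set

    @property
    def classes(self) -> dict[str, set]:
        return {"cyt_only": self.cyt_only, "nuc_only": self.nuc_only, "both": self.both}


def classify_regulation(
    affected_pvnes: Mapping[tuple, set],
    affected_nlspv: Mapping[tuple, set],
) -> RegulationAssignment:
    """Pool per-condition calcium-affected sets (union over conditions)
    and partition: cyt_only = Cyt \\ Nuc, nuc_only = Nuc \\ Cyt,
    both = Cyt intersect Nuc.  Condition keys must match."""
    if set(affected_pvnes) != set(affected_nlspv):
        raise CalncError("condition keys differ between compartments")
    cyt = set().union(*affected_pvnes.values()) if affected_pvnes else set()
    nuc = set().union(*affected_nlspv.values()) if affected_nlspv else set()
    cyt_only, nuc_only, both = cyt - nuc, nuc - cyt, cyt & nuc

    genes = sorted(cyt | nuc)
    rows = []
    for g in genes:
        klass = "both" if g in both else ("cyt_only" if g in cyt_only else "nuc_only")
        row = {"calcium_class": klass}
        for cond in sorted(affected_pvnes):
            tag = "_".join(map(str, cond))
            row[f"cyt_{tag}"] = g in affected_pvnes[cond]
            row[f"nuc_{tag}"] = g in affected_nlspv[cond]
        rows.append(row)
    table = pd.DataFrame(rows, index=pd.Index(genes, name="transcript_id"))
    return RegulationAssignment(table=table, cyt_only=cyt_only, nuc_only=nuc_only, both=both)


def attribute_from_de(
    de_sets: Mapping, conditions: Optional[Sequence[tuple]] = None
) -> RegulationAssignment:
    """Build the attribution from per-contrast DE sets keyed by Contrast.

    ``conditions`` restricts to particular (treatment, time_h) cells,
    e.g. for a per-treatment or per-time breakdown; default = all.
    """
    by = {(c.genotype, c.treatment, c.time_h): s for c, s in de_sets.items()}
    if conditions is None:
        conditions = sorted({(t, h) for (_, t, h) in by})
    aff_cyt, aff_nuc = {}, {}
    for (t, h) in conditions:
        wt = by.get(("WT", t, h), set())
        aff_cyt[(t, h)] = calcium_affected(by.get(("PV_NES", t, h), set()), wt)
        aff_nuc[(t, h)] = calcium_affected(by.get(("NLS_PV", t, h), set()), wt)
    return classify_regulation(aff_cyt, aff_nuc)


# ---------------------------------------------------------------------------
# comparison statistics
# ---------------------------------------------------------------------------

def compare_fraction_fisher(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Returns (odds_ratio, p); a zero margin gives p = 1 and odds ratio
    NaN (undefined).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return float("nan"), 1.0
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def _mwu_u(ranks_a: np.ndarray, n_a: int) -> float:
    return ranks_a.sum() - n_a * (n_a + 1) / 2.0


def compare_levels_mwu(values_a, values_b, exact_max_n: int = 20) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midrank ties.

    Exact p by full enumeration of labelings when nA + nB <= exact_max_n
    (two-sided = doubled smaller tail, capped at 1); tie-corrected normal
    approximation with continuity correction otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise CalncError("both value vectors must be non-empty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    u_obs = _mwu_u(ranks[:na], na)

    if na + nb <= exact_max_n:
        idx = np.array(list(itertools.combinations(range(na + nb), na)))
        u_all = ranks[idx].sum(axis=1) - na * (na + 1) / 2.0
        tol = 1e-9
        lo = np.mean(u_all <= u_obs + tol)
        hi = np.mean(u_all >= u_obs - tol)
        p = min(1.0, 2.0 * min(lo, hi))
        return float(u_obs), float(p)

    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def class_comparison_table(
    classes: Mapping[str, set],
    lnc_ids: set,
    abs_lfc: Mapping[str, float],
) -> pd.DataFrame:
    """Pairwise comparisons between calcium classes: Fisher's exact test
    on the lncRNA/PCG composition (counts) and Mann-Whitney U on the
    |log2FC| of the member genes (expression levels)."""
    rows = []
    names = sorted(classes)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ga, gb = classes[a], classes[b]
            if not ga or not gb:
                continue
            tab = [
                [sum(g in lnc_ids for g in ga), sum(g not in lnc_ids for g in ga)],
                [sum(g in lnc_ids for g in gb), sum(g not in lnc_ids for g in gb)],
            ]
            odds, p_f = compare_fraction_fisher(tab)
            rows.append({"comparison": f"{a}_vs_{b}", "test": "fisher_lnc_vs_pcg",
                         "statistic": odds, "p": p_f})
            va = [abs_lfc[g] for g in ga if g in abs_lfc]
            vb = [abs_lfc[g] for g in gb if g in abs_lfc]
            if va and vb:
                u, p_u = compare_levels_mwu(va, vb)
                rows.append({"comparison": f"{a}_vs_{b}", "test": "mwu_abs_log2fc",
                             "statistic": u, "p": p_u})
    return pd.DataFrame(rows, columns=["comparison", "test", "statistic", "p"])


# ---------------------------------------------------------------------------
# co-expression universe
# ---------------------------------------------------------------------------

def select_universe(
    matrix: ExpressionMatrix,
    treatment: str,
    compartment: str,
    min_fpkm: float = 0.1,
) -> set:
    """Transcripts with group-mean FPKM >= min_fpkm in >= 1 group among
    {WT, the compartment's mutant} x {treatment} (all timepoints).

    This is the expression-support screen feeding the co-expression
    stage; 'cyt' pairs WT with PV-NES, 'nuc' with NLS-PV.
    """
    if compartment not in COMPARTMENT_MUTANT:
        raise CalncError(f"unknown compartment {compartment!r}; use 'cyt' or 'nuc'")
    genos = ("WT", COMPARTMENT_MUTANT[compartment])
    keep = []
    for g, cols in matrix.groups().items():
        if g[0] in genos and g[1] == treatment:
            keep.append(matrix.values[cols].mean(axis=1))
    means = pd.concat(keep, axis=1)
    ok = means.max(axis=1) >= min_fpkm
    return set(ok.index[ok])
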