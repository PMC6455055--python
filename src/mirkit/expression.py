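"""Expression quantification, differential expression and trend profiling."""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

#: ordered developmental stages; leaves and stems form two ordered series
DEFAULT_TISSUES = ("sBud", "sL1", "sL2", "sS1", "sS2")

#: ordered non-flat step signatures -> profile index 0..7
PROFILE_ORDER: Tuple[Tuple[int, int], ...] = (
    (-1, -1),
    (-1, 0),
    (-1, 1),
    (0, -1),
    (0, 1),
    (1, -1),
    (1, 0),
    (1, 1),
)

_CLASS_OF_SIGNATURE = {
    (-1, -1): "down",
    (-1, 0): "down",
    (0, -1): "down",
    (1, 1): "up",
    (1, 0): "up",
    (0, 1): "up",
    (1, -1): "peak",
    (-1, 1): "valley",
    (0, 0): "flat",
}


def tpm_normalize(
    counts: pd.DataFrame, library_totals: Mapping[str, int]
) -> pd.DataFrame:
    """Tags-per-million: count / library-total-clean-tags * 1e6, per column."""
    totals = pd.Series({lib: library_totals[lib] for lib in counts.columns})
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"non-positive library totals: {bad}")
    return counts.div(totals, axis=1) * 1e6


def class_ratio_percent(class_count: int, library_total: int) -> float:
    """Class-tag share of a library in percent, rounded to 2 decimals."""
    if library_total <= 0:
        raise ValueError("library total must be positive")
    return round(class_count / library_total * 100, 2)


def replicate_correlation(
    tpm: pd.DataFrame, tissue_of: Mapping[str, str]
) -> pd.DataFrame:
    """Pearson r on log2(TPM+1) for every within-tissue replicate pair."""
    rows = []
    by_tissue: Dict[str, List[str]] = {}
    for lib in tpm.columns:
        by_tissue.setdefault(tissue_of[lib], []).append(lib)
    for tissue, libs in by_tissue.items():
        if len(libs) < 2:
            raise ValueError(f"tissue {tissue} has fewer than 2 replicates")
        for a, b in combinations(libs, 2):
            x = np.log2(tpm[a].to_numpy() + 1.0)
            y = np.log2(tpm[b].to_numpy() + 1.0)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r = math.nan
            else:
                r = float(stats.pearsonr(x, y).statistic)
            rows.append({"tissue": tissue, "lib_a": a, "lib_b": b, "r": r})
    return pd.DataFrame(rows)


@dataclass
class DEResult:
    mirna: str
    comparison: str
    log2_fold_change: float
    p_value: float
    significant: bool


def differential_expression(
    counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    library_totals: Mapping[str, int],
    alpha: float = 0.05,
    lfc: float = 2.0,
    pseudo_tpm: float = 0.01,
    comparison: Optional[str] = None,
) -> List[DEResult]:
    """Pooled Fisher-exact differential expression between two library groups.

    Replicates are pooled by summation; each miRNA is tested on the 2x2 table
    [miRNA tags vs remaining tags] x [group A vs B] with a doubled smaller
    one-sided hypergeometric tail (capped at 1).  log2FC uses group-mean TPM
    with a pseudo-TPM to keep zero groups finite.  Significant iff
    p < alpha and \\|log2FC\\| >= lfc.
    """
    if not group_a or not group_b:
        raise ValueError("both groups need at least one library")
    comparison = comparison or f"{'+'.join(group_a)}_vs_{'+'.join(group_b)}"
    tot_a = sum(library_totals[l] for l in group_a)
    tot_b = sum(library_totals[l] for l in group_b)
    tpm = tpm_normalize(counts[list(group_a) + list(group_b)], library_totals)
    results = []
    for mirna, row in counts.iterrows():
        a = int(row[list(group_a)].sum())
        b = int(row[list(group_b)].sum())
        # X ~ Hypergeom(N=tot_a+tot_b, K=a+b, n=tot_a): tags of this miRNA in A
        rv = stats.hypergeom(tot_a + tot_b, a + b, tot_a)
        p = min(1.0, 2.0 * min(rv.cdf(a), rv.sf(a - 1)))
        mean_tpm_a = float(tpm.loc[mirna, list(group_a)].mean())
        mean_tpm_b = float(tpm.loc[mirna, list(group_b)].mean())
        l2fc = math.log2((mean_tpm_a + pseudo_tpm) / (mean_tpm_b + pseudo_tpm))
        results.append(
            DEResult(
                mirna=str(mirna),
                comparison=comparison,
                log2_fold_change=l2fc,
                p_value=float(p),
                significant=p < alpha and abs(l2fc) >= lfc,
            )
        )
    return results


def tissue_specific(
    counts: pd.DataFrame,
    tissue_of: Mapping[str, str],
    classes: Optional[Mapping[str, Sequence[str]]] = None,
    min_replicates: int = 2,
) -> Tuple[Dict[str, List[str]], Dict[frozenset, List[str]]]:
    """Classify miRNAs expressed exclusively within one tissue class.

    A miRNA is "expressed" in a tissue iff it has a raw count >= 1 in at
    least ``min_replicates`` of that tissue's replicate libraries, and is
    specific to class X iff expressed in at least one tissue of X and in no
    tissue outside X.  Returns (class -> miRNA list, Venn partition keyed by
    frozenset of expressed classes).
    """
    if classes is None:
        classes = {
            "bud": ("sBud",),
            "leaf": ("sL1", "sL2"),
            "stem": ("sS1", "sS2"),
        }
    tissue_libs: Dict[str, List[str]] = {}
    for lib in counts.columns:
        tissue_libs.setdefault(tissue_of[lib], []).append(lib)
    class_of_tissue = {t: cls for cls, ts in classes.items() for t in ts}

    specific: Dict[str, List[str]] = {cls: [] for cls in classes}
    venn: Dict[frozenset, List[str]] = {}
    for mirna, row in counts.iterrows():
        expressed_tissues = {
            tissue
            for tissue, libs in tissue_libs.items()
            if sum(row[l] >= 1 for l in libs) >= min(min_replicates, len(libs))
        }
        expressed_classes = frozenset(
            class_of_tissue[t] for t in expressed_tissues if t in class_of_tissue
        )
        if expressed_classes:
            venn.setdefault(expressed_classes, []).append(str(mirna))
        if len(expressed_classes) == 1:
            specific[next(iter(expressed_classes))].append(str(mirna))
    return specific, venn


@dataclass
class TrendAssignment:
    mirna: str
    group: str
    signature: Tuple[int, int]
    profile_index: Optional[int]  # None for flat
    trend_class: str


def assign_trend(
    mirna: str,
    stage_means: Sequence[float],
    group: str = "G1",
    fold: float = 1.5,
    pseudo: float = 0.01,
) -> TrendAssignment:
    """Assign a step signature and trend class over three ordered stage means.

    Step = +1 if (next+pseudo)/(prev+pseudo) >= fold, -1 if <= 1/fold, else 0.
    Flat (0, 0) profiles are excluded from the eight indexed profiles.
    """
    if len(stage_means) != 3:
        raise ValueError("exactly three ordered stage means required")
    steps = []
    for prev, nxt in zip(stage_means, stage_means[1:]):
        ratio = (nxt + pseudo) / (prev + pseudo)
        steps.append(1 if ratio >= fold else (-1 if ratio <= 1.0 / fold else 0))
    signature = (steps[0], steps[1])
    trend_class = _CLASS_OF_SIGNATURE[signature]
    index = PROFILE_ORDER.index(signature) if signature != (0, 0) else None
    return TrendAssignment(mirna, group, signature, index, trend_class)


def summarize_trends(
    assignments: Sequence[TrendAssignment],
) -> Dict[str, object]:
    """Per-profile and per-class counts with class percentages (1 decimal).

    Flat assignments are excluded from the denominator, mirroring their
    exclusion from the eight profiles.
    """
    non_flat = [a for a in assignments if a.trend_class != "flat"]
    per_profile = {sig: 0 for sig in PROFILE_ORDER}
    per_class = {"down": 0, "up": 0, "peak": 0, "valley": 0}
    for a in non_flat:
        per_profile[a.signature] += 1
        per_class[a.trend_class] += 1
    total = len(non_flat)
    percentages = {
        cls: round(n / total * 100, 1) if total else math.nan
        for cls, n in per_class.items()
    }
    return {
        "total": total,
        "per_profile": per_profile,
        "per_class": per_class,
        "percent": percentages,
    }


def ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_cal: float,
    ct_ref_cal: float,
) -> float:
    """Relative qPCR fold change 2**-ddCT of target vs reference gene."""
    for v in (ct_target_sample, ct_ref_sample, ct_target_cal, ct_ref_cal):
        if not math.isfinite(v):
            raise ValueError("CT values must be finite")
    ddct_value = (ct_target_sample - ct_ref_sample) - (ct_target_cal - ct_ref_cal)
    return 2.0 ** (-ddct_value)
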