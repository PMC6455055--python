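"""Rule-based plant miRNA target prediction on ungapped duplexes.

A candidate site is the transcript subsequence of the miRNA's length at one
offset.  Position ``i`` of the miRNA (counted 1..L from its 5' end) is paired
against position ``L-i+1`` of the site; each position is a Watson-Crick pair,
a G:U wobble (weight 0.5) or a mismatch (weight 1.0).  Six rules decide a
site:

R1  total weight <= 4
R2  no run of >= 3 consecutive non-WC positions
R3  no two consecutive non-WC positions both inside miRNA positions 2-12
R4  positions 10 and 11 must be Watson-Crick
R5  summed weight over positions 1-12 <= 2.5
R6  duplex energy >= 60% of the energy of the miRNA bound to its perfect
    complement (one fold provider's pair model for both)

By default wobbles count as non-WC in the adjacency/position rules (R2-R4),
the strictest reading; ``gu_counts_in_adjacency=False`` relaxes them to
mismatches only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

from .fold import pair_energy

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "U"), ("U", "G")}

STATE_WC = "W"
STATE_GU = "G"
STATE_MISMATCH = "M"

_WEIGHT = {STATE_WC: 0.0, STATE_GU: 0.5, STATE_MISMATCH: 1.0}

RULE_NAMES = ("R1", "R2", "R3", "R4", "R5", "R6")


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def rna_complement(seq: str) -> str:
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    return "".join(comp[c] for c in seq)


@dataclass
class DuplexAlignment:
    """One ungapped miRNA/site duplex with a per-position state vector."""

    mirna: str  # RNA, 5'->3'
    site: str  # RNA, transcript subsequence, 5'->3'
    states: str  # W/G/M per miRNA position 1..L

    @property
    def total_weight(self) -> float:
        return sum(_WEIGHT[s] for s in self.states)


def align_duplex(mirna: str, site: str) -> DuplexAlignment:
    """Pair miRNA position i against site position L-i+1 and classify each."""
    m = _rna(mirna)
    s = _rna(site)
    if len(m) != len(s):
        raise ValueError(f"length mismatch: miRNA {len(m)} vs site {len(s)}")
    L = len(m)
    states = []
    for i in range(L):
        pair = (m[i], s[L - 1 - i])
        if pair in WC_PAIRS:
            states.append(STATE_WC)
        elif pair in GU_PAIRS:
            states.append(STATE_GU)
        else:
            states.append(STATE_MISMATCH)
    return DuplexAlignment(m, s, "".join(states))


@dataclass
class RuleConfig:
    max_total_weight: float = 4.0
    max_run: int = 2  # longest permitted run of non-WC positions
    adjacency_window: Tuple[int, int] = (2, 12)  # 1-based inclusive, R3
    protected_positions: Tuple[int, ...] = (10, 11)  # R4
    seed_window: Tuple[int, int] = (1, 12)  # 1-based inclusive, R5
    max_seed_weight: float = 2.5
    min_energy_ratio: float = 60.0
    gu_counts_in_adjacency: bool = True  # wobble is non-WC for R2/R3/R4


def score_rules(
    alignment: DuplexAlignment, config: Optional[RuleConfig] = None
) -> Dict[str, bool]:
    """Evaluate rules R1-R5 independently (R6 needs a fold model; see below)."""
    cfg = config or RuleConfig()
    states = alignment.states
    if cfg.gu_counts_in_adjacency:
        non_wc = [s != STATE_WC for s in states]
    else:
        non_wc = [s == STATE_MISMATCH for s in states]

    verdicts = {}
    verdicts["R1"] = alignment.total_weight <= cfg.max_total_weight

    run = longest = 0
    for bad in non_wc:
        run = run + 1 if bad else 0
        longest = max(longest, run)
    verdicts["R2"] = longest <= cfg.max_run

    lo, hi = cfg.adjacency_window
    verdicts["R3"] = not any(
        non_wc[i - 1] and non_wc[i]
        for i in range(1, len(states))
        if lo <= i <= hi and lo <= i + 1 <= hi
    )

    verdicts["R4"] = all(
        not non_wc[p - 1] for p in cfg.protected_positions if p <= len(states)
    )

    s_lo, s_hi = cfg.seed_window
    seed_weight = sum(
        _WEIGHT[states[p - 1]] for p in range(s_lo, min(s_hi, len(states)) + 1)
    )
    verdicts["R5"] = seed_weight <= cfg.max_seed_weight
    return verdicts


def duplex_energy(alignment: DuplexAlignment) -> float:
    """Sum of pair energies over WC/GU positions (mismatches contribute 0)."""
    L = len(alignment.mirna)
    total = 0.0
    for i, state in enumerate(alignment.states):
        if state != STATE_MISMATCH:
            total += pair_energy(alignment.mirna[i], alignment.site[L - 1 - i])
    return total


def perfect_energy(mirna: str) -> float:
    """Energy of the miRNA bound to its exact complement under the pair model."""
    m = _rna(mirna)
    return sum(pair_energy(c, p) for c, p in zip(m, rna_complement(m)))


def energy_ratio(alignment: DuplexAlignment) -> Optional[float]:
    """Duplex/perfect energy as a percentage; None if the perfect energy is 0."""
    perfect = perfect_energy(alignment.mirna)
    if perfect == 0.0:
        return None
    return duplex_energy(alignment) / perfect * 100.0


@dataclass
class TargetSite:
    mirna_id: str
    transcript_id: str
    start: int  # 1-based site start on the transcript, sense strand
    alignment: DuplexAlignment
    mismatch_score: float
    energy_ratio: Optional[float]
    rule_verdicts: Dict[str, bool] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.rule_verdicts.get(r, False) for r in RULE_NAMES)

    @property
    def first_failed_rule(self) -> Optional[str]:
        for r in RULE_NAMES:
            if not self.rule_verdicts.get(r, False):
                return r
        return None


def score_site(
    mirna_id: str,
    mirna_seq: str,
    transcript_id: str,
    transcript_seq: str,
    offset: int,
    config: Optional[RuleConfig] = None,
) -> TargetSite:
    """Build and fully score the site at 0-based ``offset`` on the transcript."""
    cfg = config or RuleConfig()
    t = _rna(transcript_seq)
    m = _rna(mirna_seq)
    site = t[offset : offset + len(m)]
    aln = align_duplex(m, site)
    verdicts = score_rules(aln, cfg)
    ratio = energy_ratio(aln)
    verdicts["R6"] = ratio is not None and ratio >= cfg.min_energy_ratio
    return TargetSite(
        mirna_id=mirna_id,
        transcript_id=transcript_id,
        start=offset + 1,
        alignment=aln,
        mismatch_score=aln.total_weight,
        energy_ratio=ratio,
        rule_verdicts=verdicts,
    )


def predict_targets(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    config: Optional[RuleConfig] = None,
    keep_failed: bool = False,
) -> List[TargetSite]:
    """Slide every miRNA over every transcript and emit rule-passing sites.

    Overlapping passing sites are all reported; a transcript may host several
    sites and several miRNAs.
    """
    cfg = config or RuleConfig()
    out: List[TargetSite] = []
    for tid in sorted(transcripts):
        t = _rna(transcripts[tid])
        for mid in sorted(mirnas):
            m = _rna(mirnas[mid])
            L = len(m)
            for offset in range(0, len(t) - L + 1):
                site = score_site(mid, m, tid, t, offset, cfg)
                if site.passed or keep_failed:
                    out.append(site)
    return out
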