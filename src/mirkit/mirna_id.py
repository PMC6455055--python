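"""miRNA identification: catalog matching, novel hairpin calling, summaries."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from . import fold as _fold
from .fold import FoldProvider


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq.upper()))


@dataclass
class MatureMiRNA:
    """A mature miRNA with per-library aggregated tag counts."""

    id: str
    sequence: str  # RNA alphabet, 5'->3'
    family: str
    origin: str  # "known" | "novel"
    precursor_id: Optional[str] = None
    counts: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = _rna(self.sequence)


@dataclass
class PrecursorHairpin:
    """A folded precursor locus hosting one mature arm."""

    id: str
    sequence: str
    contig: str
    start: int  # 0-based half-open genome coordinates, + strand of precursor
    end: int
    strand: str
    structure: str
    mfe: float
    mature_arm: str  # "5p" | "3p"
    mature_offset: int  # 0-based offset of the mature within the precursor

    def __post_init__(self) -> None:
        if self.mfe > 0:
            raise ValueError("precursor MFE must be <= 0")
        if len(self.structure) != len(self.sequence):
            raise ValueError("structure/sequence length mismatch")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    return sum(x != y for x, y in zip(a, b))


def match_known(
    tag_counts: Mapping[str, Mapping[str, int]],
    catalog: Mapping[str, str],
    max_mismatch: int = 2,
    families: Optional[Mapping[str, str]] = None,
) -> Tuple[List[MatureMiRNA], List[str]]:
    """Assign tags to catalog matures by ungapped Hamming matching.

    A tag matches a reference of equal length iff their Hamming distance is
    <= ``max_mismatch``; it is assigned to the minimum-distance reference,
    ties broken by lexicographically smallest reference id.  Returns the
    matched miRNAs (counts aggregated over their tags) and the list of
    unmatched tag sequences.

    Parameters
    ----------
    tag_counts : mapping tag sequence -> {library: count}
    catalog : mapping reference id -> mature sequence
    families : optional mapping reference id -> family name
    """
    if not catalog:
        raise ValueError("catalog is empty")
    ref = {rid: _rna(seq) for rid, seq in catalog.items()}
    by_len: Dict[int, List[Tuple[str, str]]] = {}
    for rid in sorted(ref):
        by_len.setdefault(len(ref[rid]), []).append((rid, ref[rid]))

    hits: Dict[str, MatureMiRNA] = {}
    unmatched: List[str] = []
    for tag in tag_counts:
        rtag = _rna(tag)
        best_id, best_d = None, max_mismatch + 1
        for rid, rseq in by_len.get(len(rtag), []):
            d = hamming(rtag, rseq)
            if d < best_d:  # sorted ids make ties resolve lexicographically
                best_id, best_d = rid, d
        if best_id is None:
            unmatched.append(tag)
            continue
        mir = hits.get(best_id)
        if mir is None:
            fam = families.get(best_id, best_id) if families else best_id
            mir = MatureMiRNA(best_id, ref[best_id], fam, "known")
            hits[best_id] = mir
        for lib, n in tag_counts[tag].items():
            mir.counts[lib] = mir.counts.get(lib, 0) + n
    return [hits[k] for k in sorted(hits)], unmatched


@dataclass
class NovelCriteria:
    """Acceptance thresholds for a novel precursor hairpin."""

    max_mfe: float = -18.0
    min_precursor_len: int = 65
    max_precursor_len: int = 400
    min_paired_mature: int = 14
    max_unpaired_run: int = 6
    flank_short: int = 20
    flank_long: int = 200


def _find_loci(genome: Mapping[str, str], tag: str) -> List[Tuple[str, int, str]]:
    """All exact occurrences of ``tag`` (DNA) on either strand: (contig, start, strand)."""
    dna = _rna(tag).replace("U", "T")
    rc = revcomp(dna)
    loci = []
    for contig in sorted(genome):
        seq = genome[contig].upper()
        for query, strand in ((dna, "+"), (rc, "-")):
            start = seq.find(query)
            while start != -1:
                loci.append((contig, start, strand))
                start = seq.find(query, start + 1)
    return loci


def _check_hairpin(
    precursor: str,
    structure: str,
    mfe: float,
    mature_offset: int,
    mature_len: int,
    criteria: NovelCriteria,
) -> Optional[str]:
    """Return the mature arm ("5p"/"3p") if all hairpin rules hold, else None."""
    if mfe > criteria.max_mfe:
        return None
    if not criteria.min_precursor_len <= len(precursor) <= criteria.max_precursor_len:
        return None
    region = structure[mature_offset : mature_offset + mature_len]
    # the mature must sit on a single arm, outside any loop it would straddle
    if "(" in region and ")" in region:
        return None
    paired = sum(1 for c in region if c != ".")
    if paired < criteria.min_paired_mature:
        return None
    run = best = 0
    for c in region:
        run = run + 1 if c == "." else 0
        best = max(best, run)
    if best > criteria.max_unpaired_run:
        return None
    return "5p" if "(" in region else "3p"


def call_novel(
    tags: Iterable[str],
    genome: Mapping[str, str],
    fold_provider: FoldProvider = _fold.fold,
    criteria: Optional[NovelCriteria] = None,
    tag_counts: Optional[Mapping[str, Mapping[str, int]]] = None,
    name_prefix: str = "novel-m",
) -> List[Tuple[MatureMiRNA, PrecursorHairpin]]:
    """Call novel miRNAs from genome-mapped tags by hairpin folding.

    For each occurrence of a tag on the genome, two candidate precursors are
    extracted (short flank upstream / long flank downstream, and the reverse
    arrangement), folded, and checked against ``criteria``; the best-MFE
    passing candidate per locus is kept.  One miRNA is reported per distinct
    tag sequence (its best locus); candidates whose window would run past a
    contig edge are clipped to the contig.
    """
    criteria = criteria or NovelCriteria()
    results: List[Tuple[MatureMiRNA, PrecursorHairpin]] = []
    fold_cache: Dict[str, Tuple[str, float]] = {}
    index = 0
    for tag in tags:
        mature_rna = _rna(tag)
        mlen = len(mature_rna)
        best: Optional[Tuple[float, PrecursorHairpin, str]] = None
        for contig, start, strand in _find_loci(genome, tag):
            contig_seq = genome[contig].upper()
            end = start + mlen
            for up, down in (
                (criteria.flank_short, criteria.flank_long),
                (criteria.flank_long, criteria.flank_short),
            ):
                if strand == "+":
                    w0, w1 = max(0, start - up), min(len(contig_seq), end + down)
                    window = contig_seq[w0:w1]
                    offset = start - w0
                else:
                    w0, w1 = max(0, start - down), min(len(contig_seq), end + up)
                    window = revcomp(contig_seq[w0:w1])
                    offset = w1 - end
                precursor = _rna(window)
                if precursor[offset : offset + mlen] != mature_rna:
                    continue
                cached = fold_cache.get(precursor)
                if cached is None:
                    cached = fold_cache[precursor] = fold_provider(precursor)
                structure, mfe = cached
                arm = _check_hairpin(precursor, structure, mfe, offset, mlen, criteria)
                if arm is None:
                    continue
                if best is None or mfe < best[0]:
                    hp = PrecursorHairpin(
                        id="",
                        sequence=precursor,
                        contig=contig,
                        start=w0,
                        end=w1,
                        strand=strand,
                        structure=structure,
                        mfe=mfe,
                        mature_arm=arm,
                        mature_offset=offset,
                    )
                    best = (mfe, hp, arm)
        if best is None:
            continue
        index += 1
        _, hp, arm = best
        stem = f"{name_prefix}{index:04d}"
        hp.id = stem
        mir = MatureMiRNA(
            id=f"{stem}-{arm}",
            sequence=mature_rna,
            family=stem,
            origin="novel",
            precursor_id=stem,
        )
        if tag_counts is not None and tag in tag_counts:
            mir.counts = dict(tag_counts[tag])
        results.append((mir, hp))
    return results


def conservation_summary(
    presence: Mapping[str, Sequence[int]],
    families: Sequence[str],
    threshold: int = 10,
) -> Dict[str, Tuple[int, bool]]:
    """Per-family species count and conserved flag (count strictly > threshold).

    ``presence`` maps species -> 0/1 vector aligned with ``families``.
    """
    if not presence:
        raise ValueError("presence matrix is empty")
    widths = {len(v) for v in presence.values()}
    if widths != {len(families)}:
        raise ValueError("presence matrix is not rectangular over the family list")
    out = {}
    for j, fam in enumerate(families):
        if fam in out:
            raise ValueError(f"duplicate family {fam}")
        count = sum(int(bool(v[j])) for v in presence.values())
        out[fam] = (count, count > threshold)
    return out


def composition_bias(
    sequences: Iterable[str],
) -> Tuple[Dict[int, Dict[str, float]], Dict[int, Dict[str, float]]]:
    """Positional and first-nucleotide base frequencies.

    Returns ``(per_position, first_by_length)`` where ``per_position[p]`` is
    the A/C/G/U frequency at 1-based position ``p`` among sequences of length
    >= p, and ``first_by_length[L]`` the first-base frequencies among
    sequences of length ``L``.  Frequencies at each key sum to 1.
    """
    seqs = [_rna(s) for s in sequences]
    if not seqs:
        raise ValueError("no sequences")
    per_pos: Dict[int, Dict[str, float]] = {}
    first: Dict[int, Dict[str, int]] = {}
    maxlen = max(len(s) for s in seqs)
    for p in range(1, maxlen + 1):
        counts = {b: 0 for b in "ACGU"}
        total = 0
        for s in seqs:
            if len(s) >= p:
                counts[s[p - 1]] += 1
                total += 1
        per_pos[p] = {b: c / total for b, c in counts.items()}
    for s in seqs:
        d = first.setdefault(len(s), {b: 0 for b in "ACGU"})
        d[s[0]] += 1
    first_freq = {
        L: {b: c / sum(d.values()) for b, c in d.items()} for L, d in first.items()
    }
    return per_pos, first_freq
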