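"""Raw read cleaning, tag collapsing, structural-RNA annotation and stats.

Reads are adapter-trimmed (exact-prefix search at the 3' end allowing one
mismatch, no indels), length/quality filtered and collapsed into unique tags
with one count per library.  Tags are then assigned exactly one annotation
class in priority order rRNA > tRNA > snRNA > snoRNA > exon_sense > repeat >
clean (genome-mapped, zero mismatches, either strand) > unmapped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from Bio import SeqIO

from .mirna_id import revcomp

ANNOTATION_CLASSES = (
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "exon_sense",
    "repeat",
    "clean",
    "unmapped",
)


@dataclass
class TagTable:
    """Unique tag sequences with per-library counts and an annotation class."""

    libraries: List[str]
    counts: Dict[str, Dict[str, int]] = field(default_factory=dict)
    classes: Dict[str, str] = field(default_factory=dict)

    def add(self, tag: str, library: str, n: int = 1) -> None:
        self.counts.setdefault(tag, {})[library] = (
            self.counts.get(tag, {}).get(library, 0) + n
        )

    def library_total(self, library: str) -> int:
        return sum(c.get(library, 0) for c in self.counts.values())

    def tags_of_class(self, cls: str) -> List[str]:
        return [t for t, c in self.classes.items() if c == cls]


@dataclass
class LibraryStats:
    library: str
    raw_reads: int
    clean_total: int
    clean_unique: int
    class_totals: Dict[str, int]
    length_histogram: Dict[int, int]

    def __post_init__(self) -> None:
        if self.class_totals and sum(self.class_totals.values()) != self.clean_total:
            raise ValueError("class totals must sum to the clean-tag total")

    @property
    def modal_length(self) -> int:
        return max(sorted(self.length_histogram), key=lambda L: self.length_histogram[L])


def trim_adapter(
    read: str, adapter: str, max_mismatch: int = 1, min_overlap: int = 3
) -> str:
    """Trim a 3' adapter found by leftmost prefix match with <= 1 mismatch.

    At each start position the overlapping prefix of the adapter is compared
    to the read suffix; the first acceptable position wins.  Overlaps shorter
    than ``min_overlap`` are ignored and short overlaps (< 2*max_mismatch+2)
    must match exactly, so stray 1-2 base suffix coincidences never clip an
    adapter-free read.  Untouched if the adapter is never found.
    """
    if not adapter:
        return read
    read_u, ad_u = read.upper(), adapter.upper()
    for start in range(len(read_u) - min_overlap + 1):
        overlap = min(len(ad_u), len(read_u) - start)
        allowed = max_mismatch if overlap >= 2 * max_mismatch + 2 else 0
        mm = sum(1 for i in range(overlap) if read_u[start + i] != ad_u[i])
        if mm <= allowed:
            return read[:start]
    return read


def clean_reads(
    fastq_path: str,
    adapter: str,
    library: str,
    tag_table: Optional[TagTable] = None,
    min_len: int = 18,
    max_len: int = 30,
    min_qual: float = 20.0,
) -> Tuple[TagTable, int]:
    """Clean one FASTQ library into (tag table, raw read count)."""
    if tag_table is None:
        tag_table = TagTable(libraries=[library])
    if library not in tag_table.libraries:
        tag_table.libraries.append(library)
    raw = 0
    try:
        for rec in SeqIO.parse(fastq_path, "fastq"):
            raw += 1
            seq = str(rec.seq).upper()
            quals = rec.letter_annotations["phred_quality"]
            trimmed = trim_adapter(seq, adapter)
            if not min_len <= len(trimmed) <= max_len:
                continue
            q = quals[: len(trimmed)]
            if q and sum(q) / len(q) < min_qual:
                continue
            tag_table.add(trimmed, library)
    except ValueError as exc:
        raise ValueError(f"unreadable FASTQ {fastq_path} at record {raw + 1}: {exc}")
    return tag_table, raw


def _occurrences(haystack: str, needle: str) -> List[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _overlaps(start: int, end: int, intervals: Sequence[Tuple[int, int]]) -> bool:
    return any(start < e and s < end for s, e in intervals)


def annotate_tags(
    tags: TagTable,
    ncrna: Mapping[str, Mapping[str, str]],
    genome: Mapping[str, str],
    exon_intervals: Optional[Mapping[str, Sequence[Tuple[int, int]]]] = None,
    repeat_intervals: Optional[Mapping[str, Sequence[Tuple[int, int]]]] = None,
) -> TagTable:
    """Assign each tag its single annotation class.

    ``ncrna`` maps class name ("rRNA", "tRNA", ...) to {seq id: sequence};
    a tag belongs to a class if the tag or its reverse complement is an exact
    substring of any reference in that class.  Exon matching is sense-strand
    only (forward genome occurrences overlapping an exon interval); repeat
    matching uses occurrences on either strand.  Intervals are 0-based
    half-open per contig.
    """
    for cls in ("rRNA", "tRNA", "snRNA", "snoRNA"):
        if cls not in ncrna:
            raise FileNotFoundError(f"missing ncRNA reference set: {cls}")
    exon_intervals = exon_intervals or {}
    repeat_intervals = repeat_intervals or {}
    genome_u = {c: s.upper() for c, s in genome.items()}

    for tag in tags.counts:
        dna = tag.upper().replace("U", "T")
        rc = revcomp(dna)
        assigned = None
        for cls in ("rRNA", "tRNA", "snRNA", "snoRNA"):
            refs = ncrna[cls]
            if any(dna in r.upper() or rc in r.upper() for r in refs.values()):
                assigned = cls
                break
        if assigned is None:
            fwd: Dict[str, List[int]] = {}
            rev: Dict[str, List[int]] = {}
            for contig, seq in genome_u.items():
                f = _occurrences(seq, dna)
                r = _occurrences(seq, rc)
                if f:
                    fwd[contig] = f
                if r:
                    rev[contig] = r
            L = len(dna)
            if any(
                _overlaps(p, p + L, exon_intervals.get(c, ()))
                for c, ps in fwd.items()
                for p in ps
            ):
                assigned = "exon_sense"
            elif any(
                _overlaps(p, p + L, repeat_intervals.get(c, ()))
                for strandhits in (fwd, rev)
                for c, ps in strandhits.items()
                for p in ps
            ):
                assigned = "repeat"
            elif fwd or rev:
                assigned = "clean"
            else:
                assigned = "unmapped"
        tags.classes[tag] = assigned
    return tags


def library_stats(tags: TagTable, library: str, raw_reads: int) -> LibraryStats:
    clean_total = 0
    class_totals = Counter()
    length_hist = Counter()
    unique = 0
    for tag, counts in tags.counts.items():
        n = counts.get(library, 0)
        if n == 0:
            continue
        unique += 1
        clean_total += n
        class_totals[tags.classes.get(tag, "unmapped")] += n
        length_hist[len(tag)] += n
    return LibraryStats(
        library=library,
        raw_reads=raw_reads,
        clean_total=clean_total,
        clean_unique=unique,
        class_totals=dict(class_totals),
        length_histogram=dict(length_hist),
    )


def library_summary(
    clean_totals: Mapping[str, int],
    tissue_of: Mapping[str, str],
) -> Dict[str, int]:
    """Arithmetic mean of replicate clean-tag totals per tissue, rounded.

    Uses round-half-up so e.g. a .5 mean rounds toward the larger integer.
    """
    groups: Dict[str, List[int]] = {}
    for lib, total in clean_totals.items():
        tissue = tissue_of[lib]
        groups.setdefault(tissue, []).append(total)
    out = {}
    for tissue, totals in groups.items():
        if not totals:
            raise ValueError(f"no libraries for tissue {tissue}")
        mean = sum(totals) / len(totals)
        out[tissue] = int(mean + 0.5)
    return out
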