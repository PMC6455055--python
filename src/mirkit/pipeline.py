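"""High-level orchestration of the full analysis over a study directory."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd

from . import expression as _expression
from . import preprocess as _preprocess
from .mirna_id import MatureMiRNA, call_novel, match_known
from .synthdata import ReferenceBundle


@dataclass
class StudyResult:
    tag_table: _preprocess.TagTable
    raw_reads: Dict[str, int]
    library_totals: Dict[str, int]
    mirnas: List[MatureMiRNA]
    counts: pd.DataFrame  # miRNA x library raw counts
    tpm: pd.DataFrame
    tissue_of: Dict[str, str]

    def tissue_mean_tpm(self) -> Dict[str, List[float]]:
        """Per-miRNA replicate-mean TPM over the ordered tissues."""
        tissues = list(dict.fromkeys(self.tissue_of.values()))
        out = {}
        for mirna in self.tpm.index:
            out[str(mirna)] = [
                float(
                    self.tpm.loc[
                        mirna, [l for l in self.tpm.columns if self.tissue_of[l] == t]
                    ].mean()
                )
                for t in tissues
            ]
        return out


def collapse_and_annotate(
    fastq_paths: Mapping[str, str],
    adapter: str,
    ncrna: Mapping[str, Mapping[str, str]],
    genome: Mapping[str, str],
    exon_intervals=None,
    repeat_intervals=None,
) -> Tuple[_preprocess.TagTable, Dict[str, int]]:
    table = _preprocess.TagTable(libraries=[])
    raw = {}
    for lib in fastq_paths:
        _, n = _preprocess.clean_reads(fastq_paths[lib], adapter, lib, table)
        raw[lib] = n
    _preprocess.annotate_tags(table, ncrna, genome, exon_intervals, repeat_intervals)
    return table, raw


def identify_mirnas(
    table: _preprocess.TagTable,
    catalog: Mapping[str, str],
    genome: Mapping[str, str],
    novel_lengths: Optional[Tuple[int, int]] = (18, 27),
) -> List[MatureMiRNA]:
    """Known catalog matching followed by novel hairpin calling on the rest.

    ``novel_lengths`` restricts which unmatched clean tags are folded (novel
    calling is the expensive step); None folds everything.
    """
    clean = {
        t: c for t, c in table.counts.items() if table.classes.get(t) == "clean"
    }
    if catalog:
        known, unmatched = match_known(clean, catalog)
    else:
        known, unmatched = [], list(clean)
    if novel_lengths is not None:
        lo, hi = novel_lengths
        unmatched = [t for t in unmatched if lo <= len(t) <= hi]
    novel = call_novel(unmatched, genome, tag_counts=clean)
    return known + [m for m, _ in novel]


def run_study(
    fastq_paths: Mapping[str, str],
    adapter: str,
    bundle: ReferenceBundle,
    tissue_of: Mapping[str, str],
    novel_lengths: Optional[Tuple[int, int]] = (20, 24),
) -> StudyResult:
    """Clean, annotate, identify and quantify one study end to end."""
    table, raw = collapse_and_annotate(
        fastq_paths, adapter, bundle.ncrna, bundle.genome
    )
    mirnas = identify_mirnas(table, bundle.catalog, bundle.genome, novel_lengths)
    totals = {lib: table.library_total(lib) for lib in table.libraries}
    counts = pd.DataFrame(
        {
            lib: [m.counts.get(lib, 0) for m in mirnas]
            for lib in table.libraries
        },
        index=[m.id for m in mirnas],
    )
    tpm = _expression.tpm_normalize(counts, totals)
    return StudyResult(
        tag_table=table,
        raw_reads=raw,
        library_totals=totals,
        mirnas=mirnas,
        counts=counts,
        tpm=tpm,
        tissue_of=dict(tissue_of),
    )
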