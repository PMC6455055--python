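"""Synthetic study generator with planted, recoverable ground truth.

Generates a complete toy dataset for a 5-tissue x 3-replicate small-RNA
design: a genome carrying hairpin precursors, a mature-miRNA catalog (a
configurable subset is "known", the rest are left for novel discovery),
transcripts carrying planted target sites, structural-RNA contaminant
references, TF and term annotation tables, per-library FASTQ reads whose
miRNA abundances follow planted trend signatures, an mRNA tissue-profile
table anti-monotone to its targeting miRNA (planted repression), and a
metabolite table linearly tied to planted transcripts.

Everything is driven by a single integer seed: the same (config, seed)
produces byte-identical output files, and every planted structure is
recoverable by the corresponding analysis module in the zero-noise limit
(verified at generation time for target sites and hairpins).
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import fold as _fold
from . import targets as _targets
from .expression import PROFILE_ORDER
from .mirna_id import NovelCriteria, _check_hairpin, revcomp

METABOLITES = ("GC", "EGC", "C", "EGCG", "EC", "ECG", "caffeine", "theanine")

TF_FAMILIES = ("SBP", "MYB", "bHLH", "HD-ZIP", "GRF", "NAC", "TCP", "ARF")

Signature = Tuple[int, int]


@dataclass
class SyntheticConfig:
    seed: int = 0
    tissues: Tuple[str, ...] = ("sBud", "sL1", "sL2", "sS1", "sS2")
    n_reps: int = 3
    n_mirnas: int = 8
    n_known: Optional[int] = None  # default: half the miRNAs go in the catalog
    n_transcripts: int = 10
    transcript_length: int = 300
    genome_length: int = 30000
    mirna_length: int = 21
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    reads_per_library: int = 20000
    dispersion: float = 0.0  # NB dispersion; 0 = deterministic counts
    contaminant_fraction: float = 0.0
    base_abundance: Tuple[float, float] = (20.0, 60.0)
    step_fold: float = 5.0  # per-step expression fold of planted trends
    n_filler_loci: int = 30  # distinct background genomic tag loci
    metabolite_noise_sd: float = 0.05  # relative to the profile spread
    n_triplets: int = 3
    planted_profiles: Optional[Dict[int, Dict[str, Signature]]] = None
    planted_targets: Optional[List[Tuple[int, int, int]]] = None
    planted_metabolite_links: Optional[List[Tuple[int, str, int]]] = None

    def __post_init__(self) -> None:
        if self.n_mirnas < 0:
            raise ValueError("n_mirnas must be >= 0")
        if self.n_known is None:
            self.n_known = self.n_mirnas // 2
        if self.n_known > self.n_mirnas:
            raise ValueError("n_known cannot exceed n_mirnas")
        # every precursor occupies ~100 bases plus spacing on the genome
        needed = self.n_mirnas * 200 + 1000
        if self.n_mirnas and self.genome_length < needed:
            raise ValueError(
                f"genome_length={self.genome_length} too short to place "
                f"{self.n_mirnas} precursors (need >= {needed})"
            )
        if self.planted_targets is None:
            k = min(self.n_triplets, self.n_mirnas, self.n_transcripts)
            self.planted_targets = [(i, i, 50) for i in range(k)]
        if self.planted_metabolite_links is None:
            links = []
            targeted = sorted({t for _, t, _ in self.planted_targets})
            for idx, tx in enumerate(targeted):
                links.append((tx, METABOLITES[idx % len(METABOLITES)], +1))
            self.planted_metabolite_links = links
        if self.planted_profiles is None:
            profiles = {}
            for i in range(self.n_mirnas):
                profiles[i] = {
                    "G1": PROFILE_ORDER[i % len(PROFILE_ORDER)],
                    "G2": PROFILE_ORDER[(3 * i + 1) % len(PROFILE_ORDER)],
                }
            self.planted_profiles = profiles

    @property
    def libraries(self) -> List[str]:
        return [f"{t}-{r}" for t in self.tissues for r in range(1, self.n_reps + 1)]


@dataclass
class GroundTruth:
    true_mirnas: List[str]
    matures: Dict[str, str]  # id -> RNA sequence
    known_ids: List[str]
    true_hairpins: List[Tuple[str, str, int]]  # (precursor id, sequence, mature offset)
    tissue_means: Dict[str, Dict[str, float]]  # mirna -> tissue -> expected count
    true_trend: Dict[str, Dict[str, Signature]]
    true_de: Dict[Tuple[str, str], List[str]]  # (tissueA, tissueB) -> DE miRNA ids
    true_targets: List[Tuple[str, str, int]]  # (mirna id, transcript id, 0-based offset)
    true_edges: List[Tuple[str, str, str]]  # (mirna, transcript, metabolite)
    mrna_profiles: Dict[str, List[float]]  # transcript -> per-tissue means


@dataclass
class ReferenceBundle:
    genome: Dict[str, str]
    transcripts: Dict[str, str]
    catalog: Dict[str, str]  # known mature id -> RNA sequence
    catalog_families: Dict[str, str]
    species_presence: Dict[str, List[int]]
    presence_families: List[str]
    ncrna: Dict[str, Dict[str, str]]
    go_annotation: List[Tuple[str, str, str, str]]  # gene, term, namespace, label
    tf_table: Dict[str, str]
    precursor_loci: Dict[str, Tuple[str, int, int, str]]


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _step_factor(step: int, fold: float) -> float:
    return {1: fold, 0: 1.0, -1: 1.0 / fold}[step]


def planted_tissue_means(
    config: SyntheticConfig, base: Mapping[str, float]
) -> Dict[str, Dict[str, float]]:
    """Expected per-tissue abundance from the planted G1/G2 signatures."""
    means: Dict[str, Dict[str, float]] = {}
    bud, l1, l2, s1, s2 = config.tissues
    for i, (mid, w) in enumerate(base.items()):
        sig = config.planted_profiles[i]
        g1, g2 = sig["G1"], sig["G2"]
        f = config.step_fold
        m = {bud: w}
        m[l1] = m[bud] * _step_factor(g1[0], f)
        m[l2] = m[l1] * _step_factor(g1[1], f)
        m[s1] = m[bud] * _step_factor(g2[0], f)
        m[s2] = m[s1] * _step_factor(g2[1], f)
        means[mid] = m
    return means


def _make_precursor(
    rng: np.random.Generator, mature_rna: str, criteria: NovelCriteria
) -> Optional[Tuple[str, int, str]]:
    """Build a hairpin precursor hosting ``mature_rna`` on its 5' arm.

    Layout: 5' flank + mature + loop + revcomp(mature) + 3' flank.  Returns
    (precursor RNA, mature offset, structure) once the folded precursor
    passes the novel-miRNA hairpin criteria, else None.
    """
    flank5 = _random_dna(rng, 12).replace("T", "U")
    flank3 = _random_dna(rng, 12).replace("T", "U")
    loop = _random_dna(rng, 8).replace("T", "U")
    arm3 = revcomp(mature_rna).replace("T", "U")
    precursor = flank5 + mature_rna + loop + arm3 + flank3
    structure, mfe = _fold.fold(precursor)
    arm = _check_hairpin(
        precursor, structure, mfe, len(flank5), len(mature_rna), criteria
    )
    if arm != "5p":
        return None
    return precursor, len(flank5), structure


def generate_reference(
    config: SyntheticConfig,
) -> Tuple[ReferenceBundle, GroundTruth]:
    """Generate the reference bundle and its ground truth (deterministic)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    criteria = NovelCriteria()
    L = config.mirna_length

    matures: Dict[str, str] = {}
    hairpins: List[Tuple[str, str, int]] = []
    precursor_dna: List[str] = []
    structures: Dict[str, str] = {}
    mature_list: List[str] = []
    while len(matures) < config.n_mirnas:
        mature = "U" + _random_dna(rng, L - 1).replace("T", "U")
        # keep matures mutually distant so known/novel assignment is unambiguous
        if any(
            sum(a != b for a, b in zip(mature, m)) <= 4 for m in mature_list
        ):
            continue
        made = _make_precursor(rng, mature, criteria)
        if made is None:
            continue
        idx = len(matures)
        mid = f"mir-{idx + 1:03d}"
        precursor, offset, structure = made
        matures[mid] = mature
        mature_list.append(mature)
        hairpins.append((f"pre-{idx + 1:03d}", precursor, offset))
        structures[f"pre-{idx + 1:03d}"] = structure
        precursor_dna.append(precursor.replace("U", "T"))

    # place precursors on the genome with generous spacing
    genome_chars = list(_random_dna(rng, config.genome_length))
    loci: Dict[str, Tuple[str, int, int, str]] = {}
    slot = 500
    for (pid, precursor, _off), dna in zip(hairpins, precursor_dna):
        genome_chars[slot : slot + len(dna)] = list(dna)
        loci[pid] = ("chr1", slot, slot + len(dna), "+")
        slot += len(dna) + 150
    genome = {"chr1": "".join(genome_chars)}
    # A hairpin precursor inherently carries the mature once forward and its
    # reverse complement once (the 3' arm); reject assemblies where a mature
    # additionally leaks into the random background.
    for mid in matures:
        dna = matures[mid].replace("U", "T")
        if genome["chr1"].count(dna) != 1 or genome["chr1"].count(revcomp(dna)) != 1:
            cfg2 = dataclasses.replace(config, seed=config.seed + 7919)
            return generate_reference(cfg2)

    mirna_ids = list(matures)
    known_ids = mirna_ids[: config.n_known]
    catalog = {mid: matures[mid] for mid in known_ids}
    catalog_families = {mid: f"fam-{mid.split('-')[1]}" for mid in known_ids}

    # family presence/absence matrix across synthetic species
    n_species = 20
    presence_fams = sorted(set(catalog_families.values()))
    species_presence = {}
    for s in range(n_species):
        row = (rng.random(len(presence_fams)) < 0.6).astype(int).tolist()
        species_presence[f"species_{s + 1:02d}"] = row

    # transcripts with planted target sites (exact reverse complements)
    transcripts: Dict[str, str] = {}
    for t in range(config.n_transcripts):
        transcripts[f"TX{t + 1:04d}"] = _random_dna(rng, config.transcript_length)
    tx_ids = list(transcripts)
    true_targets: List[Tuple[str, str, int]] = []
    for mi, ti, offset in config.planted_targets:
        mid, tid = mirna_ids[mi], tx_ids[ti]
        site_dna = revcomp(matures[mid].replace("U", "T"))
        seq = transcripts[tid]
        if offset + len(site_dna) > len(seq):
            raise ValueError(f"target offset {offset} beyond transcript {tid}")
        transcripts[tid] = seq[:offset] + site_dna + seq[offset + len(site_dna):]
        true_targets.append((mid, tid, offset))
    # generation-time check: every planted site passes the full rule set
    for mid, tid, offset in true_targets:
        site = _targets.score_site(mid, matures[mid], tid, transcripts[tid], offset)
        if not site.passed:
            raise AssertionError(
                f"planted site {mid}->{tid}@{offset} fails {site.first_failed_rule}"
            )

    ncrna = {
        "rRNA": {"rRNA_1": _random_dna(rng, 500)},
        "tRNA": {"tRNA_1": _random_dna(rng, 80)},
        "snRNA": {"snRNA_1": _random_dna(rng, 120)},
        "snoRNA": {"snoRNA_1": _random_dna(rng, 140)},
    }

    # expression ground truth
    lo, hi = config.base_abundance
    base = {mid: float(rng.uniform(lo, hi)) for mid in mirna_ids}
    tissue_means = planted_tissue_means(config, base)
    true_trend = {
        mirna_ids[i]: dict(config.planted_profiles[i]) for i in range(len(mirna_ids))
    }
    pseudo = 0.01
    scale = 1e6 / config.reads_per_library  # expected TPM per expected count
    true_de: Dict[Tuple[str, str], List[str]] = {}
    for a in config.tissues:
        for b in config.tissues:
            if a >= b:
                continue
            des = []
            for mid in mirna_ids:
                # mirror the zero-dispersion simulator (integer counts) so the
                # planted DE set is exactly recoverable in the noiseless limit
                ta = round(tissue_means[mid][a]) * scale + pseudo
                tb = round(tissue_means[mid][b]) * scale + pseudo
                if abs(np.log2(ta / tb)) >= 2.0:
                    des.append(mid)
            true_de[(a, b)] = des

    # mRNA tissue profiles: planted targets are exactly anti-monotone
    mrna_profiles: Dict[str, List[float]] = {}
    targeted = {tid: mid for mid, tid, _ in true_targets}
    for tid in tx_ids:
        if tid in targeted:
            m = [tissue_means[targeted[tid]][t] for t in config.tissues]
            mrna_profiles[tid] = [(max(m) + min(m)) - v for v in m]
        else:
            mrna_profiles[tid] = list(rng.uniform(5.0, 15.0, size=len(config.tissues)))

    # TF families for targeted transcripts (plus one decoy non-TF transcript)
    tf_table = {
        tid: TF_FAMILIES[i % len(TF_FAMILIES)]
        for i, tid in enumerate(sorted(targeted))
    }

    link_by_tx = {tx_ids[ti]: met for ti, met, _ in config.planted_metabolite_links}
    true_edges = [
        (mid, tid, link_by_tx[tid])
        for mid, tid, _ in true_targets
        if tid in link_by_tx
    ]

    go_annotation = []
    planted_term = ("GO:9000001", "BP", "planted regulation")
    for tid in sorted(targeted):
        go_annotation.append((tid, *planted_term))
    for i, tid in enumerate(tx_ids):
        go_annotation.append((tid, f"GO:10000{i % 4:02d}", "BP", f"background {i % 4}"))

    bundle = ReferenceBundle(
        genome=genome,
        transcripts=transcripts,
        catalog=catalog,
        catalog_families=catalog_families,
        species_presence=species_presence,
        presence_families=presence_fams,
        ncrna=ncrna,
        go_annotation=go_annotation,
        tf_table=tf_table,
        precursor_loci=loci,
    )
    truth = GroundTruth(
        true_mirnas=mirna_ids,
        matures=matures,
        known_ids=known_ids,
        true_hairpins=hairpins,
        tissue_means=tissue_means,
        true_trend=true_trend,
        true_de=true_de,
        true_targets=true_targets,
        true_edges=true_edges,
        mrna_profiles=mrna_profiles,
    )
    return bundle, truth


def _nb_counts(
    rng: np.random.Generator, mean: float, dispersion: float
) -> int:
    """Negative-binomial count with var = m + d*m^2; deterministic at d=0."""
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(round(mean))
    size = 1.0 / dispersion
    p = size / (size + mean)
    return int(rng.negative_binomial(size, p))


def simulate_reads(
    config: SyntheticConfig,
    bundle: ReferenceBundle,
    truth: GroundTruth,
    out_dir: str,
) -> Dict[str, str]:
    """Write one FASTQ per library; returns {library: path}.

    Each library holds exactly ``reads_per_library`` reads: miRNA reads with
    planted per-tissue abundances, a ``contaminant_fraction`` share of
    structural-RNA fragments, and background genomic 24-mers filling the
    remainder so every library total is identical.
    """
    os.makedirs(out_dir, exist_ok=True)
    genome = bundle.genome["chr1"]
    # background tag loci avoiding the precursor band at the genome start
    occupied_end = max((e for _, s, e, _ in bundle.precursor_loci.values()), default=0)
    rng0 = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    filler_tags = []
    while len(filler_tags) < config.n_filler_loci:
        pos = int(rng0.integers(occupied_end + 100, len(genome) - 40))
        tag = genome[pos : pos + 24]
        if "N" not in tag:
            filler_tags.append(tag)
    contaminant_pool = list(bundle.ncrna["rRNA"].values()) + list(
        bundle.ncrna["tRNA"].values()
    )

    paths = {}
    for lib_index, lib in enumerate(config.libraries):
        tissue = lib.rsplit("-", 1)[0]
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 303, lib_index])
        )
        reads: List[str] = []
        for mid in truth.true_mirnas:
            n = _nb_counts(rng, truth.tissue_means[mid][tissue], config.dispersion)
            reads.extend([truth.matures[mid].replace("U", "T")] * n)
        n_cont = int(round(config.contaminant_fraction * config.reads_per_library))
        for _ in range(n_cont):
            src = contaminant_pool[int(rng.integers(len(contaminant_pool)))]
            length = int(rng.integers(18, 29))
            start = int(rng.integers(0, len(src) - length))
            reads.append(src[start : start + length])
        n_fill = config.reads_per_library - len(reads)
        if n_fill < 0:
            reads = reads[: config.reads_per_library]
            n_fill = 0
        for _ in range(n_fill):
            reads.append(filler_tags[int(rng.integers(len(filler_tags)))])

        path = os.path.join(out_dir, f"{lib}.fastq")
        with open(path, "w") as fh:
            for i, tag in enumerate(reads):
                seq = tag + config.adapter
                fh.write(f"@{lib}:read{i + 1:06d}\n{seq}\n+\n{'I' * len(seq)}\n")
        paths[lib] = path
    return paths


def simulate_metabolites(
    config: SyntheticConfig,
    truth: GroundTruth,
    noise_sd: Optional[float] = None,
) -> Dict[str, List[float]]:
    """Metabolite contents (mg/g) per tissue, linearly tied to planted mRNAs.

    Linked metabolites are ``sign * scaled transcript profile + noise`` with
    Gaussian noise whose sd is ``metabolite_noise_sd`` times the profile
    spread; unlinked metabolites are independent random profiles.  Values are
    shifted to remain non-negative.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    if noise_sd is None:
        noise_sd = config.metabolite_noise_sd
    tx_ids = list(truth.mrna_profiles)
    out: Dict[str, List[float]] = {}
    linked = {}
    for ti, met, sign in config.planted_metabolite_links:
        linked[met] = (tx_ids[ti], sign)
    for met in METABOLITES:
        if met in linked:
            tid, sign = linked[met]
            profile = np.asarray(truth.mrna_profiles[tid], float)
            spread = float(np.ptp(profile)) or 1.0
            values = sign * profile / spread * 10.0
            values = values + rng.normal(0.0, noise_sd * 10.0, size=values.size)
            values = values - values.min() + 1.0
        else:
            values = rng.uniform(1.0, 12.0, size=len(config.tissues))
        out[met] = [float(v) for v in values]
    return out


# ---------------------------------------------------------------------------
# file writers


def _write_fasta(path: str, records: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


def write_bundle(
    config: SyntheticConfig,
    bundle: ReferenceBundle,
    truth: GroundTruth,
    out_dir: str,
) -> None:
    """Write the reference bundle, ground truth and metabolite table to disk."""
    os.makedirs(out_dir, exist_ok=True)
    _write_fasta(os.path.join(out_dir, "genome.fa"), bundle.genome)
    _write_fasta(os.path.join(out_dir, "transcripts.fa"), bundle.transcripts)
    _write_fasta(os.path.join(out_dir, "mature_catalog.fa"), bundle.catalog)
    for cls, seqs in bundle.ncrna.items():
        _write_fasta(os.path.join(out_dir, f"ncrna_{cls}.fa"), seqs)
    with open(os.path.join(out_dir, "species_presence.tsv"), "w") as fh:
        fh.write("species\t" + "\t".join(bundle.presence_families) + "\n")
        for sp, row in bundle.species_presence.items():
            fh.write(sp + "\t" + "\t".join(map(str, row)) + "\n")
    with open(os.path.join(out_dir, "annotation.tsv"), "w") as fh:
        fh.write("gene\tterm\tnamespace\tlabel\n")
        for gene, term, ns, label in bundle.go_annotation:
            fh.write(f"{gene}\t{term}\t{ns}\t{label}\n")
    with open(os.path.join(out_dir, "tf_families.tsv"), "w") as fh:
        fh.write("gene\tfamily\n")
        for gene in sorted(bundle.tf_table):
            fh.write(f"{gene}\t{bundle.tf_table[gene]}\n")
    with open(os.path.join(out_dir, "mrna_profiles.tsv"), "w") as fh:
        fh.write("transcript\t" + "\t".join(config.tissues) + "\n")
        for tid, prof in truth.mrna_profiles.items():
            fh.write(tid + "\t" + "\t".join(f"{v:.6g}" for v in prof) + "\n")
    metabolites = simulate_metabolites(config, truth)
    with open(os.path.join(out_dir, "metabolites.tsv"), "w") as fh:
        fh.write("metabolite\t" + "\t".join(config.tissues) + "\n")
        for met, vals in metabolites.items():
            fh.write(met + "\t" + "\t".join(f"{v:.6g}" for v in vals) + "\n")
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(
            {
                "true_mirnas": truth.true_mirnas,
                "matures": truth.matures,
                "known_ids": truth.known_ids,
                "true_hairpins": truth.true_hairpins,
                "tissue_means": truth.tissue_means,
                "true_trend": {
                    m: {g: list(s) for g, s in d.items()}
                    for m, d in truth.true_trend.items()
                },
                "true_de": {f"{a}|{b}": v for (a, b), v in truth.true_de.items()},
                "true_targets": truth.true_targets,
                "true_edges": truth.true_edges,
                "mrna_profiles": truth.mrna_profiles,
            },
            fh,
            indent=1,
            sort_keys=True,
        )


def generate_study(config: SyntheticConfig, out_dir: str) -> Dict[str, str]:
    """Full generation: references, truth, metabolites and FASTQ libraries."""
    bundle, truth = generate_reference(config)
    write_bundle(config, bundle, truth, out_dir)
    return simulate_reads(config, bundle, truth, os.path.join(out_dir, "reads"))
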