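"""Bundled demonstration tables for a 15-library (5 tissue x 3 replicate) sRNA study.

These are small literature-style summary tables used by the test suite, the
acceptance report and the documentation examples: per-library tag statistics,
a miRNA family-by-species presence/absence matrix, tissue-specific miRNA
membership lists, and trend-profile membership counts for the two ordered
developmental series (G1 = Bud/L1/L2, G2 = Bud/S1/S2).
"""

TISSUES = ("sBud", "sL1", "sL2", "sS1", "sS2")

LIBRARIES = tuple(f"{t}-{r}" for t in TISSUES for r in (1, 2, 3))

#: per-library totals of clean tags
LIBRARY_TOTALS = {
    "sBud-1": 13025496,
    "sBud-2": 13672142,
    "sBud-3": 15543919,
    "sL1-1": 13217393,
    "sL1-2": 12086276,
    "sL1-3": 13026547,
    "sL2-1": 11146588,
    "sL2-2": 13556636,
    "sL2-3": 10788646,
    "sS1-1": 10821241,
    "sS1-2": 11025165,
    "sS1-3": 12606617,
    "sS2-1": 9125465,
    "sS2-2": 11303334,
    "sS2-3": 9039947,
}

#: per-library totals of tags assigned to catalog (known) miRNAs
KNOWN_MIRNA_TAGS = {
    "sBud-1": 145547,
    "sBud-2": 96863,
    "sBud-3": 79234,
    "sL1-1": 237953,
    "sL1-2": 205017,
    "sL1-3": 127242,
    "sL2-1": 151824,
    "sL2-2": 162349,
    "sL2-3": 201288,
    "sS1-1": 48215,
    "sS1-2": 48019,
    "sS1-3": 74064,
    "sS2-1": 114250,
    "sS2-2": 130149,
    "sS2-3": 106664,
}

#: per-library totals of tags assigned to novel miRNAs
NOVEL_MIRNA_TAGS = {
    "sBud-1": 35371,
    "sBud-2": 22599,
    "sBud-3": 23593,
    "sL1-1": 47097,
    "sL1-2": 36970,
    "sL1-3": 30010,
    "sL2-1": 26207,
    "sL2-2": 21904,
    "sL2-3": 27762,
    "sS1-1": 11804,
    "sS1-2": 10145,
    "sS1-3": 18301,
    "sS2-1": 25010,
    "sS2-2": 26705,
    "sS2-3": 21290,
}

#: miRNA family presence (1) / absence (0) across 72 plant species
FAMILY_COLUMNS = ('miR156', 'miR396', 'miR166', 'miR171', 'miR160', 'miR167', 'miR164', 'miR172', 'miR319', 'miR159', 'miR169', 'miR408', 'miR390', 'miR395', 'miR398', 'miR168', 'miR399', 'miR162', 'miR393', 'miR394', 'miR482', 'miR403', 'miR530', 'miR2111', 'miR477', 'miR535', 'miR2118')

SPECIES_PRESENCE = {
    "Brachypodium distachyon": (1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 1, 0, 0, 0, 1),
    "Glycine max": (1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 1),
    "Arabidopsis thaliana": (1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 1, 0, 1, 0, 0, 0),
    "Oryza sativa": (1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 1, 0, 0, 1, 1),
    "Arabidopsis lyrata": (1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 1, 0, 1, 0, 0, 0),
    "Malus domestica": (1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 1, 1, 1, 1),
    "Prunus persica": (1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0),
    "Vitis vinifera": (1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 1, 1, 1, 0),
    "Populus trichocarpa": (1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 0),
    "Solanum tuberosum": (1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 1, 1, 1, 1, 1, 0, 1, 1, 1, 0, 1, 0, 1, 0, 1, 0, 0),
    "Citrus sinensis": (1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 1, 1, 1, 1, 1, 1, 1, 0, 1, 1, 0),
    "Cucumis melo": (1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 1, 1, 1, 0, 0),
    "Manihot esculenta": (1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0),
    "Amborella trichopoda": (1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 1, 1, 1, 1, 0, 0, 1, 1, 0, 0, 0, 1, 1, 1, 0),
    "Medicago truncatula": (1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 1, 0, 1, 1, 0, 0, 1),
    "Nicotiana tabacum": (1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 1, 1, 0, 0, 0, 1, 0, 0),
    "Aegilops tauschii": (1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 1, 1, 1, 1, 1, 1, 1, 0, 1, 1, 0, 0, 0, 0, 0, 0, 1),
    "Zea mays": (1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 1),
    "Sorghum bicolor": (1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 1),
    "Theobroma cacao": (1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 1, 0, 1, 1, 1, 1, 1, 1, 1, 1, 0, 1, 1, 1, 0, 1, 0),
    "Carica papaya": (1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 1, 1, 1, 0, 0, 0, 0, 1, 1, 0),
    "Linum usitatissimum": (1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 1, 0, 0, 0, 0),
    "Ricinus communis": (1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 1, 0, 0, 0, 1, 0),
    "Solanum lycopersicum": (1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 1, 1, 0, 1, 1, 1, 0, 1, 1, 1, 0, 0, 1, 0, 0),
    "Triticum aestivum": (1, 1, 0, 1, 1, 1, 1, 0, 1, 1, 1, 1, 0, 1, 1, 0, 1, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0),
    "Aquilegia caerulea": (1, 1, 1, 1, 1, 1, 0, 1, 1, 1, 1, 1, 0, 1, 1, 1, 1, 0, 0, 0, 1, 0, 1, 0, 1, 1, 0),
    "Brassica napus": (1, 1, 1, 1, 1, 1, 1, 1, 0, 1, 1, 0, 1, 1, 0, 1, 1, 1, 1, 1, 0, 1, 0, 1, 0, 0, 0),
    "Brassica rapa": (1, 1, 0, 1, 1, 1, 1, 1, 1, 1, 0, 1, 1, 1, 1, 1, 0, 1, 0, 0, 0, 1, 0, 1, 0, 0, 0),
    "Cynara cardunculus": (1, 1, 0, 1, 1, 1, 1, 1, 1, 0, 1, 1, 1, 1, 1, 1, 1, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0),
    "Physcomitrella patens": (1, 0, 1, 1, 1, 1, 0, 0, 1, 0, 0, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 0),
    "Gossypium hirsutum": (1, 1, 1, 0, 1, 1, 1, 1, 0, 0, 1, 0, 1, 0, 1, 0, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0),
    "Hevea brasiliensis": (1, 1, 1, 0, 0, 0, 0, 0, 1, 1, 0, 1, 0, 0, 1, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 1),
    "Vigna unguiculata": (1, 0, 0, 0, 1, 0, 1, 1, 1, 0, 1, 1, 0, 1, 0, 1, 1, 1, 0, 0, 1, 0, 0, 0, 0, 0, 1),
    "Gossypium raimondii": (0, 0, 1, 0, 0, 1, 1, 1, 0, 0, 0, 0, 0, 0, 1, 0, 1, 0, 0, 0, 1, 0, 1, 0, 1, 0, 0),
    "Salvia sclarea": (1, 1, 1, 1, 0, 0, 1, 1, 0, 0, 1, 0, 0, 1, 1, 0, 1, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0),
    "Pinus taeda": (1, 1, 1, 1, 0, 0, 0, 0, 1, 1, 0, 1, 1, 0, 1, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0),
    "Festuca arundinacea": (1, 1, 1, 1, 1, 0, 1, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Saccharum* sp.": (1, 1, 1, 0, 0, 1, 0, 0, 0, 1, 1, 1, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Arachis hypogaea": (1, 0, 0, 0, 1, 1, 0, 0, 0, 1, 0, 1, 0, 0, 1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0),
    "Helianthus tuberosus": (1, 0, 0, 1, 1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 1, 1, 0, 0, 1, 1, 0, 0, 0, 0),
    "Hordeum vulgare": (1, 0, 1, 1, 0, 0, 0, 0, 0, 1, 1, 0, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Lotus japonicus": (0, 1, 0, 1, 0, 1, 0, 1, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0),
    "Pinus densata": (0, 1, 1, 1, 0, 0, 0, 0, 0, 1, 1, 0, 1, 0, 0, 0, 0, 1, 0, 0, 1, 0, 0, 0, 0, 0, 0),
    "Selaginella moellendorffii": (1, 1, 1, 1, 1, 0, 0, 0, 1, 1, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Digitalis purpurea": (1, 1, 1, 0, 1, 1, 0, 1, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Picea abies": (0, 1, 1, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1, 0),
    "Acacia auriculiformis": (0, 1, 0, 0, 1, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 1, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Citrus trifoliata": (1, 0, 1, 1, 0, 1, 1, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Phaseolus vulgaris": (0, 0, 1, 0, 0, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0, 0, 0, 0, 1),
    "Saccharum officinarum": (1, 1, 0, 0, 0, 1, 0, 0, 0, 1, 0, 1, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Brassica oleracea": (0, 0, 0, 1, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Citrus clementina": (0, 1, 0, 1, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Citrus reticulata": (0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Cunninghamia lanceolata": (0, 0, 1, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Glycine soja": (0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0),
    "Helianthus annuus": (1, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Helianthus paradoxus": (1, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Helianthus petiolaris": (0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0, 0, 0, 0),
    "Rehmannia glutinosa": (0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Acacia mangium": (0, 1, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Avicennia marina": (1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Bruguiera cylindrica": (1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Bruguiera gymnorhiza": (1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Helianthus argophyllus": (1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0),
    "Helianthus ciliaris": (1, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Panax ginseng": (0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 1),
    "Chlamydomonas reinhardtii": (0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Elaeis guineensis": (0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Gossypium herbaceum": (0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Helianthus exilis": (0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Populus euphratica": (0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    "Triticum turgidum": (0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
}

#: tissue-specific miRNA membership lists (bud / leaf / stem classes)
TISSUE_SPECIFIC = {
    "bud": ('miR1128-x', 'miR781-y', 'miR8590-y', 'miR870-y', 'miR9759-y'),
    "leaf": ('miR1042-x', 'miR1045-x', 'miR1057-y', 'miR1063-x', 'miR1515-x', 'miR164-y', 'miR1866-y', 'miR2083-y', 'miR2111-y', 'miR2275-y', 'miR393-x', 'miR5061-y', 'miR5181-y', 'miR5523-y', 'miR5538-x', 'miR5653-y', 'miR6173-y', 'miR6281-x', 'miR7528-y', 'miR7711-x', 'miR7725-x', 'miR845-z', 'miR858-y', 'miR8665-y', 'miR9569-x', 'novel-m0703-5p', 'novel-m0722-5p', 'novel-m0945-3p', 'novel-m0953-5p', 'novel-m1089-3p', 'novel-m1125-5p'),
    "stem": ('miR1127-x', 'miR1865-x', 'miR2275-x', 'miR3512-y', 'miR3630-x', 'miR4388-y', 'miR474-x', 'miR474-y', 'miR5021-x', 'miR5385-x', 'miR5834-x', 'miR6485-x', 'miR7713-x', 'miR7717-x', 'miR7762-y', 'miR8007-y', 'miR8681-y', 'miR9863-x', 'novel-m0024-3p', 'novel-m0095-3p', 'novel-m0155-3p', 'novel-m0331-5p', 'novel-m0392-5p', 'novel-m0828-3p', 'novel-m0906-3p', 'novel-m1037-3p', 'novel-m1040-3p', 'novel-m1041-5p'),
}

#: trend-profile membership counts per ordered series, keyed by step signature.
#: Signatures are (step1, step2) with -1 = down, 0 = flat step, +1 = up.
TREND_PROFILE_COUNTS = {
    "G1": {(-1, -1): 75, (-1, 0): 67, (0, -1): 15,
           (1, 1): 40, (1, 0): 12, (0, 1): 1,
           (1, -1): 9, (-1, 1): 7},
    "G2": {(-1, -1): 42, (-1, 0): 34, (0, -1): 15,
           (1, 1): 35, (0, 1): 25, (1, 0): 4,
           (-1, 1): 95, (1, -1): 23},
}

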