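"""Reference stage-mean CPM table for 35 Syrah pericarp genes.

Independently tabulated reference values for cell-wall, water- and
sugar-transport genes at the growing (G), peak (P) and shrivelling (S)
stages, together with their reported integer percent variation, one-decimal
CPM difference (S - G, derived from unrounded stage means) and rank by
absolute difference within the full merged DEG list.  Used by the golden
tests: the package must reproduce the variation and difference columns
from the stage means and preserve the relative rank order.
"""

from __future__ import annotations

from typing import NamedTuple


class ReferenceGene(NamedTuple):
    gene_id_a: str  # VCost.v3 accession
    gene_id_b: str  # RefSeq locus
    cpm_G: float
    cpm_P: float
    cpm_S: float
    variation_pct: int
    difference: float  # one decimal, from unrounded stage means
    rank: int
    annotation: str


TABLE1: list[ReferenceGene] = [
    ReferenceGene("Vitvi05g01947", "LOC100264738", 5380, 974, 376, -93, -5003.9, 1, "Early nodulin-75-like"),
    ReferenceGene("Vitvi04g00442", "LOC100252479", 4387, 720, 241, -95, -4146.8, 2, "Uncharacterised"),
    ReferenceGene("Vitvi02g00310", "LOC100233001", 4818, 1336, 814, -83, -4004.5, 3, "[Aquaporin] VviPIP1-3"),
    ReferenceGene("Vitvi16g01800", "LOC100232884", 8635, 6627, 5693, -34, -2941.5, 4, "[Cell wall - SWITCH] invertase/pectin methylesterase inhibitor"),
    ReferenceGene("Vitvi13g00605", "LOC100233002", 2773, 971, 462, -83, -2311.3, 5, "[Aquaporin] VviPIP2-5"),
    ReferenceGene("Vitvi18g00189", "LOC100245385", 2812, 1299, 751, -73, -2061.0, 8, "[Cell wall] Expansin A (VvEXPA19)"),
    ReferenceGene("Vitvi13g00172", "LOC100244917", 1941, 414, 161, -92, -1780.1, 13, "[Cell wall] Expansin A (VvEXPA14)"),
    ReferenceGene("Vitvi18g00056", "LOC100232977", 1609, 345, 302, -81, -1307.6, 21, "[Sugar] Tonoplast Monosaccharide Transporter HT6"),
    ReferenceGene("Vitvi05g00953", "LOC100232902", 1143, 72, 17, -98, -1125.5, 24, "[Cell wall] Pectate lyase"),
    ReferenceGene("Vitvi08g01038", "LOC100233094", 1045, 105, 74, -93, -971.6, 26, "[Aquaporin] VviPIP2-3"),
    ReferenceGene("Vitvi12g02137", "LOC100233113", 1185, 499, 250, -79, -934.2, 27, "[Cell wall] Pectin methylesterase"),
    ReferenceGene("Vitvi06g01329", "LOC100265471", 1947, 1129, 1070, -45, -876.4, 29, "[Cell wall - SWITCH] xyloglucan endotransglucosylase/hydrolase 32"),
    ReferenceGene("Vitvi04g00465", "LOC100254408", 1092, 388, 308, -72, -783.6, 32, "[Cell wall] Cellulose synthase CESA1"),
    ReferenceGene("Vitvi08g01602", "LOC100233004", 823, 163, 101, -88, -721.4, 34, "[Aquaporin] VviTIP1-2"),
    ReferenceGene("Vitvi05g00548", "LOC100245945", 605, 52, 45, -93, -559.8, 40, "Sulfate transporter 3.1"),
    ReferenceGene("Vitvi15g01110", "LOC100240701", 827, 360, 322, -61, -504.8, 47, "[Aquaporin] VviPIP1-4"),
    ReferenceGene("Vitvi17g00070", "LOC100267921", 511, 71, 48, -91, -462.8, 52, "[Sugar] bidirectional sugar transporter SWEET10"),
    ReferenceGene("Vitvi15g00643", "LOC100253046", 1015, 413, 554, -45, -460.7, 53, "[Cell wall - SWITCH] Expansin B (VvEXPB04)"),
    ReferenceGene("Vitvi03g00247", "LOC100264011", 594, 212, 143, -76, -451.2, 55, "[Sugar] Tonoplast Monosaccharide Transporter TMT2"),
    ReferenceGene("Vitvi18g00008", "LOC100242715", 441, 80, 72, -84, -369.5, 72, "[Cell wall] Cellulose synthase CESA2"),
    ReferenceGene("Vitvi03g00155", "LOC100233027", 434, 139, 70, -84, -363.9, 73, "[Aquaporin] VviPIP2-7"),
    ReferenceGene("Vitvi11g00272", "LOC100233140", 541, 259, 177, -67, -363.6, 74, "Malate dehydrogenase (NADP+)"),
    ReferenceGene("Vitvi04g01668", "LOC100232854", 1434, 786, 1084, -24, -350.1, 78, "Alcohol dehydrogenase 2"),
    ReferenceGene("Vitvi16g00713", "LOC100256970", 351, 24, 15, -96, -335.9, 82, "[Sugar] Vacuolar Invertase GIN1"),
    ReferenceGene("Vitvi14g01977", "LOC100244103", 297, 2, 3, -99, -294.2, 93, "[Cell wall] Expansin A (VvEXPA16)"),
    ReferenceGene("Vitvi18g00397", "LOC100232961", 333, 119, 52, -84, -280.7, 105, "[Sugar] Hexose transporter HT2"),
    ReferenceGene("Vitvi03g00209", "LOC100258952", 286, 35, 25, -91, -260.4, 113, "[Cell wall] Expansin A-like (VvEXLA01)"),
    ReferenceGene("Vitvi18g01628", "LOC100255463", 351, 133, 106, -70, -245.8, 124, "[Cell wall] Cellulose synthase CESA2"),
    ReferenceGene("Vitvi11g00835", "LOC100248411", 277, 102, 47, -83, -229.9, 131, "[Cuticle metabolism] CER3-like - Aliphatic wax"),
    ReferenceGene("Vitvi12g00721", "LOC100242544", 237, 9, 9, -96, -227.4, 134, "Fasciclin-like arabinogalactan protein 2"),
    ReferenceGene("Vitvi13g00255", "LOC100233003", 245, 48, 32, -87, -213.6, 143, "[Aquaporin] VviTIP1-3"),
    ReferenceGene("Vitvi13g01731", "LOC100256811", 289, 126, 133, -54, -156.0, 186, "Cellulose synthase CESA3"),
    ReferenceGene("Vitvi01g01805", "LOC100232906", 157, 7, 3, -98, -153.9, 189, "Xyloglucan endotransglucosylase/hydrolase protein B"),
    ReferenceGene("Vitvi17g01251", "LOC100261426", 136, 7, 2, -99, -134.2, 225, "Expansin A (VvEXPA18)"),
    ReferenceGene("Vitvi06g00281", "LOC100233093", 126, 23, 12, -91, -113.9, 281, "[Aquaporin] VviPIP2-4"),
]

#: Eight-gene golden subset used by the exact acceptance checks
#: (nodulin-75, PIP1-3, PIP2-5, HT6, TIP1-2, SWEET10, EXPA16, HT2).
GOLDEN8 = (
    "Vitvi05g01947", "Vitvi02g00310", "Vitvi13g00605", "Vitvi18g00056",
    "Vitvi08g01602", "Vitvi17g00070", "Vitvi14g01977", "Vitvi18g00397",
)
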