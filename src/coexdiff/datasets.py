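"""Published reference values for cross-checking the differential-correlation test.

The GSE134347 sepsis cohort (156 sepsis patients, 82 healthy controls,
HTA2.0 arrays) is the canonical two-condition dataset for this kind of
analysis.  ``GSE134347_TOP_SWITCH_PAIRS`` lists the twenty most significant
oppositely correlated gene pairs reported for that cohort: per-condition
Pearson correlations (r_sepsis, r_healthy) for pairs from the two most
trait-associated modules, every one of which flips sign between conditions
and was called significant at local FDR < 0.05.  They serve as worked
inputs for :func:`coexdiff.diffcorr.fisher_z_test`; the expression matrices
themselves are not redistributed here.
"""

from __future__ import annotations

__all__ = [
    "GSE134347_N_SEPSIS",
    "GSE134347_N_HEALTHY",
    "GSE134347_TOP_SWITCH_PAIRS",
]

GSE134347_N_SEPSIS = 156
GSE134347_N_HEALTHY = 82

#: (gene_a, gene_b, r_sepsis, r_healthy, module colour)
GSE134347_TOP_SWITCH_PAIRS: tuple[tuple[str, str, float, float, str], ...] = (
    ("ZMYM6NB", "FAM20A", 0.406621495, -0.728163034, "blue"),
    ("ZNF366", "GOLGA1", 0.410168886, -0.681188564, "blue"),
    ("ZNF609", "FAM20A", 0.42304016, -0.680428116, "blue"),
    ("ZNF366", "WDR37", 0.443006043, -0.647605336, "blue"),
    ("ZNF366", "FBXW2", 0.401904401, -0.643995081, "blue"),
    ("ZNF282", "ATP11B", 0.422093972, -0.63235805, "blue"),
    ("ZNF366", "SDHC", 0.418454554, -0.626207078, "blue"),
    ("ZNF366", "PAG1", 0.436699597, -0.610998009, "blue"),
    ("ZNF366", "MAP2K6", 0.427097546, -0.609906763, "blue"),
    ("ZNF282", "AGTPBP1", 0.512056621, -0.592121258, "blue"),
    ("ZDHHC3", "C14orf159", -0.709976288, 0.51884098, "darkred"),
    ("TRMT6", "BTN3A1", -0.57700653, 0.498814377, "darkred"),
    ("TRMT6", "OSCAR", 0.519497637, -0.537521238, "darkred"),
    ("TRMT6", "CA4", 0.564335391, -0.491940678, "darkred"),
    ("TSPO", "TRMT6", 0.570633674, -0.551005684, "darkred"),
    ("ZDHHC19", "UBE2H", 0.584905223, -0.452219991, "darkred"),
    ("ZDHHC19", "TRMT6", 0.586845831, -0.641186062, "darkred"),
    ("SVIP", "CKAP4", 0.603948148, -0.440800517, "darkred"),
    ("SVIP", "CMTM4", 0.632331442, -0.468788719, "darkred"),
    ("ZDHHC3", "IL10", 0.635678135, -0.408650989, "darkred"),
)
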