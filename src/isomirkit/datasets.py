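"""Bundled values from a published breast normal/tumor small-RNA study.

These small tables are the study conditions that the synthetic-data
generator emulates and the inputs to the validation computations:

* ``validation_table`` — 23 miRNAs with sequencing TPM in each library, the
  sequencing (NGS) fold change, and the stem-loop qPCR fold change used to
  validate it.
* ``arm_usage_counts`` — per-hairpin 5p/3p read counts in each library for
  the hairpins whose arm preference was examined.
* ``class_proportions`` — the 10-class composition of clean reads per
  library.
* ``library_stats`` — headline per-library statistics (clean-read totals,
  miRNA fraction, 3'-modification percentage, detection counts).
* ``shift5_law`` / ``shift3_law`` — the isomiR 5'/3' position-shift spectra
  of miRNA reads.
"""

from __future__ import annotations

import io

import pandas as pd

_VALIDATION_TSV = """\
mature_name	tpm_normal	tpm_tumor	ngs_fc	pcr_fc	consistent
has-let-7b	32594.1	16107.1	0.49	0.46	Y
hsa-let-7c	7710.1	2439.1	0.32	0.44	Y
hsa-miR-22	69532.1	24576.1	0.35	0.24	Y
hsa-miR-125b	44624.1	6613.1	0.15	0.37	Y
hsa-miR-143	38419.1	17359.1	0.45	0.14	Y
hsa-miR-144	3548.1	351.1	0.10	0.30	Y
hsa-miR-145	28682.1	6435.1	0.22	0.26	Y
hsa-miR-193a-5p	1836.1	298.1	0.16	0.27	Y
hsa-miR-193b	2469.1	1058.1	0.43	0.30	Y
hsa-miR-199b-5p	1608.1	1055.1	0.66	0.83	Y
hsa-miR-320a	16734.1	3060.1	0.18	0.75	Y
hsa-miR-378	12610.1	1542.1	0.12	0.24	Y
hsa-miR-497	8005.1	2010.1	0.25	0.29	Y
hsa-miR-99a	31360.1	5548.1	0.18	0.16	Y
hsa-miR-141	5007.1	14541.1	2.90	5.88	Y
hsa-miR-375	240.1	2372.1	9.88	37.95	Y
hsa-miR-425	592.1	2529.1	4.27	1.93	Y
hsa-miR-203	197.1	1045.1	5.30	9.80	Y
hsa-miR-342-3p	350.1	1331.1	3.80	3.43	Y
hsa-miR-182	316.1	1653.1	5.23	11.86	Y
hsa-miR-200b	1362.1	4162.1	3.06	12.61	Y
hsa-miR-183	118.1	1067.1	9.04	6.12	Y
hsa-miR-423-3p	2446.1	1993.1	0.81	5.96	N
"""

_ARM_USAGE_TSV = """\
hairpin_id	n5p	n3p	t5p	t3p
hsa-miR-214	88	226	133	171
hsa-miR-576	7	44	19	17
hsa-miR-154	21	8	7	14
hsa-miR-193a	1836	1127	488	2384
hsa-miR-296	24	34	8	4
hsa-miR-361	105	215	1043	310
hsa-miR-324	233	341	317	91
hsa-miR-339	215	217	298	194
hsa-miR-493	2	5	22	9
hsa-miR-455	99	72	107	308
hsa-miR-664	58	8	21	87
hsa-miR-212	22	7	7	6
hsa-miR-142	914	1102	8661	10074
hsa-miR-362	174	34	145	114
hsa-miR-376a-1	41	24	9	13
hsa-miR-382	217	23	51	30
hsa-miR-151	946	1249	2721	3109
"""


def validation_table() -> pd.DataFrame:
    """The 23-miRNA sequencing-vs-qPCR validation table."""
    return pd.read_csv(io.StringIO(_VALIDATION_TSV), sep="\t")


def arm_usage_counts() -> pd.DataFrame:
    """Per-hairpin (5p, 3p) read counts in the normal and tumor libraries."""
    return pd.read_csv(io.StringIO(_ARM_USAGE_TSV), sep="\t")


#: Clean-read composition per library (fractions over the 10 classes).
CLASS_PROPORTIONS = {
    "normal": {
        "miRNA": 0.7524, "mRNA": 0.0216, "tRNA": 0.0047, "rRNA": 0.0087,
        "snoRNA": 0.0084, "scaRNA": 0.0004, "snRNA": 0.0012,
        "other ncRNA": 0.0978, "repeat": 0.000349, "unknown": 0.104451,
    },
    "tumor": {
        "miRNA": 0.8479, "mRNA": 0.0086, "tRNA": 0.0037, "rRNA": 0.0033,
        "snoRNA": 0.0035, "scaRNA": 0.0004, "snRNA": 0.0014,
        "other ncRNA": 0.0640, "repeat": 0.000006, "unknown": 0.067194,
    },
}

#: Headline per-library statistics of the study.
LIBRARY_STATS = {
    "normal": {
        "n_clean_reads": 2_785_848, "pct_mirna_reads": 75.24,
        "n_detected_premirnas": 455, "n_detected_mirnas": 631,
        "n_detected_opposite_arm": 54, "pct_modified": 17.65,
    },
    "tumor": {
        "n_clean_reads": 38_335_412, "pct_mirna_reads": 84.79,
        "n_detected_premirnas": 689, "n_detected_mirnas": 906,
        "n_detected_opposite_arm": 150, "pct_modified": 12.45,
    },
}

#: 5' position-shift spectrum of miRNA reads (fraction of read counts).
SHIFT5_LAW = {-1: 0.01, 0: 0.95, 1: 0.04}

#: 3' position-shift spectrum. Shifts within ±2 carry 97% of reads; the
#: remaining 3% is split over ±3.
SHIFT3_LAW = {-3: 0.015, -2: 0.05, -1: 0.20, 0: 0.56, 1: 0.15, 2: 0.01, 3: 0.015}

#: 3'-tail composition among modification events. A and U together dominate
#: (~80%); the dinucleotides AA/UU/AU and the bases C and G each contribute
#: at least 1%.
TAIL_COMPOSITION = {
    "A": 0.44, "U": 0.36, "AA": 0.05, "UU": 0.04, "AU": 0.03,
    "C": 0.04, "G": 0.03, "other": 0.01,
}

#: Fraction of miRNA reads carrying a 3' nontemplate tail, per library.
TAILING_PROB = {"normal": 0.1765, "tumor": 0.1245}
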