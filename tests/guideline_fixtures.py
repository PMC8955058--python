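"""Frozen guideline facts shared by the unit and acceptance tests.

TABLE1_CELLS freezes the published differences grid between the four
guideline systems, one assertion per printed cell (blank cells are not
asserted; the packaged tables resolve them to ``unknown``). Doses are
absolute mg chosen to hit the stated mg/m² bands at the 1.48 m² reference
BSA. The Japan methotrexate cells follow the dose bands the source text
states operationally (>250 high, 50-250 moderate, <50 low).

TABLE4_REGIMENS expands every named regimen of the per-cancer regimen
examples via its abbreviation key, with the risk column it is printed under.
"""

import datetime as dt

from cinv_audit.regimen import Component, RegimenEpisode
from cinv_audit.risk import Route

# (drug_id, dose_mg, auc, guideline, expected category)
TABLE1_CELLS = [
    ("carboplatin", None, None, "JSCO", "moderate"),
    ("carboplatin", None, None, "ASCO", "moderate"),
    ("carboplatin", None, None, "MASCC", "moderate"),
    ("carboplatin", None, 5.0, "NCCN", "high"),
    ("carboplatin", None, 3.9, "NCCN", "moderate"),
    ("doxorubicin", 50, None, "JSCO", "moderate"),
    ("doxorubicin", 74, None, "JSCO", "moderate"),
    ("doxorubicin", 50, None, "ASCO", "moderate"),
    ("doxorubicin", 50, None, "MASCC", "moderate"),
    ("doxorubicin", 60, None, "NCCN", "high"),
    ("doxorubicin", 74, None, "NCCN", "high"),
    ("epirubicin", 88, None, "JSCO", "moderate"),
    ("epirubicin", 88, None, "ASCO", "moderate"),
    ("epirubicin", 88, None, "MASCC", "moderate"),
    ("epirubicin", 91, None, "NCCN", "high"),
    ("ifosfamide", 2000, None, "JSCO", "moderate"),
    ("ifosfamide", 2000, None, "ASCO", "moderate"),
    ("ifosfamide", 2000, None, "MASCC", "moderate"),
    ("ifosfamide", 2960, None, "NCCN", "high"),   # 2000 mg/m² per dose
    ("cytarabine", 444, None, "JSCO", "moderate"),   # 300 mg/m² > 200
    ("cytarabine", 444, None, "NCCN", "moderate"),
    ("cytarabine", 1776, None, "ASCO", "moderate"),  # 1200 mg/m² > 1000
    ("cytarabine", 1776, None, "MASCC", "moderate"),
    ("methotrexate", 444, None, "JSCO", "high"),     # 300 mg/m² > 250
    ("methotrexate", 444, None, "NCCN", "moderate"),
    ("methotrexate", 148, None, "JSCO", "moderate"),  # 100 mg/m² in 50-250
    ("methotrexate", 148, None, "NCCN", "low"),
    ("methotrexate", 444, None, "ASCO", "low"),
    ("methotrexate", 444, None, "MASCC", "low"),
    ("bortezomib", None, None, "ASCO", "low"),
    ("bortezomib", None, None, "MASCC", "low"),
    ("bortezomib", None, None, "JSCO", "minimal"),
    ("bortezomib", None, None, "NCCN", "minimal"),
    ("cetuximab", None, None, "ASCO", "low"),
    ("cetuximab", None, None, "MASCC", "low"),
    ("cetuximab", None, None, "JSCO", "minimal"),
    ("cetuximab", None, None, "NCCN", "minimal"),
    ("nelarabine", None, None, "ASCO", "low"),
    ("nelarabine", None, None, "JSCO", "minimal"),
    ("nelarabine", None, None, "NCCN", "minimal"),
    ("panitumumab", None, None, "ASCO", "low"),
    ("panitumumab", None, None, "MASCC", "low"),
    ("panitumumab", None, None, "JSCO", "minimal"),
    ("panitumumab", None, None, "NCCN", "minimal"),
    ("pertuzumab", None, None, "ASCO", "low"),
    ("pertuzumab", None, None, "JSCO", "minimal"),
    ("pertuzumab", None, None, "NCCN", "minimal"),
    # blank cells resolve to unknown rather than an inferred category
    ("nelarabine", None, None, "MASCC", "unknown"),
    ("pertuzumab", None, None, "MASCC", "unknown"),
]


def episode(cancer_type, components):
    """Build a RegimenEpisode from (drug, route, dose) triples."""
    comps = tuple(Component(drug, Route(route), dose)
                  for drug, route, dose in components)
    return RegimenEpisode("test", dt.date(2016, 1, 1), comps, cancer_type)


# (cancer_type, regimen label, components, printed risk column)
TABLE4_REGIMENS = [
    ("non_small_cell_lung", "CDDP+pemetrexed",
     [("cisplatin", "IV", 111), ("pemetrexed", "IV", 740)], "high"),
    ("non_small_cell_lung", "NP",
     [("cisplatin", "IV", 118), ("vinorelbine", "IV", 37)], "high"),
    ("non_small_cell_lung", "TC",
     [("carboplatin", "IV", 600), ("paclitaxel", "IV", 296)], "moderate"),
    ("non_small_cell_lung", "UFT", [("tegafur-uracil", "PO", 400)], "low"),
    ("non_small_cell_lung", "pemetrexed", [("pemetrexed", "IV", 740)], "low"),
    ("non_small_cell_lung", "gefitinib", [("gefitinib", "PO", 250)], "minimal"),
    ("non_small_cell_lung", "erlotinib", [("erlotinib", "PO", 150)], "minimal"),
    ("colorectal", "FOLFOXIRI",
     [("fluorouracil", "IV", 2368), ("levofolinate", "IV", 296),
      ("oxaliplatin", "IV", 125), ("irinotecan", "IV", 244)], "high"),
    ("colorectal", "CAPOX",
     [("capecitabine", "PO", 2960), ("oxaliplatin", "IV", 192)], "moderate"),
    ("colorectal", "FOLFOX",
     [("fluorouracil", "IV", 2960), ("levofolinate", "IV", 296),
      ("oxaliplatin", "IV", 125)], "moderate"),
    ("colorectal", "capecitabine", [("capecitabine", "PO", 2960)], "low"),
    ("colorectal", "UFT+LV",
     [("tegafur-uracil", "PO", 400), ("folinate", "PO", 75)], "low"),
    ("colorectal", "panitumumab", [("panitumumab", "IV", 888)], "minimal"),
    ("colorectal", "regorafenib", [("regorafenib", "PO", 160)], "minimal"),
    ("breast", "FEC",
     [("fluorouracil", "IV", 740), ("epirubicin", "IV", 148),
      ("cyclophosphamide", "IV", 888)], "high"),
    ("breast", "EC",
     [("epirubicin", "IV", 133), ("cyclophosphamide", "IV", 888)], "high"),
    ("breast", "AC",
     [("doxorubicin", "IV", 89), ("cyclophosphamide", "IV", 888)], "high"),
    ("breast", "TC-breast",
     [("docetaxel", "IV", 111), ("cyclophosphamide", "IV", 1110)], "moderate"),
    ("breast", "PTX", [("paclitaxel", "IV", 133)], "low"),
    ("breast", "trastuzumab+PTX",
     [("trastuzumab", "IV", 296), ("paclitaxel", "IV", 133)], "low"),
    ("breast", "DTX", [("docetaxel", "IV", 111)], "low"),
    ("breast", "trastuzumab", [("trastuzumab", "IV", 296)], "minimal"),
    ("gastric", "S-1+CDDP",
     [("s-1", "PO", 120), ("cisplatin", "IV", 89)], "high"),
    ("gastric", "Cape+CDDP",
     [("capecitabine", "PO", 2960), ("cisplatin", "IV", 118)], "high"),
    ("gastric", "SOX",
     [("s-1", "PO", 120), ("oxaliplatin", "IV", 192)], "moderate"),
    ("gastric", "S-1", [("s-1", "PO", 120)], "low"),
    ("gastric", "nivolumab", [("nivolumab", "IV", 240)], "minimal"),
    ("gastric", "ramucirumab", [("ramucirumab", "IV", 473)], "minimal"),
    # prednisolone in CHOP arrives as a steroid claim, never as a regimen
    # component, so the cytotoxic trio carries the classification
    ("malignant_lymphoma", "CHOP",
     [("cyclophosphamide", "IV", 1110), ("doxorubicin", "IV", 74),
      ("vincristine", "IV", 2)], "high"),
    ("malignant_lymphoma", "CPM<1500",
     [("cyclophosphamide", "IV", 1110)], "moderate"),
    ("pancreatic", "FOLFIRINOX",
     [("oxaliplatin", "IV", 125), ("irinotecan", "IV", 266),
      ("fluorouracil", "IV", 2960), ("levofolinate", "IV", 296)], "high"),
    ("pancreatic", "GEM+nab-PTX",
     [("gemcitabine", "IV", 1480), ("nab-paclitaxel", "IV", 185)], "moderate"),
    ("pancreatic", "S-1", [("s-1", "PO", 120)], "low"),
    ("pancreatic", "GEM", [("gemcitabine", "IV", 1480)], "low"),
    ("oesophageal", "FP",
     [("fluorouracil", "IV", 1184), ("cisplatin", "IV", 118)], "high"),
    ("oesophageal", "DCF",
     [("docetaxel", "IV", 104), ("cisplatin", "IV", 104),
      ("fluorouracil", "IV", 1110)], "high"),
    ("oesophageal", "nedaplatin+5-FU",
     [("nedaplatin", "IV", 133), ("fluorouracil", "IV", 1184)], "moderate"),
    ("oesophageal", "DTX", [("docetaxel", "IV", 104)], "low"),
    ("small_cell_lung", "PE",
     [("cisplatin", "IV", 118), ("etoposide", "IV", 148)], "high"),
    ("small_cell_lung", "PI",
     [("cisplatin", "IV", 89), ("irinotecan", "IV", 89)], "high"),
    ("small_cell_lung", "CBDCA+etoposide",
     [("carboplatin", "IV", 625), ("etoposide", "IV", 148)], "moderate"),
    ("small_cell_lung", "CBDCA+CPT11",
     [("carboplatin", "IV", 625), ("irinotecan", "IV", 89)], "moderate"),
    ("small_cell_lung", "CPT11", [("irinotecan", "IV", 148)], "low"),
]
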