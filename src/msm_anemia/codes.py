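"""Default ICD-10 code maps: Quan Charlson categories and CV-event codes.

The Charlson map uses the Quan et al. ICD-10 coding algorithms with the
original Charlson weights.  Codes are stored as dot-free prefixes; claim
codes are normalized (dots stripped, upper-cased) before prefix matching.
The shipped map is an illustrative default -- real analyses supply their own
JSON map ``{category: {"codes": [...], "weight": int}}``.
"""

from __future__ import annotations

import json
from typing import Dict, List


def _span(prefix: str, lo: int, hi: int) -> List[str]:
    return [f"{prefix}{i:02d}" for i in range(lo, hi + 1)]


CCI_CODE_MAP: Dict[str, dict] = {
    "mi": {"codes": ["I21", "I22", "I252"], "weight": 1},
    "chf": {
        "codes": ["I099", "I110", "I130", "I132", "I255", "I420", "I425",
                  "I426", "I427", "I428", "I429", "I43", "I50", "P290"],
        "weight": 1,
    },
    "pvd": {
        "codes": ["I70", "I71", "I731", "I738", "I739", "I771", "I790",
                  "I792", "K551", "K558", "K559", "Z958", "Z959"],
        "weight": 1,
    },
    "cvd": {"codes": ["G45", "G46", "H340"] + _span("I", 60, 69), "weight": 1},
    "dementia": {"codes": _span("F", 0, 3) + ["F051", "G30", "G311"], "weight": 1},
    "cpd": {
        "codes": ["I278", "I279"] + _span("J", 40, 47) + _span("J", 60, 67)
        + ["J684", "J701", "J703"],
        "weight": 1,
    },
    "rheumatic": {
        "codes": ["M05", "M06", "M315", "M32", "M33", "M34", "M351", "M353",
                  "M360"],
        "weight": 1,
    },
    "pud": {"codes": _span("K", 25, 28), "weight": 1},
    "mild_liver": {
        "codes": ["B18", "K700", "K701", "K702", "K703", "K709", "K713",
                  "K714", "K715", "K717", "K73", "K74", "K760", "K762",
                  "K763", "K764", "K768", "K769", "Z944"],
        "weight": 1,
    },
    "diabetes_uncomplicated": {
        "codes": [f"E{b}{s}" for b in (10, 11, 12, 13, 14)
                  for s in (0, 1, 6, 8, 9)],
        "weight": 1,
    },
    "diabetes_complicated": {
        "codes": [f"E{b}{s}" for b in (10, 11, 12, 13, 14)
                  for s in (2, 3, 4, 5, 7)],
        "weight": 2,
    },
    "hemiplegia": {
        "codes": ["G041", "G114", "G801", "G802", "G81", "G82", "G830",
                  "G831", "G832", "G833", "G834", "G839"],
        "weight": 2,
    },
    "renal_disease": {
        "codes": ["I120", "I131", "N032", "N033", "N034", "N035", "N036",
                  "N037", "N052", "N053", "N054", "N055", "N056", "N057",
                  "N18", "N19", "N250", "Z490", "Z491", "Z492", "Z940",
                  "Z992"],
        "weight": 2,
    },
    "malignancy": {
        "codes": _span("C", 0, 26) + _span("C", 30, 34) + _span("C", 37, 41)
        + ["C43"] + _span("C", 45, 58) + _span("C", 60, 76)
        + _span("C", 81, 85) + ["C88", "C90", "C91", "C92", "C93", "C94",
                                "C95", "C96", "C97"],
        "weight": 2,
    },
    "mod_sev_liver": {
        "codes": ["I850", "I859", "I864", "I982", "K704", "K711", "K721",
                  "K729", "K765", "K766", "K767"],
        "weight": 3,
    },
    "metastatic": {"codes": _span("C", 77, 80), "weight": 6},
    "aids": {"codes": _span("B", 20, 24), "weight": 6},
}

# Higher-severity category supersedes its milder counterpart.
CCI_HIERARCHY = {
    "diabetes_uncomplicated": "diabetes_complicated",
    "malignancy": "metastatic",
    "mild_liver": "mod_sev_liver",
}

# Categories defining a history of cardiovascular disease.
CV_HISTORY_CATEGORIES = ("mi", "chf", "pvd", "cvd")

# Composite cardiovascular endpoint components.
CV_EVENT_CODE_MAP: Dict[str, List[str]] = {
    "unstable_angina": ["I200"],
    "mi": ["I21", "I22"],
    "heart_failure": ["I50"],
    "cerebrovascular": ["I60", "I61", "I62", "I63", "I64"],
}

DIABETES_CATEGORIES = ("diabetes_uncomplicated", "diabetes_complicated")
ANTIDIABETIC_CODES = ("sglt2i", "glp", "other_antidiabetic", "insulin")


def normalize_icd(codes) -> "pd.Series":
    import pandas as pd

    return pd.Series(codes).astype(str).str.replace(".", "", regex=False).str.upper()


def load_code_map(path=None) -> Dict[str, dict]:
    """Load a CCI code map from JSON, or return the shipped default."""
    if path is None:
        return CCI_CODE_MAP
    with open(path) as fh:
        raw = json.load(fh)
    for cat, entry in raw.items():
        if not isinstance(entry, dict) or "codes" not in entry or "weight" not in entry:
            raise ValueError(f"malformed code_map entry for {cat!r}")
    return raw


def dump_default_code_map(path) -> None:
    with open(path, "w") as fh:
        json.dump(CCI_CODE_MAP, fh, indent=1)
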