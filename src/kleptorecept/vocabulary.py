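"""Mapping from Pfam family names to the canonical domain labels used in
arrangement strings and classification rules.

The receptor classes are defined over *concepts* (CTLD, SRCR, CD36, TSP1, ...)
rather than individual Pfam families, so the mapping is data, not code: it can
be replaced or extended from a YAML file.  Unmapped Pfam names pass through
unchanged and simply never match any rule.
"""

from __future__ import annotations

from pathlib import Path

import yaml

# canonical label constants (values appear verbatim in arrangement strings)
TM = "TM"
CD36 = "CD36"
CTLD = "CTLD"
SRCR = "SRCR"
TSP1 = "TSP1"
TSP3 = "TSP3"
EGF = "EGF"
COLLAGEN = "Collagen"
SEMA = "SEMA"
PSI = "PSI"
PLAC = "PLAC"
ADAMTS_SPACER = "ADAMTS-spacer"
ADAM_MP = "ADAM-MP"
L_LECTIN = "L-lectin"

#: Pfam family name -> canonical label.  Keys follow Pfam-A nomenclature;
#: a handful of aliases let pre-canonicalized inputs round-trip.
DEFAULT_VOCABULARY: dict[str, str] = {
    "CD36": CD36,
    "Lectin_C": CTLD,
    "CTLD": CTLD,
    "SRCR": SRCR,
    "SRCR_2": SRCR,
    "TSP_1": TSP1,
    "TSP1": TSP1,
    "TSP_3": TSP3,
    "TSP3": TSP3,
    "EGF": EGF,
    "EGF_CA": EGF,
    "cEGF": EGF,
    "Collagen": COLLAGEN,
    "Sema": SEMA,
    "SEMA": SEMA,
    "PSI": PSI,
    "PLAC": PLAC,
    "Plac": PLAC,
    "ADAM_spacer1": ADAMTS_SPACER,
    "ADAMTS-spacer": ADAMTS_SPACER,
    "Reprolysin": ADAM_MP,
    "Pep_M12B_propep": ADAM_MP,
    "ADAM_CR": ADAM_MP,
    "ADAM-MP": ADAM_MP,
    "TSP_C": L_LECTIN,
    "Lectin_leg": L_LECTIN,
    "L-lectin": L_LECTIN,
    # pass-through renames for families that appear in mixed TSR arrangements
    "V-set": "Ig",
    "Ig_2": "Ig",
    "I-set": "I-set",
    "VWA": "VWA",
    "Ldl_recept_a": "LDL",
    "CUB": "CUB",
    "UNC-5": "UNC-5",
    "Kunitz_BPTI": "Kunitz-BPTI",
    "LRR_8": "LRR8",
}


def canonical_label(domain_name: str, vocabulary: dict[str, str] | None = None) -> str:
    """Map a Pfam family name to its canonical label (identity if unmapped)."""
    vocab = DEFAULT_VOCABULARY if vocabulary is None else vocabulary
    return vocab.get(domain_name, domain_name)


def load_vocabulary(path: str | Path) -> dict[str, str]:
    """Load a Pfam-name -> canonical-label mapping from YAML."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: vocabulary YAML must be a flat mapping")
    return {str(k): str(v) for k, v in data.items()}


def save_vocabulary(vocabulary: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(vocabulary, fh, sort_keys=True)
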