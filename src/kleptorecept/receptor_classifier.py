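"""Rule-based assignment of domain architectures to scavenger-receptor (SR)
classes and thrombospondin-type-1-repeat (TSR) families.

SR classes follow the standard nomenclature: SR-A is a membrane receptor with
a collagenous stalk and a C-terminal SRCR domain; SR-B exposes a CD36
extracellular loop anchored by a transmembrane helix on each side; SR-E-like
carries a single C-type lectin domain (CTLD) plus a single TM (the "-like"
suffix is kept because scavenger activity can only be shown experimentally); SR-I has
multiple SRCR domains plus a TM.  Remaining CTLD+TM proteins are generic
C-type lectins and remaining SRCR proteins are SRCR members.

TSR families: thrombospondin-5/COMP-like proteins (EGF + type-3 repeats +
C-terminal L-type lectin domain), ADAMTS(-like) proteases (metalloproteinase
or ADAMTS-spacer evidence with TSP1 repeats, or TSP1 repeats with a PLAC
domain), semaphorins/plexins (Sema domain), properdin-like TSP1-only
proteins without TM (TSR_noTM), TSP1-only proteins with TM (TSR_withTM), and
TSP1 domains mixed with other domains (TSR_other).

Rules are evaluated in a fixed, documented order; the first match wins
(SR rules before TSR rules, specific before generic).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .architecture import ArchitectureElement, DomainArchitecture
from . import vocabulary as V

CATEGORIES = (
    "SR_A",
    "SR_B",
    "SR_E_like",
    "SR_I",
    "C_type_lectin",
    "SRCR_member",
    "TSP_COMP",
    "ADAMTS_like",
    "semaphorin_plexin",
    "TSR_withTM",
    "TSR_noTM",
    "TSR_other",
    "unclassified",
)


@dataclass(frozen=True)
class ReceptorAssignment:
    protein_id: str
    category: str
    matched_rule: str
    arrangement_string: str


@dataclass(frozen=True)
class Rule:
    category: str
    name: str
    predicate: Callable[[DomainArchitecture], str | None]
    """Returns a match description (truthy) or None."""


def _pfam(arch: DomainArchitecture) -> list[ArchitectureElement]:
    return [e for e in arch.elements if e.kind == "pfam_domain"]


def _tms(arch: DomainArchitecture) -> list[ArchitectureElement]:
    return [e for e in arch.elements if e.kind == "tm"]


def _counts(arch: DomainArchitecture) -> Counter:
    return Counter(e.label for e in _pfam(arch))


def _sr_a(arch: DomainArchitecture) -> str | None:
    pfam = _pfam(arch)
    if not pfam or not _tms(arch):
        return None
    has_collagen = any(e.label == V.COLLAGEN for e in pfam)
    c_terminal = max(pfam, key=lambda e: e.end)
    if has_collagen and c_terminal.label == V.SRCR:
        return "TM + collagen stalk + C-terminal SRCR"
    return None


def _sr_b(arch: DomainArchitecture) -> str | None:
    pfam = _pfam(arch)
    tms = _tms(arch)
    for cd36 in (e for e in pfam if e.label == V.CD36):
        left_ok = any(
            t.end < cd36.start
            and not any(
                p is not cd36 and p.start > t.end and p.end < cd36.start for p in pfam
            )
            for t in tms
        )
        right_ok = any(
            t.start > cd36.end
            and not any(
                p is not cd36 and p.start > cd36.end and p.end < t.start for p in pfam
            )
            for t in tms
        )
        if left_ok and right_ok:
            return "CD36 loop flanked by two TMs"
    return None


def _sr_e_like(arch: DomainArchitecture) -> str | None:
    # exactly one CTLD with exactly one TM: proteins whose single CTLD is
    # flanked by two TMs are classed as generic C-type lectins instead
    if _counts(arch)[V.CTLD] == 1 and len(_tms(arch)) == 1:
        return "single CTLD with single TM"
    return None


def _sr_i(arch: DomainArchitecture) -> str | None:
    if _counts(arch)[V.SRCR] >= 2 and _tms(arch):
        return "multiple SRCR domains with TM"
    return None


def _c_type_lectin(arch: DomainArchitecture) -> str | None:
    if _counts(arch)[V.CTLD] >= 1 and _tms(arch):
        return "CTLD(s) with TM, not SR-E-like"
    return None


def _srcr_member(arch: DomainArchitecture) -> str | None:
    if _counts(arch)[V.SRCR] >= 1:
        return "SRCR domain(s), not assignable to an SR class"
    return None


def _tsp_comp(arch: DomainArchitecture) -> str | None:
    counts = _counts(arch)
    pfam = _pfam(arch)
    if not pfam:
        return None
    if counts[V.TSP3] < 1:
        return None
    if counts[V.TSP1] < 1 and counts[V.EGF] < 1:
        return None
    c_terminal = max(pfam, key=lambda e: e.end)
    if c_terminal.label == V.L_LECTIN:
        return "EGF/TSP1 region + TSP3 repeats + C-terminal lectin-like domain"
    return None


def _adamts_like(arch: DomainArchitecture) -> str | None:
    counts = _counts(arch)
    has_core = counts[V.ADAMTS_SPACER] >= 1 or counts[V.ADAM_MP] >= 1
    if has_core and counts[V.TSP1] >= 1:
        return "ADAMTS spacer/metalloproteinase with TSP1 repeat(s)"
    if counts[V.TSP1] >= 1 and counts[V.PLAC] >= 1:
        return "TSP1 repeats with PLAC domain"
    if counts[V.ADAMTS_SPACER] >= 1:
        return "ADAMTS spacer (no TSP1)"
    return None


def _semaphorin_plexin(arch: DomainArchitecture) -> str | None:
    if _counts(arch)[V.SEMA] >= 1:
        return "Sema domain present"
    return None


def _tsp1_only(arch: DomainArchitecture) -> bool:
    counts = _counts(arch)
    return counts[V.TSP1] >= 1 and set(counts) == {V.TSP1}


def _tsr_with_tm(arch: DomainArchitecture) -> str | None:
    if _tsp1_only(arch) and _tms(arch):
        return "only TSP1 domains, with TM"
    return None


def _tsr_no_tm(arch: DomainArchitecture) -> str | None:
    if _tsp1_only(arch) and not _tms(arch):
        return "only TSP1 domains, no TM (properdin-like)"
    return None


def _tsr_other(arch: DomainArchitecture) -> str | None:
    if _counts(arch)[V.TSP1] >= 1:
        return "TSP1 domain(s) mixed with other domains"
    return None


#: Evaluation order is part of the contract: first match wins.
DEFAULT_RULESET: tuple[Rule, ...] = (
    Rule("SR_A", "SR-A", _sr_a),
    Rule("SR_B", "SR-B", _sr_b),
    Rule("SR_E_like", "SR-E-like", _sr_e_like),
    Rule("SR_I", "SR-I", _sr_i),
    Rule("C_type_lectin", "C-type lectin", _c_type_lectin),
    Rule("SRCR_member", "SRCR member", _srcr_member),
    Rule("TSP_COMP", "TSP-5/COMP", _tsp_comp),
    Rule("ADAMTS_like", "ADAMTS-like", _adamts_like),
    Rule("semaphorin_plexin", "semaphorin/plexin", _semaphorin_plexin),
    Rule("TSR_withTM", "TSR + TM", _tsr_with_tm),
    Rule("TSR_noTM", "TSR - TM", _tsr_no_tm),
    Rule("TSR_other", "TSR other", _tsr_other),
)

SR_CATEGORIES = frozenset(
    {"SR_A", "SR_B", "SR_E_like", "SR_I", "C_type_lectin", "SRCR_member"}
)
TSR_CATEGORIES = frozenset(
    {"TSP_COMP", "ADAMTS_like", "semaphorin_plexin", "TSR_withTM", "TSR_noTM", "TSR_other"}
)


def classify(
    arch: DomainArchitecture, rules: Sequence[Rule] = DEFAULT_RULESET
) -> ReceptorAssignment:
    """Assign one architecture to the first matching category."""
    for rule in rules:
        match = rule.predicate(arch)
        if match:
            return ReceptorAssignment(
                protein_id=arch.protein_id,
                category=rule.category,
                matched_rule=f"{rule.name}: {match}",
                arrangement_string=arch.arrangement_string,
            )
    return ReceptorAssignment(
        protein_id=arch.protein_id,
        category="unclassified",
        matched_rule="",
        arrangement_string=arch.arrangement_string,
    )


def classify_all(
    archs: Iterable[DomainArchitecture], rules: Sequence[Rule] = DEFAULT_RULESET
) -> tuple[list[ReceptorAssignment], pd.DataFrame]:
    """Classify every architecture; also return a category count table.

    The count table partitions the input: counts sum to the number of
    architectures.
    """
    assignments = [classify(a, rules) for a in archs]
    counts = Counter(a.category for a in assignments)
    table = pd.DataFrame(
        [{"category": c, "n": counts.get(c, 0)} for c in CATEGORIES if counts.get(c, 0)],
        columns=["category", "n"],
    )
    return assignments, table


def write_assignments(assignments: Iterable[ReceptorAssignment], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "protein_id": a.protein_id,
                "category": a.category,
                "matched_rule": a.matched_rule,
                "arrangement": a.arrangement_string,
            }
            for a in assignments
        ]
    ).to_csv(path, sep="\t", index=False)


def classify_arrangement_string(
    arrangement: str, protein_length: int = 1000, with_lengths: dict | None = None
) -> str:
    """Classify a bare arrangement string like ``"TM + CD36 + TM"``.

    Convenience for curated tables where only the arrangement is known:
    elements are laid out left to right with nominal extents, so positional
    clauses (C-terminal SRCR, TM flanking) follow the written order.
    """
    from .architecture import ArchitectureElement, DomainArchitecture

    labels = [s.strip() for s in arrangement.split("+") if s.strip()]
    elements = []
    pos = 1
    for lab in labels:
        canon = V.canonical_label(lab)
        span = 21 if canon == V.TM else 60
        kind = "tm" if canon == V.TM else "pfam_domain"
        elements.append(
            ArchitectureElement(kind=kind, label=canon, start=pos, end=pos + span - 1)
        )
        pos += span + 5
    arch = DomainArchitecture(
        protein_id="?", protein_length=max(protein_length, pos), elements=tuple(elements)
    )
    return classify(arch).category
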