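"""Build ordered, non-overlapping domain architectures per protein.

A protein's architecture is the ascending-start sequence of its surviving
Pfam domain envelopes and transmembrane helices, rendered as an arrangement
string such as ``"TM + CD36 + TM"``.  Two filters gate entry: proteins
shorter than 150 aa are discarded, and domain hits with independent E-value
above 1e-5 are dropped (both configurable via
:class:`~kleptorecept.annotation_io.PipelineConfig`).

Overlapping Pfam hits are reconciled greedily: hits are ranked by
(i-E-value, -bit score, start) and admitted while their overlap with every
already-admitted hit stays at or below ``max_overlap_frac`` of the shorter
hit.  TM helices are never discarded by this resolution, but a helix buried
inside a retained Pfam domain (overlap > 50% of the helix) is suppressed in
the arrangement string — a TM inside a domain is topology, not arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotation_io import DomainHit, PipelineConfig, ProteinRecord, TMRegion
from .vocabulary import TM as TM_LABEL
from .vocabulary import canonical_label


class ArchitectureError(ValueError):
    """Raised when hits or TM regions are inconsistent with their protein."""


@dataclass(frozen=True)
class ArchitectureElement:
    kind: str  # "pfam_domain" | "tm"
    label: str  # canonical domain label or "TM"
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ArchitectureError(f"element {self.label}: start > end")
        if self.kind not in ("pfam_domain", "tm"):
            raise ArchitectureError(f"unknown element kind {self.kind!r}")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainArchitecture:
    protein_id: str
    protein_length: int
    elements: tuple[ArchitectureElement, ...]

    @property
    def arrangement_string(self) -> str:
        return " + ".join(e.label for e in self.elements)

    def labels(self, kind: str | None = None) -> list[str]:
        return [e.label for e in self.elements if kind is None or e.kind == kind]


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def resolve_overlaps(
    hits: Sequence[DomainHit], max_overlap_frac: float = 0.25
) -> list[DomainHit]:
    """Greedy reconciliation of overlapping Pfam hits on one protein.

    Hits are sorted by (i-E-value, -bit score, start) and admitted in order;
    a hit is rejected if it overlaps any admitted hit by more than
    *max_overlap_frac* of the shorter of the two.  Returned hits are in
    admission order re-sorted by start.
    """
    if len({h.protein_id for h in hits}) > 1:
        raise ArchitectureError("resolve_overlaps expects hits from a single protein")
    ranked = sorted(hits, key=lambda h: (h.i_evalue, -h.bit_score, h.start))
    admitted: list[DomainHit] = []
    for hit in ranked:
        ok = True
        for kept in admitted:
            ov = _overlap(hit.start, hit.end, kept.start, kept.end)
            if ov > max_overlap_frac * min(hit.span, kept.span):
                ok = False
                break
        if ok:
            admitted.append(hit)
    admitted.sort(key=lambda h: (h.start, h.end, h.domain_name))
    return admitted


def build_architecture(
    protein: ProteinRecord,
    hits: Sequence[DomainHit],
    tms: Sequence[TMRegion],
    config: PipelineConfig | None = None,
    vocabulary: dict[str, str] | None = None,
) -> DomainArchitecture | None:
    """Assemble one protein's architecture, or ``None`` if it fails the
    minimum-length filter.

    Hits above the i-E-value threshold are dropped before overlap
    resolution; elements exceeding the protein length are hard errors.
    """
    config = config or PipelineConfig()
    if protein.length < config.min_protein_length:
        return None
    for h in hits:
        if h.protein_id != protein.id:
            raise ArchitectureError(
                f"hit on {h.protein_id} passed with protein {protein.id}"
            )
        if h.end > protein.length:
            raise ArchitectureError(
                f"hit {h.domain_name} ends at {h.end} beyond protein "
                f"{protein.id} length {protein.length}"
            )
    for t in tms:
        if t.protein_id != protein.id:
            raise ArchitectureError(
                f"TM on {t.protein_id} passed with protein {protein.id}"
            )
        if t.end > protein.length:
            raise ArchitectureError(
                f"TM ends at {t.end} beyond protein {protein.id} length "
                f"{protein.length}"
            )
    surviving = [h for h in hits if h.i_evalue <= config.domain_ievalue_max]
    resolved = resolve_overlaps(surviving, config.max_overlap_frac)

    elements = [
        ArchitectureElement(
            kind="pfam_domain",
            label=canonical_label(h.domain_name, vocabulary),
            start=h.start,
            end=h.end,
        )
        for h in resolved
    ]
    for t in sorted(tms, key=lambda r: r.start):
        buried = any(
            _overlap(t.start, t.end, h.start, h.end) > 0.5 * t.span for h in resolved
        )
        if not buried:
            elements.append(
                ArchitectureElement(kind="tm", label=TM_LABEL, start=t.start, end=t.end)
            )
    elements.sort(key=lambda e: (e.start, e.end, e.label))
    return DomainArchitecture(
        protein_id=protein.id,
        protein_length=protein.length,
        elements=tuple(elements),
    )


def build_architectures(
    proteins: Sequence[ProteinRecord],
    hits: Sequence[DomainHit],
    tms: Sequence[TMRegion],
    config: PipelineConfig | None = None,
    vocabulary: dict[str, str] | None = None,
) -> list[DomainArchitecture]:
    """Vector form of :func:`build_architecture` over a whole proteome.

    Proteins referenced by hits or TM regions but absent from the FASTA set
    are a hard error.
    """
    by_id = {p.id: p for p in proteins}
    unknown = {h.protein_id for h in hits} - by_id.keys()
    unknown |= {t.protein_id for t in tms} - by_id.keys()
    if unknown:
        raise ArchitectureError(
            f"hits/TM regions reference proteins absent from the FASTA: "
            f"{sorted(unknown)[:5]}"
        )
    hits_by: dict[str, list[DomainHit]] = {}
    for h in hits:
        hits_by.setdefault(h.protein_id, []).append(h)
    tms_by: dict[str, list[TMRegion]] = {}
    for t in tms:
        tms_by.setdefault(t.protein_id, []).append(t)
    archs = []
    for p in proteins:
        arch = build_architecture(
            p, hits_by.get(p.id, []), tms_by.get(p.id, []), config, vocabulary
        )
        if arch is not None:
            archs.append(arch)
    return archs


def summarize_architectures(
    archs: Iterable[DomainArchitecture], max_examples: int = 3
) -> pd.DataFrame:
    """One row per distinct arrangement string: (arrangement, n, examples)."""
    groups: dict[str, list[str]] = {}
    for arch in archs:
        groups.setdefault(arch.arrangement_string, []).append(arch.protein_id)
    rows = [
        {
            "arrangement": arr,
            "n": len(ids),
            "examples": ",".join(ids[:max_examples]),
        }
        for arr, ids in groups.items()
    ]
    df = pd.DataFrame(rows, columns=["arrangement", "n", "examples"])
    if not df.empty:
        df = df.sort_values(["n", "arrangement"], ascending=[False, True]).reset_index(
            drop=True
        )
    return df


def write_summary(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
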