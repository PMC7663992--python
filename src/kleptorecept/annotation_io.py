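"""Readers and filters for the annotation artifacts the pipeline consumes.

The pipeline never runs the upstream tools (CD-HIT, TransDecoder, BLASTP,
HMMER, TMHMM); it parses their standard text outputs:

* protein FASTA (one record per translated ORF),
* HMMER3 per-domain tabular output (``--domtblout``, hmmscan orientation:
  target = Pfam family, query = protein),
* TMHMM transmembrane-topology predictions (long ``TMhelix`` rows or the
  one-line ``Topology=`` summary; dialect auto-detected),
* 12/13-column tabular BLAST (outfmt-6 style) joined to a two-column
  subject-accession -> taxon-group map.

All coordinates are 1-based inclusive amino-acid positions, matching the
conventions of the emitting tools.  Domain extents are taken from the
*envelope* columns of the domtblout table, not the alignment columns:
envelopes are wider and are what arrangement adjacency should see.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

# 20 standard residues plus X for ambiguity; '*' stops are rejected so that
# translated ORFs must be stripped before entering the pipeline.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation inputs."""


@dataclass(frozen=True)
class ProteinRecord:
    """A translated protein sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise AnnotationError(f"protein {self.id!r} has an empty sequence")
        bad = set(self.sequence.upper()) - _VALID_RESIDUES
        if bad:
            raise AnnotationError(
                f"protein {self.id!r} contains non-amino-acid symbols: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    """One Pfam domain hit on one protein (envelope coordinates, 1-based)."""

    protein_id: str
    domain_name: str
    accession: str
    i_evalue: float
    start: int
    end: int
    bit_score: float

    def __post_init__(self) -> None:
        if self.i_evalue <= 0 or not math.isfinite(self.i_evalue):
            raise AnnotationError(
                f"domain hit {self.domain_name} on {self.protein_id}: "
                f"i-E-value must be positive, got {self.i_evalue}"
            )
        if not (1 <= self.start <= self.end):
            raise AnnotationError(
                f"domain hit {self.domain_name} on {self.protein_id}: "
                f"bad envelope coordinates {self.start}..{self.end}"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TMRegion:
    """One predicted transmembrane helix (1-based inclusive)."""

    protein_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise AnnotationError(
                f"TM region on {self.protein_id}: bad coordinates "
                f"{self.start}..{self.end}"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AnnotationRecord:
    """One homology annotation (BLAST hit joined to a taxon group)."""

    protein_id: str
    subject_id: str
    description: str
    evalue: float
    taxon_group: str  # "metazoa" | "non_metazoa" | "unknown"

    def __post_init__(self) -> None:
        if self.evalue <= 0 or not math.isfinite(self.evalue):
            raise AnnotationError(
                f"annotation of {self.protein_id}: E-value must be positive"
            )
        if self.taxon_group not in ("metazoa", "non_metazoa", "unknown"):
            raise AnnotationError(
                f"annotation of {self.protein_id}: unknown taxon group "
                f"{self.taxon_group!r}"
            )


@dataclass
class PipelineConfig:
    """All numeric thresholds of the pipeline in one place.

    Defaults are the study conditions: homology annotations at BLAST
    E-value <= 1e-10 restricted to Metazoa; domain hits at independent
    E-value <= 1e-5 on proteins of >= 150 aa; expression candidates from
    genes with >= 100 raw counts in >= 2 samples and |log2 fold change| > 1.
    """

    blast_evalue_max: float = 1e-10
    domain_ievalue_max: float = 1e-5
    min_protein_length: int = 150
    l2fc_threshold: float = 1.0
    min_raw_count: int = 100
    min_samples_at_count: int = 2
    logo_pseudocount: float = 0.0
    rng_seed: int = 0
    # plumbing knobs (not printed thresholds)
    max_overlap_frac: float = 0.25
    prior_count: float = 0.5
    best_hit_only: bool = True

    def __post_init__(self) -> None:
        for name in (
            "blast_evalue_max",
            "domain_ievalue_max",
            "min_protein_length",
            "l2fc_threshold",
            "min_raw_count",
            "min_samples_at_count",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.logo_pseudocount < 0:
            raise ValueError("logo_pseudocount must be non-negative")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Order is preserved; duplicate ids and empty sequences are hard errors.
    No length filtering happens here (that is the architecture stage's job).
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise AnnotationError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write proteins as FASTA (wrap at *width* columns)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# HMMER domtblout

# hmmscan --domtblout columns (0-based): 0 target(domain) name, 1 target acc,
# 3 query(protein) name, 11 c-Evalue, 12 i-Evalue, 13 domain bit score,
# 19 env from, 20 env to.  22 whitespace-separated fields precede the
# free-text description.
_DOMTBL_MIN_FIELDS = 22


def parse_domain_hits(path: str | Path, dialect: str = "domtblout") -> list[DomainHit]:
    """Parse a HMMER3 per-domain table into :class:`DomainHit` objects.

    Only the ``domtblout`` dialect is supported.  Coordinates come from the
    envelope columns; comment lines (``#``) are skipped; malformed rows are
    hard errors reported with their line number.
    """
    if dialect != "domtblout":
        raise AnnotationError(f"unsupported domain-table dialect {dialect!r}")
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < _DOMTBL_MIN_FIELDS:
                raise AnnotationError(
                    f"{path}:{lineno}: expected >= {_DOMTBL_MIN_FIELDS} columns, "
                    f"got {len(fields)}"
                )
            try:
                hit = DomainHit(
                    protein_id=fields[3],
                    domain_name=fields[0],
                    accession=fields[1],
                    i_evalue=float(fields[12]),
                    start=int(fields[19]),
                    end=int(fields[20]),
                    bit_score=float(fields[13]),
                )
            except (ValueError, AnnotationError) as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# TMHMM


def _parse_tmhmm_long_line(fields: Sequence[str]) -> TMRegion | None:
    # "<id>  TMHMM2.0  TMhelix  <start>  <end>"; inside/outside rows ignored
    if fields[2] == "TMhelix":
        return TMRegion(protein_id=fields[0], start=int(fields[3]), end=int(fields[4]))
    if fields[2] in ("inside", "outside"):
        return None
    raise AnnotationError(f"unknown topology element {fields[2]!r}")


def _parse_tmhmm_short_line(line: str) -> list[TMRegion]:
    fields = line.split()
    protein_id = fields[0]
    topo = None
    for f in fields[1:]:
        if f.startswith("Topology="):
            topo = f[len("Topology=") :]
    if topo is None:
        raise AnnotationError("short-dialect line lacks Topology= field")
    regions: list[TMRegion] = []
    # Topology like "o7-29i40-62o": helices are the digit-digit pairs.
    i = 0
    while i < len(topo):
        if topo[i].isdigit():
            j = i
            while j < len(topo) and topo[j].isdigit():
                j += 1
            if j >= len(topo) or topo[j] != "-":
                raise AnnotationError(f"cannot parse topology string {topo!r}")
            k = j + 1
            m = k
            while m < len(topo) and topo[m].isdigit():
                m += 1
            regions.append(
                TMRegion(protein_id=protein_id, start=int(topo[i:j]), end=int(topo[k:m]))
            )
            i = m
        else:
            i += 1
    return regions


def parse_tm_regions(path: str | Path) -> list[TMRegion]:
    """Parse TMHMM output (long or short dialect, auto-detected).

    Returns one :class:`TMRegion` per predicted helix, sorted by start within
    each protein.  Overlapping helices for one protein are a hard error.
    """
    regions: list[TMRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if "Topology=" in line:
                regions.extend(_parse_tmhmm_short_line(line))
                continue
            fields = line.split()
            if len(fields) >= 5 and fields[2] in ("TMhelix", "inside", "outside"):
                try:
                    reg = _parse_tmhmm_long_line(fields)
                except (ValueError, AnnotationError) as exc:
                    raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
                if reg is not None:
                    regions.append(reg)
                continue
            raise AnnotationError(
                f"{path}:{lineno}: unrecognized TMHMM dialect; first offending "
                f"line: {line.rstrip()!r}"
            )
    regions.sort(key=lambda r: (r.protein_id, r.start))
    by_protein: dict[str, int] = {}
    for reg in regions:
        prev_end = by_protein.get(reg.protein_id)
        if prev_end is not None and reg.start <= prev_end:
            raise AnnotationError(
                f"overlapping TM helices on {reg.protein_id} near position {reg.start}"
            )
        by_protein[reg.protein_id] = reg.end
    return regions


# ---------------------------------------------------------------------------
# BLAST tabular + taxonomy


def load_taxonomy_map(path: str | Path) -> dict[str, str]:
    """Load a two-column TSV mapping subject accession -> taxon group."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise AnnotationError(f"{path}:{lineno}: expected 2 columns")
            mapping[fields[0]] = fields[1]
    return mapping


def parse_blast_annotations(
    path: str | Path, taxonomy: dict[str, str]
) -> list[AnnotationRecord]:
    """Parse 12/13-column tabular BLAST and join the taxonomy map.

    Column 13, when present, is a free-text subject title used as the
    description; otherwise the subject id stands in.  Subjects missing from
    the taxonomy map are tagged ``unknown`` (and later dropped by
    :func:`filter_annotations`, with a logged count).
    """
    records: list[AnnotationRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise AnnotationError(
                    f"{path}:{lineno}: expected >= 12 tab-separated columns"
                )
            subject = fields[1]
            group = taxonomy.get(subject, "unknown")
            if group not in ("metazoa", "non_metazoa"):
                group = "unknown" if group == "unknown" else "non_metazoa"
            try:
                records.append(
                    AnnotationRecord(
                        protein_id=fields[0],
                        subject_id=subject,
                        description=fields[12] if len(fields) > 12 else subject,
                        evalue=float(fields[10]),
                        taxon_group=group,
                    )
                )
            except (ValueError, AnnotationError) as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    return records


def filter_annotations(
    records: Sequence[AnnotationRecord],
    config: PipelineConfig,
    keep_all_hits: bool | None = None,
) -> list[AnnotationRecord]:
    """Apply the homology-annotation filter.

    A record is retained iff its E-value is <= ``blast_evalue_max`` and its
    taxon group is metazoa.  Records with unknown taxonomy are dropped (their
    count is logged).  By default only the best (lowest-E-value) hit per
    protein is considered; pass ``keep_all_hits=True`` (or set
    ``config.best_hit_only = False``) to filter every hit.  Idempotent.
    """
    best_only = config.best_hit_only if keep_all_hits is None else not keep_all_hits
    n_unknown = sum(1 for r in records if r.taxon_group == "unknown")
    if n_unknown:
        logger.info("dropping %d annotation records with unknown taxonomy", n_unknown)
    known = [r for r in records if r.taxon_group != "unknown"]
    if best_only:
        best: dict[str, AnnotationRecord] = {}
        for rec in known:
            cur = best.get(rec.protein_id)
            if cur is None or rec.evalue < cur.evalue:
                best[rec.protein_id] = rec
        known = [best[pid] for pid in sorted(best)]
    return [
        r
        for r in known
        if r.evalue <= config.blast_evalue_max and r.taxon_group == "metazoa"
    ]
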