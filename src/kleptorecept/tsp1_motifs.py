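"""Motif scanning and sequence-logo matrices for thrombospondin type-1
repeat (TSP1) domain segments.

The TSP1 repeat (~50 aa) carries a set of functional sequence features: six
conserved cysteines, a tryptophan tract WXXWXXW that binds proteins and
glycosaminoglycans (GAG), and the CD36/SR-B binding motifs CSVTCG and
GVQTRXR, usually followed by an RXR tract of polar residues
(arginine/lysine/glutamine).  This module extracts TSP1 segments from
architectures, scans them for those motifs, and turns aligned segment sets
into position-frequency/information matrices for sequence logos.

Motif matching conventions:

* ``X`` matches any residue.
* CSVTCG and GVQTRXR are each reported twice: exact, and in a
  one-mismatch-tolerant mode (Hamming distance <= 1 over the non-X
  positions) — real TSP1 repeats usually carry a motif *similar* to CSVTCG
  rather than the literal hexapeptide.
* The RXR tract is matched in a relaxed mode by default, with R standing
  for any of R/K/Q; a strict arginine-only mode is available.

Information content is ``log2(20) - H`` where ``H`` is the Shannon entropy
of an alignment column in bits (no small-sample correction).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation_io import AMINO_ACIDS, ProteinRecord
from .architecture import DomainArchitecture
from .vocabulary import TSP1

GAG_MOTIF_RE = re.compile(r"W..W..W")
RXR_RELAXED_RE = re.compile(r"[RKQ].[RKQ]")
RXR_STRICT_RE = re.compile(r"R.R")
CSVTCG = "CSVTCG"
GVQTRXR = "GVQTRXR"

MAX_BITS = math.log2(20)


class MotifError(ValueError):
    pass


@dataclass(frozen=True)
class Tsp1MotifReport:
    protein_id: str
    segment_index: int
    segment: str
    cysteine_count: int
    has_gag_motif: bool
    has_csvtcg_exact: bool
    has_csvtcg_like: bool
    has_gvqtrxr_exact: bool
    has_gvqtrxr_like: bool
    has_rxr_motif: bool


def extract_tsp1_segments(
    arch: DomainArchitecture, protein: ProteinRecord
) -> list[str]:
    """Subsequences of *protein* under each TSP1 element of *arch*, in order."""
    if arch.protein_id != protein.id:
        raise MotifError(
            f"architecture {arch.protein_id} does not belong to protein {protein.id}"
        )
    segments = []
    for el in arch.elements:
        if el.kind == "pfam_domain" and el.label == TSP1:
            if el.end > protein.length:
                raise MotifError(
                    f"TSP1 element {el.start}..{el.end} exceeds protein "
                    f"{protein.id} length {protein.length}"
                )
            segments.append(protein.sequence[el.start - 1 : el.end])
    return segments


def _fuzzy_contains(segment: str, motif: str, max_mismatch: int) -> bool:
    """Window scan: does *segment* contain *motif* with <= max_mismatch
    mismatches?  'X' in the motif matches anything and never counts."""
    k = len(motif)
    for i in range(len(segment) - k + 1):
        window = segment[i : i + k]
        mism = sum(
            1 for a, b in zip(motif, window) if a != "X" and a != b
        )
        if mism <= max_mismatch:
            return True
    return False


def scan_motifs(
    segment: str,
    protein_id: str = "",
    segment_index: int = 0,
    mismatch_tolerance: int = 1,
    strict_rxr: bool = False,
) -> Tsp1MotifReport:
    """Scan one TSP1 segment for the motif set.

    ``cysteine_count`` is the total number of C residues in the segment
    (the consensus-level conserved-cysteine count is a property of the
    aligned set; see :func:`conserved_cysteine_columns`).
    """
    if not segment:
        raise MotifError("cannot scan an empty segment")
    seg = segment.upper()
    rxr_re = RXR_STRICT_RE if strict_rxr else RXR_RELAXED_RE
    return Tsp1MotifReport(
        protein_id=protein_id,
        segment_index=segment_index,
        segment=seg,
        cysteine_count=seg.count("C"),
        has_gag_motif=GAG_MOTIF_RE.search(seg) is not None,
        has_csvtcg_exact=CSVTCG in seg,
        has_csvtcg_like=_fuzzy_contains(seg, CSVTCG, mismatch_tolerance),
        has_gvqtrxr_exact=_fuzzy_contains(seg, GVQTRXR, 0),
        has_gvqtrxr_like=_fuzzy_contains(seg, GVQTRXR, mismatch_tolerance),
        has_rxr_motif=rxr_re.search(seg) is not None,
    )


def reports_to_frame(reports: Sequence[Tsp1MotifReport]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in reports])


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-column residue frequencies and information content (bits).

    ``frequencies`` is positions x 20 (columns ordered as
    :data:`~kleptorecept.annotation_io.AMINO_ACIDS`); each row sums to 1.
    ``information`` is ``log2(20) - H`` per column, in [0, log2(20)].
    """

    frequencies: pd.DataFrame
    information: np.ndarray
    n_sequences: int

    def conserved_cysteine_columns(self, min_freq: float = 0.5) -> list[int]:
        """0-based indices of C-majority columns (frequency of C > min_freq)."""
        return [
            int(i)
            for i, f in enumerate(self.frequencies["C"].to_numpy())
            if f > min_freq
        ]

    def to_tsv(self, path: str | Path) -> None:
        out = self.frequencies.copy()
        out.insert(0, "position", np.arange(1, len(out) + 1))
        out["bits"] = self.information
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def build_logo_matrix(
    aligned_segments: Sequence[str], pseudocount: float = 0.0
) -> PositionFrequencyMatrix:
    """Column frequencies + information content for equal-length segments.

    With pseudocount c, column frequency of residue a is
    ``(count_a + c) / (n + 20 c)``; information is ``log2(20) - H`` with H
    the Shannon entropy in bits (0*log 0 := 0).  Unequal segment lengths are
    a hard error: alignment is the caller's responsibility.
    """
    if not aligned_segments:
        raise MotifError("need at least one segment")
    if pseudocount < 0:
        raise MotifError("pseudocount must be non-negative")
    length = len(aligned_segments[0])
    if any(len(s) != length for s in aligned_segments):
        raise MotifError("aligned segments must all share one length")
    n = len(aligned_segments)
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    counts = np.zeros((length, 20), dtype=float)
    for seg in aligned_segments:
        for pos, res in enumerate(seg.upper()):
            idx = aa_index.get(res)
            if idx is not None:  # X / gaps excluded from the column statistics
                counts[pos, idx] += 1.0
    col_totals = counts.sum(axis=1) + 20.0 * pseudocount
    if np.any(col_totals == 0):
        raise MotifError("a column contains only ambiguous residues")
    freqs = (counts + pseudocount) / col_totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    information = np.clip(MAX_BITS - entropy, 0.0, MAX_BITS)
    return PositionFrequencyMatrix(
        frequencies=pd.DataFrame(freqs, columns=list(AMINO_ACIDS)),
        information=information,
        n_sequences=n,
    )


def read_aligned_fasta(path: str | Path) -> list[str]:
    """Read equal-length (pre-aligned) segments from FASTA."""
    from Bio import SeqIO

    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]


def plot_logo(matrix: PositionFrequencyMatrix, path: str | Path) -> None:
    """Render a minimal stacked-letter logo (letters scaled by f * bits)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    length = len(matrix.frequencies)
    fig, ax = plt.subplots(figsize=(max(6, length * 0.25), 2.5))
    for pos in range(length):
        col = matrix.frequencies.iloc[pos]
        bits = matrix.information[pos]
        y = 0.0
        for aa, f in sorted(col.items(), key=lambda kv: kv[1]):
            h = f * bits
            if h < 0.01:
                continue
            ax.text(
                pos + 0.5,
                y + h / 2,
                aa,
                ha="center",
                va="center",
                fontsize=8,
                color="darkorange" if aa == "C" else "black",
            )
            y += h
    ax.set_xlim(0, length)
    ax.set_ylim(0, MAX_BITS)
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
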