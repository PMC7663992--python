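"""Synthetic inputs for every pipeline stage.

Three generators emulate the products of the real data sources — annotated
sea-slug proteomes (translated transcriptome assemblies with Pfam domain
hits and TMHMM helices) and RNA-seq count matrices for the two experimental
designs (adult fed-vs-starvation series without replicates; staged juvenile
series with triplicates) — with planted ground truth, so classification
recovery, motif recovery and differential-expression recovery are all
self-scoring.

The amino-acid content of generated proteins is uniform background: the
pipeline classifies from annotation files, never by re-detecting domains
from sequence, so only coordinates and labels must be realistic.  Files are
emitted in exactly the dialects the parsers consume (round-trip contract).

All generators are pure functions of (plan, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import AMINO_ACIDS, DomainHit, ProteinRecord, TMRegion, write_fasta

# Per-category element templates: (kind, Pfam family name or TM, length in aa).
# Each realizes the category's defining arrangement under the default
# vocabulary and rule set.
CATEGORY_TEMPLATES: dict[str, list[tuple[str, str, int]]] = {
    "SR_A": [("tm", "TM", 21), ("pfam", "Collagen", 60), ("pfam", "SRCR", 100)],
    "SR_B": [("tm", "TM", 21), ("pfam", "CD36", 330), ("tm", "TM", 21)],
    "SR_E_like": [("tm", "TM", 21), ("pfam", "Lectin_C", 115)],
    "SR_I": [("tm", "TM", 21), ("pfam", "SRCR", 100), ("pfam", "SRCR", 100)],
    "C_type_lectin": [("pfam", "Lectin_C", 115), ("pfam", "Lectin_C", 115), ("tm", "TM", 21)],
    "SRCR_member": [("pfam", "SRCR", 100), ("pfam", "SRCR", 100)],
    "TSP_COMP": [
        ("pfam", "EGF", 40),
        ("pfam", "TSP_3", 35),
        ("pfam", "TSP_3", 35),
        ("pfam", "TSP_C", 180),
    ],
    "ADAMTS_like": [
        ("pfam", "Reprolysin", 200),
        ("pfam", "TSP_1", 50),
        ("pfam", "ADAM_spacer1", 120),
        ("pfam", "TSP_1", 50),
    ],
    "semaphorin_plexin": [("pfam", "Sema", 380), ("pfam", "PSI", 50)],
    "TSR_withTM": [("pfam", "TSP_1", 50), ("pfam", "TSP_1", 50), ("tm", "TM", 21)],
    "TSR_noTM": [("pfam", "TSP_1", 50)] * 6,
    "TSR_other": [("pfam", "VWA", 170), ("pfam", "TSP_1", 50), ("pfam", "VWA", 170)],
    "unclassified": [("pfam", "Pkinase", 250)],
}

#: domain families used for sub-threshold distractor hits (label is
#: irrelevant: they must never reach the classifier)
DISTRACTOR_FAMILIES = ("CD36", "Lectin_C", "SRCR", "TSP_1", "WD40", "Pkinase", "Ank_2")


class GenerationError(ValueError):
    pass


@dataclass
class ProteomePlan:
    """How many proteins of each category to plant, plus noise settings."""

    category_counts: dict[str, int] = field(
        default_factory=lambda: {
            "SR_B": 10,
            "SR_E_like": 10,
            "SR_I": 5,
            "C_type_lectin": 10,
            "SRCR_member": 5,
            "TSP_COMP": 3,
            "ADAMTS_like": 5,
            "semaphorin_plexin": 5,
            "TSR_withTM": 10,
            "TSR_noTM": 5,
            "TSR_other": 5,
            "unclassified": 10,
        }
    )
    noise_domain_rate: float = 0.3  # expected sub-threshold distractor hits/protein
    length_range: tuple[int, int] = (150, 1500)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for cat, n in self.category_counts.items():
            if cat not in CATEGORY_TEMPLATES:
                raise GenerationError(f"unknown category {cat!r}")
            if n < 0:
                raise GenerationError(f"negative count for {cat!r}")
        if self.noise_domain_rate < 0:
            raise GenerationError("noise_domain_rate must be >= 0")


@dataclass
class ProteomeBundle:
    proteins: list[ProteinRecord]
    hits: list[DomainHit]
    tms: list[TMRegion]
    truth: pd.DataFrame  # columns: protein_id, category, arrangement
    fasta_path: Path | None = None
    domtbl_path: Path | None = None
    tmhmm_path: Path | None = None
    truth_path: Path | None = None


def _random_sequence(rng: np.random.Generator, length: int, alphabet: str = AMINO_ACIDS) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _layout_elements(
    template: Sequence[tuple[str, str, int]],
    rng: np.random.Generator,
    length_range: tuple[int, int],
) -> tuple[list[tuple[str, str, int, int]], int]:
    """Place template elements left to right with random gaps.

    Returns ([(kind, name, start, end)], protein_length)."""
    placed = []
    pos = 1 + int(rng.integers(2, 25))
    for kind, name, span in template:
        start = pos
        end = start + span - 1
        placed.append((kind, name, start, end))
        pos = end + 1 + int(rng.integers(3, 30))
    tail = int(rng.integers(5, 40))
    total = placed[-1][3] + tail
    lo, hi = length_range
    if total > hi:
        raise GenerationError(
            f"template needs {total} aa but plan allows at most {hi}"
        )
    total = max(total, lo)
    return placed, total


def _expected_arrangement(template: Sequence[tuple[str, str, int]]) -> str:
    from .vocabulary import canonical_label

    return " + ".join(
        "TM" if kind == "tm" else canonical_label(name) for kind, name, _ in template
    )


def generate_proteome(
    plan: ProteomePlan, out_dir: str | Path | None = None
) -> ProteomeBundle:
    """Generate a proteome with planted architectures and its annotation files.

    Real hits get i-E-values sampled well below the 1e-5 threshold
    (10^-30..10^-6); distractor hits (Poisson-thinned at
    ``noise_domain_rate`` per protein) land just above it (10^-4.9..10^-1.5)
    so that a correct threshold leaves classification unchanged.
    """
    rng = np.random.default_rng(plan.rng_seed)
    proteins: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    tms: list[TMRegion] = []
    truth_rows = []
    serial = 0
    for cat in sorted(plan.category_counts):
        template = CATEGORY_TEMPLATES[cat]
        for _ in range(plan.category_counts[cat]):
            serial += 1
            pid = f"synthpro{serial:05d}"
            placed, length = _layout_elements(template, rng, plan.length_range)
            proteins.append(ProteinRecord(id=pid, sequence=_random_sequence(rng, length)))
            for kind, name, start, end in placed:
                if kind == "tm":
                    tms.append(TMRegion(protein_id=pid, start=start, end=end))
                else:
                    hits.append(
                        DomainHit(
                            protein_id=pid,
                            domain_name=name,
                            accession=f"PF{abs(hash(name)) % 90000 + 10000:05d}.1",
                            i_evalue=float(10.0 ** -rng.uniform(6, 30)),
                            start=start,
                            end=end,
                            bit_score=float(rng.uniform(50, 400)),
                        )
                    )
            n_noise = int(rng.poisson(plan.noise_domain_rate))
            for _ in range(n_noise):
                span = int(rng.integers(20, 60))
                if length <= span + 1:
                    continue
                start = int(rng.integers(1, length - span))
                hits.append(
                    DomainHit(
                        protein_id=pid,
                        domain_name=str(rng.choice(DISTRACTOR_FAMILIES)),
                        accession="PF99999.1",
                        i_evalue=float(10.0 ** -rng.uniform(1.5, 4.9)),
                        start=start,
                        end=start + span - 1,
                        bit_score=float(rng.uniform(5, 25)),
                    )
                )
            truth_rows.append(
                {
                    "protein_id": pid,
                    "category": cat,
                    "arrangement": _expected_arrangement(template),
                }
            )
    truth = pd.DataFrame(truth_rows, columns=["protein_id", "category", "arrangement"])
    bundle = ProteomeBundle(proteins=proteins, hits=hits, tms=tms, truth=truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle.fasta_path = out / "proteome.fasta"
        bundle.domtbl_path = out / "domains.domtblout"
        bundle.tmhmm_path = out / "tmhmm.txt"
        bundle.truth_path = out / "proteome_truth.tsv"
        write_fasta(proteins, bundle.fasta_path)
        lengths = {p.id: p.length for p in proteins}
        write_domtblout(hits, lengths, bundle.domtbl_path)
        write_tmhmm_long(tms, bundle.tmhmm_path)
        truth.to_csv(bundle.truth_path, sep="\t", index=False)
    return bundle


def write_domtblout(
    hits: Sequence[DomainHit], protein_lengths: Mapping[str, int], path: str | Path
) -> None:
    """Emit hits in the HMMER3 per-domain tabular dialect (hmmscan
    orientation: target = Pfam family, query = protein)."""
    with open(path, "w") as fh:
        fh.write("# synthetic per-domain hits\n")
        fh.write("#" + " " * 20 + "--- full sequence --- -------------- this domain"
                 " -------------   hmm coord   ali coord   env coord\n")
        by_protein: dict[str, list[DomainHit]] = {}
        for h in hits:
            by_protein.setdefault(h.protein_id, []).append(h)
        for pid in by_protein:
            phits = sorted(by_protein[pid], key=lambda h: h.start)
            ndom = len(phits)
            for i, h in enumerate(phits, start=1):
                dlen = h.end - h.start + 1
                fields = [
                    h.domain_name,          # 0 target name
                    h.accession,            # 1 target accession
                    str(dlen),              # 2 tlen
                    pid,                    # 3 query name
                    "-",                    # 4 query accession
                    str(protein_lengths[pid]),  # 5 qlen
                    f"{h.i_evalue:.2g}",    # 6 full-seq E-value
                    f"{h.bit_score:.1f}",   # 7 full-seq score
                    "0.1",                  # 8 bias
                    str(i),                 # 9 domain index
                    str(ndom),              # 10 of
                    f"{h.i_evalue:.2g}",    # 11 c-Evalue
                    f"{h.i_evalue:.2g}",    # 12 i-Evalue
                    f"{h.bit_score:.1f}",   # 13 domain score
                    "0.1",                  # 14 domain bias
                    "1",                    # 15 hmm from
                    str(dlen),              # 16 hmm to
                    str(h.start),           # 17 ali from
                    str(h.end),             # 18 ali to
                    str(h.start),           # 19 env from
                    str(h.end),             # 20 env to
                    "0.95",                 # 21 acc
                    "synthetic hit",        # 22 description
                ]
                fh.write(" ".join(fields) + "\n")


def write_tmhmm_long(tms: Sequence[TMRegion], path: str | Path) -> None:
    """Emit helices in the TMHMM long dialect (TMhelix rows)."""
    with open(path, "w") as fh:
        for t in sorted(tms, key=lambda r: (r.protein_id, r.start)):
            fh.write(f"{t.protein_id}\tTMHMM2.0\tTMhelix\t{t.start}\t{t.end}\n")


def generate_homology_table(
    n_records: int,
    n_metazoa_pass: int,
    seed: int = 0,
    evalue_threshold: float = 1e-10,
) -> tuple[list, dict[str, str]]:
    """Annotation records with exactly *n_metazoa_pass* planted to survive the
    homology filter (metazoan, E-value below threshold); the rest fail by
    taxon or by E-value.  Returns (records, taxonomy_map)."""
    from .annotation_io import AnnotationRecord

    if n_metazoa_pass > n_records:
        raise GenerationError("n_metazoa_pass cannot exceed n_records")
    rng = np.random.default_rng(seed)
    records = []
    taxmap: dict[str, str] = {}
    for i in range(n_records):
        pid = f"annotq{i:04d}"
        sid = f"SUBJ{i:04d}"
        if i < n_metazoa_pass:
            group, evalue = "metazoa", float(10.0 ** -rng.uniform(11, 40))
        elif i % 2 == 0:
            group, evalue = "non_metazoa", float(10.0 ** -rng.uniform(11, 40))
        else:  # metazoan but too weak
            group, evalue = "metazoa", float(
                10.0 ** -rng.uniform(2, -np.log10(evalue_threshold) - 0.5)
            )
        taxmap[sid] = group
        records.append(
            AnnotationRecord(
                protein_id=pid,
                subject_id=sid,
                description=f"synthetic subject {i}",
                evalue=evalue,
                taxon_group=group,
            )
        )
    return records, taxmap


# ---------------------------------------------------------------------------
# TSP1 segment sets

#: fixed alignment layout (0-based columns) of the planted TSP1 features
TSP1_SEGMENT_LENGTH = 56
TSP1_GAG_COLUMNS = (3, 6, 9)          # W..W..W
TSP1_CSVTCG_START = 12                # CSVTCG at 12..17
TSP1_RXR_COLUMNS = (20, 22)           # polar R/K/Q flanking any residue
TSP1_GVQTRXR_START = 25               # GVQTRXR at 25..31
TSP1_EXTRA_CYS_COLUMNS = (35, 40, 45, 50)
#: the six conserved cysteine columns: the two inside CSVTCG plus four more
TSP1_CYSTEINE_COLUMNS = (12, 16, 35, 40, 45, 50)

_NO_CYS = AMINO_ACIDS.replace("C", "")
_POLAR_R = "RKQ"


def generate_tsp1_set(
    n: int,
    seed: int = 0,
    plant_gag: bool = True,
    plant_csvtcg: bool = True,
    plant_gvqtrxr: bool = True,
    plant_rxr: bool = True,
) -> tuple[list[str], dict]:
    """Aligned TSP1 segments with motifs planted at fixed columns.

    Background is uniform over the 19 non-cysteine residues, so every
    segment carries exactly the six planted cysteines and the conserved
    cysteine columns of the aligned set are unambiguous.  Returns
    (segments, truth) where truth records the planted columns.
    """
    if n < 1:
        raise GenerationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    segments = []
    for _ in range(n):
        seq = list(_random_sequence(rng, TSP1_SEGMENT_LENGTH, _NO_CYS))
        if plant_gag:
            for col in TSP1_GAG_COLUMNS:
                seq[col] = "W"
        if plant_csvtcg:
            seq[TSP1_CSVTCG_START : TSP1_CSVTCG_START + 6] = list("CSVTCG")
        if plant_rxr:
            for col in TSP1_RXR_COLUMNS:
                seq[col] = str(rng.choice(list(_POLAR_R)))
        if plant_gvqtrxr:
            motif = list("GVQTR") + [str(rng.choice(list(_NO_CYS)))] + ["R"]
            seq[TSP1_GVQTRXR_START : TSP1_GVQTRXR_START + 7] = motif
        for col in TSP1_EXTRA_CYS_COLUMNS:
            seq[col] = "C"
        segments.append("".join(seq))
    truth = {
        "cysteine_columns": list(TSP1_CYSTEINE_COLUMNS) if plant_csvtcg else list(TSP1_EXTRA_CYS_COLUMNS),
        "gag_columns": list(TSP1_GAG_COLUMNS) if plant_gag else [],
        "csvtcg_span": (TSP1_CSVTCG_START, TSP1_CSVTCG_START + 5) if plant_csvtcg else None,
        "gvqtrxr_span": (TSP1_GVQTRXR_START, TSP1_GVQTRXR_START + 6) if plant_gvqtrxr else None,
        "rxr_columns": list(TSP1_RXR_COLUMNS) if plant_rxr else [],
    }
    return segments, truth


# ---------------------------------------------------------------------------
# Count matrices


@dataclass
class CountsPlan:
    """Negative-binomial count matrix with planted fed/initial upregulation.

    Defaults mirror the study designs: 1,000 genes, 20 planted candidates, a
    planted log2 effect of 2, NB dispersion 0.1 and ~1M reads per library.
    ``fed_vs_starvation`` emits one library per condition (fed + k
    starvation periods); ``staged_juvenile`` emits triplicates of apo, fed5,
    fed7 and fed10, with planted genes elevated from fed5 onward (so the
    initial-phase contrast carries the effect).
    """

    n_genes: int = 1000
    n_planted_up: int = 20
    design: str = "fed_vs_starvation"
    n_starvation_conditions: int = 2
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    dispersion: float = 0.1
    planted_log2_effect: float = 2.0
    depth: float = 1e6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_up > self.n_genes:
            raise GenerationError("n_planted_up cannot exceed n_genes")
        if self.design not in ("fed_vs_starvation", "staged_juvenile"):
            raise GenerationError(f"unknown design {self.design!r}")
        for name in ("n_genes", "dispersion", "depth"):
            if getattr(self, name) <= 0:
                raise GenerationError(f"{name} must be positive")


@dataclass
class CountsBundle:
    counts: pd.DataFrame  # genes x samples
    sample_conditions: dict[str, str]
    design: str
    truth_up: list[str]
    counts_path: Path | None = None
    design_path: Path | None = None
    truth_path: Path | None = None


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with var = mu + dispersion * mu^2 (edgeR parameterization)."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_counts(plan: CountsPlan, out_dir: str | Path | None = None) -> CountsBundle:
    """Simulate the count matrix + design files for one species design."""
    rng = np.random.default_rng(plan.rng_seed)
    gene_ids = [f"gene{i:05d}" for i in range(plan.n_genes)]
    planted = gene_ids[: plan.n_planted_up]
    base = 2.0 ** rng.normal(plan.baseline_log2_mean, plan.baseline_log2_sd, plan.n_genes)
    rel = base / base.sum()

    if plan.design == "fed_vs_starvation":
        conditions = ["fed"] + [
            f"starved_{d}" for d in ("d4", "d7", "d30")[: plan.n_starvation_conditions]
        ]
        samples = {c: c for c in conditions}  # one library per condition
    else:
        conditions = ["apo", "fed5", "fed7", "fed10"]
        samples = {
            f"{c}_r{r}": c for c in conditions for r in (1, 2, 3)
        }

    effect = 2.0**plan.planted_log2_effect
    up_mask = np.isin(gene_ids, planted)
    cols = {}
    for sample, cond in samples.items():
        mu_rel = rel.copy()
        elevated = (cond == "fed") if plan.design == "fed_vs_starvation" else (
            cond in ("fed5", "fed7", "fed10")
        )
        if elevated:
            mu_rel = np.where(up_mask, mu_rel * effect, mu_rel)
        mu = mu_rel / mu_rel.sum() * plan.depth
        cols[sample] = _nb_draw(rng, mu, plan.dispersion)
    counts = pd.DataFrame(cols, index=gene_ids)
    bundle = CountsBundle(
        counts=counts,
        sample_conditions=dict(samples),
        design=plan.design,
        truth_up=list(planted),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle.counts_path = out / "counts.tsv"
        bundle.design_path = out / "design.tsv"
        bundle.truth_path = out / "counts_truth.tsv"
        counts.to_csv(bundle.counts_path, sep="\t", index_label="gene_id")
        with open(bundle.design_path, "w") as fh:
            for sample, cond in samples.items():
                fh.write(f"{sample}\t{cond}\n")
        pd.DataFrame({"gene_id": planted}).to_csv(bundle.truth_path, sep="\t", index=False)
    return bundle
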