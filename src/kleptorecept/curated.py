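"""Published candidate receptor genes for the three *Elysia* species.

These are the reported per-gene log2 fold changes of the receptor genes
found significantly upregulated in freshly fed adults (*E. cornigera*,
*E. timida*; fed vs each starvation period) or during the initial phase of
functional kleptoplasty (*E. chlorotica*; staged juvenile design).  They
serve as worked examples: embedded among non-qualifying decoy genes, the
selection rule must recover exactly these rows.

Gene ids are the species' TSA / assembly transcript identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CuratedCandidate:
    gene_id: str
    receptor_group: str  # "SR" | "TSR"
    category: str
    arrangement: str
    annotation: str
    l2fc: dict[str, float]


E_CORNIGERA_COMPARISONS = ("starved_d4", "starved_d7")
E_CORNIGERA_CANDIDATES: tuple[CuratedCandidate, ...] = (
    CuratedCandidate(
        "GBRW01136834.1", "SR", "SR_B", "TM + CD36 + TM",
        "Scavenger receptor class B member 1",
        {"starved_d4": 2.41, "starved_d7": 1.43},
    ),
    CuratedCandidate(
        "GBRW01100272.1", "SR", "SR_E_like", "TM + CTLD", "Perlucin",
        {"starved_d4": 3.04, "starved_d7": 1.32},
    ),
    CuratedCandidate(
        "GBRW01106608.1", "SR", "C_type_lectin", "CTLD + CTLD + TM",
        "C-type mannose receptor 2",
        {"starved_d4": 2.53, "starved_d7": 8.50},
    ),
    CuratedCandidate(
        "GBRW01166191.1", "SR", "C_type_lectin", "CTLD + CTLD + TM",
        "C-type mannose receptor 2",
        {"starved_d4": 2.11, "starved_d7": 1.15},
    ),
    CuratedCandidate(
        "GBRW01163094.1", "SR", "C_type_lectin", "CTLD + CTLD + TM",
        "Versican core protein",
        {"starved_d4": 1.22, "starved_d7": 2.28},
    ),
    CuratedCandidate(
        "GBRW01019759.1", "SR", "C_type_lectin", "TM + CTLD + CTLD + TM",
        "Snaclec agglucetin subunit beta-1",
        {"starved_d4": 1.69, "starved_d7": 1.17},
    ),
    CuratedCandidate(
        "GBRW01123401.1", "TSR", "TSR_noTM", "TSP1", "Hemicentin-1",
        {"starved_d4": 3.24, "starved_d7": 2.69},
    ),
)

E_TIMIDA_COMPARISONS = ("starved_d4", "starved_d7", "starved_d30")
E_TIMIDA_CANDIDATES: tuple[CuratedCandidate, ...] = (
    CuratedCandidate(
        "GBRM01064602.1", "SR", "SR_E_like", "TM + CTLD", "Collectin-10",
        {"starved_d4": 2.66, "starved_d7": 3.54, "starved_d30": 2.08},
    ),
    CuratedCandidate(
        "GBRM01009636.1", "SR", "SR_E_like", "TM + CTLD", "C-type lectin 37 Da",
        {"starved_d4": 2.80, "starved_d7": 2.54, "starved_d30": 6.14},
    ),
    CuratedCandidate(
        "GBRM01066486.1", "SR", "SR_E_like", "TM + CTLD", "C-type lectin 37 Da",
        {"starved_d4": 3.87, "starved_d7": 3.66, "starved_d30": 6.09},
    ),
    CuratedCandidate(
        "GBRM01066478.1", "SR", "SR_E_like", "TM + CTLD", "Perlucin",
        {"starved_d4": 3.69, "starved_d7": 3.92, "starved_d30": 4.63},
    ),
    CuratedCandidate(
        "GBRM01039872.1", "SR", "SR_E_like", "TM + CTLD", "C-type mannose receptor 2",
        {"starved_d4": 2.90, "starved_d7": 2.61, "starved_d30": 2.36},
    ),
    CuratedCandidate(
        "GBRM01017414.1", "SR", "C_type_lectin", "TM + CTLD + TM", "Collectin-12",
        {"starved_d4": 3.58, "starved_d7": 1.73, "starved_d30": 2.72},
    ),
    CuratedCandidate(
        "GBRM01039431.1", "TSR", "ADAMTS_like", "TSP1 + TSP1 + I-set + Plac",
        "Protein madd-4",
        {"starved_d4": 8.92, "starved_d7": 9.47, "starved_d30": 10.06},
    ),
)

E_CHLOROTICA_COMPARISONS = ("initial", "transient", "stable")
#: staged juvenile design: selection looks at the initial-phase contrast only
E_CHLOROTICA_CANDIDATES: tuple[CuratedCandidate, ...] = (
    CuratedCandidate(
        "c104938_g1_i1_1-2480", "SR", "SR_B", "TM + CD36 + TM",
        "Lysosome membrane protein 2",
        {"initial": 2.02, "transient": -2.12, "stable": 1.33},
    ),
    CuratedCandidate(
        "c128999_g1_i3_1-4140", "SR", "SR_B", "TM + CD36 + TM",
        "Scavenger receptor class B member 1",
        {"initial": 2.58, "transient": -0.38, "stable": 1.90},
    ),
    CuratedCandidate(
        "c119366_g1_i1_1-1981", "SR", "C_type_lectin", "CTLD + CTLD + TM",
        "Snaclec B1",
        {"initial": 1.10, "transient": -0.05, "stable": 3.17},
    ),
    CuratedCandidate(
        "c124460_g1_i2_1-2516", "SR", "C_type_lectin", "CTLD + CTLD + TM",
        "Secretory phospholipase A2 receptor",
        {"initial": 1.68, "transient": 0.48, "stable": 2.95},
    ),
    CuratedCandidate(
        "c108772_g2_i1_27-1786", "TSR", "TSR_other", "VWA + TSP1 + VWA",
        "Collagen alpha-5 chain",
        {"initial": 1.05, "transient": 2.00, "stable": -1.55},
    ),
    CuratedCandidate(
        "c126864_g2_i1_1-2228", "TSR", "semaphorin_plexin", "SEMA + PSI",
        "Plexin-B",
        {"initial": 1.33, "transient": 0.39, "stable": 0.72},
    ),
)

def embed_among_decoys(
    species: str, n_decoys: int = 1000, seed: int = 0
) -> tuple[dict, list[str]]:
    """Worked-example harness: the curated per-gene L2FC values embedded among
    *n_decoys* non-qualifying decoy genes.

    Decoys are constructed to fail the selection rule by definition — for the
    fed-vs-starvation designs at least one comparison is at or below the
    threshold of 1; for the staged design the initial-phase contrast is.
    Returns (l2fc_tables, expected_candidate_ids): running
    :func:`~kleptorecept.expression_de.select_candidates` on the tables must
    recover exactly the curated ids.
    """
    import numpy as np
    import pandas as pd

    entry = SPECIES_TABLES[species]
    comparisons = list(entry["comparisons"])
    candidates = entry["candidates"]
    rng = np.random.default_rng(seed)
    gene_ids = [c.gene_id for c in candidates] + [
        f"{species}_decoy{i:05d}" for i in range(n_decoys)
    ]
    values = {name: [] for name in comparisons}
    for c in candidates:
        for name in comparisons:
            values[name].append(c.l2fc[name])
    for _ in range(n_decoys):
        row = {name: float(rng.uniform(-4, 4)) for name in comparisons}
        if entry["design"] == "fed_vs_starvation":
            if all(v > 1.0 for v in row.values()):
                fail = comparisons[int(rng.integers(len(comparisons)))]
                row[fail] = float(rng.uniform(-4, 1.0))
        else:
            row["initial"] = float(rng.uniform(-4, 1.0))
        for name in comparisons:
            values[name].append(row[name])
    tables = {
        name: pd.Series(values[name], index=gene_ids, name=name)
        for name in comparisons
    }
    order = rng.permutation(len(gene_ids))
    tables = {name: s.iloc[order] for name, s in tables.items()}
    return tables, [c.gene_id for c in candidates]


SPECIES_TABLES: dict[str, dict] = {
    "e_cornigera": {
        "design": "fed_vs_starvation",
        "comparisons": E_CORNIGERA_COMPARISONS,
        "candidates": E_CORNIGERA_CANDIDATES,
    },
    "e_timida": {
        "design": "fed_vs_starvation",
        "comparisons": E_TIMIDA_COMPARISONS,
        "candidates": E_TIMIDA_CANDIDATES,
    },
    "e_chlorotica": {
        "design": "staged_juvenile",
        "comparisons": E_CHLOROTICA_COMPARISONS,
        "candidates": E_CHLOROTICA_CANDIDATES,
    },
}
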