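"""Expression analysis: low-count filtering, TMM/CPM normalization, log2
fold changes, and the all-comparisons candidate-selection rule.

The designs this module serves have either no biological replicates (adult
fed-vs-starvation series, one library per condition) or triplicates (staged
juvenile series).  With unreplicated libraries no dispersion can be
estimated, so significance is defined purely by effect size: a gene is
differentially expressed when |log2 fold change| exceeds a threshold
(default 1, i.e. a two-fold change).  No p-values are produced.

TMM (trimmed mean of M-values) normalization is computed in-repo following
the canonical definition: per-gene log2 ratios (M) and average log2
abundances (A) against a reference sample, genes with a zero in either
sample excluded, the M-distribution trimmed by 30% on each tail and the
A-distribution by 5%, and the surviving M-values averaged with inverse
asymptotic-variance weights.  Factors are rescaled to geometric mean 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import PipelineConfig

DESIGN_KINDS = ("fed_vs_starvation", "staged_juvenile")


class ExpressionError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Raw counts (genes x samples) plus per-sample normalization factors."""

    counts: pd.DataFrame  # non-negative integers
    norm_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ExpressionError("counts must be non-negative")
        if self.norm_factors is None:
            self.norm_factors = pd.Series(1.0, index=self.counts.columns)
        else:
            self.norm_factors = self.norm_factors.reindex(self.counts.columns)
            if self.norm_factors.isna().any() or (self.norm_factors <= 0).any():
                raise ExpressionError("norm factors must be positive and complete")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def effective_library_sizes(self) -> pd.Series:
        return self.library_sizes * self.norm_factors

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts=df)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene_id")


@dataclass(frozen=True)
class ComparisonDesign:
    """One named between-condition contrast (group_a vs group_b)."""

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    species_design: str = "fed_vs_starvation"

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ExpressionError(f"comparison {self.name!r}: empty group")
        if set(self.group_a) & set(self.group_b):
            raise ExpressionError(f"comparison {self.name!r}: groups overlap")
        if self.species_design not in DESIGN_KINDS:
            raise ExpressionError(
                f"comparison {self.name!r}: unknown design {self.species_design!r}"
            )


def filter_low_counts(m: CountMatrix, config: PipelineConfig | None = None) -> CountMatrix:
    """Keep genes with >= ``min_raw_count`` raw counts in >=
    ``min_samples_at_count`` samples (defaults: 100 counts in any 2 samples)."""
    config = config or PipelineConfig()
    ok = (m.counts >= config.min_raw_count).sum(axis=1) >= config.min_samples_at_count
    return CountMatrix(counts=m.counts.loc[ok].copy())


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    log_ratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> float:
    """TMM factor of one sample against the reference (canonical definition)."""
    mask = (obs > 0) & (ref > 0)
    o = obs[mask].astype(float)
    r = ref[mask].astype(float)
    if o.size == 0:
        return 1.0
    log_r = np.log2((o / lib_obs) / (r / lib_ref))
    abs_e = (np.log2(o / lib_obs) + np.log2(r / lib_ref)) / 2.0
    var = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    finite = np.isfinite(log_r) & np.isfinite(abs_e) & np.isfinite(var) & (var > 0)
    log_r, abs_e, var = log_r[finite], abs_e[finite], var[finite]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = math.floor(n * log_ratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = pd.Series(log_r).rank().to_numpy()
    rank_s = pd.Series(abs_e).rank().to_numpy()
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_s >= lo_s) & (rank_s <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / var[keep]) / np.sum(1.0 / var[keep])
    return float(2.0**f)


def tmm_factors(m: CountMatrix, reference_sample: str | None = None) -> pd.Series:
    """Per-sample TMM normalization factors, rescaled to geometric mean 1.

    The automatic reference is the sample whose upper-quartile count
    fraction is closest to the mean upper-quartile fraction.  A sample with
    all-zero counts is a hard error.
    """
    if m.counts.shape[1] < 2:
        raise ExpressionError("TMM needs at least two samples")
    lib = m.library_sizes
    if (lib == 0).any():
        zero = list(lib.index[lib == 0])
        raise ExpressionError(f"sample(s) with all-zero counts: {zero}")
    x = m.counts.to_numpy(dtype=float)
    if reference_sample is None:
        f75 = np.quantile(x / lib.to_numpy()[None, :], 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        if reference_sample not in m.sample_ids:
            raise ExpressionError(f"unknown reference sample {reference_sample!r}")
        ref_idx = m.sample_ids.index(reference_sample)
    ref = x[:, ref_idx]
    lib_ref = float(lib.iloc[ref_idx])
    factors = np.array(
        [
            1.0
            if j == ref_idx
            else _tmm_pair(x[:, j], ref, float(lib.iloc[j]), lib_ref)
            for j in range(x.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.counts.columns)


def normalize(m: CountMatrix, reference_sample: str | None = None) -> CountMatrix:
    """Return a copy of *m* with TMM factors attached."""
    return CountMatrix(counts=m.counts.copy(), norm_factors=tmm_factors(m, reference_sample))


def cpm(m: CountMatrix) -> pd.DataFrame:
    """Counts per million using effective library sizes."""
    eff = m.effective_library_sizes
    if (eff <= 0).any():
        raise ExpressionError("non-positive effective library size")
    return m.counts / eff * 1e6


def log2_fold_change(
    m: CountMatrix, design: ComparisonDesign, prior_count: float = 0.5
) -> pd.Series:
    """Per-gene L2FC = log2((meanCPM_a + prior) / (meanCPM_b + prior)).

    Group means are taken over CPM values (after normalization); with a
    single sample per group the mean is that sample's CPM.  The prior is a
    CPM-scale pseudo-offset guarding against division by zero.
    """
    missing = (set(design.group_a) | set(design.group_b)) - set(m.sample_ids)
    if missing:
        raise ExpressionError(
            f"comparison {design.name!r}: samples absent from matrix: {sorted(missing)}"
        )
    c = cpm(m)
    mean_a = c[list(design.group_a)].mean(axis=1)
    mean_b = c[list(design.group_b)].mean(axis=1)
    out = np.log2((mean_a + prior_count) / (mean_b + prior_count))
    out.name = design.name
    return out


def select_candidates(
    l2fc_tables: Mapping[str, pd.Series],
    design_kind: str,
    config: PipelineConfig | None = None,
    initial_comparison: str = "initial",
) -> list[str]:
    """Apply the candidate-selection rule to per-comparison L2FC tables.

    * ``fed_vs_starvation``: a gene is selected iff its L2FC exceeds the
      threshold in EVERY fed-vs-starved comparison (highly expressed while
      feeding, regardless of starvation length).
    * ``staged_juvenile``: the candidate set is the genes upregulated
      (L2FC > threshold) in the initial-phase comparison.
    """
    config = config or PipelineConfig()
    if not l2fc_tables:
        raise ExpressionError("no comparisons supplied")
    if design_kind == "fed_vs_starvation":
        table = pd.DataFrame(dict(l2fc_tables))
        selected = table.index[(table > config.l2fc_threshold).all(axis=1)]
        return list(selected)
    if design_kind == "staged_juvenile":
        if initial_comparison not in l2fc_tables:
            raise ExpressionError(
                f"missing comparison {initial_comparison!r} for the staged design"
            )
        init = l2fc_tables[initial_comparison]
        return list(init.index[init > config.l2fc_threshold])
    raise ExpressionError(f"unknown design kind {design_kind!r}")


def stage_regulation(
    l2fc_tables: Mapping[str, pd.Series], config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Per-stage up/down/unchanged calls for the staged-juvenile design."""
    config = config or PipelineConfig()
    table = pd.DataFrame(dict(l2fc_tables))
    calls = pd.DataFrame("unchanged", index=table.index, columns=table.columns)
    calls = calls.mask(table > config.l2fc_threshold, "up")
    calls = calls.mask(table < -config.l2fc_threshold, "down")
    return calls


def report_candidates(
    selected: Sequence[str],
    assignments: Mapping[str, object],
    annotations: Mapping[str, str],
    l2fc_tables: Mapping[str, pd.Series],
) -> pd.DataFrame:
    """Candidate table: receptor category, domain arrangement, gene id,
    annotation, one L2FC column per comparison; sorted by category then id.

    *assignments* maps gene id -> ReceptorAssignment (or any object with
    ``category`` and ``arrangement_string``); unassigned genes are reported
    as ``unclassified``.
    """
    rows = []
    for gid in selected:
        a = assignments.get(gid)
        row = {
            "category": getattr(a, "category", "unclassified") if a else "unclassified",
            "arrangement": getattr(a, "arrangement_string", "") if a else "",
            "gene_id": gid,
            "annotation": annotations.get(gid, ""),
        }
        for name, series in l2fc_tables.items():
            row[f"l2fc_{name}"] = float(series.get(gid, np.nan))
        rows.append(row)
    cols = ["category", "arrangement", "gene_id", "annotation"] + [
        f"l2fc_{n}" for n in l2fc_tables
    ]
    df = pd.DataFrame(rows, columns=cols)
    if not df.empty:
        df = df.sort_values(["category", "gene_id"]).reset_index(drop=True)
    return df


def full_l2fc_table(l2fc_tables: Mapping[str, pd.Series]) -> pd.DataFrame:
    """All genes x comparisons L2FC table (heat-map export)."""
    return pd.DataFrame(dict(l2fc_tables))


def read_design(path: str | Path) -> dict[str, str]:
    """Read a two-column sample -> condition TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "condition"], comment="#")
    return dict(zip(df["sample"].astype(str), df["condition"].astype(str)))


def comparisons_from_conditions(
    sample_conditions: Mapping[str, str], design_kind: str
) -> list[ComparisonDesign]:
    """Build the standard contrasts for a design from sample->condition labels.

    ``fed_vs_starvation``: condition ``fed`` vs each ``starved_*`` condition
    (one comparison per starvation period, named after the condition).
    ``staged_juvenile``: ``initial`` = fed5 vs apo, ``transient`` = fed7 vs
    fed5, ``stable`` = fed10 vs fed7.
    """
    groups: dict[str, list[str]] = {}
    for sample, cond in sample_conditions.items():
        groups.setdefault(cond, []).append(sample)
    if design_kind == "fed_vs_starvation":
        if "fed" not in groups:
            raise ExpressionError("fed_vs_starvation design needs a 'fed' condition")
        starved = sorted(c for c in groups if c != "fed")
        if not starved:
            raise ExpressionError("no starvation conditions found")
        return [
            ComparisonDesign(
                name=cond,
                group_a=tuple(groups["fed"]),
                group_b=tuple(groups[cond]),
                species_design="fed_vs_starvation",
            )
            for cond in starved
        ]
    if design_kind == "staged_juvenile":
        needed = {"apo", "fed5", "fed7", "fed10"}
        missing = needed - set(groups)
        if missing:
            raise ExpressionError(f"staged design missing conditions: {sorted(missing)}")
        pairs = [("initial", "fed5", "apo"), ("transient", "fed7", "fed5"), ("stable", "fed10", "fed7")]
        return [
            ComparisonDesign(
                name=name,
                group_a=tuple(sorted(groups[a])),
                group_b=tuple(sorted(groups[b])),
                species_design="staged_juvenile",
            )
            for name, a, b in pairs
        ]
    raise ExpressionError(f"unknown design kind {design_kind!r}")
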