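"""Low-count filter, TMM/CPM, log2 fold changes, candidate selection."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from kleptorecept.annotation_io import PipelineConfig
from kleptorecept.expression_de import (
    ComparisonDesign,
    CountMatrix,
    ExpressionError,
    cpm,
    filter_low_counts,
    log2_fold_change,
    normalize,
    report_candidates,
    select_candidates,
    tmm_factors,
)
from kleptorecept.receptor_classifier import ReceptorAssignment
from kleptorecept.synthetic_data import CountsPlan, generate_counts


def _matrix(data, samples=None):
    df = pd.DataFrame(data).T if isinstance(data, dict) else pd.DataFrame(data)
    if samples is not None:
        df.columns = samples
    return CountMatrix(counts=df)


# ---------------------------------------------------------------------------
# low-count filter


def test_gene_with_one_strong_sample_dropped(config):
    m = _matrix({"g": [99, 99, 200]})
    assert filter_low_counts(m, config).gene_ids == []


def test_gene_with_exactly_two_samples_at_threshold_kept(config):
    m = _matrix({"g": [100, 100, 0]})
    assert filter_low_counts(m, config).gene_ids == ["g"]


def test_filter_matches_per_gene_scan_oracle(config):
    rng = np.random.default_rng(3)
    counts = pd.DataFrame(
        rng.integers(0, 300, size=(200, 4)),
        index=[f"g{i}" for i in range(200)],
    )
    kept = set(filter_low_counts(CountMatrix(counts=counts), config).gene_ids)
    oracle = {
        g for g, row in counts.iterrows() if sum(v >= 100 for v in row) >= 2
    }
    assert kept == oracle


# ---------------------------------------------------------------------------
# TMM


def test_identical_columns_give_unit_factors():
    col = np.arange(1, 201)
    m = _matrix(pd.DataFrame({"a": col, "b": col}))
    f = tmm_factors(m)
    assert f.tolist() == [1.0, 1.0]


def test_pure_depth_difference_absorbed_by_library_size():
    col = np.arange(1, 201)
    m = _matrix(pd.DataFrame({"a": col, "b": 2 * col}))
    f = tmm_factors(m)
    np.testing.assert_allclose(f.to_numpy(), [1.0, 1.0], atol=1e-12)


def test_all_zero_sample_is_hard_error():
    m = _matrix(pd.DataFrame({"a": [1, 2, 3], "b": [0, 0, 0]}))
    with pytest.raises(ExpressionError, match="zero"):
        tmm_factors(m)


def _oracle_tmm(counts: pd.DataFrame) -> np.ndarray:
    """Independent TMM oracle: exhaustive summation, sort-based trimming."""
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    f75 = np.quantile(x / lib, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = []
    for j in range(x.shape[1]):
        if j == ref:
            factors.append(1.0)
            continue
        o, r = x[:, j], x[:, ref]
        keep = (o > 0) & (r > 0)
        o, r = o[keep], r[keep]
        M = np.log2((o / lib[j]) / (r / lib[ref]))
        A = 0.5 * (np.log2(o / lib[j]) + np.log2(r / lib[ref]))
        w = (lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r)
        n = len(M)
        mlo, mhi = int(np.floor(n * 0.3)), n - int(np.floor(n * 0.3))
        alo, ahi = int(np.floor(n * 0.05)), n - int(np.floor(n * 0.05))
        m_order = np.argsort(M, kind="stable")
        a_order = np.argsort(A, kind="stable")
        sel = set(m_order[mlo:mhi]) & set(a_order[alo:ahi])
        idx = np.array(sorted(sel))
        f = np.sum(M[idx] / w[idx]) / np.sum(1.0 / w[idx])
        factors.append(2.0**f)
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


def test_tmm_within_2pct_of_direct_formula_oracle():
    bundle = generate_counts(
        CountsPlan(rng_seed=21, n_genes=2000, n_planted_up=100, planted_log2_effect=2.5)
    )
    m = CountMatrix(counts=bundle.counts)
    mine = tmm_factors(m).to_numpy()
    oracle = _oracle_tmm(bundle.counts)
    np.testing.assert_allclose(mine, oracle, rtol=0.02)


def test_tmm_matches_edger_reference(tmp_path):
    """Cross-check against the canonical Bioconductor implementation."""
    bundle = generate_counts(
        CountsPlan(rng_seed=8, n_genes=500, n_planted_up=25,
                   design="fed_vs_starvation", n_starvation_conditions=2)
    )
    counts_path = tmp_path / "c.tsv"
    bundle.counts.to_csv(counts_path, sep="\t")
    script = tmp_path / "tmm.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(edgeR))
        x <- as.matrix(read.delim("{counts_path}", row.names=1))
        cat(calcNormFactors(DGEList(counts=x))$samples$norm.factors, sep="\\n")
    """))
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, check=True
    )
    reference = np.array([float(v) for v in out.stdout.split()])
    mine = tmm_factors(CountMatrix(counts=bundle.counts)).to_numpy()
    np.testing.assert_allclose(mine, reference, rtol=1e-6)


# ---------------------------------------------------------------------------
# log2 fold change


def test_equal_groups_give_zero_l2fc():
    m = _matrix(pd.DataFrame({"a": [50, 100], "b": [50, 100]}))
    d = ComparisonDesign(name="c", group_a=("a",), group_b=("b",))
    np.testing.assert_allclose(log2_fold_change(m, d).to_numpy(), 0.0, atol=1e-12)


def test_fourfold_cpm_gives_l2fc_two():
    # equal library sizes; gene g0 has 4x the CPM in a vs b
    m = _matrix(pd.DataFrame({"a": [4000, 96000], "b": [1000, 99000]}))
    d = ComparisonDesign(name="c", group_a=("a",), group_b=("b",))
    val = log2_fold_change(m, d, prior_count=1e-9)["g0" if "g0" in m.gene_ids else 0]
    assert val == pytest.approx(2.0, abs=1e-6)


def test_l2fc_matches_direct_formula_oracle():
    rng = np.random.default_rng(17)
    counts = pd.DataFrame(
        rng.integers(1, 5000, size=(100, 4)),
        index=[f"g{i}" for i in range(100)],
        columns=["a1", "a2", "b1", "b2"],
    )
    m = normalize(CountMatrix(counts=counts))
    d = ComparisonDesign(name="c", group_a=("a1", "a2"), group_b=("b1", "b2"))
    got = log2_fold_change(m, d, prior_count=0.5)
    eff = (counts.sum(axis=0) * m.norm_factors).to_numpy()
    for i, g in enumerate(counts.index):
        cpm_vals = counts.loc[g].to_numpy() / eff * 1e6
        expect = np.log2((cpm_vals[:2].mean() + 0.5) / (cpm_vals[2:].mean() + 0.5))
        assert got[g] == pytest.approx(expect, abs=1e-10)


def test_empty_group_rejected():
    with pytest.raises(ExpressionError):
        ComparisonDesign(name="c", group_a=(), group_b=("b",))


# ---------------------------------------------------------------------------
# candidate selection


def test_gene_passing_every_comparison_selected(config):
    tables = {
        "starved_d4": pd.Series({"g": 2.41, "h": 2.5}),
        "starved_d7": pd.Series({"g": 1.43, "h": 0.8}),
    }
    assert select_candidates(tables, "fed_vs_starvation", config) == ["g"]


def test_staged_design_selects_initial_upregulated(config):
    tables = {
        "initial": pd.Series({"g": 2.02, "h": 0.5}),
        "transient": pd.Series({"g": -2.12, "h": 3.0}),
        "stable": pd.Series({"g": 1.33, "h": 3.0}),
    }
    assert select_candidates(tables, "staged_juvenile", config) == ["g"]


def test_missing_comparison_named_in_error(config):
    tables = {"transient": pd.Series({"g": 2.0})}
    with pytest.raises(ExpressionError, match="initial"):
        select_candidates(tables, "staged_juvenile", config)


def test_selection_monotone_in_threshold():
    rng = np.random.default_rng(2)
    genes = [f"g{i}" for i in range(300)]
    tables = {
        c: pd.Series(rng.uniform(-3, 3, size=300), index=genes)
        for c in ("starved_d4", "starved_d7")
    }
    prev = None
    for thr in (0.5, 1.0, 1.5, 2.0):
        sel = set(select_candidates(tables, "fed_vs_starvation",
                                    PipelineConfig(l2fc_threshold=thr)))
        if prev is not None:
            assert sel <= prev
        prev = sel


def test_planted_effect3_recovery_in_unreplicated_design(config):
    plan = CountsPlan(rng_seed=19, planted_log2_effect=3.0, n_planted_up=20,
                      design="fed_vs_starvation", n_starvation_conditions=2)
    bundle = generate_counts(plan)
    m = normalize(filter_low_counts(CountMatrix(counts=bundle.counts), config))
    tables = {
        cond: log2_fold_change(
            m, ComparisonDesign(name=cond, group_a=("fed",), group_b=(cond,))
        )
        for cond in ("starved_d4", "starved_d7")
    }
    sel = set(select_candidates(tables, "fed_vs_starvation", config))
    assert len(sel & set(bundle.truth_up)) >= 19


def test_sensitivity_and_false_selection_in_triplicated_design(config):
    plan = CountsPlan(rng_seed=29, design="staged_juvenile",
                      planted_log2_effect=2.0, n_genes=1000, n_planted_up=20)
    bundle = generate_counts(plan)
    m = normalize(filter_low_counts(CountMatrix(counts=bundle.counts), config))
    groups = {}
    for s, c in bundle.sample_conditions.items():
        groups.setdefault(c, []).append(s)
    tables = {
        "initial": log2_fold_change(
            m, ComparisonDesign("initial", tuple(groups["fed5"]), tuple(groups["apo"]),
                                "staged_juvenile")
        )
    }
    sel = set(select_candidates(tables, "staged_juvenile", config))
    truth = set(bundle.truth_up) & set(m.gene_ids)
    sensitivity = len(sel & truth) / len(truth)
    false_rate = len(sel - truth) / max(1, len(m.gene_ids) - len(truth))
    assert sensitivity >= 0.95
    assert false_rate <= 0.05


# ---------------------------------------------------------------------------
# reporting


def test_candidate_table_single_sr_b_row():
    tables = {"starved_d4": pd.Series({"g1": 2.41}), "starved_d7": pd.Series({"g1": 1.43})}
    assign = {
        "g1": ReceptorAssignment(
            protein_id="g1", category="SR_B", matched_rule="SR-B",
            arrangement_string="TM + CD36 + TM",
        )
    }
    df = report_candidates(["g1"], assign, {"g1": "Scavenger receptor class B member 1"}, tables)
    assert len(df) == 1
    row = df.iloc[0]
    assert row["category"] == "SR_B"
    assert row["arrangement"] == "TM + CD36 + TM"
    assert row["l2fc_starved_d4"] == pytest.approx(2.41)


def test_empty_selection_yields_header_only_table():
    df = report_candidates([], {}, {}, {"c": pd.Series(dtype=float)})
    assert df.empty
    assert list(df.columns) == ["category", "arrangement", "gene_id", "annotation", "l2fc_c"]


def test_unassigned_gene_reported_as_unclassified():
    tables = {"c": pd.Series({"g": 2.0})}
    df = report_candidates(["g"], {}, {}, tables)
    assert df.iloc[0]["category"] == "unclassified"
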