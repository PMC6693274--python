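"""Differential segment usage and differential PSI testing."""

import numpy as np
import pandas as pd
import pytest

from txseg.differential import DesignSpec, export_for_dexseq, size_factors
from txseg.differential import test_differential_psi as diff_psi_test
from txseg.differential import (
    test_differential_segment_usage as usage_test,
)
from txseg.fixtures import simulate_usage_counts
from txseg.quantification import PsiTable, SegmentCountMatrix


def _design(n=3):
    samples = [f"s{i}" for i in range(2 * n)]
    return DesignSpec(samples, ["a"] * n + ["b"] * n)


def test_single_condition_design_is_rejected():
    with pytest.raises(ValueError, match="two condition"):
        DesignSpec(["a", "b", "c", "d"], ["x", "x", "x", "x"])
    with pytest.raises(ValueError, match=">=2 samples"):
        DesignSpec(["a", "b", "c"], ["x", "x", "y"])


def test_benjamini_hochberg_matches_textbook_stepup():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(0)
    p = rng.uniform(size=57)
    got = multipletests(p, method="fdr_bh")[1]
    # direct step-up definition
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    assert np.allclose(got, adj)


def test_single_segment_gene_is_excluded_from_usage_testing():
    scm, segments, design, _ = simulate_usage_counts(
        5, seed=1, segments_per_gene=1
    )
    res = usage_test(scm, segments, design)
    assert len(res.gene_table) == 0
    assert len(res.skipped_genes) == 5


def test_all_zero_gene_is_skipped_with_flag():
    scm, segments, design, _ = simulate_usage_counts(3, seed=2)
    scm.counts.loc[[s.seg_id for s in segments if s.gene_id == "sim0001"]] = 0
    res = usage_test(scm, segments, design)
    assert "sim0001" in res.skipped_genes
    assert len(res.gene_table) == 2


def test_null_usage_simulation_controls_type_one_error():
    scm, segments, design, _ = simulate_usage_counts(
        150, seed=11, flagged_fraction=0.0
    )
    res = usage_test(scm, segments, design)
    frac = (res.gene_table["qvalue"] < 0.05).mean()
    assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(res.gene_table))


def test_switch_simulation_ranks_flagged_genes_first():
    scm, segments, design, flagged = simulate_usage_counts(
        150, seed=7, flagged_fraction=0.5
    )
    res = usage_test(scm, segments, design)
    tab = res.gene_table.set_index("gene_id")
    y = np.array([g in set(flagged) for g in tab.index])
    score = -tab["pvalue"].values
    # area under ROC by rank statistic
    order = np.argsort(score)
    ranks = np.empty(len(score))
    ranks[order] = np.arange(1, len(score) + 1)
    auc = (ranks[y].sum() - y.sum() * (y.sum() + 1) / 2) / (
        y.sum() * (~y).sum()
    )
    assert auc > 0.9


def test_permuting_condition_labels_destroys_signal():
    scm, segments, design, flagged = simulate_usage_counts(
        100, seed=19, flagged_fraction=0.5
    )
    rng = np.random.default_rng(0)
    perm = list(rng.permutation(design.condition))
    # balanced permutation across the original groups
    while perm[:3].count("a") != 2:
        perm = list(rng.permutation(design.condition))
    pdesign = DesignSpec(design.sample_ids, perm)
    res = usage_test(scm, segments, pdesign)
    frac = (res.gene_table["qvalue"] < 0.05).mean()
    assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(res.gene_table))


def test_nb_glm_approaches_poisson_at_vanishing_dispersion():
    import statsmodels.api as sm

    rng = np.random.default_rng(3)
    y = rng.poisson(30, size=12).astype(float)
    X = np.column_stack([np.ones(12), np.repeat([0.0, 1.0], 6)])
    pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    nb = sm.GLM(
        y, X, family=sm.families.NegativeBinomial(alpha=1e-8)
    ).fit()
    assert np.isclose(pois.deviance, nb.deviance, rtol=1e-4)
    assert np.allclose(pois.params, nb.params, atol=1e-5)


def test_identical_psi_across_conditions_gives_p_one():
    design = _design()
    psi = pd.DataFrame(
        [[0.4] * 6], index=["e1"], columns=design.sample_ids
    )
    res = diff_psi_test(PsiTable(psi, None, None), design)
    assert res.loc[0, "pvalue"] == 1.0
    assert bool(res.loc[0, "degenerate"])


def test_null_psi_simulation_has_nominal_type_one_error():
    rng = np.random.default_rng(5)
    design = _design()
    n_ev = 1000
    psi = pd.DataFrame(
        np.clip(rng.normal(0.5, 0.08, size=(n_ev, 6)), 0, 1),
        index=[f"e{i}" for i in range(n_ev)],
        columns=design.sample_ids,
    )
    res = diff_psi_test(PsiTable(psi, None, None), design)
    frac = (res["pvalue"] < 0.05).mean()
    assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_ev)


def test_injected_delta_psi_is_detected_with_high_power():
    rng = np.random.default_rng(6)
    design = _design()
    n_ev = 200
    base = np.clip(rng.normal(0.4, 0.05, size=(n_ev, 6)), 0, 1)
    base[:, 3:] += 0.3
    psi = pd.DataFrame(
        np.clip(base, 0, 1),
        index=[f"e{i}" for i in range(n_ev)],
        columns=design.sample_ids,
    )
    res = diff_psi_test(PsiTable(psi, None, None), design)
    assert (res["qvalue"] < 0.05).mean() > 0.9


def test_events_with_too_few_defined_psi_are_degenerate():
    design = _design()
    vals = [[0.2, np.nan, np.nan, 0.8, 0.9, 0.7]]
    psi = pd.DataFrame(vals, index=["e1"], columns=design.sample_ids)
    res = diff_psi_test(PsiTable(psi, None, None), design)
    assert bool(res.loc[0, "degenerate"])


def test_size_factors_are_one_for_identical_columns():
    counts = pd.DataFrame(
        {"a": [10, 20, 30], "b": [10, 20, 30]}, index=["x", "y", "z"]
    )
    sf = size_factors(counts)
    assert np.allclose(sf.values, 1.0)


def test_dexseq_export_toy_gene(tmp_path, toy_segments):
    counts = pd.DataFrame(
        [[5], [6], [7], [8]],
        index=[s.seg_id for s in toy_segments],
        columns=["s1"],
    )
    scm = SegmentCountMatrix(counts)
    gff, files = export_for_dexseq(scm, toy_segments, tmp_path / "dex")
    gff_lines = open(gff).read().splitlines()
    assert sum(1 for l in gff_lines if "\taggregate_gene\t" in l) == 1
    parts = [l for l in gff_lines if "\texonic_part\t" in l]
    assert len(parts) == 4
    (cf,) = files
    keys = [l.split("\t")[0] for l in open(cf).read().splitlines()]
    assert keys == [f"G:{s.seg_id}" for s in toy_segments]


def test_dexseq_export_empty_matrix(tmp_path):
    counts = pd.DataFrame(index=pd.Index([], name="seg_id"), columns=["s1"])
    scm = SegmentCountMatrix(counts.astype(int))
    gff, files = export_for_dexseq(scm, [], tmp_path / "dex")
    assert open(gff).read() == ""
    assert open(files[0]).read() == ""
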