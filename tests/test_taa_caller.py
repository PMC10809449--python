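"""Gene-level TPM aggregation and the dual-threshold TAA rule."""

import numpy as np
import pandas as pd
import pytest

from oran.taa_caller import (
    ExpressionMatrix,
    call_taas,
    gene_tpm,
    load_expression_tsv,
)


def _matrix(values, gene_map: dict, group: str) -> ExpressionMatrix:
    df = (values.copy() if isinstance(values, pd.DataFrame)
          else pd.DataFrame(values, index=list(gene_map)))
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ExpressionMatrix(df, pd.Series(gene_map),
                                {c: group for c in df.columns})


GENES = {"t1": "gA", "t2": "gA", "t3": "gB"}


def test_gene_tpm_is_isoform_sum():
    m = _matrix({"n1": [0.4, 0.5, 2.0]},
                GENES, "normal")
    g = gene_tpm(m)
    assert g.loc["gA", "n1"] == pytest.approx(0.9)
    assert g.loc["gB", "n1"] == pytest.approx(2.0)  # single isoform


def test_gene_absent_everywhere_is_zero():
    m = _matrix({"n1": [0.0, 0.0, 1.0]}, GENES, "normal")
    assert gene_tpm(m).loc["gA", "n1"] == 0.0


def _pair(tumor_vals, normal_cols):
    tumor = _matrix({"tum1": tumor_vals}, GENES, "tumor")
    normal = _matrix(normal_cols, GENES, "normal")
    return tumor, normal


class TestCallTaas:
    def test_called_when_silent_in_all_normals(self):
        tumor, normal = _pair([1.5, 0.0, 0.0],
                              {"n1": [0.3, 0.2, 5.0], "n2": [0.4, 0.4, 5.0]})
        calls = {c.transcript_id: c for c in call_taas(tumor, normal)}
        assert calls["t1"].passed
        assert calls["t1"].max_normal_gene_tpm == pytest.approx(0.8)

    def test_one_hot_normal_rejects(self):
        tumor, normal = _pair([1.5, 0.0, 0.0],
                              {"n1": [1.2, 0.0, 0.0], "n2": [0.1, 0.0, 0.0]})
        calls = {c.transcript_id: c for c in call_taas(tumor, normal)}
        assert not calls["t1"].passed

    def test_tumor_boundary_strict(self):
        tumor, normal = _pair([1.0, 0.0, 0.0], {"n1": [0.1, 0.1, 0.0]})
        calls = {c.transcript_id: c for c in call_taas(tumor, normal)}
        assert not calls["t1"].passed

    def test_isoform_sum_rule_rejects(self):
        # each sibling isoform is below 1 in the normal but the gene sum
        # reaches 1.2, so the tumor-high isoform must not be called
        tumor, normal = _pair([2.0, 0.0, 0.0], {"n1": [0.6, 0.6, 0.0]})
        calls = {c.transcript_id: c for c in call_taas(tumor, normal)}
        assert not calls["t1"].passed
        assert calls["t1"].max_normal_gene_tpm == pytest.approx(1.2)

    def test_empty_normal_panel_is_error(self):
        tumor, normal = _pair([2.0, 0.0, 0.0], {"n1": [0.0, 0.0, 0.0]})
        normal.values = normal.values.drop(columns="n1")
        with pytest.raises(ValueError):
            call_taas(tumor, normal)

    def test_union_aggregation_uses_any_replicate(self):
        tumor = _matrix({"tum1": [0.5, 0, 0], "tum2": [1.4, 0, 0]},
                        GENES, "tumor")
        normal = _matrix({"n1": [0.1, 0.1, 0.0]}, GENES, "normal")
        mean_calls = {c.transcript_id: c.passed
                      for c in call_taas(tumor, normal, aggregation="mean")}
        union_calls = {c.transcript_id: c.passed
                       for c in call_taas(tumor, normal, aggregation="union")}
        assert not mean_calls["t1"]  # mean 0.95 fails
        assert union_calls["t1"]     # max 1.4 passes
        assert call_taas(tumor, normal)[0].replicate_pass_pattern == \
            (False, True)


def _random_pair(rng, n_genes=6, n_iso=2, n_tumor=3, n_normal=5):
    tids, gmap = [], {}
    for g in range(n_genes):
        for i in range(n_iso):
            tid = f"t{g}_{i}"
            tids.append(tid)
            gmap[tid] = f"g{g}"
    tumor = _matrix(
        {f"tum{j}": rng.exponential(1.0, len(tids)) for j in range(n_tumor)},
        gmap, "tumor")
    normal = _matrix(
        {f"n{j}": rng.exponential(0.8, len(tids)) for j in range(n_normal)},
        gmap, "normal")
    return tumor, normal


def naive_taa_oracle(tumor, normal):
    """Double-loop restatement of the rule, independent of pandas ops."""
    passed = set()
    for tid in tumor.values.index:
        gid = tumor.gene_map[tid]
        mean_tumor = float(np.mean(tumor.values.loc[tid]))
        ok = mean_tumor > 1.0
        for col in normal.values.columns:
            gene_sum = sum(
                float(normal.values.loc[other, col])
                for other in normal.values.index
                if normal.gene_map[other] == gid)
            if gene_sum >= 1.0:
                ok = False
        if ok:
            passed.add(tid)
    return passed


def test_matches_naive_oracle_on_random_matrices():
    rng = np.random.default_rng(17)
    for _ in range(30):
        tumor, normal = _random_pair(rng)
        got = {c.transcript_id for c in call_taas(tumor, normal) if c.passed}
        assert got == naive_taa_oracle(tumor, normal)


def test_monotonicity_in_normal_and_tumor_values():
    rng = np.random.default_rng(23)
    tumor, normal = _random_pair(rng)
    base = {c.transcript_id for c in call_taas(tumor, normal) if c.passed}
    # raising any normal value never adds a call
    normal2 = _matrix(normal.values * 3.0, normal.gene_map.to_dict(),
                      "normal")
    after = {c.transcript_id for c in call_taas(tumor, normal2) if c.passed}
    assert after <= base
    # raising one tumor transcript never removes another's call
    tumor2 = _matrix(tumor.values.copy(), tumor.gene_map.to_dict(), "tumor")
    boosted = tumor2.values.index[0]
    tumor2.values.loc[boosted] += 100.0
    after_t = {c.transcript_id for c in call_taas(tumor2, normal)
               if c.passed}
    assert base - {boosted} <= after_t


def test_load_expression_tsv_roundtrip(tmp_path):
    path = tmp_path / "expr.tsv"
    path.write_text(
        "transcript_id\tgene_id\ts1\ts2\n"
        "t1\tgA\t1.5\t2.0\n"
        "t2\tgA\t0.1\t0.2\n")
    groups = tmp_path / "samples.tsv"
    groups.write_text("s1\ttumor\ns2\tnormal\n")
    m = load_expression_tsv(path, groups)
    assert m.values.loc["t1", "s2"] == 2.0
    assert m.groups == {"s1": "tumor", "s2": "normal"}
    with pytest.raises(ValueError, match="first two columns"):
        bad = tmp_path / "bad.tsv"
        bad.write_text("foo\tbar\ts1\nx\ty\t1\n")
        load_expression_tsv(bad)
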