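"""Scoring engine: filter, composite gene score, cell-type score, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clustercall import (
    CellTypeAnnotator,
    annotate,
    celltype_scores,
    filter_markers,
    gene_score,
    select_top_n,
    to_indicator,
)
from clustercall.markerdb import IndicatorMatrix

from conftest import make_db


def brute_force_celltype_scores(rows, memberships):
    """Independent triple-loop evaluation of S_c = (1/I_k) * sum_i S_i * d_ic.

    rows: list of (cluster, gene, s_gene); memberships: set of (gene, cell_type).
    Returns {(cluster, cell_type): score}.
    """
    clusters = list(dict.fromkeys(c for c, _, _ in rows))
    cell_types = sorted({ct for _, ct in memberships})
    out = {}
    for k in clusters:
        genes = [(g, s) for c, g, s in rows if c == k]
        for ct in cell_types:
            total = 0.0
            for g, s in genes:
                d = 1 if (g, ct) in memberships else 0
                total += s * d
            out[(k, ct)] = total / len(genes)
    return out


class TestFilter:
    def test_boundary_rows_dropped(self):
        t = pd.DataFrame(
            {
                "cluster": ["0"] * 4,
                "gene": ["A", "B", "C", "D"],
                "avg_log2fc": [1.0] * 4,
                "pct_in": [0.25, 0.30, 0.30, 0.26],
                "pct_out": [0.1] * 4,
                "p_adj": [0.01, 0.05, 0.01, 0.049],
            }
        )
        kept = filter_markers(t)
        # pct_in == 0.25 dropped (strict >); p_adj == 0.05 dropped (strict <)
        assert kept["gene"].tolist() == ["C", "D"]
        assert kept.attrs["i_k"] == {"0": 2}

    def test_brute_force_row_scan(self):
        rng = np.random.default_rng(5)
        t = pd.DataFrame(
            {
                "cluster": [str(i % 3) for i in range(10)],
                "gene": [f"G{i}" for i in range(10)],
                "avg_log2fc": rng.normal(size=10),
                "pct_in": rng.uniform(0.1, 0.9, 10),
                "pct_out": rng.uniform(0, 0.5, 10),
                "p_adj": rng.uniform(0, 0.2, 10),
            }
        )
        kept = filter_markers(t)
        expect = [
            g
            for g, p, a in zip(t["gene"], t["pct_in"], t["p_adj"])
            if p > 0.25 and a < 0.05
        ]
        assert kept["gene"].tolist() == expect  # exact rows, input order preserved

    def test_emptied_cluster_flagged_not_error(self):
        t = pd.DataFrame(
            {
                "cluster": ["0", "1"],
                "gene": ["A", "B"],
                "avg_log2fc": [1.0, 1.0],
                "pct_in": [0.5, 0.1],
                "pct_out": [0.1, 0.1],
                "p_adj": [0.01, 0.01],
            }
        )
        kept = filter_markers(t)
        assert kept.attrs["i_k"] == {"0": 1, "1": 0}

    def test_duplicate_cluster_gene_rejected(self):
        t = pd.DataFrame(
            {
                "cluster": ["0", "0"],
                "gene": ["A", "A"],
                "avg_log2fc": [1.0, 2.0],
                "pct_in": [0.5, 0.6],
                "pct_out": [0.1, 0.1],
                "p_adj": [0.01, 0.01],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            filter_markers(t)

    def test_malformed_row_named(self):
        t = pd.DataFrame(
            {
                "cluster": ["0"],
                "gene": ["A"],
                "avg_log2fc": [np.inf],
                "pct_in": [0.5],
                "pct_out": [0.1],
                "p_adj": [0.01],
            }
        )
        with pytest.raises(ValueError, match="cluster '0'"):
            filter_markers(t)


class TestGeneScore:
    def test_identity_when_fold_and_prevalence_cancel(self):
        for x in (0.1, 0.5, 1.0):
            assert gene_score(0.0, x, x) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        assert gene_score(1.0, 0.5, 0.25) == pytest.approx(4.0)

    def test_zero_pct_out_floored(self):
        assert gene_score(2.0, 0.8, 0.0, zero_floor=0.001) == pytest.approx(3200.0)

    def test_log_decomposition(self):
        # log S = log fold change + log prevalence ratio
        s = gene_score(1.7, 0.6, 0.2)
        assert np.log2(s) == pytest.approx(1.7 + np.log2(0.6 / 0.2))

    def test_zero_pct_in_rejected(self):
        with pytest.raises(ValueError):
            gene_score(1.0, 0.0, 0.1)


class TestCellTypeScores:
    def _indicator(self, memberships, genes, cell_types):
        d = np.zeros((len(genes), len(cell_types)), dtype=np.int8)
        for g, ct in memberships:
            d[genes.index(g), cell_types.index(ct)] = 1
        return IndicatorMatrix(
            tuple(genes), tuple(("t", c) for c in cell_types), d
        )

    def test_full_and_partial_match(self):
        scores = pd.DataFrame(
            {"cluster": ["k", "k"], "gene": ["A", "B"], "s_gene": [4.0, 2.0]}
        )
        ind = self._indicator([("A", "X"), ("B", "X"), ("A", "Y")], ["A", "B"], ["X", "Y"])
        mat = celltype_scores(scores, ind)
        frame = mat.to_frame()
        assert frame.loc["k", ("t", "X")] == pytest.approx(3.0)  # (4+2)/2
        assert frame.loc["k", ("t", "Y")] == pytest.approx(2.0)  # 4/2, I_k stays 2

    def test_unmatched_genes_zero_row(self):
        scores = pd.DataFrame({"cluster": ["k"], "gene": ["ZZZ"], "s_gene": [9.0]})
        ind = self._indicator([("A", "X")], ["A"], ["X"])
        mat = celltype_scores(scores, ind)
        assert (mat.s == 0).all() and mat.i_k[0] == 1

    def test_oracle_equivalence_random_instances(self):
        """Matrix implementation equals triple-loop evaluation exactly."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n_k = rng.integers(1, 7)
            n_g = rng.integers(1, 13)
            n_c = rng.integers(1, 9)
            genes = [f"G{i}" for i in range(n_g)]
            cell_types = [f"C{j}" for j in range(n_c)]
            memberships = {
                (g, c) for g in genes for c in cell_types if rng.random() < 0.3
            }
            # every cell type needs >= 1 marker for a valid indicator
            for c in cell_types:
                if not any(m[1] == c for m in memberships):
                    memberships.add((genes[int(rng.integers(n_g))], c))
            rows = []
            for k in range(n_k):
                for g in rng.choice(genes, size=rng.integers(1, n_g + 1), replace=False):
                    # dyadic rationals: exact under any summation order
                    rows.append((f"k{k}", g, float(rng.integers(1, 2**20)) / 1024.0))
            scores = pd.DataFrame(rows, columns=["cluster", "gene", "s_gene"])
            ind = self._indicator(sorted(memberships), genes, cell_types)
            mat = celltype_scores(scores, ind)
            oracle = brute_force_celltype_scores(rows, {(g, ("t", c)) for g, c in memberships})
            frame = mat.to_frame()
            for (k, ct), v in oracle.items():
                assert frame.loc[k, ct] == v  # exact, same float operations order-free

    def test_scale_covariance(self):
        scores = pd.DataFrame(
            {"cluster": ["k"] * 3, "gene": ["A", "B", "C"], "s_gene": [4.0, 2.0, 1.0]}
        )
        ind = self._indicator([("A", "X"), ("B", "Y"), ("C", "Y")], ["A", "B", "C"], ["X", "Y"])
        base = celltype_scores(scores, ind).s
        scaled = scores.assign(s_gene=scores["s_gene"] * 7.5)
        assert celltype_scores(scaled, ind).s == pytest.approx(7.5 * base)

    def test_monotonicity_added_marker(self):
        scores = pd.DataFrame(
            {"cluster": ["k"] * 2, "gene": ["A", "B"], "s_gene": [4.0, 2.0]}
        )
        ind0 = self._indicator([("A", "X"), ("B", "Y")], ["A", "B"], ["X", "Y"])
        ind1 = self._indicator(
            [("A", "X"), ("B", "X"), ("B", "Y")], ["A", "B"], ["X", "Y"]
        )
        s0, s1 = celltype_scores(scores, ind0).s[0], celltype_scores(scores, ind1).s[0]
        assert s1[0] > s0[0]  # X gained marker B
        assert s1[1] == s0[1]  # Y untouched

    def test_denominator_semantics(self):
        """An unmatched retained gene shrinks every score, preserves ranking."""
        ind = self._indicator([("A", "X"), ("B", "Y")], ["A", "B"], ["X", "Y"])
        base = pd.DataFrame({"cluster": ["k"] * 2, "gene": ["A", "B"], "s_gene": [4.0, 2.0]})
        plus = pd.concat(
            [base, pd.DataFrame({"cluster": ["k"], "gene": ["ZZ"], "s_gene": [1.0]})],
            ignore_index=True,
        )
        s0, s1 = celltype_scores(base, ind).s[0], celltype_scores(plus, ind).s[0]
        assert (s1 < s0).all()
        assert np.argsort(s0).tolist() == np.argsort(s1).tolist()


class TestSelectTopN:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ([10, 1, 0.5], 1),   # dominant leader
            ([5, 5, 0.1], 2),    # similar evidence co-assigned
            ([3, 0, 0], 1),      # single positive score
            ([4, 4, 4], 1),      # no gap at all: ties break toward smaller n
            ([0, 0, 0], 0),      # nothing to assign
            ([7], 1),
        ],
    )
    def test_examples(self, scores, expected):
        assert select_top_n(scores) == expected

    def test_max_n_cap(self):
        assert select_top_n([9, 8.9, 8.8, 8.7, 0.1], max_n=3) == 3
        assert select_top_n([9, 8.9, 8.8, 8.7, 0.1], max_n=10) == 4

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            select_top_n([1, 5, 2])

    def test_agrees_with_exhaustive_gap_enumeration(self):
        """Compare against a naive scan on all sorted vectors over a value grid."""
        from itertools import combinations_with_replacement

        grid = [0.0, 0.5, 1.0, 2.0, 10.0]
        for length in range(1, 7):
            for combo in combinations_with_replacement(grid, length):
                s = sorted(combo, reverse=True)
                pos = [x for x in s if x > 0]
                if not pos:
                    assert select_top_n(s, max_n=6) == 0
                    continue
                m_max = min(len(pos), len(s) - 1)
                if m_max < 1:
                    expected = 1
                else:
                    gaps = [s[m - 1] - s[m] for m in range(1, m_max + 1)]
                    expected = min(int(np.argmax(gaps)) + 1, 6)
                assert select_top_n(s, max_n=6) == expected


class TestAnnotate:
    def test_planted_fixture_top1(self, pancreas_db, marker_table):
        res = annotate(marker_table, pancreas_db)
        assert res.assignments["c0"] == "beta cell"
        assert res.assignments["c1"] == "alpha cell"
        # noise genes failed the filter: I_k excludes them
        assert res.i_k.tolist() == [2, 2]

    def test_planted_truth_synthetic(self, scenario):
        _, db, truth, table = scenario
        res = annotate(table, db)
        for cl, _, ct, _ in truth.table.itertuples(index=False):
            assert res.assignments[cl] == ct

    def test_cluster_permutation_invariance(self, scenario):
        _, db, _, table = scenario
        a = annotate(table, db)
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        b = annotate(shuffled, db)
        assert a.assignments.sort_index().equals(b.assignments.sort_index())
        cols = ["cluster", "rank", "tissue", "cell_type", "score"]
        pd.testing.assert_frame_equal(
            a.ranked[cols].sort_values(cols).reset_index(drop=True),
            b.ranked[cols].sort_values(cols).reset_index(drop=True),
        )

    def test_tissue_restriction_noop_single_tissue(self, scenario):
        _, db, _, table = scenario
        full = annotate(table, db)
        restricted = annotate(table, db, tissue="tissue01")
        assert full.assignments.equals(restricted.assignments)

    def test_normalized_score_unit_max(self, scenario):
        _, db, _, table = scenario
        res = annotate(table, db)
        top = res.ranked.groupby("cluster")["normalized_score"].max()
        assert (top == 1.0).all()
        assert res.ranked["normalized_score"].between(0, 1).all()

    def test_selected_is_prefix_of_ranking(self, scenario):
        _, db, _, table = scenario
        res = annotate(table, db)
        for _, grp in res.ranked.groupby("cluster"):
            sel = grp.sort_values("rank")["selected"].tolist()
            assert sel == sorted(sel, reverse=True)  # True block first
            assert 1 <= sum(sel) <= 3

    def test_evidence_genes_are_markers(self, scenario):
        _, db, _, table = scenario
        res = annotate(table, db)
        members = {
            (t, c, g)
            for t, c, g in db.records[["tissue", "cell_type", "gene_key"]].itertuples(index=False)
        }
        assert len(res.evidence) > 0
        for _, t, c, g, s in res.evidence.itertuples(index=False):
            assert (t, c, g.upper()) in members
            assert s > 0

    def test_no_database_overlap_warns_all_unassigned(self, pancreas_db):
        t = pd.DataFrame(
            {
                "cluster": ["0"],
                "gene": ["NOTAGENE"],
                "avg_log2fc": [2.0],
                "pct_in": [0.8],
                "pct_out": [0.1],
                "p_adj": [1e-5],
            }
        )
        with pytest.warns(UserWarning, match="no overlap"):
            res = annotate(t, pancreas_db)
        assert res.assignments["0"] == "unassigned"
        assert "0" in res.unassigned

    def test_all_filtered_cluster_unassigned_with_reason(self, pancreas_db):
        t = pd.DataFrame(
            {
                "cluster": ["0", "1"],
                "gene": ["INS", "GCG"],
                "avg_log2fc": [2.0, 2.0],
                "pct_in": [0.8, 0.1],  # cluster 1 fails the filter
                "pct_out": [0.05, 0.05],
                "p_adj": [1e-5, 1e-5],
            }
        )
        res = annotate(t, pancreas_db)
        assert res.assignments["1"] == "unassigned"
        assert "filter" in res.unassigned["1"]

    @given(lam=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_ranking_scale_invariance(self, lam):
        """Scaling all fold changes by a common log2 offset preserves ranking and n."""
        db = make_db(
            [("t", "x", "A"), ("t", "x", "B"), ("t", "y", "B"), ("t", "y", "C")]
        )
        base = pd.DataFrame(
            {
                "cluster": ["0"] * 3,
                "gene": ["A", "B", "C"],
                "avg_log2fc": [2.0, 1.0, 0.5],
                "pct_in": [0.8, 0.6, 0.5],
                "pct_out": [0.05, 0.1, 0.2],
                "p_adj": [1e-6] * 3,
            }
        )
        shifted = base.assign(avg_log2fc=base["avg_log2fc"] + np.log2(lam))
        a, b = annotate(base, db), annotate(shifted, db)
        pd.testing.assert_frame_equal(
            a.ranked[["cluster", "rank", "cell_type", "selected"]],
            b.ranked[["cluster", "rank", "cell_type", "selected"]],
        )
        assert b.ranked["score"].to_numpy() == pytest.approx(
            lam * a.ranked["score"].to_numpy()
        )


class TestModelSurface:
    def test_from_files_and_summary(self, tmp_path, scenario):
        from clustercall.simulate import write_fixture_scenario

        cfg, db, truth, _ = scenario
        paths = write_fixture_scenario(tmp_path, cfg)
        model = CellTypeAnnotator.from_files(paths["markers"], paths["database"])
        res = model.fit()
        text = res.summary()
        assert "clusters: 8" in text and "celltype01" in text

    def test_invalid_thresholds_rejected(self, pancreas_db, marker_table):
        with pytest.raises(ValueError):
            CellTypeAnnotator(marker_table, pancreas_db, pct_threshold=1.5)
        with pytest.raises(ValueError):
            CellTypeAnnotator(marker_table, pancreas_db, max_n=0)
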