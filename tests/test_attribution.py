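"""Rank-correlation annotation, the gating oracle and their concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import skinmap as sm
from skinmap.attribution import OTHER_LABEL
from skinmap.io import ValidationError

from conftest import small_cell_table


# ---------------------------------------------------------------------------
# dynamic adaptation
# ---------------------------------------------------------------------------

class TestAdaptMatrix:
    def test_ones_become_channel_maxima_zeros_stay(self, lymphoid_matrix):
        mfi = {m: [10.0 * (j + 1), 3.0] for j, m in enumerate(lymphoid_matrix.markers)}
        mfi["CD3"] = [812.5, 100.0]
        table = small_cell_table(mfi)
        adapted = sm.adapt_matrix(lymphoid_matrix, table)
        # brute-force scan oracle: per-marker maxima computed independently
        for m in lymphoid_matrix.markers:
            expected_max = max(mfi[m])
            for cid in adapted.values.columns:
                src = lymphoid_matrix.values.loc[m, cid]
                want = expected_max if src == 1 else 0.0
                assert adapted.values.loc[m, cid] == want
        assert adapted.values.loc["CD3", "dn T cell"] == 812.5

    def test_empty_table_rejected(self, lymphoid_matrix):
        table = small_cell_table({m: [1.0] for m in lymphoid_matrix.markers})
        table.cells = table.cells.iloc[:0]
        with pytest.raises(ValidationError, match="empty"):
            sm.adapt_matrix(lymphoid_matrix, table)


# ---------------------------------------------------------------------------
# Spearman's rho
# ---------------------------------------------------------------------------

def _brute_force_spearman(a, b):
    """Independent oracle: average ranks by sorting, then the explicit
    product-moment formula evaluated with plain Python sums."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r
    ra, rb = ranks(list(a)), ranks(list(b))
    n = len(ra)
    ma, mb = sum(ra) / n, sum(rb) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(ra, rb))
    den = (sum((x - ma) ** 2 for x in ra) * sum((y - mb) ** 2 for y in rb)) ** 0.5
    return num / den


class TestSpearmanRho:
    def test_identity_and_reversal(self):
        a = [3.0, 1.0, 4.0, 1.5, 9.0]
        assert sm.spearman_rho(a, a) == pytest.approx(1.0)
        assert sm.spearman_rho(sorted(a), sorted(a, reverse=True)) == pytest.approx(-1.0)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a = rng.integers(0, 4, 6).astype(float)  # integer draws force ties
            b = rng.normal(size=6)
            if a.max() == a.min():
                continue
            assert sm.spearman_rho(a, b) == pytest.approx(
                _brute_force_spearman(a, b), abs=1e-12)

    def test_constant_vector_is_undefined(self):
        assert np.isnan(sm.spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            sm.spearman_rho([1.0, 2.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _two_label_matrix():
    values = pd.DataFrame({"A": [1, 1, 0, 0], "B": [1, 0, 1, 0]},
                          index=["CD45", "CD3", "CD20", "CD57"]).astype(float)
    return sm.AttributionMatrix("toy", list(values.index), values,
                                {"A": "A", "B": "B"})


class TestAnnotateCells:
    def test_perfect_match_cell_gets_rho_one(self):
        matrix = _two_label_matrix()
        table = small_cell_table({"CD45": [100.0, 100.0], "CD3": [80.0, 0.0],
                                  "CD20": [0.0, 60.0], "CD57": [0.0, 0.0]})
        result = sm.annotate_cells(table, sm.adapt_matrix(matrix, table))
        assert list(result.cells["label"]) == ["A", "B"]
        assert result.cells["rho_best"].to_numpy() == pytest.approx([1.0, 1.0])
        assert not result.cells["tied"].any()

    def test_exact_tie_across_labels_is_other(self):
        matrix = _two_label_matrix()
        # CD3 and CD20 intensities swapped make both signatures equally good
        table = small_cell_table({"CD45": [100.0], "CD3": [50.0],
                                  "CD20": [50.0], "CD57": [0.0]})
        result = sm.annotate_cells(table, sm.adapt_matrix(matrix, table))
        assert list(result.cells["label"]) == [OTHER_LABEL]
        assert bool(result.cells["tied"][0])

    def test_constant_mfi_vector_is_other(self):
        matrix = _two_label_matrix()
        table = small_cell_table({"CD45": [100.0, 5.0], "CD3": [80.0, 5.0],
                                  "CD20": [0.0, 5.0], "CD57": [0.0, 5.0]})
        result = sm.annotate_cells(table, sm.adapt_matrix(matrix, table))
        assert result.cells["label"][1] == OTHER_LABEL
        assert np.isnan(result.cells["rho_best"][1])

    def test_agrees_with_per_cell_brute_force_argmax(self, suite, lymphoid_matrix):
        """Vectorized annotation equals an independent per-cell loop that
        scores each signature column with spearman_rho and takes argmax."""
        table = suite["lymphoid"].sample.table
        sub = table.cells.iloc[:200]
        table = sm.CellTable("sub", sub.reset_index(drop=True), table.channels)
        adapted = sm.adapt_matrix(lymphoid_matrix, table)
        result = sm.annotate_cells(table, adapted)

        X = table.mfi_matrix(adapted.markers)
        for i in range(table.n_cells):
            scores = {}
            for cid in adapted.values.columns:
                rho = sm.spearman_rho(X[i], adapted.values[cid].to_numpy())
                if not np.isnan(rho):
                    lab = adapted.column_labels[cid]
                    scores[lab] = max(scores.get(lab, -2.0), round(rho, 12))
            if not scores:
                expected = OTHER_LABEL
            else:
                best = max(scores.values())
                winners = [lab for lab, s in scores.items() if s == best]
                expected = winners[0] if len(winners) == 1 else OTHER_LABEL
            assert result.cells["label"][i] == expected

    def test_every_cell_gets_exactly_one_label(self, suite, myeloid_matrix):
        table = suite["myeloid"].sample.table
        result = sm.annotate_cells(table, sm.adapt_matrix(myeloid_matrix, table))
        assert result.label_counts(include_other=True).sum() == table.n_cells

    @given(scale=st.floats(min_value=0.01, max_value=100.0,
                           allow_nan=False, allow_infinity=False),
           perm_seed=st.integers(0, 2**16))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_rescaling_and_cell_order(self, scale, perm_seed,
                                                   suite, lymphoid_matrix):
        """Rank-based annotation ignores a common positive rescaling of
        all channels, and permuting cells permutes labels identically."""
        base = suite["lymphoid"].sample.table
        sub = base.cells.iloc[:60].reset_index(drop=True)
        table = sm.CellTable("sub", sub, base.channels)
        labels = sm.annotate_cells(
            table, sm.adapt_matrix(lymphoid_matrix, table)).cells["label"]

        scaled = sub.copy()
        scaled[base.channels] = scaled[base.channels] * scale
        t2 = sm.CellTable("scaled", scaled, base.channels)
        labels2 = sm.annotate_cells(
            t2, sm.adapt_matrix(lymphoid_matrix, t2)).cells["label"]
        assert list(labels) == list(labels2)

        perm = np.random.default_rng(perm_seed).permutation(len(sub))
        shuffled = sub.iloc[perm].reset_index(drop=True)
        t3 = sm.CellTable("perm", shuffled, base.channels)
        labels3 = sm.annotate_cells(
            t3, sm.adapt_matrix(lymphoid_matrix, t3)).cells["label"]
        assert list(labels3) == list(labels.iloc[perm])


# ---------------------------------------------------------------------------
# gating oracle
# ---------------------------------------------------------------------------

class TestGating:
    def _table(self, **mfi):
        base = {m: [0.0] for m in
                ["CD45", "CD3", "CD4", "CD8", "TCRgd", "CD20", "CD57"]}
        base.update({k: [float(v)] for k, v in mfi.items()})
        return small_cell_table(base)

    @pytest.fixture
    def gates(self):
        thresholds = {m: 10.0 for m in
                      ["CD45", "CD3", "CD4", "CD8", "TCRgd", "CD20", "CD57"]}
        return sm.load_default_gates("lymphoid", thresholds)

    @pytest.mark.parametrize("mfi, expected", [
        (dict(CD45=100, CD20=50), "B cell"),
        (dict(CD45=100, CD3=50), "dn T cell"),
        (dict(CD45=100, CD3=50, CD4=40, CD8=45), "dp T cell"),
        (dict(CD45=100, CD57=80), "NK cell"),
        (dict(CD45=100, CD3=50, CD8=45, CD57=80), "CD8 T CD57high"),
        (dict(CD45=100, CD3=50, CD8=45), "CD8 T CD57low"),
        (dict(), "Other"),
    ])
    def test_flow_style_hierarchy(self, gates, mfi, expected):
        result = sm.gate_cells(self._table(**mfi), gates)
        assert result.cells["label"][0] == expected

    def test_missing_threshold_is_an_error(self):
        gates = sm.load_default_gates("lymphoid", {"CD45": 10.0})
        with pytest.raises(ValidationError, match="threshold"):
            sm.gate_cells(self._table(CD45=100), gates)

    def test_derive_thresholds_valley_separates_bimodal_marker(self):
        rng = np.random.default_rng(5)
        low = rng.lognormal(np.log(8), 0.3, 600)
        high = rng.lognormal(np.log(400), 0.3, 400)
        values = np.concatenate([low, high])
        table = small_cell_table({"CD3": values})
        thr = sm.derive_gate_thresholds(table, ["CD3"], method="valley")["CD3"]
        assert low.max() * 0.5 < thr < high.min() * 2
        assert ((values > thr) == np.r_[np.zeros(600, bool), np.ones(400, bool)]).mean() > 0.995

    def test_derive_thresholds_first_peak_sits_at_background_mode(self):
        rng = np.random.default_rng(6)
        values = np.concatenate([rng.lognormal(np.log(8), 0.3, 600),
                                 rng.lognormal(np.log(400), 0.3, 400)])
        thr = sm.derive_gate_thresholds(
            small_cell_table({"CD3": values}), ["CD3"], method="first_peak")["CD3"]
        assert 4 < thr < 20


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

class TestCompareAnnotations:
    def test_identical_annotations_give_r_one(self, suite, lymphoid_matrix):
        table = suite["lymphoid"].sample.table
        ann = sm.annotate_cells(table, sm.adapt_matrix(lymphoid_matrix, table))
        res = sm.compare_annotations(ann, ann, lymphoid_matrix.labels, 0.0048)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)

    def test_matches_closed_form_regression(self):
        # densities {(10,12),(5,4),(20,19)}: r by the explicit formula
        xs, ys = [10.0, 5.0, 20.0], [12.0, 4.0, 19.0]
        n = 3
        sx, sy = sum(xs), sum(ys)
        sxx = sum(x * x for x in xs)
        sxy = sum(x * y for x, y in zip(xs, ys))
        syy = sum(y * y for y in ys)
        r_hand = (n * sxy - sx * sy) / (
            ((n * sxx - sx * sx) * (n * syy - sy * sy)) ** 0.5)

        def fake(counts):
            labels, values = zip(*counts.items())
            cells = pd.DataFrame({
                "cell_id": range(sum(int(v) for v in values)),
                "label": sum(([lab] * int(v) for lab, v in counts.items()), []),
                "rho_best": 1.0, "rho_runner_up": 0.0, "tied": False})
            return sm.AnnotationResult(cells, labels=list(labels))

        a = fake({"A": 10, "B": 5, "C": 20})
        b = fake({"A": 12, "B": 4, "C": 19})
        res = sm.compare_annotations(a, b, ["A", "B", "C"], roi_volume_mm3=1.0)
        assert res.r == pytest.approx(r_hand, abs=1e-12)

    def test_too_few_populated_labels_rejected(self):
        cells = pd.DataFrame({"cell_id": [1, 2], "label": ["A", "A"],
                              "rho_best": 1.0, "rho_runner_up": 0.0, "tied": False})
        ann = sm.AnnotationResult(cells, labels=["A", "B", "C"])
        with pytest.raises(ValidationError, match="ill-posed"):
            sm.compare_annotations(ann, ann, ["A", "B", "C"], 1.0)
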