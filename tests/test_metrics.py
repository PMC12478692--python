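"""CAFA-style metrics against independent brute-force oracles."""
import numpy as np
import pytest

from bandfold import ICTable, OntologyDAG, aupr, fmax, propagate, propagate_scores, smin
from bandfold.metrics import DEFAULT_GRID, evaluate

# ---------------------------------------------------------------- oracles
# Deliberately naive re-implementations, loop-based and structured
# differently from the library code, used only as ground truth here.


def fmax_oracle(scores, truth, grid=DEFAULT_GRID):
    best = 0.0
    proteins = [p for p in truth if truth[p]]
    for tau in grid:
        prec_list, rec_list = [], []
        for p in proteins:
            pred = set()
            for term, sc in scores.get(p, {}).items():
                if sc >= tau:
                    pred.add(term)
            tp = 0
            for t in pred:
                if t in truth[p]:
                    tp += 1
            if len(pred) > 0:
                prec_list.append(tp / len(pred))
            rec_list.append(tp / len(truth[p]))
        if prec_list:
            pr = sum(prec_list) / len(prec_list)
            rc = sum(rec_list) / len(rec_list)
            if pr + rc > 0:
                best = max(best, 2 * pr * rc / (pr + rc))
    return best


def smin_oracle(scores, truth, ic, grid=DEFAULT_GRID):
    proteins = [p for p in truth if truth[p]]
    best = float("inf")
    for tau in grid:
        ru = mi = 0.0
        for p in proteins:
            pred = {t for t, sc in scores.get(p, {}).items() if sc >= tau}
            for t in truth[p]:
                if t not in pred:
                    ru += ic[t]
            for t in pred:
                if t not in truth[p]:
                    mi += ic[t]
        best = min(best, ((ru / len(proteins)) ** 2 + (mi / len(proteins)) ** 2) ** 0.5)
    return best


def aupr_oracle(scores, truth):
    # pairwise micro AP by explicit step-wise integration over tied groups
    pairs = []
    proteins = sorted(set(truth) | set(scores))
    for p in proteins:
        terms = sorted(set(scores.get(p, {})) | truth.get(p, set()))
        for t in terms:
            pairs.append((scores.get(p, {}).get(t, 0.0), 1 if t in truth.get(p, set()) else 0))
    n_pos = sum(y for _, y in pairs)
    by_score = {}
    for sc, y in pairs:
        by_score.setdefault(sc, [0, 0])
        by_score[sc][y] += 1
    tp = fp = 0
    area, prev_recall = 0.0, 0.0
    for sc in sorted(by_score, reverse=True):
        neg, pos = by_score[sc]
        tp += pos
        fp += neg
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def random_case(rng):
    n_prot = int(rng.integers(2, 7))
    n_term = int(rng.integers(3, 9))
    terms = [f"t{j}" for j in range(n_term)]
    truth, scores = {}, {}
    for i in range(n_prot):
        pid = f"p{i}"
        truth[pid] = {t for t in terms if rng.random() < 0.4}
        scores[pid] = {t: float(np.round(rng.random(), 3)) for t in terms
                       if rng.random() < 0.8}
    if not any(truth.values()):
        truth["p0"] = {terms[0]}
    return scores, truth


# ------------------------------------------------------------------ the DAG


@pytest.fixture
def dag():
    return OntologyDAG.from_edges(
        [("t", "a"), ("a", "root"), ("b", "root"), ("leaf2", "b")]
    )


class TestOntology:
    def test_roots_and_ancestors(self, dag):
        assert dag.roots == {"root"}
        assert dag.ancestors("t") == {"a", "root"}

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            OntologyDAG.from_edges([("a", "b"), ("b", "a")])

    def test_obo_parsing_keeps_is_a_only(self, tmp_path):
        obo = tmp_path / "toy.obo"
        obo.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0000001\nname: root\n\n"
            "[Term]\nid: GO:0000002\nname: child\nis_a: GO:0000001 ! root\n"
            "relationship: part_of GO:0000003\n\n"
            "[Term]\nid: GO:0000003\nname: other\n"
        )
        dag = OntologyDAG.from_obo(obo)
        assert dag.parents["GO:0000002"] == {"GO:0000001"}
        assert "GO:0000003" in dag.terms

    def test_edge_tsv_roundtrip(self, tmp_path, dag):
        path = tmp_path / "edges.tsv"
        path.write_text("child\tparent\nt\ta\na\troot\nb\troot\nleaf2\tb\n")
        loaded = OntologyDAG.from_edge_tsv(path)
        assert loaded.ancestors("t") == dag.ancestors("t")


class TestPropagate:
    def test_leaf_closure(self, dag):
        out = propagate({"p": {"t"}}, dag)
        assert out["p"] == {"t", "a", "root"}

    def test_idempotent(self, dag):
        once = propagate({"p": {"t", "leaf2"}}, dag)
        np.testing.assert_array_equal(sorted(propagate(once, dag)["p"]),
                                      sorted(once["p"]))

    def test_empty_set_stays_empty(self, dag):
        assert propagate({"p": set()}, dag)["p"] == set()

    def test_unknown_term_rejected(self, dag):
        with pytest.raises(KeyError, match="nope"):
            propagate({"p": {"nope"}}, dag)

    def test_score_propagation_takes_max_over_descendants(self, dag):
        out = propagate_scores({"p": {"t": 0.7, "a": 0.2}}, dag)
        assert out["p"]["a"] == 0.7 and out["p"]["root"] == 0.7


class TestICTable:
    def test_universal_terms_have_zero_ic(self, dag):
        ref = {"p1": {"t"}, "p2": {"leaf2"}}
        ic = ICTable.from_annotations(ref, dag)
        assert ic["root"] == 0.0
        assert ic["a"] == pytest.approx(1.0)  # in 1 of 2 proteins

    def test_unseen_terms_capped(self, dag):
        ic = ICTable.from_annotations({"p1": {"t"}}, dag)
        assert ic["leaf2"] == pytest.approx(1.0)  # -log2(1/(N+1)), N=1
        with pytest.raises(KeyError):
            ic["unknown-term"]


class TestFmax:
    def test_perfect_predictor(self):
        truth = {"p1": {"a", "b"}, "p2": {"a"}}
        scores = {p: {t: 1.0 for t in ts} for p, ts in truth.items()}
        value, tau = fmax(scores, truth)
        assert value == pytest.approx(1.0)
        assert tau <= 1.0

    def test_hand_derived_two_thirds(self):
        # one protein, truth {t1}; at tau <= 0.4 precision 1/2, recall 1
        value, tau = fmax({"p": {"t1": 0.4, "t2": 0.9}}, {"p": {"t1"}})
        assert value == pytest.approx(2 / 3, abs=1e-12)
        assert tau <= 0.4

    def test_agrees_with_oracle_on_random_suite(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            scores, truth = random_case(rng)
            assert fmax(scores, truth)[0] == pytest.approx(
                fmax_oracle(scores, truth), abs=1e-12
            )

    def test_invariant_to_subgrid_perturbations(self):
        # scores at grid-cell midpoints; rank-preserving jitter smaller than
        # the 0.01 grid resolution cannot change any thresholded set
        rng = np.random.default_rng(1)
        scores, truth = random_case(rng)
        mid = {p: {t: np.floor(sc * 100) / 100 + 0.005 for t, sc in d.items()}
               for p, d in scores.items()}
        jittered = {p: {t: sc + rng.uniform(-0.004, 0.004) for t, sc in d.items()}
                    for p, d in mid.items()}
        assert fmax(mid, truth)[0] == pytest.approx(fmax(jittered, truth)[0], abs=1e-12)

    def test_no_true_terms_rejected(self):
        with pytest.raises(ValueError):
            fmax({"p": {"t": 1.0}}, {"p": set()})


class TestSmin:
    @pytest.fixture
    def flat_ic(self):
        return ICTable(ic={f"t{j}": 1.0 + 0.25 * j for j in range(10)}, ceiling=5.0)

    def test_perfect_predictor_gives_zero(self, flat_ic):
        truth = {"p1": {"t1", "t2"}}
        scores = {"p1": {"t1": 1.0, "t2": 1.0}}
        assert smin(scores, truth, flat_ic) == pytest.approx(0.0)

    def test_silent_predictor_gives_mean_total_ic(self, flat_ic):
        truth = {"p1": {"t1", "t2"}, "p2": {"t3"}}
        scores = {"p1": {}, "p2": {}}
        expected = (flat_ic["t1"] + flat_ic["t2"] + flat_ic["t3"]) / 2
        assert smin(scores, truth, flat_ic) == pytest.approx(expected)

    def test_agrees_with_oracle_on_random_suite(self, flat_ic):
        rng = np.random.default_rng(43)
        for _ in range(50):
            scores, truth = random_case(rng)
            assert smin(scores, truth, flat_ic) == pytest.approx(
                smin_oracle(scores, truth, flat_ic), abs=1e-12
            )

    def test_correct_prediction_never_hurts(self, flat_ic):
        truth = {"p1": {"t1", "t2"}}
        partial = {"p1": {"t1": 0.9}}
        better = {"p1": {"t1": 0.9, "t2": 0.9}}
        assert smin(better, truth, flat_ic) <= smin(partial, truth, flat_ic)


class TestAUPR:
    def test_perfect_separation(self):
        truth = {"p1": {"a"}, "p2": {"b"}}
        scores = {"p1": {"a": 0.9, "b": 0.2}, "p2": {"a": 0.1, "b": 0.8}}
        assert aupr(scores, truth) == pytest.approx(1.0)

    def test_constant_scores_give_prevalence(self):
        truth = {"p1": {"a"}, "p2": set()}
        scores = {"p1": {"a": 0.5, "b": 0.5}, "p2": {"a": 0.5, "b": 0.5}}
        assert aupr(scores, truth) == pytest.approx(0.25)

    def test_agrees_with_oracle_on_random_suite(self):
        rng = np.random.default_rng(44)
        for _ in range(50):
            scores, truth = random_case(rng)
            assert aupr(scores, truth) == pytest.approx(
                aupr_oracle(scores, truth), abs=1e-10
            )

    def test_zero_positives_rejected(self):
        with pytest.raises(ValueError):
            aupr({"p": {"t": 0.4}}, {"p": set()})


class TestEvaluate:
    def test_perfect_predictions_end_to_end(self, dag):
        truth = {"p1": {"t"}, "p2": {"leaf2"}}
        scores = {"p1": {"t": 1.0}, "p2": {"leaf2": 1.0}}
        result = evaluate(scores, truth, dag)
        assert result.fmax == pytest.approx(1.0)
        assert result.smin == pytest.approx(0.0)
        assert result.aupr == pytest.approx(1.0)

    def test_result_tsv(self, tmp_path, dag):
        truth = {"p1": {"t"}}
        result = evaluate({"p1": {"t": 1.0}}, truth, dag)
        out = tmp_path / "eval.tsv"
        result.write_tsv(out)
        header, row = out.read_text().strip().splitlines()
        assert header.split("\t") == ["fmax", "fmax_threshold", "smin", "aupr"]
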