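import numpy as np
import pytest

from fovod.detector import Detection, score_all
from fovod.search import (FixationState, NoCandidateError, SearchConfig,
                          next_fixation_map, next_fixation_random,
                          run_search, score_to_posterior)

from conftest import make_handbuilt_model


def _det(box, score, comp=0, sigma=1.0):
    return Detection(box=np.asarray(box, dtype=float), score=score,
                     sigma=sigma, component_id=comp)


def _state(ppd=12.5, ior=2.0):
    return FixationState(pixels_per_degree=ppd, ior_radius_deg=ior)


class TestPosterior:
    def test_zero_score_gives_half(self):
        assert score_to_posterior(0.0) == 0.5

    def test_monotone_and_bounded(self):
        s = np.linspace(-30, 30, 101)
        p = score_to_posterior(s)
        assert (np.diff(p) > 0).all()
        assert p.min() >= 0 and p.max() <= 1

    def test_posterior_ratio_identity(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=200) * 3
        p = score_to_posterior(s)
        np.testing.assert_allclose(p / (1 - p), np.exp(s), rtol=1e-12)


class TestIntegration:
    def test_single_fixation_equals_raw_scores(self):
        st = _state()
        dets = [_det((50, 50, 0, 0), 1.5, comp=0),
                _det((50, 50, 200, 200), -0.5, comp=1)]
        st.add_fixation((25, 25))
        st.integrate(dets)
        assert sorted(st.accumulator.values()) == [-0.5, 1.5]

    def test_matches_log_product_of_posterior_ratios(self):
        """Summed scores equal the log product of sigmoid posterior
        ratios, fixation by fixation (direct-product oracle)."""
        rng = np.random.default_rng(1)
        for _ in range(300):
            m = rng.integers(1, 6)
            scores = rng.normal(size=m) * 2
            st = _state()
            for i, s in enumerate(scores):
                st.integrate([_det((40, 40, 0, 0), float(s), comp=i)])
            acc = st.accumulator[st.box_key((40, 40, 0, 0))]
            p = score_to_posterior(scores)
            oracle = np.log(p / (1 - p)).sum()
            assert acc == pytest.approx(oracle, abs=1e-9)

    def test_all_zero_scores_accumulate_to_indifference(self):
        st = _state()
        for i in range(4):
            st.integrate([_det((40, 40, 0, 0), 0.0, comp=i)])
        assert st.accumulator[st.box_key((40, 40, 0, 0))] == 0.0

    def test_per_fixation_max_over_latents(self):
        st = _state()
        st.integrate([_det((40, 40, 0, 0), 0.3, comp=0),
                      _det((40, 41, 0.5, 0), 0.9, comp=1)])  # same slot
        assert list(st.accumulator.values()) == [0.9]

    def test_identical_observation_not_double_counted(self):
        st = _state()
        st.integrate([_det((40, 40, 0, 0), 0.7, comp=3, sigma=0.5)])
        st.integrate([_det((40, 40, 0, 0), 0.7, comp=3, sigma=0.5)])
        assert st.accumulator[st.box_key((40, 40, 0, 0))] == 0.7

    def test_order_invariance_of_final_scores(self):
        rng = np.random.default_rng(2)
        obs = [[_det((40, 40, 0, 0), float(rng.normal()), comp=i),
                _det((60, 60, 100, 100), float(rng.normal()), comp=i)]
               for i in range(5)]
        st1, st2 = _state(), _state()
        for o in obs:
            st1.integrate(o)
        for o in reversed(obs):
            st2.integrate(o)
        for k in st1.accumulator:
            assert st1.accumulator[k] == pytest.approx(st2.accumulator[k])


class TestNextFixation:
    def test_single_uninhibited_candidate_selected(self):
        st = _state()
        st.add_fixation((0, 0))
        st.integrate([_det((20, 20, 100, 100), -5.0)])
        assert next_fixation_map(st) == (110.0, 110.0)

    def test_matches_posterior_argmax_oracle(self):
        rng = np.random.default_rng(3)
        st = _state()
        boxes = [(20, 20, 40 * i, 0) for i in range(10)]
        scores = rng.normal(size=10)
        st.integrate([_det(b, float(s), comp=i)
                      for i, (b, s) in enumerate(zip(boxes, scores))])
        got = next_fixation_map(st)
        # brute force on the sigmoid posterior (monotone in the score)
        best = max(range(10), key=lambda i: score_to_posterior(
            st.accumulator[st.box_key(boxes[i])]))
        assert got == (boxes[best][2] + 10, boxes[best][3] + 10)

    def test_ior_radius_excludes_near_but_not_far(self):
        st = _state(ppd=12.5, ior=2.0)     # 25 px radius
        st.add_fixation((100.0, 100.0))
        near = (20, 20, 100 - 10 - 1.9 * 12.5, 90)   # center 1.9 deg left
        far = (20, 20, 100 - 10 + 2.1 * 12.5, 90)    # center 2.1 deg right
        st.integrate([_det(near, 5.0, comp=0), _det(far, 1.0, comp=1)])
        fx, fy = next_fixation_map(st)
        assert fx == pytest.approx(100 + 2.1 * 12.5)

    def test_all_inhibited_raises(self):
        st = _state()
        st.add_fixation((110, 110))
        st.integrate([_det((20, 20, 100, 100), 1.0)])
        with pytest.raises(NoCandidateError):
            next_fixation_map(st)

    def test_random_reproducible_and_respects_ior(self):
        st = _state()
        st.add_fixation((50.0, 50.0))
        for i in range(8):
            st.integrate([_det((20, 20, 30 * i, 100), 0.0, comp=i)])
        draws1 = [next_fixation_random(st, np.random.default_rng(9))
                  for _ in range(5)]
        draws2 = [next_fixation_random(st, np.random.default_rng(9))
                  for _ in range(5)]
        assert draws1 == draws2
        for p in (next_fixation_random(st, np.random.default_rng(k),
                                       image_shape=(200, 300))
                  for k in range(50)):
            assert np.hypot(p[0] - 50, p[1] - 50) >= 25.0
            assert 0 <= p[0] < 300 and 0 <= p[1] < 200

    def test_random_candidate_draw_uniform(self):
        st = _state()
        n = 6
        for i in range(n):
            st.integrate([_det((20, 20, 40 * i, 100), 0.0, comp=i)])
        rng = np.random.default_rng(11)
        counts = np.zeros(n)
        for _ in range(6000):
            p = next_fixation_random(st, rng)
            counts[int((p[0] - 20) // 40)] += 1
        from scipy.stats import chisquare
        assert chisquare(counts).pvalue > 0.01


class TestRunSearch:
    def test_single_fixation_equals_score_all_plus_nms(self, toy_model):
        rng = np.random.default_rng(5)
        img = rng.random((200, 200))
        pyr = toy_model.pyramid_of(img)
        dets, trace = run_search(toy_model, img,
                                 SearchConfig(n_fixations=1), pyramid=pyr)
        assert len(trace) == 1
        assert trace[0]["x"] == 100 and trace[0]["y"] == 100
        # every reported score must equal the best single-fixation score
        # among raw detections mapping to the same slot
        raw = score_all(toy_model, pyr, (100.0, 100.0))
        st = FixationState(pixels_per_degree=12.5, ior_radius_deg=2.0)
        best = {}
        for d in raw:
            k = st.box_key(d.box)
            best[k] = max(best.get(k, -np.inf), d.score)
        for d in dets:
            assert d.score == pytest.approx(best[st.box_key(d.box)])

    def test_map_and_rand_share_first_fixation(self, toy_model):
        rng = np.random.default_rng(6)
        img = rng.random((200, 200))
        pyr = toy_model.pyramid_of(img)
        _, t1 = run_search(toy_model, img, SearchConfig(
            strategy="MAP", n_fixations=3), pyramid=pyr)
        _, t2 = run_search(toy_model, img, SearchConfig(
            strategy="RAND", n_fixations=3, seed=4), pyramid=pyr)
        assert (t1[0]["x"], t1[0]["y"]) == (t2[0]["x"], t2[0]["y"])

    def test_fixations_respect_pairwise_ior_distance(self, toy_model):
        rng = np.random.default_rng(7)
        img = rng.random((200, 200))
        for strat in ("MAP", "RAND"):
            _, trace = run_search(toy_model, img, SearchConfig(
                strategy=strat, n_fixations=5, seed=2))
            pts = [(t["x"], t["y"]) for t in trace]
            r_px = 2.0 * toy_model.field.config.pixels_per_degree
            for i in range(len(pts)):
                for j in range(i + 1, len(pts)):
                    d = np.hypot(pts[i][0] - pts[j][0],
                                 pts[i][1] - pts[j][1])
                    assert d >= r_px - 1e-9

    def test_cumulative_cost_non_decreasing(self, toy_model):
        from fovod.evaluation import CostLedger
        rng = np.random.default_rng(8)
        img = rng.random((200, 200))
        led = CostLedger()
        _, trace = run_search(toy_model, img,
                              SearchConfig(n_fixations=4), ledger=led)
        ops = [t["cumulative_ops"] for t in trace]
        assert all(b > a for a, b in zip(ops, ops[1:]))

    def test_second_map_fixation_approaches_peripheral_target(
            self, small_trained):
        """A high-contrast glyph planted in the periphery attracts the
        second fixation (the qualitative guided-saccade behavior)."""
        from fovod.synthetic import glyph_mask, one_over_f_noise
        model = small_trained["model"]
        rng = np.random.default_rng(9)
        img = 0.45 + one_over_f_noise((256, 256), rng, 0.07)
        gw, gh = 96, 68
        x0, y0 = 150, 40                 # well away from the center start
        img[y0:y0 + gh, x0:x0 + gw][glyph_mask("wedge", 0, gw, gh)] = 1.0
        img = np.clip(img, 0, 1)
        _, trace = run_search(model, img, SearchConfig(n_fixations=2))
        fx, fy = trace[1]["x"], trace[1]["y"]
        assert x0 - 16 <= fx <= x0 + gw + 16
        assert y0 - 16 <= fy <= y0 + gh + 16


def test_trace_table_and_overlay(toy_model):
    import matplotlib
    matplotlib.use("Agg")
    from fovod.search import trace_table, plot_search
    rng = np.random.default_rng(10)
    img = rng.random((200, 200))
    dets, trace = run_search(toy_model, img, SearchConfig(n_fixations=3))
    tab = trace_table(trace)
    assert list(tab.columns) == ["index", "x", "y", "cumulative_ops"]
    assert len(tab) == 3
    assert plot_search(img, dets, trace) is not None


def test_edge_start_average(small_trained):
    from fovod.experiment import edge_start_mean_ap, ground_truth_by_class
    model = small_trained["model"]
    test = small_trained["test"]
    gt = ground_truth_by_class(test, small_trained["spec"].classes)["wedge"]
    ap = edge_start_mean_ap(model, test, gt, n_fixations=3, seed=1)
    assert 0.0 <= ap <= 100.0
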