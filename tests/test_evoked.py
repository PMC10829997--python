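import numpy as np
import pytest

from helpers import render_bursts

from meavocab import make_geometry
from meavocab.evoked import (ExplainParams, SiteSummary, define_sites,
                             explain_response, label_clusters, select_sites,
                             site_summary)
from meavocab.vocabulary import Vocabulary


class TestDefineSites:
    def test_default_tiling(self, geometry):
        sites = define_sites(geometry)
        assert len(sites) == 20
        all_e = [e for s in sites for e in s.electrodes]
        assert len(all_e) == 120 and len(set(all_e)) == 120
        for s in sites:
            rows = sorted({geometry.index_to_rowcol(e)[0] for e in s.electrodes})
            cols = sorted({geometry.index_to_rowcol(e)[1] for e in s.electrodes})
            assert len(rows) == 3 and rows[2] - rows[0] == 2
            assert len(cols) == 2 and cols[1] - cols[0] == 1

    def test_six_by_two_grid_has_two_sites(self):
        sites = define_sites(make_geometry(6, 2, 1.0, 1.5))
        assert len(sites) == 2

    def test_untileable_grid_rejected(self):
        with pytest.raises(ValueError):
            define_sites(make_geometry(5, 5, 1.0, 1.0))


class TestExplainParams:
    @pytest.mark.parametrize("f_th,m", [(0.0, 0.5), (1.2, 0.5), (0.88, 0.0), (0.88, 100.0)])
    def test_invalid_rejected(self, f_th, m):
        with pytest.raises(ValueError):
            ExplainParams(f_th=f_th, m=m)


@pytest.fixture(scope="module")
def small_vocab(templates3, geometry):
    """60 spontaneous bursts (3 clusters of 20) with a hand-built vocabulary."""
    rng = np.random.default_rng(77)
    bursts, labels = [], []
    for t in templates3:
        bursts.extend(render_bursts(t, geometry, rng, 20))
        labels.extend([t.template_id] * 20)
    vocab = Vocabulary(labels=np.asarray(labels), k=3, theta=0.7)
    return bursts, vocab


class TestExplainResponse:
    def test_cluster_member_lookalike_explained(self, small_vocab, geometry, templates3):
        bursts, vocab = small_vocab
        rng = np.random.default_rng(5)
        [resp] = render_bursts(templates3[1], geometry, rng, 1)
        assert explain_response(resp, bursts, vocab) == 1

    def test_unrelated_response_unexplained(self, small_vocab, geometry):
        bursts, vocab = small_vocab
        rng = np.random.default_rng(6)
        resp = bursts[0].__class__(matrix=rng.uniform(size=(120, 20)),
                                   initial_state=rng.uniform(size=120), start_ms=0.0)
        assert explain_response(resp, bursts, vocab) is None

    def test_order_invariance(self, small_vocab, geometry, templates3):
        bursts, vocab = small_vocab
        rng = np.random.default_rng(9)
        [resp] = render_bursts(templates3[2], geometry, rng, 1)
        perm = np.random.default_rng(1).permutation(len(bursts))
        shuffled = [bursts[i] for i in perm]
        v2 = Vocabulary(labels=vocab.labels[perm], k=3, theta=0.7)
        assert explain_response(resp, bursts, vocab) \
            == explain_response(resp, shuffled, v2) == 2

    def test_minimum_similar_fraction_enforced(self, small_vocab, geometry, templates3):
        bursts, vocab = small_vocab
        rng = np.random.default_rng(10)
        [resp] = render_bursts(templates3[0], geometry, rng, 1)
        strict = ExplainParams(f_th=0.88, m=50.0)   # needs 30 similar bursts
        assert explain_response(resp, bursts, vocab, strict) is None


class TestSiteSummary:
    def test_identical_responses_single_cluster(self, small_vocab, geometry, templates3):
        bursts, vocab = small_vocab
        site = define_sites(geometry)[0]
        rng = np.random.default_rng(13)
        [proto] = render_bursts(templates3[0], geometry, rng, 1)
        responses = [proto.__class__(matrix=proto.matrix.copy(),
                                     initial_state=proto.initial_state.copy(),
                                     start_ms=float(i)) for i in range(30)]
        s = site_summary(site, responses, bursts, vocab)
        assert s.robustness == pytest.approx(1.0)
        assert s.existence == 1
        assert all(c == 0 for c in s.explaining)

    def test_unexplained_responses_infinite_existence(self, small_vocab, geometry):
        bursts, vocab = small_vocab
        site = define_sites(geometry)[0]
        rng = np.random.default_rng(14)
        responses = [bursts[0].__class__(matrix=rng.uniform(size=(120, 20)),
                                         initial_state=rng.uniform(size=120),
                                         start_ms=float(i)) for i in range(10)]
        s = site_summary(site, responses, bursts, vocab)
        assert np.isinf(s.existence)

    def test_majority_split_greedy_count(self, small_vocab, geometry, templates3):
        """18 of 30 repetitions from one cluster already cover 50%."""
        bursts, vocab = small_vocab
        site = define_sites(geometry)[2]
        rng = np.random.default_rng(15)
        responses = render_bursts(templates3[0], geometry, rng, 18) \
            + render_bursts(templates3[1], geometry, rng, 12)
        s = site_summary(site, responses, bursts, vocab)
        assert s.existence == 1

    def test_needs_two_repetitions(self, small_vocab, geometry, templates3):
        bursts, vocab = small_vocab
        site = define_sites(geometry)[0]
        rng = np.random.default_rng(16)
        with pytest.raises(ValueError):
            site_summary(site, render_bursts(templates3[0], geometry, rng, 1),
                         bursts, vocab)


def make_summary(site_id, robustness, existence, explaining, p=1e-6):
    return SiteSummary(site_id=site_id, robustness=robustness, existence=existence,
                       explaining=explaining, within_corr=np.array([robustness]),
                       across_corr=np.array([0.1]), uniqueness_p=p)


class TestSelectSites:
    def test_three_robust_among_noise(self):
        summaries = [make_summary(i, 0.3, np.inf, [None] * 30, p=0.5)
                     for i in range(1, 18)]
        summaries += [make_summary(18, 0.9, 1, [2] * 30),
                      make_summary(19, 0.88, 1, [4] * 30),
                      make_summary(20, 0.92, 1, [7] * 30)]
        sel = select_sites(summaries, n=3)
        assert sorted(sel.selected) == [18, 19, 20]
        assert sel.complete

    def test_uniqueness_failure_empties_selection(self):
        summaries = [make_summary(i, 0.9, 1, [1] * 30, p=0.8) for i in range(1, 6)]
        sel = select_sites(summaries, n=3)
        assert sel.selected == []
        assert not sel.complete

    def test_single_site_selection(self):
        summaries = [make_summary(1, 0.95, 1, [0] * 30),
                     make_summary(2, 0.2, np.inf, [None] * 30, p=0.9)]
        sel = select_sites(summaries, n=1)
        assert sel.selected == [1]

    def test_dendrogram_separation_enforced(self):
        summaries = [make_summary(i, 0.9 - 0.01 * i, 1, [i] * 30) for i in range(1, 5)]
        # sites 1 and 2 give near-identical responses: same branch
        cross = {(1, 2): 0.95, (1, 3): 0.1, (1, 4): 0.1,
                 (2, 3): 0.1, (2, 4): 0.1, (3, 4): 0.1}
        sel = select_sites(summaries, n=3, cross_site_corr=cross)
        assert 1 in sel.selected and 2 not in sel.selected
        assert sorted(sel.selected) == [1, 3, 4]


class TestLabelClusters:
    def vocab(self):
        return Vocabulary(labels=np.repeat(np.arange(6), 10), k=6, theta=0.7)

    def test_dominant_cluster_stimulated(self):
        s = make_summary(1, 0.9, 1, [5] * 28 + [None] * 2)
        stim, non = label_clusters([s], self.vocab())
        assert stim == {5}

    def test_never_explaining_cluster_non_stimulated(self):
        s = make_summary(1, 0.9, 1, [5] * 30)
        stim, non = label_clusters([s], self.vocab())
        assert 3 in non and 5 not in non

    def test_weakly_explaining_cluster_in_neither(self):
        s1 = make_summary(1, 0.9, 1, [5] * 29 + [2])
        s2 = make_summary(2, 0.9, 1, [4] * 30)
        stim, non = label_clusters([s1, s2], self.vocab())
        assert 2 not in stim and 2 not in non

    def test_unqualified_sites_contribute_no_stimulated(self):
        s = make_summary(1, 0.5, 1, [5] * 30)   # below the robustness bound
        stim, non = label_clusters([s], self.vocab())
        assert stim == set()


def test_explain_stable_over_parameter_grid(small_vocab, geometry, templates3):
    """The explain assignment agrees across the (f_th, m) grid for >= 90%
    of responses."""
    bursts, vocab = small_vocab
    rng = np.random.default_rng(30)
    responses = [b for t in templates3 for b in render_bursts(t, geometry, rng, 10)]
    grids = [(0.85, 0.5), (0.85, 1.0), (0.88, 0.5), (0.88, 1.0), (0.9, 0.5), (0.9, 1.0)]
    assignments = []
    for f_th, m in grids:
        params = ExplainParams(f_th=f_th, m=m)
        assignments.append([explain_response(r, bursts, vocab, params)
                            for r in responses])
    base = assignments[2]
    for other in assignments:
        agree = np.mean([a == b for a, b in zip(base, other)])
        assert agree >= 0.9
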