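"""Biaffine scoring against brute-force oracles; losses; argmax decoding."""

import numpy as np
import pytest

from famgraph.autodiff import Tensor
from famgraph.biaffine import (
    BiaffineConfig,
    BiaffineScorer,
    arc_loss,
    compute_loss,
    decode_scores,
    label_loss,
)
from famgraph.types import ArcGraph, LabelScheme

THREE = LabelScheme(LabelScheme.THREE)
FIVE = LabelScheme(LabelScheme.FIVE)


def brute_force_scores(scorer, ah, ad, lh, ld):
    """Triple-loop evaluation of the biaffine forms."""
    B, n1, p = ah.shape
    n = n1 - 1
    L = len(scorer.scheme)
    U, u = scorer.U_arc.data, scorer.u_arc.data
    arc = np.zeros((B, n1, n))
    lab = np.zeros((B, n1, n, L))
    for b in range(B):
        for i in range(n1):
            for j in range(n):
                arc[b, i, j] = ah[b, i] @ U @ ad[b, j + 1] + u @ ah[b, i]
                for l in range(L):
                    lab[b, i, j, l] = (
                        lh[b, i] @ scorer.U_label.data[l] @ ld[b, j + 1]
                        + scorer.W_label.data[l]
                        @ np.concatenate([lh[b, i], ld[b, j + 1]])
                        + scorer.u_label.data[l]
                    )
    return arc, lab


@pytest.fixture
def scorer():
    return BiaffineScorer(
        token_dim=5,
        scheme=THREE,
        config=BiaffineConfig(arc_mlp_dim=3, label_mlp_dim=2, dropout=0.0),
        rng=np.random.default_rng(11),
    )


class TestProjection:
    def test_shapes(self, scorer):
        rng = np.random.default_rng(0)
        rep = Tensor(rng.normal(size=(2, 5, 5)))
        ah, ad, lh, ld = scorer.project(rep, rng, train=False)
        assert ah.shape == ad.shape == (2, 5, 3)
        assert lh.shape == ld.shape == (2, 5, 2)

    def test_zero_weights_zero_projections(self, scorer):
        rng = np.random.default_rng(0)
        for mlp in (scorer.arc_head_mlp, scorer.arc_dep_mlp):
            mlp.fc2.W.data[:] = 0.0
            mlp.fc2.b.data[:] = 0.0
        rep = Tensor(rng.normal(size=(1, 3, 5)))
        ah, ad, _, _ = scorer.project(rep, rng, train=False)
        assert np.all(ah.data == 0.0) and np.all(ad.data == 0.0)

    def test_hand_computed_single_token(self):
        """1-token sentence through fixed weights equals hand matmul."""
        sc = BiaffineScorer(
            2, THREE, BiaffineConfig(arc_mlp_dim=2, label_mlp_dim=2, dropout=0.0),
            np.random.default_rng(0),
        )
        sc.arc_head_mlp.fc1.W.data = np.eye(2)
        sc.arc_head_mlp.fc1.b.data = np.zeros(2)
        sc.arc_head_mlp.fc2.W.data = np.array([[1.0, 2.0], [3.0, 4.0]])
        sc.arc_head_mlp.fc2.b.data = np.array([0.5, -0.5])
        rep = Tensor(np.array([[[1.0, 2.0], [3.0, 4.0]]]))  # ROOT + 1 token
        ah, _, _, _ = sc.project(rep, np.random.default_rng(0), train=False)
        # relu([1,2]) @ W2 + b2 = [1*1+2*3+0.5, 1*2+2*4-0.5]
        assert np.allclose(ah.data[0, 0], [7.5, 9.5])
        assert np.allclose(ah.data[0, 1], [3 * 1 + 4 * 3 + 0.5, 3 * 2 + 4 * 4 - 0.5])


class TestScoring:
    def test_brute_force_equivalence(self, scorer):
        """Vectorized scores match triple-loop oracles to 1e-5."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(1, 5))
            rep = Tensor(rng.normal(size=(2, n + 1, 5)))
            ah, ad, lh, ld = scorer.project(rep, rng, train=False)
            arc = scorer.score_arcs(ah, ad)
            lab = scorer.score_labels(lh, ld)
            ref_arc, ref_lab = brute_force_scores(
                scorer, ah.data, ad.data, lh.data, ld.data
            )
            assert np.abs(arc.data - ref_arc).max() < 1e-5
            assert np.abs(lab.data - ref_lab).max() < 1e-5

    def test_zero_params_uniform_softmax(self, scorer):
        scorer.U_arc.data[:] = 0.0
        scorer.u_arc.data[:] = 0.0
        rng = np.random.default_rng(0)
        ah = Tensor(rng.normal(size=(1, 4, 3)))
        ad = Tensor(rng.normal(size=(1, 4, 3)))
        s = scorer.score_arcs(ah, ad)
        assert np.all(s.data == 0.0)
        p = np.exp(s.log_softmax(axis=1).data)
        assert np.allclose(p, 1.0 / 4, atol=1e-12)

    def test_identity_bilinear_is_dot_product(self, scorer):
        scorer.U_arc.data = np.eye(3)
        scorer.u_arc.data[:] = 0.0
        rng = np.random.default_rng(0)
        ah = Tensor(rng.normal(size=(1, 3, 3)))
        ad = Tensor(rng.normal(size=(1, 3, 3)))
        s = scorer.score_arcs(ah, ad)
        for i in range(3):
            for j in range(2):
                assert s.data[0, i, j] == pytest.approx(
                    float(ah.data[0, i] @ ad.data[0, j + 1])
                )

    def test_bias_only_label_scores(self, scorer):
        scorer.U_label.data[:] = 0.0
        scorer.W_label.data[:] = 0.0
        scorer.u_label.data = np.arange(5, dtype=float)
        rng = np.random.default_rng(0)
        lh = Tensor(rng.normal(size=(1, 3, 2)))
        ld = Tensor(rng.normal(size=(1, 3, 2)))
        s = scorer.score_labels(lh, ld)
        assert np.allclose(s.data, np.arange(5.0), atol=1e-12)

    def test_softmax_axes_normalize(self, scorer):
        rng = np.random.default_rng(0)
        rep = Tensor(rng.normal(size=(1, 4, 5)))
        mask = np.ones((1, 3), bool)
        arc, lab = scorer.score(rep, mask, rng, train=False)
        assert np.allclose(np.exp(arc.log_softmax(axis=1).data).sum(axis=1), 1.0, atol=1e-6)
        assert np.allclose(np.exp(lab.log_softmax(axis=-1).data).sum(axis=-1), 1.0, atol=1e-6)


class TestLoss:
    def test_uniform_arc_loss_closed_form(self):
        """All-equal scores over n+1 candidate heads give loss ln(n+1)."""
        for n in (1, 3, 7):
            arc = Tensor(np.zeros((1, n + 1, n)))
            mask = np.ones((1, n), bool)
            loss = arc_loss(arc, np.zeros((1, n), int), mask)
            assert float(loss.data) == pytest.approx(np.log(n + 1), abs=1e-12)

    def test_peaked_scores_loss_vanishes(self):
        n = 3
        arc = np.full((1, n + 1, n), -1e3)
        gold = np.array([[1, 0, 2]])
        for j in range(n):
            arc[0, gold[0, j], j] = 1e3
        loss = arc_loss(Tensor(arc), gold, np.ones((1, n), bool))
        assert float(loss.data) < 1e-8

    def test_against_independent_nll(self, scorer):
        """Loss equals an independent log-softmax + NLL computation."""
        rng = np.random.default_rng(5)
        n, L = 4, 5
        arc = rng.normal(size=(2, n + 1, n))
        lab = rng.normal(size=(2, n + 1, n, L))
        heads = rng.integers(0, n + 1, size=(2, n))
        labels = rng.integers(0, L, size=(2, n))
        mask = np.array([[1, 1, 1, 0], [1, 1, 1, 1]], bool)
        got = compute_loss(Tensor(arc), Tensor(lab), heads, labels, mask, "joint")

        def logsoftmax(x, axis):
            m = x.max(axis=axis, keepdims=True)
            return x - m - np.log(np.exp(x - m).sum(axis=axis, keepdims=True))

        la = logsoftmax(arc, 1)
        ll = logsoftmax(lab, -1)
        ref, cnt = 0.0, 0
        for b in range(2):
            for j in range(n):
                if mask[b, j]:
                    ref -= la[b, heads[b, j], j]
                    ref -= ll[b, heads[b, j], j, labels[b, j]]
                    cnt += 1
        assert float(got.data) == pytest.approx(ref / cnt, abs=1e-10)

    def test_joint_equals_sum_of_parts(self, scorer):
        rng = np.random.default_rng(5)
        n = 3
        arc = Tensor(rng.normal(size=(1, n + 1, n)))
        lab = Tensor(rng.normal(size=(1, n + 1, n, 5)))
        heads = rng.integers(0, n + 1, size=(1, n))
        labels = rng.integers(0, 5, size=(1, n))
        mask = np.ones((1, n), bool)
        joint = compute_loss(arc, lab, heads, labels, mask, "joint")
        a = compute_loss(arc, lab, heads, labels, mask, "arc_only")
        l = compute_loss(arc, lab, heads, labels, mask, "label_only")
        assert float(joint.data) == pytest.approx(float(a.data) + float(l.data), abs=1e-12)

    def test_label_loss_conditions_on_given_heads(self):
        rng = np.random.default_rng(5)
        n = 3
        lab = Tensor(rng.normal(size=(1, n + 1, n, 5)))
        labels = rng.integers(0, 5, size=(1, n))
        mask = np.ones((1, n), bool)
        gold = np.array([[1, 2, 0]])
        pred = np.array([[0, 2, 3]])
        lg = label_loss(lab, gold, labels, mask)
        lp = label_loss(lab, pred, labels, mask)
        assert float(lg.data) != pytest.approx(float(lp.data))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            compute_loss(
                Tensor(np.zeros((1, 2, 1))),
                Tensor(np.zeros((1, 2, 1, 5))),
                np.zeros((1, 1), int),
                np.zeros((1, 1), int),
                np.ones((1, 1), bool),
                "bogus",
            )


class TestDecode:
    def test_engineered_scores_reproduce_structure(self):
        """Scores peaked at a target graph decode to exactly that graph:
        FM 'children' at token 1, LS 'generally healthy' at 3-4, related."""
        target = ArcGraph(
            (0, 0, 0, 5, 2), ("NULL", "FamilyMember", "NULL", "app", "LivingStatus")
        )
        n = len(target)
        arc = np.zeros((1, n + 1, n))
        lab = np.zeros((1, n + 1, n, len(THREE)))
        for j in range(n):
            arc[0, target.heads[j], j] = 10.0
            lab[0, target.heads[j], j, THREE.index(target.labels[j])] = 10.0
        [got] = decode_scores(arc, lab, np.ones((1, n), bool), THREE)
        assert got == target

    def test_tie_breaks_to_lowest_index(self):
        n = 2
        arc = np.zeros((1, n + 1, n))
        lab = np.zeros((1, n + 1, n, len(THREE)))
        [g] = decode_scores(arc, lab, np.ones((1, n), bool), THREE)
        assert g.heads == (0, 0)
        assert g.labels == (THREE.labels[0],) * n

    def test_matches_brute_force_argmax(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 6))
            arc = rng.normal(size=(1, n + 1, n))
            lab = rng.normal(size=(1, n + 1, n, len(THREE)))
            [g] = decode_scores(arc, lab, np.ones((1, n), bool), THREE)
            for j in range(n):
                h = int(np.argmax(arc[0, :, j]))
                assert g.heads[j] == h
                assert g.labels[j] == THREE.labels[int(np.argmax(lab[0, h, j]))]


def test_scheme_agnostic_shapes():
    """Five-type vs three-type changes only the label dimension."""
    rng = np.random.default_rng(0)
    cfg = BiaffineConfig(arc_mlp_dim=3, label_mlp_dim=2, dropout=0.0)
    s3 = BiaffineScorer(5, THREE, cfg, rng)
    s5 = BiaffineScorer(5, FIVE, cfg, rng)
    rep = Tensor(np.random.default_rng(1).normal(size=(1, 4, 5)))
    mask = np.ones((1, 3), bool)
    a3, l3 = s3.score(rep, mask, rng, train=False)
    a5, l5 = s5.score(rep, mask, rng, train=False)
    assert a3.shape == a5.shape
    assert l3.shape[:-1] == l5.shape[:-1]
    assert l3.shape[-1] == 5 and l5.shape[-1] == 7
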