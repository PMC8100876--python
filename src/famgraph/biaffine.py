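"""Deep biaffine attention: arc scoring, label scoring, losses, decoding.

Given token representations r_0..r_n (row 0 = ROOT), four single-hidden-
layer MLPs project each row into head/dependent spaces for arcs (dim p)
and labels (dim q).  The score of the arc from candidate head i to
dependent j is the biaffine form

    s_arc[i, j] = h_i^T U_arc d_j + u_arc^T h_i

(the bias multiplies the head projection, following the standard deep
biaffine parser formulation), and the label score vector of the arc (i, j)
is, per label l,

    s_lab[i, j, l] = h_i^T U_lab[l] d_j + W_lab[l] . [h_i ; d_j] + u_lab[l].

Head and label are both predicted by softmax + argmax per dependent token;
training minimizes the mean cross-entropy of the head distribution, of the
label distribution conditioned on the (gold, during training) head, or
their sum for the joint model.  Decoding is plain per-token argmax with
lowest-index tie-breaking — no tree constraint; downstream graph decoding
repairs inconsistent structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, stack, where_mask
from .nn import MLP, NEG_INF, Module, xavier
from .types import ArcGraph, LabelScheme


@dataclass
class BiaffineConfig:
    arc_mlp_dim: int = 500
    label_mlp_dim: int = 100
    dropout: float = 0.5

    @staticmethod
    def toy(**overrides) -> "BiaffineConfig":
        cfg = dict(arc_mlp_dim=48, label_mlp_dim=24, dropout=0.1)
        cfg.update(overrides)
        return BiaffineConfig(**cfg)


class BiaffineScorer(Module):
    """Projections plus the two biaffine classifiers over one label scheme."""

    def __init__(
        self,
        token_dim: int,
        scheme: LabelScheme,
        config: BiaffineConfig,
        rng: np.random.Generator,
    ):
        p, q = config.arc_mlp_dim, config.label_mlp_dim
        L = len(scheme)
        self.scheme = scheme
        self.config = config
        self.arc_head_mlp = MLP(rng, token_dim, p, config.dropout)
        self.arc_dep_mlp = MLP(rng, token_dim, p, config.dropout)
        self.label_head_mlp = MLP(rng, token_dim, q, config.dropout)
        self.label_dep_mlp = MLP(rng, token_dim, q, config.dropout)
        self.U_arc = xavier(rng, p, p)
        self.u_arc = Tensor(np.zeros(p), requires_grad=True)
        self.U_label = xavier(rng, L, q, q)
        self.W_label = xavier(rng, L, 2 * q)
        self.u_label = Tensor(np.zeros(L), requires_grad=True)

    # -- projections ---------------------------------------------------------

    def project(
        self, rep: Tensor, rng: np.random.Generator, train: bool
    ) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        """Four projected views of (B, n+1, d): arc-head, arc-dep,
        label-head, label-dep.  Dependent views keep the ROOT row (it is
        sliced away in scoring) so all four share one shape."""
        return (
            self.arc_head_mlp(rep, rng, train),
            self.arc_dep_mlp(rep, rng, train),
            self.label_head_mlp(rep, rng, train),
            self.label_dep_mlp(rep, rng, train),
        )

    # -- scoring -------------------------------------------------------------

    def score_arcs(self, arc_head: Tensor, arc_dep: Tensor) -> Tensor:
        """(B, n+1, p) head and dep projections -> arc scores (B, n+1, n).

        Column j scores every candidate head (ROOT plus each token) of
        dependent token j (dep rows exclude ROOT)."""
        dep = arc_dep[:, 1:, :]
        bilinear = (arc_head @ self.U_arc) @ dep.swapaxes(-1, -2)  # (B, n+1, n)
        bias = (arc_head @ self.u_arc).reshape(*arc_head.shape[:2], 1)
        return bilinear + bias

    def score_labels(self, label_head: Tensor, label_dep: Tensor) -> Tensor:
        """(B, n+1, q) projections -> label scores (B, n+1, n, |L|)."""
        dep = label_dep[:, 1:, :]
        per_label = []
        L = len(self.scheme)
        for l in range(L):
            per_label.append((label_head @ self.U_label[l]) @ dep.swapaxes(-1, -2))
        bilinear = stack(per_label, axis=-1)  # (B, n+1, n, L)
        q = self.config.label_mlp_dim
        w_head = label_head @ self.W_label[:, :q].swapaxes(0, 1)  # (B, n+1, L)
        w_dep = dep @ self.W_label[:, q:].swapaxes(0, 1)  # (B, n, L)
        B, n1, _ = label_head.shape
        lin = w_head.reshape(B, n1, 1, L) + w_dep.reshape(B, 1, n1 - 1, L)
        return bilinear + lin + self.u_label

    def score(
        self, rep: Tensor, mask: np.ndarray, rng: np.random.Generator, train: bool
    ) -> tuple[Tensor, Tensor]:
        """Full scoring pass; invalid head rows are masked to -inf."""
        ah, ad, lh, ld = self.project(rep, rng, train)
        arc_scores = self.score_arcs(ah, ad)
        label_scores = self.score_labels(lh, ld)
        head_valid = head_mask(mask)
        arc_scores = where_mask(arc_scores, head_valid, NEG_INF)
        return arc_scores, label_scores


def head_mask(mask: np.ndarray) -> np.ndarray:
    """(B, T) token mask -> (B, T+1, T) validity of head candidate i for
    dependent j (ROOT always valid; padding rows invalid)."""
    B, T = mask.shape
    valid_heads = np.concatenate([np.ones((B, 1), bool), mask], axis=1)  # (B, T+1)
    return valid_heads[:, :, None] & mask[:, None, :]


# -- losses -------------------------------------------------------------------


def arc_loss(arc_scores: Tensor, heads: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean cross-entropy of softmax over candidate heads vs gold heads.

    ``arc_scores``: (B, n+1, n); ``heads``: (B, n) gold head indices
    (0 = ROOT); ``mask``: (B, n) valid-token mask.
    """
    lp = arc_scores.log_softmax(axis=1)
    b, j = np.nonzero(mask)
    picked = lp[(b, heads[b, j], j)]
    return -picked.sum() / len(b)


def label_loss(
    label_scores: Tensor,
    cond_heads: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
) -> Tensor:
    """Mean cross-entropy of the label distribution on the arc into each
    token, conditioned on ``cond_heads`` (gold heads during training,
    predicted heads for the pipeline's second stage)."""
    b, j = np.nonzero(mask)
    picked_rows = label_scores[(b, cond_heads[b, j], j)]  # (N, L)
    lp = picked_rows.log_softmax(axis=-1)
    picked = lp[(np.arange(len(b)), labels[b, j])]
    return -picked.sum() / len(b)


def compute_loss(
    arc_scores: Tensor,
    label_scores: Tensor,
    heads: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
    mode: str = "joint",
    cond_heads: np.ndarray | None = None,
) -> Tensor:
    """Training objective: ``joint`` = arc + label cross-entropies;
    ``arc_only`` / ``label_only`` are the pipeline stages."""
    if mode not in ("joint", "arc_only", "label_only"):
        raise ValueError(f"unknown loss mode {mode!r}")
    if mode == "arc_only":
        return arc_loss(arc_scores, heads, mask)
    cond = cond_heads if cond_heads is not None else heads
    if cond is None:
        raise ValueError("label loss requires conditioning heads")
    ll = label_loss(label_scores, cond, labels, mask)
    if mode == "label_only":
        return ll
    return arc_loss(arc_scores, heads, mask) + ll


# -- decoding -----------------------------------------------------------------


def decode_scores(
    arc_scores: np.ndarray,
    label_scores: np.ndarray,
    mask: np.ndarray,
    scheme: LabelScheme,
) -> list[ArcGraph]:
    """Greedy per-token argmax decoding to one :class:`ArcGraph` per
    sentence.  NumPy argmax breaks ties toward the lowest index."""
    B, _, T = arc_scores.shape
    hm = head_mask(mask)
    masked = np.where(hm, arc_scores, NEG_INF)
    heads = masked.argmax(axis=1)  # (B, T)
    graphs = []
    for b in range(B):
        n = int(mask[b].sum())
        hs, labs = [], []
        for j in range(n):
            h = int(heads[b, j])
            lab = int(label_scores[b, h, j].argmax())
            hs.append(h)
            labs.append(scheme.labels[lab])
        graphs.append(ArcGraph(tuple(hs), tuple(labs)))
    return graphs
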