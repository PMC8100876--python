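"""The trainable joint extraction model as a scikit-learn style estimator.

:class:`BiaffineFamilyHistoryTagger` wraps the representation layer and the
biaffine scorer behind ``fit``/``predict``.  Inputs are sentences (lists of
token strings); targets are (entities, relations) annotation pairs which
are encoded to arc graphs internally.  Three training modes mirror the
experimental settings:

* ``joint`` — one model minimizing arc + label cross-entropy;
* ``pipeline`` — a first model trained on the arc loss alone, then a second,
  fully separate model trained on the label loss conditioned on the first
  model's predicted heads;
* ``ner_only`` — targets from the NER-only graph conversion (all heads
  ROOT), so no relations are learned.

Early stopping monitors micro-F1 of decoded entities + relations on a
held-out development fraction of the training data.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
from sklearn.base import BaseEstimator

from . import codec
from .biaffine import (
    BiaffineConfig,
    BiaffineScorer,
    compute_loss,
    decode_scores,
    head_mask,
)
from .encoder import CharVocab, EncoderConfig, HashedContextualEncoder, SentenceEncoder
from .nn import NEG_INF, Adam, Module
from .types import ArcGraph, Entity, LabelScheme, Relation, Token

Annotation = tuple[list[Entity], list[Relation]]


class _Network(Module):
    """One encoder + one biaffine scorer."""

    def __init__(self, enc_cfg, char_vocab, contextual, scheme, bi_cfg, rng):
        self.encoder = SentenceEncoder(enc_cfg, char_vocab, contextual, rng)
        self.scorer = BiaffineScorer(enc_cfg.token_dim, scheme, bi_cfg, rng)

    def forward(self, sentences, rng, train):
        rep, mask = self.encoder(sentences, rng, train)
        arc_scores, label_scores = self.scorer.score(rep, mask, rng, train)
        return arc_scores, label_scores, mask


class BiaffineFamilyHistoryTagger(BaseEstimator):
    """Joint family-history entity/relation tagger with biaffine attention.

    Parameters follow the published defaults (Adam, learning rate 2e-5,
    batch size 32, up to 100 epochs, dropout 0.5); desk-scale work passes a
    toy :class:`EncoderConfig`/:class:`BiaffineConfig` and a larger
    learning rate suited to training from scratch.

    Fitted attributes end in an underscore: ``scheme_``, ``char_vocab_``,
    ``network_`` (joint / ner_only) or ``arc_network_``/``label_network_``
    (pipeline), ``history_`` (per-epoch loss and dev F1), ``best_epoch_``.
    """

    def __init__(
        self,
        scheme: str = LabelScheme.FIVE,
        mode: str = "joint",
        encoder_config: EncoderConfig | None = None,
        biaffine_config: BiaffineConfig | None = None,
        lr: float = 2e-5,
        batch_size: int = 32,
        max_epochs: int = 100,
        patience: int = 10,
        dev_fraction: float = 0.1,
        seed: int = 0,
        contextual=None,
        verbose: bool = False,
    ):
        self.scheme = scheme
        self.mode = mode
        self.encoder_config = encoder_config
        self.biaffine_config = biaffine_config
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.dev_fraction = dev_fraction
        self.seed = seed
        self.contextual = contextual
        self.verbose = verbose

    # -- fitting ---------------------------------------------------------

    def fit(self, X: list[list[str]], y: list[Annotation]):
        """Train on sentences ``X`` with gold annotations ``y``."""
        if not X:
            raise ValueError("empty training corpus")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if self.mode not in ("joint", "pipeline", "ner_only"):
            raise ValueError(f"unknown mode {self.mode!r}")

        rng = np.random.default_rng(self.seed)
        self.scheme_ = LabelScheme(self.scheme)
        enc_cfg = self.encoder_config or EncoderConfig()
        bi_cfg = self.biaffine_config or BiaffineConfig()
        self.char_vocab_ = CharVocab.fit(X)
        contextual = self.contextual or HashedContextualEncoder(enc_cfg.contextual_dim)

        graphs = [self._encode_target(s, ann) for s, ann in zip(X, y)]

        # dev split for early stopping
        n_dev = max(1, int(round(self.dev_fraction * len(X)))) if len(X) > 4 else 0
        perm = rng.permutation(len(X))
        dev_idx, train_idx = perm[:n_dev], perm[n_dev:]
        Xtr = [X[i] for i in train_idx]
        Gtr = [graphs[i] for i in train_idx]
        Xdev = [X[i] for i in dev_idx]
        ydev = [y[i] for i in dev_idx]
        Gdev = [graphs[i] for i in dev_idx]

        if self.mode == "pipeline":
            self.arc_network_ = _Network(
                enc_cfg, self.char_vocab_, contextual, self.scheme_, bi_cfg, rng
            )
            hist1 = self._train_network(
                self.arc_network_, Xtr, Gtr, Xdev, ydev, Gdev, rng, loss_mode="arc_only"
            )
            self.label_network_ = _Network(
                enc_cfg, self.char_vocab_, contextual, self.scheme_, bi_cfg, rng
            )
            hist2 = self._train_network(
                self.label_network_,
                Xtr,
                Gtr,
                Xdev,
                ydev,
                Gdev,
                rng,
                loss_mode="label_only",
                head_model=self.arc_network_,
            )
            self.history_ = {"arc_stage": hist1, "label_stage": hist2}
        else:
            self.network_ = _Network(
                enc_cfg, self.char_vocab_, contextual, self.scheme_, bi_cfg, rng
            )
            self.history_ = self._train_network(
                self.network_, Xtr, Gtr, Xdev, ydev, Gdev, rng, loss_mode="joint"
            )
        return self

    def _encode_target(self, sent: list[str], ann: Annotation) -> ArcGraph:
        toks = Token.sequence(sent)
        entities, relations = ann
        if self.mode == "ner_only":
            return codec.encode_ner_only(toks, entities, self.scheme_)
        return codec.encode_graph(toks, entities, relations, self.scheme_)

    def _train_network(
        self, net, Xtr, Gtr, Xdev, ydev, Gdev, rng, loss_mode, head_model=None
    ) -> list[dict]:
        opt = Adam(net.parameters(), lr=self.lr)
        order = np.argsort([len(s) for s in Xtr], kind="stable")
        batches = [
            order[i : i + self.batch_size]
            for i in range(0, len(order), self.batch_size)
        ]
        history: list[dict] = []
        best_metric, best_state, best_epoch, since_best = -1.0, None, 0, 0
        for epoch in range(1, self.max_epochs + 1):
            epoch_loss, n_batches = 0.0, 0
            for bi in rng.permutation(len(batches)):
                idx = batches[bi]
                sents = [Xtr[i] for i in idx]
                heads, labels, mask = self._pack_targets([Gtr[i] for i in idx])
                arc_s, lab_s, fmask = net.forward(sents, rng, train=True)
                cond = None
                if loss_mode == "label_only":
                    cond = self._predicted_heads(head_model, sents, fmask)
                loss = compute_loss(
                    arc_s, lab_s, heads, labels, fmask, loss_mode, cond_heads=cond
                )
                net.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data)
                n_batches += 1
            record = {"epoch": epoch, "train_loss": epoch_loss / n_batches}
            if Xdev:
                if loss_mode == "arc_only":
                    # stage-1 metric: unlabeled head accuracy on dev
                    record["dev_f1"] = self._head_accuracy(net, Xdev, Gdev)
                else:
                    preds = self._predict_with(
                        Xdev, net=net, head_model=head_model, loss_mode=loss_mode
                    )
                    record["dev_f1"] = _annotation_micro_f1(
                        ydev, preds, include_relations=self.mode != "ner_only"
                    )
                metric = record["dev_f1"]
            else:
                metric = -record["train_loss"]
            history.append(record)
            if self.verbose:
                print(f"[{loss_mode}] {record}")
            if metric > best_metric + 1e-12:
                best_metric, best_state, best_epoch = metric, net.state_dict(), epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        if best_state is not None:
            net.load_state_dict(best_state)
        self.best_epoch_ = best_epoch
        return history

    def _pack_targets(self, graphs: list[ArcGraph]):
        B = len(graphs)
        T = max(len(g) for g in graphs)
        heads = np.zeros((B, T), dtype=int)
        labels = np.zeros((B, T), dtype=int)
        mask = np.zeros((B, T), dtype=bool)
        for b, g in enumerate(graphs):
            n = len(g)
            heads[b, :n] = g.heads
            labels[b, :n] = [self.scheme_.index(lab) for lab in g.labels]
            mask[b, :n] = True
        return heads, labels, mask

    def _predicted_heads(self, head_model, sents, mask) -> np.ndarray:
        rng = np.random.default_rng(0)
        arc_s, _, _ = head_model.forward(sents, rng, train=False)
        masked = np.where(head_mask(mask), arc_s.data, NEG_INF)
        return masked.argmax(axis=1)

    def _head_accuracy(self, net, Xdev, Gdev) -> float:
        correct = total = 0
        for i in range(0, len(Xdev), self.batch_size):
            sents = Xdev[i : i + self.batch_size]
            golds = Gdev[i : i + self.batch_size]
            heads, _, mask = self._pack_targets(golds)
            pred = self._predicted_heads(net, sents, mask)
            correct += int((pred[mask] == heads[mask]).sum())
            total += int(mask.sum())
        return correct / max(total, 1)

    # -- prediction ------------------------------------------------------

    def predict_graphs(self, X: list[list[str]]) -> list[ArcGraph]:
        """Eval-mode arc graphs, one per sentence."""
        self._check_fitted()
        if not X:
            return []
        loss_mode = "joint" if self.mode != "pipeline" else "label_only"
        net = self.network_ if self.mode != "pipeline" else self.label_network_
        head_model = None if self.mode != "pipeline" else self.arc_network_
        return self._predict_graphs_with(X, net, head_model, loss_mode)

    def _predict_graphs_with(self, X, net, head_model, loss_mode):
        rng = np.random.default_rng(0)
        order = np.argsort([len(s) for s in X], kind="stable")
        out: dict[int, ArcGraph] = {}
        for i in range(0, len(order), self.batch_size):
            idx = order[i : i + self.batch_size]
            sents = [X[j] for j in idx]
            arc_s, lab_s, mask = net.forward(sents, rng, train=False)
            arc_data = arc_s.data
            if head_model is not None:
                # pipeline: heads come from the first-stage model
                h = self._predicted_heads(head_model, sents, mask)
                arc_data = np.full_like(arc_data, NEG_INF)
                b, j = np.nonzero(mask)
                arc_data[b, h[b, j], j] = 0.0
            if self.mode == "ner_only":
                # heads are ROOT by construction of the target graphs
                arc_data = np.full_like(arc_data, NEG_INF)
                arc_data[:, 0, :] = 0.0
            decoded = decode_scores(arc_data, lab_s.data, mask, self.scheme_)
            for j, g in zip(idx, decoded):
                out[j] = g
        return [out[j] for j in range(len(X))]

    def _predict_with(self, X, net, head_model, loss_mode) -> list[Annotation]:
        if loss_mode == "arc_only":
            # stage-1 dev metric: unlabeled heads only — score against gold
            # graphs is not available here, so decode with this net's own
            # label scores (metric is still dominated by head accuracy).
            head_model = None
        graphs = self._predict_graphs_with(X, net, head_model, loss_mode)
        return [codec.decode_graph(g, self.scheme_) for g in graphs]

    def predict(self, X: list[list[str]]) -> list[Annotation]:
        """Decoded (entities, relations) per sentence (attributes unset;
        apply :mod:`famgraph.postprocess` for sides, scores and negation)."""
        return [
            codec.decode_graph(g, self.scheme_) for g in self.predict_graphs(X)
        ]

    def _check_fitted(self):
        if not hasattr(self, "scheme_"):
            raise RuntimeError("estimator is not fitted")

    # -- persistence -----------------------------------------------------

    def save(self, path: str) -> None:
        """Versioned checkpoint: weights + configs + vocab + contextual
        fingerprint, as a NumPy archive."""
        self._check_fitted()
        nets = (
            {"network": self.network_}
            if self.mode != "pipeline"
            else {"arc_network": self.arc_network_, "label_network": self.label_network_}
        )
        arrays = {}
        meta_nets = {}
        for name, net in nets.items():
            state = net.state_dict()
            meta_nets[name] = len(state)
            for k, arr in enumerate(state):
                arrays[f"{name}__{k}"] = arr
        enc_cfg = self.encoder_config or EncoderConfig()
        bi_cfg = self.biaffine_config or BiaffineConfig()
        contextual = self.contextual or HashedContextualEncoder(enc_cfg.contextual_dim)
        meta = {
            "format_version": 1,
            "scheme": self.scheme,
            "mode": self.mode,
            "encoder_config": asdict(enc_cfg),
            "biaffine_config": asdict(bi_cfg),
            "char_vocab": self.char_vocab_.chars,
            "contextual_fingerprint": contextual.fingerprint(),
            "params": {
                "lr": self.lr,
                "batch_size": self.batch_size,
                "max_epochs": self.max_epochs,
                "patience": self.patience,
                "dev_fraction": self.dev_fraction,
                "seed": self.seed,
            },
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "BiaffineFamilyHistoryTagger":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("format_version") != 1:
                raise ValueError("unsupported checkpoint version")
            enc_cfg = EncoderConfig(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in meta["encoder_config"].items()
                }
            )
            bi_cfg = BiaffineConfig(**meta["biaffine_config"])
            contextual = HashedContextualEncoder(enc_cfg.contextual_dim)
            if contextual.fingerprint() != meta["contextual_fingerprint"]:
                raise ValueError(
                    "checkpoint was trained with a different contextual encoder: "
                    f"{meta['contextual_fingerprint']}"
                )
            est = cls(
                scheme=meta["scheme"],
                mode=meta["mode"],
                encoder_config=enc_cfg,
                biaffine_config=bi_cfg,
                **meta["params"],
            )
            est.scheme_ = LabelScheme(meta["scheme"])
            est.char_vocab_ = CharVocab(meta["char_vocab"])
            rng = np.random.default_rng(0)

            def restore(name):
                net = _Network(
                    enc_cfg, est.char_vocab_, contextual, est.scheme_, bi_cfg, rng
                )
                n = len(net.parameters())
                net.load_state_dict([data[f"{name}__{k}"] for k in range(n)])
                return net

            if meta["mode"] == "pipeline":
                est.arc_network_ = restore("arc_network")
                est.label_network_ = restore("label_network")
            else:
                est.network_ = restore("network")
            est.history_ = []
            est.best_epoch_ = 0
        return est


# -- functional wrappers -------------------------------------------------------


def train(
    corpus: list[tuple[list[str], Annotation]],
    mode: str = "joint",
    seed: int = 0,
    **params,
) -> BiaffineFamilyHistoryTagger:
    """Train a tagger on (sentence, annotation) pairs."""
    if not corpus:
        raise ValueError("empty corpus")
    X = [s for s, _ in corpus]
    y = [a for _, a in corpus]
    est = BiaffineFamilyHistoryTagger(mode=mode, seed=seed, **params)
    return est.fit(X, y)


def predict(
    model: BiaffineFamilyHistoryTagger, sentences: list[list[str]]
) -> list[Annotation]:
    return model.predict(sentences)


def _annotation_micro_f1(
    gold: list[Annotation], pred: list[Annotation], include_relations: bool = True
) -> float:
    """Micro-F1 over entity (span, type) and relation (span pairs) tuples."""
    def coarse(e: Entity):
        # five-type labels collapse to FamilyMember so the metric is
        # comparable across schemes (side is scored downstream)
        etype = "FamilyMember" if e.is_family_member() else e.etype
        return (e.first, e.last, etype)

    tp = fp = fn = 0
    for (ge, gr), (pe, pr) in zip(gold, pred):
        gset: set = {coarse(e) for e in ge}
        pset: set = {coarse(e) for e in pe}
        if include_relations:
            gset |= {(r.head.span, r.dep.span, "rel") for r in gr}
            pset |= {(r.head.span, r.dep.span, "rel") for r in pr}
        tp += len(gset & pset)
        fp += len(pset - gset)
        fn += len(gset - pset)
    if tp == 0:
        return 0.0
    p, r = tp / (tp + fp), tp / (tp + fn)
    return 2 * p * r / (p + r)
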