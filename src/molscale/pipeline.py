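"""Pre-training orchestration: configuration, the training loop, inference.

The loop per step, for a batch of conformers:

1. build one positive view per scale (jitter / torsion perturbation /
   shape-preserving resampling);
2. online encoder → per-scale embeddings z_k; momentum (key) encoder on the
   views → targets z_k⁺;
3. per-scale InfoNCE against the other molecules' keys in the batch plus a
   per-scale FIFO queue, combined with learnable simplex weights λ;
4. coordinate head on the online node embeddings → internal-coordinate
   regularization against the un-augmented conformer's reference geometry;
5. one Adam step with cosine learning-rate decay, momentum update of the key
   encoder, queue pushes and λ re-normalization.

Reference defaults mirror the full-scale recipe (6×256×8 encoder, τ = 0.07,
queue 65,536, momentum 0.999, batch 256, cosine 1e−4 → 1e−6, γ = 0.1,
η = 0.01, λ init 1/3); :meth:`TrainConfig.smoke` is the desk-scale
configuration used by the test suite.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .autodiff import Tensor, Adam
from .augment import augment_for_scale
from .contrastive import (ContrastiveConfig, NegativeQueue, info_nce,
                          hierarchical_loss, momentum_update, queue_update,
                          mi_lower_bound, lambdas_from_logits)
from .geomreg import (GeoRegConfig, geo_loss, coordinate_head,
                      init_coordinate_head)
from .molgraph import MolecularGraph, extract_geometry_reference
from .scale_attention import (EncoderConfig, encoder_forward, init_params,
                              save_checkpoint, load_checkpoint,
                              scales_from_params, specialization_score)

__all__ = ["TrainConfig", "RunManifest", "pretrain", "encode", "finetune",
           "gate_specialization"]


@dataclass
class TrainConfig:
    """Everything a pre-training run needs, with reference defaults."""

    epochs: int = 100
    batch_size: int = 256
    lr_max: float = 1e-4
    lr_min: float = 1e-6
    seed: int = 0
    w_geo: float = 1.0
    max_disp: float = 0.1            # scale-1 jitter bound, Å
    max_torsion_deg: float = 30.0    # scale-2 torsion bound
    rg_tolerance: float = 0.15       # scale-3 shape band
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    contrastive: ContrastiveConfig = field(default_factory=ContrastiveConfig)
    georeg: GeoRegConfig = field(default_factory=GeoRegConfig)
    log_path: str | None = None

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")

    @classmethod
    def smoke(cls, in_dim: int = 16, seed: int = 0, **kw) -> "TrainConfig":
        """Desk-scale configuration: small encoder, short schedule."""
        defaults = dict(
            epochs=5, batch_size=32, lr_max=2e-3, lr_min=2e-4, seed=seed,
            encoder=EncoderConfig(in_dim=in_dim, hidden=64, layers=2, heads=8,
                                  head_split=(3, 3, 2), proj_dim=32, seed=seed),
            contrastive=ContrastiveConfig(queue_size=512),
        )
        defaults.update(kw)
        return cls(**defaults)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["encoder"]["head_split"] = list(d["encoder"]["head_split"])
        return d


@dataclass
class RunManifest:
    """Reproducibility record of one pre-training run."""

    config: dict
    seed: int
    loss_curve: list            # per-epoch mean combined loss
    step_log: list              # per-step dicts (losses, lambdas, bounds)
    final_lambdas: list
    specialization_init: dict
    specialization_final: dict

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _cosine_lr(step: int, total: int, lr_max: float, lr_min: float) -> float:
    if total <= 1:
        return lr_max
    return lr_min + 0.5 * (lr_max - lr_min) * (1 + math.cos(math.pi * step / (total - 1)))


def gate_specialization(params: dict, corpus, form: str,
                        rng: np.random.Generator) -> dict:
    """Δ_k of the current gates against the corpus' own distance bands."""
    from .molgraph import pairwise_distances

    dists = []
    for g in corpus[: min(len(corpus), 50)]:
        d = pairwise_distances(g.coords)
        dists.append(d[np.triu_indices_from(d, k=1)])
    all_d = np.concatenate(dists)
    bands = [(1.0, 2.0), (2.0, 5.0), (5.0, 12.0)]
    samples = []
    for lo, hi in bands:
        sel = all_d[(all_d >= lo) & (all_d < hi)]
        if sel.size == 0:  # synthetic corpora can be small; fall back to the band
            sel = rng.uniform(lo, hi, 256)
        samples.append(sel)
    scales = scales_from_params(params)
    return specialization_score(scales, samples, form=form)


def pretrain(corpus, config: TrainConfig):
    """Run self-supervised pre-training; returns (params, manifest).

    Deterministic for a fixed corpus, config and seed.  Raises on NaN loss
    with a diagnostic payload naming the offending step.
    """
    if not corpus:
        raise ValueError("empty corpus")
    rng = np.random.default_rng(config.seed)
    enc_cfg = config.encoder
    if enc_cfg.in_dim != corpus[0].atom_features.shape[1]:
        raise ValueError("encoder in_dim does not match corpus features")

    params = init_params(enc_cfg, requires_grad=True)
    params.update(init_coordinate_head(enc_cfg.hidden, seed=config.seed + 1))
    params["lambda_logits"] = Tensor(np.zeros(3), requires_grad=True)
    key_params = {k: Tensor(p.data.copy()) for k, p in params.items()
                  if not k.startswith(("coord_", "lambda_"))}

    trainable = {k: p for k, p in params.items() if p.requires_grad}
    opt = Adam(trainable, lr=config.lr_max)
    queues = {k: NegativeQueue(config.contrastive.queue_size) for k in (1, 2, 3)}
    refs = [extract_geometry_reference(g) for g in corpus]
    tau = config.contrastive.temperature
    inc_pos = config.contrastive.include_positive_in_denominator

    # prefill the queues with key embeddings of augmented corpus views so the
    # negative count (and hence the InfoNCE scale) is constant from step 0
    n = len(corpus)
    fill_target = min(config.contrastive.queue_size, 2 * n)
    for k in (1, 2, 3):
        while len(queues[k]) < fill_target:
            idx = int(rng.integers(n))
            pair = augment_for_scale(corpus[idx], k, int(rng.integers(2**31)),
                                     config.max_disp, config.max_torsion_deg,
                                     config.rg_tolerance)
            kemb = encoder_forward(pair.positive, key_params, enc_cfg)
            queues[k].push(kemb.scale_embeddings[k])

    spec_init = gate_specialization(params, corpus, enc_cfg.gate_form, rng)
    steps_per_epoch = max(1, n // config.batch_size)
    total_steps = config.epochs * steps_per_epoch
    step_log, loss_curve = [], []
    log_fh = open(config.log_path, "w") if config.log_path else None
    step = 0
    try:
        for epoch in range(config.epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for b in range(steps_per_epoch):
                batch_idx = order[b * config.batch_size:(b + 1) * config.batch_size]
                if batch_idx.size == 0:
                    continue
                lam_t = params["lambda_logits"].softmax(axis=0)
                lambdas = lam_t.data.copy()

                # --- forward all molecules, collect per-scale anchors/keys
                online, keys = [], {1: [], 2: [], 3: []}
                geo_terms = []
                for mi_, idx in enumerate(batch_idx):
                    g = corpus[idx]
                    emb = encoder_forward(g, params, enc_cfg, want_tensors=True)
                    online.append(emb)
                    for k in (1, 2, 3):
                        aug_seed = int(rng.integers(2**31))
                        pair = augment_for_scale(
                            g, k, aug_seed, config.max_disp,
                            config.max_torsion_deg, config.rg_tolerance)
                        kemb = encoder_forward(pair.positive, key_params, enc_cfg)
                        keys[k].append(kemb.scale_embeddings[k])
                    pred = coordinate_head(emb.tensors["nodes"],
                                           g.coords, params)
                    geo_terms.append(geo_loss(pred, refs[idx], config.georeg))

                # --- contrastive losses
                per_scale_means = {}
                for k in (1, 2, 3):
                    knp = np.array(keys[k])
                    qarr = queues[k].as_array()
                    losses_k = []
                    for a, emb in enumerate(online):
                        negs = np.vstack([np.delete(knp, a, axis=0)] +
                                         ([qarr] if qarr.size else []))
                        losses_k.append(info_nce(
                            emb.tensors["z"][k], knp[a], negs, tau, inc_pos))
                    acc = losses_k[0]
                    for t in losses_k[1:]:
                        acc = acc + t
                    per_scale_means[k] = acc * (1.0 / len(losses_k))

                contrast = hierarchical_loss(
                    [per_scale_means[k] for k in (1, 2, 3)], lam_t)
                geo_acc = geo_terms[0].tensors["total"]
                for t in geo_terms[1:]:
                    geo_acc = geo_acc + t.tensors["total"]
                geo_mean = geo_acc * (1.0 / len(geo_terms))
                total = contrast + config.w_geo * geo_mean if config.w_geo else contrast
                combined = float(contrast.data) + config.w_geo * float(geo_mean.data)
                if not np.isfinite(combined):
                    raise RuntimeError(
                        f"NaN loss at step {step}: batch={batch_idx.tolist()}, "
                        f"contrast={float(contrast.data)}, geo={float(geo_mean.data)}")

                # --- backward + updates
                opt.zero_grad()
                total.backward()
                opt.step(lr=_cosine_lr(step, total_steps, config.lr_max, config.lr_min))
                enc_online = {k: p for k, p in params.items() if k in key_params}
                momentum_update(enc_online, key_params, config.contrastive.momentum)
                for k in (1, 2, 3):
                    queue_update(queues[k], np.array(keys[k]))

                n_negs = {k: len(queues[k]) + len(batch_idx) - 1 for k in (1, 2, 3)}
                rec = {
                    "step": step, "epoch": epoch,
                    "loss_total": combined,
                    "loss_contrast": float(contrast.data),
                    "loss_geo": float(geo_mean.data),
                    **{f"L{k}": float(per_scale_means[k].data) for k in (1, 2, 3)},
                    **{f"lambda{k}": float(lambdas[k - 1]) for k in (1, 2, 3)},
                    **{f"bound{k}": mi_lower_bound(
                        float(per_scale_means[k].data), max(n_negs[k], 1))
                        for k in (1, 2, 3)},
                }
                step_log.append(rec)
                if log_fh:
                    log_fh.write(json.dumps(rec) + "\n")
                epoch_losses.append(combined)
                step += 1
            loss_curve.append(float(np.mean(epoch_losses)))
    finally:
        if log_fh:
            log_fh.close()

    spec_final = gate_specialization(params, corpus, enc_cfg.gate_form, rng)
    manifest = RunManifest(
        config=config.to_dict(), seed=config.seed, loss_curve=loss_curve,
        step_log=step_log,
        final_lambdas=lambdas_from_logits(params["lambda_logits"]).tolist(),
        specialization_init={str(k): float(v) for k, v in spec_init.items()},
        specialization_final={str(k): float(v) for k, v in spec_final.items()},
    )
    return params, manifest


def save_pretrained(path, params: dict, config: TrainConfig,
                    manifest: RunManifest | None = None):
    extra = {"train_config": config.to_dict()}
    if manifest is not None:
        extra["final_lambdas"] = manifest.final_lambdas
    save_checkpoint(path, params, config.encoder, extra)


def load_pretrained(path):
    params, enc_cfg, extra = load_checkpoint(path)
    return params, enc_cfg, extra


def encode(molecules, params: dict, enc_cfg: EncoderConfig) -> pd.DataFrame:
    """Embed molecules; one row each: z_1, z_2, z_3 and mean-pooled node h."""
    if isinstance(molecules, MolecularGraph):
        molecules = [molecules]
    rows = []
    for g in molecules:
        if g.atom_features.shape[1] != enc_cfg.in_dim:
            raise ValueError("feature dimension does not match checkpoint")
        emb = encoder_forward(g, params, enc_cfg)
        row = {"name": g.name}
        for k in (1, 2, 3):
            for d, v in enumerate(emb.scale_embeddings[k]):
                row[f"z{k}_{d}"] = v
        for d, v in enumerate(emb.node_embeddings.mean(axis=0)):
            row[f"h_{d}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def _embedding_matrix(df: pd.DataFrame) -> np.ndarray:
    cols = [c for c in df.columns if c.startswith(("z1_", "z2_", "z3_"))]
    return df[cols].to_numpy(float)


def finetune(params: dict, enc_cfg: EncoderConfig, molecules, labels,
             task: str = "regression", runs: int = 5, test_frac: float = 0.3,
             seed: int = 0, alpha: float = 1.0) -> dict:
    """Linear probe on frozen concatenated scale embeddings.

    Ridge regression (RMSE) or logistic regression (ROC-AUC) over ``runs``
    random splits; reports mean ± the 95% t-interval half-width
    t_{0.025,n−1}·σ/√n.
    """
    from scipy import stats
    from sklearn.linear_model import LogisticRegression, Ridge
    from sklearn.metrics import mean_squared_error, roc_auc_score

    labels = np.asarray(labels, float)
    if task == "binary" and len(np.unique(labels)) < 2:
        raise ValueError("binary task requires both classes present")
    feats = _embedding_matrix(encode(molecules, params, enc_cfg))
    scores = []
    for r in range(runs):
        rng = np.random.default_rng(seed + r)
        idx = rng.permutation(len(labels))
        n_test = max(1, int(len(labels) * test_frac))
        test, train = idx[:n_test], idx[n_test:]
        if task == "regression":
            model = Ridge(alpha=alpha).fit(feats[train], labels[train])
            scores.append(float(np.sqrt(mean_squared_error(
                labels[test], model.predict(feats[test])))))
        elif task == "binary":
            if len(np.unique(labels[train])) < 2:
                continue
            model = LogisticRegression(max_iter=1000).fit(feats[train], labels[train])
            scores.append(float(roc_auc_score(
                labels[test], model.predict_proba(feats[test])[:, 1])))
        else:
            raise ValueError(f"unknown task: {task}")
    scores = np.array(scores)
    n = len(scores)
    half = float(stats.t.ppf(0.975, n - 1) * scores.std(ddof=1) / math.sqrt(n)) \
        if n > 1 else float("nan")
    metric = "rmse" if task == "regression" else "roc_auc"
    return {"metric": metric, "mean": float(scores.mean()), "ci95_half": half,
            "runs": int(n), "scores": scores.tolist()}
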