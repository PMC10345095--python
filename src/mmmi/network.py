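"""The multi-modal multi-instance (MMMI) network.

Architecture, per patient:

1. an attentive tabular encoder turns the encoded clinicopathological row
   into a fixed-length embedding, keeping per-step feature masks for
   interpretation;
2. each magnification's instance matrix (patch features) is global-average
   pooled into one vector per scale;
3. pooled per-scale vectors and the tabular embedding are concatenated and
   passed through a fully connected layer to form the cross-modal fusion
   vector;
4. at each scale the fusion vector is concatenated to every instance and a
   small MLP scores each patch; softmax over the bag gives instance-attention
   weights, and the weighted sum of (feature-gated) instances is the scale
   embedding;
5. a sigmoid gate computed from the fusion vector recalibrates the tabular
   embedding dimension-wise;
6. the recalibrated tabular embedding and the per-scale embeddings are
   concatenated and classified into the four nodal classes
   (negative / ITC / micro / macro) by an MLP with a softmax head.

Single-modality ablation heads (tabular-only, image-only) live in the same
parameter object so the three models compared in evaluation share code
paths.  Everything runs on :mod:`mmmi.autodiff` tensors.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concat, softmax

__all__ = [
    "ModelConfig",
    "MMMINet",
    "TabularEncoder",
    "pool_scale",
    "N_CLASSES",
    "CLASS_NAMES",
]

N_CLASSES = 4
CLASS_NAMES = ("negative", "itc", "micro", "macro")


@dataclass
class ModelConfig:
    """Dimensions and structural choices of the network.

    The published description fixes none of these sizes; defaults are modest
    widths suitable for CPU training and are all overridable.
    """

    feature_dim: int = 64            # patch-feature dimensionality d
    n_variables: int = 17            # tabular variables after encoding
    embed_dim: int = 32              # tabular embedding width
    fusion_dim: int = 64             # cross-modal fusion vector width
    attn_hidden: int = 32            # instance-attention MLP hidden width
    classifier_hidden: tuple = (64, 32)
    n_steps: int = 3                 # tabular encoder decision steps
    scales: tuple = (5, 10, 20)
    relaxation: float = 1.3          # prior relaxation across decision steps
    instance_cap: int = 2000         # uniform subsample cap per bag (seeded)
    modality: str = "mmmi"           # mmmi | tabular | image

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def _glorot(rng, n_in, n_out):
    lim = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-lim, lim, size=(n_in, n_out))


def pool_scale(instances) -> np.ndarray:
    """Global average pooling of a bag: the arithmetic mean over instances."""
    arr = instances.data if isinstance(instances, Tensor) else np.asarray(instances)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("pool_scale needs a nonempty n_instances x d matrix")
    if isinstance(instances, Tensor):
        return instances.mean(axis=0, keepdims=True)
    return arr.mean(axis=0, keepdims=True)


class TabularEncoder:
    """Attentive tabular encoder with sequential feature masking.

    At each decision step a linear attentive transformer scores the input
    variables, a softmax (rescaled by a prior that discounts variables already
    used in earlier steps) yields a nonnegative mask summing to one, and the
    masked input passes through a ReLU feature transformer.  Step outputs are
    summed into the embedding; the per-step masks are retained so variable
    importance can be aggregated from them.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator,
                 params: dict | None = None, prefix: str = "tab"):
        self.config = config
        self.prefix = prefix
        v, e = config.n_variables, config.embed_dim
        if params is None:
            params = {}
            for s in range(config.n_steps):
                params[f"{prefix}.att{s}.W"] = Tensor(_glorot(rng, v, v), True)
                params[f"{prefix}.att{s}.b"] = Tensor(np.zeros(v), True)
                params[f"{prefix}.feat{s}.W"] = Tensor(_glorot(rng, v, e), True)
                params[f"{prefix}.feat{s}.b"] = Tensor(np.zeros(e), True)
        self.params = params

    def __call__(self, x: Tensor):
        """Encode rows ``x`` (n, n_variables) -> (embedding (n, e), masks (steps, n, v))."""
        p, cfg = self.params, self.config
        prior = Tensor(np.ones_like(x.data))
        emb = None
        masks = []
        for s in range(cfg.n_steps):
            score = x @ p[f"{self.prefix}.att{s}.W"] + p[f"{self.prefix}.att{s}.b"]
            m = softmax(score, axis=-1) * prior
            m = m / m.sum(axis=-1, keepdims=True)
            masks.append(m)
            h = ((x * m) @ p[f"{self.prefix}.feat{s}.W"]
                 + p[f"{self.prefix}.feat{s}.b"]).relu()
            emb = h if emb is None else emb + h
            prior = prior * (cfg.relaxation - m)
        return emb, masks


class MMMINet:
    """Parameter container plus forward pass for the full model and its
    single-modality ablation heads."""

    def __init__(self, config: ModelConfig, seed: int = 0,
                 params: dict | None = None):
        self.config = config
        rng = np.random.default_rng(seed)
        d, e, f, h = (config.feature_dim, config.embed_dim,
                      config.fusion_dim, config.attn_hidden)
        ns = len(config.scales)
        if params is None:
            params = {}
            self.encoder = TabularEncoder(config, rng, prefix="tab")
            params.update(self.encoder.params)
            # cross-modal fusion (image pools + tabular embedding)
            params["fuse.W"] = Tensor(_glorot(rng, ns * d + e, f), True)
            params["fuse.b"] = Tensor(np.zeros(f), True)
            # image-only fusion used by the image ablation head
            params["fuse_img.W"] = Tensor(_glorot(rng, ns * d, f), True)
            params["fuse_img.b"] = Tensor(np.zeros(f), True)
            for sc in config.scales:
                # W1 is split into an instance part and a fusion part; the
                # two matmuls sum, equivalent to one matmul on the
                # concatenation but without tiling the fusion vector
                params[f"attn{sc}.W1i"] = Tensor(_glorot(rng, d, h), True)
                params[f"attn{sc}.W1f"] = Tensor(_glorot(rng, f, h), True)
                params[f"attn{sc}.b1"] = Tensor(np.zeros(h), True)
                params[f"attn{sc}.W2"] = Tensor(_glorot(rng, h, 1), True)
                params[f"attn{sc}.b2"] = Tensor(np.zeros(1), True)
                params[f"gate{sc}"] = Tensor(np.zeros(d), True)  # feature-level gate
            params["recal.W"] = Tensor(_glorot(rng, f, e), True)
            params["recal.b"] = Tensor(np.zeros(e), True)
            self._init_mlp(params, "clf", e + ns * d, config.classifier_hidden,
                           N_CLASSES, rng)
            self._init_mlp(params, "head_tab", e, (config.classifier_hidden[-1],),
                           N_CLASSES, rng)
            self._init_mlp(params, "head_img", ns * d,
                           (config.classifier_hidden[-1],), N_CLASSES, rng)
        else:
            self.encoder = TabularEncoder(config, rng, params=params, prefix="tab")
        self.params = params

    @staticmethod
    def _init_mlp(params, name, n_in, hidden, n_out, rng):
        dims = [n_in, *hidden, n_out]
        for i in range(len(dims) - 1):
            params[f"{name}.{i}.W"] = Tensor(_glorot(rng, dims[i], dims[i + 1]), True)
            params[f"{name}.{i}.b"] = Tensor(np.zeros(dims[i + 1]), True)

    def _mlp(self, name, x: Tensor, n_layers: int) -> Tensor:
        for i in range(n_layers):
            x = x @ self.params[f"{name}.{i}.W"] + self.params[f"{name}.{i}.b"]
            if i < n_layers - 1:
                x = x.relu()
        return x

    # -- component operations -------------------------------------------------
    def fuse_modalities(self, pooled: dict, tab_emb: Tensor) -> Tensor:
        """Concatenate per-scale pooled vectors with the tabular embedding and
        map through a fully connected layer (tanh) to the fusion vector."""
        parts = [pooled[sc] for sc in self.config.scales] + [tab_emb]
        return (concat(parts, axis=-1) @ self.params["fuse.W"]
                + self.params["fuse.b"]).tanh()

    def fuse_image_only(self, pooled: dict) -> Tensor:
        parts = [pooled[sc] for sc in self.config.scales]
        return (concat(parts, axis=-1) @ self.params["fuse_img.W"]
                + self.params["fuse_img.b"]).tanh()

    def attend_instances(self, instances: Tensor, fusion: Tensor, scale: int):
        """Fusion-guided instance attention at one scale.

        Returns (weights (n,), scale embedding (1, d)).  Weights are a softmax
        over patch scores, so they are nonnegative and sum to one; the
        embedding is the attention-weighted sum of feature-gated instances,
        hence invariant to instance order.
        """
        n = instances.data.shape[0]
        if n < 1:
            raise ValueError("empty bag")
        h = (instances @ self.params[f"attn{scale}.W1i"]
             + fusion @ self.params[f"attn{scale}.W1f"]
             + self.params[f"attn{scale}.b1"]).tanh()
        scores = (h @ self.params[f"attn{scale}.W2"]
                  + self.params[f"attn{scale}.b2"]).reshape(1, n)
        w = softmax(scores, axis=-1)
        gate = self.params[f"gate{scale}"].sigmoid() * 2.0  # feature-level gate
        emb = w @ (instances * gate)
        return w.reshape(n), emb

    def recalibrate_tabular(self, tab_emb: Tensor, fusion: Tensor):
        """Sigmoid gate from the fusion vector, applied dimension-wise."""
        gate = (fusion @ self.params["recal.W"] + self.params["recal.b"]).sigmoid()
        return gate * tab_emb, gate

    def classify(self, tab_recal: Tensor, scale_embs: dict) -> Tensor:
        parts = [tab_recal] + [scale_embs[sc] for sc in self.config.scales]
        return self._mlp("clf", concat(parts, axis=-1),
                         len(self.config.classifier_hidden) + 1)

    # -- forward passes -------------------------------------------------------
    def _prepare_bag(self, bag: dict, seed: int | None = None) -> dict:
        """Tensor-ify a scale->array bag, subsampling above the instance cap."""
        out = {}
        cap = self.config.instance_cap
        rng = np.random.default_rng(seed) if seed is not None else None
        for sc in self.config.scales:
            if isinstance(bag[sc], Tensor):      # already prepared (cached)
                out[sc] = bag[sc]
                continue
            arr = np.asarray(bag[sc], dtype=np.float64)
            if arr.ndim != 2 or arr.shape[0] < 1:
                raise ValueError(f"scale {sc}: empty or malformed instance matrix")
            if arr.shape[0] > cap:
                r = rng or np.random.default_rng(0)
                idx = np.sort(r.choice(arr.shape[0], size=cap, replace=False))
                arr = arr[idx]
            out[sc] = Tensor(arr)
        return out

    def forward(self, bag: dict | None, x_row, mode: str | None = None):
        """Full forward pass for one patient.

        Parameters
        ----------
        bag : mapping scale -> (n_s, d) array (``None`` allowed for tabular mode)
        x_row : (n_variables,) encoded, standardized tabular row
                (``None`` allowed for image mode)
        mode : "mmmi" (default from config), "tabular" or "image"

        Returns ``(logits (1,4) Tensor, state dict)``; the state exposes
        attention weights, the recalibration gate and the fusion vector.
        """
        mode = mode or self.config.modality
        state: dict = {"mode": mode}
        if mode == "tabular":
            x = Tensor(np.asarray(x_row, dtype=np.float64).reshape(1, -1))
            emb, masks = self.encoder(x)
            state["feature_masks"] = [m.data[0] for m in masks]
            logits = self._mlp("head_tab", emb, 2)
            return logits, state

        bags = self._prepare_bag(bag)
        pooled = {sc: pool_scale(bags[sc]) for sc in self.config.scales}

        if mode == "image":
            fusion = self.fuse_image_only(pooled)
        else:
            x = Tensor(np.asarray(x_row, dtype=np.float64).reshape(1, -1))
            tab_emb, masks = self.encoder(x)
            state["feature_masks"] = [m.data[0] for m in masks]
            fusion = self.fuse_modalities(pooled, tab_emb)
        state["fusion_vector"] = fusion.data[0]

        weights, scale_embs = {}, {}
        for sc in self.config.scales:
            w, emb = self.attend_instances(bags[sc], fusion, sc)
            weights[sc], scale_embs[sc] = w, emb
        state["attention"] = {sc: weights[sc].data for sc in weights}

        if mode == "image":
            logits = self._mlp(
                "head_img",
                concat([scale_embs[sc] for sc in self.config.scales], axis=-1), 2)
            return logits, state

        tab_recal, gate = self.recalibrate_tabular(tab_emb, fusion)
        state["tabular_gate"] = gate.data[0]
        logits = self.classify(tab_recal, scale_embs)
        return logits, state

    def predict_proba(self, bag, x_row, mode: str | None = None):
        logits, state = self.forward(bag, x_row, mode=mode)
        probs = softmax(logits, axis=-1)
        return probs.data[0], state

    # -- parameter bookkeeping ------------------------------------------------
    def parameter_groups(self, mode: str | None = None) -> dict:
        """Map group name -> parameter names, restricted to the active head.

        Groups mirror the published per-group learning rates: the tabular
        encoder, the classifier head(s), and everything else.
        """
        mode = mode or self.config.modality
        names = set(self.params)
        tab = {n for n in names if n.startswith("tab.")}
        heads = {"mmmi": "clf", "tabular": "head_tab", "image": "head_img"}
        clf = {n for n in names if n.startswith(heads[mode] + ".")}
        if mode == "tabular":
            rest: set = set()
        elif mode == "image":
            rest = {n for n in names
                    if n.startswith(("attn", "gate", "fuse_img."))}
            tab = set()
        else:
            rest = {n for n in names
                    if n.startswith(("attn", "gate", "fuse.", "recal."))}
        return {"tabular": sorted(tab), "classifier": sorted(clf),
                "rest": sorted(rest)}

    def config_hash(self) -> str:
        return hashlib.sha256(self.config.to_json().encode()).hexdigest()[:12]

    def save(self, path):
        """Single-file checkpoint: npz of arrays + embedded config JSON."""
        arrays = {k: v.data for k, v in self.params.items()}
        buf = io.BytesIO()
        np.savez(buf, **arrays)
        with open(path, "wb") as fh:
            header = json.dumps({"config": asdict(self.config),
                                 "hash": self.config_hash()}).encode()
            fh.write(len(header).to_bytes(8, "little"))
            fh.write(header)
            fh.write(buf.getvalue())

    @classmethod
    def load(cls, path) -> "MMMINet":
        with open(path, "rb") as fh:
            n = int.from_bytes(fh.read(8), "little")
            meta = json.loads(fh.read(n).decode())
            npz = np.load(io.BytesIO(fh.read()))
        cfg = ModelConfig(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in meta["config"].items()})
        params = {k: Tensor(npz[k], True) for k in npz.files}
        return cls(cfg, params=params)

    def copy(self) -> "MMMINet":
        params = {k: Tensor(v.data.copy(), True) for k, v in self.params.items()}
        return MMMINet(self.config, params=params)
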