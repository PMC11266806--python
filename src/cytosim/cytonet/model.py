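"""CytoNet model definition: 4 Conv1D + 3 Pool1D + SE attention + GAP + FC."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from cytosim.cytonet import _layers as L

CLASS_NAMES = ("WBC", "TUMOR")

CHECKPOINT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyper-parameters.

    The layer counts (4 convolution stages, 3 pooling stages, attention
    before global average pooling, 2-class softmax head) are structural
    invariants; filter counts and kernel size are configurable stand-ins.
    """

    input_len: int = 100
    in_channels: int = 6
    filters: tuple = (32, 64, 64, 128)
    kernel_size: int = 5
    channel_attention: bool = True
    attention_reduction: int = 4
    n_classes: int = 2

    def __post_init__(self) -> None:
        if len(self.filters) != 4:
            raise ValueError("exactly 4 convolution stages required")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 1")
        if self.n_classes != 2:
            raise ValueError("the classifier head is a 2-class softmax")
        if self.attention_reduction < 1:
            raise ValueError("attention_reduction must be >= 1")
        object.__setattr__(self, "filters", tuple(int(f) for f in self.filters))

    @property
    def n_pool_layers(self) -> int:
        return 3


class CytoNetModel:
    """NumPy forward/backward implementation of the classifier."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        k = spec.kernel_size
        p: dict[str, np.ndarray] = {}
        c_in = spec.in_channels
        for i, f in enumerate(spec.filters):
            p[f"conv{i}_w"] = L.he_init(rng, c_in * k, (c_in * k, f))
            p[f"conv{i}_b"] = np.zeros(f, dtype=np.float32)
            c_in = f
        if spec.channel_attention:
            c = spec.filters[-1]
            hidden = max(1, c // spec.attention_reduction)
            p["se_w1"] = L.he_init(rng, c, (c, hidden))
            p["se_b1"] = np.zeros(hidden, dtype=np.float32)
            p["se_w2"] = L.he_init(rng, hidden, (hidden, c))
            p["se_b2"] = np.zeros(c, dtype=np.float32)
        p["fc_w"] = L.he_init(rng, spec.filters[-1], (spec.filters[-1], spec.n_classes))
        p["fc_b"] = np.zeros(spec.n_classes, dtype=np.float32)
        self.params = p

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, return_cache: bool = False):
        """x: (N, 100, 6) -> logits (N, 2)."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 3 or x.shape[1:] != (self.spec.input_len, self.spec.in_channels):
            raise ValueError(
                f"expected input (N, {self.spec.input_len}, {self.spec.in_channels})"
            )
        p = self.params
        caches = []
        h = x
        for i in range(4):
            h, c_conv = L.conv1d_forward(h, p[f"conv{i}_w"], p[f"conv{i}_b"],
                                         self.spec.kernel_size)
            h, c_relu = L.relu_forward(h)
            if i < 3:
                h, c_pool = L.maxpool_forward(h)
            else:
                c_pool = None
            caches.append((c_conv, c_relu, c_pool))
        if self.spec.channel_attention:
            h, c_se = L.se_forward(h, p["se_w1"], p["se_b1"], p["se_w2"], p["se_b2"])
        else:
            c_se = None
        g, c_gap = L.gap_forward(h)
        logits, c_fc = L.dense_forward(g, p["fc_w"], p["fc_b"])
        if return_cache:
            return logits, (caches, c_se, c_gap, c_fc)
        return logits

    def backward(self, dlogits: np.ndarray, cache) -> dict:
        caches, c_se, c_gap, c_fc = cache
        p = self.params
        grads: dict[str, np.ndarray] = {}
        dg, grads["fc_w"], grads["fc_b"] = L.dense_backward(dlogits, c_fc, p["fc_w"])
        dh = L.gap_backward(dg, c_gap)
        if self.spec.channel_attention:
            dh, grads["se_w1"], grads["se_b1"], grads["se_w2"], grads["se_b2"] = (
                L.se_backward(dh, c_se)
            )
        for i in range(3, -1, -1):
            c_conv, c_relu, c_pool = caches[i]
            if c_pool is not None:
                dh = L.maxpool_backward(dh, c_pool)
            dh = L.relu_backward(dh, c_relu)
            dh, grads[f"conv{i}_w"], grads[f"conv{i}_b"] = L.conv1d_backward(dh, c_conv)
        return grads

    # -- inference ----------------------------------------------------------

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Class probabilities (softmax), components >= 0 summing to 1."""
        x = np.asarray(x, dtype=np.float32)
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(L.softmax(self.forward(x[i : i + batch_size])))
        return np.vstack(out) if out else np.empty((0, self.spec.n_classes))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        header = {
            "schema_version": CHECKPOINT_SCHEMA_VERSION,
            "spec": asdict(self.spec),
            "class_names": list(CLASS_NAMES),
        }
        np.savez(path, __header__=np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path) -> "CytoNetModel":
        data = np.load(path)
        header = json.loads(bytes(data["__header__"]).decode())
        version = header.get("schema_version")
        if version != CHECKPOINT_SCHEMA_VERSION:
            raise ValueError(
                f"unsupported checkpoint schema version {version} "
                f"(expected {CHECKPOINT_SCHEMA_VERSION})"
            )
        spec_d = header["spec"]
        spec_d["filters"] = tuple(spec_d["filters"])
        model = cls(ModelSpec(**spec_d), seed=0)
        for key in model.params:
            model.params[key] = data[key]
        return model


def build_model(spec: ModelSpec | None = None, seed: int = 0) -> CytoNetModel:
    """Deterministically initialised, untrained model."""
    return CytoNetModel(spec or ModelSpec(), seed=seed)
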