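"""The EEG sequence classifier.

Two parts, mirroring the sleep-staging network family it derives from:

* a dual-branch multi-scale 1-D convolutional **feature extractor** — a
  small-kernel branch (kernel 50, stride 6) tuned to fast/temporal detail and
  a large-kernel branch (kernel 400, stride 50) tuned to slow rhythms, each
  followed by max-pooling, three mid convolutions and a second pooling; the
  two 128-channel branch outputs are truncated to a common time length and
  concatenated into 256-dim feature vectors per epoch;

* a **seq2seq classifier** over sequences of consecutive epochs — a 2-layer
  bidirectional LSTM encoder (128 units per direction), multiplicative
  (Luong) attention with a 64-dim projection, a 2-layer LSTM decoder that
  embeds the previously emitted label (embed size 10, teacher forcing during
  training, greedy decoding otherwise) and a dense output head with 5 (sleep
  stages) or 3 (fatigue levels) classes.

All tensors run on the package's own numpy autograd engine.  Initialisation:
Glorot-uniform for dense/conv kernels, per-gate orthogonal for recurrent
kernels, zero biases — so an all-zero input yields all-zero extractor
features at initialisation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .eeg_core import ParameterError

__all__ = [
    "ConvStage", "FeatureExtractorSpec", "Seq2SeqSpec", "DEFAULT_EXTRACTOR",
    "DEFAULT_SEQ2SEQ", "conv_output_length", "branch_output_length",
    "FeatureExtractor", "SeqClassifier", "EEGSeqNet", "forward_features",
    "forward_classify", "replace_head", "parameter_checksums",
    "count_parameters", "save_model", "load_model",
]

#: Label-embedding vocabulary: the 5 source classes + 1 start token.  Target
#: classes reuse indices 0–2, so swapping the dense head never touches the
#: embedding table.
VOCAB_SIZE = 6
START_TOKEN = 5


# ------------------------------------------------------------------- specs

@dataclass(frozen=True)
class ConvStage:
    """One branch of the extractor: first conv, pool, three mid convs, pool."""

    conv1_kernel: int
    conv1_stride: int
    conv1_filters: int
    pool1: int                   # window == stride
    mid_kernel: int
    mid_filters: int
    pool2: int


@dataclass(frozen=True)
class FeatureExtractorSpec:
    small: ConvStage = ConvStage(50, 6, 64, 8, 8, 128, 4)
    large: ConvStage = ConvStage(400, 50, 64, 4, 6, 128, 2)
    dropout: float = 0.5
    input_length: int = 3000

    @property
    def feature_dim(self) -> int:
        return self.small.mid_filters + self.large.mid_filters


@dataclass(frozen=True)
class Seq2SeqSpec:
    embed_size: int = 10
    encoder_layers: int = 2
    encoder_units: int = 128
    attention_size: int = 64
    decoder_layers: int = 2
    decoder_units: int = 128
    n_classes: int = 5
    input_dim: int = 256

    def __post_init__(self):
        if self.n_classes not in (3, 5):
            raise ParameterError("n_classes must be 3 or 5")


DEFAULT_EXTRACTOR = FeatureExtractorSpec()
DEFAULT_SEQ2SEQ = Seq2SeqSpec()


def conv_output_length(length: int, kernel: int, stride: int,
                       padding: str = "valid") -> int:
    """Output length of a 1-D convolution/pooling stage."""
    if padding == "valid":
        if length < kernel:
            raise ParameterError(f"length {length} shorter than kernel {kernel}")
        return (length - kernel) // stride + 1
    if padding == "same":
        return -(-length // stride)  # ceil
    raise ParameterError(f"unknown padding {padding!r}")


def branch_output_length(input_length: int, stage: ConvStage) -> int:
    """Closed-form time length of one branch for any input length ≥ kernel.

    The first (wide) conv and both pools are valid; the three mid convs use
    'same' padding, which is what keeps the large branch viable (valid
    kernel-6 convs would need length ≥ 16 where only 13 samples remain).
    """
    n = conv_output_length(input_length, stage.conv1_kernel, stage.conv1_stride)
    n = conv_output_length(n, stage.pool1, stage.pool1)
    for _ in range(3):
        n = conv_output_length(n, stage.mid_kernel, 1, padding="same")
    n = conv_output_length(n, stage.pool2, stage.pool2)
    return n


# ------------------------------------------------------------------- layers

def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def _orthogonal_gates(rng: np.random.Generator, n: int, gates: int) -> Tensor:
    """(n, gates*n) matrix made of per-gate orthogonal blocks."""
    blocks = []
    for _ in range(gates):
        q, _r = np.linalg.qr(rng.standard_normal((n, n)))
        blocks.append(q)
    return Tensor(np.concatenate(blocks, axis=1), requires_grad=True)


class _Module:
    """Tiny parameter-registry base class."""

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad is not None:
                if isinstance(val.data, np.ndarray):
                    out[name] = val
            elif isinstance(val, _Module):
                for k, v in val.parameters().items():
                    out[f"{name}.{k}"] = v
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, _Module):
                        for k, v in item.parameters().items():
                            out[f"{name}.{i}.{k}"] = v
        return out


class Dense(_Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = _glorot(rng, (in_dim, out_dim), in_dim, out_dim)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Conv1d(_Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator, padding: str = "valid"):
        self.kernel, self.stride, self.padding = kernel, stride, padding
        fan_in, fan_out = in_ch * kernel, out_ch * kernel
        self.W = _glorot(rng, (out_ch, in_ch, kernel), fan_in, fan_out)
        self.b = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        pad = 0
        if self.padding == "same":
            # total pad so out_len = ceil(in/stride); stride is 1 for mid convs
            pad = (self.kernel - 1) // 2
            if (self.kernel - 1) % 2:
                # asymmetric case: pad one extra on the right only
                B, C, L = x.shape
                x = ag.concatenate([x, Tensor(np.zeros((B, C, 1)))], axis=2)
        return x.conv1d(self.W, self.b, stride=self.stride, padding=pad)


class LSTMLayer(_Module):
    """Single-direction LSTM; gate order i, f, g, o; zero initial state."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.W = _glorot(rng, (in_dim, 4 * hidden), in_dim, 4 * hidden)
        self.U = _orthogonal_gates(rng, hidden, 4)
        self.b = Tensor(np.zeros(4 * hidden), requires_grad=True)

    def step(self, x_t: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        H = self.hidden
        z = x_t @ self.W + h @ self.U + self.b
        i = z[:, 0 * H:1 * H].sigmoid()
        f = z[:, 1 * H:2 * H].sigmoid()
        g = z[:, 2 * H:3 * H].tanh()
        o = z[:, 3 * H:4 * H].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new

    def __call__(self, xs: Tensor, reverse: bool = False) -> Tensor:
        B, S, _ = xs.shape
        h = Tensor(np.zeros((B, self.hidden)))
        c = Tensor(np.zeros((B, self.hidden)))
        outs: list[Tensor] = []
        order = range(S - 1, -1, -1) if reverse else range(S)
        for t in order:
            h, c = self.step(xs[:, t, :], h, c)
            outs.append(h)
        if reverse:
            outs = outs[::-1]
        return ag.stack(outs, axis=1)  # (B, S, H)


class BiLSTMLayer(_Module):
    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.fwd = LSTMLayer(in_dim, hidden, rng)
        self.bwd = LSTMLayer(in_dim, hidden, rng)

    def __call__(self, xs: Tensor) -> Tensor:
        return ag.concatenate([self.fwd(xs), self.bwd(xs, reverse=True)], axis=2)


def _dropout(x: Tensor, p: float, rng: np.random.Generator,
             training: bool) -> Tensor:
    if not training or p <= 0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


# -------------------------------------------------------- feature extractor

class _Branch(_Module):
    def __init__(self, stage: ConvStage, dropout: float, rng):
        self.stage, self.dropout = stage, dropout
        self.conv1 = Conv1d(1, stage.conv1_filters, stage.conv1_kernel,
                            stage.conv1_stride, rng)
        self.mids = [
            Conv1d(stage.conv1_filters if i == 0 else stage.mid_filters,
                   stage.mid_filters, stage.mid_kernel, 1, rng, padding="same")
            for i in range(3)
        ]

    def __call__(self, x: Tensor, training: bool, rng) -> Tensor:
        st = self.stage
        h = self.conv1(x).relu()
        h = h.maxpool1d(st.pool1, st.pool1)
        h = _dropout(h, self.dropout, rng, training)
        for conv in self.mids:
            h = conv(h).relu()
        h = h.maxpool1d(st.pool2, st.pool2)
        h = _dropout(h, self.dropout, rng, training)
        return h  # (B, mid_filters, T)


class FeatureExtractor(_Module):
    def __init__(self, spec: FeatureExtractorSpec = DEFAULT_EXTRACTOR,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.small = _Branch(spec.small, spec.dropout, rng)
        self.large = _Branch(spec.large, spec.dropout, rng)
        self._drop_rng = np.random.default_rng(seed + 1)

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        """x: (B, L) raw epochs → (B, T, 256) feature sequences.

        Each epoch is z-scored first (standard practice for raw-waveform EEG
        networks; microvolt-scale inputs would saturate downstream gates).
        """
        B, L = x.shape
        exp = self.spec.input_length
        if L != exp:
            raise ParameterError(
                f"expected epochs of length {exp} samples, got {L}")
        mu = x.data.mean(axis=1, keepdims=True)
        sd = x.data.std(axis=1, keepdims=True) + 1e-12
        x = (x - Tensor(mu)) * Tensor(1.0 / sd)
        x3 = x.reshape(B, 1, L)
        hs = self.small(x3, training, self._drop_rng)
        hl = self.large(x3, training, self._drop_rng)
        T = min(hs.shape[2], hl.shape[2])
        merged = ag.concatenate([hs[:, :, :T], hl[:, :, :T]], axis=1)
        return merged.transpose(0, 2, 1)  # (B, T, 256)


# --------------------------------------------------------- seq2seq classifier

class SeqClassifier(_Module):
    def __init__(self, spec: Seq2SeqSpec = DEFAULT_SEQ2SEQ, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        H, A = spec.encoder_units, spec.attention_size
        enc_out_dim = 2 * H
        self.embedding = _glorot(rng, (VOCAB_SIZE, spec.embed_size),
                                 VOCAB_SIZE, spec.embed_size)
        self.encoder = [
            BiLSTMLayer(spec.input_dim if i == 0 else enc_out_dim, H, rng)
            for i in range(spec.encoder_layers)
        ]
        self.decoder = [
            LSTMLayer(spec.embed_size if i == 0 else spec.decoder_units,
                      spec.decoder_units, rng)
            for i in range(spec.decoder_layers)
        ]
        self.attn_enc = Dense(enc_out_dim, A, rng)
        self.attn_dec = Dense(spec.decoder_units, A, rng)
        # combine sees [attention context; aligned encoder state; decoder
        # state]: labels align one-to-one with input epochs, so the step-t
        # encoder state is a legitimate direct input alongside the context
        self.combine = Dense(2 * enc_out_dim + spec.decoder_units,
                             spec.decoder_units, rng)
        self.head = Dense(spec.decoder_units, spec.n_classes, rng)
        self._head_seed = seed

    # -- encoder ---------------------------------------------------------

    def encode(self, feats: Tensor) -> Tensor:
        """(B, S, input_dim) epoch embeddings → (B, S, 2H) encoder states."""
        h = feats
        for layer in self.encoder:
            h = layer(h)
        return h

    # -- decoder with Luong attention ------------------------------------

    def decode(self, enc_out: Tensor, labels: np.ndarray | None,
               training: bool) -> tuple[Tensor, np.ndarray]:
        B, S, _ = enc_out.shape
        enc_proj = self.attn_enc(enc_out)  # (B, S, A)
        hs = [Tensor(np.zeros((B, self.spec.decoder_units)))
              for _ in self.decoder]
        cs = [Tensor(np.zeros((B, self.spec.decoder_units)))
              for _ in self.decoder]
        prev = np.full(B, START_TOKEN, dtype=np.int64)
        logits_steps: list[Tensor] = []
        attn = np.zeros((B, S, S))
        for t in range(S):
            x = self.embedding[prev]  # (B, embed)
            for li, layer in enumerate(self.decoder):
                hs[li], cs[li] = layer.step(x, hs[li], cs[li])
                x = hs[li]
            dec_proj = self.attn_dec(x)                       # (B, A)
            scores = (enc_proj * dec_proj.reshape(B, 1, -1)).sum(axis=2)
            alpha = scores.log_softmax(axis=1).exp()          # (B, S)
            attn[:, t, :] = alpha.data
            context = (enc_out * alpha.reshape(B, S, 1)).sum(axis=1)
            combined = ag.concatenate([context, enc_out[:, t, :], x], axis=1)
            h_tilde = self.combine(combined).tanh()
            step_logits = self.head(h_tilde)                  # (B, n_classes)
            logits_steps.append(step_logits)
            if training and labels is not None:
                prev = labels[:, t].astype(np.int64)          # teacher forcing
            else:
                prev = step_logits.data.argmax(axis=1)        # greedy
        return ag.stack(logits_steps, axis=1), attn            # (B, S, K)

    def __call__(self, feats: Tensor, labels: np.ndarray | None = None,
                 training: bool = False):
        if feats.shape[2] != self.spec.input_dim:
            raise ParameterError(
                f"feature dim {feats.shape[2]} != spec input_dim "
                f"{self.spec.input_dim}")
        # parameter-free layer norm: pooled conv features arrive at a tiny
        # dynamic range; normalising each epoch embedding across its 256
        # dims keeps the recurrent gates in their responsive region
        mu = feats.mean(axis=2, keepdims=True)
        centred = feats - mu
        var = (centred * centred).mean(axis=2, keepdims=True)
        feats = centred * ((var + 1e-8) ** -0.5)
        enc_out = self.encode(feats)
        logits, attn = self.decode(enc_out, labels, training)
        return logits, attn, enc_out


# ----------------------------------------------------------------- full net

class EEGSeqNet(_Module):
    """Extractor + seq2seq over sequences of consecutive epochs."""

    def __init__(self, extractor_spec: FeatureExtractorSpec = DEFAULT_EXTRACTOR,
                 seq_spec: Seq2SeqSpec = DEFAULT_SEQ2SEQ, seed: int = 0):
        self.seed = seed
        self.extractor = FeatureExtractor(extractor_spec, seed)
        self.classifier = SeqClassifier(seq_spec, seed + 1000)
        self.extractor_frozen = False

    # epoch features -> per-epoch embedding: mean over the within-epoch time
    # axis, giving one 256-vector per epoch for the sequence model.

    def epoch_embeddings(self, x: Tensor, training: bool = False) -> Tensor:
        """x: (B, S, L) epoch sequences → (B, S, 256)."""
        B, S, L = x.shape
        feats = self.extractor(x.reshape(B * S, L),
                               training=training and not self.extractor_frozen)
        emb = feats.mean(axis=1)          # (B*S, 256)
        return emb.reshape(B, S, -1)

    def forward(self, x: Tensor, labels: np.ndarray | None = None,
                training: bool = False):
        """Returns (logits (B,S,K), attention (B,S,S), pooled enc (B, 2H))."""
        emb = self.epoch_embeddings(x, training)
        logits, attn, enc_out = self.classifier(emb, labels, training)
        return logits, attn, enc_out.mean(axis=1)

    def classify_from_embeddings(self, emb: Tensor,
                                 labels: np.ndarray | None = None,
                                 training: bool = False):
        logits, attn, enc_out = self.classifier(emb, labels, training)
        return logits, attn, enc_out.mean(axis=1)

    def predict(self, x: Tensor) -> np.ndarray:
        logits, _, _ = self.forward(x, training=False)
        return logits.data.argmax(axis=2)

    def freeze_extractor(self):
        for p in self.extractor.parameters().values():
            p.requires_grad = False
        self.extractor_frozen = True

    def trainable_parameters(self) -> dict[str, Tensor]:
        return {k: v for k, v in self.parameters().items() if v.requires_grad}


# ------------------------------------------------------------- op wrappers

def forward_features(extractor: FeatureExtractor, epochs: np.ndarray,
                     training: bool = False) -> np.ndarray:
    """(n_epochs, L) raw samples → (n_epochs, T, 256) feature sequences."""
    out = extractor(Tensor(np.asarray(epochs, dtype=float)), training=training)
    return out.data


def forward_classify(classifier: SeqClassifier, features: np.ndarray,
                     training: bool = False, labels: np.ndarray | None = None):
    """(B, S, 256) epoch-embedding sequences → (scores (B,S,K), attention)."""
    logits, attn, _ = classifier(Tensor(np.asarray(features, dtype=float)),
                                 labels, training)
    return logits.data, attn


def replace_head(model: EEGSeqNet, n_classes: int,
                 seed: int | None = None) -> EEGSeqNet:
    """Swap the dense output head for a freshly initialised one.

    Every other parameter is preserved bit-exactly; the new head is drawn
    from a fresh stream so a 5→3→5 round trip re-initialises rather than
    recovers the old weights.
    """
    cls = model.classifier
    old_spec = cls.spec
    new_spec = Seq2SeqSpec(
        embed_size=old_spec.embed_size, encoder_layers=old_spec.encoder_layers,
        encoder_units=old_spec.encoder_units,
        attention_size=old_spec.attention_size,
        decoder_layers=old_spec.decoder_layers,
        decoder_units=old_spec.decoder_units, n_classes=n_classes,
        input_dim=old_spec.input_dim)
    cls._head_seed += 1
    rng = np.random.default_rng(cls._head_seed + 7919 * n_classes)
    cls.head = Dense(old_spec.decoder_units, n_classes, rng)
    cls.spec = new_spec
    return model


# ---------------------------------------------------------------- utilities

def parameter_checksums(module: _Module) -> dict[str, str]:
    """MD5 of each parameter's raw bytes (bit-exact equality probe)."""
    return {k: hashlib.md5(np.ascontiguousarray(v.data).tobytes()).hexdigest()
            for k, v in module.parameters().items()}


def count_parameters(module: _Module) -> int:
    return sum(v.data.size for v in module.parameters().values())


def save_model(model: EEGSeqNet, path) -> None:
    """Arrays to ``<path>`` (npz) plus a JSON sidecar with spec/seed/scheme."""
    path = Path(path)
    np.savez(path, **{k: v.data for k, v in model.parameters().items()})
    sidecar = {
        "seed": model.seed,
        "n_classes": model.classifier.spec.n_classes,
        "head_seed": model.classifier._head_seed,
        "extractor_frozen": model.extractor_frozen,
        "input_length": model.extractor.spec.input_length,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> EEGSeqNet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec = FeatureExtractorSpec(input_length=sidecar["input_length"])
    model = EEGSeqNet(extractor_spec=spec, seed=sidecar["seed"])
    if sidecar["n_classes"] != 5:
        replace_head(model, sidecar["n_classes"])
    model.classifier._head_seed = sidecar["head_seed"]
    arrays = np.load(path if path.suffix == ".npz" else str(path) + ".npz")
    params = model.parameters()
    for k, v in params.items():
        v.data = arrays[k].copy()
    if sidecar["extractor_frozen"]:
        model.freeze_extractor()
    return model
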