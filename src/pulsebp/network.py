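"""Dual Conv1D encoder + LSTM blood-pressure regressor.

Two weight-independent convolutional branches encode the 200-point PPG and
ECG segments into length-``n`` latent vectors ``Z_PPG`` and ``Z_ECG``.  The
branches are fused by concatenation into a length-``2n`` hybrid vector,
batch-normalized, and consumed by an ``n``-unit LSTM — by default as a
single timestep carrying all ``2n`` features (``lstm_mode="single_step"``;
the alternative reading, a sequence of ``2n`` scalar timesteps, is available
as ``"scalar_sequence"``) — whose final short-term state is the summary
``Z̄``.  ``Z̄`` is concatenated with the two R-R durations, passed
through dropout, a 16-unit ELU hidden layer and a single softplus output
neuron, so predicted pressures are strictly positive.  One such network is
trained per target (systolic or diastolic) under a mean-squared-error loss.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .layers import BatchNorm, Conv1D, Dense, Dropout, ELU, Layer, LSTM, MaxPool1D, softplus, _sigmoid
from .records import BeatSegment

DEFAULT_CONV_LAYERS: tuple[tuple[int, int], ...] = ((64, 2), (32, 4), (16, 6), (16, 4))


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``n`` is the latent width per branch (and LSTM width); with the default
    encoder (final map 16 channels x 10 samples, max-pooled 5/5 to 16 x 2,
    flattened channel-major) the latent length is exactly ``n`` = 32.
    ``use_rr`` toggles the two R-R duration features in the head (the
    ablation variant has head input width ``n`` instead of ``n + 2``).
    """

    n: int = 32
    dropout_rate: float = 0.2
    hidden_units: int = 16
    input_len: int = 200
    rr_features: int = 2
    use_rr: bool = True
    conv_layers: tuple[tuple[int, int], ...] = DEFAULT_CONV_LAYERS
    stride: int = 2
    pool_size: int = 5
    elu_alpha: float = 1.0
    lstm_mode: Literal["scalar_sequence", "single_step"] = "single_step"
    normalize_inputs: bool = True
    #: initial output-neuron bias on the pressure scale (mmHg).  Starting the
    #: softplus output near a typical arterial pressure instead of softplus(0)
    #: ≈ 0.69 removes thousands of optimizer steps spent climbing the bias.
    init_output: float = 100.0
    #: compute precision; float32 roughly halves training time, float64 is
    #: used by the gradient-correctness tests
    dtype: str = "float32"

    def validate(self) -> None:
        problems = []
        if self.n <= 0:
            problems.append(f"latent width n must be > 0 (got {self.n})")
        if not 0.0 <= self.dropout_rate < 1.0:
            problems.append(f"dropout_rate must be in [0, 1) (got {self.dropout_rate})")
        if self.hidden_units <= 0:
            problems.append(f"hidden_units must be > 0 (got {self.hidden_units})")
        L = self.input_len
        try:
            for _, k in self.conv_layers:
                L = conv_output_length(L, k, self.stride)
        except ValueError as exc:
            problems.append(str(exc))
        else:
            latent = self.conv_layers[-1][0] * (L // self.pool_size)
            if latent != self.n:
                problems.append(
                    f"encoder latent length {latent} "
                    f"({self.conv_layers[-1][0]} channels x {L // self.pool_size} pooled) "
                    f"must equal n={self.n}"
                )
        if problems:
            raise ValueError("invalid NetworkConfig: " + "; ".join(problems))

    def feature_map_lengths(self) -> list[int]:
        """Per-conv-layer output lengths, e.g. [100, 49, 22, 10] for defaults."""
        lengths = []
        L = self.input_len
        for _, k in self.conv_layers:
            L = conv_output_length(L, k, self.stride)
            lengths.append(L)
        return lengths


def conv_output_length(L: int, k: int, stride: int) -> int:
    """Valid-convolution output length: floor((L − k) / stride) + 1."""
    if k < 1 or stride < 1:
        raise ValueError(f"kernel and stride must be >= 1 (got k={k}, stride={stride})")
    return Conv1D.output_length(L, k, stride)


def fuse(z_ppg: np.ndarray, z_ecg: np.ndarray) -> np.ndarray:
    """Concatenate branch latents, PPG first: positions 0..n−1 PPG, n..2n−1 ECG."""
    z_ppg = np.asarray(z_ppg)
    z_ecg = np.asarray(z_ecg)
    if z_ppg.shape != z_ecg.shape:
        raise ValueError(f"latent shape mismatch: {z_ppg.shape} vs {z_ecg.shape}")
    return np.concatenate([z_ppg, z_ecg], axis=-1)


def mse_loss(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Mean squared error (1/m) Σ (ŷ − y)²."""
    predictions = np.asarray(predictions, dtype=float).ravel()
    targets = np.asarray(targets, dtype=float).ravel()
    if predictions.size == 0:
        raise ValueError("empty prediction set")
    if predictions.shape != targets.shape:
        raise ValueError(f"length mismatch: {predictions.shape} vs {targets.shape}")
    return float(np.mean((predictions - targets) ** 2))


class _Encoder:
    """One convolutional branch: stacked (conv → batch-norm → ELU), max pool."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator) -> None:
        self.blocks: list[Layer] = []
        cin = 1
        for filters, k in cfg.conv_layers:
            self.blocks += [
                Conv1D(cin, filters, k, cfg.stride, rng),
                BatchNorm(filters),
                ELU(cfg.elu_alpha),
            ]
            cin = filters
        self.pool = MaxPool1D(cfg.pool_size)
        self.channels = cin

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = x[:, :, None]
        for block in self.blocks:
            h = block.forward(h, train)
        h = self.pool.forward(h, train)  # (B, T', C)
        B, Tp, C = h.shape
        self._pooled_shape = (B, Tp, C)
        return h.transpose(0, 2, 1).reshape(B, C * Tp)  # channel-major flatten

    def backward(self, dz: np.ndarray) -> np.ndarray:
        B, Tp, C = self._pooled_shape
        dh = dz.reshape(B, C, Tp).transpose(0, 2, 1)
        dh = self.pool.backward(dh)
        for block in reversed(self.blocks):
            dh = block.backward(dh)
        return dh[:, :, 0]

    def layers(self) -> list[Layer]:
        return [*self.blocks, self.pool]


class BPNet:
    """The full regressor; deterministic given (config, seed)."""

    def __init__(self, config: NetworkConfig | None = None, seed: int = 0) -> None:
        self.config = config or NetworkConfig()
        self.config.validate()
        cfg = self.config
        rng = np.random.default_rng(seed)
        self.seed = seed
        self.ppg_encoder = _Encoder(cfg, rng)
        self.ecg_encoder = _Encoder(cfg, rng)
        self.hybrid_bn = BatchNorm(self._hybrid_bn_channels())
        lstm_in = 1 if cfg.lstm_mode == "scalar_sequence" else 2 * cfg.n
        self.lstm = LSTM(lstm_in, cfg.n, rng)
        self.dropout = Dropout(cfg.dropout_rate, rng)
        head_in = cfg.n + (cfg.rr_features if cfg.use_rr else 0)
        self.hidden = Dense(head_in, cfg.hidden_units, rng)
        self.hidden_act = ELU(cfg.elu_alpha)
        self.out = Dense(cfg.hidden_units, 1, rng)
        if cfg.init_output > 0:
            # softplus^-1(p) = p + log(1 - exp(-p))
            self.out.params["b"][0] = cfg.init_output + np.log1p(-np.exp(-cfg.init_output))
        for layer in self.layers():
            layer.astype(np.dtype(cfg.dtype))

    def _hybrid_bn_channels(self) -> int:
        return 2 * self.config.n

    # -- layer bookkeeping ---------------------------------------------------

    def layers(self) -> list[Layer]:
        return [
            *self.ppg_encoder.layers(),
            *self.ecg_encoder.layers(),
            self.hybrid_bn,
            self.lstm,
            self.dropout,
            self.hidden,
            self.hidden_act,
            self.out,
        ]

    def zero_grad(self) -> None:
        for layer in self.layers():
            layer.zero_grad()

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, key) for layer in self.layers() for key in layer.params]

    def count_parameters(self) -> int:
        """Trainable scalars (batch-norm running statistics excluded)."""
        return sum(layer.n_params() for layer in self.layers())

    # -- forward / backward ---------------------------------------------------

    @staticmethod
    def _zscore(x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        return (x - mu) / np.maximum(sd, 1e-8)

    def _check_inputs(self, ppg: np.ndarray, ecg: np.ndarray, rr: np.ndarray) -> None:
        L = self.config.input_len
        if ppg.shape[1] != L or ecg.shape[1] != L:
            raise ValueError(f"inputs must be {L}-point, got {ppg.shape[1]}/{ecg.shape[1]}")
        if not (np.all(np.isfinite(ppg)) and np.all(np.isfinite(ecg)) and np.all(np.isfinite(rr))):
            raise ValueError("non-finite network inputs")

    def forward(
        self,
        ppg: np.ndarray,
        ecg: np.ndarray,
        rr: np.ndarray,
        train: bool = False,
    ) -> np.ndarray:
        """Predict pressures for a batch; returns shape (B,) of positives."""
        dtype = np.dtype(self.config.dtype)
        ppg = np.atleast_2d(np.asarray(ppg, dtype=dtype))
        ecg = np.atleast_2d(np.asarray(ecg, dtype=dtype))
        rr = np.atleast_2d(np.asarray(rr, dtype=dtype))
        self._check_inputs(ppg, ecg, rr)
        if self.config.normalize_inputs:
            ppg = self._zscore(ppg)
            ecg = self._zscore(ecg)
        z_ppg = self.ppg_encoder.forward(ppg, train)
        z_ecg = self.ecg_encoder.forward(ecg, train)
        z_hybrid = fuse(z_ppg, z_ecg)
        z_hybrid = self.hybrid_bn.forward(z_hybrid, train)
        B = z_hybrid.shape[0]
        if self.config.lstm_mode == "scalar_sequence":
            seq = z_hybrid[:, :, None]  # 2n timesteps of one scalar each
        else:
            seq = z_hybrid[:, None, :]  # one timestep of 2n features
        z_bar = self.lstm.forward(seq, train)
        if self.config.use_rr:
            h = np.concatenate([z_bar, rr], axis=1)
        else:
            h = z_bar
        h = self.dropout.forward(h, train)
        h = self.hidden.forward(h, train)
        h = self.hidden_act.forward(h, train)
        u = self.out.forward(h, train)
        if train:
            self._pre_softplus = u
        return softplus(u)[:, 0]

    def backward(self, dy: np.ndarray) -> None:
        """Accumulate parameter gradients; dy is dLoss/dPrediction, shape (B,)."""
        dy = np.asarray(dy, dtype=self.config.dtype)
        du = dy[:, None] * _sigmoid(self._pre_softplus)
        dh = self.out.backward(du)
        dh = self.hidden_act.backward(dh)
        dh = self.hidden.backward(dh)
        dh = self.dropout.backward(dh)
        if self.config.use_rr:
            dz_bar = dh[:, : self.config.n]
        else:
            dz_bar = dh
        dseq = self.lstm.backward(dz_bar)
        if self.config.lstm_mode == "scalar_sequence":
            dz_hybrid = dseq[:, :, 0]
        else:
            dz_hybrid = dseq[:, 0, :]
        dz_hybrid = self.hybrid_bn.backward(dz_hybrid)
        n = self.config.n
        self.ppg_encoder.backward(dz_hybrid[:, :n])
        self.ecg_encoder.backward(dz_hybrid[:, n:])

    # -- spec-surface convenience ops -----------------------------------------

    def encode_signal(self, x200: np.ndarray, branch: str = "ppg") -> np.ndarray:
        """Latent length-n vector for a single 200-point signal (inference)."""
        x = np.atleast_2d(np.asarray(x200, dtype=float))
        if x.shape[1] != self.config.input_len:
            raise ValueError(f"input must be {self.config.input_len}-point, got {x.shape[1]}")
        if self.config.normalize_inputs:
            x = self._zscore(x)
        enc = self.ppg_encoder if branch == "ppg" else self.ecg_encoder
        return enc.forward(x, train=False)[0]

    def lstm_process(self, z_hybrid: np.ndarray) -> np.ndarray:
        """Run the (batch-normalized) hybrid vector through the LSTM."""
        z = np.atleast_2d(np.asarray(z_hybrid, dtype=float))
        if z.shape[1] != 2 * self.config.n:
            raise ValueError(f"hybrid vector must have length {2 * self.config.n}")
        seq = z[:, :, None] if self.config.lstm_mode == "scalar_sequence" else z[:, None, :]
        return self.lstm.forward(seq, train=False)[0]

    def head(self, z_bar: np.ndarray, rr1: float, rr2: float) -> float:
        """Dense head on Z̄ (++ rr1 ++ rr2): softplus(ELU(· W_h + b_h) W_out + b_out)."""
        z_bar = np.atleast_2d(np.asarray(z_bar, dtype=float))
        if self.config.use_rr:
            if not (np.isfinite(rr1) and np.isfinite(rr2)):
                raise ValueError("non-finite R-R features")
            h = np.concatenate([z_bar, [[rr1, rr2]]], axis=1)
        else:
            h = z_bar
        h = self.hidden_act.forward(self.hidden.forward(h))
        return float(softplus(self.out.forward(h))[0, 0])

    # -- segment-level API -----------------------------------------------------

    def predict_segments(self, segments: Sequence[BeatSegment]) -> np.ndarray:
        ppg = np.stack([s.ppg200 for s in segments])
        ecg = np.stack([s.ecg200 for s in segments])
        rr = np.array([[s.rr1, s.rr2] for s in segments])
        return self.forward(ppg, ecg, rr, train=False)

    # -- persistence -----------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers()):
            for key, val in layer.params.items():
                out[f"layer{i:02d}.{key}"] = val
            if isinstance(layer, BatchNorm):
                out[f"layer{i:02d}.running_mean"] = layer.running_mean
                out[f"layer{i:02d}.running_var"] = layer.running_var
        return out

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        cfg_json = json.dumps({"config": asdict(self.config), "seed": self.seed})
        np.savez(path, __meta__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
                 **self.state_arrays())

    @classmethod
    def load(cls, path: str | Path) -> "BPNet":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
            cfg = meta["config"]
            cfg["conv_layers"] = tuple(tuple(p) for p in cfg["conv_layers"])
            net = cls(NetworkConfig(**cfg), seed=meta["seed"])
            for i, layer in enumerate(net.layers()):
                for key in layer.params:
                    layer.params[key] = data[f"layer{i:02d}.{key}"].copy()
                if isinstance(layer, BatchNorm):
                    layer.running_mean = data[f"layer{i:02d}.running_mean"].copy()
                    layer.running_var = data[f"layer{i:02d}.running_var"].copy()
        return net


def build_network(config: NetworkConfig | None = None, seed: int = 0) -> BPNet:
    """Construct a reproducible network; see :class:`NetworkConfig`."""
    return BPNet(config, seed)


def count_parameters(net: BPNet) -> int:
    return net.count_parameters()
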