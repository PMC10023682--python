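"""The two-stage ArNet2 network and its training procedure.

Stage 1 is a pre-activation residual CNN over a single 59-RR-interval
window: n_b = 5 residual blocks (two same-padded 1-D convolutions each,
filter length 10), the filter count doubling and the temporal length
halving every second block ([64, 64, 128, 128, 256] at defaults), then
flatten and three dense layers (512 -> 256 -> 128, each with dropout 0.5)
feeding a final size-1 dense output.  The 128-dimensional activations
entering that final layer are the window *embedding*.

Stage 2 is a pool of four structurally identical GRU heads, one per AF_l
severity stratum (Non-AF_l / mild / moderate / severe).  Each head
consumes the temporal concatenation of a window's embedding with its h=6
predecessors (zero-padded when fewer exist) and emits one probability.
During training every head sees only windows from recordings of its
stratum, computed from TRUE labels; at inference a single head is chosen
for the whole recording from the stage-1 estimated AFB.

Both stages use weighted binary cross-entropy (positive class up-weighted
by N_neg/N_pos unless overridden), Adam at lr 1e-2, early stopping on the
validation loss (min delta 0.001), and keep the checkpoint with the best
validation AUROC.  Classification thresholds maximize F1 on the training
set.
"""
from __future__ import annotations

import io
import json
import math
import zipfile
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from . import nn
from .datatypes import SEVERITY_LEVELS, WINDOW_RR, PredictionSet, WindowedRecording
from .metrics import classify_severity, compute_afb

CHECKPOINT_FORMAT = "arnet2-ckpt-v1"


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters (defaults = study values)."""

    n_b: int = 5                 # residual blocks
    n_f: int = 64                # initial filters
    f_l: int = 10                # filter length
    d_r1: float = 0.2            # inter-block dropout
    d_r2: float = 0.5            # dense dropout
    n_d: int = 512               # first dense width, halved per layer
    n_dense: int = 3             # dense layer count
    h: int = 6                   # history length (preceding windows)
    lr: float = 1e-2
    pos_weight: Optional[float] = None   # None -> N_neg / N_pos of train set
    early_stop_min_delta: float = 0.001
    early_stop_patience: int = 5
    gru_units: int = 64
    stage2_dense: int = 64
    max_grad_norm: Optional[float] = 1.0  # global-norm gradient clipping
    max_epochs: int = 30
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.n_b < 1 or self.h < 0:
            raise ValueError("n_b must be >= 1 and h >= 0")
        for name in ("n_f", "f_l", "n_d", "n_dense", "lr", "gru_units",
                     "stage2_dense", "max_epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def embedding_dim(self) -> int:
        return self.n_d // (2 ** (self.n_dense - 1))

    def filter_sequence(self) -> List[int]:
        return [self.n_f * 2 ** (i // 2) for i in range(self.n_b)]


@dataclass
class TrainingLog:
    epochs: List[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_auroc: float = math.nan

    @property
    def final_val_loss(self) -> float:
        return self.epochs[-1]["val_loss"] if self.epochs else math.nan


def default_pos_weight(y: np.ndarray) -> float:
    """Prevalence correction N_neg / N_pos."""
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to derive pos_weight")
    return n_neg / n_pos


class Stage1Net(nn.Layer):
    """Residual CNN over one 59-RR window; exposes the embedding."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator,
                 dtype=np.float32):
        self.config = config
        layers: list = []
        in_ch, length = 1, WINDOW_RR
        for i, f in enumerate(config.filter_sequence()):
            down = (i + 1) % 2 == 0
            layers.append(nn.ResBlock(in_ch, f, config.f_l, down, rng, dtype=dtype))
            if down:
                length = nn.MaxPool1D.out_len(length)
            if length < 1:
                raise ValueError("configuration collapses the temporal length to zero")
            if i + 1 < config.n_b:
                layers.append(nn.Dropout(config.d_r1, rng))
            in_ch = f
        layers += [nn.BatchNorm(in_ch, dtype=dtype), nn.ReLU(), nn.Flatten()]
        d_in = in_ch * length
        for j in range(config.n_dense):
            d_out = config.n_d // (2 ** j)
            layers += [nn.Dense(d_in, d_out, rng, dtype=dtype), nn.ReLU(),
                       nn.Dropout(config.d_r2, rng)]
            d_in = d_out
        self.backbone = nn.Sequential(layers)
        self.head = nn.Dense(d_in, 1, rng, dtype=dtype)
        self.dtype = dtype

    def params(self):
        return self.backbone.params() + self.head.params()

    def children(self):
        return [self.backbone, self.head]

    def forward(self, x, training):
        emb = self.backbone.forward(x, training)
        self._emb = emb
        return self.head.forward(emb, training)

    def backward(self, dout):
        demb = self.head.backward(dout)
        return self.backbone.backward(demb)

    def logits(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Inference-mode logits, invariant to batch composition."""
        out = []
        for i in range(0, len(X), batch_size):
            out.append(self.forward(self._shape(X[i:i + batch_size]), False).reshape(-1))
        return np.concatenate(out) if out else np.array([])

    def embeddings(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(X), batch_size):
            self.forward(self._shape(X[i:i + batch_size]), False)
            out.append(self._emb.copy())
        return (np.concatenate(out) if out
                else np.empty((0, self.config.embedding_dim), dtype=self.dtype))

    def _shape(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim == 2:
            X = X[:, :, None]
        return X


class GRUHead(nn.Layer):
    """One severity-conditioned head: GRU -> Dense -> ReLU -> Dense(1)."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator,
                 dtype=np.float32):
        self.gru = nn.GRU(config.embedding_dim, config.gru_units, rng, dtype=dtype)
        self.net = nn.Sequential([
            nn.Dense(config.gru_units, config.stage2_dense, rng, dtype=dtype),
            nn.ReLU(),
            nn.Dense(config.stage2_dense, 1, rng, dtype=dtype),
        ])
        self.dtype = dtype

    def params(self):
        return self.gru.params() + self.net.params()

    def children(self):
        return [self.gru, self.net]

    def forward(self, x, training):
        h = self.gru.forward(np.asarray(x, dtype=self.dtype), training)
        return self.net.forward(h, training)

    def backward(self, dout):
        dh = self.net.backward(dout)
        return self.gru.backward(dh)

    def logits(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        out = []
        for i in range(0, len(X), batch_size):
            out.append(self.forward(X[i:i + batch_size], False).reshape(-1))
        return np.concatenate(out) if out else np.array([])


def build_stage1_cnn(config: ModelConfig, seed: Optional[int] = None,
                     dtype=np.float32) -> Stage1Net:
    rng = np.random.Generator(np.random.PCG64(config.seed if seed is None else seed))
    return Stage1Net(config, rng, dtype=dtype)


def build_gru_pool(config: ModelConfig, seed: Optional[int] = None,
                   dtype=np.float32) -> Dict[str, GRUHead]:
    """Four structurally identical severity heads with independent weights."""
    base = config.seed if seed is None else seed
    heads = {}
    for k, level in enumerate(SEVERITY_LEVELS):
        rng = np.random.Generator(np.random.PCG64(base + 1000 + k))
        heads[level] = GRUHead(config, rng, dtype=dtype)
    return heads


def fit_binary(net: nn.Layer, X_train: np.ndarray, y_train: np.ndarray,
               X_val: np.ndarray, y_val: np.ndarray, config: ModelConfig,
               rng: np.random.Generator, pos_weight: float,
               shape_fn=None) -> TrainingLog:
    """Mini-batch Adam training with early stopping and best-AUROC restore.

    Early stopping watches the validation loss with the configured minimum
    delta and patience; the returned network carries the parameters of the
    epoch with the highest validation AUROC (falling back to the lowest
    validation loss when the validation labels are single-class).
    """
    shape_fn = shape_fn or (lambda a: a)
    opt = nn.Adam(net.params(), lr=config.lr,
                  max_grad_norm=config.max_grad_norm)
    log = TrainingLog()
    best_state = nn.get_state(net)
    best_val_loss = math.inf
    best_auroc = -math.inf
    patience_left = config.early_stop_patience
    n = len(X_train)
    val_two_class = len(np.unique(y_val)) == 2
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        train_loss = 0.0
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            xb, yb = shape_fn(X_train[idx]), y_train[idx]
            opt.zero_grad()
            logits = net.forward(xb, True)
            loss, dlogits = nn.weighted_bce_with_logits(logits, yb, pos_weight)
            net.backward(dlogits)
            opt.step()
            train_loss += loss * len(idx)
        train_loss /= max(n, 1)
        val_logits = _batched_logits(net, X_val, config.batch_size, shape_fn)
        val_loss, _ = nn.weighted_bce_with_logits(val_logits, y_val, pos_weight)
        val_auroc = (float(roc_auc_score(y_val, val_logits))
                     if val_two_class else math.nan)
        log.epochs.append({"epoch": epoch, "train_loss": train_loss,
                           "val_loss": val_loss, "val_auroc": val_auroc})
        better = (val_auroc > best_auroc) if val_two_class else (val_loss < best_val_loss)
        if better:
            best_auroc = val_auroc if val_two_class else best_auroc
            best_state = nn.get_state(net)
            log.best_epoch = epoch
            log.best_val_auroc = val_auroc
        if val_loss < best_val_loss - config.early_stop_min_delta:
            best_val_loss = val_loss
            patience_left = config.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
        best_val_loss = min(best_val_loss, val_loss)
    nn.set_state(net, best_state)
    return log


def _batched_logits(net, X, batch_size, shape_fn):
    out = []
    for i in range(0, len(X), batch_size):
        out.append(net.forward(shape_fn(X[i:i + batch_size]), False).reshape(-1))
    return np.concatenate(out) if out else np.array([])


def choose_threshold(probabilities: Sequence[float], labels: Sequence[int]) -> float:
    """Observed probability value maximizing F1; ties -> lowest threshold.

    Predictions are positive when p >= threshold.  Raises if only one
    class is present.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have equal length")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes required to choose a threshold")
    # sort descending; sweeping thresholds over observed values
    order = np.argsort(-p, kind="stable")
    ps, ys = p[order], y[order]
    tp = np.cumsum(ys)
    pred_pos = np.arange(1, len(ys) + 1)
    n_pos = int(ys.sum())
    # threshold = ps[k] means all entries with p >= ps[k]; because of ties,
    # evaluate at the last occurrence of each distinct value
    last = np.r_[np.diff(ps) != 0, True]
    f1 = 2 * tp / (pred_pos + n_pos)  # == 2*se*ppv/(se+ppv)
    f1c, thrc = f1[last], ps[last]
    best = np.max(f1c)
    # ties toward the lowest threshold value among maximizers
    return float(np.min(thrc[np.isclose(f1c, best, rtol=0, atol=1e-15)]))


@dataclass
class ArNet2Model:
    """Trained two-stage model: CNN + severity-conditioned GRU pool."""

    config: ModelConfig
    stage1: Stage1Net
    heads: Dict[str, GRUHead]
    stage1_threshold: float = 0.5
    head_thresholds: Dict[str, float] = field(default_factory=dict)
    stage1_log: Optional[TrainingLog] = None
    head_logs: Dict[str, TrainingLog] = field(default_factory=dict)

    # -------------------------------------------------------------- training
    @classmethod
    def train(cls, recordings: List[WindowedRecording],
              val_recordings: List[WindowedRecording],
              config: ModelConfig) -> "ArNet2Model":
        """Full two-stage training on patient-separated train/validation sets.

        Stage 1 trains on all included windows pooled across training
        recordings; stage 2 partitions the training recordings into
        severity strata from their TRUE window labels and trains one GRU
        head per stratum on embedding histories.
        """
        rng = np.random.Generator(np.random.PCG64(config.seed))
        stage1 = build_stage1_cnn(config)
        Xtr, ytr, _ = stack_windows(recordings)
        Xval, yval, _ = stack_windows(val_recordings)
        if len(np.unique(ytr)) < 2:
            raise ValueError("stage-1 training set contains a single class")
        pos_w = config.pos_weight if config.pos_weight is not None else default_pos_weight(ytr)
        log1 = fit_binary(stage1, Xtr, ytr, Xval, yval, config, rng, pos_w,
                          shape_fn=stage1._shape)
        p_train1 = nn.sigmoid(stage1.logits(Xtr))
        thr1 = choose_threshold(p_train1, ytr)

        heads = build_gru_pool(config)
        head_logs: Dict[str, TrainingLog] = {}
        head_thresholds: Dict[str, float] = {}
        train_by_sev = _severity_partition(recordings)
        val_by_sev = _severity_partition(val_recordings)
        for level in SEVERITY_LEVELS:
            recs = train_by_sev.get(level, [])
            seqs, labels = _embedding_sequences(stage1, recs, config)
            if len(labels) == 0:
                head_logs[level] = TrainingLog()  # empty stratum: keep init
                head_thresholds[level] = 0.5
                continue
            vrecs = val_by_sev.get(level, []) or recs
            vseqs, vlabels = _embedding_sequences(stage1, vrecs, config)
            try:
                pw = config.pos_weight if config.pos_weight is not None else default_pos_weight(labels)
            except ValueError:
                pw = 1.0
            head = heads[level]
            head_logs[level] = fit_binary(head, seqs, labels, vseqs, vlabels,
                                          config, rng, pw)
            p_head = nn.sigmoid(head.logits(seqs))
            try:
                head_thresholds[level] = choose_threshold(p_head, labels)
            except ValueError:
                head_thresholds[level] = 0.5
        return cls(config=config, stage1=stage1, heads=heads,
                   stage1_threshold=thr1, head_thresholds=head_thresholds,
                   stage1_log=log1, head_logs=head_logs)

    # ------------------------------------------------------------- inference
    def predict(self, rec: WindowedRecording) -> PredictionSet:
        """Two-pass prediction for one recording.

        Pass 1: stage-1 probabilities for all included windows, binarized
        at the stage-1 threshold; the estimated AFB and total AF_l time
        select ONE severity head for the whole recording.  Pass 2: that
        head scores every window from its h-window embedding history
        (zero-padded at the start); final labels at the head's threshold.
        """
        windows = rec.included_windows
        if not windows:
            return PredictionSet(
                record_id=rec.record_id, window_indices=np.array([], dtype=int),
                p_stage1=np.array([]), p_stage2=np.array([]),
                y_hat=np.array([], dtype=int), threshold=math.nan,
                t_ms=np.array([]), estimated_afb=None, estimated_af_time_ms=None)
        X = np.stack([w.rr_ms for w in windows])
        t_ms = np.array([w.t_ms for w in windows])
        p1 = nn.sigmoid(self.stage1.logits(X))
        y1 = (p1 >= self.stage1_threshold).astype(int)
        burden1 = compute_afb(t_ms, y1)
        severity = classify_severity(burden1.total_af_time_ms, burden1.afb)
        head = self.heads[severity]
        emb = self.stage1.embeddings(X)
        seqs = _history_stack(emb, self.config.h)
        p2 = nn.sigmoid(head.logits(seqs))
        thr = self.head_thresholds.get(severity, 0.5)
        y_hat = (p2 >= thr).astype(int)
        burden2 = compute_afb(t_ms, y_hat)
        return PredictionSet(
            record_id=rec.record_id,
            window_indices=np.array([w.index for w in windows], dtype=int),
            p_stage1=p1, p_stage2=p2, y_hat=y_hat, threshold=thr, t_ms=t_ms,
            estimated_afb=burden2.afb,
            estimated_af_time_ms=burden2.total_af_time_ms,
            severity_used=severity)

    # ------------------------------------------------------------ checkpoint
    def save(self, path) -> None:
        """Single-archive checkpoint: config echo, weights, thresholds."""
        arrays = {}
        for i, p in enumerate(self.stage1.params()):
            arrays[f"stage1/{i}"] = p.value
        arrays.update(_bn_stats_arrays("stage1_bn", self.stage1))
        for level, head in self.heads.items():
            for i, p in enumerate(head.params()):
                arrays[f"head/{level}/{i}"] = p.value
        meta = {
            "format": CHECKPOINT_FORMAT,
            "config": asdict(self.config),
            "stage1_threshold": self.stage1_threshold,
            "head_thresholds": self.head_thresholds,
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta, indent=1))
            buf = io.BytesIO()
            np.savez(buf, **arrays)
            zf.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "ArNet2Model":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta.get("format") != CHECKPOINT_FORMAT:
                raise ValueError(f"unsupported checkpoint format: {meta.get('format')}")
            npz = np.load(io.BytesIO(zf.read("weights.npz")))
        config = ModelConfig(**meta["config"])
        stage1 = build_stage1_cnn(config)
        for i, p in enumerate(stage1.params()):
            p.value[...] = npz[f"stage1/{i}"]
        _bn_stats_restore("stage1_bn", stage1, npz)
        heads = build_gru_pool(config)
        for level, head in heads.items():
            for i, p in enumerate(head.params()):
                p.value[...] = npz[f"head/{level}/{i}"]
        return cls(config=config, stage1=stage1, heads=heads,
                   stage1_threshold=float(meta["stage1_threshold"]),
                   head_thresholds={k: float(v) for k, v in meta["head_thresholds"].items()})


# --------------------------------------------------------------- assembling

def stack_windows(recordings: List[WindowedRecording]) -> tuple:
    """Pool included windows: (X (n, 59), y (n,), recording index (n,))."""
    X, y, rid = [], [], []
    for k, rec in enumerate(recordings):
        for w in rec.included_windows:
            X.append(w.rr_ms)
            y.append(w.y)
            rid.append(k)
    if not X:
        return (np.empty((0, WINDOW_RR)), np.array([], dtype=int),
                np.array([], dtype=int))
    return np.stack(X), np.asarray(y, dtype=int), np.asarray(rid, dtype=int)


def _severity_partition(recordings: List[WindowedRecording]) -> Dict[str, list]:
    """Assign each recording to a severity stratum from its TRUE labels."""
    out: Dict[str, list] = {}
    for rec in recordings:
        windows = rec.included_windows
        if not windows:
            continue
        t = np.array([w.t_ms for w in windows])
        y = np.array([w.y for w in windows], dtype=int)
        b = compute_afb(t, y)
        out.setdefault(classify_severity(b.total_af_time_ms, b.afb), []).append(rec)
    return out


def _history_stack(emb: np.ndarray, h: int) -> np.ndarray:
    """(n, d) embeddings -> (n, h+1, d) zero-padded history sequences."""
    n, d = emb.shape
    seqs = np.zeros((n, h + 1, d), dtype=emb.dtype)
    for i in range(n):
        lo = max(i - h, 0)
        hist = emb[lo:i + 1]
        seqs[i, h + 1 - len(hist):, :] = hist
    return seqs


def _embedding_sequences(stage1: Stage1Net, recordings: List[WindowedRecording],
                         config: ModelConfig) -> tuple:
    """Per-recording embedding histories and labels, concatenated."""
    seqs, labels = [], []
    for rec in recordings:
        windows = rec.included_windows
        if not windows:
            continue
        X = np.stack([w.rr_ms for w in windows])
        emb = stage1.embeddings(X)
        seqs.append(_history_stack(emb, config.h))
        labels.extend(int(w.y) for w in windows)
    if not seqs:
        return (np.empty((0, config.h + 1, config.embedding_dim), dtype=np.float32),
                np.array([], dtype=int))
    return np.concatenate(seqs), np.asarray(labels, dtype=int)


def _bn_stats_arrays(prefix: str, net: Stage1Net) -> dict:
    out = {}
    for i, bn in enumerate(nn.batchnorms(net)):
        out[f"{prefix}/{i}/mean"] = bn.running_mean
        out[f"{prefix}/{i}/var"] = bn.running_var
    return out


def _bn_stats_restore(prefix: str, net: Stage1Net, npz) -> None:
    for i, bn in enumerate(nn.batchnorms(net)):
        bn.running_mean = npz[f"{prefix}/{i}/mean"]
        bn.running_var = npz[f"{prefix}/{i}/var"]

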