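"""Behaviour-to-neural encoding model.

A small multi-layer network maps 30-Hz face-movie SVD features to 100-ms
binned firing rates: a per-frame linear layer, a temporal convolution, a
ReLU, a low-dimensional linear layer (the latents) and a linear output
layer, fit with AdamW and validation early stopping.  Test-segment
predictions are then refined by averaging recorded activity at the 50
nearest training latents, and residuals (recorded minus nearest-neighbour
prediction) quantify activity not explained by facial behaviour.

The network is implemented directly in numpy (forward, backprop and the
AdamW update), sized for desk-scale sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import pairwise_distances

from .session import AnalysisWindow, LaserEvent
from .spikes import BinnedRates

__all__ = ["SplitPlan", "EncodingNetworkSpec", "EncodingModel", "EncodingResult",
           "make_split", "train_encoder", "nn_latent_predict", "compute_residuals",
           "residual_window_means", "model_metrics"]


@dataclass
class SplitPlan:
    """Segmented train/validation/test split.

    Test segments are one 63-s no-laser control plus one 63-s window (-3 to
    +60 s) per laser; the remaining data are tiled into 50-s segments split
    80/20 into train and validation.  Segments are disjoint and no laser
    period touches train or validation.
    """

    train: list[AnalysisWindow]
    validation: list[AnalysisWindow]
    test: list[AnalysisWindow]      # roles: "control" | "laser_test"
    seed: int | None = None

    def test_segments(self, role: str | None = None) -> list[AnalysisWindow]:
        return [w for w in self.test if role is None or w.role == role]

    def all_test_spans(self) -> list[tuple[float, float]]:
        return [(w.start, w.end) for w in self.test]


def make_split(duration: float, lasers: list[LaserEvent],
               seg_nontest: float = 50.0, seg_test: float = 63.0,
               test_pre: float = 3.0, test_post: float = 60.0,
               val_frac: float = 0.2, seed: int | None = 0) -> SplitPlan:
    """Build the segmented split for a session of the given duration.

    Deterministic under ``seed``; the test segments do not depend on the
    seed at all (only the train/validation assignment does).
    """
    test: list[AnalysisWindow] = []
    for ev in sorted(lasers, key=lambda e: e.onset):
        s, e = ev.onset - test_pre, ev.onset + test_post
        if s < 0 or e > duration:
            raise ValueError(f"laser test window [{s:.1f}, {e:.1f}] outside session")
        test.append(AnalysisWindow(s, e, role="laser_test"))

    # complement of the laser test windows
    gaps, cursor = [], 0.0
    for w in test:
        if w.start - cursor > 0:
            gaps.append((cursor, w.start))
        cursor = max(cursor, w.end)
    if duration - cursor > 0:
        gaps.append((cursor, duration))

    control = None
    for g0, g1 in gaps:
        if g1 - g0 >= seg_test:
            control = AnalysisWindow(g0, g0 + seg_test, role="control")
            break
    if control is None:
        raise ValueError(f"no {seg_test:.0f}-s laser-free span for the control segment "
                         f"(largest gap {max((g1 - g0 for g0, g1 in gaps), default=0):.1f} s)")
    test = [control] + test

    nontest: list[AnalysisWindow] = []
    for g0, g1 in gaps:
        s = g0
        if control.start >= g0 and control.end <= g1:
            s = control.end  # control carved out of this gap
        while g1 - s >= seg_nontest:
            nontest.append(AnalysisWindow(s, s + seg_nontest, role="baseline"))
            s += seg_nontest
    if len(nontest) < 2:
        raise ValueError(f"only {len(nontest)} non-test 50-s segments available; "
                         "need at least one train and one validation segment")
    if len(nontest) < 5:
        warnings.warn(f"only {len(nontest)} non-test segments; split is coarse")

    rng = np.random.default_rng(seed)
    n_val = max(1, int(round(val_frac * len(nontest))))
    val_idx = set(rng.choice(len(nontest), size=n_val, replace=False).tolist())
    train = [w for i, w in enumerate(nontest) if i not in val_idx]
    validation = [w for i, w in enumerate(nontest) if i in val_idx]
    return SplitPlan(train=train, validation=validation, test=test, seed=seed)


@dataclass
class EncodingNetworkSpec:
    """Architecture and optimization settings for the encoding network."""

    input_dim: int
    n_units: int
    hidden: int = 200
    conv_channels: int = 100
    conv_kernel: int = 15          # frames, ~0.5 s at 30 Hz
    latent_dim: int = 32
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    max_epochs: int = 300
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim >= self.hidden:
            raise ValueError("latent dim must be smaller than the first linear width")


class _AdamW:
    """Decoupled-weight-decay Adam on a list of numpy parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float, weight_decay: float,
                 betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p)


class EncodingModel:
    """The fitted network; exposes direct predictions and latents per bin."""

    def __init__(self, spec: EncodingNetworkSpec, frames_per_bin: int):
        self.spec = spec
        self.frames_per_bin = frames_per_bin
        rng = np.random.default_rng(spec.seed)
        D, h, C, K, L, U = (spec.input_dim, spec.hidden, spec.conv_channels,
                            spec.conv_kernel, spec.latent_dim, spec.n_units)
        def init(*shape):
            fan_in = int(np.prod(shape[:-1])) or shape[0]
            return rng.normal(0, np.sqrt(2.0 / fan_in), size=shape)
        self.W1 = init(D, h); self.b1 = np.zeros(h)
        self.Wc = init(C, K, h) * np.sqrt(1.0 / K); self.bc = np.zeros(C)
        self.Wl = init(C, L); self.bl = np.zeros(L)
        self.Wo = init(L, U); self.bo = np.zeros(U)
        self.train_history: list[float] = []
        self.val_history: list[float] = []

    # -- geometry ----------------------------------------------------------
    def bin_centre_frame(self, bins: np.ndarray) -> np.ndarray:
        """Video frame aligned with each rate bin's centre."""
        r = self.frames_per_bin
        return bins * r + r // 2

    def _window_index(self, bins: np.ndarray, n_frames: int) -> np.ndarray:
        K = self.spec.conv_kernel
        off = np.arange(K) - K // 2
        idx = self.bin_centre_frame(bins)[:, None] + off[None, :]
        return np.clip(idx, 0, n_frames - 1)

    # -- forward / backward ------------------------------------------------
    def _forward(self, X: np.ndarray, bins: np.ndarray):
        F_idx = self._window_index(bins, X.shape[1])
        Hfull = X.T @ self.W1 + self.b1
        Hw = Hfull[F_idx]                                   # (B, K, h)
        Z = np.tensordot(Hw, self.Wc, axes=([1, 2], [1, 2])) + self.bc
        A = np.maximum(Z, 0.0)
        Lat = A @ self.Wl + self.bl
        Y = Lat @ self.Wo + self.bo
        return F_idx, Hw, Z, A, Lat, Y

    def _params(self):
        return [self.W1, self.b1, self.Wc, self.bc, self.Wl, self.bl, self.Wo, self.bo]

    def fit(self, X: np.ndarray, R: np.ndarray, train_bins: np.ndarray,
            val_bins: np.ndarray) -> "EncodingModel":
        """Full-batch AdamW with early stopping on validation MSE.

        ``X`` is features x frames (30 Hz); ``R`` is bins x units (Hz).
        Only the given train/validation bins are ever touched.
        """
        spec = self.spec
        opt = _AdamW(self._params(), spec.learning_rate, spec.weight_decay)
        Rtr, Rva = R[train_bins], R[val_bins]
        best_val, best, since = np.inf, None, 0
        for epoch in range(spec.max_epochs):
            F_idx, Hw, Z, A, Lat, Y = self._forward(X, train_bins)
            err = Y - Rtr
            loss = float(np.mean(err ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "training diverged (NaN loss); lower the learning rate")
            B, U = err.shape
            dY = 2.0 * err / (B * U)
            gWo = Lat.T @ dY; gbo = dY.sum(0)
            dLat = dY @ self.Wo.T
            gWl = A.T @ dLat; gbl = dLat.sum(0)
            dZ = (dLat @ self.Wl.T) * (Z > 0)
            gWc = np.einsum("bc,bkh->ckh", dZ, Hw); gbc = dZ.sum(0)
            dHw = np.einsum("bc,ckh->bkh", dZ, self.Wc)
            dHfull = np.zeros((X.shape[1], spec.hidden))
            np.add.at(dHfull, F_idx, dHw)
            gW1 = X @ dHfull; gb1 = dHfull.sum(0)
            opt.step([gW1, gb1, gWc, gbc, gWl, gbl, gWo, gbo])

            val = float(np.mean((self.predict(X, val_bins) - Rva) ** 2))
            self.train_history.append(loss)
            self.val_history.append(val)
            if val < best_val - 1e-12:
                best_val, since = val, 0
                best = [p.copy() for p in self._params()]
            else:
                since += 1
                if since >= spec.patience:
                    break
        if best is not None:
            for p, bp in zip(self._params(), best):
                p[...] = bp
        return self

    def predict(self, X: np.ndarray, bins: np.ndarray) -> np.ndarray:
        return self._forward(X, bins)[-1]

    def latents(self, X: np.ndarray, bins: np.ndarray) -> np.ndarray:
        return self._forward(X, bins)[-2]


def _bins_in_windows(windows: list[AnalysisWindow], bin_width: float,
                     n_bins: int, t0: float = 0.0) -> np.ndarray:
    """Indices of bins wholly inside any of the windows."""
    idx = []
    for w in windows:
        b0 = int(np.ceil((w.start - t0) / bin_width - 1e-9))
        b1 = int(np.floor((w.end - t0) / bin_width + 1e-9))
        idx.append(np.arange(max(b0, 0), min(b1, n_bins)))
    return np.unique(np.concatenate(idx)) if idx else np.array([], dtype=int)


def train_encoder(behavior: np.ndarray, rates: BinnedRates, split: SplitPlan,
                  spec: EncodingNetworkSpec | None = None,
                  video_rate: float = 30.0, **spec_kwargs) -> EncodingModel:
    """Fit the encoding network on the split's train/validation segments.

    ``behavior`` is features x frames at 30 Hz (movie and motion SVDs
    concatenated); rates are the 100-ms binned unit activities.
    """
    n_bins = rates.counts.shape[1]
    if spec is None:
        spec = EncodingNetworkSpec(input_dim=behavior.shape[0],
                                   n_units=rates.counts.shape[0], **spec_kwargs)
    r = int(round(video_rate * rates.bin_width))
    model = EncodingModel(spec, frames_per_bin=r)
    train_bins = _bins_in_windows(split.train, rates.bin_width, n_bins, rates.t0)
    val_bins = _bins_in_windows(split.validation, rates.bin_width, n_bins, rates.t0)
    R = rates.rates.T  # (bins, units) in Hz
    model.fit(behavior, R, train_bins, val_bins)
    return model


def nn_latent_predict(train_latents: np.ndarray, train_targets: np.ndarray,
                      test_latents: np.ndarray, k: int = 50) -> np.ndarray:
    """Average recorded activity at the k nearest training latents.

    Euclidean metric; ties broken toward the earlier training time point
    (stable sort).  ``k`` is clipped to the number of training points with a
    warning.
    """
    n_train = train_latents.shape[0]
    if k > n_train:
        warnings.warn(f"k={k} exceeds {n_train} training points; clipped")
        k = n_train
    d = pairwise_distances(test_latents, train_latents)
    nbrs = np.argsort(d, axis=1, kind="stable")[:, :k]
    return train_targets[nbrs].mean(axis=1)


@dataclass
class EncodingResult:
    """Predictions, latents and residuals on the test bins.

    ``residual = recorded - nn_prediction`` holds exactly, bin-wise.
    """

    test_bins: np.ndarray        # indices into the session bin grid
    recorded: np.ndarray         # (B, U) Hz
    direct: np.ndarray           # (B, U) network prediction
    nn: np.ndarray               # (B, U) nearest-neighbour prediction
    latents: np.ndarray          # (B, L)
    bin_width: float
    t0: float
    unit_ids: list[str]
    regions: list[str]
    residual: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.residual = self.recorded - self.nn

    def bin_times(self) -> np.ndarray:
        return self.t0 + self.test_bins * self.bin_width


def compute_residuals(behavior: np.ndarray, rates: BinnedRates, split: SplitPlan,
                      model: EncodingModel, k: int = 50) -> EncodingResult:
    """Direct and nearest-neighbour predictions plus residuals on test bins."""
    n_bins = rates.counts.shape[1]
    R = rates.rates.T
    train_bins = _bins_in_windows(split.train, rates.bin_width, n_bins, rates.t0)
    test_bins = _bins_in_windows(split.test, rates.bin_width, n_bins, rates.t0)
    train_lat = model.latents(behavior, train_bins)
    test_lat = model.latents(behavior, test_bins)
    direct = model.predict(behavior, test_bins)
    nn = nn_latent_predict(train_lat, R[train_bins], test_lat, k=k)
    return EncodingResult(test_bins=test_bins, recorded=R[test_bins],
                          direct=direct, nn=nn, latents=test_lat,
                          bin_width=rates.bin_width, t0=rates.t0,
                          unit_ids=rates.unit_ids, regions=rates.regions)


def residual_window_means(result: EncodingResult,
                          windows: list[AnalysisWindow]) -> np.ndarray:
    """Per-unit mean residual in each window (residuals exist only on test
    bins; a window outside them raises)."""
    times = result.bin_times()
    out = np.empty((len(windows), result.residual.shape[1]))
    for i, w in enumerate(windows):
        sel = (times >= w.start - 1e-9) & (times + result.bin_width <= w.end + 1e-9)
        if not sel.any():
            raise ValueError(f"window [{w.start:.2f}, {w.end:.2f}] has no test bins; "
                             "residuals are defined only on test segments")
        out[i] = result.residual[sel].mean(axis=0)
    return out


def _segment_metrics(rec: np.ndarray, pred: np.ndarray, bins_per_s: int):
    """Per-unit VE and 1-s-binned correlation on one segment class."""
    U = rec.shape[1]
    if rec.shape[0] == 0:
        return np.full(U, np.nan), np.full(U, np.nan)
    var = rec.var(axis=0)
    ve = np.where(var > 0, 1.0 - ((rec - pred) ** 2).mean(axis=0) / var, np.nan)
    n = (rec.shape[0] // bins_per_s) * bins_per_s
    r = np.full(U, np.nan)
    if n >= 2 * bins_per_s:
        rc = rec[:n].reshape(-1, bins_per_s, U).mean(axis=1)
        pc = pred[:n].reshape(-1, bins_per_s, U).mean(axis=1)
        for u in range(U):
            if rc[:, u].std() > 0 and pc[:, u].std() > 0:
                r[u] = np.corrcoef(rc[:, u], pc[:, u])[0, 1]
    return ve, r


def model_metrics(result: EncodingResult, split: SplitPlan) -> pd.DataFrame:
    """Per-unit variance explained (control segment) and 1-s correlations.

    VE is reported for both the nearest-neighbour and the direct prediction;
    correlations use the nearest-neighbour prediction on the control and
    laser test segments separately.  Zero-variance units yield NaN.
    """
    times = result.bin_times()
    bins_per_s = int(round(1.0 / result.bin_width))
    masks = {}
    for role in ("control", "laser_test"):
        sel = np.zeros(times.size, dtype=bool)
        for w in split.test_segments(role):
            sel |= (times >= w.start - 1e-9) & (times < w.end)
        masks[role] = sel
    ve_nn, r_ctrl = _segment_metrics(result.recorded[masks["control"]],
                                     result.nn[masks["control"]], bins_per_s)
    ve_dir, _ = _segment_metrics(result.recorded[masks["control"]],
                                 result.direct[masks["control"]], bins_per_s)
    _, r_laser = _segment_metrics(result.recorded[masks["laser_test"]],
                                  result.nn[masks["laser_test"]], bins_per_s)
    return pd.DataFrame({
        "unit_id": result.unit_ids, "region": result.regions,
        "ve_nn_control": ve_nn, "ve_direct_control": ve_dir,
        "r_control_1s": r_ctrl, "r_laser_1s": r_laser,
    })
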