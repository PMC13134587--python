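"""Tabular GAN cohort synthesis with distributional-fidelity validation.

A generator network maps latent Gaussian noise to a mixed-type patient
profile (continuous features on a standardized scale, Bernoulli
probabilities for comorbidity flags, softmax blocks for sex and surgery
type); a discriminator network is trained to distinguish synthetic from
real rows.  Both are compact multilayer perceptrons (two hidden layers,
width 64) trained with the standard minimax objective — non-saturating
generator loss, Adam updates — implemented directly in numpy with
explicit backpropagation, which keeps training deterministic under a
seed and dependency-light.

Fidelity of a synthetic table is validated against the real one with
two-sample Kolmogorov-Smirnov statistics per continuous feature,
total-variation distance of category frequencies per categorical
feature, and the Frobenius norm of the difference between the two
continuous correlation matrices ("correlation gap").

A Gaussian-copula generator (empirical marginals + Gaussian dependence)
serves as the non-adversarial baseline the GAN is regression-tested
against.

Outcome columns are never generated adversarially: POAF outcomes are
re-simulated from the ground-truth hazard on the generated covariates
(see ``synth_cohort.draw_outcomes``), keeping the trial engine's event
mechanism explicit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp, norm

from .synth_cohort import (
    BOOLEAN_COLUMNS,
    CONTINUOUS_COLUMNS,
)

__all__ = [
    "GanConfig",
    "FidelityThresholds",
    "FidelityReport",
    "GanGenerator",
    "CopulaGenerator",
    "fit_generator",
    "sample_cohort",
    "fidelity_report",
    "copula_baseline",
    "TrainingDivergedError",
]

CATEGORICAL_COLUMNS = {"sex": ["female", "male"],
                       "surgery_type": ["CABG", "valve", "combined", "aortic"]}


class TrainingDivergedError(RuntimeError):
    """Non-finite adversarial loss during training."""


@dataclass(frozen=True)
class GanConfig:
    latent_dim: int = 16
    generator_layers: tuple[int, ...] = (64, 64)
    discriminator_layers: tuple[int, ...] = (64, 64)
    epochs: int = 300
    batch_size: int = 128
    learning_rate: float = 1e-3
    beta1: float = 0.5
    beta2: float = 0.999
    lr_decay: bool = True      # cosine decay of the learning rate to 0
    ema_decay: float = 0.999   # exponential moving average of generator weights
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("latent_dim", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


# ---------------------------------------------------------------------------
# minimal MLP machinery


class _Adam:
    def __init__(self, shapes, lr, beta1, beta2, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _MLP:
    """Fully connected net with ReLU hidden layers and linear output."""

    def __init__(self, dims, rng):
        self.W = [rng.normal(0, np.sqrt(2.0 / dims[i]),
                             (dims[i], dims[i + 1]))
                  for i in range(len(dims) - 1)]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        self._cache = None

    @property
    def params(self):
        return self.W + self.b

    def forward(self, x):
        hs = [x]
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = hs[-1] @ W + b
            if i < len(self.W) - 1:
                z = np.maximum(z, 0.0)
            hs.append(z)
        self._cache = hs
        return hs[-1]

    def backward(self, dout):
        """Gradient w.r.t. input; parameter grads returned alongside."""
        hs = self._cache
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = dout
        for i in reversed(range(len(self.W))):
            gW[i] = hs[i].T @ delta
            gb[i] = delta.sum(axis=0)
            delta = delta @ self.W[i].T
            if i > 0:
                delta = delta * (hs[i] > 0)
        return delta, gW + gb


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _softmax(x):
    e = np.exp(x - x.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# mixed-type table codec


#: strictly positive, right-skewed features encoded on the log scale
LOG_SCALE_COLUMNS = ("crp_mg_l", "bnp_pg_ml", "hrv_sdnn_ms")


class _Codec:
    """Standardize continuous columns (log scale for skewed biomarkers),
    one-hot the categoricals."""

    def __init__(self, table: pd.DataFrame):
        self.cont = [c for c in CONTINUOUS_COLUMNS if c in table.columns]
        self.bools = [c for c in BOOLEAN_COLUMNS if c in table.columns]
        self.cats = {c: v for c, v in CATEGORICAL_COLUMNS.items()
                     if c in table.columns}
        self.log_cols = [c in LOG_SCALE_COLUMNS for c in self.cont]
        X = self._to_model_scale(table)
        self.mean = X.mean(axis=0)
        self.std = X.std(axis=0)
        self.std[self.std == 0] = 1.0
        self.lo = X.min(axis=0)
        self.hi = X.max(axis=0)

    def _to_model_scale(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.cont].to_numpy(float).copy()
        for j, is_log in enumerate(self.log_cols):
            if is_log:
                X[:, j] = np.log(np.maximum(X[:, j], 1e-9))
        return X

    @property
    def n_cont(self):
        return len(self.cont)

    @property
    def dim(self):
        return (self.n_cont + len(self.bools)
                + sum(len(v) for v in self.cats.values()))

    def encode(self, table: pd.DataFrame) -> np.ndarray:
        parts = [(self._to_model_scale(table) - self.mean) / self.std]
        if self.bools:
            parts.append(table[self.bools].to_numpy(float))
        for c, levels in self.cats.items():
            onehot = np.zeros((len(table), len(levels)))
            for j, lev in enumerate(levels):
                onehot[:, j] = (table[c] == lev).to_numpy(float)
            parts.append(onehot)
        return np.concatenate(parts, axis=1)

    def activate(self, raw: np.ndarray) -> np.ndarray:
        """Output activation: identity / sigmoid / softmax per block."""
        out = raw.copy()
        i = self.n_cont
        if self.bools:
            out[:, i:i + len(self.bools)] = _sigmoid(raw[:, i:i + len(self.bools)])
            i += len(self.bools)
        for levels in self.cats.values():
            out[:, i:i + len(levels)] = _softmax(raw[:, i:i + len(levels)])
            i += len(levels)
        return out

    def harden(self, act: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Sample hard 0/1 flags and one-hots from the emitted probabilities.

        Used during training so the discriminator sees the same discrete
        support in fake rows as in real rows; gradients flow through the
        underlying probabilities (straight-through estimator).
        """
        out = act.copy()
        i = self.n_cont
        if self.bools:
            p = act[:, i:i + len(self.bools)]
            out[:, i:i + len(self.bools)] = (rng.random(p.shape) < p)
            i += len(self.bools)
        for levels in self.cats.values():
            p = act[:, i:i + len(levels)]
            psum = p / p.sum(axis=1, keepdims=True)
            u = rng.random(p.shape[0])
            idx = (psum.cumsum(axis=1) < u[:, None]).sum(axis=1)
            hard = np.zeros_like(p)
            hard[np.arange(p.shape[0]), np.minimum(idx, len(levels) - 1)] = 1.0
            out[:, i:i + len(levels)] = hard
            i += len(levels)
        return out

    def activate_backward(self, act: np.ndarray, dact: np.ndarray) -> np.ndarray:
        """Jacobian-vector product of :meth:`activate`."""
        draw = dact.copy()
        i = self.n_cont
        if self.bools:
            s = act[:, i:i + len(self.bools)]
            draw[:, i:i + len(self.bools)] = dact[:, i:i + len(self.bools)] * s * (1 - s)
            i += len(self.bools)
        for levels in self.cats.values():
            s = act[:, i:i + len(levels)]
            d = dact[:, i:i + len(levels)]
            draw[:, i:i + len(levels)] = s * (d - (d * s).sum(axis=1, keepdims=True))
            i += len(levels)
        return draw

    def decode(self, act: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
        """Back to natural units; flags/categories sampled from the emitted
        probabilities; continuous values clipped to the training range."""
        cols = {}
        X = act[:, :self.n_cont] * self.std + self.mean
        X = np.clip(X, self.lo, self.hi)
        for j, c in enumerate(self.cont):
            cols[c] = np.exp(X[:, j]) if self.log_cols[j] else X[:, j]
        i = self.n_cont
        for b in self.bools:
            cols[b] = rng.random(act.shape[0]) < act[:, i]
            i += 1
        for c, levels in self.cats.items():
            probs = act[:, i:i + len(levels)]
            probs = probs / probs.sum(axis=1, keepdims=True)
            u = rng.random(act.shape[0])
            idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
            cols[c] = np.asarray(levels, dtype=object)[np.minimum(idx, len(levels) - 1)]
            i += len(levels)
        df = pd.DataFrame(cols)
        if "age" in df.columns:
            df["age"] = np.maximum(df["age"], 18.0)
        # preserve the qt < rr*1000 invariant after independent clipping
        if {"qt_ms", "rr_s"}.issubset(df.columns):
            df["qt_ms"] = np.minimum(df["qt_ms"], df["rr_s"] * 1000.0 - 1.0)
        return df


# ---------------------------------------------------------------------------
# GAN


class GanGenerator:
    """Trained generator handle: sample tables, save/load checkpoints."""

    def __init__(self, codec: _Codec, net: _MLP, config: GanConfig,
                 loss_history: list[tuple[float, float]]):
        self.codec = codec
        self.net = net
        self.config = config
        self.loss_history = loss_history

    def sample(self, n: int, seed: int = 0) -> pd.DataFrame:
        if n <= 0:
            raise ValueError("n must be positive")
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n, self.config.latent_dim))
        act = self.codec.activate(self.net.forward(z))
        df = self.codec.decode(act, rng)
        df.insert(0, "id", [f"S{i:06d}" for i in range(n)])
        return df

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"W{i}": w for i, w in enumerate(self.net.W)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.net.b)})
        arrays.update(mean=self.codec.mean, std=self.codec.std,
                      lo=self.codec.lo, hi=self.codec.hi)
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {"config": asdict(self.config),
                "cont": self.codec.cont, "bools": self.codec.bools,
                "cats": self.codec.cats, "log_cols": self.codec.log_cols,
                "loss_history": self.loss_history}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "GanGenerator":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        data = np.load(path.with_suffix(".npz"))
        codec = _Codec.__new__(_Codec)
        codec.cont = meta["cont"]
        codec.bools = meta["bools"]
        codec.cats = meta["cats"]
        codec.log_cols = meta["log_cols"]
        codec.mean, codec.std = data["mean"], data["std"]
        codec.lo, codec.hi = data["lo"], data["hi"]
        config = GanConfig(**{k: tuple(v) if isinstance(v, list) else v
                              for k, v in meta["config"].items()})
        n_w = sum(1 for k in data.files if k.startswith("W"))
        net = _MLP.__new__(_MLP)
        net.W = [data[f"W{i}"] for i in range(n_w)]
        net.b = [data[f"b{i}"] for i in range(n_w)]
        return cls(codec, net, config,
                   [tuple(x) for x in meta["loss_history"]])


def fit_generator(table: pd.DataFrame,
                  config: GanConfig | None = None) -> GanGenerator:
    """Adversarial training on a complete covariate table.

    Loss history holds one ``(d_loss, g_loss)`` pair per epoch.  With
    ``epochs=0`` the generator samples from its random initialization.
    Deterministic under ``config.seed`` for fixed library versions.
    """
    config = config or GanConfig()
    codec = _Codec(table)
    rng = np.random.default_rng(config.seed)
    X = codec.encode(table)
    n = X.shape[0]
    gen = _MLP([config.latent_dim, *config.generator_layers, codec.dim], rng)
    dis = _MLP([codec.dim, *config.discriminator_layers, 1], rng)
    opt_g = _Adam([p.shape for p in gen.params], config.learning_rate,
                  config.beta1, config.beta2)
    opt_d = _Adam([p.shape for p in dis.params], config.learning_rate,
                  config.beta1, config.beta2)
    bs = min(config.batch_size, n)
    steps = max(n // bs, 1)
    history: list[tuple[float, float]] = []
    ema = [p.copy() for p in gen.params]
    base_lr = config.learning_rate
    for epoch in range(config.epochs):
        if config.lr_decay and config.epochs > 1:
            frac = epoch / (config.epochs - 1)
            lr = base_lr * 0.5 * (1 + np.cos(np.pi * frac))
            opt_g.lr = opt_d.lr = max(lr, base_lr * 1e-3)
        perm = rng.permutation(n)
        d_losses, g_losses = [], []
        for step in range(steps):
            real = X[perm[step * bs:(step + 1) * bs]]
            m = real.shape[0]
            # --- discriminator update
            z = rng.standard_normal((m, config.latent_dim))
            fake = codec.harden(codec.activate(gen.forward(z)), rng)
            logits_r = dis.forward(real)[:, 0]
            p_r = _sigmoid(logits_r)
            d_r, grads_r = dis.backward(((p_r - 1.0) / m)[:, None])
            logits_f = dis.forward(fake)[:, 0]
            p_f = _sigmoid(logits_f)
            d_f, grads_f = dis.backward((p_f / m)[:, None])
            opt_d.step(dis.params, [gr + gf for gr, gf in zip(grads_r, grads_f)])
            d_loss = float(-np.mean(np.log(p_r + 1e-12))
                           - np.mean(np.log(1 - p_f + 1e-12)))
            # --- generator update (non-saturating loss)
            z = rng.standard_normal((m, config.latent_dim))
            raw = gen.forward(z)
            soft = codec.activate(raw)
            fake = codec.harden(soft, rng)  # straight-through: hard forward
            logits = dis.forward(fake)[:, 0]
            p = _sigmoid(logits)
            g_loss = float(-np.mean(np.log(p + 1e-12)))
            dfake, _ = dis.backward(((p - 1.0) / m)[:, None])
            draw = codec.activate_backward(soft, dfake)
            _, grads_g = gen.backward(draw)
            opt_g.step(gen.params, grads_g)
            for e, p in zip(ema, gen.params):
                e *= config.ema_decay
                e += (1 - config.ema_decay) * p
            if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
                raise TrainingDivergedError(
                    f"non-finite adversarial loss at epoch {epoch}"
                )
            d_losses.append(d_loss)
            g_losses.append(g_loss)
        history.append((float(np.mean(d_losses)), float(np.mean(g_losses))))
    if config.epochs > 0 and config.ema_decay > 0:
        n_w = len(gen.W)
        gen.W = [e for e in ema[:n_w]]
        gen.b = [e for e in ema[n_w:]]
    return GanGenerator(codec, gen, config, history)


def sample_cohort(generator, n: int, seed: int = 0) -> pd.DataFrame:
    """Sample ``n`` rows from a trained generator handle, in natural units."""
    return generator.sample(n, seed=seed)


# ---------------------------------------------------------------------------
# fidelity


@dataclass(frozen=True)
class FidelityThresholds:
    ks_d_max: float = 0.1
    tv_max: float = 0.05
    correlation_gap_max: float = 0.5


@dataclass
class FidelityReport:
    ks: dict            # feature -> {"D": ..., "p": ..., "pass": ...}
    tv: dict            # feature -> {"tv": ..., "pass": ...}
    correlation_gap: float
    passed: bool

    def to_dict(self) -> dict:
        return {"ks": self.ks, "tv": self.tv,
                "correlation_gap": self.correlation_gap, "pass": self.passed}

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def fidelity_report(real_table: pd.DataFrame, synthetic_table: pd.DataFrame,
                    thresholds: FidelityThresholds | None = None
                    ) -> FidelityReport:
    """Distributional similarity of synthetic vs real tables.

    Two-sample KS per continuous feature, total-variation distance of
    category frequencies per boolean/categorical feature, and the
    Frobenius norm of the continuous correlation-matrix difference.
    """
    thresholds = thresholds or FidelityThresholds()
    cont = [c for c in CONTINUOUS_COLUMNS if c in real_table.columns]
    missing = [c for c in cont if c not in synthetic_table.columns]
    cats = [c for c in BOOLEAN_COLUMNS + list(CATEGORICAL_COLUMNS)
            if c in real_table.columns]
    missing += [c for c in cats if c not in synthetic_table.columns]
    if missing:
        raise ValueError(f"synthetic table lacks column(s): {missing}")
    ks = {}
    for c in cont:
        stat = ks_2samp(real_table[c].to_numpy(float),
                        synthetic_table[c].to_numpy(float))
        ks[c] = {"D": float(stat.statistic), "p": float(stat.pvalue),
                 "pass": bool(stat.statistic < thresholds.ks_d_max)}
    tv = {}
    for c in cats:
        fr = real_table[c].value_counts(normalize=True)
        fs = synthetic_table[c].value_counts(normalize=True)
        levels = fr.index.union(fs.index)
        dist = 0.5 * float(sum(abs(fr.get(l, 0.0) - fs.get(l, 0.0))
                               for l in levels))
        tv[c] = {"tv": dist, "pass": bool(dist < thresholds.tv_max)}
    if len(cont) >= 2:
        r_real = np.corrcoef(real_table[cont].to_numpy(float), rowvar=False)
        r_syn = np.corrcoef(synthetic_table[cont].to_numpy(float), rowvar=False)
        gap = float(np.linalg.norm(r_real - r_syn, "fro"))
    else:
        gap = 0.0  # no off-diagonal structure with < 2 continuous features
    passed = (all(v["pass"] for v in ks.values())
              and all(v["pass"] for v in tv.values())
              and gap < thresholds.correlation_gap_max)
    return FidelityReport(ks=ks, tv=tv, correlation_gap=gap, passed=passed)


# ---------------------------------------------------------------------------
# copula baseline


class CopulaGenerator:
    """Gaussian copula: empirical marginals + Gaussian dependence.

    Continuous features are mapped to normal scores, their correlation
    estimated, and samples mapped back through the empirical quantile
    functions.  Boolean/categorical columns are resampled jointly from
    the observed rows (row bootstrap), preserving their joint frequencies.
    """

    def __init__(self, table: pd.DataFrame, seed: int = 0):
        import warnings as _w

        self.cont = [c for c in CONTINUOUS_COLUMNS if c in table.columns]
        self.cats = [c for c in BOOLEAN_COLUMNS + list(CATEGORICAL_COLUMNS)
                     if c in table.columns]
        X = table[self.cont].to_numpy(float)
        for j, c in enumerate(self.cont):
            if np.ptp(X[:, j]) == 0:
                _w.warn(f"degenerate (constant) marginal in column {c!r}",
                        stacklevel=3)
        n = X.shape[0]
        ranks = np.argsort(np.argsort(X, axis=0), axis=0) + 1.0
        z = norm.ppf(ranks / (n + 1.0))
        self.corr = np.corrcoef(z, rowvar=False)
        # guard against non-PSD estimates on tiny samples
        w, V = np.linalg.eigh(self.corr)
        w = np.maximum(w, 1e-8)
        self.corr = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(self.corr))
        self.corr /= np.outer(d, d)
        self.sorted_cols = np.sort(X, axis=0)
        self.cat_rows = table[self.cats].reset_index(drop=True)
        self.seed = seed

    def sample(self, n: int, seed: int | None = None) -> pd.DataFrame:
        if n <= 0:
            raise ValueError("n must be positive")
        rng = np.random.default_rng(self.seed if seed is None else seed)
        z = rng.standard_normal((n, len(self.cont))) @ \
            np.linalg.cholesky(self.corr).T
        u = norm.cdf(z)
        cols = {}
        m = self.sorted_cols.shape[0]
        q = (np.arange(m) + 0.5) / m
        for j, c in enumerate(self.cont):
            cols[c] = np.interp(u[:, j], q, self.sorted_cols[:, j])
        idx = rng.integers(0, len(self.cat_rows), size=n)
        df = pd.DataFrame(cols)
        for c in self.cats:
            df[c] = self.cat_rows[c].to_numpy()[idx]
        if {"qt_ms", "rr_s"}.issubset(df.columns):
            df["qt_ms"] = np.minimum(df["qt_ms"], df["rr_s"] * 1000.0 - 1.0)
        df.insert(0, "id", [f"C{i:06d}" for i in range(n)])
        return df


def copula_baseline(real_table: pd.DataFrame, seed: int = 0) -> CopulaGenerator:
    """Non-adversarial fidelity baseline the GAN must match or beat."""
    return CopulaGenerator(real_table, seed=seed)
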