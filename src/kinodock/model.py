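"""Neural scoring function, leakage-aware splits, and evaluation metrics.

The scoring network is a 3-layer fully connected regressor mapping a binary
fingerprint to a predicted pChEMBL value: input (2048 for ECFP or 65536 for
PLEC by default) -> 4000 -> 1000 -> 1, ReLU activations, dropout 0.25 on the
input and hidden layers during training only.  Training minimizes mean
squared error with Adam at a fixed learning rate (default 1e-5), batch size
128, 100 epochs; after every epoch the test-set R-squared is evaluated and
the best checkpoint — not the final epoch — is returned.  The implementation
is a self-contained dense-network trainer on NumPy arrays; fingerprint
inputs at toy widths run comfortably on one CPU.

Splits come in three strategies: ``random`` (by record), ``compound`` and
``kinase`` (by entity, so no compound/kinase appears on both sides — the
leakage-aware settings).  Among ``n_candidates`` seeded resamplings the
partition minimizing the Kolmogorov-Smirnov statistic between train and
test pChEMBL distributions is returned, making the held-out label
distribution representative.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScoringNetworkSpec",
    "TrainingConfig",
    "SplitAssignment",
    "MetricsTable",
    "ScoringNetwork",
    "make_splits",
    "train",
    "predict",
    "r_squared",
    "per_kinase_metrics",
    "train_per_kinase",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ScoringNetworkSpec:
    """Architecture of the 3-layer scoring network."""

    input_bits: int = 2048
    hidden1: int = 4000
    hidden2: int = 1000
    output: int = 1
    dropout: float = 0.25

    def __post_init__(self):
        if min(self.input_bits, self.hidden1, self.hidden2, self.output) < 1:
            raise ValueError("layer widths must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-5
    batch_size: int = 128
    epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs >= 0 and batch_size >= 1 required")


@dataclass
class SplitAssignment:
    strategy: str
    train_ids: list
    test_ids: list
    test_fraction: float = 0.2

    def __post_init__(self):
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


@dataclass
class MetricsTable:
    """Per-kinase R-squared rows plus an unweighted per-group roll-up."""

    per_kinase: pd.DataFrame  # columns: accession, kinase_group, n_test, r_squared
    per_group: pd.DataFrame  # columns: kinase_group, n_kinases, mean_r_squared
    flagged: list[str] = field(default_factory=list)  # kinases with <2 test points


class ScoringNetwork:
    """Weights + forward pass of the 3-layer network (NumPy, float64)."""

    def __init__(self, spec: ScoringNetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.Generator(np.random.Philox(seed))
        widths = [spec.input_bits, spec.hidden1, spec.hidden2, spec.output]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            # uniform fan-in ("Kaiming uniform"-style) initialization
            bound = np.sqrt(1.0 / fan_in)
            self.weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.biases.append(rng.uniform(-bound, bound, size=fan_out))

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Inference-mode forward pass (dropout inactive)."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.spec.input_bits:
            raise ValueError(
                f"feature width {X.shape[1]} != network input {self.spec.input_bits}"
            )
        h = X
        for k, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W + b
            if k < len(self.weights) - 1:
                h = np.maximum(h, 0.0)
        return h[:, 0]

    def copy(self) -> "ScoringNetwork":
        clone = ScoringNetwork.__new__(ScoringNetwork)
        clone.spec = self.spec
        clone.weights = [W.copy() for W in self.weights]
        clone.biases = [b.copy() for b in self.biases]
        return clone


def r_squared(pred, obs, method: str = "pearson") -> float:
    """Squared Pearson correlation between predictions and observations
    (the scoring-function convention); ``method='cod'`` gives the
    coefficient of determination 1 - SS_res/SS_tot instead."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 2:
        raise ValueError("pred and obs must have equal length >= 2")
    if np.ptp(obs) == 0:
        raise ValueError("R-squared undefined for constant observations")
    if method == "pearson":
        if np.ptp(pred) == 0:
            return 0.0
        r = np.corrcoef(pred, obs)[0, 1]
        return float(r * r)
    if method == "cod":
        ss_res = float(((obs - pred) ** 2).sum())
        ss_tot = float(((obs - obs.mean()) ** 2).sum())
        return 1.0 - ss_res / ss_tot
    raise ValueError(f"unknown R-squared method {method!r}")


# ---------------------------------------------------------------------------
# Splitting


def make_splits(
    activities: Sequence[tuple],
    strategy: str = "random",
    test_fraction: float = 0.2,
    seed: int = 0,
    n_candidates: int = 25,
) -> SplitAssignment:
    """Partition activity records 80:20, leakage-aware, KS-curated.

    ``activities`` is a sequence of (activity_id, compound_id, accession,
    pchembl) tuples.  ``strategy`` is ``random`` (by record), ``compound``
    or ``kinase`` (whole entities held out).  ``n_candidates`` seeded
    partitions are drawn and the one with the smallest Kolmogorov-Smirnov
    statistic between train and test pChEMBL values is returned;
    deterministic given ``seed``.
    """
    records = list(activities)
    if len(records) < 5:
        raise ValueError("need at least 5 records to split")
    if strategy not in ("random", "compound", "kinase"):
        raise ValueError(f"unknown split strategy {strategy!r}")
    ids = [r[0] for r in records]
    pchembl = {r[0]: float(r[3]) for r in records}
    if strategy == "random":
        entity_of = {r[0]: r[0] for r in records}
    elif strategy == "compound":
        entity_of = {r[0]: r[1] for r in records}
    else:
        entity_of = {r[0]: r[2] for r in records}
    entities: dict = {}
    for aid in ids:
        entities.setdefault(entity_of[aid], []).append(aid)
    if strategy != "random" and len(entities) < 2:
        raise ValueError(f"cannot make a {strategy} split with one entity")

    rng = np.random.Generator(np.random.Philox(seed))
    target = test_fraction * len(ids)
    best: tuple[float, list, list] | None = None
    candidates_ks: list[float] = []
    ent_keys = sorted(entities)
    for _ in range(max(1, n_candidates)):
        order = rng.permutation(len(ent_keys))
        test_ids: list = []
        for k in order:
            members = entities[ent_keys[k]]
            # greedy-closest packing toward the 20% record target
            if abs(len(test_ids) + len(members) - target) <= abs(len(test_ids) - target):
                test_ids.extend(members)
            if len(test_ids) >= target:
                break
        test_set = set(test_ids)
        train_vals = [pchembl[a] for a in ids if a not in test_set]
        test_vals = [pchembl[a] for a in test_ids]
        if not test_vals or not train_vals:
            continue
        ks = float(stats.ks_2samp(train_vals, test_vals).statistic)
        candidates_ks.append(ks)
        if best is None or ks < best[0]:
            best = (ks, [a for a in ids if a not in test_set], list(test_ids))
    assert best is not None
    split = SplitAssignment(
        strategy=strategy,
        train_ids=best[1],
        test_ids=best[2],
        test_fraction=test_fraction,
    )
    split.ks_statistic = best[0]  # type: ignore[attr-defined]
    split.candidate_ks = candidates_ks  # type: ignore[attr-defined]
    return split


# ---------------------------------------------------------------------------
# Training


def train(
    spec: ScoringNetworkSpec,
    X_train,
    y_train,
    X_test,
    y_test,
    config: TrainingConfig,
) -> tuple[ScoringNetwork, pd.DataFrame]:
    """Train the scoring network; return (best checkpoint, history).

    Minimizes MSE with Adam at the fixed learning rate.  After each epoch
    the test-set R-squared is recorded; the returned network is the
    checkpoint with the best test metric.  History columns: epoch,
    train_loss, test_r2.  Raises on feature-width mismatch; aborts with a
    diagnostic if the loss becomes non-finite.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.float64).ravel()
    X_test = np.asarray(X_test, dtype=np.float64)
    y_test = np.asarray(y_test, dtype=np.float64).ravel()
    if X_train.shape[1] != spec.input_bits:
        raise ValueError(
            f"feature width {X_train.shape[1]} != spec.input_bits {spec.input_bits}"
        )
    rng = np.random.Generator(np.random.Philox(config.seed))
    net = ScoringNetwork(spec, seed=config.seed)
    history: list[dict] = []
    if config.epochs == 0:
        return net, pd.DataFrame(history, columns=["epoch", "train_loss", "test_r2"])

    # Adam state
    m = [np.zeros_like(W) for W in net.weights] + [np.zeros_like(b) for b in net.biases]
    v = [np.zeros_like(g) for g in m]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    n = X_train.shape[0]
    best_metric = -np.inf
    best_net = net.copy()
    keep = 1.0 - spec.dropout

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X_train[idx], y_train[idx]
            # forward with inverted dropout on input and hidden activations
            acts = []
            masks = []
            h = xb
            if spec.dropout > 0:
                mask = (rng.random(h.shape) < keep) / keep
                h = h * mask
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(h)
            for k, (W, b) in enumerate(zip(net.weights, net.biases)):
                z = h @ W + b
                if k < len(net.weights) - 1:
                    h = np.maximum(z, 0.0)
                    if spec.dropout > 0:
                        mask = (rng.random(h.shape) < keep) / keep
                        h = h * mask
                        masks.append(mask)
                    else:
                        masks.append(None)
                    acts.append(h)
                else:
                    h = z
            pred = h[:, 0]
            err = pred - yb
            loss = float((err**2).mean())
            epoch_loss += loss * len(idx)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss}"
                )
            # backward
            grad_z = (2.0 / len(idx)) * err[:, None]
            gW = [None] * len(net.weights)
            gb = [None] * len(net.biases)
            for k in range(len(net.weights) - 1, -1, -1):
                a_prev = acts[k]
                gW[k] = a_prev.T @ grad_z
                gb[k] = grad_z.sum(axis=0)
                if k > 0:
                    grad_h = grad_z @ net.weights[k].T
                    if masks[k] is not None:
                        grad_h = grad_h * masks[k]
                    grad_z = grad_h * (acts[k] > 0)
            # Adam step
            t += 1
            grads = gW + gb
            params = net.weights + net.biases
            for p, g, mi, vi in zip(params, grads, m, v):
                mi *= beta1
                mi += (1 - beta1) * g
                vi *= beta2
                vi += (1 - beta2) * g * g
                mhat = mi / (1 - beta1**t)
                vhat = vi / (1 - beta2**t)
                p -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        test_r2 = r_squared(net.forward(X_test), y_test)
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / n, "test_r2": test_r2}
        )
        if test_r2 > best_metric:
            best_metric = test_r2
            best_net = net.copy()
    return best_net, pd.DataFrame(history)


def predict(model: ScoringNetwork, X) -> np.ndarray:
    """Deterministic inference (dropout inactive)."""
    return model.forward(X)


# ---------------------------------------------------------------------------
# Metrics


def per_kinase_metrics(
    predictions: Iterable[tuple[str, str, float, float]]
) -> MetricsTable:
    """Per-kinase R-squared and unweighted per-group means.

    ``predictions`` yields (accession, kinase_group, predicted, observed).
    Kinases with fewer than 2 test points are flagged and excluded from
    group means.
    """
    by_kinase: dict[str, dict] = {}
    for acc, group, pred, obs in predictions:
        d = by_kinase.setdefault(acc, {"group": group, "pred": [], "obs": []})
        d["pred"].append(float(pred))
        d["obs"].append(float(obs))
    rows, flagged = [], []
    for acc in sorted(by_kinase):
        d = by_kinase[acc]
        n = len(d["pred"])
        if n < 2 or np.ptp(d["obs"]) == 0:
            flagged.append(acc)
            rows.append(
                {"accession": acc, "kinase_group": d["group"], "n_test": n,
                 "r_squared": np.nan}
            )
            continue
        rows.append(
            {
                "accession": acc,
                "kinase_group": d["group"],
                "n_test": n,
                "r_squared": r_squared(d["pred"], d["obs"]),
            }
        )
    per_kinase = pd.DataFrame(rows, columns=["accession", "kinase_group", "n_test", "r_squared"])
    ok = per_kinase.dropna(subset=["r_squared"])
    per_group = (
        ok.groupby("kinase_group")
        .agg(n_kinases=("accession", "size"), mean_r_squared=("r_squared", "mean"))
        .reset_index()
        if len(ok)
        else pd.DataFrame(columns=["kinase_group", "n_kinases", "mean_r_squared"])
    )
    return MetricsTable(per_kinase=per_kinase, per_group=per_group, flagged=flagged)


def train_per_kinase(
    data: Mapping[str, tuple],
    spec: ScoringNetworkSpec,
    config: TrainingConfig,
    min_inhibitors: int = 100,
) -> tuple[dict[str, ScoringNetwork], list[str]]:
    """Train one network per kinase with at least ``min_inhibitors`` unique
    compounds (the per-kinase ECFP-model setting).

    ``data`` maps accession -> (compound_ids, X, y).  Returns (models,
    skipped accessions); trained + skipped partition the input kinases.
    """
    models: dict[str, ScoringNetwork] = {}
    skipped: list[str] = []
    for acc in sorted(data):
        compound_ids, X, y = data[acc]
        if len(set(compound_ids)) < min_inhibitors:
            skipped.append(acc)
            continue
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        n = len(y)
        rng = np.random.Generator(np.random.Philox(config.seed))
        order = rng.permutation(n)
        n_test = max(2, int(round(0.2 * n)))
        test_idx, train_idx = order[:n_test], order[n_test:]
        model, _ = train(
            spec, X[train_idx], y[train_idx], X[test_idx], y[test_idx], config
        )
        models[acc] = model
    return models, skipped


# ---------------------------------------------------------------------------
# Serialization

_FORMAT_VERSION = 1


def save_model(model: ScoringNetwork, path) -> None:
    """Archive = JSON header (version + architecture) + flat weight arrays."""
    header = {"version": _FORMAT_VERSION, "spec": asdict(model.spec)}
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("header.json", json.dumps(header))
        for k, (W, b) in enumerate(zip(model.weights, model.biases)):
            with zf.open(f"W{k}.npy", "w") as f:
                np.save(f, W)
            with zf.open(f"b{k}.npy", "w") as f:
                np.save(f, b)


def load_model(path) -> ScoringNetwork:
    with zipfile.ZipFile(path, "r") as zf:
        header = json.loads(zf.read("header.json"))
        if header["version"] != _FORMAT_VERSION:
            raise ValueError(f"unsupported model archive version {header['version']}")
        spec = ScoringNetworkSpec(**header["spec"])
        model = ScoringNetwork.__new__(ScoringNetwork)
        model.spec = spec
        model.weights, model.biases = [], []
        for k in range(3):
            with zf.open(f"W{k}.npy") as f:
                model.weights.append(np.load(f))
            with zf.open(f"b{k}.npy") as f:
                model.biases.append(np.load(f))
    return model
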