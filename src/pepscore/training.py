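"""Training of the graph-network score against normalized ligand RMSD.

The target is a single global quantity per complex,
``lrmsd_norm = 1/(1 + (LRMSD/8)^2)``, regressed with mean squared error.
Optimization is Adam with dropout active and batch-norm statistics
updating; early stopping watches validation MSE and the parameters of the
best validation epoch are returned.

:func:`iterative_retrain` closes the loop between scoring and sampling:
after each fit, Monte-Carlo refinement trajectories are run with the
current model as an energy term and their snapshots — accepted and
rejected alike — are labelled with recomputed targets and appended to the
training pool, so the training distribution tracks the states the score
actually visits during refinement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import metrics
from .decoys import PerturbationParams, assemble_balanced_set
from .gnn import (
    GraphBatch,
    ModelConfig,
    ModelParams,
    forward_batch,
    init_params,
    recalibrate_bn,
)
from .graph import ComplexGraph, build_graph
from .mc import MCConfig, refine
from .structure import PepComplex

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 8
    max_epochs: int = 200
    patience: int = 10
    dropout_rate: float = 0.40
    n_retrain_iterations: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.n_retrain_iterations < 1:
            raise ValueError("n_retrain_iterations must be >= 1")


@dataclass
class TrainReport:
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = np.inf
    iterations: list[dict] = field(default_factory=list)


def loss(pred: float, target: float) -> float:
    """Squared error of a single prediction; batch loss is the mean."""
    if not 0.0 <= target <= 1.0:
        raise ValueError(f"target out of [0, 1]: {target}")
    return float((pred - target) ** 2)


def batch_loss(preds: np.ndarray, targets: np.ndarray) -> float:
    return float(np.mean((np.asarray(preds) - np.asarray(targets)) ** 2))


class _Adam:
    def __init__(self, keys: list[str], lr: float):
        self.lr = lr
        self.m = {k: None for k in keys}
        self.v = {k: None for k in keys}
        self.t = 0
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: ModelParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if g is None:
                continue
            if self.m[k] is None:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            params.arrays[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _evaluate(
    pairs: list[tuple[ComplexGraph, float]], params: ModelParams
) -> float:
    batch = GraphBatch.from_graphs([g for g, _ in pairs])
    scores, _, _ = forward_batch(batch, params, training=False)
    targets = np.array([t for _, t in pairs])
    return batch_loss(scores.data[:, 0], targets)


def fit(
    train: list[tuple[ComplexGraph, float]],
    val: list[tuple[ComplexGraph, float]],
    config: TrainConfig,
    model_config: ModelConfig | None = None,
    init: ModelParams | None = None,
) -> tuple[ModelParams, TrainReport]:
    """Gradient training with early stopping on validation MSE.

    Returns the parameters of the best validation epoch.  Fully
    reproducible from ``config.seed``.
    """
    if not train or not val:
        raise ValueError("train and val sets must be non-empty")
    for _, t in train + val:
        if not 0.0 < t <= 1.0:
            raise ValueError(f"target out of (0, 1]: {t}")

    model_config = model_config or ModelConfig(
        dropout_rate=config.dropout_rate, seed=config.seed
    )
    rng = np.random.default_rng(config.seed)
    params = init.copy() if init is not None else init_params(model_config, rng)
    # single precision keeps desk-scale training fast; scores are cast back
    for k in params.arrays:
        params.arrays[k] = params.arrays[k].astype(np.float32)
    opt = _Adam(params.trainable_keys(), config.learning_rate)
    report = TrainReport()

    best_params = params.copy()
    epochs_since_best = 0
    full_train_batch = GraphBatch.from_graphs([g for g, _ in train]).astype(np.float32)
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train))
        epoch_losses = []
        for lo in range(0, len(train), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            batch = GraphBatch.from_graphs([train[i][0] for i in idx]).astype(np.float32)
            targets = np.array([[train[i][1]] for i in idx], dtype=np.float32)
            scores, _, state = forward_batch(
                batch, params, training=True, rng=rng, trainable=True
            )
            sq = (scores - targets).square().mean()
            if not np.isfinite(sq.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}; "
                    f"last finite epoch {epoch - 1}"
                )
            sq.backward()
            grads = {
                k: state.tensors[k].grad
                for k in params.trainable_keys()
            }
            opt.step(params, grads)
            epoch_losses.append(float(sq.data))
        report.train_losses.append(float(np.mean(epoch_losses)))

        recalibrate_bn(params, full_train_batch)
        val_loss = _evaluate(val, params)
        report.val_losses.append(val_loss)
        if val_loss < report.best_val_loss:
            report.best_val_loss = val_loss
            report.best_epoch = epoch
            best_params = params.copy()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= config.patience:
                logger.info("early stop at epoch %d (best %d)", epoch, report.best_epoch)
                break
    return best_params, report


def early_stop_index(val_losses: list[float], patience: int) -> int:
    """Index of the epoch at which the patience rule halts a loss sequence."""
    best, best_i, since = np.inf, -1, 0
    for i, v in enumerate(val_losses):
        if v < best:
            best, best_i, since = v, i, 0
        else:
            since += 1
            if since >= patience:
                return i
    return len(val_losses) - 1


def harvest_snapshots(
    native: PepComplex,
    starts: list[PepComplex],
    params: ModelParams | None,
    mc_config: MCConfig,
) -> list[tuple[ComplexGraph, float]]:
    """Refinement snapshots of ``starts`` labelled with recomputed targets."""
    pairs = []
    for i, start in enumerate(starts):
        cfg = replace(mc_config, seed=mc_config.seed + i)
        traj = refine(start, params, cfg)
        for snap in traj.snapshots:
            lr = metrics.lrmsd(snap.complex, native)
            pairs.append((build_graph(snap.complex), metrics.lrmsd_norm(lr)))
    return pairs


def iterative_retrain(
    natives: list[PepComplex],
    config: TrainConfig,
    mc_config: MCConfig,
    n_decoys_per_native: int = 20,
    n_starts_per_native: int = 2,
    perturbation: PerturbationParams | None = None,
    model_config: ModelConfig | None = None,
) -> tuple[ModelParams, TrainReport]:
    """Alternating train / sample-with-current-score / extend-pool loop.

    Stops after ``config.n_retrain_iterations`` rounds or as soon as an
    iteration fails to improve validation loss; the best iteration's
    parameters are returned.
    """
    if not natives:
        raise ValueError("need at least one native complex")
    rng = np.random.default_rng(config.seed)

    pool: list[tuple[ComplexGraph, float]] = []
    val: list[tuple[ComplexGraph, float]] = []
    for native in natives:
        records = assemble_balanced_set(
            native, n_decoys_per_native, perturbation, rng
        )
        pairs = [(build_graph(r.complex), r.target) for r in records]
        n_val = max(2, len(pairs) // 5)
        val.extend(pairs[:n_val])
        pool.extend(pairs[n_val:])

    best_params: ModelParams | None = None
    best_val = np.inf
    report = TrainReport()
    params: ModelParams | None = None
    for iteration in range(config.n_retrain_iterations):
        params, fit_report = fit(
            pool, val, config, model_config=model_config, init=params
        )
        report.train_losses.extend(fit_report.train_losses)
        report.val_losses.extend(fit_report.val_losses)
        report.iterations.append(
            {
                "iteration": iteration,
                "pool_size": len(pool),
                "val_loss": fit_report.best_val_loss,
                "best_epoch": fit_report.best_epoch,
            }
        )
        if fit_report.best_val_loss < best_val:
            best_val = fit_report.best_val_loss
            best_params = params.copy()
            report.best_epoch = len(report.val_losses) - 1
            report.best_val_loss = best_val
        elif iteration > 0:
            logger.info("validation stopped improving at iteration %d", iteration)
            break
        if iteration == config.n_retrain_iterations - 1:
            break
        for ni, native in enumerate(natives):
            starts = [
                r.complex
                for r in assemble_balanced_set(
                    native, 2 * n_starts_per_native, perturbation, rng
                )[: n_starts_per_native]
            ]
            cfg = replace(mc_config, seed=int(rng.integers(2**31)))
            pool.extend(harvest_snapshots(native, starts, params, cfg))
    assert best_params is not None
    return best_params, report
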