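"""Concentration-aware multi-output fraction-bound regressor.

A fully connected network maps (M, C) — the substructure-count vector M of
a glycoconjugate and a protein concentration C — to a vector f of fractions
bound, one output per lectin group.  Heterogeneous datasets are merged by
training with a *masked* mean-squared-error loss: each (molecule,
concentration, lectin) triple carries an observed flag, and unobserved
targets contribute zero gradient.  This is what lets array data (all
lectins, some concentrations) and affinity data (few lectins, dense
concentrations) coexist in one model.

Cross-validation is grouped by glycan structure: records sharing a
canonical structure land in the same fold, and all concentrations of a
molecule live in its fold, so held-out performance measures generalization
to unseen structures rather than interpolation along a dose curve.

The network is deliberately small (two to three hidden layers of 50–100
tanh units, linear outputs clamped to [0, 1] at reporting time) and is
trained with Adam using 0.001 learning rate and 0.0001 weight decay.  The
optimizer, forward and backward passes are implemented directly on numpy
arrays; at these layer widths a framework would add dependency weight
without adding speed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class Dataset:
    """Molecule features plus a (molecule × concentration × lectin) target tensor.

    ``mask`` marks which triples have observed data; every observed target
    is a fraction bound in [0, 1].  ``group_keys`` carry the canonical
    structure key used for fold grouping (defaults to molecule_id).
    """

    molecule_ids: list[str]
    features: np.ndarray  # (n_molecules, n_features)
    concentrations: np.ndarray  # (n_concentrations,) positive
    lectin_ids: list[str]
    targets: np.ndarray  # (n_molecules, n_concentrations, n_lectins)
    mask: np.ndarray  # same shape, bool
    group_keys: list[str] | None = None

    def __post_init__(self) -> None:
        n_mol, n_conc, n_lec = self.targets.shape
        if self.features.shape[0] != n_mol or len(self.molecule_ids) != n_mol:
            raise ValueError("molecule dimension mismatch")
        if len(self.concentrations) != n_conc or len(self.lectin_ids) != n_lec:
            raise ValueError("target tensor shape mismatch")
        if self.mask.shape != self.targets.shape:
            raise ValueError("mask shape mismatch")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        observed = self.targets[self.mask]
        if observed.size and (observed.min() < 0 or observed.max() > 1):
            raise ValueError("observed targets must lie in [0, 1]")
        if self.group_keys is None:
            self.group_keys = list(self.molecule_ids)


@dataclass
class FoldAssignment:
    """molecule_id → fold index; structure groups never straddle folds."""

    assignment: dict[str, int]
    k: int = 10

    def fold_of(self, molecule_id: str) -> int:
        return self.assignment[molecule_id]


@dataclass
class ModelSpec:
    """Architecture: input = fingerprint dim + 1 (concentration)."""

    fingerprint_dim: int
    output_dim: int
    hidden_layers: tuple[int, ...] = (100, 100)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= len(self.hidden_layers) <= 4:
            raise ValueError("hidden_layers must have 1-4 entries")

    @property
    def input_dim(self) -> int:
        return self.fingerprint_dim + 1


@dataclass
class TrainHyperparams:
    learning_rate: float = 0.001
    weight_decay: float = 0.0001
    epochs: int = 200
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.epochs, self.batch_size) <= 0 or self.weight_decay < 0:
            raise ValueError("hyperparameters must be positive (weight_decay ≥ 0)")


@dataclass
class TrainedModel:
    """Weights plus the input transform needed to reproduce predictions.

    ``log_c_mean``/``log_c_std`` standardize log10(concentration);
    ``feature_scale`` divides the count vector (counts can reach hundreds
    for large glycans, so a fixed scale keeps activations in range).
    """

    spec: ModelSpec
    weights: list[np.ndarray] = field(repr=False, default_factory=list)
    biases: list[np.ndarray] = field(repr=False, default_factory=list)
    log_c_mean: float = 0.0
    log_c_std: float = 1.0
    feature_scale: float = 1.0
    lectin_ids: list[str] = field(default_factory=list)

    # -- forward pass -------------------------------------------------------
    def _forward(self, x: np.ndarray, keep: bool = False):
        acts = [x]
        h = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.tanh(h @ w + b)
            acts.append(h)
        out = h @ self.weights[-1] + self.biases[-1]
        return (out, acts) if keep else out

    def _encode(self, fingerprints: np.ndarray, concentrations: np.ndarray) -> np.ndarray:
        if np.any(concentrations <= 0):
            raise ValueError("concentration must be positive (log transform)")
        log_c = (np.log10(concentrations) - self.log_c_mean) / self.log_c_std
        return np.column_stack([fingerprints / self.feature_scale, log_c])

    def predict_raw(self, fingerprints: np.ndarray, concentrations: np.ndarray) -> np.ndarray:
        fingerprints = np.atleast_2d(np.asarray(fingerprints, dtype=float))
        concentrations = np.atleast_1d(np.asarray(concentrations, dtype=float))
        if fingerprints.shape[1] != self.spec.fingerprint_dim:
            raise ValueError(
                f"feature dimension {fingerprints.shape[1]} does not match model "
                f"fingerprint_dim {self.spec.fingerprint_dim}"
            )
        return self._forward(self._encode(fingerprints, concentrations))

    # -- persistence --------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **{f"w{i}": w for i, w in enumerate(self.weights)},
                 **{f"b{i}": b for i, b in enumerate(self.biases)})
        manifest = {
            "fingerprint_dim": self.spec.fingerprint_dim,
            "output_dim": self.spec.output_dim,
            "hidden_layers": list(self.spec.hidden_layers),
            "seed": self.spec.seed,
            "log_c_mean": self.log_c_mean,
            "log_c_std": self.log_c_std,
            "feature_scale": self.feature_scale,
            "lectin_ids": self.lectin_ids,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        spec = ModelSpec(
            fingerprint_dim=manifest["fingerprint_dim"],
            output_dim=manifest["output_dim"],
            hidden_layers=tuple(manifest["hidden_layers"]),
            seed=manifest["seed"],
        )
        data = np.load(directory / "weights.npz")
        n_layers = len(spec.hidden_layers) + 1
        return cls(
            spec=spec,
            weights=[data[f"w{i}"] for i in range(n_layers)],
            biases=[data[f"b{i}"] for i in range(n_layers)],
            log_c_mean=manifest["log_c_mean"],
            log_c_std=manifest["log_c_std"],
            feature_scale=manifest["feature_scale"],
            lectin_ids=manifest["lectin_ids"],
        )


def assign_folds(
    molecule_ids: list[str],
    k: int = 10,
    seed: int = 0,
    group_keys: list[str] | None = None,
) -> FoldAssignment:
    """Grouped, balanced fold assignment.

    Molecules sharing a structure key (canonical SMILES by default the
    caller's choice) are dealt to folds as one unit, round-robin after a
    seeded shuffle, so fold sizes differ by at most one group.
    """
    if k < 2:
        raise ValueError("k must be ≥ 2")
    if group_keys is None:
        group_keys = list(molecule_ids)
    if len(group_keys) != len(molecule_ids):
        raise ValueError("group_keys length mismatch")
    groups: dict[str, list[str]] = {}
    for mid, key in zip(molecule_ids, group_keys):
        groups.setdefault(key, []).append(mid)
    if len(groups) < k:
        raise ValueError(f"only {len(groups)} structure groups for {k} folds")
    keys = sorted(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    assignment: dict[str, int] = {}
    for i, key in enumerate(keys):
        for mid in groups[key]:
            assignment[mid] = i % k
    return FoldAssignment(assignment=assignment, k=k)


def build_model(spec: ModelSpec) -> TrainedModel:
    """Initialize an untrained network (Glorot weights, seeded)."""
    rng = np.random.default_rng(spec.seed)
    dims = [spec.input_dim, *spec.hidden_layers, spec.output_dim]
    weights, biases = [], []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        limit = np.sqrt(6.0 / (d_in + d_out))
        weights.append(rng.uniform(-limit, limit, size=(d_in, d_out)))
        biases.append(np.zeros(d_out))
    return TrainedModel(spec=spec, weights=weights, biases=biases)


def _flatten_dataset(data: Dataset, molecule_idx: np.ndarray):
    """Rows = (molecule, concentration) pairs with ≥1 observed target."""
    rows_x_mol, rows_c, rows_y, rows_m = [], [], [], []
    for mi in molecule_idx:
        for ci, c in enumerate(data.concentrations):
            m = data.mask[mi, ci]
            if m.any():
                rows_x_mol.append(mi)
                rows_c.append(c)
                rows_y.append(data.targets[mi, ci])
                rows_m.append(m)
    if not rows_x_mol:
        return None
    return (
        data.features[np.array(rows_x_mol)].astype(float),
        np.array(rows_c, dtype=float),
        np.array(rows_y, dtype=float),
        np.array(rows_m, dtype=bool),
    )


def masked_mse(pred: np.ndarray, target: np.ndarray, mask: np.ndarray) -> float:
    """MSE over observed entries only."""
    if not mask.any():
        raise ValueError("no observed targets")
    diff = (pred - target)[mask]
    return float(np.mean(diff**2))


def train(
    data: Dataset,
    spec: ModelSpec,
    hp: TrainHyperparams | None = None,
    molecule_idx: np.ndarray | None = None,
) -> TrainedModel:
    """Fit the network with Adam on the masked MSE loss.

    ``molecule_idx`` restricts training to a subset of molecules (used for
    cross-validation and for dataset-subset experiments).  Unobserved
    targets contribute zero gradient, so records observed on only a few
    outputs train exactly as if the model had only those outputs.
    """
    hp = hp or TrainHyperparams()
    if molecule_idx is None:
        molecule_idx = np.arange(len(data.molecule_ids))
    flat = _flatten_dataset(data, molecule_idx)
    if flat is None:
        raise ValueError("no observed targets in the training subset")
    features, conc, targets, mask = flat

    model = build_model(spec)
    model.lectin_ids = list(data.lectin_ids)
    log_c = np.log10(conc)
    model.log_c_mean = float(log_c.mean())
    model.log_c_std = float(log_c.std()) or 1.0
    model.feature_scale = float(max(np.abs(features).max(), 1.0))
    x = model._encode(features, conc)

    params = model.weights + model.biases
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    rng = np.random.default_rng(hp.seed)
    n = x.shape[0]
    n_hidden = len(model.weights) - 1

    for _epoch in range(hp.epochs):
        order = rng.permutation(n)
        for start in range(0, n, hp.batch_size):
            batch = order[start : start + hp.batch_size]
            xb, yb, mb = x[batch], targets[batch], mask[batch]
            out, acts = model._forward(xb, keep=True)
            n_obs = mb.sum()
            if n_obs == 0:
                continue
            # d loss / d out for masked MSE
            delta = np.where(mb, 2.0 * (out - yb) / n_obs, 0.0)
            grads_w = [None] * len(model.weights)
            grads_b = [None] * len(model.biases)
            grads_w[-1] = acts[-1].T @ delta
            grads_b[-1] = delta.sum(axis=0)
            for layer in range(n_hidden - 1, -1, -1):
                delta = (delta @ model.weights[layer + 1].T) * (1.0 - acts[layer + 1] ** 2)
                grads_w[layer] = acts[layer].T @ delta
                grads_b[layer] = delta.sum(axis=0)
            grads = grads_w + grads_b
            # L2 weight decay coupled into the gradient (Adam convention)
            for gi, p in enumerate(params):
                if gi < len(model.weights):
                    grads[gi] = grads[gi] + hp.weight_decay * p
            step += 1
            for p, g, m_, v_ in zip(params, grads, m_t, v_t):
                m_ *= beta1
                m_ += (1 - beta1) * g
                v_ *= beta2
                v_ += (1 - beta2) * g**2
                m_hat = m_ / (1 - beta1**step)
                v_hat = v_ / (1 - beta2**step)
                p -= hp.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
    return model


def predict(model: TrainedModel, fingerprints: np.ndarray, concentrations: np.ndarray) -> np.ndarray:
    """Fractions bound for each lectin output, clamped to [0, 1].

    Raw network outputs are linear and may leave [0, 1]; the clamp is
    applied for reporting.  Monotonicity in concentration is not enforced.
    """
    return np.clip(model.predict_raw(fingerprints, concentrations), 0.0, 1.0)


def evaluate_mse(model: TrainedModel, data: Dataset, molecule_idx: np.ndarray) -> float:
    """Masked MSE of raw predictions over a molecule subset."""
    flat = _flatten_dataset(data, molecule_idx)
    if flat is None:
        raise ValueError("no observed targets in the evaluation subset")
    features, conc, targets, mask = flat
    pred = model.predict_raw(features, conc)
    return masked_mse(pred, targets, mask)


def cross_validate(
    data: Dataset,
    spec: ModelSpec,
    hp: TrainHyperparams | None = None,
    k: int = 10,
    seed: int = 0,
    return_models: bool = False,
):
    """Glycan-grouped k-fold CV; returns per-fold held-out masked MSE.

    Each fold's model is trained on the other k−1 folds with a seed derived
    from (hp.seed, fold) so runs are reproducible.
    """
    hp = hp or TrainHyperparams()
    folds = assign_folds(data.molecule_ids, k=k, seed=seed, group_keys=data.group_keys)
    fold_of = np.array([folds.fold_of(m) for m in data.molecule_ids])
    mses, models = [], []
    for fold in range(k):
        train_idx = np.where(fold_of != fold)[0]
        test_idx = np.where(fold_of == fold)[0]
        fold_spec = ModelSpec(
            fingerprint_dim=spec.fingerprint_dim,
            output_dim=spec.output_dim,
            hidden_layers=spec.hidden_layers,
            seed=spec.seed + fold,
        )
        fold_hp = TrainHyperparams(
            learning_rate=hp.learning_rate,
            weight_decay=hp.weight_decay,
            epochs=hp.epochs,
            batch_size=hp.batch_size,
            seed=hp.seed + fold,
        )
        model = train(data, fold_spec, fold_hp, molecule_idx=train_idx)
        mses.append(evaluate_mse(model, data, test_idx))
        if return_models:
            models.append(model)
    if return_models:
        return mses, folds, models
    return mses, folds
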