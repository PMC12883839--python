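"""Repeated hold-out evaluation, chemometric metrics, and ablation.

The protocol: the labeled dataset is repeatedly split 70/10/20 into
train/validation/test with distinct seeds; per repetition the full pipeline
(optional GAN augmentation of the training rows -> feature extractor ->
regression head) is trained with SGD and evaluated, and metrics are
aggregated as mean +/- SD over the repetitions.

Leakage discipline: spectra are normalized per row (no statistics fitted on
any split), the GAN sees only training rows, and the label grid is built
from training labels only.

Metric conventions (per split, on vectors y and y-hat):
    R^2   = 1 - SS_res / SS_tot
    RMSE  = sqrt(mean squared residual)
    MAE   = mean absolute residual
    RPD   = sample SD of y (ddof=1) / RMSE
    RPIQ  = IQR of y (linear-interpolation quartiles) / RMSE
Across repetitions SDR is reported as the mean of the per-split SD/RMSE
ratios, while the aggregated RPD is the pooled SD over all test rows
divided by the pooled RMSE — two common aggregation conventions for the
same ratio family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .cgan_augment import CGANConfig, augment_training_set, train_cgan
from .darn_regression import (
    DistributionHead,
    LossConfig,
    PointHead,
    SpectralRegressor,
    build_label_grid,
    encode_label_distribution,
)
from .irac_features import IRACConfig, build_irac
from .spectral_core import SpectraSet, max_abs_normalize

__all__ = [
    "SplitPlan",
    "TrainConfig",
    "AblationConfig",
    "ABLATION_TABLE",
    "repeated_holdout_split",
    "compute_metrics",
    "aggregate_metrics",
    "train_cidl",
    "grid_search_sigma_l",
    "sweep_C",
    "run_ablation",
]


@dataclass(frozen=True)
class SplitPlan:
    """One seeded train/validation/test partition of the sample indices."""

    seed: int
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)


@dataclass
class TrainConfig:
    """SGD settings for the regression model.

    Momentum 0.9, batch size 256, dropout 0.2 on fully connected layers,
    initial learning rate 0.05 decayed by 0.1 every 100 epochs with a floor
    of 1e-9; He initialization for convolutional and Glorot for fully
    connected layers (built into the layer constructors). Batches larger
    than the training set degrade to one full batch.
    """

    epochs: int = 300
    lr: float = 0.05
    momentum: float = 0.9
    batch_size: int = 256
    dropout: float = 0.2
    lr_decay: float = 0.1
    lr_step: int = 100
    lr_floor: float = 1e-9
    hidden: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs <= 0:
            raise ValueError("epochs must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class AblationConfig:
    """Component switches: all False is the Baseline, all True the full model."""

    use_cgan: bool = True
    use_acmix: bool = True
    use_darn: bool = True

    def label(self) -> str:
        if not any((self.use_cgan, self.use_acmix, self.use_darn)):
            return "Baseline"
        parts = ["Baseline"]
        if self.use_cgan:
            parts.append("CGAN")
        if self.use_acmix:
            parts.append("ACmix")
        if self.use_darn:
            parts.append("DARN")
        return " + ".join(parts)


#: The eight component combinations of the ablation matrix, in report order.
ABLATION_TABLE: tuple[AblationConfig, ...] = (
    AblationConfig(False, False, False),
    AblationConfig(True, False, False),
    AblationConfig(False, True, False),
    AblationConfig(False, False, True),
    AblationConfig(True, True, False),
    AblationConfig(True, False, True),
    AblationConfig(False, True, True),
    AblationConfig(True, True, True),
)


def repeated_holdout_split(n: int, seeds: list[int]) -> list[SplitPlan]:
    """Seeded 70/10/20 shuffled partitions (floor rounding, remainder to test)."""
    if n < 10:
        raise ValueError("need at least 10 samples to split 70/10/20")
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    n_train = math.floor(0.7 * n)
    n_val = math.floor(0.1 * n)
    plans = []
    for seed in seeds:
        perm = np.random.default_rng(seed).permutation(n)
        plans.append(
            SplitPlan(
                seed=seed,
                train=np.sort(perm[:n_train]),
                val=np.sort(perm[n_train : n_train + n_val]),
                test=np.sort(perm[n_train + n_val :]),
            )
        )
    return plans


def compute_metrics(y: np.ndarray, y_hat: np.ndarray) -> dict[str, float]:
    """Chemometric metric record for one split (see module docstring)."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size == 0 or y.shape != y_hat.shape:
        raise ValueError("y and y_hat must be equal-length nonempty vectors")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero variance in reference values; R2/RPD undefined")
    resid = y - y_hat
    ss_res = float(np.sum(resid**2))
    rmse = float(np.sqrt(ss_res / y.size))
    sd = float(np.std(y, ddof=1))
    q1, q3 = np.percentile(y, [25, 75])  # linear-interpolation quartiles
    iqr = float(q3 - q1)
    if rmse == 0:
        rpd = rpiq = float("inf")
    else:
        rpd = sd / rmse
        rpiq = iqr / rmse
    return {
        "r2": 1.0 - ss_res / ss_tot,
        "rmse": rmse,
        "mae": float(np.mean(np.abs(resid))),
        "sd": sd,
        "iqr": iqr,
        "rpd": rpd,
        "rpiq": rpiq,
        "n": int(y.size),
        "ss_res": ss_res,
    }


def aggregate_metrics(records: list[dict[str, float]]) -> dict[str, float]:
    """Mean +/- SD over repetitions, plus pooled-ratio metrics.

    SDR = mean over splits of SD(y)/RMSE; RPD = pooled SD / pooled RMSE
    (pooled RMSE from the summed squared residuals over all test rows).
    """
    out: dict[str, float] = {}
    for key in ("r2", "rmse", "mae", "rpd", "rpiq"):
        vals = np.array([r[key] for r in records], dtype=float)
        out[f"{key}_mean"] = float(vals.mean())
        out[f"{key}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    out["sdr_mean"] = out["rpd_mean"]
    sdr_vals = np.array([r["rpd"] for r in records])
    out["sdr_sd"] = float(sdr_vals.std(ddof=1)) if len(sdr_vals) > 1 else 0.0
    total_n = sum(r["n"] for r in records)
    pooled_rmse = float(np.sqrt(sum(r["ss_res"] for r in records) / total_n))
    pooled_sd = float(np.mean([r["sd"] for r in records]))
    out["rpd_pooled"] = pooled_sd / pooled_rmse if pooled_rmse > 0 else float("inf")
    out["n_reps"] = len(records)
    return out


def _minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    bs = min(batch_size, n)
    for start in range(0, n, bs):
        yield order[start : start + bs]


def train_cidl(
    dataset: SpectraSet,
    split: SplitPlan,
    ablation: AblationConfig = AblationConfig(),
    tcfg: TrainConfig | None = None,
    icfg: IRACConfig | None = None,
    dcfg: LossConfig | None = None,
    ccfg: CGANConfig | None = None,
    grid_l: float = 0.15,
) -> tuple[SpectralRegressor, dict]:
    """Train one model on one split and evaluate on train/val/test.

    Pipeline: row-wise max-abs normalization -> optional GAN augmentation of
    the training rows -> feature extractor (dual-path blocks per the
    ablation flag) -> distribution head with the combined KL+MSE objective,
    or a plain point head with MSE when the distribution component is
    ablated -> SGD with the configured schedule. Returns the model and a
    record with per-subset metric dicts.
    """
    if not dataset.is_labeled:
        raise ValueError("training requires Psi labels")
    tcfg = tcfg or TrainConfig()
    icfg = icfg or IRACConfig()
    dcfg = dcfg or LossConfig()
    ccfg = ccfg or CGANConfig()
    if icfg.seq_len != dataset.grid.n_bands:
        raise ValueError(
            f"extractor expects {icfg.seq_len} bands, dataset has {dataset.grid.n_bands}"
        )

    norm = SpectraSet(
        grid=dataset.grid,
        spectra=max_abs_normalize(dataset.spectra, axis=-1),
        psi=dataset.psi,
        sample_ids=list(dataset.sample_ids),
        provenance=list(dataset.provenance),
    )
    train_set = norm.subset(split.train)

    if ablation.use_cgan and ccfg.n_synthetic > 0:
        bundle = train_cgan(train_set, replace(ccfg, seed=ccfg.seed + split.seed))
        train_set = augment_training_set(train_set, bundle)

    # label grid from *training* labels only, padded by 3 sigma
    grid = build_label_grid(
        float(norm.psi[split.train].min()) - 3 * dcfg.sigma,
        float(norm.psi[split.train].max()) + 3 * dcfg.sigma,
        grid_l,
    )

    rng = np.random.default_rng(tcfg.seed + split.seed)
    extractor = build_irac(
        replace(icfg, acmix_enabled=ablation.use_acmix), seed=tcfg.seed + split.seed + 1
    )
    head_rng = np.random.default_rng(tcfg.seed + split.seed + 2)
    if ablation.use_darn:
        head = DistributionHead(
            icfg.feature_dim, grid.k, head_rng, hidden=tcfg.hidden, dropout=tcfg.dropout
        )
    else:
        head = PointHead(
            icfg.feature_dim, head_rng, hidden=tcfg.hidden, dropout=tcfg.dropout
        )
    model = SpectralRegressor(extractor, head, grid if ablation.use_darn else None)

    X = train_set.spectra
    y = train_set.psi
    targets = encode_label_distribution(y, grid, dcfg.sigma) if ablation.use_darn else None
    centers_t = nn.Tensor(grid.centers)
    params = model.parameters()
    opt = nn.SGD(params, lr=tcfg.lr, momentum=tcfg.momentum)
    loss_trace: list[float] = []

    model.train()
    for epoch in range(tcfg.epochs):
        opt.lr = max(tcfg.lr * tcfg.lr_decay ** (epoch // tcfg.lr_step), tcfg.lr_floor)
        epoch_losses = []
        for idx in _minibatches(len(y), tcfg.batch_size, rng):
            xb = nn.Tensor(X[idx][:, None, :])
            out = model(xb)
            if ablation.use_darn:
                p = nn.Tensor(targets[idx])
                ratio = (p + dcfg.epsilon) / (out + dcfg.epsilon)
                ld = (p * ratio.log()).sum(axis=1).mean()
                y_hat = (out * centers_t).sum(axis=1)
                reg = ((nn.Tensor(y[idx]) - y_hat) ** 2.0).mean()
                loss = dcfg.C * reg + ld
            else:
                y_hat = out.reshape(-1)
                loss = ((nn.Tensor(y[idx]) - y_hat) ** 2.0).mean()
            if dcfg.eta > 0:
                penalty = None
                for prm in params:
                    term = (prm**2.0).sum()
                    penalty = term if penalty is None else penalty + term
                loss = loss + dcfg.eta * penalty
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        loss_trace.append(float(np.mean(epoch_losses)))

    # refresh BN running stats on the final parameters for clean inference
    nn.reestimate_batchnorm(model, lambda: model(nn.Tensor(X[:, None, :])))
    model.eval()
    record = {
        "ablation": ablation,
        "split_seed": split.seed,
        "loss_trace": loss_trace,
        "label_grid_k": grid.k,
    }
    for name, idx in (("train", split.train), ("val", split.val), ("test", split.test)):
        pred = model.predict(norm.subset(idx), normalize=False)
        record[name] = compute_metrics(norm.psi[idx], pred)
    return model, record


def _mean_val_r2(
    dataset: SpectraSet,
    plans: list[SplitPlan],
    ablation: AblationConfig,
    tcfg: TrainConfig,
    icfg: IRACConfig,
    dcfg: LossConfig,
    ccfg: CGANConfig,
    grid_l: float,
) -> tuple[float, list[float]]:
    vals = []
    for plan in plans:
        _, rec = train_cidl(dataset, plan, ablation, tcfg, icfg, dcfg, ccfg, grid_l)
        vals.append(rec["val"]["r2"])
    return float(np.mean(vals)), vals


def grid_search_sigma_l(
    dataset: SpectraSet,
    seeds: list[int],
    sigma_grid: list[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
    l_grid: list[float] = (0.05, 0.1, 0.15, 0.2, 0.25),
    ablation: AblationConfig = AblationConfig(),
    tcfg: TrainConfig | None = None,
    icfg: IRACConfig | None = None,
    ccfg: CGANConfig | None = None,
) -> tuple[tuple[float, float], pd.DataFrame]:
    """Mean validation R^2 per (sigma, l) cell with C fixed at 1.

    Returns the argmax pair and the full matrix (rows l, columns sigma) for
    a heat map.
    """
    if not sigma_grid or not l_grid:
        raise ValueError("sigma and l grids must be nonempty")
    plans = repeated_holdout_split(dataset.n_samples, seeds)
    matrix = pd.DataFrame(index=list(l_grid), columns=list(sigma_grid), dtype=float)
    best, best_pair = -np.inf, None
    for l in l_grid:
        for sigma in sigma_grid:
            dcfg = LossConfig(sigma=sigma, C=1.0)
            mean_r2, _ = _mean_val_r2(
                dataset, plans, ablation, tcfg or TrainConfig(), icfg or IRACConfig(),
                dcfg, ccfg or CGANConfig(), grid_l=l,
            )
            matrix.loc[l, sigma] = mean_r2
            if mean_r2 > best:
                best, best_pair = mean_r2, (sigma, l)
    return best_pair, matrix


def sweep_C(
    dataset: SpectraSet,
    seeds: list[int],
    C_grid: list[float] = (0, 1, 2, 3, 4, 5, 6),
    sigma: float = 0.4,
    grid_l: float = 0.15,
    ablation: AblationConfig = AblationConfig(),
    tcfg: TrainConfig | None = None,
    icfg: IRACConfig | None = None,
    ccfg: CGANConfig | None = None,
) -> tuple[float, pd.DataFrame]:
    """Mean (and per-seed SD) validation R^2 per regression-loss coefficient C,
    at fixed (sigma, l); returns the argmax C and the curve."""
    if len(C_grid) == 0:
        raise ValueError("C grid must be nonempty")
    plans = repeated_holdout_split(dataset.n_samples, seeds)
    rows = []
    for C in C_grid:
        dcfg = LossConfig(sigma=sigma, C=float(C))
        mean_r2, vals = _mean_val_r2(
            dataset, plans, ablation, tcfg or TrainConfig(), icfg or IRACConfig(),
            dcfg, ccfg or CGANConfig(), grid_l=grid_l,
        )
        rows.append(
            {
                "C": float(C),
                "val_r2_mean": mean_r2,
                "val_r2_sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            }
        )
    curve = pd.DataFrame(rows)
    best_C = float(curve.loc[curve["val_r2_mean"].idxmax(), "C"])
    return best_C, curve


def run_ablation(
    dataset: SpectraSet,
    seeds: list[int],
    tcfg: TrainConfig | None = None,
    icfg: IRACConfig | None = None,
    dcfg: LossConfig | None = None,
    ccfg: CGANConfig | None = None,
    grid_l: float = 0.15,
) -> pd.DataFrame:
    """Paired ablation: the eight component combinations on shared splits.

    Returns a DataFrame with one row per configuration (test R^2
    mean +/- SD and the component flags), splits identical across rows so
    differences are attributable to the components.
    """
    plans = repeated_holdout_split(dataset.n_samples, seeds)
    rows = []
    for ab in ABLATION_TABLE:
        r2s = []
        for plan in plans:
            _, rec = train_cidl(dataset, plan, ab, tcfg, icfg, dcfg, ccfg, grid_l)
            r2s.append(rec["test"]["r2"])
        rows.append(
            {
                "configuration": ab.label(),
                "use_cgan": ab.use_cgan,
                "use_acmix": ab.use_acmix,
                "use_darn": ab.use_darn,
                "test_r2_mean": float(np.mean(r2s)),
                "test_r2_sd": float(np.std(r2s, ddof=1)) if len(r2s) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
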