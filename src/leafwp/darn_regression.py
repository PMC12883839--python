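"""Distribution-aware regression of leaf water potential.

Instead of pointwise regression, the scalar target y (Psi_leaf, MPa) is
encoded as a probability vector over a discretized label axis: the axis
[lo, hi] is cut into k intervals of length l with centers l_k, and the
target distribution is a Gaussian kernel of width sigma evaluated at the
centers and renormalized,

    p_k  proportional to  exp(-(l_k - y)^2 / (2 sigma^2)).

The network emits a softmax distribution p-hat over the same bins; training
minimizes a mean KL divergence between target and predicted distributions,

    L_ld = (1/B) sum_i sum_k p_k ln(p_k / p-hat_k),

plus a mean-squared-error term on the decoded expectation

    y-hat = sum_k p-hat_k l_k,        L_reg = (1/B) sum_i (y_i - y-hat_i)^2,

combined as  L_total = C * L_reg + L_ld + eta * sum(theta^2).  The soft
encoding spreads supervision over neighbouring bins, which stabilizes
learning on imbalanced targets; the MSE term corrects the small bias the
discrete expectation introduces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .spectral_core import SpectraSet, max_abs_normalize

__all__ = [
    "LabelGrid",
    "LossConfig",
    "build_label_grid",
    "encode_label_distribution",
    "kl_loss",
    "expectation_decode",
    "regression_loss",
    "total_loss",
    "DistributionHead",
    "PointHead",
    "SpectralRegressor",
    "predict",
]


@dataclass(frozen=True)
class LabelGrid:
    """Discretized label axis: k intervals of length l covering [lo, hi]."""

    lo: float
    hi: float
    l: float
    centers: np.ndarray

    @property
    def k(self) -> int:
        return int(self.centers.size)


@dataclass
class LossConfig:
    """Hyperparameters of the distribution-aware objective (MPa scale).

    sigma is the Gaussian label-smoothing width, C the coefficient of the
    regression (expectation) loss, eta the L2 penalty weight and epsilon the
    clamp applied to predicted probabilities inside the logarithm.
    """

    sigma: float = 0.4
    C: float = 1.0
    eta: float = 1e-6
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.C < 0 or self.eta < 0:
            raise ValueError("C and eta must be >= 0")


def build_label_grid(lo: float, hi: float, l: float) -> LabelGrid:
    """Partition [lo, hi] into k = ceil((hi-lo)/l) intervals of length l.

    Centers are lo + (j + 1/2) l; when l does not divide the range exactly
    the last interval overshoots hi, so every label in [lo, hi] is covered.
    """
    if not lo < hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    if l <= 0:
        raise ValueError("interval length l must be > 0")
    k = int(np.ceil((hi - lo) / l - 1e-12))
    centers = lo + (np.arange(k) + 0.5) * l
    return LabelGrid(lo=lo, hi=hi, l=l, centers=centers)


def encode_label_distribution(
    y: float | np.ndarray, grid: LabelGrid, sigma: float
) -> np.ndarray:
    """Gaussian soft encoding of scalar target(s) over the label grid.

    Returns a probability vector per target (rows sum to one). The Gaussian
    density evaluated on a discrete grid does not sum to one, so the kernel
    values are renormalized — required for the KL objective to compare
    probability vectors.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    y_arr = np.atleast_1d(np.asarray(y, dtype=float))
    z = grid.centers[None, :] - y_arr[:, None]
    logp = -0.5 * (z / sigma) ** 2
    logp -= logp.max(axis=1, keepdims=True)  # stable for sigma << l
    p = np.exp(logp)
    p /= p.sum(axis=1, keepdims=True)
    return p[0] if np.isscalar(y) or np.asarray(y).ndim == 0 else p


def kl_loss(p: np.ndarray, p_hat: np.ndarray, epsilon: float = 1e-12) -> float:
    """Batch-mean KL divergence (1/B) sum_i sum_k p ln(p / p_hat).

    p_hat is clamped below at epsilon; terms with p_k = 0 contribute zero.
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    p_hat = np.atleast_2d(np.asarray(p_hat, dtype=float))
    if p.shape != p_hat.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {p_hat.shape}")
    q = np.clip(p_hat, epsilon, None)
    terms = np.where(p > 0, p * np.log(np.clip(p, epsilon, None) / q), 0.0)
    return float(terms.sum(axis=1).mean())


def expectation_decode(p_hat: np.ndarray, grid: LabelGrid) -> float | np.ndarray:
    """Decode distribution(s) to scalar prediction(s): y-hat = sum_k p_hat_k l_k."""
    p = np.atleast_2d(np.asarray(p_hat, dtype=float))
    if p.shape[1] != grid.k:
        raise ValueError(f"distribution length {p.shape[1]} != grid bins {grid.k}")
    sums = p.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("label distribution rows must sum to 1")
    out = p @ grid.centers
    return float(out[0]) if np.asarray(p_hat).ndim == 1 else out


def regression_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Batch-mean squared error (1/B) sum_i (y_i - y-hat_i)^2."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty batch")
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.size} vs {y_hat.size}")
    return float(np.mean((y - y_hat) ** 2))


def total_loss(
    reg: float, ld: float, params: list[np.ndarray], cfg: LossConfig
) -> float:
    """Combined objective C * L_reg + L_ld + eta * sum(theta^2)."""
    penalty = sum(float(np.sum(p**2)) for p in params)
    return cfg.C * reg + ld + cfg.eta * penalty


# ---------------------------------------------------------------------------
# network heads and the composed regressor
# ---------------------------------------------------------------------------


class DistributionHead(nn.Module):
    """Fully connected head emitting a softmax distribution over label bins.

    A feature-wise batch norm equalizes the flattened extractor features
    (whose per-feature variances differ by orders of magnitude) before the
    fully connected stack — without it, gradient descent along the
    low-variance but informative directions is impractically slow.
    """

    def __init__(
        self,
        feature_dim: int,
        k: int,
        rng: np.random.Generator,
        hidden: int = 64,
        dropout: float = 0.2,
    ):
        super().__init__()
        self.feat_bn = nn.BatchNorm1d(feature_dim)
        self.fc1 = nn.Linear(feature_dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, k, rng)
        self.dropout = dropout
        self._rng = rng

    def forward(self, features: nn.Tensor) -> nn.Tensor:
        h = self.fc1(self.feat_bn(features)).relu()
        h = nn.dropout(h, self.dropout, self._rng, self.training)
        return nn.softmax(self.fc2(h), axis=-1)


class PointHead(nn.Module):
    """Plain fully connected regression head (single scalar output)."""

    def __init__(
        self,
        feature_dim: int,
        rng: np.random.Generator,
        hidden: int = 64,
        dropout: float = 0.2,
    ):
        super().__init__()
        self.feat_bn = nn.BatchNorm1d(feature_dim)
        self.fc1 = nn.Linear(feature_dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, 1, rng)
        self.dropout = dropout
        self._rng = rng

    def forward(self, features: nn.Tensor) -> nn.Tensor:
        h = self.fc1(self.feat_bn(features)).relu()
        h = nn.dropout(h, self.dropout, self._rng, self.training)
        return self.fc2(h)


class SpectralRegressor(nn.Module):
    """Feature extractor plus head; predicts Psi_leaf (MPa) from spectra.

    With a :class:`DistributionHead` the forward pass returns bin
    probabilities and predictions are decoded expectations (always inside
    [min center, max center]); with a :class:`PointHead` it returns the
    scalar directly.
    """

    def __init__(self, extractor: nn.Module, head: nn.Module, grid: LabelGrid | None):
        super().__init__()
        self.extractor = extractor
        self.head = head
        self.grid = grid
        if isinstance(head, DistributionHead) and grid is None:
            raise ValueError("a DistributionHead requires a LabelGrid")

    @property
    def distributional(self) -> bool:
        return self.grid is not None

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.head(self.extractor(x))

    def predict(self, spectra: np.ndarray | SpectraSet, normalize: bool = True) -> np.ndarray:
        """Deterministic inference: spectra (n, n_bands) -> Psi in MPa."""
        x = spectra.spectra if isinstance(spectra, SpectraSet) else np.asarray(spectra)
        if normalize:
            x = max_abs_normalize(x, axis=-1)
        was_training = self.training
        self.eval()
        out = self.forward(nn.Tensor(x[:, None, :]))
        if was_training:
            self.train()
        if self.distributional:
            return np.asarray(expectation_decode(out.data, self.grid))
        return out.data.ravel()


def predict(model: SpectralRegressor, spectra: np.ndarray | SpectraSet) -> np.ndarray:
    """Functional alias for :meth:`SpectralRegressor.predict`."""
    return model.predict(spectra)
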