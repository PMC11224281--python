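"""A small capsule network trained by derivative-free optimization.

The network follows the classic capsule design: a single convolutional
feature layer (tanh), a reshape into *primary capsules* whose activity
vectors are squashed, per-pair linear prediction maps
``û_{j|i} = W_{ij} x_i`` into *class capsules*, and dynamic
routing-by-agreement.  The length ``‖v_j‖ ∈ [0, 1)`` of each class
capsule's output vector is read as the probability that class ``j`` is
present; training minimises the margin loss.

There is no backpropagation anywhere: all weights and biases live in a
single flat parameter vector that a box-constrained metaheuristic (the
osprey optimizer) searches directly.  The default architecture is kept
tiny (a few thousand parameters) so that derivative-free search is
feasible; a hard cap rejects architectures too large to train this way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optimizer import OptimizationResult, OptimizerConfig, SearchSpace, run

__all__ = [
    "CapsNetArchitecture",
    "ParameterVector",
    "RoutingState",
    "MarginLossParams",
    "squash",
    "coupling_coefficients",
    "dynamic_routing",
    "forward",
    "forward_batch",
    "margin_loss",
    "fitness",
    "FitnessEvaluator",
    "train_with_optimizer",
    "predict",
]

PARAMETER_CAP = 20_000


@dataclass(frozen=True)
class CapsNetArchitecture:
    """Shape hyper-parameters of the tiny capsule network.

    The conv layer uses valid padding; its flattened output must divide
    evenly into primary capsules of ``primary_dim`` coordinates.
    """

    input_height: int = 16
    input_width: int = 16
    input_channels: int = 1
    conv_filters: int = 4
    conv_kernel: int = 3
    conv_stride: int = 2
    primary_dim: int = 4
    class_caps: int = 2
    class_dim: int = 8
    routing_iterations: int = 3

    def __post_init__(self):
        for name in ("input_height", "input_width", "input_channels",
                     "conv_filters", "conv_kernel", "conv_stride",
                     "primary_dim", "class_caps", "class_dim",
                     "routing_iterations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.conv_out_height < 1 or self.conv_out_width < 1:
            raise ValueError("conv kernel/stride too large for the input")
        n_feat = self.conv_out_height * self.conv_out_width * self.conv_filters
        if n_feat % self.primary_dim != 0:
            raise ValueError(
                f"conv output size {n_feat} is not divisible by "
                f"primary_dim={self.primary_dim}"
            )

    @property
    def conv_out_height(self) -> int:
        return (self.input_height - self.conv_kernel) // self.conv_stride + 1

    @property
    def conv_out_width(self) -> int:
        return (self.input_width - self.conv_kernel) // self.conv_stride + 1

    @property
    def primary_caps(self) -> int:
        return (self.conv_out_height * self.conv_out_width
                * self.conv_filters) // self.primary_dim

    @property
    def segment_shapes(self) -> dict:
        """Ordered parameter segments: conv weights/biases, capsule transforms/biases."""
        k, c, f = self.conv_kernel, self.input_channels, self.conv_filters
        return {
            "conv_weights": (f, k, k, c),
            "conv_biases": (f,),
            "caps_weights": (self.primary_caps, self.class_caps,
                             self.class_dim, self.primary_dim),
            "caps_biases": (self.class_caps, self.class_dim),
        }

    @property
    def parameter_count(self) -> int:
        return sum(int(np.prod(s)) for s in self.segment_shapes.values())


@dataclass(frozen=True)
class ParameterVector:
    """Flat parameter vector with its packing layout."""

    values: np.ndarray
    arch: CapsNetArchitecture

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float).ravel()
        if values.size != self.arch.parameter_count:
            raise ValueError(
                f"expected {self.arch.parameter_count} parameters, got {values.size}"
            )
        object.__setattr__(self, "values", values)

    def unpack(self) -> dict:
        """Split the flat vector into named, shaped tensors."""
        out, offset = {}, 0
        for name, shape in self.arch.segment_shapes.items():
            n = int(np.prod(shape))
            out[name] = self.values[offset:offset + n].reshape(shape)
            offset += n
        return out

    @classmethod
    def pack(cls, segments: dict, arch: CapsNetArchitecture) -> "ParameterVector":
        parts = [np.asarray(segments[name], dtype=float).ravel()
                 for name in arch.segment_shapes]
        return cls(np.concatenate(parts), arch)


@dataclass
class RoutingState:
    """Intermediate quantities of the final routing round."""

    b: np.ndarray        # log priors, (..., P, J)
    c: np.ndarray        # coupling coefficients, rows over J sum to 1
    u_hat: np.ndarray    # prediction vectors, (..., P, J, D)
    s: np.ndarray        # pre-squash class vectors, (..., J, D)
    v: np.ndarray        # output class vectors, (..., J, D)


@dataclass(frozen=True)
class MarginLossParams:
    m_plus: float = 0.9
    m_minus: float = 0.1
    lam: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.m_minus < self.m_plus < 1.0:
            raise ValueError("need 0 < m_minus < m_plus < 1")
        if self.lam < 0.0:
            raise ValueError("lambda must be non-negative")


# ---------------------------------------------------------------------------
# capsule primitives
# ---------------------------------------------------------------------------

def squash(s: np.ndarray, axis: int = -1) -> np.ndarray:
    """``v = (‖s‖² / (1 + ‖s‖²)) · s/‖s‖``; the zero vector maps to zero."""
    sq = np.sum(np.square(s), axis=axis, keepdims=True)
    norm = np.sqrt(sq)
    scale = np.where(norm > 0.0, sq / ((1.0 + sq) * np.where(norm > 0, norm, 1.0)), 0.0)
    return s * scale


def coupling_coefficients(b: np.ndarray) -> np.ndarray:
    """Row-wise softmax of routing logits over the class axis (last)."""
    z = b - np.max(b, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=-1, keepdims=True)


def dynamic_routing(u_hat: np.ndarray, iterations: int,
                    bias: np.ndarray | None = None):
    """Routing by agreement between primary and class capsules.

    ``u_hat`` has shape ``(..., P, J, D)``.  Log priors start at zero;
    each round computes couplings by softmax, the coupled sum
    ``s_j = Σ_i c_ij û_{j|i}`` (plus the optional per-class bias),
    squashes it, and increments the priors by the agreement
    ``û_{j|i} · v_j``.  Returns the class vectors ``v`` of shape
    ``(..., J, D)`` and the final :class:`RoutingState`.
    """
    if iterations < 1:
        raise ValueError("routing needs at least one iteration")
    # work in (..., J, P, D) layout so both contractions are matmuls
    U = np.swapaxes(u_hat, -3, -2)
    bt = np.zeros(U.shape[:-1])  # logits, (..., J, P)
    for _ in range(iterations):
        z = bt - bt.max(axis=-2, keepdims=True)  # softmax over classes J
        e = np.exp(z)
        ct = e / e.sum(axis=-2, keepdims=True)
        s = np.matmul(ct[..., None, :], U)[..., 0, :]  # s_j = Σ_i c_ij û_{j|i}
        if bias is not None:
            s = s + bias
        v = squash(s)
        at = np.matmul(U, v[..., None])[..., 0]  # agreement û·v
        bt = bt + at
    state = RoutingState(b=np.swapaxes(bt, -1, -2), c=np.swapaxes(ct, -1, -2),
                         u_hat=u_hat, s=s, v=v)
    return v, state


def margin_loss(lengths: np.ndarray, target: np.ndarray,
                p: MarginLossParams = MarginLossParams()) -> float:
    """Hinge-squared class-presence loss, summed over classes.

    ``L = Σ_c T_c·max(0, m₊−‖v_c‖)² + λ(1−T_c)·max(0, ‖v_c‖−m₋)²``
    for a one-hot target ``T``; batched inputs return the mean over the
    leading axes.
    """
    lengths = np.asarray(lengths, dtype=float)
    target = np.asarray(target, dtype=float)
    pos = np.maximum(0.0, p.m_plus - lengths) ** 2
    neg = np.maximum(0.0, lengths - p.m_minus) ** 2
    per_sample = np.sum(target * pos + p.lam * (1.0 - target) * neg, axis=-1)
    return float(np.mean(per_sample))


def predict(lengths: np.ndarray) -> np.ndarray:
    """Class with the longest output vector; lowest index on ties."""
    return np.argmax(np.asarray(lengths), axis=-1)


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

def _extract_patches(images: np.ndarray, arch: CapsNetArchitecture) -> np.ndarray:
    """im2col: (B, H, W, C) -> (B, S, k*k*C) for the valid-padding conv."""
    k, st = arch.conv_kernel, arch.conv_stride
    win = np.lib.stride_tricks.sliding_window_view(images, (k, k), axis=(1, 2))
    win = win[:, ::st, ::st]  # (B, oh, ow, C, k, k)
    B, oh, ow = win.shape[:3]
    # order (k, k, C) to match the conv_weights layout
    win = np.moveaxis(win, 3, -1)
    return np.ascontiguousarray(win).reshape(B, oh * ow, k * k * arch.input_channels)


def _forward_from_patches(patches: np.ndarray, params: ParameterVector):
    """Shared tail of the forward pass; returns (lengths, v, state)."""
    arch = params.arch
    seg = params.unpack()
    k, c = arch.conv_kernel, arch.input_channels
    w = seg["conv_weights"].reshape(arch.conv_filters, k * k * c)
    feat = np.tanh(patches @ w.T + seg["conv_biases"])  # (B, S, F)
    B = feat.shape[0]
    x = feat.reshape(B, arch.primary_caps, arch.primary_dim)
    x = squash(x)
    # û_{j|i} = W_ij x_i, batched:  (P, J*D, Dp) @ (B, P, Dp, 1)
    P, J, D, Dp = (arch.primary_caps, arch.class_caps,
                   arch.class_dim, arch.primary_dim)
    W = seg["caps_weights"].reshape(P, J * D, Dp)
    u_hat = np.matmul(W, x[..., None]).reshape(B, P, J, D)
    v, state = dynamic_routing(u_hat, arch.routing_iterations,
                               bias=seg["caps_biases"])
    lengths = np.linalg.norm(v, axis=-1)
    return lengths, v, state


def forward_batch(images: np.ndarray, params: ParameterVector) -> np.ndarray:
    """Class-vector lengths for a batch of images, shape (B, class_caps)."""
    arch = params.arch
    images = np.asarray(images, dtype=float)
    if images.ndim == 3:
        images = images[..., None]
    expected = (arch.input_height, arch.input_width, arch.input_channels)
    if images.shape[1:] != expected:
        raise ValueError(f"expected images of shape {expected}, got {images.shape[1:]}")
    patches = _extract_patches(images, arch)
    lengths, _, _ = _forward_from_patches(patches, params)
    return lengths


def forward(image: np.ndarray, params: ParameterVector,
            return_state: bool = False):
    """Class-vector lengths ``‖v_j‖`` for one image (values in [0, 1))."""
    arch = params.arch
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = image[..., None]
    expected = (arch.input_height, arch.input_width, arch.input_channels)
    if image.shape != expected:
        raise ValueError(f"expected image of shape {expected}, got {image.shape}")
    patches = _extract_patches(image[None], arch)
    lengths, v, state = _forward_from_patches(patches, params)
    if return_state:
        return lengths[0], state
    return lengths[0]


# ---------------------------------------------------------------------------
# training objective
# ---------------------------------------------------------------------------

class FitnessEvaluator:
    """Mean margin loss over a fixed dataset as a flat-vector objective.

    Precomputes the im2col patches once, so repeated calls (tens of
    thousands during a metaheuristic run) only pay for the parameter-
    dependent part of the forward pass.  Full-batch and deterministic,
    so greedy acceptance in the optimizer is well-defined.
    """

    def __init__(self, images: np.ndarray, labels: np.ndarray,
                 arch: CapsNetArchitecture,
                 loss_params: MarginLossParams = MarginLossParams()):
        images = np.asarray(images, dtype=float)
        labels = np.asarray(labels, dtype=int)
        if images.shape[0] == 0:
            raise ValueError("dataset must be non-empty")
        if images.shape[0] != labels.shape[0]:
            raise ValueError("images and labels disagree in length")
        if images.ndim == 3:
            images = images[..., None]
        self.arch = arch
        self.loss_params = loss_params
        self.labels = labels
        self.patches = _extract_patches(images, arch)
        self.targets = np.eye(arch.class_caps)[labels]

    def __call__(self, theta: np.ndarray) -> float:
        params = ParameterVector(theta, self.arch)
        lengths, _, _ = _forward_from_patches(self.patches, params)
        return margin_loss(lengths, self.targets, self.loss_params)

    def lengths(self, theta: np.ndarray) -> np.ndarray:
        params = ParameterVector(theta, self.arch)
        lengths, _, _ = _forward_from_patches(self.patches, params)
        return lengths

    def accuracy(self, theta: np.ndarray) -> float:
        return float(np.mean(predict(self.lengths(theta)) == self.labels))


def fitness(params: ParameterVector, images: np.ndarray, labels: np.ndarray,
            loss_params: MarginLossParams = MarginLossParams()) -> float:
    """Mean margin loss of ``params`` over the labeled image set."""
    ev = FitnessEvaluator(images, labels, params.arch, loss_params)
    return ev(params.values)


def train_with_optimizer(
    arch: CapsNetArchitecture,
    images: np.ndarray,
    labels: np.ndarray,
    optimizer_config: OptimizerConfig,
    weight_bound: float = 1.0,
    loss_params: MarginLossParams = MarginLossParams(),
) -> tuple[ParameterVector, OptimizationResult]:
    """Fit all network parameters by minimising margin loss with OOA/MOP.

    The search space is the cube ``[-weight_bound, weight_bound]^n`` over
    the flat parameter vector.  Architectures above ``PARAMETER_CAP``
    parameters are rejected: derivative-free search does not scale to
    them, use a smaller architecture.
    """
    n = arch.parameter_count
    if n > PARAMETER_CAP:
        raise ValueError(
            f"architecture has {n} parameters, above the cap of "
            f"{PARAMETER_CAP} for derivative-free training; "
            "use a smaller architecture"
        )
    objective = FitnessEvaluator(images, labels, arch, loss_params)
    space = SearchSpace.cube(-weight_bound, weight_bound, n)
    result = run(objective, space, optimizer_config)
    return ParameterVector(result.best_position, arch), result
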