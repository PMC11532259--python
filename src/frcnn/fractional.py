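"""Generalized fractional stochastic gradient descent (GFSGD).

The optimizer replaces the ordinary gradient in the SGD update with a
Caputo fractional derivative of order ``alpha``, truncated by the short
memory principle to the single previous iterate (fixed memory length 1)
and to the first term of its Taylor-series expansion.  The resulting
per-coordinate update is

    x_new = x - lr * g * (|x - x_prev| + eps)**(1 - alpha) / Gamma(2 - alpha)

which reduces exactly to plain SGD at ``alpha = 1``.  Taking the absolute
value of the iterate difference keeps the power real and extends the
admissible fractional order to ``0 < alpha < 2``; the small stabilizer
``eps`` guards the ``x == x_prev`` case.

Besides the optimizer, this module exposes the closed-form Caputo
derivative of monomials and the Taylor-series expansion of the Caputo
integral, which serve as analytic oracles for the truncation used in the
update rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "FractionalConfig",
    "OptimizerState",
    "CaputoQuery",
    "GFSGD",
    "gamma_fn",
    "fractional_scale",
    "gfsgd_update",
    "caputo_truncated",
    "caputo_monomial_closed_form",
    "caputo_series",
]

FIRST_STEP_MODES = ("plain_sgd", "epsilon_power")


def gamma_fn(z: float) -> float:
    """Gamma function restricted to the positive real axis.

    Parameters
    ----------
    z : float
        Argument, must be ``> 0``.

    Returns
    -------
    float
        ``Gamma(z)``, accurate to at least 10 significant digits.
    """
    if not z > 0:
        raise ValueError(f"gamma_fn requires z > 0, got {z!r}")
    return float(special.gamma(z))


@dataclass(frozen=True)
class FractionalConfig:
    """Hyperparameters of the fractional update rule.

    Attributes
    ----------
    alpha : float
        Fractional order, strictly inside ``(0, 2)``.  ``alpha = 1``
        recovers plain gradient descent; ``alpha > 1`` amplifies the
        step when successive iterates are close (|diff| < 1).
    learning_rate : float
        Step size ``lr > 0``.
    epsilon : float
        Stabilizer added to ``|x - x_prev|`` before the power, default 1e-8.
    first_step_mode : str
        How to treat the very first update, where no previous iterate
        exists.  ``"plain_sgd"`` (default) uses scale factor 1;
        ``"epsilon_power"`` initializes the previous iterate to the
        current parameters, so the scale becomes ``eps**(1-alpha) /
        Gamma(2-alpha)`` — which is explosive for ``alpha > 1``.
    clip_step : float or None
        Optional elementwise bound on the magnitude of the effective
        step (guards the amplification at ``alpha > 1``).  Default off.
    """

    alpha: float
    learning_rate: float
    epsilon: float = 1e-8
    first_step_mode: str = "plain_sgd"
    clip_step: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 2.0:
            raise ValueError(f"alpha must satisfy 0 < alpha < 2, got {self.alpha}")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if self.first_step_mode not in FIRST_STEP_MODES:
            raise ValueError(
                f"first_step_mode must be one of {FIRST_STEP_MODES}, "
                f"got {self.first_step_mode!r}"
            )

    @property
    def inv_gamma_2_minus_alpha(self) -> float:
        # Gamma(2 - alpha) is update-invariant; evaluated once per config.
        return 1.0 / gamma_fn(2.0 - self.alpha)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "learning_rate": self.learning_rate,
            "epsilon": self.epsilon,
            "first_step_mode": self.first_step_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FractionalConfig":
        return cls(
            alpha=float(d["alpha"]),
            learning_rate=float(d["learning_rate"]),
            epsilon=float(d.get("epsilon", 1e-8)),
            first_step_mode=str(d.get("first_step_mode", "plain_sgd")),
        )


@dataclass
class OptimizerState:
    """Single-previous-iterate memory of the truncated fractional update."""

    previous_params: np.ndarray
    step_count: int = 0


@dataclass(frozen=True)
class CaputoQuery:
    """A Caputo-derivative evaluation request for the monomial g(x) = x**p."""

    exponent: float
    order: float
    eval_point: float
    lower_bound: float = 0.0

    def __post_init__(self) -> None:
        if self.exponent < 0:
            raise ValueError("exponent must be >= 0")
        if not 0.0 < self.order < 1.0:
            raise ValueError("order must lie in (0, 1)")
        if not self.eval_point > self.lower_bound:
            raise ValueError("eval_point must exceed lower_bound")


def fractional_scale(diff_abs, config: FractionalConfig):
    """Per-coordinate gradient scale ``(|dx|+eps)**(1-alpha) / Gamma(2-alpha)``.

    Accepts scalars or arrays; strictly positive; exactly 1 at alpha=1
    (the exponent is exactly 0.0 and Gamma(1) = 1.0 in floating point).
    """
    diff_abs = np.asarray(diff_abs)
    if np.any(diff_abs < 0):
        raise ValueError("diff_abs must be non-negative")
    out = (diff_abs + config.epsilon) ** (1.0 - config.alpha)
    out = out * config.inv_gamma_2_minus_alpha
    if out.ndim == 0:
        return float(out)
    return out


def gfsgd_update(
    params: np.ndarray,
    grads: np.ndarray,
    state: OptimizerState,
    config: FractionalConfig,
) -> tuple[np.ndarray, OptimizerState]:
    """One fractional descent step on a flat parameter vector.

    Elementwise: ``x_new = x - lr * g * scale(|x - x_prev|)``.  The
    returned state stores the pre-update parameters and an incremented
    step counter.  On the first step (``step_count == 0``) with
    ``first_step_mode="plain_sgd"`` the scale factor is 1 everywhere.
    """
    params = np.asarray(params)
    grads = np.asarray(grads)
    if params.shape != grads.shape or params.shape != state.previous_params.shape:
        raise ValueError(
            f"shape mismatch: params {params.shape}, grads {grads.shape}, "
            f"previous_params {state.previous_params.shape}"
        )
    if state.step_count == 0 and config.first_step_mode == "plain_sgd":
        step = config.learning_rate * grads
    else:
        scale = fractional_scale(np.abs(params - state.previous_params), config)
        step = config.learning_rate * grads * scale
    if config.clip_step is not None:
        step = np.clip(step, -config.clip_step, config.clip_step)
    new_params = params - step
    bad = ~np.isfinite(new_params)
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        raise FloatingPointError(
            f"non-finite parameter update at coordinate {idx} "
            f"(alpha={config.alpha}, step_count={state.step_count})"
        )
    new_state = OptimizerState(
        previous_params=params.copy(), step_count=state.step_count + 1
    )
    return new_params, new_state


class GFSGD:
    """Stateful wrapper around :func:`gfsgd_update` for lists of parameter arrays.

    Keeps one :class:`OptimizerState` per parameter array (any shape; the
    update is elementwise) and applies the fractional step in place of
    plain SGD inside a training loop.
    """

    def __init__(self, config: FractionalConfig):
        self.config = config
        self._states: list[OptimizerState] | None = None

    def update(self, params: list[np.ndarray], grads: list[np.ndarray]) -> list[np.ndarray]:
        if self._states is None:
            # prev initialized to current params; under "epsilon_power" the
            # first scale is eps**(1-alpha), under "plain_sgd" it is 1.
            self._states = [OptimizerState(p.copy(), 0) for p in params]
        out = []
        for i, (p, g) in enumerate(zip(params, grads, strict=True)):
            flat_state = OptimizerState(
                self._states[i].previous_params.ravel(), self._states[i].step_count
            )
            new_flat, new_state = gfsgd_update(
                p.ravel(), np.asarray(g).ravel(), flat_state, self.config
            )
            self._states[i] = OptimizerState(
                new_state.previous_params.reshape(p.shape), new_state.step_count
            )
            out.append(new_flat.reshape(p.shape).astype(p.dtype, copy=False))
        return out


def caputo_truncated(
    g1_at_x: float, x: float, x_prev: float, config: FractionalConfig
) -> float:
    """First-term, memory-1 truncation of the Caputo derivative.

    ``g'(x) * (|x - x_prev| + eps)**(1-alpha) / Gamma(2-alpha)`` — the
    quantity the optimizer substitutes for the gradient.  Equals
    ``g1_at_x`` exactly when ``alpha = 1``.
    """
    return float(g1_at_x * fractional_scale(abs(x - x_prev), config))


def caputo_monomial_closed_form(q: CaputoQuery) -> float:
    """Exact Caputo derivative of ``x**p`` of order ``alpha`` on ``[0, x]``.

    ``Gamma(p+1) / Gamma(p+1-alpha) * x**(p-alpha)``; the analytic oracle
    against which the series and its truncation are validated.  Only the
    canonical lower bound 0 has a closed form here.
    """
    if q.lower_bound != 0.0:
        raise NotImplementedError("closed form requires lower_bound == 0")
    if q.exponent < 1:
        raise ValueError("closed form implemented for exponent >= 1")
    p, a, x = q.exponent, q.order, q.eval_point
    return float(
        special.gamma(p + 1) / special.gamma(p + 1 - a) * x ** (p - a)
    )


def _monomial_derivative(p: float, j: int, x: float) -> float:
    """j-th derivative of x**p at x, for integer-valued p (terminating)."""
    if j > p:
        return 0.0
    coeff = 1.0
    for i in range(j):
        coeff *= p - i
    return coeff * x ** (p - j)


def caputo_series(q: CaputoQuery, terms: int) -> float:
    """Partial Taylor-series expansion of the Caputo derivative of ``x**p``.

    Sums ``binom(alpha-n, j-n) * g^(j)(x) / Gamma(j-alpha+1) *
    (x-a)**(j-alpha)`` for ``j = n .. n+terms-1`` with ``n = 1`` (order in
    (0,1)).  For integer exponents the monomial's derivatives vanish past
    ``j = p``, so the series terminates and the partial sum is exact once
    ``terms`` covers ``j = p``.
    """
    if terms < 1:
        raise ValueError("terms must be >= 1")
    n = 1  # order in (0, 1) by CaputoQuery invariant
    a = q.order
    dx = q.eval_point - q.lower_bound
    total = 0.0
    for j in range(n, n + terms):
        gj = _monomial_derivative(q.exponent, j, q.eval_point)
        if gj == 0.0:
            continue
        total += (
            special.binom(a - n, j - n)
            * gj
            / special.gamma(j - a + 1)
            * dx ** (j - a)
        )
    return float(total)
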