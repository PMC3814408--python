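"""Monotone transforms linking effect-site drug concentration to the
burst suppression probability (BSP).

The BSP is the brain's instantaneous probability of the EEG being in the
suppressed state.  It must lie in [0, 1) and increase monotonically with
the (nonnegative, dimensionless) effect-site concentration ``x_e``.  Two
hyperbolic transform families are provided:

``hyperbolic_ratio``
    p = x / (1 + x), the rectangular hyperbola (default).  Its inverse
    x = p / (1 - p) shows the characteristic steep growth of required
    concentration as the target BSP approaches 1 — holding the EEG
    suppressed 90% of the time takes far more drug than 50%.
``tanh``
    p = tanh(x).

Both map [0, inf) onto [0, 1) bijectively with p(0) = 0.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BSPTransform", "HyperbolicRatio", "TanhTransform", "get_transform"]


class BSPTransform:
    """Abstract monotone map from effect-site concentration to BSP.

    Subclasses supply ``forward``, ``inverse`` and the first two
    derivatives of ``forward`` (needed by the Bayesian filter's Newton
    update, where the likelihood is differentiated through the
    transform).
    """

    name: str = "abstract"

    def forward(self, x_e):
        """BSP as a function of effect-site concentration (vectorized)."""
        raise NotImplementedError

    def inverse(self, p):
        """Effect-site concentration producing BSP ``p``."""
        raise NotImplementedError

    def d1(self, x_e):
        """dp/dx at ``x_e``."""
        raise NotImplementedError

    def d2(self, x_e):
        """d²p/dx² at ``x_e``."""
        raise NotImplementedError

    # -- shared validation ------------------------------------------------
    @staticmethod
    def _check_conc(x_e):
        x = np.asarray(x_e, dtype=float)
        if np.any(x < 0):
            raise ValueError("effect-site concentration must be nonnegative")
        return x

    @staticmethod
    def _check_prob(p):
        q = np.asarray(p, dtype=float)
        if np.any(q < 0) or np.any(q >= 1):
            raise ValueError("BSP must lie in [0, 1)")
        return q

    def __call__(self, x_e):
        return self.forward(x_e)

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"{type(self).__name__}()"


class HyperbolicRatio(BSPTransform):
    """p = x / (1 + x); inverse x = p / (1 - p)."""

    name = "hyperbolic_ratio"

    def forward(self, x_e):
        x = self._check_conc(x_e)
        return x / (1.0 + x)

    def inverse(self, p):
        q = self._check_prob(p)
        return q / (1.0 - q)

    def d1(self, x_e):
        x = self._check_conc(x_e)
        return 1.0 / (1.0 + x) ** 2

    def d2(self, x_e):
        x = self._check_conc(x_e)
        return -2.0 / (1.0 + x) ** 3


class TanhTransform(BSPTransform):
    """p = tanh(x); inverse x = atanh(p)."""

    name = "tanh"

    def forward(self, x_e):
        x = self._check_conc(x_e)
        return np.tanh(x)

    def inverse(self, p):
        q = self._check_prob(p)
        return np.arctanh(q)

    def d1(self, x_e):
        x = self._check_conc(x_e)
        return 1.0 / np.cosh(x) ** 2

    def d2(self, x_e):
        x = self._check_conc(x_e)
        t = np.tanh(x)
        return -2.0 * t / np.cosh(x) ** 2


_REGISTRY = {
    HyperbolicRatio.name: HyperbolicRatio,
    TanhTransform.name: TanhTransform,
}


def get_transform(name: str | BSPTransform = "hyperbolic_ratio") -> BSPTransform:
    """Look up a transform by name ('hyperbolic_ratio' or 'tanh')."""
    if isinstance(name, BSPTransform):
        return name
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise ValueError(
            f"unknown transform {name!r}; choose from {sorted(_REGISTRY)}"
        ) from None
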