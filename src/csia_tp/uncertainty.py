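"""First-order Taylor-series uncertainty propagation into trophic-position estimates.

Every equation has the form TP = (numerator)/(denominator) + constant, with
the numerator linear in the measured δ15N values and the β/TDF parameters.
Writing λ for the denominator TDF, the propagated variance with independent
inputs is

    Var(TP) = Σᵢ (∂TP/∂xᵢ)² σᵢ²

with analytically coded partial derivatives: every additive numerator term
contributes ±1/λ, and the denominator contributes −numerator/λ². A
Monte-Carlo propagator with Gaussian marginals serves as an independent
oracle; for equations that are linear in their uncertain inputs (σ on
numerator terms only) the first-order result is exact and the two agree to
Monte-Carlo error.

All uncertain inputs are assumed independent (no covariance structure is
available for the published parameters).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .frameworks import TDFFramework, UncertainValue

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PropagationInputs:
    """Uncertain inputs for one trophic-position estimate.

    Exactly one of ``delta`` (Δ ± sd) or the (``glx``, ``phe``) component
    pair must be given; in component mode σ_Δ² = σ_Glx² + σ_Phe². For
    equation 2, ``delta`` carries Σtrophic − Σsource with the SD of that
    difference of means.
    """

    beta: UncertainValue
    tdf_base: UncertainValue
    tdf_consumer: UncertainValue | None = None
    delta: UncertainValue | None = None
    glx: UncertainValue | None = None
    phe: UncertainValue | None = None

    def __post_init__(self):
        component = self.glx is not None or self.phe is not None
        if component and (self.glx is None or self.phe is None):
            raise ConfigurationError("component mode requires both glx and phe")
        if component == (self.delta is not None):
            raise ConfigurationError("provide either delta or the (glx, phe) pair, not both")

    @property
    def delta_value(self) -> float:
        if self.delta is not None:
            return self.delta.value
        return self.glx.value - self.phe.value

    @property
    def delta_var(self) -> float:
        if self.delta is not None:
            return self.delta.sd**2
        return self.glx.sd**2 + self.phe.sd**2

    @classmethod
    def from_framework(
        cls,
        framework: TDFFramework,
        *,
        delta: UncertainValue | None = None,
        glx: UncertainValue | None = None,
        phe: UncertainValue | None = None,
    ) -> "PropagationInputs":
        return cls(
            beta=framework.beta,
            tdf_base=framework.tdf_base,
            tdf_consumer=framework.tdf_consumer,
            delta=delta,
            glx=glx,
            phe=phe,
        )


def _numerator(equation_id: int, delta: float, inputs: PropagationInputs) -> float:
    if equation_id in (1, 2):
        return delta - inputs.beta.value
    if equation_id == 3:
        return delta - inputs.tdf_consumer.value - inputs.beta.value
    return delta - inputs.tdf_base.value - inputs.beta.value


def _check_consumer(equation_id: int, inputs: PropagationInputs) -> None:
    if equation_id in (3, 4) and inputs.tdf_consumer is None:
        raise ConfigurationError(f"equation {equation_id} requires a consumer TDF")


def propagate_taylor(equation_id: int, inputs: PropagationInputs) -> float:
    """Propagated trophic-position SD from the first-order expansion.

    Closed forms (λ = denominator TDF, N = numerator):

    * equations 1/2: Var = (σ_Δ² + σ_β²)/λ² + (N σ_λ / λ²)², λ = tdf_base
    * equation 3:    Var = (σ_Δ² + σ_β² + σ_TDFc²)/λ² + (N σ_λ / λ²)²
    * equation 4:    Var = (σ_Δ² + σ_β² + σ_TDFbase²)/λ² + (N σ_λ / λ²)²,
      with λ = tdf_consumer (the penguin TDF divides) and σ_λ its SD.
    """
    _check_consumer(equation_id, inputs)
    if equation_id == 4:
        lam = inputs.tdf_consumer
        extra_var = inputs.tdf_base.sd**2
    else:
        lam = inputs.tdf_base
        extra_var = inputs.tdf_consumer.sd**2 if equation_id == 3 else 0.0
    num = _numerator(equation_id, inputs.delta_value, inputs)
    num_var = inputs.delta_var + inputs.beta.sd**2 + extra_var
    var = num_var / lam.value**2 + (num * lam.sd / lam.value**2) ** 2
    assert var >= 0
    return math.sqrt(var)


def propagate_mc(
    equation_id: int,
    inputs: PropagationInputs,
    n_draws: int = 100_000,
    seed: int | None = None,
    max_rejection_rounds: int = 100,
) -> float:
    """Monte-Carlo oracle for ``propagate_taylor``.

    Draws every uncertain input from an independent Gaussian, evaluates the
    trophic-position equation per draw, and returns the sample SD.
    Denominator draws <= 0 would make the estimate blow up; they are
    rejected and redrawn, with a warning if more than 1% of draws were
    rejected. ``seed`` is required for reproducible results and must be
    passed explicitly.
    """
    if n_draws < 10_000:
        raise ValueError("n_draws must be at least 10_000 for a stable SD")
    if seed is None:
        raise ValueError("an explicit seed is required")
    _check_consumer(equation_id, inputs)
    rng = np.random.default_rng(seed)

    delta = rng.normal(inputs.delta_value, math.sqrt(inputs.delta_var), n_draws)
    beta = rng.normal(inputs.beta.value, inputs.beta.sd, n_draws)
    lam_uv = inputs.tdf_consumer if equation_id == 4 else inputs.tdf_base
    lam = rng.normal(lam_uv.value, lam_uv.sd, n_draws)
    if equation_id == 3:
        other = rng.normal(inputs.tdf_consumer.value, inputs.tdf_consumer.sd, n_draws)
    elif equation_id == 4:
        other = rng.normal(inputs.tdf_base.value, inputs.tdf_base.sd, n_draws)
    else:
        other = np.zeros(n_draws)

    n_rejected = 0
    for _ in range(max_rejection_rounds):
        bad = lam <= 0
        n_bad = int(bad.sum())
        if n_bad == 0:
            break
        n_rejected += n_bad
        lam[bad] = rng.normal(lam_uv.value, lam_uv.sd, n_bad)
    else:
        raise RuntimeError("could not redraw a positive denominator TDF")
    if n_rejected:
        logger.info("redrew %d non-positive denominator TDF draws", n_rejected)
        if n_rejected > 0.01 * n_draws:
            logger.warning(
                "%.1f%% of denominator TDF draws were non-positive; the Gaussian "
                "assumption is strained for this parameter",
                100 * n_rejected / n_draws,
            )

    if equation_id in (1, 2):
        tp = (delta - beta) / lam + 1.0
    elif equation_id == 3:
        tp = (delta - other - beta) / lam + 2.0
    else:
        tp = (delta - other - beta) / lam + 2.0
    return float(np.std(tp, ddof=1))
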