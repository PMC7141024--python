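"""Trophic-position equations and trophic-discrimination-factor frameworks.

Four published equation forms estimate trophic position (TP) from the
consumer's trophic-minus-source amino-acid δ15N difference Δ (usually
δ15N_Glx-Phe), the producer-level offset β, and one or two trophic
discrimination factors (TDFs):

====  ==========================================  =====================================
id    formula                                     parameters
====  ==========================================  =====================================
1     TP = (Δ − β) / TDF + 1                      single TDF (7.6‰) on every transfer
2     TP = (Σtrophic − Σsource − β) / TDF + 1     as 1, with multi-amino-acid means
3     TP = (Δ − TDF_consumer − β) / TDF + 2       consumer TDF (seal, 4.3‰) applied to
                                                  the final transfer only
4     TP = (Δ − TDF − β) / TDF_consumer + 2       lower consumer TDF (penguin, 3.5‰) on
                                                  all transfers after the first
====  ==========================================  =====================================

Defaults: β = 3.4 ± 0.9‰ (marine algae/cyanobacteria), TDF = 7.6 ± 1.2‰
(invertebrates/fish), seal TDF = 4.3 ± 1.2‰, penguin TDF = 3.5 ± 0.4‰.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .errors import ConfigurationError, ParameterError


@dataclass(frozen=True)
class UncertainValue:
    """A value with a standard deviation, e.g. a TDF of 7.6 ± 1.2‰."""

    value: float
    sd: float = 0.0

    def __post_init__(self):
        if not math.isfinite(self.value):
            raise ValueError(f"value must be finite, got {self.value}")
        if not (math.isfinite(self.sd) and self.sd >= 0):
            raise ValueError(f"sd must be finite and >= 0, got {self.sd}")


@dataclass(frozen=True)
class TDFFramework:
    """A named TP-estimating equation with its β/TDF parameters.

    ``tdf_base`` is the planktonic food-web TDF appearing in every equation;
    ``tdf_consumer`` is the consumer-specific TDF required by equations 3
    (seal) and 4 (penguin) and forbidden for equations 1 and 2.
    """

    name: str
    equation_id: int
    beta: UncertainValue = UncertainValue(3.4, 0.9)
    tdf_base: UncertainValue = UncertainValue(7.6, 1.2)
    tdf_consumer: UncertainValue | None = None

    def __post_init__(self):
        if self.equation_id not in (1, 2, 3, 4):
            raise ConfigurationError(f"unknown equation id {self.equation_id}")
        if self.tdf_base.value <= 0:
            raise ParameterError(f"tdf_base must be positive, got {self.tdf_base.value}")
        if self.equation_id in (1, 2) and self.tdf_consumer is not None:
            raise ConfigurationError(
                f"equation {self.equation_id} does not take a consumer TDF"
            )
        if self.equation_id in (3, 4) and self.tdf_consumer is None:
            raise ConfigurationError(
                f"equation {self.equation_id} requires a consumer-specific TDF"
            )
        if self.equation_id == 4 and self.tdf_consumer.value <= 0:
            raise ParameterError(
                f"equation 4 divides by the consumer TDF; got {self.tdf_consumer.value}"
            )


#: The four published parameter sets, immutable. Overrides are made by
#: constructing a new TDFFramework (dataclasses.replace), never by mutation.
DEFAULT_FRAMEWORKS: dict[str, TDFFramework] = {
    "chikaraishi_single": TDFFramework("chikaraishi_single", 1),
    "multi_aa": TDFFramework("multi_aa", 2),
    "germain_dual": TDFFramework("germain_dual", 3, tdf_consumer=UncertainValue(4.3, 1.2)),
    "mcmahon_dual": TDFFramework("mcmahon_dual", 4, tdf_consumer=UncertainValue(3.5, 0.4)),
}


def tp_equation_1(delta_glx_phe: float, framework: TDFFramework) -> float:
    """Single-TDF trophic position: (Δ − β)/TDF + 1."""
    _require(framework, 1)
    return (delta_glx_phe - framework.beta.value) / framework.tdf_base.value + 1.0


def tp_equation_2(mean_trophic: float, mean_source: float, framework: TDFFramework) -> float:
    """Multi-amino-acid trophic position: (Σtrophic − Σsource − β)/TDF + 1."""
    _require(framework, 2)
    delta = mean_trophic - mean_source
    return (delta - framework.beta.value) / framework.tdf_base.value + 1.0


def tp_equation_3(delta_glx_phe: float, framework: TDFFramework) -> float:
    """Dual-TDF trophic position with the consumer TDF on the final transfer only:
    (Δ − TDF_consumer − β)/TDF + 2."""
    _require(framework, 3)
    num = delta_glx_phe - framework.tdf_consumer.value - framework.beta.value
    return num / framework.tdf_base.value + 2.0


def tp_equation_4(delta_glx_phe: float, framework: TDFFramework) -> float:
    """Dual-TDF trophic position with the lower consumer TDF on all transfers
    after the first: (Δ − TDF − β)/TDF_consumer + 2."""
    _require(framework, 4)
    num = delta_glx_phe - framework.tdf_base.value - framework.beta.value
    return num / framework.tdf_consumer.value + 2.0


def tp_from_delta(delta: float, framework: TDFFramework) -> float:
    """Dispatch Δ-based estimation to the framework's equation (1, 3 or 4).

    Equation 2 takes averaged inputs, not a single Δ; use ``tp_equation_2``.
    For dispatch purposes equation 2 applied to Σtrophic − Σsource is the
    same closed form as equation 1.
    """
    if framework.equation_id == 1:
        return tp_equation_1(delta, framework)
    if framework.equation_id == 2:
        return (delta - framework.beta.value) / framework.tdf_base.value + 1.0
    if framework.equation_id == 3:
        return tp_equation_3(delta, framework)
    return tp_equation_4(delta, framework)


def _require(framework: TDFFramework, equation_id: int) -> None:
    if framework.equation_id != equation_id:
        raise ConfigurationError(
            f"framework {framework.name!r} is for equation {framework.equation_id}, "
            f"not {equation_id}"
        )


@dataclass(frozen=True)
class DietComposition:
    """Prey items with trophic positions and diet proportions.

    Used for the stomach-content trophic position
    TP_SC = 1 + Σᵢ pᵢ · TPᵢ. Proportions must be non-negative and sum to 1;
    prey TPs must be >= 1 (primary producers occupy TP 1).
    """

    items: tuple[tuple[str, float, float], ...]

    def __post_init__(self):
        items = tuple((str(l), float(tp), float(p)) for l, tp, p in self.items)
        object.__setattr__(self, "items", items)
        if not items:
            raise ValueError("diet composition must contain at least one prey item")
        for label, tp, p in items:
            if p < 0:
                raise ValueError(f"prey {label!r}: proportion {p} is negative")
            if tp < 1:
                raise ValueError(f"prey {label!r}: trophic position {tp} is below 1")
        total = sum(p for _, _, p in items)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"diet proportions sum to {total!r}, not 1")


def tp_stomach_content(diet: DietComposition) -> float:
    """Diet-weighted stomach-content trophic position: 1 + Σᵢ pᵢ · TPᵢ."""
    return 1.0 + sum(p * tp for _, tp, p in diet.items)
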