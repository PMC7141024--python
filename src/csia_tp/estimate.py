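"""Per-specimen trophic-position estimation across frameworks.

Drives the full chain: derived Δ (or multi-amino-acid means) per specimen,
the framework's closed-form trophic position, and the first-order propagated
SD. Specimens that cannot be estimated under a framework (missing analytes
in strict mode) yield flagged rows carrying the error message rather than
being silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MissingAnalyteError
from .frameworks import (
    DEFAULT_FRAMEWORKS,
    DietComposition,
    TDFFramework,
    UncertainValue,
    tp_equation_2,
    tp_from_delta,
    tp_stomach_content,
)
from .profiles import (
    DEFAULT_CLASSIFICATION,
    DEFAULT_MEASUREMENT_SD,
    AAClassification,
    AminoAcidProfile,
    glx_phe_difference,
    mean_source,
    mean_trophic,
)
from .rounding import round_half_up
from .uncertainty import PropagationInputs, propagate_taylor

#: Diagnostic flags a TPEstimate may carry.
FLAG_BELOW_ONE = "below_one"
FLAG_MISSING_SD_DEFAULTED = "missing_sd_defaulted"
FLAG_PERMISSIVE_AA_SET = "permissive_aa_set"


@dataclass(frozen=True)
class TPEstimate:
    """One specimen × framework trophic-position result.

    ``tp`` below 1 is physically dubious (below primary producers) and is
    flagged ``below_one`` but never clamped. ``error`` is set (and ``tp``
    is NaN) when the specimen could not be estimated under this framework.
    """

    specimen_id: str
    equation_id: int
    framework_name: str
    delta_input: float
    tp: float
    tp_sd: float
    flags: frozenset[str] = frozenset()
    error: str | None = None

    def __post_init__(self):
        if self.error is None:
            if not math.isfinite(self.tp):
                raise ValueError("tp must be finite for a successful estimate")
            if not (math.isfinite(self.tp_sd) and self.tp_sd >= 0):
                raise ValueError("tp_sd must be finite and >= 0")
            if self.tp < 1 and FLAG_BELOW_ONE not in self.flags:
                raise ValueError("tp < 1 must carry the below_one flag")


def _flags_for(tp: float, defaulted_sd: bool, permissive: bool) -> frozenset[str]:
    flags = set()
    if tp < 1:
        flags.add(FLAG_BELOW_ONE)
    if defaulted_sd:
        flags.add(FLAG_MISSING_SD_DEFAULTED)
    if permissive:
        flags.add(FLAG_PERMISSIVE_AA_SET)
    return frozenset(flags)


def _failed(profile_id: str, framework: TDFFramework, exc: Exception) -> TPEstimate:
    return TPEstimate(
        specimen_id=profile_id,
        equation_id=framework.equation_id,
        framework_name=framework.name,
        delta_input=float("nan"),
        tp=float("nan"),
        tp_sd=float("nan"),
        flags=frozenset(),
        error=str(exc),
    )


def estimate_one(
    profile: AminoAcidProfile,
    framework: TDFFramework,
    classification: AAClassification = DEFAULT_CLASSIFICATION,
    default_measurement_sd: float = DEFAULT_MEASUREMENT_SD,
    strict: bool = True,
) -> TPEstimate:
    """Estimate one specimen under one framework, with propagated SD.

    Measurement SDs come from the profile's replicate SDs where present and
    fall back to ``default_measurement_sd`` otherwise (flagged). Equation 2
    in strict mode requires every trophic and source amino acid; permissive
    mode averages whatever subset is present and flags the estimate.
    """
    eq = framework.equation_id
    if eq == 2:
        tmean = mean_trophic(profile, classification, strict=strict)
        smean = mean_source(profile, classification, strict=strict)
        delta = tmean - smean
        tro = sorted((classification.trophic - classification.excluded) & set(profile.aa_d15n))
        src = sorted((classification.source - classification.excluded) & set(profile.aa_d15n))
        permissive = set(tro) != classification.trophic - classification.excluded or set(
            src
        ) != classification.source - classification.excluded
        t_sds = [profile.sd_for(a, default_measurement_sd) for a in tro]
        s_sds = [profile.sd_for(a, default_measurement_sd) for a in src]
        defaulted = any(d for _, d in t_sds + s_sds)
        # SD of a mean of independent measurements: sqrt(sum sd_i^2) / k
        t_var = sum(s**2 for s, _ in t_sds) / len(t_sds) ** 2
        s_var = sum(s**2 for s, _ in s_sds) / len(s_sds) ** 2
        delta_uv = UncertainValue(delta, math.sqrt(t_var + s_var))
        tp = tp_equation_2(tmean, smean, framework)
    else:
        delta = glx_phe_difference(profile)
        glx_sd, d1 = profile.sd_for("Glx", default_measurement_sd)
        phe_sd, d2 = profile.sd_for("Phe", default_measurement_sd)
        defaulted = d1 or d2
        permissive = False
        delta_uv = None
        tp = tp_from_delta(delta, framework)

    if eq == 2:
        inputs = PropagationInputs.from_framework(framework, delta=delta_uv)
    else:
        inputs = PropagationInputs.from_framework(
            framework,
            glx=UncertainValue(profile.aa_d15n["Glx"], glx_sd),
            phe=UncertainValue(profile.aa_d15n["Phe"], phe_sd),
        )
    tp_sd = propagate_taylor(eq, inputs)
    return TPEstimate(
        specimen_id=profile.specimen_id,
        equation_id=eq,
        framework_name=framework.name,
        delta_input=delta,
        tp=tp,
        tp_sd=tp_sd,
        flags=_flags_for(tp, defaulted, permissive),
    )


def estimate_all(
    profiles: Sequence[AminoAcidProfile],
    frameworks: Mapping[str, TDFFramework] | Sequence[TDFFramework] | None = None,
    classification: AAClassification = DEFAULT_CLASSIFICATION,
    default_measurement_sd: float = DEFAULT_MEASUREMENT_SD,
    strict: bool = True,
) -> list[TPEstimate]:
    """One TPEstimate per (specimen, framework), ordered by (specimen_id, equation_id).

    Per-specimen missing-analyte failures become flagged error rows; they
    are never silently dropped.
    """
    if frameworks is None:
        frameworks = DEFAULT_FRAMEWORKS
    if isinstance(frameworks, Mapping):
        frameworks = list(frameworks.values())
    else:
        frameworks = list(frameworks)
    if not frameworks:
        raise ValueError("at least one framework is required")

    results: list[TPEstimate] = []
    for profile in profiles:
        for fw in frameworks:
            try:
                results.append(
                    estimate_one(
                        profile,
                        fw,
                        classification=classification,
                        default_measurement_sd=default_measurement_sd,
                        strict=strict,
                    )
                )
            except MissingAnalyteError as exc:
                results.append(_failed(profile.specimen_id, fw, exc))
    results.sort(key=lambda e: (e.specimen_id, e.equation_id))
    return results


def estimate_from_delta(
    delta: float,
    framework: TDFFramework,
    delta_sd: float | None = None,
    specimen_id: str = "<delta>",
    default_measurement_sd: float = DEFAULT_MEASUREMENT_SD,
) -> TPEstimate:
    """Estimate directly from a δ15N_Glx-Phe value (equations 1, 3 and 4).

    Used for published per-individual Δ values where the underlying Glx and
    Phe measurements are not available. When ``delta_sd`` is None it
    defaults to sqrt(2) · ``default_measurement_sd`` (both components at
    the tissue-level default), and the estimate is flagged accordingly.
    """
    defaulted = delta_sd is None
    if defaulted:
        delta_sd = math.sqrt(2.0) * default_measurement_sd
    tp = tp_from_delta(delta, framework)
    inputs = PropagationInputs.from_framework(
        framework, delta=UncertainValue(delta, delta_sd)
    )
    tp_sd = propagate_taylor(framework.equation_id, inputs)
    return TPEstimate(
        specimen_id=specimen_id,
        equation_id=framework.equation_id,
        framework_name=framework.name,
        delta_input=delta,
        tp=tp,
        tp_sd=tp_sd,
        flags=_flags_for(tp, defaulted, False),
    )


def estimates_to_table(
    estimates: Iterable[TPEstimate],
    meta: Mapping[str, Mapping[str, object]] | None = None,
    diet_tps: Mapping[str, float] | None = None,
    ndigits_tp: int = 1,
) -> pd.DataFrame:
    """Wide per-specimen report table (one row per specimen, one TP ± SD pair per equation).

    ``meta`` maps specimen_id to metadata columns (species, tissue, ...);
    ``diet_tps`` maps species to a stomach-content TP, reported alongside
    for comparison. TPs and SDs are rounded half-up to ``ndigits_tp`` for
    display; Δ is reported at 2 decimals.
    """
    rows: dict[str, dict] = {}
    for e in sorted(estimates, key=lambda e: (e.specimen_id, e.equation_id)):
        row = rows.setdefault(e.specimen_id, {"specimen_id": e.specimen_id})
        if meta and e.specimen_id in meta:
            row.update(meta[e.specimen_id])
        if not math.isnan(e.delta_input):
            row["delta_glx_phe"] = round_half_up(e.delta_input, 2)
        if e.error is not None:
            row[f"tp_eq{e.equation_id}"] = np.nan
            row[f"tp_eq{e.equation_id}_sd"] = np.nan
        else:
            row[f"tp_eq{e.equation_id}"] = round_half_up(e.tp, ndigits_tp)
            row[f"tp_eq{e.equation_id}_sd"] = round_half_up(e.tp_sd, ndigits_tp)
        flags = row.get("_flags", set())
        flags |= set(e.flags)
        if e.error is not None:
            flags.add(f"eq{e.equation_id}_error")
        row["_flags"] = flags
    out = []
    for sid in sorted(rows):
        row = rows[sid]
        if diet_tps is not None:
            species = row.get("species")
            if species in diet_tps:
                row["tp_sc"] = diet_tps[species]
        row["flags"] = "|".join(sorted(row.pop("_flags", set())))
        out.append(row)
    return pd.DataFrame(out)


def compare_to_stomach_content(
    table: pd.DataFrame,
    group_keys: Sequence[str] = ("species", "tissue"),
) -> pd.DataFrame:
    """Per-group mean deviation TP_SC − TP_CSIA for each equation column.

    Positive deviations mean the isotope-based estimate sits below the
    stomach-content estimate. Rows lacking a TP_SC are excluded and counted
    in the ``n_missing_tp_sc`` column.
    """
    if "tp_sc" not in table.columns:
        raise ValueError("table has no tp_sc column; supply diet compositions first")
    eq_cols = [c for c in table.columns if c.startswith("tp_eq") and not c.endswith("_sd")]
    work = table.copy()
    for c in eq_cols:
        work[f"dev_{c[3:]}"] = work["tp_sc"] - work[c]
    dev_cols = [f"dev_{c[3:]}" for c in eq_cols]
    grouped = work.groupby(list(group_keys), sort=True)
    agg = grouped[dev_cols].mean()
    agg["n"] = grouped.size()
    agg["n_missing_tp_sc"] = grouped["tp_sc"].apply(lambda s: int(s.isna().sum()))
    return agg.reset_index()


def stomach_content_tps(
    diets: Mapping[str, DietComposition],
) -> dict[str, float]:
    """Evaluate TP_SC = 1 + Σ pᵢ·TPᵢ for each species' diet composition."""
    return {species: tp_stomach_content(diet) for species, diet in diets.items()}
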