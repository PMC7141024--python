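"""Amino-acid δ15N profiles: data model, I/O and per-specimen derived quantities.

A specimen's compound-specific nitrogen-isotope measurement is a map from
amino-acid code to δ15N (‰ vs. atmospheric N2). Acid hydrolysis converts
glutamine to glutamic acid and asparagine to aspartic acid, so the measured
pools are the combined Glx (Glu+Gln) and Asx (Asp+Asn); the ``Glu``/``Asp``
aliases are normalised to ``Glx``/``Asx`` on ingest.

Amino acids are classified as *trophic* (15N-enriched with each trophic
transfer: Glx, Asx, Ala, Ile, Leu, Pro, Val) or *source* (near-conservative,
proxying the primary-producer baseline: Phe). Gly was formerly treated as a
source amino acid but is excluded by default.

The canonical on-disk representation is a tidy long table with columns
``specimen_id, species, tissue, aa, d15n[, sd, n_reps]``; a wide-format
reader is provided as a convenience and converted on ingest.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, IngestError, MissingAnalyteError

logger = logging.getLogger(__name__)

#: Amino-acid codes accepted by the data model.
CANONICAL_AAS: frozenset[str] = frozenset(
    {"Glx", "Asx", "Ala", "Ile", "Leu", "Pro", "Val", "Gly", "Phe", "Thr", "Met"}
)

#: Hydrolysis aliases normalised on ingest (Gln/Glu -> Glx, Asn/Asp -> Asx).
AA_ALIASES: Mapping[str, str] = {"Glu": "Glx", "Gln": "Glx", "Asp": "Asx", "Asn": "Asx"}

#: Plausibility bounds for a δ15N value, in ‰ vs. atmospheric N2.
D15N_BOUNDS = (-30.0, 60.0)

#: Tissues the data model recognises.
TISSUES: frozenset[str] = frozenset({"baleen", "skin", "dentine_collagen"})

#: Default per-amino-acid measurement SD (‰) when no replicate SD is recorded.
#: Analytical precision from duplicate/triplicate GC-IRMS runs is < 1‰.
DEFAULT_MEASUREMENT_SD = 0.5


def normalize_aa(code: str) -> str:
    """Return the canonical amino-acid code for ``code``.

    Raises ``IngestError`` for codes outside the canonical set.
    """
    code = code.strip()
    code = AA_ALIASES.get(code, code)
    if code not in CANONICAL_AAS:
        raise IngestError(f"unknown amino acid code: {code!r}")
    return code


@dataclass(frozen=True)
class AAClassification:
    """Partition of amino acids into trophic, source and excluded sets.

    Defaults follow current practice: seven trophic amino acids identified
    a priori, Phe as the sole source amino acid, and Gly excluded (no longer
    considered a reliable source amino acid).
    """

    trophic: frozenset[str] = frozenset({"Glx", "Asx", "Ala", "Ile", "Leu", "Pro", "Val"})
    source: frozenset[str] = frozenset({"Phe"})
    excluded: frozenset[str] = frozenset({"Gly"})

    def __post_init__(self):
        object.__setattr__(self, "trophic", frozenset(normalize_aa(a) for a in self.trophic))
        object.__setattr__(self, "source", frozenset(normalize_aa(a) for a in self.source))
        object.__setattr__(self, "excluded", frozenset(normalize_aa(a) for a in self.excluded))
        if not self.trophic or not self.source:
            raise ValueError("trophic and source sets must both be non-empty")
        if self.trophic & self.source:
            raise ValueError(f"trophic and source sets overlap: {self.trophic & self.source}")
        # exclusion overrides membership: an excluded amino acid never enters a mean
        if not self.trophic - self.excluded or not self.source - self.excluded:
            raise ValueError("exclusions leave the trophic or source set empty")


DEFAULT_CLASSIFICATION = AAClassification()


@dataclass(frozen=True)
class AminoAcidProfile:
    """One specimen's amino-acid δ15N values with metadata.

    Parameters
    ----------
    specimen_id
        Opaque identifier, unique within a collection.
    species, tissue
        Metadata labels; ``tissue`` must be one of ``baleen``, ``skin``,
        ``dentine_collagen``.
    aa_d15n
        Map from canonical amino-acid code to δ15N (‰ vs. atmospheric N2).
    aa_sd
        Optional map from code to replicate standard deviation (‰, >= 0).
    n_replicates
        Optional map from code to replicate count.
    """

    specimen_id: str
    species: str
    tissue: str
    aa_d15n: Mapping[str, float]
    aa_sd: Mapping[str, float] | None = None
    n_replicates: Mapping[str, int] | None = None

    def __post_init__(self):
        if self.tissue not in TISSUES:
            raise ValueError(
                f"specimen {self.specimen_id!r}: unknown tissue {self.tissue!r} "
                f"(expected one of {sorted(TISSUES)})"
            )
        clean: dict[str, float] = {}
        for aa, value in self.aa_d15n.items():
            aa = normalize_aa(aa)
            if aa in clean:
                raise IngestError(
                    f"specimen {self.specimen_id!r}: duplicate amino acid {aa!r} after aliasing"
                )
            value = float(value)
            if not math.isfinite(value):
                raise ValueError(f"specimen {self.specimen_id!r}: non-finite δ15N for {aa}")
            if not (D15N_BOUNDS[0] <= value <= D15N_BOUNDS[1]):
                raise ValueError(
                    f"specimen {self.specimen_id!r}: δ15N {value}‰ for {aa} outside "
                    f"plausible range {list(D15N_BOUNDS)}‰"
                )
            clean[aa] = value
        object.__setattr__(self, "aa_d15n", clean)
        if self.aa_sd is not None:
            sds = {normalize_aa(a): float(s) for a, s in self.aa_sd.items()}
            for aa, s in sds.items():
                if not math.isfinite(s) or s < 0:
                    raise ValueError(
                        f"specimen {self.specimen_id!r}: invalid replicate SD {s} for {aa}"
                    )
            object.__setattr__(self, "aa_sd", sds)
        if self.n_replicates is not None:
            object.__setattr__(
                self,
                "n_replicates",
                {normalize_aa(a): int(n) for a, n in self.n_replicates.items()},
            )

    def sd_for(self, aa: str, default: float = DEFAULT_MEASUREMENT_SD) -> tuple[float, bool]:
        """Measurement SD for one amino acid and whether the default was used."""
        if self.aa_sd is not None and aa in self.aa_sd:
            return self.aa_sd[aa], False
        return default, True


def glx_phe_difference(profile: AminoAcidProfile) -> float:
    """δ15N_Glx-Phe: the consumer Glx minus Phe δ15N difference (‰).

    This is the internal-calibration statistic from which trophic position
    is computed; it is invariant to adding a constant to every amino acid
    (baseline shifts cancel).
    """
    missing = {"Glx", "Phe"} - set(profile.aa_d15n)
    if missing:
        raise MissingAnalyteError(profile.specimen_id, missing)
    return profile.aa_d15n["Glx"] - profile.aa_d15n["Phe"]


def _mean_over(
    profile: AminoAcidProfile,
    aa_set: frozenset[str],
    excluded: frozenset[str],
    strict: bool,
    label: str,
) -> float:
    wanted = aa_set - excluded
    present = sorted(wanted & set(profile.aa_d15n))
    if strict and set(present) != wanted:
        raise MissingAnalyteError(profile.specimen_id, wanted - set(present))
    if not present:
        raise MissingAnalyteError(profile.specimen_id, wanted)
    if not strict and set(present) != wanted:
        logger.warning(
            "specimen %r: permissive %s mean over %d of %d amino acids",
            profile.specimen_id, label, len(present), len(wanted),
        )
    return float(np.mean([profile.aa_d15n[a] for a in present]))


def mean_trophic(
    profile: AminoAcidProfile,
    classification: AAClassification = DEFAULT_CLASSIFICATION,
    strict: bool = True,
) -> float:
    """Unweighted mean δ15N over the trophic amino acids (the Σtrophic term)."""
    return _mean_over(profile, classification.trophic, classification.excluded, strict, "trophic")


def mean_source(
    profile: AminoAcidProfile,
    classification: AAClassification = DEFAULT_CLASSIFICATION,
    strict: bool = True,
) -> float:
    """Unweighted mean δ15N over the source amino acids (the Σsource term)."""
    return _mean_over(profile, classification.source, classification.excluded, strict, "source")


_MANDATORY_COLUMNS = ("specimen_id", "species", "tissue", "aa", "d15n")


def _detect_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header and "," not in header else ","


def read_profiles(
    path,
    sep: str | None = None,
    strict: bool = True,
) -> list[AminoAcidProfile]:
    """Read a tidy long-format delimited table of per-specimen δ15N values.

    Expected columns: ``specimen_id, species, tissue, aa, d15n`` with
    optional ``sd`` and ``n_reps``. Comma is the default delimiter; tab is
    accepted (auto-detected when ``sep`` is None). Aliases such as ``Glu``
    are normalised; rows with unknown amino-acid codes raise ``IngestError``
    in strict mode and are reported and skipped otherwise.
    """
    try:
        df = pd.read_csv(path, sep=sep if sep is not None else _detect_sep(path))
    except pd.errors.EmptyDataError:
        logger.warning("empty input file %s: returning no profiles", path)
        return []
    missing_cols = set(_MANDATORY_COLUMNS) - set(df.columns)
    if missing_cols:
        raise FormatError(f"{path}: missing mandatory column(s): {sorted(missing_cols)}")
    if df.empty:
        logger.warning("input file %s has a header but no rows", path)
        return []
    return profiles_from_long(df, strict=strict)


def read_profiles_wide(path, sep: str | None = None, strict: bool = True) -> list[AminoAcidProfile]:
    """Convenience reader for wide tables (one column per amino acid).

    Columns ``specimen_id, species, tissue`` plus one column per amino-acid
    code; melted to the canonical long layout on ingest. Replicate SDs
    cannot be represented in this layout.
    """
    try:
        df = pd.read_csv(path, sep=sep if sep is not None else _detect_sep(path))
    except pd.errors.EmptyDataError:
        logger.warning("empty input file %s: returning no profiles", path)
        return []
    meta = ["specimen_id", "species", "tissue"]
    missing_cols = set(meta) - set(df.columns)
    if missing_cols:
        raise FormatError(f"{path}: missing mandatory column(s): {sorted(missing_cols)}")
    long = df.melt(id_vars=meta, var_name="aa", value_name="d15n").dropna(subset=["d15n"])
    return profiles_from_long(long, strict=strict)


def profiles_from_long(df: pd.DataFrame, strict: bool = True) -> list[AminoAcidProfile]:
    """Build profiles from an in-memory long-format frame (see ``read_profiles``)."""
    rows = []
    for i, row in df.iterrows():
        try:
            aa = normalize_aa(str(row["aa"]))
        except IngestError:
            if strict:
                raise
            logger.warning(
                "skipping row %s (specimen %r): unknown amino acid %r",
                i, row["specimen_id"], row["aa"],
            )
            continue
        rows.append((row, aa))

    profiles: list[AminoAcidProfile] = []
    by_specimen: dict[str, list] = {}
    order: list[str] = []
    for row, aa in rows:
        sid = str(row["specimen_id"])
        if sid not in by_specimen:
            by_specimen[sid] = []
            order.append(sid)
        by_specimen[sid].append((row, aa))

    for sid in order:
        group = by_specimen[sid]
        aa_d15n: dict[str, float] = {}
        aa_sd: dict[str, float] = {}
        n_reps: dict[str, int] = {}
        for row, aa in group:
            if aa in aa_d15n:
                raise IngestError(f"duplicate (specimen, amino acid) rows for {sid!r} / {aa}")
            aa_d15n[aa] = float(row["d15n"])
            if "sd" in row.index and pd.notna(row.get("sd")):
                aa_sd[aa] = float(row["sd"])
            if "n_reps" in row.index and pd.notna(row.get("n_reps")):
                n_reps[aa] = int(row["n_reps"])
        first = group[0][0]
        profiles.append(
            AminoAcidProfile(
                specimen_id=sid,
                species=str(first["species"]),
                tissue=str(first["tissue"]),
                aa_d15n=aa_d15n,
                aa_sd=aa_sd or None,
                n_replicates=n_reps or None,
            )
        )
    return profiles


def profiles_to_long(profiles: Iterable[AminoAcidProfile]) -> pd.DataFrame:
    """Flatten profiles to the canonical long layout (full precision)."""
    records = []
    for p in profiles:
        for aa in sorted(p.aa_d15n):
            records.append(
                {
                    "specimen_id": p.specimen_id,
                    "species": p.species,
                    "tissue": p.tissue,
                    "aa": aa,
                    "d15n": p.aa_d15n[aa],
                    "sd": (p.aa_sd or {}).get(aa),
                    "n_reps": (p.n_replicates or {}).get(aa),
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["specimen_id", "species", "tissue", "aa", "d15n", "sd", "n_reps"]
    )


def write_profiles(profiles: Iterable[AminoAcidProfile], path, sep: str = ",") -> None:
    """Write profiles as tidy long-format delimited text at full precision."""
    df = profiles_to_long(profiles)
    df.to_csv(path, sep=sep, index=False, float_format="%.15g")


def summarize_by_group(
    profiles: Sequence[AminoAcidProfile],
    group_keys: Sequence[str] = ("species", "tissue"),
) -> pd.DataFrame:
    """Per-group mean, sample SD (n-1 denominator) and n of δ15N_Glx-Phe and each amino acid.

    Groups with a single member report the SD as missing. Specimens lacking
    Glx or Phe contribute to per-amino-acid summaries but not to the
    δ15N_Glx-Phe column.
    """
    records = []
    for p in profiles:
        rec = {k: getattr(p, k) for k in group_keys}
        rec.update({f"d15n_{aa}": v for aa, v in p.aa_d15n.items()})
        if {"Glx", "Phe"} <= set(p.aa_d15n):
            rec["d15n_glx_phe"] = glx_phe_difference(p)
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    value_cols = [c for c in df.columns if c not in group_keys]
    out = df.groupby(list(group_keys), sort=True)[value_cols].agg(["mean", "std", "count"])
    out.columns = [f"{col}_{stat}".replace("count", "n") for col, stat in out.columns]
    return out.reset_index()
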