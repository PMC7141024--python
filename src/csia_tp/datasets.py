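"""Packaged study data: per-individual δ15N_Glx-Phe values and group-level means.

Two small delimited-text tables ship with the package:

* ``study_individual_deltas.csv`` — 60 per-individual consumer δ15N_Glx-Phe
  values across five cetacean species (bowhead whale, beluga, common
  dolphin, sperm whale, and fish-eating [FE] and marine-mammal-eating [MME]
  killer whale ecotypes) and three tissues, together with the published
  stomach-content trophic positions (TP_SC) and the published per-equation
  trophic-position estimates with their propagated SDs.
* ``study_group_means.csv`` — species × tissue mean ± SD of nine amino
  acids' δ15N values.

Known internal inconsistency of the published summaries, preserved as
printed: the bowhead-skin group's mean δ15N_Glx-Phe is quoted as 13.50‰,
while the ten per-individual values here average 13.59‰. Recomputed
summaries from this module therefore reproduce the per-individual values,
not every quoted rounding.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .profiles import AminoAcidProfile

#: Published stomach-content trophic positions by species.
STUDY_TP_SC: dict[str, float] = {
    "bowhead_whale": 3.2,
    "beluga": 4.0,
    "common_dolphin": 4.2,
    "fe_killer_whale": 4.3,
    "sperm_whale": 4.4,
    "mme_killer_whale": 5.0,
}


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("csia_tp.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_individual_deltas() -> pd.DataFrame:
    """The 60-row per-individual δ15N_Glx-Phe table with published TP columns."""
    return _read_packaged("study_individual_deltas.csv")


def load_group_means() -> pd.DataFrame:
    """Species × tissue × amino-acid mean ± SD table (long format)."""
    return _read_packaged("study_group_means.csv")


def make_study_fixture() -> tuple[list[AminoAcidProfile], pd.DataFrame]:
    """Profiles plus the Δ table for the study individuals.

    Per-individual measurements were published only as the Glx − Phe
    difference, so the returned profiles are *synthetic reconstructions*:
    each specimen's Phe is anchored at its species × tissue group-mean Phe
    value and Glx is set to Phe + Δ. Because Δ-based estimation is
    translation-invariant, trophic positions computed from these profiles
    under the Δ-based equations are exactly those implied by the published
    per-individual differences; the profiles carry no other amino acids, so
    the multi-amino-acid equation correctly reports them as missing
    analytes.
    """
    deltas = load_individual_deltas()
    means = load_group_means()
    phe_by_group = {
        (r.species, r.tissue): r.mean_d15n
        for r in means[means.aa == "Phe"].itertuples()
    }
    profiles = []
    for row in deltas.itertuples():
        phe = phe_by_group[(row.species, row.tissue)]
        profiles.append(
            AminoAcidProfile(
                specimen_id=row.specimen_id,
                species=row.species,
                tissue=row.tissue,
                aa_d15n={"Phe": phe, "Glx": phe + row.d15n_glx_phe},
            )
        )
    return profiles, deltas
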