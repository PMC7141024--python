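# csia-tp

Trophic-position estimation from compound-specific stable-isotope analysis
of amino acids (CSIA-AA), built for marine-mammal ecologists working with
δ¹⁵N profiles of individual amino acids in tissues such as skin, baleen and
dentine collagen.

## The problem and the model

"Trophic" amino acids (Glx, Asx, Ala, Ile, Leu, Pro, Val) become enriched
in ¹⁵N with each trophic transfer, while "source" amino acids (canonically
Phe) conserve the primary-producer baseline. The difference
δ¹⁵N_Glx-Phe = δ¹⁵N_Glx − δ¹⁵N_Phe therefore carries an internally
baseline-corrected trophic-position (TP) signal. Four published
equation/TDF (trophic discrimination factor) frameworks turn it into a TP
estimate:

| id | equation | framework name |
|----|----------|----------------|
| 1 | TP = (δ¹⁵N_Glx-Phe − β) / TDF + 1 | `chikaraishi_single` |
| 2 | TP = (δ¹⁵N_Σtrophic − δ¹⁵N_Σsource − β) / TDF + 1 | `multi_aa` |
| 3 | TP = (δ¹⁵N_Glx-Phe − TDF_seal − β) / TDF + 2 | `germain_dual` |
| 4 | TP = (δ¹⁵N_Glx-Phe − TDF − β) / TDF_penguin + 2 | `mcmahon_dual` |

with β = 3.4 ± 0.9 ‰ (producer-level Glx−Phe offset in marine
algae/cyanobacteria), TDF = 7.6 ± 1.2 ‰ (per-step discrimination in
invertebrates/fish), TDF_seal = 4.3 ± 1.2 ‰ (applied to the final transfer
only) and TDF_penguin = 3.5 ± 0.4 ‰ (applied to all transfers after the
first). Parameter and measurement uncertainty is propagated to the TP by a
first-order Taylor expansion, validated against a Monte-Carlo oracle.
Diet-weighted stomach-content trophic positions
(TP_SC = 1 + Σᵢ pᵢ·TPᵢ over prey items) provide the independent comparison,
and a forward food-web fractionation simulator generates consumer profiles
at known TP so the whole chain can be tested end-to-end.

The package ships a 60-specimen fixture of published per-individual
δ¹⁵N_Glx-Phe values for five cetacean species (bowhead whale, beluga,
common dolphin, sperm whale, and fish-eating [FE] and marine-mammal-eating
[MME] killer-whale ecotypes), plus species × tissue amino-acid means.

## Worked example

```python
from csia_tp import (DEFAULT_FRAMEWORKS, estimate_all, estimates_to_table,
                     make_study_fixture, STUDY_TP_SC)

profiles, deltas = make_study_fixture()
estimates = estimate_all(profiles, DEFAULT_FRAMEWORKS)
meta = {p.specimen_id: {"species": p.species, "tissue": p.tissue} for p in profiles}
table = estimates_to_table(estimates, meta=meta, diet_tps=STUDY_TP_SC)
print(table[["specimen_id", "species", "delta_glx_phe", "tp_sc",
             "tp_eq1", "tp_eq3", "tp_eq4"]].head(2).to_string(index=False))
```

prints

```
specimen_id       species  delta_glx_phe  tp_sc  tp_eq1  tp_eq3  tp_eq4
   bw-ba-01 bowhead_whale          12.40    3.2     2.2     2.6     2.4
   bw-ba-02 bowhead_whale          12.75    3.2     2.2     2.7     2.5
```

A bowhead baleen specimen with δ¹⁵N_Glx-Phe = 12.40 ‰ estimates at TP 2.2
under the single-TDF equation — a full trophic step below its
stomach-content TP of 3.2 — rising to 2.6 under the seal dual-TDF form.
Species-level deviations (`compare_to_stomach_content`) reproduce the
characteristic pattern: isotope-based estimates sit roughly 1–2.5 steps
below stomach-content values under the single TDF, the penguin dual-TDF
equation closes the gap for bowheads, belugas and FE killer whales, and
MME killer whales stay more than 2 steps low under every framework. See
`examples/` for runnable scripts covering estimation, uncertainty
propagation and forward simulation, and `docs/methods.md` for the model
assumptions.

A thin CLI wraps the same pipeline:

```sh
csia-tp estimate --input profiles.csv --out reports/
csia-tp simulate --tp 3 --n 50 --seed 1 --out sim.csv
csia-tp compare --input profiles.csv --diet diet.yaml --out deviations.csv
```

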