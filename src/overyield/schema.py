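"""Canonical column names for the plot-level species-yield CSV schema.

Every module exchanges data through this one schema: one row per
(study, plot, year, harvest, species) with the biomass of that species,
whether it was sown, its sown proportion, and the plot's N treatment.
"""

STUDY = "study_id"
PLOT = "plot_id"
YEAR = "year"
HARVEST = "harvest_index"
SPECIES = "species_id"
BIOMASS = "biomass_g_m2"
SOWN = "sown"
SOWN_PROP = "sown_proportion"
N_RATE = "n_rate_kg_ha_yr"
N_TREATMENT = "n_treatment"

#: required header of the canonical input CSV, in order
CANONICAL_COLUMNS = [
    STUDY,
    PLOT,
    YEAR,
    HARVEST,
    SPECIES,
    BIOMASS,
    SOWN,
    SOWN_PROP,
    N_RATE,
    N_TREATMENT,
]

#: columns of the partition-result output CSV
PARTITION_COLUMNS = [
    STUDY,
    PLOT,
    YEAR,
    "richness",
    "nbe",
    "ce",
    "se",
    "ryt",
    "flags",
]

#: columns of the exposure output CSV
EXPOSURE_COLUMNS = [
    STUDY,
    PLOT,
    YEAR,
    "annual_rate_total",
    "cum_experimental",
    "cum_deposition",
    "cum_total",
]
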