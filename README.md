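# copelink

Small copepods (<2 mm) dominate marine zooplankton and are usually
modelled as grazers of unicellular plankton — phytoplankton, ciliates,
heterotrophic dinoflagellates. Gut-content sequencing shows they also
eat metazoan prey (crustacean larvae, bivalve larvae, fish, even other
copepods), a trophic pathway missing from global ecosystem models.
`copelink` implements the estimation chain that scales this
**metazoan-copepod link** to a global annual carbon flux, and the
gut-content OTU analysis that motivates it. It is aimed at plankton
ecologists and biogeochemical modellers who want the chain reproducible,
parameterised and testable.

## The model

The chain is closed-form arithmetic on a small set of published
parameters:

1. **Composition** — plankton-database records are filtered to adults
   and copepodites caught above 100 m with fine mesh (100–116 µm); the
   abundance-weighted order shares give per-realm profiles (coastal:
   60.5% calanoids, 39.5% cyclopoids with poecilostomatoids merged;
   oceanic: 91.3% / ~6%).
2. **Standing stock** — the global mesozooplankton stock in the top
   100 m, corrected and partitioned:
   `B_adult = z0 · (1 + 1/3) · f_copepod · f_adult = 0.31 · 4/3 · 0.8 · 0.6 = 0.1984 GtC`,
   then split by the realm profile into calanoid and cyclopoid stocks.
3. **WSIR** — weight-specific ingestion rates (µgC prey · µgC
   copepod⁻¹ · d⁻¹) from a feeding-rate meta-analysis, fitted as a
   log-log allometry `log10 I = a + b·log10 M` and evaluated at the
   group mean mass; canonical defaults are 0.023 / 0.063 (field) and
   0.396 / 0.241 (laboratory) for calanoids / cyclopoids.
4. **Annual ingestion** —
   `I_annual = (B_cal·WSIR_cal + B_cyc·WSIR_cyc) · 365`,
   over 2 realms × 2 settings, spanning 1.79–27.2 GtC/yr.
5. **C/N flux budget** — copepod physiology closes carbon exactly
   (growth 0.3 I + respiration 0.4 I + egestion 0.3 I = I, with
   AE = 0.7, GGE = 0.3); nitrogen enters via prey C:N ratios (6.6
   phytoplankton, 5.0 ciliates, 6.86 metazoans) with 20% excreted as
   NH₄⁺ and 40% released in pellets/debris; exports follow fixed
   fractions (8% HTL, 8% remineralization, 3–5% DOM, sinking = 3% of
   egestion). Headline percentages relate the link to primary
   production and to unicellular ingestion.
6. **Gut content** — ~200 bp 16S clone libraries are clustered into
   OTUs at <1% divergence (greedy centroid, global alignment) and the
   copepod × OTU incidence matrix yields per-condition diet summaries.

A synthetic-data module generates all three input families (abundance
tables, ingestion records, clone libraries) with planted ground truth,
so every estimator is validated by parameter recovery.

## Worked example

```sh
$ copelink stock
paper_replication  coastal  adult=0.1984 cal=0.1200 cyc=0.0780 GtC
paper_replication  oceanic  adult=0.1984 cal=0.1811 cyc=0.0117 GtC
best_practice      coastal  adult=0.1984 cal=0.1200 cyc=0.0784 GtC
best_practice      oceanic  adult=0.1984 cal=0.1811 cyc=0.0125 GtC

$ copelink ingest
coastal  field         2.80 GtC/yr
coastal  laboratory   24.21 GtC/yr
oceanic  field         1.79 GtC/yr
oceanic  laboratory   27.21 GtC/yr

$ copelink otus
16 OTUs total; per condition {'downwelling': 7, 'upwelling': 12}; per phylum {'Crustacea': 13, 'Mollusca': 2, 'Chordata': 1}; t=-0.291 p=0.775
```

The stock lines are the adult copepod stock (0.1984 GtC) split by realm
composition — coastal calanoids hold 0.12 GtC, oceanic calanoids
0.181 GtC. The ingestion grid spans the global range of the link:
field-rate scenarios put it at 1.79–2.80 GtC/yr, laboratory rates at
24.2–27.2 GtC/yr. The OTU line summarises the packaged prey-incidence
matrix: 16 metazoan prey taxa across 17 copepod species, with no
significant richness difference between upwelling and downwelling.

The flux budget over the field range prints, among other lines:

```sh
$ copelink budget
...
pct_of_PP: [3.977, 6.224]
pct_increment_over_unicellular: [15.58, 24.38]
pct_PP_indirect: [18.94, 29.64]
N_regeneration_ratio: [1.139, 1.217]
```

i.e. the link is 4.0–6.2% of primary production, a 15.6–24.4% increment
over unicellular ingestion (8.67 + 2.82 GtC/yr), routes 18.9–29.7% of
PP to copepods indirectly through their metazoan prey, and raises
regenerated nitrogen by up to a factor 1.22.

`copelink run --out-dir out/` writes the full report bundle (scenario
table, budget edge list + DOT graph, diet summary, provenance block);
`copelink synth` generates the synthetic input families. Python API:
see the module docstrings (`copelink.stocks`, `copelink.budget`, …).

## Input schemas

* Abundance CSV: `station_id, realm, depth_m, mesh_um, order, stage,
  abundance` (orders: calanoid, cyclopoid, harpacticoid,
  poecilostomatoid, other; stages: adult, copepodite, nauplius).
* Ingestion CSV: `group, setting, diet, body_mass_ugC,
  ingestion_ugC_per_day`.
* Clone libraries: multi-FASTA with headers `>copepodID|cloneN`, plus a
  `copepod,condition` CSV.

See `docs/methods.md` for model assumptions, parameter defaults and
known limitations.
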