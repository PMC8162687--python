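# platekit

Headless library and CLI for managing multi-well plate layouts and the
data that comes off plate readers. It targets the everyday bookkeeping of
screening and assay-development labs: declaring *what is in each well* of
a 6- to 1536-well plate (samples, self-numbering compound ranges,
positive/negative controls, concentrations and serial dilutions, stacked
on independent layers for combination experiments), binding the
well-per-row result lists that readers emit, and turning the two into
quality-control and aggregation tables ready for downstream analysis.

## The model

A **layout** is an ordered set of **layers**, each mapping wells to at
most one **area** tag. Areas are typed — `sample`, `range`,
`positive_control`, `negative_control` — and in the default *strict*
tagging mode a well may never carry both a control tag and a
sample/range tag, on any combination of layers. **Ranges** are
self-incrementing sample areas: tagging a block assigns item indices
1, 2, … in a scan order controlled by a replicate count, a direction
(horizontal/vertical) and a priority (row/column); item names resolve
through a *definition file* (a list mapping indices or wells to compound
names, per plate). Overlapping layers encode factorials: a well tagged
`CellA` on layer 1 and `VirusA` @ MOI 5 on layer 2 belongs to the
CellA × VirusA × MOI 5 condition, and the analysis tools enumerate every
such unique combination automatically.

Aggregation uses the population statistics

```
SD = sqrt( (1/n) Σ (xᵢ − Avg)² )        CV = 100 × SD / Avg   (%)
```

and assay quality for each positive × negative control pair is scored by
the Z-factor and signal window

```
Z′ = 1 − 3 (SD₊ + SD₋) / |Avg₊ − Avg₋|       W = max(Avg₊, Avg₋) / min(Avg₊, Avg₋)
```

Z′ is 1 for a noiseless assay and conventionally excellent above 0.5.
Degenerate cases (equal control means, a zero mean) become typed
"undefined" cells rendered blank in exports, never mid-report exceptions.

Result files (CSV/TSV with sniffed delimiter, or xlsx) are streamed row
by row, so multi-plate files of hundreds of thousands of rows never need
to fit in memory. Values bind to wells through a column mapping (any
column whose name contains "well" is auto-assigned to the Well ID; an
optional Plate ID column splits the file into plates, otherwise the
repetition count of each well name does). Heatmap support normalizes
values to a three-color ramp against a global, per-plate or custom
min/max domain, with a palette of 138 uniquely-valued named colors.

## Worked example

Generate a synthetic 3-plate primary screen (96-well: an 80-compound
range, a solvent column as negative control, an inhibitor column as
positive control) and run the controls QC:

```
$ platekit fixtures make screening --plates 3 --seed 1 --out demo
$ platekit analyze controls --layout demo/screening_layout.json \
      --results demo/screening_results.csv --print
== controls/plate_Plate_1.tsv ==
Control Avg     SD      N
Inhibitor       8.79594 4.24537 8
Solvent 99.7498 2.90723 8
== controls/plate_Plate_1_zprime.tsv ==
Positive        Negative        Z'      Window
Inhibitor       Solvent 0.764081        11.3404
...
== controls/summary.tsv ==
Positive        Negative        Metric  Avg     SD      N
Inhibitor       Solvent z_prime 0.704437        0.0434018       3
Inhibitor       Solvent window  10.8458 0.395547        3
```

Each plate table aggregates the 8 wells of each control with average,
population SD and count; the pair table scores the assay (here
Z′ ≈ 0.70 — an excellent separation between the ~100-signal solvent
wells and the ~10-signal inhibitor wells — with a ~10.8-fold window);
the summary averages Z′ and window over the 3 visited plates. The same
pattern drives `analyze columns` (one statistics column per unique
combination, with optional compound-name resolution through
`--defs`) and `analyze grouped` (a two-entry table, e.g.
`--rows conc --cols range` for a 10-dose × 6-compound dose-response
matrix), and `heatmap export` writes a per-well hex-color TSV.
All analysis commands accept `--out DIR`, `--zip FILE` and `--print`.

The same operations are ordinary library calls
(`platekit.controls_report`, `platekit.column_analysis`,
`platekit.grouped_analysis`, …) for use from notebooks and pipelines.

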