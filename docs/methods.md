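# Methods notes

## Plate model

Supported geometries are the seven standard rectangular formats (6, 12,
24, 48, 96, 384, 1536 wells) in their conventional 2:3-family shapes;
non-standard shapes are rejected at construction. Wells are 0-based
`(row, col)` pairs internally; all text I/O uses letter + 1-based-column
names. Row letters beyond `Z` continue `AA…AF` (bijective base-26),
chosen because it is the only widely used convention producing 32
distinct labels for 1536-well plates. Names parse case-insensitively and
tolerate zero-padded columns (`a01` ≡ `A1`) because plate readers
disagree on padding; emitted names are always uppercase and unpadded.
The row-major index `row × n_cols + col` defines the "first well" of a
multi-well range item, which is the well used for name resolution.

## Tagging semantics

* A layer holds at most one tag per well; re-tagging overwrites.
* Strict mode (default) rejects any tagging that would leave a well with
  both a control tag and a sample/range tag, **across all layers and
  including the tag being replaced** — converting a sample well into a
  control well is deliberately a permissive-mode operation, so that a
  strict-built layout can never pass through an inconsistent state.
  `validate_layout` re-checks the invariant on loaded documents.
* Range numbering scan order: *direction* fixes the axis along which one
  item's `replicates` wells are contiguous (horizontal = consecutive
  columns, vertical = consecutive rows); *priority* fixes the axis along
  which successive items advance first. Concretely, horizontal/row is
  plain row-major grouping, vertical/column plain column-major;
  horizontal/column stacks items downward within a band of `replicates`
  columns before moving to the next band, vertical/row advances items
  rightward within a band of `replicates` rows. Bands are computed
  relative to the selection's bounding box, so a block numbers the same
  wherever it sits on the plate. Non-rectangular selections are simply
  grouped in the same scan order over whatever wells are present, and a
  trailing group smaller than `replicates` still receives the next index
  — erroring would block common ragged layouts. Tagging a non-custom
  range continues numbering after the highest index that area already
  carries on the layer (self-incrementing across tagging gestures);
  the pure `assign_range_indices` always starts at 1.
* Concentrations `(value > 0, unit)` annotate an existing area tag
  (last write wins) and are part of the combination identity, so two
  MOI levels on the same virus area yield two conditions. Dose-response
  tagging lays `top / fold^k` (k = 0…n−1) across the selection in the
  same scan-order machinery with `|selection| / n_doses` replicate wells
  per dose; the selection must divide evenly.

## File binding

Delimited text is sniffed among comma/semicolon/tab; xlsx is read
through openpyxl in read-only mode, cell values normalized to the text
their CSV export would carry (dates returned as spreadsheet serial
numbers, not interpreted; integral floats printed without a decimal
point). Both paths satisfy the same row-iterator contract — one record
per data row, header consumed for names, no whole-file materialization —
so a CSV and its xlsx counterpart stream identical records. Legacy
binary `.xls` is out of scope; files should be converted to xlsx or CSV.

Plate indexing without a Plate ID column uses the occurrence rule: the
j-th repetition of a well name belongs to synthetic plate j, and the
number of plates is the maximum multiplicity of any well name. Duplicate
(plate, well) rows keep the last value and warn — deterministic and
consistent with overwrite-on-read. Unparseable numeric cells become
missing values and are excluded from every aggregation (N counts
included values only).

Definition name resolution implements the four mapping configurations
(no columns / Well ID / Plate ID / both) with item index `i` 1-based and
plate position `j` 0-based — the only base assignment under which the
row-counting rule `i + n × j` lands on row `i` for the first plate. For
the well-only configuration the `(j+1)`-th occurrence of the item's
first-well ID is used, consistent with that choice. Resolution is total:
every miss falls back to the generic `"RangeName (#i)"`.

The layout JSON schema (`schema_version: 1`) is defined by this package
and validated structurally on load, with JSON-path error locations; no
import of any third-party layout format is promised.

## Analyses

SD uses the population divisor *n* to match the printed statistics the
tables are meant to reproduce (a sample-SD variant is a one-line change
but is deliberately not a switch). Z′/Window undefined cases propagate
as typed `Undefined` values rendered blank, so one degenerate pair
cannot abort a multi-plate report. The window is undefined when the
smaller control mean is exactly zero; control means are assumed
positive — with a negative mean the ratio is reported as computed and
is not meaningful. The cross-plate controls summary takes average/SD/N
of the per-plate Z′ and window values, over defined values only; with
well-behaved controls that N equals the number of visited plates.

Combination keys order components by layer id; list ordering is layers
by id, then area name, range item index, concentration descending
(dose-response reading order, top dose first). Grouped-table axes are
concentration series (sorted descending), range items (by index, with
optional name resolution) or area sets; `average` mode emits the mean
only, `full` the whole summary.

## Heatmaps

Normalization clamps out-of-domain values to 0/1 instead of erroring so
a fixed custom domain survives plate browsing, and a constant domain
maps everything to 0.5 (uniform mid color rather than a division by
zero). Color mapping is piecewise-linear per channel, low→mid on
[0, 0.5] and mid→high on [0.5, 1], rounded half-up to 8-bit. The palette
is the CSS3 extended named-color list with alias spellings collapsed
(gray/grey, aqua/cyan, …), which leaves exactly 138 uniquely-valued
entries; the default ramp is blue–white–red. The TSV hex-grid export
exists so heatmaps can be tested bit-exactly; PNG rendering via
matplotlib is optional sugar.

## Synthetic fixtures

The three generators emulate the layouts and file shapes of real
screening campaigns with controllable ground truth; they do not emulate
spatial artifacts (edge effects, drift), reader-specific headers, or
non-normal noise, so passing recovery tests demonstrates correctness of
the bookkeeping and statistics, not robustness to instrument pathology.

* **screening** — 3 × 96-well plates by default: negative control mean
  100, positive control mean 10, SD 5 (a typical normalized-viability
  scale with a 10-fold window), hit rate 5% with hits drawn from the
  positive distribution. Definition file keyed by plate name, so
  auto-pairing by name exercises the Plate-ID resolution rule.
* **drc** — 6 compounds × 10 doses, 2-fold from a 20 µM top (written
  `uM` in files to keep them ASCII-clean). Responses follow the
  saturation form `5 + 100·c/(c + EC50)` with per-compound EC50
  log-uniform on [0.05, 5] µM and SD-2 noise; the mean response is
  strictly decreasing along the dilution, which the zero-noise test
  checks. The dose overlay uses vertical/column ordering so each plate
  column is one dose across the six compound rows, while the compound
  range itself uses the default horizontal/row order with 10 replicates.
* **infection** — two cell types (row halves, layer 1) × two virus
  strains (column halves, layer 2) × MOI 5/20 (tagged on the virus
  layer): 8 conditions of 12 wells with distinct means 20…90 in steps of
  10 and SD-3 noise, giving a per-condition standard error of ≈0.87 for
  the 3-SE recovery check.

All generators derive every draw from one `numpy` generator seeded by
the caller, and format values at fixed precision, so outputs are
byte-identical for a fixed seed.

## Problem sizes

The test suite and the acceptance script run the fixtures at their
natural sizes (1–3 plates of 96 wells), 200 randomized layouts for the
serialization round-trip, 1000 random vectors for the statistics
oracle, and 100 random rectangles × 4 modes for the numbering
properties — sizes at which every behavior under test is already fully
exercised and the whole suite completes in seconds.

## Known limitations

No curve fitting/IC50, hit calling or significance testing (the tables
are inputs to those tools, not replacements); no binary `.xls`; no
rendering beyond the optional PNG; strict-mode semantics are defined
across layers, which is the conservative reading when a well-level rule
is stated without layer qualification.
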