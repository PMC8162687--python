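"""Serialization round-trips, streaming parsers, mapping and pairing."""

import json
import random
import warnings

import pytest

from platekit import (
    AreaKind,
    ColumnMapping,
    Concentration,
    DefinitionSource,
    Layout,
    MappingError,
    PairingError,
    PlateGeometry,
    ResultSet,
    ValidationError,
    WellRef,
    WellTag,
    auto_map_columns,
    fetch_plate_values,
    load_layout,
    pair_plates,
    resolve_range_name,
    save_layout,
    stream_rows,
    well_name,
)
from platekit.fixtures import infection_layout, screening_layout
from platekit.layout_core import Area, Direction, Layer, Priority, RangeSpec


def random_layout(rng: random.Random) -> Layout:
    """A structurally valid randomized layout (not necessarily strict)."""
    geometry = PlateGeometry.from_format(rng.choice([6, 24, 96]))
    kinds = list(AreaKind)
    areas = {}
    for name in ["Alpha", "Beta", "Gamma"][: rng.randint(1, 3)]:
        kind = rng.choice(kinds)
        spec = None
        if kind is AreaKind.RANGE:
            spec = RangeSpec(
                rng.randint(1, 4),
                rng.choice(list(Direction)),
                rng.choice(list(Priority)),
                rng.random() < 0.2,
            )
        areas[name] = Area(name, kind, rng.choice(["red", "blue", ""]), spec)
    layers = []
    for lid in range(1, rng.randint(1, 3) + 1):
        layer = Layer(id=lid)
        for _ in range(rng.randint(0, 10)):
            well = WellRef(
                rng.randrange(geometry.n_rows), rng.randrange(geometry.n_cols)
            )
            name = rng.choice(list(areas))
            idx = (
                rng.randint(1, 20)
                if areas[name].kind is AreaKind.RANGE
                else None
            )
            conc = (
                Concentration(round(rng.uniform(0.01, 50), 3), rng.choice(["uM", "MOI"]))
                if rng.random() < 0.5
                else None
            )
            layer.tags[well] = WellTag(name, idx, conc)
        layers.append(layer)
    return Layout(geometry, layers, areas)


class TestLayoutJson:
    def test_empty_layout_roundtrip(self):
        layout = Layout(PlateGeometry.from_format(96))
        assert load_layout(save_layout(layout)) == layout

    def test_screening_layout_roundtrip(self):
        layout = screening_layout()
        doc = save_layout(layout)
        assert len(doc["areas"]) == 3 and len(doc["layers"]) == 1
        assert load_layout(doc) == layout

    def test_infection_layout_roundtrip_with_concentrations(self):
        layout = infection_layout()
        again = load_layout(save_layout(layout))
        assert again == layout
        tag = again.layers[1].tags[WellRef(0, 0)]
        assert tag.concentration == Concentration(5.0, "MOI")

    def test_roundtrip_identity_on_randomized_layouts(self):
        rng = random.Random(20240901)
        for _ in range(50):
            layout = random_layout(rng)
            assert load_layout(save_layout(layout)) == layout

    def test_document_is_json_serializable(self):
        json.dumps(save_layout(infection_layout()))

    @pytest.mark.parametrize(
        "mutate,path_fragment",
        [
            (lambda d: d.pop("geometry"), "$"),
            (lambda d: d["areas"][0].pop("kind"), "$.areas[0]"),
            (lambda d: d["layers"][0]["tags"].update(
                {"Z9": {"area": "Compounds", "range_index": 1}}), "tags"),
            (lambda d: d.update(schema_version=99), "schema_version"),
        ],
    )
    def test_schema_violations_carry_json_path(self, mutate, path_fragment):
        doc = save_layout(screening_layout())
        mutate(doc)
        with pytest.raises(ValidationError) as exc:
            load_layout(doc)
        assert path_fragment in exc.value.path

    def test_range_index_iff_range_area(self):
        doc = save_layout(screening_layout())
        doc["layers"][0]["tags"]["A1"] = {"area": "Compounds"}  # range, no index
        with pytest.raises(ValidationError):
            load_layout(doc)


def write(path, text):
    path.write_text(text, encoding="utf-8")
    return str(path)


class TestStreaming:
    def test_csv_rows_in_order(self, tmp_path):
        src = write(tmp_path / "t.csv", "Well,V\nA1,1\nA2,2\nA3,3\n")
        rows = list(stream_rows(src))
        assert rows == [{"Well": "A1", "V": "1"}, {"Well": "A2", "V": "2"},
                        {"Well": "A3", "V": "3"}]

    @pytest.mark.parametrize("delim", [",", ";", "\t"])
    def test_delimiter_sniffing(self, tmp_path, delim):
        src = write(tmp_path / "t.csv", f"Well{delim}V\nA1{delim}1\n")
        assert list(stream_rows(src)) == [{"Well": "A1", "V": "1"}]

    def test_empty_file_header_error(self, tmp_path):
        src = write(tmp_path / "empty.csv", "")
        with pytest.raises(MappingError):
            list(stream_rows(src))

    def test_ragged_row_padded_with_warning(self, tmp_path):
        src = write(tmp_path / "t.csv", "A,B,C\n1,2\n")
        with pytest.warns(UserWarning, match="ragged"):
            rows = list(stream_rows(src))
        assert rows == [{"A": "1", "B": "2", "C": ""}]

    def test_xlsx_matches_csv_export(self, tmp_path):
        """The same table as CSV and as xlsx yields identical records."""
        import openpyxl

        table = [["Well", "Plate", "Count"],
                 ["A1", "P1", "12"], ["B2", "P1", "3.25"], ["C3", "P2", "hello"]]
        src_csv = write(
            tmp_path / "t.csv", "\n".join(",".join(r) for r in table) + "\n"
        )
        wb = openpyxl.Workbook()
        ws = wb.active
        for row in table:
            ws.append(
                [float(c) if c.replace(".", "", 1).isdigit() else c for c in row]
            )
        src_xlsx = tmp_path / "t.xlsx"
        wb.save(src_xlsx)
        assert list(stream_rows(src_csv)) == list(stream_rows(str(src_xlsx)))

    def test_xls_rejected(self, tmp_path):
        src = write(tmp_path / "t.xls", "binary")
        with pytest.raises(MappingError, match="xls"):
            list(stream_rows(src))


class TestAutoMapping:
    def test_well_keyword_and_numeric_detection(self):
        header = ["Well", "Cell count", "Nuclei area", "Cell area", "Cell intensity"]
        mapping = auto_map_columns(header, ["A1", "120", "4.5", "300.2", "88"])
        assert mapping.well_col == "Well"
        assert mapping.param_cols == [
            ("Cell count", True), ("Nuclei area", True),
            ("Cell area", True), ("Cell intensity", True),
        ]

    def test_no_well_column_leaves_unset(self):
        mapping = auto_map_columns(["Barcode", "Value"], ["X", "1"])
        assert mapping.well_col is None

    def test_case_insensitive_substring(self):
        mapping = auto_map_columns(["WELL NAME", "conc"], ["a1", "text"])
        assert mapping.well_col == "WELL NAME"
        assert mapping.param_cols == [("conc", False)]

    def test_resultset_requires_well_and_param(self, tmp_path):
        with pytest.raises(MappingError):
            ResultSet("x.csv", ColumnMapping(well_col=None,
                                             param_cols=[("V", True)]))
        with pytest.raises(MappingError):
            ResultSet("x.csv", ColumnMapping(well_col="Well", param_cols=[]))


def make_results(tmp_path, text, plate_col=None):
    src = write(tmp_path / "r.csv", text)
    header = text.splitlines()[0].split(",")
    params = [(h, True) for h in header if h not in ("Well", plate_col)]
    return ResultSet(src, ColumnMapping("Well", plate_col, params))


class TestPlateIndexing:
    def test_named_plates_first_appearance_order(self, tmp_path):
        rs = make_results(
            tmp_path, "Plate,Well,V\nP1,A1,1\nP1,A2,2\nP2,A1,3\n", "Plate"
        )
        assert rs.plate_keys == ["P1", "P2"]

    def test_occurrence_count_rule(self, tmp_path):
        """Without a plate column, the key count is the maximum well-name
        multiplicity (brute-force count oracle)."""
        rows = ["Well,V"] + ["A1,%d" % i for i in (1, 2, 3)] + ["B1,9"]
        rs = make_results(tmp_path, "\n".join(rows) + "\n")
        occurrences = {}
        for line in rows[1:]:
            occurrences[line.split(",")[0]] = occurrences.get(line.split(",")[0], 0) + 1
        assert rs.plate_keys == list(range(1, max(occurrences.values()) + 1))

    def test_single_plate_when_each_well_once(self, tmp_path):
        rs = make_results(tmp_path, "Well,V\nA1,1\nA2,2\n")
        assert rs.plate_keys == [1]


class TestFetchValues:
    def test_named_plate_values(self, tmp_path, geo96):
        rs = make_results(
            tmp_path, "Plate,Well,V\nP1,A1,1.5\nP1,A2,2\nP2,A1,9\n", "Plate"
        )
        values = fetch_plate_values(rs, "P1", "V", geo96)
        assert values == {WellRef(0, 0): 1.5, WellRef(0, 1): 2.0}

    def test_occurrence_order_selects_jth_value(self, tmp_path, geo96):
        rs = make_results(tmp_path, "Well,V\nA1,1\nA1,2\nA1,3\n")
        assert fetch_plate_values(rs, 2, "V", geo96) == {WellRef(0, 0): 2.0}

    def test_unparseable_numeric_cell_missing(self, tmp_path, geo96):
        rs = make_results(tmp_path, "Well,V\nA1,oops\nA2,4\n")
        assert fetch_plate_values(rs, 1, "V", geo96) == {WellRef(0, 1): 4.0}

    def test_duplicate_pair_last_wins_with_warning(self, tmp_path, geo96):
        rs = make_results(
            tmp_path, "Plate,Well,V\nP1,A1,1\nP1,A1,7\n", "Plate"
        )
        with pytest.warns(UserWarning, match="duplicate"):
            values = fetch_plate_values(rs, "P1", "V", geo96)
        assert values == {WellRef(0, 0): 7.0}

    def test_unknown_plate_key_rejected(self, tmp_path, geo96):
        rs = make_results(tmp_path, "Well,V\nA1,1\n")
        with pytest.raises(MappingError):
            fetch_plate_values(rs, 5, "V", geo96)


class NameTable:
    """In-memory definition table with a brute-force row-scan resolver."""

    def __init__(self, rows):
        self.rows = rows  # list of dicts with Name / Well / Plate

    def brute_force(self, config, range_name, i, j, n, well_id=None, plate_id=None):
        fallback = f"{range_name} (#{i})"
        if config == "none":
            target = i + n * j
            if 1 <= target <= len(self.rows):
                return self.rows[target - 1]["Name"] or fallback
            return fallback
        if config == "well":
            hits = [r for r in self.rows if r["Well"].upper() == str(well_id).upper()]
            return hits[j]["Name"] if j < len(hits) else fallback
        if config == "plate":
            hits = [r for r in self.rows if r["Plate"] == plate_id]
            return hits[i - 1]["Name"] if 0 < i <= len(hits) else fallback
        hits = [
            r for r in self.rows
            if r["Well"].upper() == str(well_id).upper() and r["Plate"] == plate_id
        ]
        return hits[0]["Name"] if hits else fallback


CONFIG_COLS = {
    "none": {},
    "well": {"well_col": "Well"},
    "plate": {"plate_col": "Plate"},
    "both": {"well_col": "Well", "plate_col": "Plate"},
}


class TestNameResolution:
    def write_defs(self, tmp_path, rows):
        lines = ["Name,Well,Plate"] + [
            f"{r['Name']},{r['Well']},{r['Plate']}" for r in rows
        ]
        return write(tmp_path / "defs.csv", "\n".join(lines) + "\n")

    def test_row_formula_first_and_second_plate(self, tmp_path):
        """With no columns mapped, the name sits at data row i + n*j."""
        rows = [
            {"Name": f"N{k}", "Well": "", "Plate": ""} for k in range(1, 9)
        ]
        src = self.write_defs(tmp_path, rows)
        defn = DefinitionSource(src, "Name", n_items=4)
        assert resolve_range_name(defn, "R", 2, 0) == "N2"
        assert resolve_range_name(defn, "R", 2, 1) == "N6"

    def test_fallback_beyond_file_end(self, tmp_path):
        src = self.write_defs(tmp_path, [{"Name": "N1", "Well": "", "Plate": ""}])
        defn = DefinitionSource(src, "Name", n_items=4)
        assert resolve_range_name(defn, "Compounds", 7, 0) == "Compounds (#7)"

    @pytest.mark.parametrize("config", list(CONFIG_COLS))
    def test_matches_brute_force_oracle(self, tmp_path, config):
        """Randomized files under all four mapping configurations resolve
        identically to a brute-force row scan; every miss falls back."""
        rng = random.Random(f"defs-{config}")
        geometry = PlateGeometry.from_format(24)
        n = 6
        plates = ["P1", "P2", "P3"]
        rows = []
        for plate in plates:
            for i in range(n):
                if rng.random() < 0.15:
                    continue  # holes force fallbacks
                rows.append({
                    "Name": f"cmp-{plate}-{i + 1}",
                    "Well": well_name(geometry, WellRef(i // 4, i % 4)),
                    "Plate": plate,
                })
        rng.shuffle(rows)
        src = self.write_defs(tmp_path, rows)
        defn = DefinitionSource(src, "Name", n_items=n, **CONFIG_COLS[config])
        table = NameTable(rows)
        for i in range(1, n + 2):  # n+1 probes a guaranteed miss
            for j in range(len(plates) + 1):
                well_id = well_name(
                    geometry, WellRef((i - 1) // 4, (i - 1) % 4)
                ) if i <= n else "D6"
                plate_id = plates[j] if j < len(plates) else "P9"
                got = resolve_range_name(
                    defn, "R", i, j, well_id=well_id, plate_id=plate_id
                )
                expected = table.brute_force(
                    config, "R", i, j, n, well_id=well_id, plate_id=plate_id
                )
                assert got == expected, (config, i, j)
                assert isinstance(got, str) and got  # resolution is total

    def test_both_columns_independent_of_row_order(self, tmp_path):
        rows = [
            {"Name": f"cmp{i}{p}", "Well": f"A{i}", "Plate": p}
            for p in ("P1", "P2") for i in (1, 2, 3)
        ]
        shuffled = rows[::-1]
        src1 = self.write_defs(tmp_path, rows)
        src2 = write(
            tmp_path / "defs2.csv",
            "Name,Well,Plate\n"
            + "\n".join(f"{r['Name']},{r['Well']},{r['Plate']}" for r in shuffled)
            + "\n",
        )
        for src in (src1, src2):
            defn = DefinitionSource(src, "Name", "Well", "Plate", 3)
            assert resolve_range_name(
                defn, "R", 2, 0, well_id="A2", plate_id="P2"
            ) == "cmp2P2"


class TestPairing:
    def test_auto_by_name(self):
        pm = pair_plates(["P1", "P2"], ["P2", "P1"], "auto_by_name")
        assert pm.pairs == {"P1": ["P1"], "P2": ["P2"]}

    def test_unmatched_result_plate_warns(self):
        with pytest.warns(UserWarning, match="no matching"):
            pm = pair_plates(["P1"], ["D1"], "auto_by_name")
        assert pm.definition_plates("P1") == []

    def test_by_index_positional(self):
        pm = pair_plates(["P1", "P2"], ["D1", "D2"], "by_index")
        assert pm.pairs == {"P1": ["D1"], "P2": ["D2"]}

    def test_manual_unknown_key_rejected(self):
        with pytest.raises(PairingError):
            pair_plates(["P1"], ["D1"], "manual", manual={"P9": ["D1"]})
        with pytest.raises(PairingError):
            pair_plates(["P1"], ["D1"], "manual", manual={"P1": ["D9"]})
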