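"""RDF graph shape, serialization round-trips, BGP queries, CSV and CCC."""

from __future__ import annotations

import numpy as np
import pytest
from rdflib import Graph

from fairomics.features import FeatureResult
from fairomics.semantic import (
    FO,
    LOCAL,
    RO,
    CaseProvenance,
    build_graph,
    ccc,
    default_mapping,
    map_feature,
    parse_graph,
    query,
    serialize,
    to_csv,
)


def fake_features(n=6, fp="cfgfp"):
    out = []
    names = [("firstorder", "Entropy", "TLU2"), ("glcm", "Joint Entropy", "TU9B")]
    for i in range(n):
        fam, name, code = names[i] if i < len(names) else ("glrlm", f"Feature {i}", None)
        out.append(FeatureResult(fam, name, float(i) + 0.125, ibsi_code=code,
                                 config_fingerprint=fp))
    return out


@pytest.fixture
def prov():
    return CaseProvenance(patient_id="P-7", voi_name="GTV-1",
                          settings={"bin_width": 25, "resample_spacing": None})


class TestMapping:
    def test_paper_anchored_ibsi_codes(self):
        assert map_feature("firstorder/Entropy") == RO["TLU2"]
        assert map_feature("glcm/Joint Entropy") == RO["TU9B"]

    def test_unknown_name_falls_back_to_deterministic_local_iri(self):
        a = map_feature("my_custom feature!")
        assert a == LOCAL["my_custom_feature"]
        assert map_feature("my_custom feature!") == a

    def test_builtin_table_covers_the_whole_panel(self):
        from fairomics.features import PANEL

        table = default_mapping()
        assert len(table.rows) == 105
        assert sum(1 for _, src in table.rows.values() if src == "ibsi") == 2
        for family, names in PANEL.items():
            for name in names:
                assert f"{family}/{name}" in table.rows


class TestGraphShape:
    def test_value_literal_and_software_node_counts(self, prov):
        g = build_graph(fake_features(105), prov)
        assert len(list(g.triples((None, FO.hasValue, None)))) == 105
        assert len(set(g.subjects(FO.softwareVersion, None))) == 1

    def test_two_vois_share_one_patient_node(self, prov):
        g = build_graph(fake_features(5), prov)
        prov2 = CaseProvenance(patient_id="P-7", voi_name="GTV-2")
        build_graph(fake_features(5), prov2, graph=g)
        assert len(set(g.subjects(FO.patientID, None))) == 1
        assert len(set(g.objects(None, FO.ofVOI))) == 2

    def test_empty_feature_list_is_an_error(self, prov):
        with pytest.raises(ValueError):
            build_graph([], prov)

    def test_missing_patient_id_is_an_error(self):
        with pytest.raises(ValueError, match="patient"):
            build_graph(fake_features(2), CaseProvenance(patient_id="", voi_name="v"))


class TestSerialization:
    @pytest.mark.parametrize("fmt,suffix", [("turtle", ".ttl"), ("ntriples", ".nt")])
    def test_round_trip_is_identity_on_triple_sets(self, tmp_path, prov, fmt, suffix):
        g = build_graph(fake_features(8), prov)
        path = serialize(g, tmp_path / f"g{suffix}", fmt)
        back = parse_graph(path)
        assert set(g) == set(back)

    def test_empty_graph_serializes_to_parseable_document(self, tmp_path):
        path = serialize(Graph(), tmp_path / "e.nt", "ntriples")
        assert len(parse_graph(path)) == 0

    def test_merging_two_runs_is_set_union(self, tmp_path, prov):
        g1 = build_graph(fake_features(4, fp="runA"), prov)
        prov_b = CaseProvenance(patient_id="P-7", voi_name="GTV-1",
                                software_version="9.9")
        g2 = build_graph(fake_features(4, fp="runB"), prov_b)
        merged = Graph()
        for t in g1:
            merged.add(t)
        for t in g2:
            merged.add(t)
        assert set(merged) == set(g1) | set(g2)


class TestCsvAndQueryConsistency:
    def test_csv_has_one_row_per_feature_with_codes(self, tmp_path, prov):
        feats = fake_features(6)
        df = to_csv(feats, prov, tmp_path / "f.csv")
        assert len(df) == 6
        text = (tmp_path / "f.csv").read_text().splitlines()
        assert text[0] == "patient_id,voi,family,name,ibsi_code,value"
        assert len(text) == 7

    def test_empty_selection_gives_header_only_file(self, tmp_path, prov):
        df = to_csv([], prov, tmp_path / "f.csv")
        assert len(df) == 0
        assert (tmp_path / "f.csv").read_text().strip() == (
            "patient_id,voi,family,name,ibsi_code,value"
        )

    def test_graph_and_csv_agree_bit_for_bit(self, prov):
        feats = fake_features(6)
        g = build_graph(feats, prov)
        df = to_csv(feats, prov)
        graph_values = sorted(
            str(v) for v in query(g, "?f fo:hasValue ?v")["v"]
        )
        assert graph_values == sorted(df["value"])


class TestQueryEngine:
    def test_single_pattern_single_row(self, prov):
        g = build_graph(fake_features(6), prov)
        res = query(g, "?f a ro:TLU2 . ?f fo:hasValue ?v")
        assert list(res.columns) == ["f", "v"]
        assert len(res) == 1
        assert float(res["v"][0]) == 0.125

    def test_empty_graph_gives_empty_table(self):
        assert len(query(Graph(), "?s ?p ?o")) == 0

    def test_malformed_term_is_an_error(self, prov):
        g = build_graph(fake_features(2), prov)
        with pytest.raises(ValueError):
            query(g, "?f badtoken ?v")

    def test_five_variable_provenance_query_separates_software(self, prov):
        """Merged graph of two software runs; the query attributes each value."""
        g = build_graph(fake_features(2, fp="runA"), prov)
        prov_b = CaseProvenance(
            patient_id="P-7", voi_name="GTV-1", software_name="matlab-toolbox",
            software_version="2.1", software_language="MATLAB",
        )
        build_graph(fake_features(2, fp="runB"), prov_b, graph=g)
        res = query(
            g,
            "?f rdfs:label ?name . ?f fo:hasValue ?value . "
            "?f fo:computedBy ?s . ?s fo:softwareVersion ?version . "
            "?s fo:programmingLanguage ?language . "
            "?f fo:ofVOI ?voi . ?voi fo:ofPatient ?p . ?p fo:patientID ?pid",
        )
        assert set(res.columns) >= {"name", "value", "version", "language", "pid"}
        assert len(res) == 4  # 2 features x 2 software runs
        assert set(res["language"]) == {"Python", "MATLAB"}
        assert set(res["pid"]) == {"P-7"}


class TestCCC:
    def test_identity_gives_one(self):
        x = np.array([0.3, 1.7, 2.9, 5.0])
        assert ccc(x, x) == pytest.approx(1.0)

    def test_hand_formula_on_reversed_triplet(self):
        # x=(1,2,3), y=(3,2,1): cov=-2/3, var=2/3 each, equal means
        # CCC = 2(-2/3) / (4/3) = -1, consistent with CCC = r at equal moments
        assert ccc([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_equal_moments_reduces_to_pearson(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = np.roll(x, 7)  # same moments, decorrelated
        r = float(np.corrcoef(x, y)[0, 1])
        assert ccc(x, y) == pytest.approx(r, abs=1e-12)

    def test_scale_shift_penalty_bounds_ccc_by_pearson(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        y = 3.0 * x + 2.0
        r = float(np.corrcoef(x, y)[0, 1])
        assert ccc(x, y) < abs(r)

    def test_symmetry_and_constant_convention(self):
        x = [1.0, 2.0, 5.0]
        y = [2.0, 2.5, 3.0]
        assert ccc(x, y) == pytest.approx(ccc(y, x))
        assert ccc([2.0, 2.0], [2.0, 2.0]) == 1.0

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            ccc([1.0, 2.0], [1.0, 2.0, 3.0])
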