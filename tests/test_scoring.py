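"""Six-component gene scores, the CAD/Tox expression pipeline and module
feasibility means."""
import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cadnet.annotations import AnnotationBundle, DRUG_COLUMNS
from cadnet.errors import ConfigurationError, LookupError_
from cadnet.modules import Module
from cadnet.networks import ExpressionMatrix
from cadnet.scoring import (
    _tox_tissue_summary,
    annotation_components,
    cad_tox_expression_score,
    distance_component,
    module_feasibility,
    score_genes,
    vascular_component,
)

GENES = ["gHigh", "gLow", "gMid1", "gMid2"]


def cad_matrix(tissue, values: dict[str, float]) -> ExpressionMatrix:
    df = pd.DataFrame({"S1": values, "S2": values})
    return ExpressionMatrix(tissue=tissue, scale="rma_log2", values=df)


def tox_matrix(tissue, values: dict[str, float], tags=None) -> ExpressionMatrix:
    df = pd.DataFrame({"S1": values, "S2": values})
    return ExpressionMatrix(
        tissue=tissue, scale="fpkm", values=df,
        quality_tags=pd.Series(tags) if tags else None,
    )


@pytest.fixture()
def panels():
    """gHigh: strong in CAD, weak in Tox; gLow: the reverse; two middles."""
    cad = {
        "AAW": cad_matrix("AAW", {"gHigh": 9.0, "gLow": 4.0, "gMid1": 6.0, "gMid2": 6.5}),
        "IMA": cad_matrix("IMA", {"gHigh": 9.0, "gLow": 4.0, "gMid1": 6.0, "gMid2": 6.5}),
        "SM": cad_matrix("SM", {"gHigh": 8.5, "gLow": 4.2, "gMid1": 6.1, "gMid2": 6.2}),
        "LIV": cad_matrix("LIV", {"gHigh": 6.0, "gLow": 6.0, "gMid1": 6.0, "gMid2": 6.0}),
    }
    tox = {
        "liver": tox_matrix("liver", {"gHigh": 64.0, "gLow": 64.0, "gMid1": 64.0, "gMid2": 64.0}),
        "heart": tox_matrix("heart", {"gHigh": 2.0, "gLow": 400.0, "gMid1": 60.0, "gMid2": 50.0}),
        "kidney": tox_matrix("kidney", {"gHigh": 4.0, "gLow": 500.0, "gMid1": 70.0, "gMid2": 40.0}),
    }
    return cad, tox


class TestDistanceComponent:
    def path_graph(self):
        g = nx.Graph(network_id="1")
        nx.add_path(g, ["cand", "n1", "n2", "n3"])
        return g

    @pytest.mark.parametrize(
        "node,expected", [("cand", 4), ("n1", 2), ("n2", 1), ("n3", 0)]
    )
    def test_distance_mapping(self, node, expected):
        assert distance_component(self.path_graph(), node, {"cand"}) == expected

    def test_unreachable_node_scores_zero(self):
        g = self.path_graph()
        g.add_node("island")
        assert distance_component(g, "island", {"cand"}) == 0

    def test_absent_node_raises_lookup_error(self):
        with pytest.raises(LookupError_):
            distance_component(self.path_graph(), "ghost", {"cand"})

    def test_adding_an_edge_never_decreases_the_component(self):
        g = self.path_graph()
        before = {n: distance_component(g, n, {"cand"}) for n in g.nodes}
        g.add_edge("cand", "n3")
        after = {n: distance_component(g, n, {"cand"}) for n in g.nodes}
        assert all(after[n] >= before[n] for n in before)


class TestExpressionScore:
    def test_extreme_genes_attain_plus_minus_two(self, panels):
        cad, tox = panels
        scores = cad_tox_expression_score(cad, tox)
        assert scores.loc["gHigh"] == pytest.approx(2.0)
        assert scores.loc["gLow"] == pytest.approx(-2.0)
        assert scores.between(-2, 2).all()

    def test_gene_missing_from_tox_panel_not_scored(self, panels):
        cad, tox = panels
        tox["heart"].quality_tags = pd.Series(
            {"gHigh": "OK", "gLow": "OK", "gMid1": "LOWDATA", "gMid2": "OK"}
        )
        tox["kidney"].quality_tags = pd.Series(
            {"gHigh": "OK", "gLow": "OK", "gMid1": "FAIL", "gMid2": "OK"}
        )
        tox["liver"].quality_tags = pd.Series(
            {"gHigh": "OK", "gLow": "OK", "gMid1": "FAIL", "gMid2": "OK"}
        )
        scores = cad_tox_expression_score(cad, tox)
        assert "gMid1" not in scores.index

    def test_missing_liver_reference_raises(self, panels):
        cad, tox = panels
        del cad["LIV"]
        with pytest.raises(ConfigurationError, match="reference"):
            cad_tox_expression_score(cad, tox)

    def test_zero_fpkm_replaced_and_quality_rows_dropped(self):
        mat = tox_matrix(
            "heart",
            {"a": 0.0, "b": 8.0, "c": 8.0},
            tags={"a": "OK", "b": "LOWDATA", "c": "OK"},
        )
        summary = _tox_tissue_summary({"heart": mat})["heart"]
        assert summary.loc["a"] == 0.5  # exact zero -> 0.5 FPKM
        assert "b" not in summary.index  # LOWDATA removed
        assert summary.loc["c"] == 8.0

    def test_duplicate_gene_rows_averaged(self):
        df = pd.DataFrame(
            [[4.0, 4.0], [8.0, 8.0]], index=["a", "a"], columns=["S1", "S2"]
        )
        mat = ExpressionMatrix(tissue="heart", scale="fpkm", values=df)
        summary = _tox_tissue_summary({"heart": mat})["heart"]
        assert summary.loc["a"] == pytest.approx(6.0)


class TestVascularComponent:
    @pytest.mark.parametrize(
        "fractions,expected",
        [({"IMA": 0.5, "AAW": 0.1}, 1),
         ({"IMA": 0.49, "AAW": 0.49}, 0),
         ({"IMA": 0.0, "AAW": 1.0}, 1)],
    )
    def test_presence_threshold(self, fractions, expected):
        assert vascular_component(pd.Series(fractions)) == expected

    def test_no_presence_data_scores_zero(self):
        assert vascular_component(None) == 0


class TestAnnotationComponents:
    def bundle(self):
        drugs = pd.DataFrame(
            [("gDrug", "D1", False, "L"),
             ("gDrug", "D2", False, "N"),
             ("gDrug", "D3", False, "C")],
            columns=DRUG_COLUMNS,
        )
        return AnnotationBundle(drugs, family_set={"gGpcr"}, mouse_set={"gMouse"})

    def test_gpcr_only(self):
        assert annotation_components("gGpcr", self.bundle()) == (2, 0, 0)

    def test_three_noncardiometabolic_drugs(self):
        assert annotation_components("gDrug", self.bundle()) == (0, 2, 0)

    def test_unannotated_gene(self):
        assert annotation_components("gNone", self.bundle()) == (0, 0, 0)


class TestIntegratedAndModuleScores:
    def test_module_score_is_mean_of_member_scores(self):
        gene_scores = pd.DataFrame(
            {"gene": list("abcd"), "integrated": [4.0, 2.0, 0.0, -2.0]}
        )
        mod = Module("1_1", "1", set("abcd"))
        mf = module_feasibility(mod, gene_scores)
        assert mf.score == pytest.approx(1.0)
        assert mf.size == 4

    def test_unscored_member_raises(self):
        gene_scores = pd.DataFrame({"gene": ["a"], "integrated": [1.0]})
        with pytest.raises(LookupError_):
            module_feasibility(Module("1_1", "1", {"a", "zz"}), gene_scores)

    def test_empty_module_rejected(self):
        with pytest.raises(ConfigurationError):
            module_feasibility(
                Module("1_1", "1", set()), pd.DataFrame(columns=["gene", "integrated"])
            )


def full_bundle(vascular: pd.DataFrame) -> AnnotationBundle:
    drugs = pd.DataFrame([("gHigh", "D1", True, "C")], columns=DRUG_COLUMNS)
    return AnnotationBundle(
        drugs, family_set={"gHigh"}, mouse_set={"gHigh"},
        vascular_presence=vascular,
    )


def test_score_range_extremes_reachable(panels):
    """A maximal gene scores exactly 12 and a minimal gene exactly -2,
    and single-gene modules inherit those bounds."""
    cad, tox = panels
    g = nx.Graph(network_id="1")
    nx.add_path(g, ["gHigh", "x1", "x2", "gLow"])  # gLow 3 hops from gHigh
    vascular = pd.DataFrame({"IMA": {"gHigh": 0.9, "gLow": 0.1},
                             "AAW": {"gHigh": 0.8, "gLow": 0.0}})
    bundle = full_bundle(vascular)
    expr = cad_tox_expression_score(cad, tox)
    scores = score_genes(g, {"gHigh"}, expr, bundle).set_index("gene")
    assert scores.loc["gHigh", "integrated"] == pytest.approx(12.0)
    assert scores.loc["gLow", "integrated"] == pytest.approx(-2.0)
    assert scores["integrated"].between(-2, 12).all()
    top = module_feasibility(
        Module("1_1", "1", {"gHigh"}), scores.reset_index()
    )
    bottom = module_feasibility(
        Module("1_2", "1", {"gLow"}), scores.reset_index()
    )
    assert top.score == pytest.approx(12.0)
    assert bottom.score == pytest.approx(-2.0)


def test_emptying_one_annotation_set_zeroes_exactly_that_component(panels):
    cad, tox = panels
    g = nx.Graph(network_id="1")
    nx.add_path(g, ["gHigh", "gMid1", "gMid2", "gLow"])
    vascular = pd.DataFrame({"IMA": {g_: 0.9 for g_ in GENES},
                             "AAW": {g_: 0.1 for g_ in GENES}})
    bundle = full_bundle(vascular)
    bundle.family_set = set(GENES)
    expr = cad_tox_expression_score(cad, tox)
    with_family = score_genes(g, {"gHigh"}, expr, bundle).set_index("gene")
    bundle2 = full_bundle(vascular)
    bundle2.family_set = set()
    without = score_genes(g, {"gHigh"}, expr, bundle2).set_index("gene")
    assert (with_family["family_component"] == 2).all()
    assert (without["family_component"] == 0).all()
    for col in ["distance_component", "expression_component",
                "vascular_component", "drug_component", "mouse_component"]:
        pd.testing.assert_series_equal(with_family[col], without[col])
    diff = with_family["integrated"] - without["integrated"]
    assert (diff == 2).all()
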