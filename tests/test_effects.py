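"""Path enumeration and effect decomposition on the eGFR slope."""

import numpy as np
import pandas as pd
import pytest

from iganpath import (PUBLISHED_COEFFICIENTS, EffectPath, decompose,
                      decompose_all, discrepancy_report, enumerate_paths,
                      final_spec, fit, generate_standardized,
                      implied_covariance, path_product, published_path_set)
from iganpath.synth import GeneratorConfig


class TestEnumeration:
    def test_single_route_source(self, final_model):
        paths = enumerate_paths(final_model, "E")
        assert [p.mediators for p in paths] == [("ST",)]

    def test_tubular_atrophy_routes(self, final_model):
        got = {p.mediators for p in enumerate_paths(final_model, "T")}
        assert got == {(), ("SReGFR0c",), ("SReGFR0c", "ST"),
                       ("MAPc01", "ST")}

    def test_dead_end_node_has_no_routes(self, final_model):
        assert enumerate_paths(final_model, "RASB") == []

    def test_correlational_link_never_traversed(self, final_model):
        # SReGFR0c ~~ UPE0c is a link, not a route segment
        for p in enumerate_paths(final_model, "S"):
            assert "UPE0c" not in p.mediators

    def test_unknown_source_rejected(self, final_model):
        with pytest.raises(ValueError):
            enumerate_paths(final_model, "BMI")

    def test_deterministic_order(self, final_model):
        a = enumerate_paths(final_model, "T")
        b = enumerate_paths(final_model, "T")
        assert [p.mediators for p in a] == [p.mediators for p in b]
        assert a[0].mediators == ()   # direct route first


class TestProductsAndTotals:
    @pytest.mark.parametrize("source,mediators,expected", [
        ("C", ("ST",), 0.023),
        ("M", ("UPE0c",), -0.014),
        ("T", ("SReGFR0c", "ST"), -0.008),
        ("S", ("MAPc01", "ST"), -0.001),
    ])
    def test_published_indirect_products(self, source, mediators, expected):
        path = EffectPath(source=source, mediators=mediators)
        assert path_product(path, PUBLISHED_COEFFICIENTS) == pytest.approx(
            expected, abs=0.001)

    def test_zero_coefficient_annihilates(self):
        coeffs = dict(PUBLISHED_COEFFICIENTS)
        coeffs[("ST", "SLOPE")] = 0.0
        path = EffectPath(source="E", mediators=("ST",))
        assert path_product(path, coeffs) == 0.0

    def test_missing_coefficient_names_edge(self):
        path = EffectPath(source="E", mediators=("ST",))
        with pytest.raises(KeyError, match="ST->SLOPE"):
            path_product(path, {("E", "ST"): 0.1})

    @pytest.mark.parametrize("source,expected_total", [
        ("T", -0.105), ("S", 0.019), ("M", -0.011), ("E", 0.014),
        ("C", 0.024),
    ])
    def test_published_totals(self, source, expected_total):
        dec = decompose(source, published_path_set()[source],
                        PUBLISHED_COEFFICIENTS)
        assert dec.total_coefficient == pytest.approx(expected_total,
                                                      abs=0.001)

    def test_total_equals_direct_plus_indirect_sum(self, final_model):
        for src, dec in decompose_all(final_model,
                                      PUBLISHED_COEFFICIENTS).items():
            parts = dec.direct_coefficient + sum(
                p.coefficient for p in dec.indirect_paths)
            assert dec.total_coefficient == pytest.approx(parts, abs=1e-12)

    def test_duplicate_path_rejected(self):
        paths = [EffectPath("E", ("ST",)), EffectPath("E", ("ST",))]
        with pytest.raises(ValueError):
            decompose("E", paths, PUBLISHED_COEFFICIENTS)

    def test_linearity_in_edge_coefficients(self, final_model):
        doubled = {k: 2.0 * v for k, v in PUBLISHED_COEFFICIENTS.items()}
        for mediators in [(), ("SReGFR0c",), ("SReGFR0c", "ST")]:
            path = EffectPath(source="T", mediators=mediators)
            k = len(mediators) + 1
            assert path_product(path, doubled) == pytest.approx(
                2.0 ** k * path_product(path, PUBLISHED_COEFFICIENTS),
                abs=1e-14)


class TestPublishedListing:
    def test_eleven_rows(self):
        listing = published_path_set()
        assert sum(len(v) for v in listing.values()) == 11

    def test_every_listed_route_is_traversable(self, final_model):
        edges = {(e.parent, e.child) for e in final_model.directed_edges
                 if e.traversable}
        for paths in published_path_set().values():
            for path in paths:
                assert set(path.edges()) <= edges

    def test_omitted_routes_identified(self, final_model):
        full = {p.mediators for p in enumerate_paths(final_model, "T")}
        listed = {p.mediators for p in published_path_set()["T"]}
        assert full - listed == {("SReGFR0c",)}
        full_c = {p.mediators for p in enumerate_paths(final_model, "C")}
        listed_c = {p.mediators for p in published_path_set()["C"]}
        assert full_c - listed_c == {("UPE0c",)}


class TestDiscrepancyReport:
    def test_modes_agree_where_listings_complete(self, final_model):
        report = discrepancy_report(final_model, PUBLISHED_COEFFICIENTS)
        for src in ("M", "E"):
            assert report.loc[src, "extra_paths"] == ""
            assert report.loc[src, "total_full_enumeration"] == \
                pytest.approx(report.loc[src, "total_as_published"],
                              abs=1e-12)
        # three published listings omit structurally valid routes
        assert "SReGFR0c" in report.loc["T", "extra_paths"]
        assert "UPE0c" in report.loc["C", "extra_paths"]
        assert report.loc["S", "extra_paths"] == "ST"
        assert report.loc["S", "extra_contribution"] == pytest.approx(
            0.127 * 0.127, abs=1e-12)


class TestPathTracingConsistency:
    def test_total_effect_equals_implied_simple_regression(self):
        """With uncorrelated sources and no correlational link, the
        full-enumeration total effect of an exogenous variable equals
        cov(source, SLOPE)/var(source) in the implied covariance (Wright's
        path tracing).  The correlational link must be absent because it
        contributes non-causal covariance channels that traversable-route
        enumeration excludes by design.
        """
        from iganpath import parse_model

        syntax = (
            "UPE0c ~ M + C\n"
            "MAPc01 ~ S + T\n"
            "SReGFR0c ~ S + T\n"
            "ST ~ UPE0c + MAPc01 + SReGFR0c + S + E + C\n"
            "RASB ~ UPE0c + MAPc01 + SReGFR0c\n"
            "SLOPE ~ UPE0c + SReGFR0c + ST + T\n")
        spec = parse_model(syntax)
        coeffs = {k: v for k, v in PUBLISHED_COEFFICIENTS.items()
                  if k != ("SReGFR0c", "UPE0c")}
        cfg = GeneratorConfig(
            n=946, seed=55, path_coefficients=coeffs,
            histology_latent_correlations=pd.DataFrame(
                np.eye(5), index=list("MESTC"), columns=list("MESTC")))
        res = fit(spec, generate_standardized(cfg))
        totals = decompose_all(spec, res.coefficient_map(),
                               sources=list("MESTC"),
                               mode="full_enumeration")
        # the generator draws uncorrelated sources; replace the sample
        # source block by its population identity so the comparison is
        # exact rather than up to sampling noise
        exog = list("MESTC")
        res.correlation.loc[exog, exog] = np.eye(5)
        sigma = implied_covariance(spec, res)
        for src in exog:
            assert sigma.loc[src, "SLOPE"] == pytest.approx(
                totals[src].total_coefficient, abs=1e-10)
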