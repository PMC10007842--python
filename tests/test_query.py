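"""Query modes: gene search, accession search and the modal detail view."""

import json

import pytest

from allelecat.io_formats import ConfigError
from allelecat.query import (
    NoResultsError,
    accession_detail,
    details_to_json,
    details_to_tsv,
    gene_results_to_json,
    search_by_accessions_and_gene,
    search_by_gene_ids,
)


def _a_gene_with_positions(panel):
    return next(
        gid for gid, gs in panel.catalog.gene_sets.items() if gs.positions
    )


class TestSearchByGeneIds:
    def test_full_frequency_table(self, panel):
        gid = _a_gene_with_positions(panel)
        (result,), warnings = search_by_gene_ids(panel.catalog, [gid])
        assert warnings == []
        assert result.table.rows[0].total == max(r.total for r in result.table.rows)
        assert sum(r.total for r in result.table.rows) == len(panel.accessions)
        assert result.position_labels == tuple(panel.catalog.gene_sets[gid].labels)

    def test_unknown_ids_warn_but_do_not_fail(self, panel):
        gid = _a_gene_with_positions(panel)
        results, warnings = search_by_gene_ids(panel.catalog, [gid, "bogus"])
        assert len(results) == 1
        assert warnings == ["unknown gene id: bogus"]

    def test_all_unknown_raises(self, panel):
        with pytest.raises(NoResultsError):
            search_by_gene_ids(panel.catalog, ["bogus"])

    def test_empty_request_is_an_error(self, panel):
        with pytest.raises(ValueError):
            search_by_gene_ids(panel.catalog, [])

    def test_category_filter_recomputes_totals(self, panel):
        """Filtering to Elite restricts every count to Elite accessions."""
        gid = _a_gene_with_positions(panel)
        spec = panel.catalog.category_spec
        elite = {
            acc
            for acc, md in panel.catalog.metadata.items()
            if md.categories.get(spec.category_column) == "Elite"
        }
        (result,), _ = search_by_gene_ids(
            panel.catalog, [gid], {"Improvement Status": ["Elite"]}
        )
        assert sum(r.total for r in result.table.rows) == len(elite)
        for group in result.allele_rows:
            for row in group:
                assert row.accession in elite

    def test_unknown_filter_column_is_config_error(self, panel):
        gid = _a_gene_with_positions(panel)
        with pytest.raises(ConfigError):
            search_by_gene_ids(panel.catalog, [gid], {"Nope": ["x"]})

    def test_json_serialization_parses(self, panel):
        gid = _a_gene_with_positions(panel)
        results, warnings = search_by_gene_ids(panel.catalog, [gid])
        payload = json.loads(gene_results_to_json(results, warnings))
        assert payload["genes"][0]["gene_id"] == gid
        cell = payload["genes"][0]["alleles"][0][0]["cells"]
        if cell:
            assert {"position", "state", "display_color"} <= set(cell[0])


class TestSearchByAccessionsAndGene:
    def test_rows_in_request_order_without_frequencies(self, panel):
        gid = _a_gene_with_positions(panel)
        request = [panel.accessions[3], panel.accessions[0], panel.accessions[7]]
        details, warnings = search_by_accessions_and_gene(panel.catalog, request, gid)
        assert [d.accession for d in details] == request
        assert warnings == []
        assert not hasattr(details[0], "total")

    def test_unknown_accession_omitted_with_warning(self, panel):
        gid = _a_gene_with_positions(panel)
        details, warnings = search_by_accessions_and_gene(
            panel.catalog, ["NOPE", panel.accessions[0]], gid
        )
        assert [d.accession for d in details] == [panel.accessions[0]]
        assert warnings == ["accession not in panel: NOPE"]

    def test_unknown_gene_is_an_error(self, panel):
        with pytest.raises(KeyError):
            search_by_accessions_and_gene(panel.catalog, panel.accessions[:1], "bogus")

    def test_reference_carrier_renders_all_grey(self, panel):
        gid = _a_gene_with_positions(panel)
        gs = panel.catalog.gene_sets[gid]
        ref_vec = tuple(p.ref_seq for p in gs.positions)
        ref_allele = next(
            (a for a in panel.catalog.alleles[gid] if a.state_vector == ref_vec), None
        )
        assert ref_allele is not None, "panel gene should retain a reference allele"
        acc = ref_allele.carriers[0]
        (detail,), _ = search_by_accessions_and_gene(panel.catalog, [acc], gid)
        assert set(detail.colors) == {"grey"}

    def test_matches_union_of_detail_queries(self, panel):
        gid = _a_gene_with_positions(panel)
        everyone, _ = search_by_accessions_and_gene(
            panel.catalog, panel.accessions, gid
        )
        union = []
        for idx in range(1, len(panel.catalog.alleles[gid]) + 1):
            union.extend(accession_detail(panel.catalog, gid, idx, "Total"))
        key = lambda d: d.accession
        assert sorted(everyone, key=key) == sorted(union, key=key)


class TestAccessionDetail:
    def test_category_cell_matches_hand_count(self, panel):
        gid = _a_gene_with_positions(panel)
        spec = panel.catalog.category_spec
        table = panel.catalog.tables[gid]
        for row in table.rows:
            for value in spec.values:
                details = accession_detail(panel.catalog, gid, row.allele_index, value)
                assert len(details) == row.counts[value]
            assert len(
                accession_detail(panel.catalog, gid, row.allele_index, "Total")
            ) == row.total

    def test_zero_count_cell_yields_empty_list(self, panel):
        spec = panel.catalog.category_spec
        for gid, table in panel.catalog.tables.items():
            for row in table.rows:
                for value in spec.values:
                    if row.counts[value] == 0:
                        assert (
                            accession_detail(panel.catalog, gid, row.allele_index, value)
                            == []
                        )
                        return
        raise AssertionError("expected at least one zero cell in the panel")

    def test_category_partition_covers_total_minus_uncategorized(self, panel):
        gid = _a_gene_with_positions(panel)
        spec = panel.catalog.category_spec
        for idx, allele in enumerate(panel.catalog.alleles[gid], 1):
            per_value = sum(
                len(accession_detail(panel.catalog, gid, idx, v)) for v in spec.values
            )
            uncategorized = sum(
                1
                for acc in allele.carriers
                if acc not in panel.catalog.metadata
                or panel.catalog.metadata[acc].categories.get(spec.category_column)
                not in spec.values
            )
            assert per_value == allele.total - uncategorized

    def test_invalid_inputs(self, panel):
        gid = _a_gene_with_positions(panel)
        with pytest.raises(IndexError):
            accession_detail(panel.catalog, gid, 999, "Total")
        with pytest.raises(KeyError):
            accession_detail(panel.catalog, "bogus", 1, "Total")
        with pytest.raises(ValueError):
            accession_detail(panel.catalog, gid, 1, "NotACategory")

    def test_detail_serializations(self, panel):
        gid = _a_gene_with_positions(panel)
        details = accession_detail(panel.catalog, gid, 1, "Total")
        payload = json.loads(details_to_json(details, []))
        assert len(payload["accessions"]) == len(details)
        tsv = details_to_tsv(details, [])
        header = tsv.splitlines()[0].split("\t")
        assert header[0] == "Accession" and "Imputation" in header
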