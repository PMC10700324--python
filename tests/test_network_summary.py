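"""Region- and network-level summaries: conservation, symmetry, contribution."""

import numpy as np
import pandas as pd
import pytest

from corrtf.longitudinal_stats import LongitudinalTestResult
from corrtf.network_summary import (compare_methods, count_by_source_region,
                                    count_network_pairs, percent_contribution,
                                    write_circos_table)
from corrtf.regions import NETWORKS


def make_result(source, target, significant=True, group="G"):
    return LongitudinalTestResult(
        group=group, connection=(source, target),
        t_baseline_v1=1.0, p_baseline_v1=0.01, t_v1_v2=-1.0, p_v1_v2=0.01,
        f_anova=5.0, p_anova=0.01, significant=significant,
        sign_pattern="positive_to_negative")


@pytest.fixture()
def mixed_results(rng, table):
    """10 significant + 5 non-significant connections over random regions."""
    picks = rng.choice(np.arange(1, 117), size=(15, 2), replace=False)
    return [make_result(int(s), int(t), significant=(k < 10))
            for k, (s, t) in enumerate(picks)]


class TestSourceCounts:
    def test_counts_sum_to_significant_total(self, mixed_results):
        counts = count_by_source_region(mixed_results)
        assert sum(counts.values()) == 10

    def test_single_connection(self):
        assert count_by_source_region([make_result(7, 9)]) == {7: 1}

    def test_empty_input(self):
        assert count_by_source_region([]) == {}

    def test_figure_style_sum_of_parts(self):
        """Per-source counts of a constructed set reproduce the set size,
        mirroring the 101+12+10+3+3+2+1+1 = 133 bookkeeping identity."""
        per_source = {110: 101, 43: 12, 69: 10, 84: 3, 83: 3, 79: 2, 38: 1, 59: 1}
        results = []
        target = 1
        for src, n in per_source.items():
            for _ in range(n):
                target += 1
                results.append(make_result(src, 1 + (target % 100)))
        counts = count_by_source_region(results)
        assert counts == per_source
        assert sum(counts.values()) == 133 == len(results)


class TestNetworkPairs:
    def test_all_21_keys_present_and_conserved(self, mixed_results, table):
        pairs = count_network_pairs(mixed_results, table)
        assert len(pairs.counts) == 21
        assert pairs.total == 10

    def test_vermis_to_calcarine_lands_in_cereb_vc(self, table):
        vermis3 = table.by_abbreviation("Vermis3").index
        cal = table.by_abbreviation("CAL.L").index
        pairs = count_network_pairs([make_result(vermis3, cal)], table)
        assert pairs.counts[("VC", "Cereb")] == 1
        assert pairs.total == 1

    def test_direction_reversal_invariance(self, mixed_results, table):
        fwd = count_network_pairs(mixed_results, table)
        rev = [make_result(r.connection[1], r.connection[0],
                           significant=r.significant) for r in mixed_results]
        assert count_network_pairs(rev, table).counts == fwd.counts

    def test_reciprocal_pair_counts_twice(self, table):
        pairs = count_network_pairs([make_result(1, 4), make_result(4, 1)], table)
        assert pairs.total == 2 and max(pairs.counts.values()) == 2

    def test_matrix_is_symmetric(self, mixed_results, table):
        mat = count_network_pairs(mixed_results, table).matrix()
        assert (mat.values == mat.values.T).all()


class TestContribution:
    def test_uniform_three_networks(self, table):
        # one Cereb, one VC, one SMC region; each network contributes 1 of 3
        vermis3 = table.by_abbreviation("Vermis3").index
        cal = table.by_abbreviation("CAL.L").index
        pcl = table.by_abbreviation("PCL.L").index
        results = [make_result(vermis3, cal), make_result(vermis3, pcl)]
        contrib = percent_contribution(results, table)
        assert contrib.percentages["Cereb"] == pytest.approx(100 / 3)
        assert contrib.percentages["VC"] == pytest.approx(100 / 3)
        assert contrib.percentages["SMC"] == pytest.approx(100 / 3)
        assert contrib.percentages["DMN"] == 0.0

    def test_within_network_connection_gives_100_percent(self, table):
        results = [make_result(91, 92)]  # both cerebellar
        contrib = percent_contribution(results, table)
        assert contrib.percentages["Cereb"] == 100.0
        assert sum(contrib.percentages.values()) == 100.0

    def test_empty_set_is_all_zero(self, table):
        contrib = percent_contribution([], table)
        assert all(v == 0.0 for v in contrib.percentages.values())

    def test_matches_brute_force_set_union(self, mixed_results, table):
        contrib = percent_contribution(mixed_results, table)
        regions = {i for r in mixed_results if r.significant for i in r.connection}
        for net in NETWORKS:
            want = sum(1 for i in regions if table.network_of(i) == net)
            assert contrib.region_counts[net] == want
        assert sum(contrib.percentages.values()) == pytest.approx(100.0)

    def test_endpoint_denominator_variant(self, table):
        results = [make_result(91, 92), make_result(91, 43)]
        by_regions = percent_contribution(results, table)
        by_endpoints = percent_contribution(results, table,
                                            denominator="endpoints")
        # region 91 counted once vs twice
        assert by_regions.region_counts["Cereb"] == 2
        assert by_endpoints.region_counts["Cereb"] == 3

    def test_permutation_equivariance(self, mixed_results, table):
        """Consistently relabeling regions leaves network summaries unchanged."""
        perm = np.arange(1, 117)
        rng = np.random.default_rng(3)
        # permute within networks so the region->network map is preserved
        for net in NETWORKS:
            idxs = np.array(table.indices_of_network(net))
            perm[idxs - 1] = rng.permutation(idxs)
        relabeled = [make_result(int(perm[r.connection[0] - 1]),
                                 int(perm[r.connection[1] - 1]),
                                 significant=r.significant)
                     for r in mixed_results]
        a = count_network_pairs(mixed_results, table).counts
        b = count_network_pairs(relabeled, table).counts
        assert a == b


class TestCompareAndExport:
    def test_identical_tables_zero_difference(self, mixed_results, table):
        c = percent_contribution(mixed_results, table)
        frame = compare_methods(c, c)
        assert (frame["difference"] == 0).all()

    def test_empty_vs_nonempty(self, mixed_results, table):
        full = percent_contribution(mixed_results, table)
        empty = percent_contribution([], table)
        frame = compare_methods(full, empty)
        np.testing.assert_allclose(frame["difference"],
                                   frame["corrtf_percent"])

    def test_circos_table_format(self, mixed_results, table, tmp_path):
        path = tmp_path / "circos.tsv"
        write_circos_table(mixed_results, table, path)
        lines = path.read_text().strip().split("\n")
        header = lines[0].split("\t")
        assert header[0] == "labels"
        n = len(header) - 1
        assert len(lines) == n + 1
        total = sum(int(v) for line in lines[1:] for v in line.split("\t")[1:])
        assert total == 10
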