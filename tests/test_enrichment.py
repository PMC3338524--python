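"""Chi-squared/Fisher enrichment statistics and lifestyle associations."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cladeshift.enrichment import (
    Status,
    chi_squared,
    enrich_by_category,
    enrich_by_species,
    enrich_species_by_category,
    fisher_exact_2xc,
    lifestyle_association,
    lifestyle_table_test,
    make_branch_table,
)


def branch_table(rows):
    """rows: (group, node, is_fd, category, species set)"""
    return make_branch_table(
        [
            dict(group_id=g, node_id=n, is_fd=f, category=c, species=s)
            for g, n, f, c, s in rows
        ]
    )


class TestChiSquared:
    def test_perfect_fit(self):
        stat, p = chi_squared([10, 10], [10, 10])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        stat, p = chi_squared([12, 8], [10, 10], df=1)
        assert stat == pytest.approx(0.8)

    def test_printed_tail_value(self):
        # chi2 = 0.9762 on 2 df has upper tail 0.6138
        assert stats.chi2.sf(0.9762, 2) == pytest.approx(0.6138, abs=5e-5)
        stat, p = chi_squared([3, 4, 2], [2.2, 4.9, 1.9], df=2)
        assert p == pytest.approx(stats.chi2.sf(stat, 2))

    def test_zero_expected_count_is_degenerate(self):
        with pytest.raises(ValueError):
            chi_squared([1, 2], [0, 3])

    def test_agrees_with_independent_computation_on_random_tables(self, rng):
        for _ in range(1000):
            k = int(rng.integers(2, 6))
            e = rng.uniform(1, 50, size=k)
            o = rng.poisson(e).astype(float)
            stat, p = chi_squared(o, e)
            ref_stat = sum((oi - ei) ** 2 / ei for oi, ei in zip(o, e))
            assert stat == pytest.approx(ref_stat, abs=1e-10)
            assert p == pytest.approx(stats.chi2.sf(ref_stat, k - 1), abs=1e-10)


class TestFisher2xc:
    def test_matches_r_fisher_test(self):
        tables = [
            [[2, 6, 1], [61, 433, 66]],
            [[3, 1, 4], [2, 7, 5]],
            [[0, 5, 2], [8, 3, 1]],
        ]
        ps = [fisher_exact_2xc(np.array(t)) for t in tables]
        script = (
            "cat(fisher.test(matrix(c(2,61,6,433,1,66),2))$p.value,"
            "fisher.test(matrix(c(3,2,1,7,4,5),2))$p.value,"
            "fisher.test(matrix(c(0,8,5,3,2,1),2))$p.value, sep='\\n')"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        ref = [float(x) for x in out.stdout.split()]
        assert ps == pytest.approx(ref, rel=1e-6)

    def test_2x2_matches_scipy(self):
        t = np.array([[3, 7], [9, 2]])
        assert fisher_exact_2xc(t) == pytest.approx(
            stats.fisher_exact(t)[1], rel=1e-10
        )


class TestLifestyleTable:
    def test_low_expected_count_takes_fisher_path(self):
        # min expected cell is ~1.0 (<5), so the exact test must be used
        counts = np.array([[2, 6, 1], [61, 433, 66]])
        assert stats.contingency.expected_freq(counts).min() < 5
        name, stat, p = lifestyle_table_test(counts)
        assert name == "fisher"
        assert p > 0.05  # psychrophile-style contrast is not significant

    def test_identical_distributions_not_significant(self):
        name, stat, p = lifestyle_table_test(np.array([[10, 40, 10], [10, 40, 10]]))
        assert p > 0.95

    def test_association_direction_and_filtering(self):
        status = {f"s{i}": Status.ENRICHED for i in range(12)}
        status.update({f"t{i}": Status.IMPOVERISHED for i in range(12)})
        status.update({f"u{i}": Status.NEITHER for i in range(4)})
        lifestyles = {sp: ("host" if sp.startswith("s") else "free") for sp in status}
        lifestyles["u0"] = "other"  # neither-focal-nor-comparison is ignored
        res = lifestyle_association(status, lifestyles, "host", "free")
        assert res.counts.sum() == 27
        assert res.p_value < 0.05
        assert res.direction == "+"


def standard_table():
    """900 background tests (85 positive) + one hot category (50/100)."""
    rows = []
    for i in range(900):
        rows.append((f"bg{i}", 0, i < 85, "J", {f"sp{i % 10}"}))
    for i in range(100):
        rows.append((f"hot{i}", 0, i < 50, "E", {"sp_hot"}))
    return branch_table(rows)


class TestEnrichByCategory:
    def test_background_proportion_category_is_neither(self):
        rows = [(f"g{i}", 0, i < 2, "J", {"a"}) for i in range(20)]
        rows += [(f"h{i}", 0, i < 2, "E", {"a"}) for i in range(20)]
        cells = enrich_by_category(branch_table(rows))
        assert cells["J"].status is Status.NEITHER
        assert cells["E"].status is Status.NEITHER

    def test_hot_category_is_enriched(self):
        cells = enrich_by_category(standard_table())
        assert cells["E"].status is Status.ENRICHED
        assert cells["E"].observed_fd == 50
        assert cells["E"].total_tests == 100
        # expected from the background (other categories): 85/900 * 100
        assert cells["E"].expected_fd == pytest.approx(100 * 85 / 900)
        assert cells["J"].status is Status.IMPOVERISHED

    def test_statuses_partition_the_units(self):
        cells = enrich_by_category(standard_table())
        assert sum(
            c.status in (Status.ENRICHED, Status.IMPOVERISHED, Status.NEITHER,
                         Status.NO_DATA)
            for c in cells.values()
        ) == len(cells)

    def test_randomised_labels_leave_most_categories_neither(self, rng):
        """Shuffling category labels destroys enrichment structure."""
        statuses = []
        for _ in range(10):
            rows = [
                (f"g{i}", 0, bool(rng.random() < 0.2),
                 "ABCDEFGHIJ"[rng.integers(10)], {"sp"})
                for i in range(400)
            ]
            cells = enrich_by_category(branch_table(rows))
            statuses += [c.status for c in cells.values()]
        frac_neither = np.mean([s is Status.NEITHER for s in statuses])
        assert frac_neither >= 0.85

    def test_counts_conserve_the_background(self):
        table = standard_table()
        cells = enrich_by_category(table)
        assert sum(c.observed_fd for c in cells.values()) == int(table["is_fd"].sum())
        assert sum(c.total_tests for c in cells.values()) == len(table)


class TestEnrichBySpecies:
    def test_outgroup_only_species_gets_no_data(self):
        # species z never appears in a clade, only implicit outgroups
        rows = [("g1", 0, True, "J", {"a", "b"}), ("g2", 0, False, "J", {"a", "c"})]
        cells = enrich_by_species(branch_table(rows))
        assert "z" not in cells
        assert cells["a"].total_tests == 2
        assert cells["b"].observed_fd == 1

    def test_single_branch_attributes_to_every_clade_species(self):
        rows = [("g1", 0, True, "J", {"a", "b", "c"})]
        cells = enrich_by_species(branch_table(rows))
        for sp in "abc":
            assert cells[sp].observed_fd == 1
            assert cells[sp].total_tests == 1

    def test_duplicating_the_dataset_keeps_proportions(self):
        rows = [("g1", 0, True, "J", {"a"}), ("g2", 0, False, "J", {"a"}),
                ("g3", 0, False, "J", {"b"})]
        once = enrich_by_species(branch_table(rows))
        twice = enrich_by_species(
            branch_table(rows + [(g + "x", n, f, c, s) for g, n, f, c, s in rows])
        )
        for sp in ("a", "b"):
            p1 = once[sp].observed_fd / once[sp].total_tests
            p2 = twice[sp].observed_fd / twice[sp].total_tests
            assert p1 == pytest.approx(p2)


class TestSpeciesByCategory:
    def test_single_category_gives_one_column(self):
        rows = [("g1", 0, True, "J", {"a"}), ("g2", 0, False, "J", {"b"})]
        matrix, cells = enrich_species_by_category(branch_table(rows))
        assert list(matrix.columns) == ["J"]
        assert sorted(matrix.index) == ["a", "b"]

    def test_cell_counts_sum_to_species_totals(self):
        rows = [
            ("g1", 0, True, "J", {"a", "b"}),
            ("g2", 0, False, "E", {"a"}),
            ("g3", 1, True, "E", {"a", "b"}),
        ]
        table = branch_table(rows)
        _, cells = enrich_species_by_category(table)
        species_cells = enrich_by_species(table)
        for sp in ("a", "b"):
            total = sum(
                c.total_tests for (s, _), c in cells.items() if s == sp
            )
            assert total == species_cells[sp].total_tests

    def test_planted_cell_enriched_others_not(self):
        rows = [(f"p{i}", 0, True, "U", {"sp1"}) for i in range(6)]
        rows += [(f"n{i}", 0, False, "J", {f"sp{2 + i % 5}"}) for i in range(12)]
        matrix, cells = enrich_species_by_category(branch_table(rows))
        assert cells[("sp1", "U")].status is Status.ENRICHED
        for key, cell in cells.items():
            if key != ("sp1", "U"):
                assert cell.status in (Status.NEITHER, Status.NO_DATA)
        assert matrix.loc["sp1", "U"] == 1.0
        assert np.isnan(matrix.loc["sp2", "U"])  # no-data encoded as NaN
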