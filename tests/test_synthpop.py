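import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fiveaday import synthpop
from fiveaday.core import PROV_CODE, Grid, category_of
from fiveaday.toyregion import zone_cell_weights

from conftest import binom_bound99


def make_counts(rows):
    return pd.DataFrame(rows, columns=["zone", "sex", "age_band", "edu_level", "count"])


def weights_frame(rows):
    return pd.DataFrame(rows, columns=["zone", "cell_id", "weight"])


def make_trips(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "respondent_id", "sex", "age_band", "edu_level",
            "night_cell", "stay_cell", "start_min", "end_min",
        ],
    )


class TestNightAllocation:
    def test_single_cell_zone_forces_all_agents_there(self, rng):
        grid = Grid.regular(1, 1)
        counts = make_counts([(0, "male", "15-29", "low", 5)])
        roster = synthpop.allocate_night_cells(
            counts, weights_frame([(0, 0, 1.0)]), grid, rng
        )
        assert len(roster) == 5
        assert (roster.night == 0).all()

    def test_weighted_cells_follow_weights_within_binomial_bounds(self, rng):
        grid = Grid.regular(2, 1)
        n = 40_000
        counts = make_counts([(0, "male", "15-29", "low", n)])
        weights = weights_frame([(0, 0, 3.0), (0, 1, 1.0)])
        roster = synthpop.allocate_night_cells(counts, weights, grid, rng)
        share0 = (roster.night == 0).mean()
        assert abs(share0 - 0.75) < binom_bound99(0.75, n)

    def test_zero_counts_give_empty_roster(self, rng):
        grid = Grid.regular(2, 1)
        counts = make_counts([(0, "male", "15-29", "low", 0)])
        roster = synthpop.allocate_night_cells(
            counts, weights_frame([(0, 0, 1.0)]), grid, rng
        )
        assert len(roster) == 0

    def test_all_zero_weights_error_names_zone(self, rng):
        grid = Grid.regular(2, 1)
        counts = make_counts([("Z9", "male", "15-29", "low", 3)])
        with pytest.raises(ValueError, match="Z9"):
            synthpop.allocate_night_cells(
                counts, weights_frame([("Z9", 0, 0.0)]), grid, rng
            )

    def test_negative_count_errors(self, rng):
        grid = Grid.regular(1, 1)
        counts = make_counts([(0, "male", "15-29", "low", -1)])
        with pytest.raises(ValueError, match="negative count"):
            synthpop.allocate_night_cells(
                counts, weights_frame([(0, 0, 1.0)]), grid, rng
            )

    def test_category_totals_conserved(self, small_region, rng):
        roster = synthpop.allocate_night_cells(
            small_region.counts,
            zone_cell_weights(small_region),
            small_region.grid,
            rng,
        )
        expected = small_region.counts.groupby(
            ["sex", "age_band", "edu_level"]
        )["count"].sum()
        totals = roster.category_totals()
        for (sex, age, edu), n in expected.items():
            assert totals[category_of(sex, age, edu)] == n


class TestPresenceProbabilities:
    def test_equal_time_in_two_cells_gives_half_half(self):
        grid = Grid.regular(2, 1)
        trips = make_trips([
            (0, "male", "15-29", "low", 0, 0, 480, 720),   # 4 h in cell 0
            (0, "male", "15-29", "low", 0, 1, 720, 960),   # 4 h in cell 1
        ])
        table = synthpop.compute_presence_probabilities(trips, grid)
        cells, probs, prov = table.get(category_of("male", "15-29", "low"), 0, "day")
        assert prov == "observed"
        assert np.allclose(probs, [0.5, 0.5])

    def test_two_respondents_pool_their_minutes(self):
        grid = Grid.regular(2, 1)
        trips = make_trips([
            (0, "male", "15-29", "low", 0, 0, 480, 960),
            (1, "male", "15-29", "low", 0, 1, 480, 960),
        ])
        table = synthpop.compute_presence_probabilities(trips, grid)
        _, probs, _ = table.get(category_of("male", "15-29", "low"), 0, "day")
        assert np.allclose(probs, [0.5, 0.5])

    def test_key_without_respondents_is_absent(self):
        grid = Grid.regular(2, 1)
        trips = make_trips([(0, "male", "15-29", "low", 0, 0, 480, 960)])
        table = synthpop.compute_presence_probabilities(trips, grid)
        assert table.get(category_of("female", "15-29", "low"), 0, "day") is None
        assert table.get(category_of("male", "15-29", "low"), 0, "evening") is None

    def test_stay_crossing_slice_boundary_errors(self):
        grid = Grid.regular(1, 1)
        trips = make_trips([(0, "male", "15-29", "low", 0, 0, 900, 1000)])
        with pytest.raises(ValueError, match="crosses"):
            synthpop.compute_presence_probabilities(trips, grid)

    def test_unknown_cell_errors(self):
        grid = Grid.regular(1, 1)
        trips = make_trips([(0, "male", "15-29", "low", 0, 99, 480, 960)])
        with pytest.raises(ValueError, match="99"):
            synthpop.compute_presence_probabilities(trips, grid)

    def test_split_stays_helper_makes_input_acceptable(self):
        grid = Grid.regular(1, 1)
        trips = make_trips([(0, "male", "15-29", "low", 0, 0, 700, 1100)])
        split = synthpop.split_stays_at_boundaries(trips)
        assert list(zip(split["start_min"], split["end_min"])) == [
            (700, 960), (960, 1100),
        ]
        table = synthpop.compute_presence_probabilities(split, grid)
        assert table.get(category_of("male", "15-29", "low"), 0, "day") is not None

    def test_distributions_sum_to_one(self, small_region):
        table = synthpop.compute_presence_probabilities(
            small_region.trips, small_region.grid
        )
        for cells, probs, _ in table.entries.values():
            assert abs(probs.sum() - 1.0) < 1e-9
            assert (probs >= 0).all()


class TestInterpolation:
    @staticmethod
    def observed_table(grid, donors):
        """Table with one observed day entry per donor night cell."""
        table = synthpop.PresenceProbabilityTable(grid=grid)
        cat = category_of("male", "15-29", "low")
        for night, dest in donors.items():
            table.entries[(cat, night, "day")] = (
                np.array([dest]), np.array([1.0]), "observed",
            )
        return table

    def test_nearest_donor_wins(self):
        # donors at x=0 and x=3; the cell at x=1 is nearer to x=0
        grid = Grid.regular(4, 1)
        table = self.observed_table(grid, {0: 0, 3: 3})
        out = synthpop.interpolate_presence(table)
        cat = category_of("male", "15-29", "low")
        cells, _, prov = out.get(cat, 1, "day")
        assert prov == "interpolated"
        assert cells[0] == 0  # copied from the x=0 donor
        cells2, _, _ = out.get(cat, 2, "day")
        assert cells2[0] == 3

    def test_equidistant_tie_breaks_on_lower_cell_id(self):
        grid = Grid.regular(3, 1)
        table = self.observed_table(grid, {0: 0, 2: 2})
        out = synthpop.interpolate_presence(table)
        cat = category_of("male", "15-29", "low")
        cells, _, _ = out.get(cat, 1, "day")
        assert cells[0] == 0

    def test_single_donor_fills_all_populated_cells(self):
        grid = Grid.regular(3, 3)
        table = self.observed_table(grid, {4: 4})
        out = synthpop.interpolate_presence(table)
        cat = category_of("male", "15-29", "low")
        for night in range(9):
            entry = out.get(cat, night, "day")
            assert entry is not None and entry[0][0] == 4

    def test_brute_force_nearest_neighbour_oracle(self, small_region):
        """Interpolated donors match an exhaustive nearest-donor search."""
        observed = synthpop.compute_presence_probabilities(
            small_region.trips.iloc[:60], small_region.grid
        )
        out = synthpop.interpolate_presence(observed)
        coords = small_region.grid.populated_coords().astype(float)
        pop_ids = small_region.grid.populated_ids
        for (cat, night, sl), (cells, probs, prov) in out.entries.items():
            if prov != "interpolated":
                continue
            donors = [
                d for (c, d, s), (_, _, p) in observed.entries.items()
                if c == cat and s == sl and p == "observed"
            ]
            # exhaustive scan with the same tie rule
            best = min(
                donors,
                key=lambda d: (
                    float(np.sum((coords[d] - coords[night]) ** 2)),
                    int(pop_ids[d]),
                ),
            )
            ref_cells, ref_probs, _ = observed.entries[(cat, best, sl)]
            assert np.array_equal(cells, ref_cells)
            assert np.array_equal(probs, ref_probs)

    def test_observed_entries_never_modified(self, small_region):
        observed = synthpop.compute_presence_probabilities(
            small_region.trips, small_region.grid
        )
        before = {
            k: (v[0].copy(), v[1].copy(), v[2]) for k, v in observed.entries.items()
        }
        out = synthpop.interpolate_presence(observed)
        for k, (cells, probs, prov) in before.items():
            oc, op, oprov = out.entries[k]
            assert np.array_equal(oc, cells) and np.array_equal(op, probs)
            assert oprov == prov

    def test_idempotent_on_complete_tables(self, small_region):
        once = synthpop.interpolate_presence(
            synthpop.compute_presence_probabilities(
                small_region.trips, small_region.grid
            )
        )
        twice = synthpop.interpolate_presence(once)
        assert set(once.entries) == set(twice.entries)

    def test_category_with_no_donor_left_missing(self):
        grid = Grid.regular(2, 1)
        table = self.observed_table(grid, {0: 0})
        out = synthpop.interpolate_presence(table)
        assert out.get(category_of("female", "60-75", "high"), 0, "day") is None


class TestSliceAssignment:
    def test_fallback_chain(self, rng):
        grid = Grid.regular(2, 1)
        table = synthpop.PresenceProbabilityTable(grid=grid)
        m = category_of("male", "15-29", "low")
        f = category_of("female", "15-29", "low")
        lone = category_of("male", "60-75", "high")
        # only the male entry exists; females fall back to it; the lone
        # category has neither and stays immobile
        for sl in ("day", "evening"):
            table.entries[(m, 0, sl)] = (np.array([1]), np.array([1.0]), "observed")
        from fiveaday.core import Roster
        roster = Roster(
            category=np.array([m, f, lone], np.int8),
            night=np.zeros(3, np.int64),
            day=np.zeros(3, np.int64),
            evening=np.zeros(3, np.int64),
            day_prov=np.zeros(3, np.int8),
            evening_prov=np.zeros(3, np.int8),
        )
        out = synthpop.assign_slice_cells(roster, table, rng)
        assert out.day[0] == 1 and out.day_prov[0] == PROV_CODE["observed"]
        assert out.day[1] == 1 and out.day_prov[1] == PROV_CODE["opposite_sex_fallback"]
        assert out.day[2] == 0 and out.day_prov[2] == PROV_CODE["immobile"]
        assert out.evening[2] == 0

    def test_assignment_is_total(self, small_region, rng):
        roster = synthpop.allocate_night_cells(
            small_region.counts, zone_cell_weights(small_region),
            small_region.grid, rng,
        )
        table = synthpop.interpolate_presence(
            synthpop.compute_presence_probabilities(
                small_region.trips.iloc[:100], small_region.grid
            )
        )
        out = synthpop.assign_slice_cells(roster, table, rng)
        n_pop = int(small_region.grid.populated.sum())
        assert ((out.day >= 0) & (out.day < n_pop)).all()
        assert ((out.evening >= 0) & (out.evening < n_pop)).all()

    def test_empirical_day_distribution_matches_table(self, rng):
        """Chi-square goodness of fit at n = 1e5 on a fully observed table."""
        grid = Grid.regular(4, 1)
        cat = category_of("male", "15-29", "low")
        table = synthpop.PresenceProbabilityTable(grid=grid)
        p = np.array([0.1, 0.2, 0.3, 0.4])
        for sl in ("day", "evening"):
            table.entries[(cat, 0, sl)] = (np.arange(4), p, "observed")
        from fiveaday.core import Roster
        n = 100_000
        roster = Roster(
            category=np.full(n, cat, np.int8),
            night=np.zeros(n, np.int64),
            day=np.zeros(n, np.int64),
            evening=np.zeros(n, np.int64),
            day_prov=np.zeros(n, np.int8),
            evening_prov=np.zeros(n, np.int8),
        )
        out = synthpop.assign_slice_cells(roster, table, rng)
        obs = np.bincount(out.day, minlength=4)
        chi2, pval = stats.chisquare(obs, n * p)
        assert pval > 0.01


class TestRandomize:
    def test_p0_is_identity(self, small_region, small_engine, rng):
        from fiveaday.experiments import ScenarioConfig
        roster = small_engine.build_allocation(ScenarioConfig("2C"), rng)
        out = synthpop.randomize_allocation(
            roster, small_region.grid, "day_evening", 0.0, rng
        )
        assert np.array_equal(out.day, roster.day)
        assert np.array_equal(out.evening, roster.evening)

    def test_p1_day_cells_uniform_over_populated(self, small_region, rng):
        from fiveaday.core import Roster
        n = 50_000
        n_pop = int(small_region.grid.populated.sum())
        roster = Roster(
            category=np.zeros(n, np.int8),
            night=np.zeros(n, np.int64),
            day=np.zeros(n, np.int64),
            evening=np.zeros(n, np.int64),
            day_prov=np.zeros(n, np.int8),
            evening_prov=np.zeros(n, np.int8),
        )
        out = synthpop.randomize_allocation(
            roster, small_region.grid, "day_evening", 1.0, rng
        )
        obs = np.bincount(out.day, minlength=n_pop)
        _, pval = stats.chisquare(obs)
        assert pval > 0.01

    def test_p_half_randomises_about_half(self, small_region, rng):
        from fiveaday.core import Roster
        n = 40_000
        roster = Roster(
            category=np.zeros(n, np.int8),
            night=np.zeros(n, np.int64),
            day=np.zeros(n, np.int64),
            evening=np.zeros(n, np.int64),
            day_prov=np.zeros(n, np.int8),
            evening_prov=np.zeros(n, np.int8),
        )
        out = synthpop.randomize_allocation(
            roster, small_region.grid, "night", 0.5, rng
        )
        moved = (out.night != roster.night).mean()
        n_pop = int(small_region.grid.populated.sum())
        # a randomised agent stays put with probability 1/n_pop
        expected = 0.5 * (1 - 1 / n_pop)
        assert abs(moved - expected) < binom_bound99(expected, n)
        # category totals untouched by night randomisation
        assert np.array_equal(out.category_totals(), roster.category_totals())

    def test_invalid_inputs(self, small_region, rng):
        from fiveaday.core import Roster
        roster = Roster(
            category=np.zeros(1, np.int8), night=np.zeros(1, np.int64),
            day=np.zeros(1, np.int64), evening=np.zeros(1, np.int64),
            day_prov=np.zeros(1, np.int8), evening_prov=np.zeros(1, np.int8),
        )
        with pytest.raises(ValueError, match="fraction"):
            synthpop.randomize_allocation(roster, small_region.grid, "night", 1.5, rng)
        empty_grid = Grid(
            cell_ids=np.array([0]), x=np.array([0]), y=np.array([0]),
            populated=np.array([False]),
        )
        with pytest.raises(ValueError, match="populated"):
            synthpop.randomize_allocation(roster, empty_grid, "night", 0.5, rng)
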