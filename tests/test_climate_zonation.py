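"""Primary/secondary division, threshold intervals, and label determinism."""

import itertools

import numpy as np
import pytest

from nsikit.climate_zonation import (
    PRIMARY_TEMPERATURE_INTERVALS,
    SubAreaAssignment,
    ZonationConfig,
    assign_plots,
    primary_division,
    secondary_division,
    zonate,
)
from nsikit.errors import ConfigurationError, IntegrityError
from nsikit.records_io import SECONDARY_FACTORS, TownClimateRecord

from conftest import G, make_plot


def town(tid, at=5000.0, prec=1000.0, rh=75.0, temp=15.0, alt=1500.0):
    return TownClimateRecord(tid, at, prec, rh, temp, alt)


THRESHOLD = ZonationConfig(mode="threshold")


class TestPrimaryDivision:
    @pytest.mark.parametrize(
        "at,region", [(2000.0, "C"), (7000.0, "H"), (3300.0, "M"), (5000.0, "W")]
    )
    def test_threshold_mode_published_intervals(self, at, region):
        assert primary_division([town("T1", at=at)], THRESHOLD) == {"T1": region}

    def test_threshold_mode_interval_endpoints(self):
        # every published interval bound maps into its own region
        for region, (lo, hi) in PRIMARY_TEMPERATURE_INTERVALS.items():
            got = primary_division([town("a", at=lo), town("b", at=hi)], THRESHOLD)
            assert got == {"a": region, "b": region}

    def test_threshold_mode_gap_value_snaps_to_nearest(self, caplog):
        # 3240 sits in the gap between C (ends 3215) and M (starts 3280),
        # 25 from C's upper bound and 40 from M's lower: snaps to C
        with caplog.at_level("WARNING"):
            got = primary_division([town("T1", at=3240.0)], THRESHOLD)
        assert got == {"T1": "C"}
        assert any("outside all published intervals" in m for m in caplog.messages)

    def test_cluster_mode_four_separated_towns_are_singletons(self):
        towns = [town(t, at=v) for t, v in zip("abcd", (1500.0, 3300.0, 4400.0, 6400.0))]
        got = primary_division(towns, ZonationConfig(mode="cluster"))
        # brute force: any correct 4-clustering of 4 distinct points is
        # singletons; labels follow ascending means
        assert got == {"a": "C", "b": "M", "c": "W", "d": "H"}

    def test_cluster_mode_labels_invariant_under_row_permutation(self):
        rng = np.random.default_rng(7)
        towns = [town(f"T{i}", at=float(v)) for i, v in enumerate(rng.uniform(1500, 8000, 24))]
        reference = primary_division(towns, ZonationConfig(mode="cluster"))
        for perm in itertools.islice(itertools.permutations(towns), 0, 120, 17):
            assert primary_division(list(perm), ZonationConfig(mode="cluster")) == reference

    def test_fewer_towns_than_k_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            primary_division([town("T1")], ZonationConfig(mode="cluster", primary_k=4))


class TestSecondaryDivision:
    def test_k1_labels_everything_region_one(self):
        towns = [town(f"T{i}") for i in range(4)]
        got = secondary_division(towns, "W", k=1)
        assert set(got.values()) == {"W-I"}

    def test_two_singletons_follow_tie_break_chain(self):
        # equal sizes; lower mean precipitation gets the earlier numeral
        a, b = town("a", prec=700.0), town("b", prec=1400.0)
        assert secondary_division([a, b], "C", k=2) == {"a": "C-I", "b": "C-II"}
        assert secondary_division([b, a], "C", k=2) == {"a": "C-I", "b": "C-II"}

    def test_recovers_two_separated_factor_boxes(self):
        # towns drawn from two well-separated factor boxes; the exhaustive
        # minimum within-group-variance 2-partition is the oracle
        rng = np.random.default_rng(3)
        boxes = [
            {"prec": (1504, 2253), "rh": (77, 87), "temp": (16, 23), "alt": (334, 1770)},
            {"prec": (636, 898), "rh": (65, 77), "temp": (1, 10), "alt": (2614, 4069)},
        ]
        towns, truth = [], {}
        for b, box in enumerate(boxes):
            for i in range(5):
                tid = f"B{b}T{i}"
                towns.append(
                    town(
                        tid,
                        prec=float(rng.uniform(*box["prec"])),
                        rh=float(rng.uniform(*box["rh"])),
                        temp=float(rng.uniform(*box["temp"])),
                        alt=float(rng.uniform(*box["alt"])),
                    )
                )
                truth[tid] = b

        got = secondary_division(towns, "H", k=2)

        X = np.array([[getattr(t, f) for f in SECONDARY_FACTORS] for t in towns])
        Z = (X - X.mean(0)) / X.std(0)

        def ssw(mask):
            return sum(
                ((Z[idx] - Z[idx].mean(0)) ** 2).sum()
                for idx in (mask, ~mask)
                if idx.any()
            )

        best = min(
            (np.array([(m >> i) & 1 == 1 for i in range(len(towns))]) for m in range(1, 2 ** len(towns) - 1)),
            key=ssw,
        )
        oracle_partition = {frozenset(t.town_id for t, b in zip(towns, best) if b),
                            frozenset(t.town_id for t, b in zip(towns, best) if not b)}
        got_partition = {
            frozenset(tid for tid, lab in got.items() if lab == label)
            for label in set(got.values())
        }
        assert got_partition == oracle_partition
        # and the oracle partition is the generating one
        assert oracle_partition == {
            frozenset(t for t, b in truth.items() if b == 0),
            frozenset(t for t, b in truth.items() if b == 1),
        }

    def test_k_exceeding_town_count_errors(self):
        with pytest.raises(ConfigurationError):
            secondary_division([town("T1")], "C", k=2)


class TestZonate:
    def test_labels_partition_each_region(self):
        rng = np.random.default_rng(11)
        towns = [
            town(
                f"T{i:02d}",
                at=float(rng.uniform(1500, 8200)),
                prec=float(rng.uniform(600, 2200)),
                rh=float(rng.uniform(63, 87)),
                temp=float(rng.uniform(1, 23)),
                alt=float(rng.uniform(300, 4000)),
            )
            for i in range(40)
        ]
        config = ZonationConfig(mode="threshold", secondary_k={"C": 2, "M": 2, "W": 2, "H": 2})
        assignments = zonate(towns, config)
        assert len(assignments) == len(towns)
        assert {a.town_id for a in assignments} == {t.town_id for t in towns}
        for a in assignments:
            assert a.subarea_label.startswith(a.region_label + "-")

    def test_subarea_prefix_enforced(self):
        with pytest.raises(ValueError):
            SubAreaAssignment("T1", "C", "M-I")


class TestAssignPlots:
    def test_plot_inherits_town_subarea(self):
        a = SubAreaAssignment("T1", "H", "H-I")
        plot = make_plot([G] * 7, town_id="T1")
        assert assign_plots([plot], [a]) == {"P1": "H-I"}

    def test_orphan_town_is_integrity_error(self):
        plot = make_plot([G] * 7, town_id="T9")
        with pytest.raises(IntegrityError, match="P1"):
            assign_plots([plot], [SubAreaAssignment("T1", "H", "H-I")])

    def test_total_map_counts(self):
        assignments = [
            SubAreaAssignment("T1", "H", "H-I"),
            SubAreaAssignment("T2", "C", "C-I"),
            SubAreaAssignment("T3", "W", "W-II"),
        ]
        plots = [
            make_plot([G] * 7, plot_id=f"P{i}", town_id=f"T{1 + i % 3}") for i in range(10)
        ]
        assert len(assign_plots(plots, assignments)) == 10
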