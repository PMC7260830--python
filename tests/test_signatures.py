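"""Cloud/dispersed splitting, EM attribution, exposures, phenotypes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sigmodules import simulate as sim
from sigmodules.contexts import CHANNELS, channel_of, validate_catalog
from sigmodules.signatures import (
    attribute_mutations,
    build_exposure_table,
    filter_abundant,
    make_phenotype,
    split_cloud_dispersed,
)


def _mut_frame(rows):
    return pd.DataFrame(rows, columns=["sample", "chrom", "pos"]).assign(
        ref="C", alt="A", variant_type="SNV", consequence="non-silent", gene="")


class TestSplitCloudDispersed:
    @pytest.mark.parametrize(
        "rows, expected",
        [
            # two close + one far on one chromosome
            ([("s", "1", 100), ("s", "1", 600), ("s", "1", 10 ** 6)], ["C", "C", "D"]),
            # a single mutation is always dispersed
            ([("s", "1", 100)], ["D"]),
            # identical positions on different chromosomes are never neighbours
            ([("s", "1", 100), ("s", "2", 100), ("s", "3", 100)], ["D", "D", "D"]),
            # different samples are never neighbours
            ([("s1", "1", 100), ("s2", "1", 150)], ["D", "D"]),
            # boundary: distance exactly equal to the threshold counts as close
            ([("s", "1", 100), ("s", "1", 1100)], ["C", "C"]),
        ],
    )
    def test_labels(self, rows, expected):
        out = split_cloud_dispersed(_mut_frame(rows), distance_bp=1000)
        assert out.tolist() == expected

    def test_rejects_unsorted(self):
        df = _mut_frame([("s", "1", 600), ("s", "1", 100)])
        with pytest.raises(ValueError, match="sorted"):
            split_cloud_dispersed(df, 1000)

    def test_symmetric_labelling(self):
        """Labels form a symmetric neighbour relation: the label of each
        mutation is unchanged when the cohort is assembled in any order and
        re-sorted."""
        rng = np.random.default_rng(0)
        rows = [("s", "1", int(p)) for p in np.sort(rng.integers(1, 10 ** 6, 60))]
        df = _mut_frame(rows).drop_duplicates(subset=["sample", "chrom", "pos"])
        a = split_cloud_dispersed(df, 1000)
        shuffled = df.sample(frac=1, random_state=1).sort_values(
            ["sample", "chrom", "pos"]).reset_index(drop=True)
        b = split_cloud_dispersed(shuffled, 1000)
        merged = df.assign(lab=a.values).merge(
            shuffled.assign(lab2=b.values), on=["sample", "chrom", "pos"])
        assert (merged["lab"] == merged["lab2"]).all()


class TestAttribution:
    def test_single_signature_catalog(self, disjoint_catalog):
        cat = disjoint_catalog[["A"]]
        df = _mut_frame([("s", "1", i * 10 ** 5) for i in range(1, 21)])
        df["channel"] = np.arange(20)
        att, weights = attribute_mutations(df, cat, n_restarts=3, seed=0)
        assert (att["assigned_signature"] == "A").all()
        assert weights.loc["s", "A"] == pytest.approx(1.0)

    def test_disjoint_support_is_exact(self, disjoint_catalog):
        cfg = sim.SimulationConfig(
            n_patients=4, signature_catalog=disjoint_catalog,
            exposure_means={"A": 60, "B": 40}, seed=7)
        mut = sim.generate_mutation_catalog(cfg)
        att, _ = attribute_mutations(mut, disjoint_catalog, n_restarts=5, seed=1)
        assert (att["assigned_signature"] == att["true_signature"]).all()

    def test_mixture_weight_recovery(self, overlap_catalog):
        """70/30 mixture, ~1000 mutations: EM weights within 0.05 of truth."""
        cfg = sim.SimulationConfig(
            n_patients=1, signature_catalog=overlap_catalog,
            exposure_means={"A": 700, "B": 300}, seed=11)
        mut = sim.generate_mutation_catalog(cfg)
        _, weights = attribute_mutations(mut, overlap_catalog, n_restarts=7, seed=2)
        truth = mut["true_signature"].value_counts(normalize=True)
        assert weights.iloc[0]["A"] == pytest.approx(truth["A"], abs=0.05)
        assert weights.iloc[0]["B"] == pytest.approx(truth["B"], abs=0.05)

    def test_patient_without_snvs_is_tolerated(self, disjoint_catalog):
        df = _mut_frame([("s", "1", 100)])
        df["variant_type"] = "indel"
        att, weights = attribute_mutations(df, disjoint_catalog, n_restarts=2, seed=0)
        assert (att["assigned_signature"] == "").all()
        assert weights.loc["s"].isna().all()


class TestExposureTable:
    def test_counts_by_label(self):
        df = _mut_frame([("p", "1", 100), ("p", "1", 200), ("p", "1", 300)])
        df["assigned_signature"] = "2"
        df["context_group"] = "C"
        table = build_exposure_table(df)
        assert table.loc["p", "2C"] == 3
        assert table.to_numpy().sum() == 3

    def test_empty_input_gives_zero_table(self):
        df = _mut_frame([]).assign(assigned_signature=[], context_group=[])
        table = build_exposure_table(df, patients=["p1", "p2"])
        assert list(table.index) == ["p1", "p2"]
        assert (table.to_numpy() == 0).all() if table.shape[1] else True

    def test_conservation_against_generator_truth(self, disjoint_catalog):
        """Using the generator's true labels, column sums equal the number
        of mutations per signature-context."""
        cfg = sim.SimulationConfig(
            n_patients=3, signature_catalog=disjoint_catalog,
            exposure_means={"A": 50, "B": 30}, cloud_fraction=0.4, seed=5)
        mut = sim.generate_mutation_catalog(cfg)
        mut["assigned_signature"] = mut["true_signature"]
        mut["context_group"] = np.where(mut["true_cloud"], "C", "D")
        table = build_exposure_table(mut)
        for sig in ("A", "B"):
            for grp, flag in (("C", True), ("D", False)):
                expected = ((mut["true_signature"] == sig) & (mut["true_cloud"] == flag)).sum()
                got = table.get(f"{sig}{grp}", pd.Series(0, index=table.index)).sum()
                assert got == expected
        assert table.to_numpy().sum() == len(mut)


@pytest.mark.filterwarnings("ignore:no mutations in group:RuntimeWarning")
class TestFilterAbundant:
    def test_per_group_shares(self):
        table = pd.DataFrame({"1D": [150], "2D": [40], "5D": [810]}, index=["p"])
        assert filter_abundant(table, 0.10) == ["1D", "5D"]

    def test_boundary_is_strict(self):
        table = pd.DataFrame({"1D": [10], "2D": [90]}, index=["p"])
        assert filter_abundant(table, 0.10) == ["2D"]

    def test_uniform_twelve_signatures_all_dropped(self):
        table = pd.DataFrame({f"{i}D": [10] for i in range(1, 13)}, index=["p"])
        assert filter_abundant(table, 0.10) == []

    def test_groups_filtered_independently(self):
        table = pd.DataFrame({"1C": [90], "2C": [10], "1D": [5], "2D": [95]}, index=["p"])
        assert filter_abundant(table, 0.10) == ["1C", "2D"]

    def test_empty_group_warns(self):
        table = pd.DataFrame({"1D": [100]}, index=["p"])
        with pytest.warns(RuntimeWarning, match="group C"):
            assert filter_abundant(table) == ["1D"]


class TestMakePhenotype:
    def test_log_z_closed_form(self):
        table = pd.DataFrame({"2C": [9, 99, 999]}, index=["a", "b", "c"])
        z = make_phenotype(table, "2C", pseudocount=1).values
        assert np.allclose(z.to_numpy(), [-1.0, 0.0, 1.0])

    def test_constant_counts_error(self):
        table = pd.DataFrame({"2C": [5, 5, 5]}, index=list("abc"))
        with pytest.raises(ValueError, match="constant"):
            make_phenotype(table, "2C")

    @given(st.lists(st.integers(0, 10 ** 6), min_size=3, max_size=40))
    def test_z_score_identity(self, counts):
        table = pd.DataFrame({"x": counts}, index=[f"p{i}" for i in range(len(counts))])
        if len(set(counts)) < 2:
            with pytest.raises(ValueError):
                make_phenotype(table, "x")
            return
        z = make_phenotype(table, "x").values
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1.0) < 1e-9


def test_channel_of_pyrimidine_and_purine_strands():
    # A[C>A]A is channel 0; its reverse complement T[G>T]T maps to the same channel
    assert channel_of("A", "C", "A", "A") == 0
    assert channel_of("T", "G", "T", "T") == 0
    assert CHANNELS[channel_of("T", "T", "G", "G")] == "T[T>G]G"
    with pytest.raises(ValueError):
        channel_of("A", "C", "C", "A")


def test_validate_catalog_rejects_bad_rows(disjoint_catalog):
    bad = disjoint_catalog.copy()
    bad.iloc[0, 0] += 0.5
    with pytest.raises(ValueError, match="sum"):
        validate_catalog(bad)
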