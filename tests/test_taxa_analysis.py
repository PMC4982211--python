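import numpy as np
import pandas as pd
import pytest

from metacoman.io_tab import AnnotationMap, SampleMetadata
from metacoman.taxa_analysis import (
    feature_phylum_components,
    taxon_contribution,
    taxon_distribution,
    transcription_activation,
)


@pytest.fixture
def annot():
    return AnnotationMap(
        systems={
            "KO": {"gF": {"KO1"}, "gB": {"KO1"}, "gX": {"KO9"}},
        },
        phylum_of={"gF": "Firmicutes", "gB": "Bacteroidetes", "gX": "Proteobacteria"},
    )


@pytest.fixture
def meta():
    return SampleMetadata({"s1": "A", "s2": "A", "s3": "B", "s4": "B"})


def counts_frame(rows, samples):
    return pd.DataFrame(rows, columns=samples)


class TestComponents:
    def test_components_sum_to_profile_entry(self, annot):
        counts = pd.DataFrame(
            {"s1": [5, 5, 90]}, index=["gF", "gB", "gX"]
        )
        comp = feature_phylum_components(counts, annot, "KO")
        # KO1 total = 10 of 100 annotated reads
        assert comp.loc[("KO1", "Firmicutes"), "s1"] == pytest.approx(0.05)
        assert comp.loc[("KO1", "Bacteroidetes"), "s1"] == pytest.approx(0.05)
        assert comp.xs("KO1", level="feature")["s1"].sum() == pytest.approx(0.10)

    def test_unknown_system_errors(self, annot):
        counts = pd.DataFrame({"s1": [1]}, index=["gF"])
        with pytest.raises(KeyError, match="COG"):
            feature_phylum_components(counts, annot, "COG")


class TestTaxonContribution:
    def test_delta_and_share_example(self, annot, meta):
        # equal per-sample annotated totals (100), so components are counts/100.
        counts = pd.DataFrame(
            {
                "s1": [5, 5, 90],
                "s2": [5, 5, 90],
                "s3": [13, 7, 80],
                "s4": [13, 7, 80],
            },
            index=["gF", "gB", "gX"],
        )
        out = taxon_contribution(counts, annot, meta, ["KO1"])
        assert out.loc[("KO1", "Firmicutes"), "delta"] == pytest.approx(0.08)
        assert out.loc[("KO1", "Bacteroidetes"), "delta"] == pytest.approx(0.02)
        assert out.loc[("KO1", "Firmicutes"), "share"] == pytest.approx(0.8)
        assert out.loc[("KO1", "Bacteroidetes"), "share"] == pytest.approx(0.2)
        assert bool(out.loc[("KO1", "Firmicutes"), "top_phylum"])
        assert not bool(out.loc[("KO1", "Bacteroidetes"), "top_phylum"])

    def test_single_phylum_share_is_one(self, meta):
        annot = AnnotationMap(
            systems={"KO": {"gF": {"KO1"}}}, phylum_of={"gF": "Firmicutes"}
        )
        counts = pd.DataFrame(
            {"s1": [10], "s2": [10], "s3": [20], "s4": [20]}, index=["gF"]
        )
        out = taxon_contribution(counts, annot, meta, ["KO1"])
        # relative abundance of the only feature is constant 1.0, so delta = 0
        # unless another feature exists; use two features to create change
        assert out.loc[("KO1", "Firmicutes"), "flag"] == "no_variation"

    def test_no_variation_flag(self, annot, meta):
        counts = pd.DataFrame(
            {"s1": [5, 5, 90], "s2": [5, 5, 90], "s3": [5, 5, 90], "s4": [5, 5, 90]},
            index=["gF", "gB", "gX"],
        )
        out = taxon_contribution(counts, annot, meta, ["KO1"])
        assert (out["flag"] == "no_variation").all()
        assert out["share"].isna().all()

    def test_missing_feature_warns(self, annot, meta):
        counts = pd.DataFrame(
            {"s1": [5, 5, 90], "s2": [5, 5, 90], "s3": [13, 7, 80], "s4": [13, 7, 80]},
            index=["gF", "gB", "gX"],
        )
        with pytest.warns(UserWarning, match="no reads"):
            out = taxon_contribution(counts, annot, meta, ["KO1", "KO_absent"])
        assert "KO_absent" not in out.index.get_level_values("feature")


class TestTaxonDistribution:
    def test_fractions_per_condition(self, annot, meta):
        counts = pd.DataFrame(
            {"s1": [6, 4, 0], "s2": [6, 4, 0], "s3": [1, 9, 0], "s4": [1, 9, 0]},
            index=["gF", "gB", "gX"],
        )
        out = taxon_distribution(counts, annot, meta, ["KO1"])
        assert out.loc[("KO1", "A", "Firmicutes"), "fraction"] == pytest.approx(0.6)
        assert out.loc[("KO1", "A", "Bacteroidetes"), "fraction"] == pytest.approx(0.4)
        assert out.loc[("KO1", "B", "Firmicutes"), "fraction"] == pytest.approx(0.1)

    def test_condition_without_reads_has_no_rows(self, annot, meta):
        counts = pd.DataFrame(
            {"s1": [6, 4, 0], "s2": [6, 4, 0], "s3": [0, 0, 0], "s4": [0, 0, 0]},
            index=["gF", "gB", "gX"],
        )
        out = taxon_distribution(counts, annot, meta, ["KO1"])
        assert "B" not in out.index.get_level_values("condition")

    def test_fractions_sum_to_one_per_group(self, annot, meta, rng):
        counts = pd.DataFrame(
            rng.integers(1, 40, size=(3, 4)),
            index=["gF", "gB", "gX"],
            columns=["s1", "s2", "s3", "s4"],
        )
        out = taxon_distribution(counts, annot, meta, ["KO1", "KO9"])
        sums = out.groupby(level=["feature", "condition"])["fraction"].sum()
        np.testing.assert_allclose(sums, 1.0)

    def test_sample_order_invariance(self, annot, meta, rng):
        counts = pd.DataFrame(
            rng.integers(1, 40, size=(3, 4)),
            index=["gF", "gB", "gX"],
            columns=["s1", "s2", "s3", "s4"],
        )
        a = taxon_distribution(counts, annot, meta, ["KO1"])
        b = taxon_distribution(counts[["s4", "s2", "s3", "s1"]], annot, meta, ["KO1"])
        pd.testing.assert_frame_equal(a, b)


class TestTranscriptionActivation:
    def _taxa(self):
        return pd.DataFrame(
            {
                "s1": [0.25, 0.75],
                "s2": [0.25, 0.75],
                "s3": [0.50, 0.50],
                "s4": [0.50, 0.50],
            },
            index=["Firmicutes", "Bacteroidetes"],
        )

    def test_worked_ratio(self, meta):
        expr = pd.DataFrame(
            {"s1": [0.10], "s2": [0.10], "s3": [0.10], "s4": [0.10]}, index=["KO1"]
        )
        norm, _ = transcription_activation(
            expr, {"KO1": "Firmicutes"}, self._taxa(), meta
        )
        assert norm.loc["KO1", "s1"] == pytest.approx(0.10 / 0.25)
        assert norm.loc["KO1", "s3"] == pytest.approx(0.10 / 0.50)

    def test_proportional_change_gives_flat_activation(self, meta):
        # expression doubles where the phylum doubles: activation constant
        expr = pd.DataFrame(
            {"s1": [0.10], "s2": [0.10], "s3": [0.20], "s4": [0.20]}, index=["KO1"]
        )
        norm, stats = transcription_activation(
            expr, {"KO1": "Firmicutes"}, self._taxa(), meta
        )
        np.testing.assert_allclose(norm.loc["KO1"], 0.4)
        assert stats.loc["KO1", "p_value"] == 1.0

    def test_zero_phylum_fraction_is_missing_with_warning(self, meta):
        taxa = self._taxa()
        taxa.loc["Firmicutes", "s1"] = 0.0
        taxa.loc["Bacteroidetes", "s1"] = 1.0
        expr = pd.DataFrame(
            {"s1": [0.10], "s2": [0.10], "s3": [0.10], "s4": [0.10]}, index=["KO1"]
        )
        with pytest.warns(UserWarning, match="zero phylum abundance"):
            norm, _ = transcription_activation(
                expr, {"KO1": "Firmicutes"}, taxa, meta
            )
        assert np.isnan(norm.loc["KO1", "s1"])
        assert norm.loc["KO1", "s2"] == pytest.approx(0.4)

    def test_taxa_counts_normalised_per_sample(self, meta):
        taxa_counts = self._taxa() * 1000  # counts, not fractions
        expr = pd.DataFrame(
            {"s1": [0.10], "s2": [0.10], "s3": [0.10], "s4": [0.10]}, index=["KO1"]
        )
        norm, _ = transcription_activation(
            expr, {"KO1": "Firmicutes"}, taxa_counts, meta
        )
        assert norm.loc["KO1", "s1"] == pytest.approx(0.4)

    def test_no_shared_samples_errors(self, meta):
        taxa = self._taxa().rename(columns=lambda c: c + "_other")
        expr = pd.DataFrame({"s1": [0.1]}, index=["KO1"])
        with pytest.raises(ValueError, match="share no samples"):
            transcription_activation(expr, {"KO1": "Firmicutes"}, taxa, meta)
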