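"""zOTU post-processing: decontamination, density, curation, composition."""

import numpy as np
import pandas as pd
import pytest

from nestniche import (
    RAMatrix,
    curation_filter,
    decontaminate,
    designate_symbiotic,
    order_composition,
    prevalence,
    relative_abundance,
    spike_density,
    strain_profile,
    subtract_taxon_reads,
)


def _tax(zotus, **overrides):
    df = pd.DataFrame(
        {
            "order": "SomeOrder",
            "family": "SomeFamily",
            "genus": "SomeGenus",
            "is_spike_in": False,
            "is_anaplasmataceae": False,
            "is_weissella_target": False,
        },
        index=pd.Index(zotus, name="zotu"),
    )
    for col, vals in overrides.items():
        df[col] = vals
    return df


def _meta(samples, roles, **cols):
    df = pd.DataFrame({"role": roles}, index=pd.Index(samples, name="sample_id"))
    df["taxon_group"] = cols.get("taxon_group", "silverfish")
    df["lifestyle"] = cols.get("lifestyle", "Messor-specialized")
    df["nest_id"] = cols.get("nest_id", "N1")
    df["template_ng"] = cols.get("template_ng", 10.0)
    return df


class TestRelativeAbundance:
    def test_single_zotu_ra_one(self):
        counts = pd.DataFrame({"z1": [5, 50]}, index=["s1", "s2"])
        ra = relative_abundance(counts, _tax(["z1"]))
        assert (ra.data["z1"] == 1.0).all()

    def test_spike_excluded_from_denominator(self):
        counts = pd.DataFrame({"z1": [90], "spike": [10]}, index=["s1"])
        tax = _tax(["z1", "spike"], is_spike_in=[False, True])
        ra = relative_abundance(counts, tax)
        assert ra.data.loc["s1", "z1"] == pytest.approx(1.0)
        assert "spike" not in ra.data.columns
        assert "spike" in ra.excluded

    def test_rows_sum_to_one_random(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(1, 100, size=(20, 8)),
            index=[f"s{i}" for i in range(20)],
            columns=[f"z{i}" for i in range(8)],
        )
        ra = relative_abundance(counts, _tax(counts.columns))
        np.testing.assert_allclose(ra.data.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_read_sample_rejected(self):
        counts = pd.DataFrame({"z1": [0], "spike": [10]}, index=["s1"])
        tax = _tax(["z1", "spike"], is_spike_in=[False, True])
        with pytest.raises(ValueError):
            relative_abundance(counts, tax)


class TestDecontaminate:
    def _ra(self, exp_ra, blank_ra):
        data = pd.DataFrame(
            {"z1": [exp_ra, blank_ra], "zfill": [1 - exp_ra, 1 - blank_ra]},
            index=["exp1", "blank1"],
        )
        return RAMatrix(data, [], "test")

    def _meta2(self):
        return _meta(["exp1", "blank1"], ["experimental", "blank"])

    def test_tenfold_boundary_retained(self):
        # blank max 0.004, experimental max 0.05: 0.05 >= 0.04 -> retained
        kept, audit = decontaminate(self._ra(0.05, 0.004), self._meta2())
        assert "z1" in kept
        assert audit.loc["z1", "retained"]

    def test_below_tenfold_removed(self):
        kept, _ = decontaminate(self._ra(0.03, 0.004), self._meta2())
        assert "z1" not in kept

    def test_blank_only_removed_and_blank_free_retained(self):
        kept, _ = decontaminate(self._ra(0.0, 0.5), self._meta2())
        assert "z1" not in kept
        kept, audit = decontaminate(self._ra(0.0001, 0.0), self._meta2())
        assert "z1" in kept
        assert audit.loc["z1", "reason"] == "absent from all blanks"

    def test_no_blanks_is_an_error(self):
        ra = self._ra(0.5, 0.5)
        meta = _meta(["exp1", "blank1"], ["experimental", "experimental"])
        with pytest.raises(ValueError, match="blank"):
            decontaminate(ra, meta)

    def test_monotone_in_fold(self, amplicon_panel):
        counts, tax, meta = amplicon_panel
        ra = relative_abundance(counts, tax)
        kept10, _ = decontaminate(ra, meta, fold=10)
        kept5, _ = decontaminate(ra, meta, fold=5)
        assert set(kept10) <= set(kept5)

    def test_synthetic_panel_exact_separation(self, amplicon_panel):
        """Every injected contaminant removed, every symbiont retained."""
        counts, tax, meta = amplicon_panel
        ra = relative_abundance(counts, tax)
        kept, _ = decontaminate(ra, meta, fold=10)
        contaminants = {z for z in counts.columns if z.startswith("zotu_cont_")}
        symbionts = set(counts.columns) - contaminants - {"zotu_spike_ec5502"}
        assert contaminants.isdisjoint(kept)
        assert symbionts <= set(kept)


class TestDesignateSymbiotic:
    def _run(self, max_ra):
        data = pd.DataFrame({"z1": [max_ra, 1.0], "zf": [1 - max_ra, 0.0]},
                            index=["e1", "e2"])
        data.loc["e2"] = [0.0, 1.0]
        meta = _meta(["e1", "e2"], ["experimental", "experimental"])
        return designate_symbiotic(RAMatrix(data, [], ""), meta, threshold=0.001)

    def test_above_threshold_symbiotic(self):
        assert "z1" in self._run(0.0011)

    def test_exact_threshold_not_symbiotic(self):
        # the rule is strictly "higher than 0.001"
        assert "z1" not in self._run(0.001)

    def test_all_zero_not_symbiotic(self):
        assert "z1" not in self._run(0.0)


class TestSubtractTaxonReads:
    def test_identity_without_flagged_columns(self):
        counts = pd.DataFrame({"z1": [1], "z2": [2]}, index=["s1"])
        out = subtract_taxon_reads(counts, _tax(["z1", "z2"]))
        pd.testing.assert_frame_equal(out, counts)

    def test_flagged_columns_removed_conservatively(self):
        counts = pd.DataFrame(
            {"z1": [5], "w1": [7], "w2": [3], "w3": [2]}, index=["s1"]
        )
        tax = _tax(
            ["z1", "w1", "w2", "w3"],
            is_anaplasmataceae=[False, True, True, True],
        )
        out = subtract_taxon_reads(counts, tax)
        assert list(out.columns) == ["z1"]
        assert counts.sum(axis=1)[0] - out.sum(axis=1)[0] == 12

    def test_composition_changes_only_through_denominator(self):
        counts = pd.DataFrame({"a": [30], "b": [10], "w": [60]}, index=["s1"])
        tax = _tax(
            ["a", "b", "w"],
            order=["O1", "O2", "O3"],
            is_anaplasmataceae=[False, False, True],
        )
        before = order_composition(counts, tax, top_n=3)
        after = order_composition(subtract_taxon_reads(counts, tax), tax, top_n=2)
        # numerator ratio a:b is preserved; only the denominator changed
        assert before.loc["s1", "O1"] / before.loc["s1", "O2"] == pytest.approx(3.0)
        assert after.loc["s1", "O1"] == pytest.approx(0.75)
        assert after.loc["s1", "O2"] == pytest.approx(0.25)


class TestSpikeDensity:
    def _tables(self, sym=10000, spike=1000, wolb=0, ng=10.0):
        counts = pd.DataFrame(
            {"z1": [sym], "w1": [wolb], "spike": [spike]}, index=["s1"]
        )
        tax = _tax(
            ["z1", "w1", "spike"],
            is_anaplasmataceae=[False, True, False],
            is_spike_in=[False, False, True],
        )
        meta = _meta(["s1"], ["experimental"], template_ng=ng)
        return counts, tax, meta

    def test_formula_arithmetic(self):
        # 10000 symbiotic reads / 1000 spike reads * 1000 copies / 10 ng
        d = spike_density(*self._tables())
        assert d.loc["s1", "copies_per_ng"] == pytest.approx(1000.0)

    def test_all_reads_subtracted_gives_zero(self):
        d = spike_density(*self._tables(sym=0, wolb=5000))
        assert d.loc["s1", "copies_per_ng"] == 0.0
        assert d.loc["s1", "subtracted_reads"] == 5000

    def test_doubling_template_halves_density(self):
        d1 = spike_density(*self._tables(ng=10.0))
        d2 = spike_density(*self._tables(ng=20.0))
        assert d2.loc["s1", "copies_per_ng"] == pytest.approx(
            d1.loc["s1", "copies_per_ng"] / 2
        )

    def test_zero_spike_flagged_undefined(self):
        d = spike_density(*self._tables(spike=0))
        assert bool(d.loc["s1", "undefined"])
        assert np.isnan(d.loc["s1", "copies_per_ng"])

    def test_recovers_generator_truth(self, amplicon_panel):
        """Estimated copies/ng tracks the generator's ground truth."""
        counts, tax, meta = amplicon_panel
        ra = relative_abundance(counts, tax)
        kept, _ = decontaminate(ra, meta)
        sym = designate_symbiotic(RAMatrix(ra.data[kept], [], ""), meta)
        d = spike_density(counts, tax, meta, zotus=sym)
        ok = ~d["undefined"]
        est = d.loc[ok, "copies_per_ng"]
        truth = meta.loc[est.index, "true_copies_per_ng"]
        rel_bias = (est.mean() - truth.mean()) / truth.mean()
        assert abs(rel_bias) < 0.02


class TestCurationFilter:
    def test_mean_threshold_boundary_inclusive(self):
        rng = np.random.default_rng(0)
        base = rng.integers(50, 100, size=(10, 1))
        cols = {
            "z_low": np.full(10, 19.9) + rng.normal(0, 3, 10),
            "z_edge": np.full(10, 20.0),
            "z_high": base[:, 0].astype(float),
        }
        counts = pd.DataFrame(cols).round().astype(int)
        counts["z_low"] -= counts["z_low"].mean().astype(int) - 19  # mean < 20
        counts["z_edge"] = [20] * 5 + [19, 21, 18, 22, 20]  # mean exactly 20
        kept, audit = curation_filter(counts, mean_threshold=20)
        assert not audit.loc["z_low", "passed_mean"]
        assert audit.loc["z_edge", "passed_mean"]

    def test_constant_zotu_removed_by_variance_step(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            {
                "z_const": [30] * 10,
                **{f"z{i}": rng.integers(20, 80, 10) for i in range(5)},
            }
        )
        kept, _ = curation_filter(counts)
        assert "z_const" not in kept

    def test_lowest_decile_sd_removed(self):
        # 10 zOTUs with SDs 1..10 at fraction 0.10: exactly the SD=1 one drops
        rng = np.random.default_rng(2)
        cols = {}
        for k in range(1, 11):
            x = rng.normal(100, k, 400)
            x = (x - x.mean()) / x.std(ddof=1) * k + 100  # exact mean/SD
            cols[f"z{k}"] = x
        counts = pd.DataFrame(cols)
        kept, audit = curation_filter(counts, mean_threshold=20, low_variance_fraction=0.10)
        assert "z1" not in kept
        assert all(f"z{k}" in kept for k in range(2, 11))

    def test_all_filtered_is_an_error(self):
        counts = pd.DataFrame({"z1": [1, 2], "z2": [0, 1]})
        with pytest.raises(ValueError):
            curation_filter(counts, mean_threshold=20)


class TestOrderComposition:
    def test_single_order_is_unity(self):
        counts = pd.DataFrame({"z1": [10], "z2": [5]}, index=["s1"])
        tax = _tax(["z1", "z2"], order=["O1", "O1"])
        comp = order_composition(counts, tax, top_n=9)
        assert comp.loc["s1", "O1"] == pytest.approx(1.0)

    def test_nest_average_is_mean_of_proportions(self):
        counts = pd.DataFrame(
            {"z1": [20, 40], "z2": [80, 60]}, index=["s1", "s2"]
        )
        tax = _tax(["z1", "z2"], order=["O1", "O2"])
        meta = _meta(["s1", "s2"], ["experimental", "experimental"])
        comp = order_composition(counts, tax, meta, top_n=2, group_by=["nest_id"])
        assert comp.iloc[0]["O1"] == pytest.approx(0.3)
        assert comp.iloc[0]["O2"] == pytest.approx(0.7)

    def test_rows_sum_to_one_after_folding(self):
        rng = np.random.default_rng(3)
        zotus = [f"z{i}" for i in range(30)]
        counts = pd.DataFrame(
            rng.integers(0, 200, size=(12, 30)) + 1,
            index=[f"s{i}" for i in range(12)],
            columns=zotus,
        )
        orders = [f"O{i % 13}" if i % 5 else "unassigned" for i in range(30)]
        tax = _tax(zotus, order=orders)
        comp = order_composition(counts, tax, top_n=9)
        np.testing.assert_allclose(comp.sum(axis=1), 1.0, atol=1e-9)
        assert "Other" in comp.columns
        assert "unassigned" not in comp.columns
        assert comp.shape[1] == 10

    def test_unassigned_never_ranked(self):
        counts = pd.DataFrame({"z1": [90], "z2": [10]}, index=["s1"])
        tax = _tax(["z1", "z2"], order=["unassigned", "O1"])
        comp = order_composition(counts, tax, top_n=1)
        assert list(comp.columns) == ["O1", "Other"]
        assert comp.loc["s1", "Other"] == pytest.approx(0.9)


class TestStrainProfileAndPrevalence:
    def test_zero_counts_all_absent(self):
        counts = pd.DataFrame({"w1": [0, 0], "w2": [0, 0]}, index=["s1", "s2"])
        tax = _tax(["w1", "w2"], is_weissella_target=[True, True])
        prof = strain_profile(counts, tax)
        assert not prof.to_numpy().any()

    def test_flagged_columns_define_width(self):
        zotus = [f"w{i}" for i in range(18)] + ["z1"]
        counts = pd.DataFrame(
            np.ones((2, 19), dtype=int), index=["s1", "s2"], columns=zotus
        )
        tax = _tax(zotus, is_weissella_target=[True] * 18 + [False])
        prof = strain_profile(counts, tax)
        assert prof.shape[1] == 18

    def test_detection_threshold(self):
        counts = pd.DataFrame({"w1": [1]}, index=["s1"])
        tax = _tax(["w1"], is_weissella_target=[True])
        assert strain_profile(counts, tax, detection_min_reads=1).loc["s1", "w1"] == 1
        assert strain_profile(counts, tax, detection_min_reads=2).loc["s1", "w1"] == 0

    def test_prevalence_fraction(self):
        prof = pd.DataFrame(
            {"w1": [1] * 7 + [0] * 3}, index=[f"s{i}" for i in range(10)]
        )
        meta = _meta(prof.index, ["experimental"] * 10)
        out = prevalence(prof, meta, "lifestyle")
        assert out.loc[0, "prevalence"] == pytest.approx(0.7)

    def test_union_prevalence_dominates_single_targets(self):
        rng = np.random.default_rng(4)
        prof = pd.DataFrame(
            rng.integers(0, 2, size=(30, 2)),
            index=[f"s{i}" for i in range(30)],
            columns=["w1", "w2"],
        )
        meta = _meta(prof.index, ["experimental"] * 30)
        union = prevalence(prof, meta, "lifestyle").loc[0, "prevalence"]
        singles = [
            prevalence(prof[[c]], meta, "lifestyle").loc[0, "prevalence"]
            for c in prof.columns
        ]
        assert union >= max(singles)
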