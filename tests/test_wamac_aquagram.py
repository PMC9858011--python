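import numpy as np
import pandas as pd
import pytest

from waspmon import spectra_io as io
from waspmon import wamac_aquagram as wa
from waspmon.diffspec import empty_peak_table

from conftest import make_set


def _peaks(source, context, wavelengths):
    return pd.DataFrame(
        {
            "wavelength": [float(w) for w in wavelengths],
            "sign": [1] * len(wavelengths),
            "magnitude": [1.0] * len(wavelengths),
            "source": source,
            "context": context,
        }
    )


class TestBuildEvidence:
    def test_empty_inputs_give_empty_table(self):
        assert len(wa.build_evidence([empty_peak_table()], "outer")) == 0

    def test_duplicates_within_context_collapse(self):
        t = pd.concat([_peaks("diff", "Day 2-Day 1", [1441]),
                       _peaks("diff", "Day 2-Day 1", [1441])])
        ev = wa.build_evidence([t], "outer")
        assert len(ev) == 1

    def test_snapping_to_grid_with_warning_beyond_half_spacing(self):
        grid = io.SpectrumGrid(np.arange(1300.0, 1400.0, 10.0))
        ev = wa.build_evidence([_peaks("diff", "c", [1342.0])], "outer", grid)
        assert ev["wavelength"].tolist() == [1340.0]
        # off-grid beyond half a channel spacing (below the grid start)
        with pytest.warns(UserWarning, match="half spacing"):
            wa.build_evidence([_peaks("diff", "c", [1292.0])], "outer", grid)

    def test_published_table_fixture_counts(self):
        # consistent-only evidence for the inner zone: count equals the
        # hand count of highlighted entries in the bundled table
        ev = wa.reference_evidence("inner")
        by_source = ev.groupby("source").size().to_dict()
        assert by_source["diff"] == 21
        assert by_source["lda_contrib"] == 5
        assert by_source["pls_vector"] == 11
        assert len(ev) == ev.drop_duplicates(["source", "context", "wavelength"]).shape[0]


class TestSelectWamacs:
    def test_two_sources_one_zone_plus_presence_other_zone_selected(self):
        inner = wa.build_evidence([_peaks("diff", "Day 2-Day 1", [1441])], "inner")
        outer = wa.build_evidence(
            [_peaks("diff", "Day 3-Day 1", [1441]), _peaks("pls_vector", "rv", [1441])],
            "outer",
        )
        sel = wa.select_wamacs(inner, outer)
        assert sel.wavelengths == [1441.0]

    def test_single_nomination_single_zone_not_selected(self):
        outer = wa.build_evidence([_peaks("diff", "Day 2-Day 1", [1441])], "outer")
        sel = wa.select_wamacs(wa.build_evidence([], "inner"), outer)
        assert sel.wavelengths == []

    def test_both_zone_requirement_can_be_relaxed(self):
        outer = wa.build_evidence(
            [_peaks("diff", "d", [1497]), _peaks("lda_contrib", "o", [1497])], "outer"
        )
        inner = wa.build_evidence([], "inner")
        assert wa.select_wamacs(inner, outer).wavelengths == []
        assert wa.select_wamacs(inner, outer, require_both_zones=False).wavelengths == [1497.0]

    def test_monotone_adding_evidence_never_removes_selection(self):
        inner = wa.reference_evidence("inner")
        outer = wa.reference_evidence("outer")
        base = set(wa.select_wamacs(inner, outer).wavelengths)
        extra = pd.concat(
            [outer, wa.build_evidence([_peaks("diff", "Day 9-Day 1", [1500])], "outer")],
            ignore_index=True,
        )
        grown = set(wa.select_wamacs(inner, extra).wavelengths)
        assert base <= grown

    def test_published_evidence_tables_reproduce_the_19_wamacs(self):
        """The frozen consensus rule (>=2 distinct sources in one zone, and
        presence in both zones) applied to the published prominent-wavelength
        tables selects exactly the 19 published WAMACs."""
        sel = wa.select_wamacs(
            wa.reference_evidence("inner"), wa.reference_evidence("outer")
        )
        published = wa.load_reference_tables()["published_wamacs"]
        assert sel.wavelengths == [float(w) for w in published]
        assert len(sel) == 19


class TestComputeAquagram:
    def _group_set(self, rows_by_day, p=8):
        rows, days = [], []
        for day, specs in rows_by_day.items():
            for r in specs:
                rows.append(np.full(p, float(r)) if np.isscalar(r) else r)
                days.append(day)
        return make_set(np.array(rows), days=days)

    def test_identical_groups_give_zero(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=8)
        jitter = rng.normal(scale=1e-3, size=(6, 8))
        data = self._group_set({1: [base + jitter[i] for i in range(3)],
                                2: [base + jitter[i + 3] for i in range(3)]})
        wam = wa.WamacSet([1310.0, 1340.0], {})
        aq = wa.compute_aquagram(data, wam, reference_group=1, pretreat=[])
        # groups drawn from the same distribution: values near zero
        assert np.abs(aq.values.to_numpy()).max() < 2.0
        np.testing.assert_allclose(aq.values.loc[1], 0, atol=1e-12)

    def test_two_group_hand_computation(self):
        # one informative channel, groups {g1: 0, g2: 2}, two rows each
        x = np.zeros((4, 8))
        x[2:, 3] = 2.0
        data = self._group_set({1: [x[0], x[1]], 2: [x[2], x[3]]})
        wam = wa.WamacSet([1330.0], {})
        aq = wa.compute_aquagram(data, wam, reference_group=1, pretreat=[])
        # channel values [0,0,2,2]: mu=1, sd=sqrt(4/3); z = -+1/sd
        sd = np.sqrt(4.0 / 3.0)
        assert aq.values.loc[2, 1330.0] == pytest.approx(2.0 / sd)
        assert aq.values.loc[1, 1330.0] == 0.0

    def test_invariant_to_global_affine_transform(self, trimmed):
        z = trimmed.zone("outer")
        wam = wa.WamacSet([1441.0, 1534.0], {})
        a = wa.compute_aquagram(z, wam, pretreat=[])
        z2 = z.with_absorbance(3.0 * z.absorbance + 0.7)
        b = wa.compute_aquagram(z2, wam, pretreat=[])
        np.testing.assert_allclose(a.values.to_numpy(), b.values.to_numpy(), atol=1e-9)

    def test_seeded_synthetic_outer_day6_signs_match_programmed_trends(self, trimmed):
        """The aquagram recovers the programmed storage dynamics: at day 6
        the outer-zone value is positive at 1534 nm (growing band) and
        negative at 1441 nm (shrinking band)."""
        wam = wa.WamacSet([1441.0, 1534.0], {})
        aq = wa.compute_aquagram(trimmed.zone("outer"), wam)
        assert aq.values.loc[6, 1534.0] > 0
        assert aq.values.loc[6, 1441.0] < 0

    def test_zero_variance_channel_reported(self):
        data = self._group_set({1: [np.zeros(8)], 2: [np.zeros(8)]})
        wam = wa.WamacSet([1310.0], {})
        with pytest.raises(ValueError, match="zero variance"):
            wa.compute_aquagram(data, wam, reference_group=1, pretreat=[])


class TestAnnotation:
    def test_class_assignment_examples(self):
        wam = wa.WamacSet([1300.0, 1422.0, 1571.0], {})
        ann = wa.wamac_annotation(wam).set_index("wavelength")
        assert ann.loc[1422.0, "wamac_class"] == "C6"
        assert ann.loc[1571.0, "wamac_class"] == "unclassified"  # 1560-1590 range
        assert ann.loc[1300.0, "wamac_class"] == "unclassified"

    def test_all_19_wamacs_annotated(self):
        wam = wa.WamacSet(
            [float(w) for w in wa.load_reference_tables()["published_wamacs"]], {}
        )
        ann = wa.wamac_annotation(wam)
        assert len(ann) == 19
        assert (ann["assignment"] != "").all()
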