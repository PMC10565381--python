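"""Low-count removal, induction ratios, regulated-gene selection, classes."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lncscreen.ko_screen import (
    GROUPS,
    ScreenConfig,
    ScreenRecord,
    cluster_classes,
    induction_difference_ratio,
    low_count_filter,
    relative_foldchange_ratio,
    run_screen,
    select_regulated,
)


def record(wt0, wt4, ko0, ko4, reads=100, gene="g"):
    return ScreenRecord(
        gene,
        dict(zip(GROUPS, map(float, (wt0, wt4, ko0, ko4)))),
        {g: reads for g in GROUPS},
    )


class TestLowCountFilter:
    def make(self, gene, reads_by_group):
        return ScreenRecord(
            gene, {g: 1.0 for g in GROUPS}, dict(zip(GROUPS, reads_by_group))
        )

    def test_all_groups_low_removed(self):
        recs = [
            self.make("zero", (0, 0, 0, 0)),
            self.make("four", (4, 4, 4, 4)),
            self.make("one_high", (0, 100, 0, 0)),
            self.make("rich", (50, 60, 70, 80)),
        ]
        retained, removed = low_count_filter(recs)
        assert removed == ["zero", "four"]
        assert [r.gene_id for r in retained] == ["one_high", "rich"]

    def test_any_group_variant(self):
        recs = [self.make("one_high", (0, 100, 0, 0))]
        cfg = ScreenConfig(low_in_all_groups=False)
        retained, removed = low_count_filter(recs, cfg)
        assert removed == ["one_high"] and not retained


class TestRatios:
    def test_hand_arithmetic(self):
        r = record(2, 10, 2, 4)
        assert induction_difference_ratio(r) == pytest.approx(0.25)
        assert relative_foldchange_ratio(r, epsilon=0.0) == pytest.approx(0.4)

    def test_identical_induction_is_unity(self):
        r = record(2, 6, 3, 7)  # same +4 difference
        assert induction_difference_ratio(r) == pytest.approx(1.0)
        flat = record(5, 5, 5, 5)
        assert relative_foldchange_ratio(flat, epsilon=0.0) == pytest.approx(1.0)

    def test_degenerate_wt_difference_gives_signed_infinity(self):
        assert induction_difference_ratio(record(5, 5, 5, 9)) == math.inf
        assert induction_difference_ratio(record(5, 5, 9, 5)) == -math.inf
        assert math.isnan(induction_difference_ratio(record(5, 5, 7, 7)))

    def test_zero_fpkm_needs_epsilon(self):
        r = record(0, 10, 2, 4)
        with pytest.raises(ValueError, match="epsilon"):
            relative_foldchange_ratio(r, epsilon=0.0)
        assert relative_foldchange_ratio(r, epsilon=0.01) > 0

    def test_wt_ko_swap_inverts_r_fc(self):
        r = record(2, 10, 3, 4)
        swapped = record(3, 4, 2, 10)
        assert relative_foldchange_ratio(r, 0.0) == pytest.approx(
            1.0 / relative_foldchange_ratio(swapped, 0.0)
        )

    @given(
        st.floats(0.5, 100), st.floats(0.5, 100), st.floats(0.5, 100), st.floats(0.5, 100),
        st.floats(0.1, 10),
    )
    def test_scale_invariance(self, wt0, wt4, ko0, ko4, c):
        r1 = record(wt0, wt4, ko0, ko4)
        r2 = record(c * wt0, c * wt4, c * ko0, c * ko4)
        f1 = relative_foldchange_ratio(r1, 0.0)
        f2 = relative_foldchange_ratio(r2, 0.0)
        assert f1 == pytest.approx(f2, rel=1e-9)
        d1 = induction_difference_ratio(r1)
        d2 = induction_difference_ratio(r2)
        if math.isfinite(d1):
            assert d1 == pytest.approx(d2, rel=1e-9, abs=1e-12)


class TestSelection:
    def selected(self, r_rec):
        return select_regulated([r_rec], ScreenConfig(epsilon=0.0)).selected

    def test_both_criteria_in_low_tail(self):
        assert self.selected(record(2, 10, 2, 4)) == ["g"]  # 0.25 / 0.4

    def test_null_gene_not_selected(self):
        assert not self.selected(record(5, 10, 5, 10))  # 1 / 1

    def test_conjunction_required(self):
        # r_diff = 3 but r_fc = (16/4)/(8/4) = 2 exactly: ">2" is strict,
        # the second criterion fails and the conjunction rejects the gene
        assert not self.selected(record(4, 8, 4, 16))

    def test_negative_r_diff_counts_as_low(self):
        # KO goes down while WT goes up; r_fc deep in the low tail too
        assert self.selected(record(4, 16, 16, 4)) == ["g"]

    def test_selection_invariant_under_wt_ko_exchange(self, rng):
        cfg = ScreenConfig(epsilon=0.0)
        for _ in range(200):
            wt0, ko0 = rng.uniform(1, 50, size=2)
            wt4, ko4 = rng.uniform(1, 50, size=2)
            r = record(wt0, wt4, ko0, ko4)
            s = record(ko0, ko4, wt0, wt4)
            d1 = induction_difference_ratio(r)
            if not (math.isfinite(d1) and d1 > 0):
                continue
            sel1 = bool(select_regulated([r], cfg).ratios["selected"].iloc[0])
            sel2 = bool(select_regulated([s], cfg).ratios["selected"].iloc[0])
            assert sel1 == sel2


def archetype_matrix():
    """10 genes each of three well-separated profile archetypes, 12 samples."""
    profiles = {
        "up": (1, 3, 1, 17),
        "down": (1, 3, 4, 2),
        "wtonly": (1, 5, 1, 1),
    }
    rows, names, truth = [], [], {}
    for arch, mult in profiles.items():
        for i in range(10):
            b = 5.0 + 3.0 * i
            rows.append(np.repeat([b * m for m in mult], 3))
            names.append(f"{arch}_{i}")
            truth[f"{arch}_{i}"] = arch
    cols = [f"{g}_r{r}" for g in GROUPS for r in (1, 2, 3)]
    return pd.DataFrame(rows, index=names, columns=cols), truth


class TestClusterClasses:
    def test_planted_archetypes_recovered_purely(self):
        fpkm, truth = archetype_matrix()
        labels = cluster_classes(fpkm, k=3)
        by_label = {}
        for gene, lab in labels.items():
            by_label.setdefault(lab, set()).add(truth[gene])
        assert sorted(by_label) == ["I", "II", "III"]
        assert all(len(archs) == 1 for archs in by_label.values())

    def test_row_permutation_invariance(self, rng):
        fpkm, _ = archetype_matrix()
        perm = fpkm.sample(frac=1.0, random_state=3)
        assert cluster_classes(fpkm) == cluster_classes(perm)

    def test_identical_rows_rejected(self):
        fpkm = pd.DataFrame(np.ones((5, 12)), index=[f"g{i}" for i in range(5)])
        with pytest.raises(ValueError, match="identical"):
            cluster_classes(fpkm)

    def test_too_few_genes_rejected(self):
        fpkm, _ = archetype_matrix()
        with pytest.raises(ValueError, match="need >= 3"):
            cluster_classes(fpkm.iloc[:2])


class TestBookkeeping:
    def test_partition_of_input_genes(self):
        low = ScreenRecord("low", {g: 1.0 for g in GROUPS}, {g: 1 for g in GROUPS})
        null = record(5, 10, 5, 10, gene="null")
        hit = record(2, 10, 2, 4, gene="hit")
        fpkm = pd.DataFrame(
            np.ones((3, 12)),
            index=["low", "null", "hit"],
            columns=[f"{g}_r{r}" for g in GROUPS for r in (1, 2, 3)],
        )
        result, removed = run_screen([low, null, hit], fpkm)
        n_rejected = int((~result.ratios["selected"]).sum())
        assert len(result.selected) + n_rejected + len(removed) == 3
        assert result.selected == ["hit"] and removed == ["low"]
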