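"""Relative positions, positional densities, Tau stratification, family
density tables."""

import numpy as np
import pandas as pd
import pytest

from tadgc.features import (
    class_expression_comparison,
    family_density_table,
    position_band,
    positional_density,
    relative_positions,
    stratify_genes,
    tau,
)
from tadgc.intervals import Feature, FeatureSet, GenomicInterval
from tadgc.io import ExpressionTable


def fs(*triples):
    return FeatureSet(
        [Feature(GenomicInterval(c, s, e), k, i) for (c, s, e), k, i in triples]
    )


class TestRelativePositions:
    tads = [("t1", GenomicInterval("chr1", 0, 1000))]

    def test_midpoint_arithmetic(self):
        res = relative_positions(self.tads, fs((("chr1", 100, 200), "gene", "g")))
        assert res.records.loc[0, "rel_pos"] == pytest.approx(0.15)

    def test_boundary_spanning_dropped(self):
        res = relative_positions(self.tads, fs((("chr1", 900, 1100), "gene", "g")))
        assert len(res.records) == 0
        assert res.n_boundary_dropped == 1

    def test_point_like_feature_at_start(self):
        res = relative_positions(self.tads, fs((("chr1", 0, 2), "ctcf", "c")))
        assert res.records.loc[0, "rel_pos"] == pytest.approx(0.001)

    def test_outside_all_tads(self):
        res = relative_positions(self.tads, fs((("chr2", 0, 10), "gene", "g")))
        assert res.n_outside == 1

    def test_nested_tads_smallest_container_wins(self):
        tads = [
            ("outer", GenomicInterval("chr1", 0, 10_000)),
            ("inner", GenomicInterval("chr1", 4000, 6000)),
        ]
        res = relative_positions(tads, fs((("chr1", 4500, 4700), "gene", "g")))
        assert res.records.loc[0, "tad_id"] == "inner"

    def test_accounting_conservation(self, rng):
        """assigned + boundary-dropped + outside = total features."""
        tads = [
            (f"t{i}", GenomicInterval("chr1", i * 10_000, i * 10_000 + 8000))
            for i in range(20)
        ]
        feats = []
        for i in range(300):
            start = int(rng.integers(0, 210_000))
            feats.append(
                Feature(GenomicInterval("chr1", start, start + 500), "gene", f"g{i}")
            )
        res = relative_positions(tads, FeatureSet(feats))
        assert res.n_assigned + res.n_boundary_dropped + res.n_outside == 300

    def test_orientation_duality(self, rng):
        """Mirroring feature and TAD coordinates maps rel_pos -> 1 - rel_pos."""
        L = 100_000
        starts = rng.integers(0, L - 500, size=50)
        fwd = relative_positions(
            [("t", GenomicInterval("chr1", 0, L))],
            FeatureSet(
                [Feature(GenomicInterval("chr1", int(s), int(s) + 500), "gene", f"g{i}")
                 for i, s in enumerate(starts)]
            ),
        )
        rev = relative_positions(
            [("t", GenomicInterval("chr1", 0, L))],
            FeatureSet(
                [Feature(GenomicInterval("chr1", L - int(s) - 500, L - int(s)), "gene", f"g{i}")
                 for i, s in enumerate(starts)]
            ),
        )
        assert np.allclose(
            fwd.records["rel_pos"], 1.0 - rev.records["rel_pos"], atol=1e-12
        )

    @pytest.mark.parametrize(
        "pos,band", [(0.1, "border"), (0.9, "border"), (0.5, "centre"), (0.25, "intermediate")]
    )
    def test_bands(self, pos, band):
        assert position_band(pos) == band


class TestPositionalDensity:
    def test_point_mass_mode(self, rng):
        data = np.full(200, 0.5) + rng.normal(0, 0.01, 200)
        dens = positional_density(data)
        assert abs(dens.kde_x[np.argmax(dens.kde_y)] - 0.5) < 0.05

    def test_kde_integrates_to_one(self, rng):
        for data in (rng.beta(0.5, 0.5, 500), rng.uniform(0, 1, 500), rng.beta(4, 4, 500)):
            dens = positional_density(data)
            integral = np.trapezoid(dens.kde_y, dens.kde_x)
            assert integral == pytest.approx(1.0, abs=0.01)

    def test_few_records_histogram_only(self):
        dens = positional_density([0.1, 0.5, 0.9])
        assert dens.kde_x is None
        assert dens.hist_counts.sum() == 3

    def test_border_biased_shape(self, rng):
        data = rng.beta(0.5, 0.5, 2000)
        dens = positional_density(data)
        edges = dens.hist_edges
        border = dens.hist_counts[edges[:-1] < 0.1].sum() + dens.hist_counts[edges[:-1] >= 0.9].sum()
        centre = dens.hist_counts[(edges[:-1] >= 0.45) & (edges[:-1] < 0.55)].sum()
        assert border > centre


class TestTau:
    def test_uniform_row_zero(self):
        assert tau([5.0, 5.0, 5.0, 5.0]) == 0.0

    def test_one_hot_row_one(self):
        assert tau([0.0, 0.0, 9.0, 0.0]) == 1.0

    def test_hand_computed_four_tissue_example(self):
        """Hand-calculator oracle for TPM row (8, 2, 0.5, 0.5)."""
        # x = log2(TPM + 1) = (log2 9, log2 3, log2 1.5, log2 1.5)
        # x / max = (1, 1/2, log2(1.5)/log2(9), same)  [log2 3 / log2 9 = 1/2]
        l = np.log2(1.5) / np.log2(9.0)
        expected = ((1 - 1) + (1 - 0.5) + 2 * (1 - l)) / 3
        assert tau([8.0, 2.0, 0.5, 0.5]) == pytest.approx(expected, abs=1e-9)

    def test_all_zero_undefined(self):
        assert np.isnan(tau([0.0, 0.0, 0.0]))

    def test_raw_transform_scale_invariance(self, rng):
        """Under the raw (untransformed) max-normalization, tau(c*row) = tau(row)."""
        row = rng.uniform(0, 50, 27)
        assert tau(3.7 * row, transform="raw") == pytest.approx(
            tau(row, transform="raw"), abs=1e-12
        )

    def test_single_tissue_rejected(self):
        with pytest.raises(ValueError):
            tau([1.0])


class TestStratifyGenes:
    def make_table(self, rows, ids=None):
        n = len(rows[0])
        return ExpressionTable(
            pd.DataFrame(
                rows,
                index=ids or [f"g{i}" for i in range(len(rows))],
                columns=[f"t{j}" for j in range(n)],
            )
        )

    def test_extreme_classes(self):
        table = self.make_table(
            [[10.0] * 27, [0.0] * 26 + [100.0], [0.0] * 27]
        )
        out = stratify_genes(table)
        assert list(out["expression_class"]) == [
            "housekeeping", "tissue_specific", "undefined"
        ]
        assert np.isnan(out.loc[2, "tau"])

    def test_threshold_values_are_intermediate(self):
        """Strict inequalities: tau equal to a cut-point is intermediate."""
        table = self.make_table([[8.0, 2.0, 0.5, 0.5]])
        t = stratify_genes(table).loc[0, "tau"]
        out = stratify_genes(table, thresholds=(t, 0.9))
        assert out.loc[0, "expression_class"] == "intermediate"
        out = stratify_genes(table, thresholds=(0.1, t))
        assert out.loc[0, "expression_class"] == "intermediate"

    def test_mean_tpm_columns(self):
        table = self.make_table([[1.0, 3.0], [0.0, 0.0]])
        out = stratify_genes(table)
        assert out.loc[0, "mean_tpm"] == pytest.approx(2.0)
        assert out.loc[0, "log10_mean_tpm"] == pytest.approx(np.log10(2.0))
        assert np.isnan(out.loc[1, "log10_mean_tpm"])


class TestFamilyDensity:
    def test_single_tad_density(self):
        tads = pd.DataFrame(
            [{"tad_id": "t1", "chrom": "chr1", "start": 0, "end": 200_000, "family": "H2"}]
        )
        genes = fs(*[((("chr1", 10_000 * (i + 1), 10_000 * (i + 1) + 1000)), "gene", f"g{i}")
                     for i in range(4)])
        table = family_density_table(tads, {"gene": genes})
        assert table.loc["H2", "gene_per_100kb"] == pytest.approx(2.0)
        assert table["proportion"].sum() == pytest.approx(1.0)

    def test_zero_length_family_undefined(self):
        tads = pd.DataFrame(
            [{"tad_id": "t1", "chrom": "chr1", "start": 0, "end": 100_000, "family": "L1"}]
        )
        table = family_density_table(tads, {"gene": FeatureSet([])})
        assert np.isnan(table.loc["H3", "gene_per_100kb"])
        assert table.loc["L1", "gene_per_100kb"] == 0.0


class TestClassExpressionComparison:
    def make_inputs(self, counts_b, counts_c, length=100_000):
        rows, gene_rows, class_rows = [], [], []
        gid = 0
        pos = 0
        for cls, counts in (("B", counts_b), ("C", counts_c)):
            for i, n in enumerate(counts):
                tid = f"{cls}{i}"
                rows.append(
                    {"tad_id": tid, "start": pos, "end": pos + length,
                     "gradient_class": cls}
                )
                pos += length
                for _ in range(int(n)):
                    gene_rows.append(
                        {"feature_id": f"g{gid}", "tad_id": tid, "kind": "gene",
                         "rel_pos": 0.5, "band": "centre"}
                    )
                    class_rows.append(
                        {"gene_id": f"g{gid}", "expression_class": "housekeeping"}
                    )
                    gid += 1
        return (
            pd.DataFrame(rows),
            pd.DataFrame(gene_rows, columns=["feature_id", "tad_id", "kind", "rel_pos", "band"]),
            pd.DataFrame(class_rows, columns=["gene_id", "expression_class"]),
        )

    def test_identical_distributions_null(self):
        counts = list(range(10))
        tads, recs, classes = self.make_inputs(counts, counts)
        res = class_expression_comparison(tads, recs, classes)
        assert res.p_value == pytest.approx(1.0)

    def test_twofold_rate_detected(self, rng):
        tads, recs, classes = self.make_inputs(
            rng.poisson(4.0, 200), rng.poisson(2.0, 200)
        )
        res = class_expression_comparison(tads, recs, classes)
        assert res.p_value < 0.01
        assert res.densities_a.mean() > res.densities_b.mean()

    def test_single_tad_class_rejected(self):
        tads, recs, classes = self.make_inputs([3], [1, 2])
        with pytest.raises(ValueError, match=">= 2"):
            class_expression_comparison(tads, recs, classes)
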