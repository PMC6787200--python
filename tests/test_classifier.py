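"""GC-gradient classifier: half correlations, class mapping, perturbation,
sub-structure enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tadgc.classifier import (
    CLASSES,
    ClassifierConfig,
    InsufficientBinsError,
    PerturbationConfig,
    classify,
    classify_all,
    classify_profile,
    half_correlations,
    perturb_and_reclassify,
    stay_rates,
    substructure_enrichment,
)
from tadgc.composition import tad_gc_profile
from tadgc.intervals import Feature, FeatureSet, GenomicInterval
from tadgc.synth import SyntheticConfig, make_gc_target_profile, synthesize_genome

import pandas as pd


def pearson_oracle(x, y):
    """From-scratch covariance-formula Pearson r."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))


class TestHalfCorrelations:
    def test_perfect_ramp(self):
        r1, r2 = half_correlations(np.linspace(40, 46, 100))
        assert r1 == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_symmetric_triangle(self):
        x = np.arange(100)
        tri = 50.0 - np.abs(x - 49.5) / 10
        r1, r2 = half_correlations(tri)
        assert r1 == pytest.approx(1.0) and r2 == pytest.approx(-1.0)

    def test_constant_is_zero(self):
        assert half_correlations(np.full(100, 42.0)) == (0.0, 0.0)

    def test_masked_bins_dropped_pairwise(self, rng):
        bins = np.linspace(30, 50, 100) + rng.normal(0, 2, 100)
        masked = bins.copy()
        masked[[3, 17, 60, 88]] = np.nan
        r1, r2 = half_correlations(masked)
        idx = np.arange(100, dtype=float)
        ok1 = ~np.isnan(masked[:50])
        assert r1 == pytest.approx(
            pearson_oracle(idx[:50][ok1], masked[:50][ok1]), abs=1e-12
        )

    def test_too_few_unmasked_raises(self):
        bins = np.full(100, np.nan)
        bins[:50] = 40.0
        bins[50:53] = [40, 41, 42]
        half_correlations(bins)  # exactly 3 is enough
        bins[52] = np.nan
        with pytest.raises(InsufficientBinsError):
            half_correlations(bins)

    def test_matches_covariance_oracle(self, rng):
        for _ in range(200):
            bins = rng.uniform(30, 60, 100)
            r1, r2 = half_correlations(bins)
            assert r1 == pytest.approx(pearson_oracle(np.arange(50), bins[:50]), abs=1e-12)
            assert r2 == pytest.approx(pearson_oracle(np.arange(50), bins[50:]), abs=1e-12)


class TestClassify:
    @pytest.mark.parametrize(
        "r1,r2,expected",
        [
            (0.9, -0.9, "B"),
            (-0.9, 0.9, "C"),
            (-0.2, 0.3, "D"),
            (0.9, 0.9, "A"),
            (-0.9, -0.9, "A"),
            (0.7, 0.1, "B-"),
            (-0.1, -0.7, "B-"),
            (-0.7, 0.1, "C-"),
            (0.1, 0.7, "C-"),
            (0.4, 0.4, "A"),  # threshold value is non-flat
            (0.39, -0.39, "D"),
        ],
    )
    def test_sign_table(self, r1, r2, expected):
        assert classify(r1, r2) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify(1.5, 0.0)

    def test_partition_is_exhaustive(self):
        for r1 in np.linspace(-1, 1, 21):
            for r2 in np.linspace(-1, 1, 21):
                assert classify(r1, r2) in CLASSES

    @given(
        bins=st.lists(
            st.floats(0, 100, allow_nan=False), min_size=100, max_size=100
        )
    )
    @settings(max_examples=300, deadline=None)
    def test_orientation_equivalence(self, bins):
        """Reversing a profile never changes its class."""
        bins = np.array(bins)
        assert classify_profile(bins)[0] == classify_profile(bins[::-1])[0]

    def test_affine_invariance(self, rng):
        """GC -> a*GC + b (a > 0) preserves the class (Pearson r does)."""
        for _ in range(50):
            bins = 45 + np.cumsum(rng.normal(0, 2, 100))
            base = classify_profile(bins)[0]
            for a, b in [(0.5, 10.0), (2.0, -5.0), (3.0, 0.0)]:
                assert classify_profile(a * bins + b)[0] == base

    def test_noiseless_shapes_recovered(self, rng):
        for cls in CLASSES:
            profile = make_gc_target_profile(cls, 100, 45.0, 6.0, rng)
            assert classify_profile(profile)[0] == cls

    def test_weak_half_threshold_converts_minus_classes(self, rng):
        """B-/C- are attenuated B/C: lowering the flat threshold below the
        realized |r| of the weak half upgrades them."""
        profile = make_gc_target_profile("B-", 100, 45.0, 6.0, rng)
        # give the plateau noise plus a weak bell-ward drift so its |r| is
        # small but nonzero: downward drift when the plateau is the second
        # half, upward when it is the first
        strong_first = np.std(profile[:50]) > np.std(profile[50:])
        drift = np.linspace(0, 0.6, 50) + rng.normal(0, 0.6, 50)
        if strong_first:
            profile[50:] -= drift
        else:
            profile[:50] += drift
        label, r1, r2 = classify_profile(profile)
        assert label == "B-"
        weak = min(abs(r1), abs(r2))
        assert 0 < weak < 0.4
        lowered = ClassifierConfig(flat_threshold=weak * 0.9)
        assert classify(r1, r2, lowered) == "B"


class TestClassifyAll:
    def test_frequency_rows_sum_to_one(self, suite_classification):
        props = suite_classification.proportions.dropna(how="all")
        assert np.allclose(props.sum(axis=1), 1.0)

    def test_mix_recovered_within_tolerance(self, suite, suite_classification):
        """Observed class proportions track the generating mix at noise sd 1."""
        props = suite_classification.proportions.loc["all"]
        for cls in CLASSES:
            assert props[cls] == pytest.approx(1 / 6, abs=0.03)

    def test_excluded_tads_reported(self):
        genome = {"chr1": "N" * 5000 + "ACGT" * 2500}
        profiles = [
            tad_gc_profile(genome, GenomicInterval("chr1", 0, 5000), tad_id="gap"),
            tad_gc_profile(genome, GenomicInterval("chr1", 5000, 15000), tad_id="ok"),
        ]
        res = classify_all(profiles)
        assert list(res.excluded["tad_id"]) == ["gap"]
        assert list(res.per_tad["tad_id"]) == ["ok"]


def _flat_flank_config(**overrides):
    base = dict(
        n_chroms=2,
        n_tads=12,
        tad_length_range=(210_000, 300_000),
        gap_length_range=(110_000, 130_000),
        class_mix={"D": 1.0},
        mean_gc_range=(40.0, 40.0),
        bin_noise_sd=0.0,
        background_gc=40.0,
        seed=11,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


class TestPerturbation:
    def test_noiseless_d_tads_stay_d(self):
        """Flat TADs in matched flat flanks are insensitive to +/-50 kb."""
        config = _flat_flank_config()
        genome, tads = synthesize_genome(config)
        profiles = [
            tad_gc_profile(genome, GenomicInterval(r.chrom, r.start, r.end), tad_id=r.tad_id)
            for r in tads.itertuples(index=False)
        ]
        mats = perturb_and_reclassify(profiles, genome)
        for mode in ("expand", "shrink"):
            assert mats[mode].loc["D", "D"] == len(tads)
            assert stay_rates(mats[mode])["D"] == 1.0

    def test_transition_rows_conserve_counts(self, suite, suite_classification):
        profiles = suite.profiles[:120]
        mats = perturb_and_reclassify(profiles, suite.genome)
        labels = [classify_profile(p.bins)[0] for p in profiles]
        orig_counts = pd.Series(labels).value_counts()
        for mat in mats.values():
            for cls in CLASSES:
                assert mat.loc[cls].sum() == orig_counts.get(cls, 0)

    def test_expanded_bell_stays_bell_like(self):
        """A bell TAD expanded into flat flanks lands in B or B-."""
        config = _flat_flank_config(class_mix={"B": 1.0}, gradient_amplitude=6.0)
        genome, tads = synthesize_genome(config)
        profiles = [
            tad_gc_profile(genome, GenomicInterval(r.chrom, r.start, r.end), tad_id=r.tad_id)
            for r in tads.itertuples(index=False)
        ]
        mat = perturb_and_reclassify(
            profiles, genome, PerturbationConfig(modes=("expand",))
        )["expand"]
        assert mat.loc["B", ["B", "B-"]].sum() == len(tads)

    def test_short_tads_counted_excluded(self):
        genome = {"chr1": "ACGT" * 50_000}
        profiles = [
            tad_gc_profile(genome, GenomicInterval("chr1", 0, 60_000), tad_id="short")
        ]
        mat = perturb_and_reclassify(
            profiles, genome, PerturbationConfig(delta=50_000, modes=("shrink",))
        )["shrink"]
        assert mat["excluded"].sum() == 1


def _tads_frame(n_per_class, length=100_000):
    rows = []
    pos = 0
    for cls in ("B", "C"):
        for i in range(n_per_class):
            rows.append(
                {
                    "tad_id": f"{cls}{i}",
                    "chrom": "chr1",
                    "start": pos,
                    "end": pos + length,
                    "gradient_class": cls,
                }
            )
            pos += length + 10_000
    return pd.DataFrame(rows)


def _subtad_set(per_tad, counts):
    feats = []
    k = 0
    for row, n in zip(per_tad.itertuples(index=False), counts):
        for _ in range(int(n)):
            feats.append(
                Feature(
                    GenomicInterval(row.chrom, row.start + 100 + 50 * k % 1000,
                                    row.start + 5_000 + 50 * (k % 1000)),
                    "sub_tad",
                    f"s{k}",
                )
            )
            k += 1
    return FeatureSet(feats)


class TestSubstructureEnrichment:
    def test_identical_distributions_null(self):
        per_tad = _tads_frame(50)
        counts = list(range(50)) * 2  # same multiset in both classes
        res = substructure_enrichment(per_tad, _subtad_set(per_tad, [c % 5 for c in counts]))
        assert res.ratio == pytest.approx(1.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_threefold_rate_recovered(self, rng):
        per_tad = _tads_frame(200)
        counts = np.concatenate(
            [rng.poisson(1.2, 200), rng.poisson(0.4, 200)]
        )
        res = substructure_enrichment(per_tad, _subtad_set(per_tad, counts))
        assert 2.5 <= res.ratio <= 3.5
        assert res.p_value < 0.01

    def test_zero_reference_class_flagged(self):
        per_tad = _tads_frame(5)
        counts = [2, 3, 1, 2, 4] + [0] * 5
        res = substructure_enrichment(per_tad, _subtad_set(per_tad, counts))
        assert np.isnan(res.ratio)

    def test_single_member_class_rejected(self):
        per_tad = _tads_frame(30)
        per_tad = per_tad[per_tad["gradient_class"].eq("B") | per_tad["tad_id"].eq("C0")]
        with pytest.raises(ValueError, match=">= 2"):
            substructure_enrichment(per_tad, _subtad_set(per_tad, [1] * len(per_tad)))
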