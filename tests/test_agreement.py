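"""Weighted Bland-Altman, percentage error and interchangeability verdicts."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemoconcord.agreement import (
    PairedSample,
    Verdict,
    bland_altman,
    interchangeability_verdict,
    percentage_error,
    percentage_error_single,
)


def samples_from(spec):
    """spec: {animal: [(ref, dut), ...]}"""
    out = []
    for animal, pairs in spec.items():
        for k, (r, d) in enumerate(pairs):
            out.append(PairedSample(animal, 5.0 * k, r, d))
    return out


#: Two animals with opposite constant offsets and unequal pair counts; the
#: equal-animal weighting makes the bias 0 while the plain mean would be
#: -0.1333.
WORKED_EXAMPLE = {
    "A": [(5.0, 5.4), (5.0, 5.4)],
    "B": [(5.0, 4.6), (5.0, 4.6), (5.0, 4.6), (5.0, 4.6)],
}


def oracle_two_level(spec):
    """Brute-force one-way random-effects decomposition of the differences."""
    d_by = {a: [d - r for r, d in pairs] for a, pairs in spec.items()}
    A = len(d_by)
    N = sum(len(v) for v in d_by.values())
    means = {a: sum(v) / len(v) for a, v in d_by.items()}
    bias = sum(means.values()) / A
    ssw = sum(sum((x - means[a]) ** 2 for x in v) for a, v in d_by.items())
    s2w = ssw / (N - A)
    grand = sum(len(v) * means[a] for a, v in d_by.items()) / N
    msb = sum(len(v) * (means[a] - grand) ** 2 for a, v in d_by.items()) / (A - 1)
    n0 = (N - sum(len(v) ** 2 for v in d_by.values()) / N) / (A - 1)
    s2b = max(0.0, (msb - s2w) / n0)
    sd = np.sqrt(s2w + s2b)
    return bias, sd


class TestBlandAltman:
    def test_all_zero_differences_degenerate(self, caplog):
        spec = {"A": [(5.0, 5.0)] * 3, "B": [(6.0, 6.0)] * 3}
        with caplog.at_level("WARNING"):
            rep = bland_altman(samples_from(spec))
        assert rep.bias == 0.0
        assert (rep.loa_low, rep.loa_high) == (0.0, 0.0)
        assert rep.pe_overall == 0.0
        assert rep.degenerate_variance

    def test_worked_example_matches_brute_force_oracle(self):
        rep = bland_altman(samples_from(WORKED_EXAMPLE))
        bias, sd = oracle_two_level(WORKED_EXAMPLE)
        assert rep.bias == pytest.approx(bias, abs=1e-10)
        assert rep.bias == pytest.approx(0.0, abs=1e-10)
        assert rep.sd_total == pytest.approx(sd, abs=1e-10)
        assert rep.loa_low == pytest.approx(bias - 1.96 * sd, abs=1e-10)
        assert rep.loa_high == pytest.approx(bias + 1.96 * sd, abs=1e-10)
        # hand-computed values for this 6-pair set
        assert sd == pytest.approx(np.sqrt(0.32), abs=1e-12)
        assert rep.n_pairs == 6 and rep.n_animals == 2

    def test_random_samples_match_oracle(self, rng):
        spec = {f"a{i}": [(rng.uniform(4, 7), rng.uniform(4, 7))
                          for _ in range(rng.integers(3, 30))]
                for i in range(6)}
        rep = bland_altman(samples_from(spec))
        bias, sd = oracle_two_level(spec)
        assert rep.bias == pytest.approx(bias, abs=1e-10)
        assert rep.sd_total == pytest.approx(sd, abs=1e-10)

    def test_equal_counts_weighted_bias_equals_plain_mean(self, rng):
        spec = {f"a{i}": [(rng.uniform(4, 7), rng.uniform(4, 7))
                          for _ in range(10)] for i in range(5)}
        rep = bland_altman(samples_from(spec))
        plain = np.mean([d - r for pairs in spec.values() for r, d in pairs])
        assert rep.bias == pytest.approx(plain, abs=1e-12)

    def test_single_animal_directed_to_unweighted_variant(self):
        with pytest.raises(ValueError, match="single animal"):
            bland_altman(samples_from({"A": [(5, 5.1), (5, 5.2)]}))

    def test_invariant_under_relabeling_and_constant_shift(self, rng):
        spec = {f"a{i}": [(rng.uniform(4, 7), rng.uniform(4, 7))
                          for _ in range(8)] for i in range(4)}
        rep = bland_altman(samples_from(spec))
        relabeled = {f"z{9 - i}": v for i, (_, v) in enumerate(spec.items())}
        shifted = {a: [(r + 2.0, d + 2.0) for r, d in v]
                   for a, v in relabeled.items()}
        rep2 = bland_altman(samples_from(shifted))
        assert rep2.bias == pytest.approx(rep.bias, abs=1e-12)
        assert rep2.sd_total == pytest.approx(rep.sd_total, abs=1e-12)

    def test_gaussian_simulation_recovers_parameters(self):
        """d ~ N(0.2, 0.5^2): bias and LoA estimates cover the truth."""
        hits_bias = hits_loa = 0
        n_rep = 60
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            spec = {f"a{i}": [(5.0, 5.0 + r.normal(0.2, 0.5))
                              for _ in range(100)] for i in range(20)}
            rep = bland_altman(samples_from(spec))
            hits_bias += rep.ci_bias[0] <= 0.2 <= rep.ci_bias[1]
            hits_loa += (rep.ci_loa_low[0] <= 0.2 - 0.98 <= rep.ci_loa_low[1]
                         and rep.ci_loa_high[0] <= 0.2 + 0.98 <= rep.ci_loa_high[1])
        assert hits_bias >= 0.9 * n_rep
        assert hits_loa >= 0.9 * n_rep


class TestPercentageError:
    def test_closed_form_case(self):
        # per-animal differences [1, -1, 0]: two-level SD exactly 1.0
        spec = {a: [(5.0, 6.0), (5.0, 4.0), (5.0, 5.0)] for a in "AB"}
        pe = percentage_error(samples_from(spec))
        assert pe == pytest.approx(100 * 1.96 * 1.0 / 5.0)  # 39.2

    def test_self_comparison_is_zero(self):
        spec = {a: [(5.0, 5.0)] * 4 for a in "AB"}
        assert percentage_error(samples_from(spec)) == 0.0

    def test_single_animal_uses_plain_sd(self, rng):
        pairs = [(float(r), float(d)) for r, d in
                 zip(rng.uniform(4, 7, 50), rng.uniform(4, 7, 50))]
        pe = percentage_error_single(samples_from({"A": pairs}))
        d = np.array([d - r for r, d in pairs])
        refs = np.array([r for r, _ in pairs])
        assert pe == pytest.approx(100 * 1.96 * d.std(ddof=1) / refs.mean())

    def test_nonpositive_reference_mean_rejected(self):
        spec = {a: [(-5.0, -5.1), (-5.0, -4.9)] for a in "AB"}
        with pytest.raises(ValueError, match="positive"):
            percentage_error(samples_from(spec))


class TestVerdict:
    @pytest.mark.parametrize("pe,expected", [
        (26.1, Verdict.ICO_INTERCHANGEABLE),
        (30.0, Verdict.ICO_INTERCHANGEABLE),   # boundary inclusive
        (34.6, Verdict.CCO_PRACTICAL),
        (42.0, Verdict.CCO_PRACTICAL),          # boundary inclusive
        (42.1, Verdict.NOT_MET),
        (0.0, Verdict.ICO_INTERCHANGEABLE),
    ])
    def test_thresholds(self, pe, expected):
        assert interchangeability_verdict(pe) is expected

    def test_negative_pe_rejected(self):
        with pytest.raises(ValueError):
            interchangeability_verdict(-1.0)
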