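import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from taxalink import best_hits, normalize_profiles, pearson_cross, prevalence_filter
from taxalink.errors import ValidationError
from taxalink.linking import (
    DEFAULT_CUTOFF,
    DEFAULT_MIN_PREVALENCE,
    DEFAULT_PSEUDOCOUNT,
    read_links,
    write_links,
)

from conftest import make_counts


def naive_pearson(x, y):
    """Textbook covariance / sigma-sigma oracle."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    if sx == 0 or sy == 0:
        return None
    return cov / (sx * sy)


class TestNormalizeProfiles:
    def test_half_half_column(self):
        m = make_counts([[1], [1]])
        out = normalize_profiles(m)
        expected = math.log10(0.5 + 1e-17)
        assert np.allclose(out.iloc[:, 0], expected)
        assert out.iloc[0, 0] == pytest.approx(-0.30103, abs=1e-5)

    def test_zero_count_maps_exactly_to_minus_17(self):
        m = make_counts([[0, 5], [10, 5]])
        out = normalize_profiles(m)
        assert out.iloc[0, 0] == math.log10(1e-17) == -17.0

    def test_default_pseudocount(self):
        assert DEFAULT_PSEUDOCOUNT == 1e-17

    def test_all_zero_column_rejected_naming_sample(self):
        m = make_counts([[1, 0]], samples=["ok", "empty"])
        with pytest.raises(ValidationError, match="empty"):
            normalize_profiles(m)

    def test_nonpositive_pseudocount_rejected(self):
        with pytest.raises(ValidationError):
            normalize_profiles(make_counts([[1]]), pseudocount=0)

    def test_accepts_real_valued_profiles(self):
        df = pd.DataFrame([[0.2, 0.5], [0.6, 0.5]], columns=["s1", "s2"])
        out = normalize_profiles(df)
        assert out.iloc[0, 0] == pytest.approx(math.log10(0.25), abs=1e-12)


class TestPrevalenceFilter:
    def test_strict_inequality_at_threshold(self):
        n_samples = 138
        row10 = [1] * 10 + [0] * (n_samples - 10)
        row11 = [1] * 11 + [0] * (n_samples - 11)
        m = make_counts([row10, row11], rows=["ten", "eleven"])
        filtered, dropped = prevalence_filter(m, 10)
        assert dropped == ["ten"]
        assert filtered.row_ids == ["eleven"]

    def test_all_zero_row_dropped(self):
        m = make_counts([[0] * 20, [1] * 20], rows=["empty", "full"])
        filtered, dropped = prevalence_filter(m, 10)
        assert dropped == ["empty"]

    def test_default_threshold(self):
        assert DEFAULT_MIN_PREVALENCE == 10

    def test_real_valued_rows_use_strict_positivity(self):
        df = pd.DataFrame([[0.0] * 11 + [1e-9] * 11, [0.0] * 22],
                          index=["tiny", "zero"])
        filtered, dropped = prevalence_filter(df, 10)
        assert list(filtered.index) == ["tiny"]
        assert dropped == ["zero"]


class TestPearsonCross:
    def test_self_correlation_is_one(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0, 5.0]], index=["a"])
        assert pearson_cross(df, df).loc["a", "a"] == pytest.approx(1.0, abs=1e-12)

    def test_exact_linearity(self):
        a = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["x"])
        b = pd.DataFrame([[2.0, 4.0, 6.0, 8.0], [8.0, 6.0, 4.0, 2.0]],
                         index=["up", "down"])
        corr = pearson_cross(a, b)
        assert corr.loc["x", "up"] == pytest.approx(1.0, abs=1e-12)
        assert corr.loc["x", "down"] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        a = pd.DataFrame(rng.integers(0, 10, size=(3, 6)).astype(float),
                         index=["a0", "a1", "a2"])
        b = pd.DataFrame(rng.integers(0, 10, size=(3, 6)).astype(float),
                         index=["b0", "b1", "b2"])
        corr = pearson_cross(a, b)
        for i in a.index:
            for j in b.index:
                expected = naive_pearson(list(a.loc[i]), list(b.loc[j]))
                if expected is None:
                    assert np.isnan(corr.loc[i, j])
                else:
                    assert corr.loc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_row_undefined(self):
        a = pd.DataFrame([[1.0, 1.0, 1.0]], index=["flat"])
        b = pd.DataFrame([[1.0, 2.0, 3.0]], index=["var"])
        assert np.isnan(pearson_cross(a, b).loc["flat", "var"])

    def test_sample_mismatch_rejected(self):
        a = pd.DataFrame([[1.0, 2.0, 3.0]], columns=["s1", "s2", "s3"])
        b = pd.DataFrame([[1.0, 2.0, 3.0]], columns=["s1", "s3", "s2"])
        with pytest.raises(ValidationError, match="sample"):
            pearson_cross(a, b)

    def test_too_few_samples_rejected(self):
        a = pd.DataFrame([[1.0, 2.0]])
        with pytest.raises(ValidationError, match="3 samples"):
            pearson_cross(a, a)

    @given(arrays(np.int64, (4, 8), elements=st.integers(min_value=0, max_value=50)))
    def test_log_base_invariance(self, values):
        """Pearson on log profiles is identical under log10 and natural log."""
        m = make_counts(values + 1)  # avoid all-zero columns
        base10 = normalize_profiles(m)
        ratios = (values + 1) / (values + 1).sum(axis=0)
        natural = pd.DataFrame(np.log(ratios + 1e-17), index=base10.index,
                               columns=base10.columns)
        c10 = pearson_cross(base10, base10).to_numpy()
        cn = pearson_cross(natural, natural).to_numpy()
        assert np.allclose(c10, cn, atol=1e-12, equal_nan=True)


class TestBestHits:
    def test_single_candidate(self):
        corr = pd.DataFrame([[0.9]], index=["q"], columns=["A"])
        (link,) = best_hits(corr)
        assert (link.best_id, link.best_r) == ("A", 0.9)
        assert link.second_id is None and link.second_r is None
        assert link.passes_cutoff and link.n_candidates == 1

    def test_tie_broken_lexicographically(self):
        corr = pd.DataFrame([[0.10, 0.70, 0.70]], index=["q"],
                            columns=["C", "B", "A"])
        (link,) = best_hits(corr, cutoff=0.65)
        assert link.best_id == "A" and link.second_id == "B"
        assert link.best_r == link.second_r == 0.70
        assert link.passes_cutoff

    def test_default_cutoff(self):
        assert DEFAULT_CUTOFF == 0.65

    def test_cutoff_is_inclusive(self):
        corr = pd.DataFrame([[0.65]], index=["q"], columns=["A"])
        assert best_hits(corr)[0].passes_cutoff

    def test_all_undefined_query_yields_missing_best(self):
        corr = pd.DataFrame([[np.nan, np.nan]], index=["q"], columns=["A", "B"])
        (link,) = best_hits(corr)
        assert link.best_id is None and not link.passes_cutoff
        assert link.n_candidates == 0

    def test_query_cols_direction_transposes(self):
        corr = pd.DataFrame([[0.9], [0.1]], index=["A", "B"], columns=["q"])
        (link,) = best_hits(corr, direction="query_cols")
        assert link.query_id == "q" and link.best_id == "A"

    def test_matches_exhaustive_search_on_random_tables(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n, m = rng.integers(1, 11, size=2)
            values = np.round(rng.uniform(-1, 1, size=(n, m)), 2)
            # sprinkle undefined entries
            mask = rng.random(values.shape) < 0.1
            values[mask] = np.nan
            corr = pd.DataFrame(values, index=[f"q{i}" for i in range(n)],
                                columns=[f"c{j}" for j in range(m)])
            for link in best_hits(corr, cutoff=0.5):
                row = corr.loc[link.query_id]
                defined = sorted(
                    [(c, row[c]) for c in corr.columns if not np.isnan(row[c])],
                    key=lambda t: (-t[1], t[0]),
                )
                if not defined:
                    assert link.best_id is None
                    continue
                assert (link.best_id, link.best_r) == defined[0]
                if len(defined) > 1:
                    assert (link.second_id, link.second_r) == defined[1]
                assert link.passes_cutoff == (defined[0][1] >= 0.5)
                assert link.n_candidates == len(defined)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        corr = pd.DataFrame(rng.uniform(-1, 1, size=(3, 6)),
                            index=["q0", "q1", "q2"],
                            columns=[f"c{j}" for j in range(6)])
        base = best_hits(corr)
        perm = corr[rng.permutation(corr.columns)]
        assert best_hits(perm) == base

    def test_best_r_never_below_second_r(self):
        rng = np.random.default_rng(13)
        corr = pd.DataFrame(rng.uniform(-1, 1, size=(10, 10)))
        for link in best_hits(corr):
            if link.second_r is not None:
                assert link.best_r >= link.second_r

    def test_passing_count_monotone_in_cutoff(self):
        rng = np.random.default_rng(17)
        corr = pd.DataFrame(rng.uniform(-1, 1, size=(20, 8)))
        counts = [
            sum(l.passes_cutoff for l in best_hits(corr, cutoff=c))
            for c in np.linspace(-1, 1.05, 12)
        ]
        assert counts == sorted(counts, reverse=True)


def test_links_table_round_trip(tmp_path):
    corr = pd.DataFrame([[0.9, 0.3], [np.nan, np.nan]], index=["q1", "q2"],
                        columns=["A", "B"])
    links = best_hits(corr)
    path = tmp_path / "links.tsv"
    write_links(links, path)
    assert read_links(path) == links
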